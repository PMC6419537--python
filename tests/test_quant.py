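"""Per-cell quantification: background, segmentation, QC, MCC, ratios."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ciliaflow import (
    CompartmentState,
    ImagingParams,
    QuantSettings,
    RegionSet,
    VoxelStack,
    cilium_qc,
    manders_mcc,
    quantify_cell,
    render_stack,
    segment_cilium,
    subtract_background,
    surface_total_ratio,
)

from conftest import FAST, quantify_truth, regions_from_truth


def _stack(data, names=("gfp",), voxel=(0.3, 0.1, 0.1)):
    return VoxelStack(np.asarray(data, dtype=np.float64), tuple(names), voxel)


# ---------------------------------------------------------------- background


def test_constant_background_subtracts_to_zero():
    data = np.full((1, 4, 8, 8), 7.0)
    region = np.zeros((4, 8, 8), dtype=bool)
    region[:, :2, :2] = True
    out = subtract_background(_stack(data), RegionSet(background={"bg": region}))
    assert np.all(out.data == 0.0)
    assert out.metadata["background_counts"]["gfp"] == 7.0


def test_subtraction_clips_negative_values():
    data = np.full((1, 1, 4, 4), 5.0)
    data[0, 0, 0, 0] = 20.0
    region = np.zeros((1, 4, 4), dtype=bool)
    region[0, 2:, 2:] = True  # mean over region = 5 -> most voxels go to 0...
    data[0, 0, 2:, 2:] = 10.0  # region mean 10 > voxel value 5
    out = subtract_background(_stack(data), RegionSet(background={"bg": region}))
    assert out.data.min() == 0.0
    assert out.data[0, 0, 0, 0] == 10.0


def test_empty_background_region_rejected():
    region = np.zeros((1, 4, 4), dtype=bool)
    with pytest.raises(ValueError, match="empty"):
        subtract_background(_stack(np.ones((1, 1, 4, 4))), RegionSet(background={"bg": region}))


def test_background_region_overlapping_cell_warns():
    region = np.ones((1, 4, 4), dtype=bool)
    cell = np.zeros((1, 4, 4), dtype=bool)
    cell[0, 1, 1] = True
    rs = RegionSet(background={"bg": region}, cell_mask=cell)
    with pytest.warns(UserWarning, match="overlaps"):
        subtract_background(_stack(np.ones((1, 1, 4, 4))), rs)


def test_background_estimate_unbiased_on_renders(geometry, saturated_state, voxelized_fast, basis_fast):
    """Post-subtraction mean over an empty region stays within +-3 counts."""
    residuals = []
    for seed in range(10):
        img = FAST.with_(seed=seed)
        stack, truth = render_stack(
            geometry, saturated_state, img, voxelized=voxelized_fast, blur_basis=basis_fast
        )
        nb = truth.background_region()
        # estimate from one half of the neighbors, check the other half
        half = np.zeros_like(nb)
        half[:, :, : nb.shape[2] // 2] = True
        est_region, check_region = nb & half, nb & ~half
        sub = subtract_background(stack, RegionSet(background={"bg": est_region}))
        estimate = sub.metadata["background_counts"]["gfp"]
        residuals.append(float(stack.channel("gfp")[check_region].mean()) - estimate)
    assert -3.0 < np.mean(residuals) < 3.0


def test_background_idempotence(geometry, saturated_state, voxelized_fast, basis_fast):
    """A second background estimate on an already-subtracted image is ~0."""
    stack, truth = render_stack(
        geometry, saturated_state, FAST.with_(seed=5), voxelized=voxelized_fast, blur_basis=basis_fast
    )
    rs = RegionSet(background={"bg": truth.background_region()})
    once = subtract_background(stack, rs)
    second_estimate = once.metadata["background_counts"]["gfp"]
    twice = subtract_background(once, rs)
    assert twice.metadata["background_counts"]["gfp"] < 0.05 * second_estimate or (
        twice.metadata["background_counts"]["gfp"] < 5.0
    )


# -------------------------------------------------------------- segmentation


def test_segmentation_overlaps_ground_truth(rendered_saturated, geometry):
    stack, truth = rendered_saturated
    sub = subtract_background(stack, regions_from_truth(truth))
    mask = segment_cilium(sub.channel("cilium"), stack.voxel_size, geometry.apical_z)
    gt = truth.cilium_support
    jaccard = (mask & gt).sum() / (mask | gt).sum()
    assert jaccard > 0.5


def test_all_zero_channel_gives_empty_mask():
    mask = segment_cilium(np.zeros((5, 8, 8)), (0.3, 0.1, 0.1), apical_z_um=1.0)
    assert mask.sum() == 0


def test_intracellular_component_rejected():
    """Of two bright blobs, only the one protruding above the apical plane is kept."""
    chan = np.zeros((20, 16, 16))
    chan[2:6, 4:6, 4:6] = 100.0  # below the apical plane: intracellular mimic
    chan[12:19, 10:12, 10:12] = 80.0  # protruding: the true cilium (dimmer, larger)
    mask = segment_cilium(chan, (0.3, 0.1, 0.1), apical_z_um=3.0, threshold=50.0)
    zs = np.nonzero(mask)[0]
    assert zs.min() >= 12
    assert mask[2:6, 4:6, 4:6].sum() == 0


# ------------------------------------------------------------------------ QC


def test_vertical_cilium_passes_qc():
    mask = np.zeros((30, 8, 8), dtype=bool)
    mask[10:22, 4, 4] = True  # 3.6 µm vertical, apical plane at 3 µm
    ok, reason = cilium_qc(mask, apical_z_um=3.0, voxel_size=(0.3, 0.1, 0.1))
    assert ok and reason == ""


def test_flat_cilium_fails_as_sharply_tilted():
    mask = np.zeros((30, 64, 8), dtype=bool)
    mask[11, 10:40, 4] = True  # lies in one z-plane above the apical plane
    ok, reason = cilium_qc(mask, apical_z_um=3.0, voxel_size=(0.3, 0.1, 0.1))
    assert not ok
    assert "tilted" in reason


def test_empty_mask_fails_qc():
    ok, reason = cilium_qc(np.zeros((5, 5, 5), dtype=bool), 1.0, (0.3, 0.1, 0.1))
    assert not ok
    assert "no cilium" in reason


def test_short_stub_fails_protrusion():
    mask = np.zeros((30, 8, 8), dtype=bool)
    mask[10:12, 4, 4] = True  # 0.6 µm only
    ok, reason = cilium_qc(mask, apical_z_um=3.0, voxel_size=(0.3, 0.1, 0.1))
    assert not ok
    assert "protrusion" in reason


# ----------------------------------------------------------------------- MCC


def test_mcc_is_one_when_all_signal_in_mask():
    gfp = np.zeros((4, 4, 4))
    gfp[1, 1, 1] = 10.0
    mask = np.zeros_like(gfp, dtype=bool)
    mask[1, 1, 1] = True
    assert manders_mcc(gfp, mask) == 1.0


def test_mcc_uniform_signal_is_mask_fraction():
    gfp = np.ones((5, 6, 7))
    mask = np.zeros_like(gfp, dtype=bool)
    mask.ravel()[:42] = True
    assert manders_mcc(gfp, mask) == pytest.approx(42 / gfp.size, rel=1e-12)


def test_mcc_random_delivery_bound():
    """Uniform reporter at a 1/2700 volume ratio gives MCC 3.70e-4 < 4e-4."""
    gfp = np.ones((27, 10, 10))  # 2700 voxels
    mask = np.zeros_like(gfp, dtype=bool)
    mask[0, 0, 0] = True
    mcc = manders_mcc(gfp, mask)
    assert mcc == pytest.approx(3.70e-4, rel=5e-3)
    assert mcc < 4e-4


def test_mcc_zero_total_signal_is_error():
    with pytest.raises(ValueError, match="undefined"):
        manders_mcc(np.zeros((3, 3, 3)), np.ones((3, 3, 3), dtype=bool))


@settings(max_examples=25, deadline=None)
@given(st.integers(0, 2**31 - 1))
def test_mcc_matches_direct_summation_oracle(seed):
    """On small stacks the vectorized MCC equals an explicit double loop."""
    rng = np.random.default_rng(seed)
    shape = tuple(rng.integers(3, 21, size=3))
    gfp = rng.gamma(0.5, 50.0, size=shape)
    gfp[rng.random(shape) < 0.4] = 0.0
    mask = rng.random(shape) < 0.1
    if gfp.sum() == 0:
        gfp[0, 0, 0] = 1.0
    num = 0.0
    den = 0.0
    for idx in np.ndindex(shape):
        v = gfp[idx]
        if v > 0:
            den += v
            if mask[idx]:
                num += v
    expected = num / den
    assert manders_mcc(gfp, mask) == pytest.approx(expected, rel=1e-12)
    assert 0.0 <= manders_mcc(gfp, mask) <= 1.0


def test_mcc_additive_over_disjoint_masks():
    rng = np.random.default_rng(1)
    gfp = rng.gamma(1.0, 10.0, size=(10, 10, 10))
    mask = rng.random((10, 10, 10)) < 0.2
    full = np.ones_like(mask)
    mcc_mask = manders_mcc(gfp, mask)
    mcc_complement = manders_mcc(gfp, ~mask)
    mcc_full = manders_mcc(gfp, full)
    assert mcc_mask + mcc_complement == pytest.approx(mcc_full, rel=1e-12)
    assert mcc_full == pytest.approx(1.0)


# -------------------------------------------------------------------- ratios


def test_zero_surface_channel_gives_zero_ratio():
    gfp = np.ones((4, 4, 4))
    mask = np.ones_like(gfp, dtype=bool)
    assert surface_total_ratio(np.zeros_like(gfp), gfp, mask) == 0.0


def test_identical_channels_give_unit_ratio():
    rng = np.random.default_rng(2)
    gfp = rng.random((4, 4, 4)) + 0.1
    mask = np.ones_like(gfp, dtype=bool)
    assert surface_total_ratio(gfp, gfp, mask) == pytest.approx(1.0, rel=1e-12)


def test_surface_ratio_recovers_known_fraction(geometry, voxelized_fast, basis_fast):
    """A cell with 30% of the reporter on the stained side reads out 0.30 +- 0.02."""
    state = CompartmentState(
        time=1.0, er=0.40, apical_pm=0.30, basolateral_pm=0.25, cilium=0.0, internalized=0.05
    )
    vals = []
    for seed in range(10):
        stack, truth = render_stack(
            geometry, state, FAST.with_(seed=seed), voxelized=voxelized_fast, blur_basis=basis_fast
        )
        res = quantify_truth(stack, truth)
        vals.append({r.side: r.surface_ratio for r in res.records}["apical"])
    assert np.mean(vals) == pytest.approx(0.30, abs=0.02)


def test_zero_gfp_ratio_is_error():
    mask = np.ones((2, 2, 2), dtype=bool)
    with pytest.raises(ValueError, match="undefined"):
        surface_total_ratio(np.ones((2, 2, 2)), np.zeros((2, 2, 2)), mask)


# --------------------------------------------------------------- full chain


def test_time_zero_cell_has_no_surface_or_ciliary_signal(geometry, voxelized_fast, basis_fast):
    state = CompartmentState(time=0.0, er=1.0, apical_pm=0.0, basolateral_pm=0.0, cilium=0.0)
    stack, truth = render_stack(
        geometry, state, FAST.with_(seed=4), voxelized=voxelized_fast, blur_basis=basis_fast
    )
    res = quantify_truth(stack, truth)
    by_side = {r.side: r for r in res.records}
    assert by_side["apical"].surface_ratio == pytest.approx(0.0, abs=0.01)
    assert by_side["basolateral"].surface_ratio == pytest.approx(0.0, abs=0.01)
    rec = by_side["apical"]
    assert (not rec.qc_pass) or rec.mcc < 0.01


def test_saturated_cell_mcc_recovered(geometry, saturated_state, voxelized_default):
    """5% of reporter in the cilium is read back as MCC 0.05 +- 0.01."""
    vals = []
    for seed in range(3):
        stack, truth = render_stack(
            geometry, saturated_state, ImagingParams(seed=seed), voxelized=voxelized_default
        )
        res = quantify_truth(stack, truth)
        assert res.records[0].qc_pass
        vals.append(res.records[0].mcc)
    assert np.mean(vals) == pytest.approx(0.05, abs=0.01)


def test_tilted_cilium_fails_qc_but_keeps_ratios(saturated_state):
    geom_flat = __import__("ciliaflow").CellGeometry(cilium_tilt_deg=88.0)
    img = FAST.with_(seed=9)
    stack, truth = render_stack(geom_flat, saturated_state, img)
    res = quantify_truth(stack, truth)
    rec = res.records[0]
    assert not rec.qc_pass
    assert rec.mcc is None
    assert rec.surface_ratio is not None
    assert rec.qc_reason != ""


def test_quantify_requires_cell_mask(rendered_saturated):
    stack, truth = rendered_saturated
    rs = RegionSet(background={"bg": truth.background_region()})
    with pytest.raises(ValueError, match="cell mask"):
        quantify_cell(stack, rs, QuantSettings())
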