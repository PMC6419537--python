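"""Population statistics: ciliation ratio, time courses, slopes, paired test."""

import math

import numpy as np
import pytest

from ciliaflow import (
    CellQuantification,
    SlopeFit,
    build_timecourse,
    compare_slopes,
    fit_mcc_vs_surface,
    generate_population,
    normalized_ciliation_ratio,
)

from conftest import FAST, quantify_truth


def _rec(side, surface, mcc, rep="r0", t=1.0, cell="c0", qc=True):
    return CellQuantification(
        cell_id=cell, release_time_h=t, side=side, surface_ratio=surface,
        mcc=mcc, cilium_voxels=50, qc_pass=qc, replicate_id=rep,
    )


# ------------------------------------------------------------- ciliation


@pytest.mark.parametrize(
    "transfected,all_cells,expected",
    [(53.7, 75.0, 72), (38.1, 53.0, 72), (40.0, 40.0, 100), (9.1, 75.0, 12)],
)
def test_normalized_ciliation_ratio(transfected, all_cells, expected):
    assert normalized_ciliation_ratio(transfected, all_cells) == expected


def test_ciliation_ratio_validates_inputs():
    with pytest.raises(ValueError):
        normalized_ciliation_ratio(0.0, 50.0)
    with pytest.raises(ValueError):
        normalized_ciliation_ratio(50.0, 0.0)


# ------------------------------------------------------------ time course


def _series_records(values_by_rep, side="apical"):
    recs = []
    for rep, values in values_by_rep.items():
        for i, v in enumerate(values):
            recs.append(_rec(side, v, 0.01, rep=rep, t=float(i), cell=f"{rep}_c{i}"))
    return recs


def test_max_normalization():
    tc = build_timecourse(_series_records({"r0": [1.0, 2.0, 4.0]}), "apical")
    np.testing.assert_allclose(tc.normalized[0], [0.25, 0.5, 1.0])
    assert tc.normalized.max(axis=1) == pytest.approx(1.0)


def test_identical_replicates_have_zero_sem():
    tc = build_timecourse(
        _series_records({"r0": [1.0, 3.0, 2.0], "r1": [1.0, 3.0, 2.0]}), "apical"
    )
    np.testing.assert_allclose(tc.sem, 0.0)


def test_normalization_invariant_to_replicate_gain():
    base = {"r0": [1.0, 2.0, 4.0], "r1": [2.0, 3.0, 5.0]}
    scaled = {"r0": [7.0, 14.0, 28.0], "r1": [0.5, 0.75, 1.25]}
    a = build_timecourse(_series_records(base), "apical")
    b = build_timecourse(_series_records(scaled), "apical")
    np.testing.assert_allclose(a.normalized, b.normalized, rtol=1e-12)
    np.testing.assert_allclose(a.mean, b.mean, rtol=1e-12)


def test_all_zero_replicate_is_named_in_error():
    recs = _series_records({"r0": [1.0, 2.0], "rbad": [0.0, 0.0]})
    with pytest.raises(ValueError, match="rbad"):
        build_timecourse(recs, "apical")


def test_mcc_timecourse_uses_only_qc_passing_cells():
    recs = [
        _rec("apical", 0.3, 0.05, t=0.0, cell="a"),
        _rec("apical", 0.3, 0.50, t=0.0, cell="b", qc=False),
        _rec("apical", 0.4, 0.10, t=1.0, cell="c"),
    ]
    recs[1].mcc = None  # QC-failed cells carry no MCC
    tc = build_timecourse(recs, "mcc")
    np.testing.assert_allclose(tc.raw_means[0], [0.05, 0.10])


def test_synthetic_timecourse_peaks_at_expected_times():
    """Rendered populations reproduce the basolateral-then-apical peak order.

    Three replicate simulations of 50 cells at 0-2 h; the normalized
    basolateral series must top out at 1 h and the apical one at 1.5 h.
    """
    records = []
    times = [0.0, 0.5, 1.0, 1.5, 2.0]
    imaging = FAST.with_(voxel_size=(0.3, 0.25, 0.25))
    for rep in range(3):
        for i, t in enumerate(times):
            pop = generate_population(
                50, time=t, seed=1000 + 100 * rep + i, imaging=imaging,
                replicate_id=f"r{rep}",
            )
            for stack, truth in pop:
                records.extend(quantify_truth(stack, truth).records)
    ap = build_timecourse(records, "apical")
    bl = build_timecourse(records, "basolateral")
    assert bl.peak_time() == 1.0
    assert ap.peak_time() == 1.5
    mcc = build_timecourse(records, "mcc")
    assert mcc.mean[-1] > 0.9  # ciliary signal saturates late


# ----------------------------------------------------------------- slopes


def test_exact_line_recovered():
    recs = [
        _rec("apical", x, 0.02 * x + 0.01, cell=f"c{i}") for i, x in enumerate([0.1, 0.3, 0.7])
    ]
    fit = fit_mcc_vs_surface(recs, "apical")
    assert fit.slope == pytest.approx(0.02, rel=1e-12)
    assert fit.intercept == pytest.approx(0.01, rel=1e-12)


def test_three_point_unit_slope():
    recs = [_rec("apical", float(i), float(i), cell=f"c{i}") for i in range(3)]
    fit = fit_mcc_vs_surface(recs, "apical")
    assert fit.slope == pytest.approx(1.0)
    assert fit.n_cells == 3


def test_slope_matches_covariance_oracle():
    rng = np.random.default_rng(8)
    x = rng.random(40)
    y = 0.03 * x + rng.normal(0, 0.005, 40)
    recs = [_rec("apical", xi, yi, cell=f"c{i}") for i, (xi, yi) in enumerate(zip(x, y))]
    fit = fit_mcc_vs_surface(recs, "apical")
    # direct-summation OLS: slope = cov(x, y) / var(x)
    xm, ym = x.mean(), y.mean()
    slope = float(((x - xm) * (y - ym)).sum() / ((x - xm) ** 2).sum())
    assert fit.slope == pytest.approx(slope, rel=1e-10)
    assert fit.intercept == pytest.approx(ym - slope * xm, rel=1e-10)


def test_slope_errors():
    with pytest.raises(ValueError, match=">= 2"):
        fit_mcc_vs_surface([_rec("apical", 0.1, 0.01)], "apical")
    same_x = [_rec("apical", 0.5, 0.01 * i, cell=f"c{i}") for i in range(3)]
    with pytest.raises(ValueError, match="variance"):
        fit_mcc_vs_surface(same_x, "apical")


def test_rendered_population_slope_signs():
    pop = generate_population(25, time=1.0, seed=77, imaging=FAST)
    records = []
    for stack, truth in pop:
        records.extend(quantify_truth(stack, truth).records)
    assert fit_mcc_vs_surface(records, "apical").slope > 0
    assert fit_mcc_vs_surface(records, "basolateral").slope < 0


# ------------------------------------------------------------ paired test


def _fits(slopes, side):
    return [
        SlopeFit(side=side, slope=s, intercept=0.0, n_cells=50, replicate_id=f"r{i}")
        for i, s in enumerate(slopes)
    ]


def test_identical_slope_lists_give_null_result():
    res = compare_slopes(_fits([0.02, 0.03], "apical"), _fits([0.02, 0.03], "basolateral"))
    assert res.t_statistic == 0.0
    assert res.p_value == 1.0


def test_opposite_slopes_significant():
    ap = _fits([0.031, 0.029, 0.030], "apical")
    bl = _fits([-0.030, -0.027, -0.033], "basolateral")
    res = compare_slopes(ap, bl)
    assert res.p_value < 0.05
    # closed-form paired t on the three differences
    d = np.array([a.slope - b.slope for a, b in zip(ap, bl)])
    t = d.mean() / (d.std(ddof=1) / math.sqrt(len(d)))
    assert res.t_statistic == pytest.approx(t, rel=1e-10)
    from scipy import stats as sps

    assert res.p_value == pytest.approx(2 * sps.t.sf(abs(t), len(d) - 1), rel=1e-10)


def test_paired_test_errors():
    with pytest.raises(ValueError, match=">= 2"):
        compare_slopes(_fits([0.1], "apical"), _fits([0.2], "basolateral"))
    ap = _fits([0.1, 0.2], "apical")
    bl = _fits([0.1, 0.2], "basolateral")
    bl = [SlopeFit("basolateral", f.slope, 0.0, 50, replicate_id="weird" + f.replicate_id) for f in bl]
    with pytest.raises(ValueError, match="not paired"):
        compare_slopes(ap, bl)
    with pytest.raises(ValueError, match="equal length"):
        compare_slopes(_fits([0.1, 0.2], "apical"), _fits([0.1], "basolateral"))
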