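"""Stack and table I/O: round trips, metadata survival, degenerate inputs."""

import numpy as np
import pytest
import tifffile

from ciliaflow import (
    CellQuantification,
    VoxelStack,
    read_quant_table,
    read_stack,
    write_quant_table,
    write_stack,
)


@pytest.fixture
def small_stack():
    rng = np.random.default_rng(0)
    data = rng.integers(0, 4000, size=(3, 4, 16, 16)).astype(np.uint16)
    return VoxelStack(
        data=data,
        channel_names=("gfp", "surface_apical", "cilium"),
        voxel_size=(0.3, 0.11, 0.11),
        metadata={"release_time_h": 1.0, "stained_side": "apical", "replicate_id": "r2"},
    )


def test_stack_round_trip_bit_identical(tmp_path, small_stack):
    path = tmp_path / "cell.ome.tif"
    write_stack(small_stack, path)
    back = read_stack(path)
    assert np.array_equal(back.data, small_stack.data)
    assert back.channel_names == small_stack.channel_names
    assert back.voxel_size == pytest.approx(small_stack.voxel_size)
    assert back.metadata["stained_side"] == "apical"
    assert back.metadata["release_time_h"] == 1.0


def test_round_trip_without_sidecar_uses_ome_metadata(tmp_path, small_stack):
    path = tmp_path / "cell.ome.tif"
    write_stack(small_stack, path)
    path.with_suffix(".json").unlink()
    back = read_stack(path)
    assert np.array_equal(back.data, small_stack.data)
    assert back.voxel_size == pytest.approx(small_stack.voxel_size)
    assert back.channel_names == small_stack.channel_names


def test_single_plane_tiff_promoted_to_stack(tmp_path):
    img = np.arange(64, dtype=np.uint16).reshape(8, 8)
    path = tmp_path / "plane.tif"
    tifffile.imwrite(path, img)
    with pytest.warns(UserWarning, match="voxel-size"):
        stack = read_stack(path)
    assert stack.data.shape == (1, 1, 8, 8)
    assert stack.voxel_size == (0.3, 0.1, 0.1)
    assert np.array_equal(stack.data[0, 0], img)


def test_channel_name_count_mismatch_raises(tmp_path):
    data = np.zeros((4, 2, 8, 8), dtype=np.uint16)
    path = tmp_path / "four.tif"
    tifffile.imwrite(path, data)
    with pytest.raises(ValueError, match="4 channels"):
        with pytest.warns(UserWarning):
            read_stack(path, channel_names=["gfp", "surface", "cilium"])


def test_missing_file_raises(tmp_path):
    with pytest.raises(FileNotFoundError):
        read_stack(tmp_path / "nope.tif")


def test_voxel_stack_validation():
    with pytest.raises(ValueError, match="channel names"):
        VoxelStack(np.zeros((2, 1, 4, 4)), channel_names=("a",))
    with pytest.raises(ValueError, match="voxel_size"):
        VoxelStack(np.zeros((1, 1, 4, 4)), channel_names=("a",), voxel_size=(0, 0.1, 0.1))
    with pytest.raises(ValueError):
        VoxelStack(np.full((1, 1, 4, 4), -1.0), channel_names=("a",))


def _records():
    return [
        CellQuantification(
            cell_id="c0", release_time_h=1.0, side="apical", surface_ratio=0.41,
            mcc=0.048, cilium_voxels=120, qc_pass=True, replicate_id="r0",
        ),
        CellQuantification(
            cell_id="c1", release_time_h=1.0, side="apical", surface_ratio=0.38,
            mcc=None, cilium_voxels=0, qc_pass=False, qc_reason="no cilium detected",
            replicate_id="r0",
        ),
    ]


def test_quant_table_round_trip(tmp_path):
    path = tmp_path / "quant.csv"
    write_quant_table(_records(), path)
    back = read_quant_table(path)
    assert back == _records()


def test_quant_table_qc_failed_row_has_empty_mcc(tmp_path):
    path = tmp_path / "quant.csv"
    write_quant_table(_records(), path)
    lines = path.read_text().strip().splitlines()
    assert len(lines) == 3  # header + 2 rows
    header = lines[0].split(",")
    row = dict(zip(header, lines[2].split(",")))
    assert row["mcc"] == ""
    assert row["qc_reason"] == "no cilium detected"
    assert row["surface_ratio"] != ""


def test_single_record_table(tmp_path):
    path = tmp_path / "one.csv"
    write_quant_table(_records()[:1], path)
    lines = path.read_text().strip().splitlines()
    assert len(lines) == 2


def test_empty_records_rejected(tmp_path):
    with pytest.raises(ValueError):
        write_quant_table([], tmp_path / "empty.csv")
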