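"""End-to-end pipeline: simulate -> quantify -> time course + slope stats.

Every run writes a manifest JSON listing each output file with its SHA-256
hash and the fully-resolved configuration, so a run is reproducible from its
manifest alone (deterministic stages are bit-identical given config + seed).
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np

from .analysis import build_timecourse, compare_slopes, fit_mcc_vs_surface
from .config import RunConfig
from .population import generate_population
from .quant import quantify_cell
from .stack_io import RegionSet, write_quant_table

__all__ = ["run_pipeline"]

log = logging.getLogger("ciliaflow")

_MAX_SEED = 2**31 - 1


def run_pipeline(config: RunConfig) -> dict:
    """Execute simulate -> quantify -> timecourse/slopes per the config.

    Returns the manifest (also written to ``manifest.json`` in the
    output directory).  Any stage failure raises with a stage-named
    message.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)

    records = []
    try:
        for rep in range(config.n_replicates):
            rep_id = f"r{rep}"
            for t in config.times_h:
                pop = generate_population(
                    n_cells=config.n_cells,
                    params=config.kinetics,
                    variability=config.variability,
                    time=t,
                    seed=int(rng.integers(0, _MAX_SEED)),
                    geometry=config.geometry,
                    imaging=config.imaging,
                    channels=config.channels,
                    replicate_id=rep_id,
                )
                for stack, truth in pop:
                    regions = RegionSet(
                        background={"neighbors": truth.background_region()},
                        cell_mask=truth.cell_mask,
                    )
                    settings = config.quant.with_(apical_z_um=truth.apical_z_um())
                    result = quantify_cell(stack, regions, settings)
                    records.extend(result.records)
                log.info("replicate %s t=%.2f h: %d cells quantified", rep_id, t, len(pop))
    except Exception as exc:
        raise RuntimeError(f"stage 'simulate/quantify' failed: {exc}") from exc

    outputs: dict[str, Path] = {}
    quant_csv = out / "quantifications.csv"
    write_quant_table(records, quant_csv)
    outputs["quantifications"] = quant_csv

    try:
        stats: dict = {"timecourses": {}, "slopes": None}
        for statistic in ("apical", "basolateral", "mcc"):
            tc = build_timecourse(records, statistic)
            path = out / f"timecourse_{statistic}.csv"
            tc.as_frame().to_csv(path, index=False)
            outputs[f"timecourse_{statistic}"] = path
            stats["timecourses"][statistic] = {
                "times_h": tc.times.tolist(),
                "mean_normalized": tc.mean.tolist(),
                "sem": tc.sem.tolist(),
                "peak_time_h": tc.peak_time(),
            }
    except Exception as exc:
        raise RuntimeError(f"stage 'timecourse' failed: {exc}") from exc

    try:
        if config.n_replicates >= 2:
            fit_time = _slope_time(config.times_h)
            fit_records = [r for r in records if r.release_time_h == fit_time]
            rep_ids = sorted({r.replicate_id for r in fit_records})
            ap = [fit_mcc_vs_surface(fit_records, "apical", rid) for rid in rep_ids]
            bl = [fit_mcc_vs_surface(fit_records, "basolateral", rid) for rid in rep_ids]
            cmp_ = compare_slopes(ap, bl)
            stats["slopes"] = {
                "fit_time_h": fit_time,
                "apical": list(cmp_.apical_slopes),
                "basolateral": list(cmp_.basolateral_slopes),
                "t_statistic": cmp_.t_statistic,
                "p_value": cmp_.p_value,
                "n_replicates": cmp_.n_replicates,
            }
    except Exception as exc:
        raise RuntimeError(f"stage 'slopes' failed: {exc}") from exc

    stats_path = out / "statistics.json"
    stats_path.write_text(json.dumps(stats, indent=2))
    outputs["statistics"] = stats_path

    manifest = {
        "config": config.resolved(),
        "n_records": len(records),
        "outputs": {
            name: {"path": str(p), "sha256": _sha256(p)} for name, p in outputs.items()
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def _slope_time(times) -> float:
    """Release time used for the slope fits: 1 h if simulated, else the latest."""
    return 1.0 if 1.0 in times else times[-1]


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()
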