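"""Population-level statistics: ciliation ratios, time courses, slope tests.

Aggregation conventions follow common practice for replicated single-cell
imaging experiments: per-replicate, per-time-point cell means first, then
max-normalization of each replicate's own time series, then the
cross-replicate mean with SEM over replicates (not over cells).  Cells that
failed cilium QC contribute to surface time courses but never to MCC
statistics.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .quant import CellQuantification

__all__ = [
    "TimeCourseResult",
    "SlopeFit",
    "SlopeComparison",
    "normalized_ciliation_ratio",
    "build_timecourse",
    "fit_mcc_vs_surface",
    "compare_slopes",
]


def normalized_ciliation_ratio(transfected_ciliated_pct: float, all_ciliated_pct: float) -> int:
    """Ciliation of transfected cells relative to all cells, in percent.

    Both inputs are percentages in (0, 100]; the result is
    ``100 * transfected / all`` rounded to the nearest integer percent,
    the form in which ciliation reduction is reported.
    """
    if not 0 < transfected_ciliated_pct <= 100:
        raise ValueError("transfected_ciliated_pct must be in (0, 100]")
    if not 0 < all_ciliated_pct <= 100:
        raise ValueError("all_ciliated_pct must be in (0, 100]")
    return int(round(100.0 * transfected_ciliated_pct / all_ciliated_pct))


@dataclass
class TimeCourseResult:
    """Replicate-averaged, max-normalized kinetics of one statistic."""

    statistic: str  # "apical", "basolateral" or "mcc"
    times: np.ndarray  # h, ascending
    replicate_ids: list[str]
    raw_means: np.ndarray  # (n_replicates, n_times) per-replicate cell means
    normalized: np.ndarray  # raw_means / per-replicate max
    mean: np.ndarray  # cross-replicate mean of normalized, (n_times,)
    sem: np.ndarray  # SEM over replicates, (n_times,)

    def peak_time(self) -> float:
        """Time of the maximum of the cross-replicate mean series."""
        return float(self.times[int(np.argmax(self.mean))])

    def as_frame(self) -> pd.DataFrame:
        rows = []
        for r, rid in enumerate(self.replicate_ids):
            for t, raw, norm in zip(self.times, self.raw_means[r], self.normalized[r]):
                rows.append(
                    {
                        "statistic": self.statistic,
                        "replicate_id": rid,
                        "time_h": t,
                        "raw_mean": raw,
                        "normalized": norm,
                    }
                )
        return pd.DataFrame(rows)


def _records_frame(records: Iterable[CellQuantification]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "replicate_id": r.replicate_id,
            "time_h": r.release_time_h,
            "side": r.side,
            "surface_ratio": r.surface_ratio,
            "mcc": r.mcc,
            "qc_pass": r.qc_pass,
        }
        for r in records
    )


def build_timecourse(
    records: Sequence[CellQuantification],
    statistic: str = "apical",
) -> TimeCourseResult:
    """Aggregate per-cell records into a normalized arrival time course.

    ``statistic`` selects the apical or basolateral surface-to-total
    ratio, or "mcc" for the ciliary fraction (QC-passing cells only).
    Each replicate is averaged over cells per time point, then divided
    by the maximum of its own series, so acquisition-gain differences
    between replicates cancel; the cross-replicate mean and SEM are
    computed on the normalized series.
    """
    if statistic not in ("apical", "basolateral", "mcc"):
        raise ValueError("statistic must be 'apical', 'basolateral' or 'mcc'")
    df = _records_frame(records)
    if df.empty:
        raise ValueError("no records")
    if statistic == "mcc":
        # rows are per stained side but the MCC is per cell: deduplicate
        df = df[df.qc_pass & df.mcc.notna()]
        df = df.drop_duplicates(subset=["replicate_id", "time_h", "mcc"])
        value = "mcc"
    else:
        df = df[(df.side == statistic) & df.surface_ratio.notna()]
        value = "surface_ratio"
    if df.empty:
        raise ValueError(f"no usable records for statistic {statistic!r}")

    piv = df.groupby(["replicate_id", "time_h"])[value].mean().unstack("time_h")
    if piv.isna().any().any():
        missing = piv[piv.isna().any(axis=1)].index.tolist()
        raise ValueError(f"replicates {missing} are missing time points")
    times = piv.columns.to_numpy(dtype=float)
    raw = piv.to_numpy(dtype=float)
    maxima = raw.max(axis=1)
    if np.any(maxima <= 0):
        bad = [rid for rid, m in zip(piv.index, maxima) if m <= 0]
        raise ValueError(f"replicate(s) {bad} have an all-zero series; cannot normalize")
    normalized = raw / maxima[:, None]
    mean = normalized.mean(axis=0)
    n = normalized.shape[0]
    sem = normalized.std(axis=0, ddof=1) / np.sqrt(n) if n > 1 else np.zeros_like(mean)
    return TimeCourseResult(
        statistic=statistic,
        times=times,
        replicate_ids=[str(r) for r in piv.index],
        raw_means=raw,
        normalized=normalized,
        mean=mean,
        sem=sem,
    )


@dataclass(frozen=True)
class SlopeFit:
    """Ordinary-least-squares fit of MCC against a surface-to-total ratio."""

    side: str
    slope: float
    intercept: float
    n_cells: int
    replicate_id: str = "r0"


def fit_mcc_vs_surface(
    records: Sequence[CellQuantification],
    side: str,
    replicate_id: str | None = None,
) -> SlopeFit:
    """OLS fit of per-cell MCC versus the surface-to-total ratio of ``side``.

    Only QC-passing cells with both statistics defined enter the fit;
    the slope measures how ciliary localization scales with that side's
    surface arrival across cells of one condition.
    """
    pts = [
        (r.surface_ratio, r.mcc)
        for r in records
        if r.side == side
        and r.qc_pass
        and r.mcc is not None
        and r.surface_ratio is not None
        and (replicate_id is None or r.replicate_id == replicate_id)
    ]
    if len(pts) < 2:
        raise ValueError(f"need >= 2 QC-passing cells for side {side!r}, got {len(pts)}")
    x = np.array([p[0] for p in pts])
    y = np.array([p[1] for p in pts])
    if np.ptp(x) == 0:
        raise ValueError("zero variance in surface ratio; slope undefined")
    fit = stats.linregress(x, y)
    rid = replicate_id if replicate_id is not None else "all"
    return SlopeFit(
        side=side,
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        n_cells=len(pts),
        replicate_id=rid,
    )


@dataclass(frozen=True)
class SlopeComparison:
    """Replicate-paired comparison of apical vs basolateral slopes."""

    apical_slopes: tuple[float, ...]
    basolateral_slopes: tuple[float, ...]
    mean_apical: float
    mean_basolateral: float
    t_statistic: float
    p_value: float  # two-tailed, paired
    n_replicates: int


def compare_slopes(
    apical: Sequence[SlopeFit],
    basolateral: Sequence[SlopeFit],
) -> SlopeComparison:
    """Two-tailed paired t-test on per-replicate apical vs basolateral slopes.

    Fits are paired by replicate ID; at least two replicates are needed
    for the test to have degrees of freedom.
    """
    if len(apical) != len(basolateral):
        raise ValueError("apical and basolateral fit lists must have equal length")
    if len(apical) < 2:
        raise ValueError("need >= 2 replicates for a paired t-test")
    ap = {f.replicate_id: f for f in apical}
    bl = {f.replicate_id: f for f in basolateral}
    if set(ap) != set(bl) or len(ap) != len(apical):
        raise ValueError(
            f"replicate IDs are not paired: apical {sorted(ap)}, basolateral {sorted(bl)}"
        )
    rids = sorted(ap)
    a = np.array([ap[r].slope for r in rids])
    b = np.array([bl[r].slope for r in rids])
    if np.allclose(a, b):
        t, p = 0.0, 1.0
    else:
        t, p = stats.ttest_rel(a, b)
    return SlopeComparison(
        apical_slopes=tuple(a),
        basolateral_slopes=tuple(b),
        mean_apical=float(a.mean()),
        mean_basolateral=float(b.mean()),
        t_statistic=float(t),
        p_value=float(p),
        n_replicates=len(rids),
    )
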