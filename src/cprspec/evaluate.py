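"""Evaluation protocol: paired windows, RMSE, Bland-Altman, summaries.

Method and reference feedback are computed on the same grid of
nonoverlapping analysis windows and paired per window.  Differences are
always oriented method - reference.  Global accuracy is the RMSE of all
window-level differences in a session kind; agreement is assessed with
Bland-Altman 95% limits (bias +/- 1.96 SD); per-condition summaries report
median (5-95 percentile) of per-record means, compared across sources with
the Mann-Whitney U test.  A naive double-integration baseline demonstrates
the drift the spectral method avoids.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence, Union

import numpy as np
import pandas as pd
from scipy import integrate, stats

from .errors import CprspecError
from .preprocess import ANALYSIS_FS, condition
from .reference import detect_compressions, reference_session
from .signal_io import SessionMeta
from .spectral import (
    AnalysisWindow,
    FeedbackEstimate,
    SpectralConfig,
    WindowGap,
    analyze_session,
)
from .synthetic import BenchmarkRecord

__all__ = [
    "PairedFeedback",
    "PairingResult",
    "BlandAltman",
    "pair_windows",
    "rmse",
    "benchmark_pairs",
    "rmse_vs_tw",
    "bland_altman",
    "summarize_by_condition",
    "mann_whitney_u",
    "naive_double_integration",
]


@dataclass
class PairedFeedback:
    """Method and reference feedback for the same analysis window."""

    window_start: float
    duration: float
    method_rate: float
    ref_rate: float
    method_depth: float
    ref_depth: float
    session: SessionMeta | None = None


@dataclass
class PairingResult:
    pairs: list[PairedFeedback]
    n_excluded: int


class BlandAltman(NamedTuple):
    bias: float
    loa_low: float
    loa_high: float


def pair_windows(
    method: Sequence[FeedbackEstimate | WindowGap],
    reference: Sequence[FeedbackEstimate | WindowGap],
    session: SessionMeta | None = None,
) -> PairingResult:
    """Pair per-window estimates from the two sources.

    Both sequences must cover the same window grid.  Windows where either
    source produced a gap are excluded and counted.
    """
    if len(method) != len(reference):
        raise ValueError(
            f"mismatched window grids: {len(method)} method vs {len(reference)} reference windows"
        )
    pairs: list[PairedFeedback] = []
    n_excluded = 0
    for m, r in zip(method, reference):
        if m.window_start != r.window_start or m.duration != r.duration:
            raise ValueError(
                f"mismatched window at {m.window_start} s vs {r.window_start} s"
            )
        if isinstance(m, WindowGap) or isinstance(r, WindowGap):
            n_excluded += 1
            continue
        pairs.append(
            PairedFeedback(
                window_start=m.window_start,
                duration=m.duration,
                method_rate=m.rate,
                ref_rate=r.rate,
                method_depth=m.depth,
                ref_depth=r.depth,
                session=session,
            )
        )
    return PairingResult(pairs=pairs, n_excluded=n_excluded)


def rmse(differences: Sequence[float]) -> float:
    """Root-mean-square of a sequence of differences."""
    d = np.asarray(differences, dtype=float)
    if d.size == 0:
        raise ValueError("RMSE of an empty sequence is undefined")
    return float(np.sqrt(np.mean(d**2)))


def _pairs_frame(result: PairingResult) -> pd.DataFrame:
    rows = []
    for p in result.pairs:
        meta = p.session
        rows.append(
            {
                "window_start_s": p.window_start,
                "tw_s": p.duration,
                "method_rate": p.method_rate,
                "ref_rate": p.ref_rate,
                "method_depth": p.method_depth,
                "ref_depth": p.ref_depth,
                "rescuer_id": meta.rescuer_id if meta else "",
                "target_rate": meta.target_rate if meta else np.nan,
                "target_depth": meta.target_depth if meta else np.nan,
                "session_kind": meta.session_kind if meta else "",
            }
        )
    return pd.DataFrame(rows)


def benchmark_pairs(
    records: Sequence[BenchmarkRecord],
    tw: float,
    cfg: SpectralConfig | None = None,
    mode: Union[str, int] = "principal",
    fs_analysis: float = ANALYSIS_FS,
) -> tuple[pd.DataFrame, int]:
    """Run the full pipeline on a benchmark at one window length.

    Each record's acceleration and displacement are conditioned (15 Hz
    low-pass, resample to the analysis rate), the method and the
    peak-detector reference are evaluated on the same window grid, and all
    pairs are pooled into one tidy frame.  Returns (pairs, n_excluded).
    """
    frames, excluded = [], 0
    for rec in records:
        accel = condition(rec.accel, fs_analysis)
        cd = condition(rec.displacement, fs_analysis)
        annotations = detect_compressions(cd)
        method = analyze_session(accel, tw, cfg, mode=mode)
        reference = reference_session(annotations, cd.duration, tw)
        result = pair_windows(method, reference, session=rec.meta)
        excluded += result.n_excluded
        if result.pairs:
            frames.append(_pairs_frame(result))
    if not frames:
        return pd.DataFrame(), excluded
    return pd.concat(frames, ignore_index=True), excluded


def rmse_vs_tw(
    records: Sequence[BenchmarkRecord],
    tw_list: Sequence[float] = tuple(range(1, 11)),
    cfg: SpectralConfig | None = None,
    mode: Union[str, int] = "principal",
    fs_analysis: float = ANALYSIS_FS,
) -> pd.DataFrame:
    """Pooled rate/depth RMSE per session kind as a function of window length.

    Records are conditioned and annotated once; the window-level analysis
    is repeated for every requested window duration.  Returns a frame with
    columns ``tw_s, session_kind, rate_rmse, depth_rmse, n_pairs``.
    """
    prepared = []
    for rec in records:
        accel = condition(rec.accel, fs_analysis)
        cd = condition(rec.displacement, fs_analysis)
        prepared.append((rec, accel, detect_compressions(cd), cd.duration))
    rows = []
    for tw in tw_list:
        frames = []
        for rec, accel, annotations, dur in prepared:
            result = pair_windows(
                analyze_session(accel, tw, cfg, mode=mode),
                reference_session(annotations, dur, tw),
                session=rec.meta,
            )
            if result.pairs:
                frames.append(_pairs_frame(result))
        pairs = pd.concat(frames, ignore_index=True)
        for kind, grp in pairs.groupby("session_kind"):
            rows.append(
                {
                    "tw_s": tw,
                    "session_kind": kind,
                    "rate_rmse": rmse(grp["method_rate"] - grp["ref_rate"]),
                    "depth_rmse": rmse(grp["method_depth"] - grp["ref_depth"]),
                    "n_pairs": len(grp),
                }
            )
    return pd.DataFrame(rows)


def bland_altman(
    pairs: Union[Sequence[PairedFeedback], pd.DataFrame], quantity: str
) -> BlandAltman:
    """Bias and 95% limits of agreement of method - reference differences.

    bias = mean difference; limits = bias +/- 1.96 * SD (sample SD, n-1).
    ``quantity`` is ``"rate"`` or ``"depth"``.  Requires at least 3 pairs.
    """
    if quantity not in ("rate", "depth"):
        raise ValueError(f"quantity must be 'rate' or 'depth', got {quantity!r}")
    if isinstance(pairs, pd.DataFrame):
        d = (pairs[f"method_{quantity}"] - pairs[f"ref_{quantity}"]).to_numpy(dtype=float)
    else:
        d = np.array(
            [getattr(p, f"method_{quantity}") - getattr(p, f"ref_{quantity}") for p in pairs]
        )
    if d.size < 3:
        raise ValueError(f"Bland-Altman needs >= 3 pairs, got {d.size}")
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return BlandAltman(bias=bias, loa_low=bias - 1.96 * sd, loa_high=bias + 1.96 * sd)


def mann_whitney_u(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test.

    Exact null distribution for small samples without ties, tie-corrected
    normal approximation otherwise.  Returns (U of x, two-sided p).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method="auto")
    return float(res.statistic), float(res.pvalue)


def summarize_by_condition(
    records: Sequence[BenchmarkRecord],
    tw: float = 3.0,
    cfg: SpectralConfig | None = None,
    mode: Union[str, int] = "principal",
) -> pd.DataFrame:
    """Median (5-95 percentile) of per-record mean rate and depth.

    The unit of analysis is the record: each record's window estimates are
    averaged, then records are grouped per session kind and per target --
    rate targets pool both depths, depth targets pool all rates.  Both the
    reference and the spectral columns are reported, with the Mann-Whitney
    p value comparing them.  Percentiles use linear interpolation.
    """
    pairs, _ = benchmark_pairs(records, tw, cfg, mode=mode)
    per_record = (
        pairs.groupby(["rescuer_id", "target_rate", "target_depth", "session_kind"])
        .agg(
            method_rate=("method_rate", "mean"),
            ref_rate=("ref_rate", "mean"),
            method_depth=("method_depth", "mean"),
            ref_depth=("ref_depth", "mean"),
        )
        .reset_index()
    )
    rows = []
    specs = [("rate", "target_rate"), ("depth", "target_depth")]
    for quantity, target_col in specs:
        for (kind, target), grp in per_record.groupby(["session_kind", target_col]):
            m = grp[f"method_{quantity}"].to_numpy()
            r = grp[f"ref_{quantity}"].to_numpy()
            _, p = mann_whitney_u(m, r)
            for source, vals in (("reference", r), ("spectral", m)):
                rows.append(
                    {
                        "quantity": quantity,
                        "target": target,
                        "session_kind": kind,
                        "source": source,
                        "n_records": len(grp),
                        "median": float(np.median(vals)),
                        "p5": float(np.percentile(vals, 5)),
                        "p95": float(np.percentile(vals, 95)),
                        "p_value": p,
                    }
                )
    return pd.DataFrame(rows)


def naive_double_integration(win: AnalysisWindow) -> np.ndarray:
    """Displacement (mm) by integrating acceleration twice, no compensation.

    Cumulative trapezoidal integration with zero initial conditions.  Any
    offset b in the acceleration grows as 1000 * b * t^2 / 2 mm -- the
    drift that motivates the spectral approach.  Demonstration baseline
    only.
    """
    t = np.arange(len(win.samples)) / win.fs
    v = integrate.cumulative_trapezoid(win.samples, t, initial=0.0)
    s = integrate.cumulative_trapezoid(v, t, initial=0.0)
    return 1000.0 * s
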