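"""Case-vs-control physical coverage CNV detection in fixed windows.

Physical (gapped) coverage counts each proper mate pair once per window it
overlaps, using the full fragment span including the unsequenced gap between
mates.  Per-sample window counts are normalized to sum to one, log2-ratioed
between case and control, and smoothed with a centered moving average; a
heterozygous deletion in the case shows up as a run of windows near -1 (half
coverage), an extra copy near +0.58.  Windows tile the chromosome from
coordinate 0, so reported breakpoints land on the window grid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class CoverageWindow:
    chrom: str
    start: int  # 0-based half-open
    end: int
    raw_case: int
    raw_control: int
    log2diff: float
    smoothed: float


@dataclass
class DeletionCall:
    chrom: str
    start: int  # grid coordinate of the first affected window boundary
    end: int
    n_windows: int
    mean_log2diff: float
    origin: str = "undetermined"


def physical_coverage(
    fragments: pd.DataFrame,
    region_start: int,
    region_end: int,
    window: int = 100,
) -> np.ndarray:
    """Raw gapped-fragment counts per window.

    ``fragments`` holds 0-based half-open spans (columns start, end); each
    fragment increments every window it overlaps by exactly one.  Fragments
    with end <= start are dropped.  The window grid is anchored at
    coordinate 0, so window boundaries are multiples of ``window``.
    """
    first_w = region_start // window
    n_windows = (region_end + window - 1) // window - first_w
    starts = np.asarray(fragments["start"], dtype=np.int64)
    ends = np.asarray(fragments["end"], dtype=np.int64)
    valid = ends > starts
    starts, ends = starts[valid], ends[valid]
    w_lo = np.clip(starts // window - first_w, 0, n_windows)
    w_hi = np.clip((ends - 1) // window - first_w + 1, 0, n_windows)
    delta = np.zeros(n_windows + 1, dtype=np.int64)
    np.add.at(delta, w_lo, 1)
    np.add.at(delta, w_hi, -1)
    return np.cumsum(delta)[:-1]


def normalize(raw: np.ndarray) -> np.ndarray:
    total = raw.sum()
    if total == 0:
        raise ValueError("no fragments in region: cannot normalize coverage")
    return raw / total


def log2_difference(raw_case: np.ndarray, raw_control: np.ndarray) -> np.ndarray:
    """Per-window log2(case_norm / control_norm) with a half-count pseudocount.

    The pseudocount is 0.5 / total per sample, so the statistic is invariant
    to scaling either sample's counts.  Windows where both samples have zero
    raw coverage are NaN (missing), not zero.
    """
    if raw_case.shape != raw_control.shape:
        raise ValueError("case and control window grids differ")
    tc, tk = raw_case.sum(), raw_control.sum()
    if tc == 0 or tk == 0:
        raise ValueError("a sample has no coverage in the region")
    case = (raw_case + 0.5) / tc
    control = (raw_control + 0.5) / tk
    out = np.log2(case) - np.log2(control)
    out[(raw_case == 0) & (raw_control == 0)] = np.nan
    return out


def smooth(log2diff: np.ndarray, span: int = 25) -> np.ndarray:
    """Centered moving average over ``span`` windows, ignoring missing ones;
    edges use truncated windows."""
    s = pd.Series(log2diff)
    return s.rolling(window=span, center=True, min_periods=1).mean().to_numpy()


def _step_sse(values: np.ndarray, w0: int, b: int,
              level_out: float, level_in: float, rising: bool) -> float:
    """Squared error of a sharp step template with its edge at window ``b``."""
    w = np.arange(w0, w0 + len(values))
    if rising:
        pred = np.where(w < b, level_in, level_out)
    else:
        pred = np.where(w < b, level_out, level_in)
    ok = ~np.isnan(values)
    return float(np.sum((values[ok] - pred[ok]) ** 2))


def _refine_edge(
    log2diff: np.ndarray,
    run_lo: int,
    run_hi: int,
    baseline: float,
    plateau: float,
    span: int,
) -> tuple[int, int]:
    """Matched-filter refinement of a run's two edges.

    The run was found on the smoothed profile, whose moving average blurs
    each breakpoint by ~span/2 windows; the edge is re-fitted as a sharp step
    on the unsmoothed per-window log2 difference, where the noise is nearly
    window-independent, which localizes the breakpoint to about one window.
    """
    n = len(log2diff)
    edges = []
    for coarse, rising in ((run_lo, False), (run_hi + 1, True)):
        candidates = range(max(coarse - span, 0), min(coarse + span, n) + 1)
        lo_w = max(coarse - 3 * span, 0)
        hi_w = min(coarse + 3 * span, n)
        segment = log2diff[lo_w:hi_w]
        best = min(
            candidates,
            key=lambda b: _step_sse(segment, lo_w, b, baseline, plateau, rising),
        )
        edges.append(best)
    lo, hi = edges[0], edges[1] - 1
    if hi < lo:
        lo, hi = run_lo, run_hi
    return lo, hi


def call_deletions(
    log2diff: np.ndarray,
    smoothed: np.ndarray,
    region_start: int,
    window: int = 100,
    threshold: float = -0.7,
    min_windows: int = 10,
    gap_windows: int = 5,
    chrom: str = "X",
    refine: bool = True,
    span: int = 25,
) -> list[DeletionCall]:
    """Runs of smoothed log2 difference at or below the threshold.

    The nominal heterozygous-deletion level is -1; the default calling
    threshold keeps a margin for capture noise.  Sub-threshold runs are
    merged across a gap when the gap is at most ``gap_windows`` long, or when
    the smoothed signal throughout the gap stays below half the threshold
    (hysteresis: noise excursions inside a deep deletion must not split it).
    Runs shorter than ``min_windows`` after merging are dropped.  With
    ``refine`` each breakpoint is re-fitted as a sharp step on the unsmoothed
    per-window values, undoing the blur the moving average introduces.
    """
    first_w = region_start // window
    below = np.where(~np.isnan(smoothed) & (smoothed <= threshold))[0]
    if below.size == 0:
        return []
    relax = threshold / 2.0
    runs: list[list[int]] = [[int(below[0]), int(below[0])]]
    for idx in below[1:]:
        gap = smoothed[runs[-1][1] + 1 : idx]
        if idx - runs[-1][1] <= gap_windows or bool(np.all(gap[~np.isnan(gap)] <= relax)):
            runs[-1][1] = int(idx)
        else:
            runs.append([int(idx), int(idx)])
    outside = np.ones(len(smoothed), dtype=bool)
    for lo, hi in runs:
        outside[lo : hi + 1] = False
    baseline_raw = float(np.nanmedian(log2diff[outside])) if outside.any() else 0.0
    calls = []
    for lo, hi in runs:
        if hi - lo + 1 < min_windows:
            continue
        plateau = float(np.nanmedian(log2diff[lo : hi + 1]))
        if refine:
            lo, hi = _refine_edge(log2diff, lo, hi, baseline_raw, plateau, span)
        mean_diff = float(np.nanmean(log2diff[lo : hi + 1]))
        calls.append(
            DeletionCall(
                chrom=chrom,
                start=(first_w + lo) * window,
                end=(first_w + hi + 1) * window,
                n_windows=hi - lo + 1,
                mean_log2diff=mean_diff,
            )
        )
    return calls


def coverage_frame(
    raw_case: np.ndarray,
    raw_control: np.ndarray,
    region_start: int,
    window: int = 100,
    span: int = 25,
    chrom: str = "X",
) -> pd.DataFrame:
    """Window table (chrom, start, end, raw counts, log2diff, smoothed)."""
    diff = log2_difference(raw_case, raw_control)
    sm = smooth(diff, span=span)
    first_w = region_start // window
    starts = (first_w + np.arange(len(raw_case))) * window
    return pd.DataFrame(
        {
            "chrom": chrom,
            "start": starts,
            "end": starts + window,
            "raw_case": raw_case,
            "raw_control": raw_control,
            "log2diff": diff,
            "smoothed": sm,
        }
    )


def run_cnv(
    case_fragments: pd.DataFrame,
    control_fragments: pd.DataFrame,
    region_start: int,
    region_end: int,
    window: int = 100,
    span: int = 25,
    threshold: float = -0.7,
    min_windows: int = 10,
    gap_windows: int = 5,
    chrom: str = "X",
) -> tuple[pd.DataFrame, list[DeletionCall]]:
    """End-to-end window coverage comparison and deletion calling."""
    raw_case = physical_coverage(case_fragments, region_start, region_end, window)
    raw_control = physical_coverage(control_fragments, region_start, region_end, window)
    frame = coverage_frame(raw_case, raw_control, region_start, window, span, chrom)
    calls = call_deletions(
        frame["log2diff"].to_numpy(), frame["smoothed"].to_numpy(),
        region_start, window, threshold, min_windows, gap_windows, chrom,
        span=span,
    )
    return frame, calls
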