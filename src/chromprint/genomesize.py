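"""GC-adjusted genome-size estimation from windowed read depth.

Median read depth is taken in gap-free 1-kb windows, adjusted per
integer GC percent by the factor f = (overall median across windows) /
(median of windows with that GC), and the true base count is estimated
as the sum over windows of window length x adjusted depth / overall
median.  Scaling by assembly length over included length extrapolates to
regions the windowing excluded.  The estimator assumes the genome-wide
median depth represents the diploid copy number; windows well above it
flag collapsed repeats.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

WINDOW = 1000


def window_depth_gc(
    depth: dict[str, np.ndarray],
    seqs: dict[str, str],
    *,
    window: int = WINDOW,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Median depth and integer GC percent per gap-free full window.

    Windows containing any N, and trailing windows shorter than the
    window size, are excluded; exclusion counts are reported.
    """
    rows = []
    excluded = {"gap": 0, "short": 0}
    for name, seq in seqs.items():
        d = depth.get(name)
        if d is None or len(d) < len(seq):
            raise ValueError(f"depth track shorter than scaffold {name!r}")
        codes = np.frombuffer(seq.encode(), dtype=np.uint8)
        n_full = len(seq) // window
        if len(seq) % window:
            excluded["short"] += 1
        for wi in range(n_full):
            s = wi * window
            chunk = codes[s : s + window]
            if (chunk == ord("N")).any():
                excluded["gap"] += 1
                continue
            gc = int(round(100 * np.isin(chunk, (ord("G"), ord("C"))).mean()))
            med = float(np.median(d[s : s + window]))
            rows.append((name, s, s + window, gc, med))
    df = pd.DataFrame(
        rows, columns=["scaffold", "start", "end", "gc", "median_depth"]
    )
    return df, excluded


def gc_adjust(windows: pd.DataFrame) -> pd.DataFrame:
    """Fill the per-GC adjustment factor f and the adjusted depth."""
    if windows.empty:
        raise ValueError("no windows to adjust")
    out = windows.copy()
    overall = float(out.median_depth.median())
    per_gc = out.groupby("gc")["median_depth"].median()
    f = overall / per_gc
    out["f"] = out.gc.map(f)
    out["adjusted_depth"] = out.median_depth * out.f
    return out


def estimate_genome_size(
    windows: pd.DataFrame,
    assembly_total_bp: int,
    included_bp: int | None = None,
    *,
    repeat_flag_factor: float = 1.5,
) -> dict:
    """Estimate true genome size from GC-adjusted windows.

    raw = sum over windows of len(w) x adjusted_depth(w) / overall
    median; scaled = raw x assembly length / included length.  Windows
    with adjusted depth >= ``repeat_flag_factor`` x the overall median
    are reported as collapsed-repeat candidates.
    """
    if "adjusted_depth" not in windows.columns:
        windows = gc_adjust(windows)
    lens = windows.end - windows.start
    included = int(included_bp if included_bp is not None else lens.sum())
    if included == 0:
        raise ValueError("included_bp is zero")
    overall = float(windows.median_depth.median())
    raw = float((lens * windows.adjusted_depth).sum() / overall)
    scaled = raw * assembly_total_bp / included
    flagged = windows[windows.adjusted_depth >= repeat_flag_factor * overall]
    return dict(
        raw_estimate_bp=raw,
        scaled_estimate_bp=scaled,
        assembly_total_bp=int(assembly_total_bp),
        included_bp=included,
        overall_median_depth=overall,
        collapsed_candidate_windows=int(len(flagged)),
        collapsed_candidate_bp=int((flagged.end - flagged.start).sum()),
    )
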