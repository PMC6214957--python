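"""Half-open genomic interval arithmetic on (chrom, start, end) frames.

All functions treat intervals as 0-based half-open and are pure: inputs are
never mutated.  Frames only need the three columns ``chrom``, ``start``,
``end``; extra columns are dropped.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

_COLS = ["chrom", "start", "end"]


def _empty() -> pd.DataFrame:
    return pd.DataFrame({"chrom": pd.Series(dtype=object),
                         "start": pd.Series(dtype=np.int64),
                         "end": pd.Series(dtype=np.int64)})


def merge_intervals(df: pd.DataFrame) -> pd.DataFrame:
    """Union of intervals: merge overlapping or abutting intervals per chromosome."""
    if df is None or len(df) == 0:
        return _empty()
    out = []
    for chrom, g in df.groupby("chrom", sort=True, observed=True):
        s = g["start"].to_numpy(np.int64)
        e = g["end"].to_numpy(np.int64)
        order = np.argsort(s, kind="stable")
        s, e = s[order], e[order]
        cm = np.maximum.accumulate(e)
        new = np.ones(len(s), dtype=bool)
        new[1:] = s[1:] > cm[:-1]
        idx = np.flatnonzero(new)
        out.append(pd.DataFrame({
            "chrom": chrom,
            "start": s[idx],
            "end": np.maximum.reduceat(e, idx),
        }))
    return pd.concat(out, ignore_index=True)


def subtract_intervals(a: pd.DataFrame, b: pd.DataFrame) -> pd.DataFrame:
    """Set difference a \\ b (both merged internally)."""
    a = merge_intervals(a)
    b = merge_intervals(b)
    if len(a) == 0:
        return _empty()
    if len(b) == 0:
        return a
    pieces: list[tuple] = []
    for chrom, ga in a.groupby("chrom", sort=True, observed=True):
        gb = b[b["chrom"] == chrom]
        bs = gb["start"].to_numpy(np.int64)
        be = gb["end"].to_numpy(np.int64)
        for s, e in zip(ga["start"].to_numpy(np.int64), ga["end"].to_numpy(np.int64)):
            cur = int(s)
            i = int(np.searchsorted(be, cur, side="right"))
            while cur < e and i < len(bs) and bs[i] < e:
                if bs[i] > cur:
                    pieces.append((chrom, cur, int(bs[i])))
                cur = max(cur, int(be[i]))
                i += 1
            if cur < e:
                pieces.append((chrom, cur, int(e)))
    if not pieces:
        return _empty()
    return pd.DataFrame(pieces, columns=_COLS)


def union_length(df: pd.DataFrame) -> int:
    """Total number of bases covered by the union of the intervals."""
    m = merge_intervals(df)
    if len(m) == 0:
        return 0
    return int((m["end"] - m["start"]).sum())


def window_totals(df: pd.DataFrame, chrom_lengths: dict[str, int],
                  window: int) -> pd.DataFrame:
    """Per-window covered-base totals of the interval union.

    Returns a frame (chrom, start, covered) tiling every chromosome in
    ``chrom_lengths`` with windows of size ``window`` (last window truncated).
    """
    if window <= 0:
        raise ValueError("window must be positive")
    m = merge_intervals(df)
    rows = []
    for chrom in sorted(chrom_lengths):
        length = chrom_lengths[chrom]
        nwin = max(1, math.ceil(length / window))
        tot = np.zeros(nwin, dtype=np.int64)
        g = m[m["chrom"] == chrom]
        for s, e in zip(g["start"].to_numpy(np.int64), g["end"].to_numpy(np.int64)):
            w0 = s // window
            w1 = (e - 1) // window
            if w0 == w1:
                tot[w0] += e - s
            else:
                tot[w0] += (w0 + 1) * window - s
                tot[w1] += e - w1 * window
                tot[w0 + 1:w1] += window
        rows.append(pd.DataFrame({
            "chrom": chrom,
            "start": np.arange(nwin, dtype=np.int64) * window,
            "covered": tot,
        }))
    return pd.concat(rows, ignore_index=True)
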