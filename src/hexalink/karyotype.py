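"""Windowed read-depth profiles and per-chromosome aneuploidy testing.

The copy estimate for a chromosome is ``base_ploidy`` times the median of
its normalized window depth ratios, making it invariant to global depth
scaling.  The two-sided test is a Wilcoxon signed-rank of the chromosome's
ratios against the genome-wide expectation of 1; the optional threshold
p-value is a one-sided normal test of the mean ratio against ``c0 /
base_ploidy`` with the empirical window standard deviation.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats


def depth_profile(aln, chrom_lengths: dict[str, int],
                  window: int = 100_000) -> pd.DataFrame:
    """Per-window raw depth (aligned bases / window size) and normalized
    ratio rho (depth over the genome-wide median window depth)."""
    if window < 1_000:
        raise ValueError("window must be at least 1 kb")
    rows = []
    for chrom in sorted(chrom_lengths):
        length = chrom_lengths[chrom]
        g = aln.reads[aln.reads["chrom"] == chrom]
        diff = np.zeros(length + 1, dtype=np.int64)
        if len(g):
            np.add.at(diff, g["start"].to_numpy(np.int64), 1)
            np.add.at(diff, g["end"].to_numpy(np.int64), -1)
        per_base = np.cumsum(diff[:-1])
        n_win = max(1, -(-length // window))
        starts = np.arange(n_win, dtype=np.int64) * window
        sums = np.add.reduceat(per_base, starts)
        sizes = np.minimum(starts + window, length) - starts
        rows.append(pd.DataFrame({
            "chrom": chrom,
            "start": starts,
            "depth": sums / window,     # fixed window denominator; the final
                                        # short window is slightly deflated
            "win_size": sizes,
        }))
    profile = pd.concat(rows, ignore_index=True)
    return normalize_profile(profile)


def normalize_profile(profile: pd.DataFrame) -> pd.DataFrame:
    """Attach rho = depth / genome-wide median window depth."""
    med = float(profile["depth"].median())
    if med <= 0:
        raise ValueError("genome-wide median window depth is zero; no data")
    out = profile.copy()
    out["rho"] = out["depth"] / med
    return out


def aneuploidy_test(profile: pd.DataFrame,
                    base_ploidy: int = 6,
                    alpha: float = 0.05,
                    c0: dict[str, float] | float | None = None,
                    min_windows: int = 10,
                    estimator: str = "median",
                    method: str = "between_chrom") -> pd.DataFrame:
    """Per-chromosome fractional copy estimate and aneuploidy calls.

    ``direction`` is set (loss/gain) when the two-sided p-value clears a
    Bonferroni-corrected ``alpha`` over the testable chromosomes.  ``c0``
    requests an additional one-sided p-value against a user copy-number
    hypothesis (scalar, or a per-chromosome mapping).

    Two-sided test methods:

    * ``between_chrom`` (default): Student-t of the chromosome's depth-ratio
      center against the leave-one-out distribution of the other
      chromosomes' centers.  Molecules span several windows, so
      within-chromosome window ratios are positively autocorrelated and a
      per-window location test is anti-conservative; chromosome centers are
      mutually independent and calibrate correctly.  Needs >= 4 testable
      chromosomes; falls back to ``wilcoxon`` below that.
    * ``wilcoxon``: signed-rank of the chromosome's window ratios against 1.
      Only calibrated when windows are much longer than molecules.
    """
    if estimator not in ("median", "mean"):
        raise ValueError("estimator must be 'median' or 'mean'")
    if method not in ("between_chrom", "wilcoxon"):
        raise ValueError("method must be 'between_chrom' or 'wilcoxon'")
    chroms = sorted(profile["chrom"].unique())
    testable = [c for c in chroms
                if (profile["chrom"] == c).sum() >= min_windows]
    n_tests = max(len(testable), 1)

    def _center(values: np.ndarray) -> float:
        return float(np.median(values) if estimator == "median"
                     else values.mean())

    centers = {c: _center(profile.loc[profile["chrom"] == c,
                                      "rho"].to_numpy(np.float64))
               for c in testable}
    use_between = method == "between_chrom" and len(testable) >= 4
    rows = []
    for chrom in chroms:
        rho = profile.loc[profile["chrom"] == chrom, "rho"].to_numpy(np.float64)
        n = len(rho)
        if n < min_windows:
            rows.append((chrom, float("nan"), float("nan"), float("nan"),
                         "untestable", n))
            continue
        center = centers[chrom]
        c_hat = base_ploidy * center
        if use_between:
            others = np.array([v for c, v in centers.items() if c != chrom])
            sd = others.std(ddof=1)
            if sd == 0:
                p_two = 1.0 if center == others.mean() else np.nextafter(0, 1)
            else:
                t = (center - others.mean()) / (sd * np.sqrt(1 + 1 / len(others)))
                p_two = float(2 * stats.t.sf(abs(t), df=len(others) - 1))
        else:
            diffs = rho - 1.0
            if np.all(diffs == 0):
                p_two = 1.0
            else:
                p_two = float(stats.wilcoxon(diffs, zero_method="wilcox",
                                             alternative="two-sided").pvalue)
        direction = "none"
        if p_two < alpha / n_tests:
            direction = "loss" if c_hat < base_ploidy else "gain"
        c0_chrom = c0.get(chrom) if isinstance(c0, dict) else c0
        if c0_chrom is None:
            p_thr = float("nan")
        else:
            sd = rho.std(ddof=1)
            if sd == 0:
                p_thr = float("nan")
            else:
                z = (rho.mean() - c0_chrom / base_ploidy) / (sd / np.sqrt(n))
                # loss candidate: H0 c >= c0, reject for small mean
                p_thr = float(stats.norm.cdf(z) if c_hat < base_ploidy
                              else stats.norm.sf(z))
        rows.append((chrom, c_hat, p_two, p_thr, direction, n))
    return pd.DataFrame(rows, columns=["chrom", "c_hat", "p_two_sided",
                                       "p_threshold", "direction", "n_windows"])
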