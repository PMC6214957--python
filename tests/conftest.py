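"""Shared fixtures and independent oracles.

The oracles here deliberately re-derive results by brute force (pairwise
single-linkage, exact hypergeometric enumeration, per-base boolean coverage,
log-likelihood scans) and must stay independent of the package's vectorised
implementations.
"""

from __future__ import annotations

import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest

from hexalink import simdata


# ---------------------------------------------------------------------------
# construction helpers
# ---------------------------------------------------------------------------

def make_alignment(reads, obs=None, ref="A") -> simdata.AlignmentTable:
    """Build an AlignmentTable from plain tuples.

    ``reads``: (read_id, barcode, chrom, start, end, mapq);
    ``obs``: (read_id, chrom, pos, base).
    """
    reads_df = pd.DataFrame(reads, columns=["read_id", "barcode", "chrom",
                                            "start", "end", "mapq"])
    obs_df = pd.DataFrame(obs or [], columns=["read_id", "chrom", "pos", "base"])
    return simdata.AlignmentTable(ref=ref, reads=reads_df, obs=obs_df)


# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------

def single_linkage_molecules(reads_df: pd.DataFrame,
                             max_gap: int = 10_000,
                             min_span: int = 10_000,
                             min_mapq: int = 30) -> set:
    """O(n^2) single-linkage clustering of read intervals.

    Two reads are linked when they share barcode and chromosome and the gap
    between their intervals (0 for overlaps) is at most ``max_gap``.
    Returns the set of retained molecules as (read-id frozenset, start, end).
    """
    from scipy.sparse import csr_matrix
    from scipy.sparse.csgraph import connected_components

    df = reads_df[reads_df["mapq"] >= min_mapq].reset_index(drop=True)
    n = len(df)
    if n == 0:
        return set()
    bc = pd.factorize(df["barcode"])[0]
    ch = pd.factorize(df["chrom"])[0]
    s = df["start"].to_numpy(np.int64)
    e = df["end"].to_numpy(np.int64)
    same = (bc[:, None] == bc[None, :]) & (ch[:, None] == ch[None, :])
    gap = np.maximum(np.maximum(s[:, None], s[None, :])
                     - np.minimum(e[:, None], e[None, :]), 0)
    linked = same & (gap <= max_gap)
    _, labels = connected_components(csr_matrix(linked), directed=False)
    out = set()
    for comp in np.unique(labels):
        idx = np.flatnonzero(labels == comp)
        start, end = int(s[idx].min()), int(e[idx].max())
        if end - start >= min_span:
            out.add((frozenset(df["read_id"].iloc[idx].tolist()), start, end))
    return out


def fisher_two_sided_exact(table) -> float:
    """Two-sided Fisher p by exact hypergeometric enumeration (Fractions)."""
    (a, b), (c, d) = table
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    if n == 0:
        return 1.0
    denom = math.comb(n, c1)
    def pmf(k: int) -> Fraction:
        return Fraction(math.comb(r1, k) * math.comb(r2, c1 - k), denom)
    p_obs = pmf(a)
    total = sum((p for k in range(max(0, c1 - r2), min(r1, c1) + 1)
                 if (p := pmf(k)) <= p_obs), start=Fraction(0))
    return float(total)


def dosage_map_candidates(ref: int, alt: int, ploidy: int = 6,
                          error_rate: float = 0.01) -> set:
    """All maximum-likelihood dosages by a direct log-likelihood scan."""
    lls = []
    for d in range(ploidy + 1):
        p = d / ploidy * (1 - 2 * error_rate) + error_rate
        ll = 0.0
        ll += alt * math.log(p) if alt else 0.0
        ll += ref * math.log(1 - p) if ref else 0.0
        lls.append(ll)
    best = max(lls)
    return {d for d, ll in enumerate(lls) if math.isclose(ll, best,
                                                          rel_tol=0, abs_tol=1e-9)}


def binom_two_sided_exact(k: int, n: int, p: float) -> float:
    """Two-sided exact binomial p: sum of outcome probabilities <= P(k)."""
    probs = [math.comb(n, i) * p ** i * (1 - p) ** (n - i) for i in range(n + 1)]
    pk = probs[k]
    return float(sum(q for q in probs if q <= pk * (1 + 1e-12)))


def coverage_per_base(intervals, genome_len: int) -> int:
    """Union length via an explicit per-base boolean array."""
    mask = np.zeros(genome_len, dtype=bool)
    for start, end in intervals:
        mask[start:end] = True
    return int(mask.sum())


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------

@pytest.fixture(scope="session")
def small_genome():
    """300 kb x 2 chromosomes with one A-specific segment, plus a hexaploid
    with recombination and fixation at the default parameters."""
    pair, variants = simdata.simulate_progenitors(
        seed=41, n_chrom=2, chrom_len=300_000, divergence_rate=0.01,
        specific_segments=[("A", "chr01", 60_000, 90_000)])
    truth = simdata.simulate_hexaploid(
        pair, variants, switch_rate_per_mb=2.0,
        phi_a=simdata.DEFAULT_PHI_A, phi_b=simdata.DEFAULT_PHI_B, seed=42)
    return pair, variants, truth


@pytest.fixture(scope="session")
def small_reads(small_genome):
    pair, variants, truth = small_genome
    aln_a, aln_b, mol_truth = simdata.simulate_linked_reads(
        pair, truth, variants, coverage=30.0, error_rate=0.01, seed=43)
    return aln_a, aln_b, mol_truth
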