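"""Polyploid dosage genotyping from allele depths and association testing.

The caller is a maximum-likelihood binomial classifier: dosage d maps to an
alternate-read probability p_d = (d/ploidy)(1-e) + (1-d/ploidy)e and the
call is the d maximising Binomial(n=ref+alt, k=alt, p_d) under a flat prior.
Depth and minor-allele-fraction filters are applied around it.  Association
between a binary phenotype and per-site allele frequencies uses a two-sided
Fisher's exact test on pooled dosage-weighted allele counts.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import xlogy

PASS = "pass"
LOW_DEPTH = "low_depth"
HIGH_DEPTH = "high_depth"
MINOR_FRAC = "minor_frac"


def _dosage_probs(ploidy: int, error_rate: float) -> np.ndarray:
    """p_d for d = 0..ploidy, built so that p[ploidy-d] == 1 - p[d]
    bit-exactly (keeps the caller mirror-symmetric in ref/alt)."""
    d = np.arange(ploidy + 1, dtype=np.float64)
    p = d / ploidy * (1 - 2 * error_rate) + error_rate
    half = ploidy // 2
    p[ploidy - np.arange(half)] = 1.0 - p[np.arange(half)]
    if ploidy % 2 == 0:
        p[half] = 0.5
    return p


def call_dosages(depths: pd.DataFrame,
                 ploidy: int = 6,
                 error_rate: float = 0.01,
                 min_depth: int = 18,
                 max_depth: float | None = None,
                 min_minor_frac: float = 0.05) -> pd.DataFrame:
    """Vectorised dosage calls for a frame with ref_depth / alt_depth columns.

    Filters are applied in order low_depth, high_depth, minor_frac.  A call
    whose minor-allele fraction is below ``min_minor_frac`` passes only if
    the maximum-likelihood dosage is homozygous (the call collapses onto the
    consistent homozygote); a heterozygous-looking call with sub-threshold
    minor support becomes a no-call.
    """
    if ploidy < 1:
        raise ValueError("ploidy must be >= 1")
    if not 0 <= error_rate < 0.5:
        raise ValueError("error_rate must be in [0, 0.5)")
    ref = depths["ref_depth"].to_numpy(np.int64)
    alt = depths["alt_depth"].to_numpy(np.int64)
    if (ref < 0).any() or (alt < 0).any():
        raise ValueError("depths must be non-negative")
    n = ref + alt

    p = _dosage_probs(ploidy, error_rate)
    # ll[i, d] = alt*log(p_d) + ref*log(1 - p_d); 1 - p_d == p[ploidy-d]
    ll = (xlogy(alt[:, None], p[None, :])
          + xlogy(ref[:, None], p[None, ::-1]))
    best = ll.max(axis=1, keepdims=True)
    is_best = ll == best
    d_grid = np.arange(ploidy + 1)
    # tie-break symmetric under ref<->alt: take the largest tied d when the
    # alternate allele is in the majority, the smallest otherwise
    lo = np.argmax(is_best, axis=1)
    hi = ploidy - np.argmax(is_best[:, ::-1], axis=1)
    dosage = np.where(alt * 2 > n, hi, lo).astype(np.int64)

    status = np.full(len(n), PASS, dtype=object)
    status[n < min_depth] = LOW_DEPTH
    if max_depth is not None:
        status[(status == PASS) & (n > max_depth)] = HIGH_DEPTH
    minor = np.minimum(ref, alt)
    with np.errstate(invalid="ignore", divide="ignore"):
        minor_frac = np.where(n > 0, minor / np.maximum(n, 1), 0.0)
    het = (dosage != 0) & (dosage != ploidy)
    status[(status == PASS) & het & (minor_frac < min_minor_frac)] = MINOR_FRAC

    out = depths.copy()
    out["dosage"] = pd.array(np.where(status == PASS, dosage, -1),
                             dtype="Int64")
    out.loc[status != PASS, "dosage"] = pd.NA
    out["filter_status"] = status
    return out


def call_dosage(ref_depth: int, alt_depth: int, **kwargs):
    """Scalar convenience wrapper; returns (dosage or None, filter_status)."""
    df = pd.DataFrame({"ref_depth": [ref_depth], "alt_depth": [alt_depth]})
    res = call_dosages(df, **kwargs)
    d = res["dosage"].iloc[0]
    return (None if pd.isna(d) else int(d)), res["filter_status"].iloc[0]


def per_sample_max_depth(depths: pd.DataFrame, n_sd: float = 2.0) -> pd.Series:
    """Per-sample depth ceiling: mean total depth plus ``n_sd`` standard
    deviations, computed from the input itself."""
    total = depths["ref_depth"] + depths["alt_depth"]
    g = total.groupby(depths["sample"])
    return g.mean() + n_sd * g.std(ddof=1).fillna(0.0)


def genotype_cohort(depths: pd.DataFrame, **kwargs) -> pd.DataFrame:
    """Call dosages per sample, using the per-sample mean + 2 SD depth
    ceiling unless an explicit ``max_depth`` is passed."""
    if "max_depth" in kwargs and kwargs["max_depth"] is not None:
        return call_dosages(depths, **kwargs)
    kwargs.pop("max_depth", None)
    ceilings = per_sample_max_depth(depths)
    frames = []
    for sample, g in depths.groupby("sample", sort=True):
        frames.append(call_dosages(g, max_depth=float(ceilings.loc[sample]),
                                   **kwargs))
    return pd.concat(frames, ignore_index=True)


def dosage_spectrum(genotypes: pd.DataFrame, ploidy: int = 6) -> dict:
    """Heterozygous calls folded by minor-allele dosage class, plus the
    per-sample heterozygosity rate among pass-filter calls."""
    called = genotypes[genotypes["filter_status"] == PASS]
    d = called["dosage"].astype(np.int64).to_numpy()
    minor = np.minimum(d, ploidy - d)
    classes = {}
    for k in range(1, ploidy // 2 + 1):
        classes[k] = int((minor == k).sum())
    het = minor > 0
    het_rate = (pd.Series(het, index=called.index)
                .groupby(called["sample"]).mean().to_dict()
                if "sample" in called.columns else {})
    return {"class_counts": classes, "n_het": int(het.sum()),
            "n_called": int(len(called)), "het_rate_per_sample": het_rate}


def allele_freq_assoc(genotypes: pd.DataFrame,
                      phenotype: pd.DataFrame,
                      ploidy: int = 6,
                      mode: str = "dosage",
                      gene_map: pd.DataFrame | None = None,
                      gene_p_mode: str = "min") -> dict:
    """Per-site Fisher's exact test of allele frequencies between two groups.

    ``mode='dosage'`` pools dosage-weighted allele counts (each called sample
    contributes ``d`` alternate and ``ploidy - d`` reference alleles);
    ``mode='presence'`` counts samples carrying / not carrying the alternate
    allele instead.  Sites with called samples in only one group are skipped
    and reported.  Optional ``gene_map`` (chrom, start, end, gene_id)
    aggregates SNP p-values per gene by minimum p (or Bonferroni-adjusted
    minimum with ``gene_p_mode='bonferroni'``).
    """
    if mode not in ("dosage", "presence"):
        raise ValueError("mode must be 'dosage' or 'presence'")
    groups = phenotype.set_index("sample")["group"]
    levels = sorted(groups.unique())
    if len(levels) != 2:
        raise ValueError("phenotype must define exactly two groups")
    called = genotypes[genotypes["filter_status"] == PASS].copy()
    called["group"] = called["sample"].map(groups)
    called = called[called["group"].notna()]

    rows = []
    skipped = []
    for (chrom, pos), g in called.groupby(["chrom", "pos"], sort=True):
        by = {lvl: g[g["group"] == lvl]["dosage"].astype(np.int64).to_numpy()
              for lvl in levels}
        if any(len(v) == 0 for v in by.values()):
            skipped.append((chrom, pos))
            continue
        if mode == "dosage":
            alt1, alt2 = int(by[levels[0]].sum()), int(by[levels[1]].sum())
            ref1 = int(len(by[levels[0]]) * ploidy - alt1)
            ref2 = int(len(by[levels[1]]) * ploidy - alt2)
        else:
            alt1 = int((by[levels[0]] > 0).sum())
            alt2 = int((by[levels[1]] > 0).sum())
            ref1 = int(len(by[levels[0]]) - alt1)
            ref2 = int(len(by[levels[1]]) - alt2)
        table = [[ref1, alt1], [ref2, alt2]]
        p = float(stats.fisher_exact(table, alternative="two-sided")[1])
        rows.append((chrom, pos, ref1, alt1, ref2, alt2, p,
                     p < 0.005, p < 0.05))
    results = pd.DataFrame(rows, columns=[
        "chrom", "pos", "ref_g1", "alt_g1", "ref_g2", "alt_g2",
        "p", "sig_005", "sig_05"])

    genes = None
    if gene_map is not None and len(results):
        gene_ids = np.full(len(results), None, dtype=object)
        pos_all = results["pos"].to_numpy(np.int64)
        for chrom, g in gene_map.groupby("chrom"):
            mask = (results["chrom"] == chrom).to_numpy()
            for start, end, gid in g[["start", "end", "gene_id"]].itertuples(index=False):
                gene_ids[mask & (pos_all >= start) & (pos_all < end)] = gid
        results = results.assign(gene_id=gene_ids)
        with_gene = results[results["gene_id"].notna()]
        agg = with_gene.groupby("gene_id").agg(
            min_p=("p", "min"), n_snps=("p", "size")).reset_index()
        if gene_p_mode == "bonferroni":
            agg["gene_p"] = np.minimum(1.0, agg["min_p"] * agg["n_snps"])
        else:
            agg["gene_p"] = agg["min_p"]
        genes = agg
    return {"sites": results, "genes": genes,
            "skipped": pd.DataFrame(skipped, columns=["chrom", "pos"])}


def allele_bias_test(rna_ref_count: int,
                     rna_alt_count: int,
                     genomic_dosage: int,
                     ploidy: int = 6) -> dict:
    """Two-sided exact binomial test of RNA allele counts against the
    genomic dosage proportion d/ploidy.  A homozygous dosage with opposing
    reads is reported as incompatible (no p-value)."""
    if rna_ref_count < 0 or rna_alt_count < 0:
        raise ValueError("counts must be non-negative")
    if not 0 <= genomic_dosage <= ploidy:
        raise ValueError("dosage out of range")
    n = rna_ref_count + rna_alt_count
    expected = genomic_dosage / ploidy
    if genomic_dosage == 0 and rna_alt_count > 0:
        return {"status": "incompatible", "p": None, "expected_alt_frac": expected}
    if genomic_dosage == ploidy and rna_ref_count > 0:
        return {"status": "incompatible", "p": None, "expected_alt_frac": expected}
    if n == 0:
        return {"status": "no_data", "p": None, "expected_alt_frac": expected}
    p = float(stats.binomtest(rna_alt_count, n, expected,
                              alternative="two-sided").pvalue)
    return {"status": "ok", "p": p, "expected_alt_frac": expected}
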