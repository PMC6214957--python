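"""Allele-depth tallies and fixed/polymorphic classification of variant sites.

A variant site is classified from the pooled read support for the two
reference alleles: sites below a depth floor are ``low_coverage``; sites
where both alleles carry minimum minor-allele evidence (read count and
fraction) are ``polymorphic``; the remainder are fixed for the majority
allele (``A_fixed`` / ``B_fixed``).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

CLASSES = ("A_fixed", "B_fixed", "polymorphic", "low_coverage")

_BASE_CATS = ["A", "C", "G", "T"]


def base_codes(values) -> np.ndarray:
    """Map single-character bases to int8 codes (A,C,G,T -> 0..3, else -1)."""
    return np.asarray(pd.Categorical(values, categories=_BASE_CATS).codes,
                      dtype=np.int8)


def match_obs_to_variants(obs: pd.DataFrame, variants: pd.DataFrame):
    """Vectorised (chrom, pos) lookup of observations into the variant table.

    Returns (variant_row_index, valid_mask) where ``valid_mask`` flags
    observations at positions present in the variant table.
    """
    categories = list(pd.unique(variants["chrom"]))
    vc = np.asarray(pd.Categorical(variants["chrom"],
                                   categories=categories).codes, dtype=np.int64)
    oc = np.asarray(pd.Categorical(obs["chrom"],
                                   categories=categories).codes, dtype=np.int64)
    vpos = variants["pos"].to_numpy(np.int64)
    opos = obs["pos"].to_numpy(np.int64)
    mult = np.int64(max(int(vpos.max(initial=0)), int(opos.max(initial=0))) + 1)
    vkey = vc * mult + vpos
    order = np.argsort(vkey, kind="stable")
    okey = oc * mult + opos
    idx_sorted = np.searchsorted(vkey[order], okey)
    idx_sorted = np.clip(idx_sorted, 0, len(vkey) - 1)
    vrow = order[idx_sorted]
    valid = (oc >= 0) & (vkey[vrow] == okey)
    return vrow, valid


def tally_site_depths(aln, variants: pd.DataFrame) -> pd.DataFrame:
    """Count reads supporting each allele at every variant site.

    Returns one row per variant-table site with columns depth_a, depth_b and
    depth_other (observations matching neither reference allele).  Sites
    without any overlapping observation get zero depths.
    """
    obs = aln.obs
    out = variants[["chrom", "pos", "allele_A", "allele_B"]].copy()
    n_var = len(variants)
    if len(obs) == 0 or n_var == 0:
        out["depth_a"] = 0
        out["depth_b"] = 0
        out["depth_other"] = 0
        return out
    vrow, valid = match_obs_to_variants(obs, variants)
    vrow = vrow[valid]
    bcode = base_codes(obs["base"])[valid]
    acode = base_codes(variants["allele_A"])
    bcode_ref = base_codes(variants["allele_B"])
    is_a = bcode == acode[vrow]
    is_b = bcode == bcode_ref[vrow]
    out["depth_a"] = np.bincount(vrow, weights=is_a, minlength=n_var).astype(np.int64)
    out["depth_b"] = np.bincount(vrow, weights=is_b, minlength=n_var).astype(np.int64)
    out["depth_other"] = np.bincount(vrow, weights=~(is_a | is_b),
                                     minlength=n_var).astype(np.int64)
    return out


def classify_sites(obs: pd.DataFrame,
                   min_depth: int = 10,
                   min_minor_reads: int = 2,
                   min_minor_frac: float = 0.10) -> pd.DataFrame:
    """Assign a class to every site; ties at the polymorphic thresholds count
    as polymorphic.  ``depth_other`` is excluded from all denominators."""
    if min_depth <= 0 or min_minor_reads <= 0 or min_minor_frac <= 0:
        raise ValueError("classification thresholds must be positive")
    da = obs["depth_a"].to_numpy(np.int64)
    db = obs["depth_b"].to_numpy(np.int64)
    depth = da + db
    minor = np.minimum(da, db)
    low = depth < min_depth
    poly = (~low) & (minor >= min_minor_reads) & (minor >= min_minor_frac * depth)
    a_fixed = (~low) & (~poly) & (da >= db)   # da == db with depth >= min_depth is always poly
    b_fixed = (~low) & (~poly) & (db > da)
    site_class = np.empty(len(obs), dtype=object)
    site_class[low] = "low_coverage"
    site_class[poly] = "polymorphic"
    site_class[a_fixed] = "A_fixed"
    site_class[b_fixed] = "B_fixed"
    out = obs.copy()
    out["site_class"] = site_class
    return out


def class_fractions(classified: pd.DataFrame) -> dict:
    """Summary fractions over sites passing the depth filter, plus counts."""
    counts = {c: int((classified["site_class"] == c).sum()) for c in CLASSES}
    n_pass = sum(counts[c] for c in CLASSES[:3])
    fractions = {c: (counts[c] / n_pass if n_pass else float("nan"))
                 for c in CLASSES[:3]}
    fractions["nonpolymorphic"] = (
        (counts["A_fixed"] + counts["B_fixed"]) / n_pass if n_pass else float("nan"))
    return {"counts": counts, "n_pass_depth": n_pass, "fractions": fractions}


def allele_depth_histogram(classified: pd.DataFrame,
                           bin_width: float = 0.05) -> dict:
    """Per-class histogram of depth_a / (depth_a + depth_b).

    Returns {class: {"edges": [...], "counts": [...]}} for the three
    depth-passing classes; counts sum to the class sizes.
    """
    n_bins = int(round(1.0 / bin_width))
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    out = {}
    for cls in CLASSES[:3]:
        g = classified[classified["site_class"] == cls]
        depth = (g["depth_a"] + g["depth_b"]).to_numpy(np.float64)
        with np.errstate(invalid="ignore"):
            ratio = g["depth_a"].to_numpy(np.float64) / depth
        ratio = ratio[~np.isnan(ratio)]
        counts, _ = np.histogram(ratio, bins=edges)
        out[cls] = {"edges": edges.tolist(), "counts": counts.tolist()}
    return out
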