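"""Molecule reconstruction from barcoded alignments and downstream profiling.

Reads sharing a barcode on one chromosome are chained while the alignment
distance between consecutive reads (next start minus running maximum end,
clamped at zero) stays within ``max_gap``; maximal chains spanning at least
``min_span`` become molecules.  This is exactly single-linkage clustering of
read intervals under the gap threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._intervals import merge_intervals, subtract_intervals, union_length, window_totals


@dataclass
class MoleculeSet:
    """Reconstructed molecules against one reference.

    ``molecules`` columns: molecule_id, barcode, chrom, start, end, n_reads.
    ``assignments`` maps every retained read to its molecule.
    """

    ref: str
    molecules: pd.DataFrame
    assignments: pd.DataFrame       # read_id, molecule_id
    n_discarded_chains: int = 0

    def __len__(self) -> int:
        return len(self.molecules)

    def to_tsv(self, path, profile: pd.DataFrame | None = None) -> None:
        df = self.molecules.copy()
        df["ref"] = self.ref
        if profile is not None:
            df = df.merge(profile[["molecule_id", "n_a", "n_b", "prop_a"]],
                          on="molecule_id", how="left")
        df.to_csv(path, sep="\t", index=False)


def reconstruct_molecules(aln,
                          max_gap: int = 10_000,
                          min_span: int = 10_000,
                          min_mapq: int = 30) -> MoleculeSet:
    """Chain barcoded reads into molecules (see module docstring).

    Reads below ``min_mapq`` are dropped before chaining.  The result is
    invariant to the order of the input records.
    """
    if max_gap < 0 or min_span < 0:
        raise ValueError("max_gap and min_span must be non-negative")
    reads = aln.reads[aln.reads["mapq"] >= min_mapq]
    if len(reads) == 0:
        return MoleculeSet(ref=aln.ref,
                           molecules=pd.DataFrame(columns=[
                               "molecule_id", "barcode", "chrom", "start",
                               "end", "n_reads"]),
                           assignments=pd.DataFrame(columns=["read_id", "molecule_id"]))

    bc, bc_vals = pd.factorize(reads["barcode"], sort=True)
    ch, ch_vals = pd.factorize(reads["chrom"], sort=True)
    start = reads["start"].to_numpy(np.int64)
    end = reads["end"].to_numpy(np.int64)
    rid = reads["read_id"].to_numpy()
    grp = bc.astype(np.int64) * len(ch_vals) + ch

    order = np.lexsort((rid, end, start, grp))
    grp, start, end, rid = grp[order], start[order], end[order], rid[order]
    bc_sorted = bc[order]
    ch_sorted = ch[order]

    big = np.int64(int(end.max()) + max_gap + 2)
    adj_end = end + grp * big
    run_max = np.maximum.accumulate(adj_end)
    new_chain = np.ones(len(grp), dtype=bool)
    new_chain[1:] = ((grp[1:] != grp[:-1])
                     | (start[1:] + grp[1:] * big - run_max[:-1] > max_gap))
    chain_first = np.flatnonzero(new_chain)
    chain_of_read = np.cumsum(new_chain) - 1

    chain_start = start[chain_first]
    chain_end = np.maximum.reduceat(end, chain_first)
    chain_n = np.diff(np.append(chain_first, len(grp)))
    keep = chain_end - chain_start >= min_span

    mol_id_of_chain = np.full(len(chain_first), -1, dtype=np.int64)
    mol_id_of_chain[keep] = np.arange(int(keep.sum()))
    molecules = pd.DataFrame({
        "molecule_id": mol_id_of_chain[keep],
        "barcode": np.asarray(bc_vals)[bc_sorted[chain_first[keep]]],
        "chrom": np.asarray(ch_vals)[ch_sorted[chain_first[keep]]],
        "start": chain_start[keep],
        "end": chain_end[keep],
        "n_reads": chain_n[keep].astype(np.int64),
    })
    read_mol = mol_id_of_chain[chain_of_read]
    retained = read_mol >= 0
    assignments = pd.DataFrame({"read_id": rid[retained],
                                "molecule_id": read_mol[retained]})
    return MoleculeSet(ref=aln.ref, molecules=molecules,
                       assignments=assignments,
                       n_discarded_chains=int((~keep).sum()))


def molecule_allele_profile(mset: MoleculeSet,
                            aln,
                            variants: pd.DataFrame,
                            bin_width: float = 0.02,
                            min_informative: int = 5) -> tuple[pd.DataFrame, dict]:
    """Per-molecule subgenome allele tallies and the genome-wide summary.

    Every observation at a variant-table site is attributed to the A or B
    subgenome by allele identity.  Molecules with no attributable
    observation have an undefined proportion and are excluded from the
    histogram; "pure" molecules have prop_a in {0, 1} with at least
    ``min_informative`` attributable observations.
    """
    from .sitescan import base_codes, match_obs_to_variants

    vrow, valid = match_obs_to_variants(aln.obs, variants)
    obs = aln.obs[valid].copy()
    vrow = vrow[valid]
    bcode = base_codes(obs["base"])
    is_a_all = bcode == base_codes(variants["allele_A"])[vrow]
    is_b_all = bcode == base_codes(variants["allele_B"])[vrow]
    obs["is_a"] = is_a_all
    obs["is_b"] = is_b_all
    obs = obs[["read_id", "is_a", "is_b"]].merge(mset.assignments,
                                                 on="read_id", how="inner")
    is_a = obs["is_a"].to_numpy()
    is_b = obs["is_b"].to_numpy()
    n_mol = len(mset.molecules)
    mol_idx = obs["molecule_id"].to_numpy(np.int64)
    n_a = np.bincount(mol_idx, weights=is_a, minlength=n_mol).astype(np.int64)
    n_b = np.bincount(mol_idx, weights=is_b, minlength=n_mol).astype(np.int64)
    total = n_a + n_b
    with np.errstate(invalid="ignore"):
        prop = np.where(total > 0, n_a / np.maximum(total, 1), np.nan)
    prop[total == 0] = np.nan
    per_mol = mset.molecules[["molecule_id", "barcode", "chrom", "start",
                              "end", "n_reads"]].copy()
    per_mol["n_a"] = n_a
    per_mol["n_b"] = n_b
    per_mol["prop_a"] = prop
    summary = profile_summary(per_mol, bin_width=bin_width,
                              min_informative=min_informative)
    return per_mol, summary


def profile_summary(per_mol: pd.DataFrame,
                    bin_width: float = 0.02,
                    min_informative: int = 5,
                    n_a_col: str = "n_a", n_b_col: str = "n_b") -> dict:
    """Histogram, modal proportion and pure-molecule fraction of a profile.

    Works on any frame with per-molecule A/B tallies, including the molecule
    truth table from the generator (pass ``n_a_col='n_true_a'`` etc.).
    """
    n_a = per_mol[n_a_col].to_numpy(np.float64)
    n_b = per_mol[n_b_col].to_numpy(np.float64)
    total = n_a + n_b
    defined = total > 0
    informative = total >= min_informative
    # the histogram (and its mode) uses informative molecules only: with a
    # handful of observations the proportion collapses onto coarse rationals
    # (1/2, 1/3, ...) and those atoms distort the bin argmax
    prop = n_a[informative] / total[informative]
    n_bins = int(round(1.0 / bin_width))
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    counts, _ = np.histogram(prop, bins=edges)
    if counts.sum():
        imax = int(np.argmax(counts))
        mode = float((edges[imax] + edges[imax + 1]) / 2)
    else:
        mode = float("nan")
    n_informative = int(informative.sum())
    if n_informative:
        p_inf = n_a[informative] / total[informative]
        pure_fraction = float(((p_inf == 0.0) | (p_inf == 1.0)).mean())
    else:
        pure_fraction = float("nan")
    return {
        "n_molecules": int(len(per_mol)),
        "n_defined": int(defined.sum()),
        "n_informative": n_informative,
        "histogram": {"edges": edges.tolist(), "counts": counts.tolist()},
        "mode": mode,
        "pure_fraction": pure_fraction,
    }


def match_molecules(mset_a: MoleculeSet,
                    mset_b: MoleculeSet,
                    min_read_jaccard: float = 0.9) -> dict:
    """Pair molecules across the two references by shared reads.

    Candidate pairs share a barcode and have read-set Jaccard at or above
    the threshold; assignment is greedy by descending Jaccard with ties
    broken by leftmost span.  Returns ``pairs`` plus the unmatched molecule
    frames on each side.
    """
    a = mset_a.assignments.rename(columns={"molecule_id": "mol_a"})
    b = mset_b.assignments.rename(columns={"molecule_id": "mol_b"})
    shared = a.merge(b, on="read_id", how="inner")
    size_a = mset_a.molecules.set_index("molecule_id")["n_reads"]
    size_b = mset_b.molecules.set_index("molecule_id")["n_reads"]
    start_a = mset_a.molecules.set_index("molecule_id")["start"]
    start_b = mset_b.molecules.set_index("molecule_id")["start"]
    bc_a = mset_a.molecules.set_index("molecule_id")["barcode"]
    bc_b = mset_b.molecules.set_index("molecule_id")["barcode"]

    matched_pairs = []
    if len(shared):
        inter = (shared.groupby(["mol_a", "mol_b"], sort=False)
                 .size().rename("n_shared").reset_index())
        same_bc = (bc_a.loc[inter["mol_a"]].to_numpy()
                   == bc_b.loc[inter["mol_b"]].to_numpy())
        inter = inter[same_bc]
        na = size_a.loc[inter["mol_a"]].to_numpy(np.float64)
        nb = size_b.loc[inter["mol_b"]].to_numpy(np.float64)
        ns = inter["n_shared"].to_numpy(np.float64)
        inter = inter.assign(jaccard=ns / (na + nb - ns))
        inter = inter[inter["jaccard"] >= min_read_jaccard]
        inter = inter.assign(
            start_a=start_a.loc[inter["mol_a"]].to_numpy(),
            start_b=start_b.loc[inter["mol_b"]].to_numpy(),
        ).sort_values(["jaccard", "start_a", "start_b", "mol_a", "mol_b"],
                      ascending=[False, True, True, True, True])
        used_a: set = set()
        used_b: set = set()
        for mol_a, mol_b, _, jac, *_ in inter.itertuples(index=False):
            if mol_a in used_a or mol_b in used_b:
                continue
            used_a.add(mol_a)
            used_b.add(mol_b)
            matched_pairs.append((mol_a, mol_b, jac))
    pairs = pd.DataFrame(matched_pairs, columns=["mol_a", "mol_b", "jaccard"])
    unmatched_a = mset_a.molecules[
        ~mset_a.molecules["molecule_id"].isin(pairs["mol_a"])].reset_index(drop=True)
    unmatched_b = mset_b.molecules[
        ~mset_b.molecules["molecule_id"].isin(pairs["mol_b"])].reset_index(drop=True)
    return {"pairs": pairs, "unmatched_a": unmatched_a, "unmatched_b": unmatched_b}


def homology_regions(match: dict,
                     mset_a: MoleculeSet,
                     mset_b: MoleculeSet,
                     chrom_lengths: dict[str, int],
                     window: int = 1_000_000) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Shared three-way and reference-specific regions from match results.

    A matched pair certifies homology only where both of its spans agree, so
    shared regions are the merged per-pair span intersections; X-specific
    regions are the merged spans of unmatched vs-X molecules minus the shared
    regions.  Also returns per-window covered-base totals for each status.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    mols_a = mset_a.molecules.set_index("molecule_id")
    mols_b = mset_b.molecules.set_index("molecule_id")
    pairs = match["pairs"]
    if len(pairs):
        sa = mols_a.loc[pairs["mol_a"], "start"].to_numpy(np.int64)
        ea = mols_a.loc[pairs["mol_a"], "end"].to_numpy(np.int64)
        sb = mols_b.loc[pairs["mol_b"], "start"].to_numpy(np.int64)
        eb = mols_b.loc[pairs["mol_b"], "end"].to_numpy(np.int64)
        istart = np.maximum(sa, sb)
        iend = np.minimum(ea, eb)
        nonempty = iend > istart
        shared_src = pd.DataFrame({
            "chrom": mols_a.loc[pairs["mol_a"], "chrom"].to_numpy()[nonempty],
            "start": istart[nonempty],
            "end": iend[nonempty],
        })
    else:
        shared_src = pd.DataFrame(columns=["chrom", "start", "end"])
    shared = merge_intervals(shared_src)
    a_specific = subtract_intervals(
        match["unmatched_a"][["chrom", "start", "end"]], shared)
    b_specific = subtract_intervals(
        match["unmatched_b"][["chrom", "start", "end"]], shared)

    frames = []
    for status, df in (("shared_three_way", shared),
                       ("A_specific", a_specific),
                       ("B_specific", b_specific)):
        d = df.copy()
        d["status"] = status
        frames.append(d)
    regions = pd.concat(frames, ignore_index=True)

    win_frames = []
    for status, df in (("shared_three_way", shared),
                       ("A_specific", a_specific),
                       ("B_specific", b_specific)):
        w = window_totals(df, chrom_lengths, window)
        w = w.rename(columns={"covered": status})
        win_frames.append(w.set_index(["chrom", "start"]))
    windows = pd.concat(win_frames, axis=1).reset_index()
    return regions, windows


def reference_coverage(mset: MoleculeSet, genome_length: int) -> dict:
    """Union length of molecule spans and the fraction of the genome covered."""
    covered = union_length(mset.molecules[["chrom", "start", "end"]])
    return {"covered_bases": int(covered),
            "fraction": covered / genome_length if genome_length else float("nan")}
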