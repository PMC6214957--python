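import numpy as np
import pandas as pd
import pytest

from hexalink import molecules, simdata
from hexalink._intervals import merge_intervals, subtract_intervals, union_length

from conftest import coverage_per_base, make_alignment, single_linkage_molecules


def reconstruct(reads, **kwargs):
    return molecules.reconstruct_molecules(make_alignment(reads), **kwargs)


class TestReconstruct:
    def test_two_reads_within_gap_form_one_molecule(self):
        mset = reconstruct([("r1", "b1", "c1", 0, 150, 60),
                            ("r2", "b1", "c1", 5_000, 12_000, 60)])
        assert len(mset) == 1
        mol = mset.molecules.iloc[0]
        assert (mol["start"], mol["end"], mol["n_reads"]) == (0, 12_000, 2)

    def test_far_reads_with_short_spans_yield_nothing(self):
        mset = reconstruct([("r1", "b1", "c1", 0, 150, 60),
                            ("r2", "b1", "c1", 15_150, 15_300, 60)])
        assert len(mset) == 0
        assert mset.n_discarded_chains == 2

    def test_gap_exactly_at_threshold_links(self):
        mset = reconstruct([("r1", "b1", "c1", 0, 1_000, 60),
                            ("r2", "b1", "c1", 11_000, 12_000, 60)])
        assert len(mset) == 1

    def test_gap_one_past_threshold_breaks(self):
        mset = reconstruct([("r1", "b1", "c1", 0, 1_000, 60),
                            ("r2", "b1", "c1", 11_001, 12_000, 60)])
        assert len(mset) == 0

    def test_span_exactly_min_span_retained(self):
        mset = reconstruct([("r1", "b1", "c1", 0, 5_000, 60),
                            ("r2", "b1", "c1", 6_000, 10_000, 60)])
        assert len(mset) == 1

    def test_different_barcodes_never_chain(self):
        mset = reconstruct([("r1", "b1", "c1", 0, 8_000, 60),
                            ("r2", "b2", "c1", 8_100, 16_000, 60)])
        assert len(mset) == 0

    def test_low_mapq_reads_dropped_before_chaining(self):
        mset = reconstruct([("r1", "b1", "c1", 0, 8_000, 10),
                            ("r2", "b1", "c1", 8_100, 16_000, 60)])
        assert len(mset) == 0
        mset = reconstruct([("r1", "b1", "c1", 0, 8_000, 30),
                            ("r2", "b1", "c1", 8_100, 16_000, 60)])
        assert len(mset) == 1

    def test_nested_reads_use_running_maximum_end(self):
        # r2 nests inside r1; r3 is within max_gap of r1's end, not r2's
        mset = reconstruct([("r1", "b1", "c1", 0, 20_000, 60),
                            ("r2", "b1", "c1", 1_000, 2_000, 60),
                            ("r3", "b1", "c1", 29_000, 30_000, 60)])
        assert len(mset) == 1
        assert mset.molecules.iloc[0]["end"] == 30_000

    def test_negative_thresholds_rejected(self):
        with pytest.raises(ValueError):
            reconstruct([("r1", "b1", "c1", 0, 150, 60)], max_gap=-1)

    def test_order_invariance(self):
        rng = np.random.default_rng(3)
        reads = [(f"r{i}", f"b{rng.integers(4)}", "c1",
                  int(s := rng.integers(0, 100_000)), int(s + rng.integers(100, 3000)), 60)
                 for i in range(200)]
        base = reconstruct(reads)
        shuffled = [reads[i] for i in rng.permutation(len(reads))]
        other = reconstruct(shuffled)
        def canon(mset):
            merged = mset.assignments.groupby("molecule_id")["read_id"].agg(frozenset)
            spans = mset.molecules.set_index("molecule_id")
            return {(merged.loc[m], spans.loc[m, "start"], spans.loc[m, "end"])
                    for m in spans.index}
        assert canon(base) == canon(other)

    def test_every_retained_read_in_exactly_one_molecule(self, small_reads):
        aln_a, _, _ = small_reads
        mset = molecules.reconstruct_molecules(aln_a)
        assert mset.assignments["read_id"].is_unique
        counts = mset.assignments.groupby("molecule_id").size()
        assert (counts == mset.molecules.set_index("molecule_id")["n_reads"]).all()

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_single_linkage_oracle(self, seed):
        rng = np.random.default_rng(100 + seed)
        n = int(rng.integers(20, 300))
        reads = []
        for i in range(n):
            s = int(rng.integers(0, 150_000))
            reads.append((f"r{i}", f"b{rng.integers(10)}",
                          f"c{rng.integers(2)}", s,
                          s + int(rng.integers(100, 2_000)),
                          int(rng.choice([10, 60]))))
        aln = make_alignment(reads)
        mset = molecules.reconstruct_molecules(aln)
        got = {(frozenset(g["read_id"]), spans["start"], spans["end"])
               for mid, g in mset.assignments.groupby("molecule_id")
               for spans in [mset.molecules.set_index("molecule_id").loc[mid]]}
        expected = single_linkage_molecules(aln.reads)
        assert got == expected


class TestProfile:
    def test_counting_example(self):
        reads = [("r1", "b1", "c1", 0, 12_000, 60)]
        obs = [("r1", "c1", 10, "A"), ("r1", "c1", 20, "A"),
               ("r1", "c1", 30, "A"), ("r1", "c1", 40, "C")]
        aln = make_alignment(reads, obs=obs)
        variants = pd.DataFrame({"chrom": "c1", "pos": [10, 20, 30, 40],
                                 "allele_A": "A", "allele_B": "C"})
        mset = molecules.reconstruct_molecules(aln, min_span=10_000)
        per_mol, summary = molecules.molecule_allele_profile(mset, aln, variants)
        assert per_mol["prop_a"].iloc[0] == pytest.approx(0.75)
        assert summary["n_defined"] == 1

    def test_no_observations_gives_undefined_proportion(self):
        reads = [("r1", "b1", "c1", 0, 12_000, 60)]
        aln = make_alignment(reads, obs=[])
        variants = pd.DataFrame({"chrom": ["c1"], "pos": [10],
                                 "allele_A": ["A"], "allele_B": ["C"]})
        mset = molecules.reconstruct_molecules(aln)
        per_mol, summary = molecules.molecule_allele_profile(mset, aln, variants)
        assert np.isnan(per_mol["prop_a"].iloc[0])
        assert summary["n_defined"] == 0
        assert sum(summary["histogram"]["counts"]) == 0

    def test_pure_fraction_without_recombination(self):
        # no recombination, no fixation, no errors: every molecule is pure
        pair, variants = simdata.simulate_progenitors(
            seed=81, n_chrom=1, chrom_len=400_000, divergence_rate=0.01)
        truth = simdata.simulate_hexaploid(pair, variants,
                                           switch_rate_per_mb=0.0, seed=82)
        aln_a, _, _ = simdata.simulate_linked_reads(
            pair, truth, variants, coverage=20, error_rate=0.0, seed=83)
        mset = molecules.reconstruct_molecules(aln_a)
        _, summary = molecules.molecule_allele_profile(mset, aln_a, variants)
        assert summary["pure_fraction"] >= 0.99

    def test_mode_recovery_against_molecule_truth(self, small_genome, small_reads):
        pair, variants, truth = small_genome
        aln_a, _, mol_truth = small_reads
        mset = molecules.reconstruct_molecules(aln_a)
        per_mol, _ = molecules.molecule_allele_profile(mset, aln_a, variants)
        summary = molecules.profile_summary(per_mol, min_informative=30)
        truth_summary = molecules.profile_summary(
            mol_truth, n_a_col="n_true_a", n_b_col="n_true_b",
            min_informative=30)
        assert abs(summary["mode"] - truth_summary["mode"]) <= 0.05


class TestMatch:
    def _msets(self, reads_a, reads_b):
        return (molecules.reconstruct_molecules(make_alignment(reads_a, ref="A")),
                molecules.reconstruct_molecules(make_alignment(reads_b, ref="B")))

    def test_identical_read_sets_match_at_jaccard_one(self):
        reads = [("r1", "b1", "c1", 0, 150, 60),
                 ("r2", "b1", "c1", 9_000, 12_000, 60)]
        mset_a, mset_b = self._msets(reads, reads)
        match = molecules.match_molecules(mset_a, mset_b)
        assert len(match["pairs"]) == 1
        assert match["pairs"]["jaccard"].iloc[0] == 1.0
        assert len(match["unmatched_a"]) == 0

    def test_disjoint_read_sets_stay_unmatched(self):
        reads_a = [("r1", "b1", "c1", 0, 150, 60),
                   ("r2", "b1", "c1", 9_000, 12_000, 60)]
        reads_b = [("r3", "b1", "c1", 0, 150, 60),
                   ("r4", "b1", "c1", 9_000, 12_000, 60)]
        mset_a, mset_b = self._msets(reads_a, reads_b)
        match = molecules.match_molecules(mset_a, mset_b)
        assert len(match["pairs"]) == 0
        assert len(match["unmatched_a"]) == 1
        assert len(match["unmatched_b"]) == 1

    def test_simulation_matches_most_molecules(self):
        # no specific segments, no errors: nearly everything pairs up
        pair, variants = simdata.simulate_progenitors(
            seed=91, n_chrom=1, chrom_len=500_000, divergence_rate=0.01)
        truth = simdata.simulate_hexaploid(pair, variants, seed=92)
        aln_a, aln_b, _ = simdata.simulate_linked_reads(
            pair, truth, variants, coverage=25, error_rate=0.0, seed=93)
        mset_a = molecules.reconstruct_molecules(aln_a)
        mset_b = molecules.reconstruct_molecules(aln_b)
        match = molecules.match_molecules(mset_a, mset_b)
        multi = (mset_a.molecules["n_reads"] >= 2).sum()
        assert len(match["pairs"]) >= 0.95 * multi


class TestHomologyAndCoverage:
    def test_all_matched_means_no_specific_regions(self):
        reads = [("r1", "b1", "c1", 0, 150, 60),
                 ("r2", "b1", "c1", 9_000, 12_000, 60)]
        mset_a = molecules.reconstruct_molecules(make_alignment(reads, ref="A"))
        mset_b = molecules.reconstruct_molecules(make_alignment(reads, ref="B"))
        match = molecules.match_molecules(mset_a, mset_b)
        regions, windows = molecules.homology_regions(
            match, mset_a, mset_b, {"c1": 20_000}, window=10_000)
        by_status = regions.groupby("status").apply(
            lambda g: (g["end"] - g["start"]).sum(), include_groups=False)
        assert by_status.get("A_specific", 0) == 0
        assert by_status.get("B_specific", 0) == 0
        assert by_status["shared_three_way"] == 12_000

    def test_specific_segment_recovery(self, small_genome, small_reads):
        pair, variants, truth = small_genome
        aln_a, aln_b, _ = small_reads
        mset_a = molecules.reconstruct_molecules(aln_a)
        mset_b = molecules.reconstruct_molecules(aln_b)
        match = molecules.match_molecules(mset_a, mset_b)
        regions, _ = molecules.homology_regions(
            match, mset_a, mset_b, pair.chrom_lengths)
        seg = pair.specific_segments[0]
        detected = regions[regions["status"] == "A_specific"]
        length = (detected["end"] - detected["start"]).sum()
        true_len = seg.end - seg.start
        assert abs(length - true_len) <= 0.2 * true_len

    def test_window_totals_bounded_by_window_size(self, small_genome, small_reads):
        pair, variants, truth = small_genome
        aln_a, aln_b, _ = small_reads
        mset_a = molecules.reconstruct_molecules(aln_a)
        mset_b = molecules.reconstruct_molecules(aln_b)
        match = molecules.match_molecules(mset_a, mset_b)
        _, windows = molecules.homology_regions(
            match, mset_a, mset_b, pair.chrom_lengths, window=50_000)
        for col in ("shared_three_way", "A_specific", "B_specific"):
            assert (windows[col] <= 50_000).all()

    def test_reference_coverage_examples(self):
        mset = molecules.MoleculeSet(
            ref="A",
            molecules=pd.DataFrame({"molecule_id": [0], "barcode": ["b"],
                                    "chrom": ["c1"], "start": [0],
                                    "end": [10_000], "n_reads": [2]}),
            assignments=pd.DataFrame({"read_id": ["r1", "r2"],
                                      "molecule_id": [0, 0]}))
        assert molecules.reference_coverage(mset, 100_000)["fraction"] == 0.10

    def test_overlapping_spans_count_union(self):
        mols = pd.DataFrame({"molecule_id": [0, 1], "barcode": ["b", "b"],
                             "chrom": ["c1", "c1"], "start": [0, 5_000],
                             "end": [10_000, 20_000], "n_reads": [2, 2]})
        mset = molecules.MoleculeSet(ref="A", molecules=mols,
                                     assignments=pd.DataFrame())
        assert molecules.reference_coverage(mset, 100_000)["covered_bases"] == 20_000

    def test_coverage_matches_per_base_oracle(self):
        rng = np.random.default_rng(12)
        spans = [(int(s := rng.integers(0, 90_000)), int(s + rng.integers(1, 9_000)))
                 for _ in range(60)]
        mols = pd.DataFrame({"molecule_id": range(60),
                             "barcode": "b", "chrom": "c1",
                             "start": [s for s, _ in spans],
                             "end": [e for _, e in spans],
                             "n_reads": 2})
        mset = molecules.MoleculeSet(ref="A", molecules=mols,
                                     assignments=pd.DataFrame())
        got = molecules.reference_coverage(mset, 100_000)["covered_bases"]
        assert got == coverage_per_base(spans, 100_000)


class TestIntervalOps:
    def test_merge_subtract_union_against_per_base_oracle(self):
        rng = np.random.default_rng(9)
        def random_frame(n):
            spans = [(int(s := rng.integers(0, 5_000)), int(s + rng.integers(1, 400)))
                     for _ in range(n)]
            return pd.DataFrame({"chrom": "c", "start": [s for s, _ in spans],
                                 "end": [e for _, e in spans]}), spans
        a, spans_a = random_frame(40)
        b, spans_b = random_frame(25)
        assert union_length(a) == coverage_per_base(spans_a, 6_000)
        mask_a = np.zeros(6_000, dtype=bool)
        mask_b = np.zeros(6_000, dtype=bool)
        for s, e in spans_a:
            mask_a[s:e] = True
        for s, e in spans_b:
            mask_b[s:e] = True
        assert union_length(subtract_intervals(a, b)) == int((mask_a & ~mask_b).sum())
        merged = merge_intervals(a)
        assert (merged["start"].iloc[1:].to_numpy()
                > merged["end"].iloc[:-1].to_numpy()).all()
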