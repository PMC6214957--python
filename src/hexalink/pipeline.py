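"""End-to-end orchestration of the synthetic analyses, plus small utilities.

``run_pipeline`` executes simulate -> sitescan -> molecules -> karyotype ->
dosage/association on a synthetic genome and cohort, and emits a single
versioned JSON report aggregating every stage summary together with a full
parameter manifest.  ``divergence_time`` and ``expanded_families`` are the
stand-alone comparative-genomics utilities.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import dosage_assoc, io, karyotype, molecules, simdata, sitescan

logger = logging.getLogger("hexalink")

REPORT_SCHEMA_VERSION = 1
_REQUIRED_REPORT_KEYS = ("schema_version", "manifest", "stages")


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

def _strict_fields(cls, data: dict):
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown {cls.__name__} keys: {sorted(unknown)}")


@dataclass
class GenomeConfig:
    n_chrom: int = 5
    chrom_len: int = 2_000_000
    divergence_rate: float = 0.01
    specific_segments: list = field(default_factory=lambda: [
        ["A", "chr01", 500_000, 550_000],
        ["B", "chr03", 1_200_000, 1_260_000],
    ])


@dataclass
class HexaploidConfig:
    composition: list = field(default_factory=lambda: [4, 2])
    pi_a: float = simdata.DEFAULT_PI_A
    switch_rate_per_mb: float = 2.0
    phi_a: float = simdata.DEFAULT_PHI_A
    phi_b: float = simdata.DEFAULT_PHI_B
    copy_spec: dict = field(default_factory=lambda: {"chr05": 5})


@dataclass
class ReadsConfig:
    coverage: float = 30.0
    molecule_len_mean: float = simdata.DEFAULT_MOLECULE_LEN_MEAN
    reads_per_kb: float = 0.5
    read_len: int = 150
    error_rate: float = 0.01
    barcode_pool: int = 500_000


@dataclass
class SitescanConfig:
    min_depth: int = 10
    min_minor_reads: int = 2
    min_minor_frac: float = 0.10
    hist_bin_width: float = 0.05


@dataclass
class MoleculesConfig:
    max_gap: int = 10_000
    min_span: int = 10_000
    min_mapq: int = 30
    min_read_jaccard: float = 0.9
    window: int = 1_000_000
    profile_bin_width: float = 0.02
    min_informative: int = 5


@dataclass
class KaryotypeConfig:
    window: int = 100_000
    base_ploidy: int = 6
    alpha: float = 0.05
    min_windows: int = 10


@dataclass
class CohortConfig:
    n_per_group: int = 20
    n_sites: int = 400
    mean_depth: float = 60.0
    error_rate: float = 0.01
    base_freq_low: float = 0.2
    base_freq_high: float = 0.8
    causal_freqs: list = field(default_factory=lambda: [0.2, 0.6])


@dataclass
class DosageConfig:
    ploidy: int = 6
    error_rate: float = 0.01
    min_depth: int = 18
    min_minor_frac: float = 0.05


@dataclass
class StageToggles:
    sitescan: bool = True
    molecules: bool = True
    karyotype: bool = True
    dosage: bool = True


@dataclass
class PipelineConfig:
    seed: int = 1
    genome: GenomeConfig = field(default_factory=GenomeConfig)
    hexaploid: HexaploidConfig = field(default_factory=HexaploidConfig)
    reads: ReadsConfig = field(default_factory=ReadsConfig)
    sitescan: SitescanConfig = field(default_factory=SitescanConfig)
    molecules: MoleculesConfig = field(default_factory=MoleculesConfig)
    karyotype: KaryotypeConfig = field(default_factory=KaryotypeConfig)
    cohort: CohortConfig = field(default_factory=CohortConfig)
    dosage: DosageConfig = field(default_factory=DosageConfig)
    stages: StageToggles = field(default_factory=StageToggles)
    write_intermediate: bool = False

    _SECTIONS = {
        "genome": GenomeConfig, "hexaploid": HexaploidConfig,
        "reads": ReadsConfig, "sitescan": SitescanConfig,
        "molecules": MoleculesConfig, "karyotype": KaryotypeConfig,
        "cohort": CohortConfig, "dosage": DosageConfig,
        "stages": StageToggles,
    }

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        _strict_fields(cls, {k: v for k, v in data.items()})
        kwargs = {}
        for key, value in data.items():
            section = cls._SECTIONS.get(key)
            if section is not None:
                _strict_fields(section, value)
                kwargs[key] = section(**value)
            else:
                kwargs[key] = value
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

def run_pipeline(config: PipelineConfig | None = None,
                 out_dir=None) -> dict:
    """Run every enabled stage on the synthetic genome and cohort.

    Returns the report dict; when ``out_dir`` is given the report (and,
    with ``write_intermediate``, the stage outputs) are written there.
    Deterministic for a fixed config: the report contains no content that
    varies between runs outside the ``timing`` block.
    """
    cfg = config or PipelineConfig()
    t0 = time.time()
    report: dict = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "manifest": {"config": cfg.to_dict()},
        "stages": {},
        "timing": {},
    }
    out = io.ensure_dir(out_dir) if out_dir is not None else None

    def _stage_done(name, started):
        report["timing"][name] = round(time.time() - started, 3)
        logger.info("stage %s done in %.1fs", name, report["timing"][name])

    # --- simulate ----------------------------------------------------------
    t = time.time()
    g = cfg.genome
    pair, variants = simdata.simulate_progenitors(
        seed=cfg.seed, n_chrom=g.n_chrom, chrom_len=g.chrom_len,
        divergence_rate=g.divergence_rate,
        specific_segments=[tuple(s) for s in g.specific_segments])
    h = cfg.hexaploid
    truth = simdata.simulate_hexaploid(
        pair, variants, composition=tuple(h.composition), pi_a=h.pi_a,
        switch_rate_per_mb=h.switch_rate_per_mb, phi_a=h.phi_a,
        phi_b=h.phi_b, copy_spec=dict(h.copy_spec), seed=cfg.seed + 1)
    r = cfg.reads
    aln_a, aln_b, mol_truth = simdata.simulate_linked_reads(
        pair, truth, variants, coverage=r.coverage,
        molecule_len_mean=r.molecule_len_mean, reads_per_kb=r.reads_per_kb,
        read_len=r.read_len, error_rate=r.error_rate,
        barcode_pool=r.barcode_pool, seed=cfg.seed + 2)
    report["stages"]["simulate"] = {
        "n_variants": int(len(variants)),
        "n_reads": int(aln_a.n_reads),
        "total_aligned_bases": int(aln_a.total_aligned_bases()),
        "genome_length": int(pair.genome_length),
        "copy_number": dict(truth.copy_number),
        "truth_a_length_fraction": truth.a_length_fraction(),
    }
    if out is not None and cfg.write_intermediate:
        pair.write(out / "genome")
        truth.write(out / "genome")
        io.write_variants_vcf(variants, pair.chrom_lengths,
                              out / "genome" / "variants.vcf")
        aln_a.to_tsv(out / "alignments_A.tsv")
        aln_b.to_tsv(out / "alignments_B.tsv")
        mol_truth.to_csv(out / "molecule_truth.tsv", sep="\t", index=False)
    _stage_done("simulate", t)

    # --- sitescan ----------------------------------------------------------
    site_table = None
    if cfg.stages.sitescan:
        t = time.time()
        s = cfg.sitescan
        obs = sitescan.tally_site_depths(aln_a, variants)
        site_table = sitescan.classify_sites(
            obs, min_depth=s.min_depth, min_minor_reads=s.min_minor_reads,
            min_minor_frac=s.min_minor_frac)
        summary = sitescan.class_fractions(site_table)
        summary["histogram"] = sitescan.allele_depth_histogram(
            site_table, bin_width=s.hist_bin_width)
        report["stages"]["sitescan"] = summary
        if out is not None and cfg.write_intermediate:
            site_table.to_csv(out / "site_classes.tsv", sep="\t", index=False)
        _stage_done("sitescan", t)

    # --- molecules ---------------------------------------------------------
    if cfg.stages.molecules:
        t = time.time()
        m = cfg.molecules
        mset_a = molecules.reconstruct_molecules(
            aln_a, max_gap=m.max_gap, min_span=m.min_span, min_mapq=m.min_mapq)
        mset_b = molecules.reconstruct_molecules(
            aln_b, max_gap=m.max_gap, min_span=m.min_span, min_mapq=m.min_mapq)
        per_mol, prof_summary = molecules.molecule_allele_profile(
            mset_a, aln_a, variants, bin_width=m.profile_bin_width,
            min_informative=m.min_informative)
        match = molecules.match_molecules(
            mset_a, mset_b, min_read_jaccard=m.min_read_jaccard)
        regions, windows = molecules.homology_regions(
            match, mset_a, mset_b, pair.chrom_lengths, window=m.window)
        spec_len = {
            status: int(regions.loc[regions["status"] == status,
                                    ["end"]].to_numpy().sum()
                        - regions.loc[regions["status"] == status,
                                      ["start"]].to_numpy().sum())
            for status in ("shared_three_way", "A_specific", "B_specific")}
        report["stages"]["molecules"] = {
            "n_molecules_a": len(mset_a),
            "n_molecules_b": len(mset_b),
            "n_matched": int(len(match["pairs"])),
            "profile": prof_summary,
            "region_lengths": spec_len,
            "coverage_a": molecules.reference_coverage(mset_a, pair.genome_length),
            "coverage_b": molecules.reference_coverage(mset_b, pair.genome_length),
        }
        if out is not None and cfg.write_intermediate:
            mset_a.to_tsv(out / "molecules_A.tsv", profile=per_mol)
            mset_b.to_tsv(out / "molecules_B.tsv")
            io.write_bed(regions, out / "homology_regions.bed",
                         extra_cols=["status"])
            windows.to_csv(out / "homology_windows.tsv", sep="\t", index=False)
        _stage_done("molecules", t)

    # --- karyotype ---------------------------------------------------------
    if cfg.stages.karyotype:
        t = time.time()
        k = cfg.karyotype
        profile = karyotype.depth_profile(aln_a, pair.chrom_lengths,
                                          window=k.window)
        calls = karyotype.aneuploidy_test(
            profile, base_ploidy=k.base_ploidy, alpha=k.alpha,
            min_windows=k.min_windows)
        records = [
            {k: (None if isinstance(v, float) and np.isnan(v) else v)
             for k, v in rec.items()}
            for rec in calls.to_dict(orient="records")]
        report["stages"]["karyotype"] = {"calls": records}
        if out is not None and cfg.write_intermediate:
            profile.to_csv(out / "depth_profile.tsv", sep="\t", index=False)
            calls.to_csv(out / "aneuploidy_calls.tsv", sep="\t", index=False)
        _stage_done("karyotype", t)

    # --- dosage / association ---------------------------------------------
    if cfg.stages.dosage:
        t = time.time()
        c = cfg.cohort
        rng = np.random.default_rng(cfg.seed + 3)
        freqs = rng.uniform(c.base_freq_low, c.base_freq_high, size=c.n_sites)
        site_freqs = pd.DataFrame({
            "chrom": "chrA01",
            "pos": np.arange(c.n_sites, dtype=np.int64) * 1000,
            "freq_g1": freqs, "freq_g2": freqs,
        })
        causal_pos = int(site_freqs["pos"].iloc[c.n_sites // 2])
        site_freqs.loc[site_freqs["pos"] == causal_pos,
                       ["freq_g1", "freq_g2"]] = cfg.cohort.causal_freqs
        truth_cohort, phenotype = simdata.simulate_group_dosages(
            site_freqs, n_per_group=c.n_per_group, seed=cfg.seed + 4,
            ploidy=cfg.dosage.ploidy)
        depths = simdata.simulate_allele_depths(
            truth_cohort, mean_depth=c.mean_depth, seed=cfg.seed + 5,
            ploidy=cfg.dosage.ploidy, error_rate=c.error_rate)
        d = cfg.dosage
        genotypes = dosage_assoc.genotype_cohort(
            depths, ploidy=d.ploidy, error_rate=d.error_rate,
            min_depth=d.min_depth, min_minor_frac=d.min_minor_frac)
        spectrum = dosage_assoc.dosage_spectrum(genotypes, ploidy=d.ploidy)
        assoc = dosage_assoc.allele_freq_assoc(genotypes, phenotype,
                                               ploidy=d.ploidy)
        sites = assoc["sites"]
        min_p_row = sites.loc[sites["p"].idxmin()] if len(sites) else None
        pass_mask = genotypes["filter_status"] == dosage_assoc.PASS
        passed = genotypes[pass_mask]
        concordance = float(
            (passed["dosage"].astype(np.int64).to_numpy()
             == passed["truth_dosage"].to_numpy()).mean())
        report["stages"]["dosage"] = {
            "n_genotypes": int(len(genotypes)),
            "pass_fraction": float(pass_mask.mean()),
            "truth_concordance": concordance,
            "spectrum": {str(k_): v for k_, v in spectrum["class_counts"].items()},
            "n_het": spectrum["n_het"],
            "association": {
                "n_sites_tested": int(len(sites)),
                "n_sig_005": int(sites["sig_005"].sum()),
                "n_sig_05": int(sites["sig_05"].sum()),
                "causal_pos": causal_pos,
                "min_p_pos": (int(min_p_row["pos"])
                              if min_p_row is not None else None),
                "min_p": (float(min_p_row["p"])
                          if min_p_row is not None else None),
                "causal_recovered": (min_p_row is not None
                                     and int(min_p_row["pos"]) == causal_pos),
            },
        }
        if out is not None and cfg.write_intermediate:
            genotypes.to_csv(out / "genotypes.tsv", sep="\t", index=False)
            sites.to_csv(out / "association.tsv", sep="\t", index=False)
        _stage_done("dosage", t)

    report["timing"]["total"] = round(time.time() - t0, 3)
    validate_report(report)
    if out is not None:
        write_report(report, out / "report.json")
    return report


def validate_report(report: dict) -> None:
    for key in _REQUIRED_REPORT_KEYS:
        if key not in report:
            raise ValueError(f"report missing required key {key!r}")
    if report["schema_version"] != REPORT_SCHEMA_VERSION:
        raise ValueError("report schema version mismatch")
    if "config" not in report["manifest"]:
        raise ValueError("report manifest must echo the config")
    if not isinstance(report["stages"], dict):
        raise ValueError("report stages must be a mapping")


def write_report(report: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")


# ---------------------------------------------------------------------------
# stand-alone utilities
# ---------------------------------------------------------------------------

def divergence_time(ks: float, rate: float) -> float:
    """Divergence time in years from synonymous substitutions per site and
    the per-site per-year substitution rate: T = Ks / (2 r)."""
    if rate <= 0:
        raise ValueError("substitution rate must be positive")
    if ks < 0:
        raise ValueError("Ks must be non-negative")
    return ks / (2.0 * rate)


def expanded_families(counts: pd.DataFrame,
                      focal: tuple[str, str],
                      min_genes: int = 10,
                      ratio: float = 1.5,
                      mode: str = "both") -> list:
    """Flag gene families expanded in the two focal species.

    A family is expanded when either focal species has strictly more than
    ``min_genes`` genes and the focal counts are at least ``ratio`` times the
    largest count in any other species — required of both focal species with
    ``mode='both'`` (default), or of at least one with ``mode='either'``.
    """
    if mode not in ("both", "either"):
        raise ValueError("mode must be 'both' or 'either'")
    for col in focal:
        if col not in counts.columns:
            raise ValueError(f"missing focal column {col!r}")
    others = [c for c in counts.columns
              if c not in focal and c != "family_id"]
    if not others:
        raise ValueError("need at least one non-focal species column")
    if (counts[list(focal) + others] < 0).to_numpy().any():
        raise ValueError("gene counts must be non-negative")
    f1 = counts[focal[0]].to_numpy(np.int64)
    f2 = counts[focal[1]].to_numpy(np.int64)
    other_max = counts[others].to_numpy(np.int64).max(axis=1)
    size_ok = (f1 > min_genes) | (f2 > min_genes)
    if mode == "both":
        ratio_ok = np.minimum(f1, f2) >= ratio * other_max
    else:
        ratio_ok = np.maximum(f1, f2) >= ratio * other_max
    flagged = size_ok & ratio_ok
    ids = (counts["family_id"] if "family_id" in counts.columns
           else counts.index.to_series())
    return list(ids[flagged])
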