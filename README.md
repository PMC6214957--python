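# hexalink

Linked-read and dosage analyses for hexaploid genomes evaluated against two
diploid progenitor references, together with a synthetic allohexaploid data
generator that provides ground truth for every analysis.

The package covers five analysis stages plus orchestration:

| module | what it does |
| --- | --- |
| `hexalink.simdata` | simulates two SNP-diverged progenitor references (shared coordinates, optional reference-specific segments), a six-haplotype individual with inter-subgenome recombination mosaics, site fixation and whole-chromosome copy changes, barcoded linked reads, and allele-depth cohorts — all with truth files |
| `hexalink.sitescan` | tallies per-site allele depths and classifies variant sites as A-fixed / B-fixed / polymorphic / low-coverage |
| `hexalink.molecules` | reconstructs molecules from barcoded alignments (gap ≤ 10 kb chaining, span ≥ 10 kb), profiles per-molecule subgenome allele composition, matches molecules across the two references and derives shared / reference-specific regions |
| `hexalink.karyotype` | windowed depth profiles, fractional per-chromosome copy estimates and aneuploidy tests |
| `hexalink.dosage_assoc` | ploidy-6 binomial-MAP dosage calling with depth / minor-fraction filters, dosage spectra, Fisher's exact allele-frequency association for a binary phenotype, and an allele-bias (expression) test |
| `hexalink.pipeline` | configuration, the `run-all` orchestration with a versioned JSON report, divergence-time (`T = Ks/2r`) and gene-family-expansion utilities |

## Quick start (Python)

```python
from hexalink import simdata, sitescan, molecules, karyotype

pair, variants = simdata.simulate_progenitors(seed=1, n_chrom=3,
                                              chrom_len=1_000_000)
truth = simdata.simulate_hexaploid(pair, variants, switch_rate_per_mb=2.0,
                                   phi_a=0.462, phi_b=0.277, seed=2)
aln_a, aln_b, mol_truth = simdata.simulate_linked_reads(
    pair, truth, variants, coverage=30, error_rate=0.01, seed=3)

obs = sitescan.tally_site_depths(aln_a, variants)
classes = sitescan.classify_sites(obs)
mset = molecules.reconstruct_molecules(aln_a)
profile = karyotype.depth_profile(aln_a, pair.chrom_lengths)
calls = karyotype.aneuploidy_test(profile)
```

## CLI

```sh
hexalink simulate --seed 1 --out-dir out                 # synthetic dataset
hexalink sitescan --alignments out/alignments_A.tsv --vcf out/variants.vcf --out-dir scan
hexalink molecules --alignments-a out/alignments_A.tsv --alignments-b out/alignments_B.tsv \
    --vcf out/variants.vcf --out-dir mols
hexalink karyotype --alignments out/alignments_A.tsv --out-dir karyo
hexalink assoc --depths depths.tsv --phenotype phenotype.tsv --out-dir assoc
hexalink run-all --seed 1 --out-dir run                  # full pipeline + report.json
hexalink divergence-time 0.65 7.0e-9
hexalink famexp counts.tsv --focal sppA sppB
```

On-disk formats are plain text: FASTA references, VCF v4.2 variant sites
(REF = allele A, ALT = allele B), BED truth/region tracks (0-based
half-open), and a TSV alignment table with columns
`read_id barcode ref chrom start end mapq obs` where `obs` is
`pos:base;pos:base;...`.

## Tests and acceptance

```sh
python -m pytest -q tests/                    # unit + property + acceptance suite
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

`tests/test_acceptance.py` holds the acceptance criteria (oracle equality for
molecule chaining, parameter-recovery for site classification and subgenome
mixtures, aneuploidy type-I/power, dosage-caller symmetry and concordance,
Fisher exactness and calibration, the divergence-time closed form, and the
full-pipeline budget). `scripts/acceptance.py` runs a seed-controlled
end-to-end pipeline smoke; there are no numeric acceptance targets, so it
writes an empty JSON mapping.
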