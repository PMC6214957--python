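"""Synthetic allohexaploid genome, linked-read and dosage-cohort generators.

The generator family emulates the structure the downstream analyses assume:

* two SNP-diverged progenitor reference genomes sharing one coordinate
  system, with optional reference-specific (mutually unalignable) segments;
* a six-haplotype individual whose haplotypes are two-state (A/B origin)
  Markov mosaics along each chromosome, with optional site fixation (drift)
  and whole-chromosome copy gains/losses;
* barcoded molecules with exponential lengths carrying uniformly placed
  reads, each read reporting the source haplotype's allele at every variant
  site it covers (flipped with a symmetric error probability);
* per-sample allele-depth cohorts for the dosage genotyper and the
  allele-frequency association scan.

Every public function is deterministic given its ``seed``.  Truth structures
(haplotype tracks, per-molecule origin tallies, per-site dosages) are
returned alongside the observable data so that recovery tests can score the
analyses against the generator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import io

_BASES = np.array(["A", "C", "G", "T"])

#: default stationary A-origin probability (two A-like : one B-like contribution)
DEFAULT_PI_A = 2.0 / 3.0
#: default genome-wide fixation fractions for the A and B allele
DEFAULT_PHI_A = 0.462
DEFAULT_PHI_B = 0.277
DEFAULT_MOLECULE_LEN_MEAN = 50_000
DEFAULT_PLOIDY = 6


def _ragged_ranges(lo: np.ndarray, hi: np.ndarray):
    """Expand per-row [lo, hi) index ranges into flat (row, index) arrays."""
    counts = (hi - lo).astype(np.int64)
    total = int(counts.sum())
    if total == 0:
        return (np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64))
    rows = np.repeat(np.arange(len(lo), dtype=np.int64), counts)
    starts = np.concatenate(([0], np.cumsum(counts)[:-1]))
    offsets = np.arange(total, dtype=np.int64) - np.repeat(starts, counts)
    return rows, np.repeat(lo.astype(np.int64), counts) + offsets


# ---------------------------------------------------------------------------
# progenitor pair
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SpecificSegment:
    """Interval alignable only against one reference (``ref`` in {'A','B'})."""
    ref: str
    chrom: str
    start: int
    end: int


@dataclass
class ProgenitorPair:
    """Two same-coordinate reference genomes plus their specific segments."""

    chrom_names: list[str]
    chrom_lengths: dict[str, int]
    seq_a: dict[str, str]
    seq_b: dict[str, str]
    specific_segments: list[SpecificSegment] = field(default_factory=list)

    @property
    def genome_length(self) -> int:
        return sum(self.chrom_lengths.values())

    def segments_for(self, ref: str) -> pd.DataFrame:
        segs = [(s.chrom, s.start, s.end) for s in self.specific_segments
                if s.ref == ref]
        return pd.DataFrame(segs, columns=["chrom", "start", "end"])

    def write(self, out_dir) -> None:
        out = io.ensure_dir(out_dir)
        io.write_fasta(self.seq_a, out / "reference_A.fasta")
        io.write_fasta(self.seq_b, out / "reference_B.fasta")
        segs = pd.DataFrame(
            [(s.chrom, s.start, s.end, s.ref) for s in self.specific_segments],
            columns=["chrom", "start", "end", "ref"])
        io.write_bed(segs, out / "specific_segments.bed", extra_cols=["ref"])


def _validate_segments(segments: list[SpecificSegment],
                       chrom_lengths: dict[str, int]) -> None:
    by_chrom: dict[str, list[SpecificSegment]] = {}
    for seg in segments:
        if seg.ref not in ("A", "B"):
            raise ValueError(f"segment ref must be 'A' or 'B', got {seg.ref!r}")
        if seg.chrom not in chrom_lengths:
            raise ValueError(f"segment on unknown chromosome {seg.chrom!r}")
        if not (0 <= seg.start < seg.end <= chrom_lengths[seg.chrom]):
            raise ValueError(f"segment out of bounds: {seg}")
        by_chrom.setdefault(seg.chrom, []).append(seg)
    for chrom, segs in by_chrom.items():
        segs = sorted(segs, key=lambda s: s.start)
        for prev, cur in zip(segs, segs[1:]):
            if cur.start < prev.end:
                raise ValueError(
                    f"overlapping specific segments on {chrom}: {prev} / {cur}")


def simulate_progenitors(seed: int,
                         n_chrom: int = 1,
                         chrom_len: int | list[int] = 1_000_000,
                         divergence_rate: float = 0.01,
                         specific_segments: list | None = None,
                         ) -> tuple[ProgenitorPair, pd.DataFrame]:
    """Generate two SNP-diverged references and their variant table.

    ``specific_segments`` is a list of ``SpecificSegment`` or
    ``(ref, chrom, start, end)`` tuples.  Variant positions are drawn i.i.d.
    at ``divergence_rate`` outside specific segments; the B allele always
    differs from the A allele.
    """
    if not 0.0 <= divergence_rate <= 0.1:
        raise ValueError("divergence_rate must be in [0, 0.1]")
    lengths = ([int(chrom_len)] * n_chrom if np.isscalar(chrom_len)
               else [int(x) for x in chrom_len])
    if len(lengths) != n_chrom:
        raise ValueError("chrom_len list must have n_chrom entries")
    if any(length < 10_000 for length in lengths):
        raise ValueError("chromosomes must be at least 10 kb")

    names = [f"chr{i + 1:02d}" for i in range(n_chrom)]
    chrom_lengths = dict(zip(names, lengths))
    segments = [s if isinstance(s, SpecificSegment) else SpecificSegment(*s)
                for s in (specific_segments or [])]
    _validate_segments(segments, chrom_lengths)

    rng = np.random.default_rng(seed)
    seq_a: dict[str, str] = {}
    seq_b: dict[str, str] = {}
    var_frames = []
    for name, length in zip(names, lengths):
        codes_a = rng.integers(0, 4, size=length, dtype=np.int8)
        mask = rng.random(length) < divergence_rate
        for seg in segments:
            if seg.chrom == name:
                mask[seg.start:seg.end] = False
        pos = np.flatnonzero(mask)
        offset = rng.integers(1, 4, size=len(pos), dtype=np.int8)
        codes_b = codes_a.copy()
        codes_b[pos] = (codes_a[pos] + offset) % 4
        seq_a[name] = _codes_to_str(codes_a)
        seq_b[name] = _codes_to_str(codes_b)
        var_frames.append(pd.DataFrame({
            "chrom": name,
            "pos": pos.astype(np.int64),
            "allele_A": _BASES[codes_a[pos]],
            "allele_B": _BASES[codes_b[pos]],
        }))
    variants = pd.concat(var_frames, ignore_index=True)
    pair = ProgenitorPair(names, chrom_lengths, seq_a, seq_b, segments)
    return pair, variants


def _codes_to_str(codes: np.ndarray) -> str:
    ascii_map = np.array([65, 67, 71, 84], dtype=np.uint8)  # A C G T
    return ascii_map[codes].tobytes().decode("ascii")


# ---------------------------------------------------------------------------
# hexaploid individual
# ---------------------------------------------------------------------------

@dataclass
class HexaploidTruth:
    """Ground truth for one simulated polyploid individual.

    ``tracks`` tiles every haplotype copy of every chromosome with
    (start, end, origin) segments.  ``fixation`` parallels the variant table
    with a forced-allele flag in {'A', 'B', '.'}.
    """

    base_ploidy: int
    copy_number: dict[str, int]
    tracks: pd.DataFrame           # chrom, hap, start, end, origin
    fixation: pd.DataFrame         # chrom, pos, fixed
    pi_a: float
    switch_rate_per_mb: float
    phi_a: float
    phi_b: float
    _index: dict = field(default_factory=dict, repr=False)

    def _track_arrays(self, chrom: str, hap: int):
        key = (chrom, hap)
        if key not in self._index:
            g = self.tracks[(self.tracks["chrom"] == chrom)
                            & (self.tracks["hap"] == hap)]
            g = g.sort_values("start")
            self._index[key] = (g["start"].to_numpy(np.int64),
                                (g["origin"].to_numpy() == "A"))
        return self._index[key]

    def origin_is_a(self, chrom: str, hap: int, pos: np.ndarray) -> np.ndarray:
        starts, is_a = self._track_arrays(chrom, hap)
        idx = np.searchsorted(starts, np.asarray(pos, dtype=np.int64),
                              side="right") - 1
        return is_a[idx]

    def truth_dosage(self, variants: pd.DataFrame) -> np.ndarray:
        """Number of haplotype copies carrying the A allele at each variant."""
        dosage = np.zeros(len(variants), dtype=np.int64)
        pos_all = variants["pos"].to_numpy(np.int64)
        chroms = variants["chrom"].to_numpy()
        for chrom, copies in self.copy_number.items():
            mask = chroms == chrom
            if not mask.any():
                continue
            pos = pos_all[mask]
            tally = np.zeros(len(pos), dtype=np.int64)
            for hap in range(copies):
                tally += self.origin_is_a(chrom, hap, pos)
            dosage[mask] = tally
        fixed = self.fixation["fixed"].to_numpy()
        copies_per_row = variants["chrom"].map(self.copy_number).to_numpy(np.int64)
        dosage = np.where(fixed == "A", copies_per_row, dosage)
        dosage = np.where(fixed == "B", 0, dosage)
        return dosage

    def a_length_fraction(self) -> float:
        lengths = (self.tracks["end"] - self.tracks["start"]).to_numpy(np.float64)
        is_a = self.tracks["origin"].to_numpy() == "A"
        return float(lengths[is_a].sum() / lengths.sum())

    def write(self, out_dir) -> None:
        out = io.ensure_dir(out_dir)
        bed = self.tracks.copy()
        bed["name"] = ("hap" + bed["hap"].astype(str) + ":" + bed["origin"])
        io.write_bed(bed, out / "haplotype_tracks.bed", extra_cols=["name"])
        self.fixation.to_csv(out / "fixation.tsv", sep="\t", index=False)


def simulate_hexaploid(pair: ProgenitorPair,
                       variants: pd.DataFrame,
                       composition: tuple[int, int] = (4, 2),
                       pi_a: float = DEFAULT_PI_A,
                       switch_rate_per_mb: float = 0.0,
                       phi_a: float = 0.0,
                       phi_b: float = 0.0,
                       copy_spec: dict[str, int] | None = None,
                       seed: int = 0) -> HexaploidTruth:
    """Draw haplotype origin mosaics, fixation flags and copy numbers.

    Each haplotype starts in its composition-assigned origin state; switch
    points follow a Poisson process at ``switch_rate_per_mb`` and each switch
    resamples the origin from Bernoulli(``pi_a``), so the track is a two-state
    mosaic with stationary A-probability ``pi_a``.
    """
    if switch_rate_per_mb < 0:
        raise ValueError("switch_rate_per_mb must be >= 0")
    if not (0 <= phi_a <= 1 and 0 <= phi_b <= 1 and phi_a + phi_b <= 1):
        raise ValueError("phi_a, phi_b must be probabilities with phi_a+phi_b <= 1")
    base_ploidy = int(sum(composition))
    copy_spec = dict(copy_spec or {})
    for chrom, copies in copy_spec.items():
        if chrom not in pair.chrom_lengths:
            raise ValueError(f"copy_spec names unknown chromosome {chrom!r}")
        if not 1 <= copies <= 12:
            raise ValueError(f"copy number for {chrom} must be in [1, 12]")

    rng = np.random.default_rng(seed)
    base_origins = ["A"] * int(composition[0]) + ["B"] * int(composition[1])
    rate_bp = switch_rate_per_mb / 1e6

    rows = []
    copy_number: dict[str, int] = {}
    for chrom in pair.chrom_names:
        length = pair.chrom_lengths[chrom]
        copies = copy_spec.get(chrom, base_ploidy)
        copy_number[chrom] = copies
        origins = list(base_origins)
        if copies < base_ploidy:
            drop = rng.choice(base_ploidy, size=base_ploidy - copies, replace=False)
            origins = [o for i, o in enumerate(origins) if i not in set(drop.tolist())]
        elif copies > base_ploidy:
            dup = rng.choice(base_ploidy, size=copies - base_ploidy, replace=True)
            origins = origins + [origins[i] for i in dup.tolist()]
        for hap, start_state in enumerate(origins):
            n_events = rng.poisson(rate_bp * length)
            breaks = np.sort(rng.integers(1, length, size=n_events)) if n_events else np.empty(0, np.int64)
            states = [start_state]
            if n_events:
                draws = rng.random(n_events) < pi_a
                states += ["A" if d else "B" for d in draws]
            bounds = np.concatenate(([0], breaks, [length])).astype(np.int64)
            # merge consecutive identical states
            seg_start = int(bounds[0])
            for i in range(len(states)):
                s, e = int(bounds[i]), int(bounds[i + 1])
                if i + 1 < len(states) and states[i + 1] == states[i]:
                    continue_merge = True
                else:
                    continue_merge = False
                if not continue_merge:
                    rows.append((chrom, hap, seg_start, e, states[i]))
                    seg_start = e
    tracks = pd.DataFrame(rows, columns=["chrom", "hap", "start", "end", "origin"])
    tracks = tracks[tracks["end"] > tracks["start"]].reset_index(drop=True)

    u = rng.random(len(variants))
    fixed = np.full(len(variants), ".", dtype=object)
    fixed[u < phi_a] = "A"
    fixed[(u >= phi_a) & (u < phi_a + phi_b)] = "B"
    fixation = pd.DataFrame({"chrom": variants["chrom"].to_numpy(),
                             "pos": variants["pos"].to_numpy(np.int64),
                             "fixed": fixed})
    return HexaploidTruth(base_ploidy=base_ploidy, copy_number=copy_number,
                          tracks=tracks, fixation=fixation, pi_a=pi_a,
                          switch_rate_per_mb=switch_rate_per_mb,
                          phi_a=phi_a, phi_b=phi_b)


# ---------------------------------------------------------------------------
# linked reads
# ---------------------------------------------------------------------------

@dataclass
class AlignmentTable:
    """Barcoded alignment records against one reference.

    ``reads`` columns: read_id, barcode, chrom, start, end, mapq.
    ``obs`` columns: read_id, chrom, pos, base — one row per allele
    observation at a variant site covered by the read.
    """

    ref: str
    reads: pd.DataFrame
    obs: pd.DataFrame

    @property
    def n_reads(self) -> int:
        return len(self.reads)

    def total_aligned_bases(self) -> int:
        return int((self.reads["end"] - self.reads["start"]).sum())

    def to_tsv(self, path) -> None:
        reads = self.reads.copy()
        if self.obs.empty:
            obs_str = pd.Series(dtype=object)
        else:
            obs = self.obs.sort_values(["read_id", "pos"])
            joined = (obs["pos"].astype(str) + ":" + obs["base"].astype(str))
            obs_str = joined.groupby(obs["read_id"].to_numpy()).agg(";".join)
        reads["read_id"] = reads["read_id"].map(_format_read_id)
        reads["barcode"] = reads["barcode"].map(_format_barcode)
        reads["ref"] = self.ref
        reads["obs"] = self.reads["read_id"].map(obs_str).fillna(".").to_numpy()
        cols = ["read_id", "barcode", "ref", "chrom", "start", "end", "mapq", "obs"]
        reads[cols].to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "AlignmentTable":
        df = pd.read_csv(path, sep="\t", dtype={"obs": str})
        refs = df["ref"].unique()
        if len(refs) != 1:
            raise ValueError("alignment TSV must carry a single reference tag")
        obs_rows = {"read_id": [], "chrom": [], "pos": [], "base": []}
        for read_id, chrom, obs in df[["read_id", "chrom", "obs"]].itertuples(index=False):
            if obs == "." or pd.isna(obs):
                continue
            for item in obs.split(";"):
                pos, base = item.split(":")
                obs_rows["read_id"].append(read_id)
                obs_rows["chrom"].append(chrom)
                obs_rows["pos"].append(int(pos))
                obs_rows["base"].append(base)
        reads = df.drop(columns=["obs", "ref"])
        obs_df = pd.DataFrame(obs_rows)
        return cls(ref=str(refs[0]), reads=reads, obs=obs_df)


def _format_read_id(x) -> str:
    return f"r{x:09d}" if isinstance(x, (int, np.integer)) else str(x)


def _format_barcode(x) -> str:
    return f"BX{x:08d}" if isinstance(x, (int, np.integer)) else str(x)


def simulate_linked_reads(pair: ProgenitorPair,
                          truth: HexaploidTruth,
                          variants: pd.DataFrame,
                          coverage: float = 30.0,
                          molecule_len_mean: float = DEFAULT_MOLECULE_LEN_MEAN,
                          reads_per_kb: float = 0.5,
                          read_len: int = 150,
                          error_rate: float = 0.0,
                          barcode_pool: int = 500_000,
                          mapq: int = 60,
                          seed: int = 0,
                          ) -> tuple[AlignmentTable, AlignmentTable, pd.DataFrame]:
    """Simulate barcoded molecules and reads against both references.

    ``coverage`` is the target depth at a euploid reference position (all
    haplotype copies pooled); chromosomes with ``c`` copies receive depth
    ``coverage * c / base_ploidy``.  Molecule placement is edge-uniform:
    a molecule of length ``l`` starts uniformly on ``[-l, L)`` and is clipped
    to the chromosome, so expected coverage is flat along the chromosome.

    Returns the vs-A table, the vs-B table (identical coordinates except that
    reads overlapping a reference-specific segment of X only appear in the
    vs-X table) and a molecule truth frame with per-molecule pre-error allele
    tallies (n_true_a / n_true_b).
    """
    if coverage <= 0:
        raise ValueError("coverage must be positive")
    if not 0 <= error_rate <= 1:
        raise ValueError("error_rate must be a probability")

    rng = np.random.default_rng(seed)
    chroms = list(pair.chrom_names)
    lengths = np.array([pair.chrom_lengths[c] for c in chroms], dtype=np.float64)
    copies = np.array([truth.copy_number[c] for c in chroms], dtype=np.float64)
    weights = lengths * copies
    probs = weights / weights.sum()
    target_bases = coverage * float(weights.sum()) / truth.base_ploidy

    est_bases_per_mol = max(
        reads_per_kb * 0.8 * molecule_len_mean / 1000.0 * read_len, read_len)
    batch = int(target_bases / est_bases_per_mol * 1.25) + 32

    chrom_idx_l, mstart_l, mend_l, hap_l, bc_l, nreads_l = [], [], [], [], [], []
    emitted = 0.0
    while emitted < target_bases:
        ci = rng.choice(len(chroms), size=batch, p=probs)
        mlen = rng.exponential(molecule_len_mean, size=batch)
        L = lengths[ci]
        s0 = rng.uniform(-mlen, L)
        ms = np.maximum(s0, 0.0).astype(np.int64)
        me = np.minimum(s0 + mlen, L).astype(np.int64)
        real_len = me - ms
        lam = reads_per_kb * np.maximum(real_len, 0) / 1000.0
        nr = rng.poisson(lam)
        nr[real_len < 1] = 0
        bc = rng.integers(0, barcode_pool, size=batch)
        hap = np.floor(rng.random(batch) * copies[ci]).astype(np.int64)
        cum = emitted + np.cumsum(nr.astype(np.float64) * read_len)
        cut = int(np.searchsorted(cum, target_bases)) + 1
        cut = min(cut, batch)
        chrom_idx_l.append(ci[:cut]); mstart_l.append(ms[:cut])
        mend_l.append(me[:cut]); hap_l.append(hap[:cut])
        bc_l.append(bc[:cut]); nreads_l.append(nr[:cut])
        emitted = float(cum[cut - 1]) if cut else emitted

    chrom_idx = np.concatenate(chrom_idx_l)
    mstart = np.concatenate(mstart_l)
    mend = np.concatenate(mend_l)
    hap = np.concatenate(hap_l)
    barcode = np.concatenate(bc_l)
    n_reads = np.concatenate(nreads_l)
    n_mol = len(chrom_idx)

    mol_of_read = np.repeat(np.arange(n_mol, dtype=np.int64), n_reads)
    tot = len(mol_of_read)
    offmax = np.maximum((mend - mstart) - read_len, 0)
    rstart = mstart[mol_of_read] + np.floor(
        rng.random(tot) * (offmax[mol_of_read] + 1)).astype(np.int64)
    rend = np.minimum(rstart + read_len, mend[mol_of_read])

    chrom_arr = np.array(chroms, dtype=object)
    read_chrom_idx = chrom_idx[mol_of_read]

    # --- allele observations ------------------------------------------------
    var_chrom = variants["chrom"].to_numpy()
    var_pos = variants["pos"].to_numpy(np.int64)
    allele_a = variants["allele_A"].to_numpy()
    allele_b = variants["allele_B"].to_numpy()
    fixed = truth.fixation["fixed"].to_numpy()

    obs_read_l, obs_var_l = [], []
    var_offsets = {}
    for k, chrom in enumerate(chroms):
        vmask = var_chrom == chrom
        voffset = int(np.flatnonzero(vmask)[0]) if vmask.any() else 0
        var_offsets[chrom] = voffset
        vpos = var_pos[vmask]
        rmask = np.flatnonzero(read_chrom_idx == k)
        if len(rmask) == 0 or len(vpos) == 0:
            continue
        lo = np.searchsorted(vpos, rstart[rmask])
        hi = np.searchsorted(vpos, rend[rmask])
        rows, vidx = _ragged_ranges(lo, hi)
        obs_read_l.append(rmask[rows])
        obs_var_l.append(vidx + voffset)
    if obs_read_l:
        obs_read = np.concatenate(obs_read_l)
        obs_var = np.concatenate(obs_var_l)
    else:
        obs_read = np.empty(0, dtype=np.int64)
        obs_var = np.empty(0, dtype=np.int64)

    # truth allele per observation
    is_a_true = np.zeros(len(obs_var), dtype=bool)
    obs_fixed = fixed[obs_var]
    is_a_true[obs_fixed == "A"] = True
    free = obs_fixed == "."
    if free.any():
        obs_hap = hap[mol_of_read[obs_read]]
        obs_chrom_idx = read_chrom_idx[obs_read]
        for k, chrom in enumerate(chroms):
            for h in range(int(copies[k])):
                sel = np.flatnonzero(free & (obs_chrom_idx == k) & (obs_hap == h))
                if len(sel) == 0:
                    continue
                is_a_true[sel] = truth.origin_is_a(chrom, h, var_pos[obs_var[sel]])

    flips = rng.random(len(obs_var)) < error_rate
    is_a_obs = is_a_true ^ flips
    base_cats = list(_BASES)
    code_a = pd.Categorical(allele_a, categories=base_cats).codes
    code_b = pd.Categorical(allele_b, categories=base_cats).codes
    obs_base_codes = np.where(is_a_obs, code_a[obs_var], code_b[obs_var])

    # categoricals keep the big frames integer-backed
    reads_df = pd.DataFrame({
        "read_id": np.arange(tot, dtype=np.int64),
        "barcode": barcode[mol_of_read],
        "chrom": pd.Categorical.from_codes(read_chrom_idx, categories=chroms),
        "start": rstart,
        "end": rend,
        "mapq": np.full(tot, mapq, dtype=np.int16),
        "hap": hap[mol_of_read],
        "molecule_id": mol_of_read,
    })
    obs_df = pd.DataFrame({
        "read_id": obs_read,
        "chrom": pd.Categorical.from_codes(read_chrom_idx[obs_read],
                                           categories=chroms),
        "pos": var_pos[obs_var],
        "base": pd.Categorical.from_codes(obs_base_codes, categories=base_cats),
    })

    # molecule truth with pre-error allele tallies
    n_true_a = np.bincount(mol_of_read[obs_read], weights=is_a_true,
                           minlength=n_mol).astype(np.int64)
    n_obs_tot = np.bincount(mol_of_read[obs_read], minlength=n_mol)
    mol_truth = pd.DataFrame({
        "molecule_id": np.arange(n_mol, dtype=np.int64),
        "barcode": barcode,
        "chrom": chrom_arr[chrom_idx],
        "start": mstart,
        "end": mend,
        "hap": hap,
        "n_reads": n_reads.astype(np.int64),
        "n_true_a": n_true_a,
        "n_true_b": (n_obs_tot - n_true_a).astype(np.int64),
    })
    mol_truth = mol_truth[mol_truth["n_reads"] > 0].reset_index(drop=True)

    # reference-specific segment masking
    keep_a = np.ones(tot, dtype=bool)   # vs-A table: drop reads in B-specific
    keep_b = np.ones(tot, dtype=bool)
    for seg in pair.specific_segments:
        k = chroms.index(seg.chrom)
        overlap = ((read_chrom_idx == k) & (rstart < seg.end)
                   & (rend > seg.start))
        if seg.ref == "A":
            keep_b &= ~overlap
        else:
            keep_a &= ~overlap

    def _table(ref: str, keep: np.ndarray) -> AlignmentTable:
        kept_reads = reads_df.loc[keep, ["read_id", "barcode", "chrom",
                                         "start", "end", "mapq"]].reset_index(drop=True)
        # read_id is the row position in reads_df, so keep[] indexes directly
        obs_keep = obs_df[keep[obs_df["read_id"].to_numpy()]].reset_index(drop=True)
        return AlignmentTable(ref=ref, reads=kept_reads, obs=obs_keep)

    aln_a = _table("A", keep_a)
    aln_b = _table("B", keep_b)
    return aln_a, aln_b, mol_truth


# ---------------------------------------------------------------------------
# dosage cohorts
# ---------------------------------------------------------------------------

def simulate_cohort_truth(n_samples: int,
                          n_sites: int,
                          seed: int,
                          ploidy: int = DEFAULT_PLOIDY,
                          hom_fraction: float = 0.45,
                          het_class_weights: tuple = (3.0, 2.0, 1.0),
                          chrom: str = "chr01",
                          spacing: int = 200) -> pd.DataFrame:
    """Per-sample truth dosages with a configurable heterozygous class mix.

    With probability ``hom_fraction`` a call is homozygous (dosage 0 or
    ``ploidy``, equiprobable); otherwise the minor-allele class is drawn from
    ``het_class_weights`` (classes 1..len(weights)) and the minor side is
    chosen at random.
    """
    rng = np.random.default_rng(seed)
    w = np.asarray(het_class_weights, dtype=np.float64)
    w = w / w.sum()
    total = n_samples * n_sites
    u_hom = rng.random(total) < hom_fraction
    cls = rng.choice(np.arange(1, len(w) + 1), size=total, p=w)
    minor_is_alt = rng.random(total) < 0.5
    hom_alt = rng.random(total) < 0.5
    dosage = np.where(minor_is_alt, cls, ploidy - cls)
    dosage = np.where(u_hom, np.where(hom_alt, ploidy, 0), dosage)
    samples = np.repeat([f"S{i:03d}" for i in range(n_samples)], n_sites)
    pos = np.tile(np.arange(n_sites, dtype=np.int64) * spacing, n_samples)
    return pd.DataFrame({"sample": samples, "chrom": chrom, "pos": pos,
                         "dosage": dosage.astype(np.int64)})


def simulate_group_dosages(site_freqs: pd.DataFrame,
                           n_per_group: int,
                           seed: int,
                           ploidy: int = DEFAULT_PLOIDY,
                           ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Population-model truth dosages for a two-group cohort.

    ``site_freqs`` columns: chrom, pos, freq_g1, freq_g2 — the alternate
    allele frequency in each group; dosages are Binomial(ploidy, freq).
    Returns (truth frame, phenotype frame).
    """
    rng = np.random.default_rng(seed)
    samples = [f"S{i:03d}" for i in range(2 * n_per_group)]
    groups = ["group1"] * n_per_group + ["group2"] * n_per_group
    phenotype = pd.DataFrame({"sample": samples, "group": groups})
    frames = []
    for sample, group in zip(samples, groups):
        q = site_freqs["freq_g1" if group == "group1" else "freq_g2"].to_numpy()
        dosage = rng.binomial(ploidy, q)
        frames.append(pd.DataFrame({
            "sample": sample,
            "chrom": site_freqs["chrom"].to_numpy(),
            "pos": site_freqs["pos"].to_numpy(np.int64),
            "dosage": dosage.astype(np.int64),
        }))
    return pd.concat(frames, ignore_index=True), phenotype


def simulate_allele_depths(truth: pd.DataFrame,
                           mean_depth: float,
                           seed: int,
                           ploidy: int = DEFAULT_PLOIDY,
                           error_rate: float = 0.01) -> pd.DataFrame:
    """Draw (ref_depth, alt_depth) for each truth dosage row.

    Total depth is Poisson(``mean_depth``); alternate reads are binomial with
    success probability (d/ploidy)(1-e) + (1-d/ploidy)e.
    """
    if mean_depth <= 0:
        raise ValueError("mean_depth must be positive")
    rng = np.random.default_rng(seed)
    d = truth["dosage"].to_numpy(np.int64)
    n = rng.poisson(mean_depth, size=len(d))
    p = (d / ploidy) * (1 - error_rate) + (1 - d / ploidy) * error_rate
    alt = rng.binomial(n, p)
    out = truth.rename(columns={"dosage": "truth_dosage"}).copy()
    out["ref_depth"] = (n - alt).astype(np.int64)
    out["alt_depth"] = alt.astype(np.int64)
    return out
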