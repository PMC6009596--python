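"""Seeded toy allotetraploid truth set and simulated evidence.

The generator emulates, at desk scale, the data supporting assembly
curation of an AABB-type allotetraploid: two diploid ancestors, two
homoeologous subgenomes derived from them, a fragmented draft with planted
chimeric joins, nick-site optical molecules with sizing noise, mate-pair
libraries with per-library insert distributions, long reads with soft-clip
signatures at misjoins, and Hi-C contacts with power-law distance decay
plus a uniform inter-chromosome background.

Every simulator is a pure function of (truth, config); randomness comes
from ``numpy.random.default_rng([config.seed, OP_TAG])`` with one tag per
operation, so stages can be re-run independently and outputs are
byte-identical under a fixed seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .optical import DEFAULT_MOTIF, NickMap, OpticalMolecule, digest_sequence, reverse_complement

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

# per-operation RNG stream tags
_TAG_TRUTH = 11
_TAG_DRAFT = 23
_TAG_MOLECULES = 37
_TAG_MATEPAIRS = 41
_TAG_LONGREADS = 53
_TAG_CONTACTS = 67


# ---------------------------------------------------------------------------
# Configuration and truth containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MPLibrarySpec:
    name: str
    insert_mean: int
    insert_sd: int
    n_pairs: int


@dataclass
class SimulationConfig:
    """Study conditions for the toy allotetraploid.

    Defaults: 2 subgenomes x 2 chromosomes x 500 kb, 3% divergence between
    ancestors, 1% from each ancestor to its subgenome, 5 planted chimeras,
    ~80-kb draft fragments, three mate-pair libraries spanning the 3-17 kb
    insert range, 25x optical-molecule coverage, 10x long-read coverage and
    150k Hi-C contacts with decay exponent 1.
    """

    seed: int = 0
    n_chromosomes_per_subgenome: int = 2
    chromosome_length: int = 500_000
    ancestor_divergence: float = 0.03
    subgenome_divergence: float = 0.01
    indel_rate: float = 1e-4
    max_indel: int = 5
    n_chimeras: int = 5
    chimera_cross_subgenome_prob: float = 0.5
    fragment_length_mean: int = 80_000
    fragment_length_sd: int = 15_000
    fragment_length_min: int = 40_000
    mp_libraries: Tuple[MPLibrarySpec, ...] = (
        MPLibrarySpec("mp3k", 3_000, 300, 20_000),
        MPLibrarySpec("mp8k", 8_000, 800, 10_000),
        MPLibrarySpec("mp17k", 17_000, 1_700, 5_000),
    )
    mp_read_length: int = 100
    mp_nonunique_fraction: float = 0.05
    molecule_coverage: float = 25.0
    molecule_length_mean: int = 220_000
    molecule_length_sd: int = 40_000
    molecule_fail_fraction: float = 0.10
    sizing_noise: float = 0.02
    label_fn_rate: float = 0.05
    label_fp_rate: float = 1e-6
    longread_coverage: float = 10.0
    longread_length_mean: int = 12_000
    longread_length_sd: int = 3_000
    longread_length_min: int = 2_000
    longread_min_overlap: int = 500
    clip_jitter_sd: float = 30.0
    n_contacts: int = 150_000
    hic_decay_exponent: float = 1.0
    hic_inter_fraction: float = 0.10
    hic_low_mapq_fraction: float = 0.10
    hic_dup_fraction: float = 0.05

    def __post_init__(self) -> None:
        libs = tuple(MPLibrarySpec(*lib) if not isinstance(lib, MPLibrarySpec) else lib
                     for lib in self.mp_libraries)
        self.mp_libraries = libs
        for name in ("ancestor_divergence", "subgenome_divergence", "indel_rate",
                     "chimera_cross_subgenome_prob", "mp_nonunique_fraction",
                     "molecule_fail_fraction", "label_fn_rate", "label_fp_rate",
                     "hic_inter_fraction", "hic_low_mapq_fraction",
                     "hic_dup_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("n_chromosomes_per_subgenome", "chromosome_length",
                     "fragment_length_mean", "mp_read_length",
                     "molecule_length_mean", "longread_length_mean",
                     "n_contacts"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_chimeras < 0:
            raise ValueError("n_chimeras must be >= 0")
        if self.molecule_coverage <= 0:
            raise ValueError("molecule_coverage must be positive")
        for lib in self.mp_libraries:
            if lib.insert_sd <= 0:
                raise ValueError(f"library {lib.name}: insert_sd must be > 0")
            if lib.insert_mean <= 0:
                raise ValueError(f"library {lib.name}: insert_mean must be > 0")

    def rng(self, tag: int) -> np.random.Generator:
        return np.random.default_rng([self.seed, tag])


@dataclass
class Fragment:
    """One contiguous truth interval placed in the draft assembly."""

    chrom: str
    start: int  # truth coordinates, 0-based half-open
    end: int
    strand: str  # orientation of this interval inside its draft sequence
    draft_id: str
    draft_start: int  # offset of the interval within the draft sequence
    order_index: int  # position along the truth chromosome

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class Chimera:
    """A planted misjoin: one draft sequence concatenating two non-adjacent
    truth intervals."""

    draft_id: str
    junction: int  # 0-based coordinate in the draft sequence
    left: Tuple[str, int, int, str]  # (chrom, start, end, strand)
    right: Tuple[str, int, int, str]


@dataclass
class TruthSet:
    chromosomes: Dict[str, str]  # subgenome chromosome sequences
    ancestors: Dict[str, Dict[str, str]]  # {'A': {...}, 'B': {...}}
    subgenome_of: Dict[str, str]  # chromosome -> 'A' | 'B'
    fragments: List[Fragment] = field(default_factory=list)
    chimeras: List[Chimera] = field(default_factory=list)

    def fragments_of_chrom(self, chrom: str) -> List[Fragment]:
        frags = [f for f in self.fragments if f.chrom == chrom]
        return sorted(frags, key=lambda f: f.start)

    def chrom_length(self, chrom: str) -> int:
        return len(self.chromosomes[chrom])


# ---------------------------------------------------------------------------
# Sequence helpers (uint8 codes 0..3 internally)
# ---------------------------------------------------------------------------

def _codes_to_str(codes: np.ndarray) -> str:
    return _BASES[codes].tobytes().decode("ascii")


def _str_to_codes(seq: str) -> np.ndarray:
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    codes = np.zeros(raw.size, dtype=np.uint8)
    for i, b in enumerate(b"ACGT"):
        codes[raw == b] = i
    return codes


def _mutate(codes: np.ndarray, sub_rate: float, indel_rate: float,
            max_indel: int, rng: np.random.Generator) -> np.ndarray:
    """Point substitutions at sub_rate plus short (<= max_indel) indels."""
    out = codes.copy()
    n = out.size
    if sub_rate > 0:
        mask = rng.random(n) < sub_rate
        shifts = rng.integers(1, 4, size=int(mask.sum()), dtype=np.uint8)
        out[mask] = (out[mask] + shifts) % 4
    if indel_rate > 0:
        n_indels = rng.binomial(n, indel_rate)
        if n_indels:
            sites = np.sort(rng.choice(n, size=n_indels, replace=False))
            is_ins = rng.random(n_indels) < 0.5
            sizes = rng.integers(1, max_indel + 1, size=n_indels)
            pieces = []
            prev = 0
            for site, ins, size in zip(sites, is_ins, sizes):
                pieces.append(out[prev:site])
                if ins:
                    pieces.append(rng.integers(0, 4, size=size, dtype=np.uint8))
                    prev = site
                else:
                    prev = min(site + size, n)
            pieces.append(out[prev:])
            out = np.concatenate(pieces)
    return out


# ---------------------------------------------------------------------------
# Truth simulation
# ---------------------------------------------------------------------------

def simulate_truth(config: SimulationConfig) -> TruthSet:
    """Two ancestors and two derived subgenomes.

    Ancestor A is random; ancestor B diverges from it by
    ``ancestor_divergence`` substitutions/bp (plus rare short indels); each
    subgenome diverges from its ancestor by ``subgenome_divergence``.
    """
    if config.chromosome_length <= 0:
        raise ValueError("chromosome_length must be positive")
    rng = config.rng(_TAG_TRUTH)
    anc: Dict[str, Dict[str, str]] = {"A": {}, "B": {}}
    chroms: Dict[str, str] = {}
    subg: Dict[str, str] = {}
    for i in range(config.n_chromosomes_per_subgenome):
        base = rng.integers(0, 4, size=config.chromosome_length, dtype=np.uint8)
        anc_b = _mutate(base, config.ancestor_divergence, config.indel_rate,
                        config.max_indel, rng)
        name_a, name_b = f"ancA_chr{i + 1}", f"ancB_chr{i + 1}"
        anc["A"][name_a] = _codes_to_str(base)
        anc["B"][name_b] = _codes_to_str(anc_b)
        sub_a = _mutate(base, config.subgenome_divergence, config.indel_rate,
                        config.max_indel, rng)
        sub_b = _mutate(anc_b, config.subgenome_divergence, config.indel_rate,
                        config.max_indel, rng)
        ca, cb = f"A{i + 1:02d}", f"B{i + 1:02d}"
        chroms[ca] = _codes_to_str(sub_a)
        chroms[cb] = _codes_to_str(sub_b)
        subg[ca] = "A"
        subg[cb] = "B"
    return TruthSet(chromosomes=chroms, ancestors=anc, subgenome_of=subg)


# ---------------------------------------------------------------------------
# Draft assembly with planted chimeras
# ---------------------------------------------------------------------------

def _fragment_chromosome(length: int, config: SimulationConfig,
                         rng: np.random.Generator) -> List[Tuple[int, int]]:
    cuts = [0]
    while cuts[-1] < length:
        size = int(rng.normal(config.fragment_length_mean,
                              config.fragment_length_sd))
        size = max(size, config.fragment_length_min)
        cuts.append(min(cuts[-1] + size, length))
    if len(cuts) > 2 and cuts[-1] - cuts[-2] < config.fragment_length_min:
        del cuts[-2]  # merge a short terminal sliver into its neighbour
    return list(zip(cuts[:-1], cuts[1:]))


def make_draft_with_chimeras(truth: TruthSet, config: SimulationConfig
                             ) -> Tuple[Dict[str, str], TruthSet]:
    """Fragment truth chromosomes into draft contigs and fuse ``n_chimeras``
    non-adjacent fragment pairs into chimeric contigs, recording the planted
    junctions in the returned (new) truth set."""
    rng = config.rng(_TAG_DRAFT)
    frags: List[Fragment] = []
    idx = 0
    for chrom in sorted(truth.chromosomes):
        seq = truth.chromosomes[chrom]
        for order, (s, e) in enumerate(_fragment_chromosome(len(seq), config, rng)):
            idx += 1
            strand = "+" if rng.random() < 0.5 else "-"
            frags.append(Fragment(chrom=chrom, start=s, end=e, strand=strand,
                                  draft_id=f"ctg{idx:04d}", draft_start=0,
                                  order_index=order))
    if 2 * config.n_chimeras > len(frags):
        raise ValueError(
            f"n_chimeras={config.n_chimeras} needs {2 * config.n_chimeras} "
            f"fragments but only {len(frags)} were produced")

    def adjacent(f1: Fragment, f2: Fragment) -> bool:
        return f1.chrom == f2.chrom and abs(f1.order_index - f2.order_index) <= 1

    chimeras: List[Chimera] = []
    used: set = set()
    pool = list(range(len(frags)))
    for k in range(config.n_chimeras):
        avail = [i for i in pool if i not in used]
        cross = rng.random() < config.chimera_cross_subgenome_prob
        for _ in range(200):  # rejection-sample a valid pair
            i, j = rng.choice(len(avail), size=2, replace=False)
            f1, f2 = frags[avail[i]], frags[avail[j]]
            if adjacent(f1, f2):
                continue
            diff_sub = truth.subgenome_of[f1.chrom] != truth.subgenome_of[f2.chrom]
            if cross and not diff_sub and rng.random() < 0.8:
                continue
            used.add(avail[i])
            used.add(avail[j])
            cid = f"chim{k + 1:02d}"
            f1 = dataclasses.replace(f1, draft_id=cid, draft_start=0)
            f2 = dataclasses.replace(f2, draft_id=cid, draft_start=f1.length)
            frags[avail[i]] = f1
            frags[avail[j]] = f2
            chimeras.append(Chimera(
                draft_id=cid, junction=f1.length,
                left=(f1.chrom, f1.start, f1.end, f1.strand),
                right=(f2.chrom, f2.start, f2.end, f2.strand)))
            break
        else:  # pragma: no cover - would need a pathological config
            raise RuntimeError("could not place a chimera pair")

    def frag_seq(f: Fragment) -> str:
        s = truth.chromosomes[f.chrom][f.start:f.end]
        return s if f.strand == "+" else reverse_complement(s)

    draft: Dict[str, str] = {}
    for f in frags:
        if f.draft_id.startswith("chim"):
            continue
        draft[f.draft_id] = frag_seq(f)
    for ch in chimeras:
        parts = sorted((f for f in frags if f.draft_id == ch.draft_id),
                       key=lambda f: f.draft_start)
        draft[ch.draft_id] = "".join(frag_seq(f) for f in parts)

    new_truth = dataclasses.replace(truth, fragments=frags, chimeras=chimeras)
    return draft, new_truth


# ---------------------------------------------------------------------------
# Truth -> draft coordinate lifting
# ---------------------------------------------------------------------------

class CoordinateLifter:
    """Maps truth points/reads into draft coordinates via the fragment table."""

    def __init__(self, truth: TruthSet):
        self._by_chrom: Dict[str, Tuple[np.ndarray, List[Fragment]]] = {}
        for chrom in truth.chromosomes:
            frs = truth.fragments_of_chrom(chrom)
            starts = np.array([f.start for f in frs], dtype=np.int64)
            self._by_chrom[chrom] = (starts, frs)

    def fragment_at(self, chrom: str, pos: int) -> Optional[Fragment]:
        starts, frs = self._by_chrom[chrom]
        i = int(np.searchsorted(starts, pos, side="right")) - 1
        if i < 0 or pos >= frs[i].end:
            return None
        return frs[i]

    def lift_point(self, chrom: str, pos: int) -> Optional[Tuple[str, int]]:
        f = self.fragment_at(chrom, pos)
        if f is None:
            return None
        off = pos - f.start
        if f.strand == "+":
            return f.draft_id, f.draft_start + off
        return f.draft_id, f.draft_start + (f.length - 1 - off)

    def lift_read(self, chrom: str, start: int, length: int, strand: str
                  ) -> Optional[Tuple[str, int, str]]:
        """Lift a read interval [start, start+length); None if it is not
        fully contained in a single fragment.  Returns (draft_id, leftmost
        draft coordinate, draft strand)."""
        f = self.fragment_at(chrom, start)
        if f is None or start + length > f.end:
            return None
        if f.strand == "+":
            return f.draft_id, f.draft_start + (start - f.start), strand
        dstart = f.draft_start + (f.end - start - length)
        return f.draft_id, dstart, ("-" if strand == "+" else "+")


# ---------------------------------------------------------------------------
# Optical molecules
# ---------------------------------------------------------------------------

def simulate_molecules(truth: TruthSet, motif: str = DEFAULT_MOTIF,
                       config: Optional[SimulationConfig] = None
                       ) -> List[OpticalMolecule]:
    """Sample molecules from the true chromosomes at ``molecule_coverage``,
    with Gaussian sizing noise proportional to inter-label distance, missed
    and spurious labels at the configured rates, and quality attributes drawn
    so that ``molecule_fail_fraction`` of molecules fail the retention
    filters."""
    if not motif:
        raise ValueError("motif must be non-empty")
    config = config or SimulationConfig()
    if config.molecule_coverage <= 0:
        raise ValueError("molecule_coverage must be positive")
    rng = config.rng(_TAG_MOLECULES)
    chroms = sorted(truth.chromosomes)
    lengths = np.array([len(truth.chromosomes[c]) for c in chroms], dtype=np.int64)
    nicks = {c: digest_sequence(truth.chromosomes[c], motif, c).labels
             for c in chroms}
    target = config.molecule_coverage * lengths.sum()
    total = 0
    out: List[OpticalMolecule] = []
    i = 0
    p = lengths / lengths.sum()
    while total < target:
        i += 1
        chrom = chroms[rng.choice(len(chroms), p=p)]
        L = len(truth.chromosomes[chrom])
        fail = rng.random() < config.molecule_fail_fraction
        if fail:
            mode = rng.integers(0, 3)
        else:
            mode = -1
        if mode == 0:  # too short
            mlen = int(rng.uniform(60_000, 150_000))
        else:
            mlen = int(rng.normal(config.molecule_length_mean,
                                  config.molecule_length_sd))
            mlen = max(mlen, 155_000)
        mlen = min(mlen, L)
        start = int(rng.integers(0, max(L - mlen, 0) + 1))
        pos = nicks[chrom]
        rel = pos[(pos >= start) & (pos < start + mlen)] - start
        # missed labels
        if config.label_fn_rate > 0 and rel.size:
            rel = rel[rng.random(rel.size) >= config.label_fn_rate]
        # spurious labels
        n_fp = rng.poisson(config.label_fp_rate * mlen)
        if n_fp:
            rel = np.concatenate([rel, rng.integers(0, mlen, size=n_fp)])
            rel = np.sort(rel)
        # sizing noise on inter-label intervals (incl. offset from the start)
        if config.sizing_noise > 0 and rel.size:
            diffs = np.diff(np.concatenate([[0], rel])).astype(np.float64)
            diffs *= 1.0 + rng.normal(0.0, config.sizing_noise, size=diffs.size)
            rel = np.cumsum(diffs)
        rel = np.unique(np.clip(np.round(rel).astype(np.int64), 0, mlen - 1))
        if rng.random() < 0.5:  # molecules are imaged strand-agnostically
            rel = np.sort(mlen - 1 - rel)
        snr = rng.uniform(0.5, 2.9) if mode == 1 else rng.uniform(3.0, 20.0)
        inten = rng.uniform(0.61, 0.95) if mode == 2 else rng.uniform(0.1, 0.59)
        out.append(OpticalMolecule(map_id=f"mol{i:05d}", length=mlen,
                                   labels=rel, label_snr=float(snr),
                                   avg_intensity=float(inten)))
        total += mlen
    return out


# ---------------------------------------------------------------------------
# Mate pairs
# ---------------------------------------------------------------------------

MP_COLUMNS = ["read_id", "mate", "contig", "pos0", "strand", "read_len",
              "mapq", "unique", "library"]


def simulate_mate_pairs(truth: TruthSet, draft: Dict[str, str],
                        config: SimulationConfig) -> pd.DataFrame:
    """Alignment-style mate-pair records in draft coordinates (innie
    convention after library circularisation: forward mate on the left).
    Pairs whose mates cross a fragment boundary in truth are dropped, so
    pairs crossing a planted chimera junction are discordant by
    construction."""
    lifter = CoordinateLifter(truth)
    rng = config.rng(_TAG_MATEPAIRS)
    chroms = sorted(truth.chromosomes)
    lengths = np.array([len(truth.chromosomes[c]) for c in chroms], dtype=np.int64)
    p = lengths / lengths.sum()
    rl = config.mp_read_length
    rows = []
    for lib in config.mp_libraries:
        if lib.insert_sd <= 0:
            raise ValueError(f"library {lib.name}: insert_sd must be > 0")
        for k in range(lib.n_pairs):
            ci = rng.choice(len(chroms), p=p)
            chrom, L = chroms[ci], int(lengths[ci])
            insert = int(round(rng.normal(lib.insert_mean, lib.insert_sd)))
            insert = max(insert, 2 * rl)
            if insert >= L:
                continue
            x = int(rng.integers(0, L - insert + 1))
            m1 = lifter.lift_read(chrom, x, rl, "+")
            m2 = lifter.lift_read(chrom, x + insert - rl, rl, "-")
            if m1 is None or m2 is None:
                continue
            uniq = rng.random() >= config.mp_nonunique_fraction
            rid = f"{lib.name}_p{k:06d}"
            for mate, (ctg, pos, strand) in ((1, m1), (2, m2)):
                rows.append((rid, mate, ctg, pos, strand, rl,
                             60 if uniq else 0, uniq, lib.name))
    return pd.DataFrame(rows, columns=MP_COLUMNS)


# ---------------------------------------------------------------------------
# Long reads with soft-clip signatures
# ---------------------------------------------------------------------------

LONGREAD_COLUMNS = ["read_id", "contig", "start", "end", "clip_left", "clip_right"]


def simulate_long_read_clips(truth: TruthSet, draft: Dict[str, str],
                             config: SimulationConfig) -> pd.DataFrame:
    """Long-read alignment records in draft coordinates.

    Reads are simulated along each draft component's source interval in
    truth; the part of a read falling outside the interval cannot align and
    becomes a soft clip, so every planted chimera accumulates clip
    boundaries at its junction while clean regions keep full spanning
    coverage."""
    if not draft:
        return pd.DataFrame(columns=LONGREAD_COLUMNS)
    rng = config.rng(_TAG_LONGREADS)
    rows = []
    rid = 0
    min_ov = config.longread_min_overlap
    for f in sorted(truth.fragments, key=lambda f: (f.draft_id, f.draft_start)):
        flen = f.length
        n_reads = int(round(config.longread_coverage * flen
                            / config.longread_length_mean))
        for _ in range(n_reads):
            lr = int(rng.normal(config.longread_length_mean,
                                config.longread_length_sd))
            lr = max(lr, config.longread_length_min)
            s = int(rng.integers(f.start - lr + min_ov, f.end - min_ov))
            e = s + lr
            a0, a1 = max(s, f.start), min(e, f.end)
            if a1 - a0 < min_ov:
                continue
            clip_l, clip_r = a0 - s, e - a1
            # lift aligned interval into draft coordinates
            if f.strand == "+":
                d0 = f.draft_start + (a0 - f.start)
                d1 = f.draft_start + (a1 - f.start)
            else:
                d0 = f.draft_start + (f.end - a1)
                d1 = f.draft_start + (f.end - a0)
                clip_l, clip_r = clip_r, clip_l
            # jitter on clipped boundaries (alignment-end uncertainty)
            if clip_l > 0:
                d0 = min(d1 - 1, max(0, d0 + int(round(
                    rng.normal(0, config.clip_jitter_sd)))))
            if clip_r > 0:
                d1 = max(d0 + 1, min(len(draft[f.draft_id]), d1 + int(round(
                    rng.normal(0, config.clip_jitter_sd)))))
            rid += 1
            rows.append((f"lr{rid:06d}", f.draft_id, d0, d1, clip_l, clip_r))
    return pd.DataFrame(rows, columns=LONGREAD_COLUMNS)


# ---------------------------------------------------------------------------
# Hi-C contacts
# ---------------------------------------------------------------------------

CONTACT_COLUMNS = ["seq1", "pos1", "seq2", "pos2", "mapq", "dup"]


def _sample_powerlaw_distance(rng: np.random.Generator, n: int, L: int,
                              alpha: float) -> np.ndarray:
    """Distances d >= 1 with p(d) ~ (1 + d)^(-alpha), truncated at L - 1."""
    u = rng.random(n)
    if abs(alpha - 1.0) < 1e-9:
        d = np.exp(u * np.log(L)) - 1.0
    else:
        top = (1.0 + (L - 1)) ** (1.0 - alpha)
        d = (1.0 + u * (top - 1.0)) ** (1.0 / (1.0 - alpha)) - 1.0
    return np.maximum(1, np.round(d).astype(np.int64))


def simulate_contacts(truth: TruthSet, draft: Dict[str, str],
                      config: SimulationConfig) -> pd.DataFrame:
    """Hi-C contact records against draft coordinates: intra-chromosome
    pairs with power-law distance decay, plus a uniform inter-chromosome
    background carrying ``hic_inter_fraction`` of all pairs."""
    if config.hic_decay_exponent <= 0:
        raise ValueError("hic_decay_exponent must be positive")
    lifter = CoordinateLifter(truth)
    rng = config.rng(_TAG_CONTACTS)
    chroms = sorted(truth.chromosomes)
    lengths = np.array([len(truth.chromosomes[c]) for c in chroms], dtype=np.int64)
    p = lengths / lengths.sum()
    n = config.n_contacts
    n_inter = int(round(n * config.hic_inter_fraction))
    rows_c1, rows_p1, rows_c2, rows_p2 = [], [], [], []
    # intra-chromosome contacts
    n_intra = n - n_inter
    ci = rng.choice(len(chroms), size=n_intra, p=p)
    for k in range(len(chroms)):
        m = int((ci == k).sum())
        if not m:
            continue
        L = int(lengths[k])
        d = _sample_powerlaw_distance(rng, m, L, config.hic_decay_exponent)
        x1 = rng.integers(0, L, size=m)
        sign = rng.choice([-1, 1], size=m)
        x2 = np.clip(x1 + sign * d, 0, L - 1)
        rows_c1.extend([chroms[k]] * m)
        rows_p1.extend(x1.tolist())
        rows_c2.extend([chroms[k]] * m)
        rows_p2.extend(x2.tolist())
    # inter-chromosome background
    if n_inter and len(chroms) > 1:
        for _ in range(n_inter):
            a, b = rng.choice(len(chroms), size=2, replace=False, p=p)
            rows_c1.append(chroms[a])
            rows_p1.append(int(rng.integers(0, lengths[a])))
            rows_c2.append(chroms[b])
            rows_p2.append(int(rng.integers(0, lengths[b])))
    # lift to draft coordinates
    recs = []
    n_total = len(rows_c1)
    low_mask = rng.random(n_total) < config.hic_low_mapq_fraction
    dup_mask = rng.random(n_total) < config.hic_dup_fraction
    low_q = rng.integers(0, 21, size=n_total)
    for idx in range(n_total):
        l1 = lifter.lift_point(rows_c1[idx], int(rows_p1[idx]))
        l2 = lifter.lift_point(rows_c2[idx], int(rows_p2[idx]))
        if l1 is None or l2 is None:  # pragma: no cover - full coverage lift
            continue
        mapq = int(low_q[idx]) if low_mask[idx] else 60
        recs.append((l1[0], l1[1], l2[0], l2[1], mapq, int(dup_mask[idx])))
    return pd.DataFrame(recs, columns=CONTACT_COLUMNS)


# ---------------------------------------------------------------------------
# File output
# ---------------------------------------------------------------------------

def write_fasta(seqs: Dict[str, str], path) -> None:
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    records = [SeqRecord(Seq(s), id=name, description="")
               for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> Dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_chimera_truth(truth: TruthSet, path) -> None:
    """Planted chimeras as BED-like TSV (0-based, half-open)."""
    rows = [(c.draft_id, c.junction, c.junction + 1,
             f"{c.left[0]}:{c.left[1]}-{c.left[2]}({c.left[3]})",
             f"{c.right[0]}:{c.right[1]}-{c.right[2]}({c.right[3]})")
            for c in truth.chimeras]
    pd.DataFrame(rows, columns=["draft_id", "junction0", "junction1",
                                "left_interval", "right_interval"]
                 ).to_csv(path, sep="\t", index=False)
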