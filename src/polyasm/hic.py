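"""Hi-C scaffolding: contact binning and normalization, hierarchical
grouping, subgroup/super-bin ordering and orientation, pseudomolecule
construction and the log2 heatmap.

Proximity-ligation contact frequency decays with linear genomic distance,
so scaffolds from one chromosome share far more contacts than scaffolds
from different chromosomes (clustering signal), adjacent scaffolds share
more than distant ones (ordering signal), and within a scaffold the bins
nearest a true neighbour interact with it most (orientation signal).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd


@dataclass
class HiCParams:
    min_mapq: int = 20  # strict: records must have mapq > min_mapq
    bin_size: int = 50_000
    n_groups: int = 20
    n_subgroups: int = 5
    heatmap_bin: int = 500_000
    pseudomolecule_gap: int = 100

    def __post_init__(self) -> None:
        for f in ("bin_size", "n_groups", "n_subgroups", "heatmap_bin",
                  "pseudomolecule_gap"):
            if getattr(self, f) <= 0:
                raise ValueError(f"{f} must be positive")


@dataclass
class ContactMatrix:
    bin_size: int
    seq_names: List[str]
    bin_seq: np.ndarray  # sequence index per global bin
    bin_start: np.ndarray  # bin start offset within its sequence
    raw: np.ndarray  # symmetric raw counts
    norm: np.ndarray  # symmetric normalized weights
    seq_bin_range: Dict[str, Tuple[int, int]]  # name -> [lo, hi) global bins

    @property
    def n_bins(self) -> int:
        return int(self.bin_seq.size)

    def total_links(self) -> int:
        """Total link count represented by the raw matrix."""
        return int((self.raw.sum() + np.trace(self.raw)) // 2)

    def bins_of(self, seq: str) -> np.ndarray:
        lo, hi = self.seq_bin_range[seq]
        return np.arange(lo, hi)

    def scaffold_similarity(self, seqs: Optional[Sequence[str]] = None
                            ) -> Tuple[np.ndarray, List[str]]:
        """Mean normalized inter-scaffold contact per bin pair."""
        seqs = list(seqs) if seqs is not None else list(self.seq_names)
        k = len(seqs)
        sim = np.zeros((k, k))
        for i in range(k):
            bi = self.bins_of(seqs[i])
            for j in range(i + 1, k):
                bj = self.bins_of(seqs[j])
                block = self.norm[np.ix_(bi, bj)]
                sim[i, j] = sim[j, i] = block.mean() if block.size else 0.0
        return sim, seqs


# ---------------------------------------------------------------------------
# Binning and normalization
# ---------------------------------------------------------------------------

def bin_and_normalize(records: pd.DataFrame, lengths: Dict[str, int],
                      params: Optional[HiCParams] = None) -> ContactMatrix:
    """Aggregate contacts into fixed-size bins and normalize intra- and
    inter-sequence submatrices separately.

    Records with mapq <= min_mapq or flagged as duplicates are discarded.
    Each entry is divided by the product of its bins' total coverage
    (computed within its own intra/inter submatrix) and each submatrix is
    rescaled so its nonzero entries have mean 1.
    """
    params = params or HiCParams()
    if params.bin_size <= 0:
        raise ValueError("bin_size must be positive")
    seq_names = sorted(lengths)
    n_bins_per = {s: max(1, -(-lengths[s] // params.bin_size)) for s in seq_names}
    seq_bin_range: Dict[str, Tuple[int, int]] = {}
    lo = 0
    for s in seq_names:
        seq_bin_range[s] = (lo, lo + n_bins_per[s])
        lo += n_bins_per[s]
    n = lo
    bin_seq = np.empty(n, dtype=np.int64)
    bin_start = np.empty(n, dtype=np.int64)
    for si, s in enumerate(seq_names):
        a, b = seq_bin_range[s]
        bin_seq[a:b] = si
        bin_start[a:b] = np.arange(b - a) * params.bin_size

    df = records[(records["mapq"] > params.min_mapq) & (records["dup"] == 0)]
    df = df[df["seq1"].isin(seq_bin_range) & df["seq2"].isin(seq_bin_range)]
    raw = np.zeros((n, n), dtype=np.float64)
    if not df.empty:
        base = pd.Series({s: seq_bin_range[s][0] for s in seq_names})
        b1 = (df["seq1"].map(base) + df["pos1"] // params.bin_size).to_numpy()
        b2 = (df["seq2"].map(base) + df["pos2"] // params.bin_size).to_numpy()
        np.add.at(raw, (b1, b2), 1.0)
        np.add.at(raw, (b2, b1), 1.0)
        # diagonal entries were double-counted by the symmetric update
        diag = b1 == b2
        if diag.any():
            np.add.at(raw, (b1[diag], b1[diag]), -1.0)

    intra = bin_seq[:, None] == bin_seq[None, :]
    norm = np.zeros_like(raw)
    for mask in (intra, ~intra):
        sub = np.where(mask, raw, 0.0)
        cov = sub.sum(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            denom = cov[:, None] * cov[None, :]
            part = np.where((denom > 0) & mask, sub / np.where(denom > 0, denom, 1.0), 0.0)
        nz = part[mask] > 0
        if nz.any():
            part = part / part[mask][nz].mean()
        norm += part
    return ContactMatrix(bin_size=params.bin_size, seq_names=seq_names,
                         bin_seq=bin_seq, bin_start=bin_start, raw=raw,
                         norm=norm, seq_bin_range=seq_bin_range)


# ---------------------------------------------------------------------------
# Hierarchical grouping (average linkage on contact similarity)
# ---------------------------------------------------------------------------

def _average_linkage(sim: np.ndarray, names: Sequence[str], k: int
                     ) -> List[List[int]]:
    """Agglomerate to k clusters, merging the pair with the highest average
    inter-cluster similarity; equal similarities merge the lexicographically
    smallest pair (clusters keyed by their smallest member name)."""
    clusters: List[List[int]] = [[i] for i in range(len(names))]
    while len(clusters) > k:
        best = None
        for a in range(len(clusters)):
            for b in range(a + 1, len(clusters)):
                s = float(np.mean(sim[np.ix_(clusters[a], clusters[b])]))
                key_ab = tuple(sorted((min(names[i] for i in clusters[a]),
                                       min(names[i] for i in clusters[b]))))
                cand = (-s, key_ab, a, b)
                if best is None or cand < best:
                    best = cand
        _, _, a, b = best
        clusters[a] = sorted(clusters[a] + clusters[b])
        del clusters[b]
    return clusters


def cluster_groups(matrix: ContactMatrix, n_groups: int,
                   seqs: Optional[Sequence[str]] = None) -> Dict[str, int]:
    """Cluster scaffolds into n_groups chromosome groups by average-linkage
    agglomeration on inter-scaffold normalized contact frequency."""
    sim, names = matrix.scaffold_similarity(seqs)
    if n_groups > len(names):
        raise ValueError(f"n_groups={n_groups} exceeds {len(names)} scaffolds")
    clusters = _average_linkage(sim, names, n_groups)
    clusters.sort(key=lambda c: min(names[i] for i in c))
    return {names[i]: gi for gi, c in enumerate(clusters) for i in c}


# ---------------------------------------------------------------------------
# Ordering and orientation
# ---------------------------------------------------------------------------

def _greedy_chain(items: Sequence[str], weight: Dict[Tuple[str, str], float]
                  ) -> List[str]:
    """Path through all items greedily maximizing summed adjacent weight:
    heaviest edges first subject to degree <= 2 and acyclicity, then chains
    merged by their best end-to-end edge.  Deterministic (lexicographic
    tie-breaks)."""
    items = sorted(items)
    if len(items) <= 1:
        return list(items)

    def w(a: str, b: str) -> float:
        return weight.get((a, b), weight.get((b, a), 0.0))

    edges = sorted(((a, b) for i, a in enumerate(items) for b in items[i + 1:]),
                   key=lambda e: (-w(*e), e))
    chains: Dict[str, List[str]] = {it: [it] for it in items}  # keyed by id
    chain_of = {it: it for it in items}
    degree = {it: 0 for it in items}
    for a, b in edges:
        if degree[a] >= 2 or degree[b] >= 2 or chain_of[a] == chain_of[b]:
            continue
        ca, cb = chains[chain_of[a]], chains[chain_of[b]]
        if ca[-1] != a:
            ca.reverse()
        if cb[0] != b:
            cb.reverse()
        merged = ca + cb
        key = chain_of[a]
        dead = chain_of[b]
        chains[key] = merged
        del chains[dead]
        for it in merged:
            chain_of[it] = key
        degree[a] += 1
        degree[b] += 1
    remaining = sorted(chains.values(), key=lambda c: c[0])
    while len(remaining) > 1:
        best = None
        for i in range(len(remaining)):
            for j in range(i + 1, len(remaining)):
                for ci, flip_i in ((remaining[i], False), (remaining[i][::-1], True)):
                    for cj, flip_j in ((remaining[j], False), (remaining[j][::-1], True)):
                        cand = (-w(ci[-1], cj[0]), ci[-1], cj[0], i, j,
                                flip_i, flip_j)
                        if best is None or cand < best:
                            best = cand
        _, _, _, i, j, flip_i, flip_j = best
        ci = remaining[i][::-1] if flip_i else remaining[i]
        cj = remaining[j][::-1] if flip_j else remaining[j]
        merged = ci + cj
        remaining = [c for t, c in enumerate(remaining) if t not in (i, j)]
        remaining.append(merged)
        remaining.sort(key=lambda c: c[0])
    return remaining[0]


def _pair_weights(matrix: ContactMatrix, seqs: Sequence[str]
                  ) -> Dict[Tuple[str, str], float]:
    sim, names = matrix.scaffold_similarity(seqs)
    out = {}
    for i, a in enumerate(names):
        for j in range(i + 1, len(names)):
            out[(a, names[j])] = float(sim[i, j])
    return out


def _orient_by_gradient(matrix: ContactMatrix, order: Sequence[str]
                        ) -> Dict[str, str]:
    """Orient each scaffold by the contact-weighted position gradient toward
    its neighbours: bins nearest a neighbour should interact with it most."""
    orientation: Dict[str, str] = {}
    for idx, s in enumerate(order):
        bins = matrix.bins_of(s)
        if bins.size <= 1:
            orientation[s] = "+"
            continue
        pos = np.arange(bins.size, dtype=float)
        pos -= pos.mean()
        signal = np.zeros(bins.size)
        if idx > 0:
            nb = matrix.bins_of(order[idx - 1])
            signal -= matrix.norm[np.ix_(bins, nb)].sum(axis=1)
        if idx < len(order) - 1:
            nb = matrix.bins_of(order[idx + 1])
            signal += matrix.norm[np.ix_(bins, nb)].sum(axis=1)
        grad = float(np.dot(pos, signal))
        orientation[s] = "+" if grad >= 0 else "-"
    return orientation


def order_and_orient(matrix: ContactMatrix, seqs: Sequence[str],
                     n_subgroups: int = 5) -> List[Tuple[str, str]]:
    """Order and orient one chromosome group's scaffolds.

    (1) subcluster into min(n_subgroups, group size) subgroups; (2) order
    each subgroup by greedy adjacent-contact chaining and orient by the
    position gradient; (3) collapse each ordered subgroup into a super-bin,
    chain super-bins the same way and decide each super-bin's direction by
    the gradient of its scaffolds toward neighbouring super-bins; (4)
    concatenate, canonicalised so the lexicographically smaller terminal
    scaffold comes first.
    """
    seqs = sorted(seqs)
    if len(seqs) == 1:
        return [(seqs[0], "+")]
    k = min(n_subgroups, len(seqs))
    sub_of = cluster_groups(matrix, k, seqs)
    weights = _pair_weights(matrix, seqs)
    subgroups: List[List[str]] = []
    for gi in range(k):
        members = sorted(s for s, g in sub_of.items() if g == gi)
        subgroups.append(_greedy_chain(members, weights))
    # super-bin weights: mean normalized contact per bin pair across groups
    def super_weight(ga: Sequence[str], gb: Sequence[str]) -> float:
        ba = np.concatenate([matrix.bins_of(s) for s in ga])
        bb = np.concatenate([matrix.bins_of(s) for s in gb])
        return float(matrix.norm[np.ix_(ba, bb)].mean())

    tags = [f"sb{i}" for i in range(len(subgroups))]
    sw = {}
    for i in range(len(tags)):
        for j in range(i + 1, len(tags)):
            sw[(tags[i], tags[j])] = super_weight(subgroups[i], subgroups[j])
    super_order = _greedy_chain(tags, sw)
    ordered_groups = [subgroups[int(t[2:])] for t in super_order]
    # decide each super-bin's direction by its scaffolds' gradient toward
    # the neighbouring super-bins
    final_order: List[str] = []
    for gi, grp in enumerate(ordered_groups):
        if len(grp) > 1:
            pos = np.arange(len(grp), dtype=float)
            pos -= pos.mean()
            signal = np.zeros(len(grp))
            for si, s in enumerate(grp):
                bs = matrix.bins_of(s)
                if gi > 0:
                    nb = np.concatenate([matrix.bins_of(x)
                                         for x in ordered_groups[gi - 1]])
                    signal[si] -= matrix.norm[np.ix_(bs, nb)].mean()
                if gi < len(ordered_groups) - 1:
                    nb = np.concatenate([matrix.bins_of(x)
                                         for x in ordered_groups[gi + 1]])
                    signal[si] += matrix.norm[np.ix_(bs, nb)].mean()
            if float(np.dot(pos, signal)) < 0:
                grp = grp[::-1]
        final_order.extend(grp)
    if final_order[-1] < final_order[0]:
        final_order.reverse()
    orientation = _orient_by_gradient(matrix, final_order)
    return [(s, orientation[s]) for s in final_order]


@dataclass
class GroupingResult:
    group_of: Dict[str, int]
    subgroup_of: Dict[str, int]
    order: Dict[int, List[str]]
    orientation: Dict[str, str]


def cluster_order_orient(matrix: ContactMatrix, params: Optional[HiCParams] = None,
                         seqs: Optional[Sequence[str]] = None) -> GroupingResult:
    """Full hierarchical pass: groups, then per-group order/orientation."""
    params = params or HiCParams()
    group_of = cluster_groups(matrix, params.n_groups, seqs)
    order: Dict[int, List[str]] = {}
    orientation: Dict[str, str] = {}
    subgroup_of: Dict[str, int] = {}
    for gi in sorted(set(group_of.values())):
        members = sorted(s for s, g in group_of.items() if g == gi)
        k = min(params.n_subgroups, len(members))
        for s, sg in cluster_groups(matrix, k, members).items():
            subgroup_of[s] = sg
        oo = order_and_orient(matrix, members, params.n_subgroups)
        order[gi] = [s for s, _ in oo]
        orientation.update(dict(oo))
    return GroupingResult(group_of=group_of, subgroup_of=subgroup_of,
                          order=order, orientation=orientation)


# ---------------------------------------------------------------------------
# Pseudomolecules
# ---------------------------------------------------------------------------

def build_pseudomolecules(assembly: Dict[str, str], grouping: GroupingResult,
                          params: Optional[HiCParams] = None
                          ) -> Tuple[Dict[str, str], pd.DataFrame, List[str]]:
    """Concatenate each group's ordered, oriented scaffolds with N gaps.

    Returns (chromosome sequences, placement table with 0-based half-open
    chromosome coordinates, unplaced scaffold ids).
    """
    from .optical import reverse_complement

    params = params or HiCParams()
    placed: set = set()
    chroms: Dict[str, str] = {}
    rows = []
    for gi in sorted(grouping.order):
        name = f"chr{gi + 1:02d}"
        parts = []
        pos = 0
        for t, scaf in enumerate(grouping.order[gi]):
            if scaf in placed:
                raise ValueError(f"scaffold {scaf} placed twice")
            placed.add(scaf)
            seq = assembly[scaf]
            orient = grouping.orientation[scaf]
            parts.append(seq if orient == "+" else reverse_complement(seq))
            rows.append((name, pos, pos + len(seq), scaf, orient, len(seq)))
            pos += len(seq)
            if t < len(grouping.order[gi]) - 1:
                parts.append("N" * params.pseudomolecule_gap)
                pos += params.pseudomolecule_gap
        chroms[name] = "".join(parts)
    placements = pd.DataFrame(rows, columns=[
        "chrom", "start", "end", "component", "orientation", "comp_length"])
    unplaced = sorted(set(assembly) - placed)
    return chroms, placements, unplaced


def pseudomolecules_to_agp(placements: pd.DataFrame, gap: int = 100
                           ) -> pd.DataFrame:
    """AGP v2.1 (1-based inclusive) for Hi-C pseudomolecules."""
    rows = []
    for chrom, grp in placements.groupby("chrom", sort=True):
        grp = grp.sort_values("start")
        part = 0
        prev_end = None
        for _, r in grp.iterrows():
            if prev_end is not None and r["start"] > prev_end:
                part += 1
                rows.append((chrom, prev_end + 1, r["start"], part, "N",
                             r["start"] - prev_end, "scaffold", "yes",
                             "proximity_ligation"))
            part += 1
            rows.append((chrom, r["start"] + 1, r["end"], part, "W",
                         r["component"], 1, r["comp_length"], r["orientation"]))
            prev_end = r["end"]
    return pd.DataFrame(rows, columns=[
        "object", "object_beg", "object_end", "part_number", "component_type",
        "component_id", "component_beg", "component_end", "orientation"])


def agp_to_sequences(agp: pd.DataFrame, components: Dict[str, str]
                     ) -> Dict[str, str]:
    """Reconstruct object sequences from AGP rows (round-trip check)."""
    from .optical import reverse_complement

    out: Dict[str, str] = {}
    for obj, grp in agp.groupby("object", sort=True):
        parts = []
        for _, r in grp.sort_values("part_number").iterrows():
            if r["component_type"] == "N":
                parts.append("N" * int(r["component_id"]))
            else:
                seq = components[r["component_id"]]
                seq = seq[int(r["component_beg"]) - 1:int(r["component_end"])]
                parts.append(seq if r["orientation"] == "+"
                             else reverse_complement(seq))
        out[obj] = "".join(parts)
    return out


# ---------------------------------------------------------------------------
# Heatmap
# ---------------------------------------------------------------------------

def heatmap_matrix(records: pd.DataFrame, placements: pd.DataFrame,
                   chrom_lengths: Dict[str, int],
                   params: Optional[HiCParams] = None
                   ) -> Tuple[np.ndarray, pd.DataFrame]:
    """Genome-wide heatmap: valid links counted in fixed nonoverlapping
    windows along the pseudomolecules; each entry is log2(count) for
    count >= 1 and NaN (masked) for empty bins, matching a 0-10 display
    scale."""
    params = params or HiCParams()
    comp = placements.set_index("component")
    chrom_names = sorted(chrom_lengths)
    n_bins_per = {c: max(1, -(-chrom_lengths[c] // params.heatmap_bin))
                  for c in chrom_names}
    base = {}
    lo = 0
    bin_rows = []
    for c in chrom_names:
        base[c] = lo
        for b in range(n_bins_per[c]):
            bin_rows.append((c, b * params.heatmap_bin))
        lo += n_bins_per[c]
    n = lo
    counts = np.zeros((n, n), dtype=np.int64)

    df = records[(records["mapq"] > params.min_mapq) & (records["dup"] == 0)]
    df = df[df["seq1"].isin(comp.index) & df["seq2"].isin(comp.index)]
    if not df.empty:
        for side in ("1", "2"):
            seqs = df[f"seq{side}"]
            starts = seqs.map(comp["start"]).to_numpy()
            clens = seqs.map(comp["comp_length"]).to_numpy()
            plus = (seqs.map(comp["orientation"]) == "+").to_numpy()
            pos = df[f"pos{side}"].to_numpy()
            gpos = np.where(plus, starts + pos, starts + clens - 1 - pos)
            cb = seqs.map(comp["chrom"]).map(base).to_numpy()
            df = df.assign(**{f"b{side}": cb + gpos // params.heatmap_bin})
        b1 = df["b1"].to_numpy()
        b2 = df["b2"].to_numpy()
        np.add.at(counts, (b1, b2), 1)
        off = b1 != b2
        np.add.at(counts, (b2[off], b1[off]), 1)
    with np.errstate(divide="ignore"):
        mat = np.where(counts >= 1, np.log2(np.maximum(counts, 1)), np.nan)
    bins = pd.DataFrame(bin_rows, columns=["chrom", "start"])
    return mat, bins
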