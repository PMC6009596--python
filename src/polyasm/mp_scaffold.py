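"""Mate-pair scaffolding: unique-link collection, insert-size filtering,
conservative contig joining and gap estimation.

Two contigs are joined when at least ``min_links`` reasonable links from a
single library (implied insert within insert mean +- 5 SD) support the same
pair of contig ends; any contig end with competing supported partners
contributes no join, so scaffolds are maximal unambiguous paths.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .synthetic import MPLibrarySpec


@dataclass
class MatePairLink:
    contig_a: str
    contig_b: str
    end_a: str  # 'head' | 'tail' — the end of contig_a the partner lies beyond
    end_b: str
    dist_a: int  # distance from the mate to the joined end of its contig
    dist_b: int
    library: str

    def __post_init__(self) -> None:
        if self.contig_a == self.contig_b:
            raise ValueError("a link must connect two different contigs")

    @property
    def implied_insert(self) -> int:
        # gap is unobservable before joining; d_a + d_b is the zero-gap insert
        return self.dist_a + self.dist_b

    def canonical(self) -> "MatePairLink":
        if (self.contig_b, self.end_b) < (self.contig_a, self.end_a):
            return MatePairLink(self.contig_b, self.contig_a, self.end_b,
                                self.end_a, self.dist_b, self.dist_a,
                                self.library)
        return self


@dataclass
class ScaffoldPath:
    scaffold_id: str
    items: List[Tuple[str, str, int]]  # (contig_id, orientation, gap_after)

    @property
    def contigs(self) -> List[str]:
        return [c for c, _, _ in self.items]


# ---------------------------------------------------------------------------
# Link collection
# ---------------------------------------------------------------------------

def collect_links(records: pd.DataFrame, contig_lengths: Dict[str, int]
                  ) -> Tuple[List[MatePairLink], int]:
    """Pair alignment records by read id and keep pairs with both mates
    unique and on different contigs.

    The joined end and mate-to-end distance follow the innie convention:
    a forward mate's partner lies beyond the contig tail, a reverse mate's
    beyond the head.  Records referencing unknown contigs are rejected;
    returns (links, n_rejected).
    """
    unknown = ~records["contig"].isin(contig_lengths)
    n_rejected = int(unknown.sum())
    if n_rejected:
        # e.g. alignments to sequences that were since broken or dropped
        records = records[~unknown]
    m1 = records[records["mate"] == 1]
    m2 = records[records["mate"] == 2]
    df = m1.merge(m2, on="read_id", suffixes=("_1", "_2"), sort=True)
    df = df[df["unique_1"] & df["unique_2"]
            & (df["contig_1"] != df["contig_2"])]
    if df.empty:
        return [], n_rejected
    lens1 = df["contig_1"].map(contig_lengths).to_numpy()
    lens2 = df["contig_2"].map(contig_lengths).to_numpy()
    fwd1 = (df["strand_1"] == "+").to_numpy()
    fwd2 = (df["strand_2"] == "+").to_numpy()
    end1 = np.where(fwd1, "tail", "head")
    end2 = np.where(fwd2, "tail", "head")
    pos1 = df["pos0_1"].to_numpy()
    pos2 = df["pos0_2"].to_numpy()
    rl1 = df["read_len_1"].to_numpy()
    rl2 = df["read_len_2"].to_numpy()
    d1 = np.where(fwd1, lens1 - pos1, pos1 + rl1)
    d2 = np.where(fwd2, lens2 - pos2, pos2 + rl2)
    links = [MatePairLink(ca, cb, ea, eb, int(da), int(db), lib).canonical()
             for ca, cb, ea, eb, da, db, lib in zip(
                 df["contig_1"], df["contig_2"], end1, end2, d1, d2,
                 df["library_1"])]
    return links, n_rejected


# ---------------------------------------------------------------------------
# Insert filtering
# ---------------------------------------------------------------------------

def filter_links_by_insert(links: Iterable[MatePairLink],
                           libraries: Dict[str, MPLibrarySpec],
                           k_sd: float = 5.0) -> List[MatePairLink]:
    """A link is reasonable iff its implied insert lies within
    [mean - k_sd*sd, mean + k_sd*sd] of its library (boundaries inclusive)."""
    out = []
    for link in links:
        lib = libraries.get(link.library)
        if lib is None:
            raise KeyError(f"unknown library {link.library!r}")
        lo = lib.insert_mean - k_sd * lib.insert_sd
        hi = lib.insert_mean + k_sd * lib.insert_sd
        if lo <= link.implied_insert <= hi:
            out.append(link)
    return out


# ---------------------------------------------------------------------------
# Joining
# ---------------------------------------------------------------------------

End = Tuple[str, str]  # (contig, 'head'|'tail')


def _supported_edges(links: Sequence[MatePairLink], min_links: int
                     ) -> Dict[Tuple[End, End], List[MatePairLink]]:
    """End pairs where some single library contributes >= min_links links."""
    grouped: Dict[Tuple[End, End], Dict[str, List[MatePairLink]]] = {}
    for link in links:
        lk = link.canonical()
        key = ((lk.contig_a, lk.end_a), (lk.contig_b, lk.end_b))
        grouped.setdefault(key, {}).setdefault(lk.library, []).append(lk)
    edges: Dict[Tuple[End, End], List[MatePairLink]] = {}
    for key, by_lib in grouped.items():
        if any(len(ls) >= min_links for ls in by_lib.values()):
            edges[key] = [l for ls in by_lib.values() for l in ls]
    return edges


def join_contigs(contig_lengths: Dict[str, int],
                 links: Sequence[MatePairLink],
                 libraries: Dict[str, MPLibrarySpec],
                 min_links: int = 3, min_gap: int = 10
                 ) -> List[ScaffoldPath]:
    """Join contigs along unambiguous supported end-to-end edges.

    Any end participating in >= 2 supported edges is ambiguous and
    contributes no join.  Output is the set of maximal simple paths
    (singletons included), deterministically ordered, with gaps estimated
    from the supporting links.
    """
    edges = _supported_edges(links, min_links)
    degree: Dict[End, int] = {}
    for (ea, eb) in edges:
        degree[ea] = degree.get(ea, 0) + 1
        degree[eb] = degree.get(eb, 0) + 1
    kept = {key: ls for key, ls in edges.items()
            if degree[key[0]] == 1 and degree[key[1]] == 1}
    partner: Dict[End, Tuple[End, List[MatePairLink]]] = {}
    for (ea, eb), ls in kept.items():
        partner[ea] = (eb, ls)
        partner[eb] = (ea, ls)

    def other_end(e: End) -> End:
        return (e[0], "head" if e[1] == "tail" else "tail")

    visited: set = set()
    paths: List[ScaffoldPath] = []
    sid = 0
    for contig in sorted(contig_lengths):
        if contig in visited:
            continue
        # walk left from this contig to a terminal
        cur: End = (contig, "head")
        seen = {contig}
        while cur in partner:
            nxt = partner[cur][0]
            if nxt[0] in seen:
                break  # cycle guard
            seen.add(nxt[0])
            cur = other_end(nxt)
        # cur is the outward-facing end of the terminal contig
        start = cur[0]
        orient0 = "+" if cur[1] == "head" else "-"
        items: List[Tuple[str, str, int]] = []
        node, orient = start, orient0
        while True:
            visited.add(node)
            exit_end: End = (node, "tail" if orient == "+" else "head")
            if exit_end in partner and partner[exit_end][0][0] not in visited:
                nxt_end, ls = partner[exit_end]
                gap = estimate_gap(ls, libraries, min_gap)[0]
                items.append((node, orient, gap))
                node = nxt_end[0]
                orient = "+" if nxt_end[1] == "head" else "-"
            else:
                items.append((node, orient, 0))
                break
        # deterministic canonical direction: smaller terminal contig first
        if items[-1][0] < items[0][0]:
            flipped = [(c, "+" if o == "-" else "-", 0) for c, o, _ in items[::-1]]
            gaps = [g for _, _, g in items[::-1]][1:] + [0]
            items = [(c, o, g) for (c, o, _), g in zip(flipped, gaps)]
        sid += 1
        paths.append(ScaffoldPath(scaffold_id=f"scaffold{sid:04d}", items=items))
    return paths


# ---------------------------------------------------------------------------
# Gap estimation
# ---------------------------------------------------------------------------

def estimate_gap(links: Sequence[MatePairLink],
                 libraries: Dict[str, MPLibrarySpec],
                 min_gap: int = 10) -> Tuple[int, bool]:
    """gap = round(mean over links of (insert_mean - d_a - d_b)); estimates
    below ``min_gap`` are clamped and flagged.  Returns (gap, clamped)."""
    if not links:
        raise ValueError("gap estimation needs at least one link")
    ests = [libraries[l.library].insert_mean - l.dist_a - l.dist_b
            for l in links]
    gap = int(round(float(np.mean(ests))))
    if gap < min_gap:
        return min_gap, True
    return gap, False


# ---------------------------------------------------------------------------
# Output
# ---------------------------------------------------------------------------

def scaffold_sequences(paths: Sequence[ScaffoldPath],
                       contigs: Dict[str, str]) -> Dict[str, str]:
    """Render scaffold FASTA sequences with N-run gaps."""
    from .optical import reverse_complement

    out: Dict[str, str] = {}
    for p in paths:
        parts = []
        for i, (cid, orient, gap) in enumerate(p.items):
            seq = contigs[cid]
            parts.append(seq if orient == "+" else reverse_complement(seq))
            if i < len(p.items) - 1:
                parts.append("N" * gap)
        out[p.scaffold_id] = "".join(parts)
    return out


def scaffolds_to_agp(paths: Sequence[ScaffoldPath],
                     contig_lengths: Dict[str, int]) -> pd.DataFrame:
    """AGP v2.1 rows (1-based inclusive) for mate-pair scaffolds."""
    rows = []
    for p in paths:
        pos = 0
        part = 0
        for i, (cid, orient, gap) in enumerate(p.items):
            clen = contig_lengths[cid]
            part += 1
            rows.append((p.scaffold_id, pos + 1, pos + clen, part, "W",
                         cid, 1, clen, orient))
            pos += clen
            if i < len(p.items) - 1 and gap > 0:
                part += 1
                rows.append((p.scaffold_id, pos + 1, pos + gap, part, "N",
                             gap, "scaffold", "yes", "paired-ends"))
                pos += gap
    return pd.DataFrame(rows, columns=[
        "object", "object_beg", "object_end", "part_number", "component_type",
        "component_id", "component_beg", "component_end", "orientation"])
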