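"""Subgenome partitioning by diagnostic k-mer voting.

In an allotetraploid, each assembled scaffold descends from one of the two
diploid ancestors.  Canonical k-mers present in exactly one ancestor are
diagnostic for that ancestor; counting how many of a scaffold's k-mers fall
in each diagnostic set gives two vote totals, and a scaffold is labelled A
or B when its winning side clears a vote floor and a margin ratio.  A
per-window vote track is retained so within-scaffold label switches (a
chimera signature) stay visible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

_CODE = np.full(256, 4, dtype=np.int64)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i
    _CODE[ord(chr(_b).lower())] = _i


@dataclass
class AncestorIndex:
    k: int
    diagnostic_a: np.ndarray  # sorted canonical k-mer codes unique to A
    diagnostic_b: np.ndarray


@dataclass
class SubgenomeAssignment:
    sequence_id: str
    label: str  # 'A' | 'B' | 'unassigned' | 'ambiguous'
    votes_a: int
    votes_b: int
    margin: float
    window_votes: pd.DataFrame = field(repr=False, default=None)


def _canonical_kmers(seq: str, k: int, chunk: int = 200_000
                     ) -> Tuple[np.ndarray, np.ndarray]:
    """Canonical (strand-collapsed) k-mer codes and their start positions;
    windows touching an N are excluded.  Vectorised: 2-bit codes dotted
    with base-4 weights."""
    codes = _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    n = codes.size - k + 1
    empty = np.empty(0, dtype=np.int64)
    if n <= 0:
        return empty, empty
    fw_w = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
    rc_w = 4 ** np.arange(k, dtype=np.int64)
    out, pos = [], []
    for lo in range(0, n, chunk):
        hi = min(lo + chunk, n)
        win = np.lib.stride_tricks.sliding_window_view(
            codes[lo:hi + k - 1], k)
        valid = ~(win == 4).any(axis=1)
        if not valid.any():
            continue
        w = win[valid]
        fwd = w @ fw_w
        rev = (3 - w) @ rc_w
        out.append(np.minimum(fwd, rev))
        pos.append(lo + np.flatnonzero(valid))
    if not out:
        return empty, empty
    return np.concatenate(out), np.concatenate(pos)


def build_ancestor_index(ancestor_a: Dict[str, str], ancestor_b: Dict[str, str],
                         k: int = 21) -> AncestorIndex:
    """Diagnostic canonical k-mer sets: k-mers of one ancestor absent from
    the other.  k must be odd (canonicalization) and >= 11."""
    if k < 11 or k % 2 == 0:
        raise ValueError("k must be odd and >= 11")
    if not ancestor_a or not ancestor_b:
        raise ValueError("both ancestor sequence sets must be nonempty")

    def all_kmers(seqs: Dict[str, str]) -> np.ndarray:
        parts = [_canonical_kmers(s, k)[0] for _, s in sorted(seqs.items())]
        parts = [p for p in parts if p.size]
        if not parts:
            return np.empty(0, dtype=np.int64)
        return np.unique(np.concatenate(parts))

    ka = all_kmers(ancestor_a)
    kb = all_kmers(ancestor_b)
    return AncestorIndex(k=k,
                         diagnostic_a=np.setdiff1d(ka, kb, assume_unique=True),
                         diagnostic_b=np.setdiff1d(kb, ka, assume_unique=True))


def _count_in(sorted_set: np.ndarray, kmers: np.ndarray) -> np.ndarray:
    """Boolean membership of kmers in a sorted unique array."""
    if sorted_set.size == 0 or kmers.size == 0:
        return np.zeros(kmers.size, dtype=bool)
    idx = np.searchsorted(sorted_set, kmers)
    idx[idx == sorted_set.size] = sorted_set.size - 1
    return sorted_set[idx] == kmers


def assign_scaffolds(sequences: Dict[str, str], index: AncestorIndex,
                     min_votes: int = 10, min_margin: float = 2.0,
                     window: int = 10_000) -> List[SubgenomeAssignment]:
    """Vote each scaffold's canonical k-mers against the diagnostic sets.

    Label A iff votes_a >= min_votes and votes_a >= min_margin * votes_b
    (symmetric for B); both sides >= min_votes with margin unmet ->
    ambiguous; otherwise unassigned.
    """
    out: List[SubgenomeAssignment] = []
    k = index.k
    for name in sorted(sequences):
        seq = sequences[name]
        kmers, kpos = _canonical_kmers(seq, k)
        in_a = _count_in(index.diagnostic_a, kmers)
        in_b = _count_in(index.diagnostic_b, kmers)
        va, vb = int(in_a.sum()), int(in_b.sum())
        if va >= min_votes and va >= min_margin * max(vb, 0) and va > vb:
            label = "A"
        elif vb >= min_votes and vb >= min_margin * max(va, 0) and vb > va:
            label = "B"
        elif va >= min_votes and vb >= min_votes:
            label = "ambiguous"
        else:
            label = "unassigned"
        margin = (max(va, vb) / min(va, vb)) if min(va, vb) > 0 else float("inf")
        # per-window vote track for chimera diagnostics
        n_kmers = kmers.size
        if n_kmers:
            wins = kpos // window
            wv = pd.DataFrame({
                "window_start": np.arange(wins.max() + 1) * window,
                "votes_a": np.bincount(wins, weights=in_a).astype(int),
                "votes_b": np.bincount(wins, weights=in_b).astype(int)})
        else:
            wv = pd.DataFrame(columns=["window_start", "votes_a", "votes_b"])
        out.append(SubgenomeAssignment(sequence_id=name, label=label,
                                       votes_a=va, votes_b=vb,
                                       margin=float(margin), window_votes=wv))
    return out


def partition_table(assignments: Iterable[SubgenomeAssignment]) -> pd.DataFrame:
    return pd.DataFrame(
        [(a.sequence_id, a.label, a.votes_a, a.votes_b,
          a.margin if np.isfinite(a.margin) else np.inf)
         for a in assignments],
        columns=["sequence", "label", "votes_a", "votes_b", "margin"])
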