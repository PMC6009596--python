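"""Optical (nick) map primitives: in-silico digestion, molecule filtering,
restriction-map alignment and junction support classification.

A nick map is an ordered list of label positions along a molecule or a
sequence, produced either by a nicking endonuclease (e.g. Nt.BspQI,
recognition site GCTCTTC) acting on single DNA molecules, or by in-silico
digestion of an assembled sequence.  Alignment of two maps is a dynamic
programme over label intervals: matched intervals are penalised by their
squared sizing residual relative to a tolerance, and skipped labels on
either side carry fixed penalties.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

# Nt.BspQI recognition sequence, the single-enzyme channel used throughout.
DEFAULT_MOTIF = "GCTCTTC"

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class NickMap:
    """Ordered label positions (0-based bp) on a molecule or sequence."""

    map_id: str
    length: int
    labels: np.ndarray  # strictly increasing int positions

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.length <= 0:
            raise ValueError(f"map {self.map_id}: non-positive length")
        if self.labels.size:
            if np.any(np.diff(self.labels) <= 0):
                raise ValueError(f"map {self.map_id}: labels not strictly increasing")
            if self.labels[0] < 0 or self.labels[-1] >= self.length:
                raise ValueError(f"map {self.map_id}: label outside [0, length)")

    @property
    def n_labels(self) -> int:
        return int(self.labels.size)


@dataclass
class OpticalMolecule(NickMap):
    """A single imaged molecule: a nick map plus per-molecule quality scores."""

    label_snr: float = 0.0
    avg_intensity: float = 0.0

    def __post_init__(self) -> None:
        super().__post_init__()
        if self.label_snr < 0 or self.avg_intensity < 0:
            raise ValueError("molecule quality attributes must be >= 0")


@dataclass
class MoleculeFilter:
    """Retention thresholds for raw molecules.

    Defaults follow standard single-enzyme optical-map QC: molecules longer
    than 150 kb, at least 8 labels, label SNR >= 3.0 and average molecule
    intensity < 0.6.
    """

    min_length: int = 150_000
    min_labels: int = 8
    min_snr: float = 3.0
    max_intensity: float = 0.6

    def __post_init__(self) -> None:
        if min(self.min_length, self.min_labels, self.min_snr, self.max_intensity) < 0:
            raise ValueError("filter thresholds must be >= 0")

    def retains(self, mol: OpticalMolecule) -> bool:
        return (
            mol.length > self.min_length
            and mol.n_labels >= self.min_labels
            and mol.label_snr >= self.min_snr
            and mol.avg_intensity < self.max_intensity
        )


@dataclass
class AlignParams:
    """Scoring for restriction-map alignment.

    match_reward is earned per matched label pair; sizing residuals are
    penalised as (residual / tol)^2 with tol = max(tol_bp, tol_rel * ref
    interval); missing (ref-only) and extra (query-only) labels inside the
    aligned span carry fixed penalties, unmatched query labels at the ends a
    smaller one.  max_skip bounds how many consecutive labels a transition
    may skip on either map.
    """

    match_reward: float = 3.0
    miss_penalty: float = 3.0
    extra_penalty: float = 3.0
    end_penalty: float = 0.5
    tol_bp: float = 500.0
    tol_rel: float = 0.10
    max_skip: int = 4
    min_score: float = 6.0

    def tolerance(self, ref_interval: float) -> float:
        return max(self.tol_bp, self.tol_rel * ref_interval)


@dataclass
class MapAlignment:
    query_id: str
    ref_id: str
    orientation: str  # '+' or '-'
    pairs: List[Tuple[int, int]]  # (query label index, ref label index), query order
    residuals: List[float]  # per adjacent matched interval, bp (query - ref)
    missing_label_count: int
    extra_label_count: int
    score: float
    fully_aligned: bool
    ref_start: int  # smallest matched ref label position
    ref_end: int  # largest matched ref label position
    query_start: int
    query_end: int

    @property
    def n_matched(self) -> int:
        return len(self.pairs)


@dataclass
class SupportRecord:
    """Classification of one molecule alignment against a junction window."""

    molecule_id: str
    fully_aligned_in_window: bool
    spans_junction: bool

    @property
    def category(self) -> str:
        if self.fully_aligned_in_window and self.spans_junction:
            return "fully_aligned_in_window"
        if self.spans_junction:
            return "spans_junction"
        return "other"


# ---------------------------------------------------------------------------
# In-silico digestion
# ---------------------------------------------------------------------------

def digest_sequence(sequence: str, motif: str = DEFAULT_MOTIF,
                    map_id: str = "map") -> NickMap:
    """Digest a sequence with a nicking motif, one label per occurrence on
    either strand; label position = occurrence start in forward coordinates.

    Motif matches that would overlap an N never fire (exact matching only).
    """
    if len(motif) < 4 or any(c not in "ACGT" for c in motif.upper()):
        raise ValueError("motif must be >= 4 bp over {A,C,G,T}")
    seq = sequence.upper()
    bad = set(seq) - set("ACGTN")
    if bad:
        raise ValueError(f"sequence contains invalid characters: {sorted(bad)}")
    motif = motif.upper()
    positions = set()
    for pat in {motif, reverse_complement(motif)}:
        start = seq.find(pat)
        while start != -1:
            positions.add(start)
            start = seq.find(pat, start + 1)
    labels = np.array(sorted(positions), dtype=np.int64)
    return NickMap(map_id=map_id, length=len(seq), labels=labels)


# ---------------------------------------------------------------------------
# Molecule filtering
# ---------------------------------------------------------------------------

def filter_molecules(molecules: Iterable[OpticalMolecule],
                     flt: Optional[MoleculeFilter] = None) -> List[OpticalMolecule]:
    """Retain molecules passing all thresholds; input order preserved."""
    flt = flt or MoleculeFilter()
    return [m for m in molecules if flt.retains(m)]


# ---------------------------------------------------------------------------
# Dynamic-programming map alignment
# ---------------------------------------------------------------------------

def _dp_kernel_py(q, r, max_skip, match_reward, miss_pen, extra_pen,
                  end_pen, tol_bp, tol_rel):
    """Fill the label-matching DP.  S[i, j] = best score of an alignment whose
    last matched pair is (query i, ref j), including the end penalty for
    unmatched leading query labels.  Back pointers record (a, b) skips."""
    m = q.shape[0]
    n = r.shape[0]
    S = np.full((m, n), -1e18)
    back_a = np.zeros((m, n), dtype=np.int16)
    back_b = np.zeros((m, n), dtype=np.int16)
    for i in range(m):
        for j in range(n):
            best = match_reward - end_pen * i  # start a fresh alignment here
            ba = 0
            bb = 0
            amax = i if i < max_skip else max_skip
            bmax = j if j < max_skip else max_skip
            for a in range(1, amax + 1):
                dq = q[i] - q[i - a]
                for b in range(1, bmax + 1):
                    prev = S[i - a, j - b]
                    if prev <= -1e17:
                        continue
                    dr = r[j] - r[j - b]
                    tol = tol_rel * dr
                    if tol < tol_bp:
                        tol = tol_bp
                    resid = (dq - dr) / tol
                    cand = (prev + match_reward - resid * resid
                            - extra_pen * (a - 1) - miss_pen * (b - 1))
                    if cand > best:
                        best = cand
                        ba = a
                        bb = b
            S[i, j] = best
            back_a[i, j] = ba
            back_b[i, j] = bb
    return S, back_a, back_b


try:  # optional JIT; the pure-Python kernel is the reference either way
    from numba import njit as _njit

    _dp_kernel = _njit(cache=False)(_dp_kernel_py)
except Exception:  # pragma: no cover - numba present in normal installs
    _dp_kernel = _dp_kernel_py


def _align_one_orientation(qpos: np.ndarray, rpos: np.ndarray,
                           params: AlignParams):
    """Run the DP for one query orientation.  Returns (score, pairs) with
    pairs as (query index in qpos order, ref index), or None."""
    m, n = qpos.size, rpos.size
    if m < 2 or n < 1:
        return None
    S, back_a, back_b = _dp_kernel(
        qpos.astype(np.float64), rpos.astype(np.float64),
        params.max_skip, params.match_reward, params.miss_penalty,
        params.extra_penalty, params.end_penalty, params.tol_bp, params.tol_rel)
    # total score adds the trailing end penalty
    total = S - params.end_penalty * (m - 1 - np.arange(m))[:, None]
    best_flat = np.argmax(total)
    bi, bj = divmod(int(best_flat), n)
    best_score = float(total[bi, bj])
    # prefer leftmost ref start on ties: scan column-major ascending j
    for j in range(n):
        col = total[:, j]
        i = int(np.argmax(col))
        if col[i] >= best_score - 1e-12:
            bi, bj, best_score = i, j, float(col[i])
            break
    pairs = []
    i, j = bi, bj
    while True:
        pairs.append((i, j))
        a, b = int(back_a[i, j]), int(back_b[i, j])
        if a == 0:
            break
        i, j = i - a, j - b
    pairs.reverse()
    return best_score, pairs


def align_maps(query: NickMap, ref: NickMap,
               params: Optional[AlignParams] = None) -> Optional[MapAlignment]:
    """Best-scoring alignment of ``query`` against ``ref`` over both
    orientations, or None if nothing reaches the score floor.

    Ties prefer '+' orientation, then the leftmost ref start.
    """
    params = params or AlignParams()
    if query.n_labels < 2:
        raise ValueError("query must have >= 2 labels")
    qpos = query.labels.astype(np.float64)
    rpos = ref.labels.astype(np.float64)
    candidates = []
    res_plus = _align_one_orientation(qpos, rpos, params)
    if res_plus is not None:
        candidates.append(("+", res_plus))
    qrev = (query.length - query.labels[::-1]).astype(np.float64)
    res_minus = _align_one_orientation(qrev, rpos, params)
    if res_minus is not None:
        candidates.append(("-", res_minus))
    best = None
    for orient, (score, pairs) in candidates:
        if score < params.min_score:
            continue
        if best is None or score > best[1] + 1e-12:
            best = (orient, score, pairs)
    if best is None:
        return None
    orient, score, pairs = best
    m = query.n_labels
    if orient == "-":
        # map reversed-query indices back to original label indices
        pairs_orig = [(m - 1 - i, j) for (i, j) in pairs]
        qpos_used = qrev
    else:
        pairs_orig = list(pairs)
        qpos_used = qpos
    # bookkeeping computed on DP-order pairs
    missing = sum(pairs[t][1] - pairs[t - 1][1] - 1 for t in range(1, len(pairs)))
    extra = sum(pairs[t][0] - pairs[t - 1][0] - 1 for t in range(1, len(pairs)))
    residuals = []
    for t in range(1, len(pairs)):
        dq = qpos_used[pairs[t][0]] - qpos_used[pairs[t - 1][0]]
        dr = rpos[pairs[t][1]] - rpos[pairs[t - 1][1]]
        residuals.append(float(dq - dr))
    left_unmatched = pairs[0][0]
    right_unmatched = m - 1 - pairs[-1][0]
    fully = extra == 0 and left_unmatched <= 1 and right_unmatched <= 1
    ref_positions = [int(ref.labels[j]) for (_, j) in pairs]
    q_positions = [int(query.labels[i]) for (i, _) in pairs_orig]
    return MapAlignment(
        query_id=query.map_id, ref_id=ref.map_id, orientation=orient,
        pairs=sorted(pairs_orig), residuals=residuals,
        missing_label_count=int(missing), extra_label_count=int(extra),
        score=float(score), fully_aligned=bool(fully),
        ref_start=min(ref_positions), ref_end=max(ref_positions),
        query_start=min(q_positions), query_end=max(q_positions))


def align_to_best_ref(query: NickMap, refs: Sequence[NickMap],
                      params: Optional[AlignParams] = None) -> Optional[MapAlignment]:
    """Best alignment of ``query`` over a panel of reference maps."""
    best = None
    for ref in refs:
        aln = align_maps(query, ref, params)
        if aln is None:
            continue
        if best is None or aln.score > best.score + 1e-12:
            best = aln
    return best


# ---------------------------------------------------------------------------
# Junction support classification
# ---------------------------------------------------------------------------

def classify_flank_support(alignments: Iterable[MapAlignment],
                           junction: Tuple[str, int],
                           flank: int = 50_000) -> List[SupportRecord]:
    """Classify molecule alignments against the window around a junction
    on a reference map.

    A molecule participates if its aligned ref span overlaps
    [junction - flank, junction + flank]; it spans the junction if it has
    matched labels strictly on both sides of the junction coordinate.
    """
    if flank <= 0:
        raise ValueError("flank must be positive")
    map_id, coord = junction
    lo, hi = coord - flank, coord + flank
    out: List[SupportRecord] = []
    for aln in alignments:
        if aln.ref_id != map_id:
            continue
        if aln.ref_end < lo or aln.ref_start > hi:
            continue
        spans = aln.ref_start < coord < aln.ref_end
        out.append(SupportRecord(
            molecule_id=aln.query_id,
            fully_aligned_in_window=aln.fully_aligned,
            spans_junction=spans))
    return out


# ---------------------------------------------------------------------------
# Simplified CMAP dialect I/O
# ---------------------------------------------------------------------------

_CMAP_COLS = ["CMapId", "ContigLength", "NumSites", "SiteID", "Position"]


def write_cmap(maps: Sequence[NickMap], path) -> None:
    """Write maps as headered TSV.  Each map gets one row per label (SiteID
    1..N) plus a trailing end-marker row (SiteID N+1, Position = length),
    so zero-label maps survive a round trip.  Molecules also carry SNR and
    Intensity columns."""
    molecules = any(isinstance(m, OpticalMolecule) for m in maps)
    rows = []
    for m in maps:
        snr = getattr(m, "label_snr", "")
        inten = getattr(m, "avg_intensity", "")
        n = m.n_labels
        for sid, pos in enumerate(m.labels, start=1):
            rows.append((m.map_id, m.length, n, sid, int(pos), snr, inten))
        rows.append((m.map_id, m.length, n, n + 1, m.length, snr, inten))
    cols = _CMAP_COLS + (["SNR", "Intensity"] if molecules else [])
    df = pd.DataFrame(rows, columns=_CMAP_COLS + ["SNR", "Intensity"])
    df[cols].to_csv(path, sep="\t", index=False)


def read_cmap(path) -> List[NickMap]:
    """Read the simplified CMAP dialect written by :func:`write_cmap`."""
    df = pd.read_csv(path, sep="\t", dtype={"CMapId": str})
    has_quality = "SNR" in df.columns and df["SNR"].notna().any()
    maps: List[NickMap] = []
    for map_id, grp in df.groupby("CMapId", sort=False):
        grp = grp.sort_values("SiteID")
        length = int(grp["ContigLength"].iloc[0])
        n = int(grp["NumSites"].iloc[0])
        labels = grp["Position"].to_numpy(dtype=np.int64)[:n]
        if has_quality:
            maps.append(OpticalMolecule(
                map_id=map_id, length=length, labels=labels,
                label_snr=float(grp["SNR"].iloc[0]),
                avg_intensity=float(grp["Intensity"].iloc[0])))
        else:
            maps.append(NickMap(map_id=map_id, length=length, labels=labels))
    return maps
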