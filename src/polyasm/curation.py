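"""Sequence-vs-optical-map conflict detection and chimera curation.

A draft sequence whose in-silico nick map cannot be explained by a single
placement on the optical genome map is a conflict candidate.  Each
candidate junction is scored by the *chimeric score* — the percentage of
locally overlapping optical molecules that fully align across the 50-kb
flanks of the junction on the genome map — and confirmed or vetoed by
mate-pair concordance over 10-kb sequence flanks and by the coverage of
long reads that fully span the junction.  Confirmed junctions are broken at
the consistent soft-clip site of the long reads.

Decision rule: a junction is a candidate chimera iff chimeric score >= 30
and more than two fully aligned molecules span it on the genome map; a
candidate is broken iff the mate-pair relationship of its 10-kb flanks is
in disagreement or fewer than 5 fully aligned long reads span the region.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .optical import (AlignParams, MapAlignment, MoleculeFilter, NickMap,
                      OpticalMolecule, SupportRecord, align_maps,
                      align_to_best_ref, classify_flank_support,
                      digest_sequence, filter_molecules, DEFAULT_MOTIF)
from .synthetic import MPLibrarySpec


# ---------------------------------------------------------------------------
# Types
# ---------------------------------------------------------------------------

@dataclass
class CurationThresholds:
    flank: int = 50_000
    min_chimeric_score: float = 30.0
    min_spanning_molecules: int = 2  # rule is "> 2", i.e. at least 3
    mp_flank: int = 10_000
    min_concordant_mp: int = 3
    min_longread_span_coverage: int = 5
    longread_span_flank: int = 500
    longread_max_clip: int = 200
    clip_cluster_tolerance: int = 100
    clip_min_reads: int = 3
    min_clip_length: int = 200

    def __post_init__(self) -> None:
        for f in ("flank", "min_chimeric_score", "min_spanning_molecules",
                  "mp_flank", "min_longread_span_coverage",
                  "clip_cluster_tolerance", "clip_min_reads"):
            if getattr(self, f) <= 0:
                raise ValueError(f"{f} must be positive")


@dataclass
class ConflictJunction:
    sequence_id: str
    sequence_coordinate: int
    map_id: str
    map_coordinate: int
    conflict_kind: str  # 'split_alignment' | 'sizing_discordance'
    # label-bounded uncertainty: the junction lies between the innermost
    # matched labels of the two placements; resolution is label-limited
    lo: Optional[int] = None
    hi: Optional[int] = None
    # the other placement's inner edge on the genome map (a split junction
    # disagrees with both placements; either side's molecules are evidence)
    alt_map_id: Optional[str] = None
    alt_map_coordinate: Optional[int] = None

    def __post_init__(self) -> None:
        if self.lo is None:
            self.lo = self.sequence_coordinate
        if self.hi is None:
            self.hi = self.sequence_coordinate


@dataclass
class ChimericScore:
    score: float  # percent, [0, 100]
    n_overlapping: int
    n_fully_aligned: int
    n_spanning_fully_aligned: int
    no_evidence: bool


@dataclass
class CurationDecision:
    junction: ConflictJunction
    chimeric_score: float
    spanning_fully_aligned_molecules: int
    mp_concordant: bool
    longread_span_coverage: int
    action: str  # 'break' | 'keep'
    breakpoint: Optional[int]
    rationale_code: str

    def __post_init__(self) -> None:
        if self.action == "break" and self.breakpoint is None:
            raise ValueError("break decision requires a breakpoint")
        if not 0.0 <= self.chimeric_score <= 100.0:
            raise ValueError("chimeric score must be in [0, 100]")


# ---------------------------------------------------------------------------
# Conflict detection
# ---------------------------------------------------------------------------

def _trimmed_matched_indices(aln: MapAlignment, smap: NickMap,
                             ref_labels: Dict[str, np.ndarray],
                             max_residual: float = 250.0) -> List[int]:
    """Query label indices of the alignment after trimming terminal matched
    pairs whose adjacent interval residual is implausibly large.

    A correct placement of an in-silico digested sequence on the genome map
    has near-zero interval residuals (small indel drift at most), while a
    spurious terminal extension typically mis-sizes by hundreds of bp; the
    trim keeps split-alignment tails clean so junctions land between the
    two true placements.
    """
    pairs = sorted(aln.pairs)
    rpos = ref_labels[aln.ref_id]
    qpos = smap.labels

    def resid(t: int) -> float:
        dq = float(qpos[pairs[t + 1][0]] - qpos[pairs[t][0]])
        dr = abs(float(rpos[pairs[t + 1][1]] - rpos[pairs[t][1]]))
        return abs(dq - dr)

    lo, hi = 0, len(pairs) - 1
    while hi - lo >= 2 and resid(hi - 1) > max_residual:
        hi -= 1
    while hi - lo >= 2 and resid(lo) > max_residual:
        lo += 1
    return [pairs[t][0] for t in range(lo, hi + 1)]


def _tail_submap(seq_map: NickMap, indices: np.ndarray) -> NickMap:
    pos = seq_map.labels[indices]
    return NickMap(map_id=f"{seq_map.map_id}|tail", length=seq_map.length,
                   labels=pos)


def _placement_offset_consistent(primary: MapAlignment, secondary: MapAlignment,
                                 slack: int = 30_000) -> bool:
    """True when the secondary placement merely continues the primary one
    colinearly on the same map (same orientation, compatible diagonal)."""
    if primary.ref_id != secondary.ref_id:
        return False
    if primary.orientation != secondary.orientation:
        return False
    if primary.orientation == "+":
        off_p = primary.ref_start - primary.query_start
        off_s = secondary.ref_start - secondary.query_start
    else:
        off_p = primary.ref_start + primary.query_end
        off_s = secondary.ref_start + secondary.query_end
    return abs(off_p - off_s) <= slack


def detect_conflicts(seq_maps: Sequence[NickMap], ref_maps: Sequence[NickMap],
                     params: Optional[AlignParams] = None,
                     min_tail_labels: int = 3,
                     min_discordant_run: int = 3) -> List[ConflictJunction]:
    """Emit a conflict where a sequence map's best explanation needs two
    disjoint optical-map placements (split alignment), or where a run of
    >= ``min_discordant_run`` consecutive matched intervals each exceed the
    sizing tolerance (sizing discordance)."""
    params = params or AlignParams()
    ref_labels = {r.map_id: r.labels for r in ref_maps}
    conflicts: List[ConflictJunction] = []
    for smap in seq_maps:
        if smap.n_labels < 2 * min_tail_labels:
            continue
        primary = align_to_best_ref(smap, ref_maps, params)
        if primary is None:
            continue
        matched = np.array(_trimmed_matched_indices(primary, smap, ref_labels))
        m = smap.n_labels
        left_run = int(matched[0])
        right_run = int(m - 1 - matched[-1])
        for side, run in (("left", left_run), ("right", right_run)):
            if run < min_tail_labels:
                continue
            tail_idx = (np.arange(0, matched[0]) if side == "left"
                        else np.arange(matched[-1] + 1, m))
            sub = _tail_submap(smap, tail_idx)
            secondary = align_to_best_ref(sub, ref_maps, params)
            if secondary is None or secondary.n_matched < min_tail_labels:
                continue
            if _placement_offset_consistent(primary, secondary):
                continue
            # refine the split point: the junction is the label boundary
            # maximizing the summed score of the prefix aligned against one
            # placement's map and the suffix against the other's.  A
            # homoeologous continuation past the true junction scores
            # strictly worse (its labels are partly missing), so the
            # optimum stays at the misjoin even for cross-subgenome joins
            # of near-syntenic regions.
            ref_by_id = {r.map_id: r for r in ref_maps}
            left_ref = ref_by_id[secondary.ref_id if side == "left"
                                 else primary.ref_id]
            right_ref = ref_by_id[primary.ref_id if side == "left"
                                  else secondary.ref_id]
            best = None
            for t in range(min_tail_labels - 1, m - min_tail_labels):
                prefix = NickMap(f"{smap.map_id}|p", smap.length,
                                 smap.labels[:t + 1])
                suffix = NickMap(f"{smap.map_id}|s", smap.length,
                                 smap.labels[t + 1:])
                pa = align_maps(prefix, left_ref, params)
                pb = align_maps(suffix, right_ref, params)
                if pa is None or pb is None:
                    continue
                tot = pa.score + pb.score
                if best is None or tot > best[0] + 1e-9:
                    best = (tot, t, pa, pb)
            if best is None:
                continue
            _, t, pa, pb = best
            inner_q, outer_q = int(smap.labels[t]), int(smap.labels[t + 1])
            seq_coord = (inner_q + outer_q) // 2
            # each placement's inner edge on the genome map
            qi_a, ri_a = max(pa.pairs)
            qi_b, ri_b = min(pb.pairs)
            coord_a = int(left_ref.labels[ri_a])
            coord_b = int(right_ref.labels[ri_b])
            if pa.n_matched >= pb.n_matched:
                main_id, main_c = left_ref.map_id, coord_a
                alt_id, alt_c = right_ref.map_id, coord_b
            else:
                main_id, main_c = right_ref.map_id, coord_b
                alt_id, alt_c = left_ref.map_id, coord_a
            conflicts.append(ConflictJunction(
                sequence_id=smap.map_id, sequence_coordinate=seq_coord,
                map_id=main_id, map_coordinate=main_c,
                conflict_kind="split_alignment", lo=inner_q, hi=outer_q,
                alt_map_id=alt_id, alt_map_coordinate=alt_c))
            break  # one split conflict per sequence map
        else:
            # sizing discordance scan on the primary alignment
            pairs = sorted(primary.pairs)
            bad = [abs(resid) > params.tolerance(
                       abs(smap.labels[pairs[t + 1][0]] - smap.labels[pairs[t][0]]))
                   for t, resid in enumerate(primary.residuals)]
            run_start, run_len = 0, 0
            for t, flag in enumerate(bad + [False]):
                if flag:
                    if run_len == 0:
                        run_start = t
                    run_len += 1
                else:
                    if run_len >= min_discordant_run:
                        mid = run_start + run_len // 2
                        q_mid = int((smap.labels[pairs[mid][0]]
                                     + smap.labels[pairs[mid + 1][0]]) // 2)
                        r_mid = int(primary.ref_start)
                        conflicts.append(ConflictJunction(
                            sequence_id=smap.map_id, sequence_coordinate=q_mid,
                            map_id=primary.ref_id, map_coordinate=r_mid,
                            conflict_kind="sizing_discordance"))
                        break
                    run_len = 0
    return conflicts


# ---------------------------------------------------------------------------
# Chimeric score
# ---------------------------------------------------------------------------

def chimeric_score(support: Iterable[SupportRecord]) -> ChimericScore:
    """Percentage of window-overlapping molecules that fully align; an empty
    window scores 0 with the no-evidence flag set (absence of optical
    evidence never nominates a break)."""
    support = list(support)
    n = len(support)
    if n == 0:
        return ChimericScore(0.0, 0, 0, 0, no_evidence=True)
    n_full = sum(1 for s in support if s.fully_aligned_in_window)
    n_span_full = sum(1 for s in support
                      if s.fully_aligned_in_window and s.spans_junction)
    return ChimericScore(100.0 * n_full / n, n, n_full, n_span_full, False)


# ---------------------------------------------------------------------------
# Mate-pair and long-read evidence at a junction
# ---------------------------------------------------------------------------

def _mp_flank_concordance(junction: ConflictJunction, mp_records: pd.DataFrame,
                          libraries: Dict[str, MPLibrarySpec],
                          thresholds: CurationThresholds, k_sd: float = 5.0
                          ) -> bool:
    """Mate-pair agreement over the junction's 10-kb flanks: at least
    ``min_concordant_mp`` unique pairs with one mate in each flank, innie
    orientation, and implied insert within mean +- k_sd * sd.

    The flanks sit outside the junction's label-bounded uncertainty
    interval, so a concordant pair genuinely bridges the two placements."""
    jl, jr = junction.lo, junction.hi
    lo, hi = jl - thresholds.mp_flank, jr + thresholds.mp_flank
    df = mp_records[(mp_records["contig"] == junction.sequence_id)
                    & mp_records["unique"]]
    if df.empty:
        return False
    pairs = df.groupby("read_id")
    n_ok = 0
    for _, grp in pairs:
        if len(grp) != 2:
            continue
        g = grp.sort_values("pos0")
        left, right = g.iloc[0], g.iloc[1]
        if not (lo <= left["pos0"] + left["read_len"] <= jl
                and jr <= right["pos0"] <= hi):
            continue
        if left["strand"] != "+" or right["strand"] != "-":
            continue
        lib = libraries[left["library"]]
        insert = right["pos0"] + right["read_len"] - left["pos0"]
        if abs(insert - lib.insert_mean) <= k_sd * lib.insert_sd:
            n_ok += 1
            if n_ok >= thresholds.min_concordant_mp:
                return True
    return False


def _longread_span_coverage(junction: ConflictJunction,
                            longreads: pd.DataFrame,
                            thresholds: CurationThresholds) -> int:
    """Number of fully aligned long reads spanning the junction region
    (the whole label-bounded uncertainty interval plus a margin)."""
    f = thresholds.longread_span_flank
    df = longreads[longreads["contig"] == junction.sequence_id]
    if df.empty:
        return 0
    ok = ((df["start"] <= junction.lo - f) & (df["end"] >= junction.hi + f)
          & (df["clip_left"] <= thresholds.longread_max_clip)
          & (df["clip_right"] <= thresholds.longread_max_clip))
    return int(ok.sum())


# ---------------------------------------------------------------------------
# Junction evaluation
# ---------------------------------------------------------------------------

def evaluate_junction(junction: ConflictJunction, score: ChimericScore,
                      mp_records: pd.DataFrame, longreads: pd.DataFrame,
                      libraries: Dict[str, MPLibrarySpec],
                      thresholds: Optional[CurationThresholds] = None,
                      sequence_length: Optional[int] = None
                      ) -> CurationDecision:
    """Apply the decision rules to one conflict junction.

    Candidate iff score >= min_chimeric_score AND spanning fully aligned
    molecules > min_spanning_molecules; a candidate breaks iff the MP
    relationship of the 10-kb flanks disagrees OR fewer than
    min_longread_span_coverage fully aligned long reads span the region.
    """
    thresholds = thresholds or CurationThresholds()
    spanning = score.n_spanning_fully_aligned
    mp_ok = _mp_flank_concordance(junction, mp_records, libraries, thresholds)
    lr_cov = _longread_span_coverage(junction, longreads, thresholds)

    if score.no_evidence:
        action, rationale, bp = "keep", "no_optical_evidence", None
    elif score.score < thresholds.min_chimeric_score:
        action, rationale, bp = "keep", "score_below_threshold", None
    elif spanning <= thresholds.min_spanning_molecules:
        action, rationale, bp = "keep", "too_few_spanning_molecules", None
    elif not mp_ok:
        action, rationale = "break", "mp_disagreement"
        bp = locate_breakpoint(junction, longreads, thresholds, sequence_length)
    elif lr_cov < thresholds.min_longread_span_coverage:
        action, rationale = "break", "low_longread_span_coverage"
        bp = locate_breakpoint(junction, longreads, thresholds, sequence_length)
    else:
        action, rationale, bp = "keep", "supported_by_mp_and_longreads", None
    return CurationDecision(
        junction=junction, chimeric_score=score.score,
        spanning_fully_aligned_molecules=spanning, mp_concordant=mp_ok,
        longread_span_coverage=lr_cov, action=action, breakpoint=bp,
        rationale_code=rationale)


# ---------------------------------------------------------------------------
# Breakpoint localisation from soft clips
# ---------------------------------------------------------------------------

def locate_breakpoint(junction: ConflictJunction, longreads: pd.DataFrame,
                      thresholds: Optional[CurationThresholds] = None,
                      sequence_length: Optional[int] = None) -> int:
    """Consistent soft-clip sites near the junction give the accurate break
    point: cluster clip boundaries within clip_cluster_tolerance, take the
    largest cluster with >= clip_min_reads within mp_flank of the junction
    (ties go to the cluster nearest the junction) and return its median
    boundary; with no such cluster fall back to the junction coordinate."""
    thresholds = thresholds or CurationThresholds()
    j = junction.sequence_coordinate
    win_lo = junction.lo - thresholds.mp_flank
    win_hi = junction.hi + thresholds.mp_flank
    df = longreads[longreads["contig"] == junction.sequence_id]
    boundaries: List[int] = []
    if not df.empty:
        left_clipped = df[df["clip_left"] >= thresholds.min_clip_length]
        right_clipped = df[df["clip_right"] >= thresholds.min_clip_length]
        boundaries.extend(int(x) for x in left_clipped["start"])
        boundaries.extend(int(x) for x in right_clipped["end"])
    boundaries = [b for b in boundaries if win_lo <= b <= win_hi]
    if sequence_length is not None:
        # clip pileups at sequence termini are alignment-edge artifacts
        boundaries = [b for b in boundaries if 1000 <= b <= sequence_length - 1000]
    boundaries = sorted(boundaries)
    fallback = j if sequence_length is None else max(1, min(j, sequence_length - 1))
    if not boundaries:
        return fallback
    clusters: List[List[int]] = [[boundaries[0]]]
    for b in boundaries[1:]:
        if b - clusters[-1][-1] <= thresholds.clip_cluster_tolerance:
            clusters[-1].append(b)
        else:
            clusters.append([b])
    clusters = [c for c in clusters if len(c) >= thresholds.clip_min_reads]
    if not clusters:
        return fallback
    def key(c: List[int]) -> Tuple[int, int]:
        med = int(np.median(c))
        return (-len(c), abs(med - j))
    best = min(clusters, key=key)
    return int(np.median(best))


# ---------------------------------------------------------------------------
# Breaking
# ---------------------------------------------------------------------------

def apply_breaks(draft: Dict[str, str], decisions: Sequence[CurationDecision]
                 ) -> Tuple[Dict[str, str], pd.DataFrame]:
    """Execute break decisions.  Broken sequences are replaced by fragments
    named ``{id}.1, {id}.2, ...`` left to right; total base count is
    conserved.  Returns (curated assembly, break log)."""
    by_seq: Dict[str, List[CurationDecision]] = {}
    for d in decisions:
        if d.action != "break":
            continue
        seq = draft.get(d.junction.sequence_id)
        if seq is None:
            raise KeyError(f"unknown sequence {d.junction.sequence_id}")
        if not 0 < d.breakpoint < len(seq):
            raise ValueError(
                f"breakpoint {d.breakpoint} not strictly inside "
                f"{d.junction.sequence_id} (length {len(seq)})")
        by_seq.setdefault(d.junction.sequence_id, []).append(d)
    curated: Dict[str, str] = {}
    log_rows = []
    for name, seq in draft.items():
        if name not in by_seq:
            curated[name] = seq
            continue
        ds = sorted(by_seq[name], key=lambda d: d.breakpoint)
        points = sorted({d.breakpoint for d in ds})
        bounds = [0] + points + [len(seq)]
        new_ids = [f"{name}.{i + 1}" for i in range(len(bounds) - 1)]
        for i, nid in enumerate(new_ids):
            curated[nid] = seq[bounds[i]:bounds[i + 1]]
        for d in ds:
            log_rows.append((name, ",".join(new_ids), d.breakpoint,
                             round(d.chimeric_score, 2),
                             d.spanning_fully_aligned_molecules,
                             d.mp_concordant, d.longread_span_coverage,
                             d.rationale_code))
    log = pd.DataFrame(log_rows, columns=[
        "sequence", "new_ids", "breakpoint0", "score", "spanning",
        "mp_concordant", "longread_cov", "rationale"])
    return curated, log


# ---------------------------------------------------------------------------
# End-to-end curation
# ---------------------------------------------------------------------------

@dataclass
class CurationResult:
    curated: Dict[str, str]
    decisions: List[CurationDecision]
    conflicts: List[ConflictJunction]
    break_log: pd.DataFrame


def curate_assembly(draft: Dict[str, str],
                    molecules: Sequence[OpticalMolecule],
                    genome_maps: Sequence[NickMap],
                    mp_records: pd.DataFrame,
                    longreads: pd.DataFrame,
                    libraries: Dict[str, MPLibrarySpec],
                    thresholds: Optional[CurationThresholds] = None,
                    align_params: Optional[AlignParams] = None,
                    molecule_filter: Optional[MoleculeFilter] = None,
                    motif: str = DEFAULT_MOTIF) -> CurationResult:
    """Full curation pass: filter molecules, align them to the genome maps,
    digest and align the draft, detect conflicts, score and decide each
    junction, and break confirmed chimeras."""
    thresholds = thresholds or CurationThresholds()
    align_params = align_params or AlignParams()
    kept = filter_molecules(molecules, molecule_filter)
    mol_alignments: List[MapAlignment] = []
    for mol in kept:
        if mol.n_labels < 2:
            continue
        aln = align_to_best_ref(mol, genome_maps, align_params)
        if aln is not None:
            mol_alignments.append(aln)
    seq_maps = [digest_sequence(seq, motif, name)
                for name, seq in sorted(draft.items())]
    conflicts = detect_conflicts(seq_maps, genome_maps, align_params)
    decisions: List[CurationDecision] = []
    for junction in conflicts:
        support = classify_flank_support(
            mol_alignments, (junction.map_id, junction.map_coordinate),
            thresholds.flank)
        score = chimeric_score(support)
        if junction.alt_map_id is not None:
            # a split junction disagrees with both placements; score it on
            # whichever genome-map side carries more molecule evidence
            alt = chimeric_score(classify_flank_support(
                mol_alignments,
                (junction.alt_map_id, junction.alt_map_coordinate),
                thresholds.flank))
            if ((alt.n_overlapping, alt.n_spanning_fully_aligned)
                    > (score.n_overlapping, score.n_spanning_fully_aligned)):
                score = alt
        decisions.append(evaluate_junction(
            junction, score, mp_records, longreads, libraries, thresholds,
            sequence_length=len(draft[junction.sequence_id])))
    curated, log = apply_breaks(draft, decisions)
    return CurationResult(curated=curated, decisions=decisions,
                          conflicts=conflicts, break_log=log)
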