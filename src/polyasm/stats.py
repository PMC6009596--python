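"""Assembly contiguity, gap and anchoring statistics.

Per-chromosome reports follow the conventional pseudochromosome table
layout (length, gap count, gap length, gap ratio %, anchored %), and
per-subgenome summaries follow the assembly-comparison layout (size,
contig count, max/min, N50/N90, gap number, gap ratio, GC%).  Ratios are
rounded half-up to 2 decimals, matching how such tables are printed.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from importlib import resources
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

_GAP_RE = re.compile(r"N+")


def round2(x: float) -> float:
    """Half-up rounding to 2 decimals (matches printed tables)."""
    return float(Decimal(repr(float(x))).quantize(Decimal("0.01"),
                                                  rounding=ROUND_HALF_UP))


# ---------------------------------------------------------------------------
# Contiguity
# ---------------------------------------------------------------------------

@dataclass
class ContiguityStats:
    total: int
    count: int
    max_length: int
    min_length: int
    n50: int
    l50: int
    n90: int
    gap_count: int = 0
    gap_length: int = 0
    gc_percent: Optional[float] = None


def _nx(sorted_desc: np.ndarray, frac: float) -> Tuple[int, int]:
    """Length of the smallest sequence in the minimal descending prefix
    reaching frac of the total, and the prefix size."""
    target = frac * sorted_desc.sum()
    csum = np.cumsum(sorted_desc)
    idx = int(np.searchsorted(csum, target, side="left"))
    return int(sorted_desc[idx]), idx + 1


def gap_runs(seq: str) -> List[Tuple[int, int]]:
    """Maximal runs of N (0-based half-open intervals)."""
    return [(m.start(), m.end()) for m in _GAP_RE.finditer(seq.upper())]


def contiguity_stats(lengths: Sequence[int],
                     sequences: Optional[Iterable[str]] = None
                     ) -> ContiguityStats:
    """N50/N90/L50 and friends; GC% (over non-N bases) and gap statistics
    when sequences are supplied."""
    lengths = np.asarray(list(lengths), dtype=np.int64)
    if lengths.size == 0:
        raise ValueError("empty length list")
    desc = np.sort(lengths)[::-1]
    n50, l50 = _nx(desc, 0.5)
    n90, _ = _nx(desc, 0.9)
    gap_count = gap_length = 0
    gc = None
    if sequences is not None:
        at = gc_bases = 0
        for seq in sequences:
            s = seq.upper()
            for a, b in gap_runs(s):
                gap_count += 1
                gap_length += b - a
            gc_bases += s.count("G") + s.count("C")
            at += s.count("A") + s.count("T")
        denom = gc_bases + at
        gc = round2(100.0 * gc_bases / denom) if denom else 0.0
    return ContiguityStats(total=int(desc.sum()), count=int(desc.size),
                           max_length=int(desc[0]), min_length=int(desc[-1]),
                           n50=n50, l50=l50, n90=n90, gap_count=gap_count,
                           gap_length=gap_length, gc_percent=gc)


# ---------------------------------------------------------------------------
# Pseudochromosome table
# ---------------------------------------------------------------------------

def chromosome_table(rows: pd.DataFrame, total_assembly_length: int
                     ) -> pd.DataFrame:
    """Per-chromosome gap ratio and anchored percent, plus a totals row.

    ``rows`` needs columns: subgenome, chromosome, length_bp, gap_count,
    gap_length_bp.  gap ratio = 100 * gap_length / length; anchored
    percent = 100 * length / total assembly length; both half-up to 2
    decimals.  The totals row recomputes its ratio from the summed columns.
    """
    if total_assembly_length <= 0:
        raise ValueError("total_assembly_length must be positive")
    out = rows.copy()
    out["gap_ratio_pct"] = [
        round2(100.0 * g / l) for g, l in zip(out["gap_length_bp"],
                                              out["length_bp"])]
    out["anchored_pct"] = [round2(100.0 * l / total_assembly_length)
                           for l in out["length_bp"]]
    totals = pd.DataFrame([{
        "subgenome": "total", "chromosome": "Total",
        "length_bp": int(out["length_bp"].sum()),
        "gap_count": int(out["gap_count"].sum()),
        "gap_length_bp": int(out["gap_length_bp"].sum()),
        "gap_ratio_pct": round2(100.0 * out["gap_length_bp"].sum()
                                / out["length_bp"].sum()),
        "anchored_pct": round2(100.0 * out["length_bp"].sum()
                               / total_assembly_length)}])
    return pd.concat([out, totals], ignore_index=True)


# ---------------------------------------------------------------------------
# Subgenome summary
# ---------------------------------------------------------------------------

def subgenome_table(partition: pd.DataFrame, sequences: Dict[str, str],
                    min_length: int = 10_000) -> pd.DataFrame:
    """Per-subgenome assembly summary over sequences longer than
    ``min_length`` (strictly: exactly 10 kb is excluded).

    ``partition`` needs columns sequence and label ('A'/'B'/...).
    """
    rows = []
    for label in sorted(partition["label"].unique()):
        ids = partition.loc[partition["label"] == label, "sequence"]
        seqs = [sequences[i] for i in ids
                if i in sequences and len(sequences[i]) > min_length]
        if not seqs:
            rows.append({"subgenome": label, "genome_size_bp": 0,
                         "contig_count": 0, "max_length_bp": 0,
                         "min_length_bp": 0, "n50_bp": 0, "n90_bp": 0,
                         "gap_count": 0, "gap_ratio_pct": 0.0,
                         "gc_percent": 0.0})
            continue
        st = contiguity_stats([len(s) for s in seqs], seqs)
        rows.append({"subgenome": label, "genome_size_bp": st.total,
                     "contig_count": st.count, "max_length_bp": st.max_length,
                     "min_length_bp": st.min_length, "n50_bp": st.n50,
                     "n90_bp": st.n90, "gap_count": st.gap_count,
                     "gap_ratio_pct": round2(100.0 * st.gap_length / st.total),
                     "gc_percent": st.gc_percent})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Anchoring summary
# ---------------------------------------------------------------------------

def anchoring_summary(rows: pd.DataFrame) -> Tuple[float, float]:
    """(anchored %, subgenome-separated %) from a pseudochromosome table.

    Anchored % = named-pseudochromosome length / grand total; separated %
    = length of all A- and B-labelled entries (named or not) / grand
    total; both half-up to 2 decimals.
    """
    total = int(rows["length_bp"].sum())
    named = rows[(rows["subgenome"].isin(["A", "B"]))
                 & (rows["chromosome"] != "Un-chr")]
    labelled = rows[rows["subgenome"].isin(["A", "B"])]
    anchored = round2(100.0 * named["length_bp"].sum() / total)
    separated = round2(100.0 * labelled["length_bp"].sum() / total)
    return anchored, separated


def load_published_pseudochromosome_stats() -> pd.DataFrame:
    """The published pseudochromosome statistics of the A. monticola
    reference assembly (20 named chromosomes, two unplaced-per-subgenome
    entries and an unknown bin), used as printed input for table
    arithmetic."""
    with resources.files("polyasm.data").joinpath(
            "pseudochromosome_stats.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")
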