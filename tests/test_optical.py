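"""Nick-map digestion, molecule filtering, map alignment and CMAP I/O."""

import itertools

import numpy as np
import pytest

from polyasm import (AlignParams, MoleculeFilter, NickMap, OpticalMolecule,
                     align_maps, classify_flank_support, digest_sequence,
                     filter_molecules, read_cmap, reverse_complement,
                     write_cmap, DEFAULT_MOTIF)

MOTIF = "GCTCTTC"


# ---------------------------------------------------------------------------
# digestion
# ---------------------------------------------------------------------------

def brute_force_digest(seq: str, motif: str):
    """Independent oracle: scan every offset on both strands."""
    rc = reverse_complement(motif)
    hits = set()
    for i in range(len(seq) - len(motif) + 1):
        window = seq[i:i + len(motif)]
        if window == motif or window == rc:
            hits.add(i)
    return sorted(hits)


def test_digest_no_occurrence_gives_empty_map():
    assert digest_sequence("ACGT" * 10, MOTIF).n_labels == 0


def test_digest_single_forward_site_at_offset_5():
    seq = "ACGTA" + MOTIF + "ACGTACGT"
    nm = digest_sequence(seq, MOTIF)
    assert list(nm.labels) == [5]
    assert nm.labels.tolist() == brute_force_digest(seq, MOTIF)


def test_digest_reverse_strand_site_found():
    seq = "AC" + reverse_complement(MOTIF) + "GGGG"
    assert list(digest_sequence(seq, MOTIF).labels) == [2]


@pytest.mark.parametrize("seed", range(5))
def test_digest_matches_brute_force_on_random_sequence(seed, rng):
    seq = "".join(np.random.default_rng(seed).choice(list("ACGT"), 3000))
    nm = digest_sequence(seq, MOTIF)
    assert nm.labels.tolist() == brute_force_digest(seq, MOTIF)


def test_digest_is_local_over_concatenation(rng):
    s1 = "".join(rng.choice(list("ACGT"), 2000))
    s2 = "".join(rng.choice(list("ACGT"), 2000))
    joint = digest_sequence(s1 + s2, MOTIF).labels.tolist()
    # compare away from the junction neighbourhood
    margin = len(MOTIF) - 1
    expect = (digest_sequence(s1, MOTIF).labels.tolist()
              + [p + len(s1) for p in digest_sequence(s2, MOTIF).labels])
    joint_far = [p for p in joint if not len(s1) - margin <= p < len(s1)]
    expect_far = [p for p in expect if not len(s1) - margin <= p < len(s1)]
    assert joint_far == expect_far


def test_digest_skips_sites_with_n_and_rejects_bad_chars():
    seq = "AAAA" + MOTIF.replace("T", "N", 1) + "AAAA"
    assert digest_sequence(seq, MOTIF).n_labels == 0
    with pytest.raises(ValueError):
        digest_sequence("ACGTXACGT", MOTIF)


# ---------------------------------------------------------------------------
# molecule filtering (boundary semantics as printed)
# ---------------------------------------------------------------------------

def _mol(length, n_labels, snr, intensity):
    labels = np.linspace(10, length - 10, n_labels).astype(int)
    return OpticalMolecule(map_id="m", length=length, labels=labels,
                           label_snr=snr, avg_intensity=intensity)


@pytest.mark.parametrize("mol,kept", [
    (_mol(149_999, 10, 4.0, 0.5), False),   # length must exceed 150 kb
    (_mol(150_000, 10, 4.0, 0.5), False),   # 'more than', not 'at least'
    (_mol(200_000, 8, 3.0, 0.59), True),    # snr >= 3.0, intensity < 0.6, 8 labels
    (_mol(200_000, 7, 4.0, 0.5), False),    # below min label count
    (_mol(200_000, 8, 2.99, 0.5), False),
    (_mol(200_000, 8, 3.0, 0.60), False),   # intensity must be < 0.6
])
def test_molecule_filter_boundaries(mol, kept):
    assert (filter_molecules([mol]) == [mol]) is kept


def test_molecule_filter_empty_and_order_preserved():
    assert filter_molecules([]) == []
    mols = [_mol(200_000 + i, 9, 4.0, 0.3) for i in range(5)]
    assert filter_molecules(mols) == mols


# ---------------------------------------------------------------------------
# alignment: brute-force oracle
# ---------------------------------------------------------------------------

def objective(qpos, rpos, qs, rs, p: AlignParams):
    score = p.match_reward * len(qs)
    for t in range(1, len(qs)):
        dq = qpos[qs[t]] - qpos[qs[t - 1]]
        dr = rpos[rs[t]] - rpos[rs[t - 1]]
        tol = max(p.tol_bp, p.tol_rel * dr)
        score -= ((dq - dr) / tol) ** 2
        score -= p.extra_penalty * (qs[t] - qs[t - 1] - 1)
        score -= p.miss_penalty * (rs[t] - rs[t - 1] - 1)
    score -= p.end_penalty * (qs[0] + (len(qpos) - 1 - qs[-1]))
    return score


def brute_force_best(query: NickMap, ref: NickMap, p: AlignParams):
    """Exhaustive enumeration over all monotone matchings, both
    orientations."""
    best = -np.inf
    rpos = ref.labels.astype(float)
    for qpos in (query.labels.astype(float),
                 (query.length - query.labels[::-1]).astype(float)):
        m, n = len(qpos), len(rpos)
        for k in range(1, min(m, n) + 1):
            for qs in itertools.combinations(range(m), k):
                if any(qs[t] - qs[t - 1] > p.max_skip for t in range(1, k)):
                    continue
                for rs in itertools.combinations(range(n), k):
                    if any(rs[t] - rs[t - 1] > p.max_skip
                           for t in range(1, k)):
                        continue
                    best = max(best, objective(qpos, rpos, qs, rs, p))
    return best


def _random_map(rng, n_labels, map_id="q"):
    gaps = rng.integers(500, 30_000, size=n_labels)
    labels = np.cumsum(gaps)
    return NickMap(map_id=map_id, length=int(labels[-1] + 1000), labels=labels)


def test_dp_equals_exhaustive_enumeration_small_maps():
    """On maps with <= 6 labels the DP must equal brute-force enumeration
    over all monotone matchings (>= 100 random pairs)."""
    params = AlignParams(max_skip=6, min_score=-1e9)
    rng = np.random.default_rng(7)
    n_checked = 0
    for _ in range(120):
        q = _random_map(rng, int(rng.integers(2, 7)))
        r = _random_map(rng, int(rng.integers(2, 7)), "r")
        aln = align_maps(q, r, params)
        expected = brute_force_best(q, r, params)
        assert aln is not None
        assert aln.score == pytest.approx(expected, abs=1e-6)
        n_checked += 1
    assert n_checked >= 100


def test_self_alignment_is_fully_aligned_identity(rng):
    for n in (5, 9, 14):
        x = _random_map(rng, n)
        aln = align_maps(x, x)
        assert aln is not None and aln.fully_aligned
        assert aln.n_matched == n
        assert aln.missing_label_count == 0 and aln.extra_label_count == 0
        assert all(r == pytest.approx(0.0) for r in aln.residuals)


def test_query_with_one_deleted_internal_label():
    ref = _random_map(np.random.default_rng(3), 10, "r")
    keep = np.delete(np.arange(10), 5)
    query = NickMap("q", ref.length, ref.labels[keep])
    aln = align_maps(query, ref)
    assert aln.missing_label_count == 1
    assert aln.fully_aligned


def test_alignment_score_symmetric_under_joint_reversal(rng):
    q = _random_map(rng, 6)
    r = _random_map(rng, 10, "r")
    params = AlignParams(min_score=-1e9)
    fwd = align_maps(q, r, params)
    q_rev = NickMap("q", q.length, np.sort(q.length - q.labels))
    r_rev = NickMap("r", r.length, np.sort(r.length - r.labels))
    rev = align_maps(q_rev, r_rev, params)
    assert fwd.score == pytest.approx(rev.score, abs=1e-6)


def test_alignment_rejects_single_label_query():
    r = _random_map(np.random.default_rng(0), 5, "r")
    with pytest.raises(ValueError):
        align_maps(NickMap("q", 1000, np.array([500])), r)


# ---------------------------------------------------------------------------
# flank support classification
# ---------------------------------------------------------------------------

def _identity_alignment(ref, lo_idx, hi_idx, fully=True, mol_id="m"):
    from polyasm import MapAlignment

    pairs = [(i - lo_idx, i) for i in range(lo_idx, hi_idx + 1)]
    return MapAlignment(query_id=mol_id, ref_id=ref.map_id, orientation="+",
                        pairs=pairs, residuals=[0.0] * (len(pairs) - 1),
                        missing_label_count=0, extra_label_count=0,
                        score=50.0, fully_aligned=fully,
                        ref_start=int(ref.labels[lo_idx]),
                        ref_end=int(ref.labels[hi_idx]),
                        query_start=0, query_end=1)


def test_flank_support_classification_cases():
    ref = NickMap("r", 400_000,
                  np.array([10_000, 90_000, 110_000, 190_000, 300_000]))
    junction = ("r", 100_000)
    # spans: matched labels at 90k and 110k, both sides of the junction
    spanning = _identity_alignment(ref, 0, 3)
    # only left of junction
    left_only = _identity_alignment(ref, 0, 1, mol_id="left")
    # far away: no window overlap
    far = _identity_alignment(ref, 4, 4, mol_id="far")
    far.ref_start = far.ref_end = 300_000
    recs = classify_flank_support([spanning, left_only, far], junction,
                                  flank=50_000)
    by_id = {r.molecule_id: r for r in recs}
    assert set(by_id) == {"m", "left"}
    assert by_id["m"].fully_aligned_in_window and by_id["m"].spans_junction
    assert by_id["left"].fully_aligned_in_window
    assert not by_id["left"].spans_junction
    assert classify_flank_support([], junction, 50_000) == []
    with pytest.raises(ValueError):
        classify_flank_support([], junction, flank=0)


# ---------------------------------------------------------------------------
# CMAP dialect round trip
# ---------------------------------------------------------------------------

def test_cmap_round_trip_identity(tmp_path, rng):
    maps = [_random_map(rng, n, f"map{n}") for n in (2, 5, 9)]
    maps.append(NickMap("empty", 50_000, np.array([], dtype=np.int64)))
    path = tmp_path / "maps.cmap.tsv"
    write_cmap(maps, path)
    back = read_cmap(path)
    assert [m.map_id for m in back] == [m.map_id for m in maps]
    for a, b in zip(maps, back):
        assert a.length == b.length
        assert a.labels.tolist() == b.labels.tolist()


def test_cmap_round_trip_preserves_molecule_quality(tmp_path):
    mol = _mol(200_000, 9, 4.5, 0.31)
    path = tmp_path / "mol.cmap.tsv"
    write_cmap([mol], path)
    (back,) = read_cmap(path)
    assert isinstance(back, OpticalMolecule)
    assert back.label_snr == pytest.approx(4.5)
    assert back.avg_intensity == pytest.approx(0.31)


def test_digest_round_trip_through_cmap(tmp_path, rng):
    seq = "".join(rng.choice(list("ACGT"), 60_000))
    nm = digest_sequence(seq, MOTIF, "s1")
    write_cmap([nm], tmp_path / "d.tsv")
    (back,) = read_cmap(tmp_path / "d.tsv")
    assert back.labels.tolist() == nm.labels.tolist()
    assert back.length == nm.length
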