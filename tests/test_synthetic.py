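"""Truth-set and evidence simulators: determinism, conservation, rates."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from polyasm import (DEFAULT_MOTIF, SimulationConfig, digest_sequence,
                     make_draft_with_chimeras, reverse_complement,
                     simulate_contacts, simulate_long_read_clips,
                     simulate_mate_pairs, simulate_molecules, simulate_truth)


def small_cfg(**kw):
    base = dict(seed=5, n_chromosomes_per_subgenome=1,
                chromosome_length=200_000, n_chimeras=1,
                fragment_length_mean=50_000, fragment_length_sd=8_000,
                fragment_length_min=25_000, n_contacts=20_000)
    base.update(kw)
    return SimulationConfig(**base)


# ---------------------------------------------------------------------------
# config validation
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("kw", [
    dict(chromosome_length=0),
    dict(ancestor_divergence=1.5),
    dict(molecule_coverage=0),
    dict(mp_libraries=(("lib", 3000, 0, 100),)),
    dict(n_chimeras=-1),
])
def test_invalid_configs_rejected(kw):
    with pytest.raises(ValueError):
        small_cfg(**kw)


# ---------------------------------------------------------------------------
# truth simulation
# ---------------------------------------------------------------------------

def test_zero_subgenome_divergence_copies_ancestors():
    cfg = small_cfg(subgenome_divergence=0.0, indel_rate=0.0)
    truth = simulate_truth(cfg)
    assert truth.chromosomes["A01"] == truth.ancestors["A"]["ancA_chr1"]
    assert truth.chromosomes["B01"] == truth.ancestors["B"]["ancB_chr1"]


def test_truth_simulation_deterministic_under_seed():
    a = simulate_truth(small_cfg())
    b = simulate_truth(small_cfg())
    assert a.chromosomes == b.chromosomes
    assert a.ancestors == b.ancestors


def test_ancestor_divergence_realized_within_20_percent():
    cfg = small_cfg(ancestor_divergence=0.03, indel_rate=0.0,
                    chromosome_length=100_000)
    truth = simulate_truth(cfg)
    a = truth.ancestors["A"]["ancA_chr1"]
    b = truth.ancestors["B"]["ancB_chr1"]
    mismatch = sum(x != y for x, y in zip(a, b)) / len(a)
    # substitutions can coincide; expected realized rate = 0.03 * 3/4 hit
    # distinct bases, i.e. observed mismatches ~ 0.03 within +-20%
    assert 0.03 * 0.8 <= mismatch <= 0.03 * 1.2


def test_subgenome_divergence_rate_within_3_binomial_sd():
    rate = 0.01
    cfg = small_cfg(subgenome_divergence=rate, indel_rate=0.0)
    truth = simulate_truth(cfg)
    a = truth.ancestors["A"]["ancA_chr1"]
    s = truth.chromosomes["A01"]
    n = len(a)
    mismatch = sum(x != y for x, y in zip(a, s))
    sd = np.sqrt(n * rate * (1 - rate))
    assert abs(mismatch - n * rate) <= 3 * sd


# ---------------------------------------------------------------------------
# draft and chimeras
# ---------------------------------------------------------------------------

def test_chimera_free_draft_contains_only_contiguous_intervals():
    cfg = small_cfg(n_chimeras=0)
    truth = simulate_truth(cfg)
    draft, truth = make_draft_with_chimeras(truth, cfg)
    assert truth.chimeras == []
    for f in truth.fragments:
        seq = truth.chromosomes[f.chrom][f.start:f.end]
        if f.strand == "-":
            seq = reverse_complement(seq)
        assert draft[f.draft_id] == seq


def test_exact_chimera_count_and_junction_inside_sequence(truth_and_draft):
    truth, draft = truth_and_draft
    assert len(truth.chimeras) == 5
    for ch in truth.chimeras:
        assert 0 < ch.junction < len(draft[ch.draft_id])


def test_fragment_concatenation_reconstructs_chromosome():
    cfg = small_cfg(n_chimeras=0)
    truth = simulate_truth(cfg)
    draft, truth = make_draft_with_chimeras(truth, cfg)
    for chrom, seq in truth.chromosomes.items():
        frs = truth.fragments_of_chrom(chrom)
        rebuilt = "".join(
            draft[f.draft_id] if f.strand == "+"
            else reverse_complement(draft[f.draft_id]) for f in frs)
        assert rebuilt == seq


def test_draft_length_conserved(truth_and_draft):
    truth, draft = truth_and_draft
    assert (sum(len(s) for s in draft.values())
            == sum(len(s) for s in truth.chromosomes.values()))


def test_too_many_chimeras_rejected():
    cfg = small_cfg(n_chimeras=50)
    truth = simulate_truth(cfg)
    with pytest.raises(ValueError):
        make_draft_with_chimeras(truth, cfg)


# ---------------------------------------------------------------------------
# optical molecules
# ---------------------------------------------------------------------------

def test_noise_free_molecule_labels_match_truth_digest():
    cfg = small_cfg(sizing_noise=0.0, label_fn_rate=0.0, label_fp_rate=0.0,
                    molecule_fail_fraction=0.0, chromosome_length=400_000)
    truth = simulate_truth(cfg)
    mols = simulate_molecules(truth, DEFAULT_MOTIF, cfg)
    nicks = {c: digest_sequence(s, DEFAULT_MOTIF, c).labels
             for c, s in truth.chromosomes.items()}
    checked = 0
    for mol in mols[:20]:
        if mol.n_labels == 0:
            continue
        hit = False
        for c, pos in nicks.items():
            # noise-free labels are exact offsets of true nicks: candidate
            # starts follow from anchoring the first/last label
            starts = set((pos - mol.labels[0]).tolist())
            starts |= set((pos - (mol.length - 1 - mol.labels[-1])).tolist())
            for start in starts:
                if start < 0 or start + mol.length > len(truth.chromosomes[c]):
                    continue
                rel = pos[(pos >= start) & (pos < start + mol.length)] - start
                rev = sorted(mol.length - 1 - rel)
                if mol.labels.tolist() in (rel.tolist(), rev):
                    hit = True
                    break
            if hit:
                break
        checked += 1 if hit else 0
        assert hit, f"molecule {mol.map_id} does not match any truth interval"
    assert checked >= 15


def test_molecule_coverage_total_length_within_15_percent():
    cfg = small_cfg(molecule_coverage=30.0, chromosome_length=500_000,
                    n_chromosomes_per_subgenome=1)
    truth = simulate_truth(cfg)
    mols = simulate_molecules(truth, DEFAULT_MOTIF, cfg)
    total = sum(m.length for m in mols)
    target = 30.0 * sum(len(s) for s in truth.chromosomes.values())
    assert abs(total - target) / target <= 0.15


def test_molecule_fail_fraction_binomial():
    from polyasm import filter_molecules

    cfg = small_cfg(molecule_fail_fraction=0.2, molecule_coverage=250.0,
                    chromosome_length=500_000, n_chromosomes_per_subgenome=1)
    truth = simulate_truth(cfg)
    mols = simulate_molecules(truth, DEFAULT_MOTIF, cfg)
    assert len(mols) >= 1000
    mols = mols[:1000]
    n_fail = 1000 - len(filter_molecules(mols))
    assert 160 <= n_fail <= 240  # 200 +- 40


def test_molecules_deterministic_and_coverage_validation(truth_and_draft,
                                                         default_config):
    truth, _ = truth_and_draft
    a = simulate_molecules(truth, DEFAULT_MOTIF, default_config)
    b = simulate_molecules(truth, DEFAULT_MOTIF, default_config)
    assert [(m.map_id, m.labels.tolist()) for m in a] \
        == [(m.map_id, m.labels.tolist()) for m in b]
    with pytest.raises(ValueError):
        simulate_molecules(truth, "", default_config)


# ---------------------------------------------------------------------------
# mate pairs
# ---------------------------------------------------------------------------

def test_mate_pairs_deterministic(truth_and_draft, default_config):
    truth, draft = truth_and_draft
    a = simulate_mate_pairs(truth, draft, default_config)
    b = simulate_mate_pairs(truth, draft, default_config)
    pd.testing.assert_frame_equal(a, b)


def test_same_contig_pair_insert_near_mean_with_tiny_sd():
    cfg = small_cfg(n_chimeras=0, fragment_length_mean=200_000,
                    mp_libraries=(("lib", 5_000, 1, 2_000),))
    truth = simulate_truth(cfg)
    draft, truth = make_draft_with_chimeras(truth, cfg)
    mp = simulate_mate_pairs(truth, draft, cfg)
    m1 = mp[mp["mate"] == 1].set_index("read_id")
    m2 = mp[mp["mate"] == 2].set_index("read_id")
    both = m1.join(m2, lsuffix="_1", rsuffix="_2")
    same = both[both["contig_1"] == both["contig_2"]]
    assert len(same) > 100
    lo = same[["pos0_1", "pos0_2"]].min(axis=1)
    hi = same[["pos0_1", "pos0_2"]].max(axis=1)
    implied = hi + 100 - lo
    assert (abs(implied - 5_000) <= 5).all()


def test_pair_spanning_adjacent_fragments_links_their_contigs():
    from polyasm import collect_links

    cfg = small_cfg(n_chimeras=0)
    truth = simulate_truth(cfg)
    draft, truth = make_draft_with_chimeras(truth, cfg)
    mp = simulate_mate_pairs(truth, draft, cfg)
    links, _ = collect_links(mp, {n: len(s) for n, s in draft.items()})
    true_adj = set()
    for chrom in truth.chromosomes:
        frs = truth.fragments_of_chrom(chrom)
        for a, b in zip(frs, frs[1:]):
            true_adj.add(frozenset((a.draft_id, b.draft_id)))
    linked = {frozenset((l.contig_a, l.contig_b)) for l in links}
    assert true_adj <= linked


# ---------------------------------------------------------------------------
# long reads
# ---------------------------------------------------------------------------

def test_clean_contig_every_internal_window_spanned():
    cfg = small_cfg(n_chimeras=0, longread_coverage=10.0)
    truth = simulate_truth(cfg)
    draft, truth = make_draft_with_chimeras(truth, cfg)
    lr = simulate_long_read_clips(truth, draft, cfg)
    name, seq = next(iter(sorted(draft.items())))
    sub = lr[lr["contig"] == name]
    for w in range(5_000, len(seq) - 5_000, 5_000):
        cov = ((sub["start"] <= w - 500) & (sub["end"] >= w + 500)).sum()
        assert cov >= 5


def test_each_chimera_junction_collects_clip_cluster(truth_and_draft,
                                                     default_config):
    truth, draft = truth_and_draft
    lr = simulate_long_read_clips(truth, draft, default_config)
    tol = 500
    for ch in truth.chimeras:
        sub = lr[lr["contig"] == ch.draft_id]
        clipped = ((sub["clip_right"] > 0)
                   & (abs(sub["end"] - ch.junction) <= tol)).sum()
        clipped += ((sub["clip_left"] > 0)
                    & (abs(sub["start"] - ch.junction) <= tol)).sum()
        assert clipped >= 3


def test_empty_draft_gives_empty_long_read_table():
    cfg = small_cfg()
    truth = simulate_truth(cfg)
    out = simulate_long_read_clips(truth, {}, cfg)
    assert out.empty


# ---------------------------------------------------------------------------
# Hi-C contacts
# ---------------------------------------------------------------------------

def test_zero_inter_fraction_gives_no_cross_chromosome_contacts():
    cfg = small_cfg(hic_inter_fraction=0.0, n_chimeras=0,
                    n_chromosomes_per_subgenome=2)
    truth = simulate_truth(cfg)
    draft, truth = make_draft_with_chimeras(truth, cfg)
    hc = simulate_contacts(truth, draft, cfg)
    chrom_of = {f.draft_id: f.chrom for f in truth.fragments}
    assert (hc["seq1"].map(chrom_of) == hc["seq2"].map(chrom_of)).all()


def test_contact_frequency_decays_with_distance():
    cfg = small_cfg(n_chimeras=0, n_chromosomes_per_subgenome=1,
                    chromosome_length=1_500_000, fragment_length_mean=2_000_000,
                    n_contacts=50_000)
    truth = simulate_truth(cfg)
    draft, truth = make_draft_with_chimeras(truth, cfg)
    hc = simulate_contacts(truth, draft, cfg)
    intra = hc[hc["seq1"] == hc["seq2"]]
    d = (intra["pos1"] - intra["pos2"]).abs()
    near = ((d >= 5_000) & (d < 15_000)).sum()
    far = ((d >= 995_000) & (d < 1_005_000)).sum()
    assert near > far


def test_contacts_deterministic(truth_and_draft, default_config):
    truth, draft = truth_and_draft
    a = simulate_contacts(truth, draft, default_config)
    b = simulate_contacts(truth, draft, default_config)
    pd.testing.assert_frame_equal(a, b)
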