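"""Simulator: fixture construction, cut-site model, ligation sampling,
library rendering, and the ground-truth guarantees downstream tests rely on."""

import numpy as np
import pytest
from scipy import stats

from mccu import (
    ContactModel,
    build_fixture,
    layout_nucleosome_array,
    render_sequencing_library,
    simulate_ligation_events,
)
from mccu.seq import revcomp
from mccu.synthetic import (
    CORE_HALF,
    FLANK_WEIGHT,
    SimulatedMolecule,
    cut_weights,
    pair_weight_marginal,
    truth_junction_set,
)


@pytest.mark.parametrize(
    "n,repeat,span", [(16, 190, 3040), (1, 190, 190), (10, 185, 1850)]
)
def test_nucleosome_array_span(n, repeat, span):
    dyads, total = layout_nucleosome_array(n, repeat)
    assert total == span
    assert len(dyads) == n
    assert dyads[0] == repeat // 2
    if n > 1:
        assert all(b - a == repeat for a, b in zip(dyads, dyads[1:]))


def test_nucleosome_array_rejects_bad_input():
    with pytest.raises(ValueError):
        layout_nucleosome_array(0, 190)
    with pytest.raises(ValueError):
        layout_nucleosome_array(4, 150)


def test_fixture_tiles_nucleosomes_at_repeat_length():
    fx = build_fixture(10000, 190, seed=0)
    assert len(fx.nucleosomes) == 10000 // 190  # 52


def test_fixture_excludes_dyads_from_ndrs():
    fx = build_fixture(6000, 190, ndrs=[(2900, 3100)], seed=0)
    assert all(not (2900 <= n.dyad < 3100) for n in fx.nucleosomes)
    # the whole 147-bp core stays clear of the NDR
    for n in fx.nucleosomes:
        assert n.dyad + CORE_HALF + 1 <= 2900 or n.dyad - CORE_HALF >= 3100


def test_fixture_is_reproducible():
    a = build_fixture(5000, 190, ndrs=[(2000, 2200)], seed=7)
    b = build_fixture(5000, 190, ndrs=[(2000, 2200)], seed=7)
    assert a.sequence == b.sequence
    assert a.nucleosomes == b.nucleosomes
    assert a.ndrs == b.ndrs


def test_fixture_validation():
    with pytest.raises(ValueError, match="overlap"):
        build_fixture(5000, 190, ndrs=[(1000, 1500), (1400, 1800)])
    with pytest.raises(ValueError, match="repeat_length"):
        build_fixture(5000, 150)
    with pytest.raises(ValueError):
        build_fixture(500, 190)


def test_cut_weights_respect_protection():
    fx = build_fixture(
        6000, 190, ndrs=[(2000, 2400)], tf_footprints=[((2100, 2120), "TF")], seed=3
    )
    w = cut_weights(fx)
    for n in fx.nucleosomes:
        assert np.all(w[n.dyad - CORE_HALF : n.dyad + CORE_HALF + 1] == 0)
    assert np.all(w[2100:2120] == 0)  # footprint interior protected
    assert np.all(w[2095:2100] == FLANK_WEIGHT)
    assert np.all(w[2120:2125] == FLANK_WEIGHT)
    assert np.all(w[2400:2460][w[2400:2460] > 0] >= 0)  # finite, nonnegative


def test_contact_model_validation():
    with pytest.raises(ValueError):
        ContactModel(ndr_pair_factor=0.5).validate()
    with pytest.raises(ValueError):
        ContactModel(background_rate=-1).validate()


def test_single_event_yields_one_truth_record(fixture12k, default_model):
    mols = simulate_ligation_events(fixture12k, default_model, 1, seed=0)
    assert len(mols) == 1
    assert 1 <= len(mols[0].junctions) <= 2


def test_simulation_is_deterministic(fixture12k, default_model):
    a = simulate_ligation_events(fixture12k, default_model, 50, seed=5)
    b = simulate_ligation_events(fixture12k, default_model, 50, seed=5)
    assert [m.sequence for m in a] == [m.sequence for m in b]
    assert [m.junctions for m in a] == [m.junctions for m in b]


def test_molecule_pieces_match_reference(fixture12k, default_model):
    """Every fragment of every simulated molecule is an exact (strand-aware)
    substring of the fixture at its recorded coordinates."""
    mols = simulate_ligation_events(fixture12k, default_model, 300, seed=9)
    seq = fixture12k.sequence
    for m in mols:
        off = 0
        for gs, ge, strand in m.pieces:
            expect = seq[gs:ge] if strand == "+" else revcomp(seq[gs:ge])
            assert m.sequence[off : off + (ge - gs)] == expect
            off += ge - gs


def test_truth_junction_context_matches_fixture(fixture12k, default_model):
    """Spec of the truth record: the +/-20-bp sequence context around each
    junction locates the recorded coordinates exactly in the fixture."""
    mols = simulate_ligation_events(fixture12k, default_model, 300, seed=13)
    seq = fixture12k.sequence

    def left_candidates(pos):
        return {seq[pos - 19 : pos + 1], revcomp(seq[pos : pos + 20])}

    def right_candidates(pos):
        return {seq[pos : pos + 20], revcomp(seq[pos - 19 : pos + 1])}

    checked = 0
    for m in mols:
        for j in m.junctions:
            t = j.read_offset
            if t < 20 or t + 20 > len(m.sequence):
                continue
            left = m.sequence[t - 20 : t]
            right = m.sequence[t : t + 20]
            assert left in left_candidates(j.pos_a) | left_candidates(j.pos_b)
            assert right in right_candidates(j.pos_a) | right_candidates(j.pos_b)
            checked += 1
    assert checked > 200


def test_ndr_pair_enrichment_vs_distance_matched_control():
    """With a strong NDR-pair factor, junctions joining the two NDRs vastly
    outnumber junctions joining distance-matched nucleosomal control windows."""
    fx = build_fixture(12000, 190, ndrs=[(4000, 4300), (7000, 7300)], seed=11)
    model = ContactModel(ndr_pair_factor=50.0)
    mols = simulate_ligation_events(fx, model, 50000, seed=31)

    def pair_count(w1, w2):
        n = 0
        for m in mols:
            for j in m.junctions:
                a, b = j.pos_a, j.pos_b
                if (w1[0] <= a < w1[1] and w2[0] <= b < w2[1]) or (
                    w2[0] <= a < w2[1] and w1[0] <= b < w1[1]
                ):
                    n += 1
        return n

    k_ndr = pair_count((4000, 4300), (7000, 7300))
    k_ctl = pair_count((5000, 5300), (8000, 8300))  # same widths, same separation
    res = stats.binomtest(k_ndr, k_ndr + k_ctl, 0.5, alternative="greater")
    assert res.pvalue < 0.01


def test_ndr_fraction_monotone_in_pair_factor(fixture12k):
    """Expected NDR x NDR junction fraction increases with the pair factor."""
    fracs = []
    for factor in (1.0, 10.0, 50.0):
        model = ContactModel(ndr_pair_factor=factor)
        mols = simulate_ligation_events(fixture12k, model, 50000, seed=41)
        in_ndr = lambda p: any(s <= p < e for s, e in fixture12k.ndrs)
        tot = hit = 0
        for m in mols:
            for j in m.junctions:
                tot += 1
                if in_ndr(j.pos_a) and in_ndr(j.pos_b):
                    hit += 1
        fracs.append(hit / tot)
    assert fracs[0] < fracs[1] < fracs[2]


def test_background_junction_marginal_matches_model():
    """Background-only sampling: per-linker junction-end counts agree with
    the exact model marginal (multinomial goodness-of-fit oracle)."""
    fx = build_fixture(10000, 190, seed=17)
    model = ContactModel(
        within_domain_factor=1.0, ndr_pair_factor=1.0, ctcf_pair_factor=1.0
    )
    mols = simulate_ligation_events(fx, model, 10000, seed=18, third_fragment_prob=0.0)
    positions, marg = pair_weight_marginal(fx, model)

    # group candidate positions into linkers (runs of consecutive candidates)
    breaks = np.flatnonzero(np.diff(positions) > 1) + 1
    groups = np.split(np.arange(len(positions)), breaks)

    obs = np.zeros(len(positions))
    pos_index = {int(p): i for i, p in enumerate(positions)}
    n_ends = 0
    for m in mols:
        for j in m.junctions:
            for p, d in ((j.pos_a, j.dir_a), (j.pos_b, j.dir_b)):
                cut = p + 1 if d == "U" else p  # recover the cut boundary
                i = pos_index.get(int(cut))
                if i is not None:
                    obs[i] += 1
                    n_ends += 1
    assert n_ends > 18000  # nearly all ends map back to candidate cut sites
    z = []
    for g in groups:
        pg = marg[g].sum()
        e = n_ends * pg
        sd = np.sqrt(n_ends * pg * (1 - pg))
        z.append((obs[g].sum() - e) / sd)
    z = np.abs(np.array(z))
    assert np.sum(z > 3) <= 1 and np.all(z < 4.5)


def test_rejects_zero_weight_model(fixture12k):
    with pytest.raises(ValueError):
        simulate_ligation_events(fixture12k, ContactModel(background_rate=0.0), 10)


# ---------------------------------------------------------------------------
# sequencing-library rendering


def test_short_molecule_gives_identity_read_pair(fixture12k):
    frag = fixture12k.sequence[1000:1150]  # exactly read length
    mol = SimulatedMolecule(0, frag, [(1000, 1150, "+")], [])
    r1, r2, truth = render_sequencing_library([mol], seed=0)
    assert len(r1) == 1
    assert r1[0][1] == frag
    assert r2[0][1] == revcomp(frag)


def test_render_is_deterministic(library10k, fixture12k, default_model):
    mols = simulate_ligation_events(fixture12k, default_model, 100, seed=3)
    a = render_sequencing_library(mols, seed=9)
    b = render_sequencing_library(mols, seed=9)
    assert a[0] == b[0] and a[1] == b[1]
    assert a[2].equals(b[2])


def test_render_conservation(library10k):
    _, r1, r2, truth = library10k
    assert len(r1) == len(r2) == len(truth)  # one pair per fragment
    assert truth["read_id"].is_unique


def test_render_validation(fixture12k):
    mol = SimulatedMolecule(0, fixture12k.sequence[:500], [(0, 500, "+")], [])
    with pytest.raises(ValueError):
        render_sequencing_library([mol], error_rate=0.5)
    with pytest.raises(ValueError):
        render_sequencing_library([mol], read_length=30)
    with pytest.raises(ValueError):
        render_sequencing_library([mol], mean_fragment=60, read_length=150)


def test_duplication_rate_re_emits_fragments(fixture12k, default_model):
    mols = simulate_ligation_events(fixture12k, default_model, 200, seed=4)
    r1_plain, _, _ = render_sequencing_library(mols, seed=5)
    r1_dup, _, truth = render_sequencing_library(mols, duplication_rate=0.5, seed=5)
    assert len(r1_dup) > len(r1_plain) * 1.3
    dups = [r for r in truth["read_id"] if "D" in r.split("F")[1]]
    assert dups


def test_sequencing_errors_are_substitutions_only(fixture12k, default_model):
    mols = simulate_ligation_events(fixture12k, default_model, 100, seed=6)
    r1a, _, _ = render_sequencing_library(mols, error_rate=0.0, seed=7)
    r1b, _, _ = render_sequencing_library(mols, error_rate=0.05, seed=7)
    assert all(len(a[1]) == len(b[1]) for a, b in zip(r1a, r1b))
    diffs = sum(
        sum(x != y for x, y in zip(a[1], b[1])) for a, b in zip(r1a, r1b)
    )
    total = sum(len(a[1]) for a in r1a)
    assert 0.02 < diffs / total < 0.08


def test_truth_table_flags_destroyed_junctions(library10k):
    _, _, _, truth = library10k
    flat = ";".join(s for s in truth["junctions"] if s)
    assert "|0" in flat and "|1" in flat  # both survived and destroyed occur
    surv = truth_junction_set(truth, survived_only=True)
    allj = truth_junction_set(truth, survived_only=False)
    assert surv < allj
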