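"""Dissection: match gate, DP optimality against exhaustive enumeration,
additivity, and report writers."""

import json
import math

import numpy as np
import pytest

from foldict.codec import (CodeSpec, dictionary_len, null_tableau_len,
                           uniform_angle_len, von_mises_angle_len)
from foldict.dictionary import Dictionary, extract_candidate
from foldict.dissection import (INVALID, brute_force_dissect, dissect,
                                match_cost, total_collection_len,
                                write_dissection_report)
from foldict.synthetic import SynthParams, make_benchmark
from foldict.tableau import Tableau, wrap_angle

from conftest import make_random_dictionary, make_random_tableau


# ---------------------------------------------------------------------------
# match_cost
# ---------------------------------------------------------------------------

def _self_concept(t, span, spec, kappa=None):
    return extract_candidate(t, span, spec, concept_id="c_0001", kappa=kappa)


def test_exact_match_with_high_kappa_beats_null(spec):
    rng = np.random.default_rng(31)
    for _ in range(20):
        t = make_random_tableau(rng, spec, n_min=4, n_max=7)
        try:
            c = _self_concept(t, (1, 3), spec, kappa=spec.kappa_grid[-1])
        except ValueError:
            continue
        mc = match_cost(t, (1, 3), c, spec)
        assert mc is not INVALID
        # null coding of the same cells: KT-cost varies, but angles alone
        # dominate: uniform per contacting pair vs ~0 for delta=0, huge kappa
        n_pairs = int(np.count_nonzero(np.triu(t.contacts[:3, :3], 1)))
        if n_pairs:
            assert mc < n_pairs * uniform_angle_len(spec)


def test_missing_archetype_contact_invalidates(spec):
    t = _make_chain_tableau("HEHE", [(0, 1), (1, 2), (2, 3)], spec)
    c = _self_concept(t, (1, 4), spec)
    t2 = Tableau(id="t2", sse_string=t.sse_string,
                 contacts=np.zeros_like(t.contacts), angles=t.angles)
    assert match_cost(t2, (1, 4), c, spec) is INVALID


def test_sse_mismatch_invalidates(spec):
    t = _make_chain_tableau("HH", [(0, 1)], spec)
    c = _self_concept(t, (1, 2), spec)
    t2 = _make_chain_tableau("HE", [(0, 1)], spec)
    assert match_cost(t2, (1, 2), c, spec) is INVALID


def _make_chain_tableau(sse, pairs, spec, angle=45.5):
    n = len(sse)
    contacts = np.zeros((n, n), dtype=bool)
    angles = np.zeros((n, n), dtype=float)
    for i, j in pairs:
        contacts[i, j] = contacts[j, i] = True
        angles[i, j] = angles[j, i] = angle
    return Tableau(id="chain", sse_string=sse, contacts=contacts,
                   angles=angles)


def _straight_line_match_cost(t, span, c, spec):
    """Independent re-implementation of the concept region cost."""
    a = span[0] - 1
    arch = c.archetype
    nc = arch.n
    if t.sse_string[a:a + nc] != arch.sse_string:
        return INVALID
    cost = 0.0
    for i in range(nc):
        for j in range(i + 1, nc):
            tc = bool(t.contacts[a + i, a + j])
            ac = bool(arch.contacts[i, j])
            if ac and not tc:
                return INVALID
            cost += -math.log2(spec.flip_prob) if (tc != ac) \
                else -math.log2(1 - spec.flip_prob)
            if tc:
                if ac:
                    cost += von_mises_angle_len(
                        wrap_angle(t.angles[a + i, a + j] - arch.angles[i, j]),
                        c.kappa, spec)
                else:
                    cost += uniform_angle_len(spec)
    return cost


def test_match_cost_agrees_with_straight_line_reimplementation(spec):
    rng = np.random.default_rng(32)
    checked = 0
    while checked < 200:
        t = make_random_tableau(rng, spec, n_min=3, n_max=8)
        src = make_random_tableau(rng, spec, n_min=3, n_max=8,
                                  tableau_id="src")
        a = int(rng.integers(1, src.n))
        b = int(rng.integers(a + 1, src.n + 1))
        try:
            c = extract_candidate(
                src, (a, b), spec,
                kappa=spec.kappa_grid[int(rng.integers(65))])
        except ValueError:
            continue
        if c.n > t.n:
            continue
        start = int(rng.integers(1, t.n - c.n + 2))
        span = (start, start + c.n - 1)
        got = match_cost(t, span, c, spec)
        want = _straight_line_match_cost(t, span, c, spec)
        if want is INVALID:
            assert got is INVALID
        else:
            assert got is not INVALID and np.isclose(got, want, atol=1e-9)
        checked += 1


# ---------------------------------------------------------------------------
# DP vs brute force
# ---------------------------------------------------------------------------

def test_empty_dictionary_gives_all_null_at_null_length(spec):
    rng = np.random.default_rng(33)
    E = Dictionary(spec=spec)
    for _ in range(10):
        t = make_random_tableau(rng, spec, n_min=0, n_max=8)
        d = dissect(t, E, spec)
        assert all(r.is_null for r in d.regions)
        assert len(d.regions) == t.n
        assert np.isclose(d.total_bits.bits, null_tableau_len(t, spec).bits,
                          atol=1e-9)


def test_archetype_tableau_collapses_to_single_region(spec):
    params = SynthParams(n_tableaux=1, sse_range=(4, 4), plant_fraction=1.0,
                         seed=40, spec=spec)
    coll, truth = make_benchmark(params)
    t = coll[0]
    C = Dictionary(concepts=[truth.motif], spec=spec)
    d = dissect(t, C, spec)
    assert len(d.regions) == 1
    assert d.regions[0].concept_id == truth.motif.id
    E = Dictionary(spec=spec)
    assert d.total_bits.bits < dissect(t, E, spec).total_bits.bits


def test_dp_equals_brute_force_on_random_instances(spec):
    rng = np.random.default_rng(34)
    for _ in range(60):
        coll = [make_random_tableau(rng, spec, n_min=2, n_max=8,
                                    tableau_id=f"s{i}") for i in range(3)]
        C = make_random_dictionary(rng, spec, coll, max_concepts=4)
        t = make_random_tableau(rng, spec, n_min=0, n_max=8)
        d1 = dissect(t, C, spec)
        d2 = brute_force_dissect(t, C, spec)
        assert abs(d1.total_bits.bits - d2.total_bits.bits) < 1e-9
        assert [(r.span, r.concept_id) for r in d1.regions] == \
            [(r.span, r.concept_id) for r in d2.regions]


def test_brute_force_refuses_large_instances(spec):
    rng = np.random.default_rng(35)
    t = make_random_tableau(rng, spec, n_min=13, n_max=13)
    with pytest.raises(ValueError, match="n <= 12"):
        brute_force_dissect(t, Dictionary(spec=spec), spec)


def test_spans_tile_the_tableau(spec):
    rng = np.random.default_rng(36)
    for _ in range(30):
        coll = [make_random_tableau(rng, spec, n_min=2, n_max=8,
                                    tableau_id=f"s{i}") for i in range(3)]
        C = make_random_dictionary(rng, spec, coll, max_concepts=4)
        t = make_random_tableau(rng, spec, n_min=1, n_max=8)
        d = dissect(t, C, spec)
        covered = []
        for r in d.regions:
            covered.extend(range(r.span[0], r.span[1] + 1))
        assert covered == list(range(1, t.n + 1))


def test_total_bits_breakdown_sums(spec):
    rng = np.random.default_rng(37)
    coll = [make_random_tableau(rng, spec, n_min=2, n_max=8,
                                tableau_id=f"s{i}") for i in range(3)]
    C = make_random_dictionary(rng, spec, coll, max_concepts=3)
    t = make_random_tableau(rng, spec, n_min=4, n_max=8)
    d = dissect(t, C, spec)
    assert np.isclose(d.total_bits.bits, sum(d.total_bits.breakdown.values()),
                      atol=1e-9)


def test_adding_concept_bounded_by_label_cost_change(spec):
    """Growing the dictionary can only inflate a tableau's dissected length
    through the label-cost change: the old segmentation stays available, so
    total(C + c) <= total(C) + n * (log2(|C|+2) - log2(|C|+1))."""
    rng = np.random.default_rng(45)
    checked = 0
    while checked < 30:
        coll = [make_random_tableau(rng, spec, n_min=2, n_max=8,
                                    tableau_id=f"s{i}") for i in range(3)]
        C = make_random_dictionary(rng, spec, coll, max_concepts=3)
        extra = make_random_dictionary(rng, spec, coll, max_concepts=1)
        if not extra.concepts:
            continue
        c = extra.concepts[0]
        bigger = Dictionary(concepts=list(C.concepts) + [c], spec=spec)
        t = make_random_tableau(rng, spec, n_min=1, n_max=8)
        old = dissect(t, C, spec).total_bits.bits
        new = dissect(t, bigger, spec).total_bits.bits
        dlabel = math.log2(len(C.concepts) + 2) - math.log2(len(C.concepts) + 1)
        assert new <= old + t.n * dlabel + 1e-9
        checked += 1


# ---------------------------------------------------------------------------
# Collection totals
# ---------------------------------------------------------------------------

def test_total_collection_len_empty_dictionary(spec):
    rng = np.random.default_rng(38)
    coll = [make_random_tableau(rng, spec, n_min=2, n_max=7,
                                tableau_id=f"s{i}") for i in range(5)]
    E = Dictionary(spec=spec)
    total = total_collection_len(coll, E, spec)
    null_sum = sum(null_tableau_len(t, spec).bits for t in coll)
    assert np.isclose(total.bits, 1.0 + null_sum, atol=1e-9)


def test_two_part_additivity(spec):
    rng = np.random.default_rng(39)
    for _ in range(10):
        coll = [make_random_tableau(rng, spec, n_min=2, n_max=8,
                                    tableau_id=f"s{i}") for i in range(4)]
        C = make_random_dictionary(rng, spec, coll, max_concepts=4)
        total = total_collection_len(coll, C, spec)
        expected = dictionary_len(C, spec).bits + sum(
            dissect(t, C, spec).total_bits.bits for t in coll)
        assert np.isclose(total.bits, expected, atol=1e-6)


def test_planted_motif_dictionary_has_positive_gain(spec):
    from foldict.search import compression_gain
    params = SynthParams(n_tableaux=20, sse_range=(5, 8), seed=41, spec=spec)
    coll, truth = make_benchmark(params)
    C = Dictionary(concepts=[truth.motif], spec=spec)
    assert compression_gain(coll, C, spec) > 0
    E = Dictionary(spec=spec)
    assert np.isclose(compression_gain(coll, E, spec), -1.0, atol=1e-9)


# ---------------------------------------------------------------------------
# Reports
# ---------------------------------------------------------------------------

def test_empty_dissection_report(spec):
    t = Tableau(id="empty", sse_string="")
    d = dissect(t, Dictionary(spec=spec), spec)
    markup, js, fasta = write_dissection_report(d, sequence="",
                                                sse_residue_spans=[])
    assert fasta == ""
    assert js["regions"] == []


def test_two_region_report_fasta_spans(spec):
    params = SynthParams(n_tableaux=1, sse_range=(5, 5), plant_fraction=1.0,
                         seed=42, spec=spec)
    coll, truth = make_benchmark(params)
    t = coll[0]
    C = Dictionary(concepts=[truth.motif], spec=spec)
    d = dissect(t, C, spec)
    seq = "ACDEFGHIKLMNPQRSTVWYACDEF"
    spans = [(1 + 5 * i, 5 + 5 * i) for i in range(t.n)]
    markup, js, fasta = write_dissection_report(d, sequence=seq,
                                                sse_residue_spans=spans)
    records = [r for r in fasta.split(">") if r]
    assert len(records) == len(d.regions)
    for rec, reg in zip(records, d.regions):
        header, body = rec.split("\n")[:2]
        tid, cid, rspan = header.split("|")
        assert cid == reg.concept_id
        lo, hi = map(int, rspan.split("-"))
        assert body == seq[lo - 1:hi]


def test_report_rejects_inconsistent_spans(spec):
    rng = np.random.default_rng(43)
    t = make_random_tableau(rng, spec, n_min=3, n_max=3)
    d = dissect(t, Dictionary(spec=spec), spec)
    with pytest.raises(ValueError, match="outside sequence"):
        write_dissection_report(d, sequence="ACD",
                                sse_residue_spans=[(1, 2), (3, 9), (10, 12)])


def test_dissection_json_round_trip(tmp_path, spec):
    rng = np.random.default_rng(44)
    coll = [make_random_tableau(rng, spec, n_min=3, n_max=8,
                                tableau_id=f"s{i}") for i in range(3)]
    C = make_random_dictionary(rng, spec, coll, max_concepts=3)
    d = dissect(coll[0], C, spec)
    js = d.to_json_dict()
    p = tmp_path / "d.json"
    p.write_text(json.dumps(js))
    back = json.loads(p.read_text())
    assert back == js
    assert np.isclose(back["total_bits"], d.total_bits.bits, atol=1e-5)
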