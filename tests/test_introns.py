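import random

import numpy as np
import pytest

from oracles import random_dna
from spliceagree.introns import (b_reducible, classify_intron, extract_introns,
                                 reduce_introns)
from spliceagree.params import Parameters
from spliceagree.simulate import perturb_junctions
from spliceagree.spliced_alignment import (AlignedFactor, Composition,
                                           edit_distance)


@pytest.mark.parametrize(
    "donor,acceptor,pattern,u_type",
    [
        ("GT", "AG", "GT-AG", "U2"),
        ("GC", "AG", "GC-AG", "U2"),
        ("AT", "AC", "AT-AC", "U12"),
        ("CT", "TG", "other", "unclassified"),
        ("GT", "AC", "other", "unclassified"),
    ],
)
def test_classify_intron(donor, acceptor, pattern, u_type):
    assert classify_intron(donor, acceptor) == (pattern, u_type)


def _exact_comp(tid, P, T, intervals):
    """Composition whose factors tile P over the given genomic intervals."""
    factors = []
    p = 0
    for s, e in intervals:
        length = e - s
        factors.append(AlignedFactor(
            p, p + length, s, e, edit_distance(P[p:p + length], T[s:e])))
        p += length
    return Composition(tid, tuple(factors), sum(f.edit for f in factors))


class TestExtractIntrons:
    def test_coordinates_and_dinucleotides(self):
        rng = random.Random(0)
        T = random_dna(rng, 300)
        comp = _exact_comp("a", T[0:100] + T[200:300], T, [(0, 100), (200, 300)])
        (rec,) = extract_introns({"a": comp}, T)
        assert (rec.t_start, rec.t_end) == (100, 200)
        assert rec.donor == T[100:102] and rec.acceptor == T[198:200]
        assert rec.supports == [("a", 0)]

    def test_shared_junction_aggregates_supports(self):
        rng = random.Random(1)
        T = random_dna(rng, 300)
        P = T[0:100] + T[200:300]
        comps = {t: _exact_comp(t, P, T, [(0, 100), (200, 300)])
                 for t in ("a", "NM_b")}
        (rec,) = extract_introns(comps, T, refseq_ids={"NM_b"})
        assert len(rec.supports) == 2 and rec.refseq_supported

    def test_single_factor_compositions_yield_nothing(self):
        rng = random.Random(2)
        T = random_dna(rng, 100)
        comp = _exact_comp("a", T[10:90], T, [(10, 90)])
        assert extract_introns({"a": comp}, T) == []


def _planted(rng, shift=0, b_params=None):
    """Genome with one GT-AG intron; composition optionally mis-placed.

    Exon bases flanking the junction are fixed so that no zero-cost
    alternative placement exists.
    """
    params = b_params or Parameters()
    exon1 = random_dna(rng, 79) + "C"
    exon2 = "A" + random_dna(rng, 79)
    intron = "GT" + random_dna(rng, 96) + "AG"
    T = exon1 + intron + exon2
    P = exon1 + exon2
    s, e = 80, 180
    comp = _exact_comp("a", P, T, [(0, s + shift), (e + shift, len(T))])
    return params, P, T, comp, (s, e)


class TestBReducible:
    def test_zero_shift_is_always_reducible(self):
        rng = random.Random(3)
        params, P, T, comp, true_iv = _planted(rng)
        ok, pair = b_reducible(comp, 0, true_iv, 0, P, T, params)
        assert ok and pair == (comp.factors[0], comp.factors[1])

    def test_spurious_call_shifts_back_to_truth(self):
        rng = random.Random(4)
        params, P, T, comp, true_iv = _planted(rng, shift=2)
        assert comp.total_edit <= 4  # mis-placed boundaries cost a little
        ok, pair = b_reducible(comp, 0, true_iv, 2 + comp.total_edit, P, T, params)
        assert ok
        assert (pair[0].t_end, pair[1].t_start) == true_iv
        assert pair[0].edit + pair[1].edit == 0

    def test_budget_zero_rejects_costly_shift(self):
        rng = random.Random(5)
        params, P, T, comp, true_iv = _planted(rng)
        # target shifted by 1 from the truth: re-alignment must add errors
        target = (true_iv[0] + 1, true_iv[1] + 1)
        ok, pair = b_reducible(comp, 0, target, 0, P, T, params)
        assert not ok and pair is None


def _pipeline_state(rng_seed, n_est=6):
    """Planted two-intron gene with a RefSeq and several exact ESTs."""
    rng = random.Random(rng_seed)
    exons = [random_dna(rng, 90) for _ in range(3)]
    introns = ["GT" + random_dna(rng, 80) + "AG" for _ in range(2)]
    T = exons[0] + introns[0] + exons[1] + introns[1] + exons[2]
    ivs = [(90, 174), (264, 348)]
    P = "".join(exons)
    tiling = [(0, 90), (174, 264), (348, 438)]
    chosen = {"NM_ref": _exact_comp("NM_ref", P, T, tiling)}
    for i in range(n_est):
        chosen[f"EST_{i}"] = _exact_comp(f"EST_{i}", P, T, tiling)
    p_map = {tid: P for tid in chosen}
    return T, P, chosen, p_map, ivs


class TestReduceIntrons:
    def test_noncanonical_near_refseq_intron_is_merged(self):
        params = Parameters()
        T, P, chosen, p_map, ivs = _pipeline_state(6)
        np_rng = np.random.default_rng(0)
        perturbed, moved = perturb_junctions(
            chosen, p_map, T, fraction=0.5, max_shift=3, rng=np_rng,
            refseq_ids={"NM_ref"})
        assert moved, "perturbation produced no shifted junctions"
        before = extract_introns(perturbed, T, {"NM_ref"})
        assert any(r.pattern == "other" for r in before)
        after, fixed = reduce_introns(before, perturbed, p_map, T, params,
                                      {"NM_ref"})
        assert sorted(r.key() for r in after) == sorted(set(ivs))
        assert all(r.pattern == "GT-AG" for r in after)

    def test_unreachable_target_leaves_record_unchanged(self):
        params = Parameters()
        T, P, chosen, p_map, ivs = _pipeline_state(7, n_est=1)
        # fabricate a junction 30 nt from any trusted intron: outside the
        # b-reducibility shift window, so it must stay where it is
        lone = _exact_comp("EST_far", P, T, [(0, 120), (204, 438)])
        merged = dict(chosen)
        merged["EST_far"] = lone
        pm = dict(p_map)
        pm["EST_far"] = P
        before = extract_introns(merged, T, {"NM_ref"})
        far_before = next(r for r in before if r.t_start == 120)
        assert far_before.pattern == "other"
        after, _ = reduce_introns(before, merged, pm, T, params, {"NM_ref"})
        assert sorted(r.key() for r in after) == sorted(r.key() for r in before)
        assert (sum(len(r.supports) for r in after)
                == sum(len(r.supports) for r in before))

    def test_canonical_introns_never_reduced(self):
        params = Parameters()
        T, P, chosen, p_map, ivs = _pipeline_state(8)
        before = extract_introns(chosen, T, {"NM_ref"})
        assert all(r.pattern == "GT-AG" for r in before)
        after, chosen2 = reduce_introns(before, chosen, p_map, T, params,
                                        {"NM_ref"})
        assert [r.key() for r in after] == [r.key() for r in before]
        assert chosen2 == chosen

    def test_idempotent_and_support_conserving(self):
        params = Parameters()
        T, P, chosen, p_map, ivs = _pipeline_state(9)
        np_rng = np.random.default_rng(1)
        perturbed, moved = perturb_junctions(
            chosen, p_map, T, fraction=0.4, max_shift=3, rng=np_rng,
            refseq_ids={"NM_ref"})
        before = extract_introns(perturbed, T, {"NM_ref"})
        n0 = sum(len(r.supports) for r in before)
        once, chosen1 = reduce_introns(before, perturbed, p_map, T, params,
                                       {"NM_ref"})
        assert sum(len(r.supports) for r in once) == n0
        twice, chosen2 = reduce_introns(once, chosen1, p_map, T, params,
                                        {"NM_ref"})
        assert [r.key() for r in twice] == [r.key() for r in once]
        assert chosen2 == chosen1

    def test_planted_error_recovery_over_replicates(self):
        """Junction calls perturbed by <= 3 nt are all restored exactly."""
        params = Parameters()
        restored = total = 0
        for seed in range(20):
            T, P, chosen, p_map, ivs = _pipeline_state(100 + seed)
            np_rng = np.random.default_rng(seed)
            perturbed, moved = perturb_junctions(
                chosen, p_map, T, fraction=0.15, max_shift=3, rng=np_rng,
                refseq_ids={"NM_ref"})
            before = extract_introns(perturbed, T, {"NM_ref"})
            after, _ = reduce_introns(before, perturbed, p_map, T, params,
                                      {"NM_ref"})
            keys = {r.key() for r in after}
            total += len(moved)
            restored += sum(1 for _tid, _j, iv in moved if iv in keys)
            assert keys == set(ivs)
        assert total > 0 and restored == total
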