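"""Hairpin stem enumeration, register shifts and the design filter."""

import pytest
from hypothesis import given, strategies as st

from rnaexcite import pop_from_dG
from rnaexcite.design import (
    STRONG_PAIRS,
    BasePair,
    EnergyBackend,
    HairpinSpec,
    NearestNeighborBackend,
    StemCandidate,
    alternative_ddGs,
    classify_pair,
    design_filter,
    enumerate_stems,
    register_shift,
    score_candidate,
)
from rnaexcite.nn_params import hairpin_loop_dg, stack_dg

from oracles import naive_enumerate, naive_type1_es


class TestClassifyPair:
    @pytest.mark.parametrize("pair,klass", [
        ("GC", "strong"), ("AU", "strong"), ("GU", "strong"), ("UG", "strong"),
        ("GA", "weak"), ("AG", "weak"), ("GG", "weak"), ("UU", "weak"),
        ("CU", "other"), ("AA", "other"), ("CC", "other"),
    ])
    def test_classification_rules(self, pair, klass):
        assert classify_pair(pair) == klass

    def test_rejects_non_rna_bases(self):
        with pytest.raises(ValueError):
            classify_pair("GT")
        with pytest.raises(ValueError):
            BasePair("X", "A")


class TestRegisterShift:
    def test_zero_shift_is_identity(self):
        gs = tuple(BasePair.from_str(s) for s in ("GC", "AU", "UA"))
        es, displaced = register_shift(gs, 0)
        assert es == gs and displaced == ()

    def test_toy_stem_matches_hand_enumeration(self):
        stem = ["GC", "GU", "AU"]  # loop -> terminal
        es, displaced = register_shift(stem, "type1", five_prime_context=("G",))
        assert [p.as_str for p in es] == naive_type1_es(stem, "G")
        # the loop-adjacent 5' base joins the loop (tetraloop -> pentaloop)
        assert ("G", "5p", "loop") in displaced

    def test_opposite_shifts_restore_interior_pairs(self):
        gs = tuple(BasePair.from_str(s) for s in ("GC", "AU", "UA", "CG"))
        es, _ = register_shift(gs, +1, five_prime_context=("G",))
        back, _ = register_shift(es, -1, three_prime_context=("A",))
        assert back[:-1] == gs[1:]

    def test_shift_exceeding_stem_rejected(self):
        with pytest.raises(ValueError, match="exceeds stem length"):
            register_shift(("GC",), 2)

    @given(
        st.lists(st.sampled_from(STRONG_PAIRS), min_size=2, max_size=6),
        st.sampled_from([+1, -1, +2]),
    )
    def test_nucleotide_content_is_conserved(self, stem, shift):
        ctx5 = ("G", "G")
        ctx3 = ("A",)
        es, displaced = register_shift(stem, shift, ctx5, ctx3)
        into = sorted(
            [b for p in stem for b in p]
            + list(ctx5[: max(shift, 0)])
            + list(ctx3 if shift > 0 else ctx3[: -shift])
            + (list(ctx5) if shift < 0 else [])
        )
        out = sorted(
            [b for p in es for b in (p.five_prime_base, p.three_prime_base)]
            + [b for b, _, _ in displaced]
        )
        assert into == out


class TestEnumeration:
    def test_unconstrained_strong_library_size(self):
        spec = HairpinSpec(stem_len=5)
        assert len(enumerate_stems(spec, constraints=("strong",))) == 6**5

    def test_single_position_stem(self):
        spec = HairpinSpec(stem_len=1, shift_mode="type1")
        assert len(enumerate_stems(spec, constraints=("strong",))) == 6

    def test_matches_naive_oracle_on_short_stems(self):
        spec = HairpinSpec(stem_len=3, shift_mode="type1",
                           closing_mismatch=("G", "A"))
        got = [tuple(p.as_str for p in c.gs_pairs) for c in enumerate_stems(spec)]
        expected = naive_enumerate(3, "loop", ("G", "A"))
        assert got == expected

    def test_enumeration_order_is_lexicographic(self):
        spec = HairpinSpec(stem_len=2)
        combos = [tuple(p.as_str for p in c.gs_pairs)
                  for c in enumerate_stems(spec, constraints=("strong",))]
        assert combos == sorted(combos)

    def test_gu_only_triplet_switch_is_weaker(self):
        spec = HairpinSpec(stem_len=4)
        full = enumerate_stems(spec, constraints=("triplet",))
        gu_only = enumerate_stems(spec, constraints=("triplet",),
                                  gu_only_triplets=True)
        assert len(gu_only) >= len(full)


class TestScoring:
    def make_candidate(self, gs, es, displaced=()):
        spec = HairpinSpec(stem_len=len(gs))
        return StemCandidate(
            spec=spec,
            gs_pairs=tuple(BasePair.from_str(p) for p in gs),
            es_pairs=tuple(BasePair.from_str(p) for p in es),
            displaced=tuple(displaced),
            triplet_signatures=(),
        )

    def test_identical_structures_score_zero(self):
        c = self.make_candidate(["GC", "CG", "GC"], ["GC", "CG", "GC"])
        assert score_candidate(c) == pytest.approx(0.0)

    def test_single_pair_swap_equals_tabulated_stack_difference(self):
        c = self.make_candidate(["GC", "CG", "GC"], ["GC", "CG", "GU"])
        expected = stack_dg("CG", "GU") - stack_dg("CG", "GC")
        assert score_candidate(c) == pytest.approx(expected)

    def test_more_stable_es_scores_negative_and_flags_inversion(self):
        c = self.make_candidate(["AU", "UA", "AU"], ["GC", "CG", "GC"])
        assert score_candidate(c) < 0.0
        assert c.inverted
        assert design_filter([c], include_scan=False,
                             external_alternatives=[[]]) == []

    def test_loop_growth_penalty_included(self):
        grown = self.make_candidate(
            ["GC", "CG", "GC"], ["GC", "CG", "GC"],
            displaced=(("G", "5p", "loop"),),
        )
        expected = hairpin_loop_dg(5) - hairpin_loop_dg(4)
        assert score_candidate(grown) == pytest.approx(expected)

    def test_disallowed_pair_raises(self):
        backend = NearestNeighborBackend()
        with pytest.raises(ValueError, match="neither strong nor weak"):
            backend.score_structure(["GC", "CC"], 4)

    def test_missing_stack_parameter_names_the_stack(self):
        from rnaexcite.nn_params import stack_dg as lookup
        with pytest.raises(KeyError, match="no stacking parameter"):
            lookup("GC", "XX")


class ToyBackend(EnergyBackend):
    """Deterministic scorer used only for filter-logic tests."""

    name = "toy"

    def score_structure(self, pairs, loop_size):
        score = 0.3 * loop_size
        for p in pairs:
            s = p.as_str if hasattr(p, "as_str") else str(p)
            score += {"strong": -1.5, "weak": 0.8}.get(classify_pair(s), 50.0)
        return score


class TestDesignFilter:
    def test_threshold_is_inclusive(self):
        spec = HairpinSpec(stem_len=2)
        cand = StemCandidate(
            spec=spec,
            gs_pairs=(BasePair.from_str("GC"), BasePair.from_str("AU")),
            es_pairs=(BasePair.from_str("GC"), BasePair.from_str("AU")),
            displaced=(),
            triplet_signatures=(),
            ddG=3.0,
        )
        accepted = design_filter([cand], threshold=3.0,
                                 external_alternatives=[[10.0]],
                                 include_scan=False)
        assert cand in accepted

    def test_better_alternative_rejects_candidate(self):
        spec = HairpinSpec(stem_len=2)
        cand = StemCandidate(
            spec=spec,
            gs_pairs=(BasePair.from_str("GC"), BasePair.from_str("AU")),
            es_pairs=(BasePair.from_str("GC"), BasePair.from_str("AU")),
            displaced=(),
            triplet_signatures=(),
            ddG=2.0,
        )
        accepted = design_filter([cand], threshold=3.0,
                                 external_alternatives=[[1.5]],
                                 include_scan=False)
        assert accepted == [] and cand.rank_ok is False

    def test_matches_brute_force_filter_oracle(self):
        spec = HairpinSpec(stem_len=3)
        cands = enumerate_stems(spec)[:20]
        backend = ToyBackend()
        accepted = design_filter(cands, threshold=3.0, backend=backend)
        # independent re-derivation of the accept/reject decision
        expected = []
        for c in cands:
            ddG = score_candidate(c, backend)
            alts = alternative_ddGs(c, backend)
            if 0.0 <= ddG <= 3.0 and (not alts or ddG <= min(alts)):
                expected.append(c)
        expected.sort(key=lambda c: c.ddG)
        assert accepted == expected

    def test_accepted_designs_reverify_all_constraints(self):
        spec = HairpinSpec(stem_len=4, shift_mode="type1")
        accepted = design_filter(enumerate_stems(spec), threshold=3.0)
        assert accepted, "expected at least one accepted design"
        assert accepted == sorted(accepted, key=lambda c: c.ddG)
        for c in accepted:
            assert all(p.klass == "strong" for p in c.gs_pairs)
            klasses = [p.klass for p in c.es_pairs]
            assert "other" not in klasses
            assert sum(k == "weak" for k in klasses) <= 1
            assert len(set(c.triplet_signatures)) == len(c.triplet_signatures)

    def test_threshold_maps_to_detection_floor_population(self):
        assert 100 * pop_from_dG(3.0, 283.15) == pytest.approx(0.5, abs=0.05)


class TestSpecValidation:
    def test_shift_larger_than_stem_rejected(self):
        with pytest.raises(ValueError, match="exceeds stem"):
            HairpinSpec(stem_len=1, shift_mode="type3")

    def test_sequence_assembly(self):
        spec = HairpinSpec(loop_seq="GCAA", stem_len=2,
                           closing_mismatch=("G", "A"), dangling_5prime="G")
        cand = enumerate_stems(spec, constraints=("strong",))[0]
        seq = cand.sequence()
        assert seq.startswith("GG") and "GCAA" in seq and seq.endswith("A")
        assert len(seq) == 1 + 1 + 2 + 4 + 2 + 1
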