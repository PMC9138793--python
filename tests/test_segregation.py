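"""Segregation engine: strict/slack strata, recessive model, brute-force
set-logic oracles, and the full per-family cascade."""

import itertools

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import famseg
from famseg import (
    FAIL,
    MISSING,
    SLACK_ONLY,
    STRICT,
    GenotypeMatrix,
    SegregationConfig,
    VariantKey,
    is_carrier,
    run_family_cascade,
    segregate_recessive,
    segregate_slack,
    segregate_slack_by_enumeration,
    segregate_strict,
)


def matrix_from_rows(individuals, rows):
    keys = [VariantKey("chr1", 100 + i, "A", "C") for i in range(len(rows))]
    return keys, GenotypeMatrix(keys, individuals, np.array(rows, dtype=np.int8))


F1_IDS = ["FA1", "MO1", "PB1", "SI1A", "SI1B", "SI1C"]
F1_CONFIG = SegregationConfig(
    obligate_carriers=frozenset({"MO1", "PB1"}),
    hard_excluders=frozenset({"FA1"}),
    slack_pool=frozenset({"SI1A", "SI1B", "SI1C"}),
    slack_k=1,
)


def set_logic_oracle(calls, obligates, excluders, pool, k):
    """Direct set-comprehension statement of the filter semantics."""
    carriers = {i for i, ac in calls.items() if ac in (1, 2)}
    if any(calls[i] == MISSING for i in obligates):
        return FAIL
    if not obligates <= carriers:
        return FAIL
    if excluders & carriers:
        return FAIL
    n_pool = len(pool & carriers)
    if n_pool == 0:
        return STRICT
    if n_pool <= k:
        return SLACK_ONLY
    return FAIL


class TestCarrierStatus:
    @pytest.mark.parametrize("ac,carrier", [(0, False), (1, True), (2, True), (MISSING, False)])
    def test_dominant(self, ac, carrier):
        assert is_carrier(ac, "dominant") is carrier

    @pytest.mark.parametrize("ac,carrier", [(0, False), (1, False), (2, True)])
    def test_recessive_requires_homozygosity(self, ac, carrier):
        assert is_carrier(ac, "recessive") is carrier

    def test_hemizygous_male_x_is_carrier(self):
        # male X alt calls are normalized to dosage 2 on read / gene-drop
        assert is_carrier(2, "dominant")


class TestStrictFilter:
    def test_affected_only_pattern_is_strict(self):
        keys, m = matrix_from_rows(F1_IDS, [[0, 1, 1, 0, 0, 0]])
        (o,) = segregate_strict(keys, m, F1_CONFIG)
        assert o.stratum == STRICT and o.slack_carriers_used == 0
        assert o.carriers == frozenset({"MO1", "PB1"})

    def test_father_carriage_disqualifies(self):
        keys, m = matrix_from_rows(F1_IDS, [[1, 1, 1, 0, 0, 0]])
        (o,) = segregate_strict(keys, m, F1_CONFIG)
        assert o.stratum == FAIL and o.reason == "excluder-carrier:FA1"

    def test_missing_obligate_genotype_fails_with_reason(self):
        keys, m = matrix_from_rows(F1_IDS, [[0, MISSING, 1, 0, 0, 0]])
        (o,) = segregate_strict(keys, m, F1_CONFIG)
        assert o.stratum == FAIL and o.reason == "genotype-incomplete:MO1"

    def test_missing_slack_genotype_is_noncarrier_with_warning(self):
        keys, m = matrix_from_rows(F1_IDS, [[0, 1, 1, MISSING, 0, 0]])
        (o,) = segregate_strict(keys, m, F1_CONFIG)
        assert o.stratum == STRICT
        assert "missing-genotype:SI1A" in o.warnings


class TestSlackFilter:
    def test_one_nonpenetrant_sister_is_slack_only(self):
        keys, m = matrix_from_rows(F1_IDS, [[0, 1, 1, 1, 0, 0]])
        (o,) = segregate_slack(keys, m, F1_CONFIG)
        assert o.stratum == SLACK_ONLY and o.slack_carriers_used == 1

    def test_two_sisters_exceed_slack(self):
        keys, m = matrix_from_rows(F1_IDS, [[0, 1, 1, 1, 1, 0]])
        (o,) = segregate_slack(keys, m, F1_CONFIG)
        assert o.stratum == FAIL

    def test_father_remains_hard_excluder_under_slack(self):
        keys, m = matrix_from_rows(F1_IDS, [[1, 1, 1, 1, 0, 0]])
        (o,) = segregate_slack(keys, m, F1_CONFIG)
        assert o.stratum == FAIL

    def test_strict_variants_not_rereported_as_slack(self):
        keys, m = matrix_from_rows(F1_IDS, [[0, 1, 1, 0, 0, 0], [0, 1, 1, 0, 1, 0]])
        outcomes = segregate_slack(keys, m, F1_CONFIG)
        assert [o.stratum for o in outcomes] == [STRICT, SLACK_ONLY]

    def test_slack_k_zero_equals_strict(self):
        config = SegregationConfig(
            obligate_carriers=frozenset({"MO1", "PB1"}),
            hard_excluders=frozenset({"FA1"}),
            slack_pool=frozenset({"SI1A", "SI1B", "SI1C"}),
            slack_k=0,
        )
        patterns = [list(p) for p in itertools.product([0, 1], repeat=6)]
        keys, m = matrix_from_rows(F1_IDS, patterns)
        strict = segregate_strict(keys, m, config)
        both = famseg.segregate_strata(keys, m, config.strata)
        assert [o.stratum for o in both] == [o.stratum for o in strict]
        assert all(o.stratum != SLACK_ONLY for o in both)


class TestOracleEquivalence:
    def test_exhaustive_four_member_pedigree(self):
        ids = ["a", "b", "c", "d"]
        config = SegregationConfig(
            obligate_carriers=frozenset({"a"}),
            hard_excluders=frozenset({"b"}),
            slack_pool=frozenset({"c", "d"}),
            slack_k=1,
        )
        patterns = [list(p) for p in itertools.product([0, 1, 2], repeat=4)]
        keys, m = matrix_from_rows(ids, patterns)
        outcomes = famseg.segregate_strata(keys, m, config.strata)
        for pattern, outcome in zip(patterns, outcomes):
            calls = dict(zip(ids, pattern))
            assert outcome.stratum == set_logic_oracle(
                calls, {"a"}, {"b"}, {"c", "d"}, 1
            ), pattern

    def test_count_and_enumeration_semantics_agree_on_six_members(self):
        # both formulations of "different combinations" slack, all 3^6 patterns
        patterns = [list(p) for p in itertools.product([0, 1, 2], repeat=6)]
        keys, m = matrix_from_rows(F1_IDS, patterns)
        for k in (1, 2):
            config = SegregationConfig(
                obligate_carriers=F1_CONFIG.obligate_carriers,
                hard_excluders=F1_CONFIG.hard_excluders,
                slack_pool=F1_CONFIG.slack_pool,
                slack_k=k,
            )
            fast = segregate_slack(keys, m, config)
            slow = segregate_slack_by_enumeration(keys, m, config)
            assert [o.stratum for o in fast] == [o.stratum for o in slow]

    @given(
        patterns=st.lists(
            st.lists(st.sampled_from([0, 1, 2, MISSING]), min_size=6, max_size=6),
            min_size=1,
            max_size=30,
        ),
        k=st.integers(1, 3),
    )
    def test_increasing_slack_never_shrinks_survivors(self, patterns, k):
        keys, m = matrix_from_rows(F1_IDS, patterns)
        base = SegregationConfig(
            obligate_carriers=F1_CONFIG.obligate_carriers,
            hard_excluders=F1_CONFIG.hard_excluders,
            slack_pool=F1_CONFIG.slack_pool,
            slack_k=k,
        )
        wider = SegregationConfig(
            obligate_carriers=F1_CONFIG.obligate_carriers,
            hard_excluders=F1_CONFIG.hard_excluders,
            slack_pool=F1_CONFIG.slack_pool,
            slack_k=min(k + 1, 3),
        )
        survive = lambda outcomes: {
            o.key for o in outcomes if o.stratum in (STRICT, SLACK_ONLY)
        }
        assert survive(segregate_slack(keys, m, base)) <= survive(
            segregate_slack(keys, m, wider)
        )


class TestRecessive:
    F3_IDS = ["FA3", "MO3", "BR3A", "BR3B"]
    CONFIG = SegregationConfig(
        model="recessive",
        obligate_carriers=frozenset({"BR3A", "BR3B"}),
        slack_pool=frozenset({"MO3", "FA3"}),
        slack_k=1,
        recessive_parent_set=frozenset({"MO3", "FA3"}),
    )

    def test_het_parents_hom_brothers_pass(self):
        keys, m = matrix_from_rows(self.F3_IDS, [[1, 1, 2, 2]])
        (o,) = segregate_recessive(keys, m, self.CONFIG)
        assert o.stratum == STRICT

    def test_homozygous_parent_fails(self):
        keys, m = matrix_from_rows(self.F3_IDS, [[2, 1, 2, 2]])
        (o,) = segregate_recessive(keys, m, self.CONFIG)
        assert o.stratum == FAIL and "FA3" in o.reason

    def test_het_brother_fails(self):
        keys, m = matrix_from_rows(self.F3_IDS, [[1, 1, 1, 2]])
        (o,) = segregate_recessive(keys, m, self.CONFIG)
        assert o.stratum == FAIL

    def test_family3_fixture_has_no_recessive_candidates(self, fixtures):
        # the recessive search over the family's variants comes up empty
        fx = fixtures["Family3"]
        config = SegregationConfig(
            model="recessive",
            obligate_carriers=frozenset({"BR3A", "BR3B"}),
            recessive_parent_set=frozenset({"MO3", "FA3"}),
        )
        outcomes = segregate_recessive(
            [a.key for a in fx.annotations], fx.genotypes, config
        )
        assert all(o.stratum == FAIL for o in outcomes)

    def test_empty_parent_set_rejected(self):
        keys, m = matrix_from_rows(self.F3_IDS, [[1, 1, 2, 2]])
        config = SegregationConfig(model="recessive", obligate_carriers=frozenset({"BR3A"}))
        with pytest.raises(ValueError, match="parent"):
            segregate_recessive(keys, m, config)


class TestConfigValidation:
    def test_overlapping_sets_rejected(self):
        with pytest.raises(ValueError, match="disjoint"):
            SegregationConfig(
                obligate_carriers=frozenset({"a"}), hard_excluders=frozenset({"a"})
            )

    def test_slack_k_larger_than_pool_rejected(self):
        with pytest.raises(ValueError, match="slack_k"):
            SegregationConfig(slack_pool=frozenset({"a"}), slack_k=2)


class TestCascade:
    def test_empty_variant_list_gives_zero_funnel(self, fixtures):
        fx = fixtures["Family1"]
        candidates, funnel = run_family_cascade([], fx.genotypes, fx.config)
        assert candidates == []
        assert set(funnel.as_dict().values()) == {0}

    def test_funnel_counts_non_increasing(self, cascades):
        for candidates, funnel in cascades.values():
            d = funnel.as_dict()
            chain = [d["total"], d["post_population"], d["post_exonic"], d["post_segregation_slack"]]
            assert chain == sorted(chain, reverse=True)
            assert d["post_segregation_strict"] <= d["post_segregation_slack"]
            assert d["post_cadd"] == d["strict_candidates"] + d["slack_candidates"]

    def test_filters_commute(self, fixtures):
        """Population, exonic, CADD and segregation select independently, so
        the final candidate set is order-invariant."""
        fx = fixtures["Family1"]
        reference, _ = run_family_cascade(fx.annotations, fx.genotypes, fx.config, fx.thresholds)
        ref_keys = {c.annotation.key for c in reference}

        outcomes = famseg.segregate_strata(
            [a.key for a in fx.annotations], fx.genotypes, fx.config.strata
        )
        seg_pass = {o.key for o in outcomes if o.stratum in (STRICT, SLACK_ONLY)}
        # reversed order: CADD -> segregation -> exonic -> population
        step = [a for a in fx.annotations if famseg.cadd_tier(a.cadd, fx.thresholds) != "fail"]
        step = [a for a in step if a.key in seg_pass]
        step = famseg.exonic_filter(step)
        step = famseg.population_filter(step, fx.thresholds)
        assert {a.key for a in step} == ref_keys

    def test_candidate_strata_are_disjoint(self, cascades):
        for candidates, _ in cascades.values():
            strict = {c.annotation.key for c in candidates if c.stratum == STRICT}
            slack = {c.annotation.key for c in candidates if c.stratum == SLACK_ONLY}
            assert strict.isdisjoint(slack)

    def test_cascade_is_deterministic(self, fixtures):
        fx = fixtures["Family2"]
        first = run_family_cascade(fx.annotations, fx.genotypes, fx.config, fx.thresholds)
        second = run_family_cascade(fx.annotations, fx.genotypes, fx.config, fx.thresholds)
        assert first[0] == second[0]
        assert first[1].as_dict() == second[1].as_dict()
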