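"""Pedigree segregation filtering — the core computation.

A variant *segregates* with disease when every affected family member
carries it and unaffected members do not, under an assumed inheritance
model.  Because penetrance is rarely complete, each family is analysed in
two strata:

* **strict** (filter 1): only the stratum's obligate carriers may carry the
  variant; any carriage by a hard excluder or a slack-pool member
  disqualifies it.
* **slack** (filter 2, less stringent): up to ``slack_k`` members of a
  designated pool of unaffected relatives may carry the variant
  (non-penetrant carriers).  Equivalently — and provably so — the variant
  survives for at least one choice of ``slack_k`` pool members designated
  permissible carriers, which is the "different combinations" enumeration.
  Both formulations are implemented; tests prove them equal by exhaustion.

Strata generalize beyond a slack allowance: a family whose two filters
differ by their obligate-carrier *definition* (e.g. affected = breast+lung
double primaries vs. affected = any breast cancer) is expressed as two
explicit strata with different obligate sets.  A variant is assigned to the
first stratum it passes; later strata report only their additional passes,
so reported strata are always disjoint.

The recessive model is single-variant homozygous: affected individuals must
be homozygous alternate and the designated parents heterozygous.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

from .annotation import (
    TIER_FAIL,
    Thresholds,
    VariantAnnotation,
    cadd_tier,
    exonic_filter,
    population_filter,
)
from .variants import MISSING, GenotypeMatrix, VariantKey

STRICT = "strict"
SLACK_ONLY = "slack_only"
FAIL = "fail"

DOMINANT = "dominant"
RECESSIVE = "recessive"


@dataclass(frozen=True)
class Stratum:
    """One filter definition: who must carry, who must not, who may."""

    name: str
    obligate_carriers: frozenset[str]
    hard_excluders: frozenset[str] = frozenset()
    slack_pool: frozenset[str] = frozenset()
    slack_k: int = 0

    def __post_init__(self) -> None:
        if self.slack_k < 0:
            raise ValueError("slack_k must be >= 0")
        overlaps = (
            self.obligate_carriers & self.hard_excluders,
            self.obligate_carriers & self.slack_pool,
            self.hard_excluders & self.slack_pool,
        )
        if any(overlaps):
            raise ValueError(
                f"stratum {self.name}: obligate/excluder/slack sets must be pairwise disjoint"
            )
        if self.slack_k > len(self.slack_pool):
            raise ValueError(
                f"stratum {self.name}: slack_k={self.slack_k} exceeds pool size {len(self.slack_pool)}"
            )


@dataclass
class SegregationConfig:
    """Inheritance model plus the carrier-set definitions for one family.

    For the common case (one obligate set, a hard-excluder set and a slack
    pool) the two strata are derived automatically: stratum 1 is the strict
    filter (slack_k forced to 0), stratum 2 allows up to ``slack_k``
    slack-pool carriers.  Families needing different obligate sets per
    filter pass an explicit ``strata`` list instead.
    """

    model: str = DOMINANT
    obligate_carriers: frozenset[str] = frozenset()
    hard_excluders: frozenset[str] = frozenset()
    slack_pool: frozenset[str] = frozenset()
    slack_k: int = 1
    recessive_parent_set: frozenset[str] = frozenset()
    strata: list[Stratum] | None = None

    def __post_init__(self) -> None:
        self.obligate_carriers = frozenset(self.obligate_carriers)
        self.hard_excluders = frozenset(self.hard_excluders)
        self.slack_pool = frozenset(self.slack_pool)
        self.recessive_parent_set = frozenset(self.recessive_parent_set)
        if self.model not in (DOMINANT, RECESSIVE):
            raise ValueError(f"unknown model {self.model!r}")
        if self.strata is None:
            # with no slack pool the relaxed stratum degenerates to strict
            k = self.slack_k if self.slack_pool else 0
            # validates disjointness / slack_k bounds as a side effect
            self.strata = [
                Stratum(STRICT, self.obligate_carriers, self.hard_excluders, self.slack_pool, 0),
                Stratum("slack", self.obligate_carriers, self.hard_excluders, self.slack_pool, k),
            ]

    def all_ids(self) -> frozenset[str]:
        ids: set[str] = set(self.recessive_parent_set)
        for st in self.strata:
            ids |= st.obligate_carriers | st.hard_excluders | st.slack_pool
        return frozenset(ids)


def is_carrier(allele_count: int, model: str = DOMINANT) -> bool:
    """Carrier status from an alt-allele dosage (0/1/2, MISSING = not carrier).

    Dominant: one or two alt alleles.  Recessive: homozygous alternate only
    (heterozygotes are transmitting parents, not affected-carriers).
    Hemizygous male X calls arrive normalized to dosage 2, so a single alt
    allele on X counts as carriage under either model.
    """
    if allele_count == MISSING:
        return False
    if model == RECESSIVE:
        return allele_count == 2
    return allele_count in (1, 2)


@dataclass(frozen=True)
class FilterOutcome:
    key: VariantKey
    stratum: str  # STRICT | SLACK_ONLY | FAIL
    carriers: frozenset[str] = frozenset()
    slack_carriers_used: int = 0
    stratum_name: str | None = None  # which configured stratum passed
    filter_index: int = 0  # 1-based index of the passing stratum (0 = none)
    reason: str | None = None
    warnings: tuple[str, ...] = ()


def _evaluate_stratum(
    calls: dict[str, int], stratum: Stratum, model: str = DOMINANT
) -> tuple[bool, int, str | None, tuple[str, ...]]:
    """(passes, slack_carriers, fail_reason, warnings) for one variant/stratum.

    Missing genotypes: in an obligate carrier the variant fails outright
    (genotype-incomplete); in an excluder or slack-pool member the call is
    conservatively treated as non-carrier, with a warning.
    """
    warnings: list[str] = []
    for iid in sorted(stratum.obligate_carriers):
        ac = calls.get(iid, MISSING)
        if ac == MISSING:
            return False, 0, f"genotype-incomplete:{iid}", tuple(warnings)
        if not is_carrier(ac, model):
            return False, 0, f"obligate-noncarrier:{iid}", tuple(warnings)
    for iid in sorted(stratum.hard_excluders):
        ac = calls.get(iid, MISSING)
        if ac == MISSING:
            warnings.append(f"missing-genotype:{iid}")
        elif is_carrier(ac, model):
            return False, 0, f"excluder-carrier:{iid}", tuple(warnings)
    slack_carriers = 0
    for iid in sorted(stratum.slack_pool):
        ac = calls.get(iid, MISSING)
        if ac == MISSING:
            warnings.append(f"missing-genotype:{iid}")
        elif is_carrier(ac, model):
            slack_carriers += 1
    if slack_carriers > stratum.slack_k:
        return False, slack_carriers, "slack-exceeded", tuple(warnings)
    return True, slack_carriers, None, tuple(warnings)


def _carrier_set(calls: dict[str, int], model: str = DOMINANT) -> frozenset[str]:
    return frozenset(iid for iid, ac in calls.items() if is_carrier(ac, model))


def segregate_strata(
    variants: list[VariantKey],
    genotypes: GenotypeMatrix,
    strata: list[Stratum],
    model: str = DOMINANT,
) -> list[FilterOutcome]:
    """Assign each variant to the first stratum whose filter it passes.

    Stratum 1 is the strict filter; later strata report only the variants
    not already captured, so the reported strata partition the survivors
    ("additional" semantics).
    """
    outcomes: list[FilterOutcome] = []
    for key in variants:
        calls = genotypes.row(key)
        carriers = _carrier_set(calls, model)
        assigned: FilterOutcome | None = None
        last_reason = None
        warnings: tuple[str, ...] = ()
        for index, stratum in enumerate(strata, start=1):
            passes, slack_used, reason, warns = _evaluate_stratum(calls, stratum, model)
            warnings = warnings + warns
            if passes:
                label = STRICT if index == 1 else SLACK_ONLY
                assigned = FilterOutcome(
                    key,
                    label,
                    carriers,
                    slack_used,
                    stratum_name=stratum.name,
                    filter_index=index,
                    warnings=warnings,
                )
                break
            last_reason = reason
        if assigned is None:
            assigned = FilterOutcome(key, FAIL, carriers, 0, reason=last_reason, warnings=warnings)
        outcomes.append(assigned)
    return outcomes


def segregate_strict(
    variants: list[VariantKey], genotypes: GenotypeMatrix, config: SegregationConfig
) -> list[FilterOutcome]:
    """The strict filter alone: only obligate carriers may carry."""
    return segregate_strata(variants, genotypes, [config.strata[0]], config.model)


def segregate_slack(
    variants: list[VariantKey], genotypes: GenotypeMatrix, config: SegregationConfig
) -> list[FilterOutcome]:
    """Both strata: strict first, then the slack allowance for the rest."""
    if all(st.slack_k < 1 for st in config.strata[1:]) and config.strata[0] == config.strata[-1]:
        raise ValueError("slack filtering requires slack_k >= 1 in a relaxed stratum")
    return segregate_strata(variants, genotypes, config.strata, config.model)


def segregate_slack_by_enumeration(
    variants: list[VariantKey], genotypes: GenotypeMatrix, config: SegregationConfig
) -> list[FilterOutcome]:
    """The "different combinations" formulation of the slack filter.

    For every combination of ``slack_k`` slack-pool members designated
    permissible carriers, the remaining pool members are treated as hard
    excluders and the strict filter is re-run; a variant is slack-only if it
    survives at least one combination without being strict.  Semantically
    identical to the count-based filter (proved by exhaustion in the tests);
    exponential in the pool size, so used as an oracle, not in production.
    """
    strict_outcomes = {o.key: o for o in segregate_strict(variants, genotypes, config)}
    base = config.strata[1] if len(config.strata) > 1 else config.strata[0]
    results: list[FilterOutcome] = []
    for key in variants:
        strict = strict_outcomes[key]
        if strict.stratum == STRICT:
            results.append(strict)
            continue
        calls = genotypes.row(key)
        carriers = _carrier_set(calls, config.model)
        hit = None
        for combo in itertools.combinations(sorted(base.slack_pool), base.slack_k):
            trial = Stratum(
                "combo",
                base.obligate_carriers,
                base.hard_excluders | (base.slack_pool - set(combo)),
                frozenset(combo),
                slack_k=base.slack_k,
            )
            passes, slack_used, _, _ = _evaluate_stratum(calls, trial, config.model)
            if passes:
                hit = slack_used
                break
        if hit is not None:
            results.append(FilterOutcome(key, SLACK_ONLY, carriers, hit, filter_index=2))
        else:
            results.append(FilterOutcome(key, FAIL, carriers, 0, reason=strict.reason))
    return results


def segregate_recessive(
    variants: list[VariantKey], genotypes: GenotypeMatrix, config: SegregationConfig
) -> list[FilterOutcome]:
    """Single-variant recessive filter: affecteds homozygous, parents het."""
    if not config.recessive_parent_set:
        raise ValueError("recessive model requires a non-empty recessive_parent_set")
    obligates = config.strata[0].obligate_carriers
    outcomes: list[FilterOutcome] = []
    for key in variants:
        calls = genotypes.row(key)
        carriers = _carrier_set(calls, DOMINANT)
        reason = None
        for iid in sorted(obligates):
            ac = calls.get(iid, MISSING)
            if ac == MISSING:
                reason = f"genotype-incomplete:{iid}"
                break
            if ac != 2:
                reason = f"obligate-not-homozygous:{iid}"
                break
        if reason is None:
            for iid in sorted(config.recessive_parent_set):
                if calls.get(iid, MISSING) != 1:
                    reason = f"parent-not-heterozygous:{iid}"
                    break
        if reason is None:
            outcomes.append(FilterOutcome(key, STRICT, carriers, 0, stratum_name="recessive", filter_index=1))
        else:
            outcomes.append(FilterOutcome(key, FAIL, carriers, reason=reason))
    return outcomes


# ---------------------------------------------------------------------------
# Full per-family cascade
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Candidate:
    """A variant surviving the whole cascade, with its stratum and tier."""

    annotation: VariantAnnotation
    stratum: str  # STRICT | SLACK_ONLY
    filter_index: int  # 1 = strict filter, 2 = relaxed filter
    tier: str  # candidate | high_risk
    carriers: frozenset[str] = frozenset()


@dataclass
class Funnel:
    """Stage-by-stage surviving-variant counts for one family run."""

    stages: list[tuple[str, int]] = field(default_factory=list)

    def add(self, name: str, count: int) -> None:
        self.stages.append((name, count))

    def as_dict(self) -> dict[str, int]:
        return dict(self.stages)

    def __getitem__(self, name: str) -> int:
        return self.as_dict()[name]


def run_family_cascade(
    annotations: list[VariantAnnotation],
    genotypes: GenotypeMatrix,
    config: SegregationConfig,
    thresholds: Thresholds = Thresholds(),
) -> tuple[list[Candidate], Funnel]:
    """Population filter -> exonic filter -> segregation strata -> CADD tiers.

    Returns surviving candidates (stratum-labelled, CADD-tiered) and the
    funnel of per-stage counts.  Deterministic for fixed inputs.  The four
    filters commute — only the funnel's intermediate counts depend on the
    order, which follows the analysis workflow: rarity, exonic location,
    family segregation, deleteriousness.
    """
    funnel = Funnel()
    funnel.add("total", len(annotations))

    rare = population_filter(annotations, thresholds)
    funnel.add("post_population", len(rare))

    exonic = exonic_filter(rare)
    funnel.add("post_exonic", len(exonic))

    keys = [v.key for v in exonic]
    if config.model == RECESSIVE:
        outcomes = segregate_recessive(keys, genotypes, config)
    else:
        outcomes = segregate_strata(keys, genotypes, config.strata, config.model)
    by_key = {o.key: o for o in outcomes}
    strict_survivors = [v for v in exonic if by_key[v.key].stratum == STRICT]
    slack_survivors = [v for v in exonic if by_key[v.key].stratum == SLACK_ONLY]
    funnel.add("post_segregation_strict", len(strict_survivors))
    funnel.add("post_segregation_slack", len(strict_survivors) + len(slack_survivors))

    candidates: list[Candidate] = []
    for v in strict_survivors + slack_survivors:
        tier = cadd_tier(v.cadd, thresholds)
        if tier == TIER_FAIL:
            continue
        outcome = by_key[v.key]
        candidates.append(
            Candidate(v, outcome.stratum, outcome.filter_index, tier, outcome.carriers)
        )
    funnel.add("post_cadd", len(candidates))
    funnel.add("strict_candidates", sum(1 for c in candidates if c.stratum == STRICT))
    funnel.add("slack_candidates", sum(1 for c in candidates if c.stratum == SLACK_ONLY))
    return candidates, funnel
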