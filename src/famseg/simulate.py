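"""Synthetic data: Mendelian gene-dropping, planted causal variants,
simulated annotation tables, and the three built-in study-family fixtures.

Gene dropping draws founder alleles independently from a site's population
alternate-allele frequency and transmits one uniformly chosen allele from
each parent down the pedigree (single maternal allele for male X).  A
*planted* causal variant is seeded heterozygous in a chosen individual,
transmitted the same way, and phenotypes are assigned with a penetrance
``f`` for carriers and a phenocopy rate for non-carriers — the disease
architecture the dominant segregation filters assume.

The built-in fixtures reconstruct the three study families from their
published candidate tables: every printed variant with its gene, position,
stratum, MMAF and CADD, plus genotypes that encode the stated carrier
patterns, plus decoy variants that each fail exactly one cascade stage so
every filter is exercised negatively.  The genotype and phenotype detail
not printed for individual family members (which healthy relative carries
which relaxed-filter variant, unprinted onset ages) is synthetic: slack
carriers rotate deterministically through the pool, which leaves every
printed count unchanged.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np

from .annotation import Thresholds, VariantAnnotation, classify_consequence
from .pedigree import FEMALE, MALE, Individual, Pedigree, Phenotype
from .segregation import DOMINANT, RECESSIVE, SegregationConfig, Stratum
from .variants import MISSING, GenotypeMatrix, VariantKey, normalize_chrom

# ---------------------------------------------------------------------------
# Gene dropping
# ---------------------------------------------------------------------------

def _transmit(parent_a1, parent_a2, pick):
    return np.where(pick, parent_a1, parent_a2)


def gene_drop(
    pedigree: Pedigree,
    site_afs,
    seed: int | np.random.Generator,
    keys: list[VariantKey] | None = None,
    chroms: list[str] | None = None,
) -> GenotypeMatrix:
    """Drop alleles down a pedigree at independent sites.

    Founder alleles are Bernoulli(af) per chromosome copy; every non-founder
    inherits one uniformly chosen allele from each parent.  Sites whose
    chromosome is ``chrX`` give males a single maternal allele, normalized to
    dosage 0/2 and flagged hemizygous.  A parent referenced but absent from
    the pedigree is treated as an unrelated founder.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    afs = np.asarray(site_afs, dtype=float)
    if np.any((afs < 0) | (afs > 1)):
        raise ValueError("allele frequencies must lie in [0, 1]")
    n = afs.size
    if keys is None:
        keys = [VariantKey("chr1", 1_000_000 + i, "A", "G") for i in range(n)]
    if chroms is None:
        chroms = [k.chrom for k in keys]
    is_x = np.array([normalize_chrom(c) == "chrX" for c in chroms])

    order = pedigree.topological_order()
    alleles: dict[str, tuple[np.ndarray, np.ndarray]] = {}

    def founder_pair() -> tuple[np.ndarray, np.ndarray]:
        return (
            (rng.random(n) < afs).astype(np.int8),
            (rng.random(n) < afs).astype(np.int8),
        )

    for ind in order:
        if ind.is_founder:
            alleles[ind.id] = founder_pair()
            continue
        pairs = []
        for pid in (ind.mother_id, ind.father_id):
            if pid is not None and pid in alleles:
                a1, a2 = alleles[pid]
                pick = rng.integers(0, 2, n).astype(bool)
                pairs.append(_transmit(a1, a2, pick))
            else:
                # parent outside the pedigree: an unrelated founder
                pairs.append((rng.random(n) < afs).astype(np.int8))
        maternal, paternal = pairs
        if ind.sex == MALE and is_x.any():
            # male X: hemizygous, single maternal allele
            paternal = np.where(is_x, maternal, paternal).astype(np.int8)
        alleles[ind.id] = (maternal.astype(np.int8), paternal.astype(np.int8))

    individuals = [ind.id for ind in pedigree]
    calls = np.zeros((n, len(individuals)), dtype=np.int8)
    hemi = np.zeros_like(calls, dtype=bool)
    for j, iid in enumerate(individuals):
        a1, a2 = alleles[iid]
        calls[:, j] = a1 + a2
        if pedigree[iid].sex == MALE:
            hemi[:, j] = is_x
    return GenotypeMatrix(keys, individuals, calls, hemi)


def mendelian_violations(matrix: GenotypeMatrix, pedigree: Pedigree) -> list[tuple[VariantKey, str]]:
    """Exhaustive trio-consistency check over every child and site.

    A child's dosage must be expressible as one allele from each parent
    (dosage 0 transmits 0, dosage 2 transmits 1, dosage 1 either); male
    hemizygous X calls must equal twice a maternal allele.  Returns a list
    of (variant, child id) violations — empty for any correctly gene-dropped
    matrix.
    """
    transmissible = {0: {0}, 1: {0, 1}, 2: {1}}
    idx = {s: j for j, s in enumerate(matrix.individuals)}
    out: list[tuple[VariantKey, str]] = []
    for ind in pedigree:
        if ind.is_founder:
            continue
        if ind.id not in idx:
            continue
        j = idx[ind.id]
        jm = idx.get(ind.mother_id) if ind.mother_id else None
        jf = idx.get(ind.father_id) if ind.father_id else None
        for i, key in enumerate(matrix.variants):
            c = int(matrix.calls[i, j])
            if c == MISSING:
                continue
            mom = transmissible.get(int(matrix.calls[i, jm]), {0, 1}) if jm is not None else {0, 1}
            dad = transmissible.get(int(matrix.calls[i, jf]), {0, 1}) if jf is not None else {0, 1}
            if matrix.hemizygous[i, j]:
                ok = any(2 * a == c for a in mom)
            else:
                ok = any(a + b == c for a in mom for b in dad)
            if not ok:
                out.append((key, ind.id))
    return out


# ---------------------------------------------------------------------------
# Planted causal variants
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CausalSpec:
    """Disease architecture for a planted variant."""

    founder_id: str
    model: str = DOMINANT
    penetrance: float = 1.0
    phenocopy_rate: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.penetrance <= 1.0 or not 0.0 <= self.phenocopy_rate <= 1.0:
            raise ValueError("penetrance and phenocopy rate must lie in [0, 1]")
        if self.model not in (DOMINANT, RECESSIVE):
            raise ValueError(f"unknown model {self.model!r}")


def _drop_single_site(
    pedigree: Pedigree, seed_alleles: dict[str, tuple[int, int]], rng: np.random.Generator
) -> dict[str, tuple[int, int]]:
    """One-site gene drop with forced genotypes in ``seed_alleles``.

    A seeded non-founder overrides inheritance (interpreted as the variant
    entering through that individual's unobserved lineage); descendants
    inherit from the seeded genotype as usual.
    """
    alleles: dict[str, tuple[int, int]] = {}
    for ind in pedigree.topological_order():
        if ind.id in seed_alleles:
            alleles[ind.id] = seed_alleles[ind.id]
        elif ind.is_founder:
            alleles[ind.id] = (0, 0)
        else:
            pair = []
            for pid in (ind.mother_id, ind.father_id):
                if pid is not None and pid in alleles:
                    pair.append(alleles[pid][int(rng.integers(0, 2))])
                else:
                    pair.append(0)
            alleles[ind.id] = (pair[0], pair[1])
    return alleles


def plant_causal_variant(
    matrix: GenotypeMatrix,
    pedigree: Pedigree,
    spec: CausalSpec,
    seed: int | np.random.Generator,
    key: VariantKey | None = None,
) -> tuple[GenotypeMatrix, dict[str, bool], dict]:
    """Insert one causal variant and assign phenotypes.

    Dominant: the chosen individual starts heterozygous (for a non-founder,
    the variant entered through their unobserved lineage).  Recessive: every
    founder starts heterozygous so homozygous offspring are reachable.  The
    variant is transmitted by gene dropping; each carrier is affected with
    probability ``penetrance`` and each non-carrier with probability
    ``phenocopy_rate``.  Returns the extended matrix, the phenotype
    assignment, and a truth record for recovery tests (written by callers to
    a sidecar, never into the VCF).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if key is None:
        key = VariantKey("chr22", 99_000_001, "A", "T")
    if spec.model == RECESSIVE:
        founder_alleles = {f.id: (0, 1) for f in pedigree.founders}
    else:
        founder_alleles = {spec.founder_id: (0, 1)}
    alleles = _drop_single_site(pedigree, founder_alleles, rng)

    carriers = set()
    for iid, (a1, a2) in alleles.items():
        dosage = a1 + a2
        if spec.model == RECESSIVE:
            if dosage == 2:
                carriers.add(iid)
        elif dosage >= 1:
            carriers.add(iid)

    affected: dict[str, bool] = {}
    for ind in pedigree:
        p = spec.penetrance if ind.id in carriers else spec.phenocopy_rate
        affected[ind.id] = bool(rng.random() < p)

    row = np.array(
        [[sum(alleles[iid]) for iid in matrix.individuals]], dtype=np.int8
    )
    new = GenotypeMatrix(
        matrix.variants + [key],
        matrix.individuals,
        np.vstack([matrix.calls, row]) if matrix.n_variants else row,
        np.vstack([matrix.hemizygous, np.zeros_like(row, bool)])
        if matrix.n_variants
        else np.zeros_like(row, bool),
    )
    truth = {
        "key": key,
        "model": spec.model,
        "founder": spec.founder_id,
        "penetrance": spec.penetrance,
        "phenocopy_rate": spec.phenocopy_rate,
        "carriers": frozenset(carriers),
        "dosages": {iid: sum(a) for iid, a in alleles.items()},
    }
    return new, affected, truth


# ---------------------------------------------------------------------------
# Simulated annotation tables
# ---------------------------------------------------------------------------

DEFAULT_CONSEQUENCE_MIX: dict[str, float] = {
    "missense": 0.50,
    "synonymous": 0.25,
    "non_exonic": 0.12,
    "splicing": 0.05,
    "nonsense": 0.03,
    "frameshift": 0.03,
    "inframe_indel": 0.02,
}


@dataclass
class SimulationConfig:
    """Background-variant simulation parameters.

    Allele frequencies follow a mixture: with weight ``af_zero_weight`` the
    variant is unseen in the databases (AF absent -> novel, MMAF 0), else
    the AF is log-uniform on ``af_range`` — a crude but standard stand-in
    for the heavy left tail of site-frequency spectra.  CADD is uniform on
    ``cadd_range`` and the consequence class is drawn from
    ``consequence_mix``.
    """

    n_variants: int = 2000
    af_zero_weight: float = 0.3
    af_range: tuple[float, float] = (1e-6, 0.5)
    cadd_range: tuple[float, float] = (0.0, 40.0)
    consequence_mix: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CONSEQUENCE_MIX)
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.af_zero_weight <= 1.0:
            raise ValueError("af_zero_weight must lie in [0, 1]")
        total = sum(self.consequence_mix.values())
        if not math.isclose(total, 1.0, rel_tol=1e-9):
            raise ValueError(f"consequence_mix weights sum to {total}, expected 1")

    def af_mass_below(self, x: float) -> float:
        """Analytic P(MMAF < x) under the mixture (for calibration tests)."""
        lo, hi = self.af_range
        if x <= lo:
            return self.af_zero_weight
        frac = (math.log(min(x, hi)) - math.log(lo)) / (math.log(hi) - math.log(lo))
        return self.af_zero_weight + (1.0 - self.af_zero_weight) * frac


def simulate_annotations(
    variant_keys: list[VariantKey], config: SimulationConfig, seed: int | None = None
):
    """Draw per-variant AFs, consequence class and CADD; returns a DataFrame
    that round-trips through ``read_annotation_table``."""
    import pandas as pd

    rng = np.random.default_rng(config.seed if seed is None else seed)
    n = len(variant_keys)
    lo, hi = config.af_range
    zero = rng.random(n) < config.af_zero_weight
    afs = np.exp(rng.uniform(math.log(lo), math.log(hi), n))
    afs[zero] = 0.0
    # second database sees a correlated but not identical frequency
    gnomad = afs * rng.uniform(0.5, 1.0, n)
    classes = list(config.consequence_mix)
    probs = np.array([config.consequence_mix[c] for c in classes])
    cons = rng.choice(classes, size=n, p=probs)
    cadd = rng.uniform(*config.cadd_range, n).round(1)
    rows = {
        "chrom": [k.chrom for k in variant_keys],
        "pos": [k.pos for k in variant_keys],
        "ref": [k.ref for k in variant_keys],
        "alt": [k.alt for k in variant_keys],
        "gene": [f"SIMG{i:05d}" for i in range(n)],
        "consequence": cons,
        "cadd": cadd,
        "swegen_af": ["." if z else f"{a:.8f}" for z, a in zip(zero, afs)],
        "gnomad_af": ["." if z else f"{g:.8f}" for z, g in zip(zero, gnomad)],
        "rsid": ["." for _ in range(n)],
        "clinvar": ["." for _ in range(n)],
        "hgvs": ["." for _ in range(n)],
    }
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Study-family fixtures
# ---------------------------------------------------------------------------

@dataclass
class PaperFixture:
    """One reconstructed study family, ready to run through the cascade."""

    family_id: str
    pedigree: Pedigree
    annotations: list[VariantAnnotation]
    genotypes: GenotypeMatrix
    config: SegregationConfig
    thresholds: Thresholds
    expected: list[dict]  # published table rows: filter/gene/position/mmaf/cadd
    disease_labels: frozenset[str] = frozenset({"breast_cancer", "lung_cancer", "rcc"})


def _family1_pedigree() -> Pedigree:
    bc = Phenotype("breast_cancer", 40)
    return Pedigree.from_members(
        "Family1",
        [
            Individual("GM1", sex=FEMALE, phenotypes=frozenset({Phenotype("breast_cancer", 42)})),
            Individual("FA1", sex=MALE, sequenced=True),
            Individual(
                "MO1",
                mother_id="GM1",
                sex=FEMALE,
                phenotypes=frozenset({Phenotype("breast_cancer", 52)}),
                sequenced=True,
            ),
            Individual("PB1", "FA1", "MO1", FEMALE, frozenset({bc}), True),
            Individual("SI1A", "FA1", "MO1", FEMALE, frozenset(), True),
            Individual("SI1B", "FA1", "MO1", FEMALE, frozenset(), True),
            Individual("SI1C", "FA1", "MO1", FEMALE, frozenset(), True),
        ],
    )


def _family2_pedigree() -> Pedigree:
    def ph(*items):
        return frozenset(Phenotype(l, a) for l, a in items)

    return Pedigree.from_members(
        "Family2",
        [
            Individual("GM2", sex=FEMALE),
            Individual("HU2", sex=MALE),
            Individual(
                "MO2", mother_id="GM2", sex=FEMALE,
                phenotypes=ph(("breast_cancer", 72), ("lung_cancer", None)), sequenced=True,
            ),
            Individual(
                "AU2", mother_id="GM2", sex=FEMALE,
                phenotypes=ph(("breast_cancer", 75), ("lung_cancer", None)), sequenced=True,
            ),
            Individual("PB2", "HU2", "MO2", FEMALE, ph(("breast_cancer", 51)), True),
            Individual(
                "SB2", "HU2", "MO2", FEMALE,
                ph(("breast_cancer", 47), ("lung_cancer", None)), True,
            ),
            Individual("SP2", sex=MALE),
            Individual("SN2", "SP2", "PB2", MALE, ph(("gist", 42)), False),
        ],
    )


def _family3_pedigree() -> Pedigree:
    return Pedigree.from_members(
        "Family3",
        [
            Individual("FA3", sex=MALE, sequenced=True),
            Individual("MO3", sex=FEMALE, sequenced=True),
            Individual(
                "BR3A", "FA3", "MO3", MALE,
                frozenset({Phenotype("breast_cancer", 25)}), True,
            ),
            Individual(
                "BR3B", "FA3", "MO3", MALE,
                frozenset({Phenotype("rcc", 35)}), True,
            ),
        ],
    )


def _family_configs() -> dict[str, SegregationConfig]:
    return {
        "Family1": SegregationConfig(
            model=DOMINANT,
            obligate_carriers=frozenset({"MO1", "PB1"}),
            hard_excluders=frozenset({"FA1"}),
            slack_pool=frozenset({"SI1A", "SI1B", "SI1C"}),
            slack_k=1,
        ),
        # The two filters differ by their affected-set definition, not by a
        # slack allowance: filter 1 takes the breast+lung double primaries as
        # obligate carriers and the breast-only proband as a non-carrier;
        # filter 2 obliges all four affected women.
        "Family2": SegregationConfig(
            model=DOMINANT,
            strata=[
                Stratum(
                    "breast_and_lung",
                    obligate_carriers=frozenset({"MO2", "AU2", "SB2"}),
                    hard_excluders=frozenset({"PB2"}),
                ),
                Stratum("all_breast", obligate_carriers=frozenset({"MO2", "AU2", "PB2", "SB2"})),
            ],
        ),
        "Family3": SegregationConfig(
            model=DOMINANT,
            obligate_carriers=frozenset({"BR3A", "BR3B"}),
            slack_pool=frozenset({"MO3", "FA3"}),
            slack_k=1,
            recessive_parent_set=frozenset({"MO3", "FA3"}),
        ),
    }


# Which individuals carry filter-1 vs filter-2 variants, and who rotates as
# the single permitted relaxed-filter carrier (synthetic choice: the tables
# do not say which healthy relative carried which variant).
_CARRIER_PLANS = {
    "Family1": {"strict": ("MO1", "PB1"), "rotate": ("SI1A", "SI1B", "SI1C")},
    "Family2": {"strict": ("MO2", "AU2", "SB2"), "filter2": ("MO2", "AU2", "PB2", "SB2")},
    "Family3": {"strict": ("BR3A", "BR3B"), "rotate": ("MO3", "FA3")},
}

# Decoy carrier patterns: each fails segregation for a distinct reason.
_SEG_DECOY_PATTERNS = {
    "Family1": [
        ("FA1", "MO1", "PB1"),          # hard excluder (father) carries
        ("MO1", "PB1", "SI1A", "SI1B"),  # two healthy sisters carry (> slack)
        ("MO1", "SI1A"),                 # obligate carrier (proband) lacks it
        ("FA1",),                        # excluder-only
    ],
    "Family2": [
        ("PB2",),                        # proband-only: fails both strata
        ("PB2", "SB2"),                  # missing two obligates
        ("MO2",),
        ("MO2", "AU2"),
    ],
    "Family3": [
        ("BR3A", "BR3B", "MO3", "FA3"),  # both parents carry (> slack)
        ("MO3", "BR3A"),                 # one brother lacks it
        ("FA3",),
        ("BR3B", "FA3"),
    ],
}

# Side-channel rows: panel-gene and risk-SNP carriers observed in the
# families.  Positions are synthetic placeholders within the right genes;
# MMAFs above the cascade cutoff keep these out of the candidate funnel.
_PANEL_ROWS = {
    "Family1": [
        ("FANCA", "chr16", 89849480, "C", "T", "rs755555501", 0.010, 12.0, "benign", ("MO1", "PB1")),
        ("FANCA", "chr16", 89858512, "G", "A", "rs755555502", 0.020, 9.5, "benign", ("MO1", "PB1")),
        ("FANCM", "chr14", 45605064, "A", "G", "rs755555503", 0.005, 11.0, "benign", ("MO1", "PB1")),
        ("TOPBP1", "chr3", 133317121, "T", "C", "rs755555504", 0.004, 10.0, "benign", ("MO1", "PB1")),
        # common FANCA polymorphism above the 0.2 panel cut: must never report
        ("FANCA", "chr16", 89836323, "A", "G", "rs755555505", 0.25, 3.0, "benign", ("MO1", "PB1")),
    ],
    "Family2": [
        ("BRCA2", "chr13", 32911888, "A", "G", "rs80358899", 0.003, 14.0, "benign", ("PB2",)),
        ("CASP8", "chr2", 202149589, "G", "C", "rs1045485", 0.120, 0.5, "benign", ("PB2", "SB2")),
    ],
    "Family3": [],
}


def _parse_position(text: str) -> tuple[str, int]:
    chrom, pos = text.split(":")
    return normalize_chrom(chrom), int(pos)


def _load_table(family_id: str) -> list[dict]:
    fname = f"data/{family_id.lower()}_candidates.tsv"
    text = resources.files("famseg").joinpath(fname).read_text()
    lines = text.strip().splitlines()
    header = lines[0].split("\t")
    rows = []
    for line in lines[1:]:
        row = dict(zip(header, line.split("\t")))
        row["filter"] = int(row["filter"])
        row["mmaf"] = float(row["mmaf"])
        row["cadd"] = float(row["cadd"])
        rows.append(row)
    return rows


def _row_annotation(row: dict) -> VariantAnnotation:
    chrom, pos = _parse_position(row["position"])
    key = VariantKey(chrom, pos, row["ref"], row["alt"])
    mmaf = row["mmaf"]
    if mmaf > 0:
        # SweGen carries the max; gnomAD a correlated lower frequency
        afs = (("gnomad_af", round(mmaf * 0.75, 10)), ("swegen_af", mmaf))
    else:
        afs = ()
    clinvar = "likely_benign" if row["gene"] == "PRKD1" else "absent"
    return VariantAnnotation(
        key=key,
        gene=row["gene"],
        consequence=classify_consequence(row["type"]),
        cadd=row["cadd"],
        af_by_source=afs,
        rsid=None if row["rsid"] == "." else row["rsid"],
        hgvs=None if row["change"] == "." else row["change"],
        clinvar=clinvar,
        raw_consequence=row["type"],
    )


def _decoy_annotations(family_id: str, n_per_mode: int = 4) -> list[tuple[VariantAnnotation, tuple[str, ...]]]:
    """Synthetic decoys: (annotation, carrier ids); each fails one stage."""
    plan = _CARRIER_PLANS[family_id]
    strict = plan["strict"]
    relaxed = plan.get("filter2") or strict + (plan["rotate"][0],)
    # Family 3's strict pattern (both brothers, neither parent) is de-novo-
    # like; decoys there use the Mendelian brothers+parent pattern, which
    # still passes segregation (via the relaxed stratum).
    passing = relaxed if family_id == "Family3" else strict
    fam_no = family_id[-1]
    base_pos = 10_000_000 + int(fam_no) * 1_000_000
    out: list[tuple[VariantAnnotation, tuple[str, ...]]] = []

    def add(i, gene, consequence, mmaf, cadd, carriers, raw=None):
        key = VariantKey("chr12", base_pos + i * 137, "A", "T")
        afs = (("swegen_af", mmaf),) if mmaf > 0 else ()
        out.append(
            (
                VariantAnnotation(
                    key=key,
                    gene=gene,
                    consequence=classify_consequence(raw or consequence),
                    cadd=cadd,
                    af_by_source=afs,
                    raw_consequence=raw or consequence,
                ),
                carriers,
            )
        )

    i = 0
    for mmaf in (0.05, 0.01, 0.001, 0.3)[:n_per_mode]:  # 0.001 = boundary, excluded
        add(i, f"DCYPOP{fam_no}{i}", "missense", mmaf, 26.0, passing)
        i += 1
    for raw in ("intronic", "UTR5", "synonymous SNV", "intergenic")[:n_per_mode]:
        add(i, f"DCYNEX{fam_no}{i}", "missense", 0.00005, 24.0, passing, raw=raw)
        i += 1
    for j, cadd in enumerate((19.9, 20.0, 12.0, 3.0)[:n_per_mode]):  # 20.0 = boundary
        carriers = passing if j % 2 == 0 else relaxed
        add(i, f"DCYCAD{fam_no}{i}", "missense", 0.00005, cadd, carriers)
        i += 1
    for pattern in _SEG_DECOY_PATTERNS[family_id][:n_per_mode]:
        add(i, f"DCYSEG{fam_no}{i}", "missense", 0.00005, 28.0, pattern)
        i += 1
    return out


def _panel_annotations(family_id: str) -> list[tuple[VariantAnnotation, tuple[str, ...]]]:
    out = []
    for gene, chrom, pos, ref, alt, rsid, mmaf, cadd, clinvar, carriers in _PANEL_ROWS[family_id]:
        out.append(
            (
                VariantAnnotation(
                    key=VariantKey(chrom, pos, ref, alt),
                    gene=gene,
                    consequence="missense",
                    cadd=cadd,
                    af_by_source=(("swegen_af", mmaf),),
                    rsid=rsid,
                    clinvar=clinvar,
                    raw_consequence="missense",
                ),
                carriers,
            )
        )
    return out


def build_paper_fixture(family_id: str) -> PaperFixture:
    """Reconstruct one study family from its published candidate table."""
    pedigrees = {
        "Family1": _family1_pedigree,
        "Family2": _family2_pedigree,
        "Family3": _family3_pedigree,
    }
    if family_id not in pedigrees:
        raise ValueError(f"unknown fixture family {family_id!r}")
    pedigree = pedigrees[family_id]()
    config = _family_configs()[family_id]
    plan = _CARRIER_PLANS[family_id]
    rows = _load_table(family_id)

    annotations: list[VariantAnnotation] = []
    carrier_sets: list[tuple[str, ...]] = []
    relaxed_index = 0
    for row in rows:
        annotations.append(_row_annotation(row))
        if row["filter"] == 1:
            carrier_sets.append(plan["strict"])
        elif "filter2" in plan:
            carrier_sets.append(plan["filter2"])
        else:
            pool = plan["rotate"]
            carrier_sets.append(plan["strict"] + (pool[relaxed_index % len(pool)],))
            relaxed_index += 1

    for ann, carriers in _decoy_annotations(family_id) + _panel_annotations(family_id):
        annotations.append(ann)
        carrier_sets.append(carriers)

    samples = pedigree.sequenced_ids
    calls = np.zeros((len(annotations), len(samples)), dtype=np.int8)
    for i, carriers in enumerate(carrier_sets):
        for iid in carriers:
            calls[i, samples.index(iid)] = 1
    genotypes = GenotypeMatrix([a.key for a in annotations], samples, calls)
    return PaperFixture(
        family_id=family_id,
        pedigree=pedigree,
        annotations=annotations,
        genotypes=genotypes,
        config=config,
        thresholds=Thresholds(),
        expected=rows,
    )


def build_paper_fixtures() -> dict[str, PaperFixture]:
    """All three study families, deterministic (no randomness involved)."""
    return {fid: build_paper_fixture(fid) for fid in ("Family1", "Family2", "Family3")}


def write_fixture_files(fixture: PaperFixture, out_dir: str | Path) -> dict[str, Path]:
    """Emit a fixture as VCF + PED/sidecar + annotation TSV + config INI."""
    from .pedigree import write_ped
    from .variants import format_frequency, write_vcf

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    fid = fixture.family_id.lower()
    paths = {
        "vcf": out / f"{fid}.vcf",
        "ped": out / f"{fid}.ped",
        "sidecar": out / f"{fid}.phenotypes.tsv",
        "annotations": out / f"{fid}.annotations.tsv",
        "config": out / f"{fid}.config.ini",
    }
    write_vcf(fixture.genotypes, paths["vcf"])
    write_ped(fixture.pedigree, paths["ped"], paths["sidecar"])

    header = "chrom\tpos\tref\talt\tgene\tconsequence\tcadd\tswegen_af\tgnomad_af\trsid\tclinvar\thgvs"
    lines = [header]
    for a in fixture.annotations:
        afs = dict(a.af_by_source)
        lines.append(
            "\t".join(
                [
                    a.key.chrom,
                    str(a.key.pos),
                    a.key.ref,
                    a.key.alt,
                    a.gene,
                    a.raw_consequence or a.consequence,
                    f"{a.cadd:g}",
                    format_frequency(afs["swegen_af"]) if "swegen_af" in afs else ".",
                    format_frequency(afs["gnomad_af"]) if "gnomad_af" in afs else ".",
                    a.rsid or ".",
                    "." if a.clinvar == "absent" else a.clinvar,
                    a.hgvs or ".",
                ]
            )
        )
    paths["annotations"].write_text("\n".join(lines) + "\n")

    cfg_lines = [
        "[family]",
        f"id = {fixture.family_id}",
        f"model = {fixture.config.model}",
        "",
        "[thresholds]",
        f"mmaf_max = {fixture.thresholds.mmaf_population_max}",
        f"cadd_min = {fixture.thresholds.cadd_min:g}",
        f"cadd_highrisk = {fixture.thresholds.cadd_highrisk:g}",
        "",
        "[affected]",
        "ids = " + ", ".join(sorted(
            i.id for i in fixture.pedigree if i.labels & fixture.disease_labels
        )),
        "",
    ]
    for n, st in enumerate(fixture.config.strata, start=1):
        cfg_lines += [
            f"[stratum.{n}]",
            "obligate = " + ", ".join(sorted(st.obligate_carriers)),
            "excluders = " + ", ".join(sorted(st.hard_excluders)),
            "slack_pool = " + ", ".join(sorted(st.slack_pool)),
            f"slack_k = {st.slack_k}",
            "",
        ]
    if fixture.config.recessive_parent_set:
        cfg_lines += [
            "[recessive]",
            "parents = " + ", ".join(sorted(fixture.config.recessive_parent_set)),
            "",
        ]
    paths["config"].write_text("\n".join(cfg_lines))
    return paths
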