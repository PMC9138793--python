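"""Variant annotation: MMAF, consequence classes, rarity/deleteriousness
filters, and the gene-panel / risk-SNP side screens.

The rarity statistic is the **MMAF** (max minor allele frequency): the
maximum of a variant's alternate-allele frequencies over the consulted
population databases (SweGen and gnomAD by default).  A variant absent from
every database has MMAF 0 and is flagged *novel*.  Deleteriousness is the
phred-scaled **CADD** score; CADD > 20 marks a candidate and CADD > 25 a
high-risk variant.  All cutoffs are strict inequalities: the population
filter keeps MMAF < 0.1% (a variant at exactly 0.001 is excluded), the
ultra-rare tier keeps MMAF < 0.0001, and the CADD tiers keep scores strictly
above their cutoffs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

from .variants import VariantKey

log = logging.getLogger("famseg")

# Consequence categories used throughout the cascade.
MISSENSE = "missense"
NONSENSE = "nonsense"
SPLICING = "splicing"
SYNONYMOUS = "synonymous"
FRAMESHIFT = "frameshift"
INFRAME_INDEL = "inframe_indel"
NON_EXONIC = "non_exonic"
OTHER = "other"

#: Categories that survive the exonic filter (protein-altering or splice).
EXONIC_CLASSES = frozenset({MISSENSE, NONSENSE, SPLICING, FRAMESHIFT, INFRAME_INDEL})

#: Annotation-tool vocabulary -> category.  Editable: pass an extended copy
#: to classify_consequence for other annotators.
CONSEQUENCE_MAP: dict[str, str] = {
    "missense": MISSENSE,
    "nonsynonymous snv": MISSENSE,
    "missense_variant": MISSENSE,
    "nonsense": NONSENSE,
    "stopgain": NONSENSE,
    "stop_gained": NONSENSE,
    "stoploss": NONSENSE,
    "splicing": SPLICING,
    "splice_acceptor_variant": SPLICING,
    "splice_donor_variant": SPLICING,
    "splice site": SPLICING,
    "synonymous": SYNONYMOUS,
    "synonymous snv": SYNONYMOUS,
    "synonymous_variant": SYNONYMOUS,
    "frameshift": FRAMESHIFT,
    "frameshift insertion": FRAMESHIFT,
    "frameshift deletion": FRAMESHIFT,
    "frameshift_variant": FRAMESHIFT,
    "nonframeshift insertion": INFRAME_INDEL,
    "nonframeshift deletion": INFRAME_INDEL,
    "inframe_indel": INFRAME_INDEL,
    "intronic": NON_EXONIC,
    "intergenic": NON_EXONIC,
    "utr3": NON_EXONIC,
    "utr5": NON_EXONIC,
    "upstream": NON_EXONIC,
    "downstream": NON_EXONIC,
    "ncrna_intronic": NON_EXONIC,
    "non_exonic": NON_EXONIC,
}

CLINVAR_CLASSES = (
    "pathogenic",
    "likely_pathogenic",
    "vus",
    "likely_benign",
    "benign",
    "absent",
)


def classify_consequence(raw_label: str, mapping: dict[str, str] | None = None) -> str:
    """Map an annotation-tool consequence label onto the category enum.

    Unknown labels map to ``other`` with a logged warning rather than an
    error, so one exotic annotation row cannot abort a whole run.
    """
    table = CONSEQUENCE_MAP if mapping is None else mapping
    category = table.get(str(raw_label).strip().lower())
    if category is None:
        log.warning("unknown consequence label %r -> other", raw_label)
        return OTHER
    return category


def compute_mmaf(af_by_source: dict[str, float]) -> float:
    """Max alternate-allele frequency across population databases.

    An empty mapping (variant unseen in every database) gives 0; such a
    variant is *novel* (``is_novel``).  Frequencies outside [0, 1] raise.
    """
    for source, value in af_by_source.items():
        if not 0.0 <= value <= 1.0:
            raise ValueError(f"allele frequency {value} for {source} outside [0, 1]")
    if not af_by_source:
        return 0.0
    return max(af_by_source.values())


def is_novel(af_by_source: dict[str, float]) -> bool:
    return not af_by_source


@dataclass(frozen=True)
class VariantAnnotation:
    """One variant's annotation: identity, gene, consequence, rarity, CADD."""

    key: VariantKey
    gene: str
    consequence: str  # category (see module constants)
    cadd: float
    af_by_source: tuple[tuple[str, float], ...] = ()
    rsid: str | None = None
    hgvs: str | None = None
    clinvar: str = "absent"
    raw_consequence: str | None = None

    def __post_init__(self) -> None:
        if self.cadd < 0:
            raise ValueError(f"CADD must be >= 0, got {self.cadd}")

    @property
    def mmaf(self) -> float:
        return compute_mmaf(dict(self.af_by_source))

    @property
    def novel(self) -> bool:
        return is_novel(dict(self.af_by_source))

    @classmethod
    def from_raw(cls, key: VariantKey, raw: dict) -> "VariantAnnotation":
        """Build from a read_annotation_table row dict."""
        raw_cons = raw["consequence"]
        return cls(
            key=key,
            gene=raw["gene"],
            consequence=classify_consequence(raw_cons),
            cadd=float(raw["cadd"]),
            af_by_source=tuple(sorted(raw.get("af_by_source", {}).items())),
            rsid=raw.get("rsid"),
            hgvs=raw.get("hgvs"),
            clinvar=raw.get("clinvar") or "absent",
            raw_consequence=raw_cons,
        )


def build_annotations(raw_map: dict[VariantKey, dict]) -> list[VariantAnnotation]:
    return [VariantAnnotation.from_raw(k, raw) for k, raw in raw_map.items()]


@dataclass(frozen=True)
class Thresholds:
    """The cascade's tunable cutoffs (all strict inequalities)."""

    mmaf_population_max: float = 0.001
    mmaf_ultrarare: float = 0.0001
    cadd_min: float = 20.0
    cadd_highrisk: float = 25.0
    panel_mmaf_max: float = 0.2

    def __post_init__(self) -> None:
        for name in ("mmaf_population_max", "mmaf_ultrarare", "panel_mmaf_max"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name}={value} outside [0, 1]")
        if self.cadd_highrisk < self.cadd_min:
            raise ValueError("cadd_highrisk must be >= cadd_min")


# CADD tiers
TIER_FAIL = "fail"
TIER_CANDIDATE = "candidate"
TIER_HIGH_RISK = "high_risk"


def population_filter(
    variants: list[VariantAnnotation], thresholds: Thresholds = Thresholds()
) -> list[VariantAnnotation]:
    """Keep variants rarer than the population cutoff (MMAF strictly <)."""
    return [v for v in variants if v.mmaf < thresholds.mmaf_population_max]


def exonic_filter(variants: list[VariantAnnotation]) -> list[VariantAnnotation]:
    """Keep protein-altering and splice variants; drop synonymous/non-exonic/other."""
    return [v for v in variants if v.consequence in EXONIC_CLASSES]


def cadd_tier(cadd: float, thresholds: Thresholds = Thresholds()) -> str:
    if cadd > thresholds.cadd_highrisk:
        return TIER_HIGH_RISK
    if cadd > thresholds.cadd_min:
        return TIER_CANDIDATE
    return TIER_FAIL


def cadd_tiers(
    variants: list[VariantAnnotation], thresholds: Thresholds = Thresholds()
) -> dict[VariantKey, str]:
    """Assign each variant a deleteriousness tier by its CADD score."""
    return {v.key: cadd_tier(v.cadd, thresholds) for v in variants}


# ---------------------------------------------------------------------------
# Gene-panel and known-SNP side screens
# ---------------------------------------------------------------------------

def load_panel_genes() -> frozenset[str]:
    """The built-in 64-gene hereditary-breast-cancer panel."""
    text = resources.files("famseg").joinpath("data/panel_genes.txt").read_text()
    return frozenset(line.strip() for line in text.splitlines() if line.strip())


def load_risk_snps() -> list[str]:
    """Built-in breast-cancer risk-SNP rsIDs (user-extensible list)."""
    text = resources.files("famseg").joinpath("data/risk_snps.txt").read_text()
    return [line.strip() for line in text.splitlines() if line.strip() and not line.startswith("#")]


@dataclass(frozen=True)
class PanelHit:
    gene: str
    key: VariantKey
    rsid: str | None
    mmaf: float
    cadd: float
    clinvar: str


def panel_screen(
    variants: list[VariantAnnotation],
    panel_genes: frozenset[str] | None = None,
    thresholds: Thresholds = Thresholds(),
) -> list[PanelHit]:
    """Report variants in known hereditary-cancer panel genes.

    This is a side channel: hits are reported with their ClinVar assertion
    but never removed from (or added to) the main cascade.  The frequency
    cut is ``panel_mmaf_max`` (strict <).
    """
    panel = load_panel_genes() if panel_genes is None else panel_genes
    if not panel:
        raise ValueError("empty panel gene list")
    return [
        PanelHit(v.gene, v.key, v.rsid, v.mmaf, v.cadd, v.clinvar)
        for v in variants
        if v.gene in panel and v.mmaf < thresholds.panel_mmaf_max
    ]


@dataclass(frozen=True)
class SnpReportRow:
    rsid: str
    observed: bool
    carriers: tuple[str, ...] = ()
    affected_carriers: tuple[str, ...] = ()


def known_snp_screen(
    genotypes,
    variants: list[VariantAnnotation],
    snp_list: list[str],
    pedigree,
    disease_labels: frozenset[str] | None = None,
) -> list[SnpReportRow]:
    """Per-SNP carrier report for a user-supplied list of risk rsIDs.

    For each rsID found in the data, lists carrier ids and which of them are
    affected (any phenotype label, or any label in ``disease_labels`` when
    given).  rsIDs absent from the data yield a "not observed" row.
    """
    by_rsid = {v.rsid: v for v in variants if v.rsid}
    rows: list[SnpReportRow] = []
    for rsid in snp_list:
        ann = by_rsid.get(rsid)
        if ann is None or ann.key not in genotypes._vidx:
            rows.append(SnpReportRow(rsid, observed=False))
            continue
        calls = genotypes.row(ann.key)
        carriers = tuple(s for s in genotypes.individuals if calls[s] in (1, 2))
        affected = []
        for iid in carriers:
            labels = pedigree[iid].labels if iid in pedigree else frozenset()
            hit = bool(labels) if disease_labels is None else bool(labels & disease_labels)
            if hit:
                affected.append(iid)
        rows.append(SnpReportRow(rsid, True, carriers, tuple(affected)))
    return rows
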