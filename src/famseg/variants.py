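"""Variant containers and file I/O: multi-sample VCF, annotation tables,
candidate tables, per-family configuration.

Coordinates are 1-based hg19 with ``chr``-prefixed names; bare names
("17") are normalized on read.  Multi-allelic VCF records are decomposed into
one biallelic key per alternate allele, with genotypes recoded against that
allele, so everything downstream sees single-alt keys only.  Phasing is
ignored (carrier logic is phase-free).
"""

from __future__ import annotations

import configparser
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pysam

MISSING = -1  # allele count for ./.

DEFAULT_AF_SOURCES = ("swegen_af", "gnomad_af")


def normalize_chrom(name: str) -> str:
    name = str(name).strip()
    if name.lower().startswith("chr"):
        return "chr" + name[3:]
    return "chr" + name


@dataclass(frozen=True, order=True)
class VariantKey:
    """One biallelic site: chrom, 1-based pos, ref and a single alt allele."""

    chrom: str
    pos: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise ValueError(f"ref and alt identical at {self.chrom}:{self.pos}")
        if "," in self.alt:
            raise ValueError("VariantKey takes a single alt allele; decompose first")

    @property
    def locus(self) -> str:
        return f"{self.chrom}:{self.pos}"

    def __str__(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}>{self.alt}"


class GenotypeMatrix:
    """Dense alt-allele dosage matrix: variants x individuals.

    Cell values are 0/1/2 alt-allele counts or ``MISSING``.  Hemizygous male
    X calls are normalized to 0 or 2 and flagged in ``hemizygous``.
    """

    def __init__(
        self,
        variants: list[VariantKey],
        individuals: list[str],
        calls: np.ndarray,
        hemizygous: np.ndarray | None = None,
    ) -> None:
        calls = np.asarray(calls, dtype=np.int8)
        if calls.shape != (len(variants), len(individuals)):
            raise ValueError(
                f"calls shape {calls.shape} != ({len(variants)}, {len(individuals)})"
            )
        self.variants = list(variants)
        self.individuals = list(individuals)
        self.calls = calls
        self.hemizygous = (
            np.zeros_like(calls, dtype=bool) if hemizygous is None else np.asarray(hemizygous, bool)
        )
        self._vidx = {v: i for i, v in enumerate(self.variants)}
        self._iidx = {s: j for j, s in enumerate(self.individuals)}

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def allele_count(self, key: VariantKey, individual_id: str) -> int:
        return int(self.calls[self._vidx[key], self._iidx[individual_id]])

    def row(self, key: VariantKey) -> dict[str, int]:
        i = self._vidx[key]
        return {s: int(self.calls[i, j]) for j, s in enumerate(self.individuals)}

    def subset_individuals(self, ids: list[str]) -> "GenotypeMatrix":
        cols = [self._iidx[s] for s in ids]
        return GenotypeMatrix(
            self.variants, list(ids), self.calls[:, cols], self.hemizygous[:, cols]
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        return (
            self.variants == other.variants
            and self.individuals == other.individuals
            and np.array_equal(self.calls, other.calls)
        )


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_vcf(path: str | Path, sample_subset: set[str] | None = None) -> GenotypeMatrix:
    """Read a multi-sample VCF into a GenotypeMatrix.

    Multi-allelic records are decomposed: a site with alts C,T yields two
    VariantKeys, and a 1/2 genotype contributes one alt allele to each.  Any
    missing allele in GT marks the call missing for every decomposed key.
    """
    with pysam.VariantFile(str(path)) as vcf:
        header_samples = list(vcf.header.samples)
        if sample_subset is not None:
            absent = sorted(set(sample_subset) - set(header_samples))
            if absent:
                raise ValueError(f"{path}: samples not in VCF header: {absent}")
            samples = [s for s in header_samples if s in sample_subset]
        else:
            samples = header_samples
        variants: list[VariantKey] = []
        rows: list[list[int]] = []
        for rec in vcf:
            chrom = normalize_chrom(rec.chrom)
            alts = rec.alts or ()
            gts = [rec.samples[s].get("GT", (None, None)) for s in samples]
            for alt_index, alt in enumerate(alts, start=1):
                key = VariantKey(chrom, rec.pos, rec.ref, alt)
                row = []
                for gt in gts:
                    if gt is None or any(a is None for a in gt):
                        row.append(MISSING)
                    else:
                        row.append(sum(1 for a in gt if a == alt_index))
                variants.append(key)
                rows.append(row)
    calls = (
        np.array(rows, dtype=np.int8)
        if rows
        else np.zeros((0, len(samples)), dtype=np.int8)
    )
    return GenotypeMatrix(variants, samples, calls)


_GT_STR = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(matrix: GenotypeMatrix, path: str | Path) -> None:
    """Write a GenotypeMatrix as an uncompressed VCF v4.2 text file.

    Hemizygous calls are written diploid (2 -> 1/1); the round trip preserves
    keys, sample order and alt-allele counts exactly.
    """
    chroms = []
    for v in matrix.variants:
        if v.chrom not in chroms:
            chroms.append(v.chrom)
    lines = ["##fileformat=VCFv4.2"]
    lines += [f"##contig=<ID={c}>" for c in chroms]
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(matrix.individuals)
    )
    for i, v in enumerate(matrix.variants):
        gts = "\t".join(_GT_STR[int(ac)] for ac in matrix.calls[i])
        lines.append(f"{v.chrom}\t{v.pos}\t.\t{v.ref}\t{v.alt}\t.\t.\t.\tGT\t{gts}")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Annotation tables
# ---------------------------------------------------------------------------

def _parse_af(token: str) -> float | None:
    token = str(token).strip()
    if token in (".", "", "nan", "NA"):
        return None  # absent: not observed in that database (distinct from 0)
    value = float(token)
    if not 0.0 <= value <= 1.0:
        raise ValueError(f"allele frequency {value} outside [0, 1]")
    return value


def read_annotation_table(
    path: str | Path, af_columns: tuple[str, ...] = DEFAULT_AF_SOURCES
) -> dict[VariantKey, dict]:
    """Read a tab-separated per-variant annotation table.

    Required header columns: chrom, pos, ref, alt, gene, consequence, cadd.
    Optional: rsid, clinvar, hgvs, plus the per-database allele-frequency
    columns named in ``af_columns``.  A "." or empty frequency cell means
    *absent* (not observed in that database), which is not the same as an
    explicit 0.
    """
    lines = Path(path).read_text().splitlines()
    if not lines:
        raise ValueError(f"{path}: empty annotation table")
    header = lines[0].rstrip("\n").split("\t")
    col = {name.lower(): i for i, name in enumerate(header)}
    for required in ("chrom", "pos", "ref", "alt", "gene", "consequence", "cadd"):
        if required not in col:
            raise ValueError(f"{path}: missing required column {required!r}")
    out: dict[VariantKey, dict] = {}
    for rowno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")

        def get(name: str) -> str | None:
            i = col.get(name)
            if i is None or i >= len(fields):
                return None
            return fields[i]

        key = VariantKey(
            normalize_chrom(get("chrom")), int(get("pos")), get("ref"), get("alt")
        )
        if key in out:
            raise ValueError(f"{path}: row {rowno}: duplicate variant {key}")
        try:
            cadd = float(get("cadd"))
        except (TypeError, ValueError) as exc:
            raise ValueError(f"{path}: row {rowno}: unparseable CADD: {exc}") from exc
        af_by_source = {}
        for src in af_columns:
            if src.lower() in col:
                value = _parse_af(fields[col[src.lower()]] if col[src.lower()] < len(fields) else ".")
                if value is not None:
                    af_by_source[src] = value
        rsid = get("rsid")
        out[key] = {
            "gene": get("gene"),
            "consequence": get("consequence"),
            "cadd": cadd,
            "af_by_source": af_by_source,
            "rsid": None if rsid in (None, ".", "") else rsid,
            "clinvar": get("clinvar") or None,
            "hgvs": get("hgvs") or None,
        }
    return out


def format_frequency(value: float) -> str:
    """Fixed-notation frequency, as population databases print it (no 1e-05)."""
    if value == 0:
        return "0"
    text = f"{value:.10f}".rstrip("0")
    return text.rstrip(".")


CANDIDATE_COLUMNS = ("Filter", "Gene", "Position", "Ref/Alt", "SNP", "Type", "Change", "MMAF", "CADD")


def write_candidate_table(candidates, path: str | Path) -> None:
    """Write the candidate-variant report table.

    Columns mirror the per-family report layout (Filter / Gene / Position /
    Ref/Alt / SNP / Type / Change / MMAF / CADD); rows sorted by filter
    stratum ascending, then CADD descending, ties broken by position
    ascending.  ``candidates`` is an iterable of
    :class:`famseg.segregation.Candidate`.
    """
    ordered = sorted(
        candidates,
        key=lambda c: (c.filter_index, -c.annotation.cadd, c.annotation.key.chrom, c.annotation.key.pos),
    )
    lines = ["\t".join(CANDIDATE_COLUMNS)]
    for c in ordered:
        a = c.annotation
        lines.append(
            "\t".join(
                [
                    str(c.filter_index),
                    a.gene,
                    a.key.locus,
                    f"{a.key.ref}/{a.key.alt}",
                    a.rsid or ".",
                    a.consequence,
                    a.hgvs or ".",
                    format_frequency(a.mmaf),
                    f"{a.cadd:g}",
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Per-family configuration
# ---------------------------------------------------------------------------

@dataclass
class FamilyConfig:
    """Fully resolved per-family run configuration."""

    family_id: str
    model: str  # "dominant" | "recessive"
    affected: frozenset[str]
    strata: list  # list[famseg.segregation.Stratum]
    mmaf_max: float = 0.001
    mmaf_ultrarare: float = 0.0001
    cadd_min: float = 20.0
    cadd_highrisk: float = 25.0
    panel_mmaf_max: float = 0.2
    recessive_parent_set: frozenset[str] = frozenset()
    extra: dict = field(default_factory=dict)


def _ids(raw: str) -> frozenset[str]:
    return frozenset(tok.strip() for tok in raw.replace(",", " ").split() if tok.strip())


def read_family_config(path: str | Path, pedigree=None) -> FamilyConfig:
    """Parse an INI-style per-family config.

    Sections: ``[family]`` (id, model), ``[thresholds]``, ``[affected]``,
    ``[obligate_carriers]``, ``[excluders]``, ``[slack_pool]`` (ids + k), and
    optionally explicit ``[stratum.N]`` sections for families whose two
    filters differ by more than a slack allowance (each with obligate,
    excluders, slack_pool, slack_k).  Defaults: mmaf_max 0.001, cadd_min 20,
    cadd_highrisk 25, slack k 1.  If ``pedigree`` is given every id is
    checked against it.
    """
    from .segregation import Stratum  # local import to avoid a cycle

    parser = configparser.ConfigParser()
    read = parser.read(str(path))
    if not read:
        raise FileNotFoundError(f"config file not found: {path}")

    family_id = parser.get("family", "id", fallback="family")
    model = parser.get("family", "model", fallback="dominant")
    if model not in ("dominant", "recessive"):
        raise ValueError(f"{path}: unknown inheritance model {model!r}")

    thresholds = dict(
        mmaf_max=parser.getfloat("thresholds", "mmaf_max", fallback=0.001),
        mmaf_ultrarare=parser.getfloat("thresholds", "mmaf_ultrarare", fallback=0.0001),
        cadd_min=parser.getfloat("thresholds", "cadd_min", fallback=20.0),
        cadd_highrisk=parser.getfloat("thresholds", "cadd_highrisk", fallback=25.0),
        panel_mmaf_max=parser.getfloat("thresholds", "panel_mmaf_max", fallback=0.2),
    )

    affected = _ids(parser.get("affected", "ids", fallback=""))

    stratum_sections = sorted(s for s in parser.sections() if s.startswith("stratum."))
    strata: list[Stratum] = []
    if stratum_sections:
        for name in stratum_sections:
            sec = parser[name]
            strata.append(
                Stratum(
                    name=name.split(".", 1)[1],
                    obligate_carriers=_ids(sec.get("obligate", "")),
                    hard_excluders=_ids(sec.get("excluders", "")),
                    slack_pool=_ids(sec.get("slack_pool", "")),
                    slack_k=int(sec.get("slack_k", "0")),
                )
            )
    else:
        obligate = _ids(parser.get("obligate_carriers", "ids", fallback=""))
        excluders = _ids(parser.get("excluders", "ids", fallback=""))
        slack_pool = _ids(parser.get("slack_pool", "ids", fallback=""))
        slack_k = parser.getint("slack_pool", "k", fallback=1)
        if slack_k < 0:
            raise ValueError(f"{path}: slack k must be >= 0, got {slack_k}")
        strata = [
            Stratum("strict", obligate, excluders, slack_pool, 0),
            Stratum("slack", obligate, excluders, slack_pool, slack_k if slack_pool else 0),
        ]

    for st in strata:
        if st.slack_k < 0:
            raise ValueError(f"{path}: stratum {st.name}: slack_k must be >= 0")

    recessive_parents = _ids(parser.get("recessive", "parents", fallback=""))

    if pedigree is not None:
        known = set(pedigree.individuals)
        mentioned: set[str] = set(affected) | set(recessive_parents)
        for st in strata:
            mentioned |= st.obligate_carriers | st.hard_excluders | st.slack_pool
        unknown = sorted(mentioned - known)
        if unknown:
            raise ValueError(f"{path}: ids not present in pedigree: {unknown}")

    return FamilyConfig(
        family_id=family_id,
        model=model,
        affected=affected,
        strata=strata,
        recessive_parent_set=recessive_parents,
        **thresholds,
    )
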