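"""End-to-end orchestration and reporting: run a family cascade from files,
summarize candidate sets, and record a reproducibility manifest."""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

from . import __version__
from .annotation import (
    TIER_HIGH_RISK,
    Thresholds,
    build_annotations,
    known_snp_screen,
    load_risk_snps,
    panel_screen,
)
from .pedigree import read_ped
from .segregation import (
    SLACK_ONLY,
    STRICT,
    Candidate,
    Funnel,
    SegregationConfig,
    run_family_cascade,
)
from .variants import (
    FamilyConfig,
    read_annotation_table,
    read_family_config,
    read_vcf,
    write_candidate_table,
)


def config_to_segregation(config: FamilyConfig) -> tuple[SegregationConfig, Thresholds]:
    seg = SegregationConfig(
        model=config.model,
        strata=list(config.strata),
        recessive_parent_set=config.recessive_parent_set,
    )
    thresholds = Thresholds(
        mmaf_population_max=config.mmaf_max,
        mmaf_ultrarare=config.mmaf_ultrarare,
        cadd_min=config.cadd_min,
        cadd_highrisk=config.cadd_highrisk,
        panel_mmaf_max=config.panel_mmaf_max,
    )
    return seg, thresholds


@dataclass
class RunManifest:
    """What went into a run: file digests, config, version, seed, funnel.

    Re-running on identical inputs reproduces everything but the timestamp.
    """

    inputs: dict[str, str]
    config_snapshot: str
    version: str = __version__
    seed: int | None = None
    funnel: dict[str, int] = field(default_factory=dict)
    timestamp: str = ""

    @classmethod
    def create(cls, paths: dict[str, Path], config_text: str, funnel: Funnel, seed=None):
        digests = {
            name: hashlib.sha256(Path(p).read_bytes()).hexdigest() for name, p in paths.items()
        }
        return cls(
            inputs=digests,
            config_snapshot=config_text,
            seed=seed,
            funnel=funnel.as_dict(),
            timestamp=datetime.now(timezone.utc).isoformat(),
        )

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2, sort_keys=True)


@dataclass
class RunResult:
    family_id: str
    candidates: list[Candidate]
    funnel: Funnel
    panel_hits: list
    snp_rows: list
    manifest: RunManifest


def run_from_files(
    vcf: str | Path,
    ped: str | Path,
    annotations: str | Path,
    config: str | Path,
    out_dir: str | Path,
    sidecar: str | Path | None = None,
    snp_list: list[str] | None = None,
    seed: int | None = None,
) -> RunResult:
    """Full pipeline from input files to report files in ``out_dir``.

    Writes per-stratum candidate TSVs, a combined table, the funnel, panel
    and SNP screens, and the manifest.  Raises ValueError / FileNotFoundError
    on validation problems (the CLI maps those to exit code 2).
    """
    for path in (vcf, ped, annotations, config):
        if not Path(path).exists():
            raise FileNotFoundError(f"input file not found: {path}")

    pedigree = read_ped(ped, sidecar)
    family_config = read_family_config(config, pedigree)
    seg_config, thresholds = config_to_segregation(family_config)
    matrix = read_vcf(vcf)
    missing = sorted(seg_config.all_ids() - set(matrix.individuals))
    if missing:
        raise ValueError(f"config references samples absent from VCF: {missing}")
    raw = read_annotation_table(annotations)
    annos = build_annotations(raw)
    known_keys = set(matrix._vidx)
    unmatched = [a for a in annos if a.key not in known_keys]
    if unmatched:
        raise ValueError(
            f"{len(unmatched)} annotated variants missing from VCF, first: {unmatched[0].key}"
        )

    candidates, funnel = run_family_cascade(annos, matrix, seg_config, thresholds)
    panel_hits = panel_screen(annos, thresholds=thresholds)
    snps = snp_list if snp_list is not None else load_risk_snps()
    snp_rows = known_snp_screen(matrix, annos, snps, pedigree)

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_candidate_table(candidates, out / "candidates.tsv")
    write_candidate_table([c for c in candidates if c.stratum == STRICT], out / "candidates_strict.tsv")
    write_candidate_table(
        [c for c in candidates if c.stratum == SLACK_ONLY], out / "candidates_slack.tsv"
    )
    (out / "funnel.json").write_text(json.dumps(funnel.as_dict(), indent=2) + "\n")

    panel_lines = ["gene\tposition\tref_alt\trsid\tmmaf\tcadd\tclinvar"]
    for h in panel_hits:
        panel_lines.append(
            f"{h.gene}\t{h.key.locus}\t{h.key.ref}/{h.key.alt}\t{h.rsid or '.'}"
            f"\t{h.mmaf:g}\t{h.cadd:g}\t{h.clinvar}"
        )
    (out / "panel_screen.tsv").write_text("\n".join(panel_lines) + "\n")

    snp_lines = ["rsid\tobserved\tcarriers\taffected_carriers"]
    for r in snp_rows:
        snp_lines.append(
            f"{r.rsid}\t{'yes' if r.observed else 'not observed'}"
            f"\t{','.join(r.carriers) or '.'}\t{','.join(r.affected_carriers) or '.'}"
        )
    (out / "snp_screen.tsv").write_text("\n".join(snp_lines) + "\n")

    manifest = RunManifest.create(
        {"vcf": Path(vcf), "ped": Path(ped), "annotations": Path(annotations), "config": Path(config)},
        Path(config).read_text(),
        funnel,
        seed,
    )
    (out / "manifest.json").write_text(manifest.to_json() + "\n")
    return RunResult(family_config.family_id, candidates, funnel, panel_hits, snp_rows, manifest)


def summarize(
    candidates_by_family: dict[str, list[Candidate]], thresholds: Thresholds = Thresholds()
) -> dict:
    """Per-family totals, per-stratum splits, high-risk and ultra-rare subsets."""
    summary: dict = {}
    for family_id, candidates in candidates_by_family.items():
        strict = [c for c in candidates if c.stratum == STRICT]
        slack = [c for c in candidates if c.stratum == SLACK_ONLY]
        summary[family_id] = {
            "total": len(candidates),
            "strict": len(strict),
            "slack_only": len(slack),
            "high_risk": sum(1 for c in candidates if c.tier == TIER_HIGH_RISK),
            "high_risk_strict": sum(1 for c in strict if c.tier == TIER_HIGH_RISK),
            "ultra_rare": sum(
                1 for c in candidates if c.annotation.mmaf < thresholds.mmaf_ultrarare
            ),
        }
    return summary


def render_summary(summary: dict) -> str:
    lines = [
        f"{'family':<10}{'total':>6}{'strict':>8}{'slack':>7}{'high_risk':>11}{'ultra_rare':>12}"
    ]
    for family_id, s in summary.items():
        lines.append(
            f"{family_id:<10}{s['total']:>6}{s['strict']:>8}{s['slack_only']:>7}"
            f"{s['high_risk']:>11}{s['ultra_rare']:>12}"
        )
    return "\n".join(lines)
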