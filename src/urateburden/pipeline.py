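"""End-to-end orchestration: HWE QC -> exclusion -> frequencies ->
reference comparisons -> risk-allele burden, with table rendering.

Stage order is fixed and every intermediate is retained on the report:

1. HWE chi-square per SNP x population,
2. exclusion of loci deviant in *every* subgroup,
3. allele counts/frequencies on the retained loci,
4. per-locus 2x2 tests against the reference at the configured threshold,
5. per-population risk-burden summaries.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from . import burden as burden_mod
from . import comparison as comparison_mod
from . import frequency as frequency_mod
from . import hwe as hwe_mod
from .burden import RiskBurdenSummary, risk_burden_summary, summary_to_dict
from .comparison import ComparisonResult, compare_population_to_reference
from .frequency import genotype_to_allele_counts
from .hwe import ExclusionDecision, HweResult, hwe_chi_square_test, hwe_exclusion_filter
from .types import (
    AlleleCounts,
    GenotypeCounts,
    ReferencePanel,
    SnpAnnotation,
    ValidationError,
)

__all__ = [
    "PipelineConfig",
    "AnalysisReport",
    "run_pipeline",
    "render_report",
    "report_from_dict",
]

logger = logging.getLogger("urateburden")


@dataclass(frozen=True)
class PipelineConfig:
    threshold: float = comparison_mod.DEFAULT_THRESHOLD
    hwe_threshold: float = hwe_mod.DEFAULT_HWE_THRESHOLD
    yates: bool = False


@dataclass
class AnalysisReport:
    config: PipelineConfig
    populations: list[str]
    hwe_results: list[HweResult]
    exclusions: list[ExclusionDecision]
    excluded_rs_ids: list[str]
    retained_rs_ids: list[str]
    allele_counts: list[AlleleCounts]
    comparisons: list[ComparisonResult]
    summaries: list[RiskBurdenSummary]

    def to_dict(self) -> dict:
        return {
            "config": {
                "threshold": self.config.threshold,
                "hwe_threshold": self.config.hwe_threshold,
                "yates": self.config.yates,
            },
            "populations": list(self.populations),
            "hwe": [
                {
                    "rs_id": r.rs_id,
                    "population": r.population,
                    "chi_square": r.chi_square,
                    "df": r.df,
                    "p_value": r.p_value,
                    "expected": [r.expected_aa, r.expected_ab, r.expected_bb],
                    "monomorphic": r.monomorphic,
                }
                for r in self.hwe_results
            ],
            "exclusions": [
                {
                    "rs_id": d.rs_id,
                    "exclude": d.exclude,
                    "threshold": d.threshold,
                    "deviant": d.deviant,
                    "p_values": d.p_values,
                }
                for d in self.exclusions
            ],
            "excluded_rs_ids": list(self.excluded_rs_ids),
            "retained_rs_ids": list(self.retained_rs_ids),
            "allele_counts": [
                {
                    "rs_id": c.rs_id,
                    "population": c.population,
                    "count_a": c.count_a,
                    "count_b": c.count_b,
                    "allele_a": c.allele_a,
                    "allele_b": c.allele_b,
                }
                for c in self.allele_counts
            ],
            "comparisons": [comparison_mod.comparison_to_dict(r) for r in self.comparisons],
            "risk_burden": [summary_to_dict(s) for s in self.summaries],
        }


def _stage(stage: str, rs_id: str | None = None, population: str | None = None):
    where = ", ".join(x for x in (rs_id, population) if x)
    return f"stage {stage}" + (f" ({where})" if where else "")


def run_pipeline(
    annotations: Sequence[SnpAnnotation],
    counts: Sequence[GenotypeCounts],
    reference: ReferencePanel,
    config: PipelineConfig | None = None,
) -> AnalysisReport:
    """Run the full analysis; any stage error aborts naming stage, SNP, population."""
    config = config or PipelineConfig()
    if not counts:
        raise ValidationError("empty genotype counts table")
    by_rs = {a.rs_id: a for a in annotations}
    unknown = sorted({g.rs_id for g in counts} - set(by_rs))
    if unknown:
        raise ValidationError(f"unannotated SNP(s) in counts: {', '.join(unknown)}")
    present_rs = {g.rs_id for g in counts}
    reference.require_coverage([a for a in annotations if a.rs_id in present_rs])

    populations = sorted({g.population for g in counts})
    ordered_rs = [a.rs_id for a in annotations if a.rs_id in present_rs]

    # stage 1: HWE per SNP x population
    hwe_results: list[HweResult] = []
    for g in counts:
        try:
            hwe_results.append(hwe_chi_square_test(g))
        except Exception as exc:
            raise ValidationError(
                f"{_stage('hwe', g.rs_id, g.population)}: {exc}") from exc
    logger.info("[hwe] tested %d SNP x population cells", len(hwe_results))

    # stage 2: exclusion of loci deviant in every subgroup
    exclusions: list[ExclusionDecision] = []
    for rs_id in ordered_rs:
        per_locus = [r for r in hwe_results if r.rs_id == rs_id]
        try:
            exclusions.append(hwe_exclusion_filter(per_locus, config.hwe_threshold))
        except Exception as exc:
            raise ValidationError(f"{_stage('exclusion', rs_id)}: {exc}") from exc
    excluded = [d.rs_id for d in exclusions if d.exclude]
    retained = [d.rs_id for d in exclusions if not d.exclude]
    logger.info("[exclusion] excluded %d, retained %d loci", len(excluded), len(retained))

    # stage 3: allele counts on retained loci
    allele_counts: list[AlleleCounts] = []
    for g in counts:
        if g.rs_id not in retained:
            continue
        try:
            allele_counts.append(genotype_to_allele_counts(g, by_rs[g.rs_id]))
        except Exception as exc:
            raise ValidationError(
                f"{_stage('frequency', g.rs_id, g.population)}: {exc}") from exc

    # stage 4: comparisons vs reference
    comparisons: list[ComparisonResult] = []
    for c in allele_counts:
        try:
            comparisons.append(
                compare_population_to_reference(
                    c, reference[c.rs_id], by_rs[c.rs_id],
                    threshold=config.threshold, yates=config.yates))
        except Exception as exc:
            raise ValidationError(
                f"{_stage('comparison', c.rs_id, c.population)}: {exc}") from exc
    logger.info("[comparison] %d locus x population tests vs %s",
                len(comparisons), reference.label)

    # stage 5: risk burden per population
    summaries: list[RiskBurdenSummary] = []
    for population in populations:
        per_pop = [r for r in comparisons if r.population == population]
        try:
            summaries.append(risk_burden_summary(per_pop))
        except Exception as exc:
            raise ValidationError(
                f"{_stage('risk_burden', population=population)}: {exc}") from exc

    return AnalysisReport(
        config=config,
        populations=populations,
        hwe_results=hwe_results,
        exclusions=exclusions,
        excluded_rs_ids=excluded,
        retained_rs_ids=retained,
        allele_counts=allele_counts,
        comparisons=comparisons,
        summaries=summaries,
    )


def render_report(
    report: AnalysisReport,
    out_dir: str | Path,
    annotations: Sequence[SnpAnnotation] | None = None,
    counts: Sequence[GenotypeCounts] | None = None,
) -> dict[str, Path]:
    """Write the frequency, HWE, comparison and burden tables plus a JSON dump.

    Repeated invocation on the same report produces identical bytes.  The
    frequency table needs the original annotations and counts; it is skipped
    when they are not supplied.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    if annotations is not None and counts is not None:
        retained_counts = [g for g in counts if g.rs_id in report.retained_rs_ids]
        path = out_dir / "frequencies.tsv"
        frequency_mod.write_frequency_table(retained_counts, list(annotations), path)
        written["frequencies"] = path

    path = out_dir / "hwe_matrix.tsv"
    hwe_mod.write_hwe_matrix(report.hwe_results, path)
    written["hwe_matrix"] = path

    path = out_dir / "comparisons.tsv"
    comparison_mod.write_comparison_table(report.comparisons, path)
    written["comparisons"] = path

    path = out_dir / "risk_burden.tsv"
    burden_mod.write_burden_table(report.summaries, path)
    written["risk_burden"] = path

    path = out_dir / "report.json"
    path.write_text(json.dumps(report.to_dict(), indent=2) + "\n")
    written["report"] = path
    return written


def report_from_dict(payload: dict) -> AnalysisReport:
    """Rebuild an :class:`AnalysisReport` from its JSON form (inverse of to_dict)."""
    config = PipelineConfig(**payload["config"])
    hwe_results = [
        HweResult(
            rs_id=r["rs_id"], population=r["population"],
            chi_square=r["chi_square"], df=r["df"], p_value=r["p_value"],
            expected_aa=r["expected"][0], expected_ab=r["expected"][1],
            expected_bb=r["expected"][2], monomorphic=r["monomorphic"],
        )
        for r in payload["hwe"]
    ]
    exclusions = [
        ExclusionDecision(
            rs_id=d["rs_id"], exclude=d["exclude"], threshold=d["threshold"],
            deviant=dict(d["deviant"]), p_values=dict(d["p_values"]),
        )
        for d in payload["exclusions"]
    ]
    allele_counts = [
        AlleleCounts(
            rs_id=c["rs_id"], population=c["population"],
            count_a=c["count_a"], count_b=c["count_b"],
            allele_a=c["allele_a"], allele_b=c["allele_b"],
        )
        for c in payload["allele_counts"]
    ]
    comparisons = [
        ComparisonResult(
            rs_id=r["rs_id"], population=r["population"], reference=r["reference"],
            contingency=tuple(tuple(row) for row in r["contingency"]),
            test_used=r["test_used"], statistic=r["statistic"],
            p_value=r["p_value"], threshold=r["threshold"],
            significant=r["significant"], risk_allele=r["risk_allele"],
            risk_allele_freq_population=r["risk_allele_freq_population"],
            risk_allele_freq_reference=r["risk_allele_freq_reference"],
            risk_allele_higher=r["risk_allele_higher"],
        )
        for r in payload["comparisons"]
    ]
    summaries = [
        RiskBurdenSummary(
            population=s["population"], n_tested=s["n_tested"],
            n_significant=s["n_significant"], risk_index=s["risk_index"],
            risk_percentage=s["risk_percentage"],
            risk_locus_list=tuple(s["risk_locus_list"]),
        )
        for s in payload["risk_burden"]
    ]
    return AnalysisReport(
        config=config,
        populations=list(payload["populations"]),
        hwe_results=hwe_results,
        exclusions=exclusions,
        excluded_rs_ids=list(payload["excluded_rs_ids"]),
        retained_rs_ids=list(payload["retained_rs_ids"]),
        allele_counts=allele_counts,
        comparisons=comparisons,
        summaries=summaries,
    )
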