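"""Per-locus 2x2 allele-count tests of a population against a reference panel.

Each comparison places the population's and the reference's chromosome counts
of the two alleles in a 2x2 table and tests homogeneity of allele frequency.
The workhorse is the Pearson chi-square with 1 df and *no* Yates continuity
correction; Fisher's exact test (two-sided, point-probability method) is
dispatched instead whenever any expected cell under independence falls below
5 (Cochran's rule).  Significance is the strict inequality p < threshold,
with the study's operative Bonferroni-style threshold of 0.006 as default.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .frequency import allele_frequencies, percent
from .types import AlleleCounts, DegenerateInputError, SnpAnnotation, ValidationError

__all__ = [
    "DEFAULT_THRESHOLD",
    "COCHRAN_MINIMUM_EXPECTED",
    "ComparisonResult",
    "build_2x2",
    "expected_cells_2x2",
    "chi_square_2x2",
    "fisher_exact_2x2",
    "compare_population_to_reference",
    "bonferroni_threshold",
    "comparison_table",
    "write_comparison_table",
    "write_comparison_json",
]

#: Operative significance level printed by the study (stated as a Bonferroni
#: correction; the exact 0.05/9 would be 0.00556).
DEFAULT_THRESHOLD = 0.006

#: Minimum expected cell count for the chi-square approximation (Cochran).
COCHRAN_MINIMUM_EXPECTED = 5.0


@dataclass(frozen=True)
class ComparisonResult:
    rs_id: str
    population: str
    reference: str
    contingency: tuple[tuple[int, int], tuple[int, int]]
    test_used: str  # "chi_square" | "fisher_exact"
    statistic: float | None
    p_value: float
    threshold: float
    significant: bool
    risk_allele: str
    risk_allele_freq_population: float
    risk_allele_freq_reference: float
    risk_allele_higher: bool


def build_2x2(pop: AlleleCounts, ref: AlleleCounts) -> np.ndarray:
    """2x2 table [[pop_a, pop_b], [ref_a, ref_b]] after orientation checks."""
    if pop.rs_id != ref.rs_id:
        raise ValidationError(
            f"rsID mismatch: population {pop.rs_id} vs reference {ref.rs_id}")
    if (
        pop.allele_a is not None and ref.allele_a is not None
        and (pop.allele_a, pop.allele_b) != (ref.allele_a, ref.allele_b)
    ):
        raise ValidationError(
            f"{pop.rs_id}: allele orientation mismatch "
            f"({pop.allele_a}/{pop.allele_b} vs {ref.allele_a}/{ref.allele_b})")
    return np.array(
        [[pop.count_a, pop.count_b], [ref.count_a, ref.count_b]], dtype=np.int64)


def expected_cells_2x2(table: np.ndarray) -> np.ndarray:
    """Expected cell counts under row/column independence."""
    table = np.asarray(table, dtype=float)
    total = table.sum()
    if total <= 0:
        raise DegenerateInputError("empty 2x2 table")
    return np.outer(table.sum(axis=1), table.sum(axis=0)) / total


def chi_square_2x2(table: np.ndarray) -> tuple[float, float]:
    """Pearson chi-square (1 df, no continuity correction) on a 2x2 table."""
    table = np.asarray(table, dtype=np.int64)
    if (table < 0).any():
        raise ValidationError("negative cell in 2x2 table")
    if (table.sum(axis=1) == 0).any() or (table.sum(axis=0) == 0).any():
        raise DegenerateInputError(
            "zero row or column margin; use fisher_exact_2x2 instead")
    statistic, p_value, _, _ = stats.chi2_contingency(table, correction=False)
    return float(statistic), float(p_value)


def fisher_exact_2x2(table: np.ndarray) -> float:
    """Two-sided Fisher exact p-value (point-probability method)."""
    table = np.asarray(table, dtype=np.int64)
    if (table < 0).any():
        raise ValidationError("negative cell in 2x2 table")
    return float(stats.fisher_exact(table, alternative="two-sided")[1])


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Family-wise threshold alpha/m for m tests."""
    if not 0.0 < alpha < 1.0:
        raise ValidationError(f"alpha={alpha} outside (0, 1)")
    if m < 1:
        raise ValidationError(f"number of tests must be >= 1, got {m}")
    return alpha / m


def compare_population_to_reference(
    pop: AlleleCounts,
    ref: AlleleCounts,
    annotation: SnpAnnotation,
    threshold: float = DEFAULT_THRESHOLD,
    yates: bool = False,
) -> ComparisonResult:
    """Test one population's allele counts against the reference panel.

    Dispatches Fisher's exact test when any expected cell is below 5, the
    Pearson chi-square otherwise.  ``yates`` applies the continuity
    correction to the chi-square branch (off by default; the uncorrected
    statistic is the study convention).
    """
    if annotation.rs_id != pop.rs_id:
        raise ValidationError(
            f"annotation {annotation.rs_id} does not match counts {pop.rs_id}")
    table = build_2x2(pop, ref)
    expected = expected_cells_2x2(table)
    if (expected < COCHRAN_MINIMUM_EXPECTED).any():
        test_used = "fisher_exact"
        statistic: float | None = None
        p_value = fisher_exact_2x2(table)
    else:
        test_used = "chi_square"
        if yates:
            chi2_res = stats.chi2_contingency(table, correction=True)
            statistic, p_value = float(chi2_res[0]), float(chi2_res[1])
        else:
            statistic, p_value = chi_square_2x2(table)

    pop_freqs = allele_frequencies(pop)
    ref_freqs = allele_frequencies(ref)
    if annotation.risk_is_allele_a:
        freq_pop, freq_ref = pop_freqs.freq_a, ref_freqs.freq_a
    else:
        freq_pop, freq_ref = pop_freqs.freq_b, ref_freqs.freq_b

    return ComparisonResult(
        rs_id=pop.rs_id,
        population=pop.population,
        reference=ref.population,
        contingency=tuple(map(tuple, table.tolist())),
        test_used=test_used,
        statistic=statistic,
        p_value=p_value,
        threshold=threshold,
        significant=p_value < threshold,
        risk_allele=annotation.risk_allele,
        risk_allele_freq_population=freq_pop,
        risk_allele_freq_reference=freq_ref,
        risk_allele_higher=freq_pop > freq_ref,
    )


def comparison_table(results: Iterable[ComparisonResult]):
    """Long-format comparison table with significance markers."""
    import pandas as pd

    rows = []
    for r in results:
        rows.append({
            "rs_id": r.rs_id,
            "population": r.population,
            "reference": r.reference,
            "risk_allele": r.risk_allele,
            "risk_freq_percent": percent(r.risk_allele_freq_population),
            "reference_risk_freq_percent": percent(r.risk_allele_freq_reference),
            "test_used": r.test_used,
            "statistic": "" if r.statistic is None else f"{r.statistic:.4f}",
            "p_value": f"{r.p_value:.3e}",
            "significant": "*" if r.significant else "",
            "risk_allele_higher": r.risk_allele_higher,
        })
    return pd.DataFrame(rows)


def write_comparison_table(results: Iterable[ComparisonResult], path: str | Path) -> None:
    comparison_table(results).to_csv(path, sep="\t", index=False)


def write_comparison_json(results: Sequence[ComparisonResult], path: str | Path) -> None:
    payload = [comparison_to_dict(r) for r in results]
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def comparison_to_dict(r: ComparisonResult) -> dict:
    return {
        "rs_id": r.rs_id,
        "population": r.population,
        "reference": r.reference,
        "contingency": [list(row) for row in r.contingency],
        "test_used": r.test_used,
        "statistic": r.statistic,
        "p_value": r.p_value,
        "threshold": r.threshold,
        "significant": r.significant,
        "risk_allele": r.risk_allele,
        "risk_allele_freq_population": r.risk_allele_freq_population,
        "risk_allele_freq_reference": r.risk_allele_freq_reference,
        "risk_allele_higher": r.risk_allele_higher,
    }
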