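"""Allele counts, allele frequencies and genotyping call rates.

Statistics downstream always use unrounded proportions; the percent values
rounded half-up to one decimal exist only for report parity with published
frequency tables.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable

import pandas as pd

from .types import (
    AlleleCounts,
    AlleleFrequencies,
    DegenerateInputError,
    GenotypeCounts,
    SnpAnnotation,
    ValidationError,
)

__all__ = [
    "genotype_to_allele_counts",
    "allele_frequencies",
    "call_rate",
    "percent",
    "frequency_table",
    "write_frequency_table",
]


def percent(proportion: float, ndigits: int = 1) -> float:
    """Round a proportion to a percentage, half-up, as printed in reports."""
    quantum = Decimal(1).scaleb(-ndigits)
    return float(Decimal(str(proportion * 100)).quantize(quantum, rounding=ROUND_HALF_UP))


def genotype_to_allele_counts(
    g: GenotypeCounts, annotation: SnpAnnotation | None = None
) -> AlleleCounts:
    """Convert diploid genotype counts to chromosome counts of each allele.

    count_a = 2*n_aa + n_ab and count_b = n_ab + 2*n_bb, so the total is
    always 2*n_total.  If an annotation is supplied its allele labels are
    attached to the result (after an rsID check).
    """
    if g.n_total == 0:
        raise DegenerateInputError(
            f"{g.rs_id}/{g.population}: no genotyped individuals")
    allele_a = allele_b = None
    if annotation is not None:
        if annotation.rs_id != g.rs_id:
            raise ValidationError(
                f"annotation {annotation.rs_id} does not match counts {g.rs_id}")
        allele_a, allele_b = annotation.allele_a, annotation.allele_b
    return AlleleCounts(
        rs_id=g.rs_id,
        population=g.population,
        count_a=2 * g.n_aa + g.n_ab,
        count_b=g.n_ab + 2 * g.n_bb,
        allele_a=allele_a,
        allele_b=allele_b,
    )


def allele_frequencies(c: AlleleCounts) -> AlleleFrequencies:
    """Allele proportions from chromosome counts."""
    if c.total == 0:
        raise DegenerateInputError(f"{c.rs_id}/{c.population}: zero chromosomes")
    return AlleleFrequencies(
        rs_id=c.rs_id,
        population=c.population,
        freq_a=c.count_a / c.total,
        freq_b=c.count_b / c.total,
    )


def call_rate(n_genotyped: int, n_total_individuals: int) -> float:
    """Fraction of individuals with a successful genotype call."""
    if n_total_individuals <= 0:
        raise ValidationError("n_total_individuals must be positive")
    if not 0 <= n_genotyped <= n_total_individuals:
        raise ValidationError(
            f"n_genotyped={n_genotyped} outside [0, {n_total_individuals}]")
    return n_genotyped / n_total_individuals


def frequency_table(
    counts: Iterable[GenotypeCounts], annotations: list[SnpAnnotation]
) -> pd.DataFrame:
    """Long-format allele frequency table with risk-allele flags.

    One row per SNP x population x allele with the chromosome count, the
    percent frequency (half-up, 1 decimal) and whether the allele is the
    locus's risk allele.
    """
    by_rs = {a.rs_id: a for a in annotations}
    rows = []
    for g in counts:
        annotation = by_rs[g.rs_id]
        ac = genotype_to_allele_counts(g, annotation)
        freqs = allele_frequencies(ac)
        for allele, count, freq in (
            (annotation.allele_a, ac.count_a, freqs.freq_a),
            (annotation.allele_b, ac.count_b, freqs.freq_b),
        ):
            rows.append({
                "rs_id": g.rs_id,
                "gene": annotation.gene,
                "population": g.population,
                "allele": allele,
                "count": count,
                "frequency_percent": percent(freq),
                "risk_allele_flag": allele == annotation.risk_allele,
            })
    return pd.DataFrame(rows)


def write_frequency_table(
    counts: Iterable[GenotypeCounts],
    annotations: list[SnpAnnotation],
    path: str | Path,
) -> None:
    frequency_table(counts, annotations).to_csv(path, sep="\t", index=False)
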