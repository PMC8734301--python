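"""Hardy-Weinberg equilibrium testing and the all-subgroups exclusion rule.

The default test is the plain 1-df chi-square on the three genotype classes
against the p^2, 2pq, q^2 expectations, with no continuity correction — the
convention used by common genotyping QC software.  A monomorphic site cannot
deviate from equilibrium, so it is reported with chi_square = 0 and p = 1 and
an explicit flag.  A locus is excluded from downstream comparison only when
it deviates (p below the threshold) in *every* population subgroup; the
reference panel takes no part in QC.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from scipy import stats

from .types import DegenerateInputError, GenotypeCounts, ValidationError

__all__ = [
    "DEFAULT_HWE_THRESHOLD",
    "HweResult",
    "ExclusionDecision",
    "hwe_expected_counts",
    "hwe_chi_square_test",
    "hwe_exact_test",
    "hwe_exclusion_filter",
    "hwe_matrix",
    "write_hwe_matrix",
    "write_exclusion_report",
]

#: Operative significance level of the study's QC rule (a Bonferroni-style
#: threshold stated as 0.006, not the exact 0.05/9).
DEFAULT_HWE_THRESHOLD = 0.006


@dataclass(frozen=True)
class HweResult:
    rs_id: str
    population: str
    chi_square: float
    df: int
    p_value: float
    expected_aa: float
    expected_ab: float
    expected_bb: float
    monomorphic: bool


@dataclass(frozen=True)
class ExclusionDecision:
    """Keep/exclude verdict for one SNP with per-population deviation flags."""

    rs_id: str
    exclude: bool
    threshold: float
    deviant: dict[str, bool] = field(default_factory=dict)
    p_values: dict[str, float] = field(default_factory=dict)


def hwe_expected_counts(g: GenotypeCounts) -> tuple[float, float, float]:
    """Expected genotype counts (n*p^2, n*2pq, n*q^2) from observed alleles."""
    n = g.n_total
    if n == 0:
        raise DegenerateInputError(f"{g.rs_id}/{g.population}: no genotyped individuals")
    p = (2 * g.n_aa + g.n_ab) / (2 * n)
    q = 1.0 - p
    return n * p * p, 2.0 * n * p * q, n * q * q


def hwe_chi_square_test(g: GenotypeCounts) -> HweResult:
    """1-df chi-square goodness-of-fit test against HWE expectations.

    Degenerate expected cells (an allele entirely absent) contribute zero to
    the statistic, the limit of (obs - exp)^2 / exp with obs = exp = 0.
    """
    expected = hwe_expected_counts(g)
    observed = (g.n_aa, g.n_ab, g.n_bb)
    monomorphic = g.is_monomorphic
    if monomorphic:
        chi_square, p_value = 0.0, 1.0
    else:
        chi_square = sum(
            (o - e) ** 2 / e for o, e in zip(observed, expected) if e > 0)
        p_value = float(stats.chi2.sf(chi_square, df=1))
    return HweResult(
        rs_id=g.rs_id,
        population=g.population,
        chi_square=chi_square,
        df=1,
        p_value=p_value,
        expected_aa=expected[0],
        expected_ab=expected[1],
        expected_bb=expected[2],
        monomorphic=monomorphic,
    )


def hwe_exact_test(g: GenotypeCounts) -> HweResult:
    """Exact HWE test (optional alternative to the default chi-square).

    Conditional on the observed allele counts, sums the probabilities of all
    heterozygote counts whose probability does not exceed that of the observed
    table.  Expected counts and the monomorphic convention match the
    chi-square variant; the chi_square field is reported as NaN.
    """
    expected = hwe_expected_counts(g)
    if g.is_monomorphic:
        p_value: float = 1.0
    else:
        n = g.n_total
        n_a = 2 * g.n_aa + g.n_ab
        n_b = 2 * n - n_a
        rare = min(n_a, n_b)
        # log-probability of each feasible heterozygote count, same parity as rare
        log_probs = {}
        for n_ab in range(rare % 2, rare + 1, 2):
            n_aa = (n_a - n_ab) // 2
            n_bb = (n_b - n_ab) // 2
            if n_aa < 0 or n_bb < 0:
                continue
            log_probs[n_ab] = (
                n_ab * math.log(2)
                + math.lgamma(n + 1) - math.lgamma(n_aa + 1)
                - math.lgamma(n_ab + 1) - math.lgamma(n_bb + 1)
                + math.lgamma(n_a + 1) + math.lgamma(n_b + 1)
                - math.lgamma(2 * n + 1)
            )
        observed_lp = log_probs[g.n_ab]
        p_value = min(1.0, sum(
            math.exp(lp) for lp in log_probs.values() if lp <= observed_lp + 1e-12))
    return HweResult(
        rs_id=g.rs_id,
        population=g.population,
        chi_square=float("nan"),
        df=1,
        p_value=p_value,
        expected_aa=expected[0],
        expected_ab=expected[1],
        expected_bb=expected[2],
        monomorphic=g.is_monomorphic,
    )


def hwe_exclusion_filter(
    results: Sequence[HweResult], threshold: float = DEFAULT_HWE_THRESHOLD
) -> ExclusionDecision:
    """Exclude a SNP only if it deviates from HWE in every population subgroup."""
    if not results:
        raise ValidationError("no HWE results supplied")
    rs_ids = {r.rs_id for r in results}
    if len(rs_ids) != 1:
        raise ValidationError(f"results span multiple SNPs: {sorted(rs_ids)}")
    deviant = {r.population: r.p_value < threshold for r in results}
    return ExclusionDecision(
        rs_id=results[0].rs_id,
        exclude=all(deviant.values()),
        threshold=threshold,
        deviant=deviant,
        p_values={r.population: r.p_value for r in results},
    )


def hwe_matrix(results: Iterable[HweResult]) -> pd.DataFrame:
    """SNP-by-population matrix of HWE p-values."""
    frame = pd.DataFrame(
        [(r.rs_id, r.population, r.p_value) for r in results],
        columns=["rs_id", "population", "p_value"],
    )
    return frame.pivot(index="rs_id", columns="population", values="p_value")


def write_hwe_matrix(results: Iterable[HweResult], path: str | Path) -> None:
    hwe_matrix(results).to_csv(path, sep="\t", float_format="%.4f")


def write_exclusion_report(
    decisions: Iterable[ExclusionDecision], path: str | Path
) -> None:
    payload = [
        {
            "rs_id": d.rs_id,
            "exclude": d.exclude,
            "threshold": d.threshold,
            "deviant": d.deviant,
            "p_values": d.p_values,
        }
        for d in decisions
    ]
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
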