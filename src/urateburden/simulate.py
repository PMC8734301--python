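"""Synthetic multi-population diploid cohorts with controlled allele
frequencies, HWE deviation and missingness.

Genotypes at a locus with allele_a frequency ``p`` are drawn independently per
individual from the inbreeding model

    P(aa) = p^2 + F p q,   P(ab) = 2 p q (1 - F),   P(bb) = q^2 + F p q,

where ``F`` is Wright's inbreeding coefficient: F = 0 is exact
Hardy-Weinberg equilibrium, F > 0 produces the heterozygote deficit that the
QC stage is designed to detect.  Calls are then masked missing independently
with the per-SNP missing rate.  A single integer seed drives one pseudorandom
stream consumed in population, then SNP (sorted by rsID), then individual
order, so identical specs yield byte-identical cohorts.

The reference panel is drawn directly as allele counts (one binomial draw on
2 * n_ref chromosomes per SNP) because only allele counts of the referent
enter the comparison stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .types import (
    AlleleCounts,
    IndividualGenotypeTable,
    ReferencePanel,
    ValidationError,
)

__all__ = [
    "PopulationSpec",
    "CohortSpec",
    "simulate_genotypes",
    "simulate_study_cohort",
]


def _check_unit(name: str, x: float, *, open_right: bool = False) -> float:
    x = float(x)
    high_ok = x < 1.0 if open_right else x <= 1.0
    if not (0.0 <= x and high_ok):
        interval = "[0, 1)" if open_right else "[0, 1]"
        raise ValidationError(f"{name}={x} outside {interval}")
    return x


@dataclass(frozen=True)
class PopulationSpec:
    """One simulated subgroup: size, per-SNP allele_a frequencies, inbreeding."""

    label: str
    n_individuals: int
    freq_a: Mapping[str, float]
    inbreeding: float = 0.0

    def __post_init__(self) -> None:
        if self.n_individuals <= 0:
            raise ValidationError(f"{self.label}: n_individuals must be positive")
        for rs_id, freq in self.freq_a.items():
            _check_unit(f"{self.label}/{rs_id}: freq_a", freq)
        _check_unit(f"{self.label}: inbreeding", self.inbreeding)


@dataclass(frozen=True)
class CohortSpec:
    """Full study design: subgroups, a reference panel, missingness, a seed."""

    populations: tuple[PopulationSpec, ...]
    reference_freq_a: Mapping[str, float]
    reference_n: int = 503
    reference_label: str = "EUR"
    missing_rate: Mapping[str, float] | float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.populations:
            raise ValidationError("population list is empty")
        if self.reference_n <= 0:
            raise ValidationError("reference_n must be positive")
        for rs_id, freq in self.reference_freq_a.items():
            _check_unit(f"{self.reference_label}/{rs_id}: freq_a", freq)
        for rs_id in self.rs_ids:
            self.snp_missing_rate(rs_id)

    @property
    def rs_ids(self) -> list[str]:
        ids: set[str] = set(self.reference_freq_a)
        for population in self.populations:
            ids.update(population.freq_a)
        return sorted(ids)

    def snp_missing_rate(self, rs_id: str) -> float:
        if isinstance(self.missing_rate, Mapping):
            rate = self.missing_rate.get(rs_id, 0.0)
        else:
            rate = self.missing_rate
        return _check_unit(f"{rs_id}: missing_rate", rate, open_right=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CohortSpec":
        """Load a cohort design from a YAML config.

        Expected layout::

            seed: 7
            reference: {label: EUR, n: 503, freq_a: {rs123: 0.9}}
            missing_rate: 0.02            # or a {rs_id: rate} mapping
            populations:
              - {label: Japanese, n: 210, inbreeding: 0.0,
                 freq_a: {rs123: 0.74}}
        """
        config = yaml.safe_load(Path(path).read_text())
        reference = config.get("reference", {})
        populations = tuple(
            PopulationSpec(
                label=entry["label"],
                n_individuals=int(entry["n"]),
                freq_a={k: float(v) for k, v in entry["freq_a"].items()},
                inbreeding=float(entry.get("inbreeding", 0.0)),
            )
            for entry in config.get("populations", [])
        )
        raw_missing = config.get("missing_rate", 0.0)
        missing = (
            {k: float(v) for k, v in raw_missing.items()}
            if isinstance(raw_missing, dict) else float(raw_missing))
        return cls(
            populations=populations,
            reference_freq_a={k: float(v) for k, v in reference.get("freq_a", {}).items()},
            reference_n=int(reference.get("n", 503)),
            reference_label=reference.get("label", "EUR"),
            missing_rate=missing,
            seed=int(config.get("seed", 0)),
        )


def _draw_snp_calls(
    rng: np.random.Generator, n: int, freq_a: float, inbreeding: float,
    missing_rate: float,
) -> np.ndarray:
    p, q, f = freq_a, 1.0 - freq_a, inbreeding
    probs = np.array([p * p + f * p * q, 2 * p * q * (1 - f), q * q + f * p * q])
    probs = probs / probs.sum()  # guard rounding; each term is >= 0 for F in [0,1]
    codes = rng.choice(3, size=n, p=probs)
    calls = np.array(["aa", "ab", "bb"], dtype=object)[codes]
    if missing_rate > 0.0:
        calls[rng.random(n) < missing_rate] = "missing"
    return calls


def simulate_genotypes(
    n: int,
    freq_a: float,
    inbreeding: float = 0.0,
    missing_rate: float = 0.0,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    rs_id: str = "rs0",
    population: str = "simulated",
) -> IndividualGenotypeTable:
    """Simulate one SNP for ``n`` individuals under the inbreeding model."""
    if n <= 0:
        raise ValidationError("n must be positive")
    _check_unit("freq_a", freq_a)
    _check_unit("inbreeding", inbreeding)
    _check_unit("missing_rate", missing_rate, open_right=True)
    if rng is None:
        rng = np.random.default_rng(seed)
    calls = _draw_snp_calls(rng, n, freq_a, inbreeding, missing_rate)
    frame = pd.DataFrame(
        {rs_id: calls},
        index=[f"{population}_{i:05d}" for i in range(n)],
    )
    return IndividualGenotypeTable(population=population, calls=frame)


def simulate_study_cohort(
    spec: CohortSpec,
) -> tuple[dict[str, IndividualGenotypeTable], ReferencePanel]:
    """Simulate every subgroup plus the reference panel from one seed."""
    rng = np.random.default_rng(spec.seed)
    tables: dict[str, IndividualGenotypeTable] = {}
    for population in spec.populations:
        columns = {}
        for rs_id in sorted(population.freq_a):
            columns[rs_id] = _draw_snp_calls(
                rng,
                population.n_individuals,
                population.freq_a[rs_id],
                population.inbreeding,
                spec.snp_missing_rate(rs_id),
            )
        frame = pd.DataFrame(
            columns,
            index=[f"{population.label}_{i:05d}"
                   for i in range(population.n_individuals)],
        )
        tables[population.label] = IndividualGenotypeTable(
            population=population.label, calls=frame)

    alleles: dict[str, AlleleCounts] = {}
    chromosomes = 2 * spec.reference_n
    for rs_id in sorted(spec.reference_freq_a):
        count_a = int(rng.binomial(chromosomes, spec.reference_freq_a[rs_id]))
        alleles[rs_id] = AlleleCounts(
            rs_id=rs_id,
            population=spec.reference_label,
            count_a=count_a,
            count_b=chromosomes - count_a,
        )
    return tables, ReferencePanel(label=spec.reference_label, alleles=alleles)
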