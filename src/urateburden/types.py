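"""Domain types for biallelic SNP genotype data across population subgroups.

Conventions
-----------
Every SNP is biallelic with alleles ``allele_a`` and ``allele_b``, where
``allele_a`` is the alphabetically first nucleotide.  Genotype counts are
always ordered ``(n_aa, n_ab, n_bb)`` in that orientation, matching the order
in which homozygote classes are conventionally tabulated (AA/AT/TT, CC/CT/TT,
...).  The risk allele of a locus is the allele associated with baseline or
higher serum urate / gout risk and must be one of the two declared alleles.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import pandas as pd

__all__ = [
    "VALID_VARIANT_CLASSES",
    "VALID_EFFECT_DIRECTIONS",
    "GENOTYPE_CALLS",
    "ValidationError",
    "SchemaError",
    "DegenerateInputError",
    "SnpAnnotation",
    "GenotypeCounts",
    "AlleleCounts",
    "AlleleFrequencies",
    "IndividualGenotypeTable",
    "ReferencePanel",
]

VALID_VARIANT_CLASSES = frozenset({"missense", "intronic", "intergenic"})
VALID_EFFECT_DIRECTIONS = frozenset({"raises_urate", "lowers_urate"})
GENOTYPE_CALLS = ("aa", "ab", "bb", "missing")

_RS_PATTERN = re.compile(r"^rs[0-9]+$")
_NUCLEOTIDES = frozenset("ACGT")


class ValidationError(ValueError):
    """A record violates a domain invariant."""


class SchemaError(ValueError):
    """A tabular input does not match the documented schema."""


class DegenerateInputError(ValueError):
    """An operation received an input outside its mathematical domain."""


def _check_count(name: str, value: object) -> int:
    if isinstance(value, bool) or not isinstance(value, (int,)):
        raise ValidationError(f"{name} must be an integer, got {value!r}")
    if value < 0:
        raise ValidationError(f"{name} must be non-negative, got {value}")
    return int(value)


@dataclass(frozen=True)
class SnpAnnotation:
    """Identity, allele pair, risk allele and effect direction of one locus.

    ``effect_direction`` records whether the locus's published effect allele is
    associated with raised or lowered serum urate; ``effect_note`` is free-text
    metadata (effect sizes, odds ratios) and never enters any computation.
    """

    rs_id: str
    gene: str
    variant_class: str
    allele_a: str
    allele_b: str
    risk_allele: str
    effect_direction: str
    effect_note: str = ""

    def __post_init__(self) -> None:
        if not _RS_PATTERN.match(self.rs_id):
            raise ValidationError(f"invalid rsID {self.rs_id!r}")
        if self.variant_class not in VALID_VARIANT_CLASSES:
            raise ValidationError(
                f"{self.rs_id}: variant_class {self.variant_class!r} not in "
                f"{sorted(VALID_VARIANT_CLASSES)}"
            )
        for name in ("allele_a", "allele_b", "risk_allele"):
            allele = getattr(self, name)
            if allele not in _NUCLEOTIDES:
                raise ValidationError(f"{self.rs_id}: {name} {allele!r} is not a nucleotide")
        if self.allele_a == self.allele_b:
            raise ValidationError(f"{self.rs_id}: alleles must differ")
        if self.risk_allele not in (self.allele_a, self.allele_b):
            raise ValidationError(
                f"{self.rs_id}: risk allele {self.risk_allele!r} is neither "
                f"{self.allele_a!r} nor {self.allele_b!r}"
            )
        if self.effect_direction not in VALID_EFFECT_DIRECTIONS:
            raise ValidationError(
                f"{self.rs_id}: effect_direction {self.effect_direction!r} not in "
                f"{sorted(VALID_EFFECT_DIRECTIONS)}"
            )

    @property
    def risk_is_allele_a(self) -> bool:
        return self.risk_allele == self.allele_a


@dataclass(frozen=True)
class GenotypeCounts:
    """Diploid genotype counts for one SNP in one population.

    ``n_missing`` is the number of no-call individuals when individual-level
    data were tallied; ``None`` means the number of no-calls is unknown (the
    usual case when counts were transcribed from a published table), in which
    case a call rate is not computable.
    """

    rs_id: str
    population: str
    n_aa: int
    n_ab: int
    n_bb: int
    n_missing: int | None = None

    def __post_init__(self) -> None:
        for name in ("n_aa", "n_ab", "n_bb"):
            _check_count(f"{self.rs_id}/{self.population}: {name}", getattr(self, name))
        if self.n_missing is not None:
            _check_count(f"{self.rs_id}/{self.population}: n_missing", self.n_missing)

    @property
    def n_total(self) -> int:
        """Number of successfully genotyped individuals."""
        return self.n_aa + self.n_ab + self.n_bb

    @property
    def is_monomorphic(self) -> bool:
        return self.n_ab == 0 and (self.n_aa == 0 or self.n_bb == 0)


@dataclass(frozen=True)
class AlleleCounts:
    """Chromosome counts of the two alleles for one SNP in one population.

    Allele labels are optional; when present they pin the orientation so that
    two tables can be checked for compatibility before being compared.
    """

    rs_id: str
    population: str
    count_a: int
    count_b: int
    allele_a: str | None = None
    allele_b: str | None = None

    def __post_init__(self) -> None:
        _check_count(f"{self.rs_id}/{self.population}: count_a", self.count_a)
        _check_count(f"{self.rs_id}/{self.population}: count_b", self.count_b)

    @property
    def total(self) -> int:
        return self.count_a + self.count_b


@dataclass(frozen=True)
class AlleleFrequencies:
    """Allele proportions for one SNP in one population; freq_a + freq_b = 1."""

    rs_id: str
    population: str
    freq_a: float
    freq_b: float

    def __post_init__(self) -> None:
        for name in ("freq_a", "freq_b"):
            x = getattr(self, name)
            if not 0.0 <= x <= 1.0:
                raise ValidationError(f"{self.rs_id}: {name}={x} outside [0, 1]")
        if abs(self.freq_a + self.freq_b - 1.0) > 1e-12:
            raise ValidationError(
                f"{self.rs_id}/{self.population}: frequencies sum to "
                f"{self.freq_a + self.freq_b}, not 1"
            )


@dataclass
class IndividualGenotypeTable:
    """Per-individual diploid calls for one population.

    ``calls`` is a DataFrame indexed by individual identifier with one column
    per rsID; every cell is one of ``"aa"``, ``"ab"``, ``"bb"``, ``"missing"``.
    """

    population: str
    calls: pd.DataFrame

    def __post_init__(self) -> None:
        bad = set(self.calls.to_numpy().ravel()) - set(GENOTYPE_CALLS)
        if bad:
            raise ValidationError(
                f"{self.population}: invalid genotype call(s) {sorted(map(str, bad))}"
            )
        if self.calls.index.has_duplicates:
            raise ValidationError(f"{self.population}: duplicate individual identifiers")

    @property
    def n_individuals(self) -> int:
        return len(self.calls)

    @property
    def rs_ids(self) -> list[str]:
        return list(self.calls.columns)

    def to_genotype_counts(self) -> list[GenotypeCounts]:
        """Tally the table into one :class:`GenotypeCounts` per SNP."""
        out = []
        for rs_id in self.calls.columns:
            col = self.calls[rs_id]
            tally = col.value_counts()
            out.append(
                GenotypeCounts(
                    rs_id=rs_id,
                    population=self.population,
                    n_aa=int(tally.get("aa", 0)),
                    n_ab=int(tally.get("ab", 0)),
                    n_bb=int(tally.get("bb", 0)),
                    n_missing=int(tally.get("missing", 0)),
                )
            )
        return out


@dataclass
class ReferencePanel:
    """A labelled set of reference allele counts, one per SNP (e.g. EUR)."""

    label: str
    alleles: dict[str, AlleleCounts] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for rs_id, counts in self.alleles.items():
            if counts.rs_id != rs_id:
                raise ValidationError(
                    f"reference panel key {rs_id!r} does not match record {counts.rs_id!r}"
                )

    def covers(self, annotations: list[SnpAnnotation]) -> bool:
        return all(a.rs_id in self.alleles for a in annotations)

    def require_coverage(self, annotations: list[SnpAnnotation]) -> None:
        missing = [a.rs_id for a in annotations if a.rs_id not in self.alleles]
        if missing:
            raise ValidationError(
                f"reference panel {self.label!r} missing SNP(s): {', '.join(missing)}"
            )

    def __getitem__(self, rs_id: str) -> AlleleCounts:
        return self.alleles[rs_id]
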