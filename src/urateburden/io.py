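"""Tabular readers/writers, the packaged study fixture, and VCF ingestion.

All tabular formats are tab-delimited UTF-8 with a header row; ``"."`` marks
an absent optional value.  The packaged fixture ships the nine urate loci of
the study cohort: SNP annotations, genotype counts for the six ancestral
subgroups, and EUR reference allele counts from the 1000 Genomes Project
Phase III.
"""

from __future__ import annotations

import csv
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .types import (
    AlleleCounts,
    GenotypeCounts,
    IndividualGenotypeTable,
    ReferencePanel,
    SchemaError,
    SnpAnnotation,
    ValidationError,
)

__all__ = [
    "read_annotations",
    "write_annotations",
    "read_genotype_counts",
    "write_genotype_counts",
    "read_reference_panel",
    "write_reference_panel",
    "ingest_individual_genotypes",
    "read_vcf_genotypes",
    "load_packaged_annotations",
    "load_packaged_cohort_counts",
    "load_packaged_reference",
]

_ANNOTATION_COLUMNS = [
    "rs_id", "gene", "variant_class", "allele_a", "allele_b",
    "risk_allele", "effect_direction", "effect_note",
]
_COUNT_COLUMNS = ["rs_id", "population", "n_aa", "n_ab", "n_bb", "n_missing"]
_REFERENCE_COLUMNS = ["rs_id", "allele_a", "allele_b", "count_a", "count_b"]

MISSING = "."


def _read_rows(path: str | Path, required: list[str]) -> list[dict[str, str]]:
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        header = reader.fieldnames or []
        for column in required:
            if column not in header:
                raise SchemaError(f"{path}: missing required column {column!r}")
        return list(reader)


def _int_field(row: dict[str, str], column: str, context: str) -> int:
    raw = row.get(column, "").strip()
    try:
        return int(raw)
    except ValueError:
        raise SchemaError(f"{context}: column {column!r} has non-integer value {raw!r}")


def read_annotations(path: str | Path) -> list[SnpAnnotation]:
    """Read a SNP annotation table; order is preserved.

    Raises :class:`SchemaError` for a missing column and
    :class:`~urateburden.types.ValidationError` (naming the rsID) for a risk
    allele outside the declared pair.
    """
    annotations = []
    seen: set[str] = set()
    for row in _read_rows(path, _ANNOTATION_COLUMNS[:-1]):
        annotation = SnpAnnotation(
            rs_id=row["rs_id"].strip(),
            gene=row["gene"].strip(),
            variant_class=row["variant_class"].strip(),
            allele_a=row["allele_a"].strip(),
            allele_b=row["allele_b"].strip(),
            risk_allele=row["risk_allele"].strip(),
            effect_direction=row["effect_direction"].strip(),
            effect_note=(row.get("effect_note") or "").strip(),
        )
        if annotation.rs_id in seen:
            raise ValidationError(f"duplicate annotation for {annotation.rs_id}")
        seen.add(annotation.rs_id)
        annotations.append(annotation)
    return annotations


def write_annotations(annotations: Iterable[SnpAnnotation], path: str | Path) -> None:
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(_ANNOTATION_COLUMNS)
        for a in annotations:
            writer.writerow([a.rs_id, a.gene, a.variant_class, a.allele_a,
                             a.allele_b, a.risk_allele, a.effect_direction, a.effect_note])


def read_genotype_counts(
    path: str | Path, annotations: list[SnpAnnotation]
) -> list[GenotypeCounts]:
    """Read per-population genotype counts; every rsID must be annotated."""
    known = {a.rs_id for a in annotations}
    records = []
    for row in _read_rows(path, _COUNT_COLUMNS[:-1]):
        rs_id = row["rs_id"].strip()
        population = row["population"].strip()
        if rs_id not in known:
            raise ValidationError(f"genotype counts reference unannotated SNP {rs_id!r}")
        context = f"{rs_id}/{population}"
        raw_missing = (row.get("n_missing") or MISSING).strip()
        records.append(
            GenotypeCounts(
                rs_id=rs_id,
                population=population,
                n_aa=_int_field(row, "n_aa", context),
                n_ab=_int_field(row, "n_ab", context),
                n_bb=_int_field(row, "n_bb", context),
                n_missing=None if raw_missing == MISSING else _int_field(
                    row, "n_missing", context),
            )
        )
    return records


def write_genotype_counts(records: Iterable[GenotypeCounts], path: str | Path) -> None:
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(_COUNT_COLUMNS)
        for g in records:
            writer.writerow([
                g.rs_id, g.population, g.n_aa, g.n_ab, g.n_bb,
                MISSING if g.n_missing is None else g.n_missing,
            ])


def read_reference_panel(path: str | Path, label: str = "EUR") -> ReferencePanel:
    """Read a reference panel of per-SNP allele counts."""
    alleles: dict[str, AlleleCounts] = {}
    for row in _read_rows(path, _REFERENCE_COLUMNS):
        rs_id = row["rs_id"].strip()
        if rs_id in alleles:
            raise ValidationError(f"duplicate reference record for {rs_id}")
        context = f"{rs_id}/{label}"
        allele_a = row["allele_a"].strip()
        allele_b = row["allele_b"].strip()
        alleles[rs_id] = AlleleCounts(
            rs_id=rs_id,
            population=label,
            count_a=_int_field(row, "count_a", context),
            count_b=_int_field(row, "count_b", context),
            allele_a=None if allele_a == MISSING else allele_a,
            allele_b=None if allele_b == MISSING else allele_b,
        )
    return ReferencePanel(label=label, alleles=alleles)


def write_reference_panel(panel: ReferencePanel, path: str | Path) -> None:
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(_REFERENCE_COLUMNS)
        for rs_id in sorted(panel.alleles):
            c = panel.alleles[rs_id]
            writer.writerow([rs_id, c.allele_a or MISSING, c.allele_b or MISSING,
                             c.count_a, c.count_b])


# ---------------------------------------------------------------------------
# Per-individual ingestion

def ingest_individual_genotypes(
    table: IndividualGenotypeTable, annotations: list[SnpAnnotation]
) -> tuple[list[GenotypeCounts], dict[str, tuple[int, int]]]:
    """Aggregate per-individual calls into genotype counts plus call-rate inputs.

    Returns the counts and a mapping ``rs_id -> (n_genotyped, n_individuals)``
    suitable for :func:`urateburden.frequency.call_rate`.
    """
    known = {a.rs_id for a in annotations}
    unknown = [rs for rs in table.rs_ids if rs not in known]
    if unknown:
        raise ValidationError(
            f"{table.population}: unannotated SNP(s) {', '.join(unknown)}")
    counts = table.to_genotype_counts()
    call_inputs = {g.rs_id: (g.n_total, table.n_individuals) for g in counts}
    return counts, call_inputs


def read_vcf_genotypes(
    path: str | Path,
    annotations: list[SnpAnnotation],
    sample_populations: Mapping[str, str],
) -> list[IndividualGenotypeTable]:
    """Read diploid GT calls for annotated biallelic SNVs from a VCF file.

    Records are matched to annotations by ID.  ``./.`` and ``.`` genotypes are
    treated as missing; haploid or multi-allelic genotypes raise an error
    naming the record.  Every sample must have a population assignment.
    """
    import pysam

    by_rs = {a.rs_id: a for a in annotations}
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        unassigned = [s for s in samples if s not in sample_populations]
        if unassigned:
            raise ValidationError(
                f"sample(s) without population assignment: {', '.join(unassigned)}")
        calls: dict[str, dict[str, str]] = {s: {} for s in samples}
        for record in vcf:
            rs_id = record.id
            if rs_id is None or rs_id not in by_rs:
                continue
            annotation = by_rs[rs_id]
            alts = record.alts or ()
            if len(alts) != 1:
                raise ValidationError(f"{rs_id}: multi-allelic record not supported")
            site_alleles = {record.ref, alts[0]}
            declared = {annotation.allele_a, annotation.allele_b}
            if site_alleles != declared:
                raise ValidationError(
                    f"{rs_id}: VCF alleles {sorted(site_alleles)} do not match "
                    f"annotation {sorted(declared)}")
            for sample in samples:
                gt = record.samples[sample].get("GT")
                if gt is None or all(a is None for a in gt):
                    calls[sample][rs_id] = "missing"
                    continue
                if len(gt) != 2 or any(a is None for a in gt):
                    raise ValidationError(f"{rs_id}/{sample}: non-diploid genotype {gt}")
                bases = sorted(record.alleles[i] for i in gt)
                if bases[0] == bases[1]:
                    calls[sample][rs_id] = "aa" if bases[0] == annotation.allele_a else "bb"
                else:
                    calls[sample][rs_id] = "ab"

    tables = []
    for population in sorted(set(sample_populations[s] for s in samples)):
        members = [s for s in samples if sample_populations[s] == population]
        frame = pd.DataFrame.from_dict(
            {s: calls[s] for s in members}, orient="index").fillna("missing")
        tables.append(IndividualGenotypeTable(population=population, calls=frame))
    return tables


# ---------------------------------------------------------------------------
# Packaged fixture

def _packaged(name: str) -> Path:
    return Path(str(resources.files("urateburden.data").joinpath(name)))


def load_packaged_annotations() -> list[SnpAnnotation]:
    """The nine urate gene/SNP pairs with risk alleles and effect directions."""
    return read_annotations(_packaged("annotations_9snp.tsv"))


def load_packaged_cohort_counts() -> list[GenotypeCounts]:
    """Genotype counts for the six ancestral subgroups of the study cohort."""
    return read_genotype_counts(_packaged("counts_6pop.tsv"), load_packaged_annotations())


def load_packaged_reference() -> ReferencePanel:
    """EUR allele counts (1000 Genomes Phase III) for the nine loci."""
    return read_reference_panel(_packaged("reference_eur.tsv"), label="EUR")
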