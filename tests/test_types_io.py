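"""Domain types, TSV round-trips, the packaged fixture, and VCF ingestion."""

import textwrap

import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import urateburden as ub
from urateburden.io import ingest_individual_genotypes, read_vcf_genotypes

import published


# ---------------------------------------------------------------------------
# annotations

ANNOTATION_HEADER = (
    "rs_id\tgene\tvariant_class\tallele_a\tallele_b\t"
    "risk_allele\teffect_direction\teffect_note\n"
)


def test_read_annotations_row(tmp_path):
    path = tmp_path / "ann.tsv"
    path.write_text(
        ANNOTATION_HEADER
        + "rs2231142\tABCG2\tmissense\tG\tT\tT\traises_urate\tQ141K\n")
    (annotation,) = ub.read_annotations(path)
    assert annotation.risk_allele == "T"
    assert annotation.gene == "ABCG2"
    assert not annotation.risk_is_allele_a


def test_annotation_risk_allele_outside_pair(tmp_path):
    path = tmp_path / "ann.tsv"
    path.write_text(
        ANNOTATION_HEADER + "rs2231142\tABCG2\tmissense\tG\tT\tC\traises_urate\t\n")
    with pytest.raises(ub.ValidationError, match="rs2231142"):
        ub.read_annotations(path)


def test_annotations_header_only_is_empty(tmp_path):
    path = tmp_path / "ann.tsv"
    path.write_text(ANNOTATION_HEADER)
    assert ub.read_annotations(path) == []


def test_annotations_missing_column_names_it(tmp_path):
    path = tmp_path / "ann.tsv"
    path.write_text("rs_id\tgene\nrs1\tX\n")
    with pytest.raises(ub.SchemaError, match="variant_class"):
        ub.read_annotations(path)


@pytest.mark.parametrize(
    "kwargs",
    [
        {"rs_id": "snp1"},
        {"variant_class": "synonymous"},
        {"allele_b": "G"},
        {"effect_direction": "up"},
    ],
)
def test_annotation_invariants(kwargs):
    base = dict(rs_id="rs1", gene="X", variant_class="missense", allele_a="G",
                allele_b="T", risk_allele="T", effect_direction="raises_urate")
    base.update(kwargs)
    with pytest.raises(ub.ValidationError):
        ub.SnpAnnotation(**base)


# ---------------------------------------------------------------------------
# genotype counts

def test_genotype_counts_roundtrip(tmp_path, cohort_counts, annotations):
    path = tmp_path / "counts.tsv"
    ub.write_genotype_counts(cohort_counts, path)
    assert ub.read_genotype_counts(path, annotations) == cohort_counts


def test_negative_count_rejected(tmp_path, annotations):
    path = tmp_path / "counts.tsv"
    path.write_text(
        "rs_id\tpopulation\tn_aa\tn_ab\tn_bb\tn_missing\n"
        "rs2231142\tFilipino\t51\t-1\t36\t.\n")
    with pytest.raises(ub.ValidationError):
        ub.read_genotype_counts(path, annotations)


def test_unknown_rs_id_named(tmp_path, annotations):
    path = tmp_path / "counts.tsv"
    path.write_text(
        "rs_id\tpopulation\tn_aa\tn_ab\tn_bb\tn_missing\n"
        "rs99999\tFilipino\t1\t2\t3\t.\n")
    with pytest.raises(ub.ValidationError, match="rs99999"):
        ub.read_genotype_counts(path, annotations)


def test_monomorphic_record_is_valid(counts_by):
    g = counts_by[("rs734553", "Marshallese")]
    assert (g.n_aa, g.n_ab, g.n_bb) == (0, 0, 121)
    assert g.is_monomorphic


# ---------------------------------------------------------------------------
# packaged fixture integrity

def test_fixture_has_nine_unique_loci(annotations):
    assert len(annotations) == 9
    assert len({a.rs_id for a in annotations}) == 9
    for a in annotations:
        assert a.allele_a < a.allele_b  # alphabetical orientation


def test_fixture_counts_cover_six_subgroups(cohort_counts):
    populations = {g.population for g in cohort_counts}
    assert populations == {"Filipino", "Japanese", "Korean", "Native Hawaiian",
                           "Marshallese", "Samoan"}
    assert len(cohort_counts) == 54


def test_reference_covers_annotations(reference, annotations):
    assert reference.label == "EUR"
    reference.require_coverage(annotations)


def test_fixture_allele_counts_match_published(cohort_counts, ann_by_rs):
    """Every derived allele count equals the published per-cell count."""
    for g in cohort_counts:
        ac = ub.genotype_to_allele_counts(g, ann_by_rs[g.rs_id])
        expected = published.ALLELE_COUNTS[g.rs_id][g.population]
        assert (ac.count_a, ac.count_b) == expected, (g.rs_id, g.population)


# ---------------------------------------------------------------------------
# per-individual layer

def _table(population, rows):
    frame = pd.DataFrame(rows).T
    return ub.IndividualGenotypeTable(population=population, calls=frame)


def test_individual_tally(ann_by_rs):
    calls = {f"i{k}": {"rs2231142": c}
             for k, c in enumerate(["aa"] * 4 + ["ab"] * 5 + ["bb"])}
    (counts,), rates = ingest_individual_genotypes(
        _table("P", calls), [ann_by_rs["rs2231142"]])
    assert (counts.n_aa, counts.n_ab, counts.n_bb, counts.n_missing) == (4, 5, 1, 0)
    assert rates["rs2231142"] == (10, 10)


def test_individual_tally_with_missing(ann_by_rs):
    calls = {f"i{k}": {"rs2231142": c}
             for k, c in enumerate(["aa"] * 4 + ["ab"] * 3 + ["bb"] + ["missing"] * 2)}
    (counts,), rates = ingest_individual_genotypes(
        _table("P", calls), [ann_by_rs["rs2231142"]])
    assert counts.n_missing == 2
    assert counts.n_total == 8
    assert rates["rs2231142"] == (8, 10)


def test_invalid_call_rejected():
    with pytest.raises(ub.ValidationError):
        _table("P", {"i0": {"rs2231142": "AB"}})


@settings(max_examples=50, deadline=None)
@given(st.lists(st.sampled_from(["aa", "ab", "bb", "missing"]), min_size=1, max_size=40))
def test_aggregation_conserves_individuals(calls):
    table = _table("P", {f"i{k}": {"rs1": c} for k, c in enumerate(calls)})
    (g,) = table.to_genotype_counts()
    assert g.n_aa + g.n_ab + g.n_bb + g.n_missing == len(calls)


# ---------------------------------------------------------------------------
# VCF ingestion

VCF_TEXT = textwrap.dedent("""\
    ##fileformat=VCFv4.2
    ##contig=<ID=4>
    ##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
    #CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2\tS3
    4\t89052323\trs2231142\tG\tT\t.\tPASS\t.\tGT\t0/1\t1/1\t./.
    4\t9922166\trs734553\tG\tT\t.\tPASS\t.\tGT\t1/1\t0/0\t0/1
    """)


def test_vcf_heterozygote_counted(tmp_path, annotations):
    path = tmp_path / "calls.vcf"
    path.write_text(VCF_TEXT)
    tables = read_vcf_genotypes(
        path, annotations, {"S1": "P1", "S2": "P1", "S3": "P1"})
    (table,) = tables
    counts = {g.rs_id: g for g in table.to_genotype_counts()}
    # independent hand tally: 0/1 het, 1/1 hom-alt, ./. missing
    assert (counts["rs2231142"].n_aa, counts["rs2231142"].n_ab,
            counts["rs2231142"].n_bb, counts["rs2231142"].n_missing) == (0, 1, 1, 1)
    assert (counts["rs734553"].n_aa, counts["rs734553"].n_ab,
            counts["rs734553"].n_bb, counts["rs734553"].n_missing) == (1, 1, 1, 0)


def test_vcf_splits_populations(tmp_path, annotations):
    path = tmp_path / "calls.vcf"
    path.write_text(VCF_TEXT)
    tables = read_vcf_genotypes(
        path, annotations, {"S1": "P1", "S2": "P2", "S3": "P1"})
    assert sorted(t.population for t in tables) == ["P1", "P2"]
    sizes = {t.population: t.n_individuals for t in tables}
    assert sizes == {"P1": 2, "P2": 1}


def test_vcf_unassigned_sample_rejected(tmp_path, annotations):
    path = tmp_path / "calls.vcf"
    path.write_text(VCF_TEXT)
    with pytest.raises(ub.ValidationError, match="S3"):
        read_vcf_genotypes(path, annotations, {"S1": "P1", "S2": "P1"})


def test_vcf_haploid_genotype_rejected(tmp_path, annotations):
    path = tmp_path / "calls.vcf"
    path.write_text(VCF_TEXT.replace("GT\t0/1\t1/1\t./.", "GT\t0\t1/1\t./."))
    with pytest.raises(ub.ValidationError, match="rs2231142"):
        read_vcf_genotypes(path, annotations, {"S1": "P1", "S2": "P1", "S3": "P1"})
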