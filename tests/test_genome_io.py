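"""Format round trips, coordinate conventions, and interval algebra."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from malines.genome_io import (
    AnnotationSet,
    DataError,
    FormatError,
    GenomicInterval,
    ReferenceGenome,
    VariantCall,
    complement_intervals,
    interval_length,
    merge_intervals,
    read_fasta,
    read_intervals,
    read_variants,
    write_fasta,
    write_variants,
)


# -- FASTA ------------------------------------------------------------------

def test_fasta_round_trip_and_total_length(tmp_path):
    path = tmp_path / "g.fa"
    path.write_text(">a\nACGTACGTAC\n>b\nTTTTTTTTTT\n")
    g = read_fasta(path)
    assert g.total_length == 20
    assert g.sequences["a"] == "ACGTACGTAC"
    out = tmp_path / "out.fa"
    write_fasta(g, out)
    assert read_fasta(out).sequences == g.sequences


def test_fasta_lowercase_folded(tmp_path):
    path = tmp_path / "g.fa"
    path.write_text(">a\nacgtN\n")
    assert read_fasta(path).sequences["a"] == "ACGTN"


def test_fasta_ambiguity_code_rejected_with_line(tmp_path):
    path = tmp_path / "g.fa"
    path.write_text(">a\nACGT\nACRT\n")
    with pytest.raises(FormatError, match="line 3"):
        read_fasta(path)


def test_fasta_not_fasta(tmp_path):
    path = tmp_path / "g.fa"
    path.write_text("ACGT\n")
    with pytest.raises(FormatError):
        read_fasta(path)


def test_reference_genome_rejects_bad_alphabet():
    with pytest.raises(FormatError):
        ReferenceGenome({"a": "ACGU"})


# -- intervals --------------------------------------------------------------

def test_bed_identity_and_merge(tmp_path):
    path = tmp_path / "iv.bed"
    path.write_text("chr1\t5\t10\nchr1\t0\t10\nchr1\t5\t15\n")
    ivs = read_intervals(path, fmt="bed")
    assert ivs == [GenomicInterval("chr1", 0, 15)]


def test_gff3_one_based_conversion(tmp_path):
    path = tmp_path / "ann.gff3"
    path.write_text(
        "##gff-version 3\n"
        "chr1\tsrc\tCDS\t6\t10\t.\t+\t0\tID=x\n"
        "chr1\tsrc\tgene\t1\t100\t.\t+\t.\tID=y\n"
    )
    assert read_intervals(path, fmt="gff3") == [GenomicInterval("chr1", 5, 10)]


def test_empty_interval_is_format_error(tmp_path):
    path = tmp_path / "iv.bed"
    path.write_text("chr1\t10\t10\n")
    with pytest.raises(FormatError, match="line 1"):
        read_intervals(path, fmt="bed")


def test_complement_edge_cases():
    mask = [GenomicInterval("c", 0, 100)]
    assert complement_intervals([], mask) == mask
    assert complement_intervals(mask, mask) == []


@settings(max_examples=60, derandomize=True, deadline=None)
@given(
    st.lists(
        st.tuples(st.integers(0, 990), st.integers(1, 120)).map(
            lambda t: (t[0], min(t[0] + t[1], 1000))
        ),
        max_size=30,
    )
)
def test_interval_algebra_against_bitmap(pairs):
    """Merge/complement agree with a per-bp bitmap; complement is an involution."""
    mask = [GenomicInterval("c", 0, 1000)]
    ivs = [GenomicInterval("c", s, e) for s, e in pairs if e > s]
    merged = merge_intervals(ivs)
    comp = complement_intervals(merged, mask)
    bitmap = np.zeros(1000, dtype=bool)
    for s, e in pairs:
        bitmap[s:e] = True
    got = np.zeros(1000, dtype=bool)
    for iv in merged:
        got[iv.start : iv.end] = True
    assert np.array_equal(bitmap, got)
    assert interval_length(merged) + interval_length(comp) == 1000
    assert complement_intervals(comp, mask) == merged


def test_annotation_partition(toy_genome, toy_annotation):
    ann = toy_annotation
    assert ann.coding_length + ann.noncoding_length == toy_genome.total_length
    assert ann.compartment_of("chr1", 5) == "coding"
    assert ann.compartment_of("chr1", 25) == "noncoding"


# -- variants ---------------------------------------------------------------

def test_vcf_round_trip(tmp_path, toy_genome):
    calls = [
        VariantCall("chr1", 6, "G", "A", "iso1"),
        VariantCall("chr1", 9, "CA", "C", "iso1"),
    ]
    path = tmp_path / "v.vcf"
    write_variants(calls, path, reference=toy_genome)
    back = read_variants(path, reference=toy_genome, isolate_id="iso1")
    assert [v.key for v in back] == [v.key for v in calls]


def test_vcf_multiallelic_split(tmp_path):
    path = tmp_path / "v.vcf"
    path.write_text(
        "##fileformat=VCFv4.2\n"
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
        "chr1\t7\t.\tA\tG,T\t.\t.\t.\n"
    )
    calls = read_variants(path)
    assert [(v.pos, v.ref, v.alt) for v in calls] == [(6, "A", "G"), (6, "A", "T")]


def test_vcf_empty_body(tmp_path):
    path = tmp_path / "v.vcf"
    path.write_text(
        "##fileformat=VCFv4.2\n#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
    )
    assert read_variants(path) == []


def test_vcf_ref_mismatch(tmp_path, toy_genome):
    path = tmp_path / "v.vcf"
    path.write_text(
        "##fileformat=VCFv4.2\n"
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
        "chr1\t1\t.\tT\tG\t.\t.\t.\n"  # reference has A at chr1:1
    )
    with pytest.raises(DataError, match="chr1:1"):
        read_variants(path, reference=toy_genome)


def test_tsv_round_trip(tmp_path):
    calls = [VariantCall("chr2", 3, "T", "G", "isoX")]
    path = tmp_path / "v.tsv"
    write_variants(calls, path)
    back = read_variants(path)
    assert back[0].key == calls[0].key
    assert back[0].isolate_id == "isoX"
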