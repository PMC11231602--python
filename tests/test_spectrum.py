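"""Normalization, ancestral subtraction, classification, pooling."""
import numpy as np
import pytest

from malines.genome_io import ConfigError, DataError, ReferenceGenome, VariantCall
from malines.spectrum import (
    COMPLEX,
    DELETION,
    INSERTION,
    SUBSTITUTION,
    IsolatePair,
    classify_alleles,
    normalize_variant,
    pool_by_genotype,
    subtract_generation0,
)


# -- normalization ----------------------------------------------------------

def test_deletion_left_aligned_across_run():
    g = ReferenceGenome({"c": "GGCAAAATT"})
    # delete the 3rd A of the run, represented mid-run
    v = VariantCall("c", 4, "AA", "A")
    n = normalize_variant(v, g)
    assert (n.pos, n.ref, n.alt) == (2, "CA", "C")


def test_insertion_left_aligned_across_run():
    g = ReferenceGenome({"c": "GGCAAAATT"})
    v = VariantCall("c", 5, "A", "AA")  # insert an A mid-run
    n = normalize_variant(v, g)
    assert (n.pos, n.ref, n.alt) == (2, "C", "CA")


def test_mnv_with_single_difference_reduced_to_snv():
    g = ReferenceGenome({"c": "GGCAAAATT"})
    v = VariantCall("c", 1, "GCA", "GTA")
    n = normalize_variant(v, g)
    assert (n.pos, n.ref, n.alt) == (2, "C", "T")


def test_non_variant_rejected():
    g = ReferenceGenome({"c": "ACGT"})
    with pytest.raises(DataError):
        VariantCall("c", 0, "A", "A")


def test_ref_mismatch_rejected():
    g = ReferenceGenome({"c": "ACGT"})
    with pytest.raises(DataError, match="REF"):
        normalize_variant(VariantCall("c", 0, "C", "G"), g)


def _oracle_leftmost_deletion(seq, hap, d):
    """Leftmost i such that removing seq[i:i+d] reproduces the haplotype."""
    for i in range(len(seq) - d + 1):
        if seq[:i] + seq[i + d :] == hap:
            return i
    raise AssertionError("no placement found")


def _oracle_leftmost_insertion(seq, hap, d):
    """Leftmost gap j and inserted string recovering the haplotype."""
    for j in range(len(seq) + 1):
        ins = hap[j : j + d]
        if seq[:j] + ins + seq[j:] == hap:
            return j, ins
    raise AssertionError("no placement found")


def test_normalization_matches_slide_left_oracle(rng):
    """Normalized indels land at the leftmost haplotype-equivalent placement."""
    bases = np.array(list("AACGT"))  # A-rich to create runs
    for _ in range(300):
        seq = "".join(rng.choice(bases, size=60))
        g = ReferenceGenome({"c": seq})
        d = int(rng.integers(1, 4))
        if rng.random() < 0.5:  # deletion, anchored representation
            i = int(rng.integers(1, 60 - d))
            v = VariantCall("c", i - 1, seq[i - 1 : i + d], seq[i - 1])
            hap = seq[:i] + seq[i + d :]
            i_star = _oracle_leftmost_deletion(seq, hap, d)
            if i_star == 0:
                continue  # slides to the contig start: no left anchor exists
            n = normalize_variant(v, g)
            assert (n.pos, n.ref, n.alt) == (
                i_star - 1,
                seq[i_star - 1 : i_star + d],
                seq[i_star - 1],
            )
        else:  # insertion
            j = int(rng.integers(1, 60))
            ins = "".join(rng.choice(bases, size=d))
            v = VariantCall("c", j - 1, seq[j - 1], seq[j - 1] + ins)
            hap = seq[:j] + ins + seq[j:]
            j_star, ins_star = _oracle_leftmost_insertion(seq, hap, d)
            if j_star == 0:
                continue  # slides to the contig start: no left anchor exists
            n = normalize_variant(v, g)
            assert (n.pos, n.ref, n.alt) == (
                j_star - 1,
                seq[j_star - 1],
                seq[j_star - 1] + ins_star,
            )
        # applying the normalized variant reproduces the haplotype
        assert (
            seq[: n.pos] + n.alt + seq[n.pos + len(n.ref) :] == hap
        )


# -- classification ---------------------------------------------------------

@pytest.mark.parametrize(
    "ref,alt,mclass,size",
    [
        ("A", "G", SUBSTITUTION, 0),
        ("CA", "C", DELETION, 1),
        ("C", "CTT", INSERTION, 2),
        ("ACG", "ATG", SUBSTITUTION, 0),
        ("ACG", "ATA", COMPLEX, 0),
    ],
)
def test_classify_alleles(ref, alt, mclass, size):
    assert classify_alleles(ref, alt) == (mclass, size)


# -- subtraction ------------------------------------------------------------

def _pair(gen0, final, iso="i1", gt="g"):
    return IsolatePair(iso, gt, gen0, final, generations=900)


def test_subtraction_examples():
    vs = [VariantCall("c", i, "A", "G") for i in range(5)]
    assert subtract_generation0(_pair(vs, vs)) == []
    out = subtract_generation0(_pair([], vs))
    assert [m.key for m in out] == [v.key for v in vs]


def test_subtraction_idempotent():
    gen0 = [VariantCall("c", 1, "A", "G")]
    final = gen0 + [VariantCall("c", 5, "C", "T"), VariantCall("c", 8, "CA", "C")]
    once = subtract_generation0(_pair(gen0, final))
    keys = {m.key for m in once}
    again = subtract_generation0(
        _pair(gen0, [v for v in final if v.key not in {g.key for g in gen0}])
    )
    assert {m.key for m in again} == keys


# -- pooling ----------------------------------------------------------------

def test_pooling_totals_and_generations():
    pairs = [
        _pair([], [VariantCall("c", i, "A", "G") for i in range(3)], iso=f"i{k}")
        for k in range(9)
    ]
    spectra = pool_by_genotype(pairs)
    sp = spectra["g"]
    assert sp.n_isolates == 9
    assert sp.total_generations == 8100
    assert len(sp.mutations) == 27
    # conservation: pooled == sum over isolates; classes partition the total
    assert sum(len(v) for v in sp.per_isolate.values()) == len(sp.mutations)
    by_class = sum(
        len(sp.of_class(c)) for c in (SUBSTITUTION, INSERTION, DELETION, COMPLEX)
    )
    assert by_class == len(sp.mutations)


def test_duplicate_isolate_rejected():
    pairs = [_pair([], [], iso="dup"), _pair([], [], iso="dup", gt="other")]
    with pytest.raises(ConfigError):
        pool_by_genotype(pairs)
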