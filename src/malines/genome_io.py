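"""I/O for the standard genomics formats the pipeline touches.

Coordinate convention: everything held in memory is 0-based, half-open.
Conversion to and from each format's native convention (BED 0-based
half-open; GFF3 and VCF 1-based) happens in this module and nowhere else,
so there is a single place where off-by-one errors could live.
"""
from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from cyvcf2 import VCF

__all__ = [
    "FormatError",
    "DataError",
    "ConfigError",
    "ReferenceGenome",
    "GenomicInterval",
    "AnnotationSet",
    "VariantCall",
    "reverse_complement",
    "complement_base",
    "read_fasta",
    "write_fasta",
    "read_intervals",
    "merge_intervals",
    "complement_intervals",
    "clip_intervals",
    "interval_length",
    "read_variants",
    "write_variants",
]

VALID_BASES = frozenset("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class FormatError(ValueError):
    """A file does not conform to its declared format."""


class DataError(ValueError):
    """Well-formed input that contradicts the reference or itself."""


class ConfigError(ValueError):
    """Invalid run configuration."""


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def complement_base(base: str) -> str:
    return base.translate(_COMPLEMENT)


@dataclass(frozen=True)
class GenomicInterval:
    """Half-open interval [start, end) on a named chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0 or self.end <= self.start:
            raise FormatError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class ReferenceGenome:
    """In-memory reference: chromosome name -> uppercase A/C/G/T/N string."""

    sequences: dict[str, str]

    def __post_init__(self) -> None:
        for name, seq in self.sequences.items():
            if not seq:
                raise FormatError(f"empty sequence for chromosome {name!r}")
            bad = set(seq) - VALID_BASES
            if bad:
                raise FormatError(
                    f"chromosome {name!r} contains non-ACGTN characters: {sorted(bad)}"
                )

    @property
    def chromosomes(self) -> list[str]:
        return list(self.sequences)

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.sequences.values())

    def length(self, chrom: str) -> int:
        return len(self.sequences[chrom])

    def fetch(self, chrom: str, start: int, end: int) -> str:
        seq = self.sequences[chrom]
        if start < 0 or end > len(seq) or end < start:
            raise DataError(f"fetch {chrom}:{start}-{end} outside chromosome bounds")
        return seq[start:end]

    def base(self, chrom: str, pos: int) -> str:
        return self.fetch(chrom, pos, pos + 1)


def _first_bad_line(path: Path, bad: set[str]) -> int:
    """Line number (1-based) of the first FASTA line with an offending char."""
    with open(path) as fh:
        for i, line in enumerate(fh, 1):
            if line.startswith(">"):
                continue
            if set(line.strip().upper()) & bad:
                return i
    return 0


def read_fasta(path: str | Path) -> ReferenceGenome:
    """Load a FASTA file; lowercase is folded to uppercase.

    Ambiguity codes other than N are rejected with the line number of the
    first offending sequence line.
    """
    path = Path(path)
    try:
        with open(path) as fh:
            records = list(SeqIO.parse(fh, "fasta"))
    except ValueError as exc:
        raise FormatError(f"{path}: not FASTA (line 1): {exc}") from None
    if not records:
        with open(path) as fh:
            if any(line.strip() for line in fh):
                raise FormatError(f"{path}: not FASTA (no '>' header at line 1)")
        return ReferenceGenome({})  # empty file -> empty genome; rejected below anyway
    sequences: dict[str, str] = {}
    for rec in records:
        if rec.id in sequences:
            raise FormatError(f"{path}: duplicate chromosome name {rec.id!r}")
        seq = str(rec.seq).upper()
        if not seq:
            raise FormatError(f"{path}: record {rec.id!r} has an empty sequence")
        bad = set(seq) - VALID_BASES
        if bad:
            line = _first_bad_line(path, bad)
            raise FormatError(
                f"{path}: record {rec.id!r} contains invalid character(s) "
                f"{sorted(bad)} (line {line})"
            )
        sequences[rec.id] = seq
    return ReferenceGenome(sequences)


def write_fasta(genome: ReferenceGenome, path: str | Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_intervals(
    path: str | Path,
    fmt: str = "bed",
    feature_filter: Sequence[str] = ("CDS",),
) -> list[GenomicInterval]:
    """Read BED (0-based half-open) or GFF3 (1-based closed) intervals.

    Returns merged, sorted intervals in the internal 0-based half-open
    convention. For GFF3 only features whose type is in ``feature_filter``
    are kept (default CDS).
    """
    if fmt not in ("bed", "gff3"):
        raise ConfigError(f"unknown interval format {fmt!r}")
    intervals: list[GenomicInterval] = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, 1):
            s = line.strip()
            if not s or s.startswith(("#", "track", "browser")):
                continue
            cols = s.split("\t") if "\t" in s else s.split()
            try:
                if fmt == "bed":
                    if len(cols) < 3:
                        raise ValueError("fewer than 3 columns")
                    chrom, start, end = cols[0], int(cols[1]), int(cols[2])
                else:
                    if len(cols) < 9:
                        raise ValueError("fewer than 9 columns")
                    if feature_filter and cols[2] not in feature_filter:
                        continue
                    chrom, start, end = cols[0], int(cols[3]) - 1, int(cols[4])
            except ValueError as exc:
                raise FormatError(f"{path}: line {line_no}: {exc}") from None
            if end <= start:
                raise FormatError(
                    f"{path}: line {line_no}: empty/negative interval "
                    f"{chrom}:{start}-{end} after conversion"
                )
            intervals.append(GenomicInterval(chrom, start, end))
    return merge_intervals(intervals)


def merge_intervals(intervals: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    """Sort and merge overlapping or book-ended intervals."""
    ivs = sorted(intervals, key=lambda iv: (iv.chrom, iv.start, iv.end))
    merged: list[GenomicInterval] = []
    for iv in ivs:
        if merged and merged[-1].chrom == iv.chrom and iv.start <= merged[-1].end:
            last = merged[-1]
            if iv.end > last.end:
                merged[-1] = GenomicInterval(last.chrom, last.start, iv.end)
        else:
            merged.append(iv)
    return merged


def clip_intervals(
    intervals: Iterable[GenomicInterval], mask: Iterable[GenomicInterval]
) -> list[GenomicInterval]:
    """Intersect intervals with a mask (both merged internally)."""
    ivs = merge_intervals(intervals)
    msk = merge_intervals(mask)
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for m in msk:
        by_chrom.setdefault(m.chrom, []).append(m)
    out: list[GenomicInterval] = []
    for iv in ivs:
        for m in by_chrom.get(iv.chrom, ()):
            s, e = max(iv.start, m.start), min(iv.end, m.end)
            if s < e:
                out.append(GenomicInterval(iv.chrom, s, e))
    return merge_intervals(out)


def complement_intervals(
    intervals: Iterable[GenomicInterval], mask: Iterable[GenomicInterval]
) -> list[GenomicInterval]:
    """Intervals covering mask minus input; disjoint from the input."""
    inside = clip_intervals(intervals, mask)
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in inside:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    out: list[GenomicInterval] = []
    for m in merge_intervals(mask):
        cursor = m.start
        for iv in by_chrom.get(m.chrom, ()):
            if iv.end <= m.start or iv.start >= m.end:
                continue
            if iv.start > cursor:
                out.append(GenomicInterval(m.chrom, cursor, iv.start))
            cursor = max(cursor, iv.end)
        if cursor < m.end:
            out.append(GenomicInterval(m.chrom, cursor, m.end))
    return out


def interval_length(intervals: Iterable[GenomicInterval]) -> int:
    return sum(iv.length for iv in intervals)


class _IntervalLookup:
    """Sorted-array point-membership lookup, one pair of arrays per chromosome."""

    def __init__(self, intervals: Iterable[GenomicInterval]):
        self._starts: dict[str, list[int]] = {}
        self._ends: dict[str, list[int]] = {}
        for iv in merge_intervals(intervals):
            self._starts.setdefault(iv.chrom, []).append(iv.start)
            self._ends.setdefault(iv.chrom, []).append(iv.end)

    def __contains__(self, site: tuple[str, int]) -> bool:
        chrom, pos = site
        starts = self._starts.get(chrom)
        if not starts:
            return False
        i = bisect_right(starts, pos) - 1
        return i >= 0 and pos < self._ends[chrom][i]


@dataclass
class AnnotationSet:
    """Coding intervals plus their complement within the callable mask."""

    coding: list[GenomicInterval]
    noncoding: list[GenomicInterval]

    def __post_init__(self) -> None:
        self._coding_lookup = _IntervalLookup(self.coding)
        self._noncoding_lookup = _IntervalLookup(self.noncoding)

    @classmethod
    def from_coding(
        cls,
        coding: Iterable[GenomicInterval],
        mask: Iterable[GenomicInterval],
    ) -> "AnnotationSet":
        coding = clip_intervals(coding, mask)
        noncoding = complement_intervals(coding, mask)
        return cls(coding=coding, noncoding=noncoding)

    @property
    def coding_length(self) -> int:
        return interval_length(self.coding)

    @property
    def noncoding_length(self) -> int:
        return interval_length(self.noncoding)

    @property
    def callable_length(self) -> int:
        return self.coding_length + self.noncoding_length

    def compartment_of(self, chrom: str, pos: int) -> str | None:
        """'coding', 'noncoding', or None if outside the callable mask."""
        if (chrom, pos) in self._coding_lookup:
            return "coding"
        if (chrom, pos) in self._noncoding_lookup:
            return "noncoding"
        return None


@dataclass(frozen=True)
class VariantCall:
    """One called variant; ``pos`` is the 0-based position of the first ref base."""

    chrom: str
    pos: int
    ref: str
    alt: str
    isolate_id: str | None = None
    genotype_label: str | None = None

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise DataError(
                f"{self.chrom}:{self.pos + 1} {self.ref}>{self.alt}: not a variant"
            )

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)


def _infer_variant_format(path: Path, fmt: str | None) -> str:
    if fmt:
        return fmt
    if path.suffix == ".vcf" or path.name.endswith(".vcf.gz"):
        return "vcf"
    return "tsv"


def _validate_against_reference(
    calls: list[VariantCall], reference: ReferenceGenome, path: Path
) -> None:
    bad = []
    for v in calls:
        expected = reference.fetch(v.chrom, v.pos, v.pos + len(v.ref))
        if expected != v.ref:
            bad.append(f"{v.chrom}:{v.pos + 1} REF {v.ref} (reference has {expected})")
    if bad:
        raise DataError(f"{path}: REF allele mismatches: " + "; ".join(bad[:10]))


def read_variants(
    path: str | Path,
    fmt: str | None = None,
    reference: ReferenceGenome | None = None,
    isolate_id: str | None = None,
    genotype_label: str | None = None,
) -> list[VariantCall]:
    """Read variants from VCF (multi-allelic records split) or a 5-column TSV.

    TSV columns: chrom, pos (1-based), ref, alt, isolate. Positions are
    validated against ``reference`` when one is supplied.
    """
    path = Path(path)
    fmt = _infer_variant_format(path, fmt)
    calls: list[VariantCall] = []
    if fmt == "vcf":
        vcf = VCF(str(path))
        sample = isolate_id or (vcf.samples[0] if vcf.samples else None)
        for rec in vcf:
            for alt in rec.ALT or ():
                calls.append(
                    VariantCall(
                        rec.CHROM, rec.POS - 1, rec.REF, alt, sample, genotype_label
                    )
                )
        vcf.close()
    elif fmt == "tsv":
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "ref": str, "alt": str})
        required = {"chrom", "pos", "ref", "alt"}
        if not required <= set(df.columns):
            raise FormatError(
                f"{path}: TSV needs columns {sorted(required)}, got {list(df.columns)}"
            )
        for row in df.itertuples(index=False):
            calls.append(
                VariantCall(
                    str(row.chrom),
                    int(row.pos) - 1,
                    row.ref,
                    row.alt,
                    isolate_id or getattr(row, "isolate", None),
                    genotype_label,
                )
            )
    else:
        raise ConfigError(f"unknown variant format {fmt!r}")
    if reference is not None:
        _validate_against_reference(calls, reference, path)
    return calls


def write_variants(
    variants: Sequence[VariantCall],
    path: str | Path,
    fmt: str | None = None,
    reference: ReferenceGenome | None = None,
) -> None:
    """Write variants as minimal VCF v4.2 or TSV (both 1-based on disk)."""
    path = Path(path)
    fmt = _infer_variant_format(path, fmt)
    if fmt == "vcf":
        with open(path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            if reference is not None:
                for name in reference.chromosomes:
                    fh.write(f"##contig=<ID={name},length={reference.length(name)}>\n")
            fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
            for v in variants:
                fh.write(
                    f"{v.chrom}\t{v.pos + 1}\t.\t{v.ref}\t{v.alt}\t.\t.\t.\n"
                )
    else:
        rows = [
            {
                "chrom": v.chrom,
                "pos": v.pos + 1,
                "ref": v.ref,
                "alt": v.alt,
                "isolate": v.isolate_id or "",
            }
            for v in variants
        ]
        pd.DataFrame(
            rows, columns=["chrom", "pos", "ref", "alt", "isolate"]
        ).to_csv(path, sep="\t", index=False)
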