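"""96-class trinucleotide substitution signatures and sequence-logo matrices.

Base substitutions are reported on the pyrimidine-strand convention: a
mutation whose reference base is a purine is represented by its reverse
complement, so the six substitution types are C>A, C>G, C>T, T>A, T>C,
T>G and each carries a 5' and 3' flanking base (6 x 16 = 96 classes,
canonical COSMIC ordering).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from .genome_io import DataError, ReferenceGenome, complement_base, reverse_complement
from .spectrum import SUBSTITUTION, MutationRecord, MutationSpectrum

__all__ = [
    "BASES",
    "SUBST_TYPES",
    "CLASSES_96",
    "CLASS_INDEX",
    "MMR_PEAK_CLASSES",
    "SubstClass96",
    "TrinucSignature",
    "LogoMatrix",
    "pyrimidine_context",
    "collapse_to_pyrimidine",
    "build_signature",
    "peak_fraction",
    "build_logo",
    "signature_table",
    "logo_table",
]

logger = logging.getLogger(__name__)

BASES = "ACGT"
SUBST_TYPES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")

#: (substitution type, trinucleotide context) in canonical COSMIC order:
#: C>A..T>G, flanks lexicographic A,C,G,T.
CLASSES_96: list[tuple[str, str]] = [
    (st, f5 + st[0] + f3)
    for st in SUBST_TYPES
    for f5 in BASES
    for f3 in BASES
]
CLASS_INDEX: dict[tuple[str, str], int] = {c: i for i, c in enumerate(CLASSES_96)}

#: The three dominant classes of the MMR-deficiency spectrum:
#: C>T at GCA and ACA, C>A at CCT.
MMR_PEAK_CLASSES = frozenset({("C>T", "GCA"), ("C>T", "ACA"), ("C>A", "CCT")})


@dataclass(frozen=True)
class SubstClass96:
    """One of the 96 trinucleotide substitution classes."""

    ref: str  # pyrimidine, C or T
    alt: str
    flank5: str
    flank3: str

    @property
    def subst_type(self) -> str:
        return f"{self.ref}>{self.alt}"

    @property
    def context(self) -> str:
        return self.flank5 + self.ref + self.flank3

    @property
    def index(self) -> int:
        return CLASS_INDEX[(self.subst_type, self.context)]

    @property
    def label(self) -> str:
        return f"{self.flank5}[{self.subst_type}]{self.flank3}"


def pyrimidine_context(
    genome: ReferenceGenome,
    chrom: str,
    pos: int,
    ref: str,
    alt: str,
    k: int = 1,
) -> tuple[str, str] | None:
    """Substitution type and (2k+1)-mer context on the pyrimidine strand.

    Returns None when the window runs off the contig or contains an N;
    such mutations are excluded from context analyses and logged by the
    callers that count them.
    """
    if len(ref) != 1 or len(alt) != 1:
        raise DataError(f"{chrom}:{pos + 1}: {ref}>{alt} is not a base substitution")
    start, end = pos - k, pos + k + 1
    if start < 0 or end > genome.length(chrom):
        return None
    window = genome.fetch(chrom, start, end)
    if "N" in window or ref == "N" or alt == "N":
        return None
    if window[k] != ref:
        raise DataError(
            f"{chrom}:{pos + 1}: REF {ref} does not match reference ({window[k]})"
        )
    if ref in "CT":
        return f"{ref}>{alt}", window
    return (
        f"{complement_base(ref)}>{complement_base(alt)}",
        reverse_complement(window),
    )


def collapse_to_pyrimidine(
    genome: ReferenceGenome, chrom: str, pos: int, ref: str, alt: str
) -> SubstClass96 | None:
    """Classify one substitution into its 96-class; None if N/edge-excluded."""
    res = pyrimidine_context(genome, chrom, pos, ref, alt, k=1)
    if res is None:
        return None
    subst, ctx = res
    return SubstClass96(ref=subst[0], alt=subst[2], flank5=ctx[0], flank3=ctx[2])


@dataclass
class TrinucSignature:
    """Counts over the 96 classes plus the number of excluded substitutions."""

    counts: np.ndarray  # shape (96,), int
    n_excluded: int = 0

    @property
    def n_total(self) -> int:
        return int(self.counts.sum())

    @property
    def fractions(self) -> np.ndarray:
        n = self.n_total
        return self.counts / n if n > 0 else np.zeros(96)

    def __add__(self, other: "TrinucSignature") -> "TrinucSignature":
        return TrinucSignature(
            self.counts + other.counts, self.n_excluded + other.n_excluded
        )


def _iter_substitutions(
    source: MutationSpectrum | Iterable[MutationRecord],
) -> Iterable[MutationRecord]:
    mutations = source.mutations if isinstance(source, MutationSpectrum) else source
    return (m for m in mutations if m.mclass == SUBSTITUTION and len(m.ref) == 1)


def build_signature(
    source: MutationSpectrum | Iterable[MutationRecord], genome: ReferenceGenome
) -> TrinucSignature:
    """96-class signature of all classifiable substitutions in a spectrum."""
    counts = np.zeros(96, dtype=int)
    excluded = 0
    for m in _iter_substitutions(source):
        cls = collapse_to_pyrimidine(genome, m.chrom, m.pos, m.ref, m.alt)
        if cls is None:
            excluded += 1
            logger.info(
                "substitution at %s:%d excluded from signature (N or contig edge)",
                m.chrom, m.pos + 1,
            )
            continue
        counts[cls.index] += 1
    return TrinucSignature(counts, excluded)


def peak_fraction(
    signature: TrinucSignature, class_set: Iterable[tuple[str, str]]
) -> float | None:
    """Fraction of all classified substitutions falling in ``class_set``.

    None when the signature is empty (the fraction is undefined).
    """
    if signature.n_total == 0:
        return None
    idx = [CLASS_INDEX[c] for c in class_set]
    return float(signature.counts[idx].sum() / signature.n_total)


@dataclass
class LogoMatrix:
    """Per-position base counts around mutated sites, pyrimidine-oriented.

    Rows are positions -k..+k relative to the mutated base; columns A,C,G,T.
    """

    window: int
    counts: np.ndarray  # shape (2k+1, 4), int
    n_excluded: int = 0

    @property
    def n_sequences(self) -> int:
        return int(self.counts[self.window].sum())

    @property
    def frequencies(self) -> np.ndarray:
        totals = self.counts.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            freq = np.where(totals > 0, self.counts / totals, 0.0)
        return freq

    @property
    def info_content(self) -> np.ndarray:
        """Per-position information content in bits: 2 - H(p), H in log2.

        No small-sample correction is applied (toggle is the caller's
        choice of post-processing); 0*log(0) is taken as 0.
        """
        p = self.frequencies
        with np.errstate(invalid="ignore", divide="ignore"):
            plogp = np.where(p > 0, p * np.log2(p), 0.0)
        return 2.0 + plogp.sum(axis=1)


def build_logo(
    source: MutationSpectrum | Iterable[MutationRecord],
    subst_class: str,
    window_k: int,
    genome: ReferenceGenome,
) -> LogoMatrix:
    """Base-count matrix over +-k around substitutions of one type.

    Flanks are taken on the strand on which the mutated base is the
    pyrimidine. Windows running off a contig or over an N are excluded
    and counted in ``n_excluded``.
    """
    if subst_class not in SUBST_TYPES:
        raise DataError(f"unknown substitution type {subst_class!r}")
    counts = np.zeros((2 * window_k + 1, 4), dtype=int)
    base_idx = {b: i for i, b in enumerate(BASES)}
    n = 0
    excluded = 0
    for m in _iter_substitutions(source):
        res = pyrimidine_context(genome, m.chrom, m.pos, m.ref, m.alt, k=window_k)
        if res is None:
            # only excluded if it is of the requested type at radius 1
            near = pyrimidine_context(genome, m.chrom, m.pos, m.ref, m.alt, k=0)
            if near is not None and near[0] == subst_class:
                excluded += 1
            continue
        subst, window = res
        if subst != subst_class:
            continue
        for i, b in enumerate(window):
            counts[i, base_idx[b]] += 1
        n += 1
    if n == 0:
        raise DataError(f"no qualifying {subst_class} substitutions for logo")
    return LogoMatrix(window_k, counts, excluded)


def match_context(context: str, pattern: str) -> bool:
    """Does a pyrimidine-strand context match a pattern with N wildcards?"""
    return len(context) == len(pattern) and all(
        p in ("N", c) for c, p in zip(context, pattern)
    )


def count_context_sites(genome: ReferenceGenome, pattern: str) -> int:
    """Genomic positions whose pyrimidine-collapsed context matches a pattern.

    Every non-N position is counted once: a site is read on the strand on
    which its central base is a pyrimidine.
    """
    k = (len(pattern) - 1) // 2
    if len(pattern) != 2 * k + 1:
        raise DataError("context pattern must have odd length")
    n = 0
    for chrom in genome.chromosomes:
        seq = genome.sequences[chrom]
        for pos in range(k, len(seq) - k):
            window = seq[pos - k : pos + k + 1]
            if "N" in window:
                continue
            if window[k] in "AG":
                window = reverse_complement(window)
            if match_context(window, pattern):
                n += 1
    return n


def signature_table(signature: TrinucSignature) -> pd.DataFrame:
    """96-row table (canonical order) with counts and fractions."""
    frac = signature.fractions
    return pd.DataFrame(
        {
            "subst_type": [st for st, _ in CLASSES_96],
            "context": [ctx for _, ctx in CLASSES_96],
            "count": signature.counts,
            "fraction": frac,
        }
    )


def logo_table(logo: LogoMatrix) -> pd.DataFrame:
    k = logo.window
    freq = logo.frequencies
    info = logo.info_content
    rows = []
    for i in range(2 * k + 1):
        row: dict[str, object] = {"position": i - k}
        for j, b in enumerate(BASES):
            row[f"count_{b}"] = int(logo.counts[i, j])
            row[f"freq_{b}"] = freq[i, j]
        row["info_bits"] = info[i]
        rows.append(row)
    return pd.DataFrame(rows)
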