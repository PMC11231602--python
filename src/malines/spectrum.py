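"""De novo mutation derivation and per-genotype pooling.

A mutation-accumulation isolate is sequenced at generation 0 and again
after ~900 generations of single-cell bottleneck passaging. De novo
mutations are the final-generation variants minus the generation-0
variants of the same isolate, compared by exact normalized identity
(chrom, pos, ref, alt). Left-alignment makes that identity well defined
for indels regardless of how the caller represented them.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .genome_io import ConfigError, DataError, ReferenceGenome, VariantCall

__all__ = [
    "SUBSTITUTION",
    "INSERTION",
    "DELETION",
    "COMPLEX",
    "MutationRecord",
    "IsolatePair",
    "MutationSpectrum",
    "normalize_variant",
    "classify_alleles",
    "subtract_generation0",
    "pool_by_genotype",
    "spectrum_table",
]

logger = logging.getLogger(__name__)

SUBSTITUTION = "substitution"
INSERTION = "insertion"
DELETION = "deletion"
COMPLEX = "complex"


@dataclass(frozen=True)
class MutationRecord:
    """One de novo mutation with its class and provenance."""

    chrom: str
    pos: int  # 0-based position of the first ref base
    ref: str
    alt: str
    isolate_id: str
    genotype_label: str
    mclass: str
    indel_size: int

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass
class IsolatePair:
    """Variant lists of one isolate at generation 0 and the final generation."""

    isolate_id: str
    genotype_label: str
    gen0_variants: list[VariantCall]
    gen_final_variants: list[VariantCall]
    generations: int = 900

    def __post_init__(self) -> None:
        if self.generations <= 0:
            raise ConfigError(f"isolate {self.isolate_id}: generations must be > 0")


@dataclass
class MutationSpectrum:
    """Pooled de novo mutations of one genotype across its isolates."""

    genotype_label: str
    mutations: list[MutationRecord]
    per_isolate: dict[str, list[MutationRecord]]
    generations: dict[str, int]  # isolate -> generations passaged

    @property
    def n_isolates(self) -> int:
        return len(self.per_isolate)

    @property
    def total_generations(self) -> int:
        return sum(self.generations.values())

    def of_class(self, mclass: str) -> list[MutationRecord]:
        return [m for m in self.mutations if m.mclass == mclass]

    @property
    def substitutions(self) -> list[MutationRecord]:
        return self.of_class(SUBSTITUTION)


def classify_alleles(ref: str, alt: str) -> tuple[str, int]:
    """Mutation class and indel size from a (normalized) allele pair.

    Equal-length multi-base pairs that differ at a single base would have
    been reduced to that base by normalization; if one still reaches here
    it is classified as a substitution. Equal-length pairs differing at
    several bases are complex events: retained in totals, excluded from
    the 96-class signature.
    """
    if len(ref) == 1 and len(alt) == 1:
        return SUBSTITUTION, 0
    if len(alt) > len(ref):
        return INSERTION, len(alt) - len(ref)
    if len(ref) > len(alt):
        return DELETION, len(ref) - len(alt)
    diffs = sum(a != b for a, b in zip(ref, alt))
    return (SUBSTITUTION, 0) if diffs == 1 else (COMPLEX, 0)


def normalize_variant(v: VariantCall, genome: ReferenceGenome) -> VariantCall:
    """Left-align and minimally represent a variant.

    Shared suffix bases are trimmed (extending one reference base to the
    left whenever an allele would become empty, which slides indels to
    the leftmost equivalent placement), then shared prefix bases are
    trimmed down to the single anchor base indels keep for VCF emission.
    """
    chrom, pos, ref, alt = v.chrom, v.pos, v.ref, v.alt
    if ref == alt:
        raise DataError(f"{chrom}:{pos + 1} {ref}>{alt}: not a variant")
    observed = genome.fetch(chrom, pos, pos + len(ref))
    if observed != ref:
        raise DataError(
            f"{chrom}:{pos + 1}: REF {ref} does not match reference ({observed})"
        )
    while ref[-1] == alt[-1]:
        if len(ref) == 1 or len(alt) == 1:
            if pos == 0:
                break  # cannot left-extend past the contig edge
            pos -= 1
            b = genome.base(chrom, pos)
            ref = b + ref
            alt = b + alt
        ref = ref[:-1]
        alt = alt[:-1]
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref = ref[1:]
        alt = alt[1:]
        pos += 1
    return VariantCall(chrom, pos, ref, alt, v.isolate_id, v.genotype_label)


def subtract_generation0(pair: IsolatePair) -> list[MutationRecord]:
    """Final-generation minus generation-0 variants, by exact identity."""
    ancestral = {v.key for v in pair.gen0_variants}
    records: list[MutationRecord] = []
    for v in pair.gen_final_variants:
        if v.key in ancestral:
            continue
        mclass, size = classify_alleles(v.ref, v.alt)
        if mclass == COMPLEX:
            logger.info(
                "isolate %s: complex event at %s:%d %s>%s (kept in totals, "
                "excluded from signatures)",
                pair.isolate_id, v.chrom, v.pos + 1, v.ref, v.alt,
            )
        records.append(
            MutationRecord(
                v.chrom, v.pos, v.ref, v.alt,
                pair.isolate_id, pair.genotype_label, mclass, size,
            )
        )
    return records


def pool_by_genotype(pairs: Iterable[IsolatePair]) -> dict[str, MutationSpectrum]:
    """De novo mutations of every isolate, pooled per genotype."""
    pairs = list(pairs)
    seen: dict[str, str] = {}
    for p in pairs:
        if p.isolate_id in seen and seen[p.isolate_id] != p.genotype_label:
            raise ConfigError(
                f"isolate {p.isolate_id!r} appears under genotypes "
                f"{seen[p.isolate_id]!r} and {p.genotype_label!r}"
            )
        if p.isolate_id in seen:
            raise ConfigError(f"duplicate isolate id {p.isolate_id!r}")
        seen[p.isolate_id] = p.genotype_label
    spectra: dict[str, MutationSpectrum] = {}
    for p in pairs:
        sp = spectra.setdefault(
            p.genotype_label,
            MutationSpectrum(p.genotype_label, [], {}, {}),
        )
        denovo = subtract_generation0(p)
        sp.mutations.extend(denovo)
        sp.per_isolate[p.isolate_id] = denovo
        sp.generations[p.isolate_id] = p.generations
    return spectra


def spectrum_table(spectrum: MutationSpectrum) -> pd.DataFrame:
    """One mutation per row (positions 1-based for export)."""
    return pd.DataFrame(
        [
            {
                "genotype": m.genotype_label,
                "isolate": m.isolate_id,
                "chrom": m.chrom,
                "pos": m.pos + 1,
                "ref": m.ref,
                "alt": m.alt,
                "class": m.mclass,
                "indel_size": m.indel_size,
            }
            for m in spectrum.mutations
        ],
        columns=[
            "genotype", "isolate", "chrom", "pos", "ref", "alt", "class", "indel_size",
        ],
    )
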