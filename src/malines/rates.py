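"""Mutation-rate estimation for mutation-accumulation experiments.

The pooled point estimate is mu = N_i / gen / N_g: N_i mutations of type
i accumulated over gen total generations (summed across isolates) in a
callable genome of N_g base pairs (the diploid yeast value is
22,983,805 bp). Figure-style error bars are the mean +- sample SD of the
same quantity computed per isolate.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

from .genome_io import DataError, ReferenceGenome
from .signatures import match_context, pyrimidine_context, count_context_sites
from .spectrum import (
    DELETION,
    INSERTION,
    SUBSTITUTION,
    MutationRecord,
    MutationSpectrum,
)

__all__ = [
    "YEAST_DIPLOID_NG",
    "RateEstimate",
    "pooled_rate",
    "per_isolate_rates",
    "context_rate",
    "per_division_rate",
    "fold_change",
    "class_selector",
    "ALL_MUTATIONS",
]

#: Size of the diploid S. cerevisiae genome in which variants are called.
YEAST_DIPLOID_NG = 22_983_805

Selector = Callable[[MutationRecord], bool]

ALL_MUTATIONS: Selector = lambda m: True  # noqa: E731


def class_selector(mclass: str) -> Selector:
    if mclass not in (SUBSTITUTION, INSERTION, DELETION, "complex"):
        raise DataError(f"unknown mutation class {mclass!r}")
    return lambda m: m.mclass == mclass


@dataclass
class RateEstimate:
    """A mutation rate with its inputs and per-isolate dispersion.

    ``mu`` is the pooled estimate N_i/gen/N_g; ``mean``/``sd`` summarize
    the per-isolate estimates (sd is None with fewer than two isolates).
    """

    mu: float
    n_i: int
    gen: float
    n_g: float
    per_isolate_mu: tuple[float, ...] = ()
    mean: float | None = None
    sd: float | None = None
    divisor_kind: str = "bp_generations"


def pooled_rate(n_i: int, gen: float, n_g: float) -> float:
    """mu = N_i / gen / N_g."""
    if n_i < 0:
        raise DataError("mutation count must be non-negative")
    if gen <= 0 or n_g <= 0:
        raise DataError("gen and N_g must be strictly positive")
    return n_i / gen / n_g


def _mean_sd(values: Sequence[float]) -> tuple[float, float | None]:
    mean = sum(values) / len(values)
    if len(values) < 2:
        return mean, None
    var = sum((v - mean) ** 2 for v in values) / (len(values) - 1)
    return mean, math.sqrt(var)


def _estimate_from_counts(
    counts: dict[str, int], generations: dict[str, int], n_g: float
) -> RateEstimate:
    gen_total = sum(generations.values())
    n_total = sum(counts.values())
    per_iso = tuple(
        pooled_rate(counts[iso], generations[iso], n_g) for iso in generations
    )
    mean, sd = _mean_sd(per_iso) if per_iso else (0.0, None)
    return RateEstimate(
        mu=pooled_rate(n_total, gen_total, n_g),
        n_i=n_total,
        gen=gen_total,
        n_g=n_g,
        per_isolate_mu=per_iso,
        mean=mean,
        sd=sd,
    )


def per_isolate_rates(
    spectrum: MutationSpectrum, selector: Selector, n_g: float
) -> RateEstimate:
    """Pooled rate plus per-isolate mean +- SD for a mutation selector."""
    counts = {
        iso: sum(1 for m in muts if selector(m))
        for iso, muts in spectrum.per_isolate.items()
    }
    return _estimate_from_counts(counts, spectrum.generations, n_g)


def context_rate(
    spectrum: MutationSpectrum,
    subst_class: str,
    context_pattern: str,
    genome: ReferenceGenome,
    n_g: float,
    per_target_site: bool = False,
) -> RateEstimate:
    """Rate of substitutions of one type in a context pattern.

    ``subst_class`` is on the pyrimidine convention (e.g. "T>C") and
    ``context_pattern`` an odd-length string over A/C/G/T/N centered on
    the mutated base (e.g. "ATA", "NTN"). Matching is done after strand
    collapse, so an A>G on the plus strand with context TAT counts as
    T>C at ATA. The divisor is gen x N_g by default; with
    ``per_target_site`` it is gen x (number of genomic positions whose
    collapsed context matches the pattern).
    """
    if len(context_pattern) % 2 != 1:
        raise DataError("context pattern must have odd length")
    if any(c not in "ACGTN" for c in context_pattern):
        raise DataError(f"invalid context pattern {context_pattern!r}")
    k = (len(context_pattern) - 1) // 2
    counts: dict[str, int] = {}
    for iso, muts in spectrum.per_isolate.items():
        n = 0
        for m in muts:
            if m.mclass != SUBSTITUTION or len(m.ref) != 1:
                continue
            res = pyrimidine_context(genome, m.chrom, m.pos, m.ref, m.alt, k)
            if res is None:
                continue
            subst, ctx = res
            if subst == subst_class and match_context(ctx, context_pattern):
                n += 1
        counts[iso] = n
    divisor = (
        count_context_sites(genome, context_pattern) if per_target_site else n_g
    )
    est = _estimate_from_counts(counts, spectrum.generations, divisor)
    if per_target_site:
        est.divisor_kind = "target_sites"
    return est


def per_division_rate(
    mutation_counts: Sequence[int], divisions_per_sample: Sequence[float]
) -> RateEstimate:
    """Mutations per cell division, the convention used for cultured cells.

    One count and one division number per sample; the pooled estimate is
    total mutations over total divisions, and mean +- SD summarize the
    per-sample rates.
    """
    if len(mutation_counts) != len(divisions_per_sample) or not mutation_counts:
        raise DataError("need one mutation count per division number")
    if any(d <= 0 for d in divisions_per_sample):
        raise DataError("divisions must be strictly positive")
    per_sample = tuple(
        c / d for c, d in zip(mutation_counts, divisions_per_sample)
    )
    mean, sd = _mean_sd(per_sample)
    return RateEstimate(
        mu=sum(mutation_counts) / sum(divisions_per_sample),
        n_i=int(sum(mutation_counts)),
        gen=float(sum(divisions_per_sample)),
        n_g=1.0,
        per_isolate_mu=per_sample,
        mean=mean,
        sd=sd,
        divisor_kind="cell_divisions",
    )


def fold_change(rate_a: RateEstimate | float, rate_b: RateEstimate | float) -> float:
    """Ratio of pooled rates a/b; infinite (with a warning) when b is 0."""
    a = rate_a.mu if isinstance(rate_a, RateEstimate) else float(rate_a)
    b = rate_b.mu if isinstance(rate_b, RateEstimate) else float(rate_b)
    if b == 0:
        warnings.warn("fold change relative to a zero rate is infinite")
        return math.inf
    return a / b
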