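"""Coding/noncoding partition of mutations: observed/expected ratios,
the noncoding-preference statistic, and per-compartment rates.

The expected count in a compartment is proportional to its length
within the callable mask (the natural null of uniform per-bp mutation).
"Preference" is O/E(noncoding) / O/E(coding), which algebraically equals
the per-bp mutation density ratio between the compartments — with
noncoding only ~1/4 of the yeast genome, a bare O/E is bounded near 4
and cannot express the 8-10-fold biases this ratio can.
"""
from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from typing import Iterable

import pandas as pd

from .genome_io import AnnotationSet, DataError
from .rates import RateEstimate, Selector, ALL_MUTATIONS, _estimate_from_counts
from .spectrum import DELETION, MutationRecord, MutationSpectrum

__all__ = [
    "CompartmentCounts",
    "assign_compartment",
    "compartment_counts",
    "observed_expected",
    "noncoding_preference",
    "compartment_rates",
    "compartment_table",
]

logger = logging.getLogger(__name__)


@dataclass
class CompartmentCounts:
    coding_count: int
    noncoding_count: int
    coding_length: int
    noncoding_length: int

    @property
    def total(self) -> int:
        return self.coding_count + self.noncoding_count


def _anchor_position(m: MutationRecord) -> int:
    """First reference base affected by a normalized mutation.

    Substitutions: the substituted base. Deletions: the first deleted
    base (one past the anchor). Insertions: the base 5' of the insertion
    point (the anchor itself).
    """
    if m.mclass == DELETION and len(m.ref) > 1:
        return m.pos + 1
    return m.pos


def assign_compartment(m: MutationRecord, annotation: AnnotationSet) -> str | None:
    """'coding' or 'noncoding'; None (logged) outside the callable mask."""
    comp = annotation.compartment_of(m.chrom, _anchor_position(m))
    if comp is None:
        logger.info(
            "mutation at %s:%d outside callable mask, excluded", m.chrom, m.pos + 1
        )
    return comp


def compartment_counts(
    mutations: Iterable[MutationRecord], annotation: AnnotationSet
) -> CompartmentCounts:
    coding = noncoding = 0
    for m in mutations:
        comp = assign_compartment(m, annotation)
        if comp == "coding":
            coding += 1
        elif comp == "noncoding":
            noncoding += 1
    return CompartmentCounts(
        coding, noncoding, annotation.coding_length, annotation.noncoding_length
    )


def observed_expected(counts: CompartmentCounts) -> dict[str, float]:
    """O/E per compartment under the length-proportional null."""
    if counts.coding_length <= 0 or counts.noncoding_length <= 0:
        raise DataError("both compartments need non-zero length")
    if counts.total == 0:
        raise DataError("no mutations to distribute")
    total_len = counts.coding_length + counts.noncoding_length
    exp_coding = counts.total * counts.coding_length / total_len
    exp_noncoding = counts.total * counts.noncoding_length / total_len
    return {
        "coding": counts.coding_count / exp_coding,
        "noncoding": counts.noncoding_count / exp_noncoding,
    }


def noncoding_preference(counts: CompartmentCounts) -> float:
    """O/E(noncoding) / O/E(coding) == per-bp density ratio noncoding/coding."""
    oe = observed_expected(counts)
    if oe["coding"] == 0:
        warnings.warn("no coding mutations: noncoding preference is infinite")
        return math.inf
    return oe["noncoding"] / oe["coding"]


def compartment_rates(
    spectrum: MutationSpectrum,
    annotation: AnnotationSet,
    selector: Selector = ALL_MUTATIONS,
    ploidy_factor: int = 2,
) -> dict[str, RateEstimate]:
    """Per-compartment rates: N_c / gen / (compartment length x ploidy).

    The length-weighted mean of the two rates equals the genome-wide
    rate for the same selector and mask.
    """
    counts: dict[str, dict[str, int]] = {
        "coding": {iso: 0 for iso in spectrum.per_isolate},
        "noncoding": {iso: 0 for iso in spectrum.per_isolate},
    }
    for iso, muts in spectrum.per_isolate.items():
        for m in muts:
            if not selector(m):
                continue
            comp = assign_compartment(m, annotation)
            if comp is not None:
                counts[comp][iso] += 1
    lengths = {
        "coding": annotation.coding_length * ploidy_factor,
        "noncoding": annotation.noncoding_length * ploidy_factor,
    }
    return {
        comp: _estimate_from_counts(counts[comp], spectrum.generations, lengths[comp])
        for comp in ("coding", "noncoding")
    }


def compartment_table(
    spectrum: MutationSpectrum,
    annotation: AnnotationSet,
    selectors: dict[str, Selector],
    ploidy_factor: int = 2,
) -> pd.DataFrame:
    """Report rows per mutation class: observed, expected, O/E, preference, rate."""
    rows = []
    for name, sel in selectors.items():
        cc = compartment_counts((m for m in spectrum.mutations if sel(m)), annotation)
        rates = compartment_rates(spectrum, annotation, sel, ploidy_factor)
        if cc.total > 0:
            oe = observed_expected(cc)
            pref = noncoding_preference(cc)
        else:
            oe = {"coding": float("nan"), "noncoding": float("nan")}
            pref = float("nan")
        total_len = cc.coding_length + cc.noncoding_length
        for comp in ("coding", "noncoding"):
            obs = cc.coding_count if comp == "coding" else cc.noncoding_count
            length = cc.coding_length if comp == "coding" else cc.noncoding_length
            rows.append(
                {
                    "class": name,
                    "compartment": comp,
                    "observed": obs,
                    "expected": cc.total * length / total_len,
                    "oe": oe[comp],
                    "noncoding_preference": pref,
                    "rate": rates[comp].mu,
                    "rate_mean": rates[comp].mean,
                    "rate_sd": rates[comp].sd,
                }
            )
    return pd.DataFrame(rows)
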