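"""Homopolymeric-run detection and run-stratified mutation analyses.

A homopolymeric run is a maximal stretch of one repeated base; N breaks
runs, and "N3"/"A11" analyses use exact run length (3 or 11), not a
minimum. Reference T-runs are the reverse-strand reading of A-runs, so
A-run analyses orient T-runs onto the A strand before looking at the
downstream base.
"""
from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from .genome_io import DataError, ReferenceGenome, complement_base
from .rates import RateEstimate, _estimate_from_counts
from .signatures import pyrimidine_context
from .spectrum import DELETION, SUBSTITUTION, MutationRecord, MutationSpectrum

__all__ = [
    "HomopolymerRun",
    "find_runs",
    "run_at",
    "run_length_at",
    "run_length_totals",
    "substitutions_by_run_length",
    "rate_in_runs",
    "deletion_run_assignment",
    "downstream_base_profile",
    "runs_to_bed",
    "histogram_table",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class HomopolymerRun:
    """Maximal single-base repeat [start, end) of ``base`` on ``chrom``."""

    chrom: str
    start: int
    end: int
    base: str

    @property
    def length(self) -> int:
        return self.end - self.start


def find_runs(genome: ReferenceGenome, min_len: int = 1) -> list[HomopolymerRun]:
    """All maximal runs of length >= min_len; N breaks runs."""
    if min_len < 1:
        raise DataError("min_len must be >= 1")
    runs: list[HomopolymerRun] = []
    for chrom, seq in genome.sequences.items():
        codes = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
        change = np.flatnonzero(codes[1:] != codes[:-1]) + 1
        starts = np.concatenate(([0], change))
        ends = np.concatenate((change, [len(seq)]))
        keep = (ends - starts) >= min_len
        for s, e in zip(starts[keep], ends[keep]):
            b = seq[s]
            if b != "N":
                runs.append(HomopolymerRun(chrom, int(s), int(e), b))
    return runs


def run_at(genome: ReferenceGenome, chrom: str, pos: int) -> HomopolymerRun | None:
    """The maximal run containing a position; None on an N base."""
    seq = genome.sequences[chrom]
    b = seq[pos]
    if b == "N":
        return None
    s = pos
    while s > 0 and seq[s - 1] == b:
        s -= 1
    e = pos + 1
    while e < len(seq) and seq[e] == b:
        e += 1
    return HomopolymerRun(chrom, s, e, b)


def run_length_at(genome: ReferenceGenome, chrom: str, pos: int) -> int | None:
    run = run_at(genome, chrom, pos)
    return run.length if run else None


def run_length_totals(genome: ReferenceGenome) -> dict[int, int]:
    """Total non-N bp lying in runs of each exact length."""
    totals: Counter[int] = Counter()
    for chrom, seq in genome.sequences.items():
        codes = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
        change = np.flatnonzero(codes[1:] != codes[:-1]) + 1
        starts = np.concatenate(([0], change))
        ends = np.concatenate((change, [len(seq)]))
        lengths = ends - starts
        is_n = codes[starts] == ord("N")
        for ln, cnt in zip(*np.unique(lengths[~is_n], return_counts=True)):
            totals[int(ln)] += int(ln) * int(cnt)
    return dict(totals)


def substitutions_by_run_length(
    spectrum: MutationSpectrum, genome: ReferenceGenome
) -> dict[int, int]:
    """Histogram: run length at the mutated position -> substitution count."""
    hist: Counter[int] = Counter()
    for m in spectrum.substitutions:
        ln = run_length_at(genome, m.chrom, m.pos)
        if ln is None:
            logger.info("substitution on N at %s:%d excluded", m.chrom, m.pos + 1)
            continue
        hist[ln] += 1
    return dict(hist)


def rate_in_runs(
    spectrum: MutationSpectrum,
    genome: ReferenceGenome,
    run_length: int,
    n_g: float,
    subst_class: str | None = None,
    per_run_bp: bool = False,
) -> RateEstimate:
    """Rate of substitutions lying in runs of exactly ``run_length``.

    ``subst_class`` restricts to one pyrimidine-strand type (e.g. "C>T");
    None counts every substitution. The divisor is gen x N_g; with
    ``per_run_bp`` it is gen x (total bp in runs of that length).
    """
    if run_length < 1:
        raise DataError("run_length must be >= 1")
    counts: dict[str, int] = {}
    for iso, muts in spectrum.per_isolate.items():
        n = 0
        for m in muts:
            if m.mclass != SUBSTITUTION or len(m.ref) != 1:
                continue
            if run_length_at(genome, m.chrom, m.pos) != run_length:
                continue
            if subst_class is not None:
                res = pyrimidine_context(genome, m.chrom, m.pos, m.ref, m.alt, 0)
                if res is None or res[0] != subst_class:
                    continue
            n += 1
        counts[iso] = n
    divisor = float(n_g)
    kind = "bp_generations"
    if per_run_bp:
        divisor = float(run_length_totals(genome).get(run_length, 0))
        kind = "run_bp_generations"
        if divisor == 0:
            raise DataError(f"no runs of length {run_length} in the genome")
    est = _estimate_from_counts(counts, spectrum.generations, divisor)
    est.divisor_kind = kind
    return est


def deletion_run_assignment(
    m: MutationRecord, genome: ReferenceGenome
) -> HomopolymerRun | None:
    """The run a (left-aligned, anchored) 1-bp deletion removed a base from.

    Returns None unless the deleted base equals the base of the run it
    sits in; the assignment is invariant to where in the run the caller
    placed the deletion because normalization left-aligned it first.
    """
    if m.mclass != DELETION or m.indel_size != 1 or len(m.ref) != 2:
        return None
    deleted_pos = m.pos + 1
    deleted_base = m.ref[1]
    run = run_at(genome, m.chrom, deleted_pos)
    if run is None or run.base != deleted_base:
        return None
    return run


def downstream_base_profile(
    spectrum: MutationSpectrum,
    genome: ReferenceGenome,
    base: str = "A",
    run_length: int = 11,
) -> dict[str, float]:
    """Base immediately 3' of runs in which 1-bp deletions accumulated.

    Runs are strand-oriented to read as ``base``: a reference T-run is
    reverse-complemented, so its oriented downstream base is the
    complement of the reference base 5' of the run. Frequencies sum to 1
    over counted events; runs at contig edges are excluded.
    """
    if base not in "ACGT":
        raise DataError(f"invalid run base {base!r}")
    comp = complement_base(base)
    counts: Counter[str] = Counter()
    for m in spectrum.mutations:
        run = deletion_run_assignment(m, genome)
        if run is None or run.length != run_length:
            continue
        if run.base == base:
            if run.end >= genome.length(run.chrom):
                logger.info("run at contig edge excluded: %s:%d", run.chrom, run.start)
                continue
            nb = genome.base(run.chrom, run.end)
        elif run.base == comp:
            if run.start == 0:
                logger.info("run at contig edge excluded: %s:%d", run.chrom, run.start)
                continue
            nb = complement_base(genome.base(run.chrom, run.start - 1))
        else:
            continue
        if nb == "N":
            continue
        counts[nb] += 1
    total = sum(counts.values())
    return {b: counts[b] / total for b in sorted(counts)} if total else {}


def runs_to_bed(runs: Iterable[HomopolymerRun], path) -> None:
    with open(path, "w") as fh:
        for r in runs:
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.base}{r.length}\n")


def histogram_table(hist: dict[int, int]) -> pd.DataFrame:
    return pd.DataFrame(
        {"run_length": sorted(hist), "count": [hist[k] for k in sorted(hist)]}
    )
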