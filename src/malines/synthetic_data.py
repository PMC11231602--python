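"""Synthetic mutation-accumulation datasets with known ground truth.

Generates toy genomes with a coding/noncoding layout and homopolymer-
enriched noncoding DNA, then simulates passaged diploid isolates: each
isolate carries planted ancestral variants (present at generation 0 and
the final generation alike) plus de novo mutations whose counts are
Poisson in rate x generations x ploidy x target bp and whose placement
follows a configurable rate model (96-class weights, context
multipliers, compartment-biased substitution and 1-bp-indel densities,
run-length-weighted indel placement, downstream-base bias of A/T-run
deletions). Single-cell bottleneck passaging accumulates mutations
approximately as a Poisson process, so no explicit genealogy is drawn.

Every planted de novo mutation is emitted in a truth table so that each
downstream stage of the pipeline can be checked against what was put in.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable

import numpy as np
import pandas as pd

from .genome_io import (
    AnnotationSet,
    ConfigError,
    GenomicInterval,
    ReferenceGenome,
    VariantCall,
)
from .signatures import BASES, CLASSES_96, CLASS_INDEX, SUBST_TYPES
from .spectrum import DELETION, INSERTION, SUBSTITUTION, IsolatePair

__all__ = [
    "RateModel",
    "SimConfig",
    "SimResult",
    "make_genome",
    "GenomeIndex",
    "simulate_lines",
    "scenario_presets",
]

_BASE_BYTES = np.frombuffer(b"ACGT", dtype=np.uint8)
_CODE = {b: i for i, b in enumerate(BASES)}
_N_CODE = 4


@dataclass
class RateModel:
    """Mutational parameters of one simulated genotype.

    Rates are per haploid bp per generation; the ploidy factor of the
    config multiplies the target size. ``class_weights`` override the
    uniform relative weight (1.0) of listed 96-classes;
    ``context_multipliers`` ("T>C|ATA" -> factor) multiply on top.
    Indels are 1-bp events inside homopolymer runs, placed across runs
    with probability proportional to length**run_length_exponent (and a
    downstream-base bias for A/T runs when configured).
    """

    sub_rate: float = 0.0
    sub_rate_noncoding: float | None = None
    class_weights: dict[tuple[str, str], float] = field(default_factory=dict)
    context_multipliers: dict[str, float] = field(default_factory=dict)
    indel_rate: float = 0.0
    indel_rate_noncoding: float | None = None
    deletion_fraction: float = 0.7
    run_length_exponent: float = 1.0
    run3_extra_sub_rate: float = 0.0
    downstream_bias: dict[str, float] | None = None
    ancestral_count: int = 50

    def validate(self) -> None:
        for r in (
            self.sub_rate,
            self.indel_rate,
            self.run3_extra_sub_rate,
            self.sub_rate_noncoding or 0.0,
            self.indel_rate_noncoding or 0.0,
        ):
            if r < 0:
                raise ConfigError("rates must be non-negative")
        if not 0.0 <= self.deletion_fraction <= 1.0:
            raise ConfigError("deletion_fraction must be in [0, 1]")
        if self.run_length_exponent < 0:
            raise ConfigError(
                "run_length_exponent must be >= 0 (placement nondecreasing in length)"
            )
        if self.ancestral_count < 0:
            raise ConfigError("ancestral_count must be >= 0")
        for key in self.class_weights:
            if key not in CLASS_INDEX:
                raise ConfigError(f"unknown 96-class {key!r}")
        for key in self.context_multipliers:
            subst, _, ctx = key.partition("|")
            if subst not in SUBST_TYPES or (subst, ctx) not in CLASS_INDEX:
                raise ConfigError(f"unknown context multiplier key {key!r}")

    def class_probabilities(self) -> np.ndarray:
        """Normalized sampling probabilities over the 96 classes."""
        w = np.ones(96)
        for key, val in self.class_weights.items():
            w[CLASS_INDEX[key]] = val
        for key, mult in self.context_multipliers.items():
            subst, _, ctx = key.partition("|")
            w[CLASS_INDEX[(subst, ctx)]] *= mult
        return w / w.sum()

    def compartment_rates(self, kind: str) -> tuple[float, float]:
        """(coding, noncoding) per-bp rate for 'sub' or 'indel'."""
        if kind == "sub":
            return self.sub_rate, (
                self.sub_rate if self.sub_rate_noncoding is None
                else self.sub_rate_noncoding
            )
        return self.indel_rate, (
            self.indel_rate if self.indel_rate_noncoding is None
            else self.indel_rate_noncoding
        )


@dataclass
class SimConfig:
    """Study conditions of one simulated genotype."""

    genome_length: int = 1_000_000
    n_chromosomes: int = 1
    coding_fraction: float = 0.75
    gc_content: float = 0.38
    homopolymer_boost: float = 0.55
    gene_length: int = 1500
    planted_runs: tuple[tuple[str, int, int], ...] = ()  # (base, length, count)
    n_isolates: int = 9
    generations: int = 900
    ploidy_factor: int = 2
    genotype_label: str = "sim"
    rate_model: RateModel = field(default_factory=RateModel)
    seed: int = 0

    def validate(self) -> None:
        if self.genome_length < 1000:
            raise ConfigError("genome_length must be >= 1000")
        if not 0.0 <= self.coding_fraction <= 1.0:
            raise ConfigError("coding_fraction must be in [0, 1]")
        if not 0.0 < self.gc_content < 1.0:
            raise ConfigError("gc_content must be in (0, 1)")
        if not 0.0 <= self.homopolymer_boost < 1.0:
            raise ConfigError("homopolymer_boost must be in [0, 1)")
        if self.n_isolates < 1 or self.generations < 1 or self.ploidy_factor < 1:
            raise ConfigError("isolates, generations and ploidy must be >= 1")
        self.rate_model.validate()


def _coding_layout(length: int, fraction: float, gene_length: int) -> list[tuple[int, int]]:
    """Alternating gene/intergenic tiling achieving ~fraction coding bp."""
    if fraction <= 0:
        return []
    if fraction >= 1:
        return [(0, length)]
    period = max(gene_length + 1, int(round(gene_length / fraction)))
    offset = (period - gene_length) // 2
    layout = []
    start = offset
    while start < length:
        end = min(start + gene_length, length)
        if end > start:
            layout.append((start, end))
        start += period
    return layout


def _iid_segment(rng: np.random.Generator, n: int, probs: np.ndarray) -> np.ndarray:
    return rng.choice(4, size=n, p=probs)


def _run_segment(
    rng: np.random.Generator, n: int, probs: np.ndarray, boost: float
) -> np.ndarray:
    """Run-structured sequence: A/T runs extended with probability ``boost``."""
    p_ext = np.array([boost, probs[1], probs[2], boost])
    mean_len = float((probs / (1.0 - p_ext)).sum())
    chunks: list[np.ndarray] = []
    total = 0
    while total < n:
        m = max(16, int((n - total) / mean_len * 1.2))
        bases = rng.choice(4, size=m, p=probs)
        lengths = rng.geometric(1.0 - p_ext[bases])
        chunk = np.repeat(bases, lengths)
        chunks.append(chunk)
        total += len(chunk)
    return np.concatenate(chunks)[:n]


def make_genome(config: SimConfig) -> tuple[ReferenceGenome, AnnotationSet]:
    """Random genome plus its coding annotation (full-genome callable mask)."""
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(0,)))
    gc = config.gc_content
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    base_len = config.genome_length // config.n_chromosomes
    lengths = [base_len] * config.n_chromosomes
    lengths[-1] += config.genome_length - base_len * config.n_chromosomes
    code_arrays: dict[str, np.ndarray] = {}
    coding: list[GenomicInterval] = []
    noncoding_spans: list[tuple[str, int, int]] = []
    for ci, clen in enumerate(lengths):
        chrom = f"chr{ci + 1}"
        genes = _coding_layout(clen, config.coding_fraction, config.gene_length)
        arr = np.empty(clen, dtype=np.int64)
        cursor = 0
        for s, e in genes:
            if s > cursor:
                arr[cursor:s] = (
                    _run_segment(rng, s - cursor, probs, config.homopolymer_boost)
                    if config.homopolymer_boost > 0
                    else _iid_segment(rng, s - cursor, probs)
                )
                noncoding_spans.append((chrom, cursor, s))
            arr[s:e] = _iid_segment(rng, e - s, probs)
            coding.append(GenomicInterval(chrom, s, e))
            cursor = e
        if cursor < clen:
            arr[cursor:clen] = (
                _run_segment(rng, clen - cursor, probs, config.homopolymer_boost)
                if config.homopolymer_boost > 0
                else _iid_segment(rng, clen - cursor, probs)
            )
            noncoding_spans.append((chrom, cursor, clen))
        code_arrays[chrom] = arr
    _plant_runs(rng, code_arrays, noncoding_spans, config.planted_runs)
    sequences = {
        chrom: _BASE_BYTES[arr].tobytes().decode("ascii")
        for chrom, arr in code_arrays.items()
    }
    genome = ReferenceGenome(sequences)
    mask = [GenomicInterval(c, 0, genome.length(c)) for c in genome.chromosomes]
    annotation = AnnotationSet.from_coding(coding, mask)
    return genome, annotation


def _plant_runs(
    rng: np.random.Generator,
    code_arrays: dict[str, np.ndarray],
    noncoding_spans: list[tuple[str, int, int]],
    planted: Iterable[tuple[str, int, int]],
) -> None:
    """Overwrite noncoding stretches with exact-length homopolymer runs."""
    for base, run_len, count in planted:
        bcode = _CODE[base]
        others = [c for c in range(4) if c != bcode]
        spans = [
            (chrom, s, e)
            for chrom, s, e in noncoding_spans
            if e - s >= run_len + 4
        ]
        if not spans:
            raise ConfigError(
                f"no noncoding span can hold a planted {base}{run_len} run"
            )
        for _ in range(count):
            chrom, s, e = spans[rng.integers(len(spans))]
            off = int(rng.integers(s + 1, e - run_len - 1))
            arr = code_arrays[chrom]
            arr[off : off + run_len] = bcode
            # force differing flanks so the planted run is maximal at its length
            arr[off - 1] = others[rng.integers(3)]
            arr[off + run_len] = others[rng.integers(3)]


class GenomeIndex:
    """Precomputed lookups used by the simulator on one genome.

    Chromosomes are concatenated into a virtual coordinate space; the
    index exposes per-(context, compartment) position pools for planting
    substitutions, plus run tables for planting 1-bp indels.
    """

    def __init__(self, genome: ReferenceGenome, annotation: AnnotationSet):
        self.genome = genome
        self.chroms = genome.chromosomes
        self.lengths = np.array([genome.length(c) for c in self.chroms])
        self.offsets = np.concatenate(([0], np.cumsum(self.lengths)))
        total = int(self.offsets[-1])
        codes = np.empty(total, dtype=np.uint8)
        lut = np.full(256, _N_CODE, dtype=np.uint8)
        for b, i in _CODE.items():
            lut[ord(b)] = i
        for ci, chrom in enumerate(self.chroms):
            raw = np.frombuffer(genome.sequences[chrom].encode("ascii"), np.uint8)
            codes[self.offsets[ci] : self.offsets[ci + 1]] = lut[raw]
        self.codes = codes
        coding_mask = np.zeros(total, dtype=bool)
        for iv in annotation.coding:
            ci = self.chroms.index(iv.chrom)
            coding_mask[self.offsets[ci] + iv.start : self.offsets[ci] + iv.end] = True
        self.coding_mask = coding_mask
        self._build_context_pools()
        self._build_run_tables()

    # -- context pools ----------------------------------------------------
    @staticmethod
    def context32_code(trinuc: str) -> int:
        """0..31 code of a pyrimidine-centered trinucleotide context."""
        l, c, r = (_CODE[b] for b in trinuc)
        if c not in (1, 3):
            raise ConfigError(f"context {trinuc!r} is not pyrimidine-centered")
        return l * 8 + (4 if c == 3 else 0) + r

    def _build_context_pools(self) -> None:
        total = len(self.codes)
        ctx = np.full(total, -1, dtype=np.int8)
        for ci in range(len(self.chroms)):
            lo, hi = int(self.offsets[ci]), int(self.offsets[ci + 1])
            if hi - lo < 3:
                continue
            seg = self.codes[lo:hi].astype(np.int16)
            l, c, r = seg[:-2], seg[1:-1], seg[2:]
            valid = (l < 4) & (c < 4) & (r < 4)
            pyr = (c == 1) | (c == 3)
            lc = np.where(pyr, l, 3 - r)
            cc = np.where(pyr, c, 3 - c)
            rc = np.where(pyr, r, 3 - l)
            code = lc * 8 + np.where(cc == 3, 4, 0) + rc
            out = np.full(hi - lo - 2, -1, dtype=np.int8)
            out[valid] = code[valid].astype(np.int8)
            ctx[lo + 1 : hi - 1] = out
        valid_pos = np.flatnonzero(ctx >= 0)
        key = ctx[valid_pos].astype(np.int32) * 2 + self.coding_mask[valid_pos]
        order = np.argsort(key, kind="stable")
        sorted_pos = valid_pos[order]
        sorted_key = key[order]
        self._pools: dict[tuple[int, bool], np.ndarray] = {}
        bounds = np.searchsorted(sorted_key, np.arange(65))
        for code in range(32):
            for coding in (False, True):
                k = code * 2 + int(coding)
                pool = sorted_pos[bounds[k] : bounds[k + 1]]
                self._pools[(code, coding)] = pool

    def context_pool(self, trinuc: str, coding: bool) -> np.ndarray:
        return self._pools[(self.context32_code(trinuc), coding)]

    # -- run tables -------------------------------------------------------
    def _build_run_tables(self) -> None:
        starts_all, lens_all, bases_all = [], [], []
        for ci in range(len(self.chroms)):
            lo, hi = int(self.offsets[ci]), int(self.offsets[ci + 1])
            seg = self.codes[lo:hi]
            change = np.flatnonzero(seg[1:] != seg[:-1]) + 1
            starts = np.concatenate(([0], change))
            ends = np.concatenate((change, [hi - lo]))
            keep = seg[starts] != _N_CODE
            # indel planting needs a left anchor base inside the chromosome
            keep &= starts > 0
            starts_all.append(starts[keep] + lo)
            lens_all.append((ends - starts)[keep])
            bases_all.append(seg[starts[keep]])
        self.run_starts = np.concatenate(starts_all)
        self.run_lengths = np.concatenate(lens_all)
        self.run_bases = np.concatenate(bases_all)
        self.run_coding = self.coding_mask[self.run_starts]
        # oriented downstream base of A/T runs (-1 when unknown/edge)
        down = np.full(len(self.run_starts), -1, dtype=np.int8)
        ends = self.run_starts + self.run_lengths
        is_a = self.run_bases == _CODE["A"]
        ok = is_a & (ends < len(self.codes))
        nb = self.codes[np.minimum(ends, len(self.codes) - 1)]
        down[ok & (nb < 4)] = nb[ok & (nb < 4)]
        is_t = self.run_bases == _CODE["T"]
        ub = self.codes[self.run_starts - 1]
        ok_t = is_t & (ub < 4)
        down[ok_t] = 3 - ub[ok_t]
        self.run_downstream = down
        self.run3_positions = self._positions_of_runs(self.run_lengths == 3)

    def _positions_of_runs(self, mask: np.ndarray) -> np.ndarray:
        starts = self.run_starts[mask]
        lengths = self.run_lengths[mask]
        if len(starts) == 0:
            return np.empty(0, dtype=np.int64)
        total = int(lengths.sum())
        excl = np.concatenate(([0], np.cumsum(lengths)[:-1]))
        return np.repeat(starts - excl, lengths) + np.arange(total)

    # -- coordinates ------------------------------------------------------
    def locate(self, vpos: int) -> tuple[str, int]:
        ci = int(np.searchsorted(self.offsets, vpos, side="right")) - 1
        return self.chroms[ci], int(vpos - self.offsets[ci])

    def compartment_lengths(self) -> tuple[int, int]:
        c = int(self.coding_mask.sum())
        return c, len(self.codes) - c


@dataclass
class SimResult:
    pairs: list[IsolatePair]
    truth: pd.DataFrame  # planted de novo mutations, 1-based positions


def _class_of_index(idx: int) -> tuple[str, str]:
    return CLASSES_96[idx]


def simulate_lines(
    genome: ReferenceGenome,
    annotation: AnnotationSet,
    rate_model: RateModel,
    config: SimConfig,
    index: GenomeIndex | None = None,
) -> SimResult:
    """Simulate the isolates of one genotype on a given genome."""
    config.validate()
    idx = index if index is not None else GenomeIndex(genome, annotation)
    rng = np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(1,)))
    probs = rate_model.class_probabilities()
    subst_marginal = probs.reshape(6, 16).sum(axis=1)
    gen, ploidy = config.generations, config.ploidy_factor
    len_coding, len_noncoding = idx.compartment_lengths()
    comp_lengths = {"coding": len_coding, "noncoding": len_noncoding}
    pairs: list[IsolatePair] = []
    truth_rows: list[dict] = []
    label = config.genotype_label
    for j in range(config.n_isolates):
        iso = f"{label}_{j + 1:02d}"
        used: set[int] = set()
        ancestral = _sample_ancestral(rng, idx, rate_model.ancestral_count, iso, label, used)
        denovo: list[tuple[VariantCall, str]] = []
        for comp, rate in zip(
            ("coding", "noncoding"), rate_model.compartment_rates("sub")
        ):
            lam = rate * gen * ploidy * comp_lengths[comp]
            if lam <= 0:
                continue
            n = rng.poisson(lam)
            denovo += _plant_substitutions(
                rng, idx, probs, n, comp == "coding", iso, label, used
            )
        if rate_model.run3_extra_sub_rate > 0 and len(idx.run3_positions) > 0:
            lam = (
                rate_model.run3_extra_sub_rate * gen * ploidy
                * len(idx.run3_positions)
            )
            denovo += _plant_run3_substitutions(
                rng, idx, subst_marginal, rng.poisson(lam), iso, label, used
            )
        for comp, rate in zip(
            ("coding", "noncoding"), rate_model.compartment_rates("indel")
        ):
            lam = rate * gen * ploidy * comp_lengths[comp]
            if lam <= 0:
                continue
            denovo += _plant_indels(
                rng, idx, rate_model, rng.poisson(lam), comp == "coding",
                iso, label, used,
            )
        denovo.sort(key=lambda vc: vc[0].pos)
        gen_final = sorted(
            ancestral + [v for v, _ in denovo], key=lambda v: (v.chrom, v.pos)
        )
        pairs.append(
            IsolatePair(
                isolate_id=iso,
                genotype_label=label,
                gen0_variants=list(ancestral),
                gen_final_variants=gen_final,
                generations=gen,
            )
        )
        for v, mclass in denovo:
            truth_rows.append(
                {
                    "isolate": iso,
                    "genotype": label,
                    "chrom": v.chrom,
                    "pos": v.pos + 1,
                    "ref": v.ref,
                    "alt": v.alt,
                    "class": mclass,
                }
            )
    truth = pd.DataFrame(
        truth_rows,
        columns=["isolate", "genotype", "chrom", "pos", "ref", "alt", "class"],
    )
    return SimResult(pairs, truth)


def _sample_ancestral(
    rng: np.random.Generator,
    idx: GenomeIndex,
    count: int,
    iso: str,
    label: str,
    used: set[int],
) -> list[VariantCall]:
    out: list[VariantCall] = []
    total = len(idx.codes)
    while len(out) < count:
        v = int(rng.integers(total))
        if v in used or idx.codes[v] >= 4:
            continue
        used.add(v)
        ref = BASES[idx.codes[v]]
        alt = BASES[[c for c in range(4) if c != idx.codes[v]][rng.integers(3)]]
        chrom, pos = idx.locate(v)
        out.append(VariantCall(chrom, pos, ref, alt, iso, label))
    return out


_COMP_BASE = {"A": "T", "C": "G", "G": "C", "T": "A"}


def _plant_substitutions(
    rng: np.random.Generator,
    idx: GenomeIndex,
    probs: np.ndarray,
    n: int,
    coding: bool,
    iso: str,
    label: str,
    used: set[int],
) -> list[tuple[VariantCall, str]]:
    out: list[tuple[VariantCall, str]] = []
    if n == 0:
        return out
    counts = np.bincount(rng.choice(96, size=n, p=probs), minlength=96)
    for ci in np.flatnonzero(counts):
        subst, trinuc = _class_of_index(int(ci))
        pool = idx.context_pool(trinuc, coding)
        if len(pool) == 0:
            continue  # context absent from this compartment; undersampled
        picks = pool[rng.integers(0, len(pool), int(counts[ci]))]
        alt_pyr = subst[2]
        for v in picks:
            v = int(v)
            if v in used:
                continue
            used.add(v)
            refc = idx.codes[v]
            ref = BASES[refc]
            alt = alt_pyr if ref in "CT" else _COMP_BASE[alt_pyr]
            chrom, pos = idx.locate(v)
            out.append(
                (VariantCall(chrom, pos, ref, alt, iso, label), SUBSTITUTION)
            )
    return out


def _plant_run3_substitutions(
    rng: np.random.Generator,
    idx: GenomeIndex,
    subst_marginal: np.ndarray,
    n: int,
    iso: str,
    label: str,
    used: set[int],
) -> list[tuple[VariantCall, str]]:
    out: list[tuple[VariantCall, str]] = []
    if n == 0:
        return out
    picks = idx.run3_positions[rng.integers(0, len(idx.run3_positions), n)]
    types = rng.choice(6, size=n, p=subst_marginal / subst_marginal.sum())
    for v, ti in zip(picks, types):
        v = int(v)
        if v in used:
            continue
        used.add(v)
        ref = BASES[idx.codes[v]]
        alt_pyr = SUBST_TYPES[ti][2]
        alt = alt_pyr if ref in "CT" else _COMP_BASE[alt_pyr]
        if alt == ref:  # type not applicable to this center base's strand pairing
            alt = [b for b in BASES if b != ref][rng.integers(3)]
        chrom, pos = idx.locate(v)
        out.append((VariantCall(chrom, pos, ref, alt, iso, label), SUBSTITUTION))
    return out


def _plant_indels(
    rng: np.random.Generator,
    idx: GenomeIndex,
    model: RateModel,
    n: int,
    coding: bool,
    iso: str,
    label: str,
    used: set[int],
) -> list[tuple[VariantCall, str]]:
    out: list[tuple[VariantCall, str]] = []
    if n == 0:
        return out
    sel = np.flatnonzero(idx.run_coding == coding)
    if len(sel) == 0:
        return out
    w = idx.run_lengths[sel].astype(float) ** model.run_length_exponent
    if model.downstream_bias:
        bias = np.ones(4)
        for b, val in model.downstream_bias.items():
            bias[_CODE[b]] = val
        is_at = (idx.run_bases[sel] == _CODE["A"]) | (idx.run_bases[sel] == _CODE["T"])
        down = idx.run_downstream[sel]
        ok = is_at & (down >= 0)
        w[ok] *= bias[down[ok]]
    w_sum = w.sum()
    if w_sum <= 0:
        return out
    runs = sel[rng.choice(len(sel), size=n, p=w / w_sum)]
    is_del = rng.random(n) < model.deletion_fraction
    for ri, deletion in zip(runs, is_del):
        start = int(idx.run_starts[ri])
        anchor = start - 1  # guaranteed inside the chromosome by the run table
        if anchor in used or idx.codes[anchor] >= 4:
            continue
        used.add(anchor)
        anchor_base = BASES[idx.codes[anchor]]
        run_base = BASES[idx.run_bases[ri]]
        chrom, pos = idx.locate(anchor)
        if deletion:
            vc = VariantCall(
                chrom, pos, anchor_base + run_base, anchor_base, iso, label
            )
            out.append((vc, DELETION))
        else:
            vc = VariantCall(
                chrom, pos, anchor_base, anchor_base + run_base, iso, label
            )
            out.append((vc, INSERTION))
    return out


def scenario_presets() -> dict[str, SimConfig]:
    """Named study conditions mirroring the genotypes of the experiment.

    Rates are per haploid bp per generation on a 10 Mb diploid-convention
    genome: wild-type-like 3.3e-10 total; MMR-null-like 130x that
    (4.29e-8, 60% substitutions / 40% 1-bp indels) with the signature
    peaks C>T@GCA, C>T@ACA and C>A@CCT jointly carrying ~25% of
    substitutions; the MutL-alpha-null-like preset adds a 5x T>C|ATA
    context multiplier and a G-downstream bias of A-run deletions; the
    Msh2-null-like preset adds an N3-run substitution excess and a
    T-downstream bias; the compartment-bias preset plants indels 8x more
    densely in noncoding DNA.
    """
    # three peak classes jointly 25% of substitutions: x/(3x+93) = 0.25/3
    peak_weight = 0.25 / 3 * 93 / 0.75
    peaks = {c: peak_weight for c in
             (("C>T", "GCA"), ("C>T", "ACA"), ("C>A", "CCT"))}
    base = SimConfig(
        genome_length=10_000_000,
        coding_fraction=0.75,
        gc_content=0.38,
        homopolymer_boost=0.55,
        generations=900,
        ploidy_factor=2,
    )
    a11 = (("A", 11, 400), ("T", 11, 400))
    presets = {
        "wt_like": replace(
            base,
            genotype_label="wt_like",
            n_isolates=15,
            rate_model=RateModel(sub_rate=3.3e-10, indel_rate=0.0),
        ),
        "mmr_null_like": replace(
            base,
            genotype_label="mmr_null_like",
            n_isolates=9,
            rate_model=RateModel(
                sub_rate=2.574e-8,
                indel_rate=1.716e-8,
                class_weights=dict(peaks),
            ),
        ),
        "pms1_like": replace(
            base,
            genotype_label="pms1_like",
            n_isolates=9,
            planted_runs=a11,
            rate_model=RateModel(
                sub_rate=2.574e-8,
                indel_rate=1.716e-8,
                class_weights=dict(peaks),
                context_multipliers={"T>C|ATA": 5.0},
                downstream_bias={"G": 0.6, "A": 0.4 / 3, "C": 0.4 / 3, "T": 0.4 / 3},
            ),
        ),
        "msh2_like": replace(
            base,
            genotype_label="msh2_like",
            n_isolates=8,
            planted_runs=a11,
            rate_model=RateModel(
                sub_rate=2.574e-8,
                indel_rate=1.716e-8,
                class_weights=dict(peaks),
                run3_extra_sub_rate=5e-9,
                downstream_bias={"T": 0.6, "A": 0.4 / 3, "C": 0.4 / 3, "G": 0.4 / 3},
            ),
        ),
        "noncoding_biased_indels": replace(
            base,
            genotype_label="noncoding_biased_indels",
            n_isolates=9,
            rate_model=RateModel(
                indel_rate=2.0e-9,
                indel_rate_noncoding=1.6e-8,
            ),
        ),
    }
    return presets
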