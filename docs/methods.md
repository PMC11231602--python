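# Methods

## The estimator and its conventions

Mutation-accumulation (MA) passaging through single-cell bottlenecks keeps
the effective population size near one, so selection is nearly powerless
and mutations accumulate approximately linearly in time. De novo mutations
of one isolate are defined by exact set subtraction: every variant present
at the final generation whose normalized identity (chrom, pos, ref, alt)
is absent from the same isolate's generation-0 list. Normalization
left-aligns indels and reduces them to a minimal anchored representation,
which makes the identity representation-invariant; subtraction is
therefore idempotent and recovers a simulator's truth table exactly.

The pooled rate for a genotype is

    mu = N_i / gen / N_g

with `N_i` mutations of type *i* summed over isolates, `gen` the summed
generations, and `N_g` the callable genome size in bp on the diploid
convention (for *S. cerevisiae* runs, 22,983,805 bp; for synthetic
genomes, callable mask length × ploidy factor, default 2). The pooled
value is the primary point estimate; per-isolate estimates give the
figure-style mean ± sample SD (SD undefined and reported absent for a
single isolate). Repetitive or otherwise uncallable regions are handled
as a user-supplied callable mask (default: whole genome), not recomputed.

Internally all coordinates are 0-based half-open; conversions to BED
(identical), GFF3/VCF (1-based) happen only in `genome_io`. Diploid
zygosity is ignored: a mutated site counts once. Recurrent identical
mutations in different isolates each count (per-isolate provenance is
kept), since hotspot recurrence is part of the mutational process being
measured.

## 96-class signatures and logos

Substitutions are classified on the pyrimidine-strand convention: a
purine reference base is complemented and its flanks reverse-complemented
(strand involution is property-tested against a two-strand enumeration
oracle). Classes are ordered C>A…T>G with flanks lexicographic, counts
and fractions both emitted. Substitutions whose trinucleotide window
leaves the contig or touches an N are excluded and counted, so signature
counts plus exclusions always equal the classified substitutions. Complex
events (equal-length multi-base changes) stay in totals but never enter
the signature. Context-restricted rates (e.g. T>C in 5'-ATA-3') use the
same collapse with N as a wildcard and keep the gen × N_g divisor (the
single-divisor convention); per-target-site normalization is available
behind a flag but off by default. For cultured-cell data the divisor can
instead be cell divisions (`per_division_rate`).

Sequence logos are emitted as matrices, not images: per-position base
counts over a ±k window (default k = 5; the choice is cosmetic for the
analyses here) on the pyrimidine-oriented strand, column-normalized
frequencies, and information content 2 − H(p) bits with H in log₂ and no
small-sample correction (the correction is a well-known WebLogo option;
applying it is a one-line post-process on the emitted matrix).

## Homopolymer runs

Runs are maximal single-base repeats; N and contig edges break them.
"N₃" and "A₁₁" mean exact length, matching discrete-length binning, and
A-run analyses include reference T-runs read on the reverse strand: the
oriented downstream base of a T-run is the complement of the reference
base 5' of the run. A 1-bp deletion is assigned to the run containing its
deleted base; left-alignment makes this invariant to the caller's
placement of the indel inside the run. Multi-bp deletions are excluded
from run analyses.

## Compartments

Expected counts under the null are proportional to compartment length
within the callable mask. The preference statistic is O/E(noncoding) ÷
O/E(coding), which equals the per-bp density ratio; with noncoding DNA
only ~a quarter of the genome a bare O/E(noncoding) is bounded near 4 and
cannot express 8–10-fold biases, so the ratio of ratios is the meaningful
quantity. A mutation is assigned by its first affected reference base
(substituted base; first deleted base; the base 5' of an insertion
point). Compartment rates divide by compartment length × ploidy, so the
length-weighted mean of the two compartment rates reproduces the
genome-wide rate (tested as an identity). "Coding" defaults to CDS
features when reading GFF3 — the natural choice when the annotation
distinguishes CDS from gene spans — and is exposed as `feature_filter`.

## Significance tests

Mann–Whitney U is exact (full enumeration of rank assignments) for
tie-free samples with n₁+n₂ ≤ 16 by default, and a tie-corrected normal
approximation with continuity correction otherwise; the two-tailed p is
2·min(P(U ≤ u), P(U ≥ u)) capped at 1, matching common statistical
software. The exact threshold is a parameter: at the experiment's sample
sizes (9 and 8) the exact test is still cheap (C(17,9) = 24,310
assignments) and the calibration test runs it exactly there, where its
empirical type-I error at α = 0.05 is ≈ 0.043–0.05 over 10⁴ null
replicates. The t test is Student's pooled-variance form with
df = n₁+n₂−2. Tests operate on per-isolate (or per-sample) rate vectors;
no multiple-testing correction is applied because raw p values are
reported.

## The simulator

`make_genome` builds chromosomes with an alternating gene/intergenic
layout (gene length 1500 bp; the period sets the coding fraction,
default 0.75 since noncoding DNA is roughly a third the size of coding
DNA in yeast), iid base composition at a configurable GC content
(default 0.38, yeast-like), and homopolymer-enriched noncoding DNA: in
noncoding segments A/T runs extend with probability `homopolymer_boost`
(default 0.55, mean A/T run ≈ 2.2 bp) while coding segments stay iid —
reproducing the empirical pattern that long dA:dT tracts concentrate in
promoters and intergenic DNA. Exact-length runs (e.g. A₁₁) can be
planted explicitly with randomized non-run flanking bases.

`simulate_lines` draws, per isolate, ancestral variants (present in both
the generation-0 and final lists) and de novo events with Poisson counts
`rate × generations × ploidy × target bp` — single-cell bottleneck
passaging makes accumulation approximately Poisson, so no genealogy is
simulated. Substitutions are assigned a 96-class by weight (uniform
unless overridden; context multipliers like "T>C|ATA" multiply on top)
and then a uniformly random genome position whose collapsed context
matches the class, exercising both strands. Compartment-biased rates
plant class-resolved densities per compartment. 1-bp indels (deletion
fraction 0.7, substitution-dominant totals being split 60/40 between
substitutions and indels in the MMR-null presets) are placed across
homopolymer runs with probability ∝ length^exponent (default 1 =
uniform per run-bp), optionally biased by the oriented downstream base
of A/T runs, and are emitted already left-aligned with their anchor
base. Every planted de novo event goes into a truth table. A fixed seed
gives byte-identical FASTA/BED/VCF output.

What the simulator does **not** emulate: sequencing/calling error,
uncallable repetitive regions (the mask is exercised as plumbing, not as
a mappability model), multi-bp indels and structural variants, clustered
mutations, selection, and real yeast base composition beyond GC content
and A/T-run enrichment. Passing recovery tests therefore demonstrates
the correctness of the estimators on data satisfying the MA model's
assumptions, not robustness to upstream calling artifacts.

## Scenario presets and test problem sizes

Presets encode the study conditions: wild-type-like (3.3·10⁻¹⁰ bp⁻¹gen⁻¹
total, 15 isolates), MMR-null-like (130× = 4.29·10⁻⁸, 9 isolates,
signature peaks C>T@GCA/ACA + C>A@CCT at 25% joint mass), a
MutLα-null-like variant (adds the 5× T>C|ATA multiplier and a
G-downstream bias for A-run deletions), an Msh2-null-like variant (N₃-run
substitution excess, T-downstream bias, 8 isolates), and a
compartment-biased indel scenario (2.0·10⁻⁹ coding vs 1.6·10⁻⁸
noncoding). All presets use 10 Mb genomes with ploidy factor 2 and 900
generations; recovery checks in the test suite use 10 Mb for the three
headline recoveries and 0.2–1 Mb for conservation and unit checks, sizes
at which the planted quantities' sampling error is comfortably inside
the asserted tolerances. The fold-change recovery is the noisiest check
(the wild-type arm expects only ~90 events, CV ≈ 11%), which is why its
tolerance is ±20% while the compartment recoveries use ±15%.

## Numerical and degenerate-input choices

Zero divisors raise; fold changes against a zero rate return infinity
with a warning; O/E is undefined (raises) with zero total mutations, and
the empty-signature peak fraction is reported absent rather than 0.
Normalization cannot left-extend past a contig start; an indel pinned
there keeps its anchorless representation. Logo information content
defines 0·log 0 = 0. The zero-pooled-variance t test reports p = 1 for
equal means and a denormal-adjacent p with a warning otherwise.
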