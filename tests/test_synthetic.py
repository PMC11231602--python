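"""Simulator determinism, bookkeeping, and statistical structure."""
import numpy as np
import pytest

from malines.genome_io import ConfigError
from malines.homopolymers import find_runs
from malines.spectrum import subtract_generation0
from malines.synthetic_data import (
    GenomeIndex,
    RateModel,
    SimConfig,
    make_genome,
    scenario_presets,
    simulate_lines,
)


def _cfg(**kw):
    defaults = dict(
        genome_length=200_000,
        n_isolates=4,
        seed=42,
        genotype_label="test",
        rate_model=RateModel(sub_rate=2e-8, indel_rate=1e-8, ancestral_count=20),
    )
    defaults.update(kw)
    return SimConfig(**defaults)


def test_determinism_byte_identical():
    cfg = _cfg()
    g1, a1 = make_genome(cfg)
    g2, a2 = make_genome(cfg)
    assert g1.sequences == g2.sequences
    assert a1.coding == a2.coding
    r1 = simulate_lines(g1, a1, cfg.rate_model, cfg)
    r2 = simulate_lines(g2, a2, cfg.rate_model, cfg)
    for p1, p2 in zip(r1.pairs, r2.pairs):
        assert [v.key for v in p1.gen_final_variants] == [
            v.key for v in p2.gen_final_variants
        ]
    assert r1.truth.equals(r2.truth)


def test_different_seed_differs():
    g1, _ = make_genome(_cfg(seed=1))
    g2, _ = make_genome(_cfg(seed=2))
    assert g1.sequences != g2.sequences


def test_zero_rates_final_equals_gen0():
    cfg = _cfg(rate_model=RateModel(ancestral_count=15))
    g, a = make_genome(cfg)
    res = simulate_lines(g, a, cfg.rate_model, cfg)
    assert len(res.truth) == 0
    for p in res.pairs:
        assert [v.key for v in p.gen_final_variants] == sorted(
            v.key for v in p.gen0_variants
        )


def test_subtraction_recovers_truth_table():
    cfg = _cfg()
    g, a = make_genome(cfg)
    res = simulate_lines(g, a, cfg.rate_model, cfg)
    assert len(res.truth) > 0
    recovered = set()
    for pair in res.pairs:
        for m in subtract_generation0(pair):
            recovered.add((m.isolate_id, m.chrom, m.pos + 1, m.ref, m.alt))
    planted = {
        (t.isolate, t.chrom, t.pos, t.ref, t.alt)
        for t in res.truth.itertuples(index=False)
    }
    assert recovered == planted


def test_poisson_mean_of_de_novo_counts():
    cfg = _cfg(genome_length=500_000, n_isolates=40,
               rate_model=RateModel(sub_rate=1e-8, ancestral_count=0))
    g, a = make_genome(cfg)
    idx = GenomeIndex(g, a)
    res = simulate_lines(g, a, cfg.rate_model, cfg, idx)
    lam = 1e-8 * 900 * 2 * 500_000  # = 9 per isolate
    counts = res.truth.groupby("isolate").size().reindex(
        [p.isolate_id for p in res.pairs], fill_value=0
    )
    se = np.sqrt(lam / cfg.n_isolates)
    assert abs(counts.mean() - lam) < 3 * se


def test_coding_fraction_and_lengths():
    cfg = _cfg(coding_fraction=0.75)
    _, ann = make_genome(cfg)
    frac = ann.coding_length / (ann.coding_length + ann.noncoding_length)
    assert frac == pytest.approx(0.75, abs=0.02)
    assert ann.coding_length + ann.noncoding_length == cfg.genome_length


def test_boost_zero_matches_iid_run_law():
    """Without boost, A-run lengths follow the geometric law of iid sequence."""
    cfg = _cfg(genome_length=400_000, homopolymer_boost=0.0, gc_content=0.4)
    g, _ = make_genome(cfg)
    lengths = np.array([r.length for r in find_runs(g, 1) if r.base == "A"])
    p = 0.3  # P(A) at GC 0.4
    assert lengths.mean() == pytest.approx(1 / (1 - p), rel=0.02)
    # chi-square on length classes 1..5 and 6+
    obs = np.array([(lengths == k).sum() for k in range(1, 6)] + [(lengths >= 6).sum()])
    probs = np.array([(1 - p) * p ** (k - 1) for k in range(1, 6)] + [p**5])
    chi2 = sps_chisquare(obs, probs * len(lengths))
    assert chi2 > 1e-4  # not rejected at any sane level


def sps_chisquare(obs, exp):
    from scipy.stats import chisquare

    return chisquare(obs, exp).pvalue


def test_boost_enriches_noncoding_at_runs():
    cfg = _cfg(genome_length=400_000, homopolymer_boost=0.55)
    g, ann = make_genome(cfg)
    runs = find_runs(g, 1)
    nc, cod = [], []
    for r in runs:
        if r.base not in "AT":
            continue
        comp = ann.compartment_of(r.chrom, r.start)
        (cod if comp == "coding" else nc).append(r.length)
    assert np.mean(nc) > np.mean(cod) + 0.3


def test_planted_runs_present_at_exact_length():
    cfg = _cfg(planted_runs=(("A", 11, 30), ("T", 11, 30)))
    g, ann = make_genome(cfg)
    a11 = [r for r in find_runs(g, 11) if r.length == 11 and r.base in "AT"]
    assert len(a11) >= 40  # most planted runs survive overlaps
    for r in a11[:10]:
        assert ann.compartment_of(r.chrom, r.start) == "noncoding"


def test_indels_left_aligned_and_in_runs():
    cfg = _cfg(rate_model=RateModel(indel_rate=5e-8, ancestral_count=0))
    g, a = make_genome(cfg)
    res = simulate_lines(g, a, cfg.rate_model, cfg)
    dels = res.truth[res.truth["class"] == "deletion"]
    assert len(dels) > 0
    for t in dels.itertuples(index=False):
        pos0 = t.pos - 1  # anchor, 0-based
        anchor, deleted = t.ref[0], t.ref[1]
        seq = g.sequences[t.chrom]
        assert seq[pos0] == anchor
        assert seq[pos0 + 1] == deleted
        assert anchor != deleted  # left-aligned: anchor differs from run base


def test_presets_load_and_encode_study_conditions():
    presets = scenario_presets()
    assert set(presets) >= {
        "wt_like", "mmr_null_like", "pms1_like", "msh2_like",
        "noncoding_biased_indels",
    }
    for cfg in presets.values():
        cfg.validate()
    wt = presets["wt_like"].rate_model
    mn = presets["mmr_null_like"].rate_model
    total_wt = wt.sub_rate + wt.indel_rate
    total_mn = mn.sub_rate + mn.indel_rate
    assert total_mn / total_wt == pytest.approx(130.0)
    assert presets["wt_like"].n_isolates == 15
    assert presets["mmr_null_like"].n_isolates == 9
    assert presets["msh2_like"].n_isolates == 8
    assert presets["pms1_like"].rate_model.context_multipliers["T>C|ATA"] == 5.0
    probs = mn.class_probabilities()
    assert probs.sum() == pytest.approx(1.0)


def test_invalid_config_rejected():
    with pytest.raises(ConfigError):
        SimConfig(genome_length=10).validate()
    with pytest.raises(ConfigError):
        SimConfig(coding_fraction=1.5).validate()
    with pytest.raises(ConfigError):
        RateModel(sub_rate=-1).validate()
    with pytest.raises(ConfigError):
        RateModel(class_weights={("X>Y", "AAA"): 1.0}).validate()


def test_context_multiplier_recovered_in_rates():
    """A planted 5x T>C|ATA multiplier shows up as ~5x the mean non-ATA rate."""
    from malines.cli import analyze_dataset
    from malines.rates import context_rate

    cfg = _cfg(
        genome_length=500_000,
        n_isolates=8,
        seed=77,
        rate_model=RateModel(
            sub_rate=6e-8,
            context_multipliers={"T>C|ATA": 5.0},
            ancestral_count=0,
        ),
    )
    g, a = make_genome(cfg)
    res = simulate_lines(g, a, cfg.rate_model, cfg)
    report = analyze_dataset(g, a, res.pairs)
    sp = report["spectra"]["test"]
    n_g = report["n_g"]
    ata = context_rate(sp, "T>C", "ATA", g, n_g).mu
    others = [
        context_rate(sp, "T>C", f5 + "T" + f3, g, n_g).mu
        for f5 in "ACGT"
        for f3 in "ACGT"
        if (f5, f3) != ("A", "A")
    ]
    ratio = ata / np.mean(others)
    assert abs(ratio - 5.0) < 2.0  # sampling error at ~900 substitutions


def test_downstream_bias_recovered_in_a11_profile():
    """A G-downstream deletion bias is recovered from the A11 profile.

    The expected profile is the bias reweighting of the available
    length-11 A/T runs' oriented downstream bases.
    """
    from malines.genome_io import complement_base
    from malines.homopolymers import downstream_base_profile
    from malines.spectrum import pool_by_genotype

    bias = {"G": 0.6, "A": 0.4 / 3, "C": 0.4 / 3, "T": 0.4 / 3}
    cfg = _cfg(
        genome_length=200_000,
        coding_fraction=0.1,
        n_isolates=9,
        seed=88,
        planted_runs=(("A", 11, 600), ("T", 11, 600)),
        rate_model=RateModel(
            indel_rate=2e-7,
            deletion_fraction=1.0,
            run_length_exponent=3.0,  # concentrate events in the long runs
            downstream_bias=bias,
            ancestral_count=0,
        ),
    )
    g, a = make_genome(cfg)
    res = simulate_lines(g, a, cfg.rate_model, cfg)
    sp = pool_by_genotype(res.pairs)[cfg.genotype_label]
    profile = downstream_base_profile(sp, g, base="A", run_length=11)
    # availability of oriented downstream bases among length-11 A/T runs
    avail = {b: 0 for b in "ACGT"}
    for r in find_runs(g, 11):
        if r.length != 11 or r.base not in "AT":
            continue
        if r.base == "A":
            if r.end >= g.length(r.chrom):
                continue
            nb = g.base(r.chrom, r.end)
        else:
            if r.start == 0:
                continue
            nb = complement_base(g.base(r.chrom, r.start - 1))
        if nb != "N":
            avail[nb] += 1
    z = sum(bias[b] * avail[b] for b in "ACGT")
    expected_g = bias["G"] * avail["G"] / z
    n_events = sum(
        1 for m in sp.mutations
        if m.mclass == "deletion"
    )
    assert n_events > 100
    se = np.sqrt(expected_g * (1 - expected_g) / n_events)
    assert profile["G"] == max(profile.values())
    assert abs(profile["G"] - expected_g) <= 4 * se
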