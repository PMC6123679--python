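"""Synthetic-data generators: ground truth, distributions, determinism."""

import numpy as np
import pandas as pd
import pytest

from sbevol import simulate
from sbevol.errors import ConfigError
from sbevol.simulate import (
    SimConfig,
    assign_labels,
    gen_expression_study,
    gen_gene_map,
    gen_mk_counts,
    gen_multispecies_sb_calls,
    gen_plasticity_study,
    gen_tissue_panel,
    gen_trio_alignments,
    true_tau,
)


def test_label_proportions_exact():
    cfg = SimConfig(seed=0, n_genes=1000, frac_female_biased=0.1, frac_male_biased=0.1)
    truth = assign_labels(cfg)
    assert (truth["label"] == simulate.FEMALE).sum() == 100
    assert (truth["label"] == simulate.MALE).sum() == 100


def test_zero_effect_means_no_bias():
    cfg = SimConfig(seed=0, n_genes=100, effect_log2fc=0.0)
    truth = assign_labels(cfg)
    assert (truth["true_log2fc"] == 0).all()


def test_invalid_proportions_rejected():
    with pytest.raises(ConfigError):
        SimConfig(frac_female_biased=0.7, frac_male_biased=0.5)
    with pytest.raises(ConfigError):
        SimConfig(dispersion=-0.1)


def test_poisson_limit_moment_check():
    """At dispersion 0 the per-gene variance across replicates matches the mean."""
    cfg = SimConfig(
        seed=4, n_genes=2000, n_samples_per_group=4, dispersion=0.0,
        library_size=1e6, frac_female_biased=0.0, frac_male_biased=0.0,
    )
    cm, _ = gen_expression_study(cfg)
    x = cm.counts.to_numpy(dtype=float)
    mean = x.mean(axis=1)
    var = x.var(axis=1, ddof=1)
    keep = mean > 20
    ratio = var[keep] / mean[keep]
    # per-gene var/mean has mean 1 under Poisson; average over genes is tight
    assert np.mean(ratio) == pytest.approx(1.0, abs=0.05)


def test_overdispersion_visible_when_requested():
    cfg = SimConfig(
        seed=4, n_genes=2000, n_samples_per_group=4, dispersion=0.3,
        library_size=1e6, frac_female_biased=0.0, frac_male_biased=0.0,
    )
    cm, _ = gen_expression_study(cfg)
    x = cm.counts.to_numpy(dtype=float)
    mean = x.mean(axis=1)
    var = x.var(axis=1, ddof=1)
    keep = mean > 100
    assert np.mean(var[keep] / mean[keep]) > 2.0


def test_expression_effect_size_recovered():
    cfg = SimConfig(seed=9, n_genes=500, dispersion=0.05, effect_log2fc=2.0)
    cm, truth = gen_expression_study(cfg)
    fem = truth["label"] == simulate.FEMALE
    f_cols = [s for s in cm.sample_ids if s.startswith("F")]
    m_cols = [s for s in cm.sample_ids if s.startswith("M")]
    fc = np.log2(
        (cm.counts[f_cols].mean(axis=1) + 0.5) / (cm.counts[m_cols].mean(axis=1) + 0.5)
    )
    assert fc[fem.to_numpy()].mean() == pytest.approx(2.0, abs=0.2)


def test_generators_are_deterministic(small_config):
    a1, t1 = gen_expression_study(small_config)
    a2, t2 = gen_expression_study(small_config)
    assert a1.counts.equals(a2.counts) and t1.equals(t2)
    p1, _ = gen_plasticity_study(small_config)
    p2, _ = gen_plasticity_study(small_config)
    assert p1.counts.equals(p2.counts)


def test_counts_are_nonnegative_integers(small_config):
    cm, _ = gen_expression_study(small_config)
    assert (cm.counts.to_numpy() >= 0).all()
    assert cm.counts.dtypes.eq("int64").all()
    assert cm.gene_ids.is_unique and cm.sample_ids.is_unique


@pytest.mark.parametrize(
    "profile, expected",
    [([5, 0, 0, 0], 1.0), ([3, 3, 3], 0.0), ([1.0, 0.5, 0.0], 0.75)],
)
def test_true_tau_closed_form(profile, expected):
    assert true_tau(np.asarray(profile, dtype=float)) == pytest.approx(expected)


def test_tissue_panel_requires_two_tissues():
    with pytest.raises(ConfigError):
        gen_tissue_panel(SimConfig(n_tissues=1))


def test_tissue_panel_truth_covers_archetypes(small_config):
    _, truth = gen_tissue_panel(small_config)
    assert set(truth["archetype"]) == {"single", "uniform", "graded"}
    assert truth.loc[truth["archetype"] == "single", "true_tau"].eq(1.0).all()
    # uniform tau is ~0; small deviations come from per-tissue cpm totals
    uniform = truth.loc[truth["archetype"] == "uniform", "true_tau"]
    assert uniform.abs().max() < 0.05
    graded = truth.loc[truth["archetype"] == "graded", "true_tau"]
    assert ((graded > 0) & (graded < 1)).all()


def test_plasticity_design_and_response(small_config):
    cm, truth = gen_plasticity_study(small_config)
    assert set(cm.samples["condition"]) == {"control", "stress"}
    assert cm.samples["stage"].nunique() == small_config.n_stages
    plastic = truth["plastic"].to_numpy()
    stress = cm.samples.index[cm.samples["condition"] == "stress"]
    control = cm.samples.index[cm.samples["condition"] == "control"]
    fc = np.log2(
        (cm.counts[list(stress)].mean(axis=1) + 0.5)
        / (cm.counts[list(control)].mean(axis=1) + 0.5)
    )
    assert np.abs(fc[plastic]).mean() == pytest.approx(
        small_config.effect_log2fc, abs=0.4
    )
    assert np.abs(fc[~plastic]).mean() < 0.2


def test_gene_map_uses_configured_chromosomes():
    cfg = SimConfig(seed=1, n_genes=480, n_chromosomes=24)
    gmap = gen_gene_map(cfg, assign_labels(cfg))
    assert len(gmap.chromosomes) == 24
    assert len(gmap) == 480


def test_blocked_map_contains_a_full_run():
    cfg = SimConfig(
        seed=2, n_genes=500, n_chromosomes=5, clustering_mode="blocked", block_size=10
    )
    truth = assign_labels(cfg)
    gmap = gen_gene_map(cfg, truth)
    target = set(truth.loc[truth["label"] != simulate.UNBIASED, "gene"])
    best = 0
    for chrom in gmap.chromosomes:
        seq = gmap.label_sequence(chrom, target)
        run = cur = 0
        for v in seq:
            cur = cur + 1 if v else 0
            run = max(run, cur)
        best = max(best, run)
    assert best >= 10


def test_random_map_longest_run_consistent_with_permutation_null():
    """Label order in random mode is exchangeable: the longest run should not
    exceed the 99th percentile of a permutation null in most replicate maps."""

    def longest_run(seq):
        run = cur = 0
        for v in seq:
            cur = cur + 1 if v else 0
            run = max(run, cur)
        return run

    cfg0 = SimConfig(seed=0, n_genes=200, n_chromosomes=1)
    truth0 = assign_labels(cfg0)
    target0 = set(truth0.loc[truth0["label"] != simulate.UNBIASED, "gene"])
    rng = np.random.default_rng(123)
    base = gen_gene_map(cfg0, truth0).label_sequence("chr1", target0)
    null = sorted(
        longest_run(rng.permutation(base)) for _ in range(500)
    )
    cutoff = null[int(0.99 * len(null))]
    exceed = 0
    n_maps = 100
    for seed in range(n_maps):
        cfg = SimConfig(seed=seed, n_genes=200, n_chromosomes=1)
        truth = assign_labels(cfg)
        target = set(truth.loc[truth["label"] != simulate.UNBIASED, "gene"])
        seq = gen_gene_map(cfg, truth).label_sequence("chr1", target)
        exceed += longest_run(seq) > cutoff
    assert exceed / n_maps <= 0.05


def test_block_size_validation():
    with pytest.raises(ConfigError):
        cfg = SimConfig(
            seed=0, n_genes=100, n_chromosomes=10, clustering_mode="blocked", block_size=50
        )
        gen_gene_map(cfg, assign_labels(cfg))


def test_trio_zero_branch_lengths_identical():
    cfg = SimConfig(seed=3, n_genes=5, branch_lengths=(0.0, 0.0, 0.0), n_codons=50)
    aligns, rec = gen_trio_alignments(cfg, assign_labels(cfg))
    for trio in aligns:
        assert trio.focal == trio.sister == trio.outgroup
    assert (rec["true_focal_syn"] == 0).all() and (rec["true_focal_nonsyn"] == 0).all()


def test_trio_records_focal_substitution_bookkeeping():
    """With substitutions only on the focal branch, every observed codon
    difference from the (identical) sister/outgroup reflects recorded events."""
    cfg = SimConfig(seed=5, n_genes=10, branch_lengths=(0.1, 0.0, 0.0), n_codons=100)
    aligns, rec = gen_trio_alignments(cfg, assign_labels(cfg))
    for trio, (_, row) in zip(aligns, rec.iterrows()):
        assert trio.sister == trio.outgroup
        n_diff_codons = sum(
            trio.focal[i : i + 3] != trio.sister[i : i + 3]
            for i in range(0, len(trio.focal), 3)
        )
        total_events = row["true_focal_syn"] + row["true_focal_nonsyn"]
        assert total_events >= n_diff_codons


def test_mk_neutral_regime_centered_on_zero_dos():
    from sbevol.mk import dos

    cfg = SimConfig(seed=6, n_genes=5000)
    counts = gen_mk_counts(cfg, assign_labels(cfg))
    assert dos(counts).mean() == pytest.approx(0.0, abs=0.02)


def test_mk_regime_shapes():
    from sbevol.mk import dos, ni_tg

    del_cfg = SimConfig(seed=7, n_genes=500, mk_regime="deleterious")
    assert ni_tg(gen_mk_counts(del_cfg, assign_labels(del_cfg))) > 1
    pos_cfg = SimConfig(seed=7, n_genes=500, mk_regime="positive")
    assert dos(gen_mk_counts(pos_cfg, assign_labels(pos_cfg))).median() > 0


def test_multispecies_conservation_edge_cases():
    cfg = SimConfig(
        seed=8, n_genes=300, n_species=3, conservation_prob=1.0, false_positive_rate=0.0
    )
    truth = assign_labels(cfg)
    calls = gen_multispecies_sb_calls(cfg, truth)
    for c in calls:
        assert c["label"].equals(truth["label"])
    cfg0 = SimConfig(
        seed=8, n_genes=300, n_species=3, conservation_prob=0.0, false_positive_rate=0.0
    )
    calls0 = gen_multispecies_sb_calls(cfg0, truth)
    for c in calls0:
        assert (c["label"] == simulate.UNBIASED).all()


def test_multispecies_conserved_fraction_binomial():
    cfg = SimConfig(
        seed=9, n_genes=4000, n_species=6, conservation_prob=0.8,
        false_positive_rate=0.0, frac_female_biased=0.25, frac_male_biased=0.25,
    )
    truth = assign_labels(cfg)
    calls = gen_multispecies_sb_calls(cfg, truth)
    biased = truth["label"] != simulate.UNBIASED
    conserved = pd.concat(
        [c.set_index("gene")["label"] == truth.set_index("gene")["label"] for c in calls],
        axis=1,
    ).all(axis=1)
    frac = conserved[biased.to_numpy()].mean()
    expected = 0.8**6
    n_biased = int(biased.sum())
    tol = 4 * np.sqrt(expected * (1 - expected) / n_biased)
    assert frac == pytest.approx(expected, abs=tol)
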