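"""End-to-end pipeline assembly on synthetic inputs.

Glues the generators to the analysis stages: expression counts -> gene-class
calls -> codon trios evolved with per-class omega -> lineage rates -> class
comparisons (and optionally MK statistics and clustering tests).
"""

from __future__ import annotations

from dataclasses import replace

import pandas as pd

from . import cluster as cluster_mod
from . import simulate
from .compare import class_distributions, pairwise_compare
from .de import GeneSets, call_sb_genes, conserved_sb, de_pipeline
from .mk import dos, ni_tg
from .rates import filter_rates, process_trio, rates_table
from .simulate import SimConfig


def species_gene_sets(calls: pd.DataFrame) -> GeneSets:
    """Per-species call table (gene, label) -> GeneSets with fem/male filled."""
    return GeneSets(
        fem=set(calls.loc[calls["label"] == simulate.FEMALE, "gene"]),
        male=set(calls.loc[calls["label"] == simulate.MALE, "gene"]),
    )


def classify_expression(config: SimConfig):
    """Simulate the two-sex study, run DE, and build the gene classes
    (including the conserved-in-all-species sets)."""
    cm, truth = simulate.gen_expression_study(config)
    de_res = de_pipeline(cm)
    sets, labeled = call_sb_genes(de_res)
    calls = simulate.gen_multispecies_sb_calls(config, truth)
    fem6, male6 = conserved_sb([species_gene_sets(c) for c in calls])
    sets.fem_6sp = fem6 & sets.fem
    sets.male_6sp = male6 & sets.male
    return cm, truth, labeled, sets


def estimate_class_rates(config: SimConfig, truth: pd.DataFrame):
    """Simulate trios under per-class omega and estimate focal-branch rates."""
    alignments, sim_truth = simulate.gen_trio_alignments(config, truth)
    records = [process_trio(a, kappa=config.kappa) for a in alignments]
    retained, excluded = filter_rates(records)
    return rates_table(retained), rates_table(excluded), sim_truth


def pooled_omega(rates: pd.DataFrame) -> float:
    """Class-level mean omega by pooling counts across genes (ratio of totals);
    robust to the per-gene small-count ratio noise."""
    pn = rates["nd"].sum() / rates["N"].sum()
    ps = rates["sd"].sum() / rates["S"].sum()
    return float("nan") if ps == 0 else float(pn / ps)


def run_selection_study(config: SimConfig, family: list | None = None) -> dict:
    """Full qualitative-reproduction study.

    Expression classes are called from simulated counts, trios are evolved
    with the configured per-class omega, rates estimated and filtered, and
    the strong-bias classes compared with UB by Wilcoxon rank-sum with
    Bonferroni adjustment.
    """
    cm, truth, labeled, sets = classify_expression(config)
    rates, _, sim_truth = estimate_class_rates(config, truth)
    named = {"Fem_FC3": sets.fem_fc3, "Male_FC3": sets.male_fc3, "UB": sets.ub}
    dists = class_distributions(rates, named, "omega")
    if family is None:
        family = [("Fem_FC3", "UB"), ("Male_FC3", "UB"), ("Fem_FC3", "Male_FC3")]
    family = [pair for pair in family if pair[0] in dists and pair[1] in dists]
    comparisons = pairwise_compare(dists, family)
    return {
        "counts": cm,
        "truth": truth,
        "de": labeled,
        "sets": sets,
        "rates": rates,
        "sim_truth": sim_truth,
        "comparisons": comparisons,
    }


def run_mk_study(config: SimConfig) -> dict:
    counts = simulate.gen_mk_counts(config, simulate.assign_labels(config))
    return {"mk": counts, "dos": dos(counts), "ni_tg": ni_tg(counts)}


def run_cluster_study(config: SimConfig, n_perm: int = 10_000) -> pd.DataFrame:
    truth = simulate.assign_labels(config)
    gmap = simulate.gen_gene_map(config, truth)
    target = set(truth.loc[truth["label"] != simulate.UNBIASED, "gene"])
    return cluster_mod.cluster_tests(gmap, target, n_perm=n_perm, seed=config.seed)


def female_selection_config(seed: int = 0, n_genes: int = 600) -> SimConfig:
    """Study conditions for the female-selection scenario: strongly biased
    genes (|log2FC| = 4) with elevated omega only in the female-biased class."""
    return replace(
        SimConfig(seed=seed),
        n_genes=n_genes,
        effect_log2fc=4.0,
        omega_by_class={
            simulate.FEMALE: 0.6,
            simulate.MALE: 0.2,
            simulate.UNBIASED: 0.2,
        },
    )
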