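"""Self-validation benchmarks for the whole pipeline.

Each function runs one property-based check end to end on synthetic data
with known ground truth -- index identities, normalization sanity, error
control and power of the DE stage, omega parameter recovery, filter and
masking gates, selection-statistic calibration, clustering-test calibration,
small-sample agreement with enumeration oracles, and qualitative
reproduction of the female-biased selection pattern -- and returns the
measured quantities as a flat dict of floats.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import simulate, workflow
from .cluster import markov_odds, permutation_pvalue
from .compare import fisher_2x2, wilcoxon_rank_sum
from .containers import CountMatrix, TrioAlignment
from .de import call_sb_genes, compute_tmm_factors, de_pipeline
from .indices import tau
from .mk import dos, ni_tg
from .rates import (
    RateRecord,
    SHORT_ALIGNMENT,
    filter_rates,
    lineage_substitutions,
    mask_alignment,
    process_trio,
)
from .simulate import SimConfig, assign_labels


def tau_identities() -> dict[str, float]:
    """Closed-form tau identities on archetypal profiles."""
    return {
        "tau_single_tissue": tau([5.0, 0.0, 0.0, 0.0]),
        "tau_uniform": tau([2.0, 2.0, 2.0, 2.0, 2.0]),
        "tau_graded": tau([1.0, 0.5, 0.0]),
    }


def _plain_matrix(columns: dict[str, np.ndarray]) -> CountMatrix:
    df = pd.DataFrame(columns, index=[f"g{i}" for i in range(len(next(iter(columns.values()))))])
    return CountMatrix(df, pd.DataFrame(index=df.columns))


def tmm_checks() -> dict[str, float]:
    """TMM factor identities and the hand-computed composition-shift case."""
    base = np.array([10, 20, 30, 40])
    identical = _plain_matrix({"a": base, "b": base.copy()})
    dev_ident = float(np.abs(compute_tmm_factors(identical) - 1.0).max())
    scaled = _plain_matrix({"a": base, "b": 2 * base})
    dev_scaled = float(np.abs(compute_tmm_factors(scaled) - 1.0).max())
    a = np.array([100, 200, 300, 400, 1000])
    b = np.array([100, 200, 300, 400, 4000])
    toy = _plain_matrix({"a": a, "b": b})
    na, nb = a.sum(), b.sum()
    m = np.log2((b / nb) / (a / na))
    v = (nb - b) / (nb * b) + (na - a) / (na * a)
    rank = np.argsort(np.argsort(m)) + 1
    sel = (rank >= 2) & (rank <= 4)  # 30% two-sided trim on n = 5
    f = np.sum(m[sel] / v[sel]) / np.sum(1.0 / v[sel])
    expected = np.array([1.0, 2.0**f]) / math.sqrt(2.0**f)
    got = compute_tmm_factors(toy, reference="a").to_numpy()
    return {
        "tmm_identical_max_dev": dev_ident,
        "tmm_depth_scaled_max_dev": dev_scaled,
        "tmm_toy_max_dev_from_hand_value": float(np.abs(got - expected).max()),
    }


def de_error_control(seed: int = 0, n_seeds: int = 20) -> dict[str, float]:
    """Null false-call fraction and power of the DE + class-calling stage."""
    called = total = 0
    for i in range(n_seeds):
        cfg = SimConfig(
            seed=seed * 1000 + i, n_genes=2000, frac_female_biased=0.0,
            frac_male_biased=0.0,
        )
        cm, _ = simulate.gen_expression_study(cfg)
        sets, _ = call_sb_genes(de_pipeline(cm))
        called += len(sets.sb)
        total += cfg.n_genes
    cfg = SimConfig(seed=seed * 1000 + 999, n_genes=2000, effect_log2fc=3.0)
    cm, truth = simulate.gen_expression_study(cfg)
    sets, _ = call_sb_genes(de_pipeline(cm))
    fem_true = set(truth.loc[truth["label"] == simulate.FEMALE, "gene"])
    male_true = set(truth.loc[truth["label"] == simulate.MALE, "gene"])
    power = (len(sets.fem & fem_true) + len(sets.male & male_true)) / (
        len(fem_true) + len(male_true)
    )
    return {
        "de_null_sb_fraction": called / total,
        "de_power_log2fc3": power,
    }


def _omega_estimates(omega: float, seed: int, n_genes: int, n_codons: int):
    cfg = SimConfig(
        seed=seed, n_genes=n_genes, frac_female_biased=0.0, frac_male_biased=0.0,
        omega_by_class={"unbiased": omega}, n_codons=n_codons,
    )
    aligns, _ = simulate.gen_trio_alignments(cfg, assign_labels(cfg))
    retained, _ = filter_rates([process_trio(a, kappa=cfg.kappa) for a in aligns])
    per_gene = np.array([r.omega for r in retained if not np.isnan(r.omega)])
    pooled = (sum(r.nd for r in retained) / sum(r.n_sites for r in retained)) / (
        sum(r.sd for r in retained) / sum(r.s_sites for r in retained)
    )
    return pooled, float(np.median(per_gene))


def omega_recovery(seed: int = 0, n_genes: int = 300, n_codons: int = 300) -> dict[str, float]:
    """Parameter recovery of the dN/dS estimator at neutral and purifying omega.

    The class-mean omega is the pooled (ratio-of-totals) estimate; per-gene
    medians are reported alongside.
    """
    mean_1, med_1 = _omega_estimates(1.0, seed + 41, n_genes, n_codons)
    mean_02, med_02 = _omega_estimates(0.2, seed + 42, n_genes, n_codons)
    return {
        "omega1_mean_estimate": mean_1,
        "omega1_median_estimate": med_1,
        "omega02_mean_estimate": mean_02,
        "omega02_median_estimate": med_02,
        "omega02_median_rel_error": abs(med_02 - 0.2) / 0.2,
    }


def filter_gate_checks() -> dict[str, float]:
    """Constructed RateRecords exercising each exclusion gate."""

    def rec(gene, **kw):
        base = dict(n_sites=300.0, s_sites=100.0, nd=30.0, sd=10.0, dn=0.1, ds=0.1)
        base.update(kw)
        return RateRecord(gene, **base)

    records = [
        rec("saturated", ds=2.5),
        rec("low_ndn", dn=0.5 / 300.0),
        RateRecord("short90bp", flags={SHORT_ALIGNMENT}),
        rec("passing"),
    ]
    retained, excluded = filter_rates(records)
    correct = (
        {r.gene_id for r in excluded} == {"saturated", "low_ndn", "short90bp"}
        and {r.gene_id for r in retained} == {"passing"}
    )
    return {"filter_gates_correct": float(correct)}


def masking_checks() -> dict[str, float]:
    """Constructed windows at and below the masking cutoff, vs a brute-force scan."""
    focal = ["ATG", "AAA", "CCC", "GGG", "TTT", "GAT", "CAT", "ATG"] * 5
    swap = {"ATG": "CTG", "AAA": "GAA", "CCC": "ACC", "GGG": "AGG", "TTT": "GTT",
            "GAT": "AAT", "CAT": "AAT"}

    def scenario(n_diffs):
        sister = list(focal)
        for p in range(10, 10 + n_diffs):
            sister[p] = swap[sister[p]]
        trio = TrioAlignment("m", "".join(focal), "".join(sister), "".join(focal))
        return "NNN" in mask_alignment(trio).sister

    four_masked = scenario(4)
    three_unmasked = not scenario(3)
    return {"masking_cutoff_behaviour_correct": float(four_masked and three_unmasked)}


def mk_statistics(seed: int = 0) -> dict[str, float]:
    """Calibration of DoS and NI_TG under the three selection regimes."""
    cfg = SimConfig(seed=seed + 100, n_genes=5000)
    counts = simulate.gen_mk_counts(cfg, assign_labels(cfg))
    neutral_dos = float(dos(counts).mean())
    ni_vals = []
    for i in range(20):
        c = SimConfig(seed=seed + 200 + i, n_genes=5000)
        ni_vals.append(ni_tg(simulate.gen_mk_counts(c, assign_labels(c))))
    above = 0
    n_rep = 200
    for i in range(n_rep):
        c = SimConfig(seed=seed + 300 + i, n_genes=200, mk_regime="deleterious")
        above += ni_tg(simulate.gen_mk_counts(c, assign_labels(c))) > 1.0
    pos_cfg = SimConfig(seed=seed + 600, n_genes=2000, mk_regime="positive")
    pos_median = float(dos(simulate.gen_mk_counts(pos_cfg, assign_labels(pos_cfg))).median())
    return {
        "dos_neutral_mean": neutral_dos,
        "ni_tg_neutral_min": float(np.min(ni_vals)),
        "ni_tg_neutral_max": float(np.max(ni_vals)),
        "ni_tg_deleterious_frac_above_1": above / n_rep,
        "dos_positive_median": pos_median,
    }


def cluster_calibration(
    seed: int = 0, n_sims: int = 1000, n: int = 500, k: int = 50, n_perm: int = 400
) -> dict[str, float]:
    """Type-I error under random placement and power under blocked placement."""
    rng = np.random.default_rng(seed + 7000)
    rejections = 0
    for i in range(n_sims):
        seq = np.zeros(n, dtype=np.int64)
        seq[rng.choice(n, size=k, replace=False)] = 1
        _, p = permutation_pvalue(seq, n_perm=n_perm, seed=seed + 8000 + i)
        rejections += p <= 0.05
    type1 = rejections / n_sims
    power_hits = 0
    n_power = 200
    block = 10
    for i in range(n_power):
        seq = np.zeros(n, dtype=np.int64)
        starts = rng.choice(n - block, size=k // block, replace=False)
        for s in starts:
            seq[s : s + block] = 1
        k_eff = int(seq.sum())
        if k_eff == 0:
            continue
        _, p = permutation_pvalue(seq, n_perm=n_perm, seed=seed + 9000 + i)
        power_hits += p <= 0.05
    return {
        "cluster_type1_error": type1,
        "cluster_power_blocked": power_hits / n_power,
    }


def _enum_wilcoxon(a, b) -> float:
    pooled = np.concatenate([a, b])
    na = len(a)
    ranks = sps.rankdata(pooled)
    obs = ranks[:na].sum()
    mean = na * (len(pooled) + 1) / 2
    count = total = 0
    for idx in itertools.combinations(range(len(pooled)), na):
        w = ranks[list(idx)].sum()
        total += 1
        count += abs(w - mean) >= abs(obs - mean) - 1e-9
    return count / total


def _enum_fisher(a, b, c, d) -> float:
    r1, r2, c1, n = a + b, c + d, a + c, a + b + c + d

    def prob(x):
        if not (0 <= x <= r1 and 0 <= c1 - x <= r2):
            return 0.0
        return math.comb(r1, x) * math.comb(r2, c1 - x) / math.comb(n, c1)

    p_obs = prob(a)
    return sum(prob(x) for x in range(r1 + 1) if prob(x) <= p_obs + 1e-12)


def small_sample_agreement(seed: int = 0) -> dict[str, float]:
    """Worst-case deviation from enumeration oracles at small n."""
    rng = np.random.default_rng(seed + 50)
    values = np.sort(rng.random(8)) + np.arange(8)  # 8 distinct values
    worst_w = 0.0
    for na in range(1, 8):
        for idx in itertools.combinations(range(8), na):
            mask = np.zeros(8, dtype=bool)
            mask[list(idx)] = True
            a, b = values[mask], values[~mask]
            _, p = wilcoxon_rank_sum(a, b)
            worst_w = max(worst_w, abs(p - _enum_wilcoxon(a, b)))
    worst_f = 0.0
    for a in range(5):
        for b in range(5):
            for c in range(5):
                for d in range(5):
                    if 0 < a + b + c + d <= 12 and (a + b) and (c + d):
                        _, p = fisher_2x2([[a, b], [c, d]])
                        worst_f = max(worst_f, abs(p - _enum_fisher(a, b, c, d)))
    return {
        "wilcoxon_enum_max_abs_dev": worst_w,
        "fisher_enum_max_abs_dev": worst_f,
    }


def female_selection_reproduction(seed: int = 0) -> dict[str, float]:
    """End-to-end qualitative pattern: elevated omega only in strongly
    female-biased genes must surface as a significant Fem-FC3 vs UB contrast
    and no Male-FC3 elevation."""
    result = workflow.run_selection_study(workflow.female_selection_config(seed=seed + 77))
    comp = result["comparisons"].set_index(["group1", "group2"])
    fem = comp.loc[("Fem_FC3", "UB")]
    male = comp.loc[("Male_FC3", "UB")]
    # "elevation" is directional: a significant contrast with a lower
    # Male-FC3 median is not a male elevation
    male_elevated = float(
        male["p_bonferroni"] < 0.05 and male["median1"] > male["median2"]
    )
    return {
        "endtoend_fem_fc3_median_omega": float(fem["median1"]),
        "endtoend_ub_median_omega": float(fem["median2"]),
        "endtoend_male_fc3_median_omega": float(male["median1"]),
        "endtoend_fem_fc3_vs_ub_p_bonf": float(fem["p_bonferroni"]),
        "endtoend_male_fc3_vs_ub_p_bonf": float(male["p_bonferroni"]),
        "endtoend_male_fc3_elevated": male_elevated,
    }


ALL_BENCHMARKS = (
    tau_identities,
    tmm_checks,
    de_error_control,
    omega_recovery,
    filter_gate_checks,
    masking_checks,
    mk_statistics,
    cluster_calibration,
    small_sample_agreement,
    female_selection_reproduction,
)


def run_all(seed: int = 0) -> dict[str, float]:
    out: dict[str, float] = {}
    for fn in ALL_BENCHMARKS:
        kwargs = {"seed": seed} if "seed" in fn.__code__.co_varnames else {}
        out.update(fn(**kwargs))
    return out
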