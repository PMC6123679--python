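"""Synthetic data generators with known ground truth.

Every pipeline input can be produced here: negative-binomial RNA-seq counts
for a two-sex gonad study, a multi-tissue panel built from tissue-specificity
archetypes, a stress-response study at three larval stages, gene placements
along chromosomes (random or blocked), codon-level trio alignments evolved
under a Goldman-Yang-style model with per-class omega, McDonald-Kreitman
count tables under neutral / deleterious / positive regimes, and per-species
sex-bias call tables for conservation analysis.

Counts follow the standard RNA-seq negative-binomial parameterization
(mean mu, variance mu + phi * mu^2); phi = 0 degenerates to Poisson.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .codon import MutationTable, SENSE_CODONS
from .containers import CountMatrix, GeneMap, TrioAlignment
from .errors import ConfigError

FEMALE = "female_biased"
MALE = "male_biased"
UNBIASED = "unbiased"

# independent RNG streams per generator so outputs do not depend on call order
_STREAMS = {
    "expression": 1,
    "tissue": 2,
    "plasticity": 3,
    "map": 4,
    "trio": 5,
    "mk": 6,
    "species": 7,
}


@dataclass
class SimConfig:
    """Simulation parameters; defaults mirror the gonad study design
    (4 vs 4 samples, ~5M reads) at desk scale."""

    seed: int = 0
    n_genes: int = 2000
    n_samples_per_group: int = 4
    library_size: float = 5e6
    dispersion: float = 0.1
    frac_female_biased: float = 0.1
    frac_male_biased: float = 0.1
    effect_log2fc: float = 3.0
    n_tissues: int = 9
    n_reps_per_tissue: int = 3
    n_chromosomes: int = 24
    clustering_mode: str = "random"
    block_size: int = 10
    omega_by_class: dict = field(
        default_factory=lambda: {FEMALE: 0.2, MALE: 0.2, UNBIASED: 0.2}
    )
    branch_lengths: tuple = (0.05, 0.05, 0.1)  # focal, sister, outgroup; subs/codon
    kappa: float = 2.0
    n_codons: int = 300
    mk_regime: str = "neutral"
    mk_nonsyn_sites: float = 250.0
    mk_syn_sites: float = 100.0
    mk_poly_rate: float = 0.05
    mk_div_rate: float = 0.1
    mk_selection_factor: float = 2.0
    frac_plastic: float = 0.2
    n_stages: int = 3
    n_species: int = 6
    conservation_prob: float = 0.8
    false_positive_rate: float = 0.02

    def __post_init__(self) -> None:
        probs = {
            "frac_female_biased": self.frac_female_biased,
            "frac_male_biased": self.frac_male_biased,
            "conservation_prob": self.conservation_prob,
            "false_positive_rate": self.false_positive_rate,
            "frac_plastic": self.frac_plastic,
        }
        for name, p in probs.items():
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"{name}={p} outside [0, 1]")
        if self.frac_female_biased + self.frac_male_biased > 1.0 + 1e-12:
            raise ConfigError("frac_female_biased + frac_male_biased exceeds 1")
        counts = {
            "n_genes": self.n_genes,
            "n_samples_per_group": self.n_samples_per_group,
            "n_chromosomes": self.n_chromosomes,
            "block_size": self.block_size,
            "n_codons": self.n_codons,
            "n_species": self.n_species,
            "n_stages": self.n_stages,
            "n_reps_per_tissue": self.n_reps_per_tissue,
        }
        for name, c in counts.items():
            if int(c) != c or c <= 0:
                raise ConfigError(f"{name}={c} must be a positive integer")
        if self.dispersion < 0:
            raise ConfigError("dispersion must be >= 0")
        if any(b < 0 for b in self.branch_lengths) or len(self.branch_lengths) != 3:
            raise ConfigError("branch_lengths must be three non-negative numbers")
        if self.library_size <= 0:
            raise ConfigError("library_size must be positive")
        if self.mk_regime not in {"neutral", "deleterious", "positive"}:
            raise ConfigError(f"unknown mk_regime {self.mk_regime!r}")
        if self.clustering_mode not in {"random", "blocked"}:
            raise ConfigError(f"unknown clustering_mode {self.clustering_mode!r}")

    def rng(self, stream: str) -> np.random.Generator:
        return np.random.default_rng([_STREAMS[stream], self.seed])

    def with_seed(self, seed: int) -> "SimConfig":
        return replace(self, seed=seed)


def _gene_ids(n: int) -> list[str]:
    width = max(4, len(str(n - 1)))
    return [f"g{i:0{width}d}" for i in range(n)]


def assign_labels(config: SimConfig) -> pd.DataFrame:
    """Deterministic ground-truth class labels and true effects.

    Class proportions match the configuration exactly (rounded counts); the
    first round(f_fem * n) genes are female-biased, the next round(f_male * n)
    male-biased, the remainder unbiased.
    """
    n = config.n_genes
    n_fem = int(round(config.frac_female_biased * n))
    n_male = int(round(config.frac_male_biased * n))
    labels = [FEMALE] * n_fem + [MALE] * n_male + [UNBIASED] * (n - n_fem - n_male)
    fc = np.where(
        np.array(labels) == FEMALE,
        config.effect_log2fc,
        np.where(np.array(labels) == MALE, -config.effect_log2fc, 0.0),
    )
    return pd.DataFrame({"gene": _gene_ids(n), "label": labels, "true_log2fc": fc})


def _nb_counts(mu: np.ndarray, phi: float, rng: np.random.Generator) -> np.ndarray:
    """NB(mu, var = mu + phi mu^2) via gamma-Poisson mixing; phi=0 is Poisson."""
    if phi == 0:
        return rng.poisson(mu)
    lam = rng.gamma(shape=1.0 / phi, scale=phi * mu)
    return rng.poisson(lam)


def gen_expression_study(config: SimConfig) -> tuple[CountMatrix, pd.DataFrame]:
    """Two-group (female vs male gonad) NB count matrix with known biased genes.

    The per-gene effect is applied symmetrically (half up in one sex, half
    down in the other, on the log2 scale) so library composition stays
    balanced when the two biased fractions are equal.
    """
    truth = assign_labels(config)
    rng = config.rng("expression")
    n = config.n_genes
    base = rng.lognormal(mean=0.0, sigma=1.5, size=n)
    base /= base.sum()
    half = truth["true_log2fc"].to_numpy() / 2.0
    mu_f = base * np.exp2(half) * config.library_size
    mu_m = base * np.exp2(-half) * config.library_size
    k = config.n_samples_per_group
    mu = np.column_stack([np.tile(mu_f[:, None], k), np.tile(mu_m[:, None], k)])
    counts = _nb_counts(mu, config.dispersion, rng)
    sample_ids = [f"F{i+1}" for i in range(k)] + [f"M{i+1}" for i in range(k)]
    samples = pd.DataFrame(
        {
            "tissue": "gonad",
            "sex": ["female"] * k + ["male"] * k,
            "condition": "NA",
            "stage": "adult",
            "species": "focal",
        },
        index=pd.Index(sample_ids, name="sample"),
    )
    cm = CountMatrix(pd.DataFrame(counts, index=truth["gene"], columns=sample_ids), samples)
    return cm, truth


# archetype peak expression: 2^8 = 256 relative cpm units before rescaling
_PEAK_LOG2 = 8.0


def _archetype_profiles(n_tissues: int) -> dict[str, np.ndarray]:
    """Designed relative-cpm profiles; entries of exactly 0 mean unexpressed."""
    ramp_log2 = _PEAK_LOG2 * (1.0 - np.arange(n_tissues) / (n_tissues - 1))
    graded = np.exp2(ramp_log2)
    graded[-1] = 0.0  # lowest tissue truly silent
    return {
        "single": np.array([2.0**_PEAK_LOG2] + [0.0] * (n_tissues - 1)),
        "uniform": np.full(n_tissues, 2.0**_PEAK_LOG2),
        "graded": graded,
    }


def true_tau(profile: np.ndarray) -> float:
    """Closed-form tau of a noiseless non-negative profile."""
    x = np.asarray(profile, dtype=float)
    x = x / x.max()
    return float((1.0 - x).sum() / (len(x) - 1))


def gen_tissue_panel(config: SimConfig) -> tuple[CountMatrix, pd.DataFrame]:
    """Multi-tissue NB counts from tau archetypes (single / uniform / graded).

    Archetypes are assigned round-robin and each gene's designed profile is
    rotated across tissues so every tissue carries expression.  Per-tissue
    expected totals equal the configured library size, so the expected
    realized cpm of gene g in tissue t is designed_gt / C_t * 1e6 with C_t
    the designed per-tissue total.  Ground truth records each gene's
    closed-form tau on that expected floored log2-cpm profile -- the same
    scale the estimator operates on.  Unexpressed tissues (designed 0) give
    tau = 1 for the single-tissue archetype exactly.
    """
    if config.n_tissues < 2:
        raise ConfigError("n_tissues must be >= 2")
    genes = _gene_ids(config.n_genes)
    rng = config.rng("tissue")
    profiles = _archetype_profiles(config.n_tissues)
    names = list(profiles)
    tissues = [f"tissue{t+1}" for t in range(config.n_tissues)]
    reps = config.n_reps_per_tissue
    designed = np.zeros((config.n_genes, config.n_tissues))
    arch_of = []
    for i in range(config.n_genes):
        arch = names[i % len(names)]
        arch_of.append(arch)
        designed[i] = np.roll(profiles[arch], i % config.n_tissues)
    totals = designed.sum(axis=0)  # C_t per tissue
    expected_cpm = designed / totals * 1e6
    with np.errstate(divide="ignore"):
        expected_log2cpm = np.where(
            expected_cpm > 0, np.maximum(0.0, np.log2(np.maximum(expected_cpm, 1e-300))), 0.0
        )
    truth_rows = [
        {"gene": g, "archetype": a, "true_tau": true_tau(expected_log2cpm[i])}
        for i, (g, a) in enumerate(zip(genes, arch_of))
    ]
    mu_per_rep = designed / totals * config.library_size
    rows = [
        _nb_counts(np.repeat(mu_per_rep[i], reps), config.dispersion, rng)
        for i in range(config.n_genes)
    ]
    sample_ids = [f"{t}_r{r+1}" for t in tissues for r in range(reps)]
    samples = pd.DataFrame(
        {
            "tissue": np.repeat(tissues, reps),
            "sex": "NA",
            "condition": "NA",
            "stage": "NA",
            "species": "focal",
        },
        index=pd.Index(sample_ids, name="sample"),
    )
    cm = CountMatrix(pd.DataFrame(np.array(rows), index=genes, columns=sample_ids), samples)
    return cm, pd.DataFrame(truth_rows)


def gen_plasticity_study(config: SimConfig) -> tuple[CountMatrix, pd.DataFrame]:
    """Counts for n_stages x {control, stress} with designated plastic genes.

    Plastic genes respond at effect_log2fc in every stress contrast; response
    direction alternates across plastic genes to keep composition balanced.
    """
    genes = _gene_ids(config.n_genes)
    rng = config.rng("plasticity")
    n = config.n_genes
    n_plastic = int(round(config.frac_plastic * n))
    plastic = np.zeros(n, dtype=bool)
    plastic[:n_plastic] = True
    sign = np.where(np.arange(n) % 2 == 0, 1.0, -1.0)
    delta = np.where(plastic, sign * config.effect_log2fc, 0.0)
    base = rng.lognormal(mean=0.0, sigma=1.5, size=n)
    base /= base.sum()
    k = config.n_samples_per_group
    blocks, meta = [], []
    for stage in range(1, config.n_stages + 1):
        for cond in ("control", "stress"):
            shift = delta / 2.0 if cond == "stress" else -delta / 2.0
            mu = base * np.exp2(shift) * config.library_size
            for r in range(k):
                blocks.append(_nb_counts(mu, config.dispersion, rng))
                meta.append(
                    {
                        "sample": f"st{stage}_{cond}_r{r+1}",
                        "tissue": "larva",
                        "sex": "NA",
                        "condition": cond,
                        "stage": f"stage{stage}",
                        "species": "focal",
                    }
                )
    samples = pd.DataFrame(meta).set_index("sample")
    cm = CountMatrix(
        pd.DataFrame(np.column_stack(blocks), index=genes, columns=samples.index), samples
    )
    truth = pd.DataFrame({"gene": genes, "plastic": plastic, "true_response_log2fc": delta})
    return cm, truth


def gen_gene_map(config: SimConfig, truth: pd.DataFrame) -> GeneMap:
    """Place genes on chromosomes, uniformly or with biased genes in blocks.

    Placement is by ordinal rank; start coordinates are synthesized as
    rank * 10 kb.  In blocked mode, genes whose ground-truth label is biased
    are grouped into runs of ``block_size`` consecutive ranks.
    """
    rng = config.rng("map")
    genes = truth["gene"].to_numpy()
    is_target = (truth["label"] != UNBIASED).to_numpy()
    n = len(genes)
    per_chrom = n // config.n_chromosomes
    if per_chrom == 0:
        raise ConfigError("fewer genes than chromosomes")
    if config.clustering_mode == "blocked" and config.block_size > per_chrom:
        raise ConfigError("block_size exceeds the number of genes per chromosome")
    if config.clustering_mode == "random":
        order = rng.permutation(n)
    else:
        targets = list(genes[is_target])
        others = list(genes[~is_target])
        units: list[list[str]] = [
            targets[i : i + config.block_size]
            for i in range(0, len(targets), config.block_size)
        ]
        units += [[g] for g in others]
        rng.shuffle(units)
        flat = [g for unit in units for g in unit]
        pos = {g: i for i, g in enumerate(genes)}
        order = np.array([pos[g] for g in flat])
    ordered = genes[order]
    sizes = np.full(config.n_chromosomes, per_chrom)
    sizes[: n - per_chrom * config.n_chromosomes] += 1
    rows = []
    start = 0
    for c, size in enumerate(sizes):
        for rank, gene in enumerate(ordered[start : start + size]):
            rows.append(
                {"gene": gene, "chrom": f"chr{c+1}", "start": rank * 10_000, "rank": rank}
            )
        start += size
    return GeneMap(pd.DataFrame(rows))


def gen_trio_alignments(
    config: SimConfig, truth: pd.DataFrame
) -> tuple[list[TrioAlignment], pd.DataFrame]:
    """Evolve codon trios under per-class omega on the 3-branch tree.

    The ancestral sequence sits at the focal/sister split; the outgroup
    branch spans root-to-outgroup.  Returns the alignments and a table of
    true per-gene omega and realized focal-branch substitution counts.
    """
    if config.n_codons < 1:
        raise ConfigError("n_codons must be positive")
    rng = config.rng("trio")
    tables = {
        label: MutationTable(omega, config.kappa)
        for label, omega in config.omega_by_class.items()
    }
    t_f, t_s, t_o = config.branch_lengths
    sense = np.array(SENSE_CODONS)
    alignments, records = [], []
    for gene, label in zip(truth["gene"], truth["label"]):
        if label not in tables:
            raise ConfigError(f"omega_by_class has no entry for class {label!r}")
        table = tables[label]
        anc = sense[rng.integers(0, len(sense), size=config.n_codons)]
        seqs = {}
        focal_sd = focal_nd = 0
        for name, t in (("focal", t_f), ("sister", t_s), ("outgroup", t_o)):
            out = []
            for codon in anc:
                final, sd, nd = table.evolve_codon(codon, t, rng)
                out.append(final)
                if name == "focal":
                    focal_sd += sd
                    focal_nd += nd
            seqs[name] = "".join(out)
        alignments.append(
            TrioAlignment(gene, seqs["focal"], seqs["sister"], seqs["outgroup"])
        )
        records.append(
            {
                "gene": gene,
                "label": label,
                "true_omega": table.omega,
                "true_focal_syn": focal_sd,
                "true_focal_nonsyn": focal_nd,
            }
        )
    return alignments, pd.DataFrame(records)


def gen_mk_counts(config: SimConfig, truth: pd.DataFrame) -> pd.DataFrame:
    """Per-gene Pn/Ps/Dn/Ds under the configured selection regime.

    Counts are Poisson with equal per-site rates in the neutral regime, so
    E[DoS] = 0 by construction.  The deleterious regime inflates only Pn,
    the positive regime only Dn, by ``mk_selection_factor``.
    """
    rng = config.rng("mk")
    n = len(truth)
    ln, ls = config.mk_nonsyn_sites, config.mk_syn_sites
    pn_rate = ln * config.mk_poly_rate
    ps_rate = ls * config.mk_poly_rate
    dn_rate = ln * config.mk_div_rate
    ds_rate = ls * config.mk_div_rate
    if config.mk_regime == "deleterious":
        pn_rate *= config.mk_selection_factor
    elif config.mk_regime == "positive":
        dn_rate *= config.mk_selection_factor
    return pd.DataFrame(
        {
            "gene": truth["gene"].to_numpy(),
            "Pn": rng.poisson(pn_rate, n),
            "Ps": rng.poisson(ps_rate, n),
            "Dn": rng.poisson(dn_rate, n),
            "Ds": rng.poisson(ds_rate, n),
        }
    )


def gen_multispecies_sb_calls(config: SimConfig, truth: pd.DataFrame) -> list[pd.DataFrame]:
    """Per-species sex-bias call tables for conservation analysis.

    A truly biased gene keeps its direction and is called in each species
    independently with ``conservation_prob``; unbiased genes are called (in a
    random direction) at ``false_positive_rate``.
    """
    if config.n_species < 2:
        raise ConfigError("n_species must be >= 2")
    rng = config.rng("species")
    labels = truth["label"].to_numpy()
    genes = truth["gene"].to_numpy()
    out = []
    for s in range(config.n_species):
        called = np.where(
            labels != UNBIASED,
            np.where(rng.random(len(genes)) < config.conservation_prob, labels, UNBIASED),
            np.where(
                rng.random(len(genes)) < config.false_positive_rate,
                np.where(rng.random(len(genes)) < 0.5, FEMALE, MALE),
                UNBIASED,
            ),
        )
        out.append(pd.DataFrame({"gene": genes, "label": called, "species": f"sp{s+1}"}))
    return out
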