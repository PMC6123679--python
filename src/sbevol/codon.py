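"""Genetic-code machinery shared by the codon simulator and the rate estimator.

Everything here operates on the standard nuclear genetic code.  Site counting
follows the mutational-opportunity logic of Nei & Gojobori: each codon
position contributes one site, split between synonymous and non-synonymous in
proportion to the (optionally transition-weighted) mutation rates of the three
alternative bases.  Substitutions between codons differing at more than one
position are averaged over minimal mutational pathways, excluding pathways
that traverse a stop codon.
"""

from __future__ import annotations

import itertools
from functools import lru_cache

import numpy as np
from Bio.Data.CodonTable import standard_dna_table

BASES = "ACGT"
PURINES = frozenset("AG")
PYRIMIDINES = frozenset("CT")
STOP_CODONS = frozenset(standard_dna_table.stop_codons)  # TAA, TAG, TGA
CODONS = ["".join(c) for c in itertools.product(BASES, repeat=3)]
SENSE_CODONS = [c for c in CODONS if c not in STOP_CODONS]

CODON_TO_AA = dict(standard_dna_table.forward_table)
for _stop in STOP_CODONS:
    CODON_TO_AA[_stop] = "*"

GAP_CHARS = frozenset("-Nn")


def is_transition(a: str, b: str) -> bool:
    """True when the a<->b change is a purine<->purine or pyrimidine<->pyrimidine swap."""
    return (a in PURINES and b in PURINES) or (a in PYRIMIDINES and b in PYRIMIDINES)


def is_valid_codon(codon: str) -> bool:
    return len(codon) == 3 and all(b in BASES for b in codon)


def split_codons(seq: str) -> list[str]:
    if len(seq) % 3 != 0:
        raise ValueError(f"sequence length {len(seq)} is not a multiple of 3")
    return [seq[i : i + 3] for i in range(0, len(seq), 3)]


@lru_cache(maxsize=None)
def codon_sites(codon: str, kappa: float = 1.0) -> tuple[float, float]:
    """Synonymous and non-synonymous site counts for one codon.

    Each position contributes one site, partitioned by the fraction of
    single-base changes at that position that are synonymous.  Changes to stop
    codons are excluded and the fractions renormalized, so S + N = 3 exactly.
    ``kappa`` weights transitions relative to transversions; kappa = 1 is the
    classic equal-rate Nei-Gojobori count.

    Returns (S, N).
    """
    if codon in STOP_CODONS:
        raise ValueError(f"stop codon {codon!r} has no defined site counts")
    if not is_valid_codon(codon):
        raise ValueError(f"invalid codon {codon!r}")
    aa = CODON_TO_AA[codon]
    syn = 0.0
    for pos in range(3):
        w_syn = w_tot = 0.0
        for alt in BASES:
            if alt == codon[pos]:
                continue
            mutant = codon[:pos] + alt + codon[pos + 1 :]
            if mutant in STOP_CODONS:
                continue
            w = kappa if is_transition(codon[pos], alt) else 1.0
            w_tot += w
            if CODON_TO_AA[mutant] == aa:
                w_syn += w
        if w_tot > 0:
            syn += w_syn / w_tot
    return syn, 3.0 - syn


def sequence_sites(seq: str, kappa: float = 1.0) -> tuple[float, float]:
    """(S, N) summed over the codons of a gap-free coding sequence."""
    s = n = 0.0
    for i, codon in enumerate(split_codons(seq)):
        if codon in STOP_CODONS:
            raise ValueError(f"in-frame stop codon at codon index {i}")
        cs, cn = codon_sites(codon, kappa)
        s += cs
        n += cn
    return s, n


@lru_cache(maxsize=None)
def pathway_counts(c1: str, c2: str) -> tuple[float, float] | None:
    """Average (syn, nonsyn) substitution counts over minimal pathways c1 -> c2.

    Pathways passing through a stop codon are dropped and the remaining ones
    weighted equally.  Returns None when every pathway is blocked by a stop.
    """
    if c1 in STOP_CODONS or c2 in STOP_CODONS:
        raise ValueError("pathway counting is undefined for stop codons")
    diff = [i for i in range(3) if c1[i] != c2[i]]
    if not diff:
        return 0.0, 0.0
    outcomes: list[tuple[int, int]] = []
    for order in itertools.permutations(diff):
        cur = c1
        sd = nd = 0
        ok = True
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if nxt in STOP_CODONS:
                ok = False
                break
            if CODON_TO_AA[nxt] == CODON_TO_AA[cur]:
                sd += 1
            else:
                nd += 1
            cur = nxt
        if ok:
            outcomes.append((sd, nd))
    if not outcomes:
        return None
    arr = np.asarray(outcomes, dtype=float)
    return float(arr[:, 0].mean()), float(arr[:, 1].mean())


class MutationTable:
    """Per-codon single-base mutation targets and rates under a GY-style scheme.

    Rates are kappa^transition * omega^nonsynonymous per target codon; stop
    targets are rejected (rate 0).  ``mean_rate`` is the average total rate
    over the 61 sense codons, used to express branch lengths in expected
    substitutions per codon.
    """

    def __init__(self, omega: float, kappa: float = 2.0):
        if omega < 0 or kappa <= 0:
            raise ValueError("omega must be >= 0 and kappa > 0")
        self.omega = omega
        self.kappa = kappa
        self.targets: dict[str, list[str]] = {}
        self.is_syn: dict[str, np.ndarray] = {}
        self.rates: dict[str, np.ndarray] = {}
        self.total_rate: dict[str, float] = {}
        for codon in SENSE_CODONS:
            tg, sy, rt = [], [], []
            for pos in range(3):
                for alt in BASES:
                    if alt == codon[pos]:
                        continue
                    mutant = codon[:pos] + alt + codon[pos + 1 :]
                    if mutant in STOP_CODONS:
                        continue
                    syn = CODON_TO_AA[mutant] == CODON_TO_AA[codon]
                    rate = (kappa if is_transition(codon[pos], alt) else 1.0) * (
                        1.0 if syn else omega
                    )
                    tg.append(mutant)
                    sy.append(syn)
                    rt.append(rate)
            rt_arr = np.asarray(rt, dtype=float)
            self.targets[codon] = tg
            self.is_syn[codon] = np.asarray(sy, dtype=bool)
            self.rates[codon] = rt_arr
            self.total_rate[codon] = float(rt_arr.sum())
        self.mean_rate = float(np.mean([self.total_rate[c] for c in SENSE_CODONS]))

    def evolve_codon(
        self, codon: str, branch_length: float, rng: np.random.Generator
    ) -> tuple[str, int, int]:
        """Evolve one codon for ``branch_length`` expected substitutions/codon.

        Uses the embedded jump chain of the normalized rate process and
        returns (final codon, n_synonymous events, n_nonsynonymous events).
        """
        t = branch_length
        sd = nd = 0
        while True:
            rate = self.total_rate[codon] / self.mean_rate
            if rate <= 0:
                break
            dt = rng.exponential(1.0 / rate)
            if dt > t:
                break
            t -= dt
            r = self.rates[codon]
            idx = rng.choice(len(r), p=r / r.sum())
            if self.is_syn[codon][idx]:
                sd += 1
            else:
                nd += 1
            codon = self.targets[codon][idx]
        return codon, sd, nd
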