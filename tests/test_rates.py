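"""Alignment cleaning, masking, substitution counting and rate estimation."""

import math

import numpy as np
import pytest

from sbevol.containers import TrioAlignment
from sbevol.errors import ComputationError
from sbevol.rates import (
    MASKED_SHORT,
    SHORT_ALIGNMENT,
    RateRecord,
    clean_alignment,
    count_sites,
    estimate_rates,
    filter_rates,
    lineage_substitutions,
    mask_alignment,
    process_trio,
)


def trio_of(focal, sister, outgroup, gene="g"):
    return TrioAlignment(gene, focal, sister, outgroup)


class TestClean:
    def test_gap_column_removed_everywhere(self):
        t = trio_of("ATGAAA", "ATGAAA", "AT-AAA")
        out = clean_alignment(t)
        assert out.focal == out.sister == out.outgroup == "AAA"

    def test_n_column_removed(self):
        t = trio_of("ATGNAA" + "CCC", "ATGAAA" + "CCC", "ATGAAA" + "CCC")
        out = clean_alignment(t)
        assert out.focal == "ATGCCC"

    def test_clean_is_identity_without_gaps(self):
        seq = "ATGAAACCC" * 12  # 108 bp, above the short-alignment gate
        t = trio_of(seq, seq, seq)
        out = clean_alignment(t)
        assert out.focal == t.focal and not out.flags

    def test_short_alignment_flagged(self):
        t = trio_of("ATGAAA", "ATGAAA", "ATGAAA")  # 6 bp < 100 bp
        assert SHORT_ALIGNMENT in clean_alignment(t).flags


def brute_force_mask(target_codons, focal_codons, cutoff=4, window=5):
    """Independent exhaustive window scan."""
    from sbevol.codon import CODON_TO_AA, STOP_CODONS

    def nonsyn(a, b):
        ok = all(ch in "ACGT" for ch in a + b)
        return (
            ok
            and a != b
            and a not in STOP_CODONS
            and b not in STOP_CODONS
            and CODON_TO_AA[a] != CODON_TO_AA[b]
        )

    n = len(target_codons)
    masked = set()
    for start in range(n - window + 1):
        hits = sum(
            nonsyn(target_codons[start + j], focal_codons[start + j]) for j in range(window)
        )
        if hits >= cutoff:
            masked.update(range(start, start + window))
    return masked


class TestMask:
    FOCAL = ["ATG", "AAA", "CCC", "GGG", "TTT", "GAT", "CAT", "ATG"] * 5

    def _with_diffs(self, positions):
        """Sister copies focal except non-synonymous changes at positions."""
        swap = {"ATG": "CTG", "AAA": "GAA", "CCC": "ACC", "GGG": "AGG", "TTT": "GTT",
                "GAT": "AAT", "CAT": "AAT"}
        sister = list(self.FOCAL)
        for p in positions:
            sister[p] = swap[sister[p]]
        return sister

    def test_window_with_four_nonsyn_diffs_masked(self):
        sister = self._with_diffs([10, 11, 12, 13])
        t = trio_of("".join(self.FOCAL), "".join(sister), "".join(self.FOCAL))
        out = mask_alignment(t)
        assert "NNN" in out.sister
        masked_idx = {i for i in range(len(self.FOCAL)) if out.sister[3 * i : 3 * i + 3] == "NNN"}
        oracle = brute_force_mask(sister, self.FOCAL)
        assert masked_idx == oracle

    def test_three_diffs_not_masked(self):
        sister = self._with_diffs([10, 11, 12])
        t = trio_of("".join(self.FOCAL), "".join(sister), "".join(self.FOCAL))
        out = mask_alignment(t)
        assert "NNN" not in out.sister
        assert brute_force_mask(sister, self.FOCAL) == set()

    def test_identical_sequences_untouched(self):
        seq = "".join(self.FOCAL)
        out = mask_alignment(trio_of(seq, seq, seq))
        assert out.sister == seq and out.outgroup == seq

    def test_random_masking_matches_bruteforce_oracle(self):
        from sbevol.codon import SENSE_CODONS

        rng = np.random.default_rng(7)
        for _ in range(10):
            focal = list(rng.choice(SENSE_CODONS, size=30))
            sister = list(focal)
            for p in rng.choice(30, size=12, replace=False):
                sister[p] = str(rng.choice(SENSE_CODONS))
            t = trio_of("".join(focal), "".join(sister), "".join(focal))
            out = mask_alignment(t)
            masked_idx = {i for i in range(30) if out.sister[3 * i : 3 * i + 3] == "NNN"}
            assert masked_idx == brute_force_mask(sister, focal)

    def test_masking_never_increases_substitution_counts(self):
        from sbevol.codon import SENSE_CODONS

        rng = np.random.default_rng(8)
        for _ in range(10):
            focal = list(rng.choice(SENSE_CODONS, size=40))
            sister = [
                str(rng.choice(SENSE_CODONS)) if rng.random() < 0.3 else c for c in focal
            ]
            out_s = [
                str(rng.choice(SENSE_CODONS)) if rng.random() < 0.1 else c for c in sister
            ]
            t = trio_of("".join(focal), "".join(sister), "".join(out_s))
            nd0, sd0, _ = lineage_substitutions(t)
            nd1, sd1, _ = lineage_substitutions(mask_alignment(t))
            assert nd1 <= nd0 + 1e-9 and sd1 <= sd0 + 1e-9

    def test_heavily_masked_sequence_flagged(self):
        focal = ["ATG", "AAA", "CCC", "GGG", "TTT", "GAT", "CAT"] * 4  # 28 codons, 84 bp
        sister = self._with_diffs(range(7))[:28]
        sister = list(focal)
        swap = {"ATG": "CTG", "AAA": "GAA", "CCC": "ACC", "GGG": "AGG", "TTT": "GTT",
                "GAT": "AAT", "CAT": "AAT"}
        sister = [swap[c] for c in sister]  # everything non-synonymous
        t = trio_of("".join(focal), "".join(sister), "".join(focal))
        out = mask_alignment(t)
        assert MASKED_SHORT in out.flags

    def test_window_longer_than_alignment_is_noop(self):
        t = trio_of("ATGAAA", "ATGAAG", "ATGAAA")
        out = mask_alignment(t, window=5)
        assert out.sister == t.sister


class TestSitesAndSubstitutions:
    def test_known_site_counts(self):
        n, s = count_sites("TTT", kappa=1.0)
        assert s == pytest.approx(1 / 3) and n == pytest.approx(8 / 3)
        n, s = count_sites("ATG", kappa=1.0)
        assert (s, n) == (0.0, 3.0)

    def test_site_conservation(self):
        seq = "ATGTTTAAACCCGGGCTTGAT"
        n, s = count_sites(seq, kappa=1.0)
        assert n + s == pytest.approx(len(seq))

    def test_stop_codon_error_names_index(self):
        with pytest.raises(ComputationError, match="codon index 1"):
            count_sites("ATGTAAAAA")

    def test_focal_synonymous_substitution(self):
        t = trio_of("TTC", "TTT", "TTT")
        nd, sd, amb = lineage_substitutions(t)
        assert (nd, sd, amb) == (0.0, 1.0, 0)

    def test_invariant_column_contributes_nothing(self):
        t = trio_of("TTT", "TTT", "TTT")
        assert lineage_substitutions(t) == (0.0, 0.0, 0)

    def test_all_distinct_is_ambiguous(self):
        t = trio_of("AAA", "AAG", "AAC")
        nd, sd, amb = lineage_substitutions(t)
        assert (nd, sd, amb) == (0.0, 0.0, 1)

    def test_focal_equals_outgroup_is_ambiguous(self):
        t = trio_of("AAA", "AAG", "AAA")
        assert lineage_substitutions(t)[2] == 1

    def test_outgroup_branch_change_ignored(self):
        t = trio_of("AAA", "AAA", "AAG")
        assert lineage_substitutions(t) == (0.0, 0.0, 0)

    def test_sister_outgroup_swap_invariance_when_equal(self):
        t1 = trio_of("TTCAAA", "TTTAAA", "TTTAAA")
        t2 = trio_of("TTCAAA", "TTTAAA", "TTTAAA")
        assert lineage_substitutions(t1) == lineage_substitutions(t2)


class TestEstimateAndFilter:
    def test_zero_counts_zero_rates(self):
        seq = "ATGAAACCCGGGTTTGATCATGAAACCCGGGTTTGATCA".replace(" ", "")
        seq = ("ATGAAACCCGGGTTTGATCAT" * 6)[:126]
        t = trio_of(seq, seq, seq)
        rec = estimate_rates(t)
        assert rec.dn == 0.0 and rec.ds == 0.0 and math.isnan(rec.omega)

    def test_jukes_cantor_hand_case(self):
        rec = RateRecord("g", n_sites=240.0, s_sites=60.0, nd=2.0, sd=6.0)
        pn, ps = 2 / 240, 6 / 60
        dn_expect = -0.75 * math.log(1 - 4 * pn / 3)
        ds_expect = -0.75 * math.log(1 - 4 * ps / 3)
        t = None
        # evaluate through the estimator path by constructing the same ratios
        from sbevol.rates import _jukes_cantor

        assert _jukes_cantor(pn) == pytest.approx(dn_expect)
        assert _jukes_cantor(ps) == pytest.approx(ds_expect)

    def test_saturation_domain_boundary(self):
        from sbevol.rates import _jukes_cantor

        assert math.isnan(_jukes_cantor(0.75))

    def test_filter_gates(self):
        def rec(**kw):
            base = dict(n_sites=300.0, s_sites=100.0, nd=30.0, sd=10.0, dn=0.1, ds=0.1)
            base.update(kw)
            return RateRecord("g", **base)

        retained, excluded = filter_rates(
            [
                rec(ds=2.5),                       # saturated dS
                rec(dn=0.001),                     # N*dN = 0.3 < 1
                rec(ds=0.005),                     # S*dS = 0.5 < 1
                RateRecord("short", flags={SHORT_ALIGNMENT}),
                rec(),                             # passes every gate
            ]
        )
        assert len(retained) == 1 and len(excluded) == 4

    def test_short_alignment_excluded_after_processing(self):
        t = trio_of("ATGAAA", "ATGAAA", "ATGAAA")
        rec = process_trio(t)
        retained, excluded = filter_rates([rec])
        assert retained == [] and excluded == [rec]


class TestParameterRecovery:
    def test_purifying_omega_recovered(self):
        """Simulated omega = 0.2 trios: pooled and median estimates near truth."""
        from sbevol.simulate import SimConfig, assign_labels, gen_trio_alignments

        cfg = SimConfig(
            seed=31, n_genes=100, frac_female_biased=0, frac_male_biased=0,
            omega_by_class={"unbiased": 0.2}, n_codons=300,
        )
        aligns, _ = gen_trio_alignments(cfg, assign_labels(cfg))
        recs = [process_trio(a) for a in aligns]
        retained, _ = filter_rates(recs)
        pooled = (sum(r.nd for r in retained) / sum(r.n_sites for r in retained)) / (
            sum(r.sd for r in retained) / sum(r.s_sites for r in retained)
        )
        assert pooled == pytest.approx(0.2, rel=0.25)

    def test_plain_ng_sites_underestimate_with_transition_bias(self):
        """kappa-blind site counting must undercount omega on kappa = 2 data;
        the kappa-aware count removes that bias (the reason it is the default)."""
        from sbevol.simulate import SimConfig, assign_labels, gen_trio_alignments

        cfg = SimConfig(
            seed=32, n_genes=120, frac_female_biased=0, frac_male_biased=0,
            omega_by_class={"unbiased": 1.0}, n_codons=300,
        )
        aligns, _ = gen_trio_alignments(cfg, assign_labels(cfg))

        def pooled(kappa):
            recs = [process_trio(a, kappa=kappa, mask=False) for a in aligns]
            retained, _ = filter_rates(recs)
            return (sum(r.nd for r in retained) / sum(r.n_sites for r in retained)) / (
                sum(r.sd for r in retained) / sum(r.s_sites for r in retained)
            )

        assert pooled(2.0) == pytest.approx(1.0, abs=0.12)
        assert pooled(1.0) < pooled(2.0) * 0.92
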