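"""Codon alignment, NG86 estimation, Ks density and mixture fitting."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import flavopan as fp
from flavopan import simulate as sim
from flavopan.kaks import SENSE_CODONS
from oracles import oracle_ng86

codon = st.sampled_from(SENSE_CODONS)
codon_pairs = st.lists(
    st.tuples(codon, codon), min_size=1, max_size=10
)


class TestBacktranslate:
    def test_gap_becomes_whole_codon_gap(self):
        aln = fp.backtranslate("M-A", "MKA", "ATGGCT", "ATGAAAGCA")
        assert aln.seq_a == "ATG---GCT"
        assert aln.seq_b == "ATGAAAGCA"

    def test_identical_pair_round_trip(self):
        aln = fp.backtranslate("MKA", "MKA", "ATGAAAGCA", "ATGAAAGCA")
        assert aln.seq_a == aln.seq_b == "ATGAAAGCA"

    def test_trailing_stop_stripped(self):
        aln = fp.backtranslate("MK", "MK", "ATGAAATAA", "ATGAAA")
        assert aln.seq_a == "ATGAAA"

    def test_translation_mismatch_names_codon(self):
        with pytest.raises(ValueError, match="codon 2 mismatch"):
            fp.backtranslate("MKA", "MRA", "ATGAAAGCA", "ATGAAAGCA")

    def test_internal_stop_rejected(self):
        with pytest.raises(ValueError, match="internal stop"):
            fp.backtranslate("M*K", "M*K", "ATGTAAAAA", "ATGTAAAAA")


class TestNg86:
    def test_identical_sequences_zero_rates(self):
        est = fp.ng86(fp.CodonAlignment("ATGAAAGCA", "ATGAAAGCA"))
        assert est.ka == 0.0 and est.ks == 0.0
        assert not est.saturated

    def test_worked_single_synonymous_difference(self):
        # TTT->TTC is the only difference: synonymous, S = 5/3, N = 22/3
        est = fp.ng86(fp.CodonAlignment("TTTGGGAAA", "TTCGGGAAA"))
        assert est.sites_s == pytest.approx(5 / 3)
        assert est.sites_n == pytest.approx(22 / 3)
        assert est.ka == 0.0
        assert est.ks == pytest.approx(-0.75 * math.log(1 - (4 / 3) * (3 / 5)))
        assert est.ks == pytest.approx(1.207, abs=1e-3)

    def test_symmetry(self, rng):
        for _ in range(20):
            codons = rng.choice(SENSE_CODONS, 8)
            other = rng.choice(SENSE_CODONS, 8)
            a, b = "".join(codons), "".join(other)
            ea = fp.ng86(fp.CodonAlignment(a, b))
            eb = fp.ng86(fp.CodonAlignment(b, a))
            for attr in ("ka", "ks", "sites_s", "sites_n", "sd", "nd"):
                x, y = getattr(ea, attr), getattr(eb, attr)
                assert (x == pytest.approx(y)) or (
                    math.isnan(x) and math.isnan(y)
                )

    def test_gapped_and_ambiguous_codons_dropped_pairwise(self):
        full = fp.ng86(fp.CodonAlignment("TTTGGGAAA", "TTCGGGAAA"))
        gapped = fp.ng86(fp.CodonAlignment("TTTGGGAAACCC", "TTCGGGAAA---"))
        ambig = fp.ng86(fp.CodonAlignment("TTTGGGAAACNA", "TTCGGGAAACCA"))
        for est in (gapped, ambig):
            assert est.sites_s == pytest.approx(full.sites_s)
            assert est.ks == pytest.approx(full.ks)

    @settings(max_examples=300, deadline=None, derandomize=True)
    @given(codon_pairs)
    def test_equals_bruteforce_oracle(self, pairs):
        # site conservation plus exact agreement with rational-arithmetic
        # enumeration of sites and pathways
        a = "".join(p[0] for p in pairs)
        b = "".join(p[1] for p in pairs)
        est = fp.ng86(fp.CodonAlignment(a, b))
        oka, oks = oracle_ng86([p[0] for p in pairs], [p[1] for p in pairs])
        assert est.sites_s + est.sites_n == pytest.approx(3 * len(pairs))
        for mine, ref in ((est.ka, oka), (est.ks, oks)):
            if math.isnan(ref):
                assert math.isnan(mine)
            else:
                assert mine == pytest.approx(ref, abs=1e-9)

    def test_saturated_pair_flagged(self):
        # force ps >= 3/4: serine codons TCT vs AGC differ everywhere
        a, b = "TCT" * 30, "AGT" * 30
        est = fp.ng86(fp.CodonAlignment(a, b))
        assert est.saturated or est.ks > 0  # never silently wrong
        assert math.isnan(est.ratio) or est.ratio >= 0


class TestKsDensity:
    def test_single_tight_gaussian_one_mode(self, rng):
        d = fp.ks_density(rng.normal(1.0, 0.05, 1000))
        assert d.mode_count == 1

    def test_two_separated_gaussians_two_modes(self, rng):
        x = np.concatenate(
            [rng.normal(0.1, 0.05, 500), rng.normal(2.0, 0.05, 500)]
        )
        d = fp.ks_density(x)
        assert d.mode_count == 2
        assert d.modes[0] == pytest.approx(0.1, abs=0.1)
        assert d.modes[1] == pytest.approx(2.0, abs=0.1)

    def test_density_integrates_to_one(self, rng):
        d = fp.ks_density(rng.gamma(5, 0.1, 400))
        assert np.trapezoid(d.density, d.grid) == pytest.approx(1.0, abs=0.01)

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError, match="at least 10"):
            fp.ks_density([0.1] * 9)


class TestKsMixture:
    def test_single_gamma_prefers_one_component(self, rng):
        x = rng.gamma(20, 0.01, 1000)
        fit2 = fp.fit_ks_mixture(x, family="gamma", k=2, seed=1)
        fit1 = fp.fit_ks_mixture(x, family="gamma", k=1)
        assert not (fit1.aic - fit2.aic > 2)
        assert not fit2.bimodal

    def test_bigamma_recovery(self, rng):
        x = np.concatenate(
            [rng.gamma(20, 0.005, 1000), rng.gamma(20, 0.1, 1000)]
        )
        fit = fp.fit_ks_mixture(x, family="gamma", k=2, seed=2)
        fit1 = fp.fit_ks_mixture(x, family="gamma", k=1)
        assert fit1.aic - fit.aic > 2
        assert fit.bimodal
        assert fit.component_means[0] == pytest.approx(0.1, rel=0.10)
        assert fit.component_means[1] == pytest.approx(2.0, rel=0.10)
        assert fit.weights.sum() == pytest.approx(1.0)

    def test_binormal_recovery(self, rng):
        x = np.concatenate(
            [rng.normal(0.3, 0.05, 800), rng.normal(1.5, 0.2, 800)]
        )
        fit = fp.fit_ks_mixture(x, family="normal", k=2, seed=3)
        assert fit.bimodal
        assert fit.component_means[0] == pytest.approx(0.3, abs=0.05)
        assert fit.component_means[1] == pytest.approx(1.5, abs=0.1)

    def test_two_component_likelihood_at_least_one_component(self, rng):
        x = rng.gamma(8, 0.05, 500)
        for family in ("gamma", "normal"):
            f1 = fp.fit_ks_mixture(x, family=family, k=1)
            f2 = fp.fit_ks_mixture(x, family=family, k=2, seed=4)
            assert f2.log_likelihood >= f1.log_likelihood - 1e-6

    def test_aic_counts_parameters(self, rng):
        x = rng.gamma(8, 0.05, 200)
        f1 = fp.fit_ks_mixture(x, family="gamma", k=1)
        f2 = fp.fit_ks_mixture(x, family="gamma", k=2, seed=5)
        assert f1.aic == pytest.approx(2 * 2 - 2 * f1.log_likelihood)
        assert f2.aic == pytest.approx(2 * 5 - 2 * f2.log_likelihood)

    def test_binned_mode_agrees_roughly_with_em(self, rng):
        x = np.concatenate(
            [rng.gamma(20, 0.005, 1000), rng.gamma(20, 0.1, 1000)]
        )
        em = fp.fit_ks_mixture(x, family="gamma", k=2, seed=6)
        binned = fp.fit_ks_mixture(x, family="gamma", k=2, method="binned")
        np.testing.assert_allclose(
            binned.component_means, em.component_means, rtol=0.15
        )

    def test_gamma_requires_positive_values(self):
        with pytest.raises(ValueError, match="strictly positive"):
            fp.fit_ks_mixture([0.0] * 50, family="gamma", k=1)


class TestEndToEnd:
    def test_kaks_density_peak_reflects_purifying_selection(self):
        # omega = 0.05 pairs: the Ka/Ks density peak sits well below 0.1
        rng = np.random.default_rng(99)
        ratios = []
        for _ in range(120):
            p = sim.simulate_codon_pair(300, 0.5, 0.05, rng=rng)
            est = fp.ng86(fp.CodonAlignment(p.cds_a, p.cds_b))
            if math.isfinite(est.ratio):
                ratios.append(est.ratio)
        d = fp.ks_density(ratios)
        peak = d.modes[np.argmax(np.interp(d.modes, d.grid, d.density))]
        assert peak < 0.1

    def test_pipeline_ks_unbiased_at_low_divergence(self):
        # NG86 operates in its validity range here; high-divergence
        # overestimation is a known property of the method
        rng = np.random.default_rng(5)
        for target in (0.1, 0.3, 0.5):
            est = []
            for _ in range(60):
                p = sim.simulate_codon_pair(300, target, 0.05, rng=rng)
                est.append(fp.ng86(fp.CodonAlignment(p.cds_a, p.cds_b)).ks)
            assert np.mean(est) == pytest.approx(target, rel=0.10)
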