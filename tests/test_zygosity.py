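"""Classifier: category probabilities, the sequential-binomial chain and its
multinomial identity, priors, per-site decisions and long/short fusion."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import multinomial

from hetcorr.align import PileupColumn, RankedCounts, rank_alleles
from hetcorr import zygosity as zy


def ranked(counts: dict) -> RankedCounts:
    return rank_alleles(PileupColumn(site=0, counts=counts))


def multinomial_log_pmf(counts, probs) -> float:
    """Independent oracle: multinomial pmf of the ranked vector padded to 5."""
    padded = list(counts) + [0] * (5 - len(counts))
    return float(multinomial.logpmf(padded, n=sum(counts), p=probs))


def partitions(n, k, cap=None):
    """Non-increasing positive integer vectors of length <= k summing to n."""
    cap = cap or n
    if n == 0:
        yield ()
        return
    if k == 0:
        return
    for first in range(min(cap, n), 0, -1):
        for rest in partitions(n - first, k - 1, first):
            yield (first,) + rest


class TestCategoryProbs:
    @pytest.mark.parametrize(
        "hyp,e,expected",
        [
            (zy.HOMOZYGOUS, 0.2, (0.8, 0.05, 0.05, 0.05, 0.05)),
            (zy.HETEROZYGOUS, 0.15, (0.425, 0.425, 0.05, 0.05, 0.05)),
            (zy.HOMOZYGOUS, 1e-9, (1.0, 0.0, 0.0, 0.0, 0.0)),
        ],
    )
    def test_values(self, hyp, e, expected):
        probs = zy.category_probs(hyp, e)
        assert probs == pytest.approx(expected, abs=1e-6)
        assert probs.sum() == pytest.approx(1.0)

    def test_rank_inversion_guard(self):
        with pytest.raises(ValueError, match="rank"):
            zy.category_probs(zy.HOMOZYGOUS, 0.6)


class TestSequentialLikelihood:
    @pytest.mark.parametrize(
        "counts,hyp,e,expected",
        [
            # 10 * 0.8^3 * 0.05^2
            ({"A": 3, "C": 2}, zy.HOMOZYGOUS, 0.2, 0.0128),
            # 10 * 0.4^3 * 0.4^2 (verified against the multinomial pmf)
            ({"A": 3, "C": 2}, zy.HETEROZYGOUS, 0.2, 0.1024),
        ],
    )
    def test_frozen_values(self, counts, hyp, e, expected):
        ll = zy.sequential_log_likelihood(ranked(counts), zy.category_probs(hyp, e))
        assert np.exp(ll) == pytest.approx(expected, rel=1e-9)

    def test_single_allele_reduces_to_power_of_pi1(self):
        for hyp in (zy.HOMOZYGOUS, zy.HETEROZYGOUS):
            probs = zy.category_probs(hyp, 0.15)
            ll = zy.sequential_log_likelihood(ranked({"T": 7}), probs)
            assert ll == pytest.approx(7 * np.log(probs[0]))

    def test_empty_column_rejected(self):
        with pytest.raises(ValueError):
            zy.sequential_log_likelihood(ranked({}), zy.category_probs(zy.HOMOZYGOUS, 0.1))

    def test_chain_equals_multinomial_exhaustively(self):
        """The conditional-binomial chain is exactly the multinomial pmf for
        every ranked count vector up to depth 12 and both hypotheses."""
        alleles = "ACGTN"
        for e in (0.05, 0.15, 0.2):
            for hyp in (zy.HOMOZYGOUS, zy.HETEROZYGOUS):
                probs = zy.category_probs(hyp, e)
                for n in range(1, 13):
                    for part in partitions(n, 5):
                        rc = ranked({alleles[i]: c for i, c in enumerate(part)})
                        chain = zy.sequential_log_likelihood(rc, probs)
                        oracle = multinomial_log_pmf(part, probs)
                        assert chain == pytest.approx(oracle, abs=1e-9), (e, hyp, part)


class TestPriorSpec:
    def test_point_prior_sums_to_one(self):
        ps = zy.PriorSpec(kind="point", p_homo=0.5)
        assert zy.prior_value(ps, zy.HOMOZYGOUS) == 0.5
        assert zy.prior_value(ps, zy.HETEROZYGOUS) == 0.5

    def test_beta_mean(self):
        ps = zy.PriorSpec(kind="beta", a=300, b=300, beta_mode="mean")
        assert zy.prior_value(ps, zy.HOMOZYGOUS) == pytest.approx(0.5)

    def test_beta_sample_reproducible(self):
        ps = zy.PriorSpec(kind="beta", a=5, b=5, beta_mode="sample", seed=42)
        x = zy.prior_value(ps, zy.HOMOZYGOUS)
        assert 0.0 < x < 1.0
        assert zy.prior_value(ps, zy.HOMOZYGOUS) == x

    def test_beta_density_renormalized(self):
        ps = zy.PriorSpec(kind="beta", a=5, b=3, beta_mode="density_at_guess",
                          theta_guess=0.6)
        p = zy.prior_value(ps, zy.HOMOZYGOUS)
        q = zy.prior_value(ps, zy.HETEROZYGOUS)
        assert p + q == pytest.approx(1.0)
        assert p > 0.5  # Beta(5,3) density is larger at 0.6 than at 0.4

    def test_invalid_shapes_rejected(self):
        with pytest.raises(ValueError):
            zy.PriorSpec(kind="beta", a=-1, b=2)


class TestClassifySite:
    def test_single_allele_is_homozygous(self):
        call = zy.classify_site(ranked({"A": 7}), 0.15, zy.PriorSpec())
        assert call.hypothesis == zy.HOMOZYGOUS
        assert call.top_alleles == ["A"]
        assert np.isfinite(call.log_posterior_homo)

    def test_balanced_column_is_heterozygous(self):
        call = zy.classify_site(ranked({"A": 3, "C": 2}), 0.2, zy.PriorSpec())
        assert call.hypothesis == zy.HETEROZYGOUS
        assert call.top_alleles == ["A", "C"]
        # unnormalized posteriors from the multinomial oracle, prior 0.5 each
        assert np.exp(call.log_posterior_het) == pytest.approx(0.0512, rel=1e-9)
        assert np.exp(call.log_posterior_homo) == pytest.approx(0.0064, rel=1e-9)

    def test_skewed_column_is_homozygous(self):
        # brute force over both hypotheses: homo 10*0.85^9*0.0375 = 0.0867
        # beats het 10*0.425^10 = 0.00183
        call = zy.classify_site(ranked({"A": 9, "C": 1}), 0.15, zy.PriorSpec())
        assert call.hypothesis == zy.HOMOZYGOUS

    def test_vectorised_path_agrees_with_scalar(self, rng):
        counts = rng.integers(0, 8, size=(5, 40)).astype(np.int32)
        ps = zy.PriorSpec(p_homo=0.3)
        dec, lp_h, lp_x = zy.classify_columns(counts, 0.15, ps)
        for j in range(counts.shape[1]):
            col = {a: int(c) for a, c in zip("ACGTN", counts[:, j])}
            rc = ranked(col)
            if rc.depth == 0:
                assert dec[j] == zy.NO_CALL
                continue
            call = zy.classify_site(rc, 0.15, ps)
            expect = zy.HOMO_CODE if call.hypothesis == zy.HOMOZYGOUS else zy.HET_CODE
            assert dec[j] == expect
            assert lp_h[j] == pytest.approx(call.log_posterior_homo, abs=1e-8)
            assert lp_x[j] == pytest.approx(call.log_posterior_het, abs=1e-8)

    @given(n2=st.integers(0, 6))
    @settings(deadline=None, max_examples=7)
    def test_posterior_ratio_monotone_in_minor_count(self, n2):
        """Moving counts from (n,0) toward an even split can only favor
        heterozygosity."""
        n = 12
        ps = zy.PriorSpec()

        def log_ratio(k):
            rc = ranked({"A": n - k, "C": k} if k else {"A": n})
            call = zy.classify_site(rc, 0.15, ps)
            return call.log_posterior_het - call.log_posterior_homo

        if n2 < 6:
            assert log_ratio(n2 + 1) >= log_ratio(n2)

    def test_decision_monotone_in_prior(self):
        rc = ranked({"A": 4, "C": 2})
        decisions = []
        for p_homo in (0.01, 0.3, 0.5, 0.7, 0.99):
            call = zy.classify_site(rc, 0.15, zy.PriorSpec(p_homo=p_homo))
            decisions.append(call.hypothesis)
        # once homozygous, stays homozygous as the prior grows
        first_homo = decisions.index(zy.HOMOZYGOUS) if zy.HOMOZYGOUS in decisions else len(decisions)
        assert all(d == zy.HOMOZYGOUS for d in decisions[first_homo:])
        # an overwhelming homozygosity prior forces the call
        assert decisions[-1] == zy.HOMOZYGOUS


class TestCombineCalls:
    def c(self, hyp):
        return zy.ZygosityCall(hyp, -1.0, -2.0, ["A"], site=0)

    @pytest.mark.parametrize(
        "long_h,short_h,expected",
        [
            (zy.HETEROZYGOUS, zy.HETEROZYGOUS, zy.HETEROZYGOUS),
            (zy.HOMOZYGOUS, zy.HOMOZYGOUS, zy.HOMOZYGOUS),
            (zy.HETEROZYGOUS, zy.HOMOZYGOUS, zy.HOMOZYGOUS),
            (zy.HOMOZYGOUS, zy.HETEROZYGOUS, zy.HOMOZYGOUS),
        ],
    )
    def test_fusion_table(self, long_h, short_h, expected):
        assert zy.combine_calls(self.c(long_h), self.c(short_h)) == expected

    def test_single_source_passes_through(self):
        assert zy.combine_calls(None, self.c(zy.HETEROZYGOUS)) == zy.HETEROZYGOUS
        assert zy.combine_calls(self.c(zy.HOMOZYGOUS), None) == zy.HOMOZYGOUS
        with pytest.raises(ValueError):
            zy.combine_calls(None, None)

    def test_vectorised_fusion(self):
        dl = np.array([0, 0, 1, 2, 1, 2], dtype=np.int8)
        ds = np.array([0, 2, 0, 2, 2, 1], dtype=np.int8)
        fused = zy.combine_decisions(dl, ds)
        assert fused.tolist() == [0, 2, 1, 2, 1, 1]
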