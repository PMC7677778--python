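"""Bayesian homozygous-vs-heterozygous classification of pileup columns.

At an anchor site the observed alleles are ranked by count.  Under the
homozygous hypothesis the top rank is the true allele and everything else
is sequencing error; under the heterozygous hypothesis the top two ranks
are the two alleles.  With per-base error rate ``e`` the per-allele
category probabilities are

* homozygous:    (1-e, e/4, e/4, e/4, e/4)
* heterozygous:  ((1-e)/2, (1-e)/2, e/3, e/3, e/3)

The likelihood of the ranked count vector is a chain of binomial terms,
each conditioned on the preceding ranks: rank q contributes
``Binom(|X_q|; n = D_q, pi_q)`` with ``D_q`` the total count at ranks
q..5 and ``pi_q = p_q / sum_{j>=q} p_j``.  The chain's product equals the
multinomial pmf of the count vector under the category probabilities — an
identity the test suite checks exhaustively.  Multiplying by the prior
P(c) gives the unnormalized posterior; the larger posterior wins, ties
going conservatively to homozygous.  A site showing a single allele is
judged homozygous outright.

Requires ``e < 0.6``: beyond that an error allele under the heterozygous
hypothesis (e/3) would be more probable than a true allele ((1-e)/2) and
the rank ordering of the model would invert.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.special import betaln, gammaln
from scipy.stats import binom

from hetcorr.align import ALLELES, RankedCounts

HOMOZYGOUS = "homozygous"
HETEROZYGOUS = "heterozygous"

# integer decision codes used by the vectorised pipeline path
NO_CALL, HOMO_CODE, HET_CODE = 0, 1, 2


@dataclass
class PriorSpec:
    """Prior on zygosity: a point probability or a Beta distribution.

    ``point``: P(homozygous) = ``p_homo``.  ``beta``: P(homozygous) derives
    from Beta(a, b) according to ``beta_mode`` — the Beta mean ``a/(a+b)``
    (default), a seeded draw (``sample``), or the density at ``theta_guess``
    renormalized against the density at the complementary guess
    (``density_at_guess``).
    """

    kind: str = "point"
    p_homo: float = 0.5
    a: float = 300.0
    b: float = 300.0
    theta_guess: float = 0.5
    beta_mode: str = "mean"
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.kind not in ("point", "beta"):
            raise ValueError(f"unknown prior kind {self.kind!r}")
        if self.kind == "point" and not 0.0 < self.p_homo < 1.0:
            raise ValueError("point prior p_homo must lie strictly in (0,1)")
        if self.kind == "beta" and (self.a <= 0 or self.b <= 0):
            raise ValueError("Beta shape parameters must be positive")

    def probability_homo(self) -> float:
        if self.kind == "point":
            return self.p_homo
        if self.beta_mode == "mean":
            return self.a / (self.a + self.b)
        if self.beta_mode == "sample":
            rng = np.random.default_rng(self.seed)
            return float(rng.beta(self.a, self.b))
        if self.beta_mode == "density_at_guess":
            w_homo = _beta_pdf(self.theta_guess, self.a, self.b)
            w_het = _beta_pdf(1.0 - self.theta_guess, self.a, self.b)
            if w_homo + w_het == 0.0:
                raise ValueError("Beta density vanishes at both guesses")
            return w_homo / (w_homo + w_het)
        raise ValueError(f"unknown beta_mode {self.beta_mode!r}")


def _beta_pdf(x: float, a: float, b: float) -> float:
    if not 0.0 < x < 1.0:
        return 0.0
    return float(np.exp((a - 1) * np.log(x) + (b - 1) * np.log1p(-x) - betaln(a, b)))


def prior_value(ps: PriorSpec, c: str) -> float:
    """P(c) under the prior specification; the pair sums to one."""
    p = ps.probability_homo()
    return p if c == HOMOZYGOUS else 1.0 - p


def category_probs(c: str, e: float, d: Optional[int] = None) -> np.ndarray:
    """Per-rank allele probabilities p_1..p_5 under hypothesis ``c``.

    ``d`` is accepted for interface symmetry with the ranked counts but the
    probabilities do not depend on it: unobserved ranks simply carry zero
    counts in the likelihood.
    """
    if not 0.0 < e < 0.6:
        raise ValueError(
            "error rate must lie in (0, 0.6): at e >= 0.6 an error allele "
            "becomes as likely as a heterozygous allele ((1-e)/2 <= e/3) and "
            "the rank order of the model inverts"
        )
    if c == HOMOZYGOUS:
        return np.array([1.0 - e, e / 4, e / 4, e / 4, e / 4])
    if c == HETEROZYGOUS:
        h = (1.0 - e) / 2
        return np.array([h, h, e / 3, e / 3, e / 3])
    raise ValueError(f"unknown hypothesis {c!r}")


def sequential_log_likelihood(rc: RankedCounts, probs: Sequence[float]) -> float:
    """Log-likelihood of ranked counts as a chain of conditional binomials.

    Rank q contributes Binom(|X_q|; D_q, p_q / sum_{j>=q} p_j) with D_q the
    suffix count total; zero-count ranks are skipped.  Equals the log
    multinomial pmf of the count vector under ``probs``.
    """
    if rc.depth < 1:
        raise ValueError("likelihood undefined for an empty column")
    p = np.asarray(probs, dtype=float)
    counts = rc.counts
    suffix = rc.suffix_totals()
    total = 0.0
    for q, (c_q, n_q) in enumerate(zip(counts, suffix)):
        tail = float(p[q:].sum())
        pi_q = p[q] / tail
        total += float(binom.logpmf(c_q, n_q, pi_q))
    return total


@dataclass
class ZygosityCall:
    """Decision at one site with both unnormalized log posteriors."""

    hypothesis: str
    log_posterior_homo: float
    log_posterior_het: float
    top_alleles: list[str]
    site: int = -1
    source: str = "long"


def classify_site(
    rc: RankedCounts,
    e: float,
    ps: PriorSpec,
    site: int = -1,
    source: str = "long",
) -> ZygosityCall:
    """Classify one ranked column; single-allele columns are homozygous.

    Ties between the two posteriors resolve to homozygous (conservative:
    heterozygosity is never fabricated on equal evidence).
    """
    if rc.depth < 1:
        raise ValueError("cannot classify an uncovered site")
    ll_homo = sequential_log_likelihood(rc, category_probs(HOMOZYGOUS, e))
    ll_het = sequential_log_likelihood(rc, category_probs(HETEROZYGOUS, e))
    lp_homo = ll_homo + float(np.log(prior_value(ps, HOMOZYGOUS)))
    lp_het = ll_het + float(np.log(prior_value(ps, HETEROZYGOUS)))
    if rc.d == 1 or lp_homo >= lp_het:
        hyp = HOMOZYGOUS
        top = [rc.alleles[0][0]]
    else:
        hyp = HETEROZYGOUS
        top = [rc.alleles[0][0], rc.alleles[1][0]]
    return ZygosityCall(hyp, lp_homo, lp_het, top, site=site, source=source)


def combine_calls(
    call_long: Optional[ZygosityCall], call_short: Optional[ZygosityCall]
) -> str:
    """Fuse the long-read and short-read judgments at a shared anchor.

    Agreement adopts the short-read judgment (short reads are the more
    accurate technology); disagreement adopts the homozygous side.  With
    one judgment absent, the present one stands.
    """
    if call_long is None and call_short is None:
        raise ValueError("no judgment available at this site")
    if call_long is None:
        return call_short.hypothesis
    if call_short is None:
        return call_long.hypothesis
    if call_long.hypothesis == call_short.hypothesis:
        return call_short.hypothesis
    return HOMOZYGOUS


# ---------------------------------------------------------------------------
# vectorised pipeline path


def classify_columns(
    counts: np.ndarray, e: float, ps: PriorSpec
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised :func:`classify_site` over a (5, L) pileup count matrix.

    Returns (decision codes, log-posterior homo, log-posterior het); the
    decision is 0 for uncovered columns, 1 homozygous, 2 heterozygous.
    Uses the multinomial form of the likelihood, which equals the
    per-column sequential-binomial chain.
    """
    sorted_counts = -np.sort(-counts, axis=0).astype(np.float64)
    n = sorted_counts.sum(axis=0)
    d = (sorted_counts > 0).sum(axis=0)
    with np.errstate(invalid="ignore"):
        log_mult = gammaln(n + 1) - gammaln(sorted_counts + 1).sum(axis=0)
    p_homo = category_probs(HOMOZYGOUS, e)
    p_het = category_probs(HETEROZYGOUS, e)
    ll_homo = log_mult + sorted_counts.T @ np.log(p_homo)
    ll_het = log_mult + sorted_counts.T @ np.log(p_het)
    prior_h = ps.probability_homo()
    lp_homo = ll_homo + np.log(prior_h)
    lp_het = ll_het + np.log1p(-prior_h)
    decision = np.where(
        n == 0,
        NO_CALL,
        np.where((d <= 1) | (lp_homo >= lp_het), HOMO_CODE, HET_CODE),
    ).astype(np.int8)
    return decision, lp_homo, lp_het


def combine_decisions(dec_long: np.ndarray, dec_short: np.ndarray) -> np.ndarray:
    """Vectorised :func:`combine_calls` on decision-code arrays."""
    both = (dec_long != NO_CALL) & (dec_short != NO_CALL)
    fused = np.where(dec_long == NO_CALL, dec_short, dec_long)
    agree = dec_long == dec_short
    fused = np.where(both, np.where(agree, dec_short, HOMO_CODE), fused)
    return fused.astype(np.int8)
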