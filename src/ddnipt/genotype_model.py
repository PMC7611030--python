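"""Joint Bayesian inference of fetal genotype and fetal fraction from ddPCR.

The mother is heterozygous for a pathogenic variant; the question is whether
the fetus inherited it.  Cell-free DNA in maternal plasma is a mixture of
maternal DNA (fraction ``1 - f``) and fetal DNA (fraction ``f``).  If the
fetus is heterozygous too, the reference:variant allele balance in plasma is
50:50 regardless of ``f``; if the fetus is homozygous reference, the
reference allele is over-represented at ``0.5 + f/2`` (55:45 at ``f = 0.10``).
Because ``f`` is small, the two hypotheses are separated by only a few
percent of allelic balance, so genotype and fetal fraction are inferred
jointly from the droplet counts of both assays.

Data-generating model (four fluorescence channels per sample):

    k_ch ~ Binomial(n_ch, 1 - exp(-lam_ch * v))        per channel
    lam_ref = C_var * theta,  lam_var = C_var * (1 - theta)
    theta   = expected_ref_fraction(G, f, bias)
    lam_pat = C_ff * f / 2,   lam_mat = C_ff * (1 - f / 2)

with latent fetal genotype ``G`` (Bernoulli prior), fetal fraction ``f``
(uniform prior) and per-assay total concentrations ``C_var``, ``C_ff``
(vague uniform priors).  A copy-number mode replaces the allelic pair with a
target/reference-locus pair for maternal deletions.

Two posterior engines are provided: a deterministic nested-quadrature
integration (:func:`quadrature_posterior`) and a Metropolis-within-Gibbs
MCMC sampler (:func:`run_mcmc`) matching the published chain schedule; they
must agree, and the test suite holds them to it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping

import numba as nb
import numpy as np
from scipy.special import expit, gammaln, logsumexp

from .droplet_stats import (
    DEFAULT_DROPLET_VOLUME_UL,
    ChannelCounts,
    estimate_concentration,
)
from .fetal_fraction import FFAssayObservation


class FetalGenotype(str, Enum):
    """Fetal genotype at the maternal variant.

    In the copy-number (deletion) assay mode ``HET`` denotes a fetus
    heterozygous for the maternal deletion.
    """

    HOM_REF = "HOM_REF"
    HET = "HET"


class AssayMode(str, Enum):
    ALLELIC = "ALLELIC"
    CNV_DELETION = "CNV_DELETION"


@dataclass(frozen=True)
class SampleObservation:
    """Merged droplet counts for one plasma sample: variant assay + ff assay.

    In ``ALLELIC`` mode ``variant_a``/``variant_b`` are the reference/variant
    allele channels; in ``CNV_DELETION`` mode they are the target (deleted
    region) and a two-copy reference-locus channel.
    """

    sample_id: str
    variant_a: ChannelCounts
    variant_b: ChannelCounts
    ff_assay: FFAssayObservation
    pregnancy_id: str = ""
    assay_id: str = ""
    gestation_weeks: float | None = None
    droplet_volume: float = DEFAULT_DROPLET_VOLUME_UL
    assay_mode: AssayMode = AssayMode.ALLELIC


@dataclass(frozen=True)
class ModelConfig:
    """Priors and fixed quantities of the model.

    f_prior: Uniform(f_low, f_high), default Uniform(0, 0.5).  A point prior
    (f_low == f_high) pins the fetal fraction.
    conc priors: Uniform(0, conc_max) per assay, with conc_max set to
    ``conc_max_mult`` times the point-estimate concentration from the data.
    genotype_prior: prior probability the fetus is homozygous reference
    (0.5 under Mendelian segregation from a heterozygous mother).
    bias: multiplicative reference-allele detection bias of the variant
    assay, as measured on heterozygous gDNA controls (1.0 = unbiased).
    """

    f_low: float = 0.0
    f_high: float = 0.5
    genotype_prior: float = 0.5
    conc_max_mult: float = 5.0
    bias: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 < self.genotype_prior < 1.0:
            raise ValueError("genotype_prior must lie in (0, 1)")
        if not (0.0 <= self.f_low <= self.f_high <= 1.0):
            raise ValueError("need 0 <= f_low <= f_high <= 1")
        if self.bias <= 0:
            raise ValueError("bias must be > 0")
        if self.conc_max_mult <= 1:
            raise ValueError("conc_max_mult must be > 1")


@dataclass(frozen=True)
class MCMCConfig:
    """Chain schedule; defaults reproduce the published analysis settings."""

    chains: int = 4
    adapt_iters: int = 1000
    burn_in: int = 10000
    sampling_iters: int = 50000
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("chains", "adapt_iters", "burn_in", "sampling_iters"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")


@dataclass(frozen=True)
class PosteriorSummary:
    p_hom: float
    f_post: dict
    conc_var_post: dict
    conc_ff_post: dict
    diagnostics: dict
    total_samples: int
    engine: str
    converged: bool = True
    draws: dict | None = None


# ---------------------------------------------------------------------------
# deterministic maps


def expected_ref_fraction(genotype: FetalGenotype, f, bias: float = 1.0):
    """Expected reference-allele fraction in cfDNA.

    A heterozygous fetus keeps the balance at 0.5 for any fetal fraction; a
    homozygous-reference fetus shifts it to ``0.5 + f/2``.  ``bias`` maps the
    true fraction to the assay's apparent fraction via the odds
    ``bias*theta0 : (1-theta0)``.
    """
    f = np.asarray(f, dtype=float)
    if np.any((f < 0) | (f > 1)):
        raise ValueError("fetal fraction must lie in [0, 1]")
    if bias <= 0:
        raise ValueError("bias must be > 0")
    theta0 = 0.5 + f / 2 if genotype is FetalGenotype.HOM_REF else 0.5 + 0.0 * f
    theta = bias * theta0 / (bias * theta0 + (1.0 - theta0))
    return float(theta) if theta.ndim == 0 else theta


def expected_cnv_ratio(genotype: FetalGenotype, f):
    """Expected target : reference-locus concentration ratio, deletion mode.

    The mother carries one intact copy of the target region (the other is
    deleted) and two copies of the reference locus.  Copy counting per
    genome equivalent: a homozygous-reference fetus contributes 2 target
    copies, giving ``((1-f)*1 + f*2) / 2 = 0.5 + f/2``; a fetus inheriting
    the deletion contributes 1, leaving the ratio at 0.5.
    """
    f = np.asarray(f, dtype=float)
    if np.any((f < 0) | (f > 1)):
        raise ValueError("fetal fraction must lie in [0, 1]")
    r = 0.5 + f / 2 if genotype is FetalGenotype.HOM_REF else 0.5 + 0.0 * f
    return float(r) if r.ndim == 0 else r


# ---------------------------------------------------------------------------
# likelihood


class _Channel:
    """Precomputed constants for one channel's binomial log-mass."""

    __slots__ = ("k", "n", "logcoef")

    def __init__(self, c: ChannelCounts):
        self.k = c.k
        self.n = c.n
        self.logcoef = float(
            gammaln(c.n + 1) - gammaln(c.k + 1) - gammaln(c.n - c.k + 1)
        )

    def logpmf(self, lam, v: float):
        """log Binomial(k | n, 1 - exp(-lam*v)); lam may be an ndarray."""
        t = np.asarray(lam, dtype=float) * v
        with np.errstate(divide="ignore", invalid="ignore"):
            log_p = np.where(t > 0, np.log(-np.expm1(-np.maximum(t, 1e-300))), -np.inf)
        if self.k == 0:
            return self.logcoef - self.n * t
        return self.logcoef + self.k * log_p - (self.n - self.k) * t


class _SampleLik:
    """Vectorised log-likelihood terms for one sample."""

    def __init__(self, obs: SampleObservation, cfg: ModelConfig):
        self.v = obs.droplet_volume
        self.mode = obs.assay_mode
        self.bias = cfg.bias
        self.ch_a = _Channel(obs.variant_a)
        self.ch_b = _Channel(obs.variant_b)
        self.ch_mat = _Channel(obs.ff_assay.maternal_channel)
        self.ch_pat = _Channel(obs.ff_assay.paternal_channel)

    def ll_variant(self, genotype: FetalGenotype, f, conc):
        """Variant-assay log-likelihood at fetal fraction f, concentration conc.

        In ALLELIC mode ``conc`` is the total assay concentration; in
        CNV_DELETION mode it is the reference-locus concentration and the
        target channel sits at ``conc * expected_cnv_ratio``.
        """
        if self.mode is AssayMode.ALLELIC:
            theta = expected_ref_fraction(genotype, f, self.bias)
            lam_a = conc * theta
            lam_b = conc * (1.0 - theta)
        else:
            r = expected_cnv_ratio(genotype, f)
            lam_a = conc * r
            lam_b = conc * np.ones_like(np.asarray(f, dtype=float))
        return self.ch_a.logpmf(lam_a, self.v) + self.ch_b.logpmf(lam_b, self.v)

    def ll_ff(self, f, conc):
        """Fetal-fraction-assay log-likelihood (genotype independent)."""
        f = np.asarray(f, dtype=float)
        return self.ch_pat.logpmf(conc * f / 2.0, self.v) + self.ch_mat.logpmf(
            conc * (1.0 - f / 2.0), self.v
        )


def log_likelihood(
    obs: SampleObservation,
    genotype: FetalGenotype,
    f: float,
    conc_var: float,
    conc_ff: float,
    cfg: ModelConfig | None = None,
) -> float:
    """Joint log-likelihood of the four droplet-count channels.

    Parameters outside the prior support return ``-inf`` (rejection
    semantics) rather than raising.
    """
    cfg = cfg or ModelConfig()
    if not (cfg.f_low <= f <= cfg.f_high) or conc_var < 0 or conc_ff < 0:
        return -math.inf
    lik = _SampleLik(obs, cfg)
    return float(
        lik.ll_variant(genotype, f, conc_var) + lik.ll_ff(f, conc_ff)
    )


# ---------------------------------------------------------------------------
# concentration scales


def _conc_hats(obs: SampleObservation) -> tuple[float, float]:
    """Point-estimate assay concentrations used to scale the vague priors."""
    v = obs.droplet_volume
    la = estimate_concentration(obs.variant_a, v)
    lb = estimate_concentration(obs.variant_b, v)
    if obs.assay_mode is AssayMode.ALLELIC:
        c_var = la.lam + lb.lam
    else:  # free parameter is the reference-locus concentration
        c_var = lb.lam
    mat = estimate_concentration(obs.ff_assay.maternal_channel, v)
    pat = estimate_concentration(obs.ff_assay.paternal_channel, v)
    c_ff = mat.lam + pat.lam
    # floor at ~1 expected copy over the pooled droplets so the prior never
    # collapses to zero width on an empty channel
    floor_var = 1.0 / (max(obs.variant_a.n, 1) * v)
    floor_ff = 1.0 / (max(obs.ff_assay.maternal_channel.n, 1) * v)
    return max(c_var, floor_var), max(c_ff, floor_ff)


# ---------------------------------------------------------------------------
# quadrature engine


def _grid_quantiles(x: np.ndarray, w: np.ndarray, qs) -> list[float]:
    """Quantiles of a density known on a grid, by linear CDF interpolation."""
    w = np.maximum(w, 0)
    total = w.sum()
    if total == 0:
        return [float(x[0])] * len(qs)
    cdf = np.cumsum(w) / total
    return [float(np.interp(q, cdf, x)) for q in qs]


def quadrature_posterior(
    obs: SampleObservation,
    cfg: ModelConfig | None = None,
    n_f: int = 257,
    n_conc: int = 129,
) -> PosteriorSummary:
    """Deterministic posterior by nested 1-D quadrature.

    Given ``f`` and the genotype, the two assays factorise and each
    concentration integrates out in one dimension; the marginal likelihood
    of each genotype is then a 1-D integral over ``f``.  All sums are in
    log space (trapezoid weights + logsumexp), so valid inputs cannot
    underflow to a zero marginal.
    """
    cfg = cfg or ModelConfig()
    if n_f < 64 or n_conc < 64:
        raise ValueError("need at least 64 grid points per dimension")
    lik = _SampleLik(obs, cfg)
    c_var_hat, c_ff_hat = _conc_hats(obs)
    cv_max = cfg.conc_max_mult * c_var_hat
    cf_max = cfg.conc_max_mult * c_ff_hat

    if cfg.f_low == cfg.f_high:
        f_grid = np.array([cfg.f_low])
        log_wf = np.array([0.0])
    else:
        f_grid = np.linspace(cfg.f_low, cfg.f_high, n_f)
        wf = np.full(n_f, f_grid[1] - f_grid[0])
        wf[[0, -1]] /= 2
        log_wf = np.log(wf)

    def conc_grid(cmax: float) -> tuple[np.ndarray, np.ndarray]:
        g = np.linspace(cmax / n_conc, cmax, n_conc)
        w = np.full(n_conc, g[1] - g[0]) if n_conc > 1 else np.array([cmax])
        log_w = np.log(w)
        return g, log_w

    cv_grid, log_wcv = conc_grid(cv_max)
    cf_grid, log_wcf = conc_grid(cf_max)

    F = f_grid[:, None]
    # variant assay: (genotype, f, conc)
    llv = np.stack(
        [lik.ll_variant(g, F, cv_grid[None, :]) for g in FetalGenotype], axis=0
    )
    llf = lik.ll_ff(F, cf_grid[None, :])  # (f, conc)

    # integrate out each concentration in 1-D (uniform prior constants cancel
    # in the genotype posterior and do not affect quantiles)
    m_var = logsumexp(llv + log_wcv[None, None, :], axis=2)  # (genotype, f)
    m_ff = logsumexp(llf + log_wcf[None, :], axis=1)  # (f,)

    log_prior_g = np.log(
        [cfg.genotype_prior, 1.0 - cfg.genotype_prior]
    )  # order: HOM_REF, HET
    lp = log_prior_g[:, None] + m_var + m_ff[None, :] + log_wf[None, :]
    logz = logsumexp(lp, axis=1)  # per-genotype marginal
    if not np.isfinite(logsumexp(logz)):
        raise FloatingPointError("zero marginal likelihood: invalid inputs")
    p_hom = float(np.exp(logz[0] - logsumexp(logz)))

    # fetal-fraction posterior: genotype-mixture density on the f grid
    w_f = np.exp(logsumexp(lp, axis=0) - logsumexp(logz))
    f_med, f_lo, f_hi = _grid_quantiles(f_grid, w_f, [0.5, 0.025, 0.975])

    # per-assay concentration marginals; f points with -inf evidence carry no
    # posterior mass, so their (-inf) - (-inf) terms are masked to -inf
    post_f_norm = lp - logsumexp(logz)
    with np.errstate(invalid="ignore"):
        term_v = (
            post_f_norm[:, :, None]
            + (llv + log_wcv[None, None, :])
            - m_var[:, :, None]
        )
        term_f = (
            logsumexp(post_f_norm, axis=0)[:, None]
            + (llf + log_wcf[None, :])
            - m_ff[:, None]
        )
    term_v = np.where(np.isnan(term_v), -np.inf, term_v)
    term_f = np.where(np.isnan(term_f), -np.inf, term_f)
    lw_cv = logsumexp(term_v, axis=(0, 1))
    cv_w = np.exp(lw_cv - logsumexp(lw_cv))
    lw_cf = logsumexp(term_f, axis=0)
    cf_w = np.exp(lw_cf - logsumexp(lw_cf))
    cvq = _grid_quantiles(cv_grid, cv_w, [0.5, 0.025, 0.975])
    cfq = _grid_quantiles(cf_grid, cf_w, [0.5, 0.025, 0.975])

    return PosteriorSummary(
        p_hom=p_hom,
        f_post={"median": f_med, "q2.5": f_lo, "q97.5": f_hi},
        conc_var_post={"median": cvq[0], "q2.5": cvq[1], "q97.5": cvq[2]},
        conc_ff_post={"median": cfq[0], "q2.5": cfq[1], "q97.5": cfq[2]},
        diagnostics={},
        total_samples=0,
        engine="quadrature",
        converged=True,
    )


# ---------------------------------------------------------------------------
# MCMC engine
#
# The sweep is a handful of scalar operations per chain, repeated for 61 000
# iterations under the default schedule, so the chain loop is compiled with
# numba; chains are run sequentially inside the kernel, each on its own
# deterministic seed.


def _logit(p):
    return np.log(p) - np.log1p(-p)


@nb.njit(inline="always")
def _softplus(x: float) -> float:
    return x if x > 35.0 else math.log1p(math.exp(x))


@nb.njit(inline="always")
def _sigmoid_nb(x: float) -> float:
    if x >= 0:
        return 1.0 / (1.0 + math.exp(-x))
    e = math.exp(x)
    return e / (1.0 + e)


@nb.njit(inline="always")
def _lj_nb(x: float) -> float:
    """log-Jacobian of the sigmoid transform (flat prior on the value)."""
    return -_softplus(x) - _softplus(-x)


@nb.njit(inline="always")
def _lp_nb(k: int, n: int, logcoef: float, lam: float, v: float) -> float:
    """log Binomial(k | n, 1 - exp(-lam*v)) for scalar lam."""
    t = lam * v
    if t <= 0.0:
        return logcoef if k == 0 else -np.inf
    if k == 0:
        return logcoef - n * t
    p = -math.expm1(-t)
    return logcoef + k * math.log(p) - (n - k) * t


@nb.njit(inline="always")
def _llvar_nb(g_hom, f, conc, cnv, bias, ka, na, lca, kb, nbb, lcb, v):
    if cnv:
        r = 0.5 + f / 2.0 if g_hom else 0.5
        lam_a = conc * r
        lam_b = conc
    else:
        t0 = 0.5 + f / 2.0 if g_hom else 0.5
        th = bias * t0 / (bias * t0 + 1.0 - t0)
        lam_a = conc * th
        lam_b = conc * (1.0 - th)
    return _lp_nb(ka, na, lca, lam_a, v) + _lp_nb(kb, nbb, lcb, lam_b, v)


@nb.njit(inline="always")
def _llff_nb(f, conc, kp, npp, lcp, km, nm, lcm, v):
    return _lp_nb(kp, npp, lcp, conc * f / 2.0, v) + _lp_nb(
        km, nm, lcm, conc * (1.0 - f / 2.0), v
    )


@nb.njit
def _mwg_chains(
    ka, na, lca, kb, nbb, lcb, kp, npp, lcp, km, nm, lcm,
    v, bias, cnv, f_low, f_high, sample_f, cv_max, cf_max,
    log_odds_prior, p_g_prior, xcv0, xcf0,
    adapt, burn, n_keep, seeds,
):
    nch = seeds.shape[0]
    f_d = np.empty((nch, n_keep))
    cv_d = np.empty((nch, n_keep))
    cf_d = np.empty((nch, n_keep))
    g_d = np.empty((nch, n_keep), dtype=np.uint8)
    total = adapt + burn + n_keep
    for c in range(nch):
        np.random.seed(seeds[c])
        xf = 0.5 * np.random.normal()
        xcv = xcv0 + 0.3 * np.random.normal()
        xcf = xcf0 + 0.3 * np.random.normal()
        g = np.random.random() < p_g_prior
        f = f_low + (f_high - f_low) * _sigmoid_nb(xf) if sample_f else f_low
        cv = cv_max * _sigmoid_nb(xcv)
        cf = cf_max * _sigmoid_nb(xcf)
        llv = _llvar_nb(g, f, cv, cnv, bias, ka, na, lca, kb, nbb, lcb, v)
        llf = _llff_nb(f, cf, kp, npp, lcp, km, nm, lcm, v)
        s_f = 0.5
        s_cv = 0.5
        s_cf = 0.5
        for it in range(total):
            eta = (1.0 + it) ** -0.6
            adapting = it < adapt

            if sample_f:
                prop = xf + s_f * np.random.normal()
                fp = f_low + (f_high - f_low) * _sigmoid_nb(prop)
                llv_p = _llvar_nb(g, fp, cv, cnv, bias, ka, na, lca, kb, nbb, lcb, v)
                llf_p = _llff_nb(fp, cf, kp, npp, lcp, km, nm, lcm, v)
                la = llv_p + llf_p + _lj_nb(prop) - (llv + llf + _lj_nb(xf))
                acc = math.log(np.random.random()) < la
                if acc:
                    xf, f, llv, llf = prop, fp, llv_p, llf_p
                if adapting:
                    s_f *= math.exp(((1.0 if acc else 0.0) - 0.44) * eta)

            prop = xcv + s_cv * np.random.normal()
            cvp = cv_max * _sigmoid_nb(prop)
            llv_p = _llvar_nb(g, f, cvp, cnv, bias, ka, na, lca, kb, nbb, lcb, v)
            la = llv_p + _lj_nb(prop) - (llv + _lj_nb(xcv))
            acc = math.log(np.random.random()) < la
            if acc:
                xcv, cv, llv = prop, cvp, llv_p
            if adapting:
                s_cv *= math.exp(((1.0 if acc else 0.0) - 0.44) * eta)

            prop = xcf + s_cf * np.random.normal()
            cfp = cf_max * _sigmoid_nb(prop)
            llf_p = _llff_nb(f, cfp, kp, npp, lcp, km, nm, lcm, v)
            la = llf_p + _lj_nb(prop) - (llf + _lj_nb(xcf))
            acc = math.log(np.random.random()) < la
            if acc:
                xcf, cf, llf = prop, cfp, llf_p
            if adapting:
                s_cf *= math.exp(((1.0 if acc else 0.0) - 0.44) * eta)

            # exact Gibbs draw of the genotype from its full conditional
            ll_hom = _llvar_nb(True, f, cv, cnv, bias, ka, na, lca, kb, nbb, lcb, v)
            ll_het = _llvar_nb(False, f, cv, cnv, bias, ka, na, lca, kb, nbb, lcb, v)
            pg = _sigmoid_nb(log_odds_prior + ll_hom - ll_het)
            g = np.random.random() < pg
            llv = ll_hom if g else ll_het

            kept = it - adapt - burn
            if kept >= 0:
                f_d[c, kept] = f
                cv_d[c, kept] = cv
                cf_d[c, kept] = cf
                g_d[c, kept] = 1 if g else 0
    return f_d, cv_d, cf_d, g_d


def run_mcmc(
    obs: SampleObservation,
    cfg: ModelConfig | None = None,
    mcmc: MCMCConfig | None = None,
    return_draws: bool = False,
) -> PosteriorSummary:
    """Metropolis-within-Gibbs posterior sampler.

    Gaussian random-walk proposals on logit-transformed fetal fraction and
    concentrations (step sizes adapted to ~44% acceptance during the
    adaptation phase only), with an exact Gibbs draw of the binary fetal
    genotype from its full conditional each sweep.  All chains are advanced
    in lockstep as vectorised numpy operations.  Reproducible given
    ``mcmc.seed``; flagged (not rejected) when any split-R-hat exceeds 1.05.
    """
    cfg = cfg or ModelConfig()
    mcmc = mcmc or MCMCConfig()
    lik = _SampleLik(obs, cfg)
    c_var_hat, c_ff_hat = _conc_hats(obs)
    cv_max = cfg.conc_max_mult * c_var_hat
    cf_max = cfg.conc_max_mult * c_ff_hat
    point_f = cfg.f_low == cfg.f_high
    # one integer seed fans out to one deterministic stream per chain
    seeds = (
        np.random.SeedSequence(mcmc.seed).generate_state(mcmc.chains) % (2**31)
    ).astype(np.int64)
    log_odds_prior = math.log(cfg.genotype_prior) - math.log1p(-cfg.genotype_prior)
    xcv0 = float(_logit(np.clip(c_var_hat / cv_max, 1e-6, 1 - 1e-6)))
    xcf0 = float(_logit(np.clip(c_ff_hat / cf_max, 1e-6, 1 - 1e-6)))

    f_draws, cv_draws, cf_draws, g_draws = _mwg_chains(
        lik.ch_a.k, lik.ch_a.n, lik.ch_a.logcoef,
        lik.ch_b.k, lik.ch_b.n, lik.ch_b.logcoef,
        lik.ch_pat.k, lik.ch_pat.n, lik.ch_pat.logcoef,
        lik.ch_mat.k, lik.ch_mat.n, lik.ch_mat.logcoef,
        lik.v, cfg.bias, obs.assay_mode is AssayMode.CNV_DELETION,
        cfg.f_low, cfg.f_high, not point_f, cv_max, cf_max,
        log_odds_prior, cfg.genotype_prior, xcv0, xcf0,
        mcmc.adapt_iters, mcmc.burn_in, mcmc.sampling_iters, seeds,
    )
    g_draws = g_draws.astype(bool)
    nch, n_keep = mcmc.chains, mcmc.sampling_iters

    draws = {"f": f_draws, "conc_var": cv_draws, "conc_ff": cf_draws}
    diag = convergence_diagnostics(
        {k: v for k, v in draws.items() if not (k == "f" and point_f)}
    )
    converged = all(
        (d["rhat"] is not None and d["rhat"] <= 1.05) for d in diag.values()
    )

    def q(a):
        med, lo, hi = np.quantile(a, [0.5, 0.025, 0.975])
        return {"median": float(med), "q2.5": float(lo), "q97.5": float(hi)}

    return PosteriorSummary(
        p_hom=float(g_draws.mean()),
        f_post=q(f_draws),
        conc_var_post=q(cv_draws),
        conc_ff_post=q(cf_draws),
        diagnostics=diag,
        total_samples=nch * n_keep,
        engine="mcmc",
        converged=bool(converged),
        draws={**draws, "genotype_hom": g_draws} if return_draws else None,
    )


def calibrate_bias(
    ref: ChannelCounts,
    var: ChannelCounts,
    droplet_volume: float = DEFAULT_DROPLET_VOLUME_UL,
) -> float:
    """Reference-allele bias factor from a heterozygous gDNA control.

    A maternal genomic-DNA control is exactly heterozygous, so the two
    channels should report equal concentrations; their ratio
    ``lam_ref / lam_var`` is the assay's apparent reference bias (1.0 when
    unbiased) and is applied inside :func:`expected_ref_fraction`.
    """
    if ref.k == 0 or var.k == 0:
        raise ValueError("cannot calibrate bias from a channel with zero positives")
    lam_ref = estimate_concentration(ref, droplet_volume).lam
    lam_var = estimate_concentration(var, droplet_volume).lam
    return lam_ref / lam_var


def convergence_diagnostics(
    draws: Mapping[str, np.ndarray], min_draws: int = 100
) -> dict:
    """Split-R-hat and bulk ESS per parameter from (chain, draw) arrays.

    Returns ``{param: {"rhat": float|None, "ess": float|None, "flag": bool}}``;
    ``flag`` marks non-convergence (R-hat > 1.05) or degenerate (zero
    variance) chains, for which R-hat is undefined and reported as ``None``.
    """
    import arviz as az

    out: dict[str, dict] = {}
    for name, arr in draws.items():
        arr = np.asarray(arr, dtype=float)
        if arr.ndim != 2 or arr.shape[0] < 2:
            raise ValueError(f"{name}: need >= 2 chains of draws, shape (chains, n)")
        if arr.shape[1] < min_draws:
            raise ValueError(f"{name}: need >= {min_draws} draws per chain")
        if np.allclose(arr.var(axis=1), 0):
            out[name] = {"rhat": None, "ess": None, "flag": True}
            continue
        rhat = float(az.rhat(az.convert_to_dataset(arr))["x"])
        ess = float(az.ess(az.convert_to_dataset(arr))["x"])
        out[name] = {
            "rhat": rhat,
            "ess": ess,
            "flag": bool(not np.isfinite(rhat) or rhat > 1.05),
        }
    return out
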