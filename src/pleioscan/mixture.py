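"""Causal Gaussian-mixture models of polygenic architecture and overlap.

The univariate model is a point-normal architecture observed through GWAS
noise: each variant is causal with probability pi, causal effects are
Normal(0, sigma_beta2) on the standardized-genotype scale, and the z-score
of a variant is Normal(0, sigma0^2) if null or Normal(0, sigma0^2 +
n*sigma_beta2) if causal (sigma0 absorbs residual inflation). Derived
estimands: observed-scale SNP heritability h2 = M*pi*sigma_beta2,
polygenicity (number of causal variants explaining 90% of h2) and
discoverability (sigma_beta2, the causal-effect variance).

The bivariate model assigns each variant to one of four components — null,
trait-1-only, trait-2-only, shared — with effect correlation rho12 inside
the shared component and residual z correlation rho0 (sample overlap) in
every component. Derived: overlap fractions pi12/(pi1+pi12) and
pi12/(pi2+pi12), the shared-component genetic correlation rho12, and the
fraction of shared causal variants with concordant effect signs, 1/2 +
arcsin(rho12)/pi.

Likelihoods are exact finite Gaussian mixtures (no quadrature). An optional
LD extension for the univariate model mixes over the number c of tagged
causal variants, c ~ Binomial(round(l_j), pi) for LD score l_j, with
variance sigma0^2 + c*n*sigma_beta2*mean_w2. Fitting is multi-start
Nelder-Mead on unconstrained transforms (logit pi, log variances, atanh
correlations); model-fit support is assessed by AIC against constrained
alternatives (infinitesimal pi=1; zero- and maximum-overlap).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit
from scipy import optimize, stats
from scipy.special import expit, logit, logsumexp

__all__ = [
    "UnivariateParams",
    "BivariateParams",
    "MixtureFit",
    "univariate_loglik",
    "bivariate_loglik",
    "fit_univariate",
    "fit_bivariate",
    "polygenicity90",
    "concordance_from_rho",
    "concordance_posterior",
    "aic_compare",
    "subsample_average",
]

_LOG2PI = np.log(2.0 * np.pi)


class FitError(RuntimeError):
    """The optimizer failed to produce a finite maximum from any start."""


@dataclass(frozen=True)
class UnivariateParams:
    pi: float  # causal fraction
    sigma_beta2: float  # causal-effect variance (standardized-genotype scale)
    sigma0: float  # residual/inflation SD of null z-scores


@dataclass(frozen=True)
class BivariateParams:
    pi0: float
    pi1: float
    pi2: float
    pi12: float
    rho12: float  # effect correlation within the shared component
    rho0: float  # residual z correlation (sample overlap)
    sigma_beta2_1: float
    sigma_beta2_2: float
    sigma0_1: float
    sigma0_2: float


@dataclass
class MixtureFit:
    """A fitted mixture with its likelihood, AIC and derived estimands."""

    kind: str  # "univariate" | "bivariate"
    params: UnivariateParams | BivariateParams
    loglik: float
    n_params: int
    M: int
    derived: dict = field(default_factory=dict)
    n_starts_converged: int = 0

    @property
    def aic(self) -> float:
        return 2.0 * self.n_params - 2.0 * self.loglik


# ---------------------------------------------------------------------------
# univariate


def univariate_loglik(
    params: UnivariateParams,
    z: np.ndarray,
    n: float,
    ld_scores: np.ndarray | None = None,
    c_max: int = 20,
    mean_w2: float = 1.0,
) -> float:
    """Log-likelihood of z-scores under the point-normal architecture.

    No-LD mode: per variant, log[(1-pi) phi(z; sigma0^2) + pi phi(z;
    sigma0^2 + n sigma_beta2)]. LD mode (``ld_scores`` given): mixture over
    c = 0..c_max tagged causals with Binomial(round(l_j), pi) weights and
    variance sigma0^2 + c n sigma_beta2 mean_w2.
    """
    pi, s2b, s0 = params.pi, params.sigma_beta2, params.sigma0
    z = np.asarray(z, float)
    v0 = s0 * s0
    if ld_scores is None:
        if pi <= 0.0:
            ll = stats.norm.logpdf(z, scale=s0).sum()
        else:
            v1 = v0 + n * s2b
            a = np.log1p(-pi) - 0.5 * (_LOG2PI + np.log(v0) + z * z / v0) if pi < 1 else None
            b = np.log(pi) - 0.5 * (_LOG2PI + np.log(v1) + z * z / v1)
            ll = float(np.sum(b if a is None else np.logaddexp(a, b)))
    else:
        L = np.maximum(np.round(np.asarray(ld_scores, float)).astype(int), 1)
        ll = 0.0
        for Lu in np.unique(L):
            zz = z[L == Lu]
            cc = np.arange(0, min(c_max, Lu) + 1)
            w = stats.binom.pmf(cc, Lu, pi)
            w = np.clip(w, 1e-300, None)
            var = v0 + cc * n * s2b * mean_w2
            lp = (
                np.log(w)[None, :]
                - 0.5 * (_LOG2PI + np.log(var)[None, :] + zz[:, None] ** 2 / var[None, :])
            )
            ll += float(logsumexp(lp, axis=1).sum())
    if not np.isfinite(ll):
        raise FitError(f"non-finite log-likelihood at {params}")
    return ll


def _uni_derived(p: UnivariateParams, M: int) -> dict:
    return {
        "h2_obs": M * p.pi * p.sigma_beta2,
        "n_causal": p.pi * M,
        # fewer than one expected causal variant: polygenicity is undefined
        "polygenicity90": polygenicity90(p.pi, M) if p.pi * M >= 1 else np.nan,
        "discoverability": p.sigma_beta2,
    }


def fit_univariate(
    z: np.ndarray,
    n: float,
    ld_scores: np.ndarray | None = None,
    n_starts: int = 5,
    seed: int = 0,
    fix_pi: float | None = None,
    xtol: float = 1e-6,
    ftol: float = 1e-8,
    max_iter: int = 2000,
) -> MixtureFit:
    """Maximum-likelihood point-normal fit with multi-start Nelder-Mead.

    Parameters are optimized on (logit pi, log sigma_beta2, log sigma0).
    Starting points spread pi over decades, with sigma_beta2 matched to the
    observed excess z variance. ``fix_pi`` fits the constrained model with pi
    held fixed (pi=1 gives the infinitesimal baseline for AIC comparison).
    """
    z = np.asarray(z, float)
    M = len(z)
    rng = np.random.default_rng(seed)
    excess = max(float(np.mean(z * z)) - 1.0, 1e-4)

    def unpack(x: np.ndarray) -> UnivariateParams:
        if fix_pi is None:
            pi = float(expit(x[0]))
            s2b, s0 = np.exp(x[1]), np.exp(x[2])
        else:
            pi = fix_pi
            s2b, s0 = np.exp(x[0]), np.exp(x[1])
        return UnivariateParams(pi, float(s2b), float(s0))

    def nll(x: np.ndarray) -> float:
        try:
            return -univariate_loglik(unpack(x), z, n, ld_scores)
        except (FitError, FloatingPointError):
            return np.inf

    pis = [1e-4, 1e-3, 1e-2, 1e-1]
    starts = []
    for i in range(n_starts):
        pi0 = pis[i % len(pis)] * np.exp(rng.normal(0, 0.3))
        s2b0 = excess / (max(pi0, 1e-6) * n)
        if fix_pi is None:
            starts.append([logit(np.clip(pi0, 1e-8, 1 - 1e-8)), np.log(s2b0), 0.0])
        else:
            starts.append([np.log(excess / (max(fix_pi, 1e-6) * n)), 0.0])

    best = None
    converged = 0
    for x0 in starts:
        res = optimize.minimize(
            nll,
            np.asarray(x0, float),
            method="Nelder-Mead",
            options={"xatol": xtol, "fatol": ftol, "maxiter": max_iter},
        )
        if np.isfinite(res.fun):
            converged += 1
            if best is None or res.fun < best.fun:
                best = res
    if best is None:
        raise FitError("univariate fit failed from every start")
    p = unpack(best.x)
    k = 2 if fix_pi is not None else 3
    return MixtureFit(
        kind="univariate",
        params=p,
        loglik=-float(best.fun),
        n_params=k,
        M=M,
        derived=_uni_derived(p, M),
        n_starts_converged=converged,
    )


def polygenicity90(pi: float, M: int, sigma_beta2: float | None = None, fraction: float = 0.9):
    """Number of causal variants explaining ``fraction`` of SNP heritability.

    For iid Normal(0, sigma_beta2) effects the threshold t* on beta^2 above
    which the top effects carry a fraction f of total E[beta^2] satisfies
    P(chi2_3 > t*) = f (since E[X^2 1(X^2 > a)] = P(chi2_3 > a) for standard
    normal X); the expected count above threshold is then pi*M*P(chi2_1 >
    t*). Scale-free in sigma_beta2.
    """
    if pi * M < 1:
        raise ValueError("pi*M must be at least 1")
    t_star = stats.chi2.isf(fraction, df=3)
    return float(round(pi * M * stats.chi2.sf(t_star, df=1)))


def concordance_from_rho(rho12: float) -> float:
    """Fraction of shared causal pairs with agreeing effect signs.

    Orthant probability of a bivariate normal with correlation rho12:
    1/2 + arcsin(rho12)/pi.
    """
    if abs(rho12) > 1:
        raise ValueError("rho12 outside [-1,1]")
    return 0.5 + float(np.arcsin(rho12)) / np.pi


# ---------------------------------------------------------------------------
# bivariate


def _bvn_logpdf(z1, z2, v1, v2, cov) -> np.ndarray:
    det = v1 * v2 - cov * cov
    if det <= 0 or v1 <= 0 or v2 <= 0:
        return np.full(np.broadcast(z1, z2).shape, -np.inf)
    quad = (v2 * z1 * z1 - 2.0 * cov * z1 * z2 + v1 * z2 * z2) / det
    return -_LOG2PI - 0.5 * np.log(det) - 0.5 * quad


def _biv_components(p: BivariateParams, n1: float, n2: float):
    """(weight, v1, v2, cov) for the four mixture components."""
    s01sq, s02sq = p.sigma0_1**2, p.sigma0_2**2
    c0 = p.rho0 * p.sigma0_1 * p.sigma0_2
    g1, g2 = n1 * p.sigma_beta2_1, n2 * p.sigma_beta2_2
    c12 = p.rho12 * np.sqrt(g1 * g2)
    return [
        (p.pi0, s01sq, s02sq, c0),
        (p.pi1, s01sq + g1, s02sq, c0),
        (p.pi2, s01sq, s02sq + g2, c0),
        (p.pi12, s01sq + g1, s02sq + g2, c0 + c12),
    ]


def _biv_loglik_core(
    params: BivariateParams,
    z11: np.ndarray,
    z22: np.ndarray,
    z12: np.ndarray,
    n1: float,
    n2: float,
) -> float:
    """Mixture log-likelihood from precomputed products z1*z1, z2*z2, z1*z2."""
    comps = _biv_components(params, n1, n2)
    lps = []
    for w, v1, v2, cov in comps:
        if w <= 0.0:
            continue
        det = v1 * v2 - cov * cov
        if det <= 0.0 or v1 <= 0.0 or v2 <= 0.0:
            return -np.inf  # non-PD component covariance: reject parameters
        quad = (v2 * z11 - 2.0 * cov * z12 + v1 * z22) / det
        lps.append(np.log(w) - _LOG2PI - 0.5 * np.log(det) - 0.5 * quad)
    if not lps:
        return -np.inf
    L = np.column_stack(lps)
    mx = L.max(axis=1)
    return float((mx + np.log(np.exp(L - mx[:, None]).sum(axis=1))).sum())


@njit(cache=True, fastmath=True)
def _biv_nll_kernel(z11, z22, z12, logw, v1s, v2s, covs):  # pragma: no cover
    """Fused negative log-likelihood for the optimizer hot path.

    Same mixture as :func:`_biv_loglik_core`; components with weight 0 are
    passed with logw = -inf and skipped by the max trick.
    """
    nc = logw.shape[0]
    M = z11.shape[0]
    logdet = np.empty(nc)
    a = np.empty(nc)
    b = np.empty(nc)
    c = np.empty(nc)
    for k in range(nc):
        det = v1s[k] * v2s[k] - covs[k] * covs[k]
        if det <= 0.0 or v1s[k] <= 0.0 or v2s[k] <= 0.0:
            return np.inf
        logdet[k] = np.log(det)
        a[k] = v2s[k] / det
        b[k] = covs[k] / det
        c[k] = v1s[k] / det
    const = -1.8378770664093453  # log(2*pi)
    total = 0.0
    lp = np.empty(nc)
    for i in range(M):
        mx = -1e308
        for k in range(nc):
            q = a[k] * z11[i] - 2.0 * b[k] * z12[i] + c[k] * z22[i]
            v = logw[k] + const - 0.5 * logdet[k] - 0.5 * q
            lp[k] = v
            if v > mx:
                mx = v
        s = 0.0
        for k in range(nc):
            s += np.exp(lp[k] - mx)
        total += mx + np.log(s)
    return -total


def bivariate_loglik(
    params: BivariateParams,
    z1: np.ndarray,
    z2: np.ndarray,
    n1: float,
    n2: float,
    ld_scores: np.ndarray | None = None,
) -> float:
    """Log-likelihood of paired z-scores under the four-component model.

    Exact finite-mixture form; the LD-score extension is defined for the
    univariate model only, so ``ld_scores`` must be None here.
    """
    if ld_scores is not None:
        raise NotImplementedError("bivariate likelihood is no-LD only")
    z1 = np.asarray(z1, float)
    z2 = np.asarray(z2, float)
    return _biv_loglik_core(params, z1 * z1, z2 * z2, z1 * z2, n1, n2)


def _biv_derived(p: BivariateParams, M: int) -> dict:
    of1 = p.pi12 / (p.pi1 + p.pi12) if (p.pi1 + p.pi12) > 0 else np.nan
    of2 = p.pi12 / (p.pi2 + p.pi12) if (p.pi2 + p.pi12) > 0 else np.nan
    return {
        "n_shared": p.pi12 * M,
        "n_causal_1": (p.pi1 + p.pi12) * M,
        "n_causal_2": (p.pi2 + p.pi12) * M,
        "overlap_frac_1": of1,
        "overlap_frac_2": of2,
        "rg_shared": p.rho12,
        "concordance": concordance_from_rho(p.rho12),
        "h2_obs_1": M * (p.pi1 + p.pi12) * p.sigma_beta2_1,
        "h2_obs_2": M * (p.pi2 + p.pi12) * p.sigma_beta2_2,
    }


def fit_bivariate(
    z1: np.ndarray,
    z2: np.ndarray,
    n1: float,
    n2: float,
    uni1: MixtureFit,
    uni2: MixtureFit,
    n_starts: int = 3,
    seed: int = 0,
    constraint: str = "none",
    xtol: float = 1e-6,
    ftol: float = 1e-8,
    max_iter: int = 4000,
) -> MixtureFit:
    """Maximum-likelihood four-component fit anchored on univariate fits.

    The simplex (pi0, pi1, pi2, pi12) is parametrized by softmax logits,
    correlations by atanh, variances by log. Starting points place the shared
    fraction at several values between the univariate polygenicities.
    ``constraint`` fits the AIC baselines: "no_overlap" forces pi12 = 0 and
    "max_overlap" nests the sparser trait's causals inside the other's.
    """
    z1 = np.asarray(z1, float)
    z2 = np.asarray(z2, float)
    M = len(z1)
    if len(z2) != M:
        raise ValueError("z vectors not aligned")
    rng = np.random.default_rng(seed)
    p1u, p2u = uni1.params, uni2.params
    pi1_tot = min(max(p1u.pi, 1e-6), 0.5)
    pi2_tot = min(max(p2u.pi, 1e-6), 0.5)
    rho0_emp = float(np.corrcoef(z1, z2)[0, 1])
    rho0_emp = float(np.clip(rho0_emp, -0.9, 0.9))

    sparser_is_1 = pi1_tot <= pi2_tot

    def unpack(x: np.ndarray) -> BivariateParams:
        i = 0
        if constraint == "none":
            logits = np.array([0.0, x[0], x[1], x[2]])
            i = 3
        elif constraint == "no_overlap":
            logits = np.array([0.0, x[0], x[1], -np.inf])
            i = 2
        elif constraint == "max_overlap":
            # the sparser trait's causal set is fully shared: its "only"
            # component is empty
            if sparser_is_1:
                logits = np.array([0.0, -np.inf, x[0], x[1]])
            else:
                logits = np.array([0.0, x[0], -np.inf, x[1]])
            i = 2
        else:
            raise ValueError(f"unknown constraint {constraint!r}")
        w = np.exp(logits - logsumexp(logits))
        rho12 = float(np.tanh(x[i])) if constraint != "no_overlap" else 0.0
        if constraint != "no_overlap":
            i += 1
        rho0 = float(np.tanh(x[i]))
        s2b1, s2b2 = np.exp(x[i + 1]), np.exp(x[i + 2])
        s01, s02 = np.exp(x[i + 3]), np.exp(x[i + 4])
        return BivariateParams(
            pi0=float(w[0]),
            pi1=float(w[1]),
            pi2=float(w[2]),
            pi12=float(w[3]),
            rho12=rho12,
            rho0=rho0,
            sigma_beta2_1=float(s2b1),
            sigma_beta2_2=float(s2b2),
            sigma0_1=float(s01),
            sigma0_2=float(s02),
        )

    z11, z22, z12 = z1 * z1, z2 * z2, z1 * z2

    def nll(x: np.ndarray) -> float:
        p = unpack(x)
        comps = [c for c in _biv_components(p, n1, n2) if c[0] > 0.0]
        logw = np.array([np.log(w) for w, _, _, _ in comps])
        v1s = np.array([v1 for _, v1, _, _ in comps])
        v2s = np.array([v2 for _, _, v2, _ in comps])
        covs = np.array([cov for _, _, _, cov in comps])
        return float(_biv_nll_kernel(z11, z22, z12, logw, v1s, v2s, covs))

    def pack_start(frac_shared: float, rho12_0: float) -> np.ndarray:
        pi12 = frac_shared * min(pi1_tot, pi2_tot)
        pi1 = max(pi1_tot - pi12, 1e-8)
        pi2 = max(pi2_tot - pi12, 1e-8)
        pi0 = max(1.0 - pi1 - pi2 - pi12, 1e-8)
        logits = np.log([pi1, pi2, max(pi12, 1e-10)]) - np.log(pi0)
        x = []
        if constraint == "none":
            x += list(logits)
        elif constraint == "no_overlap":
            x += list(logits[:2])
        else:  # max_overlap
            x += [logits[1], logits[2]] if sparser_is_1 else [logits[0], logits[2]]
        if constraint != "no_overlap":
            x.append(np.arctanh(np.clip(rho12_0, -0.95, 0.95)))
        x.append(np.arctanh(rho0_emp))
        x += [
            np.log(max(p1u.sigma_beta2, 1e-12)),
            np.log(max(p2u.sigma_beta2, 1e-12)),
            np.log(max(p1u.sigma0, 1e-3)),
            np.log(max(p2u.sigma0, 1e-3)),
        ]
        return np.asarray(x, float)

    fracs = [0.5, 0.2, 0.8, 0.35, 0.65]
    rhos = [0.0, 0.5, -0.5, 0.25, -0.25]
    starts = [
        pack_start(fracs[i % len(fracs)], rhos[i % len(rhos)]) for i in range(n_starts)
    ]
    # jitter later starts slightly for basin diversity
    for i in range(1, len(starts)):
        starts[i] = starts[i] + rng.normal(0, 0.05, size=starts[i].shape)

    best = None
    converged = 0
    for x0 in starts:
        res = optimize.minimize(
            nll,
            x0,
            method="Nelder-Mead",
            options={"xatol": xtol, "fatol": ftol, "maxiter": max_iter},
        )
        if np.isfinite(res.fun):
            converged += 1
            if best is None or res.fun < best.fun:
                best = res
    if best is None:
        raise FitError("bivariate fit failed from every start")
    p = unpack(best.x)
    n_params = {"none": 9, "no_overlap": 7, "max_overlap": 8}[constraint]
    return MixtureFit(
        kind="bivariate",
        params=p,
        loglik=_biv_loglik_core(p, z11, z22, z12, n1, n2),
        n_params=n_params,
        M=M,
        derived=_biv_derived(p, M),
        n_starts_converged=converged,
    )


def concordance_posterior(
    params: BivariateParams,
    z1: np.ndarray,
    z2: np.ndarray,
    n1: float,
    n2: float,
    max_variants: int = 2000,
    seed: int = 0,
) -> float:
    """Posterior-counting cross-check of the orthant concordance formula.

    Weights each variant by its posterior probability of the shared
    component and, within it, by the posterior probability that the two true
    effects agree in sign (Monte-Carlo over the Gaussian effect posterior).
    """
    rng = np.random.default_rng(seed)
    z1 = np.asarray(z1, float)
    z2 = np.asarray(z2, float)
    comps = _biv_components(params, n1, n2)
    lps = np.stack(
        [
            (np.log(w) if w > 0 else -np.inf) + _bvn_logpdf(z1, z2, v1, v2, cov)
            for w, v1, v2, cov in comps
        ]
    )
    post12 = np.exp(lps[3] - logsumexp(lps, axis=0))
    idx = np.argsort(-post12)[:max_variants]

    # effect prior within the shared component (scaled to z units)
    g1, g2 = n1 * params.sigma_beta2_1, n2 * params.sigma_beta2_2
    c12 = params.rho12 * np.sqrt(g1 * g2)
    S = np.array([[g1, c12], [c12, g2]])
    R = np.array(
        [
            [params.sigma0_1**2, params.rho0 * params.sigma0_1 * params.sigma0_2],
            [params.rho0 * params.sigma0_1 * params.sigma0_2, params.sigma0_2**2],
        ]
    )
    A = S @ np.linalg.inv(S + R)  # posterior mean operator: E[b|z] = A z
    post_cov = S - A @ S
    Lp = np.linalg.cholesky(post_cov + 1e-12 * np.eye(2))
    draws = rng.standard_normal((400, 2)) @ Lp.T

    num = 0.0
    den = 0.0
    for i in idx:
        mu = A @ np.array([z1[i], z2[i]])
        b = draws + mu
        agree = float(np.mean(np.sign(b[:, 0]) == np.sign(b[:, 1])))
        num += post12[i] * agree
        den += post12[i]
    return num / den if den > 0 else np.nan


# ---------------------------------------------------------------------------
# model-fit assessment and subset averaging


def aic_compare(fit: MixtureFit, constrained: dict[str, MixtureFit]) -> dict[str, float]:
    """AIC(constrained) - AIC(full) per baseline; positive supports the fit.

    All fits must be on identical data (checked via the stored M).
    """
    out = {}
    for name, cf in constrained.items():
        if cf.M != fit.M:
            raise ValueError(f"constrained fit {name!r} used different data")
        out[name] = cf.aic - fit.aic
    return out


def subsample_average(
    fit_fn,
    n_variants: int,
    k_subsets: int = 20,
    subset_size: int | None = None,
    seed: int = 0,
):
    """Average a fit over random variant subsets (mean and SE per parameter).

    ``fit_fn(indices)`` must return a MixtureFit; ``subset_size`` defaults to
    all variants. Returns (mean_dict, se_dict, fits); scalars averaged are
    the flattened params plus derived quantities.
    """
    subset_size = subset_size or n_variants
    if subset_size > n_variants:
        raise ValueError("subset_size exceeds number of variants")
    rng = np.random.default_rng(seed)
    fits = []
    values: dict[str, list[float]] = {}
    for _ in range(k_subsets):
        if subset_size == n_variants:
            idx = np.arange(n_variants)
        else:
            idx = np.sort(rng.choice(n_variants, size=subset_size, replace=False))
        f = fit_fn(idx)
        fits.append(f)
        scalars = {**vars(f.params), **f.derived, "loglik": f.loglik, "aic": f.aic}
        for k, v in scalars.items():
            values.setdefault(k, []).append(float(v))
    mean = {k: float(np.mean(v)) for k, v in values.items()}
    se = {
        k: float(np.std(v, ddof=1) / np.sqrt(len(v))) if len(v) > 1 else 0.0
        for k, v in values.items()
    }
    return mean, se, fits
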