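"""Two-sample MR causal-effect estimators and heterogeneity diagnostics.

All estimators consume a :class:`~mrkit.sumstats.HarmonizedSet` (per-SNP
exposure effects γ_j with SE σ_γj and outcome log-odds effects Γ_j with
SE σ_Γj, oriented so γ_j ≥ 0) and return an :class:`MrEstimate` with the
causal log-OR per SD of exposure, its SE, normal-theory 95% CI and the
corresponding odds ratios.

Conventions shared across the suite:

* first-order (delta-method) Wald-ratio weights w_j = γ_j²/σ_Γj², i.e.
  exposure-side uncertainty is ignored in weighting;
* IVW and Egger standard errors use the fixed-effect /
  multiplicative-random-effect hybrid: the weighted-regression SE with
  the residual scale floored at 1;
* 95% intervals use the normal 1.959964 quantile, no small-sample
  corrections.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .sumstats import HarmonizedSet, LdMatrix

Z_95 = 1.959964


@dataclass
class MrEstimate:
    """One estimator's causal-effect result."""

    method: str
    beta: float
    se: float
    n_snps: int
    intercept: float | None = None
    intercept_se: float | None = None
    intercept_p: float | None = None
    q_stat: float | None = None
    q_df: int | None = None
    q_p: float | None = None

    @property
    def ci_low(self) -> float:
        return self.beta - Z_95 * self.se

    @property
    def ci_high(self) -> float:
        return self.beta + Z_95 * self.se

    @property
    def or_(self) -> float:
        return float(np.exp(self.beta))

    @property
    def or_low(self) -> float:
        return float(np.exp(self.ci_low))

    @property
    def or_high(self) -> float:
        return float(np.exp(self.ci_high))

    @property
    def pvalue(self) -> float:
        return float(2.0 * stats.norm.sf(abs(self.beta) / self.se))

    def as_dict(self) -> dict:
        return {
            "method": self.method, "n_snps": self.n_snps,
            "beta": self.beta, "se": self.se, "pvalue": self.pvalue,
            "ci_low": self.ci_low, "ci_high": self.ci_high,
            "or": self.or_, "or_low": self.or_low, "or_high": self.or_high,
            "egger_intercept": self.intercept,
            "egger_intercept_se": self.intercept_se,
            "egger_intercept_p": self.intercept_p,
            "q_stat": self.q_stat, "q_df": self.q_df, "q_p": self.q_p,
        }


def _arrays(h):
    if isinstance(h, HarmonizedSet):
        return h.arrays()
    return tuple(np.asarray(a, float) for a in h)


def wald_ratio(gamma: float, sigma_gamma: float, Gamma: float,
               sigma_Gamma: float, second_order: bool = False) -> MrEstimate:
    """Single-SNP causal estimate: outcome effect over exposure effect.

    The default SE is the first-order delta method σ_Γ/|γ| (exposure
    uncertainty ignored); ``second_order`` adds the exposure-side term
    Γ²σ_γ²/γ⁴ under the two-sample independence assumption.
    """
    if gamma == 0:
        raise ValueError("Wald ratio undefined for gamma = 0")
    beta = Gamma / gamma
    var = sigma_Gamma ** 2 / gamma ** 2
    if second_order:
        var += Gamma ** 2 * sigma_gamma ** 2 / gamma ** 4
    return MrEstimate("wald_ratio", float(beta), float(np.sqrt(var)), 1)


def _wls_origin(gamma, Gamma, weights):
    """Weighted least squares of Gamma on gamma through the origin.
    Returns (slope, fixed-effect SE, residual scale sigma_hat)."""
    sw = np.sum(weights * gamma * gamma)
    slope = np.sum(weights * gamma * Gamma) / sw
    se_fixed = sw ** -0.5
    J = len(gamma)
    if J > 1:
        rss = np.sum(weights * (Gamma - slope * gamma) ** 2)
        sigma_hat = np.sqrt(rss / (J - 1))
    else:
        sigma_hat = 1.0
    return slope, se_fixed, sigma_hat


def ivw(h, min_snps: int = 2) -> MrEstimate:
    """Inverse-variance weighted estimate.

    Weighted regression of Γ on γ through the origin with weights
    1/σ_Γ²; algebraically the inverse-variance weighted mean of the
    per-SNP Wald ratios under first-order weights.  With a single SNP
    this reduces to the Wald ratio.  The SE is the regression SE with
    the residual scale floored at 1 (fixed-effect floor, multiplicative
    over-dispersion allowed).
    """
    gamma, sg, Gamma, sG = _arrays(h)
    if len(gamma) == 0:
        raise ValueError("empty harmonized set")
    if np.all(gamma == 0):
        raise ValueError("all exposure effects are zero")
    if len(gamma) == 1:
        est = wald_ratio(gamma[0], sg[0], Gamma[0], sG[0])
        return MrEstimate("ivw", est.beta, est.se, 1)
    w = 1.0 / sG ** 2
    slope, se_fixed, sigma_hat = _wls_origin(gamma, Gamma, w)
    se = se_fixed * max(sigma_hat, 1.0)
    return MrEstimate("ivw", float(slope), float(se), len(gamma))


def mr_egger(h) -> MrEstimate:
    """MR-Egger: weighted regression of Γ on γ with a free intercept.

    The slope is the causal estimate; the intercept estimates the mean
    directional-pleiotropy effect and its two-sided normal test is
    reported.  Requires ≥ 3 SNPs and the γ ≥ 0 orientation convention.
    """
    gamma, sg, Gamma, sG = _arrays(h)
    J = len(gamma)
    if J < 3:
        raise ValueError("MR-Egger requires at least 3 SNPs")
    w = 1.0 / sG ** 2
    X = np.column_stack([np.ones(J), gamma])
    WX = X * w[:, None]
    xtwx = X.T @ WX
    coef = np.linalg.solve(xtwx, WX.T @ Gamma)
    resid = Gamma - X @ coef
    sigma_hat = np.sqrt(np.sum(w * resid ** 2) / (J - 2)) if J > 2 else 1.0
    cov_fixed = np.linalg.inv(xtwx)
    scale = max(sigma_hat, 1.0)
    se_int = float(np.sqrt(cov_fixed[0, 0]) * scale)
    se_slope = float(np.sqrt(cov_fixed[1, 1]) * scale)
    int_p = float(2.0 * stats.norm.sf(abs(coef[0]) / se_int))
    return MrEstimate("egger", float(coef[1]), se_slope, J,
                      intercept=float(coef[0]), intercept_se=se_int,
                      intercept_p=int_p)


def _ratios_weights(gamma, sG):
    """First-order Wald-ratio weights w_j = γ_j²/σ_Γj²."""
    return gamma ** 2 / sG ** 2


def _weighted_median(ratios, weights):
    order = np.argsort(ratios)
    b = ratios[order]
    w = weights[order]
    s = (np.cumsum(w) - 0.5 * w) / np.sum(w)
    return float(np.interp(0.5, s, b))


def _parametric_bootstrap(fn, gamma, sg, Gamma, sG, n_boot, seed):
    rng = np.random.default_rng(seed)
    est = np.empty(n_boot)
    for i in range(n_boot):
        g = rng.normal(gamma, sg)
        G = rng.normal(Gamma, sG)
        est[i] = fn(g, G)
    return float(np.std(est, ddof=1))


def weighted_median(h, n_boot: int = 1000, seed: int | None = None) -> MrEstimate:
    """Weighted median of the per-SNP Wald ratios.

    Ratios are sorted and the estimate is the linear interpolation of
    the ratio at standardized mid-cumulative weight 0.5; it is consistent
    when instruments carrying at least half the weight are valid.  The
    SE is the standard deviation over ``n_boot`` parametric-bootstrap
    resamples of (γ_j, Γ_j); ``seed`` is mandatory for reproducibility.
    """
    if seed is None:
        raise ValueError("seed is required for the bootstrap SE")
    if n_boot < 100:
        import warnings
        warnings.warn("n_boot < 100 gives an unstable bootstrap SE")
    gamma, sg, Gamma, sG = _arrays(h)
    if len(gamma) < 3:
        raise ValueError("weighted median requires at least 3 SNPs")
    w = _ratios_weights(gamma, sG)
    beta = _weighted_median(Gamma / gamma, w)
    se = _parametric_bootstrap(
        lambda g, G: _weighted_median(G / g, _ratios_weights(g, sG)),
        gamma, sg, Gamma, sG, n_boot, seed)
    return MrEstimate("weighted_median", beta, se, len(gamma))


def _mode_bandwidth(ratios, phi):
    J = len(ratios)
    s = np.std(ratios, ddof=1)
    mad = stats.median_abs_deviation(ratios, scale=1.0)
    spread = min(s, 1.4826 * mad)
    if spread == 0:
        spread = s  # MAD degenerate but ratios not all equal
    return phi * 0.9 * spread * J ** (-1 / 5)


def _weighted_mode(ratios, weights, phi):
    hband = _mode_bandwidth(ratios, phi)
    if hband == 0 or not np.isfinite(hband):
        return float(ratios[0])
    grid = np.linspace(ratios.min() - 3 * hband, ratios.max() + 3 * hband, 512)
    dens = np.sum(weights[:, None]
                  * np.exp(-0.5 * ((grid[None, :] - ratios[:, None]) / hband) ** 2),
                  axis=0)
    return float(grid[np.argmax(dens)])


def weighted_mode(h, phi: float = 1.0, n_boot: int = 1000,
                  seed: int | None = None) -> MrEstimate:
    """Mode of the smoothed weighted density of per-SNP Wald ratios.

    A normal-kernel density with bandwidth
    phi · 0.9 · min(sd, 1.4826·MAD) · J^(−1/5) is evaluated on a
    512-point grid spanning the ratios ± 3 bandwidths; the estimate is
    the density argmax — consistent when the largest group of
    instruments sharing a ratio is valid (ZEMPA).  Bootstrap SE as in
    :func:`weighted_median`.
    """
    if seed is None:
        raise ValueError("seed is required for the bootstrap SE")
    gamma, sg, Gamma, sG = _arrays(h)
    if len(gamma) < 3:
        raise ValueError("weighted mode requires at least 3 SNPs")
    w = _ratios_weights(gamma, sG)
    beta = _weighted_mode(Gamma / gamma, w, phi)
    se = _parametric_bootstrap(
        lambda g, G: _weighted_mode(G / g, _ratios_weights(g, sG), phi),
        gamma, sg, Gamma, sG, n_boot, seed)
    return MrEstimate("weighted_mode", beta, se, len(gamma))


def _raps_t(beta, gamma, sg, Gamma, sG):
    return (Gamma - beta * gamma) / np.sqrt(sG ** 2 + beta ** 2 * sg ** 2)


def _raps_loss(t, loss, k):
    if loss == "l2":
        return 0.5 * t * t
    a = np.abs(t)
    return np.where(a <= k, 0.5 * t * t, k * a - 0.5 * k * k)


def mr_raps(h, loss: str = "l2", huber_k: float = 1.345,
            bracket: tuple[float, float] = (-5.0, 5.0)) -> MrEstimate:
    """Robust adjusted profile score estimate (simple variant).

    The profile residual t_j(β) = (Γ_j − βγ_j)/√(σ_Γj² + β²σ_γj²)
    accounts for uncertainty on both sides, making the estimator
    consistent under many weak instruments.  β minimizes Σ ρ(t_j) with
    ρ the squared-error (``l2``) or Huber loss; no over-dispersion term
    is fitted.  The SE is a numerically differentiated sandwich.
    """
    gamma, sg, Gamma, sG = _arrays(h)
    if len(gamma) < 1:
        raise ValueError("empty harmonized set")
    if loss not in ("l2", "huber"):
        raise ValueError("loss must be 'l2' or 'huber'")

    def objective(b):
        return float(np.sum(_raps_loss(_raps_t(b, gamma, sg, Gamma, sG),
                                       loss, huber_k)))

    res = optimize.minimize_scalar(objective, bounds=bracket, method="bounded",
                                   options={"xatol": 1e-10})
    beta = float(res.x)
    lo, hi = bracket
    if min(beta - lo, hi - beta) < 1e-6 * (hi - lo):
        raise RuntimeError(
            "optimizer hit the bracket boundary; widen `bracket`")

    # sandwich SE: bread = numerically differentiated observed score,
    # meat = expected squared score under the model t_j ~ N(0,1)
    # (Gauss-Hermite quadrature; the empirical squared score collapses
    # when few SNPs leave near-zero fitted residuals)
    def psi(b):
        t = _raps_t(b, gamma, sg, Gamma, sG)
        if loss == "l2":
            dldt = t
        else:
            dldt = np.clip(t, -huber_k, huber_k)
        s2 = sG ** 2 + b ** 2 * sg ** 2
        dt = -gamma / np.sqrt(s2) - t * b * sg ** 2 / s2
        return dldt * dt

    eps = 1e-5 * max(1.0, abs(beta))
    A = float(np.sum(psi(beta + eps) - psi(beta - eps)) / (2 * eps))
    s2 = sG ** 2 + beta ** 2 * sg ** 2
    a_j = -gamma / np.sqrt(s2)
    b_j = -beta * sg ** 2 / s2
    nodes, wts = np.polynomial.hermite_e.hermegauss(64)
    wq = wts / np.sqrt(2.0 * np.pi)
    if loss == "l2":
        dldt_nodes = nodes
    else:
        dldt_nodes = np.clip(nodes, -huber_k, huber_k)
    psi_model = dldt_nodes[None, :] * (a_j[:, None] + b_j[:, None] * nodes[None, :])
    B = float(np.sum(psi_model ** 2 @ wq))
    if A == 0:
        A = 1e-12
    se = float(np.sqrt(B) / abs(A))
    return MrEstimate("raps", beta, se, len(gamma))


def wglr(h, ld: LdMatrix) -> MrEstimate:
    """Generalized (correlation-weighted) IVW for instruments in LD.

    With Ω = D ρ D, D = diag(σ_Γ) and ρ the signed LD correlation
    matrix, the estimate is the GLS slope (γᵀΩ⁻¹γ)⁻¹ γᵀΩ⁻¹Γ with SE
    √((γᵀΩ⁻¹γ)⁻¹).  Reduces exactly to fixed-effect IVW when ρ = I.
    """
    gamma, sg, Gamma, sG = _arrays(h)
    if isinstance(h, HarmonizedSet):
        ld = ld.subset(h.retained["snp_id"].tolist())
    rho = ld.rho
    omega = rho * np.outer(sG, sG)
    if np.linalg.cond(omega) > 1e8:
        raise np.linalg.LinAlgError(
            "LD-weighted covariance is near-singular; prune instrument "
            "pairs with |rho| > 0.95 before calling wglr")
    oi_g = np.linalg.solve(omega, gamma)
    denom = float(gamma @ oi_g)
    beta = float(oi_g @ Gamma) / denom
    se = denom ** -0.5
    return MrEstimate("wglr", beta, float(se), len(gamma))


def cochran_q(h) -> tuple[float, int, float]:
    """Cochran heterogeneity statistic over the per-SNP Wald ratios.

    Q = Σ w_j (β_j − β_IVW)² with first-order weights w_j = γ_j²/σ_Γj²;
    under homogeneity Q ~ chi-square(J−1).  Excess heterogeneity flags
    pleiotropic instruments.
    """
    gamma, sg, Gamma, sG = _arrays(h)
    J = len(gamma)
    if J < 2:
        raise ValueError("Q statistic requires at least 2 SNPs")
    ratios = Gamma / gamma
    w = _ratios_weights(gamma, sG)
    b_ivw = np.sum(w * ratios) / np.sum(w)
    q = float(np.sum(w * (ratios - b_ivw) ** 2))
    df = J - 1
    return q, df, float(stats.chi2.sf(q, df))
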