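"""Instrument-strength metrics, binary-outcome power, and directionality.

The power model is the mRnd binary-outcome calculation: the observed
genotype-outcome association is attenuated through the instrumented
exposure, giving a noncentral chi-square test with
NCP = N·R²·b01²/(K(1−K) − b01²) where b01 = K(OR/(1+K(OR−1)) − 1),
N the outcome sample size, K the case fraction, and R² the variance in
the exposure explained by the instruments.  Note that instrument
variance-explained values printed as percentages in study tables must
be passed on whichever scale the original calculation used; both are
accepted, the caller decides.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .sumstats import HarmonizedSet


@dataclass
class StrengthReport:
    """Variance explained and F statistic for one instrument set."""

    per_snp_r2: list[float]
    n_exposure: int
    k: int

    @property
    def total_r2(self) -> float:
        return float(np.sum(self.per_snp_r2))

    @property
    def f_stat(self) -> float:
        return f_statistic(self.total_r2, self.n_exposure, self.k)


@dataclass
class PowerSpec:
    """Inputs to the binary-outcome power calculation."""

    n_total: int
    case_fraction: float
    r2: float
    alpha: float = 0.05
    target_power: float = 0.8

    def __post_init__(self) -> None:
        if not 0 < self.case_fraction < 1:
            raise ValueError("case_fraction must lie in (0, 1)")
        if not 0 < self.r2 < 1:
            raise ValueError("r2 must lie in (0, 1)")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")


@dataclass
class SteigerResult:
    """Directionality test comparing instrument variance explained."""

    r2_exposure: float
    r2_outcome: float
    z: float
    p: float

    @property
    def direction_forward(self) -> bool:
        return self.r2_exposure > self.r2_outcome


def variance_explained(beta: float, eaf: float, trait_variance: float = 1.0) -> float:
    """Per-SNP variance in the trait explained by an additive biallelic
    variant: 2·b²·p·(1−p)/var.  Symmetric in p and 1−p."""
    if not 0 < eaf < 1:
        raise ValueError("eaf must lie in (0, 1)")
    if trait_variance <= 0:
        raise ValueError("trait_variance must be positive")
    return 2.0 * beta ** 2 * eaf * (1.0 - eaf) / trait_variance


def f_statistic(total_r2: float, n: int, k: int) -> float:
    """Instrument-strength F = r²(n−1−k)/((1−r²)k); values below ~10
    conventionally flag weak-instrument bias."""
    if k < 1:
        raise ValueError("k must be at least 1")
    if n <= k + 1:
        raise ValueError("n must exceed k + 1")
    if total_r2 >= 1:
        raise ValueError("total_r2 must be below 1")
    return total_r2 * (n - 1 - k) / ((1.0 - total_r2) * k)


def _attenuation(odds_ratio: float, k: float) -> float:
    return k * (odds_ratio / (1.0 + k * (odds_ratio - 1.0)) - 1.0)


def power_binary(spec: PowerSpec, odds_ratio: float) -> float:
    """Power to detect ``odds_ratio`` per SD of exposure on a binary
    outcome (mRnd model; see module docstring for the NCP)."""
    if odds_ratio <= 0:
        raise ValueError("odds_ratio must be positive")
    k = spec.case_fraction
    b01 = _attenuation(odds_ratio, k)
    denom = k * (1.0 - k) - b01 ** 2
    if denom <= 0:
        raise ValueError("attenuation out of range: K(1-K) <= b01^2")
    ncp = spec.n_total * spec.r2 * b01 ** 2 / denom
    crit = stats.chi2.ppf(1.0 - spec.alpha, 1)
    return float(stats.ncx2.sf(crit, 1, ncp))


def _power_or_nan(spec, odds_ratio):
    try:
        return power_binary(spec, odds_ratio)
    except ValueError:
        return np.nan


def detectable_or(spec: PowerSpec) -> tuple[float, float]:
    """Odds ratios on either side of 1 detectable at ``target_power``.

    Bisection solves power(OR) = target_power separately below and above
    1 to absolute OR tolerance 1e−6.  The valid OR range is bounded by
    the attenuation constraint; the bracket is grown adaptively within
    it and a missing root raises.
    """
    if not spec.alpha < spec.target_power < 1:
        raise ValueError("target_power must lie in (alpha, 1)")

    def f(o):
        return _power_or_nan(spec, o) - spec.target_power

    # grow the bracket away from OR=1 until power exceeds the target or
    # the attenuation constraint is hit
    lo = 0.99
    while np.isfinite(f(lo)) and f(lo) < 0 and lo > 1e-6:
        lo *= 0.9
    if not (np.isfinite(f(lo)) and f(lo) >= 0):
        raise ValueError("no detectable OR below 1 within the valid range")
    or_low = optimize.brentq(f, lo, 1.0 - 1e-12, xtol=1e-6)

    hi = 1.01
    while np.isfinite(f(hi)) and f(hi) < 0 and hi < 100:
        hi *= 1.1
    if not (np.isfinite(f(hi)) and f(hi) >= 0):
        raise ValueError("no detectable OR above 1 within the valid range")
    or_high = optimize.brentq(f, 1.0 + 1e-12, hi, xtol=1e-6)
    return float(or_low), float(or_high)


def strength_report(h: HarmonizedSet, n_exposure: int | None = None,
                    trait_variance: float = 1.0) -> StrengthReport:
    """Per-SNP and total variance explained plus F for a harmonized set."""
    r = h.retained
    per = [variance_explained(b, p, trait_variance)
           for b, p in zip(r["gamma"], r["eaf"])]
    n = n_exposure if n_exposure is not None else h.exposure_n
    return StrengthReport(per, int(n), len(per))


def steiger_test(h: HarmonizedSet, n_exposure: int | None = None,
                 n_outcome: int | None = None) -> SteigerResult:
    """MR Steiger directionality test.

    Variance explained in the (standardized) exposure is Σ 2γ²p(1−p);
    in the outcome it is approximated per SNP from the association Z as
    Z²/(Z² + N) and summed.  The implied correlations are compared with
    a two-sample Fisher-z test; a forward (exposure → outcome) direction
    is inferred when the instruments explain more exposure variance.
    """
    n_exp = n_exposure if n_exposure is not None else h.exposure_n
    n_out = n_outcome if n_outcome is not None else h.outcome_n
    if n_exp is None or n_out is None or n_exp <= 3 or n_out <= 3:
        raise ValueError("sample sizes above 3 are required on both sides")
    r = h.retained
    if len(r) < 1:
        raise ValueError("at least one retained SNP is required")
    r2_exp = float(np.sum([variance_explained(b, p)
                           for b, p in zip(r["gamma"], r["eaf"])]))
    z_out = (r["Gamma"] / r["sigma_Gamma"]).to_numpy(float)
    r2_out = float(np.sum(z_out ** 2 / (z_out ** 2 + n_out)))
    return steiger_from_r2(r2_exp, r2_out, n_exp, n_out)


def steiger_from_r2(r2_exposure: float, r2_outcome: float,
                    n_exposure: int, n_outcome: int) -> SteigerResult:
    if r2_exposure >= 1 or r2_outcome >= 1:
        raise ValueError("variance explained must be below 1")
    r_exp, r_out = np.sqrt(r2_exposure), np.sqrt(r2_outcome)
    z = (np.arctanh(r_exp) - np.arctanh(r_out)) / np.sqrt(
        1.0 / (n_exposure - 3) + 1.0 / (n_outcome - 3))
    p = float(2.0 * stats.norm.sf(abs(z)))
    return SteigerResult(float(r2_exposure), float(r2_outcome), float(z), p)
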