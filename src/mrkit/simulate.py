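"""Synthetic two-sample GWAS data with known ground truth.

The generator emulates the structure of a metabolite-exposure,
case-control-outcome two-sample MR study: two exposure cohorts measuring
a standardized metabolite, one large case-control outcome sample and two
smaller case-control strata, weak instruments clustered in LD blocks on
a single chromosome, and optional directional pleiotropy.  Defaults
reflect that setting: exposure cohorts of 5,841 and 8,455, a 120,328
outcome sample with 45.85% cases, strata of 1,589 (51.0% cases) and
5,660 (59.0% cases), and per-SNP exposure effects sized so a ~45-SNP
panel explains on the order of 0.05% of the exposure variance.

All randomness flows from ``SimulationConfig.seed`` through
``numpy.random.SeedSequence`` children, one per sampled component, so
identical configs yield bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.linalg import block_diag

from .sumstats import CANONICAL_COLUMNS, LdMatrix, SummaryTable, zscore_pvalue

_ALLELE_PAIRS = [("A", "G"), ("C", "T"), ("G", "A"), ("T", "C")]

#: default outcome samples: (n_total, case_fraction, label)
DEFAULT_OUTCOMES = [
    (120_328, 55_168 / 120_328, "consortium"),
    (1_589, 810 / 1_589, "strat_users"),
    (5_660, 3_340 / 5_660, "strat_nonusers"),
]


@dataclass
class SimulationConfig:
    """Ground-truth parameters for the synthetic two-sample study."""

    n_snps: int = 45
    maf_range: tuple[float, float] = (0.05, 0.5)
    true_gamma_sd: float = 0.006
    causal_beta: float = 0.0
    pleiotropy_mean: float = 0.0
    pleiotropy_sd: float = 0.0
    invalid_fraction: float = 0.0
    ld_block_sizes: list[int] | None = None
    ld_ar1_rho: float = 0.9
    n_exp_a: int = 5_841
    n_exp_b: int = 8_455
    outcomes: list[tuple[int, float, str]] = field(
        default_factory=lambda: list(DEFAULT_OUTCOMES))
    seed: int = 0

    def __post_init__(self) -> None:
        if self.ld_block_sizes is None:
            self.ld_block_sizes = [self.n_snps]
        if sum(self.ld_block_sizes) != self.n_snps:
            raise ValueError("ld_block_sizes must sum to n_snps")
        if not 0 <= self.invalid_fraction <= 1:
            raise ValueError("invalid_fraction must lie in [0, 1]")
        if not -1 < self.ld_ar1_rho < 1:
            raise ValueError("ld_ar1_rho must lie in (-1, 1)")


def _ar1_block(size: int, rho: float) -> np.ndarray:
    idx = np.arange(size)
    return rho ** np.abs(idx[:, None] - idx[None, :])


def ld_from_config(cfg: SimulationConfig, snp_ids: list[str]) -> LdMatrix:
    rho = block_diag(*[_ar1_block(s, cfg.ld_ar1_rho)
                       for s in cfg.ld_block_sizes])
    return LdMatrix(snp_ids, rho)


def _seed_children(cfg: SimulationConfig, n: int):
    return np.random.SeedSequence(cfg.seed).spawn(n)


def draw_snp_panel(cfg: SimulationConfig) -> pd.DataFrame:
    """Draw the shared SNP panel: positions on one chromosome, MAFs,
    true exposure effects γ_j and per-SNP pleiotropic effects α_j."""
    rng = np.random.default_rng(_seed_children(cfg, 1)[0])
    J = cfg.n_snps
    maf = rng.uniform(*cfg.maf_range, size=J)
    gamma = rng.normal(0.0, cfg.true_gamma_sd, size=J)
    n_invalid = int(round(cfg.invalid_fraction * J))
    invalid = np.zeros(J, bool)
    invalid[rng.choice(J, size=n_invalid, replace=False)] = True
    alpha = np.where(invalid,
                     rng.normal(cfg.pleiotropy_mean, cfg.pleiotropy_sd, size=J),
                     0.0)
    pairs = [_ALLELE_PAIRS[j % len(_ALLELE_PAIRS)] for j in range(J)]
    return pd.DataFrame({
        "snp_id": [f"rs{1000 + j}" for j in range(J)],
        "chrom": "16",
        "pos": 31_000_000 + 20_000 * np.arange(J),
        "effect_allele": [p[0] for p in pairs],
        "other_allele": [p[1] for p in pairs],
        "maf": maf, "gamma": gamma, "alpha": alpha, "invalid": invalid,
    })


def _summary_table(panel, beta_true, se, noise, n, trait_name, trait_type,
                   case_fraction=None):
    beta_hat = beta_true + noise
    df = pd.DataFrame({
        "snp_id": panel["snp_id"], "chrom": panel["chrom"],
        "pos": panel["pos"], "effect_allele": panel["effect_allele"],
        "other_allele": panel["other_allele"], "eaf": panel["maf"],
        "beta": beta_hat, "se": se,
        "pvalue": zscore_pvalue(beta_hat, se),
        "n": n,
        "n_cases": (np.round(case_fraction * n)
                    if case_fraction is not None else np.nan),
        "mac": np.round(2.0 * n * panel["maf"]),
    })
    return SummaryTable(df[CANONICAL_COLUMNS], trait_name=trait_name,
                        trait_type=trait_type, sample_n=int(n),
                        case_fraction=case_fraction)


@dataclass
class SimulatedSummaryData:
    """Summary-level synthetic dataset plus its generating truth."""

    exposure_a: SummaryTable
    exposure_b: SummaryTable
    outcomes: dict[str, SummaryTable]
    ld: LdMatrix
    truth: dict


def simulate_summary_two_sample(cfg: SimulationConfig) -> SimulatedSummaryData:
    """Draw summary statistics for two exposure cohorts and every
    configured outcome sample.

    Standard-error scaling follows the usual asymptotics for a
    standardized trait: σ_γj = 1/√(2p_j(1−p_j)N) for the exposure and
    σ_Γj = 1/√(2p_j(1−p_j)N·K(1−K)) on the log-odds scale for a
    case-control outcome.  Estimation errors are correlated across SNPs
    through the block-AR1 LD matrix (error covariance D ρ D).  True
    outcome effects are Γ_j = β·γ_j + α_j with α_j nonzero only for the
    configured invalid fraction.  Exposure and outcome errors are drawn
    independently (non-overlapping samples).
    """
    panel = draw_snp_panel(cfg)
    ld = ld_from_config(cfg, panel["snp_id"].tolist())
    L = np.linalg.cholesky(ld.rho + 1e-12 * np.eye(cfg.n_snps))
    het = 2.0 * panel["maf"].to_numpy() * (1.0 - panel["maf"].to_numpy())
    children = _seed_children(cfg, 3 + len(cfg.outcomes))

    gamma = panel["gamma"].to_numpy()
    # pleiotropy is directional with respect to the exposure-increasing
    # allele: alpha enters with sign(gamma) so it survives the gamma >= 0
    # harmonization orientation instead of being randomized by it
    Gamma_true = cfg.causal_beta * gamma + panel["alpha"].to_numpy() * np.sign(gamma)

    def corr_noise(se, child):
        rng = np.random.default_rng(child)
        return se * (L @ rng.standard_normal(cfg.n_snps))

    se_a = 1.0 / np.sqrt(het * cfg.n_exp_a)
    se_b = 1.0 / np.sqrt(het * cfg.n_exp_b)
    exposure_a = _summary_table(panel, gamma, se_a, corr_noise(se_a, children[1]),
                                cfg.n_exp_a, "exposure", "continuous")
    exposure_b = _summary_table(panel, gamma, se_b, corr_noise(se_b, children[2]),
                                cfg.n_exp_b, "exposure", "continuous")

    outcomes = {}
    for (n_out, k, label), child in zip(cfg.outcomes, children[3:]):
        se_o = 1.0 / np.sqrt(het * n_out * k * (1.0 - k))
        outcomes[label] = _summary_table(
            panel, Gamma_true, se_o, corr_noise(se_o, child),
            n_out, label, "binary", case_fraction=k)

    truth = {
        "causal_beta": cfg.causal_beta,
        "gamma": gamma.tolist(),
        "alpha": panel["alpha"].tolist(),
        "invalid": panel["invalid"].tolist(),
        "maf": panel["maf"].tolist(),
        "snp_ids": panel["snp_id"].tolist(),
        "seed": cfg.seed,
    }
    return SimulatedSummaryData(exposure_a, exposure_b, outcomes, ld, truth)


@dataclass
class CohortSim:
    """Individual-level synthetic case-control cohort."""

    genotypes: np.ndarray
    exposure: np.ndarray
    outcome: np.ndarray
    stratum: np.ndarray
    age: np.ndarray
    sex: np.ndarray
    snps: pd.DataFrame
    truth: dict


def _copula_genotypes(rng, maf, L, n):
    """Dosages from two thresholded latent Gaussian haplotypes sharing a
    block-LD correlation structure."""
    thr = stats.norm.ppf(maf)
    g = np.zeros((n, len(maf)), dtype=np.int8)
    for _ in range(2):
        z = rng.standard_normal((n, len(maf))) @ L.T
        g += (z < thr).astype(np.int8)
    return g


def simulate_cohort(cfg: SimulationConfig, n_individuals: int,
                    prevalence: float, user_fraction: float = 0.2,
                    ) -> CohortSim:
    """Simulate genotypes, a standardized exposure, and a binary outcome
    with covariates, from the same SNP panel as the summary-level route.

    The outcome follows a logistic model
    logit P(Y=1) = c + β·exposure + 0.01·age + 0.2·sex with the
    intercept c solved numerically so the realized prevalence matches
    ``prevalence``.  Stratum membership (user/nonuser) is assigned
    independently of genotype.
    """
    if n_individuals < 100:
        raise ValueError("n_individuals must be at least 100")
    if not 0.05 < prevalence < 0.95:
        raise ValueError("prevalence must lie in (0.05, 0.95)")
    panel = draw_snp_panel(cfg)
    ld = ld_from_config(cfg, panel["snp_id"].tolist())
    L = np.linalg.cholesky(ld.rho + 1e-12 * np.eye(cfg.n_snps))
    # child 32 is reserved for the individual-level route so it never
    # shares a stream with the summary-level noise draws (children 1..)
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed).spawn(64)[32])

    maf = panel["maf"].to_numpy()
    g = _copula_genotypes(rng, maf, L, n_individuals)
    g_std = (g - 2.0 * maf) / np.sqrt(2.0 * maf * (1.0 - maf))
    score = g_std @ panel["gamma"].to_numpy()
    noise_var = max(1e-3, 1.0 - float(np.var(score)))
    exposure = score + rng.normal(0.0, np.sqrt(noise_var), size=n_individuals)
    exposure = (exposure - exposure.mean()) / exposure.std()

    age = rng.normal(62.0, 10.0, size=n_individuals)
    sex = rng.integers(0, 2, size=n_individuals)
    lp = cfg.causal_beta * exposure + 0.01 * age + 0.2 * sex

    def excess(c):
        return float(np.mean(1.0 / (1.0 + np.exp(-(c + lp))))) - prevalence

    c = optimize.brentq(excess, -30.0, 30.0, xtol=1e-10)
    outcome = rng.binomial(1, 1.0 / (1.0 + np.exp(-(c + lp))))
    stratum = np.where(rng.random(n_individuals) < user_fraction,
                       "user", "nonuser")
    truth = {"causal_beta": cfg.causal_beta, "intercept": c,
             "prevalence": prevalence, "seed": cfg.seed}
    return CohortSim(g, exposure, outcome, stratum, age, sex, panel, truth)


def per_snp_gwas(cohort: CohortSim, trait: str = "exposure",
                 stratum_filter: str | None = None) -> SummaryTable:
    """Per-SNP association scan adjusting for age and sex.

    Continuous trait: ordinary least squares of the trait on additive
    dosage, age and sex.  Binary trait: per-SNP logistic regression
    (IRLS, tolerance 1e−8, at most 50 iterations) reporting the log-OR.
    SNPs with non-convergent or separated fits are dropped and logged.
    """
    import statsmodels.api as sm

    if trait not in ("exposure", "outcome"):
        raise ValueError("trait must be 'exposure' or 'outcome'")
    mask = np.ones(len(cohort.exposure), bool)
    if stratum_filter is not None:
        mask = cohort.stratum == stratum_filter
        if mask.sum() < 100:
            raise ValueError("fewer than 100 individuals in stratum")
    y = (cohort.exposure if trait == "exposure" else cohort.outcome)[mask]
    n = int(mask.sum())
    rows = []
    for j, rec in cohort.snps.iterrows():
        X = np.column_stack([np.ones(n), cohort.genotypes[mask, j],
                             cohort.age[mask], cohort.sex[mask]])
        try:
            if trait == "exposure":
                fit = sm.OLS(y, X).fit()
            else:
                fit = sm.GLM(y, X, family=sm.families.Binomial()).fit(
                    maxiter=50, tol=1e-8)
                if not fit.converged:
                    raise ValueError("IRLS did not converge")
        except Exception:  # separation / convergence failure at this SNP
            continue
        beta, se = float(fit.params[1]), float(fit.bse[1])
        if not np.isfinite(beta) or not np.isfinite(se) or se > 1e3:
            continue
        rows.append({
            "snp_id": rec["snp_id"], "chrom": rec["chrom"], "pos": rec["pos"],
            "effect_allele": rec["effect_allele"],
            "other_allele": rec["other_allele"],
            "eaf": float(np.mean(cohort.genotypes[mask, j]) / 2.0),
            "beta": beta, "se": se,
            "pvalue": float(zscore_pvalue(beta, se)),
            "n": n,
            "n_cases": int(y.sum()) if trait == "outcome" else np.nan,
            "mac": np.nan,
        })
    df = pd.DataFrame(rows, columns=CANONICAL_COLUMNS)
    if trait == "outcome":
        return SummaryTable(df, trait_name="outcome", trait_type="binary",
                            sample_n=n, case_fraction=float(y.mean()))
    return SummaryTable(df, trait_name="exposure", sample_n=n)
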