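"""End-to-end orchestration: meta-analysis, instrument selection,
clumping, harmonization, the estimator suite, and diagnostics tables.

The pipeline mirrors the standard two-sample MR workflow for a
metabolite exposure: pool the two exposure cohorts, build up to three
instrument sets (functional, pathway, genome-wide), clump each at every
configured LD threshold, harmonize against each outcome sample, and run
every applicable estimator.  Estimator applicability is gated, never
silent: Wald ratio/IVW always run; weighted median, weighted mode and
MR-Egger require more than 2 SNPs; the LD-aware GLS estimator runs only
at relaxed clumping thresholds where correlated instruments are kept.
Combinations whose preconditions fail appear in the results table with
an explicit skip reason.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import __version__
from .diagnostics import PowerSpec, detectable_or, steiger_test, strength_report
from .estimators import (Z_95, cochran_q, ivw, mr_egger, mr_raps, wald_ratio,
                         weighted_median, weighted_mode, wglr)
from .instruments import (GeneRegion, InstrumentSet, ld_clump,
                          read_regions_bed, select_functional,
                          select_genomewide, select_pathway)
from .sumstats import (HarmonizedSet, LdMatrix, SummaryTable, harmonize,
                       meta_analyze_fixed, read_ld_matrix, read_summary_stats)
from scipy import stats

#: clumping thresholds at or above this are "relaxed": correlated
#: instruments are retained and the LD-aware estimator applies
RELAXED_LD_THRESHOLD = 0.1

_ESTIMATE_COLUMNS = [
    "instrument_set", "ld_r2", "outcome", "method", "status", "n_snps",
    "beta", "se", "pvalue", "ci_low", "ci_high", "or", "or_low", "or_high",
    "egger_intercept", "egger_intercept_se", "egger_intercept_p",
    "q_stat", "q_df", "q_p",
]


@dataclass
class AnalysisConfig:
    """Inputs and thresholds for one full pipeline run."""

    exposure_a: SummaryTable
    exposure_b: SummaryTable
    outcomes: dict[str, SummaryTable]
    ld: LdMatrix
    regions: list[GeneRegion] | None = None
    functional_snps: list[str] = field(default_factory=list)
    ld_r2_thresholds: list[float] = field(default_factory=lambda: [0.001, 0.8])
    clump_window_kb: int = 10_000
    functional_alpha: float = 0.05
    alpha_family: float = 0.05
    p_meta: float = 5e-8
    p_cohort: float = 0.01
    maf_min: float = 0.01
    min_mac: int = 10
    palindrome_window: tuple[float, float] = (0.42, 0.58)
    n_boot: int = 1000
    seed: int = 0
    phi: float = 1.0
    raps_loss: str = "l2"
    power_alpha: float = 0.05
    target_power: float = 0.8

    def fingerprint(self) -> str:
        """Stable hash of all thresholds and input tables."""
        h = hashlib.sha256()
        scalars = {k: v for k, v in self.__dict__.items()
                   if isinstance(v, (int, float, str, list, tuple))}
        h.update(json.dumps(scalars, sort_keys=True, default=str).encode())
        for t in [self.exposure_a, self.exposure_b, *self.outcomes.values()]:
            h.update(t.df.to_csv(float_format="%.17g").encode())
        h.update(np.ascontiguousarray(self.ld.rho).tobytes())
        return h.hexdigest()

    @classmethod
    def from_json(cls, path) -> "AnalysisConfig":
        """Build a config from a JSON document of file paths and
        thresholds (see the CLI docs for the schema)."""
        with open(path) as fh:
            doc = json.load(fh)
        paths = doc["paths"]
        outcomes = {}
        for label, spec in paths["outcomes"].items():
            outcomes[label] = read_summary_stats(
                spec["path"], trait_name=label, trait_type="binary",
                case_fraction=spec["case_fraction"])
            if "n_total" in spec:
                outcomes[label].sample_n = spec["n_total"]
        kwargs = dict(
            exposure_a=read_summary_stats(paths["exposure_a"],
                                          trait_name="exposure"),
            exposure_b=read_summary_stats(paths["exposure_b"],
                                          trait_name="exposure"),
            outcomes=outcomes,
            ld=read_ld_matrix(paths["ld"]),
            functional_snps=paths.get("functional_snps", []),
        )
        if "regions" in paths:
            kwargs["regions"] = read_regions_bed(paths["regions"])
        for key, val in doc.get("thresholds", {}).items():
            kwargs[key] = tuple(val) if key == "palindrome_window" else val
        return cls(**kwargs)


@dataclass
class ResultsBundle:
    """Everything one pipeline run produced, plus a reproducibility
    manifest (config fingerprint, seed, package version, content hash)."""

    estimates: pd.DataFrame
    power: pd.DataFrame
    strength: pd.DataFrame
    selection: dict[str, pd.DataFrame]
    manifest: dict

    def content_hash(self) -> str:
        h = hashlib.sha256()
        for df in (self.estimates, self.power, self.strength,
                   *[self.selection[k] for k in sorted(self.selection)]):
            h.update(df.to_csv(index=False, float_format="%.17g").encode())
        return h.hexdigest()

    def write(self, out_dir) -> None:
        import pathlib
        out = pathlib.Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.estimates.to_csv(out / "estimates.tsv", sep="\t", index=False,
                              float_format="%.17g")
        self.power.to_csv(out / "power.tsv", sep="\t", index=False,
                          float_format="%.17g")
        self.strength.to_csv(out / "strength.tsv", sep="\t", index=False,
                             float_format="%.17g")
        for name, df in self.selection.items():
            df.to_csv(out / f"selection_{name}.tsv", sep="\t", index=False)
        with open(out / "manifest.json", "w") as fh:
            json.dump(self.manifest, fh, indent=2, sort_keys=True)


def _estimate_row(instrument_set, ld_r2, outcome, est=None, method=None,
                  status="ok", n_snps=0):
    row = dict.fromkeys(_ESTIMATE_COLUMNS, np.nan)
    row.update(instrument_set=instrument_set, ld_r2=ld_r2, outcome=outcome,
               status=status, n_snps=n_snps)
    if est is not None:
        d = est.as_dict()
        row.update(method=d["method"], n_snps=d["n_snps"], beta=d["beta"],
                   se=d["se"], pvalue=d["pvalue"], ci_low=d["ci_low"],
                   ci_high=d["ci_high"])
        row["or"] = d["or"]
        row["or_low"], row["or_high"] = d["or_low"], d["or_high"]
        row["egger_intercept"] = d["egger_intercept"]
        row["egger_intercept_se"] = d["egger_intercept_se"]
        row["egger_intercept_p"] = d["egger_intercept_p"]
    else:
        row["method"] = method
    return row


def _run_estimators(cfg: AnalysisConfig, h: HarmonizedSet, set_name: str,
                    ld_r2: float, outcome_label: str, rows: list) -> None:
    J = h.n_snps
    where = dict(instrument_set=set_name, ld_r2=ld_r2, outcome=outcome_label)
    if J == 0:
        rows.append(_estimate_row(**where, method="all",
                                  status="skip: no SNPs after harmonization"))
        return

    gamma, sg, Gamma, sG = h.arrays()
    if J == 1:
        est = wald_ratio(gamma[0], sg[0], Gamma[0], sG[0])
        rows.append(_estimate_row(**where, est=est))
    q_fields = {}
    if J >= 2:
        q, df_, qp = cochran_q(h)
        q_fields = {"q_stat": q, "q_df": df_, "q_p": qp}
        for est in (ivw(h), mr_raps(h, loss=cfg.raps_loss)):
            row = _estimate_row(**where, est=est)
            row.update(q_fields)
            rows.append(row)
    else:
        for m in ("ivw", "raps"):
            rows.append(_estimate_row(**where, method=m,
                                      status="skip: single SNP, Wald ratio reported"))
    if J > 2:
        rows.append(_estimate_row(**where, est=weighted_median(
            h, n_boot=cfg.n_boot, seed=cfg.seed)))
        rows.append(_estimate_row(**where, est=weighted_mode(
            h, phi=cfg.phi, n_boot=cfg.n_boot, seed=cfg.seed)))
        rows.append(_estimate_row(**where, est=mr_egger(h)))
    else:
        for m in ("weighted_median", "weighted_mode", "egger"):
            rows.append(_estimate_row(**where, method=m, n_snps=J,
                                      status="skip: requires more than 2 SNPs"))
    if ld_r2 >= RELAXED_LD_THRESHOLD:
        if J >= 2:
            rows.append(_estimate_row(**where, est=wglr(h, cfg.ld)))
        else:
            rows.append(_estimate_row(**where, method="wglr", n_snps=J,
                                      status="skip: requires at least 2 SNPs"))


def run_pipeline(cfg: AnalysisConfig) -> ResultsBundle:
    """Execute the full analysis and return a :class:`ResultsBundle`."""
    meta = meta_analyze_fixed(cfg.exposure_a, cfg.exposure_b,
                              min_mac=cfg.min_mac)
    selection: dict[str, pd.DataFrame] = {}
    rows: list[dict] = []
    power_rows: list[dict] = []
    strength_rows: list[dict] = []
    instrument_sets: dict[str, InstrumentSet] = {}

    if cfg.functional_snps:
        func = select_functional(cfg.functional_snps, meta,
                                 alpha=cfg.functional_alpha)
        selection["functional"] = func
        passing = func.loc[func["passes"], "snp_id"].tolist()
        if passing:
            instrument_sets["functional"] = InstrumentSet("functional", passing,
                                                          selection_log=func)
        else:
            rows.append(_estimate_row(
                "functional", np.nan, "all", method="all",
                status="skip: no candidate associated with the exposure"))

    if cfg.regions:
        sel = select_pathway(meta, cfg.exposure_a, cfg.exposure_b,
                             list(cfg.outcomes.values()), cfg.regions,
                             maf_min=cfg.maf_min, alpha_family=cfg.alpha_family)
        selection["pathway"] = sel.selection_log
        if sel.snp_ids:
            instrument_sets["pathway"] = sel

    sel_gw = select_genomewide(meta, cfg.exposure_a, cfg.exposure_b,
                               list(cfg.outcomes.values()),
                               maf_min=cfg.maf_min, p_meta=cfg.p_meta,
                               p_cohort=cfg.p_cohort)
    selection["genomewide"] = sel_gw.selection_log
    if sel_gw.snp_ids:
        instrument_sets["genomewide"] = sel_gw

    for set_name, sel in instrument_sets.items():
        for ld_r2 in cfg.ld_r2_thresholds:
            clumped = ld_clump(sel, meta, cfg.ld, r2_threshold=ld_r2,
                               window_kb=cfg.clump_window_kb)
            selection[f"{set_name}_clumped_r2_{ld_r2:g}"] = clumped.selection_log
            instr_meta = meta.subset(clumped.snp_ids)
            for label, outcome in cfg.outcomes.items():
                h = harmonize(instr_meta, outcome,
                              palindrome_eaf_window=cfg.palindrome_window)
                _run_estimators(cfg, h, set_name, ld_r2, label, rows)
                if h.n_snps >= 1:
                    rep = strength_report(h, n_exposure=int(meta.df["n"].max()))
                    st = steiger_test(h)
                    strength_rows.append({
                        "instrument_set": set_name, "ld_r2": ld_r2,
                        "outcome": label, "k": rep.k,
                        "total_r2": rep.total_r2, "f_stat": rep.f_stat,
                        "steiger_r2_exposure": st.r2_exposure,
                        "steiger_r2_outcome": st.r2_outcome,
                        "steiger_forward": st.direction_forward,
                        "steiger_p": st.p,
                    })
                    if outcome.case_fraction is not None and rep.total_r2 > 0:
                        spec = PowerSpec(outcome.sample_n,
                                         outcome.case_fraction, rep.total_r2,
                                         alpha=cfg.power_alpha,
                                         target_power=cfg.target_power)
                        try:
                            or_lo, or_hi = detectable_or(spec)
                        except ValueError:
                            or_lo = or_hi = np.nan
                        power_rows.append({
                            "instrument_set": set_name, "ld_r2": ld_r2,
                            "outcome": label, "n_total": outcome.sample_n,
                            "case_fraction": outcome.case_fraction,
                            "k": rep.k, "r2": rep.total_r2,
                            "f_stat": rep.f_stat,
                            "or_80pct_low": or_lo, "or_80pct_high": or_hi,
                        })

    estimates = pd.DataFrame(rows, columns=_ESTIMATE_COLUMNS)
    power = pd.DataFrame(power_rows)
    strength = pd.DataFrame(strength_rows)
    bundle = ResultsBundle(estimates, power, strength, selection, {})
    bundle.manifest = {
        "config_fingerprint": cfg.fingerprint(),
        "seed": cfg.seed,
        "version": __version__,
        "content_hash": bundle.content_hash(),
    }
    return bundle


def stratified_compare(bundle: ResultsBundle, stratum_a: str,
                       stratum_b: str) -> pd.DataFrame:
    """Per-method difference in causal estimates between two outcome
    strata: Δβ = β_a − β_b, SE = √(se_a² + se_b²), two-sided normal p."""
    est = bundle.estimates
    est = est[est["status"] == "ok"]
    a = est[est["outcome"] == stratum_a]
    b = est[est["outcome"] == stratum_b]
    if a.empty or b.empty:
        raise ValueError("both strata must have estimates in the bundle")
    keys = ["instrument_set", "ld_r2", "method"]
    merged = a.merge(b, on=keys, suffixes=("_a", "_b"))
    diff = merged["beta_a"] - merged["beta_b"]
    se = np.sqrt(merged["se_a"] ** 2 + merged["se_b"] ** 2)
    out = merged[keys].copy()
    out["beta_diff"] = diff
    out["se_diff"] = se
    out["ci_low"] = diff - Z_95 * se
    out["ci_high"] = diff + Z_95 * se
    out["pvalue"] = 2.0 * stats.norm.sf(np.abs(diff) / se)
    return out
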