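"""GWAS summary statistics: containers, TSV I/O, meta-analysis, harmonization.

The in-memory container for per-SNP association records is a pandas
DataFrame with canonical columns; :class:`SummaryTable` wraps it with
trait-level metadata and validation.  All positions are 1-based and the
strand is implicit (forward): strand mismatches are resolved only by
allele complementing during harmonization.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

#: canonical column order of the summary-statistics TSV dialect
CANONICAL_COLUMNS = [
    "snp_id", "chrom", "pos", "effect_allele", "other_allele",
    "eaf", "beta", "se", "pvalue", "n", "n_cases", "mac",
]

#: file-header aliases for the canonical columns
DEFAULT_COLUMN_MAP = {
    "SNP": "snp_id", "CHR": "chrom", "POS": "pos", "EA": "effect_allele",
    "OA": "other_allele", "EAF": "eaf", "BETA": "beta", "SE": "se",
    "P": "pvalue", "N": "n", "N_CASES": "n_cases", "MAC": "mac",
}

_MANDATORY = ["snp_id", "chrom", "pos", "effect_allele", "other_allele",
              "eaf", "beta", "se", "n"]

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
_VALID_ALLELES = frozenset("ACGT")


def is_palindromic(ea: str, oa: str) -> bool:
    """True for A/T and G/C variants, whose strand cannot be resolved
    from allele labels alone."""
    return _COMPLEMENT.get(ea) == oa


def zscore_pvalue(beta: np.ndarray, se: np.ndarray) -> np.ndarray:
    """Two-sided normal p-value from a Wald Z = beta/se."""
    z = np.asarray(beta, float) / np.asarray(se, float)
    return 2.0 * stats.norm.sf(np.abs(z))


@dataclass
class SummaryTable:
    """Per-SNP GWAS association records for one trait in one sample.

    Parameters
    ----------
    df
        Records with the canonical columns (``snp_id`` unique).
    trait_name
        Label for the measured trait.
    trait_type
        ``"continuous"`` (beta in standardized trait units) or
        ``"binary"`` (beta on the log-odds scale).
    sample_n
        Study sample size (per-SNP ``n`` may be smaller).
    case_fraction
        Proportion of cases; required when ``trait_type == "binary"``.
    """

    df: pd.DataFrame
    trait_name: str = "trait"
    trait_type: str = "continuous"
    sample_n: int | None = None
    case_fraction: float | None = None

    def __post_init__(self) -> None:
        if self.trait_type not in ("continuous", "binary"):
            raise ValueError(f"unknown trait_type {self.trait_type!r}")
        if self.trait_type == "binary" and self.case_fraction is None:
            raise ValueError("binary trait requires case_fraction")
        if self.df["snp_id"].duplicated().any():
            dup = self.df.loc[self.df["snp_id"].duplicated(), "snp_id"].iloc[0]
            raise ValueError(f"duplicate snp_id: {dup!r}")
        for col in ("n_cases", "mac"):
            if col not in self.df.columns:
                self.df[col] = np.nan
        self.df = self.df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def snp_ids(self) -> list[str]:
        return self.df["snp_id"].tolist()

    def indexed(self) -> pd.DataFrame:
        return self.df.set_index("snp_id", drop=False)

    def maf(self) -> pd.Series:
        eaf = self.df["eaf"]
        return np.minimum(eaf, 1.0 - eaf)

    def subset(self, snp_ids) -> "SummaryTable":
        keep = self.df["snp_id"].isin(list(snp_ids))
        return replace(self, df=self.df.loc[keep].reset_index(drop=True))


def _validate_rows(df: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Apply per-record invariants; return (valid rows, n dropped)."""
    ea = df["effect_allele"].astype(str).str.upper()
    oa = df["other_allele"].astype(str).str.upper()
    ok = (
        (df["pos"] >= 1)
        & ea.isin(_VALID_ALLELES)
        & oa.isin(_VALID_ALLELES)
        & (ea != oa)
        & (df["se"] > 0)
        & (df["eaf"] > 0) & (df["eaf"] < 1)
        & (df["n"] > 0)
    )
    if "n_cases" in df.columns:
        ok &= df["n_cases"].isna() | (df["n_cases"] <= df["n"])
    out = df.loc[ok].copy()
    out["effect_allele"] = ea[ok]
    out["other_allele"] = oa[ok]
    return out, int((~ok).sum())


def read_summary_stats(
    path,
    column_map: dict | None = None,
    trait_name: str = "trait",
    trait_type: str = "continuous",
    case_fraction: float | None = None,
) -> SummaryTable:
    """Read a tab-separated summary-statistics file.

    ``column_map`` maps file headers to canonical names and defaults to
    the canonical dialect (SNP, CHR, POS, EA, OA, EAF, BETA, SE, P, N,
    N_CASES, MAC).  Rows violating record invariants (non-positive SE,
    EAF outside (0,1), identical alleles, ...) are dropped with a logged
    count; p-values are recomputed from beta/SE for internal consistency.
    """
    cmap = dict(DEFAULT_COLUMN_MAP if column_map is None else column_map)
    df = pd.read_csv(path, sep="\t", dtype={c: str for c in cmap
                                            if cmap[c] in ("snp_id", "chrom",
                                                           "effect_allele",
                                                           "other_allele")})
    df = df.rename(columns=cmap)
    missing = [c for c in _MANDATORY if c not in df.columns]
    if missing:
        raise ValueError(f"missing mandatory column(s): {', '.join(missing)}")
    for col in CANONICAL_COLUMNS:
        if col not in df.columns:
            df[col] = np.nan
    df = df[CANONICAL_COLUMNS]
    df, n_dropped = _validate_rows(df)
    if n_dropped:
        logger.info("read_summary_stats: dropped %d invalid row(s) from %s",
                    n_dropped, path)
    df["pvalue"] = zscore_pvalue(df["beta"].to_numpy(), df["se"].to_numpy())
    n_total = int(df["n"].max()) if len(df) else 0
    table = SummaryTable(df.reset_index(drop=True), trait_name=trait_name,
                         trait_type=trait_type, sample_n=n_total,
                         case_fraction=case_fraction)
    return table


def write_summary_stats(table: SummaryTable, path) -> None:
    """Write a SummaryTable in the canonical TSV dialect (17 significant
    digits, lossless for float64)."""
    inv = {v: k for k, v in DEFAULT_COLUMN_MAP.items()}
    out = table.df[CANONICAL_COLUMNS].rename(columns=inv)
    out.to_csv(path, sep="\t", index=False, float_format="%.17g")


@dataclass
class LdMatrix:
    """Signed LD correlations r over an ordered SNP panel."""

    snp_ids: list[str]
    rho: np.ndarray

    def __post_init__(self) -> None:
        self.rho = np.asarray(self.rho, float)
        k = len(self.snp_ids)
        if self.rho.shape != (k, k):
            raise ValueError("rho shape does not match snp_ids")
        if not np.allclose(self.rho, self.rho.T, atol=1e-12):
            raise ValueError("rho must be symmetric")
        if not np.allclose(np.diag(self.rho), 1.0, atol=1e-12):
            raise ValueError("rho diagonal must be exactly 1")
        np.fill_diagonal(self.rho, 1.0)
        self.rho = (self.rho + self.rho.T) / 2.0
        self._index = {s: i for i, s in enumerate(self.snp_ids)}

    def r(self, a: str, b: str, default: float | None = None) -> float:
        ia, ib = self._index.get(a), self._index.get(b)
        if ia is None or ib is None:
            if default is None:
                raise KeyError(f"SNP pair ({a}, {b}) absent from LD matrix")
            return default
        return float(self.rho[ia, ib])

    def subset(self, snp_ids) -> "LdMatrix":
        idx = [self._index[s] for s in snp_ids]
        return LdMatrix(list(snp_ids), self.rho[np.ix_(idx, idx)])


def read_ld_matrix(path) -> LdMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return LdMatrix(list(df.columns), df.to_numpy(float))


def write_ld_matrix(ld: LdMatrix, path) -> None:
    pd.DataFrame(ld.rho, index=ld.snp_ids, columns=ld.snp_ids).to_csv(
        path, sep="\t", float_format="%.17g")


# ---------------------------------------------------------------------------
# allele alignment primitives

def _align_sign(ea_ref, oa_ref, ea, oa):
    """How to bring (ea, oa) onto the reference allele pair.

    Returns (sign, strand_flipped) where sign multiplies the effect and
    flag says a strand complement was needed; None if irreconcilable.
    Palindromic pairs are label-aligned only (frequency checks are the
    caller's concern).
    """
    if (ea, oa) == (ea_ref, oa_ref):
        return 1, False
    if (ea, oa) == (oa_ref, ea_ref):
        return -1, False
    cea, coa = _COMPLEMENT.get(ea), _COMPLEMENT.get(oa)
    if (cea, coa) == (ea_ref, oa_ref):
        return 1, True
    if (cea, coa) == (oa_ref, ea_ref):
        return -1, True
    return None


def meta_analyze_fixed(cohort_a: SummaryTable, cohort_b: SummaryTable,
                       min_mac: int = 10) -> SummaryTable:
    """Inverse-variance-weighted fixed-effect meta-analysis of two cohorts.

    Only SNPs present in both cohorts with minor allele count strictly
    above ``min_mac`` in each are pooled: beta = Σw·b/Σw with w = 1/SE²,
    SE = (Σw)^(-1/2), p from the normal Z.  Cohort B is sign/strand
    aligned to cohort A first; irreconcilable alleles exclude the SNP.
    Per-cohort effects are carried along (``beta_a``, ``p_a``, ...) for
    downstream direction-consistency filters.
    """
    a = cohort_a.indexed()
    b = cohort_b.indexed()
    shared = a.index.intersection(b.index)
    rows = []
    n_allele_excluded = 0
    for snp in shared:
        ra, rb = a.loc[snp], b.loc[snp]
        align = _align_sign(ra["effect_allele"], ra["other_allele"],
                            rb["effect_allele"], rb["other_allele"])
        if align is None:
            n_allele_excluded += 1
            continue
        sign, _ = align
        beta_b = sign * rb["beta"]
        eaf_b = rb["eaf"] if sign == 1 else 1.0 - rb["eaf"]
        macs = []
        for rec, eaf in ((ra, ra["eaf"]), (rb, eaf_b)):
            mac = rec["mac"]
            if pd.isna(mac):
                mac = round(2.0 * rec["n"] * min(eaf, 1.0 - eaf))
            macs.append(mac)
        if not all(m > min_mac for m in macs):
            continue
        wa, wb = 1.0 / ra["se"] ** 2, 1.0 / rb["se"] ** 2
        beta = (wa * ra["beta"] + wb * beta_b) / (wa + wb)
        se = (wa + wb) ** -0.5
        rows.append({
            "snp_id": snp, "chrom": ra["chrom"], "pos": ra["pos"],
            "effect_allele": ra["effect_allele"],
            "other_allele": ra["other_allele"],
            "eaf": (ra["n"] * ra["eaf"] + rb["n"] * eaf_b) / (ra["n"] + rb["n"]),
            "beta": beta, "se": se,
            "pvalue": float(zscore_pvalue(beta, se)),
            "n": ra["n"] + rb["n"],
            "n_cases": np.nan, "mac": min(macs),
            "beta_a": ra["beta"], "se_a": ra["se"],
            "p_a": float(zscore_pvalue(ra["beta"], ra["se"])),
            "beta_b": beta_b, "se_b": rb["se"],
            "p_b": float(zscore_pvalue(beta_b, rb["se"])),
        })
    if n_allele_excluded:
        logger.info("meta_analyze_fixed: excluded %d SNP(s) with "
                    "irreconcilable alleles", n_allele_excluded)
    cols = CANONICAL_COLUMNS + ["beta_a", "se_a", "p_a", "beta_b", "se_b", "p_b"]
    df = pd.DataFrame(rows, columns=cols)
    return SummaryTable(df, trait_name=cohort_a.trait_name,
                        trait_type=cohort_a.trait_type,
                        sample_n=(cohort_a.sample_n or 0) + (cohort_b.sample_n or 0))


@dataclass
class HarmonizedSet:
    """Exposure-outcome aligned per-SNP effect pairs ready for MR.

    ``df`` holds one row per intersection SNP with columns ``snp_id``,
    ``effect_allele``, ``other_allele``, ``gamma`` (exposure effect,
    oriented non-negative), ``sigma_gamma``, ``Gamma`` (outcome log-odds
    effect), ``sigma_Gamma``, ``eaf`` and ``action``.  Rows whose action
    starts with ``dropped_`` are excluded from estimation but retained
    for bookkeeping.
    """

    df: pd.DataFrame
    exposure_n: int | None = None
    outcome_n: int | None = None
    outcome_case_fraction: float | None = None
    exposure_name: str = "exposure"
    outcome_name: str = "outcome"

    RETAINED_ACTIONS = ("unchanged", "sign_flipped", "strand_flipped")

    @property
    def retained(self) -> pd.DataFrame:
        return self.df[~self.df["action"].str.startswith("dropped")]

    @property
    def n_snps(self) -> int:
        return len(self.retained)

    def arrays(self):
        """(gamma, sigma_gamma, Gamma, sigma_Gamma) for retained SNPs."""
        r = self.retained
        return (r["gamma"].to_numpy(float), r["sigma_gamma"].to_numpy(float),
                r["Gamma"].to_numpy(float), r["sigma_Gamma"].to_numpy(float))

    def subset(self, snp_ids) -> "HarmonizedSet":
        keep = self.df["snp_id"].isin(list(snp_ids))
        return replace(self, df=self.df.loc[keep].reset_index(drop=True))

    def to_tables(self) -> tuple[SummaryTable, SummaryTable]:
        """Re-express the retained pairs as exposure/outcome SummaryTables
        (shared alleles); useful for idempotence checks and re-export."""
        r = self.retained
        base = {
            "snp_id": r["snp_id"], "chrom": r.get("chrom", "1"),
            "pos": r.get("pos", np.arange(1, len(r) + 1)),
            "effect_allele": r["effect_allele"],
            "other_allele": r["other_allele"], "eaf": r["eaf"],
        }
        exp = pd.DataFrame({**base, "beta": r["gamma"], "se": r["sigma_gamma"],
                            "pvalue": zscore_pvalue(r["gamma"], r["sigma_gamma"]),
                            "n": self.exposure_n or 1})
        out = pd.DataFrame({**base, "beta": r["Gamma"], "se": r["sigma_Gamma"],
                            "pvalue": zscore_pvalue(r["Gamma"], r["sigma_Gamma"]),
                            "n": self.outcome_n or 1})
        k = self.outcome_case_fraction
        exp_t = SummaryTable(exp.reset_index(drop=True), self.exposure_name)
        out_t = SummaryTable(out.reset_index(drop=True), self.outcome_name,
                             trait_type="binary" if k is not None else "continuous",
                             case_fraction=k)
        return exp_t, out_t


def harmonize(exposure: SummaryTable, outcome: SummaryTable,
              palindrome_eaf_window: tuple[float, float] = (0.42, 0.58),
              ) -> HarmonizedSet:
    """Align exposure and outcome effects to a shared effect allele.

    The exposure is first oriented so every effect is non-negative (the
    effect allele is the trait-increasing allele); the outcome is then
    aligned to the exposure's effect allele, negating the effect and
    complementing the EAF when alleles are swapped, and complementing
    allele labels when they match only on the opposite strand.
    Palindromic variants (A/T, G/C) are retained only when both EAFs lie
    outside ``palindrome_eaf_window`` and agree on which allele is minor;
    they are dropped when the outcome EAF is unavailable.
    """
    lo, hi = palindrome_eaf_window
    e = exposure.indexed()
    o = outcome.indexed()
    shared = e.index.intersection(o.index)
    if len(shared) == 0:
        raise ValueError("no shared SNPs between exposure and outcome")

    rows = []
    for snp in shared:
        re_, ro = e.loc[snp], o.loc[snp]
        gamma, ea, oa, eaf = (float(re_["beta"]), re_["effect_allele"],
                              re_["other_allele"], float(re_["eaf"]))
        if gamma < 0:  # orient exposure: effect allele = trait-increasing
            gamma, ea, oa, eaf = -gamma, oa, ea, 1.0 - eaf
        Gamma, sigma_Gamma = float(ro["beta"]), float(ro["se"])
        eaf_out = float(ro["eaf"]) if pd.notna(ro["eaf"]) else np.nan

        row = {"snp_id": snp, "chrom": re_["chrom"], "pos": re_["pos"],
               "effect_allele": ea, "other_allele": oa,
               "gamma": gamma, "sigma_gamma": float(re_["se"]),
               "Gamma": np.nan, "sigma_Gamma": sigma_Gamma, "eaf": eaf}

        if is_palindromic(ea, oa):
            align = _align_sign(ea, oa, ro["effect_allele"], ro["other_allele"])
            if align is None:
                row["action"] = "dropped_mismatch"
            elif np.isnan(eaf_out):
                row["action"] = "dropped_palindromic"
            else:
                sign = align[0]
                eaf_o = eaf_out if sign == 1 else 1.0 - eaf_out
                outside = lambda f: f < lo or f > hi
                if outside(eaf) and outside(eaf_o) and (eaf < 0.5) == (eaf_o < 0.5):
                    row["Gamma"] = sign * Gamma
                    row["action"] = "unchanged" if sign == 1 else "sign_flipped"
                else:
                    row["action"] = "dropped_palindromic"
        else:
            align = _align_sign(ea, oa, ro["effect_allele"], ro["other_allele"])
            if align is None:
                row["action"] = "dropped_mismatch"
            else:
                sign, strand = align
                row["Gamma"] = sign * Gamma
                if strand:
                    row["action"] = "strand_flipped"
                else:
                    row["action"] = "unchanged" if sign == 1 else "sign_flipped"
        rows.append(row)

    df = pd.DataFrame(rows)
    return HarmonizedSet(
        df,
        exposure_n=exposure.sample_n, outcome_n=outcome.sample_n,
        outcome_case_fraction=outcome.case_fraction,
        exposure_name=exposure.trait_name, outcome_name=outcome.trait_name)
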