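"""Instrument selection: candidate filtering strategies and LD clumping.

Three strategies mirror common metabolite-MR practice: a curated list of
functional variants tested for nominal association, a pathway screen of
variants inside gene regions with a Bonferroni threshold computed from
the number of variants screened, and a genome-wide screen.  All
strategies additionally require a consistent direction of effect across
the two exposure cohorts and a minor-allele-frequency floor in exposure
and outcome samples.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .sumstats import LdMatrix, SummaryTable

logger = logging.getLogger(__name__)


@dataclass
class GeneRegion:
    """A gene's genomic interval, 1-based and inclusive at both ends."""

    gene_name: str
    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"{self.gene_name}: start > end")

    def contains(self, chrom: str, pos: int) -> bool:
        return str(chrom) == str(self.chrom) and self.start <= pos <= self.end


def read_regions_bed(path) -> list[GeneRegion]:
    """Read a 4-column BED-like file (chrom, start, end, name).

    BED coordinates are 0-based, half-open; they are converted to the
    package's 1-based inclusive convention on read.
    """
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["chrom", "start", "end", "name"],
                     dtype={"chrom": str})
    return [GeneRegion(r["name"], r["chrom"], int(r["start"]) + 1, int(r["end"]))
            for _, r in df.iterrows()]


#: default gene panel for the aspirin/salicylate metabolism pathway;
#: placeholder coordinates for testing — real analyses supply a BED file
#: with build-specific coordinates.
DEFAULT_PATHWAY_GENES = [
    GeneRegion("BCHE", "3", 1, 2),
    GeneRegion("PAFAH1B2", "11", 1, 2),
    GeneRegion("PAFAH1B3", "19", 1, 2),
    GeneRegion("UGT1A6", "2", 1, 2),
    GeneRegion("ACSM2B", "16", 1, 2),
    GeneRegion("CYP2C9", "10", 1, 2),
]


#: curated variants reported to alter aspirin/salicylate-metabolising
#: enzyme activity (BChE, UGT1A6 x2, CYP2C9)
DEFAULT_FUNCTIONAL_SNPS = ["rs6445035", "rs2070959", "rs1105879", "rs1799853"]


@dataclass
class InstrumentSet:
    """SNPs surviving one selection strategy, with a per-SNP filter log."""

    method: str
    snp_ids: list[str]
    ld_r2_threshold: float | None = None
    selection_log: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __len__(self) -> int:
        return len(self.snp_ids)

    def to_frame(self) -> pd.DataFrame:
        return self.selection_log


def select_functional(candidates: list[str], exposure_meta: SummaryTable,
                      alpha: float = 0.05) -> pd.DataFrame:
    """Look up curated candidate SNPs in the exposure meta-analysis.

    Returns one row per candidate with its association (beta, se, p),
    a ``present`` flag, and ``passes`` = (p < alpha).  An empty pass set
    signals the candidate panel must not be carried into MR.
    """
    if not candidates:
        raise ValueError("candidate list is empty")
    idx = exposure_meta.indexed()
    rows = []
    for snp in candidates:
        if snp in idx.index:
            r = idx.loc[snp]
            rows.append({"snp_id": snp, "present": True,
                         "beta": r["beta"], "se": r["se"],
                         "pvalue": r["pvalue"],
                         "passes": bool(r["pvalue"] < alpha)})
        else:
            rows.append({"snp_id": snp, "present": False, "beta": np.nan,
                         "se": np.nan, "pvalue": np.nan, "passes": False})
    return pd.DataFrame(rows)


def _maf(eaf) -> float:
    return min(float(eaf), 1.0 - float(eaf))


def _common_filters(meta_df: pd.DataFrame, outcomes: list[SummaryTable],
                    maf_min: float) -> pd.DataFrame:
    """Direction consistency across cohorts and MAF floor in exposure and
    every outcome (SNPs absent from an outcome fail its MAF filter)."""
    flags = pd.DataFrame(index=meta_df.index)
    sa, sb = np.sign(meta_df["beta_a"]), np.sign(meta_df["beta_b"])
    flags["direction_consistent"] = (sa == sb) & (sa != 0)
    flags["maf_exposure"] = meta_df["eaf"].map(_maf) >= maf_min
    maf_out = pd.Series(True, index=meta_df.index)
    for out in outcomes:
        o = out.indexed()
        in_out = meta_df["snp_id"].isin(o.index)
        omaf = meta_df["snp_id"].map(
            lambda s: _maf(o.loc[s, "eaf"]) if s in o.index else np.nan)
        maf_out &= in_out & (omaf >= maf_min)
    flags["maf_outcome"] = maf_out
    return flags


def _as_outcome_list(outcome) -> list[SummaryTable]:
    if isinstance(outcome, SummaryTable):
        return [outcome]
    return list(outcome)


def select_pathway(exposure_meta: SummaryTable, cohort_a: SummaryTable,
                   cohort_b: SummaryTable, outcome,
                   regions: list[GeneRegion], maf_min: float = 0.01,
                   alpha_family: float = 0.05) -> InstrumentSet:
    """Pathway screen: variants inside supplied gene regions passing a
    Bonferroni threshold alpha_family/m, where m is the number of
    exposure variants falling in the regions, plus the common direction
    and MAF filters.

    ``cohort_a``/``cohort_b`` supply per-cohort effect directions; the
    meta table must carry ``beta_a``/``beta_b`` columns (as produced by
    :func:`mrkit.sumstats.meta_analyze_fixed`).
    """
    if not regions:
        raise ValueError("region list is empty")
    df = exposure_meta.df
    in_region = df.apply(
        lambda r: any(g.contains(r["chrom"], r["pos"]) for g in regions), axis=1)
    m = int(in_region.sum())
    if m == 0:
        raise ValueError("no exposure SNPs fall within the supplied regions")
    threshold = alpha_family / m
    flags = _common_filters(df, _as_outcome_list(outcome), maf_min)
    flags.insert(0, "snp_id", df["snp_id"])
    flags.insert(1, "in_region", in_region)
    flags.insert(2, "bonferroni", df["pvalue"] < threshold)
    flags["retained"] = (flags["in_region"] & flags["bonferroni"]
                         & flags["direction_consistent"]
                         & flags["maf_exposure"] & flags["maf_outcome"])
    logger.info("select_pathway: m=%d region SNPs, threshold=%.3g, %d retained",
                m, threshold, int(flags["retained"].sum()))
    sel = InstrumentSet("pathway", df.loc[flags["retained"], "snp_id"].tolist(),
                        selection_log=flags)
    sel.selection_log.attrs["m"] = m
    sel.selection_log.attrs["threshold"] = threshold
    return sel


def select_genomewide(exposure_meta: SummaryTable, cohort_a: SummaryTable,
                      cohort_b: SummaryTable, outcome,
                      maf_min: float = 0.01, p_meta: float = 5e-8,
                      p_cohort: float = 0.01) -> InstrumentSet:
    """Genome-wide screen: meta-analysis p < ``p_meta``, per-cohort
    p < ``p_cohort`` in both cohorts, consistent direction, MAF floor."""
    df = exposure_meta.df
    flags = _common_filters(df, _as_outcome_list(outcome), maf_min)
    flags.insert(0, "snp_id", df["snp_id"])
    flags.insert(1, "meta_significant", df["pvalue"] < p_meta)
    flags.insert(2, "cohort_significant",
                 (df["p_a"] < p_cohort) & (df["p_b"] < p_cohort))
    flags["retained"] = (flags["meta_significant"] & flags["cohort_significant"]
                         & flags["direction_consistent"]
                         & flags["maf_exposure"] & flags["maf_outcome"])
    return InstrumentSet("genomewide",
                         df.loc[flags["retained"], "snp_id"].tolist(),
                         selection_log=flags)


def ld_clump(candidates, exposure_meta: SummaryTable, ld: LdMatrix,
             r2_threshold: float = 0.001, window_kb: int = 10_000,
             ) -> InstrumentSet:
    """Greedy LD clumping.

    Repeatedly takes the remaining candidate with the smallest exposure
    p-value as an index SNP (ties broken by chromosome, position, then
    snp_id) and removes every other candidate on the same chromosome
    within ``window_kb`` whose squared correlation with it is at or above
    ``r2_threshold``.  Pairs absent from the LD matrix are treated as
    uncorrelated (logged).  Index SNPs are returned in selection order.
    """
    if not (0 < r2_threshold <= 1):
        raise ValueError("r2_threshold must lie in (0, 1]")
    snp_ids = candidates.snp_ids if isinstance(candidates, InstrumentSet) else list(candidates)
    method = candidates.method if isinstance(candidates, InstrumentSet) else "custom"
    idx = exposure_meta.indexed()
    missing = [s for s in snp_ids if s not in idx.index]
    if missing:
        raise ValueError(f"candidate(s) absent from exposure table: {missing[:3]}")

    def sort_key(s):
        r = idx.loc[s]
        return (float(r["pvalue"]), str(r["chrom"]), int(r["pos"]), s)

    remaining = sorted(snp_ids, key=sort_key)
    kept: list[str] = []
    n_missing_pairs = 0
    while remaining:
        index_snp = remaining.pop(0)
        kept.append(index_snp)
        ri = idx.loc[index_snp]
        survivors = []
        for s in remaining:
            rs = idx.loc[s]
            if (str(rs["chrom"]) == str(ri["chrom"])
                    and abs(int(rs["pos"]) - int(ri["pos"])) <= window_kb * 1000):
                try:
                    r = ld.r(index_snp, s)
                except KeyError:
                    r = 0.0
                    n_missing_pairs += 1
                if r * r >= r2_threshold:
                    continue
            survivors.append(s)
        remaining = survivors
    if n_missing_pairs:
        logger.info("ld_clump: %d in-window pair(s) absent from LD matrix, "
                    "treated as r=0", n_missing_pairs)
    log = pd.DataFrame({"snp_id": snp_ids,
                        "retained": [s in kept for s in snp_ids]})
    return InstrumentSet(method, kept, ld_r2_threshold=r2_threshold,
                         selection_log=log)


def write_instrument_set(sel: InstrumentSet, path) -> None:
    sel.selection_log.to_csv(path, sep="\t", index=False)
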