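import numpy as np
import pandas as pd
import pytest

from mrkit.sumstats import CANONICAL_COLUMNS, SummaryTable, zscore_pvalue


def make_table(rows, **kwargs):
    """Build a SummaryTable from a list of dicts, filling defaults."""
    recs = []
    for i, r in enumerate(rows):
        rec = {"snp_id": f"rs{i}", "chrom": "1", "pos": 1000 * (i + 1),
               "effect_allele": "A", "other_allele": "G", "eaf": 0.3,
               "beta": 0.1, "se": 0.05, "n": 10_000,
               "n_cases": np.nan, "mac": np.nan}
        rec.update(r)
        rec["pvalue"] = float(zscore_pvalue(rec["beta"], rec["se"]))
        recs.append(rec)
    df = pd.DataFrame(recs, columns=CANONICAL_COLUMNS)
    kwargs.setdefault("sample_n", int(df["n"].max()))
    return SummaryTable(df, **kwargs)


def make_harmonized(gamma, sigma_gamma, Gamma, sigma_Gamma, eaf=None):
    """Build a HarmonizedSet directly from effect arrays."""
    from mrkit.sumstats import HarmonizedSet
    J = len(gamma)
    if eaf is None:
        eaf = np.full(J, 0.3)
    df = pd.DataFrame({
        "snp_id": [f"rs{i}" for i in range(J)],
        "chrom": "1", "pos": 1000 * (np.arange(J) + 1),
        "effect_allele": "A", "other_allele": "G",
        "gamma": np.asarray(gamma, float),
        "sigma_gamma": np.asarray(sigma_gamma, float),
        "Gamma": np.asarray(Gamma, float),
        "sigma_Gamma": np.asarray(sigma_Gamma, float),
        "eaf": np.asarray(eaf, float),
        "action": "unchanged",
    })
    return HarmonizedSet(df, exposure_n=10_000, outcome_n=10_000,
                         outcome_case_fraction=0.5)


@pytest.fixture
def rng():
    return np.random.default_rng(20_240_901)
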