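"""Y-A-S life-history strategy profiling and environment screens.

The Y-A-S framework partitions functional genes into growth Yield,
resource Acquisition, and Stress tolerance categories.  A gene -> category
trait map is an input contract (the upstream HMM search that produces it
is out of scope); per-sample category shares are computed over mapped
genes only, with coverage reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core import CommunityTable, SampleMetadata

CATEGORIES = ("Y", "A", "S")


@dataclass
class CATProfile:
    """Per-sample ternary (y, a, s) shares of mapped gene abundance."""

    data: pd.DataFrame               # columns Y, A, S; rows sum to 1
    coverage: pd.Series = field(default_factory=pd.Series)  # mapped share per sample
    n_mapped: int = 0
    n_unmapped: int = 0


def read_trait_map(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"gene_id", "category"}.issubset(df.columns):
        raise ValueError("trait map must have gene_id and category columns")
    return df


def cat_profile(gene_table: CommunityTable, trait_map: pd.DataFrame) -> CATProfile:
    """Aggregate a gene table into Y/A/S category shares per sample.

    Shares are mapped-gene abundance per category divided by total
    mapped-gene abundance, so they are invariant to any per-sample
    rescaling (CPM or otherwise).  A sample with zero mapped abundance is
    rejected by name.
    """
    tm = trait_map.copy()
    bad = set(tm["category"]) - set(CATEGORIES)
    if bad:
        raise ValueError(f"unknown trait categories: {sorted(bad)}")
    if tm["gene_id"].duplicated().any():
        dupes = tm.loc[tm["gene_id"].duplicated(), "gene_id"].tolist()
        raise ValueError(f"genes mapped more than once: {dupes[:5]}")
    cat_of = dict(zip(tm["gene_id"], tm["category"]))

    mapped = [g for g in gene_table.feature_ids if g in cat_of]
    n_unmapped = gene_table.n_features - len(mapped)
    if not mapped:
        raise ValueError("no genes in the table are present in the trait map")
    sub = gene_table.data[mapped]
    totals = sub.sum(axis=1)
    empty = totals.index[totals <= 0].tolist()
    if empty:
        raise ValueError(f"zero mapped-gene abundance in sample(s): {empty}")

    shares = pd.DataFrame(0.0, index=gene_table.data.index, columns=list(CATEGORIES))
    for cat in CATEGORIES:
        genes = [g for g in mapped if cat_of[g] == cat]
        if genes:
            shares[cat] = sub[genes].sum(axis=1) / totals
    coverage = sub.sum(axis=1) / gene_table.data.sum(axis=1)
    return CATProfile(data=shares, coverage=coverage,
                      n_mapped=len(mapped), n_unmapped=n_unmapped)


def profile_as_table(profile: CATProfile) -> CommunityTable:
    """Expose the ternary shares as a CommunityTable so the dispersion
    machinery can test homogenization of strategy space."""
    return CommunityTable(profile.data.copy(), feature_kind="gene",
                          normalization="relative")


def compare_cat(profile: CATProfile, metadata: SampleMetadata) -> pd.DataFrame:
    """Per-category two-sided rank-sum test of AS vs NS shares."""
    md = metadata.data.loc[profile.data.index]
    lu = md["land_use"].to_numpy()
    if len(set(lu)) < 2:
        raise ValueError("both land uses must be present")
    rows = []
    for cat in CATEGORIES:
        a = profile.data.loc[lu == "AS", cat].to_numpy()
        b = profile.data.loc[lu == "NS", cat].to_numpy()
        res = stats.mannwhitneyu(a, b, alternative="two-sided")
        direction = "AS>NS" if np.median(a) > np.median(b) else (
            "AS<NS" if np.median(a) < np.median(b) else "AS=NS")
        rows.append({"category": cat, "statistic": float(res.statistic),
                     "p_value": float(res.pvalue),
                     "mean_AS": float(a.mean()), "mean_NS": float(b.mean()),
                     "direction": direction})
    return pd.DataFrame(rows).set_index("category")


@dataclass
class CorrelationScreen:
    covariate: str
    method: str
    results: pd.DataFrame            # r, p, q, direction per feature
    n_positive: int = 0
    n_negative: int = 0
    n_ns: int = 0


def env_correlation_screen(table: CommunityTable, metadata: SampleMetadata,
                           covariate: str, method: str = "pearson",
                           alpha: float = 0.05,
                           bh_correct: bool = True) -> CorrelationScreen:
    """Per-feature correlation with one environmental covariate.

    Significance labels use BH-adjusted q-values by default
    (``bh_correct=False`` falls back to raw p); features are labelled
    positive / negative / ns.
    """
    md = metadata.data.loc[table.sample_ids]
    if covariate not in md.columns:
        raise ValueError(f"covariate {covariate!r} not in metadata")
    x = md[covariate].to_numpy(dtype=float)
    if np.ptp(x) == 0:
        raise ValueError(f"covariate {covariate!r} is constant")
    if method not in ("pearson", "spearman"):
        raise ValueError(f"unknown method {method!r}")

    counts = table.counts.astype(float)
    rs = np.empty(table.n_features)
    ps = np.empty(table.n_features)
    corr = stats.pearsonr if method == "pearson" else stats.spearmanr
    for j in range(table.n_features):
        col = counts[:, j]
        if np.ptp(col) == 0:
            rs[j], ps[j] = 0.0, 1.0
        else:
            r, p = corr(col, x)
            rs[j], ps[j] = float(r), float(p)
    qs = multipletests(ps, method="fdr_bh")[1] if bh_correct else ps.copy()

    signif = qs < alpha
    direction = np.where(~signif, "ns", np.where(rs > 0, "positive", "negative"))
    df = pd.DataFrame(
        {"r": rs, "p": ps, "q": qs, "direction": direction},
        index=pd.Index(table.feature_ids, name="feature_id"),
    )
    return CorrelationScreen(
        covariate=covariate, method=method, results=df,
        n_positive=int((direction == "positive").sum()),
        n_negative=int((direction == "negative").sum()),
        n_ns=int((direction == "ns").sum()),
    )
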