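"""Community assembly statistics.

Three complementary views of how communities assemble:

* Sloan neutral community model (NCM) — fits a single migration rate m so
  that a taxon's occurrence frequency across samples is predicted from its
  mean relative abundance via the beta stationary approximation; a high R2
  indicates neutral (dispersal/drift) assembly.
* Levins niche breadth — B_j = 1/sum_i P_ij^2, the effective number of
  samples taxon j occupies; the community mean Bcom summarizes habitat
  generalism.
* Normalized stochasticity ratio (NST) — compares observed pairwise
  Bray-Curtis dissimilarity with the expectation under a null model that
  preserves per-sample richness and depth; values above the 50% boundary
  indicate predominantly stochastic assembly, below it deterministic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.spatial.distance import pdist, squareform

from .core import CommunityTable

logger = logging.getLogger(__name__)

_Z95 = stats.norm.ppf(0.975)


# ---------------------------------------------------------------------------
# Sloan neutral community model
# ---------------------------------------------------------------------------

@dataclass
class NCMFit:
    m: float
    N: float
    Nm: float
    r2: float
    taxa: pd.DataFrame               # p, freq, predicted, lower, upper, partition
    n_samples: int = 0

    @property
    def partition_counts(self) -> pd.Series:
        return self.taxa["partition"].value_counts()


def _ncm_predict(m: float, N: float, p: np.ndarray, detection: float) -> np.ndarray:
    a = N * m * p
    b = N * m * (1.0 - p)
    return 1.0 - stats.beta.cdf(detection, a, b)


def ncm_fit(table: CommunityTable) -> NCMFit:
    """Fit the neutral model's migration rate m to occurrence frequencies.

    N is fixed at the mean sample depth; the detection limit is one read
    (1/N).  m is fit by bounded least squares of observed vs predicted
    frequency; R2 = 1 - SSE/SST may be negative for strongly non-neutral
    data.  Wilson 95% score intervals around the predicted frequencies
    (at the realized number of samples) partition taxa into above /
    within / below the neutral envelope.
    """
    counts = table.counts.astype(float)
    n_samples = counts.shape[0]
    depths = counts.sum(axis=1)
    if np.any(depths <= 0):
        raise ValueError("all samples must have positive depth")
    N = float(depths.mean())
    rel = counts / depths[:, None]
    p = rel.mean(axis=0)
    freq = (counts > 0).mean(axis=0)
    present = p > 0
    p, freq = p[present], freq[present]
    ids = np.asarray(table.feature_ids)[present]

    informative = int(((freq > 0) & (freq < 1)).sum())
    if informative < 10:
        raise ValueError(
            f"only {informative} taxa with intermediate frequency; "
            "neutral fit unidentifiable"
        )
    detection = 1.0 / N

    def sse(m: float) -> float:
        resid = freq - _ncm_predict(m, N, p, detection)
        return float((resid ** 2).sum())

    res = optimize.minimize_scalar(sse, bounds=(1e-6, 1.0), method="bounded",
                                   options={"xatol": 1e-8})
    m = float(res.x)
    pred = _ncm_predict(m, N, p, detection)
    sst = float(((freq - freq.mean()) ** 2).sum())
    r2 = 1.0 - res.fun / sst if sst > 0 else np.nan

    lower, upper = _wilson_interval(pred, n_samples)
    partition = np.where(freq > upper, "above",
                         np.where(freq < lower, "below", "within"))
    taxa = pd.DataFrame(
        {"p": p, "freq": freq, "predicted": pred,
         "lower": lower, "upper": upper, "partition": partition},
        index=pd.Index(ids, name="feature_id"),
    )
    return NCMFit(m=m, N=N, Nm=N * m, r2=float(r2), taxa=taxa,
                  n_samples=n_samples)


def _wilson_interval(p: np.ndarray, n: int):
    z2 = _Z95 ** 2
    denom = 1.0 + z2 / n
    center = (p + z2 / (2 * n)) / denom
    half = _Z95 * np.sqrt(p * (1 - p) / n + z2 / (4 * n ** 2)) / denom
    return np.clip(center - half, 0, 1), np.clip(center + half, 0, 1)


# ---------------------------------------------------------------------------
# Levins niche breadth
# ---------------------------------------------------------------------------

@dataclass
class NicheBreadth:
    b: pd.Series                     # per-taxon Levins index
    bcom: float
    weighted: bool = False


def niche_breadth(table: CommunityTable, weighted: bool = False) -> NicheBreadth:
    """Levins B_j = 1/sum_i P_ij^2 with P_ij taxon j's share in sample i.

    Bcom is the unweighted mean over taxa by default; ``weighted=True``
    weights taxa by occupancy (number of samples occupied).  Taxa absent
    from every sample are dropped with a warning.
    """
    counts = table.counts.astype(float)
    if counts.size == 0:
        raise ValueError("empty table")
    totals = counts.sum(axis=0)
    absent = totals == 0
    if absent.any():
        logger.warning("niche_breadth: dropping %d taxa absent everywhere",
                       int(absent.sum()))
    counts = counts[:, ~absent]
    ids = np.asarray(table.feature_ids)[~absent]
    if counts.shape[1] == 0:
        raise ValueError("no taxa present in any sample")
    share = counts / counts.sum(axis=0, keepdims=True)
    b = 1.0 / (share ** 2).sum(axis=0)
    b_series = pd.Series(b, index=pd.Index(ids, name="feature_id"), name="B")
    if weighted:
        w = (counts > 0).sum(axis=0).astype(float)
        bcom = float(np.average(b, weights=w))
    else:
        bcom = float(b.mean())
    return NicheBreadth(b=b_series, bcom=bcom, weighted=weighted)


# ---------------------------------------------------------------------------
# Normalized stochasticity ratio
# ---------------------------------------------------------------------------

@dataclass
class NSTResult:
    pairs: pd.DataFrame              # group, sample_i, sample_j, observed, expected, nst
    group_nst: dict = field(default_factory=dict)
    null_model: str = "PF"
    n_null: int = 0
    seed: int | None = None


def _null_sample(rng, richness: int, depth: int, occ_freq: np.ndarray,
                 regional: np.ndarray) -> np.ndarray:
    """One null community: proportional-occupancy taxon draw, fixed
    richness, fixed depth, abundances proportional to regional means."""
    nf = occ_freq.size
    available = np.flatnonzero(occ_freq > 0)
    k = min(richness, available.size)
    probs = occ_freq[available] / occ_freq[available].sum()
    chosen = rng.choice(available, size=k, replace=False, p=probs)
    out = np.zeros(nf, dtype=np.int64)
    out[chosen] = 1
    rest = depth - k
    if rest > 0:
        q = regional[chosen]
        q = q / q.sum() if q.sum() > 0 else np.full(k, 1.0 / k)
        out[chosen] += rng.multinomial(rest, q)
    return out


def pf_null_communities(table: CommunityTable, seed: int | None = None) -> CommunityTable:
    """One draw of the proportional-occupancy / fixed-richness /
    fixed-depth null model for every sample of ``table`` (pooled as one
    group).  Useful for generating communities whose assembly is, by
    construction, maximally stochastic with respect to the NST null.
    """
    rng = np.random.default_rng(seed)
    counts = table.counts.astype(np.int64)
    depths = counts.sum(axis=1)
    richness = (counts > 0).sum(axis=1)
    occ_freq = (counts > 0).mean(axis=0)
    regional = (counts / depths[:, None]).mean(axis=0)
    null = np.stack([
        _null_sample(rng, int(richness[i]), int(depths[i]), occ_freq, regional)
        for i in range(counts.shape[0])
    ])
    df = pd.DataFrame(null, index=table.sample_ids, columns=table.feature_ids)
    return CommunityTable(df, table.feature_kind, table.normalization)


def nst(table: CommunityTable, groups, null_model: str = "PF",
        n_null: int = 1000, seed: int | None = None) -> NSTResult:
    """Normalized stochasticity ratio on within-group Bray-Curtis pairs.

    For each within-group pair, E_ij is the mean Bray-Curtis dissimilarity
    between the corresponding null communities over ``n_null`` draws;
    NST_ij = D_ij/E_ij when D_ij <= E_ij, else (1-D_ij)/(1-E_ij), so that
    NST = 1 when observed matches the null exactly and decreases toward 0
    as observed dissimilarity departs from the null in either direction.
    Pairs whose null expectation is degenerate (0 or 1) are excluded.
    """
    if null_model != "PF":
        raise ValueError(f"unknown null model {null_model!r}")
    if n_null < 100:
        raise ValueError("n_null must be >= 100")
    groups = pd.Series(np.asarray(groups), index=table.sample_ids)
    rng = np.random.default_rng(seed)

    records = []
    group_nst = {}
    for g in pd.unique(groups):
        sample_idx = np.flatnonzero(groups.to_numpy() == g)
        if sample_idx.size < 3:
            raise ValueError(f"group {g!r} has fewer than 3 samples")
        counts = table.counts[sample_idx].astype(np.int64)
        ids = [table.sample_ids[i] for i in sample_idx]
        n_g = counts.shape[0]
        depths = counts.sum(axis=1)
        richness = (counts > 0).sum(axis=1)
        occ_freq = (counts > 0).mean(axis=0)
        rel = counts / depths[:, None]
        regional = rel.mean(axis=0)

        obs = squareform(pdist(counts.astype(float), metric="braycurtis"))
        e_sum = np.zeros((n_g, n_g))
        for _ in range(n_null):
            null = np.stack([
                _null_sample(rng, int(richness[i]), int(depths[i]),
                             occ_freq, regional)
                for i in range(n_g)
            ])
            e_sum += squareform(pdist(null.astype(float), metric="braycurtis"))
        e = e_sum / n_null

        vals = []
        for i in range(n_g):
            for j in range(i + 1, n_g):
                d_ij, e_ij = obs[i, j], e[i, j]
                if e_ij <= 0.0 or e_ij >= 1.0:
                    logger.warning("nst: degenerate null expectation for pair "
                                   "(%s, %s); excluded", ids[i], ids[j])
                    continue
                if d_ij <= e_ij:
                    nst_ij = d_ij / e_ij
                else:
                    nst_ij = (1.0 - d_ij) / (1.0 - e_ij)
                records.append({"group": g, "sample_i": ids[i],
                                "sample_j": ids[j], "observed": d_ij,
                                "expected": e_ij, "nst": nst_ij})
                vals.append(nst_ij)
        group_nst[g] = float(np.mean(vals)) if vals else np.nan

    return NSTResult(
        pairs=pd.DataFrame(records,
                           columns=["group", "sample_i", "sample_j",
                                    "observed", "expected", "nst"]),
        group_nst=group_nst,
        null_model=null_model,
        n_null=n_null,
        seed=seed,
    )
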