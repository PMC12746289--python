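"""Spatial statistics: distance-decay, PCNM eigenvectors, forward
selection, variation partitioning, and PERMANOVA.

Distance-decay relationships (DDR) regress community similarity
(1 - Bray-Curtis) on geographic distance over all unordered sample pairs
within a group; the inferential surface for a slope difference between
land uses is a permutation test that reshuffles land-use labels over
samples (pair-level regression p-values are anti-conservative because
pairs are not independent, and are reported only descriptively).

Variation partitioning uses redundancy analysis (RDA) on
Hellinger-transformed counts with adjusted R-squared fractions; spatial
predictors come from principal coordinates of neighbor matrices (PCNM).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.sparse.csgraph import minimum_spanning_tree
from skbio import DistanceMatrix

from .core import CommunityTable
from .dispersion import pcoa

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Distance-decay
# ---------------------------------------------------------------------------

@dataclass
class DDRFit:
    per_group: dict                  # group -> {slope, intercept, r2, p, n_pairs}
    pairs: pd.DataFrame              # tidy (group, distance, similarity)
    slope_diff: float | None = None
    slope_diff_p: float | None = None
    n_perm: int = 0


def _pair_arrays(comm: np.ndarray, geo: np.ndarray, idx: np.ndarray):
    sub_d = comm[np.ix_(idx, idx)]
    sub_g = geo[np.ix_(idx, idx)]
    iu = np.triu_indices(len(idx), k=1)
    return sub_g[iu], 1.0 - sub_d[iu]


def _ols_slope(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    denom = (xc ** 2).sum()
    if denom == 0:
        return 0.0
    return float((xc * (y - y.mean())).sum() / denom)


def ddr_fit(community_dm: DistanceMatrix, geo_dm: DistanceMatrix, groups,
            n_perm: int = 999, seed: int | None = None) -> DDRFit:
    """Per-group OLS of similarity on distance plus a permutation test of
    the slope difference between exactly two groups."""
    if list(community_dm.ids) != list(geo_dm.ids):
        raise ValueError("community and geographic matrices must share labels")
    comm = np.asarray(community_dm.data, dtype=float)
    geo = np.asarray(geo_dm.data, dtype=float)
    groups = np.asarray(groups)
    levels = sorted(pd.unique(groups))

    per_group, frames = {}, []
    for g in levels:
        idx = np.flatnonzero(groups == g)
        x, y = _pair_arrays(comm, geo, idx)
        if x.size < 3:
            raise ValueError(f"group {g!r} has fewer than 3 pairs")
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            slope, intercept, r2, p = _ols_slope(x, y), float(y.mean()), 0.0, 1.0
        else:
            fit = stats.linregress(x, y)
            slope, intercept = float(fit.slope), float(fit.intercept)
            r2, p = float(fit.rvalue ** 2), float(fit.pvalue)
        per_group[g] = {"slope": slope, "intercept": intercept, "r2": r2,
                        "p": p, "n_pairs": int(x.size)}
        frames.append(pd.DataFrame({"group": g, "distance": x, "similarity": y}))

    result = DDRFit(per_group=per_group, pairs=pd.concat(frames, ignore_index=True))
    if len(levels) == 2:
        a, b = levels
        obs = per_group[a]["slope"] - per_group[b]["slope"]
        rng = np.random.default_rng(seed)
        count = 0
        for _ in range(n_perm):
            perm = rng.permutation(groups)
            diffs = []
            for g in (a, b):
                idx = np.flatnonzero(perm == g)
                x, y = _pair_arrays(comm, geo, idx)
                diffs.append(_ols_slope(x, y))
            if abs(diffs[0] - diffs[1]) >= abs(obs):
                count += 1
        result.slope_diff = float(obs)
        result.slope_diff_p = (count + 1) / (n_perm + 1)
        result.n_perm = n_perm
    return result


# ---------------------------------------------------------------------------
# PCNM
# ---------------------------------------------------------------------------

@dataclass
class PCNMBasis:
    threshold: float
    eigenvalues: np.ndarray
    vectors: pd.DataFrame            # samples x PCNM axes, orthonormal columns


def pcnm(geo_dm: DistanceMatrix, truncation: float | None = None) -> PCNMBasis:
    """Spatial eigenvectors from the truncated geographic distance matrix.

    Distances beyond the truncation threshold (default: the longest edge of
    the minimum spanning tree, which guarantees connectivity) are replaced
    by 4x the threshold; positive-eigenvalue principal-coordinate axes of
    the result are returned as orthonormal spatial predictors.
    """
    d = np.asarray(geo_dm.data, dtype=float)
    offdiag = d[~np.eye(d.shape[0], dtype=bool)]
    if np.all(offdiag == 0):
        raise ValueError("all locations identical; PCNM undefined")
    uniq = np.unique(d.round(12), axis=0)
    if uniq.shape[0] < 3:
        raise ValueError("PCNM needs at least 3 unique locations")
    if truncation is None:
        mst = minimum_spanning_tree(d).toarray()
        truncation = float(mst.max())
    w = d.copy()
    w[w > truncation] = 4.0 * truncation
    res = pcoa(DistanceMatrix(w, ids=list(geo_dm.ids)))
    n_pos = res.real.shape[1]
    eigvals = res.eigenvalues[:n_pos]
    # orthonormal eigenvectors: undo the sqrt(lambda) scaling of PCoA axes
    vectors = res.real / np.sqrt(eigvals)[None, :]
    cols = [f"PCNM{k + 1}" for k in range(n_pos)]
    return PCNMBasis(
        threshold=truncation,
        eigenvalues=eigvals,
        vectors=pd.DataFrame(vectors, index=list(geo_dm.ids), columns=cols),
    )


# ---------------------------------------------------------------------------
# RDA machinery: forward selection and variation partitioning
# ---------------------------------------------------------------------------

def hellinger(table: CommunityTable) -> np.ndarray:
    """Hellinger transform: sqrt of relative abundances."""
    counts = table.counts.astype(float)
    sums = counts.sum(axis=1, keepdims=True)
    if np.any(sums <= 0):
        raise ValueError("zero-sum rows cannot be Hellinger-transformed")
    return np.sqrt(counts / sums)


def _as_response(response) -> np.ndarray:
    if isinstance(response, CommunityTable):
        return hellinger(response)
    return np.asarray(response, dtype=float)


def _rda_fit(y: np.ndarray, x: np.ndarray):
    """Centered RDA; returns (R2, adjusted R2, rank, residual SS)."""
    n = y.shape[0]
    yc = y - y.mean(axis=0)
    ss_total = float((yc ** 2).sum())
    if x.size == 0:
        return 0.0, 0.0, 0, ss_total
    xc = x - x.mean(axis=0)
    beta, _, rank, _ = np.linalg.lstsq(xc, yc, rcond=None)
    fitted = xc @ beta
    ss_fit = float((fitted ** 2).sum())
    r2 = ss_fit / ss_total if ss_total > 0 else 0.0
    if n - rank - 1 <= 0:
        raise ValueError("too few samples for the number of predictors")
    adj = 1.0 - (1.0 - r2) * (n - 1) / (n - rank - 1)
    return r2, adj, int(rank), ss_total - ss_fit


@dataclass
class SelectionResult:
    selected: list
    records: pd.DataFrame            # per-step variable, adjR2, F, p
    global_adj_r2: float | None = None


def forward_select(response, candidates: pd.DataFrame, alpha: float = 0.05,
                   n_perm: int = 199, seed: int | None = None,
                   adj_r2_stop: float | None = None) -> SelectionResult:
    """Greedy forward selection of RDA predictors.

    At each step the candidate with the largest partial-F (equivalently,
    adjusted-R2 gain) is entered if the max-F permutation test over all
    remaining candidates is significant — taking the maximum inside the
    permutation corrects the best-of-k selection bias, so a pure-noise
    candidate pool is selected from at the nominal rate.  Selection stops
    when that test exceeds ``alpha``, when the adjusted R2 of the
    selection reaches the global model's (double stopping rule), or when
    no candidate improves the criterion.
    """
    y = _as_response(response)
    n = y.shape[0]
    if candidates.shape[0] != n:
        raise ValueError("candidate rows must match response rows")
    rng = np.random.default_rng(seed)
    names = list(candidates.columns)

    global_adj = adj_r2_stop
    if global_adj is None and names:
        try:
            _, global_adj, _, _ = _rda_fit(y, candidates.to_numpy(dtype=float))
        except ValueError:
            global_adj = None

    selected: list = []
    records = []
    while len(selected) < len(names):
        x_sel = (candidates[selected].to_numpy(dtype=float)
                 if selected else np.empty((n, 0)))
        _, adj_sel, rank_sel, _ = _rda_fit(y, x_sel)
        if global_adj is not None and selected and adj_sel >= global_adj:
            break

        # residualize response and candidates on the current selection
        y_res = _residualize_cols(y - y.mean(axis=0), x_sel)
        remaining = [nm for nm in names if nm not in selected]
        c_res, kept = [], []
        for nm in remaining:
            r = _residualize_cols(
                candidates[nm].to_numpy(dtype=float)[:, None], x_sel)[:, 0]
            if (r ** 2).sum() > 1e-10 * n:      # rank guard: collinear
                c_res.append(r)
                kept.append(nm)
        if not kept:
            break
        c_mat = np.column_stack(c_res)
        df_resid = n - rank_sel - 2
        if df_resid <= 0:
            break

        f_all = _partial_f_all(y_res, c_mat, df_resid)
        best_idx = int(np.argmax(f_all))
        f_obs = f_all[best_idx]
        count = 0
        for _ in range(n_perm):
            y_perm = y_res[rng.permutation(n)]
            if _partial_f_all(y_perm, c_mat, df_resid).max() >= f_obs:
                count += 1
        p = (count + 1) / (n_perm + 1)
        if p > alpha:
            break
        best = kept[best_idx]
        selected.append(best)
        _, adj_new, _, _ = _rda_fit(
            y, candidates[selected].to_numpy(dtype=float))
        records.append({"variable": best, "adj_r2": adj_new,
                        "F": f_obs, "p": p})
    return SelectionResult(
        selected=selected,
        records=pd.DataFrame(records, columns=["variable", "adj_r2", "F", "p"]),
        global_adj_r2=global_adj,
    )


def _residualize_cols(v: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Residuals of (already centered) columns of v on centered x."""
    v = v - v.mean(axis=0)
    if x.size == 0:
        return v
    xc = x - x.mean(axis=0)
    beta, *_ = np.linalg.lstsq(xc, v, rcond=None)
    return v - xc @ beta


def _partial_f_all(y_res: np.ndarray, c_mat: np.ndarray,
                   df_resid: int) -> np.ndarray:
    """Partial F of each candidate column against the residual response."""
    ss_total = (y_res ** 2).sum()
    proj = c_mat.T @ y_res                       # m x p
    norms = (c_mat ** 2).sum(axis=0)
    ss_fit = (proj ** 2).sum(axis=1) / norms
    rss = ss_total - ss_fit
    with np.errstate(divide="ignore"):
        return np.where(rss > 0, ss_fit / (rss / df_resid), np.inf)


@dataclass
class VPAResult:
    env_variables: list
    spatial_variables: list
    a: float                         # pure environmental
    b: float                         # shared
    c: float                         # pure spatial
    d: float                         # residual
    adj_env: float = 0.0
    adj_spatial: float = 0.0
    adj_joint: float = 0.0


def variation_partition(response, env: pd.DataFrame | None,
                        spatial: pd.DataFrame | None) -> VPAResult:
    """Partition adjusted R2 into pure env (a), shared (b), pure spatial
    (c) and residual (d) fractions; a+b+c+d = 1 by construction."""
    y = _as_response(response)
    env = env if env is not None else pd.DataFrame(index=range(y.shape[0]))
    spatial = spatial if spatial is not None else pd.DataFrame(index=range(y.shape[0]))
    xe = env.to_numpy(dtype=float) if env.shape[1] else np.empty((y.shape[0], 0))
    xs = spatial.to_numpy(dtype=float) if spatial.shape[1] else np.empty((y.shape[0], 0))
    _, adj_e, _, _ = _rda_fit(y, xe)
    _, adj_s, _, _ = _rda_fit(y, xs)
    joint = np.column_stack([xe, xs]) if (xe.size or xs.size) else np.empty((y.shape[0], 0))
    _, adj_j, _, _ = _rda_fit(y, joint)
    a = adj_j - adj_s
    c = adj_j - adj_e
    b = adj_e + adj_s - adj_j
    d = 1.0 - adj_j
    return VPAResult(
        env_variables=list(env.columns),
        spatial_variables=list(spatial.columns),
        a=float(a), b=float(b), c=float(c), d=float(d),
        adj_env=float(adj_e), adj_spatial=float(adj_s), adj_joint=float(adj_j),
    )


# ---------------------------------------------------------------------------
# PERMANOVA
# ---------------------------------------------------------------------------

def _permanova_stats(d2: np.ndarray, codes: np.ndarray, n_levels: int):
    n = d2.shape[0]
    sst = d2.sum() / (2.0 * n)
    ssw = 0.0
    for g in range(n_levels):
        idx = np.flatnonzero(codes == g)
        ssw += d2[np.ix_(idx, idx)].sum() / (2.0 * idx.size)
    ssa = sst - ssw
    f = (ssa / (n_levels - 1)) / (ssw / (n - n_levels))
    return f, ssa / sst


def permanova(dm: DistanceMatrix, factor, n_perm: int = 999,
              seed: int | None = None) -> dict:
    """One-factor PERMANOVA: pseudo-F, R2 and a free-permutation p-value."""
    codes, levels = pd.factorize(np.asarray(factor))
    if len(levels) < 2:
        raise ValueError("factor must have at least 2 levels")
    d2 = np.asarray(dm.data, dtype=float) ** 2
    f_obs, r2 = _permanova_stats(d2, codes, len(levels))
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        f_perm, _ = _permanova_stats(d2, rng.permutation(codes), len(levels))
        if f_perm >= f_obs:
            count += 1
    return {"pseudo_F": float(f_obs), "r2": float(r2),
            "p_value": (count + 1) / (n_perm + 1), "n_perm": n_perm,
            "levels": list(map(str, levels))}


def permanova_terms(dm: DistanceMatrix, terms: dict, n_perm: int = 999,
                    seed: int | None = None) -> pd.DataFrame:
    """Sequential (type-I) multi-term PERMANOVA on predictor matrices.

    ``terms`` maps term name -> DataFrame/array of predictors (factors
    should be dummy-coded by the caller; a 1-D array of labels is coded
    automatically).  Main-effects only; rows of the Gower-centered matrix
    are permuted freely.
    """
    d = np.asarray(dm.data, dtype=float)
    n = d.shape[0]
    a = -0.5 * d ** 2
    g = a - a.mean(axis=1, keepdims=True) - a.mean(axis=0, keepdims=True) + a.mean()

    mats, names = [], []
    for name, x in terms.items():
        x = np.asarray(x if not isinstance(x, pd.DataFrame) else x.to_numpy())
        if x.ndim == 1 and not np.issubdtype(x.dtype, np.number):
            x = pd.get_dummies(pd.Series(x), drop_first=True).to_numpy(dtype=float)
        elif x.ndim == 1:
            x = x[:, None].astype(float)
        mats.append(x.astype(float))
        names.append(name)

    def hat(x):
        xc = np.column_stack([np.ones(n), x])
        q, _ = np.linalg.qr(xc)
        return q @ q.T

    def seq_ss(gmat):
        out, prev_ss, acc = [], 0.0, None
        for x in mats:
            acc = x if acc is None else np.column_stack([acc, x])
            h = hat(acc)
            ss = float(np.trace(h @ gmat))
            out.append(ss - prev_ss)
            prev_ss = ss
        resid = float(np.trace(gmat)) - prev_ss
        return out, resid

    ss_terms, ss_resid = seq_ss(g)
    df_terms = [np.linalg.matrix_rank(x - x.mean(axis=0)) for x in mats]
    df_resid = n - 1 - sum(df_terms)
    f_obs = [(ss / max(dfi, 1)) / (ss_resid / df_resid)
             for ss, dfi in zip(ss_terms, df_terms)]

    rng = np.random.default_rng(seed)
    counts = np.zeros(len(mats))
    for _ in range(n_perm):
        perm = rng.permutation(n)
        gp = g[np.ix_(perm, perm)]
        ss_p, resid_p = seq_ss(gp)
        f_p = [(ss / max(dfi, 1)) / (resid_p / df_resid)
               for ss, dfi in zip(ss_p, df_terms)]
        counts += np.asarray(f_p) >= np.asarray(f_obs)

    total = float(np.trace(g))
    return pd.DataFrame({
        "term": names,
        "df": df_terms,
        "ss": ss_terms,
        "r2": [ss / total for ss in ss_terms],
        "pseudo_F": f_obs,
        "p_value": (counts + 1) / (n_perm + 1),
    })
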