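"""Multivariate dispersion (homogenization) testing.

The homogenization engine: principal-coordinates embedding of a
dissimilarity matrix (keeping "imaginary" axes from negative eigenvalues,
as Bray–Curtis matrices are generally non-Euclidean), per-sample distance
to the group centroid in that space, and a two-group comparison of those
distances.  Smaller dispersion means a more homogeneous group.

Two grouping schemes matter for a paired land-use survey:

* regional — one group per land use, pooling all sites: between-site plus
  within-site variation;
* local — one group per (site, land use) plot: within-site variation only,
  pooled across sites before the land-use comparison.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg
from scipy import stats
from skbio import DistanceMatrix

from .core import CommunityTable, SampleMetadata, bray_curtis

logger = logging.getLogger(__name__)

_EIG_REL_TOL = 1e-12


@dataclass
class PCoAResult:
    """Principal-coordinates embedding split by eigenvalue sign.

    ``real`` holds coordinates on positive-eigenvalue axes (scaled by
    sqrt(lambda)); ``imaginary`` the |lambda|-scaled coordinates on
    negative axes.  Squared inter-point distances are recovered as
    ||du||^2 - ||dv||^2 over the real/imaginary blocks.
    """

    labels: list
    eigenvalues: np.ndarray          # all eigenvalues, descending
    real: np.ndarray                 # n x n_pos
    imaginary: np.ndarray            # n x n_neg
    trace: float = 0.0


@dataclass
class DispersionResult:
    """Distances to group centroids plus the group comparison."""

    z: pd.Series                     # per-sample distance to own centroid
    groups: pd.Series
    scheme: str                      # "regional" | "local" | "custom"
    group_means: pd.Series = field(default_factory=pd.Series)
    test: dict | None = None


def pcoa(dm: DistanceMatrix) -> PCoAResult:
    """Gower-centered eigendecomposition of -D^2/2, all axes retained."""
    d = np.asarray(dm.data, dtype=float)
    if d.shape[0] != d.shape[1] or not np.allclose(d, d.T):
        raise ValueError("distance matrix must be square and symmetric")
    a = -0.5 * d ** 2
    row = a.mean(axis=1, keepdims=True)
    col = a.mean(axis=0, keepdims=True)
    g = a - row - col + a.mean()
    w, v = scipy.linalg.eigh(g)
    order = np.argsort(w)[::-1]
    w, v = w[order], v[:, order]
    tol = max(np.abs(w).max(), 1.0) * _EIG_REL_TOL * d.shape[0]
    pos = w > tol
    neg = w < -tol
    real = v[:, pos] * np.sqrt(w[pos])
    imag = v[:, neg] * np.sqrt(-w[neg])
    return PCoAResult(
        labels=list(dm.ids),
        eigenvalues=w,
        real=real,
        imaginary=imag,
        trace=float(np.trace(g)),
    )


def betadisper(dm: DistanceMatrix, groups, scheme: str = "custom") -> DispersionResult:
    """Per-sample distance to its group centroid in PCoA space.

    For sample j in group g, ``z_j^2 = ||u_j - c_g||^2 - ||v_j - c_g'||^2``
    over the real and imaginary coordinate blocks; negative squared
    distances (possible with strongly non-Euclidean input) are clamped to
    zero and logged.  Singleton groups are rejected.
    """
    groups = pd.Series(np.asarray(groups), index=list(dm.ids), name="group")
    sizes = groups.value_counts()
    singletons = sizes.index[sizes < 2].tolist()
    if singletons:
        raise ValueError(f"singleton group(s) not allowed: {singletons}")
    res = pcoa(dm)
    z2 = np.empty(len(groups))
    for g in sizes.index:
        idx = np.flatnonzero(groups.to_numpy() == g)
        cu = res.real[idx].mean(axis=0)
        cv = res.imaginary[idx].mean(axis=0) if res.imaginary.size else np.zeros(0)
        du = ((res.real[idx] - cu) ** 2).sum(axis=1)
        dv = ((res.imaginary[idx] - cv) ** 2).sum(axis=1) if res.imaginary.size else 0.0
        z2[idx] = du - dv
    n_clamped = int((z2 < 0).sum())
    if n_clamped:
        logger.warning(
            "betadisper: clamped %d negative squared centroid distance(s) "
            "(min %.3e) to zero", n_clamped, float(z2.min()),
        )
    z = pd.Series(np.sqrt(np.clip(z2, 0.0, None)), index=groups.index, name="z")
    means = z.groupby(groups).mean()
    return DispersionResult(z=z, groups=groups, scheme=scheme, group_means=means)


def compare_dispersion(z_a, z_b, method: str = "ranksum",
                       n_perm: int = 999, seed: int | None = None) -> dict:
    """Two-group comparison of distances-to-centroid.

    ``ranksum`` is the two-sided Wilcoxon rank-sum (Mann-Whitney, with the
    tie-corrected normal approximation); ``permF`` is the PERMDISP-style
    permutation of group labels on the one-way F statistic.
    """
    za = np.asarray(z_a, dtype=float)
    zb = np.asarray(z_b, dtype=float)
    if za.size == 0 or zb.size == 0:
        raise ValueError("both groups must be non-empty")
    if method == "ranksum":
        res = stats.mannwhitneyu(za, zb, alternative="two-sided")
        return {"method": "ranksum", "statistic": float(res.statistic),
                "p_value": float(res.pvalue),
                "mean_a": float(za.mean()), "mean_b": float(zb.mean())}
    if method == "permF":
        pooled = np.concatenate([za, zb])
        na = za.size
        f_obs = _anova_f(pooled, na)
        rng = np.random.default_rng(seed)
        count = 0
        for _ in range(n_perm):
            perm = rng.permutation(pooled)
            if _anova_f(perm, na) >= f_obs:
                count += 1
        return {"method": "permF", "statistic": float(f_obs),
                "p_value": (count + 1) / (n_perm + 1),
                "n_perm": n_perm,
                "mean_a": float(za.mean()), "mean_b": float(zb.mean())}
    raise ValueError(f"unknown method {method!r}")


def _anova_f(pooled: np.ndarray, na: int) -> float:
    a, b = pooled[:na], pooled[na:]
    n = pooled.size
    grand = pooled.mean()
    ss_between = na * (a.mean() - grand) ** 2 + (n - na) * (b.mean() - grand) ** 2
    ss_within = ((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()
    if ss_within == 0:
        return np.inf if ss_between > 0 else 0.0
    return (ss_between / 1.0) / (ss_within / (n - 2))


@dataclass
class TwoScaleReport:
    """Paired regional + local dispersion results for one feature table."""

    regional: DispersionResult
    local: DispersionResult
    regional_test: dict = field(default_factory=dict)
    local_test: dict = field(default_factory=dict)


def two_scale_homogeneity(table_or_dm, metadata: SampleMetadata,
                          method: str = "ranksum", n_perm: int = 999,
                          seed: int | None = None) -> TwoScaleReport:
    """Run the dispersion comparison at regional and local scales.

    Regional: groups = land use over all replicate samples.  Local:
    groups = (site, land use); the per-sample distances are pooled across
    sites within each land use before the AS-vs-NS comparison.  Sites
    missing one land use are kept in the embedding but excluded from no
    comparison (a warning is logged).
    """
    if isinstance(table_or_dm, CommunityTable):
        dm = bray_curtis(table_or_dm)
    else:
        dm = table_or_dm
    md = metadata.data.loc[list(dm.ids)]
    land_use = md["land_use"]
    sites = md["site_id"].astype(str) + "_" + land_use.astype(str)

    pair_check = md.groupby("site_id")["land_use"].nunique()
    unpaired = pair_check.index[pair_check < 2].tolist()
    if unpaired:
        logger.warning("sites missing a land-use pair: %s", unpaired)

    regional = betadisper(dm, land_use.to_numpy(), scheme="regional")
    local = betadisper(dm, sites.to_numpy(), scheme="local")

    z_as_r = regional.z[land_use.to_numpy() == "AS"]
    z_ns_r = regional.z[land_use.to_numpy() == "NS"]
    z_as_l = local.z[land_use.to_numpy() == "AS"]
    z_ns_l = local.z[land_use.to_numpy() == "NS"]

    return TwoScaleReport(
        regional=regional,
        local=local,
        regional_test=compare_dispersion(z_as_r, z_ns_r, method, n_perm, seed),
        local_test=compare_dispersion(z_as_l, z_ns_l, method, n_perm, seed),
    )


def two_scale_by_kingdom(table: CommunityTable, metadata: SampleMetadata,
                         kingdom_of: dict, **kwargs) -> dict:
    """Per-kingdom two-scale reports for a taxon-family table.

    ``kingdom_of`` maps feature id -> kingdom label; features without a
    label are skipped.
    """
    reports = {}
    for kingdom in sorted(set(kingdom_of.values())):
        feats = [f for f in table.feature_ids if kingdom_of.get(f) == kingdom]
        if not feats:
            continue
        sub = CommunityTable(table.data[feats], table.feature_kind,
                             table.normalization)
        reports[kingdom] = two_scale_homogeneity(sub, metadata, **kwargs)
    return reports
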