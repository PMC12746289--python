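"""Synthetic paired-site soil-community generator with known ground truth.

Emulates the sampling design of a paired land-use survey: ``n_sites`` sites
along a ~900 km transect, each contributing an agricultural (AS) and a
natural-steppe (NS) plot with ``n_replicates`` soil cores apiece.  The
generator exposes explicit knobs for every process the downstream
statistics are meant to detect:

* ``dispersion_as`` / ``dispersion_ns`` — within-plot log-abundance noise
  SD; smaller values homogenize that land use at the local scale.
* ``site_sd_as`` / ``site_sd_ns`` — between-site random shifts; smaller
  values homogenize at the regional scale.
* ``selection_strength`` — quadratic environmental filtering against a
  latitude-linked gradient; larger values make assembly more
  deterministic (lower stochasticity ratio).
* ``migration`` — neutral migration rate used by
  :func:`simulate_neutral`, whose sampling scheme is exactly the beta
  stationary approximation the Sloan neutral model fits.

All generators are deterministic under a fixed seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import CommunityTable, SampleMetadata

#: reference latitude/longitude of the southern end of the transect
_BASE_LAT = 43.5
_BASE_LON = 124.5
_KM_PER_DEG_LAT = 111.19


@dataclass
class SimConfig:
    """Parameters of the paired-design generator; defaults are the survey
    layout (27 sites x 2 land uses x 5 replicates over ~900 km)."""

    n_sites: int = 27
    n_replicates: int = 5
    n_features: int = 500
    lognormal_mu: float = 0.0
    lognormal_sigma: float = 1.5
    depth: int = 2000
    migration: float = 0.1
    dispersion_as: float = 0.3
    dispersion_ns: float = 1.0
    site_sd_as: float = 5.0
    site_sd_ns: float = 5.0
    spatial_sd_as: float = 2.0
    spatial_sd_ns: float = 2.0
    spatial_range_as_km: float = 250.0
    spatial_range_ns_km: float = 250.0
    site_scale_sd: float = 0.5
    landuse_sd: float = 0.5
    selection_strength: float = 0.0
    extent_km: float = 900.0
    env_noise_sd: float = 0.3
    two_dimensional: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("lognormal_sigma", "dispersion_as", "dispersion_ns",
                     "site_sd_as", "site_sd_ns", "spatial_sd_as",
                     "spatial_sd_ns", "spatial_range_as_km",
                     "spatial_range_ns_km", "site_scale_sd", "landuse_sd",
                     "selection_strength", "env_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not (0 < self.migration <= 1):
            raise ValueError("migration must be in (0, 1]")
        if self.depth < 100:
            raise ValueError("depth must be >= 100")
        if self.n_features < 2:
            raise ValueError("n_features must be >= 2")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _feature_ids(n: int) -> list[str]:
    return [f"F{j:05d}" for j in range(1, n + 1)]


def simulate_metacommunity(config: SimConfig, rng: np.random.Generator | None = None) -> np.ndarray:
    """Lognormal metacommunity relative abundances (strictly positive, sum 1).

    ``lognormal_sigma = 0`` degenerates to the uniform vector 1/n.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    z = rng.standard_normal(config.n_features)
    log_abund = config.lognormal_mu + config.lognormal_sigma * z
    abund = np.exp(log_abund - log_abund.max())  # guard overflow
    return abund / abund.sum()


def simulate_neutral(config: SimConfig, n_samples: int | None = None) -> CommunityTable:
    """Neutral local communities in the well-mixed migration regime.

    Each sample's latent relative abundances are a Dirichlet draw with
    concentration ``depth * migration * p`` around the metacommunity ``p``
    (marginally Beta(Nmp, Nm(1-p)), the stationary approximation of the
    neutral model).  ``depth`` reads are then allocated to the taxa above
    the one-read detection limit (latent abundance > 1/N), one guaranteed
    read each plus a multinomial remainder, so a taxon's occurrence
    frequency is exactly 1 - BetaCDF(1/N; Nmp, Nm(1-p)) — the analytic
    target the neutral-model fit assumes.
    """
    rng = np.random.default_rng(config.seed)
    meta = simulate_metacommunity(config, rng)
    if n_samples is None:
        n_samples = 2 * config.n_sites * config.n_replicates
    depth = config.depth
    conc = depth * config.migration * meta
    counts = np.zeros((n_samples, config.n_features), dtype=np.int64)
    for i in range(n_samples):
        local = rng.dirichlet(conc)
        detected = np.flatnonzero(local > 1.0 / depth)
        if detected.size == 0:
            detected = np.array([int(np.argmax(local))])
        counts[i, detected] = 1
        rest = depth - detected.size
        if rest > 0:
            q = local[detected] / local[detected].sum()
            counts[i, detected] += rng.multinomial(rest, q)
    df = pd.DataFrame(
        counts,
        index=[f"SAMP{i + 1:04d}" for i in range(n_samples)],
        columns=_feature_ids(config.n_features),
    )
    return CommunityTable(df, feature_kind="asv", normalization="rarefied")


def _site_coordinates(config: SimConfig, rng: np.random.Generator):
    """Site positions on a transect (or a square with ``two_dimensional``)."""
    n = config.n_sites
    frac = np.linspace(0.0, 1.0, n) if n > 1 else np.array([0.5])
    lat = _BASE_LAT + frac * config.extent_km / _KM_PER_DEG_LAT
    if config.two_dimensional:
        width_deg = 0.3 * config.extent_km / _KM_PER_DEG_LAT
        lon = _BASE_LON + rng.uniform(0.0, width_deg, size=n)
    else:
        lon = np.full(n, _BASE_LON) + rng.normal(0.0, 0.01, size=n)
    return lat, lon


def _gp_site_effects(rng: np.random.Generator, site_km: np.ndarray,
                     nugget_sd: float, spatial_sd: float, range_km: float,
                     n_features: int) -> np.ndarray:
    """Per-feature site effects: independent site distinctiveness (nugget)
    plus a spatially structured GP with exponential covariance."""
    n = site_km.size
    cov = nugget_sd ** 2 * np.eye(n)
    if spatial_sd > 0 and range_km > 0:
        cov = cov + spatial_sd ** 2 * np.exp(
            -np.abs(site_km[:, None] - site_km[None, :]) / range_km)
    if not cov.any():
        return np.zeros((n, n_features))
    chol = np.linalg.cholesky(cov + 1e-10 * np.eye(n))
    return chol @ rng.standard_normal((n, n_features))


def simulate_paired_design(config: SimConfig) -> tuple[CommunityTable, SampleMetadata]:
    """Full paired survey: counts plus metadata for every replicate core.

    Per-feature log intensity for a core in land use L at site i::

        log lam = log(meta) + site_effect(i, L) + landuse_effect(L)
                  - selection_strength * (env_i - optimum)^2
                  + Normal(0, dispersion_L)

    Counts are multinomial at ``depth`` on the softmax of ``log lam``.
    Site effects are drawn per land use from a Gaussian process along the
    transect whose covariance is an independent-site nugget
    (``site_sd_*^2``) plus a spatially structured exponential term
    (``spatial_sd_*^2 exp(-d/range)``): nearby sites share community
    structure, so similarity decays with distance (the substrate for
    distance-decay and spatial-partitioning analyses), while the nugget
    keeps sites individually distinctive.  A per-site lognormal
    distinctiveness multiplier (``site_scale_sd``), shared by the two
    paired plots of a site, makes some sites more idiosyncratic than
    others.  ``env`` is a standardized latitude gradient plus noise; pH and
    TC in the metadata are linear in that gradient, mimicking the survey's
    key environmental drivers.
    """
    rng = np.random.default_rng(config.seed)
    meta = simulate_metacommunity(config, rng)
    log_meta = np.log(meta)
    nf = config.n_features
    lat, lon = _site_coordinates(config, rng)
    frac = (lat - lat.mean()) / (lat.std() if lat.std() > 0 else 1.0)
    site_km = (lat - lat[0]) * _KM_PER_DEG_LAT

    landuse_effect = rng.normal(0.0, config.landuse_sd, size=nf)
    optimum = rng.uniform(-1.5, 1.5, size=nf)

    disp = {"AS": config.dispersion_as, "NS": config.dispersion_ns}
    site_effects = {
        lu: _gp_site_effects(rng, site_km, sd, sp_sd, rng_km, nf)
        for lu, sd, sp_sd, rng_km in (
            ("NS", config.site_sd_ns, config.spatial_sd_ns,
             config.spatial_range_ns_km),
            ("AS", config.site_sd_as, config.spatial_sd_as,
             config.spatial_range_as_km),
        )
    }
    # sites differ in how distinctive their soils are; the multiplier is a
    # property of the site, shared by its paired plots
    site_scale = np.exp(rng.normal(0.0, config.site_scale_sd, size=config.n_sites))
    for lu in site_effects:
        site_effects[lu] = site_effects[lu] * site_scale[:, None]

    rows, meta_rows, ids = [], [], []
    for i in range(config.n_sites):
        for lu in ("NS", "AS"):
            site_effect = site_effects[lu][i]
            env_plot = frac[i] + rng.normal(0.0, config.env_noise_sd)
            for rep in range(1, config.n_replicates + 1):
                env = env_plot + rng.normal(0.0, 0.05)
                log_lam = log_meta + site_effect
                if lu == "AS":
                    log_lam = log_lam + landuse_effect
                if config.selection_strength > 0:
                    log_lam = log_lam - config.selection_strength * (env - optimum) ** 2
                log_lam = log_lam + rng.normal(0.0, disp[lu], size=nf)
                p = np.exp(log_lam - log_lam.max())
                p /= p.sum()
                rows.append(rng.multinomial(config.depth, p))
                sid = f"S{i + 1:02d}_{lu}_{rep}"
                ids.append(sid)
                meta_rows.append(
                    {
                        "sample_id": sid,
                        "site_id": i + 1,
                        "land_use": lu,
                        "replicate": rep,
                        "latitude": lat[i],
                        "longitude": lon[i],
                        "env": env,
                        "pH": 6.8 - 0.6 * env + rng.normal(0.0, 0.05),
                        "TC": 25.0 + 6.0 * env + rng.normal(0.0, 0.5),
                    }
                )

    table = CommunityTable(
        pd.DataFrame(np.array(rows), index=ids, columns=_feature_ids(nf)),
        feature_kind="asv",
        normalization="rarefied",
    )
    metadata = SampleMetadata(pd.DataFrame(meta_rows))
    return table, metadata


def simulate_trait_table(n_genes: int, proportions, seed: int = 0,
                         gene_ids=None) -> pd.DataFrame:
    """Assign each gene one Y/A/S life-history category.

    ``proportions`` are the (Y, A, S) category probabilities and must sum
    to 1.  Returns a two-column frame (``gene_id``, ``category``).
    """
    props = np.asarray(proportions, dtype=float)
    if props.shape != (3,) or np.any(props < 0) or abs(props.sum() - 1.0) > 1e-9:
        raise ValueError("proportions must be 3 non-negative values summing to 1")
    rng = np.random.default_rng(seed)
    cats = rng.choice(np.array(["Y", "A", "S"]), size=n_genes, p=props)
    if gene_ids is None:
        gene_ids = [f"K{j:05d}" for j in range(1, n_genes + 1)]
    return pd.DataFrame({"gene_id": list(gene_ids), "category": cats})
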