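"""Synthetic trait-database generator with known ground truth.

Emulates the statistical structure of a multi-source tundra trait database:
log-normal traits with a three-level variance hierarchy (functional group /
species / within-species), a planted two-factor covariance across traits
(a plant-size axis and a resource-economics axis injected into species
effects), spatially clustered collection sites with distance-decaying
species turnover, an environmental-filtering term (species originating in
the same site cluster share a trait shift, so local communities are more
similar than the biome pool), and injected exact-duplicate records and
multiplicative outliers emulating unit errors.

Every draw is governed by a single integer seed, so identical configs give
byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .scan import haversine_km

__all__ = [
    "SyntheticConfig",
    "GroundTruth",
    "generate_sites",
    "generate_database",
    "generate_balanced_trait",
    "write_database",
]

KM_PER_DEG_LAT = 6371.0 * np.pi / 180.0

DEFAULT_TRAITS = ("plant height", "leaf area", "seed mass",
                  "LMA", "leaf nitrogen", "LDMC")
DEFAULT_MU_LOG = (-1.6, 1.6, 0.0, 4.1, 0.7, -1.2)
# size axis loads the stature traits, economics axis the leaf-resource
# traits (leaf nitrogen opposes LMA/LDMC along the acquisitive-conservative
# spectrum); magnitudes calibrated so biome-level variance fractions land
# near functional group ~0.26, species ~0.51, within ~0.23
DEFAULT_LOADINGS = (
    (0.38, 0.00),    # plant height
    (0.36, 0.08),    # leaf area
    (0.37, 0.00),    # seed mass
    (0.00, 0.37),    # LMA
    (0.07, -0.36),   # leaf nitrogen
    (0.00, 0.37),    # LDMC
)
FUNCTIONAL_GROUP_NAMES = ("deciduous shrub", "evergreen shrub",
                          "graminoid", "forb")


@dataclass
class SyntheticConfig:
    n_functional_groups: int = 4
    n_species: int = 90
    n_sites: int = 24
    n_site_clusters: int = 4
    cluster_radius_km: float = 40.0
    inter_cluster_km: float = 800.0
    obs_per_species_site: int = 4
    trait_names: tuple = DEFAULT_TRAITS
    mu_log: tuple = DEFAULT_MU_LOG
    var_group: tuple = (0.078,) * 6
    var_species: tuple = (0.011,) * 6
    var_within: tuple = (0.069,) * 6
    var_habitat: tuple = (0.0075,) * 6
    factor_loadings: tuple = DEFAULT_LOADINGS
    turnover_rate: float = 0.0015
    outlier_rate: float = 0.02
    outlier_factor: float = 50.0
    duplicate_rate: float = 0.02
    n_datasets: int = 40
    base_latitude: float = 68.0
    mat_range: tuple = (-8.0, 4.0)
    class_temp_range: tuple = (-3.0, 3.0)
    seed: int = 0

    def __post_init__(self) -> None:
        k = len(self.trait_names)
        for name in ("mu_log", "var_group", "var_species", "var_within",
                     "var_habitat"):
            if len(getattr(self, name)) != k:
                raise ValueError(f"{name} must have one entry per trait")
        if len(self.factor_loadings) != k:
            raise ValueError("factor_loadings must have one row per trait")
        for name in ("var_group", "var_species", "var_within", "var_habitat"):
            if any(v < 0 for v in getattr(self, name)):
                raise ValueError(f"{name} entries must be >= 0")
        for name in ("outlier_rate", "duplicate_rate"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.n_species < self.n_functional_groups:
            raise ValueError("n_species must be >= n_functional_groups")
        if not 1 <= self.n_site_clusters <= self.n_sites:
            raise ValueError("need n_sites >= n_site_clusters >= 1")

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(_plain(dataclasses.asdict(self)), fh,
                           sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "SyntheticConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        for key, val in raw.items():
            if isinstance(val, list):
                raw[key] = tuple(tuple(v) if isinstance(v, list) else v
                                 for v in val)
        return cls(**raw)


def _plain(obj):
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    return obj


@dataclass
class GroundTruth:
    """Planted truth for one generated database."""

    true_fractions: pd.DataFrame          # trait x (f_group, f_species, f_within)
    factor_scores: pd.DataFrame           # species x (size, economics)
    flags: pd.DataFrame                   # record_id, is_outlier, is_duplicate
    occupancy: pd.DataFrame               # species x site booleans

    def __post_init__(self) -> None:
        sums = self.true_fractions[["f_group", "f_species", "f_within"]].sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-12):
            raise ValueError("true fractions must sum to 1 per trait")


# ---------------------------------------------------------------------------
# sites


def generate_sites(config: SyntheticConfig) -> pd.DataFrame:
    """Place clustered sites and draw site temperatures.

    Cluster centres sit on one parallel, spaced so every between-cluster
    great-circle separation is at least ``inter_cluster_km``; sites scatter
    within ``cluster_radius_km / 2`` of their centre so the within-cluster
    spread (max pairwise distance) stays below ``cluster_radius_km``.
    """
    cfg = config
    if cfg.n_site_clusters > 1 and cfg.cluster_radius_km >= cfg.inter_cluster_km / 2:
        raise ValueError(
            "infeasible geometry: cluster_radius_km must be < inter_cluster_km/2")
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 101]))

    lat0 = cfg.base_latitude
    if cfg.n_site_clusters > 1:
        # exact inversion of the same-parallel great-circle distance
        margin = 1.02 * (cfg.inter_cluster_km + cfg.cluster_radius_km)
        arg = np.sin(margin / (2 * 6371.0)) / np.cos(np.radians(lat0))
        if arg >= 1.0:
            raise ValueError("clusters do not fit on the parallel")
        dlon = 2 * np.degrees(np.arcsin(arg))
        if dlon * cfg.n_site_clusters > 350.0:
            raise ValueError("clusters do not fit on the parallel")
    else:
        dlon = 0.0
    centres = [(lat0, -150.0 + k * dlon) for k in range(cfg.n_site_clusters)]

    cluster_of_site = np.arange(cfg.n_sites) % cfg.n_site_clusters
    rows = []
    for i in range(cfg.n_sites):
        clat, clon = centres[cluster_of_site[i]]
        r = rng.uniform(0.0, 0.49 * cfg.cluster_radius_km)
        theta = rng.uniform(0.0, 2 * np.pi)
        lat = clat + r * np.cos(theta) / KM_PER_DEG_LAT
        lon = clon + r * np.sin(theta) / (KM_PER_DEG_LAT * np.cos(np.radians(clat)))
        rows.append({
            "site_id": f"site{i:03d}",
            "latitude": lat,
            "longitude": lon,
            "mean_annual_temperature": rng.uniform(*cfg.mat_range),
            "class_temperature": rng.uniform(*cfg.class_temp_range),
            "cluster": int(cluster_of_site[i]),
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# database


def generate_database(config: SyntheticConfig) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Generate ``(records, sites, ground_truth)``.

    The log value of each clean record is
    ``mu_log[t] + a_g + (L[t] . z_s + h_c(s) + b_s) + e`` with the variance
    components of the config; values are exported on the natural scale.
    Species occupy sites with probability ``exp(-turnover_rate * d_home)``.
    """
    cfg = config
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 202]))
    sites = generate_sites(cfg)
    n_t = len(cfg.trait_names)
    n_s = cfg.n_species
    n_g = cfg.n_functional_groups

    group_of_species = np.arange(n_s) * n_g // n_s  # contiguous blocks
    group_names = [FUNCTIONAL_GROUP_NAMES[g % 4] if n_g <= 4
                   else f"group{g:02d}" for g in range(n_g)]
    species_names = np.array([f"Genus{i // 4:02d} species{i:03d}"
                              for i in range(n_s)])
    genus_names = np.array([f"Genus{i // 4:02d}" for i in range(n_s)])

    mu = np.asarray(cfg.mu_log, dtype=float)
    v_g = np.asarray(cfg.var_group, dtype=float)
    v_s = np.asarray(cfg.var_species, dtype=float)
    v_w = np.asarray(cfg.var_within, dtype=float)
    v_h = np.asarray(cfg.var_habitat, dtype=float)
    L = np.asarray(cfg.factor_loadings, dtype=float)   # n_t x 2

    a = rng.normal(0.0, np.sqrt(v_g), size=(n_g, n_t))
    z = rng.normal(0.0, 1.0, size=(n_s, 2))
    b = rng.normal(0.0, np.sqrt(v_s), size=(n_s, n_t))
    h = rng.normal(0.0, np.sqrt(v_h), size=(cfg.n_site_clusters, n_t))

    home = rng.integers(0, cfg.n_sites, size=n_s)
    home_cluster = sites["cluster"].to_numpy()[home]
    sp_eff = z @ L.T + b + h[home_cluster]             # n_s x n_t

    lat = sites["latitude"].to_numpy()
    lon = sites["longitude"].to_numpy()
    dist = np.zeros((cfg.n_sites, cfg.n_sites))
    for i in range(cfg.n_sites):
        dist[i] = haversine_km((lat[i], lon[i]), (lat, lon))
    p_occ = np.exp(-cfg.turnover_rate * dist[home])    # n_s x n_sites
    occ = rng.random((n_s, cfg.n_sites)) < p_occ
    occ[np.arange(n_s), home] = True

    sp_idx, site_idx = np.nonzero(occ)
    n_pairs = sp_idx.size
    m = cfg.obs_per_species_site
    # expand to (pair, obs, trait)
    sp_rec = np.repeat(sp_idx, m * n_t)
    site_rec = np.repeat(site_idx, m * n_t)
    trait_rec = np.tile(np.arange(n_t), n_pairs * m)
    e = rng.normal(0.0, 1.0, size=sp_rec.size) * np.sqrt(v_w)[trait_rec]
    logv = (mu[trait_rec] + a[group_of_species[sp_rec], trait_rec]
            + sp_eff[sp_rec, trait_rec] + e)
    values = np.exp(logv)

    n_rec = values.size
    records = pd.DataFrame({
        "record_id": [f"r{i:07d}" for i in range(n_rec)],
        "species": species_names[sp_rec],
        "genus": genus_names[sp_rec],
        "functional_group": np.array(group_names)[group_of_species[sp_rec]],
        "dataset_id": np.array([f"ds{k}" for k in
                                rng.integers(0, cfg.n_datasets, size=n_rec)]),
        "site_id": sites["site_id"].to_numpy()[site_rec],
        "latitude": lat[site_rec],
        "longitude": lon[site_rec],
        "trait": np.array(cfg.trait_names)[trait_rec],
        "value": values,
        "units": "synthetic",
    })

    is_outlier = np.zeros(n_rec, dtype=bool)
    n_out = int(np.floor(cfg.outlier_rate * n_rec))
    if n_out:
        out_idx = rng.choice(n_rec, size=n_out, replace=False)
        is_outlier[out_idx] = True
        records.loc[records.index[out_idx], "value"] *= cfg.outlier_factor
    records["is_outlier"] = is_outlier  # temporary, moved to flags below

    n_dup = int(np.floor(cfg.duplicate_rate * n_rec))
    if n_dup:
        src = rng.choice(n_rec, size=n_dup, replace=False)
        dups = records.iloc[src].copy()
        dups["record_id"] = [f"d{i:07d}" for i in range(n_dup)]
        dups["is_duplicate"] = True
        records["is_duplicate"] = False
        records = pd.concat([records, dups], ignore_index=True)
    else:
        records["is_duplicate"] = False

    flags = records[["record_id", "is_outlier", "is_duplicate"]].copy()
    records = records.drop(columns=["is_outlier", "is_duplicate"])

    species_var_total = v_s + (L ** 2).sum(axis=1) + v_h
    total = v_g + species_var_total + v_w
    truth = pd.DataFrame({
        "trait": list(cfg.trait_names),
        "f_group": v_g / total,
        "f_species": species_var_total / total,
        "f_within": v_w / total,
    })
    scores = pd.DataFrame(z, columns=["size", "economics"])
    scores.insert(0, "species", species_names)
    occupancy = pd.DataFrame(occ, index=species_names,
                             columns=sites["site_id"])
    occupancy.index.name = "species"
    gt = GroundTruth(true_fractions=truth, factor_scores=scores,
                     flags=flags, occupancy=occupancy)
    return records, sites, gt


def generate_balanced_trait(
    n_groups: int = 4,
    species_per_group: int = 25,
    obs_per_species: int = 20,
    fractions: tuple[float, float, float] = (0.25, 0.50, 0.25),
    total_var: float = 1.0,
    mu_log: float = 0.0,
    seed: int = 0,
    trait: str = "trait",
) -> pd.DataFrame:
    """Balanced nested draw for one trait (no spatial structure).

    Useful for checking estimators against the closed-form expected-mean-
    squares decomposition, which only exists for balanced designs.
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    rng = np.random.default_rng(seed)
    v = np.asarray(fractions) * total_var
    a, b, n = n_groups, species_per_group, obs_per_species
    g_eff = np.repeat(rng.normal(0, np.sqrt(v[0]), a), b * n)
    s_eff = np.repeat(rng.normal(0, np.sqrt(v[1]), a * b), n)
    e = rng.normal(0, np.sqrt(v[2]), a * b * n)
    logv = mu_log + g_eff + s_eff + e
    return pd.DataFrame({
        "functional_group": [f"group{k}" for k in np.repeat(np.arange(a), b * n)],
        "species": [f"sp{k:04d}" for k in np.repeat(np.arange(a * b), n)],
        "trait": trait,
        "value": np.exp(logv),
    })


def write_database(records: pd.DataFrame, sites: pd.DataFrame,
                   ground_truth: GroundTruth, config: SyntheticConfig,
                   outdir) -> None:
    """Write the database as delimited text plus ground-truth sidecars."""
    import pathlib

    out = pathlib.Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    records.to_csv(out / "records.csv", index=False)
    sites.to_csv(out / "sites.csv", index=False)
    ground_truth.true_fractions.to_csv(out / "truth_fractions.csv", index=False)
    ground_truth.factor_scores.to_csv(out / "truth_factor_scores.csv", index=False)
    ground_truth.flags.to_csv(out / "truth_flags.csv", index=False)
    ground_truth.occupancy.to_csv(out / "truth_occupancy.csv")
    config.to_yaml(out / "config.yaml")
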