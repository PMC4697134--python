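"""Synthetic two-stage cluster nutrition surveys.

This module generates child-level survey data with the statistical
structure that the spatial-temporal model assumes: communities (clusters)
sampled within districts and livelihood strata, ~30 households per
cluster, children aged 6-59 months with binary morbidity/vaccination
covariates, household composition, maternal measurements, spatially
correlated environmental surfaces (EVI, rainfall, temperature), and
Bernoulli malnutrition outcomes driven by a logistic linear predictor

    eta = alpha + beta' x + u_cluster + v_cluster + w_district + t_round + season

where ``u`` is an intrinsic CAR field on the cluster neighbourhood graph,
``v`` and ``w`` are exchangeable Gaussian effects and ``t`` is a first-order
random walk over survey rounds.  Rounds alternate between the two rainy
seasons (Gu, April-June; Deyr, October-November), two per year.

Anthropometry is emitted as z-scores directly: each child's weight-for-
height and height-for-age z-scores are drawn from unit-variance Gaussians
whose means are shifted so that the probability of falling below the -2
case threshold equals the inverse-logit of the child's linear predictor
(and likewise for MUAC below 125 mm); thresholding therefore reproduces
the intended Bernoulli outcome exactly.

Default parameter values (marginal covariate prevalences, effect sizes,
random-effect precisions, calibrated intercepts) live in
``data/defaults.json`` and reproduce the marginal prevalences of wasting,
stunting and low MUAC of roughly 21%, 31% and 36% reported for Somali
surveys from 2007-2010.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit, ndtri

from .spatial import build_adjacency, haversine_km, icar_precision, sample_icar, write_edge_list

__all__ = [
    "GeneratorConfig",
    "SurveyDataset",
    "default_config",
    "generate_survey",
    "generate_env_field",
    "INDICATORS",
    "COVARIATE_COLUMNS",
]

INDICATORS = ("wasting", "stunting", "low_muac")

#: canonical covariate name -> column of the records/clusters tables
COVARIATE_COLUMNS = {
    "female": "female",
    "age_12_23": "age_12_23",
    "age_24_59": "age_24_59",
    "fever": "fever_2wk",
    "diarrhoea": "diarrhoea_2wk",
    "ari": "ari_2wk",
    "measles": "measles_vax",
    "polio": "polio_vax",
    "vita": "vitA_6mo",
    "access_protein": "access_protein",
    "access_carb": "access_carb",
    "access_fruitveg": "access_fruitveg",
    "household_size": "household_size",
    "n_under5": "n_under5",
    "head_female": "head_female",
    "mother_muac_mm": "mother_muac_mm",
    "evi": "evi",
    "rainfall": "rainfall",
    "temperature": "temperature",
}

# synthetic study region (lon/lat decimal degrees), a 10 x 10 degree box
REGION_LON = (42.0, 52.0)
REGION_LAT = (0.0, 10.0)

_SEASONS = ("Gu", "Deyr")  # rounds alternate starting Gu of the first year
_FIRST_YEAR = 2007


@dataclass
class GeneratorConfig:
    """True parameters and design sizes for one synthetic survey.

    ``beta`` maps each indicator to a ``{covariate: log-odds}`` dict;
    ``intercept`` and ``season_effect`` (Gu relative to Deyr) are log-odds.
    Precisions are inverse variances of the random-effect terms; ``inf``
    pins a term at zero.
    """

    n_districts: int = 24
    n_clusters: int = 1064
    households_per_cluster: int = 30
    rounds: int = 8
    zone_labels: tuple = ("NW", "NE", "SC")
    zone_weights: tuple = (0.22, 0.15, 0.63)
    livelihood_labels: tuple = ("agro-pastoral", "pastoral", "riverine", "IDP", "urban")
    livelihood_weights: tuple = (0.42, 0.27, 0.16, 0.11, 0.04)
    covariate_marginals: dict = field(default_factory=dict)
    household: dict = field(default_factory=dict)
    beta: dict = field(default_factory=dict)
    intercept: dict = field(default_factory=dict)
    season_effect: dict = field(default_factory=dict)
    tau_spatial: float = 25.0
    tau_unstruct: float = 25.0
    tau_district: float = 25.0
    tau_temporal: float = 100.0
    env_field: dict = field(default_factory=dict)
    muac_sd: float = 11.0
    knn_k: int = 5
    missing_coord_clusters: int = 0
    seed: int = 0

    def __post_init__(self):
        for name in ("n_districts", "n_clusters", "households_per_cluster", "rounds"):
            if int(getattr(self, name)) < 1:
                raise ValueError(f"{name} must be >= 1")
        for name in ("tau_spatial", "tau_unstruct", "tau_district", "tau_temporal"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        if len(self.zone_labels) != 3:
            raise ValueError("exactly 3 zone labels expected")
        if abs(sum(self.livelihood_weights) - 1.0) > 1e-9:
            raise ValueError("livelihood weights must sum to 1")
        if abs(sum(self.zone_weights) - 1.0) > 1e-9:
            raise ValueError("zone weights must sum to 1")
        for ind in self.beta:
            if ind not in INDICATORS:
                raise ValueError(f"unknown indicator {ind!r}")
            unknown = set(self.beta[ind]) - set(COVARIATE_COLUMNS)
            if unknown:
                raise ValueError(f"unknown covariates in beta[{ind!r}]: {sorted(unknown)}")

    def replace(self, **changes) -> "GeneratorConfig":
        return dataclasses.replace(self, **changes)

    def to_json(self, path) -> None:
        d = dataclasses.asdict(self)
        Path(path).write_text(json.dumps(d, indent=2, default=list))

    @classmethod
    def from_json(cls, path) -> "GeneratorConfig":
        d = json.loads(Path(path).read_text())
        for key in ("zone_labels", "zone_weights", "livelihood_labels", "livelihood_weights"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


def default_config(**overrides) -> GeneratorConfig:
    """The calibrated default configuration shipped with the package."""
    raw = json.loads(resources.files("nutsurv.data").joinpath("defaults.json").read_text())
    beta = {
        ind: {cov: float(np.log(or_)) for cov, or_ in raw["effects_or"][ind].items()}
        for ind in INDICATORS
    }
    season = {ind: float(np.log(raw["season_or_gu"][ind])) for ind in INDICATORS}
    cfg = dict(
        n_districts=raw["design"]["n_districts"],
        n_clusters=raw["design"]["n_clusters"],
        households_per_cluster=raw["design"]["households_per_cluster"],
        rounds=raw["design"]["rounds"],
        zone_labels=tuple(raw["zones"]["labels"]),
        zone_weights=tuple(raw["zones"]["weights"]),
        livelihood_labels=tuple(raw["livelihoods"]["labels"]),
        livelihood_weights=tuple(raw["livelihoods"]["weights"]),
        covariate_marginals=dict(raw["covariate_marginals"]),
        household=dict(raw["household"]),
        beta=beta,
        intercept={ind: float(raw["intercept"][ind]) for ind in INDICATORS},
        season_effect=season,
        tau_spatial=raw["precisions"]["spatial"],
        tau_unstruct=raw["precisions"]["unstruct"],
        tau_district=raw["precisions"]["district"],
        tau_temporal=raw["precisions"]["temporal"],
        env_field={k: dict(v) for k, v in raw["env_fields"].items()},
        muac_sd=raw["muac_sd"],
    )
    cfg.update(overrides)
    return GeneratorConfig(**cfg)


@dataclass
class SurveyDataset:
    """Child records plus the cluster/district survey structure.

    ``records`` has one row per child; ``clusters`` one row per cluster
    site (id, lon, lat, district, zone, livelihood, round, season and
    environmental covariates).  ``provenance`` is the generating config or
    the string ``"external"`` for loaded data.
    """

    records: pd.DataFrame
    clusters: pd.DataFrame
    districts: list
    provenance: object = "external"

    def __post_init__(self):
        known = set(self.clusters["cluster_id"])
        unknown = set(self.records["cluster_id"]) - known
        if unknown:
            raise ValueError(f"records reference unknown clusters: {sorted(unknown)[:5]}")
        missing_d = set(self.clusters["district_id"]) - set(self.districts)
        if missing_d:
            raise ValueError(f"clusters reference unknown districts: {sorted(missing_d)[:5]}")
        per = self.clusters.groupby("cluster_id")["round"].nunique()
        if (per > 1).any():
            raise ValueError("a cluster may belong to exactly one survey round")

    @property
    def n_children(self) -> int:
        return len(self.records)

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)

    def adjacency(self, method: str = "knn", k: int = 5):
        sites = self.clusters.rename(columns={"cluster_id": "id"})[
            ["id", "lon", "lat", "district_id"]
        ].dropna(subset=["lon", "lat"])
        return build_adjacency(sites, method=method, k=k)

    def write(self, out_dir) -> None:
        """Write records/clusters CSVs, the edge list and the config JSON."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.records.to_csv(out / "records.csv", index=False)
        self.clusters.to_csv(out / "clusters.csv", index=False)
        if self.clusters[["lon", "lat"]].notna().all(axis=1).sum() >= 2:
            write_edge_list(self.adjacency(), out / "edges.txt")
        if isinstance(self.provenance, GeneratorConfig):
            self.provenance.to_json(out / "config.json")

    @classmethod
    def read(cls, in_dir) -> "SurveyDataset":
        p = Path(in_dir)
        records = pd.read_csv(p / "records.csv")
        clusters = pd.read_csv(p / "clusters.csv")
        prov = "external"
        if (p / "config.json").exists():
            prov = GeneratorConfig.from_json(p / "config.json")
        return cls(
            records=records,
            clusters=clusters,
            districts=sorted(clusters["district_id"].unique()),
            provenance=prov,
        )


def generate_env_field(sites: pd.DataFrame, range_km: float, variance: float,
                       bounds=None, seed=None) -> np.ndarray:
    """Spatially correlated surface values at survey sites.

    Draws a zero-mean Gaussian process with exponential covariance
    ``variance * exp(-d/range_km)`` over haversine distances, then, when
    ``bounds=(lo, hi)`` is given, maps it through the Gaussian CDF onto the
    interval (uniform marginal on ``[lo, hi]``).  ``variance=0`` yields a
    constant field.  Coincident sites receive identical values.
    """
    if len(sites) < 1:
        raise ValueError("need at least one site")
    if range_km <= 0:
        raise ValueError("range_km must be positive")
    if variance < 0:
        raise ValueError("variance must be non-negative")
    rng = np.random.default_rng(seed)
    lon = sites["lon"].to_numpy(dtype=float)
    lat = sites["lat"].to_numpy(dtype=float)
    coords = np.column_stack([lon, lat])
    uniq, inverse = np.unique(coords, axis=0, return_inverse=True)
    m = len(uniq)
    if variance == 0:
        z = np.zeros(m)
    else:
        d = haversine_km(uniq[:, 0][:, None], uniq[:, 1][:, None],
                         uniq[:, 0][None, :], uniq[:, 1][None, :])
        cov = variance * np.exp(-d / range_km)
        cov[np.diag_indices(m)] += 1e-9 * variance
        chol = np.linalg.cholesky(cov)
        z = chol @ rng.standard_normal(m)
    z = z[inverse]
    if bounds is None:
        return z
    lo, hi = bounds
    if variance == 0:
        return np.full(len(z), lo + 0.5 * (hi - lo))
    from scipy.special import ndtr

    return lo + (hi - lo) * ndtr(z / np.sqrt(variance))


def _rw1(rng, n, tau):
    """Sum-to-zero first-order random walk with increment precision tau."""
    if n == 1 or np.isinf(tau):
        return np.zeros(n)
    steps = rng.normal(0.0, 1.0 / np.sqrt(tau), size=n - 1)
    t = np.concatenate([[0.0], np.cumsum(steps)])
    return t - t.mean()


def _truncnorm(rng, mean, sd, lo, hi, size):
    x = rng.normal(mean, sd, size=size)
    return np.clip(x, lo, hi)


def generate_survey(config: GeneratorConfig, seed=None) -> SurveyDataset:
    """Generate one synthetic survey dataset.

    Identical ``config`` (including ``config.seed``, unless overridden by
    ``seed``) produces a bitwise-identical dataset.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n_d, n_c, rounds = config.n_districts, config.n_clusters, config.rounds

    # --- districts tile the region as a grid; zones are contiguous blocks
    g = int(np.ceil(np.sqrt(n_d)))
    district_ids = [f"d{i:03d}" for i in range(n_d)]
    cell_lon = (REGION_LON[1] - REGION_LON[0]) / g
    cell_lat = (REGION_LAT[1] - REGION_LAT[0]) / g
    d_row, d_col = np.divmod(np.arange(n_d), g)
    zone_cut = np.cumsum(np.asarray(config.zone_weights))[:-1]
    # districts ordered by grid position; first block NW, then NE, then SC
    frac = (np.arange(n_d) + 0.5) / n_d
    zone_idx = np.searchsorted(zone_cut, frac)
    district_zone = np.asarray(config.zone_labels)[zone_idx]

    # --- clusters: district assignment, position, stratum, round
    cl_district = rng.integers(0, n_d, size=n_c)
    lon = REGION_LON[0] + (d_col[cl_district] + rng.random(n_c)) * cell_lon
    lat = REGION_LAT[0] + (d_row[cl_district] + rng.random(n_c)) * cell_lat
    cluster_ids = [f"c{i:04d}" for i in range(n_c)]
    livelihood = rng.choice(
        list(config.livelihood_labels), size=n_c, p=list(config.livelihood_weights)
    )
    cl_round = np.arange(n_c) % rounds
    cl_round = rng.permutation(cl_round)
    season = np.where(cl_round % 2 == 0, _SEASONS[0], _SEASONS[1])
    year = _FIRST_YEAR + cl_round // 2

    clusters = pd.DataFrame(
        {
            "cluster_id": cluster_ids,
            "lon": lon,
            "lat": lat,
            "district_id": np.asarray(district_ids)[cl_district],
            "zone": district_zone[cl_district],
            "livelihood": livelihood,
            "round": cl_round,
            "year": year,
            "season": season,
        }
    )

    # --- environmental surfaces at cluster sites
    env_defaults = {
        "evi": {"range_km": 110.0, "variance": 1.0, "bounds": (0.0, 1.0)},
        "rainfall": {"range_km": 160.0, "variance": 1.0, "bounds": (0.0, 600.0)},
        "temperature": {"range_km": 220.0, "variance": 1.0, "bounds": (18.0, 38.0)},
    }
    env_cfg = {**env_defaults, **{k: {**env_defaults.get(k, {}), **v} for k, v in config.env_field.items()}}
    for name in ("evi", "rainfall", "temperature"):
        c = env_cfg[name]
        clusters[name] = generate_env_field(
            clusters, c["range_km"], c["variance"], bounds=tuple(c["bounds"]), seed=rng
        )

    # --- random effects on clusters / districts / rounds
    if np.isinf(config.tau_spatial):
        u = np.zeros(n_c)
    else:
        graph = build_adjacency(
            clusters.rename(columns={"cluster_id": "id"}), method="knn", k=config.knn_k
        )
        prec = icar_precision(graph)
        u_by_node = sample_icar(prec, config.tau_spatial, seed=rng)
        order = {node: i for i, node in enumerate(graph.nodes)}
        u = u_by_node[[order[c] for c in cluster_ids]]
    v = np.zeros(n_c) if np.isinf(config.tau_unstruct) else rng.normal(
        0.0, 1.0 / np.sqrt(config.tau_unstruct), size=n_c
    )
    w = np.zeros(n_d) if np.isinf(config.tau_district) else rng.normal(
        0.0, 1.0 / np.sqrt(config.tau_district), size=n_d
    )
    t_round = _rw1(rng, rounds, config.tau_temporal)

    # --- households
    hh_per = config.households_per_cluster
    n_hh = n_c * hh_per
    hh_cluster = np.repeat(np.arange(n_c), hh_per)
    hh = dict(config.household)
    size_mean = hh.get("size_mean", 6.0)
    household_size = 1 + rng.poisson(max(size_mean - 1.0, 0.1), size=n_hh)
    under5 = np.clip(
        rng.poisson(hh.get("under5_mean", 2.0), size=n_hh),
        int(hh.get("under5_min", 1)),
        int(hh.get("under5_max", 4)),
    )
    head_female = rng.random(n_hh) < hh.get("head_female", 0.19)
    mother_age = _truncnorm(rng, hh.get("mother_age_mean", 31.0), hh.get("mother_age_sd", 7.0),
                            15.0, 49.0, n_hh)
    mother_muac = _truncnorm(rng, hh.get("mother_muac_mean", 255.0), hh.get("mother_muac_sd", 25.0),
                             181.0, 299.0, n_hh)

    # --- children: one row per under-5 child in each sampled household
    n_child_hh = under5  # surveyed children per household
    child_hh = np.repeat(np.arange(n_hh), n_child_hh)
    n_children = len(child_hh)
    ci = hh_cluster[child_hh]  # cluster index per child
    marg = {
        "female": 0.5, "fever": 0.21, "diarrhoea": 0.17, "ari": 0.26,
        "measles": 0.50, "polio": 0.82, "vita": 0.50,
        "access_protein": 0.92, "access_carb": 0.92, "access_fruitveg": 0.41,
    }
    marg.update(config.covariate_marginals)
    age = rng.integers(6, 60, size=n_children)
    draws = {k: (rng.random(n_children) < marg[k]) for k in marg}

    records = pd.DataFrame(
        {
            "child_id": [f"ch{i:06d}" for i in range(n_children)],
            "cluster_id": np.asarray(cluster_ids)[ci],
            "household_id": [f"h{i:05d}" for i in child_hh],
            "age_months": age,
            "sex": np.where(draws["female"], "female", "male"),
            "fever_2wk": draws["fever"].astype(int),
            "diarrhoea_2wk": draws["diarrhoea"].astype(int),
            "ari_2wk": draws["ari"].astype(int),
            "measles_vax": draws["measles"].astype(int),
            "polio_vax": draws["polio"].astype(int),
            "vitA_6mo": draws["vita"].astype(int),
            "access_protein": draws["access_protein"].astype(int),
            "access_carb": draws["access_carb"].astype(int),
            "access_fruitveg": draws["access_fruitveg"].astype(int),
            "household_size": household_size[child_hh],
            "n_under5": under5[child_hh],
            "head_sex": np.where(head_female[child_hh], "female", "male"),
            "mother_age_years": np.round(mother_age[child_hh], 1),
            "mother_muac_mm": np.round(mother_muac[child_hh], 1),
        }
    )
    records["age_band"] = pd.cut(
        records["age_months"], bins=[5, 11, 23, 59], labels=["6-11", "12-23", "24-59"]
    ).astype(str)
    records["female"] = (records["sex"] == "female").astype(int)
    records["head_female"] = (records["head_sex"] == "female").astype(int)
    records["age_12_23"] = (records["age_band"] == "12-23").astype(int)
    records["age_24_59"] = (records["age_band"] == "24-59").astype(int)

    # --- linear predictors and outcomes per indicator
    cl_cols = clusters.set_index("cluster_id")
    for env_name in ("evi", "rainfall", "temperature"):
        records[env_name] = cl_cols[env_name].to_numpy()[ci]
    is_gu = (season[ci] == "Gu").astype(float)
    di = cl_district[ci]
    ri = cl_round[ci]

    z_shift = {}
    for ind in INDICATORS:
        eta = np.full(n_children, config.intercept.get(ind, 0.0))
        for cov, b in config.beta.get(ind, {}).items():
            eta = eta + b * records[COVARIATE_COLUMNS[cov]].to_numpy(dtype=float)
        eta = eta + u[ci] + v[ci] + w[di] + t_round[ri]
        eta = eta + config.season_effect.get(ind, 0.0) * is_gu
        z_shift[ind] = ndtri(expit(eta))

    # z-scores / MUAC with exceedance probability equal to inverse-logit(eta)
    records["whz"] = np.round(-2.0 - z_shift["wasting"] + rng.standard_normal(n_children), 3)
    records["haz"] = np.round(-2.0 - z_shift["stunting"] + rng.standard_normal(n_children), 3)
    records["muac_mm"] = np.round(
        125.0 - config.muac_sd * z_shift["low_muac"]
        + config.muac_sd * rng.standard_normal(n_children),
        1,
    )
    records["wasted"] = (records["whz"] < -2.0).astype(int)
    records["stunted"] = (records["haz"] < -2.0).astype(int)
    records["low_muac"] = (records["muac_mm"] < 125.0).astype(int)

    # optionally knock out coordinates for a few clusters (exclusion testing)
    if config.missing_coord_clusters > 0:
        drop = rng.choice(n_c, size=min(config.missing_coord_clusters, n_c), replace=False)
        clusters.loc[clusters.index[drop], ["lon", "lat"]] = np.nan

    records = records.drop(columns=["female", "head_female", "age_12_23", "age_24_59",
                                    "evi", "rainfall", "temperature"])
    return SurveyDataset(
        records=records,
        clusters=clusters,
        districts=district_ids,
        provenance=config,
    )
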