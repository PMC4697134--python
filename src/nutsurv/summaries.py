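"""Descriptive statistics, exclusions, seasonal averaging and stratified fits.

These operations mirror the standard reporting around a cluster-survey
malnutrition analysis: a descriptive table of covariates and indicator
prevalences (overall and by zone / livelihood stratum), explicit exclusion
of clusters whose coordinates cannot be resolved, seasonal averaging of
monthly environmental series over the four Somali seasons (Jilal Dec-Mar,
Gu Apr-Jun, Hagaa Jul-Sep, Deyr Oct-Nov), and independent per-zone model
fits for comparing covariate effects across zones.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .mcmc import SamplerConfig, fit
from .model import ModelSpec, OUTCOME_COLUMNS

__all__ = [
    "SeasonWindows",
    "DescriptiveTable",
    "descriptive_table",
    "exclude_unlocated",
    "seasonal_average",
    "fit_by_zone",
]


@dataclass(frozen=True)
class SeasonWindows:
    """Month windows (1-12) of the four Somali seasons; they partition the year."""

    jilal: tuple = (12, 1, 2, 3)
    gu: tuple = (4, 5, 6)
    hagaa: tuple = (7, 8, 9)
    deyr: tuple = (10, 11)

    def __post_init__(self):
        months = [m for w in (self.jilal, self.gu, self.hagaa, self.deyr) for m in w]
        if sorted(months) != list(range(1, 13)):
            raise ValueError("season windows must partition the 12 months")

    def items(self):
        return [("Jilal", self.jilal), ("Gu", self.gu), ("Hagaa", self.hagaa), ("Deyr", self.deyr)]


def seasonal_average(monthly, windows: SeasonWindows = SeasonWindows()) -> dict:
    """Per-season means of a monthly series (Jan-first, length a multiple of 12).

    Multi-year series are averaged within each season window per year and
    then across years, so every month of a given season carries equal
    weight regardless of how many years are supplied.
    """
    x = np.asarray(monthly, dtype=float)
    if x.ndim != 1 or len(x) == 0 or len(x) % 12 != 0:
        raise ValueError("monthly series length must be a positive multiple of 12")
    years = x.reshape(-1, 12)
    out = {}
    for name, months in windows.items():
        idx = [m - 1 for m in months]
        out[name] = float(years[:, idx].mean())
    return out


@dataclass
class DescriptiveTable:
    """Survey summary: per-variable statistics and indicator prevalences."""

    n_children: int
    n_clusters: int
    variables: pd.DataFrame  # variable, kind, n, value (proportion or mean), dispersion
    prevalence: dict  # indicator -> proportion
    by_zone: pd.DataFrame
    by_livelihood: pd.DataFrame
    exclusions: dict = field(default_factory=dict)

    def to_csv(self, path) -> None:
        self.variables.to_csv(path, index=False)


_BINARY_VARS = {
    "female": ("sex", "female"),
    "head_female": ("head_sex", "female"),
    "fever_2wk": None,
    "diarrhoea_2wk": None,
    "ari_2wk": None,
    "measles_vax": None,
    "polio_vax": None,
    "vitA_6mo": None,
    "access_protein": None,
    "access_carb": None,
    "access_fruitveg": None,
}
_CONTINUOUS_VARS = ["age_months", "household_size", "n_under5", "mother_age_years",
                    "mother_muac_mm", "whz", "haz", "muac_mm"]


def descriptive_table(dataset) -> DescriptiveTable:
    """Descriptive statistics of a survey dataset.

    Prevalence of each indicator is the count of flagged children over the
    count of children with a non-missing flag.  Children in clusters
    without valid coordinates are *included* here (they are survey data);
    use :func:`exclude_unlocated` before modelling.
    """
    rec = dataset.records
    if len(rec) == 0:
        raise ValueError("empty dataset")
    rows = []
    for var, derive in _BINARY_VARS.items():
        if derive is not None:
            col_name, level = derive
            if col_name not in rec.columns:
                continue
            col = (rec[col_name] == level).astype(float)
        elif var in rec.columns:
            col = rec[var].astype(float)
        else:
            continue
        n = int(col.notna().sum())
        p = float(col.mean())
        rows.append({"variable": var, "kind": "proportion", "n": n, "value": p,
                     "dispersion": float(np.sqrt(p * (1 - p)))})
    for var in _CONTINUOUS_VARS:
        if var not in rec.columns:
            continue
        col = rec[var]
        rows.append({"variable": var, "kind": "mean", "n": int(col.notna().sum()),
                     "value": float(col.mean()), "dispersion": float(col.std())})

    prevalence = {}
    for ind, col in OUTCOME_COLUMNS.items():
        flags = rec[col]
        prevalence[ind] = float(flags.sum() / flags.notna().sum())

    merged = rec.merge(dataset.clusters[["cluster_id", "zone", "livelihood"]], on="cluster_id")
    flag_cols = list(OUTCOME_COLUMNS.values())

    def strata(key):
        g = merged.groupby(key, observed=True)
        out = g[flag_cols].mean()
        out.insert(0, "n", g.size())
        return out.reset_index()

    return DescriptiveTable(
        n_children=len(rec),
        n_clusters=len(dataset.clusters),
        variables=pd.DataFrame(rows),
        prevalence=prevalence,
        by_zone=strata("zone"),
        by_livelihood=strata("livelihood"),
    )


def exclude_unlocated(dataset):
    """Drop every record belonging to a cluster without valid coordinates.

    Returns ``(retained_dataset, report)`` where the report lists excluded
    cluster ids and child counts; retained + excluded equals the input.
    """
    cl = dataset.clusters
    bad = cl.loc[cl["lon"].isna() | cl["lat"].isna(), "cluster_id"]
    bad_set = set(bad)
    mask = dataset.records["cluster_id"].isin(bad_set)
    excluded_counts = (
        dataset.records.loc[mask].groupby("cluster_id").size().to_dict()
    )
    for cid in bad_set - set(excluded_counts):
        excluded_counts[cid] = 0
    report = {
        "n_clusters_excluded": len(bad_set),
        "n_children_excluded": int(mask.sum()),
        "excluded_clusters": {k: int(v) for k, v in sorted(excluded_counts.items())},
    }
    retained_cl = cl[~cl["cluster_id"].isin(bad_set)].reset_index(drop=True)
    retained_rec = dataset.records[~mask].reset_index(drop=True)
    if len(retained_rec) == 0:
        warnings.warn("all clusters lack coordinates; retained dataset is empty")
    return _bare_dataset(retained_rec, retained_cl, dataset), report


def _bare_dataset(records, clusters, parent):
    from .synthetic import SurveyDataset

    ds = SurveyDataset.__new__(SurveyDataset)
    ds.records = records
    ds.clusters = clusters
    ds.districts = parent.districts
    ds.provenance = parent.provenance
    return ds


def fit_by_zone(dataset, spec: ModelSpec = None, config: SamplerConfig = None,
                min_clusters: int = 10) -> dict:
    """Fit the model independently within each zone.

    Zones with fewer than ``min_clusters`` clusters are skipped with a
    warning.  Returns ``{zone: PosteriorResult}``; covariates align across
    zones because every fit uses the same ModelSpec.
    """
    spec = spec or ModelSpec()
    config = config or SamplerConfig()
    if "zone" not in dataset.clusters.columns:
        raise ValueError("dataset has no zone column")
    zones = [z for z in pd.unique(dataset.clusters["zone"]) if pd.notna(z)]
    if not zones:
        raise ValueError("dataset has no zone labels")
    results = {}
    for zone in zones:
        cl = dataset.clusters[dataset.clusters["zone"] == zone].reset_index(drop=True)
        if len(cl) < min_clusters:
            warnings.warn(f"zone {zone!r}: only {len(cl)} clusters, skipped")
            continue
        keep = set(cl["cluster_id"])
        rec = dataset.records[dataset.records["cluster_id"].isin(keep)].reset_index(drop=True)
        sub = _bare_dataset(rec, cl, dataset)
        results[zone] = fit(sub, spec, config)
    return results


def zone_effect_table(results: dict, level: float = 0.95) -> pd.DataFrame:
    """Long-format OR/CrI table aligned across zones."""
    frames = []
    for zone, res in results.items():
        tab = res.effects(level=level)
        tab.insert(0, "zone", zone)
        frames.append(tab)
    return pd.concat(frames, ignore_index=True)
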