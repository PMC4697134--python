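import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
from hypothesis import HealthCheck, settings

from nutsurv.model import ModelData, ModelSpec
from nutsurv.synthetic import default_config, generate_survey

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_survey():
    """A reduced synthetic survey (~1500 children) shared across tests."""
    cfg = default_config(n_clusters=60, households_per_cluster=12, n_districts=12, seed=2024)
    return generate_survey(cfg)


def make_bare_design(y, X, colnames, indicator="wasting"):
    """ModelData for a plain logistic regression (no random terms)."""
    n = len(y)
    spec = ModelSpec(indicator=indicator, fixed_covariates=tuple(colnames[1:]), random_terms=())
    return ModelData(
        spec=spec,
        y=np.asarray(y, dtype=float),
        X=np.asarray(X, dtype=float),
        colnames=list(colnames),
        cluster_ids=[],
        cluster_codes=np.zeros(n, dtype=int),
        district_ids=[],
        district_codes=np.zeros(n, dtype=int),
        round_values=[],
        round_codes=np.zeros(n, dtype=int),
        R_rw1=sp.csr_matrix((0, 0)),
    )


def make_sites(coords, ids=None):
    """Sites DataFrame from a list of (lon, lat) pairs."""
    coords = np.asarray(coords, dtype=float)
    if ids is None:
        ids = [f"s{i}" for i in range(len(coords))]
    return pd.DataFrame({"id": ids, "lon": coords[:, 0], "lat": coords[:, 1]})
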