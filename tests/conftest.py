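import numpy as np
import pandas as pd
import pytest

from traitvar.synthetic import SyntheticConfig, generate_database


@pytest.fixture(scope="session")
def default_db():
    """One default-sized synthetic database with ground truth."""
    return generate_database(SyntheticConfig(seed=7))


@pytest.fixture(scope="session")
def clean_world_db():
    """Synthetic database with no injected outliers or duplicates."""
    cfg = SyntheticConfig(seed=11, outlier_rate=0.0, duplicate_rate=0.0)
    return generate_database(cfg)


@pytest.fixture(scope="session")
def small_db():
    """A small database for fast structural tests."""
    cfg = SyntheticConfig(seed=3, n_species=24, n_sites=9, n_site_clusters=3,
                          obs_per_species_site=3, n_datasets=12,
                          outlier_rate=0.0, duplicate_rate=0.0)
    return generate_database(cfg)


def nested_sample(seed, a=4, b=6, n=8, v=(0.3, 0.5, 0.4)):
    """Balanced nested draw returned as a records DataFrame (log-normal)."""
    rng = np.random.default_rng(seed)
    g = np.repeat(np.arange(a), b * n)
    s = np.repeat(np.arange(a * b), n)
    y = (np.repeat(rng.normal(0, np.sqrt(v[0]), a), b * n)
         + np.repeat(rng.normal(0, np.sqrt(v[1]), a * b), n)
         + rng.normal(0, np.sqrt(v[2]), a * b * n))
    return pd.DataFrame({
        "functional_group": [f"g{k}" for k in g],
        "species": [f"s{k:03d}" for k in s],
        "trait": "trait",
        "value": np.exp(y),
    })


def ems_balanced_fractions(records):
    """Closed-form expected-mean-squares decomposition for a balanced
    nested design (independent oracle; truncation at zero applied)."""
    df = records.copy()
    df["y"] = np.log(df["value"].astype(float))
    groups = sorted(df["functional_group"].unique())
    a = len(groups)
    b = df.groupby("functional_group")["species"].nunique().iloc[0]
    n = df.groupby("species").size().iloc[0]
    ybar = df["y"].mean()
    gm = df.groupby("functional_group")["y"].mean()
    sm = df.groupby(["functional_group", "species"])["y"].mean()
    ss_g = b * n * ((gm - ybar) ** 2).sum()
    ss_s = n * ((sm - gm.reindex(sm.index.get_level_values(0)).values) ** 2).sum()
    ss_e = ((df["y"] - sm.reindex(list(zip(df["functional_group"],
                                           df["species"]))).values) ** 2).sum()
    ms_g = ss_g / (a - 1)
    ms_s = ss_s / (a * (b - 1))
    ms_e = ss_e / (a * b * (n - 1))
    s2_e = ms_e
    s2_s = (ms_s - ms_e) / n
    s2_g = (ms_g - ms_s) / (b * n)
    comps = np.clip([s2_g, s2_s, s2_e], 0.0, None)
    return comps / comps.sum(), np.array([s2_g, s2_s, s2_e])
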