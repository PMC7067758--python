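"""Data model and readers/writers for long-format trait tables.

One row of a trait table is one measurement of one trait on one individual,
with taxonomic (species, genus, functional group), dataset and spatial
(site, latitude/longitude) provenance.  Readers validate invariants row by
row and report violations with row numbers instead of silently coercing.

Also houses the derived classifications shared by the analysis stages:
the biome species pool (survey species plus species collected at sites
with mean annual temperature below 0 degC), the climate-extreme subset
(north of the Arctic Circle or MAT < 0 degC), and species temperature
classes (cold / mid / warm with thresholds -1 and +1 degC; boundary values
fall in "mid" because the class definitions use strict inequalities).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "TRAITS",
    "CORE_TRAITS",
    "FUNCTIONAL_GROUPS",
    "RowDiagnostic",
    "read_trait_table",
    "write_trait_table",
    "read_site_table",
    "write_site_table",
    "read_species_list",
    "select_biome_pool",
    "select_extreme_subset",
    "assign_temperature_class",
]

CORE_TRAITS = ("plant height", "leaf area", "seed mass",
               "LMA", "leaf nitrogen", "LDMC")
TRAITS = CORE_TRAITS + ("SSD",)
FUNCTIONAL_GROUPS = ("deciduous shrub", "evergreen shrub", "graminoid", "forb")

MANDATORY_COLUMNS = ("record_id", "species", "genus", "functional_group",
                     "dataset_id", "site_id", "trait", "value")
OPTIONAL_COLUMNS = ("latitude", "longitude", "units")

ARCTIC_CIRCLE_LAT = 66.5


@dataclass(frozen=True)
class RowDiagnostic:
    row: int            # 0-based data row number
    record_id: str
    reason: str


def read_trait_table(path, strict_enums: bool = True
                     ) -> tuple[pd.DataFrame, list[RowDiagnostic]]:
    """Read a delimited trait table, rejecting invalid rows with reasons.

    Returns ``(records, diagnostics)``.  Missing mandatory columns raise
    immediately, naming them.  Rows failing an invariant (non-positive
    value, unknown trait or functional group, one-sided coordinates,
    out-of-range coordinates) are excluded and listed in the diagnostics.
    """
    df = pd.read_csv(path, dtype={"record_id": str, "species": str,
                                  "genus": str, "site_id": str,
                                  "dataset_id": str})
    missing = [c for c in MANDATORY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing mandatory columns: {missing}")
    for col in OPTIONAL_COLUMNS:
        if col not in df.columns:
            df[col] = np.nan

    diags: list[RowDiagnostic] = []
    bad = pd.Series(False, index=df.index)

    def flag(mask: pd.Series, reason: str) -> None:
        for i in df.index[mask & ~bad]:
            diags.append(RowDiagnostic(int(i), str(df.at[i, "record_id"]), reason))
        bad.loc[mask] = True

    value = pd.to_numeric(df["value"], errors="coerce")
    flag(value.isna(), "non-numeric value")
    flag(value <= 0, "non-positive value")
    df["value"] = value
    if strict_enums:
        flag(~df["trait"].isin(TRAITS), "unknown trait")
        flag(~df["functional_group"].isin(FUNCTIONAL_GROUPS),
             "unknown functional group")
    lat = pd.to_numeric(df["latitude"], errors="coerce")
    lon = pd.to_numeric(df["longitude"], errors="coerce")
    flag(lat.isna() ^ lon.isna(), "coordinates must be both present or both absent")
    flag(lat.abs() > 90, "latitude out of range")
    flag(lon.abs() > 180, "longitude out of range")
    df["latitude"], df["longitude"] = lat, lon
    return df[~bad].reset_index(drop=True), diags


def write_trait_table(records: pd.DataFrame, path) -> None:
    records.to_csv(path, index=False)


def read_site_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"site_id": str})
    required = ("site_id", "latitude", "longitude",
                "mean_annual_temperature", "class_temperature")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"missing site columns: {missing}")
    for col in required[1:]:
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any():
            raise ValueError(f"non-numeric entries in site column {col!r}")
        df[col] = vals
    if (df["latitude"].abs() > 90).any() or (df["longitude"].abs() > 180).any():
        raise ValueError("site coordinates out of range")
    return df


def write_site_table(sites: pd.DataFrame, path) -> None:
    sites.to_csv(path, index=False)


def read_species_list(path) -> list[str]:
    with open(path, encoding="utf-8") as fh:
        return [line.strip() for line in fh if line.strip()]


def _check_sites_known(records: pd.DataFrame, site_table: pd.DataFrame) -> None:
    known = set(site_table["site_id"].astype(str))
    offenders = sorted(set(records["site_id"].astype(str)) - known)
    if offenders:
        raise ValueError(f"unknown site_ids in records: {offenders}")


def select_biome_pool(records: pd.DataFrame, plot_species_list,
                      site_table: pd.DataFrame,
                      mat_threshold_C: float = 0.0) -> set[str]:
    """Union of the survey species and species with at least one record at a
    site with mean annual temperature below the threshold."""
    _check_sites_known(records, site_table)
    cold_sites = set(site_table.loc[
        site_table["mean_annual_temperature"] < mat_threshold_C,
        "site_id"].astype(str))
    cold_species = set(records.loc[records["site_id"].astype(str)
                                   .isin(cold_sites), "species"])
    return set(plot_species_list) | cold_species


def select_extreme_subset(records: pd.DataFrame, site_table: pd.DataFrame,
                          lat_threshold: float = ARCTIC_CIRCLE_LAT,
                          mat_threshold_C: float = 0.0) -> set[str]:
    """Species with >= 1 record north of the Arctic Circle or at a site with
    MAT below 0 degC.  Records without coordinates only count through the
    temperature criterion."""
    _check_sites_known(records, site_table)
    lat = pd.to_numeric(records.get("latitude"), errors="coerce")
    by_lat = set(records.loc[lat > lat_threshold, "species"])
    cold_sites = set(site_table.loc[
        site_table["mean_annual_temperature"] < mat_threshold_C,
        "site_id"].astype(str))
    by_mat = set(records.loc[records["site_id"].astype(str)
                             .isin(cold_sites), "species"])
    return by_lat | by_mat


def assign_temperature_class(records: pd.DataFrame, site_table: pd.DataFrame,
                             cold_max: float = -1.0,
                             warm_min: float = 1.0) -> pd.DataFrame:
    """Classify species as cold / mid / warm by the unweighted mean of
    ``class_temperature`` over their unique georeferenced collection sites.

    Strict inequalities: mean < cold_max -> cold, mean > warm_min -> warm,
    otherwise mid (so a mean exactly at a threshold is mid).  Species with
    no georeferenced site are flagged ``unclassified``, not dropped.
    """
    _check_sites_known(records, site_table)
    site_temp = site_table.set_index(site_table["site_id"].astype(str)
                                     )["class_temperature"]
    has_coords = ~pd.to_numeric(records.get("latitude"),
                                errors="coerce").isna()
    geo = records[has_coords]
    pairs = geo[["species", "site_id"]].drop_duplicates()
    pairs = pairs.assign(temp=pairs["site_id"].astype(str).map(site_temp))
    mean_temp = pairs.groupby("species")["temp"].mean()

    rows = []
    for sp in sorted(records["species"].unique()):
        if sp not in mean_temp.index or pd.isna(mean_temp[sp]):
            rows.append({"species": sp, "mean_class_temperature": np.nan,
                         "temperature_class": "unclassified"})
            continue
        t = float(mean_temp[sp])
        if t < cold_max:
            cls = "cold"
        elif t > warm_min:
            cls = "warm"
        else:
            cls = "mid"
        rows.append({"species": sp, "mean_class_temperature": t,
                     "temperature_class": cls})
    return pd.DataFrame(rows)
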