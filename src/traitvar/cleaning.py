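"""Hierarchical error-risk cleaning of a multi-source trait database.

Two tools, matching how heterogeneous trait compilations are curated:

* a duplicate-ratio rule: within each contributed dataset, the fraction of
  records whose (species, trait, value) triple repeats an earlier record is
  computed; datasets above the threshold (default 30%) are collapsed to one
  record per triple, datasets below it are left alone, since sparse repeats
  are plausibly two real individuals with the same measurement;

* a three-step outlier ladder keyed on "error risk" — the absolute distance
  of an observation (or group mean) from its reference group's mean,
  excluding the observation itself, in units of the group's standard
  deviation.  Step 1 screens each record against the entire distribution of
  its trait (risk > 8).  Step 2 screens dataset-level species means (species
  in >= 4 datasets, risk > 3.0) or genus means (risk > 3.5) and drops the
  offending dataset x species (or x genus) cell.  Step 3 screens records
  against their own species with a sample-size-dependent threshold rising
  from 2.25 (< 10 records) to 4.0 (> 30 records).  Each step recomputes
  statistics on the survivors of the previous one, and every removal is
  recorded with its step, risk and threshold.

The ladder flags likely unit errors while deliberately sparing true extreme
values — the thresholds are generous because trait variation itself is the
object of study.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CleaningConfig",
    "CleaningReport",
    "error_risk",
    "duplicate_ratio",
    "dedup_within_dataset",
    "species_level_threshold",
    "clean_pipeline",
]

STEP_GLOBAL = "global"
STEP_DATASET = "dataset"
STEP_SPECIES = "species"


@dataclass(frozen=True)
class CleaningConfig:
    duplicate_ratio_threshold: float = 0.30
    global_risk: float = 8.0
    dataset_species_risk: float = 3.0
    dataset_genus_risk: float = 3.5
    min_datasets_for_species_rule: int = 4
    species_risk_min: float = 2.25
    species_risk_max: float = 4.0
    species_risk_n_low: int = 10
    species_risk_n_high: int = 30
    min_records_species_rule: int = 4
    sd_excludes_x: bool = True
    dataset_means_on_log: bool = False

    def __post_init__(self) -> None:
        for name in ("duplicate_ratio_threshold", "global_risk",
                     "dataset_species_risk", "dataset_genus_risk",
                     "species_risk_min", "species_risk_max"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.species_risk_min > self.species_risk_max:
            raise ValueError("species_risk_min must be <= species_risk_max")
        if self.species_risk_n_low >= self.species_risk_n_high:
            raise ValueError("species_risk_n_low must be < species_risk_n_high")


@dataclass
class CleaningReport:
    """Audit of the cleaning run: one entry per removed record."""

    entries: pd.DataFrame   # record_id, trait, step, risk, threshold
    n_input: int
    skipped: list = field(default_factory=list)

    @property
    def counts(self) -> dict[str, int]:
        if self.entries.empty:
            return {}
        return self.entries.groupby("step", observed=True).size().to_dict()

    @property
    def n_removed(self) -> int:
        return len(self.entries)

    @property
    def removed_fraction(self) -> float:
        return self.n_removed / self.n_input if self.n_input else 0.0


def error_risk(x: float, group, sd_excludes_x: bool = True) -> float:
    """|x - mean(group without x)| / sd of the (reduced) group.

    ``group`` must contain ``x`` (one occurrence of it is excluded from the
    mean, and from the sd when ``sd_excludes_x``).  With zero spread the
    risk is 0 when x equals the common value and +inf otherwise; groups of
    fewer than 3 values are undefined.
    """
    g = np.asarray(group, dtype=float)
    if g.size < 3:
        raise ValueError("error risk undefined for groups of fewer than 3 values")
    hits = np.flatnonzero(np.isclose(g, x, rtol=0.0, atol=0.0))
    if hits.size == 0:
        raise ValueError("group must contain x")
    rest = np.delete(g, hits[0])
    mean = rest.mean()
    sd = rest.std(ddof=1) if sd_excludes_x else g.std(ddof=1)
    if sd == 0.0:
        return 0.0 if x == mean else float("inf")
    return float(abs(x - mean) / sd)


def _risks_within(values: np.ndarray, sd_excludes_x: bool) -> np.ndarray:
    """Vectorised error risk of every element against its own group."""
    n = values.size
    if n < 3:
        return np.full(n, np.nan)
    S = values.sum()
    Q = (values ** 2).sum()
    mean_wo = (S - values) / (n - 1)
    if sd_excludes_x:
        var = (Q - values ** 2 - (n - 1) * mean_wo ** 2) / (n - 2)
        var = np.clip(var, 0.0, None)
        sd = np.sqrt(var)
    else:
        sd = np.full(n, values.std(ddof=1))
    diff = np.abs(values - mean_wo)
    with np.errstate(divide="ignore", invalid="ignore"):
        risk = diff / sd
    risk = np.where(sd == 0.0, np.where(diff == 0.0, 0.0, np.inf), risk)
    return risk


def duplicate_ratio(dataset_records: pd.DataFrame) -> float:
    """Fraction of a dataset's records that repeat a (species, trait, value)
    triple already seen in that dataset (each extra copy counts once)."""
    n = len(dataset_records)
    if n == 0:
        return 0.0
    dup = dataset_records.duplicated(subset=["species", "trait", "value"])
    return float(dup.sum() / n)


def dedup_within_dataset(records: pd.DataFrame,
                         threshold: float = 0.30) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Collapse duplicated triples in datasets whose duplicate ratio exceeds
    ``threshold`` (strictly); other datasets are untouched.

    Returns ``(kept_records, removal_table)``; the removal table lists the
    dropped record_ids with their dataset's duplicate ratio.
    """
    records = records.sort_values("record_id", kind="stable")
    keep_masks = []
    removed = []
    for ds, sub in records.groupby("dataset_id", observed=True, sort=False):
        ratio = duplicate_ratio(sub)
        if ratio > threshold:
            dup = sub.duplicated(subset=["species", "trait", "value"])
            keep_masks.append(~dup)
            for rid, tr in zip(sub.loc[dup, "record_id"], sub.loc[dup, "trait"]):
                removed.append({"record_id": rid, "trait": tr,
                                "dataset_id": ds, "duplicate_ratio": ratio})
        else:
            keep_masks.append(pd.Series(True, index=sub.index))
    keep = pd.concat(keep_masks).reindex(records.index)
    out = records[keep].sort_index()
    return out, pd.DataFrame(removed, columns=["record_id", "trait",
                                               "dataset_id", "duplicate_ratio"])


def species_level_threshold(n_records: int,
                            config: CleaningConfig = CleaningConfig()) -> float:
    """Sample-size-dependent risk threshold for the species-level step."""
    if n_records < 1:
        raise ValueError("n_records must be >= 1")
    c = config
    if n_records < c.species_risk_n_low:
        return c.species_risk_min
    if n_records > c.species_risk_n_high:
        return c.species_risk_max
    frac = (n_records - c.species_risk_n_low) / (c.species_risk_n_high
                                                 - c.species_risk_n_low)
    return c.species_risk_min + (c.species_risk_max - c.species_risk_min) * frac


def _dataset_step(df: pd.DataFrame, cfg: CleaningConfig, skipped: list):
    """Flag whole dataset x species (or x genus) cells whose dataset-level
    mean is an outlier among the other datasets' means."""
    entries = []
    vals = np.log(df["value"]) if cfg.dataset_means_on_log else df["value"]
    work = df.assign(_v=vals)
    for trait, sub in work.groupby("trait", observed=True, sort=False):
        ds_per_species = sub.groupby("species", observed=True)["dataset_id"].nunique()
        many = set(ds_per_species[ds_per_species >=
                                  cfg.min_datasets_for_species_rule].index)

        # species rule
        sp_sub = sub[sub["species"].isin(many)]
        if not sp_sub.empty:
            means = sp_sub.groupby(["species", "dataset_id"], observed=True)["_v"].mean()
            for sp, m in means.groupby(level="species", observed=True):
                risks = _risks_within(m.to_numpy(), cfg.sd_excludes_x)
                for (_, ds), r in zip(m.index, risks):
                    if np.isfinite(r) and r > cfg.dataset_species_risk:
                        cell = sub[(sub["species"] == sp)
                                   & (sub["dataset_id"] == ds)]
                        for rid in cell["record_id"]:
                            entries.append({"record_id": rid, "trait": trait,
                                            "step": STEP_DATASET, "risk": float(r),
                                            "threshold": cfg.dataset_species_risk})

        # genus rule for the rest
        gn_sub = sub[~sub["species"].isin(many)]
        if not gn_sub.empty and "genus" in gn_sub.columns:
            means = gn_sub.groupby(["genus", "dataset_id"], observed=True)["_v"].mean()
            for gn, m in means.groupby(level="genus", observed=True):
                if len(m) < 3:
                    skipped.append((STEP_DATASET, trait, gn,
                                    "fewer than 3 dataset means"))
                    continue
                risks = _risks_within(m.to_numpy(), cfg.sd_excludes_x)
                for (_, ds), r in zip(m.index, risks):
                    if np.isfinite(r) and r > cfg.dataset_genus_risk:
                        cell = gn_sub[(gn_sub["genus"] == gn)
                                      & (gn_sub["dataset_id"] == ds)]
                        for rid in cell["record_id"]:
                            entries.append({"record_id": rid, "trait": trait,
                                            "step": STEP_DATASET, "risk": float(r),
                                            "threshold": cfg.dataset_genus_risk})
    return entries


def clean_pipeline(records: pd.DataFrame,
                   config: CleaningConfig = CleaningConfig()
                   ) -> tuple[pd.DataFrame, CleaningReport]:
    """Run the three-step error-risk ladder; values are never modified.

    Each trait is processed independently; each step recomputes its group
    statistics on the survivors of the previous step.  Groups too small for
    a step are skipped (and logged on the report), never an error.
    """
    cfg = config
    df = records.copy()
    n_input = len(df)
    all_entries: list[dict] = []
    skipped: list[tuple] = []

    # step 1: record vs entire trait distribution
    drop_ids: set = set()
    for trait, sub in df.groupby("trait", observed=True, sort=False):
        v = sub["value"].to_numpy(dtype=float)
        if v.size < 3:
            skipped.append((STEP_GLOBAL, trait, None, "fewer than 3 records"))
            continue
        risks = _risks_within(v, cfg.sd_excludes_x)
        bad = np.flatnonzero(risks > cfg.global_risk)
        for i in bad:
            rid = sub["record_id"].iloc[i]
            drop_ids.add(rid)
            all_entries.append({"record_id": rid, "trait": trait,
                                "step": STEP_GLOBAL,
                                "risk": float(risks[i]),
                                "threshold": cfg.global_risk})
    df = df[~df["record_id"].isin(drop_ids)]

    # step 2: dataset-level species / genus means
    entries = _dataset_step(df, cfg, skipped)
    all_entries.extend(entries)
    df = df[~df["record_id"].isin({e["record_id"] for e in entries})]

    # step 3: record vs its species distribution
    drop_ids = set()
    for (trait, sp), sub in df.groupby(["trait", "species"], observed=True,
                                       sort=False):
        n = len(sub)
        if n <= cfg.min_records_species_rule:
            continue
        if n < 3:
            skipped.append((STEP_SPECIES, trait, sp, "fewer than 3 records"))
            continue
        thr = species_level_threshold(n, cfg)
        risks = _risks_within(sub["value"].to_numpy(dtype=float),
                              cfg.sd_excludes_x)
        bad = np.flatnonzero(risks > thr)
        for i in bad:
            rid = sub["record_id"].iloc[i]
            drop_ids.add(rid)
            all_entries.append({"record_id": rid, "trait": trait,
                                "step": STEP_SPECIES,
                                "risk": float(risks[i]), "threshold": thr})
    df = df[~df["record_id"].isin(drop_ids)]

    report = CleaningReport(
        entries=pd.DataFrame(all_entries, columns=["record_id", "trait",
                                                   "step", "risk", "threshold"]),
        n_input=n_input, skipped=skipped)
    return df.reset_index(drop=True), report
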