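"""End-to-end orchestration: generate -> clean -> partition -> scan -> trait space.

A run is driven by a single YAML-able config dict; every stage writes its
tables under the output directory and the manifest records the seed, a
config hash, library versions and per-stage row counts, so a rerun with
the same seed and config reproduces the manifest except for the timestamp.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import pathlib
import time

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cleaning import CleaningConfig, clean_pipeline, dedup_within_dataset
from .scan import (ScanEligibility, bin_and_interval, fit_breakpoint,
                   scan_all_sites, test_bin_significance)
from .synthetic import SyntheticConfig, generate_database, write_database
from .traitspace import build_species_matrix, run_pca
from .varcomp import SiteFilter, coefficient_of_variation, partition_by_site

log = logging.getLogger("traitvar")

DEFAULT_STAGES = ("generate", "clean", "partition", "scan", "traitspace")


def default_config(seed: int = 0) -> dict:
    return {
        "seed": seed,
        "stages": list(DEFAULT_STAGES),
        "synthetic": {},          # SyntheticConfig overrides
        "cleaning": {},           # CleaningConfig overrides
        "site_filter": {},        # SiteFilter overrides
        "scan_eligibility": {},   # ScanEligibility overrides
        "scan": {"bin_width_km": 5.0, "bin_width_species": 1.0,
                 "n_significance_bins": 10, "alpha": 0.05},
        "pca": {"standardize": True},
    }


def demo_config(seed: int = 1) -> dict:
    """A small, fast end-to-end configuration (reduced site and species
    counts) used by the bundled demo and the determinism checks."""
    cfg = default_config(seed)
    cfg["synthetic"] = {
        "n_species": 30, "n_sites": 12, "n_site_clusters": 3,
        "obs_per_species_site": 5, "n_datasets": 20,
    }
    return cfg


def load_config(path) -> dict:
    with open(path, encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh) or {}
    merged = default_config()
    for key, val in cfg.items():
        if isinstance(val, dict) and isinstance(merged.get(key), dict):
            merged[key].update(val)
        else:
            merged[key] = val
    return merged


def _config_hash(config: dict) -> str:
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def run(config: dict, outdir) -> dict:
    """Execute the enabled stages in order and return the run manifest."""
    out = pathlib.Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    stages = list(config.get("stages", DEFAULT_STAGES))
    seed = int(config.get("seed", 0))
    manifest = {
        "package_version": __version__,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        "seed": seed,
        "config_hash": _config_hash(config),
        "stages": {},
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }

    if "generate" in stages:
        syn = SyntheticConfig(seed=seed, **config.get("synthetic", {}))
        records, sites, gt = generate_database(syn)
        write_database(records, sites, gt, syn, out / "synthetic")
        manifest["stages"]["generate"] = {
            "rows_out": int(len(records)), "n_sites": int(len(sites))}
        log.info("generate: %d records, %d sites", len(records), len(sites))
    else:
        records = pd.read_csv(out / "synthetic" / "records.csv")
        sites = pd.read_csv(out / "synthetic" / "sites.csv")

    if "clean" in stages:
        ccfg = CleaningConfig(**config.get("cleaning", {}))
        deduped, dedup_report = dedup_within_dataset(
            records, ccfg.duplicate_ratio_threshold)
        cleaned, report = clean_pipeline(deduped, ccfg)
        cleaned.to_csv(out / "cleaned.csv", index=False)
        report.entries.to_csv(out / "cleaning_report.csv", index=False)
        dedup_report.to_csv(out / "dedup_report.csv", index=False)
        manifest["stages"]["clean"] = {
            "rows_in": int(len(records)),
            "rows_deduped": int(len(deduped)),
            "rows_out": int(len(cleaned)),
            "removed_by_step": {k: int(v) for k, v in report.counts.items()},
            "removed_fraction": round(
                (len(records) - len(cleaned)) / max(len(records), 1), 6),
        }
        log.info("clean: %d -> %d records", len(records), len(cleaned))
    else:
        cleaned = pd.read_csv(out / "cleaned.csv")

    if "partition" in stages:
        sf = SiteFilter(**config.get("site_filter", {}))
        per_site, summary = partition_by_site(cleaned, sf)
        per_site.to_csv(out / "varcomp_per_site.csv", index=False)
        summary.to_csv(out / "varcomp_summary.csv", index=False)
        cv = (cleaned.groupby("trait", observed=True)["value"]
              .apply(lambda v: coefficient_of_variation(v))
              .rename("cv").reset_index())
        cv.to_csv(out / "trait_cv.csv", index=False)
        manifest["stages"]["partition"] = {
            "rows_in": int(len(cleaned)),
            "n_site_trait_fits": int(len(per_site)),
        }
        log.info("partition: %d site x trait fits", len(per_site))

    if "scan" in stages:
        elig = ScanEligibility(**config.get("scan_eligibility", {}))
        sc = config.get("scan", {})
        steps = scan_all_sites(cleaned, sites, elig)
        steps.to_csv(out / "scan_steps.csv", index=False)
        summaries = []
        if not steps.empty:
            for axis, width in (("scale_km", sc.get("bin_width_km", 5.0)),
                                ("richness", sc.get("bin_width_species", 1.0))):
                b = bin_and_interval(steps, axis=axis, width=width)
                b.insert(0, "axis", axis)
                summaries.append(b)
                sig = test_bin_significance(
                    steps, axis=axis,
                    n_bins=sc.get("n_significance_bins", 10),
                    alpha=sc.get("alpha", 0.05))
                sig.insert(0, "axis", axis)
                sig.to_csv(out / f"scan_significance_{axis}.csv", index=False)
            pd.concat(summaries, ignore_index=True).to_csv(
                out / "scan_binned.csv", index=False)
            bps = []
            for (axis, trait), sub in (
                    steps.assign(axis="scale_km")
                    .groupby(["axis", "trait"], observed=True)):
                x = np.log10(sub["scale_km"].to_numpy(float) + 1.0)
                y = sub["f_within"].to_numpy(float)
                if len(sub) >= 6 and np.unique(x).size >= 4:
                    fit = fit_breakpoint(x, y)
                    bps.append({"axis": axis, "trait": trait,
                                "psi_log10": fit.psi,
                                "slope_left": fit.slope_left,
                                "slope_right": fit.slope_right,
                                "rss": fit.rss, "converged": fit.converged})
            pd.DataFrame(bps).to_csv(out / "scan_breakpoints.csv", index=False)
        manifest["stages"]["scan"] = {"rows_out": int(len(steps))}
        log.info("scan: %d step x trait rows", len(steps))

    if "traitspace" in stages:
        stm = build_species_matrix(cleaned)
        pca = run_pca(stm.matrix,
                      standardize=config.get("pca", {}).get("standardize", True))
        pca.loadings.to_csv(out / "pca_loadings.csv")
        pca.scores.to_csv(out / "pca_scores.csv")
        pca.contributions.to_csv(out / "pca_contributions.csv")
        pd.DataFrame({"axis": [f"PC{i+1}" for i in range(len(pca.explained))],
                      "explained_fraction": pca.explained}).to_csv(
            out / "pca_explained.csv", index=False)
        manifest["stages"]["traitspace"] = {
            "n_species": int(len(stm.matrix)),
            "n_dropped_incomplete": int(len(stm.dropped_species)),
            "explained_first_two": round(float(pca.explained[:2].sum()), 6),
        }
        log.info("traitspace: %d complete species", len(stm.matrix))

    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
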