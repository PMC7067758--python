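"""Trait-space ordination: species-mean log traits and their PCA.

Species x trait matrices of mean log values (traits are close to
log-normal, and the log also puts incommensurate units on comparable
scales) are ordinated by principal component analysis on the correlation
matrix (centred, unit-scaled columns).  The two leading axes are read as
plant size and resource economics.  Signs of PCA axes are arbitrary, so a
deterministic convention is applied: each axis is oriented so that its
largest-magnitude loading is positive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SpeciesTraitMatrix",
    "PCAResult",
    "build_species_matrix",
    "run_pca",
    "subspace_projection",
    "axis_score_ranges",
    "ssd_to_ldmc",
    "SSDConversion",
    "subspace_congruence",
]


@dataclass
class SpeciesTraitMatrix:
    matrix: pd.DataFrame            # species x trait mean log values (complete)
    cell_counts: pd.DataFrame       # records per cell, same shape
    dropped_species: list           # species excluded for incompleteness


@dataclass
class PCAResult:
    loadings: pd.DataFrame          # trait x axis, orthonormal columns
    explained: np.ndarray           # explained variance fraction per axis
    scores: pd.DataFrame            # species x axis
    contributions: pd.DataFrame     # trait x axis, percent, sums to 100
    standardized: bool
    column_mean: pd.Series
    column_scale: pd.Series


def build_species_matrix(records: pd.DataFrame,
                         traits=None) -> SpeciesTraitMatrix:
    """Mean of log values per species per trait; complete cases only.

    Species missing any of the selected traits are excluded (and listed on
    the result).  Fewer than 3 complete species is an error.
    """
    from .io import CORE_TRAITS

    traits = list(traits) if traits is not None else list(CORE_TRAITS)
    sub = records[records["trait"].isin(traits)]
    if (sub["value"] <= 0).any():
        raise ValueError("trait values must be positive for the log transform")
    logs = sub.assign(logv=np.log(sub["value"].astype(float)))
    mat = logs.pivot_table(index="species", columns="trait", values="logv",
                           aggfunc="mean")
    counts = logs.pivot_table(index="species", columns="trait", values="logv",
                              aggfunc="size").fillna(0).astype(int)
    mat = mat.reindex(columns=traits)
    counts = counts.reindex(columns=traits, fill_value=0)
    complete = mat.dropna()
    dropped = sorted(set(mat.index) - set(complete.index))
    if len(complete) < 3:
        raise ValueError("fewer than 3 species with all selected traits; "
                         "PCA is meaningless")
    return SpeciesTraitMatrix(matrix=complete,
                              cell_counts=counts.loc[complete.index],
                              dropped_species=dropped)


def run_pca(matrix: pd.DataFrame, standardize: bool = True) -> PCAResult:
    """PCA by singular value decomposition of the (scaled) centred matrix.

    Axes are ordered by explained variance; each axis is flipped, if
    needed, so its largest-magnitude loading is positive.  Contributions
    are ``100 * loading^2 / sum(loading^2)`` per axis.
    """
    X = matrix.to_numpy(dtype=float)
    n, p = X.shape
    if n < 3 or p < 2:
        raise ValueError("PCA needs >= 3 species and >= 2 traits")
    mean = X.mean(axis=0)
    Xc = X - mean
    sd = X.std(axis=0, ddof=1)
    if standardize:
        zero = np.flatnonzero(sd == 0)
        if zero.size:
            names = [str(matrix.columns[i]) for i in zero]
            raise ValueError(f"zero-variance trait column(s): {names}")
        Xc = Xc / sd
        scale = sd
    else:
        scale = np.ones(p)
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    loadings = Vt.T                       # p x k, orthonormal columns
    # deterministic sign: largest |loading| positive on each axis
    for j in range(loadings.shape[1]):
        i = np.argmax(np.abs(loadings[:, j]))
        if loadings[i, j] < 0:
            loadings[:, j] *= -1
            U[:, j] *= -1
    var = S ** 2
    explained = var / var.sum() if var.sum() > 0 else var
    scores = U * S
    axes = [f"PC{j + 1}" for j in range(loadings.shape[1])]
    load_df = pd.DataFrame(loadings, index=matrix.columns, columns=axes)
    contrib = 100.0 * load_df ** 2 / (load_df ** 2).sum(axis=0)
    score_df = pd.DataFrame(scores, index=matrix.index, columns=axes)
    return PCAResult(loadings=load_df, explained=explained, scores=score_df,
                     contributions=contrib, standardized=standardize,
                     column_mean=pd.Series(mean, index=matrix.columns),
                     column_scale=pd.Series(scale, index=matrix.columns))


def subspace_projection(pca: PCAResult, species) -> tuple[pd.DataFrame, list]:
    """Scores of a species subset in the fitted axes (rows of the global
    score matrix).  Unknown species are listed, not an error."""
    wanted = list(species)
    known = [s for s in wanted if s in pca.scores.index]
    missing = sorted(set(wanted) - set(known))
    return pca.scores.loc[known], missing


def axis_score_ranges(pca: PCAResult, species=None) -> pd.Series:
    """Score range (max - min) per axis, optionally for a species subset."""
    scores = pca.scores if species is None else subspace_projection(pca, species)[0]
    return scores.max() - scores.min()


@dataclass(frozen=True)
class SSDConversion:
    slope: float
    intercept: float
    r: float

    def predict_log(self, log_ssd) -> np.ndarray:
        return self.intercept + self.slope * np.asarray(log_ssd, dtype=float)


def ssd_to_ldmc(ssd_values, calibration_pairs: pd.DataFrame
                ) -> tuple[np.ndarray, SSDConversion]:
    """Predict LDMC from stem-specific density via a log-log regression
    fitted to caller-supplied co-measured (ssd, ldmc) calibration pairs.

    Supplementary-comparison use only; converted values never enter the
    main pipeline.
    """
    if len(calibration_pairs) < 3:
        raise ValueError("need at least 3 calibration pairs")
    x = np.log(np.asarray(calibration_pairs["ssd"], dtype=float))
    y = np.log(np.asarray(calibration_pairs["ldmc"], dtype=float))
    fit = stats.linregress(x, y)
    conv = SSDConversion(slope=float(fit.slope), intercept=float(fit.intercept),
                         r=float(fit.rvalue))
    pred = np.exp(conv.predict_log(np.log(np.asarray(ssd_values, dtype=float))))
    return pred, conv


def subspace_congruence(A, B) -> float:
    """Tucker-style congruence of two column subspaces: the smallest cosine
    of the principal angles between span(A) and span(B).  1 means B lies in
    the span of A."""
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    Qa, _ = np.linalg.qr(A)
    Qb, _ = np.linalg.qr(B)
    s = np.linalg.svd(Qa.T @ Qb, compute_uv=False)
    return float(np.min(np.clip(s, 0.0, 1.0)))
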