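"""Sparse voxel-wise encoding: predict BOLD from layer features by LASSO.

One encoding sample is one (excerpt, subject) pair: a design matrix D of
HRF-convolved layer features (m TR volumes x c channels) and the
normalized BOLD matrix X (m x V voxels). Each voxel is fit independently
by LASSO,

    min_a  1/(2m) ||x - D a||_2^2 + lambda ||a||_1

with no intercept (both sides are zero-mean), and scored by the Pearson
correlation between D a and x. The sparsity penalty lambda is selected on
a small grid by leave-one-sample-out cross-validation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import Lasso

from .metrics import pearson_columns
from .stimulus import StimulusSpec

DEFAULT_LAMBDA_GRID = (0.05, 0.10, 0.15)


def normalize_voxels(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Zero-mean/unit-SD each voxel column (population SD).

    Returns (normalized, missing) where ``missing`` flags constant
    columns, which are set to all-zero and must be excluded downstream.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("X must be (m >= 2, V)")
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    missing = sd == 0
    safe = np.where(missing, 1.0, sd)
    Xn = (X - mu) / safe
    Xn[:, missing] = 0.0
    return Xn, missing


def standardize_columns(D: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Z-score design columns; constant columns zeroed and recorded."""
    D = np.asarray(D, dtype=float)
    sd = D.std(axis=0)
    constant = sd == 0
    Dz = (D - D.mean(axis=0)) / np.where(constant, 1.0, sd)
    Dz[:, constant] = 0.0
    return Dz, constant


def lasso_fit(D: np.ndarray, x: np.ndarray, lam: float) -> np.ndarray:
    """Solve the encoding objective for one voxel (or a stack of voxels).

    ``x`` may be (m,) or (m, V); the returned coefficients are (c,) or
    (V, c). ``lam = 0`` falls back to least squares (minimum-norm).
    """
    D = np.asarray(D, dtype=float)
    x = np.asarray(x, dtype=float)
    if not (np.all(np.isfinite(D)) and np.all(np.isfinite(x))):
        raise ValueError("non-finite values in design or response")
    if lam < 0:
        raise ValueError("lambda must be non-negative")
    if lam == 0:
        coef, *_ = np.linalg.lstsq(D, x, rcond=None)
        return coef.T if x.ndim == 2 else coef
    model = Lasso(alpha=lam, fit_intercept=False, max_iter=50_000, tol=1e-8)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        model.fit(D, x)
    return model.coef_


class VoxelEncodingModel(RegressorMixin, BaseEstimator):
    """Per-voxel LASSO encoding model, sklearn-style.

    Fit on a design ``D`` of shape (m, c) and a BOLD matrix ``X`` of
    shape (m, V); every voxel column is regressed independently under the
    1/(2m) residual convention, so the published lambda values apply
    directly. Design columns are z-scored before fitting by default
    (constant columns dropped and recorded), making lambda comparable
    across layers with different channel scales.

    Attributes
    ----------
    coef_ : ndarray (V, c)
        Sparse encoding coefficients per voxel (zeros in dropped columns).
    missing_ : ndarray of bool (V,)
        Voxels whose series was constant; excluded from all scores.
    dropped_columns_ : ndarray of bool (c,)
        Constant design columns excluded from the fit.
    """

    def __init__(self, alpha: float = 0.1, standardize: bool = True):
        self.alpha = alpha
        self.standardize = standardize

    def _prepare(self, D):
        D = np.asarray(D, dtype=float)
        if self.standardize:
            Dz, const = standardize_columns(D)
        else:
            Dz, const = D, np.zeros(D.shape[1], dtype=bool)
        return Dz, const

    def fit(self, D, X):
        D = np.asarray(D, dtype=float)
        X = np.asarray(X, dtype=float)
        if D.shape[0] != X.shape[0]:
            raise ValueError("D and X must share the time dimension")
        Dz, const = self._prepare(D)
        self.dropped_columns_ = const
        self.missing_ = X.std(axis=0) == 0
        self.n_features_in_ = D.shape[1]
        coef = np.zeros((X.shape[1], D.shape[1]))
        active = ~self.missing_
        if np.any(active):
            sub = lasso_fit(Dz[:, ~const], X[:, active], self.alpha)
            sub = np.atleast_2d(sub)
            full = np.zeros((int(active.sum()), D.shape[1]))
            full[:, ~const] = sub
            coef[active] = full
        self.coef_ = coef
        return self

    def predict(self, D):
        Dz, _ = self._prepare(D)
        return Dz @ self.coef_.T

    def pcc(self, D, X) -> np.ndarray:
        """Per-voxel PCC between prediction and data.

        An all-zero coefficient vector predicts a constant, whose
        correlation is undefined; such voxels score 0 (no predictive
        power). NaN is reserved for missing (constant-series) voxels.
        """
        pred = self.predict(D)
        X = np.asarray(X, dtype=float)
        r = pearson_columns(pred, X)
        degenerate = (pred.std(axis=0) == 0) & ~self.missing_
        r[degenerate] = 0.0
        r[self.missing_] = np.nan
        return r

    def score(self, D, X, sample_weight=None):
        """Mean PCC over non-missing voxels."""
        r = self.pcc(D, X)
        return float(np.nanmean(r))


@dataclass
class EncodingSample:
    """One (excerpt, subject) pair for one feature layer."""

    design: np.ndarray  # (m, c) HRF-convolved layer features
    bold: np.ndarray  # (m, V) normalized voxel series
    subject: int
    excerpt: int
    category: int
    layer: int
    missing: np.ndarray = field(default=None)  # voxels flagged at normalization

    def __post_init__(self):
        if self.design.shape[0] != self.bold.shape[0]:
            raise ValueError("design and bold must share the time dimension")
        if self.missing is None:
            self.missing = np.zeros(self.bold.shape[1], dtype=bool)


@dataclass
class EncodingResult:
    """Fitted coefficients and PCC map for one sample."""

    coef: np.ndarray  # (V, c)
    alpha: float
    pcc: np.ndarray  # (V,), NaN for missing voxels
    subject: int
    excerpt: int
    category: int
    layer: int


def fit_sample(sample: EncodingSample, lam: float) -> EncodingResult:
    """Fit every voxel of one sample at a fixed penalty."""
    model = VoxelEncodingModel(alpha=lam).fit(sample.design, sample.bold)
    r = model.pcc(sample.design, sample.bold)
    r[sample.missing] = np.nan
    return EncodingResult(
        coef=model.coef_,
        alpha=lam,
        pcc=r,
        subject=sample.subject,
        excerpt=sample.excerpt,
        category=sample.category,
        layer=sample.layer,
    )


def build_encoding_dataset(
    designs: Sequence[np.ndarray],
    bold: Mapping[tuple[int, int], np.ndarray],
    spec: StimulusSpec,
    layer: int,
    categories: Sequence[int] | None = None,
) -> list[EncodingSample]:
    """Assemble one sample per (excerpt, subject) pair.

    ``designs[e]`` is excerpt e's design for ``layer``; ``bold`` maps
    (subject, excerpt) to a raw (m, V) matrix, normalized here. The
    result has n_categories x excerpts_per_category x n_subjects entries
    (126 at the default protocol).
    """
    missing_pairs = [
        (s, e)
        for s in range(spec.n_subjects)
        for e in range(spec.n_excerpts)
        if (s, e) not in bold
    ]
    if missing_pairs:
        raise ValueError(f"missing BOLD data for (subject, excerpt) pairs: {missing_pairs}")
    if len(designs) != spec.n_excerpts:
        raise ValueError(
            f"need {spec.n_excerpts} excerpt designs, got {len(designs)}"
        )
    samples = []
    for s in range(spec.n_subjects):
        for e in range(spec.n_excerpts):
            Xn, miss = normalize_voxels(bold[(s, e)])
            cat = (
                int(categories[e])
                if categories is not None
                else e // spec.excerpts_per_category
            )
            samples.append(
                EncodingSample(
                    design=designs[e],
                    bold=Xn,
                    subject=s,
                    excerpt=e,
                    category=cat,
                    layer=layer,
                    missing=miss,
                )
            )
    return samples


def select_lambda(
    samples: Sequence[EncodingSample],
    grid: Sequence[float] = DEFAULT_LAMBDA_GRID,
) -> tuple[float, pd.DataFrame]:
    """Leave-one-sample-out selection of the sparsity penalty.

    For each candidate, each sample is held out in turn; the model is fit
    on the remaining samples' stacked (z-scored) designs and responses,
    then scored on the held-out sample (mean PCC over its non-missing
    voxels). Fold scores are averaged unweighted; ties break toward the
    larger (sparser) penalty. Returns (best_lambda, selection record).
    """
    if len(samples) < 2:
        raise ValueError("need at least 2 samples for leave-one-out selection")
    grid = sorted(grid)
    if any(g <= 0 for g in grid):
        raise ValueError("grid values must be strictly positive")
    # per-sample standardization once, outside the fold loop
    zdesigns = [standardize_columns(s.design)[0] for s in samples]
    rows = []
    for lam in grid:
        fold_scores = []
        for i, held in enumerate(samples):
            Dtr = np.concatenate([z for j, z in enumerate(zdesigns) if j != i])
            Xtr = np.concatenate([s.bold for j, s in enumerate(samples) if j != i])
            model = VoxelEncodingModel(alpha=lam, standardize=False).fit(Dtr, Xtr)
            pred = zdesigns[i] @ model.coef_.T
            r = pearson_columns(pred, held.bold)
            r[(pred.std(axis=0) == 0) & ~held.missing] = 0.0
            r[held.missing] = np.nan
            fold_scores.append(np.nanmean(r))
        rows.append({"lambda": lam, "mean_heldout_pcc": float(np.mean(fold_scores))})
    record = pd.DataFrame(rows)
    best_score = record["mean_heldout_pcc"].max()
    best = record.loc[
        record["mean_heldout_pcc"] >= best_score - 1e-12, "lambda"
    ].max()  # ties -> larger penalty
    return float(best), record
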