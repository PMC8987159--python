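"""Pearson-correlation scoring used throughout the encoding pipeline."""

from __future__ import annotations

import numpy as np


def pearson(a: np.ndarray, b: np.ndarray) -> float:
    """PCC of two 1-D vectors; NaN if either is constant."""
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.shape != b.shape:
        raise ValueError("vectors must have equal length")
    ac = a - a.mean()
    bc = b - b.mean()
    na = np.sqrt(ac @ ac)
    nb = np.sqrt(bc @ bc)
    if na == 0.0 or nb == 0.0:
        return np.nan
    return float(np.clip(ac @ bc / (na * nb), -1.0, 1.0))


def pearson_columns(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Column-wise PCC between two (m, V) matrices; NaN where constant."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"shape mismatch: {x.shape} vs {y.shape}")
    xc = x - x.mean(axis=0)
    yc = y - y.mean(axis=0)
    nx = np.linalg.norm(xc, axis=0)
    ny = np.linalg.norm(yc, axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.einsum("ij,ij->j", xc, yc) / (nx * ny)
    r[(nx == 0) | (ny == 0)] = np.nan
    return np.clip(r, -1.0, 1.0)


def pearson_rows(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Row-wise PCC between two (n, t) matrices; NaN where constant."""
    return pearson_columns(np.asarray(x).T, np.asarray(y).T)
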