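"""Body size as a geometric mean and phylogenetic size correction.

Traits are log-transformed and regressed on log size by generalized least
squares whose error covariance is the Brownian-motion tree covariance
(shared path lengths); the residuals are the size-corrected shape traits.
Natural logs throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve

from .data_io import TRAIT_COLUMNS
from .phylo import Phylogeny

__all__ = ["SizeCorrectedTraits", "geometric_mean_size", "phylo_size_residuals"]


@dataclass
class SizeCorrectedTraits:
    """GLS residuals of log traits on log size, plus the fitted allometry."""

    species: list
    size: pd.Series
    residuals: pd.DataFrame
    slopes: pd.Series
    intercepts: pd.Series


def geometric_mean_size(std_length, body_width, body_depth):
    """Geometric mean of the three major body axes: (a*b*c)^(1/3)."""
    a = np.asarray(std_length, dtype=float)
    b = np.asarray(body_width, dtype=float)
    c = np.asarray(body_depth, dtype=float)
    if np.any(a <= 0) or np.any(b <= 0) or np.any(c <= 0):
        raise ValueError("size axes must be positive")
    return np.exp((np.log(a) + np.log(b) + np.log(c)) / 3.0)


def gls_fit(C: np.ndarray, x: np.ndarray, y: np.ndarray):
    """Closed-form GLS of y on [1, x]: returns (intercept, slope, residuals)."""
    n = len(x)
    X = np.column_stack([np.ones(n), x])
    cf = cho_factor(C)
    CiX = cho_solve(cf, X)
    Ciy = cho_solve(cf, y)
    beta = np.linalg.solve(X.T @ CiX, X.T @ Ciy)
    resid = y - X @ beta
    return float(beta[0]), float(beta[1]), resid


def phylo_size_residuals(tree: Phylogeny, traits: pd.DataFrame,
                         trait_columns=None, size=None) -> SizeCorrectedTraits:
    """Size-correct log traits via phylogenetic GLS residuals on log size.

    ``traits`` holds raw positive measurements with a ``species`` column (or
    species index) aligned to ``tree``; ``size`` defaults to the geometric
    mean of standard length, body width and body depth.
    """
    if trait_columns is None:
        trait_columns = [c for c in TRAIT_COLUMNS if c in traits.columns]
        if not trait_columns:
            raise ValueError("no recognized trait columns in table")
    df = traits.set_index("species") if "species" in traits.columns else traits
    df = df.loc[tree.tip_labels]
    if size is None:
        size = pd.Series(
            geometric_mean_size(df["std_length"], df["body_width"], df["body_depth"]),
            index=df.index, name="size",
        )
    else:
        size = pd.Series(np.asarray(size, dtype=float), index=df.index, name="size")
    vals = df[trait_columns].to_numpy(dtype=float)
    if np.any(vals <= 0):
        raise ValueError("raw traits must be positive for log transform")
    C = tree.vcv()
    log_size = np.log(size.to_numpy())
    resid = np.empty_like(vals)
    slopes, intercepts = {}, {}
    for j, col in enumerate(trait_columns):
        b0, b1, r = gls_fit(C, log_size, np.log(vals[:, j]))
        intercepts[col], slopes[col] = b0, b1
        resid[:, j] = r
    residuals = pd.DataFrame(resid, index=df.index, columns=trait_columns)
    return SizeCorrectedTraits(
        species=list(df.index),
        size=size,
        residuals=residuals,
        slopes=pd.Series(slopes),
        intercepts=pd.Series(intercepts),
    )
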