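"""Landmark-based affine alignment of serial-section coordinate frames."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import pearsonr

from .hotspots import GridSpec, rasterize
from .celltable import DEFAULT_CHANNEL_MAP


@dataclass(frozen=True)
class AffineTransform:
    """2-D affine map ``p -> A @ p + t``."""

    A: np.ndarray  # (2, 2)
    t: np.ndarray  # (2,)

    def __post_init__(self):
        A = np.asarray(self.A, float)
        t = np.asarray(self.t, float)
        if A.shape != (2, 2) or t.shape != (2,):
            raise ValueError("A must be 2x2 and t length-2")
        if not (np.isfinite(A).all() and np.isfinite(t).all()):
            raise ValueError("transform entries must be finite")
        object.__setattr__(self, "A", A)
        object.__setattr__(self, "t", t)

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, float)
        return pts @ self.A.T + self.t

    def inverse(self) -> "AffineTransform":
        Ainv = np.linalg.inv(self.A)
        return AffineTransform(Ainv, -Ainv @ self.t)

    def to_dict(self) -> dict:
        a = self.A
        return {
            "a11": a[0, 0], "a12": a[0, 1], "a21": a[1, 0], "a22": a[1, 1],
            "tx": self.t[0], "ty": self.t[1],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AffineTransform":
        return cls(
            np.array([[d["a11"], d["a12"]], [d["a21"], d["a22"]]], float),
            np.array([d["tx"], d["ty"]], float),
        )

    @classmethod
    def identity(cls) -> "AffineTransform":
        return cls(np.eye(2), np.zeros(2))


def _check_landmarks(moving: np.ndarray, fixed: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    moving = np.asarray(moving, float)
    fixed = np.asarray(fixed, float)
    if moving.ndim != 2 or moving.shape[1] != 2 or moving.shape != fixed.shape:
        raise ValueError("landmarks must be matched (n, 2) arrays")
    if not (np.isfinite(moving).all() and np.isfinite(fixed).all()):
        raise ValueError("landmarks must be finite")
    return moving, fixed


def fit_affine(moving: np.ndarray, fixed: np.ndarray) -> AffineTransform:
    """Least-squares affine transform mapping moving landmarks onto fixed ones.

    Minimises ``sum ||A m_i + t - f_i||^2``.  Requires at least 3
    non-collinear moving landmarks; exactly 3 non-collinear pairs are
    interpolated exactly.
    """
    moving, fixed = _check_landmarks(moving, fixed)
    n = len(moving)
    if n < 3:
        raise ValueError(f"affine fit needs >= 3 landmark pairs, got {n}")
    centered = moving - moving.mean(axis=0)
    if np.linalg.matrix_rank(centered, tol=1e-9 * max(1.0, np.abs(moving).max())) < 2:
        raise ValueError("moving landmarks are collinear: affine fit is degenerate")
    design = np.column_stack([moving, np.ones(n)])
    coef, *_ = np.linalg.lstsq(design, fixed, rcond=None)
    A = coef[:2].T
    t = coef[2]
    return AffineTransform(A, t)


def registration_error(
    transform: AffineTransform,
    moving: np.ndarray,
    fixed: np.ndarray,
    diagonal_um: float,
) -> float:
    """Target registration error as a percentage of the image diagonal.

    Mean over landmark pairs of the residual distance after transformation,
    normalised by the fixed-frame diagonal length, times 100.
    """
    moving, fixed = _check_landmarks(moving, fixed)
    if diagonal_um <= 0:
        raise ValueError("diagonal length must be positive")
    residuals = np.linalg.norm(transform.apply(moving) - fixed, axis=1)
    return float(residuals.mean() / diagonal_um * 100.0)


def density_concordance(
    cells_a: pd.DataFrame,
    cells_b: pd.DataFrame,
    spec: GridSpec,
    channel: str | None = None,
) -> tuple[float, float]:
    """Pearson correlation of per-grid densities between two modalities.

    Both cell tables must already be in the fixed frame.  With ``channel``
    "cancer" or "lymphocyte" only that channel is correlated, otherwise all
    cells count.  Grids that are tissue in either table enter the
    correlation; fewer than 3 such grids is an error.

    Returns ``(r, p)``.
    """
    lat_a = rasterize(cells_a, spec, DEFAULT_CHANNEL_MAP)
    lat_b = rasterize(cells_b, spec, DEFAULT_CHANNEL_MAP)
    if channel is None:
        counts_a = lat_a.cancer + lat_a.lymphocyte
        counts_b = lat_b.cancer + lat_b.lymphocyte
    else:
        counts_a = lat_a.counts(channel)
        counts_b = lat_b.counts(channel)
    mask = lat_a.tissue | lat_b.tissue
    if int(mask.sum()) < 3:
        raise ValueError("need >= 3 occupied grids for a correlation")
    a = counts_a[mask].astype(float)
    b = counts_b[mask].astype(float)
    if a.std() == 0 or b.std() == 0:
        raise ValueError("zero variance in per-grid densities")
    r, p = pearsonr(a, b)
    return float(r), float(p)


def transform_cells(cells: pd.DataFrame, transform: AffineTransform) -> pd.DataFrame:
    """Apply an affine transform to a cell table's coordinates."""
    out = cells.copy()
    pts = transform.apply(out[["x_um", "y_um"]].to_numpy(float))
    out["x_um"] = pts[:, 0]
    out["y_um"] = pts[:, 1]
    return out


def read_landmarks(path) -> tuple[np.ndarray, np.ndarray]:
    """Landmark CSV with columns moving_x_um, moving_y_um, fixed_x_um, fixed_y_um."""
    df = pd.read_csv(path)
    required = ["moving_x_um", "moving_y_um", "fixed_x_um", "fixed_y_um"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"landmark file missing columns {missing}")
    return (
        df[["moving_x_um", "moving_y_um"]].to_numpy(float),
        df[["fixed_x_um", "fixed_y_um"]].to_numpy(float),
    )
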