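"""Grid-based hotspot detection.

Cells are binned onto a square lattice (50x50 um by default), a local
Getis-Ord statistic is evaluated per grid for the cancer and lymphocyte
channels, grids are labelled as cancer hotspots (CH), peritumoral immune
hotspots (IH_peri) or intratumoral immune hotspots (IH_intra), and three
spatial scores summarise the label map.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.stats import norm

from .celltable import DEFAULT_CHANNEL_MAP

# compartment label codes
NONE_LABEL = 0
CH = 1
IH_PERI = 2
IH_INTRA = 3

LABEL_NAMES = {NONE_LABEL: "NONE", CH: "CH", IH_PERI: "IH_peri", IH_INTRA: "IH_intra"}
LABEL_CODES = {v: k for k, v in LABEL_NAMES.items()}


@dataclass(frozen=True)
class GridSpec:
    """Square lattice covering a slide.

    Grid ``(row, col)`` covers the half-open box
    ``[x0 + col*g, x0 + (col+1)*g) x [y0 + row*g, y0 + (row+1)*g)``.
    """

    x0: float
    y0: float
    g: float = 50.0
    n_cols: int = 0
    n_rows: int = 0

    def __post_init__(self):
        if not np.isfinite(self.g) or self.g <= 0:
            raise ValueError("grid size g must be positive and finite")
        if self.n_cols < 0 or self.n_rows < 0:
            raise ValueError("lattice dimensions must be non-negative")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @classmethod
    def from_cells(cls, cells: pd.DataFrame, g: float = 50.0) -> "GridSpec":
        """Lattice covering the bounding box of a cell table.

        The origin is the floor of the bounding-box minimum to a multiple of
        ``g`` so that identical inputs always map to the same lattice.
        """
        if len(cells) == 0:
            return cls(0.0, 0.0, g, 0, 0)
        x = cells["x_um"].to_numpy(dtype=float)
        y = cells["y_um"].to_numpy(dtype=float)
        x0 = np.floor(x.min() / g) * g
        y0 = np.floor(y.min() / g) * g
        n_cols = int(np.floor((x.max() - x0) / g)) + 1
        n_rows = int(np.floor((y.max() - y0) / g)) + 1
        return cls(float(x0), float(y0), g, n_cols, n_rows)

    def bin_indices(self, x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Map coordinates to (row, col) via the half-open convention."""
        col = np.floor((np.asarray(x, float) - self.x0) / self.g).astype(int)
        row = np.floor((np.asarray(y, float) - self.y0) / self.g).astype(int)
        return row, col

    def centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Grid-center coordinates as (x_centers, y_centers) meshgrids."""
        cx = self.x0 + (np.arange(self.n_cols) + 0.5) * self.g
        cy = self.y0 + (np.arange(self.n_rows) + 0.5) * self.g
        return np.meshgrid(cx, cy)


@dataclass
class CountLattice:
    """Per-grid counts for both channels plus the tissue mask."""

    spec: GridSpec
    cancer: np.ndarray  # (n_rows, n_cols) int
    lymphocyte: np.ndarray
    tissue: np.ndarray  # bool: grid contains >= 1 cell of any class

    def counts(self, channel: str) -> np.ndarray:
        if channel not in ("cancer", "lymphocyte"):
            raise ValueError(f"unknown channel {channel!r}")
        return getattr(self, channel)


@dataclass(frozen=True)
class NeighborWeights:
    """Binary queen-contiguity weights up to Chebyshev order ``max_order``.

    Order-1 neighbors are the <=8 grids sharing an edge or vertex; order ``k``
    is the full ``(2k+1) x (2k+1)`` window (Chebyshev distance <= k).  The
    focal grid itself is included iff ``include_self`` (Gi* convention).
    """

    spec: GridSpec
    max_order: int = 4
    include_self: bool = True

    def __post_init__(self):
        if self.max_order < 1:
            raise ValueError("max_order must be >= 1")

    def kernel(self) -> np.ndarray:
        k = self.max_order
        kern = np.ones((2 * k + 1, 2 * k + 1), dtype=float)
        if not self.include_self:
            kern[k, k] = 0.0
        return kern

    def neighbor_indices(self, row: int, col: int) -> list[tuple[int, int]]:
        """Explicit neighbor set of one grid (clipped to the lattice)."""
        k = self.max_order
        out = []
        for r in range(max(0, row - k), min(self.spec.n_rows, row + k + 1)):
            for c in range(max(0, col - k), min(self.spec.n_cols, col + k + 1)):
                if (r, c) == (row, col) and not self.include_self:
                    continue
                out.append((r, c))
        return out


@dataclass
class HotspotLabelMap:
    """Per-grid Getis-Ord z/p values for both channels plus compartment label."""

    spec: GridSpec
    z_cancer: np.ndarray
    z_lymph: np.ndarray
    p_cancer: np.ndarray
    p_lymph: np.ndarray
    labels: np.ndarray  # int codes, NONE_LABEL outside tissue
    tissue: np.ndarray
    alpha: float = 0.05
    metadata: dict = field(default_factory=dict)

    def label_counts(self) -> dict[str, int]:
        return {
            name: int(np.sum(self.labels == code))
            for code, name in LABEL_NAMES.items()
        }

    def to_frame(self) -> pd.DataFrame:
        rows, cols = np.nonzero(self.tissue)
        return pd.DataFrame(
            {
                "row": rows,
                "col": cols,
                "z_cancer": self.z_cancer[rows, cols],
                "z_lymph": self.z_lymph[rows, cols],
                "p_cancer": self.p_cancer[rows, cols],
                "p_lymph": self.p_lymph[rows, cols],
                "label": [LABEL_NAMES[c] for c in self.labels[rows, cols]],
            }
        )


@dataclass
class SpatialScores:
    """The three intratumoral-IH spatial scores plus compartment areas."""

    s_intra_immune: Optional[float]
    s_intra_cancer: Optional[float]
    s_intra_tissue: Optional[float]
    n_ih_intra: int
    n_ih_peri: int
    n_ch: int
    n_tissue: int
    notes: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "s_intra_immune": self.s_intra_immune,
                    "s_intra_cancer": self.s_intra_cancer,
                    "s_intra_tissue": self.s_intra_tissue,
                    "n_ih_intra": self.n_ih_intra,
                    "n_ih_peri": self.n_ih_peri,
                    "n_ch": self.n_ch,
                    "n_tissue": self.n_tissue,
                }
            ]
        )


def rasterize(
    cells: pd.DataFrame,
    spec: GridSpec,
    channel_map: Mapping[str, str] = DEFAULT_CHANNEL_MAP,
) -> CountLattice:
    """Bin cells onto the lattice and count per channel.

    Each cell falls in exactly one grid via half-open intervals
    ``[x0 + c*g, x0 + (c+1)*g)``.  A grid is tissue iff it contains at least
    one cell of any class (including ignored classes).  Cells outside the
    lattice bounds raise, reporting how many fell outside.
    """
    cancer = np.zeros(spec.shape, dtype=np.int64)
    lymph = np.zeros(spec.shape, dtype=np.int64)
    tissue = np.zeros(spec.shape, dtype=bool)
    if len(cells) == 0:
        return CountLattice(spec, cancer, lymph, tissue)

    x = cells["x_um"].to_numpy(dtype=float)
    y = cells["y_um"].to_numpy(dtype=float)
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("cell coordinates must be finite")
    row, col = spec.bin_indices(x, y)
    outside = (row < 0) | (row >= spec.n_rows) | (col < 0) | (col >= spec.n_cols)
    if outside.any():
        raise ValueError(
            f"{int(outside.sum())} cells fall outside the lattice bounds"
        )

    labels = cells["class"].astype(str).to_numpy()
    unknown = sorted(set(labels) - set(channel_map))
    if unknown:
        raise ValueError(f"classes {unknown} missing from channel_map")
    channels = np.array([channel_map[lbl] for lbl in labels], dtype=object)

    np.add.at(tissue, (row, col), True)
    m = channels == "cancer"
    np.add.at(cancer, (row[m], col[m]), 1)
    m = channels == "lymphocyte"
    np.add.at(lymph, (row[m], col[m]), 1)
    return CountLattice(spec, cancer, lymph, tissue)


def build_neighbors(
    spec: GridSpec, max_order: int = 4, include_self: bool = True
) -> NeighborWeights:
    """Queen-contiguity neighborhood up to Chebyshev order ``max_order``."""
    return NeighborWeights(spec, max_order, include_self)


def getis_ord(
    lattice: CountLattice,
    weights: NeighborWeights,
    channel: str,
) -> tuple[np.ndarray, np.ndarray]:
    """Local Getis-Ord statistic per tissue grid for one channel.

    With binary weights ``W`` over the neighborhood window, the z score of
    grid j is::

        z_j = (sum_i W_ji C_i - xbar * sum_i W_ji)
              / (S * sqrt((n * sum_i W_ji - (sum_i W_ji)^2) / (n - 1)))

    where the sums range over tissue grids, ``n`` is the number of tissue
    grids and ``xbar``/``S`` are the mean and population SD of counts over
    tissue grids.  Background (non-tissue) grids carry no counts, do not
    enter the statistic population, and receive ``z = p = NaN``.  The p value
    is the one-sided upper tail of the standard normal (hotspots only).

    Returns ``(z, p)`` arrays of the lattice shape.
    """
    C = lattice.counts(channel).astype(float)
    T = lattice.tissue
    n = int(T.sum())
    z = np.full(lattice.spec.shape, np.nan)
    p = np.full(lattice.spec.shape, np.nan)
    if n < 2:
        raise ValueError("need at least 2 tissue grids")

    vals = C[T]
    xbar = vals.mean()
    S = vals.std()  # population SD
    if S == 0.0:
        # zero count variance: statistic undefined everywhere
        return z, p

    kern = weights.kernel()
    # neighbor sums restricted to tissue grids; W binary so sum(W^2) = sum(W)
    wc = ndimage.convolve(C * T, kern, mode="constant", cval=0.0)
    wsum = ndimage.convolve(T.astype(float), kern, mode="constant", cval=0.0)

    with np.errstate(invalid="ignore", divide="ignore"):
        var_term = (n * wsum - wsum**2) / (n - 1)
        denom = S * np.sqrt(var_term)
        zz = (wc - xbar * wsum) / denom
    z[T] = zz[T]
    p[T] = norm.sf(z[T])
    return z, p


def getis_ord_loop(
    lattice: CountLattice, weights: NeighborWeights, channel: str
) -> np.ndarray:
    """Literal per-grid loop evaluation of the same statistic (reference path,
    used by the oracle-equivalence checks; O(n * window))."""
    C = lattice.counts(channel).astype(float)
    T = lattice.tissue
    n = int(T.sum())
    z = np.full(lattice.spec.shape, np.nan)
    if n < 2:
        raise ValueError("need at least 2 tissue grids")
    vals = C[T]
    xbar = float(vals.mean())
    S = float(vals.std())
    if S == 0.0:
        return z
    for row in range(lattice.spec.n_rows):
        for col in range(lattice.spec.n_cols):
            if not T[row, col]:
                continue
            wc = 0.0
            wsum = 0.0
            for r, c in weights.neighbor_indices(row, col):
                if T[r, c]:
                    wc += C[r, c]
                    wsum += 1.0
            var_term = (n * wsum - wsum * wsum) / (n - 1)
            if var_term <= 0:
                continue
            z[row, col] = (wc - xbar * wsum) / (S * np.sqrt(var_term))
    return z


def label_compartments(
    lattice: CountLattice,
    weights: NeighborWeights,
    alpha: float = 0.05,
) -> HotspotLabelMap:
    """Run both channels and label compartments at threshold ``alpha``.

    Label rules (strict inequality; ties at ``p == alpha`` are
    non-significant):

    * CH:       p_cancer < alpha and p_lymph >= alpha
    * IH_peri:  p_lymph < alpha and p_cancer >= alpha
    * IH_intra: both p < alpha
    * NONE:     otherwise, and all non-tissue grids
    """
    z_c, p_c = getis_ord(lattice, weights, "cancer")
    z_l, p_l = getis_ord(lattice, weights, "lymphocyte")
    return label_from_pvalues(lattice.spec, z_c, z_l, p_c, p_l, lattice.tissue, alpha)


def label_from_pvalues(
    spec: GridSpec,
    z_c: np.ndarray,
    z_l: np.ndarray,
    p_c: np.ndarray,
    p_l: np.ndarray,
    tissue: np.ndarray,
    alpha: float = 0.05,
) -> HotspotLabelMap:
    """Compartment labelling given precomputed per-grid p values."""
    labels = np.full(spec.shape, NONE_LABEL, dtype=np.int8)
    with np.errstate(invalid="ignore"):
        sig_c = (p_c < alpha) & tissue & np.isfinite(p_c)
        sig_l = (p_l < alpha) & tissue & np.isfinite(p_l)
    labels[sig_c & ~sig_l] = CH
    labels[sig_l & ~sig_c] = IH_PERI
    labels[sig_c & sig_l] = IH_INTRA
    degenerate = not (np.isfinite(p_c[tissue]).any() or np.isfinite(p_l[tissue]).any())
    meta = {"alpha": alpha, "degenerate": bool(degenerate)}
    return HotspotLabelMap(spec, z_c, z_l, p_c, p_l, labels, tissue, alpha, meta)


def spatial_scores(label_map: HotspotLabelMap) -> SpatialScores:
    """The three spatial scores from compartment areas (in grid counts).

    * s_intra_immune = |IH_intra| / (|IH_intra| + |IH_peri|)
    * s_intra_cancer = |IH_intra| / (|IH_intra| + |CH|)
    * s_intra_tissue = |IH_intra| / |tissue|

    A zero denominator yields ``None`` with an explanatory note.  A map with
    no tissue grids is an error.
    """
    n_tissue = int(label_map.tissue.sum())
    if n_tissue == 0:
        raise ValueError("no tissue grids: scores undefined")
    n_intra = int(np.sum(label_map.labels == IH_INTRA))
    n_peri = int(np.sum(label_map.labels == IH_PERI))
    n_ch = int(np.sum(label_map.labels == CH))

    notes: dict[str, str] = {}

    def ratio(num: int, den: int, name: str) -> Optional[float]:
        if den == 0:
            notes[name] = "denominator is zero"
            return None
        return num / den

    return SpatialScores(
        s_intra_immune=ratio(n_intra, n_intra + n_peri, "s_intra_immune"),
        s_intra_cancer=ratio(n_intra, n_intra + n_ch, "s_intra_cancer"),
        s_intra_tissue=ratio(n_intra, n_tissue, "s_intra_tissue"),
        n_ih_intra=n_intra,
        n_ih_peri=n_peri,
        n_ch=n_ch,
        n_tissue=n_tissue,
        notes=notes,
    )
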