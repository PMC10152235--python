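"""Individual immune hotspots: 8-connected components of IH grids,
exclusion of annotated lymphoid structures, and majority-area compartment
assignment of those structures."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
import shapely
from scipy import ndimage
from shapely.geometry import shape as shapely_shape

from .hotspots import (
    CH,
    GridSpec,
    HotspotLabelMap,
    IH_INTRA,
    IH_PERI,
    LABEL_NAMES,
    NONE_LABEL,
)

ANNOTATION_KINDS = ("TLS", "LAG")


@dataclass
class RegionAnnotation:
    """A pathologist-delineated lymphoid structure (TLS or LAG) polygon."""

    id: str
    kind: str  # TLS | LAG
    geometry: shapely.Geometry
    grid_mask: Optional[np.ndarray] = None  # filled by rasterize_annotation
    assigned_compartment: Optional[str] = None

    def __post_init__(self):
        if self.kind not in ANNOTATION_KINDS:
            raise ValueError(f"annotation kind must be one of {ANNOTATION_KINDS}")
        if not self.geometry.is_valid:
            raise ValueError(f"annotation {self.id}: invalid (self-intersecting?) geometry")


@dataclass
class IHComponent:
    """One 8-connected individual immune hotspot."""

    component_id: int
    grids: np.ndarray  # (n, 2) array of (row, col)
    grid_labels: np.ndarray  # per-grid label code (IH_PERI or IH_INTRA)
    cell_index: Optional[np.ndarray] = None  # indices into the IHC cell table

    @property
    def area(self) -> int:
        return len(self.grids)

    @property
    def n_intra(self) -> int:
        return int(np.sum(self.grid_labels == IH_INTRA))

    @property
    def n_peri(self) -> int:
        return int(np.sum(self.grid_labels == IH_PERI))

    @property
    def majority_compartment(self) -> str:
        # peri/intra tie resolved toward intratumoral
        return "IH_intra" if self.n_intra >= self.n_peri else "IH_peri"


def rasterize_annotation(annotation: RegionAnnotation, spec: GridSpec) -> np.ndarray:
    """Boolean grid mask: grids whose centers fall inside the polygon."""
    cx, cy = spec.centers()
    if cx.size == 0:
        mask = np.zeros(spec.shape, dtype=bool)
    else:
        mask = shapely.contains_xy(annotation.geometry, cx.ravel(), cy.ravel()).reshape(
            spec.shape
        )
    annotation.grid_mask = mask
    return mask


def annotation_mask(
    annotations: Iterable[RegionAnnotation], spec: GridSpec
) -> np.ndarray:
    """Union of all annotation grid masks."""
    total = np.zeros(spec.shape, dtype=bool)
    for ann in annotations:
        mask = ann.grid_mask if ann.grid_mask is not None else rasterize_annotation(ann, spec)
        if mask.shape != spec.shape:
            mask = rasterize_annotation(ann, spec)
        total |= mask
    return total


def connected_components(
    label_map: HotspotLabelMap,
    annotations: Sequence[RegionAnnotation] = (),
    connectivity: int = 8,
) -> tuple[list[IHComponent], dict]:
    """Segment individual immune hotspots.

    Components are computed over the union of IH_peri and IH_intra grids
    (the hotspot is indexed regardless of its compartment make-up) with the
    requested connectivity; each member grid then retains its own peri/intra
    label.  Grids inside any TLS/LAG annotation are removed *before* the
    component analysis, so an annotation may split a hotspot in two.

    Returns ``(components, info)`` where ``info`` reports the number of IH
    grids excluded by annotations.
    """
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    ih = np.isin(label_map.labels, (IH_PERI, IH_INTRA))
    excluded = annotation_mask(annotations, label_map.spec) if annotations else np.zeros_like(ih)
    n_excluded_ih = int(np.sum(ih & excluded))
    mask = ih & ~excluded

    structure = (
        np.ones((3, 3), dtype=int) if connectivity == 8 else ndimage.generate_binary_structure(2, 1)
    )
    labeled, n = ndimage.label(mask, structure=structure)
    components: list[IHComponent] = []
    for comp_id in range(1, n + 1):
        rows, cols = np.nonzero(labeled == comp_id)
        grids = np.column_stack([rows, cols])
        grid_labels = label_map.labels[rows, cols]
        components.append(IHComponent(comp_id, grids, grid_labels))
    info = {
        "n_components": n,
        "n_ih_grids": int(ih.sum()),
        "n_excluded_ih_grids": n_excluded_ih,
        "component_label_array": labeled,
    }
    return components, info


def assign_cells(
    components: Sequence[IHComponent],
    cells: pd.DataFrame,
    spec: GridSpec,
) -> None:
    """Attach cell indices to each component.

    A cell belongs to a component iff its containing grid is a member grid;
    cells in excluded/other grids are left unassigned.
    """
    if len(cells) == 0:
        for comp in components:
            comp.cell_index = np.array([], dtype=int)
        return
    row, col = spec.bin_indices(
        cells["x_um"].to_numpy(float), cells["y_um"].to_numpy(float)
    )
    inside = (row >= 0) & (row < spec.n_rows) & (col >= 0) & (col < spec.n_cols)
    flat = np.full(len(cells), -1, dtype=np.int64)
    flat[inside] = row[inside] * spec.n_cols + col[inside]
    for comp in components:
        member_flat = comp.grids[:, 0] * spec.n_cols + comp.grids[:, 1]
        comp.cell_index = np.flatnonzero(np.isin(flat, member_flat))


def assign_structure_compartment(
    annotation: RegionAnnotation, label_map: HotspotLabelMap
) -> str:
    """Assign a TLS/LAG to the compartment holding the majority of its area.

    Overlap is measured in grids (center-inclusion rasterization).  An exact
    peri/intra tie goes to IH_intra; zero overlap with tissue yields NONE.
    """
    mask = annotation.grid_mask
    if mask is None or mask.shape != label_map.spec.shape:
        mask = rasterize_annotation(annotation, label_map.spec)
    overlap_tissue = mask & label_map.tissue
    if not overlap_tissue.any():
        annotation.assigned_compartment = "NONE"
        return "NONE"
    labels = label_map.labels[overlap_tissue]
    # argmax over this order resolves the documented peri/intra tie toward
    # IH_intra (and any other exact tie toward the earlier compartment)
    order = (IH_INTRA, IH_PERI, CH, NONE_LABEL)
    counts = [int(np.sum(labels == code)) for code in order]
    winner = order[int(np.argmax(counts))]
    name = LABEL_NAMES[winner]
    annotation.assigned_compartment = name
    return name


def components_table(components: Sequence[IHComponent]) -> pd.DataFrame:
    """Summary table, one row per individual immune hotspot."""
    rows = []
    for comp in components:
        rows.append(
            {
                "component_id": comp.component_id,
                "n_grids": comp.area,
                "n_grids_intra": comp.n_intra,
                "n_grids_peri": comp.n_peri,
                "majority_compartment": comp.majority_compartment,
                "n_cells": len(comp.cell_index) if comp.cell_index is not None else np.nan,
            }
        )
    cols = [
        "component_id",
        "n_grids",
        "n_grids_intra",
        "n_grids_peri",
        "majority_compartment",
        "n_cells",
    ]
    return pd.DataFrame(rows, columns=cols)


def annotations_from_geojson(obj: dict) -> list[RegionAnnotation]:
    """Parse a GeoJSON FeatureCollection with a ``kind`` property per feature."""
    if obj.get("type") != "FeatureCollection":
        raise ValueError("expected a GeoJSON FeatureCollection")
    out = []
    for i, feat in enumerate(obj.get("features", [])):
        props = feat.get("properties") or {}
        kind = props.get("kind")
        if kind not in ANNOTATION_KINDS:
            raise ValueError(f"feature {i}: property 'kind' must be one of {ANNOTATION_KINDS}")
        geom = shapely_shape(feat["geometry"])
        out.append(RegionAnnotation(id=str(props.get("id", i)), kind=kind, geometry=geom))
    return out
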