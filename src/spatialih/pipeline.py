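"""End-to-end per-slide pipeline driver.

Stages: (optional) registration -> rasterize -> Getis-Ord -> compartment
labels -> spatial scores -> individual hotspot components -> interaction
profiles.  Each stage writes its artifacts into the output directory along
with the config; a structured log records per-stage counts.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from . import components as comp_mod
from . import hotspots as hs
from . import interactions as ia
from .celltable import IMMUNE_SUBSETS
from .io import PipelineConfig, write_cell_table, write_geojson
from .registration import AffineTransform, transform_cells

logger = logging.getLogger("spatialih")


class StageError(RuntimeError):
    """A pipeline stage failed; the stage name is part of the message."""


def run_slide(
    cells: pd.DataFrame,
    config: PipelineConfig,
    out_dir: Optional[Path] = None,
    annotations: Sequence[comp_mod.RegionAnnotation] = (),
    ihc_cells: Optional[pd.DataFrame] = None,
    transform: Optional[AffineTransform] = None,
    slide_id: str = "slide",
) -> dict:
    """Run the per-slide pipeline and (optionally) write the output bundle.

    ``cells`` drives hotspot detection (H&E channels or mapped IHC classes);
    ``ihc_cells`` (defaults to ``cells``) supplies the immune cells for the
    interaction stage.  A fitted ``transform`` is applied to ``ihc_cells``
    before analysis.  Returns a dict bundle with every stage's artifacts.
    """
    bundle: dict = {"slide_id": slide_id, "config_hash": config.config_hash()}
    stage = "setup"
    try:
        if ihc_cells is None:
            ihc_cells = cells
        if transform is not None:
            stage = "register"
            ihc_cells = transform_cells(ihc_cells, transform)
            logger.info("%s register: transformed %d cells", slide_id, len(ihc_cells))

        stage = "rasterize"
        spec = hs.GridSpec.from_cells(cells, config.grid_um)
        lattice = hs.rasterize(cells, spec)
        logger.info(
            "%s rasterize: %d cells -> %dx%d lattice, %d tissue grids",
            slide_id, len(cells), spec.n_rows, spec.n_cols, int(lattice.tissue.sum()),
        )
        bundle["spec"] = spec
        bundle["lattice"] = lattice

        stage = "getis_ord"
        weights = hs.build_neighbors(spec, config.neighbor_order, config.include_self)
        label_map = hs.label_compartments(lattice, weights, config.alpha)
        bundle["label_map"] = label_map
        logger.info("%s getis_ord: labels %s", slide_id, label_map.label_counts())

        stage = "spatial_scores"
        scores = hs.spatial_scores(label_map)
        bundle["scores"] = scores

        if config.run_components:
            stage = "components"
            comps, info = comp_mod.connected_components(
                label_map, annotations, config.connectivity
            )
            comp_mod.assign_cells(comps, ihc_cells, spec)
            for ann in annotations:
                comp_mod.assign_structure_compartment(ann, label_map)
            bundle["components"] = comps
            bundle["components_info"] = info
            logger.info(
                "%s components: %d hotspots, %d IH grids excluded by annotations",
                slide_id, info["n_components"], info["n_excluded_ih_grids"],
            )

            if config.run_interactions:
                stage = "interactions"
                bundle["profiles"] = _interaction_profiles(
                    comps, ihc_cells, config.max_edge_um
                )
                logger.info(
                    "%s interactions: %d profiled hotspots", slide_id,
                    len(bundle["profiles"]),
                )
    except Exception as exc:
        raise StageError(f"stage {stage!r} failed for {slide_id}: {exc}") from exc

    if out_dir is not None:
        _write_bundle(bundle, Path(out_dir), config, annotations)
    return bundle


def _interaction_profiles(
    components: Sequence[comp_mod.IHComponent],
    ihc_cells: pd.DataFrame,
    max_edge_um: float,
) -> pd.DataFrame:
    labels_all = ihc_cells["class"].to_numpy(object)
    immune_mask = pd.Series(labels_all).isin(IMMUNE_SUBSETS).to_numpy()
    rows = []
    for comp in components:
        idx = comp.cell_index
        if idx is None:
            continue
        idx = idx[immune_mask[idx]]
        sub = ihc_cells.iloc[idx]
        graph = ia.build_graph(
            sub["x_um"].to_numpy(float), sub["y_um"].to_numpy(float), max_edge_um
        )
        lbls = sub["class"].to_numpy(object)
        if graph.vertex_index is not None:
            lbls = lbls[graph.vertex_index]
        profile = ia.interaction_fractions(graph, lbls)
        row = {
            "component_id": comp.component_id,
            "compartment": comp.majority_compartment,
        }
        row.update(profile.to_row())
        rows.append(row)
    return pd.DataFrame(rows)


def _write_bundle(bundle, out_dir: Path, config: PipelineConfig, annotations) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    config.dump(out_dir)
    sid = bundle["slide_id"]
    label_map = bundle["label_map"]
    df = label_map.to_frame()
    df.insert(0, "config_hash", bundle["config_hash"])
    df.to_csv(out_dir / f"{sid}_hotspots.csv", index=False)
    scores_df = bundle["scores"].to_frame()
    scores_df.insert(0, "slide_id", sid)
    scores_df.insert(1, "config_hash", bundle["config_hash"])
    scores_df.to_csv(out_dir / f"{sid}_scores.tsv", sep="\t", index=False)
    if "components" in bundle:
        comp_df = comp_mod.components_table(bundle["components"])
        comp_df.insert(0, "config_hash", bundle["config_hash"])
        comp_df.to_csv(out_dir / f"{sid}_components.csv", index=False)
        if annotations:
            ann_df = pd.DataFrame(
                [
                    {"id": a.id, "kind": a.kind, "compartment": a.assigned_compartment}
                    for a in annotations
                ]
            )
            ann_df.to_csv(out_dir / f"{sid}_structures.csv", index=False)
    if "profiles" in bundle and len(bundle["profiles"]):
        prof = bundle["profiles"].copy()
        prof.insert(0, "config_hash", bundle["config_hash"])
        prof.to_csv(out_dir / f"{sid}_interactions.csv", index=False)


def run_cohort(
    slides: dict[str, pd.DataFrame],
    config: PipelineConfig,
    out_dir: Optional[Path] = None,
) -> pd.DataFrame:
    """Run every slide and collect one score row per slide."""
    rows = []
    for slide_id, cells in slides.items():
        bundle = run_slide(cells, config, out_dir=None, slide_id=slide_id)
        s = bundle["scores"]
        rows.append(
            {
                "slide_id": slide_id,
                "s_intra_immune": s.s_intra_immune,
                "s_intra_cancer": s.s_intra_cancer,
                "s_intra_tissue": s.s_intra_tissue,
                "n_ih_intra": s.n_ih_intra,
                "n_ih_peri": s.n_ih_peri,
                "n_ch": s.n_ch,
                "n_tissue": s.n_tissue,
            }
        )
    out = pd.DataFrame(rows)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        config.dump(out_dir)
        out.insert(1, "config_hash", config.config_hash())
        out.to_csv(out_dir / "cohort_scores.csv", index=False)
    return out
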