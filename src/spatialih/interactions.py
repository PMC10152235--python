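"""Cell-cell interaction analysis within individual immune hotspots.

Immune cells of one hotspot are joined by a Delaunay triangulation whose
edges longer than 250 um are discarded; pairwise link fractions, Shannon
diversity indices and composition metrics are derived per hotspot, and the
comparative statistics (Wilcoxon tests with BH adjustment, median splits,
univariate logistic regression) operate on the per-hotspot profiles.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.spatial import Delaunay, QhullError
from scipy.stats import mannwhitneyu, wilcoxon
from statsmodels.stats.multitest import multipletests

from .celltable import B_SUBSETS, IMMUNE_SUBSETS

#: the 21 unordered subset pairs (6 same-type + 15 mixed), canonical order
SUBSET_PAIRS: tuple[tuple[str, str], ...] = tuple(
    itertools.combinations_with_replacement(IMMUNE_SUBSETS, 2)
)


def pair_key(a: str, b: str) -> tuple[str, str]:
    """Canonical unordered pair."""
    i, j = IMMUNE_SUBSETS.index(a), IMMUNE_SUBSETS.index(b)
    return (a, b) if i <= j else (b, a)


@dataclass
class DelaunayGraph:
    """Pruned Delaunay graph over the immune cells of one hotspot."""

    points: np.ndarray  # (n, 2), deduplicated locations
    edges: np.ndarray  # (m, 2) vertex index pairs, i < j
    lengths: np.ndarray  # (m,) Euclidean edge lengths in um
    max_edge_um: float
    n_duplicates: int = 0  # coincident input points collapsed
    degenerate: bool = False  # < 3 points or collinear: no triangulation
    vertex_index: Optional[np.ndarray] = None  # rows of the input kept per vertex

    @property
    def n_vertices(self) -> int:
        return len(self.points)

    @property
    def n_edges(self) -> int:
        return len(self.edges)


@dataclass
class InteractionProfile:
    """Link fractions, diversity and composition of one hotspot."""

    fractions: dict  # (a, b) canonical pair -> fraction of edges
    n_edges: int
    counts: dict  # subset -> vertex count
    percentages: dict  # subset -> count / total immune cells
    h_interaction: Optional[float]
    h_composition: Optional[float]
    cd8_treg_ratio: Optional[float]
    b_cell_pct: Optional[float]

    def to_row(self) -> dict:
        row: dict = {"n_edges": self.n_edges}
        for a, b in SUBSET_PAIRS:
            val = self.fractions.get((a, b), np.nan) if self.fractions else np.nan
            row[f"f_{a}__{b}"] = val
        for s in IMMUNE_SUBSETS:
            row[f"n_{s}"] = self.counts.get(s, 0)
            row[f"pct_{s}"] = self.percentages.get(s, np.nan)
        row["h_interaction"] = self.h_interaction
        row["h_composition"] = self.h_composition
        row["cd8_treg_ratio"] = self.cd8_treg_ratio
        row["b_cell_pct"] = self.b_cell_pct
        return row


def build_graph(
    x: np.ndarray,
    y: np.ndarray,
    max_edge_um: float = 250.0,
) -> DelaunayGraph:
    """Delaunay triangulation of cell coordinates with long edges pruned.

    Coincident points are collapsed to a single vertex (count recorded in
    ``n_duplicates``); fewer than 3 distinct points, or a collinear
    configuration, yields an empty edge set flagged ``degenerate``.
    """
    pts = np.column_stack([np.asarray(x, float), np.asarray(y, float)])
    if not np.isfinite(pts).all():
        raise ValueError("coordinates must be finite")
    uniq, index = np.unique(pts, axis=0, return_index=True)
    # keep first-seen order so vertex labels stay aligned with the input
    keep = np.sort(index)
    dedup = pts[keep]
    n_dup = len(pts) - len(dedup)

    empty = DelaunayGraph(
        dedup,
        np.empty((0, 2), dtype=int),
        np.empty(0),
        max_edge_um,
        n_dup,
        degenerate=True,
        vertex_index=keep,
    )
    if len(dedup) < 3:
        return empty
    try:
        tri = Delaunay(dedup)
    except QhullError:
        return empty

    edges = set()
    for simplex in tri.simplices:
        for i, j in itertools.combinations(simplex, 2):
            edges.add((min(i, j), max(i, j)))
    edge_arr = np.array(sorted(edges), dtype=int)
    lengths = np.linalg.norm(dedup[edge_arr[:, 0]] - dedup[edge_arr[:, 1]], axis=1)
    keep_e = lengths <= max_edge_um
    return DelaunayGraph(
        dedup,
        edge_arr[keep_e],
        lengths[keep_e],
        max_edge_um,
        n_dup,
        degenerate=False,
        vertex_index=keep,
    )


def shannon(values: Sequence[float], base: Optional[float] = None) -> float:
    """Shannon diversity H = -sum p_k log p_k over categories with p_k > 0.

    Natural log by default; pass ``base`` for another logarithm base.
    All-zero (or empty) input is an error.
    """
    w = np.asarray(values, dtype=float)
    if w.size == 0 or np.any(w < 0) or not np.isfinite(w).all():
        raise ValueError("weights must be finite and non-negative")
    total = w.sum()
    if total == 0:
        raise ValueError("all-zero weights: diversity undefined")
    p = w[w > 0] / total
    h = float(-(p * np.log(p)).sum())
    if base is not None:
        h /= np.log(base)
    return h


def interaction_fractions(
    graph: DelaunayGraph, labels: Sequence[str]
) -> InteractionProfile:
    """Per-hotspot interaction profile from a pruned Delaunay graph.

    ``f(a,b)`` is the fraction of edges whose endpoint subsets are ``{a,b}``,
    over the 21 unordered pairs.  Composition metrics (counts, percentages,
    CD8/Treg ratio, B-cell fraction) come from the vertex labels alone and
    are computed even when the graph has no edges (fractions then undefined).
    """
    labels = np.asarray(labels, dtype=object)
    if len(labels) != graph.n_vertices:
        raise ValueError("labels must match graph vertices")
    unknown = sorted(set(labels) - set(IMMUNE_SUBSETS))
    if unknown:
        raise ValueError(f"labels outside the 6 immune subsets: {unknown}")

    counts = {s: int(np.sum(labels == s)) for s in IMMUNE_SUBSETS}
    total = sum(counts.values())
    percentages = (
        {s: counts[s] / total for s in IMMUNE_SUBSETS} if total else {}
    )
    n_treg = counts.get("CD4_FOXP3pos", 0)
    cd8_treg = counts["CD8"] / n_treg if n_treg > 0 else None
    b_pct = sum(counts[s] for s in B_SUBSETS) / total if total else None
    h_comp = (
        shannon([counts[s] for s in IMMUNE_SUBSETS]) if total else None
    )

    if graph.n_edges == 0:
        return InteractionProfile(
            fractions={},
            n_edges=0,
            counts=counts,
            percentages=percentages,
            h_interaction=None,
            h_composition=h_comp,
            cd8_treg_ratio=cd8_treg,
            b_cell_pct=b_pct,
        )

    pair_counts = {pair: 0 for pair in SUBSET_PAIRS}
    for i, j in graph.edges:
        pair_counts[pair_key(labels[i], labels[j])] += 1
    m = graph.n_edges
    fractions = {pair: c / m for pair, c in pair_counts.items()}
    h_inter = shannon(list(pair_counts.values()))
    return InteractionProfile(
        fractions=fractions,
        n_edges=m,
        counts=counts,
        percentages=percentages,
        h_interaction=h_inter,
        h_composition=h_comp,
        cd8_treg_ratio=cd8_treg,
        b_cell_pct=b_pct,
    )


def profiles_table(
    profiles: Sequence[InteractionProfile],
    component_ids: Sequence[int],
    compartments: Sequence[str],
) -> pd.DataFrame:
    """One row per hotspot: ids, compartment, and the full profile."""
    rows = []
    for cid, comp, prof in zip(component_ids, compartments, profiles):
        row = {"component_id": cid, "compartment": comp}
        row.update(prof.to_row())
        rows.append(row)
    return pd.DataFrame(rows)


def compare_groups(
    data: pd.DataFrame,
    value_cols: Sequence[str],
    group_col: str,
    paired: bool = False,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Two-sided Wilcoxon tests per variable with BH adjustment.

    Signed-rank when ``paired`` (rows must be aligned pairs after sorting by
    index within groups), rank-sum otherwise.  Variables with fewer than two
    observations per group are skipped with a reason.
    """
    groups = [g for g, _ in data.groupby(group_col, sort=True)]
    if len(groups) != 2:
        raise ValueError("compare_groups requires exactly 2 groups")
    g0 = data[data[group_col] == groups[0]]
    g1 = data[data[group_col] == groups[1]]

    rows = []
    for col in value_cols:
        a = g0[col].dropna().to_numpy(float)
        b = g1[col].dropna().to_numpy(float)
        if len(a) < 2 or len(b) < 2:
            rows.append(
                {"variable": col, "statistic": np.nan, "p": np.nan,
                 "skipped": "fewer than 2 observations in a group"}
            )
            continue
        if paired:
            if len(a) != len(b):
                rows.append(
                    {"variable": col, "statistic": np.nan, "p": np.nan,
                     "skipped": "paired test with unequal group sizes"}
                )
                continue
            if np.allclose(a, b):
                stat, p = 0.0, 1.0
            else:
                stat, p = wilcoxon(a, b, alternative="two-sided")
        else:
            stat, p = mannwhitneyu(a, b, alternative="two-sided")
        rows.append({"variable": col, "statistic": stat, "p": p, "skipped": ""})

    out = pd.DataFrame(rows)
    tested = out["p"].notna()
    out["p_adj"] = np.nan
    if tested.any():
        out.loc[tested, "p_adj"] = bh_adjust(out.loc[tested, "p"].to_numpy())
    out["significant"] = out["p_adj"] < alpha
    return out


def bh_adjust(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p values."""
    return multipletests(np.asarray(pvalues, float), method="fdr_bh")[1]


def classify_by_median(
    values: Sequence[float], compartments: Sequence[str]
) -> np.ndarray:
    """High/low labels using a median computed separately per compartment.

    Values strictly above their compartment's median are "high"; values at or
    below it are "low".  Constant values within a compartment are all "low".
    """
    values = np.asarray(values, dtype=float)
    compartments = np.asarray(compartments, dtype=object)
    out = np.empty(len(values), dtype=object)
    for comp in np.unique(compartments):
        m = compartments == comp
        if m.sum() < 2:
            raise ValueError(f"compartment {comp!r} has fewer than 2 hotspots")
        med = np.median(values[m])
        out[m] = np.where(values[m] > med, "high", "low")
    return out


def interaction_logistic(
    profiles: pd.DataFrame,
    fraction_cols: Sequence[str],
    outcome_col: str = "compartment",
    positive_class: str = "IH_intra",
    min_per_class: int = 10,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Univariate logistic regressions of compartment on each link fraction.

    One model per interaction fraction with the outcome coded 1 for
    ``positive_class`` (intratumoral) — a negative coefficient therefore
    means the interaction is more frequent in peritumoral hotspots.  Wald
    two-sided p values, BH-adjusted across interactions.  Complete
    separation or non-convergence is flagged per variable.
    """
    y_raw = profiles[outcome_col]
    classes = sorted(y_raw.dropna().unique())
    if len(classes) != 2:
        raise ValueError("outcome must have exactly 2 classes")
    y_all = (y_raw == positive_class).astype(float)
    counts = y_all.value_counts()
    if counts.min() < min_per_class:
        raise ValueError(
            f"need >= {min_per_class} hotspots per class, got {counts.to_dict()}"
        )

    rows = []
    for col in fraction_cols:
        sub = profiles[[col]].copy()
        sub["_y"] = y_all
        sub = sub.dropna()
        x = sub[col].to_numpy(float)
        y = sub["_y"].to_numpy(float)
        flag = ""
        coef = se = p = np.nan
        if min(np.sum(y == 0), np.sum(y == 1)) < min_per_class:
            flag = "insufficient observations"
        elif np.ptp(x) == 0:
            flag = "constant predictor"
        else:
            X = sm.add_constant(x)
            try:
                with np.errstate(all="ignore"):
                    fit = sm.Logit(y, X).fit(disp=False, maxiter=200)
                coef = float(fit.params[1])
                se = float(fit.bse[1])
                p = float(fit.pvalues[1])
                if not fit.mle_retvals.get("converged", True) or se > 1e3:
                    flag = "unstable (possible separation)"
            except Exception:  # PerfectSeparationError and friends
                flag = "separation"
        rows.append(
            {"variable": col, "coef": coef, "se": se, "p": p, "flag": flag}
        )
    out = pd.DataFrame(rows)
    tested = out["p"].notna()
    out["p_adj"] = np.nan
    if tested.any():
        out.loc[tested, "p_adj"] = bh_adjust(out.loc[tested, "p"].to_numpy())
    out["significant"] = out["p_adj"] < alpha
    return out
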