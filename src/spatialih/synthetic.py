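"""Synthetic slide and cohort generation.

Produces multi-class point patterns with the statistical structure the
downstream analysis assumes: inhomogeneous-Poisson cancer cells inside
tumor nests, Thomas-cluster lymphocyte infiltrates placed inside nests, in
the peritumoral margin band, or distant from tumors, zoned TLS-like
aggregates (B-cell-dominant core, T-cell ring), and cohort-level survival
outcomes whose log-hazard carries a known coefficient on the patient's true
intratumoral-immune score.

Densities are package defaults chosen for testability, not published
values.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from shapely.geometry import Point
from shapely.ops import unary_union

from .celltable import ALL_CLASSES, IMMUNE_SUBSETS, empty_cell_table, make_cell_table

MARGIN_BAND_UM = 200.0  # annulus width outside a nest counted as peritumoral

IMMUNE_REGIONS = ("inside_nest", "margin_band", "distant")

#: default zoned TLS mixes: B-dominant core, T-dominant ring
TLS_CORE_MIX = {
    "CD20_CXCR5pos": 0.40,
    "CD79b": 0.25,
    "CD20_CXCR5neg": 0.15,
    "CD4_FOXP3neg": 0.12,
    "CD8": 0.05,
    "CD4_FOXP3pos": 0.03,
}
TLS_RING_MIX = {
    "CD4_FOXP3neg": 0.45,
    "CD8": 0.30,
    "CD4_FOXP3pos": 0.10,
    "CD20_CXCR5neg": 0.08,
    "CD20_CXCR5pos": 0.04,
    "CD79b": 0.03,
}


def _check_mix(mix: dict, where: str) -> None:
    unknown = sorted(set(mix) - set(ALL_CLASSES))
    if unknown:
        raise ValueError(f"{where}: unknown classes {unknown}")
    probs = np.array(list(mix.values()), float)
    if np.any(probs < 0) or not np.isfinite(probs).all():
        raise ValueError(f"{where}: mix probabilities must be finite and >= 0")
    if abs(probs.sum() - 1.0) > 1e-9:
        raise ValueError(f"{where}: mix must sum to 1 (got {probs.sum()})")


def _check_nonneg(value: float, name: str) -> None:
    if not np.isfinite(value) or value < 0:
        raise ValueError(f"{name} must be finite and >= 0 (got {value})")


@dataclass(frozen=True)
class TumorNest:
    center: tuple[float, float]
    radius_um: float
    cancer_intensity: float  # cells per um^2

    def validate(self) -> None:
        if not np.isfinite(self.radius_um) or self.radius_um <= 0:
            raise ValueError("nest radius must be positive")
        _check_nonneg(self.cancer_intensity, "cancer_intensity")


@dataclass(frozen=True)
class ImmuneField:
    """Thomas-type clustered lymphocyte infiltrate in one tissue region."""

    region: str  # inside_nest | margin_band | distant
    mix: dict  # subset -> probability over the 6 lymphocyte classes
    parent_intensity: float  # parents per um^2 within the region
    offspring_per_parent: float
    offspring_sd_um: float
    nest_indices: Optional[tuple[int, ...]] = None  # restrict region to these nests

    def validate(self) -> None:
        if self.region not in IMMUNE_REGIONS:
            raise ValueError(f"region must be one of {IMMUNE_REGIONS}")
        _check_mix(self.mix, f"immune field ({self.region})")
        _check_nonneg(self.parent_intensity, "parent_intensity")
        _check_nonneg(self.offspring_per_parent, "offspring_per_parent")
        if not np.isfinite(self.offspring_sd_um) or self.offspring_sd_um <= 0:
            raise ValueError("offspring_sd_um must be positive")


@dataclass(frozen=True)
class TLSSpec:
    """Zoned lymphoid aggregate: B-dominant core disc plus T-cell ring."""

    center: tuple[float, float]
    core_radius_um: float
    ring_width_um: float
    core_intensity: float = 0.02
    ring_intensity: float = 0.01
    core_mix: dict = field(default_factory=lambda: dict(TLS_CORE_MIX))
    ring_mix: dict = field(default_factory=lambda: dict(TLS_RING_MIX))

    @property
    def outer_radius_um(self) -> float:
        return self.core_radius_um + self.ring_width_um

    def validate(self) -> None:
        if self.core_radius_um <= 0 or self.ring_width_um <= 0:
            raise ValueError("TLS radii must be positive")
        _check_nonneg(self.core_intensity, "core_intensity")
        _check_nonneg(self.ring_intensity, "ring_intensity")
        _check_mix(self.core_mix, "TLS core")
        _check_mix(self.ring_mix, "TLS ring")


@dataclass(frozen=True)
class SlideConfig:
    width_um: float
    height_um: float
    tumor_nests: tuple[TumorNest, ...] = ()
    immune_fields: tuple[ImmuneField, ...] = ()
    tls_specs: tuple[TLSSpec, ...] = ()
    stromal_intensity: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.width_um <= 0 or self.height_um <= 0:
            raise ValueError("slide dimensions must be positive")
        _check_nonneg(self.stromal_intensity, "stromal_intensity")
        for nest in self.tumor_nests:
            nest.validate()
        for f in self.immune_fields:
            f.validate()
        for t in self.tls_specs:
            t.validate()

    @property
    def area_um2(self) -> float:
        return self.width_um * self.height_um


# ---------------------------------------------------------------------------
# point-process primitives

def _poisson_disc(rng, center, radius, intensity) -> np.ndarray:
    """Homogeneous Poisson sample on a disc."""
    lam = intensity * np.pi * radius**2
    n = rng.poisson(lam)
    r = radius * np.sqrt(rng.uniform(size=n))
    theta = rng.uniform(0, 2 * np.pi, size=n)
    return np.column_stack([center[0] + r * np.cos(theta), center[1] + r * np.sin(theta)])


def _poisson_rect(rng, width, height, intensity) -> np.ndarray:
    n = rng.poisson(intensity * width * height)
    return np.column_stack([rng.uniform(0, width, n), rng.uniform(0, height, n)])


def _region_codes(points: np.ndarray, nests: Sequence[TumorNest]) -> np.ndarray:
    """0 = inside a nest, 1 = in a margin band (and no nest), 2 = distant."""
    n = len(points)
    inside = np.zeros(n, dtype=bool)
    band = np.zeros(n, dtype=bool)
    for nest in nests:
        d = np.hypot(points[:, 0] - nest.center[0], points[:, 1] - nest.center[1])
        inside |= d <= nest.radius_um
        band |= (d > nest.radius_um) & (d <= nest.radius_um + MARGIN_BAND_UM)
    codes = np.full(n, 2, dtype=int)
    codes[band & ~inside] = 1
    codes[inside] = 0
    return codes


def generate_slide(config: SlideConfig) -> pd.DataFrame:
    """Generate a cell table for one synthetic slide.

    The RNG stream is keyed by ``config.seed``; independent sub-streams are
    drawn in a fixed order (stromal, nests, immune fields, TLS) so that
    editing one compartment's parameters leaves the sampled points of the
    others unchanged.
    """
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    rng_stromal, rng_nest, rng_immune, rng_tls = [
        np.random.default_rng(child) for child in ss.spawn(4)
    ]

    xs: list[np.ndarray] = []
    ys: list[np.ndarray] = []
    labels: list[np.ndarray] = []

    def emit(points: np.ndarray, lbls: np.ndarray) -> None:
        if len(points) == 0:
            return
        in_bounds = (
            (points[:, 0] >= 0)
            & (points[:, 0] < config.width_um)
            & (points[:, 1] >= 0)
            & (points[:, 1] < config.height_um)
        )
        xs.append(points[in_bounds, 0])
        ys.append(points[in_bounds, 1])
        labels.append(np.asarray(lbls, object)[in_bounds])

    # stromal background
    pts = _poisson_rect(rng_stromal, config.width_um, config.height_um, config.stromal_intensity)
    emit(pts, np.full(len(pts), "stromal"))

    # cancer cells: Poisson on nest interiors
    for nest in config.tumor_nests:
        pts = _poisson_disc(rng_nest, nest.center, nest.radius_um, nest.cancer_intensity)
        emit(pts, np.full(len(pts), "cancer"))

    # lymphocytes: Thomas parent-offspring clusters, thinned to the region.
    # Parents are sampled homogeneously over the slide then filtered by
    # region membership, which realises a homogeneous parent process of the
    # configured intensity restricted to that region.
    for fld in config.immune_fields:
        parents = _poisson_rect(
            rng_immune, config.width_um, config.height_um, fld.parent_intensity
        )
        nests = (
            config.tumor_nests
            if fld.nest_indices is None
            else tuple(config.tumor_nests[i] for i in fld.nest_indices)
        )
        codes = _region_codes(parents, nests)
        want = IMMUNE_REGIONS.index(fld.region)
        parents = parents[codes == want]
        if len(parents) == 0:
            continue
        n_off = rng_immune.poisson(fld.offspring_per_parent, size=len(parents))
        total = int(n_off.sum())
        if total == 0:
            continue
        centers = np.repeat(parents, n_off, axis=0)
        offs = centers + rng_immune.normal(0.0, fld.offspring_sd_um, size=(total, 2))
        subsets = list(fld.mix.keys())
        probs = np.array([fld.mix[s] for s in subsets], float)
        lbls = rng_immune.choice(subsets, size=total, p=probs)
        emit(offs, lbls)

    # TLS-like zoned aggregates
    for tls in config.tls_specs:
        core = _poisson_disc(rng_tls, tls.center, tls.core_radius_um, tls.core_intensity)
        subsets = list(tls.core_mix.keys())
        probs = np.array([tls.core_mix[s] for s in subsets], float)
        emit(core, rng_tls.choice(subsets, size=len(core), p=probs))

        # ring: uniform on the annulus [core_radius, outer_radius]
        r_in, r_out = tls.core_radius_um, tls.outer_radius_um
        lam = tls.ring_intensity * np.pi * (r_out**2 - r_in**2)
        n = rng_tls.poisson(lam)
        r = np.sqrt(rng_tls.uniform(r_in**2, r_out**2, size=n))
        theta = rng_tls.uniform(0, 2 * np.pi, size=n)
        ring = np.column_stack(
            [tls.center[0] + r * np.cos(theta), tls.center[1] + r * np.sin(theta)]
        )
        subsets = list(tls.ring_mix.keys())
        probs = np.array([tls.ring_mix[s] for s in subsets], float)
        emit(ring, rng_tls.choice(subsets, size=n, p=probs))

    if not xs:
        return empty_cell_table()
    return make_cell_table(
        np.concatenate(xs), np.concatenate(ys), np.concatenate(labels)
    )


def truth_regions(config: SlideConfig) -> dict:
    """Ground-truth compartment geometry implied by a config.

    Returns shapely geometries: ``nest`` (union of tumor nests), ``margin``
    (peritumoral bands minus nests), ``tls`` (outer discs of TLS specs).
    Empty geometries where a compartment is absent.
    """
    nests = unary_union(
        [Point(*n.center).buffer(n.radius_um, quad_segs=64) for n in config.tumor_nests]
    )
    bands = unary_union(
        [
            Point(*n.center).buffer(n.radius_um + MARGIN_BAND_UM, quad_segs=64)
            for n in config.tumor_nests
        ]
    )
    margin = bands.difference(nests)
    tls = unary_union(
        [Point(*t.center).buffer(t.outer_radius_um, quad_segs=64) for t in config.tls_specs]
    )
    return {"nest": nests, "margin": margin, "tls": tls}


# ---------------------------------------------------------------------------
# cohort generation

STAGE_LEVELS = ("I", "II", "III", "IV")
STAGE_PROBS = (0.45, 0.28, 0.2, 0.07)
STAGE_LOGHR = {"I": 0.0, "II": 0.25, "III": 0.55, "IV": 0.9}
AGE_LOGHR_PER_DECADE = 0.15
PACKYEARS_LOGHR_PER_10 = 0.03


@dataclass
class SyntheticCohort:
    """Per-patient slide configs plus linked survival outcomes.

    ``spatial_effect`` is the true log-hazard-ratio on ``true_score`` and is
    stored for parameter-recovery tests.
    """

    configs: list[SlideConfig]
    survival: pd.DataFrame
    spatial_effect: float


def make_patient_config(
    true_score: float, seed: int, width_um: float = 2000.0, height_um: float = 2000.0
) -> SlideConfig:
    """A small slide whose intratumoral immune share tracks ``true_score``.

    ``true_score`` in [0, 1] splits a fixed immune budget between an
    inside-nest field (weight = score) and a margin-band field.
    """
    if not 0 <= true_score <= 1:
        raise ValueError("true_score must lie in [0, 1]")
    mix = {s: 1.0 / len(IMMUNE_SUBSETS) for s in IMMUNE_SUBSETS}
    base_parent = 4e-5
    fields = []
    if true_score > 0:
        fields.append(
            ImmuneField("inside_nest", mix, base_parent * true_score, 12.0, 25.0)
        )
    if true_score < 1:
        fields.append(
            ImmuneField("margin_band", mix, base_parent * (1 - true_score), 12.0, 25.0)
        )
    return SlideConfig(
        width_um=width_um,
        height_um=height_um,
        tumor_nests=(TumorNest((width_um / 2, height_um / 2), 500.0, 0.004),),
        immune_fields=tuple(fields),
        stromal_intensity=2e-4,
        seed=seed,
    )


def generate_cohort(
    n_patients: int,
    spatial_effect: float,
    seed: int,
    baseline_hazard: float = 1.0 / 1000.0,
    censor_hazard: float = 1.0 / 2500.0,
) -> SyntheticCohort:
    """Cohort with exponential proportional-hazards survival outcomes.

    Patients span low-to-high true intratumoral-immune scores; the
    log-hazard is ``spatial_effect * true_score`` plus small stage, age and
    pack-year effects.  Censoring is independent exponential.
    """
    if n_patients < 2:
        raise ValueError("a cohort needs at least 2 patients")
    if not np.isfinite(spatial_effect):
        raise ValueError("spatial_effect must be finite")
    rng = np.random.default_rng(seed)

    # evenly spread scores with small jitter, shuffled
    base = np.linspace(0.05, 0.95, n_patients)
    scores = np.clip(base + rng.normal(0, 0.02, n_patients), 0.0, 1.0)
    rng.shuffle(scores)

    age = np.clip(rng.normal(67, 9, n_patients), 35, 90)
    stage = rng.choice(STAGE_LEVELS, size=n_patients, p=STAGE_PROBS)
    pack_years = np.clip(rng.gamma(3.0, 15.0, n_patients), 0, 200)

    lp = (
        spatial_effect * scores
        + np.array([STAGE_LOGHR[s] for s in stage])
        + AGE_LOGHR_PER_DECADE * (age - 67) / 10.0
        + PACKYEARS_LOGHR_PER_10 * (pack_years - 45) / 10.0
    )
    rate = baseline_hazard * np.exp(lp)
    t_event = rng.exponential(1.0 / rate)
    t_censor = rng.exponential(1.0 / censor_hazard, n_patients)
    time = np.minimum(t_event, t_censor)
    event = (t_event <= t_censor).astype(int)

    child_seeds = rng.integers(0, 2**31 - 1, size=n_patients)
    configs = [
        make_patient_config(float(s), int(cs)) for s, cs in zip(scores, child_seeds)
    ]
    survival = pd.DataFrame(
        {
            "patient_id": [f"P{i:04d}" for i in range(n_patients)],
            "time": time,
            "event": event,
            "age": age,
            "stage": stage,
            "pack_years": pack_years,
            "true_score": scores,
        }
    )
    return SyntheticCohort(configs, survival, spatial_effect)
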