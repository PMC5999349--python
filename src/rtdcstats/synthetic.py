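"""Synthetic inputs with known ground truth for every analysis stage.

No public RT-DC measurements accompany the methods implemented here, so
each statistical component is exercised on data generated from explicit,
documented models: parametric contours with closed-form geometry,
(area, modulus) populations pushed through the elasticity surrogate,
shrinking-separation two-population assays, planted rare sub-populations
for PCA screening, and replicate-structured two-condition datasets for
mixed-model testing.  Every generator is a pure function of its spec and
seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .features import Contour, ImagePatch
from .surrogate import FlowConditions, surrogate_deformation

__all__ = [
    "PopulationSpec",
    "AssaySpec",
    "ReplicateSpec",
    "gen_contour",
    "gen_population",
    "gen_two_population_assay",
    "gen_rare_subpopulation",
    "gen_replicates",
    "gen_reservoir_channel",
]


@dataclass(frozen=True)
class PopulationSpec:
    """One homogeneous cell population in (area, modulus) space.

    Defaults reproduce the reference artificial dataset: area and
    elastic modulus normally distributed with mean area 343 μm² (SD 80),
    mean modulus 7 kPa (SD 1.2), at 0.04 μl/s, 15 mPa·s effective
    viscosity and a 20 μm square channel.  Non-positive normal draws
    are resampled (truncation), keeping D continuous.
    """

    n: int = 5000
    mean_area: float = 343.0
    sd_area: float = 80.0
    mean_emod: float = 7.0
    sd_emod: float = 1.2
    flow: FlowConditions = field(default_factory=FlowConditions)

    def __post_init__(self):
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.sd_area < 0 or self.sd_emod < 0:
            raise ValueError("standard deviations must be >= 0")
        if self.mean_area <= 0 or self.mean_emod <= 0:
            raise ValueError("means must be positive")


@dataclass(frozen=True)
class AssaySpec:
    """Shrinking-separation two-population assay configuration.

    Population 1 is stationary at mean area 70 μm²; population 2 starts
    larger and its mean is reduced by 5 μm² per step, moving along the
    isoelasticity lines since both share a mean modulus of 2.5 kPa.
    A small modulus spread (10% CV) and an area SD of 5 μm² give the
    populations genuine two-dimensional extent in (A, ln D) while
    keeping each one close to Gaussian in that plane (a wide area
    spread would bend the population along the ln-D curve and the
    mixture model would split the bend into spurious components).
    """

    n_events: int = 1000
    mean_area_stationary: float = 70.0
    area_start: float = 130.0
    delta_area: float = 5.0
    sd_area: float = 5.0
    mean_emod: float = 2.5
    sd_emod: float = 0.25
    flow: FlowConditions = field(default_factory=FlowConditions)


@dataclass(frozen=True)
class ReplicateSpec:
    """Two-condition multi-replicate design for mixed-model testing.

    Replicate r contributes a random intercept a_r ~ N(0, intercept_sd²)
    and a random slope b_r ~ N(0, slope_sd²); an observation under
    condition x ∈ {0, 1} is  baseline + a_r + (effect + b_r)·x + ε  with
    ε ~ N(0, residual_sd²).  Unequal replicate counts per condition
    (incomplete pairing, e.g. 2 control vs 3 treatment) are supported.
    Default scales mirror deformation-like data.
    """

    n_replicates_control: int = 4
    n_replicates_treatment: int = 4
    events_per_replicate: int = 100
    baseline: float = 0.03
    effect: float = 0.004
    intercept_sd: float = 0.005
    slope_sd: float = 0.002
    residual_sd: float = 0.01

    def __post_init__(self):
        if min(self.intercept_sd, self.slope_sd, self.residual_sd) < 0:
            raise ValueError("standard deviations must be >= 0")
        if max(self.n_replicates_control, self.n_replicates_treatment) < 1:
            raise ValueError("need at least one replicate")


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                      n: int, lower: float = 0.0) -> np.ndarray:
    """Normal draws resampled until strictly above ``lower``."""
    out = rng.normal(mean, sd, n)
    bad = out <= lower
    guard = 0
    while bad.any():
        out[bad] = rng.normal(mean, sd, bad.sum())
        bad = out <= lower
        guard += 1
        if guard > 1000:
            raise RuntimeError("truncation resampling failed; check spec")
    return out


# ---------------------------------------------------------------------------
# contours

def _smooth_radii(rng: np.random.Generator, n: int, roughness: float) -> np.ndarray:
    """Smooth 2π-periodic radial perturbation from low-order Fourier modes."""
    t = np.linspace(0.0, 2 * math.pi, n, endpoint=False)
    r = np.zeros(n)
    for k in range(2, 6):
        r += rng.normal(0, roughness / k) * np.cos(k * t + rng.uniform(0, 2 * math.pi))
    return r


def gen_contour(shape: str = "circle", *, radius: float = 10.0,
                a: float = 10.0, b: float = 5.0, n_vertices: int = 180,
                n_spikes: int = 5, inner_fraction: float = 0.5,
                roughness: float = 0.1, rotation: float = 0.0,
                center: tuple[float, float] = (0.0, 0.0),
                pixelate: bool = False, pixel_size: float = 1.0,
                texture: tuple[float, float] | None = None,
                background: float = 200.0,
                seed: int | None = None) -> Contour | tuple[Contour, ImagePatch]:
    """Parametric test contour with analytically known geometry.

    Shapes: ``circle`` (radius), ``ellipse`` (semi-axes a along flow,
    b across), ``star`` (n_spikes spikes between radius and
    inner_fraction·radius) and ``blob`` (circle with a smooth random
    radial perturbation of relative amplitude ``roughness``).  With
    ``pixelate`` the vertices are rounded to the integer pixel grid;
    with ``texture=(mean, sd)`` a grayscale patch is rasterized and
    returned alongside (cell filled with N(mean, sd) noise clipped to
    8 bits on a uniform ``background``).
    """
    if n_vertices < 12:
        raise ValueError("need at least 12 vertices")
    if min(radius, a, b) <= 0:
        raise ValueError("radii must be positive")
    rng = np.random.default_rng(seed)
    t = np.linspace(0.0, 2 * math.pi, n_vertices, endpoint=False)
    if shape == "circle":
        xy = np.column_stack([radius * np.cos(t), radius * np.sin(t)])
    elif shape == "ellipse":
        xy = np.column_stack([a * np.cos(t), b * np.sin(t)])
    elif shape == "star":
        # alternate outer/inner radii at 2*n_spikes anchor angles
        anchors = np.linspace(0.0, 2 * math.pi, 2 * n_spikes, endpoint=False)
        radii = np.where(np.arange(2 * n_spikes) % 2 == 0, radius,
                         inner_fraction * radius)
        xy = np.column_stack([radii * np.cos(anchors), radii * np.sin(anchors)])
        t = anchors
    elif shape == "blob":
        r = radius * (1.0 + _smooth_radii(rng, n_vertices, roughness))
        xy = np.column_stack([r * np.cos(t), r * np.sin(t)])
    else:
        raise ValueError(f"unknown shape {shape!r}")
    if rotation:
        c, s = math.cos(rotation), math.sin(rotation)
        xy = xy @ np.array([[c, s], [-s, c]])
    xy = xy + np.asarray(center, dtype=float)
    if pixelate:
        xy = np.round(xy)
        keep = np.any(np.diff(np.vstack([xy, xy[:1]]), axis=0) != 0, axis=1)
        xy = xy[keep]
        if xy.shape[0] < 3:
            raise ValueError("pixelation collapsed the contour")
    contour = Contour(xy, pixel_size)
    if texture is None:
        return contour
    from .features import _mask_for  # local import to avoid cycle at import time
    lo = np.floor(xy.min(axis=0)) - 2
    hi = np.ceil(xy.max(axis=0)) + 3
    shape_px = (int(hi[1] - lo[1]), int(hi[0] - lo[0]))
    patch = np.full(shape_px, background, dtype=float)
    img = ImagePatch(np.zeros(shape_px, dtype=np.uint8), origin=(lo[0], lo[1]))
    mask = _mask_for(img, contour)
    mean, sd = texture
    patch[mask] = rng.normal(mean, sd, int(mask.sum()))
    patch = np.clip(np.round(patch), 0, 255).astype(np.uint8)
    return contour, ImagePatch(patch, origin=(lo[0], lo[1]))


# ---------------------------------------------------------------------------
# populations

def gen_population(spec: PopulationSpec, seed: int | None = None,
                   surrogate=surrogate_deformation) -> pd.DataFrame:
    """Sample (A, E) from the spec's normals and map to deformation.

    Returns an event table with columns ``A`` (μm²), ``D`` and ``E``
    (kPa).  A normally distributed modulus produces a right-skewed
    deformation distribution through the surrogate's 1/E dependence.
    """
    rng = np.random.default_rng(seed)
    area = _truncated_normal(rng, spec.mean_area, spec.sd_area, spec.n)
    emod = _truncated_normal(rng, spec.mean_emod, spec.sd_emod, spec.n)
    deform = surrogate(area, emod, spec.flow)
    return pd.DataFrame({"A": area, "D": np.asarray(deform), "E": emod})


def gen_two_population_assay(step_count: int | None = None,
                             seed: int | None = None,
                             spec: AssaySpec | None = None,
                             surrogate=surrogate_deformation):
    """Paired event tables for the shrinking-separation assay.

    Yields one ``(stationary, moving)`` pair per step; the moving
    population's mean area starts at ``spec.area_start`` and decreases
    by ``spec.delta_area`` per step (never below the stationary mean).
    Per-step seeds are spawned deterministically from ``seed``.
    """
    spec = spec or AssaySpec()
    if step_count is None:
        step_count = int(round((spec.area_start - spec.mean_area_stationary)
                               / spec.delta_area)) + 1
    if step_count < 1:
        raise ValueError("step_count must be >= 1")
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(2 * step_count)
    pairs = []
    for k in range(step_count):
        mean2 = max(spec.area_start - k * spec.delta_area,
                    spec.mean_area_stationary)
        spec1 = PopulationSpec(n=spec.n_events,
                               mean_area=spec.mean_area_stationary,
                               sd_area=spec.sd_area, mean_emod=spec.mean_emod,
                               sd_emod=spec.sd_emod, flow=spec.flow)
        spec2 = replace(spec1, mean_area=mean2)
        pairs.append((
            gen_population(spec1, np.random.default_rng(children[2 * k]).integers(2**31),
                           surrogate),
            gen_population(spec2, np.random.default_rng(children[2 * k + 1]).integers(2**31),
                           surrogate),
        ))
    return pairs


#: Feature set of the rare-sub-population generator: the "label-free
#: parameters" screened by PCA.
RARE_FEATURES = ("A", "V", "D", "I", "Delta", "Sx", "Sy", "B", "BStD",
                 "h_asm", "h_contrast")

#: Default shift of the planted population, in units of the base SD per
#: feature: small (area/volume down), dark (brightness down), with a
#: distinct texture signature.
DEFAULT_RARE_SHIFT = {
    "A": -2.5, "V": -2.5, "B": -3.0, "BStD": 1.0,
    "h_asm": 3.0, "h_contrast": -2.0,
}


def gen_rare_subpopulation(base_spec: PopulationSpec | None = None,
                           rare_fraction: float = 0.02,
                           shift_vector: dict[str, float] | None = None,
                           seed: int | None = None) -> pd.DataFrame:
    """Event table with a planted rare sub-population, labels retained.

    The base population carries the 11 label-free features in
    :data:`RARE_FEATURES` (area/deformation/modulus from the surrogate
    plus plausibly scaled morphology, brightness and texture columns);
    a ``rare_fraction`` of events is shifted by ``shift_vector`` (in
    base-SD units per feature).  Column ``label`` is 0 for base events
    and 1 for planted ones.
    """
    if not 0 <= rare_fraction < 0.5:
        raise ValueError("rare_fraction must be in [0, 0.5)")
    base_spec = base_spec or PopulationSpec()
    rng = np.random.default_rng(seed)
    n = base_spec.n
    pop = gen_population(base_spec, int(rng.integers(2**31)))
    v = 0.75 * pop["A"] ** 1.5 * np.exp(rng.normal(0, 0.03, n))
    df = pd.DataFrame({
        "A": pop["A"],
        "V": v,
        "D": pop["D"],
        "I": 1.0 + np.abs(rng.normal(0.1, 0.05, n)),
        "Delta": 1.0 + np.abs(rng.normal(0.0, 0.015, n)),
        "Sx": rng.normal(0.0, 0.05, n),
        "Sy": rng.normal(0.0, 0.05, n),
        "B": rng.normal(120.0, 8.0, n),
        "BStD": rng.normal(15.0, 3.0, n),
        "h_asm": rng.normal(0.1, 0.02, n),
        "h_contrast": rng.normal(5.0, 1.0, n),
    })
    labels = np.zeros(n, dtype=int)
    n_rare = rng.binomial(n, rare_fraction)
    if n_rare:
        idx = rng.choice(n, size=n_rare, replace=False)
        labels[idx] = 1
        shifts = dict(DEFAULT_RARE_SHIFT if shift_vector is None else shift_vector)
        for feat, k_sd in shifts.items():
            df.loc[idx, feat] = df.loc[idx, feat] + k_sd * df[feat].std()
    df["label"] = labels
    return df


# ---------------------------------------------------------------------------
# replicate designs

def gen_replicates(spec: ReplicateSpec, seed: int | None = None) -> pd.DataFrame:
    """Long-format two-condition replicate data for the mixed model.

    Columns: ``value``, ``condition`` (0 control / 1 treatment),
    ``replicate``.  Replicates are paired by index; with unequal counts
    the excess replicates carry a single condition only.
    """
    rng = np.random.default_rng(seed)
    n_rep = max(spec.n_replicates_control, spec.n_replicates_treatment)
    rows = []
    for r in range(n_rep):
        a_r = rng.normal(0.0, spec.intercept_sd)
        b_r = rng.normal(0.0, spec.slope_sd)
        for cond, n_max in ((0, spec.n_replicates_control),
                            (1, spec.n_replicates_treatment)):
            if r >= n_max:
                continue
            eps = rng.normal(0.0, spec.residual_sd, spec.events_per_replicate)
            y = spec.baseline + a_r + (spec.effect + b_r) * cond + eps
            rows.append(pd.DataFrame({
                "value": y, "condition": cond, "replicate": r,
            }))
    return pd.concat(rows, ignore_index=True)


def gen_reservoir_channel(n: int = 1000, baseline_median: float = 0.02,
                          baseline_spread: float = 0.4,
                          stress_shift: float = 0.03,
                          seed: int | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Paired reservoir/channel deformation samples of one measurement.

    The reservoir sample is log-normal around ``baseline_median`` (cells
    need not be spherical at rest); the channel sample adds the
    hydrodynamic ``stress_shift`` on top of an independent draw of the
    same baseline shape distribution.  Returns ``(reservoir, channel)``.
    """
    rng = np.random.default_rng(seed)
    res = baseline_median * np.exp(rng.normal(0.0, baseline_spread, n))
    ch = baseline_median * np.exp(rng.normal(0.0, baseline_spread, n)) + stress_shift
    return res, ch
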