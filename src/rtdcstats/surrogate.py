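"""Surrogate mechanical model linking cell size, stiffness and deformation.

The full hydrodynamic theory that maps a cell of area A and Young's
modulus E flowing through a narrow channel onto a steady-state
deformation is deliberately not reproduced here.  Instead this module
provides a documented closed-form *surrogate* with the qualitative
properties the statistical methods rely on:

* D increases with A at fixed E (larger cells deform more),
* D decreases with E at fixed A, with D → 0 as E → ∞,
* a normally distributed E at roughly fixed A yields a right-skewed
  (log-normal-like) distribution of D.

Default form::

    D = c · (flow_rate · viscosity / channel_width³) · A^(3/2) / E

with A in μm², E in kPa, flow in μl/s, viscosity in mPa·s and the
channel width in μm.  The calibration constant ``c`` (default 0.5)
absorbs unit conversion and is chosen so that a typical measurement
(A ≈ 343 μm², E ≈ 7 kPa at 0.04 μl/s, 15 mPa·s, 20 μm channel) lands in
the small-deformation regime (median D ≈ 0.02–0.06).  Any callable with
the same signature can be plugged in wherever a surrogate is accepted,
so a faithful hydrodynamic model can replace this one without touching
the statistics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "FlowConditions",
    "DEFAULT_CALIBRATION",
    "surrogate_deformation",
    "surrogate_modulus",
    "ElasticityLUT",
    "build_lut",
    "save_lut",
    "load_lut",
    "lookup_modulus",
    "isoelasticity_lines",
    "AREA_RATIO_GATE",
    "DEFORMATION_GATE",
]

#: Modulus-validity gate on the area ratio: only smooth convex contours
#: (1.0 <= Delta <= 1.05) support a linear-elastic modulus estimate.
AREA_RATIO_GATE = (1.0, 1.05)

#: Small-deformation gate: D above this in the channel leaves the
#: linear-elastic regime the modulus lookup assumes.
DEFORMATION_GATE = 0.03

DEFAULT_CALIBRATION = 0.5


@dataclass(frozen=True)
class FlowConditions:
    """Experimental flow configuration of a square-channel measurement.

    ``viscosity`` is the *effective* buffer viscosity in the channel;
    shear-thinning (e.g. 15 mPa·s at rest dropping to 5.4 mPa·s at
    0.16 μl/s in a 30 μm channel) is the user's responsibility.
    """

    flow_rate: float = 0.04     # μl/s
    viscosity: float = 15.0     # mPa·s
    channel_width: float = 20.0  # μm, square cross-section

    def __post_init__(self):
        if self.flow_rate <= 0 or self.viscosity <= 0 or self.channel_width <= 0:
            raise ValueError("flow conditions must all be positive")

    @property
    def stress_scale(self) -> float:
        return self.flow_rate * self.viscosity / self.channel_width ** 3


def surrogate_deformation(area, emod, flow: FlowConditions | None = None,
                          calibration: float = DEFAULT_CALIBRATION):
    """Deformation D for cells of ``area`` (μm²) and modulus ``emod`` (kPa)."""
    flow = flow or FlowConditions()
    area = np.asarray(area, dtype=float)
    emod = np.asarray(emod, dtype=float)
    if np.any(area <= 0) or np.any(emod <= 0):
        raise ValueError("area and modulus must be positive")
    d = calibration * flow.stress_scale * area ** 1.5 / emod
    return d if d.ndim else float(d)


def surrogate_modulus(area, deform, flow: FlowConditions | None = None,
                      calibration: float = DEFAULT_CALIBRATION):
    """Exact inverse of :func:`surrogate_deformation` at fixed area."""
    flow = flow or FlowConditions()
    area = np.asarray(area, dtype=float)
    deform = np.asarray(deform, dtype=float)
    if np.any(area <= 0) or np.any(deform <= 0):
        raise ValueError("area and deformation must be positive")
    e = calibration * flow.stress_scale * area ** 1.5 / deform
    return e if e.ndim else float(e)


@dataclass
class ElasticityLUT:
    """Lookup table E(A, D) inverting a monotone surrogate on a grid.

    ``emod[i, j]`` is the modulus at ``(a_grid[i], d_grid[j])``; cells
    outside the surrogate's range carry NaN and a False validity mask.
    """

    a_grid: np.ndarray
    d_grid: np.ndarray
    emod: np.ndarray
    flow: FlowConditions
    mask: np.ndarray

    def __post_init__(self):
        if np.any(self.emod[self.mask] <= 0):
            raise ValueError("lookup table holds non-positive moduli")


def build_lut(flow: FlowConditions | None = None,
              a_grid: np.ndarray | None = None,
              e_grid: np.ndarray | None = None,
              n_deform: int = 200,
              surrogate=surrogate_deformation) -> ElasticityLUT:
    """Tabulate D over (A, E) and invert to E over (A, D).

    For each area the surrogate's deformation must be strictly monotone
    in E; the inversion is a monotone interpolation per area column.
    Queries outside the tabulated deformation range are masked invalid,
    never extrapolated.
    """
    flow = flow or FlowConditions()
    if a_grid is None:
        a_grid = np.linspace(30.0, 500.0, 120)
    if e_grid is None:
        e_grid = np.linspace(0.3, 30.0, 240)
    a_grid = np.asarray(a_grid, dtype=float)
    e_grid = np.asarray(e_grid, dtype=float)
    if np.any(np.diff(a_grid) <= 0) or np.any(np.diff(e_grid) <= 0):
        raise ValueError("grids must be strictly increasing")

    d_table = np.empty((a_grid.size, e_grid.size))
    for i, a in enumerate(a_grid):
        d_table[i] = surrogate(np.full_like(e_grid, a), e_grid, flow)
        diffs = np.diff(d_table[i])
        if not (np.all(diffs < 0) or np.all(diffs > 0)):
            raise ValueError("surrogate is not monotone in E over the grid")

    # geometric spacing in D with log-log interpolation: both D(E) and
    # E(D) are near power laws, so this keeps interpolation error small
    # across the orders of magnitude the deformation spans
    d_grid = np.geomspace(d_table.min(), d_table.max(), n_deform)
    emod = np.full((a_grid.size, n_deform), np.nan)
    for i in range(a_grid.size):
        col_d = d_table[i]
        col_e = e_grid
        if col_d[0] > col_d[-1]:  # sort ascending in D for interp
            col_d, col_e = col_d[::-1], col_e[::-1]
        inside = (d_grid >= col_d[0]) & (d_grid <= col_d[-1])
        emod[i, inside] = np.exp(np.interp(np.log(d_grid[inside]),
                                           np.log(col_d), np.log(col_e)))
    mask = np.isfinite(emod)
    return ElasticityLUT(a_grid=a_grid, d_grid=d_grid, emod=emod,
                         flow=flow, mask=mask)


def lookup_modulus(lut: ElasticityLUT, area: float, deform: float,
                   area_ratio: float = 1.0,
                   apply_deformation_gate: bool = True) -> float:
    """Bilinear E(A, D) from the table, NaN when any validity gate fails.

    Invalid (NaN, not an error) when: the query leaves the tabulated
    grid or masked region; the area ratio leaves the convexity gate
    1.0 <= Delta <= 1.05; or (if the gate is on) D exceeds the
    small-deformation limit 0.03.
    """
    if not (AREA_RATIO_GATE[0] <= area_ratio <= AREA_RATIO_GATE[1]):
        return float("nan")
    if apply_deformation_gate and deform > DEFORMATION_GATE:
        return float("nan")
    a, d = lut.a_grid, lut.d_grid
    if not (a[0] <= area <= a[-1] and d[0] <= deform <= d[-1]):
        return float("nan")
    i = min(np.searchsorted(a, area) - 1, a.size - 2)
    j = min(np.searchsorted(d, deform) - 1, d.size - 2)
    i = max(i, 0)
    j = max(j, 0)
    corners = lut.emod[i:i + 2, j:j + 2]
    if not np.all(np.isfinite(corners)):
        return float("nan")
    ta = (area - a[i]) / (a[i + 1] - a[i])
    td = ((math.log(deform) - math.log(d[j]))
          / (math.log(d[j + 1]) - math.log(d[j])))
    log_c = np.log(corners)
    top = log_c[0, 0] * (1 - td) + log_c[0, 1] * td
    bot = log_c[1, 0] * (1 - td) + log_c[1, 1] * td
    return float(math.exp(top * (1 - ta) + bot * ta))


def save_lut(lut: ElasticityLUT, path) -> None:
    """Serialize a lookup table to long-format TSV (area, deformation, E).

    Flow conditions ride along as header comments; invalid cells are
    omitted rather than written as NaN.
    """
    from pathlib import Path

    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# flow_rate={lut.flow.flow_rate:.9g}\n")
        fh.write(f"# viscosity={lut.flow.viscosity:.9g}\n")
        fh.write(f"# channel_width={lut.flow.channel_width:.9g}\n")
        fh.write("A\tD\tE\n")
        for i, a in enumerate(lut.a_grid):
            for j, d in enumerate(lut.d_grid):
                if lut.mask[i, j]:
                    fh.write(f"{a:.9g}\t{d:.9g}\t{lut.emod[i, j]:.9g}\n")


def load_lut(path) -> ElasticityLUT:
    """Rebuild an :class:`ElasticityLUT` from :func:`save_lut` output."""
    from pathlib import Path

    path = Path(path)
    meta = {}
    rows = []
    for line in path.read_text().splitlines():
        if line.startswith("#"):
            key, val = line[1:].strip().split("=", 1)
            meta[key] = float(val)
        elif line and not line.startswith("A\t"):
            rows.append(tuple(float(x) for x in line.split("\t")))
    data = np.asarray(rows)
    a_grid = np.unique(data[:, 0])
    d_grid = np.unique(data[:, 1])
    emod = np.full((a_grid.size, d_grid.size), np.nan)
    i = np.searchsorted(a_grid, data[:, 0])
    j = np.searchsorted(d_grid, data[:, 1])
    emod[i, j] = data[:, 2]
    return ElasticityLUT(a_grid=a_grid, d_grid=d_grid, emod=emod,
                         flow=FlowConditions(**meta), mask=np.isfinite(emod))


def isoelasticity_lines(e_values, flow: FlowConditions | None = None,
                        a_range=(30.0, 500.0), n_points: int = 100,
                        surrogate=surrogate_deformation):
    """Constant-E level sets in the (A, D) plane, one curve per modulus.

    Each curve is an (n, 2) array of (area, deformation) points; for a
    monotone surrogate the curves increase with area and never cross.
    """
    flow = flow or FlowConditions()
    areas = np.linspace(a_range[0], a_range[1], n_points)
    curves = []
    for e in np.atleast_1d(np.asarray(e_values, dtype=float)):
        d = surrogate(areas, np.full_like(areas, e), flow)
        curves.append(np.column_stack([areas, d]))
    return curves
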