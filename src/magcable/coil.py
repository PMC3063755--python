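"""Magnetically induced electric field of a planar circular coil.

A current-pulsed coil lying in the plane ``z = standoff`` induces an electric
field in the neuron plane ``z = 0``.  Because the coil is parallel to the
neuron plane the induced field separates into a purely spatial vector factor
and a scalar temporal factor,

    E(x, y, t) = S(x, y) * g(t),        g(t) = dI/dt,

where ``S`` (units V/m per A/s) is minus ``N`` times the azimuthal vector
potential of a single loop carrying unit current.  The per-turn vector
potential has the classical closed form in complete elliptic integrals; a
Biot-Savart line-integral quadrature over an arbitrary polyline is provided
both as an independent oracle for the closed form and as the pathway for
non-circular coils.

All quantities in this module are SI (metres, amperes, volts).  The cable
engine performs its own single conversion into (um, mV, nA) units.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import numpy as np
from scipy.special import ellipe, ellipk

__all__ = [
    "MU_0",
    "Coil",
    "SpatialField",
    "SingularFieldPoint",
    "vector_potential_per_turn",
    "line_integral_field",
    "spatial_field",
    "spatial_field_many",
    "locate_radial_maximum",
    "export_field_grid",
    "save_field_grid",
    "load_field_grid",
]

#: Vacuum permeability, H/m.
MU_0 = 4e-7 * np.pi


class SingularFieldPoint(ValueError):
    """Raised when the vector potential is requested on the coil wire itself."""


@dataclass(frozen=True)
class Coil:
    """A planar multi-turn circular coil parallel to the neuron plane.

    Parameters
    ----------
    radius
        Loop radius in metres.
    turns
        Number of loops (all at the same radius, in series).
    standoff
        Distance between the coil plane and the neuron plane, metres.
    center_offset
        (x, y) position of the coil axis in neuron-plane coordinates, metres.
    permeability
        Magnetic permeability of the medium, H/m.
    """

    radius: float
    turns: int = 30
    standoff: float = 0.01
    center_offset: tuple[float, float] = (0.0, 0.0)
    permeability: float = MU_0

    def __post_init__(self) -> None:
        if not self.radius > 0:
            raise ValueError(f"coil radius must be > 0, got {self.radius}")
        if not (isinstance(self.turns, (int, np.integer)) and self.turns >= 1):
            raise ValueError(f"turns must be an integer >= 1, got {self.turns!r}")
        if not self.standoff > 0:
            raise ValueError(f"standoff must be > 0, got {self.standoff}")
        if not self.permeability > 0:
            raise ValueError("permeability must be > 0")
        if len(self.center_offset) != 2:
            raise ValueError("center_offset must be a 2-vector (x, y) in metres")


def vector_potential_per_turn(
    rho: float | np.ndarray,
    z: float | np.ndarray,
    coil_radius: float,
    permeability: float = MU_0,
) -> float | np.ndarray:
    """Azimuthal vector potential A_phi of one circular loop per unit current.

    Closed form in the complete elliptic integrals K(m) and E(m) with the
    *parameter* convention m = k^2 = 4 r rho / ((r + rho)^2 + z^2) (the
    convention used by ``scipy.special.ellipk``/``ellipe``); this convention
    is pinned against the Biot-Savart line-integral oracle in the test suite.

    Parameters are cylindrical coordinates about the coil axis: ``rho`` the
    radial distance and ``z`` the axial distance from the coil plane, both in
    metres.  Returns T*m/A (equivalently V/m per A/s of current derivative).
    """
    if coil_radius <= 0:
        raise ValueError("coil_radius must be > 0")
    rho_a = np.asarray(rho, dtype=float)
    z_a = np.asarray(z, dtype=float)
    if np.any(rho_a < 0):
        raise ValueError("rho must be >= 0")
    on_wire = (np.abs(rho_a - coil_radius) < 1e-12 * coil_radius) & (z_a == 0)
    if np.any(on_wire):
        raise SingularFieldPoint(
            "vector potential is singular on the coil wire (rho = r, z = 0)"
        )
    denom = (coil_radius + rho_a) ** 2 + z_a**2
    m = 4.0 * coil_radius * rho_a / denom
    safe_m = np.where(m > 0, m, 1.0)
    pref = permeability / (4.0 * np.pi) * 4.0 * coil_radius / np.sqrt(denom)
    with np.errstate(invalid="ignore"):
        val = pref * ((2.0 - safe_m) * ellipk(safe_m) - 2.0 * ellipe(safe_m)) / safe_m
    out = np.where(m > 0, val, 0.0)
    if np.isscalar(rho) and np.isscalar(z):
        return float(out)
    return out


def line_integral_field(
    path: np.ndarray,
    point: np.ndarray,
    n_elements: int = 100_000,
    permeability: float = MU_0,
) -> np.ndarray:
    """Vector potential per unit current of a closed polyline current path.

    Discretises the path into ``n_elements`` straight current elements and
    sums mu0/(4 pi) * dl / R (Biot-Savart form for A).  Serves as the
    independent oracle for :func:`vector_potential_per_turn` and as the
    generic pathway for arbitrary coil shapes (e.g. figure-of-eight coils via
    superposition of two loops).

    Parameters
    ----------
    path
        (n, 3) array of points in metres.  Must be closed (first == last
        point within 1e-12 of the path extent).
    point
        (3,) evaluation point, metres.
    n_elements
        Number of straight elements the polyline is resampled into (>= 3).

    Returns
    -------
    (3,) vector potential per unit current, T*m/A.
    """
    path = np.asarray(path, dtype=float)
    point = np.asarray(point, dtype=float)
    if path.ndim != 2 or path.shape[1] != 3 or path.shape[0] < 3:
        raise ValueError("path must be an (n >= 3, 3) array of points")
    scale = max(np.ptp(path), 1e-30)
    if np.linalg.norm(path[0] - path[-1]) > 1e-12 * scale:
        raise ValueError("path must be closed (first point == last point)")
    if n_elements < 3:
        raise ValueError("n_elements must be >= 3")

    # resample the polyline by arclength into n_elements equal pieces
    seg = np.diff(path, axis=0)
    seglen = np.linalg.norm(seg, axis=1)
    s = np.concatenate([[0.0], np.cumsum(seglen)])
    total = s[-1]
    if total <= 0:
        raise ValueError("path has zero length")
    ss = np.linspace(0.0, total, n_elements + 1)
    pts = np.empty((n_elements + 1, 3))
    for k in range(3):
        pts[:, k] = np.interp(ss, s, path[:, k])

    mid = 0.5 * (pts[1:] + pts[:-1])
    dl = np.diff(pts, axis=0)
    rvec = point[None, :] - mid
    dist = np.linalg.norm(rvec, axis=1)
    # within one element of the wire the quadrature is effectively singular
    if np.min(dist) < total / n_elements:
        raise SingularFieldPoint("evaluation point lies on the current path")
    return permeability / (4.0 * np.pi) * np.sum(dl / dist[:, None], axis=0)


def spatial_field(point, coil: Coil) -> np.ndarray:
    """Spatial factor S of the induced field at one neuron-plane point.

    ``E(x, y, t) = S(x, y) * dI/dt``.  S is tangential (azimuthal about the
    coil axis): with (dx, dy) the point relative to the coil center and
    rho = |(dx, dy)|, the azimuthal unit vector is (-dy/rho, dx/rho) and

        S = -N * A_unit(rho, standoff) * phi_hat .

    Returns (Sx, Sy) in V/m per A/s; (0, 0) exactly on the coil axis.
    """
    return spatial_field_many(np.asarray(point, float)[None, :], coil)[0]


def spatial_field_many(points: np.ndarray, coil: Coil) -> np.ndarray:
    """Vectorised :func:`spatial_field` for an (n, 2) array of points."""
    points = np.asarray(points, dtype=float)
    if points.ndim != 2 or points.shape[1] != 2:
        raise ValueError("points must be an (n, 2) array")
    dx = points[:, 0] - coil.center_offset[0]
    dy = points[:, 1] - coil.center_offset[1]
    rho = np.hypot(dx, dy)
    a = vector_potential_per_turn(
        rho, coil.standoff, coil.radius, coil.permeability
    )
    out = np.zeros_like(points)
    nz = rho > 0
    amp = -coil.turns * np.asarray(a)
    out[nz, 0] = amp[nz] * (-dy[nz] / rho[nz])
    out[nz, 1] = amp[nz] * (dx[nz] / rho[nz])
    return out


def locate_radial_maximum(coil: Coil, scan_resolution: float = 1e-4) -> float:
    """Radial distance from the coil axis at which |S| peaks on the neuron plane.

    Scans rho on a uniform grid at ``scan_resolution`` (metres) out to
    ``3 * radius + 5 * standoff`` and returns the argmax.  |S| depends only
    on rho, so a 1-D scan is exact to within the resolution.
    """
    if not scan_resolution > 0:
        raise ValueError("scan_resolution must be > 0")
    rho_max = 3.0 * coil.radius + 5.0 * coil.standoff
    rho = np.arange(scan_resolution, rho_max, scan_resolution)
    a = vector_potential_per_turn(rho, coil.standoff, coil.radius, coil.permeability)
    return float(rho[int(np.argmax(np.abs(a)))])


@dataclass
class SpatialField:
    """The spatial factor of the induced field, analytic and/or sampled.

    ``evaluator(points)`` maps an (n, 2) array of neuron-plane points (m) to
    (n, 2) field factors (V/m per A/s).  When produced by
    :func:`export_field_grid` the sampled component arrays and grid metadata
    are attached as well; grid values equal analytic evaluation at the cell
    centers.
    """

    evaluator: Callable[[np.ndarray], np.ndarray]
    coil: Coil | None = None
    extent: float | None = None
    resolution: float | None = None
    center: tuple[float, float] = (0.0, 0.0)
    xs: np.ndarray | None = field(default=None, repr=False)
    ys: np.ndarray | None = field(default=None, repr=False)
    sx: np.ndarray | None = field(default=None, repr=False)
    sy: np.ndarray | None = field(default=None, repr=False)

    def __call__(self, points: np.ndarray) -> np.ndarray:
        return self.evaluator(points)


def analytic_field(coil: Coil) -> SpatialField:
    """On-demand analytic evaluator for a coil (the engine's default)."""
    return SpatialField(evaluator=lambda pts: spatial_field_many(pts, coil), coil=coil)


def export_field_grid(
    coil: Coil,
    extent: float,
    resolution: float,
    center: tuple[float, float] = (0.0, 0.0),
    memory_cap_bytes: int = 2**28,
) -> SpatialField:
    """Sample S on a square grid of side ``extent`` centred at ``center``.

    The grid is an export/interchange feature only -- the simulation engine
    always evaluates the field analytically at segment endpoints, which is
    exact and needs no 1 um lookup matrices.

    Raises ``MemoryError`` (advising analytic evaluation) if the two
    component arrays would exceed ``memory_cap_bytes``.
    """
    if extent <= 0 or resolution <= 0:
        raise ValueError("extent and resolution must be > 0")
    n = int(round(extent / resolution))
    if n < 1:
        raise ValueError("extent must be at least one resolution cell")
    nbytes = 2 * n * n * 8
    if nbytes > memory_cap_bytes:
        raise MemoryError(
            f"field grid of {n}x{n} cells needs {nbytes} bytes "
            f"(cap {memory_cap_bytes}); use analytic evaluation instead"
        )
    # cell-center coordinates
    axis = (np.arange(n) + 0.5) * resolution - extent / 2.0
    xs = axis + center[0]
    ys = axis + center[1]
    xx, yy = np.meshgrid(xs, ys, indexing="ij")
    pts = np.column_stack([xx.ravel(), yy.ravel()])
    s = spatial_field_many(pts, coil)
    fld = analytic_field(coil)
    fld.extent = extent
    fld.resolution = resolution
    fld.center = tuple(center)
    fld.xs = xs
    fld.ys = ys
    fld.sx = s[:, 0].reshape(n, n)
    fld.sy = s[:, 1].reshape(n, n)
    return fld


def save_field_grid(fld: SpatialField, basepath: str | Path) -> None:
    """Write a sampled grid as paired TSV matrices plus a JSON sidecar.

    Produces ``<base>_Sx.tsv``, ``<base>_Sy.tsv`` (rows = x index, columns =
    y index) and ``<base>.json`` with extent, resolution, coil parameters and
    units (V/m per A/s).
    """
    if fld.sx is None or fld.sy is None:
        raise ValueError("field has no sampled grid; call export_field_grid first")
    base = Path(basepath)
    np.savetxt(base.parent / f"{base.name}_Sx.tsv", fld.sx, delimiter="\t")
    np.savetxt(base.parent / f"{base.name}_Sy.tsv", fld.sy, delimiter="\t")
    meta = {
        "units": "V/m per (A/s)",
        "extent_m": fld.extent,
        "resolution_m": fld.resolution,
        "center_m": list(fld.center),
        "coil": {
            "radius_m": fld.coil.radius if fld.coil else None,
            "turns": fld.coil.turns if fld.coil else None,
            "standoff_m": fld.coil.standoff if fld.coil else None,
            "center_offset_m": list(fld.coil.center_offset) if fld.coil else None,
            "permeability_H_per_m": fld.coil.permeability if fld.coil else None,
        },
        "layout": "rows = x index, columns = y index, cell-center sampling",
    }
    (base.parent / f"{base.name}.json").write_text(json.dumps(meta, indent=2))


def load_field_grid(basepath: str | Path) -> SpatialField:
    """Read a grid written by :func:`save_field_grid`."""
    base = Path(basepath)
    meta = json.loads((base.parent / f"{base.name}.json").read_text())
    c = meta["coil"]
    coil = Coil(
        radius=c["radius_m"],
        turns=c["turns"],
        standoff=c["standoff_m"],
        center_offset=tuple(c["center_offset_m"]),
        permeability=c["permeability_H_per_m"],
    )
    fld = export_field_grid(
        coil, meta["extent_m"], meta["resolution_m"], tuple(meta["center_m"])
    )
    fld.sx = np.loadtxt(base.parent / f"{base.name}_Sx.tsv", delimiter="\t")
    fld.sy = np.loadtxt(base.parent / f"{base.name}_Sy.tsv", delimiter="\t")
    return fld
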