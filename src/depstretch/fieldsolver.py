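"""2D electrostatic field solver for electrode geometries.

The stretching stress on a trapped cell depends on the electrode layout
only through a dimensionless geometric constant

    n = |E| * r * (d|E|/dx) / E0^2

evaluated at the cell position, where ``r`` is the cell radius, ``x`` the
stretching axis through the capture port and ``E0`` a reference field
(by default applied voltage / smallest electrode gap).  ``n`` is invariant
under rescaling of the applied voltage, since numerator and denominator
are both quadratic in it.

The solver discretises the electrode plane (the chip's channel height is
uniform, so a 2D section suffices) on a regular grid and solves the
Laplace equation with a 5-point stencil: Dirichlet values on electrode
nodes, zero-normal-flux (mirror) conditions on the outer boundary, direct
sparse factorisation.  The discrete maximum principle — interior
potentials bounded by the electrode potentials — holds by construction
and is exposed for testing.

Geometry coordinates and grid spacing are in micrometres; potentials in
volts; fields in V/m and V/m^2 (spacing is converted internally).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import sparse
from scipy.interpolate import RegularGridInterpolator
from scipy.sparse.linalg import spsolve
from scipy.spatial import cKDTree

__all__ = [
    "Electrode",
    "ElectrodeGeometry",
    "FieldSolution",
    "solve_laplace_2d",
    "field_at",
    "geometric_constant",
    "facing_tips_geometry",
]


class ConfigurationError(ValueError):
    """Raised for geometries that cannot define a solvable problem."""


@dataclass(frozen=True)
class Electrode:
    """An equipotential conductor: a polyline or an arbitrary region.

    ``polyline`` is a sequence of (x, y) vertices in μm, rasterised onto
    grid nodes within half a grid spacing of any segment.  ``region`` is a
    vectorised predicate ``f(X, Y) -> bool array`` over node coordinate
    grids (μm), for electrodes that are not thin traces (discs, blocks).
    Exactly one of the two must be given.
    """

    potential: float
    polyline: tuple[tuple[float, float], ...] | None = None
    region: Callable[[np.ndarray, np.ndarray], np.ndarray] | None = None

    def __post_init__(self) -> None:
        if (self.polyline is None) == (self.region is None):
            raise ConfigurationError(
                "electrode needs exactly one of polyline or region"
            )
        if self.polyline is not None:
            object.__setattr__(self, "polyline", tuple(map(tuple, self.polyline)))


@dataclass(frozen=True)
class ElectrodeGeometry:
    """Rectangular solution domain with embedded electrodes.

    ``width``/``height`` are the domain extents in μm; ``spacing`` the
    grid pitch in μm (must resolve the narrowest electrode gap).
    """

    width: float
    height: float
    spacing: float
    electrodes: tuple[Electrode, ...]

    def __post_init__(self) -> None:
        if not (self.width > 0 and self.height > 0 and self.spacing > 0):
            raise ConfigurationError("domain extents and spacing must be > 0")
        object.__setattr__(self, "electrodes", tuple(self.electrodes))
        if len({e.potential for e in self.electrodes}) < 2:
            raise ConfigurationError(
                "need at least two electrodes at distinct potentials"
            )


def _segment_mask(X, Y, p0, p1, half_width):
    """Nodes within ``half_width`` of segment p0-p1 (all in μm)."""
    p0 = np.asarray(p0, float)
    d = np.asarray(p1, float) - p0
    L2 = float(d @ d)
    px, py = X - p0[0], Y - p0[1]
    if L2 == 0.0:
        dist2 = px**2 + py**2
    else:
        t = np.clip((px * d[0] + py * d[1]) / L2, 0.0, 1.0)
        dist2 = (px - t * d[0]) ** 2 + (py - t * d[1]) ** 2
    return dist2 <= half_width**2


def _rasterize(geom: ElectrodeGeometry):
    """Return node coordinate vectors, Dirichlet mask and value grid."""
    nx = int(round(geom.width / geom.spacing)) + 1
    ny = int(round(geom.height / geom.spacing)) + 1
    x = np.linspace(0.0, geom.width, nx)
    y = np.linspace(0.0, geom.height, ny)
    X, Y = np.meshgrid(x, y, indexing="xy")  # shape (ny, nx)
    mask = np.zeros((ny, nx), dtype=bool)
    values = np.zeros((ny, nx), dtype=float)
    for el in geom.electrodes:
        if el.region is not None:
            m = np.asarray(el.region(X, Y), dtype=bool)
        else:
            m = np.zeros((ny, nx), dtype=bool)
            pts = el.polyline
            for p0, p1 in zip(pts[:-1], pts[1:]):
                m |= _segment_mask(X, Y, p0, p1, geom.spacing / 2)
            if len(pts) == 1:
                m |= _segment_mask(X, Y, pts[0], pts[0], geom.spacing / 2)
        if not m.any():
            raise ConfigurationError(
                f"electrode at {el.potential} V rasterises to no grid node"
            )
        mask |= m
        values[m] = el.potential
    return x, y, mask, values


def _smallest_gap(x, y, mask, values) -> float:
    """Smallest node-to-node distance (μm) between distinct potentials."""
    pots = np.unique(values[mask])
    groups = []
    X, Y = np.meshgrid(x, y, indexing="xy")
    for p in pots:
        sel = mask & (values == p)
        groups.append(np.column_stack([X[sel], Y[sel]]))
    best = np.inf
    for i in range(len(groups)):
        tree = cKDTree(groups[i])
        for j in range(i + 1, len(groups)):
            d, _ = tree.query(groups[j], k=1)
            best = min(best, float(d.min()))
    return best


@dataclass
class FieldSolution:
    """Discretised potential and derived field maps.

    Attributes are 2D arrays of shape (ny, nx); ``x``/``y`` node
    coordinates in μm.  ``e_mag`` is |E| in V/m, ``de_dx`` the gradient of
    |E| along the stretching axis x in V/m^2, ``e0`` the reference field in
    V/m used to normalise the geometric constant.
    """

    x: np.ndarray
    y: np.ndarray
    potential: np.ndarray
    e_mag: np.ndarray
    de_dx: np.ndarray
    electrode_mask: np.ndarray
    e0: float
    _interp_e: RegularGridInterpolator = field(repr=False, default=None)
    _interp_de: RegularGridInterpolator = field(repr=False, default=None)

    def __post_init__(self):
        self._interp_e = RegularGridInterpolator(
            (self.y, self.x), self.e_mag, method="linear"
        )
        self._interp_de = RegularGridInterpolator(
            (self.y, self.x), self.de_dx, method="linear"
        )

    def max_principle_violation(self) -> float:
        """Largest overshoot of non-electrode potentials beyond the
        electrode range (0 when the discrete maximum principle holds)."""
        free = ~self.electrode_mask
        lo = self.potential[self.electrode_mask].min()
        hi = self.potential[self.electrode_mask].max()
        p = self.potential[free]
        return max(float((p - hi).max(initial=0.0)), float((lo - p).max(initial=0.0)))

    def laplace_residual(self) -> float:
        """Max |discrete Laplacian| at interior non-electrode nodes,
        relative to the applied potential span."""
        p = self.potential
        lap = (
            p[1:-1, :-2] + p[1:-1, 2:] + p[:-2, 1:-1] + p[2:, 1:-1]
            - 4 * p[1:-1, 1:-1]
        )
        free = ~self.electrode_mask[1:-1, 1:-1]
        span = float(np.ptp(self.potential[self.electrode_mask])) or 1.0
        return float(np.abs(lap[free]).max(initial=0.0)) / span


def solve_laplace_2d(geom: ElectrodeGeometry, e0: float | None = None) -> FieldSolution:
    """Solve the Laplace equation on ``geom`` and derive field maps.

    Electrode nodes are Dirichlet; the outer boundary is zero-normal-flux
    (mirror stencil).  Returns a :class:`FieldSolution` with |E| and
    d|E|/dx from central differences of the potential.  ``e0`` overrides
    the reference field; the default is (applied potential span) /
    (smallest electrode gap).
    """
    x, y, mask, values = _rasterize(geom)
    ny, nx = mask.shape
    n = ny * nx
    idx = np.arange(n).reshape(ny, nx)

    rows, cols, data = [], [], []
    rhs = np.zeros(n)

    flat_mask = mask.ravel()
    flat_vals = values.ravel()

    # Dirichlet rows
    dir_idx = np.flatnonzero(flat_mask)
    rows.extend(dir_idx)
    cols.extend(dir_idx)
    data.extend(np.ones_like(dir_idx, dtype=float))
    rhs[dir_idx] = flat_vals[dir_idx]

    # Free rows: 5-point Laplacian with mirrored neighbours at the edges.
    jj, ii = np.meshgrid(np.arange(nx), np.arange(ny), indexing="xy")
    free = ~mask
    fi = ii[free]
    fj = jj[free]
    centre = idx[fi, fj]
    rows.extend(centre)
    cols.extend(centre)
    data.extend(np.full(centre.size, -4.0))
    for di, dj in ((0, -1), (0, 1), (-1, 0), (1, 0)):
        ni = fi + di
        nj = fj + dj
        # mirror across the boundary: the ghost node equals the inner one
        ni = np.where(ni < 0, 1, np.where(ni > ny - 1, ny - 2, ni))
        nj = np.where(nj < 0, 1, np.where(nj > nx - 1, nx - 2, nj))
        rows.extend(centre)
        cols.extend(idx[ni, nj])
        data.extend(np.ones(centre.size))

    A = sparse.csr_matrix(
        (np.asarray(data), (np.asarray(rows), np.asarray(cols))), shape=(n, n)
    )
    try:
        phi = spsolve(A.tocsc(), rhs)
    except Exception as exc:  # pragma: no cover - scipy error path
        raise RuntimeError(f"Laplace solve failed: {exc}") from exc
    if not np.all(np.isfinite(phi)):
        raise RuntimeError("Laplace solve produced non-finite potentials")
    phi = phi.reshape(ny, nx)

    h_m = geom.spacing * 1e-6  # grid spacing in metres
    # E = -grad(phi); np.gradient axis 0 is y, axis 1 is x
    dpdy, dpdx = np.gradient(phi, h_m, h_m)
    e_mag = np.hypot(dpdx, dpdy)
    de_dx = np.gradient(e_mag, h_m, axis=1)

    if e0 is None:
        gap_um = _smallest_gap(x, y, mask, values)
        span = float(values[mask].max() - values[mask].min())
        if not np.isfinite(gap_um) or gap_um <= 0:
            raise ConfigurationError("cannot determine electrode gap for E0")
        e0 = span / (gap_um * 1e-6)
    if e0 == 0:
        raise ConfigurationError("reference field E0 must be nonzero")

    return FieldSolution(
        x=x, y=y, potential=phi, e_mag=e_mag, de_dx=de_dx,
        electrode_mask=mask, e0=float(e0),
    )


def field_at(sol: FieldSolution, point: Sequence[float]) -> tuple[float, float]:
    """(|E|, d|E|/dx) at ``point`` = (x, y) in μm, bilinearly interpolated.

    The point must lie inside the domain and off electrode nodes.
    """
    px, py = float(point[0]), float(point[1])
    if not (sol.x[0] <= px <= sol.x[-1] and sol.y[0] <= py <= sol.y[-1]):
        raise ValueError(f"point {point!r} outside solution domain")
    e = float(sol._interp_e((py, px)))
    de = float(sol._interp_de((py, px)))
    return e, de


def geometric_constant(
    sol: FieldSolution,
    cell_radius: float,
    point: Sequence[float],
    e0: float | None = None,
) -> float:
    """Geometric constant n = |E| r (d|E|/dx) / E0^2 at ``point``.

    ``cell_radius`` in metres.  Dimensionless and invariant under voltage
    rescaling.  ``e0`` (V/m) overrides the solution's reference field.
    """
    e0 = sol.e0 if e0 is None else float(e0)
    if e0 == 0:
        raise ConfigurationError("reference field E0 must be nonzero")
    e, de = field_at(sol, point)
    return e * cell_radius * de / e0**2


def facing_tips_geometry(
    gap: float = 18.0,
    voltage: float = 10.0,
    domain: float = 60.0,
    spacing: float = 0.5,
) -> ElectrodeGeometry:
    """Demo geometry: two facing electrode tips across a capture-port gap.

    Two collinear traces along the stretching axis x, separated by ``gap``
    μm at the domain centre, at 0 and ``voltage`` volts — an idealisation
    of the electrode pair flanking one capture port.  All lengths in μm.
    """
    mid = domain / 2
    x0 = mid - gap / 2
    x1 = mid + gap / 2
    return ElectrodeGeometry(
        width=domain,
        height=domain,
        spacing=spacing,
        electrodes=(
            Electrode(potential=voltage, polyline=((0.0, mid), (x0, mid))),
            Electrode(potential=0.0, polyline=((x1, mid), (domain, mid))),
        ),
    )
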