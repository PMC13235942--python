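"""Rectilinear cell-centered mesh with synapse region labelling.

The mesh is a tensor-product grid defined by edge coordinates per axis.
Unknowns live at cell centers; region labels are assigned by cell-center
containment.  Every geometric region boundary (membrane faces, vesicle,
vesicle opening, AMPA area, cell footprint) is snapped to a mesh edge, so
containment is unambiguous and region volumes are exact.

Grading: the grid is finest across the cleft and membranes (y) and around
the vesicle opening (x, z), and coarsens geometrically away from them with
a user-set growth ratio.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import cached_property

import numpy as np

from .geometry import Geometry

__all__ = [
    "Region",
    "MeshResolution",
    "Mesh",
    "FaceGeometry",
    "build_mesh",
    "build_interval_mesh",
]


class Region:
    """Integer cell labels.  Exactly one label per cell."""

    EXTRACELLULAR = 0
    INTRA_PRE = 1
    INTRA_POST = 2
    MEMBRANE_PRE = 3
    MEMBRANE_POST = 4
    CLEFT = 5
    VESICLE = 6
    VESICLE_OPENING = 7

    NAMES = {
        0: "extracellular",
        1: "intracellular_pre",
        2: "intracellular_post",
        3: "membrane_pre",
        4: "membrane_post",
        5: "cleft",
        6: "vesicle",
        7: "vesicle_opening",
    }

    #: labels belonging to the aqueous intracellular compartments
    INTRACELLULAR = (INTRA_PRE, INTRA_POST)
    #: labels where transport is blocked (lipid)
    MEMBRANES = (MEMBRANE_PRE, MEMBRANE_POST)
    #: labels with restricted (kappa-reduced) diffusion
    RESTRICTED = (CLEFT, VESICLE_OPENING)


@dataclass(frozen=True)
class MeshResolution:
    """Mesh-grading specification.

    Attributes
    ----------
    n_cleft : number of cells across the cleft height (>= 3 so the cleft
        spacing never exceeds h/3).
    n_mem : cells across each membrane.
    n_vesicle : cells across the vesicle in y.
    ratio : geometric coarsening ratio away from the fine regions.
    h_max : cap on any cell size, nm.
    """

    n_cleft: int = 3
    n_mem: int = 1
    n_vesicle: int = 3
    ratio: float = 1.3
    h_max: float = 250.0

    def __post_init__(self) -> None:
        if self.n_cleft < 1 or self.n_mem < 1 or self.n_vesicle < 1:
            raise ValueError("cell counts must be positive")
        if self.ratio < 1.0:
            raise ValueError("coarsening ratio must be >= 1")
        if self.h_max <= 0:
            raise ValueError("h_max must be positive")

    @classmethod
    def coarse(cls) -> "MeshResolution":
        """Desk-scale preset used for the reduced-resolution 3D runs."""
        return cls(n_cleft=3, n_mem=1, n_vesicle=3, ratio=1.9, h_max=350.0)

    @classmethod
    def fine(cls) -> "MeshResolution":
        """Higher-resolution preset (substantially more expensive)."""
        return cls(n_cleft=6, n_mem=2, n_vesicle=4, ratio=1.25, h_max=120.0)


def _graded_sizes(length: float, h0: float, ratio: float, h_max: float) -> np.ndarray:
    """Cell sizes filling ``length`` starting near ``h0`` and growing by
    ``ratio`` up to ``h_max``; rescaled so the sizes sum exactly to length."""
    if length <= 0:
        return np.empty(0)
    if h0 >= length:
        return np.array([length])
    sizes = []
    h, total = h0, 0.0
    while total < length:
        sizes.append(h)
        total += h
        h = min(h * ratio, h_max)
    out = np.asarray(sizes)
    return out * (length / out.sum())


def _mirror(half_sizes: np.ndarray, center_size: float) -> np.ndarray:
    """Symmetric size sequence: reversed half, center cell, half."""
    return np.concatenate([half_sizes[::-1], [center_size], half_sizes])


def _edges_from_sizes(start: float, sizes: np.ndarray) -> np.ndarray:
    return start + np.concatenate([[0.0], np.cumsum(sizes)])


def _lateral_edges(half_breaks: list[float], center_size: float,
                   res: MeshResolution) -> np.ndarray:
    """Edges of a symmetric lateral axis.

    ``half_breaks`` are the positive breakpoints (excluding the center cell
    half-width, which is ``center_size / 2``), in increasing order.
    """
    sizes = []
    prev = center_size
    lo = center_size / 2.0
    for hi in half_breaks:
        seg = _graded_sizes(hi - lo, min(prev * res.ratio, res.h_max),
                            res.ratio, res.h_max)
        sizes.extend(seg.tolist())
        prev = seg[-1]
        lo = hi
    half = np.asarray(sizes)
    all_sizes = _mirror(half, center_size)
    return _edges_from_sizes(-half_breaks[-1], all_sizes)


@dataclass
class FaceGeometry:
    """Flat arrays describing internal and boundary faces of a mesh.

    Internal faces connect cell ``lo`` to cell ``hi`` (flat C-order
    indices); ``d_lo``/``d_hi`` are the center-to-face distances used for
    distance-weighted harmonic means of discontinuous coefficients.
    Boundary faces carry the flat index of the adjacent cell, the
    center-to-face distance, the side id (0..5 for x-,x+,y-,y+,z-,z+) and
    the region of the adjacent cell (used to classify Dirichlet patches).
    """

    lo: np.ndarray
    hi: np.ndarray
    area: np.ndarray
    d_lo: np.ndarray
    d_hi: np.ndarray
    axis: np.ndarray
    region_lo: np.ndarray
    region_hi: np.ndarray
    blocked: np.ndarray  # vesicle-wall faces (impermeable regardless of D)
    b_cell: np.ndarray
    b_area: np.ndarray
    b_dist: np.ndarray
    b_side: np.ndarray
    b_region: np.ndarray

    @property
    def dist(self) -> np.ndarray:
        return self.d_lo + self.d_hi

    def harmonic(self, values: np.ndarray, zero_blocked: bool = True) -> np.ndarray:
        """Distance-weighted harmonic mean of a per-cell coefficient on
        internal faces; zero where either side is zero (or blocked)."""
        a = values[self.lo]
        b = values[self.hi]
        num = (self.d_lo + self.d_hi) * a * b
        den = self.d_lo * b + self.d_hi * a
        out = np.divide(num, den, out=np.zeros_like(num), where=den > 0)
        if zero_blocked:
            out[self.blocked] = 0.0
        return out


@dataclass
class Mesh:
    """Rectilinear cell-centered mesh.

    ``region`` has shape (nx, ny, nz) and holds one :class:`Region` label
    per cell.  AMPA-zone bookkeeping (lateral columns and the y-indices of
    the cleft cell below / intracellular cell above the postsynaptic
    membrane) is only present for synapse meshes.
    """

    ex: np.ndarray
    ey: np.ndarray
    ez: np.ndarray
    region: np.ndarray
    geometry: Geometry | None = None
    ampa_ix: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))
    ampa_iz: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))
    j_cleft_top: int = -1
    j_intra_post: int = -1

    # -- basic coordinates -------------------------------------------------
    @property
    def shape(self) -> tuple[int, int, int]:
        return (len(self.ex) - 1, len(self.ey) - 1, len(self.ez) - 1)

    @property
    def n_cells(self) -> int:
        nx, ny, nz = self.shape
        return nx * ny * nz

    @cached_property
    def cx(self) -> np.ndarray:
        return 0.5 * (self.ex[:-1] + self.ex[1:])

    @cached_property
    def cy(self) -> np.ndarray:
        return 0.5 * (self.ey[:-1] + self.ey[1:])

    @cached_property
    def cz(self) -> np.ndarray:
        return 0.5 * (self.ez[:-1] + self.ez[1:])

    @cached_property
    def wx(self) -> np.ndarray:
        return np.diff(self.ex)

    @cached_property
    def wy(self) -> np.ndarray:
        return np.diff(self.ey)

    @cached_property
    def wz(self) -> np.ndarray:
        return np.diff(self.ez)

    @cached_property
    def volumes(self) -> np.ndarray:
        """Cell volumes, shape (nx, ny, nz), nm^3."""
        return (self.wx[:, None, None] * self.wy[None, :, None]
                * self.wz[None, None, :])

    def flat(self, i, j, k):
        nx, ny, nz = self.shape
        return (np.asarray(i) * ny + np.asarray(j)) * nz + np.asarray(k)

    def find_cell(self, x: float, y: float, z: float) -> tuple[int, int, int]:
        """Indices of the cell containing (or nearest to) a point."""
        i = int(np.clip(np.searchsorted(self.ex, x) - 1, 0, self.shape[0] - 1))
        j = int(np.clip(np.searchsorted(self.ey, y) - 1, 0, self.shape[1] - 1))
        k = int(np.clip(np.searchsorted(self.ez, z) - 1, 0, self.shape[2] - 1))
        return i, j, k

    def region_volume(self, label: int) -> float:
        return float(self.volumes[self.region == label].sum())

    # -- material coefficients --------------------------------------------
    def cell_diffusivity(self, sp) -> np.ndarray:
        """Per-cell diffusion coefficient for one species (flat array)."""
        D = np.full(self.n_cells, sp.D_bulk)
        r = self.region.ravel()
        D[np.isin(r, Region.MEMBRANES)] = 0.0
        D[np.isin(r, Region.RESTRICTED)] = sp.D_cleft
        return D

    def cell_permittivity(self, constants) -> np.ndarray:
        """Per-cell relative permittivity times eps0 (flat array)."""
        eps = np.full(self.n_cells, constants.eps_bulk * constants.eps0)
        r = self.region.ravel()
        eps[np.isin(r, Region.MEMBRANES)] = constants.eps_mem * constants.eps0
        return eps

    # -- faces -------------------------------------------------------------
    @cached_property
    def faces(self) -> FaceGeometry:
        nx, ny, nz = self.shape
        r = self.region
        lo_l, hi_l, area_l, dlo_l, dhi_l, ax_l = [], [], [], [], [], []
        centers = (self.cx, self.cy, self.cz)
        edges = (self.ex, self.ey, self.ez)
        widths = (self.wx, self.wy, self.wz)
        I, J, K = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz),
                              indexing="ij")
        for axis in range(3):
            n_ax = self.shape[axis]
            if n_ax < 2:
                continue
            sl_lo = [slice(None)] * 3
            sl_hi = [slice(None)] * 3
            sl_lo[axis] = slice(0, n_ax - 1)
            sl_hi[axis] = slice(1, n_ax)
            lo = self.flat(I[tuple(sl_lo)], J[tuple(sl_lo)], K[tuple(sl_lo)]).ravel()
            hi = self.flat(I[tuple(sl_hi)], J[tuple(sl_hi)], K[tuple(sl_hi)]).ravel()
            w = widths[axis]
            # face position = shared edge
            other = [a for a in range(3) if a != axis]
            wa = widths[other[0]]
            wb = widths[other[1]]
            shp = [1, 1, 1]
            shp[other[0]] = len(wa)
            area3 = np.ones((nx, ny, nz))
            area3 *= wa.reshape(shp)
            shp = [1, 1, 1]
            shp[other[1]] = len(wb)
            area3 *= wb.reshape(shp)
            area = area3[tuple(sl_lo)].ravel()
            d_half = 0.5 * w
            d_lo3 = np.ones((nx, ny, nz))
            shp = [1, 1, 1]
            shp[axis] = n_ax
            d_lo3 *= d_half.reshape(shp)
            d_lo = d_lo3[tuple(sl_lo)].ravel()
            d_hi = d_lo3[tuple(sl_hi)].ravel()
            lo_l.append(lo)
            hi_l.append(hi)
            area_l.append(area)
            dlo_l.append(d_lo)
            dhi_l.append(d_hi)
            ax_l.append(np.full(lo.shape, axis, dtype=np.int8))
        lo = np.concatenate(lo_l)
        hi = np.concatenate(hi_l)
        area = np.concatenate(area_l)
        d_lo = np.concatenate(dlo_l)
        d_hi = np.concatenate(dhi_l)
        ax = np.concatenate(ax_l)
        rflat = r.ravel()
        region_lo = rflat[lo]
        region_hi = rflat[hi]
        # vesicle wall: impermeable except through the opening
        blocked = (
            ((region_lo == Region.VESICLE) & (region_hi == Region.INTRA_PRE))
            | ((region_lo == Region.INTRA_PRE) & (region_hi == Region.VESICLE))
        )

        # boundary faces
        b_cell, b_area, b_dist, b_side = [], [], [], []
        for axis in range(3):
            n_ax = self.shape[axis]
            other = [a for a in range(3) if a != axis]
            wa = widths[other[0]]
            wb = widths[other[1]]
            shp = [1, 1, 1]
            shp[other[0]] = len(wa)
            area3 = np.ones((nx, ny, nz)) * wa.reshape(shp)
            shp = [1, 1, 1]
            shp[other[1]] = len(wb)
            area3 *= wb.reshape(shp)
            for side, idx in ((0, 0), (1, n_ax - 1)):
                sl = [slice(None)] * 3
                sl[axis] = idx
                cells = self.flat(I[tuple(sl)], J[tuple(sl)], K[tuple(sl)]).ravel()
                b_cell.append(cells)
                b_area.append(area3[tuple(sl)].ravel())
                b_dist.append(np.full(cells.shape, 0.5 * widths[axis][idx]))
                b_side.append(np.full(cells.shape, 2 * axis + side, dtype=np.int8))
        b_cell = np.concatenate(b_cell)
        b_area = np.concatenate(b_area)
        b_dist = np.concatenate(b_dist)
        b_side = np.concatenate(b_side)
        return FaceGeometry(
            lo=lo, hi=hi, area=area, d_lo=d_lo, d_hi=d_hi, axis=ax,
            region_lo=region_lo, region_hi=region_hi, blocked=blocked,
            b_cell=b_cell, b_area=b_area, b_dist=b_dist, b_side=b_side,
            b_region=rflat[b_cell],
        )


def build_mesh(geometry: Geometry, resolution: MeshResolution | None = None) -> Mesh:
    """Build the labelled synapse mesh from a geometry and grading spec.

    Raises
    ------
    ValueError
        If the cleft spacing would exceed h/3, or the geometry is invalid.
    """
    g = geometry
    res = resolution or MeshResolution()
    if g.h / res.n_cleft > g.h / 3.0 + 1e-12:
        raise ValueError(
            "cleft must be resolved: y-spacing in the cleft may not exceed h/3 "
            f"(need n_cleft >= 3, got {res.n_cleft})"
        )

    # lateral axes: breakpoints at the opening, vesicle, AMPA area, cell
    # footprint and domain boundary
    def lateral(l_cell: float, l_dom: float) -> np.ndarray:
        breaks = sorted({g.w_v / 2.0, g.w_a / 2.0, l_cell / 2.0, l_dom / 2.0})
        if not breaks[-1] == l_dom / 2.0:
            raise ValueError("domain must be the outermost lateral extent")
        return _lateral_edges(breaks, g.w_vo, res)

    ex = lateral(g.l_ix, g.l_ex)
    ez = lateral(g.l_iz, g.l_ez)

    # y axis, from the presynaptic outer boundary upward
    h_cleft = g.h / res.n_cleft
    h_mem = g.l_m / res.n_mem
    h_ves = g.w_v / res.n_vesicle
    y_sizes = []
    # presynaptic bulk below the vesicle (coarsening downward)
    pre_bulk = _graded_sizes(g.l_iy - g.w_v, min(h_ves * res.ratio, res.h_max),
                             res.ratio, res.h_max)
    y_sizes.extend(pre_bulk[::-1].tolist())
    y_sizes.extend([h_ves] * res.n_vesicle)
    y_sizes.extend([h_mem] * res.n_mem)
    y_sizes.extend([h_cleft] * res.n_cleft)
    y_sizes.extend([h_mem] * res.n_mem)
    post_bulk = _graded_sizes(g.l_iy, min(h_mem * res.ratio, res.h_max),
                              res.ratio, res.h_max)
    y_sizes.extend(post_bulk.tolist())
    ey = _edges_from_sizes(0.0, np.asarray(y_sizes))

    mesh = Mesh(ex=ex, ey=ey, ez=ez, region=np.empty(0), geometry=g)
    cx, cy, cz = mesh.cx, mesh.cy, mesh.cz
    nx, ny, nz = len(cx), len(cy), len(cz)

    # The two cells and their membranes span the full lateral domain; the
    # extracellular space is the thin sheet between the membranes, whose
    # central l_ix x l_iz part is the synaptic cleft proper (restricted
    # diffusion); beyond the cleft edge the sheet continues as unrestricted
    # extracellular space out to the Dirichlet reservoir at the domain edge.
    X = np.abs(cx)[:, None, None]
    Y = cy[None, :, None]
    Z = np.abs(cz)[None, None, :]
    region = np.full((nx, ny, nz), Region.EXTRACELLULAR, dtype=np.int8)
    foot = (X < g.l_ix / 2.0) & (Z < g.l_iz / 2.0)
    y0m, y1m = g.y_pre_membrane
    y0c, y1c = g.y_cleft
    y0p, y1p = g.y_post_membrane
    region[:, cy < y0m, :] = Region.INTRA_PRE
    region[:, (cy > y0m) & (cy < y1m), :] = Region.MEMBRANE_PRE
    region[foot & (Y > y0c) & (Y < y1c)] = Region.CLEFT
    region[:, (cy > y0p) & (cy < y1p), :] = Region.MEMBRANE_POST
    region[:, cy > y1p, :] = Region.INTRA_POST
    yv0, yv1 = g.y_vesicle
    ves = (X < g.w_v / 2.0) & (Z < g.w_v / 2.0) & (Y > yv0) & (Y < yv1)
    region[ves] = Region.VESICLE
    opening = (X < g.w_vo / 2.0) & (Z < g.w_vo / 2.0) & (Y > y0m) & (Y < y1m)
    region[opening] = Region.VESICLE_OPENING
    mesh.region = region

    # AMPA zone: lateral columns whose centers lie inside the w_a square
    ampa_x = np.where(np.abs(cx) < g.w_a / 2.0)[0]
    ampa_z = np.where(np.abs(cz) < g.w_a / 2.0)[0]
    IX, IZ = np.meshgrid(ampa_x, ampa_z, indexing="ij")
    mesh.ampa_ix = IX.ravel()
    mesh.ampa_iz = IZ.ravel()
    # last cell below the postsynaptic membrane / first cell above it
    mesh.j_cleft_top = int(np.searchsorted(ey, y1c - 1e-9) - 1)
    mesh.j_intra_post = int(np.searchsorted(ey, y1p + 1e-9) - 1)
    i0, k0 = nx // 2, nz // 2
    assert mesh.region[i0, mesh.j_cleft_top, k0] == Region.CLEFT
    assert mesh.region[i0, mesh.j_intra_post, k0] == Region.INTRA_POST
    return mesh


def build_interval_mesh(length: float, n: int, thickness: float = 1.0,
                        region: int = Region.EXTRACELLULAR) -> Mesh:
    """Uniform 1D mesh on (0, length) along x with unit cross-section.

    Used for the one-dimensional equilibrium problems and manufactured-
    solution convergence studies.
    """
    if n < 2:
        raise ValueError("need at least two cells")
    ex = np.linspace(0.0, length, n + 1)
    ey = np.array([0.0, thickness])
    ez = np.array([0.0, thickness])
    reg = np.full((n, 1, 1), region, dtype=np.int8)
    return Mesh(ex=ex, ey=ey, ez=ez, region=reg, geometry=None)
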