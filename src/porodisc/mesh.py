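"""Structured axisymmetric mesh of the two-region disk.

The meridional section [0, R] x [0, H] is meshed with a regular grid of
8-node serendipity quadrilaterals: quadratic interpolation of the
displacement field on all 8 nodes, bilinear interpolation of pore
pressure on the 4 corner nodes (a Taylor-Hood-type u-p pair, stable for
consolidation problems).  Elements whose centroid lies inside the nucleus
radius are tagged NP, the rest AF.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .disk import DiskGeometry

__all__ = ["Mesh", "build_mesh"]


@dataclass(frozen=True)
class Mesh:
    """Structured Q8/Q4 axisymmetric mesh.

    Attributes
    ----------
    coords_u : (n_unodes, 2) float array
        (r, z) coordinates of displacement nodes, mm.
    coords_p : (n_pnodes, 2) float array
        (r, z) coordinates of pressure (corner) nodes, mm.
    elems_u : (n_elems, 8) int array
        Displacement connectivity: 4 corners counter-clockwise starting at
        (r-, z-), then 4 mid-side nodes (bottom, right, top, left).
    elems_p : (n_elems, 4) int array
        Pressure connectivity (the 4 corners, same order).
    region : (n_elems,) array of 'NP' / 'AF'
    *_unodes / *_pnodes : int arrays
        Boundary node sets: axis (r=0), outer (r=R), bottom (z=0),
        top (z=H).
    """

    geometry: DiskGeometry
    nr: int
    nz: int
    radial_edges: np.ndarray
    coords_u: np.ndarray
    coords_p: np.ndarray
    elems_u: np.ndarray
    elems_p: np.ndarray
    region: np.ndarray
    axis_unodes: np.ndarray
    outer_unodes: np.ndarray
    bottom_unodes: np.ndarray
    top_unodes: np.ndarray
    axis_pnodes: np.ndarray
    outer_pnodes: np.ndarray
    bottom_pnodes: np.ndarray
    top_pnodes: np.ndarray

    @property
    def n_elems(self) -> int:
        return self.elems_u.shape[0]

    @property
    def n_unodes(self) -> int:
        return self.coords_u.shape[0]

    @property
    def n_pnodes(self) -> int:
        return self.coords_p.shape[0]

    @property
    def dz(self) -> float:
        """Axial element height (uniform), mm."""
        return self.geometry.height / self.nz

    @property
    def element_dr(self) -> np.ndarray:
        """Radial width of each element, mm (varies with grading)."""
        widths = np.diff(self.radial_edges)
        return np.tile(widths, self.nz)

    @property
    def element_r0(self) -> np.ndarray:
        """Inner radius of each element, mm."""
        return np.tile(self.radial_edges[:-1], self.nz)

    def nearest_pnode(self, r: float, z: float) -> int:
        d2 = (self.coords_p[:, 0] - r) ** 2 + (self.coords_p[:, 1] - z) ** 2
        return int(np.argmin(d2))

    def element_volumes(self) -> np.ndarray:
        """Revolved volume of each element, mm^3 (2 pi r_bar dr dz)."""
        dr = self.element_dr
        r_cent = self.element_r0 + 0.5 * dr
        return 2.0 * np.pi * r_cent * dr * self.dz

    def fluid_volume(self) -> float:
        """Interstitial fluid volume, mm^3, from element porosities."""
        g = self.geometry
        poro = np.where(self.region == "NP", g.porosity_np, g.porosity_af)
        return float(np.sum(poro * self.element_volumes()))


def build_mesh(
    geometry: DiskGeometry, nr: int = 16, nz: int = 6, radial_grading: float = 1.0
) -> Mesh:
    """Build a structured nr x nz mesh of the disk section.

    Parameters
    ----------
    geometry : DiskGeometry
    nr, nz : int
        Number of elements radially and axially (nr >= 4, nz >= 2).
    radial_grading : float
        Ratio of successive radial element widths (outer/inner).  1.0
        gives a uniform mesh; values < 1 concentrate elements near the
        draining outer surface, where the pore-pressure boundary layer
        lives.
    """
    if nr < 4 or nz < 2:
        raise ValueError(f"need nr >= 4 and nz >= 2, got nr={nr}, nz={nz}")
    if not 0.0 < radial_grading <= 1.0:
        raise ValueError(f"radial_grading must be in (0, 1], got {radial_grading}")

    R, H = geometry.radius, geometry.height

    # radial corner positions: widths in geometric progression
    if radial_grading == 1.0:
        redges = np.linspace(0.0, R, nr + 1)
    else:
        w = radial_grading ** np.arange(nr)
        redges = np.concatenate([[0.0], np.cumsum(w)]) * (R / w.sum())
        redges[-1] = R
    # displacement-node radial/axial positions (corners + edge midpoints)
    rpos = np.empty(2 * nr + 1)
    rpos[0::2] = redges
    rpos[1::2] = 0.5 * (redges[:-1] + redges[1:])
    zpos = np.linspace(0.0, H, 2 * nz + 1)

    # displacement node grid (2nr+1) x (2nz+1), serendipity: skip odd-odd
    ni, nj = 2 * nr + 1, 2 * nz + 1
    uid = -np.ones((ni, nj), dtype=int)
    coords_u = []
    n = 0
    for j in range(nj):
        for i in range(ni):
            if i % 2 == 1 and j % 2 == 1:
                continue
            uid[i, j] = n
            coords_u.append((rpos[i], zpos[j]))
            n += 1
    coords_u = np.asarray(coords_u)

    # pressure node grid (nr+1) x (nz+1)
    pid = np.arange((nr + 1) * (nz + 1)).reshape(nr + 1, nz + 1, order="F")
    rp, zp = np.meshgrid(redges, np.linspace(0, H, nz + 1), indexing="ij")
    coords_p = np.column_stack([rp.ravel(order="F"), zp.ravel(order="F")])

    elems_u, elems_p, region = [], [], []
    r_np = geometry.np_radius_fraction * R
    for ej in range(nz):
        for ei in range(nr):
            i0, j0 = 2 * ei, 2 * ej
            elems_u.append(
                [
                    uid[i0, j0], uid[i0 + 2, j0], uid[i0 + 2, j0 + 2], uid[i0, j0 + 2],
                    uid[i0 + 1, j0], uid[i0 + 2, j0 + 1], uid[i0 + 1, j0 + 2], uid[i0, j0 + 1],
                ]
            )
            elems_p.append([pid[ei, ej], pid[ei + 1, ej], pid[ei + 1, ej + 1], pid[ei, ej + 1]])
            r_cent = 0.5 * (redges[ei] + redges[ei + 1])
            region.append("NP" if r_cent < r_np else "AF")

    elems_u = np.asarray(elems_u, dtype=int)
    elems_p = np.asarray(elems_p, dtype=int)
    region = np.asarray(region)

    tol = 1e-9 * max(R, H)
    ru, zu = coords_u[:, 0], coords_u[:, 1]
    rpc, zpc = coords_p[:, 0], coords_p[:, 1]
    return Mesh(
        geometry=geometry,
        nr=nr,
        nz=nz,
        radial_edges=redges,
        coords_u=coords_u,
        coords_p=coords_p,
        elems_u=elems_u,
        elems_p=elems_p,
        region=region,
        axis_unodes=np.flatnonzero(ru < tol),
        outer_unodes=np.flatnonzero(ru > R - tol),
        bottom_unodes=np.flatnonzero(zu < tol),
        top_unodes=np.flatnonzero(zu > H - tol),
        axis_pnodes=np.flatnonzero(rpc < tol),
        outer_pnodes=np.flatnonzero(rpc > R - tol),
        bottom_pnodes=np.flatnonzero(zpc < tol),
        top_pnodes=np.flatnonzero(zpc > H - tol),
    )
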