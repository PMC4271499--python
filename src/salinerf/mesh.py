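"""Graded conforming triangulation of the axisymmetric domain.

The mesher is column based: a set of graded radial stations is chosen, every
station carries a sorted list of nodes (material-interface crossings plus
points of a global graded z-ladder), and the strip between two neighbouring
stations is triangulated by merging the two node columns top-to-bottom.  All
material interfaces are forced onto element edges: interface crossings are
column nodes, and ladder points falling between the crossing heights of
neighbouring stations are suppressed so the interface polyline survives the
merge.  The result is a conforming mesh with exact subdomain boundaries and
grading controlled by a single interface element size.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import cached_property

import numpy as np

from .geometry import (ELECTRODE, MATERIAL_NAMES, PLASTIC, SALINE, TISSUE,
                       Geometry, GeometryError, MM)


class MeshingError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# 1-D grading helpers


def graded_points(x0: float, x1: float, h0: float, h1: float,
                  ratio: float = 1.35) -> np.ndarray:
    """Points from ``x0`` to ``x1`` with spacing ``h0`` at ``x0`` geometrically
    approaching ``h1`` at ``x1`` (growth capped by ``ratio``)."""
    if x1 <= x0:
        raise ValueError("need x1 > x0")
    span = x1 - x0
    if h1 < h0:  # refine toward x1: mirror the growing ladder
        g = graded_points(0.0, span, h1, h0, ratio)
        return x1 - g[::-1]
    steps = []
    h, s = float(h0), 0.0
    while s < span * (1 - 1e-12):
        steps.append(h)
        s += h
        h = min(h * ratio, h1)
    steps = np.asarray(steps) * (span / s)
    pts = np.empty(len(steps) + 1)
    pts[0] = x0
    pts[1:] = x0 + np.cumsum(steps)
    pts[-1] = x1
    return pts


def _chain(segments: list[np.ndarray]) -> np.ndarray:
    out = [segments[0]]
    for s in segments[1:]:
        out.append(s[1:])
    return np.concatenate(out)


# ---------------------------------------------------------------------------
# mesh container


@dataclass
class AxisymmetricMesh:
    """Triangulated (r, z) half-plane with subdomain and boundary labels.

    ``points`` are in metres; ``material`` holds a per-triangle code indexing
    :data:`~salinerf.geometry.MATERIAL_NAMES`.
    """

    points: np.ndarray          # (N, 2) float
    triangles: np.ndarray       # (M, 3) int, CCW
    material: np.ndarray        # (M,) int8
    geom: Geometry | None = None
    edge_labels: dict = field(default_factory=dict)

    @property
    def n_points(self) -> int:
        return len(self.points)

    @property
    def n_elements(self) -> int:
        return len(self.triangles)

    @cached_property
    def areas(self) -> np.ndarray:
        p = self.points[self.triangles]
        d1 = p[:, 1] - p[:, 0]
        d2 = p[:, 2] - p[:, 0]
        return 0.5 * (d1[:, 0] * d2[:, 1] - d1[:, 1] * d2[:, 0])

    @cached_property
    def centroids(self) -> np.ndarray:
        return self.points[self.triangles].mean(axis=1)

    @cached_property
    def _edge_table(self):
        """Sorted-edge -> (count, adjacent element(s), orientation info)."""
        tris = self.triangles
        edges = np.concatenate([tris[:, [0, 1]], tris[:, [1, 2]], tris[:, [2, 0]]])
        owner = np.tile(np.arange(len(tris)), 3)
        key = np.sort(edges, axis=1)
        order = np.lexsort((key[:, 1], key[:, 0]))
        return edges[order], owner[order], key[order]

    @cached_property
    def boundary_edges(self) -> tuple[np.ndarray, np.ndarray]:
        """(edges (B,2) oriented as in their element, owning element ids)."""
        edges, owner, key = self._edge_table
        uniq, idx, counts = np.unique(key, axis=0, return_index=True,
                                      return_counts=True)
        sel = idx[counts == 1]
        return edges[sel], owner[sel]

    @cached_property
    def interface_edges(self) -> dict[tuple[int, int], np.ndarray]:
        """Edges shared by two elements of different materials, keyed by the
        sorted material pair."""
        edges, owner, key = self._edge_table
        uniq, idx, counts = np.unique(key, axis=0, return_index=True,
                                      return_counts=True)
        out: dict[tuple[int, int], list] = {}
        dbl = idx[counts == 2]
        for i in dbl:
            e1, e2 = owner[i], owner[i + 1]
            m1, m2 = int(self.material[e1]), int(self.material[e2])
            if m1 != m2:
                out.setdefault(tuple(sorted((m1, m2))), []).append(edges[i])
        return {k: np.asarray(v) for k, v in out.items()}

    def material_mask(self, name: str) -> np.ndarray:
        return self.material == MATERIAL_NAMES.index(name)

    def nodes_of(self, name: str) -> np.ndarray:
        """Nodes touching at least one element of the given material."""
        return np.unique(self.triangles[self.material_mask(name)])

    def subdomain_areas(self) -> dict[str, float]:
        out = {}
        for i, name in enumerate(MATERIAL_NAMES):
            m = self.material == i
            if m.any():
                out[name] = float(self.areas[m].sum())
        return out

    def subdomain_volume(self, name: str) -> float:
        """Axisymmetric volume 2*pi*int r dA of a subdomain."""
        m = self.material_mask(name)
        return float(2.0 * math.pi *
                     (self.areas[m] * self.centroids[m, 0]).sum())

    def check_valid(self) -> None:
        if (self.areas <= 0).any():
            raise MeshingError("non-positive element area")
        if (self.points[:, 0] < -1e-15).any():
            raise MeshingError("negative radius")
        edges, owner, key = self._edge_table
        _, counts = np.unique(key, axis=0, return_counts=True)
        if (counts > 2).any():
            raise MeshingError("non-manifold edge")


# ---------------------------------------------------------------------------
# station / ladder construction


def _radial_stations(geom: Geometry, h: float, ratio: float) -> np.ndarray:
    a, R = geom.a, geom.R
    segs = []
    if geom.topology == "surface_contact":
        rcap = geom.rcap
        segs.append(graded_points(0.0, rcap, 1.6 * h, 1.2 * h, ratio))
        segs.append(graded_points(rcap, a, h, h, ratio))
        r_mid = min(9.0 * MM, geom.Rs if geom.has_saline else R)
        if geom.has_saline:
            segs.append(graded_points(a, a + geom.r0, h, 2.0 * h, ratio))
            segs.append(graded_points(a + geom.r0, r_mid, 2.0 * h, 6.0 * h, ratio))
        else:
            segs.append(graded_points(a, r_mid, h, 6.0 * h, ratio))
        if r_mid < R:
            segs.append(graded_points(r_mid, R, 6.0 * h, 40.0 * h, ratio))
        if geom.has_saline and geom.Rs < R and geom.Rs not in (r_mid,):
            pass
    else:
        segs.append(graded_points(0.0, a, 2.0 * h, h, ratio))
        segs.append(graded_points(a, a + 2.0 * MM, h, 3.0 * h, ratio))
        segs.append(graded_points(a + 2.0 * MM, min(9.0 * MM, R), 3.0 * h, 8.0 * h, ratio))
        if R > 9.0 * MM:
            segs.append(graded_points(9.0 * MM, R, 8.0 * h, 40.0 * h, ratio))
    rs = _chain(segs)
    # force key radii (saline rim, zone-1 edge) onto stations
    for rk in geom.key_radii():
        i = int(np.argmin(np.abs(rs - rk)))
        if abs(rs[i] - rk) > 1e-12:
            if 0 < i < len(rs) - 1:
                rs[i] = rk
            else:
                rs = np.sort(np.append(rs, rk))
    return np.unique(rs)


def _z_ladder(geom: Geometry, h: float, ratio: float) -> np.ndarray:
    H, Ztop = geom.H, geom.Ztop
    segs = []
    if geom.topology == "surface_contact":
        zfine_top = -geom.L if geom.has_saline else -1.0 * MM
        segs.append(graded_points(-Ztop, zfine_top, 12.0 * h, 2.0 * h, ratio))
        segs.append(graded_points(zfine_top, geom.D, h, h, ratio))
        segs.append(graded_points(geom.D, geom.D + 2.0 * MM, h, 2.0 * h, ratio))
        segs.append(graded_points(geom.D + 2.0 * MM, 10.0 * MM, 2.0 * h, 8.0 * h, ratio))
        segs.append(graded_points(10.0 * MM, H, 8.0 * h, 40.0 * h, ratio))
    else:
        tip = geom.z_tip
        segs.append(graded_points(-Ztop, -1.0 * MM, 12.0 * h, 3.0 * h, ratio))
        segs.append(graded_points(-1.0 * MM, tip + 1.0 * MM, 2.0 * h, 2.0 * h, ratio))
        segs.append(graded_points(tip + 1.0 * MM, tip + 4.0 * MM, 2.0 * h, 6.0 * h, ratio))
        segs.append(graded_points(tip + 4.0 * MM, H, 6.0 * h, 40.0 * h, ratio))
    zl = _chain(segs)
    for zk in geom.key_levels():
        i = int(np.argmin(np.abs(zl - zk)))
        if abs(zl[i] - zk) > 1e-12 and 0 < i < len(zl) - 1:
            zl[i] = zk
    return np.unique(zl)


# ---------------------------------------------------------------------------
# column assembly and strip stitching


def _merge_intervals(ivs: list[tuple[float, float]], tol: float):
    ivs = sorted(ivs)
    out = [list(ivs[0])]
    for t, b in ivs[1:]:
        if t <= out[-1][1] + tol:
            out[-1][1] = max(out[-1][1], b)
        else:
            out.append([t, b])
    return [tuple(iv) for iv in out]


def _column_nodes(geom: Geometry, rs: np.ndarray, i: int,
                  ladder: np.ndarray, gaps: np.ndarray) -> np.ndarray:
    """Sorted node z-values for station ``i``."""
    r = rs[i]
    sides = []
    if i > 0:
        sides.append(-1)
    if i < len(rs) - 1:
        sides.append(+1)
    ivs, cross = [], []
    for s in sides:
        ivs += geom.intervals(r, s)
        cross += geom.crossings(r, s)
    tol = 1e-12
    ivs = _merge_intervals(ivs, tol)
    fixed = set()
    for t, b in ivs:
        fixed.add(t); fixed.add(b)
    for z in cross:
        fixed.add(z)
    fixed = np.array(sorted(fixed))

    # exclusion bands around interface curves spanned by neighbouring stations
    bands = []
    neigh = [rs[j] for j in (i - 1, i, i + 1) if 0 <= j < len(rs)]
    for f, rlo, rhi in geom.interface_curves:
        pts = [float(f(min(max(rn, rlo), rhi))) for rn in neigh
               if rlo - 1e-12 <= rn <= rhi + 1e-12]
        if pts:
            bands.append((min(pts), max(pts)))

    nodes = [fixed]
    for t, b in ivs:
        zc = ladder[(ladder > t) & (ladder < b)]
        if len(zc) == 0:
            continue
        g = gaps[np.clip(np.searchsorted(ladder, zc) - 1, 0, len(gaps) - 1)]
        keep = np.ones(len(zc), bool)
        for zf in fixed:
            keep &= np.abs(zc - zf) > 0.45 * g
        for lo, hi in bands:
            g2 = 0.3 * g
            keep &= ~((zc > lo - g2) & (zc < hi + g2))
        nodes.append(zc[keep])
    out = np.unique(np.concatenate(nodes))
    # drop accidental near-duplicates
    if len(out) > 1:
        d = np.diff(out)
        out = np.concatenate([[out[0]], out[1:][d > 1e-12]])
    return out


def _stitch(idsL, zL, idsR, zR) -> list[tuple[int, int, int]]:
    """Triangulate the strip between two sorted node columns."""
    tris = []
    i = j = 0
    nL, nR = len(idsL), len(idsR)
    while i < nL - 1 or j < nR - 1:
        if j == nR - 1:
            adv_left = True
        elif i == nL - 1:
            adv_left = False
        else:
            adv_left = zL[i + 1] <= zR[j + 1]
        if adv_left:
            tris.append((idsL[i], idsR[j], idsL[i + 1]))
            i += 1
        else:
            tris.append((idsL[i], idsR[j + 1], idsR[j]))
            j += 1
    return tris


def generate_mesh(geom: Geometry, h_interface: float = 0.085,
                  grading: float = 1.35) -> AxisymmetricMesh:
    """Generate the graded conforming triangulation.

    Parameters
    ----------
    geom:
        Labelled region set from :func:`~salinerf.geometry.build_geometry`.
    h_interface:
        Element size (mm) at the electrode-tissue interface, the finest zone.
    grading:
        Geometric growth ratio of element sizes away from the interface.
    """
    if h_interface <= 0:
        raise ValueError("h_interface must be > 0")
    h = h_interface * MM
    rs = _radial_stations(geom, h, grading)
    ladder = _z_ladder(geom, h, grading)
    gaps = np.diff(ladder)

    cols_z, cols_id = [], []
    points = []
    n = 0
    for i in range(len(rs)):
        z = _column_nodes(geom, rs, i, ladder, gaps)
        ids = np.arange(n, n + len(z))
        n += len(z)
        cols_z.append(z)
        cols_id.append(ids)
        points.append(np.column_stack([np.full(len(z), rs[i]), z]))
    points = np.concatenate(points)

    tris = []
    for i in range(len(rs) - 1):
        ivL = geom.intervals(rs[i], +1)
        ivR = geom.intervals(rs[i + 1], -1)
        if len(ivL) != len(ivR):
            raise MeshingError(
                f"interval mismatch in strip r = [{rs[i]:.4g}, {rs[i+1]:.4g}] m "
                f"({len(ivL)} vs {len(ivR)} regions); add a station at the "
                "transition radius")
        for (tL, bL), (tR, bR) in zip(ivL, ivR):
            eps = 1e-12
            mL = (cols_z[i] >= tL - eps) & (cols_z[i] <= bL + eps)
            mR = (cols_z[i + 1] >= tR - eps) & (cols_z[i + 1] <= bR + eps)
            tris += _stitch(cols_id[i][mL], cols_z[i][mL],
                            cols_id[i + 1][mR], cols_z[i + 1][mR])
    tris = np.asarray(tris, dtype=np.int64)

    # orientation and degeneracy
    p = points[tris]
    area2 = ((p[:, 1, 0] - p[:, 0, 0]) * (p[:, 2, 1] - p[:, 0, 1])
             - (p[:, 1, 1] - p[:, 0, 1]) * (p[:, 2, 0] - p[:, 0, 0]))
    flip = area2 < 0
    tris[flip] = tris[flip][:, [0, 2, 1]]
    keep = np.abs(area2) > 1e-16
    tris = tris[keep]

    # drop nodes not referenced by any triangle (collapsed strip corners)
    used = np.zeros(len(points), dtype=bool)
    used[tris] = True
    remap = np.cumsum(used) - 1
    points = points[used]
    tris = remap[tris]

    centroids = points[tris].mean(axis=1)
    material = geom.material_of_elements(centroids)
    if (material < 0).any():
        bad = centroids[material < 0]
        raise MeshingError(
            f"{len(bad)} unclassifiable elements, first at {bad[0]}")

    mesh = AxisymmetricMesh(points=points, triangles=tris,
                            material=material, geom=geom)
    mesh.check_valid()
    mesh.edge_labels = classify_boundaries(mesh)
    return mesh


# ---------------------------------------------------------------------------
# boundary labelling


def classify_boundaries(mesh: AxisymmetricMesh) -> dict[str, np.ndarray]:
    """Label boundary and interface edges with the physical surface names."""
    geom = mesh.geom
    edges, owners = mesh.boundary_edges
    pts = mesh.points
    mid = 0.5 * (pts[edges[:, 0]] + pts[edges[:, 1]])
    emat = mesh.material[owners]
    tol = 1e-9
    labels: dict[str, list] = {}

    def put(name, mask):
        if mask.any():
            labels.setdefault(name, []).append(edges[mask])

    r, z = mid[:, 0], mid[:, 1]
    on_axis = np.abs(pts[edges[:, 0], 0]) < tol
    on_axis &= np.abs(pts[edges[:, 1], 0]) < tol
    bottom = np.abs(z - geom.H) < geom.H * 1e-9
    lateral = np.abs(r - geom.R) < geom.R * 1e-9
    rest = ~(on_axis | bottom | lateral)
    put("axis", on_axis)
    put("dispersive", bottom)
    medium = geom.medium
    put("tissue_lateral", lateral & (emat == medium))
    if geom.has_saline:
        # the film edge facing the void crevice under the tip is a wall,
        # not a free surface
        wedge = rest & (emat == SALINE) & (np.abs(r - geom.a) < 1e-7 * geom.a) \
            & (z > geom.zc)
        put("saline_wedge_wall", wedge)
        put("saline_free_surface", rest & (emat == SALINE) & ~wedge)
        put("saline_free_surface", lateral & (emat == SALINE))
    put("plastic_outer", rest & (emat == PLASTIC))
    put("electrode_active", rest & (emat == ELECTRODE))
    put("tissue_top", rest & (emat == medium))

    out = {k: np.concatenate(v) for k, v in labels.items()}

    iface = mesh.interface_edges
    pair = tuple(sorted((SALINE, TISSUE)))
    if pair in iface:
        out["saline_tissue_interface"] = iface[pair]
    pair = tuple(sorted((SALINE, ELECTRODE)))
    if pair in iface and geom.has_saline:
        e = iface[pair]
        m = 0.5 * (pts[e[:, 0]] + pts[e[:, 1]])
        z_hi, z_lo = geom.inflow_band()
        sel = (m[:, 1] >= z_hi - tol) & (m[:, 1] <= z_lo + tol)
        out["saline_inflow"] = e[sel]
        out["saline_electrode_wall"] = e[~sel]
    return out


# ---------------------------------------------------------------------------
# simple structured fixture mesh


def rectangle_mesh(r0: float, r1: float, z0: float, z1: float,
                   nr: int, nz: int) -> tuple[np.ndarray, np.ndarray]:
    """Structured rectangle triangulation: 2 triangles per cell (SI units)."""
    rv = np.linspace(r0, r1, nr + 1)
    zv = np.linspace(z0, z1, nz + 1)
    R, Z = np.meshgrid(rv, zv, indexing="ij")
    pts = np.column_stack([R.ravel(), Z.ravel()])
    tris = []
    for i in range(nr):
        for j in range(nz):
            n00 = i * (nz + 1) + j
            n01 = n00 + 1
            n10 = n00 + (nz + 1)
            n11 = n10 + 1
            tris.append((n00, n10, n11))
            tris.append((n00, n11, n01))
    return pts, np.asarray(tris, dtype=np.int64)
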