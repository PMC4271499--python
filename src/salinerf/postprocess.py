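"""Isotherm extraction and lesion metrics.

The visible whitening boundary of heated liver corresponds approximately to
the 60 degC isotherm, so lesion size is quantified from the level set of the
final temperature field restricted to the tissue subdomain: depth is the
largest ``z`` the contour reaches below the surface, width the full diameter
``2 r`` at which the surface plane ``z = 0`` still reaches the level.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import SALINE, TISSUE
from .mesh import AxisymmetricMesh

MM = 1e-3


@dataclass
class LesionMetrics:
    level: float                # isotherm level, degC
    depth: float                # mm below the tissue surface
    width: float                # mm, full diameter at the surface plane
    max_tissue_T: float         # degC
    max_saline_T: float | None  # degC, None without a saline layer
    empty: bool = False         # no tissue point reached the level


def _segments(points, tris, values, level):
    """Marching-triangles level-set segments, one per crossed triangle."""
    v = values[tris]                       # (M,3)
    segs = []
    for loc in ((0, 1), (1, 2), (2, 0)):
        a, b = tris[:, loc[0]], tris[:, loc[1]]
        va, vb = values[a], values[b]
        cross = (va - level) * (vb - level) < 0
        t = np.zeros(len(tris))
        t[cross] = (level - va[cross]) / (vb[cross] - va[cross])
        pt = points[a] + t[:, None] * (points[b] - points[a])
        segs.append((cross, pt))
    out = []
    for e in range(len(tris)):
        pts = [segs[i][1][e] for i in range(3) if segs[i][0][e]]
        if len(pts) == 2:
            out.append(np.array(pts))
    return out


def extract_isotherm(points: np.ndarray, triangles: np.ndarray,
                     values: np.ndarray, level: float) -> list[np.ndarray]:
    """Level-set polylines of a nodal field on a triangulation.

    Returns a (possibly empty) list of ``(k, 2)`` polylines; closed contours
    repeat the first point at the end.
    """
    segs = _segments(points, triangles, values, level)
    if not segs:
        return []
    # chain segments by matching endpoints
    scale = max(np.ptp(points[:, 0]), np.ptp(points[:, 1]), 1e-300)
    key = lambda p: (round(p[0] / scale, 9), round(p[1] / scale, 9))
    ends: dict = {}
    for i, s in enumerate(segs):
        for j in (0, 1):
            ends.setdefault(key(s[j]), []).append((i, j))
    used = np.zeros(len(segs), bool)
    lines = []
    for start in range(len(segs)):
        if used[start]:
            continue
        used[start] = True
        line = [segs[start][0], segs[start][1]]
        for head in (1, 0):
            while True:
                candidates = [c for c in ends.get(key(line[-1] if head else line[0]), [])
                              if not used[c[0]]]
                if not candidates:
                    break
                i, j = candidates[0]
                used[i] = True
                nxt = segs[i][1 - j]
                if head:
                    line.append(nxt)
                else:
                    line.insert(0, nxt)
        lines.append(np.asarray(line))
    return lines


def _tissue_surface_edges(mesh: AxisymmetricMesh) -> np.ndarray:
    """Edges of tissue elements lying in the surface plane z = 0."""
    cand = []
    for label in ("saline_tissue_interface", "tissue_top"):
        if label in mesh.edge_labels:
            cand.append(mesh.edge_labels[label])
    if not cand:
        return np.empty((0, 2), dtype=np.int64)
    edges = np.concatenate(cand)
    z = mesh.points[:, 1]
    tol = 1e-7 * max(mesh.geom.H, 1e-3) if mesh.geom else 1e-9
    flat = (np.abs(z[edges[:, 0]]) < tol) & (np.abs(z[edges[:, 1]]) < tol)
    return edges[flat]


def lesion_dimensions(mesh: AxisymmetricMesh, T: np.ndarray,
                      level: float = 60.0) -> LesionMetrics:
    """Depth/width of the level isotherm in the tissue subdomain.

    Depth is measured anywhere on the contour (the lesion is centred under
    the electrode); width on the undisturbed surface plane ``z = 0``, where
    whitening is assessed in the bench experiments.
    """
    tmask = mesh.material == TISSUE
    t_nodes = mesh.nodes_of("tissue")
    max_tissue = float(T[t_nodes].max())
    smask = mesh.material == SALINE
    max_saline = float(T[np.unique(mesh.triangles[smask])].max()) if smask.any() else None

    segs = _segments(mesh.points, mesh.triangles[tmask], T, level)
    hot_nodes = t_nodes[T[t_nodes] >= level]
    pts = [np.concatenate(segs)] if segs else []
    if len(hot_nodes):
        pts.append(mesh.points[hot_nodes])
    depth = 0.0
    if pts:
        pts = np.concatenate(pts)
        i = int(np.argmax(pts[:, 1]))
        r_deep, z_deep = pts[i]
        # depth is measured from the local tissue surface: at the centre the
        # lesion starts at the floor of the tip indentation (the white-zone
        # thickness seen on cross-section photographs), outside the contact
        # ring at the undisturbed plane z = 0
        surf = 0.0
        geom = mesh.geom
        if geom is not None and geom.topology == "surface_contact" \
                and r_deep < geom.rcap:
            surf = float(geom.z_electrode_bottom(r_deep))
        depth = float(z_deep - surf)

    width = 0.0
    edges = _tissue_surface_edges(mesh)
    if len(edges):
        r = mesh.points[:, 0]
        va, vb = T[edges[:, 0]], T[edges[:, 1]]
        ra, rb = r[edges[:, 0]], r[edges[:, 1]]
        hot = np.concatenate([ra[va >= level], rb[vb >= level]])
        if len(hot):
            width = float(hot.max())
        cross = (va - level) * (vb - level) < 0
        if cross.any():
            t = (level - va[cross]) / (vb[cross] - va[cross])
            rc = ra[cross] + t * (rb[cross] - ra[cross])
            width = max(width, float(rc.max()))
        width *= 2.0

    empty = max_tissue < level
    return LesionMetrics(level=level, depth=0.0 if empty else depth / MM,
                         width=0.0 if empty else width / MM,
                         max_tissue_T=max_tissue, max_saline_T=max_saline,
                         empty=empty)
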