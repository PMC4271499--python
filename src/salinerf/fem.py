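"""Shared axisymmetric P1 finite-element machinery.

All weak forms are weighted by ``2*pi*r`` (volume of revolution).  For linear
triangles the ``r``-weighted element integrals used here are evaluated in
closed form, so no quadrature loop is needed:

* ``int_K grad(l_i).grad(l_j) r dA = (g_i . g_j) A r_bar``
* ``int_K l_i r dA             = A (3 r_bar + r_i) / 12``
* ``int_K l_i l_m r dA         = A sum_n r_n t_imn`` with the standard
  barycentric moment tensor ``t``.
"""

from __future__ import annotations

import math

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

TWO_PI = 2.0 * math.pi

# barycentric moment tensor: int l_i l_m l_n dA / A
_T3 = np.full((3, 3, 3), 1.0 / 60.0)
for _i in range(3):
    for _m in range(3):
        for _n in range(3):
            eq = (_i == _m) + (_i == _n) + (_m == _n)
            if eq == 3:
                _T3[_i, _m, _n] = 1.0 / 10.0
            elif eq == 1:
                _T3[_i, _m, _n] = 1.0 / 30.0


class P1Fem:
    """Precomputed element geometry and assembly routines for one mesh."""

    def __init__(self, points: np.ndarray, triangles: np.ndarray):
        self.points = np.asarray(points, float)
        self.tris = np.asarray(triangles, np.int64)
        p = self.points[self.tris]                       # (M,3,2)
        d1 = p[:, 1] - p[:, 0]
        d2 = p[:, 2] - p[:, 0]
        det = d1[:, 0] * d2[:, 1] - d1[:, 1] * d2[:, 0]
        self.area = 0.5 * det
        if (self.area <= 0).any():
            raise ValueError("mesh must be CCW with positive areas")
        # gradients of the barycentric shape functions
        g = np.empty((len(self.tris), 3, 2))
        g[:, 1, 0] = d2[:, 1] / det
        g[:, 1, 1] = -d2[:, 0] / det
        g[:, 2, 0] = -d1[:, 1] / det
        g[:, 2, 1] = d1[:, 0] / det
        g[:, 0] = -g[:, 1] - g[:, 2]
        self.grads = g
        self.rnode = p[:, :, 0]
        self.rbar = self.rnode.mean(axis=1)
        self.n = len(self.points)
        self._rows = np.repeat(self.tris, 3, axis=1).reshape(-1)
        self._cols = np.tile(self.tris, (1, 3)).reshape(-1)
        # int l_i r dA per element/node
        self._wl = self.area[:, None] * (3.0 * self.rbar[:, None] + self.rnode) / 12.0
        # int l_i l_m r dA
        self._wlm = np.einsum('imn,en->eim', _T3, self.rnode) * self.area[:, None, None]

    # -- assembly ------------------------------------------------------------

    def assemble(self, Ke: np.ndarray) -> sp.csr_matrix:
        """Assemble per-element 3x3 blocks into a global sparse matrix."""
        A = sp.coo_matrix((Ke.reshape(-1), (self._rows, self._cols)),
                          shape=(self.n, self.n))
        return A.tocsr()

    def stiffness(self, coeff_elem: np.ndarray) -> sp.csr_matrix:
        """int coeff grad(u).grad(v) 2 pi r dA with element-wise coefficient."""
        gg = np.einsum('eik,ejk->eij', self.grads, self.grads)
        Ke = (TWO_PI * coeff_elem * self.area * self.rbar)[:, None, None] * gg
        return self.assemble(Ke)

    def lumped(self, coeff_elem: np.ndarray) -> np.ndarray:
        """Row-sum (lumped) mass vector of int coeff u v 2 pi r dA."""
        vals = TWO_PI * coeff_elem[:, None] * self._wl
        out = np.zeros(self.n)
        np.add.at(out, self.tris.reshape(-1), vals.reshape(-1))
        return out

    def load(self, source_elem: np.ndarray) -> np.ndarray:
        """Load vector of an element-wise constant volumetric source."""
        return self.lumped(source_elem)

    def integrate(self, f_elem: np.ndarray) -> float:
        """Volume integral 2 pi int f r dA of an element-wise constant field."""
        return float(TWO_PI * np.sum(f_elem * self.area * self.rbar))

    def convection(self, u_node: np.ndarray, coeff_elem: np.ndarray,
                   k_elem: np.ndarray | None = None,
                   stabilize: bool = True) -> sp.csr_matrix:
        """int coeff (u . grad T) v 2 pi r dA with P1 velocity ``u_node``.

        With ``stabilize`` a streamline (SU) artificial diffusion with the
        classic coth rule is added, sized by the element Peclet number
        (requires ``k_elem``); it only acts along the flow direction.
        """
        U = u_node[self.tris]                            # (M,3,2)
        dot = np.einsum('emk,ejk->emj', U, self.grads)   # u_m . g_j
        Ke = TWO_PI * coeff_elem[:, None, None] * \
            np.einsum('eim,emj->eij', self._wlm, dot)
        if stabilize:
            if k_elem is None:
                raise ValueError("stabilization needs the conductivity")
            ub = U.mean(axis=1)
            speed = np.hypot(ub[:, 0], ub[:, 1])
            h = np.sqrt(4.0 * self.area / math.sqrt(3.0))
            pe = coeff_elem * speed * h / (2.0 * np.maximum(k_elem, 1e-300))
            with np.errstate(over='ignore', invalid='ignore', divide='ignore'):
                xi = np.where(pe > 1e-6, 1.0 / np.tanh(pe) - 1.0 / pe, pe / 3.0)
                tau = np.where(speed > 0, h * xi / (2.0 * speed), 0.0)
            ug = np.einsum('ek,eik->ei', ub, self.grads)
            Se = (TWO_PI * tau * coeff_elem * self.area * self.rbar)[:, None, None] \
                * ug[:, :, None] * ug[:, None, :]
            Ke = Ke + Se
        return self.assemble(Ke)

    def robin(self, edges: np.ndarray, h_coef: float
              ) -> tuple[sp.csr_matrix, np.ndarray]:
        """Boundary term of Newton cooling h (T - Ta) on the given edges.

        Returns ``(M, w)`` with matrix contribution ``M`` and weight vector
        ``w`` such that the RHS contribution is ``w * Ta``.
        """
        if len(edges) == 0:
            return sp.csr_matrix((self.n, self.n)), np.zeros(self.n)
        p0 = self.points[edges[:, 0]]
        p1 = self.points[edges[:, 1]]
        ell = np.hypot(*(p1 - p0).T)
        r0, r1 = p0[:, 0], p1[:, 0]
        f = TWO_PI * h_coef * ell / 12.0
        K = np.empty((len(edges), 2, 2))
        K[:, 0, 0] = f * (3 * r0 + r1)
        K[:, 1, 1] = f * (r0 + 3 * r1)
        K[:, 0, 1] = K[:, 1, 0] = f * (r0 + r1)
        rows = np.repeat(edges, 2, axis=1).reshape(-1)
        cols = np.tile(edges, (1, 2)).reshape(-1)
        M = sp.coo_matrix((K.reshape(-1), (rows, cols)),
                          shape=(self.n, self.n)).tocsr()
        w = np.zeros(self.n)
        np.add.at(w, edges[:, 0], TWO_PI * h_coef * ell * (2 * r0 + r1) / 6.0)
        np.add.at(w, edges[:, 1], TWO_PI * h_coef * ell * (r0 + 2 * r1) / 6.0)
        return M, w

    def gradient(self, field: np.ndarray) -> np.ndarray:
        """Element-wise (constant) gradient of a nodal field."""
        return np.einsum('ei,eik->ek', field[self.tris], self.grads)


def edge_normal_flux(points: np.ndarray, edges: np.ndarray,
                     u_node: np.ndarray, normals: np.ndarray) -> float:
    """int u.n 2 pi r ds over a set of edges with P1 velocity (SI units)."""
    p0, p1 = points[edges[:, 0]], points[edges[:, 1]]
    ell = np.hypot(*(p1 - p0).T)
    r0, r1 = p0[:, 0], p1[:, 0]
    un0 = np.einsum('ek,ek->e', u_node[edges[:, 0]], normals)
    un1 = np.einsum('ek,ek->e', u_node[edges[:, 1]], normals)
    return float(TWO_PI * np.sum(ell * (un0 * (2 * r0 + r1) + un1 * (r0 + 2 * r1)) / 6.0))


def outward_edge_normals(points: np.ndarray, edges: np.ndarray,
                         interior_ref: np.ndarray) -> np.ndarray:
    """Unit normals of boundary edges pointing away from reference points.

    ``interior_ref``: one interior point per edge (e.g. the owning element's
    centroid); the normal is flipped to point away from it.
    """
    t = points[edges[:, 1]] - points[edges[:, 0]]
    n = np.column_stack([t[:, 1], -t[:, 0]])
    n /= np.hypot(n[:, 0], n[:, 1])[:, None]
    mid = 0.5 * (points[edges[:, 0]] + points[edges[:, 1]])
    flip = np.einsum('ek,ek->e', n, interior_ref - mid) > 0
    n[flip] *= -1.0
    return n


def solve_dirichlet(A: sp.csr_matrix, b: np.ndarray,
                    fixed: np.ndarray, values: np.ndarray) -> np.ndarray:
    """Solve ``A x = b`` with prescribed values on the ``fixed`` dofs."""
    n = A.shape[0]
    x = np.zeros(n)
    x[fixed] = values
    free = np.ones(n, dtype=bool)
    free[fixed] = False
    free_idx = np.flatnonzero(free)
    if len(free_idx) == 0:
        return x
    A_csc = A.tocsc()
    rhs = b[free_idx] - A_csc[free_idx][:, fixed] @ x[fixed]
    Aff = A_csc[free_idx][:, free_idx]
    x[free_idx] = spla.spsolve(Aff.tocsc(), rhs)
    return x
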