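"""Taylor–Hood finite-element solver for the Stokes system on simplicial meshes.

The state equations are the creeping-flow (Stokes) equations on the cell
interior Ω with Dirichlet boundary control g on Γ and, in 2D, an apparent
divergence source r accounting for out-of-plane motion::

    ∇p − μ ∇²u = f   in Ω
        ∇·u     = r   in Ω   (r ≡ 0 in 3D)
          u     = g   on Γ

Discretisation: continuous piecewise-quadratic velocity / piecewise-linear
pressure (Taylor–Hood, inf-sup stable); force f and source r live on the
linear vertex space; g on the quadratic trace space of Γ. Dirichlet data is
imposed strongly on boundary velocity nodes. Units: μm, s, Pa (f in Pa/μm).

Pure-Dirichlet Stokes determines the pressure only up to a constant and
requires ∮Γ g·n dΓ = ∫Ω r dΩ. Both issues are handled by one scalar Lagrange
multiplier pair: a zero-mean row fixes the pressure gauge, and a uniform
divergence column absorbs any flux mismatch (its magnitude is reported as a
diagnostic and is folded back into r by the assimilation layer, see
:mod:`stokesflow.assimilation`).

Linear systems use a sparse direct (multifrontal-type) factorisation
(``scipy.sparse.linalg.splu``); the accuracy contract is the residual norms,
not the solver brand.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from functools import cached_property

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from scipy.interpolate import LinearNDInterpolator, NearestNDInterpolator

from .errors import CompatibilityError
from .geometry import FEMesh

__all__ = [
    "P2Space",
    "StokesSystem",
    "VelocityField",
    "PressureField",
    "ForceField",
    "BoundaryVelocity",
    "DivergenceSource",
    "solve_stokes",
    "solve_adjoint",
    "residuals",
    "l2_error",
    "SOLVER_TOL",
]

SOLVER_TOL = 1e-8  # relative residual contract for direct solves


# ---------------------------------------------------------------------------
# Reference-simplex quadrature (weights sum to the reference measure 1/d!)
# ---------------------------------------------------------------------------

def _tri_rule():
    a1, w1 = 0.445948490915965, 0.223381589678011
    a2, w2 = 0.091576213509771, 0.109951743655322
    bary = []
    wts = []
    for a, w in ((a1, w1), (a2, w2)):
        pts = {(1 - 2 * a, a, a), (a, 1 - 2 * a, a), (a, a, 1 - 2 * a)}
        for p in sorted(pts):
            bary.append(p)
            wts.append(w)
    bary = np.array(bary)
    return bary[:, 1:], np.array(wts) * 0.5  # degree 4, 6 points


def _tet_rule():
    bary, wts = [], []
    bary.append((0.25, 0.25, 0.25, 0.25))
    wts.append(-0.013155555555555555)
    a, b, w = 0.7857142857142857, 0.07142857142857143, 0.007622222222222222
    for i in range(4):
        p = [b] * 4
        p[i] = a
        bary.append(tuple(p))
        wts.append(w)
    a, b, w = 0.3994035761667992, 0.1005964238332008, 0.024888888888888888
    for pair in itertools.combinations(range(4), 2):
        p = [b] * 4
        p[pair[0]] = p[pair[1]] = a
        bary.append(tuple(p))
        wts.append(w)
    bary = np.array(bary)
    return bary[:, 1:], np.array(wts)  # Keast degree 4, 11 points


def _interval_rule():
    s = 0.5 * np.sqrt(3.0 / 5.0)
    pts = np.array([[0.5 - s], [0.5], [0.5 + s]])
    wts = np.array([5.0, 8.0, 5.0]) / 18.0
    return pts, wts  # Gauss, degree 5


_VOLUME_RULES = {1: _interval_rule, 2: _tri_rule, 3: _tet_rule}


def simplex_rule(d: int):
    return _VOLUME_RULES[d]()


def _edge_pairs(d: int):
    return list(itertools.combinations(range(d + 1), 2))


def p2_basis(d: int, xi: np.ndarray):
    """Quadratic Lagrange basis on the reference d-simplex.

    Returns values ``(nq, nloc)`` and reference gradients ``(nq, nloc, d)``
    for local ordering: vertices 0..d, then edge midpoints in lexicographic
    vertex-pair order.
    """
    xi = np.atleast_2d(xi)
    nq = xi.shape[0]
    lam = np.empty((nq, d + 1))
    lam[:, 0] = 1.0 - xi.sum(axis=1)
    lam[:, 1:] = xi
    dlam = np.vstack([-np.ones((1, d)), np.eye(d)])  # (d+1, d)
    pairs = _edge_pairs(d)
    nloc = d + 1 + len(pairs)
    vals = np.empty((nq, nloc))
    grads = np.empty((nq, nloc, d))
    for i in range(d + 1):
        vals[:, i] = lam[:, i] * (2 * lam[:, i] - 1)
        grads[:, i, :] = (4 * lam[:, i] - 1)[:, None] * dlam[i]
    for k, (i, j) in enumerate(pairs):
        vals[:, d + 1 + k] = 4 * lam[:, i] * lam[:, j]
        grads[:, d + 1 + k, :] = 4 * (
            lam[:, j][:, None] * dlam[i] + lam[:, i][:, None] * dlam[j]
        )
    return vals, grads


def p1_basis(d: int, xi: np.ndarray):
    xi = np.atleast_2d(xi)
    nq = xi.shape[0]
    lam = np.empty((nq, d + 1))
    lam[:, 0] = 1.0 - xi.sum(axis=1)
    lam[:, 1:] = xi
    dlam = np.vstack([-np.ones((1, d)), np.eye(d)])
    return lam, np.broadcast_to(dlam, (nq, d + 1, d)).copy()


# ---------------------------------------------------------------------------
# P2 function space with boundary trace
# ---------------------------------------------------------------------------

class P2Space:
    """Scalar continuous-quadratic space on a simplicial mesh.

    Degrees of freedom: mesh vertices followed by edge midpoints.
    """

    def __init__(self, mesh: FEMesh):
        self.mesh = mesh
        d = mesh.dim
        self.dim = d
        pairs = _edge_pairs(d)
        edge_index: dict[tuple[int, int], int] = {}
        nv = mesh.n_nodes
        elem = np.empty((len(mesh.simplices), d + 1 + len(pairs)), dtype=np.int64)
        elem[:, : d + 1] = mesh.simplices
        for k, (i, j) in enumerate(pairs):
            a = mesh.simplices[:, i]
            b = mesh.simplices[:, j]
            lo, hi = np.minimum(a, b), np.maximum(a, b)
            for e in range(len(a)):
                key = (lo[e], hi[e])
                idx = edge_index.setdefault(key, nv + len(edge_index))
                elem[e, d + 1 + k] = idx
        self.edge_index = edge_index
        self.element_dofs = elem
        self.n_dofs = nv + len(edge_index)
        coords = np.empty((self.n_dofs, d))
        coords[:nv] = mesh.nodes
        for (a, b), idx in edge_index.items():
            coords[idx] = 0.5 * (mesh.nodes[a] + mesh.nodes[b])
        self.coords = coords

        # boundary trace dofs, facet-wise (vertices then facet-edge midpoints)
        fpairs = _edge_pairs(d - 1)
        fd = np.empty((len(mesh.boundary_facets), d + len(fpairs)), dtype=np.int64)
        fd[:, :d] = mesh.boundary_facets
        for k, (i, j) in enumerate(fpairs):
            a = mesh.boundary_facets[:, i]
            b = mesh.boundary_facets[:, j]
            lo, hi = np.minimum(a, b), np.maximum(a, b)
            fd[:, d + k] = [edge_index[(lo[e], hi[e])] for e in range(len(a))]
        self.facet_dofs = fd
        self.boundary_dofs = np.unique(fd)
        self._bpos = {int(g): i for i, g in enumerate(self.boundary_dofs)}
        self.n_boundary = len(self.boundary_dofs)

    # -- volume quadrature geometry --------------------------------------
    @cached_property
    def _geometry(self):
        mesh = self.mesh
        d = mesh.dim
        xi, w = simplex_rule(d)
        v = mesh.nodes[mesh.simplices]           # (m, d+1, d)
        J = np.transpose(v[:, 1:] - v[:, :1], (0, 2, 1))  # (m, d, d)
        detJ = np.linalg.det(J)
        invJT = np.transpose(np.linalg.inv(J), (0, 2, 1))
        phi2, g2ref = p2_basis(d, xi)
        phi1, _ = p1_basis(d, xi)
        dlam = np.vstack([-np.ones((1, d)), np.eye(d)])
        g1 = np.einsum("eab,ib->eia", invJT, dlam)         # (m, d+1, d) const
        g2 = np.einsum("eab,qib->eqia", invJT, g2ref)      # (m, nq, nloc, d)
        wq = np.abs(detJ)[:, None] * w[None, :]            # (m, nq)
        xq = v[:, 0][:, None, :] + np.einsum("eab,qb->eqa", J, xi)
        return {"xq": xq, "wq": wq, "phi2": phi2, "g2": g2, "phi1": phi1, "g1": g1}

    def quad(self):
        """Physical quadrature points, weights, and basis tables."""
        g = self._geometry
        return g["xq"], g["wq"], g["phi2"], g["g2"], g["phi1"], g["g1"]

    # -- boundary quadrature geometry ------------------------------------
    @cached_property
    def _bgeometry(self):
        mesh = self.mesh
        d, df = mesh.dim, mesh.dim - 1
        xi, w = simplex_rule(df)
        v = mesh.nodes[mesh.boundary_facets]  # (b, df+1, d)
        Jf = np.transpose(v[:, 1:] - v[:, :1], (0, 2, 1))  # (b, d, df)
        G = np.einsum("bak,bal->bkl", Jf, Jf)
        sdet = np.sqrt(np.abs(np.linalg.det(G)))
        Ginv = np.linalg.inv(G)
        phi, gref = p2_basis(df, xi)
        # tangential gradients in ambient coordinates
        tg = np.einsum("bak,bkl,qil->bqia", Jf, Ginv, gref)
        wq = sdet[:, None] * w[None, :]
        xq = v[:, 0][:, None, :] + np.einsum("bak,qk->bqa", Jf, xi)
        return {"xq": xq, "wq": wq, "phi": phi, "tg": tg}

    def boundary_quad(self):
        g = self._bgeometry
        return g["xq"], g["wq"], g["phi"], g["tg"]

    def _assemble(self, local, rows, cols, shape):
        return sp.coo_matrix(
            (local.ravel(), (rows.ravel(), cols.ravel())), shape=shape
        ).tocsr()

    @cached_property
    def stiffness(self) -> sp.csr_matrix:
        """∫ ∇φ_i·∇φ_j over Ω on the quadratic space."""
        _, wq, _, g2, _, _ = self.quad()
        loc = np.einsum("eq,eqia,eqja->eij", wq, g2, g2)
        e = self.element_dofs
        return self._assemble(loc, e[:, :, None] * np.ones_like(e)[:, None, :],
                              np.ones_like(e)[:, :, None] * e[:, None, :],
                              (self.n_dofs, self.n_dofs))

    @cached_property
    def mixed_mass(self) -> sp.csr_matrix:
        """∫ φ_i^{P2} ψ_j^{P1} (load map from vertex data to quadratic tests)."""
        _, wq, phi2, _, phi1, _ = self.quad()
        loc = np.einsum("eq,qi,qj->eij", wq, phi2, phi1)
        e2, e1 = self.element_dofs, self.mesh.simplices
        rows = e2[:, :, None] * np.ones((1, 1, e1.shape[1]), dtype=int)
        cols = np.ones((1, e2.shape[1], 1), dtype=int) * e1[:, None, :]
        return self._assemble(loc, rows, cols, (self.n_dofs, self.mesh.n_nodes))

    @cached_property
    def p1_mass(self) -> sp.csr_matrix:
        _, wq, _, _, phi1, _ = self.quad()
        loc = np.einsum("eq,qi,qj->eij", wq, phi1, phi1)
        e1 = self.mesh.simplices
        rows = e1[:, :, None] * np.ones((1, 1, e1.shape[1]), dtype=int)
        cols = np.ones((1, e1.shape[1], 1), dtype=int) * e1[:, None, :]
        return self._assemble(loc, rows, cols, (self.mesh.n_nodes, self.mesh.n_nodes))

    @cached_property
    def p1_stiffness(self) -> sp.csr_matrix:
        _, wq, _, _, _, g1 = self.quad()
        vol = wq.sum(axis=1)
        loc = np.einsum("e,eia,eja->eij", vol, g1, g1)
        e1 = self.mesh.simplices
        rows = e1[:, :, None] * np.ones((1, 1, e1.shape[1]), dtype=int)
        cols = np.ones((1, e1.shape[1], 1), dtype=int) * e1[:, None, :]
        return self._assemble(loc, rows, cols, (self.mesh.n_nodes, self.mesh.n_nodes))

    @cached_property
    def divergence(self) -> sp.csr_matrix:
        """B with B[j, k*n2+i] = ∫ ψ_j ∂φ_i/∂x_k (row: P1 test, col: vel dof)."""
        _, wq, _, g2, phi1, _ = self.quad()
        n2, n1, d = self.n_dofs, self.mesh.n_nodes, self.dim
        blocks = []
        e2, e1 = self.element_dofs, self.mesh.simplices
        rows = e1[:, :, None] * np.ones((1, 1, e2.shape[1]), dtype=int)
        cols = np.ones((1, e1.shape[1], 1), dtype=int) * e2[:, None, :]
        for k in range(d):
            loc = np.einsum("eq,qj,eqi->eji", wq, phi1, g2[:, :, :, k])
            blocks.append(self._assemble(loc, rows, cols, (n1, n2)))
        return sp.hstack(blocks).tocsr()

    @cached_property
    def p1_integral(self) -> np.ndarray:
        """Vector m with m_j = ∫ ψ_j dΩ (so mᵀ p = ∫ p)."""
        _, wq, _, _, phi1, _ = self.quad()
        m = np.zeros(self.mesh.n_nodes)
        np.add.at(m, self.mesh.simplices.ravel(),
                  np.einsum("eq,qi->ei", wq, phi1).ravel())
        return m

    @cached_property
    def boundary_tangential_stiffness(self) -> sp.csr_matrix:
        """∮ ∇_Γ N_i · ∇_Γ N_j dΓ on boundary trace dofs (local indexing)."""
        _, wq, _, tg = self.boundary_quad()
        loc = np.einsum("bq,bqia,bqja->bij", wq, tg, tg)
        fl = np.vectorize(self._bpos.__getitem__)(self.facet_dofs)
        rows = fl[:, :, None] * np.ones((1, 1, fl.shape[1]), dtype=int)
        cols = np.ones((1, fl.shape[1], 1), dtype=int) * fl[:, None, :]
        return self._assemble(loc, rows, cols, (self.n_boundary, self.n_boundary))

    @cached_property
    def facet_normals_at_dofs(self) -> np.ndarray:
        """Measure-weighted averaged outward unit normal per boundary dof."""
        n = np.zeros((self.n_boundary, self.dim))
        meas = self.mesh.facet_measures()
        for b, facet in enumerate(self.facet_dofs):
            for gdof in facet:
                n[self._bpos[int(gdof)]] += meas[b] * self.mesh.boundary_normals[b]
        n /= np.linalg.norm(n, axis=1, keepdims=True)
        return n

    def boundary_flux_form(self) -> np.ndarray:
        """Vector F with F[(k, i)] = ∮ N_i n_k dΓ so that F·g = ∮ g·n dΓ.

        Indexed over boundary trace dofs (local), component-major.
        """
        _, wq, phi, _ = self.boundary_quad()
        out = np.zeros((self.dim, self.n_boundary))
        fl = np.vectorize(self._bpos.__getitem__)(self.facet_dofs)
        contrib = np.einsum("bq,qi->bi", wq, phi)  # (b, nloc)
        for k in range(self.dim):
            vals = contrib * self.mesh.boundary_normals[:, k][:, None]
            np.add.at(out[k], fl.ravel(), vals.ravel())
        return out.ravel()

    def boundary_measure(self) -> float:
        _, wq, _, _ = self.boundary_quad()
        return float(wq.sum())

    def interpolator(self, values: np.ndarray):
        """Piecewise-linear interpolant of nodal values at the P2 nodes.

        ``values`` has shape ``(n_dofs,)`` or ``(k, n_dofs)``; returns a
        callable on physical points that falls back to nearest-neighbour
        outside the convex hull.
        """
        vals = np.atleast_2d(values).T
        lin = LinearNDInterpolator(self.coords, vals)
        near = NearestNDInterpolator(self.coords, vals)

        def f(points):
            points = np.atleast_2d(points)
            out = lin(points)
            bad = np.isnan(out).any(axis=1)
            if bad.any():
                out[bad] = near(points[bad])
            return out.T.squeeze()

        return f


# ---------------------------------------------------------------------------
# Field containers
# ---------------------------------------------------------------------------

@dataclass
class VelocityField:
    """Vector field on the quadratic space; ``dofs`` shape (d, n_p2), μm/s."""

    space: P2Space
    dofs: np.ndarray

    def at(self, points):
        return self.space.interpolator(self.dofs)(points)

    def magnitude(self) -> np.ndarray:
        return np.linalg.norm(self.dofs, axis=0)


@dataclass
class PressureField:
    """Scalar field on mesh vertices, Pa; zero mean over Ω by gauge."""

    space: P2Space
    dofs: np.ndarray

    def at(self, points):
        nv = self.space.mesh.n_nodes
        lin = LinearNDInterpolator(self.space.mesh.nodes, self.dofs[:nv])
        near = NearestNDInterpolator(self.space.mesh.nodes, self.dofs[:nv])
        points = np.atleast_2d(points)
        out = lin(points)
        bad = np.isnan(out)
        if bad.any():
            out[bad] = near(points[bad])
        return out


@dataclass
class ForceField:
    """Vector force density on mesh vertices, Pa/μm; see ``to_nN_per_um2``."""

    space: P2Space
    dofs: np.ndarray  # (d, n_vertices)

    def magnitude(self) -> np.ndarray:
        return np.linalg.norm(self.dofs, axis=0)

    def to_nN_per_um2(self, slab_um: float = 1.0) -> np.ndarray:
        """In-plane force surface density over a slab of given depth.

        1 Pa/μm integrated over a 1 μm slab equals 1e-3 nN/μm².
        """
        return 1e-3 * slab_um * self.dofs


@dataclass
class BoundaryVelocity:
    """Velocity control on boundary trace dofs, μm/s; ``dofs`` (d, n_boundary)."""

    space: P2Space
    dofs: np.ndarray

    def flux(self) -> float:
        """∮Γ g·n dΓ."""
        return float(self.space.boundary_flux_form() @ self.dofs.ravel())


@dataclass
class DivergenceSource:
    """Out-of-plane divergence source on mesh vertices, 1/s (2D only)."""

    space: P2Space
    dofs: np.ndarray

    def integral(self) -> float:
        return float(self.space.p1_integral @ self.dofs)


# ---------------------------------------------------------------------------
# The Stokes saddle system
# ---------------------------------------------------------------------------

class StokesSystem:
    """Assembled Taylor–Hood saddle system for one mesh and viscosity.

    Unknown layout: ``[U (d*n2) | P (n1) | λ (1)]`` with velocity dofs
    component-major. Dirichlet rows are replaced by identity; the factorised
    operator is reused for forward and adjoint solves.
    """

    def __init__(self, mesh: FEMesh, mu: float = 1.0):
        if mu <= 0:
            raise ValueError("viscosity must be positive")
        self.mesh = mesh
        self.mu = float(mu)
        self.space = P2Space(mesh)
        sp2 = self.space
        d, n2, n1 = sp2.dim, sp2.n_dofs, mesh.n_nodes
        self.d, self.n2, self.n1 = d, n2, n1
        self.N = d * n2 + n1 + 1

        A = mu * sp.kron(sp.eye(d), sp2.stiffness, format="csr")
        B = sp2.divergence
        m = sp2.p1_integral
        self.A, self.B, self.m = A, B, m
        self.Mf = sp.kron(sp.eye(d), sp2.mixed_mass, format="csr")
        self.Mp = sp2.p1_mass

        bd = np.concatenate([k * n2 + sp2.boundary_dofs for k in range(d)])
        self.dirichlet_dofs = bd
        keep = np.ones(d * n2)
        keep[bd] = 0.0
        self._keep = keep

        mcol = sp.csr_matrix((m, (np.arange(n1), np.zeros(n1, dtype=int))),
                             shape=(n1, 1))
        K = sp.bmat(
            [
                [A, -B.T, None],
                [-B, None, mcol],
                [None, mcol.T, None],
            ],
            format="csr",
        )
        # strong Dirichlet: replace boundary velocity rows by identity
        row_scale = np.ones(self.N)
        row_scale[bd] = 0.0
        K = sp.diags(row_scale) @ K + sp.diags(
            np.concatenate([1.0 - keep, np.zeros(n1 + 1)])
        )
        self.K = K.tocsc()
        self._lu = None
        # load map with Dirichlet rows removed (they carry g instead)
        self.Mf_masked = (sp.diags(keep) @ self.Mf).tocsr()

    @property
    def lu(self):
        if self._lu is None:
            # the saddle matrix has a (nearly) symmetric pattern; symmetric-mode
            # minimum-degree ordering roughly halves fill and solve time
            self._lu = spla.splu(self.K, permc_spec="MMD_AT_PLUS_A",
                                 options=dict(SymmetricMode=True))
        return self._lu

    # -- assembling right-hand sides -------------------------------------
    def rhs(self, f=None, g=None, r=None) -> np.ndarray:
        d, n2, n1 = self.d, self.n2, self.n1
        F = np.zeros(self.N)
        if f is not None:
            F[: d * n2] = self.Mf_masked @ np.asarray(f).ravel()
        if g is not None:
            F[self.dirichlet_dofs] = np.asarray(g).ravel()
        if r is not None:
            F[d * n2 : d * n2 + n1] = -(self.Mp @ np.asarray(r))
        return F

    def rhs_from_callable(self, f_callable, g=None, r=None) -> np.ndarray:
        """Right-hand side with the body force integrated analytically at
        quadrature points (used by convergence studies)."""
        xq, wq, phi2, _, _, _ = self.space.quad()
        d, n2 = self.d, self.n2
        fvals = np.asarray(f_callable(xq.reshape(-1, d))).reshape(
            xq.shape[0], xq.shape[1], d
        )
        load = np.zeros((d, n2))
        e2 = self.space.element_dofs
        for k in range(d):
            contrib = np.einsum("eq,eq,qi->ei", wq, fvals[:, :, k], phi2)
            np.add.at(load[k], e2.ravel(), contrib.ravel())
        F = self.rhs(g=g, r=r)
        body = (load.ravel()) * self._keep
        F[: d * n2] += body
        return F

    # -- solves -----------------------------------------------------------
    def solve_full(self, F: np.ndarray) -> np.ndarray:
        return self.lu.solve(F)

    def solve_adjoint_full(self, W: np.ndarray) -> np.ndarray:
        return self.lu.solve(W, trans="T")

    def split(self, X: np.ndarray):
        d, n2, n1 = self.d, self.n2, self.n1
        U = X[: d * n2].reshape(d, n2)
        P = X[d * n2 : d * n2 + n1]
        lam = float(X[-1])
        return U, P, lam


def _as_dofs(x, shape, space, kind):
    """Accept a field object, an array, a callable, or None (zeros)."""
    if x is None:
        return np.zeros(shape)
    if isinstance(x, (VelocityField, ForceField, BoundaryVelocity, DivergenceSource, PressureField)):
        return np.asarray(x.dofs, dtype=float)
    if callable(x):
        if kind == "f":
            return np.asarray([x(space.mesh.nodes)[..., k] for k in range(shape[0])])
        if kind == "g":
            pts = space.coords[space.boundary_dofs]
            vals = np.asarray(x(pts))
            return vals.T if vals.shape == (shape[1], shape[0]) else vals
        if kind == "r":
            return np.asarray(x(space.mesh.nodes)).ravel()
    arr = np.asarray(x, dtype=float)
    if arr.shape != shape:
        arr = np.broadcast_to(arr.reshape(-1, *([1] * (len(shape) - 1))), shape).copy()
    return arr


def solve_stokes(
    mesh: FEMesh,
    mu: float = 1.0,
    f=None,
    g=None,
    r=None,
    compatibility_mode: str = "project",
    system: StokesSystem | None = None,
):
    """Solve the Stokes system for velocity and (zero-mean) pressure.

    ``f`` may be a ``ForceField``, a ``(d, n_vertices)`` array, or a callable
    of physical points (then integrated exactly at quadrature level); ``g`` a
    ``BoundaryVelocity``/array/callable on Γ; ``r`` a vertex array or callable
    (2D only).

    In 3D (or with ``r`` absent) the boundary data must satisfy
    ∮Γ g·n dΓ = 0: ``strict`` raises :class:`CompatibilityError`, ``project``
    removes a constant normal flux.
    """
    sys_ = system or StokesSystem(mesh, mu)
    spc = sys_.space
    d = sys_.d
    if r is not None and d == 3:
        raise ValueError("divergence source r is a 2D-only concept")
    gd = _as_dofs(g, (d, spc.n_boundary), spc, "g")
    rd = _as_dofs(r, (sys_.n1,), spc, "r") if r is not None else None

    flux = float(spc.boundary_flux_form() @ gd.ravel())
    target = float(spc.p1_integral @ rd) if rd is not None else 0.0
    scale = max(np.abs(gd).max(initial=0.0) * spc.boundary_measure(), 1e-300)
    if r is None and abs(flux - target) > 1e-8 * scale:
        if compatibility_mode == "strict":
            raise CompatibilityError(
                f"∮g·n = {flux:.3e} violates the incompressibility condition"
            )
        normals = spc.facet_normals_at_dofs
        flux_of_normals = float(spc.boundary_flux_form() @ normals.T.ravel())
        gd = gd - (flux - target) / flux_of_normals * normals.T

    if callable(f):
        F = sys_.rhs_from_callable(f, g=gd, r=rd)
    else:
        fd = _as_dofs(f, (d, sys_.n1), spc, "f")
        F = sys_.rhs(f=fd, g=gd, r=rd)
    U, P, lam = sys_.split(sys_.solve_full(F))
    return VelocityField(spc, U), PressureField(spc, P)


def solve_adjoint(mesh: FEMesh, mu: float, data_misfit_source: np.ndarray,
                  system: StokesSystem | None = None):
    """Adjoint Stokes solve with homogeneous Dirichlet boundary.

    ``data_misfit_source`` is the assembled linear functional over velocity
    dofs (shape ``(d, n_p2)`` or flat). Returns adjoint velocity and pressure
    fields; used by the reduced-gradient computation.
    """
    sys_ = system or StokesSystem(mesh, mu)
    W = np.zeros(sys_.N)
    W[: sys_.d * sys_.n2] = np.asarray(data_misfit_source).ravel()
    lam = sys_.solve_adjoint_full(W)
    U, P, _ = sys_.split(lam)
    return VelocityField(sys_.space, U), PressureField(sys_.space, P)


def residuals(mesh: FEMesh, mu: float, u, p, f=None, g=None, r=None,
              system: StokesSystem | None = None):
    """Relative weak-form residual norms (momentum, continuity, boundary).

    All three are below :data:`SOLVER_TOL` for any output of
    :func:`solve_stokes` with the multiplier folded in.
    """
    sys_ = system or StokesSystem(mesh, mu)
    spc = sys_.space
    d, n2, n1 = sys_.d, sys_.n2, sys_.n1
    ud = _as_dofs(u, (d, n2), spc, "u").ravel()
    pd = _as_dofs(p, (n1,), spc, "p")
    fd = _as_dofs(f, (d, n1), spc, "f").ravel()
    gd = _as_dofs(g, (d, spc.n_boundary), spc, "g").ravel()
    rd = _as_dofs(r, (n1,), spc, "r") if r is not None else np.zeros(n1)

    def _mag(op, vec):
        # no-cancellation magnitude |op| @ |vec| as a relative scale
        return np.linalg.norm(abs(op) @ np.abs(vec))

    mom = (sys_.A @ ud - sys_.B.T @ pd - sys_.Mf @ fd) * sys_._keep
    mscale = max(_mag(sys_.A, ud), _mag(sys_.B.T, pd), _mag(sys_.Mf, fd))
    mom_norm = np.linalg.norm(mom) / mscale if mscale > 0 else 0.0

    cont = sys_.B @ ud - sys_.Mp @ rd
    cscale = max(_mag(sys_.B, ud), _mag(sys_.Mp, rd))
    cont_norm = np.linalg.norm(cont) / cscale if cscale > 0 else 0.0

    ub = ud.reshape(d, n2)[:, spc.boundary_dofs].ravel()
    bscale = max(np.linalg.norm(gd), np.linalg.norm(ub))
    bnd_norm = np.linalg.norm(ub - gd) / bscale if bscale > 0 else 0.0
    return float(mom_norm), float(cont_norm), float(bnd_norm)


def l2_error(space: P2Space, dofs: np.ndarray, exact, kind: str = "p2"):
    """L2 norm of (discrete field − exact callable) over Ω.

    ``kind``: ``p2`` for quadratic (vector or scalar) dofs, ``p1`` for vertex
    scalars. ``exact`` maps ``(n, d)`` points to values.
    """
    xq, wq, phi2, _, phi1, _ = space.quad()
    pts = xq.reshape(-1, space.dim)
    exq = np.asarray(exact(pts))
    dofs = np.atleast_2d(dofs)
    ncomp = dofs.shape[0]
    exq = exq.reshape(xq.shape[0], xq.shape[1], -1)
    err2 = 0.0
    for k in range(ncomp):
        if kind == "p2":
            uh = np.einsum("qi,ei->eq", phi2, dofs[k][space.element_dofs])
        else:
            uh = np.einsum("qi,ei->eq", phi1, dofs[k][space.mesh.simplices])
        err2 += float((wq * (uh - exq[:, :, k]) ** 2).sum())
    return np.sqrt(err2)
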