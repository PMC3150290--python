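"""Stabilized advection-diffusion-reaction transport of oxygen and lactate.

Solves the tissue-averaged continuity equation for each solute on the NP+AF
subdomain with quadratic elements and implicit Euler stepping:

    dc/dt + v . grad c = div( D(phi) grad c ) + R

Diffusivity follows Mackie-Meares from the current porosity (or the initial
one when the strain coupling is off); the advective velocity is the Darcy
flux handed over by the poromechanical solver; streamline-diffusion (SUPG
type) stabilization controls advective oscillations; a Courant check guards
the explicit geometry/velocity exchange.  On a deforming mesh the previous
mass matrix multiplies the previous concentration, which conserves solute
content exactly under compaction with closed boundaries (the squeezed tissue
concentrates its solutes; drainage advects them out through the advection
term).

Boundary conditions are Dirichlet: fixed solute values on the outer annulus
edge and on the cartilage-endplate interface across the full disc
footprint.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from . import fem
from .constitutive import mackie_meares_diffusivity
from .geometry import DiscMesh
from .parameters import ParameterSet
from .poromechanics import PoroState
from .units import SECONDS_PER_HOUR


@dataclass
class SoluteSpec:
    """One solute: units, free-water diffusivity and boundary data."""

    name: str                       # "oxygen" | "lactate"
    unit: str                       # "kPa" | "nmol mm^-3"
    d_water: float                  # mm^2 s^-1
    bc_af: float                    # value at the outer AF edge
    bc_cep: float                   # value at the CEP interface
    initial: float = 0.0            # initial value in the disc

    def __post_init__(self) -> None:
        if self.d_water <= 0:
            raise ValueError("free-water diffusivity must be positive")
        if self.bc_af < 0 or self.bc_cep < 0:
            raise ValueError("boundary values must be non-negative")

    @classmethod
    def oxygen(cls, params: ParameterSet) -> "SoluteSpec":
        return cls("oxygen", "kPa", params.d_water_oxygen,
                   params.oxygen_bc_af, params.oxygen_bc_cep)

    @classmethod
    def lactate(cls, params: ParameterSet) -> "SoluteSpec":
        return cls("lactate", "nmol mm^-3", params.d_water_lactate,
                   params.lactate_bc_af, params.lactate_bc_cep)


@dataclass
class SoluteState:
    """Nodal concentration field on the transport subdomain."""

    c: np.ndarray                   # local nodal values (transport nodes)
    time: float                     # s
    couplings: dict = field(default_factory=dict)


def courant_check(velocity, dt: float, mesh: DiscMesh,
                  elements: Optional[np.ndarray] = None) -> float:
    """Max element Courant number C = |v| dt / h (caller enforces C <= 1)."""
    h = mesh.element_sizes()
    v = np.asarray(velocity, dtype=float)
    speed = np.abs(v) if v.ndim == 1 else np.linalg.norm(v, axis=1)
    if elements is not None:
        h, speed = h[elements], speed[elements]
    if speed.size == 0:
        return 0.0
    return float((speed * dt / h).max())


def steady_state_time(times_h: Sequence[float], probe_values: np.ndarray,
                      tolerance: float = 0.005) -> Optional[float]:
    """First time (hours) after which the relative probe change per hour
    stays below ``tolerance`` for the rest of the history; None if never."""
    t = np.asarray(times_h, dtype=float)
    c = np.atleast_2d(np.asarray(probe_values, dtype=float).T).T  # (nt, np)
    if len(t) < 2:
        return 0.0
    dt = np.diff(t)
    scale = np.maximum(np.abs(c[1:]), 1e-12)
    rate = np.abs(np.diff(c, axis=0)) / scale / dt[:, None]
    ok = (rate < tolerance).all(axis=1)
    # earliest index from which all later intervals are quiescent
    idx = len(ok)
    for i in range(len(ok) - 1, -1, -1):
        if ok[i]:
            idx = i
        else:
            break
    if idx == len(ok):
        return None
    return float(t[idx])


class TransportSolver:
    """ADR solver bound to the NP+AF subdomain of a disc (or column) mesh."""

    def __init__(self, mesh: DiscMesh, params: ParameterSet,
                 spec: SoluteSpec):
        self.mesh = mesh
        self.params = params
        self.spec = spec
        self._axisym = mesh.kind == "axisym"
        self.elements = mesh.disc_elements()
        self.econn = mesh.elems_p2[self.elements]
        self.region = mesh.region[self.elements]
        self.tnodes = np.unique(self.econn)
        self.nn = len(self.tnodes)
        gmap = -np.ones(mesh.n_nodes, dtype=int)
        gmap[self.tnodes] = np.arange(self.nn)
        self.gmap = gmap
        self.lconn = gmap[self.econn]
        nb = self.lconn.shape[1]
        self._rows = np.repeat(self.lconn, nb, axis=1).ravel()
        self._cols = np.tile(self.lconn, (1, nb)).ravel()

        self.phi0_elem = np.array(
            [params.regions[r].phi0 for r in self.region])
        self.rho_elem = np.array(
            [params.regions[r].rho_cell for r in self.region])
        # nodal cell density / phi0 (simple average over adjacent elements)
        self.rho_node = self._node_average(self.rho_elem)
        self.phi0_node = self._node_average(self.phi0_elem)

        if self._axisym:
            self.qp, self.qw = fem.TRI_QP, fem.TRI_QW
            self.N, self.dNref = fem.tri_p2_shape(self.qp)
        else:
            self.qp, self.qw = fem.LINE_QP, fem.LINE_QW
            self.N, self.dNref = fem.line_p2_shape(self.qp)

        self._setup_dirichlet()
        self.set_geometry(mesh.nodes)

    # ---- helpers -------------------------------------------------------
    def _node_average(self, elem_values: np.ndarray) -> np.ndarray:
        num = np.zeros(self.nn)
        den = np.zeros(self.nn)
        np.add.at(num, self.lconn.ravel(),
                  np.repeat(elem_values, self.lconn.shape[1]))
        np.add.at(den, self.lconn.ravel(), 1.0)
        return num / den

    def _setup_dirichlet(self) -> None:
        mesh = self.mesh
        if self._axisym:
            af_nodes = np.unique(mesh.facets["disc_lateral"])
            cep = [mesh.facets["cep_interface"]]
            if len(mesh.facets.get("cep_interface_outer", ())):
                cep.append(mesh.facets["cep_interface_outer"])
            cep_nodes = np.setdiff1d(np.unique(np.vstack(cep)), af_nodes)
        else:
            af_nodes = np.unique(mesh.facets["top"])
            cep_nodes = np.unique(mesh.facets["bottom"])
        af = self.gmap[af_nodes]
        cep = self.gmap[cep_nodes]
        af = af[af >= 0]
        cep = cep[cep >= 0]
        self.dirichlet = np.concatenate([af, cep])
        self.dirichlet_values = np.concatenate(
            [np.full(len(af), self.spec.bc_af),
             np.full(len(cep), self.spec.bc_cep)])

    # ---- geometry-dependent assembly -----------------------------------
    def set_geometry(self, coords_global: np.ndarray,
                     phi_elem: Optional[np.ndarray] = None,
                     velocity_elem: Optional[np.ndarray] = None) -> None:
        """(Re)assemble mass/stiffness for the current configuration.

        ``coords_global`` are coordinates of ALL mesh nodes (deformed or
        reference); ``phi_elem`` per-subdomain-element porosity for the
        strain-dependent diffusivity (defaults to phi0); ``velocity_elem``
        the per-element Darcy flux (defaults to zero: diffusion only).
        """
        phi = self.phi0_elem if phi_elem is None else phi_elem
        D = mackie_meares_diffusivity(phi, self.spec.d_water)
        ne, nb = self.lconn.shape
        K = np.zeros((ne, nb, nb))
        Ml = np.zeros(self.nn)

        if self._axisym:
            tri_local = self.mesh.elems_p1[self.elements]
            _, detJ, invJ = fem.tri_geometry(coords_global, tri_local)
            ecoords_r = coords_global[self.econn, 0]
            if velocity_elem is None:
                v = np.zeros((ne, 2))
            else:
                v = np.asarray(velocity_elem)
            speed = np.linalg.norm(v, axis=1)
            h = np.sqrt(2.0 * detJ)
            tau = self._supg_tau(speed, h, D)
            m_diag = np.zeros((ne, nb))
            vol = np.zeros(ne)
            for q in range(len(self.qw)):
                dNdX = np.einsum("im,emk->eik", self.dNref[q], invJ)
                r_q = ecoords_r @ self.N[q]
                wd = self.qw[q] * detJ * r_q
                K += wd[:, None, None] * (
                    D[:, None, None]
                    * np.einsum("eik,ejk->eij", dNdX, dNdX))
                vdN = np.einsum("ek,ejk->ej", v, dNdX)
                K += wd[:, None, None] * (
                    np.einsum("i,ej->eij", self.N[q], vdN)
                    + tau[:, None, None]
                    * np.einsum("ei,ej->eij", vdN, vdN))
                m_diag += wd[:, None] * self.N[q][None, :] ** 2
                vol += wd
        else:
            z = coords_global[:, 0] if coords_global.ndim > 1 \
                else coords_global
            h_el = z[self.econn[:, 1]] - z[self.econn[:, 0]]
            detJ = h_el
            if velocity_elem is None:
                v = np.zeros(ne)
            else:
                v = np.asarray(velocity_elem)
            tau = self._supg_tau(np.abs(v), np.abs(h_el), D)
            m_diag = np.zeros((ne, nb))
            vol = np.zeros(ne)
            for q in range(len(self.qw)):
                dNdX = self.dNref[q][None, :] / detJ[:, None]
                wd = self.qw[q] * detJ
                K += wd[:, None, None] * (
                    D[:, None, None] * np.einsum("ei,ej->eij", dNdX, dNdX))
                vdN = v[:, None] * dNdX
                K += wd[:, None, None] * (
                    np.einsum("i,ej->eij", self.N[q], vdN)
                    + tau[:, None, None] * np.einsum("ei,ej->eij",
                                                     vdN, vdN))
                m_diag += wd[:, None] * self.N[q][None, :] ** 2
                vol += wd

        # HRZ lumping: scale diagonal so each element conserves its mass
        scale = vol / m_diag.sum(axis=1)
        np.add.at(Ml, self.lconn.ravel(), (m_diag * scale[:, None]).ravel())
        self.M_prev = getattr(self, "M_lump", Ml)
        self.M_lump = Ml
        self.K = sp.coo_matrix((K.ravel(), (self._rows, self._cols)),
                               shape=(self.nn, self.nn)).tocsr()

    @staticmethod
    def _supg_tau(speed, h, D):
        pe = speed * h / (2.0 * np.maximum(D, 1e-30))
        pe_safe = np.clip(pe, 1e-6, 50.0)
        xi = np.where(pe > 1e-6,
                      1.0 / np.tanh(pe_safe) - 1.0 / pe_safe, 0.0)
        return np.where(speed > 0,
                        h / (2.0 * np.maximum(speed, 1e-30)) * xi, 0.0)

    # ---- stepping ------------------------------------------------------
    def initial_state(self) -> SoluteState:
        c = np.full(self.nn, self.spec.initial, dtype=float)
        c[self.dirichlet] = self.dirichlet_values
        return SoluteState(c=c, time=0.0)

    def step(self, state: SoluteState, dt: float,
             source: Optional[np.ndarray] = None,
             sink_coeff: Optional[np.ndarray] = None,
             use_prev_mass: bool = False) -> SoluteState:
        """One implicit Euler step.

        ``source`` is a nodal production rate (units/s, >= 0); ``sink_coeff``
        a nodal linearised consumption coefficient (1/s) applied implicitly.
        ``use_prev_mass`` multiplies the old concentration by the mass matrix
        of the previous geometry (conservative deforming-mesh transport).
        """
        if dt <= 0:
            raise ValueError("dt must be positive")
        A = (sp.diags(self.M_lump / dt) + self.K)
        if sink_coeff is not None:
            A = A + sp.diags(self.M_lump * sink_coeff)
        M_old = self.M_prev if use_prev_mass else self.M_lump
        b = M_old / dt * state.c
        if source is not None:
            b = b + self.M_lump * source
        A = A.tolil()
        A[self.dirichlet, :] = 0.0
        A[self.dirichlet, self.dirichlet] = 1.0
        b[self.dirichlet] = self.dirichlet_values
        c_new = spla.spsolve(A.tocsr(), b)
        # quadratic interpolation produces Gibbs undershoots of a few % of
        # the boundary jump while the initial sharp layer diffuses away;
        # tolerate 10% of the boundary scale, clip, and fail beyond that
        tol = 0.1 * max(self.spec.bc_af, self.spec.bc_cep, 1.0)
        if np.any(c_new < -tol):
            raise RuntimeError(
                f"negative {self.spec.name} concentration beyond tolerance "
                f"({c_new.min():.3e})")
        np.clip(c_new, 0.0, None, out=c_new)
        return SoluteState(c=c_new, time=state.time + dt,
                           couplings=dict(state.couplings))

    # ---- field access --------------------------------------------------
    def probe_value(self, state: SoluteState, probe: str) -> float:
        gid = self.mesh.probes[probe]
        return float(state.c[self.gmap[gid]])

    def field_on_mesh(self, state: SoluteState) -> np.ndarray:
        """Concentration on all mesh nodes (NaN outside the subdomain)."""
        out = np.full(self.mesh.n_nodes, np.nan)
        out[self.tnodes] = state.c
        return out

    def total_content(self, state: SoluteState) -> float:
        return float((self.M_lump * state.c).sum())


def advance_solute(solver: TransportSolver, state: SoluteState, dt: float,
                   poro: Optional[PoroState] = None,
                   reaction: Optional[np.ndarray] = None,
                   strain_diffusivity: bool = True,
                   advection: bool = True,
                   deform_geometry: bool = True,
                   max_courant: float = 1.0) -> SoluteState:
    """Single coupled ADR step driven by an optional poromechanical state.

    ``reaction`` is a nodal source rate per HOUR (negative = consumption),
    applied explicitly.  Raises on Courant violation.
    """
    mesh = solver.mesh
    if poro is not None:
        disp = poro.displacement
        coords = (mesh.nodes + disp if deform_geometry
                  else mesh.nodes.copy())
        phi = (poro.phi_qp.mean(axis=1)[solver.elements]
               if strain_diffusivity else None)
        vel = (poro.velocity[solver.elements] if advection else None)
    else:
        coords, phi, vel = mesh.nodes, None, None
    if vel is not None:
        C = courant_check(poro.velocity, dt, mesh, solver.elements)
        if C > max_courant:
            raise RuntimeError(
                f"Courant violation: max local C = {C:.2f} > "
                f"{max_courant:g}")
    solver.set_geometry(coords, phi_elem=phi, velocity_elem=vel)
    source = None
    if reaction is not None:
        source = np.asarray(reaction, dtype=float) / SECONDS_PER_HOUR
    new = solver.step(state, dt, source=source,
                      use_prev_mass=poro is not None and deform_geometry)
    new.couplings = {"deform_geometry": deform_geometry and poro is not None,
                     "strain_diffusivity": strain_diffusivity
                     and poro is not None,
                     "advection": advection and poro is not None}
    return new
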