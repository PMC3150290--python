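"""Parametric disc and benchmark-column meshes.

The disc is meshed as an axisymmetric (r, z) section of an equivalent-area
cylinder: the in-plane 50 x 35 mm ellipse is represented by a circle of equal
area, which preserves the order of magnitude of the diffusion distances --
the quantity that controls nutrient transport in this tissue.  The section
stacks, bottom to top: vertebral bone, bony endplate (BEP), cartilage
endplate (CEP), disc (NP + inner/outer annulus), CEP, BEP, bone.  Vertebral
bone is trabecular with a cortical rim at the outer radius.

Displacement and solute fields use 6-node quadratic (P2) triangles; pore
pressure uses the 3-node linear (P1) vertices of the same triangles
(Taylor-Hood pairing).  The 1D column mesh uses quadratic line elements and
serves the consolidation and reaction-diffusion benchmarks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .parameters import DISC_REGIONS, HEALTHY_HEIGHT


@dataclass
class DiscGeometrySpec:
    """Parametric description of the disc geometry (lengths in mm)."""

    height: float = HEALTHY_HEIGHT      # disc (NP+AF) height
    lateral_width: float = 50.0         # in-plane lateral diameter
    ap_depth: float = 35.0              # in-plane anteroposterior diameter
    np_area_fraction: float = 0.4       # NP share of the in-plane area
    inner_af_split: float = 0.5         # inner-AF share of annulus thickness
    cep_thickness: float = 0.8
    bep_thickness: float = 0.6
    bone_thickness: float = 4.0         # vertebral bone block per side
    cortical_thickness: float = 1.5     # cortical rim width
    endplate_layer: float = 0.1         # thinnest disc layer at the CEP
                                        # (~ drainage depth of a 60 s ramp)
    resolution: int = 1                 # mesh refinement level (>= 1)

    def __post_init__(self) -> None:
        if self.height <= 0:
            raise ValueError("height must be positive")
        for name in ("np_area_fraction", "inner_af_split"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must lie in (0,1), got {v}")
        for name in ("lateral_width", "ap_depth", "cep_thickness",
                     "bep_thickness", "bone_thickness", "cortical_thickness"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.resolution < 1:
            raise ValueError("resolution level must be >= 1")

    def to_yaml(self, path=None) -> str:
        import yaml
        from dataclasses import asdict
        text = yaml.safe_dump(asdict(self), sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_yaml(cls, source) -> "DiscGeometrySpec":
        import yaml
        try:
            with open(source) as fh:
                data = yaml.safe_load(fh)
        except (OSError, TypeError):
            data = yaml.safe_load(source)
        return cls(**data)

    @property
    def outer_radius(self) -> float:
        """Equivalent-area radius of the in-plane ellipse."""
        return float(np.sqrt(self.lateral_width * self.ap_depth) / 2.0)

    @property
    def np_radius(self) -> float:
        return self.outer_radius * float(np.sqrt(self.np_area_fraction))

    @property
    def afi_outer_radius(self) -> float:
        r_np, r_out = self.np_radius, self.outer_radius
        return r_np + self.inner_af_split * (r_out - r_np)


@dataclass
class DiscMesh:
    """Labeled quadratic mesh (axisymmetric section or 1D column).

    ``nodes`` holds (r, z) coordinates [or (z,) for a column] of all P2
    nodes; ``elems_p2`` the 6-node [3-node] connectivity
    (v0, v1, v2, m01, m12, m20) [(v0, v1, m)]; ``elems_p1`` the vertex
    connectivity.  ``facets[tag]`` lists boundary/interface edges as
    (v0, v1, mid) node triples.  ``probes`` maps probe names to node ids.
    """

    kind: str                       # "axisym" | "column"
    nodes: np.ndarray
    elems_p2: np.ndarray
    elems_p1: np.ndarray
    region: np.ndarray              # per-element region label (object array)
    facets: dict[str, np.ndarray]
    probes: dict[str, int]
    vertex_ids: np.ndarray          # node ids that carry a P1 (pressure) dof
    spec: Optional[DiscGeometrySpec] = None
    disc_z: Optional[tuple[float, float]] = None  # z-range of the NP+AF band

    # ---- derived quantities -------------------------------------------
    @property
    def n_nodes(self) -> int:
        return self.nodes.shape[0]

    @property
    def n_elements(self) -> int:
        return self.elems_p2.shape[0]

    def element_measures(self, coords: Optional[np.ndarray] = None
                         ) -> np.ndarray:
        """Element volumes (axisym, 2*pi*r_c*A) or lengths (column)."""
        x = self.nodes if coords is None else coords
        if self.kind == "column":
            tri = self.elems_p2
            return np.abs(x[tri[:, 1]] - x[tri[:, 0]]).ravel()
        v = self.elems_p1
        p0, p1, p2 = x[v[:, 0]], x[v[:, 1]], x[v[:, 2]]
        area = 0.5 * np.abs(
            (p1[:, 0] - p0[:, 0]) * (p2[:, 1] - p0[:, 1])
            - (p2[:, 0] - p0[:, 0]) * (p1[:, 1] - p0[:, 1]))
        r_c = (p0[:, 0] + p1[:, 0] + p2[:, 0]) / 3.0
        return 2.0 * np.pi * r_c * area

    def region_volumes(self) -> dict[str, float]:
        vols = self.element_measures()
        out: dict[str, float] = {}
        for label in np.unique(self.region):
            out[str(label)] = float(vols[self.region == label].sum())
        return out

    def element_sizes(self) -> np.ndarray:
        """Characteristic element length h (for Courant checks)."""
        if self.kind == "column":
            return self.element_measures()
        v = self.elems_p1
        x = self.nodes
        e01 = np.linalg.norm(x[v[:, 1]] - x[v[:, 0]], axis=1)
        e12 = np.linalg.norm(x[v[:, 2]] - x[v[:, 1]], axis=1)
        e20 = np.linalg.norm(x[v[:, 0]] - x[v[:, 2]], axis=1)
        return np.minimum(np.minimum(e01, e12), e20)

    def disc_elements(self) -> np.ndarray:
        """Indices of NP+AF elements (the transport domain)."""
        return np.flatnonzero(np.isin(self.region, DISC_REGIONS))

    def disc_height(self, displacement: Optional[np.ndarray] = None) -> float:
        """Axial extent of the NP+AF region (optionally deformed)."""
        idx = self.disc_elements()
        node_ids = np.unique(self.elems_p2[idx])
        if self.kind == "column":
            z = self.nodes[node_ids, 0] if self.nodes.ndim > 1 \
                else self.nodes[node_ids]
            if displacement is not None:
                z = z + displacement[node_ids]
        else:
            z = self.nodes[node_ids, 1]
            if displacement is not None:
                z = z + displacement[node_ids, 1]
        return float(z.max() - z.min())


def _graded_band(z0: float, z1: float, n: int, edge: float) -> np.ndarray:
    """Symmetric axial grading of the disc band: the layer adjacent to each
    endplate has thickness ~``edge`` (resolving the drainage boundary
    layer), growing geometrically towards mid-height."""
    H = z1 - z0
    half_n = n // 2
    if half_n < 2 or edge * half_n >= H / 2 or edge <= 0:
        return np.linspace(z0, z1, n + 1)

    def total(g: float) -> float:
        return edge * (g ** half_n - 1.0) / (g - 1.0)

    lo, hi = 1.0 + 1e-9, 50.0
    for _ in range(80):                      # bisection for the growth rate
        mid = 0.5 * (lo + hi)
        if total(mid) < H / 2:
            lo = mid
        else:
            hi = mid
    g = 0.5 * (lo + hi)
    t = edge * g ** np.arange(half_n)
    t *= (H / 2) / t.sum()
    lower = z0 + np.concatenate([[0.0], np.cumsum(t)])
    upper = z1 - np.concatenate([[0.0], np.cumsum(t)])[::-1]
    if n % 2:                                # odd: split the central layer
        mid_pts = np.array([0.5 * (lower[-1] + upper[0])])
        return np.concatenate([lower[:-1], mid_pts, upper])
    return np.concatenate([lower[:-1], upper])


def _p2_grid(r_lines: np.ndarray, z_lines: np.ndarray):
    """Structured triangulation with P2 midside nodes."""
    nr, nz = len(r_lines) - 1, len(z_lines) - 1
    vid = np.arange((nr + 1) * (nz + 1)).reshape(nr + 1, nz + 1)
    verts = np.array([[r_lines[i], z_lines[j]]
                      for i in range(nr + 1) for j in range(nz + 1)])
    tris = []
    for i in range(nr):
        for j in range(nz):
            a, b = vid[i, j], vid[i + 1, j]
            c, d = vid[i + 1, j + 1], vid[i, j + 1]
            tris.append((a, b, c))
            tris.append((a, c, d))
    tris = np.array(tris, dtype=int)

    nodes = [tuple(p) for p in verts]
    mid_of: dict[tuple[int, int], int] = {}

    def midpoint(a: int, b: int) -> int:
        key = (a, b) if a < b else (b, a)
        if key not in mid_of:
            mid_of[key] = len(nodes)
            nodes.append(tuple((verts[a] + verts[b]) / 2.0))
        return mid_of[key]

    elems = []
    for (a, b, c) in tris:
        elems.append((a, b, c, midpoint(a, b), midpoint(b, c),
                      midpoint(c, a)))
    return (np.array(nodes), np.array(elems, dtype=int), tris, vid,
            midpoint)


def build_disc_mesh(spec: DiscGeometrySpec) -> DiscMesh:
    """Generate the labeled axisymmetric disc mesh from a geometry spec."""
    res = spec.resolution
    r_np, r_afi = spec.np_radius, spec.afi_outer_radius
    r_out = spec.outer_radius
    r_cort = r_out - spec.cortical_thickness
    if not r_afi < r_cort < r_out:
        raise ValueError(
            "resolution/geometry cannot resolve region 'AFO': cortical rim "
            f"radius {r_cort:.2f} must lie inside the outer annulus "
            f"({r_afi:.2f}, {r_out:.2f})")

    def lin(a: float, b: float, n: int) -> np.ndarray:
        return np.linspace(a, b, n + 1)

    nr_np, nr_afi, nr_afo = 2 + res, res, res
    r_lines = np.concatenate([
        lin(0.0, r_np, nr_np)[:-1],
        lin(r_np, r_afi, nr_afi)[:-1],
        lin(r_afi, r_cort, nr_afo)[:-1],
        lin(r_cort, r_out, 1),
    ])

    nz_disc = 4 + 2 * res
    nz_cep = max(1, res - 1)
    nz_bone = max(1, res - 1)
    tb, tbep, tcep = spec.bone_thickness, spec.bep_thickness, \
        spec.cep_thickness
    z0_disc = tb + tbep + tcep
    z1_disc = z0_disc + spec.height
    z_top = z1_disc + tcep + tbep + tb
    z_lines = np.concatenate([
        lin(0.0, tb, nz_bone)[:-1],
        lin(tb, tb + tbep, 1)[:-1],
        lin(tb + tbep, z0_disc, nz_cep)[:-1],
        _graded_band(z0_disc, z1_disc, nz_disc, spec.endplate_layer)[:-1],
        lin(z1_disc, z1_disc + tcep, nz_cep)[:-1],
        lin(z1_disc + tcep, z1_disc + tcep + tbep, 1)[:-1],
        lin(z1_disc + tcep + tbep, z_top, nz_bone),
    ])

    nodes, elems, tris, vid, midpoint = _p2_grid(r_lines, z_lines)

    # region labels from element centroids
    cent = nodes[tris].mean(axis=1)
    region = np.empty(len(tris), dtype=object)
    eps = 1e-9
    for e, (rc, zc) in enumerate(cent):
        if z0_disc - eps <= zc <= z1_disc + eps:
            if rc < r_np:
                region[e] = "NP"
            elif rc < r_afi:
                region[e] = "AFI"
            else:
                region[e] = "AFO"
        elif (tb + tbep - eps <= zc <= z0_disc + eps or
              z1_disc - eps <= zc <= z1_disc + tcep + eps):
            region[e] = "CEP"
        elif (tb - eps <= zc <= tb + tbep + eps or
              z1_disc + tcep - eps <= zc <= z1_disc + tcep + tbep + eps):
            region[e] = "BEP"
        else:
            region[e] = "cortical" if rc > r_cort else "trabecular"

    # facet tags (edges as (v0, v1, mid))
    nr, nz = len(r_lines) - 1, len(z_lines) - 1

    def h_edges(j: int, rmax: float = np.inf) -> np.ndarray:
        rows = []
        for i in range(nr):
            if 0.5 * (r_lines[i] + r_lines[i + 1]) <= rmax:
                a, b = int(vid[i, j]), int(vid[i + 1, j])
                rows.append((a, b, midpoint(a, b)))
        return np.array(rows, dtype=int)

    def v_edges(i: int, z_lo: float = -np.inf,
                z_hi: float = np.inf) -> np.ndarray:
        rows = []
        for j in range(nz):
            zc = 0.5 * (z_lines[j] + z_lines[j + 1])
            if z_lo - eps <= zc <= z_hi + eps:
                a, b = int(vid[i, j]), int(vid[i, j + 1])
                rows.append((a, b, midpoint(a, b)))
        return np.array(rows, dtype=int)

    j_disc0 = int(np.argmin(np.abs(z_lines - z0_disc)))
    j_disc1 = int(np.argmin(np.abs(z_lines - z1_disc)))
    facets = {
        "top": h_edges(nz),
        "bottom": h_edges(0),
        "lateral": v_edges(nr),
        "disc_lateral": v_edges(nr, z0_disc, z1_disc),
        "cep_interface": np.vstack([h_edges(j_disc0, rmax=r_afi),
                                    h_edges(j_disc1, rmax=r_afi)]),
    }
    # outer-annulus part of the endplate interface (the cartilage layer
    # spans the full disc footprint; kept as a separate tag so the
    # NP+inner-annulus subset remains addressable)
    inner = {tuple(sorted(e[:2])) for e in facets["cep_interface"]}
    outer = []
    for j in (j_disc0, j_disc1):
        for e in h_edges(j):
            if tuple(sorted(e[:2])) not in inner:
                outer.append(e)
    facets["cep_interface_outer"] = (np.array(outer, dtype=int)
                                     if outer else
                                     np.empty((0, 3), dtype=int))

    z_mid = 0.5 * (z0_disc + z1_disc)
    probes = {
        "NP": int(np.argmin(np.hypot(nodes[:, 0] - 0.0,
                                     nodes[:, 1] - z_mid))),
        "AFO": int(np.argmin(np.hypot(nodes[:, 0] - 0.5 * (r_afi + r_out),
                                      nodes[:, 1] - z_mid))),
    }

    mesh = DiscMesh(kind="axisym", nodes=nodes, elems_p2=elems,
                    elems_p1=tris, region=region, facets=facets,
                    probes=probes, vertex_ids=np.unique(tris),
                    spec=spec, disc_z=(z0_disc, z1_disc))
    # sanity: probes must sit in their named regions at mid-height
    for name, want in (("NP", "NP"), ("AFO", "AFO")):
        owner = np.flatnonzero((elems == probes[name]).any(axis=1))
        if not (region[owner] == want).any():
            raise RuntimeError(
                f"resolution too coarse to resolve region '{want}' "
                "(probe fell outside it)")
    return mesh


def build_column_mesh(height: float, n_elements: int,
                      region: str = "NP") -> DiscMesh:
    """1D consolidation/transport benchmark column (drained top, fixed
    impermeable bottom), quadratic elements."""
    if n_elements < 2:
        raise ValueError("n_elements must be >= 2")
    if height <= 0:
        raise ValueError("height must be positive")
    nv = n_elements + 1
    z_v = np.linspace(0.0, height, nv)
    nodes = [float(z) for z in z_v]
    elems = []
    for e in range(n_elements):
        mid = len(nodes)
        nodes.append(0.5 * (z_v[e] + z_v[e + 1]))
        elems.append((e, e + 1, mid))
    nodes = np.array(nodes)[:, None]
    elems = np.array(elems, dtype=int)
    facets = {
        "top": np.array([[nv - 1]], dtype=int),
        "bottom": np.array([[0]], dtype=int),
    }
    probes = {"center": int(np.argmin(np.abs(nodes[:, 0] - height / 2)))}
    return DiscMesh(kind="column", nodes=nodes, elems_p2=elems,
                    elems_p1=elems[:, :2],
                    region=np.array([region] * n_elements, dtype=object),
                    facets=facets, probes=probes,
                    vertex_ids=np.arange(nv),
                    disc_z=(0.0, height))
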