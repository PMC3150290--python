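"""Small finite-element toolbox: quadrature and P1/P2 bases.

Triangles are affine (straight-sided, midside nodes at edge midpoints), so
the geometric Jacobian is constant per element and all assembly loops
vectorise over elements.
"""

from __future__ import annotations

import numpy as np

# --- 6-point degree-4 triangle rule (weights include the 1/2 area factor) --
_a1, _b1, _w1 = 0.816847572980459, 0.091576213509771, 0.109951743655322
_a2, _b2, _w2 = 0.108103018168070, 0.445948490915965, 0.223381589678011
TRI_QP = np.array([
    [_b1, _b1], [_a1, _b1], [_b1, _a1],
    [_b2, _b2], [_a2, _b2], [_b2, _a2],
])
TRI_QW = 0.5 * np.array([_w1, _w1, _w1, _w2, _w2, _w2])

# --- 3-point Gauss rule on [0, 1] -----------------------------------------
_g = 0.5 * np.sqrt(3.0 / 5.0)
LINE_QP = np.array([0.5 - _g, 0.5, 0.5 + _g])
LINE_QW = np.array([5.0, 8.0, 5.0]) / 18.0


def tri_p2_shape(xi: np.ndarray):
    """P2 shapes and reference gradients at points (nq, 2).

    Node order: vertices v0, v1, v2 then midsides m01, m12, m20.
    Returns (N (nq, 6), dN (nq, 6, 2)).
    """
    x, y = xi[:, 0], xi[:, 1]
    L = np.stack([1.0 - x - y, x, y], axis=1)           # (nq, 3)
    dL = np.array([[-1.0, -1.0], [1.0, 0.0], [0.0, 1.0]])
    N = np.empty((len(xi), 6))
    dN = np.empty((len(xi), 6, 2))
    for v in range(3):
        N[:, v] = L[:, v] * (2.0 * L[:, v] - 1.0)
        dN[:, v, :] = (4.0 * L[:, v] - 1.0)[:, None] * dL[v]
    pairs = [(0, 1), (1, 2), (2, 0)]
    for m, (i, j) in enumerate(pairs):
        N[:, 3 + m] = 4.0 * L[:, i] * L[:, j]
        dN[:, 3 + m, :] = 4.0 * (L[:, i][:, None] * dL[j]
                                 + L[:, j][:, None] * dL[i])
    return N, dN


def tri_p1_shape(xi: np.ndarray):
    x, y = xi[:, 0], xi[:, 1]
    N = np.stack([1.0 - x - y, x, y], axis=1)
    dN = np.broadcast_to(
        np.array([[-1.0, -1.0], [1.0, 0.0], [0.0, 1.0]]),
        (len(xi), 3, 2)).copy()
    return N, dN


def line_p2_shape(t: np.ndarray):
    """P2 shapes on [0,1], node order (end0, end1, mid)."""
    N = np.stack([2.0 * (t - 0.5) * (t - 1.0),
                  2.0 * t * (t - 0.5),
                  4.0 * t * (1.0 - t)], axis=1)
    dN = np.stack([4.0 * t - 3.0, 4.0 * t - 1.0, 4.0 - 8.0 * t], axis=1)
    return N, dN


def line_p1_shape(t: np.ndarray):
    N = np.stack([1.0 - t, t], axis=1)
    dN = np.stack([-np.ones_like(t), np.ones_like(t)], axis=1)
    return N, dN


def tri_geometry(nodes: np.ndarray, tris: np.ndarray):
    """Affine element geometry: Jacobian matrix, determinant, inverse."""
    p0 = nodes[tris[:, 0]]
    Jmat = np.stack([nodes[tris[:, 1]] - p0, nodes[tris[:, 2]] - p0],
                    axis=2)                      # (ne, 2, 2), columns dx/dxi
    detJ = (Jmat[:, 0, 0] * Jmat[:, 1, 1] - Jmat[:, 0, 1] * Jmat[:, 1, 0])
    if np.any(detJ <= 0.0):
        raise ValueError("mesh contains inverted or zero-area triangles")
    inv = np.empty_like(Jmat)
    inv[:, 0, 0] = Jmat[:, 1, 1]
    inv[:, 1, 1] = Jmat[:, 0, 0]
    inv[:, 0, 1] = -Jmat[:, 0, 1]
    inv[:, 1, 0] = -Jmat[:, 1, 0]
    inv /= detJ[:, None, None]
    return Jmat, detJ, inv
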