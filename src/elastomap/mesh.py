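"""Structured triangulations of the unit square.

The reference geometry throughout the package is a "crossed" triangulation:
an ``n x n`` grid of square cells, each split into four triangles by both
diagonals, which meet at an added cell-center node.  For resolution ``n``
this gives ``4*n**2`` elements and ``(n+1)**2 + n**2`` nodes; ``n = 50``
yields the 10,000-element / 5,101-node mesh used for the full-scale
experiments.

Node ordering is deterministic: grid vertices first, row-major from
``(0, 0)`` (x fastest), then cell-center vertices, row-major.  All element
connectivity is 0-based and counterclockwise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["TriMesh", "make_crossed_mesh"]


@dataclass(frozen=True)
class TriMesh:
    """An immutable triangle mesh on the unit square.

    Attributes
    ----------
    nodes : ndarray, shape (n_nodes, 2)
        Vertex coordinates, all inside ``[0, 1]^2``.
    elements : ndarray, shape (n_elements, 3)
        Counterclockwise vertex-index triplets (0-based).
    """

    nodes: np.ndarray
    elements: np.ndarray

    def __post_init__(self):
        nodes = np.asarray(self.nodes, dtype=float)
        elements = np.asarray(self.elements, dtype=np.int64)
        object.__setattr__(self, "nodes", nodes)
        object.__setattr__(self, "elements", elements)
        if nodes.ndim != 2 or nodes.shape[1] != 2:
            raise ValueError("nodes must have shape (n_nodes, 2)")
        if elements.ndim != 2 or elements.shape[1] != 3:
            raise ValueError("elements must have shape (n_elements, 3)")
        if nodes.min() < -1e-12 or nodes.max() > 1 + 1e-12:
            raise ValueError("node coordinates must lie in the unit square")
        if self.signed_areas().min() <= 0:
            raise ValueError("all elements must have positive signed area")

    @property
    def n_nodes(self) -> int:
        return self.nodes.shape[0]

    @property
    def n_elements(self) -> int:
        return self.elements.shape[0]

    def signed_areas(self) -> np.ndarray:
        """Signed area of every element (positive for CCW orientation)."""
        p = self.nodes[self.elements]
        return 0.5 * (
            (p[:, 1, 0] - p[:, 0, 0]) * (p[:, 2, 1] - p[:, 0, 1])
            - (p[:, 2, 0] - p[:, 0, 0]) * (p[:, 1, 1] - p[:, 0, 1])
        )

    def boundary_node_mask(self) -> np.ndarray:
        """Boolean mask of nodes on the boundary of the unit square."""
        x, y = self.nodes[:, 0], self.nodes[:, 1]
        tol = 1e-12
        return (
            (np.abs(x) < tol)
            | (np.abs(x - 1) < tol)
            | (np.abs(y) < tol)
            | (np.abs(y - 1) < tol)
        )

    def shape_function_gradients(self) -> np.ndarray:
        """Gradients of the P1 shape functions, shape (n_elements, 3, 2).

        ``dN[e, i, j]`` is the derivative of local shape function ``i`` of
        element ``e`` with respect to coordinate ``j``; constant per element.
        """
        p = self.nodes[self.elements]
        x1, y1 = p[:, 0, 0], p[:, 0, 1]
        x2, y2 = p[:, 1, 0], p[:, 1, 1]
        x3, y3 = p[:, 2, 0], p[:, 2, 1]
        two_a = (x2 - x1) * (y3 - y1) - (x3 - x1) * (y2 - y1)
        dN = np.empty((self.n_elements, 3, 2))
        dN[:, 0, 0] = y2 - y3
        dN[:, 0, 1] = x3 - x2
        dN[:, 1, 0] = y3 - y1
        dN[:, 1, 1] = x1 - x3
        dN[:, 2, 0] = y1 - y2
        dN[:, 2, 1] = x2 - x1
        dN /= two_a[:, None, None]
        return dN

    def to_text(self) -> str:
        """Plain-text node/element listing."""
        lines = [f"nodes {self.n_nodes}"]
        lines += [f"{x:.17g} {y:.17g}" for x, y in self.nodes]
        lines.append(f"elements {self.n_elements}")
        lines += [f"{a} {b} {c}" for a, b, c in self.elements]
        return "\n".join(lines) + "\n"


def make_crossed_mesh(n: int) -> TriMesh:
    """Build the crossed triangulation of the unit square at resolution ``n``.

    Parameters
    ----------
    n : int
        Number of square cells per side; must be >= 1.

    Returns
    -------
    TriMesh
        Mesh with ``(n+1)**2 + n**2`` nodes and ``4*n**2`` elements.
    """
    if not isinstance(n, (int, np.integer)) or n < 1:
        raise ValueError(f"mesh resolution must be a positive integer, got {n!r}")
    n = int(n)
    g = np.linspace(0.0, 1.0, n + 1)
    gx, gy = np.meshgrid(g, g, indexing="xy")
    grid_nodes = np.column_stack([gx.ravel(), gy.ravel()])
    c = (np.arange(n) + 0.5) / n
    cx, cy = np.meshgrid(c, c, indexing="xy")
    center_nodes = np.column_stack([cx.ravel(), cy.ravel()])
    nodes = np.vstack([grid_nodes, center_nodes])

    n_grid = (n + 1) ** 2
    iy, ix = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
    iy, ix = iy.ravel(), ix.ravel()
    ll = iy * (n + 1) + ix
    lr = ll + 1
    ul = ll + (n + 1)
    ur = ul + 1
    cc = n_grid + iy * n + ix
    # four CCW triangles per cell, fanning around the center node
    elements = np.empty((4 * n * n, 3), dtype=np.int64)
    elements[0::4] = np.column_stack([ll, lr, cc])
    elements[1::4] = np.column_stack([lr, ur, cc])
    elements[2::4] = np.column_stack([ur, ul, cc])
    elements[3::4] = np.column_stack([ul, ll, cc])
    return TriMesh(nodes, elements)
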