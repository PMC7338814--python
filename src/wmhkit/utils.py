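"""Shared numerical helpers: polynomial bases and voxel connectivity."""

from __future__ import annotations

import numpy as np
from scipy import ndimage

__all__ = ["polynomial_basis", "connectivity_structure"]


def polynomial_basis(shape, mask, order):
    """3-D monomial basis x^a y^b z^c with a+b+c <= order.

    Coordinates are normalized to [-1, 1] along each axis of the full grid;
    the basis is evaluated at the voxels selected by ``mask``.

    Returns
    -------
    basis : ndarray, (mask.sum(), n_terms)
    powers : list of (a, b, c) tuples, same order as the columns
    """
    coords = []
    for axis, s in enumerate(shape):
        c = np.arange(s, dtype=float)
        c = 2.0 * (c - c.mean()) / max(s - 1, 1)
        sl = [None, None, None]
        sl[axis] = slice(None)
        coords.append(c[tuple(sl)])
    terms, powers = [], []
    for a in range(order + 1):
        for b in range(order + 1 - a):
            for c in range(order + 1 - a - b):
                powers.append((a, b, c))
                term = (coords[0] ** a) * (coords[1] ** b) * (coords[2] ** c)
                terms.append(np.broadcast_to(term, shape)[mask])
    return np.column_stack(terms), powers


def connectivity_structure(connectivity: int):
    """Binary structuring element for 6 / 18 / 26 voxel neighbourhoods."""
    rank = {6: 1, 18: 2, 26: 3}
    if connectivity not in rank:
        raise ValueError(f"connectivity must be 6, 18 or 26, got {connectivity}")
    return ndimage.generate_binary_structure(3, rank[connectivity])
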