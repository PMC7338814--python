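"""Bullseye coordinate system for regional lesion/error burden.

The white-matter + deep-grey domain between the ventricular surface and the
cortical sheet is foliated by the solution of the Laplace equation with
Dirichlet values 0 on the ventricles and 1 on the cortex; level sets of the
potential give four equidistant layers. Crossing the layers with nine lobar
regions (frontal/parietal/temporal/occipital x left/right, plus one
subcortical label) yields the 4 x 9 = 36 bullseye regions in which lesion
or error volumes are accumulated and normalized for plotting.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.sparse import coo_matrix, diags
from scipy.sparse.linalg import cg, spsolve

from .utils import connectivity_structure
from .volumes import voxel_volume_ml

__all__ = [
    "LayerField",
    "BullseyeParcellation",
    "solve_laplace",
    "assign_layers",
    "propagate_lobes",
    "combine_parcellation",
    "aggregate_regions",
    "wedge_geometry",
]

N_LAYERS = 4
N_LOBES = 9


@dataclass
class LayerField:
    """Laplace potential on the bullseye domain: 0 at the ventricular
    surface, 1 at the cortical sheet, discrete-harmonic in between."""

    phi: np.ndarray
    nodes: np.ndarray  # all voxels carrying a potential (domain + boundaries)
    inner: np.ndarray
    outer: np.ndarray
    residual: float


def solve_laplace(domain, inner, outer, tol=1e-5, voxel_mm=(1.0, 1.0, 1.0)) -> LayerField:
    """Solve the discrete Dirichlet problem on ``domain``.

    7-point Laplacian with voxel-size-aware weights; Dirichlet values 0 on
    ``inner`` (ventricular surface) and 1 on ``outer`` (cortical sheet).
    Interior faces not touching another node are treated as insulating
    (zero-flux), so the potential is defined exactly on
    ``domain | inner | outer``.

    Raises if some domain voxels have no 6-connected path to either
    boundary (their potential would be undetermined).
    """
    domain = np.asarray(domain, bool)
    inner = np.asarray(inner, bool)
    outer = np.asarray(outer, bool)
    if not inner.any() or not outer.any():
        raise ValueError("both boundary sets must be nonempty")
    if (inner & outer).any():
        raise ValueError("inner and outer boundaries overlap")

    nodes = domain | inner | outer
    fixed = inner | outer
    unknown = nodes & ~fixed

    # reachability: every unknown's 6-connected node component must contain
    # a boundary voxel, otherwise the system is singular
    labels, n_comp = ndimage.label(nodes, structure=connectivity_structure(6))
    ok = np.zeros(n_comp + 1, dtype=bool)
    ok[np.unique(labels[fixed])] = True
    if unknown.any() and not ok[labels[unknown]].all():
        raise ValueError(
            "domain voxels with no path to either boundary; "
            "check the ventricle/cortex masks"
        )

    phi = np.zeros(domain.shape)
    phi[outer] = 1.0
    if not unknown.any():
        return LayerField(phi, nodes, inner, outer, 0.0)

    idx = -np.ones(domain.shape, dtype=np.int64)
    un = np.argwhere(unknown)
    idx[tuple(un.T)] = np.arange(len(un))

    vx = np.asarray(voxel_mm, float)
    w_axis = 1.0 / vx**2
    rows, cols, vals = [], [], []
    b = np.zeros(len(un))
    diag = np.zeros(len(un))
    for axis in range(3):
        for step in (-1, 1):
            shifted = un.copy()
            shifted[:, axis] += step
            inside = (shifted[:, axis] >= 0) & (
                shifted[:, axis] < domain.shape[axis]
            )
            s_in = shifted[inside]
            nb_is_node = nodes[tuple(s_in.T)]
            sel = np.flatnonzero(inside)[nb_is_node]
            s_nodes = s_in[nb_is_node]
            w = w_axis[axis]
            diag[sel] += w
            nb_unknown = unknown[tuple(s_nodes.T)]
            # unknown neighbours go into the matrix
            r = sel[nb_unknown]
            c = idx[tuple(s_nodes[nb_unknown].T)]
            rows.extend(r.tolist())
            cols.extend(c.tolist())
            vals.extend([-w] * len(r))
            # fixed neighbours contribute to the right-hand side
            rf = sel[~nb_unknown]
            b[rf] += w * phi[tuple(s_nodes[~nb_unknown].T)]

    n = len(un)
    A = coo_matrix(
        (np.concatenate([diag, np.asarray(vals)]),
         (np.concatenate([np.arange(n), np.asarray(rows)]),
          np.concatenate([np.arange(n), np.asarray(cols)]))),
        shape=(n, n),
    ).tocsr()
    if n < 20_000:
        x = spsolve(A, b)
    else:
        # the system is symmetric positive definite: Jacobi-preconditioned
        # conjugate gradients scale to fine grids
        M = diags(1.0 / A.diagonal())
        x, info = cg(A, b, rtol=1e-10, atol=0.0, maxiter=20_000, M=M)
        if info != 0:
            raise RuntimeError(f"conjugate-gradient solver failed (info={info})")
    residual = float(np.abs(A @ x - b).max() / max(np.abs(b).max(), 1e-30))
    if residual > tol:
        raise RuntimeError(f"Laplace solve residual {residual:.2e} exceeds tol {tol}")
    phi[tuple(un.T)] = x
    phi[nodes] = np.clip(phi[nodes], 0.0, 1.0)
    return LayerField(phi, nodes, inner, outer, residual)


def assign_layers(field: LayerField, n_layers: int = N_LAYERS):
    """Equidistant layers from the potential: layer k covers
    phi in [(k-1)/n, k/n), with phi = 1 folded into the last layer."""
    layers = np.zeros(field.phi.shape, dtype=np.int16)
    sel = field.nodes
    k = np.floor(field.phi[sel] * n_layers).astype(np.int16) + 1
    layers[sel] = np.clip(k, 1, n_layers)
    return layers


def propagate_lobes(cortex_lobes, domain):
    """Propagate lobar labels from the cortical ribbon onto the domain by
    nearest labelled voxel (Euclidean distance); deterministic given the
    label volume."""
    cortex_lobes = np.asarray(cortex_lobes)
    have = cortex_lobes > 0
    if not have.any():
        raise ValueError("no lobar labels to propagate")
    _, (ix, iy, iz) = ndimage.distance_transform_edt(
        ~have, return_indices=True
    )
    out = np.zeros_like(cortex_lobes)
    dom = np.asarray(domain, bool)
    out[dom] = cortex_lobes[ix[dom], iy[dom], iz[dom]]
    return out


@dataclass
class BullseyeParcellation:
    """Per-voxel (layer 1-4, lobe 1-9) assignment over the bullseye domain."""

    layer: np.ndarray
    lobe: np.ndarray
    domain: np.ndarray

    def region_id(self):
        """Dense region id (layer - 1) * 9 + lobe on the domain, 0 outside."""
        rid = np.zeros(self.layer.shape, dtype=np.int16)
        d = self.domain
        rid[d] = (self.layer[d] - 1) * N_LOBES + self.lobe[d]
        return rid

    @staticmethod
    def from_region_id(rid):
        """Inverse of :meth:`region_id` (lossless round trip)."""
        d = rid > 0
        layer = np.zeros(rid.shape, dtype=np.int16)
        lobe = np.zeros(rid.shape, dtype=np.int16)
        layer[d] = (rid[d] - 1) // N_LOBES + 1
        lobe[d] = (rid[d] - 1) % N_LOBES + 1
        return BullseyeParcellation(layer, lobe, d)


def combine_parcellation(layers, lobe_labels, domain) -> BullseyeParcellation:
    """Cross 4 layers with 9 lobes into the 36-region bullseye."""
    domain = np.asarray(domain, bool)
    layers = np.asarray(layers)
    lobe_labels = np.asarray(lobe_labels)
    if (layers[domain] < 1).any() or (layers[domain] > N_LAYERS).any():
        raise ValueError("layer labels must cover the domain with values 1-4")
    if (lobe_labels[domain] < 1).any() or (lobe_labels[domain] > N_LOBES).any():
        raise ValueError("lobe labels must cover the domain with values 1-9")
    return BullseyeParcellation(
        layers.astype(np.int16), lobe_labels.astype(np.int16), domain
    )


def aggregate_regions(
    value_map,
    parcellation: BullseyeParcellation,
    voxel_mm=(1.0, 1.0, 1.0),
    normalizer: str = "none",
    tp_volume_ml: float | None = None,
) -> pd.DataFrame:
    """Accumulate a nonnegative voxel map into the 36 regions.

    ``normalizer``: "none" reports raw ml; "total_error" divides by the
    map's own total; "tp_volume" divides by ``tp_volume_ml``. Regions with a
    zero denominator report proportion 0 with ``zero_denominator`` flagged.
    """
    value_map = np.asarray(value_map, float)
    if (value_map < 0).any():
        raise ValueError("value map must be nonnegative")
    if normalizer not in ("none", "total_error", "tp_volume"):
        raise ValueError(f"unknown normalizer {normalizer!r}")
    vox = voxel_volume_ml(voxel_mm)
    rid = parcellation.region_id()
    sums = ndimage.sum_labels(value_map, rid, index=np.arange(1, 37))
    ml = sums * vox

    total = ml.sum() if normalizer == "total_error" else (
        tp_volume_ml if normalizer == "tp_volume" else None
    )
    if normalizer == "tp_volume" and total is None:
        raise ValueError("tp_volume normalizer requires tp_volume_ml")
    zero_denom = normalizer != "none" and not (total and total > 0)
    if normalizer == "none":
        prop = ml.copy()
    elif zero_denom:
        prop = np.zeros_like(ml)
    else:
        prop = ml / total

    region = np.arange(1, 37)
    return pd.DataFrame(
        {
            "region_id": region,
            "layer": (region - 1) // N_LOBES + 1,
            "lobe": (region - 1) % N_LOBES + 1,
            "ml": ml,
            "proportion": prop,
            "zero_denominator": zero_denom,
        }
    )


def wedge_geometry():
    """Polar-wedge layout for plotting: per lobe an angular span, per layer
    a radial band. The subcortical label occupies the innermost disc by
    convention and is returned with a full angular span."""
    wedges = []
    peripheral = [1, 2, 3, 4, 5, 6, 7, 8]
    step = 360.0 / len(peripheral)
    for i, lobe in enumerate(peripheral):
        wedges.append(
            {"lobe": lobe, "angle_start": i * step, "angle_stop": (i + 1) * step}
        )
    wedges.append({"lobe": 9, "angle_start": 0.0, "angle_stop": 360.0})
    bands = [
        {"layer": k, "r_inner": (k - 1) / N_LAYERS, "r_outer": k / N_LAYERS}
        for k in range(1, N_LAYERS + 1)
    ]
    return {"wedges": wedges, "bands": bands}
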