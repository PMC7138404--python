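"""Topology-preserving 3D thinning (curve skeletonisation).

Sequential border deletion of *simple points*: a foreground voxel may be
removed iff deleting it changes neither the number of foreground objects,
holes nor cavities.  Simplicity is decided locally in the 3x3x3
neighbourhood by the two topological numbers of Malandain & Bertrand:

* C*  — number of 26-connected foreground components in the 26-neighbourhood;
* Cb  — number of 6-connected background components of the 18-neighbourhood
        that are 6-adjacent to the centre voxel.

The voxel is simple iff C* == 1 and Cb == 1.  Curve endpoints (voxels with
at most one foreground neighbour) are never removed, so one-voxel-wide
centrelines of elongated structures survive.  Deletion proceeds in six
directional passes (up/down/north/south/east/west borders) for a centred
result, and inside each pass voxels are processed in eight parity subfields:
voxels of equal (x%2, y%2, z%2) are mutually outside each other's 3x3x3
neighbourhoods, so deleting them simultaneously is equivalent to sequential
deletion.  Iteration stops at a fixed point.
"""

from __future__ import annotations

from itertools import product

import numpy as np

_OFFSETS = [np.array(o) for o in product((-1, 0, 1), repeat=3)]
_CENTER = 13  # index of (0,0,0)

# adjacency (as index pairs) between the 26 neighbour cells
_N26_IDX = [i for i in range(27) if i != _CENTER]
_N18_IDX = [i for i in range(27)
            if i != _CENTER and np.abs(_OFFSETS[i]).sum() <= 2]
_FACE_IDX = [i for i in range(27) if np.abs(_OFFSETS[i]).sum() == 1]


def _adjacency(cells, metric):
    """cells -> list of neighbour-index lists under the given adjacency."""
    pos = {c: k for k, c in enumerate(cells)}
    adj = [[] for _ in cells]
    for a in cells:
        for b in cells:
            if a == b:
                continue
            d = np.abs(_OFFSETS[a] - _OFFSETS[b])
            if metric == 26 and d.max() == 1:
                adj[pos[a]].append(pos[b])
            elif metric == 6 and d.sum() == 1:
                adj[pos[a]].append(pos[b])
    return adj


_ADJ26 = _adjacency(_N26_IDX, 26)
_ADJ6 = _adjacency(_N18_IDX, 6)
_FACE_IN_N18 = [_N18_IDX.index(i) for i in _FACE_IDX]


def _label_components(active, adj):
    """Minimum-label propagation on fixed small graphs, vectorised over rows.

    ``active``: (n, m) bool.  Returns (n, m) int labels (-1 where inactive);
    connected cells share the row-minimum active index.
    """
    n, m = active.shape
    labels = np.where(active, np.arange(m)[None, :], m)
    for _ in range(m):  # diameter bound; converges much faster
        new = labels.copy()
        for k, nbrs in enumerate(adj):
            if not nbrs:
                continue
            col = labels[:, nbrs].min(axis=1)
            new[:, k] = np.minimum(new[:, k], np.where(active[:, k], col, m))
        if np.array_equal(new, labels):
            break
        labels = new
    return np.where(active, labels, -1)


def _count_components(active, adj):
    labels = _label_components(active, adj)
    counts = np.zeros(active.shape[0], dtype=int)
    for k in range(active.shape[1]):
        counts += active[:, k] & (labels[:, k] == k)
    return counts


def _neighborhoods(padded, coords):
    """(n, 27) boolean neighbourhoods of given voxel coordinates."""
    n = coords.shape[0]
    out = np.empty((n, 27), dtype=bool)
    for i, off in enumerate(_OFFSETS):
        out[:, i] = padded[coords[:, 0] + off[0] + 1,
                           coords[:, 1] + off[1] + 1,
                           coords[:, 2] + off[2] + 1]
    return out


def _simple_and_not_endpoint(nb):
    """Deletable mask for (n, 27) neighbourhoods."""
    fg26 = nb[:, _N26_IDX]
    n_nb = fg26.sum(axis=1)
    endpoint = n_nb <= 1
    c_star = _count_components(fg26, _ADJ26)
    bg18 = ~nb[:, _N18_IDX]
    labels = _label_components(bg18, _ADJ6)
    face_labels = labels[:, _FACE_IN_N18]
    face_bg = bg18[:, _FACE_IN_N18]
    # number of distinct background components among the six face neighbours
    cb = np.zeros(nb.shape[0], dtype=int)
    seen = np.full((nb.shape[0], len(_FACE_IN_N18)), -2)
    for k in range(len(_FACE_IN_N18)):
        lab = np.where(face_bg[:, k], face_labels[:, k], -1)
        new = face_bg[:, k] & ~(seen == lab[:, None]).any(axis=1)
        cb += new
        seen[:, k] = np.where(new, lab, -2)
    return (c_star == 1) & (cb == 1) & ~endpoint


def thin_3d(volume: np.ndarray) -> np.ndarray:
    """Thin a 3D binary volume to a one-voxel-wide curve skeleton."""
    img = np.asarray(volume, dtype=bool).copy()
    if img.ndim != 3:
        raise ValueError("thin_3d expects a 3D volume")
    if not img.any():
        return img
    directions = [(0, -1), (0, 1), (1, -1), (1, 1), (2, -1), (2, 1)]
    padded = np.zeros(tuple(s + 2 for s in img.shape), dtype=bool)
    while True:
        changed = False
        for axis, sign in directions:
            # border voxels: background in the (axis, sign) direction
            shifted = np.roll(np.pad(img, 1, constant_values=False),
                              -sign, axis=axis)[1:-1, 1:-1, 1:-1]
            border = img & ~shifted
            coords = np.argwhere(border)
            if coords.size == 0:
                continue
            parity = (coords[:, 0] % 2) * 4 + (coords[:, 1] % 2) * 2 \
                + (coords[:, 2] % 2)
            for sub in range(8):
                sel = coords[parity == sub]
                if sel.size == 0:
                    continue
                sel = sel[img[sel[:, 0], sel[:, 1], sel[:, 2]]]
                if sel.size == 0:
                    continue
                padded[1:-1, 1:-1, 1:-1] = img
                nb = _neighborhoods(padded, sel)
                kill = _simple_and_not_endpoint(nb)
                if kill.any():
                    k = sel[kill]
                    img[k[:, 0], k[:, 1], k[:, 2]] = False
                    changed = True
        if not changed:
            return img
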