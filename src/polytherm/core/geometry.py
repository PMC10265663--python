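"""Minimum-image geometry for orthorhombic boxes."""

from __future__ import annotations

import numpy as np

from polytherm.core.types import Box


def min_image_displacement(delta: np.ndarray, box: Box) -> np.ndarray:
    """Apply the minimum-image convention to displacement vectors.

    ``delta`` is (..., 3) in nm; each component is mapped into
    [-L/2, L/2) for the corresponding box edge.
    """
    lengths = box.lengths
    return delta - lengths * np.round(delta / lengths)


def min_image_distance(a: np.ndarray, b: np.ndarray, box: Box) -> np.ndarray:
    """Pairwise minimum-image distances between points ``a`` (..., 3) and ``b`` (..., 3)."""
    d = min_image_displacement(np.asarray(a) - np.asarray(b), box)
    return np.sqrt(np.sum(d * d, axis=-1))


def pair_distances(positions: np.ndarray, box: Box, cutoff: float | None = None) -> np.ndarray:
    """All unique pair distances (i < j) under minimum image, optionally cut off.

    Returns a flat array of distances in nm. O(n^2) memory; intended for
    the desk-scale frames this package analyses.
    """
    pos = np.asarray(positions, dtype=float)
    n = len(pos)
    if n < 2:
        return np.empty(0)
    iu, ju = np.triu_indices(n, k=1)
    d = min_image_displacement(pos[iu] - pos[ju], box)
    r = np.sqrt(np.sum(d * d, axis=1))
    if cutoff is not None:
        r = r[r <= cutoff]
    return r
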