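"""Topological skeletons of silhouettes by iterative thinning.

The skeleton (medial axis) abstracts a shape to a 1-pixel-wide, 8-connected
linear structure that captures its internal organization and branching.  No
pruning of spurious branches is applied, so contour noise survives as short
spurs; that is deliberate, the measurement protocol treats the raw thinned
set as the structural signal.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from skimage.morphology import medial_axis, skeletonize

from .silhouettes import Silhouette

__all__ = ["skeletonize_mask", "is_point", "POINT_PIXEL_LIMIT"]

#: A skeleton with at most this many 8-connected pixels is degenerate
#: ("point-like"): the source shape (e.g. a filled disk) has no linear
#: structure, and its specimen is flagged singular downstream.
POINT_PIXEL_LIMIT = 4

_EIGHT = np.ones((3, 3), dtype=int)


def skeletonize_mask(sil: Silhouette, method: str = "zhang") -> Silhouette:
    """Thin a binary silhouette to its 1-px topological skeleton.

    ``method`` selects the reduction: ``"zhang"`` (iterative contour
    erosion until an equidistant median line remains; the default) or
    ``"medial_axis"`` (distance-transform ridge).  Thinning is confined to
    the foreground bounding box, which does not change the result but keeps
    large, mostly-empty frames cheap.
    """
    mask = sil.pixels
    if not mask.any():
        raise ValueError("cannot skeletonize an empty silhouette")
    ys, xs = np.nonzero(mask)
    y0, y1 = ys.min(), ys.max() + 1
    x0, x1 = xs.min(), xs.max() + 1
    sub = mask[y0:y1, x0:x1]
    if method == "zhang":
        thin = skeletonize(sub, method="zhang")
    elif method == "medial_axis":
        thin = medial_axis(sub)
    else:
        raise ValueError(f"unknown thinning method {method!r}")
    out = np.zeros_like(mask)
    out[y0:y1, x0:x1] = thin
    if not out.any():
        # Zhang thinning can erase a shape only in the single-pixel corner
        # case; keep one pixel so a skeleton is never empty.
        out[ys[0], xs[0]] = True
    return sil.copy_with(out, is_skeleton=True)


def is_point(skel: Silhouette) -> bool:
    """Whether a skeleton degenerated to a point-like cluster (<= 4 px)."""
    return skel.n_foreground <= POINT_PIXEL_LIMIT


def n_components(sil: Silhouette) -> int:
    """Number of 8-connected foreground components."""
    _, n = ndimage.label(sil.pixels, structure=_EIGHT)
    return int(n)
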