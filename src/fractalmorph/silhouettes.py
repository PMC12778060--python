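"""Binary silhouette handling: loading, standardization, rotation, and tables.

A *silhouette* is a binary raster mask of a body form: foreground pixels are
the organism (conventionally drawn black on white), background is empty
space.  Every downstream measurement operates on silhouettes that have been
standardized to a common body length of 860 pixels, centered in a square
1000x1000 frame, so that box-counting scales are comparable across
specimens of wildly different physical sizes.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from PIL import Image
from scipy import ndimage
from scipy.spatial import ConvexHull, QhullError

__all__ = [
    "Silhouette",
    "load_silhouette",
    "write_silhouette",
    "standardize",
    "rotate_mask",
    "body_length",
    "MEASUREMENT_COLUMNS",
    "write_measurements",
    "read_measurements",
]

#: Default frame side (px) and standardized body length (px).
DEFAULT_FRAME = 1000
DEFAULT_BODY_LENGTH = 860


@dataclass
class Silhouette:
    """A binary mask plus bookkeeping.

    Parameters
    ----------
    pixels
        2-D boolean array; ``True`` is foreground.
    id
        Free-text specimen label.
    is_skeleton
        Whether this mask is a 1-px-wide topological skeleton.
    degenerate
        Set when the foreground was a single pixel at standardization time
        (length zero, so no rescaling was possible).
    """

    pixels: np.ndarray
    id: str = ""
    is_skeleton: bool = False
    degenerate: bool = field(default=False, compare=False)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=bool)
        if self.pixels.ndim != 2:
            raise ValueError("silhouette pixels must be a 2-D array")

    @property
    def frame_size(self) -> int:
        return max(self.pixels.shape)

    @property
    def n_foreground(self) -> int:
        return int(self.pixels.sum())

    @property
    def body_length_px(self) -> int:
        return int(round(body_length(self.pixels)))

    def foreground_coords(self) -> tuple[np.ndarray, np.ndarray]:
        ys, xs = np.nonzero(self.pixels)
        return ys, xs

    def copy_with(self, pixels: np.ndarray, **kw) -> "Silhouette":
        return replace(self, pixels=pixels, **kw)


def _max_pairwise_distance(points: np.ndarray) -> float:
    """Maximum Feret diameter of a point cloud (exact, via convex hull)."""
    if len(points) < 2:
        return 0.0
    pts = points.astype(float)
    try:
        hull = ConvexHull(pts)
        verts = pts[hull.vertices]
    except QhullError:
        # Degenerate (collinear) clouds: the farthest pair is extreme along
        # one of the coordinate projections.
        cand = []
        for proj in (pts[:, 0], pts[:, 1], pts.sum(axis=1), pts[:, 0] - pts[:, 1]):
            cand.append(pts[int(np.argmin(proj))])
            cand.append(pts[int(np.argmax(proj))])
        verts = np.array(cand)
    d2 = ((verts[:, None, :] - verts[None, :, :]) ** 2).sum(axis=-1)
    return float(np.sqrt(d2.max()))


def body_length(mask: np.ndarray) -> float:
    """Body length of a mask in pixels.

    Defined as the maximum Feret diameter of the foreground (largest
    center-to-center pixel distance) plus one pixel, so a horizontal run of
    430 pixels has body length exactly 430.
    """
    ys, xs = np.nonzero(mask)
    if len(ys) == 0:
        raise ValueError("empty silhouette: no foreground pixels")
    if len(ys) == 1:
        return 1.0
    return _max_pairwise_distance(np.column_stack([ys, xs])) + 1.0


def load_silhouette(path, foreground: str = "dark", id: str | None = None) -> Silhouette:
    """Read a PNG/BMP raster as a binary silhouette.

    Gray values are thresholded at mid-intensity.  ``foreground`` selects
    polarity: ``"dark"`` (black shape on white, the drawing convention) or
    ``"light"``.
    """
    if foreground not in ("dark", "light"):
        raise ValueError(f"foreground must be 'dark' or 'light', got {foreground!r}")
    with Image.open(path) as im:
        arr = np.asarray(im.convert("L"))
    mask = arr < 128 if foreground == "dark" else arr >= 128
    if not mask.any():
        raise ValueError(f"empty silhouette: no foreground pixels in {path}")
    _warn_speckle(mask, str(path))
    name = id if id is not None else _stem(path)
    return Silhouette(pixels=mask, id=name)


def _stem(path) -> str:
    import os

    return os.path.splitext(os.path.basename(str(path)))[0]


def _warn_speckle(mask: np.ndarray, label: str) -> None:
    """Warn when isolated single-pixel islands exceed 5% of the foreground.

    Heavy speckle usually means the source image kept textural detail finer
    than the ~1 per mil of body length the silhouette convention allows.
    """
    lab, n = ndimage.label(mask, structure=np.ones((3, 3), dtype=int))
    if n <= 1:
        return
    sizes = np.bincount(lab.ravel())[1:]
    singles = int((sizes == 1).sum())
    if singles > 0.05 * mask.sum():
        warnings.warn(
            f"{label}: {singles} isolated single-pixel islands exceed 5% of "
            "the foreground; check vectorization noise",
            stacklevel=3,
        )


def write_silhouette(sil: Silhouette, path) -> None:
    """Write a silhouette as an 8-bit PNG (black foreground on white)."""
    arr = np.where(sil.pixels, 0, 255).astype(np.uint8)
    Image.fromarray(arr).save(path)


def _center_in_frame(mask: np.ndarray, frame: int) -> np.ndarray:
    """Place the foreground bounding box centered in a frame x frame canvas."""
    ys, xs = np.nonzero(mask)
    y0, y1 = ys.min(), ys.max()
    x0, x1 = xs.min(), xs.max()
    h, w = y1 - y0 + 1, x1 - x0 + 1
    if h > frame or w > frame:
        raise ValueError(f"foreground ({h}x{w}) does not fit in a {frame}px frame")
    out = np.zeros((frame, frame), dtype=bool)
    oy = (frame - h) // 2
    ox = (frame - w) // 2
    out[oy : oy + h, ox : ox + w] = mask[y0 : y1 + 1, x0 : x1 + 1]
    return out


def standardize(
    sil: Silhouette,
    frame: int = DEFAULT_FRAME,
    target_length: int = DEFAULT_BODY_LENGTH,
) -> Silhouette:
    """Rescale a silhouette to the standard body length and center it.

    The longest foreground extent (maximum Feret diameter) is rescaled to
    ``target_length`` by nearest-neighbor resampling (binarity preserved)
    and the foreground bounding box is centered in a square frame.  A
    single-pixel foreground cannot be scaled; it is centered as-is and
    flagged ``degenerate``.
    """
    mask = sil.pixels
    if not mask.any():
        raise ValueError("empty silhouette: no foreground pixels")
    length = body_length(mask)
    if length <= 1.0:
        return sil.copy_with(_center_in_frame(mask, frame), degenerate=True)
    scale = target_length / length
    if not math.isclose(scale, 1.0, abs_tol=1e-12):
        scaled = ndimage.zoom(mask.astype(np.uint8), scale, order=0, grid_mode=True,
                              mode="grid-constant") > 0
        if not scaled.any():  # pragma: no cover - extreme downscale guard
            raise ValueError("standardization erased the foreground")
    else:
        scaled = mask
    return sil.copy_with(_center_in_frame(scaled, frame))


def rotate_mask(sil: Silhouette, degrees: float) -> Silhouette:
    """Rotate a mask about the frame center on an enlarged canvas.

    The canvas is enlarged to ``ceil(frame * sqrt(2))`` (rounded up to an
    even side) so no foreground is clipped at any angle.  Multiples of 90
    degrees are computed exactly (transpose/flip); other angles use
    nearest-neighbor resampling, which keeps the mask strictly binary.
    """
    mask = sil.pixels
    side = max(mask.shape)
    canvas = int(math.ceil(side * math.sqrt(2.0)))
    canvas += canvas % 2
    emb = np.zeros((canvas, canvas), dtype=bool)
    oy = (canvas - mask.shape[0]) // 2
    ox = (canvas - mask.shape[1]) // 2
    emb[oy : oy + mask.shape[0], ox : ox + mask.shape[1]] = mask

    deg = float(degrees) % 360.0
    if math.isclose(deg % 90.0, 0.0, abs_tol=1e-12):
        out = np.rot90(emb, k=int(round(deg / 90.0)) % 4)
    else:
        theta = math.radians(deg)
        c, s = math.cos(theta), math.sin(theta)
        center = (canvas - 1) / 2.0
        matrix = np.array([[c, -s], [s, c]])  # inverse map: output -> input
        offset = np.array([center, center]) - matrix @ np.array([center, center])
        out = (
            ndimage.affine_transform(
                emb.astype(np.uint8), matrix, offset=offset, order=0,
                prefilter=False, mode="constant", cval=0,
            )
            > 0
        )
    return sil.copy_with(out)


# ---------------------------------------------------------------------------
# Measurement tables

MEASUREMENT_COLUMNS = [
    "id",
    "group",
    "D_SI",
    "sd_D_SI",
    "D_SK",
    "sd_D_SK",
    "L_SI",
    "sd_L_SI",
    "L_SK",
    "sd_L_SK",
    "singular",
]


def write_measurements(table: pd.DataFrame, path) -> None:
    """Write a measurement table to CSV (round-trips through the reader).

    Requires unique specimen ids and at least one row; numeric fields are
    written at 6 decimal places.
    """
    if len(table) == 0:
        raise ValueError("refusing to write an empty measurement table")
    dup = table["id"][table["id"].duplicated()]
    if len(dup):
        raise ValueError(f"duplicate specimen id(s): {sorted(set(dup))}")
    cols = [c for c in MEASUREMENT_COLUMNS if c in table.columns]
    cols += [c for c in table.columns if c not in cols]
    table[cols].to_csv(path, index=False, float_format="%.6f")


def read_measurements(path) -> pd.DataFrame:
    """Read a measurement table written by :func:`write_measurements`."""
    df = pd.read_csv(path)
    if "singular" in df.columns:
        df["singular"] = df["singular"].astype(bool)
    return df
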