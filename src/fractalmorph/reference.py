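"""Deterministic reference shapes: primitives, classical self-similar
fractals, and an articulated humanoid.

The primitives and fractals serve as calibration standards: each comes
with its exact self-similarity dimension, against which empirical
box-counting estimates are regressed to fit the power-law correction.
Fractal rasters are built analytically (iterated substitution on exact
ternary/binary grids, or turtle vertices for the Koch curve) before
standardization, so no resampling artifact enters the construction.

The humanoid is a jointed stick-figure silhouette (trunk, head, two arms
and two legs with elbow/knee joints) used to probe how sensitive the four
parameters are to body posture.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from skimage.draw import disk as draw_disk
from skimage.draw import ellipse as draw_ellipse
from skimage.draw import line as draw_line
from skimage.draw import polygon as draw_polygon

from scipy import ndimage as _ndimage

from .fractal import theoretical_dimension
from .silhouettes import (
    DEFAULT_BODY_LENGTH,
    DEFAULT_FRAME,
    Silhouette,
    standardize,
)
from .silhouettes import _center_in_frame

__all__ = [
    "ReferenceShapeSpec",
    "make_reference",
    "reference_suite",
    "default_reference_suite",
    "HumanoidPose",
    "make_humanoid",
    "humanoid_posture_suite",
]

# Substitution patterns for iterated (IFS) fractals.  True cells are kept
# at each subdivision; N kept cells in a base b x b pattern give dimension
# ln(N)/ln(b).  The scale-4 ("quad") family provides intermediate
# dimensions between the classical ternary forms.
_SUBSTITUTION_PATTERNS = {
    "sierpinski_carpet": np.array(
        [[1, 1, 1], [1, 0, 1], [1, 1, 1]], dtype=bool
    ),
    "cantor_dust_2d": np.array(
        [[1, 0, 1], [0, 0, 0], [1, 0, 1]], dtype=bool
    ),
    "vicsek": np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool),
    # Intermediate "mixed carpet" patterns between the Vicsek cross
    # (ln5/ln3) and the full carpet (ln8/ln3).
    "mixed_carpet_6": np.array([[1, 1, 1], [1, 0, 1], [1, 0, 0]], dtype=bool),
    "mixed_carpet_7": np.array([[1, 1, 1], [1, 0, 1], [1, 1, 0]], dtype=bool),
    # Scale-4 patterns: ln(5)/ln(4), ln(7)/ln(4), ln(10)/ln(4).
    "quad_dust_5": np.array(
        [[1, 0, 0, 1], [0, 1, 0, 0], [0, 0, 0, 0], [1, 0, 0, 1]], dtype=bool
    ),
    "quad_carpet_7": np.array(
        [[1, 0, 0, 1], [0, 1, 1, 0], [0, 1, 0, 0], [1, 0, 0, 1]], dtype=bool
    ),
    "quad_carpet_10": np.array(
        [[1, 1, 1, 1], [1, 0, 0, 1], [1, 0, 0, 1], [1, 1, 0, 0]], dtype=bool
    ),
}

FRACTAL_KINDS = {"koch_curve", "sierpinski_triangle"} | set(_SUBSTITUTION_PATTERNS)
PRIMITIVE_KINDS = {"point", "line", "ellipse", "disk", "filled_square"}


@dataclass(frozen=True)
class ReferenceShapeSpec:
    """Recipe for one reference shape.

    ``depth`` is the iteration count for fractal kinds; ``aspect`` the
    height/width ratio for ellipses; ``size`` the standardization frame.
    """

    kind: str
    depth: int = 4
    aspect: float = 0.25
    size: int = DEFAULT_FRAME

    def __post_init__(self):
        if self.kind not in FRACTAL_KINDS | PRIMITIVE_KINDS:
            raise ValueError(f"unknown reference kind {self.kind!r}")
        if self.kind in FRACTAL_KINDS and self.depth < 1:
            raise ValueError("fractal depth must be >= 1")


def _ternary_ifs(pattern: np.ndarray, depth: int) -> np.ndarray:
    grid = pattern.copy()
    for _ in range(depth - 1):
        grid = np.kron(grid, pattern)
    return grid


def _sierpinski_triangle(depth: int) -> np.ndarray:
    n = 2**depth
    i, j = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
    return (i & j) == 0


def koch_vertices(depth: int) -> np.ndarray:
    """Vertices of the Koch curve over [0, 1] as complex numbers."""
    pts = np.array([0.0 + 0.0j, 1.0 + 0.0j])
    turn = np.exp(-1j * math.pi / 3.0)  # peak points "up" in image coords
    for _ in range(depth):
        a = pts[:-1]
        b = pts[1:]
        d = (b - a) / 3.0
        new = np.empty(4 * len(a) + 1, dtype=complex)
        new[0:-1:4] = a
        new[1::4] = a + d
        new[2::4] = a + d + d * turn
        new[3::4] = a + 2 * d
        new[-1] = pts[-1]
        pts = new
    return pts


def _raster_koch(depth: int, segment_px: int | None = None) -> np.ndarray:
    """Draw a Koch curve with 1-px strokes.

    ``segment_px`` fixes the drawn length of the finest segment; by
    default it is the largest integer keeping the base within ~860 px.
    """
    if segment_px is None:
        segment_px = max(3, 860 // 3**depth)
    width = segment_px * 3**depth
    verts = koch_vertices(depth) * width
    height = int(math.ceil(width * math.sqrt(3) / 6)) + 2
    canvas = np.zeros((height + 2, width + 2), dtype=bool)
    rows = np.round(verts.imag).astype(int) + height
    cols = np.round(verts.real).astype(int) + 1
    rows = np.clip(rows, 0, canvas.shape[0] - 1)
    cols = np.clip(cols, 0, canvas.shape[1] - 1)
    for k in range(len(verts) - 1):
        rr, cc = draw_line(rows[k], cols[k], rows[k + 1], cols[k + 1])
        canvas[rr, cc] = True
    return canvas


def _upscale_to(grid: np.ndarray, target: int) -> np.ndarray:
    """Integer-replicate a fractal grid toward the target extent."""
    k = max(1, target // max(grid.shape))
    if k > 1:
        grid = np.kron(grid, np.ones((k, k), dtype=bool))
    return grid


def _axis_standardize(mask: np.ndarray, frame: int) -> np.ndarray:
    """Scale the longest axis-aligned extent to 860 px and center.

    Reference standards are geometric constructions whose nominal size is
    their drawn extent (a square's side, a disk's diameter), so they are
    standardized along the longest bounding-box axis rather than by the
    Feret diameter used for organismal silhouettes -- the latter would
    shrink a square to 860/sqrt(2) via its diagonal and change what the
    fixture means.
    """
    ys, xs = np.nonzero(mask)
    extent = max(ys.max() - ys.min() + 1, xs.max() - xs.min() + 1)
    scale = DEFAULT_BODY_LENGTH / extent
    if abs(scale - 1.0) > 1e-12:
        mask = _ndimage.zoom(mask.astype(np.uint8), scale, order=0,
                             grid_mode=True, mode="grid-constant") > 0
    return _center_in_frame(mask, frame)


def make_reference(spec: ReferenceShapeSpec) -> tuple[Silhouette, float]:
    """Render one reference shape and return it with its exact dimension."""
    L = DEFAULT_BODY_LENGTH
    kind = spec.kind
    if kind == "point":
        mask = np.zeros((3, 3), dtype=bool)
        mask[1, 1] = True
        d_theo = 0.0
    elif kind == "line":
        mask = np.zeros((3, L), dtype=bool)
        mask[1, :] = True
        d_theo = 1.0
    elif kind == "filled_square":
        mask = np.ones((L, L), dtype=bool)
        d_theo = 2.0
    elif kind == "disk":
        mask = np.zeros((L + 2, L + 2), dtype=bool)
        rr, cc = draw_disk((L // 2 + 1, L // 2 + 1), L / 2.0, shape=mask.shape)
        mask[rr, cc] = True
        d_theo = 2.0
    elif kind == "ellipse":
        h = max(2, int(round(L * spec.aspect)))
        mask = np.zeros((h + 2, L + 2), dtype=bool)
        rr, cc = draw_ellipse(h // 2 + 1, L // 2 + 1, h / 2.0, L / 2.0, shape=mask.shape)
        mask[rr, cc] = True
        d_theo = 2.0
    elif kind == "koch_curve":
        if 3**spec.depth > 2 * L:
            raise ValueError(f"koch depth {spec.depth} below raster resolution")
        mask = _raster_koch(spec.depth)
        d_theo = theoretical_dimension(4, 3)
    elif kind == "sierpinski_triangle":
        if 2**spec.depth > spec.size:
            raise ValueError("triangle depth below raster resolution")
        mask = _upscale_to(_sierpinski_triangle(spec.depth), L)
        d_theo = theoretical_dimension(3, 2)
    else:
        pattern = _SUBSTITUTION_PATTERNS[kind]
        base = pattern.shape[0]
        if base**spec.depth > spec.size:
            raise ValueError(f"{kind} depth {spec.depth} below raster resolution")
        mask = _upscale_to(_ternary_ifs(pattern, spec.depth), L)
        d_theo = theoretical_dimension(int(pattern.sum()), base)
    sil = Silhouette(_axis_standardize(mask, spec.size), id=f"{kind}_d{spec.depth}")
    return sil, d_theo


def default_reference_suite(size: int = DEFAULT_FRAME) -> list[ReferenceShapeSpec]:
    """The 11-member calibration suite spanning dimensions [1, 2].

    Members are chosen so that the finite-resolution bias of the
    box-counting estimator is rank-monotone across the suite: distinct
    theoretical dimensions are separated by at least ~0.1 (exact ties are
    fine, rank correlation handles them), iterated forms use depths with
    comparable truncation scales, and solids of extreme aspect ratio are
    excluded because a thin filled ellipse measures like a mid-dimension
    fractal at 1000-px resolution even though its theoretical dimension
    is 2.  Ellipses, shallower depths and further substitution patterns
    remain available as kinds for sensitivity studies.
    """
    return [
        ReferenceShapeSpec("line", size=size),
        ReferenceShapeSpec("quad_dust_5", depth=4, size=size),
        ReferenceShapeSpec("koch_curve", depth=4, size=size),
        ReferenceShapeSpec("cantor_dust_2d", depth=4, size=size),
        ReferenceShapeSpec("quad_carpet_7", depth=4, size=size),
        ReferenceShapeSpec("vicsek", depth=4, size=size),
        ReferenceShapeSpec("sierpinski_triangle", depth=8, size=size),
        ReferenceShapeSpec("quad_carpet_10", depth=4, size=size),
        ReferenceShapeSpec("mixed_carpet_7", depth=4, size=size),
        ReferenceShapeSpec("sierpinski_carpet", depth=4, size=size),
        ReferenceShapeSpec("disk", size=size),
        ReferenceShapeSpec("filled_square", size=size),
    ]


def reference_suite(specs=None) -> list[tuple[Silhouette, float]]:
    """Render a suite of (silhouette, theoretical dimension) pairs."""
    if specs is None:
        specs = default_reference_suite()
    return [make_reference(s) for s in specs]


# ---------------------------------------------------------------------------
# Articulated humanoid


@dataclass(frozen=True)
class HumanoidPose:
    """Joint angles (degrees) of the stick-figure humanoid.

    Limb angles are measured from straight down: ``arm_*`` abducts the
    upper arm outward from the trunk, ``elbow_*`` bends the forearm
    further outward, ``leg_*`` splays the thigh, ``knee_*`` bends the shin
    outward.  Ranges are kept moderate so limbs never overlap the trunk or
    each other.
    """

    arm_l: float = 40.0
    arm_r: float = 40.0
    elbow_l: float = 10.0
    elbow_r: float = 10.0
    leg_l: float = 14.0
    leg_r: float = 14.0
    knee_l: float = 5.0
    knee_r: float = 5.0


def _capsule(canvas, p0, p1, halfwidth):
    (r0, c0), (r1, c1) = p0, p1
    dr, dc = r1 - r0, c1 - c0
    norm = math.hypot(dr, dc)
    if norm < 1e-9:
        rr, cc = draw_disk((r0, c0), max(halfwidth, 1.0), shape=canvas.shape)
        canvas[rr, cc] = True
        return
    ur, uc = -dc / norm, dr / norm  # unit perpendicular
    corners_r = [r0 + ur * halfwidth, r1 + ur * halfwidth,
                 r1 - ur * halfwidth, r0 - ur * halfwidth]
    corners_c = [c0 + uc * halfwidth, c1 + uc * halfwidth,
                 c1 - uc * halfwidth, c0 - uc * halfwidth]
    rr, cc = draw_polygon(corners_r, corners_c, shape=canvas.shape)
    canvas[rr, cc] = True
    for r, c in ((r0, c0), (r1, c1)):
        rr, cc = draw_disk((r, c), max(halfwidth, 1.0), shape=canvas.shape)
        canvas[rr, cc] = True


def make_humanoid(pose: HumanoidPose = HumanoidPose(), frame: int = DEFAULT_FRAME) -> Silhouette:
    """Render a standardized humanoid silhouette in the given posture."""
    S = 700.0  # px per body unit before standardization
    canvas = np.zeros((1400, 1400), dtype=bool)
    origin = (820.0, 700.0)  # pelvis (row, col)

    def pt(x: float, y: float) -> tuple[float, float]:
        return (origin[0] - y * S, origin[1] + x * S)

    def limb(base_xy, length, width, angle_deg, side):
        """Endpoint of a segment hanging from base, rotated outward."""
        a = math.radians(angle_deg)
        dx = side * math.sin(a) * length
        dy = -math.cos(a) * length
        end = (base_xy[0] + dx, base_xy[1] + dy)
        _capsule(canvas, pt(*base_xy), pt(*end), width * S)
        return end

    # trunk, neck, head
    _capsule(canvas, pt(0, 0.0), pt(0, 0.36), 0.090 * S)
    _capsule(canvas, pt(0, 0.36), pt(0, 0.43), 0.035 * S)
    rr, cc = draw_disk(pt(0, 0.52), 0.080 * S, shape=canvas.shape)
    canvas[rr, cc] = True

    for side, arm, elbow, leg, knee in (
        (-1, pose.arm_l, pose.elbow_l, pose.leg_l, pose.knee_l),
        (+1, pose.arm_r, pose.elbow_r, pose.leg_r, pose.knee_r),
    ):
        shoulder = (side * 0.085, 0.335)
        wrist0 = limb(shoulder, 0.175, 0.0275, arm, side)
        limb(wrist0, 0.165, 0.0240, arm + elbow, side)
        hip = (side * 0.048, 0.01)
        knee0 = limb(hip, 0.255, 0.0400, leg, side)
        limb(knee0, 0.250, 0.0330, leg + knee, side)

    sil = Silhouette(canvas, id="humanoid")
    return standardize(sil, frame=frame)


def humanoid_posture_suite(
    n: int = 36, seed: int | None = None, frame: int = DEFAULT_FRAME
) -> list[Silhouette]:
    """Generate posture variants of the humanoid.

    Even-index variants are bilaterally symmetric, odd ones asymmetric,
    with joint angles covering the non-overlapping ranges (arms 25-80,
    elbows 0-30, legs 6-26, knees 0-15 degrees).  With ``seed`` set,
    angles are drawn reproducibly at random; otherwise a deterministic
    low-discrepancy schedule is used.
    """
    if n < 2:
        raise ValueError("need at least 2 posture variants")
    rng = np.random.default_rng(seed) if seed is not None else None
    golden = 0.6180339887498949
    variants = []
    for i in range(n):
        if rng is not None:
            u = rng.random(8)
        else:
            u = np.array([((i + 1) * golden * (k + 1)) % 1.0 for k in range(8)])
        arm_l = 25 + 55 * u[0]
        elbow_l = 30 * u[1]
        leg_l = 6 + 20 * u[2]
        knee_l = 15 * u[3]
        if i % 2 == 0:  # symmetric posture
            arm_r, elbow_r, leg_r, knee_r = arm_l, elbow_l, leg_l, knee_l
        else:
            arm_r = 25 + 55 * u[4]
            elbow_r = 30 * u[5]
            leg_r = 6 + 20 * u[6]
            knee_r = 15 * u[7]
        pose = HumanoidPose(arm_l, arm_r, elbow_l, elbow_r,
                            leg_l, leg_r, knee_l, knee_r)
        sil = make_humanoid(pose, frame=frame)
        sil.id = f"humanoid_{i:02d}"
        variants.append(sil)
    return variants
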