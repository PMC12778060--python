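"""Artificial biomorph simulators: the field of geometrically possible forms.

Two complementary generators chart the space of possibilities that real
organisms are compared against.  The Gielis superformula deforms a circle
in polar coordinates and produces rotationally symmetric, asymmetric or
spiral outlines reminiscent of cells, flowers and radiolarians.  The
vector model composes an elliptic body mass with radial, equiangular
appendage systems, covering bacterial-like peritrichous/lophotrichous
architectures with very thin appendages that the superformula cannot
reach.  Three post-transformations (central-mass addition,
skeletonization to threads, thickening) push shapes into otherwise empty
regions of the complexity space.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from skimage.draw import disk as draw_disk
from skimage.draw import line as draw_line
from skimage.draw import polygon as draw_polygon
from skimage.morphology import dilation, disk as disk_footprint

from .silhouettes import DEFAULT_BODY_LENGTH, DEFAULT_FRAME, Silhouette, standardize
from .skeletons import skeletonize_mask

__all__ = [
    "GielisParams",
    "VectorBiomorphParams",
    "SweepSpec",
    "gielis_radius",
    "render_gielis",
    "render_vector_biomorph",
    "transform_biomorph",
    "run_sweep",
]

#: Angular modifier functions f(phi) of the superformula.
MODIFIERS = {
    "1": lambda phi: np.ones_like(phi),
    "phi": lambda phi: phi,
    "sin_phi": np.sin,
    "cos_phi": np.cos,
    "sqrt_phi": lambda phi: np.sqrt(np.abs(phi)),
    "sin2_phi": lambda phi: np.sin(phi) ** 2,
    "cos2_phi": lambda phi: np.cos(phi) ** 2,
    "1+sin2_phi": lambda phi: 1.0 + np.sin(phi) ** 2,
    "1+cos2_phi": lambda phi: 1.0 + np.cos(phi) ** 2,
    "atan_phi": np.arctan,
}


@dataclass(frozen=True)
class GielisParams:
    """Parameters of the superformula ``r(phi)``.

    ``m`` sets the order of rotational symmetry; ``n2``/``n3`` control
    corner homogeneity and edge concavity/convexity; ``n1`` the sharpness
    of corners; ``a``/``b`` the magnitude of the deformations.  ``f_kind``
    names the angular modifier (identity leaves the shape unchanged;
    monotone modifiers such as ``phi`` open the outline into a spiral).
    ``smoothing_p``, when set, low-pass filters the radius profile by a
    truncated Fourier series of that order.  ``closed`` selects filled
    region vs 1-px stroked curve rendering.
    """

    m: float = 4.0
    n1: float = 2.0
    n2: float = 2.0
    n3: float = 2.0
    a: float = 1.0
    b: float = 1.0
    f_kind: str = "1"
    smoothing_p: int | None = None
    phi_range: tuple[float, float] = (0.0, 2.0 * math.pi)
    closed: bool = True

    def __post_init__(self):
        if self.n1 == 0:
            raise ValueError("n1 must be nonzero")
        if self.a <= 0 or self.b <= 0:
            raise ValueError("a and b must be positive")
        if self.f_kind not in MODIFIERS:
            raise ValueError(f"unknown modifier {self.f_kind!r}")
        if self.closed and (self.phi_range[1] - self.phi_range[0]) < 2 * math.pi - 1e-9:
            raise ValueError("closed shapes need phi_range covering a full period")


def gielis_radius(p: GielisParams, phi):
    """Evaluate the superformula radius at angle(s) ``phi``.

    r = f(phi) * (|cos(m phi/4)/a|^n2 + |sin(m phi/4)/b|^n3)^(-1/n1)

    Angles where the bracket vanishes while the exponent is negative are
    undefined and returned as NaN (rendering skips them).
    """
    phi = np.asarray(phi, dtype=float)
    bracket = (
        np.abs(np.cos(p.m * phi / 4.0) / p.a) ** p.n2
        + np.abs(np.sin(p.m * phi / 4.0) / p.b) ** p.n3
    )
    f = MODIFIERS[p.f_kind](phi)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = f * bracket ** (-1.0 / p.n1)
    r = np.where(np.isfinite(r), r, np.nan)
    return float(r) if r.ndim == 0 else r


def _smooth_profile(r: np.ndarray, order: int) -> np.ndarray:
    """Truncate the Fourier series of a periodic radius profile."""
    coeffs = np.fft.rfft(r)
    coeffs[order + 1 :] = 0.0
    return np.fft.irfft(coeffs, n=len(r))


def render_gielis(
    p: GielisParams, n_phi: int = 3600, frame: int = DEFAULT_FRAME
) -> Silhouette:
    """Rasterize a superformula shape as a standardized silhouette.

    Closed shapes are filled polygons; open curves (spirals and other
    monotone modifiers) are stroked 1 px wide before standardization.
    """
    if n_phi < 720:
        raise ValueError("need n_phi >= 720 samples")
    lo, hi = p.phi_range
    phi = np.linspace(lo, hi, n_phi, endpoint=not p.closed)
    r = gielis_radius(p, phi)
    good = np.isfinite(r) & (r >= 0)
    phi, r = phi[good], r[good]
    if p.smoothing_p is not None and p.closed and len(r) == n_phi:
        r = np.clip(_smooth_profile(r, int(p.smoothing_p)), 0.0, None)
    if len(r) < 3 or np.nanmax(r) <= 0:
        raise ValueError("degenerate superformula shape (fewer than 3 vertices)")
    x = r * np.cos(phi)
    y = r * np.sin(phi)
    span = max(x.max() - x.min(), y.max() - y.min())
    if span <= 0:
        raise ValueError("degenerate superformula shape (zero extent)")
    scale = (DEFAULT_BODY_LENGTH - 4) / span
    cols = np.round((x - x.min()) * scale).astype(int) + 2
    rows = np.round((y - y.min()) * scale).astype(int) + 2
    canvas = np.zeros((rows.max() + 3, cols.max() + 3), dtype=bool)
    if p.closed:
        rr, cc = draw_polygon(rows, cols, shape=canvas.shape)
        canvas[rr, cc] = True
        canvas[rows, cols] = True  # keep the outline itself
    else:
        for k in range(len(rows) - 1):
            rr, cc = draw_line(rows[k], cols[k], rows[k + 1], cols[k + 1])
            canvas[rr, cc] = True
    if len(np.unique(np.column_stack([rows, cols]), axis=0)) < 3:
        raise ValueError("degenerate superformula shape (fewer than 3 vertices)")
    return standardize(Silhouette(canvas, id="gielis"), frame=frame)


@dataclass(frozen=True)
class VectorBiomorphParams:
    """Parameters of the elliptic-mass + appendage-system model.

    The body mass is an ellipse of relative length ``S_M`` (fraction of
    the 860-px shape length) and rotundity ``R_M`` (height/width ratio),
    oriented ``O_M`` (parallel or perpendicular to the major axis).  A
    primary appendage system of ``N_P`` straight lines (base length
    430 px, thickness ``T_P`` x 860 px) fans equiangularly over ``Ro_P``
    degrees around the anchor ``A_P`` (mass center or periphery), with
    optional deformation ``D_P`` stretching the total length to 860 px
    and/or compressing the fan toward the mass height.  A secondary
    system of ``N_S`` appendages (relative size ``S_S``) is intercalated
    midway between primary ones over its own span ``Ro_S``.
    """

    R_M: float = 1.0
    S_M: float = 0.5
    O_M: str = "parallel"
    A_P: str = "center"
    N_P: int = 0
    Ro_P: float = 360.0
    T_P: float = 0.002
    D_P: str = "none"
    N_S: int = 0
    Ro_S: float = 360.0
    S_S: float = 0.25

    def __post_init__(self):
        if not (0.001 < self.R_M <= 1.0):
            raise ValueError("R_M must be in (0.001, 1]")
        if not (0.0 <= self.S_M <= 1.0):
            raise ValueError("S_M must be in [0, 1]")
        if self.S_M == 0 and self.N_P < 1:
            raise ValueError("shape is empty: need S_M > 0 or N_P >= 1")
        if self.O_M not in ("parallel", "perpendicular"):
            raise ValueError("O_M must be 'parallel' or 'perpendicular'")
        if self.A_P not in ("center", "periphery"):
            raise ValueError("A_P must be 'center' or 'periphery'")
        if not (0 <= self.N_P <= 2000) or not (0 <= self.N_S <= 1500):
            raise ValueError("appendage counts out of range")
        if self.N_P and not (0.0 < self.Ro_P <= 360.0):
            raise ValueError("Ro_P must be in (0, 360]")
        if self.D_P not in ("none", "stretch", "compress", "both"):
            raise ValueError("unknown deformation D_P")
        if self.N_S and not (0.015 < self.S_S <= 1.0):
            raise ValueError("S_S must be in (0.015, 1]")


def _thick_segment(canvas, p0, p1, halfwidth):
    if halfwidth < 0.75:
        rr, cc = draw_line(int(round(p0[0])), int(round(p0[1])),
                           int(round(p1[0])), int(round(p1[1])))
        ok = (rr >= 0) & (rr < canvas.shape[0]) & (cc >= 0) & (cc < canvas.shape[1])
        canvas[rr[ok], cc[ok]] = True
        return
    dr, dc = p1[0] - p0[0], p1[1] - p0[1]
    norm = math.hypot(dr, dc)
    if norm < 1e-9:
        return
    ur, uc = -dc / norm, dr / norm
    rr, cc = draw_polygon(
        [p0[0] + ur * halfwidth, p1[0] + ur * halfwidth,
         p1[0] - ur * halfwidth, p0[0] - ur * halfwidth],
        [p0[1] + uc * halfwidth, p1[1] + uc * halfwidth,
         p1[1] - uc * halfwidth, p0[1] - uc * halfwidth],
        shape=canvas.shape,
    )
    canvas[rr, cc] = True


def render_vector_biomorph(
    p: VectorBiomorphParams, frame: int = DEFAULT_FRAME
) -> Silhouette:
    """Rasterize a vector biomorph as a standardized silhouette."""
    L = DEFAULT_BODY_LENGTH
    big = 2 * L + 200
    canvas = np.zeros((big, big), dtype=bool)
    center = (big / 2.0, big / 2.0)

    mass_len = p.S_M * L
    # R_M is height over width of the mass ellipse.
    width = mass_len
    height = max(1.0, p.R_M * width) if mass_len > 0 else 0.0
    if mass_len > 0:
        if p.O_M == "parallel":
            r_rad, c_rad = height / 2.0, width / 2.0
        else:
            r_rad, c_rad = width / 2.0, height / 2.0
        from skimage.draw import ellipse as draw_ellipse

        rr, cc = draw_ellipse(center[0], center[1], max(r_rad, 0.5),
                              max(c_rad, 0.5), shape=canvas.shape)
        canvas[rr, cc] = True

    app_len = 430.0
    if p.D_P in ("stretch", "both") and p.N_P:
        # stretch the primary system so the composition spans the full
        # 860-px length: anchor-to-tip reach = half mass + appendage
        reach = L / 2.0 if p.A_P == "center" else L - mass_len
        app_len = max(app_len, reach if p.A_P == "periphery" else L / 2.0)
    compress = None
    if p.D_P in ("compress", "both") and p.N_P:
        # squash the fan's extent perpendicular to the major axis down to
        # the body-mass height
        compress = max(height / (2.0 * app_len), 0.02)

    thickness = max(1.0, p.T_P * L)
    anchor = center if p.A_P == "center" else (center[0], center[1] + mass_len / 2.0)

    def draw_fan(n, span_deg, length, thick):
        if n == 0:
            return []
        if span_deg >= 360.0 - 1e-9:
            angles = np.linspace(0.0, 360.0, n, endpoint=False)
        elif n == 1:
            angles = np.array([0.0])
        else:
            angles = np.linspace(-span_deg / 2.0, span_deg / 2.0, n)
        for adeg in angles:
            a = math.radians(adeg)
            dy = math.sin(a) * length
            dx = math.cos(a) * length
            if compress is not None:
                dy *= compress
            _thick_segment(canvas, anchor, (anchor[0] + dy, anchor[1] + dx),
                           thick / 2.0)
        return list(angles)

    prim = draw_fan(p.N_P, p.Ro_P, app_len, thickness)
    if p.N_S:
        sec_len = p.S_S * L
        if len(prim) >= 2:
            mids = [(a + b) / 2.0 for a, b in zip(prim[:-1], prim[1:])]
            if p.Ro_P >= 360.0 - 1e-9:
                mids.append((prim[-1] + prim[0] + 360.0) / 2.0)
            mids = (mids * (p.N_S // len(mids) + 1))[: p.N_S]
            for adeg in mids:
                a = math.radians(adeg)
                dy = math.sin(a) * sec_len
                dx = math.cos(a) * sec_len
                if compress is not None:
                    dy *= compress
                _thick_segment(canvas, anchor, (anchor[0] + dy, anchor[1] + dx),
                               thickness / 2.0)
        else:
            span = p.Ro_S
            saved = prim
            draw_fan(p.N_S, span, sec_len, thickness)
            prim = saved
    if not canvas.any():
        raise ValueError("empty biomorph composition")
    return standardize(Silhouette(canvas, id="vector_biomorph"), frame=frame)


def transform_biomorph(sil: Silhouette, op: str, radius: int = 100, k: int = 1) -> Silhouette:
    """Post-transformations pushing shapes into new regions of the space.

    ``add_central_mass`` unions a centered disk of ``radius`` px;
    ``to_thread`` replaces the mask by its topological skeleton;
    ``thicken`` dilates by ``k`` px.
    """
    if op == "add_central_mass":
        out = sil.pixels.copy()
        rr, cc = draw_disk((out.shape[0] // 2, out.shape[1] // 2), radius,
                           shape=out.shape)
        out[rr, cc] = True
        return sil.copy_with(out)
    if op == "to_thread":
        return skeletonize_mask(sil)
    if op == "thicken":
        if k < 1:
            raise ValueError("thicken needs k >= 1")
        return sil.copy_with(
            dilation(sil.pixels, disk_footprint(k)), is_skeleton=False
        )
    raise ValueError(f"unknown transform {op!r}")


# ---------------------------------------------------------------------------
# Parameter sweeps


@dataclass(frozen=True)
class SweepSpec:
    """A reproducible biomorph sweep.

    ``generator`` is ``"gielis"`` or ``"vector"``; ``grid`` maps parameter
    names to explicit value lists combined as a full factorial;
    ``random`` maps parameter names to (low, high) ranges sampled
    uniformly (integer parameters when both bounds are ints); ``n`` is
    the target shape count and ``seed`` fixes the sampling.
    """

    generator: str = "gielis"
    n: int = 100
    seed: int = 0
    grid: dict = field(default_factory=dict)
    random: dict = field(default_factory=dict)
    fixed: dict = field(default_factory=dict)
    transforms: tuple = ()

    def __post_init__(self):
        if self.generator not in ("gielis", "vector"):
            raise ValueError("generator must be 'gielis' or 'vector'")
        if self.n < 1:
            raise ValueError("sweep needs n >= 1")


def _param_sets(spec: SweepSpec) -> list[dict]:
    rng = np.random.default_rng(spec.seed)
    sets: list[dict] = []
    if spec.grid:
        keys = sorted(spec.grid)
        from itertools import product

        for combo in product(*(spec.grid[k] for k in keys)):
            sets.append(dict(zip(keys, combo)))
    while len(sets) < spec.n:
        d = {}
        for k in sorted(spec.random):
            lo, hi = spec.random[k]
            if isinstance(lo, int) and isinstance(hi, int):
                d[k] = int(rng.integers(lo, hi + 1))
            else:
                d[k] = float(rng.uniform(lo, hi))
        sets.append(d)
    sets = sets[: spec.n]
    for d in sets:
        d.update(spec.fixed)
    return sets


def run_sweep(spec: SweepSpec) -> tuple[list[Silhouette], pd.DataFrame]:
    """Generate a deterministic biomorph set with a parameter manifest.

    Raises if more than 10% of the attempted parameter sets fail to
    render (degenerate shapes are skipped with a manifest-less log).
    """
    cls = GielisParams if spec.generator == "gielis" else VectorBiomorphParams
    shapes: list[Silhouette] = []
    rows: list[dict] = []
    failures = 0
    for i, params in enumerate(_param_sets(spec)):
        try:
            p = cls(**params)
            if spec.generator == "gielis":
                sil = render_gielis(p)
            else:
                sil = render_vector_biomorph(p)
            for op in spec.transforms:
                sil = transform_biomorph(sil, op)
        except (ValueError, ArithmeticError):
            failures += 1
            continue
        sil.id = f"{spec.generator}_{spec.seed}_{i:05d}"
        shapes.append(sil)
        row = {"id": sil.id, "generator": spec.generator, "seed": spec.seed,
               "params": json.dumps(asdict(p), sort_keys=True, default=str)}
        rows.append(row)
    if failures > 0.1 * spec.n:
        raise RuntimeError(
            f"sustained generation failures: {failures}/{spec.n} attempts"
        )
    return shapes, pd.DataFrame(rows)
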