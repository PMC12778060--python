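"""The geometric complexity space: ordination, density and disparity.

Specimens live in a 4-parameter space (D_SI, D_SK, L_SI, L_SK).  This
module assembles measurement tables into analysis-ready matrices,
projects them to 2-D with Isomap (k-nearest-neighbor graph, geodesic
shortest paths, classical metric scaling), maps point densities with an
isotropic Gaussian kernel, and quantifies group disparity as
bootstrapped, rarefied ratios of generalized variances (determinants of
group covariance matrices), with the highest-variance group fixed as the
common denominator.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components, shortest_path
from scipy.spatial.distance import cdist, pdist, squareform

from .fractal import ProtocolConfig, DEFAULT_PROTOCOL, measure_protocol
from .silhouettes import Silhouette

__all__ = [
    "ComplexityDataset",
    "Embedding",
    "DensityGrid",
    "DisparityResult",
    "assemble",
    "isomap_embed",
    "kde_map",
    "generalized_variance",
    "rgv_disparity",
    "posture_sensitivity",
]

log = logging.getLogger(__name__)

PARAM_COLUMNS = ["D_SI", "D_SK", "L_SI", "L_SK"]


@dataclass
class ComplexityDataset:
    """Specimens x 4 parameters, with group labels."""

    X: np.ndarray
    ids: list[str]
    groups: np.ndarray
    standardized: bool

    def __len__(self) -> int:
        return len(self.X)

    def group_rows(self, name) -> np.ndarray:
        return self.X[self.groups == name]


@dataclass
class Embedding:
    coords: np.ndarray
    k: int
    eigenvalues: np.ndarray
    n_components_graph: int = 1


@dataclass
class DensityGrid:
    values: np.ndarray
    x_edges: np.ndarray
    y_edges: np.ndarray
    radius: float


@dataclass
class DisparityResult:
    """Bootstrapped rarefied ratio-of-generalized-variances summaries."""

    groups: list
    full_gv: dict
    denominator_group: object
    ratios: dict  # group -> bootstrap distribution (np.ndarray)
    summary: pd.DataFrame
    n_rarefy: int
    n_boot: int
    seed: int


def assemble(table: pd.DataFrame, standardize: bool = True) -> ComplexityDataset:
    """Build the parameter matrix from a measurement table.

    Singular specimens (point skeletons: the shape has no linear
    structure, so the skeleton axes are undefined) are dropped with a
    logged count.  With ``standardize`` each column is z-scored.
    """
    df = table.copy()
    if "singular" in df.columns:
        n_sing = int(df["singular"].sum())
        if n_sing:
            log.info("%d singular specimen(s) excluded", n_sing)
        df = df[~df["singular"].astype(bool)]
    df = df.dropna(subset=PARAM_COLUMNS)
    if len(df) < 2:
        raise ValueError("fewer than 2 non-singular rows")
    X = df[PARAM_COLUMNS].to_numpy(dtype=float)
    if standardize:
        sd = X.std(axis=0, ddof=0)
        sd[sd == 0] = 1.0
        X = (X - X.mean(axis=0)) / sd
    groups = (
        df["group"].to_numpy() if "group" in df.columns else np.array([""] * len(df))
    )
    return ComplexityDataset(
        X=X, ids=[str(i) for i in df["id"]], groups=groups, standardized=standardize
    )


# ---------------------------------------------------------------------------
# Isomap


def isomap_embed(
    data: ComplexityDataset | np.ndarray,
    k: int = 100,
    dims: int = 2,
    largest_component: bool = False,
) -> Embedding:
    """Isomap ordination of the parameter space.

    Builds a symmetric k-nearest-neighbor graph on Euclidean distances,
    estimates geodesics as graph shortest paths, and applies classical
    (Torgerson) metric scaling to the geodesic matrix.  With ``k`` at
    least n-1 the graph is complete and the result coincides with
    classical scaling of the plain Euclidean matrix.
    """
    X = data.X if isinstance(data, ComplexityDataset) else np.asarray(data, float)
    n = len(X)
    if n < 3:
        raise ValueError("need at least 3 points to embed")
    k_eff = min(k, n - 1)
    D = squareform(pdist(X))
    # k-NN graph, symmetrized by union
    order = np.argsort(D, axis=1)[:, 1 : k_eff + 1]
    rows = np.repeat(np.arange(n), k_eff)
    cols = order.ravel()
    w = D[rows, cols]
    graph = csr_matrix((w, (rows, cols)), shape=(n, n))
    graph = graph.maximum(graph.T)
    n_comp, labels = connected_components(graph, directed=False)
    if n_comp > 1:
        sizes = np.bincount(labels)
        if not largest_component:
            raise ValueError(
                f"neighborhood graph is disconnected (k={k_eff}): component "
                f"sizes {sorted(sizes.tolist(), reverse=True)}; raise k or pass "
                "largest_component=True"
            )
        keep = labels == np.argmax(sizes)
        sub = isomap_embed(X[keep], k=k, dims=dims)
        return Embedding(sub.coords, k_eff, sub.eigenvalues, n_components_graph=n_comp)
    G = shortest_path(graph, method="D", directed=False)
    # classical metric scaling (principal coordinates) of geodesics
    G2 = G**2
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ G2 @ J
    B = (B + B.T) / 2.0
    evals, evecs = np.linalg.eigh(B)
    idx = np.argsort(evals)[::-1][:dims]
    lam = np.clip(evals[idx], 0.0, None)
    coords = evecs[:, idx] * np.sqrt(lam)
    # deterministic sign convention: largest-magnitude loading positive
    for j in range(coords.shape[1]):
        col = coords[:, j]
        if len(col) and col[np.argmax(np.abs(col))] < 0:
            coords[:, j] = -col
    return Embedding(coords=coords, k=k_eff, eigenvalues=evals[idx])


# ---------------------------------------------------------------------------
# Kernel density maps


def kde_map(
    points: np.ndarray,
    radius: float = 0.15,
    grid: int = 200,
    bounds: tuple | None = None,
) -> DensityGrid:
    """Gaussian kernel density of embedded points on a regular grid.

    Each point contributes an isotropic normalized Gaussian with scale
    parameter ``radius`` (so the map integrates to the point count within
    the grid bounds, up to edge truncation).
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if pts.shape[0] < 1 or radius <= 0:
        raise ValueError("need >= 1 point and a positive radius")
    if bounds is None:
        pad = 3.0 * radius
        bounds = (
            pts[:, 0].min() - pad,
            pts[:, 0].max() + pad,
            pts[:, 1].min() - pad,
            pts[:, 1].max() + pad,
        )
    x0, x1, y0, y1 = bounds
    xe = np.linspace(x0, x1, grid + 1)
    ye = np.linspace(y0, y1, grid + 1)
    xc = (xe[:-1] + xe[1:]) / 2.0
    yc = (ye[:-1] + ye[1:]) / 2.0
    gx, gy = np.meshgrid(xc, yc, indexing="ij")
    nodes = np.column_stack([gx.ravel(), gy.ravel()])
    d2 = cdist(nodes, pts, "sqeuclidean")
    dens = np.exp(-d2 / (2.0 * radius**2)).sum(axis=1) / (2.0 * np.pi * radius**2)
    return DensityGrid(
        values=dens.reshape(grid, grid), x_edges=xe, y_edges=ye, radius=radius
    )


# ---------------------------------------------------------------------------
# Disparity


def generalized_variance(rows: np.ndarray) -> float:
    """Determinant of the sample covariance matrix (denominator n-1)."""
    X = np.asarray(rows, dtype=float)
    n, d = X.shape
    if n < d + 1:
        raise ValueError(f"need at least {d + 1} rows for a {d}-D covariance")
    return float(np.linalg.det(np.cov(X, rowvar=False, ddof=1)))


def rgv_disparity(
    data: ComplexityDataset,
    groups=None,
    n_rarefy: int = 50,
    n_boot: int = 1000,
    seed: int = 0,
    replace: bool = False,
    per_replicate_denominator: bool = False,
) -> DisparityResult:
    """Bootstrapped, rarefied ratios of generalized variances.

    Each bootstrap replicate draws ``n_rarefy`` rows per group (without
    replacement by default) and computes each group's generalized
    variance.  Ratios are expressed against the group with the highest
    full-sample generalized variance (the common denominator), on the
    generalized-standard-deviation scale: ratio = sqrt(GV_g / GV_denom).
    The square root makes the statistic scale as c^dims when a group
    shrinks isotropically by c (the raw determinant ratio scales as
    c^(2 dims)), which is the natural "occupied fraction of the field"
    reading.  Groups smaller than ``n_rarefy`` are rarefied to their own
    size with a warning.
    """
    if seed is None:
        raise ValueError("seed is required for reproducible bootstraps")
    names = list(groups) if groups is not None else sorted(set(data.groups.tolist()))
    dims = data.X.shape[1]
    rows_by_group = {}
    r_by_group = {}
    for g in names:
        rows = data.group_rows(g)
        if len(rows) < dims + 2:
            raise ValueError(f"group {g!r} has {len(rows)} rows; need >= {dims + 2}")
        r = n_rarefy
        if len(rows) < n_rarefy:
            log.warning(
                "group %r has %d rows < n_rarefy=%d; rarefying to its size",
                g, len(rows), n_rarefy,
            )
            r = len(rows)
        rows_by_group[g] = rows
        r_by_group[g] = r

    full_gv = {g: generalized_variance(rows_by_group[g]) for g in names}
    denom_group = max(full_gv, key=full_gv.get)

    rng = np.random.default_rng(seed)
    boot_gv = {g: np.empty(n_boot) for g in names}
    for b in range(n_boot):
        for g in names:
            rows = rows_by_group[g]
            idx = (
                rng.integers(0, len(rows), r_by_group[g])
                if replace
                else rng.choice(len(rows), size=r_by_group[g], replace=False)
            )
            boot_gv[g][b] = generalized_variance(rows[idx])
    if per_replicate_denominator:
        denom_vals = np.max(np.column_stack([boot_gv[g] for g in names]), axis=1)
    else:
        # denominator group fixed from full-sample GVs so ratios are
        # comparable across replicates
        denom_vals = boot_gv[denom_group]
    ratios = {g: np.sqrt(np.clip(boot_gv[g] / denom_vals, 0.0, None)) for g in names}
    summary = pd.DataFrame(
        {
            "group": names,
            "gv_full": [full_gv[g] for g in names],
            "ratio_mean": [float(np.mean(ratios[g])) for g in names],
            "ratio_sd": [float(np.std(ratios[g], ddof=0)) for g in names],
            "ratio_q25": [float(np.quantile(ratios[g], 0.25)) for g in names],
            "ratio_median": [float(np.quantile(ratios[g], 0.5)) for g in names],
            "ratio_q75": [float(np.quantile(ratios[g], 0.75)) for g in names],
        }
    )
    return DisparityResult(
        groups=names,
        full_gv=full_gv,
        denominator_group=denom_group,
        ratios=ratios,
        summary=summary,
        n_rarefy=n_rarefy,
        n_boot=n_boot,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Posture sensitivity


def posture_sensitivity(
    variants: list[Silhouette], config: ProtocolConfig = DEFAULT_PROTOCOL
) -> dict:
    """Two-sigma spread of the four parameters across posture variants.

    Measures every variant of one articulated form under the full
    protocol and reports 2 x SD per parameter; skeleton-based metrics are
    expected to be far more stable under limb repositioning than
    silhouette-based ones.
    """
    if len(variants) < 2:
        raise ValueError("need at least 2 posture variants")
    meas = [measure_protocol(v, config) for v in variants]
    out = {}
    for p in PARAM_COLUMNS:
        vals = np.array([getattr(m, p) for m in meas])
        out[f"two_sigma_{p}"] = float(2.0 * vals.std(ddof=0))
    out["n_variants"] = len(variants)
    out["measurements"] = meas
    return out
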