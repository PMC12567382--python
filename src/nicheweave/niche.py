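"""Realized climate niches as convex hulls in PCA space, and their overlap.

The nine harmonic predictors of all grid cells define a common environmental
space.  A centered, unit-variance PCA of that background reduces it to two
orthogonal axes; each taxon's realized niche within an ecosystem is the
convex hull of its presence cells projected onto those axes.  Niche sharing
between a tick and a host is the Jaccard overlap of their hulls,

    J = 100 * area(H1 n H2) / (area(H1) + area(H2) - area(H1 n H2))

reported as a percentage in [0, 100].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, QhullError
from shapely.geometry import Polygon
from sklearn.decomposition import PCA

from .grids import EcosystemMap, PredictorStack


@dataclass
class PCASpace:
    """Fitted PCA: loadings, explained variance, and the scaling applied."""

    loadings: np.ndarray  # (n_features, k)
    explained_variance_ratio: np.ndarray
    center: np.ndarray
    scale: np.ndarray
    kept_columns: np.ndarray  # indices of non-degenerate input columns

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)[:, self.kept_columns]
        return (X - self.center) / self.scale @ self.loadings

    def inverse_transform(self, scores: np.ndarray) -> np.ndarray:
        """Back-project to the centered/scaled feature space (kept columns)."""
        return np.asarray(scores) @ self.loadings.T


@dataclass
class NicheHull:
    """Convex niche polygon of one taxon in one ecosystem (2-D PC space)."""

    taxon_id: str
    ecosystem_id: int | None
    vertices: np.ndarray  # (m, 2) counter-clockwise, not repeated at the end
    area: float
    n_source_points: int
    degenerate: bool = False

    def polygon(self) -> Polygon:
        if self.degenerate:
            raise ValueError("degenerate hull has no polygon")
        return Polygon(self.vertices)


@dataclass
class OverlapMatrix:
    """Tick x host Jaccard overlap percentages for one ecosystem.

    ``defined`` flags cells where both taxa had a non-degenerate hull in the
    ecosystem; undefined cells are excluded from all averages.
    """

    ecosystem_id: int
    values: pd.DataFrame  # ticks (rows) x hosts (cols), percentages
    defined: pd.DataFrame = field(default=None)

    def __post_init__(self) -> None:
        if self.defined is None:
            self.defined = ~self.values.isna()

    @property
    def tick_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def host_ids(self) -> list[str]:
        return list(self.values.columns)


def fit_pca(table: np.ndarray, k: int = 2) -> PCASpace:
    """Centered, unit-variance PCA of the background predictor table.

    Zero-variance columns are dropped with a warning.  The sign of each axis
    is fixed so the loading with the largest magnitude is positive.
    """
    X = np.asarray(table, dtype=float)
    if k < 1:
        raise ValueError("k must be >= 1")
    if X.shape[0] < k + 1:
        raise ValueError("need at least k + 1 rows to fit a PCA")
    sd = X.std(axis=0, ddof=1)
    kept = np.flatnonzero(sd > 0)
    if kept.size < X.shape[1]:
        warnings.warn(
            f"dropping {X.shape[1] - kept.size} zero-variance column(s)", stacklevel=2
        )
    if kept.size == 0:
        raise ValueError("all columns have zero variance")
    center = X[:, kept].mean(axis=0)
    scale = sd[kept]
    Z = (X[:, kept] - center) / scale
    pca = PCA(n_components=min(k, kept.size), svd_solver="full")
    pca.fit(Z)
    loadings = pca.components_.T.copy()  # (n_kept, k)
    for j in range(loadings.shape[1]):
        i = int(np.argmax(np.abs(loadings[:, j])))
        if loadings[i, j] < 0:
            loadings[:, j] *= -1
    return PCASpace(
        loadings=loadings,
        explained_variance_ratio=pca.explained_variance_ratio_.copy(),
        center=center,
        scale=scale,
        kept_columns=kept,
    )


def taxon_niche_points(
    binary: np.ndarray,
    eco: EcosystemMap,
    ecosystem_id: int,
    space: PCASpace,
    predictors: PredictorStack,
) -> np.ndarray:
    """Projected predictor vectors of cells predicted present inside an ecosystem.

    Returns an (n, 2) array; empty when the taxon does not occur in the
    ecosystem (flagged downstream, not an error).
    """
    binary = np.asarray(binary)
    if binary.shape != eco.labels.shape or binary.shape != predictors.mask.shape:
        raise ValueError("binary map, ecosystem map and predictors must share geometry")
    select = (binary > 0) & eco.cells_of(ecosystem_id) & ~predictors.mask
    if not np.any(select):
        return np.empty((0, 2))
    X = predictors.layers[:, select].T
    return space.transform(X)[:, :2]


def occurrence_niche_points(
    occurrences,
    eco: EcosystemMap,
    ecosystem_id: int,
    space: PCASpace,
    predictors: PredictorStack,
) -> np.ndarray:
    """Raw-occurrence alternative to :func:`taxon_niche_points`.

    Uses the predictor vectors of the cells holding occurrence records
    (rather than modelled presence cells) that fall inside the ecosystem.
    """
    geom = predictors.geometry
    inside = eco.cells_of(ecosystem_id) & ~predictors.mask
    rows = []
    for lon, lat in zip(occurrences["lon"], occurrences["lat"]):
        r, c = geom.cell_index(float(lon), float(lat))
        if inside[r, c]:
            rows.append(predictors.cell_vector(r, c))
    if not rows:
        return np.empty((0, 2))
    return space.transform(np.stack(rows))[:, :2]


def convex_hull(
    points: np.ndarray, taxon_id: str = "", ecosystem_id: int | None = None
) -> NicheHull:
    """Convex hull of a 2-D point set with shoelace area.

    Fewer than three points, or collinear points, yield a degenerate hull
    (area 0, flagged) rather than an error: an unresolvable niche cannot
    share area but should not stop a batch run.
    """
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    if pts.shape[0] < 3:
        return NicheHull(taxon_id, ecosystem_id, pts.copy(), 0.0, pts.shape[0], True)
    try:
        hull = ConvexHull(pts)
    except QhullError:  # collinear / duplicate input
        return NicheHull(taxon_id, ecosystem_id, pts.copy(), 0.0, pts.shape[0], True)
    vertices = pts[hull.vertices]  # scipy returns CCW order in 2-D
    return NicheHull(
        taxon_id=taxon_id,
        ecosystem_id=ecosystem_id,
        vertices=vertices,
        area=float(hull.volume),  # "volume" is the area in 2-D
        n_source_points=pts.shape[0],
    )


def shoelace_area(vertices: np.ndarray) -> float:
    v = np.asarray(vertices, dtype=float)
    x, y = v[:, 0], v[:, 1]
    return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


def hull_intersection_area(h1: NicheHull, h2: NicheHull) -> float:
    """Area of the convex intersection polygon; 0 if disjoint or degenerate."""
    if h1.degenerate or h2.degenerate:
        return 0.0
    return float(h1.polygon().intersection(h2.polygon()).area)


def jaccard_overlap(h1: NicheHull, h2: NicheHull) -> float:
    """Jaccard overlap percentage of two niche hulls, 0-100.

    Degenerate hulls score 0; two degenerate hulls are undefined (NaN).
    """
    if h1.degenerate and h2.degenerate:
        return float("nan")
    if h1.degenerate or h2.degenerate:
        return 0.0
    p1, p2 = h1.polygon(), h2.polygon()
    inter = p1.intersection(p2).area
    # the union area equals A1 + A2 - intersection; computing it with the
    # same polygon backend keeps identical hulls at exactly 100
    union = p1.union(p2).area
    if union <= 0:
        return float("nan")
    return 100.0 * inter / union


def ecosystem_overlap_matrix(
    tick_hulls: dict[str, NicheHull],
    host_hulls: dict[str, NicheHull],
    ecosystem_id: int,
) -> OverlapMatrix:
    """Full tick x host Jaccard table for one ecosystem.

    Cells where either hull is degenerate (taxon effectively absent from the
    ecosystem) are flagged undefined.
    """
    if not any(not h.degenerate for h in tick_hulls.values()) or not any(
        not h.degenerate for h in host_hulls.values()
    ):
        raise ValueError(f"no defined niche hull on one side in ecosystem {ecosystem_id}")
    ticks = list(tick_hulls)
    hosts = list(host_hulls)
    values = pd.DataFrame(np.nan, index=ticks, columns=hosts)
    defined = pd.DataFrame(False, index=ticks, columns=hosts)
    for t in ticks:
        for h in hosts:
            ht, hh = tick_hulls[t], host_hulls[h]
            if ht.degenerate or hh.degenerate:
                continue
            values.loc[t, h] = jaccard_overlap(ht, hh)
            defined.loc[t, h] = True
    return OverlapMatrix(ecosystem_id=ecosystem_id, values=values, defined=defined)


def biotic_suitability(matrix: OverlapMatrix, tick_id: str) -> float:
    """Mean Jaccard overlap of one tick with the hosts of the same ecosystem.

    Undefined cells (host absent from the ecosystem) are excluded; a tick
    with no defined host cell has undefined biotic suitability (NaN).
    """
    if tick_id not in matrix.tick_ids:
        raise KeyError(f"tick {tick_id!r} not in overlap matrix")
    row = matrix.values.loc[tick_id]
    ok = matrix.defined.loc[tick_id]
    if not ok.any():
        return float("nan")
    return float(row[ok].mean())


def overlap_matrix_to_csv(matrix: OverlapMatrix, path) -> None:
    """Ticks as rows, hosts as columns; undefined cells left empty."""
    out = matrix.values.where(matrix.defined)
    out.to_csv(path, index_label="tick_id")


def overlap_matrix_from_csv(path, ecosystem_id: int) -> OverlapMatrix:
    values = pd.read_csv(path, index_col="tick_id")
    return OverlapMatrix(ecosystem_id=ecosystem_id, values=values)
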