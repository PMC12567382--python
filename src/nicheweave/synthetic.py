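"""Synthetic study systems with known ground truth.

Every input the real analysis takes from external repositories — monthly
climate rasters, an ecosystem map, georeferenced tick and host records, a
host phylogeny — is emulated here with known generating parameters, so each
downstream stage admits parameter-recovery tests:

* climate follows a first-order annual harmonic per variable whose
  coefficients vary along a latitudinal gradient, plus i.i.d. Gaussian
  noise (default sd = 5% of the local seasonal amplitude);
* virtual taxa have Gaussian (bell-shaped) climate niches in the 9-D
  predictor space, the virtual-species standard, which makes true niche
  hulls ellipsoidal and their overlap controllable;
* occurrence records are drawn with replacement across cells with
  probability proportional to true suitability (repeat records at a
  locality occur in real tick data);
* phylogenies are Yule trees; tip traits follow lambda-transformed
  Brownian motion.

One global seed expands into independent per-stage seeds through
:func:`child_seed` (SHA-256 of ``"{seed}:{stage}"``, truncated below 2^31),
so stages are reproducible in isolation.
"""

from __future__ import annotations

import hashlib
import random
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd
from dendropy.simulate import treesim
from sklearn.cluster import KMeans

from . import niche
from .grids import CLIMATE_VARIABLES, ClimateGrid, EcosystemMap, GridGeometry, PredictorStack
from .phylo import lambda_transform, phylo_vcv

# Anchor harmonic coefficients (a0, a1, b1) at the southern and northern
# grid edges, loosely emulating a Mediterranean-to-boreal transect:
# warm south with strong annual cycle, cold north, drier air northwards.
DEFAULT_REGIONAL_HARMONICS = (
    {"tmax": (22.0, -9.0, -4.0), "tmin": (11.0, -7.0, -3.0), "vpd": (1.10, -0.50, -0.25)},
    {"tmax": (4.0, -12.0, -5.0), "tmin": (-4.0, -10.0, -4.0), "vpd": (0.35, -0.18, -0.08)},
)


def child_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the global seed."""
    digest = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


# ---------------------------------------------------------------------------
# Climate and ecosystems
# ---------------------------------------------------------------------------


def make_climate_grid(
    n_rows: int,
    n_cols: int,
    seed: int,
    regional_harmonics=DEFAULT_REGIONAL_HARMONICS,
    smooth: bool = True,
    noise_frac: float = 0.05,
    noise_sd: float | None = None,
    cell_size: float = 1.0,
) -> ClimateGrid:
    """Monthly climatologies from latitudinally varying annual harmonics.

    ``regional_harmonics`` lists per-band anchor coefficients from south to
    north.  With ``smooth=True`` coefficients are interpolated linearly
    between band centers (a smooth latitudinal gradient); otherwise each
    band is internally constant.  Noise is additive i.i.d. Gaussian per
    cell-month with sd ``noise_sd`` if given, else ``noise_frac`` times the
    local seasonal amplitude sqrt(a1^2 + b1^2).
    """
    if n_rows < 2 or n_cols < 2:
        raise ValueError("grid must be at least 2 x 2")
    bands = list(regional_harmonics)
    for band in bands:
        for var in CLIMATE_VARIABLES:
            if var not in band:
                raise ValueError(f"band parameters missing variable {var!r}")
            if not np.all(np.isfinite(band[var])):
                raise ValueError(f"non-finite harmonic parameters for {var!r}")
    if noise_sd is not None and (not np.isfinite(noise_sd) or noise_sd < 0):
        raise ValueError("noise_sd must be finite and non-negative")

    geometry = GridGeometry(n_rows=n_rows, n_cols=n_cols, cell_size=cell_size)
    rng = np.random.default_rng(seed)
    months = np.arange(1, 13)
    cos_m = np.cos(2 * np.pi * months / 12)
    sin_m = np.sin(2 * np.pi * months / 12)

    # per-row coefficient profiles, south (row 0) to north
    n_bands = len(bands)
    row_frac = (np.arange(n_rows) + 0.5) / n_rows
    if smooth and n_bands > 1:
        anchors = (np.arange(n_bands) + 0.5) / n_bands
    values: dict[str, np.ndarray] = {}
    for var in CLIMATE_VARIABLES:
        coef = np.array([band[var] for band in bands], dtype=float)  # (B, 3)
        if smooth and n_bands > 1:
            prof = np.stack([np.interp(row_frac, anchors, coef[:, c]) for c in range(3)], axis=1)
        else:
            band_of_row = np.minimum((row_frac * n_bands).astype(int), n_bands - 1)
            prof = coef[band_of_row]
        a0, a1, b1 = prof[:, 0], prof[:, 1], prof[:, 2]
        clean = (
            a0[None, :, None]
            + a1[None, :, None] * cos_m[:, None, None]
            + b1[None, :, None] * sin_m[:, None, None]
        )
        clean = np.broadcast_to(clean, (12, n_rows, n_cols)).copy()
        if noise_sd is not None:
            sd = np.full(n_rows, noise_sd)
        else:
            sd = noise_frac * np.hypot(a1, b1)
        noise = rng.standard_normal((12, n_rows, n_cols)) * sd[None, :, None]
        values[var] = clean + noise
    return ClimateGrid(geometry=geometry, values=values)


def make_ecosystem_map(
    grid: ClimateGrid,
    k: int,
    scheme: str = "latitudinal_bands",
    seed: int = 0,
) -> EcosystemMap:
    """Partition the grid into k ecosystems.

    ``latitudinal_bands`` slices rows into k near-equal contiguous bands;
    ``kmeans_on_climate`` clusters cells on their 36 monthly values and
    renumbers clusters south to north for stable labels.
    """
    geom = grid.geometry
    if k < 2:
        raise ValueError("need at least 2 ecosystems")
    if k > geom.n_cells:
        raise ValueError("more ecosystems than grid cells")
    if scheme == "latitudinal_bands":
        if k > geom.n_rows:
            raise ValueError("latitudinal bands need k <= n_rows")
        labels = np.empty((geom.n_rows, geom.n_cols), dtype=int)
        for i, rows in enumerate(np.array_split(np.arange(geom.n_rows), k)):
            labels[rows, :] = i
    elif scheme == "kmeans_on_climate":
        X = np.concatenate(
            [grid.values[var].reshape(12, -1) for var in CLIMATE_VARIABLES], axis=0
        ).T  # (cells, 36)
        X = (X - X.mean(axis=0)) / np.maximum(X.std(axis=0), 1e-12)
        km = KMeans(n_clusters=k, n_init=10, random_state=seed % (2**31))
        raw = km.fit_predict(X)
        # stable renumbering: order clusters by mean row index (latitude)
        rows = np.repeat(np.arange(geom.n_rows), geom.n_cols)
        order = np.argsort([rows[raw == c].mean() for c in range(k)])
        remap = np.empty(k, dtype=int)
        remap[order] = np.arange(k)
        labels = remap[raw].reshape(geom.n_rows, geom.n_cols)
    else:
        raise ValueError(f"unknown scheme {scheme!r}")
    legend = {i: f"eco_{i}" for i in range(k)}
    return EcosystemMap(geometry=geom, labels=labels, legend=legend)


# ---------------------------------------------------------------------------
# Virtual taxa and ground truth
# ---------------------------------------------------------------------------


@dataclass
class VirtualTaxon:
    """A virtual tick or host with a Gaussian climate niche.

    Suitability at predictor vector x is
    ``max_prevalence * exp(-0.5 * (x-c)' B^-1 (x-c))`` with niche center c
    and positive-definite breadth matrix B (a diagonal vector is accepted).
    """

    taxon_id: str
    role: str  # "tick" | "host"
    niche_center: np.ndarray
    niche_breadth: np.ndarray  # (9,) diagonal variances or (9, 9) SPD matrix
    max_prevalence: float = 1.0

    def __post_init__(self) -> None:
        if self.role not in ("tick", "host"):
            raise ValueError("role must be 'tick' or 'host'")
        self.niche_center = np.asarray(self.niche_center, dtype=float)
        if self.niche_center.shape != (9,):
            raise ValueError("niche_center must be a 9-vector")
        B = np.asarray(self.niche_breadth, dtype=float)
        if B.ndim == 1:
            if B.shape != (9,) or np.any(B <= 0):
                raise ValueError("diagonal breadth needs 9 positive variances")
        else:
            if B.shape != (9, 9) or not np.allclose(B, B.T):
                raise ValueError("breadth matrix must be symmetric 9 x 9")
            if np.any(np.linalg.eigvalsh(B) <= 0):
                raise ValueError("breadth matrix must be positive definite")
        self.niche_breadth = B
        if not (0 < self.max_prevalence <= 1):
            raise ValueError("max_prevalence must be in (0, 1]")

    def suitability(self, X: np.ndarray) -> np.ndarray:
        """Suitability in [0, max_prevalence] for rows of X (n, 9)."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        d = X - self.niche_center
        if self.niche_breadth.ndim == 1:
            m2 = np.sum(d**2 / self.niche_breadth, axis=1)
        else:
            m2 = np.einsum("ij,jk,ik->i", d, np.linalg.inv(self.niche_breadth), d)
        return self.max_prevalence * np.exp(-0.5 * m2)


@dataclass
class SyntheticTruth:
    """Generator-side ground truth for parameter-recovery tests."""

    taxa: list[VirtualTaxon]
    predictors: PredictorStack
    true_suitability: dict[str, np.ndarray]  # taxon_id -> (n_rows, n_cols)
    true_pairwise_overlap: pd.DataFrame  # ticks x hosts, Jaccard %
    space: niche.PCASpace
    level: float
    true_hulls: dict[str, niche.NicheHull] = field(default_factory=dict)

    def taxon(self, taxon_id: str) -> VirtualTaxon:
        for t in self.taxa:
            if t.taxon_id == taxon_id:
                return t
        raise KeyError(taxon_id)


def build_truth(
    taxa: list[VirtualTaxon],
    predictors: PredictorStack,
    level: float = 0.5,
) -> SyntheticTruth:
    """Compute true suitability surfaces and true pairwise niche overlap.

    The true niche of a taxon is the level set where suitability exceeds
    ``level`` times its maximum; its hull in the common 2-PC space of the
    background predictors defines true overlap, so identical niches overlap
    by exactly 100 and overlap decays with niche-center separation.
    """
    ids, X = predictors.as_table()
    space = niche.fit_pca(X, k=2)
    scores = space.transform(X)[:, :2]
    geom = predictors.geometry
    suit: dict[str, np.ndarray] = {}
    hulls: dict[str, niche.NicheHull] = {}
    for taxon in taxa:
        s_flat = taxon.suitability(X)
        surf = np.zeros(geom.n_cells)
        surf[ids] = s_flat
        suit[taxon.taxon_id] = surf.reshape(geom.n_rows, geom.n_cols)
        inside = s_flat >= level * taxon.max_prevalence
        hulls[taxon.taxon_id] = niche.convex_hull(scores[inside], taxon.taxon_id)
    ticks = [t.taxon_id for t in taxa if t.role == "tick"]
    hosts = [t.taxon_id for t in taxa if t.role == "host"]
    overlap = pd.DataFrame(np.nan, index=ticks, columns=hosts)
    for t in ticks:
        for h in hosts:
            overlap.loc[t, h] = niche.jaccard_overlap(hulls[t], hulls[h])
    return SyntheticTruth(
        taxa=taxa,
        predictors=predictors,
        true_suitability=suit,
        true_pairwise_overlap=overlap,
        space=space,
        level=level,
        true_hulls=hulls,
    )


def sample_occurrences(
    taxon: VirtualTaxon, truth: SyntheticTruth, n: int, seed: int
) -> pd.DataFrame:
    """Draw n occurrence records with probability proportional to suitability.

    Sampling is over cells, with replacement; rows carry the taxon id, role
    and the sampled cell's center coordinates (columns
    ``taxon_id, role, lon, lat``).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    surf = truth.true_suitability[taxon.taxon_id].reshape(-1)
    total = surf.sum()
    if total <= 0:
        raise ValueError(f"all-zero suitability for {taxon.taxon_id!r}")
    rng = np.random.default_rng(seed)
    cells = rng.choice(surf.size, size=n, replace=True, p=surf / total)
    geom = truth.predictors.geometry
    rows, cols = np.divmod(cells, geom.n_cols)
    lon = geom.x_origin + (cols + 0.5) * geom.cell_size
    lat = geom.y_origin + (rows + 0.5) * geom.cell_size
    return pd.DataFrame(
        {"taxon_id": taxon.taxon_id, "role": taxon.role, "lon": lon, "lat": lat}
    )


def make_taxa(
    predictors: PredictorStack,
    n_ticks: int,
    n_hosts: int,
    seed: int,
    breadth_scale: float = 1.0,
    max_prevalence: float = 1.0,
) -> list[VirtualTaxon]:
    """Random virtual community: niche centers drawn from occupied climate space.

    Centers are predictor vectors of randomly chosen cells; breadths are
    diagonal, proportional to the squared background standard deviation of
    each predictor times ``breadth_scale``.
    """
    rng = np.random.default_rng(seed)
    _, X = predictors.as_table()
    sd2 = np.maximum(X.var(axis=0), 1e-12)
    taxa = []
    for i in range(n_ticks + n_hosts):
        role = "tick" if i < n_ticks else "host"
        label = f"{role}_{i if role == 'tick' else i - n_ticks}"
        center = X[rng.integers(X.shape[0])]
        breadth = breadth_scale * sd2 * rng.uniform(0.5, 1.5, size=9)
        taxa.append(VirtualTaxon(label, role, center, breadth, max_prevalence))
    return taxa


def make_structured_community(
    predictors: PredictorStack,
    n_ticks: int,
    n_hosts: int,
    seed: int,
    structure: str = "nested",
) -> list[VirtualTaxon]:
    """Community whose true tick-host network has a prescribed architecture.

    ``nested`` (an "extreme-climate" ecosystem): hosts sit at increasing
    distances from a focal climate along the dominant background axis while
    ticks share the focal center with increasing niche breadth, so each
    narrower tick's hosts are a subset of each broader tick's — a nested
    incidence matrix by construction.  ``random``: independent random
    centers and breadths with no imposed architecture.
    """
    if structure == "random":
        return make_taxa(predictors, n_ticks, n_hosts, seed, breadth_scale=0.25)
    if structure != "nested":
        raise ValueError(f"unknown structure {structure!r}")
    rng = np.random.default_rng(seed)
    geom = predictors.geometry
    sd2 = np.maximum(predictors.layers.reshape(9, -1).var(axis=1), 1e-12)
    # anchor niches on real cells so level sets stay on the climate manifold:
    # hosts march north from a southern focal cell, ticks sit at the focal
    # cell with growing breadth
    mid_col = geom.n_cols // 2
    focal_row = geom.n_rows // 6
    top_row = int(geom.n_rows * 0.55)
    focal = predictors.cell_vector(focal_row, mid_col)
    base = 0.1 * sd2
    taxa = []
    for i in range(n_ticks):
        scale = (1.0 + 12.0 * i / max(n_ticks - 1, 1)) ** 2
        jitter = (1 + 0.02 * rng.standard_normal(9)) ** 2
        taxa.append(VirtualTaxon(f"tick_{i}", "tick", focal, scale * base * jitter))
    host_rows = np.linspace(focal_row, top_row, n_hosts).round().astype(int)
    for j, row in enumerate(host_rows):
        center = predictors.cell_vector(int(row), mid_col)
        jitter = (1 + 0.02 * rng.standard_normal(9)) ** 2
        taxa.append(VirtualTaxon(f"host_{j}", "host", center, base * jitter))
    return taxa


def make_overlap_profiles(
    n_ticks: int,
    n_hosts: int,
    n_ecosystems: int,
    seed: int,
    noise_sd: float = 6.0,
) -> dict[int, "niche.OverlapMatrix"]:
    """Per-ecosystem overlap matrices with ecosystem-specific host pools.

    The union host set is split into disjoint pools, one per ecosystem;
    hosts outside an ecosystem's pool are undefined there (absent).  Within
    a pool each host has a characteristic overlap level (uniform on
    [40, 90]) shared by all ticks up to Gaussian noise, so overlap profiles
    cluster by ecosystem — the structure the ordination stage should
    recover.
    """
    if n_hosts < n_ecosystems:
        raise ValueError("need at least one host per ecosystem")
    rng = np.random.default_rng(seed)
    ticks = [f"tick_{i}" for i in range(n_ticks)]
    hosts = [f"host_{j}" for j in range(n_hosts)]
    pools = np.array_split(np.arange(n_hosts), n_ecosystems)
    out: dict[int, niche.OverlapMatrix] = {}
    for eco_id, pool in enumerate(pools):
        values = pd.DataFrame(np.nan, index=ticks, columns=hosts)
        defined = pd.DataFrame(False, index=ticks, columns=hosts)
        base = rng.uniform(40, 90, size=pool.size)
        for k, j in enumerate(pool):
            col = hosts[j]
            values[col] = np.clip(base[k] + noise_sd * rng.standard_normal(n_ticks), 0, 100)
            defined[col] = True
        out[eco_id] = niche.OverlapMatrix(ecosystem_id=eco_id, values=values, defined=defined)
    return out


# ---------------------------------------------------------------------------
# Phylogeny and traits
# ---------------------------------------------------------------------------


def make_phylogeny(taxon_ids: list[str], seed: int, model: str = "yule") -> dendropy.Tree:
    """Binary rooted Yule tree with tips labelled by ``taxon_ids``."""
    if model != "yule":
        raise ValueError(f"unknown model {model!r}")
    ids = list(taxon_ids)
    if len(ids) < 2:
        raise ValueError("need at least 2 taxa")
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate taxon_ids")
    rng = random.Random(seed)
    tree = treesim.birth_death_tree(
        birth_rate=1.0,
        death_rate=0.0,
        num_extant_tips=len(ids),
        rng=rng,
        repeat_until_success=True,
    )
    namespace = dendropy.TaxonNamespace()
    for leaf, label in zip(tree.leaf_node_iter(), ids):
        leaf.taxon = namespace.new_taxon(label)
    tree.taxon_namespace = namespace
    tree.is_rooted = True
    for node in tree.preorder_node_iter():
        if node.parent_node is not None and (node.edge.length is None or node.edge.length <= 0):
            node.edge.length = 1e-8
    return tree


def simulate_bm_trait(
    tree: dendropy.Tree, lambda_true: float, sigma2: float, seed: int
) -> pd.Series:
    """Tip trait under lambda-transformed Brownian motion.

    The draw is multivariate normal with covariance sigma^2 times the
    phylogenetic covariance matrix whose off-diagonals are scaled by
    ``lambda_true`` (diagonal unchanged).
    """
    if not (0 <= lambda_true <= 1):
        raise ValueError("lambda_true must be in [0, 1]")
    if sigma2 <= 0:
        raise ValueError("sigma2 must be positive")
    labels, V = phylo_vcv(tree)
    cov = sigma2 * lambda_transform(V, lambda_true)
    L = np.linalg.cholesky(cov + 1e-12 * np.eye(len(labels)))
    rng = np.random.default_rng(seed)
    values = L @ rng.standard_normal(len(labels))
    return pd.Series(values, index=labels)
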