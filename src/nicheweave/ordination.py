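"""Non-metric MDS of tick-by-ecosystem host-overlap profiles.

Each (tick, ecosystem) pair is described by its profile of Jaccard overlap
with the union host set (undefined hosts as 0).  Profiles are converted to
a distance matrix — by default the Euclidean distance between profile
vectors rescaled to [0, 100], a bounded complement of similarity (the
reciprocal transform 100/(1 + s) is available but unbounded behaviour near
zero overlap makes the complement the default).

The embedding is Kruskal-style non-metric MDS: disparities are fitted to
the configuration distances by isotonic (monotone) regression on the rank
order of the input dissimilarities and the configuration is updated with
the Guttman transform (SMACOF), restarted from several seeded initial
configurations; the reported misfit is Kruskal stress-1,

    stress = sqrt( sum (d_ij - dhat_ij)^2 / sum d_ij^2 ).

Stress below 0.05 is read as a reliable two-dimensional reduction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.isotonic import IsotonicRegression

from .niche import OverlapMatrix


@dataclass
class OrdinationResult:
    items: list[tuple[str, int]]  # (tick_id, ecosystem_id)
    coordinates: np.ndarray  # (n, dim), centered at the origin
    stress: float
    converged: bool
    seed: int
    degenerate: bool = False
    stress_history: list[float] = field(default_factory=list)

    def as_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.coordinates, columns=["x", "y"][: self.coordinates.shape[1]])
        df.insert(0, "ecosystem_id", [e for _, e in self.items])
        df.insert(0, "tick_id", [t for t, _ in self.items])
        df["stress"] = self.stress
        return df


def overlap_to_distance(
    matrices: dict[int, OverlapMatrix], mode: str = "complement"
) -> tuple[list[tuple[str, int]], np.ndarray]:
    """Distance matrix over (tick, ecosystem) items from overlap profiles.

    Profiles span the union host set over all ecosystems; hosts undefined
    for an item contribute 0 overlap.  ``complement`` divides the Euclidean
    profile distance by sqrt(n_hosts) so antipodal profiles (all-100 vs
    all-0) are exactly 100 apart; ``reciprocal`` first maps each overlap s
    to 100/(1 + s).
    """
    hosts = sorted({h for m in matrices.values() for h in m.host_ids})
    items: list[tuple[str, int]] = []
    profiles: list[np.ndarray] = []
    for eco_id in sorted(matrices):
        m = matrices[eco_id]
        for t in m.tick_ids:
            row = m.values.loc[t].where(m.defined.loc[t], 0.0).fillna(0.0)
            vec = np.array([row.get(h, 0.0) for h in hosts], dtype=float)
            items.append((t, eco_id))
            profiles.append(vec)
    if len(items) < 3:
        raise ValueError("need at least 3 (tick, ecosystem) items")
    P = np.stack(profiles)
    if mode == "reciprocal":
        P = 100.0 / (1.0 + P)
    elif mode != "complement":
        raise ValueError(f"unknown distance mode {mode!r}")
    diff = P[:, None, :] - P[None, :, :]
    D = np.sqrt((diff**2).sum(axis=2) / P.shape[1])
    np.fill_diagonal(D, 0.0)
    return items, D


def _classical_mds(D: np.ndarray, dim: int) -> np.ndarray:
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D**2) @ J
    vals, vecs = np.linalg.eigh(B)
    order = np.argsort(vals)[::-1][:dim]
    lam = np.clip(vals[order], 0, None)
    return vecs[:, order] * np.sqrt(lam)


def _pairwise(X: np.ndarray) -> np.ndarray:
    diff = X[:, None, :] - X[None, :, :]
    return np.sqrt((diff**2).sum(axis=2))


def nmds(
    D: np.ndarray,
    dim: int = 2,
    seed: int = 0,
    n_starts: int = 8,
    max_iter: int = 300,
    tol: float = 1e-6,
    items: list[tuple[str, int]] | None = None,
) -> OrdinationResult:
    """Non-metric MDS by SMACOF with monotone regression and seeded restarts.

    The first start is the classical (metric) MDS configuration; the
    remaining starts are random.  The lowest-stress configuration is
    returned, centered at the origin.  An all-zero distance matrix is
    degenerate and flagged rather than embedded.
    """
    D = np.asarray(D, dtype=float)
    n = D.shape[0]
    if D.shape != (n, n) or not np.allclose(D, D.T):
        raise ValueError("distance matrix must be square and symmetric")
    if dim >= n - 1:
        raise ValueError("dim must be smaller than n - 1")
    items = items or [(f"item_{i}", 0) for i in range(n)]
    iu = np.triu_indices(n, k=1)
    delta = D[iu]
    if np.all(delta == 0):
        return OrdinationResult(
            items=items,
            coordinates=np.zeros((n, dim)),
            stress=float("nan"),
            converged=False,
            seed=seed,
            degenerate=True,
        )
    rng = np.random.default_rng(seed)
    order = np.argsort(delta, kind="stable")
    best: OrdinationResult | None = None
    for start in range(max(1, n_starts)):
        if start == 0:
            X = _classical_mds(D, dim)
        else:
            X = rng.standard_normal((n, dim)) * delta.std()
        history: list[float] = []
        prev = np.inf
        converged = False
        for _ in range(max_iter):
            d = _pairwise(X)[iu]
            iso = IsotonicRegression(increasing=True, out_of_bounds="clip")
            dhat = np.empty_like(d)
            dhat[order] = iso.fit_transform(np.arange(d.size), d[order])
            denom = np.sum(d**2)
            if denom <= 0:
                break
            stress = float(np.sqrt(np.sum((d - dhat) ** 2) / denom))
            history.append(stress)
            # relative stress decrement, so exactly embeddable inputs keep
            # annealing toward zero instead of stopping at the absolute tol
            if np.isfinite(prev) and prev - stress < tol * max(prev, 1e-12):
                converged = True
                break
            prev = stress
            # Guttman transform with disparities dhat
            full_d = _pairwise(X)
            full_dhat = np.zeros_like(full_d)
            full_dhat[iu] = dhat
            full_dhat += full_dhat.T
            with np.errstate(divide="ignore", invalid="ignore"):
                ratio = np.where(full_d > 0, full_dhat / full_d, 0.0)
            Bmat = -ratio
            np.fill_diagonal(Bmat, ratio.sum(axis=1))
            X = Bmat @ X / n
        final = history[-1] if history else float("inf")
        if best is None or final < best.stress:
            Xc = X - X.mean(axis=0)
            best = OrdinationResult(
                items=items,
                coordinates=Xc,
                stress=final,
                converged=converged,
                seed=seed,
                stress_history=history,
            )
    return best


def stress_check(result: OrdinationResult, threshold: float = 0.05) -> bool:
    """True iff stress is strictly below the reliability threshold."""
    return bool(result.stress < threshold)


def ecosystem_grouping_test(
    D: np.ndarray,
    groups: list,
    n_perm: int = 999,
    seed: int = 0,
) -> tuple[float, float]:
    """Distance-based permutation test for grouping structure (PERMANOVA).

    Returns the pseudo-F statistic and its permutation p-value.  This is a
    companion diagnostic for ordination plots, not a reproduction of any
    particular published test.
    """
    from skbio import DistanceMatrix
    from skbio.stats.distance import permanova

    ids = [str(i) for i in range(len(groups))]
    dm = DistanceMatrix(np.asarray(D, dtype=float), ids)
    state = np.random.get_state()
    try:
        np.random.seed(seed % (2**31))
        res = permanova(dm, grouping=[str(g) for g in groups], permutations=n_perm)
    finally:
        np.random.set_state(state)
    return float(res["test statistic"]), float(res["p-value"])
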