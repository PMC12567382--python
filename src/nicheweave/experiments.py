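"""Canned parameter-recovery and calibration experiments.

Each function runs one self-contained study on synthetic data with known
ground truth and returns a dictionary of summary numbers.  They are the
package's own evidence that the pipeline recovers what the generator put
in: the test-suite asserts on their outputs and the acceptance script
reports them.  Problem sizes are chosen to be informative on a single CPU
within seconds to a few minutes.
"""

from __future__ import annotations

import numpy as np

from . import climate, networks, niche, ordination, phylo, sdm, synthetic
from .synthetic import child_seed


def harmonic_recovery(seed: int, n_rows: int = 10, n_cols: int = 10, noise_sd: float = 0.5) -> dict:
    """Recover per-cell harmonic coefficients from a noisy climate grid.

    With i.i.d. Gaussian noise of known sd the orthogonal-basis estimators
    have closed-form standard errors (sd/sqrt(12) for a0, sd/sqrt(6) for a1
    and b1); reports the worst absolute z-score over all cells, variables
    and coefficients.
    """
    noisy = synthetic.make_climate_grid(n_rows, n_cols, seed=seed, noise_sd=noise_sd)
    clean = synthetic.make_climate_grid(n_rows, n_cols, seed=seed, noise_sd=0.0)
    est = climate.build_predictors(noisy)
    true = climate.build_predictors(clean)
    se = np.array([noise_sd / np.sqrt(12), noise_sd / np.sqrt(6), noise_sd / np.sqrt(6)] * 3)
    err = est.layers - true.layers
    z = np.abs(err) / se[:, None, None]
    # with 9 coefficients per cell the appropriate "within 3 SE" summary is
    # coverage: ~99.7% of estimates should fall inside under Gaussian noise
    return {
        "share_within_3se": float(np.mean(z <= 3)),
        "max_abs_z": float(z.max()),
        "mean_abs_error": float(np.abs(err).mean()),
        "n_cells": n_rows * n_cols,
    }


def sdm_recovery(
    seed: int, n_rows: int = 50, n_cols: int = 50, n_presences: int = 300
) -> dict:
    """Ensemble SDM recovery of one Gaussian virtual species.

    Reports held-out ensemble kappa and the Pearson correlation between the
    ensemble surface and the generating suitability.
    """
    grid = synthetic.make_climate_grid(n_rows, n_cols, seed=child_seed(seed, "climate"))
    preds = climate.build_predictors(grid)
    taxa = synthetic.make_taxa(preds, 1, 0, seed=child_seed(seed, "taxa"), breadth_scale=0.6)
    truth = synthetic.build_truth(taxa, preds)
    taxon = taxa[0]
    occ = synthetic.sample_occurrences(taxon, truth, n_presences, seed=child_seed(seed, "occ"))
    res = sdm.train_sdm(occ, preds, seed=child_seed(seed, "sdm"))
    est = res.suitability.values.reshape(-1)
    tru = truth.true_suitability[taxon.taxon_id].reshape(-1)
    ok = ~np.isnan(est)
    corr = float(np.corrcoef(est[ok], tru[ok])[0, 1])
    return {
        "kappa": float(res.ensemble_metrics.kappa),
        "surface_correlation": corr,
        "n_presences": n_presences,
    }


def overlap_separation_sweep(
    seed: int,
    n_rows: int = 40,
    n_cols: int = 40,
    n_occurrences: int = 500,
    n_separations: int = 6,
) -> dict:
    """Pairwise niche-overlap recovery across a sweep of niche separations.

    Two virtual taxa share a diagonal breadth while their center separation
    grows.  The estimated overlap comes from the full pipeline (occurrence
    sampling, ensemble SDM, max-TSS binary map, hulls in PC space); the
    truth applies the same max-TSS thresholding rule to the *true*
    suitability surface at the same test records, so both hulls use the
    same presence threshold rule.
    """
    grid = synthetic.make_climate_grid(n_rows, n_cols, seed=child_seed(seed, "climate"))
    preds = climate.build_predictors(grid)
    ids, X = preds.as_table()
    sd2 = X.var(axis=0)
    center = X.mean(axis=0)
    breadth = 0.6 * sd2
    direction = np.sqrt(sd2) / np.linalg.norm(np.sqrt(sd2))
    estimates, truths = [], []
    for i, sep in enumerate(np.linspace(0.0, 2.0, n_separations)):
        c2 = center + sep * direction * np.sqrt(sd2)
        pair = [
            synthetic.VirtualTaxon("tick_0", "tick", center, breadth),
            synthetic.VirtualTaxon("host_0", "host", c2, breadth),
        ]
        truth = synthetic.build_truth(pair, preds)
        hulls_est, hulls_true = {}, {}
        for k, taxon in enumerate(pair):
            occ = synthetic.sample_occurrences(
                taxon, truth, n_occurrences, seed=child_seed(seed, f"occ:{i}:{k}")
            )
            res = sdm.train_sdm(occ, preds, seed=child_seed(seed, f"sdm:{i}:{k}"))
            test = res.points[res.points["partition"] == "test"]
            cells = test["cell_id"].to_numpy(int)
            labels = test["label"].to_numpy(int)
            est_present = res.binary.values.reshape(-1)[ids] > 0
            hulls_est[taxon.taxon_id] = niche.convex_hull(
                truth.space.transform(X[est_present])[:, :2]
            )
            s_true = truth.true_suitability[taxon.taxon_id].reshape(-1)
            t_true, _ = sdm.threshold_max_tss(s_true[cells], labels)
            hulls_true[taxon.taxon_id] = niche.convex_hull(
                truth.space.transform(X[s_true[ids] >= t_true])[:, :2]
            )
        estimates.append(niche.jaccard_overlap(hulls_est["tick_0"], hulls_est["host_0"]))
        truths.append(niche.jaccard_overlap(hulls_true["tick_0"], hulls_true["host_0"]))
    est = np.asarray(estimates)
    tru = np.asarray(truths)
    return {
        "estimated": est.tolist(),
        "truth": tru.tolist(),
        "max_abs_error": float(np.max(np.abs(est - tru))),
        "strictly_decreasing": bool(np.all(np.diff(est) < 0)),
    }


def lambda_recovery(seed: int, n_tips: int = 100, n_reps: int = 20) -> dict:
    """Mean ML estimate of Pagel's lambda at the boundary truths 0 and 1."""
    tree = synthetic.make_phylogeny(
        [f"t{i}" for i in range(n_tips)], seed=child_seed(seed, "tree")
    )
    out = {}
    for lam_true in (0.0, 1.0):
        hats = []
        for rep in range(n_reps):
            trait = synthetic.simulate_bm_trait(
                tree, lam_true, 1.0, seed=child_seed(seed, f"trait:{lam_true}:{rep}")
            )
            hats.append(phylo.pagels_lambda(tree, trait).lambda_hat)
        out[f"mean_lambda_hat_at_{int(lam_true)}"] = float(np.mean(hats))
    return out


def nestedness_contrast(seed: int, n_rows: int = 30, n_cols: int = 30) -> dict:
    """NODF of a constructed nested ('extreme-climate') vs random community."""
    grid = synthetic.make_climate_grid(n_rows, n_cols, seed=child_seed(seed, "climate"))
    preds = climate.build_predictors(grid)
    out = {}
    for structure in ("nested", "random"):
        taxa = synthetic.make_structured_community(
            preds, 4, 8, seed=child_seed(seed, "community"), structure=structure
        )
        truth = synthetic.build_truth(taxa, preds)
        binary = (truth.true_pairwise_overlap.fillna(0).to_numpy() > 0).astype(float)
        out[f"nodf_{structure}"] = float(networks.nodf(binary))
    return out


def ordination_structure(seed: int, n_ticks: int = 4, n_hosts: int = 9, n_ecos: int = 3) -> dict:
    """NMDS of ecosystem-structured overlap profiles.

    Reports the stress, the within- vs between-ecosystem mean ordination
    distances and the grouping-test p-value.
    """
    mats = synthetic.make_overlap_profiles(n_ticks, n_hosts, n_ecos, seed=child_seed(seed, "prof"))
    items, D = ordination.overlap_to_distance(mats)
    res = ordination.nmds(D, seed=child_seed(seed, "nmds"), items=items)
    groups = np.array([e for _, e in items])
    coords = res.coordinates
    dd = np.sqrt(((coords[:, None] - coords[None]) ** 2).sum(-1))
    iu = np.triu_indices(len(items), 1)
    same = groups[iu[0]] == groups[iu[1]]
    f_stat, p_val = ordination.ecosystem_grouping_test(
        D, list(groups), seed=child_seed(seed, "grouping")
    )
    return {
        "stress": float(res.stress),
        "within_mean_distance": float(dd[iu][same].mean()),
        "between_mean_distance": float(dd[iu][~same].mean()),
        "grouping_p": float(p_val),
    }


def nmds_exact_embedding(seed: int, n_points: int = 10) -> dict:
    """Stress of NMDS on distances computed from actual 2-D points."""
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n_points, 2))
    D = np.sqrt(((X[:, None] - X[None]) ** 2).sum(-1))
    res = ordination.nmds(D, seed=seed)
    return {"stress": float(res.stress)}


def mantel_type_i(seed: int, n_sims: int = 500, n_objects: int = 7, n_perm: int = 99) -> dict:
    """Empirical size of the Mantel test at alpha = 0.05 under independence."""
    rej = 0
    for s in range(n_sims):
        rng = np.random.default_rng(child_seed(seed, f"mantel:{s}"))
        A = rng.random((n_objects, 2))
        B = rng.random((n_objects, 2))
        dA = np.sqrt(((A[:, None] - A[None]) ** 2).sum(-1))
        dB = np.sqrt(((B[:, None] - B[None]) ** 2).sum(-1))
        _, p = networks.mantel(dA, dB, n_perm=n_perm, seed=child_seed(seed, f"perm:{s}"))
        rej += p <= 0.05
    return {"rejection_rate": rej / n_sims, "n_sims": n_sims}


def null_model_type_i(
    seed: int, n_sims: int = 500, shape: tuple[int, int] = (8, 10), n_null: int = 99
) -> dict:
    """Empirical size of the nestedness null-model test at alpha = 0.05.

    The observed matrix is drawn from a fully specified proportional null
    and tested against that same null, under which the Monte-Carlo p-value
    is uniform up to ties.
    """
    rng = np.random.default_rng(child_seed(seed, "base"))
    base = (rng.random(shape) < 0.5).astype(float)
    p = networks.proportional_probabilities(base)
    rej = 0
    done = 0
    for s in range(n_sims):
        rg = np.random.default_rng(child_seed(seed, f"obs:{s}"))
        M = networks.proportional_null(base, rg, probabilities=p)
        try:
            stats = networks.null_significance(
                M, "nodf", n_null=n_null, seed=child_seed(seed, f"null:{s}"),
                probabilities=p,
            )
        except ValueError:  # degenerate draw (empty rows/columns)
            continue
        done += 1
        rej += stats.p_value <= 0.05
    return {"rejection_rate": rej / done, "n_sims": done}
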