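"""End-to-end orchestration: synthetic inputs -> report of figure-grade quantities.

``run_all`` executes the stages in dependency order — synthetic inputs,
harmonic predictors, per-taxon ensemble SDMs, per-ecosystem niche hulls and
overlap matrices, phylogenetic diversity, network structure, ordination —
writing every intermediate artifact to the output directory so each
reported number can be recomputed from files.  The whole run is a
deterministic function of the configuration and one seed: per-stage seeds
derive from the global seed by a fixed hashing rule.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import climate, grids, networks, niche, ordination, phylo, sdm, synthetic
from .synthetic import child_seed

logger = logging.getLogger("nicheweave")

_CONFIG_FIELDS = {
    "seed",
    "n_rows",
    "n_cols",
    "n_ecosystems",
    "n_ticks",
    "n_hosts",
    "n_occurrences",
    "breadth_scale",
    "noise_frac",
    "train_fraction",
    "retain_kappa",
    "edge_threshold",
    "n_null",
    "n_perm",
    "k_pcs",
    "distance_mode",
    "ecosystem_scheme",
}


@dataclass
class RunConfig:
    """Parameters of a full synthetic pipeline run."""

    seed: int = 0
    n_rows: int = 30
    n_cols: int = 30
    n_ecosystems: int = 3
    n_ticks: int = 3
    n_hosts: int = 8
    n_occurrences: int = 150
    breadth_scale: float = 1.0
    noise_frac: float = 0.05
    train_fraction: float = 0.7
    retain_kappa: float = 0.4
    edge_threshold: float = 0.0
    n_null: int = 199
    n_perm: int = 199
    k_pcs: int = 2
    distance_mode: str = "complement"
    ecosystem_scheme: str = "latitudinal_bands"

    def __post_init__(self) -> None:
        if not (0 < self.train_fraction < 1):
            raise ValueError("train_fraction must be in (0, 1)")
        if self.n_ecosystems < 2:
            raise ValueError("need at least 2 ecosystems")
        if self.n_null < 99 or self.n_perm < 99:
            raise ValueError("n_null and n_perm must be >= 99")
        if self.distance_mode not in ("complement", "reciprocal"):
            raise ValueError("distance_mode must be 'complement' or 'reciprocal'")

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        unknown = set(data) - _CONFIG_FIELDS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(data)

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class RunReport:
    """Figure-grade quantities of one run, all traceable to stage artifacts."""

    config: dict
    config_hash: str
    seed: int
    version: str
    suitability_table: list[dict] = field(default_factory=list)  # tick x eco rows
    pd_table: list[dict] = field(default_factory=list)
    network_stats: list[dict] = field(default_factory=list)
    ordination: dict = field(default_factory=dict)
    sdm_metrics: dict = field(default_factory=dict)
    failures: list[dict] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, sort_keys=True))


def _jsonable(value):
    if isinstance(value, (np.floating, np.integer)):
        return value.item()
    return value


def run_all(config: RunConfig, outdir: str | Path) -> RunReport:
    """Run every stage on synthetic inputs and emit artifacts plus a report."""
    from importlib.metadata import version as pkg_version

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    try:
        ver = pkg_version("nicheweave")
    except Exception:
        ver = "unknown"
    report = RunReport(
        config=asdict(config), config_hash=config.config_hash(), seed=config.seed, version=ver
    )
    seed = config.seed

    # --- stage 1: synthetic inputs -------------------------------------
    logger.info("stage simulate: seed=%d", child_seed(seed, "climate"))
    grid = synthetic.make_climate_grid(
        config.n_rows, config.n_cols, seed=child_seed(seed, "climate"),
        noise_frac=config.noise_frac,
    )
    grids.write_climate_grid(outdir / "climate.grid", grid)
    eco = synthetic.make_ecosystem_map(
        grid, k=config.n_ecosystems, scheme=config.ecosystem_scheme,
        seed=child_seed(seed, "ecosystems"),
    )
    grids.write_ecosystem_map(outdir / "ecosystems.grid", eco)

    predictors = climate.build_predictors(grid)
    grids.write_predictor_stack(outdir / "predictors.grid", predictors)

    taxa = synthetic.make_taxa(
        predictors, config.n_ticks, config.n_hosts,
        seed=child_seed(seed, "taxa"), breadth_scale=config.breadth_scale,
    )
    truth = synthetic.build_truth(taxa, predictors)
    occurrences = pd.concat(
        [
            synthetic.sample_occurrences(
                t, truth, config.n_occurrences, seed=child_seed(seed, f"occ:{t.taxon_id}")
            )
            for t in taxa
        ],
        ignore_index=True,
    )
    occurrences.to_csv(outdir / "occurrences.csv", index=False)
    host_ids = [t.taxon_id for t in taxa if t.role == "host"]
    tree = synthetic.make_phylogeny(host_ids, seed=child_seed(seed, "phylogeny"))
    (outdir / "hosts.nwk").write_text(phylo.to_newick(tree) + "\n")

    # --- stage 2: per-taxon ensemble SDMs ------------------------------
    results: dict[str, sdm.SDMResult] = {}
    for taxon in taxa:
        pres = occurrences[occurrences["taxon_id"] == taxon.taxon_id]
        try:
            res = sdm.train_sdm(
                pres, predictors, seed=child_seed(seed, f"sdm:{taxon.taxon_id}"),
                taxon_id=taxon.taxon_id, train_fraction=config.train_fraction,
                retain_kappa=config.retain_kappa,
            )
        except ValueError as exc:
            report.failures.append({"stage": "sdm", "taxon": taxon.taxon_id, "cause": str(exc)})
            logger.warning("sdm failed for %s: %s", taxon.taxon_id, exc)
            continue
        results[taxon.taxon_id] = res
        grids.write_text_grid(
            outdir / f"binary_{taxon.taxon_id}.grid",
            predictors.geometry,
            {"binary": res.binary.values.astype(float)},
        )
        report.sdm_metrics[taxon.taxon_id] = {
            "ensemble": {k: _jsonable(v) for k, v in res.ensemble_metrics.as_dict().items()},
            "members": {n: m.as_dict() for n, m in res.member_metrics.items()},
        }

    # --- stage 3: niche hulls and overlap matrices ---------------------
    _, X = predictors.as_table()
    space = niche.fit_pca(X, k=config.k_pcs)
    tick_ids = [t.taxon_id for t in taxa if t.role == "tick" and t.taxon_id in results]
    matrices: dict[int, niche.OverlapMatrix] = {}
    for eco_id in eco.ecosystem_ids:
        tick_hulls = {}
        host_hulls = {}
        for taxon in taxa:
            if taxon.taxon_id not in results:
                continue
            pts = niche.taxon_niche_points(
                results[taxon.taxon_id].binary.values, eco, eco_id, space, predictors
            )
            hull = niche.convex_hull(pts, taxon.taxon_id, eco_id)
            (tick_hulls if taxon.role == "tick" else host_hulls)[taxon.taxon_id] = hull
        try:
            matrix = niche.ecosystem_overlap_matrix(tick_hulls, host_hulls, eco_id)
        except ValueError as exc:
            report.failures.append({"stage": "niche", "ecosystem": eco_id, "cause": str(exc)})
            continue
        matrices[eco_id] = matrix
        niche.overlap_matrix_to_csv(matrix, outdir / f"overlap_eco{eco_id}.csv")

    # --- stage 4: suitability table (abiotic + biotic) -----------------
    for eco_id, matrix in matrices.items():
        for tick in tick_ids:
            row = {
                "tick_id": tick,
                "ecosystem_id": eco_id,
                "abiotic_suitability": sdm.abiotic_suitability(
                    results[tick].suitability, eco, eco_id
                ),
                "biotic_suitability": niche.biotic_suitability(matrix, tick),
            }
            report.suitability_table.append({k: _jsonable(v) for k, v in row.items()})

    # --- stage 5: phylogenetic diversity -------------------------------
    for eco_id, matrix in matrices.items():
        for tick in tick_ids:
            hosts = [h for h in matrix.host_ids if bool(matrix.defined.loc[tick, h])]
            pd_val = phylo.faith_pd(tree, hosts) if hosts else float("nan")
            lam = float("nan")
            if len(hosts) >= 4:
                trait = {h: float(matrix.values.loc[tick, h]) for h in hosts}
                sub = tree.extract_tree_with_taxa_labels(hosts)
                try:
                    lam = phylo.pagels_lambda(sub, trait).lambda_hat
                except ValueError:
                    lam = float("nan")
            report.pd_table.append(
                {
                    "tick_id": tick,
                    "ecosystem_id": eco_id,
                    "n_hosts": len(hosts),
                    "faith_pd": _jsonable(pd_val),
                    "pagels_lambda": _jsonable(lam),
                }
            )
    pd.DataFrame(report.pd_table).to_csv(outdir / "pd_table.csv", index=False)

    # --- stage 6: network structure ------------------------------------
    for eco_id, matrix in matrices.items():
        net = networks.build_network(matrix, edge_threshold=config.edge_threshold)
        W = net.weight_matrix()
        entry: dict = {"ecosystem_id": eco_id, "n_edges": net.n_edges}
        try:
            entry["nodf"] = networks.nodf(W)
            entry["wnodf"] = networks.wnodf(W)
            q, _ = networks.bipartite_modularity(
                net, seed=child_seed(seed, f"modularity:{eco_id}")
            )
            entry["modularity_q"] = q
            stats = networks.null_significance(
                W, metric="nodf", n_null=config.n_null,
                seed=child_seed(seed, f"null:{eco_id}"),
            )
            entry.update(
                nodf_null_mean=stats.null_mean,
                nodf_null_sd=stats.null_sd,
                nodf_z=stats.z,
                nodf_p=stats.p_value,
            )
        except ValueError as exc:
            report.failures.append({"stage": "networks", "ecosystem": eco_id, "cause": str(exc)})
        report.network_stats.append({k: _jsonable(v) for k, v in entry.items()})
        edges = [
            {"tick_id": t, "host_id": h, "weight": float(net.incidence.loc[t, h]),
             "ecosystem": eco_id}
            for t in net.incidence.index
            for h in net.incidence.columns
            if net.incidence.loc[t, h] > 0
        ]
        pd.DataFrame(edges).to_csv(outdir / f"edges_eco{eco_id}.tsv", sep="\t", index=False)
    (outdir / "network_stats.json").write_text(
        json.dumps(report.network_stats, indent=2, sort_keys=True)
    )

    # --- stage 7: ordination -------------------------------------------
    if len(matrices) >= 2:
        try:
            items, D = ordination.overlap_to_distance(matrices, mode=config.distance_mode)
            result = ordination.nmds(
                D, dim=2, seed=child_seed(seed, "nmds"), items=items
            )
            coords = result.as_frame()
            coords.to_csv(outdir / "ordination.csv", index=False)
            f_stat, p_val = ordination.ecosystem_grouping_test(
                D, [e for _, e in items], n_perm=config.n_perm,
                seed=child_seed(seed, "grouping"),
            )
            report.ordination = {
                "stress": _jsonable(result.stress),
                "converged": result.converged,
                "reliable": ordination.stress_check(result),
                "grouping_pseudo_f": f_stat,
                "grouping_p": p_val,
                "items": [[t, int(e)] for t, e in items],
                "coordinates": [[float(x), float(y)] for x, y in result.coordinates],
            }
        except ValueError as exc:
            report.failures.append({"stage": "ordination", "cause": str(exc)})

    pd.DataFrame(report.suitability_table).to_csv(outdir / "suitability_table.csv", index=False)
    report.to_json(outdir / "report.json")
    return report
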