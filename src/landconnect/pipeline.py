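"""End-to-end orchestration: simulate/load -> genetics -> population graph
-> circuit -> covariates -> inference, with a YAML config and a manifest.

The pipeline accepts either a genotype CSV plus a resistance (or
land-cover) raster, or a ``simulate`` block that generates both; every
stage writes its artifact into the run directory and the manifest records
config hash, seeds, package versions and per-stage counts so a run can be
audited and reproduced.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .circuit import (
    build_circuit,
    classify_landcover,
    neighborhood_analysis,
    omnidirectional_map,
)
from .covariates import DEFAULT_RADII_M, assemble_records
from .genetics import (
    encode_multivariate,
    filter_individuals,
    population_covariance,
    read_genotypes,
    write_genotypes,
)
from .inference import DEFAULT_SPECIES_GROUPS, fit_ols, run_pca
from .popgraph import (
    conditional_genetic_distance,
    node_connectivity,
    prune_edges,
    saturated_graph,
    write_graphml,
)
from .raster import Raster, read_ascii_grid, write_ascii_grid
from .synthetic import (
    LandscapeSpec,
    SimSpec,
    generate_landscape,
    inject_missing,
    place_sites,
    simulate_genotypes,
)

__all__ = [
    "RunConfig",
    "PipelineError",
    "validate_config",
    "run_pipeline",
    "run_synthetic_study",
]

log = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failure; carries the stage name for the abort message."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Validated, defaults-filled pipeline configuration."""

    output_dir: str = "landconnect_run"
    seed: int = 0
    genotypes: str | None = None
    sites: str | None = None
    genotype_format: str = "csv"
    resistance_raster: str | None = None
    landcover_raster: str | None = None
    cost_table: dict = field(default_factory=dict)
    simulate: dict | None = None
    max_missing: float = 0.35
    alpha: float = 0.05
    radii_km: list = field(default_factory=lambda: [6.0, 20.0, 120.0])
    as_diameter: bool = False
    inset_m: float = 300.0
    n_pairs: int = 64
    buffer_cells: int = 8
    connectivity: str = "four"
    k_rule: dict = field(default_factory=lambda: {"mode": "fixed", "value": 4})
    subsets: list = field(default_factory=lambda: ["full"])
    species_groups: dict = field(default_factory=lambda: dict(DEFAULT_SPECIES_GROUPS))
    neighborhoods: bool = False
    neighborhood_radii_km: list | None = None

    def radii_m(self) -> tuple[float, ...]:
        scale = 500.0 if self.as_diameter else 1000.0
        return tuple(float(r) * scale for r in self.radii_km)


_SIM_KEYS = {
    "grid_rows", "grid_cols", "cell_size_m", "habitat_fraction", "clustering",
    "cost_classes", "semi_fraction", "n_sites", "n_loci", "alleles_per_locus",
    "n_per_site", "drift_scale", "missing_rate", "min_site_separation_m",
}


def validate_config(path: str | Path | dict) -> RunConfig:
    """Load and validate a YAML config, filling documented defaults.

    All errors are itemized in one exception so a user can fix a config
    in a single pass.
    """
    if isinstance(path, dict):
        raw = dict(path)
        base = Path(".")
    else:
        base = Path(path).parent
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
    known = set(RunConfig.__dataclass_fields__)
    errors = [f"unknown config key: {k!r}" for k in raw if k not in known]
    cfg = RunConfig(**{k: v for k, v in raw.items() if k in known})

    if cfg.seed < 0:
        errors.append("seed must be >= 0")
    if not 0 <= cfg.max_missing <= 1:
        errors.append("max_missing must lie in [0, 1]")
    if not 0 < cfg.alpha <= 1:
        errors.append("alpha must lie in (0, 1]")
    if any(r <= 0 for r in cfg.radii_km):
        errors.append("radii_km entries must be positive")
    if cfg.inset_m < 0:
        errors.append("inset_m must be >= 0")
    if cfg.n_pairs < 1:
        errors.append("n_pairs must be >= 1")
    if cfg.buffer_cells < 1:
        errors.append("buffer_cells must be >= 1")
    if cfg.connectivity not in {"four", "eight"}:
        errors.append("connectivity must be 'four' or 'eight'")
    if cfg.resistance_raster and cfg.landcover_raster:
        errors.append("give either resistance_raster or landcover_raster, not both")
    if cfg.landcover_raster and not cfg.cost_table:
        errors.append("landcover_raster requires a cost_table")
    if cfg.simulate is None:
        if not cfg.genotypes:
            errors.append("either a 'simulate' block or a 'genotypes' path is required")
        if not (cfg.resistance_raster or cfg.landcover_raster):
            errors.append("either a 'simulate' block or an input raster is required")
    else:
        bad = set(cfg.simulate) - _SIM_KEYS
        if bad:
            errors.append(f"unknown simulate keys: {sorted(bad)}")
    for attr in ("genotypes", "sites", "resistance_raster", "landcover_raster"):
        p = getattr(cfg, attr)
        if p:
            resolved = (base / p) if not Path(p).is_absolute() else Path(p)
            if not resolved.exists():
                errors.append(f"{attr} path does not exist: {p}")
            else:
                setattr(cfg, attr, str(resolved))
    known_species = {s for group in cfg.species_groups.values() for s in group}
    for subset in cfg.subsets:
        if subset != "full" and subset not in cfg.species_groups:
            errors.append(f"subset {subset!r} has no species_groups entry")
    if errors:
        raise ValueError("invalid config:\n  - " + "\n  - ".join(errors))
    log.info("config validated: %d species groups, subsets=%s, %d radii",
             len(known_species), cfg.subsets, len(cfg.radii_km))
    return cfg


def _stage(name):
    def deco(fn):
        def wrapper(*a, **kw):
            try:
                return fn(*a, **kw)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(name, exc) from exc
        return wrapper
    return deco


def run_synthetic_study(
    habitat_fraction: float = 0.5,
    drift_scale: float = 0.01,
    seed: int = 0,
    grid: int = 48,
    cell_size_m: float = 100.0,
    clustering: float = 3.0,
    n_sites: int = 14,
    n_per_site: int = 20,
    n_loci: int = 10,
    alleles_per_locus: int = 8,
    missing_rate: float = 0.0,
    min_separation_m: float = 400.0,
    n_pairs: int = 24,
    buffer_cells: int = 6,
    radii_m: tuple[float, ...] = (800.0,),
    alpha: float = 0.05,
    connectivity: str = "four",
    k_rule: tuple[str, float] = ("fixed", 4),
    habitat_sites: bool = True,
) -> dict:
    """One fully in-memory synthetic run of the whole pipeline.

    Sample sizes per site are drawn uniformly in [0.6, 1.4] x
    ``n_per_site`` (at least 2) so that sample size is an informative
    predictor, as in real multi-site surveys, and sites are placed on
    habitat cells by default (animals are sampled where they live).
    Returns a dict of every intermediate product (landscape, sites,
    genotypes, matrices, graphs, current map, records, pca, regression).
    """
    rng = np.random.default_rng(seed)
    landscape = generate_landscape(
        LandscapeSpec(
            grid_rows=grid, grid_cols=grid, cell_size_m=cell_size_m,
            habitat_fraction=habitat_fraction, clustering=clustering,
            seed=int(rng.integers(2**31 - 1)),
        )
    )
    sizes = [
        max(2, int(round(n_per_site * rng.uniform(0.6, 1.4))))
        for _ in range(n_sites)
    ]
    sim = SimSpec(
        n_sites=n_sites, n_loci=n_loci, alleles_per_locus=alleles_per_locus,
        n_per_site=sizes, drift_scale=drift_scale, missing_rate=missing_rate,
        min_site_separation_m=min_separation_m, seed=int(rng.integers(2**31 - 1)),
    )
    sites = place_sites(landscape, sim, habitat_only=habitat_sites)
    table = simulate_genotypes(landscape, sites, sim)
    if missing_rate > 0:
        table = inject_missing(table, missing_rate, seed=int(rng.integers(2**31 - 1)))
        table = filter_individuals(table)
    encoded = encode_multivariate(table)
    mats = population_covariance(encoded, np.asarray(table.site_ids))

    meta = sites[["site_id", "x", "y"]].copy()
    meta["species"] = "sim"
    graph = saturated_graph(mats, meta)
    pruned = prune_edges(graph, mats.C, n_total=table.n_individuals, alpha=alpha)
    nodes = node_connectivity(pruned)

    cmap = omnidirectional_map(
        landscape, n_pairs=n_pairs, buffer_cells=buffer_cells,
        seed=int(rng.integers(2**31 - 1)), connectivity=connectivity,
    )
    records = assemble_records(nodes, landscape, cmap, radii_m=radii_m)
    pca = run_pca(records, k_rule=k_rule)
    reg = fit_ols(records, pca, subset="full")
    return {
        "landscape": landscape, "sites": sites, "genotypes": table,
        "matrices": mats, "graph": graph, "pruned": pruned, "nodes": nodes,
        "current_map": cmap, "records": records, "pca": pca, "regression": reg,
    }


def run_pipeline(config: RunConfig) -> Path:
    """Execute every stage and write the run directory.

    Artifacts: node table, GraphML graph, cGD matrix, current-density
    raster (ESRI ASCII), covariate table, PCA loadings/variance tables,
    per-subset regression tables, optional neighborhood table, and a JSON
    manifest.  Any stage error aborts with the stage named; artifacts
    written before the failure are preserved.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "config_hash": hashlib.sha256(
            json.dumps(asdict(config), sort_keys=True, default=str).encode()
        ).hexdigest()[:16],
        "stages": {},
    }
    rng = np.random.default_rng(config.seed)

    @_stage("inputs")
    def load_inputs():
        if config.simulate is not None:
            sim_cfg = dict(config.simulate)
            land_keys = {
                k: sim_cfg.pop(k) for k in list(sim_cfg)
                if k in {"grid_rows", "grid_cols", "cell_size_m",
                         "habitat_fraction", "clustering", "cost_classes",
                         "semi_fraction"}
            }
            land_keys.setdefault("grid_rows", 60)
            land_keys.setdefault("grid_cols", 60)
            if "cost_classes" in land_keys:
                land_keys["cost_classes"] = tuple(land_keys["cost_classes"])
            landscape = generate_landscape(
                LandscapeSpec(seed=int(rng.integers(2**31 - 1)), **land_keys)
            )
            sim = SimSpec(seed=int(rng.integers(2**31 - 1)), **sim_cfg)
            sites = place_sites(landscape, sim)
            table = simulate_genotypes(landscape, sites, sim)
            if sim.missing_rate > 0:
                table = inject_missing(
                    table, sim.missing_rate, seed=int(rng.integers(2**31 - 1))
                )
            write_ascii_grid(landscape, out / "resistance.asc")
            write_genotypes(table, out / "genotypes.csv", out / "sites.csv")
        else:
            table = read_genotypes(
                config.genotypes, format=config.genotype_format,
                sites_path=config.sites,
            )
            if config.landcover_raster:
                landscape = classify_landcover(
                    read_ascii_grid(config.landcover_raster),
                    config.cost_table or {},
                )
            else:
                landscape = read_ascii_grid(config.resistance_raster)
        return table, landscape

    table, landscape = load_inputs()
    manifest["stages"]["inputs"] = {
        "individuals": table.n_individuals, "loci": table.n_loci,
        "raster_shape": list(landscape.shape),
    }

    @_stage("genetics")
    def genetics_stage():
        filtered = filter_individuals(table, config.max_missing)
        encoded = encode_multivariate(filtered)
        mats = population_covariance(encoded, np.asarray(filtered.site_ids))
        return filtered, mats

    filtered, mats = genetics_stage()
    manifest["stages"]["genetics"] = {
        "individuals_kept": filtered.n_individuals,
        "individuals_removed": table.n_individuals - filtered.n_individuals,
        "sites": len(mats.site_order),
    }

    @_stage("popgraph")
    def popgraph_stage():
        meta = pd.DataFrame(
            [
                {"site_id": s, "x": xy[0], "y": xy[1], "species": "all"}
                for s, xy in filtered.sites.items()
            ]
        ) if filtered.sites else None
        graph = saturated_graph(mats, meta)
        pruned = prune_edges(
            graph, mats.C, n_total=filtered.n_individuals, alpha=config.alpha
        )
        cgd = conditional_genetic_distance(pruned)
        nodes = node_connectivity(pruned)
        write_graphml(pruned, out / "graph.graphml")
        pruned.graph["pruning"].to_csv(out / "edges.csv", index=False)
        cgd.to_frame().to_csv(out / "cgd.csv")
        nodes.to_csv(out / "node_table.csv", index=False)
        return pruned, nodes

    pruned, nodes = popgraph_stage()
    manifest["stages"]["popgraph"] = {
        "edges_kept": pruned.number_of_edges(),
        "edges_candidate": len(pruned.graph["pruning"]),
        "alpha": config.alpha,
    }

    @_stage("circuit")
    def circuit_stage():
        cmap = omnidirectional_map(
            landscape, n_pairs=config.n_pairs, buffer_cells=config.buffer_cells,
            seed=int(rng.integers(2**31 - 1)), connectivity=config.connectivity,
        )
        write_ascii_grid(cmap.current, out / "current_density.asc")
        return cmap

    cmap = circuit_stage()
    manifest["stages"]["circuit"] = {
        "n_pairs": cmap.n_pairs, "buffer_cells": cmap.buffer_cells,
        "buffer_cost": cmap.buffer_cost, "raw_mean": cmap.raw_mean,
    }

    @_stage("covariates")
    def covariates_stage():
        records = assemble_records(nodes, landscape, cmap, radii_m=config.radii_m())
        records.to_csv(out / "covariates.csv", index=False)
        records.attrs["correlations"].to_csv(out / "covariate_correlations.csv")
        return records

    records = covariates_stage()
    manifest["stages"]["covariates"] = {
        "nodes": len(records), "radii_m": list(config.radii_m()),
    }

    @_stage("inference")
    def inference_stage():
        k_rule = (config.k_rule.get("mode", "fixed"), config.k_rule.get("value", 4))
        pca = run_pca(records, k_rule=k_rule)
        pca.loading_table().to_csv(out / "pca_loadings.csv")
        pd.DataFrame(
            {
                "proportion": pca.variance_explained,
                "cumulative": pca.cumulative,
            },
            index=[f"PC{i + 1}" for i in range(len(pca.variance_explained))],
        ).to_csv(out / "pca_variance.csv")
        regs = {}
        for subset in config.subsets:
            reg = fit_ols(records, pca, subset=subset,
                          species_groups=config.species_groups)
            tidy = reg.coef.copy()
            tidy.insert(0, "predictor", tidy.index)
            tidy.to_csv(out / f"regression_{subset}.csv", index=False)
            regs[subset] = reg
        return pca, regs

    pca, regs = inference_stage()
    manifest["stages"]["inference"] = {
        "k_retained": pca.k,
        "cumulative_variance_k": float(pca.cumulative[pca.k - 1]),
        "models": {
            s: {"n": r.n_nodes, "adj_r_squared": r.adj_r_squared,
                "f": r.f_stat, "p": r.f_pvalue}
            for s, r in regs.items()
        },
    }

    if config.neighborhoods:
        @_stage("neighborhoods")
        def neighborhood_stage():
            radii = config.neighborhood_radii_km or config.radii_km
            scale = 500.0 if config.as_diameter else 1000.0
            rows = []
            for r in nodes.itertuples():
                for rad_km in radii:
                    res = neighborhood_analysis(
                        landscape, (float(r.x), float(r.y)), float(rad_km) * scale,
                        inset_m=config.inset_m,
                        seed=int(rng.integers(2**31 - 1)),
                        connectivity=config.connectivity,
                    )
                    rows.append(
                        {
                            "site_id": r.site_id, "radius_km": rad_km,
                            "mean_effective_resistance": res.mean_effective_resistance,
                            "mean_current_density": res.mean_current_density,
                            "clipped": res.clipped,
                        }
                    )
            df = pd.DataFrame(rows)
            df.to_csv(out / "neighborhoods.csv", index=False)
            return df

        nbh = neighborhood_stage()
        manifest["stages"]["neighborhoods"] = {"rows": len(nbh)}

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    log.info("pipeline complete: %s", out)
    return out
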