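"""End-to-end pipeline: simulate or load -> prepare -> neutral model ->
community statistics -> networks -> summaries.

A :class:`PipelineConfig` (loadable from YAML) fully determines a run;
all stage seeds derive from the master seed, so identical configs give
byte-identical outputs.  Neutral-model fits and network inference run
per estuary x season stratum, mirroring per-cruise single-estuary
analyses; strata with too few samples are skipped with a logged warning.
"""

from __future__ import annotations

import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from estuarch import __version__
from estuarch.commstats import bray_curtis, euclidean_distance, mantel, pcoa, permanova
from estuarch.errors import DegenerateFitError, EstuarchError
from estuarch.netinfer import (
    NetworkConfig,
    detect_modules,
    classify_roles,
    infer_direct_network,
    summarize_cross_domain,
    zi_pi,
)
from estuarch.neutral import classify_taxa, fit_ncm, partition_abundance
from estuarch.normalize import CssParams, css_normalize, rarefy
from estuarch.synthdata import (
    NeutralSimSpec,
    make_design,
    plant_selection,
    pool_taxonomy,
    simulate_env_covariates,
    simulate_neutral_samples,
    simulate_source_pool,
)
from estuarch.tables import (
    FeatureTable,
    SampleMetadata,
    TaxonomyMap,
    drop_low_depth_samples,
    filter_for_network,
    read_feature_table,
    read_metadata,
    read_taxonomy,
    shared_feature_counts,
    subset_by_domain,
)

log = logging.getLogger("estuarch")


@dataclass
class SimulationSpec:
    """What the synthetic multi-estuary survey looks like by default:
    4 estuaries x 2 seasons x 2 stations x 5 replicates (80 samples),
    an 800-taxon lognormal pool (70% bacteria / 20% archaea / 10%
    phytoplankton), ~30k reads per sample with estuary-specific
    migration rates, and planted selected-for/against taxa at effect 3."""

    estuaries: tuple[str, ...] = ("YE", "YA", "Q", "P")
    seasons: tuple[str, ...] = ("Winter", "Summer")
    stations: tuple[str, ...] = ("L", "M")
    replicates: int = 5
    n_taxa: int = 800
    lognormal_sigma: float = 2.0
    domain_fractions: dict = field(
        default_factory=lambda: {"bacteria": 0.7, "archaea": 0.2, "phytoplankton": 0.1}
    )
    community_size_N: int = 30_000
    # Yellow River estuary mixes strongly (weak dispersal limitation);
    # the southern estuaries are more dispersal-limited
    migration_by_estuary: dict = field(
        default_factory=lambda: {"YE": 0.4, "YA": 0.12, "Q": 0.12, "P": 0.2}
    )
    migration_default: float = 0.15
    n_selected_for: int = 15
    n_selected_against: int = 10
    selection_effect: float = 3.0


@dataclass
class PipelineConfig:
    out_dir: str = "estuarch_out"
    seed: int = 1
    simulate: SimulationSpec | None = field(default_factory=SimulationSpec)
    table_path: str | None = None
    taxonomy_path: str | None = None
    metadata_path: str | None = None
    min_reads: int = 100
    rarefaction_depth: int = 10_600
    css: CssParams = field(default_factory=CssParams)
    ncm_N: int | str = "auto"
    ncm_d: int = 1
    ncm_ci: float = 0.95
    ncm_source: str = "local"  # "local" (per-stratum pool) or "regional"
    permanova_terms: str = (
        "estuary+season+station+estuary:season+estuary:station+station:season"
    )
    n_perm: int = 999
    network: NetworkConfig = field(
        default_factory=lambda: NetworkConfig(env_names=("temperature", "salinity", "pH"))
    )
    network_min_samples: int = 10

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls()
        for key, value in raw.items():
            if key == "simulate":
                cfg.simulate = SimulationSpec(**value) if value else None
            elif key == "css":
                cfg.css = CssParams(**value)
            elif key == "network":
                if "env_names" in value:
                    value["env_names"] = tuple(value["env_names"])
                cfg.network = NetworkConfig(**value)
            elif hasattr(cfg, key):
                setattr(cfg, key, value)
            else:
                raise ValueError(f"unknown config key {key!r}")
        return cfg


def _stage_seed(master: int, stage: str) -> int:
    # stable across processes (unlike the builtin string hash)
    ss = np.random.SeedSequence([master, zlib.crc32(stage.encode()) % (2**31)])
    return int(ss.generate_state(1)[0] % (2**31))


def simulate_inputs(
    spec: SimulationSpec, seed: int
) -> tuple[FeatureTable, TaxonomyMap, SampleMetadata]:
    """Generate the synthetic survey: crossed design, env covariates, and
    per-stratum neutral communities with planted selection."""
    design = make_design(spec.estuaries, spec.seasons, spec.stations, spec.replicates)
    meta = simulate_env_covariates(design, seed=_stage_seed(seed, "env"))
    pool = simulate_source_pool(
        spec.n_taxa, spec.lognormal_sigma, spec.domain_fractions,
        seed=_stage_seed(seed, "pool"),
    )
    taxonomy = pool_taxonomy(pool)

    blocks = []
    df = meta.df
    for estuary in spec.estuaries:
        for season in spec.seasons:
            mask = (df["estuary"] == estuary) & (df["season"] == season)
            ids = list(df.index[mask])
            m = spec.migration_by_estuary.get(estuary, spec.migration_default)
            sim = NeutralSimSpec(
                n_samples=len(ids),
                community_size_N=spec.community_size_N,
                migration_m=m,
                seed=_stage_seed(seed, f"sim:{estuary}:{season}"),
            )
            tab = simulate_neutral_samples(pool, sim)
            tab.data.index = ids
            if spec.n_selected_for or spec.n_selected_against:
                rng = np.random.default_rng(_stage_seed(seed, f"plant:{estuary}:{season}"))
                freq = (tab.data > 0).mean(axis=0)
                candidates = [
                    t for t in tab.feature_ids if 0.1 <= freq[t] <= 0.3
                ]
                rng.shuffle(candidates)
                sel_for = candidates[: spec.n_selected_for]
                sel_against = [
                    t for t in tab.feature_ids if freq[t] > 0.5
                ][: spec.n_selected_against]
                if sel_for:
                    tab = plant_selection(
                        tab, sel_for, "for", spec.selection_effect,
                        seed=_stage_seed(seed, f"for:{estuary}:{season}"),
                    )
                if sel_against:
                    tab = plant_selection(
                        tab, sel_against, "against", spec.selection_effect,
                        seed=_stage_seed(seed, f"against:{estuary}:{season}"),
                    )
            blocks.append(tab.data)
    table = FeatureTable(pd.concat(blocks).loc[df.index], "raw")
    return table, taxonomy, meta


def run_pipeline(config: PipelineConfig) -> dict[str, Any]:
    """Execute every stage and write outputs under ``config.out_dir``.

    Returns the run manifest (also written as ``manifest.json``).
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {
        "version": __version__,
        "seed": config.seed,
        "stages": {},
    }

    # -- stage: inputs -----------------------------------------------------
    if config.simulate is not None:
        table, taxonomy, meta = simulate_inputs(config.simulate, config.seed)
        table.write_tsv(out / "counts.tsv")
        taxonomy.write_tsv(out / "taxonomy.tsv")
        meta.write_tsv(out / "metadata.tsv")
    else:
        if not (config.table_path and config.taxonomy_path and config.metadata_path):
            raise EstuarchError("load mode requires table/taxonomy/metadata paths")
        table = read_feature_table(config.table_path)
        taxonomy = read_taxonomy(config.taxonomy_path)
        meta = read_metadata(config.metadata_path)
    manifest["stages"]["inputs"] = {
        "n_samples": table.n_samples,
        "n_features": table.n_features,
    }

    # -- stage: prep -------------------------------------------------------
    archaea = subset_by_domain(table, taxonomy, "is_archaeon")
    archaea_kept = drop_low_depth_samples(archaea, config.min_reads)
    css_table = css_normalize(archaea_kept, config.css)
    css_table.write_tsv(out / "archaea_css.tsv")
    try:
        rarefied = rarefy(table, config.rarefaction_depth, _stage_seed(config.seed, "rarefy"))
    except EstuarchError:
        rarefied = None
    manifest["stages"]["prep"] = {
        "archaeal_features": archaea.n_features,
        "archaeal_samples_kept": archaea_kept.n_samples,
        "rarefied_samples": rarefied.n_samples if rarefied is not None else 0,
    }

    meta_kept = SampleMetadata(meta.df.loc[archaea_kept.sample_ids], meta.factors)
    strata = sorted(
        meta.df[["estuary", "season"]].drop_duplicates().itertuples(index=False)
    )

    # -- stage: neutral model ---------------------------------------------
    ncm_rows = []
    regional_p = table.feature_sums().astype(float)
    regional_p = regional_p / regional_p.sum()
    arch_ids = set(archaea.feature_ids)
    for estuary, season in strata:
        ids = [
            s
            for s in table.sample_ids
            if meta.df.loc[s, "estuary"] == estuary and meta.df.loc[s, "season"] == season
        ]
        local = FeatureTable(table.data.loc[ids], "raw")
        if local.n_samples < 5:
            log.warning("NCM skipped for %s/%s: %d samples", estuary, season, local.n_samples)
            continue
        try:
            fit = fit_ncm(
                local,
                source=None if config.ncm_source == "regional" else local,
                source_p=regional_p if config.ncm_source == "regional" else None,
                N=config.ncm_N if config.ncm_N != "auto" else "auto",
                d=config.ncm_d,
                ci_level=config.ncm_ci,
            )
        except DegenerateFitError as exc:
            log.warning("NCM degenerate for %s/%s: %s", estuary, season, exc)
            continue
        focal = [t for t in local.feature_ids if t in arch_ids
                 and (local.data[t] >= config.ncm_d).any()]
        cats = classify_taxa(fit, focal)
        shares = partition_abundance(local, cats)
        fit.to_frame().to_csv(out / f"ncm_{estuary}_{season}.tsv", sep="\t")
        ncm_rows.append(
            (estuary, season, fit.Nm, fit.m, fit.N, fit.r_squared,
             shares["neutral"], shares["above"], shares["below"])
        )
    ncm_df = pd.DataFrame(
        ncm_rows,
        columns=["estuary", "season", "Nm", "m", "N", "r_squared",
                 "frac_neutral", "frac_above", "frac_below"],
    )
    ncm_df.to_csv(out / "ncm_summary.tsv", sep="\t", index=False)
    manifest["stages"]["ncm"] = {"n_fits": len(ncm_df)}

    # shared/unique archaeal features across estuaries per season
    venn: dict[str, dict[str, int]] = {}
    for season in meta.df["season"].unique():
        groups = {}
        for estuary in meta.df["estuary"].unique():
            ids = [
                s for s in archaea_kept.sample_ids
                if meta.df.loc[s, "estuary"] == estuary
                and meta.df.loc[s, "season"] == season
            ]
            if ids:
                groups[estuary] = FeatureTable(archaea_kept.data.loc[ids], "raw")
        if len(groups) >= 2:
            patterns = shared_feature_counts(groups)
            venn[season] = {"|".join(sorted(k)): v for k, v in patterns.items()}
    with open(out / "shared_features.json", "w") as fh:
        json.dump(venn, fh, indent=1, sort_keys=True)

    # -- stage: community statistics ---------------------------------------
    dm = bray_curtis(css_table)
    coords, eigvals, prop = pcoa(dm, n_axes=min(3, dm.n))
    coords.to_csv(out / "pcoa_coordinates.tsv", sep="\t")
    perm = permanova(
        dm, meta_kept, config.permanova_terms,
        n_perm=config.n_perm, seed=_stage_seed(config.seed, "permanova"),
    )
    perm.table.to_csv(out / "permanova.tsv", sep="\t")
    env_cols = [c for c in ("temperature", "salinity", "pH") if c in meta_kept.df.columns]
    mantel_row = {}
    if env_cols:
        env_dm = euclidean_distance(meta_kept.df[env_cols])
        mres = mantel(dm, env_dm, n_perm=config.n_perm,
                      seed=_stage_seed(config.seed, "mantel"))
        mantel_row = {"rho": mres.rho, "p": mres.p_value}
        pd.DataFrame([mantel_row]).to_csv(out / "mantel_env.tsv", sep="\t", index=False)
    manifest["stages"]["stats"] = {
        "permanova_terms": len(perm.table) - 2,
        "pcoa_prop_pc1": float(prop[0]) if len(prop) else float("nan"),
        "mantel_env": mantel_row,
    }

    # -- stage: networks ---------------------------------------------------
    net_rows = []
    for estuary, season in strata:
        ids = [
            s for s in table.sample_ids
            if meta.df.loc[s, "estuary"] == estuary and meta.df.loc[s, "season"] == season
        ]
        sub = FeatureTable(table.data.loc[ids], "raw")
        if sub.n_samples < config.network_min_samples:
            log.warning("network skipped for %s/%s: %d samples", estuary, season, sub.n_samples)
            continue
        filtered = filter_for_network(sub)
        if filtered.n_features < 2:
            log.warning("network skipped for %s/%s: too few features", estuary, season)
            continue
        env_tab = meta.df.loc[ids, list(config.network.env_names)]
        if env_tab.isna().any().any():
            raise EstuarchError(
                f"network stage {estuary}/{season}: missing environmental values "
                f"in columns {env_tab.columns[env_tab.isna().any()].tolist()}"
            )
        net = infer_direct_network(
            filtered, env_tab, config.network,
            seed=_stage_seed(config.seed, f"net:{estuary}:{season}"),
            taxonomy=taxonomy,
        )
        modules = detect_modules(net, seed=_stage_seed(config.seed, f"mod:{estuary}:{season}"))
        zp = zi_pi(net, modules)
        roles = classify_roles(zp)
        for node, role in roles.items():
            net.graph.nodes[node]["role"] = role
        summary = summarize_cross_domain(net, taxonomy)
        prefix = out / f"network_{estuary}_{season}"
        net.edge_frame().to_csv(f"{prefix}_edges.tsv", sep="\t", index=False)
        net.node_frame().to_csv(f"{prefix}_nodes.tsv", sep="\t", index=False)
        summary["edge_classes"].to_csv(f"{prefix}_edge_classes.tsv", sep="\t", index=False)
        all_row = summary["edge_classes"].set_index("edge_class").loc["all"]
        net_rows.append(
            (estuary, season, net.graph.number_of_nodes(), net.graph.number_of_edges(),
             float(all_row["pct_positive"]) if net.graph.number_of_edges() else float("nan"))
        )
    net_df = pd.DataFrame(
        net_rows, columns=["estuary", "season", "n_nodes", "n_edges", "pct_positive"]
    )
    net_df.to_csv(out / "network_summary.tsv", sep="\t", index=False)
    manifest["stages"]["network"] = {"n_networks": len(net_df)}

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest
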