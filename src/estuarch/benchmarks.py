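"""Validation experiments with known ground truth.

Each function runs one self-contained experiment — closed form vs
Monte-Carlo, parameter recovery from simulation, exact permutation
enumeration, planted-graph recovery — and returns a flat dict of the
quantities it measured.  The experiments double as the package's
acceptance checks and as reproducible benchmark entry points; every one
is deterministic given its seed.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import rankdata, spearmanr

from estuarch.commstats import (
    DistanceMatrix,
    bray_curtis,
    mantel,
    partial_mantel,
    pcoa,
    permanova,
)
from estuarch.neutral import classify_taxa, expected_frequency, fit_ncm
from estuarch.netinfer import NetworkConfig, infer_direct_network
from estuarch.synthdata import (
    NeutralSimSpec,
    PlantedGraphSpec,
    plant_selection,
    random_planted_graph_spec,
    simulate_graph_counts,
    simulate_neutral_samples,
    simulate_source_pool,
)
from estuarch.tables import FeatureTable


# ---------------------------------------------------------------------------
# neutral model
# ---------------------------------------------------------------------------

def ncm_closed_form_vs_monte_carlo(
    seed: int = 0, n_draws: int = 10**6, N: int = 1000, d: int = 1
) -> dict:
    """Closed-form detection probability vs beta-sampling Monte Carlo on
    a 5x5 grid of (p, Nm).  Reports the worst absolute deviation in
    Monte-Carlo standard errors (with a 1/n_draws floor for saturated
    cells)."""
    rng = np.random.default_rng(seed)
    ps = [0.0005, 0.002, 0.01, 0.05, 0.2]
    nms = [10.0, 50.0, 100.0, 500.0, 2000.0]
    worst = 0.0
    for p in ps:
        for nm in nms:
            draws = rng.beta(nm * p, nm * (1 - p), n_draws)
            mc = float((draws > d / N).mean())
            closed = expected_frequency(p, nm, N, d)
            se = max(np.sqrt(mc * (1 - mc) / n_draws), 1.0 / n_draws)
            worst = max(worst, abs(closed - mc) / se)
    return {"grid_cells": len(ps) * len(nms), "max_abs_z": worst}


def ncm_migration_recovery(
    seed: int = 0,
    true_m: tuple[float, ...] = (0.05, 0.1, 0.5),
    n_sims: int = 20,
    S: int = 500,
    N: int = 10_000,
    n_samples: int = 100,
) -> dict:
    """Fit the neutral model to its own simulator output.

    ``n_sims`` seeded simulations spread across the true migration
    rates; reports the median relative error of the fitted m and the
    Spearman correlation between true and fitted m (monotonicity)."""
    reps = [true_m[i % len(true_m)] for i in range(n_sims)]
    errors, fitted, truth = [], [], []
    for i, m in enumerate(sorted(reps)):
        pool = simulate_source_pool(S, 2.0, seed=seed + 7919 * i + 1)
        tab = simulate_neutral_samples(
            pool, NeutralSimSpec(n_samples, N, m, seed=seed + 104729 * i + 2)
        )
        fit = fit_ncm(tab, source_p=pool.as_series(), N=N)
        errors.append(abs(fit.m - m) / m)
        fitted.append(fit.m)
        truth.append(m)
    rho = spearmanr(truth, fitted).statistic
    return {
        "n_sims": n_sims,
        "median_rel_error_m": float(np.median(errors)),
        "monotonicity_rho": float(rho),
    }


def ncm_selection_recovery(
    seed: int = 0,
    n_planted: int = 20,
    effect: float = 3.0,
    S: int = 500,
    N: int = 10_000,
    n_samples: int = 100,
    m: float = 0.1,
) -> dict:
    """Plant selected-for taxa on a neutral table, refit, and measure the
    sensitivity of the "above" label plus the false-above rate among the
    untouched (truly neutral) taxa."""
    pool = simulate_source_pool(S, 2.0, seed=seed + 11)
    tab = simulate_neutral_samples(pool, NeutralSimSpec(n_samples, N, m, seed=seed + 12))
    freq = (tab.data > 0).mean(axis=0)
    planted = [t for t in tab.feature_ids if 0.05 <= freq[t] <= 0.3][:n_planted]
    perturbed = plant_selection(tab, planted, "for", effect, seed=seed + 13)
    fit = fit_ncm(perturbed, source_p=pool.as_series(), N=N)
    cats = classify_taxa(fit, planted)
    sensitivity = float((cats == "above").mean())
    neutral_taxa = [t for t in tab.feature_ids if t not in planted and freq[t] > 0]
    false_above = float((classify_taxa(fit, neutral_taxa) == "above").mean())
    return {
        "n_planted": len(planted),
        "sensitivity_above": sensitivity,
        "false_above_rate": false_above,
    }


# ---------------------------------------------------------------------------
# PERMANOVA / Mantel / PCoA
# ---------------------------------------------------------------------------

def _two_group_pseudo_f(d: np.ndarray, labels: np.ndarray) -> float:
    n = len(labels)
    groups = np.unique(labels)
    sst = (d[np.triu_indices(n, 1)] ** 2).sum() / n
    ssw = 0.0
    for g in groups:
        idx = np.flatnonzero(labels == g)
        sub = d[np.ix_(idx, idx)]
        ssw += (sub[np.triu_indices(len(idx), 1)] ** 2).sum() / len(idx)
    ssa = sst - ssw
    return (ssa / (len(groups) - 1)) / (ssw / (n - len(groups)))


def permanova_exhaustive_check(seed: int = 0) -> dict:
    """n=6 two-group design: the permutation p-value from the sequential
    projection implementation vs brute-force enumeration of all 720
    relabelings with the classical group-sum pseudo-F."""
    rng = np.random.default_rng(seed)
    pts = rng.normal(size=(6, 3))
    d = DistanceMatrix(squareform(pdist(pts)), [f"s{i}" for i in range(6)])
    labels = np.array(["A", "A", "A", "B", "B", "B"])
    meta = pd.DataFrame({"grp": labels}, index=d.sample_ids)
    res = permanova(d, meta, ["grp"], all_perms=True)
    f_obs = _two_group_pseudo_f(d.values, labels)
    count = total = 0
    for pm in itertools.permutations(range(6)):
        dp = d.values[np.ix_(pm, pm)]
        count += _two_group_pseudo_f(dp, labels) >= f_obs - 1e-12
        total += 1
    return {
        "p_implementation": float(res["grp"]["p"]),
        "p_enumeration": count / total,
        "abs_f_diff_vs_oracle": abs(float(res["grp"]["F"]) - f_obs),
    }


def permanova_type_i_error(
    seed: int = 0, n_datasets: int = 200, n_perm: int = 999, n_samples: int = 16
) -> dict:
    """Null rejection rate at alpha=0.05 over structureless datasets:
    random counts, random balanced two-group labels."""
    rng = np.random.default_rng(seed)
    rejections = 0
    for i in range(n_datasets):
        counts = rng.integers(0, 60, size=(n_samples, 25))
        counts[counts.sum(axis=1) == 0, 0] = 1
        tab = FeatureTable(
            pd.DataFrame(counts, index=[f"s{j}" for j in range(n_samples)])
        )
        d = bray_curtis(tab)
        labels = np.array(["A", "B"] * (n_samples // 2))
        rng.shuffle(labels)
        meta = pd.DataFrame({"grp": labels}, index=d.sample_ids)
        res = permanova(d, meta, ["grp"], n_perm=n_perm,
                        seed=int(rng.integers(2**31)))
        if res["grp"]["p"] <= 0.05:
            rejections += 1
    return {
        "n_datasets": n_datasets,
        "rejection_rate": rejections / n_datasets,
    }


def mantel_checks(seed: int = 0) -> dict:
    """Identity rho, exhaustive n=5 p-value agreement, and the partial
    test against a shared latent driver."""
    rng = np.random.default_rng(seed)
    pts = rng.normal(size=(8, 3))
    d = DistanceMatrix(squareform(pdist(pts)), [f"s{i}" for i in range(8)])
    rho_self = mantel(d, d, n_perm=99, seed=seed).rho

    pts1 = rng.normal(size=(5, 2))
    pts2 = rng.normal(size=(5, 2))
    ids5 = [f"s{i}" for i in range(5)]
    d1 = DistanceMatrix(squareform(pdist(pts1)), ids5)
    d2 = DistanceMatrix(squareform(pdist(pts2)), ids5)
    res = mantel(d1, d2, all_perms=True)
    v1 = rankdata(squareform(d1.values, checks=False))
    count = total = 0
    for pm in itertools.permutations(range(5)):
        v2 = rankdata(squareform(d2.values[np.ix_(pm, pm)], checks=False))
        count += np.corrcoef(v1, v2)[0, 1] >= res.rho - 1e-12
        total += 1

    # shared latent driver: D1 and D2 = driver distance + independent
    # pair-level noise; n = 40 keeps the partial-correlation sampling
    # noise well below the 0.1 scale of interest
    n = 40
    driver = rng.normal(size=(n, 1))
    d3v = squareform(pdist(driver))
    ids = [f"s{i}" for i in range(n)]
    def noisy():
        noise = rng.normal(0, 0.4, size=(n, n))
        noise = np.abs(noise + noise.T) / 2
        np.fill_diagonal(noise, 0)
        vals = d3v + noise
        np.fill_diagonal(vals, 0)
        return DistanceMatrix(vals, ids)
    da, db = noisy(), noisy()
    d3 = DistanceMatrix(d3v, ids)
    partial_rho = partial_mantel(da, db, d3, n_perm=99, seed=seed).rho
    return {
        "rho_identity": float(rho_self),
        "p_implementation": float(res.p_value),
        "p_enumeration": count / total,
        "partial_rho_given_driver": float(partial_rho),
    }


def pcoa_checks(seed: int = 0, n_points: int = 15) -> dict:
    """Planar configuration reconstruction error and the eigenvalue
    trace identity of Gower centering."""
    rng = np.random.default_rng(seed)
    pts = rng.normal(size=(n_points, 2))
    ids = [f"s{i}" for i in range(n_points)]
    d = DistanceMatrix(squareform(pdist(pts)), ids)
    coords, eig, _ = pcoa(d, 2)
    recon = squareform(pdist(coords.to_numpy()))
    a = -0.5 * d.values**2
    j = np.eye(n_points) - np.ones((n_points, n_points)) / n_points
    g = j @ a @ j
    return {
        "max_reconstruction_error": float(np.abs(recon - d.values).max()),
        "trace_identity_error": float(abs(eig.sum() - np.trace(g))),
    }


# ---------------------------------------------------------------------------
# network inference
# ---------------------------------------------------------------------------

def network_planted_benchmark(seed: int = 3) -> dict:
    """50 taxa / 40 planted edges / n=200: precision and recall of the
    inferred edge set against the planted graph."""
    spec = random_planted_graph_spec(seed=seed)
    tab, _ = simulate_graph_counts(spec)
    net = infer_direct_network(tab, None, NetworkConfig(), seed=0)
    got = set(net.edges)
    truth = {tuple(sorted((a, b))) for a, b, _, _ in spec.edges}
    tp = len(got & truth)
    return {
        "n_true_edges": len(truth),
        "n_found_edges": len(got),
        "precision": tp / len(got) if got else 0.0,
        "recall": tp / len(truth),
    }


def network_chain_skip_rate(seed: int = 0, n_runs: int = 40) -> dict:
    """Latent chains of length 3-5 embedded among independent taxa: the
    fraction of seeded runs reporting any skip-level edge between chain
    members."""
    runs_with_skip = 0
    total = 0
    lengths = [3, 4, 5]
    per = [n_runs // 3 + (1 if i < n_runs % 3 else 0) for i in range(3)]
    for L, reps in zip(lengths, per):
        taxa = [f"ZOTU{i+1}" for i in range(30)]
        edges = tuple((taxa[i], taxa[i + 1], 1, 0.4) for i in range(L - 1))
        truth = {tuple(sorted(e[:2])) for e in edges}
        chain = set(taxa[:L])
        for r in reps * [None]:
            spec = PlantedGraphSpec(30, edges, (), 500, 50_000,
                                    seed=seed + 1000 * L + total)
            tab, _ = simulate_graph_counts(spec)
            net = infer_direct_network(tab, None, NetworkConfig(), seed=0)
            skips = {
                e for e in net.edges if e[0] in chain and e[1] in chain
            } - truth
            runs_with_skip += bool(skips)
            total += 1
    return {
        "n_runs": total,
        "skip_free_fraction": 1.0 - runs_with_skip / total,
    }


def network_env_confounder_check(seed: int = 5) -> dict:
    """Two taxa driven by temperature with no direct edge: the inferred
    network must drop the taxon-taxon edge and keep both taxon-env
    edges."""
    spec = PlantedGraphSpec(
        20, (), (("temperature", "ZOTU1", 1.0), ("temperature", "ZOTU2", 1.0)),
        300, 50_000, seed=seed,
    )
    tab, env = simulate_graph_counts(spec)
    net = infer_direct_network(
        tab, env, NetworkConfig(env_names=("temperature",)), seed=0
    )
    got = set(net.edges)
    return {
        "confounded_pair_edge": int(("ZOTU1", "ZOTU2") in got),
        "env_edges_kept": int(("ZOTU1", "temperature") in got)
        + int(("ZOTU2", "temperature") in got),
    }
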