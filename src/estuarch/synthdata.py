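"""Synthetic inputs with known ground truth.

Every downstream stage is validated against data whose generating
process is known exactly:

* a lognormal source pool (the classic shape of rank-abundance curves in
  amplicon surveys), split into archaeal / bacterial / phytoplankton
  fractions;
* neutral local communities sampled from the stationary distribution of
  the neutral model — per taxon and sample, a relative abundance
  x ~ Beta(N*m*p, N*m*(1-p)) followed by a Binomial(N, x) read count —
  so the simulator is the exact generative counterpart of the fitted
  model rather than an agent-based approximation;
* planted selection: listed taxa get their occurrence frequency inflated
  ("selected for") or deflated ("selected against") by a known factor,
  leaving everything else untouched, for classification recovery tests;
* compositional counts with a known sparse direct-association graph: a
  latent Gaussian with the planted edges as the only nonzero precision
  off-diagonals (plus optional environmental parent effects), pushed
  through softmax-to-proportions and a multinomial read draw, matching
  the clr-based assumptions of the network module;
* the multi-estuary crossed sampling design (estuary x season x
  station x replicate) with the field's sample-id scheme.

All generators are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from estuarch.tables import FeatureTable, SampleMetadata, TaxonomyMap


@dataclass
class SourcePool:
    """Metacommunity relative abundances (the p of the neutral model)."""

    taxon_ids: list[str]
    rel_abundance: np.ndarray
    domain_labels: list[str]

    def __post_init__(self) -> None:
        if len(set(self.taxon_ids)) != len(self.taxon_ids):
            raise ValueError("taxon_ids must be unique")
        ra = np.asarray(self.rel_abundance, dtype=float)
        if np.any(ra < 0) or abs(ra.sum() - 1.0) > 1e-12:
            raise ValueError("rel_abundance must be nonnegative and sum to 1")
        self.rel_abundance = ra

    @property
    def n_taxa(self) -> int:
        return len(self.taxon_ids)

    def as_series(self) -> pd.Series:
        return pd.Series(self.rel_abundance, index=self.taxon_ids, name="p")


@dataclass(frozen=True)
class NeutralSimSpec:
    """Conditions of a neutral-assembly simulation."""

    n_samples: int
    community_size_N: int
    migration_m: float
    detection_d: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        if self.community_size_N < 1:
            raise ValueError("community_size_N must be >= 1")
        if not 0.0 < self.migration_m <= 1.0:
            raise ValueError("migration_m must be in (0, 1]")
        if self.detection_d < 1:
            raise ValueError("detection_d must be >= 1")


@dataclass(frozen=True)
class PlantedGraphSpec:
    """A known sparse direct-association structure for benchmarks.

    ``edges`` are (taxon_a, taxon_b, sign, strength) with sign in
    {+1, -1} and strength in (0, 1): the magnitude of the planted latent
    partial correlation.  ``env_effects`` are (env_name, taxon, strength)
    linear parent effects of standard-normal environmental covariates on
    the latent abundances.
    """

    n_taxa: int
    edges: tuple[tuple[str, str, int, float], ...] = ()
    env_effects: tuple[tuple[str, str, float], ...] = ()
    n_samples: int = 200
    sequencing_depth: int = 50_000
    seed: int = 0

    def __post_init__(self) -> None:
        for a, b, sign, s in self.edges:
            if a == b:
                raise ValueError(f"self-loop on {a!r}")
            if sign not in (-1, 1):
                raise ValueError(f"edge sign must be +-1, got {sign}")
            if not 0.0 < abs(s) < 1.0:
                raise ValueError(f"edge strength must be in (0, 1), got {s}")


def taxon_names(n_taxa: int) -> list[str]:
    return [f"ZOTU{i+1}" for i in range(n_taxa)]


def simulate_source_pool(
    n_taxa: int,
    lognormal_sigma: float = 2.0,
    domain_fractions: dict[str, float] | None = None,
    seed: int = 0,
) -> SourcePool:
    """Lognormal source pool with domain labels in stated fractions.

    Relative abundances are exp(sigma * z) draws renormalized to 1; in
    the sigma -> 0 limit all taxa are equally abundant.  Domain labels
    ("archaea", "bacteria", "phytoplankton", ...) are assigned in the
    given fractions (largest-remainder rounding) and shuffled so domain
    does not correlate with abundance rank.
    """
    if n_taxa < 2:
        raise ValueError("n_taxa must be >= 2")
    if lognormal_sigma < 0:
        raise ValueError("lognormal_sigma must be >= 0")
    if domain_fractions is None:
        domain_fractions = {"archaea": 1.0}
    total = sum(domain_fractions.values())
    if abs(total - 1.0) > 1e-9:
        raise ValueError("domain_fractions must sum to 1")

    rng = np.random.default_rng(seed)
    z = rng.standard_normal(n_taxa)
    ra = np.exp(lognormal_sigma * z)
    ra = ra / ra.sum()

    domains = list(domain_fractions)
    raw = np.array([domain_fractions[d] * n_taxa for d in domains])
    counts = np.floor(raw).astype(int)
    remainder = n_taxa - counts.sum()
    order = np.argsort(-(raw - counts))
    for i in range(remainder):
        counts[order[i % len(domains)]] += 1
    labels = [d for d, c in zip(domains, counts) for _ in range(c)]
    rng.shuffle(labels)
    return SourcePool(taxon_names(n_taxa), ra, labels)


def pool_taxonomy(pool: SourcePool) -> TaxonomyMap:
    """Minimal taxonomy for a synthetic pool: domain from the pool label,
    genus = one synthetic genus per 10 taxa within each domain."""
    rows = {}
    per_domain_counter: dict[str, int] = {}
    for tid, label in zip(pool.taxon_ids, pool.domain_labels):
        k = per_domain_counter.get(label, 0)
        per_domain_counter[label] = k + 1
        genus = f"{label[:3].capitalize()}Genus{k // 10 + 1}"
        if label == "phytoplankton":
            rows[tid] = ("Bacteria", "Cyanobacteria", "Cyanobacteriia",
                         "Chloroplast", f"{genus}aceae", genus)
        elif label == "archaea":
            rows[tid] = ("Archaea", "Thermoproteota", "Nitrososphaeria",
                         "Nitrosopumilales", f"{genus}aceae", genus)
        else:
            rows[tid] = ("Bacteria", "Proteobacteria", "Gammaproteobacteria",
                         "Pseudomonadales", f"{genus}aceae", genus)
    df = pd.DataFrame.from_dict(
        rows, orient="index", columns=list(TaxonomyMap.RANKS)
    )
    return TaxonomyMap(df)


def simulate_neutral_samples(pool: SourcePool, spec: NeutralSimSpec) -> FeatureTable:
    """Sample local communities from the neutral model's stationary
    distribution.

    Per taxon i and sample j: x_ij ~ Beta(N*m*p_i, N*m*(1-p_i)), then
    count_ij ~ Binomial(N, x_ij).  Counts are drawn per taxon
    independently (the independent-taxon approximation under which the
    model is fitted), so row sums vary around N rather than equalling it.
    """
    if pool.n_taxa == 0:
        raise ValueError("empty source pool")
    p = pool.rel_abundance
    Nm = spec.community_size_N * spec.migration_m
    a = Nm * p
    b = Nm * (1.0 - p)
    if np.all(a == 0):
        raise ValueError("N*m*p is zero for every taxon; nothing to simulate")

    rng = np.random.default_rng(spec.seed)
    n, S = spec.n_samples, pool.n_taxa
    x = np.empty((n, S))
    pos = (a > 0) & (b > 0)
    x[:, pos] = rng.beta(a[pos], b[pos], size=(n, pos.sum()))
    x[:, a == 0] = 0.0  # p = 0: taxon absent from the source
    x[:, b == 0] = 1.0  # p = 1: taxon fixed in the source
    counts = rng.binomial(spec.community_size_N, x)
    df = pd.DataFrame(
        counts,
        index=[f"S{j+1}" for j in range(n)],
        columns=pool.taxon_ids,
    )
    return FeatureTable(df, "raw")


def plant_selection(
    table: FeatureTable,
    taxa: Sequence[str],
    mode: Literal["for", "against"],
    effect: float,
    seed: int = 0,
) -> FeatureTable:
    """Perturb occurrence frequency of listed taxa by a known factor.

    mode "for": zeros of each listed taxon are converted to detections
    (counts resampled from its nonzero counts) until its frequency
    reaches min(effect * freq, 1) — mimicking taxa favoured by local
    conditions.  mode "against": detections are zeroed until the
    frequency drops to freq / effect.  ``effect`` = 1 is the identity.
    Other taxa are untouched; frequency targets are met in expectation
    by rounding to the nearest achievable sample count.
    """
    if effect < 1.0:
        raise ValueError("effect must be >= 1")
    missing = [t for t in taxa if t not in table.feature_ids]
    if missing:
        raise KeyError(f"unknown taxa: {missing[:10]}")
    rng = np.random.default_rng(seed)
    data = table.data.copy()
    n = table.n_samples
    for t in taxa:
        col = data[t].to_numpy().copy()
        detected = col > 0
        k = int(detected.sum())
        if mode == "for":
            target = min(int(round(k * effect)), n)
            need = target - k
            zeros = np.flatnonzero(~detected)
            if need > 0 and k > 0 and zeros.size:
                flip = rng.choice(zeros, size=min(need, zeros.size), replace=False)
                col[flip] = rng.choice(col[detected], size=flip.size, replace=True)
        elif mode == "against":
            target = int(round(k / effect))
            drop = k - target
            ones = np.flatnonzero(detected)
            if drop > 0 and ones.size:
                kill = rng.choice(ones, size=min(drop, ones.size), replace=False)
                col[kill] = 0
        else:
            raise ValueError(f"unknown mode {mode!r}")
        data[t] = col
    return FeatureTable(data, table.normalized)


def _build_precision(
    taxa: list[str], edges: Sequence[tuple[str, str, int, float]]
) -> np.ndarray:
    idx = {t: i for i, t in enumerate(taxa)}
    S = len(taxa)
    omega = np.eye(S)
    for a, b, sign, strength in edges:
        if a not in idx or b not in idx:
            raise KeyError(f"edge endpoint not in taxa: {(a, b)}")
        i, j = idx[a], idx[b]
        # partial correlation of a Gaussian is -omega_ij / sqrt(omega_ii omega_jj)
        omega[i, j] = omega[j, i] = -sign * abs(strength)
    eigmin = float(np.linalg.eigvalsh(omega).min())
    if eigmin <= 1e-10:
        raise ValueError(
            f"planted precision matrix is not positive definite "
            f"(min eigenvalue {eigmin:.3g}); reduce edge strengths or degree "
            f"of edges {list(edges)[:5]}..."
        )
    return omega


def simulate_graph_counts(
    spec: PlantedGraphSpec,
) -> tuple[FeatureTable, pd.DataFrame]:
    """Compositional counts whose latent direct-association graph is known.

    Latent taxon abundances z ~ N(0, Omega^{-1}) with Omega the unit-
    diagonal precision matrix carrying exactly the planted edges (so the
    latent partial correlations equal the edge strengths with the edge
    signs).  Environmental covariates e_k ~ N(0, 1) act as additional
    linear parents: z_i += strength * e_k.  Per sample, proportions =
    softmax(z + log-baseline) and counts ~ Multinomial(depth), so rows
    close to the sequencing depth exactly and clr(counts) tracks the
    latent field up to centering.

    Returns (counts, env_table).
    """
    taxa = taxon_names(spec.n_taxa)
    omega = _build_precision(taxa, spec.edges)
    cov = np.linalg.inv(omega)
    rng = np.random.default_rng(spec.seed)
    chol = np.linalg.cholesky(cov)
    z = rng.standard_normal((spec.n_samples, spec.n_taxa)) @ chol.T

    env_names = sorted({e for e, _, _ in spec.env_effects})
    env = pd.DataFrame(
        rng.standard_normal((spec.n_samples, len(env_names))),
        columns=env_names,
        index=[f"S{j+1}" for j in range(spec.n_samples)],
    )
    idx = {t: i for i, t in enumerate(taxa)}
    for env_name, taxon, strength in spec.env_effects:
        if taxon not in idx:
            raise KeyError(f"env effect on unknown taxon {taxon!r}")
        z[:, idx[taxon]] += strength * env[env_name].to_numpy()

    # moderate lognormal baseline keeps all taxa detectable at this depth
    base = 0.5 * np.random.default_rng(spec.seed + 1).standard_normal(spec.n_taxa)
    logits = z + base
    expz = np.exp(logits - logits.max(axis=1, keepdims=True))
    props = expz / expz.sum(axis=1, keepdims=True)
    counts = np.vstack(
        [rng.multinomial(spec.sequencing_depth, props[j]) for j in range(spec.n_samples)]
    )
    table = FeatureTable(
        pd.DataFrame(counts, index=env.index, columns=taxa), "raw"
    )
    return table, env


def random_planted_graph_spec(
    n_taxa: int = 50,
    n_edges: int = 40,
    strength: float = 0.3,
    max_degree: int = 3,
    positive_fraction: float = 0.7,
    n_samples: int = 200,
    sequencing_depth: int = 50_000,
    seed: int = 3,
) -> PlantedGraphSpec:
    """Random sparse association graph with bounded degree.

    The degree bound keeps the unit-diagonal precision matrix positive
    definite at the given edge ``strength`` (|latent partial
    correlation| of every planted edge); signs are positive with the
    given fraction, mirroring the dominance of positive associations in
    plankton co-occurrence networks.
    """
    rng = np.random.default_rng(seed)
    taxa = taxon_names(n_taxa)
    deg = {t: 0 for t in taxa}
    chosen: set[tuple[str, str]] = set()
    edges: list[tuple[str, str, int, float]] = []
    attempts = 0
    while len(edges) < n_edges:
        attempts += 1
        if attempts > 100 * n_edges:
            raise ValueError("could not place requested edges under degree bound")
        i, j = rng.choice(n_taxa, size=2, replace=False)
        a, b = sorted((taxa[i], taxa[j]))
        if deg[a] >= max_degree or deg[b] >= max_degree or (a, b) in chosen:
            continue
        sign = 1 if rng.random() < positive_fraction else -1
        edges.append((a, b, sign, strength))
        chosen.add((a, b))
        deg[a] += 1
        deg[b] += 1
    return PlantedGraphSpec(
        n_taxa, tuple(edges), (), n_samples, sequencing_depth, seed
    )


def ground_truth_edges(spec: PlantedGraphSpec) -> pd.DataFrame:
    """Planted edge list as a 3-column frame (node_a, node_b, sign)."""
    rows = [
        (*sorted((a, b)), "+" if sign > 0 else "-") for a, b, sign, _ in spec.edges
    ]
    return pd.DataFrame(rows, columns=["node_a", "node_b", "sign"]).sort_values(
        ["node_a", "node_b"]
    ).reset_index(drop=True)


# ---------------------------------------------------------------------------
# sampling design
# ---------------------------------------------------------------------------

DEFAULT_ESTUARIES = ("YE", "YA", "Q", "P")  # Yellow, Yangtze, Qiantang, Pearl
DEFAULT_SEASONS = ("Winter", "Summer")
DEFAULT_STATIONS = ("L", "M")  # low (~10 psu) / medium (~25 psu) salinity


def make_design(
    estuaries: Sequence[str] = DEFAULT_ESTUARIES,
    seasons: Sequence[str] = DEFAULT_SEASONS,
    stations: Sequence[str] = DEFAULT_STATIONS,
    replicates: int = 5,
) -> SampleMetadata:
    """Fully crossed estuary x season x station x replicate design.

    Sample ids follow the cruise naming scheme: season initial + estuary
    code + station code + replicate, e.g. ``WYE_L_1`` for winter, Yellow
    River estuary, low-salinity station, replicate 1.  The default
    4 x 2 x 2 x 5 design yields 80 samples.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    if not (estuaries and seasons and stations):
        raise ValueError("estuaries, seasons and stations must be nonempty")
    rows = []
    for season in seasons:
        for estuary in estuaries:
            for station in stations:
                for rep in range(1, replicates + 1):
                    sid = f"{season[0].upper()}{estuary}_{station}_{rep}"
                    rows.append((sid, estuary, season, station))
    df = pd.DataFrame(rows, columns=["sample_id", "estuary", "season", "station"]).set_index(
        "sample_id"
    )
    if df.index.has_duplicates:
        raise ValueError("design produces duplicate sample ids; use distinct codes")
    return SampleMetadata(df)


def simulate_env_covariates(design: SampleMetadata, seed: int = 0) -> SampleMetadata:
    """Fill the design with environmental covariates that track the
    factors: temperature follows season (winter ~5-18 C by latitude,
    summer ~25-30 C), salinity the station level (~10 vs ~25 psu), with
    pH, DO, nutrients and COD varying around typical estuarine values
    plus replicate noise."""
    rng = np.random.default_rng(seed)
    df = design.df.copy()
    n = len(df)
    est_codes = sorted(df["estuary"].unique())
    lat_rank = {e: i / max(len(est_codes) - 1, 1) for i, e in enumerate(est_codes)}
    winter = df["season"].str.lower().str.startswith("w").to_numpy()
    lat = df["estuary"].map(lat_rank).to_numpy()
    df["temperature"] = np.where(winter, 3.0 + 14.0 * lat, 25.0 + 4.0 * lat) + rng.normal(0, 1.0, n)
    df["salinity"] = np.where(df["station"] == "L", 10.0, 25.0) + rng.normal(0, 1.5, n)
    df["pH"] = 8.0 + 0.1 * (df["salinity"] - 17.5) / 7.5 + rng.normal(0, 0.08, n)
    df["DO"] = np.where(winter, 9.5, 6.5) - 1.5 * lat + rng.normal(0, 0.5, n)
    df["NO3"] = np.exp(rng.normal(2.5, 0.5, n)) * (1.6 - 0.04 * df["salinity"]) / 30.0
    df["NO2"] = np.exp(rng.normal(0.0, 0.5, n)) / 10.0
    df["PO4"] = np.exp(rng.normal(0.0, 0.4, n)) / 2.0
    df["SiO3"] = np.exp(rng.normal(2.0, 0.5, n)) * (1.6 - 0.04 * df["salinity"]) / 10.0
    df["COD"] = 2.0 + 1.5 * (1.0 - lat) + rng.normal(0, 0.3, n)
    return SampleMetadata(df, design.factors)
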