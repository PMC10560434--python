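"""Distance-based community statistics.

Implements Bray-Curtis dissimilarity, principal coordinate analysis
(classical MDS via Gower centering), multi-factor PERMANOVA with
sequential (Type I) sums of squares and interaction terms, Mantel and
partial Mantel permutation tests, and a Spearman environment-abundance
correlation screen.  The permutation machinery is shared: all p-values
use the add-one rule p = (1 + #{perm >= obs}) / (1 + n_perm) and are
deterministic given a seed; small designs may request exhaustive
enumeration of every relabeling instead of random sampling.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform

from estuarch.errors import DesignError, UndefinedCorrelationError
from estuarch.tables import FeatureTable, SampleMetadata


@dataclass
class DistanceMatrix:
    """Symmetric nonnegative distance matrix keyed by sample ids."""

    values: np.ndarray
    sample_ids: list[str]

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("distance matrix must be square")
        if len(self.sample_ids) != v.shape[0]:
            raise ValueError("sample_ids length mismatch")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.abs(np.diag(v)) > 1e-12):
            raise ValueError("distance matrix diagonal must be zero")
        if v.size and v.min() < 0:
            raise ValueError("distances must be nonnegative")
        self.values = (v + v.T) / 2.0
        np.fill_diagonal(self.values, 0.0)

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def condensed(self) -> np.ndarray:
        """Upper-triangle (off-diagonal) entries in scipy condensed order."""
        return squareform(self.values, checks=False)

    def subset(self, ids: list[str]) -> "DistanceMatrix":
        idx = [self.sample_ids.index(i) for i in ids]
        return DistanceMatrix(self.values[np.ix_(idx, idx)], list(ids))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.sample_ids)


def bray_curtis(table: FeatureTable) -> DistanceMatrix:
    """Bray-Curtis dissimilarity d(x, y) = sum|x_i - y_i| / sum(x_i + y_i)."""
    v = table.values.astype(float)
    zero = v.sum(axis=1) == 0
    if zero.any():
        bad = [s for s, z in zip(table.sample_ids, zero) if z]
        raise ValueError(f"all-zero samples have undefined Bray-Curtis distance: {bad}")
    dm = squareform(pdist(v, metric="braycurtis"))
    return DistanceMatrix(dm, table.sample_ids)


def euclidean_distance(df: pd.DataFrame, standardize: bool = True) -> DistanceMatrix:
    """Euclidean distance between samples on (optionally z-scored) columns;
    the usual metric for environmental covariate matrices."""
    x = df.to_numpy(dtype=float)
    if standardize:
        sd = x.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        x = (x - x.mean(axis=0)) / sd
    return DistanceMatrix(squareform(pdist(x)), list(df.index))


def _gower_center(d: np.ndarray) -> np.ndarray:
    a = -0.5 * d ** 2
    row = a.mean(axis=1, keepdims=True)
    col = a.mean(axis=0, keepdims=True)
    return a - row - col + a.mean()


def pcoa(D: DistanceMatrix, n_axes: int | None = None):
    """Principal coordinate analysis (classical metric MDS).

    Eigendecomposes the Gower-centered matrix -1/2 J D^2 J.  Axes are
    ordered by descending eigenvalue; negative eigenvalues (from
    non-Euclidean dissimilarities such as Bray-Curtis) are reported, not
    corrected, and proportion explained is over positive eigenvalues
    only.

    Returns
    -------
    (coordinates, eigenvalues, proportion_explained)
        coordinates: DataFrame (samples x axes, columns PC1..);
        eigenvalues: full descending spectrum; proportion_explained:
        per returned axis.
    """
    n = D.n
    if n_axes is None:
        n_axes = n
    if n_axes > n:
        raise ValueError(f"n_axes={n_axes} exceeds matrix size {n}")
    g = _gower_center(D.values)
    eigvals, eigvecs = np.linalg.eigh(g)
    order = np.argsort(eigvals)[::-1]
    eigvals = eigvals[order]
    eigvecs = eigvecs[:, order]
    coords = np.zeros((n, n_axes))
    pos = eigvals > 0
    scale = np.sqrt(np.where(pos, eigvals, 0.0))
    coords = eigvecs[:, :n_axes] * scale[:n_axes]
    pos_sum = eigvals[pos].sum()
    prop = np.where(eigvals[:n_axes] > 0, eigvals[:n_axes], 0.0) / pos_sum if pos_sum > 0 else np.zeros(n_axes)
    coord_df = pd.DataFrame(
        coords, index=D.sample_ids, columns=[f"PC{i+1}" for i in range(n_axes)]
    )
    return coord_df, eigvals, prop


# ---------------------------------------------------------------------------
# PERMANOVA
# ---------------------------------------------------------------------------

@dataclass
class PermanovaResult:
    """Sequential PERMANOVA table; terms in fitting order followed by
    Residual and Total rows."""

    table: pd.DataFrame  # index term; columns df, SumOfSqs, R2, F, p

    def __getitem__(self, term: str) -> pd.Series:
        return self.table.loc[term]

    def __repr__(self) -> str:
        return repr(self.table)


def _design_columns(meta: pd.DataFrame, term: str) -> np.ndarray:
    """Full dummy coding (all levels) of a main effect or interaction
    ``a:b``; rank handled downstream via projections."""
    parts = term.split(":")
    for pcol in parts:
        if pcol not in meta.columns:
            raise DesignError(f"unknown factor {pcol!r} in term {term!r}")
    combo = meta[parts[0]].astype(str)
    for pcol in parts[1:]:
        combo = combo + "\x1f" + meta[pcol].astype(str)
    return pd.get_dummies(combo).to_numpy(dtype=float)


def _projection(x: np.ndarray) -> np.ndarray:
    """Orthogonal projector onto the column space of x (rank-safe)."""
    q, r = np.linalg.qr(x)
    diag = np.abs(np.diag(r))
    keep = diag > 1e-10 * max(1.0, diag.max())
    q = q[:, keep]
    return q @ q.T


def parse_terms(formula: str) -> list[str]:
    """Split a "a+b+a:b"-style term list into ordered terms."""
    return [t.strip() for t in formula.split("+") if t.strip()]


def permanova(
    D: DistanceMatrix,
    metadata: SampleMetadata | pd.DataFrame,
    terms: list[str] | str,
    n_perm: int = 999,
    seed: int = 0,
    all_perms: bool = False,
) -> PermanovaResult:
    """Permutational multivariate ANOVA with sequential (Type I) SS.

    Partitions the total sum of squares of the Gower-centered distance
    matrix among the ordered ``terms`` (main effects and ``a:b``
    interactions) via projection matrices.  Pseudo-F per term is
    (SS_term/df_term)/(SS_resid/df_resid); p-values come from free
    permutation of sample labels (add-one rule), or from exhaustive
    enumeration of all n! relabelings when ``all_perms`` is set.

    Term order matters for unbalanced designs (sequential SS); the total
    SS is invariant to it.
    """
    meta = metadata.df if isinstance(metadata, SampleMetadata) else metadata
    if isinstance(terms, str):
        terms = parse_terms(terms)
    missing = [s for s in D.sample_ids if s not in meta.index]
    if missing:
        raise DesignError(f"samples without metadata: {missing[:10]}")
    meta = meta.loc[D.sample_ids]
    n = D.n

    g = _gower_center(D.values)
    ss_total = float(np.trace(g))

    # nested projectors H_0 (intercept) .. H_k (all terms up to k)
    ones = np.ones((n, 1))
    xs = [ones]
    projectors = [_projection(ones)]
    dfs: list[int] = []
    for term in terms:
        xs.append(_design_columns(meta, term))
        h = _projection(np.hstack(xs))
        df_term = int(round(np.trace(h) - np.trace(projectors[-1])))
        dfs.append(df_term)
        projectors.append(h)
    h_full = projectors[-1]
    df_resid = n - int(round(np.trace(h_full)))
    if df_resid <= 0:
        raise DesignError("zero residual degrees of freedom (saturated/aliased design)")
    if any(df == 0 for df in dfs):
        bad = [t for t, df in zip(terms, dfs) if df == 0]
        raise DesignError(f"aliased terms contribute no degrees of freedom: {bad}")

    diff_projs = [projectors[k + 1] - projectors[k] for k in range(len(terms))]
    resid_proj = np.eye(n) - h_full

    def stats_for(gmat: np.ndarray) -> tuple[np.ndarray, float]:
        ss_terms = np.array([float(np.sum(dp * gmat)) for dp in diff_projs])
        # numerically-zero residual (perfect separation) clamps to 0 so
        # the pseudo-F is reported +inf rather than a sign-flipped value
        ss_resid = max(float(np.sum(resid_proj * gmat)), 0.0)
        return ss_terms, ss_resid

    ss_terms, ss_resid = stats_for(g)
    with np.errstate(divide="ignore", invalid="ignore"):
        f_obs = (ss_terms / np.array(dfs)) / (ss_resid / df_resid)

    if all_perms:
        perms = [np.array(pm) for pm in itertools.permutations(range(n))]
        count = np.zeros(len(terms))
        total = 0
        for pm in perms:
            gp = g[np.ix_(pm, pm)]
            ss_t, ss_r = stats_for(gp)
            with np.errstate(divide="ignore", invalid="ignore"):
                f_p = (ss_t / np.array(dfs)) / (ss_r / df_resid)
            count += f_p >= f_obs - 1e-12
            total += 1
        pvals = count / total  # identity permutation included
    else:
        rng = np.random.default_rng(seed)
        count = np.zeros(len(terms))
        for _ in range(n_perm):
            pm = rng.permutation(n)
            gp = g[np.ix_(pm, pm)]
            ss_t, ss_r = stats_for(gp)
            with np.errstate(divide="ignore", invalid="ignore"):
                f_p = (ss_t / np.array(dfs)) / (ss_r / df_resid)
            count += f_p >= f_obs - 1e-12
        pvals = (1.0 + count) / (1.0 + n_perm)

    rows = []
    for i, term in enumerate(terms):
        rows.append((term, dfs[i], ss_terms[i], ss_terms[i] / ss_total, f_obs[i], pvals[i]))
    rows.append(("Residual", df_resid, ss_resid, ss_resid / ss_total, np.nan, np.nan))
    rows.append(("Total", n - 1, ss_total, 1.0, np.nan, np.nan))
    tab = pd.DataFrame(rows, columns=["term", "df", "SumOfSqs", "R2", "F", "p"]).set_index("term")
    return PermanovaResult(tab)


# ---------------------------------------------------------------------------
# Mantel tests
# ---------------------------------------------------------------------------

@dataclass
class MantelResult:
    rho: float
    p_value: float
    n_perm: int
    method: str
    controlled: tuple[str, ...] = ()


def _aligned_condensed(*mats: DistanceMatrix) -> list[np.ndarray]:
    ids = mats[0].sample_ids
    out = [mats[0].condensed()]
    for m in mats[1:]:
        if m.sample_ids != ids:
            if set(m.sample_ids) != set(ids):
                raise ValueError("distance matrices must share sample sets")
            m = m.subset(ids)
        out.append(m.condensed())
    return out


def _corr(x: np.ndarray, y: np.ndarray) -> float:
    if np.std(x) == 0 or np.std(y) == 0:
        raise UndefinedCorrelationError("constant off-diagonal vector")
    return float(np.corrcoef(x, y)[0, 1])


def _perm_condensed(values: np.ndarray, perm: np.ndarray) -> np.ndarray:
    return squareform(values[np.ix_(perm, perm)], checks=False)


def mantel(
    D1: DistanceMatrix,
    D2: DistanceMatrix,
    method: str = "spearman",
    n_perm: int = 999,
    seed: int = 0,
    all_perms: bool = False,
) -> MantelResult:
    """Mantel permutation test between two distance matrices.

    rho correlates the off-diagonal vectors (rank-transformed for
    Spearman); the null distribution permutes rows/columns of D2
    simultaneously.  One-sided (positive association), add-one rule.
    """
    v1, v2 = _aligned_condensed(D1, D2)
    if method == "spearman":
        v1 = stats.rankdata(v1)
        transform = stats.rankdata
    elif method == "pearson":
        transform = lambda x: x  # noqa: E731
    else:
        raise ValueError(f"unknown method {method!r}")
    rho_obs = _corr(v1, transform(v2))

    n = D1.n
    mat2 = squareform(v2, checks=False) if method == "pearson" else D2.subset(D1.sample_ids).values
    if all_perms:
        count = total = 0
        for pm in itertools.permutations(range(n)):
            vp = transform(_perm_condensed(mat2, np.array(pm)))
            count += _corr(v1, vp) >= rho_obs - 1e-12
            total += 1
        p = count / total
        n_used = total - 1
    else:
        rng = np.random.default_rng(seed)
        count = 0
        for _ in range(n_perm):
            pm = rng.permutation(n)
            vp = transform(_perm_condensed(mat2, pm))
            count += _corr(v1, vp) >= rho_obs - 1e-12
        p = (1.0 + count) / (1.0 + n_perm)
        n_used = n_perm
    return MantelResult(rho_obs, float(p), n_used, method)


def _residualize(y: np.ndarray, x: np.ndarray) -> np.ndarray:
    x1 = np.column_stack([np.ones_like(x), x])
    beta, *_ = np.linalg.lstsq(x1, y, rcond=None)
    return y - x1 @ beta


def partial_mantel(
    D1: DistanceMatrix,
    D2: DistanceMatrix,
    D3: DistanceMatrix,
    method: str = "spearman",
    n_perm: int = 999,
    seed: int = 0,
) -> MantelResult:
    """Partial Mantel test of D1 ~ D2 controlling for D3.

    Correlates the residuals of the (ranked, for Spearman) off-diagonal
    vectors of D1 and D2 after regressing each on the D3 vector; the
    null permutes D2's rows/columns, re-residualizing each permuted
    vector."""
    v1, v2, v3 = _aligned_condensed(D1, D2, D3)
    if method == "spearman":
        v1, v2c, v3 = stats.rankdata(v1), stats.rankdata(v2), stats.rankdata(v3)
        transform = stats.rankdata
    elif method == "pearson":
        v2c = v2
        transform = lambda x: x  # noqa: E731
    else:
        raise ValueError(f"unknown method {method!r}")
    r1 = _residualize(v1, v3)
    r2 = _residualize(v2c, v3)
    if np.allclose(r1, 0) or np.allclose(r2, 0):
        raise UndefinedCorrelationError("zero residuals; partial correlation undefined")
    rho_obs = _corr(r1, r2)

    n = D1.n
    mat2 = D2.subset(D1.sample_ids).values
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        pm = rng.permutation(n)
        vp = transform(_perm_condensed(mat2, pm))
        rp = _residualize(vp, v3)
        if np.allclose(rp, 0):
            count += 1
            continue
        count += _corr(r1, rp) >= rho_obs - 1e-12
    p = (1.0 + count) / (1.0 + n_perm)
    return MantelResult(rho_obs, float(p), n_perm, method, controlled=("D3",))


def env_correlations(
    abundances: pd.DataFrame, env: pd.DataFrame
) -> pd.DataFrame:
    """Spearman correlation screen of taxon-group abundances against
    environmental covariates.

    Returns a long-format DataFrame (group, covariate, rho, p, n) with
    pairwise deletion of missing env values; pairs with fewer than 4
    complete observations or a constant vector report missing rho.
    """
    rows = []
    common = abundances.index.intersection(env.index)
    ab = abundances.loc[common]
    ev = env.loc[common]
    for g in ab.columns:
        for c in ev.columns:
            pair = pd.concat([ab[g], ev[c]], axis=1).dropna()
            n = len(pair)
            if n < 4 or pair.iloc[:, 0].nunique() < 2 or pair.iloc[:, 1].nunique() < 2:
                rows.append((g, c, np.nan, np.nan, n))
                continue
            rho, p = stats.spearmanr(pair.iloc[:, 0], pair.iloc[:, 1])
            rows.append((g, c, float(rho), float(p), n))
    return pd.DataFrame(rows, columns=["group", "covariate", "rho", "p", "n"])
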