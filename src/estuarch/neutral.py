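"""Sloan neutral community model: fitting, prediction envelope, taxon
classification and cumulative-abundance partitioning.

The model predicts how often a taxon is detected across local communities
from nothing but its mean relative abundance p in the source pool
(metacommunity), the local community size N (reads), and the migration
rate m — the probability that a death in a local community is replaced by
an immigrant from the source rather than by local reproduction.  At
stationarity the local relative abundance x of a taxon follows

    x ~ Beta(N*m*p, N*m*(1 - p))

so the probability of detecting it at or above a detection limit of d
reads out of N is

    F(p) = 1 - I_{d/N}(N*m*p, N*m*(1 - p))

with I the regularized incomplete beta function.  N*m is the single free
parameter fitted by least squares on the (p, observed frequency) cloud;
m = N*m / N measures dispersal limitation (higher m = less limited).

Taxa whose observed occurrence frequency falls above the 95% envelope
around the fitted curve occur more often than neutrality predicts and
are interpreted as selected for by local conditions; those below as
selected against and/or dispersal-limited; those within the envelope as
neutrally distributed.  Cumulative relative abundance per category
summarizes the balance of stochastic versus deterministic assembly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from estuarch.errors import DegenerateFitError, EmptyResultError
from estuarch.tables import FeatureTable

Category = Literal["above", "neutral", "below"]


def expected_frequency(
    p: float | np.ndarray, Nm: float, N: int, d: int = 1
) -> float | np.ndarray:
    """Neutral prediction of occurrence frequency.

    Probability that a taxon with source relative abundance ``p`` is
    present at >= ``d`` reads in a local community of ``N`` reads when
    the local abundance follows the stationary Beta(Nm*p, Nm*(1-p))
    distribution.  Monotone non-decreasing in p; 0 at p=0 and 1 at p=1.
    """
    if Nm <= 0:
        raise ValueError("Nm must be positive")
    if not 1 <= d <= N:
        raise ValueError("detection limit d must satisfy 1 <= d <= N")
    p_arr = np.asarray(p, dtype=float)
    if np.any((p_arr < 0) | (p_arr > 1)):
        raise ValueError("p must lie in [0, 1]")
    a = Nm * p_arr
    b = Nm * (1.0 - p_arr)
    with np.errstate(invalid="ignore"):
        out = 1.0 - special.betainc(a, b, d / N)
    # degenerate beta masses: all mass at 0 (p=0) or at 1 (p=1)
    out = np.where(p_arr == 0.0, 0.0, out)
    out = np.where(p_arr == 1.0, 1.0, out)
    out = np.clip(out, 0.0, 1.0)
    return float(out) if np.isscalar(p) or p_arr.ndim == 0 else out


def expected_frequency_exact(
    p: float | np.ndarray, Nm: float, N: int, d: int = 1
) -> float | np.ndarray:
    """Exact neutral detection probability under the count layer.

    With x ~ Beta(Nm*p, Nm*(1-p)) and reads ~ Binomial(N, x), the read
    count is beta-binomial and P(count >= d) = BetaBin.sf(d-1; N, a, b).
    :func:`expected_frequency` is this quantity's continuum
    approximation, thresholding x at d/N; the exact form matters when
    fitting data whose counts really are discrete draws.
    """
    if Nm <= 0:
        raise ValueError("Nm must be positive")
    if not 1 <= d <= N:
        raise ValueError("detection limit d must satisfy 1 <= d <= N")
    scalar = np.isscalar(p) or np.asarray(p).ndim == 0
    p_arr = np.atleast_1d(np.asarray(p, dtype=float))
    if np.any((p_arr < 0) | (p_arr > 1)):
        raise ValueError("p must lie in [0, 1]")
    a = Nm * p_arr
    b = Nm * (1.0 - p_arr)
    out = np.zeros_like(p_arr)
    interior = (p_arr > 0) & (p_arr < 1)
    if interior.any():
        out[interior] = stats.betabinom.sf(d - 1, N, a[interior], b[interior])
    out[p_arr == 1.0] = 1.0
    out = np.clip(out, 0.0, 1.0)
    return float(out[0]) if scalar else out


def _wilson_interval(phat: np.ndarray, n: int, ci_level: float) -> tuple[np.ndarray, np.ndarray]:
    """Wilson score interval for a proportion ``phat`` observed over ``n``
    trials.  Used to build the envelope around the fitted curve."""
    z = stats.norm.ppf(0.5 + ci_level / 2.0)
    denom = 1.0 + z * z / n
    center = (phat + z * z / (2 * n)) / denom
    half = z * np.sqrt(phat * (1.0 - phat) / n + z * z / (4.0 * n * n)) / denom
    lo = np.clip(center - half, 0.0, 1.0)
    hi = np.clip(center + half, 0.0, 1.0)
    return lo, hi


def _binomial_envelope(
    pred: np.ndarray, n: int, ci_level: float
) -> tuple[np.ndarray, np.ndarray]:
    """Central binomial acceptance region for the observed frequency.

    With freq_obs = K/n and K ~ Binomial(n, f_pred) under neutrality,
    the region [ppf(alpha/2), ppf(1-alpha/2)]/n has >= ci_level coverage
    for the *observation* — unlike a confidence interval for the
    underlying proportion, it reaches 0 and 1 at the extremes, where a
    full (or empty) detection record is entirely consistent with the
    prediction.  Bounds are widened to contain f_pred itself so the
    envelope invariant ci_low <= pred <= ci_high always holds.
    """
    alpha = 1.0 - ci_level
    lo = stats.binom.ppf(alpha / 2.0, n, pred) / n
    hi = stats.binom.ppf(1.0 - alpha / 2.0, n, pred) / n
    return np.minimum(lo, pred), np.maximum(hi, pred)


@dataclass
class NeutralCurvePoint:
    taxon_id: str
    p: float
    freq_obs: float
    freq_pred: float
    ci_low: float
    ci_high: float
    category: Category


@dataclass
class NeutralFitResult:
    """Result of a neutral-model fit.

    Nm is the fitted product of community size and migration rate
    (in reads); m = Nm / N.  ``r_squared`` uses the SST-about-the-mean
    convention and may be negative when the model fits worse than the
    mean frequency — reported as-is, never truncated.
    """

    Nm: float
    m: float
    N: int
    d: int
    ci_level: float
    r_squared: float
    points: list[NeutralCurvePoint] = field(default_factory=list)

    @property
    def taxon_ids(self) -> list[str]:
        return [pt.taxon_id for pt in self.points]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "taxon_id": [pt.taxon_id for pt in self.points],
                "p": [pt.p for pt in self.points],
                "freq_obs": [pt.freq_obs for pt in self.points],
                "freq_pred": [pt.freq_pred for pt in self.points],
                "ci_low": [pt.ci_low for pt in self.points],
                "ci_high": [pt.ci_high for pt in self.points],
                "category": [pt.category for pt in self.points],
            }
        ).set_index("taxon_id")


def _categorize(freq_obs: np.ndarray, lo: np.ndarray, hi: np.ndarray) -> list[Category]:
    # envelope boundaries are inclusive on the neutral side
    cats: list[Category] = []
    for f, a, b in zip(freq_obs, lo, hi):
        if f > b:
            cats.append("above")
        elif f < a:
            cats.append("below")
        else:
            cats.append("neutral")
    return cats


def fit_ncm(
    local: FeatureTable,
    source: FeatureTable | None = None,
    *,
    source_p: pd.Series | None = None,
    N: int | Literal["auto"] = "auto",
    d: int = 1,
    ci_level: float = 0.95,
    detection: Literal["exact", "threshold"] = "exact",
    envelope: Literal["binomial", "wilson"] = "binomial",
) -> NeutralFitResult:
    """Fit the neutral model to a set of local communities.

    Parameters
    ----------
    local:
        Count table of the local communities (samples x features).
    source:
        Count table defining the source pool; source relative abundance
        p_i is each feature's share of the pooled source reads.  Features
        of ``local`` must be a subset of the source features.  Pass the
        all-estuary table for a regional pool or the local table itself
        for a within-estuary pool.
    source_p:
        Alternatively, explicit source relative abundances indexed by
        feature id (overrides ``source``).
    N:
        Local community size in reads; ``"auto"`` uses the rounded mean
        local sample depth.
    d:
        Detection limit in reads (a taxon "occurs" at >= d reads).
    ci_level:
        Envelope level around the fitted curve (Wilson score interval
        with n = number of local samples).

    detection:
        Detection-probability model: ``"exact"`` (beta-binomial, the
        exact occurrence probability when counts are discrete reads;
        default) or ``"threshold"`` (the classic continuum
        approximation 1 - I_{d/N}(Nm*p, Nm*(1-p)), matching the widely
        used fitting scripts).  The threshold form overestimates Nm on
        genuinely discrete counts.
    envelope:
        ``"binomial"`` (default): central binomial acceptance region for
        the observed frequency given n local samples — calibrated at
        extreme predictions, where it correctly reaches 0/1.
        ``"wilson"``: Wilson score interval around the fitted curve, the
        convention of the classic workflow; its upper bound never
        reaches 1, so abundant taxa detected in every sample are flagged
        "above" even when that is the expected outcome.

    Only taxa actually detected in the local table (freq_obs > 0) and
    with p > 0 enter the least-squares objective, mirroring the standard
    fitting workflow for this model.
    """
    if local.n_samples < 5:
        raise ValueError("need at least 5 local samples to fit")
    if source_p is None:
        if source is None:
            raise ValueError("provide either source or source_p")
        missing = set(local.feature_ids) - set(source.feature_ids)
        if missing:
            raise KeyError(
                f"local features absent from source: {sorted(missing)[:10]}"
            )
        pooled = source.feature_sums().astype(float)
        source_p = pooled / pooled.sum()
    else:
        source_p = source_p.astype(float)
        missing = set(local.feature_ids) - set(source_p.index)
        if missing:
            raise KeyError(
                f"local features absent from source_p: {sorted(missing)[:10]}"
            )

    n_samples = local.n_samples
    if N == "auto":
        N = int(round(local.sample_sums().mean()))
    if not 1 <= d <= N:
        raise ValueError("detection limit d must satisfy 1 <= d <= N")

    freq_obs_all = ((local.data >= d).sum(axis=0) / n_samples).astype(float)
    p_all = source_p.reindex(local.feature_ids).to_numpy()
    freq_arr = freq_obs_all.to_numpy()

    fit_mask = (freq_arr > 0) & (p_all > 0)
    p_fit = p_all[fit_mask]
    f_fit = freq_arr[fit_mask]
    if np.unique(f_fit).size < 3:
        raise DegenerateFitError(
            "fewer than 3 distinct observed frequencies; nothing to fit"
        )

    freq_fn = expected_frequency_exact if detection == "exact" else expected_frequency

    def sse(log_nm: float) -> float:
        resid = f_fit - freq_fn(p_fit, float(np.exp(log_nm)), N, d)
        return float(resid @ resid)

    # coarse log-spaced grid then local refinement; objective is smooth
    # and unimodal in practice but the grid guards against bad brackets
    grid = np.linspace(np.log(1e-2), np.log(N * 1e3), 120)
    losses = [sse(g) for g in grid]
    k = int(np.argmin(losses))
    lo = grid[max(k - 1, 0)]
    hi = grid[min(k + 1, len(grid) - 1)]
    res = optimize.minimize_scalar(sse, bounds=(lo, hi), method="bounded",
                                   options={"xatol": 1e-10})
    if not res.success:
        raise DegenerateFitError(f"Nm optimization failed: {res.message}")
    Nm = float(np.exp(res.x))

    pred_fit = freq_fn(p_fit, Nm, N, d)
    ss_res = float(np.sum((f_fit - pred_fit) ** 2))
    ss_tot = float(np.sum((f_fit - f_fit.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot

    pred_all = np.asarray(freq_fn(np.clip(p_all, 0, 1), Nm, N, d))
    if envelope == "binomial":
        ci_lo, ci_hi = _binomial_envelope(pred_all, n_samples, ci_level)
    elif envelope == "wilson":
        ci_lo, ci_hi = _wilson_interval(pred_all, n_samples, ci_level)
    else:
        raise ValueError(f"unknown envelope {envelope!r}")
    cats = _categorize(freq_arr, ci_lo, ci_hi)

    points = [
        NeutralCurvePoint(t, float(p_all[i]), float(freq_arr[i]), float(pred_all[i]),
                          float(ci_lo[i]), float(ci_hi[i]), cats[i])
        for i, t in enumerate(local.feature_ids)
    ]
    return NeutralFitResult(
        Nm=Nm, m=Nm / N, N=N, d=d, ci_level=ci_level, r_squared=r2, points=points
    )


def classify_taxa(
    fit: NeutralFitResult, focal: Iterable[str]
) -> pd.Series:
    """Three-way neutral/above/below label for each focal taxon.

    A taxon is "above" when its observed frequency strictly exceeds the
    upper envelope bound at its p, "below" when strictly under the lower
    bound, otherwise "neutral" (boundaries inclusive on the neutral
    side)."""
    by_id = {pt.taxon_id: pt for pt in fit.points}
    focal = list(focal)
    missing = [t for t in focal if t not in by_id]
    if missing:
        raise KeyError(f"focal taxa absent from fit: {missing[:10]}")
    return pd.Series({t: by_id[t].category for t in focal}, name="category")


def partition_abundance(
    local: FeatureTable,
    categories: pd.Series | dict[str, Category],
    focal: Sequence[str] | None = None,
) -> dict[Category, float]:
    """Cumulative relative abundance of each assembly category.

    Sums the local reads of focal taxa per category and divides by total
    focal reads; the three values sum to 1.  The neutral share measures
    the relative importance of stochastic assembly; above/below shares
    that of selection for/against local conditions.
    """
    categories = pd.Series(categories)
    if focal is None:
        focal = list(categories.index)
    missing = [t for t in focal if t not in categories.index]
    if missing:
        raise KeyError(f"taxa without category: {missing[:10]}")
    reads = local.data[list(focal)].sum(axis=0).astype(float)
    total = reads.sum()
    if total == 0:
        raise EmptyResultError("zero focal reads; cannot partition abundance")
    out: dict[Category, float] = {"neutral": 0.0, "above": 0.0, "below": 0.0}
    for t in focal:
        out[categories.loc[t]] += float(reads.loc[t])
    return {k: v / total for k, v in out.items()}
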