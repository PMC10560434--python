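"""Rarefaction and cumulative sum scaling (CSS) of count tables.

Amplicon read depth varies by orders of magnitude between samples, and
the archaeal fraction of a universal-primer library is especially uneven.
Two depth corrections are provided:

* :func:`rarefy` — subsample every sample without replacement to a fixed
  depth (multivariate hypergeometric draw), dropping samples below it.
* :func:`css_normalize` — cumulative sum scaling: divide each sample's
  counts by the cumulated count up to a chosen quantile of its nonzero
  counts, then rescale.  CSS corrects depth bias without discarding
  reads and is robust to the high-count tail that distorts total-sum
  scaling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from estuarch.errors import EmptyResultError
from estuarch.tables import FeatureTable


@dataclass(frozen=True)
class CssParams:
    """Parameters of cumulative sum scaling.

    quantile_l:
        Quantile of the per-sample nonzero count distribution up to which
        counts are cumulated (strictly inside (0, 1)).  Fixed at the
        median by default; the adaptive instability search of the
        original method is intentionally not implemented.
    scale_constant:
        Post-division rescale, conventionally 1000 ("per-thousand
        pseudo-reads").
    log_transform:
        Apply log2(x + 1) after scaling.
    """

    quantile_l: float = 0.5
    scale_constant: float = 1000.0
    log_transform: bool = False

    def __post_init__(self) -> None:
        if not 0.0 < self.quantile_l < 1.0:
            raise ValueError("quantile_l must be strictly inside (0, 1)")
        if self.scale_constant <= 0:
            raise ValueError("scale_constant must be positive")


def rarefy(table: FeatureTable, depth: int, seed: int) -> FeatureTable:
    """Subsample each sample to exactly ``depth`` reads without replacement.

    Samples whose total is below ``depth`` are dropped with a warning.
    Deterministic given ``seed``; each retained row sums to ``depth``
    exactly and stays integer.
    """
    if depth <= 0:
        raise ValueError("rarefaction depth must be positive")
    if table.normalized not in ("raw", "rarefied"):
        raise ValueError("rarefy expects raw counts")
    sums = table.sample_sums()
    keep = sums >= depth
    dropped = sums.index[~keep].tolist()
    if dropped:
        warnings.warn(
            f"rarefy dropped {len(dropped)} samples below depth {depth}: "
            f"{dropped[:5]}{'...' if len(dropped) > 5 else ''}",
            stacklevel=2,
        )
    if not keep.any():
        raise EmptyResultError(f"no sample reaches rarefaction depth {depth}")
    data = table.data.loc[keep]
    rng = np.random.default_rng(seed)
    out = np.empty(data.shape, dtype=np.int64)
    counts = data.to_numpy().astype(np.int64)
    for i in range(counts.shape[0]):
        if counts[i].sum() == depth:
            out[i] = counts[i]
        else:
            out[i] = rng.multivariate_hypergeometric(counts[i], depth)
    return FeatureTable(
        pd.DataFrame(out, index=data.index, columns=data.columns), "rarefied"
    )


def _css_scaling_factor(row: np.ndarray, quantile_l: float) -> float:
    nonzero = row[row > 0]
    if nonzero.size == 0:
        return 0.0
    q = np.quantile(nonzero, quantile_l, method="linear")
    return float(row[row <= q].sum())


def css_normalize(table: FeatureTable, params: CssParams = CssParams()) -> FeatureTable:
    """Cumulative sum scaling.

    For sample j let q_j be the ``quantile_l`` quantile (linear
    interpolation) of its nonzero counts and s_j the sum of counts
    c_ij <= q_j.  Normalized values are c_ij / s_j * scale_constant,
    optionally log2(x+1)-transformed.  s_j ignores the high-count tail,
    so the scaling is stable under the dominance of a few abundant taxa
    and exactly invariant to per-sample multiplicative depth.
    """
    if table.normalized not in ("raw", "rarefied"):
        raise ValueError("css_normalize expects raw counts")
    counts = table.values.astype(float)
    scaled = np.empty_like(counts)
    for i, sample in enumerate(table.sample_ids):
        s = _css_scaling_factor(counts[i], params.quantile_l)
        if s == 0.0:
            raise EmptyResultError(f"zero CSS scaling factor for sample {sample!r}")
        scaled[i] = counts[i] / s * params.scale_constant
    if params.log_transform:
        scaled = np.log2(scaled + 1.0)
    return FeatureTable(
        pd.DataFrame(scaled, index=table.data.index, columns=table.data.columns),
        "css",
    )
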