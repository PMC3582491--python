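"""Correlation meta-analysis of paired effect sizes (EMSA g vs. ELISA g).

Each PRE variant contributes one (g_x, g_y) pair -- its standardized
binding effect from the gel shift and its standardized expression effect
from the reporter assay -- with the wildtype control contributing the
(0, 0) pair by construction.  Inference on the product-moment correlation
is by case bootstrap: pairs are resampled with replacement, r recomputed
each time, and the significance of r != 0 estimated as the fraction of the
bootstrap distribution falling on the opposite side of zero from the
observed r (one-sided sign-crossing fraction).  Two bootstrap
distributions are compared by percent histogram overlap on a common grid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["EffectPairSet", "BootstrapResult", "pearson_r", "bootstrap_r",
           "overlap_pct"]


@dataclass
class EffectPairSet:
    """Labelled (g_x, g_y) pairs; >= 3 pairs required for correlation."""

    labels: list
    g_x: np.ndarray
    g_y: np.ndarray

    @classmethod
    def from_arrays(cls, g_x, g_y, labels=None) -> "EffectPairSet":
        g_x = np.asarray(g_x, float)
        g_y = np.asarray(g_y, float)
        if g_x.shape != g_y.shape:
            raise ValueError("paired arrays must have equal length")
        if labels is None:
            labels = [str(i) for i in range(len(g_x))]
        return cls(list(labels), g_x, g_y)

    @classmethod
    def from_tsv(cls, path) -> "EffectPairSet":
        df = pd.read_csv(path, sep="\t")
        return cls.from_arrays(df["g_x"], df["g_y"], list(df["variant"]))

    def __len__(self) -> int:
        return len(self.g_x)


@dataclass
class BootstrapResult:
    r_observed: float
    B: int
    seed: int
    distribution: np.ndarray
    p: float
    n_degenerate: int = 0


def pearson_r(pairs: EffectPairSet) -> float:
    """Product-moment correlation of the paired effect sizes."""
    if len(pairs) < 3:
        raise ValueError("correlation requires at least 3 pairs")
    if np.std(pairs.g_x) == 0 or np.std(pairs.g_y) == 0:
        raise ValueError("zero variance on an axis: correlation undefined")
    return float(stats.pearsonr(pairs.g_x, pairs.g_y).statistic)


def _row_pearson(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Pearson r of each row pair of two (B, n) arrays (NaN if degenerate)."""
    xc = x - x.mean(axis=1, keepdims=True)
    yc = y - y.mean(axis=1, keepdims=True)
    num = (xc * yc).sum(axis=1)
    den = np.sqrt((xc * xc).sum(axis=1) * (yc * yc).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = num / den
    r[den == 0] = np.nan
    return r


def bootstrap_r(pairs: EffectPairSet, B: int = 100_000,
                seed: int | None = None) -> BootstrapResult:
    """Case bootstrap of the correlation with one-sided sign-crossing p.

    Resamples the n pairs with replacement B times; degenerate resamples
    (zero variance on an axis) are skipped and counted.  p is the fraction
    of valid bootstrap r values whose sign is opposite to the observed r
    (for r_observed = 0 the fraction below zero, which converges to 1/2).
    """
    if B < 1000:
        raise ValueError("B must be >= 1000")
    if seed is None:
        raise ValueError("a seed is required for bootstrap inference")
    r_obs = pearson_r(pairs)
    rng = np.random.default_rng(seed)
    n = len(pairs)
    dist = np.empty(B)
    pos = 0
    chunk = 50_000
    while pos < B:
        b = min(chunk, B - pos)
        idx = rng.integers(0, n, size=(b, n))
        dist[pos:pos + b] = _row_pearson(pairs.g_x[idx], pairs.g_y[idx])
        pos += b
    valid = dist[~np.isnan(dist)]
    n_degenerate = int(B - valid.size)
    sign = 1.0 if r_obs >= 0 else -1.0
    p = float(np.mean(valid * sign < 0)) if valid.size else float("nan")
    return BootstrapResult(r_observed=r_obs, B=B, seed=seed,
                           distribution=valid, p=p,
                           n_degenerate=n_degenerate)


def overlap_pct(dist_a, dist_b, bins: int = 50) -> float:
    """Percent overlap of two samples' relative-frequency histograms.

    Histograms share an equal-width bin grid spanning the pooled range;
    overlap = 100 * sum_bins min(f_a, f_b), in [0, 100].
    """
    a = np.asarray(dist_a, float)
    b = np.asarray(dist_b, float)
    if a.size == 0 or b.size == 0:
        raise ValueError("empty distribution")
    lo = min(a.min(), b.min())
    hi = max(a.max(), b.max())
    if lo == hi:
        return 100.0
    edges = np.linspace(lo, hi, bins + 1)
    fa, _ = np.histogram(a, bins=edges)
    fb, _ = np.histogram(b, bins=edges)
    return float(100.0 * np.minimum(fa / a.size, fb / b.size).sum())
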