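"""Residual spatial-autocorrelation diagnostics.

A global regression that ignores spatially varying carrying coefficients
leaves spatially structured residuals; a well-bandwidthed GWR should not.
The diagnostic is a correlogram: Moran's I of the residuals computed per
great-circle-distance bin with binary neighbour weights (w_ij = 1 iff the
pair's distance falls in the bin), with significance from random label
permutations rather than the analytic normal approximation — pair counts
per bin are small and the weights are binary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .ballast_gwr import distance_matrix
from .data_io import StationTable

logger = logging.getLogger(__name__)


@dataclass
class Correlogram:
    """Per-distance-bin Moran's I with permutation p-values.

    ``bin_edges`` has length n_bins + 1 (km); ``morans_i`` / ``p_perm`` /
    ``n_pairs`` have length n_bins.  Bins with no pairs or undefined
    statistics hold NaN and are listed in ``flags``.
    """

    bin_edges: np.ndarray
    morans_i: np.ndarray
    p_perm: np.ndarray
    n_pairs: np.ndarray
    n_perm: int
    seed: int
    flags: list[str]

    @property
    def significant(self) -> np.ndarray:
        """Boolean mask of bins with p_perm < 0.05 (NaN-safe)."""
        with np.errstate(invalid="ignore"):
            return np.asarray(self.p_perm < 0.05)


def _binary_bin_weights(dist: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Symmetric binary weight matrix: 1 iff lo <= d_ij < hi, i ≠ j."""
    W = ((dist >= lo) & (dist < hi)).astype(float)
    np.fill_diagonal(W, 0.0)
    return W


def _morans_i_from_weights(values: np.ndarray, W: np.ndarray) -> float:
    z = values - values.mean()
    denom = float(z @ z)
    wsum = float(W.sum())
    if denom == 0.0 or wsum == 0.0:
        return float("nan")
    return (len(values) / wsum) * float(z @ W @ z) / denom


def morans_i(
    values: np.ndarray,
    table: StationTable,
    bin: tuple[float, float],
    dist: np.ndarray | None = None,
) -> tuple[float, int]:
    """Moran's I of ``values`` over station pairs whose distance lies in ``bin``.

    Weights are binary: w_ij = 1 iff distance(i, j) ∈ [lo, hi).  Returns
    the statistic and the number of (unordered) pairs in the bin; the
    statistic is NaN if the bin is empty or the values have zero variance.
    """
    values = np.asarray(values, dtype=float)
    if values.shape != (len(table),):
        raise ValueError("values must have one entry per station")
    if dist is None:
        dist = distance_matrix(table)
    lo, hi = bin
    W = _binary_bin_weights(dist, lo, hi)
    n_pairs = int(W.sum()) // 2
    stat = _morans_i_from_weights(values, W)
    if np.isnan(stat):
        logger.warning("Moran's I undefined in bin [%g, %g): empty bin or zero variance", lo, hi)
    return stat, n_pairs


def quantile_bin_edges(table: StationTable, n_bins: int = 10) -> np.ndarray:
    """Equal-pair-count distance bin edges over the observed pair distances.

    Quantile bins keep per-bin pair counts comparable despite the very
    uneven station density across basins.  The last edge is nudged up so
    the maximal pair distance falls inside the final half-open bin.
    """
    dist = distance_matrix(table)
    iu = np.triu_indices(len(table), k=1)
    d = dist[iu]
    edges = np.quantile(d, np.linspace(0.0, 1.0, n_bins + 1))
    edges = np.unique(edges)
    edges[-1] *= 1.0 + 1e-9
    return edges


def residual_correlogram(
    residuals: np.ndarray,
    table: StationTable,
    bins: np.ndarray | int = 10,
    n_perm: int = 999,
    seed: int = 0,
) -> Correlogram:
    """Moran's I correlogram of fit residuals with permutation significance.

    ``bins`` may be explicit edges (km) or a count of equal-pair-count
    quantile bins.  Two-sided permutation p-values come from ``n_perm``
    seeded random relabelings of the residuals across stations; with the
    +1 correction the smallest attainable p is 1/(n_perm + 1).
    """
    residuals = np.asarray(residuals, dtype=float)
    n = len(table)
    if residuals.shape != (n,):
        raise ValueError("residuals must have one entry per station")
    if n_perm < 99:
        logger.warning("n_perm=%d < 99: permutation p-value resolution is limited", n_perm)
    edges = quantile_bin_edges(table, bins) if isinstance(bins, int) else np.asarray(bins, float)
    dist = distance_matrix(table)

    rng = np.random.default_rng(seed)
    perms = np.array([rng.permutation(n) for _ in range(n_perm)])

    n_bins = len(edges) - 1
    stats_ = np.full(n_bins, np.nan)
    pvals = np.full(n_bins, np.nan)
    n_pairs = np.zeros(n_bins, dtype=int)
    flags: list[str] = []
    z = residuals - residuals.mean()
    denom = float(z @ z)
    for b in range(n_bins):
        W = _binary_bin_weights(dist, edges[b], edges[b + 1])
        n_pairs[b] = int(W.sum()) // 2
        if n_pairs[b] < 2:
            flags.append(f"bin {b}: fewer than 2 pairs, statistic undefined")
            continue
        if denom == 0.0:
            flags.append(f"bin {b}: zero residual variance")
            continue
        obs = _morans_i_from_weights(residuals, W)
        stats_[b] = obs
        # same permutations across bins; binary W keeps z'Wz cheap
        zp = z[perms]  # n_perm × n
        perm_stats = (n / W.sum()) * np.einsum("pi,ij,pj->p", zp, W, zp) / denom
        n_ge = int((perm_stats >= obs).sum())
        n_le = int((perm_stats <= obs).sum())
        pvals[b] = min(1.0, 2.0 * (min(n_ge, n_le) + 1) / (n_perm + 1))
    return Correlogram(
        bin_edges=edges,
        morans_i=stats_,
        p_perm=pvals,
        n_pairs=n_pairs,
        n_perm=n_perm,
        seed=seed,
        flags=flags,
    )
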