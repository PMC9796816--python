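"""Group-level nonparametric inference.

Under the null hypothesis that a statistic (decoding accuracy minus
chance, a correlation) is zero in every participant, participant signs
are exchangeable: a sign-permutation test multiplies each participant's
map by +-1 and recomputes the group mean.  Family-wise error over time
courses and 2-D maps is controlled by max-cluster-size inference: p-value
maps (observed and permuted alike) are thresholded at a cluster-defining
alpha, and an observed cluster is significant only if its size beats the
95th percentile of the permutation distribution of the *largest* cluster
size.  Point-wise families (e.g. searchlight channels, model
correlations) use Benjamini-Hochberg FDR instead.  Latency uncertainty
uses percentile bootstrap over participants.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numba
import numpy as np
from scipy import ndimage
from scipy.stats import rankdata
from statsmodels.stats.multitest import multipletests


@dataclass
class StatMapSample:
    """Per-participant statistic maps, already expressed relative to chance."""

    data: np.ndarray               # participants x map shape
    tail: str = "right"            # "right" or "two"
    axes: dict = field(default_factory=dict)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim < 2:
            raise ValueError("data must be participants x map")
        if self.data.shape[0] < 2:
            raise ValueError("need at least 2 participants")
        if self.tail not in ("right", "two"):
            raise ValueError("tail must be 'right' or 'two'")


@dataclass
class PermutationResult:
    """Observed group mean, p map, and the permutation statistic stack."""

    mean_map: np.ndarray
    p_map: np.ndarray
    stack: np.ndarray              # (n_perm + 1) x map shape, identity first
    tail: str
    n_perm: int


@dataclass
class ClusterInferenceResult:
    """Cluster-corrected significance for a statistic map."""

    mean_map: np.ndarray
    p_map: np.ndarray
    mask: np.ndarray               # significant cells
    clusters: list                 # [{"cells", "size", "corrected_p", "significant"}]
    null_max_sizes: np.ndarray
    params: dict


@dataclass
class LatencyCI:
    """Bootstrap percentile CI for a latency-type estimate."""

    estimate: float
    ci_low: float
    ci_high: float
    kind: str = "peak"
    n_boot: int = 0
    missing_fraction: float = 0.0
    significant: bool | None = None   # for differences: 0 outside the CI


def sign_permutation_pvals(sample: StatMapSample, n_perm=10000,
                           rng=None) -> PermutationResult:
    """Monte-Carlo sign-permutation p values for a group-mean map.

    The identity permutation is part of the null set, so p is bounded
    below by ``1/(n_perm + 1)`` and can never be exactly zero.
    """
    if n_perm < 100:
        warnings.warn(f"n_perm={n_perm} gives a very coarse p resolution",
                      stacklevel=2)
    rng = np.random.default_rng(rng)
    data = sample.data
    n_sub = data.shape[0]
    shape = data.shape[1:]
    flat = data.reshape(n_sub, -1)
    signs = rng.integers(0, 2, size=(n_perm, n_sub)) * 2 - 1
    stack = np.empty((n_perm + 1, flat.shape[1]))
    stack[0] = flat.mean(axis=0)
    stack[1:] = signs @ flat / n_sub
    stat = np.abs(stack) if sample.tail == "two" else stack
    nan_cells = np.isnan(flat).any(axis=0)
    with np.errstate(invalid="ignore"):
        p = (stat >= stat[0]).sum(axis=0) / (n_perm + 1.0)
    p[nan_cells] = np.nan
    return PermutationResult(
        mean_map=stack[0].reshape(shape),
        p_map=p.reshape(shape),
        stack=stack.reshape((n_perm + 1,) + shape),
        tail=sample.tail,
        n_perm=n_perm,
    )


@numba.njit(cache=True)
def _max_run_per_row(b):  # pragma: no cover - jitted
    n, m = b.shape
    out = np.zeros(n, np.int64)
    for i in range(n):
        run = 0
        best = 0
        for j in range(m):
            if b[i, j]:
                run += 1
                if run > best:
                    best = run
            else:
                run = 0
        out[i] = best
    return out


def _connectivity_structure(ndim, connectivity):
    if ndim == 1:
        return np.ones(3, dtype=bool)
    if connectivity == 8:
        return np.ones((3, 3), dtype=bool)
    return ndimage.generate_binary_structure(2, 1)      # edge-adjacent


def _stack_pvals(stat):
    """p value of every stack row against the whole stack, per cell."""
    n = stat.shape[0]
    ranks = rankdata(stat, method="min", axis=0)
    return (n - ranks + 1.0) / n


def cluster_correct(perm: PermutationResult, cluster_alpha=0.005,
                    fwer_alpha=0.05, connectivity=4) -> ClusterInferenceResult:
    """Max-cluster-size correction from a permutation stack.

    Every permutation's map is converted to p values against the same
    null stack, thresholded at ``cluster_alpha`` and its largest
    suprathreshold cluster recorded; an observed cluster is significant
    when its size exceeds the ``1 - fwer_alpha`` quantile of that null
    distribution.  1-D maps use run contiguity; 2-D maps edge adjacency
    (``connectivity=4``, set 8 to include diagonals).
    """
    shape = perm.mean_map.shape
    n = perm.stack.shape[0]
    stat = np.abs(perm.stack) if perm.tail == "two" else perm.stack
    flat = stat.reshape(n, -1)
    nan_cells = np.isnan(flat[0])
    flat = np.nan_to_num(flat, nan=-np.inf)
    supra = _stack_pvals(flat) < cluster_alpha
    supra[:, nan_cells] = False

    if len(shape) == 1:
        null_max = _max_run_per_row(supra)
    elif len(shape) == 2:
        struct = _connectivity_structure(2, connectivity)
        null_max = np.zeros(n, dtype=np.int64)
        for i in range(n):
            lab, nlab = ndimage.label(supra[i].reshape(shape), struct)
            if nlab:
                null_max[i] = np.bincount(lab.ravel())[1:].max()
    else:
        raise ValueError("cluster inference supports 1-D and 2-D maps")

    # observed clusters from the identity row
    obs = supra[0].reshape(shape)
    struct = _connectivity_structure(len(shape), connectivity)
    lab, nlab = ndimage.label(obs, struct if len(shape) > 1 else None)
    threshold = np.quantile(null_max, 1.0 - fwer_alpha) if n else 0
    clusters = []
    mask = np.zeros(shape, dtype=bool)
    for li in range(1, nlab + 1):
        cells = lab == li
        size = int(cells.sum())
        corr_p = float((null_max >= size).sum() / n)
        significant = size > threshold
        clusters.append({
            "cells": np.flatnonzero(cells.ravel()),
            "size": size,
            "corrected_p": corr_p,
            "significant": bool(significant),
        })
        if significant:
            mask |= cells
    return ClusterInferenceResult(
        mean_map=perm.mean_map,
        p_map=perm.p_map,
        mask=mask,
        clusters=clusters,
        null_max_sizes=null_max,
        params={"n_perm": perm.n_perm, "cluster_alpha": cluster_alpha,
                "fwer_alpha": fwer_alpha, "connectivity": connectivity,
                "tail": perm.tail},
    )


def fdr_correct(pvals, q=0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up rejection mask for a p-value family."""
    pvals = np.asarray(pvals, dtype=float)
    if pvals.size == 0:
        return np.zeros(0, dtype=bool)
    if not np.all(np.isfinite(pvals)):
        raise ValueError("p values must be finite")
    reject, *_ = multipletests(pvals.ravel(), alpha=q, method="fdr_bh")
    return reject.reshape(pvals.shape)


def bootstrap_latency(group_inputs, estimator, n_boot=1000,
                      rng=None, kind="peak") -> LatencyCI:
    """Percentile bootstrap CI of a group-level latency estimator.

    ``estimator`` maps an array of participant inputs (resampled with
    replacement along axis 0) to a scalar latency; it may return NaN when
    undefined on a resample (e.g. no significant cluster), and the
    fraction of such resamples is reported.
    """
    group_inputs = np.asarray(group_inputs)
    rng = np.random.default_rng(rng)
    n = group_inputs.shape[0]
    point = float(estimator(group_inputs))
    draws = np.empty(n_boot)
    for i in range(n_boot):
        idx = rng.integers(0, n, size=n)
        draws[i] = estimator(group_inputs[idx])
    ok = np.isfinite(draws)
    missing = 1.0 - ok.mean()
    if not ok.any():
        return LatencyCI(point, np.nan, np.nan, kind, n_boot, missing)
    lo, hi = np.percentile(draws[ok], [2.5, 97.5])
    return LatencyCI(point, float(lo), float(hi), kind, n_boot, missing)


def bootstrap_peak_difference(latencies_a, latencies_b, n_boot=1000,
                              rng=None) -> LatencyCI:
    """Bootstrap CI for the difference of two groups' mean latencies.

    Resamples each group's participant-specific latencies with
    replacement; the null of no difference is rejected when 0 lies
    outside the 95% percentile interval of ``mean(a) - mean(b)``.
    """
    a = np.asarray(latencies_a, dtype=float)
    b = np.asarray(latencies_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 latencies")
    rng = np.random.default_rng(rng)
    draws = (
        a[rng.integers(0, a.size, size=(n_boot, a.size))].mean(axis=1)
        - b[rng.integers(0, b.size, size=(n_boot, b.size))].mean(axis=1)
    )
    lo, hi = np.percentile(draws, [2.5, 97.5])
    return LatencyCI(
        estimate=float(a.mean() - b.mean()), ci_low=float(lo),
        ci_high=float(hi), kind="peak difference", n_boot=n_boot,
        significant=bool(lo > 0 or hi < 0),
    )


def peak_onset_offset(mean_curve, mask=None, times=None, window=None):
    """Peak, onset and offset latencies of a 1-D group-mean curve.

    Peak: first occurrence of the maximum inside ``window`` (default: the
    whole axis).  Onset/offset: first bin of the first and last bin of
    the last significant cluster in ``mask``; NaN when the mask is empty.
    """
    mean_curve = np.asarray(mean_curve, dtype=float)
    if times is None:
        times = np.arange(mean_curve.size, dtype=float)
    times = np.asarray(times, dtype=float)
    sel = np.ones_like(mean_curve, dtype=bool)
    if window is not None:
        sel = (times >= window[0]) & (times < window[1])
        if not sel.any():
            raise ValueError("window selects no bins")
    sub = np.where(sel, mean_curve, -np.inf)
    peak = float(times[int(np.argmax(sub))])
    onset = offset = float("nan")
    if mask is not None:
        idx = np.flatnonzero(np.asarray(mask, dtype=bool))
        if idx.size:
            onset = float(times[idx[0]])
            offset = float(times[idx[-1]])
    return {"peak": peak, "onset": onset, "offset": offset}
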