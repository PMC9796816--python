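"""Pseudo-trial construction and cross-validated pairwise decoding.

The decoding scheme is the standard pseudo-trial MVPA pipeline for
category-evoked EEG: per repetition, raw trials of each category are
randomly partitioned into ``n_bins`` bins of approximately equal size and
averaged into pseudo-trials; a linear C-SVC (C = 1, no feature scaling) is
trained to discriminate each pair of categories on all-but-one pseudo-trial
per class and tested on the held-out pair, rotating the held-out bin over
all folds; accuracies are averaged over folds and repetitions.  Chance
level is 50%.

Variants share that contract:

* :func:`decode_timecourse` — one 4x4 accuracy matrix per time point;
* :func:`decode_timegen`   — train at one time point, test at all others;
* :func:`decode_searchlight` — whole pipeline restricted to each channel's
  k nearest neighbours, averaged into 200 ms bins;
* :func:`decode_timefreq`  — the time course pipeline per frequency bin of
  a time-frequency power decomposition.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy.spatial.distance import cdist

from .epochs import EpochsSet, bin_downsample_array
from .svm import decision_accuracy, fit_linear_svm_batch

_TRI = {}  # cached lower-triangle index pairs per K


def _pairs(k: int):
    if k not in _TRI:
        _TRI[k] = list(combinations(range(k), 2))
    return _TRI[k]


@dataclass
class DecodingSeries:
    """Time-resolved pairwise decoding accuracies (percent, 4x4 per bin)."""

    times: np.ndarray                 # ms
    accuracy: np.ndarray              # time x K x K, symmetric, NaN diagonal
    n_reps: int
    provenance: dict = field(default_factory=dict)

    def grand_average(self) -> np.ndarray:
        """Mean of the lower triangle per time point (percent)."""
        k = self.accuracy.shape[1]
        idx = np.tril_indices(k, -1)
        return self.accuracy[:, idx[0], idx[1]].mean(axis=1)


@dataclass
class TimeGenMap:
    """Temporal generalization accuracy map (train time x test time)."""

    train_times: np.ndarray
    test_times: np.ndarray
    accuracy: np.ndarray              # train x test, percent, pair-averaged
    n_reps: int
    provenance: dict = field(default_factory=dict)


@dataclass
class SearchlightMap:
    """Channel-resolved decoding accuracy in coarse time bins."""

    channel_names: list
    time_bins: np.ndarray             # bin-center ms
    accuracy: np.ndarray              # channel x bin, percent
    k_neighbors: int
    provenance: dict = field(default_factory=dict)


@dataclass
class FrequencyResolvedDecoding:
    """One :class:`DecodingSeries` per frequency bin."""

    freqs: np.ndarray
    series: list                      # list of DecodingSeries

    def grand_average_map(self) -> np.ndarray:
        """freq x time matrix of grand-average accuracy (percent)."""
        return np.stack([s.grand_average() for s in self.series])


def partition_indices(n: int, n_bins: int, rng: np.random.Generator):
    """Random partition of ``range(n)`` into bins differing in size by <= 1."""
    if n < n_bins:
        raise ValueError(f"cannot split {n} trials into {n_bins} bins")
    return np.array_split(rng.permutation(n), n_bins)


def make_pseudotrials(trials_by_category, n_bins=4, rng=None, category_names=None):
    """Average randomly partitioned raw trials into pseudo-trials.

    Parameters
    ----------
    trials_by_category : sequence of ndarray
        One array of raw trial patterns (trials x ...) per category.
    n_bins : int
        Number of pseudo-trials per category (4 in the reference pipeline).
    rng : numpy.random.Generator

    Returns
    -------
    list of ndarray
        Per category, an array of shape (n_bins, ...) of bin means.
    """
    rng = np.random.default_rng(rng)
    out = []
    for c, trials in enumerate(trials_by_category):
        trials = np.asarray(trials)
        if trials.shape[0] < n_bins:
            name = category_names[c] if category_names else f"category {c}"
            raise ValueError(
                f"{name}: {trials.shape[0]} trials cannot fill {n_bins} "
                "pseudo-trial bins"
            )
        parts = partition_indices(trials.shape[0], n_bins, rng)
        out.append(np.stack([trials[p].mean(axis=0) for p in parts]))
    return out


def _check_decodable(X, labels, n_bins):
    if not np.all(np.isfinite(X)):
        raise ValueError("input patterns contain NaN or infinite values")
    k = int(labels.max()) + 1
    if k < 2:
        raise ValueError("need at least two categories")
    counts = np.bincount(labels, minlength=k)
    bad = np.flatnonzero(counts < n_bins)
    if bad.size:
        raise ValueError(
            f"categories {bad.tolist()} have fewer trials than {n_bins} bins"
        )
    return k


def _draw_pseudotrials(X, cat_idx, n_bins, rng):
    """Pseudo-trials for one repetition: (K, n_bins, F, T)."""
    return np.stack(
        [
            np.stack(
                [X[idx[p]].mean(axis=0)
                 for p in partition_indices(idx.size, n_bins, rng)]
            )
            for idx in cat_idx
        ]
    )


def _decode_core(X, labels, n_reps, n_bins, rng, C=1.0, full_rotation=True,
                 chunk=10, timegen=False):
    """Shared pseudo-trial CV engine.

    Returns per-pair accuracy in [0, 1]: shape (T, n_pairs), or
    (T_train, T_test, n_pairs) when ``timegen``.
    """
    rng = np.random.default_rng(rng)
    k = _check_decodable(X, labels, n_bins)
    n_t = X.shape[2]
    pairs = _pairs(k)
    cat_idx = [np.flatnonzero(labels == c) for c in range(k)]
    folds = list(range(n_bins)) if full_rotation else [n_bins - 1]
    notf = [[g for g in range(n_bins) if g != f] for f in folds]
    y = np.concatenate([np.ones(n_bins - 1), -np.ones(n_bins - 1)])

    shape = (n_t, n_t, len(pairs)) if timegen else (n_t, len(pairs))
    acc_sum = np.zeros(shape)
    done = 0
    while done < n_reps:
        r = min(chunk, n_reps - done)
        # (R, K, n_bins, T, F); one partition per repetition and category,
        # shared across all time points of that repetition
        ps = np.stack([_draw_pseudotrials(X, cat_idx, n_bins, rng)
                       for _ in range(r)])
        pt = np.ascontiguousarray(ps.transpose(0, 1, 2, 4, 3))
        xtr, ta, tb = [], [], []
        for a, b in pairs:
            for fi, f in enumerate(folds):
                tr = np.concatenate(
                    [pt[:, a, notf[fi]], pt[:, b, notf[fi]]], axis=1
                )                                   # (R, 2nb-2, T, F)
                xtr.append(tr.transpose(0, 2, 1, 3).reshape(
                    r * n_t, 2 * n_bins - 2, -1))
                ta.append(pt[:, a, f])              # (R, T, F)
                tb.append(pt[:, b, f])
        w, bias = fit_linear_svm_batch(np.concatenate(xtr), y, C=C)
        n_blk = len(pairs) * len(folds)
        w = w.reshape(n_blk, r, n_t, -1)
        bias = bias.reshape(n_blk, r, n_t)
        ta = np.stack(ta)                           # (blk, R, T, F)
        tb = np.stack(tb)
        if timegen:
            sa = np.einsum("krtf,krsf->krts", w, ta) + bias[..., None]
            sb = np.einsum("krtf,krsf->krts", w, tb) + bias[..., None]
        else:
            sa = np.einsum("krtf,krtf->krt", w, ta) + bias
            sb = np.einsum("krtf,krtf->krt", w, tb) + bias
        a_ok = 0.5 * (decision_accuracy(sa, 1.0) + decision_accuracy(sb, -1.0))
        # (pairs, folds, R, ...) -> sum over folds and repetitions
        a_ok = a_ok.reshape((len(pairs), len(folds), r) + a_ok.shape[2:])
        acc_sum += np.moveaxis(a_ok.sum(axis=(1, 2)), 0, -1)
        done += r
    return acc_sum / (n_reps * len(folds))


def _to_matrix(acc_pairs, k):
    """(..., n_pairs) in [0,1] -> (..., K, K) percent, NaN diagonal."""
    out = np.full(acc_pairs.shape[:-1] + (k, k), np.nan)
    for pi, (a, b) in enumerate(_pairs(k)):
        out[..., a, b] = out[..., b, a] = 100.0 * acc_pairs[..., pi]
    return out


def decode_timecourse(epochs: EpochsSet, n_reps=100, n_bins=4, rng=None,
                      C=1.0, full_rotation=True) -> DecodingSeries:
    """Time-resolved pairwise category decoding for one participant."""
    acc = _decode_core(epochs.data, epochs.labels, n_reps, n_bins, rng,
                       C=C, full_rotation=full_rotation)
    return DecodingSeries(
        times=epochs.times.copy(),
        accuracy=_to_matrix(acc, epochs.n_categories),
        n_reps=n_reps,
        provenance={"participant": epochs.participant_id,
                    "group": epochs.group_tag, "kind": "timecourse"},
    )


def decode_timegen(epochs: EpochsSet, n_reps=100, n_bins=4, rng=None,
                   C=1.0, full_rotation=True) -> TimeGenMap:
    """Temporal generalization: train at t1, test at every t2.

    Expects temporally binned input (the reference pipeline uses 20 ms
    bins, i.e. 50 Hz); a high sampling rate makes the train x test grid
    quadratically expensive.
    """
    if epochs.srate > 100:
        warnings.warn(
            f"time generalization on {epochs.srate:g} Hz data; "
            "bin_downsample to ~50 Hz first", stacklevel=2,
        )
    acc = _decode_core(epochs.data, epochs.labels, n_reps, n_bins, rng,
                       C=C, full_rotation=full_rotation, timegen=True,
                       chunk=4)
    return TimeGenMap(
        train_times=epochs.times.copy(),
        test_times=epochs.times.copy(),
        accuracy=100.0 * acc.mean(axis=-1),
        n_reps=n_reps,
        provenance={"participant": epochs.participant_id,
                    "group": epochs.group_tag, "kind": "timegen"},
    )


def channel_neighborhoods(positions, k_neighbors):
    """Indices of each channel's ``k`` nearest channels (self included).

    Distances are Euclidean on the montage coordinates; equidistant
    channels are ordered by index.
    """
    positions = np.asarray(positions, dtype=float)
    d = cdist(positions, positions)
    order = np.argsort(d, axis=1, kind="stable")
    return order[:, :k_neighbors]


def decode_searchlight(epochs: EpochsSet, k_neighbors=None, timebin_ms=200.0,
                       n_reps=100, n_bins=4, rng=None, C=1.0) -> SearchlightMap:
    """Channel-space searchlight decoding.

    Each channel's neighbourhood is its ``k_neighbors`` closest channels
    (default 5 for infant-tagged data, 10 otherwise, following the
    montage sizes of the two cohorts); the time-resolved pipeline runs on
    that subset and the grand-average time course is averaged into
    ``timebin_ms`` bins.
    """
    if epochs.channel_positions is None:
        raise ValueError("searchlight requires montage coordinates")
    if k_neighbors is None:
        k_neighbors = 5 if epochs.group_tag == "infant" else 10
    if k_neighbors > epochs.n_channels:
        raise ValueError("k_neighbors exceeds channel count")
    rng = np.random.default_rng(rng)
    neigh = channel_neighborhoods(epochs.channel_positions, k_neighbors)
    rows = []
    for ch in range(epochs.n_channels):
        acc = _decode_core(epochs.data[:, neigh[ch], :], epochs.labels,
                           n_reps, n_bins, rng, C=C)
        rows.append(100.0 * acc.mean(axis=1))        # grand average, (T,)
    curve = np.stack(rows)                           # channels x T
    binned, bin_times = bin_downsample_array(
        curve, epochs.times, epochs.srate, timebin_ms
    )
    return SearchlightMap(
        channel_names=list(epochs.channel_names),
        time_bins=bin_times,
        accuracy=binned,
        k_neighbors=int(k_neighbors),
        provenance={"participant": epochs.participant_id,
                    "group": epochs.group_tag, "kind": "searchlight"},
    )


def decode_timefreq(tfpower, n_reps=100, n_bins=4, rng=None,
                    C=1.0) -> FrequencyResolvedDecoding:
    """Run the time-resolved pipeline separately on each frequency bin.

    ``tfpower`` is a :class:`~catdecode.timefreq.TFPowerSet`; the classifier
    contract is identical to :func:`decode_timecourse`, with channel
    patterns of baseline-normalized power instead of voltage.
    """
    rng = np.random.default_rng(rng)
    series = []
    k = int(tfpower.labels.max()) + 1
    for fi in range(tfpower.freqs.size):
        acc = _decode_core(tfpower.power[:, :, fi, :], tfpower.labels,
                           n_reps, n_bins, rng, C=C)
        series.append(DecodingSeries(
            times=tfpower.times.copy(),
            accuracy=_to_matrix(acc, k),
            n_reps=n_reps,
            provenance={"kind": "timefreq",
                        "freq_hz": float(tfpower.freqs[fi])},
        ))
    return FrequencyResolvedDecoding(freqs=tfpower.freqs.copy(), series=series)
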