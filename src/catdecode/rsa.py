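"""Representational similarity analyses on decoding-derived RDMs.

A 4x4 matrix of pairwise decoding accuracies is read as a representational
dissimilarity matrix (RDM): the better two categories decode, the more
dissimilar their neural patterns.  Because RDMs abstract away from the
recording's channel space, they can be compared across cohorts with
different montages, against image-computable model RDMs, and across
time/frequency grids.  All comparisons use Spearman's R on the K(K-1)/2
lower-triangle entries (average ranks on ties); a rank-constant vector
makes R undefined and the comparison is recorded as NaN rather than
silently dropped entry-wise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm
from scipy.stats import rankdata


def lower_tri(rdm: np.ndarray) -> np.ndarray:
    """Lower-triangle entries (excluding diagonal) of (..., K, K)."""
    rdm = np.asarray(rdm)
    k = rdm.shape[-1]
    i, j = np.tril_indices(k, -1)
    return rdm[..., i, j]


def _rank(v: np.ndarray) -> np.ndarray:
    """Average ranks along the last axis."""
    return rankdata(v, method="average", axis=-1).astype(float)


def spearman_vec(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Spearman's R between last-axis vectors, broadcasting leading axes.

    Returns NaN where either vector is rank-constant or contains NaN.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    bad = np.isnan(a).any(axis=-1) | np.isnan(b).any(axis=-1)
    ra = _rank(np.nan_to_num(a))
    rb = _rank(np.nan_to_num(b))
    ra = ra - ra.mean(axis=-1, keepdims=True)
    rb = rb - rb.mean(axis=-1, keepdims=True)
    na = np.sqrt((ra ** 2).sum(axis=-1))
    nb = np.sqrt((rb ** 2).sum(axis=-1))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (ra * rb).sum(axis=-1) / (na * nb)
    r = np.where((na == 0) | (nb == 0) | bad, np.nan, r)
    return r


@dataclass
class CrossGroupMap:
    """Per-participant Spearman maps across two analysis grids.

    ``maps`` is participants x rows x cols; axis names/values say what the
    grids are (e.g. infant time x adult time, or adult time x adult
    frequency).
    """

    maps: np.ndarray
    row_values: np.ndarray
    col_values: np.ndarray
    row_name: str = "row"
    col_name: str = "col"
    provenance: dict = field(default_factory=dict)

    def mean_map(self) -> np.ndarray:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            return np.nanmean(self.maps, axis=0)


@dataclass
class VariancePartition:
    """R-squared decomposition of a model RDM onto two group RDMs."""

    total_infant: float
    total_adult: float
    unique_infant: float
    unique_adult: float
    shared: float


@dataclass
class PeakWindowResult:
    """Per-participant peak-window RDMs with the exclusion inventory."""

    rdms: list                     # one K x K array or None per participant
    excluded: list                 # indices of participants with no valid bin

    def stack(self) -> np.ndarray:
        """Included participants' RDMs as one array."""
        return np.stack([r for r in self.rdms if r is not None])


def peak_window_rdm(series_list, window, min_mean_acc=50.0) -> PeakWindowResult:
    """Average each participant's RDMs over a latency window.

    Only time points whose matrix mean (lower triangle) reaches
    ``min_mean_acc`` percent for that participant enter the average — the
    standard above-chance inclusion criterion, orthogonal to any geometry
    hypothesis.  Participants with no qualifying time point are excluded
    and listed, never silently dropped.
    """
    t0, t1 = window
    rdms, excluded = [], []
    for p, series in enumerate(series_list):
        sel = (series.times >= t0) & (series.times < t1)
        if not sel.any():
            raise ValueError(f"window [{t0}, {t1}) ms outside the series grid")
        mats = series.accuracy[sel]
        ok = lower_tri(mats).mean(axis=-1) >= min_mean_acc
        if ok.any():
            rdms.append(mats[ok].mean(axis=0))
        else:
            rdms.append(None)
            excluded.append(p)
    return PeakWindowResult(rdms=rdms, excluded=excluded)


def crossgroup_timegen(infant_series, adult_series) -> CrossGroupMap:
    """Cross-cohort time-generalized RSA.

    Infant RDMs are averaged across participants per time point (SNR);
    the average infant RDM at every infant time is then Spearman-correlated
    with each adult participant's RDM at every adult time, one
    (infant time x adult time) map per adult.
    """
    for s in list(infant_series) + list(adult_series):
        dt = np.diff(s.times)
        if dt.size and not np.allclose(dt, dt[0]):
            raise ValueError("series must be on uniform time grids")
    infant_mean = np.mean([s.accuracy for s in infant_series], axis=0)
    inf_v = lower_tri(infant_mean)                      # Ti x 6
    maps = []
    for s in adult_series:
        adu_v = lower_tri(s.accuracy)                   # Ta x 6
        maps.append(spearman_vec(inf_v[:, None, :], adu_v[None, :, :]))
    return CrossGroupMap(
        maps=np.stack(maps),
        row_values=infant_series[0].times.copy(),
        col_values=adult_series[0].times.copy(),
        row_name="infant_time_ms", col_name="adult_time_ms",
        provenance={"n_adults": len(adult_series),
                    "n_infants": len(infant_series)},
    )


def stack_tf_rdms(freq_resolved) -> np.ndarray:
    """(freqs, times, K, K) stack from a FrequencyResolvedDecoding."""
    return np.stack([s.accuracy for s in freq_resolved.series])


def tf_template_rsa(infant_tf_rdms, cluster_mask, adult_tf_rdms,
                    min_mean_acc=50.0) -> CrossGroupMap:
    """Frequency-template RSA across cohorts.

    A single aggregate template RDM is built by averaging infant RDMs over
    the (frequency, time) extent of the significant infant cluster,
    applying the >= ``min_mean_acc`` inclusion criterion per participant
    and cell.  The template is then Spearman-correlated with every adult
    participant's RDM at every (time, frequency) cell.

    Parameters
    ----------
    infant_tf_rdms : ndarray, (participants, freqs, times, K, K)
    cluster_mask : boolean ndarray, (freqs, times)
    adult_tf_rdms : ndarray, (participants, freqs, times, K, K)
    """
    infant_tf_rdms = np.asarray(infant_tf_rdms)
    adult_tf_rdms = np.asarray(adult_tf_rdms)
    cluster_mask = np.asarray(cluster_mask, dtype=bool)
    if not cluster_mask.any():
        raise ValueError("empty cluster mask: no cells to aggregate over")
    cells = infant_tf_rdms[:, cluster_mask]             # P x n_cells x K x K
    vecs = lower_tri(cells)                             # P x n_cells x 6
    ok = vecs.mean(axis=-1) >= min_mean_acc
    if not ok.any():
        raise ValueError(
            "no (participant, cell) RDM passes the inclusion criterion"
        )
    template = vecs[ok].mean(axis=0)                    # (6,)
    adu_v = lower_tri(adult_tf_rdms)                    # P x F x T x 6
    maps = spearman_vec(template, adu_v)                # P x F x T
    return CrossGroupMap(
        maps=np.transpose(maps, (0, 2, 1)),             # P x T x F
        row_values=np.arange(adult_tf_rdms.shape[2]),
        col_values=np.arange(adult_tf_rdms.shape[1]),
        row_name="adult_time_bin", col_name="adult_freq_bin",
        provenance={"template": template,
                    "n_template_rdms": int(ok.sum())},
    )


def model_rsa(participant_rdms, model_rdm) -> np.ndarray:
    """Spearman's R between each participant's RDM and one model RDM."""
    part = lower_tri(np.asarray(participant_rdms))
    model = lower_tri(np.asarray(model_rdm))
    return spearman_vec(part, model)


def partial_model_rsa(participant_rdms, model_rdm, covariate_rdm) -> np.ndarray:
    """Partial Spearman: model-participant correlation given a covariate RDM.

    All three RDM vectors are rank-transformed; participant and model
    ranks are each regressed on the covariate ranks (with intercept) and
    the Pearson correlation of the residuals is returned.  A participant
    identical to the covariate leaves a zero residual vector; its partial
    R is defined as 0.
    """
    single = np.asarray(participant_rdms).ndim == 2
    part = _rank(lower_tri(np.asarray(participant_rdms)))
    model = _rank(lower_tri(np.asarray(model_rdm)))
    cov = _rank(lower_tri(np.asarray(covariate_rdm)))
    if np.all(cov == cov[..., :1]):
        raise ValueError("covariate RDM is rank-constant")
    rc = spearman_vec(model, cov)
    if np.any(np.abs(rc) >= 1.0 - 1e-12):
        raise ValueError("covariate RDM is collinear with the model RDM")

    def _residual(v):
        x = np.column_stack([np.ones_like(cov), cov])
        beta, *_ = np.linalg.lstsq(x, v, rcond=None)
        return v - x @ beta

    rm = _residual(model)
    part = np.atleast_2d(part)
    out = np.empty(part.shape[0])
    tol = 1e-9 * np.sqrt(part.shape[1])      # rank scale ~ O(1)
    for i, v in enumerate(part):
        rp = _residual(v)
        na, nb = np.linalg.norm(rp), np.linalg.norm(rm)
        out[i] = 0.0 if (na < tol or nb < tol) else float(rp @ rm / (na * nb))
    return float(out[0]) if single else out


def noise_ceiling(participant_rdms) -> tuple:
    """Upper/lower bound on any model's achievable group correlation.

    Upper: mean Spearman of each participant's RDM with the grand-mean
    RDM (the participant included).  Lower: same with the participant
    left out of the mean.
    """
    rdms = np.asarray(participant_rdms, dtype=float)
    n = rdms.shape[0]
    if n < 3:
        raise ValueError("noise ceiling needs at least 3 participants")
    vecs = lower_tri(rdms)
    mean_all = vecs.mean(axis=0)
    if np.allclose(mean_all, mean_all[0]):
        warnings.warn("grand-mean RDM is constant; noise ceiling undefined",
                      stacklevel=2)
        return float("nan"), float("nan")
    upper = float(np.mean(spearman_vec(vecs, mean_all)))
    loo = (mean_all * n - vecs) / (n - 1)
    lower = float(np.mean(spearman_vec(vecs, loo)))
    return lower, upper


def _r2(y, X) -> float:
    model = sm.OLS(y, sm.add_constant(X)).fit()
    return float(model.rsquared)


def variance_partition(model_rdm, infant_mean_rdm,
                       adult_mean_rdm) -> VariancePartition:
    """Unique and shared explained variance of a model RDM.

    OLS (with intercept) on lower-triangle vectors: the model RDM is the
    observation, the group-mean RDMs the regressors.  ``total_g`` is the
    R-squared of model ~ group g alone, ``unique_g`` the increase from
    adding g to the other group's regression, and ``shared`` the
    remainder ``total_g - unique_g`` (identical for both groups up to
    numerical error).
    """
    y = lower_tri(np.asarray(model_rdm))
    xi = lower_tri(np.asarray(infant_mean_rdm))
    xa = lower_tri(np.asarray(adult_mean_rdm))
    total_i = _r2(y, xi)
    total_a = _r2(y, xa)
    r_groups = np.corrcoef(xi, xa)[0, 1]
    if np.abs(r_groups) >= 1.0 - 1e-12:
        warnings.warn("group RDMs are collinear; unique variance set to 0",
                      stacklevel=2)
        return VariancePartition(total_i, total_a, 0.0, 0.0, total_i)
    both = _r2(y, np.column_stack([xi, xa]))
    unique_i = both - total_a
    unique_a = both - total_i
    return VariancePartition(
        total_infant=total_i, total_adult=total_a,
        unique_infant=unique_i, unique_adult=unique_a,
        shared=total_i - unique_i,
    )
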