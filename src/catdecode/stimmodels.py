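"""Image-computable model features and model RDMs.

Three feature sources feed the representational analyses:

* a Gabor wavelet pyramid (scales x orientations x positions, quadrature
  magnitude) as a fixed low-level vision model;
* spatial-frequency band-pass filtered pixel values, using a bank of
  logarithmically spaced 2-D Butterworth band-pass filters specified in
  cycles per degree (cpd);
* precomputed network layer activations loaded from an HDF5 container
  (one stimuli x features matrix per layer).

All sources end in the same place: feature values are z-scored across
stimuli, averaged into one vector per category, and converted to a K x K
model RDM of ``1 - Pearson's R`` between category vectors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import h5py
import numpy as np
from scipy.signal import fftconvolve
from skimage.filters import gabor_kernel

from . import epochs as _epochs


@dataclass
class ModelFeatureSet:
    """Stimulus x feature activation matrix with category assignment."""

    activations: np.ndarray          # stimuli x features
    labels: np.ndarray               # category per stimulus
    source: str = ""                 # e.g. "gabor", "pixel_band:2.1cpd", "layer:relu3"

    def __post_init__(self):
        self.activations = np.atleast_2d(np.asarray(self.activations, float))
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.activations.shape[1] < 1:
            raise ValueError("need at least one feature")
        if not np.all(np.isfinite(self.activations)):
            raise ValueError("activations contain non-finite values")
        if self.labels.shape[0] != self.activations.shape[0]:
            raise ValueError("one category label per stimulus required")


@dataclass
class BandDefinition:
    """One spatial-frequency band of the Butterworth filter bank (cpd)."""

    center: float
    lo_edge: float
    hi_edge: float
    order: int = 5

    def __post_init__(self):
        if not 0 < self.lo_edge < self.center < self.hi_edge:
            raise ValueError(
                f"band edges must satisfy 0 < lo < center < hi, got "
                f"({self.lo_edge}, {self.center}, {self.hi_edge})"
            )
        if self.order < 1:
            raise ValueError("filter order must be >= 1")


def make_band_filters(n=100, lo=0.1, hi=30.0, order=5):
    """Log-spaced band-pass bank: centers form an exact geometric progression.

    Centers include both endpoints; band edges sit at the geometric
    midpoints between adjacent centers (the end bands are symmetric on the
    log axis), so adjacent bands share their -3 dB edges.
    """
    if not (lo < hi and n >= 1):
        raise ValueError("require lo < hi and n >= 1")
    if n == 1:
        c = np.sqrt(lo * hi)
        step = np.sqrt(hi / lo)
    else:
        c = np.logspace(np.log10(lo), np.log10(hi), n)
        step = np.sqrt(c[1] / c[0])
        c = np.atleast_1d(c)
    centers = np.atleast_1d(c)
    return [
        BandDefinition(center=float(f), lo_edge=float(f / step),
                       hi_edge=float(f * step), order=order)
        for f in centers
    ]


def butterworth_bandpass_gain(f, band: BandDefinition):
    """Radial amplitude gain |H(f)| of the band-pass filter.

    High-pass and low-pass Butterworth magnitude responses in cascade:
    ``[1+(lo/f)^(2n)]^(-1/2) * [1+(f/hi)^(2n)]^(-1/2)``; gain is 1/sqrt(2)
    at each edge (for well separated edges) and 0 at DC.
    """
    f = np.asarray(f, dtype=float)
    g = np.zeros_like(f)
    nz = f > 0
    n2 = 2 * band.order
    g[nz] = 1.0 / np.sqrt(1.0 + (band.lo_edge / f[nz]) ** n2) \
        / np.sqrt(1.0 + (f[nz] / band.hi_edge) ** n2)
    return g


def bandpass_image(image, band: BandDefinition, deg_per_image: float):
    """Apply one spatial-frequency band-pass in the 2-D Fourier domain.

    The radial Butterworth gain scales the spectrum's magnitude while the
    phase is untouched (a real, radially symmetric transfer function);
    frequencies are in cpd via ``deg_per_image``.  Returns the real part
    of the inverse transform.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2 or image.shape[0] != image.shape[1]:
        raise ValueError("bandpass_image expects a square 2-D image")
    if deg_per_image <= 0:
        raise ValueError("deg_per_image must be positive")
    n = image.shape[0]
    nyq = n / (2.0 * deg_per_image)
    if band.lo_edge >= nyq:
        raise ValueError(
            f"band ({band.lo_edge}-{band.hi_edge} cpd) lies above the "
            f"image Nyquist frequency {nyq:g} cpd"
        )
    fx = np.fft.fftfreq(n, d=deg_per_image / n)      # cycles per degree
    radial = np.hypot(fx[:, None], fx[None, :])
    gain = butterworth_bandpass_gain(radial, band)
    return np.real(np.fft.ifft2(np.fft.fft2(image) * gain))


@dataclass
class GaborConfig:
    """Gabor pyramid layout: log-spaced frequencies, oriented quadrature pairs."""

    n_frequencies: int = 6
    n_orientations: int = 8
    min_cycles_per_image: float = 2.0
    max_cycles_per_image: float = 32.0
    positions_per_cycle: float = 0.5   # sample grid spacing ~ wavelength/this
    bandwidth: float = 1.0             # octaves, sets envelope vs wavelength


def _gabor_bank(image_size: int, config: GaborConfig):
    if config.n_frequencies < 1 or config.n_orientations < 1:
        raise ValueError("need at least one scale and one orientation")
    freqs = np.logspace(
        np.log10(config.min_cycles_per_image),
        np.log10(min(config.max_cycles_per_image, image_size / 2.0)),
        config.n_frequencies,
    ) / image_size                               # cycles per pixel
    thetas = np.arange(config.n_orientations) * np.pi / config.n_orientations
    return freqs, thetas


def gabor_features(images: _epochs.ImageSet,
                   config: GaborConfig | None = None) -> ModelFeatureSet:
    """Gabor wavelet pyramid responses for every stimulus.

    Each feature is the quadrature-pair magnitude (even/odd phase
    combined) of one (scale, orientation, position) unit; positions lie
    on a grid whose spacing scales with the wavelet's wavelength, so
    coarse scales contribute few and fine scales many units.  Kernels are
    zero-mean, hence a uniform image produces all-zero responses.
    """
    config = config or GaborConfig()
    n = images.images.shape[1]
    freqs, thetas = _gabor_bank(n, config)
    features = []
    for img in images.images:
        img = img - img.mean()          # DC carries no pattern information
        vec = []
        for f in freqs:
            wavelength = 1.0 / f
            step = max(int(round(wavelength / (2 * config.positions_per_cycle))), 1)
            grid = np.arange(step // 2, n, step)
            for theta in thetas:
                kern = gabor_kernel(frequency=f, theta=theta,
                                    bandwidth=config.bandwidth)
                even = np.real(kern)
                even = even - even.mean()            # DC-free
                odd = np.imag(kern)
                re = fftconvolve(img, even, mode="same")
                im = fftconvolve(img, odd, mode="same")
                mag = np.hypot(re, im)
                vec.append(mag[np.ix_(grid, grid)].ravel())
        features.append(np.concatenate(vec))
    return ModelFeatureSet(
        activations=np.stack(features), labels=images.labels.copy(),
        source="gabor",
    )


def feature_rdm(features: ModelFeatureSet) -> np.ndarray:
    """Category-level model RDM: z-score, category means, 1 - Pearson's R.

    Feature values are z-scored across stimuli (features with zero
    variance across stimuli are dropped — they carry no stimulus
    information), averaged over the stimuli of each category, and the
    K x K matrix of ``1 - r`` between category vectors is returned with a
    NaN diagonal.
    """
    acts = features.activations
    if acts.shape[1] < 2:
        raise ValueError("Pearson dissimilarity needs at least 2 features")
    k = int(features.labels.max()) + 1
    if np.all(acts == acts[0]):
        # identical stimuli: identical patterns, zero dissimilarity
        rdm = np.zeros((k, k))
        np.fill_diagonal(rdm, np.nan)
        return rdm
    mu = acts.mean(axis=0)
    sd = acts.std(axis=0)
    keep = sd > 0
    if keep.sum() < 2:
        raise ValueError("fewer than 2 features vary across stimuli")
    z = (acts[:, keep] - mu[keep]) / sd[keep]
    cat = np.empty((k, z.shape[1]))
    for c in range(k):
        idx = features.labels == c
        if not idx.any():
            raise ValueError(f"category {c} has no stimuli")
        cat[c] = z[idx].mean(axis=0)
    sds = cat.std(axis=1)
    flat = np.flatnonzero(sds == 0)
    if flat.size:
        raise ValueError(
            f"category vector(s) {flat.tolist()} have zero variance; "
            "1 - Pearson is undefined"
        )
    rdm = 1.0 - np.corrcoef(cat)
    np.fill_diagonal(rdm, np.nan)
    return rdm


def pixel_band_rdms(images: _epochs.ImageSet, bands) -> list:
    """Per-band category RDMs from band-pass filtered pixel values.

    Each image is filtered into each band; the filtered pixel vectors play
    the role of model activations (z-score across stimuli, category means,
    1 - Pearson), yielding one RDM per band.
    """
    out = []
    for band in bands:
        filtered = np.stack([
            bandpass_image(img, band, images.deg_per_image).ravel()
            for img in images.images
        ])
        fs = ModelFeatureSet(activations=filtered, labels=images.labels,
                             source=f"pixel_band:{band.center:.3g}cpd")
        out.append(feature_rdm(fs))
    return out


def save_layer_activations(path, layers: dict, labels) -> None:
    """Write a layers container: one stimuli x features matrix per name."""
    with h5py.File(path, "w") as f:
        f.create_dataset("labels", data=np.asarray(labels, dtype=np.int64))
        grp = f.create_group("layers")
        for name, mat in layers.items():
            grp.create_dataset(name, data=np.asarray(mat, dtype=np.float64))


def load_layer_activations(path, n_stimuli=None) -> list:
    """Load per-layer activation matrices as a list of ModelFeatureSets.

    Layers are returned in file order; each must have one row per
    stimulus (validated against ``n_stimuli`` when given).
    """
    out = []
    with h5py.File(path, "r") as f:
        labels = f["labels"][()]
        for name in f["layers"]:
            mat = f["layers"][name][()]
            if mat.shape[0] != labels.shape[0] or (
                n_stimuli is not None and mat.shape[0] != n_stimuli
            ):
                raise ValueError(
                    f"layer '{name}' has {mat.shape[0]} rows; expected one "
                    "per stimulus"
                )
            out.append(ModelFeatureSet(activations=mat, labels=labels,
                                       source=f"layer:{name}"))
    return out


def group_layers(layer_sets, n_groups=5):
    """Partition an ordered layer list into contiguous groups for reporting."""
    n_groups = min(n_groups, len(layer_sets))
    return [list(part) for part in np.array_split(np.array(layer_sets,
                                                           dtype=object),
                                                  n_groups)]


def to_luminance(image: np.ndarray) -> np.ndarray:
    """RGB -> luminance by Rec.601 weights; grayscale passes through."""
    image = np.asarray(image, dtype=float)
    if image.ndim == 2:
        return image
    if image.ndim == 3 and image.shape[-1] == 3:
        return image @ np.array([0.299, 0.587, 0.114])
    raise ValueError("expected HxW or HxWx3 image")
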