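"""Canonical containers and I/O for epoched EEG and stimulus images.

The central object is :class:`EpochsSet`, a single participant's epoched
recording (trials x channels x time, microvolts) with integer category
labels, a millisecond time axis and a 3-D montage.  Temporal operations
follow two conventions used throughout the package:

* time selections are half-open ``[t0, t1)`` in milliseconds;
* downsampling averages within fixed-width bins, labels each output
  sample by the bin *center*, and drops a trailing partial bin.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import h5py
import numpy as np

#: Default category order; index into this list is the integer label.
DEFAULT_CATEGORIES = ("toy", "body", "house", "face")


@dataclass
class EpochsSet:
    """One participant's epoched EEG with category labels.

    Parameters
    ----------
    data : ndarray, shape (n_trials, n_channels, n_times)
        Voltage in microvolts.
    labels : ndarray of int, shape (n_trials,)
        Category index per trial, ``0..K-1``.
    times : ndarray, shape (n_times,)
        Milliseconds relative to stimulus onset; strictly increasing,
        uniformly spaced.
    srate : float
        Sampling rate in Hz (consistent with ``times`` spacing).
    channel_names : sequence of str
    channel_positions : ndarray, shape (n_channels, 3)
        Montage coordinates, arbitrary but internally consistent units.
    participant_id : str
    group_tag : str
        E.g. ``"infant"`` or ``"adult"``.
    category_names : tuple of str
        Sidecar name table for the integer labels.
    """

    data: np.ndarray
    labels: np.ndarray
    times: np.ndarray
    srate: float
    channel_names: list = field(default_factory=list)
    channel_positions: np.ndarray | None = None
    participant_id: str = ""
    group_tag: str = ""
    category_names: tuple = DEFAULT_CATEGORIES

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        self.times = np.asarray(self.times, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError("data must be trials x channels x time")
        if self.labels.shape[0] != self.data.shape[0]:
            raise ValueError(
                f"label/trial count mismatch: {self.labels.shape[0]} labels "
                f"for {self.data.shape[0]} trials"
            )
        if self.times.shape[0] != self.data.shape[2]:
            raise ValueError("times length does not match data time axis")
        dt = np.diff(self.times)
        if self.times.size > 1 and (
            np.any(dt <= 0) or not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9)
        ):
            raise ValueError("times must be strictly increasing and uniform")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("data contains non-finite values")
        if not self.channel_names:
            self.channel_names = [f"ch{i:02d}" for i in range(self.data.shape[1])]

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_categories(self) -> int:
        return int(self.labels.max()) + 1 if self.labels.size else 0

    def counts_per_category(self) -> np.ndarray:
        return np.bincount(self.labels, minlength=self.n_categories)


@dataclass
class ImageSet:
    """Stimulus images (luminance in [0, 1]) with category assignment."""

    images: np.ndarray            # stimuli x height x width
    labels: np.ndarray            # category index per stimulus
    deg_per_image: float = 5.0    # degrees of visual angle subtended
    category_names: tuple = DEFAULT_CATEGORIES

    def __post_init__(self):
        self.images = np.asarray(self.images, dtype=np.float64)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.images.ndim != 3 or self.images.shape[1] != self.images.shape[2]:
            raise ValueError("images must be stimuli x N x N (square)")
        if self.labels.shape[0] != self.images.shape[0]:
            raise ValueError("one category label per stimulus required")
        counts = np.bincount(self.labels)
        if counts.size and counts.min() < 2:
            raise ValueError("every category needs at least 2 stimuli")

    @property
    def n_stimuli(self) -> int:
        return self.images.shape[0]


def write_epochs(epochs: EpochsSet, path) -> None:
    """Write an :class:`EpochsSet` to the package's HDF5 container layout."""
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=epochs.data)
        f.create_dataset("labels", data=epochs.labels)
        f.create_dataset("times_ms", data=epochs.times)
        grp = f.create_group("channels")
        grp.create_dataset(
            "names", data=np.array(epochs.channel_names, dtype=h5py.string_dtype())
        )
        if epochs.channel_positions is not None:
            grp.create_dataset("pos", data=np.asarray(epochs.channel_positions))
        f.attrs["srate"] = float(epochs.srate)
        f.attrs["participant_id"] = epochs.participant_id
        f.attrs["group_tag"] = epochs.group_tag
        f.attrs["category_names"] = list(epochs.category_names)


def read_epochs(path) -> EpochsSet:
    """Read an :class:`EpochsSet` written by :func:`write_epochs`."""
    with h5py.File(path, "r") as f:
        for key in ("data", "labels", "times_ms"):
            if key not in f:
                raise KeyError(f"container is missing required dataset '{key}'")
        pos = None
        names = []
        if "channels" in f:
            if "names" in f["channels"]:
                names = [s.decode() if isinstance(s, bytes) else str(s)
                         for s in f["channels/names"][()]]
            if "pos" in f["channels"]:
                pos = f["channels/pos"][()]
        return EpochsSet(
            data=f["data"][()].astype(np.float64),
            labels=f["labels"][()],
            times=f["times_ms"][()],
            srate=float(f.attrs["srate"]),
            channel_names=names,
            channel_positions=pos,
            participant_id=str(f.attrs.get("participant_id", "")),
            group_tag=str(f.attrs.get("group_tag", "")),
            category_names=tuple(f.attrs.get("category_names", DEFAULT_CATEGORIES)),
        )


def _bin_array(x: np.ndarray, n_per_bin: int) -> np.ndarray:
    """Average the last axis of ``x`` in consecutive bins of ``n_per_bin``."""
    n_t = x.shape[-1]
    n_bins = n_t // n_per_bin
    if n_bins == 0:
        raise ValueError("bin longer than the available time axis")
    trimmed = x[..., : n_bins * n_per_bin]
    return trimmed.reshape(x.shape[:-1] + (n_bins, n_per_bin)).mean(axis=-1)


def bin_downsample(obj, bin_ms: float):
    """Downsample by averaging the time axis in ``bin_ms`` bins.

    Accepts an :class:`EpochsSet` (returns a new one at the reduced rate) or
    a plain array plus times via :func:`bin_downsample_array`.  Output
    samples are bin means labeled at bin centers; a trailing partial bin is
    dropped.
    """
    if not isinstance(obj, EpochsSet):
        raise TypeError("bin_downsample expects an EpochsSet; "
                        "use bin_downsample_array for raw arrays")
    data, times = bin_downsample_array(obj.data, obj.times, obj.srate, bin_ms)
    return replace(obj, data=data, times=times, srate=1000.0 / bin_ms)


def bin_downsample_array(x, times, srate, bin_ms):
    """Bin-average the last axis of a 3-D/4-D array; returns (array, new_times)."""
    x = np.asarray(x)
    times = np.asarray(times, dtype=np.float64)
    period_ms = 1000.0 / srate
    n_per_bin = bin_ms / period_ms
    if abs(n_per_bin - round(n_per_bin)) > 1e-9:
        raise ValueError(
            f"bin_ms={bin_ms} is not an integer multiple of the sample "
            f"period ({period_ms:g} ms)"
        )
    n_per_bin = int(round(n_per_bin))
    if n_per_bin < 1:
        raise ValueError("bin shorter than one sample")
    out = _bin_array(x, n_per_bin)
    n_bins = out.shape[-1]
    new_times = _bin_array(times[None, None, :], n_per_bin)[0, 0][:n_bins]
    return out, new_times


def write_images(images: ImageSet, out_dir) -> None:
    """Write an :class:`ImageSet` as 8-bit grayscale PNGs plus metadata.

    Luminance in [0, 1] is quantized to 8 bits; ``manifest.json`` records
    the stimulus order, category labels, names and visual angle.
    """
    import json
    from pathlib import Path

    from PIL import Image

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    names = []
    for i, img in enumerate(images.images):
        name = f"stim_{i:03d}.png"
        arr = np.clip(np.round(img * 255.0), 0, 255).astype(np.uint8)
        Image.fromarray(arr, mode="L").save(out / name)
        names.append(name)
    with open(out / "manifest.json", "w") as f:
        json.dump({
            "files": names,
            "labels": images.labels.tolist(),
            "category_names": list(images.category_names),
            "deg_per_image": images.deg_per_image,
        }, f, indent=2)


def read_images(in_dir) -> ImageSet:
    """Read an :class:`ImageSet` written by :func:`write_images`.

    The round trip is exact up to the 8-bit PNG quantization (1/255).
    """
    import json
    from pathlib import Path

    from PIL import Image

    src = Path(in_dir)
    with open(src / "manifest.json") as f:
        meta = json.load(f)
    imgs = np.stack([
        np.asarray(Image.open(src / name), dtype=np.float64) / 255.0
        for name in meta["files"]
    ])
    return ImageSet(images=imgs, labels=np.asarray(meta["labels"]),
                    deg_per_image=float(meta["deg_per_image"]),
                    category_names=tuple(meta["category_names"]))


def crop(epochs: EpochsSet, t0: float, t1: float) -> EpochsSet:
    """Select the half-open time window ``[t0, t1)`` in milliseconds."""
    mask = (epochs.times >= t0) & (epochs.times < t1)
    if not mask.any():
        raise ValueError(f"crop to [{t0}, {t1}) ms selects no samples")
    return replace(epochs, data=epochs.data[:, :, mask], times=epochs.times[mask])
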