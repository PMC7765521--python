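"""Loading, validation, segmentation and chronological splitting of recordings.

A :class:`Recording` is a channels x samples matrix with a sampling rate,
ordered channel labels and the set of channels clinically marked as seizure
onset zone (SOZ).  Recordings come from EDF files (via :mod:`mne`) or from a
plain sample matrix (CSV with channels as columns, or a raw little-endian
float64 binary) accompanied by a JSON sidecar::

    {"fs": 2000.0, "channel_labels": ["CH01", ...], "soz_channels": ["CH01"]}

Amplitudes are kept in the physical units of the source (microvolts for EDF);
several downstream features (Var, RMS, ...) are scale-dependent, so units must
be consistent across channels — this is documented, not enforced.

Segmentation cuts every channel into non-overlapping, chronologically ordered
windows of fixed duration (20 s by default); a trailing partial window is
discarded so every feature is computed on a full-length window.  The
chronological split assigns the first ``train`` minutes of segments to
training, the next ``validation`` minutes to validation, skips an explicit
``gap``, and uses the following ``test`` minutes for testing — a time-series
forecasting layout in which test data strictly follows everything the model
ever saw.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .errors import ConfigurationError, FormatError

__all__ = [
    "Recording",
    "Segment",
    "SplitPlan",
    "read_recording",
    "write_recording",
    "segment_recording",
    "segment_array",
    "chronological_split",
    "split_segment_counts",
]


@dataclass(frozen=True)
class Recording:
    """A labelled multichannel iEEG recording.

    Parameters
    ----------
    samples
        Real matrix of shape ``(n_channels, n_samples)``.
    fs
        Sampling rate in Hz.
    channel_labels
        Ordered channel names, one per row of ``samples``.
    soz_channels
        Names of the channels labelled positive (seizure onset zone).
    """

    samples: np.ndarray
    fs: float
    channel_labels: tuple[str, ...]
    soz_channels: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples)
        if samples.ndim != 2:
            raise FormatError(f"samples must be 2-D (channels x time), got ndim={samples.ndim}")
        if samples.shape[0] == 0:
            raise FormatError("recording has zero channels")
        if self.fs <= 0:
            raise ConfigurationError(f"sampling rate must be positive, got {self.fs}")
        labels = tuple(str(c).strip() for c in self.channel_labels)
        if len(labels) != samples.shape[0]:
            raise FormatError(
                f"{len(labels)} channel labels for {samples.shape[0]} channel rows"
            )
        if len(set(labels)) != len(labels):
            raise FormatError("duplicate channel labels")
        soz = frozenset(str(c).strip() for c in self.soz_channels)
        missing = soz - set(labels)
        if missing:
            raise ConfigurationError(f"SOZ labels not present in channel_labels: {sorted(missing)}")
        object.__setattr__(self, "samples", samples)
        object.__setattr__(self, "channel_labels", labels)
        object.__setattr__(self, "soz_channels", soz)

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_seconds(self) -> float:
        return self.n_samples / self.fs

    @property
    def channel_is_soz(self) -> np.ndarray:
        """Boolean vector aligned with ``channel_labels``."""
        return np.array([c in self.soz_channels for c in self.channel_labels])

    def validate_supervised(self) -> None:
        """Require at least one positive and one negative channel."""
        n_pos = int(self.channel_is_soz.sum())
        if n_pos == 0 or n_pos == self.n_channels:
            raise ConfigurationError(
                "supervised runs need at least one SOZ and one non-SOZ channel "
                f"(got {n_pos} of {self.n_channels} positive)"
            )


@dataclass(frozen=True)
class Segment:
    """One channel's contiguous fixed-length window.

    ``x`` is a view into the recording; ``index`` is the 0-based chronological
    segment index (time covered is ``[index*T, (index+1)*T)`` seconds);
    ``label`` is 1 when the owning channel is an SOZ channel.
    """

    channel: str
    index: int
    x: np.ndarray
    label: int


@dataclass(frozen=True)
class SplitPlan:
    """Contiguous chronological partition train -> validation -> gap -> test,

    each duration in minutes.  The gap is discarded."""

    train_minutes: float = 30.0
    validation_minutes: float = 5.0
    gap_minutes: float = 5.0
    test_minutes: float = 20.0

    def __post_init__(self) -> None:
        for name in ("train_minutes", "validation_minutes", "gap_minutes", "test_minutes"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be nonnegative")

    @property
    def total_minutes(self) -> float:
        return self.train_minutes + self.validation_minutes + self.gap_minutes + self.test_minutes

    def segment_counts(self, segment_seconds: float) -> tuple[int, int, int, int]:
        """Per-partition segment counts; every duration must be an integer

        multiple of the segment length."""
        counts = []
        for name in ("train_minutes", "validation_minutes", "gap_minutes", "test_minutes"):
            seconds = getattr(self, name) * 60.0
            n = seconds / segment_seconds
            if abs(n - round(n)) > 1e-9:
                raise ConfigurationError(
                    f"{name}={getattr(self, name)} is not an integer number of "
                    f"{segment_seconds} s segments"
                )
            counts.append(int(round(n)))
        return tuple(counts)


def _load_sidecar(sidecar: str | Path) -> Mapping:
    with open(sidecar, "r", encoding="utf-8") as fh:
        meta = json.load(fh)
    if not isinstance(meta, dict):
        raise FormatError(f"sidecar {sidecar} must contain a JSON object")
    return meta


def read_recording(path: str | Path, sidecar: str | Path | None = None) -> Recording:
    """Read a recording from EDF, CSV, or raw float64 binary.

    * ``.edf`` — header supplies fs and channel labels; the sidecar (if given)
      supplies ``soz_channels``.  Physical-unit scaling is applied on read and
      amplitudes are returned in microvolts.
    * ``.csv`` — channels as columns, header row of channel names; sidecar
      must supply ``fs`` and may supply ``soz_channels``.
    * anything else — little-endian float64 raw matrix, row-major
      ``(channels, samples)``; sidecar must supply ``fs`` and
      ``channel_labels``.
    """
    path = Path(path)
    meta: Mapping = _load_sidecar(sidecar) if sidecar is not None else {}
    soz = meta.get("soz_channels", [])

    suffix = path.suffix.lower()
    if suffix == ".edf":
        try:
            import mne
        except ImportError as exc:  # pragma: no cover - environment dependent
            raise ConfigurationError("reading EDF requires the optional mne dependency") from exc
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
        samples = raw.get_data() * 1e6  # volts -> microvolts
        return Recording(samples, float(raw.info["sfreq"]), tuple(raw.ch_names), frozenset(soz))

    if suffix == ".csv":
        import pandas as pd

        frame = pd.read_csv(path)
        if frame.shape[1] == 0:
            raise FormatError(f"{path} has no channel columns")
        if "fs" not in meta:
            raise ConfigurationError(f"CSV input {path} needs a sidecar with 'fs'")
        labels = tuple(str(c) for c in frame.columns)
        return Recording(frame.to_numpy().T, float(meta["fs"]), labels, frozenset(soz))

    # raw float64 little-endian matrix
    if "fs" not in meta or "channel_labels" not in meta:
        raise ConfigurationError(
            f"raw matrix input {path} needs a sidecar with 'fs' and 'channel_labels'"
        )
    labels = tuple(str(c) for c in meta["channel_labels"])
    flat = np.fromfile(path, dtype="<f8")
    if len(labels) == 0:
        raise FormatError(f"{path}: sidecar lists zero channels")
    if flat.size % len(labels) != 0:
        raise FormatError(
            f"{path}: {flat.size} samples do not divide evenly into {len(labels)} channels"
        )
    samples = flat.reshape(len(labels), -1)
    return Recording(samples, float(meta["fs"]), labels, frozenset(soz))


def write_recording(rec: Recording, path: str | Path, sidecar: str | Path) -> None:
    """Write a recording as a raw float64 matrix (or CSV) plus JSON sidecar.

    The raw-matrix round trip is bit-exact.
    """
    path = Path(path)
    meta = {
        "fs": rec.fs,
        "channel_labels": list(rec.channel_labels),
        "soz_channels": sorted(rec.soz_channels),
    }
    if path.suffix.lower() == ".csv":
        import pandas as pd

        pd.DataFrame(rec.samples.T, columns=list(rec.channel_labels)).to_csv(path, index=False)
    else:
        np.ascontiguousarray(rec.samples, dtype="<f8").tofile(path)
    with open(sidecar, "w", encoding="utf-8") as fh:
        json.dump(meta, fh, indent=1)


def segment_array(rec: Recording, segment_seconds: float = 20.0) -> np.ndarray:
    """Reshape the recording into ``(n_channels, n_segments, L)`` windows.

    ``L = round(fs * segment_seconds)``; the trailing partial window is
    discarded.  The result is a view when the sample matrix is contiguous.
    """
    if segment_seconds <= 0:
        raise ConfigurationError("segment_seconds must be positive")
    L = int(round(rec.fs * segment_seconds))
    n_seg = rec.n_samples // L
    if n_seg == 0:
        raise FormatError(
            f"recording of {rec.duration_seconds:.1f} s is shorter than one "
            f"{segment_seconds} s segment"
        )
    return rec.samples[:, : n_seg * L].reshape(rec.n_channels, n_seg, L)


def segment_recording(
    rec: Recording, segment_seconds: float = 20.0
) -> dict[str, list[Segment]]:
    """Cut every channel into chronological :class:`Segment` windows."""
    windows = segment_array(rec, segment_seconds)
    is_soz = rec.channel_is_soz
    out: dict[str, list[Segment]] = {}
    for c, name in enumerate(rec.channel_labels):
        label = int(is_soz[c])
        out[name] = [Segment(name, i, windows[c, i], label) for i in range(windows.shape[1])]
    return out


def split_segment_counts(
    n_segments: int, plan: SplitPlan, segment_seconds: float = 20.0
) -> tuple[int, int, int, int]:
    """Validate the plan against the recording length and return per-partition

    segment counts (train, validation, gap, test)."""
    counts = plan.segment_counts(segment_seconds)
    if sum(counts) > n_segments:
        raise ConfigurationError(
            f"split plan needs {sum(counts)} segments but the recording has {n_segments}"
        )
    return counts


def chronological_split(
    segments: Mapping[str, Sequence[Segment]],
    plan: SplitPlan,
    segment_seconds: float = 20.0,
) -> tuple[dict[str, list[Segment]], dict[str, list[Segment]], dict[str, list[Segment]]]:
    """Split each channel's segment sequence into (train, validation, test).

    Gap segments between validation and test are discarded.
    """
    lengths = {len(v) for v in segments.values()}
    if len(lengths) != 1:
        raise FormatError("channels have differing segment counts")
    n_segments = lengths.pop()
    n_tr, n_va, n_gap, n_te = split_segment_counts(n_segments, plan, segment_seconds)
    train: dict[str, list[Segment]] = {}
    val: dict[str, list[Segment]] = {}
    test: dict[str, list[Segment]] = {}
    for name, seq in segments.items():
        seq = list(seq)
        train[name] = seq[:n_tr]
        val[name] = seq[n_tr : n_tr + n_va]
        test[name] = seq[n_tr + n_va + n_gap : n_tr + n_va + n_gap + n_te]
    return train, val, test
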