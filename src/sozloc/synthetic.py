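"""Synthetic interictal-like multichannel recordings with planted HFO bursts.

Each channel is a broadband noise background (pink, i.e. 1/f-shaped, by
default) into which short Gabor atoms — Gaussian-windowed sinusoids, the
standard surrogate for high-frequency oscillations — are inserted at
Poisson-distributed onset times.  Burst carrier frequencies are drawn
uniformly from the ripple or fast-ripple band (equal mix).  SOZ channels carry
a higher burst rate than non-SOZ channels; that rate asymmetry is the only
difference between the classes, mirroring the clinical picture in which
epileptogenic tissue generates HFOs at elevated rates while the background is
statistically identical everywhere.

Burst strength is set by ``burst_snr``: the RMS of the atom over its nominal
duration divided by the background RMS *within the atom's own band* (estimated
from the channel's noise spectrum), so the same ``burst_snr`` is equally hard
to detect in a pink or white background.

Default rates (SOZ 12 bursts/min, non-SOZ 1/min) and SNR (3) reflect
interictal recordings where HFOs outside the SOZ are rare and marked events
stand clearly above the in-band background.  Amplitudes are in arbitrary
microvolt-scale units; every downstream result is rank/AUC-based, so the
absolute scale is irrelevant.  The seed fixes the full sample stream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError
from .recording_io import Recording

__all__ = ["SynthSpec", "generate_recording", "generate_cohort"]


@dataclass(frozen=True)
class SynthSpec:
    """Study-condition parameters of one synthetic recording."""

    n_channels: int = 20
    soz_channels: tuple[str, ...] = ("CH01", "CH02", "CH03")
    fs: float = 2000.0
    duration_minutes: float = 60.0
    burst_rate_soz: float = 12.0  # bursts per minute
    burst_rate_nonsoz: float = 1.0
    ripple_band: tuple[float, float] = (80.0, 250.0)
    fast_ripple_band: tuple[float, float] = (250.0, 600.0)
    burst_duration_ms: float = 50.0
    burst_snr: float = 3.0
    noise: str = "pink"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_channels < 1:
            raise ConfigurationError("n_channels must be >= 1")
        if self.fs not in (1000.0, 2000.0):
            raise ConfigurationError(f"fs must be 1000 or 2000 Hz, got {self.fs}")
        if self.duration_minutes <= 0:
            raise ConfigurationError("duration_minutes must be positive")
        if not (self.burst_rate_soz >= self.burst_rate_nonsoz >= 0):
            raise ConfigurationError("need burst_rate_soz >= burst_rate_nonsoz >= 0")
        for name in ("ripple_band", "fast_ripple_band"):
            lo, hi = getattr(self, name)
            if not (0 < lo < hi < self.fs / 2):
                raise ConfigurationError(f"{name}=({lo}, {hi}) must lie below fs/2={self.fs / 2}")
        if self.burst_duration_ms <= 0 or self.burst_snr < 0:
            raise ConfigurationError("burst_duration_ms must be positive and burst_snr >= 0")
        if self.noise not in ("white", "pink"):
            raise ConfigurationError(f"noise must be 'white' or 'pink', got {self.noise!r}")
        labels = self.channel_labels
        unknown = set(self.soz_channels) - set(labels)
        if unknown:
            raise ConfigurationError(f"soz_channels not among generated labels: {sorted(unknown)}")

    @property
    def channel_labels(self) -> tuple[str, ...]:
        return tuple(f"CH{i + 1:02d}" for i in range(self.n_channels))

    @property
    def n_samples(self) -> int:
        return int(round(self.duration_minutes * 60.0 * self.fs))


#: below this frequency the 1/f background shape plateaus (EEG spectra flatten
#: at the lowest frequencies; an unbounded 1/f tail would also let a handful of
#: near-DC bins dominate each channel's total power)
PINK_FLOOR_HZ = 2.0


def _noise_channel(
    rng: np.random.Generator, n: int, fs: float, kind: str
) -> tuple[np.ndarray, np.ndarray]:
    """Unit-RMS background noise plus its one-sided amplitude spectrum."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    if kind == "pink":
        freqs = np.fft.rfftfreq(n, d=1.0 / fs)
        shape = np.zeros_like(freqs)
        above = freqs >= PINK_FLOOR_HZ
        shape[above] = freqs[above] ** -0.5  # 1/f power spectral density
        shape[(freqs > 0) & ~above] = PINK_FLOOR_HZ**-0.5
        spec *= shape
        x = np.fft.irfft(spec, n)
    else:
        x = white
        # keep the spectrum consistent with the returned samples
    scale = np.sqrt(np.mean(np.square(x)))
    x /= scale
    spec /= scale
    return x, spec


def _band_rms(spec: np.ndarray, n: int, fs: float, band: tuple[float, float]) -> float:
    """Background RMS inside a band, from the one-sided spectrum (Parseval)."""
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    mask = (freqs >= band[0]) & (freqs < band[1])
    power = np.abs(spec[mask]) ** 2
    # one-sided correction: every bin except DC/Nyquist counts twice
    full = 2.0 * power.sum()
    return float(np.sqrt(full / n**2))


def generate_recording(spec: SynthSpec) -> Recording:
    """Generate one labelled recording; bit-identical under the same seed."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n_samples
    fs = spec.fs
    labels = spec.channel_labels
    soz = frozenset(spec.soz_channels)

    dur_s = spec.burst_duration_ms / 1000.0
    half = int(round(dur_s * fs / 2))
    t_atom = (np.arange(2 * half + 1) - half) / fs
    sigma = dur_s / 6.0  # +-3 sigma spans the nominal burst duration
    envelope = np.exp(-0.5 * (t_atom / sigma) ** 2)

    samples = np.empty((spec.n_channels, n), dtype=np.float64)
    bands = (spec.ripple_band, spec.fast_ripple_band)
    for c, name in enumerate(labels):
        x, spectrum = _noise_channel(rng, n, fs, spec.noise)
        band_rms = [_band_rms(spectrum, n, fs, b) for b in bands]
        rate = spec.burst_rate_soz if name in soz else spec.burst_rate_nonsoz
        n_bursts = rng.poisson(rate * spec.duration_minutes)
        for _ in range(n_bursts):
            which = int(rng.integers(0, 2))
            lo, hi = bands[which]
            f0 = rng.uniform(lo, hi)
            phase = rng.uniform(0, 2 * np.pi)
            center = int(rng.integers(half, n - half))
            atom = envelope * np.sin(2 * np.pi * f0 * t_atom + phase)
            atom_rms = np.sqrt(np.mean(np.square(atom)))
            if atom_rms > 0 and spec.burst_snr > 0:
                atom *= spec.burst_snr * band_rms[which] / atom_rms
                x[center - half : center + half + 1] += atom
        samples[c] = x
    return Recording(samples, fs, labels, soz)


def generate_cohort(
    n_patients: int, base: SynthSpec | None = None, seed: int = 0
) -> list[Recording]:
    """Generate a cohort; channel and SOZ counts jitter around the base spec.

    Per-patient seeds derive deterministically from the cohort seed, so the
    cohort is reproducible as a whole.
    """
    if n_patients < 1:
        raise ConfigurationError("n_patients must be >= 1")
    base = base or SynthSpec()
    ss = np.random.SeedSequence(seed)
    jitter_rng = np.random.default_rng(ss.spawn(1)[0])
    recordings = []
    for child in ss.spawn(n_patients + 1)[1:]:
        patient_seed = int(child.generate_state(1)[0] % 2**31)
        n_ch = max(4, base.n_channels + int(jitter_rng.integers(-2, 3)))
        n_soz = int(np.clip(len(base.soz_channels) + int(jitter_rng.integers(-1, 2)), 1, n_ch - 1))
        spec = SynthSpec(
            n_channels=n_ch,
            soz_channels=tuple(f"CH{i + 1:02d}" for i in range(n_soz)),
            fs=base.fs,
            duration_minutes=base.duration_minutes,
            burst_rate_soz=base.burst_rate_soz,
            burst_rate_nonsoz=base.burst_rate_nonsoz,
            ripple_band=base.ripple_band,
            fast_ripple_band=base.fast_ripple_band,
            burst_duration_ms=base.burst_duration_ms,
            burst_snr=base.burst_snr,
            noise=base.noise,
            seed=patient_seed,
        )
        recordings.append(generate_recording(spec))
    return recordings
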