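"""Single-taper spectral decomposition of trial-segmented field potentials.

Each trial segment is premultiplied by a data taper (a Slepian/DPSS window by
default, rectangular as an oracle-friendly alternative) and Fourier
transformed.  The result is stored as amplitude/phase ensembles per frequency,
the form in which every coherence measure downstream operates: the complex
coefficient of channel *a* on trial *k* at frequency *f* is
``A_k(f) * exp(1j * phi_k(f))``.

Conventions
-----------
* A single taper is used (no multitaper averaging): it maximizes frequency
  resolution at the cost of estimator variance, and that variance — Rayleigh
  amplitudes, exponential power — is precisely what the bias theory in
  :mod:`cohbias.analytic` describes.
* The taper is normalized to unit energy so white-noise power levels are
  taper-independent.
* No zero-padding: frequency spacing equals 1/duration (5 Hz for a 200-ms
  epoch).
* The phase of an exactly-zero coefficient is defined as 0.
* Epoch windows are half-open ``[start, end)`` in ms relative to stimulus
  onset.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal.windows import dpss

from .errors import SpectralError

__all__ = [
    "TrialSegment",
    "TrialSpectra",
    "TaperConfig",
    "make_taper",
    "taper_transform",
    "extract_epoch",
]


@dataclass(frozen=True)
class TrialSegment:
    """One trial's voltage trace.

    Parameters
    ----------
    samples
        Voltage samples in µV.
    sampling_rate
        Sampling rate in Hz.
    t0
        Time of the first sample in ms relative to stimulus onset.
    """

    samples: np.ndarray
    sampling_rate: float
    t0: float = 0.0

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        object.__setattr__(self, "samples", samples)
        if samples.ndim != 1 or samples.size < 2:
            raise SpectralError("a trial segment needs at least 2 samples")
        if not self.sampling_rate > 0:
            raise SpectralError("sampling_rate must be positive")

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.sampling_rate


@dataclass(frozen=True)
class TaperConfig:
    """Taper choice for the direct spectral estimator.

    ``slepian`` selects the first DPSS sequence with time-bandwidth product
    ``time_bandwidth`` (single taper); ``rectangular`` is a boxcar, useful for
    exact on-bin sinusoid oracles.  Both are normalized to unit energy.
    """

    kind: str = "slepian"
    time_bandwidth: float = 1.0
    taper_index: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("slepian", "rectangular"):
            raise SpectralError(f"unknown taper kind {self.kind!r}")
        if self.kind == "slepian":
            if self.time_bandwidth < 1:
                raise SpectralError("slepian time_bandwidth must be >= 1")
            if self.taper_index != 0:
                raise SpectralError("single-taper analysis: taper_index must be 0")


@dataclass
class TrialSpectra:
    """Amplitude/phase ensembles of one channel across trials.

    ``amplitudes[k, i]`` and ``phases[k, i]`` are the polar coordinates of the
    tapered Fourier coefficient of trial ``k`` at ``freqs[i]``.
    """

    freqs: np.ndarray
    amplitudes: np.ndarray
    phases: np.ndarray
    channel_id: str = ""
    taper: TaperConfig = field(default_factory=TaperConfig)

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.amplitudes = np.asarray(self.amplitudes, dtype=float)
        self.phases = np.asarray(self.phases, dtype=float)
        if self.amplitudes.shape != self.phases.shape:
            raise SpectralError("amplitudes and phases must have the same shape")
        if self.amplitudes.ndim != 2 or self.amplitudes.shape[1] != self.freqs.size:
            raise SpectralError("expected [trial x freq] matrices matching freqs")
        if np.any(self.amplitudes < 0):
            raise SpectralError("amplitudes must be nonnegative")
        if self.freqs.size > 1 and np.any(np.diff(self.freqs) <= 0):
            raise SpectralError("freqs must be strictly increasing")

    @property
    def n_trials(self) -> int:
        return self.amplitudes.shape[0]

    @property
    def power(self) -> np.ndarray:
        """Squared amplitudes, [trial x freq]."""
        return self.amplitudes**2


def make_taper(n_samples: int, taper: TaperConfig) -> np.ndarray:
    """Return the unit-energy taper window of length ``n_samples``."""
    if taper.kind == "rectangular":
        w = np.ones(n_samples)
    else:
        w = dpss(n_samples, taper.time_bandwidth, 1)[0]
    return w / np.sqrt(np.sum(w**2))


def taper_transform(
    segments: list[TrialSegment], taper: TaperConfig | None = None
) -> TrialSpectra:
    """Tapered Fourier transform of a trial ensemble.

    Returns amplitudes and phases at nonnegative frequencies with spacing
    1/duration (no zero-padding).

    Raises
    ------
    SpectralError
        If the trial list is empty or segment lengths / rates differ.
    """
    if taper is None:
        taper = TaperConfig()
    if len(segments) == 0:
        raise SpectralError("empty trial list")
    n = segments[0].samples.size
    rate = segments[0].sampling_rate
    for i, seg in enumerate(segments):
        if seg.samples.size != n:
            raise SpectralError(
                f"trial {i} has {seg.samples.size} samples, expected {n}"
            )
        if seg.sampling_rate != rate:
            raise SpectralError(f"trial {i} sampling rate differs")

    window = make_taper(n, taper)
    data = np.stack([seg.samples for seg in segments])
    coeffs = np.fft.rfft(data * window, axis=1)
    freqs = np.fft.rfftfreq(n, d=1.0 / rate)
    amplitudes = np.abs(coeffs)
    phases = np.where(amplitudes > 0, np.angle(coeffs), 0.0)
    return TrialSpectra(freqs=freqs, amplitudes=amplitudes, phases=phases, taper=taper)


def extract_epoch(
    continuous: np.ndarray,
    time_ms: np.ndarray,
    sampling_rate: float,
    window: tuple[float, float],
) -> list[TrialSegment]:
    """Cut one epoch out of continuous per-trial traces of a single channel.

    Parameters
    ----------
    continuous
        Array [trial x samples], aligned to stimulus onset.
    time_ms
        Per-sample times in ms relative to stimulus onset.
    window
        Half-open window ``[t_start, t_end)`` in ms.

    Returns
    -------
    One :class:`TrialSegment` per trial, each with
    ``round(duration * rate)`` samples.
    """
    continuous = np.atleast_2d(np.asarray(continuous, dtype=float))
    time_ms = np.asarray(time_ms, dtype=float)
    t_start, t_end = window
    if not t_end > t_start:
        raise SpectralError(f"zero-length or inverted window {window}")
    if t_start < time_ms[0] or t_end > time_ms[-1] + 1000.0 / sampling_rate:
        raise SpectralError(
            f"window {window} ms outside recorded span "
            f"[{time_ms[0]}, {time_ms[-1]}] ms"
        )
    mask = (time_ms >= t_start) & (time_ms < t_end)
    n_expected = round((t_end - t_start) / 1000.0 * sampling_rate)
    idx = np.flatnonzero(mask)[:n_expected]
    if idx.size != n_expected:
        raise SpectralError(
            f"window {window} yields {idx.size} samples, expected {n_expected}"
        )
    t0 = time_ms[idx[0]]
    return [
        TrialSegment(samples=row[idx], sampling_rate=sampling_rate, t0=t0)
        for row in continuous
    ]
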