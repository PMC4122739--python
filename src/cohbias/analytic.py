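"""Closed-form reference values for the coherence bias theory.

The single-taper direct spectral estimator imposes a stereotyped across-trial
distribution on the Fourier coefficients of a noisy signal: the complex
coefficient is asymptotically a 2-D isotropic Gaussian, so the amplitude is
Rayleigh (CV = sqrt(4/π − 1) ≈ 0.523) and the power is exponential (CV = 1).
Those distributions, not physiology, fix two analytic constants:

* the amplitude-coherence floor π/4 for independent channels, because
  E[A·B] / sqrt(E[A²]·E[B²]) = (σ²π/2) / (2σ²) = π/4 for independent
  Rayleigh amplitudes; and
* the finite-trial bias of the phase-locking value under uniform phases,
  E[PLV] = sqrt(π/(4N)) ≈ 0.886/sqrt(N), from the mean modulus of an
  N-step 2-D random walk.

When the two channels' amplitudes are equal (amplitude correlation 1) the
coherence numerator is weighted by A² ~ exponential; the heavier weight tail
inflates the uniform-phase bias by sqrt(2) on the coherence scale:
E[C] = sqrt(π/(2N)).  (Some accounts state a factor 2; that is the factor on
the *squared* scale — the Monte-Carlo oracle in this package's tests pins the
coherence-scale factor at sqrt(2).)

For von Mises phase differences with concentration κ the true phase coherence
is the mean resultant length I₁(κ)/I₀(κ).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.special import i0e, i1e

from .errors import UndefinedMeasureError
from .spectral import TrialSpectra

__all__ = [
    "vonmises_plv",
    "plv_bias",
    "coherence_bias",
    "rayleigh_cv",
    "exponential_cv",
    "BiasModel",
    "DistributionDiagnostics",
    "distribution_diagnostics",
]

#: E[PLV]·sqrt(N) under uniform phases: sqrt(π)/2.
PLV_BIAS_COEF = float(np.sqrt(np.pi) / 2)


def vonmises_plv(kappa: float) -> float:
    """True phase coherence of von Mises phase differences: I₁(κ)/I₀(κ).

    Uses exponentially scaled Bessel functions so the ratio stays finite for
    large κ (> 700).  Strictly increasing, 0 at κ = 0, → 1 as κ → ∞.
    """
    if not np.isfinite(kappa) or kappa < 0:
        raise ValueError(f"kappa must be finite and >= 0, got {kappa}")
    return float(i1e(kappa) / i0e(kappa))


def plv_bias(n_trials: int) -> float:
    """Expected phase-locking value for N trials of uniform phase differences.

    sqrt(π/(4N)) = 0.8862.../sqrt(N).
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    return PLV_BIAS_COEF / np.sqrt(n_trials)


def coherence_bias(n_trials: int, amp_mode: str = "independent") -> float:
    """Expected coherence under uniform phases with Rayleigh amplitudes.

    ``independent``: identical to :func:`plv_bias` — the amplitude products
    decouple from the phase resultant.  ``equal`` (second channel's amplitude
    equal to the first): sqrt(2) × plv_bias, from the exponential distribution
    of the A² weights in the resultant.
    """
    if amp_mode == "independent":
        return plv_bias(n_trials)
    if amp_mode == "equal":
        return float(np.sqrt(2) * plv_bias(n_trials))
    raise ValueError(f"unknown amp_mode {amp_mode!r}")


def rayleigh_cv() -> float:
    """CV of a Rayleigh distribution: sqrt(4/π − 1) ≈ 0.5227 (scale-free)."""
    return float(np.sqrt(4 / np.pi - 1))


def exponential_cv() -> float:
    """CV of an exponential distribution: exactly 1."""
    return 1.0


@dataclass(frozen=True)
class BiasModel:
    """Predicted finite-trial coherence bias for one configuration."""

    n_trials: int
    amp_mode: str = "independent"

    @property
    def predicted_bias(self) -> float:
        return coherence_bias(self.n_trials, self.amp_mode)


@dataclass
class DistributionDiagnostics:
    """Per-frequency across-trial distribution checks of a spectral ensemble.

    ``ks_*`` are Kolmogorov–Smirnov distances (the goodness-of-fit metric used
    throughout this package): mean-scaled power against a unit-mean
    exponential, and amplitude against a Rayleigh whose scale is fitted from
    the mean amplitude.
    """

    freqs: np.ndarray
    cv_power: np.ndarray
    cv_amplitude: np.ndarray
    ks_power_vs_exponential: np.ndarray
    ks_amplitude_vs_rayleigh: np.ndarray

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "frequency_hz": self.freqs,
                "cv_power": self.cv_power,
                "cv_amplitude": self.cv_amplitude,
                "ks_power": self.ks_power_vs_exponential,
                "ks_amplitude": self.ks_amplitude_vs_rayleigh,
            }
        )


def distribution_diagnostics(spectra: TrialSpectra) -> DistributionDiagnostics:
    """CV and KS diagnostics of amplitude/power distributions across trials.

    "Scaled power" is power divided by its across-trial mean per frequency,
    making the exponential reference unit-rate.  Requires N >= 20 trials.
    """
    if spectra.n_trials < 20:
        raise UndefinedMeasureError(
            f"distribution diagnostics need >= 20 trials, got {spectra.n_trials}"
        )
    amp = spectra.amplitudes
    power = amp**2
    mean_p = power.mean(axis=0)
    mean_a = amp.mean(axis=0)
    cv_power = np.divide(
        power.std(axis=0, ddof=1), mean_p, out=np.zeros_like(mean_p), where=mean_p > 0
    )
    cv_amp = np.divide(
        amp.std(axis=0, ddof=1), mean_a, out=np.zeros_like(mean_a), where=mean_a > 0
    )
    n_f = spectra.freqs.size
    ks_p = np.ones(n_f)
    ks_a = np.ones(n_f)
    rayleigh_mean = np.sqrt(np.pi / 2)  # mean of Rayleigh(scale=1)
    for i in range(n_f):
        if mean_p[i] > 0:
            ks_p[i] = stats.kstest(power[:, i] / mean_p[i], stats.expon.cdf).statistic
            sigma_hat = mean_a[i] / rayleigh_mean
            ks_a[i] = stats.kstest(
                amp[:, i], stats.rayleigh.cdf, args=(0, sigma_hat)
            ).statistic
    return DistributionDiagnostics(
        freqs=spectra.freqs.copy(),
        cv_power=cv_power,
        cv_amplitude=cv_amp,
        ks_power_vs_exponential=ks_p,
        ks_amplitude_vs_rayleigh=ks_a,
    )
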