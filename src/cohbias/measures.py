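"""Coherence decompositions and pairwise phase consistency.

Given the tapered Fourier coefficients of two channels at one frequency,
written in polar form ``A_k e^{j phi_k}`` and ``B_k e^{j theta_k}`` over
trials ``k = 1..N``, the single-taper coherence is

    C = | sum_k A_k B_k e^{j(phi_k - theta_k)} | / sqrt(sum A_k^2 * sum B_k^2)

Four companion measures isolate its ingredients:

* phase coherence (phase-locking value, PLV): all amplitudes forced to 1 —
  the modulus of the mean unit phasor of the trial phase differences;
* amplitude coherence: all phase differences forced to 0 — bounded below by
  π/4 for independent Rayleigh amplitudes, hence never small;
* amplitude cross-correlation: amplitude coherence after subtracting the
  across-trial mean amplitude (a Pearson-type correlation, modulus taken);
* random-phase coherence: the coherence with each trial's phase difference
  replaced by an independent uniform draw on [−π, π], retaining only the
  coherence contributed by amplitude covariation plus finite-trial bias.

Pairwise phase consistency (PPC) is the average cosine of the difference of
per-trial relative phases over all trial pairs; it is an unbiased estimator
of the squared true phase consistency, unlike PLV whose expectation under
uniform phases is ≈ sqrt(π/4N).

Note on PPC indexing: the estimator is computed on per-trial relative phases
``delta_k = theta_k - phi_k``; forms that pair channel phases across
*different* trials conflate the two channels' marginal phase distributions
with their trial-by-trial relationship and are not what the unbiased
estimator prescribes.

All measures here operate per frequency; :func:`coherence_spectra` loops the
frequency axis of two :class:`~cohbias.spectral.TrialSpectra`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import UndefinedMeasureError
from .spectral import TrialSpectra

__all__ = [
    "PairedEnsemble",
    "CoherenceSpectrum",
    "coherence",
    "phase_coherence",
    "amplitude_coherence",
    "amplitude_crosscorr",
    "random_phase_coherence",
    "ppc",
    "coherence_spectra",
    "MEASURES",
]


@dataclass(frozen=True)
class PairedEnsemble:
    """Amplitudes and phases of two channels at one frequency across trials."""

    ampA: np.ndarray
    ampB: np.ndarray
    phaseA: np.ndarray
    phaseB: np.ndarray
    frequency: float = np.nan

    def __post_init__(self) -> None:
        for name in ("ampA", "ampB", "phaseA", "phaseB"):
            object.__setattr__(
                self, name, np.atleast_1d(np.asarray(getattr(self, name), dtype=float))
            )
        n = self.ampA.size
        if n < 1:
            raise UndefinedMeasureError("empty ensemble")
        for name in ("ampB", "phaseA", "phaseB"):
            if getattr(self, name).size != n:
                raise UndefinedMeasureError("ensemble vectors must have equal length")
        if np.any(self.ampA < 0) or np.any(self.ampB < 0):
            raise UndefinedMeasureError("amplitudes must be nonnegative")

    @property
    def n_trials(self) -> int:
        return self.ampA.size

    @property
    def relative_phase(self) -> np.ndarray:
        """Per-trial relative phase ``theta_k - phi_k``."""
        return self.phaseB - self.phaseA


@dataclass
class CoherenceSpectrum:
    """One measure evaluated on a frequency grid."""

    freqs: np.ndarray
    values: np.ndarray
    measure: str
    n_trials: int


# ---------------------------------------------------------------------------
# Row-stacked kernels.  Each takes (R, N) arrays — R independent ensembles of
# N trials — and returns a length-R vector.  The public scalar API and the
# Monte-Carlo drivers in cohbias.simulator share these, so simulations measure
# exactly what the per-ensemble functions measure.
# ---------------------------------------------------------------------------


def _coherence_rows(ampA, ampB, dphase) -> np.ndarray:
    num = np.abs(np.sum(ampA * ampB * np.exp(1j * dphase), axis=-1))
    den = np.sqrt(np.sum(ampA**2, axis=-1) * np.sum(ampB**2, axis=-1))
    return num / den


def _plv_rows(dphase) -> np.ndarray:
    return np.abs(np.mean(np.exp(1j * dphase), axis=-1))


def _amp_coherence_rows(ampA, ampB) -> np.ndarray:
    num = np.sum(ampA * ampB, axis=-1)
    den = np.sqrt(np.sum(ampA**2, axis=-1) * np.sum(ampB**2, axis=-1))
    return num / den


def _ppc_rows(delta) -> np.ndarray:
    # |sum e^{j delta}|^2 = N + 2 sum_{j<k} cos(delta_j - delta_k)
    n = delta.shape[-1]
    resultant_sq = np.abs(np.sum(np.exp(1j * delta), axis=-1)) ** 2
    return (resultant_sq - n) / (n * (n - 1))


def _require_nonzero_amps(ens: PairedEnsemble) -> None:
    if not np.any(ens.ampA > 0):
        raise UndefinedMeasureError("channel A amplitudes are all zero")
    if not np.any(ens.ampB > 0):
        raise UndefinedMeasureError("channel B amplitudes are all zero")


def coherence(ens: PairedEnsemble) -> float:
    """Single-taper coherence at one frequency; in [0, 1]."""
    _require_nonzero_amps(ens)
    return float(
        _coherence_rows(ens.ampA, ens.ampB, ens.phaseA - ens.phaseB)
    )


def phase_coherence(ens: PairedEnsemble) -> float:
    """Phase-locking value: mean resultant length of the phase differences.

    Ignores amplitudes entirely; in [0, 1].
    """
    return float(_plv_rows(ens.phaseA - ens.phaseB))


def amplitude_coherence(ens: PairedEnsemble) -> float:
    """Coherence with all phase differences set to 0; in [0, 1] by
    Cauchy–Schwarz."""
    _require_nonzero_amps(ens)
    return float(_amp_coherence_rows(ens.ampA, ens.ampB))


def amplitude_crosscorr(ens: PairedEnsemble) -> float:
    """Modulus of the Pearson correlation of across-trial amplitudes."""
    if ens.n_trials < 2:
        raise UndefinedMeasureError("amplitude cross-correlation needs N >= 2")
    devA = ens.ampA - ens.ampA.mean()
    devB = ens.ampB - ens.ampB.mean()
    den = np.sqrt(np.sum(devA**2) * np.sum(devB**2))
    if den == 0:
        raise UndefinedMeasureError("zero amplitude variance on one side")
    return float(np.abs(np.sum(devA * devB) / den))


def random_phase_coherence(
    ens: PairedEnsemble, seed: int | np.random.Generator
) -> float:
    """Coherence after replacing each trial's phase difference with an
    independent uniform draw on [−π, π].

    What survives phase randomization is the amplitude-driven component of
    coherence plus the finite-trial bias floor.  A seed (or Generator) is
    mandatory: the measure is stochastic by construction.
    """
    _require_nonzero_amps(ens)
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    phi_rand = rng.uniform(-np.pi, np.pi, size=ens.n_trials)
    return float(_coherence_rows(ens.ampA, ens.ampB, phi_rand))


def ppc(ens: PairedEnsemble) -> float:
    """Pairwise phase consistency on per-trial relative phases; in [−1, 1]."""
    if ens.n_trials < 2:
        raise UndefinedMeasureError("PPC needs N >= 2 trials")
    return float(_ppc_rows(ens.relative_phase))


MEASURES = {
    "coherence": coherence,
    "phase": phase_coherence,
    "amp": amplitude_coherence,
    "amp_meanDev": amplitude_crosscorr,
    "amp_randomPhase": random_phase_coherence,
    "ppc": ppc,
}


def coherence_spectra(
    specA: TrialSpectra,
    specB: TrialSpectra,
    measures: list[str] | None = None,
    seed: int | np.random.Generator | None = None,
) -> dict[str, CoherenceSpectrum]:
    """Evaluate measures at every frequency of two matched spectra.

    ``seed`` is required iff ``amp_randomPhase`` is requested; the uniform
    draws are independent per trial and per frequency.
    """
    if measures is None:
        measures = list(MEASURES)
    unknown = set(measures) - set(MEASURES)
    if unknown:
        raise ValueError(f"unknown measures: {sorted(unknown)}")
    if not np.array_equal(specA.freqs, specB.freqs):
        raise UndefinedMeasureError("frequency grids differ between channels")
    if specA.n_trials != specB.n_trials:
        raise UndefinedMeasureError("trial counts differ between channels")
    rng = None
    if "amp_randomPhase" in measures:
        if seed is None:
            raise ValueError("amp_randomPhase requires a seed")
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    out: dict[str, CoherenceSpectrum] = {}
    n_f = specA.freqs.size
    for name in measures:
        values = np.empty(n_f)
        for i in range(n_f):
            ens = PairedEnsemble(
                ampA=specA.amplitudes[:, i],
                ampB=specB.amplitudes[:, i],
                phaseA=specA.phases[:, i],
                phaseB=specB.phases[:, i],
                frequency=specA.freqs[i],
            )
            if name == "amp_randomPhase":
                values[i] = random_phase_coherence(ens, rng)
            else:
                values[i] = MEASURES[name](ens)
        out[name] = CoherenceSpectrum(
            freqs=specA.freqs.copy(),
            values=values,
            measure=name,
            n_trials=specA.n_trials,
        )
    return out
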