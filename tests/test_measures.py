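"""Coherence decompositions: hand-derived examples, brute-force oracle,
and invariance properties."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import cohbias.measures as m
from cohbias.errors import UndefinedMeasureError
from cohbias.measures import PairedEnsemble, coherence_spectra
from cohbias.spectral import TrialSpectra


def ens(ampA, ampB, phaseA, phaseB):
    return PairedEnsemble(ampA=ampA, ampB=ampB, phaseA=phaseA, phaseB=phaseB)


# ---------------------------------------------------------------------------
# Brute-force oracle: direct loop evaluation of the printed formulas.
# ---------------------------------------------------------------------------


def oracle(e: PairedEnsemble):
    A, B, phi, theta = e.ampA, e.ampB, e.phaseA, e.phaseB
    n = len(A)
    num = sum(A[k] * B[k] * np.exp(1j * (phi[k] - theta[k])) for k in range(n))
    den = np.sqrt(sum(A[k] ** 2 for k in range(n)) * sum(B[k] ** 2 for k in range(n)))
    out = {
        "coherence": abs(num) / den,
        "phase": abs(sum(np.exp(1j * (phi[k] - theta[k])) for k in range(n))) / n,
        "amp": sum(A[k] * B[k] for k in range(n)) / den,
    }
    if n >= 2:
        dA = A - np.mean(A)
        dB = B - np.mean(B)
        d = np.sqrt(sum(dA**2) * sum(dB**2))
        out["amp_meanDev"] = abs(sum(dA * dB)) / d if d > 0 else np.nan
        delta = theta - phi
        out["ppc"] = (2 / (n * (n - 1))) * sum(
            np.cos(delta[j] - delta[k])
            for j in range(n - 1)
            for k in range(j + 1, n)
        )
    return out


def enumerated_ensembles():
    """Small phase-grid ensembles, N <= 4, assorted amplitudes."""
    grid = [-np.pi / 2, 0.0, np.pi / 3, np.pi]
    cases = []
    for n in (1, 2, 3, 4):
        for i, phases in enumerate(itertools.islice(itertools.product(grid, repeat=n), 12)):
            rng = np.random.default_rng(100 * n + i)
            cases.append(
                ens(
                    rng.uniform(0.1, 2.0, n),
                    rng.uniform(0.1, 2.0, n),
                    np.array(phases),
                    rng.uniform(-np.pi, np.pi, n),
                )
            )
    return cases


@pytest.mark.parametrize("e", enumerated_ensembles())
def test_measures_match_bruteforce_oracle(e):
    ref = oracle(e)
    assert m.coherence(e) == pytest.approx(ref["coherence"], abs=1e-12)
    assert m.phase_coherence(e) == pytest.approx(ref["phase"], abs=1e-12)
    assert m.amplitude_coherence(e) == pytest.approx(ref["amp"], abs=1e-12)
    if e.n_trials >= 2:
        assert m.ppc(e) == pytest.approx(ref["ppc"], abs=1e-12)
        if not np.isnan(ref["amp_meanDev"]):
            assert m.amplitude_crosscorr(e) == pytest.approx(
                ref["amp_meanDev"], abs=1e-12
            )


def test_random_phase_matches_oracle_with_shared_draws():
    # Eq.-5 structure: the oracle consumes the same per-trial uniform draws
    e = ens([1.0, 2.0, 0.5], [0.3, 1.0, 2.0], [0.1, -1.0, 2.0], [0.5, 0.2, -0.3])
    phi = np.random.default_rng(42).uniform(-np.pi, np.pi, 3)
    num = sum(e.ampA[k] * e.ampB[k] * np.exp(1j * phi[k]) for k in range(3))
    den = np.sqrt(np.sum(e.ampA**2) * np.sum(e.ampB**2))
    assert m.random_phase_coherence(e, 42) == pytest.approx(abs(num) / den, abs=1e-12)


# ---------------------------------------------------------------------------
# Hand-derived / limiting examples
# ---------------------------------------------------------------------------


class TestExamples:
    def test_self_coherence_is_one(self, rng):
        a = rng.uniform(0.1, 2, 7)
        p = rng.uniform(-np.pi, np.pi, 7)
        assert m.coherence(ens(a, a, p, p)) == pytest.approx(1.0)

    def test_two_trials_quarter_turn(self):
        e = ens([1, 1], [1, 1], [0, 0], [0, -np.pi / 2])
        assert m.coherence(e) == pytest.approx(np.sqrt(2) / 2)

    def test_single_trial_coherence_is_one(self):
        assert m.coherence(ens([2.0], [0.7], [1.0], [-2.0])) == pytest.approx(1.0)

    def test_perfect_phase_locking(self):
        e = ens([1, 2, 3], [1, 1, 1], [0.3, 1.3, -2.0], [0.3 - 1, 1.3 - 1, -3.0])
        assert m.phase_coherence(e) == pytest.approx(1.0)

    def test_antipodal_phases_cancel(self):
        e = ens([1, 1], [1, 1], [0, 0], [0, np.pi])
        assert m.phase_coherence(e) == pytest.approx(0.0, abs=1e-15)

    def test_amplitude_coherence_equality_case(self, rng):
        a = rng.uniform(0.1, 3, 9)
        assert m.amplitude_coherence(ens(a, a, a * 0, a * 0)) == pytest.approx(1.0)

    def test_amplitude_coherence_disjoint_support(self):
        assert m.amplitude_coherence(ens([1, 0], [0, 1], [0, 0], [0, 0])) == 0.0

    def test_crosscorr_modulus_of_perfect_anticorrelation(self):
        e = ens([1, 2, 3], [3, 2, 1], [0, 0, 0], [0, 0, 0])
        assert m.amplitude_crosscorr(e) == pytest.approx(1.0)

    def test_ppc_three_trials_one_quarter_turn(self):
        e = ens([1, 1, 1], [1, 1, 1], [0, 0, 0], [0, 0, np.pi / 2])
        assert m.ppc(e) == pytest.approx(1 / 3)

    def test_ppc_identical_relative_phases(self):
        e = ens([1, 1], [1, 1], [0.4, 1.0], [0.4 + 2, 1.0 + 2])
        assert m.ppc(e) == pytest.approx(1.0)

    def test_random_phase_single_trial_is_one(self):
        assert m.random_phase_coherence(
            ens([2.0], [1.0], [0.0], [0.0]), 0
        ) == pytest.approx(1.0)


# ---------------------------------------------------------------------------
# Monte-Carlo statistics (small-scale; full scale in acceptance)
# ---------------------------------------------------------------------------


def test_uniform_phase_plv_floor(rng):
    # mean PLV for 31 uniform phase differences: sqrt(pi/(4*31)) ~ 0.159
    reps, n = 5000, 31
    d = rng.uniform(-np.pi, np.pi, (reps, n))
    plvs = np.abs(np.exp(1j * d).mean(axis=1))
    se = plvs.std() / np.sqrt(reps)
    assert abs(plvs.mean() - np.sqrt(np.pi / (4 * n))) < 3 * se


def test_independent_rayleigh_amp_coherence_floor(rng):
    a, b = rng.rayleigh(1, 10000), rng.rayleigh(1, 10000)
    e = ens(a, b, np.zeros(10000), np.zeros(10000))
    assert m.amplitude_coherence(e) == pytest.approx(np.pi / 4, abs=0.01)
    assert m.amplitude_crosscorr(e) == pytest.approx(0.0, abs=0.03)


# ---------------------------------------------------------------------------
# Properties
# ---------------------------------------------------------------------------


@settings(deadline=None, max_examples=50, derandomize=True)
@given(
    scale=st.floats(0.01, 100),
    n=st.integers(2, 8),
    seed=st.integers(0, 10_000),
)
def test_positive_rescaling_of_one_channel_is_invariant(scale, n, seed):
    rng = np.random.default_rng(seed)
    e = ens(
        rng.uniform(0.1, 2, n),
        rng.uniform(0.1, 2, n),
        rng.uniform(-np.pi, np.pi, n),
        rng.uniform(-np.pi, np.pi, n),
    )
    scaled = ens(e.ampA * scale, e.ampB, e.phaseA, e.phaseB)
    assert m.coherence(scaled) == pytest.approx(m.coherence(e), rel=1e-9)
    assert m.amplitude_coherence(scaled) == pytest.approx(
        m.amplitude_coherence(e), rel=1e-9
    )
    assert m.amplitude_crosscorr(scaled) == pytest.approx(
        m.amplitude_crosscorr(e), rel=1e-9
    )
    assert m.phase_coherence(scaled) == m.phase_coherence(e)
    assert m.random_phase_coherence(scaled, seed) == pytest.approx(
        m.random_phase_coherence(e, seed), rel=1e-9
    )


@settings(deadline=None, max_examples=50, derandomize=True)
@given(n=st.integers(1, 10), seed=st.integers(0, 10_000))
def test_unit_amplitude_coherence_equals_plv(n, seed):
    rng = np.random.default_rng(seed)
    pA = rng.uniform(-np.pi, np.pi, n)
    pB = rng.uniform(-np.pi, np.pi, n)
    e = ens(np.ones(n), np.ones(n), pA, pB)
    assert m.coherence(e) == pytest.approx(m.phase_coherence(e), abs=1e-12)


@settings(deadline=None, max_examples=50, derandomize=True)
@given(n=st.integers(2, 10), seed=st.integers(0, 10_000))
def test_measures_stay_in_bounds(n, seed):
    rng = np.random.default_rng(seed)
    e = ens(
        rng.uniform(0.01, 5, n),
        rng.uniform(0.01, 5, n),
        rng.uniform(-np.pi, np.pi, n),
        rng.uniform(-np.pi, np.pi, n),
    )
    for f in (m.coherence, m.phase_coherence, m.amplitude_coherence, m.amplitude_crosscorr):
        assert 0 <= f(e) <= 1 + 1e-12
    assert -1 <= m.ppc(e) <= 1 + 1e-12


def test_coherence_with_phases_and_amps_independent_factorizes(rng):
    # C ~ C_amp * C_phase for large N when amplitudes and phases independent
    for kappa in (2.0, 5.0):
        n = 200_000
        d = rng.vonmises(0, kappa, n)
        a, b = rng.rayleigh(1, n), rng.rayleigh(1, n)
        e = ens(a, b, d, np.zeros(n))
        assert m.coherence(e) == pytest.approx(
            m.amplitude_coherence(e) * m.phase_coherence(e), abs=0.01
        )


# ---------------------------------------------------------------------------
# Errors and the spectrum-level wrapper
# ---------------------------------------------------------------------------


class TestErrors:
    def test_all_zero_amplitudes_undefined(self):
        e = ens([0, 0], [1, 1], [0, 0], [0, 0])
        for f in (m.coherence, m.amplitude_coherence):
            with pytest.raises(UndefinedMeasureError):
                f(e)

    def test_zero_variance_crosscorr_undefined(self):
        with pytest.raises(UndefinedMeasureError):
            m.amplitude_crosscorr(ens([1, 1], [1, 2], [0, 0], [0, 0]))

    def test_ppc_needs_two_trials(self):
        with pytest.raises(UndefinedMeasureError):
            m.ppc(ens([1.0], [1.0], [0.0], [0.0]))

    def test_length_mismatch(self):
        with pytest.raises(UndefinedMeasureError):
            ens([1, 1], [1], [0, 0], [0, 0])


class TestCoherenceSpectra:
    def make_spectra(self, rng, n_trials=10, n_freq=5):
        freqs = np.arange(n_freq) * 5.0
        return TrialSpectra(
            freqs=freqs,
            amplitudes=rng.uniform(0.1, 2, (n_trials, n_freq)),
            phases=rng.uniform(-np.pi, np.pi, (n_trials, n_freq)),
        )

    def test_matches_per_frequency_scalar_calls(self, rng):
        sA, sB = self.make_spectra(rng), self.make_spectra(rng)
        out = coherence_spectra(sA, sB, ["coherence", "phase", "ppc"])
        for i in range(sA.freqs.size):
            e = ens(
                sA.amplitudes[:, i], sB.amplitudes[:, i],
                sA.phases[:, i], sB.phases[:, i],
            )
            assert out["coherence"].values[i] == pytest.approx(m.coherence(e))
            assert out["phase"].values[i] == pytest.approx(m.phase_coherence(e))
            assert out["ppc"].values[i] == pytest.approx(m.ppc(e))

    def test_mismatched_grids_rejected(self, rng):
        sA = self.make_spectra(rng)
        sB = self.make_spectra(rng)
        sB.freqs = sB.freqs + 1.0
        with pytest.raises(UndefinedMeasureError):
            coherence_spectra(sA, sB)

    def test_random_phase_requires_seed(self, rng):
        sA, sB = self.make_spectra(rng), self.make_spectra(rng)
        with pytest.raises(ValueError, match="seed"):
            coherence_spectra(sA, sB, ["amp_randomPhase"])
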