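"""Synthetic BOLD: canonical HRF convolution, 1/f^a noise, SNR mixing.

A noisy run is

    bold = sqrt(sn) * (hrf_scale * HRF) (*) rpe_events + sqrt(1 - sn) * noise

with sn = SNR / (1 + SNR) and ``noise`` z-transformed 1/f^a (pink-like) noise.
The mixing weight sn is a variance share, so it enters on the
standard-deviation scale.  The convolved signal is deliberately NOT
re-standardized before mixing: the reinforcement-efficacy parameter lambda and
the per-subject HRF amplitude survive into the BOLD amplitude, which is
precisely the mechanism that couples lambda to the fitted RPE beta.  Only the
noise is z-transformed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from nilearn.glm.first_level import spm_hrf

from .design_regressors import SamplingGrid, embed_events
from .paradigms import ParticipantSpec, Schedule, participant_rng
from .rl_core import RWParams, simulate_pavlovian

__all__ = [
    "HRFKernel",
    "NoiseSpec",
    "BoldRun",
    "canonical_hrf",
    "convolve_hrf",
    "pink_noise",
    "mix",
    "simulate_bold_run",
]


@dataclass(frozen=True)
class HRFKernel:
    """Sampled canonical double-gamma HRF in SPM's native normalization
    (the sampled kernel sums to 1; peak ~0.43 at dt=2).

    ``scale`` is the per-subject amplitude multiplier (varied U(0.5, 1.5) in
    the HRF-scaling analysis, otherwise 1).
    """

    dt: float
    values: np.ndarray
    scale: float = 1.0

    @property
    def length_s(self) -> float:
        return self.dt * len(self.values)


@dataclass(frozen=True)
class NoiseSpec:
    """1/f^a exponent and signal-to-noise ratio; sn = snr/(1+snr)."""

    exponent: float
    snr: float

    @property
    def sn(self) -> float:
        return self.snr / (1.0 + self.snr)


@dataclass
class BoldRun:
    """A regularly sampled synthetic timeseries with its sampling interval."""

    values: np.ndarray
    dt: float

    @property
    def n_samples(self) -> int:
        return len(self.values)

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) * self.dt

    def to_frame(self):
        """Two-column (time_s, value) table for TSV serialization."""
        import pandas as pd

        return pd.DataFrame({"time_s": self.times, "value": self.values})


def canonical_hrf(dt: float, scale: float = 1.0, length_s: float = 32.0) -> HRFKernel:
    """SPM's canonical double-gamma HRF sampled at dt.

    SPM defaults: response gamma delay 6 s / dispersion 1, undershoot delay
    16 s / dispersion 1, undershoot ratio 1/6, onset 0, 32 s support.  The
    kernel keeps SPM's own normalization (the sampled kernel sums to 1, which
    is what MATLAB ``spm_hrf(RT)`` returns), so the simulated BOLD amplitude
    convention matches analyses built on SPM's kernel; ``scale`` and lambda
    remain pure amplitude multipliers.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    values = spm_hrf(dt, oversampling=1, time_length=length_s)
    return HRFKernel(dt=dt, values=values, scale=scale)


def convolve_hrf(timeseries, kernel: HRFKernel) -> np.ndarray:
    """Leading-aligned linear convolution truncated to the input length,
    multiplied by the kernel's amplitude scale."""
    ts = np.asarray(timeseries, dtype=float)
    return kernel.scale * np.convolve(ts, kernel.values)[: len(ts)]


def pink_noise(n: int, exponent: float, rng: np.random.Generator) -> np.ndarray:
    """Gaussian noise with power spectral density ~ 1/f^exponent, z-transformed.

    Frequency-domain synthesis: complex Gaussian Fourier coefficients with
    amplitude f^(-exponent/2), DC bin zeroed, inverse rFFT, then normalized to
    mean 0 / SD 1 exactly.
    """
    if n < 16:
        raise ValueError("n too short for spectral shaping (need >= 16)")
    if exponent < 0:
        raise ValueError("exponent must be non-negative")
    freqs = np.fft.rfftfreq(n)
    amp = np.zeros_like(freqs)
    amp[1:] = freqs[1:] ** (-exponent / 2.0)
    coeffs = amp * (rng.standard_normal(len(freqs)) + 1j * rng.standard_normal(len(freqs)))
    coeffs[0] = 0.0
    if n % 2 == 0:  # Nyquist bin must be real
        coeffs[-1] = coeffs[-1].real
    x = np.fft.irfft(coeffs, n=n)
    return (x - x.mean()) / x.std()


def mix(signal, noise, snr: float) -> np.ndarray:
    """sqrt(sn) * signal + sqrt(1 - sn) * noise with sn = snr/(1+snr).

    sn is the signal's variance share (0.66-0.8 for SNR 2-4), so the weights
    are its square roots on the amplitude scale.
    """
    signal = np.asarray(signal, dtype=float)
    noise = np.asarray(noise, dtype=float)
    if signal.shape != noise.shape:
        raise ValueError("signal and noise must have equal length")
    if snr <= 0:
        raise ValueError("snr must be positive")
    sn = snr / (1.0 + snr)
    return np.sqrt(sn) * signal + np.sqrt(1.0 - sn) * noise


def simulate_bold_run(
    spec: ParticipantSpec,
    schedule: Schedule,
    grid: SamplingGrid,
    rng: np.random.Generator | None = None,
) -> BoldRun:
    """Ground-truth noisy BOLD for one participant on one schedule.

    Composition: agent (true alpha, lambda) -> RPE impulses on the grid ->
    HRF convolution at the participant's hrf_scale -> Eq.-style SNR mixing
    with that participant's 1/f^a noise.  The noise stream is the
    participant's stream 1 unless an explicit rng is supplied.
    """
    if schedule.n_trials != grid.n_trials:
        raise ValueError("schedule and grid disagree on n_trials")
    if rng is None:
        rng = participant_rng(spec, stream=1)
    trace = simulate_pavlovian(
        schedule.outcomes[:, 0], RWParams(alpha=spec.alpha, lam=spec.lam)
    )
    kernel = canonical_hrf(grid.dt, scale=spec.hrf_scale)
    signal = convolve_hrf(embed_events(trace.rpes, grid), kernel)
    noise = pink_noise(grid.n_samples, spec.noise_exponent, rng)
    return BoldRun(values=mix(signal, noise, spec.snr), dt=grid.dt)
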