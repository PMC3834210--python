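"""Truncated Fourier representation of band-limited periodic signals.

A real signal of period ``T`` samples is represented by its complex Fourier
coefficients ``c_k`` for harmonics ``k = 0..F`` (negative harmonics are
implied by conjugate symmetry):

    s(t) = c_0 + 2 * Re( sum_{k=1..F} c_k exp(2i pi k t / T) )

with the convention ``c_k = (1/T) sum_t s(t) exp(-2i pi k t / T)``, so a
pure cosine of unit amplitude has ``|c_1| = 1/2``.  Under this
representation a circular time delay is a per-harmonic phase rotation,
which is what makes delays continuous, differentiable parameters in the
demixing model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class FourierSeries:
    """Truncated Fourier series: harmonics 0..F of a real periodic signal.

    Parameters
    ----------
    order : int
        Highest retained harmonic F >= 1.
    period : float
        Fundamental period in samples (the trial window length).
    coeffs : complex ndarray, shape (F + 1,)
        ``coeffs[k]`` is c_k; ``coeffs[0]`` must be real (it is forced).
    """

    order: int
    period: float
    coeffs: np.ndarray

    def __post_init__(self) -> None:
        self.coeffs = np.asarray(self.coeffs, dtype=complex).copy()
        if self.order < 1:
            raise ValueError("order must be >= 1")
        if self.coeffs.shape != (self.order + 1,):
            raise ValueError(f"expected {self.order + 1} coefficients, got {self.coeffs.shape}")
        self.coeffs[0] = self.coeffs[0].real  # DC of a real signal

    def l2_norm(self, n_samples: int | None = None) -> float:
        """L2 norm of the evaluated series over one period of T samples.

        By Parseval, ``sum_t s(t)^2 = T * (c_0^2 + 2 sum_{k>=1} |c_k|^2)``.
        """
        t = self.period if n_samples is None else n_samples
        power = self.coeffs[0].real ** 2 + 2.0 * np.sum(np.abs(self.coeffs[1:]) ** 2)
        return float(np.sqrt(t * power))


def truncated_fourier_fit(signal: np.ndarray, order: int) -> FourierSeries:
    """Project a real series onto harmonics 0..order of its own period.

    The result is the discrete Fourier projection: reconstruction error is
    exactly the energy carried by the discarded harmonics.

    Raises
    ------
    ValueError
        If the series is shorter than ``2 * order + 1`` samples (the
        harmonics would alias).
    """
    signal = np.asarray(signal, dtype=float)
    t = signal.shape[-1]
    if t < 2 * order + 1:
        raise ValueError(f"order {order} needs at least {2 * order + 1} samples, got {t}")
    spectrum = np.fft.rfft(signal) / t
    return FourierSeries(order=order, period=t, coeffs=spectrum[: order + 1])


def evaluate(series: FourierSeries, n_samples: int) -> np.ndarray:
    """Evaluate the series on a uniform grid of ``n_samples`` points per period."""
    if n_samples < 2:
        raise ValueError("n_samples must be >= 2")
    k = np.arange(series.order + 1)
    t = np.arange(n_samples) * (series.period / n_samples)
    phase = np.exp(2j * np.pi * np.outer(t, k) / series.period)
    values = phase @ series.coeffs
    return series.coeffs[0].real + 2.0 * (values - series.coeffs[0]).real


def apply_delay(series: FourierSeries, tau: float) -> FourierSeries:
    """Delay the series by ``tau`` samples (circularly over the period).

    Multiplies each harmonic by ``exp(-2i pi k tau / T)``, so that
    ``evaluate(apply_delay(s, tau))[t] == evaluate(s)[t - tau]`` with
    circular, band-limited interpolation for fractional ``tau``.
    """
    k = np.arange(series.order + 1)
    rot = np.exp(-2j * np.pi * k * tau / series.period)
    return FourierSeries(order=series.order, period=series.period, coeffs=series.coeffs * rot)


def coeff_matrix(data: np.ndarray, order: int) -> np.ndarray:
    """Harmonic coefficients (rows x harmonics 0..order) of each data row."""
    data = np.atleast_2d(np.asarray(data, dtype=float))
    t = data.shape[1]
    if t < 2 * order + 1:
        raise ValueError(f"order {order} needs at least {2 * order + 1} samples, got {t}")
    return np.fft.rfft(data, axis=1)[:, : order + 1] / t


def synthesize(coeffs: np.ndarray, n_samples: int, period: float | None = None) -> np.ndarray:
    """Evaluate rows of harmonic coefficients back into the time domain."""
    coeffs = np.atleast_2d(np.asarray(coeffs, dtype=complex))
    period = float(n_samples) if period is None else period
    k = np.arange(coeffs.shape[1])
    t = np.arange(n_samples) * (period / n_samples)
    phase = np.exp(2j * np.pi * np.outer(k, t) / period)
    values = coeffs @ phase
    return coeffs[:, :1].real + 2.0 * (values - coeffs[:, :1]).real
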