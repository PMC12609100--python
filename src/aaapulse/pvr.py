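"""Viscoelastic blood-pressure to pulse-volume-recording (PVR) transfer functions.

A cuff PVR signal is the arterial pressure waveform filtered by the
artery–tissue–cuff interface. At the brachial site the interface behaves as a
standard linear solid (spring ``E_B1`` and dashpot ``eta_B`` in parallel, in
series with spring ``E_B2``):

    H_B(s) = (E_B2 + eta_B s) / (E_B1 E_B2 + (E_B1 + E_B2) eta_B s)

and at the tibial site as a Voigt body (spring ``E_T`` parallel dashpot
``eta_T``):

    H_T(s) = 1 / (E_T + eta_T s)

Both are applied per Fourier harmonic of the periodic record (the data are
steady-state periodic, so exact frequency-domain multiplication is the
faithful realisation); a bilinear-transform IIR variant is provided for
streaming use and agrees with the harmonic path on periodic inputs.

PVR amplitudes are in arbitrary volume-like units; no re-normalisation is
performed here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import lfilter

from .hemodynamics import PeriodicSignal, Waveform

__all__ = [
    "ViscoelasticParams",
    "brachial_transfer",
    "tibial_transfer",
    "brachial_pvr",
    "tibial_pvr",
    "apply_transfer_periodic",
    "brachial_pvr_iir",
    "tibial_pvr_iir",
]


@dataclass
class ViscoelasticParams:
    """Elastic/damping constants of the brachial (SLS) and tibial (Voigt) interfaces.

    Units are normalised (pressure per PVR unit); absolute PVR scale is
    arbitrary.
    """

    e_b1: float = 1.0
    e_b2: float = 4.0
    eta_b: float = 0.2
    e_t: float = 1.0
    eta_t: float = 0.1

    def __post_init__(self) -> None:
        for f in ("e_b1", "e_b2", "eta_b", "e_t", "eta_t"):
            if getattr(self, f) <= 0:
                raise ValueError(f"{f} must be strictly positive")

    def as_array(self) -> np.ndarray:
        return np.array([self.e_b1, self.e_b2, self.eta_b, self.e_t, self.eta_t])

    @classmethod
    def from_array(cls, a) -> "ViscoelasticParams":
        return cls(*(float(x) for x in a))


def brachial_transfer(params: ViscoelasticParams, omega) -> np.ndarray:
    """H_B(j omega) of the standard-linear-solid brachial interface."""
    s = 1j * np.asarray(omega, dtype=float)
    return (params.e_b2 + params.eta_b * s) / (
        params.e_b1 * params.e_b2 + (params.e_b1 + params.e_b2) * params.eta_b * s
    )


def tibial_transfer(params: ViscoelasticParams, omega) -> np.ndarray:
    """H_T(j omega) of the Voigt tibial interface (strictly low-pass)."""
    s = 1j * np.asarray(omega, dtype=float)
    return 1.0 / (params.e_t + params.eta_t * s)


def apply_transfer_periodic(sig: PeriodicSignal, transfer, params: ViscoelasticParams) -> PeriodicSignal:
    """Apply a transfer function to the harmonic form of a periodic signal."""
    h0 = complex(transfer(params, 0.0))
    hk = transfer(params, sig.omega)
    return PeriodicSignal(mean=sig.mean * h0.real, coeffs=sig.coeffs * hk, period=sig.period)


def _apply_fft(p: Waveform, transfer, params: ViscoelasticParams, site_kind: str) -> Waveform:
    if p.periodic is not None:
        out = apply_transfer_periodic(p.periodic, transfer, params)
        t = np.arange(len(p.samples)) / p.fs
        return Waveform(site=p.site, kind="pvr", samples=out.sample(t), fs=p.fs, periodic=out)
    n = len(p.samples)
    freqs = np.fft.rfftfreq(n, d=1.0 / p.fs)
    spec = np.fft.rfft(p.samples) * transfer(params, 2.0 * np.pi * freqs)
    return Waveform(site=p.site, kind="pvr", samples=np.fft.irfft(spec, n), fs=p.fs)


def brachial_pvr(p: Waveform, params: ViscoelasticParams, fs: float | None = None) -> Waveform:
    """Brachial PVR from a periodic brachial pressure record."""
    return _apply_fft(p, brachial_transfer, params, "brachial")


def tibial_pvr(p: Waveform, params: ViscoelasticParams, fs: float | None = None) -> Waveform:
    """Tibial PVR from a periodic tibial pressure record."""
    return _apply_fft(p, tibial_transfer, params, "tibial")


# -- causal IIR alternative (bilinear transform), for streaming input --------


def _bilinear_apply(b, a, p: Waveform, warmup_periods: int = 6) -> Waveform:
    n = len(p.samples)
    x = np.tile(p.samples, warmup_periods + 1)
    y = lfilter(b, a, x)[-n:]
    return Waveform(site=p.site, kind="pvr", samples=y, fs=p.fs)


def brachial_pvr_iir(p: Waveform, params: ViscoelasticParams) -> Waveform:
    """Causal discretisation of the brachial SLS transfer (bilinear transform)."""
    from scipy.signal import bilinear

    num = [params.eta_b, params.e_b2]
    den = [(params.e_b1 + params.e_b2) * params.eta_b, params.e_b1 * params.e_b2]
    b, a = bilinear(num, den, fs=p.fs)
    return _bilinear_apply(b, a, p)


def tibial_pvr_iir(p: Waveform, params: ViscoelasticParams) -> Waveform:
    """Causal discretisation of the tibial Voigt transfer (bilinear transform)."""
    from scipy.signal import bilinear

    b, a = bilinear([1.0], [params.eta_t, params.e_t], fs=p.fs)
    return _bilinear_apply(b, a, p)
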