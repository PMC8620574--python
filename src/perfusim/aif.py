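"""Arterial input function (plasma tracer concentration C_p(t))."""

from __future__ import annotations

from pathlib import Path

import numpy as np


class AIFCurve:
    """Base interface: callable t (s) -> C_p (mol/m^3), nonnegative."""

    def __call__(self, t):  # pragma: no cover - interface
        raise NotImplementedError

    #: optional list of (coefficient, decay rate) pairs when the curve is a
    #: finite sum of exponentials C_p(t) = sum c_j exp(-lambda_j t)
    exponential_terms: list[tuple[float, float]] | None = None


class BiexponentialAIF(AIFCurve):
    """Bolus-plus-washout stand-in: C_p = A (exp(-k_d t) - exp(-k_r t)).

    ``k_rise > k_decay`` gives C_p(0) = 0, a peak near
    ln(k_rise/k_decay)/(k_rise - k_decay), then slow washout.
    """

    def __init__(self, amplitude: float = 1200.0,
                 k_rise: float = 1.0 / 30.0, k_decay: float = 1.0 / 8000.0):
        if amplitude < 0:
            raise ValueError("amplitude must be nonnegative")
        if not k_rise > k_decay >= 0:
            raise ValueError("require k_rise > k_decay >= 0")
        self.amplitude = amplitude
        self.k_rise = k_rise
        self.k_decay = k_decay
        self.exponential_terms = [(amplitude, k_decay), (-amplitude, k_rise)]

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        out = self.amplitude * (np.exp(-self.k_decay * t) - np.exp(-self.k_rise * t))
        return np.maximum(out, 0.0)


class ZeroAIF(AIFCurve):
    exponential_terms: list[tuple[float, float]] = []

    def __call__(self, t):
        return np.zeros_like(np.asarray(t, dtype=float))


class ConstantAIF(AIFCurve):
    def __init__(self, value: float):
        if value < 0:
            raise ValueError("C_p must be nonnegative")
        self.value = value
        self.exponential_terms = [(value, 0.0)]

    def __call__(self, t):
        return np.full_like(np.asarray(t, dtype=float), self.value)


class TabulatedAIF(AIFCurve):
    """Piecewise-linear interpolation of a (t, C_p) table; clamped outside."""

    exponential_terms = None

    def __init__(self, times: np.ndarray, values: np.ndarray):
        times = np.asarray(times, dtype=float)
        values = np.asarray(values, dtype=float)
        if times.ndim != 1 or times.shape != values.shape or len(times) < 2:
            raise ValueError("need matching 1-D arrays with >= 2 samples")
        if np.any(np.diff(times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(values < 0):
            raise ValueError("C_p must be nonnegative")
        self.times = times
        self.values = values

    def __call__(self, t):
        return np.interp(np.asarray(t, dtype=float), self.times, self.values)

    @classmethod
    def from_csv(cls, path: str | Path) -> "TabulatedAIF":
        data = np.loadtxt(path, delimiter=",", skiprows=1)
        return cls(data[:, 0], data[:, 1])

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("t_s,Cp_mol_per_m3\n")
            for t, c in zip(self.times, self.values):
                fh.write(f"{float(t)!r},{float(c)!r}\n")
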