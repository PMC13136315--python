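"""Multi-Gaussian fitting of capillary-electrophoresis traces.

Barcoding products of different lengths separate on a TapeStation-style
capillary gel into peaks spaced one letter (20 bp by default) apart.  The
trace is modelled as a sum of ``K = R + 1`` Gaussian components

    f(l) = Σ_k A_k · exp(-(l - μ_k)² / (2 σ_k²))

one per product with 1..R letters plus one extra component for a single
off-target addition.  In *constrained* mode the extra component is tied to
the full-length one (μ_{R+1} = μ_R + letter_bp and σ_{R+1} = σ_R), which is
how an upper bound on an invisible over-length peak is extracted; in
unconstrained mode all parameters float.  Species proportions are taken as
peak areas A_k·σ_k normalized to 1 (amplitude-proportional mode available).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional

import numpy as np
import pandas as pd
from scipy import optimize

__all__ = [
    "TraceError",
    "Trace",
    "PeakModel",
    "synth_trace",
    "fit_multi_gaussian",
    "fractions_from_fit",
]

_SQRT2PI = float(np.sqrt(2.0 * np.pi))


class TraceError(ValueError):
    """Invalid trace data or fit configuration."""


@dataclass
class Trace:
    """A length-vs-intensity electropherogram curve."""

    lengths: np.ndarray
    intensities: np.ndarray

    def __post_init__(self) -> None:
        self.lengths = np.asarray(self.lengths, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.lengths.shape != self.intensities.shape:
            raise TraceError("lengths and intensities must have equal shape")
        if self.lengths.size < 10:
            raise TraceError("trace must have >= 10 points")
        if np.any(np.diff(self.lengths) <= 0):
            raise TraceError("lengths must be strictly increasing")
        if np.any(self.intensities < 0):
            raise TraceError("intensities must be non-negative")

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            {"length_bp": self.lengths, "intensity": self.intensities}
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "Trace":
        df = pd.read_csv(path)
        for col in ("length_bp", "intensity"):
            if col not in df.columns:
                raise TraceError(f"trace CSV missing required column {col!r}")
        return cls(df["length_bp"].to_numpy(), df["intensity"].to_numpy())


@dataclass
class PeakModel:
    """Fitted Gaussian components, ordered by barcode length in letters.

    ``peak_lengths[k]`` is the letter count the k-th component represents
    (1 .. R+1 for a default fit).
    """

    amplitudes: np.ndarray
    means: np.ndarray
    sigmas: np.ndarray
    peak_lengths: tuple[int, ...]
    residual: float
    converged: bool
    constrained: bool
    baseline: float = 0.0

    def __post_init__(self) -> None:
        self.amplitudes = np.asarray(self.amplitudes, dtype=float)
        self.means = np.asarray(self.means, dtype=float)
        self.sigmas = np.asarray(self.sigmas, dtype=float)
        if not (
            len(self.amplitudes) == len(self.means) == len(self.sigmas)
            == len(self.peak_lengths)
        ):
            raise TraceError("component arrays must have equal length >= 1")
        if len(self.amplitudes) < 1:
            raise TraceError("need >= 1 component")

    def evaluate(self, lengths: np.ndarray) -> np.ndarray:
        lengths = np.asarray(lengths, dtype=float)
        out = np.full(lengths.shape, self.baseline)
        for a, mu, s in zip(self.amplitudes, self.means, self.sigmas):
            out = out + a * np.exp(-((lengths - mu) ** 2) / (2.0 * s ** 2))
        return out


def synth_trace(
    fractions: Mapping[int, float],
    base_bp: float = 50.0,
    letter_bp: float = 20.0,
    sigma: float = 5.0,
    noise_sd: float = 0.0,
    grid: Optional[tuple[float, float, float]] = None,
    seed: Optional[int] = None,
    total_intensity: float = 1000.0,
) -> Trace:
    """Synthesize an electropherogram from barcode-length proportions.

    Each species with ``k`` letters contributes a Gaussian centred at
    ``base_bp + k * letter_bp`` whose *area* is proportional to its
    fraction.  Optional iid Gaussian noise (``noise_sd`` relative to the
    maximum clean intensity) is added and clipped at zero.
    """
    if not fractions:
        raise TraceError("fractions must be non-empty")
    total = sum(fractions.values())
    if abs(total - 1.0) > 1e-6:
        raise TraceError(f"fractions must sum to 1, got {total}")
    if sigma <= 0:
        raise TraceError("sigma must be positive")
    if grid is None:
        lo = base_bp + min(fractions) * letter_bp - 6.0 * sigma
        hi = base_bp + max(fractions) * letter_bp + 6.0 * sigma
        grid = (max(lo, 0.0), hi, 1.0)
    start, stop, step = grid
    lengths = np.arange(start, stop + step / 2, step)
    clean = np.zeros_like(lengths)
    for k, frac in fractions.items():
        mu = base_bp + k * letter_bp
        amp = total_intensity * frac / (sigma * _SQRT2PI)
        clean += amp * np.exp(-((lengths - mu) ** 2) / (2.0 * sigma ** 2))
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        clean = clean + rng.normal(0.0, noise_sd * clean.max(), size=clean.shape)
        clean = np.clip(clean, 0.0, None)
    return Trace(lengths, clean)


def _estimate_sigma(trace: Trace) -> float:
    """Half-max width of the dominant peak; crude but reproducible."""
    y = trace.intensities
    i = int(np.argmax(y))
    half = y[i] / 2.0
    left = i
    while left > 0 and y[left] > half:
        left -= 1
    right = i
    while right < len(y) - 1 and y[right] > half:
        right += 1
    fwhm = trace.lengths[right] - trace.lengths[left]
    if fwhm <= 0:
        return max((trace.lengths[-1] - trace.lengths[0]) / 20.0, 1.0)
    return float(fwhm / 2.355)


def fit_multi_gaussian(
    trace: Trace,
    R: int,
    constrained: bool = True,
    letter_bp: float = 20.0,
    base_bp: Optional[float] = None,
    baseline: bool = False,
) -> PeakModel:
    """Fit ``K = R + 1`` Gaussian components to a trace by least squares.

    Parameters
    ----------
    trace
        The electropherogram to fit.
    R
        Number of barcoding rounds; components represent products with
        1..R+1 letters.
    constrained
        Tie the over-length component to the full-length one
        (μ_{R+1} = μ_R + letter_bp, σ_{R+1} = σ_R).  Use this when the
        over-length peak is invisible and only an upper bound is wanted.
    base_bp
        Primer length in bp (peak k sits near ``base_bp + k*letter_bp``).
        When omitted it is inferred by anchoring the strongest peak of the
        trace at the full-length (R-letter) position.
    baseline
        Include a constant background offset in the model.
    """
    if R < 1:
        raise TraceError(f"R must be >= 1, got {R}")
    K = R + 1
    y = trace.intensities
    x = trace.lengths
    if base_bp is None:
        base_bp = float(x[np.argmax(y)] - R * letter_bp)
    mu0 = np.array([base_bp + k * letter_bp for k in range(1, K + 1)])
    if mu0[0] < x[0] - letter_bp or mu0[-2] > x[-1] + letter_bp:
        raise TraceError("trace does not cover the expected peak positions")
    s0 = _estimate_sigma(trace)
    a0 = np.clip(np.interp(mu0, x, y), y.max() * 1e-3, None)

    n_mu = R if constrained else K
    n_sig = R if constrained else K

    def unpack(p: np.ndarray):
        amps = p[:K]
        mus = p[K:K + n_mu]
        sigs = p[K + n_mu:K + n_mu + n_sig]
        off = p[-1] if baseline else 0.0
        if constrained:
            mus = np.append(mus, mus[-1] + letter_bp)
            sigs = np.append(sigs, sigs[-1])
        return amps, mus, sigs, off

    def residuals(p: np.ndarray) -> np.ndarray:
        amps, mus, sigs, off = unpack(p)
        model = np.full_like(x, off)
        for a, mu, s in zip(amps, mus, sigs):
            model = model + a * np.exp(-((x - mu) ** 2) / (2.0 * s ** 2))
        return model - y

    x0 = np.concatenate([
        a0,
        mu0[:n_mu],
        np.full(n_sig, s0),
        [0.0] if baseline else [],
    ])
    span = float(x[-1] - x[0])
    lower = np.concatenate([
        np.zeros(K),
        np.full(n_mu, x[0] - letter_bp),
        np.full(n_sig, 1e-3),
        [-np.inf] if baseline else [],
    ])
    upper = np.concatenate([
        np.full(K, np.inf),
        np.full(n_mu, x[-1] + letter_bp),
        np.full(n_sig, span),
        [np.inf] if baseline else [],
    ])
    sol = optimize.least_squares(
        residuals, x0=x0, bounds=(lower, upper), xtol=1e-12, ftol=1e-12
    )
    amps, mus, sigs, off = unpack(sol.x)
    if np.any(amps < 0):  # bounds prevent this, but guard the contract
        warnings.warn("negative fitted amplitude clipped to 0")
        amps = np.clip(amps, 0.0, None)
    if not sol.success:
        warnings.warn("multi-Gaussian fit did not converge")
    return PeakModel(
        amplitudes=amps,
        means=mus,
        sigmas=sigs,
        peak_lengths=tuple(range(1, K + 1)),
        residual=float(np.sqrt(2.0 * sol.cost)),
        converged=bool(sol.success),
        constrained=constrained,
        baseline=float(off),
    )


def fractions_from_fit(model: PeakModel, mode: str = "area") -> dict[int, float]:
    """Barcode-length proportions from fitted components.

    ``mode='area'`` (default) weights each component by A_k·σ_k, i.e. by its
    integrated signal; ``mode='amplitude'`` uses A_k alone.  Output is
    normalized to sum to 1.
    """
    if mode == "area":
        weights = model.amplitudes * model.sigmas
    elif mode == "amplitude":
        weights = np.array(model.amplitudes, dtype=float)
    else:
        raise TraceError(f"unknown fraction mode {mode!r}")
    total = weights.sum()
    if total <= 0:
        raise TraceError("all fitted components have zero weight")
    return {
        k: float(w / total) for k, w in zip(model.peak_lengths, weights)
    }
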