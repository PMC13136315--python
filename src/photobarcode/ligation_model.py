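"""Stochastic model of on/off-target letter addition.

Each of the ``R`` barcoding rounds consists of ``n_L`` letter-addition
reactions, one per letter, each under its own illumination pattern.  In the
one reaction that targets a given molecule's region, the intended letter is
added with probability ``d`` (on-target photocleavage + ligation).  In each
of the other ``n_L - 1`` reactions the molecule may still pick up a letter
with probability ``c`` (off-target photocleavage from stray or scattered
light).  All reactions are independent, so the barcode length ``L`` — the
total number of letters added — is the sum of two binomials:

    L = Binomial(R, d) + Binomial((n_L - 1) R, c)

whose convolution gives the closed-form probability

    P(L = N) = Σ_k C(R, k) d^k (1-d)^(R-k)
                 · C((n_L-1)R, N-k) c^(N-k) (1-c)^((n_L-1)R-(N-k))

with ``k`` (the on-target count) running from ``max(0, N - (n_L-1)R)`` to
``min(R, N)``.  Inverting this model against observed barcode-length
fractions yields estimates of ``d`` and ``c``.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy import optimize, special

from .codebook import Codeword

__all__ = [
    "LigationError",
    "LigationParams",
    "LengthDistribution",
    "MoleculeOutcome",
    "DCEstimate",
    "length_pmf",
    "length_distribution",
    "estimate_dc",
    "simulate_molecules",
    "length_histogram",
]


class LigationError(ValueError):
    """Invalid ligation-model parameters or inputs."""


@dataclass(frozen=True)
class LigationParams:
    """Model parameters.

    Attributes
    ----------
    d
        Per-round on-target letter-addition probability.
    c
        Per-reaction off-target letter-addition probability.
    n_L
        Number of distinct letters (reactions) per round.
    R
        Number of barcoding rounds.
    """

    d: float
    c: float
    n_L: int
    R: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.d <= 1.0:
            raise LigationError(f"d must be in [0, 1], got {self.d}")
        if not 0.0 <= self.c <= 1.0:
            raise LigationError(f"c must be in [0, 1], got {self.c}")
        if self.n_L < 1:
            raise LigationError(f"n_L must be >= 1, got {self.n_L}")
        if self.R < 1:
            raise LigationError(f"R must be >= 1, got {self.R}")

    @property
    def max_length(self) -> int:
        return self.n_L * self.R


@dataclass
class LengthDistribution:
    """Barcode-length pmf over N = 0 .. n_L * R."""

    pmf: dict[int, float]

    def __post_init__(self) -> None:
        total = sum(self.pmf.values())
        if any(p < -1e-15 for p in self.pmf.values()) or abs(total - 1.0) > 1e-9:
            raise LigationError("pmf must be non-negative and sum to 1")

    def __getitem__(self, n: int) -> float:
        return self.pmf.get(n, 0.0)


@dataclass(frozen=True)
class MoleculeOutcome:
    """One simulated molecule's barcode and its event counts."""

    barcode: tuple[int, ...]
    on_target_count: int
    off_target_count: int

    def __post_init__(self) -> None:
        if len(self.barcode) != self.on_target_count + self.off_target_count:
            raise LigationError("barcode length must equal k_on + k_off")

    @property
    def length(self) -> int:
        return len(self.barcode)


def _binom_pmf(n: int, p: float) -> np.ndarray:
    """Binomial pmf over 0..n; direct product form (stable for tiny p)."""
    k = np.arange(n + 1)
    return special.comb(n, k) * p ** k * (1.0 - p) ** (n - k)


def _pmf_vector(params: LigationParams) -> np.ndarray:
    """Full pmf over 0..n_L*R via binomial convolution."""
    on = _binom_pmf(params.R, params.d)
    off = _binom_pmf((params.n_L - 1) * params.R, params.c)
    return np.convolve(on, off)


def length_distribution(params: LigationParams) -> LengthDistribution:
    """Closed-form barcode-length distribution for the given parameters."""
    vec = _pmf_vector(params)
    return LengthDistribution({n: float(p) for n, p in enumerate(vec)})


def length_pmf(N: int, params: LigationParams) -> float:
    """Probability of ending up with a barcode of exactly ``N`` letters.

    Returns 0 outside the support ``0 <= N <= n_L * R``.
    """
    if N < 0 or N > params.max_length:
        return 0.0
    return float(_pmf_vector(params)[N])


@dataclass
class DCEstimate:
    """Result of inverting the length model for (d, c)."""

    d: float
    c: float
    residual: float
    converged: bool
    fitted_lengths: tuple[int, ...]

    @property
    def params(self) -> "LigationParams":
        raise AttributeError("use .as_params(n_L, R)")

    def as_params(self, n_L: int, R: int) -> LigationParams:
        return LigationParams(self.d, self.c, n_L, R)


def estimate_dc(
    observed: Mapping[int, float],
    n_L: int,
    R: int,
    lengths_to_fit: Optional[Sequence[int]] = None,
) -> DCEstimate:
    """Estimate (d, c) from observed barcode-length fractions.

    Minimizes the squared deviation between the closed-form pmf and the
    observed fractions at the chosen lengths, with both parameters bounded
    to [0, 1].  A 5×5 grid of starting points guards against local minima;
    ties are broken by lowest residual, then lowest ``c``.

    Parameters
    ----------
    observed
        Mapping barcode length (letters) → observed fraction.  When a length
        is only bounded from above (an undetectable gel band), the bound is
        fit as an equality.
    lengths_to_fit
        Subset of observed lengths to fit; defaults to all of them.  At
        least two are required since the model has two free parameters.
    """
    lengths = tuple(sorted(lengths_to_fit if lengths_to_fit is not None else observed))
    if len(lengths) < 2:
        raise LigationError(
            "need >= 2 observed lengths to identify both d and c"
        )
    missing = [n for n in lengths if n not in observed]
    if missing:
        raise LigationError(f"lengths {missing} not present in observations")
    targets = np.array([observed[n] for n in lengths], dtype=float)
    if np.any((targets < 0) | (targets > 1)):
        raise LigationError("observed fractions must lie in [0, 1]")

    def residuals(x: np.ndarray) -> np.ndarray:
        vec = _pmf_vector(LigationParams(x[0], x[1], n_L, R))
        model = np.array([vec[n] if n < len(vec) else 0.0 for n in lengths])
        return model - targets

    best = None
    grid = np.linspace(0.1, 0.9, 5)
    for d0 in grid:
        for c0 in grid:
            sol = optimize.least_squares(
                residuals, x0=[d0, c0], bounds=([0.0, 0.0], [1.0, 1.0]),
                xtol=1e-14, ftol=1e-14, gtol=1e-14,
            )
            key = (round(sol.cost, 15), round(sol.x[1], 12))
            if best is None or key < best[0]:
                best = (key, sol)
    sol = best[1]
    return DCEstimate(
        d=float(sol.x[0]),
        c=float(sol.x[1]),
        residual=float(np.sqrt(2.0 * sol.cost)),
        converged=bool(sol.success),
        fitted_lengths=lengths,
    )


def simulate_molecules(
    params: LigationParams,
    target: Codeword | Sequence[int],
    n_molecules: int,
    seed: Optional[int] = None,
    blocking: bool = False,
) -> list[MoleculeOutcome]:
    """Draw per-molecule barcodes from the on/off-target process.

    Per round, the ``n_L`` reactions run in ascending letter-id order.  The
    reaction matching the target codeword's digit appends that letter with
    probability ``d``; each other reaction appends its own letter with
    probability ``c``.  Rounds are independent by default (a failed ligation
    does not block later rounds), which matches the closed-form length
    distribution.

    With ``blocking=True``, all additions after the first failed on-target
    reaction are suppressed (an unphotocleaved terminus blocks extension).
    This mode deliberately does NOT follow the closed form; it exists to
    probe sensitivity to the independence assumption.
    """
    digits = target.digits if isinstance(target, Codeword) else tuple(target)
    if len(digits) != params.R:
        raise LigationError(
            f"target codeword length {len(digits)} != R={params.R}"
        )
    if any(not 1 <= d <= params.n_L for d in digits):
        raise LigationError("target digits must be letter ids 1..n_L")
    if n_molecules < 1:
        raise LigationError("n_molecules must be >= 1")
    rng = np.random.default_rng(seed)
    n = n_molecules
    on = rng.random((n, params.R)) < params.d
    off = rng.random((n, params.R, max(params.n_L - 1, 1))) < params.c
    if params.n_L == 1:
        off = np.zeros((n, params.R, 0), dtype=bool)

    # per (round, reaction in schedule order): (letter_id, on_target?, hit column)
    columns: list[tuple[int, bool, np.ndarray]] = []
    for rnd in range(params.R):
        others = [lid for lid in range(1, params.n_L + 1) if lid != digits[rnd]]
        j = 0
        for lid in range(1, params.n_L + 1):
            if lid == digits[rnd]:
                columns.append((lid, True, on[:, rnd]))
            else:
                columns.append((lid, False, off[:, rnd, j]))
                j += 1
        del others

    if blocking:
        # first failed on-target reaction truncates everything after it
        fail_round = np.where(
            on.all(axis=1), params.R, np.argmin(on, axis=1)
        )
    outcomes: list[MoleculeOutcome] = []
    per_round = params.n_L
    for i in range(n):
        barcode: list[int] = []
        k_on = 0
        k_off = 0
        for idx, (lid, is_on, hits) in enumerate(columns):
            rnd = idx // per_round
            if blocking and rnd > fail_round[i]:
                break
            if blocking and rnd == fail_round[i] and not is_on:
                # reactions after the failed targeted one in the same round
                target_pos = digits[rnd] - 1
                if idx % per_round > target_pos:
                    continue
            if hits[i]:
                barcode.append(lid)
                if is_on:
                    k_on += 1
                else:
                    k_off += 1
        outcomes.append(MoleculeOutcome(tuple(barcode), k_on, k_off))
    return outcomes


def length_histogram(outcomes: Sequence[MoleculeOutcome]) -> dict[int, float]:
    """Normalized empirical barcode-length distribution."""
    if not outcomes:
        raise LigationError("need >= 1 outcome")
    counts = Counter(o.length for o in outcomes)
    total = len(outcomes)
    return {n: counts[n] / total for n in sorted(counts)}
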