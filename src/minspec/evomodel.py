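"""Amino-acid substitution model machinery.

Implements a general time-reversible amino-acid model of the ``exchangeability
matrix x stationary frequencies`` form, with the Jones-Taylor-Thornton (JTT)
empirical exchangeabilities shipped as package data, discrete-gamma
among-site rate variation, and transition probabilities computed by
eigendecomposition of the reversibility-symmetrized generator.

Conventions
-----------
* State order is the PAML convention ``ARNDCQEGHILKMFPSTWYV``; every matrix
  in the package uses this ordering.
* The generator ``Q`` is normalized to one expected substitution per site
  per unit branch length at stationarity.
* Discrete-gamma categories are equal-probability bins of a mean-1 gamma
  distribution; each category rate is the conditional mean of its bin
  (the mean method), with the bin median available as an alternative.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
from scipy.special import gammainc
from scipy.stats import gamma as gamma_dist

__all__ = [
    "AMINO_ACIDS",
    "AA_INDEX",
    "MISSING_SYMBOLS",
    "AminoAcidAlphabet",
    "SubstitutionModel",
    "TransitionMatrix",
    "jtt_exchangeabilities",
    "jtt_frequencies",
    "build_substitution_model",
    "jtt_model",
    "discretize_gamma",
    "transition_matrix",
]

#: Canonical one-letter codes in the fixed package-wide (PAML) order.
AMINO_ACIDS: str = "ARNDCQEGHILKMFPSTWYV"

#: Map from one-letter code to row/column index.
AA_INDEX: dict[str, int] = {a: i for i, a in enumerate(AMINO_ACIDS)}

#: Symbols treated as missing data (uninformative partial likelihood).
MISSING_SYMBOLS: frozenset[str] = frozenset({"-", "X", "?", ".", "*", "B", "Z", "J", "U", "O"})

N_STATES = 20


@dataclass(frozen=True)
class AminoAcidAlphabet:
    """The 20-state amino-acid alphabet with its fixed ordering."""

    states: str = AMINO_ACIDS
    missing: frozenset[str] = MISSING_SYMBOLS

    def index(self, symbol: str) -> int:
        """Return the state index of ``symbol``, or -1 for missing data."""
        s = symbol.upper()
        if s in AA_INDEX:
            return AA_INDEX[s]
        if s in self.missing:
            return -1
        raise ValueError(f"unknown residue symbol {symbol!r}")

    def encode(self, sequence: str) -> np.ndarray:
        """Encode a sequence as int8 indices; missing data becomes -1."""
        return np.fromiter((self.index(c) for c in sequence), dtype=np.int8, count=len(sequence))


ALPHABET = AminoAcidAlphabet()


def _load_jtt() -> dict:
    with resources.files("minspec.data").joinpath("jtt.json").open() as fh:
        return json.load(fh)


_JTT_CACHE: dict | None = None


def _jtt() -> dict:
    global _JTT_CACHE
    if _JTT_CACHE is None:
        _JTT_CACHE = _load_jtt()
        if list("".join(_JTT_CACHE["order"])) != list(AMINO_ACIDS):
            raise RuntimeError("packaged JTT table is not in the canonical state order")
    return _JTT_CACHE


def jtt_exchangeabilities() -> np.ndarray:
    """The published JTT symmetric exchangeability matrix (zero diagonal)."""
    return np.asarray(_jtt()["exchangeabilities"], dtype=float)


def jtt_frequencies() -> np.ndarray:
    """The stationary amino-acid frequencies published with the JTT model."""
    f = np.asarray(_jtt()["frequencies"], dtype=float)
    return f / f.sum()


@dataclass(frozen=True)
class SubstitutionModel:
    """A reversible amino-acid substitution model with discrete-gamma rates.

    Attributes
    ----------
    exchangeabilities
        Symmetric nonnegative 20x20 matrix ``s`` with zero diagonal.
    frequencies
        Stationary distribution ``pi`` (length 20, positive, sums to 1).
    generator
        Rate matrix ``Q`` with ``Q_ij = s_ij pi_j`` off-diagonal, rows
        summing to zero, scaled to unit mean rate.
    gamma_shape
        Shape ``alpha`` of the mean-1 gamma rate distribution.
    n_categories
        Number ``K`` of equal-probability discrete rate categories.
    category_rates
        The ``K`` rate multipliers (mean 1, strictly increasing).
    """

    exchangeabilities: np.ndarray
    frequencies: np.ndarray
    generator: np.ndarray
    gamma_shape: float
    n_categories: int
    category_rates: np.ndarray
    _eig: tuple[np.ndarray, np.ndarray, np.ndarray] = field(repr=False, compare=False, default=None)

    def with_gamma_shape(self, alpha: float) -> "SubstitutionModel":
        """Return a copy of this model with a new gamma shape parameter."""
        return build_substitution_model(
            self.exchangeabilities, self.frequencies, alpha, self.n_categories
        )


@dataclass(frozen=True)
class TransitionMatrix:
    """Transition probabilities P = exp(Q t r) for one branch and rate."""

    matrix: np.ndarray
    branch_length: float
    rate: float


def discretize_gamma(gamma_shape: float, n_categories: int, method: str = "mean") -> np.ndarray:
    """Discretize a mean-1 gamma distribution into equal-probability rates.

    Parameters
    ----------
    gamma_shape
        Shape parameter ``alpha`` (> 0). The rate parameter is also
        ``alpha`` so the distribution has mean 1.
    n_categories
        Number of categories ``K`` (>= 1).
    method
        ``"mean"`` (default): each category rate is the conditional mean of
        its equal-probability bin, so rates average exactly 1.
        ``"median"``: bin medians, rescaled to mean 1.
    """
    alpha = float(gamma_shape)
    k = int(n_categories)
    if alpha <= 0:
        raise ValueError(f"gamma shape must be positive, got {alpha}")
    if k < 1:
        raise ValueError(f"need at least one rate category, got {k}")
    if k == 1:
        return np.ones(1)
    if method == "mean":
        # Bin boundaries at quantiles i/K; conditional bin means follow from
        # the incomplete-gamma identity  E[X; X<=b] = P(alpha+1, alpha*b).
        bounds = gamma_dist.ppf(np.arange(1, k) / k, alpha, scale=1.0 / alpha)
        cum = gammainc(alpha + 1.0, np.concatenate(([0.0], bounds * alpha, [np.inf])))
        rates = k * np.diff(cum)
    elif method == "median":
        q = (np.arange(k) + 0.5) / k
        rates = gamma_dist.ppf(q, alpha, scale=1.0 / alpha)
        rates = rates / rates.mean()
    else:
        raise ValueError(f"unknown discretization method {method!r}")
    return rates


def build_substitution_model(
    exchangeabilities: np.ndarray,
    frequencies: np.ndarray,
    gamma_shape: float = 1.0,
    n_categories: int = 1,
    *,
    frequency_floor: float = 1e-6,
    gamma_method: str = "mean",
) -> SubstitutionModel:
    """Assemble a reversible model from exchangeabilities and frequencies.

    Frequencies below ``frequency_floor`` are floored and the vector
    renormalized so the generator stays irreducible (empirical frequencies
    estimated from small alignments can be zero).
    """
    s = np.asarray(exchangeabilities, dtype=float).copy()
    pi = np.asarray(frequencies, dtype=float).copy()
    if s.shape != (N_STATES, N_STATES):
        raise ValueError(f"exchangeability matrix must be 20x20, got {s.shape}")
    if not np.allclose(s, s.T, atol=1e-10):
        raise ValueError("exchangeability matrix must be symmetric")
    if np.any(s < 0):
        raise ValueError("exchangeabilities must be nonnegative")
    np.fill_diagonal(s, 0.0)
    if pi.shape != (N_STATES,):
        raise ValueError(f"frequency vector must have length 20, got {pi.shape}")
    if np.any(pi < 0):
        bad = AMINO_ACIDS[int(np.argmin(pi))]
        raise ValueError(f"negative stationary frequency for state {bad!r}")
    if np.any(pi <= 0) and frequency_floor <= 0:
        bad = AMINO_ACIDS[int(np.argmin(pi))]
        raise ValueError(f"zero stationary frequency for state {bad!r}")
    if abs(pi.sum() - 1.0) > 1e-2:
        raise ValueError(f"frequencies must sum to ~1, got {pi.sum():.6g}")
    pi = np.maximum(pi, frequency_floor)
    pi = pi / pi.sum()

    q = s * pi[None, :]
    np.fill_diagonal(q, 0.0)
    np.fill_diagonal(q, -q.sum(axis=1))
    mean_rate = -float(pi @ np.diag(q))
    if mean_rate <= 0:
        raise ValueError("degenerate model: zero overall substitution rate")
    q = q / mean_rate

    rates = discretize_gamma(gamma_shape, n_categories, method=gamma_method)
    eig = _symmetric_eigendecomposition(q, pi)
    return SubstitutionModel(
        exchangeabilities=s,
        frequencies=pi,
        generator=q,
        gamma_shape=float(gamma_shape),
        n_categories=int(n_categories),
        category_rates=rates,
        _eig=eig,
    )


def jtt_model(
    gamma_shape: float = 1.0,
    n_categories: int = 1,
    frequencies: np.ndarray | None = None,
) -> SubstitutionModel:
    """Convenience constructor for JTT, optionally with empirical (+F) frequencies."""
    pi = jtt_frequencies() if frequencies is None else np.asarray(frequencies, dtype=float)
    return build_substitution_model(jtt_exchangeabilities(), pi, gamma_shape, n_categories)


def _symmetric_eigendecomposition(q: np.ndarray, pi: np.ndarray):
    """Eigendecomposition of diag(pi)^1/2 Q diag(pi)^-1/2 (symmetric for
    reversible Q), returned as (eigenvalues, left, right) so that
    exp(Qt) = right @ diag(exp(lambda t)) @ left."""
    sqrt_pi = np.sqrt(pi)
    b = (q * sqrt_pi[:, None]) / sqrt_pi[None, :]
    b = 0.5 * (b + b.T)  # clean numerical asymmetry
    lam, u = np.linalg.eigh(b)
    right = u / sqrt_pi[:, None]
    left = u.T * sqrt_pi[None, :]
    return lam, left, right


def transition_matrix(model: SubstitutionModel, branch_length: float, rate: float = 1.0) -> TransitionMatrix:
    """Transition probability matrix P = exp(Q * t * r).

    Computed from the cached eigendecomposition of the symmetrized
    generator; rows are renormalized only when floating-point drift
    exceeds 1e-12.
    """
    t = float(branch_length)
    r = float(rate)
    if t < 0:
        raise ValueError(f"branch length must be nonnegative, got {t}")
    if r < 0:
        raise ValueError(f"rate multiplier must be nonnegative, got {r}")
    p = _expm_qt(model, t * r)
    return TransitionMatrix(matrix=p, branch_length=t, rate=r)


def _expm_qt(model: SubstitutionModel, dist: float) -> np.ndarray:
    lam, left, right = model._eig
    p = (right * np.exp(lam * dist)[None, :]) @ left
    np.maximum(p, 0.0, out=p)
    rowsum = p.sum(axis=1)
    if np.any(np.abs(rowsum - 1.0) > 1e-12):
        p = p / rowsum[:, None]
    return p


def transition_matrices(model: SubstitutionModel, branch_length: float) -> np.ndarray:
    """Stacked transition matrices, one per gamma rate category (K, 20, 20)."""
    return np.stack(
        [_expm_qt(model, branch_length * r) for r in model.category_rates], axis=0
    )
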