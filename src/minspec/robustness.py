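"""Uncertainty propagation for reconstructed ancestral sequences.

Given a per-site posterior, this module samples whole alternate ancestral
sequences (sites independent, each drawn from its posterior row), ranks
unique non-MAP samples by joint posterior probability, and enumerates the
"plausible alternate" states above a PP cutoff while excluding
biochemically conservative pairs (K/R, D/E, S/T, I/L) relative to the
maximum-likelihood state - the worklist used to probe the robustness of
downstream functional conclusions by mutagenesis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .ancrec import AncestralPosterior, AncestralSequence
from .evomodel import AA_INDEX, AMINO_ACIDS

__all__ = [
    "AltAncestorSample",
    "PlausibleAlternateSet",
    "DEFAULT_EXCLUSION_PAIRS",
    "sample_alternates",
    "top_k_alternates",
    "plausible_alternates",
    "joint_pp_ratio",
    "enumerate_alternates",
]

#: Biochemically similar pairs excluded from the plausible-alternate list.
DEFAULT_EXCLUSION_PAIRS: frozenset[frozenset[str]] = frozenset(
    frozenset(p) for p in ("KR", "DE", "ST", "IL")
)


@dataclass
class AltAncestorSample:
    """One alternate ancestral sequence with its joint-PP bookkeeping."""

    states: str
    joint_log_pp: float
    pp_ratio_vs_ml: float
    n_diff_vs_ml: int


@dataclass
class PlausibleAlternateSet:
    """Per-site alternate states passing the PP cutoff and exclusion rule."""

    entries: list[tuple[int, str, float]]  # (site index, alternate state, PP)
    threshold: float
    exclusion_pairs: frozenset[frozenset[str]]
    node: str = ""

    def sites(self) -> list[int]:
        return sorted({site for site, _, _ in self.entries})


def _ml_states(posterior: AncestralPosterior) -> np.ndarray:
    return posterior.matrix.argmax(axis=1)


def joint_pp_ratio(
    seq: str | AncestralSequence, posterior: AncestralPosterior
) -> tuple[float, float]:
    """Joint log-PP of a sequence and its PP ratio against the MAP sequence.

    The joint PP is the product over sites of the marginal PP of the
    chosen state, accumulated in log space. A state with zero posterior
    yields ``(-inf, 0.0)`` explicitly.
    """
    states = seq.states if isinstance(seq, AncestralSequence) else seq
    matrix = posterior.matrix
    if len(states) != matrix.shape[0]:
        raise ValueError(
            f"sequence length {len(states)} does not match posterior sites {matrix.shape[0]}"
        )
    idx = np.array([AA_INDEX[c] for c in states.upper()])
    pp = matrix[np.arange(len(idx)), idx]
    with np.errstate(divide="ignore"):
        joint = float(np.log(pp).sum())
    ml_joint = float(np.log(matrix.max(axis=1)).sum())
    ratio = float(np.exp(joint - ml_joint)) if np.isfinite(joint) else 0.0
    return joint, ratio


def sample_alternates(
    posterior: AncestralPosterior,
    n_samples: int,
    seed: int,
) -> list[AltAncestorSample]:
    """Draw ``n_samples`` sequences from the per-site posterior rows.

    Sites are sampled independently; for each sample the joint log-PP,
    the number of differences from the MAP sequence, and the joint-PP
    ratio against it are recorded. Fully reproducible given ``seed``.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    rng = np.random.default_rng(seed)
    matrix = posterior.matrix
    n_sites = matrix.shape[0]
    ml_idx = _ml_states(posterior)
    log_matrix = np.log(np.maximum(matrix, 1e-300))
    ml_joint = float(log_matrix[np.arange(n_sites), ml_idx].sum())

    cdf = matrix.cumsum(axis=1)
    cdf[:, -1] = 1.0
    u = rng.random((n_samples, n_sites))
    draws = (u[:, :, None] > cdf[None, :, :]).sum(axis=2)  # (n_samples, n_sites)

    out = []
    site_range = np.arange(n_sites)
    for row in draws:
        joint = float(log_matrix[site_range, row].sum())
        ndiff = int((row != ml_idx).sum())
        out.append(
            AltAncestorSample(
                states="".join(AMINO_ACIDS[i] for i in row),
                joint_log_pp=joint,
                pp_ratio_vs_ml=float(np.exp(joint - ml_joint)) if ndiff else 1.0,
                n_diff_vs_ml=ndiff,
            )
        )
    return out


def top_k_alternates(
    posterior: AncestralPosterior,
    samples: list[AltAncestorSample],
    k: int,
) -> tuple[list[AltAncestorSample], np.ndarray]:
    """The ``k`` unique non-MAP sampled sequences with highest joint PP.

    Returns the ranked list (descending joint PP) and the symmetric
    pairwise difference-count matrix among them. A shorter list is
    returned with a warning when fewer unique non-MAP sequences exist.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    ml = "".join(AMINO_ACIDS[i] for i in _ml_states(posterior))
    unique: dict[str, AltAncestorSample] = {}
    for s in samples:
        if s.states != ml and s.states not in unique:
            unique[s.states] = s
    ranked = sorted(unique.values(), key=lambda s: (-s.joint_log_pp, s.states))[:k]
    if len(ranked) < k:
        warnings.warn(
            f"only {len(ranked)} unique non-ML sequences available (requested {k})"
        )
    n = len(ranked)
    diff = np.zeros((n, n), dtype=int)
    for i in range(n):
        for j in range(i + 1, n):
            d = sum(a != b for a, b in zip(ranked[i].states, ranked[j].states))
            diff[i, j] = diff[j, i] = d
    return ranked, diff


def enumerate_alternates(posterior: AncestralPosterior, max_sequences: int = 10**6):
    """Exhaustively enumerate all state combinations with nonzero PP.

    Intended for posteriors with few ambiguous sites (it refuses to
    enumerate more than ``max_sequences``); serves as the exact reference
    for the sampling-based ranking.
    """
    matrix = posterior.matrix
    supports = [np.flatnonzero(row > 0) for row in matrix]
    total = 1
    for s in supports:
        total *= len(s)
        if total > max_sequences:
            raise ValueError(f"enumeration would exceed {max_sequences} sequences")
    ml_joint = float(np.log(matrix.max(axis=1)).sum())
    out = []

    def rec(site, prefix, logpp):
        if site == matrix.shape[0]:
            states = "".join(AMINO_ACIDS[i] for i in prefix)
            out.append(
                AltAncestorSample(
                    states=states,
                    joint_log_pp=logpp,
                    pp_ratio_vs_ml=float(np.exp(logpp - ml_joint)),
                    n_diff_vs_ml=int(
                        sum(p != m for p, m in zip(prefix, _ml_states(posterior)))
                    ),
                )
            )
            return
        for state in supports[site]:
            rec(site + 1, prefix + [state], logpp + float(np.log(matrix[site, state])))

    rec(0, [], 0.0)
    out.sort(key=lambda s: (-s.joint_log_pp, s.states))
    return out


def plausible_alternates(
    posterior: AncestralPosterior,
    ml: AncestralSequence | None = None,
    threshold: float = 0.20,
    exclusions: frozenset[frozenset[str]] = DEFAULT_EXCLUSION_PAIRS,
) -> PlausibleAlternateSet:
    """Enumerate plausible alternate states: PP strictly above ``threshold``,
    excluding alternates that form a biochemically similar pair with the
    ML state (the exclusion applies to the alternate-vs-ML comparison
    only)."""
    if not (0.0 < threshold < 1.0):
        raise ValueError("threshold must lie in (0, 1)")
    matrix = posterior.matrix
    ml_idx = _ml_states(posterior)
    if ml is not None:
        stated = np.array([AA_INDEX[c] for c in ml.states])
        if not np.array_equal(stated, ml_idx):
            raise ValueError("supplied ML sequence does not match the posterior argmax")
    entries = []
    for site in range(matrix.shape[0]):
        ml_state = AMINO_ACIDS[ml_idx[site]]
        for j in np.flatnonzero(matrix[site] > threshold):
            if j == ml_idx[site]:
                continue
            alt = AMINO_ACIDS[j]
            if frozenset((alt, ml_state)) in exclusions:
                continue
            entries.append((site, alt, float(matrix[site, j])))
    return PlausibleAlternateSet(
        entries=entries,
        threshold=threshold,
        exclusion_pairs=exclusions,
        node=posterior.node,
    )
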