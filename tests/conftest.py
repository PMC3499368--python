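"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from minspec import jtt_model, parse_newick
from minspec.ancrec import AncestralPosterior
from minspec.evomodel import AMINO_ACIDS
from minspec.likelihood import site_likelihoods  # noqa: F401 (re-exported for tests)


@pytest.fixture(scope="session")
def jtt1():
    """JTT with model frequencies, single rate category."""
    return jtt_model(n_categories=1)


@pytest.fixture(scope="session")
def jtt_gamma():
    """JTT with 4-category gamma rates, alpha = 0.8."""
    return jtt_model(gamma_shape=0.8, n_categories=4)


@pytest.fixture()
def four_taxon_tree():
    return parse_newick("((A:0.21,B:0.08)u:0.12,(C:0.3,D:0.05)v:0.07)r;")


def make_posterior(rows: list[dict[str, float]], flags=None) -> AncestralPosterior:
    """Build a small ancestral posterior from per-site {state: PP} dicts."""
    m = np.zeros((len(rows), 20))
    for i, d in enumerate(rows):
        for aa, p in d.items():
            m[i, AMINO_ACIDS.index(aa)] = p
    m = m / m.sum(axis=1, keepdims=True)
    flags = np.zeros(len(rows), bool) if flags is None else np.asarray(flags, bool)
    return AncestralPosterior(
        node="anc",
        matrix=m,
        included_sites=np.flatnonzero(~flags),
        site_flags=flags,
        site_subsets={},
        tree=None,
        model=None,
    )


# ---------------------------------------------------------------------------
# exhaustive-enumeration oracle (independent of the pruning implementation)
# ---------------------------------------------------------------------------

def enumerate_site(tree, model, leaf_states: dict[str, int]):
    """Site likelihood and per-internal-node marginals by brute-force
    summation over every assignment of states to internal nodes.

    ``leaf_states`` maps leaf label to state index (-1 = missing data).
    Returns ``(likelihood, {node_label: unnormalized posterior vector})``.
    Only feasible for trees with very few internal nodes.
    """
    from minspec.evomodel import transition_matrix

    nodes = tree.postorder()
    internal = [n for n in nodes if not n.is_leaf]
    pmat = {
        id(n): transition_matrix(model, n.length, 1.0).matrix
        for n in nodes
        if n.parent is not None
    }
    pi = model.frequencies
    total = 0.0
    post = {n.label: np.zeros(20) for n in internal}
    for assignment in itertools.product(range(20), repeat=len(internal)):
        state = {id(n): s for n, s in zip(internal, assignment)}
        p = pi[state[id(tree.root)]]
        for n in nodes:
            if n.parent is None:
                continue
            parent_state = state[id(n.parent)]
            if n.is_leaf:
                s = leaf_states[n.label]
                p *= 1.0 if s < 0 else pmat[id(n)][parent_state, s]
            else:
                p *= pmat[id(n)][parent_state, state[id(n)]]
        total += p
        for n in internal:
            post[n.label][state[id(n)]] += p
    return total, post


def enumerate_alignment(tree, model, alignment):
    """Vector of site likelihoods and posterior matrices via the oracle.

    Averages over the model's gamma categories by rescaling every branch,
    exactly mirroring the mixture definition.
    """
    from minspec import build_substitution_model

    liks = np.zeros(alignment.n_sites)
    posts: dict[str, np.ndarray] = {}
    enc = alignment.encoded
    name_to_row = {n: enc[i] for i, n in enumerate(alignment.names)}
    m1 = build_substitution_model(model.exchangeabilities, model.frequencies, 1.0, 1)
    for rate in model.category_rates:
        scaled = tree.copy()
        for n in scaled.postorder():
            n.length *= rate
        for site in range(alignment.n_sites):
            leaf_states = {
                label: int(name_to_row[label][site]) for label in alignment.names
            }
            lik, post = enumerate_site(scaled, m1, leaf_states)
            liks[site] += lik / model.n_categories
            for label, vec in post.items():
                posts.setdefault(label, np.zeros((alignment.n_sites, 20)))
                posts[label][site] += vec / model.n_categories
    for label in posts:
        posts[label] = posts[label] / posts[label].sum(axis=1, keepdims=True)
    return liks, posts
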