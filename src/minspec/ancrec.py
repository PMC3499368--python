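"""Empirical-Bayes marginal ancestral reconstruction.

For a named internal node the per-site posterior over the 20 amino-acid
states is computed from the pruning partials below the node and the
"outside" partials above it, with the discrete-gamma mixture marginalized
by weighting each category by its posterior probability given the site
data. The maximum-a-posteriori sequence, the posterior probability (PP)
of each chosen state, and mean-PP summaries over site subsets (excluding
indel-containing columns, which are reported separately) follow the usual
ancestral-resurrection workflow.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from .evomodel import AMINO_ACIDS, SubstitutionModel
from .likelihood import _category_pruning, _encode_patterns, _leaf_rows, _pattern_lnL
from .phylo import PhyloTree, TreeError
from .seqs import Alignment

__all__ = ["AncestralPosterior", "AncestralSequence", "marginal_posterior",
           "ml_sequence", "mean_pp"]


@dataclass
class AncestralPosterior:
    """Per-site 20-state posterior at one internal node.

    ``matrix`` has one row per alignment site (rows sum to 1);
    ``included_sites`` lists the columns that are free of indels and enter
    mean-PP summaries.
    """

    node: str
    matrix: np.ndarray  # (n_sites, 20)
    included_sites: np.ndarray
    site_flags: np.ndarray
    site_subsets: dict[str, np.ndarray]
    tree: PhyloTree
    model: SubstitutionModel


@dataclass
class AncestralSequence:
    """A maximum-a-posteriori ancestral sequence with its per-site support."""

    node: str
    states: str
    per_site_pp: np.ndarray
    mean_pp_all: float
    mean_pp_subsets: dict[str, float]
    indel_sites: np.ndarray


def marginal_posterior(
    tree: PhyloTree,
    model: SubstitutionModel,
    alignment: Alignment,
    node: str,
) -> AncestralPosterior:
    """Marginal posterior state probabilities at the internal node ``node``.

    For each rate category k the posterior at the node is proportional to
    ``F_k(a) * G_k(a)`` where F is the ordinary below-partial and G the
    outside partial (G at the root is the stationary distribution pi);
    categories are combined with weights proportional to the per-site
    category likelihoods, i.e. the gamma mixture is marginalized rather
    than conditioned on a single category.
    """
    target = tree.find(node)
    if target.is_leaf:
        raise TreeError(f"node {node!r} is a leaf; ancestral states are defined "
                        "only for internal nodes")
    leaves, patterns, inverse = _encode_patterns(alignment, tree)
    n_patterns = patterns.shape[1]
    leaf_rows = _leaf_rows(patterns, leaves)
    partials, scales, pmats, nodes = _category_pruning(
        tree, model, leaf_rows, n_patterns
    )
    K = model.n_categories
    pi = model.frequencies

    # Outside partials G, computed root-to-tip. Scales are tracked but
    # cancel in the per-category normalization below.
    above = [dict() for _ in range(K)]
    above_scale = [dict() for _ in range(K)]
    for k in range(K):
        above[k][id(tree.root)] = np.tile(pi, (n_patterns, 1))
        above_scale[k][id(tree.root)] = np.zeros(n_patterns)
    for parent in reversed(nodes):  # preorder
        if parent.is_leaf:
            continue
        for child in parent.children:
            if child.is_leaf:
                continue
            for k in range(K):
                acc = above[k][id(parent)].copy()
                scale = above_scale[k][id(parent)].copy()
                for sib in parent.children:
                    if sib is child:
                        continue
                    acc = acc * (partials[k][id(sib)] @ pmats[k][id(sib)].T)
                    scale = scale + scales[k][id(sib)]
                g = acc @ pmats[k][id(child)]
                mx = g.max(axis=1)
                mx[mx == 0] = 1.0
                above[k][id(child)] = g / mx[:, None]
                above_scale[k][id(child)] = scale + np.log(mx)

    cat_lnL = _pattern_lnL(tree, model, partials, scales)  # (K, n_patterns)
    pattern_lnL = logsumexp(cat_lnL, axis=0) - np.log(K)
    cat_weight = np.exp(cat_lnL - pattern_lnL[None, :])  # (K, n_patterns), sums to K
    cat_weight = cat_weight / cat_weight.sum(axis=0, keepdims=True)

    post = np.zeros((n_patterns, 20))
    for k in range(K):
        joint = partials[k][id(target)] * above[k][id(target)]
        total = joint.sum(axis=1)
        if np.any(total <= 0):
            raise FloatingPointError("zero marginal likelihood at an alignment site")
        post += cat_weight[k][:, None] * (joint / total[:, None])
    post = post / post.sum(axis=1, keepdims=True)

    matrix = post[inverse]
    flags = alignment.site_flags
    included = np.flatnonzero(~flags)
    return AncestralPosterior(
        node=node,
        matrix=matrix,
        included_sites=included,
        site_flags=flags,
        site_subsets=dict(alignment.site_subsets),
        tree=tree,
        model=model,
    )


def ml_sequence(posterior: AncestralPosterior) -> AncestralSequence:
    """Maximum-a-posteriori sequence: per-site argmax with alphabetical
    tie-breaking (ties are reported via a warning)."""
    matrix = posterior.matrix
    best = matrix.argmax(axis=1)
    pp = matrix[np.arange(matrix.shape[0]), best]
    ties = (np.abs(matrix - pp[:, None]) < 1e-12).sum(axis=1) > 1
    if ties.any():
        warnings.warn(
            f"posterior ties at sites {np.flatnonzero(ties).tolist()}; "
            "alphabetically first state chosen"
        )
    states = "".join(AMINO_ACIDS[i] for i in best)
    mean_all = float(pp[posterior.included_sites].mean())
    mean_subsets = {}
    for name, subset in posterior.site_subsets.items():
        keep = np.intersect1d(subset, posterior.included_sites)
        if keep.size:
            mean_subsets[name] = float(pp[keep].mean())
    return AncestralSequence(
        node=posterior.node,
        states=states,
        per_site_pp=pp,
        mean_pp_all=mean_all,
        mean_pp_subsets=mean_subsets,
        indel_sites=np.flatnonzero(posterior.site_flags),
    )


def mean_pp(posterior: AncestralPosterior, subset: str | np.ndarray | None = None) -> float:
    """Mean posterior probability of the chosen (argmax) state.

    ``subset`` may be the name of a site subset attached to the posterior,
    an explicit array of 0-based site indices, or None for all
    indel-free sites. Indel-containing sites are always excluded.
    """
    if subset is None:
        sites = posterior.included_sites
    elif isinstance(subset, str):
        if subset not in posterior.site_subsets:
            raise KeyError(
                f"unknown site subset {subset!r}; have {sorted(posterior.site_subsets)}"
            )
        sites = np.intersect1d(posterior.site_subsets[subset], posterior.included_sites)
    else:
        sites = np.intersect1d(np.asarray(subset, dtype=int), posterior.included_sites)
    if len(sites) == 0:
        raise ValueError("empty site subset after excluding indel-containing sites")
    rows = posterior.matrix[sites]
    return float(rows.max(axis=1).mean())
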