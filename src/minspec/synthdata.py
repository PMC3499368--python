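"""Synthetic-data generators with known ground truth.

Two generators give every pipeline stage a testable input: (a) sequence
evolution along a known tree under the package's substitution model, so
the true state at every internal node is recorded and reconstruction
accuracy/calibration can be measured; and (b) triplicate dual-luciferase
dose-response curves on a 1e-12 to 1e-5 M grid with multiplicative
log-normal noise and known 4PL parameters, so EC50 estimation and
confidence-interval coverage can be measured.

All randomness flows through numpy Generators seeded from a master seed;
``derive_seed`` gives stable per-purpose substreams.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np

from .doseresponse import AssayTable, four_parameter_logistic
from .evomodel import AMINO_ACIDS, SubstitutionModel, transition_matrices
from .phylo import PhyloTree, TreeNode
from .seqs import Alignment

__all__ = [
    "SimulatedEvolution",
    "SimulatedAssay",
    "derive_seed",
    "balanced_tree",
    "two_clade_tree",
    "simulate_evolution",
    "simulate_assay",
    "DEFAULT_DOSE_GRID",
]

#: Eight log-spaced doses spanning 1e-12 to 1e-5 M.
DEFAULT_DOSE_GRID: np.ndarray = np.logspace(-12, -5, 8)


def derive_seed(master_seed: int, purpose: str) -> int:
    """A reproducible sub-seed (< 2**31) for one named purpose."""
    return int(
        np.random.SeedSequence([master_seed, zlib.crc32(purpose.encode())]).generate_state(1)[0]
        % (2**31)
    )


# ---------------------------------------------------------------------------
# trees
# ---------------------------------------------------------------------------

def balanced_tree(n_leaves: int, branch_length: float = 0.05,
                  label_internal: bool = True) -> PhyloTree:
    """A balanced binary tree with uniform branch lengths.

    Leaves are named t1..tN; internal nodes n1..n(N-1) with n1 the root.
    """
    if n_leaves < 2 or (n_leaves & (n_leaves - 1)) != 0:
        raise ValueError("n_leaves must be a power of two >= 2")
    internal_counter = [0]
    leaf_counter = [0]

    def build(n: int) -> TreeNode:
        internal_counter[0] += 1
        node = TreeNode(f"n{internal_counter[0]}" if label_internal else None, branch_length)
        for _ in range(2):
            if n == 2:
                leaf_counter[0] += 1
                node.add_child(TreeNode(f"t{leaf_counter[0]}", branch_length))
            else:
                node.add_child(build(n // 2))
        return node

    root = build(n_leaves)
    root.length = 0.0
    return PhyloTree(root)


def two_clade_tree(
    clade_size: int = 4,
    internal_length: float = 0.05,
    pendant_length: float = 0.1,
) -> PhyloTree:
    """Two balanced clades joined by one internal edge (labelled ``bridge``);
    exercises branch-support statistics on the joining edge."""
    left = balanced_tree(clade_size, pendant_length, label_internal=False).root
    right = balanced_tree(clade_size, pendant_length, label_internal=False).root
    for i, leaf in enumerate(PhyloTree(left).leaves(), start=1):
        leaf.label = f"a{i}"
    for i, leaf in enumerate(PhyloTree(right).leaves(), start=1):
        leaf.label = f"b{i}"
    root = TreeNode("root", 0.0)
    right.label = "bridge"
    right.length = internal_length
    root.add_child(right)
    for child in list(left.children):
        root.add_child(child)
    return PhyloTree(root)


# ---------------------------------------------------------------------------
# sequence evolution
# ---------------------------------------------------------------------------

@dataclass
class SimulatedEvolution:
    """Ground-truth record of one simulated evolutionary history."""

    tree: PhyloTree
    model: SubstitutionModel
    alignment: Alignment
    internal_states: dict[str, str]  # node label -> true sequence
    site_categories: np.ndarray  # rate-category index per site
    seed: int

    @property
    def root_sequence(self) -> str:
        return self.internal_states[self.tree.root.label]


def _ensure_internal_labels(tree: PhyloTree) -> PhyloTree:
    tree = tree.copy()
    used = {n.label for n in tree.postorder() if n.label}
    counter = 0
    for node in tree.postorder():
        if not node.is_leaf and node.label is None:
            counter += 1
            while f"node{counter}" in used:
                counter += 1
            node.label = f"node{counter}"
    return tree


def simulate_evolution(
    tree: PhyloTree,
    model: SubstitutionModel,
    n_sites: int,
    seed: int,
) -> SimulatedEvolution:
    """Evolve ``n_sites`` independently along ``tree`` under ``model``.

    Per-site rates are drawn uniformly from the K discrete gamma
    categories, the root sequence from the stationary distribution, and
    each branch applies the category's transition matrix. The state of
    every internal node is recorded.
    """
    if n_sites < 1:
        raise ValueError("n_sites must be >= 1")
    tree = _ensure_internal_labels(tree)
    rng = np.random.default_rng(seed)
    K = model.n_categories
    cats = rng.integers(0, K, size=n_sites)
    pi = model.frequencies
    root_states = rng.choice(20, size=n_sites, p=pi)

    states: dict[int, np.ndarray] = {id(tree.root): root_states}
    nodes = tree.postorder()
    for node in reversed(nodes):  # preorder: parents before children
        if node.parent is None:
            continue
        parent_states = states[id(node.parent)]
        pmats = transition_matrices(model, node.length)  # (K, 20, 20)
        child = np.empty(n_sites, dtype=np.int64)
        u = rng.random(n_sites)
        for k in range(K):
            sel = cats == k
            if not np.any(sel):
                continue
            cdf = pmats[k].cumsum(axis=1)
            cdf[:, -1] = 1.0
            rows = cdf[parent_states[sel]]
            child[sel] = (u[sel, None] > rows).sum(axis=1)
        states[id(node)] = child

    def seq(arr: np.ndarray) -> str:
        return "".join(AMINO_ACIDS[i] for i in arr)

    internal = {
        n.label: seq(states[id(n)]) for n in nodes if not n.is_leaf
    }
    names = [n.label for n in tree.leaves()]
    rows = [seq(states[id(n)]) for n in tree.leaves()]
    return SimulatedEvolution(
        tree=tree,
        model=model,
        alignment=Alignment(names=names, rows=rows),
        internal_states=internal,
        site_categories=cats,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# reporter assays
# ---------------------------------------------------------------------------

@dataclass
class SimulatedAssay:
    """A generated assay table with its true dose-response parameters."""

    table: AssayTable
    basal: float
    maximum: float
    ec50: float
    hill: float
    cv: float
    seed: int


def simulate_assay(
    receptor: str = "receptor",
    ligand: str = "ligand",
    basal: float = 1.0,
    maximum: float = 10.0,
    ec50: float = 1e-9,
    hill: float = 1.0,
    dose_grid: np.ndarray | None = None,
    replicates: int = 3,
    cv: float = 0.1,
    cv_renilla: float | None = None,
    renilla_base: float = 1000.0,
    n_vehicle: int = 3,
    seed: int = 0,
) -> SimulatedAssay:
    """Generate triplicate dual-luciferase wells from a known 4PL curve.

    Firefly readings are ``renilla_base * 4PL(dose)`` times log-normal
    noise with coefficient of variation ``cv`` (median-1 noise,
    ``sigma = sqrt(log(1 + cv**2))``); Renilla readings carry independent
    noise with ``cv_renilla`` (defaults to ``cv``). Vehicle wells sit at
    the basal response. With ``cv = 0`` the normalized fold activation
    reproduces the 4PL curve exactly when ``basal = 1``.
    """
    if cv < 0:
        raise ValueError("cv must be nonnegative")
    doses = DEFAULT_DOSE_GRID if dose_grid is None else np.asarray(dose_grid, dtype=float)
    cv_ren = cv if cv_renilla is None else cv_renilla
    rng = np.random.default_rng(seed)

    def lognoise(shape, c):
        if c == 0:
            return np.ones(shape)
        sigma = np.sqrt(np.log1p(c**2))
        return np.exp(rng.normal(0.0, sigma, size=shape))

    truth = four_parameter_logistic(np.log10(doses), basal, maximum, np.log10(ec50), hill)
    firefly = renilla_base * truth[:, None] * lognoise((len(doses), replicates), cv)
    renilla = renilla_base * lognoise((len(doses), replicates), cv_ren)
    vehicle_f = renilla_base * basal * lognoise(n_vehicle, cv)
    vehicle_r = renilla_base * lognoise(n_vehicle, cv_ren)
    table = AssayTable(
        receptor=receptor,
        ligand=ligand,
        doses=doses,
        firefly=firefly,
        renilla=renilla,
        vehicle_firefly=vehicle_f,
        vehicle_renilla=vehicle_r,
    )
    return SimulatedAssay(
        table=table, basal=basal, maximum=maximum, ec50=ec50, hill=hill,
        cv=cv, seed=seed,
    )
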