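"""Synthetic alignments with the statistical structure the pipeline assumes.

The simulator evolves amino-acid columns on a fixed tree under a stationary
reversible model with discrete-gamma among-site rate variation, and the
scenario builder adds the one ingredient the analysis exists to diagnose: a
pair of taxa on markedly long pendant branches whose mutual attraction is
concentrated in the fastest-evolving sites.  No gaps are ever generated by
the evolutionary simulator; missingness is a separate masking step.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .alignment import Alignment
from .inference import CladeDefinition
from .models import GammaRates, SubstitutionModel, lg_model
from .phylo import Bipartition, Node, PhyloTree, splits_compatible

__all__ = [
    "simulate_alignment",
    "make_lba_scenario",
    "mask_missing",
    "random_binary_tree",
    "LBAScenario",
]


def simulate_alignment(
    tree: PhyloTree,
    model: SubstitutionModel,
    gamma: GammaRates,
    n_sites: int,
    seed: int,
    site_rate_multipliers: Optional[np.ndarray] = None,
) -> tuple[Alignment, np.ndarray]:
    """Evolve ``n_sites`` columns down the tree; returns (alignment, true rates).

    Per site a rate is drawn from the discrete-gamma categories (optionally
    scaled by ``site_rate_multipliers``), the root state from the equilibrium
    frequencies, and each edge applies the model's transition matrix at
    (rate x branch length).  Same seed, same alignment.
    """
    if n_sites < 1:
        raise ValueError("n_sites must be >= 1")
    for node in tree.preorder():
        if node is not tree.root and node.length is None:
            raise ValueError("simulation requires branch lengths on every edge")
    rng = np.random.default_rng(seed)
    cats = rng.integers(0, gamma.n_categories, n_sites)
    rates = gamma.rates[cats]
    if site_rate_multipliers is not None:
        mult = np.asarray(site_rate_multipliers, dtype=float)
        if mult.shape != (n_sites,):
            raise ValueError("site_rate_multipliers must have one entry per site")
        rates = rates * mult

    states: dict[int, np.ndarray] = {}
    states[id(tree.root)] = rng.choice(20, size=n_sites, p=model.frequencies)
    # Distinct rate values are few (categories x multiplier groups): build each
    # edge's transition matrices per rate group and sample children vectorised.
    for node in tree.preorder():
        parent_states = states[id(node)]
        for child in node.children:
            child_states = np.empty(n_sites, dtype=np.int64)
            for rate in np.unique(rates):
                sel = np.flatnonzero(rates == rate)
                P = model.transition_matrix(rate * child.length)
                cum = np.cumsum(P, axis=1)
                u = rng.random(sel.size)
                child_states[sel] = (cum[parent_states[sel]] > u[:, None]).argmax(axis=1)
            states[id(child)] = child_states
        if node is not tree.root and node.children:
            del states[id(node)]  # interior states are not needed again

    tips = [n for n in tree.preorder() if n.is_leaf]
    data = np.vstack([states[id(t)].astype(np.int8) for t in tips])
    return Alignment([t.label for t in tips], data), rates


def mask_missing(alignment: Alignment, proportion: float, seed: int) -> Alignment:
    """Mask a random proportion of cells as missing (emulating coverage gaps)."""
    if not 0.0 <= proportion < 1.0:
        raise ValueError("proportion must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    data = alignment.data.copy()
    mask = rng.random(data.shape) < proportion
    data[mask] = -1
    return Alignment(alignment.taxa, data, alignment.site_indices)


def random_binary_tree(
    n_tips: int,
    rng: np.random.Generator,
    min_length: float = 0.05,
    max_length: float = 0.5,
    prefix: str = "t",
) -> PhyloTree:
    """Random binary topology by sequential tip insertion, random edge lengths."""
    if n_tips < 2:
        raise ValueError("need at least 2 tips")

    def draw() -> float:
        return float(rng.uniform(min_length, max_length))

    root = Node()
    root.children = [Node(f"{prefix}1", draw()), Node(f"{prefix}2", draw())]
    edges = list(root.children)
    for i in range(3, n_tips + 1):
        target = edges[rng.integers(0, len(edges))]
        # split the target edge with a new internal node and hang the new tip
        new_internal = Node(length=target.length / 2)
        target.length = target.length / 2
        new_tip = Node(f"{prefix}{i}", draw())
        parent = next(p for p in _all_nodes(root) if target in p.children)
        parent.children[parent.children.index(target)] = new_internal
        new_internal.children = [target, new_tip]
        edges.extend([new_internal, new_tip])
    return PhyloTree(root)


def _all_nodes(root: Node):
    stack = [root]
    while stack:
        n = stack.pop()
        yield n
        stack.extend(n.children)


@dataclass
class LBAScenario:
    """A synthetic long-branch-attraction setting with known truth.

    The generating tree places the two designated long-branch taxa in
    *different* true clades; classical attraction between their inflated
    pendant edges favours the artifact clade (the pair), which the true tree
    does not display.  ``fast_fraction`` of sites evolve ``fast_multiplier``
    times faster, concentrating the artefactual signal in fast sites.
    """

    tree: PhyloTree
    long_branch_pair: tuple[str, str]
    true_clade: CladeDefinition
    artifact_clade: CladeDefinition
    fast_fraction: float
    fast_multiplier: float
    long_branch_multiplier: float
    seed: int
    true_rates: Optional[np.ndarray] = None
    fast_site_mask: Optional[np.ndarray] = None

    def truth_manifest(self) -> dict:
        return {
            "long_branch_pair": list(self.long_branch_pair),
            "true_clade": {"name": self.true_clade.name, "members": sorted(self.true_clade.members)},
            "artifact_clade": {
                "name": self.artifact_clade.name,
                "members": sorted(self.artifact_clade.members),
            },
            "fast_fraction": self.fast_fraction,
            "fast_multiplier": self.fast_multiplier,
            "long_branch_multiplier": self.long_branch_multiplier,
            "seed": self.seed,
        }


# Scenario tree geometry (expected substitutions/site).  A short central stem
# separating moderate pendant edges is the classical attraction-prone regime;
# only the designated pair's pendant edges are inflated.
_PENDANT = 0.12
_INTERNAL = 0.05
_STEM = 0.02


def _balanced_clade(labels: list[str], pendant: float, internal: float) -> Node:
    """Balanced (as possible) subtree over the labels."""
    if len(labels) == 1:
        return Node(labels[0], pendant)
    mid = len(labels) // 2
    node = Node(length=internal)
    node.children = [
        _balanced_clade(labels[:mid], pendant, internal),
        _balanced_clade(labels[mid:], pendant, internal),
    ]
    return node


def make_lba_scenario(
    n_background_taxa: int = 10,
    long_branch_multiplier: float = 8.0,
    fast_fraction: float = 0.3,
    fast_multiplier: float = 6.0,
    n_sites: int = 2000,
    seed: int = 0,
    model: Optional[SubstitutionModel] = None,
    gamma: Optional[GammaRates] = None,
) -> tuple[LBAScenario, Alignment]:
    """Build an attraction scenario and simulate its alignment.

    Two clades, each holding half the background taxa plus one long-branch
    taxon (``L1`` in the left clade, ``L2`` in the right); the true clade is
    the left clade, the artifact clade the {L1, L2} pair.
    """
    if long_branch_multiplier < 1:
        raise ValueError("long_branch_multiplier must be >= 1 (1 = no-attraction control)")
    if not 0.0 <= fast_fraction < 1.0:
        raise ValueError("fast_fraction must lie in [0, 1)")
    if n_background_taxa < 2:
        raise ValueError("need at least 2 background taxa (one per clade)")
    model = model or lg_model()
    gamma = gamma or GammaRates(alpha=0.5, n_categories=4)

    n_left = (n_background_taxa + 1) // 2
    left_bg = [f"A{i}" for i in range(1, n_left + 1)]
    right_bg = [f"B{i}" for i in range(1, n_background_taxa - n_left + 1)]

    long_pendant = long_branch_multiplier * _PENDANT
    left = Node(length=_STEM)
    left.children = [Node("L1", long_pendant), _balanced_clade(left_bg, _PENDANT, _INTERNAL)]
    right = Node(length=_STEM)
    right.children = [Node("L2", long_pendant), _balanced_clade(right_bg, _PENDANT, _INTERNAL)]
    tree = PhyloTree(Node(children=[left, right]))

    all_taxa = tree.tip_labels
    true_clade = CladeDefinition("true_left_clade", ["L1"] + left_bg)
    artifact_clade = CladeDefinition("long_branch_pair", ["L1", "L2"])
    t_split = Bipartition(true_clade.members, set(all_taxa) - true_clade.members)
    a_split = Bipartition(artifact_clade.members, set(all_taxa) - artifact_clade.members)
    assert not splits_compatible(t_split, a_split), "scenario clades must conflict"

    rng = np.random.default_rng(seed)
    fast_mask = rng.random(n_sites) < fast_fraction
    multipliers = np.where(fast_mask, fast_multiplier, 1.0)
    alignment, rates = simulate_alignment(
        tree, model, gamma, n_sites, seed=int(rng.integers(0, 2**31 - 1)),
        site_rate_multipliers=multipliers,
    )
    scenario = LBAScenario(
        tree=tree,
        long_branch_pair=("L1", "L2"),
        true_clade=true_clade,
        artifact_clade=artifact_clade,
        fast_fraction=fast_fraction,
        fast_multiplier=fast_multiplier,
        long_branch_multiplier=long_branch_multiplier,
        seed=seed,
        true_rates=rates,
        fast_site_mask=fast_mask,
    )
    return scenario, alignment
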