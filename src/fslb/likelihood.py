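"""Felsenstein pruning likelihoods on a fixed tree.

All sites are evaluated at once: each node carries a (sites x 20) array of
conditional likelihoods, combined up the tree with the model's transition
matrices at (rate x branch length).  Partial likelihoods are rescaled per
node to keep deep trees away from underflow; the log-scale corrections are
accumulated exactly.
"""

from __future__ import annotations

from typing import Mapping, Optional, Sequence

import numpy as np

from .alignment import MISSING, Alignment
from .models import SubstitutionModel
from .phylo import PhyloTree

__all__ = ["site_log_likelihoods", "site_log_likelihood"]

_TINY = 1e-300


def site_log_likelihoods(
    alignment: Alignment,
    tree: PhyloTree,
    model: SubstitutionModel,
    rate: float,
) -> np.ndarray:
    """Per-site log-likelihoods of the alignment on the tree at a fixed rate.

    Alignment taxa must be a subset of the tree's tips; tips without a row
    are treated as entirely missing (all-ones conditionals), as are gap and
    ambiguity characters.  Edges touched by the computation must carry
    branch lengths.
    """
    if rate <= 0 or not np.isfinite(rate):
        raise ValueError(f"rate must be positive and finite, got {rate}")
    tipset = set(tree.tip_labels)
    extra = set(alignment.taxa) - tipset
    if extra:
        raise ValueError(f"alignment taxa absent from tree: {sorted(extra)}")

    n_sites = alignment.n_sites
    row_of = {t: i for i, t in enumerate(alignment.taxa)}

    partial: dict[int, np.ndarray] = {}
    log_scale = np.zeros(n_sites)

    for node in tree.postorder():
        if node.is_leaf:
            row = row_of.get(node.label)
            L = np.ones((n_sites, 20))
            if row is not None:
                codes = alignment.data[row]
                observed = codes != MISSING
                L[observed] = 0.0
                L[observed, codes[observed]] = 1.0
            partial[id(node)] = L
            continue
        L = np.ones((n_sites, 20))
        for child in node.children:
            if child.length is None:
                raise ValueError(
                    f"edge above {child.label or 'internal node'} has no branch length"
                )
            P = model.transition_matrix(rate * child.length)
            L *= partial.pop(id(child)) @ P.T
        scale = L.max(axis=1)
        scale[scale == 0.0] = 1.0
        L /= scale[:, None]
        log_scale += np.log(scale)
        partial[id(node)] = L

    root_L = partial[id(tree.root)]
    site_like = root_L @ model.frequencies
    return np.log(np.maximum(site_like, _TINY)) + log_scale


def site_log_likelihood(
    column: Mapping[str, str] | Sequence[tuple[str, str]],
    tree: PhyloTree,
    model: SubstitutionModel,
    rate: float,
) -> float:
    """Log-likelihood of a single site, given as {taxon: residue}."""
    items = list(column.items()) if isinstance(column, Mapping) else list(column)
    aln = Alignment.from_sequences([t for t, _ in items], [c for _, c in items])
    return float(site_log_likelihoods(aln, tree, model, rate)[0])
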