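"""Long-branch taxon ranking and the crossed taxon x site dataset grid.

The design: score every taxon by the mean of its k largest tip-to-tip
(patristic) distances, remove the longest-branching taxa one at a time to get
nested taxon sets, re-estimate site rates for each set, and cross the sets
with a ladder of fast-site removal levels.  Each grid cell is a reduced
alignment, materialised lazily and identified by a content digest.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .alignment import Alignment
from .models import GammaRates, SubstitutionModel, lg_model
from .phylo import PhyloTree
from .rates import SiteRateProfile, estimate_gamma_shape, posterior_mean_rates, site_removal_order

__all__ = [
    "LBRanking",
    "GridConfig",
    "GridManifest",
    "lb_score",
    "rank_taxa",
    "nested_taxon_sets",
    "build_grid",
]


def lb_score(dist: pd.DataFrame, taxon: str, k: int = 10) -> float:
    """Mean of the k largest tip-to-tip distances involving ``taxon``.

    With fewer than k other taxa, all available distances are averaged.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if taxon not in dist.index:
        raise KeyError(f"taxon {taxon!r} not in distance matrix")
    row = dist.loc[taxon].drop(labels=[taxon]).to_numpy(dtype=float)
    if row.size == 0:
        raise ValueError("distance matrix has a single taxon")
    top = np.sort(row)[::-1][: min(k, row.size)]
    return float(top.mean())


@dataclass(frozen=True)
class LBRanking:
    """Taxa ordered from longest- to shortest-branching, with scores."""

    order: tuple[str, ...]
    scores: dict[str, float]

    def __post_init__(self):
        if set(self.order) != set(self.scores):
            raise ValueError("ranking order and scores disagree on taxa")

    def top(self, n: int) -> list[str]:
        return list(self.order[:n])


def rank_taxa(tree: PhyloTree, k: int = 10) -> LBRanking:
    """Score and sort all taxa by LB score (descending; ties lexicographic).

    Computed once from the full tree; the sequential removals below reuse
    this single sort rather than re-ranking after each deletion.
    """
    dist = tree.patristic_distance_matrix()
    scores = {t: lb_score(dist, t, k) for t in dist.index}
    order = tuple(sorted(scores, key=lambda t: (-scores[t], t)))
    return LBRanking(order=order, scores=scores)


def nested_taxon_sets(taxa: Sequence[str], ranking: LBRanking, n_remove: int) -> list[list[str]]:
    """Set 0 = all taxa; set i removes the i longest-branching taxa."""
    taxa = list(taxa)
    if n_remove > len(taxa) - 4:
        raise ValueError(f"removing {n_remove} of {len(taxa)} taxa leaves fewer than 4")
    missing = set(ranking.order) - set(taxa)
    if missing:
        raise ValueError(f"ranking covers taxa not in the alignment: {sorted(missing)}")
    sets = [taxa]
    current = taxa
    for victim in ranking.order[:n_remove]:
        current = [t for t in current if t != victim]
        sets.append(current)
    return sets


@dataclass(frozen=True)
class GridConfig:
    """Parameters of the taxon x site removal grid."""

    k: int = 10
    n_remove_taxa: int = 35
    site_step: int = 1000
    max_sites_removed: int = 30000
    n_bootstrap: int = 100
    seed: int = 0

    def __post_init__(self):
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.site_step < 1 or self.max_sites_removed < 1:
            raise ValueError("site_step and max_sites_removed must be positive")
        if self.max_sites_removed % self.site_step != 0:
            raise ValueError("site_step must divide max_sites_removed")
        if self.n_remove_taxa < 0:
            raise ValueError("n_remove_taxa must be >= 0")
        if self.n_bootstrap < 1:
            raise ValueError("n_bootstrap must be >= 1")

    @property
    def levels(self) -> list[int]:
        """Non-zero site-removal levels: step, 2*step, ..., max."""
        return list(range(self.site_step, self.max_sites_removed + 1, self.site_step))

    def validate_against(self, alignment: Alignment) -> None:
        if self.n_remove_taxa > alignment.n_taxa - 4:
            raise ValueError(
                f"removing {self.n_remove_taxa} of {alignment.n_taxa} taxa leaves fewer than 4"
            )
        if self.max_sites_removed >= alignment.n_sites:
            raise ValueError(
                f"cannot remove {self.max_sites_removed} of {alignment.n_sites} sites"
            )


class GridManifest:
    """The full -FS/LB design: nested taxon sets x site-removal levels.

    Rate profiles (and hence per-set site-removal orders) can be computed
    eagerly or on first use; cell digests are recorded as cells are
    materialised.  Cell (i, L) is taxon set i with the L fastest sites (by
    that set's rate profile) removed; the printed cell count covers the
    non-zero levels only, with level 0 available as the reference column.
    """

    def __init__(
        self,
        alignment: Alignment,
        tree: PhyloTree,
        config: GridConfig,
        ranking: LBRanking,
        taxon_sets: list[list[str]],
        model: SubstitutionModel,
        gamma_by_set: "dict[int, GammaRates] | GammaRates",
        estimate_per_set: bool = True,
    ):
        config.validate_against(alignment)
        self.alignment = alignment
        self.tree = tree
        self.config = config
        self.ranking = ranking
        self.taxon_sets = taxon_sets
        self.model = model
        self._gamma_by_set = gamma_by_set
        self.estimate_per_set = estimate_per_set
        self._profiles: dict[int, SiteRateProfile] = {}
        self._orders: dict[int, np.ndarray] = {}
        self.digests: dict[tuple[int, int], str] = {}

    # -- bookkeeping -------------------------------------------------------

    @property
    def levels(self) -> list[int]:
        return self.config.levels

    @property
    def n_cells(self) -> int:
        return len(self.taxon_sets) * len(self.levels)

    def cells(self):
        """Iterate (set_index, level) over the counted (non-zero) cells."""
        for i in range(len(self.taxon_sets)):
            for level in self.levels:
                yield i, level

    def cell_shape(self, set_index: int, level: int) -> tuple[int, int]:
        return len(self.taxon_sets[set_index]), self.alignment.n_sites - level

    def gamma_for(self, set_index: int) -> GammaRates:
        if isinstance(self._gamma_by_set, GammaRates):
            return self._gamma_by_set
        return self._gamma_by_set[set_index]

    # -- rates -------------------------------------------------------------

    def rate_profile(self, set_index: int) -> SiteRateProfile:
        """The rate profile for one taxon set (computed and cached on demand).

        Rates are re-estimated per taxon set on the full tree pruned to that
        set (``estimate_per_set=True``), or the full-set profile is reused.
        """
        key = set_index if self.estimate_per_set else 0
        if key not in self._profiles:
            taxa = self.taxon_sets[key]
            sub = self.alignment.subset_taxa(taxa)
            subtree = (
                self.tree.prune_taxa(set(self.tree.tip_labels) - set(taxa))
                if set(taxa) != set(self.tree.tip_labels)
                else self.tree
            )
            self._profiles[key] = posterior_mean_rates(sub, subtree, self.model, self.gamma_for(key))
        return self._profiles[key]

    def removal_order(self, set_index: int) -> np.ndarray:
        key = set_index if self.estimate_per_set else 0
        if key not in self._orders:
            self._orders[key] = site_removal_order(self.rate_profile(set_index))
        return self._orders[key]

    # -- materialisation ---------------------------------------------------

    def materialize(self, set_index: int, level: int) -> Alignment:
        """Build the cell's alignment: taxon subset, fastest ``level`` sites cut."""
        if not 0 <= set_index < len(self.taxon_sets):
            raise IndexError(f"no taxon set {set_index}")
        if level != 0 and level not in self.levels:
            raise ValueError(f"level {level} not in the grid")
        sub = self.alignment.subset_taxa(self.taxon_sets[set_index])
        if level:
            doomed = self.removal_order(set_index)[:level]
            keep = np.setdiff1d(np.arange(sub.n_sites), doomed)
            sub = sub.select_site_positions(keep)
        expected = self.cell_shape(set_index, level)
        assert sub.shape == expected, f"cell {(set_index, level)}: {sub.shape} != {expected}"
        self.digests[(set_index, level)] = hashlib.sha256(sub.to_fasta().encode()).hexdigest()
        return sub

    # -- persistence -------------------------------------------------------

    def summary(self) -> dict:
        return {
            "n_taxa": self.alignment.n_taxa,
            "n_sites": self.alignment.n_sites,
            "n_taxon_sets": len(self.taxon_sets),
            "levels": self.levels,
            "n_cells": self.n_cells,
            "config": {
                "k": self.config.k,
                "n_remove_taxa": self.config.n_remove_taxa,
                "site_step": self.config.site_step,
                "max_sites_removed": self.config.max_sites_removed,
                "n_bootstrap": self.config.n_bootstrap,
                "seed": self.config.seed,
            },
            "ranking": list(self.ranking.order),
            "lb_scores": {t: self.ranking.scores[t] for t in self.ranking.order},
            "taxon_sets": [list(s) for s in self.taxon_sets],
            "estimate_per_set": self.estimate_per_set,
            "model": self.model.name,
            "digests": {f"{i},{lvl}": d for (i, lvl), d in sorted(self.digests.items())},
        }

    def save(self, directory, write_profiles: bool = True) -> Path:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        path = directory / "manifest.json"
        with open(path, "w") as fh:
            json.dump(self.summary(), fh, indent=2, sort_keys=True)
            fh.write("\n")
        if write_profiles:
            for key in sorted(self._profiles):
                self._profiles[key].to_tsv(directory / f"rates_set{key:03d}.tsv")
        return path


def build_grid(
    alignment: Alignment,
    tree: PhyloTree,
    config: GridConfig,
    model: Optional[SubstitutionModel] = None,
    gamma: Optional[GammaRates] = None,
    n_rate_categories: int = 20,
    estimate_per_set: bool = True,
    eager_rates: bool = False,
) -> GridManifest:
    """Assemble the -FS/LB grid manifest.

    The gamma shape is estimated once on the full alignment (4 categories)
    unless ``gamma`` is supplied, then posterior-mean rates use
    ``n_rate_categories`` categories.  With ``eager_rates`` every taxon set's
    profile is computed up front; otherwise profiles are computed when a cell
    at a non-zero level is first materialised, which keeps plain grid
    enumeration instant even at supermatrix scale.
    """
    config.validate_against(alignment)
    if set(alignment.taxa) != set(tree.tip_labels):
        raise ValueError("alignment taxa and tree tips differ")
    model = model or lg_model()
    ranking = rank_taxa(tree, config.k)
    sets = nested_taxon_sets(alignment.taxa, ranking, config.n_remove_taxa)
    if gamma is None:
        alpha = estimate_gamma_shape(alignment, tree, model, n_categories=4)
        gamma = GammaRates(alpha, n_rate_categories)
    manifest = GridManifest(
        alignment, tree, config, ranking, sets, model, gamma, estimate_per_set=estimate_per_set
    )
    if eager_rates:
        for i in range(len(sets)):
            manifest.rate_profile(i)
    return manifest
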