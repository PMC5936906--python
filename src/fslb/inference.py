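"""Desk-scale tree inference and bootstrap support.

The engine is deliberately cheap: maximum-likelihood pairwise distances under
the substitution model, followed by neighbor joining.  That trades the
cluster-scale ML programs' accuracy for the ability to run thousands of grid
cells on a laptop, while still being model-corrected enough to express (and
lose, as sites and taxa are removed) the long-branch-attraction artefacts this
package exists to dissect.

Two distance paths share one likelihood:

* :func:`model_corrected_distance` — bounded Brent optimisation of the
  two-sequence likelihood, accurate to the optimiser tolerance; the public,
  exact route.
* :class:`DistanceEngine` — a log-spaced lookup table over branch lengths
  with parabolic refinement, evaluating *all* pairs per bootstrap replicate
  with one matrix product; the rapid-bootstrap route.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .alignment import MISSING, Alignment
from .grid import GridConfig, GridManifest
from .models import SubstitutionModel
from .phylo import Bipartition, Node, PhyloTree, splits_compatible

__all__ = [
    "T_MAX",
    "CladeDefinition",
    "CladeSupport",
    "SupportSurface",
    "model_corrected_distance",
    "distance_matrix",
    "DistanceEngine",
    "neighbor_joining",
    "bootstrap_support",
    "clade_support",
    "support_surface",
    "conflicting_bipartitions",
]

T_MAX = 20.0  # expected substitutions/site; far beyond saturation for AA data
_TINY = 1e-300


# ---------------------------------------------------------------------------
# Pairwise distances


def _pair_counts(a: np.ndarray, b: np.ndarray) -> Optional[np.ndarray]:
    """20x20 matrix of joint residue counts over shared non-missing columns."""
    shared = (a != MISSING) & (b != MISSING)
    if not shared.any():
        return None
    idx = a[shared].astype(np.int64) * 20 + b[shared]
    return np.bincount(idx, minlength=400).astype(float).reshape(20, 20)


def _counts_log_likelihood(counts: np.ndarray, model: SubstitutionModel, t: float) -> float:
    P = model.transition_matrix(t)
    joint = model.frequencies[:, None] * P
    return float(np.sum(counts * np.log(np.maximum(joint, _TINY))))


def model_corrected_distance(
    seq_a: str | np.ndarray,
    seq_b: str | np.ndarray,
    model: SubstitutionModel,
    t_max: float = T_MAX,
) -> float:
    """ML branch length between two sequences under the model.

    Returns NaN when the sequences share no informative column (the caller
    imputes), 0.0 for identical overlap, and caps at ``t_max`` when the
    likelihood is still rising there (saturation).
    """
    a = _encode_arg(seq_a)
    b = _encode_arg(seq_b)
    if a.shape != b.shape:
        raise ValueError("sequences must have equal length")
    counts = _pair_counts(a, b)
    if counts is None:
        return float("nan")
    if counts.sum() == np.trace(counts):
        return 0.0

    res = minimize_scalar(
        lambda t: -_counts_log_likelihood(counts, model, t),
        bounds=(1e-12, t_max),
        method="bounded",
        options={"xatol": 1e-10},
    )
    t_hat = float(res.x)
    # Saturated pairs push the optimum onto the upper bound; report the cap.
    if t_max - t_hat < 1e-6 * t_max and (
        _counts_log_likelihood(counts, model, t_max) >= -res.fun - 1e-9
    ):
        return t_max
    return t_hat


def _encode_arg(seq) -> np.ndarray:
    if isinstance(seq, str):
        return Alignment.from_sequences(["x"], [seq]).data[0]
    return np.asarray(seq, dtype=np.int8)


class DistanceEngine:
    """Fast all-pairs ML distances for bootstrap resampling.

    The pair log-likelihood at branch length t is sum_ij N_ij log(pi_i
    P_ij(t)); over a fixed t-grid this is one (grid x 400) @ (400 x pairs)
    product.  The grid argmax is then refined by a parabolic step in log t,
    which is accurate to ~1e-4 — far below what NJ topology needs.
    """

    def __init__(self, model: SubstitutionModel, t_max: float = T_MAX, grid_size: int = 200):
        self.model = model
        self.t_max = t_max
        self.log_t = np.linspace(np.log(1e-4), np.log(t_max), grid_size)
        self.ts = np.exp(self.log_t)
        logP = np.empty((grid_size, 400))
        for g, t in enumerate(self.ts):
            joint = model.frequencies[:, None] * model.transition_matrix(t)
            logP[g] = np.log(np.maximum(joint, _TINY)).ravel()
        self._logP = logP

    def prepare(self, alignment: Alignment) -> "_PreparedPairs":
        return _PreparedPairs(alignment)

    def matrix(
        self,
        prepared: "_PreparedPairs",
        site_weights: Optional[np.ndarray] = None,
    ) -> np.ndarray:
        """Distance matrix (NaN where a pair shares no sampled column)."""
        counts = prepared.counts(site_weights)  # (400, n_pairs)
        n = prepared.n_taxa
        ll = self._logP @ counts  # (grid, n_pairs)
        best = np.argmax(ll, axis=0)
        dist = np.empty(counts.shape[1])
        for p in range(counts.shape[1]):
            total = prepared.pair_totals[p] if site_weights is None else counts[:, p].sum()
            if total == 0:
                dist[p] = np.nan
                continue
            diag = counts[::21, p].sum()
            if diag == total:
                dist[p] = 0.0
                continue
            g = best[p]
            if g == 0 or g == len(self.ts) - 1:
                dist[p] = self.ts[g]
                continue
            # Parabolic refinement in log t through the three bracketing points.
            y0, y1, y2 = ll[g - 1, p], ll[g, p], ll[g + 1, p]
            x0, x1, x2 = self.log_t[g - 1], self.log_t[g], self.log_t[g + 1]
            denom = (y0 - y1) * (x2 - x1) + (y2 - y1) * (x1 - x0)
            if denom >= 0:
                dist[p] = self.ts[g]
            else:
                shift = 0.5 * ((y0 - y1) * (x2 - x1) ** 2 - (y2 - y1) * (x1 - x0) ** 2) / denom
                dist[p] = float(np.exp(x1 + shift))
        out = np.zeros((n, n))
        iu = np.triu_indices(n, 1)
        out[iu] = dist
        out += out.T
        return out


class _PreparedPairs:
    """Per-alignment precomputation: joint-state index per pair per column."""

    def __init__(self, alignment: Alignment):
        self.n_taxa = alignment.n_taxa
        self.n_sites = alignment.n_sites
        data = alignment.data
        pairs = []
        for i in range(self.n_taxa):
            for j in range(i + 1, self.n_taxa):
                shared = (data[i] != MISSING) & (data[j] != MISSING)
                pos = np.flatnonzero(shared)
                idx = data[i, pos].astype(np.int64) * 20 + data[j, pos]
                pairs.append((pos, idx))
        self.pairs = pairs
        self.pair_totals = np.array([len(pos) for pos, _ in pairs], dtype=float)
        self._base: Optional[np.ndarray] = None

    def counts(self, site_weights: Optional[np.ndarray]) -> np.ndarray:
        """(400, n_pairs) joint counts, optionally site-weighted (bootstrap)."""
        if site_weights is None:
            if self._base is None:
                self._base = np.stack(
                    [np.bincount(idx, minlength=400) for _, idx in self.pairs], axis=1
                ).astype(float)
            return self._base
        return np.stack(
            [
                np.bincount(idx, weights=site_weights[pos], minlength=400)
                for pos, idx in self.pairs
            ],
            axis=1,
        )


def distance_matrix(
    alignment: Alignment,
    model: SubstitutionModel,
    method: str = "exact",
    engine: Optional[DistanceEngine] = None,
) -> pd.DataFrame:
    """All-pairs model-corrected distances (NaN marks undefined pairs)."""
    if method == "exact":
        n = alignment.n_taxa
        out = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                out[i, j] = out[j, i] = model_corrected_distance(
                    alignment.data[i], alignment.data[j], model
                )
        return pd.DataFrame(out, index=alignment.taxa, columns=alignment.taxa)
    if method == "grid":
        engine = engine or DistanceEngine(model)
        mat = engine.matrix(engine.prepare(alignment))
        return pd.DataFrame(mat, index=alignment.taxa, columns=alignment.taxa)
    raise ValueError(f"unknown method {method!r}")


def impute_undefined(dist: np.ndarray) -> np.ndarray:
    """Replace NaN distances with the matrix maximum (conservative)."""
    if not np.isnan(dist).any():
        return dist
    finite = dist[np.isfinite(dist)]
    fill = finite.max() if finite.size else T_MAX
    out = dist.copy()
    out[np.isnan(out)] = fill
    np.fill_diagonal(out, 0.0)
    return out


# ---------------------------------------------------------------------------
# Neighbor joining


def neighbor_joining(dist: pd.DataFrame | np.ndarray, labels: Optional[Sequence[str]] = None) -> PhyloTree:
    """Standard NJ agglomeration; consistent on additive (tree) metrics.

    Negative inferred branch lengths are clamped to zero with the deficit
    shifted to the sister edge (their sum — the joined pair's distance — is
    preserved).
    """
    if isinstance(dist, pd.DataFrame):
        labels = list(dist.index)
        D = dist.to_numpy(dtype=float).copy()
    else:
        D = np.asarray(dist, dtype=float).copy()
        if labels is None:
            raise ValueError("labels required with a bare matrix")
        labels = list(labels)
    n = len(labels)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    if np.isnan(D).any():
        raise ValueError("undefined distances: impute before neighbor joining")

    nodes: list[Node] = [Node(label=l) for l in labels]
    active = list(range(n))

    def clamp_pair(vi: float, vj: float) -> tuple[float, float]:
        if vi < 0:
            vi, vj = 0.0, vj + vi
        if vj < 0:
            vi, vj = vi + vj, 0.0
        return max(vi, 0.0), max(vj, 0.0)

    while len(active) > 3:
        m = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        Q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        ai, aj = np.unravel_index(np.argmin(Q), Q.shape)
        if ai > aj:
            ai, aj = aj, ai
        i, j = active[ai], active[aj]
        d_ij = D[i, j]
        vi = 0.5 * d_ij + (r[ai] - r[aj]) / (2 * (m - 2))
        vj = d_ij - vi
        vi, vj = clamp_pair(vi, vj)
        parent = Node()
        nodes[i].length = vi
        nodes[j].length = vj
        parent.children = [nodes[i], nodes[j]]
        # distances from the new node to the rest
        new_row = 0.5 * (D[i, :] + D[j, :] - d_ij)
        D[i, :] = new_row
        D[:, i] = new_row
        D[i, i] = 0.0
        nodes[i] = parent
        active.remove(j)

    a, b, c = active
    va = 0.5 * (D[a, b] + D[a, c] - D[b, c])
    vb = 0.5 * (D[a, b] + D[b, c] - D[a, c])
    vc = 0.5 * (D[a, c] + D[b, c] - D[a, b])
    root = Node()
    for idx, v in ((a, va), (b, vb), (c, vc)):
        nodes[idx].length = max(v, 0.0)
        root.children.append(nodes[idx])
    return PhyloTree(root)


# ---------------------------------------------------------------------------
# Bootstrap support


def bootstrap_support(
    alignment: Alignment,
    model: SubstitutionModel,
    n_replicates: int = 100,
    seed: int = 0,
    engine: Optional[DistanceEngine] = None,
) -> dict[Bipartition, float]:
    """Split support from site-resampled NJ replicates, in percent.

    Each replicate resamples columns with replacement (preserving length),
    rebuilds distances and an NJ tree, and tallies its non-trivial splits.
    Identical (alignment, seed) gives identical output.
    """
    if n_replicates < 1:
        raise ValueError("need at least one bootstrap replicate")
    if alignment.n_taxa < 4:
        raise ValueError("bootstrap support needs >= 4 taxa")
    engine = engine or DistanceEngine(model)
    prepared = engine.prepare(alignment)
    rng = np.random.default_rng(seed)
    tally: dict[Bipartition, int] = {}
    for _ in range(n_replicates):
        draws = rng.integers(0, alignment.n_sites, alignment.n_sites)
        weights = np.bincount(draws, minlength=alignment.n_sites).astype(float)
        D = impute_undefined(engine.matrix(prepared, site_weights=weights))
        tree = neighbor_joining(D, labels=alignment.taxa)
        for split in tree.splits_of():
            tally[split] = tally.get(split, 0) + 1
    return {s: 100.0 * c / n_replicates for s, c in tally.items()}


# ---------------------------------------------------------------------------
# Clades and surfaces


@dataclass(frozen=True)
class CladeDefinition:
    """A named clade, defined on the full taxon universe."""

    name: str
    members: frozenset

    def __init__(self, name: str, members: Iterable[str]):
        object.__setattr__(self, "name", name)
        object.__setattr__(self, "members", frozenset(members))
        if not self.members:
            raise ValueError("clade must have at least one member")


@dataclass(frozen=True)
class CladeSupport:
    value: Optional[float]  # percent, or None when undefined
    status: str  # "ok" | "trivial" | "undefined"


def clade_support(
    split_map: dict[Bipartition, float],
    clade: CladeDefinition,
    retained: Iterable[str],
) -> CladeSupport:
    """Support for the clade's split on a (possibly reduced) taxon set.

    The clade is intersected with the retained taxa; singleton or full
    intersections cannot conflict with anything and return 100 flagged
    trivial; an empty intersection is undefined.
    """
    retained = frozenset(retained)
    inside = clade.members & retained
    if not inside:
        return CladeSupport(None, "undefined")
    outside = retained - inside
    if len(inside) == 1 or not outside:
        return CladeSupport(100.0, "trivial")
    if len(outside) == 1:
        return CladeSupport(100.0, "trivial")
    target = Bipartition(inside, outside)
    return CladeSupport(split_map.get(target, 0.0), "ok")


@dataclass
class SupportSurface:
    """Bootstrap support for one clade across the grid.

    Rows follow the taxon sets in removal order; columns are site-removal
    levels ascending, level 0 included as the reference column.  NaN marks
    cells where the clade's intersection with the retained taxa is empty.
    """

    clade_name: str
    values: np.ndarray  # (n_sets, n_levels) percent or NaN
    statuses: np.ndarray  # same shape, dtype object
    row_labels: list[int]  # taxa removed
    col_labels: list[int]  # sites removed
    n_replicates: int
    seed: int

    def to_tsv(self, path=None) -> str:
        lines = ["taxa_removed\\sites_removed\t" + "\t".join(str(c) for c in self.col_labels)]
        for r, row in zip(self.row_labels, self.values):
            cells = ["NA" if np.isnan(v) else f"{v:.1f}" for v in row]
            lines.append(f"{r}\t" + "\t".join(cells))
        text = "\n".join(lines) + "\n"
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def cell_seed(master_seed: int, set_index: int, level: int) -> int:
    """Deterministic per-cell seed so any cell is independently rerunnable."""
    ss = np.random.SeedSequence(entropy=master_seed, spawn_key=(set_index, level))
    return int(ss.generate_state(1, dtype=np.uint32)[0])


def support_surface(
    manifest: GridManifest,
    clade: CladeDefinition,
    model: SubstitutionModel,
    n_replicates: Optional[int] = None,
    seed: Optional[int] = None,
    include_level_zero: bool = True,
    engine: Optional[DistanceEngine] = None,
) -> SupportSurface:
    """Evaluate bootstrap clade support at every grid cell."""
    cfg = manifest.config
    n_replicates = cfg.n_bootstrap if n_replicates is None else n_replicates
    seed = cfg.seed if seed is None else seed
    levels = ([0] if include_level_zero else []) + manifest.levels
    n_sets = len(manifest.taxon_sets)
    values = np.full((n_sets, len(levels)), np.nan)
    statuses = np.empty((n_sets, len(levels)), dtype=object)
    engine = engine or DistanceEngine(model)
    for i in range(n_sets):
        retained = manifest.taxon_sets[i]
        for c, level in enumerate(levels):
            try:
                cell = manifest.materialize(i, level)
                support = bootstrap_support(
                    cell, model, n_replicates, seed=cell_seed(seed, i, level), engine=engine
                )
                cs = clade_support(support, clade, retained)
            except Exception as exc:
                raise RuntimeError(f"surface cell (set {i}, level {level}) failed: {exc}") from exc
            statuses[i, c] = cs.status
            if cs.value is not None:
                values[i, c] = cs.value
    return SupportSurface(
        clade_name=clade.name,
        values=values,
        statuses=statuses,
        row_labels=list(range(n_sets)),
        col_labels=levels,
        n_replicates=n_replicates,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Conflict screen


def conflicting_bipartitions(
    gene_tree: PhyloTree,
    reference: PhyloTree,
    threshold: float = 70.0,
) -> list[tuple[Bipartition, float, Bipartition]]:
    """Well-supported gene-tree splits that contradict the reference tree.

    Both trees are restricted to their shared taxa; every gene-tree split
    with support strictly above ``threshold`` that is incompatible with at
    least one reference split is returned as (gene split, support,
    conflicting reference split).
    """
    shared = set(gene_tree.tip_labels) & set(reference.tip_labels)
    if len(shared) < 4:
        raise ValueError(f"only {len(shared)} shared taxa; need >= 4")
    g = gene_tree if set(gene_tree.tip_labels) == shared else gene_tree.prune_taxa(
        set(gene_tree.tip_labels) - shared
    )
    ref = reference if set(reference.tip_labels) == shared else reference.prune_taxa(
        set(reference.tip_labels) - shared
    )
    ref_splits = sorted(ref.splits_of(), key=lambda s: sorted(sorted(side) for side in s.sides))
    out = []
    for split, support in sorted(
        g.split_support_map().items(), key=lambda kv: sorted(sorted(side) for side in kv[0].sides)
    ):
        if support is None or support <= threshold:
            continue
        for rsplit in ref_splits:
            if not splits_compatible(split, rsplit):
                out.append((split, support, rsplit))
                break
    return out
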