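# Methods

This note documents the models, estimators and design choices behind the
package, in the spirit of a methods appendix: what is computed, under which
assumptions, and where the desk-scale engine deliberately diverges from the
cluster-scale programs this kind of analysis is usually run with.

## Scope and overall design

The pipeline dissects phylogenomic signal by deletion. Its unit operations
are: (1) rank taxa by a long-branch score; (2) estimate per-site relative
evolutionary rates on a fixed tree; (3) cross nested taxon sets with a
ladder of fast-site removal levels into a grid of reduced alignments;
(4) compute bootstrap support for named clades in every grid cell;
(5) screen support-annotated gene trees for conflicts with a reference
topology. Everything runs at desk scale on synthetic data; file-level
interchange (FASTA, relaxed PHYLIP, Newick, TSV, JSON) lets users swap any
internal stage for an external program.

All split and distance logic treats trees as unrooted: the long-branch
metric is built from tip-to-tip path lengths precisely so that the unknown
root position cannot bias the ranking. "Clade support" everywhere means
support for the corresponding unrooted bipartition.

## Long-branch score

A taxon's score is the mean of its `k` largest patristic distances
(default `k = 10`). The ranking is computed once on the full tree and reused
for all removals — the procedure is a single sort, not an iterative
re-ranking. When fewer than `k` other taxa remain (possible in small
synthetic runs), all available distances are averaged. Ties break
lexicographically by label so grids are reproducible.

## Substitution model and likelihood

The bundled model is LG (empirical amino-acid exchangeabilities and
frequencies; `src/fslb/data/lg.tsv`), assembled as a reversible rate matrix
Q_ij = s_ij π_j normalised to one expected substitution per unit branch
length (checked to 1e-10). Transition matrices come from one symmetric
eigendecomposition, so the thousands of P(t) evaluations in rate grids and
bootstraps are cheap and numerically stable; rows are clipped at zero and
renormalised, and are stochastic to 1e-10 at every length used.

Site likelihoods use Felsenstein pruning, vectorised across sites, with
per-node rescaling against underflow. Gaps and ambiguity codes are missing
data (all-ones conditionals), as are tips absent from the alignment. An
equal-frequency, equal-exchangeability 20-state model is provided for
closed-form cross-checks.

## Site rates

Among-site rate variation is the standard discrete gamma: C
equal-probability categories, each represented by its conditional mean, so
the category mean rate is exactly 1 for every shape α. The shape is fitted
by bounded 1-D ML search on log α over [0.02, 100] (4 categories by
default); effectively homogeneous data is reported at the upper bound.

Per-site rates are posterior means over categories under a uniform prior —
the same conditional-mean quantity the dedicated site-rate programs report,
and fully specified here. The proportion of invariable sites defaults to 0
for rate estimation: Γ alone determines the ranking, and only the ranking
feeds the removal sort. Rates default to C = 20 categories for resolution
of the ranking's tails. Sites with no observed characters carry no
information and receive the prior mean exactly.

Fast-site removal sorts descending by rate, breaking ties by removing the
higher original column index first (deterministic grids). Columns are
tracked by original 1-based index through every filter, and rates are
re-estimated per taxon set (on the full tree pruned to that set) because
removing a long-branch taxon changes which sites look fast. Columns that
become gap-only after taxon removal are retained, keeping the site-count
arithmetic of the grid exact.

## The grid

Nested taxon sets (full set, then one taxon removed per step in ranking
order) are crossed with removal levels (step, 2·step, …, max). The counted
grid covers the non-zero levels — e.g. 36 sets × 30 levels = 1 080 datasets
at the defaults (k = 10, 35 removals, steps of 1 000 up to 30 000) — with
level 0 available as the reference column of every surface. Cells are
materialised lazily (the removal ladder for a taxon set needs that set's
rate profile, computed on first use and cached), so enumerating a
supermatrix-scale grid is instant while any individual cell remains
reproducible: cell seeds derive from (master seed, set index, level), and
materialised cells get SHA-256 content digests. Scaled-down configurations
are first-class; the step, maximum and replicate count are plain
parameters.

## Inference engine

The support engine is model-corrected ML pairwise distances + neighbor
joining — not full ML tree search. The grid needs thousands of cheap
inferences, and a distance engine that corrects with a rate-homogeneous LG
model is exactly the kind of under-parameterised method that *expresses*
long-branch attraction when rate heterogeneity and saturation are present,
which is the phenomenon the pipeline exists to dissect. The NJ
implementation clamps negative branch lengths to zero, shifting the deficit
to the sister edge so the joined pair's distance is preserved; on exact
additive matrices it recovers the generating topology.

Two distance paths share one likelihood. The public
`model_corrected_distance` maximises the two-sequence likelihood by bounded
Brent iteration (tolerance 1e-10 on t, capped at t_max = 20 with saturation
reported at the cap; this matches the 20-state equal-rates closed form
−(19/20)·ln(1−(20/19)p) to better than 1e-6). Bootstrap replicates instead
evaluate all pairs on a 200-point log-spaced branch-length grid with one
matrix product per replicate, refined by a parabolic step in log t —
accurate to ~1e-4, far below what NJ topology resolution requires, and an
order of magnitude faster. Pairs with no shared sampled columns are
undefined and imputed with the matrix maximum (conservative: it keeps the
replicate usable without inventing proximity).

Bootstrap support resamples columns with replacement preserving alignment
length, accumulates non-trivial split frequencies, and is a pure function
of (alignment, seed). Clade support on a reduced taxon set uses the clade's
intersection with the retained taxa; singleton or complement-singleton
intersections are 100% by convention and flagged `trivial`, empty
intersections are `undefined` (NaN in surfaces, hatched in heat maps).
Heat maps use a linear white→red ramp, 0% → pure white, 100% → pure red.

## Conflict screen

Gene tree and reference are restricted to their shared taxa (≥ 4 required);
every gene-tree split with support strictly above the threshold (default
70) that is four-point-incompatible with some reference split is reported
together with the first conflicting reference split. Splits without a
support annotation are never reported.

## Synthetic data

The simulator draws each site's rate from the discrete-Γ categories, the
root state from the equilibrium frequencies, and evolves down the tree edge
by edge; it never generates gaps (missingness is a separate random masking
utility, so coverage regimes can be emulated without entangling the
evolutionary process). Same seed, same alignment.

The LBA scenario is two balanced clades joined by a short central stem
(0.02 substitutions/site per side), background pendants of 0.12 and internal
edges of 0.05, with one designated long-branch taxon per clade whose pendant
is inflated by the long-branch multiplier (default 8). A fast fraction of
sites (default 30%) evolves faster by a fixed multiplier (default 6). This
is the classical attraction-prone geometry: the pair's mutual distance is
underestimated by the rate-homogeneous correction much more severely than
background distances, and the short stem provides little true signal to
resist the pull. A multiplier of 1 with no fast sites is the control, on
which the engine recovers the true clade with ≥ 95% bootstrap at 2 000
sites. The true clade (one full side) and artifact clade (the long-branch
pair) are incompatible by construction.

What the generator does *not* emulate: heterotachy, compositional
heterogeneity, indels, gene-wise conflict, or empirical profile mixtures.
Passing tests therefore show that the pipeline's operations behave correctly
under the model class they assume, and that the engine can both express and
lose a classical artefact — not that any particular real dataset's support
values would be reproduced.

## Problem sizes and determinism

Default experiment sizes are chosen so the full test suite and the
acceptance script each run in minutes on one core: rate recovery uses 16
taxa × 2 000 sites (5 000 for shape recovery), attraction sweeps use 20
scenario replicates of 12 taxa × 2 000 sites with 50 bootstrap replicates
per grid cell, and grid-arithmetic checks enumerate (without bootstrapping)
the full 84 × 42 564 design. Every stochastic step is seeded; replicate
seeds derive from the master seed plus cell coordinates, so any single cell
can be recomputed in isolation.

On the taxon axis of a pair-defined artifact clade, removing one attractor
makes the clade trivial and removing both makes it undefined; support
decline along the grid is therefore measured to the maximal-removal cell at
which the clade is still non-trivially defined (the full-site-removal cell
of the intact taxon set), while the taxon axis shows its effect through the
true clade's rescue and the trivial/undefined flags.

## Known limitations

- The internal engine's absolute support values are not comparable to
  RAxML/IQ-TREE-style rapid or ultrafast bootstraps; only the qualitative
  geometry of the surfaces (declines, islands) is meaningful.
- Posterior-mean rates on a fixed tree inherit that tree's errors; the
  package deliberately re-uses the pruned full tree per taxon set rather
  than re-inferring, though re-inference via the internal engine is a
  one-line substitution.
- p_inv is carried by the model type but not used in rate ranking.
- Polytomies are accepted everywhere; paths through them are summed as-is.
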