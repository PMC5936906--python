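# fslb — fast-site / long-branch signal dissection for phylogenomics

Deep phylogenomic relationships are routinely confounded by long-branch
attraction (LBA): rapidly evolving lineages are pulled together by saturated,
multiply substituted sites rather than by shared history. A standard
diagnostic is to dissect the signal by deletion — remove the fastest-evolving
sites in steps, remove the longest-branching taxa one at a time, and watch
how bootstrap support for the contested clades responds across the crossed
grid of reduced datasets ("–FS/LB" analyses). Support that collapses as fast
sites disappear is suspect; support that emerges is signal the artefact was
masking.

`fslb` implements that dissection as a tested, reusable pipeline for
amino-acid supermatrices:

- **Long-branch scoring** — each taxon's LB score is the mean of its *k*
  largest tip-to-tip (patristic) distances (default *k* = 10), computed on
  the unrooted tree so the unknown root position is irrelevant. Taxa are
  removed in score order to give nested taxon sets.
- **Per-site rates** — discrete-gamma posterior-mean rates on a fixed tree:
  for site *i* with category rates *r₁…r_C* (equal-probability
  discretization, Γ shape α fitted by ML) and category likelihoods
  *L_i(r_c)* from Felsenstein pruning under LG,
  *rate_i = Σ_c r_c L_i(r_c) / Σ_c L_i(r_c)*. Only the ranking feeds the
  removal step.
- **The grid** — taxon sets × fast-site removal levels (e.g. 36 sets × 30
  levels of 1 000 sites = 1 080 datasets), each cell a materializable
  alignment with provenance digests.
- **Support surfaces** — per cell, model-corrected ML pairwise distances +
  neighbor joining under site-resampling bootstrap; support for named clades
  is collected into a matrix and rendered as the classic white (0% BP) to
  red (100% BP) heat map.
- **Conflict screen** — gene-tree bipartitions with bootstrap support above
  a threshold (default 70%) are cross-checked for incompatibility against a
  reference tree.
- **Synthetic data** — a simulator (LG + discrete Γ on a fixed tree) and an
  LBA scenario builder with designated long-branch taxa, a known true clade
  and a known artifact clade, so the whole pipeline is testable end to end
  without any external dataset.

## Worked example: inducing and curing an attraction artefact

```python
from fslb import (
    Bipartition, GridConfig, build_grid, distance_matrix, lg_model,
    make_lba_scenario, neighbor_joining, support_surface,
)

scen, aln = make_lba_scenario(n_background_taxa=10, n_sites=2000, seed=0)
model = lg_model()

# Full data: the long-branch pair L1+L2 (which the true tree does NOT show)
tree = neighbor_joining(distance_matrix(aln, model, method="grid"))
uni = set(aln.taxa)
artifact = Bipartition(scen.artifact_clade.members, uni - scen.artifact_clade.members)
print("artifact split in full-data tree:", artifact in tree.splits_of())

config = GridConfig(n_remove_taxa=1, site_step=500, max_sites_removed=1000,
                    n_bootstrap=50, seed=0)
manifest = build_grid(aln, scen.tree, config, model=model)
print(support_surface(manifest, scen.artifact_clade, model).to_tsv())
print(support_surface(manifest, scen.true_clade, model).to_tsv())
```

prints

```
artifact split in full-data tree: True
taxa_removed\sites_removed	0	500	1000
0	100.0	94.0	18.0
1	100.0	100.0	100.0

taxa_removed\sites_removed	0	500	1000
0	0.0	6.0	76.0
1	100.0	100.0	100.0
```

Read the first surface row by row: with all 12 taxa present, the spurious
long-branch pairing gets 100% bootstrap support on the full data, 94% after
the fastest 500 sites are removed, and collapses to 18% once half the sites
are gone. The true clade (second surface) shows the mirror image, rising
from 0% to 76% under the same removals. Row 1 removes the top-ranked
long-branch taxon, after which each clade's intersection with the retained
taxa is a single tip — trivially 100% by convention, flagged as such in the
surface's status matrix.

The same stages are scriptable from the shell (`fslb scenario`, `fslb rank`,
`fslb rates`, `fslb grid`, `fslb surface`, `fslb conflicts`, `fslb plot`,
`fslb run`); `fslb run --config run.json` executes the whole assessment and
writes surfaces, heat maps, logs and a digest manifest to an output
directory.

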