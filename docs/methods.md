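# Methods

## Model and procedure

`fosnet` treats counts of Fos-positive nuclei per brain region, per
animal, as a snapshot of regional neural activity and asks how regions
co-activate across the animals of a treatment group.  The pipeline is:

1. **log10 normalization.**  x = log10(count + pseudocount), elementwise.
   Counts span orders of magnitude (tens to thousands); the log brings
   regions onto a comparable scale so that no high-count region dominates
   the correlation structure.  Default pseudocount = 1: log10(0) is
   undefined and zero counts can occur in small regions; +1 leaves zeros
   at 0 on the log scale and shifts a count of 1000 by < 0.0005.
   Fractional input counts are rejected rather than rounded — they
   indicate malformed data, not a unit choice.

2. **Functional connectivity.**  The group's connectivity matrix is the
   sample Pearson correlation of log activity between every region pair
   across animals, computed per group with no pooling.  No p-values or
   significance filtering: edges are selected by magnitude downstream.
   At least 3 animals are required (r from 2 points is ±1 degenerately);
   a warning is emitted at 3–5 animals, where single-animal fluctuations
   still move coefficients materially.  A region constant across animals
   has undefined correlations; its entries are recorded as 0 with a
   warning naming the region.  This keeps the full region frame (a
   zero-variance region can never pass the edge threshold anyway);
   dropping the region was rejected because every table in the pipeline
   is indexed by the full atlas.

3. **Module detection.**  The distance between regions i and j is the
   Euclidean norm of the difference of their *full* correlation-matrix
   rows, including the i-th and j-th (self-correlation) coordinates.
   Including the self coordinates is the simplest consistent reading of
   "distance between correlation profiles"; it inflates every
   between-region distance by a similar amount (the diagonal contributes
   (1 − r_ij)² twice) and in practice does not reorder merges for the
   matrices seen here, but the convention is fixed and used identically
   by the test oracle.  Distances are clustered by complete linkage
   (inter-cluster distance = maximum member distance), which is monotone:
   merge heights never decrease.  Modules are the flat clusters after
   applying all merges with height ≤ cut_fraction × (final merge height),
   default cut_fraction = 0.5 ("half the tree height").  The "≤" makes
   fraction 1.0 give exactly one module and fraction 0.0 separate all
   distinct regions.  Module ids are assigned 1..N in order of each
   module's smallest region index, since no external numbering is
   canonical.  `module_count_sweep` recomputes the partition over a grid
   of fractions (default 0.1..1.0 by 0.1) to show how sensitive the
   module count is to the cut choice; nested cuts guarantee the count is
   non-increasing in the fraction.

4. **Graph construction.**  Edge (i, j) is kept iff r_ij ≥ edge
   threshold, default 0.75, boundary inclusive (the threshold is
   configurable and the inclusivity documented; at float precision the
   boundary case is measure-zero).  Only positive weights can pass a
   positive threshold, so the graph is positively weighted by
   construction; negative connectivity is out of scope.  All atlas
   regions remain as nodes, so a region disconnected at the chosen
   threshold stays in every table and export.

5. **Node cartography.**  Weighted within-module degree z-score and
   participation coefficient, with every "degree" a summed edge weight
   (raw correlation values, not binarized):

   - WMDz_i = (k_i^within − mean_{j∈s_i} k_j^within) / sd_{j∈s_i} k_j^within.
     The sd is the population (divide-by-n) standard deviation over the
     module's regions — the convention of the cartography literature.
     Singleton modules and uniform-degree modules (sd = 0) take WMDz = 0,
     the neutral role value; uniformity is detected with a relative
     tolerance of 1e-12 on the degree scale because identical degrees can
     yield an sd of a few ulps through mean roundoff, which would
     otherwise turn 0/0 into ±1.
   - PC_i = 1 − Σ_s (k_is / k_i)²; isolated nodes (k_i = 0) take PC = 0.

   Hub flags: high-PC at PC ≥ 0.30, high-WMDz at WMDz ≥ 0.80, both
   inclusive and configurable.  The network summary reports the disjoint
   census (high PC only / high WMDz only / both), edge count, and module
   sizes.

6. **Export.**  GraphML (or GEXF) with module, PC, WMDz, and hub flags as
   node attributes, preserving isolated nodes, for downstream layout and
   visualization tools.  Per-group CSV artifacts (correlation, partition,
   metrics, sweep) are written with 12 significant digits; reruns on
   identical inputs are byte-identical.

## Synthetic data generator

The generator plants a block-modular correlation structure on the log10
scale: per animal a and module m a latent factor f_{m,a} ~ N(0, 1); for
region r in module m,

    x_{r,a} = mu_r + loading · f_{m,a} + eps,   eps ~ N(0, noise_sd²),
    mu_r ~ Uniform(mean_log_range),   count = round(10^x) clipped at 0.

Within-module population correlation is loading²/(loading² + noise_sd²);
between-module correlation is 0.  Defaults: loading 2.0, noise_sd 0.5
(within-module r ≈ 0.94, comfortably above the 0.75 edge threshold while
leaving realistic sampling noise), mean_log_range (1.0, 3.5) so baseline
counts span ~10 to ~3000 — the "tens to thousands" range of real regional
Fos counts — and 5 animals per group, matching the small cohorts typical
of whole-brain Fos studies.  Per-group streams derive from
(master seed, crc32(group label)), so groups are independent and adding a
group never perturbs another.

What the generator does *not* emulate: anatomical covariance beyond
single-membership blocks (optional overlapping loadings are off by
default), count overdispersion beyond log-normality, atlas-registration
error, or any actual drug effect.  Passing the planted-recovery tests
therefore demonstrates that the machinery — normalization through
cartography — recovers known structure from data of the right scale and
noise character; it says nothing about biological validity on real
tissue.

## Reference tables

Four published per-network node tables (region, module, PC, WMDz to two
decimals; saline/cocaine/methamphetamine/nicotine) and the 178-region
atlas are packaged as data.  They are outputs of the original analysis
whose raw per-animal counts are not public, so they serve as fixed
regression fixtures — module sizes, hub censuses, extreme values — not as
pipeline inputs, and end-to-end reproduction of the original networks is
deliberately out of scope.  The nicotine table has 177 rows: one region
(interanterodorsal thalamic nucleus) was disconnected from that network
and carries no role metrics.

## Verification sizes and numerical choices

- PC/WMDz are checked against brute-force edge-loop oracles to 1e-12 on
  200 random weighted graphs (≤ 20 nodes, random partitions), plus exact
  analytic limits (even spread over N modules → 1 − 1/N; intra-module
  only → 0; uniform-degree module → 0).
- The complete-linkage tree is checked against an exhaustive-search
  oracle on 100 random 6-point Euclidean metrics, compared through
  cophenetic matrices, which are invariant to the order of equal-height
  merges (scipy's internal tie order is accepted; random metrics are
  tie-free almost surely).
- Planted-partition recovery: 4 modules × 10 regions, loading 2.0,
  noise_sd 0.5, 40 animals; the half-height partition reaches adjusted
  Rand index ≥ 0.9 in ≥ 18 of 20 seeds.
- The four-group study benchmark (7/4/3/5 planted modules) runs at
  60 regions and 60 animals with loading 3.0 and noise_sd 0.2 — a
  strong-signal regime chosen so the half-height cut resolves all seven
  control-condition modules reliably; at moderate signal the two closest
  modules occasionally merge below the cut, which is a property of
  half-height cutting, not of the clustering.
- Correlations are computed by `numpy.corrcoef` on centered data and
  clipped to [−1, 1]; matrices are symmetrized ((R + Rᵀ)/2) before
  validation to absorb last-ulp asymmetry.

## Known limitations

- Hierarchical clustering is the only community-detection method
  offered; no Louvain/spectral alternatives, by design.
- Correlation matrices from 4–5 animals are extremely noisy; the package
  warns but does not stop.  Interpretation of any single edge at such n
  is unreliable — the analysis is meant for network-level structure.
- Edge counts depend on the threshold convention (≥ vs >) only at exact
  boundary values, but module counts can be sensitive to the cut
  fraction near merge heights; the sweep output should accompany any
  reported module count.
- The cut-height rule interprets "half the tree height" as 0.5 × the
  final merge height; dendrogram-axis conventions that include padding
  would differ.
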