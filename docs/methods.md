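# Methods

This note documents the models and procedures `pcnkit` implements, the
defaults and why they were chosen, what the synthetic generator does and
does not emulate, and the numerical conventions.

## Contact network model

A Protein Contact Network is built per frame from Cα coordinates: nodes
are residues, and `A_ij = 1` iff `r_min ≤ d(Cα_i, Cα_j) ≤ r_max`, a
closed interval with defaults `r_min = 4 Å`, `r_max = 8 Å`. The closed
interval is the simpler contract and the boundary carries measure zero
for real coordinates. The 4 Å lower cutoff deliberately excludes
sequence-adjacent Cα pairs (~3.8 Å apart), the standard PCN convention
for removing trivial covalent contacts; it is a parameter, not a switch.

Descriptor conventions:

- **Degree** `k_i`: adjacency row sum.
- **Clustering** `cc_i`: fraction of connected neighbour pairs; defined
  as 0 when `k_i < 2` (the ratio is otherwise 0/0).
- **Shortest paths** `sp_ij`: unweighted hop counts (BFS); unreachable
  pairs are flagged `inf`, excluded from the average shortest path and
  from closeness farness sums (component-wise convention), and logged.
- **Betweenness** `btw_i`: exact Brandes accumulation, unnormalized,
  endpoints excluded, each unordered pair counted once, fractional
  credit when several equally short paths exist. This keeps the values
  on the integer-like scale at which protein-network thresholds such as
  btw > 1200 and |Δbtw| > 500 are meaningful for a ~300-residue protein.
- **Closeness**: reciprocal of farness (the plain sum of a node's
  shortest paths within its component), not the size-corrected variant.
- **Graph energy** `E = Σ|λ_i(A)|` (trace norm), the standard spectral
  definition.
- **Assortativity** (degree- or hydropathy-based): Pearson correlation
  of endpoint values over edges, both orientations included so the
  coefficient is symmetric. Zero endpoint variance (e.g. regular graphs)
  returns a flagged NaN, never a silent 0.
- **Dyadicity / heterophilicity**: observed same-class (hydrophobic-
  hydrophobic) and cross-class edge counts over their expectations under
  random mixing with the observed class counts and edge total,
  `m·n1(n1−1)/(n(n−1))` and `m·2n1n0/(n(n−1))`.
- **Jaccard overlap**: shared contacts over the union, on the upper
  triangle; `1 − Jacc` is the rewiring fraction between two states.
- **Difference maps**: `Δ = active − inactive`, element-aligned by
  residue key; all threshold selections are strict (`>`).

## Structure descriptors

- **RG, RGh, RGp**: mass-weighted radius of gyration; the hydrophobic
  and polar subsets are taken about their own barycentres (the most
  direct reading of "radius of gyration of the hydrophobic residues");
  masses are standard average residue masses — only relative masses
  matter here.
- **Hydrophobic/polar partition**: Kyte-Doolittle value > 0 ⇒
  hydrophobic (ALA, CYS, PHE, ILE, LEU, MET, VAL). The sign rule is the
  least arbitrary published criterion; the annotation table is
  extensible for non-canonical residues.
- **Asymmetry AS**: relative shape anisotropy
  `κ² = 1 − 3(λ1λ2+λ2λ3+λ3λ1)/(λ1+λ2+λ3)²` of the gyration-tensor
  eigenvalues; bounded [0, 1], 0 for spherical point sets, 1 for
  collinear ones.
- **Mass fractal dimension MFD**: least-squares slope of `log M(r)` vs
  `log r`, `M(r)` the mass within radius r of the barycentre, over 20
  log-spaced radii in (4 Å, RG) by default. Radii that enclose none or
  all of the mass carry no scaling information and are dropped; at least
  3 usable radii are required. Mass-radius scaling was preferred to box
  counting because it needs a single fit with fewer tuning knobs; the
  fit range is configurable and matters near the cloud edge.
- **Density and porosity**: the molecular envelope is the convex hull of
  the Cα cloud; ρ = total mass / hull volume. Occupied volume is the
  union of spheres of probe radius 3 Å centred on the Cα positions,
  integrated by Monte-Carlo rejection sampling inside the hull with a
  fixed seed (default 10⁵ points, binomial standard error < 0.002 on ε),
  so ε is reproducible bit-for-bit under one configuration. The 3 Å
  probe approximates a residue's effective packing radius at Cα-only
  resolution.
- **Hydrophobic-core correlation corrHBKD**: Pearson correlation between
  residue hydropathy and distance from the barycentre; negative values
  mean buried hydrophobics. This is an explicit operational stand-in for
  a "hydrophobic core probability": it is the simplest scalar with the
  right sign behaviour and bounded range.

## Displacement and DCC

The displacement matrix D is m frames × p residues;
`D[j, i] = ‖r_i(t_j) − r_i(t_{j−1})‖` with the input structure serving as
the predecessor of the first frame. The default DCC is the Pearson
correlation of the two scalar displacement series — self-correlation is
exactly 1 and the value is invariant to per-residue affine rescaling. A
vector mode (`<Δr_i·Δr_j>/√(<|Δr_i|²><|Δr_j|²>)`, no mean-centring) is
provided as an alternative; the two modes differ and are tagged on the
output. The normalization carries the square root over the denominator
product — without it the self-term would not be 1 and the quantity would
not be a correlation coefficient.

No superposition/least-squares frame alignment is applied before the
displacement computation; displacements are taken in the laboratory
frame (a pre-alignment can be applied upstream if desired). Frozen
residues (zero-variance series) give flagged NaN entries, excluded from
the off-diagonal average with a logged count; the reported average DCC
excludes the diagonal.

Block structure is recovered from a DCC matrix by k-means on the
leading-eigenvector embedding (spectral partitioning), seeded for
reproducibility.

## Multivariate stage

The per-frame table holds t (frame index; frames are equally spaced)
plus the ten topology and eight structure descriptors. The three
analyses:

- **Pearson map**: pairwise-complete correlations, unit diagonal,
  constant columns flagged NaN.
- **Block CCA**: first canonical correlation per block pair between
  X1 = {t}, X2 = {adeg, asp, abtw, aclose, acc, E},
  X3 = {RG, RGh, RGp, ρ, ε, AS, MFD}, computed as the largest singular
  value of the whitened cross-covariance. For the singleton time block
  this reduces to the multiple correlation of t with the other block,
  which keeps the 3×3 score matrix symmetric with unit diagonal. A ridge
  of 1e−8 (scaled by the mean block variance) stabilizes whitening:
  protein descriptor blocks are near-collinear (E and adeg correlate
  above 0.9), and unregularized whitening is numerically fragile there.
- **PCA**: on the correlation matrix — the variables carry
  incommensurable units, and loadings-as-correlations are unit-free only
  under standardization. Loadings are reported as the empirical Pearson
  correlation between each variable and each component score; only
  |loading| > 0.5 is reported as relevant. Eigenvector sign is arbitrary,
  so components are sign-fixed deterministically: t loads non-positively
  whenever it loads at all (relaxation components then always carry a
  negative time loading), otherwise the largest-|loading| variable is
  made positive. Constant columns are excluded with a warning; the
  eigenvalue sum then equals the retained-variable count.

The multivariate stage is exposed statsmodels-style as a model/results
pair (`TrajectoryMVA(...).fit() → MVAResults.summary()`) because it is
the one stage that is genuinely a statistical analysis fitted to a data
table; the descriptor computations stay plain functions since nothing is
estimated there.

## Synthetic generator

`make_fold` builds a four-helix Cα bundle from ideal α-helix geometry
(2.3 Å helix radius, 1.5 Å rise, 99.6° twist → consecutive Cα ≈ 3.8 Å;
helix axes 6.5 Å from the bundle axis, antiparallel). The geometry was
chosen once so the resulting contact network has a realistic mean degree
(≈ 6–8, as observed for real globular proteins) — a random coil would
not exercise degree thresholds like k > 10 meaningfully. With the
core-hydrophobic pattern, residues whose Cα faces the bundle axis get
hydrophobic identities, forcing a negative hydrophobic-core correlation.
A 0.05 Å seeded jitter breaks exact symmetry.

`make_trajectory` generates frame t as
`com + scale(t)·(fold − com) + a·g_b(t)·u_i + ση_i(t)`:

- `g_b(t)`: i.i.d. standard-normal latent factor per dynamical block
  (contiguous equal blocks), times a fixed random unit direction `u_i`
  per residue and amplitude `a = 2·block_corr` Å. Frame-to-frame latent
  steps are shared within a block, so scalar displacement series
  correlate within blocks and are independent across blocks — the
  analytically predictable latent-factor displacement model.
- `σ = noise_sd = 0.3 Å`: independent Gaussian jitter per residue.
- `scale(t) = 1 + α·t/m + β·z_t` with expansion α = 5% over the run and
  `β = α·sd(t/m)·√(1/ρ² − 1)` chosen in closed form so the planted
  corr(t, RG) equals the target ρ (default 0.6 in the drift preset).

Default study conditions: 60 residues, 500 frames, 2 blocks,
block_corr = 0.9 (two-block preset) or block_corr = 0.3 with
rg_drift_corr = 0.6 (drift preset). What the generator does **not**
emulate: side chains, a force field, solvent or lipid environment,
anharmonic transitions, or rotational diffusion — passing tests show the
estimators recover planted structure under Gaussian latent-factor
motion, not that real MD trajectories contain such structure. In
particular the planted block boundaries are sequence-contiguous and
sharp, which is kinder to spectral partitioning than real dynamical
domains.

`perturb_network_nodes` displaces chosen residues radially outward
(default far enough, 10–15 Å, that a node loses all its contacts while
any unperturbed neighbour loses at most the contacts to the moved nodes);
this makes the |Δk| selection exactly recover the planted set at a
threshold above the collateral loss (θ_k = 2 when two well-separated
nodes are moved), while betweenness differences ripple network-wide so
only the superset property is guaranteed for the |Δbtw| selection.

## Problem sizes and numerical choices

Test and reproduction runs use 60-residue folds; trajectory analyses use
500 frames for motion-correlation statistics and 250 frames (10 seeds)
for the canonical-correlation comparisons; Monte-Carlo porosity inside
time-series loops uses 10-20k points per frame (s.e. on ε below 0.005)
versus 10⁵ for single-frame descriptors. These sizes give stable
statistics for every planted-recovery check while keeping a full run in
the minutes range on one core.

Ties and degenerate inputs: zero-variance series and constant columns
are flagged NaN and excluded from averages with logged counts;
disconnected networks use component-wise path statistics; altloc
conflicts resolve to highest occupancy; insertion codes append to the
residue key; non-amino-acid records (ligands, waters) are excluded from
the network — the structures this package targets are single-chain
receptors, and a chain filter is available.

## Known limitations

- Cα-only resolution throughout; no all-atom contacts or solvent
  accessibility.
- Porosity and density depend on the convex-hull envelope, which
  overestimates volume for non-convex folds (ε is then biased upward).
- MFD on small proteins is sensitive to the fit range; the default
  (4 Å, RG) is documented, configurable and should be inspected on new
  systems.
- The CCA "best score" reads the first canonical correlation only; no
  significance testing is attached to it.
- Multi-frame input is multi-model PDB only; convert binary MD formats
  upstream.
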