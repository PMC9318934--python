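# pcnkit

Protein Contact Networks (PCNs), dynamic cross-correlation and
multivariate statistics for protein structures and trajectories.

Allosteric membrane proteins such as G-protein-coupled receptors change
function by rewiring residue-residue contacts rather than by large fold
changes. `pcnkit` quantifies that rewiring. It is aimed at structural
bioinformaticians who have (i) two conformational states of a protein
(e.g. an active and an inactive crystal structure or MD endpoint) and/or
(ii) a frame-ordered trajectory, and who want network-level and
statistical fingerprints of activation.

## What it computes

**Contact networks.** Residues are nodes; an edge joins residues *i*, *j*
when the Cα–Cα distance satisfies 4 Å ≤ d(i,j) ≤ 8 Å (the lower cutoff
removes trivial backbone contacts). From the adjacency matrix *A* it
derives per-node degree `k_i = Σ_j A_ij`, clustering coefficient,
hop-count shortest paths `sp_ij`, unnormalized betweenness `btw_i`
(Brandes accumulation) and closeness `1/farness`; and per-network means
of those, graph energy `E = Σ|λ_i(A)|`, degree- and hydropathy-based
assortativity, dyadicity/heterophilicity of the hydrophobic/polar residue
classes, and the Jaccard contact overlap between two states
`Jacc = M11/(M10+M01+M11)` (1 − Jacc is the rewiring fraction). Two-state
difference maps `Δk_i`, `Δbtw_i` with strict thresholds (defaults
|Δk| > 1, |Δbtw| > 500; high-value selections k > 10, btw > 1200) flag
candidate allosteric-switch residues.

**Structure descriptors.** Radius of gyration (all / hydrophobic / polar
residues), gyration-tensor shape anisotropy κ², mass fractal dimension
(slope of log M(r) vs log r), convex-hull mass density and Monte-Carlo
porosity, and the hydrophobic-core correlation (Pearson of Kyte-Doolittle
hydropathy vs distance from the barycentre).

**Motion correlation.** From an m-frame trajectory the displacement
matrix D (m×p, per-frame Euclidean displacement of each residue) and the
DCC matrix DCC(i,j) — the Pearson correlation of residue displacement
series. Hot blocks mark dynamical domains moving in concert.

**Multivariate stage.** Per-frame descriptor table → Pearson correlation
map, block canonical correlation analysis between time X1 = {t}, topology
X2 = {adeg, asp, abtw, aclose, acc, E} and structure
X3 = {RG, RGh, RGp, ρ, ε, AS, MFD} (first canonical correlation per block
pair), and correlation-matrix PCA reporting variance fractions and
|loading| > 0.5 variables.

A seeded synthetic generator (helical-bundle folds; trajectories with
planted correlated blocks and planted RG drift) makes every stage
testable without external data.

## Worked example

```python
import pcnkit as pk
from pcnkit.synth import SyntheticSpec

fold = pk.make_fold(60, seed=1)                    # 60-residue helical bundle
net = pk.build_pcn(fold)                           # 4-8 A contact network
print(pk.network_summary(net).as_dict()["adeg"])   # 7.3666...

traj, truth = pk.make_trajectory(fold, SyntheticSpec(seed=1, block_corr=0.9))
dcc = pk.dcc_matrix(pk.displacement_matrix(traj))
print(round(pk.average_dcc(dcc), 3))               # 0.449

res = pk.TrajectoryMVA.from_trajectory(traj).fit()
print(res.summary())
```

The mean degree ≈ 7.4 is in the range typical of real protein contact
networks. The average DCC 0.449 reflects the planted two-block coupling:
within-block pairs correlate near 0.93, across blocks near 0, and
`pcnkit.motion.partition_from_dcc` recovers the planted membership.
`res.summary()` prints the 3×3 canonical-correlation table, PCA variance
fractions and the thresholded loadings.

From the shell:

```bash
pcn synth --preset two-block --seed 7 --out frames.pdb --truth truth.json
pcn run --preset drift --seed 7 --outdir out/
pcn compare --active a.pdb --inactive b.pdb --outdir cmp/
```

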