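# mosi

Functional parcellation of resting-state fMRI volumes by iterative
**mo**dular analysis and **si**milarity measurements.

Resting-state BOLD analyses usually reduce tens of thousands of voxels to a
few dozen nodes using anatomical atlases — regions that are not guaranteed
to be functionally homogeneous, which biases every downstream network
estimate. `mosi` parcellates the cortex (or any masked 4D volume) from the
signal itself: it alternately **splits** each spatially contiguous module by
Louvain community detection on the module's voxel-by-voxel correlation
matrix, and **unifies** neighboring modules whose whole-volume
functional-connectivity profiles are nearly identical, iterating until the
modular structure is stable. The package is aimed at researchers who need
data-driven, multi-resolution parcellations of volumetric resting-state
data, plus the statistics to validate them.

## The algorithm in brief

At resolution $\gamma$, the split stage maximizes

$$Q = \frac{1}{2m}\sum_{ij}\Bigl[A_{ij} - \gamma\frac{k_i k_j}{2m}\Bigr]\delta(c_i, c_j)$$

over each module's regional correlation matrix (negative weights clamped,
diagonal removed); sub-communities that are not 26-connected in space are
separated. The unify stage merges 26-adjacent modules $u, v$ when the
voxel-count-weighted RMS difference of their global FC profiles,

$$d(u,v) = \sqrt{\tfrac{\sum_{k\notin\{u,v\}} n_k (r_{uk}-r_{vk})^2}{\sum_{k\notin\{u,v\}} n_k}},$$

falls below 0.05. Fragments under 10 voxels are absorbed into their
best-correlated neighbor (correlation ≥ 0.50); convergence is declared when
successive parcellations agree exactly or reach NMI > 0.95 with ≤ 1%
module-count change. Ascending $\gamma$ ladders (0.65–0.95, step 0.05) are
warm-started from the previous, coarser result, giving nested
multi-resolution parcellations whose module counts rise and whose
within-module homogeneity grows with $\gamma$. A second-level community
detection on module-mean signals then reveals large-scale networks.
Details and design rationale: [docs/methods.md](docs/methods.md).

## Worked example

Everything below runs on a fully synthetic planted volume — no imaging
data needed. Simulate a 12×12×6 volume of 8 contiguous regions (150
timepoints, SNR 2, so within-region correlations ≈ 0.8), plus an
atlas-like 4-region initial parcellation:

```sh
$ mosi simulate --dims 12,12,6 --regions 8 -T 150 --snr 2 --seed 1 \
      --init-regions 4 --out sim
wrote planted volume (864 voxels, 8 regions) to sim

$ mosi parcellate --bold sim/bold.nii --init sim/init_labels.nii \
      --gamma 0.8 --seed 7 --out parc
gamma 0.80: 8 modules, converged=True in 5 iteration(s)

$ cat parc/history.csv
gamma,iteration,module_count,nmi_to_previous,n_absorbed,n_split,n_merged
0.8,1,132,0.3791274038686285,0,163,35
0.8,2,37,0.7889607618731842,103,26,18
0.8,3,10,0.8739557426268838,19,0,8
0.8,4,8,0.970335475291685,0,0,2
0.8,5,8,1.0,0,0,0
```

Starting from 4 coarse regions, the first split shatters the volume into
132 candidate modules; absorption and profile-based unification consolidate
them over five iterations to exactly the 8 planted regions (the final
parcellation reaches NMI ≈ 0.98 against the ground truth). Validate the
homogeneity of the result:

```sh
$ mosi evaluate --bold sim/bold.nii --labels parc/labels_gamma0.80.nii \
      --out stats.csv
8 modules: mean intra-inter difference 0.8291, t=46.69, p=5.41e-10
```

Within-module voxel correlations (≈ 0.83 on average) dwarf between-module
correlations — the parcellation is homogeneous where it claims to be.
Other subcommands: `mosi ladder` (warm-started multi-resolution sweep,
e.g. `--gammas 0.65:0.95:0.05`) and `mosi networks` (second-level
community detection toward a target network count). Every command is
byte-for-byte reproducible for a fixed `--seed`.

The same functionality is available as a library:

```python
from mosi import (PlantedSpec, generate_planted_volume, grow_regions,
                  MosiConfig, mosi_iterate, normalized_mutual_information)

volume = generate_planted_volume(PlantedSpec(seed=1))
init = grow_regions(volume.lattice, 4, seed=1001)
result = mosi_iterate(init, volume.bold, MosiConfig(gamma=0.8, seed=7))
nmi = normalized_mutual_information(result.parcellation.labels,
                                    volume.parcellation.labels)
```

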