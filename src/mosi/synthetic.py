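"""Planted-parcellation volume generator.

Produces fully synthetic 4D volumes with known ground truth so that every
pipeline stage is testable without any imaging download: spatially
contiguous regions grown on the 3D lattice, each driven by a band-limited
latent Gaussian signal, voxelwise white noise at a controllable
signal-to-noise ratio, optional Gaussian spatial smoothing, and an optional
two-level mode in which regions nest inside networks through a shared
network-level signal component.

With voxel series ``snr * latent + noise`` (both unit variance), the
expected correlation of two voxels of the same region is the classic
common-signal form ``snr^2 / (1 + snr^2)`` — e.g. 0.8 at snr = 2 — while
voxels of unrelated regions are uncorrelated in expectation. Smoothing
mixes signal across region boundaries and raises cross-boundary
correlations, emulating the spatial smoothing step of standard fMRI
preprocessing; the band-limited latent emulates its temporal bandpass.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from .algorithm import BoldMatrix
from .lattice import Parcellation, VoxelLattice

__all__ = [
    "PlantedSpec",
    "PlantedVolume",
    "grow_regions",
    "band_limited_series",
    "generate_planted_volume",
]

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass(frozen=True)
class PlantedSpec:
    """Recipe for one synthetic volume.

    Parameters
    ----------
    dims : (nx, ny, nz)
        Lattice shape; the mask covers the full box.
    n_regions : int
        Number of planted contiguous regions (ignored when the two-level
        fields are set).
    n_networks, regions_per_network : int, optional
        Two-level mode: ``n_networks * regions_per_network`` regions, with
        regions of a network sharing a latent component.
    n_timepoints : int
        Series length T (>= 8).
    snr : float
        Ratio of latent-signal s.d. to noise s.d.; within-region
        correlation approaches ``snr^2 / (1 + snr^2)``.
    smoothing_fwhm : float
        Gaussian spatial smoothing FWHM in lattice units; 0 disables.
    band : (float, float)
        Latent-signal passband as fractions of the Nyquist frequency.
    network_weight : float
        In two-level mode, fraction of latent variance shared at network
        level; region means of one network then correlate about this value.
    cross_coupling : float
        Maximum amplitude of each region's secondary affiliation to one
        *other* network (graded per region, 0 disables). This gives regions
        of the same network structurally distinct global FC profiles — as
        real cortical regions have — rather than profiles identical up to
        sampling noise.
    nested_networks : bool
        In two-level mode, grow each network as one contiguous territory
        and its regions inside it (a spatially hierarchical volume). With
        ``False``, regions are grown independently and dealt to networks
        round-robin, so a network is generally spatially scattered —
        networks are then linked only through their shared signal.
    seed : int
        Master seed; generation is fully deterministic.
    """

    dims: tuple[int, int, int] = (12, 12, 6)
    n_regions: int = 8
    n_networks: int | None = None
    regions_per_network: int | None = None
    n_timepoints: int = 150
    snr: float = 2.0
    smoothing_fwhm: float = 0.0
    band: tuple[float, float] = (0.05, 0.5)
    network_weight: float = 0.7
    cross_coupling: float = 0.3
    nested_networks: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_timepoints < 8:
            raise ValueError("n_timepoints must be >= 8")
        if self.snr <= 0:
            raise ValueError("snr must be positive")
        if (self.n_networks is None) != (self.regions_per_network is None):
            raise ValueError(
                "two-level mode needs both n_networks and regions_per_network"
            )
        if not 0 < self.band[0] < self.band[1] <= 1:
            raise ValueError("band must satisfy 0 < low < high <= 1 (Nyquist units)")
        if not 0 < self.network_weight < 1:
            raise ValueError("network_weight must be in (0, 1)")
        if self.cross_coupling < 0:
            raise ValueError("cross_coupling must be >= 0")
        if self.network_weight + self.cross_coupling**2 >= 1:
            raise ValueError(
                "network_weight + cross_coupling^2 must stay below 1"
            )
        if self.total_regions < 1:
            raise ValueError("need at least one region")
        if self.total_regions > int(np.prod(self.dims)):
            raise ValueError("more regions than voxels")
        if self.smoothing_fwhm < 0:
            raise ValueError("smoothing_fwhm must be >= 0")

    @property
    def two_level(self) -> bool:
        return self.n_networks is not None

    @property
    def total_regions(self) -> int:
        if self.two_level:
            return int(self.n_networks) * int(self.regions_per_network)
        return int(self.n_regions)


@dataclass
class PlantedVolume:
    """A synthetic volume with its ground truth."""

    lattice: VoxelLattice
    bold: BoldMatrix
    parcellation: Parcellation  # planted region labels, 1..R
    network_of_region: dict[int, int] | None  # region label -> network id
    spec: PlantedSpec

    def network_labels(self) -> np.ndarray:
        """Per-voxel planted network labels (two-level volumes only)."""
        if self.network_of_region is None:
            raise ValueError("volume was not generated with two-level structure")
        lut = np.zeros(int(self.parcellation.labels.max()) + 1, dtype=np.int64)
        for region, net in self.network_of_region.items():
            lut[region] = net
        return lut[self.parcellation.labels]


def grow_regions(lattice: VoxelLattice, n_regions: int, seed: int = 0) -> Parcellation:
    """Grow ``n_regions`` contiguous regions covering the whole mask.

    Seeded multi-source frontier expansion on the 26-neighbor graph: region
    seeds are drawn at random, then regions take turns (in a fresh random
    order per round) claiming one random unassigned frontier voxel each,
    which keeps sizes roughly balanced and every region connected.
    """
    V = lattice.n_voxels
    if not 1 <= n_regions <= V:
        raise ValueError(f"n_regions must be in [1, {V}]")
    rng = np.random.default_rng(seed)
    adjacency = lattice.adjacency()
    labels = np.zeros(V, dtype=np.int64)
    seeds = rng.choice(V, size=n_regions, replace=False)
    frontiers: list[set[int]] = []
    for r, s in enumerate(seeds, start=1):
        labels[s] = r
        frontiers.append(set(adjacency.neighbors(s).tolist()))
    remaining = V - n_regions
    while remaining:
        progress = False
        for r in rng.permutation(n_regions):
            frontier = frontiers[r]
            candidates = sorted(v for v in frontier if labels[v] == 0)
            frontier.intersection_update(candidates)
            if not candidates:
                continue
            pick = candidates[rng.integers(len(candidates))]
            labels[pick] = r + 1
            frontier.discard(pick)
            frontier.update(
                v for v in adjacency.neighbors(pick).tolist() if labels[v] == 0
            )
            remaining -= 1
            progress = True
            if not remaining:
                break
        if not progress:
            raise RuntimeError(
                "mask has a connected component without a region seed"
            )
    return Parcellation(labels)


def _grow_nested(
    lattice: VoxelLattice, spec: PlantedSpec, seed: int
) -> tuple[Parcellation, dict[int, int]]:
    """Grow contiguous network territories, then regions inside each.

    Produces a spatially hierarchical ground truth: coarse resolutions can
    represent a network as a single contiguous module, finer ones its
    nested regions.
    """
    ss = np.random.SeedSequence([seed, 1])
    net_seed, *region_seeds = (
        int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(1 + spec.n_networks)
    )
    networks = grow_regions(lattice, int(spec.n_networks), seed=net_seed)
    labels = np.zeros(lattice.n_voxels, dtype=np.int64)
    network_of_region: dict[int, int] = {}
    next_region = 1
    for net in range(1, int(spec.n_networks) + 1):
        vox = networks.voxels_of(net)
        sub_mask = np.zeros(lattice.dims, dtype=bool)
        sub_mask[tuple(lattice.coords[vox].T)] = True
        sub_lattice = VoxelLattice(sub_mask)
        sub_parc = grow_regions(
            sub_lattice, int(spec.regions_per_network), seed=region_seeds[net - 1]
        )
        # sub-lattice dense order and vox are both row-major ascending
        labels[vox] = sub_parc.labels + (next_region - 1)
        for r in range(spec.regions_per_network):
            network_of_region[next_region + r] = net
        next_region += int(spec.regions_per_network)
    return Parcellation(labels), network_of_region


def band_limited_series(
    n_timepoints: int,
    band: tuple[float, float],
    rng: np.random.Generator,
    n_series: int = 1,
) -> np.ndarray:
    """Unit-variance Gaussian series with a top-hat spectrum.

    White noise is Fourier-masked to the passband ``band`` (fractions of
    Nyquist, DC always removed) and standardized per series. Shape
    ``(n_timepoints, n_series)``.
    """
    T = int(n_timepoints)
    x = rng.standard_normal((T, n_series))
    spectrum = np.fft.rfft(x, axis=0)
    freqs = np.fft.rfftfreq(T) / 0.5  # as fraction of Nyquist
    keep = (freqs >= band[0]) & (freqs <= band[1]) & (freqs > 0)
    if not keep.any():
        raise ValueError("passband contains no Fourier bin; increase T or band")
    spectrum[~keep] = 0
    y = np.fft.irfft(spectrum, n=T, axis=0)
    y -= y.mean(axis=0)
    sd = y.std(axis=0)
    if np.any(sd == 0):
        raise ValueError("degenerate band-limited series")
    return y / sd


def generate_planted_volume(spec: PlantedSpec) -> PlantedVolume:
    """Generate a volume with a planted contiguous parcellation.

    Voxel series are ``snr * latent(region) + white noise`` (both unit
    variance) with optional per-timepoint Gaussian smoothing. In two-level
    mode the region latent mixes a network-shared and a region-specific
    component, ``sqrt(w) * net + sqrt(1 - w) * region``, so regions within a
    network correlate about ``w`` while regions of different networks stay
    uncorrelated in expectation.
    """
    root = np.random.SeedSequence(spec.seed)
    seed_regions, seed_latent, seed_noise = (
        int(s.generate_state(1)[0] % (2**31)) for s in root.spawn(3)
    )
    lattice = VoxelLattice.full(spec.dims)
    network_of_region: dict[int, int] | None = None
    if spec.two_level and spec.nested_networks:
        parc, network_of_region = _grow_nested(lattice, spec, seed_regions)
    else:
        parc = grow_regions(lattice, spec.total_regions, seed=seed_regions)
        if spec.two_level:
            # deal grown regions to networks round-robin (spatially scattered)
            network_of_region = {
                r: 1 + (r - 1) % int(spec.n_networks)
                for r in range(1, spec.total_regions + 1)
            }

    rng_latent = np.random.default_rng(seed_latent)
    R = spec.total_regions
    if spec.two_level:
        nets = band_limited_series(
            spec.n_timepoints, spec.band, rng_latent, spec.n_networks
        )
        regional = band_limited_series(spec.n_timepoints, spec.band, rng_latent, R)
        w = spec.network_weight
        K = int(spec.n_networks)
        latent = np.empty_like(regional)
        members: dict[int, list[int]] = {}
        for r in range(1, R + 1):
            members.setdefault(network_of_region[r], []).append(r)
        for r in range(1, R + 1):
            home = network_of_region[r] - 1
            j = members[network_of_region[r]].index(r)  # index within network
            mix = np.sqrt(w) * nets[:, home]
            kappa = 0.0
            if K > 1 and spec.cross_coupling > 0:
                # graded secondary affiliation to one other network: gives
                # each region a distinct global FC signature
                other = (home + 1 + (j % (K - 1))) % K
                kappa = spec.cross_coupling * (j + 1) / int(spec.regions_per_network)
                mix = mix + kappa * nets[:, other]
            mix = mix + np.sqrt(1.0 - w - kappa**2) * regional[:, r - 1]
            latent[:, r - 1] = mix
        latent -= latent.mean(axis=0)
        latent /= latent.std(axis=0)
    else:
        latent = band_limited_series(spec.n_timepoints, spec.band, rng_latent, R)

    rng_noise = np.random.default_rng(seed_noise)
    noise = rng_noise.standard_normal((spec.n_timepoints, lattice.n_voxels))
    data = spec.snr * latent[:, parc.labels - 1] + noise

    if spec.smoothing_fwhm > 0:
        sigma = spec.smoothing_fwhm * _FWHM_TO_SIGMA
        vol = np.zeros(spec.dims)
        for t in range(spec.n_timepoints):
            vol[lattice.mask] = data[t]
            data[t] = gaussian_filter(vol, sigma=sigma)[lattice.mask]

    bold = BoldMatrix(data, lattice)
    return PlantedVolume(
        lattice=lattice,
        bold=bold,
        parcellation=parc,
        network_of_region=network_of_region,
        spec=spec,
    )
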