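"""The MOSI iteration: modular analysis plus similarity measurements.

Functional parcellation proceeds by alternating two moves on a labeled
voxel lattice until the modular structure stabilizes:

* **split** — each module's regional voxel-by-voxel correlation matrix is
  handed to Louvain community detection at resolution gamma; sub-communities
  that are spatially disconnected are further separated, since only
  26-neighboring voxels may share a module;
* **unify** — each module is summarized by its global functional-connectivity
  (FC) profile, the vector of correlations between its mean time series and
  every other module's mean. Neighboring modules whose profiles lie within a
  small size-weighted root-mean-square distance (default 0.05) are merged,
  greedily in ascending distance after a seeded permutation of module order,
  at most one merge per module per cycle.

At the start of every iteration, fragments smaller than ``min_module_size``
voxels are absorbed into their best-correlated 26-adjacent neighbor when
that correlation is at least ``absorb_min_corr``. Convergence is declared
when two successive parcellations are identical, or when their normalized
mutual information exceeds ``nmi_stop`` while the module count changes by at
most ``count_tolerance`` (relative to the earlier count).

Because merging is restricted to 26-adjacent modules, disjoint mask
components (e.g. the two hemispheres) can never exchange voxels and are
effectively processed independently.
"""

from __future__ import annotations

import logging
import time
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .community import (
    WeightedGraph,
    louvain_partition,
    normalized_mutual_information,
)
from .lattice import (
    Parcellation,
    VoxelLattice,
    module_neighbor_pairs,
    split_disconnected_modules,
)

__all__ = [
    "MosiConfig",
    "BoldMatrix",
    "FcProfiles",
    "IterationRecord",
    "MosiResult",
    "DEFAULT_GAMMA_LADDER",
    "regional_fc_matrix",
    "module_mean_series",
    "split_stage",
    "absorb_small_modules",
    "global_fc_profiles",
    "similarity_index",
    "unify_stage",
    "mosi_iterate",
    "mosi_ladder",
]

logger = logging.getLogger(__name__)

#: resolutions explored by default, coarse to fine
DEFAULT_GAMMA_LADDER: tuple[float, ...] = tuple(
    round(0.65 + 0.05 * k, 2) for k in range(7)
)

_STAGE_CODES = {"absorb": 1, "split": 2, "unify": 3}


def stage_seed(master: int, iteration: int, stage: str, key: int = 0) -> int:
    """Derive a per-stage child seed from the top-level run seed.

    Every random draw in a MOSI run flows from one master seed through this
    splitter, keyed by (iteration, stage, module); results are therefore
    bit-reproducible and independent of execution order.
    """
    ss = np.random.SeedSequence(
        [int(master), int(iteration), _STAGE_CODES[stage], int(key)]
    )
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass(frozen=True)
class MosiConfig:
    """Thresholds, resolution and seed for one MOSI run.

    Parameters
    ----------
    gamma : float
        Louvain resolution used in the split stage; higher values yield
        finer parcellations.
    similarity_threshold : float
        Maximum global-FC-profile distance for unifying neighboring modules.
    min_module_size : int
        Modules below this voxel count are absorption candidates.
    absorb_min_corr : float
        Minimum mean-signal correlation (inclusive) for absorbing a fragment
        into a neighbor.
    nmi_stop : float
        NMI between successive parcellations above which the run may stop.
    count_tolerance : float
        Maximum relative module-count change allowed at the NMI stop.
    max_iterations : int
        Hard iteration cap, guarding against oscillation.
    seed : int
        Master seed for all stochastic stages.
    clamp_negative : bool
        Clamp negative correlations to zero before community detection.
    """

    gamma: float = 0.8
    similarity_threshold: float = 0.05
    min_module_size: int = 10
    absorb_min_corr: float = 0.50
    nmi_stop: float = 0.95
    count_tolerance: float = 0.01
    max_iterations: int = 100
    seed: int = 0
    clamp_negative: bool = True

    def __post_init__(self) -> None:
        if self.similarity_threshold <= 0:
            raise ValueError("similarity_threshold must be positive")
        if not 0 < self.nmi_stop <= 1:
            raise ValueError("nmi_stop must be in (0, 1]")
        if self.min_module_size < 1:
            raise ValueError("min_module_size must be >= 1")
        if not 0 <= self.absorb_min_corr <= 1:
            raise ValueError("absorb_min_corr must be in [0, 1]")
        if self.gamma <= 0:
            raise ValueError("gamma must be positive")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")


class BoldMatrix:
    """Time x voxel BOLD signal matrix bound to its lattice.

    Constant (zero-variance) series make Pearson correlation undefined, so
    they are rejected up front unless ``validate=False``.
    """

    def __init__(
        self, data: np.ndarray, lattice: VoxelLattice, validate: bool = True
    ):
        data = np.asarray(data, dtype=np.float64)
        if data.ndim != 2:
            raise ValueError("BOLD data must be 2D (time x voxel)")
        if data.shape[1] != lattice.n_voxels:
            raise ValueError(
                f"BOLD has {data.shape[1]} voxels, lattice has {lattice.n_voxels}"
            )
        if validate:
            if not np.all(np.isfinite(data)):
                raise ValueError("BOLD data contains non-finite values")
            sd = data.std(axis=0)
            dead = np.flatnonzero(sd == 0)
            if dead.size:
                raise ValueError(
                    f"constant time series at voxel(s) {dead[:5].tolist()}"
                    f"{'...' if dead.size > 5 else ''}"
                )
        self.data = data
        self.lattice = lattice

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.data.shape[1]


def regional_fc_matrix(bold: BoldMatrix, voxels: Iterable[int]) -> np.ndarray:
    """Pearson correlation matrix among a module's voxel time series."""
    idx = np.unique(np.fromiter(voxels, dtype=np.int64, count=-1))
    if idx.size < 2:
        raise ValueError("need at least two voxels for a correlation matrix")
    X = bold.data[:, idx]
    sd = X.std(axis=0)
    dead = np.flatnonzero(sd == 0)
    if dead.size:
        raise ValueError(f"zero-variance time series at voxel {int(idx[dead[0]])}")
    R = np.corrcoef(X, rowvar=False)
    np.clip(R, -1.0, 1.0, out=R)
    np.fill_diagonal(R, 1.0)
    return 0.5 * (R + R.T)


def module_mean_series(
    parc: Parcellation, bold: BoldMatrix
) -> tuple[np.ndarray, np.ndarray]:
    """Mean time series per module.

    Returns ``(module_ids, M)`` with ``M`` of shape (T, n_modules), columns
    ordered like ``module_ids``.
    """
    ids = parc.module_ids
    M = np.empty((bold.n_timepoints, ids.size))
    for k, mid in enumerate(ids):
        M[:, k] = bold.data[:, parc.labels == mid].mean(axis=1)
    return ids, M


def split_stage(
    parc: Parcellation, bold: BoldMatrix, cfg: MosiConfig, iteration: int = 0
) -> Parcellation:
    """Divide every module into Louvain sub-communities of its regional
    correlation matrix, then separate spatially disconnected sub-communities.

    Single-voxel modules — and modules with no positive internal correlation,
    which carry no community structure — pass through unchanged. The module
    count never decreases.
    """
    labels = parc.labels.copy()
    next_label = int(labels.max()) + 1
    for mid in parc.module_ids:
        vox = parc.voxels_of(mid)
        if vox.size < 2:
            continue
        R = regional_fc_matrix(bold, vox)
        graph = WeightedGraph.from_correlation(R, clamp_negative=cfg.clamp_negative)
        if graph.total_weight <= 0:
            continue
        sub = louvain_partition(
            graph, cfg.gamma, seed=stage_seed(cfg.seed, iteration, "split", mid)
        )
        for c in range(2, int(sub.max()) + 1):
            labels[vox[sub == c]] = next_label
            next_label += 1
    out = split_disconnected_modules(Parcellation(labels), bold.lattice.adjacency())
    return out.canonicalized()


def _safe_corr(x: np.ndarray, y: np.ndarray) -> float:
    sx, sy = x.std(), y.std()
    if sx == 0 or sy == 0:
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])


def absorb_small_modules(
    parc: Parcellation, bold: BoldMatrix, cfg: MosiConfig
) -> Parcellation:
    """Unite undersized fragments with their best-correlated neighbor.

    Fragments (fewer than ``min_module_size`` voxels) are processed in
    ascending (size, label) order; each is relabeled into the 26-adjacent
    module whose mean time series correlates most strongly with the
    fragment's mean, provided that correlation is at least
    ``absorb_min_corr`` (inclusive). Fragments failing the threshold — or
    isolated on their own mask island — are retained.
    """
    adjacency = bold.lattice.adjacency()
    labels = parc.labels.copy()
    sizes = parc.sizes()
    small = sorted(
        (mid for mid, n in sizes.items() if n < cfg.min_module_size),
        key=lambda mid: (sizes[mid], mid),
    )
    for mid in small:
        vox = np.flatnonzero(labels == mid)
        if vox.size == 0 or vox.size >= cfg.min_module_size:
            continue  # already absorbed into, or grown past the threshold
        neighbor_ids = set()
        for v in vox:
            neighbor_ids.update(labels[adjacency.neighbors(v)].tolist())
        neighbor_ids.discard(int(mid))
        if not neighbor_ids:
            warnings.warn(
                f"module {mid} is isolated (no 26-adjacent neighbor); retained",
                stacklevel=2,
            )
            continue
        frag_mean = bold.data[:, vox].mean(axis=1)
        best_id, best_r = None, -np.inf
        for nb in sorted(neighbor_ids):
            r = _safe_corr(frag_mean, bold.data[:, labels == nb].mean(axis=1))
            if np.isnan(r):
                continue
            if r > best_r:
                best_id, best_r = nb, r
        # inclusive threshold; epsilon guards the exact-boundary case in floats
        if best_id is not None and best_r >= cfg.absorb_min_corr - 1e-9:
            labels[vox] = best_id
    return Parcellation(labels).canonicalized()


@dataclass(frozen=True)
class FcProfiles:
    """Global FC profiles of one parcellation snapshot.

    ``corr[a, b]`` is the Pearson correlation between the mean time series
    of modules ``module_ids[a]`` and ``module_ids[b]``; module ``u``'s
    profile is its row with the ``u`` entry excluded. ``sizes`` holds voxel
    counts, used as weights in the similarity index.
    """

    module_ids: np.ndarray
    corr: np.ndarray
    sizes: np.ndarray

    def profile(self, module_id: int) -> np.ndarray:
        """Correlations of ``module_id``'s mean signal to all other modules."""
        pos = self._pos(module_id)
        others = np.arange(self.module_ids.size) != pos
        return self.corr[pos, others]

    def _pos(self, module_id: int) -> int:
        pos = np.searchsorted(self.module_ids, module_id)
        if pos >= self.module_ids.size or self.module_ids[pos] != module_id:
            raise KeyError(f"unknown module {module_id}")
        return int(pos)


def global_fc_profiles(parc: Parcellation, bold: BoldMatrix) -> FcProfiles:
    """Correlate every module's mean time series with all other modules'."""
    if parc.n_modules < 3:
        raise ValueError("too few modules for similarity (need >= 3)")
    ids, M = module_mean_series(parc, bold)
    sd = M.std(axis=0)
    dead = np.flatnonzero(sd == 0)
    if dead.size:
        raise ValueError(f"constant mean series in module {int(ids[dead[0]])}")
    R = np.corrcoef(M, rowvar=False)
    np.clip(R, -1.0, 1.0, out=R)
    np.fill_diagonal(R, 1.0)
    sizes = np.array([int(n) for n in map(parc.sizes().get, ids)], dtype=np.int64)
    return FcProfiles(module_ids=ids, corr=0.5 * (R + R.T), sizes=sizes)


def similarity_index(u: int, v: int, profiles: FcProfiles) -> float:
    """Size-weighted RMS distance between two modules' global FC profiles.

        d(u, v) = sqrt( sum_k n_k (r_uk - r_vk)^2 / sum_k n_k ),  k not in {u, v}

    Reference modules are weighted by voxel count; the pair's own entries
    are excluded (r_uu is a self-correlation and r_uv appears asymmetrically
    in the two profiles). Symmetric; zero iff the profiles agree on every
    shared reference. Small d means the two modules see the rest of the
    volume identically.
    """
    if u == v:
        raise ValueError("similarity_index requires two distinct modules")
    pu, pv = profiles._pos(u), profiles._pos(v)
    keep = np.ones(profiles.module_ids.size, dtype=bool)
    keep[[pu, pv]] = False
    if not keep.any():
        raise ValueError("no shared reference modules")
    w = profiles.sizes[keep].astype(float)
    diff = profiles.corr[pu, keep] - profiles.corr[pv, keep]
    return float(np.sqrt((w * diff**2).sum() / w.sum()))


def unify_stage(
    parc: Parcellation,
    bold: BoldMatrix,
    cfg: MosiConfig,
    rng: np.random.Generator,
) -> Parcellation:
    """Merge 26-adjacent module pairs with near-identical global FC profiles.

    Candidate pairs (distance below ``similarity_threshold``) are merged
    greedily in ascending distance; ties are broken by a seeded permutation
    of module order so that no fixed module ordering dominates across
    iterations. Each module joins at most one merge per cycle, so chains
    coalesce over subsequent iterations. The module count never increases.
    """
    profiles = global_fc_profiles(parc, bold)
    pairs = module_neighbor_pairs(parc, bold.lattice.adjacency())
    if not pairs:
        return parc
    perm = rng.permutation(profiles.module_ids.size)
    rank = {int(mid): int(p) for mid, p in zip(profiles.module_ids, perm)}
    candidates = []
    for u, v in sorted(pairs):
        d = similarity_index(u, v, profiles)
        if d < cfg.similarity_threshold:
            ru, rv = sorted((rank[u], rank[v]))
            candidates.append((d, ru, rv, u, v))
    candidates.sort()
    labels = parc.labels.copy()
    used: set[int] = set()
    for d, _, _, u, v in candidates:
        if u in used or v in used:
            continue
        keep, drop = (u, v) if u < v else (v, u)
        labels[labels == drop] = keep
        used.update((u, v))
    return Parcellation(labels).canonicalized()


@dataclass(frozen=True)
class IterationRecord:
    iteration: int
    module_count: int
    nmi_to_previous: float
    n_absorbed: int
    n_split: int
    n_merged: int


@dataclass
class MosiResult:
    """Final parcellation plus the per-iteration convergence history."""

    parcellation: Parcellation
    history: list[IterationRecord]
    converged: bool
    config: MosiConfig

    def history_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(rec) for rec in self.history])

    @property
    def n_modules(self) -> int:
        return self.parcellation.n_modules


def mosi_iterate(
    initial: Parcellation, bold: BoldMatrix, cfg: MosiConfig
) -> MosiResult:
    """Run the MOSI loop (absorb -> split -> unify) to convergence.

    The initial parcellation is first made contiguous (atlas ROIs spanning
    disconnected voxel sets are split). Iteration stops when two successive
    parcellations are exactly equal (up to relabeling), or when their NMI
    exceeds ``cfg.nmi_stop`` while the module count changes by at most
    ``cfg.count_tolerance`` relative to the earlier count; otherwise after
    ``cfg.max_iterations`` with ``converged=False``.
    """
    if initial.n_voxels != bold.n_voxels:
        raise ValueError("initial parcellation does not cover the BOLD voxel set")
    adjacency = bold.lattice.adjacency()
    prev = split_disconnected_modules(initial, adjacency).canonicalized()
    history: list[IterationRecord] = []
    converged = False
    for it in range(1, cfg.max_iterations + 1):
        t0 = time.perf_counter()
        m0 = prev.n_modules
        try:
            parc = absorb_small_modules(prev, bold, cfg)
            m_absorbed = parc.n_modules
            parc = split_stage(parc, bold, cfg, iteration=it)
            m_split = parc.n_modules
            if parc.n_modules >= 3:
                rng = np.random.default_rng(stage_seed(cfg.seed, it, "unify"))
                parc = unify_stage(parc, bold, cfg, rng)
        except Exception as exc:
            raise RuntimeError(f"MOSI iteration {it} failed: {exc}") from exc
        m1 = parc.n_modules
        nmi = normalized_mutual_information(prev.labels, parc.labels)
        history.append(
            IterationRecord(
                iteration=it,
                module_count=m1,
                nmi_to_previous=nmi,
                n_absorbed=m0 - m_absorbed,
                n_split=m_split - m_absorbed,
                n_merged=m_split - m1,
            )
        )
        logger.info(
            "iter %d: modules %d, nmi %.4f, absorbed %d, split %d, merged %d "
            "(%.2fs)",
            it,
            m1,
            nmi,
            m0 - m_absorbed,
            m_split - m_absorbed,
            m_split - m1,
            time.perf_counter() - t0,
        )
        identical = np.array_equal(prev.canonicalized().labels, parc.labels)
        count_ok = abs(m1 - m0) / max(m0, 1) <= cfg.count_tolerance
        prev = parc
        if identical or (nmi > cfg.nmi_stop and count_ok):
            converged = True
            break
    return MosiResult(
        parcellation=prev.canonicalized(),
        history=history,
        converged=converged,
        config=cfg,
    )


def mosi_ladder(
    initial: Parcellation,
    bold: BoldMatrix,
    gammas: Sequence[float],
    cfg: MosiConfig,
) -> list[MosiResult]:
    """Warm-started multi-resolution sweep.

    The run at ``gammas[i > 0]`` starts from the final parcellation at
    ``gammas[i-1]``, so finer parcellations are derived from coarser ones
    instead of re-splitting the initial ROIs at high resolution. A
    single-element ladder is exactly ``mosi_iterate``.
    """
    gammas = [float(g) for g in gammas]
    if any(b <= a for a, b in zip(gammas, gammas[1:])):
        raise ValueError("gammas must be strictly ascending")
    if not gammas:
        raise ValueError("empty gamma ladder")
    results: list[MosiResult] = []
    current = initial
    for g in gammas:
        logger.info("ladder: gamma %.2f", g)
        result = mosi_iterate(current, bold, replace(cfg, gamma=g))
        results.append(result)
        current = result.parcellation
    return results
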