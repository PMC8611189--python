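"""Homogeneity validation statistics and second-level network detection.

A good functional parcellation groups voxels whose BOLD dynamics agree: the
mean voxel-pair correlation *within* a module (intra-module CC) should
exceed the average correlation between that module's mean signal and the
other modules' means (inter-module CC). These summaries feed a per-volume
paired t-test, a per-resolution grand mean, and paired comparisons across
resolutions with Bonferroni correction. Once voxels are reduced to module
nodes, running community detection again on the module-mean correlation
matrix reveals large-scale networks; spatial contiguity is deliberately not
required at this level, since large-scale networks link distant regions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .algorithm import BoldMatrix, module_mean_series, regional_fc_matrix
from .community import WeightedGraph, partition_to_target_count
from .lattice import Parcellation

__all__ = [
    "module_homogeneity",
    "HomogeneityTest",
    "homogeneity_ttest",
    "grand_mean_cc",
    "fisher_z",
    "bonferroni_alpha",
    "PairedComparison",
    "paired_gamma_comparison",
    "NetworkAssignment",
    "second_level_networks",
]


def module_homogeneity(parc: Parcellation, bold: BoldMatrix) -> pd.DataFrame:
    """Per-module intra- and inter-module correlation summaries.

    Returns a table with columns ``module_id``, ``n_voxels``, ``intra_cc``
    (mean off-diagonal voxel-pair correlation within the module; NaN for
    single-voxel modules, which cannot contribute) and ``inter_cc`` (mean
    correlation between the module's mean signal and every other module's
    mean signal).
    """
    if parc.n_modules < 2:
        raise ValueError("homogeneity needs at least two modules")
    ids, M = module_mean_series(parc, bold)
    with np.errstate(invalid="ignore", divide="ignore"):
        # a module whose voxel signals cancel has a constant mean series;
        # its inter_cc is undefined and reported as NaN
        Rmod = np.corrcoef(M, rowvar=False)
    np.clip(Rmod, -1.0, 1.0, out=Rmod)
    rows = []
    for k, mid in enumerate(ids):
        vox = parc.voxels_of(mid)
        n = vox.size
        if n >= 2:
            R = regional_fc_matrix(bold, vox)
            intra = (R.sum() - n) / (n * (n - 1))
        else:
            intra = np.nan
        others = np.arange(ids.size) != k
        inter = float(Rmod[k, others].mean())
        rows.append(
            {
                "module_id": int(mid),
                "n_voxels": int(n),
                "intra_cc": float(intra),
                "inter_cc": inter,
            }
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class HomogeneityTest:
    """One-sample t-test of per-module (intra - inter) CC differences."""

    t_statistic: float
    p_value: float
    degrees_of_freedom: int
    mean_difference: float
    exact_tie: bool = False


def homogeneity_ttest(records: pd.DataFrame) -> HomogeneityTest:
    """Test whether intra-module CC exceeds inter-module CC.

    The null hypothesis is that the per-module difference (intra - inter)
    has zero mean; a paired reading, one difference per usable module
    (size >= 2). Two-sided p-value. A zero-variance difference vector is
    degenerate: the t statistic is 0 for an all-zero difference and
    +/- infinity otherwise, flagged with ``exact_tie``.
    """
    usable = records.dropna(subset=["intra_cc", "inter_cc"])
    usable = usable[usable["n_voxels"] >= 2]
    if len(usable) < 3:
        raise ValueError("need at least three usable modules for the t-test")
    diffs = (usable["intra_cc"] - usable["inter_cc"]).to_numpy()
    dof = diffs.size - 1
    mean = float(diffs.mean())
    if diffs.std(ddof=1) == 0:
        t = 0.0 if mean == 0 else math.copysign(math.inf, mean)
        p = 1.0 if mean == 0 else 0.0
        return HomogeneityTest(t, p, dof, mean, exact_tie=True)
    t, p = stats.ttest_1samp(diffs, 0.0)
    return HomogeneityTest(float(t), float(p), dof, mean)


def grand_mean_cc(
    parc: Parcellation, bold: BoldMatrix, weighted: bool = False
) -> float:
    """Mean over modules of the within-module voxel-pair correlation.

    By default modules are averaged unweighted; ``weighted=True`` weights
    each module by its voxel count. Single-voxel modules are excluded.
    """
    table = module_homogeneity(parc, bold)
    usable = table.dropna(subset=["intra_cc"])
    usable = usable[usable["n_voxels"] >= 2]
    if usable.empty:
        raise ValueError("no module with >= 2 voxels")
    if weighted:
        w = usable["n_voxels"].to_numpy(dtype=float)
        return float(np.average(usable["intra_cc"], weights=w))
    return float(usable["intra_cc"].mean())


def fisher_z(r: np.ndarray) -> np.ndarray:
    """Fisher's variance-stabilizing transform z = atanh(r).

    Rejects |r| >= 1, where the transform diverges.
    """
    arr = np.asarray(r, dtype=float)
    if np.any(np.abs(arr) >= 1):
        raise ValueError("Fisher transform undefined for |r| >= 1")
    return np.arctanh(arr)


def bonferroni_alpha(n_conditions: int, family_alpha: float = 0.05) -> float:
    """Per-comparison alpha for all pairwise tests among ``n_conditions``."""
    if n_conditions < 2:
        raise ValueError("need at least two conditions")
    return family_alpha / math.comb(n_conditions, 2)


@dataclass
class PairedComparison:
    """All pairwise paired t-tests over a subjects x conditions table."""

    table: pd.DataFrame  # condition_a, condition_b, mean_difference, t, p, significant
    corrected_alpha: float
    n_pairs: int
    fisher_transformed: bool


def paired_gamma_comparison(
    grand_means: pd.DataFrame,
    family_alpha: float = 0.05,
    fisher: bool = False,
) -> PairedComparison:
    """Pairwise paired t-tests of grand mean CCs across conditions.

    ``grand_means`` is a subjects x conditions table (one column per gamma
    or other condition). For every condition pair (a, b) with b after a, the
    paired difference b - a is tested; significance uses the Bonferroni
    threshold ``family_alpha / C(n_conditions, 2)``. With ``fisher=True``
    the values are atanh-transformed first.
    """
    df = pd.DataFrame(grand_means)
    if df.shape[0] < 2:
        raise ValueError("need at least two subjects for paired tests")
    if df.shape[1] < 2:
        raise ValueError("need at least two conditions")
    X = fisher_z(df.to_numpy()) if fisher else df.to_numpy(dtype=float)
    cols = list(df.columns)
    alpha = bonferroni_alpha(len(cols), family_alpha)
    rows = []
    for ia, ib in combinations(range(len(cols)), 2):
        d = X[:, ib] - X[:, ia]
        t, p = stats.ttest_rel(X[:, ib], X[:, ia])
        rows.append(
            {
                "condition_a": cols[ia],
                "condition_b": cols[ib],
                "mean_difference": float(d.mean()),
                "t_statistic": float(t),
                "p_value": float(p),
                "significant": bool(p < alpha),
            }
        )
    return PairedComparison(
        table=pd.DataFrame(rows),
        corrected_alpha=alpha,
        n_pairs=len(rows),
        fisher_transformed=fisher,
    )


@dataclass(frozen=True)
class NetworkAssignment:
    """Module -> network membership from second-level community detection."""

    networks: dict[int, int]  # module id -> network id (1..K)
    gamma_used: float
    target_reached: bool

    def labels_for(self, module_ids: np.ndarray) -> np.ndarray:
        return np.array([self.networks[int(m)] for m in module_ids])


def second_level_networks(
    parc: Parcellation,
    bold: BoldMatrix,
    target_networks: int = 9,
    seed: int = 0,
    clamp_negative: bool = True,
) -> NetworkAssignment:
    """Detect large-scale networks among module nodes.

    Each module is reduced to its mean time series; community detection on
    the module-mean correlation matrix is tuned (via the resolution
    parameter) toward ``target_networks`` communities. Networks are
    anonymous integer ids — naming them (default-mode, sensorimotor, ...)
    is a visual, human task and not automated here.
    """
    ids, M = module_mean_series(parc, bold)
    if ids.size < target_networks:
        raise ValueError(
            f"fewer modules ({ids.size}) than target networks ({target_networks})"
        )
    R = np.corrcoef(M, rowvar=False)
    np.clip(R, -1.0, 1.0, out=R)
    graph = WeightedGraph.from_correlation(R, clamp_negative=clamp_negative)
    result = partition_to_target_count(graph, target_networks, seed=seed)
    networks = {int(mid): int(c) for mid, c in zip(ids, result.assignment)}
    return NetworkAssignment(
        networks=networks,
        gamma_used=result.gamma,
        target_reached=result.target_reached,
    )
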