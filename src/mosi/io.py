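"""NIfTI readers/writers, CSV outputs and the reproducibility run record.

Internal dense voxel ordering is row-major over (x, y, z). NIfTI affines
are preserved on write but never interpreted by the algorithms.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .algorithm import BoldMatrix, MosiConfig, MosiResult
from .lattice import Parcellation, VoxelLattice

__all__ = [
    "read_bold",
    "write_bold",
    "read_labels",
    "write_labels",
    "write_history",
    "write_stats",
    "RunRecord",
]

logger = logging.getLogger(__name__)


def read_bold(
    path: str | Path, mask_path: str | Path | None = None
) -> tuple[VoxelLattice, BoldMatrix]:
    """Load a 4D BOLD NIfTI (and optional 3D binary mask).

    Without a mask, every voxel is in-mask. Voxels with constant or
    non-finite series cannot enter Pearson correlations and are dropped
    from the mask with a logged count.
    """
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=np.float64)
    if data.ndim != 4:
        raise ValueError(f"expected 4D BOLD image, got {data.ndim}D: {path}")
    dims = data.shape[:3]
    if mask_path is not None:
        mask_img = nib.load(str(mask_path))
        mask = np.asarray(mask_img.dataobj) > 0
        if mask.shape != dims:
            raise ValueError(
                f"mask dims {mask.shape} do not match BOLD dims {dims}"
            )
    else:
        mask = np.ones(dims, dtype=bool)
    series = np.moveaxis(data, -1, 0)  # (T, nx, ny, nz)
    flat = series.reshape(series.shape[0], -1)
    ok = np.isfinite(flat).all(axis=0) & (flat.std(axis=0) > 0)
    ok = ok.reshape(dims)
    dropped = int((mask & ~ok).sum())
    if dropped:
        logger.warning("dropped %d constant/non-finite voxel(s) from the mask", dropped)
        mask = mask & ok
    lattice = VoxelLattice(mask, affine=img.affine)
    bold = BoldMatrix(flat[:, mask.ravel()], lattice)
    return lattice, bold


def write_bold(path: str | Path, bold: BoldMatrix) -> None:
    """Write a BOLD matrix back to a 4D NIfTI volume (0 outside mask)."""
    lattice = bold.lattice
    vol = np.zeros(lattice.dims + (bold.n_timepoints,), dtype=np.float64)
    vol[lattice.mask] = bold.data.T
    nib.save(nib.Nifti1Image(vol, lattice.affine), str(path))


def read_labels(path: str | Path, lattice: VoxelLattice) -> Parcellation:
    """Load a 3D integer label volume as a parcellation over the lattice.

    Background is 0 outside the mask; positive labels outside the mask are
    an error, as are unlabeled in-mask voxels.
    """
    img = nib.load(str(path))
    vol = np.asarray(img.dataobj)
    if vol.ndim == 4 and vol.shape[-1] == 1:
        vol = vol[..., 0]
    if vol.ndim != 3:
        raise ValueError(f"expected 3D label image, got {vol.ndim}D: {path}")
    if vol.shape != lattice.dims:
        raise ValueError(
            f"label dims {vol.shape} do not match lattice dims {lattice.dims}"
        )
    vol = np.rint(vol).astype(np.int64)
    outside = int((vol[~lattice.mask] > 0).sum())
    if outside:
        raise ValueError(f"{outside} labeled voxel(s) fall outside the mask")
    labels = vol[lattice.mask]
    if (labels < 1).any():
        raise ValueError("unlabeled in-mask voxel(s); labels must be >= 1")
    return Parcellation(labels)


def write_labels(path: str | Path, parc: Parcellation, lattice: VoxelLattice) -> None:
    """Write a parcellation as a 3D integer NIfTI (0 outside mask)."""
    if parc.n_voxels != lattice.n_voxels:
        raise ValueError("parcellation does not cover the lattice voxel set")
    vol = np.zeros(lattice.dims, dtype=np.int32)
    vol[lattice.mask] = parc.labels
    nib.save(nib.Nifti1Image(vol, lattice.affine), str(path))


def write_history(results: MosiResult | list[MosiResult], path: str | Path) -> None:
    """Write iteration histories to CSV, ordered by (gamma, iteration)."""
    if isinstance(results, MosiResult):
        results = [results]
    frames = []
    for res in results:
        frame = res.history_frame()
        frame.insert(0, "gamma", res.config.gamma)
        frames.append(frame)
    columns = [
        "gamma",
        "iteration",
        "module_count",
        "nmi_to_previous",
        "n_absorbed",
        "n_split",
        "n_merged",
    ]
    if frames:
        out = pd.concat(frames, ignore_index=True)[columns]
    else:
        out = pd.DataFrame(columns=columns)
    out.to_csv(path, index=False)


def write_stats(table: pd.DataFrame, path: str | Path) -> None:
    """Write a statistics table to CSV with deterministic row order."""
    df = pd.DataFrame(table)
    for key in ("module_id", "iteration"):
        if key in df.columns:
            df = df.sort_values(key, kind="stable")
            break
    df.to_csv(path, index=False)


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunRecord:
    """Everything needed to re-run a command bit-identically.

    Captures the resolved configuration, seeds, package version and input
    digests. Timings go to the log stream only, so record files are
    byte-stable across repeated runs.
    """

    command: str
    config: dict
    seed: int
    package_version: str
    input_digests: dict[str, str] = field(default_factory=dict)

    @classmethod
    def create(
        cls,
        command: str,
        config: MosiConfig | dict,
        seed: int,
        inputs: dict[str, str | Path] | None = None,
    ) -> "RunRecord":
        from . import __version__

        cfg = asdict(config) if isinstance(config, MosiConfig) else dict(config)
        digests = {
            name: _sha256(p) for name, p in (inputs or {}).items() if Path(p).exists()
        }
        return cls(
            command=command,
            config=cfg,
            seed=int(seed),
            package_version=__version__,
            input_digests=digests,
        )

    def write(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)
            fh.write("\n")
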