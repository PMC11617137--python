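"""File formats and study configuration.

NIfTI-1 beta images and ROI masks are read with nibabel; pattern matrices,
second-moment matrices and reports travel as TSV with H-T-E condition labels
(e.g. ``"L-R-L"``) in the header; manifests, fits and reports as JSON.  Time
is in seconds on half-open intervals and scan indices are 0-based everywhere.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .glm import PatternMatrix
from .task_design import CONDITION_LABELS

__all__ = ["StudyConfig", "read_roi_betas", "write_matrix_tsv", "read_matrix_tsv"]


def read_roi_betas(beta_paths, mask_path, subject=None, epoch=None) -> PatternMatrix:
    """Extract a condition-by-voxel pattern matrix from NIfTI beta images.

    ``beta_paths`` lists one beta image per condition in canonical order.
    Voxels where the mask is nonzero are flattened x-fastest (Fortran order);
    the same voxel order is used for every condition.
    """
    import nibabel as nib

    beta_paths = list(beta_paths)
    if len(beta_paths) != len(CONDITION_LABELS):
        raise ValueError(
            f"expected {len(CONDITION_LABELS)} beta images, got {len(beta_paths)}"
        )
    mask_img = nib.load(str(mask_path))
    mask = np.asarray(mask_img.dataobj)
    idx = np.flatnonzero(mask.ravel(order="F") != 0)
    if idx.size == 0:
        raise ValueError(f"ROI mask {mask_path} is empty")
    rows = []
    for p in beta_paths:
        img = nib.load(str(p))
        if img.shape != mask_img.shape:
            raise ValueError(
                f"grid mismatch: {p} has shape {img.shape}, mask {mask_img.shape}"
            )
        rows.append(np.asarray(img.dataobj, dtype=float).ravel(order="F")[idx])
    return PatternMatrix(values=np.vstack(rows), subject=subject, epoch=epoch)


def write_matrix_tsv(path, M: np.ndarray, labels=CONDITION_LABELS) -> None:
    """Square condition-by-condition matrix as TSV with labeled header/index."""
    import pandas as pd

    pd.DataFrame(M, index=list(labels), columns=list(labels)).to_csv(
        path, sep="\t", float_format="%.10g"
    )


def read_matrix_tsv(path) -> np.ndarray:
    import pandas as pd

    return pd.read_csv(path, sep="\t", index_col=0).to_numpy(dtype=float)


@dataclass
class StudyConfig:
    """Settings for an end-to-end analysis of one dataset manifest.

    ``manifest`` points at a synthetic-dataset manifest (or a JSON of ROI
    TSV pattern files); outputs are written under ``out_dir``.
    """

    manifest: str
    out_dir: str
    roi: str = "ROI"
    epoch: str = "early"
    pooling: str = "average"
    center: bool = True
    components: tuple[str, ...] | None = None  # None = all six
    n_permutations: int = 1000
    levels: tuple[float, ...] = (0.80, 0.95)
    rng_seed: int = 0

    def validate(self) -> None:
        if not Path(self.manifest).exists():
            raise FileNotFoundError(f"manifest not found: {self.manifest}")
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        if self.pooling not in ("average", "concatenate_runs"):
            raise ValueError(f"unknown pooling {self.pooling!r}")
        if self.epoch not in ("early", "late", "synthetic"):
            raise ValueError(f"unknown epoch {self.epoch!r}")
        for lvl in self.levels:
            if lvl not in (0.80, 0.95):
                raise ValueError("credibility levels must be 0.80 or 0.95")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["components"] = list(self.components) if self.components else None
        d["levels"] = list(self.levels)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "StudyConfig":
        d = dict(d)
        if d.get("components"):
            d["components"] = tuple(d["components"])
        if d.get("levels"):
            d["levels"] = tuple(d["levels"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        import yaml

        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def config_hash(self) -> str:
        """Stable hash of the canonical JSON form, embedded in every output."""
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]
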