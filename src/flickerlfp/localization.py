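"""Anatomical label assignment from a labeled voxel grid.

Each contact is assigned the label accumulating the greatest distance-
weighted "signal strength" over the non-white-matter atlas voxels whose
centers fall within a 5 mm search sphere around the contact: each voxel
contributes 1/r (capped at 1, the value used at r = 0).
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class LabelGrid:
    """Integer label volume with an affine from voxel index to world mm."""

    volume: np.ndarray
    affine: np.ndarray
    label_names: dict[int, str] = dataclasses.field(default_factory=dict)
    white_matter_labels: frozenset[int] = frozenset()

    def __post_init__(self) -> None:
        self.volume = np.asarray(self.volume)
        self.affine = np.asarray(self.affine, float)
        if np.linalg.det(self.affine[:3, :3]) == 0:
            raise ValueError("affine must be invertible")
        if (self.volume < 0).any():
            raise ValueError("labels must be non-negative")

    @classmethod
    def from_nifti(cls, path, label_names=None, white_matter_labels=()) -> "LabelGrid":
        import nibabel as nib
        img = nib.load(str(path))
        return cls(np.asarray(img.dataobj).astype(int), img.affine,
                   label_names or {}, frozenset(white_matter_labels))


def assign_label(
    contact_xyz,
    grid: LabelGrid,
    radius: float = 5.0,
    weight: str = "inverse",
) -> int | None:
    """Label of the strongest-signal region around a contact, or None.

    ``weight='inverse'`` uses min(1, 1/r); ``weight='gaussian'`` uses
    exp(-r^2 / (2 (radius/2)^2)) (non-default).  Background (label 0) and
    white-matter labels are excluded; ties go to the lower label id.
    """
    xyz = np.asarray(contact_xyz, float)
    inv = np.linalg.inv(grid.affine)
    vox = inv @ np.append(xyz, 1.0)
    # voxel-space bounding box covering the search sphere
    scale = np.linalg.norm(grid.affine[:3, :3], axis=0)  # mm per voxel step
    lo = np.floor(vox[:3] - radius / scale - 1).astype(int)
    hi = np.ceil(vox[:3] + radius / scale + 1).astype(int)
    lo = np.maximum(lo, 0)
    hi = np.minimum(hi, np.array(grid.volume.shape) - 1)
    if np.any(lo > hi):
        return None

    ii, jj, kk = np.meshgrid(*(np.arange(a, b + 1) for a, b in zip(lo, hi)), indexing="ij")
    idx = np.stack([ii.ravel(), jj.ravel(), kk.ravel()], axis=1)
    world = idx @ grid.affine[:3, :3].T + grid.affine[:3, 3]
    r = np.linalg.norm(world - xyz, axis=1)
    labels = grid.volume[idx[:, 0], idx[:, 1], idx[:, 2]]
    keep = (r <= radius) & (labels > 0) & ~np.isin(labels, list(grid.white_matter_labels))
    if not keep.any():
        return None
    if weight == "gaussian":
        w = np.exp(-r[keep] ** 2 / (2 * (radius / 2) ** 2))
    else:
        w = np.minimum(1.0, 1.0 / np.maximum(r[keep], np.finfo(float).tiny))
    strengths: dict[int, float] = {}
    for lab, wi in zip(labels[keep], w):
        strengths[int(lab)] = strengths.get(int(lab), 0.0) + float(wi)
    best = max(strengths.values())
    winners = sorted(lab for lab, s in strengths.items() if s == best)
    if len(winners) > 1:
        logger.info("label tie %s at contact %s; taking lowest id", winners, xyz)
    return winners[0]
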