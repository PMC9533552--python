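"""Reading and validating images, layer label masks, and exclusions.

Layer segmentation in this workflow is manual (ITK-SNAP-style label
volumes); this module only consumes masks. A record couples one label
mask with the intensity channels acquired on the same section, validates
shapes and label values, and tracks per-layer exclusion flags: when an
artifact compromises one layer, that layer's pixels are dropped from
every downstream quantity while the remaining layers are preserved.

Masks may be TIFF label images or NIfTI volumes (``.nii``/``.nii.gz``)
for ITK-SNAP interoperability; both use the coding 0 background, 1-6
layers inner to outer, 7 artifact.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import tifffile

from .layers import (
    ARTIFACT_LABEL,
    BACKGROUND_LABEL,
    LABEL_TO_LAYER,
    LAYER_TO_LABEL,
    LAYERS,
    VALID_LABELS,
)

__all__ = [
    "ChannelImage",
    "ImageRecord",
    "read_mask",
    "write_mask_nifti",
    "read_record",
    "exclude_layer",
    "layer_pixel_counts",
    "save_exclusions",
    "load_exclusions",
]

#: reporting-only fluorophore wavelengths (nm) per channel role
CHANNEL_WAVELENGTHS = {
    "amyloid": 543,
    "gs": 543,
    "marker": 488,
    "gfap": 488,
    "nuclei": 405,
}

#: channel roles each cohort must provide
REQUIRED_ROLES = {
    "TUBB3": ("amyloid", "marker"),
    "GFAP": ("amyloid", "marker"),
    "IBA-1": ("amyloid", "marker"),
    "GS": ("gs", "gfap"),
}


@dataclass(frozen=True)
class ChannelImage:
    """Single-channel intensity grid for one stain."""

    data: np.ndarray
    role: str
    wavelength_nm: int | None = None

    def __post_init__(self):
        if self.data.ndim != 2:
            raise ValueError(f"channel {self.role!r}: expected 2-D grid, got {self.data.ndim}-D")
        if np.issubdtype(self.data.dtype, np.signedinteger) and self.data.min() < 0:
            raise ValueError(f"channel {self.role!r}: negative intensities")


@dataclass
class ImageRecord:
    """One validated acquisition: mask + channels + exclusion state."""

    donor_id: str
    group: str
    region: str
    cohort: str
    section: int
    image: int
    mask: np.ndarray
    channels: dict[str, ChannelImage]
    excluded_layers: dict[str, str] = field(default_factory=dict)  # layer -> reason
    source: str | None = None

    def __post_init__(self):
        validate_mask(self.mask, where=self.source or self.donor_id)
        for role, ch in self.channels.items():
            if ch.data.shape != self.mask.shape:
                raise ValueError(
                    f"channel {role!r} shape {ch.data.shape} != mask shape {self.mask.shape}"
                    + (f" ({self.source})" if self.source else "")
                )
        required = REQUIRED_ROLES.get(self.cohort)
        if required:
            missing = [r for r in required if r not in self.channels]
            if missing:
                raise ValueError(f"cohort {self.cohort}: missing channel roles {missing}")

    @property
    def usable(self) -> bool:
        """A record is usable when at least one layer pixel survives."""
        labels = np.unique(self.mask)
        return any(lab in LABEL_TO_LAYER for lab in labels) and any(
            LABEL_TO_LAYER[lab] not in self.excluded_layers
            for lab in labels
            if lab in LABEL_TO_LAYER
        )

    def included_layers(self) -> list[str]:
        present = {LABEL_TO_LAYER[l] for l in np.unique(self.mask) if l in LABEL_TO_LAYER}
        return [lay for lay in LAYERS if lay in present and lay not in self.excluded_layers]


def validate_mask(mask: np.ndarray, where: str = "") -> None:
    if mask.ndim != 2:
        raise ValueError(f"label mask must be 2-D, got {mask.ndim}-D" + _at(where))
    bad = set(np.unique(mask)) - VALID_LABELS
    if bad:
        raise ValueError(f"unknown label value(s) {sorted(bad)} in mask" + _at(where))


def _at(where: str) -> str:
    return f" ({where})" if where else ""


def read_mask(path: str | os.PathLike) -> np.ndarray:
    """Read a label mask from TIFF or NIfTI and validate its labels."""
    path = Path(path)
    if path.suffix in (".nii",) or path.name.endswith(".nii.gz"):
        vol = np.asanyarray(nib.load(path).dataobj)
        mask = np.squeeze(vol)
        if mask.ndim != 2:
            raise ValueError(f"NIfTI label volume {path} is not a single 2-D slice")
        # NIfTI is column-major by convention; store row-major, rows axial
        mask = np.asarray(mask.T)
    else:
        mask = tifffile.imread(path)
    mask = mask.astype(np.uint8, casting="safe") if mask.dtype != np.uint8 else mask
    validate_mask(mask, where=str(path))
    return mask


def write_mask_nifti(mask: np.ndarray, path: str | os.PathLike) -> None:
    """Write a label mask as a NIfTI volume openable in ITK-SNAP."""
    validate_mask(mask)
    img = nib.Nifti1Image(np.asarray(mask.T, dtype=np.uint8), affine=np.eye(4))
    nib.save(img, str(path))


def read_record(
    row: pd.Series | dict,
    base_dir: str | os.PathLike,
    exclusions: pd.DataFrame | None = None,
) -> ImageRecord:
    """Build a validated :class:`ImageRecord` from one manifest row.

    ``exclusions`` (as produced by :func:`save_exclusions`) re-applies
    persisted per-layer exclusions for this image.
    """
    row = dict(row)
    base = Path(base_dir)
    mask_path = base / str(row["mask_file"])
    if not mask_path.exists():
        raise FileNotFoundError(f"mask file missing: {mask_path}")
    mask = read_mask(mask_path)

    channels: dict[str, ChannelImage] = {}
    for key, val in row.items():
        if not str(key).endswith("_file") or key == "mask_file":
            continue
        if val is None or (isinstance(val, float) and np.isnan(val)):
            continue
        role = str(key)[: -len("_file")]
        p = base / str(val)
        if not p.exists():
            raise FileNotFoundError(f"channel file missing: {p}")
        data = tifffile.imread(p)
        channels[role] = ChannelImage(data=data, role=role, wavelength_nm=CHANNEL_WAVELENGTHS.get(role))

    rec = ImageRecord(
        donor_id=str(row["donor_id"]),
        group=str(row["group"]),
        region=str(row["region"]),
        cohort=str(row["cohort"]),
        section=int(row["section"]),
        image=int(row["image"]),
        mask=mask,
        channels=channels,
        source=str(mask_path),
    )
    if exclusions is not None and len(exclusions):
        sel = exclusions[
            (exclusions["donor_id"] == rec.donor_id)
            & (exclusions["region"] == rec.region)
            & (exclusions["section"] == rec.section)
            & (exclusions["image"] == rec.image)
        ]
        for _, erow in sel.iterrows():
            rec = exclude_layer(rec, str(erow["layer"]), str(erow["reason"]))
    return rec


def exclude_layer(record: ImageRecord, layer: str, reason: str) -> ImageRecord:
    """Return a copy of the record with one layer flagged excluded.

    The layer's pixels no longer contribute to any downstream quantity
    for this image; all other layers are untouched.
    """
    if layer not in LAYER_TO_LABEL:
        raise ValueError(f"unknown layer {layer!r}")
    excluded = dict(record.excluded_layers)
    excluded[layer] = reason
    return dataclasses.replace(record, excluded_layers=excluded)


def layer_pixel_counts(mask: np.ndarray) -> pd.Series:
    """Per-label pixel counts: six layers plus background and artifact.

    Counts always sum to the grid size; artifact pixels are never
    attributed to a layer (they carry their own label).
    """
    validate_mask(mask)
    counts = np.bincount(mask.ravel(), minlength=8)
    index = ["background"] + list(LAYERS) + ["artifact"]
    order = [BACKGROUND_LABEL] + [LAYER_TO_LABEL[lay] for lay in LAYERS] + [ARTIFACT_LABEL]
    return pd.Series(counts[order], index=index, name="pixels")


def save_exclusions(records: list[ImageRecord], path: str | os.PathLike) -> pd.DataFrame:
    """Persist every per-layer exclusion as an audit CSV."""
    rows = [
        {
            "donor_id": r.donor_id,
            "group": r.group,
            "region": r.region,
            "section": r.section,
            "image": r.image,
            "layer": lay,
            "reason": reason,
        }
        for r in records
        for lay, reason in sorted(r.excluded_layers.items())
    ]
    df = pd.DataFrame(rows, columns=["donor_id", "group", "region", "section", "image", "layer", "reason"])
    df.to_csv(path, index=False)
    return df


def load_exclusions(path: str | os.PathLike) -> pd.DataFrame:
    return pd.read_csv(path)


def record_log_line(record: ImageRecord) -> str:
    """One JSON line summarizing a validated record, for the run log."""
    return json.dumps(
        {
            "donor_id": record.donor_id,
            "group": record.group,
            "region": record.region,
            "cohort": record.cohort,
            "section": record.section,
            "image": record.image,
            "shape": list(record.mask.shape),
            "usable": record.usable,
            "excluded_layers": record.excluded_layers,
        },
        sort_keys=True,
    )
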