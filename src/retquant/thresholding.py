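"""Intensity thresholding: from channels to binary positivity masks.

A pixel is *positive* when its intensity is greater than or equal to the
threshold (the threshold itself belongs to the positive class; the
comparison direction is fixed so masks are bit-reproducible).

Two policies are supported. ``otsu`` (the default) picks the threshold
maximizing between-class variance over the tissue pixels of each image —
a reproducible automatic stand-in for rater-chosen values. ``fixed``
injects externally chosen thresholds per channel role, optionally
overridden per cohort, emulating a workflow where raters select one
threshold per cohort from test images.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from skimage.filters import threshold_otsu

from .layers import ARTIFACT_LABEL, BACKGROUND_LABEL
from .records import ChannelImage

__all__ = ["ThresholdPolicy", "BinaryMask", "otsu_threshold", "threshold_channel", "rater_panel"]


@dataclass(frozen=True)
class BinaryMask:
    """Thresholded positivity grid for one channel."""

    data: np.ndarray  # boolean grid
    role: str
    threshold: float

    def __post_init__(self):
        if self.data.dtype != bool:
            raise ValueError("BinaryMask.data must be boolean")


@dataclass(frozen=True)
class ThresholdPolicy:
    """Resolves one threshold per channel role (and cohort)."""

    mode: str = "otsu"  # "otsu" | "fixed"
    fixed: dict[str, float] = field(default_factory=dict)  # role -> value
    overrides: dict[str, dict[str, float]] = field(default_factory=dict)  # cohort -> role -> value

    def __post_init__(self):
        if self.mode not in ("otsu", "fixed"):
            raise ValueError(f"unknown threshold mode {self.mode!r}")

    def resolve(self, role: str, cohort: str | None = None) -> float | None:
        """Fixed threshold for this role, or None meaning compute Otsu."""
        if cohort is not None and cohort in self.overrides and role in self.overrides[cohort]:
            return float(self.overrides[cohort][role])
        if self.mode == "fixed":
            if role not in self.fixed:
                raise ValueError(f"fixed threshold policy has no value for role {role!r}")
            return float(self.fixed[role])
        return None


def tissue_selector(mask: np.ndarray) -> np.ndarray:
    """Boolean grid of pixels that belong to tissue (any retinal layer)."""
    return (mask != BACKGROUND_LABEL) & (mask != ARTIFACT_LABEL)


def otsu_threshold(channel: ChannelImage | np.ndarray, restrict_to: np.ndarray | None = None) -> float:
    """Otsu threshold over the selected pixels' intensity histogram.

    ``restrict_to`` is a boolean grid (typically the tissue pixels of the
    layer mask); omitted, all pixels are considered.  A constant image
    has no separating threshold and raises :class:`ValueError`.
    """
    data = channel.data if isinstance(channel, ChannelImage) else np.asarray(channel)
    values = data[restrict_to] if restrict_to is not None else data.ravel()
    if values.size == 0:
        raise ValueError("no pixels selected for threshold estimation")
    if np.all(values == values.flat[0]):
        raise ValueError("constant image: no threshold separates classes")
    t = float(threshold_otsu(values))
    # skimage's convention is foreground > t; positivity here is >= t, so
    # return the midpoint of the gap between the two classes — same split,
    # and the threshold lies strictly between the classes' values
    below = values[values <= t]
    above = values[values > t]
    if above.size == 0 or below.size == 0:
        return t
    return float((float(below.max()) + float(above.min())) / 2.0)


def threshold_channel(
    channel: ChannelImage,
    policy: ThresholdPolicy | float,
    mask: np.ndarray | None = None,
    cohort: str | None = None,
) -> BinaryMask:
    """Apply a threshold policy to one channel.

    A bare number is accepted as a fixed threshold.  In ``otsu`` mode the
    threshold is estimated on the tissue pixels of ``mask`` when given.
    The applied threshold is recorded on the returned mask.
    """
    if isinstance(policy, (int, float)):
        t = float(policy)
    else:
        resolved = policy.resolve(channel.role, cohort)
        if resolved is not None:
            t = resolved
        else:
            sel = tissue_selector(mask) if mask is not None else None
            t = otsu_threshold(channel, restrict_to=sel)
    return BinaryMask(data=channel.data >= t, role=channel.role, threshold=t)


def rater_panel(
    channel: ChannelImage,
    candidates: list[float],
    outdir: str | os.PathLike,
    mask: np.ndarray | None = None,
) -> list[Path]:
    """Write one overlay PNG per candidate threshold for visual review.

    Shows the original intensities with the positive-pixel outline on
    top, side-by-side comparison being how raters pick thresholds.  Pure
    presentation: no analysis state is touched.
    """
    if not candidates:
        raise ValueError("at least one candidate threshold required")
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from skimage.segmentation import find_boundaries

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for t in candidates:
        bm = threshold_channel(channel, float(t), mask=mask)
        fig, ax = plt.subplots(figsize=(6, 4))
        ax.imshow(channel.data, cmap="gray", interpolation="nearest")
        outline = find_boundaries(bm.data, mode="outer")
        overlay = np.zeros((*outline.shape, 4))
        overlay[outline] = (1.0, 0.1, 0.1, 0.9)
        ax.imshow(overlay, interpolation="nearest")
        ax.set_title(f"{channel.role}  threshold={t:g}  positive={int(bm.data.sum())} px")
        ax.axis("off")
        p = outdir / f"panel_{channel.role}_t{float(t):g}.png"
        fig.savefig(p, dpi=100, bbox_inches="tight")
        plt.close(fig)
        paths.append(p)
    return paths
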