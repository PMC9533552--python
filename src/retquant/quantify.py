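"""Per-image pixel quantification within retinal layers.

All quantities are plain pixel-count ratios on the 0-100 percentage
scale:

* layer positive fraction — positive pixels of one channel within a
  layer, over the layer's pixel count;
* conditional colocalization — the red-positive percentage inside vs
  outside the green marker's footprint (equality is the "randomly
  distributed" null);
* macroglia partition — GS∩GFAP (activated Müller cells), GS-only
  (resting Müller cells) and GFAP-only (astrocytes) percentages per
  inner/outer layer group;
* coverage — the percentage of amyloid-positive pixels that fall inside
  the microglial footprint.

Undefined ratios (empty denominators) propagate as missing values, never
as zeros: a layer with no amyloid has no defined coverage. Excluded
layers simply emit no rows. Artifact pixels carry their own mask label
and are therefore absent from every numerator and denominator.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .layers import INNER_LAYERS, LAYER_TO_LABEL, LAYERS, OUTER_LAYERS, layer_group
from .records import ImageRecord
from .thresholding import BinaryMask

__all__ = [
    "layer_positive_fraction",
    "conditional_coloc",
    "macroglia_partition",
    "coverage_fraction",
]

_META_COLS = ("donor_id", "group", "region", "section", "image")


def _meta(record: ImageRecord) -> dict:
    return {
        "donor_id": record.donor_id,
        "group": record.group,
        "region": record.region,
        "section": record.section,
        "image": record.image,
    }


def _aligned(record: ImageRecord, *masks: BinaryMask) -> None:
    for bm in masks:
        if bm.data.shape != record.mask.shape:
            raise ValueError(
                f"binary mask ({bm.role}) shape {bm.data.shape} does not match "
                f"layer mask shape {record.mask.shape}"
            )


def _layer_selectors(record: ImageRecord):
    """Yield (layer name, boolean grid) for each included, non-empty layer."""
    for lay in record.included_layers():
        sel = record.mask == LAYER_TO_LABEL[lay]
        n = int(sel.sum())
        if n == 0:
            continue
        yield lay, sel, n


def layer_positive_fraction(positivity: BinaryMask, record: ImageRecord) -> pd.DataFrame:
    """One row per included layer: percent positive pixels of a channel.

    percent = 100 * |positive ∩ layer| / |layer|.  Excluded layers and
    zero-pixel layers are absent from the output.
    """
    _aligned(record, positivity)
    rows = []
    for lay, sel, n in _layer_selectors(record):
        pos = int(np.count_nonzero(positivity.data & sel))
        rows.append(
            {
                **_meta(record),
                "layer": lay,
                "role": positivity.role,
                "positive_px": pos,
                "layer_px": n,
                "percent": 100.0 * pos / n,
            }
        )
    return pd.DataFrame(
        rows, columns=[*_META_COLS, "layer", "role", "positive_px", "layer_px", "percent"]
    )


def conditional_coloc(
    red: BinaryMask, green: BinaryMask, record: ImageRecord
) -> pd.DataFrame:
    """Red-positive percentage inside vs outside the green footprint.

    Per layer L:  p_pos = 100·|R∩G∩L|/|G∩L|,  p_neg = 100·|R∩Gᶜ∩L|/|Gᶜ∩L|.
    A percentage whose denominator is empty is reported as NaN and the
    row flagged, never silently dropped.
    """
    _aligned(record, red, green)
    rows = []
    for lay, sel, n in _layer_selectors(record):
        g = green.data & sel
        n_pos = int(np.count_nonzero(g))
        n_neg = n - n_pos
        r_in = int(np.count_nonzero(red.data & g))
        r_out = int(np.count_nonzero(red.data & sel & ~green.data))
        p_pos = 100.0 * r_in / n_pos if n_pos else np.nan
        p_neg = 100.0 * r_out / n_neg if n_neg else np.nan
        rows.append(
            {
                **_meta(record),
                "layer": lay,
                "p_pos": p_pos,
                "p_neg": p_neg,
                "marker_pos_px": n_pos,
                "marker_neg_px": n_neg,
                "defined": bool(n_pos and n_neg),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[*_META_COLS, "layer", "p_pos", "p_neg", "marker_pos_px", "marker_neg_px", "defined"],
    )


def macroglia_partition(gs: BinaryMask, gfap: BinaryMask, record: ImageRecord) -> pd.DataFrame:
    """Three-way GS/GFAP pixel partition per inner/outer layer group.

    Counts are pooled over the layers of each group before normalizing
    (the exact pixel-level statistic), yielding percentages of pixels
    positive for both stains, GS only, and GFAP only.  By construction
    %both + %GS-only = %GS-total and %both + %GFAP-only = %GFAP-total.
    """
    _aligned(record, gs, gfap)
    acc: dict[str, dict[str, int]] = {
        g: {"both": 0, "gs_only": 0, "gfap_only": 0, "px": 0} for g in ("inner", "outer")
    }
    for lay, sel, n in _layer_selectors(record):
        grp = layer_group(lay)
        g_in = gs.data & sel
        f_in = gfap.data & sel
        acc[grp]["both"] += int(np.count_nonzero(g_in & f_in))
        acc[grp]["gs_only"] += int(np.count_nonzero(g_in & ~gfap.data))
        acc[grp]["gfap_only"] += int(np.count_nonzero(f_in & ~gs.data))
        acc[grp]["px"] += n
    rows = []
    for grp in ("inner", "outer"):
        c = acc[grp]
        if c["px"] == 0:
            continue  # empty layer group: no rows
        rows.append(
            {
                **_meta(record),
                "layer_group": grp,
                "pct_both": 100.0 * c["both"] / c["px"],
                "pct_gs_only": 100.0 * c["gs_only"] / c["px"],
                "pct_gfap_only": 100.0 * c["gfap_only"] / c["px"],
                "group_px": c["px"],
            }
        )
    return pd.DataFrame(
        rows,
        columns=[*_META_COLS, "layer_group", "pct_both", "pct_gs_only", "pct_gfap_only", "group_px"],
    )


def coverage_fraction(
    amyloid: BinaryMask, microglia: BinaryMask, record: ImageRecord
) -> pd.DataFrame:
    """Percentage of amyloid-positive pixels inside the microglial footprint.

    Per layer: 100·|A∩M∩L|/|A∩L|; undefined (NaN, flagged) when the
    layer holds no amyloid-positive pixel.
    """
    _aligned(record, amyloid, microglia)
    rows = []
    for lay, sel, _n in _layer_selectors(record):
        a = amyloid.data & sel
        n_a = int(np.count_nonzero(a))
        covered = int(np.count_nonzero(a & microglia.data))
        rows.append(
            {
                **_meta(record),
                "layer": lay,
                "pct_covered": 100.0 * covered / n_a if n_a else np.nan,
                "amyloid_px": n_a,
                "defined": bool(n_a),
            }
        )
    return pd.DataFrame(
        rows, columns=[*_META_COLS, "layer", "pct_covered", "amyloid_px", "defined"]
    )
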