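"""Retinal layer vocabulary and the geo-layer analysis grid.

Cross-sections are segmented into six retinal layers, ordered inner to
outer along the axial (row) direction: RNFL, GCL, IPL, INL, OPL, ONL.
Label images use a fixed integer coding: 0 background, 1..6 the layers in
that order, 7 artifact (pixels excluded from every denominator).

A *geo-layer* is one cell of the reporting grid: a retinal region
(central, ~5 mm from the optic nerve head, or mid-peripheral, ~10 mm)
crossed with either a single layer or a layer group (inner = RNFL+GCL+IPL,
outer = INL+OPL+ONL).
"""

from __future__ import annotations

BACKGROUND_LABEL = 0
ARTIFACT_LABEL = 7

LAYERS: tuple[str, ...] = ("RNFL", "GCL", "IPL", "INL", "OPL", "ONL")
LAYER_TO_LABEL: dict[str, int] = {name: i + 1 for i, name in enumerate(LAYERS)}
LABEL_TO_LAYER: dict[int, str] = {v: k for k, v in LAYER_TO_LABEL.items()}

VALID_LABELS = frozenset(range(8))

INNER_LAYERS: tuple[str, ...] = ("RNFL", "GCL", "IPL")
OUTER_LAYERS: tuple[str, ...] = ("INL", "OPL", "ONL")
LAYER_GROUPS: tuple[str, ...] = ("inner", "outer")

REGIONS: tuple[str, ...] = ("central", "mid-peripheral")
GROUPS: tuple[str, ...] = ("AD", "control")
COHORTS: tuple[str, ...] = ("TUBB3", "GFAP", "IBA-1", "GS")


def layer_group(layer: str) -> str:
    """Return "inner" or "outer" for a layer name."""
    if layer in INNER_LAYERS:
        return "inner"
    if layer in OUTER_LAYERS:
        return "outer"
    raise ValueError(f"unknown layer {layer!r}")


def geo_layer_keys(mode: str = "layer") -> list[tuple[str, str]]:
    """Enumerate the (region, layer) analysis grid.

    ``mode="layer"`` yields 2 regions x 6 layers = 12 keys;
    ``mode="layer-group"`` yields 2 regions x 2 groups = 4 keys.
    """
    if mode == "layer":
        return [(r, lay) for r in REGIONS for lay in LAYERS]
    if mode == "layer-group":
        return [(r, g) for r in REGIONS for g in LAYER_GROUPS]
    raise ValueError(f"unknown grouping mode {mode!r}")
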