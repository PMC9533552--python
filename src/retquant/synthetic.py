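"""Synthetic retinal cross-section generator with known ground truth.

Real donor material for this kind of study is not publicly deposited, so
every downstream stage is exercised on simulated cross-sections in which
the per-layer positive-pixel fractions and the red/green colocalization
structure are known exactly.

The pixel model
---------------
Within one layer, each pixel draws a pair of binary positivity states
(red, green) independently of its neighbours.  The joint law is
parameterized by the two marginal positive fractions ``p_red`` and
``p_green`` plus an enrichment ratio ``rho``:

    q_pos = P(red+ | green+),   q_neg = P(red+ | green-),
    rho   = q_pos / q_neg,
    p_red = p_green * q_pos + (1 - p_green) * q_neg.

``rho = 1`` encodes independence of the two channels; ``rho > 1`` enriches
the red stain inside the green-positive footprint while preserving the red
marginal — exactly the structure the conditional-colocalization statistic
is designed to detect.  In the marker cohorts red is amyloid-beta (Cy3)
and green the cell marker (FITC); in the GS cohort red is glutamine
synthetase and green GFAP.

Intensities are drawn per pixel from foreground/background Gaussians,
clipped to the 16-bit range, so that global thresholding separates the
classes.  No spatial texture is imposed: the statistics under study are
pure pixel counts.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .layers import (
    ARTIFACT_LABEL,
    BACKGROUND_LABEL,
    GROUPS,
    LAYER_TO_LABEL,
    LAYERS,
    REGIONS,
)

__all__ = [
    "LayerParams",
    "IntensityModel",
    "SimulationScenario",
    "conditional_probs",
    "make_layer_geometry",
    "simulate_image",
    "write_dataset",
    "default_scenario",
]


def conditional_probs(p_red: float, p_green: float, rho: float) -> tuple[float, float]:
    """Solve the joint pixel law for (q_pos, q_neg).

    Returns ``P(red+|green+)`` and ``P(red+|green-)`` given the marginals
    and the enrichment ratio.  Raises :class:`ValueError` when the triple
    is infeasible (a conditional probability would leave [0, 1]).
    """
    for name, v in (("p_red", p_red), ("p_green", p_green)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name}={v} outside [0, 1]")
    if rho < 0:
        raise ValueError(f"rho={rho} must be >= 0")
    denom = p_green * rho + (1.0 - p_green)
    if denom == 0.0:
        # p_green == 1 with rho == 0: red can only appear on green+ pixels
        if p_red == 0.0:
            return 0.0, 0.0
        raise ValueError(f"infeasible triple p_red={p_red}, p_green={p_green}, rho={rho}")
    q_neg = p_red / denom
    q_pos = rho * q_neg
    if q_pos > 1.0 + 1e-12 or q_neg > 1.0 + 1e-12:
        raise ValueError(
            f"infeasible triple p_red={p_red}, p_green={p_green}, rho={rho}: "
            f"conditionals q_pos={q_pos:.4f}, q_neg={q_neg:.4f} exceed 1"
        )
    return min(q_pos, 1.0), min(q_neg, 1.0)


@dataclass(frozen=True)
class LayerParams:
    """Ground-truth positive fractions and enrichment for one layer."""

    p_red: float
    p_green: float
    rho: float = 1.0

    def validate(self, where: str = "") -> None:
        try:
            conditional_probs(self.p_red, self.p_green, self.rho)
        except ValueError as exc:
            raise ValueError(f"{where}: {exc}" if where else str(exc)) from None


@dataclass(frozen=True)
class IntensityModel:
    """Foreground/background Gaussian intensity model, 16-bit output."""

    fg_mean: float = 45000.0
    fg_sd: float = 3000.0
    bg_mean: float = 8000.0
    bg_sd: float = 3000.0

    def render(self, positive: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        vals = np.where(
            positive,
            rng.normal(self.fg_mean, self.fg_sd, size=positive.shape),
            rng.normal(self.bg_mean, self.bg_sd, size=positive.shape),
        )
        return np.clip(vals, 0, 65535).astype(np.uint16)


DEFAULT_THICKNESSES: dict[str, int] = {
    "RNFL": 15,
    "GCL": 15,
    "IPL": 25,
    "INL": 20,
    "OPL": 15,
    "ONL": 30,
}


def make_layer_geometry(
    height: int, width: int, thicknesses: dict[str, int] | None = None
) -> np.ndarray:
    """Build a label image of six contiguous horizontal layer bands.

    Rows run inner to outer (RNFL at top, ONL at bottom); leftover rows
    become background, split between a margin above the RNFL and one
    below the ONL.
    """
    thicknesses = dict(thicknesses or DEFAULT_THICKNESSES)
    missing = set(LAYERS) - set(thicknesses)
    if missing:
        raise ValueError(f"missing thickness for layers: {sorted(missing)}")
    if any(thicknesses[lay] <= 0 for lay in LAYERS):
        raise ValueError("layer thicknesses must all be > 0")
    total = sum(thicknesses[lay] for lay in LAYERS)
    if total > height:
        raise ValueError(f"total layer thickness {total} exceeds image height {height}")
    mask = np.full((height, width), BACKGROUND_LABEL, dtype=np.uint8)
    row = (height - total) // 2
    for lay in LAYERS:
        t = thicknesses[lay]
        mask[row : row + t, :] = LAYER_TO_LABEL[lay]
        row += t
    return mask


@dataclass
class SimulatedImage:
    """One synthetic acquisition: intensity channels plus ground truth."""

    mask: np.ndarray
    channels: dict[str, np.ndarray]  # role -> uint16 grid
    truth: dict[str, np.ndarray]  # role -> boolean positivity grid
    params: dict[str, LayerParams]  # layer -> realized parameters


def simulate_image(
    geometry: np.ndarray,
    params: dict[str, LayerParams],
    seed: int | np.random.Generator,
    intensity: IntensityModel | None = None,
    red_role: str = "amyloid",
    green_role: str = "marker",
    nuclei_fractions: dict[str, float] | None = None,
) -> SimulatedImage:
    """Draw one image pair (+ nuclei channel) on a layer geometry.

    Positivity is sampled per pixel from the joint law of each layer's
    :class:`LayerParams`; the returned object carries the exact boolean
    ground-truth masks next to the rendered intensities.  Fully
    deterministic given the seed.
    """
    intensity = intensity or IntensityModel()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    # nuclei are cosmetic (DAPI); denser in the nuclear layers
    if nuclei_fractions is None:
        nuclei_fractions = {
            lay: (0.45 if lay in ("GCL", "INL", "ONL") else 0.08) for lay in LAYERS
        }

    red = np.zeros(geometry.shape, dtype=bool)
    green = np.zeros(geometry.shape, dtype=bool)
    nuclei = np.zeros(geometry.shape, dtype=bool)
    for lay in LAYERS:
        if lay not in params:
            raise ValueError(f"no parameters supplied for layer {lay}")
        lp = params[lay]
        try:
            q_pos, q_neg = conditional_probs(lp.p_red, lp.p_green, lp.rho)
        except ValueError as exc:
            raise ValueError(f"layer {lay}: {exc}") from None
        sel = geometry == LAYER_TO_LABEL[lay]
        n = int(sel.sum())
        g = rng.random(n) < lp.p_green
        r = np.where(g, rng.random(n) < q_pos, rng.random(n) < q_neg)
        green[sel] = g
        red[sel] = r
        nuclei[sel] = rng.random(n) < nuclei_fractions[lay]

    channels = {
        red_role: intensity.render(red, rng),
        green_role: intensity.render(green, rng),
        "nuclei": intensity.render(nuclei, rng),
    }
    return SimulatedImage(
        mask=geometry,
        channels=channels,
        truth={red_role: red, green_role: green},
        params=dict(params),
    )


@dataclass
class SimulationScenario:
    """Full description of a simulated cohort.

    ``params`` maps (group, region, layer) to a :class:`LayerParams`
    triple.  ``donor_sigma`` adds per-donor lognormal variability to the
    positive fractions (biological heterogeneity between donors); the
    *realized* per-image fractions are what the manifest records as
    ground truth.
    """

    cohort: str
    params: dict[tuple[str, str, str], LayerParams]
    n_ad: int = 5
    n_control: int = 7
    sections_per_donor: int = 2
    images_per_region: int = 2
    height: int = 140
    width: int = 200
    thicknesses: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_THICKNESSES))
    intensity: IntensityModel = field(default_factory=IntensityModel)
    donor_sigma: float = 0.25
    seed: int = 0

    @property
    def red_role(self) -> str:
        return "gs" if self.cohort == "GS" else "amyloid"

    @property
    def green_role(self) -> str:
        return "gfap" if self.cohort == "GS" else "marker"

    def validate(self) -> None:
        if self.n_ad < 0 or self.n_control < 0:
            raise ValueError("donor counts must be >= 0")
        for g in GROUPS:
            for r in REGIONS:
                for lay in LAYERS:
                    key = (g, r, lay)
                    if key not in self.params:
                        raise ValueError(f"scenario missing parameters for {key}")
                    self.params[key].validate(where=f"geo-layer {key}")
        make_layer_geometry(self.height, self.width, self.thicknesses)

    def donors(self) -> list[tuple[str, str]]:
        ad = [(f"A{i + 1:02d}", "AD") for i in range(self.n_ad)]
        ctl = [(f"C{i + 1:02d}", "control") for i in range(self.n_control)]
        return ad + ctl


def _realized_params(
    base: LayerParams, red_factor: float, green_factor: float
) -> LayerParams:
    """Apply donor-level multiplicative effects, kept inside feasibility."""
    p_red = min(base.p_red * red_factor, 0.95)
    p_green = min(base.p_green * green_factor, 0.95)
    lp = LayerParams(p_red=p_red, p_green=p_green, rho=base.rho)
    # shrink rho toward 1 if the scaled marginals made the triple infeasible
    rho = base.rho
    while True:
        try:
            conditional_probs(p_red, p_green, rho)
            return LayerParams(p_red=p_red, p_green=p_green, rho=rho)
        except ValueError:
            rho = 1.0 + 0.5 * (rho - 1.0)
            if abs(rho - 1.0) < 1e-6:
                return LayerParams(p_red=p_red, p_green=p_green, rho=1.0)


def write_dataset(scenario: SimulationScenario, outdir: str | os.PathLike) -> pd.DataFrame:
    """Simulate a whole cohort and write it to disk.

    Writes one 16-bit grayscale TIFF per channel, an 8-bit label TIFF per
    image, and ``manifest.csv`` with one row per image carrying the
    identifiers, relative file paths, and the realized ground-truth
    parameters per layer.  Refuses to overwrite an existing manifest.
    """
    scenario.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest_path = outdir / "manifest.csv"
    if manifest_path.exists():
        raise FileExistsError(f"manifest already exists: {manifest_path}")

    geometry = make_layer_geometry(scenario.height, scenario.width, scenario.thicknesses)
    root_ss = np.random.SeedSequence(scenario.seed)
    donor_rng = np.random.default_rng(root_ss.spawn(1)[0])
    rows: list[dict] = []
    red_role, green_role = scenario.red_role, scenario.green_role

    for donor_id, group in scenario.donors():
        red_f = float(np.exp(donor_rng.normal(0.0, scenario.donor_sigma)))
        green_f = float(np.exp(donor_rng.normal(0.0, scenario.donor_sigma)))
        for section in range(1, scenario.sections_per_donor + 1):
            for region in REGIONS:
                for image in range(1, scenario.images_per_region + 1):
                    child = root_ss.spawn(1)[0]
                    img_seed = int(child.generate_state(1)[0] % (2**31))
                    params = {
                        lay: _realized_params(
                            scenario.params[(group, region, lay)], red_f, green_f
                        )
                        for lay in LAYERS
                    }
                    sim = simulate_image(
                        geometry,
                        params,
                        seed=img_seed,
                        intensity=scenario.intensity,
                        red_role=red_role,
                        green_role=green_role,
                    )
                    region_tag = region.replace("-", "")
                    stem = f"{donor_id}_{region_tag}_{section}_{image}"
                    mask_file = f"{stem}_mask.tif"
                    tifffile.imwrite(outdir / mask_file, sim.mask)
                    row = {
                        "donor_id": donor_id,
                        "group": group,
                        "region": region,
                        "section": section,
                        "image": image,
                        "cohort": scenario.cohort,
                        "seed": img_seed,
                        "red_role": red_role,
                        "green_role": green_role,
                        "mask_file": mask_file,
                    }
                    for role, data in sim.channels.items():
                        fname = f"{stem}_{role}.tif"
                        tifffile.imwrite(outdir / fname, data)
                        row[f"{role}_file"] = fname
                    for lay in LAYERS:
                        lp = params[lay]
                        row[f"p_red_{lay}"] = lp.p_red
                        row[f"p_green_{lay}"] = lp.p_green
                        row[f"rho_{lay}"] = lp.rho
                    rows.append(row)

    manifest = pd.DataFrame(rows)
    manifest.to_csv(manifest_path, index=False)
    return manifest


# ---------------------------------------------------------------------------
# Default cohort scenarios: the qualitative AD-vs-control contrast
# ---------------------------------------------------------------------------

_ABETA_BASE = 0.025  # baseline amyloid positive fraction
_ABETA_ELEVATED = 0.06  # AD mid-peripheral GCL/IPL/INL/OPL
_ABETA_ELEVATED_LAYERS = ("GCL", "IPL", "INL", "OPL")

_GREEN_BY_COHORT: dict[str, dict[str, float]] = {
    "TUBB3": {"RNFL": 0.30, "GCL": 0.20, "IPL": 0.15, "INL": 0.10, "OPL": 0.10, "ONL": 0.08},
    "GFAP": {"RNFL": 0.25, "GCL": 0.15, "IPL": 0.10, "INL": 0.06, "OPL": 0.06, "ONL": 0.03},
    "IBA-1": {"RNFL": 0.04, "GCL": 0.03, "IPL": 0.03, "INL": 0.02, "OPL": 0.02, "ONL": 0.015},
}


def _abeta_fraction(group: str, region: str, layer: str) -> float:
    if group == "AD" and region == "mid-peripheral" and layer in _ABETA_ELEVATED_LAYERS:
        return _ABETA_ELEVATED
    return _ABETA_BASE


def default_scenario(cohort: str, seed: int = 0, **overrides) -> SimulationScenario:
    """Demo scenario for one cohort encoding the study's group contrast.

    Amyloid is elevated only in AD mid-peripheral GCL/IPL/INL/OPL; GFAP is
    globally reduced in AD; IBA-1 is elevated in AD mid-peripherally and
    its amyloid enrichment is stronger in controls; TUBB3 shows strong
    amyloid enrichment in both groups; the GS cohort reduces GS and the
    GS-GFAP coupling in AD mid-peripheral retina.
    """
    params: dict[tuple[str, str, str], LayerParams] = {}
    if cohort in ("TUBB3", "GFAP", "IBA-1"):
        green = _GREEN_BY_COHORT[cohort]
        for group in GROUPS:
            for region in REGIONS:
                for lay in LAYERS:
                    p_red = _abeta_fraction(group, region, lay)
                    p_green = green[lay]
                    if cohort == "GFAP":
                        rho = 1.1
                        if group == "AD":
                            p_green *= 0.6
                    elif cohort == "IBA-1":
                        rho = 1.3 if group == "AD" else 3.0
                        if group == "AD" and region == "mid-peripheral":
                            p_green *= 2.0
                    else:  # TUBB3
                        rho = 2.0
                    params[(group, region, lay)] = LayerParams(p_red, p_green, rho)
    elif cohort == "GS":
        gfap = _GREEN_BY_COHORT["GFAP"]
        for group in GROUPS:
            for region in REGIONS:
                for lay in LAYERS:
                    p_gs = 0.15
                    rho = 3.0
                    p_gfap = gfap[lay]
                    if group == "AD":
                        p_gfap *= 0.6
                        rho = 2.0
                        if region == "mid-peripheral" and lay in ("RNFL", "GCL", "IPL"):
                            p_gs = 0.10
                    params[(group, region, lay)] = LayerParams(p_gs, p_gfap, rho)
    else:
        raise ValueError(f"unknown cohort {cohort!r}")
    return SimulationScenario(cohort=cohort, params=params, seed=seed, **overrides)
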