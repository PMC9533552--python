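"""End-to-end orchestration: simulate -> classify -> quantify -> compare.

One YAML config drives both directions of the pipeline: ``simulate``
writes synthetic cohorts to disk (images, label masks, manifest), and
``analyze`` consumes a manifest — simulated or real — and produces every
quantification table, the geo-layer comparison results, a significance
summary, a machine-readable dump of all p-values, bar plots, and a
JSON-lines run log recording each threshold, exclusion, and outlier
decision. Identical config + seed reproduce identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import quantify, stats, synthetic
from .layers import COHORTS, GROUPS, LAYERS, REGIONS, geo_layer_keys
from .records import ImageRecord, load_exclusions, read_record, record_log_line
from .thresholding import ThresholdPolicy, threshold_channel

__all__ = ["PipelineConfig", "run_simulate", "run_analyze", "run_demo", "analyze_cohort"]


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

_SIM_KEYS = {
    "cohorts", "n_ad", "n_control", "sections_per_donor", "images_per_region",
    "height", "width", "thicknesses", "donor_sigma",
}
_ANALYZE_KEYS = {"manifests", "exclusions", "alpha"}
_THRESHOLD_KEYS = {"mode", "fixed", "overrides"}
_TOP_KEYS = {"seed", "output_dir", "threshold", "simulate", "analyze"}


def _reject_unknown(d: dict, allowed: set, where: str) -> None:
    unknown = set(d) - allowed
    if unknown:
        raise ValueError(f"unknown config key(s) in {where}: {sorted(unknown)}")


@dataclass
class PipelineConfig:
    """Validated pipeline configuration (see ``from_yaml``)."""

    output_dir: Path
    seed: int = 0
    threshold: ThresholdPolicy = field(default_factory=ThresholdPolicy)
    sim_cohorts: tuple[str, ...] = COHORTS
    sim_overrides: dict = field(default_factory=dict)
    manifests: dict[str, Path] = field(default_factory=dict)  # cohort -> manifest path
    exclusions: Path | None = None
    alpha: float = 0.05

    @classmethod
    def from_dict(cls, raw: dict, base: Path | None = None) -> "PipelineConfig":
        base = base or Path.cwd()
        _reject_unknown(raw, _TOP_KEYS, "config")
        if "output_dir" not in raw:
            raise ValueError("config requires output_dir")
        thr = raw.get("threshold", {}) or {}
        _reject_unknown(thr, _THRESHOLD_KEYS, "threshold")
        policy = ThresholdPolicy(
            mode=thr.get("mode", "otsu"),
            fixed=dict(thr.get("fixed", {}) or {}),
            overrides={k: dict(v) for k, v in (thr.get("overrides", {}) or {}).items()},
        )
        sim = raw.get("simulate", {}) or {}
        _reject_unknown(sim, _SIM_KEYS, "simulate")
        cohorts = tuple(sim.get("cohorts", COHORTS))
        bad = set(cohorts) - set(COHORTS)
        if bad:
            raise ValueError(f"unknown cohort(s) in simulate.cohorts: {sorted(bad)}")
        sim_overrides = {k: v for k, v in sim.items() if k != "cohorts"}
        ana = raw.get("analyze", {}) or {}
        _reject_unknown(ana, _ANALYZE_KEYS, "analyze")
        manifests = {
            str(c): (base / p if not Path(p).is_absolute() else Path(p))
            for c, p in (ana.get("manifests", {}) or {}).items()
        }
        excl = ana.get("exclusions")
        return cls(
            output_dir=base / raw["output_dir"] if not Path(raw["output_dir"]).is_absolute()
            else Path(raw["output_dir"]),
            seed=int(raw.get("seed", 0)),
            threshold=policy,
            sim_cohorts=cohorts,
            sim_overrides=sim_overrides,
            manifests=manifests,
            exclusions=(base / excl if excl and not Path(excl).is_absolute() else
                        Path(excl) if excl else None),
            alpha=float(ana.get("alpha", 0.05)),
        )

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "PipelineConfig":
        path = Path(path)
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw, base=path.parent)

    def archive(self, outdir: Path) -> None:
        """Serialize the effective config into the run directory."""
        d = {
            "output_dir": str(self.output_dir),
            "seed": self.seed,
            "threshold": {
                "mode": self.threshold.mode,
                "fixed": dict(self.threshold.fixed),
                "overrides": {k: dict(v) for k, v in self.threshold.overrides.items()},
            },
            "simulate": {"cohorts": list(self.sim_cohorts), **self.sim_overrides},
            "analyze": {
                "manifests": {c: str(p) for c, p in self.manifests.items()},
                "exclusions": str(self.exclusions) if self.exclusions else None,
                "alpha": self.alpha,
            },
        }
        with open(outdir / "config.yaml", "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)


# ---------------------------------------------------------------------------
# simulate
# ---------------------------------------------------------------------------

def run_simulate(config: PipelineConfig) -> dict[str, pd.DataFrame]:
    """Write one synthetic dataset per configured cohort.

    Each cohort lands in ``<output_dir>/data/<cohort>/`` with its own
    manifest; cohort seeds are derived from the config seed so the whole
    dataset is reproducible from one integer.
    """
    out = Path(config.output_dir) / "data"
    manifests: dict[str, pd.DataFrame] = {}
    for i, cohort in enumerate(config.sim_cohorts):
        scenario = synthetic.default_scenario(
            cohort, seed=config.seed * 1000 + i, **config.sim_overrides
        )
        cohort_dir = out / cohort.replace("-", "")
        manifests[cohort] = synthetic.write_dataset(scenario, cohort_dir)
        config.manifests[cohort] = cohort_dir / "manifest.csv"
    return manifests


# ---------------------------------------------------------------------------
# analyze
# ---------------------------------------------------------------------------

def _threshold_record(record: ImageRecord, policy: ThresholdPolicy):
    """Threshold the red/green channels of one record."""
    roles = [r for r in record.channels if r != "nuclei"]
    masks = {
        role: threshold_channel(record.channels[role], policy, mask=record.mask,
                                cohort=record.cohort)
        for role in roles
    }
    return masks


def analyze_cohort(
    manifest: pd.DataFrame,
    image_dir: str | os.PathLike,
    cohort: str,
    policy: ThresholdPolicy | None = None,
    exclusions: pd.DataFrame | None = None,
    log_lines: list[str] | None = None,
) -> dict[str, pd.DataFrame]:
    """Quantify every image of one cohort manifest.

    Returns long-format tables: ``fractions`` always; ``coloc`` for the
    marker cohorts; ``coverage`` for IBA-1; ``macroglia`` for GS; plus
    the per-image ``thresholds`` log.
    """
    policy = policy or ThresholdPolicy()
    fractions, coloc, coverage, macroglia, thresholds = [], [], [], [], []
    for _, row in manifest.iterrows():
        rec = read_record(row, image_dir, exclusions=exclusions)
        if log_lines is not None:
            log_lines.append(record_log_line(rec))
        if not rec.usable:
            continue
        masks = _threshold_record(rec, policy)
        for role, bm in masks.items():
            thresholds.append(
                {"donor_id": rec.donor_id, "region": rec.region, "section": rec.section,
                 "image": rec.image, "cohort": cohort, "role": role,
                 "threshold": bm.threshold}
            )
            fractions.append(quantify.layer_positive_fraction(bm, rec))
        if cohort == "GS":
            macroglia.append(quantify.macroglia_partition(masks["gs"], masks["gfap"], rec))
        else:
            coloc.append(quantify.conditional_coloc(masks["amyloid"], masks["marker"], rec))
            if cohort == "IBA-1":
                coverage.append(quantify.coverage_fraction(masks["amyloid"], masks["marker"], rec))

    def _cat(parts):
        return pd.concat(parts, ignore_index=True) if parts else pd.DataFrame()

    out = {"fractions": _cat(fractions), "thresholds": pd.DataFrame(thresholds)}
    if cohort == "GS":
        out["macroglia"] = _cat(macroglia)
    else:
        out["coloc"] = _cat(coloc)
    if cohort == "IBA-1":
        out["coverage"] = _cat(coverage)
    return out


def cohort_statistics(
    cohort: str, tables: dict[str, pd.DataFrame], alpha: float = 0.05
) -> dict[str, pd.DataFrame]:
    """Geo-layer statistics for one cohort's quantification tables.

    Marker cohorts: rank-sum AD-vs-control per role and geo-layer, plus
    the paired colocalization test per group and geo-layer (and coverage
    comparisons for IBA-1).  GS cohort: rank-sum comparisons of the
    three macroglia classes per region and inner/outer layer group.
    """
    results: dict[str, pd.DataFrame] = {}
    if cohort == "GS":
        points = stats.aggregate(
            tables["macroglia"], ["pct_both", "pct_gs_only", "pct_gfap_only"],
            mode="layer-group",
        )
        comps = []
        for measure in ("pct_both", "pct_gs_only", "pct_gfap_only"):
            for region, key in geo_layer_keys("layer-group"):
                r = stats.compare_groups(points, region, key, value_col=measure)
                row = r.row()
                row["measure"] = measure
                comps.append(row)
        results["comparisons"] = pd.DataFrame(comps)
        results["points"] = points
        return results

    frac = tables["fractions"]
    comps = []
    for role in sorted(frac["role"].unique()):
        points = stats.aggregate(frac[frac["role"] == role], "percent", mode="layer")
        for region, key in geo_layer_keys("layer"):
            r = stats.compare_groups(points, region, key, value_col="percent")
            row = r.row()
            row["measure"] = role
            comps.append(row)
    results["comparisons"] = pd.DataFrame(comps)

    cpoints = stats.aggregate(tables["coloc"], ["p_pos", "p_neg"], mode="layer")
    coloc_rows, coloc_results = [], {}
    for group in GROUPS:
        group_results = []
        for region, key in geo_layer_keys("layer"):
            r = stats.paired_coloc_test(cpoints, region, key, group, alpha=alpha)
            row = r.row()
            row["group"] = group
            coloc_rows.append(row)
            group_results.append(r)
        coloc_results[group] = stats.significance_summary(group_results, alpha=alpha)
    results["coloc_tests"] = pd.DataFrame(coloc_rows)
    results["coloc_summary"] = pd.concat(
        [df.assign(group=g) for g, df in coloc_results.items()], ignore_index=True
    )
    results["coloc_points"] = cpoints

    if cohort == "IBA-1" and "coverage" in tables and len(tables["coverage"]):
        vpoints = stats.aggregate(tables["coverage"], "pct_covered", mode="layer")
        cov = []
        for region, key in geo_layer_keys("layer"):
            r = stats.compare_groups(vpoints, region, key, value_col="pct_covered")
            row = r.row()
            row["measure"] = "coverage"
            cov.append(row)
        results["coverage_comparisons"] = pd.DataFrame(cov)
    return results


def _plot_comparisons(df: pd.DataFrame, path: Path, title: str) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, len(REGIONS), figsize=(11, 4), sharey=True)
    for ax, region in zip(np.atleast_1d(axes), REGIONS):
        sub = df[df["region"] == region]
        xs = np.arange(len(sub))
        ax.bar(xs - 0.2, sub["mean_AD"], width=0.4, yerr=sub["sem_AD"], label="AD",
               color="firebrick", capsize=2)
        ax.bar(xs + 0.2, sub["mean_control"], width=0.4, yerr=sub["sem_control"],
               label="control", color="steelblue", capsize=2)
        for x, (_, row) in zip(xs, sub.iterrows()):
            s = stats.stars(row["p_value"])
            if s:
                top = max(
                    (row["mean_AD"] or 0) + (row["sem_AD"] or 0),
                    (row["mean_control"] or 0) + (row["sem_control"] or 0),
                )
                ax.text(x, top * 1.05, s, ha="center")
        ax.set_xticks(xs, sub["key"])
        ax.set_title(region)
        ax.set_ylabel("% positive pixels")
    np.atleast_1d(axes)[0].legend()
    fig.suptitle(title)
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)


def run_analyze(config: PipelineConfig) -> dict[str, dict[str, pd.DataFrame]]:
    """Analyze every configured cohort manifest and write all outputs.

    Per cohort: quantification CSVs, comparison CSVs, bar plots.  Across
    cohorts: ``all_p_values.csv`` (every p-value computed in the run)
    and ``run_log.jsonl``.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.archive(outdir)
    exclusions = load_exclusions(config.exclusions) if config.exclusions else None
    log_lines: list[str] = []
    all_results: dict[str, dict[str, pd.DataFrame]] = {}
    p_rows = []
    for cohort, manifest_path in sorted(config.manifests.items()):
        manifest_path = Path(manifest_path)
        if not manifest_path.exists():
            raise FileNotFoundError(f"manifest not found: {manifest_path}")
        manifest = pd.read_csv(manifest_path)
        tables = analyze_cohort(
            manifest, manifest_path.parent, cohort, policy=config.threshold,
            exclusions=exclusions, log_lines=log_lines,
        )
        results = cohort_statistics(cohort, tables, alpha=config.alpha)
        cdir = outdir / cohort.replace("-", "")
        cdir.mkdir(parents=True, exist_ok=True)
        for name, df in {**tables, **results}.items():
            df.to_csv(cdir / f"{name}.csv", index=False)
        comp = results["comparisons"]
        if {"mean_AD", "mean_control"}.issubset(comp.columns):
            for measure in comp["measure"].unique():
                _plot_comparisons(
                    comp[comp["measure"] == measure].copy(),
                    cdir / f"comparisons_{measure}.png",
                    f"{cohort}: {measure} (AD vs control)",
                )
        for key in ("comparisons", "coloc_tests", "coverage_comparisons"):
            if key in results:
                sub = results[key][["region", "key", "test", "p_value"]].copy()
                sub["cohort"] = cohort
                sub["analysis"] = key
                if "group" in results[key].columns:
                    sub["group"] = results[key]["group"]
                if "measure" in results[key].columns:
                    sub["measure"] = results[key]["measure"]
                p_rows.append(sub)
        all_results[cohort] = {**tables, **results}
    pd.concat(p_rows, ignore_index=True).to_csv(outdir / "all_p_values.csv", index=False)
    with open(outdir / "run_log.jsonl", "w") as fh:
        fh.write("\n".join(log_lines) + ("\n" if log_lines else ""))
    return all_results


def run_demo(outdir: str | os.PathLike, seed: int = 0,
             cohorts: tuple[str, ...] = COHORTS) -> dict:
    """Simulate all cohorts and analyze them in one reproducible run."""
    config = PipelineConfig(output_dir=Path(outdir), seed=seed, sim_cohorts=cohorts)
    run_simulate(config)
    return run_analyze(config)
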