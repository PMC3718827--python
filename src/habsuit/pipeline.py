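"""End-to-end orchestration: simulate -> envelope -> model -> validate ->
warming scenarios -> area accounting, with a reproducibility manifest.

The run configuration is one flat JSON document; per-stage seeds are derived
deterministically from the global seed so re-running the same configuration
reproduces every output byte-for-byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from habsuit import io
from habsuit.accounting import band_areas, category_areas, loss_table, overlap_stats
from habsuit.envelope import build_envelope, envelope_area_km2, envelope_mask
from habsuit.grid import LayerStack, OccurrenceSet, RegionSet, filter_to_coverage
from habsuit.maxent import FeatureMapper, features_at, fit, predict_logistic, sample_background
from habsuit.scenarios import ScenarioSpec, apply_scenario, temperature_increment
from habsuit.synth import SyntheticConfig, TruthSpec, generate_environment, generate_occurrences, generate_regions
from habsuit.validation import SplitSpec, cross_validate

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    seed: int = 0
    synthetic: SyntheticConfig | None = None
    truth: TruthSpec | None = None
    inputs: dict | None = None  # {"stack": dir, "occurrences": csv, "regions": geojson}
    split: SplitSpec = field(default_factory=SplitSpec)
    scenario: ScenarioSpec = field(default_factory=ScenarioSpec)
    background_n: int = 10000
    buffer_km: float = 20.0
    beta: float = 1.0
    n_regions: int = 4
    linkage_km: float = 10.0
    envelope_buffer_km: float = 1.0

    def __post_init__(self) -> None:
        if (self.synthetic is None) == (self.inputs is None):
            raise ConfigError("config must name exactly one of a synthetic block or input paths")

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        synth = d.get("synthetic")
        return cls(
            seed=d.get("seed", 0),
            synthetic=SyntheticConfig(**synth) if synth is not None else None,
            truth=TruthSpec(
                intervals={k: tuple(v) for k, v in d["truth"]["intervals"].items()},
                preferred_landscape=frozenset(d["truth"]["preferred_landscape"]),
                temperature_gradient=d["truth"].get("temperature_gradient", -0.6),
            )
            if "truth" in d
            else (TruthSpec() if synth is not None else None),
            inputs=d.get("inputs"),
            split=SplitSpec(**d.get("split", {})),
            scenario=ScenarioSpec(**{**d.get("scenario", {}), "epochs": tuple(d.get("scenario", {}).get("epochs", (2030, 2050, 2080, 2100)))}),
            background_n=d.get("background", {}).get("n", 10000),
            buffer_km=d.get("background", {}).get("buffer_km", 20.0),
            beta=d.get("beta", 1.0),
            n_regions=d.get("n_regions", 4),
            linkage_km=d.get("linkage_km", 10.0),
            envelope_buffer_km=d.get("envelope_buffer_km", 1.0),
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def to_dict(self) -> dict:
        d: dict = {
            "seed": self.seed,
            "split": {"train_fraction": self.split.train_fraction, "replicates": self.split.replicates, "seed": self.split.seed},
            "scenario": {
                "baseline_year": self.scenario.baseline_year,
                "horizon_year": self.scenario.horizon_year,
                "total_increase_c": self.scenario.total_increase_c,
                "epochs": list(self.scenario.epochs),
            },
            "background": {"n": self.background_n, "buffer_km": self.buffer_km},
            "beta": self.beta,
            "n_regions": self.n_regions,
            "linkage_km": self.linkage_km,
            "envelope_buffer_km": self.envelope_buffer_km,
        }
        if self.synthetic is not None:
            d["synthetic"] = self.synthetic.to_dict()
            d["truth"] = self.truth.to_dict()
        else:
            d["inputs"] = self.inputs
        return d


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic 32-bit stage seed from the global seed and stage name."""
    digest = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _load_inputs(config: RunConfig) -> tuple[LayerStack, OccurrenceSet, RegionSet]:
    if config.synthetic is not None:
        # the synthetic seed is always derived from the global seed
        synth = SyntheticConfig(**{**config.synthetic.to_dict(), "seed": stage_seed(config.seed, "simulate")})
        stack = generate_environment(synth, config.truth)
        occ = generate_occurrences(stack, config.truth, synth)
        regions = generate_regions(synth, config.n_regions)
        return stack, occ, regions
    stack = io.read_stack(config.inputs["stack"])
    occ = io.read_occurrences(config.inputs["occurrences"])
    regions = io.read_regions(config.inputs["regions"])
    return stack, occ, regions


def run_all(config: RunConfig, outdir: str | Path) -> dict:
    """Execute every stage for both background modes and write all artifacts.

    Returns the manifest (also written to ``manifest.json``).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    def stage(name):
        logger.info("stage: %s", name)

    stage("inputs")
    stack, occ, regions = _load_inputs(config)
    occ = filter_to_coverage(occ, stack)
    io.write_stack(stack, outdir / "stack")
    io.write_occurrences(occ, outdir / "occurrences.csv")
    io.write_regions(regions, outdir / "regions.geojson")
    if config.truth is not None:
        (outdir / "truth.json").write_text(json.dumps(config.truth.to_dict(), indent=2))

    stage("eea")
    env = build_envelope(stack, occ, config.linkage_km, config.envelope_buffer_km)
    env_mask = envelope_mask(stack, env)
    (outdir / "envelope.json").write_text(json.dumps(env.to_dict(), indent=2))
    io.write_ascii_grid(env_mask, outdir / "envelope_mask.asc")

    stage("validate")
    report = cross_validate(
        occ,
        stack,
        SplitSpec(config.split.train_fraction, config.split.replicates, stage_seed(config.seed, "validate")),
        background_n=config.background_n,
        buffer_km=config.buffer_km,
        beta=config.beta,
    )
    report.replicates.to_csv(outdir / "validation_replicates.csv", index=False)
    report.summary.to_csv(outdir / "validation_summary.csv", index=False)

    stage("fit")
    occ_df = features_at(stack, occ)
    models = {}
    for mode in ("global", "bias"):
        bg = sample_background(
            stack, occ, n=config.background_n, mode=mode,
            buffer_km=config.buffer_km, seed=stage_seed(config.seed, f"background:{mode}"),
        )
        bg_df = features_at(stack, bg)
        mapper = FeatureMapper.fit(
            bg_df,
            stack.continuous_names(),
            {n: sorted(int(v) for v in np.unique(bg_df[n])) for n in stack.categorical_names()},
        )
        model = fit(
            mapper.transform(occ_df),
            mapper.transform(bg_df),
            beta=config.beta,
            mapper=mapper,
            metadata={"mode": mode, "seed": int(bg.seed), "n_background": len(bg)},
        )
        model.save(outdir / f"model_{mode}.json")
        models[mode] = model

    stage("scenarios")
    # the global model is the selected baseline model carried into projection
    selected = models["global"]
    epochs = (config.scenario.baseline_year,) + tuple(config.scenario.epochs)
    tables = {}
    for year in epochs:
        dt = temperature_increment(config.scenario, year)
        warmed = apply_scenario(stack, dt)
        suit = predict_logistic(selected, warmed)
        io.write_ascii_grid(suit, outdir / f"suitability_{year}.asc")
        tables[year] = band_areas(suit, regions)

    stage("assess")
    for year, tab in tables.items():
        tab.to_csv(outdir / f"band_areas_{year}.csv", index=False)
    cat_rows = []
    for year, tab in tables.items():
        ct = category_areas(tab)
        ct.insert(0, "epoch", year)
        cat_rows.append(ct)
    pd.concat(cat_rows).to_csv(outdir / "category_areas.csv", index=False)
    losses = loss_table(tables, config.scenario.baseline_year)
    losses.to_csv(outdir / "ms_loss.csv", index=False)
    comparison = {}
    for mode, model in models.items():
        suit = predict_logistic(model, stack)
        stats = overlap_stats(env_mask, suit)
        comparison[mode] = {
            "envelope_area_km2": stats.envelope_area_km2,
            "category_area_km2": stats.category_area_km2,
            "overlap_percent": stats.overlap_percent,
            "combined_overlap_percent": stats.combined_overlap_percent,
            "over_prediction_percent": stats.over_prediction_percent,
        }
    (outdir / "envelope_model_comparison.json").write_text(json.dumps(comparison, indent=2))

    stage("manifest")
    config_text = json.dumps(config.to_dict(), sort_keys=True)
    outputs = sorted(p for p in outdir.rglob("*") if p.is_file() and p.name != "manifest.json")
    manifest = {
        "config": config.to_dict(),
        "config_sha256": hashlib.sha256(config_text.encode()).hexdigest(),
        "seed": config.seed,
        "stage_seeds": {s: stage_seed(config.seed, s) for s in ("simulate", "validate", "background:global", "background:bias")},
        "envelope_area_km2": envelope_area_km2(env_mask),
        "outputs": {str(p.relative_to(outdir)): _sha256(p) for p in outputs},
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
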