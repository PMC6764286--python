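"""Configured, logged, reproducible end-to-end runs.

A run executes enabled stages in order — simulate (cohort + images) ->
image quantification (stacks / ihc / fish) -> stats — and writes CSV
tables plus a JSON manifest.  The manifest records the config hash, the
software version, the seed, and a checksum for every output, so an
identical config + seed reproduces byte-identical tables.  Per-stage log
lines report counts in/out at each filter so attrition is auditable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from . import __version__, fish, ihc, io, stacks, stats, synthetic

__all__ = ["RunConfig", "RunManifest", "run_pipeline"]

log = logging.getLogger("mgquant.pipeline")

_ALL_STAGES = ("simulate", "stacks", "ihc", "fish", "stats")


@dataclass
class RunConfig:
    """Declarative description of a pipeline run.

    ``stages`` selects which stages execute (order is fixed); the
    generator blocks configure the synthetic design; detection blocks
    override algorithm defaults.  Loadable from YAML/JSON with
    :meth:`from_file`; CLI flags override file values.
    """

    seed: int = 0
    outdir: str = "mgquant_run"
    stages: tuple[str, ...] = ("simulate", "stacks", "stats")
    control_group: str = "control"
    # synthetic design; None means the built-in default design
    design: dict[str, Any] | None = None
    stack_shape_xyz: tuple[int, int, int] = (256, 256, 40)
    detection: dict[str, Any] = field(default_factory=dict)
    ihc_slides: int = 2
    fish_targets: dict[str, float] = field(
        default_factory=lambda: {"Csf1": 2.08, "Il34": 0.03}
    )

    def __post_init__(self) -> None:
        bad = set(self.stages) - set(_ALL_STAGES)
        if bad:
            raise ValueError(f"unknown stages: {sorted(bad)}")
        self.stages = tuple(s for s in _ALL_STAGES if s in self.stages)

    @classmethod
    def from_file(cls, path: str | Path, **overrides: Any) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        if "stack_shape_xyz" in raw:
            raw["stack_shape_xyz"] = tuple(raw["stack_shape_xyz"])
        return cls(**raw)

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["stages"] = list(self.stages)
        d["stack_shape_xyz"] = list(self.stack_shape_xyz)
        return d

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


@dataclass
class RunManifest:
    """Self-describing record of one run."""

    config: dict[str, Any]
    config_hash: str
    version: str
    seed: int
    stages: dict[str, dict[str, Any]] = field(default_factory=dict)
    started: str = ""
    finished: str = ""
    complete: bool = False

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True))
        return path


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _design_from_config(config: RunConfig) -> synthetic.ExperimentDesign:
    template = dataclasses.replace(
        synthetic.StackSpec(), shape_xyz=config.stack_shape_xyz
    )
    if config.design is None:
        base = synthetic.default_design(seed=config.seed)
        return dataclasses.replace(base, stack_template=template)
    groups = tuple(
        synthetic.GroupSpec(g["name"], g["n_animals"], g.get("depletion", {}))
        for g in config.design["groups"]
    )
    regions = tuple(
        synthetic.RegionSpec(
            r["name"], r["baseline_density"], r.get("between_animal_cv", 0.10)
        )
        for r in config.design["regions"]
    )
    return synthetic.ExperimentDesign(
        groups=groups, regions=regions, seed=config.seed, stack_template=template
    )


def _stage_seed(base_seed: int, stage: str, index: int) -> int:
    """A stable per-item seed derived from the run seed (kept < 2^31)."""
    digest = hashlib.sha256(f"{base_seed}:{stage}:{index}".encode()).digest()
    return int.from_bytes(digest[:4], "little") % (2**31)


def run_pipeline(config: RunConfig) -> RunManifest:
    """Execute the enabled stages and return the saved manifest.

    A stage failure aborts the run with a stage-attributed error; the
    manifest on disk then marks the run incomplete.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        config=config.to_dict(),
        config_hash=config.config_hash(),
        version=__version__,
        seed=config.seed,
        started=time.strftime("%Y-%m-%dT%H:%M:%S"),
    )
    manifest.save(outdir / "manifest.json")

    design = _design_from_config(config)
    cohort = None
    stack_specs: dict = {}
    densities = None

    def record(stage: str, outputs: dict[str, Path], **info: Any) -> None:
        manifest.stages[stage] = {
            "outputs": {str(p): _sha256(p) for p in outputs.values()},
            **info,
        }
        manifest.save(outdir / "manifest.json")

    for stage in config.stages:
        log.info("stage %s: start", stage)
        try:
            if stage == "simulate":
                cohort, stack_specs = synthetic.generate_cohort(design)
                p = io.write_table(cohort, outdir / "cohort.csv")
                log.info(
                    "simulate: %d animals x %d regions -> %d rows",
                    cohort["animal_id"].nunique(),
                    cohort["region"].nunique(),
                    len(cohort),
                )
                record(stage, {"cohort": p}, n_rows=len(cohort))

            elif stage == "stacks":
                if cohort is None:
                    raise RuntimeError("stacks stage requires simulate")
                det = dict(config.detection)
                rows = []
                cell_rows = []
                for i, ((animal, region), spec) in enumerate(
                    sorted(stack_specs.items())
                ):
                    img, truth = synthetic.generate_stack(
                        spec, _stage_seed(config.seed, "stacks", i)
                    )
                    stk = stacks.ImageStack3D(img, spec.voxel_xy, spec.voxel_z)
                    pre = stacks.preprocess_stack(stk)
                    cells, _ = stacks.detect_cells_3d(pre, **det)
                    rec = stacks.compute_density(len(cells), stk, animal, region)
                    log.info(
                        "stacks: %s/%s truth=%d detected=%d",
                        animal, region, len(truth), len(cells),
                    )
                    rows.append(
                        {
                            "animal_id": animal,
                            "group": animal.rsplit("-", 1)[0],
                            "sex": cohort.loc[
                                cohort["animal_id"] == animal, "sex"
                            ].iloc[0],
                            "region": region,
                            "n_cells": rec.n_cells,
                            "volume_mm3": rec.volume_mm3,
                            "density": rec.density,
                            "n_true": len(truth),
                        }
                    )
                    for c in cells:
                        cell_rows.append(
                            {
                                "animal_id": animal,
                                "region": region,
                                "label": c.label,
                                "size_um3": c.size,
                                "touches_border": c.touches_border,
                            }
                        )
                import pandas as pd

                densities = pd.DataFrame(rows)
                p1 = io.write_table(densities, outdir / "densities.csv")
                p2 = io.write_table(pd.DataFrame(cell_rows), outdir / "cells.csv")
                record(stage, {"densities": p1, "cells": p2}, n_stacks=len(rows))

            elif stage == "ihc":
                import pandas as pd

                rows = []
                for i in range(config.ihc_slides):
                    spec = synthetic.SlideSpec()
                    rgb, truth = synthetic.generate_ihc_slide(
                        spec, _stage_seed(config.seed, "ihc", i)
                    )
                    slide = ihc.RgbSlide(rgb, spec.mpp)
                    tissue = ihc.segment_tissue(slide)
                    stain = ihc.segment_stain(slide, spec.stain_color)
                    res = ihc.count_positive_cells(stain, slide.grayscale(), tissue)
                    log.info(
                        "ihc: slide %d truth=%d counted=%d",
                        i, len(truth.centers_px), res.n_positive,
                    )
                    rows.append(
                        {
                            "slide": i,
                            "n_true": len(truth.centers_px),
                            "n_positive": res.n_positive,
                            "roi_area_mm2": res.roi_area_mm2,
                            "density_per_mm2": res.density_per_mm2,
                        }
                    )
                p = io.write_table(pd.DataFrame(rows), outdir / "ihc_counts.csv")
                record(stage, {"ihc_counts": p}, n_slides=len(rows))

            elif stage == "fish":
                import pandas as pd

                rows = []
                for i, (probe, target) in enumerate(
                    sorted(config.fish_targets.items())
                ):
                    spec = synthetic.FishSpec(target_percent_area=target)
                    sig, tissue, true_pct = synthetic.generate_fish_slide(
                        spec, _stage_seed(config.seed, "fish", i)
                    )
                    ch = fish.FishChannel(sig, probe, spec.mpp)
                    mask = fish.stain_mask_from_channel(ch)
                    roi = ihc.RoiRegion("section", np.ones(sig.shape, bool), spec.mpp)
                    puncta = fish.detect_puncta(ch)
                    res = fish.percent_area_stained(
                        mask, tissue, roi, probe, n_puncta=len(puncta)
                    )
                    log.info(
                        "fish: %s true=%.3f%% measured=%.3f%%",
                        probe, true_pct, res.percent_area,
                    )
                    rows.append(
                        {
                            "channel": probe,
                            "true_percent_area": true_pct,
                            "percent_area": res.percent_area,
                            "percent_of_roi": res.percent_of_roi,
                            "n_puncta": res.n_puncta,
                        }
                    )
                p = io.write_table(pd.DataFrame(rows), outdir / "fish_area.csv")
                record(stage, {"fish_area": p}, n_channels=len(rows))

            elif stage == "stats":
                source = densities if densities is not None else cohort
                if source is None:
                    raise RuntimeError("stats stage requires simulate or stacks")
                table = stats.analyze_cohort(
                    source, control=config.control_group, by_sex=True
                )
                p = io.write_table(table, outdir / "depletion.csv")
                log.info("stats: %d comparisons", len(table))
                record(stage, {"depletion": p}, n_comparisons=len(table))

        except Exception as exc:
            manifest.finished = time.strftime("%Y-%m-%dT%H:%M:%S")
            manifest.complete = False
            manifest.stages.setdefault(stage, {})["error"] = str(exc)
            manifest.save(outdir / "manifest.json")
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc

    manifest.finished = time.strftime("%Y-%m-%dT%H:%M:%S")
    manifest.complete = True
    manifest.save(outdir / "manifest.json")
    return manifest
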