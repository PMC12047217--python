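"""End-to-end pipeline: synthesize -> solve -> zone -> report.

One master seed fans out to named per-stage seeds, every stage logs to a
JSONL file, and a manifest records the configuration snapshot, seeds,
package version and a checksum inventory of every output file, so a run is
reproducible byte-for-byte from its manifest.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .marxan_io import write_marxan_inputs
from .objective import EV_SCENARIOS, ScenarioConfig
from .seascape import SeascapeSpec, build_seascape
from .solver import AnnealSchedule
from .zoning import ScenarioReport, scenario_report


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, original: Exception):
        self.stage = stage
        super().__init__(f"stage '{stage}' failed: {original}")


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed: hash of stage name and master seed."""
    digest = hashlib.sha256(f"{stage}:{master_seed}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass
class RunConfig:
    """Configuration of one full pipeline run."""

    master_seed: int = 1
    seascape_profile: str = "test"  # "test", "study" or "custom"
    seascape: SeascapeSpec | None = None
    scenarios: list[ScenarioConfig] = field(default_factory=list)
    # solver sizing; the defaults are the quick test profile
    n_runs: int = 50
    iterations_per_run: int = 10_000
    blm: float = 0.05
    spf: float = 100.0

    def build_seascape_spec(self) -> SeascapeSpec:
        seed = stage_seed(self.master_seed, "seascape")
        if self.seascape_profile == "custom":
            if self.seascape is None:
                raise ValueError("custom profile requires an explicit seascape")
            return dataclasses.replace(self.seascape, rng_seed=seed)
        if self.seascape_profile == "study":
            return SeascapeSpec.study_conditions(rng_seed=seed)
        if self.seascape_profile == "test":
            return SeascapeSpec.test_profile(rng_seed=seed)
        raise ValueError(f"unknown seascape profile '{self.seascape_profile}'")

    def build_scenarios(self) -> list[ScenarioConfig]:
        base = self.scenarios or EV_SCENARIOS(blm=self.blm, spf=self.spf)
        out = []
        for sc in base:
            out.append(
                sc.replace(
                    n_runs=self.n_runs,
                    iterations_per_run=self.iterations_per_run,
                    rng_seed=stage_seed(self.master_seed, f"solve:{sc.name}"),
                )
            )
        return out

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        scenarios = [
            ScenarioConfig(
                name=s.get("name", f"S{i + 1}"),
                target_fraction=s["target_fraction"],
                blm=s.get("blm", d.get("blm", 0.05)),
                spf=s.get("spf", d.get("spf", 100.0)),
            )
            for i, s in enumerate(d.get("scenarios", []))
        ]
        kwargs = {
            k: d[k]
            for k in ("master_seed", "seascape_profile", "n_runs",
                      "iterations_per_run", "blm", "spf")
            if k in d
        }
        return cls(scenarios=scenarios, **kwargs)


@dataclass
class RunManifest:
    """Reproducibility record for one pipeline run."""

    master_seed: int
    stage_seeds: dict[str, int]
    config: dict
    version: str
    files: dict[str, str]  # relative path -> sha256
    complete: bool = True
    failed_stage: str | None = None

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, sort_keys=True)

    @classmethod
    def load(cls, path: str | Path) -> "RunManifest":
        with open(path) as fh:
            return cls(**json.load(fh))

    def verify(self, out_dir: str | Path) -> list[str]:
        """Paths whose on-disk checksum no longer matches the manifest."""
        out = Path(out_dir)
        bad = []
        for rel, digest in self.files.items():
            p = out / rel
            if not p.exists() or _sha256(p) != digest:
                bad.append(rel)
        return bad


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_full(config: RunConfig, out_dir: str | Path) -> tuple[RunManifest, ScenarioReport]:
    """Execute synth -> solve -> zone -> report and write all artifacts.

    Outputs under ``out_dir``: Marxan dat files of the instance, per-scenario
    selection-frequency / zone / overlay CSVs, cross-scenario comparison
    CSVs, zoned-tessellation GeoJSONs, a JSONL log and ``manifest.json``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_path = out / "run_log.jsonl"
    log_fh = open(log_path, "w")

    def log(stage: str, **kw):
        rec = {"stage": stage, **kw}
        log_fh.write(json.dumps(rec, sort_keys=True) + "\n")
        log_fh.flush()

    stage_seeds = {"seascape": stage_seed(config.master_seed, "seascape")}
    t_start = time.time()
    try:
        log("seascape", status="start")
        try:
            spec = config.build_seascape_spec()
            tess, features = build_seascape(spec)
        except Exception as e:  # noqa: BLE001 - stage-named rethrow
            raise StageError("seascape", e) from e
        log("seascape", status="done", n_units=len(tess),
            total_area_ha=round(tess.total_area_ha, 4))

        scenarios = config.build_scenarios()
        for sc in scenarios:
            stage_seeds[f"solve:{sc.name}"] = sc.rng_seed

        try:
            write_marxan_inputs(tess, features, scenarios[0], out / "marxan_input")
        except Exception as e:
            raise StageError("marxan_export", e) from e

        log("solve", status="start", scenarios=[sc.name for sc in scenarios])
        try:
            report = scenario_report(tess, features, scenarios)
        except Exception as e:
            raise StageError("solve", e) from e
        for name, oc in report.outcomes.items():
            log("solve", status="done", scenario=name,
                n_selected=oc.best.n_selected,
                cost=oc.best.objective.cost_term,
                boundary=oc.best.objective.boundary_term,
                total=round(oc.best.objective.total, 6))

        log("report", status="start")
        try:
            report.to_csvs(out / "tables")
            for name, oc in report.outcomes.items():
                attrs = {
                    int(pu): {"zone": str(z), "score": float(s)}
                    for pu, z, s in zip(
                        oc.zoning.pu_ids, oc.zoning.labels, oc.frequency.score
                    )
                }
                tess.to_geojson(attributes=attrs,
                                path=str(out / f"zones_{name}.geojson"))
        except Exception as e:
            raise StageError("report", e) from e
        log("report", status="done", elapsed_s=round(time.time() - t_start, 2))
    except StageError as err:
        log(err.stage, status="failed", error=str(err))
        log_fh.close()
        manifest = _build_manifest(config, stage_seeds, out,
                                   complete=False, failed_stage=err.stage)
        manifest.save(out / "manifest.json")
        raise
    log_fh.close()

    manifest = _build_manifest(config, stage_seeds, out)
    manifest.save(out / "manifest.json")
    return manifest, report


def _build_manifest(
    config: RunConfig,
    stage_seeds: dict[str, int],
    out: Path,
    complete: bool = True,
    failed_stage: str | None = None,
) -> RunManifest:
    files = {}
    for p in sorted(out.rglob("*")):
        if p.is_file() and p.name not in ("manifest.json", "run_log.jsonl"):
            files[str(p.relative_to(out))] = _sha256(p)
    # JSON-normalize the snapshot (tuples -> lists) so a saved manifest
    # loads back equal to the in-memory one
    cfg = json.loads(json.dumps(dataclasses.asdict(config)))
    return RunManifest(
        master_seed=config.master_seed,
        stage_seeds=stage_seeds,
        config=cfg,
        version=__version__,
        files=files,
        complete=complete,
        failed_stage=failed_stage,
    )
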