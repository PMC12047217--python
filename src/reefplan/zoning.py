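"""Selection-frequency zoning and scenario comparison.

Selection frequencies (irreplaceability scores, 0–1000) are mapped to a
four-zone marine-protected-area scheme:

* Priority I, score in [750, 1000]  -> core conservation zone
* Priority II, score in [500, 750)  -> utilization (tourism) zone
* Priority III, score in [250, 500) -> sustainable fisheries zone
* Priority IV, score in (0, 250)    -> other uses
* score exactly 0                   -> nonpriority

The printed score ranges overlap at their endpoints; the half-open
convention above (closed at the top of the core band) is this package's
documented resolution. Zone-area tables fold the nonpriority class into
"other" by default, matching the four-row reporting style.

Scenario comparison statistics: the impact magnitude of a zone area
relative to a baseline scenario, ``100 * (value - reference) / reference``,
and conservation cost efficiency, ``SPU / CC`` (total selected planning
units over total conservation cost; higher is more cost-effective).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .objective import ScenarioConfig
from .seascape import FeatureTable
from .solver import AnnealSchedule, SelectionFrequency, Solution, run_repeats
from .tessellation import Tessellation

ZONES = ("core", "utilization", "sustainable_fisheries", "other", "nonpriority")

#: (lower, upper, closed_upper) score bands per zone, besides the exact-0 class
_BANDS = (
    ("core", 750.0, 1000.0, True),
    ("utilization", 500.0, 750.0, False),
    ("sustainable_fisheries", 250.0, 500.0, False),
    ("other", 0.0, 250.0, False),
)


@dataclass
class ZoningResult:
    """Per-planning-unit zone labels for one scenario."""

    pu_ids: np.ndarray
    labels: np.ndarray  # array of zone-name strings
    scenario: str = "custom"

    def zone_ids(self, zone: str) -> set[int]:
        return {int(i) for i in self.pu_ids[self.labels == zone]}

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({"pu_id": self.pu_ids, "zone": self.labels})


def classify_priorities(
    freq: SelectionFrequency, scenario_name: str = "custom"
) -> ZoningResult:
    """Map selection-frequency scores to the four-zone scheme.

    Scores must lie in [0, 1000]; exactly-zero units are nonpriority.
    """
    score = np.asarray(freq.score, dtype=float)
    if np.any((score < 0) | (score > 1000)):
        bad = score[(score < 0) | (score > 1000)][0]
        raise ValueError(f"selection score {bad} outside [0, 1000]")
    labels = np.full(score.shape, "nonpriority", dtype=object)
    for zone, lo, hi, closed in _BANDS:
        if closed:
            mask = (score >= lo) & (score <= hi)
        else:
            mask = (score >= lo) & (score < hi)
        if zone == "other":
            mask &= score > 0
        labels[mask] = zone
    return ZoningResult(
        pu_ids=np.asarray(freq.pu_ids), labels=labels, scenario=scenario_name
    )


def zone_area_table(
    zoning: ZoningResult,
    tess: Tessellation,
    merge_nonpriority: bool = True,
) -> pd.DataFrame:
    """Hectares and percentage of total area per zone.

    With ``merge_nonpriority`` (default) the nonpriority class is folded
    into "other", giving the four-row reporting layout; a Total row closes
    the table. Areas partition the tessellation exactly.
    """
    area_by_id = {u.id: u.area for u in tess.units}
    total = tess.total_area_ha
    labels = zoning.labels.copy()
    if merge_nonpriority:
        labels = np.where(labels == "nonpriority", "other", labels)
    rows = []
    zones = [z for z in ZONES if merge_nonpriority is False or z != "nonpriority"]
    for zone in zones:
        ha = float(
            sum(area_by_id[int(i)] for i in zoning.pu_ids[labels == zone])
        )
        rows.append({"zone": zone, "area_ha": ha, "pct_of_total": 100.0 * ha / total})
    rows.append(
        {
            "zone": "total",
            "area_ha": float(sum(r["area_ha"] for r in rows)),
            "pct_of_total": 100.0,
        }
    )
    return pd.DataFrame(rows)


def core_habitat_overlay(
    zoning: ZoningResult, features: FeatureTable
) -> pd.DataFrame:
    """Habitat amounts falling inside the core zone, per habitat and total.

    Columns: habitat, total area (ha), area inside the core zone (ha), and
    the percentage of that habitat protected, ``100 * in_core / total``.
    """
    core = zoning.zone_ids("core")
    rows = []
    for f in features.features:
        in_core = features.held(f.id, core)
        rows.append(
            {
                "habitat": f.name,
                "total_ha": f.total_amount,
                "core_ha": in_core,
                "pct_of_habitat": (
                    100.0 * in_core / f.total_amount if f.total_amount > 0 else 0.0
                ),
            }
        )
    total = sum(r["total_ha"] for r in rows)
    core_total = sum(r["core_ha"] for r in rows)
    rows.append(
        {
            "habitat": "total",
            "total_ha": total,
            "core_ha": core_total,
            "pct_of_habitat": 100.0 * core_total / total if total > 0 else 0.0,
        }
    )
    return pd.DataFrame(rows)


def impact_magnitude(value: float, reference: float) -> float:
    """Percent change of ``value`` relative to a baseline scenario's value."""
    if reference <= 0:
        raise ValueError(f"reference must be positive, got {reference}")
    return 100.0 * (value - reference) / reference


def conservation_efficiency(spu: float, cc: float) -> float:
    """Conservation cost efficiency: selected planning units per unit cost.

    Reported values are conventionally rounded to 4 decimals; this returns
    full precision.
    """
    if cc <= 0:
        raise ValueError(f"total conservation cost must be positive, got {cc}")
    if spu < 0:
        raise ValueError(f"selected planning units must be >= 0, got {spu}")
    return spu / cc


@dataclass
class EfficiencyRecord:
    """Per-scenario cost-effectiveness summary (one row of the comparison)."""

    scenario: str
    spu: int              # total selected planning units (best solution)
    cc: float             # total conservation cost (score units)
    boundary_length: float  # metres
    efficiency: float = field(init=False)

    def __post_init__(self):
        self.efficiency = conservation_efficiency(self.spu, self.cc) \
            if self.cc > 0 else 0.0

    @property
    def efficiency_rounded(self) -> float:
        return round(self.efficiency, 4)


@dataclass
class ScenarioOutcome:
    """Everything computed for one scenario."""

    scenario: ScenarioConfig
    frequency: SelectionFrequency
    best: Solution
    zoning: ZoningResult
    zone_table: pd.DataFrame
    overlay: pd.DataFrame
    efficiency: EfficiencyRecord


@dataclass
class ScenarioReport:
    """Cross-scenario comparison bundle."""

    outcomes: dict[str, ScenarioOutcome]
    zone_comparison: pd.DataFrame      # zones x per-scenario ha/% + impacts
    efficiency_comparison: pd.DataFrame  # SPU/CC/boundary/efficiency rows

    def to_csvs(self, out_dir) -> dict[str, str]:
        from pathlib import Path

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        written = {}
        for name, oc in self.outcomes.items():
            for tag, df in (
                ("selection_frequency", oc.frequency.to_dataframe()),
                ("zones", oc.zoning.to_dataframe()),
                ("zone_areas", oc.zone_table),
                ("core_overlay", oc.overlay),
            ):
                p = out / f"{name}_{tag}.csv"
                df.to_csv(p, index=False, float_format="%.6f")
                written[f"{name}_{tag}"] = str(p)
        for tag, df in (
            ("zone_comparison", self.zone_comparison),
            ("efficiency_comparison", self.efficiency_comparison),
        ):
            p = out / f"{tag}.csv"
            df.to_csv(p, index=False, float_format="%.6f")
            written[tag] = str(p)
        return written


def scenario_report(
    tess: Tessellation,
    features: FeatureTable,
    scenarios: list[ScenarioConfig],
    schedule: AnnealSchedule | None = None,
) -> ScenarioReport:
    """Run every scenario on one seascape and build comparison tables.

    Each scenario is solved with its own repeated annealing runs on the
    shared cost surface; selection frequencies are zoned, the core zone is
    overlaid with the habitat table, and the best solution provides the
    selected-unit count, conservation cost and boundary length feeding the
    efficiency comparison. Impact magnitudes are reported against the first
    scenario; with a single scenario the impact columns are omitted.
    """
    if not scenarios:
        raise ValueError("at least one scenario is required")
    outcomes: dict[str, ScenarioOutcome] = {}
    for sc in scenarios:
        freq, best, _ = run_repeats(tess, features, sc, schedule=schedule)
        zoning = classify_priorities(freq, scenario_name=sc.name)
        outcomes[sc.name] = ScenarioOutcome(
            scenario=sc,
            frequency=freq,
            best=best,
            zoning=zoning,
            zone_table=zone_area_table(zoning, tess),
            overlay=core_habitat_overlay(zoning, features),
            efficiency=EfficiencyRecord(
                scenario=sc.name,
                spu=best.n_selected,
                cc=best.objective.cost_term,
                boundary_length=best.objective.boundary_term,
            ),
        )

    names = [sc.name for sc in scenarios]
    ref = names[0]
    zone_rows = []
    ref_table = outcomes[ref].zone_table.set_index("zone")
    for zone in [z for z in ZONES if z != "nonpriority"] + ["total"]:
        row: dict = {"zone": zone}
        for name in names:
            t = outcomes[name].zone_table.set_index("zone")
            row[f"{name}_ha"] = float(t.loc[zone, "area_ha"])
            row[f"{name}_pct"] = float(t.loc[zone, "pct_of_total"])
        if len(names) > 1 and zone != "total":
            ref_ha = float(ref_table.loc[zone, "area_ha"])
            for name in names[1:]:
                row[f"{name}_impact_vs_{ref}"] = (
                    impact_magnitude(row[f"{name}_ha"], ref_ha)
                    if ref_ha > 0 else float("nan")
                )
        zone_rows.append(row)
    zone_comparison = pd.DataFrame(zone_rows)

    eff_rows = []
    for metric in ("spu", "conservation_cost", "boundary_length", "efficiency"):
        row = {"metric": metric}
        for name in names:
            e = outcomes[name].efficiency
            row[name] = {
                "spu": e.spu,
                "conservation_cost": e.cc,
                "boundary_length": e.boundary_length,
                "efficiency": e.efficiency_rounded,
            }[metric]
        eff_rows.append(row)
    efficiency_comparison = pd.DataFrame(eff_rows)

    return ScenarioReport(
        outcomes=outcomes,
        zone_comparison=zone_comparison,
        efficiency_comparison=efficiency_comparison,
    )
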