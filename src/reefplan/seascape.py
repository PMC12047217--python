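"""Synthetic seascape generation.

Builds planning instances with the structure of a small fringing-reef island
system: a rectangular marine planning region with an island landmass in the
centre, three clustered benthic habitats (coral reefs fringing the island,
seagrass meadows in the north, mangroves on the south-east shore) and
human-use cost features (residential and land-use areas that are locked out
of reserve solutions; docks and floating net cages that act as seed planning
units present in every starting solution).

The generator is fully seeded: the same :class:`SeascapeSpec` always yields
the same instance. Habitat patches are painted by thresholding spatially
smoothed noise inside per-habitat sectors, so realized areas hit their
targets exactly (the marginal planning unit holds a fractional amount) while
patches stay spatially autocorrelated and clustered.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import yaml
from scipy.ndimage import gaussian_filter

from .tessellation import (
    M2_PER_HA,
    PUStatus,
    Tessellation,
    build_hex_tessellation,
)


class InfeasibleSeascapeError(ValueError):
    """Habitat targets exceed the area available to them."""


class PlacementConflictError(ValueError):
    """A planning unit falls under both a lockout and a seed footprint."""

    def __init__(self, pu_ids: list[int]):
        self.pu_ids = pu_ids
        super().__init__(
            f"planning units covered by both lockout and seed footprints: {pu_ids}"
        )


@dataclass(frozen=True)
class Feature:
    """One conservation feature (a habitat class)."""

    id: int
    name: str
    total_amount: float  # hectares
    spf: float = 10.0


@dataclass
class FeatureTable:
    """Per-planning-unit amounts (hectares) of each conservation feature."""

    features: list[Feature]
    #: feature_id -> {pu_id -> amount (ha)}
    amounts: dict[int, dict[int, float]] = field(default_factory=dict)

    def feature(self, fid: int) -> Feature:
        for f in self.features:
            if f.id == fid:
                return f
        raise KeyError(f"unknown feature id {fid}")

    def amount(self, fid: int, pu_id: int) -> float:
        return self.amounts.get(fid, {}).get(pu_id, 0.0)

    def held(self, fid: int, selected) -> float:
        """Total amount of a feature inside a set of planning units."""
        amts = self.amounts.get(fid, {})
        return float(sum(amts.get(pu, 0.0) for pu in selected))

    def dense_amounts(self, n_units: int) -> np.ndarray:
        """Amounts as a dense (n_features, n_units) array, feature-list order."""
        out = np.zeros((len(self.features), n_units))
        for k, f in enumerate(self.features):
            for pu, a in self.amounts.get(f.id, {}).items():
                out[k, pu - 1] = a
        return out


@dataclass(frozen=True)
class Placement:
    """A circular cost-feature footprint.

    ``kind`` is one of ``residential``, ``land_use``, ``dock``,
    ``floating_net_cage``; centre in metres, radius in metres.
    """

    kind: str
    center: tuple[float, float]
    radius: float


#: Table of cost-feature scores and statuses: kind -> (PU score, PU status).
COST_FEATURES: dict[str, tuple[float, PUStatus]] = {
    "residential": (3.0, PUStatus.LOCKOUT),
    "land_use": (3.0, PUStatus.LOCKOUT),
    "dock": (1.0, PUStatus.SEED),
    "floating_net_cage": (1.0, PUStatus.SEED),
}


@dataclass
class SectorSpec:
    """Where a habitat may occur, in island-relative coordinates.

    ``rho`` is the normalized elliptical distance from the island centre
    (1.0 on the island shoreline); ``theta`` the bearing in degrees,
    measured counter-clockwise from east. ``None`` bounds are open.
    """

    rho_min: float = 1.0
    rho_max: float | None = None
    theta_min: float | None = None  # degrees in [-180, 180]
    theta_max: float | None = None
    north_of_centre: bool = False


@dataclass
class SeascapeSpec:
    """Full description of a synthetic planning instance.

    Defaults reproduce the study conditions: a 544.03 ha region of 15 m
    hexagons around a ~60 ha island, with 23.55 ha coral reef, 29.42 ha
    seagrass and 11.81 ha mangrove.
    """

    extent: tuple[float, float] = (2332.446, 2332.446)  # metres; 544.03 ha
    side: float = 15.0
    island_semi_axes: tuple[float, float] = (500.0, 380.0)
    #: habitat name -> target area (ha)
    habitat_targets: dict[str, float] = field(
        default_factory=lambda: {"coral": 23.55, "seagrass": 29.42, "mangrove": 11.81}
    )
    #: habitat name -> sector restriction
    sectors: dict[str, SectorSpec] = field(
        default_factory=lambda: {
            "coral": SectorSpec(rho_min=1.0, rho_max=1.45),
            "seagrass": SectorSpec(rho_min=1.0, north_of_centre=True),
            "mangrove": SectorSpec(
                rho_min=1.0, rho_max=1.6, theta_min=-120.0, theta_max=30.0
            ),
        }
    )
    #: spatial autocorrelation length of habitat patches, metres
    cluster_length_scale: float = 80.0
    placements: list[Placement] = field(default_factory=list)
    rng_seed: int = 20210615

    def __post_init__(self):
        if not self.placements:
            self.placements = self._default_placements()

    # island centre is the extent centre
    @property
    def island_center(self) -> tuple[float, float]:
        return (self.extent[0] / 2.0, self.extent[1] / 2.0)

    def _default_placements(self) -> list[Placement]:
        cx, cy = self.extent[0] / 2.0, self.extent[1] / 2.0
        a, b = self.island_semi_axes
        # residential on the north-west shore (on land); dock just offshore
        # of it; two floating net cages in open water north-east.
        ang = math.radians(155.0)
        return [
            Placement(
                "residential",
                (cx + 0.80 * a * math.cos(ang), cy + 0.80 * b * math.sin(ang)),
                0.14 * a,
            ),
            Placement(
                "dock",
                (cx + 1.18 * a * math.cos(ang), cy + 1.18 * b * math.sin(ang)),
                0.05 * a,
            ),
            Placement(
                "floating_net_cage",
                (cx + 1.60 * a * math.cos(math.radians(50.0)),
                 cy + 1.60 * b * math.sin(math.radians(50.0))),
                0.05 * a,
            ),
            Placement(
                "floating_net_cage",
                (cx + 1.85 * a * math.cos(math.radians(75.0)),
                 cy + 1.85 * b * math.sin(math.radians(75.0))),
                0.05 * a,
            ),
        ]

    @classmethod
    def study_conditions(cls, **overrides) -> "SeascapeSpec":
        """The default, full-size instance (~9,300 planning units)."""
        return cls(**overrides)

    @classmethod
    def test_profile(cls, rng_seed: int = 20210615) -> "SeascapeSpec":
        """A geometrically similar instance scaled to ~1,500 planning units.

        Linear dimensions shrink by sqrt(scale) and areal quantities
        (habitat targets) by scale, so habitat composition and the relative
        island footprint are preserved.
        """
        return cls.scaled(1500.0 / 9306.0, rng_seed=rng_seed)

    @classmethod
    def scaled(cls, area_scale: float, rng_seed: int = 20210615) -> "SeascapeSpec":
        """Scale the default instance's areas by ``area_scale``."""
        ref = cls()
        lin = math.sqrt(area_scale)
        return cls(
            extent=(ref.extent[0] * lin, ref.extent[1] * lin),
            side=ref.side,
            island_semi_axes=(
                ref.island_semi_axes[0] * lin,
                ref.island_semi_axes[1] * lin,
            ),
            habitat_targets={
                k: v * area_scale for k, v in ref.habitat_targets.items()
            },
            cluster_length_scale=max(ref.cluster_length_scale * lin, 2 * ref.side),
            placements=[],  # rebuilt from scaled island geometry
            rng_seed=rng_seed,
        )

    # -- geometry helpers ---------------------------------------------------

    def rho_theta(self, xy: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Normalized elliptical distance and bearing (deg) of points."""
        cx, cy = self.island_center
        a, b = self.island_semi_axes
        dx = (xy[:, 0] - cx) / a
        dy = (xy[:, 1] - cy) / b
        rho = np.hypot(dx, dy)
        theta = np.degrees(np.arctan2(xy[:, 1] - cy, xy[:, 0] - cx))
        return rho, theta

    def marine_area_ha(self) -> float:
        """Approximate water area of the extent (total minus island ellipse)."""
        a, b = self.island_semi_axes
        return (self.extent[0] * self.extent[1] - math.pi * a * b) / M2_PER_HA

    def validate(self) -> None:
        total_target = sum(self.habitat_targets.values())
        marine = self.marine_area_ha()
        if total_target > marine:
            raise InfeasibleSeascapeError(
                f"habitat targets sum to {total_target:.2f} ha but only "
                f"{marine:.2f} ha of marine area is available"
            )

    # -- serialization ------------------------------------------------------

    def to_yaml(self, path: str) -> None:
        d = asdict(self)
        d["sectors"] = {k: asdict(v) for k, v in self.sectors.items()}
        d["placements"] = [asdict(p) for p in self.placements]
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str) -> "SeascapeSpec":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        d["extent"] = tuple(d["extent"])
        d["island_semi_axes"] = tuple(d["island_semi_axes"])
        d["sectors"] = {k: SectorSpec(**v) for k, v in d.get("sectors", {}).items()}
        d["placements"] = [
            Placement(p["kind"], tuple(p["center"]), p["radius"])
            for p in d.get("placements", [])
        ]
        return cls(**d)


# feature ids follow the reporting order: coral, seagrass, mangrove
FEATURE_ORDER = ("coral", "seagrass", "mangrove")
#: habitats painted first claim planning units (map classes are exclusive)
PAINT_PRIORITY = ("mangrove", "coral", "seagrass")


def _smooth_noise_at(
    centroids: np.ndarray,
    extent: tuple[float, float],
    length_scale: float,
    cell: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Gaussian-smoothed uniform noise sampled at planning-unit centroids."""
    nx = max(int(math.ceil(extent[0] / cell)), 4)
    ny = max(int(math.ceil(extent[1] / cell)), 4)
    grid = rng.random((ny, nx))
    smooth = gaussian_filter(grid, sigma=length_scale / cell, mode="reflect")
    ix = np.clip((centroids[:, 0] / cell).astype(int), 0, nx - 1)
    iy = np.clip((centroids[:, 1] / cell).astype(int), 0, ny - 1)
    return smooth[iy, ix]


def generate_habitats(tess: Tessellation, spec: SeascapeSpec) -> FeatureTable:
    """Paint spatially clustered habitat patches onto the tessellation.

    Each habitat is restricted to its sector, ranked by smoothed noise and
    filled greedily until its target area is met; the marginal planning unit
    receives a fractional amount so the realized total equals the target
    exactly. Habitats are exclusive within a planning unit; overlaps are
    resolved in the order mangrove > coral > seagrass.

    Raises
    ------
    InfeasibleSeascapeError
        If a habitat's sector cannot hold its target area.
    """
    spec.validate()
    rng = np.random.default_rng(spec.rng_seed)
    xy = tess.centroids
    rho, theta = spec.rho_theta(xy)
    cy = spec.island_center[1]
    pu_area = tess.pu_area_ha

    taken = np.zeros(len(tess), dtype=bool)  # claimed by a previous habitat
    features: list[Feature] = []
    amounts: dict[int, dict[int, float]] = {}
    realized: dict[str, tuple[int, dict[int, float]]] = {}

    # noise fields are drawn in a fixed order for determinism
    noise_fields = {
        name: _smooth_noise_at(
            xy, spec.extent, spec.cluster_length_scale, spec.side, rng
        )
        for name in PAINT_PRIORITY
    }

    for name in PAINT_PRIORITY:
        target = spec.habitat_targets.get(name, 0.0)
        sector = spec.sectors.get(name, SectorSpec())
        mask = (rho > sector.rho_min) & ~taken
        if sector.rho_max is not None:
            mask &= rho <= sector.rho_max
        if sector.theta_min is not None:
            mask &= theta >= sector.theta_min
        if sector.theta_max is not None:
            mask &= theta <= sector.theta_max
        if sector.north_of_centre:
            mask &= xy[:, 1] > cy

        per_pu: dict[int, float] = {}
        if target > 0:
            capacity = mask.sum() * pu_area
            if capacity < target:
                raise InfeasibleSeascapeError(
                    f"habitat '{name}' target {target:.2f} ha exceeds its "
                    f"sector capacity {capacity:.2f} ha"
                )
            cand = np.flatnonzero(mask)
            order = cand[np.argsort(-noise_fields[name][cand], kind="stable")]
            n_full = int(target // pu_area)
            remainder = target - n_full * pu_area
            for idx in order[:n_full]:
                per_pu[int(idx) + 1] = pu_area
                taken[idx] = True
            if remainder > 1e-12:
                idx = order[n_full]
                per_pu[int(idx) + 1] = remainder
                taken[idx] = True
        realized[name] = (0, per_pu)

    for k, name in enumerate(FEATURE_ORDER, start=1):
        per_pu = realized[name][1]
        features.append(
            Feature(id=k, name=name, total_amount=float(sum(per_pu.values())))
        )
        amounts[k] = per_pu
    return FeatureTable(features=features, amounts=amounts)


def assign_costs_status(tess: Tessellation, spec: SeascapeSpec) -> Tessellation:
    """Assign Table-of-cost-features scores and statuses in place.

    Land planning units (inside the island ellipse) and residential
    footprints score 3 and are locked out; dock and floating-net-cage
    footprints score 1 and are seeds; everything else scores 0 and stays
    available.

    Raises
    ------
    PlacementConflictError
        If any planning unit falls under both a lockout and a seed footprint.
    """
    xy = tess.centroids
    rho, _ = spec.rho_theta(xy)

    lockout = rho <= 1.0  # island landmass = land use
    cost = np.where(lockout, 3.0, 0.0)
    seed = np.zeros(len(tess), dtype=bool)

    for p in spec.placements:
        if p.kind not in COST_FEATURES:
            raise ValueError(f"unknown cost-feature kind '{p.kind}'")
        score, status = COST_FEATURES[p.kind]
        d = np.hypot(xy[:, 0] - p.center[0], xy[:, 1] - p.center[1])
        hit = d <= p.radius
        if not hit.any():
            # a footprint smaller than the lattice pitch still claims the
            # nearest planning unit
            hit[int(np.argmin(d))] = True
        if status is PUStatus.LOCKOUT:
            lockout |= hit
            cost[hit] = score
        else:
            seed |= hit
            cost[hit & ~lockout] = score

    conflict = lockout & seed
    if conflict.any():
        raise PlacementConflictError([int(i) + 1 for i in np.flatnonzero(conflict)])

    for i, u in enumerate(tess.units):
        u.cost = float(cost[i])
        u.status = (
            PUStatus.LOCKOUT if lockout[i]
            else PUStatus.SEED if seed[i]
            else PUStatus.AVAILABLE
        )
    return tess


def build_seascape(spec: SeascapeSpec) -> tuple[Tessellation, FeatureTable]:
    """Build the full synthetic planning instance from a spec.

    Returns the cost/status-annotated tessellation and the habitat table.
    """
    tess = build_hex_tessellation(spec.extent, spec.side)
    assign_costs_status(tess, spec)
    features = generate_habitats(tess, spec)
    return tess, features
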