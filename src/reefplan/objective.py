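"""The reserve-selection objective.

A candidate reserve system (a set of selected planning units) is scored by

    total = sum(Cost) + BLM * sum(Boundary) + sum(SPF * Penalty)

where Cost is the socioeconomic score of each selected planning unit,
Boundary the exposed edge length of the selected system (metres), BLM the
boundary length modifier that trades compactness against cost, and Penalty
a per-feature shortfall term weighted by that feature's species penalty
factor (SPF). The penalty used here is the normalized shortfall
``(target - held) / target``, clipped to [0, 1], which makes the SPF
directly interpretable: a feature missing its target entirely contributes
exactly its SPF to the total.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

from .seascape import FeatureTable
from .tessellation import Tessellation, boundary_length

__all__ = [
    "ScenarioConfig",
    "ObjectiveValue",
    "shortfall_penalty",
    "objective",
    "EV_SCENARIOS",
]


@dataclass
class ScenarioConfig:
    """Parameters of one conservation scenario.

    ``target_fraction`` and ``spf`` may be scalars (applied to every
    feature) or mappings from feature id to value. The three ecological-value
    scenarios of the study protect 30%, 40% and 50% of every feature's total
    amount (EV1, EV2, EV3).
    """

    name: str = "custom"
    target_fraction: float | Mapping[int, float] = 0.30
    blm: float = 0.0
    spf: float | Mapping[int, float] = 10.0
    n_runs: int = 1000
    iterations_per_run: int = 1_000_000
    rng_seed: int = 0
    #: when True (default) seed PUs stay in every solution; when False they
    #: are ordinary flippable units that merely start selected
    seeds_locked: bool = True
    #: absolute targets (feature id -> amount); when set they take precedence
    #: over target_fraction (used by instances loaded from dat files, whose
    #: spec.dat targets are absolute)
    absolute_targets: Mapping[int, float] | None = None

    def __post_init__(self):
        fracs = (
            self.target_fraction.values()
            if isinstance(self.target_fraction, Mapping)
            else [self.target_fraction]
        )
        for f in fracs:
            if not 0 < f <= 1:
                raise ValueError(f"target_fraction must be in (0, 1], got {f}")
        if self.n_runs < 1:
            raise ValueError(f"n_runs must be >= 1, got {self.n_runs}")
        if self.blm < 0:
            raise ValueError(f"BLM must be non-negative, got {self.blm}")

    def target_fraction_for(self, feature_id: int) -> float:
        if isinstance(self.target_fraction, Mapping):
            return float(self.target_fraction[feature_id])
        return float(self.target_fraction)

    def spf_for(self, feature_id: int) -> float:
        if isinstance(self.spf, Mapping):
            return float(self.spf[feature_id])
        return float(self.spf)

    def target_for(self, feature) -> float:
        """Absolute target (ha) for one feature."""
        if self.absolute_targets is not None and feature.id in self.absolute_targets:
            return float(self.absolute_targets[feature.id])
        return self.target_fraction_for(feature.id) * feature.total_amount

    def targets(self, features: FeatureTable) -> dict[int, float]:
        """Absolute targets (ha) per feature id."""
        return {f.id: self.target_for(f) for f in features.features}

    def replace(self, **changes) -> "ScenarioConfig":
        from dataclasses import replace as _replace

        return _replace(self, **changes)


def EV_SCENARIOS(
    blm: float = 0.0,
    spf: float = 10.0,
    n_runs: int = 1000,
    iterations_per_run: int = 1_000_000,
    rng_seed: int = 0,
) -> list[ScenarioConfig]:
    """The study's three ecological-value scenarios: 30%, 40%, 50% targets."""
    return [
        ScenarioConfig(
            name=name,
            target_fraction=frac,
            blm=blm,
            spf=spf,
            n_runs=n_runs,
            iterations_per_run=iterations_per_run,
            rng_seed=rng_seed,
        )
        for name, frac in (("EV1", 0.30), ("EV2", 0.40), ("EV3", 0.50))
    ]


@dataclass(frozen=True)
class ObjectiveValue:
    """Decomposition of the total objective for one reserve system."""

    cost_term: float
    boundary_term: float  # metres of exposed edge
    penalty_term: float
    blm: float

    @property
    def total(self) -> float:
        return self.cost_term + self.blm * self.boundary_term + self.penalty_term


def shortfall_penalty(held: float, target: float) -> float:
    """Normalized shortfall of a feature against its target, in [0, 1].

    Zero when the target is met (or is zero); otherwise the unmet fraction
    ``(target - held) / target``.
    """
    if held < 0:
        raise ValueError(f"held amount must be non-negative, got {held}")
    if target < 0:
        raise ValueError(f"target must be non-negative, got {target}")
    if target == 0 or held >= target:
        return 0.0
    return (target - held) / target


def objective(
    selected: Iterable[int],
    tess: Tessellation,
    features: FeatureTable,
    scenario: ScenarioConfig,
) -> ObjectiveValue:
    """Score a reserve system under a scenario's BLM, SPF and targets."""
    sel = set(selected)
    cost_term = float(sum(tess.unit(pu).cost for pu in sel))
    boundary_term = boundary_length(sel, tess)
    penalty_term = 0.0
    for f in features.features:
        target = scenario.target_for(f)
        held = features.held(f.id, sel)
        penalty_term += scenario.spf_for(f.id) * shortfall_penalty(held, target)
    return ObjectiveValue(
        cost_term=cost_term,
        boundary_term=boundary_term,
        penalty_term=penalty_term,
        blm=scenario.blm,
    )
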