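"""Synthetic caching-count generator and model-recovery experiments.

The generator draws per-bird multinomial counts in the semantically
sorted frame under a chosen rate regime, then maps them back through a
counterbalanced sequence code so the output is a valid raw-frame
observation table.  Supported regimes:

``uniform``
    Every category has rate ``1/K`` — the compartment- and
    food-independent model that best explained the real data.
``bird_food_preference``
    Two-food only: each bird draws its own food-preference split from a
    symmetric Dirichlet, compartments uniform — the structure of the
    winning two-food model.
``FPH1`` / ``FPH2`` / ``CCH``
    Rates drawn from a symmetric Dirichlet truncated to the hypothesis's
    constraint region (group-appropriate in the food-absence layout).

Effect strength is controlled by the Dirichlet concentration ``kappa``:
draws concentrate toward the simplex centre as ``kappa`` grows, so large
``kappa`` means weak ordering effects.  The hypotheses predict only
qualitative orderings, so parameterising by ``kappa`` rather than fixed
rate vectors spans the plausible effect sizes.

Per-bird totals default to resampling the empirical totals of the
packaged tables (range 0-30, including a zero-total bird), which keeps
null-scenario recovery in the sensitivity regime of the original design.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .data import (
    CATEGORIES_TWO_FOOD,
    FOOD_ABSENCE,
    GROUPS,
    K_SLOTS,
    F_SLOTS,
    TWO_FOOD,
    BirdRecord,
    ObservationTable,
    ValidationError,
    parse_sequence_code,
)
from .inference import model_posterior
from .models import ConstraintSet, build_constraints, enumerate_models

__all__ = [
    "SCENARIOS",
    "SyntheticScenario",
    "scenario_from_dict",
    "scenario_from_file",
    "sample_constrained_rates",
    "simulate_observations",
    "model_recovery_experiment",
    "RecoverySummary",
]

SCENARIOS = ("uniform", "bird_food_preference", "FPH1", "FPH2", "CCH")

_ROTATIONS = ("ABC", "BCA", "CAB")
_FOOD_ORDERS = ("MP", "PM")

#: Default per-bird totals are resampled from these empirical totals.
_EMPIRICAL_TOTALS = {
    TWO_FOOD: (16, 1, 28, 7, 10, 0),
    FOOD_ABSENCE: (7, 2, 22, 16, 8, 25),
}

_REJECTION_CAP = 200_000


@dataclass(frozen=True)
class SyntheticScenario:
    """Configuration of one synthetic study.

    ``totals`` may be an explicit per-bird list, a single int applied to
    every bird, or ``"empirical"`` (resample the packaged tables'
    totals).  ``group_assignment`` (food-absence only) maps bird index to
    ``FF``/``EF``; by default birds alternate FF, EF, FF, ...
    """

    experiment: str
    scenario: str
    n_birds: int = 6
    totals: Sequence[int] | int | str = "empirical"
    concentration: float = 1.0
    group_assignment: tuple[str, ...] | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise ValidationError(
                f"unknown scenario {self.scenario!r}; choose from {SCENARIOS}"
            )
        if self.experiment not in (TWO_FOOD, FOOD_ABSENCE):
            raise ValidationError(f"unknown experiment {self.experiment!r}")
        if self.scenario == "bird_food_preference" and self.experiment != TWO_FOOD:
            raise ValidationError(
                "bird_food_preference applies only to the two_food experiment"
            )
        if self.n_birds < 1:
            raise ValidationError("n_birds must be >= 1")
        if not self.concentration > 0:
            raise ValidationError("concentration must be positive")
        if isinstance(self.totals, Sequence) and not isinstance(self.totals, str):
            object.__setattr__(self, "totals", tuple(int(t) for t in self.totals))
            if len(self.totals) != self.n_birds:
                raise ValidationError(
                    f"{len(self.totals)} totals for {self.n_birds} birds"
                )
            if any(t < 0 for t in self.totals):
                raise ValidationError("totals must be non-negative")
        if self.experiment == FOOD_ABSENCE:
            groups = self.group_assignment
            if groups is not None:
                groups = tuple(groups)
                if len(groups) != self.n_birds or any(g not in GROUPS for g in groups):
                    raise ValidationError(
                        f"group_assignment must give one of {GROUPS} per bird"
                    )
                object.__setattr__(self, "group_assignment", groups)
        elif self.group_assignment is not None:
            raise ValidationError("group_assignment applies only to food_absence")

    @property
    def n_categories(self) -> int:
        return 6 if self.experiment == TWO_FOOD else 3

    def resolved_groups(self) -> tuple[str, ...] | None:
        if self.experiment != FOOD_ABSENCE:
            return None
        if self.group_assignment is not None:
            return self.group_assignment
        if self.scenario in ("FPH1", "FPH2", "CCH"):
            raise ValidationError(
                f"scenario {self.scenario!r} on food_absence data requires "
                "an explicit group_assignment"
            )
        return tuple(GROUPS[i % 2] for i in range(self.n_birds))

    def resolved_totals(self, rng: np.random.Generator) -> tuple[int, ...]:
        if isinstance(self.totals, tuple):
            return self.totals
        if isinstance(self.totals, int):
            return (self.totals,) * self.n_birds
        if self.totals == "empirical":
            pool = _EMPIRICAL_TOTALS[self.experiment]
            return tuple(int(t) for t in rng.choice(pool, size=self.n_birds))
        raise ValidationError(f"unsupported totals spec {self.totals!r}")


def scenario_from_dict(doc: Mapping) -> SyntheticScenario:
    """Build a scenario from a YAML/JSON-style mapping."""
    allowed = {
        "experiment",
        "scenario",
        "n_birds",
        "totals",
        "concentration",
        "group_assignment",
        "seed",
    }
    unknown = set(doc) - allowed
    if unknown:
        raise ValidationError(f"unknown scenario fields: {sorted(unknown)}")
    kwargs = dict(doc)
    if "group_assignment" in kwargs and kwargs["group_assignment"] is not None:
        kwargs["group_assignment"] = tuple(kwargs["group_assignment"])
    return SyntheticScenario(**kwargs)


def scenario_from_file(path) -> SyntheticScenario:
    import yaml

    with open(path, encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, Mapping):
        raise ValidationError(f"scenario document must be a mapping, got {type(doc)}")
    return scenario_from_dict(doc)


def sample_constrained_rates(
    constraint: ConstraintSet,
    n_categories: int,
    concentration: float = 1.0,
    seed=None,
) -> np.ndarray:
    """One draw from a symmetric Dirichlet truncated to a constraint region.

    Rejection sampling: draw from Dirichlet(``concentration``) until the
    inequalities hold.  The expected number of tries is the reciprocal of
    the region's prior mass under that Dirichlet.
    """
    if n_categories != constraint.n_categories:
        raise ValidationError(
            f"n_categories {n_categories} != constraint's {constraint.n_categories}"
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    alpha = np.full(n_categories, float(concentration))
    batch = 64
    tried = 0
    while tried < _REJECTION_CAP:
        draws = rng.dirichlet(alpha, size=batch)
        ok = constraint.satisfied(draws)
        if ok.any():
            return draws[np.argmax(ok)]
        tried += batch
    raise ValidationError(
        f"rejection sampling failed after {_REJECTION_CAP} tries; the "
        "constraint region is too small — reduce the concentration or "
        "loosen the constraints"
    )


def _sequence_code(scenario: SyntheticScenario, i: int, group: str | None) -> str:
    rotation = _ROTATIONS[i % 3]
    if scenario.experiment == TWO_FOOD:
        return f"{rotation}-{_FOOD_ORDERS[(i // 3) % 2]}"
    return f"{rotation}-{group}"


def _bird_rates(
    scenario: SyntheticScenario, group: str | None, rng: np.random.Generator
) -> np.ndarray:
    K = scenario.n_categories
    kappa = scenario.concentration
    if scenario.scenario == "uniform":
        return np.full(K, 1.0 / K)
    if scenario.scenario == "bird_food_preference":
        food_split = rng.dirichlet(np.full(2, kappa))
        return np.array(
            [food_split[F_SLOTS.index(f)] / 3.0 for _, f in CATEGORIES_TWO_FOOD]
        )
    constraint = build_constraints(scenario.scenario, scenario.experiment, group)
    return sample_constrained_rates(constraint, K, kappa, rng)


def _raw_from_sorted(
    sorted_vec: np.ndarray, code: str, experiment: str
) -> dict:
    """Invert the semantic sort: place sorted counts into physical cells."""
    assignment = parse_sequence_code(code, experiment)
    if experiment == TWO_FOOD:
        return {
            (assignment.compartment_of[k], assignment.food_of[f]): int(v)
            for (k, f), v in zip(CATEGORIES_TWO_FOOD, sorted_vec)
        }
    return {
        assignment.compartment_of[k]: int(v) for k, v in zip(K_SLOTS, sorted_vec)
    }


def simulate_observations(
    scenario: SyntheticScenario,
) -> tuple[ObservationTable, dict]:
    """Generate one synthetic observation table plus its ground truth.

    Returns ``(table, truth)`` where ``truth`` holds the scenario label
    and each bird's generating rate vector in the sorted-frame category
    order — everything needed to score model recovery.
    """
    rng = np.random.default_rng(scenario.seed)
    groups = scenario.resolved_groups()
    totals = scenario.resolved_totals(rng)
    birds = []
    rates = {}
    for i in range(scenario.n_birds):
        group = groups[i] if groups else None
        bird_id = f"sim{i:03d}"
        code = _sequence_code(scenario, i, group)
        r = _bird_rates(scenario, group, rng)
        counts = rng.multinomial(totals[i], r)
        raw = _raw_from_sorted(counts, code, scenario.experiment)
        birds.append(BirdRecord(bird_id, code, scenario.experiment, raw))
        rates[bird_id] = [float(x) for x in r]
    table = ObservationTable(scenario.experiment, tuple(birds))
    truth = {
        "experiment": scenario.experiment,
        "scenario": scenario.scenario,
        "concentration": scenario.concentration,
        "totals": list(totals),
        "groups": list(groups) if groups else None,
        "rates": rates,
    }
    return table, truth


def _generating_target(scenario: SyntheticScenario) -> str:
    """Model id / hypothesis label that should win under each regime."""
    if scenario.scenario == "uniform":
        return "indep"
    if scenario.scenario == "bird_food_preference":
        return "food+bird"
    return scenario.scenario


@dataclass(frozen=True)
class RecoverySummary:
    """Fractions of replicates recovering the generating structure."""

    scenario: SyntheticScenario
    n_replicates: int
    target: str
    top_fraction: float
    top_se: float
    threshold: float
    above_threshold_fraction: float
    above_threshold_se: float
    replicates: tuple[dict, ...] = field(repr=False)

    def to_dict(self) -> dict:
        return {
            "scenario": self.scenario.scenario,
            "experiment": self.scenario.experiment,
            "n_replicates": self.n_replicates,
            "target": self.target,
            "top_fraction": self.top_fraction,
            "top_se": self.top_se,
            "threshold": self.threshold,
            "above_threshold_fraction": self.above_threshold_fraction,
            "above_threshold_se": self.above_threshold_se,
            "replicates": list(self.replicates),
        }


def model_recovery_experiment(
    scenario: SyntheticScenario,
    n_replicates: int,
    n_samples: int = 50_000,
    seed: int | None = None,
    threshold: float = 0.5,
) -> RecoverySummary:
    """Simulate-and-refit replicates; score how often the truth wins.

    Models sharing a hypothesis label form one family scored by its best
    variant; each unconstrained model is its own family.  A replicate
    counts as recovered when the generating family attains the highest
    family posterior; the secondary criterion asks that its posterior
    also exceed ``threshold``.
    """
    if n_replicates < 1:
        raise ValidationError("n_replicates must be >= 1")
    target = _generating_target(scenario)
    models = enumerate_models(scenario.experiment)
    root = np.random.SeedSequence(seed)
    records = []
    for rep, ss in enumerate(root.spawn(n_replicates)):
        sim_seed, fit_seed = (
            int(s.generate_state(1, dtype=np.uint64)[0] % (2**31)) for s in ss.spawn(2)
        )
        rep_scenario = SyntheticScenario(
            scenario.experiment,
            scenario.scenario,
            scenario.n_birds,
            scenario.totals,
            scenario.concentration,
            scenario.group_assignment,
            seed=sim_seed,
        )
        table, _ = simulate_observations(rep_scenario)
        post = model_posterior(table, models, n_samples, fit_seed)
        families: dict[str, float] = {}
        for m, _, p in post.entries:
            key = m.hypothesis if m.hypothesis else m.model_id
            families[key] = max(families.get(key, 0.0), p)
        winner = max(families, key=families.get)
        records.append(
            {
                "replicate": rep,
                "winner": winner,
                "target_posterior": families[target],
                "recovered": winner == target,
            }
        )
    top = float(np.mean([r["recovered"] for r in records]))
    above = float(
        np.mean([r["recovered"] and r["target_posterior"] > threshold for r in records])
    )
    se = lambda f: float(np.sqrt(f * (1 - f) / n_replicates))  # noqa: E731
    return RecoverySummary(
        scenario,
        n_replicates,
        target,
        top,
        se(top),
        threshold,
        above,
        se(above),
        tuple(records),
    )
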