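"""Candidate model space for the caching-count comparison.

Each candidate sets the multinomial caching rates ``r`` in one of two ways:

* **Dependence models** declare, per dimension (food type, bird identity,
  compartment), whether the rates vary along it.  Rates carry a flat
  Dirichlet prior (``alpha = 1``) on their free coordinates.  In the
  two-food experiment the 2**3 dependence triples collapse to 7 distinct
  models, because bird dependence is vacuous when rates are food- and
  compartment-independent (all equal to 1/6).  In the food-absence
  experiment the tuples collapse to 3 models (rates 1/3 when
  compartment-independent).

* **Hypothesis models** (FPH1, FPH2, CCH) keep fully category-dependent
  rates but truncate the flat Dirichlet prior to an order-constraint
  region expressing the hypothesis, in a bird-dependent and a
  bird-independent variant each — 6 more models per experiment.

Constraints are conjunctions of weak pairwise inequalities between rate
coordinates in the semantically sorted frame.  In the food-absence
experiment the inequality template depends on the bird's counterbalancing
group (Food-First or Empty-First), and "bird-independent" rates are
shared within each group (a single vector could not satisfy both groups'
opposite constraints; the unconstrained group-pooled model is the
matching encompassing base).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from fractions import Fraction
from typing import Mapping, Sequence

import numpy as np

from .data import (
    CATEGORIES_TWO_FOOD,
    FOOD_ABSENCE,
    GROUPS,
    K_SLOTS,
    TWO_FOOD,
    ValidationError,
)

__all__ = [
    "HYPOTHESES",
    "ConstraintSet",
    "ModelSpec",
    "build_constraints",
    "enumerate_models",
    "prior_constraint_mass",
    "models_to_json",
]

HYPOTHESES = ("FPH1", "FPH2", "CCH")

_GE, _LE = ">=", "<="


@dataclass(frozen=True)
class ConstraintSet:
    """A conjunction of weak inequalities between rate coordinates.

    ``inequalities`` is a tuple of ``(lhs, relation, rhs)`` triples where
    ``lhs``/``rhs`` index coordinates of a rate vector of length
    ``n_categories`` and ``relation`` is ``">="`` or ``"<="``.  Ties have
    zero prior probability under any continuous prior, so weak and strict
    inequalities define the same comparison.
    """

    n_categories: int
    inequalities: tuple[tuple[int, str, int], ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "inequalities", tuple(map(tuple, self.inequalities)))
        for lhs, rel, rhs in self.inequalities:
            if rel not in (_GE, _LE):
                raise ValidationError(f"unknown relation {rel!r}")
            if lhs == rhs:
                raise ValidationError(f"inequality relates coordinate {lhs} to itself")
            if not (0 <= lhs < self.n_categories and 0 <= rhs < self.n_categories):
                raise ValidationError(
                    f"coordinate out of range in ({lhs}, {rel}, {rhs})"
                )

    def __len__(self) -> int:
        return len(self.inequalities)

    def satisfied(self, rates: np.ndarray) -> np.ndarray:
        """Boolean mask of rows of ``rates`` satisfying every inequality."""
        rates = np.atleast_2d(np.asarray(rates))
        ok = np.ones(rates.shape[0], dtype=bool)
        for lhs, rel, rhs in self.inequalities:
            diff = rates[:, lhs] - rates[:, rhs]
            ok &= diff >= 0 if rel == _GE else diff <= 0
        return ok

    def flipped(self) -> "ConstraintSet":
        """The same constraints with every inequality direction reversed."""
        swap = {_GE: _LE, _LE: _GE}
        return ConstraintSet(
            self.n_categories,
            tuple((lhs, swap[rel], rhs) for lhs, rel, rhs in self.inequalities),
        )


@dataclass(frozen=True)
class ModelSpec:
    """One candidate model.

    ``constraint`` is ``None`` for dependence models, a
    :class:`ConstraintSet` for two-food hypothesis models, and a mapping
    ``group -> ConstraintSet`` for food-absence hypothesis models (the
    template differs between the FF and EF groups).
    """

    model_id: str
    experiment: str
    food_dependent: bool | None
    bird_dependent: bool
    compartment_dependent: bool
    constraint: ConstraintSet | Mapping[str, ConstraintSet] | None = None
    hypothesis: str | None = None

    def __post_init__(self) -> None:
        if (self.constraint is None) != (self.hypothesis is None):
            raise ValidationError("constraint and hypothesis must be set together")
        if self.hypothesis is not None:
            if self.hypothesis not in HYPOTHESES:
                raise ValidationError(f"unknown hypothesis {self.hypothesis!r}")
            if not self.compartment_dependent or self.food_dependent is False:
                raise ValidationError(
                    "hypothesis models require fully category-dependent rates"
                )

    @property
    def is_constrained(self) -> bool:
        return self.constraint is not None

    @property
    def hypothesis_family(self) -> str | None:
        """``"FPH"`` for either future-planning prediction, ``"CCH"``, else None."""
        if self.hypothesis is None:
            return None
        return "FPH" if self.hypothesis.startswith("FPH") else "CCH"

    def constraint_for_group(self, group: str | None) -> ConstraintSet:
        if isinstance(self.constraint, ConstraintSet):
            return self.constraint
        if self.constraint is None:
            raise ValidationError(f"model {self.model_id!r} has no constraint")
        return self.constraint[group]


def _cat_index(k_slot: str, f_slot: str | None = None) -> int:
    """Flattened index of a sorted-frame category."""
    if f_slot is None:
        return K_SLOTS.index(k_slot)
    return CATEGORIES_TWO_FOOD.index((k_slot, f_slot))


def build_constraints(
    hypothesis: str, experiment: str, group: str | None = None
) -> ConstraintSet:
    """Inequality set encoding a hypothesis in the sorted frame.

    Two-food experiment (six categories, group ignored):

    * FPH1 — provision only the next relevant trial: the rate of caching
      the soon-missing food ``f1`` in the next compartment ``K1`` is the
      maximum of all six category rates.
    * FPH2 — provision the next three trials: within the ``f1`` block the
      ``K2`` rate is lowest, within the ``f2`` block the ``K2`` rate is
      highest.
    * CCH — cache where a food was scarce in the past: the FPH2
      inequalities reversed.

    Food-absence experiment (three categories, ``group`` required): FPH1
    for a Food-First bird puts the ``K1`` rate highest; FPH2/FF and
    CCH/EF put the ``K2`` rate lowest; CCH/FF and both FPH variants for
    EF birds put the ``K2`` rate highest.
    """
    if hypothesis not in HYPOTHESES:
        raise ValidationError(f"unknown hypothesis {hypothesis!r}")
    if experiment == TWO_FOOD:
        if hypothesis == "FPH1":
            top = _cat_index("K1", "f1")
            ineqs = tuple((top, _GE, j) for j in range(6) if j != top)
            return ConstraintSet(6, ineqs)
        fph2 = ConstraintSet(
            6,
            (
                (_cat_index("K1", "f1"), _GE, _cat_index("K2", "f1")),
                (_cat_index("K3", "f1"), _GE, _cat_index("K2", "f1")),
                (_cat_index("K1", "f2"), _LE, _cat_index("K2", "f2")),
                (_cat_index("K3", "f2"), _LE, _cat_index("K2", "f2")),
            ),
        )
        return fph2 if hypothesis == "FPH2" else fph2.flipped()
    if experiment == FOOD_ABSENCE:
        if group not in GROUPS:
            raise ValidationError(
                f"food_absence constraints need group in {GROUPS}, got {group!r}"
            )
        k1, k2, k3 = (_cat_index(k) for k in K_SLOTS)
        k1_top = ConstraintSet(3, ((k1, _GE, k2), (k1, _GE, k3)))
        k2_low = ConstraintSet(3, ((k2, _LE, k1), (k2, _LE, k3)))
        k2_top = k2_low.flipped()
        if group == "FF":
            return {"FPH1": k1_top, "FPH2": k2_low, "CCH": k2_top}[hypothesis]
        # Empty-First: food arrives on even days, so predictions reverse and
        # the two future-planning variants coincide (only K2 lacks food on
        # the three hypothetical follow-up trials).
        return k2_low if hypothesis == "CCH" else k2_top
    raise ValidationError(f"unknown experiment {experiment!r}")


def _group_constraints(hypothesis: str) -> dict[str, ConstraintSet]:
    return {g: build_constraints(hypothesis, FOOD_ABSENCE, g) for g in GROUPS}


def enumerate_models(experiment: str, include_constrained: bool = True):
    """Deterministic, stably-ordered enumeration of the candidate models.

    Returns 13 models for ``two_food`` (7 dependence + 6 hypothesis), 9
    for ``food_absence`` (3 + 6); with ``include_constrained=False`` only
    the dependence models.
    """
    models: list[ModelSpec] = []
    if experiment == TWO_FOOD:
        models.append(ModelSpec("indep", experiment, False, False, False))
        for food_dep, comp_dep, tag in (
            (True, False, "food"),
            (False, True, "comp"),
            (True, True, "food+comp"),
        ):
            models.append(ModelSpec(tag, experiment, food_dep, False, comp_dep))
            models.append(
                ModelSpec(f"{tag}+bird", experiment, food_dep, True, comp_dep)
            )
        if include_constrained:
            for hyp in HYPOTHESES:
                cs = build_constraints(hyp, experiment)
                models.append(
                    ModelSpec(f"{hyp}-bird", experiment, True, True, True, cs, hyp)
                )
                models.append(
                    ModelSpec(f"{hyp}-pooled", experiment, True, False, True, cs, hyp)
                )
        return tuple(models)
    if experiment == FOOD_ABSENCE:
        models.append(ModelSpec("indep", experiment, None, False, False))
        models.append(ModelSpec("comp", experiment, None, False, True))
        models.append(ModelSpec("comp+bird", experiment, None, True, True))
        if include_constrained:
            for hyp in HYPOTHESES:
                cs = _group_constraints(hyp)
                models.append(
                    ModelSpec(f"{hyp}-bird", experiment, None, True, True, cs, hyp)
                )
                models.append(
                    ModelSpec(f"{hyp}-pooled", experiment, None, False, True, cs, hyp)
                )
        return tuple(models)
    raise ValidationError(f"unknown experiment {experiment!r}")


def _star_blocks(constraint: ConstraintSet):
    """Decompose the constraint graph into blocks, each a 'hub-extremal star'.

    A block is a connected component of the inequality graph in which one
    hub coordinate sits on the large (or small) side of every inequality
    and all inequalities are incident to the hub.  Under an exchangeable
    prior, 'hub is the extreme of its block' has probability 1/|block|,
    independently across disjoint blocks.  Returns None if the pattern
    does not decompose this way.
    """
    from collections import defaultdict

    adj = defaultdict(set)
    for lhs, rel, rhs in constraint.inequalities:
        adj[lhs].add(rhs)
        adj[rhs].add(lhs)
    seen: set[int] = set()
    blocks = []
    for start in list(adj):
        if start in seen:
            continue
        comp = {start}
        stack = [start]
        while stack:
            node = stack.pop()
            for nb in adj[node]:
                if nb not in comp:
                    comp.add(nb)
                    stack.append(nb)
        seen |= comp
        edges = [
            (lhs, rel, rhs)
            for lhs, rel, rhs in constraint.inequalities
            if lhs in comp
        ]
        hubs = set(comp)
        for lhs, rel, rhs in edges:
            big = lhs if rel == _GE else rhs
            hubs &= {big}  # hub must be the large side of every edge...
        if not hubs:
            hubs = set(comp)
            for lhs, rel, rhs in edges:
                small = rhs if rel == _GE else lhs
                hubs &= {small}  # ...or the small side of every edge
        spokes = {
            (rhs if (lhs in hubs) else lhs)
            for lhs, rel, rhs in edges
            if hubs & {lhs, rhs}
        }
        if len(hubs) != 1 or spokes != comp - hubs or len(edges) != len(comp) - 1:
            return None
        blocks.append(comp)
    return blocks


def prior_constraint_mass(
    constraint: ConstraintSet,
    n_categories: int | None = None,
    *,
    mc_samples: int = 2_000_000,
    mc_seed: int = 20210112,
) -> Fraction | float:
    """Prior probability of the constraint region under a flat Dirichlet.

    Exact (a :class:`fractions.Fraction`) whenever the constraints
    decompose into disjoint hub-extremal star blocks, by exchangeability
    of the flat Dirichlet: each block of size ``s`` contributes ``1/s``.
    Otherwise falls back to Monte Carlo with a fixed documented seed and
    raises on an (effectively) infeasible region.
    """
    if n_categories is not None and n_categories != constraint.n_categories:
        raise ValidationError(
            f"n_categories {n_categories} != constraint.n_categories "
            f"{constraint.n_categories}"
        )
    if not constraint.inequalities:
        return Fraction(1)
    blocks = _star_blocks(constraint)
    if blocks is not None:
        mass = Fraction(1)
        for comp in blocks:
            mass /= len(comp)
        return mass
    rng = np.random.default_rng(mc_seed)
    draws = rng.dirichlet(np.ones(constraint.n_categories), size=mc_samples)
    p = constraint.satisfied(draws).mean()
    if p == 0.0:
        raise ValidationError(
            "constraint region has (numerically) zero prior mass; the "
            "inequalities are infeasible or nearly so"
        )
    return float(p)


def models_to_json(models: Sequence[ModelSpec], path=None) -> str:
    """Serialise a model enumeration for audit (id, flags, constraints)."""

    def one(m: ModelSpec) -> dict:
        entry = {
            "model_id": m.model_id,
            "experiment": m.experiment,
            "food_dependent": m.food_dependent,
            "bird_dependent": m.bird_dependent,
            "compartment_dependent": m.compartment_dependent,
            "hypothesis": m.hypothesis,
        }
        if isinstance(m.constraint, ConstraintSet):
            entry["inequalities"] = [list(i) for i in m.constraint.inequalities]
        elif m.constraint is not None:
            entry["inequalities"] = {
                g: [list(i) for i in cs.inequalities] for g, cs in m.constraint.items()
            }
        return entry

    text = json.dumps([one(m) for m in models], indent=2)
    if path is not None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(text)
    return text
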