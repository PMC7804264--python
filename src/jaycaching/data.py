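"""Experimental data structures for caching-count tables.

Two experiment layouts are supported.  In the two-food layout
(``two_food``) each bird caches items of two food types (peanut ``P``,
macadamia ``M``) into three compartments (``A``, ``B``, ``C``), giving six
count categories per bird.  In the food-absence layout (``food_absence``)
a single food is cached into the three compartments, giving three
categories, and each bird belongs to a Food-First (``FF``) or Empty-First
(``EF``) counterbalancing group.

Because the schedule a bird experienced was counterbalanced, raw counts
indexed by physical compartment are not comparable across birds.  Counts
are therefore *semantically sorted* into schedule-relative slots: ``K1``,
``K2``, ``K3`` are the compartments available on experience trials 1/4/7,
2/5/8 and 3/6/9 respectively, and (two-food layout only) ``f1``/``f2`` are
the foods received on odd/even trials.  The mapping is decoded from a
sequence code such as ``"BCA-MP"`` (compartment order B, C, A; odd-trial
food M) or ``"ABC-EF"`` (compartment order A, B, C; Empty-First group).

Sorted counts are always derived from the raw counts and the sequence
code at construction time; they are never read from a file.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

__all__ = [
    "TWO_FOOD",
    "FOOD_ABSENCE",
    "COMPARTMENTS",
    "FOODS",
    "K_SLOTS",
    "F_SLOTS",
    "GROUPS",
    "ValidationError",
    "SequenceAssignment",
    "BirdRecord",
    "ObservationTable",
    "parse_sequence_code",
    "semantic_sort",
    "read_observations",
    "write_observations",
    "load_fixture",
    "exclude_bird",
]

TWO_FOOD = "two_food"
FOOD_ABSENCE = "food_absence"
EXPERIMENTS = (TWO_FOOD, FOOD_ABSENCE)

COMPARTMENTS = ("A", "B", "C")
FOODS = ("P", "M")
K_SLOTS = ("K1", "K2", "K3")
F_SLOTS = ("f1", "f2")
GROUPS = ("FF", "EF")

#: Fixed category order used for flattened count vectors.
CATEGORIES_TWO_FOOD = tuple((k, f) for k in K_SLOTS for f in F_SLOTS)
CATEGORIES_FOOD_ABSENCE = K_SLOTS

_RAW_COLUMNS = {
    TWO_FOOD: tuple(f"{c}_{f}" for c in COMPARTMENTS for f in FOODS),
    FOOD_ABSENCE: COMPARTMENTS,
}


class ValidationError(ValueError):
    """Raised when input data violates the experiment's contract."""


def _check_experiment(experiment: str) -> None:
    if experiment not in EXPERIMENTS:
        raise ValidationError(
            f"unknown experiment {experiment!r}; expected one of {EXPERIMENTS}"
        )


@dataclass(frozen=True)
class SequenceAssignment:
    """Decoded experience schedule for one bird.

    Parameters
    ----------
    compartment_of
        Bijection from semantic slot (``K1``/``K2``/``K3``) to physical
        compartment label (``A``/``B``/``C``).
    food_of
        Bijection from food slot (``f1``/``f2``) to food label
        (``P``/``M``); two-food layout only.
    group
        ``FF`` or ``EF``; food-absence layout only.

    Exactly one of ``food_of`` and ``group`` is set.
    """

    compartment_of: Mapping[str, str]
    food_of: Mapping[str, str] | None = None
    group: str | None = None

    def __post_init__(self) -> None:
        if sorted(self.compartment_of) != sorted(K_SLOTS):
            raise ValidationError(f"compartment_of keys must be {K_SLOTS}")
        if sorted(self.compartment_of.values()) != sorted(COMPARTMENTS):
            raise ValidationError(
                f"compartment_of must be a bijection onto {COMPARTMENTS}, "
                f"got {dict(self.compartment_of)}"
            )
        if (self.food_of is None) == (self.group is None):
            raise ValidationError("exactly one of food_of/group must be set")
        if self.food_of is not None and (
            sorted(self.food_of) != sorted(F_SLOTS)
            or sorted(self.food_of.values()) != sorted(FOODS)
        ):
            raise ValidationError(
                f"food_of must be a bijection {F_SLOTS} -> {FOODS}"
            )
        if self.group is not None and self.group not in GROUPS:
            raise ValidationError(f"group must be one of {GROUPS}, got {self.group!r}")


def parse_sequence_code(code: str, experiment: str) -> SequenceAssignment:
    """Decode a sequence code like ``"BCA-MP"`` or ``"ABC-EF"``.

    The prefix is a permutation of ``ABC`` giving the physical compartment
    bound to ``K1``, ``K2``, ``K3`` in order.  For the two-food layout the
    suffix is ``MP`` or ``PM`` giving the odd-trial food (``f1``) first;
    for the food-absence layout it is the group label ``FF`` or ``EF``.
    """
    _check_experiment(experiment)
    if not isinstance(code, str) or code.count("-") != 1:
        raise ValidationError(f"malformed sequence code {code!r}")
    prefix, suffix = code.split("-")
    if sorted(prefix) != sorted(COMPARTMENTS):
        raise ValidationError(
            f"sequence code {code!r}: compartment part {prefix!r} is not a "
            f"permutation of {''.join(COMPARTMENTS)}"
        )
    compartment_of = dict(zip(K_SLOTS, prefix))
    if experiment == TWO_FOOD:
        if sorted(suffix) != sorted(FOODS):
            raise ValidationError(
                f"sequence code {code!r}: food part {suffix!r} is not a "
                f"permutation of {''.join(FOODS)}"
            )
        return SequenceAssignment(compartment_of, food_of=dict(zip(F_SLOTS, suffix)))
    if suffix not in GROUPS:
        raise ValidationError(
            f"sequence code {code!r}: group part {suffix!r} not in {GROUPS}"
        )
    return SequenceAssignment(compartment_of, group=suffix)


def semantic_sort(raw_counts: Mapping, assignment: SequenceAssignment) -> dict:
    """Relabel raw counts into the schedule-relative (K, f) frame.

    ``sorted_counts[(Ki, fj)] = raw_counts[(compartment_of[Ki], food_of[fj])]``
    in the two-food layout; ``sorted_counts[Ki] = raw_counts[compartment_of[Ki]]``
    in the food-absence layout.  Totals and the multiset of cell values are
    preserved because the relabelling is a bijection of cells.
    """
    if assignment.food_of is not None:
        expected = {(c, f) for c in COMPARTMENTS for f in FOODS}
        if set(raw_counts) != expected:
            missing = expected - set(raw_counts)
            raise ValidationError(f"raw_counts missing cells: {sorted(missing)}")
        return {
            (k, f): raw_counts[(assignment.compartment_of[k], assignment.food_of[f])]
            for k in K_SLOTS
            for f in F_SLOTS
        }
    if set(raw_counts) != set(COMPARTMENTS):
        missing = set(COMPARTMENTS) - set(raw_counts)
        raise ValidationError(f"raw_counts missing cells: {sorted(missing)}")
    return {k: raw_counts[assignment.compartment_of[k]] for k in K_SLOTS}


def _validate_counts(counts: Mapping, where: str) -> None:
    for key, value in counts.items():
        if isinstance(value, bool) or not isinstance(value, int) or value < 0:
            raise ValidationError(
                f"{where}: count for {key} must be a non-negative integer, "
                f"got {value!r}"
            )


@dataclass(frozen=True)
class BirdRecord:
    """One bird's counts, in both the raw and semantically sorted frames."""

    bird_id: str
    sequence_code: str
    experiment: str
    raw_counts: Mapping = field(repr=False)
    sorted_counts: Mapping = field(init=False, repr=False)
    assignment: SequenceAssignment = field(init=False, repr=False)

    def __post_init__(self) -> None:
        _check_experiment(self.experiment)
        assignment = parse_sequence_code(self.sequence_code, self.experiment)
        _validate_counts(self.raw_counts, f"bird {self.bird_id!r}")
        object.__setattr__(self, "assignment", assignment)
        object.__setattr__(
            self, "sorted_counts", semantic_sort(self.raw_counts, assignment)
        )

    @property
    def group(self) -> str | None:
        return self.assignment.group

    @property
    def total(self) -> int:
        return sum(self.raw_counts.values())

    def sorted_vector(self) -> list[int]:
        """Sorted counts flattened in the fixed category order."""
        cats = (
            CATEGORIES_TWO_FOOD
            if self.experiment == TWO_FOOD
            else CATEGORIES_FOOD_ABSENCE
        )
        return [self.sorted_counts[c] for c in cats]

    def raw_vector(self) -> list[int]:
        if self.experiment == TWO_FOOD:
            return [self.raw_counts[(c, f)] for c in COMPARTMENTS for f in FOODS]
        return [self.raw_counts[c] for c in COMPARTMENTS]


@dataclass(frozen=True)
class ObservationTable:
    """An ordered collection of :class:`BirdRecord` for one experiment."""

    experiment: str
    birds: tuple[BirdRecord, ...]

    def __post_init__(self) -> None:
        _check_experiment(self.experiment)
        object.__setattr__(self, "birds", tuple(self.birds))
        ids = [b.bird_id for b in self.birds]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate bird_ids: {dupes}")
        for b in self.birds:
            if b.experiment != self.experiment:
                raise ValidationError(
                    f"bird {b.bird_id!r} has experiment {b.experiment!r}, "
                    f"table has {self.experiment!r}"
                )

    @property
    def n_birds(self) -> int:
        return len(self.birds)

    @property
    def dims(self) -> tuple[int, int, int]:
        """(number of birds, food slots, compartments)."""
        return (self.n_birds, 2 if self.experiment == TWO_FOOD else 1, 3)

    @property
    def n_categories(self) -> int:
        _, d_f, d_c = self.dims
        return d_f * d_c

    @property
    def bird_ids(self) -> tuple[str, ...]:
        return tuple(b.bird_id for b in self.birds)

    def sorted_matrix(self):
        """Per-bird sorted count vectors as a list of lists (birds × categories)."""
        return [b.sorted_vector() for b in self.birds]

    def groups(self) -> tuple[str, ...]:
        if self.experiment != FOOD_ABSENCE:
            raise ValidationError("groups are defined only for food_absence tables")
        return tuple(b.group for b in self.birds)

    def fingerprint(self) -> str:
        """Stable content digest used to label result tables."""
        import hashlib

        h = hashlib.sha256()
        h.update(self.experiment.encode())
        for b in self.birds:
            h.update(b.bird_id.encode())
            h.update(b.sequence_code.encode())
            h.update(",".join(map(str, b.raw_vector())).encode())
        return h.hexdigest()[:16]


def _parse_int(text: str, row: int, column: str) -> int:
    stripped = text.strip()
    if not stripped.lstrip("+").isdigit():
        raise ValidationError(
            f"row {row}: column {column!r} has malformed count {text!r} "
            "(must be a non-negative integer)"
        )
    return int(stripped)


def read_observations(path, experiment: str) -> ObservationTable:
    """Read a CSV of per-bird counts into a validated :class:`ObservationTable`.

    Expected header: ``bird_id,sequence_code`` followed by the raw count
    columns ``A_P,A_M,B_P,B_M,C_P,C_M`` (two-food) or ``A,B,C``
    (food-absence).  Sorted counts are recomputed from the sequence codes.
    """
    _check_experiment(experiment)
    raw_cols = _RAW_COLUMNS[experiment]
    expected_header = ["bird_id", "sequence_code", *raw_cols]
    if isinstance(path, io.TextIOBase):
        rows = list(csv.reader(path))
    else:
        with open(path, newline="", encoding="utf-8") as fh:
            rows = list(csv.reader(fh))
    if not rows or rows[0] != expected_header:
        raise ValidationError(
            f"bad header: expected {expected_header}, got {rows[0] if rows else None}"
        )
    birds = []
    for i, row in enumerate(rows[1:], start=2):
        if len(row) != len(expected_header):
            raise ValidationError(f"row {i}: expected {len(expected_header)} fields")
        bird_id, code = row[0], row[1]
        values = [_parse_int(v, i, c) for v, c in zip(row[2:], raw_cols)]
        if experiment == TWO_FOOD:
            raw = {
                (c, f): v
                for (c, f), v in zip(
                    ((c, f) for c in COMPARTMENTS for f in FOODS), values
                )
            }
        else:
            raw = dict(zip(COMPARTMENTS, values))
        try:
            birds.append(BirdRecord(bird_id, code, experiment, raw))
        except ValidationError as err:
            raise ValidationError(f"row {i}: {err}") from err
    return ObservationTable(experiment, tuple(birds))


def write_observations(table: ObservationTable, path) -> None:
    """Write a table in the same CSV dialect that :func:`read_observations` reads."""
    raw_cols = _RAW_COLUMNS[table.experiment]
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["bird_id", "sequence_code", *raw_cols])
        for b in table.birds:
            writer.writerow([b.bird_id, b.sequence_code, *b.raw_vector()])


_FIXTURES = {
    "table1": ("table1.csv", TWO_FOOD),
    "table2": ("table2.csv", FOOD_ABSENCE),
}


def load_fixture(name: str) -> ObservationTable:
    """Load a packaged dataset: ``"table1"`` (two-food) or ``"table2"``."""
    if name not in _FIXTURES:
        raise ValidationError(f"unknown fixture {name!r}; choose from {sorted(_FIXTURES)}")
    filename, experiment = _FIXTURES[name]
    text = resources.files("jaycaching.fixtures").joinpath(filename).read_text()
    return read_observations(io.StringIO(text), experiment)


def fixture_path(name: str) -> Path:
    """Filesystem path of a packaged fixture CSV (for copying/dumping)."""
    if name not in _FIXTURES:
        raise ValidationError(f"unknown fixture {name!r}; choose from {sorted(_FIXTURES)}")
    return Path(str(resources.files("jaycaching.fixtures").joinpath(_FIXTURES[name][0])))


def exclude_bird(table: ObservationTable, bird_id: str) -> ObservationTable:
    """Return a new table without ``bird_id``; the original is unchanged."""
    if bird_id not in table.bird_ids:
        raise ValidationError(
            f"bird {bird_id!r} not in table (birds: {list(table.bird_ids)})"
        )
    return ObservationTable(
        table.experiment, tuple(b for b in table.birds if b.bird_id != bird_id)
    )
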