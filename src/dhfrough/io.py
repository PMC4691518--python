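"""Reading, writing and generating diagnosis problem instances.

A :class:`ProblemInstance` bundles everything one diagnosis run needs: the
ordered diagnosis universe U, the symptom universe V, one dual hesitant
fuzzy relation per expert, and the patient's symptom DHFS over V.

Two on-disk formats are supported:

* **JSON** (primary): a single document with explicit universes and
  per-cell grade lists — natural for ragged cells whose hesitancy varies.
* **CSV** (spreadsheet entry): one row per relation cell
  ``expert,row,col,h,g`` with grades ``|``-joined; patient rows use the
  reserved expert name ``patient`` and an empty row label.

All elicited-input invariants (grades in [0, 1], complete grids,
``max(h) + max(g) <= 1``) are enforced at load with cell coordinates in
every error message.  ``save`` then ``load`` is the identity on canonical
forms.
"""

from __future__ import annotations

import csv
import json
import random
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Any, Sequence

from .algebra import DualHesitantElement, DualHesitantSet, ValidationError
from .rough import DualHesitantRelation

__all__ = [
    "ProblemInstance",
    "load_instance",
    "save_instance",
    "worked_example",
    "random_instance",
]


@dataclass(frozen=True)
class ProblemInstance:
    """A dual hesitant fuzzy decision information system (U, V, Rᵢ, A)."""

    diagnoses: tuple[str, ...]
    symptoms: tuple[str, ...]
    relations: tuple[DualHesitantRelation, ...]
    patient: DualHesitantSet
    metadata: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.relations:
            raise ValidationError("an instance needs at least one relation")
        for r in self.relations:
            if (
                r.row_universe != self.diagnoses
                or r.col_universe != self.symptoms
            ):
                raise ValidationError(
                    f"relation {r.name!r} does not share the instance universes"
                )
        if tuple(self.patient.universe) != self.symptoms:
            raise ValidationError(
                "patient set is not defined over the symptom universe"
            )
        for y in self.symptoms:
            if not self.patient[y].is_full_pair:
                raise ValidationError(
                    f"patient[{y}]: both h and g must be nonempty"
                )

    @property
    def bound_violations(self) -> tuple[str, ...]:
        """Human-readable coordinates of cells breaking max(h)+max(g) <= 1."""
        out = [
            f"{r.name} ({x}, {y})"
            for r in self.relations
            for (x, y) in r.bound_violations
        ]
        out.extend(
            f"patient[{y}]"
            for y in self.symptoms
            if self.patient[y].violates_bound()
        )
        return tuple(out)


def _element_from_json(obj: Any, where: str) -> DualHesitantElement:
    if (
        not isinstance(obj, dict)
        or set(obj) != {"h", "g"}
        or not all(isinstance(obj[k], list) for k in ("h", "g"))
    ):
        raise ValidationError(
            f"{where}: expected an object {{'h': [...], 'g': [...]}}"
        )
    try:
        element = DualHesitantElement.of(
            (float(v) for v in obj["h"]), (float(v) for v in obj["g"])
        )
    except ValidationError as exc:
        raise ValidationError(f"{where}: {exc}") from None
    except (TypeError, ValueError) as exc:
        raise ValidationError(f"{where}: non-numeric grade") from exc
    if not element.is_full_pair:
        raise ValidationError(f"{where}: both h and g must be nonempty")
    return element


def _element_to_json(d: DualHesitantElement) -> dict[str, list[float]]:
    return {"h": list(d.h.values), "g": list(d.g.values)}


def _instance_from_dict(doc: Any, where: str = "document") -> ProblemInstance:
    if not isinstance(doc, dict):
        raise ValidationError(f"{where}: top level must be an object")
    for key in ("diagnoses", "symptoms", "experts", "patient"):
        if key not in doc:
            raise ValidationError(f"{where}: missing required key {key!r}")
    diagnoses = tuple(str(x) for x in doc["diagnoses"])
    symptoms = tuple(str(y) for y in doc["symptoms"])
    if not isinstance(doc["experts"], list) or not doc["experts"]:
        raise ValidationError(f"{where}: 'experts' must be a nonempty list")
    relations = []
    for i, expert in enumerate(doc["experts"]):
        name = str(expert.get("name", f"expert {i + 1}"))
        grid = expert.get("cells", {})
        cells = {}
        for x in diagnoses:
            row = grid.get(x)
            if row is None:
                raise ValidationError(f"expert {name!r}: missing row {x!r}")
            for y in symptoms:
                if y not in row:
                    raise ValidationError(
                        f"expert {name!r}: missing cell ({x}, {y})"
                    )
                cells[(x, y)] = _element_from_json(
                    row[y], f"expert {name!r} cell ({x}, {y})"
                )
        relations.append(
            DualHesitantRelation(diagnoses, symptoms, cells, name=name)
        )
    patient_doc = doc["patient"]
    patient_elems = {}
    for y in symptoms:
        if y not in patient_doc:
            raise ValidationError(f"patient: missing symptom {y!r}")
        patient_elems[y] = _element_from_json(patient_doc[y], f"patient[{y}]")
    patient = DualHesitantSet(symptoms, patient_elems)
    return ProblemInstance(
        diagnoses,
        symptoms,
        tuple(relations),
        patient,
        dict(doc.get("metadata", {})),
    )


def _instance_to_dict(instance: ProblemInstance) -> dict[str, Any]:
    return {
        "diagnoses": list(instance.diagnoses),
        "symptoms": list(instance.symptoms),
        "experts": [
            {
                "name": r.name,
                "cells": {
                    x: {
                        y: _element_to_json(r[x, y]) for y in instance.symptoms
                    }
                    for x in instance.diagnoses
                },
            }
            for r in instance.relations
        ],
        "patient": {
            y: _element_to_json(instance.patient[y]) for y in instance.symptoms
        },
        "metadata": instance.metadata,
    }


_PATIENT = "patient"


def _save_csv(instance: ProblemInstance, path: Path) -> None:
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["expert", "row", "col", "h", "g"])
        for r in instance.relations:
            for x in instance.diagnoses:
                for y in instance.symptoms:
                    d = r[x, y]
                    writer.writerow(
                        [
                            r.name,
                            x,
                            y,
                            "|".join(repr(v) for v in d.h),
                            "|".join(repr(v) for v in d.g),
                        ]
                    )
        for y in instance.symptoms:
            d = instance.patient[y]
            writer.writerow(
                [
                    _PATIENT,
                    "",
                    y,
                    "|".join(repr(v) for v in d.h),
                    "|".join(repr(v) for v in d.g),
                ]
            )


def _split_grades(text: str, where: str) -> list[float]:
    try:
        return [float(tok) for tok in text.split("|") if tok != ""]
    except ValueError as exc:
        raise ValidationError(f"{where}: bad grade list {text!r}") from exc


def _load_csv(path: Path) -> ProblemInstance:
    experts: dict[str, dict[tuple[str, str], DualHesitantElement]] = {}
    patient: dict[str, DualHesitantElement] = {}
    diagnoses: list[str] = []
    symptoms: list[str] = []
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header != ["expert", "row", "col", "h", "g"]:
            raise ValidationError(
                f"{path}: expected header expert,row,col,h,g, got {header}"
            )
        for lineno, row in enumerate(reader, start=2):
            if not row or all(not f for f in row):
                continue
            if len(row) != 5:
                raise ValidationError(f"{path}:{lineno}: expected 5 fields")
            expert, x, y, h_text, g_text = row
            where = f"{path}:{lineno} ({expert!r}, {x!r}, {y!r})"
            try:
                element = DualHesitantElement.of(
                    _split_grades(h_text, where), _split_grades(g_text, where)
                )
            except ValidationError as exc:
                raise ValidationError(f"{where}: {exc}") from None
            if not element.is_full_pair:
                raise ValidationError(f"{where}: both h and g must be nonempty")
            if y not in symptoms:
                symptoms.append(y)
            if expert == _PATIENT:
                patient[y] = element
            else:
                if x not in diagnoses:
                    diagnoses.append(x)
                experts.setdefault(expert, {})[(x, y)] = element
    if not experts:
        raise ValidationError(f"{path}: no expert rows found")
    if set(patient) != set(symptoms):
        raise ValidationError(f"{path}: patient rows do not cover all symptoms")
    relations = tuple(
        DualHesitantRelation(diagnoses, symptoms, cells, name=name)
        for name, cells in experts.items()
    )
    return ProblemInstance(
        tuple(diagnoses),
        tuple(symptoms),
        relations,
        DualHesitantSet(symptoms, patient),
        {"source": str(path)},
    )


def load_instance(path: str | Path, strict: bool = False) -> ProblemInstance:
    """Load a problem instance from a ``.json`` or ``.csv`` file.

    Grade range, grid completeness and universe consistency are always
    enforced.  Cells breaking the elicited bound ``max(h) + max(g) <= 1``
    raise only under ``strict=True``; otherwise they trigger a warning and
    are listed in :attr:`ProblemInstance.bound_violations`.
    """
    path = Path(path)
    if path.suffix.lower() == ".csv":
        instance = _load_csv(path)
    else:
        try:
            doc = json.loads(path.read_text(encoding="utf-8"))
        except json.JSONDecodeError as exc:
            raise ValidationError(f"{path}: not valid JSON ({exc})") from exc
        instance = _instance_from_dict(doc, where=str(path))
    violations = instance.bound_violations
    if violations:
        if strict:
            raise ValidationError(
                f"{path}: max(h)+max(g) > 1 at {', '.join(violations)}"
            )
        warnings.warn(
            f"{path}: max(h)+max(g) > 1 at {', '.join(violations)}",
            stacklevel=2,
        )
    return instance


def save_instance(instance: ProblemInstance, path: str | Path) -> None:
    """Write an instance to ``.json`` (default) or ``.csv``."""
    path = Path(path)
    if path.suffix.lower() == ".csv":
        _save_csv(instance, path)
        return
    path.write_text(
        json.dumps(_instance_to_dict(instance), indent=1), encoding="utf-8"
    )


def worked_example() -> ProblemInstance:
    """The packaged five-diagnosis fever case study.

    Three experts assess five diagnoses (viral fever, malaria, typhoid,
    stomach problem, chest problem) against five symptoms (temperature,
    headache, cough, stomach pain, chest pain); the patient presents one
    singleton-graded DHFE per symptom.
    """
    text = (
        resources.files("dhfrough.datasets")
        .joinpath("fever.json")
        .read_text(encoding="utf-8")
    )
    return _instance_from_dict(json.loads(text), where="fever.json")


def random_instance(
    n_diagnoses: int,
    n_symptoms: int,
    n_experts: int,
    max_hesitancy: int = 3,
    seed: int | None = None,
    grade_decimals: int = 3,
) -> ProblemInstance:
    """Generate a reproducible random instance.

    Each cell draws 1..``max_hesitancy`` membership grades uniformly on
    [0, 1], then 1..``max_hesitancy`` nonmembership grades uniformly on
    [0, 1 − max(h)], so the elicited-input bound holds by construction.
    Grades are rounded to ``grade_decimals`` places (deduplication may then
    shrink a cell's hesitancy, never below one grade).  The worked example's
    shape is 5×5 with 3 experts and hesitancy ≤ 2; defaults here follow the
    caller.
    """
    if min(n_diagnoses, n_symptoms, n_experts) < 1:
        raise ValidationError("universe sizes and expert count must be >= 1")
    if max_hesitancy < 1:
        raise ValidationError("max_hesitancy must be >= 1")
    rng = random.Random(seed)
    diagnoses = tuple(f"x{i + 1}" for i in range(n_diagnoses))
    symptoms = tuple(f"y{j + 1}" for j in range(n_symptoms))

    def draw_element() -> DualHesitantElement:
        h = [
            round(rng.random(), grade_decimals)
            for _ in range(rng.randint(1, max_hesitancy))
        ]
        room = 1.0 - max(h)
        # clamp after rounding so the elicited bound survives rounding up
        g = [
            min(room, round(rng.uniform(0.0, room), grade_decimals))
            for _ in range(rng.randint(1, max_hesitancy))
        ]
        return DualHesitantElement.of(h, g)

    relations = tuple(
        DualHesitantRelation(
            diagnoses,
            symptoms,
            {
                (x, y): draw_element()
                for x in diagnoses
                for y in symptoms
            },
            name=f"expert {i + 1}",
        )
        for i in range(n_experts)
    )
    patient = DualHesitantSet(
        symptoms, {y: draw_element() for y in symptoms}
    )
    return ProblemInstance(
        diagnoses,
        symptoms,
        relations,
        patient,
        {"seed": seed, "max_hesitancy": max_hesitancy},
    )
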