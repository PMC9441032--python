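"""Three-valued (Kleene) predicate logic over patient records.

Screening rules must distinguish "the condition does not hold" from "the
data needed to decide is missing".  Every atomic test on a patient record
therefore evaluates to one of three truth values — TRUE, FALSE or UNKNOWN —
and composite AND/OR/NOT expressions combine them under strong Kleene
semantics: UNKNOWN AND FALSE = FALSE, UNKNOWN OR TRUE = TRUE, otherwise
UNKNOWN propagates.  A rule whose condition evaluates UNKNOWN yields an
``insufficient_data`` outcome rather than silently passing or failing.

Predicate expressions are plain data (dicts, as loaded from the YAML
knowledge base) compiled into :class:`Predicate` trees.  Atom vocabulary:

``{"field": path, "op": cmp, "value": v}``
    comparison on a record field (dotted path); absent field -> UNKNOWN
``{"field_absent": path}``
    two-valued presence test (TRUE when the field is absent)
``{"lab": analyte, "op": cmp, "value": v}``
    comparison on the most recent value of a numeric analyte
``{"lab_absent": analyte}``
    two-valued: TRUE when no entry for the analyte exists
``{"diagnosis": code}`` / ``{"diagnosis_any": [codes]}``
    set membership on coded diagnoses (two-valued)
``{"med": tag}`` / ``{"med_any": [tags]}``
    any current medication carries the class tag (two-valued)
``{"high_dose_oral_steroid": {"mg_per_day": x, "min_days": d}}``
    systemic corticosteroid above a prednisolone-equivalent dose for at
    least ``min_days``; UNKNOWN when a steroid is present but dose or
    duration is unrecorded
``{"early_weight_gain": true}``
    >=5% weight gain within 31 days of treatment start (ternary)
``{"bp_comorbidity_flag": true}``
    any hypertension comorbidity flag recorded (UNKNOWN without a BP block)
``{"always": true}``
    constant TRUE (context-free counselling prompts)
``{"all": [...]}, {"any": [...]}, {"not": ...}``
    composites
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Any, Callable, Iterable


class Ternary(enum.Enum):
    """Strong Kleene truth value."""

    TRUE = "true"
    FALSE = "false"
    UNKNOWN = "unknown"

    def __bool__(self) -> bool:  # pragma: no cover - guard against misuse
        raise TypeError("Ternary is not coercible to bool; compare explicitly")

    @staticmethod
    def from_bool(value: bool | None) -> "Ternary":
        if value is None:
            return Ternary.UNKNOWN
        return Ternary.TRUE if value else Ternary.FALSE


T, F, U = Ternary.TRUE, Ternary.FALSE, Ternary.UNKNOWN


def kleene_and(values: Iterable[Ternary]) -> Ternary:
    out = T
    for v in values:
        if v is F:
            return F
        if v is U:
            out = U
    return out


def kleene_or(values: Iterable[Ternary]) -> Ternary:
    out = F
    for v in values:
        if v is T:
            return T
        if v is U:
            out = U
    return out


def kleene_not(value: Ternary) -> Ternary:
    if value is U:
        return U
    return F if value is T else T


@dataclass(frozen=True)
class AtomResult:
    """One atom's contribution to a rule evaluation."""

    description: str
    value: Ternary
    fields: tuple[str, ...]


@dataclass
class Evaluation:
    value: Ternary
    atoms: list[AtomResult] = field(default_factory=list)

    @property
    def missing_fields(self) -> list[str]:
        out: list[str] = []
        for a in self.atoms:
            if a.value is U:
                for f in a.fields:
                    if f not in out:
                        out.append(f)
        return out


_OPS: dict[str, Callable[[Any, Any], bool]] = {
    "eq": lambda a, b: a == b,
    "ne": lambda a, b: a != b,
    "ge": lambda a, b: a >= b,
    "gt": lambda a, b: a > b,
    "le": lambda a, b: a <= b,
    "lt": lambda a, b: a < b,
    "in": lambda a, b: a in b,
}


class Predicate:
    """A compiled predicate-expression node."""

    kind: str

    def __init__(self, kind: str, *, children: list["Predicate"] | None = None,
                 atom: dict[str, Any] | None = None) -> None:
        self.kind = kind
        self.children = children or []
        self.atom = atom or {}

    # -- compilation ------------------------------------------------------

    @staticmethod
    def compile(expr: dict[str, Any]) -> "Predicate":
        if not isinstance(expr, dict) or not expr:
            raise ValueError(f"predicate expression must be a non-empty mapping, got {expr!r}")
        if "all" in expr:
            return Predicate("all", children=[Predicate.compile(e) for e in expr["all"]])
        if "any" in expr:
            return Predicate("any", children=[Predicate.compile(e) for e in expr["any"]])
        if "not" in expr:
            return Predicate("not", children=[Predicate.compile(expr["not"])])
        kind = _atom_kind(expr)
        _validate_atom(kind, expr)
        return Predicate(kind, atom=dict(expr))

    # -- introspection ----------------------------------------------------

    def referenced_fields(self) -> list[str]:
        """Record field paths this predicate reads, in first-use order."""
        out: list[str] = []

        def walk(node: "Predicate") -> None:
            if node.kind in ("all", "any", "not"):
                for c in node.children:
                    walk(c)
                return
            for f in _atom_fields(node.kind, node.atom):
                if f not in out:
                    out.append(f)

        walk(self)
        return out

    # -- evaluation -------------------------------------------------------

    def evaluate(self, record: Any) -> Evaluation:
        atoms: list[AtomResult] = []
        value = self._eval(record, atoms)
        return Evaluation(value=value, atoms=atoms)

    def _eval(self, record: Any, atoms: list[AtomResult]) -> Ternary:
        if self.kind == "all":
            return kleene_and(c._eval(record, atoms) for c in self.children)
        if self.kind == "any":
            return kleene_or(c._eval(record, atoms) for c in self.children)
        if self.kind == "not":
            return kleene_not(self.children[0]._eval(record, atoms))
        value = _eval_atom(self.kind, self.atom, record)
        atoms.append(AtomResult(
            description=_describe_atom(self.kind, self.atom),
            value=value,
            fields=tuple(_atom_fields(self.kind, self.atom)),
        ))
        return value


_ATOM_KEYS = (
    "field", "field_absent", "lab", "lab_absent", "diagnosis", "diagnosis_any",
    "med", "med_any", "high_dose_oral_steroid", "early_weight_gain",
    "bp_comorbidity_flag", "always",
)


def _atom_kind(expr: dict[str, Any]) -> str:
    for key in _ATOM_KEYS:
        if key in expr:
            return key
    raise ValueError(f"unrecognised predicate atom: {sorted(expr)}")


def _validate_atom(kind: str, expr: dict[str, Any]) -> None:
    if kind in ("field", "lab"):
        op = expr.get("op")
        if op not in _OPS:
            raise ValueError(f"atom {expr!r}: unknown comparison op {op!r}")
        if "value" not in expr:
            raise ValueError(f"atom {expr!r}: missing 'value'")


def _atom_fields(kind: str, atom: dict[str, Any]) -> list[str]:
    if kind == "field":
        return [atom["field"]]
    if kind == "field_absent":
        return [atom["field_absent"]]
    if kind == "lab":
        return [f"labs.{atom['lab']}"]
    if kind == "lab_absent":
        return [f"labs.{atom['lab_absent']}"]
    if kind in ("diagnosis", "diagnosis_any"):
        return ["diagnoses"]
    if kind in ("med", "med_any", "high_dose_oral_steroid"):
        return ["medications"]
    if kind == "early_weight_gain":
        return ["weight_history", "treatment_start_date"]
    if kind == "bp_comorbidity_flag":
        return ["blood_pressure.hypertension_comorbidity_flags"]
    return []


def _describe_atom(kind: str, atom: dict[str, Any]) -> str:
    if kind == "field":
        return f"{atom['field']} {atom['op']} {atom['value']!r}"
    if kind == "field_absent":
        return f"{atom['field_absent']} absent"
    if kind == "lab":
        return f"labs.{atom['lab']} {atom['op']} {atom['value']}"
    if kind == "lab_absent":
        return f"labs.{atom['lab_absent']} absent"
    if kind == "diagnosis":
        return f"diagnosis {atom['diagnosis']}"
    if kind == "diagnosis_any":
        return f"diagnosis in {sorted(atom['diagnosis_any'])}"
    if kind == "med":
        return f"medication tagged {atom['med']}"
    if kind == "med_any":
        return f"medication tagged any of {sorted(atom['med_any'])}"
    if kind == "high_dose_oral_steroid":
        spec = atom["high_dose_oral_steroid"]
        return (f"oral steroid > {spec.get('mg_per_day', 7.5)} mg/day prednisolone-eq "
                f"for >= {spec.get('min_days', 90)} days")
    if kind == "early_weight_gain":
        return "early weight gain (>=5% within 31 days of treatment start)"
    if kind == "bp_comorbidity_flag":
        return "hypertension comorbidity flag recorded"
    return "always"


def _resolve_field(record: Any, path: str) -> Any:
    """Dotted-path lookup; returns None when any hop is absent."""
    obj = record
    for part in path.split("."):
        if obj is None:
            return None
        obj = getattr(obj, part, None)
    return obj


def _eval_atom(kind: str, atom: dict[str, Any], record: Any) -> Ternary:
    if kind == "always":
        return T
    if kind == "field":
        value = _resolve_field(record, atom["field"])
        if value is None:
            return U
        if isinstance(value, enum.Enum):
            value = value.value
        return Ternary.from_bool(_OPS[atom["op"]](value, atom["value"]))
    if kind == "field_absent":
        return Ternary.from_bool(_resolve_field(record, atom["field_absent"]) is None)
    if kind == "lab":
        value = record.labs.latest_value(atom["lab"])
        if value is None:
            return U
        return Ternary.from_bool(_OPS[atom["op"]](value, atom["value"]))
    if kind == "lab_absent":
        return Ternary.from_bool(record.labs.latest_value(atom["lab_absent"]) is None)
    if kind == "diagnosis":
        return Ternary.from_bool(atom["diagnosis"] in record.diagnoses)
    if kind == "diagnosis_any":
        return Ternary.from_bool(bool(set(atom["diagnosis_any"]) & record.diagnoses))
    if kind == "med":
        return Ternary.from_bool(record.has_medication_tag(atom["med"]))
    if kind == "med_any":
        return Ternary.from_bool(any(record.has_medication_tag(t) for t in atom["med_any"]))
    if kind == "high_dose_oral_steroid":
        spec = atom["high_dose_oral_steroid"]
        return record.high_dose_oral_steroid(
            mg_per_day=spec.get("mg_per_day", 7.5), min_days=spec.get("min_days", 90))
    if kind == "early_weight_gain":
        return Ternary.from_bool(record.early_weight_gain())
    if kind == "bp_comorbidity_flag":
        bp = record.blood_pressure
        if bp is None:
            return U
        return Ternary.from_bool(bool(bp.hypertension_comorbidity_flags))
    raise AssertionError(f"unhandled atom kind {kind}")  # pragma: no cover
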