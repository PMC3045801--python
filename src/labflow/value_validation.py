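"""Validation and coercion of user-entered attribute values.

Raw values arrive as strings (the way an operator types them into a form or
onto the command line) and are checked against an :class:`AttributeSpec` in a
fixed order: **type, then format, then allowed values, then numeric range** —
the first failing check is reported for a single value, while form-level
validation (:func:`validate_form`) collects every error in one pass so the
operator can fix the whole form at once.

Auto-calculated ("derived") attributes are never typed by the operator; they
are evaluated from sibling values with a deliberately minimal arithmetic
language: ``+ - * /``, parentheses, numeric literals and sibling names.
"""

from __future__ import annotations

import ast
import datetime as dt
import hashlib
import os
import re
from dataclasses import dataclass
from enum import Enum
from typing import Mapping, Union

from .workflow_model import (
    ActivitySpec,
    AttributeSpec,
    Datatype,
    NUMERIC_TYPES,
)

__all__ = [
    "ValidationCode",
    "ValidationError",
    "FileRef",
    "FormResult",
    "validate_value",
    "validate_form",
    "validate_attributes",
    "evaluate_derived",
    "expression_names",
    "parse_raw",
    "render_raw",
    "ABSENT",
]

DEFAULT_DATE_FORMAT = "%Y-%m-%d"

#: Sentinel for "optional attribute left empty" (distinct from any typed value).
ABSENT = None


class ValidationCode(str, Enum):
    REQUIRED_MISSING = "REQUIRED_MISSING"
    TYPE_MISMATCH = "TYPE_MISMATCH"
    FORMAT_MISMATCH = "FORMAT_MISMATCH"
    NOT_IN_ALLOWED = "NOT_IN_ALLOWED"
    OUT_OF_RANGE = "OUT_OF_RANGE"
    DERIVATION_FAILED = "DERIVATION_FAILED"
    UNKNOWN_ATTRIBUTE = "UNKNOWN_ATTRIBUTE"
    DERIVED_INPUT = "DERIVED_INPUT"


@dataclass(frozen=True)
class ValidationError:
    """One rejected value; ``code`` identifies the violated spec field."""

    attribute: str
    code: ValidationCode
    message: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.attribute}: {self.code.value} ({self.message})"


@dataclass(frozen=True)
class FileRef:
    """A file-typed value: identity of the file, not its bytes.

    When the referenced path exists on disk at attachment time the SHA-256 of
    its *content* is recorded (``content_hashed=True``); otherwise the
    reference is identified by a SHA-256 of the path text itself, so that
    detached references (URIs, files on an instrument workstation) are still
    stable, auditable values.
    """

    path: str
    size: int | None
    sha256: str
    content_hashed: bool

    @classmethod
    def attach(cls, path: str) -> "FileRef":
        if os.path.isfile(path):
            h = hashlib.sha256()
            with open(path, "rb") as fh:
                for chunk in iter(lambda: fh.read(1 << 16), b""):
                    h.update(chunk)
            return cls(path=path, size=os.path.getsize(path), sha256=h.hexdigest(), content_hashed=True)
        return cls(
            path=path,
            size=None,
            sha256=hashlib.sha256(path.encode("utf-8")).hexdigest(),
            content_hashed=False,
        )


TypedValue = Union[str, int, float, dt.date, FileRef]

_INT_RE = re.compile(r"^[+-]?\d+$")
_REAL_RE = re.compile(r"^[+-]?(\d+(\.\d*)?|\.\d+)([eE][+-]?\d+)?$")


def parse_raw(
    datatype: Datatype, raw: str, date_format: str | None = None
) -> tuple[TypedValue | None, ValidationCode | None]:
    """Parse a raw string under a datatype; returns ``(typed, None)`` or
    ``(None, failure_code)``.

    Reals use a decimal point only (machine-oriented payloads, no locale
    handling).  Dates parse under ``date_format`` when given, else ISO-8601;
    failure against an explicit pattern is a :data:`FORMAT_MISMATCH`, failure
    against the default a :data:`TYPE_MISMATCH`.
    """
    datatype = Datatype(datatype)
    if datatype is Datatype.STRING:
        return raw, None
    if datatype is Datatype.INTEGER:
        if _INT_RE.match(raw):
            return int(raw), None
        return None, ValidationCode.TYPE_MISMATCH
    if datatype is Datatype.REAL:
        if _REAL_RE.match(raw):
            return float(raw), None
        return None, ValidationCode.TYPE_MISMATCH
    if datatype is Datatype.DATE:
        fmt = date_format or DEFAULT_DATE_FORMAT
        try:
            return dt.datetime.strptime(raw, fmt).date(), None
        except ValueError:
            return None, (
                ValidationCode.FORMAT_MISMATCH if date_format else ValidationCode.TYPE_MISMATCH
            )
    if datatype is Datatype.FILE:
        return FileRef.attach(raw), None
    raise AssertionError(f"unhandled datatype {datatype}")  # pragma: no cover


def render_raw(spec: AttributeSpec, typed: TypedValue) -> str:
    """Render a typed value back to the raw string form the spec accepts."""
    if spec.datatype is Datatype.DATE:
        return typed.strftime(spec.format or DEFAULT_DATE_FORMAT)
    if spec.datatype is Datatype.FILE:
        return typed.path
    if spec.datatype is Datatype.REAL:
        return repr(float(typed))
    return str(typed)


def validate_value(
    spec: AttributeSpec, raw: str | None
) -> TypedValue | None | ValidationError:
    """Validate one raw entry against one attribute spec.

    Returns the typed value, ``None`` for an optional attribute left empty,
    or a :class:`ValidationError`.  Checks run in the documented order
    (type, format, allowed values, range); the first failure is returned.
    """
    if raw is None or raw == "":
        if spec.required:
            return ValidationError(
                spec.name, ValidationCode.REQUIRED_MISSING, "value must always be filled"
            )
        return ABSENT

    typed, code = parse_raw(spec.datatype, raw, spec.format)
    if code is not None:
        return ValidationError(
            spec.name, code, f"{raw!r} is not a valid {spec.datatype.value}"
        )

    if spec.format is not None and spec.datatype is Datatype.STRING:
        if not re.fullmatch(spec.format, typed):
            return ValidationError(
                spec.name,
                ValidationCode.FORMAT_MISMATCH,
                f"{raw!r} does not match pattern {spec.format!r}",
            )

    if spec.allowed_values is not None:
        allowed_typed = [parse_raw(spec.datatype, lit, spec.format)[0] for lit in spec.allowed_values]
        if typed not in allowed_typed:
            return ValidationError(
                spec.name,
                ValidationCode.NOT_IN_ALLOWED,
                f"{raw!r} is not one of {list(spec.allowed_values)}",
            )

    if spec.numeric_range is not None and spec.datatype in NUMERIC_TYPES:
        lo, hi = spec.numeric_range
        if (lo is not None and typed < lo) or (hi is not None and typed > hi):
            return ValidationError(
                spec.name,
                ValidationCode.OUT_OF_RANGE,
                f"{typed} outside [{lo if lo is not None else '-inf'}, "
                f"{hi if hi is not None else 'inf'}]",
            )

    return typed


# ---------------------------------------------------------------------------
# Derivation expressions
# ---------------------------------------------------------------------------

_ALLOWED_BINOPS = (ast.Add, ast.Sub, ast.Mult, ast.Div)


def _parse_expression(expr: str) -> ast.expr:
    try:
        tree = ast.parse(expr, mode="eval")
    except SyntaxError as exc:
        raise ValueError(f"syntax error: {exc.msg}") from None
    for node in ast.walk(tree):
        if isinstance(node, (ast.Expression, ast.Name, ast.Load)):
            continue
        if isinstance(node, ast.Constant) and isinstance(node.value, (int, float)):
            continue
        if isinstance(node, ast.BinOp) and isinstance(node.op, _ALLOWED_BINOPS):
            continue
        if isinstance(node, ast.UnaryOp) and isinstance(node.op, (ast.USub, ast.UAdd)):
            continue
        if isinstance(node, (ast.Add, ast.Sub, ast.Mult, ast.Div, ast.USub, ast.UAdd)):
            continue
        raise ValueError(f"disallowed construct {type(node).__name__!r}")
    return tree.body


def expression_names(expr: str) -> set[str]:
    """Attribute names referenced by a derivation expression.

    Raises ``ValueError`` if the expression uses anything beyond the four
    arithmetic operators, parentheses, numbers and names.
    """
    body = _parse_expression(expr)
    return {n.id for n in ast.walk(body) if isinstance(n, ast.Name)}


def evaluate_derived(
    expr: str, values: Mapping[str, float], attribute: str = "<derived>"
) -> float | ValidationError:
    """Evaluate an auto-calculation over sibling numeric values.

    Standard precedence applies; division by zero or a missing referenced
    value yields a ``DERIVATION_FAILED`` error rather than an exception.
    """
    try:
        body = _parse_expression(expr)
    except ValueError as exc:
        return ValidationError(attribute, ValidationCode.DERIVATION_FAILED, str(exc))

    def ev(node: ast.expr) -> float:
        if isinstance(node, ast.Constant):
            return float(node.value)
        if isinstance(node, ast.Name):
            if node.id not in values or values[node.id] is None:
                raise KeyError(node.id)
            return float(values[node.id])
        if isinstance(node, ast.UnaryOp):
            v = ev(node.operand)
            return -v if isinstance(node.op, ast.USub) else v
        if isinstance(node, ast.BinOp):
            left, right = ev(node.left), ev(node.right)
            if isinstance(node.op, ast.Add):
                return left + right
            if isinstance(node.op, ast.Sub):
                return left - right
            if isinstance(node.op, ast.Mult):
                return left * right
            if right == 0.0:
                raise ZeroDivisionError
            return left / right
        raise AssertionError  # pragma: no cover

    try:
        return ev(body)
    except ZeroDivisionError:
        return ValidationError(attribute, ValidationCode.DERIVATION_FAILED, "division by zero")
    except KeyError as exc:
        return ValidationError(
            attribute,
            ValidationCode.DERIVATION_FAILED,
            f"referenced value {exc.args[0]!r} is missing",
        )


# ---------------------------------------------------------------------------
# Whole-form validation
# ---------------------------------------------------------------------------


@dataclass
class FormResult:
    """Outcome of validating a whole entry form in one pass."""

    values: dict[str, TypedValue]
    errors: list[ValidationError]

    @property
    def ok(self) -> bool:
        return not self.errors


def validate_attributes(
    specs: tuple[AttributeSpec, ...], entries: Mapping[str, str]
) -> FormResult:
    """Validate a map of raw entries against an ordered attribute schema.

    All errors are collected and reported together.  Derived attributes are
    computed only after every operator-entered attribute validates; an entry
    supplied for a derived attribute is itself an error (its value is
    computed, never typed).
    """
    by_name = {s.name: s for s in specs}
    errors: list[ValidationError] = []
    values: dict[str, TypedValue] = {}

    for name in entries:
        if name not in by_name:
            errors.append(
                ValidationError(name, ValidationCode.UNKNOWN_ATTRIBUTE, "not declared on this form")
            )
        elif by_name[name].derivation is not None and entries[name] not in ("", None):
            errors.append(
                ValidationError(
                    name, ValidationCode.DERIVED_INPUT, "auto-calculated; value cannot be entered"
                )
            )

    for spec in specs:
        if spec.derivation is not None:
            continue
        outcome = validate_value(spec, entries.get(spec.name))
        if isinstance(outcome, ValidationError):
            errors.append(outcome)
        elif outcome is not ABSENT:
            values[spec.name] = outcome

    if errors:
        return FormResult({}, errors)

    # Evaluate derivations, allowing chains (a derived attribute referencing
    # another derived sibling); unresolved after a full sweep means a cycle.
    pending = [s for s in specs if s.derivation is not None]
    numeric_env: dict[str, float] = {
        k: float(v) for k, v in values.items() if isinstance(v, (int, float))
    }
    while pending:
        progressed = False
        for spec in list(pending):
            refs = expression_names(spec.derivation)
            if refs <= set(numeric_env):
                result = evaluate_derived(spec.derivation, numeric_env, spec.name)
                if isinstance(result, ValidationError):
                    errors.append(result)
                else:
                    if spec.datatype is Datatype.INTEGER:
                        result = int(result)
                    values[spec.name] = result
                    numeric_env[spec.name] = float(result)
                pending.remove(spec)
                progressed = True
        if not progressed:
            for spec in pending:
                missing = sorted(expression_names(spec.derivation) - set(numeric_env))
                errors.append(
                    ValidationError(
                        spec.name,
                        ValidationCode.DERIVATION_FAILED,
                        f"unresolvable references {missing}",
                    )
                )
            break

    if errors:
        return FormResult({}, errors)
    return FormResult(values, [])


def validate_form(activity: ActivitySpec, entries: Mapping[str, str]) -> FormResult:
    """Validate an activity's entry form against its attribute schema."""
    return validate_attributes(activity.attributes, entries)
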