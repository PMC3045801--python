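"""Typed value validation, auto-calculation, and whole-form checking."""

import datetime as dt
import hashlib
import random

import pytest
from hypothesis import given, settings, strategies as st

from labflow.value_validation import (
    ABSENT,
    FileRef,
    ValidationCode,
    ValidationError,
    evaluate_derived,
    parse_raw,
    render_raw,
    validate_attributes,
    validate_form,
    validate_value,
)
from labflow.workflow_model import ActivitySpec, AttributeSpec, Datatype


def spec(datatype=Datatype.STRING, **kw):
    return AttributeSpec(kw.pop("name", "x"), datatype, **kw)


class TestValidateValue:
    @pytest.mark.parametrize(
        "s, raw, expected",
        [
            (spec(Datatype.REAL, name="RNA total concentration"), "250.5", 250.5),
            (spec(Datatype.REAL), "1e3", 1000.0),
            (spec(Datatype.INTEGER), "42", 42),
            (spec(Datatype.INTEGER), "-7", -7),
            (spec(Datatype.STRING), "hello", "hello"),
            (spec(Datatype.DATE), "2026-03-01", dt.date(2026, 3, 1)),
            (spec(Datatype.DATE, format="%d/%m/%Y"), "01/03/2026", dt.date(2026, 3, 1)),
            (spec(Datatype.STRING, format=r"SL-\d{4}"), "SL-0042", "SL-0042"),
            (spec(Datatype.STRING, allowed_values=("Cy3", "Cy5")), "Cy5", "Cy5"),
            (spec(Datatype.INTEGER, numeric_range=(1, 50)), "50", 50),
        ],
    )
    def test_accepts(self, s, raw, expected):
        assert validate_value(s, raw) == expected

    @pytest.mark.parametrize(
        "s, raw, code",
        [
            (spec(Datatype.INTEGER), "abc", ValidationCode.TYPE_MISMATCH),
            (spec(Datatype.INTEGER), "4.2", ValidationCode.TYPE_MISMATCH),
            (spec(Datatype.REAL), "12,5", ValidationCode.TYPE_MISMATCH),  # no locale commas
            (spec(Datatype.DATE), "not-a-date", ValidationCode.TYPE_MISMATCH),
            (spec(Datatype.DATE, format="%d/%m/%Y"), "2026-03-01", ValidationCode.FORMAT_MISMATCH),
            (spec(Datatype.STRING, format=r"SL-\d{4}"), "SL-42", ValidationCode.FORMAT_MISMATCH),
            (
                spec(Datatype.STRING, allowed_values=("Cy3", "Cy5")),
                "Cy4",
                ValidationCode.NOT_IN_ALLOWED,
            ),
            (spec(Datatype.INTEGER, numeric_range=(1, 50)), "51", ValidationCode.OUT_OF_RANGE),
            (spec(Datatype.REAL, numeric_range=(0, None)), "-0.1", ValidationCode.OUT_OF_RANGE),
        ],
    )
    def test_rejects(self, s, raw, code):
        outcome = validate_value(s, raw)
        assert isinstance(outcome, ValidationError)
        assert outcome.code is code

    def test_required_missing_and_optional_absent(self):
        required = spec(Datatype.REAL, required=True)
        outcome = validate_value(required, "")
        assert isinstance(outcome, ValidationError)
        assert outcome.code is ValidationCode.REQUIRED_MISSING
        assert validate_value(spec(Datatype.REAL), "") is ABSENT

    def test_file_attachment_hashes_content(self, tmp_path):
        f = tmp_path / "gel.png"
        f.write_bytes(b"pretend image bytes")
        ref = validate_value(spec(Datatype.FILE), str(f))
        assert isinstance(ref, FileRef)
        assert ref.content_hashed and ref.size == 19
        assert ref.sha256 == hashlib.sha256(b"pretend image bytes").hexdigest()

    def test_detached_file_reference_is_stable(self):
        a = validate_value(spec(Datatype.FILE), "instrument://scanner/run42.tif")
        b = validate_value(spec(Datatype.FILE), "instrument://scanner/run42.tif")
        assert a == b and not a.content_hashed


class TestEvaluateDerived:
    @pytest.mark.parametrize(
        "expr, values, expected",
        [
            ("mass / volume", {"mass": 10.0, "volume": 4.0}, 2.5),
            ("a + b * c", {"a": 1, "b": 2, "c": 3}, 7.0),
            ("(a + b) * c", {"a": 1, "b": 2, "c": 3}, 9.0),
            ("-a + 2", {"a": 5}, -3.0),
        ],
    )
    def test_arithmetic(self, expr, values, expected):
        assert evaluate_derived(expr, values) == expected

    @pytest.mark.parametrize(
        "expr, values",
        [
            ("x / y", {"x": 1, "y": 0}),
            ("x + y", {"x": 1}),
            ("__import__('os').getcwd()", {}),
            ("x ** 2", {"x": 3}),
        ],
    )
    def test_failures_are_values_not_exceptions(self, expr, values):
        outcome = evaluate_derived(expr, values)
        assert isinstance(outcome, ValidationError)
        assert outcome.code is ValidationCode.DERIVATION_FAILED

    def test_agrees_with_independent_tree_interpreter(self):
        """Render random expression trees to text and compare evaluation
        against direct recursive evaluation of the tree itself."""
        rng = random.Random(1234)

        def make_tree(depth):
            if depth == 0 or rng.random() < 0.3:
                if rng.random() < 0.5:
                    return ("lit", round(rng.uniform(-10, 10), 3))
                return ("var", rng.choice("abcd"))
            op = rng.choice("+-*/")
            return (op, make_tree(depth - 1), make_tree(depth - 1))

        def render(node):
            if node[0] == "lit":
                v = node[1]
                return f"({v})" if v < 0 else str(v)
            if node[0] == "var":
                return node[1]
            return f"({render(node[1])} {node[0]} {render(node[2])})"

        def interpret(node, env):
            if node[0] == "lit":
                return float(node[1])
            if node[0] == "var":
                return float(env[node[1]])
            left, right = interpret(node[1], env), interpret(node[2], env)
            if node[0] == "+":
                return left + right
            if node[0] == "-":
                return left - right
            if node[0] == "*":
                return left * right
            if right == 0:
                raise ZeroDivisionError
            return left / right

        for _ in range(1000):
            tree = make_tree(3)
            env = {v: round(rng.uniform(-5, 5), 3) for v in "abcd"}
            try:
                expected = interpret(tree, env)
            except ZeroDivisionError:
                outcome = evaluate_derived(render(tree), env)
                assert isinstance(outcome, ValidationError)
                continue
            assert evaluate_derived(render(tree), env) == pytest.approx(expected, rel=1e-12)


RNA_OUTPUT_SPECS = None  # filled by fixture below


@pytest.fixture
def rna_output_attrs(microarray):
    (iospec,) = microarray.activities["RNAExtraction"].outputs
    return iospec.attributes


class TestValidateForm:
    def test_full_rna_extraction_output_form(self, rna_output_attrs):
        result = validate_attributes(
            rna_output_attrs,
            {
                "RNA total concentration": "250.5",
                "RNA final volume": "30",
                "Gel image": "files/S01_gel.png",
                "Dosage method": "Fluorometer",
            },
        )
        assert result.ok
        assert result.values["RNA total concentration"] == 250.5
        assert isinstance(result.values["Gel image"], FileRef)
        assert len(result.values) == 4

    def test_required_missing_reported(self, rna_output_attrs):
        result = validate_attributes(
            rna_output_attrs,
            {
                "RNA total concentration": "250.5",
                "RNA final volume": "",
                "Gel image": "files/S01_gel.png",
                "Dosage method": "Fluorometer",
            },
        )
        assert [(e.attribute, e.code) for e in result.errors] == [
            ("RNA final volume", ValidationCode.REQUIRED_MISSING)
        ]
        assert result.values == {}

    def test_all_errors_collected_in_one_pass(self, rna_output_attrs):
        result = validate_attributes(
            rna_output_attrs,
            {
                "RNA total concentration": "abc",
                "RNA final volume": "30",
                "Gel image": "files/x.png",
                "Dosage method": "Guesswork",
            },
        )
        assert {(e.attribute, e.code) for e in result.errors} == {
            ("RNA total concentration", ValidationCode.TYPE_MISMATCH),
            ("Dosage method", ValidationCode.NOT_IN_ALLOWED),
        }

    def test_unknown_entry_name(self):
        act = ActivitySpec(id="A", attributes=(spec(Datatype.STRING, name="known"),))
        result = validate_form(act, {"unknown": "v"})
        assert result.errors[0].code is ValidationCode.UNKNOWN_ATTRIBUTE

    def test_derived_computed_after_plain_pass(self, microarray):
        act = microarray.activities["Hybridization"]
        result = validate_form(act, {"hyb_hours": "16", "wash_hours": "1.5"})
        assert result.ok
        assert result.values["total_hours"] == 17.5

    def test_entry_for_derived_attribute_rejected(self, microarray):
        act = microarray.activities["Hybridization"]
        result = validate_form(
            act, {"hyb_hours": "16", "wash_hours": "1.5", "total_hours": "99"}
        )
        assert any(e.code is ValidationCode.DERIVED_INPUT for e in result.errors)

    def test_derivation_chain_and_cycle(self):
        chain_specs = (
            spec(Datatype.REAL, name="a", required=True),
            spec(Datatype.REAL, name="b", derivation="a * 2"),
            spec(Datatype.REAL, name="c", derivation="b + 1"),
        )
        result = validate_attributes(chain_specs, {"a": "3"})
        assert result.ok and result.values["c"] == 7.0

        cyclic = (
            spec(Datatype.REAL, name="p", derivation="q + 1"),
            spec(Datatype.REAL, name="q", derivation="p + 1"),
        )
        result = validate_attributes(cyclic, {})
        assert all(e.code is ValidationCode.DERIVATION_FAILED for e in result.errors)
        assert result.errors


class TestPersistenceSafety:
    def _random_spec(self, rng):
        datatype = rng.choice(list(Datatype))
        kw = {"required": rng.random() < 0.5}
        if datatype in (Datatype.INTEGER, Datatype.REAL) and rng.random() < 0.5:
            lo = rng.randint(-50, 50)
            kw["numeric_range"] = (lo, lo + rng.randint(0, 100))
        if datatype is Datatype.STRING and rng.random() < 0.3:
            kw["allowed_values"] = tuple(f"v{i}" for i in range(rng.randint(1, 4)))
        if datatype is Datatype.DATE and rng.random() < 0.3:
            kw["format"] = "%d/%m/%Y"
        return AttributeSpec("f", datatype, **kw)

    def test_validation_is_idempotent_under_fuzzing(self):
        """Any value accepted once re-validates to the same typed value when
        rendered back to raw form — no invalid value can be persisted."""
        rng = random.Random(555)
        raws = ["", "abc", "42", "-1", "4.2", "1e3", "2026-03-01", "31/12/2026",
                "v1", "v9", "0", "  ", "NaN", "inf", "1_000", "files/a.dat", "£µ"]
        checked = 0
        for _ in range(2000):
            s = self._random_spec(rng)
            raw = rng.choice(raws)
            outcome = validate_value(s, raw)
            if isinstance(outcome, ValidationError) or outcome is ABSENT:
                continue
            again = validate_value(s, render_raw(s, outcome))
            assert again == outcome
            checked += 1
        assert checked > 100  # the fuzz actually exercised acceptances

    @settings(derandomize=True, max_examples=200)
    @given(
        day=st.dates(min_value=dt.date(1900, 1, 1), max_value=dt.date(2099, 12, 31)),
        fmt=st.sampled_from(["%Y-%m-%d", "%d/%m/%Y", "%m-%d-%Y", "%Y%m%d"]),
    )
    def test_date_round_trip(self, day, fmt):
        s = AttributeSpec("d", Datatype.DATE, format=fmt)
        typed, code = parse_raw(Datatype.DATE, day.strftime(fmt), fmt)
        assert code is None and typed == day
        assert validate_value(s, render_raw(s, typed)) == day
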