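"""Model dialect parsers, the expression evaluator, and attribute changes."""

import math
import random

import pytest

from simex import model_io
from simex._errors import SimexError
from simex.expressions import BoolExpression, MathExpression
from simex.synthetic_models import decay_model, species_target

DECAY_SBML = model_io.write_sbml(decay_model())


class TestSbmlSubset:
    def test_decay_fixture_counts(self):
        model = model_io.parse_sbml_subset(DECAY_SBML)
        assert len(model.species) == 2
        assert len(model.parameters) == 1
        assert len(model.reactions) == 1
        assert model.species[0] == model_io.Species("S1", 10.0)

    def test_rate_expression_evaluates(self):
        model = model_io.parse_sbml_subset(DECAY_SBML)
        assert model.reactions[0].rate.evaluate({"k": 0.5, "S1": 10.0}) == 5.0

    def test_parse_is_pure(self):
        assert model_io.parse_sbml_subset(DECAY_SBML) == model_io.parse_sbml_subset(DECAY_SBML)

    def test_piecewise_math_rejected(self):
        bad = DECAY_SBML.replace(b"<ci>k</ci>", b"<piecewise/>")
        with pytest.raises(SimexError) as err:
            model_io.parse_sbml_subset(bad)
        assert err.value.code == "UNSUPPORTED_CONSTRUCT"

    def test_events_rejected(self):
        bad = DECAY_SBML.replace(b"<listOfSpecies>", b"<listOfEvents/><listOfSpecies>")
        with pytest.raises(SimexError) as err:
            model_io.parse_sbml_subset(bad)
        assert err.value.code == "UNSUPPORTED_CONSTRUCT"

    def test_broken_xml_is_a_syntax_error(self):
        with pytest.raises(SimexError) as err:
            model_io.parse_sbml_subset(DECAY_SBML[:-30])
        assert err.value.code == "MODEL_SYNTAX_ERROR"


class TestBoolnet:
    def test_two_node_model(self):
        model = model_io.parse_boolnet(b"targets, factors\nA, !B\nB, A\n")
        assert model.node_ids() == ["A", "B"]
        assert model.nodes[0].initial_state == 0

    def test_init_comment_sets_states(self):
        model = model_io.parse_boolnet(b"targets, factors\nA, A\n# init: A=1\n")
        assert model.nodes[0].initial_state == 1

    def test_undeclared_node_rejected(self):
        with pytest.raises(SimexError) as err:
            model_io.parse_boolnet(b"targets, factors\nA, C\n")
        assert err.value.code == "UNDECLARED_NODE"

    def test_missing_header_rejected(self):
        with pytest.raises(SimexError) as err:
            model_io.parse_boolnet(b"A, B\nB, A\n")
        assert err.value.code == "MODEL_SYNTAX_ERROR"

    def test_write_parse_round_trip(self):
        model = model_io.parse_boolnet(b"targets, factors\nA, !B & A\nB, A | B\n# init: A=1, B=0\n")
        again = model_io.parse_boolnet(model_io.write_boolnet(model))
        assert [(n.id, n.initial_state) for n in again.nodes] == [("A", 1), ("B", 0)]
        env = {"A": 1, "B": 0}
        for a, b in zip(model.nodes, again.nodes):
            assert a.update.evaluate(env) == b.update.evaluate(env)


class TestExpressionOracle:
    """Evaluator vs direct Python arithmetic on random expression trees."""

    def _random_expr(self, rng, depth):
        if depth == 0 or rng.random() < 0.3:
            if rng.random() < 0.5:
                return repr(round(rng.uniform(0.1, 5.0), 3))
            return rng.choice(["x", "y", "z"])
        op = rng.choice(["+", "-", "*", "/"])
        return f"({self._random_expr(rng, depth - 1)} {op} {self._random_expr(rng, depth - 1)})"

    def test_evaluator_matches_python_eval_on_100_random_trees(self):
        rng = random.Random(20240915)
        env = {"x": 1.7, "y": 0.4, "z": 2.9}
        for _ in range(100):
            text = self._random_expr(rng, 4)
            expr = MathExpression.parse(text)
            expected = eval(text, {}, dict(env))
            assert expr.evaluate(env) == pytest.approx(expected, rel=1e-12)
            assert expr.compile()(env) == pytest.approx(expected, rel=1e-12)

    def test_power_and_exp(self):
        expr = MathExpression.parse("exp(x) + y^2")
        assert expr.evaluate({"x": 1.0, "y": 3.0}) == pytest.approx(math.e + 9.0)

    def test_mathml_round_trip(self):
        expr = MathExpression.parse("k * S1 / (1 + S1^2) - exp(S1)")
        again = MathExpression.from_mathml(expr.to_mathml())
        env = {"k": 2.0, "S1": 0.7}
        assert again.evaluate(env) == pytest.approx(expr.evaluate(env), rel=1e-15)

    def test_boolean_parser_precedence(self):
        expr = BoolExpression.parse("!A & B | C")
        # parsed as ((!A) & B) | C
        assert expr.evaluate({"A": 0, "B": 1, "C": 0}) == 1
        assert expr.evaluate({"A": 1, "B": 1, "C": 0}) == 0
        assert expr.evaluate({"A": 1, "B": 0, "C": 1}) == 1


class TestApplyChanges:
    TARGET = species_target("S1") + "/@initialAmount"

    def test_change_matches_in_memory_edit(self):
        changed = model_io.apply_changes(
            DECAY_SBML, [model_io.AttributeChange(self.TARGET, "20")]
        )
        model = model_io.parse_sbml_subset(changed)
        assert model.species[0].initial_amount == 20.0
        # the rest of the model is untouched
        base = model_io.parse_sbml_subset(DECAY_SBML)
        assert model.parameters == base.parameters
        assert model.reactions == base.reactions

    def test_original_bytes_unchanged(self):
        before = bytes(DECAY_SBML)
        model_io.apply_changes(DECAY_SBML, [model_io.AttributeChange(self.TARGET, "20")])
        assert DECAY_SBML == before

    def test_last_change_wins(self):
        changed = model_io.apply_changes(
            DECAY_SBML,
            [
                model_io.AttributeChange(self.TARGET, "20"),
                model_io.AttributeChange(self.TARGET, "30"),
            ],
        )
        assert model_io.parse_sbml_subset(changed).species[0].initial_amount == 30.0

    def test_unmatched_target(self):
        with pytest.raises(SimexError) as err:
            model_io.apply_changes(
                DECAY_SBML,
                [model_io.AttributeChange(species_target("S9") + "/@initialAmount", "1")],
            )
        assert err.value.code == "TARGET_NOT_FOUND"

    def test_ambiguous_target(self):
        with pytest.raises(SimexError) as err:
            model_io.apply_changes(
                DECAY_SBML,
                [
                    model_io.AttributeChange(
                        "/sbml/model/listOfSpecies/species/@initialAmount", "1"
                    )
                ],
            )
        assert err.value.code == "TARGET_AMBIGUOUS"

    def test_target_without_attribute_step_rejected(self):
        with pytest.raises(SimexError) as err:
            model_io.apply_changes(
                DECAY_SBML, [model_io.AttributeChange(species_target("S1"), "1")]
            )
        assert err.value.code == "TARGET_UNSUPPORTED_SYNTAX"

    def test_namespace_prefixes_tolerated(self):
        target = "/sbml:sbml/sbml:model/sbml:listOfSpecies/sbml:species[@id='S1']/@initialAmount"
        changed = model_io.apply_changes(DECAY_SBML, [model_io.AttributeChange(target, "7")])
        assert model_io.parse_sbml_subset(changed).species[0].initial_amount == 7.0
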