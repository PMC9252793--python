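"""Model dialects: an SBML subset for reaction networks and a BoolNet-style
text dialect for Boolean networks, plus SED-ML attribute changes.

The SBML subset covers Level-3-shaped documents restricted to
``listOfSpecies`` / ``listOfParameters`` / ``listOfReactions`` with
mass-action-style kinetic laws in a restricted content-MathML vocabulary.
Constructs outside the subset (events, rules, function definitions,
``piecewise`` math) are rejected explicitly rather than silently ignored.

Attribute changes are applied *textually* to the model bytes — the changed
document is re-serialized XML, not an edited in-memory model — so a kernel
(or a foreign simulator under conformance test) always receives a plain
model file.  Change targets use a restricted XPath dialect: absolute child
paths with optional single ``[@attr='value']`` predicates, matched on local
names so namespace prefixes in the wild do not matter.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

from lxml import etree

from ._errors import SimexError
from .expressions import BoolExpression, MathExpression, iter_local

SBML_NS = "http://www.sbml.org/sbml/level3/version2/core"

_UNSUPPORTED_SBML_LISTS = (
    "listOfEvents",
    "listOfRules",
    "listOfFunctionDefinitions",
    "listOfConstraints",
    "listOfInitialAssignments",
)

_ID_RE = re.compile(r"^[A-Za-z_][A-Za-z0-9_]*$")


# ---------------------------------------------------------------------------
# Reaction network model


@dataclass(frozen=True)
class Species:
    id: str
    initial_amount: float


@dataclass(frozen=True)
class Parameter:
    id: str
    value: float


@dataclass(frozen=True)
class Reaction:
    id: str
    reactants: Tuple[Tuple[str, int], ...]
    products: Tuple[Tuple[str, int], ...]
    rate: MathExpression


@dataclass
class ReactionNetworkModel:
    species: List[Species] = field(default_factory=list)
    parameters: List[Parameter] = field(default_factory=list)
    reactions: List[Reaction] = field(default_factory=list)

    def species_ids(self) -> List[str]:
        return [s.id for s in self.species]

    def check(self) -> None:
        ids = [s.id for s in self.species] + [p.id for p in self.parameters] + [
            r.id for r in self.reactions
        ]
        if len(set(ids)) != len(ids):
            raise SimexError("MODEL_SYNTAX_ERROR", "duplicate ids in model")
        declared = {s.id for s in self.species} | {p.id for p in self.parameters}
        species = {s.id for s in self.species}
        for reaction in self.reactions:
            for sid, stoich in reaction.reactants + reaction.products:
                if sid not in species:
                    raise SimexError(
                        "MODEL_SYNTAX_ERROR", f"reaction {reaction.id} references unknown {sid!r}"
                    )
                if stoich < 1:
                    raise SimexError("MODEL_SYNTAX_ERROR", "stoichiometry must be positive")
            undeclared = reaction.rate.identifiers() - declared
            if undeclared:
                raise SimexError(
                    "MODEL_SYNTAX_ERROR",
                    f"rate of {reaction.id} references undeclared {sorted(undeclared)}",
                )


def parse_sbml_subset(content: bytes) -> ReactionNetworkModel:
    """Parse the restricted SBML dialect into a :class:`ReactionNetworkModel`."""
    try:
        root = etree.fromstring(content)
    except etree.XMLSyntaxError as exc:
        raise SimexError("MODEL_SYNTAX_ERROR", f"not valid XML: {exc}")
    if etree.QName(root).localname != "sbml":
        raise SimexError("MODEL_SYNTAX_ERROR", "root element is not sbml")
    models = list(iter_local(root, "model"))
    if len(models) != 1:
        raise SimexError("MODEL_SYNTAX_ERROR", "document must contain exactly one model")
    model_el = models[0]
    for bad in _UNSUPPORTED_SBML_LISTS:
        if list(iter_local(model_el, bad)):
            raise SimexError("UNSUPPORTED_CONSTRUCT", f"{bad} is outside the supported subset")

    model = ReactionNetworkModel()
    for lst in iter_local(model_el, "listOfSpecies"):
        for el in iter_local(lst, "species"):
            sid = el.get("id")
            amount = el.get("initialAmount")
            if sid is None or amount is None:
                raise SimexError("MODEL_SYNTAX_ERROR", "species needs id and initialAmount")
            try:
                value = float(amount)
            except ValueError:
                raise SimexError("MODEL_SYNTAX_ERROR", f"bad initialAmount {amount!r}")
            if value < 0:
                raise SimexError("MODEL_SYNTAX_ERROR", "initialAmount must be nonnegative")
            model.species.append(Species(sid, value))
    for lst in iter_local(model_el, "listOfParameters"):
        for el in iter_local(lst, "parameter"):
            pid = el.get("id")
            value = el.get("value")
            if pid is None or value is None:
                raise SimexError("MODEL_SYNTAX_ERROR", "parameter needs id and value")
            try:
                model.parameters.append(Parameter(pid, float(value)))
            except ValueError:
                raise SimexError("MODEL_SYNTAX_ERROR", f"bad parameter value {value!r}")
    for lst in iter_local(model_el, "listOfReactions"):
        for el in iter_local(lst, "reaction"):
            rid = el.get("id")
            if rid is None:
                raise SimexError("MODEL_SYNTAX_ERROR", "reaction needs an id")
            reactants = _parse_species_refs(el, "listOfReactants")
            products = _parse_species_refs(el, "listOfProducts")
            laws = list(iter_local(el, "kineticLaw"))
            if len(laws) != 1:
                raise SimexError("MODEL_SYNTAX_ERROR", f"reaction {rid} needs one kineticLaw")
            maths = list(iter_local(laws[0], "math"))
            if len(maths) != 1:
                raise SimexError("MODEL_SYNTAX_ERROR", f"kineticLaw of {rid} needs one math")
            rate = MathExpression.from_mathml(maths[0])
            model.reactions.append(Reaction(rid, reactants, products, rate))
    model.check()
    return model


def _parse_species_refs(reaction_el, list_name: str) -> Tuple[Tuple[str, int], ...]:
    refs: List[Tuple[str, int]] = []
    for lst in iter_local(reaction_el, list_name):
        for el in iter_local(lst, "speciesReference"):
            sid = el.get("species")
            if sid is None:
                raise SimexError("MODEL_SYNTAX_ERROR", "speciesReference needs species")
            stoich_text = el.get("stoichiometry", "1")
            try:
                stoich = float(stoich_text)
            except ValueError:
                raise SimexError("MODEL_SYNTAX_ERROR", f"bad stoichiometry {stoich_text!r}")
            if stoich != int(stoich) or stoich < 1:
                raise SimexError("MODEL_SYNTAX_ERROR", "stoichiometry must be a positive integer")
            refs.append((sid, int(stoich)))
    return tuple(refs)


def write_sbml(model: ReactionNetworkModel) -> bytes:
    """Serialize a reaction network back to the SBML subset (deterministic)."""
    model.check()
    root = etree.Element(
        f"{{{SBML_NS}}}sbml", nsmap={None: SBML_NS}, attrib={"level": "3", "version": "2"}
    )
    model_el = etree.SubElement(root, f"{{{SBML_NS}}}model", attrib={"id": "model"})
    if model.species:
        lst = etree.SubElement(model_el, f"{{{SBML_NS}}}listOfSpecies")
        for s in model.species:
            etree.SubElement(
                lst,
                f"{{{SBML_NS}}}species",
                attrib={"id": s.id, "initialAmount": repr(s.initial_amount)},
            )
    if model.parameters:
        lst = etree.SubElement(model_el, f"{{{SBML_NS}}}listOfParameters")
        for p in model.parameters:
            etree.SubElement(
                lst,
                f"{{{SBML_NS}}}parameter",
                attrib={"id": p.id, "value": repr(p.value), "constant": "true"},
            )
    if model.reactions:
        lst = etree.SubElement(model_el, f"{{{SBML_NS}}}listOfReactions")
        for r in model.reactions:
            rel = etree.SubElement(lst, f"{{{SBML_NS}}}reaction", attrib={"id": r.id})
            for list_name, refs in (("listOfReactants", r.reactants), ("listOfProducts", r.products)):
                if refs:
                    refs_el = etree.SubElement(rel, f"{{{SBML_NS}}}{list_name}")
                    for sid, stoich in refs:
                        etree.SubElement(
                            refs_el,
                            f"{{{SBML_NS}}}speciesReference",
                            attrib={"species": sid, "stoichiometry": str(stoich)},
                        )
            law = etree.SubElement(rel, f"{{{SBML_NS}}}kineticLaw")
            law.append(r.rate.to_mathml())
    return etree.tostring(root, xml_declaration=True, encoding="UTF-8", pretty_print=True)


# ---------------------------------------------------------------------------
# Boolean network model


@dataclass(frozen=True)
class BooleanNode:
    id: str
    initial_state: int
    update: BoolExpression


@dataclass
class BooleanNetworkModel:
    nodes: List[BooleanNode] = field(default_factory=list)

    def node_ids(self) -> List[str]:
        return [n.id for n in self.nodes]

    def check(self) -> None:
        ids = self.node_ids()
        if len(set(ids)) != len(ids):
            raise SimexError("MODEL_SYNTAX_ERROR", "duplicate node ids")
        declared = set(ids)
        for node in self.nodes:
            undeclared = node.update.identifiers() - declared
            if undeclared:
                raise SimexError(
                    "UNDECLARED_NODE",
                    f"update rule of {node.id} references undeclared {sorted(undeclared)}",
                )
            if node.initial_state not in (0, 1):
                raise SimexError("MODEL_SYNTAX_ERROR", "initial state must be 0 or 1")


def parse_boolnet(content: bytes) -> BooleanNetworkModel:
    """Parse the BoolNet-style text dialect.

    Layout: a ``targets, factors`` header then one ``node, expression`` line
    per node.  An optional comment line ``# init: A=1, B=0`` sets initial
    states; nodes default to 0.
    """
    try:
        text = content.decode("utf-8")
    except UnicodeDecodeError as exc:
        raise SimexError("MODEL_SYNTAX_ERROR", f"not UTF-8 text: {exc}")
    init: Dict[str, int] = {}
    rows: List[Tuple[str, str]] = []
    saw_header = False
    for raw in text.splitlines():
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line[1:].strip()
            if body.lower().startswith("init:"):
                for item in body[5:].split(","):
                    item = item.strip()
                    if not item:
                        continue
                    if "=" not in item:
                        raise SimexError("MODEL_SYNTAX_ERROR", f"bad init entry {item!r}")
                    name, _, value = item.partition("=")
                    if value.strip() not in ("0", "1"):
                        raise SimexError("MODEL_SYNTAX_ERROR", f"bad init value {value!r}")
                    init[name.strip()] = int(value.strip())
            continue
        if not saw_header:
            if [p.strip().lower() for p in line.split(",")] != ["targets", "factors"]:
                raise SimexError("MODEL_SYNTAX_ERROR", "missing 'targets, factors' header")
            saw_header = True
            continue
        if "," not in line:
            raise SimexError("MODEL_SYNTAX_ERROR", f"line without comma: {line!r}")
        name, _, expr = line.partition(",")
        rows.append((name.strip(), expr.strip()))
    if not saw_header:
        raise SimexError("MODEL_SYNTAX_ERROR", "missing 'targets, factors' header")
    model = BooleanNetworkModel()
    for name, expr_text in rows:
        if not _ID_RE.match(name):
            raise SimexError("MODEL_SYNTAX_ERROR", f"bad node id {name!r}")
        model.nodes.append(BooleanNode(name, init.get(name, 0), BoolExpression.parse(expr_text)))
    for name in init:
        if name not in {n.id for n in model.nodes}:
            raise SimexError("UNDECLARED_NODE", f"init references undeclared node {name!r}")
    model.check()
    return model


def write_boolnet(model: BooleanNetworkModel) -> bytes:
    model.check()
    lines = ["targets, factors"]
    lines += [f"{n.id}, {n.update.to_text()}" for n in model.nodes]
    inits = ", ".join(f"{n.id}={n.initial_state}" for n in model.nodes)
    lines.append(f"# init: {inits}")
    return ("\n".join(lines) + "\n").encode("utf-8")


# ---------------------------------------------------------------------------
# SED-ML attribute changes (restricted XPath)


@dataclass(frozen=True)
class AttributeChange:
    """Replace the attribute addressed by ``target`` with ``new_value``."""

    target: str
    new_value: str


_STEP_RE = re.compile(
    r"^(?:[A-Za-z_][\w.-]*:)?(?P<name>[A-Za-z_][\w.-]*)"
    r"(?:\[@(?:[A-Za-z_][\w.-]*:)?(?P<pattr>[A-Za-z_][\w.-]*)='(?P<pval>[^']*)'\])?$"
)


def _parse_target(target: str) -> Tuple[List[Tuple[str, Optional[Tuple[str, str]]]], Optional[str]]:
    """Split a restricted-XPath target into element steps and an optional
    trailing attribute name."""
    if not target.startswith("/"):
        raise SimexError("TARGET_UNSUPPORTED_SYNTAX", f"target must be absolute: {target!r}")
    parts = target[1:].split("/")
    attr: Optional[str] = None
    if parts and parts[-1].startswith("@"):
        raw = parts.pop()[1:]
        attr = raw.split(":")[-1]
        if not _ID_RE.match(attr.replace("-", "_").replace(".", "_")):
            raise SimexError("TARGET_UNSUPPORTED_SYNTAX", f"bad attribute step @{raw!r}")
    if not parts:
        raise SimexError("TARGET_UNSUPPORTED_SYNTAX", f"empty element path in {target!r}")
    steps: List[Tuple[str, Optional[Tuple[str, str]]]] = []
    for part in parts:
        m = _STEP_RE.match(part)
        if not m:
            raise SimexError("TARGET_UNSUPPORTED_SYNTAX", f"unsupported step {part!r}")
        predicate = (m.group("pattr"), m.group("pval")) if m.group("pattr") else None
        steps.append((m.group("name"), predicate))
    return steps, attr


def _step_matches(element, step) -> bool:
    name, predicate = step
    if not isinstance(element.tag, str) or etree.QName(element).localname != name:
        return False
    if predicate is not None:
        attr, value = predicate
        actual = element.get(attr)
        if actual is None:
            # tolerate prefixed attributes by local-name comparison
            for key, val in element.attrib.items():
                if key.rsplit("}", 1)[-1] == attr:
                    actual = val
                    break
        if actual != value:
            return False
    return True


def match_target(root, target: str) -> Tuple[list, Optional[str]]:
    """All elements matched by ``target`` plus the trailing attribute name."""
    steps, attr = _parse_target(target)
    if not _step_matches(root, steps[0]):
        return [], attr
    frontier = [root]
    for step in steps[1:]:
        frontier = [child for el in frontier for child in el if _step_matches(child, step)]
    return frontier, attr


def apply_changes(model_bytes: bytes, changes: Sequence[AttributeChange]) -> bytes:
    """Apply attribute changes in order, returning new XML bytes.

    Each target must address exactly one attribute node; zero matches raise
    ``TARGET_NOT_FOUND``, several raise ``TARGET_AMBIGUOUS``.
    """
    if not changes:
        return model_bytes
    try:
        root = etree.fromstring(model_bytes)
    except etree.XMLSyntaxError as exc:
        raise SimexError("MODEL_SYNTAX_ERROR", f"not valid XML: {exc}")
    for change in changes:
        matches, attr = match_target(root, change.target)
        if attr is None:
            raise SimexError(
                "TARGET_UNSUPPORTED_SYNTAX",
                f"change target must end in an attribute step: {change.target!r}",
            )
        if not matches:
            raise SimexError("TARGET_NOT_FOUND", f"no match for {change.target!r}")
        if len(matches) > 1:
            raise SimexError("TARGET_AMBIGUOUS", f"{len(matches)} matches for {change.target!r}")
        matches[0].set(attr, change.new_value)
    return etree.tostring(root, xml_declaration=True, encoding="UTF-8", pretty_print=True)


def count_element_matches(model_bytes: bytes, target: str) -> int:
    """How many *elements* a target addresses (attribute step optional)."""
    try:
        root = etree.fromstring(model_bytes)
    except etree.XMLSyntaxError as exc:
        raise SimexError("MODEL_SYNTAX_ERROR", f"not valid XML: {exc}")
    matches, _ = match_target(root, target)
    return len(matches)
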