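"""Mini algorithm ontology and the substitution machinery.

Simulation algorithms are identified by KiSAO terms.  A request for one
algorithm can often be served by a *similar* one — e.g. a tool that only
implements RK4 can still execute a time course that asks for CVODE, because
both integrate deterministic kinetics.  Similarity is graded on a 4-level
ordinal scale:

====== =====================================================
degree meaning
====== =====================================================
0      the same method
1      a variant of the same method (shared variant group)
2      a different method within the same modeling framework
9      frameworks differ — never substitutable
====== =====================================================

The ontology ships as a bundled JSON snapshot (:data:`DEFAULT_ONTOLOGY_PATH`)
covering the handful of public terms the reference kernels and tests need;
no network access is ever required.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Dict, FrozenSet, Iterable, List, Optional, Set, Tuple, Union

from ._errors import SimexError
from .sedml import is_valid_kisao_id, normalize_kisao_id

FRAMEWORKS = ("continuous-kinetic", "discrete-stochastic", "logical")

DEGREE_SAME = 0
DEGREE_VARIANT = 1
DEGREE_FRAMEWORK = 2
DEGREE_DISTINCT = 9


@dataclass(frozen=True)
class AlgorithmTerm:
    kisao_id: str
    name: str
    parent_ids: Tuple[str, ...] = ()
    kind: str = "algorithm"  # branch | algorithm | parameter
    framework: Optional[str] = None


@dataclass
class AlgorithmOntology:
    terms: Dict[str, AlgorithmTerm] = field(default_factory=dict)
    variant_groups: List[FrozenSet[str]] = field(default_factory=list)

    def term(self, kisao_id: str) -> AlgorithmTerm:
        kisao_id = normalize_kisao_id(kisao_id)
        if kisao_id not in self.terms:
            raise SimexError("UNKNOWN_TERM", f"{kisao_id!r} is not in the ontology")
        return self.terms[kisao_id]

    def framework(self, kisao_id: str) -> Optional[str]:
        return self.term(kisao_id).framework

    def algorithm_ids(self) -> List[str]:
        return sorted(t.kisao_id for t in self.terms.values() if t.kind == "algorithm")

    def check(self) -> None:
        for term in self.terms.values():
            for parent in term.parent_ids:
                if parent not in self.terms:
                    raise SimexError(
                        "ONTOLOGY_MALFORMED", f"{term.kisao_id} has unknown parent {parent}"
                    )
            if term.kind == "algorithm" and term.framework not in FRAMEWORKS:
                raise SimexError(
                    "ONTOLOGY_MALFORMED",
                    f"algorithm term {term.kisao_id} needs one framework, got {term.framework!r}",
                )
        # acyclicity of the parent graph
        WHITE, GRAY, BLACK = 0, 1, 2
        color = {tid: WHITE for tid in self.terms}

        def visit(tid: str, stack: List[str]) -> None:
            color[tid] = GRAY
            for parent in self.terms[tid].parent_ids:
                if color[parent] == GRAY:
                    raise SimexError("ONTOLOGY_MALFORMED", f"parent cycle at {parent}")
                if color[parent] == WHITE:
                    visit(parent, stack)
            color[tid] = BLACK

        for tid in self.terms:
            if color[tid] == WHITE:
                visit(tid, [])
        for group in self.variant_groups:
            frameworks = set()
            for tid in group:
                if tid not in self.terms:
                    raise SimexError("ONTOLOGY_MALFORMED", f"variant group lists unknown {tid}")
                frameworks.add(self.terms[tid].framework)
            if len(frameworks) != 1:
                raise SimexError(
                    "ONTOLOGY_MALFORMED", f"variant group {sorted(group)} spans frameworks"
                )


DEFAULT_ONTOLOGY_PATH = "data/kisao.json"


def load_ontology(source: Optional[bytes] = None) -> AlgorithmOntology:
    """Load an ontology from JSON bytes, or the bundled snapshot by default."""
    if source is None:
        source = resources.files("simex").joinpath(DEFAULT_ONTOLOGY_PATH).read_bytes()
    try:
        raw = json.loads(source)
    except json.JSONDecodeError as exc:
        raise SimexError("ONTOLOGY_MALFORMED", f"not valid JSON: {exc}")
    if not isinstance(raw, dict) or "terms" not in raw:
        raise SimexError("ONTOLOGY_MALFORMED", "snapshot must be an object with 'terms'")
    ontology = AlgorithmOntology()
    for entry in raw["terms"]:
        try:
            kisao_id = normalize_kisao_id(entry["id"])
            term = AlgorithmTerm(
                kisao_id=kisao_id,
                name=entry["name"],
                parent_ids=tuple(normalize_kisao_id(p) for p in entry.get("parents", [])),
                kind=entry.get("kind", "algorithm"),
                framework=entry.get("framework"),
            )
        except (KeyError, TypeError) as exc:
            raise SimexError("ONTOLOGY_MALFORMED", f"bad term entry: {exc}")
        if not is_valid_kisao_id(term.kisao_id):
            raise SimexError("ONTOLOGY_MALFORMED", f"bad id {term.kisao_id!r}")
        if term.kisao_id in ontology.terms:
            raise SimexError("ONTOLOGY_MALFORMED", f"duplicate term {term.kisao_id}")
        ontology.terms[term.kisao_id] = term
    for group in raw.get("variant_groups", []):
        ontology.variant_groups.append(frozenset(normalize_kisao_id(g) for g in group))
    ontology.check()
    return ontology


def substitution_degree(
    requested: str, candidate: str, ontology: AlgorithmOntology
) -> int:
    """Ordinal substitution degree between two algorithm terms (symmetric)."""
    a = ontology.term(requested)
    b = ontology.term(candidate)
    if a.kisao_id == b.kisao_id:
        return DEGREE_SAME
    for group in ontology.variant_groups:
        if a.kisao_id in group and b.kisao_id in group:
            return DEGREE_VARIANT
    if a.framework is not None and a.framework == b.framework:
        return DEGREE_FRAMEWORK
    return DEGREE_DISTINCT


def choose_algorithm(
    requested: str,
    implemented: Union[Set[str], Iterable[str]],
    policy_max_degree: int,
    ontology: AlgorithmOntology,
) -> Optional[Tuple[str, int]]:
    """Pick the closest implemented algorithm within the substitution policy.

    Returns ``(chosen id, degree)`` of minimal degree, ties broken by
    lexicographic id, or ``None`` if nothing qualifies.
    """
    requested = normalize_kisao_id(requested)
    ontology.term(requested)  # raises UNKNOWN_TERM early
    best: Optional[Tuple[int, str]] = None
    for candidate in sorted(normalize_kisao_id(c) for c in implemented):
        degree = substitution_degree(requested, candidate, ontology)
        if degree > policy_max_degree:
            continue
        if best is None or (degree, candidate) < best:
            best = (degree, candidate)
    if best is None:
        return None
    return best[1], best[0]
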