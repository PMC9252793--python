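# Methods

This note documents the models, conventions, numerical choices and design
decisions behind simex, and what the test suite does and does not
demonstrate.

## Simulation project model

A project is a COMBINE (OMEX) archive: a zip with a `manifest.xml` listing
every member's location, a format identifier URI, and at most one `master`
flag.  The master SED-ML entry (or, absent a master, every SED-ML entry) is
executable.  Format URIs are matched permissively — COMBINE-specification
and EDAM/mediatype spellings of SBML, SED-ML and the BoolNet dialect are
treated as the same family — because both vocabularies occur in archives in
the wild.  Archive writes are deterministic: entries sorted by location,
zip timestamps pinned to the 1980 epoch, so identical archives are
byte-identical files.  A missing `.` self-entry is inserted on write; more
than one master entry is rejected (the convention is silent here; we chose
the strict reading).

The SED-ML subset is the executable core of Level 1 Version 3: models with
`changeAttribute` changes, `uniformTimeCourse` and `steadyState`
simulations with KiSAO-typed algorithms, tasks, data generators over task
variables, reports and 2-D plots.  `repeatedTask`, functional ranges, 3-D
plots and external model repositories are out of scope; model sources must
resolve inside the archive or chain to another model's id.  Three
formalizations worth restating because they are classic interop failures:

* `numberOfPoints` counts intervals; **P+1** rows are recorded, spanning
  `[outputStartTime, outputEndTime]` uniformly.
* the only recognized symbol is `urn:sedml:symbol:time`.
* KiSAO ids are accepted as `KISAO:0000032` or `KISAO_0000032` and
  normalized to the colon form.

## Model dialects

**Reaction networks** are read from an SBML subset: Level-3-shaped
documents with `listOfSpecies` (id, initialAmount), `listOfParameters`,
and `listOfReactions` with integer-stoichiometry species references and a
kinetic law in restricted content MathML (`cn`, `ci`, plus, minus, times,
divide, power, exp).  Events, rules, function definitions and any MathML
node outside the subset are rejected explicitly (`UNSUPPORTED_CONSTRUCT`)
rather than ignored, so silent mis-simulation is impossible.  Compartments
and units carry no semantics here.

**Boolean networks** use a BoolNet-style text dialect: a
`targets, factors` header, one `node, expression` line per node over
`! & |` and parentheses, and an optional `# init: A=1, B=0` line (nodes
default to 0).

**Attribute changes** use a restricted XPath dialect — absolute child paths
with optional single `[@attr='value']` predicates, ending in an attribute
step — matched on local names so namespace prefixes do not matter.  A
change target must address exactly one attribute; zero or several matches
are distinct, stable error codes.  Changes are applied *textually* to the
model bytes and the changed document is re-parsed; this mirrors how an
engine hands a modified model file to an arbitrary kernel, and it makes
"apply changes then parse" testable against "parse then edit in memory".

Because the Boolean dialect is not XML, SED-ML variable targets for logical
models are bare node ids; the validator checks them against the declared
node list.

## Reference kernels

*Deterministic kinetics.*  dx_i/dt = Σ_r ν_ir · rate_r(x, p), integrated by
forward Euler or classic RK4 with a fixed internal step (default: the full
simulated interval divided by 10,000; KiSAO 0000483 overrides it).  Each
output interval is subdivided so grid points are hit exactly.  Rate
expressions are compiled once to Python callables, which keeps the
per-step cost flat.  The steady-state solver integrates (RK4, default step
0.1) until ‖dx/dt‖∞ < `abs_tol` (default 1e-8), and reports
`NO_CONVERGENCE` if t_max (default 1e4) is reached or the state diverges.

*Stochastic kinetics.*  The Gillespie direct method.  A rate law qualifies
as mass action when it is a product of constants/parameters and reactant
identifiers matching the reactant stoichiometry; the propensity is then
c · Π C(x_i, s_i) (distinct-combination counting).  Non-mass-action rates
fall back to direct expression evaluation with a recorded warning — a
documented relaxation that keeps saturating rate laws runnable.  Recording
uses zero-order hold: each grid time receives the state after the last
event at or before it.  One generator (Python's Mersenne Twister via
`random.Random`) drives the whole run, seeded from KiSAO 0000488 when the
experiment declares a seed and from 0 otherwise, so unseeded archives are
still reproducible — a deliberate deviation from "random by default"
tools, stated here because it changes what repeat runs mean.

*Logical models.*  Synchronous updates evaluate every rule against the
previous state; asynchronous updates pick one node uniformly per step from
the seeded generator.  A uniform time course over a logical model is
interpreted as `numberOfPoints` discrete update steps, with the recorded
rows mapped onto the declared SED-ML grid; start-time offsets have no
meaning for discrete updates and are ignored.

## Algorithm substitution

Similarity between algorithm terms is an ordinal degree: 0 same method,
1 same variant group, 2 same modeling framework, 9 distinct frameworks
(never substitutable).  The 4-level scale and the variant groups
(Gillespie direct with Gibson–Bruck; forward Euler with RK4) are this
package's formalization; the bundled snapshot of ~17 public KiSAO terms is
a synthetic fixture with ids and names from the public ontology and a
pruned branch structure.  The default policy admits substitution up to
degree 2, because an engine that refuses near-matches would reject most
archives written against other tools.

`choose_algorithm` returns a minimal-degree candidate with lexicographic
tie-breaking (deterministic, testable against brute force).  The engine
additionally re-picks among equal-degree implemented algorithms by a fixed
quality preference — RK4 before forward Euler — so a CVODE request runs on
the better integrator; this preference is the engine's own choice, layered
on top of the generic chooser without changing its contract.

Tool recommendation ranks each registered tool by its **worst-case** task
degree: a tool must execute every task of a project, so the weakest task
governs.  Ties break by tool id.  (Best-case ranking was the plausible
alternative; worst-case was chosen because a partial recommendation is not
actionable.)

## Validation

`validate_project` accumulates issues — it never short-circuits — so one
pass reports every defect: manifest structure, SED-ML schema and
cross-references, model parses, change and variable targets, time-course
ordering, KiSAO id patterns.  Variable targets are checked against the
model *after* its changes are applied, matching execution-time semantics.
The error-code catalogue (stable strings such as
`SEDML_TARGET_UNRESOLVED`) is this package's own; its coverage is
demonstrated by a 12-class seeded-defect catalogue in
`synthetic_models.inject_defect`, where each mutator corrupts a pristine
archive in exactly one way and names the code it must trigger.

## Outputs

Reports land in one HDF5 file: a 2-D dataset (data set × point) per report
at `<sedml location>/<report id>`, with `dataSetIds`, `dataSetLabels` and
`sedmlId` string attributes and a file-level `schema_version`.  The
execution log is YAML with statuses from
{QUEUED, RUNNING, SUCCEEDED, SKIPPED, FAILED}; a task fails independently
of its siblings, carries an `{category, message}` exception exactly when it
failed, and document/run statuses propagate upward.  Plots are PDF with
fixed figure size and pinned metadata, so the vector content is
deterministic across runs.

## Conformance testing

The suite grades any command given as a `{archive}`/`{outdir}` template.
Checks run in a fixed order and stop at the first failure — exit status,
report presence, dataset shape, log validity, reference values — so each
failure mode maps to exactly one code.  Deterministic kernels are compared
to closed-form references at relative tolerance 1e-3; stochastic cases
check shapes plus seeded determinism (two runs with the same declared seed
must agree bitwise) because foreign tools' random streams differ.  Six
sabotage stubs — deliberately broken simulators — serve as negative
controls: each must fail with exactly its designed code.  Archive
mutations (drop the master flag, rename a report, inject a seed parameter,
swap the algorithm for a degree-2 substitute, break a variable target,
reorder the manifest) probe individual conventions.

## Synthetic data

Random mass-action networks draw up to 8 species and 12 reactions; a
conversion chain S1 → … → Sn guarantees connectivity and that every
species participates, extra reactions draw ≤ 2 reactants/products
uniformly, rate constants are log-uniform on [0.01, 10], and initial
amounts are integers in [5, 30] so the same model serves both ODE and SSA
kernels.  Random Boolean networks draw up to 10 nodes with random 2-input
AND/OR rules, each input negated with probability 0.3.  All generators are
pure functions of their seed.

What the generators do *not* emulate: realistic network topology
(hubs, motifs, conservation structure), stiff rate-constant separations,
units and compartment volumes, or models large enough to stress memory.
Passing tests therefore demonstrate correctness of the conventions and the
kernels on well-posed desk-scale inputs, not numerical robustness on stiff
or large published models.

## Problem sizes

The shipped checks use: 2,000 seeded SSA replicates for the moment checks
(standard error ≈ 0.07 on the stationary mean, giving a 3σ band of ±0.21);
50 random Boolean networks enumerated over all 2^n states; 12 × 5 seeded
defect archives plus 20 pristine controls; 1,000 and 200 randomized
instances for the substitution and ranking oracles; and a 10-case fixture
corpus for round-trip, engine-equivalence and self-hosted conformance
runs.  These sizes keep a full run around a minute on one CPU while leaving
the statistical bands far from their thresholds.

## Known limitations

* The ODE kernels are explicit; stiff systems need steps far below the
  default to remain stable, and no implicit solver is provided.
* Mass-action detection is syntactic; an algebraically mass-action rate
  written in a non-product form falls back to direct evaluation.
* The KiSAO snapshot covers only the terms the kernels and tests need;
  real archives may reference terms outside it, which surface as
  `UNKNOWN_TERM`.
* Asynchronous Boolean simulation records one trajectory, not the state
  transition graph or its attractors.
* The SED-ML writer emits a single canonical form; foreign documents
  round-trip structurally, not byte-for-byte.
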