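# simex

**simex** is a self-contained toolkit for reproducible simulation
experiments in systems biology.  It validates and executes simulation
projects packaged as COMBINE (OMEX) archives — zip containers holding a
SED-ML experiment description plus the models it simulates — and writes the
standardized outputs the community conventions prescribe: an HDF5 file of
report matrices, a YAML execution log, and PDF plots.  It also recommends
simulation tools for a project via an algorithm-similarity ontology, and
conformance-tests any command-line simulator against the same conventions.

It is aimed at modelers who want to execute and exchange kinetic or logical
simulations without tool-specific plumbing, at repository curators who need
machine-readable validation of submitted projects, and at simulator
developers who want to check that their tool honors the standardized
command-line contract.

## What is inside

| surface | what it does |
|---|---|
| `simex.omex` | read/write COMBINE archives (deterministic, byte-reproducible writes) |
| `simex.sedml` | core SED-ML L1V3 subset: time courses, steady states, tasks, data generators, reports, 2-D plots |
| `simex.model_io` | an SBML subset for reaction networks, a BoolNet-style dialect for Boolean networks, XPath-subset attribute changes |
| `simex.kernels` | reference kernels: forward Euler / RK4 ODE integration, Gillespie direct SSA, synchronous/asynchronous Boolean updates |
| `simex.kisao` | bundled mini KiSAO snapshot and the algorithm-substitution machinery |
| `simex.validation` | integrated project validation with stable error codes; simulator-spec and log validation |
| `simex.registry` | simulator-capability records and tool recommendation |
| `simex.engine` | the orchestrator: archive → kernels → `reports.h5` + `log.yml` + `plots/` |
| `simex.conformance` | fixture corpus, CLI conformance runner, archive mutations, sabotage stubs |
| `simex.synthetic_models` | curated and random model/archive generators (fully seeded) |

## The science in one paragraph

A reaction network with stoichiometry ν and rate laws *r(x, p)* is
integrated deterministically as dx/dt = ν·r(x, p) (forward Euler or classic
RK4 on a fixed step), or stochastically by the Gillespie direct method:
with propensities *a_j(x)* the waiting time to the next event is
Exponential(Σa) and reaction *j* fires with probability *a_j/Σa*.  Boolean
networks update either all nodes at once (synchronous) or one uniformly
chosen node per step (asynchronous).  A SED-ML uniform time course with
`numberOfPoints = P` records **P+1** uniformly spaced points.  When an
experiment requests an algorithm the engine does not implement exactly, the
KiSAO ontology supplies the closest implemented substitute, graded
0 (same method) / 1 (same variant group) / 2 (same modeling framework) /
9 (never substitutable); the substitution is recorded in the execution log.

## Worked example

```bash
simex make-fixtures --seed 1 --out fixtures     # write the corpus as .omex files
simex validate fixtures/curated_ode-decay.omex  # prints: valid
simex execute -i fixtures/curated_ode-decay.omex -o out
# prints: status: SUCCEEDED
```

The decay fixture is the two-species network S1 → S2 with rate k·S1,
k = 0.5, S1(0) = 10, simulated with RK4 over t ∈ [0, 10] at 10 intervals.
`out/reports.h5` then contains one 3×11 dataset at `sim.sedml/report1` —
rows time, S1, S2 — whose S1 row ends at

```
>>> from simex.engine import read_reports_h5
>>> read_reports_h5("out/reports.h5")[0].values[1, -1]
0.06737946999085512
```

matching the closed form 10·e^(−0.5·10) = 0.0673794699908547 to 1e-13.
`out/log.yml` records the task status, the requested and used algorithm and
the substitution degree (0 here; request CVODE instead and the engine runs
RK4 at degree 2).

The same engine passes its own conformance suite:

```bash
simex test-simulator --spec src/simex/data/engine_spec.json \
    --command "python -m simex.cli execute -i {archive} -o {outdir}"
# prints: PASS=10 FAIL=0 SKIPPED=0
```

## Scope notes

No network access is ever needed: models and archives are generated or
bundled, and the KiSAO snapshot ships with the package.  Out of scope by
design: full SBML (events, rules, function definitions), `repeatedTask`
and nested SED-ML experiments, flux-balance analysis, containerized tool
execution, and OMEX metadata (RDF) validation.  See `docs/methods.md` for
the model assumptions, numerical choices and known limitations.
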