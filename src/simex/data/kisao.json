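{
  "schema_version": "1",
  "comment": "Synthetic snapshot of a small slice of the Kinetic Simulation Algorithm Ontology: enough algorithm and parameter terms to drive substitution decisions. Ids and names follow the public ontology; the branch structure is a pruned simplification.",
  "terms": [
    {"id": "KISAO:0000000", "name": "modelling and simulation algorithm", "parents": [], "kind": "branch"},
    {"id": "KISAO:0000433", "name": "CVODE-like method", "parents": ["KISAO:0000000"], "kind": "branch"},
    {"id": "KISAO:0000064", "name": "Runge-Kutta based method", "parents": ["KISAO:0000000"], "kind": "branch"},
    {"id": "KISAO:0000241", "name": "Gillespie-like method", "parents": ["KISAO:0000000"], "kind": "branch"},
    {"id": "KISAO:0000448", "name": "logical simulation method", "parents": ["KISAO:0000000"], "kind": "branch"},
    {"id": "KISAO:0000019", "name": "CVODE", "parents": ["KISAO:0000433"], "kind": "algorithm", "framework": "continuous-kinetic"},
    {"id": "KISAO:0000088", "name": "LSODA", "parents": ["KISAO:0000433"], "kind": "algorithm", "framework": "continuous-kinetic"},
    {"id": "KISAO:0000030", "name": "Euler forward method", "parents": ["KISAO:0000064"], "kind": "algorithm", "framework": "continuous-kinetic"},
    {"id": "KISAO:0000032", "name": "explicit fourth-order Runge-Kutta method", "parents": ["KISAO:0000064"], "kind": "algorithm", "framework": "continuous-kinetic"},
    {"id": "KISAO:0000029", "name": "Gillespie direct algorithm", "parents": ["KISAO:0000241"], "kind": "algorithm", "framework": "discrete-stochastic"},
    {"id": "KISAO:0000027", "name": "Gibson-Bruck next reaction algorithm", "parents": ["KISAO:0000241"], "kind": "algorithm", "framework": "discrete-stochastic"},
    {"id": "KISAO:0000449", "name": "synchronous logical simulation", "parents": ["KISAO:0000448"], "kind": "algorithm", "framework": "logical"},
    {"id": "KISAO:0000450", "name": "asynchronous logical simulation", "parents": ["KISAO:0000448"], "kind": "algorithm", "framework": "logical"},
    {"id": "KISAO:0000209", "name": "relative tolerance", "parents": ["KISAO:0000000"], "kind": "parameter"},
    {"id": "KISAO:0000211", "name": "absolute tolerance", "parents": ["KISAO:0000000"], "kind": "parameter"},
    {"id": "KISAO:0000483", "name": "step size", "parents": ["KISAO:0000000"], "kind": "parameter"},
    {"id": "KISAO:0000488", "name": "seed", "parents": ["KISAO:0000000"], "kind": "parameter"}
  ],
  "variant_groups": [
    ["KISAO:0000029", "KISAO:0000027"],
    ["KISAO:0000030", "KISAO:0000032"]
  ]
}
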