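# agentchem

Tool-calling agents for small-molecule computational chemistry — and a
deterministic harness to benchmark them.

Setting up even a routine thermochemistry calculation (name → structure →
optimization → frequencies → enthalpy at a temperature) takes expert
knowledge spread over several tools. `agentchem` wraps that workflow into
six agent-callable tools behind a ReAct-style tool-calling loop, so a
backend — an LLM client, or the packaged deterministic *scripted policy* —
can solve natural-language tasks like *"calculate the reaction enthalpy
for methane combustion at 400 K"* by chaining tool calls. For complex
reaction tasks a multi-agent graph (planner → sequential executors →
aggregator) decomposes the problem into one per-species subtask each run
in an isolated context, which keeps each agent's context small.

The package is entirely offline-testable: the scripted backend replays
the expert tool chain for each of 13 task patterns, structure generation
is seeded, and the bundled 360-instance benchmark scores any backend
against references computed directly from the chemistry pipeline.

## What's inside

- **Six tools**: `molecule_name_to_smiles` (offline fixture table, optional
  remote resolver), `smiles_to_atomsdata` (seeded ETKDG embedding + UFF
  pre-relaxation), `file_to_atomsdata` / `save_atomsdata_to_file` (XYZ),
  `run_simulation` (optimization, vibrational analysis, thermochemistry),
  and a safe arithmetic `calculator`.
- **Chemistry core**: BFGS geometry optimization to a max-force criterion,
  finite-difference Hessians with translation/rotation projection, and
  ideal-gas rigid-rotor harmonic-oscillator (RRHO) thermochemistry

      ZPE = Σᵢ hνᵢ/2
      H(T) = E_elec + ZPE + 3/2·kT + E_rot + Σᵢ hνᵢ/(e^{hνᵢ/kT}−1) + kT
      S(T,P) = S_trans + S_rot + S_vib + S_elec      G = H − T·S

  in eV / Å / K / Pa, with calculator adapters (RDKit UFF and MMFF94, a
  closed-form harmonic test potential, a seam for tight-binding engines).
- **Agent graph**: message state, tool registry with schemas, ReAct loop
  with error-message feedback and an iteration cap, dual output modes
  (free text or schema-validated structured answers).
- **Multi-agent graph**: planner / loop controller / executors /
  aggregator with enforced context isolation and minimal per-species
  summaries.
- **Benchmark harness**: 13 experiments × (30 or 15) instances = 360,
  template prompting, pipeline-built references, per-field-tolerance
  scoring, tool-call metrics, repeated-run statistics, JSON reports.

## Worked example

Reaction enthalpy of methane combustion at 400 K through the multi-agent
graph, with the scripted backend and the UFF force field:

```console
$ agentchem ask "Calculate the reaction enthalpy for the reaction \
methane + 2 oxygen -> carbon dioxide + 2 water at 400 K using the uff \
method." --mode multi --structured
The reaction enthalpy is 0.037096 eV.
[12 tool calls across 4 executors]
{"value": 0.037095758844128746, "unit": "eV"}
```

The planner split the reaction into four per-species subtasks; each
executor ran the expert three-call chain (name → SMILES, SMILES → 3D
structure, thermochemistry simulation), and the aggregator combined the
four absolute enthalpies with the stoichiometric coefficients
(+1·CO₂ + 2·H₂O − 1·CH₄ − 2·O₂). Twelve tool calls is exactly the
expert baseline for a four-species reaction. Note the value is a UFF
force-field number — useful for exercising the agent machinery, not a
prediction of the true combustion enthalpy (≈ −8.3 eV); plug in a
quantum-chemistry calculator adapter for physically meaningful reaction
energetics.

The same task through the single-agent loop, plus a one-call task:

```console
$ agentchem ask "What is the SMILES string of ethanol?" --structured
The SMILES string of ethanol is CCO.
[1 tool calls]
{"smiles": "CCO"}
```

Benchmark workflow:

```bash
agentchem bench generate --out suite.json          # 360 instances + references
agentchem bench run --suite suite.json --runs 3    # execute, score, report
agentchem bench report --report report.json        # summary table
```

With the scripted backend the report shows accuracy 1.000 on all 13
experiments and tool-call means of 1,2,3,3,3,4 (name tasks),
1,2,2,2,3 (SMILES tasks) and 9–12 (reactions) with zero spread — the
harness-integrity baseline any LLM backend is measured against.

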