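# Methods

This note documents the models, conventions and design choices behind
`agentchem`: the chemistry layer (structure generation, optimization,
vibrations, thermochemistry), the agent graph (single- and multi-agent),
and the benchmark harness. It states what the deterministic test setup
shows — and what it does not show — about behaviour on real LLM backends.

## Structure model and serialization

`AtomsData` carries exactly four fields: atomic numbers, Cartesian
coordinates (Å), a 3×3 cell matrix (Å, all-zero for molecules) and three
periodic-boundary flags. Charge and spin multiplicity are deliberately
*not* structure fields; they are calculator parameters, so the same
structure can be evaluated as e.g. a cation or a triplet without mutation.
The wire format is a flat JSON-compatible dict of the four fields and
round-trips exactly. XYZ text is written with fixed 8-decimal coordinates,
so serialized traces are byte-stable and XYZ round-trips are exact to
1e-8 Å. Element symbols are case-normalized on parsing ("CL" → Cl) because
machine-generated files frequently get capitalization wrong.

## Calculator adapters

A calculator maps a structure to (energy in eV, forces in eV/Å). Bundled
adapters:

- **`uff`** and **`mmff94`** — RDKit force fields, the default engines.
  Molecular topology is taken from a `topology_smiles` parameter when the
  caller knows it (the structure-generation tool always does, and atom
  order is preserved end to end); otherwise bonds are perceived from the
  3D geometry. The force-field object is built once per topology and then
  evaluated at explicit coordinates, so the potential is a smooth,
  deterministic function of the positions.
- **`harmonic-test`** — pairwise springs E = Σ ½k(r−r₀)², with closed-form
  minimum, frequency and RRHO limits; it anchors the validation suite.
- **`double-well-test`** — a quartic double well in one bond length whose
  barrier top has exactly one negative-curvature mode; used to test
  imaginary-frequency handling.
- **`gfn2-xtb`** — an adapter seam for the semi-empirical tight-binding
  engine. It raises a structured "engine not installed" error unless the
  `xtb` package is present, which the agent loop surfaces to the backend
  as recoverable feedback. New engines register through
  `register_calculator`.

A caution on units of meaning rather than units of measure: classical
force fields do not describe bond breaking, so *reaction* energies
computed with `uff` are not thermochemically predictive. The benchmark
uses them because references and answers are built from the same
pipeline — the harness measures agent behaviour, not force-field accuracy.
Swap in a quantum-chemistry adapter for physically meaningful reaction
enthalpies.

## Geometry optimization

Quasi-Newton minimization (scipy BFGS / L-BFGS-B / CG on the flattened
coordinates, analytic forces as the gradient). Convergence is the
structure-relaxation criterion: largest per-atom force norm ≤ `fmax`,
default 0.01 eV/Å. The scipy gradient tolerance is set to 5 % of `fmax`
so the per-atom criterion is implied at the solution; the residual is
re-measured with the calculator and non-convergence raises an error that
reports the residual. Passing a simulation-method name where an optimizer
is expected — a common agent mistake — produces an error message listing
the valid optimizers, which is exactly the feedback a backend needs to
self-correct.

## Vibrations

Central finite differences of the analytic forces with a 0.01 Å
displacement give the Cartesian Hessian (symmetrized). Two
diagonalizations of the mass-weighted Hessian are reported:

1. **raw** — all 3N modes; negative-curvature modes are stored as complex
   (imaginary) entries. This is the list a formatter must preserve
   tag-for-tag.
2. **projected** — rigid translations and infinitesimal rotations are
   projected out (Eckart frame), and the 3N−6 / 3N−5 / 0 internal modes
   (nonlinear / linear / monatomic) are taken as the physical spectrum.

Linearity is decided by the principal moments of inertia: smallest/largest
ratio < 1e-6 (and any diatomic) ⇒ linear. On a purely harmonic potential
the finite-difference Hessian is exact to round-off; on force fields the
projection leaves sub-cm⁻¹ numerical residue in the zero modes, which
motivates the noise floor below.

## Thermochemistry (ideal-gas RRHO)

With E_elec, physical wavenumbers ν̃ᵢ, shape, mass, inertia moments and
electronic degeneracy g:

- ZPE = Σ hνᵢ/2
- H(T) = E_elec + ZPE + 3/2·kT (trans) + E_rot + E_vib(T) + kT,
  with E_rot = 0 / kT / 3/2·kT for monatomic / linear / nonlinear and
  E_vib = Σ hνᵢ/(exp(hνᵢ/kT)−1)
- S = S_trans (Sackur–Tetrode at pressure P) + S_rot (rigid rotor)
  + S_vib (harmonic oscillator) + k·ln g
- G = H − T·S, constructed from that identity, so it holds to 1e-10 eV on
  every result by contract.

Conventions: σ (rotational symmetry number) = 1 for all species;
g defaults to 1/2 by electron-count parity (overridable via the
`multiplicity` calculator parameter); P defaults to 101 325 Pa; units are
eV, eV/K, K, Pa. Numerical choices: physical modes with |ν̃| < 1 cm⁻¹ are
treated as projection noise and excluded from the vibrational sums;
Bose factors with hν/kT > 500 underflow to zero analytically and are
skipped. Imaginary physical modes above the noise floor mean the geometry
is not a minimum — that raises an error rather than silently dropping the
mode, so a calling agent is told to re-optimize. The `thermochemistry`
driver of `run_simulation` composes optimize → vibrations → RRHO so one
tool call per species suffices; the three drivers are also exposed
individually and the composed path equals the individually composed one on
identical inputs.

The per-species quantity the executors report is the *absolute* RRHO
enthalpy (or Gibbs energy) of the species under the chosen method, not a
heat of formation referenced to the elements. Stoichiometric differences
of absolute values within one method equal the reaction property, which is
all the reaction tasks need; the distinction only matters if per-species
values are compared across methods.

## Structure generation

SMILES → 3D goes through RDKit: hydrogen completion, one ETKDGv3
conformer at a caller-supplied seed, then UFF pre-relaxation (≤500
iterations). With a fixed seed the coordinates are bitwise reproducible on
a platform, which is what makes direct coordinate comparison in the
benchmark valid. The embedding seed is the single source of randomness in
the whole system; it is threaded from the run configuration through the
tool context and logged in every trace header.

## Agent graph

The single-agent loop alternates backend decisions with tool execution:
a decision is either a non-empty batch of tool calls or final text, never
both. Tool failures become structured error payloads
(`{"error": true, "reason": ...}`) appended as tool messages — the loop
never aborts on a tool error, because error feedback is how backends
recover. The iteration cap (default 25, chosen to accommodate the
12-call reaction chains plus retries) terminates runaway backends with an
"exceeded" flag. Failed calls count toward the tool-call metric, matching
how retry-prone backends are measured.

Structured-output mode converts a terminated state into a per-task,
schema-validated answer record (pydantic). The scripted backend extracts
payloads rule-based from tool outputs; validation failures are recorded
as formatting errors and scored incorrect — values are never coerced.
The answer schemas are one flat record per experiment (SMILES string,
wire-format structure, tagged frequency list, value+unit, or path+
structure); they are this package's reconstruction, chosen as the minimal
fields that make scoring well-defined.

The scripted backend itself is a per-pattern state machine: it parses the
rendered prompt, replays the expert tool chain, fills each call's
arguments from the previous tool output, and finishes with deterministic
text. It is the offline stand-in for an LLM; API-backed backends plug into
the same decision contract but are not part of the test suite. System
prompts are versioned text assets with a general variant and room for
per-model variants; the scripted backend ignores them.

## Multi-agent graph

For reaction tasks the planner parses the reaction equation and emits one
self-contained sub-prompt per *distinct* species (a species on both sides
is planned once), carrying the method and temperature from the original
query. The loop controller runs executors sequentially — no concurrency
contract — each as a fresh backend instance over a fresh message context,
so executor contexts are provably isolated. Executor summaries are
restricted by contract to {species, property, value, unit}; coordinates
and frequency lists are structurally excluded (enforced at construction),
which operationalizes context minimization. The aggregator computes the
stoichiometric combination exactly via `reaction_delta`; one failed
subtask yields an aggregate failure record, not a fabricated value.
Fresh-session-per-executor is an inference, consistent with isolation, not
an externally fixed requirement.

Because executors and the direct pipeline share seeds and code paths, the
multi-agent reaction property equals the directly composed per-species
computation *exactly* (float-for-float, same summation order).

## Benchmark harness

Thirteen experiments: six name-input tasks (expert chains of 1–4 tool
calls), five SMILES-input tasks (1–3 calls), two reaction tasks (9 or 12
calls for 3 or 4 distinct species). Instance counts are 30 per
single-species experiment and 15 per reaction experiment — 360 total.
Prompts are rendered from one template per experiment; only the molecule
/ SMILES / reaction slot varies between siblings, with method (`uff`),
temperature (298.15 K for single-species Gibbs tasks, 400 K for
reactions) and file naming fixed.

Molecule selection is a fixed, deterministic list: the first N fixture
entries within the experiment's max-atom cutoff, never a random sample.
The packaged fixture holds 66 name→SMILES entries; cutoffs are 40 atoms
for structure-only tasks, 20 for optimization/vibration/file tasks, and
15 for thermochemistry tasks (Hessians cost 6N force evaluations each,
and references plus agent runs double that). The cutoffs are this
package's defaults. The 15 packaged reactions are balanced equations over
fixture species, 11 with three distinct species and 4 with four.

References are built by running the chemistry pipeline directly — no
agent, no backend — with the same seed the agents use; the expected tool
sequence is the scripted policy's declared chain. Scoring: SMILES compared
after canonicalization; structures atom-by-atom at 1e-3 Å (valid because
the shared seed makes structures deterministic — no superposition is
attempted); energies at 1e-3 eV; frequencies elementwise at 1 cm⁻¹ with
real/imaginary tags compared strictly (a real value where an imaginary
entry is expected is wrong). Reaction experiments are repeated over a
configurable number of independent runs with cross-run mean/std recorded;
runs are treated as independent trials regardless of backend determinism,
because API backends vary even at temperature zero.

Running the packaged suite with the scripted backend must score accuracy
1.0 on every experiment with tool-call means equal to the expert chain
lengths and zero spread. This is a *harness-integrity* check (references
and answers share the pipeline), not a claim about any LLM: with an API
backend the same harness measures real accuracy and tool-call inflation.
What the deterministic suite cannot show: prompt-robustness, recovery
behaviour of real models, or accuracy of the underlying force field.

Problem sizes and cost: the full 360-instance suite, references included,
completes in a few seconds on one CPU core (UFF on ≤20-atom molecules);
the acceptance script, which additionally runs the closed-form
thermochemistry checks and the multi-agent/pipeline comparison, stays
well under a minute.

## Known limitations

- No solvation, anharmonicity, hindered-rotor corrections, symmetry-number
  detection, or transition-state search; σ=1 biases S_rot for symmetric
  tops (irrelevant to reaction *differences* scored against references
  built with the same convention).
- Single conformer per SMILES; conformational ensembles are out of scope.
- The `gfn2-xtb` adapter is a seam; no tight-binding engine is bundled.
- XYZ is the only structure file format (plus wire JSON).
- Tool-argument validation checks names/required flags, not deep types.
- Multi-agent mode applies to reaction-shaped prompts; there is no
  dynamic re-planning or inter-executor communication.
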