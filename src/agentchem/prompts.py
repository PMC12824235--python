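"""Versioned system-prompt text assets.

A general-purpose prompt plus optional per-model variants; API backends pick
the variant matching their model name, and the scripted backend ignores
prompts entirely (its behaviour is fixed by the task pattern).
"""

from __future__ import annotations

PROMPT_VERSION = "1"

GENERAL = """\
You are a computational-chemistry assistant with access to a set of tools
for cheminformatics and molecular simulation.  Use the tools to answer the
user's request; never invent tool outputs.  Convert molecule names to SMILES
with molecule_name_to_smiles, build 3D structures with smiles_to_atomsdata,
and run geometry optimizations, vibrational analyses or thermochemistry with
run_simulation.  Energies are in eV, forces in eV/Å, frequencies in cm⁻¹.
If a tool call fails, read the error message and correct the arguments
rather than retrying identically.  Do not call tools that are not needed.
"""

#: per-model prompt variants keyed by a model-name substring
VARIANTS: dict[str, str] = {
    "general": GENERAL,
}


def system_prompt(model: str | None = None) -> str:
    """Return the prompt variant for ``model``, falling back to general."""
    if model:
        for key, text in VARIANTS.items():
            if key != "general" and key in model.lower():
                return text
    return VARIANTS["general"]
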