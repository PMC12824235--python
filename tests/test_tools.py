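"""The six tools: resolution, embedding, file I/O, dispatch, arithmetic."""

import numpy as np
import pytest

from agentchem.atoms import to_wire, write_xyz
from agentchem.calculators import CalculatorSpec
from agentchem.tools import (
    ReactionSpec,
    SimulationRequest,
    ToolError,
    evaluate_expression,
    file_to_atomsdata,
    molecule_name_to_smiles,
    parse_reaction,
    reaction_delta,
    run_simulation,
    save_atomsdata_to_file,
    smiles_to_atomsdata,
)

UFF_H2 = CalculatorSpec("uff", {"topology_smiles": "[H][H]"})


class TestNameResolution:
    @pytest.mark.parametrize(
        "name,smiles",
        [
            ("methane", "C"),
            ("carbon dioxide", "O=C=O"),
            ("Water", "O"),  # case-insensitive
            # a systematic substituted-urea name, pinned in the fixture table
            ("1-(2-methylphenyl)-3-(3-methylpyridin-2-yl)urea",
             "Cc1ccccc1NC(=O)Nc1ncccc1C"),
        ],
    )
    def test_fixture_lookup(self, name, smiles):
        assert molecule_name_to_smiles(name) == smiles

    def test_unresolvable_name_errors(self):
        with pytest.raises(ToolError, match="resolve"):
            molecule_name_to_smiles("unobtainium dihydride")

    def test_empty_name_errors(self):
        with pytest.raises(ToolError, match="non-empty"):
            molecule_name_to_smiles("  ")


class TestEmbedding:
    @pytest.mark.parametrize("smiles,n", [("C", 5), ("O", 3), ("[H][H]", 2)])
    def test_hydrogen_completed_atom_counts(self, smiles, n):
        assert len(smiles_to_atomsdata(smiles)) == n

    def test_h2_bond_length_physical(self):
        atoms = smiles_to_atomsdata("[H][H]")
        d = np.linalg.norm(atoms.positions[0] - atoms.positions[1])
        # window pinned from the embedding + UFF pre-relaxation pipeline
        assert 0.6 <= d <= 0.9

    def test_fixed_seed_is_reproducible(self):
        a = smiles_to_atomsdata("CCO", seed=7)
        b = smiles_to_atomsdata("CCO", seed=7)
        assert a == b

    def test_unparseable_smiles_errors(self):
        with pytest.raises(ToolError, match="not parseable"):
            smiles_to_atomsdata("not-a-smiles(((")


class TestFileTools:
    def test_round_trip_via_file(self, tmp_path, water):
        path = save_atomsdata_to_file(water, tmp_path / "w.xyz")
        back = file_to_atomsdata(path)
        assert list(back.atomic_numbers) == [8, 1, 1]
        assert np.abs(back.positions - water.positions).max() <= 1e-8

    def test_missing_file_names_path(self, tmp_path):
        with pytest.raises(ToolError, match="no_such"):
            file_to_atomsdata(tmp_path / "no_such.xyz")

    def test_directory_rejected(self, tmp_path):
        with pytest.raises(ToolError, match="directory"):
            file_to_atomsdata(tmp_path)

    def test_unsupported_format_lists_supported(self, tmp_path, water):
        with pytest.raises(ToolError, match="supported formats"):
            save_atomsdata_to_file(water, tmp_path / "w.cif", fmt="cif")

    def test_overwrite_replaces_content(self, tmp_path, water, h2):
        p = tmp_path / "s.xyz"
        save_atomsdata_to_file(water, p)
        save_atomsdata_to_file(h2, p)
        assert len(file_to_atomsdata(p)) == 2

    def test_relative_paths_resolve_against_workdir(self, tmp_path, water):
        save_atomsdata_to_file(water, "sub/w.xyz", workdir=tmp_path)
        assert (tmp_path / "sub" / "w.xyz").exists()


class TestRunSimulation:
    def test_optimize_dispatch(self, h2):
        out = run_simulation(h2, UFF_H2, SimulationRequest(driver="optimize"))
        assert out["driver"] == "optimize"
        assert out["fmax_ev_per_A"] <= 0.01

    def test_thermochemistry_composes_pipeline(self, h2):
        out = run_simulation(
            h2, UFF_H2, SimulationRequest(driver="thermochemistry", temperature=400.0)
        )
        assert out["gibbs_ev"] == pytest.approx(
            out["enthalpy_ev"] - 400.0 * out["entropy_ev_per_K"], abs=1e-10
        )

    def test_unknown_driver_lists_drivers(self, h2):
        with pytest.raises(ToolError, match="optimize, vibrations, thermochemistry"):
            SimulationRequest(driver="dynamics")

    def test_engine_failure_becomes_tool_error(self, h2):
        with pytest.raises(ToolError, match="no parameters"):
            run_simulation(
                h2,
                CalculatorSpec("mmff94", {"topology_smiles": "[H][H]"}),
                SimulationRequest(driver="optimize"),
            )


class TestArithmetic:
    @pytest.mark.parametrize(
        "expr,value",
        [("2*(3+4)", 14.0), ("-1.5 + 2.25", 0.75), ("1/4", 0.25), ("-(2-5)", 3.0)],
    )
    def test_basic_arithmetic(self, expr, value):
        assert evaluate_expression(expr) == pytest.approx(value)

    @pytest.mark.parametrize("expr", ["import x", "__import__('os')", "2**8", "x+1"])
    def test_non_arithmetic_rejected(self, expr):
        with pytest.raises(ToolError):
            evaluate_expression(expr)


class TestReactions:
    def test_combustion_delta(self):
        rxn = parse_reaction("methane + 2 oxygen -> carbon dioxide + 2 water")
        values = {"methane": -10.0, "oxygen": -5.0, "carbon dioxide": -20.0,
                  "water": -15.0}
        assert reaction_delta(values, rxn) == pytest.approx(-30.0)

    def test_reversal_negates(self):
        rxn = parse_reaction("2 hydrogen + oxygen -> 2 water")
        values = {"hydrogen": -1.0, "oxygen": -2.0, "water": -7.0}
        assert reaction_delta(values, rxn.reversed()) == pytest.approx(
            -reaction_delta(values, rxn)
        )

    def test_identity_reaction_is_zero(self):
        rxn = ReactionSpec([("A", -1.0), ("A", 1.0)])
        assert reaction_delta({"A": 3.14}, rxn) == 0.0

    def test_missing_species_named(self):
        rxn = parse_reaction("A + B -> C")
        with pytest.raises(ToolError, match="'C'"):
            reaction_delta({"A": 1.0, "B": 2.0}, rxn)

    def test_one_sided_reaction_rejected(self):
        with pytest.raises(ToolError, match="reactant"):
            ReactionSpec([("A", 1.0), ("B", 2.0)])

    def test_linear_in_coefficients(self):
        values = {"A": -3.0, "B": 5.0}
        r1 = ReactionSpec([("A", -1.0), ("B", 1.0)])
        r2 = ReactionSpec([("A", -2.0), ("B", 2.0)])
        assert reaction_delta(values, r2) == pytest.approx(
            2 * reaction_delta(values, r1)
        )
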