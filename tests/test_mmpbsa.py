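"""Gas-phase sums, apolar model, ledger arithmetic and SITA/SETA assembly."""

import numpy as np
import pandas as pd
import pytest

from enmpbsa.mmpbsa import (
    ApolarModel,
    BondedTerms,
    EnergyComponents,
    FFParams,
    PolarInputSpec,
    StoichStep,
    aggregate_stats,
    apolar_solvation,
    binding_energy,
    coulomb_energy,
    interaction_energy,
    internal_energy,
    ledger_from_deltas,
    lj_energy,
    read_energy_table,
    seta_ledger,
    sita_ledger,
    snapshot_free_energy,
    species_component_table,
    total_electrostatics,
)
from enmpbsa.structures import Atom, Residue, Structure
from enmpbsa.synthetic import make_energy_table
from enmpbsa.trajectory import Trajectory


def _charged_pair(d=1.0, q1=1.0, q2=1.0):
    s = Structure(
        residues=[
            Residue("ALA", 1, "A", atoms=[Atom("CA", "C", [0, 0, 0])]),
            Residue("ALA", 1, "B", atoms=[Atom("CA", "C", [d, 0, 0])]),
        ]
    )
    ff = FFParams(
        charges={("A", 1, "CA"): q1, ("B", 1, "CA"): q2},
        lj={("A", 1, "CA"): (0.3, 0.5), ("B", 1, "CA"): (0.3, 0.5)},
    )
    return s, ff


class TestCoulomb:
    def test_unit_charges_at_one_nm(self):
        s, ff = _charged_pair()
        assert coulomb_energy(s, ff) == pytest.approx(138.935, abs=1e-3)

    def test_chargeless_system_zero(self):
        s, ff = _charged_pair(q1=0.0, q2=0.0)
        assert coulomb_energy(s, ff) == 0.0

    def test_coincident_charges_rejected(self):
        s, ff = _charged_pair(d=0.0)
        with pytest.raises(ValueError, match="coincident"):
            coulomb_energy(s, ff)

    def test_dielectric_scaling(self):
        s, ff = _charged_pair()
        assert coulomb_energy(s, ff, dielectric=2.0) == pytest.approx(coulomb_energy(s, ff) / 2)

    def test_bilinearity_cross_sum(self):
        # E(A u B) - E(A) - E(B) equals the explicit cross-pair sum
        rng = np.random.default_rng(0)
        residues, charges, lj = [], {}, {}
        for chain, n_atoms in (("A", 3), ("B", 4)):
            atoms = []
            for i in range(n_atoms):
                atoms.append(Atom(f"X{i}", "C", rng.uniform(0, 1.5, 3) + (0 if chain == "A" else 2.0)))
                charges[(chain, 1, f"X{i}")] = rng.uniform(-1, 1)
                lj[(chain, 1, f"X{i}")] = (rng.uniform(0.25, 0.35), rng.uniform(0.2, 0.8))
            residues.append(Residue("ALA", 1, chain, atoms=atoms))
        s = Structure(residues=residues)
        ff = FFParams(charges=charges, lj=lj)
        sub_a = Structure(residues=[residues[0]])
        sub_b = Structure(residues=[residues[1]])
        cross = interaction_energy(s, ["A"], ["B"], ff)
        assert cross["H_elect"] == pytest.approx(
            coulomb_energy(s, ff) - coulomb_energy(sub_a, ff) - coulomb_energy(sub_b, ff), rel=1e-9
        )
        assert cross["H_vdW"] == pytest.approx(
            lj_energy(s, ff) - lj_energy(sub_a, ff) - lj_energy(sub_b, ff), rel=1e-9
        )


class TestLennardJones:
    def test_zero_at_sigma(self):
        s, ff = _charged_pair(d=0.3)
        assert lj_energy(s, ff) == pytest.approx(0.0, abs=1e-12)

    def test_minimum_at_r_min(self):
        d = 2 ** (1 / 6) * 0.3
        s, ff = _charged_pair(d=d)
        assert lj_energy(s, ff) == pytest.approx(-0.5, rel=1e-9)

    def test_four_atom_brute_force(self):
        rng = np.random.default_rng(1)
        atoms, charges, lj = [], {}, {}
        for i in range(4):
            atoms.append(Atom(f"X{i}", "C", rng.uniform(0, 1, 3)))
            charges[("A", 1, f"X{i}")] = 0.0
            lj[("A", 1, f"X{i}")] = (rng.uniform(0.25, 0.35), rng.uniform(0.2, 0.8))
        s = Structure(residues=[Residue("ALA", 1, "A", atoms=atoms)])
        ff = FFParams(charges=charges, lj=lj)
        brute = 0.0
        for i in range(4):
            for j in range(i + 1, 4):
                si, ei = lj[("A", 1, f"X{i}")]
                sj, ej = lj[("A", 1, f"X{j}")]
                sij, eij = np.sqrt(si * sj), np.sqrt(ei * ej)
                r = np.linalg.norm(atoms[i].coords - atoms[j].coords)
                brute += 4 * eij * ((sij / r) ** 12 - (sij / r) ** 6)
        assert lj_energy(s, ff) == pytest.approx(brute, rel=1e-12)

    def test_missing_parameters_listed(self):
        s, ff = _charged_pair()
        del ff.lj[("B", 1, "CA")]
        with pytest.raises(KeyError, match="lj"):
            lj_energy(s, ff)

    def test_lorentz_rule(self):
        s = Structure(
            residues=[
                Residue("ALA", 1, "A", atoms=[Atom("CA", "C", [0, 0, 0])]),
                Residue("ALA", 1, "B", atoms=[Atom("CA", "C", [0.35, 0, 0])]),
            ]
        )
        ff = FFParams(
            charges={("A", 1, "CA"): 0.0, ("B", 1, "CA"): 0.0},
            lj={("A", 1, "CA"): (0.3, 0.4), ("B", 1, "CA"): (0.4, 0.9)},
            combination_rule="lorentz",
        )
        sij, eij = 0.35, 0.6
        expected = 4 * eij * ((sij / 0.35) ** 12 - (sij / 0.35) ** 6)
        assert lj_energy(s, ff) == pytest.approx(expected, rel=1e-12)


class TestApolarModel:
    def test_zero_sasa_returns_intercept(self):
        assert apolar_solvation(0.0) == pytest.approx(3.85112)

    def test_hundred_square_angstroms(self):
        assert apolar_solvation(100.0) == pytest.approx(6.12112)

    def test_linearity(self):
        g1 = apolar_solvation(250.0)
        g2 = apolar_solvation(500.0)
        assert g2 - g1 == pytest.approx(0.0227 * 250.0)

    def test_negative_sasa_rejected(self):
        with pytest.raises(ValueError):
            apolar_solvation(-1.0)


class TestLedgerArithmetic:
    def test_all_zero_components(self):
        assert snapshot_free_energy(EnergyComponents()) == 0.0

    def test_printed_component_column_sums(self):
        # separate-trajectory step-1 column adds to the printed total
        g = snapshot_free_energy(
            {"H_int": 94.4, "H_vdW": -202.2, "H_elect": -434.2, "G_polar": 461.6, "G_apolar": -36.4}
        )
        assert g == pytest.approx(-116.8, abs=1e-9)

    def test_missing_component_rejected(self):
        with pytest.raises(KeyError, match="missing"):
            snapshot_free_energy({"H_vdW": 1.0})

    def test_derived_fields_satisfy_identities(self):
        c = EnergyComponents(H_int=1.0, H_vdW=2.0, H_elect=3.0, G_polar=4.0, G_apolar=5.0)
        assert c.H_gas == 6.0
        assert c.G_solv == 9.0
        assert c.G == c.H_gas + c.G_solv

    def test_binding_energy_identical_partners_zero(self):
        c = EnergyComponents(H_vdW=-5.0, H_elect=2.0)
        out = binding_energy(c, [(1.0, c), (0.0, c)])
        assert out["dG_binding"] == pytest.approx(0.0)

    def test_half_dimer_coefficient(self):
        dimer = EnergyComponents(H_vdW=-10.0)
        cx = EnergyComponents(H_vdW=-5.0)
        out = binding_energy(cx, [(0.5, dimer)])
        assert out["dH_vdW"] == pytest.approx(0.0)

    def test_component_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            binding_energy(pd.Series({"H_vdW": 1.0}), [(1.0, pd.Series({"H_elect": 1.0}))])

    @pytest.mark.parametrize(
        "elect,polar,expected",
        [(-668.7, 709.3, 40.6), (-676.5, 700.9, 24.4), (-662.8, 680.4, 17.6), (-183.0, 143.3, -39.7)],
    )
    def test_total_electrostatics(self, elect, polar, expected):
        assert total_electrostatics({"dH_elect": elect, "dG_polar": polar}) == pytest.approx(expected, abs=1e-9)

    def test_total_electrostatics_zero_polar(self):
        assert total_electrostatics({"dH_elect": -5.5}) == pytest.approx(-5.5)

    def test_ledger_from_deltas_consistency(self):
        led = ledger_from_deltas(
            {"dH_vdW": -739.5, "dH_elect": -676.5, "dG_polar": 700.9, "dG_apolar": -73.4},
            sems={"dH_vdW": 2.2, "dH_elect": 4.3, "dG_polar": 4.0, "dG_apolar": 0.2},
        )
        assert led.value("dG_binding") == pytest.approx(-788.5, abs=1e-9)
        assert led.value("dG_solv") == pytest.approx(700.9 - 73.4, abs=1e-9)
        led.validate()  # bookkeeping identities hold exactly
        assert "neglected" in led.metadata["entropy"]


class TestAggregateStats:
    def test_constant_series(self):
        mean, sem = aggregate_stats([4.2] * 10)
        assert mean == pytest.approx(4.2)
        assert sem == pytest.approx(0.0, abs=1e-12)

    def test_one_two_three(self):
        mean, sem = aggregate_stats([1.0, 2.0, 3.0])
        assert mean == pytest.approx(2.0)
        assert sem == pytest.approx(np.sqrt(1.0 / 3.0))

    def test_sem_halves_when_n_quadruples(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=4000)
        _, sem_small = aggregate_stats(x[:1000])
        _, sem_large = aggregate_stats(x)
        assert sem_large == pytest.approx(sem_small / 2, rel=0.1)

    def test_too_few_snapshots(self):
        with pytest.raises(ValueError):
            aggregate_stats([1.0])


class TestInternalEnergy:
    def test_bond_angle_dihedral_terms(self):
        s = Structure(
            residues=[
                Residue(
                    "ALA",
                    1,
                    "A",
                    atoms=[
                        Atom("A1", "C", [0.0, 0.0, 0.0]),
                        Atom("A2", "C", [0.2, 0.0, 0.0]),
                        Atom("A3", "C", [0.2, 0.2, 0.0]),
                        Atom("A4", "C", [0.2, 0.2, 0.2]),
                    ],
                )
            ]
        )
        bonded = BondedTerms(
            bonds=[(("A", 1, "A1"), ("A", 1, "A2"), 0.15, 1000.0)],
            angles=[(("A", 1, "A1"), ("A", 1, "A2"), ("A", 1, "A3"), 109.5, 400.0)],
            dihedrals=[(("A", 1, "A1"), ("A", 1, "A2"), ("A", 1, "A3"), ("A", 1, "A4"), 0.0, 5.0, 3)],
        )
        e_bond = 0.5 * 1000.0 * (0.2 - 0.15) ** 2
        e_angle = 0.5 * 400.0 * (np.radians(90.0) - np.radians(109.5)) ** 2
        e_dih = 5.0 * (1 + np.cos(3 * np.radians(90.0)))
        assert internal_energy(s, bonded) == pytest.approx(e_bond + e_angle + e_dih, rel=1e-9)


class TestSita:
    def _fixture(self):
        rng = np.random.default_rng(3)
        residues, charges, lj = [], {}, {}
        for chain, base in (("A", 0.0), ("B", 0.8)):
            atoms = []
            for i in range(2):
                atoms.append(Atom(f"X{i}", "C", [base + 0.3 * i, 0.1 * i, 0.0]))
                charges[(chain, 1, f"X{i}")] = 0.3 if chain == "A" else -0.3
                lj[(chain, 1, f"X{i}")] = (0.3, 0.5)
            residues.append(Residue("ALA", 1, chain, atoms=atoms))
        topo = Structure(residues=residues)
        frames = np.array([topo.coords(), topo.coords() + rng.normal(scale=0.01, size=(4, 3))])
        traj = Trajectory(topology=topo, frames=frames)
        return traj, FFParams(charges=charges, lj=lj)

    def test_two_snapshot_ledger_matches_hand_sums(self):
        traj, ff = self._fixture()
        polar = pd.DataFrame({"complex": [10.0, 12.0], "P": [3.0, 4.0], "L": [2.0, 2.0]})
        ledger = sita_ledger(traj, {"P": ["A"], "L": ["B"]}, ff, polar_table=polar)
        # hand recompute the cross sums per snapshot
        elect, vdw = [], []
        for f in range(2):
            frame = traj.frames[f]
            e = v = 0.0
            for i in range(2):
                for j in range(2, 4):
                    r = np.linalg.norm(frame[i] - frame[j])
                    e += 138.935458 * (0.3 * -0.3) / r
                    v += 4 * 0.5 * ((0.3 / r) ** 12 - (0.3 / r) ** 6)
            elect.append(e)
            vdw.append(v)
        assert ledger.value("dH_elect") == pytest.approx(np.mean(elect), rel=1e-9)
        assert ledger.value("dH_vdW") == pytest.approx(np.mean(vdw), rel=1e-9)
        assert ledger.value("dG_polar") == pytest.approx(np.mean([10 - 3 - 2, 12 - 4 - 2]))
        ledger.validate()

    def test_internal_energy_column_identically_zero(self):
        traj, ff = self._fixture()
        ledger = sita_ledger(traj, {"P": ["A"], "L": ["B"]}, ff)
        assert ledger.value("dH_int") == 0.0
        assert float(ledger.table.loc["dH_int", "sem"]) == 0.0

    def test_partner_relabelling_symmetric(self):
        traj, ff = self._fixture()
        l1 = sita_ledger(traj, {"P": ["A"], "L": ["B"]}, ff)
        l2 = sita_ledger(traj, {"L": ["B"], "P": ["A"]}, ff)
        pd.testing.assert_frame_equal(l1.table, l2.table)

    def test_polar_table_length_mismatch(self):
        traj, ff = self._fixture()
        polar = pd.DataFrame({"complex": [1.0], "P": [0.0], "L": [0.0]})
        with pytest.raises(ValueError, match="polar table"):
            sita_ledger(traj, {"P": ["A"], "L": ["B"]}, ff, polar_table=polar)

    def test_polar_metadata_recorded(self):
        traj, ff = self._fixture()
        polar = pd.DataFrame({"complex": [1.0, 1.0], "P": [0.0, 0.0], "L": [0.0, 0.0]})
        spec = PolarInputSpec()
        ledger = sita_ledger(traj, {"P": ["A"], "L": ["B"]}, ff, polar_table=polar, polar_spec=spec)
        assert ledger.metadata["polar"]["solute_dielectric"] == 2.0
        assert ledger.metadata["polar"]["grid_points"] == 225


class TestSeta:
    TRUTH = {
        1: {"H_int": 94.4, "H_vdW": -202.2, "H_elect": -434.2, "G_polar": 461.6, "G_apolar": -36.4},
        2: {"H_int": -44.3, "H_vdW": -21.4, "H_elect": -183.0, "G_polar": 143.3, "G_apolar": -13.6},
    }

    def _tables(self, step, sigma, n=1001, seed=10):
        zeros = {k: 0.0 for k in self.TRUTH[1]}
        stoich = StoichStep.ligand_trimerization(step)
        tables = {stoich.product: make_energy_table(self.TRUTH[step], sigma, n, seed)}
        for i, (_c, sp) in enumerate(stoich.reactants):
            tables[sp] = make_energy_table(zeros, sigma, n, seed + i + 1)
        return tables, stoich

    def test_identical_static_species_all_zero(self):
        table = make_energy_table({k: 7.0 for k in self.TRUTH[1]}, 0.0, 10, 0)
        stoich = StoichStep(step_id=1, product="C", reactants=[(1.0, "P")])
        ledger = seta_ledger({"C": table, "P": table.copy()}, stoich)
        np.testing.assert_allclose(ledger.table["mean"].values, 0.0, atol=1e-12)

    def test_zero_noise_recovers_truth_exactly(self):
        tables, stoich = self._tables(1, 0.0, n=50)
        ledger = seta_ledger(tables, stoich)
        assert ledger.value("dG_binding") == pytest.approx(-116.8, abs=1e-9)
        assert ledger.value("dG_solv") == pytest.approx(425.2, abs=1e-9)

    def test_step2_column_sum(self):
        tables, stoich = self._tables(2, 0.0, n=50)
        ledger = seta_ledger(tables, stoich)
        assert ledger.value("dG_binding") == pytest.approx(-119.0, abs=1e-9)

    def test_noisy_recovery_within_three_sem(self):
        sigma, n = 12.0, 1001
        tables, stoich = self._tables(1, sigma, n=n)
        ledger = seta_ledger(tables, stoich)
        # combined SEM: product + reactant(1.0) + reactant(0.5), in quadrature
        expected_sem = sigma / np.sqrt(n) * np.sqrt(1 + 1 + 0.25)
        for comp, truth in (
            ("dH_int", 94.4),
            ("dH_vdW", -202.2),
            ("dH_elect", -434.2),
            ("dG_polar", 461.6),
            ("dG_apolar", -36.4),
        ):
            mean = ledger.value(comp)
            sem = float(ledger.table.loc[comp, "sem"])
            assert abs(mean - truth) <= 3 * sem
            assert sem == pytest.approx(expected_sem, rel=0.15)

    def test_half_coefficient_logged_and_applied(self):
        stoich = StoichStep.ligand_trimerization(2)
        assert (0.5, "(TNFR1)2") in stoich.reactants
        dimer = make_energy_table({k: 10.0 for k in self.TRUTH[1]}, 0.0, 10, 0)
        zeros = make_energy_table({k: 0.0 for k in self.TRUTH[1]}, 0.0, 10, 1)
        ledger = seta_ledger(
            {"LT-(TNFR1)2": zeros, "LT-(TNFR1)1": zeros.copy(), "(TNFR1)2": dimer}, stoich
        )
        assert ledger.value("dH_vdW") == pytest.approx(-5.0)

    def test_missing_hint_flagged(self):
        tables, stoich = self._tables(1, 0.0, n=10)
        for sp in tables:
            tables[sp] = tables[sp].drop(columns=["H_int"])
        ledger = seta_ledger(tables, stoich)
        assert "dH_int" not in ledger.table.index
        assert "incomplete" in ledger.metadata

    def test_missing_species_rejected(self):
        tables, stoich = self._tables(1, 0.0, n=10)
        tables.pop("LT")
        with pytest.raises(KeyError, match="LT"):
            seta_ledger(tables, stoich)


class TestSpeciesTable:
    def test_components_from_coordinates(self):
        s = Structure(
            residues=[
                Residue("ALA", 1, "A", atoms=[Atom("CA", "C", [0, 0, 0]), Atom("CB", "C", [0.4, 0, 0])])
            ]
        )
        ff = FFParams(
            charges={("A", 1, "CA"): 0.5, ("A", 1, "CB"): -0.5},
            lj={("A", 1, "CA"): (0.3, 0.5), ("A", 1, "CB"): (0.3, 0.5)},
        )
        traj = Trajectory(topology=s, frames=np.array([s.coords(), s.coords()]))
        table = species_component_table(traj, ff, polar=np.array([1.5, 2.5]))
        assert list(table.columns) == ["H_vdW", "H_elect", "G_polar", "G_apolar"]
        assert table["H_elect"].iloc[0] == pytest.approx(138.935458 * -0.25 / 0.4)
        assert table["G_polar"].tolist() == [1.5, 2.5]
        from enmpbsa.metrics import sasa

        _, total = sasa(s)
        assert table["G_apolar"].iloc[0] == pytest.approx(0.0227 * total + 3.85112)


class TestEnergyTableIO:
    def test_roundtrip(self, tmp_path):
        df = make_energy_table({"H_vdW": -5.0, "G_polar": 2.0}, 1.0, 20, 4)
        path = tmp_path / "table.csv"
        df.to_csv(path, index=False)
        back = read_energy_table(path)
        pd.testing.assert_frame_equal(back, df)

    def test_unknown_columns_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("H_vdW,bogus\n1.0,2.0\n")
        with pytest.raises(ValueError, match="bogus"):
            read_energy_table(path)
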