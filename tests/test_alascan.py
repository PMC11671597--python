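"""Simplified-energy alanine scanning: pair energies, mutation, ddG ledger."""

import math

import numpy as np
import pytest

from dartsdeconv import alascan, synthetic
from dartsdeconv.alascan import (
    ALA_CB_CHARGE,
    COULOMB_CONSTANT,
    AtomRecord,
    DdGRecord,
    classify_hotspots,
    ensemble_ddg,
    mutate_to_ala,
    pairwise_energy,
    residue_ligand_energy,
    total_interaction_energy,
)
from dartsdeconv.errors import (
    ResidueLookupError,
    SingularityError,
    UnsupportedMutationError,
)


def _atom(serial=1, name="SC1", rid=1, rname="ASP", q=0.0, eps=0.0, rmin=0.0,
          ligand=False):
    return AtomRecord(serial, "C", name, rid, rname, q, eps, rmin, ligand)


class TestPairwiseEnergy:
    def test_unit_charges_at_three_angstrom_hand_value(self):
        a = _atom(q=1.0)
        b = _atom(serial=2, q=-1.0, ligand=True)
        expected = COULOMB_CONSTANT * (-1.0) / (4.0 * 3.0 * 3.0)
        assert pairwise_energy(a, b, 3.0) == pytest.approx(expected, abs=1e-12)
        assert expected == pytest.approx(-9.223991666, abs=1e-6)

    def test_lj_minimum_equals_minus_epsilon(self):
        a = _atom(eps=0.25, rmin=3.2)
        b = _atom(serial=2, eps=0.25, rmin=3.2, ligand=True)
        assert pairwise_energy(a, b, 3.2) == pytest.approx(-0.25, abs=1e-12)

    def test_zero_charge_no_lj_gives_zero(self):
        assert pairwise_energy(_atom(), _atom(serial=2, q=1.0), 2.0) == 0.0

    def test_zero_distance_is_singular(self):
        with pytest.raises(SingularityError):
            pairwise_energy(_atom(q=1.0), _atom(serial=2, q=1.0), 0.0)


class TestResidueLigandEnergy:
    def test_single_pair_reduces_to_pairwise(self, contact_ensemble):
        frame = contact_ensemble.frame(0)
        lig = next(a for a in frame.atoms if a.is_ligand)
        charged = next(a for a in frame.atoms if a.charge == -1.0)
        i = frame.atoms.index(charged)
        j = frame.atoms.index(lig)
        r = float(np.linalg.norm(frame.coords[i] - frame.coords[j]))
        assert residue_ligand_energy(frame, 1, cutoff=None) == pytest.approx(
            pairwise_energy(charged, lig, r), abs=1e-12
        )

    def test_two_atom_residue_sums_hand_computed_pairs(self):
        atoms = (
            _atom(1, "CB", q=0.5),
            _atom(2, "SC1", q=-0.3),
            _atom(3, "C1", rid=2, rname="LIG", q=1.0, ligand=True),
        )
        coords = np.array([[0.0, 0, 0], [1.5, 0, 0], [4.5, 0, 0]])
        frame = alascan.Frame(atoms, coords)
        expected = (
            COULOMB_CONSTANT * 0.5 / (4 * 4.5**2)
            + COULOMB_CONSTANT * (-0.3) / (4 * 3.0**2)
        )
        assert residue_ligand_energy(frame, 1, cutoff=None) == pytest.approx(expected)

    def test_cutoff_excludes_distant_residues(self):
        spec = synthetic.ToyComplexSpec(
            n_residues=4, atoms_per_residue=6, n_snapshots=1, seed=0, jitter=0.0,
            contact_residue=1, residue_charges={1: -1.0, 4: 0.5},
        )
        frame = synthetic.generate_toy_complex(spec).frame(0)
        # residue 4's charged atom sits 18 A along x from the ligand
        assert residue_ligand_energy(frame, 4, cutoff=12.0) == 0.0
        assert residue_ligand_energy(frame, 4, cutoff=None) != 0.0

    def test_unknown_residue_raises(self, contact_ensemble):
        with pytest.raises(ResidueLookupError):
            residue_ligand_energy(contact_ensemble.frame(0), 99)

    def test_per_residue_decomposition_is_additive(self, jittered_ensemble):
        frame = jittered_ensemble.frame(0)
        for cutoff in (None, 12.0):
            total = total_interaction_energy(frame, cutoff)
            parts = sum(
                residue_ligand_energy(frame, rid, cutoff)
                for rid in frame.residue_ids()
            )
            assert total == pytest.approx(parts, abs=1e-12)


class TestMutateToAla:
    def test_truncation_keeps_backbone_and_retunes_cb(self, contact_ensemble):
        frame = contact_ensemble.frame(0)
        mut = mutate_to_ala(frame, 1)
        names = [a.name for a in mut.atoms if a.residue_id == 1 and not a.is_ligand]
        assert names == ["N", "CA", "C", "O", "CB"]
        cb = next(a for a in mut.atoms if a.residue_id == 1 and a.name == "CB")
        assert cb.charge == ALA_CB_CHARGE
        # untouched residues and coordinates
        other = [a for a in mut.atoms if a.residue_id != 1]
        assert other == [a for a in frame.atoms if a.residue_id != 1]

    def test_mutation_is_idempotent(self, contact_ensemble):
        frame = contact_ensemble.frame(0)
        m1 = mutate_to_ala(frame, 1)
        m2 = mutate_to_ala(m1, 1)
        assert m1.atoms == m2.atoms
        np.testing.assert_array_equal(m1.coords, m2.coords)

    @pytest.mark.parametrize("rname", ["GLY", "PRO", "ALA"])
    def test_unsupported_targets_raise(self, rname):
        atoms = (
            _atom(1, "CA", rid=1, rname=rname),
            _atom(2, "C1", rid=2, rname="LIG", q=1.0, ligand=True),
        )
        frame = alascan.Frame(atoms, np.zeros((2, 3)) + [[0, 0, 0], [3, 0, 0]])
        with pytest.raises(UnsupportedMutationError):
            mutate_to_ala(frame, 1)

    def test_zero_sidechain_interaction_gives_zero_ddg(self):
        """A residue whose side chain is beyond the cutoff contributes no
        interaction, so truncating it must not move the ledger."""
        spec = synthetic.ToyComplexSpec(
            n_residues=4, atoms_per_residue=6, n_snapshots=2, seed=1, jitter=0.0,
            contact_residue=1, residue_charges={1: -1.0},
        )
        ens = synthetic.generate_toy_complex(spec)
        records = ensemble_ddg(ens, [4], cutoff=12.0)  # residue 4 is ~18 A away
        assert records[0].ddg == pytest.approx(0.0, abs=1e-12)


class TestEnsembleDdg:
    def test_single_frame_single_residue_matches_hand_computation(self, contact_ensemble):
        frame = contact_ensemble.frame(0)
        dg_wt = total_interaction_energy(frame, None)
        dg_mut = total_interaction_energy(mutate_to_ala(frame, 1), None)
        rec = ensemble_ddg(contact_ensemble, [1], cutoff=None)[0]
        assert rec.dg_wt == pytest.approx(dg_wt, abs=1e-12)
        assert rec.dg_mut == pytest.approx(dg_mut, abs=1e-12)
        assert rec.ddg == pytest.approx(dg_wt - dg_mut, abs=1e-12)
        assert rec.ddg < 0  # removing the anionic contact destabilizes binding

    def test_duplicating_snapshots_leaves_ddg_unchanged(self, jittered_ensemble):
        doubled = alascan.ComplexEnsemble(
            jittered_ensemble.atoms,
            np.concatenate([jittered_ensemble.snapshots] * 2),
        )
        a = ensemble_ddg(jittered_ensemble, [2, 4])
        b = ensemble_ddg(doubled, [2, 4])
        for ra, rb in zip(a, b):
            assert ra.ddg == pytest.approx(rb.ddg, abs=1e-12)

    def test_planted_contact_ranks_first_distal_is_flat(self):
        spec = synthetic.ToyComplexSpec(
            n_residues=5, atoms_per_residue=6, n_snapshots=20, seed=7, jitter=0.05,
            contact_residue=1, residue_charges={1: -1.0},
        )
        ens = synthetic.generate_toy_complex(spec)
        records = ensemble_ddg(ens, [1, 5])
        assert records[0].residue_id == 1 and records[0].ddg < 0
        distal = next(r for r in records if r.residue_id == 5)
        assert abs(distal.ddg) < 0.1

    def test_brute_force_all_pairs_oracle(self, jittered_ensemble):
        """Independent all-pairs, all-frames recomputation (no cutoff)."""
        ens = jittered_ensemble
        def brute_dg(mutated_rid=None):
            totals = []
            for k in range(ens.n_snapshots):
                total = 0.0
                atoms = list(zip(ens.atoms, ens.snapshots[k]))
                if mutated_rid is not None:
                    kept = []
                    for a, xyz in atoms:
                        if a.is_ligand or a.residue_id != mutated_rid:
                            kept.append((a, xyz))
                        elif a.name in ("N", "CA", "C", "O", "CB"):
                            q = ALA_CB_CHARGE if a.name == "CB" else a.charge
                            kept.append((AtomRecord(a.serial, a.element, a.name,
                                                    a.residue_id, a.residue_name, q,
                                                    a.lj_epsilon, a.lj_rmin), xyz))
                    atoms = kept
                for a, xa in atoms:
                    if a.is_ligand:
                        continue
                    for b, xb in atoms:
                        if not b.is_ligand:
                            continue
                        r = math.dist(xa, xb)
                        e = 332.0637 * a.charge * b.charge / (4 * r * r)
                        eps = math.sqrt(a.lj_epsilon * b.lj_epsilon)
                        if eps > 0:
                            s6 = (0.5 * (a.lj_rmin + b.lj_rmin) / r) ** 6
                            e += eps * (s6 * s6 - 2 * s6)
                        total += e
                totals.append(total)
            return sum(totals) / len(totals)

        dg_wt = brute_dg()
        for rec in ensemble_ddg(ens, [2, 3, 4], cutoff=None):
            assert rec.dg_wt == pytest.approx(dg_wt, abs=1e-8)
            assert rec.ddg == pytest.approx(dg_wt - brute_dg(rec.residue_id), abs=1e-8)

    def test_neutral_ligand_zeroes_charge_only_ddg(self):
        spec = synthetic.ToyComplexSpec(
            n_residues=3, atoms_per_residue=6, ligand_charge=0.0, n_snapshots=3,
            seed=2, jitter=0.05, contact_residue=1, residue_charges={1: -1.0},
        )
        ens = synthetic.generate_toy_complex(spec)
        for rec in ensemble_ddg(ens, [1, 2, 3]):
            assert rec.ddg == pytest.approx(0.0, abs=1e-12)


class TestClassifyHotspots:
    @pytest.mark.parametrize(
        "ddg, tier",
        [(-20.77, "hotspot"), (-11.99, "hotspot"), (-2.70, "hotspot"),
         (-2.14, "hotspot"), (-1.79, "contributor"), (-0.5, "contributor"),
         (0.0, "neutral"), (1.3, "neutral")],
    )
    def test_default_tiers(self, ddg, tier):
        rec = DdGRecord(1, "ASP", 0.0, -ddg, ddg)
        assert classify_hotspots([rec])[0].tier == tier


class TestEnsembleIO:
    def test_pdb_and_sidecar_round_trip(self, jittered_ensemble, tmp_path):
        pdb, tsv = tmp_path / "frames.pdb", tmp_path / "params.tsv"
        alascan.write_ensemble(jittered_ensemble, pdb, tsv)
        back = alascan.read_ensemble(pdb, tsv)
        assert back.n_snapshots == jittered_ensemble.n_snapshots
        assert back.atoms == jittered_ensemble.atoms
        np.testing.assert_allclose(
            back.snapshots, jittered_ensemble.snapshots, atol=1.5e-3
        )
        # the ledger computed from the round-tripped ensemble agrees closely
        a = ensemble_ddg(jittered_ensemble, [2])
        b = ensemble_ddg(back, [2])
        assert a[0].ddg == pytest.approx(b[0].ddg, abs=1e-2)
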