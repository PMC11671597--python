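"""Ensemble computational alanine scanning with a simplified energy model.

Alanine scanning estimates each residue's contribution to ligand binding:
the residue's side chain is truncated to alanine on the wild-type
geometries (single-trajectory approximation), the receptor-ligand
interaction energy is re-evaluated over a snapshot ensemble, and

    ddG = dG_WT - dG_Mut

where dG is the ensemble mean of the total receptor-ligand interaction
energy. More negative ddG means the mutation is more destabilizing, i.e.
the residue matters more for binding.

The interaction energy here is a documented, desk-scale score — Coulomb
electrostatics with a distance-dependent dielectric eps(r) = 4r plus a
12-6 Lennard-Jones term under Lorentz-Berthelot combination:

    E(a, b, r) = 332.0637 q_a q_b / (4 r^2)
               + eps_ab [ (rmin_ab / r)^12 - 2 (rmin_ab / r)^6 ]

with eps_ab = sqrt(eps_a eps_b) and rmin_ab = (rmin_a + rmin_b) / 2.
It preserves the structure of an MM-PBSA alanine-scan ledger (per-residue
decomposition, ensemble averaging, sign convention) without solvation or
entropy terms, so absolute ddG values are not comparable to PB/GB results.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile

from .errors import (
    EvidenceError,
    ResidueLookupError,
    SingularityError,
    UnsupportedMutationError,
)

COULOMB_CONSTANT = 332.0637  # kcal * A / (mol * e^2)

# Amber ff14SB alanine CB partial charge; applied to the retained CB on mutation.
ALA_CB_CHARGE = -0.1825

BACKBONE_ATOMS = frozenset({"N", "CA", "C", "O", "H", "HA", "OXT"})
UNSUPPORTED_RESIDUES = frozenset({"GLY", "PRO", "ALA"})

DEFAULT_CUTOFF = 12.0  # Angstrom; None disables the cutoff


@dataclass(frozen=True)
class AtomRecord:
    """One atom with its coordinates-independent parameters."""

    serial: int
    element: str
    name: str
    residue_id: int
    residue_name: str
    charge: float  # elementary charges
    lj_epsilon: float  # kcal/mol
    lj_rmin: float  # Angstrom
    is_ligand: bool = False

    def __post_init__(self) -> None:
        if self.lj_epsilon < 0:
            raise EvidenceError(f"atom {self.serial}: lj_epsilon must be >= 0")
        if self.lj_epsilon > 0 and self.lj_rmin <= 0:
            raise EvidenceError(f"atom {self.serial}: lj_rmin must be > 0 when lj_epsilon > 0")


@dataclass(frozen=True, eq=False)
class Frame:
    """One coordinate snapshot over a fixed atom roster."""

    atoms: tuple[AtomRecord, ...]
    coords: np.ndarray  # (n_atoms, 3), Angstrom

    def __post_init__(self) -> None:
        if self.coords.shape != (len(self.atoms), 3):
            raise EvidenceError("coords shape does not match the atom roster")

    def residue_ids(self) -> list[int]:
        seen: list[int] = []
        for a in self.atoms:
            if not a.is_ligand and a.residue_id not in seen:
                seen.append(a.residue_id)
        return seen


@dataclass(frozen=True, eq=False)
class ComplexEnsemble:
    """Snapshot ensemble of a receptor-ligand complex."""

    atoms: tuple[AtomRecord, ...]
    snapshots: np.ndarray  # (n_snapshots, n_atoms, 3)
    interval_ps: float = 50.0  # snapshot spacing metadata

    def __post_init__(self) -> None:
        if self.snapshots.ndim != 3 or self.snapshots.shape[1:] != (len(self.atoms), 3):
            raise EvidenceError("snapshots must have shape (m, n_atoms, 3)")
        if self.n_snapshots < 1:
            raise EvidenceError("ensemble needs at least one snapshot")

    @property
    def n_snapshots(self) -> int:
        return int(self.snapshots.shape[0])

    def frame(self, k: int) -> Frame:
        return Frame(self.atoms, self.snapshots[k])


@dataclass(frozen=True)
class DdGRecord:
    residue_id: int
    residue_name: str
    dg_wt: float
    dg_mut: float
    ddg: float  # dg_wt - dg_mut; negative = destabilizing mutation
    tier: str | None = None


def pairwise_energy(a: AtomRecord, b: AtomRecord, r: float) -> float:
    """Coulomb(eps(r)=4r) + 12-6 LJ energy of one atom pair at distance r."""
    if r <= 0:
        raise SingularityError(f"nonpositive distance {r} between atoms {a.serial}, {b.serial}")
    energy = COULOMB_CONSTANT * a.charge * b.charge / (4.0 * r * r)
    eps_ab = np.sqrt(a.lj_epsilon * b.lj_epsilon)
    if eps_ab > 0.0:
        rmin_ab = 0.5 * (a.lj_rmin + b.lj_rmin)
        sr6 = (rmin_ab / r) ** 6
        energy += eps_ab * (sr6 * sr6 - 2.0 * sr6)
    return float(energy)


def _params(atoms: Sequence[AtomRecord]):
    q = np.array([a.charge for a in atoms])
    eps = np.array([a.lj_epsilon for a in atoms])
    rmin = np.array([a.lj_rmin for a in atoms])
    return q, eps, rmin


def _group_energy(
    frame: Frame,
    group_idx: np.ndarray,
    ligand_idx: np.ndarray,
    cutoff: float | None,
) -> float:
    """Summed pairwise energy between an atom group and the ligand."""
    if group_idx.size == 0 or ligand_idx.size == 0:
        return 0.0
    qa, ea, ra = _params([frame.atoms[i] for i in group_idx])
    qb, eb, rb = _params([frame.atoms[i] for i in ligand_idx])
    d = np.linalg.norm(
        frame.coords[group_idx][:, None, :] - frame.coords[ligand_idx][None, :, :],
        axis=-1,
    )
    if np.any(d <= 0):
        raise SingularityError("coincident atoms in receptor-ligand pair")
    mask = np.ones_like(d, dtype=bool) if cutoff is None else (d <= cutoff)
    coul = COULOMB_CONSTANT * qa[:, None] * qb[None, :] / (4.0 * d * d)
    eps_ab = np.sqrt(ea[:, None] * eb[None, :])
    lj = np.zeros_like(d)
    lj_mask = eps_ab > 0
    if np.any(lj_mask):
        rmin_ab = 0.5 * (ra[:, None] + rb[None, :])
        with np.errstate(divide="ignore"):
            sr6 = np.where(lj_mask, (rmin_ab / d) ** 6, 0.0)
        lj = eps_ab * (sr6 * sr6 - 2.0 * sr6)
    return float(np.sum((coul + lj)[mask]))


def _ligand_idx(atoms: Sequence[AtomRecord]) -> np.ndarray:
    idx = np.array([i for i, a in enumerate(atoms) if a.is_ligand], dtype=int)
    if idx.size == 0:
        raise EvidenceError("no ligand atoms in the complex")
    return idx


def residue_ligand_energy(
    frame: Frame, residue_id: int, cutoff: float | None = DEFAULT_CUTOFF
) -> float:
    """Interaction energy between one receptor residue and the ligand."""
    res_idx = np.array(
        [i for i, a in enumerate(frame.atoms) if not a.is_ligand and a.residue_id == residue_id],
        dtype=int,
    )
    if res_idx.size == 0:
        raise ResidueLookupError(f"residue {residue_id} not found")
    return _group_energy(frame, res_idx, _ligand_idx(frame.atoms), cutoff)


def total_interaction_energy(frame: Frame, cutoff: float | None = DEFAULT_CUTOFF) -> float:
    """Total receptor-ligand interaction energy of one frame."""
    rec_idx = np.array([i for i, a in enumerate(frame.atoms) if not a.is_ligand], dtype=int)
    return _group_energy(frame, rec_idx, _ligand_idx(frame.atoms), cutoff)


def mutate_to_ala(frame: Frame, residue_id: int, cb_charge: float = ALA_CB_CHARGE) -> Frame:
    """Truncate a residue's side chain beyond CB on the given geometry.

    Backbone atoms are untouched; the retained CB takes the alanine
    template charge; coordinates are otherwise unchanged (single-trajectory
    approximation). The original residue name is kept, which makes the
    operation idempotent. GLY, PRO and ALA targets are rejected.
    """
    res_atoms = [a for a in frame.atoms if not a.is_ligand and a.residue_id == residue_id]
    if not res_atoms:
        raise ResidueLookupError(f"residue {residue_id} not found")
    res_name = res_atoms[0].residue_name.upper()
    if res_name in UNSUPPORTED_RESIDUES:
        raise UnsupportedMutationError(f"cannot mutate {res_name} {residue_id} to alanine")
    if not any(a.name == "CB" for a in res_atoms):
        raise UnsupportedMutationError(f"residue {res_name} {residue_id} has no CB atom")
    keep_names = BACKBONE_ATOMS | {"CB"}
    atoms: list[AtomRecord] = []
    keep_idx: list[int] = []
    for i, a in enumerate(frame.atoms):
        if a.is_ligand or a.residue_id != residue_id:
            atoms.append(a)
            keep_idx.append(i)
        elif a.name in keep_names:
            atoms.append(replace(a, charge=cb_charge) if a.name == "CB" else a)
            keep_idx.append(i)
    return Frame(tuple(atoms), frame.coords[np.array(keep_idx, dtype=int)])


def ensemble_ddg(
    ensemble: ComplexEnsemble,
    residue_ids: Iterable[int],
    cutoff: float | None = DEFAULT_CUTOFF,
    cb_charge: float = ALA_CB_CHARGE,
) -> list[DdGRecord]:
    """Alanine-scan ddG ledger over a snapshot ensemble.

    dG is the mean over snapshots of the total receptor-ligand interaction
    energy; the mutant dG re-evaluates every frame with the residue
    truncated. Records are sorted ascending in ddG (most destabilizing
    mutation first).
    """
    residue_ids = list(residue_ids)
    if not residue_ids:
        raise EvidenceError("no residues requested for the alanine scan")
    names = {
        a.residue_id: a.residue_name for a in ensemble.atoms if not a.is_ligand
    }
    for rid in residue_ids:
        if rid not in names:
            raise ResidueLookupError(f"residue {rid} not found in the ensemble")
    frames = [ensemble.frame(k) for k in range(ensemble.n_snapshots)]
    dg_wt = float(np.mean([total_interaction_energy(f, cutoff) for f in frames]))
    records = []
    for rid in residue_ids:
        dg_mut = float(
            np.mean(
                [
                    total_interaction_energy(mutate_to_ala(f, rid, cb_charge), cutoff)
                    for f in frames
                ]
            )
        )
        ddg = dg_wt - dg_mut
        records.append(DdGRecord(rid, names[rid], dg_wt, dg_mut, ddg))
    return sorted(records, key=lambda r: (r.ddg, r.residue_id))


def classify_hotspots(
    records: Iterable[DdGRecord],
    hotspot_max: float = -2.0,
    contributor_max: float = -0.5,
) -> list[DdGRecord]:
    """Tier each record: hotspot (ddG <= -2), contributor (-2 < ddG <= -0.5), neutral."""
    if contributor_max < hotspot_max:
        raise EvidenceError("contributor threshold must not be below the hotspot threshold")
    out = []
    for r in records:
        if r.ddg <= hotspot_max:
            tier = "hotspot"
        elif r.ddg <= contributor_max:
            tier = "contributor"
        else:
            tier = "neutral"
        out.append(replace(r, tier=tier))
    return out


def ledger_frame(records: Iterable[DdGRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "residue_id": r.residue_id,
                "residue_name": r.residue_name,
                "dg_wt": r.dg_wt,
                "dg_mut": r.dg_mut,
                "ddg": r.ddg,
                "tier": r.tier,
            }
            for r in records
        ]
    )


# ---------------------------------------------------------------------------
# PDB + parameter-sidecar IO

LIGAND_CHAIN = "L"
RECEPTOR_CHAIN = "A"

PARAM_COLUMNS = ["serial", "charge", "lj_epsilon", "lj_rmin", "residue_id"]


def write_ensemble(ensemble: ComplexEnsemble, pdb_path: str | Path, params_path: str | Path) -> None:
    """Write snapshots as a multi-MODEL PDB plus a TSV parameter sidecar."""
    n = len(ensemble.atoms)
    stack = struc.AtomArrayStack(ensemble.n_snapshots, n)
    stack.coord = np.asarray(ensemble.snapshots, dtype=np.float32)
    stack.chain_id = np.array(
        [LIGAND_CHAIN if a.is_ligand else RECEPTOR_CHAIN for a in ensemble.atoms]
    )
    stack.res_id = np.array([a.residue_id for a in ensemble.atoms])
    stack.res_name = np.array([a.residue_name for a in ensemble.atoms])
    stack.atom_name = np.array([a.name for a in ensemble.atoms])
    stack.element = np.array([a.element for a in ensemble.atoms])
    stack.hetero = np.array([a.is_ligand for a in ensemble.atoms])
    pdb = PDBFile()
    pdb.set_structure(stack)
    pdb.write(str(pdb_path))
    pd.DataFrame(
        {
            "serial": [a.serial for a in ensemble.atoms],
            "charge": [a.charge for a in ensemble.atoms],
            "lj_epsilon": [a.lj_epsilon for a in ensemble.atoms],
            "lj_rmin": [a.lj_rmin for a in ensemble.atoms],
            "residue_id": [a.residue_id for a in ensemble.atoms],
        }
    ).to_csv(params_path, sep="\t", index=False)


def read_ensemble(
    pdb_path: str | Path, params_path: str | Path, interval_ps: float = 50.0
) -> ComplexEnsemble:
    """Read a multi-MODEL PDB ensemble and its parameter sidecar.

    Atoms on chain 'L' are the ligand. The sidecar is matched by atom order
    (serial column is 1-based file order).
    """
    stack = PDBFile.read(str(pdb_path)).get_structure(model=None)
    params = pd.read_csv(params_path, sep="\t")
    missing = set(PARAM_COLUMNS) - set(params.columns)
    if missing:
        raise EvidenceError(f"parameter sidecar lacks columns: {sorted(missing)}")
    params = params.sort_values("serial").reset_index(drop=True)
    if len(params) != stack.array_length():
        raise EvidenceError(
            f"sidecar has {len(params)} atoms but the PDB has {stack.array_length()}"
        )
    atoms = tuple(
        AtomRecord(
            serial=int(params["serial"][i]),
            element=str(stack.element[i]),
            name=str(stack.atom_name[i]),
            residue_id=int(params["residue_id"][i]),
            residue_name=str(stack.res_name[i]),
            charge=float(params["charge"][i]),
            lj_epsilon=float(params["lj_epsilon"][i]),
            lj_rmin=float(params["lj_rmin"][i]),
            is_ligand=str(stack.chain_id[i]) == LIGAND_CHAIN,
        )
        for i in range(stack.array_length())
    )
    return ComplexEnsemble(atoms, np.asarray(stack.coord, dtype=float), interval_ps)
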