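"""Synthetic inputs for the DARTS deconvolution pipeline.

Emulates a three-condition DARTS experiment over a mock proteome:

* ``control`` — trypsin-only digestion (the no-pronase arm still goes
  through MS sample prep, hence tryptic peptides);
* ``pronase`` — sequence-nonspecific per-bond Bernoulli cleavage on top of
  the tryptic digest (pronase is a broad-specificity protease mixture);
* ``pronase_drug`` — as pronase, but cleavage probability inside the
  designated target's ligand-binding footprint (plus a flank) is reduced by
  a dose-dependent logistic protection factor.

Peptides outside a detectable length window are discarded and survivors are
observed with a fixed detection probability. Detection decisions are keyed
by peptide identity (protein, coordinates), not by condition, mirroring the
fact that a peptide's MS detectability is intrinsic; identical digests
therefore yield identical evidence tables.

Also generates noiseless/noisy dose-response and binding-trace series and
toy receptor-ligand coordinate ensembles for the alanine-scan module.
All generators are bit-reproducible given (seed, configuration).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._rng import stable_uniform, substream
from .alascan import AtomRecord, ComplexEnsemble
from .coverage import EVIDENCE_COLUMNS, ProteinRecord
from .errors import ConfigurationError, ProteinLookupError
from .fits import four_pl, fraction_bound

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class ProteomeSpec:
    """Mock proteome: random sequences over the 20 standard amino acids."""

    n_proteins: int = 40
    length_range: tuple[int, int] = (60, 400)
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.length_range
        if self.n_proteins < 1:
            raise ConfigurationError("n_proteins must be >= 1")
        if lo < 10 or hi < lo:
            raise ConfigurationError("length_range must satisfy 10 <= min <= max")


@dataclass(frozen=True)
class TargetSpec:
    """The planted drug target and its protection model.

    ``footprint`` is the 1-based inclusive residue interval protected by
    ligand binding; protection of per-bond cleavage follows a logistic in
    dose with midpoint ``ec50`` and slope ``hill``, saturating at
    ``protection_max``.
    """

    protein_id: str
    footprint: tuple[int, int]
    protection_max: float = 0.8
    ec50: float = 280.0  # uM
    hill: float = 1.0

    def __post_init__(self) -> None:
        s, e = self.footprint
        if not (1 <= s <= e):
            raise ConfigurationError("footprint must be a 1-based inclusive interval")
        if not (0.0 <= self.protection_max <= 1.0):
            raise ConfigurationError("protection_max must be in [0, 1]")
        if self.ec50 <= 0 or self.hill <= 0:
            raise ConfigurationError("ec50 and hill must be positive")

    def protection(self, dose: float) -> float:
        """Fraction by which cleavage is suppressed inside the footprint."""
        if dose < 0:
            raise ConfigurationError("dose must be nonnegative")
        if dose == 0:
            return 0.0
        if math.isinf(dose):
            return self.protection_max
        return self.protection_max / (1.0 + (self.ec50 / dose) ** self.hill)


@dataclass(frozen=True)
class DigestionParams:
    """Two-stage digestion and detection model.

    Cleavage is per-bond Bernoulli at the molecule level; the evidence
    table represents peptides pooled over a vast molecule population, so a
    fragment's relative abundance is the probability that one molecule
    yields it: P(cut at each boundary) x P(no cut inside). Fragments below
    ``min_abundance`` fall under the identification limit and are never
    reported; survivors in the detectable length window are observed with
    probability ``p_detect``, keyed by peptide identity.
    """

    p_pronase: float = 0.30  # per-bond cleavage probability
    tryptic: bool = True  # cleave after K/R, not before P
    detect_len_range: tuple[int, int] = (7, 30)
    p_detect: float = 0.7
    min_abundance: float = 0.04  # identification limit on relative abundance
    flank: int = 5  # residues of protection beyond the footprint
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_pronase <= 1.0 and 0.0 <= self.p_detect <= 1.0):
            raise ConfigurationError("probabilities must be in [0, 1]")
        lo, hi = self.detect_len_range
        if lo < 1 or hi < lo:
            raise ConfigurationError("detect_len_range must satisfy 1 <= min <= max")
        if not (0.0 < self.min_abundance <= 1.0):
            raise ConfigurationError("min_abundance must be in (0, 1]")
        if self.flank < 0:
            raise ConfigurationError("flank must be nonnegative")


def generate_proteome(spec: ProteomeSpec) -> list[ProteinRecord]:
    """Random protein records, one stable substream per protein."""
    lo, hi = spec.length_range
    width = len(str(spec.n_proteins))
    records = []
    for i in range(spec.n_proteins):
        rng = substream(spec.seed, "proteome", i)
        length = int(rng.integers(lo, hi + 1))
        seq = "".join(np.array(list(AMINO_ACIDS))[rng.integers(0, 20, size=length)])
        records.append(ProteinRecord(id=f"P{i + 1:0{width}d}", sequence=seq))
    return records


def _tryptic_bonds(seq: str) -> set[int]:
    # bond i separates residues i+1 and i+2 (1-based); trypsin cuts after K/R
    # unless the next residue is proline
    return {i for i in range(len(seq) - 1) if seq[i] in "KR" and seq[i + 1] != "P"}


def _bond_cut_probabilities(
    seq: str,
    condition: str,
    params: DigestionParams,
    protected: tuple[int, int] | None,
    protection: float,
) -> np.ndarray:
    """Per-bond cleavage probability; bond i separates residues i+1, i+2."""
    length = len(seq)
    p = np.zeros(max(length - 1, 0))
    if condition != "control":
        p[:] = params.p_pronase
        if protected is not None and protection > 0:
            s, e = protected
            lo = max(1, s - params.flank)
            hi = min(length, e + params.flank)
            bonds = np.arange(length - 1)
            inside = (bonds + 1 >= lo) & (bonds + 2 <= hi)
            p[inside] *= 1.0 - protection
    if params.tryptic:
        for b in _tryptic_bonds(seq):
            p[b] = 1.0  # trypsin cleaves deterministically during MS prep
    return p


def _digest_one(
    seq: str,
    protein_id: str,
    condition: str,
    params: DigestionParams,
    protected: tuple[int, int] | None,
    protection: float,
) -> list[tuple[str, int, int]]:
    """Detected peptides (peptide, start, end) for one protein, one condition.

    Enumerates every fragment in the detectable length window; its relative
    abundance is P(cut at left boundary) * P(cut at right boundary) *
    P(no cut at any interior bond), with the protein termini counting as
    certain boundaries. Fragments at or above the identification limit are
    detected with probability p_detect via identity-keyed uniforms.
    """
    length = len(seq)
    p = _bond_cut_probabilities(seq, condition, params, protected, protection)
    # finite log-zero sentinel keeps prefix differences NaN-free; exp(-746)
    # underflows to exactly 0, so always-cut interior bonds zero the fragment
    log_surv = np.where(p >= 1.0, -746.0, np.log1p(-np.minimum(p, 1.0 - 1e-16)))
    # prefix[i] = sum of log survival over bonds 0..i-1
    prefix = np.concatenate([[0.0], np.cumsum(log_surv)])
    cut = np.concatenate([[1.0], p, [1.0]])  # boundary prob; termini certain
    lo_len, hi_len = params.detect_len_range
    out = []
    for frag_len in range(lo_len, min(hi_len, length) + 1):
        starts = np.arange(1, length - frag_len + 2)  # 1-based start positions
        ends = starts + frag_len - 1
        interior = np.exp(prefix[ends - 1] - prefix[starts - 1])
        abundance = cut[starts - 1] * cut[ends] * interior
        for s in starts[abundance >= params.min_abundance]:
            e = s + frag_len - 1
            if stable_uniform(params.seed, "detect", protein_id, s, e) < params.p_detect:
                out.append((seq[s - 1 : e], int(s), int(e)))
    return sorted(out, key=lambda t: (t[1], t[2]))


def simulate_darts_triplet(
    proteome: list[ProteinRecord],
    target: TargetSpec,
    dose: float,
    params: DigestionParams,
) -> pd.DataFrame:
    """Peptide evidence for the three DARTS conditions, one long table.

    Protection applies only to the designated target protein, only in the
    ``pronase_drug`` condition, and only to bonds within footprint +- flank.
    """
    ids = {p.id for p in proteome}
    if target.protein_id not in ids:
        raise ProteinLookupError(f"target {target.protein_id!r} not in the proteome")
    by_id = {p.id: p for p in proteome}
    s, e = target.footprint
    if e > by_id[target.protein_id].length:
        raise ConfigurationError("footprint exceeds the target protein length")
    protection = target.protection(dose)
    rows = []
    for prot in proteome:
        for condition in ("control", "pronase", "pronase_drug"):
            protected = (
                target.footprint
                if condition == "pronase_drug" and prot.id == target.protein_id
                else None
            )
            for pep, start, end in _digest_one(
                prot.sequence, prot.id, condition, params, protected, protection
            ):
                rows.append((condition, prot.id, pep, start, end))
    return pd.DataFrame(rows, columns=EVIDENCE_COLUMNS)


def simulate_dose_series(
    target: TargetSpec,
    doses: list[float],
    noise_sd: float = 0.0,
    seed: int = 0,
    bottom: float = 0.0,
    top: float = 1.0,
) -> pd.DataFrame:
    """4PL protection signal over a dose series, with Gaussian noise."""
    d = np.asarray(doses, dtype=float)
    if np.any(d <= 0):
        raise ConfigurationError("doses must be strictly positive")
    if np.any(np.diff(d) < 0):
        raise ConfigurationError("doses must be sorted ascending")
    signal = four_pl(d, bottom, top, target.ec50, target.hill)
    if noise_sd > 0:
        signal = signal + substream(seed, "dose").normal(0.0, noise_sd, size=d.size)
    return pd.DataFrame({"dose": d, "signal": signal})


def simulate_binding_trace(
    kd: float,
    protein_conc: float,
    ligand_series: list[float],
    noise_sd: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Bound fraction over a ligand titration from the exact 1:1 isotherm."""
    if kd <= 0 or protein_conc <= 0:
        raise ConfigurationError("kd and protein_conc must be positive")
    L = np.asarray(ligand_series, dtype=float)
    fb = fraction_bound(L, protein_conc, kd)
    if noise_sd > 0:
        fb = fb + substream(seed, "mst").normal(0.0, noise_sd, size=L.size)
    return pd.DataFrame({"ligand": L, "fraction_bound": fb})


def half_log_series(top: float, n: int) -> np.ndarray:
    """n concentrations descending from ``top`` in half-log (sqrt(10)) steps,
    returned ascending."""
    return np.sort(top / 10.0 ** (0.5 * np.arange(n)))


# Packaged demo configurations: the MST trace mirrors the assay conditions
# (Kd 204 uM, 50 nM protein); the dose series mirrors the DARTS titration
# (EC50 280 uM, half-log doses spanning 10-10000 uM).
MST_DEMO = {
    "kd": 204.0,
    "protein_conc": 0.05,
    "ligand_series": half_log_series(5000.0, 12).tolist(),
    "noise_sd": 0.02,
}
DOSE_DEMO = {
    "ec50": 280.0,
    "hill": 1.0,
    "doses": (10.0 * 10.0 ** (0.5 * np.arange(7))).tolist(),  # 10 .. 10000 uM
    "noise_sd": 0.03,
}


# ---------------------------------------------------------------------------
# Toy structure ensembles for the alanine scan

_ATOM_NAMES = ("N", "CA", "C", "O", "CB")


def _toy_atom_name(j: int) -> str:
    return _ATOM_NAMES[j] if j < len(_ATOM_NAMES) else f"SC{j - len(_ATOM_NAMES) + 1}"


@dataclass(frozen=True)
class ToyComplexSpec:
    """Geometry and parameters of a toy receptor-ligand complex.

    Residues sit on a lattice along x (6 A spacing) with their atoms
    stacked along y (1.4 A). Per-residue charges and LJ parameters are
    placed on the outermost side-chain atom (the one removed by an alanine
    mutation) so that planted contacts are side-chain mediated. The
    single-atom ligand sits ``contact_distance`` along z from the
    side-chain atom of ``contact_residue``.
    """

    n_residues: int = 8
    atoms_per_residue: int = 6
    ligand_charge: float = 1.0
    n_snapshots: int = 200
    seed: int = 0
    jitter: float = 0.1  # A, Gaussian positional noise per snapshot
    contact_residue: int = 1
    contact_distance: float = 3.0  # A
    residue_charges: dict[int, float] = field(default_factory=dict)
    residue_lj: dict[int, tuple[float, float]] = field(default_factory=dict)  # (eps, rmin)
    residue_name: str = "ASP"

    def __post_init__(self) -> None:
        if min(self.n_residues, self.atoms_per_residue, self.n_snapshots) < 1:
            raise ConfigurationError("counts must be >= 1")
        if not (1 <= self.contact_residue <= self.n_residues):
            raise ConfigurationError("contact_residue out of range")
        if self.contact_distance <= 0:
            raise ConfigurationError("contact_distance must be positive")


def generate_toy_complex(spec: ToyComplexSpec) -> ComplexEnsemble:
    """Deterministic toy ensemble; see :class:`ToyComplexSpec`."""
    atoms: list[AtomRecord] = []
    coords: list[list[float]] = []
    serial = 1
    for rid in range(1, spec.n_residues + 1):
        q_res = spec.residue_charges.get(rid, 0.0)
        eps_res, rmin_res = spec.residue_lj.get(rid, (0.0, 0.0))
        for j in range(spec.atoms_per_residue):
            outermost = j == spec.atoms_per_residue - 1
            atoms.append(
                AtomRecord(
                    serial=serial,
                    element="C",
                    name=_toy_atom_name(j),
                    residue_id=rid,
                    residue_name=spec.residue_name,
                    charge=q_res if outermost else 0.0,
                    lj_epsilon=eps_res if outermost else 0.0,
                    lj_rmin=rmin_res if outermost else 0.0,
                )
            )
            coords.append([6.0 * (rid - 1), 1.4 * j, 0.0])
            serial += 1
    contact_xyz = coords[(spec.contact_residue - 1) * spec.atoms_per_residue
                         + spec.atoms_per_residue - 1]
    atoms.append(
        AtomRecord(
            serial=serial,
            element="C",
            name="C1",
            residue_id=spec.n_residues + 1,
            residue_name="LIG",
            charge=spec.ligand_charge,
            lj_epsilon=0.0,
            lj_rmin=0.0,
            is_ligand=True,
        )
    )
    coords.append([contact_xyz[0], contact_xyz[1], spec.contact_distance])
    base = np.asarray(coords, dtype=float)
    snapshots = np.empty((spec.n_snapshots, base.shape[0], 3))
    for k in range(spec.n_snapshots):
        noise = (
            substream(spec.seed, "snap", k).normal(0.0, spec.jitter, size=base.shape)
            if spec.jitter > 0
            else 0.0
        )
        snapshots[k] = base + noise
    return ComplexEnsemble(tuple(atoms), snapshots)
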