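"""End-to-end orchestration: simulate -> coverage -> screen -> fits -> alascan.

One JSON-serializable, schema-validated configuration drives the whole run;
all randomness flows from a single root seed. Every stage persists its
inputs and outputs under the run directory, so stages can be re-run
individually from the serialized intermediates, and the run summary is
byte-identical across repeated runs of the same configuration.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path
from typing import Literal, Optional

from pydantic import BaseModel, ConfigDict, Field

from . import alascan, coverage, fits, screen, synthetic
from .errors import ConfigurationError

log = logging.getLogger("dartsdeconv")


class _Model(BaseModel):
    model_config = ConfigDict(extra="forbid")


class ProteomeConfig(_Model):
    n_proteins: int = 40
    length_range: tuple[int, int] = (60, 400)


class TargetConfig(_Model):
    """Planted target; ``protein_id='auto'`` picks the first protein of at
    least ``auto_min_length`` residues and centers the footprint on it."""

    protein_id: str = "auto"
    footprint: Optional[tuple[int, int]] = None
    footprint_fraction: float = Field(default=0.45, gt=0.0, le=1.0)
    auto_min_length: int = 150
    protection_max: float = Field(default=0.8, ge=0.0, le=1.0)
    ec50: float = Field(default=280.0, gt=0.0)
    hill: float = Field(default=1.0, gt=0.0)


class DigestionConfig(_Model):
    p_pronase: float = Field(default=0.30, ge=0.0, le=1.0)
    tryptic: bool = True
    detect_len_range: tuple[int, int] = (7, 30)
    p_detect: float = Field(default=0.7, ge=0.0, le=1.0)
    min_abundance: float = Field(default=0.04, gt=0.0, le=1.0)
    flank: int = Field(default=5, ge=0)


class ScreenConfig(_Model):
    min_degradation: float = Field(default=5.0, ge=0.0)
    min_stabilization: float = Field(default=5.0, ge=0.0)
    strict: bool = True
    mode: Literal["points", "relative"] = "points"


class DoseFitConfig(_Model):
    doses: list[float] = Field(default_factory=lambda: list(synthetic.DOSE_DEMO["doses"]))
    noise_sd: float = 0.03
    fix_hill: Optional[float] = None
    n_boot: int = 200


class MstConfig(_Model):
    kd: float = Field(default=204.0, gt=0.0)
    protein_conc: float = Field(default=0.05, gt=0.0)
    ligand_series: list[float] = Field(
        default_factory=lambda: list(synthetic.MST_DEMO["ligand_series"])
    )
    noise_sd: float = 0.02
    n_boot: int = 200


class AlascanConfig(_Model):
    n_residues: int = Field(default=8, ge=1)
    atoms_per_residue: int = Field(default=6, ge=1)
    ligand_charge: float = 1.0
    n_snapshots: int = Field(default=200, ge=1)
    jitter: float = Field(default=0.1, ge=0.0)
    contact_residue: int = 1
    contact_distance: float = Field(default=3.0, gt=0.0)
    contact_charge: float = -1.0
    cutoff: Optional[float] = 12.0


class RunConfig(_Model):
    """Full pipeline configuration; validated before any stage runs."""

    seed: int = 0
    dose: float = Field(default=3000.0, gt=0.0)  # drug dose in the DARTS arm, uM
    proteome: ProteomeConfig = ProteomeConfig()
    target: TargetConfig = TargetConfig()
    digestion: DigestionConfig = DigestionConfig()
    screen: ScreenConfig = ScreenConfig()
    dose_fit: DoseFitConfig = DoseFitConfig()
    mst: MstConfig = MstConfig()
    alascan: AlascanConfig = AlascanConfig()


def load_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        return RunConfig.model_validate(json.load(fh))


def resolve_target(proteins: list[coverage.ProteinRecord], cfg: TargetConfig) -> synthetic.TargetSpec:
    """Turn a TargetConfig into a concrete TargetSpec against a proteome."""
    if cfg.protein_id == "auto":
        eligible = [p for p in proteins if p.length >= cfg.auto_min_length]
        if not eligible:
            raise ConfigurationError(
                f"no protein of length >= {cfg.auto_min_length} to plant the target on"
            )
        prot = eligible[0]
    else:
        by_id = {p.id: p for p in proteins}
        if cfg.protein_id not in by_id:
            raise ConfigurationError(f"target protein {cfg.protein_id!r} not in proteome")
        prot = by_id[cfg.protein_id]
    if cfg.footprint is not None:
        footprint = cfg.footprint
    else:
        width = max(1, round(prot.length * cfg.footprint_fraction))
        start = max(1, (prot.length - width) // 2 + 1)
        footprint = (start, min(prot.length, start + width - 1))
    return synthetic.TargetSpec(
        protein_id=prot.id,
        footprint=footprint,
        protection_max=cfg.protection_max,
        ec50=cfg.ec50,
        hill=cfg.hill,
    )


def run_pipeline(config: RunConfig, outdir: str | Path) -> dict:
    """Execute all stages and return (and persist) the run summary."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.json").write_text(config.model_dump_json(indent=2))
    t0 = time.time()

    stage = "simulate"
    try:
        log.info("stage=%s seed=%d", stage, config.seed)
        proteome_spec = synthetic.ProteomeSpec(
            n_proteins=config.proteome.n_proteins,
            length_range=tuple(config.proteome.length_range),
            seed=config.seed,
        )
        proteins = synthetic.generate_proteome(proteome_spec)
        coverage.write_fasta(proteins, out / "proteome.fasta")
        target = resolve_target(proteins, config.target)
        params = synthetic.DigestionParams(
            p_pronase=config.digestion.p_pronase,
            tryptic=config.digestion.tryptic,
            detect_len_range=tuple(config.digestion.detect_len_range),
            p_detect=config.digestion.p_detect,
            min_abundance=config.digestion.min_abundance,
            flank=config.digestion.flank,
            seed=config.seed,
        )
        evidence = synthetic.simulate_darts_triplet(proteins, target, config.dose, params)
        coverage.write_evidence(evidence, out / "evidence.tsv")

        stage = "coverage"
        log.info("stage=%s n_peptides=%d", stage, len(evidence))
        cov = coverage.coverage_table(proteins, evidence)
        cov.to_csv(out / "coverage.csv", index=False)

        stage = "screen"
        stats = screen.compute_screen_stats(cov)
        thresholds = screen.ScreenThresholds(
            min_degradation=config.screen.min_degradation,
            min_stabilization=config.screen.min_stabilization,
            strict=config.screen.strict,
            mode=config.screen.mode,
        )
        candidates, cascade = screen.screen_candidates(stats, thresholds)
        log.info(
            "stage=%s total=%d degraded=%d candidates=%d",
            stage, cascade["total"], cascade["degraded"], cascade["candidates"],
        )
        stats.to_csv(out / "screen_stats.csv", index=False)
        candidates.to_csv(out / "candidates.csv", index=False)
        screen.export_heatmap_matrix(stats, candidates, out / "heatmap.csv")

        stage = "fit-dose"
        series = synthetic.simulate_dose_series(
            target, config.dose_fit.doses, config.dose_fit.noise_sd, seed=config.seed
        )
        series.to_csv(out / "dose_series.csv", index=False)
        dose_fit = fits.fit_4pl(
            series["dose"], series["signal"],
            fix_hill=config.dose_fit.fix_hill,
            n_boot=config.dose_fit.n_boot, seed=config.seed,
        )
        log.info("stage=%s ec50=%.4g hill=%.3g", stage, dose_fit.ec50, dose_fit.hill)

        stage = "fit-mst"
        trace = synthetic.simulate_binding_trace(
            config.mst.kd, config.mst.protein_conc, config.mst.ligand_series,
            config.mst.noise_sd, seed=config.seed,
        )
        trace.to_csv(out / "binding_trace.csv", index=False)
        mst_fit = fits.fit_isotherm(
            trace["ligand"], trace["fraction_bound"], config.mst.protein_conc,
            n_boot=config.mst.n_boot, seed=config.seed,
        )
        log.info("stage=%s kd=%.4g", stage, mst_fit.kd)

        stage = "alascan"
        a = config.alascan
        toy = synthetic.ToyComplexSpec(
            n_residues=a.n_residues,
            atoms_per_residue=a.atoms_per_residue,
            ligand_charge=a.ligand_charge,
            n_snapshots=a.n_snapshots,
            seed=config.seed,
            jitter=a.jitter,
            contact_residue=a.contact_residue,
            contact_distance=a.contact_distance,
            residue_charges={a.contact_residue: a.contact_charge},
        )
        ensemble = synthetic.generate_toy_complex(toy)
        alascan.write_ensemble(ensemble, out / "frames.pdb", out / "params.tsv")
        records = alascan.ensemble_ddg(
            ensemble, ensemble.frame(0).residue_ids(), cutoff=a.cutoff
        )
        records = alascan.classify_hotspots(records)
        ledger = alascan.ledger_frame(records)
        ledger.to_csv(out / "ddg_ledger.csv", index=False)
        log.info("stage=%s top_residue=%d ddg=%.3f", stage,
                 records[0].residue_id, records[0].ddg)
    except Exception:
        log.exception("pipeline aborted at stage=%s (partial outputs in %s)", stage, out)
        raise

    summary = {
        "seed": config.seed,
        "dose_uM": config.dose,
        "target": {
            "protein_id": target.protein_id,
            "footprint": list(target.footprint),
            "protection_max": target.protection_max,
            "ec50_uM": target.ec50,
            "hill": target.hill,
        },
        "cascade": cascade,
        "candidates": candidates["protein_id"].tolist(),
        "dose_fit": {
            "ec50_uM": dose_fit.ec50,
            "hill": dose_fit.hill,
            "bottom": dose_fit.bottom,
            "top": dose_fit.top,
            "ci": dose_fit.ci,
        },
        "isotherm_fit": {
            "kd_uM": mst_fit.kd,
            "amplitude": mst_fit.amplitude,
            "baseline": mst_fit.baseline,
            "ci": mst_fit.ci,
        },
        "ddg_ledger": "ddg_ledger.csv",
        "hotspots": [r.residue_id for r in records if r.tier == "hotspot"],
    }
    elapsed = time.time() - t0
    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    log.info("pipeline done in %.1fs; summary at %s", elapsed, out / "summary.json")
    return summary
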