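"""Deterministic MD-system bookkeeping.

Small, exact calculators for simulation-system arithmetic: KCl ion counts
for a target molarity with charge neutralization, membrane leaflet lipid
composition at a stated ratio, and snapshot scheduling for ensemble
analyses. All rounding is round-half-up, documented.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

from .errors import ConfigurationError

WATER_MOLARITY = 55.5  # mol/L; pure-water concentration used for ion arithmetic


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


@dataclass(frozen=True)
class SolvationSpec:
    n_water: int
    molarity: float  # mol/L
    solute_net_charge: int  # elementary charges, signed

    def __post_init__(self) -> None:
        if self.n_water < 0 or self.molarity < 0:
            raise ConfigurationError("n_water and molarity must be nonnegative")


@dataclass(frozen=True)
class LeafletSpec:
    n_primary_lipid: int
    ratio_primary_to_sterol: tuple[int, int] = (10, 1)

    def __post_init__(self) -> None:
        r1, r2 = self.ratio_primary_to_sterol
        if self.n_primary_lipid < 0 or r1 < 0 or r2 < 0:
            raise ConfigurationError("counts and ratio parts must be nonnegative")


def ion_counts(spec: SolvationSpec, water_molarity: float = WATER_MOLARITY) -> tuple[int, int]:
    """(n_cation, n_anion) for a 1:1 salt at the target molarity, neutralized.

    Base pairs n = round(molarity * n_water / water_molarity); a solute of
    net charge +z is neutralized by removing z cations (symmetrically,
    removing anions for negative z). Guarantees
    n_cation - n_anion + solute_net_charge = 0.
    """
    n = _round_half_up(spec.molarity * spec.n_water / water_molarity)
    z = spec.solute_net_charge
    n_cation = n - max(z, 0)
    n_anion = n + min(z, 0)
    if n_cation < 0 or n_anion < 0:
        raise ConfigurationError(
            f"neutralizing a charge of {z:+d} needs more than the {n} available "
            "salt pairs; use a larger water box"
        )
    return n_cation, n_anion


def leaflet_composition(spec: LeafletSpec) -> tuple[int, int]:
    """(n_primary, n_sterol) at the stated primary:sterol ratio."""
    r1, r2 = spec.ratio_primary_to_sterol
    if r1 == 0:
        raise ConfigurationError("primary part of the lipid ratio must be nonzero")
    return spec.n_primary_lipid, _round_half_up(spec.n_primary_lipid * r2 / r1)


def snapshot_schedule(
    window_start_ns: float, window_end_ns: float, interval_ps: float
) -> tuple[int, list[float]]:
    """(count, times in ps) on the half-open window (start, end].

    The half-open start means a 10 ns window sampled every 50 ps yields
    exactly 200 snapshots. A window that does not divide evenly triggers a
    warning and the count is floored.
    """
    if window_end_ns <= window_start_ns:
        raise ConfigurationError("window_end must exceed window_start")
    if interval_ps <= 0:
        raise ConfigurationError("interval must be positive")
    span_ps = (window_end_ns - window_start_ns) * 1000.0
    ratio = span_ps / interval_ps
    count = int(math.floor(ratio + 1e-9))
    if abs(ratio - count) > 1e-9:
        warnings.warn(
            f"window of {span_ps} ps is not a multiple of {interval_ps} ps; "
            f"flooring to {count} snapshots",
            stacklevel=2,
        )
    start_ps = window_start_ns * 1000.0
    return count, [start_ps + interval_ps * (k + 1) for k in range(count)]
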