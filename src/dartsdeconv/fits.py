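"""Binding-parameter estimation from stabilization and saturation data.

Two models:

* Four-parameter logistic (4PL) dose-response,
  ``y = bottom + (top - bottom) / (1 + (ec50/x)^hill)``, for the DARTS
  dose series. The EC50 is the ligand concentration giving half-maximal
  protection. Fitted over log(EC50) and log(hill), with the span
  ``top - bottom`` kept positive by a log parameterization, so the curve is
  an increasing saturation in dose and EC50 estimates are scale-equivariant.

* Exact 1:1 binding isotherm for a saturation assay (e.g. microscale
  thermophoresis), ``signal = baseline + amplitude * fb(L; P, Kd)`` where
  ``fb`` is the bound fraction of protein from the quadratic mass-balance
  solution. In the dilute limit P -> 0 this reduces to L / (L + Kd).

Uncertainty is by seeded case-resampling bootstrap with percentile
intervals (default 500 resamples).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .errors import FitError

__all__ = [
    "DoseResponseFit",
    "IsothermFit",
    "four_pl",
    "fraction_bound",
    "fit_4pl",
    "fit_isotherm",
]


def four_pl(x, bottom: float, top: float, ec50: float, hill: float):
    """Four-parameter logistic response at dose(s) x."""
    x = np.asarray(x, dtype=float)
    with np.errstate(over="ignore"):  # extreme hill during optimization
        return bottom + (top - bottom) / (1.0 + (ec50 / x) ** hill)


def fraction_bound(ligand, protein_conc: float, kd: float):
    """Bound-protein fraction from the exact 1:1 quadratic isotherm.

    Solves P*fb^2 - (P + L + Kd)*fb + L = 0 for the physical root, written
    in the cancellation-free form 2L / (S + sqrt(S^2 - 4PL)) with
    S = P + L + Kd, which is stable in the dilute limit P -> 0.
    """
    if kd <= 0 or protein_conc <= 0:
        raise FitError("kd and protein_conc must be positive")
    L = np.asarray(ligand, dtype=float)
    if np.any(L < 0):
        raise FitError("ligand concentrations must be nonnegative")
    s = protein_conc + L + kd
    disc = s * s - 4.0 * protein_conc * L
    return 2.0 * L / (s + np.sqrt(np.maximum(disc, 0.0)))


@dataclass(frozen=True)
class DoseResponseFit:
    bottom: float
    top: float
    ec50: float
    hill: float
    rss: float
    ci: dict[str, tuple[float, float]] = field(default_factory=dict)

    def predict(self, x):
        return four_pl(x, self.bottom, self.top, self.ec50, self.hill)


@dataclass(frozen=True)
class IsothermFit:
    kd: float
    amplitude: float
    baseline: float
    protein_conc: float
    rss: float
    ci: dict[str, tuple[float, float]] = field(default_factory=dict)

    def predict(self, ligand):
        return self.baseline + self.amplitude * fraction_bound(
            ligand, self.protein_conc, self.kd
        )


def _solve(residual, theta0, what: str):
    r0 = residual(theta0)
    cost0 = 0.5 * float(r0 @ r0)
    res = least_squares(residual, theta0, method="lm", xtol=1e-14, ftol=1e-14, gtol=1e-14)
    if not res.success or not np.all(np.isfinite(res.x)):
        raise FitError(f"{what} fit did not converge: {res.message}")
    if res.cost > cost0 + 1e-12:
        raise FitError(f"{what} fit worsened the initial heuristic (rss increased)")
    return res


def _percentile_ci(samples: dict[str, list[float]]) -> dict[str, tuple[float, float]]:
    return {
        name: (float(np.percentile(v, 2.5)), float(np.percentile(v, 97.5)))
        for name, v in samples.items()
    }


def _validate_xy(x, y, min_distinct: int = 3):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise FitError("doses and responses must be 1-D arrays of equal length")
    if x.size < 5:
        raise FitError(f"need at least 5 points, got {x.size}")
    if np.unique(x).size < min_distinct:
        raise FitError(f"need at least {min_distinct} distinct x values")
    return x, y


def fit_4pl(
    doses,
    responses,
    fix_hill: float | None = None,
    n_boot: int = 500,
    seed: int | None = None,
) -> DoseResponseFit:
    """Least-squares 4PL fit; EC50 and hill are optimized in log space.

    ``fix_hill`` pins the hill slope (e.g. 1.0 for a simple binding
    isotherm); by default it is free. Bootstrap CIs are computed when
    ``n_boot > 0`` (case resampling, percentile intervals, seeded).
    """
    x, y = _validate_xy(doses, responses)
    if np.any(x <= 0):
        raise FitError("doses must be strictly positive")

    span0 = max(float(np.max(y) - np.min(y)), 1e-9)
    bottom0 = float(np.min(y))
    half = bottom0 + span0 / 2.0
    above = x[y >= half]
    ec50_0 = float(above.min()) if above.size else float(np.median(x))

    def unpack(theta):
        bottom, log_span, log_ec50 = theta[0], theta[1], theta[2]
        hill = fix_hill if fix_hill is not None else np.exp(theta[3])
        return bottom, bottom + np.exp(log_span), np.exp(log_ec50), hill

    def make_residual(xv, yv):
        def residual(theta):
            b, t, e, h = unpack(theta)
            return four_pl(xv, b, t, e, h) - yv

        return residual

    theta0 = [bottom0, np.log(span0), np.log(ec50_0)]
    if fix_hill is None:
        theta0.append(0.0)  # hill = 1
    theta0 = np.asarray(theta0, dtype=float)

    res = _solve(make_residual(x, y), theta0, "4PL")
    b, t, e, h = unpack(res.x)
    fit = DoseResponseFit(bottom=float(b), top=float(t), ec50=float(e), hill=float(h),
                          rss=float(2.0 * res.cost))
    if n_boot <= 0:
        return fit
    rng = np.random.default_rng(seed)
    samples: dict[str, list[float]] = {k: [] for k in ("bottom", "top", "ec50", "hill")}
    for _ in range(n_boot):
        idx = rng.integers(0, x.size, size=x.size)
        try:
            r = _solve(make_residual(x[idx], y[idx]), res.x, "4PL bootstrap")
        except FitError:
            continue  # degenerate resample; skip
        bb, tt, ee, hh = unpack(r.x)
        for k, v in zip(("bottom", "top", "ec50", "hill"), (bb, tt, ee, hh)):
            samples[k].append(float(v))
    ci = _percentile_ci({k: v for k, v in samples.items() if v})
    return DoseResponseFit(fit.bottom, fit.top, fit.ec50, fit.hill, fit.rss, ci)


def fit_isotherm(
    ligand,
    signal,
    protein_conc: float,
    n_boot: int = 500,
    seed: int | None = None,
) -> IsothermFit:
    """Least-squares fit of the exact 1:1 quadratic isotherm.

    The protein concentration is a fixed experimental input, not a fitted
    parameter. Kd is optimized in log space; amplitude and baseline are
    free (the signal may rise or fall with binding).
    """
    L, y = _validate_xy(ligand, signal)
    if protein_conc <= 0:
        raise FitError("protein_conc must be positive")
    if np.any(L < 0):
        raise FitError("ligand concentrations must be nonnegative")

    baseline0 = float(y[np.argmin(L)])
    amp0 = float(y[np.argmax(L)] - baseline0)
    if amp0 == 0.0:
        amp0 = 1e-6
    pos = L[L > 0]
    kd0 = float(np.median(pos)) if pos.size else 1.0

    def unpack(theta):
        return theta[0], theta[1], np.exp(theta[2])  # baseline, amplitude, kd

    def make_residual(Lv, yv):
        def residual(theta):
            base, amp, kd = unpack(theta)
            return base + amp * fraction_bound(Lv, protein_conc, kd) - yv

        return residual

    theta0 = np.asarray([baseline0, amp0, np.log(kd0)], dtype=float)
    res = _solve(make_residual(L, y), theta0, "isotherm")
    base, amp, kd = unpack(res.x)
    fit = IsothermFit(kd=float(kd), amplitude=float(amp), baseline=float(base),
                      protein_conc=float(protein_conc), rss=float(2.0 * res.cost))
    if n_boot <= 0:
        return fit
    rng = np.random.default_rng(seed)
    samples: dict[str, list[float]] = {k: [] for k in ("kd", "amplitude", "baseline")}
    for _ in range(n_boot):
        idx = rng.integers(0, L.size, size=L.size)
        try:
            r = _solve(make_residual(L[idx], y[idx]), res.x, "isotherm bootstrap")
        except FitError:
            continue
        bb, aa, kk = unpack(r.x)
        for k, v in zip(("baseline", "amplitude", "kd"), (bb, aa, kk)):
            samples[k].append(float(v))
    ci = _percentile_ci({k: v for k, v in samples.items() if v})
    return IsothermFit(fit.kd, fit.amplitude, fit.baseline, fit.protein_conc, fit.rss, ci)
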