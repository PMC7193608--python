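"""Scalp/skull conductivity calibration against measured strip fields.

Only the scalp and skull conductivities are free, each bounded by the range
reported across the literature (skull 0.0028-0.08 S/m, scalp 0.0002-1.0 S/m);
all other tissues stay at the active conductivity set.  The objective blends
the two published criteria — agreement (normalized RMS difference) and linear
correlation (Pearson R) between measured and simulated strip fields — as
``w1 * (1 - R) + w2 * RMS / SD(measured)``, computed on a pool in which each
montage's values are first scaled by the SD of its own measurements (scalp
and brain-surface strips differ by orders of magnitude).

With current-controlled stimulation, brain-surface fields alone constrain
essentially only the scalp/skull conductivity *ratio* (the shunt split);
including at least one scalp-layer strip pins the absolute scale.

The search is a coarse log-spaced grid over the bounded box followed by
bounded Nelder-Mead refinement from the best grid point; every grid
evaluation is retained for audit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dc_field
from typing import Sequence

import numpy as np
from scipy import optimize, stats

from .forward import field_along_strip, solve_potential, strip_pair_fields
from .geometry import ConfigurationError, Montage, StripSpec, TissueModel

__all__ = [
    "CalibrationProblem",
    "CalibrationResult",
    "DEFAULT_BOUNDS",
    "simulate_strip_fields",
    "objective",
    "calibrate",
    "validate",
]

DEFAULT_BOUNDS = {"scalp": (0.0002, 1.0), "skull": (0.0028, 0.08)}


@dataclass
class CalibrationProblem:
    """Measured strip fields plus the model/montage context to fit them.

    ``measured_fields`` holds one per-pair field array (mV/mm) per montage.
    ``truth`` is a sealed audit field populated only by the synthetic
    generator; the calibration itself never reads it.
    """

    model: TissueModel
    montages: Sequence[Montage]
    strips: Sequence[StripSpec]
    measured_fields: Sequence[np.ndarray]
    bounds: dict = dc_field(default_factory=lambda: dict(DEFAULT_BOUNDS))
    weights: tuple = (0.5, 0.5)
    truth: dict | None = None

    def __post_init__(self):
        if not (len(self.montages) == len(self.strips) == len(self.measured_fields)):
            raise ConfigurationError("montages, strips and measurements must align")
        if len(self.montages) < 1:
            raise ConfigurationError("need at least one montage")
        for lo, hi in self.bounds.values():
            if not 0 < lo < hi:
                raise ConfigurationError("bounds must be positive and ordered")
        pooled = np.concatenate([np.asarray(m) for m in self.measured_fields])
        if len(pooled) < 2:
            raise ConfigurationError("need >= 2 measured contact-pair values")

    def pooled_measured(self) -> np.ndarray:
        return np.concatenate([np.asarray(m, dtype=float) for m in self.measured_fields])

    def to_json(self) -> str:
        return json.dumps(
            {
                "bounds_S_per_m": self.bounds,
                "weights": list(self.weights),
                "n_montages": len(self.montages),
                "measured_fields_mV_per_mm": [np.asarray(m).tolist() for m in self.measured_fields],
            },
            indent=2,
        )


@dataclass(frozen=True)
class CalibrationResult:
    sigma_scalp: float
    sigma_skull: float
    objective_value: float
    pearson_r: float
    rms_normalized: float  # RMS of per-montage SD-normalized residuals
    n_forward_solves: int
    converged: str  # "converged" | "boundary"
    grid_audit: tuple = ()  # rows of (sigma_scalp, sigma_skull, objective, R, rms)

    def to_json(self) -> str:
        return json.dumps(
            {
                "sigma_scalp_S_per_m": self.sigma_scalp,
                "sigma_skull_S_per_m": self.sigma_skull,
                "objective": self.objective_value,
                "pearson_r": self.pearson_r,
                "rms_normalized": self.rms_normalized,
                "n_forward_solves": self.n_forward_solves,
                "converged": self.converged,
            },
            indent=2,
        )


def _with_sigmas(model: TissueModel, sigma_scalp: float, sigma_skull: float) -> TissueModel:
    cs = model.conductivities.with_updates(
        provenance="calibration-trial", scalp=sigma_scalp, skull=sigma_skull
    )
    from dataclasses import replace

    return replace(model, conductivities=cs)


def simulate_strip_fields(model: TissueModel, montage: Montage,
                          strip: StripSpec) -> np.ndarray:
    """Forward-solve a montage and return the per-pair strip fields (mV/mm)."""
    montage = Montage(model=model, patches=montage.patches,
                      footprints=montage.footprints)
    sol = solve_potential(model, montage)
    pots = field_along_strip(sol, strip)
    return strip_pair_fields(pots, strip.spacing_mm)


def _normalized_pool(sims: Sequence[np.ndarray], measured: Sequence[np.ndarray]):
    """Scale each montage's simulated/measured pair by SD(measured) before
    pooling, so montages recorded in very different field magnitudes (e.g.
    scalp-layer vs brain-surface strips) contribute comparably."""
    s_all, m_all = [], []
    for s, m in zip(sims, measured):
        m = np.asarray(m, dtype=float)
        sd = np.std(m)
        scale = sd if sd > 0 else max(float(np.mean(np.abs(m))), 1e-12)
        s_all.append(np.asarray(s, dtype=float) / scale)
        m_all.append(m / scale)
    return np.concatenate(s_all), np.concatenate(m_all)


def _misfit(simulated: np.ndarray, measured: np.ndarray, weights):
    w1, w2 = weights
    sd = np.std(measured)
    rms = float(np.sqrt(np.mean((simulated - measured) ** 2)))
    degenerate = sd == 0 or np.std(simulated) == 0
    if degenerate:
        r = np.nan
        scale = sd if sd > 0 else max(np.mean(np.abs(measured)), 1e-12)
        return (w1 + w2) * rms / scale, r, rms, True
    r, _ = stats.pearsonr(simulated, measured)
    return w1 * (1.0 - r) + w2 * rms / sd, float(r), rms, False


def objective(params, problem: CalibrationProblem, _counter: list | None = None):
    """Calibration misfit at (sigma_scalp, sigma_skull); lower is better.

    Deterministic given the parameters.  When the measured values have zero
    variance the correlation term is undefined and the objective falls back
    to RMS only (flag reported by ``calibrate``).
    """
    sigma_scalp, sigma_skull = params
    lo_sc, hi_sc = problem.bounds["scalp"]
    lo_sk, hi_sk = problem.bounds["skull"]
    if not (lo_sc <= sigma_scalp <= hi_sc and lo_sk <= sigma_skull <= hi_sk):
        raise ConfigurationError("parameters outside the calibration bounds")
    model = _with_sigmas(problem.model, sigma_scalp, sigma_skull)
    sims = []
    for montage, strip in zip(problem.montages, problem.strips):
        sims.append(simulate_strip_fields(model, montage, strip))
        if _counter is not None:
            _counter[0] += 1
    simulated, measured = _normalized_pool(sims, problem.measured_fields)
    value, _, _, _ = _misfit(simulated, measured, problem.weights)
    return value


def calibrate(problem: CalibrationProblem, grid_shape: tuple = (9, 9),
              refine: bool = True, xatol_rel: float = 1e-3) -> CalibrationResult:
    """Two-stage bounded search: coarse log-space grid, then Nelder-Mead.

    Grid points where the forward model fails are skipped (and recorded with
    an infinite objective); the result is flagged ``"boundary"`` when a fitted
    parameter lands within 1% (log-scale) of a bound.
    """
    lo_sc, hi_sc = problem.bounds["scalp"]
    lo_sk, hi_sk = problem.bounds["skull"]
    sc_grid = np.geomspace(lo_sc, hi_sc, grid_shape[0])
    sk_grid = np.geomspace(lo_sk, hi_sk, grid_shape[1])
    counter = [0]

    audit = []
    best = (np.inf, None)
    for sc in sc_grid:
        for sk in sk_grid:
            try:
                model = _with_sigmas(problem.model, sc, sk)
                sims = []
                for montage, strip in zip(problem.montages, problem.strips):
                    sims.append(simulate_strip_fields(model, montage, strip))
                    counter[0] += 1
                sim_n, meas_n = _normalized_pool(sims, problem.measured_fields)
                value, r, rms, _ = _misfit(sim_n, meas_n, problem.weights)
            except Exception:
                audit.append((float(sc), float(sk), np.inf, np.nan, np.nan))
                continue
            audit.append((float(sc), float(sk), float(value), r, rms))
            if value < best[0]:
                best = (value, (float(sc), float(sk)))
    if best[1] is None:
        raise ConfigurationError("forward model failed at every grid point")

    x = np.array(best[1])
    if refine:
        log_lo = np.log([lo_sc, lo_sk])
        log_hi = np.log([hi_sc, hi_sk])

        def wrapped(logp):
            # quadratic out-of-bounds penalty (in log units) instead of a
            # silent clip: a flat plateau at the bound stalls Nelder-Mead
            clipped = np.clip(logp, log_lo, log_hi)
            penalty = float(np.sum((logp - clipped) ** 2))
            try:
                return objective(np.exp(clipped), problem, counter) + penalty
            except ConfigurationError:
                return np.inf

        res = optimize.minimize(
            wrapped, np.log(x), method="Nelder-Mead",
            options={"xatol": xatol_rel, "fatol": 1e-9, "maxiter": 200},
        )
        x = np.exp(res.x)
        x[0] = np.clip(x[0], lo_sc, hi_sc)
        x[1] = np.clip(x[1], lo_sk, hi_sk)

    model = _with_sigmas(problem.model, *x)
    sims = [
        simulate_strip_fields(model, m, s)
        for m, s in zip(problem.montages, problem.strips)
    ]
    counter[0] += len(problem.montages)
    sim_n, meas_n = _normalized_pool(sims, problem.measured_fields)
    value, r, rms, degenerate = _misfit(sim_n, meas_n, problem.weights)

    def near_bound(v, lo, hi):
        return (np.log(v / lo) < 0.01 * np.log(hi / lo)
                or np.log(hi / v) < 0.01 * np.log(hi / lo))

    flag = "boundary" if (near_bound(x[0], lo_sc, hi_sc)
                          or near_bound(x[1], lo_sk, hi_sk)) else "converged"
    return CalibrationResult(
        sigma_scalp=float(x[0]), sigma_skull=float(x[1]),
        objective_value=float(value),
        pearson_r=float(r) if not degenerate else np.nan,
        rms_normalized=float(rms),
        n_forward_solves=counter[0], converged=flag,
        grid_audit=tuple(audit),
    )


def validate(result: CalibrationResult, problem: CalibrationProblem):
    """Predict held-out strip fields with the fitted conductivities.

    ``problem`` must hold montages disjoint from those used in calibration.
    Returns ``(pearson_r, rms_normalized, table)`` where ``table`` pairs each
    measured value with its prediction (for scatter plotting); the statistics
    are computed on per-montage SD-normalized values.
    """
    if len(problem.pooled_measured()) < 2:
        raise ConfigurationError("need >= 2 held-out values (correlation undefined)")
    model = _with_sigmas(problem.model, result.sigma_scalp, result.sigma_skull)
    sims = [
        simulate_strip_fields(model, m, s)
        for m, s in zip(problem.montages, problem.strips)
    ]
    sims_n, measured_n = _normalized_pool(sims, problem.measured_fields)
    if np.std(measured_n) == 0 or np.std(sims_n) == 0:
        raise ConfigurationError("held-out values are degenerate (zero variance)")
    r, _ = stats.pearsonr(sims_n, measured_n)
    rms = float(np.sqrt(np.mean((sims_n - measured_n) ** 2)))
    table = np.column_stack([problem.pooled_measured(), np.concatenate(sims)])
    return float(r), rms, table
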