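"""Model-data agreement metrics and bounded parameter fitting.

Goodness of fit uses two statistics:

* per-species coefficient of determination R^2 = 1 - SSE/TSS, with TSS
  taken about the observation mean (the conventional reading; a literal
  variant using the model mean is available behind ``tss_about``),
* a mean-normalized total SSE across the four headspace species,
  SSE_total = sum_species sum_t (C_obs - C_model)^2 / mean(C_obs),
  which prevents the millimolar species from drowning out the nanomolar NO.

Fitting minimizes SSE_total over a named subset of kinetic / synthesis /
physical parameters with box bounds, simulating the flask per candidate.
The optimizer is a bounded Nelder-Mead simplex with optional multi-start;
any bounded local method suits the (smooth, low-dimensional) problem.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import minimize

from .kinetics import EnzymeSynthesisParams, KineticParams, PhysicalParams
from .reactor import ExperimentConfig, Trajectory, simulate

__all__ = [
    "GAS_SPECIES",
    "MeasurementSet",
    "FitResult",
    "r_squared",
    "sse_normalized",
    "fit_parameters",
    "apply_parameters",
    "parameter_value",
]

GAS_SPECIES = ("O2", "NO", "N2O", "CO2")


@dataclass
class MeasurementSet:
    """Sampled observations of one flask experiment.

    ``series`` maps a species label (headspace ``O2``/``NO``/``N2O``/``CO2``,
    optionally liquid ``NO2_liquid`` or enzyme proxies) to ``(times, values)``
    arrays.  Gas values are stored in M of gas phase; ``units`` records the
    original unit per species.
    """

    series: Dict[str, Tuple[np.ndarray, np.ndarray]]
    units: Dict[str, str] = field(default_factory=dict)
    provenance: str = ""

    def __post_init__(self) -> None:
        if not any(v[0].size for v in self.series.values()):
            raise ValueError("measurement set is empty")
        for name, (t, v) in self.series.items():
            t = np.asarray(t, dtype=float)
            v = np.asarray(v, dtype=float)
            if t.shape != v.shape:
                raise ValueError(f"{name}: time and value lengths differ")
            if np.any(np.diff(t) < 0):
                raise ValueError(f"{name}: times must be nondecreasing")
            if np.any(v < 0):
                raise ValueError(f"{name}: negative measurement")
            self.series[name] = (t, v)

    def species(self) -> List[str]:
        return list(self.series)

    def __getitem__(self, name: str) -> Tuple[np.ndarray, np.ndarray]:
        return self.series[name]


def r_squared(
    model: np.ndarray, obs: np.ndarray, tss_about: str = "obs"
) -> float:
    """Coefficient of determination 1 - SSE/TSS (may be negative).

    ``tss_about`` selects the mean used in the total sum of squares:
    ``"obs"`` (conventional) or ``"model"``.
    """
    model = np.asarray(model, dtype=float)
    obs = np.asarray(obs, dtype=float)
    if obs.size < 2:
        raise ValueError("R^2 needs at least two observations")
    center = obs.mean() if tss_about == "obs" else model.mean()
    tss = float(np.sum((obs - center) ** 2))
    if tss == 0.0:
        raise ValueError("R^2 undefined: zero variance in observations")
    sse = float(np.sum((obs - model) ** 2))
    return 1.0 - sse / tss


def _model_at(traj: Trajectory, species: str, times: np.ndarray) -> np.ndarray:
    """Model headspace series linearly interpolated to observation times."""
    return np.interp(times, traj.time, traj.headspace(species, unit="M"))


def sse_normalized(
    traj: Trajectory, obs: MeasurementSet
) -> Tuple[Dict[str, float], float]:
    """Per-species mean-normalized SSE and their total over the gas species."""
    per: Dict[str, float] = {}
    for sp in GAS_SPECIES:
        if sp not in obs.series:
            raise ValueError(f"measurement set lacks headspace species {sp}")
        t, v = obs[sp]
        m = _model_at(traj, sp, t)
        resid = float(np.sum((v - m) ** 2))
        mean = float(v.mean())
        if mean == 0.0:
            if resid == 0.0:
                per[sp] = 0.0
                continue
            raise ValueError(f"{sp}: zero observation mean with nonzero residuals")
        per[sp] = resid / mean
    return per, sum(per.values())


@dataclass
class FitResult:
    """Outcome of a bounded parameter fit."""

    parameters: Dict[str, float]
    bounds: Dict[str, Tuple[float, float]]
    sse_initial: float
    sse_total: float
    sse_per_species: Dict[str, float]
    r2_per_species: Dict[str, float]
    n_iterations: int
    n_simulations: int
    converged: bool
    seed: Optional[int]
    at_bound: List[str] = field(default_factory=list)
    message: str = ""


_PARAM_BLOCKS = {
    KineticParams: set(KineticParams.__dataclass_fields__),
    EnzymeSynthesisParams: {
        f for f in EnzymeSynthesisParams.__dataclass_fields__
        if f not in ("use_o2_nor_term", "o2_nor_mode")
    },
    PhysicalParams: set(PhysicalParams.__dataclass_fields__),
}


def _locate(name: str, kin, syn, phys):
    if name in _PARAM_BLOCKS[KineticParams]:
        return "kin"
    if name in _PARAM_BLOCKS[EnzymeSynthesisParams]:
        return "syn"
    if name in _PARAM_BLOCKS[PhysicalParams]:
        return "phys"
    raise KeyError(f"unknown parameter {name!r}")


def parameter_value(name: str, kin: KineticParams, syn: EnzymeSynthesisParams,
                    phys: PhysicalParams) -> float:
    """Look up a parameter by name across the three blocks."""
    block = _locate(name, kin, syn, phys)
    return getattr({"kin": kin, "syn": syn, "phys": phys}[block], name)


def apply_parameters(
    values: Mapping[str, float],
    kin: KineticParams,
    syn: EnzymeSynthesisParams,
    phys: PhysicalParams,
) -> Tuple[KineticParams, EnzymeSynthesisParams, PhysicalParams]:
    """Return copies of the parameter blocks with named values replaced."""
    kin_up = {n: v for n, v in values.items()
              if _locate(n, kin, syn, phys) == "kin"}
    syn_up = {n: v for n, v in values.items()
              if _locate(n, kin, syn, phys) == "syn"}
    phys_up = {n: v for n, v in values.items()
               if _locate(n, kin, syn, phys) == "phys"}
    return (
        replace(kin, **kin_up) if kin_up else kin,
        replace(syn, **syn_up) if syn_up else syn,
        replace(phys, **phys_up) if phys_up else phys,
    )


def fit_parameters(
    obs: MeasurementSet,
    config: ExperimentConfig,
    free: Sequence[str],
    bounds: Mapping[str, Tuple[float, float]],
    init: Optional[Mapping[str, float]] = None,
    kin: Optional[KineticParams] = None,
    syn: Optional[EnzymeSynthesisParams] = None,
    phys: Optional[PhysicalParams] = None,
    seed: Optional[int] = None,
    n_starts: int = 1,
    maxiter: int = 400,
    xatol_rel: float = 1e-4,
    fatol_rel: float = 1e-8,
) -> FitResult:
    """Fit the named free parameters to headspace observations.

    Minimizes SSE_total by simulating the configured flask per candidate.
    Deterministic for a given ``seed`` and ``init``; candidates whose
    simulation fails are penalized, not fatal.  Additional starts beyond
    the first are drawn log-uniformly inside the bounds from ``seed``.
    """
    kin = kin or KineticParams()
    syn = syn or EnzymeSynthesisParams()
    phys = phys or PhysicalParams()
    free = list(free)
    for name in free:
        _locate(name, kin, syn, phys)
        if name not in bounds:
            raise ValueError(f"no bounds given for free parameter {name!r}")
        lo, hi = bounds[name]
        if not (np.isfinite(lo) and np.isfinite(hi) and 0 < lo < hi):
            raise ValueError(f"bounds for {name!r} must be finite, positive, lo < hi")

    init_vals = {
        name: (init[name] if init and name in init
               else parameter_value(name, kin, syn, phys))
        for name in free
    }
    for name, v in init_vals.items():
        lo, hi = bounds[name]
        init_vals[name] = min(max(v, lo), hi)

    scale = np.array([init_vals[n] for n in free])
    lo = np.array([bounds[n][0] for n in free]) / scale
    hi = np.array([bounds[n][1] for n in free]) / scale

    n_sim = 0
    failures: List[str] = []

    def objective(x: np.ndarray) -> float:
        nonlocal n_sim
        vals = {n: float(v) for n, v in zip(free, x * scale)}
        k, s, p = apply_parameters(vals, kin, syn, phys)
        n_sim += 1
        try:
            traj = simulate(config, k, s, p)
        except (RuntimeError, FloatingPointError, ValueError) as exc:
            failures.append(f"{vals}: {exc}")
            return 1e12
        _, total = sse_normalized(traj, obs)
        return total

    x0 = np.ones(len(free))
    f0 = objective(x0)

    starts = [x0]
    if n_starts > 1:
        rng = np.random.default_rng(seed)
        draws = np.exp(
            rng.uniform(np.log(lo), np.log(hi), size=(n_starts - 1, len(free)))
        )
        starts.extend(list(np.clip(draws, lo, hi)))

    best = None
    total_iter = 0
    for x_start in starts:
        res = minimize(
            objective,
            x_start,
            method="Nelder-Mead",
            bounds=list(zip(lo, hi)),
            options={
                "maxiter": maxiter,
                "xatol": xatol_rel,
                "fatol": fatol_rel * max(f0, 1e-300),
                "adaptive": True,
            },
        )
        total_iter += res.nit
        if best is None or res.fun < best.fun:
            best = res
    assert best is not None

    if len(failures) == n_sim and n_sim > 0:
        raise RuntimeError(f"all {n_sim} candidate simulations failed; "
                           f"first: {failures[0]}")

    # never report a point worse than the start
    if best.fun > f0:
        x_best, f_best = x0, f0
    else:
        x_best, f_best = best.x, best.fun

    fitted = {n: float(v) for n, v in zip(free, x_best * scale)}
    k, s, p = apply_parameters(fitted, kin, syn, phys)
    traj = simulate(config, k, s, p)
    per, total = sse_normalized(traj, obs)
    r2 = {}
    for sp in GAS_SPECIES:
        t, v = obs[sp]
        try:
            r2[sp] = r_squared(_model_at(traj, sp, t), v)
        except ValueError:
            r2[sp] = float("nan")

    at_bound = []
    for name in free:
        b_lo, b_hi = bounds[name]
        v = fitted[name]
        span = b_hi - b_lo
        if v - b_lo < 1e-6 * span or b_hi - v < 1e-6 * span:
            at_bound.append(name)

    return FitResult(
        parameters=fitted,
        bounds={n: tuple(bounds[n]) for n in free},
        sse_initial=f0,
        sse_total=total,
        sse_per_species=per,
        r2_per_species=r2,
        n_iterations=total_iter,
        n_simulations=n_sim,
        converged=bool(best.success),
        seed=seed,
        at_bound=at_bound,
        message=str(best.message),
    )
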