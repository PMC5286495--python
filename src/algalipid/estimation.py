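"""Staged least-squares estimation of the eight model parameters.

Estimation mirrors how the model was calibrated: a first stage fits the
five growth/uptake parameters (mu_max, h0, vm, KN, Xmax) to the biomass
and external-nitrogen time series by bounded nonlinear least squares,
integrating the ODE system for every candidate; a second stage then fits
the three composition parameters (k, c, phi) to the lipid series with the
stage-1 trajectory held fixed.  A joint eight-parameter mode is available
for comparison.

Residuals in stage 1 are scaled by each series' observation standard
deviation so biomass (up to ~7 g/L) and nitrogen (down to 0) contribute
comparably to the objective.  A seeded multistart guards against the
nonconvex coupling between mu_max and h0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .kinetics import SimulationError, simulate
from .params import BatchState, CompositionParams, KineticParams

__all__ = [
    "FitConfig",
    "FitResult",
    "FitError",
    "fit_growth_uptake",
    "fit_lipid",
    "fit_staged",
    "fit_joint",
    "fit_condition_set",
    "OBS_COLUMNS",
]

#: required columns of an observations table
OBS_COLUMNS = ("t_days", "replicate", "X", "N", "L")

STAGE1_PARAMS = ("mu_max", "h0", "vm", "KN", "Xmax")
STAGE2_PARAMS = ("k", "c", "phi")

#: default parameter bounds; they cover every bundled per-condition value
#: with margin.  Xmax bounds are data-driven (see FitConfig.resolve_bounds).
DEFAULT_BOUNDS = {
    "mu_max": (0.01, 2.0),
    "h0": (-5.0, 5.0),
    "vm": (1e-3, 2.0),
    "KN": (1e-4, 1.0),
    "Xmax": None,  # (0.5 * max observed X, 10 * max observed X); the slack
    # below the observed maximum leaves room for positive measurement error
    # on the largest observations, which would otherwise bias Xmax upward
    "k": (0.1, 5.0),
    "c": (0.0, 0.8),
    "phi": (0.0, 0.5),
}

#: parameters sampled log-uniformly in multistart (strictly positive, wide range)
_LOG_SAMPLED = {"mu_max", "vm", "KN"}


class FitError(RuntimeError):
    """No multistart run converged; carries the best objective found."""

    def __init__(self, message: str, best_objective: float | None = None):
        super().__init__(message)
        self.best_objective = best_objective


@dataclass(frozen=True)
class FitConfig:
    """Configuration of the staged estimator.

    ``bounds`` entries override the defaults per parameter name.  ``weights``
    are extra multipliers applied to the SD-scaled X and N residual blocks.
    """

    bounds: dict = field(default_factory=dict)
    initial: dict = field(default_factory=dict)
    multistart: int = 8
    seed: int = 0
    weights: dict = field(default_factory=lambda: {"X": 1.0, "N": 1.0})
    ftol: float = 1e-12
    xtol: float = 1e-12
    gtol: float = 1e-12
    max_nfev: int = 1000
    joint: bool = False

    def __post_init__(self):
        if self.multistart < 1:
            raise ValueError("multistart must be >= 1")
        for name, bnd in self.bounds.items():
            if name not in DEFAULT_BOUNDS:
                raise ValueError(f"unknown parameter in bounds: {name!r}")
            if bnd is not None and not bnd[0] < bnd[1]:
                raise ValueError(f"bounds for {name!r} must satisfy lo < hi")

    def resolve_bounds(self, name: str, x_obs_max: float | None = None):
        bnd = self.bounds.get(name, DEFAULT_BOUNDS[name])
        if bnd is None:  # data-driven Xmax default
            if x_obs_max is None or x_obs_max <= 0:
                raise ValueError("Xmax bounds need a positive max observed X")
            bnd = (0.5 * x_obs_max, 10.0 * x_obs_max)
        return bnd


@dataclass(frozen=True)
class FitResult:
    """Estimates, goodness of fit and convergence metadata of one condition."""

    kinetic: KineticParams
    composition: CompositionParams | None
    state: BatchState
    r_squared: dict
    residuals: dict
    objective: float
    converged: bool
    n_evaluations: int
    multistart_objectives: tuple
    warnings: tuple
    frozen: dict = field(default_factory=dict)

    @property
    def params(self) -> dict:
        out = {p: getattr(self.kinetic, p) for p in STAGE1_PARAMS}
        if self.composition is not None:
            out.update({p: getattr(self.composition, p) for p in STAGE2_PARAMS})
        return out


def _as_table(data) -> pd.DataFrame:
    if isinstance(data, pd.DataFrame):
        df = data
    else:
        df = pd.DataFrame(data)
    missing = set(OBS_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"observations missing columns: {sorted(missing)}")
    return df.sort_values(["replicate", "t_days"], kind="mergesort").reset_index(drop=True)


def _initial_state(df: pd.DataFrame, x0, n0) -> BatchState:
    t0 = df["t_days"].min()
    if t0 != 0:
        raise ValueError("observations must include t = 0 (or pass x0/n0 explicitly)")
    first = df[df["t_days"] == t0]
    if x0 is None:
        x0 = float(first["X"].dropna().mean())
    if n0 is None:
        n0 = float(first["N"].dropna().mean())
    if not (math.isfinite(x0) and math.isfinite(n0)):
        raise ValueError("cannot infer (X0, N0) from t = 0 observations")
    return BatchState(X0=x0, N0=max(n0, 0.0))


def _series_scale(values: np.ndarray) -> float:
    sd = float(np.std(values, ddof=1)) if len(values) > 1 else 0.0
    m = float(np.abs(values).mean())
    # an (effectively) constant series gets its magnitude as scale; the
    # relative floor guards against pure roundoff jitter posing as spread
    if sd > 1e-8 * max(m, 1.0):
        return sd
    return m if m > 0 else 1.0


def _heuristic_start(df, state, bounds):
    """Data-driven stage-1 starting point, clipped inside the bounds."""
    xt = df[["t_days", "X"]].dropna().groupby("t_days").mean()
    t, x = xt.index.to_numpy(float), xt["X"].to_numpy(float)
    mu0 = 0.3
    early = (x > 0) & (t <= max(t.max() / 3.0, t[min(3, len(t) - 1)]))
    if early.sum() >= 2:
        slope = np.polyfit(t[early], np.log(x[early]), 1)[0]
        if math.isfinite(slope) and slope > 0:
            mu0 = slope
    nt = df[["t_days", "N"]].dropna()
    vm0 = 0.3
    if len(nt) and len(x) > 1:
        consumed = state.N0 - float(nt.groupby("t_days").mean()["N"].min())
        integral = float(np.trapezoid(x, t))
        if consumed > 0 and integral > 0:
            vm0 = consumed / integral
    start = {
        "mu_max": mu0,
        "h0": 0.0,
        "vm": vm0,
        "KN": max(0.1 * state.N0, 2 * bounds["KN"][0]),
        "Xmax": 1.05 * float(df["X"].dropna().max()),
    }
    return {
        name: float(np.clip(start[name], bounds[name][0] * 1.0000001, bounds[name][1] * 0.9999999))
        for name in STAGE1_PARAMS
    }


def _sample_start(rng, names, bounds):
    out = {}
    for name in names:
        lo, hi = bounds[name]
        if name in _LOG_SAMPLED and lo > 0:
            out[name] = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
        else:
            out[name] = float(rng.uniform(lo, hi))
    return out


def _r2(obs: np.ndarray, model: np.ndarray) -> float:
    ss_tot = float(np.sum((obs - obs.mean()) ** 2))
    ss_res = float(np.sum((obs - model) ** 2))
    floor = (1e-8 * max(1.0, float(np.abs(obs).mean()))) ** 2 * len(obs)
    if ss_tot <= floor:  # constant observed series: R^2 undefined
        return 1.0 if ss_res <= floor else -np.inf
    return 1.0 - ss_res / ss_tot


def _bound_warnings(names, values, bounds):
    out = []
    for name, v in zip(names, values):
        lo, hi = bounds[name]
        span = hi - lo
        if min(v - lo, hi - v) < 1e-6 * span:
            out.append(f"estimate of {name} sits on a bound [{lo:g}, {hi:g}]: "
                       "parameter may be unidentifiable from these data")
    return out


def _run_multistart(residual_fn, starts, names, bounds, cfg):
    lo = np.array([bounds[n][0] for n in names])
    hi = np.array([bounds[n][1] for n in names])
    best, objectives, n_eval = None, [], 0
    for start in starts:
        x0 = np.array([start[n] for n in names])
        try:
            res = least_squares(
                residual_fn,
                x0,
                bounds=(lo, hi),
                method="trf",
                x_scale="jac",
                ftol=cfg.ftol,
                xtol=cfg.xtol,
                gtol=cfg.gtol,
                max_nfev=cfg.max_nfev,
            )
        except (SimulationError, ValueError):
            objectives.append(math.inf)
            continue
        n_eval += res.nfev
        objectives.append(float(res.cost))
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        raise FitError("no multistart run converged", best_objective=None)
    return best, objectives, n_eval


def fit_growth_uptake(
    data,
    cfg: FitConfig | None = None,
    *,
    x0: float | None = None,
    n0: float | None = None,
    freeze: dict | None = None,
) -> FitResult:
    """Stage 1: estimate (mu_max, h0, vm, KN, Xmax) from X and N time series.

    Parameters
    ----------
    data : DataFrame-like with columns t_days, replicate, X, N, L
        Replicate-stacked observations; N (and L) cells may be missing.
    cfg : FitConfig, optional
    x0, n0 : float, optional
        Initial condition; inferred from the mean of the t = 0 observations
        when omitted.
    freeze : dict, optional
        Stage-1 parameters to hold fixed (e.g. ``{"vm": 0.285, "KN": 0.198}``
        transferred from another condition's fit).

    Returns
    -------
    FitResult with ``composition=None`` (stage 2 pending).
    """
    cfg = cfg or FitConfig()
    freeze = dict(freeze or {})
    df = _as_table(data)
    x_obs = df[["t_days", "X"]].dropna()
    n_obs = df[["t_days", "N"]].dropna()
    if len(x_obs) < 4 or len(n_obs) < 4:
        raise ValueError("need >= 4 time points each for X and N")
    state = _initial_state(df, x0, n0)

    x_max_obs = float(x_obs["X"].max())
    bounds = {n: cfg.resolve_bounds(n, x_max_obs) for n in STAGE1_PARAMS}
    free_names = [n for n in STAGE1_PARAMS if n not in freeze]
    if not free_names:
        raise ValueError("all stage-1 parameters frozen; nothing to fit")

    t_fit = np.unique(np.concatenate([[0.0], x_obs["t_days"].to_numpy(), n_obs["t_days"].to_numpy()]))
    ix_x = np.searchsorted(t_fit, x_obs["t_days"].to_numpy())
    ix_n = np.searchsorted(t_fit, n_obs["t_days"].to_numpy())
    xv = x_obs["X"].to_numpy(float)
    nv = n_obs["N"].to_numpy(float)
    sx = _series_scale(xv) / cfg.weights.get("X", 1.0)
    sn = _series_scale(nv) / cfg.weights.get("N", 1.0)
    comp0 = CompositionParams(k=1.0, c=0.0, phi=0.0)  # placeholder; unused by X/N

    def make_kinetic(theta):
        p = dict(freeze)
        p.update(dict(zip(free_names, theta)))
        return KineticParams(**p)

    def residual(theta):
        traj = simulate(make_kinetic(theta), comp0, state, t_fit)
        return np.concatenate([(traj.X[ix_x] - xv) / sx, (traj.N[ix_n] - nv) / sn])

    starts = [
        {k: v for k, v in _heuristic_start(df, state, bounds).items() if k in free_names}
    ]
    rng = np.random.default_rng(cfg.seed)
    for _ in range(cfg.multistart - 1):
        starts.append(_sample_start(rng, free_names, bounds))
    starts[0].update(
        {k: float(np.clip(cfg.initial[k], *bounds[k])) for k in cfg.initial if k in free_names}
    )

    best, objectives, n_eval = _run_multistart(residual, starts, free_names, bounds, cfg)
    kinetic = make_kinetic(best.x)
    traj = simulate(kinetic, comp0, state, t_fit)
    warnings_ = list(_bound_warnings(free_names, best.x, bounds))
    jac_norms = np.linalg.norm(best.jac, axis=0)
    for name, nrm in zip(free_names, jac_norms):
        if nrm < 1e-8 * max(1.0, float(jac_norms.max())):
            warnings_.append(f"{name} unidentifiable: residuals insensitive to it")
    warnings_ = tuple(warnings_)
    return FitResult(
        kinetic=kinetic,
        composition=None,
        state=state,
        r_squared={"X": _r2(xv, traj.X[ix_x]), "N": _r2(nv, traj.N[ix_n])},
        residuals={"X": traj.X[ix_x] - xv, "N": traj.N[ix_n] - nv},
        objective=float(best.cost),
        converged=bool(best.status > 0),
        n_evaluations=n_eval,
        multistart_objectives=tuple(objectives),
        warnings=warnings_,
        frozen=freeze,
    )


def fit_lipid(data, fitted: FitResult, cfg: FitConfig | None = None) -> FitResult:
    """Stage 2: estimate (k, c, phi) from lipid observations.

    The stage-1 trajectory supplies X(t) and N(t) at the lipid observation
    times; the lipid law L = 1 - k*(N0 - N + phi)/X - c is then fit over
    (k, c, phi) with stage-1 parameters held fixed.  Because the law is
    linear in (1-c, k, k*phi), a linear least-squares solution seeds the
    bounded refinement, and near-collinear regressors (e.g. quota
    identically zero) are flagged as unidentifiable.
    """
    cfg = cfg or FitConfig()
    df = _as_table(data)
    l_obs = df[["t_days", "L"]].dropna()
    if len(l_obs) < 3:
        raise ValueError("need >= 3 lipid observations")
    state = fitted.state

    t_fit = np.unique(np.concatenate([[0.0], l_obs["t_days"].to_numpy()]))
    ix = np.searchsorted(t_fit, l_obs["t_days"].to_numpy())
    comp0 = CompositionParams(k=1.0, c=0.0, phi=0.0)
    traj = simulate(fitted.kinetic, comp0, state, t_fit)
    u = (state.N0 - traj.N[ix]) / traj.X[ix]  # depleted N per biomass
    v = 1.0 / traj.X[ix]
    lv = l_obs["L"].to_numpy(float)

    bounds = {n: cfg.resolve_bounds(n) for n in STAGE2_PARAMS}
    censored = lv <= 0.0  # zero readings are at the assay floor (left-censored)

    def residual(theta):
        k, c, phi = theta
        model = (1.0 - c) - k * u - k * phi * v
        r = model - lv
        # a censored observation is consistent with any nonpositive model value
        return np.where(censored, np.maximum(model, 0.0), r)

    # linear seed: L = A - B*u - C*v with A = 1-c, B = k, C = k*phi
    design = np.column_stack([np.ones_like(u), -u, -v])
    coef, *_ = np.linalg.lstsq(design, lv, rcond=None)
    a_, b_, c_ = coef
    seed_start = {
        "k": float(np.clip(b_, *bounds["k"])),
        "c": float(np.clip(1.0 - a_, *bounds["c"])),
        "phi": float(np.clip(c_ / b_ if b_ > 0 else 0.0, *bounds["phi"])),
    }
    starts = [seed_start, {n: 0.5 * (bounds[n][0] + bounds[n][1]) for n in STAGE2_PARAMS}]
    rng = np.random.default_rng(cfg.seed + 1)
    for _ in range(max(0, cfg.multistart - 2)):
        starts.append(_sample_start(rng, STAGE2_PARAMS, bounds))

    best, objectives, n_eval = _run_multistart(residual, starts, list(STAGE2_PARAMS), bounds, cfg)
    k, c, phi = best.x
    composition = CompositionParams(k=float(k), c=float(c), phi=float(phi))
    model_l = (1.0 - c) - k * u - k * phi * v
    warnings_ = list(_bound_warnings(STAGE2_PARAMS, best.x, bounds))
    # identifiability: a regressor with (near-)zero column norm leaves its
    # parameter at the mercy of the start
    jac_norms = np.linalg.norm(best.jac, axis=0)
    for name, nrm in zip(STAGE2_PARAMS, jac_norms):
        if nrm < 1e-10 * max(1.0, jac_norms.max()):
            warnings_.append(f"{name} unidentifiable: lipid residuals insensitive to it")

    return replace(
        fitted,
        composition=composition,
        r_squared={**fitted.r_squared, "L": _r2(lv, model_l)},
        residuals={**fitted.residuals, "L": model_l - lv},
        objective=fitted.objective + float(best.cost),
        converged=fitted.converged and bool(best.status > 0),
        n_evaluations=fitted.n_evaluations + n_eval,
        multistart_objectives=fitted.multistart_objectives + tuple(objectives),
        warnings=fitted.warnings + tuple(warnings_),
    )


def fit_staged(data, cfg: FitConfig | None = None, *, x0=None, n0=None, freeze=None) -> FitResult:
    """Fit one condition's observations (staged by default, joint if configured)."""
    cfg = cfg or FitConfig()
    if cfg.joint:
        return fit_joint(data, cfg, x0=x0, n0=n0, freeze=freeze)
    stage1 = fit_growth_uptake(data, cfg, x0=x0, n0=n0, freeze=freeze)
    df = _as_table(data)
    if df["L"].dropna().empty:
        return stage1
    return fit_lipid(df, stage1, cfg)


def fit_joint(data, cfg: FitConfig | None = None, *, x0=None, n0=None, freeze=None) -> FitResult:
    """Joint estimation of all eight parameters (comparison mode).

    Minimizes the pooled SD-scaled residuals of X, N and L simultaneously.
    Offered for comparison with the default staged procedure; the staged
    procedure remains the reference.
    """
    cfg = cfg or FitConfig()
    freeze = dict(freeze or {})
    df = _as_table(data)
    x_obs = df[["t_days", "X"]].dropna()
    n_obs = df[["t_days", "N"]].dropna()
    l_obs = df[["t_days", "L"]].dropna()
    if len(x_obs) < 4 or len(n_obs) < 4 or len(l_obs) < 3:
        raise ValueError("joint fit needs >= 4 X and N points and >= 3 L points")
    state = _initial_state(df, x0, n0)
    x_max_obs = float(x_obs["X"].max())
    all_names = STAGE1_PARAMS + STAGE2_PARAMS
    bounds = {n: cfg.resolve_bounds(n, x_max_obs) for n in all_names}
    free_names = [n for n in all_names if n not in freeze]

    t_fit = np.unique(
        np.concatenate(
            [[0.0], x_obs["t_days"].to_numpy(), n_obs["t_days"].to_numpy(), l_obs["t_days"].to_numpy()]
        )
    )
    ix_x = np.searchsorted(t_fit, x_obs["t_days"].to_numpy())
    ix_n = np.searchsorted(t_fit, n_obs["t_days"].to_numpy())
    ix_l = np.searchsorted(t_fit, l_obs["t_days"].to_numpy())
    xv, nv, lv = (o.iloc[:, 1].to_numpy(float) for o in (x_obs, n_obs, l_obs))
    sx = _series_scale(xv) / cfg.weights.get("X", 1.0)
    sn = _series_scale(nv) / cfg.weights.get("N", 1.0)
    sl = _series_scale(lv)

    def split(theta):
        p = dict(freeze)
        p.update(dict(zip(free_names, theta)))
        kin = KineticParams(**{n: p[n] for n in STAGE1_PARAMS})
        comp = CompositionParams(**{n: p[n] for n in STAGE2_PARAMS})
        return kin, comp

    censored = lv <= 0.0

    def residual(theta):
        kin, comp = split(theta)
        traj = simulate(kin, comp, state, t_fit)
        model_l = traj.L[ix_l]
        rl = np.where(censored, np.maximum(model_l, 0.0), model_l - lv)
        return np.concatenate([(traj.X[ix_x] - xv) / sx, (traj.N[ix_n] - nv) / sn, rl / sl])

    start0 = _heuristic_start(df, state, bounds)
    start0.update({"k": 2.0, "c": 0.3, "phi": 0.01})
    starts = [{k: v for k, v in start0.items() if k in free_names}]
    rng = np.random.default_rng(cfg.seed)
    for _ in range(cfg.multistart - 1):
        starts.append(_sample_start(rng, free_names, bounds))
    starts[0].update(
        {k: float(np.clip(cfg.initial[k], *bounds[k])) for k in cfg.initial if k in free_names}
    )

    best, objectives, n_eval = _run_multistart(residual, starts, free_names, bounds, cfg)
    kinetic, composition = split(best.x)
    traj = simulate(kinetic, composition, state, t_fit)
    return FitResult(
        kinetic=kinetic,
        composition=composition,
        state=state,
        r_squared={
            "X": _r2(xv, traj.X[ix_x]),
            "N": _r2(nv, traj.N[ix_n]),
            "L": _r2(lv, traj.L[ix_l]),
        },
        residuals={"X": traj.X[ix_x] - xv, "N": traj.N[ix_n] - nv, "L": traj.L[ix_l] - lv},
        objective=float(best.cost),
        converged=bool(best.status > 0),
        n_evaluations=n_eval,
        multistart_objectives=tuple(objectives),
        warnings=tuple(_bound_warnings(free_names, best.x, bounds)),
        frozen=freeze,
    )


def fit_condition_set(
    datasets: dict,
    cfg: FitConfig | None = None,
    *,
    freeze: dict | None = None,
    x0: float | None = None,
) -> dict:
    """Fit each condition independently; failures do not abort the set.

    Parameters
    ----------
    datasets : mapping of condition label -> observations table
    freeze : dict, optional
        Stage-1 parameters (typically vm, KN) imported from another
        condition's FitResult and held fixed in every fit here, reproducing
        the cross-species transfer workflow.

    Returns
    -------
    dict mapping condition label -> FitResult, or to the raised exception
    for conditions whose fit failed.
    """
    cfg = cfg or FitConfig()
    if isinstance(freeze, FitResult):
        freeze = {"vm": freeze.kinetic.vm, "KN": freeze.kinetic.KN}
    out = {}
    for label, data in datasets.items():
        try:
            out[label] = fit_staged(data, cfg, x0=x0, freeze=freeze)
        except Exception as exc:  # propagate per-condition, keep going
            out[label] = exc
    return out
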