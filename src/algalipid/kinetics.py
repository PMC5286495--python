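"""Coupled kinetics of nitrogen-limited batch growth and lipid accumulation.

The model couples four pieces:

* logistic biomass growth modulated by the Baranyi-Roberts adjustment
  function ``alpha(t)`` describing adaptation of the inoculum,

      dX/dt = mu_max * alpha(t) * (1 - X/Xmax) * X

* Michaelis-Menten uptake of external nitrogen by the biomass,

      dN/dt = -vm * N/(N + KN) * X

* an internal nitrogen quota obtained purely by mass balance on the
  closed batch (everything that left the medium is inside the cells),

      Q(t) = (N0 - N(t) + Phi) / X(t),      Phi = X0*Q0

* and a neutral-lipid fraction that is linear in the quota, expressing
  the assumption that dry biomass is protein + lipid + carbohydrate with
  protein proportional to quota and carbohydrate constant,

      L(t) = 1 - k*Q(t) - c.

Only X and N are integrated; Q and L are derived algebraically, so the
nitrogen mass balance holds on every reported grid point by construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .params import BatchState, CompositionParams, KineticParams

__all__ = [
    "adjustment",
    "growth_rhs",
    "uptake_rhs",
    "nitrogen_quota",
    "lipid_content",
    "simulate",
    "Trajectory",
    "SimulationError",
    "TRAJECTORY_COLUMNS",
]

#: CSV schema for trajectory export/import
TRAJECTORY_COLUMNS = ("t_days", "X_gdw_per_L", "N_g_per_L", "Q_gN_per_gdw", "L_frac")


class SimulationError(RuntimeError):
    """Raised when the ODE solver fails; carries the offending parameter set."""

    def __init__(self, message: str, kinetic: KineticParams | None = None):
        if kinetic is not None:
            message = f"{message} (parameters: {kinetic})"
        super().__init__(message)
        self.kinetic = kinetic


def adjustment(t, mu_max: float, h0: float):
    """Baranyi-Roberts adjustment function ``alpha(t)``.

    Evaluated in the numerically stable form

        alpha(t) = 1 / (1 + (exp(h0) - 1) * exp(-mu_max * t))

    which is algebraically identical to the ratio-of-exponentials form
    exp(-h0) / [exp(-mu_max t) + exp(-h0) - exp(-mu_max t - h0)] but cannot
    overflow for t >= 0.  Properties: alpha(0) = exp(-h0); alpha is monotone
    in t with limit 1; alpha > 1 everywhere when h0 < 0, 0 <= alpha < 1 when
    h0 > 0, and alpha == 1 identically when h0 = 0.

    Parameters
    ----------
    t : float or array_like
        Time since inoculation (days), nonnegative.
    mu_max : float
        Maximum specific growth rate (day^-1), positive.
    h0 : float
        Dimensionless lag parameter, any sign.

    Returns
    -------
    float or ndarray
        Dimensionless adjustment factor.
    """
    t_arr = np.asarray(t, dtype=float)
    if not (math.isfinite(mu_max) and math.isfinite(h0)):
        raise ValueError("mu_max and h0 must be finite")
    if mu_max <= 0:
        raise ValueError(f"mu_max must be > 0, got {mu_max}")
    if not np.all(np.isfinite(t_arr)):
        raise ValueError("t must be finite")
    if np.any(t_arr < 0):
        raise ValueError("t must be >= 0")
    alpha = 1.0 / (1.0 + np.expm1(h0) * np.exp(-mu_max * t_arr))
    if np.ndim(t) == 0:
        return float(alpha)
    return alpha


def growth_rhs(X, t, p: KineticParams):
    """Biomass growth rate dX/dt (g dw L^-1 day^-1) of the adjusted logistic."""
    X = np.asarray(X, dtype=float)
    if np.any(X < 0):
        raise ValueError("X must be >= 0")
    out = p.mu_max * adjustment(t, p.mu_max, p.h0) * (1.0 - X / p.Xmax) * X
    return float(out) if out.ndim == 0 else out


def uptake_rhs(N, X, p: KineticParams):
    """External-nitrogen depletion rate dN/dt (g L^-1 day^-1), Michaelis-Menten.

    Always nonpositive; equals -vm*X/2 at N = KN and saturates at -vm*X for
    N >> KN.  Negative N is rejected: it signals solver underflow upstream.
    """
    N = np.asarray(N, dtype=float)
    X = np.asarray(X, dtype=float)
    if np.any(N < 0):
        raise ValueError("N must be >= 0 (negative N signals solver underflow)")
    if np.any(X < 0):
        raise ValueError("X must be >= 0")
    out = -p.vm * N / (N + p.KN) * X
    return float(out) if out.ndim == 0 else out


def nitrogen_quota(X, N, N0: float, phi: float):
    """Nitrogen quota Q = (N0 - N + Phi)/X (g N g^-1 dw) by batch mass balance."""
    X = np.asarray(X, dtype=float)
    N = np.asarray(N, dtype=float)
    if np.any(X <= 0):
        raise ValueError("X must be > 0")
    out = (N0 - N + phi) / X
    return float(out) if out.ndim == 0 else out


def lipid_content(Q, comp: CompositionParams):
    """Neutral lipid fraction L = 1 - k*Q - c (g lipid g^-1 dw).

    Deliberately not clamped to [0, 1]: a transiently negative or >1 value
    exposes model misfit (large quota early in a run) instead of hiding it.
    """
    Q = np.asarray(Q, dtype=float)
    if np.any(Q < 0):
        raise ValueError("Q must be >= 0")
    out = 1.0 - comp.k * Q - comp.c
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class Trajectory:
    """Simulated batch time course on a fixed grid.

    Columns: time (days), biomass X (g dw/L), external nitrogen N (g/L),
    quota Q (g N/g dw) and lipid fraction L (g/g).  Q and L satisfy the
    mass balance and the linear lipid law exactly by construction.
    """

    t: np.ndarray
    X: np.ndarray
    N: np.ndarray
    Q: np.ndarray
    L: np.ndarray

    def __len__(self) -> int:
        return len(self.t)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "t_days": self.t,
                "X_gdw_per_L": self.X,
                "N_g_per_L": self.N,
                "Q_gN_per_gdw": self.Q,
                "L_frac": self.L,
            }
        )

    def to_csv(self, path) -> None:
        """Write the trajectory as CSV with full float precision."""
        self.to_frame().to_csv(path, index=False, float_format="%.17g")

    @classmethod
    def from_csv(cls, path) -> "Trajectory":
        df = pd.read_csv(path)
        missing = set(TRAJECTORY_COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"trajectory CSV missing columns: {sorted(missing)}")
        return cls(
            t=df["t_days"].to_numpy(float),
            X=df["X_gdw_per_L"].to_numpy(float),
            N=df["N_g_per_L"].to_numpy(float),
            Q=df["Q_gN_per_gdw"].to_numpy(float),
            L=df["L_frac"].to_numpy(float),
        )

    def plot(self, ax=None):
        """Quick-look plot of X, N and L against time (requires matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.t, self.X, label="X (g dw/L)")
        ax.plot(self.t, self.N, label="N (g/L)")
        ax.plot(self.t, self.L, label="L (fraction)")
        ax.set_xlabel("time (days)")
        ax.legend()
        return ax


def _rk4_fixed(rhs, y0, t_grid, max_step):
    """Classical fixed-step RK4 over each grid interval (bit-reproducible)."""
    y = np.array(y0, dtype=float)
    out = np.empty((len(t_grid), len(y0)))
    out[0] = y
    for i in range(len(t_grid) - 1):
        t0, t1 = t_grid[i], t_grid[i + 1]
        n_sub = max(1, int(math.ceil((t1 - t0) / max_step)))
        h = (t1 - t0) / n_sub
        t = t0
        for _ in range(n_sub):
            k1 = rhs(t, y)
            k2 = rhs(t + h / 2, y + h / 2 * k1)
            k3 = rhs(t + h / 2, y + h / 2 * k2)
            k4 = rhs(t + h, y + h * k3)
            y = y + h / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
            t += h
        out[i + 1] = y
    return out


def simulate(
    kinetic: KineticParams,
    composition: CompositionParams,
    state: BatchState,
    t_grid,
    *,
    method: str = "rk45",
    rtol: float = 1e-7,
    atol: float = 1e-9,
    rk4_step: float = 0.02,
) -> Trajectory:
    """Integrate the coupled growth/uptake system and derive quota and lipid.

    Parameters
    ----------
    kinetic, composition : model parameters.
    state : initial condition (X0, N0) of the batch.
    t_grid : array_like
        Strictly increasing output times (days) starting at 0.
    method : {"rk45", "rk4"}
        Adaptive Runge-Kutta 4(5) (default) or fixed-step classical RK4
        (bit-reproducible, step ``rk4_step``).
    rtol, atol : adaptive-solver tolerances.

    Returns
    -------
    Trajectory
        With N clipped at zero (uptake is evaluated with max(N, 0) inside the
        right-hand side, so roundoff-negative N never produces re-release).

    Raises
    ------
    SimulationError
        On solver failure or if N is driven below -1e-6 (stiffness).
    """
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.ndim != 1 or len(t_grid) == 0:
        raise ValueError("t_grid must be a non-empty 1-D array")
    if t_grid[0] != 0:
        raise ValueError(f"t_grid must start at 0, got {t_grid[0]}")
    if len(t_grid) > 1 and not np.all(np.diff(t_grid) > 0):
        raise ValueError("t_grid must be strictly increasing")
    # X0 > Xmax is tolerated: the logistic then relaxes X down toward Xmax,
    # which keeps the objective smooth for parameter estimation

    mu_max, h0, vm, KN, Xmax = (
        kinetic.mu_max,
        kinetic.h0,
        kinetic.vm,
        kinetic.KN,
        kinetic.Xmax,
    )
    em1 = np.expm1(h0)

    def rhs(t, y):
        X, N = y
        alpha = 1.0 / (1.0 + em1 * math.exp(-mu_max * t))
        Nf = N if N > 0 else 0.0
        dX = mu_max * alpha * (1.0 - X / Xmax) * X
        dN = -vm * Nf / (Nf + KN) * X
        return np.array([dX, dN])

    if len(t_grid) == 1:
        X = np.array([state.X0])
        N = np.array([state.N0])
    elif method == "rk4":
        ys = _rk4_fixed(rhs, [state.X0, state.N0], t_grid, rk4_step)
        X, N = ys[:, 0], ys[:, 1]
    elif method == "rk45":
        from scipy.integrate import solve_ivp

        sol = solve_ivp(
            rhs,
            (t_grid[0], t_grid[-1]),
            [state.X0, state.N0],
            method="RK45",
            t_eval=t_grid,
            rtol=rtol,
            atol=atol,
        )
        if not sol.success:
            raise SimulationError(f"solver failed: {sol.message}", kinetic)
        X, N = sol.y[0], sol.y[1]
    else:
        raise ValueError(f"unknown method {method!r}")

    if np.any(N < -1e-6):
        raise SimulationError(
            f"nitrogen driven to {N.min():.3g} < -1e-6; stiffness suspected", kinetic
        )
    N = np.clip(N, 0.0, None)
    Q = nitrogen_quota(X, N, state.N0, composition.phi)
    L = 1.0 - composition.k * Q - composition.c
    return Trajectory(t=t_grid.copy(), X=X.copy(), N=N, Q=Q, L=L)
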