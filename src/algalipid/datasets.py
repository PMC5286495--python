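"""Bundled per-condition parameter sets and a seeded synthetic-data generator.

The generator emulates the batch design the model was developed on: five
initial NaNO3 levels between 0.075 and 0.9 g/L for *Coelastrum* sp. HA-1
(24-day batches, triplicates, sampling every other day) and three light
intensities for *Chlorella sorokiniana* at 1 g/L NaNO3.  Measurement error
is multiplicative (CV-based) on every observable, because dry-weight and
lipid assays scale with magnitude, with an additive floor on nitrogen to
emulate the assay detection limit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .kinetics import simulate
from .params import BatchState, CompositionParams, KineticParams

__all__ = [
    "ParameterSet",
    "DesignSpec",
    "fixture",
    "all_fixtures",
    "ha1_design",
    "generate",
]


@dataclass(frozen=True)
class ParameterSet:
    """One condition's full eight-parameter set plus its batch condition."""

    label: str
    mu_max: float
    h0: float
    vm: float
    KN: float
    Xmax: float
    k: float
    c: float
    phi: float
    N0: float

    @property
    def kinetic(self) -> KineticParams:
        return KineticParams(self.mu_max, self.h0, self.vm, self.KN, self.Xmax)

    @property
    def composition(self) -> CompositionParams:
        return CompositionParams(self.k, self.c, self.phi)

    def batch_state(self, X0: float = 0.05) -> BatchState:
        return BatchState(X0=X0, N0=self.N0)


# Fitted means for Coelastrum sp. HA-1, one column per initial NaNO3 level
# (g/L).  Order: mu_max, h0, vm, KN, Xmax, k, c, phi.
_HA1 = {
    0.075: (0.313, -0.624, 0.298, 0.002, 1.454, 2.119, 0.436, 0.052),
    0.15: (0.340, -0.719, 0.156, 0.003, 2.288, 2.121, 0.440, 0.050),
    0.3: (0.295, -1.338, 0.623, 0.142, 4.094, 2.123, 0.440, 0.050),
    0.6: (0.300, -1.289, 0.410, 0.327, 5.946, 2.122, 0.440, 0.049),
    0.9: (0.264, -1.593, 0.285, 0.198, 6.738, 2.119, 0.440, 0.050),
}

# Fitted values for C. sorokiniana at 1 g/L NaNO3, one column per light
# intensity (umol m^-2 s^-1); vm and KN transferred from HA-1 at 0.9 g/L.
_CSORO = {
    50: (0.466, -1.493, 0.285, 0.198, 1.009, 0.735, 0.113, 5.794e-7),
    100: (0.297, -1.910, 0.285, 0.198, 1.228, 0.775, 0.093, 3.450e-3),
    200: (0.455, -1.559, 0.285, 0.198, 0.678, 0.746, 0.102, 2.670e-4),
}


def fixture(species: str, N0: float | None = None, light: float | None = None) -> ParameterSet:
    """Return one bundled per-condition parameter set.

    ``fixture("HA1", N0=0.9)`` selects a *Coelastrum* sp. HA-1 nitrogen level;
    ``fixture("Csoro", light=100)`` selects a *C. sorokiniana* light level.
    """
    if species == "HA1":
        if N0 is None or N0 not in _HA1:
            raise KeyError(f"HA1 N0 must be one of {sorted(_HA1)}, got {N0}")
        vals = _HA1[N0]
        return ParameterSet(f"HA1_N0_{N0}", *vals, N0=N0)
    if species == "Csoro":
        if light is None or light not in _CSORO:
            raise KeyError(f"Csoro light must be one of {sorted(_CSORO)}, got {light}")
        vals = _CSORO[light]
        return ParameterSet(f"Csoro_{light}umol", *vals, N0=1.0)
    raise KeyError(f"unknown species {species!r}; use 'HA1' or 'Csoro'")


def all_fixtures() -> list[ParameterSet]:
    """All eight bundled parameter sets (five HA-1 nitrogen levels + three lights)."""
    return [fixture("HA1", N0=n0) for n0 in sorted(_HA1)] + [
        fixture("Csoro", light=li) for li in sorted(_CSORO)
    ]


@dataclass(frozen=True)
class DesignSpec:
    """Design of one synthetic experiment.

    Attributes
    ----------
    conditions : tuple of ParameterSet
        One entry per culture condition.
    times : tuple of float
        Sampling times in days, within [0, 30].
    replicates : int
        Biological replicates per condition (>= 1).
    cv : dict
        Multiplicative noise CV per observable, keys "X", "N", "L"; all >= 0.
    n_floor : float
        Additive noise floor (SD, g/L) on nitrogen emulating the assay
        detection limit; combined in quadrature with the CV term and only
        active when cv["N"] > 0, so a noiseless design stays exact.
    X0 : float
        Inoculum dry weight (g dw/L) used for every condition.  The default
        0.29 is the inoculum consistent with the bundled HA-1 composition
        parameters: with Phi ~= 0.05 g N/L, k ~= 2.12 and c ~= 0.44 it gives
        an initial quota Phi/X0 ~= 0.17 and hence an initial lipid fraction
        ~= 0.2, the level the assays the generator emulates actually report
        (a much smaller inoculum would imply a negative initial lipid
        fraction, which no measurement can produce).
    seed : int
        Seed of the generator; identical seeds give identical tables.
    """

    conditions: tuple
    times: tuple = tuple(float(t) for t in range(0, 25, 2))
    replicates: int = 3
    cv: dict = field(default_factory=lambda: {"X": 0.05, "N": 0.05, "L": 0.05})
    n_floor: float = 0.002
    X0: float = 0.29
    seed: int = 0

    def __post_init__(self):
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if any(v < 0 for v in self.cv.values()):
            raise ValueError("noise CVs must be >= 0")
        t = np.asarray(self.times, float)
        if np.any(t < 0) or np.any(t > 30):
            raise ValueError("sampling times must lie within [0, 30] days")
        if len(t) > 1 and not np.all(np.diff(t) > 0):
            raise ValueError("sampling times must be strictly increasing")

    def with_seed(self, seed: int) -> "DesignSpec":
        return replace(self, seed=seed)


def ha1_design(seed: int = 0, cv: float = 0.05, replicates: int = 3) -> DesignSpec:
    """Default HA-1-like design: five nitrogen levels, 13 times, triplicates."""
    return DesignSpec(
        conditions=tuple(fixture("HA1", N0=n0) for n0 in sorted(_HA1)),
        cv={"X": cv, "N": cv, "L": cv},
        replicates=replicates,
        seed=seed,
    )


def generate(design: DesignSpec) -> pd.DataFrame:
    """Generate a noisy observations table from a design.

    Each condition is simulated with the kinetics module; each observable of
    each replicate at each time gets independent multiplicative Gaussian noise
    ``y_obs = y * (1 + eps)``, ``eps ~ N(0, CV)`` (nitrogen additionally gets
    the quadrature detection floor).  Nitrogen and lipid observations are
    clipped at zero.  Deterministic under a fixed seed.

    Returns
    -------
    DataFrame with columns ``condition, t_days, replicate, X, N, L``.
    """
    rng = np.random.default_rng(design.seed)
    t = np.asarray(design.times, float)
    rows = []
    for cond in design.conditions:
        try:
            traj = simulate(cond.kinetic, cond.composition, cond.batch_state(design.X0), t)
        except Exception as exc:
            raise RuntimeError(f"simulation failed for condition {cond.label!r}") from exc
        for rep in range(1, design.replicates + 1):
            X = traj.X * (1.0 + rng.normal(0.0, design.cv["X"], len(t))) if design.cv["X"] > 0 else traj.X.copy()
            if design.cv["N"] > 0:
                sd = np.sqrt((design.cv["N"] * traj.N) ** 2 + design.n_floor**2)
                N = np.clip(traj.N + rng.normal(0.0, 1.0, len(t)) * sd, 0.0, None)
            else:
                N = traj.N.copy()
            if design.cv["L"] > 0:
                # noisy lipid assays cannot report negative fractions
                L = np.clip(traj.L * (1.0 + rng.normal(0.0, design.cv["L"], len(t))), 0.0, None)
            else:
                L = traj.L.copy()
            rows.append(
                pd.DataFrame(
                    {
                        "condition": cond.label,
                        "t_days": t,
                        "replicate": rep,
                        "X": X,
                        "N": N,
                        "L": L,
                    }
                )
            )
    return pd.concat(rows, ignore_index=True)
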