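"""Parameter and state containers for the batch lipid-accumulation model.

All quantities are in the units of the batch experiments the model was
built around: time in days, biomass as dry weight in g dw L^-1, and all
nitrogen masses in grams of NaNO3 (the salt actually weighed into the
medium).  A helper is provided to convert to elemental nitrogen, but no
conversion is ever applied implicitly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields

__all__ = [
    "KineticParams",
    "CompositionParams",
    "BatchState",
    "nitrate_to_nitrogen",
    "nitrogen_to_nitrate",
]

#: mass fraction of elemental N in NaNO3 (14.0067 / 84.9947, i.e. ~14/85)
N_FRACTION_OF_NANO3 = 14.0067 / 84.9947


def nitrate_to_nitrogen(grams_nano3: float) -> float:
    """Convert a NaNO3 mass (g) to the elemental nitrogen it carries (g N)."""
    return grams_nano3 * N_FRACTION_OF_NANO3


def nitrogen_to_nitrate(grams_n: float) -> float:
    """Convert an elemental nitrogen mass (g N) to the equivalent NaNO3 mass (g)."""
    return grams_n / N_FRACTION_OF_NANO3


def _check_finite(obj) -> None:
    for f in fields(obj):
        v = getattr(obj, f.name)
        if not math.isfinite(v):
            raise ValueError(f"{type(obj).__name__}.{f.name} must be finite, got {v!r}")


@dataclass(frozen=True)
class KineticParams:
    """Growth and nitrogen-uptake parameters.

    Attributes
    ----------
    mu_max : float
        Maximum specific growth rate (day^-1). Must be positive.
    h0 : float
        Dimensionless Baranyi-Roberts lag parameter. Negative values give an
        adjustment factor above one (initially accelerated growth), positive
        values a classical lag; zero switches the adjustment off.
    vm : float
        Maximum specific nitrogen uptake rate (g N g^-1 dw day^-1). Nonnegative.
    KN : float
        Half-saturation constant of uptake (g N L^-1). Must be positive.
    Xmax : float
        Maximum (carrying-capacity) biomass concentration (g dw L^-1).
    """

    mu_max: float
    h0: float
    vm: float
    KN: float
    Xmax: float

    def __post_init__(self) -> None:
        _check_finite(self)
        if self.mu_max <= 0:
            raise ValueError(f"mu_max must be > 0, got {self.mu_max}")
        if self.vm < 0:
            raise ValueError(f"vm must be >= 0, got {self.vm}")
        if self.KN <= 0:
            raise ValueError(f"KN must be > 0, got {self.KN}")
        if self.Xmax <= 0:
            raise ValueError(f"Xmax must be > 0, got {self.Xmax}")


@dataclass(frozen=True)
class CompositionParams:
    """Biomass-composition parameters of the lipid model L = 1 - k*Q - c.

    Attributes
    ----------
    k : float
        Nitrogen-to-protein conversion factor: the slope by which the lipid
        fraction falls per unit nitrogen quota.
    c : float
        Carbohydrate mass fraction of the biomass (g carbohydrate g^-1 dw),
        assumed constant over the batch.
    phi : float
        Initial internal nitrogen pool Phi = X0*Q0 (g N L^-1), the lumped
        constant of the quota mass balance.
    """

    k: float
    c: float
    phi: float

    def __post_init__(self) -> None:
        _check_finite(self)
        if self.k <= 0:
            raise ValueError(f"k must be > 0, got {self.k}")
        if not 0 <= self.c < 1:
            raise ValueError(f"c must be in [0, 1), got {self.c}")
        if self.phi < 0:
            raise ValueError(f"phi must be >= 0, got {self.phi}")


@dataclass(frozen=True)
class BatchState:
    """Initial condition of one batch culture: inoculum X0 and nitrogen charge N0."""

    X0: float
    N0: float

    def __post_init__(self) -> None:
        _check_finite(self)
        if self.X0 <= 0:
            raise ValueError(f"X0 must be > 0, got {self.X0}")
        if self.N0 < 0:
            raise ValueError(f"N0 must be >= 0, got {self.N0}")
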