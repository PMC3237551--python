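"""Closed-form kinetics of isotope-labeled subunit exchange.

A heterodimeric protein complex ``A + B <=> AB`` associates with rate
constant ``k_on`` (concentration^-1 s^-1) and dissociates with rate
constant ``k_off`` (s^-1).  In a subunit-exchange experiment two cell
lysates are mixed in equal volumes: one carries an affinity-tagged,
isotopically *unlabeled* variant of the complex (species ``A_TU``,
``B_U``, complex ``A_TU_B_U``), the other an untagged, metabolically
*labeled* variant (``A_L``, ``B_L``, ``A_L_B_L``).  After mixing, free
subunits shuffle between complexes by dissociation and re-association,
producing hybrid complexes.  The measurable readout is the abundance
ratio between the hybrid tagged complex and the original tagged complex,

    R(t) = [A_TU.B_L](t) / [A_TU.B_U](t),

which rises from 0 at the instant of mixing to 1 at exchange
equilibrium.

Because lysates prepared from the same number of cells in the same
volume contain the complex at identical concentrations ("equivalent
lysates"), 1:1 mixing leaves the association/dissociation reaction at
equilibrium: all four free-subunit concentrations stay constant, and the
hybrid complex accumulates by a linear first-order relaxation.  The
resulting progress curve,

    R(t) = (1 - exp(-k_off t)) / (1 + exp(-k_off t)) = tanh(k_off t / 2),

depends on ``k_off`` only -- neither ``k_on`` nor any concentration
enters -- which is what makes the exchange readout a direct probe of the
dissociation rate constant.

This module holds the closed form, its analytic inverse and sensitivity,
and the equilibrium free/bound partition of a single lysate.  Everything
here is a pure function of scalars/arrays; simulation and I/O live
elsewhere.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Mapping, Optional

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "SPECIES",
    "FREE_SPECIES",
    "COMPLEX_SPECIES",
    "COMPLEX_PARTS",
    "RateConstants",
    "LysateLabel",
    "LysateComposition",
    "SystemState",
    "ExchangePoint",
    "predict_R",
    "invert_R",
    "sensitivity",
    "peak_sensitivity_kt",
    "peak_sensitivity_time",
    "equilibrium_split",
]

#: Canonical species order used throughout the package: four free
#: subunits followed by the four complexes.
SPECIES = (
    "A_TU",
    "B_U",
    "A_L",
    "B_L",
    "A_TU_B_U",
    "A_TU_B_L",
    "A_L_B_U",
    "A_L_B_L",
)
FREE_SPECIES = SPECIES[:4]
COMPLEX_SPECIES = SPECIES[4:]

#: Complex -> (free A variant, free B variant) it assembles from.
COMPLEX_PARTS = {
    "A_TU_B_U": ("A_TU", "B_U"),
    "A_TU_B_L": ("A_TU", "B_L"),
    "A_L_B_U": ("A_L", "B_U"),
    "A_L_B_L": ("A_L", "B_L"),
}

SPECIES_INDEX = {name: i for i, name in enumerate(SPECIES)}


def _require_finite_positive(value: float, name: str) -> float:
    value = float(value)
    if not math.isfinite(value) or value <= 0.0:
        raise ValueError(f"{name} must be finite and > 0, got {value!r}")
    return value


def _require_finite_nonnegative(value: float, name: str) -> float:
    value = float(value)
    if not math.isfinite(value) or value < 0.0:
        raise ValueError(f"{name} must be finite and >= 0, got {value!r}")
    return value


@dataclass(frozen=True)
class RateConstants:
    """Kinetic parameters of the reversible association reaction.

    Parameters
    ----------
    k_on
        Association rate constant, in (concentration unit)^-1 s^-1.
        Concentrations are in arbitrary units throughout the package, so
        only the product k_on * concentration has absolute meaning.
    k_off
        Dissociation rate constant, s^-1.
    """

    k_on: float
    k_off: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "k_on", _require_finite_positive(self.k_on, "k_on"))
        object.__setattr__(self, "k_off", _require_finite_positive(self.k_off, "k_off"))

    @property
    def dissociation_constant(self) -> float:
        """Equilibrium constant K_d = k_off / k_on (concentration units)."""
        return self.k_off / self.k_on


class LysateLabel(str, enum.Enum):
    """Which culture a lysate comes from."""

    UNLABELED_TAGGED = "unlabeled_tagged"
    LABELED_UNTAGGED = "labeled_untagged"


@dataclass(frozen=True)
class LysateComposition:
    """Total subunit content of one lysate before mixing.

    ``total_A``/``total_B`` are the summed free + bound concentrations of
    each subunit in the lysate (arbitrary concentration units).
    """

    total_A: float
    total_B: float
    label: LysateLabel = LysateLabel.UNLABELED_TAGGED

    def __post_init__(self) -> None:
        object.__setattr__(self, "total_A", _require_finite_nonnegative(self.total_A, "total_A"))
        object.__setattr__(self, "total_B", _require_finite_nonnegative(self.total_B, "total_B"))
        object.__setattr__(self, "label", LysateLabel(self.label))

    @property
    def species_names(self) -> tuple[str, str, str]:
        """(free A, free B, complex) species names for this lysate's variant."""
        if self.label is LysateLabel.UNLABELED_TAGGED:
            return ("A_TU", "B_U", "A_TU_B_U")
        return ("A_L", "B_L", "A_L_B_L")


@dataclass(frozen=True)
class SystemState:
    """Concentrations of all 8 species at one instant.

    ``t`` is seconds since mixing; ``conc`` maps species name to
    concentration (arbitrary units, same scale as LysateComposition).
    """

    t: float
    conc: Mapping[str, float]

    def __post_init__(self) -> None:
        t = _require_finite_nonnegative(self.t, "t")
        object.__setattr__(self, "t", t)
        missing = set(SPECIES) - set(self.conc)
        if missing:
            raise ValueError(f"missing species: {sorted(missing)}")
        for name in SPECIES:
            _require_finite_nonnegative(self.conc[name], f"[{name}]")

    def as_vector(self) -> np.ndarray:
        """Concentrations in canonical SPECIES order."""
        return np.array([self.conc[name] for name in SPECIES], dtype=float)

    @property
    def total_A(self) -> float:
        c = self.conc
        return c["A_TU"] + c["A_L"] + c["A_TU_B_U"] + c["A_TU_B_L"] + c["A_L_B_U"] + c["A_L_B_L"]

    @property
    def total_B(self) -> float:
        c = self.conc
        return c["B_U"] + c["B_L"] + c["A_TU_B_U"] + c["A_TU_B_L"] + c["A_L_B_U"] + c["A_L_B_L"]

    @classmethod
    def from_vector(cls, t: float, vec: np.ndarray) -> "SystemState":
        return cls(t=t, conc=dict(zip(SPECIES, map(float, vec))))


@dataclass(frozen=True)
class ExchangePoint:
    """One measured (or simulated) exchange ratio.

    ``t`` seconds since mixing; ``R`` the hybrid/original abundance
    ratio; ``sigma`` an optional measurement standard deviation of R;
    ``censored`` marks points below the detection floor.
    """

    t: float
    R: float
    sigma: Optional[float] = None
    censored: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "t", _require_finite_nonnegative(self.t, "t"))
        object.__setattr__(self, "R", _require_finite_nonnegative(self.R, "R"))
        if self.sigma is not None:
            object.__setattr__(self, "sigma", _require_finite_positive(self.sigma, "sigma"))
        object.__setattr__(self, "censored", bool(self.censored))


def _check_times(t) -> tuple[np.ndarray, bool]:
    arr = np.asarray(t, dtype=float)
    scalar = arr.ndim == 0
    if not np.all(np.isfinite(arr)) or np.any(arr < 0):
        raise ValueError("t must be finite and >= 0")
    return arr, scalar


def predict_R(k_off: float, t):
    """Exchange progress ratio R(t) = tanh(k_off * t / 2).

    Parameters
    ----------
    k_off
        Dissociation rate constant (s^-1), > 0.
    t
        Time(s) since mixing, seconds, scalar or array, >= 0.

    Returns
    -------
    float or ndarray
        R in [0, 1): 0 at t=0, approaching 1 at exchange equilibrium.
        Strictly increasing in both t and k_off.
    """
    k_off = _require_finite_positive(k_off, "k_off")
    arr, scalar = _check_times(t)
    out = np.tanh(0.5 * k_off * arr)
    return float(out) if scalar else out


def invert_R(R: float, t: float) -> float:
    """Dissociation rate constant from a single exchange measurement.

    Analytic inverse of :func:`predict_R`:
    ``k_off = [ln(1+R) - ln(1-R)] / t``.  Only interior ratios carry a
    finite single-point estimate: a point at equilibrium (R >= 1) or
    before any exchange (R <= 0) is uninformative and raises.
    """
    R = float(R)
    t = float(t)
    if not math.isfinite(R) or not (0.0 < R < 1.0):
        raise ValueError(f"R must lie strictly between 0 and 1, got {R!r}")
    if not math.isfinite(t) or t <= 0.0:
        raise ValueError(f"t must be finite and > 0, got {t!r}")
    return (math.log1p(R) - math.log1p(-R)) / t


def sensitivity(k_off: float, t):
    """Partial derivative dR/dk_off of the exchange progress curve.

    Equals ``(t/2) * sech^2(k_off t / 2)``; positive for t > 0, zero at
    t = 0, and maximal at t = x*/k_off with x* ~= 1.5434 (see
    :func:`peak_sensitivity_time`).  Used for experiment design (where
    to place time points) and for weighting.
    """
    k_off = _require_finite_positive(k_off, "k_off")
    arr, scalar = _check_times(t)
    u = 0.5 * k_off * arr
    # sech(u) = 2 e^-u / (1 + e^-2u), overflow-safe for large u
    e = np.exp(-u)
    sech = 2.0 * e / (1.0 + e * e)
    out = 0.5 * arr * sech * sech
    return float(out) if scalar else out


@lru_cache(maxsize=1)
def peak_sensitivity_kt() -> float:
    """The dimensionless product k_off * t at which dR/dk_off peaks.

    Root of ``x * tanh(x/2) = 1`` (stationarity of t * sech^2(kt/2) in
    t); numerically ~1.5434.  Invariant across k_off, so the most
    informative sampling time is ``peak_sensitivity_kt() / k_off``.
    """
    return float(brentq(lambda x: x * math.tanh(0.5 * x) - 1.0, 1.0, 3.0, xtol=1e-14))


def peak_sensitivity_time(k_off: float) -> float:
    """Time (s) of maximal sensitivity of R to k_off."""
    k_off = _require_finite_positive(k_off, "k_off")
    return peak_sensitivity_kt() / k_off


def equilibrium_split(lysate: LysateComposition, rates: RateConstants) -> SystemState:
    """Free/bound partition of one lysate at binding equilibrium.

    Solves the detailed-balance condition
    ``k_on * [A_free] * [B_free] = k_off * [AB]`` together with mass
    conservation.  The bound concentration x is the smaller root of

        x^2 - (A0 + B0 + K_d) x + A0 B0 = 0

    (the root with non-negative free concentrations), evaluated in a
    cancellation-free form: in the weakly bound regime x itself is
    computed as ``2 A0 B0 / (s + sqrt(s^2 - 4 A0 B0))`` with
    ``s = A0 + B0 + K_d``; in the tightly bound regime, where
    ``min(A0,B0) - x`` would cancel catastrophically, the free
    concentration of the limiting subunit is solved from its own
    quadratic instead and x derived from it.  The detailed-balance
    residual is therefore at rounding level in every regime, and the
    mass totals are conserved to within a unit in the last place.
    """
    A0, B0 = lysate.total_A, lysate.total_B
    kd = rates.dissociation_constant
    conc = {name: 0.0 for name in SPECIES}
    free_a_name, free_b_name, complex_name = lysate.species_names
    if A0 == 0.0 or B0 == 0.0:
        conc[free_a_name] = A0
        conc[free_b_name] = B0
        return SystemState(t=0.0, conc=conc)
    S, L = min(A0, B0), max(A0, B0)
    s = A0 + B0 + kd
    disc = s * s - 4.0 * A0 * B0
    if disc < 0.0:  # impossible for positive inputs; guard against NaN
        raise AssertionError("equilibrium quadratic has no real root")
    x = 2.0 * A0 * B0 / (s + math.sqrt(disc))
    if x <= 0.5 * S:
        # weak binding: x is the small quantity and is already stable
        free_a, free_b = A0 - x, B0 - x
    else:
        # tight binding: solve the limiting subunit's free concentration
        # directly: f^2 + (L - S + kd) f - kd S = 0, positive root
        d = L - S + kd
        s_free = 2.0 * kd * S / (d + math.sqrt(d * d + 4.0 * kd * S))
        x = S - s_free
        l_free = (L - S) + s_free
        free_a, free_b = (s_free, l_free) if A0 <= B0 else (l_free, s_free)
    conc[complex_name] = x
    conc[free_a_name] = free_a
    conc[free_b_name] = free_b
    return SystemState(t=0.0, conc=conc)
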