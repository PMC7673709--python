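"""Forward models for speckle field and intensity autocorrelation functions.

The field autocorrelation of light scattered by moving particles is modelled
as a stretched/compressed exponential ``g1(tau) = exp(-(tau/tau_c)**n)``
whose exponent ``n`` encodes the dynamic light scattering regime:

* ``n = 0.5`` — multiple scattering, unordered motion (MU),
* ``n = 1``   — single scattering unordered / multiple scattering ordered (SU/MO),
* ``n = 2``   — single scattering, ordered motion (SO).

The measured intensity autocorrelation ``g2(tau)`` follows from the Siegert
relation, generalized for partial coherence (``beta``), a static scattering
fraction (``1 - rho``, which adds a heterodyne term linear in ``g1``), a
constant noise offset ``C`` and a two-component mixture of field correlation
forms (fraction ``d`` of a second component with exponent ``X``):

    g2 = 1 + beta * rho**2 * m(tau)**2 + 2*beta*(1-rho)*rho * m(tau) + C
    m(tau) = d * g1_X(tau) + (1 - d) * g1_1(tau)

Simpler models are obtained at parameter degeneracies (``d = 0``, ``rho = 1``,
``C = 0``), which is what the nested model-selection chain in
:mod:`dlsi.fitting` exploits.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "FIELD_FORMS",
    "MIX_EXPONENTS",
    "DLSIParams",
    "ModelLevel",
    "ModelSpec",
    "Regime",
    "g1_value",
    "mixture_g1",
    "g2_forward",
    "classify_regime",
    "REGIME_NAMES",
]

#: Admissible field-correlation exponents (dynamic light scattering regimes).
FIELD_FORMS = (0.5, 1.0, 2.0)

#: Admissible exponents for the second component of a mixed model.
MIX_EXPONENTS = (0.5, 2.0)


class InvalidParameterError(ValueError):
    """A model parameter lies outside its physical range."""


def _check_n(n: float) -> float:
    n = float(n)
    if n not in FIELD_FORMS:
        raise InvalidParameterError(f"field form n must be one of {FIELD_FORMS}, got {n}")
    return n


@dataclass(frozen=True)
class DLSIParams:
    """Parameter vector of the generalized intensity-autocorrelation model.

    Attributes
    ----------
    beta : float
        Composite coherence factor in [0, 1] (source coherence plus spatial
        and temporal speckle averaging).
    rho : float
        Dynamic-scattering fraction in [0, 1]; ``1 - rho`` is the static
        scattering fraction.
    tau_c : float
        Decorrelation time constant in seconds, > 0.
    d : float
        Intensity fraction of the second (exponent ``X``) dynamic component,
        in [0, 1]. ``d = 0`` collapses the mixture to the pure n=1 form.
    X : float
        Exponent of the second component, 0.5 or 2.
    C : float
        Constant offset from measurement noise / finite sampling, in [-1, 1].
    """

    beta: float
    rho: float
    tau_c: float
    d: float = 0.0
    X: float = 0.5
    C: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.beta <= 1.0:
            raise InvalidParameterError(f"beta must be in [0, 1], got {self.beta}")
        if not 0.0 <= self.rho <= 1.0:
            raise InvalidParameterError(f"rho must be in [0, 1], got {self.rho}")
        if not self.tau_c > 0.0:
            raise InvalidParameterError(f"tau_c must be > 0, got {self.tau_c}")
        if not 0.0 <= self.d <= 1.0:
            raise InvalidParameterError(f"d must be in [0, 1], got {self.d}")
        if float(self.X) not in MIX_EXPONENTS:
            raise InvalidParameterError(f"X must be one of {MIX_EXPONENTS}, got {self.X}")
        if not -1.0 <= self.C <= 1.0:
            raise InvalidParameterError(f"C must be in [-1, 1], got {self.C}")


class ModelLevel(enum.IntEnum):
    """Nested model complexity levels, ordered by free-parameter count."""

    SIEGERT = 0          # beta, tau_c
    SIEGERT_OFFSET = 1   # + C
    STATIC = 2           # + rho
    MIXED = 3            # + d (with discrete X)


_FREE_PARAMS = {
    ModelLevel.SIEGERT: 2,
    ModelLevel.SIEGERT_OFFSET: 3,
    ModelLevel.STATIC: 4,
    ModelLevel.MIXED: 5,
}


@dataclass(frozen=True)
class ModelSpec:
    """Identity of one model in the nested family.

    ``n_fixed`` selects the field-correlation exponent for levels below
    MIXED; ``X`` selects the second-component exponent at the MIXED level
    (whose first component is always n = 1).
    """

    level: ModelLevel
    n_fixed: float = 1.0
    X: float = 0.5

    def __post_init__(self) -> None:
        _check_n(self.n_fixed)
        if float(self.X) not in MIX_EXPONENTS:
            raise InvalidParameterError(f"X must be one of {MIX_EXPONENTS}, got {self.X}")

    @property
    def free_parameter_count(self) -> int:
        return _FREE_PARAMS[self.level]


class Regime(enum.IntEnum):
    """Dynamic light scattering regime labels (five-way taxonomy)."""

    INVALID = -1
    MU_N05 = 0          # multiple scattering, unordered motion (n = 0.5)
    SU_MO_N1 = 1        # single unordered / multiple ordered (n = 1)
    SO_N2 = 2           # single scattering, ordered motion (n = 2)
    MIXED_MU_TO_N1 = 3  # mixture of n = 0.5 and n = 1
    MIXED_N1_TO_SO = 4  # mixture of n = 1 and n = 2


REGIME_NAMES = {
    Regime.INVALID: "invalid",
    Regime.MU_N05: "MU_n05",
    Regime.SU_MO_N1: "SU_MO_n1",
    Regime.SO_N2: "SO_n2",
    Regime.MIXED_MU_TO_N1: "mixed_MU_to_n1",
    Regime.MIXED_N1_TO_SO: "mixed_n1_to_SO",
}


def g1_value(tau, tau_c: float, n: float):
    """Field autocorrelation ``exp(-(tau/tau_c)**n)``.

    Parameters
    ----------
    tau : float or ndarray
        Time lag(s), seconds, >= 0.
    tau_c : float
        Decorrelation time constant, seconds, > 0.
    n : float
        Field-correlation exponent, one of 0.5, 1, 2.
    """
    n = _check_n(n)
    if not tau_c > 0.0:
        raise InvalidParameterError(f"tau_c must be > 0, got {tau_c}")
    tau = np.asarray(tau, dtype=float)
    if np.any(tau < 0):
        raise InvalidParameterError("tau must be >= 0")
    out = np.exp(-((tau / tau_c) ** n))
    return out if out.ndim else float(out)


def mixture_g1(tau, tau_c: float, d: float, X: float):
    """Intensity-weighted two-component field correlation.

    Returns ``d * g1(tau; X) + (1 - d) * g1(tau; n=1)``: the cross terms of
    the two fields vanish because the component fields are uncorrelated.
    """
    if not 0.0 <= d <= 1.0:
        raise InvalidParameterError(f"d must be in [0, 1], got {d}")
    if float(X) not in MIX_EXPONENTS:
        raise InvalidParameterError(f"X must be one of {MIX_EXPONENTS}, got {X}")
    return d * g1_value(tau, tau_c, X) + (1.0 - d) * g1_value(tau, tau_c, 1.0)


def g2_forward(tau, params: DLSIParams):
    """Generalized intensity autocorrelation model.

    ``g2 = 1 + beta*rho**2*m**2 + 2*beta*(1-rho)*rho*m + C`` with
    ``m = d*g1_X + (1-d)*g1_1``. At ``rho = 1, C = 0, d in {0, 1}`` this
    reduces to the Siegert relation ``1 + beta*g1**2``.
    """
    m = mixture_g1(tau, params.tau_c, params.d, params.X)
    b, r = params.beta, params.rho
    return 1.0 + b * r * r * m * m + 2.0 * b * (1.0 - r) * r * m + params.C


def classify_regime(X: float, d: float, *, purity: float = 0.05) -> Regime:
    """Map a mixture (X, d) to the five-way regime taxonomy.

    ``d`` within ``purity`` of 0 is the pure n=1 regime regardless of ``X``;
    within ``purity`` of 1 it is the pure second-component regime; anything
    in between is a mixed regime. The purity tolerance is a convention
    (maps colour a continuum); 0.05 by default.
    """
    if float(X) not in MIX_EXPONENTS:
        raise InvalidParameterError(f"X must be one of {MIX_EXPONENTS}, got {X}")
    if not 0.0 <= d <= 1.0:
        raise InvalidParameterError(f"d must be in [0, 1], got {d}")
    if d <= purity:
        return Regime.SU_MO_N1
    if d >= 1.0 - purity:
        return Regime.MU_N05 if float(X) == 0.5 else Regime.SO_N2
    return Regime.MIXED_MU_TO_N1 if float(X) == 0.5 else Regime.MIXED_N1_TO_SO


def regime_for_pure_n(n: float) -> Regime:
    """Regime label of a single-component model with exponent ``n``."""
    n = _check_n(n)
    return {0.5: Regime.MU_N05, 1.0: Regime.SU_MO_N1, 2.0: Regime.SO_N2}[n]
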