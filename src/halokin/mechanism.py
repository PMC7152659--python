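"""Catalytic-cycle reaction schemes for haloalkane dehalogenases.

The enzyme converts a halogenated substrate through a covalent alkyl-enzyme
intermediate:

    E + S <=> ES -> EI -> EP -> E + P        (four-step cycle)
    E + S <=> ES -> EI -> E + P              (simplified three-step cycle)

with microscopic rate constants k1 (substrate binding, uM^-1 s^-1),
k-1 (dissociation, s^-1), k2 (SN2 carbon-halogen cleavage, s^-1),
k3 (hydrolysis of the alkyl-enzyme, s^-1), k4 (product release, s^-1) and
k-4 (product rebinding, uM^-1 s^-1, normally 0).  The module integrates the
mass-action ODEs and derives steady-state constants (kcat, Km, Ks,
kcat/Km) analytically from the microscopic constants.

All concentrations are in uM, times in s.
"""

from __future__ import annotations

import enum
import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.integrate import solve_ivp

__all__ = [
    "SchemeId",
    "ParamStatus",
    "Mechanism",
    "RateParameters",
    "ConfigurationError",
    "IntegrationError",
    "DegenerateMechanismError",
    "DegenerateMechanismWarning",
    "build_mechanism",
    "simulate_timecourse",
    "derived_kcat",
    "derived_km",
    "ks_from_rates",
    "specificity",
    "rate_limiting_step",
    "SPECIES",
]

#: Canonical species order used in trajectories and CSV output.
SPECIES = ("E", "S", "ES", "EI", "EP", "P")

#: Fast binding rate substituted when only Ks is specified (rapid equilibrium).
RAPID_EQ_K1 = 10.0  # uM^-1 s^-1


class ConfigurationError(ValueError):
    """Invalid mechanism or parameter configuration."""


class IntegrationError(RuntimeError):
    """ODE solver failure; carries the time at which integration stopped."""

    def __init__(self, message: str, t_fail: float | None = None):
        super().__init__(message)
        self.t_fail = t_fail


class DegenerateMechanismError(ZeroDivisionError):
    """A required rate constant is zero, making a derived quantity undefined."""


class DegenerateMechanismWarning(UserWarning):
    """A required forward rate is zero; derived turnover collapses to 0."""


class SchemeId(str, enum.Enum):
    FOUR_STEP = "four_step"
    THREE_STEP = "three_step"


class ParamStatus(str, enum.Enum):
    FIXED = "fixed"
    FREE = "free"
    LOWER_BOUND_ONLY = "lower_bound_only"


@dataclass(frozen=True)
class Mechanism:
    """Reaction-scheme topology: species roles and elementary steps."""

    scheme_id: SchemeId
    rapid_equilibrium_binding: bool
    species: tuple[str, ...]
    #: list of (reactants, products, rate-constant label)
    steps: tuple[tuple[tuple[str, ...], tuple[str, ...], str], ...]

    @property
    def n_species(self) -> int:
        return len(self.species)

    @property
    def n_steps(self) -> int:
        return len(self.steps)

    @property
    def rate_labels(self) -> tuple[str, ...]:
        return tuple(s[2] for s in self.steps)


_FOUR_STEP_STEPS = (
    (("E", "S"), ("ES",), "k1"),
    (("ES",), ("E", "S"), "k_minus1"),
    (("ES",), ("EI",), "k2"),
    (("EI",), ("EP",), "k3"),
    (("EP",), ("E", "P"), "k4"),
    (("E", "P"), ("EP",), "k_minus4"),
)

_THREE_STEP_STEPS = (
    (("E", "S"), ("ES",), "k1"),
    (("ES",), ("E", "S"), "k_minus1"),
    (("ES",), ("EI",), "k2"),
    (("EI",), ("E", "P"), "k3"),
)


def build_mechanism(
    scheme_id: SchemeId | str, rapid_equilibrium_binding: bool = False
) -> Mechanism:
    """Build a catalytic-cycle mechanism.

    Parameters
    ----------
    scheme_id : {"four_step", "three_step"}
        ``four_step`` is the full cycle through the enzyme-product complex EP;
        ``three_step`` collapses hydrolysis and release into one step (no EP).
    rapid_equilibrium_binding : bool
        When True the binding step is parameterized by the dissociation
        constant Ks instead of individual k1/k-1 (the regime where binding
        equilibrates much faster than chemistry).
    """
    try:
        scheme = SchemeId(scheme_id)
    except ValueError:
        raise ConfigurationError(
            f"unknown scheme_id {scheme_id!r}; expected 'four_step' or 'three_step'"
        ) from None
    if scheme is SchemeId.FOUR_STEP:
        return Mechanism(scheme, rapid_equilibrium_binding, SPECIES, _FOUR_STEP_STEPS)
    species = tuple(s for s in SPECIES if s != "EP")
    return Mechanism(scheme, rapid_equilibrium_binding, species, _THREE_STEP_STEPS)


@dataclass
class RateParameters:
    """Microscopic rate constants of the catalytic cycle.

    Units: k1, k_minus4 in uM^-1 s^-1; k_minus1, k2, k3, k4 in s^-1;
    Ks in uM.  ``status`` records fixed/free/lower_bound_only per label
    (used by the fitting layer; lower-bound-only constants are treated as
    effectively infinite in closed-form derivations).
    """

    k1: float = 0.0
    k_minus1: float = 0.0
    k2: float = 0.0
    k3: float = 0.0
    k4: float = 0.0
    k_minus4: float = 0.0
    Ks: float | None = None
    status: dict[str, ParamStatus] = field(default_factory=dict)

    _RATE_LABELS = ("k1", "k_minus1", "k2", "k3", "k4", "k_minus4")

    def __post_init__(self) -> None:
        for label in self._RATE_LABELS:
            if getattr(self, label) < 0:
                raise ConfigurationError(f"rate constant {label} must be >= 0")
        if self.Ks is not None and self.Ks < 0:
            raise ConfigurationError("Ks must be >= 0")
        self.status = {k: ParamStatus(v) for k, v in self.status.items()}

    def status_of(self, label: str) -> ParamStatus:
        return self.status.get(label, ParamStatus.FREE)

    def is_lower_bound(self, label: str) -> bool:
        return self.status_of(label) is ParamStatus.LOWER_BOUND_ONLY

    def resolve_binding(self, mechanism: Mechanism) -> "RateParameters":
        """Return parameters with explicit k1/k-1 for ODE integration.

        Under rapid-equilibrium binding, Ks is the binding descriptor; a fast
        explicit pair (k1 = RAPID_EQ_K1, k-1 = Ks*k1) is substituted so a
        single ODE path serves both regimes.
        """
        if not mechanism.rapid_equilibrium_binding:
            return self
        if self.Ks is None:
            raise ConfigurationError(
                "rapid_equilibrium_binding requires Ks to be set"
            )
        return replace(self, k1=RAPID_EQ_K1, k_minus1=self.Ks * RAPID_EQ_K1)

    def ks(self) -> float:
        """Binding dissociation constant: explicit Ks or k-1/k1."""
        if self.Ks is not None:
            return self.Ks
        return ks_from_rates(self.k1, self.k_minus1)


def _rhs_four_step(t, y, k1, km1, k2, k3, k4, km4):
    E, S, ES, EI, EP, P = y
    bind = k1 * E * S
    unbind = km1 * ES
    chem = k2 * ES
    hyd = k3 * EI
    rel = k4 * EP
    rebind = km4 * E * P
    return (
        -bind + unbind + rel - rebind,       # E
        -bind + unbind,                      # S
        bind - unbind - chem,                # ES
        chem - hyd,                          # EI
        hyd - rel + rebind,                  # EP
        rel - rebind,                        # P
    )


def _rhs_three_step(t, y, k1, km1, k2, k3):
    E, S, ES, EI, P = y
    bind = k1 * E * S
    unbind = km1 * ES
    chem = k2 * ES
    hyd = k3 * EI
    return (
        -bind + unbind + hyd,
        -bind + unbind,
        bind - unbind - chem,
        chem - hyd,
        hyd,
    )


def simulate_timecourse(
    mechanism: Mechanism,
    rates: RateParameters,
    E0: float,
    S0: float,
    time_grid: np.ndarray,
    solver_options: dict | None = None,
) -> np.ndarray:
    """Integrate the catalytic-cycle ODEs on a time grid.

    Returns an array of shape ``(len(time_grid), 6)`` with columns in
    :data:`SPECIES` order (EP is identically 0 for the three-step scheme).
    The initial state is E=E0, S=S0, all complexes and product 0.

    Mass conservation (enzyme ledger E+ES+EI+EP = E0 and substrate ledger
    S+ES+EI+EP+P = S0) holds at every output time to 1e-6 * max(E0, S0).
    Tiny negative solver excursions are clamped to 0; clamping beyond
    1e-6 * max(E0, S0) raises :class:`IntegrationError`.
    """
    time_grid = np.asarray(time_grid, dtype=float)
    if E0 < 0 or S0 < 0:
        raise ConfigurationError("E0 and S0 must be >= 0")
    if time_grid.ndim != 1 or time_grid.size < 1 or time_grid[0] != 0.0:
        raise ConfigurationError("time_grid must be 1-D and start at 0")
    if time_grid.size > 1 and not np.all(np.diff(time_grid) > 0):
        raise ConfigurationError("time_grid must be strictly increasing")

    opts = {"method": "LSODA", "rtol": 1e-8, "atol": 1e-10}
    if solver_options:
        opts.update(solver_options)

    r = rates.resolve_binding(mechanism)
    if mechanism.scheme_id is SchemeId.FOUR_STEP:
        rhs = _rhs_four_step
        args = (r.k1, r.k_minus1, r.k2, r.k3, r.k4, r.k_minus4)
        y0 = [E0, S0, 0.0, 0.0, 0.0, 0.0]
    else:
        rhs = _rhs_three_step
        args = (r.k1, r.k_minus1, r.k2, r.k3)
        y0 = [E0, S0, 0.0, 0.0, 0.0]

    if time_grid.size == 1:
        states = np.array([y0])
    else:
        sol = solve_ivp(
            rhs, (0.0, time_grid[-1]), y0, t_eval=time_grid, args=args, **opts
        )
        if not sol.success:
            t_fail = float(sol.t[-1]) if sol.t.size else 0.0
            raise IntegrationError(
                f"ODE integration failed at t={t_fail:.6g} s: {sol.message}", t_fail
            )
        states = sol.y.T

    scale = max(E0, S0, 1.0)
    worst = -states.min(initial=0.0)
    if worst > 1e-6 * scale:
        raise IntegrationError(
            f"negative concentration {-worst:.3g} uM exceeds clamp tolerance"
        )
    states = np.clip(states, 0.0, None)

    if mechanism.scheme_id is SchemeId.THREE_STEP:
        full = np.zeros((states.shape[0], 6))
        full[:, [0, 1, 2, 3, 5]] = states  # E,S,ES,EI,P ; EP stays 0
        states = full
    return states


def _effective_forward(rates: RateParameters, label: str) -> float:
    """Forward rate for closed-form derivations; bound-only entries -> +inf."""
    if rates.is_lower_bound(label):
        return math.inf
    return getattr(rates, label)


def derived_kcat(rates: RateParameters, mechanism: Mechanism) -> float:
    """Turnover number from the microscopic forward constants.

    For a linear chain of irreversible post-binding steps the turnover time
    is the sum of the step times, so kcat is the harmonic-style mean
    ``(1/k2 + 1/k3 + 1/k4)^-1`` (four-step) or ``(1/k2 + 1/k3)^-1``
    (three-step).  Lower-bound-only constants are treated as infinitely
    fast, yielding an upper bound on kcat.
    """
    labels = (
        ("k2", "k3", "k4")
        if mechanism.scheme_id is SchemeId.FOUR_STEP
        else ("k2", "k3")
    )
    total = 0.0
    for lab in labels:
        k = _effective_forward(rates, lab)
        if k == 0:
            warnings.warn(
                f"forward rate {lab} is 0: turnover is blocked, kcat = 0",
                DegenerateMechanismWarning,
                stacklevel=2,
            )
            return 0.0
        total += 1.0 / k
    if total == 0.0:  # every step flagged as a bound
        return math.inf
    return 1.0 / total


def derived_km(rates: RateParameters, mechanism: Mechanism) -> float:
    """Michaelis constant from microscopic constants (irreversible release).

    Steady-state algebra of the linear chain gives
    ``Km = kcat * (k-1 + k2) / (k1 * k2)``; under rapid-equilibrium binding
    (k-1 >> k2, binding described by Ks) this reduces to
    ``Km = Ks * kcat / k2``.
    """
    k2 = _effective_forward(rates, "k2")
    if k2 == 0:
        raise DegenerateMechanismError("k2 = 0: Km is undefined")
    kcat = derived_kcat(rates, mechanism)
    if mechanism.rapid_equilibrium_binding or (
        rates.Ks is not None and rates.k1 == 0
    ):
        ks = rates.ks()
        if math.isinf(k2):
            return ks  # pure binding pre-equilibrium
        return ks * kcat / k2
    if rates.k1 == 0:
        raise DegenerateMechanismError("k1 = 0: Km is undefined")
    if math.isinf(k2):
        return rates.k_minus1 / rates.k1
    return kcat * (rates.k_minus1 + k2) / (rates.k1 * k2)


def ks_from_rates(k1: float, k_minus1: float) -> float:
    """Equilibrium dissociation constant of the ES complex, Ks = k-1/k1 (uM)."""
    if k1 == 0:
        raise DegenerateMechanismError("k1 = 0: Ks = k_minus1/k1 is undefined")
    return k_minus1 / k1


def specificity(
    kcat: float,
    Km: float,
    se_kcat: float | None = None,
    se_Km: float | None = None,
) -> float | tuple[float, float]:
    """Specificity constant kcat/Km (uM^-1 s^-1), with propagated SE if given."""
    if Km == 0:
        raise DegenerateMechanismError("Km = 0: kcat/Km is undefined")
    ratio = kcat / Km
    if se_kcat is None and se_Km is None:
        return ratio
    from .fitting import propagate_ratio_error

    return propagate_ratio_error(kcat, se_kcat or 0.0, Km, se_Km or 0.0)


def rate_limiting_step(
    rates: RateParameters, mechanism: Mechanism
) -> tuple[str, ...]:
    """Label(s) of the slowest post-binding forward step(s).

    Lower-bound-only constants are never limiting.  Ties return all tied
    labels.
    """
    labels = (
        ("k2", "k3", "k4")
        if mechanism.scheme_id is SchemeId.FOUR_STEP
        else ("k2", "k3")
    )
    vals = {lab: _effective_forward(rates, lab) for lab in labels}
    kmin = min(vals.values())
    if math.isinf(kmin):
        return ()
    return tuple(lab for lab, v in vals.items() if v == kmin)
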