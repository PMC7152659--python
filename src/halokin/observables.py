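"""Fluorescence observable models mapping species trajectories to signals.

The fluorogenic substrate BDP reports on the reaction through two stopped-flow
channels.  Direct excitation at 500 nm gives

    V1 = f * (S + ES + a*EI + b*(EP + P))

where ``a`` and ``b`` scale the intensity of the covalent alkyl-enzyme
intermediate and of the (bound or free) product relative to the substrate.
Tryptophan excitation at 280 nm adds FRET from active-site tryptophans:

    V2 = f * (S + o*ES + p*EI + q*EP + r*P)

with empirical per-species factors o, p, q, r combining FRET efficiency and
intrinsic intensity changes.  ``f`` converts concentration (uM) to signal
units; an optional per-trace additive baseline models instrument drift.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np

__all__ = ["Channel", "SignalCoefficients", "signal_v1", "signal_v2", "identity_observable"]

# column indices in SPECIES order (E, S, ES, EI, EP, P)
_S, _ES, _EI, _EP, _P = 1, 2, 3, 4, 5


class Channel(str, enum.Enum):
    V1_EX500 = "V1_ex500"
    V2_EX280 = "V2_ex280"


@dataclass(frozen=True)
class SignalCoefficients:
    """Per-species scaling factors for one fluorescence channel.

    V1 uses exactly {f, a, b}; V2 uses exactly {f, o, p, q, r}.
    """

    channel: Channel
    f: float = 1.0
    a: float = 1.0
    b: float = 1.0
    o: float = 1.0
    p: float = 1.0
    q: float = 1.0
    r: float = 1.0
    baseline: float = 0.0

    def __post_init__(self):
        if self.f < 0:
            raise ValueError("overall scale f must be >= 0")
        object.__setattr__(self, "channel", Channel(self.channel))

    def as_dict(self) -> dict[str, float]:
        if self.channel is Channel.V1_EX500:
            return {"f": self.f, "a": self.a, "b": self.b, "baseline": self.baseline}
        return {
            "f": self.f, "o": self.o, "p": self.p, "q": self.q, "r": self.r,
            "baseline": self.baseline,
        }


def signal_v1(states: np.ndarray, coeffs: SignalCoefficients) -> np.ndarray:
    """Direct-excitation signal V1 = f*(S + ES + a*EI + b*(EP+P)) per frame."""
    if coeffs.channel is not Channel.V1_EX500:
        raise ValueError(f"signal_v1 requires channel V1_ex500, got {coeffs.channel.value}")
    st = np.atleast_2d(np.asarray(states, dtype=float))
    return (
        coeffs.f
        * (st[:, _S] + st[:, _ES] + coeffs.a * st[:, _EI]
           + coeffs.b * (st[:, _EP] + st[:, _P]))
        + coeffs.baseline
    )


def signal_v2(states: np.ndarray, coeffs: SignalCoefficients) -> np.ndarray:
    """FRET-modulated signal V2 = f*(S + o*ES + p*EI + q*EP + r*P) per frame."""
    if coeffs.channel is not Channel.V2_EX280:
        raise ValueError(f"signal_v2 requires channel V2_ex280, got {coeffs.channel.value}")
    st = np.atleast_2d(np.asarray(states, dtype=float))
    return (
        coeffs.f
        * (st[:, _S] + coeffs.o * st[:, _ES] + coeffs.p * st[:, _EI]
           + coeffs.q * st[:, _EP] + coeffs.r * st[:, _P])
        + coeffs.baseline
    )


def identity_observable(states: np.ndarray, species: str = "P") -> np.ndarray:
    """Observe one species concentration directly (no fluorogenic model).

    Used for substrates like DBE whose kinetics were followed without a
    fluorescence signal model.
    """
    from .mechanism import SPECIES

    st = np.atleast_2d(np.asarray(states, dtype=float))
    return st[:, SPECIES.index(species)].copy()


def evaluate_observable(states: np.ndarray, coeffs: SignalCoefficients | None,
                        species: str = "P") -> np.ndarray:
    """Dispatch to the channel's signal model, or the identity observable."""
    if coeffs is None:
        return identity_observable(states, species)
    if coeffs.channel is Channel.V1_EX500:
        return signal_v1(states, coeffs)
    return signal_v2(states, coeffs)
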