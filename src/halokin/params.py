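"""Published kinetic parameter sets for LinB variants.

Steady-state (kcat, Km) and pre-steady-state (Ks, k1, k-1, k2, k3, k4)
constants for the haloalkane dehalogenase LinB wild type and its
tunnel-engineered variants LinB32 (L177W, main tunnel closed) and LinB86
(+W140A/F143L/I211L, p3 tunnel opened), with the substrates DBE
(1,2-dibromoethane), BDP (a fluorogenic BODIPY alkyl halide) and COU
(a coumarin alkyl halide).  Values carry standard errors; entries reported
only as lower bounds (e.g. "k3 > 10 s^-1") have ``status
lower_bound_only``.  Units: uM, s.

These sets serve as ground truth for the synthetic-data generators and as
reference values for analytic consistency checks; they are inputs, not
fitted outputs, of this package.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .mechanism import ParamStatus, RateParameters

__all__ = ["VariantKinetics", "REFERENCE_KINETICS", "get_reference"]


@dataclass(frozen=True)
class VariantKinetics:
    substrate: str
    variant: str
    scheme: str                       # four_step | three_step
    rapid_equilibrium: bool
    kcat: float
    kcat_se: float
    Km: float
    Km_se: float
    rates: RateParameters = field(default=None)  # type: ignore[assignment]
    rate_se: dict[str, float] = field(default_factory=dict)


def _rp(**kw) -> RateParameters:
    status = kw.pop("status", {})
    return RateParameters(status={k: ParamStatus(v) for k, v in status.items()}, **kw)


REFERENCE_KINETICS: dict[tuple[str, str], VariantKinetics] = {
    # DBE: rapid-equilibrium binding, Ks is the only binding descriptor
    ("DBE", "LinBwt"): VariantKinetics(
        "DBE", "LinBwt", "four_step", True, kcat=12, kcat_se=4,
        Km=1700, Km_se=200,
        rates=_rp(Ks=21000.0, k2=120.0, k3=139.0, k4=10.0),
        rate_se={"Ks": 1000.0, "k2": 10.0, "k3": 5.0, "k4": 1.0},
    ),
    ("DBE", "LinB32"): VariantKinetics(
        "DBE", "LinB32", "four_step", True, kcat=3.1, kcat_se=0.1,
        Km=420, Km_se=30,
        rates=_rp(Ks=37000.0, k2=330.0, k3=109.0, k4=3.2),
        rate_se={"Ks": 2000.0, "k2": 10.0, "k3": 4.0, "k4": 0.1},
    ),
    ("DBE", "LinB86"): VariantKinetics(
        "DBE", "LinB86", "four_step", True, kcat=57, kcat_se=3,
        Km=2350, Km_se=30,
        rates=_rp(Ks=17000.0, k2=350.0, k3=340.0, k4=70.0),
        rate_se={"Ks": 1000.0, "k2": 10.0, "k3": 10.0, "k4": 5.0},
    ),
    ("BDP", "LinBwt"): VariantKinetics(
        "BDP", "LinBwt", "four_step", False, kcat=2.3, kcat_se=0.2,
        Km=17, Km_se=1,
        rates=_rp(k1=2.4, k_minus1=90.0, k2=5.9, k3=10.0, k4=10.0,
                  status={"k3": "lower_bound_only", "k4": "lower_bound_only"}),
        rate_se={"k1": 0.1, "k_minus1": 3.0, "k2": 0.2},
    ),
    ("BDP", "LinB32"): VariantKinetics(
        "BDP", "LinB32", "four_step", False, kcat=1.1, kcat_se=0.1,
        Km=24, Km_se=4,
        rates=_rp(k1=2.8, k_minus1=65.0, k2=2.1, k3=12.0, k4=10.0,
                  status={"k4": "lower_bound_only"}),
        rate_se={"k1": 0.1, "k_minus1": 1.0, "k2": 0.1, "k3": 1.0},
    ),
    ("BDP", "LinB86"): VariantKinetics(
        "BDP", "LinB86", "four_step", False, kcat=0.015, kcat_se=0.001,
        Km=26, Km_se=2,
        rates=_rp(k1=0.024, k_minus1=1.7, k2=0.18, k3=0.011, k4=18.0),
        rate_se={"k1": 0.002, "k_minus1": 0.3, "k2": 0.01, "k3": 0.001, "k4": 3.0},
    ),
    # COU: the alkyl-enzyme intermediate and product could not be
    # distinguished, so the simplified three-step model applies
    ("COU", "LinBwt"): VariantKinetics(
        "COU", "LinBwt", "three_step", False, kcat=3.9, kcat_se=0.2,
        Km=0.7, Km_se=0.5,
        rates=_rp(k1=5.1, k_minus1=0.0, k2=6.5, k3=18.0),
        rate_se={"k1": 0.6, "k2": 0.1, "k3": 1.0},
    ),
    ("COU", "LinB32"): VariantKinetics(
        "COU", "LinB32", "three_step", False, kcat=0.68, kcat_se=0.02,
        Km=13, Km_se=1,
        rates=_rp(k1=0.50, k_minus1=40.0, k2=3.1, k3=1.14),
        rate_se={"k1": 0.05, "k_minus1": 2.0, "k2": 0.2, "k3": 0.03},
    ),
    ("COU", "LinB86"): VariantKinetics(
        "COU", "LinB86", "three_step", False, kcat=0.89, kcat_se=0.03,
        Km=30, Km_se=2,
        rates=_rp(k1=0.10, k_minus1=24.0, k2=3.6, k3=1.4),
        rate_se={"k1": 0.01, "k_minus1": 2.0, "k2": 0.2, "k3": 0.1},
    ),
}


def get_reference(substrate: str, variant: str) -> VariantKinetics:
    """Look up the published kinetics for a (substrate, variant) pair."""
    try:
        return REFERENCE_KINETICS[(substrate, variant)]
    except KeyError:
        known = ", ".join(f"{s}/{v}" for s, v in REFERENCE_KINETICS)
        raise KeyError(f"no reference kinetics for {substrate}/{variant}; known: {known}") from None
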