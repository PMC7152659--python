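"""Seeded synthetic-data generators emulating the study's experiments.

Four kinds of inputs are produced, each a pure function of its arguments and
a seed (repeated calls are bit-identical):

* stopped-flow fluorescence traces — mechanistic ODE time courses pushed
  through a signal model, plus i.i.d. Gaussian noise with known per-point
  sigma (the instrument's residuals are sigma-normalized downstream);
* steady-state initial-rate tables — Michaelis-Menten rates with Gaussian
  noise and replicate structure;
* discrete Markov trajectories from a known transition matrix, optionally
  with state-conditioned spherical-Gaussian feature emissions (a desk-scale
  stand-in for featurized MD trajectories);
* toy near-attack-conformer geometry frames (nucleophile-carbon distance,
  attack angle) with ground-truth labels.

Stopped-flow traces can emulate the instrument dead time (first ~1 ms after
mixing unobservable) and optional +-10% jitter of nominal concentrations,
recording true values for recovery scoring.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np

from .mechanism import (
    ConfigurationError,
    Mechanism,
    RateParameters,
    simulate_timecourse,
)
from .observables import SignalCoefficients, evaluate_observable

__all__ = [
    "ExperimentMode",
    "ExperimentDesign",
    "Trace",
    "InitialRatePoint",
    "KineticDataset",
    "SyntheticTrajectorySet",
    "generate_stopped_flow_dataset",
    "generate_initial_rate_dataset",
    "generate_markov_trajectories",
    "generate_nac_geometries",
]

#: Canonical NAC box used when drawing reactive-geometry frames.
NAC_DISTANCE_RANGE = (2.8, 3.41)   # Angstrom
NAC_ANGLE_RANGE = (157.0, 180.0)   # degrees


class ExperimentMode(str, enum.Enum):
    STOPPED_FLOW = "stopped_flow"
    STEADY_STATE = "steady_state"


@dataclass(frozen=True)
class ExperimentDesign:
    """Design of a synthetic kinetic experiment.

    ``noise_sd`` is an absolute sigma in signal units unless
    ``noise_is_fraction`` is set, in which case it is a fraction of the
    noiseless trace amplitude (stopped flow) or of each rate (steady state).
    ``dead_time_s`` drops samples before the instrument dead time.
    ``conc_jitter`` optionally perturbs nominal E0/S0 by up to +-10%.
    """

    mode: ExperimentMode
    enzyme_conc: float
    substrate_concs: tuple[float, ...]
    time_grid: np.ndarray | None = None
    replicates: int = 1
    noise_sd: float = 0.01
    noise_is_fraction: bool = True
    seed: int = 0
    dead_time_s: float = 0.0
    conc_jitter: float = 0.0

    def __post_init__(self):
        object.__setattr__(self, "mode", ExperimentMode(self.mode))
        object.__setattr__(self, "substrate_concs", tuple(self.substrate_concs))
        if not self.substrate_concs or any(s <= 0 for s in self.substrate_concs):
            raise ConfigurationError("substrate_concs must be non-empty and > 0")
        if self.replicates < 1:
            raise ConfigurationError("replicates must be >= 1")
        if not 0.0 <= self.conc_jitter <= 0.1:
            raise ConfigurationError("conc_jitter must be within [0, 0.1]")


@dataclass
class Trace:
    """One observed stopped-flow time course with per-point sigma."""

    time: np.ndarray
    signal: np.ndarray
    sigma: np.ndarray
    E0_nominal: float
    S0_nominal: float
    E0_true: float
    S0_true: float
    meta: dict = field(default_factory=dict)


@dataclass(frozen=True)
class InitialRatePoint:
    S0: float
    E0: float
    v0: float
    sigma: float


@dataclass
class KineticDataset:
    """Heterogeneous kinetic dataset: traces and/or initial-rate tables.

    ``truth`` records the generating parameters of synthetic data so
    recovery can be scored.
    """

    traces: list[Trace] = field(default_factory=list)
    initial_rates: list[InitialRatePoint] = field(default_factory=list)
    truth: dict = field(default_factory=dict)

    def __post_init__(self):
        for tr in self.traces:
            if np.any(tr.sigma <= 0):
                raise ConfigurationError("every trace observation needs sigma > 0")
        for pt in self.initial_rates:
            if pt.sigma <= 0:
                raise ConfigurationError("every initial-rate point needs sigma > 0")


def generate_stopped_flow_dataset(
    mechanism: Mechanism,
    rates: RateParameters,
    coeffs: SignalCoefficients | None,
    design: ExperimentDesign,
    observed_species: str = "P",
) -> KineticDataset:
    """Simulate noisy stopped-flow traces for each substrate concentration.

    For every (S0, replicate) pair the mechanistic ODEs are integrated, the
    observable evaluated (``coeffs=None`` observes ``observed_species``
    directly), and Gaussian noise of the designed sigma added.  Same design
    seed => bit-identical dataset.
    """
    if design.mode is not ExperimentMode.STOPPED_FLOW:
        raise ConfigurationError("design.mode must be stopped_flow")
    if design.noise_sd < 0:
        raise ConfigurationError("noise_sd must be >= 0")
    if design.time_grid is None:
        raise ConfigurationError("stopped-flow design requires a time_grid")
    rng = np.random.default_rng(design.seed)
    time_grid = np.asarray(design.time_grid, dtype=float)
    keep = time_grid >= design.dead_time_s
    keep[0] = keep[0] and design.dead_time_s <= 0.0

    traces: list[Trace] = []
    for S0 in design.substrate_concs:
        for rep in range(design.replicates):
            E_true, S_true = design.enzyme_conc, S0
            if design.conc_jitter > 0:
                E_true *= 1.0 + rng.uniform(-design.conc_jitter, design.conc_jitter)
                S_true *= 1.0 + rng.uniform(-design.conc_jitter, design.conc_jitter)
            states = simulate_timecourse(mechanism, rates, E_true, S_true, time_grid)
            clean = evaluate_observable(states, coeffs, observed_species)
            amplitude = float(np.ptp(clean))
            sd = (
                design.noise_sd * amplitude
                if design.noise_is_fraction
                else design.noise_sd
            )
            noisy = clean + rng.normal(0.0, sd, size=clean.shape) if sd > 0 else clean.copy()
            sigma = np.full_like(clean, sd if sd > 0 else 1.0)
            traces.append(
                Trace(
                    time=time_grid[keep].copy(),
                    signal=noisy[keep],
                    sigma=sigma[keep],
                    E0_nominal=design.enzyme_conc,
                    S0_nominal=S0,
                    E0_true=E_true,
                    S0_true=S_true,
                    meta={"replicate": rep, "noise_sd": sd},
                )
            )
    truth = {
        "rates": rates,
        "coeffs": coeffs,
        "seed": design.seed,
        "scheme": mechanism.scheme_id.value,
    }
    return KineticDataset(traces=traces, truth=truth)


def generate_initial_rate_dataset(
    kcat: float, Km: float, E0: float, design: ExperimentDesign
) -> KineticDataset:
    """Simulate a steady-state initial-rate table v0 = kcat*E0*S/(Km+S) + noise."""
    if design.mode is not ExperimentMode.STEADY_STATE:
        raise ConfigurationError("design.mode must be steady_state")
    if Km <= 0:
        raise ConfigurationError("Km must be > 0")
    rng = np.random.default_rng(design.seed)
    points: list[InitialRatePoint] = []
    for S in design.substrate_concs:
        v_clean = kcat * E0 * S / (Km + S)
        sd = design.noise_sd * v_clean if design.noise_is_fraction else design.noise_sd
        for _ in range(design.replicates):
            v = v_clean + (rng.normal(0.0, sd) if sd > 0 else 0.0)
            points.append(InitialRatePoint(S, E0, v, sd if sd > 0 else 1.0))
    truth = {"kcat": kcat, "Km": Km, "E0": E0, "seed": design.seed}
    return KineticDataset(initial_rates=points, truth=truth)


@dataclass
class SyntheticTrajectorySet:
    """Discrete trajectories from a known chain, with optional emissions."""

    transition_matrix: np.ndarray
    state_sequences: list[np.ndarray]
    feature_emissions: list[np.ndarray] | None
    frame_interval: float = 1.0
    seed: int = 0


def _check_stochastic(T: np.ndarray) -> np.ndarray:
    T = np.asarray(T, dtype=float)
    if T.ndim != 2 or T.shape[0] != T.shape[1]:
        raise ConfigurationError("transition matrix must be square")
    if np.any(T < 0):
        raise ConfigurationError("transition matrix entries must be >= 0")
    sums = T.sum(axis=1)
    bad = np.where(np.abs(sums - 1.0) > 1e-12)[0]
    if bad.size:
        raise ConfigurationError(
            f"rows {bad.tolist()} of the transition matrix do not sum to 1 "
            f"(sums {sums[bad].tolist()})"
        )
    return T


def generate_markov_trajectories(
    T: np.ndarray,
    n_steps: int,
    n_traj: int = 1,
    emission_spec: dict | None = None,
    seed: int = 0,
) -> SyntheticTrajectorySet:
    """Sample discrete trajectories from a row-stochastic chain.

    Each trajectory starts from the uniform distribution over states.
    ``emission_spec`` = {"means": (n_states, d) array, "sd": float} attaches
    a spherical-Gaussian feature vector to every frame, conditioned on the
    hidden state — enough structure for TICA/clustering tests without MD
    realism.
    """
    T = _check_stochastic(T)
    if n_steps < 2:
        raise ConfigurationError("n_steps must be >= 2")
    n = T.shape[0]
    rng = np.random.default_rng(seed)
    cdf = np.cumsum(T, axis=1)
    seqs: list[np.ndarray] = []
    for _ in range(n_traj):
        s = np.empty(n_steps, dtype=np.int64)
        s[0] = rng.integers(n)
        u = rng.random(n_steps - 1)
        for t in range(1, n_steps):
            s[t] = np.searchsorted(cdf[s[t - 1]], u[t - 1], side="right")
        seqs.append(s)
    emissions = None
    if emission_spec is not None:
        means = np.asarray(emission_spec["means"], dtype=float)
        sd = float(emission_spec.get("sd", 1.0))
        emissions = [
            means[s] + rng.normal(0.0, sd, size=(n_steps, means.shape[1]))
            for s in seqs
        ]
    return SyntheticTrajectorySet(T, seqs, emissions, seed=seed)


def generate_nac_geometries(
    n_frames: int, fraction_nac: float, jitter: float = 0.0, seed: int = 0
):
    """Draw toy reaction-geometry frames with ground-truth NAC labels.

    NAC frames have nucleophile-carbon distance in [2.8, 3.41] Angstrom and
    attack angle in [157, 180] degrees; non-NAC frames fall outside at least
    one criterion.  ``jitter`` widens the non-NAC margin sampling.  Returns a
    pandas DataFrame with columns distance_A, angle_deg, is_nac.
    """
    import pandas as pd

    if not 0.0 <= fraction_nac <= 1.0:
        raise ConfigurationError("fraction_nac must be within [0, 1]")
    rng = np.random.default_rng(seed)
    is_nac = rng.random(n_frames) < fraction_nac
    d_lo, d_hi = NAC_DISTANCE_RANGE
    a_lo, a_hi = NAC_ANGLE_RANGE
    dist = np.empty(n_frames)
    ang = np.empty(n_frames)
    n_in = int(is_nac.sum())
    dist[is_nac] = rng.uniform(d_lo, d_hi, n_in)
    ang[is_nac] = rng.uniform(a_lo, a_hi, n_in)
    n_out = n_frames - n_in
    # non-reactive frames: too far, wrong angle, or both
    margin = 0.3 + jitter
    mode = rng.integers(0, 3, n_out)
    dist_out = np.where(
        mode != 1,
        rng.uniform(d_hi + 0.05, d_hi + 3.0 + margin, n_out),
        rng.uniform(d_lo, d_hi, n_out),
    )
    ang_out = np.where(
        mode != 0,
        rng.uniform(60.0, a_lo - 0.5 - jitter, n_out),
        rng.uniform(a_lo, a_hi, n_out),
    )
    dist[~is_nac] = dist_out
    ang[~is_nac] = ang_out
    return pd.DataFrame(
        {"distance_A": dist, "angle_deg": ang, "is_nac": is_nac}
    )
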