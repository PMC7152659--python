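"""Markov state models of ligand transport, with pathway flux and NAC analysis.

Pipeline (mirroring standard MSM practice for enzyme-ligand simulations):
featurize frames as a binary ligand-residue contact map (distance < 8 A),
reduce with time-lagged independent component analysis (TICA), cluster the
projections into microstates (MiniBatchKMeans), estimate a transition matrix
at a lag time, and validate by implied-timescale plateaus and
Chapman-Kolmogorov tests.  On top of the validated model, transition-path
theory decomposes the source-to-sink reactive flux among access-tunnel
channels, and equilibrium populations of macrostates are read from the
stationary distribution.

Frames can additionally be classified as near-attack conformers (NAC) from
reaction geometry: nucleophile-carbon distance <= 3.41 A and
nucleophile-carbon-halide angle within 157-180 degrees (bounds inclusive).

All trajectory input is desk-scale tabular data (distance tables, discrete
state sequences); parsing MD trajectory binaries is delegated upstream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

__all__ = [
    "MsmConfig",
    "TransitionModel",
    "NacCriteria",
    "TicaModel",
    "binary_contact_featurize",
    "tica",
    "cluster_microstates",
    "estimate_transition_model",
    "implied_timescales",
    "ck_test",
    "pathway_fractions",
    "classify_nac",
    "macrostate_population",
    "stationary_distribution",
]


@dataclass(frozen=True)
class MsmConfig:
    """Knobs of the MSM pipeline with field-standard defaults."""

    contact_cutoff: float = 8.0      # Angstrom, strict '<'
    tica_dims: int = 5
    tica_lag: int = 1                # frames (5 ns at the study's stride)
    n_clusters: int = 200
    msm_lag: int = 1                 # frames
    reversible: bool = False

    def __post_init__(self):
        if self.contact_cutoff <= 0:
            raise ValueError("contact_cutoff must be > 0")
        if self.tica_dims < 1 or self.tica_lag < 1 or self.msm_lag < 1:
            raise ValueError("dims and lags must be >= 1")
        if self.n_clusters < 2:
            raise ValueError("n_clusters must be >= 2")


@dataclass(frozen=True)
class NacCriteria:
    """Geometric near-attack-conformer criteria (inclusive bounds)."""

    max_distance: float = 3.41       # Angstrom
    angle_min: float = 157.0         # degrees
    angle_max: float = 180.0

    def __post_init__(self):
        if self.max_distance <= 0:
            raise ValueError("max_distance must be > 0")
        if not 0.0 <= self.angle_min <= self.angle_max <= 180.0:
            raise ValueError("angle range must satisfy 0 <= min <= max <= 180")


@dataclass
class TransitionModel:
    """Estimated Markov model on the largest connected state set."""

    count_matrix: np.ndarray
    transition_matrix: np.ndarray
    equilibrium_distribution: np.ndarray
    lag: int
    active_set: np.ndarray           # original state labels of the rows
    n_states_total: int
    reversible: bool = False
    dropped_states: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))

    @property
    def n_states(self) -> int:
        return self.transition_matrix.shape[0]

    def index_of(self, states) -> np.ndarray:
        """Map original state labels to model row indices."""
        lookup = {s: i for i, s in enumerate(self.active_set.tolist())}
        try:
            return np.array([lookup[s] for s in np.atleast_1d(states)])
        except KeyError as e:
            raise KeyError(f"state {e.args[0]} is not in the model's active set") from None


def binary_contact_featurize(distance_table: np.ndarray, cutoff: float = 8.0) -> np.ndarray:
    """Binarize a frames-by-pairs distance table: contact iff distance < cutoff."""
    d = np.asarray(distance_table, dtype=float)
    if np.any(d < 0):
        raise ValueError("distances must be >= 0")
    return (d < cutoff).astype(np.int8)


@dataclass
class TicaModel:
    components: np.ndarray           # (d, k) eigenvectors, columns
    eigenvalues: np.ndarray          # (k,), sorted descending
    mean: np.ndarray
    lag: int

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=float) - self.mean) @ self.components


def _as_traj_list(data) -> list[np.ndarray]:
    if isinstance(data, np.ndarray) and data.ndim == 2:
        return [data]
    return [np.asarray(x, dtype=float) for x in data]


def tica(features, lag: int, n_components: int) -> tuple[TicaModel, np.ndarray]:
    """Time-lagged independent component analysis.

    Solves the symmetrized generalized eigenproblem C_tau v = lambda C_0 v,
    where C_0 is the instantaneous and C_tau the lag-tau covariance of the
    mean-free features.  Eigenvalues are autocorrelations of the components
    at the lag (sorted descending); slow collective coordinates come first.
    Component sign is arbitrary.  A near-singular C_0 is ridge-regularized
    (1e-8 on the diagonal) with a warning.

    Returns ``(model, projections)`` with projections concatenated over
    trajectories.
    """
    trajs = _as_traj_list(features)
    d = trajs[0].shape[1]
    if n_components > d:
        raise ValueError("n_components exceeds the feature dimension")
    if all(t.shape[0] <= lag for t in trajs):
        raise ValueError("every trajectory is shorter than the lag")

    # symmetrized moments over all usable (t, t+lag) pairs
    n_pairs = 0
    sum_x = np.zeros(d)
    c0 = np.zeros((d, d))
    ct = np.zeros((d, d))
    for X in trajs:
        if X.shape[0] <= lag:
            continue
        A, B = X[:-lag], X[lag:]
        n_pairs += A.shape[0]
        sum_x += A.sum(axis=0) + B.sum(axis=0)
        c0 += A.T @ A + B.T @ B
        ct += A.T @ B + B.T @ A
    mean = sum_x / (2 * n_pairs)
    C0 = c0 / (2 * n_pairs) - np.outer(mean, mean)
    Ct = ct / (2 * n_pairs) - np.outer(mean, mean)

    ridge_used = False
    try:
        evals, evecs = linalg.eigh(Ct, C0)
    except linalg.LinAlgError:
        ridge_used = True
        C0 = C0 + 1e-8 * np.eye(d)
        warnings.warn("instantaneous covariance near-singular; ridge 1e-8 applied")
        evals, evecs = linalg.eigh(Ct, C0)
    if not ridge_used and not np.all(np.isfinite(evals)):
        C0 = C0 + 1e-8 * np.eye(d)
        warnings.warn("instantaneous covariance near-singular; ridge 1e-8 applied")
        evals, evecs = linalg.eigh(Ct, C0)
    order = np.argsort(evals)[::-1][:n_components]
    evals = evals[order]
    evecs = evecs[:, order]
    if np.any(np.abs(evals) > 1.0 + 1e-8):
        warnings.warn(
            f"TICA eigenvalues exceed 1 (max |lambda| = {np.abs(evals).max():.4f}); "
            "covariance estimate is noisy"
        )
    model = TicaModel(components=evecs, eigenvalues=evals, mean=mean, lag=lag)
    proj = np.vstack([model.transform(X) for X in trajs])
    return model, proj


def cluster_microstates(
    projections: np.ndarray, n_clusters: int, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Cluster TICA projections into microstates with MiniBatchKMeans.

    Deterministic for a given seed.  Clusters left empty by the mini-batch
    updates are removed and labels compacted (logged), so every returned
    cluster is non-empty.
    """
    from sklearn.cluster import MiniBatchKMeans

    X = np.asarray(projections, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if n_clusters > X.shape[0]:
        raise ValueError("n_clusters exceeds the number of frames")
    km = MiniBatchKMeans(
        n_clusters=n_clusters, random_state=seed, n_init=3, batch_size=256
    )
    labels = km.fit_predict(X)
    occupied = np.unique(labels)
    centers = km.cluster_centers_
    if occupied.size < n_clusters:
        warnings.warn(
            f"{n_clusters - occupied.size} empty cluster(s) removed; "
            f"{occupied.size} microstates remain"
        )
        remap = -np.ones(n_clusters, dtype=int)
        remap[occupied] = np.arange(occupied.size)
        labels = remap[labels]
        centers = centers[occupied]
    return labels, centers


def _count_matrix(dtrajs: list[np.ndarray], lag: int, n_states: int) -> np.ndarray:
    C = np.zeros((n_states, n_states))
    for s in dtrajs:
        if s.shape[0] <= lag:
            continue
        np.add.at(C, (s[:-lag], s[lag:]), 1.0)  # sliding window
    return C


def _reversible_mle(C: np.ndarray, tol: float = 1e-12, max_iter: int = 100000) -> np.ndarray:
    """Detailed-balance maximum-likelihood transition matrix.

    Fixed-point iteration on the symmetric edge weights x_ij:
    x_ij <- (c_ij + c_ji) / (c_i/x_i + c_j/x_j).
    """
    c_row = C.sum(axis=1)
    Cs = C + C.T
    x = Cs.copy()
    x[x == 0] = 0.0
    for _ in range(max_iter):
        x_row = x.sum(axis=1)
        denom = c_row[:, None] / x_row[:, None] + c_row[None, :] / x_row[None, :]
        x_new = np.where(Cs > 0, Cs / denom, 0.0)
        if np.max(np.abs(x_new - x)) < tol * max(1.0, x.max()):
            x = x_new
            break
        x = x_new
    T = x / x.sum(axis=1, keepdims=True)
    return T


def stationary_distribution(T: np.ndarray, tol: float = 1e-8) -> np.ndarray:
    """Stationary left eigenvector of a row-stochastic matrix, normalized."""
    evals, evecs = np.linalg.eig(T.T)
    i = int(np.argmin(np.abs(evals - 1.0)))
    pi = np.real(evecs[:, i])
    pi = np.abs(pi)
    pi = pi / pi.sum()
    if np.max(np.abs(pi @ T - pi)) > tol:
        raise RuntimeError("stationary distribution did not satisfy pi T = pi")
    return pi


def estimate_transition_model(
    dtrajs, lag: int, reversible: bool = False, allow_single_state: bool = False
) -> TransitionModel:
    """Estimate a transition matrix from discrete trajectories.

    Sliding-window transition counts at the lag are restricted to the
    largest strongly connected state set (dropped states reported on the
    model), then row-normalized, or — with ``reversible`` — replaced by the
    detailed-balance maximum-likelihood estimate.  The equilibrium
    distribution is the stationary left eigenvector.
    """
    if isinstance(dtrajs, np.ndarray) and dtrajs.ndim == 1:
        dtrajs = [dtrajs]
    elif len(dtrajs) and np.isscalar(dtrajs[0]):
        dtrajs = [np.asarray(dtrajs)]
    dtrajs = [np.asarray(d, dtype=np.int64) for d in dtrajs]
    n_states = int(max(d.max() for d in dtrajs)) + 1
    C_full = _count_matrix(dtrajs, lag, n_states)
    if C_full.sum() == 0:
        raise ValueError("no transitions observed at the given lag")

    adjacency = csr_matrix((C_full > 0).astype(int))
    n_comp, comp = connected_components(adjacency, directed=True, connection="strong")
    sizes = np.bincount(comp, weights=C_full.sum(axis=1)).astype(float)
    largest = int(np.argmax(sizes))
    active = np.where(comp == largest)[0]
    dropped = np.setdiff1d(np.arange(n_states), active)
    if active.size == 1 and not allow_single_state:
        raise ValueError(
            "largest connected set has a single state; pass allow_single_state=True "
            "to accept a degenerate one-state model"
        )
    C = C_full[np.ix_(active, active)]
    if reversible:
        T = _reversible_mle(C)
    else:
        T = C / C.sum(axis=1, keepdims=True)
    pi = stationary_distribution(T)
    return TransitionModel(
        count_matrix=C,
        transition_matrix=T,
        equilibrium_distribution=pi,
        lag=lag,
        active_set=active,
        n_states_total=n_states,
        reversible=reversible,
        dropped_states=dropped,
    )


def timescales_from_eigenvalues(eigenvalues, lag: int) -> np.ndarray:
    """Map transition-matrix eigenvalues to relaxation times -lag/ln(lambda).

    Eigenvalues at or above 1 correspond to non-decaying processes and map
    to infinity; non-positive eigenvalues have no relaxation-time
    interpretation and map to NaN.
    """
    ev = np.asarray(eigenvalues, dtype=float)
    ts = np.empty(ev.shape)
    for i, lam in enumerate(ev):
        if lam >= 1.0:
            ts[i] = np.inf
        elif lam <= 0.0:
            ts[i] = np.nan
        else:
            ts[i] = -lag / np.log(lam)
    return ts


def implied_timescales(
    dtrajs, lags, n_timescales: int = 3, reversible: bool = False
) -> dict[int, np.ndarray]:
    """Implied relaxation timescales t_i(tau) = -tau / ln lambda_i(tau).

    One model is estimated per lag; a plateau of t_i over tau indicates
    Markovian behavior at that lag.
    """
    out: dict[int, np.ndarray] = {}
    for lag in lags:
        model = estimate_transition_model(dtrajs, lag, reversible=reversible)
        evals = np.linalg.eigvals(model.transition_matrix)
        if reversible and np.max(np.abs(evals.imag)) > 1e-8:
            raise RuntimeError("complex eigenvalues beyond tolerance in reversible mode")
        ev = np.real(evals)
        ev = ev[np.argsort(np.abs(ev))[::-1]][1 : n_timescales + 1]
        out[int(lag)] = timescales_from_eigenvalues(ev, lag)
    return out


def ck_test(dtrajs, model: TransitionModel, factors=(2, 3, 4)) -> dict[int, dict]:
    """Chapman-Kolmogorov test: compare T(tau)^k with T estimated at k*tau.

    Returns per factor the propagated matrix, the re-estimated matrix on
    the common state set, and their maximum entrywise discrepancy.  Factors
    with too little data at k*tau are skipped with a warning.
    """
    results: dict[int, dict] = {}
    for k in factors:
        if k < 2:
            raise ValueError("factors must be >= 2")
        try:
            # deterministic/periodic chains can decouple at k*lag; a
            # single-state direct model is still comparable on the overlap
            direct = estimate_transition_model(dtrajs, k * model.lag,
                                               reversible=model.reversible,
                                               allow_single_state=True)
        except ValueError as e:
            warnings.warn(f"CK factor {k} skipped: {e}")
            continue
        common = np.intersect1d(model.active_set, direct.active_set)
        ia = model.index_of(common)
        ib = direct.index_of(common)
        predicted = np.linalg.matrix_power(model.transition_matrix, k)[np.ix_(ia, ia)]
        estimated = direct.transition_matrix[np.ix_(ib, ib)]
        results[int(k)] = {
            "predicted": predicted,
            "estimated": estimated,
            "max_discrepancy": float(np.max(np.abs(predicted - estimated))),
        }
    return results


def _committors(T: np.ndarray, pi: np.ndarray, A: np.ndarray, B: np.ndarray):
    n = T.shape[0]
    inter = np.setdiff1d(np.arange(n), np.concatenate([A, B]))
    qplus = np.zeros(n)
    qplus[B] = 1.0
    if inter.size:
        M = np.eye(inter.size) - T[np.ix_(inter, inter)]
        rhs = T[np.ix_(inter, B)].sum(axis=1)
        qplus[inter] = np.linalg.solve(M, rhs)
    # backward committor of the time-reversed chain; states with zero
    # stationary weight carry no flux and are neutralized
    with np.errstate(divide="ignore", invalid="ignore"):
        Tback = (pi[None, :] * T.T) / pi[:, None]
    Tback[~np.isfinite(Tback)] = 0.0
    qminus = np.zeros(n)
    qminus[A] = 1.0
    if inter.size:
        M = np.eye(inter.size) - Tback[np.ix_(inter, inter)]
        rhs = Tback[np.ix_(inter, A)].sum(axis=1)
        qminus[inter] = np.linalg.solve(M, rhs)
    return qplus, qminus


def pathway_fractions(
    model: TransitionModel,
    source_states,
    sink_states,
    channel_map: dict[int, str],
) -> dict[str, float]:
    """Decompose source-to-sink reactive flux among parallel channels.

    Transition-path-theory flux f_ij = pi_i q-_i T_ij q+_j is computed from
    the forward/backward committors; the net flux leaving the source is
    attributed to the channel of the first intermediate state it enters
    (direct source-to-sink transitions go to a ``"direct"`` channel).
    Every intermediate state must be mapped to exactly one channel.
    Fractions are >= 0 and sum to 1 over the reactive flux.
    """
    A = model.index_of(np.atleast_1d(source_states))
    B = model.index_of(np.atleast_1d(sink_states))
    if A.size == 0 or B.size == 0:
        raise ValueError("source and sink must be non-empty")
    if np.intersect1d(A, B).size:
        raise ValueError("source and sink must be disjoint")
    n = model.n_states
    inter = np.setdiff1d(np.arange(n), np.concatenate([A, B]))
    unmapped = [int(model.active_set[i]) for i in inter
                if int(model.active_set[i]) not in channel_map]
    if unmapped:
        raise ValueError(f"intermediate states {unmapped} have no channel assignment")

    T, pi = model.transition_matrix, model.equilibrium_distribution
    qplus, qminus = _committors(T, pi, A, B)
    flux = pi[:, None] * qminus[:, None] * T * qplus[None, :]
    np.fill_diagonal(flux, 0.0)
    net = np.maximum(flux - flux.T, 0.0)

    channel_of = {i: channel_map[int(model.active_set[i])] for i in inter}
    totals: dict[str, float] = {}
    total_flux = 0.0
    for i in A:
        for j in range(n):
            if j in A or net[i, j] <= 0:
                continue
            ch = "direct" if j in B else channel_of[j]
            totals[ch] = totals.get(ch, 0.0) + net[i, j]
            total_flux += net[i, j]
    if total_flux <= 0:
        raise ValueError("sink is unreachable from source: zero reactive flux")
    return {ch: v / total_flux for ch, v in sorted(totals.items())}


def classify_nac(
    geometry, criteria: NacCriteria = NacCriteria()
) -> tuple[np.ndarray, float]:
    """Label frames as near-attack conformers; returns (mask, fraction).

    ``geometry`` is an (n, 2) array or DataFrame with columns
    distance_A, angle_deg.  A frame is a NAC iff
    distance <= max_distance and angle_min <= angle <= angle_max
    (all bounds inclusive).
    """
    import pandas as pd

    if isinstance(geometry, pd.DataFrame):
        dist = geometry["distance_A"].to_numpy(dtype=float)
        ang = geometry["angle_deg"].to_numpy(dtype=float)
    else:
        arr = np.atleast_2d(np.asarray(geometry, dtype=float))
        dist, ang = arr[:, 0], arr[:, 1]
    if np.any(dist <= 0):
        raise ValueError("distances must be > 0")
    if np.any((ang < 0) | (ang > 180)):
        raise ValueError("angles must lie within [0, 180] degrees")
    mask = (
        (dist <= criteria.max_distance)
        & (ang >= criteria.angle_min)
        & (ang <= criteria.angle_max)
    )
    return mask, float(mask.mean()) if mask.size else 0.0


def macrostate_population(
    model: TransitionModel, state_set, reference_set=None
) -> float:
    """Equilibrium probability of a macrostate (sum of pi over its states).

    With ``reference_set`` the conditional population
    P(state_set) / P(reference_set) is returned.
    """
    states = np.atleast_1d(state_set)
    if states.size == 0:
        raise ValueError("state_set must be non-empty")
    idx = model.index_of(states)
    pop = float(model.equilibrium_distribution[idx].sum())
    if reference_set is not None:
        ref = model.index_of(np.atleast_1d(reference_set))
        denom = float(model.equilibrium_distribution[ref].sum())
        if denom == 0:
            raise ValueError("reference set has zero equilibrium probability")
        return pop / denom
    return pop
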