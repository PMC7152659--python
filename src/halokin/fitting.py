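"""Global fitting of kinetic mechanisms with identifiability analysis.

The central objective is the sigma-normalized chi-square

    chi2(theta) = sum_i ((obs_i - model_i(theta)) / sigma_i)^2

minimized by Levenberg-Marquardt over microscopic rate constants, signal
coefficients and optional bounded per-trace concentration nuisance factors
(+-10%).  Model values come from ODE integration of the mechanism per
stopped-flow trace plus the Michaelis-Menten form for initial-rate blocks
(kcat and Km derived analytically from the same microscopic constants, so
steady-state and transient data constrain one parameter set).

Positive rate parameters are fit on a log10 scale, which enforces
positivity and conditions the problem; standard errors are mapped back to
the natural scale through the Jacobian of the transform.

Uncertainty beyond covariance standard errors comes from profile-chi2
confidence contours: one parameter is scanned over a grid, all others
re-optimized, and confidence limits read where the profile crosses the
threshold chi2_min / 0.98 (a ratio convention; its implied confidence level
tightens as chi2_min grows with the number of points).  A profile that
never crosses on one side yields a one-sided bound, mirroring rate
constants reportable only as "> x".

Secondary constants (Ks = k-1/k1, kcat/Km) carry first-order propagated
errors, and variants are compared with Welch's unequal-variances t-test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import lmfit
import numpy as np
from scipy import stats

from .mechanism import (
    Mechanism,
    RateParameters,
    derived_kcat,
    derived_km,
    simulate_timecourse,
)
from .observables import SignalCoefficients, evaluate_observable
from .synthetic import KineticDataset

__all__ = [
    "FitResult",
    "ContourResult",
    "VariantComparison",
    "GlobalKineticProblem",
    "MichaelisMentenProblem",
    "global_fit",
    "fit_michaelis_menten",
    "confidence_contours",
    "propagate_ratio_error",
    "welch_t_test",
]

_RATE_LABELS = {"k1", "k_minus1", "k2", "k3", "k4", "k_minus4", "Ks", "kcat", "Km"}
_COEFF_LABELS = {"f", "a", "b", "o", "p", "q", "r", "baseline"}
# log10-parameterized (strictly positive) labels
_LOG_LABELS = _RATE_LABELS | {"f"}


@dataclass
class FitResult:
    """Outcome of a chi-square minimization."""

    estimates: dict[str, float]
    standard_errors: dict[str, float]
    chi2_min: float
    n_points: int
    n_params: int
    covariance: np.ndarray | None
    free_labels: tuple[str, ...]
    converged: bool
    n_evaluations: int
    identifiability_flags: dict[str, str] = field(default_factory=dict)

    @property
    def reduced_chi2(self) -> float:
        dof = max(self.n_points - self.n_params, 1)
        return self.chi2_min / dof


@dataclass
class ContourResult:
    """Profile-chi2 scan of one parameter."""

    parameter: str
    grid: np.ndarray
    profile_chi2: np.ndarray
    chi2_min: float
    threshold: float
    lower: float | None          # None => unbounded below within the grid
    upper: float | None
    lower_bounded_only: bool = False

    @property
    def is_bound_only(self) -> bool:
        """True when only a lower limit exists (reported as '> x')."""
        return self.lower is not None and self.upper is None


@dataclass
class VariantComparison:
    parameter: str
    mean1: float
    mean2: float
    t_statistic: float
    df: float
    p_value: float
    significance: str            # "", "*", or "**"


def _make_params(
    free: dict[str, float],
    bounds: dict[str, tuple[float, float]] | None = None,
) -> lmfit.Parameters:
    bounds = bounds or {}
    params = lmfit.Parameters()
    for label, guess in free.items():
        lo, hi = bounds.get(label, (None, None))
        if label in _LOG_LABELS or label.startswith("k"):
            if guess <= 0:
                raise ValueError(f"positive parameter {label} needs a positive guess")
            params.add(
                f"log10_{label}",
                value=math.log10(guess),
                min=math.log10(lo) if lo else -12.0,
                max=math.log10(hi) if hi else 12.0,
            )
        else:
            params.add(label, value=guess,
                       min=lo if lo is not None else -np.inf,
                       max=hi if hi is not None else np.inf)
    return params


def _unpack_params(params: lmfit.Parameters) -> dict[str, float]:
    out = {}
    for name, p in params.items():
        if name.startswith("log10_"):
            out[name[6:]] = 10.0 ** p.value
        else:
            out[name] = p.value
    return out


def _natural_errors(result: lmfit.minimizer.MinimizerResult) -> tuple[dict, dict]:
    """Map stderr and flags from the (possibly log10) fit scale back."""
    errors, flags = {}, {}
    for name, p in result.params.items():
        label = name[6:] if name.startswith("log10_") else name
        if p.stderr is None:
            errors[label] = float("nan")
            flags[label] = "se_undetermined"
        elif name.startswith("log10_"):
            errors[label] = 10.0 ** p.value * math.log(10.0) * p.stderr
        else:
            errors[label] = p.stderr
    return errors, flags


class _FitProblemBase:
    """Shared chi-square machinery: minimize, multi-start, profile refits."""

    free: dict[str, float]
    bounds: dict[str, tuple[float, float]]

    def residuals(self, values: dict[str, float]) -> np.ndarray:
        raise NotImplementedError

    def _objective(self, params: lmfit.Parameters, fixed: dict[str, float]):
        values = _unpack_params(params)
        values.update(fixed)
        return self.residuals(values)

    def fit(
        self,
        fixed: dict[str, float] | None = None,
        n_starts: int = 1,
        restart_seed: int = 0,
        start_overrides: dict[str, float] | None = None,
    ) -> FitResult:
        """Minimize chi2 by Levenberg-Marquardt.

        ``fixed`` pins parameters (removing them from the free set) — used
        by profile contours.  ``n_starts`` > 1 adds deterministic
        log-uniform restarts around the starting point and keeps the lowest
        chi2.
        """
        fixed = dict(fixed or {})
        free = {k: v for k, v in self.free.items() if k not in fixed}
        if start_overrides:
            free.update({k: v for k, v in start_overrides.items() if k in free})
        if not free:
            raise ValueError("at least one free parameter is required")
        rng = np.random.default_rng(restart_seed)
        best = None
        for start in range(max(1, n_starts)):
            guesses = dict(free)
            if start > 0:  # log-uniform perturbation within a factor of 3
                for k in guesses:
                    fac = 3.0 ** rng.uniform(-1.0, 1.0)
                    guesses[k] = (
                        guesses[k] * fac
                        if (k in _LOG_LABELS or k.startswith("k")) or guesses[k] > 0
                        else guesses[k] + rng.normal(0, 0.5)
                    )
            params = _make_params(guesses, self.bounds)
            res = lmfit.minimize(
                self._objective, params, args=(fixed,), method="leastsq"
            )
            if best is None or res.chisqr < best.chisqr:
                best = res
        estimates = _unpack_params(best.params)
        estimates.update(fixed)
        errors, flags = _natural_errors(best)
        if best.covar is None:
            flags["covariance"] = "singular"
        return FitResult(
            estimates=estimates,
            standard_errors=errors,
            chi2_min=float(best.chisqr),
            n_points=int(best.ndata),
            n_params=len(free),
            covariance=best.covar,
            free_labels=tuple(free),
            converged=bool(best.success),
            n_evaluations=int(best.nfev),
            identifiability_flags=flags,
        )


class GlobalKineticProblem(_FitProblemBase):
    """Joint fit of stopped-flow traces and initial-rate tables to one
    mechanistic parameter set.

    Parameters
    ----------
    dataset : KineticDataset
    mechanism : Mechanism
    rates : RateParameters
        Baseline values; labels not in ``free`` stay fixed at these.
    coeffs : SignalCoefficients or None
        Signal model for the traces (None observes a species directly).
    free : dict label -> starting guess
        Free parameters: rate labels, Ks, and/or coefficient labels.
    adjust_concentrations : {"", "substrate", "enzyme", "both"}
        Adds bounded per-trace nuisance factors (0.9-1.1) multiplying the
        nominal concentrations.
    """

    def __init__(
        self,
        dataset: KineticDataset,
        mechanism: Mechanism,
        rates: RateParameters,
        coeffs: SignalCoefficients | None,
        free: dict[str, float],
        bounds: dict[str, tuple[float, float]] | None = None,
        observed_species: str = "P",
        adjust_concentrations: str = "",
    ):
        unknown = set(free) - _RATE_LABELS - _COEFF_LABELS
        unknown = {u for u in unknown if not u.startswith("c_")}
        if unknown:
            raise ValueError(f"unknown fit parameter labels: {sorted(unknown)}")
        self.dataset = dataset
        self.mechanism = mechanism
        self.rates = rates
        self.coeffs = coeffs
        self.observed_species = observed_species
        self.free = dict(free)
        self.bounds = dict(bounds or {})
        if adjust_concentrations:
            for i in range(len(dataset.traces)):
                self.free[f"c_trace_{i}"] = 1.0
                self.bounds[f"c_trace_{i}"] = (0.9, 1.1)
        self.adjust = adjust_concentrations

    def _rates_from(self, values: dict[str, float]) -> RateParameters:
        kw = {}
        for lab in ("k1", "k_minus1", "k2", "k3", "k4", "k_minus4"):
            kw[lab] = values.get(lab, getattr(self.rates, lab))
        ks = values.get("Ks", self.rates.Ks)
        return RateParameters(Ks=ks, status=self.rates.status, **kw)

    def _coeffs_from(self, values: dict[str, float]) -> SignalCoefficients | None:
        if self.coeffs is None:
            return None
        kw = {k: values.get(k, getattr(self.coeffs, k))
              for k in ("f", "a", "b", "o", "p", "q", "r", "baseline")}
        return SignalCoefficients(channel=self.coeffs.channel, **kw)

    def residuals(self, values: dict[str, float]) -> np.ndarray:
        r = self._rates_from(values)
        c = self._coeffs_from(values)
        blocks = []
        for i, tr in enumerate(self.dataset.traces):
            fac = values.get(f"c_trace_{i}", 1.0)
            E0 = tr.E0_nominal * (fac if self.adjust in ("enzyme", "both") else 1.0)
            S0 = tr.S0_nominal * (fac if self.adjust in ("substrate", "both") else 1.0)
            # trace grids may start after the dead time; integrate from 0
            if tr.time[0] > 0:
                grid = np.concatenate(([0.0], tr.time))
                states = simulate_timecourse(self.mechanism, r, E0, S0, grid)[1:]
            else:
                states = simulate_timecourse(self.mechanism, r, E0, S0, tr.time)
            model = evaluate_observable(states, c, self.observed_species)
            blocks.append((tr.signal - model) / tr.sigma)
        if self.dataset.initial_rates:
            kcat = derived_kcat(r, self.mechanism)
            km = derived_km(r, self.mechanism)
            pts = self.dataset.initial_rates
            S = np.array([p.S0 for p in pts])
            E = np.array([p.E0 for p in pts])
            v = np.array([p.v0 for p in pts])
            sig = np.array([p.sigma for p in pts])
            blocks.append((v - kcat * E * S / (km + S)) / sig)
        return np.concatenate(blocks)


class MichaelisMentenProblem(_FitProblemBase):
    """Weighted nonlinear least squares of v0 = kcat*E0*S/(Km+S)."""

    def __init__(self, dataset: KineticDataset, E0: float | None = None,
                 kcat_guess: float | None = None, Km_guess: float | None = None):
        pts = dataset.initial_rates
        if len({p.S0 for p in pts}) < 3:
            raise ValueError("need >= 3 distinct substrate concentrations")
        self.S = np.array([p.S0 for p in pts])
        self.E = np.array([p.E0 for p in pts]) if E0 is None else np.full(len(pts), E0)
        self.v = np.array([p.v0 for p in pts])
        self.sig = np.array([p.sigma for p in pts])
        vmax0 = max(self.v.max(), 1e-12)
        self.free = {
            "kcat": kcat_guess or vmax0 / self.E.mean(),
            "Km": Km_guess or float(np.median(self.S)),
        }
        self.bounds = {}

    def residuals(self, values: dict[str, float]) -> np.ndarray:
        model = values["kcat"] * self.E * self.S / (values["Km"] + self.S)
        return (self.v - model) / self.sig

    def fit(self, **kw) -> FitResult:
        res = super().fit(**kw)
        # Saturation diagnostics: the (kcat, Km) pair is only identifiable
        # when the concentration range brackets Km.
        km = res.estimates.get("Km")
        if km is not None:
            if self.S.min() > 10 * km:
                res.identifiability_flags["Km"] = (
                    "unidentifiable: all concentrations saturating; "
                    "kcat = mean(v)/E0 only"
                )
            elif self.S.max() < 0.1 * km:
                res.identifiability_flags["Km"] = (
                    "unidentifiable: all concentrations sub-Km; "
                    "only the slope kcat/Km is determined"
                )
                res.identifiability_flags["kcat_over_Km"] = (
                    f"{res.estimates['kcat'] / km:.6g}"
                )
        return res


def global_fit(
    dataset: KineticDataset,
    mechanism: Mechanism,
    rates: RateParameters,
    coeffs: SignalCoefficients | None,
    free: dict[str, float],
    bounds: dict[str, tuple[float, float]] | None = None,
    observed_species: str = "P",
    adjust_concentrations: str = "",
    n_starts: int = 1,
    restart_seed: int = 0,
) -> FitResult:
    """Convenience wrapper: build a :class:`GlobalKineticProblem` and fit."""
    problem = GlobalKineticProblem(
        dataset, mechanism, rates, coeffs, free, bounds,
        observed_species, adjust_concentrations,
    )
    return problem.fit(n_starts=n_starts, restart_seed=restart_seed)


def fit_michaelis_menten(
    dataset_or_points, E0: float | None = None
) -> FitResult:
    """Fit the Michaelis-Menten equation to an initial-rate table.

    Accepts a :class:`KineticDataset` or a bare list of
    :class:`~halokin.synthetic.InitialRatePoint`.
    """
    if not isinstance(dataset_or_points, KineticDataset):
        dataset_or_points = KineticDataset(initial_rates=list(dataset_or_points))
    return MichaelisMentenProblem(dataset_or_points, E0=E0).fit()


def _refine_crossing(profile_fn, x0, c0, x1, c1, threshold):
    """Locate the chi2 profile's threshold crossing inside a bracketing cell.

    Uses Brent root-finding on the re-optimized profile; falls back to
    linear interpolation if the bracket degenerates numerically.
    """
    from scipy.optimize import brentq

    g0, g1 = c0 - threshold, c1 - threshold
    if g0 == 0:
        return x0
    if g1 == 0:
        return x1
    if g0 * g1 > 0:  # should not happen for a bracketing cell
        return x0 + (threshold - c0) * (x1 - x0) / (c1 - c0)
    return float(brentq(lambda x: profile_fn(x) - threshold, x0, x1,
                        xtol=1e-12, rtol=1e-6, maxiter=60))


def confidence_contours(
    problem: _FitProblemBase,
    fit: FitResult,
    parameter: str,
    grid: np.ndarray | None = None,
    span: float = 4.0,
    n_grid: int = 21,
    threshold_ratio: float = 0.98,
) -> ContourResult:
    """Profile-chi2 confidence contour for one parameter.

    The parameter is fixed at each grid value and all remaining free
    parameters re-optimized; confidence limits are where the profile
    crosses ``chi2_min / threshold_ratio``.  A profile that stays below the
    threshold to the grid edge leaves that side unbounded (one-sided
    bounds are reported the way lower-bound-only rate constants are
    printed, "> x").
    """
    if not fit.converged:
        raise ValueError("confidence contours require a converged fit")
    if parameter not in fit.free_labels:
        raise ValueError(f"{parameter!r} is not a free parameter of this fit")
    est = fit.estimates[parameter]
    if grid is None:
        if est > 0:
            grid = est * np.exp(np.linspace(-math.log(span), math.log(span), n_grid))
        else:
            grid = est + np.linspace(-span, span, n_grid)
    grid = np.sort(np.asarray(grid, dtype=float))
    if not (grid[0] <= est <= grid[-1]):
        raise ValueError("contour grid must bracket the point estimate")

    starts = {k: fit.estimates[k] for k in fit.free_labels if k != parameter}

    def profile_fn(val: float) -> float:
        if starts:
            return problem.fit(fixed={parameter: val}, start_overrides=starts).chi2_min
        res = problem.residuals({**fit.estimates, parameter: val})
        return float(res @ res)  # one-parameter problem: nothing to re-optimize

    profile = np.array([profile_fn(v) for v in grid])
    chi2_min = min(fit.chi2_min, float(profile.min()))
    threshold = chi2_min / threshold_ratio

    flat = np.ptp(profile) <= 1e-12 * max(chi2_min, 1.0)
    lower = upper = None
    if not flat:
        i_best = int(np.argmin(np.abs(grid - est)))
        for i in range(i_best, 0, -1):       # walk left
            if profile[i - 1] >= threshold >= profile[i]:
                lower = _refine_crossing(
                    profile_fn, grid[i - 1], profile[i - 1], grid[i], profile[i], threshold
                )
                break
        for i in range(i_best, len(grid) - 1):  # walk right
            if profile[i + 1] >= threshold >= profile[i]:
                upper = _refine_crossing(
                    profile_fn, grid[i], profile[i], grid[i + 1], profile[i + 1], threshold
                )
                break
    return ContourResult(
        parameter=parameter,
        grid=grid,
        profile_chi2=profile,
        chi2_min=chi2_min,
        threshold=threshold,
        lower=lower,
        upper=upper,
        lower_bounded_only=lower is not None and upper is None,
    )


def propagate_ratio_error(a: float, sa: float, b: float, sb: float) -> tuple[float, float]:
    """First-order error propagation for a ratio of independent quantities.

    SE(a/b) = |a/b| * sqrt((sa/a)^2 + (sb/b)^2); when a = 0 the relative
    form degenerates and SE = sa/|b| is used.
    """
    if b == 0:
        raise ZeroDivisionError("denominator b = 0 in ratio error propagation")
    ratio = a / b
    if a == 0:
        return 0.0, sa / abs(b)
    se = abs(ratio) * math.sqrt((sa / a) ** 2 + (sb / b) ** 2)
    return ratio, se


def welch_t_test(
    mean1: float, s1: float, n1: int,
    mean2: float, s2: float, n2: int,
    dispersion: str = "sd",
    parameter: str = "",
) -> VariantComparison:
    """Welch's unequal-variances t-test between two parameter estimates.

    ``dispersion`` says whether s1/s2 are standard deviations ("sd", the
    classical formula with s^2/n) or standard errors ("se", s^2 used
    directly).  Significance tiers: '*' at p < 0.05, '**' at p < 0.01.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("Welch's t-test requires n >= 2 per group")
    if s1 <= 0 or s2 <= 0:
        raise ValueError("dispersions must be > 0")
    if dispersion == "sd":
        v1, v2 = s1**2 / n1, s2**2 / n2
    elif dispersion == "se":
        v1, v2 = s1**2, s2**2
    else:
        raise ValueError("dispersion must be 'sd' or 'se'")
    se = math.sqrt(v1 + v2)
    t = (mean1 - mean2) / se
    df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    p = float(2.0 * stats.t.sf(abs(t), df))
    stars = "**" if p < 0.01 else "*" if p < 0.05 else ""
    return VariantComparison(parameter, mean1, mean2, t, df, p, stars)
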