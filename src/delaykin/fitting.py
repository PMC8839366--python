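"""Conductometric observation model and constrained parameter identification.

The forward model integrates the distributed-delay enzyme–substrate system
for each substrate dose and maps the predicted product concentration to a
specific conductance through Kohlrausch's law for strong electrolytes::

    kappa_pred = lambda0 * nP - K * nP**(3/2)

Six parameters are identified jointly from the conductance time series of
all doses: the bimolecular rate ``kd``, the delay-kernel parameters
``(a, m, tau_min)``, and the Kohlrausch coefficients ``(lambda0, K)``.  The
objective is the root-sum-of-squares residual over every series and sample,

    J(Pi) = sqrt( sum_i sum_j (kappa_exp_i(t_j) - kappa_pred_i(t_j))**2 ),

minimized under box bounds by COBYLA (derivative-free linear-approximation
trust-region method) on log10-scaled parameters — the bounds span many
orders of magnitude, and unscaled simplices degenerate.  Bounds are enforced
either as explicit COBYLA inequality constraints (default) or through the
exact-penalty objective ``Phi = J + xi * [max(-g_i)]_+`` with ``g_1 = Pi -
Pi_lower``, ``g_2 = Pi_upper - Pi``.

Units: the pipeline is unit-agnostic.  Concentrations are carried in mass
units (mg/mL); the fitted ``lambda0`` and ``K`` absorb the unit choice.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize

from .engine import DivergenceError, IntegratorSettings, integrate
from .kernels import DEFAULT_CONFIDENCE, GammaDelayKernel, truncation_bound
from .models import ESKineticParams, build_model

__all__ = [
    "PARAM_NAMES",
    "DEFAULT_PI_INIT",
    "DEFAULT_BOUNDS",
    "REFERENCE_ESTIMATE",
    "KohlrauschParams",
    "ParameterVector",
    "Bounds",
    "ConductivitySeries",
    "FitProblem",
    "FitResult",
    "kappa_pred",
    "objective_J",
    "penalty_phi",
    "fit_parameters",
]

PARAM_NAMES = ("kd", "a", "m", "tau_min", "lambda0", "K")


@dataclass(frozen=True)
class KohlrauschParams:
    """Limiting molar conductivity ``lambda0`` and Kohlrausch coefficient ``K``
    (consistent, otherwise arbitrary, conductance units)."""

    lambda0: float
    K: float

    def __post_init__(self) -> None:
        if self.lambda0 < 0 or self.K < 0:
            raise ValueError("lambda0 and K must be >= 0")

    @property
    def turning_point(self) -> float:
        """Product concentration beyond which kappa(nP) starts decreasing."""
        if self.K == 0:
            return math.inf
        return (2.0 * self.lambda0 / (3.0 * self.K)) ** 2


@dataclass(frozen=True)
class ParameterVector:
    """The six-dimensional fit target (kd, a, m, tau_min, lambda0, K)."""

    kd: float
    a: float
    m: float
    tau_min: float
    lambda0: float
    K: float

    def __post_init__(self) -> None:
        for name in PARAM_NAMES:
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in PARAM_NAMES], dtype=float)

    @classmethod
    def from_array(cls, x) -> "ParameterVector":
        x = np.asarray(x, dtype=float)
        return cls(**dict(zip(PARAM_NAMES, x)))

    @property
    def kernel(self) -> GammaDelayKernel:
        return GammaDelayKernel(rate_a=self.a, shape_m=self.m, tau_min=self.tau_min)

    @property
    def kohlrausch(self) -> KohlrauschParams:
        return KohlrauschParams(lambda0=self.lambda0, K=self.K)


@dataclass(frozen=True)
class Bounds:
    """Componentwise box bounds for the six-parameter vector."""

    lower: np.ndarray
    upper: np.ndarray

    def __post_init__(self) -> None:
        lo = np.asarray(self.lower, dtype=float)
        up = np.asarray(self.upper, dtype=float)
        object.__setattr__(self, "lower", lo)
        object.__setattr__(self, "upper", up)
        if lo.shape != (6,) or up.shape != (6,):
            raise ValueError("bounds must be 6-vectors")
        if not np.all(lo < up):
            raise ValueError("each lower bound must be strictly below its upper bound")
        if np.any(lo <= 0):
            raise ValueError("lower bounds must be strictly positive")

    def contains(self, pi: ParameterVector, slack: float = 0.0) -> bool:
        x = pi.to_array()
        return bool(np.all(x >= self.lower - slack) and np.all(x <= self.upper + slack))

    def clip(self, x: np.ndarray) -> np.ndarray:
        return np.clip(x, self.lower, self.upper)


#: Default initialization of the six-parameter search.
DEFAULT_PI_INIT = ParameterVector(kd=0.04, a=1.0, m=20.0, tau_min=5.0, lambda0=6000.0, K=50.0)

#: Default box bounds of the six-parameter search.
DEFAULT_BOUNDS = Bounds(
    lower=np.array([1e-10, 1e-10, 1e-10, 1e-4, 1e-10, 1e-10]),
    upper=np.array([1.0, 1000.0, 1000.0, 1000.0, 1e6, 1e6]),
)

#: Parameter estimate obtained for the AChE + acetylcholine-chloride
#: conductometric experiment (four substrate doses); used as the default
#: ground truth of the synthetic-recovery harness.
REFERENCE_ESTIMATE = ParameterVector(
    kd=0.04042714,
    a=1.255818,
    m=6.703709,
    tau_min=4.673685,
    lambda0=729.2215,
    K=246.2885,
)


@dataclass(frozen=True)
class ConductivitySeries:
    """One dose's observed specific-conductance time series.

    ``times`` are absolute experiment seconds; ``addition_time`` marks the
    substrate addition (model time origin).  ``baseline_window`` optionally
    restricts the pre-addition interval used for baseline estimation;
    ``nS0``/``nE0`` override the protocol mixing arithmetic when set.
    """

    series_id: str
    times: np.ndarray
    kappa: np.ndarray
    dose_volume: float | None = None
    addition_time: float = 250.0
    baseline_window: tuple[float, float] | None = None
    nS0: float | None = None
    nE0: float | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        k = np.asarray(self.kappa, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "kappa", k)
        if t.ndim != 1 or len(t) < 2:
            raise ValueError(f"series {self.series_id!r}: need >= 2 samples")
        if len(t) != len(k):
            raise ValueError(f"series {self.series_id!r}: times/kappa length mismatch")
        if not np.all(np.diff(t) > 0):
            bad = int(np.argmin(np.diff(t) > 0)) + 1
            raise ValueError(
                f"series {self.series_id!r}: times not strictly increasing at row {bad}"
            )
        if not (t[0] <= self.addition_time <= t[-1]):
            raise ValueError(
                f"series {self.series_id!r}: addition time {self.addition_time} "
                f"outside [{t[0]}, {t[-1]}]"
            )

    @property
    def n(self) -> int:
        return len(self.times)

    def baseline(self) -> float:
        """Mean conductance over the pre-addition (or configured) window."""
        if self.baseline_window is not None:
            lo, hi = self.baseline_window
            mask = (self.times >= lo) & (self.times <= hi)
        else:
            mask = self.times < self.addition_time
        if not np.any(mask):
            return 0.0
        return float(self.kappa[mask].mean())


def kappa_pred(nP, obs: KohlrauschParams):
    """Specific conductance predicted from a product concentration.

    ``kappa = lambda0 * nP - K * nP**(3/2)``; zero at zero product and
    increasing while ``nP`` stays below the turning point
    ``(2*lambda0 / (3*K))**2``, beyond which the strong-electrolyte
    approximation degrades (a warning is emitted).
    """
    nP_arr = np.asarray(nP, dtype=float)
    if np.any(nP_arr < 0):
        raise ValueError("product concentration must be >= 0")
    if np.any(nP_arr > obs.turning_point):
        warnings.warn(
            "product concentration exceeds the Kohlrausch turning point "
            f"{obs.turning_point:.6g}; kappa(nP) is no longer increasing there",
            stacklevel=2,
        )
    out = obs.lambda0 * nP_arr - obs.K * nP_arr**1.5
    return out if out.ndim else float(out)


# --------------------------------------------------------------------------
# Objective
# --------------------------------------------------------------------------


def _series_initials(series: ConductivitySeries, protocol) -> tuple[float, float]:
    if series.nS0 is not None and series.nE0 is not None:
        return float(series.nS0), float(series.nE0)
    if protocol is None or series.dose_volume is None:
        raise ValueError(
            f"series {series.series_id!r}: provide nS0/nE0 or a dose volume "
            "plus a protocol for the mixing arithmetic"
        )
    from .synthetic import dose_to_initials

    return dose_to_initials(protocol, series.dose_volume)


def predict_kappa(
    pi: ParameterVector,
    series: ConductivitySeries,
    settings: IntegratorSettings = IntegratorSettings(),
    protocol=None,
    confidence: float = DEFAULT_CONFIDENCE,
) -> np.ndarray:
    """Forward-model conductance at the series' observation times.

    Model time starts at substrate addition; samples at or before the
    addition predict zero (the Kohlrausch map has no baseline term).
    """
    nS0, nE0 = _series_initials(series, protocol)
    tm = series.times - series.addition_time
    pred = np.zeros_like(tm)
    post = tm > 0
    if np.any(post):
        kernel = pi.kernel
        rule = truncation_bound(kernel, confidence)
        model = build_model(
            "es_distributed", ESKineticParams(kd=pi.kd, delay=(kernel, rule))
        )
        from .models import InitialCondition

        traj = integrate(
            model, InitialCondition.single(nS0, nE0), float(tm[post].max()), settings
        )
        nP = np.maximum(traj.series("P", tm[post]), 0.0)
        pred[post] = kappa_pred(nP, pi.kohlrausch)
    return pred


def _residual_blocks(
    pi: ParameterVector,
    series_list,
    settings: IntegratorSettings,
    protocol,
    confidence: float,
    baseline_subtract: bool,
) -> list[np.ndarray]:
    blocks = []
    for s in series_list:
        kexp = s.kappa - (s.baseline() if baseline_subtract else 0.0)
        pred = predict_kappa(pi, s, settings, protocol, confidence)
        blocks.append(kexp - pred)
    return blocks


def objective_J(
    pi: ParameterVector,
    series_list,
    settings: IntegratorSettings = IntegratorSettings(),
    protocol=None,
    confidence: float = DEFAULT_CONFIDENCE,
    baseline_subtract: bool = True,
) -> float:
    """Root-sum-of-squares conductance residual over all series and samples."""
    try:
        blocks = _residual_blocks(
            pi, series_list, settings, protocol, confidence, baseline_subtract
        )
    except DivergenceError as err:
        raise DivergenceError(f"{err} (at parameters {pi})") from err
    return float(math.sqrt(sum(float(b @ b) for b in blocks)))


@dataclass(frozen=True)
class FitProblem:
    """Identification problem: series, initialization, bounds, stop settings."""

    series: tuple
    protocol: object = None
    pi_init: ParameterVector = DEFAULT_PI_INIT
    bounds: Bounds = DEFAULT_BOUNDS
    xi: float = 1e3
    max_iter: int = 50
    rhobeg: float = 0.5
    tol: float = 1e-6
    confidence: float = DEFAULT_CONFIDENCE
    settings: IntegratorSettings = IntegratorSettings()
    mode: str = "constrained"
    baseline_subtract: bool = True

    def __post_init__(self) -> None:
        if self.xi <= 0:
            raise ValueError("penalty weight xi must be positive")
        if self.mode not in ("constrained", "penalty"):
            raise ValueError(f"mode must be 'constrained' or 'penalty', got {self.mode!r}")
        if not self.bounds.contains(self.pi_init):
            raise ValueError("pi_init violates the bounds")
        object.__setattr__(self, "series", tuple(self.series))

    @property
    def n_points(self) -> int:
        return sum(s.n for s in self.series)


@dataclass(frozen=True)
class FitResult:
    pi_opt: ParameterVector
    J: float
    rmse: float
    n_iter: int
    converged: bool
    trace: np.ndarray
    per_series_J: dict
    pi_init: ParameterVector
    J_init: float

    def to_dict(self) -> dict:
        return {
            "pi_opt": dict(zip(PARAM_NAMES, self.pi_opt.to_array().tolist())),
            "pi_init": dict(zip(PARAM_NAMES, self.pi_init.to_array().tolist())),
            "J": self.J,
            "J_init": self.J_init,
            "rmse": self.rmse,
            "n_iter": self.n_iter,
            "converged": self.converged,
            "per_series_J": self.per_series_J,
        }


def _bound_violation(x: np.ndarray, bounds: Bounds) -> float:
    """Largest single-component violation of the box bounds (0 when inside)."""
    return float(
        max(0.0, np.max(bounds.lower - x), np.max(x - bounds.upper))
    )


def penalty_phi(pi: ParameterVector, problem: FitProblem) -> float:
    """Exact-penalty objective ``Phi = J + xi * [largest bound violation]_+``."""
    J = objective_J(
        pi,
        problem.series,
        problem.settings,
        problem.protocol,
        problem.confidence,
        problem.baseline_subtract,
    )
    return J + problem.xi * _bound_violation(pi.to_array(), problem.bounds)


def fit_parameters(problem: FitProblem) -> FitResult:
    """Minimize J under box bounds with COBYLA on log10-scaled parameters.

    The best bound-feasible point encountered is tracked across evaluations
    and returned if the optimizer's final iterate is worse, so the result
    never regresses below the initialization.  A boundary violation of the
    returned point is clipped (with a warning beyond 1e-12 relative slack).
    Reaching the evaluation cap flags the result as non-converged rather
    than raising.
    """
    lb = np.log10(problem.bounds.lower)
    ub = np.log10(problem.bounds.upper)
    x0 = np.log10(problem.pi_init.to_array())

    evals: list[tuple[float, float, np.ndarray]] = []  # (J_or_inf, phi, x_linear)

    def J_of(x_log: np.ndarray) -> tuple[float, float, np.ndarray]:
        x = np.power(10.0, np.clip(x_log, lb - 2.0, ub + 2.0))
        viol = _bound_violation(x, problem.bounds)
        x_eval = problem.bounds.clip(x)
        try:
            J = objective_J(
                ParameterVector.from_array(x_eval),
                problem.series,
                problem.settings,
                problem.protocol,
                problem.confidence,
                problem.baseline_subtract,
            )
        except DivergenceError:
            J = 1e12
        return J, viol, x

    if problem.mode == "penalty":

        def fun(x_log):
            J, viol, x = J_of(x_log)
            phi = J + problem.xi * viol
            evals.append((J if viol == 0 else math.inf, phi, x))
            return phi

        constraints = ()
    else:

        def fun(x_log):
            J, viol, x = J_of(x_log)
            evals.append((J if viol == 0 else math.inf, J, x))
            return J

        constraints = (
            {"type": "ineq", "fun": lambda x_log: x_log - lb},
            {"type": "ineq", "fun": lambda x_log: ub - x_log},
        )

    res = minimize(
        fun,
        x0,
        method="COBYLA",
        constraints=constraints,
        tol=problem.tol,
        options={"rhobeg": problem.rhobeg, "maxiter": problem.max_iter},
    )

    trace = np.minimum.accumulate([phi for _, phi, _ in evals]) if evals else np.array([])

    # candidate set: optimizer's final iterate (clipped) and the best
    # bound-feasible point seen, the initialization among them by construction
    x_final = np.power(10.0, np.asarray(res.x, dtype=float))
    viol_final = _bound_violation(x_final, problem.bounds)
    if viol_final > 1e-12 * max(1.0, np.max(np.abs(x_final))):
        warnings.warn(
            f"optimizer returned a boundary violation of {viol_final:.3g}; clipped",
            stacklevel=2,
        )
    candidates = [problem.bounds.clip(x_final)]
    feasible = [(J, x) for J, _, x in evals if math.isfinite(J)]
    if feasible:
        candidates.append(problem.bounds.clip(min(feasible, key=lambda e: e[0])[1]))
    candidates.append(problem.pi_init.to_array())

    scored = []
    for x in candidates:
        pi = ParameterVector.from_array(x)
        scored.append(
            (
                objective_J(
                    pi,
                    problem.series,
                    problem.settings,
                    problem.protocol,
                    problem.confidence,
                    problem.baseline_subtract,
                ),
                pi,
            )
        )
    J_init = scored[-1][0]
    J_best, pi_best = min(scored, key=lambda e: e[0])

    blocks = _residual_blocks(
        pi_best,
        problem.series,
        problem.settings,
        problem.protocol,
        problem.confidence,
        problem.baseline_subtract,
    )
    per_series = {
        s.series_id: float(math.sqrt(b @ b)) for s, b in zip(problem.series, blocks)
    }
    n_iter = int(res.nfev)
    hit_cap = n_iter >= problem.max_iter
    return FitResult(
        pi_opt=pi_best,
        J=J_best,
        rmse=J_best / math.sqrt(problem.n_points),
        n_iter=n_iter,
        converged=bool(res.success) and not hit_cap,
        trace=trace,
        per_series_J=per_series,
        pi_init=problem.pi_init,
        J_init=J_init,
    )
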