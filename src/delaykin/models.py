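"""Declarative kinetic models compiled to mass-action right-hand sides.

Every model family here is built from bilinear (or linear) mass-action terms.
A *term* moves mass into or out of one target species at a rate proportional
to the product of one or two factor species, evaluated either instantaneously,
at a discrete lag ``tau``, or as a distributed-delay convolution against a
truncated gamma kernel.

Families
--------
``mm``
    Classical irreversible one-complex Michaelis–Menten mechanism
    (E + S <-> C -> E + P) as four mass-action ODEs, no delays.
``es_discrete``
    Irreversible one-complex Brown mechanism: the enzyme–substrate complex
    has a fixed lifetime ``tau``; enzyme and product reappear after the lag.
``es_distributed``
    Same mechanism with the complex lifetime drawn from a shifted-gamma
    distribution; the return terms are convolution integrals.
``esi_discrete`` / ``esi_distributed``
    One substrate + one inhibitor: substrate conversion through the ES and
    EIS complexes (separate products P01, P11) and enzyme sequestration by
    inhibitor binding through the EI and EIS complexes.
``lattice_discrete`` / ``lattice_distributed``
    The general multi-substrate multi-inhibitor network reduced to delayed
    enzyme/substrate/inhibitor channels (explicit channel lists).
``lattice_full``
    The full complex-resolved lattice ODE system: every enzyme–substrate–
    inhibitor complex R_{i,j} (0<=i<=N inhibitors, 0<=j<=M substrates,
    E = R_{0,0}) is a state variable, compiled directly from the binding /
    unbinding / catalysis reaction scheme under mass action.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np

from .kernels import GammaDelayKernel, Quadrature, TruncationRule, kernel_weights

__all__ = [
    "MMRates",
    "ESKineticParams",
    "Channel",
    "ChannelRates",
    "LatticeSpec",
    "InitialCondition",
    "Term",
    "CompiledModel",
    "ModelError",
    "HistoryUnderflowError",
    "build_model",
    "evaluate_rhs",
]


class ModelError(ValueError):
    """Raised for invalid model specifications."""


class HistoryUnderflowError(RuntimeError):
    """Raised when a delayed lookup reaches before the available history."""


# --------------------------------------------------------------------------
# Parameter containers
# --------------------------------------------------------------------------

DelaySpec = None | float | tuple[GammaDelayKernel, TruncationRule]


def _check_delay(delay: DelaySpec, what: str) -> None:
    if delay is None:
        return
    if isinstance(delay, (int, float)):
        if delay < 0:
            raise ModelError(f"{what}: discrete delay must be >= 0, got {delay}")
        return
    if (
        isinstance(delay, tuple)
        and len(delay) == 2
        and isinstance(delay[0], GammaDelayKernel)
        and isinstance(delay[1], TruncationRule)
    ):
        return
    raise ModelError(
        f"{what}: delay must be None, a nonnegative lag in seconds, or a "
        f"(GammaDelayKernel, TruncationRule) pair; got {delay!r}"
    )


@dataclass(frozen=True)
class MMRates:
    """Michaelis–Menten rate constants (k1 association, k_minus1 dissociation,
    k2 catalysis)."""

    k1: float
    k_minus1: float
    k2: float

    def __post_init__(self) -> None:
        for name in ("k1", "k_minus1", "k2"):
            if getattr(self, name) < 0:
                raise ModelError(f"{name} must be >= 0")


@dataclass(frozen=True)
class ESKineticParams:
    """Brown-mechanism parameters: bimolecular rate ``kd`` and the complex
    lifetime, either a fixed lag (s) or a gamma delay kernel with its
    truncation rule."""

    kd: float
    delay: DelaySpec = 0.0

    def __post_init__(self) -> None:
        if self.kd < 0:
            raise ModelError(f"kd must be >= 0, got {self.kd}")
        _check_delay(self.delay, "ESKineticParams")


@dataclass(frozen=True)
class Channel:
    """One delayed reaction channel through the complex R_{i,j}."""

    i: int
    j: int
    rate: float
    delay: DelaySpec = 0.0

    def __post_init__(self) -> None:
        if self.rate < 0:
            raise ModelError(f"channel ({self.i},{self.j}): rate must be >= 0")
        _check_delay(self.delay, f"channel ({self.i},{self.j})")


@dataclass(frozen=True)
class ChannelRates:
    """Explicit channel lists for the delayed (channel-reduced) models.

    ``substrate_channels``: substrate S_j converted to product P_{i,j} through
    complex R_{i,j}; consumes S_j and E instantaneously, returns E (with P)
    after the channel delay.
    ``inhibitor_channels``: inhibitor I_i sequesters E through R_{i,j};
    consumes I_i and E instantaneously, returns E after the channel delay.
    """

    substrate_channels: tuple[Channel, ...]
    inhibitor_channels: tuple[Channel, ...] = ()

    def __post_init__(self) -> None:
        for group, chs in (
            ("substrate", self.substrate_channels),
            ("inhibitor", self.inhibitor_channels),
        ):
            seen = set()
            for ch in chs:
                if (ch.i, ch.j) in seen:
                    raise ModelError(f"duplicate {group} channel ({ch.i},{ch.j})")
                seen.add((ch.i, ch.j))

    @property
    def n_substrates(self) -> int:
        return max((ch.j for ch in self.substrate_channels), default=0)

    @property
    def n_inhibitors(self) -> int:
        return max((ch.i for ch in self.inhibitor_channels), default=0)


@dataclass(frozen=True)
class LatticeSpec:
    """Full complex-resolved lattice: N inhibitors, M substrates.

    Rates are mappings keyed by the complex index ``(i, j)``; anything
    absent (or referencing indices outside the lattice) is zero.

    ``alpha[(i, j)]``    forward substrate binding R_{i,j-1} + S_j -> R_{i,j}
    ``alpha_rev[(i, j)]``reverse                   R_{i,j} -> R_{i,j-1} + S_j
    ``beta[(i, j)]``     forward inhibitor binding R_{i-1,j} + I_i -> R_{i,j}
    ``beta_rev[(i, j)]`` reverse                   R_{i,j} -> R_{i-1,j} + I_i
    ``gamma[(i, j)]``    catalysis R_{i,j} -> E + P_{i,j}; gamma_{i,0} = 0 by
    default (no product from inhibitor-only complexes).
    """

    N: int
    M: int
    alpha: Mapping[tuple[int, int], float] = field(default_factory=dict)
    alpha_rev: Mapping[tuple[int, int], float] = field(default_factory=dict)
    beta: Mapping[tuple[int, int], float] = field(default_factory=dict)
    beta_rev: Mapping[tuple[int, int], float] = field(default_factory=dict)
    gamma: Mapping[tuple[int, int], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.N < 0 or self.M < 0:
            raise ModelError("N and M must be >= 0")
        for name in ("alpha", "alpha_rev", "beta", "beta_rev", "gamma"):
            for (i, j), r in getattr(self, name).items():
                if r < 0:
                    raise ModelError(f"{name}[{i},{j}] must be >= 0, got {r}")
                if not (0 <= i <= self.N and 0 <= j <= self.M):
                    raise ModelError(
                        f"{name}[{i},{j}] references a complex outside the "
                        f"(N={self.N}, M={self.M}) lattice"
                    )


@dataclass(frozen=True)
class InitialCondition:
    """Initial concentrations plus the pre-history convention.

    The history convention is: every substrate (and inhibitor) is identically
    zero on the pre-interval with a jump to its initial value at t = 0; the
    free enzyme is at ``nE0`` throughout the pre-interval; products and
    complexes start (and pre-exist) at zero.
    """

    nS0: tuple[float, ...]
    nE0: float
    nI0: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        vals = (*self.nS0, self.nE0, *self.nI0)
        if any(v < 0 for v in vals):
            raise ModelError("initial concentrations must be >= 0")

    @classmethod
    def single(cls, nS0: float, nE0: float, nI0: float | None = None) -> "InitialCondition":
        return cls(
            nS0=(float(nS0),),
            nE0=float(nE0),
            nI0=() if nI0 is None else (float(nI0),),
        )


# --------------------------------------------------------------------------
# Compiled representation
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class Term:
    """One signed mass-action contribution to a single species' derivative.

    ``d n[target] / dt += sign * rate * prod(n[factors])`` evaluated at the
    current time (``delay is None``), at ``t - delay`` (float delay), or as
    the convolution of the factor product against a truncated gamma kernel.
    """

    target: int
    sign: int
    rate: float
    factors: tuple[int, ...]
    delay: DelaySpec = None


@dataclass(frozen=True)
class CompiledModel:
    family: str
    species: tuple[str, ...]
    terms: tuple[Term, ...]

    @property
    def n_species(self) -> int:
        return len(self.species)

    def index(self, name: str) -> int:
        return self.species.index(name)

    @property
    def max_delay_horizon(self) -> float:
        """Largest lookback (s) any delayed term requires."""
        h = 0.0
        for t in self.terms:
            if t.delay is None:
                continue
            if isinstance(t.delay, (int, float)):
                h = max(h, float(t.delay))
            else:
                h = max(h, t.delay[1].tau_M)
        return h

    def distinct_kernels(self) -> list[tuple[GammaDelayKernel, TruncationRule]]:
        """Distributed delay specs in term order, deduplicated."""
        out: list[tuple[GammaDelayKernel, TruncationRule]] = []
        for t in self.terms:
            if isinstance(t.delay, tuple) and t.delay not in out:
                out.append(t.delay)
        return out

    def default_quadratures(
        self, step: float, renormalize: bool = False
    ) -> dict[tuple[GammaDelayKernel, TruncationRule], Quadrature]:
        return {
            spec: kernel_weights(spec[0], spec[1], step, renormalize=renormalize)
            for spec in self.distinct_kernels()
        }

    def initial_state(self, init: InitialCondition) -> tuple[np.ndarray, np.ndarray]:
        """Return ``(state at t=0, constant pre-history state)``.

        Substrates and inhibitors jump from 0 to their initial value at
        t = 0; free enzyme (R00 in the full lattice) holds ``nE0`` on the
        whole pre-interval; complexes and products are zero throughout.
        """
        n = self.n_species
        state0 = np.zeros(n)
        hist = np.zeros(n)
        sub_names = [s for s in self.species if s.startswith("S")]
        inh_names = [s for s in self.species if s.startswith("I")]
        if len(init.nS0) != len(sub_names):
            raise ModelError(
                f"model has {len(sub_names)} substrate(s) but the initial "
                f"condition provides {len(init.nS0)}"
            )
        if len(init.nI0) != len(inh_names):
            raise ModelError(
                f"model has {len(inh_names)} inhibitor(s) but the initial "
                f"condition provides {len(init.nI0)}"
            )
        for name, v in zip(sub_names, init.nS0):
            state0[self.index(name)] = v
        for name, v in zip(inh_names, init.nI0):
            state0[self.index(name)] = v
        e_name = "E" if "E" in self.species else "R00"
        state0[self.index(e_name)] = init.nE0
        hist[self.index(e_name)] = init.nE0
        return state0, hist


# --------------------------------------------------------------------------
# Builders
# --------------------------------------------------------------------------


def _build_mm(p: MMRates) -> CompiledModel:
    species = ("S", "E", "C", "P")
    S, E, C, P = range(4)
    terms = (
        Term(S, -1, p.k1, (S, E)),
        Term(S, +1, p.k_minus1, (C,)),
        Term(E, -1, p.k1, (S, E)),
        Term(E, +1, p.k_minus1, (C,)),
        Term(E, +1, p.k2, (C,)),
        Term(C, +1, p.k1, (S, E)),
        Term(C, -1, p.k_minus1, (C,)),
        Term(C, -1, p.k2, (C,)),
        Term(P, +1, p.k2, (C,)),
    )
    return CompiledModel("mm", species, terms)


def _build_es(p: ESKineticParams, family: str) -> CompiledModel:
    species = ("S", "E", "P")
    S, E, P = range(3)
    terms = (
        Term(S, -1, p.kd, (S, E)),
        Term(E, -1, p.kd, (S, E)),
        Term(E, +1, p.kd, (S, E), delay=p.delay),
        Term(P, +1, p.kd, (S, E), delay=p.delay),
    )
    return CompiledModel(family, species, terms)


def _channel_terms(
    rates: ChannelRates,
    species: tuple[str, ...],
    product_name: Callable[[int, int], str],
) -> tuple[Term, ...]:
    idx = {name: k for k, name in enumerate(species)}
    E = idx["E"]
    terms: list[Term] = []
    for ch in rates.substrate_channels:
        Sj = idx[f"S{ch.j}"]
        Pij = idx[product_name(ch.i, ch.j)]
        terms.append(Term(Pij, +1, ch.rate, (Sj, E), delay=ch.delay))
        terms.append(Term(Sj, -1, ch.rate, (Sj, E)))
        terms.append(Term(E, -1, ch.rate, (Sj, E)))
        terms.append(Term(E, +1, ch.rate, (Sj, E), delay=ch.delay))
    for ch in rates.inhibitor_channels:
        Ii = idx[f"I{ch.i}"]
        terms.append(Term(Ii, -1, ch.rate, (Ii, E)))
        terms.append(Term(E, -1, ch.rate, (Ii, E)))
        terms.append(Term(E, +1, ch.rate, (Ii, E), delay=ch.delay))
    return tuple(terms)


def _build_esi(rates: ChannelRates, family: str) -> CompiledModel:
    allowed_sub = {(0, 1), (1, 1)}
    allowed_inh = {(1, 0), (1, 1)}
    got_sub = {(ch.i, ch.j) for ch in rates.substrate_channels}
    got_inh = {(ch.i, ch.j) for ch in rates.inhibitor_channels}
    if not got_sub <= allowed_sub or not got_inh <= allowed_inh:
        raise ModelError(
            "esi families admit substrate channels (0,1)/(1,1) and inhibitor "
            f"channels (1,0)/(1,1); got {sorted(got_sub)}, {sorted(got_inh)}"
        )
    species = ("P01", "P11", "S1", "E", "I1")
    terms = _channel_terms(rates, species, lambda i, j: f"P{i}{j}")
    return CompiledModel(family, species, terms)


def _build_lattice_delayed(rates: ChannelRates, family: str) -> CompiledModel:
    products = tuple(f"P{ch.i}_{ch.j}" for ch in rates.substrate_channels)
    M = rates.n_substrates
    N = rates.n_inhibitors
    for ch in rates.substrate_channels:
        if ch.j < 1:
            raise ModelError(f"substrate channel ({ch.i},{ch.j}): j must be >= 1")
    for ch in rates.inhibitor_channels:
        if ch.i < 1:
            raise ModelError(f"inhibitor channel ({ch.i},{ch.j}): i must be >= 1")
    species = (
        *products,
        *(f"S{j}" for j in range(1, M + 1)),
        "E",
        *(f"I{i}" for i in range(1, N + 1)),
    )
    terms = _channel_terms(rates, species, lambda i, j: f"P{i}_{j}")
    return CompiledModel(family, species, terms)


def _build_lattice_full(spec: LatticeSpec) -> CompiledModel:
    N, M = spec.N, spec.M
    gamma = dict(spec.gamma)
    # default catalysis: product from every substrate-bearing complex unless
    # stated; never from inhibitor-only complexes
    for i in range(N + 1):
        gamma.setdefault((i, 0), 0.0)
    if any(g > 0 for (i, j), g in gamma.items() if j == 0):
        raise ModelError("gamma_{i,0} must be 0: no product from inhibitor-only complexes")
    complexes = [(i, j) for i in range(N + 1) for j in range(M + 1)]
    prod_idx = sorted((i, j) for (i, j), g in gamma.items() if g > 0)
    species = (
        *(f"S{j}" for j in range(1, M + 1)),
        *(f"I{i}" for i in range(1, N + 1)),
        *("R00" if (i, j) == (0, 0) else f"R{i}_{j}" for (i, j) in complexes),
        *(f"P{i}_{j}" for (i, j) in prod_idx),
    )
    idx = {name: k for k, name in enumerate(species)}

    def R(i: int, j: int) -> int:
        return idx["R00"] if (i, j) == (0, 0) else idx[f"R{i}_{j}"]

    terms: list[Term] = []

    def reaction(rate: float, consumed: Sequence[int], produced: Sequence[int]) -> None:
        if rate <= 0:
            return
        factors = tuple(consumed)
        for s in consumed:
            terms.append(Term(s, -1, rate, factors))
        for s in produced:
            terms.append(Term(s, +1, rate, factors))

    for i in range(N + 1):
        for j in range(1, M + 1):
            Sj = idx[f"S{j}"]
            # R_{i,j-1} + S_j <-> R_{i,j} -> E + P_{i,j}
            reaction(spec.alpha.get((i, j), 0.0), [R(i, j - 1), Sj], [R(i, j)])
            reaction(spec.alpha_rev.get((i, j), 0.0), [R(i, j)], [R(i, j - 1), Sj])
            g = gamma.get((i, j), 0.0)
            if g > 0:
                reaction(g, [R(i, j)], [R(0, 0), idx[f"P{i}_{j}"]])
    for i in range(1, N + 1):
        for j in range(M + 1):
            Ii = idx[f"I{i}"]
            reaction(spec.beta.get((i, j), 0.0), [R(i - 1, j), Ii], [R(i, j)])
            reaction(spec.beta_rev.get((i, j), 0.0), [R(i, j)], [R(i - 1, j), Ii])
    return CompiledModel("lattice_full", species, tuple(terms))


_BUILDERS = {
    "mm": (_build_mm, MMRates),
    "es_discrete": (lambda p: _build_es(p, "es_discrete"), ESKineticParams),
    "es_distributed": (lambda p: _build_es(p, "es_distributed"), ESKineticParams),
    "esi_discrete": (lambda p: _build_esi(p, "esi_discrete"), ChannelRates),
    "esi_distributed": (lambda p: _build_esi(p, "esi_distributed"), ChannelRates),
    "lattice_discrete": (
        lambda p: _build_lattice_delayed(p, "lattice_discrete"),
        ChannelRates,
    ),
    "lattice_distributed": (
        lambda p: _build_lattice_delayed(p, "lattice_distributed"),
        ChannelRates,
    ),
    "lattice_full": (_build_lattice_full, LatticeSpec),
}


def build_model(family: str, params) -> CompiledModel:
    """Compile a model family + parameter spec into a term list.

    ``es_discrete``/``esi_discrete`` require float delays and the
    ``*_distributed`` variants kernel delays; the generic ``lattice_*``
    families accept either per channel.
    """
    if family not in _BUILDERS:
        raise ModelError(
            f"unknown family {family!r}; expected one of {sorted(_BUILDERS)}"
        )
    builder, ptype = _BUILDERS[family]
    if not isinstance(params, ptype):
        raise ModelError(
            f"family {family!r} expects {ptype.__name__} parameters, "
            f"got {type(params).__name__}"
        )
    model = builder(params)
    _check_family_delays(model)
    return model


def _check_family_delays(model: CompiledModel) -> None:
    fam = model.family
    for t in model.terms:
        if t.delay is None:
            continue
        discrete = isinstance(t.delay, (int, float))
        if fam.endswith("_discrete") and not discrete:
            raise ModelError(f"family {fam!r} requires discrete (float) delays")
        if fam.endswith("_distributed") and discrete:
            raise ModelError(f"family {fam!r} requires kernel delays")


# --------------------------------------------------------------------------
# Reference right-hand side (pure Python; the integrator uses a compiled
# equivalent — see engine.py)
# --------------------------------------------------------------------------


def evaluate_rhs(
    model: CompiledModel,
    t: float,
    history: Callable[[float], np.ndarray],
    quadratures: Mapping[tuple[GammaDelayKernel, TruncationRule], Quadrature]
    | None = None,
    history_start: float = -np.inf,
    jump_time: float | None = 0.0,
) -> np.ndarray:
    """Evaluate the derivative vector at time ``t``.

    ``history(u)`` must return the full state vector for any
    ``u in [t - max_delay_horizon, t]``; ``history_start`` declares the
    earliest time it is defined, and a delayed lookup before it raises
    :class:`HistoryUnderflowError`.  Distributed terms are evaluated as
    ``rate * sum_k w_k * prod(n[factors](t + s_k))`` with the nodes/weights
    from ``quadratures`` (one entry per distinct kernel spec).

    At ``jump_time`` (the substrate-addition instant, where the solution is
    two-valued) delayed lookups return the mean of the two one-sided limits:
    quadrature across the kink needs the average value of a jump
    discontinuity to stay second-order accurate.  Pass ``jump_time=None``
    for the literal right-limit convention.
    """

    def lookup(u: float, delayed: bool) -> np.ndarray:
        if u < history_start - 1e-9:
            raise HistoryUnderflowError(
                f"history queried at t={u}, before its domain start {history_start}"
            )
        y = np.asarray(history(u), dtype=float)
        if delayed and jump_time is not None and abs(u - jump_time) < 1e-12:
            y_left = np.asarray(history(jump_time - 1e-9), dtype=float)
            y = 0.5 * (y + y_left)
        return y

    def fprod(y: np.ndarray, factors) -> float:
        return float(np.prod([y[f] for f in factors]))

    d = np.zeros(model.n_species)
    for term in model.terms:
        if term.delay is None:
            val = term.rate * fprod(lookup(t, False), term.factors)
        elif isinstance(term.delay, (int, float)):
            tau = float(term.delay)
            val = term.rate * fprod(lookup(t - tau, tau > 0), term.factors)
        else:
            if quadratures is None or term.delay not in quadratures:
                raise ModelError(
                    "distributed term needs a quadrature; pass "
                    "model.default_quadratures(step)"
                )
            quad = quadratures[term.delay]
            acc = 0.0
            for s_k, w_k in zip(quad.nodes, quad.weights):
                acc += w_k * fprod(lookup(t + s_k, s_k < 0), term.factors)
            val = term.rate * acc
        d[term.target] += term.sign * val
    return d
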