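"""CSV series I/O and YAML configuration loading.

The canonical on-disk series format is long CSV with columns
``series_id,time_s,conductivity`` (absolute experiment time in seconds; no
baseline subtraction — conversion to model time happens in the fitting
layer, never in I/O).  A wide layout is also read: a time column plus one
column per dose, dose volumes taken from the column headers or a sidecar
metadata mapping.
"""

from __future__ import annotations

from dataclasses import dataclass, fields as dc_fields

import numpy as np
import pandas as pd
import yaml

from .fitting import (
    DEFAULT_BOUNDS,
    DEFAULT_PI_INIT,
    PARAM_NAMES,
    Bounds,
    ConductivitySeries,
    ParameterVector,
)
from .kernels import DEFAULT_CONFIDENCE, GammaDelayKernel, truncation_bound
from .models import (
    Channel,
    ChannelRates,
    CompiledModel,
    ESKineticParams,
    InitialCondition,
    LatticeSpec,
    MMRates,
    build_model,
)
from .synthetic import ProtocolSpec

__all__ = [
    "FormatError",
    "ConfigError",
    "read_series",
    "write_series",
    "load_config",
    "Config",
]


class FormatError(ValueError):
    """Malformed series file."""


class ConfigError(ValueError):
    """Invalid configuration file."""


_LONG_COLUMNS = ("series_id", "time_s", "conductivity")
_TIME_ALIASES = ("time", "time_s", "t", "times")


def _dose_from_id(sid) -> float | None:
    """Dose volume from a series id that is, or ends in, a number
    (e.g. "0.3" or "dose_0.3")."""
    for cand in (sid, str(sid).rsplit("_", 1)[-1]):
        try:
            return float(cand)
        except (TypeError, ValueError):
            continue
    return None


def read_series(
    path,
    layout: str = "long",
    addition_time: float = 250.0,
    doses: dict | None = None,
) -> list[ConductivitySeries]:
    """Read conductance series from CSV.

    ``layout="long"`` expects columns ``series_id,time_s,conductivity``;
    ``layout="wide"`` expects a time column plus one column per series, with
    dose volumes parsed from numeric headers or supplied via ``doses``
    (mapping series id -> dose volume, applied in either layout).
    """
    if layout not in ("long", "wide"):
        raise FormatError(f"unknown layout {layout!r}; expected 'long' or 'wide'")
    try:
        df = pd.read_csv(path)
    except Exception as err:  # noqa: BLE001 - surface parser failures uniformly
        raise FormatError(f"{path}: {err}") from err
    doses = doses or {}

    def build(sid: str, t: np.ndarray, k: np.ndarray, rows: np.ndarray, dose):
        order = np.diff(t) > 0
        if not np.all(order):
            bad_row = int(rows[int(np.argmin(order)) + 1])
            raise FormatError(
                f"{path}: series {sid!r}: time not strictly increasing at row {bad_row}"
            )
        return ConductivitySeries(
            series_id=str(sid),
            times=t,
            kappa=k,
            dose_volume=dose,
            addition_time=addition_time,
        )

    if layout == "long":
        missing = [c for c in _LONG_COLUMNS if c not in df.columns]
        if missing:
            raise FormatError(f"{path}: missing column(s) {missing}")
        for col in ("time_s", "conductivity"):
            bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
            if bad.any():
                raise FormatError(
                    f"{path}: non-numeric {col!r} at row {int(bad.idxmax()) + 2}"
                )
            if df[col].isna().any():
                raise FormatError(
                    f"{path}: empty {col!r} at row {int(df[col].isna().idxmax()) + 2}"
                )
        out = []
        for sid, g in df.groupby("series_id", sort=False):
            dose = doses.get(str(sid))
            if dose is None:
                dose = _dose_from_id(sid)
            out.append(
                build(
                    sid,
                    g["time_s"].to_numpy(dtype=float),
                    g["conductivity"].to_numpy(dtype=float),
                    g.index.to_numpy() + 2,
                    dose,
                )
            )
        return out

    time_col = next((c for c in df.columns if str(c).lower() in _TIME_ALIASES), None)
    if time_col is None:
        raise FormatError(
            f"{path}: wide layout needs a time column named one of {_TIME_ALIASES}"
        )
    t = pd.to_numeric(df[time_col], errors="coerce")
    if t.isna().any():
        raise FormatError(
            f"{path}: non-numeric time at row {int(t.isna().idxmax()) + 2}"
        )
    out = []
    for col in df.columns:
        if col == time_col:
            continue
        k = pd.to_numeric(df[col], errors="coerce")
        if k.isna().any():
            raise FormatError(
                f"{path}: non-numeric value in column {col!r} at row "
                f"{int(k.isna().idxmax()) + 2}"
            )
        dose = doses.get(str(col))
        if dose is None:
            try:
                dose = float(col)
            except ValueError:
                dose = None
        out.append(
            build(
                str(col),
                t.to_numpy(dtype=float),
                k.to_numpy(dtype=float),
                df.index.to_numpy() + 2,
                dose,
            )
        )
    return out


def write_series(series_list, path) -> None:
    """Write series as long CSV, lossless to 10 significant digits."""
    frames = [
        pd.DataFrame(
            {"series_id": s.series_id, "time_s": s.times, "conductivity": s.kappa}
        )
        for s in series_list
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False, float_format="%.10g")


# --------------------------------------------------------------------------
# Configuration
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class FitConfig:
    pi_init: ParameterVector = DEFAULT_PI_INIT
    bounds: Bounds = DEFAULT_BOUNDS
    xi: float = 1e3
    max_iter: int = 50
    confidence: float = DEFAULT_CONFIDENCE
    mode: str = "constrained"
    baseline_subtract: bool = True
    dt: float = 0.05


@dataclass(frozen=True)
class Config:
    model: CompiledModel | None = None
    initial: InitialCondition | None = None
    fit: FitConfig = FitConfig()
    protocol: ProtocolSpec = ProtocolSpec()
    truth: ParameterVector | None = None


def _require_keys(block: dict, allowed: set, path: str) -> None:
    unknown = set(block) - allowed
    if unknown:
        raise ConfigError(
            f"{path}: unknown key(s) {sorted(unknown)}; allowed: {sorted(allowed)}"
        )


def _pi_from(node, path: str, default: ParameterVector) -> ParameterVector:
    if node is None:
        return default
    if isinstance(node, (list, tuple)):
        if len(node) != 6:
            raise ConfigError(f"{path}: need 6 values (kd, a, m, tau_min, lambda0, K)")
        return ParameterVector.from_array([float(v) for v in node])
    if isinstance(node, dict):
        _require_keys(node, set(PARAM_NAMES), path)
        vals = {n: float(node.get(n, getattr(default, n))) for n in PARAM_NAMES}
        return ParameterVector(**vals)
    raise ConfigError(f"{path}: expected list or mapping, got {type(node).__name__}")


def _kernel_from(node: dict, path: str) -> GammaDelayKernel:
    _require_keys(node, {"a", "m", "tau_min"}, path)
    try:
        return GammaDelayKernel(
            rate_a=float(node.get("a", 1.0)),
            shape_m=float(node.get("m", 0.0)),
            tau_min=float(node.get("tau_min", 0.0)),
        )
    except ValueError as err:
        raise ConfigError(f"{path}: {err}") from err


def _delay_from(node: dict, path: str, confidence: float):
    has_tau = "tau" in node
    has_kernel = "kernel" in node
    if has_tau and has_kernel:
        raise ConfigError(f"{path}: give either 'tau' or 'kernel', not both")
    if has_tau:
        return float(node["tau"])
    if has_kernel:
        kern = _kernel_from(node["kernel"], f"{path}.kernel")
        return (kern, truncation_bound(kern, confidence))
    return 0.0


def _channels_from(nodes, path: str, confidence: float) -> tuple[Channel, ...]:
    out = []
    for k, node in enumerate(nodes):
        _require_keys(node, {"i", "j", "rate", "tau", "kernel"}, f"{path}[{k}]")
        out.append(
            Channel(
                i=int(node["i"]),
                j=int(node["j"]),
                rate=float(node["rate"]),
                delay=_delay_from(node, f"{path}[{k}]", confidence),
            )
        )
    return tuple(out)


def _rates_map(node, path: str) -> dict:
    out = {}
    for k, entry in enumerate(node or []):
        _require_keys(entry, {"i", "j", "rate"}, f"{path}[{k}]")
        out[(int(entry["i"]), int(entry["j"]))] = float(entry["rate"])
    return out


def _model_from(block: dict, confidence: float):
    allowed = {
        "family", "k1", "k_minus1", "k2", "kd", "tau", "kernel", "confidence",
        "substrate_channels", "inhibitor_channels",
        "N", "M", "alpha", "alpha_rev", "beta", "beta_rev", "gamma",
        "initial",
    }
    _require_keys(block, allowed, "model")
    family = block.get("family")
    if family is None:
        raise ConfigError("model: missing 'family'")
    confidence = float(block.get("confidence", confidence))
    if family == "mm":
        params = MMRates(
            k1=float(block.get("k1", 0.0)),
            k_minus1=float(block.get("k_minus1", 0.0)),
            k2=float(block.get("k2", 0.0)),
        )
    elif family in ("es_discrete", "es_distributed"):
        params = ESKineticParams(
            kd=float(block.get("kd", 0.0)),
            delay=_delay_from(block, "model", confidence),
        )
    elif family in ("esi_discrete", "esi_distributed", "lattice_discrete", "lattice_distributed"):
        params = ChannelRates(
            substrate_channels=_channels_from(
                block.get("substrate_channels", []), "model.substrate_channels", confidence
            ),
            inhibitor_channels=_channels_from(
                block.get("inhibitor_channels", []), "model.inhibitor_channels", confidence
            ),
        )
    elif family == "lattice_full":
        params = LatticeSpec(
            N=int(block.get("N", 1)),
            M=int(block.get("M", 1)),
            alpha=_rates_map(block.get("alpha"), "model.alpha"),
            alpha_rev=_rates_map(block.get("alpha_rev"), "model.alpha_rev"),
            beta=_rates_map(block.get("beta"), "model.beta"),
            beta_rev=_rates_map(block.get("beta_rev"), "model.beta_rev"),
            gamma=_rates_map(block.get("gamma"), "model.gamma"),
        )
    else:
        raise ConfigError(f"model.family: unknown family {family!r}")
    try:
        model = build_model(family, params)
    except ValueError as err:
        raise ConfigError(f"model: {err}") from err

    initial = None
    init_block = block.get("initial")
    if init_block is not None:
        _require_keys(init_block, {"nS0", "nE0", "nI0"}, "model.initial")
        nS0 = init_block.get("nS0", 0.0)
        nI0 = init_block.get("nI0", [])
        initial = InitialCondition(
            nS0=tuple(float(v) for v in (nS0 if isinstance(nS0, list) else [nS0])),
            nE0=float(init_block.get("nE0", 0.0)),
            nI0=tuple(float(v) for v in (nI0 if isinstance(nI0, list) else [nI0])),
        )
    return model, initial


def load_config(path) -> Config:
    """Load and validate a YAML configuration.

    Top-level blocks: ``model`` (family + rates + delays + initial),
    ``fit`` (init/lower/upper default to the reference study's values when
    omitted), ``protocol`` and ``truth``.  Unknown keys anywhere are an
    error; every validation failure names the offending key path.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    _require_keys(raw, {"model", "fit", "protocol", "truth"}, "top level")

    fit_block = raw.get("fit") or {}
    _require_keys(
        fit_block,
        {"init", "lower", "upper", "xi", "max_iter", "confidence", "mode",
         "baseline_subtract", "dt"},
        "fit",
    )
    lower = fit_block.get("lower")
    upper = fit_block.get("upper")
    try:
        bounds = Bounds(
            lower=np.asarray(lower, dtype=float) if lower is not None else DEFAULT_BOUNDS.lower,
            upper=np.asarray(upper, dtype=float) if upper is not None else DEFAULT_BOUNDS.upper,
        )
        fit = FitConfig(
            pi_init=_pi_from(fit_block.get("init"), "fit.init", DEFAULT_PI_INIT),
            bounds=bounds,
            xi=float(fit_block.get("xi", 1e3)),
            max_iter=int(fit_block.get("max_iter", 50)),
            confidence=float(fit_block.get("confidence", DEFAULT_CONFIDENCE)),
            mode=str(fit_block.get("mode", "constrained")),
            baseline_subtract=bool(fit_block.get("baseline_subtract", True)),
            dt=float(fit_block.get("dt", 0.05)),
        )
    except ValueError as err:
        raise ConfigError(f"fit: {err}") from err

    proto_block = raw.get("protocol") or {}
    allowed = {f.name for f in dc_fields(ProtocolSpec)}
    _require_keys(proto_block, allowed, "protocol")
    try:
        protocol = ProtocolSpec(**{k: v for k, v in proto_block.items()})
    except (TypeError, ValueError) as err:
        raise ConfigError(f"protocol: {err}") from err

    model = initial = None
    if raw.get("model") is not None:
        model, initial = _model_from(raw["model"], fit.confidence)

    truth = None
    if raw.get("truth") is not None:
        truth = _pi_from(raw["truth"], "truth", DEFAULT_PI_INIT)

    return Config(model=model, initial=initial, fit=fit, protocol=protocol, truth=truth)
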