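"""Pipeline configuration: TOML schema, defaults, validation.

Every tunable of the simulate -> tacf -> fit -> heterogeneity pipeline lives
in one TOML file; :func:`validate_config` checks it fully (unknown keys,
types, ranges), fills defaults, and returns a normalized
:class:`PipelineConfig` whose echo reproduces the run byte for byte.
"""

from __future__ import annotations

import tomllib
from dataclasses import dataclass, field
from pathlib import Path

from .decay_fitting import FitConfig
from .synthetic import MixturePopulation, MixtureSpec, RotDiffSpec, RouseChainSpec

__all__ = ["ConfigError", "PipelineConfig", "validate_config", "parse_config_dict"]

_INPUT_KINDS = ("rotational_diffusion", "rouse", "mixture", "xyz", "archive")

_DEFAULTS = {
    "seed": 0,
    "output_dir": "ringhet_out",
    "label": "",
    "tacf": {"origin_stride": 1, "max_lag_fraction": 0.5},
    "fit": {
        "max_points": 200,
        "noise_floor": 0.0,
        "min_count": 1,
        "weighting": "equal",
        "max_modes": 6,
        "mode_improvement_threshold": 0.1,
        "multistart_seed": 20200330,
        "modes": "auto",
    },
    "heterogeneity": {
        "reference_time_ns": "self",
        "bin_width": 0.1,
        "thresholds": [1.0, 2.0],
    },
}


class ConfigError(ValueError):
    """Invalid pipeline configuration; ``errors`` lists every problem found."""

    def __init__(self, errors: list[str]):
        self.errors = list(errors)
        super().__init__("invalid configuration:\n" + "\n".join(f"  - {e}" for e in errors))


@dataclass(frozen=True)
class PipelineConfig:
    """Normalized pipeline settings (defaults filled, types checked)."""

    seed: int
    output_dir: str
    label: str
    input_kind: str
    input_params: dict
    origin_stride: int
    max_lag_fraction: float
    fit: FitConfig
    modes: str | int  # "auto" or a fixed mode count
    reference_time_ns: float | str  # "self" -> this run's ensemble KWW tau0
    bin_width: float
    thresholds: tuple[float, ...] = field(default_factory=tuple)

    def to_dict(self) -> dict:
        """Round-trippable echo: parse_config_dict(to_dict()) == self."""
        return {
            "seed": self.seed,
            "output_dir": self.output_dir,
            "label": self.label,
            "input": dict(self.input_params, kind=self.input_kind),
            "tacf": {
                "origin_stride": self.origin_stride,
                "max_lag_fraction": self.max_lag_fraction,
            },
            "fit": {
                "max_points": self.fit.max_points,
                "noise_floor": self.fit.noise_floor,
                "min_count": self.fit.min_count,
                "weighting": self.fit.weighting,
                "max_modes": self.fit.max_modes,
                "mode_improvement_threshold": self.fit.mode_improvement_threshold,
                "multistart_seed": self.fit.seed,
                "modes": self.modes,
            },
            "heterogeneity": {
                "reference_time_ns": self.reference_time_ns,
                "bin_width": self.bin_width,
                "thresholds": list(self.thresholds),
            },
        }

    def build_input_spec(self):
        """Instantiate the synthetic-data spec for generator inputs."""
        p = self.input_params
        if self.input_kind == "rotational_diffusion":
            return RotDiffSpec(
                n_molecules=p["n_molecules"],
                D_r=p["D_r"],
                dt=p["dt_ns"],
                n_frames=p["n_frames"],
                seed=self.seed,
            )
        if self.input_kind == "rouse":
            return RouseChainSpec(
                topology=p["topology"],
                n_beads=p["n_beads"],
                k=p["k"],
                zeta=p["zeta"],
                dt=p["dt_ns"],
                n_steps=p["n_steps"],
                save_stride=p["save_stride"],
                seed=self.seed,
                n_molecules=p.get("n_molecules", 1),
            )
        if self.input_kind == "mixture":
            pops = tuple(
                MixturePopulation(
                    weight=q["weight"],
                    decay_kind=q["decay_kind"],
                    tau=q["tau_ns"],
                    beta=q.get("beta", 1.0),
                )
                for q in p["populations"]
            )
            return MixtureSpec(
                populations=pops,
                n_molecules=p["n_molecules"],
                dt=p["dt_ns"],
                n_frames=p["n_frames"],
                seed=self.seed,
                n_tracers=p.get("n_tracers", 1),
            )
        raise ValueError(f"input kind {self.input_kind!r} is file-based, not a generator")


def _check(table: dict, name: str, allowed: dict[str, type | tuple[type, ...]], errors: list[str]) -> None:
    for key in table:
        if key not in allowed:
            errors.append(f"{name}: unknown key {key!r}")
    for key, typ in allowed.items():
        if key in table and not isinstance(table[key], typ):
            errors.append(f"{name}.{key}: expected {typ}, got {type(table[key]).__name__}")


def parse_config_dict(raw: dict) -> PipelineConfig:
    """Validate a parsed TOML mapping; raise ConfigError listing all faults."""
    errors: list[str] = []
    _check(
        raw,
        "config",
        {"seed": int, "output_dir": str, "label": str, "input": dict, "tacf": dict,
         "fit": dict, "heterogeneity": dict},
        errors,
    )
    seed = raw.get("seed", _DEFAULTS["seed"])
    output_dir = raw.get("output_dir", _DEFAULTS["output_dir"])
    label = raw.get("label", _DEFAULTS["label"])

    inp = raw.get("input")
    input_kind, input_params = "", {}
    if not isinstance(inp, dict):
        errors.append("input: required table missing")
    else:
        input_kind = inp.get("kind", "")
        if input_kind not in _INPUT_KINDS:
            errors.append(f"input.kind: must be one of {_INPUT_KINDS}, got {input_kind!r}")
        input_params = {k: v for k, v in inp.items() if k != "kind"}
        numeric = (int, float)
        if input_kind == "rotational_diffusion":
            _check(inp, "input", {"kind": str, "n_molecules": int, "D_r": numeric,
                                  "dt_ns": numeric, "n_frames": int}, errors)
            for req in ("n_molecules", "D_r", "dt_ns", "n_frames"):
                if req not in inp:
                    errors.append(f"input.{req}: required for rotational_diffusion")
        elif input_kind == "rouse":
            _check(inp, "input", {"kind": str, "topology": str, "n_beads": int, "k": numeric,
                                  "zeta": numeric, "dt_ns": numeric, "n_steps": int,
                                  "save_stride": int, "n_molecules": int}, errors)
            for req in ("topology", "n_beads", "k", "zeta", "dt_ns", "n_steps", "save_stride"):
                if req not in inp:
                    errors.append(f"input.{req}: required for rouse")
        elif input_kind == "mixture":
            _check(inp, "input", {"kind": str, "n_molecules": int, "dt_ns": numeric,
                                  "n_frames": int, "n_tracers": int, "populations": list}, errors)
            for req in ("n_molecules", "dt_ns", "n_frames", "populations"):
                if req not in inp:
                    errors.append(f"input.{req}: required for mixture")
            for i, pop in enumerate(inp.get("populations", [])):
                if not isinstance(pop, dict):
                    errors.append(f"input.populations[{i}]: expected a table")
                    continue
                _check(pop, f"input.populations[{i}]",
                       {"weight": numeric, "decay_kind": str, "tau_ns": numeric, "beta": numeric},
                       errors)
                for req in ("weight", "decay_kind", "tau_ns"):
                    if req not in pop:
                        errors.append(f"input.populations[{i}].{req}: required")
        elif input_kind in ("xyz", "archive"):
            allowed = {"kind": str, "path": str}
            if input_kind == "xyz":
                allowed["system"] = str
            _check(inp, "input", allowed, errors)
            if "path" not in inp:
                errors.append("input.path: required for file inputs")
            if input_kind == "xyz" and "system" not in inp:
                errors.append("input.system: required for xyz inputs (path to a system TOML)")
        if "dt_ns" in inp and isinstance(inp["dt_ns"], (int, float)) and inp["dt_ns"] <= 0:
            errors.append("input.dt_ns: must be > 0")

    tacf_raw = dict(_DEFAULTS["tacf"], **raw.get("tacf", {}))
    _check(tacf_raw, "tacf", {"origin_stride": int, "max_lag_fraction": (int, float)}, errors)
    if isinstance(tacf_raw.get("origin_stride"), int) and tacf_raw["origin_stride"] < 1:
        errors.append("tacf.origin_stride: must be >= 1")
    mlf = tacf_raw.get("max_lag_fraction")
    if isinstance(mlf, (int, float)) and not 0 < mlf <= 1:
        errors.append("tacf.max_lag_fraction: must lie in (0, 1]")

    fit_raw = dict(_DEFAULTS["fit"], **raw.get("fit", {}))
    _check(fit_raw, "fit", {"max_points": int, "noise_floor": (int, float), "min_count": int,
                            "weighting": str, "max_modes": int,
                            "mode_improvement_threshold": (int, float),
                            "multistart_seed": int, "modes": (str, int)}, errors)
    modes = fit_raw.get("modes", "auto")
    if isinstance(modes, str) and modes != "auto":
        errors.append(f"fit.modes: must be 'auto' or an integer, got {modes!r}")
    if isinstance(modes, int) and modes < 1:
        errors.append("fit.modes: must be >= 1")

    het_raw = dict(_DEFAULTS["heterogeneity"], **raw.get("heterogeneity", {}))
    _check(het_raw, "heterogeneity",
           {"reference_time_ns": (int, float, str), "bin_width": (int, float),
            "thresholds": list}, errors)
    ref = het_raw.get("reference_time_ns")
    if isinstance(ref, str) and ref != "self":
        errors.append(f"heterogeneity.reference_time_ns: must be a number or 'self', got {ref!r}")
    if isinstance(ref, (int, float)) and not isinstance(ref, bool) and ref <= 0:
        errors.append("heterogeneity.reference_time_ns: must be > 0")
    bw = het_raw.get("bin_width")
    if isinstance(bw, (int, float)) and bw <= 0:
        errors.append("heterogeneity.bin_width: must be > 0")
    thresholds = het_raw.get("thresholds", [])
    if isinstance(thresholds, list) and any(
        not isinstance(t, (int, float)) or t <= 0 for t in thresholds
    ):
        errors.append("heterogeneity.thresholds: all entries must be positive numbers")

    if errors:
        raise ConfigError(errors)

    fit_cfg = FitConfig(
        max_points=fit_raw["max_points"],
        noise_floor=float(fit_raw["noise_floor"]),
        min_count=fit_raw["min_count"],
        weighting=fit_raw["weighting"],
        max_modes=fit_raw["max_modes"],
        mode_improvement_threshold=float(fit_raw["mode_improvement_threshold"]),
        seed=fit_raw["multistart_seed"],
    )
    return PipelineConfig(
        seed=seed,
        output_dir=output_dir,
        label=label,
        input_kind=input_kind,
        input_params=input_params,
        origin_stride=tacf_raw["origin_stride"],
        max_lag_fraction=float(tacf_raw["max_lag_fraction"]),
        fit=fit_cfg,
        modes=modes,
        reference_time_ns=ref if isinstance(ref, str) else float(ref),
        bin_width=float(bw),
        thresholds=tuple(float(t) for t in thresholds),
    )


def validate_config(path) -> PipelineConfig:
    """Load and validate a pipeline TOML file."""
    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    cfg = parse_config_dict(raw)
    if cfg.input_kind in ("xyz", "archive"):
        base = Path(path).parent
        missing = [
            str(base / cfg.input_params[key])
            for key in ("path", "system")
            if key in cfg.input_params and not (base / cfg.input_params[key]).exists()
        ]
        if missing:
            raise ConfigError([f"input file does not exist: {m}" for m in missing])
    return cfg
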