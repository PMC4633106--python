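"""Run configuration: schema, validation, and packaged condition presets.

A run configuration bundles one experimental condition (concentrations,
calcium via epsilon, camera settings, background noise), the kinetic and
optical parameters, a replicate count and a master seed.  Configurations
are YAML files with the sections ``condition``, ``kinetics``, ``optics``
plus top-level ``replicates`` and ``seed``; unknown keys are rejected
with the offending field named.

The package ships presets for the nine experimental conditions simulated
in the source study (a myosin series at pCa 6 / 0.1 uM ATP / 10 Hz, a
calcium series and an ATP series at 15 nM myosin / 3.8 Hz), with the
per-condition background noise and the calcium-to-epsilon mapping
(0.4 / 0.06 / 0.02 at pCa 5 / 6 / 7) baked in, plus a myosin-free
noise-only control.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, fields

import yaml

from .render import OpticsParams
from .simulate import Condition, KineticParams

__all__ = ["RunConfig", "ConfigError", "load_config", "preset_names"]

#: epsilon at each calcium level used in the simulations (from fits).
EPSILON_BY_PCA = {5: 0.4, 6: 0.06, 7: 0.02}


class ConfigError(ValueError):
    """A configuration file violated the schema."""


@dataclass
class RunConfig:
    """Fully-validated inputs for one pipeline run."""

    condition: Condition
    kinetics: KineticParams = field(default_factory=KineticParams)
    optics: OpticsParams = field(default_factory=OpticsParams)
    n_replicates: int = 5
    seed: int = 0
    condition_id: str = "custom"
    pCa: float | None = None  # informational; epsilon is the model input

    def __post_init__(self) -> None:
        if self.n_replicates < 1:
            raise ConfigError("replicates must be >= 1")


def _build_section(cls, section: dict, name: str):
    allowed = {f.name for f in fields(cls)}
    unknown = set(section) - allowed
    if unknown:
        raise ConfigError(f"unknown key(s) {sorted(unknown)} in section '{name}'")
    try:
        return cls(**section)
    except (TypeError, ValueError) as err:
        raise ConfigError(f"invalid section '{name}': {err}") from err


def _from_dict(data: dict, condition_id: str = "custom") -> RunConfig:
    if not isinstance(data, dict):
        raise ConfigError("config root must be a mapping")
    allowed_top = {"condition", "kinetics", "optics", "replicates", "seed",
                   "condition_id", "pCa"}
    unknown = set(data) - allowed_top
    if unknown:
        raise ConfigError(f"unknown top-level key(s) {sorted(unknown)}")
    if "condition" not in data:
        raise ConfigError("missing required section 'condition'")
    cond_section = dict(data["condition"])
    pCa = cond_section.pop("pCa", data.get("pCa"))
    condition = _build_section(Condition, cond_section, "condition")
    kinetics = _build_section(KineticParams, dict(data.get("kinetics", {})), "kinetics")
    optics = _build_section(OpticsParams, dict(data.get("optics", {})), "optics")
    return RunConfig(
        condition=condition,
        kinetics=kinetics,
        optics=optics,
        n_replicates=int(data.get("replicates", 5)),
        seed=int(data.get("seed", 0)),
        condition_id=str(data.get("condition_id", condition_id)),
        pCa=pCa,
    )


def _preset_dir():
    return importlib.resources.files("thinfil") / "presets"


def preset_names() -> list[str]:
    """Names of the packaged condition presets."""
    return sorted(p.name[:-5] for p in _preset_dir().iterdir() if p.name.endswith(".yaml"))


def load_config(path_or_preset: str) -> RunConfig:
    """Load and validate a run configuration from a file or preset name.

    ``path_or_preset`` is first matched against the packaged preset
    names; otherwise it is read as a YAML file path.
    """
    name = str(path_or_preset)
    if name in preset_names():
        text = (_preset_dir() / f"{name}.yaml").read_text()
        condition_id = name
    else:
        try:
            with open(name) as fh:
                text = fh.read()
        except FileNotFoundError:
            raise ConfigError(
                f"'{name}' is neither a packaged preset ({', '.join(preset_names())}) "
                "nor a readable file"
            ) from None
        condition_id = "custom"
    try:
        data = yaml.safe_load(text)
    except yaml.YAMLError as err:
        raise ConfigError(f"malformed YAML in '{name}': {err}") from err
    return _from_dict(data, condition_id=condition_id)
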