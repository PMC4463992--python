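"""Pipeline configuration: plain YAML key/value files.

Defaults reproduce the packaged layer boundaries and combination weights
bit-for-bit; every field can be overridden from a config file or a CLI
flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import yaml

from shellsim.similarity import DEFAULT_LAYER_SCHEME, LayerScheme, WeightVector

__all__ = ["PipelineConfig", "load_config", "packaged_data_path"]

_VALID_MODES = ("union", "literal", "both")


@dataclass
class PipelineConfig:
    breakpoints: tuple[float, ...] = DEFAULT_LAYER_SCHEME.breakpoints
    weights_file: str | None = None  # None -> packaged default weights
    mode: str = "union"
    sink: str = "Cell proliferation"
    seed: int = 0
    outdir: str = "."

    def __post_init__(self) -> None:
        self.breakpoints = tuple(float(b) for b in self.breakpoints)
        LayerScheme(self.breakpoints)  # validate
        if self.mode not in _VALID_MODES:
            raise ValueError(f"mode must be one of {_VALID_MODES}, got {self.mode!r}")

    @property
    def scheme(self) -> LayerScheme:
        return LayerScheme(self.breakpoints)

    def weights(self) -> WeightVector:
        if self.weights_file is None:
            from shellsim.synthetic_data import table1_weights

            return table1_weights()
        from shellsim.weight_training import read_weights_file

        return read_weights_file(self.weights_file)


def load_config(path: str | Path | None) -> PipelineConfig:
    """Load a YAML config; a missing path returns the defaults."""
    if path is None:
        return PipelineConfig()
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"config {path} must be a mapping")
    known = {f for f in PipelineConfig.__dataclass_fields__}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"config {path}: unknown keys {sorted(unknown)}")
    return PipelineConfig(**raw)


def packaged_data_path(name: str) -> Path:
    """Path of a data file shipped inside the package."""
    return Path(resources.files("shellsim").joinpath("data", name))
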