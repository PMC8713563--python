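"""Pipeline configuration: one nested, validated structure holding every
tunable, serializable to/from YAML.  Unknown keys are rejected so typos
never silently fall back to defaults; every run writes the fully
resolved configuration next to its outputs.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .simulate import SimDesign


@dataclass
class QCConfig:
    motion_mm: float = 0.3  # mean motion per TR threshold (strict >)
    censor_frac: float = 0.30  # censor-fraction threshold (strict >)


@dataclass
class PreprocessConfig:
    n_discard: int = 4
    movement_mm: float = 0.3  # point-to-point translation censoring rule
    outlier_frac: float = 0.10
    fwhm_mm: float = 6.0
    band_hz: tuple[float, float] = (0.01, 0.08)
    n_ventricle_pcs: int = 3


@dataclass
class ICDConfig:
    param_fwhm_mm: float = 4.0  # parameter-map smoothing
    tau_step: float = 0.01
    chunk_size: int = 256
    max_fail_frac: float = 0.20


@dataclass
class GLMConfig:
    voxel_p: float = 0.001
    cluster_alpha: float = 0.05
    n_perm: int = 1000
    connectivity: int = 6
    terms: tuple[str, ...] = ("te", "sex_x_te")
    parameter: str = "alpha"  # which ICD map to analyze ("alpha" or "beta")


@dataclass
class NetworkConfig:
    # published-cohort defaults; unreachable at desk-scale n, so simulated
    # runs must lower them (see methods note)
    p_thresh: float = 1e-44
    fdr_thresh: float = 3e-16
    positive_only: bool = True


@dataclass
class PipelineConfig:
    sim: SimDesign = field(default_factory=SimDesign)
    qc: QCConfig = field(default_factory=QCConfig)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    icd: ICDConfig = field(default_factory=ICDConfig)
    glm: GLMConfig = field(default_factory=GLMConfig)
    network: NetworkConfig = field(default_factory=NetworkConfig)
    seed: int = 0

    def resolved(self) -> dict:
        return dataclasses.asdict(self)

    def to_yaml(self, path) -> None:
        payload = _plainify(self.resolved())
        Path(path).write_text(yaml.safe_dump(payload, sort_keys=True))


def _plainify(obj):
    if isinstance(obj, dict):
        return {k: _plainify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plainify(v) for v in obj]
    if hasattr(obj, "item"):  # numpy scalar
        return obj.item()
    return obj


def _build(cls, data: dict, path: str):
    fields = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(data) - set(fields)
    if unknown:
        raise ValueError(f"unknown config key(s) under '{path}': {sorted(unknown)}")
    kwargs = {}
    for name, value in data.items():
        kwargs[name] = tuple(value) if isinstance(value, list) else value
    return cls(**kwargs)


_SECTION_TYPES = {
    "sim": SimDesign,
    "qc": QCConfig,
    "preprocess": PreprocessConfig,
    "icd": ICDConfig,
    "glm": GLMConfig,
    "network": NetworkConfig,
}


def config_from_dict(data: dict) -> PipelineConfig:
    data = dict(data or {})
    kwargs = {}
    unknown = set(data) - set(_SECTION_TYPES) - {"seed"}
    if unknown:
        raise ValueError(f"unknown config key(s): {sorted(unknown)}")
    for name, cls in _SECTION_TYPES.items():
        if name in data:
            kwargs[name] = _build(cls, data[name] or {}, name)
    if "seed" in data:
        kwargs["seed"] = int(data["seed"])
    return PipelineConfig(**kwargs)


def demo_config(seed: int = 0, n_subjects: int = 60, n_perm: int = 500) -> PipelineConfig:
    """Desk-scale end-to-end configuration: the default planted-effect
    cohort with network thresholds attainable at small n."""
    return PipelineConfig(
        sim=SimDesign(n_subjects=n_subjects),
        network=NetworkConfig(p_thresh=1e-6, fdr_thresh=1e-4),
        glm=GLMConfig(n_perm=n_perm),
        seed=seed,
    )


def load_config(path) -> PipelineConfig:
    data = yaml.safe_load(Path(path).read_text())
    return config_from_dict(data or {})
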