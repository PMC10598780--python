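"""Run configuration.

A single :class:`RunConfig` drives every stage — phantom simulation,
reference fitting, preprocessing, network training and evaluation read
their parameters only from here, so a (config, seed) pair pins down a
whole experiment.  The YAML round-trip is lossless and unknown keys are
rejected with the offending key path, so a typo cannot silently fall
back to a default.

Defaults encode the acquisition protocol the pipeline targets: an
8-echo multi-echo spin-echo train at 10.5-84.0 ms (step 10.5 ms), a
FLASH T1-weighted and a TSE T2-weighted scan, a 400 ms T2 scaling
constant, and 4-fold cross-validation with a 19:2:4 subject split.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

__all__ = [
    "RunConfig",
    "PhantomConfig",
    "AcquisitionConfig",
    "SequenceConfig",
    "TrainingConfig",
    "EvaluationConfig",
    "ExperimentConfig",
    "ConfigError",
    "load_config",
    "save_config",
]

#: Echo times (ms) of the default multi-echo spin-echo train.
DEFAULT_ECHO_TIMES = (10.5, 21.0, 31.5, 42.0, 52.5, 63.0, 73.5, 84.0)

#: T2 scaling constant (ms); 0-400 ms covers most pelvic tissue.
DEFAULT_T2_SCALE = 400.0


class ConfigError(ValueError):
    """Schema violation; the message carries the key path."""


@dataclass
class SequenceConfig:
    """Acquisition parameters for one pulse sequence."""

    sequence: str = "FLASH"          # FLASH | TSE | MESE
    te: float = 2.03                 # ms (ignored for MESE)
    tr: float = 250.0                # ms
    flip_angle: float = 48.0         # degrees
    echo_times: list[float] = field(default_factory=list)  # MESE only
    noise_sigma: float = 0.0         # a.u., Rician


@dataclass
class AcquisitionConfig:
    """The three acquisitions simulated for every subject.

    Defaults follow a 3 T pelvic protocol: FLASH T1w (TE 2.03 ms, TR
    250 ms, flip 48 deg), TSE T2w (TE 108 ms, TR 3000 ms, flip 140 deg)
    and an 8-echo MESE train (TR 4980 ms, flip 180 deg).
    """

    flash: SequenceConfig = field(default_factory=lambda: SequenceConfig(
        sequence="FLASH", te=2.03, tr=250.0, flip_angle=48.0))
    tse: SequenceConfig = field(default_factory=lambda: SequenceConfig(
        sequence="TSE", te=108.0, tr=3000.0, flip_angle=140.0))
    mese: SequenceConfig = field(default_factory=lambda: SequenceConfig(
        sequence="MESE", te=10.5, tr=4980.0, flip_angle=180.0,
        echo_times=list(DEFAULT_ECHO_TIMES)))
    noise_sigma: float = 1.5         # a.u., applied to all simulated images
    deform_amplitude_mm: float = 3.0  # inter-acquisition motion amplitude
    deform_smoothness: float = 12.0   # Gaussian sigma (voxels) of the field


@dataclass
class PhantomConfig:
    """Synthetic pelvic anatomy and tissue property table.

    Tissue T2 defaults (ms): muscle 40, transition zone 90, peripheral
    zone 106.8, tumor 80.4, bladder 800 — peripheral-zone and tumor
    means at the contrast level reported for prostate cancer cohorts,
    the others literature-typical.  T1 values are assumptions (patient
    T1 is rarely reported for this protocol) and freely overridable.
    """

    grid: list[int] = field(default_factory=lambda: [128, 128, 12])
    spacing_mm: list[float] = field(default_factory=lambda: [1.172, 1.172, 3.0])
    # per-tissue [PD (a.u.), T1 (ms), T2 (ms)]
    tissues: dict[str, list[float]] = field(default_factory=lambda: {
        "background": [60.0, 900.0, 40.0],
        "muscle": [70.0, 1100.0, 40.0],
        "transition_zone": [95.0, 1400.0, 90.0],
        "peripheral_zone": [100.0, 1500.0, 106.8],
        "tumor": [100.0, 1600.0, 80.4],
        "bladder": [100.0, 4000.0, 800.0],
    })
    jitter_sd: float = 0.03          # relative per-voxel property jitter
    bias_field_amplitude: float = 0.05  # relative smooth multiplicative bias
    bias_field_smoothness: float = 32.0  # Gaussian sigma (voxels)
    include_bladder: bool = True


@dataclass
class TrainingConfig:
    """Cross-validation plan and optimizer hyperparameters."""

    k_folds: int = 4
    split: list[int] = field(default_factory=lambda: [19, 2, 4])  # train:val:test
    epochs: int = 100
    batch_size: int = 8
    learning_rate: float = 1e-2
    base_width: int = 32
    optimizer: str = "adam"
    loss: str = "l1"
    exclude_extreme_from_loss: bool = True
    exclude_bladder_from_loss: bool = False
    upsample: str = "transposed"     # transposed | nearest
    early_stop_patience: int = 0     # 0 disables early stopping


@dataclass
class EvaluationConfig:
    """Metric conventions."""

    scale_t2_ms: float = DEFAULT_T2_SCALE
    extreme_threshold_ms: float = DEFAULT_T2_SCALE
    psnr_range_ms: float = DEFAULT_T2_SCALE
    mpe_floor_ms: float = 1.0
    alpha: float = 0.05


@dataclass
class ExperimentConfig:
    """Desk-scale end-to-end recovery experiment."""

    n_subjects: int = 26
    n_train: int = 20
    n_val: int = 2
    n_test: int = 4
    folds: list[int] = field(default_factory=lambda: [0])
    epochs: int = 12
    base_width: int = 8
    registration: bool = True
    as_cohort: bool = False
    as_n_progressors: int = 11
    as_n_nonprogressors: int = 31
    as_delta_mean: list[float] = field(default_factory=lambda: [-10.7, 3.4])
    as_delta_sd: list[float] = field(default_factory=lambda: [14.2, 14.5])


@dataclass
class RunConfig:
    seed: int = 0
    output_dir: str = "out"
    phantom: PhantomConfig = field(default_factory=PhantomConfig)
    acquisition: AcquisitionConfig = field(default_factory=AcquisitionConfig)
    training: TrainingConfig = field(default_factory=TrainingConfig)
    evaluation: EvaluationConfig = field(default_factory=EvaluationConfig)
    experiment: ExperimentConfig = field(default_factory=ExperimentConfig)

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    def hash(self) -> str:
        """Stable short hash of the full configuration, for log traceability."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def _build(cls, data: Any, path: str):
    """Recursively construct a dataclass, rejecting unknown keys."""
    if not dataclasses.is_dataclass(cls):
        return data
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ConfigError(f"{path or '<root>'}: expected a mapping, got {type(data).__name__}")
    fields = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(data) - set(fields)
    if unknown:
        key = sorted(unknown)[0]
        raise ConfigError(f"unknown key {(path + '.' if path else '') + key!s}")
    kwargs = {}
    for name, f in fields.items():
        if name not in data:
            continue
        sub = f.type if isinstance(f.type, type) else None
        # dataclass fields store the class object when not a string annotation
        ftype = f.type
        if isinstance(ftype, str):
            ftype = globals().get(ftype, None)
        if dataclasses.is_dataclass(ftype):
            kwargs[name] = _build(ftype, data[name], f"{path + '.' if path else ''}{name}")
        else:
            kwargs[name] = data[name]
    try:
        return cls(**kwargs)
    except TypeError as e:  # pragma: no cover - defensive
        raise ConfigError(f"{path or '<root>'}: {e}") from e


def load_config(path: str | Path | None = None) -> RunConfig:
    """Load a YAML run configuration; an empty/missing body yields all defaults."""
    data: Any = {}
    if path is not None:
        text = Path(path).read_text()
        data = yaml.safe_load(text) or {}
    return _build(RunConfig, data, "")


def save_config(cfg: RunConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg.to_dict(), sort_keys=False))
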