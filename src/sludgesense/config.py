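"""Configuration containers for the plant model, influent generator and estimators.

All rate constants are stored in per-hour units; flows are converted from
per-day at the configuration boundary (``PlantConfig.from_flow``).  Every
section maps 1:1 onto a block of the YAML run configuration::

    plant: {...}
    kinetics: {...}
    stoichiometry: {...}
    influent: {...}
    dataset: {...}
    lstm: {...}
    ffnn: {...}
    evaluation: {...}

A single global seed is fanned out to the individual stages with
:func:`derive_seed` so that stages can be rerun independently yet
reproducibly.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, asdict, fields as dc_fields
from importlib import resources
from pathlib import Path
from typing import Any, Mapping

import yaml

__all__ = [
    "PlantConfig",
    "KineticParams",
    "StoichParams",
    "InfluentProfileConfig",
    "DatasetConfig",
    "SoftSensorHyperparams",
    "FFNNConfig",
    "EvaluationConfig",
    "RunConfig",
    "derive_seed",
    "load_config",
    "default_config",
]


def derive_seed(seed: int, stage: str) -> int:
    """Derive a per-stage 31-bit seed from the global seed and a stage name."""
    digest = hashlib.sha256(f"{int(seed)}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


class _Section:
    """Mixin: dict round-trip with field validation."""

    @classmethod
    def from_dict(cls, d: Mapping[str, Any] | None):
        d = dict(d or {})
        names = {f.name for f in dc_fields(cls)}
        unknown = set(d) - names
        if unknown:
            raise ValueError(
                f"{cls.__name__}: unknown field(s) {sorted(unknown)}; "
                f"expected a subset of {sorted(names)}"
            )
        obj = cls(**d)  # type: ignore[call-arg]
        obj.validate()
        return obj

    def to_dict(self) -> dict[str, Any]:
        return asdict(self)  # type: ignore[arg-type]

    def validate(self) -> None:  # pragma: no cover - overridden
        pass


@dataclass
class PlantConfig(_Section):
    """Reactor/settler constants of the small activated-sludge plant.

    The reference plant treats ~3000 m3/day in a 2000 m3 aeration tank, so the
    dilution rate is D = Q/V ~= 0.0625 1/h.  ``r_recycle`` is the lumped
    settler recycle/retention factor multiplying the particulate states in the
    balance equations (the ``D(r-1)X`` term): values above 1 mean the settler
    returns concentrated solids, sustaining in-reactor particulates above the
    once-through level.
    """

    V: float = 2000.0              # m3 working volume
    Q_bar: float = 3000.0          # m3/day mean influent flow
    D: float = 3000.0 / 2000.0 / 24.0   # 1/h dilution rate
    kLa: float = 4.5 / 24.0        # 1/h oxygen transfer coefficient
    X5_max: float = 4.7            # mg/L effective dissolved-oxygen saturation
    r_recycle: float = 1.97        # dimensionless settler recycle factor
    eps_waste: float = 0.0         # wastage fraction (lumped into r_recycle)
    Ts: float = 120.0 / 5020.0     # h sampling period
    COD_max: float = 150.0         # mg COD/L effluent limit
    Is: float = 30.0               # mg COD/L inert soluble material
    TN_in: float = 30.0            # mg N/L total nitrogen input

    @classmethod
    def from_flow(cls, V: float, Q_per_day: float, **kw) -> "PlantConfig":
        """Build a config from volume (m3) and flow (m3/day)."""
        return cls(V=V, Q_bar=Q_per_day, D=Q_per_day / V / 24.0, **kw)

    def validate(self) -> None:
        for name in ("V", "D", "kLa", "Ts"):
            if not getattr(self, name) > 0:
                raise ValueError(f"PlantConfig.{name} must be > 0")
        if not 0.0 <= self.eps_waste <= 1.0:
            raise ValueError("PlantConfig.eps_waste must lie in [0, 1]")
        if self.Is < 0:
            raise ValueError("PlantConfig.Is must be >= 0")


# Standard ASM1 values at 20 C, converted from per-day to per-hour.  The
# shipped calibrated configuration overrides the growth/hydrolysis constants
# (see configs/default.yaml and docs/methods.md).
@dataclass
class KineticParams(_Section):
    """Kinetic constants of the reduced activated-sludge model (per hour)."""

    mu_max_H: float = 6.0 / 24.0   # 1/h max heterotrophic growth
    mu_max_A: float = 0.8 / 24.0   # 1/h max autotrophic growth
    b_H: float = 0.62 / 24.0       # 1/h heterotrophic decay
    b_A: float = 0.1 / 24.0        # 1/h autotrophic decay
    k_h: float = 3.0 / 24.0        # 1/h max specific hydrolysis rate
    eta_g: float = 0.8             # anoxic growth correction
    eta_h: float = 0.4             # anoxic hydrolysis correction
    K_S: float = 20.0              # mg COD/L
    K_OH: float = 0.2              # mg O2/L
    K_OA: float = 0.4              # mg O2/L
    K_NH: float = 1.0              # mg N/L
    K_NO: float = 0.5              # mg N/L
    K_X: float = 0.03              # g COD / g COD
    S_NH_const: float = 20.0       # mg N/L quasi-constant ammonia surrogate
    S_NO_const: float = 5.0        # mg N/L quasi-constant nitrate surrogate

    def validate(self) -> None:
        for name in ("mu_max_H", "mu_max_A", "b_H", "b_A", "k_h",
                     "K_S", "K_OH", "K_OA", "K_NH", "K_NO", "K_X",
                     "S_NH_const", "S_NO_const"):
            if not getattr(self, name) > 0:
                raise ValueError(f"KineticParams.{name} must be > 0")
        for name in ("eta_g", "eta_h"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ValueError(f"KineticParams.{name} must lie in (0, 1]")


@dataclass
class StoichParams(_Section):
    """Yield coefficients and inert fraction of decayed biomass."""

    Y_H: float = 0.67   # g COD biomass / g COD substrate
    Y_A: float = 0.24   # g COD biomass / g N
    f_p: float = 0.08   # inert fraction of decay products

    def validate(self) -> None:
        if not 0.0 < self.Y_H < 1.0:
            raise ValueError("StoichParams.Y_H must lie in (0, 1)")
        if not 0.0 < self.Y_A < 1.0:
            raise ValueError("StoichParams.Y_A must lie in (0, 1)")
        if not 0.0 <= self.f_p < 1.0:
            raise ValueError("StoichParams.f_p must lie in [0, 1)")


@dataclass
class InfluentProfileConfig(_Section):
    """Synthetic influent forcing: diurnal sinusoids plus AR(1) log-normal noise.

    Concentration channels share one diurnal phase and one autocorrelated
    "load" factor (heavier sewage raises all organic channels together); the
    dilution rate carries its own diurnal component and noise.  Relative
    amplitudes are dimensionless fractions of the base value.
    """

    base_X1_in: float = 215.0      # mg COD/L readily biodegradable substrate
    base_X2_in: float = 75.0       # mg COD/L slowly biodegradable substrate
    base_X3_in: float = 10.0       # mg COD/L influent heterotrophs
    base_X4_in: float = 0.1        # mg COD/L influent autotrophs
    base_X5_in: float = 2.0        # mg/L influent dissolved oxygen
    base_D: float = 3000.0 / 2000.0 / 24.0  # 1/h
    diurnal_amplitude: float = 0.35        # on concentration channels
    diurnal_amplitude_D: float = 0.25      # on the dilution rate
    diurnal_phase_h: float = 6.0           # h, peak-load lag after t=0
    noise_sd: float = 0.05         # relative sd of shared AR(1) load noise
    noise_sd_D: float = 0.05       # relative sd of AR(1) flow noise
    noise_sd_X5_in: float = 0.5    # relative sd of influent dissolved-oxygen noise
    noise_sd_X4_in: float = 0.0    # relative sd of influent-autotroph seeding noise
    noise_sd_X3_in: float = 0.0    # relative sd of influent-heterotroph seeding noise
    noise_corr: float = 0.995      # per-step AR(1) coefficient
    measurement_noise_sd: float = 0.01     # relative sd added to recorded states
    warmup_h: float = 240.0        # h of operation simulated before recording
    seed: int = 20231117           # generator seed

    def validate(self) -> None:
        for name in ("base_X1_in", "base_X2_in", "base_X3_in", "base_X4_in",
                     "base_X5_in", "base_D"):
            if getattr(self, name) < 0:
                raise ValueError(f"InfluentProfileConfig.{name} must be >= 0")
        for name in ("diurnal_amplitude", "diurnal_amplitude_D"):
            if not 0.0 <= getattr(self, name) < 1.0:
                raise ValueError(f"InfluentProfileConfig.{name} must lie in [0, 1)")
        if min(self.noise_sd, self.noise_sd_D, self.noise_sd_X5_in,
               self.noise_sd_X4_in, self.noise_sd_X3_in) < 0:
            raise ValueError("noise sds must be >= 0")
        if not 0.0 <= self.noise_corr < 1.0:
            raise ValueError("InfluentProfileConfig.noise_corr must lie in [0, 1)")
        if self.measurement_noise_sd < 0:
            raise ValueError("measurement_noise_sd must be >= 0")
        if self.warmup_h < 0:
            raise ValueError("warmup_h must be >= 0")


@dataclass
class DatasetConfig(_Section):
    """Windowing and chronological split settings."""

    n_samples: int = 5020      # rows in the generated dataset
    lookback: int = 7          # most recent measurements fed to the estimator
    n_trainval: int = 4500     # leading rows split 80/20 into train/validation
    train_fraction: float = 0.8

    def validate(self) -> None:
        if self.lookback < 1:
            raise ValueError("DatasetConfig.lookback must be >= 1")
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("DatasetConfig.train_fraction must lie in (0, 1)")
        if self.n_trainval >= self.n_samples:
            raise ValueError("DatasetConfig.n_trainval must leave a test block")


@dataclass
class SoftSensorHyperparams(_Section):
    """Hyperparameters of the two-layer LSTM soft sensor."""

    batch_size: int = 128
    lookback: int = 7
    epochs: int = 700
    dropout_rate: float = 0.1
    learning_rate: float = 0.001
    cells_per_layer: tuple = (128, 64)
    dense_relu_head: bool = False   # optional dense-ReLU layer before the output
    seed: int = 0

    def validate(self) -> None:
        if self.batch_size < 1 or self.epochs < 1 or self.lookback < 1:
            raise ValueError("batch_size, epochs and lookback must be >= 1")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must lie in [0, 1)")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        self.cells_per_layer = tuple(int(c) for c in self.cells_per_layer)
        if any(c < 1 for c in self.cells_per_layer):
            raise ValueError("cells_per_layer entries must be >= 1")


@dataclass
class FFNNConfig(_Section):
    """Single-hidden-layer network trained with Levenberg-Marquardt."""

    n_hidden: int = 128
    hidden_activation: str = "tanh"     # or "logistic"
    input_mode: str = "current"         # "current" measurement or full "window"
    lm_lambda0: float = 1e-2
    lm_lambda_factor: float = 10.0
    lm_lambda_min: float = 1e-12
    lm_lambda_max: float = 1e10
    max_iters: int = 60
    tol_grad: float = 1e-6
    max_train_samples: int = 0          # 0 = use all windows (memory permitting)
    seed: int = 0

    def validate(self) -> None:
        if self.n_hidden < 1:
            raise ValueError("FFNNConfig.n_hidden must be >= 1")
        if self.hidden_activation not in ("tanh", "logistic", "identity"):
            raise ValueError("hidden_activation must be 'tanh', 'logistic' "
                             "or 'identity'")
        if self.input_mode not in ("current", "window"):
            raise ValueError("input_mode must be 'current' or 'window'")
        if self.lm_lambda0 <= 0 or self.lm_lambda_factor <= 1:
            raise ValueError("invalid Levenberg-Marquardt damping settings")
        if self.tol_grad <= 0:
            raise ValueError("FFNNConfig.tol_grad must be > 0")


@dataclass
class EvaluationConfig(_Section):
    COD_max: float = 150.0
    Is: float = 30.0

    def validate(self) -> None:
        if self.COD_max <= 0:
            raise ValueError("EvaluationConfig.COD_max must be > 0")
        if self.Is < 0:
            raise ValueError("EvaluationConfig.Is must be >= 0")


@dataclass
class RunConfig:
    """Top-level configuration tying all pipeline stages together."""

    plant: PlantConfig = field(default_factory=PlantConfig)
    kinetics: KineticParams = field(default_factory=KineticParams)
    stoichiometry: StoichParams = field(default_factory=StoichParams)
    influent: InfluentProfileConfig = field(default_factory=InfluentProfileConfig)
    dataset: DatasetConfig = field(default_factory=DatasetConfig)
    lstm: SoftSensorHyperparams = field(default_factory=SoftSensorHyperparams)
    ffnn: FFNNConfig = field(default_factory=FFNNConfig)
    evaluation: EvaluationConfig = field(default_factory=EvaluationConfig)
    seed: int = 0

    _SECTIONS = {
        "plant": PlantConfig,
        "kinetics": KineticParams,
        "stoichiometry": StoichParams,
        "influent": InfluentProfileConfig,
        "dataset": DatasetConfig,
        "lstm": SoftSensorHyperparams,
        "ffnn": FFNNConfig,
        "evaluation": EvaluationConfig,
    }

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "RunConfig":
        d = dict(d or {})
        seed = int(d.pop("seed", 0))
        errors: list[str] = []
        sections: dict[str, Any] = {}
        unknown = set(d) - set(cls._SECTIONS)
        if unknown:
            errors.append(f"unknown section(s): {sorted(unknown)}")
        for name, section_cls in cls._SECTIONS.items():
            try:
                sections[name] = section_cls.from_dict(d.get(name))
            except (ValueError, TypeError) as exc:
                errors.append(str(exc))
        if errors:
            raise ValueError("invalid configuration:\n  " + "\n  ".join(errors))
        return cls(seed=seed, **sections)

    def to_dict(self) -> dict[str, Any]:
        out: dict[str, Any] = {name: getattr(self, name).to_dict()
                               for name in self._SECTIONS}
        lstm = out["lstm"]
        lstm["cells_per_layer"] = list(lstm["cells_per_layer"])
        out["seed"] = self.seed
        return out

    def with_seed(self, seed: int) -> "RunConfig":
        """Return a copy with the global seed replaced and fanned out."""
        d = self.to_dict()
        d["seed"] = int(seed)
        d["influent"]["seed"] = derive_seed(seed, "influent")
        d["lstm"]["seed"] = derive_seed(seed, "lstm")
        d["ffnn"]["seed"] = derive_seed(seed, "ffnn")
        return RunConfig.from_dict(d)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(_plain(self.to_dict()),
                                             sort_keys=False))


def _plain(obj):
    """Recursively coerce numpy scalars so YAML serialization stays portable."""
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if hasattr(obj, "item"):
        return obj.item()
    return obj


def load_config(path: str | Path) -> RunConfig:
    """Load a YAML run configuration, validating every section."""
    with open(path) as fh:
        return RunConfig.from_dict(yaml.safe_load(fh) or {})


def default_config() -> RunConfig:
    """The shipped calibrated configuration (packaged ``configs/default.yaml``)."""
    text = resources.files("sludgesense").joinpath("configs/default.yaml").read_text()
    return RunConfig.from_dict(yaml.safe_load(text))
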