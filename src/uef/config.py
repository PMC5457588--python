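"""Run configuration: validated settings for the simulate/extract/fit pipeline."""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field, fields

import yaml

from .kinematics import InertiaModel
from .synthetic import (
    DEFAULT_GROUP_PROPORTIONS,
    DEFAULT_N_SUBJECTS,
    DEFAULT_NOISE_SD_DPS,
    DEFAULT_PROFILES,
    DEFAULT_UPPERARM_SD_DPS,
    FRIED_CATEGORIES,
    GroupProfile,
)
from .trace import DEFAULT_SAMPLING_RATE_HZ


@dataclass
class RunConfig:
    """All tunables of a pipeline run.  ``validate`` reports the offending
    field by name; the serialised config (and its hash) is embedded in every
    primary output so runs are reproducible."""

    seed: int = 0
    n_subjects: int = DEFAULT_N_SUBJECTS
    group_proportions: tuple = DEFAULT_GROUP_PROPORTIONS
    deterministic_counts: bool = True
    sampling_rate: float = DEFAULT_SAMPLING_RATE_HZ
    noise_sd: float = DEFAULT_NOISE_SD_DPS
    upperarm_sd: float = DEFAULT_UPPERARM_SD_DPS
    filter_cutoff_hz: float = 3.0
    rest_window_s: float = 0.0
    min_cycle_s: float = 0.25
    range_floor_frac: float = 0.10
    min_range_dps: float = 20.0
    segment_mass_fraction: float = 0.022
    segment_length_fraction: float = 0.254
    gyration_radius_fraction: float = 0.827
    predictors: tuple = (
        "speed",
        "flexibility",
        "log_moment",
        "speed_variability",
        "speed_reduction",
        "flexion_number",
        "bmi",
    )
    k_folds: int = 10
    bmi_handling: str = "continuous"  # continuous | categorical
    age_increment_years: float = 4.0
    profiles: dict = field(default_factory=lambda: dict(DEFAULT_PROFILES))

    def validate(self) -> None:
        if self.n_subjects < 3:
            raise ValueError("n_subjects: must be >= 3")
        p = tuple(self.group_proportions)
        if len(p) != 3 or any(not 0 <= v <= 1 for v in p):
            raise ValueError("group_proportions: need three values in [0, 1]")
        if abs(sum(p) - 1.0) > 1e-8:
            raise ValueError(f"group_proportions: must sum to 1, got {sum(p):.6f}")
        if self.sampling_rate < 50:
            raise ValueError("sampling_rate: must be >= 50 Hz")
        for name in ("noise_sd", "upperarm_sd", "rest_window_s"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name}: must be >= 0")
        for name in ("filter_cutoff_hz", "min_cycle_s", "min_range_dps",
                     "age_increment_years"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name}: must be > 0")
        if not 0 <= self.range_floor_frac < 1:
            raise ValueError("range_floor_frac: must lie in [0, 1)")
        if self.k_folds < 2:
            raise ValueError("k_folds: must be >= 2")
        if self.bmi_handling not in ("continuous", "categorical"):
            raise ValueError("bmi_handling: must be 'continuous' or 'categorical'")
        if set(self.profiles) != set(FRIED_CATEGORIES):
            raise ValueError(f"profiles: need exactly the groups {FRIED_CATEGORIES}")
        self.inertia_model()  # raises on bad fractions

    def inertia_model(self) -> InertiaModel:
        return InertiaModel(
            segment_mass_fraction=self.segment_mass_fraction,
            segment_length_fraction=self.segment_length_fraction,
            gyration_radius_fraction=self.gyration_radius_fraction,
        )

    # -- serialisation -----------------------------------------------------

    def to_yaml(self) -> str:
        d = asdict(self)
        d["group_proportions"] = [float(v) for v in self.group_proportions]
        d["predictors"] = list(self.predictors)
        d["profiles"] = {k: asdict(v) if isinstance(v, GroupProfile) else dict(v)
                         for k, v in self.profiles.items()}
        return yaml.safe_dump(d, sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        d = yaml.safe_load(text) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config field(s): {sorted(unknown)}")
        if "profiles" in d:
            d["profiles"] = {k: GroupProfile(**v) for k, v in d["profiles"].items()}
        if "group_proportions" in d:
            d["group_proportions"] = tuple(d["group_proportions"])
        if "predictors" in d:
            d["predictors"] = tuple(d["predictors"])
        cfg = cls(**d)
        cfg.validate()
        return cfg

    def hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:16]
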