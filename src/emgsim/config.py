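"""Run configuration: strict, sectioned, YAML-backed.

Every default is either pinned to the model's parameter tables (tracking
thresholds, tissue conductivities, muscle population parameters, alpha =
0.5, 20 kHz sampling, 20-2000 Hz band, the -107.5 dBW noise level) or
flagged ``not-from-paper`` in the field comment — those are free modelling
choices (pool rate parameters, scenario scale controls).  Unknown keys in
a YAML document are rejected rather than ignored.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, fields, asdict

import yaml

__all__ = ["RunConfig", "load_config"]


@dataclass
class PhantomSection:
    state: str = "rest"
    mesh_h_mm: float = 2.0
    voxel_mm: float = 2.0
    snr_db: float = 0.0  # 0 disables tensor noise; 17 mirrors acquisition


@dataclass
class TractographySection:
    fa_min: float = 0.15
    angle_max_deg: float = 15.0
    step_mm: float = 0.4
    prune_voxel_mm: float | None = None  # None -> the volume's voxel size


@dataclass
class TissueSection:
    skin: float = 4.88e-4
    fat: float = 4.07e-2
    cancellous_bone: float = 7.56e-2
    cortical_bone: float = 2.00e-2
    muscle_isotropic: float = 0.28
    muscle_longitudinal: float = 0.40
    muscle_transversal: float = 0.09


@dataclass
class MuscleSection:
    n_units: int = 120
    y1: float = 21.0
    ratio: float = 84.0
    fiber_density_per_mm2: float = 350.0
    mu_density_min: float = 25.0
    mu_density_max: float = 45.0
    # not-from-paper: which units are simulated in a desk-scale run
    sim_units: list[int] = field(default_factory=lambda: [5, 20, 40, 60, 80])


@dataclass
class PoolSection:
    n_units: int = 120
    recruited_at_plateau: int = 90
    ramp_rate_pct_s: float = 5.0
    plateau_pct: float = 25.0
    duration_s: float = 25.0
    min_rate_hz: float = 8.0  # not-from-paper
    peak_rate_hz: float = 35.0  # not-from-paper
    isi_cv: float = 0.15  # not-from-paper


@dataclass
class EmgSection:
    alpha: float = 0.5
    fs_hz: float = 20000.0
    band_low_hz: float = 20.0
    band_high_hz: float = 2000.0
    noise_sigma_v: float = 10.0 ** (-107.5 / 20.0)
    duration_s: float = 12.0  # not-from-paper: desk-scale record length
    montage: str = "corner_minus_center"


@dataclass
class ScenarioSection:
    model: str = "IV"  # I..V ladder selector
    element_order: int = 1  # 2 = production quadratic, 1 = fast


@dataclass
class RunConfig:
    phantom: PhantomSection = field(default_factory=PhantomSection)
    tractography: TractographySection = field(default_factory=TractographySection)
    tissues: TissueSection = field(default_factory=TissueSection)
    muscle: MuscleSection = field(default_factory=MuscleSection)
    pool: PoolSection = field(default_factory=PoolSection)
    emg: EmgSection = field(default_factory=EmgSection)
    scenario: ScenarioSection = field(default_factory=ScenarioSection)
    seed: int = 0

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(asdict(self), sort_keys=False)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    def override(self, dotted_key: str, value) -> None:
        """Apply a ``section.key=value`` override with type coercion."""
        parts = dotted_key.split(".")
        obj = self
        for p in parts[:-1]:
            if not hasattr(obj, p):
                raise KeyError(f"unknown config section {p!r}")
            obj = getattr(obj, p)
        leaf = parts[-1]
        if not hasattr(obj, leaf):
            raise KeyError(f"unknown config key {dotted_key!r}")
        cur = getattr(obj, leaf)
        if isinstance(cur, bool):
            value = str(value).lower() in ("1", "true", "yes")
        elif isinstance(cur, int) and not isinstance(value, bool):
            value = int(value)
        elif isinstance(cur, float):
            value = float(value)
        elif isinstance(cur, list):
            value = [int(v) for v in str(value).split(",")]
        setattr(obj, leaf, value)


def _build(cls, data: dict, path: str):
    known = {f.name: f for f in fields(cls)}
    unknown = set(data) - set(known)
    if unknown:
        raise KeyError(
            f"unknown key(s) {sorted(unknown)} in config section {path!r}"
        )
    kwargs = {}
    for name, f in known.items():
        if name not in data:
            continue
        val = data[name]
        if dataclasses.is_dataclass(f.type) or (
            isinstance(val, dict) and name in _SECTIONS
        ):
            val = _build(_SECTIONS[name], val, f"{path}.{name}" if path else name)
        kwargs[name] = val
    return cls(**kwargs)


_SECTIONS = {
    "phantom": PhantomSection,
    "tractography": TractographySection,
    "tissues": TissueSection,
    "muscle": MuscleSection,
    "pool": PoolSection,
    "emg": EmgSection,
    "scenario": ScenarioSection,
}


def load_config(path) -> RunConfig:
    """Read a YAML run config, rejecting unknown keys."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return _build(RunConfig, data, "")
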