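"""Domain types for the closed-loop circulation model.

Units follow clinical 0D-modelling convention: pressures in mmHg, volumes
in mL, flows in mL/s internally (reported in L/min), resistances in
mmHg*s/mL, compliances in mL/mmHg, elastances in mmHg/mL, time in s.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

#: Canonical order of the ten varied inputs, used everywhere a cohort table,
#: a Saltelli design or a PCE basis indexes inputs by column.
INPUT_NAMES = (
    "Ea_RA", "Eb_RA", "Ea_LV", "Eb_LV",
    "R_pv", "R_ha", "R_hv", "R_DO", "R_OO", "hpx",
)

#: The six cycle-averaged clinical outputs.
OUTPUT_NAMES = ("P_pv", "PCG", "MAP", "CO", "Q_ha", "Q_pv")

PHASES = ("pre", "post")


@dataclass(frozen=True)
class ParameterVector:
    """The ten inputs varied in the sensitivity study.

    Four heart elastances (right-atrial and left-ventricular amplitude/
    baseline), five hydraulic resistances (portal vein, hepatic artery,
    hepatic vein, digestive organs, other organs) and the resected
    liver-mass fraction ``hpx``.
    """

    Ea_RA: float
    Eb_RA: float
    Ea_LV: float
    Eb_LV: float
    R_pv: float
    R_ha: float
    R_hv: float
    R_DO: float
    R_OO: float
    hpx: float

    def __post_init__(self) -> None:
        for name in INPUT_NAMES[:-1]:
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0.0:
                raise ValueError(f"{name} must be strictly positive, got {v}")
        if not (0.0 <= self.hpx < 1.0):
            raise ValueError(f"hpx must lie in [0, 1), got {self.hpx}")

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in INPUT_NAMES], dtype=float)

    @classmethod
    def from_array(cls, x: np.ndarray) -> "ParameterVector":
        x = np.asarray(x, dtype=float)
        if x.shape != (len(INPUT_NAMES),):
            raise ValueError(f"expected {len(INPUT_NAMES)} values, got shape {x.shape}")
        return cls(**dict(zip(INPUT_NAMES, x)))

    def replace(self, **kw) -> "ParameterVector":
        return dataclasses.replace(self, **kw)


def default_parameters() -> "ParameterVector":
    """Baseline subject: resting hemodynamics near MAP 90 mmHg, CO
    5 L/min, portal pressure 10 mmHg, portocaval gradient 6 mmHg, with
    portal and hepatic-arterial flows at 20 % and 5 % of CO."""
    return ParameterVector(
        Ea_RA=0.06, Eb_RA=0.07, Ea_LV=2.5, Eb_LV=0.20,
        R_pv=0.12, R_ha=19.5, R_hv=0.19, R_DO=4.8, R_OO=1.38, hpx=0.30,
    )


@dataclass(frozen=True)
class ModelConfig:
    """Fixed circulation parameters and numerical settings.

    The defaults were set once so that the baseline subject lands at
    textbook resting hemodynamics (MAP ~90 mmHg, CO ~5 L/min, portal
    pressure ~10 mmHg, portocaval gradient ~6 mmHg, portal flow ~20 % and
    hepatic arterial flow ~5 % of CO).
    """

    # timing
    period_s: float = 60.0 / 70.0          # heart rate fixed at 70 bpm
    systole_s: float = 0.30                # ventricular activation duration
    atrial_systole_s: float = 0.17         # atrial activation duration

    # chambers not varied by the study
    Ea_RV: float = 0.35                    # mmHg/mL
    Eb_RV: float = 0.018
    Ea_LA: float = 0.07
    Eb_LA: float = 0.09

    # chamber unstressed volumes (mL)
    V0_RA: float = 4.0
    V0_RV: float = 10.0
    V0_LA: float = 4.0
    V0_LV: float = 10.0

    # end-diastolic preload reserve of both ventricles: compliant
    # filling up to a knee volume, then an exponential wall,
    # P += Kd * (exp((V - V0 - Vk)/Vd) - 1)
    diastolic_stiffness_mmHg: float = 0.5
    diastolic_volume_scale_mL: float = 15.0
    diastolic_knee_mL: float = 150.0

    # vascular compliances (mL/mmHg)
    C_sa: float = 1.3
    C_pa: float = 2.5
    C_pu: float = 4.0
    C_pvn: float = 1.5
    C_liver: float = 10.0                  # whole liver, split by lobe mass
    C_vc: float = 60.0

    # vascular unstressed volumes (mL)
    V0_sa: float = 600.0
    V0_pa: float = 100.0
    V0_pu: float = 400.0
    V0_pvn: float = 60.0
    V0_liver: float = 400.0                # whole liver, split by lobe mass
    V0_vc: float = 2800.0

    # connecting resistances (mmHg*s/mL)
    R_valve: float = 0.006
    R_pul: float = 0.02
    R_pu_la: float = 0.025
    R_vc_ra: float = 0.006

    total_volume_mL: float = 5350.0
    right_lobe_fraction: float = 0.6       # right/left liver mass split
    valve_smoothing_mmHg: float = 0.01     # regularization width of the diode law

    # numerics
    steps_per_cycle: int = 1200
    periodicity_rtol: float = 1e-3
    max_cycles: int = 60

    def __post_init__(self) -> None:
        if not (0.0 < self.right_lobe_fraction < 1.0):
            raise ValueError("right_lobe_fraction must lie in (0, 1)")
        if self.total_volume_mL <= 0:
            raise ValueError("total_volume_mL must be positive")
        if self.periodicity_rtol <= 0:
            raise ValueError("periodicity_rtol must be positive")
        if self.max_cycles < 1 or self.steps_per_cycle < 16:
            raise ValueError("max_cycles >= 1 and steps_per_cycle >= 16 required")

    @property
    def left_lobe_fraction(self) -> float:
        return 1.0 - self.right_lobe_fraction

    def replace(self, **kw) -> "ModelConfig":
        return dataclasses.replace(self, **kw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def save(self, path: str | Path) -> None:
        path = Path(path)
        doc = self.to_dict()
        if path.suffix in (".yaml", ".yml"):
            path.write_text(yaml.safe_dump(doc, sort_keys=False))
        else:
            path.write_text(json.dumps(doc, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "ModelConfig":
        path = Path(path)
        text = path.read_text()
        doc = yaml.safe_load(text)
        return cls(**doc)


@dataclass(frozen=True)
class CycleOutputs:
    """Cycle-averaged clinical outputs of one converged phase.

    Flows and cardiac output are in L/min, pressures in mmHg.  ``P_vc``
    (mean caval pressure) is retained so the stored portocaval gradient
    can always be re-checked as ``P_pv - P_vc``.
    """

    P_pv: float
    PCG: float
    MAP: float
    CO: float
    Q_ha: float
    Q_pv: float
    phase: str
    P_vc: float = float("nan")

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in OUTPUT_NAMES], dtype=float)

    def as_dict(self) -> dict:
        d = {n: float(getattr(self, n)) for n in OUTPUT_NAMES}
        d["phase"] = self.phase
        d["P_vc"] = float(self.P_vc)
        return d


@dataclass
class CirculationTrace:
    """One resolved cardiac cycle at periodic steady state."""

    time_s: np.ndarray
    pressures: dict[str, np.ndarray]
    volumes: dict[str, np.ndarray]
    flows: dict[str, np.ndarray]
    phase: str
    n_cycles_run: int = 0
    state_end: np.ndarray = field(default_factory=lambda: np.empty(0))

    def total_volume(self) -> np.ndarray:
        return np.sum([v for v in self.volumes.values()], axis=0)

    def to_frame(self):
        import pandas as pd

        cols = {"time_s": self.time_s}
        for tag, group in (("P", self.pressures), ("V", self.volumes), ("Q", self.flows)):
            for k, v in group.items():
                cols[f"{tag}_{k}"] = v
        return pd.DataFrame(cols)


class ConvergenceError(RuntimeError):
    """Periodic steady state not reached within the cycle budget."""

    def __init__(self, msg: str, residual: float = float("nan"), phase: str = ""):
        super().__init__(msg)
        self.residual = residual
        self.phase = phase


class IntegrationError(RuntimeError):
    """The state became non-finite during integration."""
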