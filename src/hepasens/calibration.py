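"""Patient-specific calibration of the circulation model.

A patient is summarized by six pre-resection targets (MAP, CO, portal
pressure, portocaval gradient, and the two hepatic flows derived as
20 % / 5 % of CO).  Calibration proceeds in two stages, mirroring the
clinical pipeline:

1. *algebraic presets*: the hydraulic resistances follow directly from
   the target pressures and flows (mean pressure drop = mean flow x
   resistance holds exactly for linear resistors), and the stressed
   blood volume is adjusted by a short fixed point so the mean caval
   pressure matches the patient's P_pv - PCG;
2. *elastance optimization*: a derivative-free simplex search minimizes
   the weighted relative error of the simulated pre-resection outputs.

Two strategies are compared: the original one frees all four varied
elastances (right atrium + left ventricle); the reduced one frees only
the left-ventricular pair and constrains it to the admissible region
carved out by the physiological filter (jointly with R_OO), which both
shrinks the search space and rejects proposals known to be
non-physiological before spending a model run on them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from io import StringIO

import numpy as np
import pandas as pd
from scipy import optimize

from .circulation_model import cycle_averages, initial_state, simulate_to_periodic
from .params import ConvergenceError, CycleOutputs, IntegrationError, ModelConfig, ParameterVector
from .physiological_filter import InputSummary

#: weights reflecting clinical confidence in each measurement
DEFAULT_WEIGHTS = {"PCG": 1.0, "MAP": 1.0, "CO": 1.0,
                   "P_pv": 2.0 / 3.0, "Q_pv": 1.0 / 3.0, "Q_ha": 1.0 / 3.0}

MLS = 1000.0 / 60.0   # L/min -> mL/s


def derive_flow_targets(CO: float) -> tuple[float, float]:
    """Portal and hepatic-arterial flow targets as fixed fractions of
    cardiac output: Q_pv = 20 % CO, Q_ha = 5 % CO (all L/min)."""
    if CO < 0:
        raise ValueError("CO must be non-negative")
    return 0.20 * CO, 0.05 * CO


@dataclass(frozen=True)
class CalibrationTarget:
    """Six pre-resection targets plus per-output weights."""

    MAP: float
    CO: float
    P_pv: float
    PCG: float
    Q_pv: float | None = None
    Q_ha: float | None = None
    weights: dict = field(default_factory=lambda: dict(DEFAULT_WEIGHTS))
    label: str = ""

    def __post_init__(self):
        if self.Q_pv is None or self.Q_ha is None:
            qpv, qha = derive_flow_targets(self.CO)
            object.__setattr__(self, "Q_pv", self.Q_pv if self.Q_pv is not None else qpv)
            object.__setattr__(self, "Q_ha", self.Q_ha if self.Q_ha is not None else qha)
        if any(w <= 0 for w in self.weights.values()):
            raise ValueError("weights must be positive")

    def as_dict(self) -> dict[str, float]:
        return {"P_pv": self.P_pv, "PCG": self.PCG, "MAP": self.MAP,
                "CO": self.CO, "Q_ha": self.Q_ha, "Q_pv": self.Q_pv}


def weighted_error(target: CalibrationTarget, simulated: CycleOutputs) -> float:
    """Weighted relative L2 misfit over the six outputs:
    sqrt( sum_i w_i ((Y_i^target - Y_i^sim) / Y_i^target)^2 )."""
    tgt = target.as_dict()
    acc = 0.0
    for name, t in tgt.items():
        if t == 0.0:
            raise ValueError(f"zero target value for {name}")
        s = getattr(simulated, name)
        acc += target.weights[name] * ((t - s) / t) ** 2
    return float(np.sqrt(acc))


# the nine virtual patients spanning hemodynamic state x portal-
# hypertension risk used for the strategy comparison
TABLE_PATIENTS_CSV = """\
patient,MAP,CO,P_pv,PCG
Baseline: low risk,76,4.65,10,4
Hypodynamics: low risk,60,3,10,4
Hyperdynamics: low risk,100,7,10,4
Baseline: high risk,76,4.65,18,14
Hypodynamics: high risk,60,3,18,14
Hyperdynamics: high risk,100,7,18,14
Baseline: intermediate risk,76,4.65,15,10
Hypodynamics: intermediate risk,60,3,15,10
Hyperdynamics: intermediate risk,100,7,15,10
"""


def reference_patients() -> list[CalibrationTarget]:
    """The nine virtual patients (flows derived from CO)."""
    df = pd.read_csv(StringIO(TABLE_PATIENTS_CSV))
    return [CalibrationTarget(MAP=r.MAP, CO=r.CO, P_pv=r.P_pv, PCG=r.PCG,
                              label=r.patient)
            for r in df.itertuples()]


def load_patients(path) -> list[CalibrationTarget]:
    df = pd.read_csv(path)
    return [CalibrationTarget(MAP=r.MAP, CO=r.CO, P_pv=r.P_pv, PCG=r.PCG,
                              label=str(r.patient))
            for r in df.itertuples()]


@dataclass
class CalibrationResult:
    params: ParameterVector
    config: ModelConfig
    err: float
    n_model_evals: int
    strategy: str
    converged: bool
    label: str = ""
    outputs: CycleOutputs | None = None

    def __post_init__(self):
        if self.err < 0 or self.n_model_evals < 1:
            raise ValueError("invalid calibration result")


def preset_parameters(target: CalibrationTarget, base: ParameterVector | None = None,
                      ) -> ParameterVector:
    """Resistances from the target pressures and flows.

    The sinusoidal (lobar) pressure is placed midway between portal and
    caval pressure, splitting the portocaval gradient between the portal
    and hepatic-venous resistances.
    """
    base = base or _default_base()
    co = target.CO * MLS
    qpv = target.Q_pv * MLS
    qha = target.Q_ha * MLS
    qoo = co - qpv - qha
    p_vc = target.P_pv - target.PCG
    p_liv = p_vc + 0.5 * target.PCG
    return base.replace(
        R_OO=(target.MAP - p_vc) / qoo,
        R_DO=(target.MAP - target.P_pv) / qpv,
        R_pv=(target.P_pv - p_liv) / qpv,
        R_hv=(p_liv - p_vc) / (qpv + qha),
        R_ha=(target.MAP - p_liv) / qha,
    )


def _default_base() -> ParameterVector:
    from .params import default_parameters

    return default_parameters()


class _BudgetExhausted(Exception):
    pass


class _Objective:
    """Counts model evaluations, keeps the best point, applies the
    admissible-region barrier before spending a simulation.

    Every evaluation re-anchors the mean caval pressure to the patient's
    P_pv - PCG by a warm-started fixed point on the stressed volume (the
    gain is the venous-side compliance), so the simplex search only has
    to resolve the elastances.
    """

    _PVC_TOL_MMHG = 0.02

    def __init__(self, target, base_params, config, free_names,
                 admissible: InputSummary | None, budget: int):
        self.target = target
        self.base = base_params
        self.config = config
        self.free = free_names
        self.admissible = admissible
        self.budget = budget
        self.n_evals = 0
        self.best = (np.inf, None, None, config)
        self.y0 = initial_state(config)
        self._gain = config.C_vc + config.C_pu + config.C_liver + config.C_pvn
        self._p_vc_target = target.P_pv - target.PCG

    def _params(self, x) -> ParameterVector:
        return self.base.replace(**{n: float(v) for n, v in zip(self.free, np.exp(x))})

    def _barrier(self, p: ParameterVector) -> float | None:
        if self.admissible is None:
            return None
        pen = 0.0
        for (a, b), grid in self.admissible.pairs.items():
            va, vb = getattr(p, a), getattr(p, b)
            if not bool(grid.admissible(va, vb)[0]):
                # distance to the grid box, normalized per axis
                ca = 0.5 * (grid.x_edges[0] + grid.x_edges[-1])
                cb = 0.5 * (grid.y_edges[0] + grid.y_edges[-1])
                sa = grid.x_edges[-1] - grid.x_edges[0]
                sb = grid.y_edges[-1] - grid.y_edges[0]
                pen += abs(va - ca) / sa + abs(vb - cb) / sb
        return 10.0 + pen if pen > 0 else None

    def simulate(self, p: ParameterVector) -> CycleOutputs:
        if self.n_evals >= self.budget:
            raise _BudgetExhausted
        self.n_evals += 1
        trace = simulate_to_periodic(p, self.config, phase="pre", y0=self.y0)
        self.y0 = trace.state_end
        return cycle_averages(trace)

    def __call__(self, x) -> float:
        try:
            p = self._params(x)
        except ValueError:
            return 1e4
        pen = self._barrier(p)
        if pen is not None:
            return pen
        try:
            out = self.simulate(p)
            # anchor the caval pressure; the volume->pressure gain is
            # learned by secant updates across evaluations
            for _ in range(5):
                dp = self._p_vc_target - out.P_vc
                if abs(dp) < self._PVC_TOL_MMHG:
                    break
                dv = self._gain * dp
                self.config = self.config.replace(
                    total_volume_mL=self.config.total_volume_mL + dv)
                y0 = self.y0.copy()
                y0[10] += dv          # volume change enters via the vena cava
                self.y0 = y0
                prev_pvc = out.P_vc
                out = self.simulate(p)
                if abs(out.P_vc - prev_pvc) > 1e-6:
                    g = dv / (out.P_vc - prev_pvc)
                    if 10.0 < g < 1000.0:
                        self._gain = g
        except (ConvergenceError, IntegrationError):
            return 1e4
        err = weighted_error(self.target, out)
        if err < self.best[0]:
            self.best = (err, p, out, self.config)
        return err


STRATEGY_FREE = {
    "original": ("Ea_RA", "Eb_RA", "Ea_LV", "Eb_LV"),
    "reduced": ("Ea_LV", "Eb_LV"),
}


def calibrate(target: CalibrationTarget, strategy: str = "reduced",
              config: ModelConfig | None = None,
              admissible: InputSummary | None = None,
              budget: int = 300) -> CalibrationResult:
    """Calibrate the model to one patient.

    ``strategy`` is ``"original"`` (four free elastances) or
    ``"reduced"`` (left-ventricular pair only, constrained to the
    filtered admissible region when one is supplied).  The optimizer is
    a Nelder-Mead simplex in log-parameter space under a shared
    model-evaluation budget; if the budget runs out the best point so
    far is returned with ``converged=False``.
    """
    if strategy not in STRATEGY_FREE:
        raise ValueError(f"unknown strategy {strategy!r}")
    config = config or ModelConfig()
    free = STRATEGY_FREE[strategy]
    params = preset_parameters(target)

    obj = _Objective(target, params, config, free,
                     admissible if strategy == "reduced" else None, budget)
    x0 = np.log([getattr(params, n) for n in free])
    converged = True
    try:
        # coarse log-grid over the LV pair to seed the simplex (the LV
        # elastances dominate MAP and CO)
        i_ea, i_eb = free.index("Ea_LV"), free.index("Eb_LV")
        best_x0, best_f = x0, np.inf
        for ma in (-0.6, 0.0, 0.6):
            for mb in (-0.6, 0.0, 0.6):
                x = x0.copy()
                x[i_ea] += ma
                x[i_eb] += mb
                f = obj(x)
                if f < best_f:
                    best_x0, best_f = x, f
        res = optimize.minimize(
            obj, best_x0, method="Nelder-Mead",
            options={"maxfev": 10 * budget, "xatol": 2e-3, "fatol": 1e-4,
                     "initial_simplex": _init_simplex(best_x0, 0.25)})
        converged = bool(res.success)
    except _BudgetExhausted:
        converged = False

    err, best_p, best_out, best_cfg = obj.best
    if best_p is None:
        raise RuntimeError(f"calibration produced no valid evaluation for {target.label!r}")
    return CalibrationResult(params=best_p, config=best_cfg, err=err,
                             n_model_evals=obj.n_evals, strategy=strategy,
                             converged=converged, label=target.label,
                             outputs=best_out)


def _init_simplex(x0: np.ndarray, step: float) -> np.ndarray:
    simplex = np.tile(x0, (len(x0) + 1, 1))
    for i in range(len(x0)):
        simplex[i + 1, i] += step
    return simplex


def compare_strategies(targets: list[CalibrationTarget],
                       config: ModelConfig | None = None,
                       admissible: InputSummary | None = None,
                       budget: int = 300) -> pd.DataFrame:
    """Run both strategies on every patient under matched budgets.

    Returns one row per (patient, strategy) with the weighted error and
    the model-evaluation count; aggregate rows carry the per-strategy
    means and the relative evaluation-count reduction of the reduced
    strategy.
    """
    rows = []
    for t in targets:
        for strategy in ("original", "reduced"):
            try:
                r = calibrate(t, strategy, config, admissible, budget)
                rows.append({"patient": t.label, "strategy": strategy,
                             "err": r.err, "n_evals": r.n_model_evals,
                             "converged": r.converged, "failed": False})
            except (RuntimeError, ConvergenceError, IntegrationError) as exc:
                rows.append({"patient": t.label, "strategy": strategy,
                             "err": np.nan, "n_evals": 0,
                             "converged": False, "failed": True,
                             "error": str(exc)})
    df = pd.DataFrame(rows)
    agg = df[~df["failed"]].groupby("strategy").agg(
        mean_err=("err", "mean"), mean_evals=("n_evals", "mean"))
    if {"original", "reduced"} <= set(agg.index):
        reduction = 1.0 - agg.loc["reduced", "mean_evals"] / agg.loc["original", "mean_evals"]
    else:
        reduction = np.nan
    df.attrs["summary"] = {
        "mean_err": {s: float(agg.loc[s, "mean_err"]) for s in agg.index},
        "mean_evals": {s: float(agg.loc[s, "mean_evals"]) for s in agg.index},
        "eval_reduction_reduced_vs_original": float(reduction),
    }
    return df
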