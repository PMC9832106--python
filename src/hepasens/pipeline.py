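"""End-to-end orchestration: cohort -> simulate -> GSA -> filter ->
PCE -> virtual population -> calibration comparison.

Every stage draws its randomness from a stream derived deterministically
from one master seed, and every artifact is a CSV or JSON file referenced
by the run manifest, so a run is reconstructible from (config, seed).
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import qmc

from . import __version__
from . import calibration as cal
from . import cohort_distributions as cd
from . import pce_surrogate as ps
from . import physiological_filter as pf
from . import sobol_saltelli as ss
from .circulation_model import evaluate_many
from .params import INPUT_NAMES, OUTPUT_NAMES, ModelConfig

log = logging.getLogger("hepasens.pipeline")

#: joint output naming used for every 12-column (output x phase) table
JOINT_OUTPUT_NAMES = tuple(f"{o}_{ph}" for ph in ("pre", "post") for o in OUTPUT_NAMES)


def spawn_seeds(master_seed: int, n: int) -> list[int]:
    """Deterministic per-stage seed streams (kept below 2**31)."""
    ss_ = np.random.SeedSequence(master_seed)
    return [int(s.generate_state(1)[0] % (2 ** 31)) for s in ss_.spawn(n)]


@dataclass
class PipelineConfig:
    N: int = 256                      # Saltelli base sample size
    N_test: int = 256                 # held-out evaluations for Q2
    q: int = 4                        # PCE total degree
    cohort_size: int = 47
    seed: int = 0
    calibration_budget: int = 300
    model: ModelConfig = field(default_factory=ModelConfig)
    bounds: pf.FilterBounds = field(default_factory=pf.FilterBounds.default)
    run_calibration: bool = True
    use_kde_marginals: bool = True    # KDE of the cohort vs the parametric families


@dataclass
class RunManifest:
    config_hash: str
    seeds: dict[str, int]
    counts: dict[str, int]
    artifacts: dict[str, str]
    versions: dict[str, str]
    timestamps: dict[str, float]

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=2))


def _outputs_frame(pre: np.ndarray, post: np.ndarray) -> pd.DataFrame:
    df = pd.DataFrame(np.hstack([pre[:, :6], post[:, :6]]),
                      columns=list(JOINT_OUTPUT_NAMES))
    df["P_vc_pre"] = pre[:, 6]
    df["P_vc_post"] = post[:, 6]
    return df


def run_full_pipeline(config: PipelineConfig, out_dir) -> RunManifest:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = dict(zip(
        ("cohort", "design", "test", "split"), spawn_seeds(config.seed, 4)))
    stamps = {"start": time.time()}
    artifacts: dict[str, str] = {}
    counts: dict[str, int] = {}

    # 1. synthetic cohort and its KDE-regularized marginals
    spec = cd.default_cohort_spec(size=config.cohort_size, seed=seeds["cohort"])
    cohort = cd.generate_synthetic_cohort(spec, out / "cohort.csv")
    artifacts["cohort"] = "cohort.csv"
    if config.use_kde_marginals:
        marginals = cd.marginals_from_cohort(cohort)
    else:
        marginals = dict(spec.marginals)
    log.info("cohort of %d subjects generated", config.cohort_size)

    # 2. Saltelli design and full-model evaluations
    design = ss.build_saltelli_design(marginals, config.N, seed=seeds["design"],
                                      input_names=INPUT_NAMES)
    counts["N"] = config.N
    counts["N_s"] = design.n_evaluations
    pre, post, ok = evaluate_many(design.rows, config.model)
    counts["n_failed"] = int((~ok).sum())
    log.info("design evaluated: %d rows, %d failed", design.n_evaluations,
             counts["n_failed"])
    inputs_df = pd.DataFrame(design.rows, columns=list(INPUT_NAMES))
    inputs_df.insert(0, "block", design.block_labels())
    outputs_df = _outputs_frame(pre, post)
    inputs_df.to_csv(out / "design_inputs.csv", index=False, float_format="%.10g")
    outputs_df.to_csv(out / "design_outputs.csv", index=False, float_format="%.10g")
    artifacts["design_inputs"] = "design_inputs.csv"
    artifacts["design_outputs"] = "design_outputs.csv"

    # 3. unfiltered pick-freeze Sobol indices (full model)
    Y = np.hstack([pre[:, :6], post[:, :6]])
    if ok.all():
        est_full = ss.estimate_sobol(design, Y, JOINT_OUTPUT_NAMES)
        est_full.save(out / "sobol_full_model.json")
        artifacts["sobol_full_model"] = "sobol_full_model.json"
        json.dump(ss.classify_sensitivity(est_full),
                  open(out / "sensitivity_classes_full.json", "w"), indent=2)
        artifacts["sensitivity_classes_full"] = "sensitivity_classes_full.json"
    else:
        log.warning("failed rows break the pick-freeze pairing; "
                    "skipping full-model Sobol stage")

    # 4. physiological filter -> virtual population
    mask, pop = pf.apply_filter(
        inputs_df[list(INPUT_NAMES)], outputs_df[[*JOINT_OUTPUT_NAMES[:6]]].rename(
            columns=lambda c: c[:-4]),
        outputs_df[[*JOINT_OUTPUT_NAMES[6:]]].rename(columns=lambda c: c[:-5]),
        config.bounds, seed=config.seed, model_version=__version__)
    counts["N_s_star"] = pop.n_retained
    pf.assemble_population(pop, out / "virtual_population.csv")
    artifacts["virtual_population"] = "virtual_population.csv"
    log.info("filter retained %d / %d couples (%.1f%%)", pop.n_retained,
             len(inputs_df), 100 * pop.retention_fraction)

    # 5. PCE surrogate on the filtered couples, validated on a disjoint
    # filtered test set
    Xf = pop.inputs.to_numpy(dtype=float)
    Yf = np.hstack([pop.pre[list(OUTPUT_NAMES)].to_numpy(),
                    pop.post[list(OUTPUT_NAMES)].to_numpy()])
    # smoke-sized runs cannot support the full degree: back off until the
    # least-squares problem is overdetermined by at least 2x
    from math import comb

    q_eff = config.q
    while q_eff > 1 and (2 * comb(len(INPUT_NAMES) + q_eff, q_eff) > len(Xf)
                         or 50 * q_eff > len(Xf)):
        q_eff -= 1
    if q_eff != config.q:
        log.warning("only %d retained couples: PCE degree reduced %d -> %d",
                    len(Xf), config.q, q_eff)
    counts["pce_degree"] = q_eff
    mset, bases = ps.build_basis(
        {n: Xf[:, j] for j, n in enumerate(INPUT_NAMES)}, q=q_eff)
    surrogate = ps.fit_pce(Xf, Yf, mset, bases, input_names=INPUT_NAMES,
                           output_names=JOINT_OUTPUT_NAMES)
    surrogate.save(out / "pce_surrogate.json")
    artifacts["pce_surrogate"] = "pce_surrogate.json"

    import warnings as _w

    with _w.catch_warnings():
        _w.filterwarnings("ignore", message=".*balance properties.*")
        eng = qmc.Sobol(len(INPUT_NAMES), scramble=True,
                        rng=np.random.default_rng(seeds["test"]))
        Ut = eng.random(config.N_test)
    Xt = np.column_stack([np.asarray(marginals[n].ppf(Ut[:, j]))
                          for j, n in enumerate(INPUT_NAMES)])
    pre_t, post_t, ok_t = evaluate_many(Xt, config.model)
    test_pre = pd.DataFrame(pre_t[:, :6], columns=list(OUTPUT_NAMES))
    mask_t = pf.retention_mask(test_pre, config.bounds) & ok_t
    counts["N_test"] = config.N_test
    counts["N_test_star"] = int(mask_t.sum())
    q2 = ps.q2_score(surrogate, Xt[mask_t],
                     np.hstack([pre_t[mask_t][:, :6], post_t[mask_t][:, :6]]))
    json.dump({"q2": q2.q2, "n_test": q2.n_test},
              open(out / "q2_report.json", "w"), indent=2)
    artifacts["q2_report"] = "q2_report.json"
    log.info("surrogate Q2 in [%.4f, %.4f] over %d outputs",
             min(q2.q2.values()), max(q2.q2.values()), len(q2.q2))

    est_pce = ps.sobol_from_pce(surrogate)
    est_pce.save(out / "sobol_pce_filtered.json")
    artifacts["sobol_pce_filtered"] = "sobol_pce_filtered.json"
    json.dump(ss.classify_sensitivity(est_pce),
              open(out / "sensitivity_classes_pce.json", "w"), indent=2)
    artifacts["sensitivity_classes_pce"] = "sensitivity_classes_pce.json"

    # 6. admissible input region for the reduced calibration (excluded
    # regions need the discarded couples too)
    rejected = inputs_df.loc[~mask, list(INPUT_NAMES)]
    summary = pf.filtered_input_summary(pop, rejected_inputs=rejected)
    json.dump(summary.to_dict(), open(out / "input_summary.json", "w"), indent=2)
    artifacts["input_summary"] = "input_summary.json"

    # 7. calibration strategy comparison on the reference patients
    if config.run_calibration:
        report = cal.compare_strategies(cal.reference_patients(),
                                        config.model, summary,
                                        budget=config.calibration_budget)
        report.to_csv(out / "calibration_report.csv", index=False)
        json.dump(report.attrs["summary"],
                  open(out / "calibration_summary.json", "w"), indent=2)
        artifacts["calibration_report"] = "calibration_report.csv"
        artifacts["calibration_summary"] = "calibration_summary.json"
        counts["calibration_evals"] = int(report["n_evals"].sum())

    stamps["end"] = time.time()
    cfg_doc = {
        "N": config.N, "N_test": config.N_test, "q": config.q,
        "cohort_size": config.cohort_size, "seed": config.seed,
        "calibration_budget": config.calibration_budget,
        "model": config.model.to_dict(),
        "bounds": config.bounds.to_dict(),
        "use_kde_marginals": config.use_kde_marginals,
    }
    (out / "config.json").write_text(json.dumps(cfg_doc, indent=2))
    artifacts["config"] = "config.json"
    manifest = RunManifest(
        config_hash=hashlib.blake2b(
            json.dumps(cfg_doc, sort_keys=True).encode(), digest_size=8).hexdigest(),
        seeds={"master": config.seed, **seeds},
        counts=counts, artifacts=artifacts,
        versions={"hepasens": __version__},
        timestamps=stamps)
    manifest.save(out / "manifest.json")
    return manifest


def generate_fixtures(out_dir, seed: int = 0) -> dict[str, str]:
    """Write the small plain-text fixtures used by tests and examples:
    the reference patient table, the default cohort spec, the filter
    bounds, and two analytic benchmark datasets (additive and Ishigami,
    with uniform inputs)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts = {}

    (out / "patients.csv").write_text(cal.TABLE_PATIENTS_CSV)
    artifacts["patients"] = "patients.csv"

    cd.default_cohort_spec(seed=seed).save(out / "cohort_spec.json")
    artifacts["cohort_spec"] = "cohort_spec.json"

    pf.FilterBounds.default().save(out / "filter_bounds.json")
    artifacts["filter_bounds"] = "filter_bounds.json"

    rng = np.random.default_rng(seed)
    X = rng.uniform(0.0, 1.0, size=(512, 2))
    df = pd.DataFrame(X, columns=["x1", "x2"])
    df["y"] = X[:, 0] + 2.0 * X[:, 1]
    df.to_csv(out / "additive.csv", index=False, float_format="%.10g")
    artifacts["additive"] = "additive.csv"

    Xi = rng.uniform(-np.pi, np.pi, size=(512, 3))
    dfi = pd.DataFrame(Xi, columns=["x1", "x2", "x3"])
    dfi["y"] = (np.sin(Xi[:, 0]) + 7.0 * np.sin(Xi[:, 1]) ** 2
                + 0.1 * Xi[:, 2] ** 4 * np.sin(Xi[:, 0]))
    dfi.to_csv(out / "ishigami.csv", index=False, float_format="%.10g")
    artifacts["ishigami"] = "ishigami.csv"

    (out / "fixtures.json").write_text(json.dumps(
        {"seed": seed, "artifacts": artifacts}, indent=2))
    return artifacts
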