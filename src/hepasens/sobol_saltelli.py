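"""Variance-based global sensitivity analysis via Saltelli designs.

First- and total-order Sobol indices are estimated with the pick-freeze
scheme: a scrambled Sobol' low-discrepancy sequence supplies two base
matrices A and B of N points each, plus the d hybrid matrices AB_j (A
with column j taken from B), for a total of (d+2)*N model evaluations.
The first-order index uses the Saltelli-2010 correlation form and the
total-order index the Jansen form; both are the modern defaults of this
estimator family.  Small negative estimates are Monte-Carlo noise and
are reported as-is, never clipped.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.stats import qmc


@dataclass(frozen=True)
class SaltelliDesign:
    """Pick-freeze evaluation plan for d inputs at base sample size N.

    ``rows`` stacks A (N rows), B (N rows) and AB_1..AB_d (N rows each)
    in that fixed order: (d+2)*N evaluation points in input units.
    """

    N: int
    d: int
    rows: np.ndarray
    input_names: tuple[str, ...]
    seed: int

    @property
    def n_evaluations(self) -> int:
        return (self.d + 2) * self.N

    @property
    def A(self) -> np.ndarray:
        return self.rows[: self.N]

    @property
    def B(self) -> np.ndarray:
        return self.rows[self.N: 2 * self.N]

    def AB(self, j: int) -> np.ndarray:
        return self.rows[(2 + j) * self.N: (3 + j) * self.N]

    def block_labels(self) -> list[str]:
        labels = ["A"] * self.N + ["B"] * self.N
        for j in range(self.d):
            labels += [f"AB_{self.input_names[j]}"] * self.N
        return labels


@dataclass(frozen=True)
class SobolEstimate:
    """First/total Sobol indices per (output, input)."""

    S: np.ndarray              # (n_outputs, d)
    ST: np.ndarray             # (n_outputs, d)
    output_names: tuple[str, ...]
    input_names: tuple[str, ...]
    N: int
    seed: int = 0

    def __post_init__(self):
        if not (np.all(np.isfinite(self.S)) and np.all(np.isfinite(self.ST))):
            raise ValueError("Sobol estimates must be finite")

    def to_dict(self) -> dict:
        return {
            "N": self.N, "seed": self.seed,
            "first": {o: dict(zip(self.input_names, map(float, self.S[i])))
                      for i, o in enumerate(self.output_names)},
            "total": {o: dict(zip(self.input_names, map(float, self.ST[i])))
                      for i, o in enumerate(self.output_names)},
        }

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


@dataclass(frozen=True)
class ConvergenceReport:
    """Per-output max-over-inputs |difference| between two estimates."""

    err_first: dict[str, float]
    err_total: dict[str, float]
    N1: int
    N2: int


def build_saltelli_design(marginals: dict, N: int, seed: int = 0,
                          input_names: tuple[str, ...] | None = None,
                          ) -> SaltelliDesign:
    """Build the (d+2)*N-point pick-freeze design.

    ``marginals`` maps input name -> object with a ``ppf`` method (a
    fitted KDE or a truncated family); base points come from a scrambled
    Sobol' sequence in [0,1]^(2d) and are mapped through the marginal
    inverse cdfs, so every column lies inside its marginal support.
    """
    if N < 2:
        raise ValueError("N must be >= 2")
    names = tuple(input_names) if input_names else tuple(marginals.keys())
    d = len(names)
    if d < 1:
        raise ValueError("at least one input required")
    import warnings

    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message=".*balance properties.*")
        eng = qmc.Sobol(2 * d, scramble=True, rng=np.random.default_rng(seed))
        U = eng.random(N)
    UA, UB = U[:, :d], U[:, d:]
    A = np.column_stack([np.asarray(marginals[n].ppf(UA[:, j])) for j, n in enumerate(names)])
    B = np.column_stack([np.asarray(marginals[n].ppf(UB[:, j])) for j, n in enumerate(names)])
    blocks = [A, B]
    for j in range(d):
        ab = A.copy()
        ab[:, j] = B[:, j]
        blocks.append(ab)
    return SaltelliDesign(N=N, d=d, rows=np.vstack(blocks), input_names=names, seed=seed)


def estimate_sobol(design: SaltelliDesign, outputs: np.ndarray,
                   output_names: tuple[str, ...] | None = None) -> SobolEstimate:
    """Pick-freeze estimates of first and total Sobol indices.

    ``outputs`` has one row per design row ((d+2)*N in design order) and
    one column per output.  Rows must all be present and finite: a
    filtered or failed subset would break the pick-freeze pairing (the
    filtered analysis goes through the PCE surrogate instead).
    """
    Y = np.atleast_2d(np.asarray(outputs, dtype=float))
    if Y.shape[0] == design.n_evaluations and Y.ndim == 2:
        pass
    elif Y.shape == (1, design.n_evaluations):
        Y = Y.T
    else:
        raise ValueError(
            f"outputs must have {design.n_evaluations} rows, got {Y.shape}")
    if not np.all(np.isfinite(Y)):
        raise ValueError("all design rows must have finite outputs")
    N, d, m = design.N, design.d, Y.shape[1]
    names = tuple(output_names) if output_names else tuple(f"y{i}" for i in range(m))
    fA = Y[:N]
    fB = Y[N: 2 * N]
    var = np.var(np.vstack([fA, fB]), axis=0, ddof=0)
    if np.any(var <= 0):
        bad = [names[i] for i in range(m) if var[i] <= 0]
        raise ValueError(f"constant output(s), zero variance: {bad}")
    S = np.empty((m, d))
    ST = np.empty((m, d))
    for j in range(d):
        fAB = Y[(2 + j) * N: (3 + j) * N]
        S[:, j] = np.mean(fB * (fAB - fA), axis=0) / var
        ST[:, j] = 0.5 * np.mean((fA - fAB) ** 2, axis=0) / var
    return SobolEstimate(S=S, ST=ST, output_names=names,
                         input_names=design.input_names, N=N, seed=design.seed)


def convergence_error(est1: SobolEstimate, est2: SobolEstimate) -> ConvergenceReport:
    """Max-over-inputs absolute index difference per output, first and
    total separately; symmetric in its arguments."""
    if est1.input_names != est2.input_names or est1.output_names != est2.output_names:
        raise ValueError("estimates must share input and output sets")
    ef = {o: float(np.max(np.abs(est1.S[i] - est2.S[i])))
          for i, o in enumerate(est1.output_names)}
    et = {o: float(np.max(np.abs(est1.ST[i] - est2.ST[i])))
          for i, o in enumerate(est1.output_names)}
    return ConvergenceReport(err_first=ef, err_total=et, N1=est1.N, N2=est2.N)


@dataclass(frozen=True)
class IndexCI:
    mean: np.ndarray
    lo: np.ndarray
    hi: np.ndarray
    level: float
    n_repeats: int


def confidence_intervals(estimates: list[SobolEstimate], level: float = 0.95,
                         which: str = "first") -> IndexCI:
    """Percentile confidence intervals across repeated estimates with
    distinct seeds (all at the same N)."""
    if len(estimates) < 2:
        raise ValueError("at least 2 repeated estimates required")
    Ns = {e.N for e in estimates}
    if len(Ns) != 1:
        raise ValueError(f"all repeats must share the same N, got {sorted(Ns)}")
    arr = np.stack([e.S if which == "first" else e.ST for e in estimates])
    alpha = 100.0 * (1.0 - level) / 2.0
    return IndexCI(
        mean=arr.mean(axis=0),
        lo=np.percentile(arr, alpha, axis=0),
        hi=np.percentile(arr, 100.0 - alpha, axis=0),
        level=level, n_repeats=len(estimates),
    )


#: classification thresholds operationalizing "sensitive S >> 0.1",
#: "fairly sensitive S ~ S_tot ~ 0.1" and "insensitive S_tot ~ 0"
CLASS_THRESHOLDS = {
    "sensitive_S": 0.2,
    "fair_S": 0.05,
    "fair_gap": 0.05,
    "insensitive_ST": 0.05,
}


def classify_sensitivity(est: SobolEstimate,
                         thresholds: dict | None = None) -> dict[str, dict[str, str]]:
    """Label every (output, input) pair as sensitive / fairly sensitive /
    insensitive / intermediate.  Raw (possibly slightly negative) index
    values are used directly."""
    th = dict(CLASS_THRESHOLDS)
    if thresholds:
        th.update(thresholds)
    table: dict[str, dict[str, str]] = {}
    for i, o in enumerate(est.output_names):
        row = {}
        for j, n in enumerate(est.input_names):
            s, st = est.S[i, j], est.ST[i, j]
            if s >= th["sensitive_S"]:
                lab = "sensitive"
            elif st < th["insensitive_ST"]:
                lab = "insensitive"
            elif th["fair_S"] <= s < th["sensitive_S"] and abs(st - s) < th["fair_gap"]:
                lab = "fairly sensitive"
            else:
                lab = "intermediate"
            row[n] = lab
        table[o] = row
    return table
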