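"""Polynomial chaos surrogate with data-driven orthonormal bases.

Each input gets a family of univariate polynomials orthonormal under the
*empirical* measure of its (possibly filtered) training sample, built by
the discrete Stieltjes three-term recurrence — numerically stabler than
Gram-Schmidt on the monomials, and applicable to arbitrary sample
measures, which is exactly what a physiologically filtered sample is.
Multivariate basis functions are tensor products restricted to total
degree <= q; coefficients come from least squares.  Because the basis is
orthonormal, output variances decompose over coefficients (Parseval) and
first/total Sobol indices follow analytically from sums of squared
coefficients — no further model evaluations required.

The filtered sample is not a product measure (the filter couples the
inputs), yet the basis is built per marginal and tensorized; the induced
approximation is a property of the method, not of this implementation.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from math import comb
from pathlib import Path

import numpy as np

from .sobol_saltelli import SobolEstimate

GRAM_TOL = 5e-2
_COND_LIMIT = 1e10
_RIDGE = 1e-8


@dataclass(frozen=True)
class OrthonormalBasis1D:
    """Three-term recurrence for polynomials orthonormal w.r.t. an
    empirical sample measure.

    With p_{-1} = 0 and p_0 = 1, the orthonormal family satisfies
    b[k+1] p_{k+1}(x) = (x - a[k]) p_k(x) - b[k] p_{k-1}(x).
    """

    name: str
    q: int
    a: np.ndarray          # length q
    b: np.ndarray          # length q+1, b[0] = 1
    n_samples: int

    def evaluate(self, x) -> np.ndarray:
        """Evaluate degrees 0..q at ``x``; returns shape (len(x), q+1)."""
        x = np.atleast_1d(np.asarray(x, dtype=float))
        out = np.empty((len(x), self.q + 1))
        out[:, 0] = 1.0
        if self.q >= 1:
            out[:, 1] = (x - self.a[0]) / self.b[1]
        for k in range(1, self.q):
            out[:, k + 1] = ((x - self.a[k]) * out[:, k]
                             - self.b[k] * out[:, k - 1]) / self.b[k + 1]
        return out

    def gram_deviation(self, x) -> float:
        """Max |Gram - I| entry of the empirical Gram matrix on ``x``."""
        P = self.evaluate(x)
        G = P.T @ P / len(x)
        return float(np.max(np.abs(G - np.eye(self.q + 1))))


def stieltjes_recurrence(samples_1d, q: int, name: str = "",
                         gram_tol: float = GRAM_TOL,
                         max_passes: int = 3) -> OrthonormalBasis1D:
    """Discrete Stieltjes construction of the orthonormal recurrence.

    Moments are taken against the empirical measure of the samples; each
    new polynomial is re-orthogonalized against its predecessors before
    normalization (one extra sweep per pass) until the recurrence-
    generated family has Gram deviation below ``gram_tol``.
    """
    x = np.asarray(samples_1d, dtype=float).ravel()
    if q < 1:
        raise ValueError("q must be >= 1")
    if len(x) < 50 * q:
        raise ValueError(f"need at least {50 * q} samples for degree {q}, got {len(x)}")
    if not np.all(np.isfinite(x)):
        raise ValueError("samples must be finite")
    if np.std(x) == 0.0:
        raise ValueError("degenerate samples: zero spread")

    n = len(x)
    for n_sweeps in range(1, max_passes + 1):
        a = np.zeros(q)
        b = np.ones(q + 1)
        p_prev = np.zeros(n)
        p_cur = np.ones(n)
        basis_vecs = [p_cur]
        ok = True
        for k in range(q):
            a[k] = np.mean(x * p_cur * p_cur)
            t = (x - a[k]) * p_cur - b[k] * p_prev
            for _ in range(n_sweeps):           # MGS hygiene sweeps
                for pv in basis_vecs:
                    t -= np.mean(t * pv) * pv
            nrm = np.sqrt(np.mean(t * t))
            if nrm <= 0 or not np.isfinite(nrm):
                ok = False
                break
            b[k + 1] = nrm
            p_prev, p_cur = p_cur, t / nrm
            basis_vecs.append(p_cur)
        if not ok:
            raise ValueError(
                f"Stieltjes breakdown at degree {k + 1}: sample measure cannot "
                f"support {q + 1} orthonormal polynomials")
        basis = OrthonormalBasis1D(name=name, q=q, a=a, b=b, n_samples=n)
        if basis.gram_deviation(x) < gram_tol:
            return basis
    warnings.warn(
        f"{name or 'basis'}: Gram deviation {basis.gram_deviation(x):.3g} "
        f"still above {gram_tol} after {max_passes} passes", RuntimeWarning)
    return basis


@dataclass(frozen=True)
class MultiIndexSet:
    """All d-dimensional multi-indices of total degree <= q, graded
    lexicographic, zero index first."""

    d: int
    q: int
    indices: np.ndarray    # (P, d) int array

    @classmethod
    def total_degree(cls, d: int, q: int) -> "MultiIndexSet":
        if d < 1 or q < 0:
            raise ValueError("d >= 1 and q >= 0 required")

        def compositions(total, parts):
            if parts == 1:
                yield (total,)
                return
            for first in range(total, -1, -1):
                for rest in compositions(total - first, parts - 1):
                    yield (first,) + rest

        idx = []
        for t in range(q + 1):
            idx.extend(sorted(compositions(t, d), reverse=True))
        arr = np.array(idx, dtype=np.int64)
        assert arr.shape[0] == comb(d + q, q)
        return cls(d=d, q=q, indices=arr)

    def __len__(self) -> int:
        return self.indices.shape[0]


def build_basis(marginal_samples: dict[str, np.ndarray], q: int,
                ) -> tuple[MultiIndexSet, dict[str, OrthonormalBasis1D]]:
    """Per-input Stieltjes bases plus the total-degree multi-index set."""
    names = list(marginal_samples.keys())
    d = len(names)
    mset = MultiIndexSet.total_degree(d, q)
    bases = {n: stieltjes_recurrence(marginal_samples[n], q, name=n) for n in names}
    return mset, bases


def _row_digests(X: np.ndarray) -> set[bytes]:
    X = np.ascontiguousarray(np.asarray(X, dtype=float))
    return {hashlib.blake2b(row.tobytes(), digest_size=16).digest() for row in X}


@dataclass(frozen=True)
class PCESurrogate:
    """Fitted polynomial chaos expansion for one or more outputs."""

    mset: MultiIndexSet
    bases: dict[str, OrthonormalBasis1D]
    beta: np.ndarray                   # (P, n_outputs)
    input_names: tuple[str, ...]
    output_names: tuple[str, ...]
    n_train: int
    residual_rms: np.ndarray           # per output
    condition_number: float
    _train_registry: frozenset = field(default=frozenset(), repr=False)

    def design_matrix(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != len(self.input_names):
            raise ValueError(f"expected {len(self.input_names)} input columns")
        Phi = np.ones((X.shape[0], len(self.mset)))
        for j, name in enumerate(self.input_names):
            Pj = self.bases[name].evaluate(X[:, j])
            Phi *= Pj[:, self.mset.indices[:, j]]
        return Phi

    def predict(self, X: np.ndarray, chunk: int = 20000) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        out = np.empty((X.shape[0], self.beta.shape[1]))
        for s in range(0, X.shape[0], chunk):
            out[s:s + chunk] = self.design_matrix(X[s:s + chunk]) @ self.beta
        return out

    def total_variance(self) -> np.ndarray:
        """Per-output variance by Parseval: sum of squared non-constant
        coefficients."""
        return np.sum(self.beta[1:] ** 2, axis=0)

    def to_dict(self) -> dict:
        return {
            "q": self.mset.q,
            "input_names": list(self.input_names),
            "output_names": list(self.output_names),
            "multi_indices": self.mset.indices.tolist(),
            "bases": {n: {"a": b.a.tolist(), "b": b.b.tolist(),
                          "n_samples": b.n_samples}
                      for n, b in self.bases.items()},
            "beta": self.beta.tolist(),
            "n_train": self.n_train,
            "residual_rms": self.residual_rms.tolist(),
            "condition_number": self.condition_number,
            "train_registry": sorted(h.hex() for h in self._train_registry),
        }

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict()))

    @classmethod
    def from_dict(cls, doc: dict) -> "PCESurrogate":
        inames = tuple(doc["input_names"])
        idx = np.array(doc["multi_indices"], dtype=np.int64)
        mset = MultiIndexSet(d=idx.shape[1], q=int(doc["q"]), indices=idx)
        bases = {
            n: OrthonormalBasis1D(name=n, q=int(doc["q"]),
                                  a=np.array(bb["a"]), b=np.array(bb["b"]),
                                  n_samples=int(bb["n_samples"]))
            for n, bb in doc["bases"].items()
        }
        return cls(
            mset=mset, bases=bases, beta=np.array(doc["beta"]),
            input_names=inames, output_names=tuple(doc["output_names"]),
            n_train=int(doc["n_train"]),
            residual_rms=np.array(doc["residual_rms"]),
            condition_number=float(doc["condition_number"]),
            _train_registry=frozenset(bytes.fromhex(h) for h in doc["train_registry"]),
        )

    @classmethod
    def load(cls, path) -> "PCESurrogate":
        return cls.from_dict(json.loads(Path(path).read_text()))


def fit_pce(X: np.ndarray, Y: np.ndarray,
            mset: MultiIndexSet, bases: dict[str, OrthonormalBasis1D],
            input_names: tuple[str, ...] | None = None,
            output_names: tuple[str, ...] | None = None) -> PCESurrogate:
    """Least-squares PCE coefficients.

    Requires at least twice as many training rows as basis functions; if
    the design is ill-conditioned beyond 1e10 a small ridge proportional
    to the Gram trace is applied (with a warning).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    if X.shape[0] != Y.shape[0]:
        raise ValueError("inputs and outputs must be row-aligned")
    P = len(mset)
    if X.shape[0] < 2 * P:
        raise ValueError(f"need at least {2 * P} training rows for {P} basis "
                         f"functions, got {X.shape[0]}")
    inames = tuple(input_names) if input_names else tuple(bases.keys())
    onames = tuple(output_names) if output_names else tuple(
        f"y{i}" for i in range(Y.shape[1]))

    proto = PCESurrogate(
        mset=mset, bases=bases, beta=np.zeros((P, Y.shape[1])),
        input_names=inames, output_names=onames, n_train=X.shape[0],
        residual_rms=np.zeros(Y.shape[1]), condition_number=0.0)
    Phi = proto.design_matrix(X)
    sv = np.linalg.svd(Phi, compute_uv=False)
    cond = float(sv[0] / sv[-1]) if sv[-1] > 0 else np.inf
    if cond > _COND_LIMIT:
        G = Phi.T @ Phi
        lam = _RIDGE * np.trace(G) / P
        warnings.warn(f"ill-conditioned PCE design (cond={cond:.3g}); "
                      f"applying ridge {lam:.3g}", RuntimeWarning)
        beta = np.linalg.solve(G + lam * np.eye(P), Phi.T @ Y)
    else:
        beta, *_ = np.linalg.lstsq(Phi, Y, rcond=None)
    resid = Y - Phi @ beta
    return PCESurrogate(
        mset=mset, bases=bases, beta=beta, input_names=inames,
        output_names=onames, n_train=X.shape[0],
        residual_rms=np.sqrt(np.mean(resid ** 2, axis=0)),
        condition_number=cond, _train_registry=frozenset(_row_digests(X)))


def sobol_from_pce(surrogate: PCESurrogate) -> SobolEstimate:
    """Analytic Sobol indices from the PCE coefficients.

    First order for input j sums squared coefficients over multi-indices
    involving only j; total order over all multi-indices with a nonzero
    power of j; both normalized by the Parseval total variance.
    """
    idx = surrogate.mset.indices
    beta2 = surrogate.beta ** 2            # (P, m)
    V = np.sum(beta2[1:], axis=0)
    V = np.where(V <= 1e-20 * np.maximum(1.0, beta2[0]), 0.0, V)
    if np.any(V <= 0):
        bad = [surrogate.output_names[i] for i in range(len(V)) if V[i] <= 0]
        raise ValueError(f"zero total variance for output(s) {bad}")
    d, m = idx.shape[1], beta2.shape[1]
    S = np.empty((m, d))
    ST = np.empty((m, d))
    nz = idx > 0
    n_active = nz.sum(axis=1)
    for j in range(d):
        only_j = nz[:, j] & (n_active == 1)
        S[:, j] = beta2[only_j].sum(axis=0) / V
        ST[:, j] = beta2[nz[:, j]].sum(axis=0) / V
    return SobolEstimate(S=S, ST=ST, output_names=surrogate.output_names,
                         input_names=surrogate.input_names,
                         N=surrogate.n_train)


@dataclass(frozen=True)
class ValidationReport:
    q2: dict[str, float]
    n_test: int


def q2_score(surrogate: PCESurrogate, X_test: np.ndarray, Y_test: np.ndarray,
             ) -> ValidationReport:
    """Predictive squared correlation coefficient on held-out data,

        Q2 = 1 - sum_l (Y_l - Yhat_l)^2 / (N_test * var(Y)),

    with the test set structurally required to be disjoint from the
    training rows."""
    X_test = np.atleast_2d(np.asarray(X_test, dtype=float))
    Y_test = np.asarray(Y_test, dtype=float)
    if Y_test.ndim == 1:
        Y_test = Y_test[:, None]
    if X_test.shape[0] < 2:
        raise ValueError("need at least 2 test rows")
    overlap = _row_digests(X_test) & surrogate._train_registry
    if overlap:
        raise ValueError(f"{len(overlap)} test rows overlap the training set")
    var = np.var(Y_test, axis=0, ddof=0)
    if np.any(var <= 0):
        raise ValueError("zero variance in test outputs")
    pred = surrogate.predict(X_test)
    q2 = 1.0 - np.sum((Y_test - pred) ** 2, axis=0) / (Y_test.shape[0] * var)
    return ValidationReport(
        q2={o: float(q2[i]) for i, o in enumerate(surrogate.output_names)},
        n_test=X_test.shape[0])
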