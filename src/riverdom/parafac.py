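"""Trilinear (PARAFAC) decomposition of EEM stacks.

A stack of excitation-emission matrices is modelled as
``X[i, j, k] = sum_r A[i, r] * B[j, r] * C[k, r]`` with non-negative
per-sample scores A, emission loadings B and excitation loadings C —
each component is one fluorophore with a fixed spectral shape and a
sample-dependent amount.  Fitting is alternating least squares with
non-negativity on all three modes, multistart from random
initialisations, and expectation-maximisation handling of missing
(scatter-masked) entries: masked cells are imputed with the current
reconstruction each sweep, so they never pull on the fit.

Model order is chosen the way EEM practitioners do: increase the number
of components while the gain in explained variance is material and the
split-half loadings replicate; the first order whose extra component
buys (almost) nothing is the last reliable one.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve, cholesky
from scipy.optimize import linear_sum_assignment, nnls

from .optics import EEM

__all__ = [
    "TrilinearModel",
    "fit_trilinear",
    "select_components",
    "component_ratios",
    "tucker_congruence",
]


@dataclass
class TrilinearModel:
    excitation: np.ndarray
    emission: np.ndarray
    ex_loadings: np.ndarray      # (n_ex, r), unit-norm, non-negative
    em_loadings: np.ndarray      # (n_em, r), unit-norm, non-negative
    scores: np.ndarray           # (n_samples, r), >= 0
    sample_ids: list[str]
    variance_explained: float
    n_iterations: int
    converged: bool
    degenerate: bool
    error_history: list[float] = field(default_factory=list)

    @property
    def n_components(self) -> int:
        return self.ex_loadings.shape[1]

    def emission_maxima(self) -> np.ndarray:
        return self.emission[np.argmax(self.em_loadings, axis=0)]

    def reconstruct(self) -> np.ndarray:
        return np.einsum("ir,jr,kr->ijk",
                         self.scores, self.em_loadings, self.ex_loadings)


def _stack(eems: list[EEM]) -> tuple[np.ndarray, np.ndarray, np.ndarray, list[str]]:
    ex, em = eems[0].excitation, eems[0].emission
    for e in eems[1:]:
        if not (np.array_equal(e.excitation, ex)
                and np.array_equal(e.emission, em)):
            raise ValueError("all EEMs must share the same grids")
    X = np.stack([e.intensity for e in eems])  # (n, em, ex)
    ids = [e.sample_id for e in eems]
    return X, em, ex, ids


def _nnls_rows(G: np.ndarray, W: np.ndarray) -> np.ndarray:
    """Row-wise argmin_{x>=0} x'Gx - 2 w'x via the Cholesky reduction.

    The unconstrained solution is used wherever it is already
    non-negative; only offending rows pay for an active-set NNLS.
    """
    r = G.shape[0]
    ridge = 1e-12 * np.trace(G) / r
    Gr = G + ridge * np.eye(r)
    c, low = cho_factor(Gr)
    X = cho_solve((c, low), W.T).T
    bad = np.nonzero(X.min(axis=1) < 0)[0]
    if bad.size:
        R = cholesky(Gr)  # upper: Gr = R'R
        Rinv_t = np.linalg.inv(R).T
        for i in bad:
            X[i], _ = nnls(R, Rinv_t @ W[i])
    return X


def _als(X: np.ndarray, mask: np.ndarray, r: int, rng: np.random.Generator,
         max_iter: int, tol: float) -> tuple[np.ndarray, np.ndarray, np.ndarray,
                                             float, int, bool]:
    n, ne, nx = X.shape
    obs = ~mask
    Xc = X.copy()
    if mask.any():
        Xc[mask] = X[obs].mean()
    A = rng.uniform(0.1, 1.0, (n, r))
    B = rng.uniform(0.1, 1.0, (ne, r))
    C = rng.uniform(0.1, 1.0, (nx, r))
    norm_obs = float(np.linalg.norm(X[obs]))
    err_prev = np.inf
    errors: list[float] = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        A = _nnls_rows((B.T @ B) * (C.T @ C),
                       np.einsum("ijk,jr,kr->ir", Xc, B, C))
        B = _nnls_rows((A.T @ A) * (C.T @ C),
                       np.einsum("ijk,ir,kr->jr", Xc, A, C))
        C = _nnls_rows((A.T @ A) * (B.T @ B),
                       np.einsum("ijk,ir,jr->kr", Xc, A, B))
        recon = np.einsum("ir,jr,kr->ijk", A, B, C)
        if mask.any():
            Xc[mask] = recon[mask]
        err = float(np.linalg.norm((X - recon)[obs])) / max(norm_obs, 1e-300)
        errors.append(err)
        if err_prev - err < tol * max(err_prev, 1e-12) and it > 1:
            converged = True
            err_prev = err
            break
        err_prev = err
    return A, B, C, err_prev, it, converged, errors


def fit_trilinear(eems: list[EEM], n_components: int, seed: int = 0,
                  n_starts: int = 10, max_iter: int = 2500,
                  tol: float = 1e-8, mask_scatter: bool = True,
                  min_samples: int = 6) -> TrilinearModel:
    """Fit a non-negative trilinear model to a stack of EEMs.

    Multistart ALS keeps the lowest-reconstruction-error run.  Scatter
    bands are masked (unless already NaN-masked upstream) and treated as
    missing.  Components are reported with unit-norm, non-negative
    loadings, ordered by ascending emission maximum, with all scale in
    the per-sample scores.  Inter-component Tucker congruence above 0.98
    flags a degenerate solution.
    """
    if len(eems) < min_samples:
        raise ValueError(f"need at least {min_samples} samples, "
                         f"got {len(eems)}")
    if mask_scatter:
        eems = [e.mask_scatter() for e in eems]
    X, em, ex, ids = _stack(eems)
    mask = np.isnan(X)
    X = np.where(mask, 0.0, X)

    rng = np.random.default_rng(seed)
    best = None
    for _ in range(n_starts):
        A, B, C, err, it, conv, errors = _als(X, mask, n_components, rng,
                                              max_iter, tol)
        if best is None or err < best[3]:
            best = (A, B, C, err, it, conv, errors)
    A, B, C, err, it, conv, errors = best

    # unit-norm loadings, scale into the scores, order by emission max
    bn = np.linalg.norm(B, axis=0)
    cn = np.linalg.norm(C, axis=0)
    bn[bn == 0] = 1.0
    cn[cn == 0] = 1.0
    B, C = B / bn, C / cn
    A = A * bn * cn
    order = np.argsort(em[np.argmax(B, axis=0)], kind="mergesort")
    A, B, C = A[:, order], B[:, order], C[:, order]

    obs = ~mask
    sst = float(np.sum((X[obs] - X[obs].mean()) ** 2))
    recon = np.einsum("ir,jr,kr->ijk", A, B, C)
    sse = float(np.sum((X - recon)[obs] ** 2))
    r2 = 1.0 if sst == 0 else 1.0 - sse / sst

    degenerate = False
    for p in range(n_components):
        for q in range(p + 1, n_components):
            cong = abs(B[:, p] @ B[:, q]) * abs(C[:, p] @ C[:, q])
            if cong > 0.98:
                degenerate = True
    if degenerate:
        warnings.warn("degenerate trilinear solution: inter-component "
                      "congruence exceeds 0.98")

    return TrilinearModel(excitation=ex, emission=em, ex_loadings=C,
                          em_loadings=B, scores=A, sample_ids=ids,
                          variance_explained=r2, n_iterations=it,
                          converged=conv, degenerate=degenerate,
                          error_history=errors)


def tucker_congruence(model_a: TrilinearModel,
                      model_b: TrilinearModel) -> np.ndarray:
    """Per-component Tucker congruence between two fitted models.

    Components are matched by maximum congruence (Hungarian assignment)
    over the product of emission- and excitation-loading cosines.
    """
    if model_a.n_components != model_b.n_components:
        raise ValueError("models have different numbers of components")

    def cos_matrix(U, V):
        Un = U / np.linalg.norm(U, axis=0, keepdims=True)
        Vn = V / np.linalg.norm(V, axis=0, keepdims=True)
        return np.abs(Un.T @ Vn)

    cong = (cos_matrix(model_a.em_loadings, model_b.em_loadings)
            * cos_matrix(model_a.ex_loadings, model_b.ex_loadings))
    row, col = linear_sum_assignment(-cong)
    return cong[row, col]


@dataclass
class ComponentSelection:
    n_components: int
    r_squared: dict[int, float]
    split_half_congruence: dict[int, float]
    passed: list[int]
    warning: str = ""


def select_components(eems: list[EEM],
                      candidate_range: tuple[int, int] = (2, 7),
                      seed: int = 0,
                      delta_r2: float = 0.005,
                      split_congruence_min: float = 0.95,
                      n_starts: int = 4,
                      max_iter: int = 500,
                      tol: float = 1e-7) -> ComponentSelection:
    """Choose the number of trilinear components.

    Walking the candidate range upward, a model order is accepted while
    (a) its explained-variance gain over the previous order exceeds
    ``delta_r2`` (default half a percentage point) and (b) its split-half
    loadings replicate with congruence above ``split_congruence_min``.
    The last accepted order is returned; once the gain collapses the
    larger models are overfitting.  If nothing is accepted, the smallest
    candidate is reported with a warning.
    """
    lo, hi = candidate_range
    if not (2 <= lo <= hi <= 7):
        raise ValueError("candidate_range must lie within [2, 7]")

    def fit(sub: list[EEM], n: int, s: int) -> TrilinearModel:
        return fit_trilinear(sub, n, seed=s, n_starts=n_starts,
                             max_iter=max_iter, tol=tol,
                             mask_scatter=False,
                             min_samples=3)

    eems = [e.mask_scatter() for e in eems]
    half_a, half_b = eems[0::2], eems[1::2]

    r2: dict[int, float] = {}
    split: dict[int, float] = {}
    passed: list[int] = []
    r2[lo - 1] = fit(eems, lo - 1, seed).variance_explained if lo > 1 else 0.0

    for n in range(lo, hi + 1):
        model = fit(eems, n, seed + n)
        r2[n] = model.variance_explained
        gain = r2[n] - r2[n - 1]
        if gain <= delta_r2:
            break
        ma = fit(half_a, n, seed + 100 + n)
        mb = fit(half_b, n, seed + 200 + n)
        split[n] = float(tucker_congruence(ma, mb).min())
        if split[n] > split_congruence_min:
            passed.append(n)

    if not passed:
        return ComponentSelection(
            n_components=lo, r_squared=r2, split_half_congruence=split,
            passed=passed,
            warning=("no candidate passed the gain and split-half "
                     "screens; reporting the range floor"))
    return ComponentSelection(n_components=passed[-1], r_squared=r2,
                              split_half_congruence=split, passed=passed)


def component_ratios(model: TrilinearModel) -> pd.DataFrame:
    """Per-sample score ratios of a three-component model.

    With components ordered by ascending emission maximum (C1 protein-
    like near 350 nm; C2, C3 humic-like near 420 and 470 nm), returns
    C2/C1, C2/(C1+C2), C2/(C1+C2+C3) and C1/(C2+C3).
    """
    if model.n_components != 3:
        raise ValueError("component ratios are defined for 3-component models")
    c1, c2, c3 = (model.scores[:, i] for i in range(3))
    if np.any(c1 == 0) or np.any(c1 + c2 == 0) or np.any(c2 + c3 == 0) \
            or np.any(c1 + c2 + c3 == 0):
        raise ZeroDivisionError("zero score denominator in component ratios")
    return pd.DataFrame({
        "c2_over_c1": c2 / c1,
        "c2_over_c1c2": c2 / (c1 + c2),
        "c2_over_c1c2c3": c2 / (c1 + c2 + c3),
        "c1_over_c2c3": c1 / (c2 + c3),
    }, index=model.sample_ids)
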