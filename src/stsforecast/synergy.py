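"""Muscle-synergy extraction and comparison.

Activation envelopes ``A`` (muscles x time, non-negative) are factorized
as ``A ~ W H`` with non-negative spatial patterns ``W`` (muscles x n)
and temporal patterns ``H`` (n x time), using multiplicative-update NMF
under the Frobenius objective with random restarts.  Concatenating
trials along time before factorizing (CNMF) stabilizes the spatial
patterns against trial-to-trial variability.

The model order ``n`` is the smallest count in ``1..K`` whose best fit
reaches VAF >= 90 % and MSE <= 1e-5, where

    VAF = 100 (1 - ||A - WH||_F^2 / ||A||_F^2)
    MSE = mean over all K*T elements of the squared residual.

The MSE threshold is scale-dependent; activation is therefore expected
on the per-muscle unit-max scale produced by the preprocessing stage.

Spatial patterns are compared by cosine similarity with an optimal
one-to-one assignment; temporal patterns can be re-estimated under fixed
spatial patterns by per-frame non-negative least squares, which is the
sequential (real-time capable) form of the factorization.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import permutations

import numpy as np
from scipy.optimize import nnls

from .preprocess import ActivationMatrix

_EPS = 1e-12


def _values(A) -> np.ndarray:
    arr = A.values if isinstance(A, ActivationMatrix) else np.asarray(A, dtype=float)
    return np.atleast_2d(arr)


@dataclass
class SynergyModel:
    """Fitted NMF model with diagnostics.

    Columns of ``W`` are max-normalized to 1; the scale is absorbed into
    the rows of ``H`` (resolving the NMF scale indeterminacy).
    """

    W: np.ndarray
    H: np.ndarray
    n: int
    vaf_percent: float
    mse: float
    residual_norm: float
    restarts: int
    seed: int
    n_iter: int


@dataclass
class OrderSelection:
    """Result of the VAF/MSE model-order sweep."""

    n: int
    satisfied: bool  # False when no order met both criteria (n = K then)
    vaf_by_n: dict[int, float]
    mse_by_n: dict[int, float]
    models: dict[int, SynergyModel] = field(default_factory=dict, repr=False)


@dataclass
class SynergyMatch:
    """Optimal pairing between two synergy sets.

    ``pairs`` maps column ``i`` of the first set to column ``j`` of the
    second with their cosine similarity; ``best_for_a`` reports, for each
    column of the first set, its maximum-similarity column in the second
    regardless of the assignment.
    """

    pairs: list[tuple[int, int, float]]
    total: float
    best_for_a: list[tuple[int, float]]
    similarity_matrix: np.ndarray


def vaf(A, W: np.ndarray, H: np.ndarray) -> float:
    """Variance accounted for, in percent (uncentered, global)."""
    A = _values(A)
    denom = float(np.sum(A * A))
    if denom == 0.0:
        raise ValueError("VAF undefined for an all-zero activation matrix")
    resid = A - W @ H
    return 100.0 * (1.0 - float(np.sum(resid * resid)) / denom)


def mse(A, W: np.ndarray, H: np.ndarray) -> float:
    """Mean squared reconstruction error over all K*T elements."""
    A = _values(A)
    if A.size == 0:
        raise ValueError("MSE undefined for an empty activation matrix")
    resid = A - W @ H
    return float(np.mean(resid * resid))


def _nmf_single(
    A: np.ndarray,
    n: int,
    rng: np.random.Generator,
    max_iter: int,
    tol: float,
    mu_iters: int = 100,
) -> tuple[np.ndarray, np.ndarray, float, int]:
    """One NMF run from a random non-negative initialization.

    A short multiplicative-update phase moves the random factors into the
    basin of a good solution; exact coordinate descent (HALS) then drives
    the Frobenius residual to the attainable floor.  Plain multiplicative
    updates alone stagnate on plateaus well above the model-order MSE
    criterion, which would corrupt order selection.
    """
    K, T = A.shape
    scale = np.sqrt(A.mean() / n + _EPS)
    W = scale * rng.uniform(0.1, 1.0, size=(K, n))
    H = scale * rng.uniform(0.1, 1.0, size=(n, T))
    for _ in range(min(mu_iters, max_iter)):
        H *= (W.T @ A) / (W.T @ (W @ H) + _EPS)
        W *= (A @ H.T) / ((W @ H) @ H.T + _EPS)
    prev = np.inf
    it = min(mu_iters, max_iter)
    for it in range(it + 1, max_iter + 1):
        WtA = W.T @ A
        WtW = W.T @ W
        for j in range(n):
            H[j] = np.maximum(
                0.0, (WtA[j] - WtW[j] @ H + WtW[j, j] * H[j]) / max(WtW[j, j], _EPS)
            )
        AHt = A @ H.T
        HHt = H @ H.T
        for j in range(n):
            W[:, j] = np.maximum(
                0.0,
                (AHt[:, j] - W @ HHt[:, j] + HHt[j, j] * W[:, j])
                / max(HHt[j, j], _EPS),
            )
        if it % 10 == 0 or it == max_iter:
            resid = float(np.linalg.norm(A - W @ H))
            if np.isfinite(prev) and prev - resid <= tol * max(prev, _EPS):
                prev = resid
                break
            prev = resid
    if not np.isfinite(prev):
        prev = float(np.linalg.norm(A - W @ H))
    return W, H, prev, it


def fit_nmf(
    A,
    n: int,
    restarts: int = 20,
    seed: int = 0,
    max_iter: int = 600,
    tol: float = 1e-6,
) -> SynergyModel:
    """Best-of-restarts NMF under the Frobenius objective.

    Deterministic given ``seed``; among ``restarts`` random non-negative
    initializations the solution with the smallest residual is kept.
    """
    Av = _values(A)
    K = Av.shape[0]
    if not 1 <= n <= K:
        raise ValueError(f"n must be in [1, {K}], got {n}")
    if np.any(Av < 0):
        raise ValueError("activation matrix must be non-negative")
    if restarts < 1:
        raise ValueError("restarts must be at least 1")
    best = None
    ss = np.random.SeedSequence([seed, n])
    for child in ss.spawn(restarts):
        rng = np.random.default_rng(child)
        W, H, resid, it = _nmf_single(Av, n, rng, max_iter, tol)
        if best is None or resid < best[2]:
            best = (W, H, resid, it)
    W, H, resid, it = best
    # push the scale indeterminacy into H: columns of W get max 1
    colmax = W.max(axis=0)
    colmax = np.where(colmax > 0, colmax, 1.0)
    W = W / colmax
    H = H * colmax[:, None]
    return SynergyModel(
        W=W,
        H=H,
        n=n,
        vaf_percent=vaf(Av, W, H),
        mse=mse(Av, W, H),
        residual_norm=resid,
        restarts=restarts,
        seed=seed,
        n_iter=it,
    )


def concat_trials(trials: list[ActivationMatrix]) -> ActivationMatrix:
    """Time-axis concatenation of trials (CNMF input), boundaries recorded."""
    if not trials:
        raise ValueError("no trials to concatenate")
    first = trials[0]
    for tr in trials[1:]:
        if tuple(tr.muscle_names) != tuple(first.muscle_names):
            raise ValueError("mismatched muscle sets across trials")
        if tr.fs != first.fs:
            raise ValueError("mismatched sampling rates across trials")
    bounds, cum = [], 0
    for tr in trials[:-1]:
        cum += tr.n_samples
        bounds.append(cum)
    values = np.concatenate([tr.values for tr in trials], axis=1)
    return ActivationMatrix(
        values, first.fs, tuple(first.muscle_names), trial_boundaries=tuple(bounds)
    )


def split_trials(A: ActivationMatrix) -> list[np.ndarray]:
    """Inverse of :func:`concat_trials` (per-trial column blocks)."""
    return np.split(A.values, list(A.trial_boundaries), axis=1)


def select_order(
    A,
    restarts: int = 20,
    seed: int = 0,
    vaf_threshold: float = 90.0,
    mse_threshold: float = 1e-5,
    max_iter: int = 600,
    keep_models: bool = True,
) -> OrderSelection:
    """Smallest n in 1..K with VAF >= 90 % and MSE <= 1e-5.

    When no order satisfies both criteria the muscle count K is returned
    with ``satisfied=False``.
    """
    Av = _values(A)
    K = Av.shape[0]
    vaf_by_n: dict[int, float] = {}
    mse_by_n: dict[int, float] = {}
    models: dict[int, SynergyModel] = {}
    chosen, satisfied = K, False
    for n in range(1, K + 1):
        model = fit_nmf(Av, n, restarts=restarts, seed=seed, max_iter=max_iter)
        vaf_by_n[n] = model.vaf_percent
        mse_by_n[n] = model.mse
        if keep_models:
            models[n] = model
        if model.vaf_percent >= vaf_threshold and model.mse <= mse_threshold:
            chosen, satisfied = n, True
            break
    return OrderSelection(chosen, satisfied, vaf_by_n, mse_by_n, models)


def cosine_similarity(w1: np.ndarray, w2: np.ndarray) -> float:
    """cos(w1, w2); in [0, 1] for non-negative patterns."""
    w1 = np.asarray(w1, dtype=float).ravel()
    w2 = np.asarray(w2, dtype=float).ravel()
    n1, n2 = np.linalg.norm(w1), np.linalg.norm(w2)
    if n1 == 0.0 or n2 == 0.0:
        raise ValueError("cosine similarity undefined for a zero vector")
    return float(w1 @ w2 / (n1 * n2))


def match_synergies(Wa: np.ndarray, Wb: np.ndarray) -> SynergyMatch:
    """Optimal one-to-one assignment maximizing total cosine similarity.

    Exhaustive over all injections of the smaller set into the larger
    (feasible for the <= 8 columns arising from 8 muscle channels).
    """
    Wa, Wb = np.atleast_2d(np.asarray(Wa, float)), np.atleast_2d(np.asarray(Wb, float))
    if Wa.shape[0] != Wb.shape[0]:
        raise ValueError("spatial patterns must share the muscle dimension")
    na, nb = Wa.shape[1], Wb.shape[1]
    S = np.empty((na, nb))
    for i in range(na):
        for j in range(nb):
            S[i, j] = cosine_similarity(Wa[:, i], Wb[:, j])
    # exhaustive search over assignments of the smaller side
    if na <= nb:
        best_perm, best_total = None, -np.inf
        for perm in permutations(range(nb), na):
            total = sum(S[i, j] for i, j in enumerate(perm))
            if total > best_total:
                best_total, best_perm = total, perm
        pairs = [(i, j, float(S[i, j])) for i, j in enumerate(best_perm)]
    else:
        best_perm, best_total = None, -np.inf
        for perm in permutations(range(na), nb):
            total = sum(S[i, j] for j, i in enumerate(perm))
            if total > best_total:
                best_total, best_perm = total, perm
        pairs = sorted((int(i), j, float(S[i, j])) for j, i in enumerate(best_perm))
    best_for_a = [(int(np.argmax(S[i])), float(S[i].max())) for i in range(na)]
    return SynergyMatch(pairs, float(best_total), best_for_a, S)


def estimate_temporal(A, W_fixed: np.ndarray) -> np.ndarray:
    """Per-frame non-negative least squares of A against fixed W.

    Solves ``min_h ||a_t - W h||`` s.t. ``h >= 0`` independently for each
    time frame, which is the sequential counterpart of the batch NMF and
    recovers H exactly on consistent systems ``A = W H`` with ``H >= 0``.
    """
    Av = _values(A)
    W = np.atleast_2d(np.asarray(W_fixed, dtype=float))
    if W.shape[0] != Av.shape[0]:
        raise ValueError("W_fixed rows must match the muscle count")
    if np.linalg.matrix_rank(W) < W.shape[1]:
        raise ValueError("W_fixed must have full column rank")
    n, T = W.shape[1], Av.shape[1]
    H = np.empty((n, T))
    for t in range(T):
        H[:, t], _ = nnls(W, Av[:, t])
    return H


def estimate_temporal_step(a: np.ndarray, W_fixed: np.ndarray) -> np.ndarray:
    """Single-frame form of :func:`estimate_temporal` (streaming use)."""
    h, _ = nnls(np.atleast_2d(W_fixed), np.asarray(a, dtype=float).ravel())
    return h
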