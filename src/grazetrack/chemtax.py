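"""CHEMTAX-style estimation of algal-group contributions to chlorophyll a.

Given a samples x pigments concentration matrix S and a groups x pigments
pigment:chl-a ratio matrix F, each sample's group abundances a >= 0 (in
chl-a-equivalent units) solve min ||s - a F||_2 by non-negative least
squares. Because literature ratio matrices only approximate a given
community, the ratio matrix is refined by a stochastic search: each
iteration perturbs the non-zero, non-chl-a entries of the current matrix
multiplicatively, fits every candidate, keeps the lowest-rms fraction and
averages them into the next proposal; the unperturbed current matrix is
always among the candidates, and the lowest-rms matrix seen so far is
retained as the estimate (so the logged rms is non-increasing by
construction). Structural zeros and the chl-a column (identically 1) are
preserved throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import nnls


def _validate_ratio_matrix(F: pd.DataFrame) -> None:
    if "chlorophyll_a" not in F.columns:
        raise ValueError("ratio matrix must contain a chlorophyll_a column")
    if (F.values < 0).any():
        raise ValueError("ratio matrix must be non-negative")
    if not np.allclose(F["chlorophyll_a"].values, 1.0):
        raise ValueError("chlorophyll_a column must be identically 1 for every group")


def fit_abundances(S: pd.DataFrame, F: pd.DataFrame) -> tuple[pd.DataFrame, float]:
    """Per-sample non-negative least-squares abundances and the fit rms.

    rms is the root of the mean squared residual over all entries of S.
    F must cover every pigment column of S and have full row rank.
    """
    _validate_ratio_matrix(F)
    missing = set(S.columns) - set(F.columns)
    if missing:
        raise ValueError(f"ratio matrix lacks pigments: {sorted(missing)}")
    if (np.asarray(S.values, dtype=float) < 0).any():
        raise ValueError("pigment concentrations must be non-negative")
    Fm = F[list(S.columns)].values.astype(float)
    if np.linalg.matrix_rank(Fm) < Fm.shape[0]:
        raise ValueError(
            "rank-deficient ratio matrix: group pigment signatures are linearly "
            "dependent, abundances are not identifiable"
        )
    Sm = S.values.astype(float)
    A = np.empty((Sm.shape[0], Fm.shape[0]))
    for i in range(Sm.shape[0]):
        A[i], _ = nnls(Fm.T, Sm[i])
    resid = Sm - A @ Fm
    rms = float(np.sqrt(np.mean(resid**2)))
    return pd.DataFrame(A, index=S.index, columns=F.index), rms


def perturb_ratio_matrix(
    F: pd.DataFrame, magnitude: float, seed: int | np.random.Generator = 0
) -> pd.DataFrame:
    """Multiplicative jitter of the adjustable ratio entries.

    Every non-zero entry outside the chlorophyll_a column is multiplied by
    an independent uniform factor in [1 - magnitude, 1 + magnitude];
    structural zeros and the chl-a column are untouched.
    """
    _validate_ratio_matrix(F)
    if not 0 <= magnitude < 1:
        raise ValueError("magnitude must be in [0, 1)")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out = F.copy()
    adjustable = [c for c in F.columns if c != "chlorophyll_a"]
    block = out[adjustable].values.astype(float)
    factors = rng.uniform(1 - magnitude, 1 + magnitude, size=block.shape)
    out[adjustable] = np.where(block > 0, block * factors, block)
    return out


@dataclass
class FitResult:
    """Outcome of the iterative ratio-matrix optimisation."""

    abundances: pd.DataFrame
    ratio_matrix: pd.DataFrame
    rms: float
    rms_log: list[float]
    converged: bool
    n_iter: int
    n_kept: int = 0


def optimize_ratios(
    S: pd.DataFrame,
    F0: pd.DataFrame,
    n_candidates: int = 60,
    keep_fraction: float = 0.1,
    magnitude: float = 0.35,
    tol: float = 1e-4,
    max_iter: int = 30,
    seed: int = 0,
) -> FitResult:
    """Iteratively refine the ratio matrix and fit abundances under it.

    Per iteration, ``n_candidates`` candidate matrices are evaluated (the
    unperturbed current matrix plus ``n_candidates - 1`` perturbations of
    it); the ``ceil(keep_fraction * n_candidates)`` lowest-rms candidates are
    averaged elementwise into the next proposal. The lowest-rms matrix ever
    evaluated is tracked and returned; ``rms_log`` records this best rms per
    iteration (non-increasing). The search stops when the best rms and the
    best matrix both change by less than ``tol`` (relative) between
    iterations, or at ``max_iter`` (flagged as non-converged).
    """
    if n_candidates * keep_fraction < 1:
        raise ValueError("n_candidates * keep_fraction must be >= 1")
    rng = np.random.default_rng(seed)
    n_keep = math.ceil(keep_fraction * n_candidates)
    current = F0.copy()
    best_F: pd.DataFrame | None = None
    best_rms = math.inf
    rms_log: list[float] = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        candidates = [current] + [
            perturb_ratio_matrix(current, magnitude, rng) for _ in range(n_candidates - 1)
        ]
        scored = []
        for Fc in candidates:
            _, rms = fit_abundances(S, Fc)
            scored.append((rms, Fc))
        order = np.argsort([r for r, _ in scored], kind="stable")
        kept = [scored[i] for i in order[:n_keep]]
        prev_best_F, prev_best_rms = best_F, best_rms
        if kept[0][0] < best_rms:
            best_rms, best_F = kept[0][0], kept[0][1].copy()
        rms_log.append(best_rms)
        if prev_best_F is not None:
            drms = abs(best_rms - prev_best_rms) <= tol * max(prev_best_rms, 1e-12)
            denom = np.maximum(np.abs(prev_best_F.values), 1e-12)
            dF = float(np.max(np.abs(best_F.values - prev_best_F.values) / denom))
            if drms and dF <= tol:
                converged = True
                break
        current = sum(F for _, F in kept) / n_keep
    assert best_F is not None
    abundances, rms = fit_abundances(S, best_F)
    return FitResult(
        abundances=abundances,
        ratio_matrix=best_F,
        rms=rms,
        rms_log=rms_log,
        converged=converged,
        n_iter=it,
        n_kept=n_keep,
    )


def composition_percent(abundances: pd.DataFrame) -> pd.DataFrame:
    """Percent contribution of each group to total chl a, per sample.

    Rows sum to 100; samples with zero total abundance are reported as
    missing (NaN row).
    """
    if (abundances.values < 0).any():
        raise ValueError("abundances must be non-negative")
    totals = abundances.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        pct = 100.0 * abundances.div(totals, axis=0)
    pct[totals == 0] = np.nan
    return pct
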