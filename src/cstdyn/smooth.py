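"""Penalized regression smooths with subject random intercepts.

Small internal engine used by the temporal models: cubic B-spline bases
with second-difference (P-spline) penalties, an optional tensor-product
construction for bivariate surfaces, and a ridge-penalized block of
subject indicator columns standing in for a random intercept (the
standard mixed-model-as-penalty identity). Smoothing parameters are
chosen by generalized cross-validation on a log-spaced grid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import BSpline
from scipy.linalg import cho_factor, cho_solve

_DEFAULT_LAM_GRID = np.logspace(-6, 6, 9)
_SUBJECT_LAM_GRID = np.logspace(-4, 4, 5)


def bspline_design(x: np.ndarray, ndim: int = 10, degree: int = 3,
                   knots: np.ndarray | None = None
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Cubic B-spline design matrix with quantile-placed interior knots.

    Returns the n x ndim design and the full knot vector (for reuse at
    prediction time). Values outside the training range are clamped to
    the boundary.
    """
    x = np.asarray(x, dtype=float)
    if knots is None:
        n_interior = ndim - degree - 1
        if n_interior < 0:
            raise ValueError(f"ndim={ndim} too small for degree {degree}")
        lo, hi = np.min(x), np.max(x)
        if hi <= lo:
            hi = lo + 1.0
        if n_interior > 0:
            qs = np.linspace(0, 1, n_interior + 2)[1:-1]
            interior = np.quantile(x, qs)
            interior = np.clip(interior, lo + 1e-9, hi - 1e-9)
        else:
            interior = np.array([])
        knots = np.concatenate([
            np.repeat(lo, degree + 1), np.sort(interior), np.repeat(hi, degree + 1)
        ])
    lo, hi = knots[0], knots[-1]
    xc = np.clip(x, lo, hi - 1e-12 * max(1.0, abs(hi)))
    basis = BSpline.design_matrix(xc, knots, degree).toarray()
    return basis, knots


def difference_penalty(ndim: int, order: int = 2) -> np.ndarray:
    d = np.eye(ndim)
    for _ in range(order):
        d = np.diff(d, axis=0)
    return d.T @ d


def tensor_design(bx: np.ndarray, bg: np.ndarray) -> np.ndarray:
    """Row-wise Kronecker (tensor product smooth) of two marginal bases."""
    n = bx.shape[0]
    return (bx[:, :, None] * bg[:, None, :]).reshape(n, -1)


def tensor_penalty(px: np.ndarray, pg: np.ndarray) -> np.ndarray:
    ix, ig = np.eye(px.shape[0]), np.eye(pg.shape[0])
    return np.kron(px, ig) + np.kron(ix, pg)


def subject_dummies(subject_ids) -> tuple[np.ndarray, list]:
    subjects = list(dict.fromkeys(subject_ids))
    index = {s: i for i, s in enumerate(subjects)}
    z = np.zeros((len(subject_ids), len(subjects)))
    for row, s in enumerate(subject_ids):
        z[row, index[s]] = 1.0
    return z, subjects


@dataclass
class PenalizedFit:
    coef: np.ndarray            # smooth-block coefficients
    subject_effects: np.ndarray
    subjects: list
    lam_smooth: float
    lam_subject: float
    edf: float
    gcv: float
    rss: float
    fitted: np.ndarray
    sigma2: float
    subject_var: float


def fit_penalized(y: np.ndarray, basis: np.ndarray, penalty,
                  subject_ids=None,
                  lam_grid: np.ndarray = _DEFAULT_LAM_GRID,
                  lam_subject_grid: np.ndarray = _SUBJECT_LAM_GRID
                  ) -> PenalizedFit:
    """Minimize ||y - X b - Z u||^2 + sum_j lam_j b'P_j b + lam_z u'u by GCV.

    ``penalty`` is one penalty matrix or a list of them (e.g. the two
    directions of a tensor-product smooth), each with its own smoothing
    parameter searched on ``lam_grid``. The ridge on the subject
    indicators is the penalized-regression form of a Gaussian random
    intercept with variance sigma^2 / lam_z.
    """
    from itertools import product

    y = np.asarray(y, dtype=float)
    n, p = basis.shape
    penalties = penalty if isinstance(penalty, (list, tuple)) else [penalty]
    if subject_ids is not None:
        z, subjects = subject_dummies(subject_ids)
        if len(subjects) <= 1:
            z, subjects = None, subjects
    else:
        z, subjects = None, []
    q = 0 if z is None else z.shape[1]
    full = basis if z is None else np.hstack([basis, z])
    xtx = full.T @ full
    xty = full.T @ y
    yty = float(y @ y)

    pen_blocks = []
    for pen in penalties:
        block = np.zeros((p + q, p + q))
        block[:p, :p] = pen
        pen_blocks.append(block)
    pen_subject = np.zeros((p + q, p + q))
    if q:
        pen_subject[p:, p:] = np.eye(q)
    subj_grid = lam_subject_grid if q else np.array([0.0])

    best = None
    for lam_z in subj_grid:
        for lams in product(lam_grid, repeat=len(pen_blocks)):
            a = xtx + lam_z * pen_subject
            for lam, block in zip(lams, pen_blocks):
                a = a + lam * block
            a[np.diag_indices_from(a)] += 1e-10  # numerical floor
            try:
                cf = cho_factor(a)
            except np.linalg.LinAlgError:
                continue
            beta = cho_solve(cf, xty)
            rss = max(yty - 2 * beta @ xty + beta @ (xtx @ beta), 0.0)
            edf = float(np.trace(cho_solve(cf, xtx)))
            denom = max(n - edf, 1e-6)
            gcv = n * rss / denom ** 2
            if best is None or gcv < best[0]:
                best = (gcv, lams[0], lam_z, beta, rss, edf)
    if best is None:
        raise np.linalg.LinAlgError("all smoothing candidates were singular")
    gcv, lam_s, lam_z, beta, rss, edf = best
    fitted = full @ beta
    sigma2 = rss / max(n - edf, 1.0)
    u = beta[p:] if q else np.array([])
    subject_var = sigma2 / lam_z if (q and lam_z > 0) else float(np.var(u)) if q else 0.0
    return PenalizedFit(
        coef=beta[:p], subject_effects=u, subjects=subjects,
        lam_smooth=lam_s, lam_subject=lam_z, edf=edf, gcv=gcv, rss=rss,
        fitted=fitted, sigma2=sigma2, subject_var=subject_var,
    )
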