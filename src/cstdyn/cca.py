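"""Cross-validated canonical correlation analysis between body sites.

Canonical weights are estimated on training subjects only (folds block
by subject, so no infant contributes to both sides of a split) and the
reported held-out correlations are Pearson correlations of the paired
projection scores of withheld samples. Temporal structure can be
removed beforehand by replacing each feature with its residual from a
natural-spline regression on post-menstrual age; comparing adjusted to
unadjusted held-out correlations separates time-mediated from residual
cross-site coupling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import patsy
from scipy import linalg


@dataclass
class CCAResult:
    pair: tuple[str, str]
    n_components: int
    train_corr: np.ndarray          # folds x components
    heldout_corr: np.ndarray        # folds x components
    heldout_mean: np.ndarray
    heldout_2sem: np.ndarray
    fold_of_subject: dict
    adjustment: str = "none"        # none | spline df used


def regress_out_time(matrix: np.ndarray, pma, df: int,
                     subject_ids=None) -> np.ndarray:
    """Residualize every feature against a natural spline of PMA.

    With ``subject_ids`` given, per-subject indicator columns join the
    projection so subject means are removed as well. Residuals are
    exactly orthogonal to the spline basis.
    """
    matrix = np.asarray(matrix, dtype=float)
    pma = np.asarray(pma, dtype=float)
    n = matrix.shape[0]
    if df >= n:
        raise ValueError(f"spline df={df} must be < n={n}")
    design = patsy.dmatrix("cr(x, df=%d)" % df, {"x": pma},
                           return_type="dataframe").to_numpy()
    if subject_ids is not None:
        from .smooth import subject_dummies
        z, _ = subject_dummies(subject_ids)
        design = np.hstack([design, z])
    beta, *_ = np.linalg.lstsq(design, matrix, rcond=None)
    return matrix - design @ beta


def _cca_weights(x: np.ndarray, y: np.ndarray, n_components: int,
                 ridge: float = 1e-3):
    """Classical CCA via whitening; ridge applied when n <= p."""
    n = x.shape[0]
    xc = x - x.mean(axis=0)
    yc = y - y.mean(axis=0)
    sxx = xc.T @ xc / n
    syy = yc.T @ yc / n
    sxy = xc.T @ yc / n
    eps_x = eps_y = 0.0
    if n <= x.shape[1] or n <= y.shape[1]:
        warnings.warn("feature count >= training samples; ridge-regularized whitening")
        eps_x = ridge * np.trace(sxx) / max(x.shape[1], 1)
        eps_y = ridge * np.trace(syy) / max(y.shape[1], 1)
    # numerical floor keeps the whitening well defined for collinear features
    floor_x = 1e-10 * max(np.trace(sxx) / max(x.shape[1], 1), 1e-30)
    floor_y = 1e-10 * max(np.trace(syy) / max(y.shape[1], 1), 1e-30)
    rx = linalg.sqrtm(sxx + (eps_x + floor_x) * np.eye(x.shape[1]))
    ry = linalg.sqrtm(syy + (eps_y + floor_y) * np.eye(y.shape[1]))
    rx, ry = np.real(rx), np.real(ry)
    m = np.linalg.solve(rx, sxy) @ np.linalg.inv(ry)
    u, s, vt = np.linalg.svd(m)
    k = min(n_components, s.size)
    wx = np.linalg.solve(rx, u[:, :k])
    wy = np.linalg.solve(ry, vt[:k].T)
    return wx, wy, s[:k], x.mean(axis=0), y.mean(axis=0)


def blocked_cv_cca(x: np.ndarray, y: np.ndarray, subject_ids, *,
                   folds: int = 10, n_components: int = 10,
                   ridge: float = 1e-3, seed: int = 0,
                   pair: tuple[str, str] = ("site_a", "site_b"),
                   adjustment: str = "none") -> CCAResult:
    """Subject-blocked cross-validated CCA.

    Subjects are shuffled into ``folds`` groups; canonical weights are
    fit on the training subjects' rows and the held-out correlation of
    each component is the Pearson correlation of the projected withheld
    samples. Reported per component: mean and two standard errors of
    the mean across folds.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape[0] != y.shape[0]:
        raise ValueError("matrices must have matched rows")
    subjects = list(dict.fromkeys(subject_ids))
    if len(subjects) < folds:
        raise ValueError(f"need >= {folds} subjects, got {len(subjects)}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(subjects))
    fold_of = {subjects[i]: int(f) for f, i in
               zip(np.arange(len(subjects)) % folds, order)}
    groups = np.array([fold_of[s] for s in subject_ids])

    n_comp_eff = min(n_components, x.shape[1], y.shape[1])
    train_corr = np.full((folds, n_comp_eff), np.nan)
    held_corr = np.full((folds, n_comp_eff), np.nan)
    for f in range(folds):
        tr, te = groups != f, groups == f
        if te.sum() < 3 or tr.sum() <= 2:
            continue
        wx, wy, s, mx, my = _cca_weights(x[tr], y[tr], n_comp_eff, ridge)
        train_corr[f, :s.size] = s
        sx = (x[te] - mx) @ wx
        sy = (y[te] - my) @ wy
        for c in range(min(n_comp_eff, wx.shape[1])):
            if np.std(sx[:, c]) == 0 or np.std(sy[:, c]) == 0:
                continue
            held_corr[f, c] = np.corrcoef(sx[:, c], sy[:, c])[0, 1]

    mean = np.nanmean(held_corr, axis=0)
    counts = np.sum(np.isfinite(held_corr), axis=0).clip(min=1)
    with np.errstate(invalid="ignore"):
        sem = np.nanstd(held_corr, axis=0, ddof=1) / np.sqrt(counts)
    return CCAResult(
        pair=tuple(pair), n_components=n_comp_eff,
        train_corr=train_corr, heldout_corr=held_corr,
        heldout_mean=mean, heldout_2sem=2 * sem,
        fold_of_subject=fold_of, adjustment=adjustment,
    )
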