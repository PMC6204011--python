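"""Temporal occurrence modeling of CSTs over infant maturity.

Each CST's membership probability is modeled on the linear probability
scale as a smooth of week of life (WOL) and gestational age at birth
(gaBirth) with a subject random intercept. The single-index restriction
replaces the bivariate smooth with a 1-D smooth along a learned
maturity axis a*WOL + b*gaBirth; the ratio b/a measures how much a week
in utero advances the CST relative to a week of post-natal life.
Binning log2(b/a), together with a logistic test of whether a CST's
occurrence in a subject depends on gestational age at birth, yields the
three occurrence patterns:

* convergent    — |log2(b/a)| < 1: pre-terms reach the CST after a
                  post-natal delay proportional to prematurity;
* chronological — b/a well below 1 and occurrence independent of
                  gestational age: WOL alone drives the CST;
* idiosyncratic — everything else: maturity at birth changes how often
                  the CST occurs at all.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .smooth import (
    PenalizedFit,
    bspline_design,
    difference_penalty,
    fit_penalized,
    tensor_design,
)
from .dmm import CSTAssignment
from .types import VisitSample


@dataclass
class OccurrenceSurfaceFit:
    """Penalized tensor-product surface P(CST) ~ f(WOL, gaBirth) + subject."""

    cst: int
    fit: PenalizedFit
    knots_wol: np.ndarray
    knots_gab: np.ndarray
    ndim: int
    degree: int = 3

    def predict(self, wol, gab) -> np.ndarray:
        """Population-level surface prediction (random intercept at zero)."""
        wol = np.atleast_1d(np.asarray(wol, dtype=float))
        gab = np.atleast_1d(np.asarray(gab, dtype=float))
        bx, _ = bspline_design(wol, self.ndim, self.degree, knots=self.knots_wol)
        bg, _ = bspline_design(gab, self.ndim, self.degree, knots=self.knots_gab)
        return tensor_design(bx, bg) @ self.fit.coef

    @property
    def subject_variance(self) -> float:
        return self.fit.subject_var

    @property
    def residual_variance(self) -> float:
        return self.fit.sigma2


@dataclass
class SingleIndexFit:
    """P(CST) ~ g(a*WOL + b*gaBirth) + subject, with (a,b) on the unit circle."""

    cst: int
    a: float
    b: float
    theta: float
    fit: PenalizedFit
    knots: np.ndarray
    ndim: int
    criterion: float
    indeterminate: bool = False
    profile_thetas: np.ndarray = field(default_factory=lambda: np.empty(0))
    profile_scores: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def log2_ratio(self) -> float:
        if self.a > 0 and self.b > 0:
            return float(np.log2(self.b / self.a))
        return float("-inf") if self.a > 0 else float("inf")

    def predict(self, wol, gab) -> np.ndarray:
        t = self.a * np.atleast_1d(wol) + self.b * np.atleast_1d(gab)
        basis, _ = bspline_design(np.asarray(t, float), self.ndim, knots=self.knots)
        return basis @ self.fit.coef


@dataclass
class PatternClass:
    cst: int
    pattern: str                      # chronological | convergent | idiosyncratic
    log2_ratio: float
    occurrence_p: float
    negative_b: bool = False


def fit_occurrence_surface(cst_probs, wol, gab, subject_ids, *,
                           ndim: int = 10, cst: int = 0) -> OccurrenceSurfaceFit:
    """Fit the bivariate occurrence surface on the linear probability scale.

    Requires at least 30 samples spanning at least 5 distinct WOL
    values. Smoothing is selected by GCV; the subject random intercept
    enters as a ridge-penalized indicator block.
    """
    y = np.asarray(cst_probs, dtype=float)
    wol = np.asarray(wol, dtype=float)
    gab = np.asarray(gab, dtype=float)
    if y.size < 30:
        raise ValueError(f"need >= 30 samples, got {y.size}")
    if np.unique(wol).size < 5:
        raise ValueError("need >= 5 distinct WOL values")
    bx, kx = bspline_design(wol, ndim)
    bg, kg = bspline_design(gab, ndim)
    design = tensor_design(bx, bg)
    # one smoothing parameter per direction so an irrelevant margin can be
    # shrunk flat without oversmoothing the other
    eye = np.eye(ndim)
    penalty = [np.kron(difference_penalty(ndim), eye),
               np.kron(eye, difference_penalty(ndim))]
    rank = np.linalg.matrix_rank(design)
    if rank < min(design.shape):
        warnings.warn(
            f"rank-deficient tensor design (rank {rank} < {design.shape[1]}); "
            "penalty regularizes the fit"
        )
    fit = fit_penalized(y, design, penalty, subject_ids)
    return OccurrenceSurfaceFit(cst=cst, fit=fit, knots_wol=kx, knots_gab=kg,
                                ndim=ndim)


def _index_fit(y, wol, gab, subject_ids, theta, ndim):
    a, b = np.cos(theta), np.sin(theta)
    t = a * wol + b * gab
    basis, knots = bspline_design(t, ndim)
    pen = difference_penalty(ndim)
    fit = fit_penalized(y, basis, pen, subject_ids)
    return fit, knots


def fit_single_index(cst_probs, wol, gab, subject_ids, *,
                     ndim: int = 10, n_grid: int = 181, cst: int = 0,
                     flat_tol: float = 1e-10) -> SingleIndexFit:
    """Profile-fit the single-index model over the index angle.

    (a, b) = (cos theta, sin theta) with theta on (-pi/2, pi/2), so
    a >= 0 by construction; each candidate angle gets a 1-D penalized
    smooth along the index with a subject random intercept, scored by
    GCV, and the best angle is refined by golden-section search.
    """
    y = np.asarray(cst_probs, dtype=float)
    wol = np.asarray(wol, dtype=float)
    gab = np.asarray(gab, dtype=float)
    if y.size < 30:
        raise ValueError(f"need >= 30 samples, got {y.size}")

    eps = 1e-3
    thetas = np.linspace(-np.pi / 2 + eps, np.pi / 2 - eps, n_grid)
    scores = np.empty(n_grid)
    for i, th in enumerate(thetas):
        fit, _ = _index_fit(y, wol, gab, subject_ids, th, ndim)
        scores[i] = fit.gcv
    best_i = int(np.argmin(scores))

    # golden-section refinement inside the bracketing grid cells
    lo = thetas[max(best_i - 1, 0)]
    hi = thetas[min(best_i + 1, n_grid - 1)]
    invphi = (np.sqrt(5) - 1) / 2
    c = hi - invphi * (hi - lo)
    d = lo + invphi * (hi - lo)
    fc = _index_fit(y, wol, gab, subject_ids, c, ndim)[0].gcv
    fd = _index_fit(y, wol, gab, subject_ids, d, ndim)[0].gcv
    for _ in range(25):
        if fc < fd:
            hi, d, fd = d, c, fc
            c = hi - invphi * (hi - lo)
            fc = _index_fit(y, wol, gab, subject_ids, c, ndim)[0].gcv
        else:
            lo, c, fc = c, d, fd
            d = lo + invphi * (hi - lo)
            fd = _index_fit(y, wol, gab, subject_ids, d, ndim)[0].gcv
        if hi - lo < 1e-4:
            break
    theta = (lo + hi) / 2
    fit, knots = _index_fit(y, wol, gab, subject_ids, theta, ndim)
    if fit.gcv > min(scores[best_i], fc, fd):
        theta = thetas[best_i]
        fit, knots = _index_fit(y, wol, gab, subject_ids, theta, ndim)

    indeterminate = float(scores.max() - scores.min()) < flat_tol * max(
        1.0, float(scores.mean()))
    return SingleIndexFit(
        cst=cst, a=float(np.cos(theta)), b=float(np.sin(theta)),
        theta=float(theta), fit=fit, knots=knots, ndim=ndim,
        criterion=float(fit.gcv), indeterminate=indeterminate,
        profile_thetas=thetas, profile_scores=scores,
    )


def occurrence_logistic_test(occurrence, gab) -> tuple[float, bool]:
    """Wald p-value for gaBirth in a logistic model of any-occurrence.

    Returns ``(p, separated)``. A degenerate outcome (all subjects
    occur, or none) gives p = 1 by convention; complete separation is
    flagged and reported as p < 1e-6 (counts as significant).
    """
    import statsmodels.api as sm

    occ = np.asarray(occurrence, dtype=float)
    gab = np.asarray(gab, dtype=float)
    if occ.min() == occ.max():
        return 1.0, False
    x = sm.add_constant(gab)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.Logit(occ, x).fit(disp=0, maxiter=200)
        except Exception:
            return 1e-7, True
    # detect (quasi-)separation: fitted probabilities saturate
    fitted = res.predict(x)
    if np.all((fitted > 1 - 1e-6) == (occ > 0.5)) and \
            np.all((fitted < 1e-6) == (occ < 0.5)) and \
            np.max(np.abs(res.params)) > 50:
        return 1e-7, True
    p = float(res.pvalues[1])
    if not np.isfinite(p):
        return 1e-7, True
    return p, False


def classify_pattern(a: float, b: float, occurrence_p: float, *,
                     ratio_threshold: float = 1.0,
                     p_threshold: float = 0.05, cst: int = 0) -> PatternClass:
    """Three-way occurrence pattern from the index weights and the
    gestational-age occurrence test.

    convergent when a,b > 0 and |log2(b/a)| < ratio_threshold;
    chronological when the ratio falls below -ratio_threshold (or b <= 0)
    and occurrence is not associated with gestational age; otherwise
    idiosyncratic.
    """
    if a < 0:
        raise ValueError("orientation convention requires a >= 0")
    if a == 0 and b == 0:
        raise ValueError("a and b cannot both be zero: no time dependence")
    negative_b = b <= 0 < a
    if a > 0 and b > 0:
        ratio = float(np.log2(b / a))
    else:
        ratio = float("-inf") if a > 0 else float("inf")
    if a > 0 and b > 0 and abs(ratio) < ratio_threshold:
        pattern = "convergent"
    elif a > 0 and (b <= 0 or ratio < -ratio_threshold) and \
            occurrence_p >= p_threshold:
        pattern = "chronological"
    else:
        pattern = "idiosyncratic"
    return PatternClass(cst=cst, pattern=pattern, log2_ratio=ratio,
                        occurrence_p=float(occurrence_p), negative_b=negative_b)


def sequence_index_summary(assignments: CSTAssignment,
                           samples: list[VisitSample]) -> pd.DataFrame:
    """Per-subject weekly CST sequences on the PMA axis.

    Observation times are floored to whole weeks of PMA; each week
    between consecutive observations takes the CST of the nearer one
    (the interval splits at the midpoint, with the later sample winning
    an exact tie). Weeks before the first or after the last observation
    are absent from the output.
    """
    label_of = dict(zip(assignments.sample_ids,
                        (int(l) for l in assignments.map_label)))
    per_subject: dict[tuple[str, str], list[tuple[int, float, int]]] = {}
    for v in samples:
        if v.sample_id not in label_of or v.illness_flag:
            continue
        key = (v.subject_id, v.site)
        per_subject.setdefault(key, []).append(
            (int(np.floor(v.pma)), v.pma, label_of[v.sample_id]))
    rows = []
    for (subject, site), obs in per_subject.items():
        obs.sort(key=lambda t: t[1])
        dedup: dict[int, tuple[float, int]] = {}
        for week, pma, cst in obs:
            if week in dedup:
                warnings.warn(
                    f"duplicate week {week} for subject {subject} site {site}; "
                    "later sample wins")
            dedup[week] = (pma, cst)
        weeks = sorted(dedup)
        points = [(w, dedup[w][1]) for w in weeks]
        for w in range(points[0][0], points[-1][0] + 1):
            # nearest observed week; exact midpoint goes to the later sample
            dists = [abs(w - pw) for pw, _ in points]
            best = int(np.argmin(dists))
            for j in range(len(points) - 1, -1, -1):
                if dists[j] == dists[best]:
                    best = j
                    break
            rows.append({"subject_id": subject, "site": site,
                         "pma_week": w, "cst": points[best][1]})
    return pd.DataFrame(rows, columns=["subject_id", "site", "pma_week", "cst"])
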