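"""Cross-body-site association structure.

Samples from two sites taken at the same visit are paired, and the
paired data feed four analyses: a chi-squared test of CST co-occurrence,
Pearson correlations between CST membership probabilities, linear
mixed-effects models relating each taxon's (arcsine-sqrt transformed)
abundance at one site to the CSTs of the other sites while adjusting
for delivery mode, gestational age at birth, birth season, and a
14-degree-of-freedom natural spline of week of life, and residual
correlations of OTUs shared between sites after removing
post-menstrual-age structure. Discoveries are controlled at 5% FDR per
outcome site with Benjamini-Hochberg, reporting only the most specific
taxon within each significant lineage.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import patsy
from scipy import stats

from .io_prep import arcsine_sqrt
from .smooth import bspline_design, difference_penalty, fit_penalized
from .types import CountsTable, VisitSample


@dataclass(frozen=True)
class VisitPair:
    subject_id: str
    visit_wol: float
    sample_a: str
    sample_b: str


@dataclass
class AssociationRecord:
    site: str                        # outcome site
    taxon: tuple[str, ...]           # lineage up to the tested rank
    rank: str
    wald_p: dict[str, dict[int, float]]        # remote site -> CST -> p
    direction: dict[str, dict[int, str]]       # remote site -> CST -> incr/decr
    f_stat: float                    # all remote CST terms, full vs null
    f_p: float
    f_p_by_site: dict[str, float] = field(default_factory=dict)
    delta_pseudo_r2: float = 0.0
    q: float = float("nan")
    converged: bool = True


def pair_visits(samples: list[VisitSample], site_a: str,
                site_b: str) -> list[VisitPair]:
    """One pair per (subject, visit) with both sites sampled and healthy."""
    def index(site):
        out = {}
        for v in samples:
            if v.site == site and not v.illness_flag:
                out[(v.subject_id, v.wol)] = v.sample_id
        return out

    a_index, b_index = index(site_a), index(site_b)
    pairs = []
    for key in sorted(set(a_index) & set(b_index)):
        pairs.append(VisitPair(subject_id=key[0], visit_wol=key[1],
                               sample_a=a_index[key], sample_b=b_index[key]))
    return pairs


def _labels_for(pairs, labels, which):
    """Resolve a label mapping or aligned array for one side of the pairs."""
    if hasattr(labels, "get"):
        ids = [p.sample_a if which == "a" else p.sample_b for p in pairs]
        return np.array([labels[s] for s in ids], dtype=int)
    arr = np.asarray(labels, dtype=int)
    if arr.size != len(pairs):
        raise ValueError("label array does not align with pairs")
    return arr


def cooccurrence_chisq(pairs: list[VisitPair], labels_a, labels_b, *,
                       monte_carlo_reps: int = 0, seed: int = 0
                       ) -> tuple[float, float]:
    """Pearson chi-squared test of CST co-occurrence across paired visits.

    ``labels_*`` are either dicts keyed by sample id or arrays aligned
    with ``pairs``. With ``monte_carlo_reps`` > 0 and any expected cell
    below 5, the p-value is computed by permutation instead of the
    asymptotic distribution.
    """
    la = _labels_for(pairs, labels_a, "a")
    lb = _labels_for(pairs, labels_b, "b")
    table = pd.crosstab(la, lb).to_numpy()
    if table.shape[0] < 2 or table.shape[1] < 2:
        raise ValueError("degenerate contingency table: need >= 2 labels per side")
    chi2, p, _, expected = stats.chi2_contingency(table, correction=False)
    if monte_carlo_reps and expected.min() < 5:
        rng = np.random.default_rng(seed)
        count = 0
        for _ in range(monte_carlo_reps):
            perm = rng.permutation(lb)
            t = pd.crosstab(la, perm).to_numpy()
            c, _, _, _ = stats.chi2_contingency(t, correction=False)
            count += c >= chi2
        p = (count + 1) / (monte_carlo_reps + 1)
    return float(chi2), float(p)


def cst_probability_correlation(pairs, assignment_a, assignment_b) -> np.ndarray:
    """Ka x Kb Pearson correlations of CST membership probabilities.

    Accepts ``CSTAssignment`` objects; entry (i, j) correlates site-a
    CST i+1 membership with site-b CST j+1 membership across pairs.
    Zero-variance columns give NaN entries.
    """
    if len(pairs) < 3:
        raise ValueError("need >= 3 pairs")
    ia = {s: i for i, s in enumerate(assignment_a.sample_ids)}
    ib = {s: i for i, s in enumerate(assignment_b.sample_ids)}
    pa = assignment_a.posterior[[ia[p.sample_a] for p in pairs]]
    pb = assignment_b.posterior[[ib[p.sample_b] for p in pairs]]
    ka, kb = pa.shape[1], pb.shape[1]
    out = np.full((ka, kb), np.nan)
    for i in range(ka):
        if np.std(pa[:, i]) == 0:
            continue
        for j in range(kb):
            if np.std(pb[:, j]) == 0:
                continue
            out[i, j] = np.corrcoef(pa[:, i], pb[:, j])[0, 1]
    return out


def taxon_abundances(table: CountsTable) -> dict[tuple[str, ...], np.ndarray]:
    """Relative abundance of every taxon at every rank, by lineage rollup.

    OTU counts are summed up each lineage prefix before converting to
    per-sample relative abundance; OTUs without taxonomy roll up under
    their own id.
    """
    totals = table.counts.sum(axis=1).astype(float)
    if np.any(totals == 0):
        raise ValueError("sample with zero total count")
    agg: dict[tuple[str, ...], np.ndarray] = {}
    for j, otu in enumerate(table.otu_ids):
        lineage = table.taxonomy.get(otu, (otu,))
        for depth in range(1, len(lineage) + 1):
            key = tuple(lineage[:depth])
            if key in agg:
                agg[key] = agg[key] + table.counts[:, j]
            else:
                agg[key] = table.counts[:, j].astype(float).copy()
    return {k: v / totals for k, v in agg.items()}


def _sum_contrasts(labels: np.ndarray) -> tuple[np.ndarray, list[int]]:
    """Sum-to-zero (deviation) coding: columns are levels 1..K-1 minus the
    grand mean; the last level's coefficient is minus the sum."""
    levels = sorted(np.unique(labels))
    k = len(levels)
    cols = np.zeros((labels.size, k - 1))
    for j, lev in enumerate(levels[:-1]):
        cols[labels == lev, j] = 1.0
    cols[labels == levels[-1], :] = -1.0
    return cols, levels


def fit_taxon_models(abund, remote_labels: dict[str, np.ndarray],
                     covariates: pd.DataFrame, subject_ids, *,
                     site: str = "", taxon: tuple[str, ...] = (),
                     rank: str = "", wol_df: int = 14,
                     transform: bool = True,
                     compute_delta: bool = True) -> AssociationRecord:
    """Mixed-model association between a taxon and remote-site CSTs.

    The outcome is the arcsine-sqrt transformed relative abundance at
    the outcome site across visit pairs. Fixed effects: sum-to-zero
    coded CSTs of each remote site (so each coefficient is that CST's
    deviation from the grand mean), delivery mode, gestational age at
    birth, birth season, and a natural spline of WOL; the subject is a
    random intercept. Fit by maximum likelihood so the nested Wald-F
    block tests are valid.
    """
    import statsmodels.api as sm

    y = arcsine_sqrt(np.asarray(abund, dtype=float)) if transform \
        else np.asarray(abund, dtype=float)
    n = y.size
    if n < 20:
        raise ValueError(f"need >= 20 pairs, got {n}")

    blocks, names = [], []
    cst_cols: dict[str, list[int]] = {}
    col = 1  # intercept occupies column 0
    parts = [np.ones((n, 1))]
    names.append("intercept")
    for rsite, labels in remote_labels.items():
        labels = np.asarray(labels, dtype=int)
        if np.unique(labels).size < 2:
            raise ValueError(f"remote site {rsite} has < 2 CST levels")
        cols, levels = _sum_contrasts(labels)
        parts.append(cols)
        cst_cols[rsite] = list(range(col, col + cols.shape[1]))
        names.extend(f"cst_{rsite}_{lev}" for lev in levels[:-1])
        col += cols.shape[1]
    cov_design = patsy.dmatrix(
        "C(delivery_mode) + ga_birth + C(birth_season) + cr(wol, df=%d) - 1"
        % wol_df, covariates, return_type="dataframe")
    # drop aliased columns (e.g. a season absent from the data)
    cov = cov_design.to_numpy()
    keep = []
    running = np.hstack(parts)
    for j in range(cov.shape[1]):
        cand = np.hstack([running, cov[:, keep + [j]]])
        if np.linalg.matrix_rank(cand) > np.linalg.matrix_rank(
                np.hstack([running, cov[:, keep]])):
            keep.append(j)
    if len(keep) < cov.shape[1]:
        warnings.warn("dropped aliased covariate columns")
    parts.append(cov[:, keep])
    names.extend(np.asarray(cov_design.columns)[keep])
    x_full = np.hstack(parts)
    col_total = x_full.shape[1]

    groups = np.asarray(subject_ids)
    converged = True
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.MixedLM(y, x_full, groups=groups).fit(reml=False, method="lbfgs")
            converged = bool(res.converged)
        except Exception:
            res = sm.MixedLM(y, x_full, groups=groups).fit(reml=False)
            converged = bool(res.converged)

    params = np.asarray(res.fe_params)
    # ML underestimates the residual variance by ~ (n - p)/n; inflate the
    # fixed-effects covariance accordingly so Wald tests hold their level
    small_sample = n / max(n - col_total, 1)
    cov_p = np.asarray(res.cov_params())[:col_total, :col_total] * small_sample

    wald_p: dict[str, dict[int, float]] = {}
    direction: dict[str, dict[int, str]] = {}
    for rsite, cols in cst_cols.items():
        labels = np.asarray(remote_labels[rsite], dtype=int)
        levels = sorted(np.unique(labels))
        wald_p[rsite], direction[rsite] = {}, {}
        for j, lev in enumerate(levels):
            contrast = np.zeros(col_total)
            if j < len(cols):
                contrast[cols[j]] = 1.0
            else:  # last level = minus the sum of the coded levels
                contrast[cols] = -1.0
            est = float(contrast @ params)
            se = float(np.sqrt(contrast @ cov_p @ contrast))
            z = est / se if se > 0 else 0.0
            wald_p[rsite][lev] = float(2 * stats.norm.sf(abs(z)))
            direction[rsite][lev] = "increase" if est > 0 else "decrease"

    all_cst = [c for cols in cst_cols.values() for c in cols]
    df_resid = max(n - col_total, 1)

    def wald_f(cols):
        if not cols:
            return float("nan"), float("nan")
        r = np.zeros((len(cols), col_total))
        for i, c in enumerate(cols):
            r[i, c] = 1.0
        rb = r @ params
        vmat = r @ cov_p @ r.T
        try:
            stat = float(rb @ np.linalg.solve(vmat, rb)) / len(cols)
        except np.linalg.LinAlgError:
            return float("nan"), float("nan")
        return stat, float(stats.f.sf(stat, len(cols), df_resid))

    f_stat, f_p = wald_f(all_cst)
    f_by_site = {rsite: wald_f(cols)[1] for rsite, cols in cst_cols.items()}

    delta_r2 = 0.0
    if compute_delta and all_cst:
        delta_r2 = _marginal_r2(res, x_full) - _null_marginal_r2(
            y, x_full, all_cst, groups)
    return AssociationRecord(
        site=site, taxon=tuple(taxon), rank=rank, wald_p=wald_p,
        direction=direction, f_stat=f_stat, f_p=f_p,
        f_p_by_site=f_by_site, delta_pseudo_r2=float(delta_r2),
        converged=converged,
    )


def _marginal_r2(res, x) -> float:
    """Fixed-effects (marginal) pseudo-R2 of a fitted random-intercept model."""
    fixed = x @ np.asarray(res.fe_params)
    var_f = float(np.var(fixed))
    cov_re = np.asarray(res.cov_re)
    var_u = float(cov_re[0, 0]) if cov_re.size else 0.0
    var_e = float(res.scale)
    total = var_f + var_u + var_e
    return var_f / total if total > 0 else 0.0


def _null_marginal_r2(y, x_full, drop_cols, groups) -> float:
    import statsmodels.api as sm

    keep = [j for j in range(x_full.shape[1]) if j not in set(drop_cols)]
    x0 = x_full[:, keep]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for method in ("lbfgs", "bfgs", "powell"):
            try:
                res0 = sm.MixedLM(y, x0, groups=groups).fit(
                    reml=False, method=method)
                return _marginal_r2(res0, x0)
            except Exception:  # noqa: BLE001 - fall through to OLS bound
                continue
    # moment-based fallback: OLS fixed effects, subject-mean variance split
    beta, *_ = np.linalg.lstsq(x0, y, rcond=None)
    fixed = x0 @ beta
    resid = y - fixed
    groups = np.asarray(groups)
    means = pd.Series(resid).groupby(pd.Series(groups)).transform("mean")
    var_f = float(np.var(fixed))
    var_u = max(float(np.var(means)), 0.0)
    var_e = max(float(np.var(resid - means)), 1e-12)
    return var_f / (var_f + var_u + var_e)


def fdr_and_rollup(records: list[AssociationRecord], site: str, *,
                   fdr: float = 0.05) -> list[AssociationRecord]:
    """Benjamini-Hochberg at the outcome site, most-specific-taxon rollup.

    BH runs across the records' overall F-test p-values; among the
    survivors, a taxon is dropped when a strictly more specific
    significant taxon shares its lineage prefix (equally specific taxa
    are all kept).
    """
    from statsmodels.stats.multitest import multipletests

    records = [r for r in records if r.site == site]
    if not records:
        return []
    pvals = np.array([r.f_p for r in records])
    ok = np.isfinite(pvals)
    qvals = np.full(pvals.size, np.nan)
    if ok.any():
        _, q, _, _ = multipletests(pvals[ok], method="fdr_bh")
        qvals[ok] = q
    for r, q in zip(records, qvals):
        r.q = float(q)
    significant = [r for r, q in zip(records, qvals)
                   if np.isfinite(q) and q <= fdr]
    sig_taxa = {r.taxon for r in significant}
    out = []
    for r in significant:
        has_descendant = any(
            t != r.taxon and len(t) > len(r.taxon) and t[:len(r.taxon)] == r.taxon
            for t in sig_taxa)
        if not has_descendant:
            out.append(r)
    return out


def shared_otu_residual_corr(pairs: list[VisitPair], table_a: CountsTable,
                             table_b: CountsTable, pma, subject_ids, *,
                             ndim: int = 10) -> pd.DataFrame:
    """Residual correlations of OTUs shared between two sites.

    Each shared OTU's arcsine-sqrt relative abundance is regressed on a
    PMA smooth with a subject random intercept, separately per site;
    the per-pair residuals are then Pearson-correlated. OTUs constant
    in either site are skipped.
    """
    shared = [o for o in table_a.otu_ids if o in set(table_b.otu_ids)]
    if not shared:
        raise ValueError("no OTU shared between the two sites")
    pma = np.asarray(pma, dtype=float)
    ia = {s: i for i, s in enumerate(table_a.sample_ids)}
    ib = {s: i for i, s in enumerate(table_b.sample_ids)}
    rows_a = [ia[p.sample_a] for p in pairs]
    rows_b = [ib[p.sample_b] for p in pairs]
    rel_a = table_a.relative_abundance()[rows_a]
    rel_b = table_b.relative_abundance()[rows_b]
    ja = {o: j for j, o in enumerate(table_a.otu_ids)}
    jb = {o: j for j, o in enumerate(table_b.otu_ids)}
    basis, _ = bspline_design(pma, ndim)
    pen = difference_penalty(ndim)
    results = []
    for otu in shared:
        ya = arcsine_sqrt(rel_a[:, ja[otu]])
        yb = arcsine_sqrt(rel_b[:, jb[otu]])
        if np.std(ya) == 0 or np.std(yb) == 0:
            continue
        ra = ya - fit_penalized(ya, basis, pen, subject_ids).fitted
        rb = yb - fit_penalized(yb, basis, pen, subject_ids).fitted
        if np.std(ra) == 0 or np.std(rb) == 0:
            continue
        results.append({"otu": otu,
                        "correlation": float(np.corrcoef(ra, rb)[0, 1])})
    return pd.DataFrame(results, columns=["otu", "correlation"])
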