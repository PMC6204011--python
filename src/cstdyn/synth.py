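"""Synthetic longitudinal multi-site infant cohorts with known ground truth.

The generator emulates the sampling design of a NICU-followup study:
pre-term infants are swabbed weekly while hospitalized (until a
discharge post-menstrual age) and monthly afterwards, full-term infants
monthly from birth. At every visit and body site a latent community
state type (CST) is drawn from a multinomial-logistic model whose
linear predictor runs along that CST's own maturity index
``a*WOL + b*gaBirth``, so the ground-truth single-index weights are
known exactly. Counts are emitted from per-CST Dirichlet-Multinomial
components. Cross-site dependence is injected two ways: with
probability ``coupling`` a site copies the reference site's CST rank,
and OTUs shared between sites load on a common per-visit log-normal
factor, producing correlated residual abundance.

Nothing here is fit to real data; defaults mirror the cohort structure
(38 pre-term / 44 full-term, GA ranges, one-year follow-up) that the
analysis stages are designed for.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .types import (
    BIRTH_SEASONS,
    CountsTable,
    DELIVERY_MODES,
    SEXES,
    SITES,
    SubjectRecord,
    VisitSample,
)


@dataclass
class SiteSpec:
    """Generative spec for one body site: K CSTs with index dynamics and
    Dirichlet-Multinomial emissions.

    ``index_weights[k] = (a, b)`` defines CST k's maturity index
    a*WOL + b*gaBirth; ``midpoints``/``slopes`` place a logistic score
    s_k * (index_k - m_k) on that index, and CST probabilities are the
    softmax of the scores. ``alpha`` is the K x n_otus matrix of
    Dirichlet parameters.
    """

    n_otus: int = 60
    k: int = 4
    index_weights: list[tuple[float, float]] = field(default_factory=list)
    midpoints: list[float] = field(default_factory=list)
    slopes: list[float] = field(default_factory=list)
    alpha: np.ndarray | None = None
    base_alpha: float = 0.05
    dominant_alpha: float = 5.0

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.n_otus < 2:
            raise ValueError("n_otus must be >= 2")
        if not self.index_weights:
            self.index_weights = [(1.0, 0.0)] * self.k
        if len(self.index_weights) != self.k:
            raise ValueError("need one (a, b) pair per CST")
        if not self.midpoints:
            # spread CST onsets across the first year of life (index units)
            self.midpoints = list(np.linspace(2.0, 40.0, self.k))
        if not self.slopes:
            # first CST declines over time, the rest rise
            self.slopes = [-0.25] + [0.25] * (self.k - 1) if self.k > 1 else [0.0]
        if self.alpha is None:
            self.alpha = self._default_alpha()
        self.alpha = np.asarray(self.alpha, dtype=float)
        if self.alpha.shape != (self.k, self.n_otus):
            raise ValueError(
                f"alpha shape {self.alpha.shape} != ({self.k}, {self.n_otus})"
            )
        if np.any(self.alpha <= 0):
            raise ValueError("all Dirichlet parameters must be positive")

    def _default_alpha(self) -> np.ndarray:
        """Well-separated components: each CST dominates a distinct OTU block."""
        alpha = np.full((self.k, self.n_otus), self.base_alpha)
        block = max(1, self.n_otus // max(self.k, 1))
        for j in range(self.k):
            lo = j * block
            hi = min(lo + block, self.n_otus)
            alpha[j, lo:hi] = self.dominant_alpha
        return alpha


@dataclass
class SynthConfig:
    """Cohort-level generative configuration."""

    n_preterm: int = 38
    n_fullterm: int = 44
    ga_preterm_range: tuple[float, float] = (23.0, 35.9)
    ga_fullterm_mean: float = 39.6
    ga_fullterm_sd: float = 1.2
    ga_fullterm_bounds: tuple[float, float] = (37.0, 42.0)
    discharge_pma: float = 38.0
    followup_weeks: int = 52
    sites: dict[str, SiteSpec] = field(default_factory=dict)
    coupling: float = 0.0
    reference_site: str = "gut"
    library_log_mean: float = 8.5
    library_log_sd: float = 0.5
    n_shared_otus: int = 10
    shared_otu_loading: float = 0.0
    illness_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_preterm < 0 or self.n_fullterm < 0 or \
                self.n_preterm + self.n_fullterm < 1:
            raise ValueError("cohort must contain at least one subject")
        if not 0.0 <= self.coupling <= 1.0:
            raise ValueError("coupling must lie in [0, 1]")
        if not self.sites:
            self.sites = {s: SiteSpec() for s in SITES}
        for site in self.sites:
            if site not in SITES:
                raise ValueError(f"unknown site {site!r}")
        if self.reference_site not in self.sites:
            self.reference_site = next(iter(self.sites))
        for spec in self.sites.values():
            if self.n_shared_otus > spec.n_otus:
                raise ValueError("n_shared_otus exceeds a site's OTU count")


@dataclass
class GroundTruth:
    """Truth ledger for recovery tests."""

    labels: pd.DataFrame            # sample_id, subject_id, site, true_cst
    index_weights: dict[str, list[tuple[float, float]]]
    pattern_class: dict[str, list[str]]
    coupling: float


def emit_counts(cst: int, alpha: np.ndarray, library_size: int,
                rng: np.random.Generator) -> np.ndarray:
    """Draw one sample's counts from CST ``cst``'s Dirichlet-Multinomial.

    ``alpha`` is the K x n_otus component matrix; proportions are drawn
    from Dirichlet(alpha[cst]) and counts from a multinomial at the
    given library size, so the output always sums to ``library_size``.
    """
    alpha = np.atleast_2d(np.asarray(alpha, dtype=float))
    if np.any(alpha <= 0):
        raise ValueError("all Dirichlet parameters must be positive")
    if library_size < 1:
        raise ValueError("library_size must be >= 1")
    if not 0 <= cst < alpha.shape[0]:
        raise ValueError(f"cst {cst} out of range for {alpha.shape[0]} components")
    p = rng.dirichlet(alpha[cst])
    return rng.multinomial(library_size, p)


def _truth_class(a: float, b: float) -> str:
    """Pattern implied by the generative index weights alone."""
    if a <= 0:
        return "idiosyncratic"
    if b <= 0:
        return "chronological"
    ratio = np.log2(b / a)
    if abs(ratio) < 1:
        return "convergent"
    return "chronological" if ratio < -1 else "idiosyncratic"


def _visit_schedule(ga_birth: float, term: str, cfg: SynthConfig) -> list[float]:
    wols: list[float] = []
    if term == "pre":
        w = 0.0
        while ga_birth + w < cfg.discharge_pma:
            wols.append(w)
            w += 1.0
        while w <= cfg.followup_weeks:
            wols.append(w)
            w += 4.0
    else:
        wols = list(np.arange(0.0, cfg.followup_weeks + 1e-9, 4.0))
    return wols


def _cst_probs(spec: SiteSpec, wol: float, gab: float) -> np.ndarray:
    scores = np.empty(spec.k)
    for j in range(spec.k):
        a, b = spec.index_weights[j]
        idx = a * wol + b * gab
        scores[j] = spec.slopes[j] * (idx - spec.midpoints[j])
    scores -= scores.max()
    p = np.exp(scores)
    return p / p.sum()


def simulate_cohort(
    config: SynthConfig,
) -> tuple[list[SubjectRecord], list[VisitSample], dict[str, CountsTable], GroundTruth]:
    """Generate a full synthetic cohort, reproducible from ``config.seed``."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)

    subjects: list[SubjectRecord] = []
    for i in range(cfg.n_preterm + cfg.n_fullterm):
        pre = i < cfg.n_preterm
        if pre:
            lo, hi = cfg.ga_preterm_range
            ga = float(rng.uniform(lo, hi))
        else:
            lo, hi = cfg.ga_fullterm_bounds
            ga = float(np.clip(rng.normal(cfg.ga_fullterm_mean, cfg.ga_fullterm_sd),
                               lo, hi))
        subjects.append(SubjectRecord(
            subject_id=f"S{i:03d}",
            ga_birth=round(ga, 2),
            delivery_mode=str(rng.choice(DELIVERY_MODES)),
            birth_season=str(rng.choice(BIRTH_SEASONS)),
            sex=str(rng.choice(SEXES)),
            ethnicity=str(rng.choice(["hispanic", "non-hispanic"], p=[0.15, 0.85])),
        ))

    site_order = list(cfg.sites)
    otu_ids = {
        site: [f"shared_OTU{j:03d}" if j < cfg.n_shared_otus
               else f"{site}_OTU{j:03d}" for j in range(spec.n_otus)]
        for site, spec in cfg.sites.items()
    }
    samples: list[VisitSample] = []
    counts: dict[str, list[np.ndarray]] = {s: [] for s in site_order}
    site_sample_ids: dict[str, list[str]] = {s: [] for s in site_order}
    truth_rows = []
    n_sample = 0

    for subj in subjects:
        for wol in _visit_schedule(subj.ga_birth, subj.term_status, cfg):
            ill = bool(rng.random() < cfg.illness_rate)
            shared_z = float(rng.normal()) if cfg.shared_otu_loading else 0.0
            ref_label: int | None = None
            for site in site_order:
                spec = cfg.sites[site]
                probs = _cst_probs(spec, wol, subj.ga_birth)
                label = int(rng.choice(spec.k, p=probs))
                if site != cfg.reference_site and ref_label is not None \
                        and rng.random() < cfg.coupling:
                    label = min(ref_label, spec.k - 1)
                if site == cfg.reference_site:
                    ref_label = label
                alpha_row = spec.alpha[label].copy()
                if cfg.shared_otu_loading:
                    alpha_row[: cfg.n_shared_otus] *= np.exp(
                        cfg.shared_otu_loading * shared_z
                    )
                lib = max(1, int(np.round(
                    rng.lognormal(cfg.library_log_mean, cfg.library_log_sd)
                )))
                vec = emit_counts(0, alpha_row[None, :], lib, rng)
                sid = f"X{n_sample:05d}"
                n_sample += 1
                samples.append(VisitSample(
                    sample_id=sid, subject_id=subj.subject_id, site=site,
                    wol=wol, pma=subj.ga_birth + wol, illness_flag=ill,
                ))
                counts[site].append(vec)
                site_sample_ids[site].append(sid)
                truth_rows.append({
                    "sample_id": sid, "subject_id": subj.subject_id,
                    "site": site, "true_cst": label + 1,
                })

    tables = {
        site: CountsTable(
            sample_ids=site_sample_ids[site],
            otu_ids=otu_ids[site],
            counts=np.array(counts[site], dtype=np.int64),
            taxonomy={o: ("Bacteria", f"Phylum{j % 5}", f"Class{j % 5}",
                          f"Order{j % 10}", f"Family{j % 20}", f"Genus{j}",
                          f"species{j}")
                      for j, o in enumerate(otu_ids[site])},
        )
        for site in site_order
    }
    truth = GroundTruth(
        labels=pd.DataFrame(truth_rows),
        index_weights={s: list(cfg.sites[s].index_weights) for s in site_order},
        pattern_class={s: [_truth_class(a, b) for a, b in cfg.sites[s].index_weights]
                       for s in site_order},
        coupling=cfg.coupling,
    )
    return subjects, samples, tables, truth


def write_cohort(outdir, subjects, samples, tables, truth=None) -> dict[str, str]:
    """Write a simulated cohort in the package's TSV dialect."""
    from pathlib import Path
    from .io_prep import write_counts_tsv

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, str] = {}
    subj = {s.subject_id: s for s in subjects}
    meta = pd.DataFrame([{
        "sample_id": v.sample_id, "subject_id": v.subject_id, "site": v.site,
        "ga_birth": subj[v.subject_id].ga_birth, "wol": v.wol,
        "delivery_mode": subj[v.subject_id].delivery_mode,
        "birth_season": subj[v.subject_id].birth_season,
        "sex": subj[v.subject_id].sex,
        "ethnicity": subj[v.subject_id].ethnicity,
        "illness_flag": v.illness_flag,
    } for v in samples])
    meta_path = outdir / "metadata.tsv"
    meta.to_csv(meta_path, sep="\t", index=False)
    paths["metadata"] = str(meta_path)
    for site, table in tables.items():
        cpath = outdir / f"counts_{site}.tsv"
        tpath = outdir / f"taxonomy_{site}.tsv"
        write_counts_tsv(table, cpath, tpath)
        paths[f"counts_{site}"] = str(cpath)
        paths[f"taxonomy_{site}"] = str(tpath)
    if truth is not None:
        gpath = outdir / "ground_truth.tsv"
        truth.labels.to_csv(gpath, sep="\t", index=False)
        paths["ground_truth"] = str(gpath)
    return paths
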