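"""End-to-end orchestration: simulate/load -> CSTs -> temporal -> cross-site -> CCA.

A single config drives every stage; all randomness derives from the
config seed, and re-running with the same config reproduces
byte-identical output tables. Every written file is recorded in a
manifest with a content hash.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .cca import blocked_cv_cca, regress_out_time
from .cross_site import (
    cooccurrence_chisq,
    cst_probability_correlation,
    fdr_and_rollup,
    fit_taxon_models,
    pair_visits,
    shared_otu_residual_corr,
    taxon_abundances,
)
from .dmm import assign_cst, fit_dmm, select_k
from .io_prep import css_normalize, dmm_normalize, load_dataset, prevalence_filter
from .synth import SiteSpec, SynthConfig, simulate_cohort, write_cohort
from .temporal import classify_pattern, fit_single_index, occurrence_logistic_test


@dataclass
class PipelineConfig:
    outdir: str = "results"
    seed: int = 0
    sites: list[str] = field(default_factory=lambda: ["gut", "nasal", "throat"])
    # input mode: either synth parameters or per-site count paths + metadata
    synth: dict | None = None
    counts_paths: dict[str, str] = field(default_factory=dict)
    taxonomy_paths: dict[str, str] = field(default_factory=dict)
    metadata_path: str | None = None
    # stage parameters
    min_prev: float = 0.05
    norm_target: int = 5000
    k_max: int = 10
    select_reps: int = 10
    select_frac: float = 0.8
    n_restarts: int = 1
    wol_df: int = 14
    fdr: float = 0.05
    taxon_ranks: list[str] = field(default_factory=lambda: ["genus"])
    cca_folds: int = 10
    cca_components: int = 10
    cca_adjust_dfs: list[int] = field(default_factory=lambda: [14, 25])
    run_taxon_models: bool = True
    run_cca: bool = True
    run_temporal: bool = True

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _synth_config(cfg: PipelineConfig) -> SynthConfig:
    params = dict(cfg.synth or {})
    site_params = params.pop("sites", None)
    params.setdefault("seed", cfg.seed)
    sc = SynthConfig(**params)
    if site_params:
        sc.sites = {name: SiteSpec(**spec) for name, spec in site_params.items()}
    return sc


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; returns (and writes) the output manifest."""
    cfg = config
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    from . import __version__ as version

    manifest: dict = {
        "version": version, "config": cfg.to_dict(),
        "stages": [], "files": {}, "notices": [],
    }

    def record(name: str, path: Path):
        manifest["files"][name] = {"path": str(path), "sha256": _sha256(path)}

    def stage_done(name: str, t0: float):
        manifest["stages"].append({"stage": name,
                                   "seconds": round(time.time() - t0, 3)})

    try:
        # ---- input ----------------------------------------------------
        t0 = time.time()
        if cfg.synth is not None:
            subjects, samples, tables, truth = simulate_cohort(_synth_config(cfg))
            paths = write_cohort(outdir / "input", subjects, samples, tables, truth)
            for key, p in paths.items():
                record(f"input/{key}", Path(p))
        else:
            if cfg.metadata_path is None or not cfg.counts_paths:
                raise ValueError("config needs either synth parameters or input paths")
            tables, truth = {}, None
            subjects, samples = [], []
            seen = set()
            for site in cfg.sites:
                table, subj, samp = load_dataset(
                    cfg.counts_paths[site], cfg.metadata_path,
                    cfg.taxonomy_paths.get(site))
                tables[site] = table
                samples.extend(samp)
                for s in subj:
                    if s.subject_id not in seen:
                        seen.add(s.subject_id)
                        subjects.append(s)
        sites = [s for s in cfg.sites if s in tables]
        clean_ids = {v.sample_id for v in samples if not v.illness_flag}
        sample_of = {v.sample_id: v for v in samples}
        subject_of = {s.subject_id: s for s in subjects}
        stage_done("input", t0)

        # ---- CST inference per site -----------------------------------
        assignments, fits, chosen_ks = {}, {}, {}
        for si, site in enumerate(sites):
            t0 = time.time()
            table = tables[site]
            table = table.select_samples(
                [s for s in table.sample_ids if s in clean_ids])
            filtered = prevalence_filter(table, site, cfg.min_prev)
            normalized = dmm_normalize(filtered, cfg.norm_target)
            sel = select_k(normalized, k_max=cfg.k_max, reps=cfg.select_reps,
                           frac=cfg.select_frac, seed=cfg.seed + 13 * si,
                           n_restarts=cfg.n_restarts)
            chosen_ks[site] = sel.chosen_k
            fit = fit_dmm(normalized, sel.chosen_k, seed=cfg.seed + 13 * si,
                          n_restarts=max(cfg.n_restarts, 3))
            asg = assign_cst(fit, normalized)
            assignments[site], fits[site] = asg, fit

            sel_df = pd.DataFrame(sel.scores,
                                  columns=[f"K{k}" for k in sel.k_values])
            p = outdir / f"kselection_{site}.tsv"
            sel_df.to_csv(p, sep="\t", index=False, float_format="%.6f")
            record(f"kselection_{site}", p)
            fit_json = {
                "site": site, "k": fit.k, "pi": fit.pi.tolist(),
                "alpha": np.round(fit.alpha, 8).tolist(),
                "loglik": round(fit.loglik, 6), "n_iter": fit.n_iter,
                "converged": fit.converged, "otu_ids": fit.otu_ids,
                "chosen_k_rule": sel.rule,
            }
            p = outdir / f"dmm_fit_{site}.json"
            p.write_text(json.dumps(fit_json, indent=1, sort_keys=True))
            record(f"dmm_fit_{site}", p)
            asg_df = pd.DataFrame(
                asg.posterior,
                columns=[f"cst{k}_prob" for k in range(1, fit.k + 1)])
            asg_df.insert(0, "sample_id", asg.sample_ids)
            asg_df["cst"] = asg.map_label
            p = outdir / f"cst_assignments_{site}.tsv"
            asg_df.to_csv(p, sep="\t", index=False, float_format="%.6g")
            record(f"cst_assignments_{site}", p)
            stage_done(f"cst_{site}", t0)

        # ---- temporal models ------------------------------------------
        if cfg.run_temporal:
            t0 = time.time()
            pattern_rows = []
            for site in sites:
                asg = assignments[site]
                k = fits[site].k
                if k == 1:
                    manifest["notices"].append(
                        f"site {site}: single CST, temporal stage skipped")
                    continue
                meta = [sample_of[s] for s in asg.sample_ids]
                wol = np.array([v.wol for v in meta])
                gab = np.array([subject_of[v.subject_id].ga_birth for v in meta])
                subj = [v.subject_id for v in meta]
                for cst in range(1, k + 1):
                    probs = asg.posterior[:, cst - 1]
                    sif = fit_single_index(probs, wol, gab, subj, cst=cst)
                    occ_subjects = sorted(set(subj))
                    occ = [bool(np.any((asg.map_label == cst)
                                       & (np.array(subj) == s)))
                           for s in occ_subjects]
                    gab_s = [subject_of[s].ga_birth for s in occ_subjects]
                    p_occ, separated = occurrence_logistic_test(occ, gab_s)
                    pat = classify_pattern(sif.a, sif.b, p_occ, cst=cst)
                    pattern_rows.append({
                        "site": site, "cst": cst, "a": round(sif.a, 6),
                        "b": round(sif.b, 6),
                        "log2_ratio": round(pat.log2_ratio, 6),
                        "occurrence_p": f"{p_occ:.6g}",
                        "separated": separated,
                        "pattern": pat.pattern,
                        "indeterminate": sif.indeterminate,
                    })
            p = outdir / "cst_patterns.tsv"
            pd.DataFrame(pattern_rows).to_csv(p, sep="\t", index=False)
            record("cst_patterns", p)
            stage_done("temporal", t0)

        # ---- cross-site -----------------------------------------------
        t0 = time.time()
        label_maps = {
            site: dict(zip(assignments[site].sample_ids,
                           (int(x) for x in assignments[site].map_label)))
            for site in sites
        }
        pair_list = [(a, b) for i, a in enumerate(sites)
                     for b in sites[i + 1:]]
        chisq_rows, corr_frames = [], []
        for a, b in pair_list:
            pairs = pair_visits(samples, a, b)
            pairs = [p_ for p_ in pairs
                     if p_.sample_a in label_maps[a] and p_.sample_b in label_maps[b]]
            if len(pairs) < 10:
                manifest["notices"].append(f"pair {a}-{b}: too few pairs, skipped")
                continue
            if chosen_ks[a] > 1 and chosen_ks[b] > 1:
                chi2, pval = cooccurrence_chisq(pairs, label_maps[a], label_maps[b])
                chisq_rows.append({"site_a": a, "site_b": b,
                                   "n_pairs": len(pairs),
                                   "chi2": round(chi2, 4), "p": f"{pval:.6g}"})
                corr = cst_probability_correlation(
                    pairs, assignments[a], assignments[b])
                cf = pd.DataFrame(
                    corr,
                    index=[f"{a}_cst{i+1}" for i in range(corr.shape[0])],
                    columns=[f"{b}_cst{j+1}" for j in range(corr.shape[1])])
                cf.insert(0, "pair", f"{a}-{b}")
                corr_frames.append(cf.reset_index(names="cst_a"))
            pma = np.array([sample_of[p_.sample_a].pma for p_ in pairs])
            subj = [p_.subject_id for p_ in pairs]
            try:
                res = shared_otu_residual_corr(
                    pairs, tables[a].select_samples(
                        [p_.sample_a for p_ in pairs]),
                    tables[b].select_samples([p_.sample_b for p_ in pairs]),
                    pma, subj)
                res.insert(0, "pair", f"{a}-{b}")
                pth = outdir / f"shared_otu_corr_{a}_{b}.tsv"
                res.to_csv(pth, sep="\t", index=False, float_format="%.6f")
                record(f"shared_otu_corr_{a}_{b}", pth)
            except ValueError:
                manifest["notices"].append(f"pair {a}-{b}: no shared OTUs")
        if chisq_rows:
            p = outdir / "cooccurrence_chisq.tsv"
            pd.DataFrame(chisq_rows).to_csv(p, sep="\t", index=False)
            record("cooccurrence_chisq", p)
        if corr_frames:
            p = outdir / "cst_probability_correlations.tsv"
            pd.concat(corr_frames).to_csv(p, sep="\t", index=False,
                                          float_format="%.6f")
            record("cst_probability_correlations", p)

        if cfg.run_taxon_models and len(sites) >= 3:
            assoc_rows = []
            for outcome in sites:
                remotes = [s for s in sites if s != outcome]
                if any(chosen_ks[r] < 2 for r in remotes):
                    manifest["notices"].append(
                        f"site {outcome}: a remote site has a single CST; "
                        "taxon models skipped")
                    continue
                complete = _triple_complete_visits(samples, sites, clean_ids)
                keep = [v for v in complete
                        if all(v[s] in label_maps[s] for s in sites)]
                if len(keep) < 20:
                    manifest["notices"].append(
                        f"site {outcome}: too few complete visits")
                    continue
                out_tab = tables[outcome].select_samples(
                    [v[outcome] for v in keep])
                abunds = taxon_abundances(out_tab)
                covariates = pd.DataFrame({
                    "delivery_mode": [subject_of[v["subject_id"]].delivery_mode
                                      for v in keep],
                    "birth_season": [subject_of[v["subject_id"]].birth_season
                                     for v in keep],
                    "ga_birth": [subject_of[v["subject_id"]].ga_birth
                                 for v in keep],
                    "wol": [v["wol"] for v in keep],
                })
                subj = [v["subject_id"] for v in keep]
                remote_labels = {
                    r: np.array([label_maps[r][v[r]] for v in keep])
                    for r in remotes
                }
                rank_names = ("kingdom", "phylum", "class", "order",
                              "family", "genus", "species")
                records = []
                for taxon, vec in sorted(abunds.items()):
                    rank = rank_names[len(taxon) - 1] \
                        if len(taxon) <= 7 else "otu"
                    if cfg.taxon_ranks and rank not in cfg.taxon_ranks:
                        continue
                    if np.std(vec) == 0:
                        continue
                    try:
                        rec = fit_taxon_models(
                            vec, remote_labels, covariates, subj,
                            site=outcome, taxon=taxon, rank=rank,
                            wol_df=min(cfg.wol_df, len(keep) // 4))
                        records.append(rec)
                    except Exception as exc:  # noqa: BLE001
                        manifest["notices"].append(
                            f"taxon model failed ({outcome}, {taxon[-1]}): {exc}")
                significant = fdr_and_rollup(records, outcome, fdr=cfg.fdr)
                sig_taxa = {r.taxon for r in significant}
                for rec in records:
                    assoc_rows.append({
                        "site": rec.site, "taxon": ";".join(rec.taxon),
                        "rank": rec.rank, "f_stat": round(rec.f_stat, 4),
                        "f_p": f"{rec.f_p:.6g}", "q": f"{rec.q:.6g}",
                        "delta_pseudo_r2": round(rec.delta_pseudo_r2, 6),
                        "significant": rec.taxon in sig_taxa,
                        "wald_p": json.dumps(
                            {s: {str(k): f"{v:.4g}" for k, v in d.items()}
                             for s, d in rec.wald_p.items()}, sort_keys=True),
                        "direction": json.dumps(
                            {s: {str(k): v for k, v in d.items()}
                             for s, d in rec.direction.items()},
                            sort_keys=True),
                    })
            if assoc_rows:
                p = outdir / "taxon_associations.tsv"
                pd.DataFrame(assoc_rows).to_csv(p, sep="\t", index=False)
                record("taxon_associations", p)
        stage_done("cross_site", t0)

        # ---- CCA ------------------------------------------------------
        if cfg.run_cca:
            t0 = time.time()
            cca_rows = []
            for a, b in pair_list:
                pairs = pair_visits(samples, a, b)
                pairs = [p_ for p_ in pairs
                         if p_.sample_a in set(tables[a].sample_ids)
                         and p_.sample_b in set(tables[b].sample_ids)]
                subj = [p_.subject_id for p_ in pairs]
                if len(set(subj)) < cfg.cca_folds or len(pairs) < 30:
                    manifest["notices"].append(f"CCA {a}-{b}: too few subjects")
                    continue
                ta = tables[a].select_samples([p_.sample_a for p_ in pairs])
                tb = tables[b].select_samples([p_.sample_b for p_ in pairs])
                xa = css_normalize(prevalence_filter(ta, a, cfg.min_prev))
                xb = css_normalize(prevalence_filter(tb, b, cfg.min_prev))
                pma = np.array([sample_of[p_.sample_a].pma for p_ in pairs])
                variants = {"none": (xa, xb)}
                for df in cfg.cca_adjust_dfs:
                    variants[str(df)] = (
                        regress_out_time(xa, pma, df),
                        regress_out_time(xb, pma, df))
                for adj, (ua, ub) in variants.items():
                    res = blocked_cv_cca(
                        ua, ub, subj, folds=cfg.cca_folds,
                        n_components=cfg.cca_components,
                        seed=cfg.seed + 7, pair=(a, b), adjustment=adj)
                    for c in range(res.n_components):
                        cca_rows.append({
                            "pair": f"{a}-{b}", "adjustment": adj,
                            "component": c + 1,
                            "train_corr": round(
                                float(np.nanmean(res.train_corr[:, c])), 6),
                            "heldout_mean": round(float(res.heldout_mean[c]), 6),
                            "heldout_2sem": round(float(res.heldout_2sem[c]), 6),
                        })
            if cca_rows:
                p = outdir / "cca_results.tsv"
                pd.DataFrame(cca_rows).to_csv(p, sep="\t", index=False)
                record("cca_results", p)
            stage_done("cca", t0)
    except Exception as exc:
        manifest["failure"] = repr(exc)
        (outdir / "manifest.json").write_text(
            json.dumps(manifest, indent=1, sort_keys=True))
        raise

    mpath = outdir / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest


def _triple_complete_visits(samples, sites, clean_ids):
    """Visits at which every site was sampled (illness-free)."""
    by_visit: dict[tuple[str, float], dict] = {}
    for v in samples:
        if v.sample_id not in clean_ids:
            continue
        entry = by_visit.setdefault((v.subject_id, v.wol),
                                    {"subject_id": v.subject_id, "wol": v.wol})
        entry[v.site] = v.sample_id
    return [e for e in by_visit.values() if all(s in e for s in sites)]
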