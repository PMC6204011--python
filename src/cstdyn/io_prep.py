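"""Reading, validation, filtering, normalization, and cohort summaries.

Count tables travel as TSV (samples as rows, OTUs as columns) with a
taxonomy sidecar of semicolon-delimited lineages; a minimal BIOM-JSON
(format 1.0) reader is provided for interoperability with common 16S
exports. Metadata is a TSV with one row per sample.
"""

from __future__ import annotations

import json
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import numpy as np
import pandas as pd

from .types import (
    BIRTH_SEASONS,
    CountsTable,
    DELIVERY_MODES,
    ETHNICITIES,
    SEXES,
    SITES,
    SubjectRecord,
    VisitSample,
    parse_lineage,
)

REQUIRED_METADATA_COLUMNS = (
    "subject_id", "sample_id", "site", "ga_birth", "wol",
    "delivery_mode", "birth_season", "illness_flag",
)


def compute_pma(ga_birth: float, wol: float) -> float:
    """Post-menstrual age in weeks: gestational age at birth plus week of life."""
    if not 20.0 <= ga_birth <= 44.0:
        raise ValueError(f"ga_birth must be in [20, 44] weeks, got {ga_birth}")
    if wol < 0:
        raise ValueError(f"wol must be >= 0, got {wol}")
    return ga_birth + wol


def read_counts_tsv(counts_path: str | Path,
                    taxonomy_path: str | Path | None = None) -> CountsTable:
    """Read a samples x OTUs TSV; first column is the sample id."""
    df = pd.read_csv(counts_path, sep="\t", index_col=0)
    taxonomy: dict[str, tuple[str, ...]] = {}
    if taxonomy_path is not None:
        tax = pd.read_csv(taxonomy_path, sep="\t", index_col=0)
        col = tax.columns[0]
        taxonomy = {str(o): parse_lineage(str(l)) for o, l in tax[col].items()}
    counts = df.to_numpy()
    if not np.issubdtype(counts.dtype, np.number):
        raise ValueError("count table contains non-numeric entries")
    if np.any(counts != np.floor(counts)):
        raise ValueError("count table contains non-integer entries")
    return CountsTable(
        sample_ids=[str(s) for s in df.index],
        otu_ids=[str(o) for o in df.columns],
        counts=counts.astype(np.int64),
        taxonomy=taxonomy,
    )


def read_counts_biom_json(path: str | Path) -> CountsTable:
    """Read a BIOM format 1.0 (JSON) table; dense or sparse."""
    with open(path) as fh:
        doc = json.load(fh)
    otu_ids = [str(r["id"]) for r in doc["rows"]]
    sample_ids = [str(c["id"]) for c in doc["columns"]]
    shape = tuple(doc["shape"])
    mat = np.zeros(shape, dtype=np.int64)
    if doc.get("matrix_type") == "dense":
        mat[:] = np.asarray(doc["data"], dtype=np.int64)
    else:
        for r, c, v in doc["data"]:
            mat[int(r), int(c)] = int(v)
    taxonomy: dict[str, tuple[str, ...]] = {}
    for r in doc["rows"]:
        meta = r.get("metadata") or {}
        lineage = meta.get("taxonomy")
        if lineage:
            if isinstance(lineage, str):
                taxonomy[str(r["id"])] = parse_lineage(lineage)
            else:
                taxonomy[str(r["id"])] = parse_lineage(";".join(lineage))
    # BIOM stores observations (OTUs) as rows; transpose to samples x OTUs
    return CountsTable(
        sample_ids=sample_ids, otu_ids=otu_ids,
        counts=mat.T.copy(), taxonomy=taxonomy,
    )


def write_counts_tsv(table: CountsTable, counts_path: str | Path,
                     taxonomy_path: str | Path | None = None) -> None:
    table.to_frame().rename_axis("sample_id").to_csv(counts_path, sep="\t")
    if taxonomy_path is not None:
        rows = {o: ";".join(table.taxonomy.get(o, ())) for o in table.otu_ids}
        pd.Series(rows, name="lineage").rename_axis("otu_id").to_csv(
            taxonomy_path, sep="\t"
        )


def _parse_bool(x) -> bool:
    if isinstance(x, (bool, np.bool_)):
        return bool(x)
    s = str(x).strip().lower()
    if s in ("true", "1", "yes", "t"):
        return True
    if s in ("false", "0", "no", "f"):
        return False
    raise ValueError(f"cannot parse boolean {x!r}")


def load_dataset(
    counts_path: str | Path,
    metadata_path: str | Path,
    taxonomy_path: str | Path | None = None,
) -> tuple[CountsTable, list[SubjectRecord], list[VisitSample]]:
    """Load and join a count table with its sample metadata.

    Every sample in the counts table must appear in the metadata; the
    reverse need not hold (metadata may describe samples from other
    sites). PMA is computed as ga_birth + wol for every sample.
    """
    counts_path = Path(counts_path)
    if str(counts_path).endswith(".json") or str(counts_path).endswith(".biom"):
        table = read_counts_biom_json(counts_path)
    else:
        table = read_counts_tsv(counts_path, taxonomy_path)
    meta = pd.read_csv(metadata_path, sep="\t", dtype={"subject_id": str, "sample_id": str})
    missing_cols = set(REQUIRED_METADATA_COLUMNS) - set(meta.columns)
    if missing_cols:
        raise ValueError(f"metadata missing columns: {sorted(missing_cols)}")
    known = set(meta["sample_id"])
    absent = [s for s in table.sample_ids if s not in known]
    if absent:
        raise ValueError(
            f"metadata missing {len(absent)} sample(s) from the count table: "
            + ", ".join(absent[:10])
        )
    subjects: dict[str, SubjectRecord] = {}
    samples: list[VisitSample] = []
    wanted = set(table.sample_ids)
    for row in meta.itertuples(index=False):
        sid = str(row.subject_id)
        if sid not in subjects:
            subjects[sid] = SubjectRecord(
                subject_id=sid,
                ga_birth=float(row.ga_birth),
                delivery_mode=str(row.delivery_mode),
                birth_season=str(row.birth_season),
                sex=str(getattr(row, "sex", "female")),
                ethnicity=str(getattr(row, "ethnicity", "unknown")),
            )
        if str(row.sample_id) not in wanted:
            continue
        samples.append(VisitSample(
            sample_id=str(row.sample_id),
            subject_id=sid,
            site=str(row.site),
            wol=float(row.wol),
            pma=compute_pma(float(row.ga_birth), float(row.wol)),
            illness_flag=_parse_bool(row.illness_flag),
        ))
    order = {s: i for i, s in enumerate(table.sample_ids)}
    samples.sort(key=lambda v: order[v.sample_id])
    return table, list(subjects.values()), samples


def prevalence_filter(counts: CountsTable, site: str | None = None,
                      min_prev: float = 0.05) -> CountsTable:
    """Keep OTUs present (count > 0) in at least ``min_prev`` of samples.

    The table must already be restricted to a single body site (``site``
    labels error messages only). The threshold is inclusive: an OTU in
    exactly 5% of samples passes.
    """
    if counts.n_samples == 0:
        raise ValueError("empty count table")
    prevalence = (counts.counts > 0).mean(axis=0)
    keep = [o for o, p in zip(counts.otu_ids, prevalence) if p >= min_prev]
    if not keep:
        where = f" at site {site!r}" if site else ""
        raise ValueError(
            f"no OTU present in >= {min_prev:.0%} of {counts.n_samples} samples{where}"
        )
    return counts.select_otus(keep)


def dmm_normalize(counts: CountsTable, target: int = 5000) -> CountsTable:
    """Rescale each sample to ``target`` total counts, flooring to integers.

    Relative abundances are multiplied by the target library size and
    rounded down, so output row sums fall in
    [target - n_otus + 1, target].
    """
    rel = counts.relative_abundance()
    scaled = np.floor(rel * target).astype(np.int64)
    return CountsTable(
        sample_ids=list(counts.sample_ids),
        otu_ids=list(counts.otu_ids),
        counts=scaled,
        taxonomy=dict(counts.taxonomy),
    )


def arcsine_sqrt(relabund):
    """Variance-stabilizing arcsine-square-root transform for proportions."""
    x = np.asarray(relabund, dtype=float)
    if np.any(x < 0) or np.any(x > 1):
        raise ValueError("arcsine_sqrt input must lie in [0, 1]")
    out = np.arcsin(np.sqrt(x))
    return float(out) if np.isscalar(relabund) or out.ndim == 0 else out


def css_normalize(counts: CountsTable, quantile: float = 0.5) -> np.ndarray:
    """Cumulative-sum scaling normalization.

    Per sample, the scaling factor is the sum of counts at or below the
    chosen quantile of that sample's nonzero count distribution; counts
    are divided by the factor and multiplied by the median factor across
    samples so output stays on a count-like scale.
    """
    if counts.n_samples == 0 or counts.n_otus == 0:
        raise ValueError("empty count table")
    mat = counts.counts.astype(float)
    factors = np.empty(counts.n_samples)
    for i in range(counts.n_samples):
        row = mat[i]
        nz = row[row > 0]
        if nz.size == 0:
            raise ValueError(f"sample {counts.sample_ids[i]!r} has all-zero counts")
        q = np.quantile(nz, quantile)
        factors[i] = row[row <= q].sum()
        if factors[i] == 0:
            factors[i] = nz.min()
    return mat / factors[:, None] * np.median(factors)


def _pct(numer: int, denom: int) -> float:
    """Percentage rounded half-up to one decimal; 0.0 for an empty denominator."""
    if denom == 0:
        return 0.0
    val = Decimal(numer) / Decimal(denom) * Decimal(100)
    return float(val.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def summarize_cohort(
    subjects: list[SubjectRecord],
    samples: list[VisitSample],
    discharge_pma: float = 38.0,
) -> pd.DataFrame:
    """Cohort demographics per term-status group.

    Categorical percentages use the group size as denominator except for
    ethnicity, which uses the known-ethnicity count. Per-site sample
    rows split counts into hospital (PMA below ``discharge_pma`` for a
    pre-term subject) versus post-discharge.
    """
    if not subjects:
        raise ValueError("empty cohort")
    groups = {"pre": [s for s in subjects if s.term_status == "pre"],
              "full": [s for s in subjects if s.term_status == "full"]}
    term_of = {s.subject_id: s.term_status for s in subjects}
    ga_of = {s.subject_id: s.ga_birth for s in subjects}
    rows = []

    def add(variable, level, stat, pre_val, full_val):
        rows.append({"variable": variable, "level": level, "statistic": stat,
                     "pre": pre_val, "full": full_val})

    n_pre, n_full = len(groups["pre"]), len(groups["full"])
    add("subjects", "", "n", n_pre, n_full)
    ga = {k: np.array([s.ga_birth for s in v]) if v else np.array([np.nan])
          for k, v in groups.items()}
    add("ga_birth", "", "mean", round(float(np.mean(ga["pre"])), 2),
        round(float(np.mean(ga["full"])), 2))
    add("ga_birth", "", "sd", round(float(np.std(ga["pre"], ddof=1)), 2)
        if n_pre > 1 else 0.0,
        round(float(np.std(ga["full"], ddof=1)), 2) if n_full > 1 else 0.0)

    categoricals = [
        ("sex", SEXES, lambda s: s.sex, None),
        ("delivery_mode", DELIVERY_MODES, lambda s: s.delivery_mode, None),
        ("birth_season", BIRTH_SEASONS, lambda s: s.birth_season, None),
        ("ethnicity", [e for e in ETHNICITIES if e != "unknown"],
         lambda s: s.ethnicity, lambda g: sum(1 for s in g if s.ethnicity != "unknown")),
    ]
    for variable, levels, getter, denom_fn in categoricals:
        for level in levels:
            counts = {k: sum(1 for s in v if getter(s) == level)
                      for k, v in groups.items()}
            denoms = {k: (denom_fn(v) if denom_fn else len(v))
                      for k, v in groups.items()}
            add(variable, level, "n", counts["pre"], counts["full"])
            add(variable, level, "pct",
                _pct(counts["pre"], denoms["pre"]),
                _pct(counts["full"], denoms["full"]))

    clean = [v for v in samples if not v.illness_flag]
    for site in SITES:
        for phase in ("hospital", "post-discharge"):
            counts = {"pre": 0, "full": 0}
            for v in clean:
                if v.site != site:
                    continue
                term = term_of.get(v.subject_id)
                if term is None:
                    continue
                in_hospital = term == "pre" and v.pma < discharge_pma
                if (phase == "hospital") == in_hospital:
                    counts[term] += 1
            add(f"samples_{site}", phase, "n", counts["pre"], counts["full"])
    return pd.DataFrame(rows)
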