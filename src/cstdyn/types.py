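"""Core domain containers: subjects, visit samples, and OTU count tables."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

TERM_STATUSES = ("pre", "full")
DELIVERY_MODES = ("c-section", "vaginal")
BIRTH_SEASONS = ("winter", "spring", "summer", "fall")
SEXES = ("male", "female")
ETHNICITIES = ("hispanic", "non-hispanic", "unknown")
SITES = ("gut", "nasal", "throat")

TAXONOMIC_RANKS = (
    "kingdom", "phylum", "class", "order", "family", "genus", "species",
)


@dataclass(frozen=True)
class SubjectRecord:
    """One enrolled infant.

    ``term_status`` is derived from gestational age at birth: infants born
    before 37 completed weeks are pre-term.
    """

    subject_id: str
    ga_birth: float
    delivery_mode: str
    birth_season: str
    sex: str
    ethnicity: str = "unknown"

    def __post_init__(self) -> None:
        if not 20.0 <= self.ga_birth <= 44.0:
            raise ValueError(
                f"ga_birth must be in [20, 44] weeks, got {self.ga_birth}"
            )
        for value, vocab, name in (
            (self.delivery_mode, DELIVERY_MODES, "delivery_mode"),
            (self.birth_season, BIRTH_SEASONS, "birth_season"),
            (self.sex, SEXES, "sex"),
            (self.ethnicity, ETHNICITIES, "ethnicity"),
        ):
            if value not in vocab:
                raise ValueError(f"{name}={value!r} not in {vocab}")

    @property
    def term_status(self) -> str:
        return "pre" if self.ga_birth < 37.0 else "full"


@dataclass(frozen=True)
class VisitSample:
    """One swab: a (subject, site, week-of-life) observation.

    Post-menstrual age is definitionally ``ga_birth + wol``; it is stored
    so downstream stages never need the subject table to recover it.
    Samples flagged as collected during an acute respiratory illness are
    excluded from every analysis stage.
    """

    sample_id: str
    subject_id: str
    site: str
    wol: float
    pma: float
    illness_flag: bool = False

    def __post_init__(self) -> None:
        if self.site not in SITES:
            raise ValueError(f"site={self.site!r} not in {SITES}")
        if self.wol < 0:
            raise ValueError(f"wol must be >= 0, got {self.wol}")


def parse_lineage(lineage: str) -> tuple[str, ...]:
    """Split a semicolon-delimited lineage, dropping empty trailing ranks."""
    parts = [p.strip() for p in lineage.split(";")]
    while parts and not parts[-1]:
        parts.pop()
    if len(parts) > len(TAXONOMIC_RANKS):
        raise ValueError(f"lineage has more than 7 ranks: {lineage!r}")
    if any(not p for p in parts):
        raise ValueError(f"lineage has an internal missing rank: {lineage!r}")
    return tuple(parts)


@dataclass
class CountsTable:
    """Samples x OTUs non-negative integer matrix with taxonomy lineages.

    ``taxonomy`` maps each OTU id to a lineage tuple of up to 7 ranks
    (kingdom -> species); missing ranks are allowed only at the tail.
    """

    sample_ids: list[str]
    otu_ids: list[str]
    counts: np.ndarray
    taxonomy: dict[str, tuple[str, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.sample_ids), len(self.otu_ids)):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.otu_ids)} OTUs"
            )
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample ids")
        if len(set(self.otu_ids)) != len(self.otu_ids):
            raise ValueError("duplicate OTU ids")
        if np.any(self.counts < 0):
            bad = np.argwhere(self.counts < 0)[0]
            raise ValueError(
                f"negative count at sample {self.sample_ids[bad[0]]!r}, "
                f"OTU {self.otu_ids[bad[1]]!r}"
            )

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_otus(self) -> int:
        return len(self.otu_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts, index=self.sample_ids, columns=self.otu_ids
        )

    def select_samples(self, sample_ids: list[str]) -> "CountsTable":
        idx = {s: i for i, s in enumerate(self.sample_ids)}
        rows = [idx[s] for s in sample_ids]
        return CountsTable(
            sample_ids=list(sample_ids),
            otu_ids=list(self.otu_ids),
            counts=self.counts[rows],
            taxonomy=dict(self.taxonomy),
        )

    def select_otus(self, otu_ids: list[str]) -> "CountsTable":
        idx = {o: i for i, o in enumerate(self.otu_ids)}
        cols = [idx[o] for o in otu_ids]
        return CountsTable(
            sample_ids=list(self.sample_ids),
            otu_ids=list(otu_ids),
            counts=self.counts[:, cols],
            taxonomy={o: self.taxonomy[o] for o in otu_ids if o in self.taxonomy},
        )

    def relative_abundance(self) -> np.ndarray:
        totals = self.counts.sum(axis=1, keepdims=True).astype(float)
        if np.any(totals == 0):
            i = int(np.argwhere(totals[:, 0] == 0)[0][0])
            raise ValueError(f"sample {self.sample_ids[i]!r} has zero total count")
        return self.counts / totals
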