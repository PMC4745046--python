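"""Cohort tables, relative abundances, transition pairing and taxon selection.

The canonical wide layout has one row per stool sample with the metadata
columns below followed by one integer count column per taxon.  Taxon names
are case-normalized to title case except the literal ``unclassified``, which
is a first-class taxon.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from tsdbn.errors import DegenerateSampleError, ParseError, SchemaError

#: Continuous clinical covariates observed at slice t.
CONTINUOUS_COVARIATES: tuple[str, ...] = (
    "day_of_life",
    "gestational_age_at_birth",
    "postconceptional_age",
    "antibiotics",
)

#: Discrete clinical covariates observed at slice t.
DISCRETE_COVARIATES: tuple[str, ...] = ("open_room",)

METADATA_COLUMNS: tuple[str, ...] = (
    ("subject_id",) + CONTINUOUS_COVARIATES + DISCRETE_COVARIATES
)

#: Suffixes used in transition-pair frames.
SOURCE_SUFFIX = ":t"
TARGET_SUFFIX = ":t1"


def normalize_taxon_name(name: str) -> str:
    """Case-normalize a taxon name; ``unclassified`` stays lowercase."""
    name = str(name).strip()
    if name.lower() == "unclassified":
        return "unclassified"
    return name[:1].upper() + name[1:]


@dataclass(frozen=True)
class SampleRecord:
    """One stool sample: identifiers, covariates and per-taxon counts."""

    subject_id: str
    day_of_life: int
    gestational_age_at_birth: float
    postconceptional_age: float
    antibiotics: float
    open_room: str
    counts: Mapping[str, int]

    @property
    def total_count(self) -> int:
        return int(sum(self.counts.values()))


@dataclass(frozen=True)
class AbundanceProfile:
    """A composition over taxa: nonnegative values summing to one."""

    values: Mapping[str, float]

    def __post_init__(self) -> None:
        total = float(sum(self.values.values()))
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"abundance profile sums to {total!r}, not 1")

    def as_array(self, taxa: Sequence[str]) -> np.ndarray:
        return np.array([self.values.get(t, 0.0) for t in taxa], dtype=float)


def to_relative_abundance(counts: Mapping[str, float]) -> AbundanceProfile:
    """Convert raw taxon counts to proportions of the sample total.

    Raises
    ------
    DegenerateSampleError
        If every count is zero.
    """
    total = float(sum(counts.values()))
    if total <= 0:
        raise DegenerateSampleError("sample has zero total count")
    return AbundanceProfile({k: v / total for k, v in counts.items()})


@dataclass
class CohortTable:
    """Wide per-sample table plus the ordered taxon universe.

    ``frame`` holds one row per sample with :data:`METADATA_COLUMNS` followed
    by one count column per taxon, sorted by (subject_id, day_of_life).
    """

    frame: pd.DataFrame
    taxa: list[str] = field(default_factory=list)
    provenance: list = field(default_factory=list)

    def __post_init__(self) -> None:
        missing = [c for c in METADATA_COLUMNS if c not in self.frame.columns]
        if missing:
            raise SchemaError(f"missing required column(s): {', '.join(missing)}")
        if not self.taxa:
            self.taxa = [
                c for c in self.frame.columns if c not in METADATA_COLUMNS
            ]
        for taxon in self.taxa:
            col = self.frame[taxon]
            if (col < 0).any():
                row = int(col.lt(0).idxmax())
                raise ParseError(f"negative count for {taxon!r} at row {row}")
        self.frame = self.frame.sort_values(
            ["subject_id", "day_of_life"], kind="mergesort"
        ).reset_index(drop=True)

    @property
    def n_samples(self) -> int:
        return len(self.frame)

    @property
    def subject_ids(self) -> list[str]:
        return list(dict.fromkeys(self.frame["subject_id"]))

    @property
    def n_subjects(self) -> int:
        return self.frame["subject_id"].nunique()

    def count_matrix(self) -> np.ndarray:
        return self.frame[self.taxa].to_numpy(dtype=float)

    def abundance_matrix(self) -> np.ndarray:
        """Per-sample relative abundances over the full taxon universe."""
        counts = self.count_matrix()
        totals = counts.sum(axis=1, keepdims=True)
        if (totals <= 0).any():
            bad = int(np.argmax(totals.ravel() <= 0))
            raise DegenerateSampleError(f"sample row {bad} has zero total count")
        return counts / totals

    def samples(self) -> Iterable[SampleRecord]:
        for _, row in self.frame.iterrows():
            yield SampleRecord(
                subject_id=row["subject_id"],
                day_of_life=int(row["day_of_life"]),
                gestational_age_at_birth=float(row["gestational_age_at_birth"]),
                postconceptional_age=float(row["postconceptional_age"]),
                antibiotics=float(row["antibiotics"]),
                open_room=str(row["open_room"]),
                counts={t: int(row[t]) for t in self.taxa},
            )

    def subset_subjects(self, subject_ids: Iterable[str]) -> "CohortTable":
        keep = set(subject_ids)
        sub = self.frame[self.frame["subject_id"].isin(keep)].copy()
        return CohortTable(sub.reset_index(drop=True), taxa=list(self.taxa))

    def to_csv(self, path: str | Path) -> None:
        self.frame.to_csv(path, index=False)

    def to_long_frame(self) -> pd.DataFrame:
        """Long format: one row per (sample, taxon) with count and proportion."""
        abund = self.abundance_matrix()
        long = self.frame.melt(
            id_vars=list(METADATA_COLUMNS),
            value_vars=self.taxa,
            var_name="taxon",
            value_name="count",
        )
        abund_df = pd.DataFrame(abund, columns=self.taxa)
        abund_long = abund_df.melt(var_name="taxon", value_name="rel_abundance")
        long["rel_abundance"] = abund_long["rel_abundance"].to_numpy()
        return long


def _coerce_counts(frame: pd.DataFrame, taxa: Sequence[str]) -> pd.DataFrame:
    for taxon in taxa:
        col = pd.to_numeric(frame[taxon], errors="coerce")
        if col.isna().any():
            row = int(col.isna().idxmax())
            raise ParseError(f"non-numeric count for {taxon!r} at row {row}")
        if (col < 0).any():
            row = int(col.lt(0).idxmax())
            raise ParseError(f"negative count for {taxon!r} at row {row}")
        frame[taxon] = col.round().astype(np.int64)
    return frame


def read_samples(
    path: str | Path,
    format: str = "csv",
    column_map: Mapping[str, str] | None = None,
    on_duplicate_day: str = "reject",
    sheet: str | int = 0,
) -> CohortTable:
    """Read a longitudinal cohort table from CSV/TSV (or the study xlsx).

    Parameters
    ----------
    path
        File to read.
    format
        ``csv``, ``tsv`` or ``study-xlsx``.
    column_map
        Optional mapping from file headers to canonical column names
        (:data:`METADATA_COLUMNS`); unmapped non-metadata columns are taxa.
    on_duplicate_day
        ``reject`` (default) errors on two samples of one subject on the
        same day; ``sum`` pools their counts instead.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "csv":
        frame = pd.read_csv(path)
    elif format == "tsv":
        frame = pd.read_csv(path, sep="\t")
    elif format == "study-xlsx":
        frame = pd.read_excel(path, sheet_name=sheet)
    else:
        raise ValueError(f"unknown format {format!r}")

    if column_map:
        frame = frame.rename(columns=dict(column_map))
    missing = [c for c in METADATA_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")

    taxa = [normalize_taxon_name(c) for c in frame.columns if c not in METADATA_COLUMNS]
    frame = frame.rename(
        columns={
            c: normalize_taxon_name(c)
            for c in frame.columns
            if c not in METADATA_COLUMNS
        }
    )
    if not taxa:
        raise SchemaError("no taxon count columns found")
    frame = _coerce_counts(frame, taxa)
    frame["day_of_life"] = pd.to_numeric(frame["day_of_life"]).astype(np.int64)

    dup = frame.duplicated(subset=["subject_id", "day_of_life"], keep=False)
    if dup.any():
        if on_duplicate_day == "reject":
            pair = frame.loc[dup, ["subject_id", "day_of_life"]].iloc[0]
            raise ParseError(
                "duplicate sample for subject "
                f"{pair['subject_id']!r} on day {int(pair['day_of_life'])}"
            )
        if on_duplicate_day == "sum":
            meta = [c for c in METADATA_COLUMNS if c not in ("subject_id", "day_of_life")]
            agg = {t: "sum" for t in taxa}
            agg.update({c: "first" for c in meta})
            frame = (
                frame.groupby(["subject_id", "day_of_life"], as_index=False)
                .agg(agg)[list(METADATA_COLUMNS) + taxa]
            )
        else:
            raise ValueError(f"unknown on_duplicate_day {on_duplicate_day!r}")

    return CohortTable(frame.reset_index(drop=True), taxa=taxa)


@dataclass
class TransitionTable:
    """Paired consecutive same-subject samples, one row per transition.

    Columns: ``subject_id``, ``gap_days``, ``target_day``, then every model
    variable at slice t (suffix ``:t``) and every taxon (and discrete
    covariate) at slice t+1 (suffix ``:t1``).  Taxon values are relative
    abundances over the full taxon universe.
    """

    frame: pd.DataFrame
    taxa: list[str]
    continuous_covariates: list[str] = field(
        default_factory=lambda: list(CONTINUOUS_COVARIATES)
    )
    discrete_covariates: list[str] = field(
        default_factory=lambda: list(DISCRETE_COVARIATES)
    )

    @property
    def n_pairs(self) -> int:
        return len(self.frame)

    @property
    def continuous_variables(self) -> list[str]:
        return list(self.taxa) + list(self.continuous_covariates)

    def source_values(self, name: str) -> np.ndarray:
        return self.frame[name + SOURCE_SUFFIX].to_numpy()

    def target_values(self, name: str) -> np.ndarray:
        return self.frame[name + TARGET_SUFFIX].to_numpy()

    def has_target(self, name: str) -> bool:
        return name + TARGET_SUFFIX in self.frame.columns

    def subset(self, mask: np.ndarray) -> "TransitionTable":
        return TransitionTable(
            self.frame[mask].reset_index(drop=True),
            taxa=list(self.taxa),
            continuous_covariates=list(self.continuous_covariates),
            discrete_covariates=list(self.discrete_covariates),
        )

    def to_csv(self, path: str | Path) -> None:
        self.frame.to_csv(path, index=False)


def build_transition_table(cohort: CohortTable) -> TransitionTable:
    """Pair each sample with the immediately preceding one per subject.

    A subject with k samples contributes exactly k-1 pairs; pairs never
    cross subjects.  Taxon columns are converted to relative abundances.
    """
    abund = cohort.abundance_matrix()
    frame = cohort.frame
    same_subject = (
        frame["subject_id"].to_numpy()[1:] == frame["subject_id"].to_numpy()[:-1]
    )
    src = np.flatnonzero(same_subject)
    tgt = src + 1

    cols: dict[str, np.ndarray] = {
        "subject_id": frame["subject_id"].to_numpy()[src],
        "gap_days": (
            frame["day_of_life"].to_numpy()[tgt] - frame["day_of_life"].to_numpy()[src]
        ),
        "target_day": frame["day_of_life"].to_numpy()[tgt],
    }
    taxon_index = {t: i for i, t in enumerate(cohort.taxa)}
    for taxon, j in taxon_index.items():
        cols[taxon + SOURCE_SUFFIX] = abund[src, j]
        cols[taxon + TARGET_SUFFIX] = abund[tgt, j]
    for cov in CONTINUOUS_COVARIATES:
        cols[cov + SOURCE_SUFFIX] = frame[cov].to_numpy(dtype=float)[src]
    for cov in DISCRETE_COVARIATES:
        cols[cov + SOURCE_SUFFIX] = frame[cov].to_numpy()[src]
        cols[cov + TARGET_SUFFIX] = frame[cov].to_numpy()[tgt]
    out = pd.DataFrame(cols)
    if len(out) and (out["gap_days"] < 1).any():
        raise ParseError("non-positive gap between consecutive samples")
    return TransitionTable(out, taxa=list(cohort.taxa))


def select_taxa(
    cohort: CohortTable,
    network=None,
    min_fraction: float = 0.01,
) -> list[str]:
    """Taxa used for modeling/error: in the network, or >= min_fraction once.

    Order follows the cohort's taxon universe (canonical ordering).
    """
    if not 0.0 <= min_fraction <= 1.0:
        raise ValueError("min_fraction must be in [0, 1]")
    in_network: set[str] = set()
    if network is not None:
        taxa_set = set(cohort.taxa)
        for child, parents in network.parent_sets.items():
            if child in taxa_set and parents:
                in_network.add(child)
            in_network.update(p for p in parents if p in taxa_set)
    abund = cohort.abundance_matrix()
    peaks = abund.max(axis=0)
    keep = {
        t for t, peak in zip(cohort.taxa, peaks) if peak >= min_fraction and peak > 0
    }
    if min_fraction == 0.0:
        keep = set(cohort.taxa)
    keep |= in_network
    return [t for t in cohort.taxa if t in keep]
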