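"""Domain types, table readers/writers, dose-group assignment and run configuration.

All tables are tab-separated UTF-8 with a header row. Abundance and count
matrices store features in rows and samples in columns, first column holding
the feature identifier. Sample metadata carries the covariates used throughout
the analysis: lifetime external gamma dose (mGy), age (years), BMI, smoking
and alcohol status.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "DOSE_GROUPS",
    "DomixError",
    "ValidationError",
    "RunConfig",
    "SampleMetadata",
    "AbundanceMatrix",
    "CountMatrix",
    "FeatureMap",
    "GeneSetCollection",
    "StudyBundle",
    "assign_dose_group",
    "read_metadata",
    "read_matrix",
    "read_counts",
    "read_feature_map",
    "read_gmt",
    "write_gmt",
    "read_study",
    "write_feature_report",
]

#: Ordered dose-group labels, from unexposed controls to > 500 mGy.
DOSE_GROUPS = ("control", "low", "medium", "high")


class DomixError(Exception):
    """Base class for package errors."""


class ValidationError(DomixError):
    """Raised when an input violates a structural invariant."""


def assign_dose_group(dose_mGy: float, boundaries: tuple[float, float] = (100.0, 500.0)) -> str:
    """Assign the categorical dose group for a lifetime external dose.

    Zero dose marks unexposed controls; doses strictly below the first
    boundary are "low"; doses in the closed interval [low, high] are
    "medium"; doses strictly above the second boundary are "high".

    Parameters
    ----------
    dose_mGy
        Total external gamma dose in milligray; must be non-negative.
    boundaries
        Strictly increasing (low, high) cut points in mGy. The default
        (100, 500) reproduces the conventional occupational binning
        <100 / 100-500 / >500 mGy.
    """
    lo, hi = boundaries
    if not lo < hi:
        raise ValidationError(f"dose-group boundaries must increase: {boundaries}")
    if not np.isfinite(dose_mGy) or dose_mGy < 0:
        raise ValidationError(f"dose must be a non-negative finite number, got {dose_mGy}")
    if dose_mGy == 0:
        return "control"
    if dose_mGy < lo:
        return "low"
    if dose_mGy <= hi:
        return "medium"
    return "high"


@dataclass(frozen=True)
class RunConfig:
    """Tunable analysis parameters with the pipeline defaults.

    fdr_level: Storey-q selection level for the group-wise stage.
    posthoc_alpha: significance level of the many-to-one post-hoc tests.
    min_total_counts: transcripts with a smaller library-wide total are
        discarded before differential expression.
    storey_lambda: fixed lambda of the pi0 estimator.
    dose_boundaries: dose-group cut points in mGy.
    integration_protein_p: which proteomics p enters the combined p-value,
        "mannwhitney" (dedicated two-group test) or "dunnett" (high-group
        adjusted post-hoc p).
    """

    fdr_level: float = 0.05
    posthoc_alpha: float = 0.05
    min_total_counts: int = 15
    storey_lambda: float = 0.5
    seed: int = 0
    dose_boundaries: tuple[float, float] = (100.0, 500.0)
    remove_outliers: bool = False
    integration_protein_p: str = "mannwhitney"
    enrichment_alpha: float = 0.05

    def __post_init__(self) -> None:
        if not 0 < self.fdr_level < 1:
            raise ValidationError(f"fdr_level must be in (0,1), got {self.fdr_level}")
        if not 0 < self.posthoc_alpha < 1:
            raise ValidationError(f"posthoc_alpha must be in (0,1), got {self.posthoc_alpha}")
        if not 0 < self.storey_lambda < 1:
            raise ValidationError(f"storey_lambda must be in (0,1), got {self.storey_lambda}")
        lo, hi = self.dose_boundaries
        if not lo < hi:
            raise ValidationError("dose boundaries must be strictly increasing")
        if self.min_total_counts < 0:
            raise ValidationError("min_total_counts must be non-negative")
        if self.integration_protein_p not in ("mannwhitney", "dunnett"):
            raise ValidationError(
                f"integration_protein_p must be 'mannwhitney' or 'dunnett', got {self.integration_protein_p!r}"
            )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: Mapping) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        kwargs = dict(raw)
        if "dose_boundaries" in kwargs:
            kwargs["dose_boundaries"] = tuple(float(b) for b in kwargs["dose_boundaries"])
        return cls(**kwargs)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["dose_boundaries"] = list(self.dose_boundaries)
        return d


class SampleMetadata:
    """Per-sample covariate table.

    Wraps a DataFrame indexed by unique sample id with columns
    ``dose_mGy, dose_group, age_years, bmi, smoker, drinker``. The dose
    group is always (re)derived from the dose so the two can never drift
    apart.
    """

    REQUIRED = ("dose_mGy", "age_years", "bmi", "smoker", "drinker")

    def __init__(self, frame: pd.DataFrame, boundaries: tuple[float, float] = (100.0, 500.0)):
        frame = frame.copy()
        if "sample_id" in frame.columns:
            frame = frame.set_index("sample_id")
        frame.index = frame.index.astype(str)
        frame.index.name = "sample_id"
        if frame.index.has_duplicates:
            dups = frame.index[frame.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample_id values: {dups}")
        missing = [c for c in self.REQUIRED if c not in frame.columns]
        if missing:
            raise ValidationError(f"metadata missing required columns: {missing}")
        if (frame["age_years"] <= 0).any():
            raise ValidationError("age_years must be positive")
        if (frame["bmi"] <= 0).any():
            raise ValidationError("bmi must be positive")
        frame["dose_group"] = [assign_dose_group(d, boundaries) for d in frame["dose_mGy"]]
        frame["smoker"] = frame["smoker"].astype(bool)
        frame["drinker"] = frame["drinker"].astype(bool)
        self.frame = frame
        self.boundaries = boundaries

    @property
    def sample_ids(self) -> list[str]:
        return list(self.frame.index)

    @property
    def dose(self) -> np.ndarray:
        return self.frame["dose_mGy"].to_numpy(float)

    @property
    def age(self) -> np.ndarray:
        return self.frame["age_years"].to_numpy(float)

    @property
    def bmi(self) -> np.ndarray:
        return self.frame["bmi"].to_numpy(float)

    @property
    def dose_group(self) -> pd.Series:
        return self.frame["dose_group"]

    def group_samples(self, group: str) -> list[str]:
        return list(self.frame.index[self.frame["dose_group"] == group])

    def subset(self, sample_ids: Sequence[str]) -> "SampleMetadata":
        return SampleMetadata(self.frame.loc[list(sample_ids)].reset_index(), self.boundaries)

    def __len__(self) -> int:
        return len(self.frame)

    def to_tsv(self, path: str | Path) -> None:
        out = self.frame.reset_index()[
            ["sample_id", "dose_mGy", "age_years", "bmi", "smoker", "drinker"]
        ]
        out.to_csv(path, sep="\t", index=False)


class _FeatureTable:
    """Shared behaviour of features x samples tables."""

    def __init__(self, values: pd.DataFrame):
        values = values.copy()
        values.index = values.index.astype(str)
        values.columns = values.columns.astype(str)
        if values.index.has_duplicates:
            dups = values.index[values.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate feature ids: {dups}")
        if values.columns.has_duplicates:
            dups = values.columns[values.columns.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample ids: {dups}")
        self.values = values

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def check_samples(self, metadata: SampleMetadata) -> None:
        extra = set(self.sample_ids) - set(metadata.sample_ids)
        if extra:
            raise ValidationError(
                f"matrix sample ids absent from metadata: {sorted(extra)}"
            )

    def to_tsv(self, path: str | Path, label: str = "feature_id") -> None:
        out = self.values.copy()
        out.index.name = label
        out.to_csv(path, sep="\t")


class AbundanceMatrix(_FeatureTable):
    """Protein abundance matrix (features x samples), NaN marks a missing
    quantification."""

    def __init__(self, values: pd.DataFrame):
        super().__init__(values.astype(float))


class CountMatrix(_FeatureTable):
    """Transcript read-count matrix (genes x samples), non-negative integers."""

    def __init__(self, values: pd.DataFrame):
        arr = values.to_numpy()
        if not np.all(np.isfinite(arr)):
            raise ValidationError("counts must be finite")
        if (arr < 0).any():
            raise ValidationError("counts must be non-negative")
        if not np.allclose(arr, np.round(arr)):
            raise ValidationError("counts must be integral")
        super().__init__(values.round().astype(np.int64))


@dataclass
class FeatureMap:
    """Gene-to-protein identifier map; many genes may map to one protein."""

    pairs: pd.DataFrame  # columns gene_id, protein_id

    def __post_init__(self) -> None:
        pairs = self.pairs[["gene_id", "protein_id"]].astype(str).reset_index(drop=True)
        if pairs.duplicated().any():
            dup = pairs[pairs.duplicated()].iloc[0]
            raise ValidationError(
                f"duplicate feature-map pair ({dup.gene_id}, {dup.protein_id})"
            )
        self.pairs = pairs

    def genes_for(self, protein_id: str) -> list[str]:
        sel = self.pairs.loc[self.pairs["protein_id"] == protein_id, "gene_id"]
        return sorted(sel)

    @property
    def gene_ids(self) -> list[str]:
        return sorted(self.pairs["gene_id"].unique())

    @property
    def protein_ids(self) -> list[str]:
        return sorted(self.pairs["protein_id"].unique())

    def to_tsv(self, path: str | Path) -> None:
        self.pairs.sort_values(["protein_id", "gene_id"]).to_csv(path, sep="\t", index=False)


@dataclass
class GeneSetCollection:
    """Named, described sets of feature identifiers (GMT semantics)."""

    sets: dict[str, set[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise ValidationError(f"gene set {name!r} is empty")
        self.descriptions = {n: self.descriptions.get(n, "") for n in self.sets}

    def __len__(self) -> int:
        return len(self.sets)

    def items(self):
        return self.sets.items()


@dataclass
class StudyBundle:
    """Everything one analysis run consumes."""

    metadata: SampleMetadata
    abundance: AbundanceMatrix
    counts: CountMatrix
    feature_map: FeatureMap
    gene_sets: GeneSetCollection


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def read_metadata(path: str | Path, boundaries: tuple[float, float] = (100.0, 500.0)) -> SampleMetadata:
    frame = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    if "sample_id" not in frame.columns:
        raise ValidationError(f"{path}: metadata must have a sample_id column")
    return SampleMetadata(frame, boundaries)


def _read_table(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t", index_col=0)
    if frame.shape[1] == 0:
        raise ValidationError(f"{path}: matrix has no sample columns")
    return frame


def read_matrix(path: str | Path) -> AbundanceMatrix:
    return AbundanceMatrix(_read_table(path))


def read_counts(path: str | Path) -> CountMatrix:
    return CountMatrix(_read_table(path))


def read_feature_map(path: str | Path) -> FeatureMap:
    frame = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("gene_id", "protein_id"):
        if col not in frame.columns:
            raise ValidationError(f"{path}: feature map must have a {col} column")
    return FeatureMap(frame)


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Parse a GMT file: set name, description, then member ids, tab-separated."""
    sets: dict[str, set[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValidationError(
                    f"{path}:{lineno}: GMT line needs name, description and >=1 member"
                )
            name = fields[0]
            if name in sets:
                raise ValidationError(f"{path}:{lineno}: duplicate set name {name!r}")
            sets[name] = set(fields[2:])
            descriptions[name] = fields[1]
    if not sets:
        raise ValidationError(f"{path}: no gene sets found")
    return GeneSetCollection(sets, descriptions)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name in sorted(collection.sets):
            members = "\t".join(sorted(collection.sets[name]))
            fh.write(f"{name}\t{collection.descriptions.get(name, '')}\t{members}\n")


def read_study(
    abundance_path: str | Path,
    counts_path: str | Path,
    metadata_path: str | Path,
    map_path: str | Path,
    genesets_path: str | Path,
    boundaries: tuple[float, float] = (100.0, 500.0),
) -> StudyBundle:
    """Load and cross-validate all study inputs."""
    metadata = read_metadata(metadata_path, boundaries)
    abundance = read_matrix(abundance_path)
    counts = read_counts(counts_path)
    feature_map = read_feature_map(map_path)
    gene_sets = read_gmt(genesets_path)
    abundance.check_samples(metadata)
    counts.check_samples(metadata)
    unknown_prot = set(feature_map.pairs["protein_id"]) - set(abundance.feature_ids)
    if unknown_prot:
        raise ValidationError(
            f"feature map references unknown protein ids: {sorted(unknown_prot)[:5]}"
        )
    return StudyBundle(metadata, abundance, counts, feature_map, gene_sets)


def write_feature_report(results: pd.DataFrame, path: str | Path, id_column: str = "feature_id") -> None:
    """Write a per-feature result table as deterministic TSV.

    Rows are sorted by feature id and columns keep their given order, so two
    runs on the same input produce byte-identical files. Floats are printed
    with 17 significant digits (round-trip exact for doubles).
    """
    if id_column not in results.columns:
        raise ValidationError(f"report must contain an {id_column!r} column")
    out = results.sort_values(id_column, kind="mergesort")
    out.to_csv(path, sep="\t", index=False, float_format="%.17g")
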