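"""Core data containers shared by every pipeline stage.

The central object is :class:`FeatureTable`, an LC-MS feature-intensity
matrix (samples x features) bundled with sample metadata (role in the study
design, storage day, replicate, dilution factor, ionization mode) and
feature metadata (retention time, m/z, mode). Missing intensities are
represented as NaN. Feature ids follow the metabolomics ``rt_mz``
convention, e.g. ``"0.31_414.8628"``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

ROLES = ("study", "qc", "qc_dilution", "blank")

SAMPLE_COLUMNS = ["role", "storage_day", "replicate", "dilution_factor", "mode"]
FEATURE_COLUMNS = ["rt_min", "mz", "mode"]


class FeatureTableError(ValueError):
    """Raised when a FeatureTable violates its structural contract."""


@dataclass
class FeatureTable:
    """Intensity matrix plus sample and feature metadata.

    Parameters
    ----------
    intensities
        samples x features DataFrame; index = sample_id, columns =
        feature_id; NaN marks a missing value; no negative entries.
    samples
        Per-sample metadata indexed by sample_id with columns
        ``role`` (study/qc/qc_dilution/blank), ``storage_day`` (int days,
        study samples only), ``replicate`` (aliquot id), ``dilution_factor``
        (relative concentration in (0,1], qc_dilution samples only) and
        ``mode`` (pos/neg).
    features
        Per-feature metadata indexed by feature_id with columns ``rt_min``,
        ``mz`` and ``mode``.
    """

    intensities: pd.DataFrame
    samples: pd.DataFrame
    features: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not self.intensities.index.equals(self.samples.index):
            raise FeatureTableError("intensity rows and sample metadata disagree")
        if not self.intensities.columns.equals(self.features.index):
            raise FeatureTableError("intensity columns and feature metadata disagree")
        if self.features.index.has_duplicates:
            raise FeatureTableError("duplicate feature ids")
        if self.samples.index.has_duplicates:
            raise FeatureTableError("duplicate sample ids")
        bad_roles = set(self.samples["role"]) - set(ROLES)
        if bad_roles:
            raise FeatureTableError(f"unknown sample roles: {sorted(bad_roles)}")
        vals = self.intensities.to_numpy(dtype=float)
        if np.nanmin(vals, initial=0.0) < 0:
            raise FeatureTableError("negative intensities")
        study = self.samples["role"] == "study"
        if self.samples.loc[study, "storage_day"].isna().any():
            raise FeatureTableError("study sample without storage_day")
        if self.samples.loc[~study, "storage_day"].notna().any():
            raise FeatureTableError("storage_day set on a non-study sample")
        dil = self.samples["role"] == "qc_dilution"
        dfac = self.samples.loc[dil, "dilution_factor"]
        if dfac.isna().any() or (dfac <= 0).any() or (dfac > 1).any():
            raise FeatureTableError("qc_dilution sample needs dilution_factor in (0, 1]")
        if self.samples.loc[~dil, "dilution_factor"].notna().any():
            raise FeatureTableError("dilution_factor set on a non-dilution sample")

    # -- convenience views -------------------------------------------------
    @property
    def feature_ids(self) -> pd.Index:
        return self.features.index

    def sample_ids(self, role: str | None = None) -> pd.Index:
        if role is None:
            return self.samples.index
        return self.samples.index[self.samples["role"] == role]

    def study_matrix(self) -> pd.DataFrame:
        """Intensities of study samples only."""
        return self.intensities.loc[self.sample_ids("study")]

    def study_design(self) -> pd.DataFrame:
        """storage_day and replicate labels for the study samples."""
        ids = self.sample_ids("study")
        return self.samples.loc[ids, ["storage_day", "replicate"]]

    def subset_features(self, keep: Iterable[str]) -> "FeatureTable":
        keep = [f for f in self.feature_ids if f in set(keep)]  # preserve order
        return FeatureTable(
            intensities=self.intensities[keep].copy(),
            samples=self.samples.copy(),
            features=self.features.loc[keep].copy(),
        )

    # -- disk round trip ---------------------------------------------------
    def to_dir(self, outdir: str | Path) -> None:
        """Write intensities.csv / samples.csv / features.csv (empty cell = missing)."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.intensities.to_csv(outdir / "intensities.csv", index_label="sample_id")
        self.samples.to_csv(outdir / "samples.csv", index_label="sample_id")
        self.features.to_csv(outdir / "features.csv", index_label="feature_id")

    @classmethod
    def from_dir(cls, indir: str | Path) -> "FeatureTable":
        indir = Path(indir)
        intens = pd.read_csv(indir / "intensities.csv", index_col="sample_id")
        samples = pd.read_csv(indir / "samples.csv", index_col="sample_id")
        features = pd.read_csv(indir / "features.csv", index_col="feature_id")
        features.index = features.index.astype(str)
        intens.columns = intens.columns.astype(str)
        samples["storage_day"] = pd.to_numeric(samples["storage_day"], errors="coerce")
        samples["dilution_factor"] = pd.to_numeric(
            samples["dilution_factor"], errors="coerce"
        )
        return cls(intensities=intens, samples=samples, features=features)


@dataclass
class FilterRecord:
    """Decision for one feature at one filter stage."""

    feature_id: str
    stage: str
    statistic: float
    decision: str  # retained | removed
    reason: str = ""


@dataclass
class FilterReport:
    """Per-feature retain/remove decisions with the statistic behind each.

    ``records`` holds one row per feature per stage it reached;
    ``stage_counts`` summarizes retained/removed per stage.
    """

    records: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["feature_id", "stage", "statistic", "decision", "reason"]
        )
    )

    @classmethod
    def from_records(cls, recs: list[FilterRecord]) -> "FilterReport":
        return cls(
            pd.DataFrame(
                [
                    (r.feature_id, r.stage, r.statistic, r.decision, r.reason)
                    for r in recs
                ],
                columns=["feature_id", "stage", "statistic", "decision", "reason"],
            )
        )

    def retained_ids(self, stage: str) -> list[str]:
        m = (self.records["stage"] == stage) & (self.records["decision"] == "retained")
        return self.records.loc[m, "feature_id"].tolist()

    @property
    def stage_counts(self) -> pd.DataFrame:
        if self.records.empty:
            return pd.DataFrame(columns=["stage", "retained", "removed"])
        order = self.records["stage"].drop_duplicates().tolist()  # pipeline order
        tab = (
            self.records.groupby(["stage", "decision"])
            .size()
            .unstack(fill_value=0)
            .reindex(columns=["retained", "removed"], fill_value=0)
            .reindex(order)
            .reset_index()
        )
        tab.columns.name = None
        return tab

    def extend(self, other: "FilterReport") -> "FilterReport":
        return FilterReport(
            pd.concat([self.records, other.records], ignore_index=True)
        )

    def to_tsv(self, path: str | Path) -> None:
        self.records.to_csv(path, sep="\t", index=False)


def write_json(obj: dict, path: str | Path) -> None:
    """Deterministic JSON writer (sorted keys, no timestamps)."""
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
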