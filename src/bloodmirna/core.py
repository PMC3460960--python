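"""Domain containers shared by every pipeline stage.

The pipeline's entry point is a collection of per-hybridization spot tables
(two-color raw intensities for every printed spot), a probe annotation panel,
and a clinical sample sheet.  Pre-processing turns these into a probe-by-sample
``ExpressionMatrix`` of summarized sample-channel signals on the linear scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ContentError

CLASS_LABELS = ("case", "control")
CONTROL_SUBTYPES = ("nodule", "high_risk", "none")


@dataclass
class ProbePanel:
    """Annotation of every printed probe.

    ``table`` is indexed by ``probe_id`` and carries:

    - ``targets``: list of RNA names the probe recognizes (empty for
      probe-less spots).  A probe can recognize more than one RNA; analyses
      treat the probe, not the RNA, as the variable, so targets are
      annotation only.
    - ``is_empty``: probe-less spot measuring pure background.
    - ``is_human``: probe targets human RNAs; non-human probes are dropped
      after summarization.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"targets", "is_empty", "is_human"}
        missing = required - set(self.table.columns)
        if missing:
            raise ContentError(f"probe panel missing columns: {sorted(missing)}")
        if not self.table.index.is_unique:
            dup = self.table.index[self.table.index.duplicated()][0]
            raise ContentError(f"duplicate probe_id in panel: {dup!r}")
        for probe_id, row in self.table.iterrows():
            n_targets = len(row["targets"])
            if row["is_empty"] and n_targets != 0:
                raise ContentError(
                    f"empty-spot probe {probe_id!r} must have zero targets"
                )
            if not row["is_empty"] and n_targets < 1:
                raise ContentError(
                    f"non-empty probe {probe_id!r} must target at least one RNA"
                )

    @property
    def probe_ids(self) -> pd.Index:
        return self.table.index

    @property
    def empty_probe_ids(self) -> pd.Index:
        return self.table.index[self.table["is_empty"].astype(bool)]

    @property
    def nonempty_probe_ids(self) -> pd.Index:
        return self.table.index[~self.table["is_empty"].astype(bool)]

    @property
    def human_probe_ids(self) -> pd.Index:
        keep = (~self.table["is_empty"].astype(bool)) & self.table["is_human"].astype(bool)
        return self.table.index[keep]


@dataclass
class SpotTable:
    """Raw two-channel intensities for one hybridization.

    ``data`` columns: ``probe_id``, ``replicate`` (1..k), ``sample_signal``
    (study specimen channel), ``reference_signal`` (common pooled reference
    channel).
    """

    array_id: str
    data: pd.DataFrame

    REQUIRED_COLUMNS = ("probe_id", "replicate", "sample_signal", "reference_signal")

    def validate(self, panel: Optional[ProbePanel] = None) -> None:
        missing = set(self.REQUIRED_COLUMNS) - set(self.data.columns)
        if missing:
            raise ContentError(
                f"spot table {self.array_id!r} missing columns: {sorted(missing)}"
            )
        for col in ("sample_signal", "reference_signal"):
            vals = self.data[col].to_numpy(dtype=float)
            if not np.all(np.isfinite(vals)):
                raise ContentError(
                    f"spot table {self.array_id!r}: non-finite values in {col!r}"
                )
            if np.any(vals < 0):
                raise ContentError(
                    f"spot table {self.array_id!r}: negative intensity in {col!r}"
                )
        if panel is not None:
            unknown = set(self.data["probe_id"]) - set(panel.probe_ids)
            if unknown:
                raise ContentError(
                    f"spot table {self.array_id!r}: probe(s) absent from panel: "
                    f"{sorted(unknown)[:5]}"
                )
            counts = self.data.groupby("probe_id").size()
            nonempty = counts.reindex(
                counts.index.intersection(panel.nonempty_probe_ids)
            )
            if len(nonempty) and nonempty.nunique() != 1:
                raise ContentError(
                    f"spot table {self.array_id!r}: non-empty probes must share a "
                    "fixed replicate count"
                )

    @property
    def replicate_count(self) -> int:
        return int(self.data.groupby("probe_id").size().max())


@dataclass
class SampleSheet:
    """Clinical annotation of the hybridized samples.

    Columns: ``sample_id``, ``class`` (case/control), ``control_subtype``
    (nodule/high_risk, ``none`` for cases), ``age`` in years, ``gender``,
    ``smoking`` (boolean), and optional blood parameters ``wbc`` and
    ``platelets`` (1000/µl) and ``hemoglobin`` (g/dl).  Missing blood values
    are kept as NaN and excluded pairwise from covariate analyses.
    """

    table: pd.DataFrame

    REQUIRED_COLUMNS = (
        "sample_id",
        "class",
        "control_subtype",
        "age",
        "gender",
        "smoking",
    )
    OPTIONAL_COLUMNS = ("wbc", "platelets", "hemoglobin")

    def __post_init__(self) -> None:
        missing = set(self.REQUIRED_COLUMNS) - set(self.table.columns)
        if missing:
            raise ContentError(f"sample sheet missing columns: {sorted(missing)}")
        bad = set(self.table["class"]) - set(CLASS_LABELS)
        if bad:
            raise ContentError(f"non-binary class label(s): {sorted(bad)}")
        bad = set(self.table["control_subtype"]) - set(CONTROL_SUBTYPES)
        if bad:
            raise ContentError(f"unknown control subtype(s): {sorted(bad)}")
        is_case = self.table["class"] == "case"
        if (is_case != (self.table["control_subtype"] == "none")).any():
            raise ContentError("control_subtype must be 'none' exactly for cases")
        ages = self.table["age"].to_numpy(dtype=float)
        if np.any(~np.isfinite(ages)) or np.any(ages <= 0):
            raise ContentError("ages must be positive and finite")
        if not self.table["sample_id"].is_unique:
            raise ContentError("sample_id values must be unique")

    @property
    def sample_ids(self) -> pd.Index:
        return pd.Index(self.table["sample_id"])

    @property
    def classes(self) -> np.ndarray:
        return self.table["class"].to_numpy()

    def class_of(self, sample_ids: Sequence[str]) -> np.ndarray:
        lookup = self.table.set_index("sample_id")["class"]
        return lookup.loc[list(sample_ids)].to_numpy()


@dataclass
class ExpressionMatrix:
    """Summarized, normalized sample-channel signals (linear scale).

    ``values`` is probes × samples with strictly positive entries (guaranteed
    by background correction with a positive offset).  ``expressed_mask`` is
    a per-probe boolean from the empty-spot expression call.  ``provenance``
    records the preprocessing parameters that produced the matrix.
    """

    values: pd.DataFrame
    expressed_mask: Optional[pd.Series] = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        vals = self.values.to_numpy(dtype=float)
        if vals.size and not np.all(np.isfinite(vals)):
            raise ContentError("expression matrix contains non-finite values")
        if vals.size and np.any(vals <= 0):
            raise ContentError("expression matrix values must be strictly positive")
        if self.expressed_mask is not None:
            if not self.expressed_mask.index.equals(self.values.index):
                raise ContentError("expressed_mask must be indexed by the matrix probes")

    @property
    def log2(self) -> pd.DataFrame:
        """Log2 view of the summarized signals."""
        return np.log2(self.values)

    @property
    def probes(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    def expressed(self) -> "ExpressionMatrix":
        """Restrict to probes flagged expressed."""
        if self.expressed_mask is None:
            raise ContentError("no expressed_mask available; run the expression call")
        mask = self.expressed_mask.astype(bool)
        return ExpressionMatrix(
            values=self.values.loc[mask],
            expressed_mask=self.expressed_mask.loc[mask],
            provenance=dict(self.provenance),
        )
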