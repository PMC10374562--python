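"""Core containers for aptamer-assay (RFU) datasets.

An :class:`RFUDataset` bundles the positive measurement matrix (samples ×
analytes, relative fluorescence units) with the two metadata tables that the
rest of the pipeline keys on: one row per sample (animal, group, study day,
plate, sample type, tumor volume) and one row per analyte (target name,
dilution bin, analyte type).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

SAMPLE_COLUMNS = [
    "AnimalId",
    "Group",
    "StudyDay",
    "PlateId",
    "SampleType",
    "TumorVolume_mm3",
]
ANALYTE_COLUMNS = ["TargetName", "DilutionBin", "AnalyteType"]

PROTEIN = "protein"
HYB_CONTROL = "hybridization-control"
DILUTION_BINS = ("5%", "2%", "0.05%")
SAMPLE_TYPES = ("study", "calibrator", "buffer")

N_HYB_CONTROLS = 12


class DatasetError(ValueError):
    """Malformed dataset: inconsistent keys, shapes or values."""


@dataclass
class RFUDataset:
    """RFU matrix plus aligned sample and analyte metadata.

    Parameters
    ----------
    values
        DataFrame of strictly positive floats; index = sample ids,
        columns = analyte (SeqId) ids.
    samples
        DataFrame indexed by sample id with columns ``SAMPLE_COLUMNS``.
    analytes
        DataFrame indexed by SeqId with columns ``ANALYTE_COLUMNS``.
    header
        Free-form key/value metadata (format version, seed, the
        normalization stages already applied, ...).
    """

    values: pd.DataFrame
    samples: pd.DataFrame
    analytes: pd.DataFrame
    header: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    # -- validation ---------------------------------------------------------
    def validate(self) -> None:
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique()
            raise DatasetError(f"duplicate sample ids: {list(dups)}")
        if self.values.columns.has_duplicates:
            dups = self.values.columns[self.values.columns.duplicated()].unique()
            raise DatasetError(f"duplicate analyte ids: {list(dups)}")
        if not self.values.index.equals(self.samples.index):
            raise DatasetError("sample ids of values and sample table differ")
        if not self.values.columns.equals(self.analytes.index):
            raise DatasetError("analyte ids of values and analyte table differ")
        missing = [c for c in SAMPLE_COLUMNS if c not in self.samples.columns]
        if missing:
            raise DatasetError(f"sample table misses columns {missing}")
        missing = [c for c in ANALYTE_COLUMNS if c not in self.analytes.columns]
        if missing:
            raise DatasetError(f"analyte table misses columns {missing}")
        vals = self.values.to_numpy(dtype=float)
        if not np.all(np.isfinite(vals)) or np.any(vals <= 0):
            bad = np.argwhere(~(np.isfinite(vals) & (vals > 0)))
            s, a = bad[0]
            raise DatasetError(
                "non-positive or non-finite RFU, first at sample "
                f"{self.values.index[s]!r}, analyte {self.values.columns[a]!r}"
            )
        bad_type = set(self.samples["SampleType"]) - set(SAMPLE_TYPES)
        if bad_type:
            raise DatasetError(f"unknown sample types: {sorted(bad_type)}")
        study = self.samples["SampleType"] == "study"
        vol = pd.to_numeric(self.samples.loc[study, "TumorVolume_mm3"])
        if vol.isna().any() or (vol < 0).any():
            raise DatasetError("study samples need a non-negative tumor volume")

    # -- convenience --------------------------------------------------------
    @property
    def protein_ids(self) -> pd.Index:
        return self.analytes.index[self.analytes["AnalyteType"] == PROTEIN]

    @property
    def hyb_control_ids(self) -> pd.Index:
        return self.analytes.index[self.analytes["AnalyteType"] == HYB_CONTROL]

    @property
    def study_ids(self) -> pd.Index:
        return self.samples.index[self.samples["SampleType"] == "study"]

    @property
    def calibrator_ids(self) -> pd.Index:
        return self.samples.index[self.samples["SampleType"] == "calibrator"]

    def copy(self) -> "RFUDataset":
        return RFUDataset(
            self.values.copy(),
            self.samples.copy(),
            self.analytes.copy(),
            dict(self.header),
        )

    def subset_samples(self, ids) -> "RFUDataset":
        ids = pd.Index(ids)
        return RFUDataset(
            self.values.loc[ids],
            self.samples.loc[ids],
            self.analytes.copy(),
            dict(self.header),
        )

    def drop_hyb_controls(self) -> "RFUDataset":
        keep = self.protein_ids
        return RFUDataset(
            self.values[keep],
            self.samples.copy(),
            self.analytes.loc[keep],
            dict(self.header),
        )
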