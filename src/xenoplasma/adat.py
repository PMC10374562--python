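"""Read and write the tab-delimited ADAT-like interchange format.

Layout (UTF-8, LF newlines, tab-delimited):

* header block — lines starting ``!`` with ``key<TAB>value`` pairs;
* ``^Analytes`` block — one row per metadata field (``SeqId``,
  ``TargetName``, ``DilutionBin``, ``AnalyteType``), values across analytes;
* ``^Samples`` block — a column-header row naming the sample metadata
  columns, then one row per sample: metadata followed by RFU values in
  ``SeqId`` order, printed with one decimal place.

The round trip is lossless at that declared precision; structural problems
(duplicate ids, dimension mismatches, non-numeric RFU) raise
:class:`AdatFormatError` naming the offending line.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd

from .dataset import ANALYTE_COLUMNS, SAMPLE_COLUMNS, RFUDataset

_ANALYTE_FIELDS = ["SeqId"] + ANALYTE_COLUMNS
_SAMPLE_HEADER = ["SampleId"] + SAMPLE_COLUMNS
FORMAT_VERSION = "1.0"


class AdatFormatError(ValueError):
    """Raised for malformed files; message carries the 1-based line number."""


def write_adat(dataset: RFUDataset, path: os.PathLike | str) -> None:
    """Serialize *dataset* to *path* in the ADAT-like dialect."""
    header = {"FormatVersion": FORMAT_VERSION, **dataset.header}
    lines: list[str] = [f"!{k}\t{v}" for k, v in header.items()]
    lines.append("^Analytes")
    an = dataset.analytes
    lines.append("\t".join(["SeqId", *an.index.astype(str)]))
    for col in ANALYTE_COLUMNS:
        lines.append("\t".join([col, *an[col].astype(str)]))
    lines.append("^Samples")
    lines.append("\t".join(_SAMPLE_HEADER))
    sm = dataset.samples
    vals = dataset.values.to_numpy(dtype=float)
    for i, sid in enumerate(dataset.values.index):
        row = sm.loc[sid]
        vol = row["TumorVolume_mm3"]
        meta = [
            str(sid),
            str(row["AnimalId"]),
            str(row["Group"]),
            str(int(row["StudyDay"])),
            str(row["PlateId"]),
            str(row["SampleType"]),
            "NA" if pd.isna(vol) else format(float(vol), ".6g"),
        ]
        rfu = [format(v, ".1f") for v in vals[i]]
        lines.append("\t".join(meta + rfu))
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\n".join(lines) + "\n")


def read_adat(path: os.PathLike | str) -> RFUDataset:
    """Parse an ADAT-like file back into an :class:`RFUDataset`."""
    with open(path, encoding="utf-8") as fh:
        raw = fh.read().splitlines()

    header: dict[str, str] = {}
    i = 0
    while i < len(raw) and raw[i].startswith("!"):
        key, _, value = raw[i][1:].partition("\t")
        header[key] = value
        i += 1

    if i >= len(raw) or raw[i] != "^Analytes":
        raise AdatFormatError(f"line {i + 1}: expected '^Analytes' block")
    i += 1
    fields: dict[str, list[str]] = {}
    for name in _ANALYTE_FIELDS:
        if i >= len(raw):
            raise AdatFormatError(f"line {i + 1}: missing analyte row {name!r}")
        parts = raw[i].split("\t")
        if parts[0] != name:
            raise AdatFormatError(
                f"line {i + 1}: expected analyte field {name!r}, got {parts[0]!r}"
            )
        fields[name] = parts[1:]
        i += 1
    n_analytes = len(fields["SeqId"])
    for name, vals in fields.items():
        if len(vals) != n_analytes:
            raise AdatFormatError(
                f"analyte field {name!r} has {len(vals)} values, expected {n_analytes}"
            )
    seq_ids = pd.Index(fields["SeqId"], name="SeqId")
    if seq_ids.has_duplicates:
        dup = seq_ids[seq_ids.duplicated()][0]
        raise AdatFormatError(f"duplicate analyte id {dup!r}")
    analytes = pd.DataFrame(
        {col: fields[col] for col in ANALYTE_COLUMNS}, index=seq_ids
    )

    if i >= len(raw) or raw[i] != "^Samples":
        raise AdatFormatError(f"line {i + 1}: expected '^Samples' block")
    i += 1
    if i >= len(raw) or raw[i].split("\t") != _SAMPLE_HEADER:
        raise AdatFormatError(f"line {i + 1}: bad sample column header")
    i += 1

    sample_ids: list[str] = []
    meta_rows: list[list] = []
    value_rows: list[np.ndarray] = []
    n_meta = len(_SAMPLE_HEADER)
    for lineno in range(i, len(raw)):
        line = raw[lineno]
        if not line:
            continue
        parts = line.split("\t")
        if len(parts) != n_meta + n_analytes:
            raise AdatFormatError(
                f"line {lineno + 1}: expected {n_meta + n_analytes} fields, "
                f"got {len(parts)}"
            )
        sid = parts[0]
        if sid in sample_ids:
            raise AdatFormatError(f"line {lineno + 1}: duplicate sample id {sid!r}")
        vol = np.nan if parts[6] == "NA" else _parse_float(parts[6], lineno)
        meta_rows.append([parts[1], parts[2], int(parts[3]), parts[4], parts[5], vol])
        try:
            value_rows.append(np.array(parts[n_meta:], dtype=float))
        except ValueError as exc:
            raise AdatFormatError(f"line {lineno + 1}: non-numeric RFU ({exc})")
        sample_ids.append(sid)

    index = pd.Index(sample_ids, name="SampleId")
    samples = pd.DataFrame(meta_rows, index=index, columns=SAMPLE_COLUMNS)
    values = pd.DataFrame(np.vstack(value_rows) if value_rows else
                          np.empty((0, n_analytes)), index=index, columns=seq_ids)
    return RFUDataset(values, samples, analytes, header)


def _parse_float(text: str, lineno: int) -> float:
    try:
        return float(text)
    except ValueError:
        raise AdatFormatError(f"line {lineno + 1}: non-numeric volume {text!r}")


def write_reference(reference: pd.Series, path: os.PathLike | str) -> None:
    """Write a per-analyte reference standard as a two-column TSV."""
    reference.rename("Reference").to_csv(path, sep="\t", index_label="SeqId")


def read_reference(path: os.PathLike | str) -> pd.Series:
    frame = pd.read_csv(path, sep="\t", index_col="SeqId")
    return frame["Reference"]
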