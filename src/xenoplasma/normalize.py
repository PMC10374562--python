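"""Three-stage normalization of raw aptamer-assay RFU matrices.

The assay introduces three multiplicative artifact layers and each stage
removes one, in the order they enter the measurement chain:

1. :func:`hyb_normalize` — per-sample readout (hybridization) efficiency,
   estimated as the median ratio of 12 spiked control oligonucleotides to
   their fixed reference values;
2. :func:`plate_calibrate` — per-plate, per-analyte calibration, estimated
   from the median signal of pooled-plasma calibrator samples run on every
   plate against a fixed per-analyte reference;
3. :func:`median_normalize` — residual per-sample intensity, estimated
   within each dilution bin as the median ratio of the intra-plate median
   of each analyte to the sample's own signal.

All scale factors are multiplicative and strictly positive, so
normalization never changes dimensions nor introduces non-positive values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dataset import HYB_CONTROL, N_HYB_CONTROLS, RFUDataset

STAGE_HYB = "hybridization"
STAGE_PLATE = "plate-calibration"
STAGE_MEDIAN = "median-signal"


class NormalizationError(ValueError):
    pass


@dataclass
class ScaleFactors:
    """Record of the multiplicative factors applied by the three stages.

    ``hybridization`` is a per-sample Series; ``calibration`` a
    plate × analyte DataFrame; ``median`` a sample × dilution-bin DataFrame.
    ``skipped_bins`` lists (bin, reason) pairs for bins the median stage
    could not normalize.
    """

    hybridization: pd.Series | None = None
    calibration: pd.DataFrame | None = None
    median: pd.DataFrame | None = None
    skipped_bins: list = field(default_factory=list)
    stages_applied: list = field(default_factory=list)


def hyb_normalize(
    dataset: RFUDataset, hyb_reference: pd.Series
) -> tuple[RFUDataset, pd.Series]:
    """Scale every sample by the median control-to-reference ratio.

    For sample *s* the factor is ``median_i(reference_i / observed_{s,i})``
    over the 12 hybridization-control analytes; every analyte of the sample
    (controls included, which makes the stage idempotent) is multiplied by
    it.
    """
    controls = dataset.hyb_control_ids
    if len(controls) != N_HYB_CONTROLS:
        raise NormalizationError(
            f"expected {N_HYB_CONTROLS} hybridization controls, found {len(controls)}"
        )
    missing = controls.difference(hyb_reference.index)
    if len(missing):
        raise NormalizationError(f"reference misses controls {list(missing)}")
    obs = dataset.values[controls]
    bad = obs.index[(obs <= 0).any(axis=1)]
    if len(bad):
        raise NormalizationError(
            f"non-positive hybridization-control signal in sample {bad[0]!r}"
        )
    ratios = hyb_reference[controls].to_numpy() / obs.to_numpy()
    scale = pd.Series(np.median(ratios, axis=1), index=dataset.values.index,
                      name="HybScale")
    out = dataset.copy()
    out.values = dataset.values.mul(scale, axis=0)
    out.header["HybNormalized"] = "true"
    return out, scale


def plate_calibrate(
    dataset: RFUDataset, calibrator_reference: pd.Series
) -> tuple[RFUDataset, pd.DataFrame]:
    """Apply per-plate, per-analyte calibration from calibrator samples.

    For plate *p* and analyte *a* the factor is
    ``reference_a / median(calibrator signal for a on p)``; it multiplies
    every sample on the plate (calibrators included).  Only analytes present
    in the reference (the protein menu) are calibrated.
    """
    cal_ids = dataset.calibrator_ids
    if not len(cal_ids):
        raise NormalizationError("dataset has no calibrator samples")
    analytes = dataset.values.columns.intersection(calibrator_reference.index)
    analytes.name = dataset.values.columns.name
    if not len(analytes):
        raise NormalizationError("calibrator reference shares no analytes with data")
    plates = dataset.samples["PlateId"]
    out = dataset.copy()
    rows = {}
    for plate, plate_samples in dataset.samples.groupby("PlateId").groups.items():
        plate_cals = pd.Index(plate_samples).intersection(cal_ids)
        if not len(plate_cals):
            raise NormalizationError(f"plate {plate!r} has no calibrator samples")
        med = dataset.values.loc[plate_cals, analytes].median(axis=0)
        scale = calibrator_reference[analytes] / med
        rows[plate] = scale
        out.values.loc[plate_samples, analytes] = (
            dataset.values.loc[plate_samples, analytes].mul(scale, axis=1)
        )
    factors = pd.DataFrame(rows).T.rename_axis("PlateId")
    out.header["PlateCalibrated"] = "true"
    return out, factors


def _log_median(a: np.ndarray, axis: int) -> np.ndarray:
    """Median on the log scale: the middle element for odd counts, the
    geometric mean of the two middle elements for even counts.

    For positive data this convention is reciprocal-symmetric
    (``median(1/y) = 1/median(y)``), which is what makes the median-signal
    fixed point exact; it agrees with the ordinary median whenever the
    count is odd.
    """
    return np.exp(np.median(np.log(a), axis=axis))


def median_normalize(
    dataset: RFUDataset,
    max_iter: int = 500,
    tol: float = 1e-12,
    min_bin_size: int = 3,
) -> tuple[RFUDataset, ScaleFactors]:
    """Per-sample, per-dilution-bin median-signal normalization.

    Within each bin, sample *s* is scaled by
    ``median_a(intraPlateMedian(a) / x_{s,a})`` where the intra-plate
    median is taken over study samples on the sample's plate.  Two
    refinements make the stage a well-defined fixed point: medians of
    positive signals use the log-scale convention of :func:`_log_median`,
    and each pass's scales are gauge-fixed by their per-plate median over
    study samples (a common factor on a whole plate-bin leaves every
    ratio unchanged, so it is not identifiable and is left alone).  The
    update is iterated until all per-pass scales are 1 within *tol*; the
    recorded factor per sample-bin is the accumulated product, so a
    re-run returns factors of 1 and the normalized matrix satisfies
    ``median_a(x_{s,a} / intraPlateMedian(a)) = 1`` for every sample-bin.

    Hybridization controls carry no dilution bin and are untouched.  Bins
    with fewer than *min_bin_size* analytes are skipped with a warning.
    """
    values = dataset.values.copy()
    samples = dataset.samples
    study = dataset.study_ids
    if not len(study):
        raise NormalizationError("median normalization needs study samples")
    protein = dataset.protein_ids
    bins = dataset.analytes.loc[protein, "DilutionBin"]
    sf = ScaleFactors()
    accum = pd.DataFrame(
        1.0, index=values.index,
        columns=pd.Index(sorted(bins.unique()), name="DilutionBin"))
    plates = samples["PlateId"].to_numpy()
    study_mask = samples["SampleType"].to_numpy() == "study"
    plate_groups = [
        (plate, np.flatnonzero(plates == plate),
         np.flatnonzero((plates == plate) & study_mask))
        for plate in pd.unique(plates)
    ]
    for plate, rows, study_rows in plate_groups:
        if not len(study_rows):
            raise NormalizationError(f"plate {plate!r} has no study samples")
    for bin_label, bin_analytes in bins.groupby(bins).groups.items():
        bin_analytes = pd.Index(bin_analytes)
        if len(bin_analytes) < min_bin_size:
            warnings.warn(
                f"dilution bin {bin_label!r} has {len(bin_analytes)} analytes "
                f"(<{min_bin_size}); skipped"
            )
            sf.skipped_bins.append((bin_label, "too few analytes"))
            accum.drop(columns=bin_label, inplace=True)
            continue
        cols = values.columns.get_indexer(bin_analytes)
        block = values.to_numpy()[:, cols].copy()
        total = np.ones(len(block))
        for _ in range(max_iter):
            scales = np.ones(len(block))
            for _, rows, study_rows in plate_groups:
                m = _log_median(block[study_rows], axis=0)
                r = _log_median(m / block[rows], axis=1)
                d = _log_median(r[np.isin(rows, study_rows)][:, None], axis=0)
                scales[rows] = r / d
            total *= scales
            block *= scales[:, None]
            if np.max(np.abs(scales - 1)) < tol:
                break
        accum[bin_label] = total
        values.iloc[:, cols] = block
    out = dataset.copy()
    out.values = values
    out.header["MedianNormalized"] = "true"
    sf.median = accum
    return out, sf


def normalize_pipeline(
    dataset: RFUDataset,
    hyb_reference: pd.Series,
    calibrator_reference: pd.Series,
) -> tuple[RFUDataset, ScaleFactors]:
    """Run the three stages in assay order and record what was applied."""
    out, hyb = hyb_normalize(dataset, hyb_reference)
    out, cal = plate_calibrate(out, calibrator_reference)
    out, sf = median_normalize(out)
    sf.hybridization = hyb
    sf.calibration = cal
    sf.stages_applied = [STAGE_HYB, STAGE_PLATE, STAGE_MEDIAN]
    out.header["NormalizationStages"] = ",".join(sf.stages_applied)
    return out, sf
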