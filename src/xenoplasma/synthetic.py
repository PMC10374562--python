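"""Synthetic xenograft cohorts with a ground-truth ledger.

The generator emulates the data structure of a longitudinal xenograft
plasma-proteomics study: groups of mice implanted with a tumor cell line
(or none, for controls) are bled on a fixed schedule; tumor volume follows
capped exponential growth with per-animal rate jitter; each plasma sample
is assayed on one of several plates, and every analyte's expected signal
responds to tumor volume through the saturating-exponential model

    RFU = C + A * (1 - exp(-B * V))

with A = 0 for null analytes.  On top of the biology sit the assay
artifacts the normalization stages are built to remove: a per-sample
hybridization scale, a per-plate per-analyte calibration scale, and
multiplicative lognormal measurement noise.  Everything planted is
recorded in a :class:`TruthLedger` so recovery tests can compare pipeline
output against the truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .dataset import (
    DILUTION_BINS,
    HYB_CONTROL,
    N_HYB_CONTROLS,
    PROTEIN,
    RFUDataset,
)

CONTROL_LINE = "control"

NULL = "null"
SHARED = "shared-responder"
LINE_SPECIFIC = "line-specific-responder"


# ---------------------------------------------------------------------------
# cohort design
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GroupDesign:
    """One experimental arm: a cell line (or control) with a bleed schedule."""

    name: str
    cell_line: str  # CONTROL_LINE for un-implanted animals
    n_animals: int
    days: tuple[int, ...]
    growth_rate: float = 0.085  # 1/day
    implant_volume: float = 50.0  # mm^3
    treated: bool = False
    treatment_window: tuple[int, int] | None = None  # [start, stop] days
    sensitive: bool = False

    def __post_init__(self):
        days = tuple(self.days)
        object.__setattr__(self, "days", days)
        if list(days) != sorted(set(days)) or 0 not in days:
            raise ValueError(f"group {self.name!r}: days must be strictly "
                             "increasing and include day 0")
        if self.n_animals < 2:
            raise ValueError(f"group {self.name!r}: need at least 2 animals")
        if self.treated:
            if self.treatment_window is None:
                raise ValueError(f"group {self.name!r}: treated without a window")
            t0, t1 = self.treatment_window
            if t0 < 0:
                raise ValueError(
                    f"group {self.name!r}: treatment window precedes day 0"
                )
            if t1 <= t0:
                raise ValueError(f"group {self.name!r}: empty treatment window")

    @property
    def is_control(self) -> bool:
        return self.cell_line == CONTROL_LINE


@dataclass(frozen=True)
class CohortDesign:
    groups: tuple[GroupDesign, ...]
    volume_cap: float = 2000.0  # mm^3, ~2 g at unit density
    n_plates: int = 2
    calibrators_per_plate: int = 5
    rate_jitter_sd: float = 0.1  # sd of log growth-rate multiplier
    treatment_decay: float = 0.1  # 1/day volume decay for sensitive arms
    caliper_aspect: float = 1.6  # length / width
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "groups", tuple(self.groups))
        if not self.groups:
            raise ValueError("design has no groups")
        if self.n_plates < 1:
            raise ValueError("need at least one plate")
        for g in self.groups:
            if not g.is_control and not (self.volume_cap > g.implant_volume > 0):
                raise ValueError(
                    f"group {g.name!r}: need volume cap > implant volume > 0"
                )
        if self.caliper_aspect < 1:
            raise ValueError("caliper aspect ratio (length/width) must be >= 1")

    @property
    def cell_lines(self) -> list[str]:
        return [g.cell_line for g in self.groups if not g.is_control]


def nsclc_design(seed: int = 0, n_animals: int = 6,
                 treated_arms: bool = False) -> CohortDesign:
    """Two NSCLC lines plus controls: the slower line sampled on days
    0/9/19/30/40/44, the faster on 0/9/19/27/30, both capped at 2000 mm^3."""
    slow = GroupDesign("H1650", "H1650", n_animals, (0, 9, 19, 30, 40, 44),
                       growth_rate=math.log(2000 / 50) / 44)
    fast = GroupDesign("H1975", "H1975", n_animals, (0, 9, 19, 27, 30),
                       growth_rate=math.log(2000 / 50) / 30)
    ctrl = GroupDesign("control", CONTROL_LINE, n_animals, (0, 9, 19, 30, 40, 44),
                       growth_rate=0.0, implant_volume=50.0)
    groups = [slow, fast, ctrl]
    if treated_arms:
        groups += [
            replace(slow, name="H1650+rx", treated=True,
                    treatment_window=(23, 37), sensitive=True),
            replace(fast, name="H1975+rx", treated=True,
                    treatment_window=(14, 28), sensitive=False),
        ]
    return CohortDesign(tuple(groups), seed=seed)


def multi_line_design(lines: dict[str, int] | None = None, seed: int = 0,
                      days: tuple[int, ...] = (0, 9, 19, 30, 40),
                      n_control: int = 6) -> CohortDesign:
    """One group per cell line (name → n animals) plus a control group."""
    if lines is None:
        lines = {"H1650": 6, "H1975": 6, "MDA-MB-231": 8, "MDA-MB-468": 8,
                 "ES-2": 12, "MDAH-2774": 12, "HCT-116": 8, "HT-29": 8}
    groups = [
        GroupDesign(line, line, n, days,
                    growth_rate=math.log(2000 / 50) / days[-1])
        for line, n in lines.items()
    ]
    groups.append(GroupDesign("control", CONTROL_LINE, n_control, days,
                              growth_rate=0.0))
    return CohortDesign(tuple(groups), n_plates=max(2, len(groups) // 3),
                        seed=seed)


# ---------------------------------------------------------------------------
# volumes and calipers
# ---------------------------------------------------------------------------

def caliper_volume(length: float, width: float) -> float:
    """Tumor volume from a caliper pair: length * width^2 / 2."""
    if length < width or width < 0:
        raise ValueError("need length >= width >= 0")
    return length * width * width / 2.0


def caliper_pair(volume: float, aspect: float = 1.6) -> tuple[float, float]:
    """Invert :func:`caliper_volume` at a fixed length/width aspect ratio."""
    if volume < 0:
        raise ValueError("volume must be non-negative")
    width = (2.0 * volume / aspect) ** (1.0 / 3.0)
    return aspect * width, width


def _log_volume(group: GroupDesign, rate: float, decay: float, t: float) -> float:
    """Uncapped log-volume at time t under piecewise exponential growth."""
    if not group.treated or not group.sensitive:
        return math.log(group.implant_volume) + rate * t
    t0, t1 = group.treatment_window
    grown = min(t, t0) * rate
    shrunk = -decay * max(0.0, min(t, t1) - t0)
    regrown = rate * max(0.0, t - t1)
    return math.log(group.implant_volume) + grown + shrunk + regrown


def generate_cohort(design: CohortDesign) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Sample table and per-animal volume trajectories for a design.

    Returns one sample row per animal per sampling day (plus the
    calibrator rows each plate carries), with tumor volumes following
    ``V(t) = min(cap, V0 * exp(r_i * t))`` where each animal's rate
    ``r_i`` carries lognormal jitter around the group rate.  Treated
    sensitive arms decay exponentially during the treatment window.
    Control volumes are identically zero.  Each volume is also expressed
    as a caliper (length, width) pair at the design's aspect ratio.
    """
    rng = np.random.default_rng(np.random.SeedSequence([design.seed, 101]))
    rows = []
    traj_rows = []
    for group in design.groups:
        jitter = np.exp(rng.normal(0.0, design.rate_jitter_sd, group.n_animals))
        for i in range(group.n_animals):
            animal = f"{group.name}:a{i + 1}"
            rate = group.growth_rate * jitter[i]
            for day in group.days:
                if group.is_control:
                    vol = 0.0
                else:
                    vol = min(
                        design.volume_cap,
                        math.exp(_log_volume(group, rate,
                                             design.treatment_decay, day)),
                    )
                    if day == 0:
                        vol = 0.0  # bled prior to implantation
                length, width = caliper_pair(vol, design.caliper_aspect)
                rows.append({
                    "SampleId": f"S{len(rows) + 1:04d}",
                    "AnimalId": animal,
                    "Group": group.name,
                    "CellLine": group.cell_line,
                    "StudyDay": day,
                    "SampleType": "study",
                    "TumorVolume_mm3": vol,
                    "CaliperLength_mm": length,
                    "CaliperWidth_mm": width,
                })
                traj_rows.append({"AnimalId": animal, "Group": group.name,
                                  "StudyDay": day, "TumorVolume_mm3": vol})
    samples = pd.DataFrame(rows).set_index("SampleId")
    # randomize study samples across plates, then add per-plate calibrators
    plates = [f"P{p + 1}" for p in range(design.n_plates)]
    order = rng.permutation(len(samples))
    plate_col = pd.Series(index=samples.index, dtype=object)
    for k, idx in enumerate(order):
        plate_col.iloc[idx] = plates[k % design.n_plates]
    samples["PlateId"] = plate_col
    cal_rows = []
    for plate in plates:
        for c in range(design.calibrators_per_plate):
            cal_rows.append({
                "SampleId": f"CAL:{plate}:{c + 1}",
                "AnimalId": "pooled",
                "Group": "calibrator",
                "CellLine": CONTROL_LINE,
                "StudyDay": 0,
                "SampleType": "calibrator",
                "TumorVolume_mm3": np.nan,
                "CaliperLength_mm": np.nan,
                "CaliperWidth_mm": np.nan,
                "PlateId": plate,
            })
    if cal_rows:
        samples = pd.concat([samples, pd.DataFrame(cal_rows).set_index("SampleId")])
    trajectories = pd.DataFrame(traj_rows)
    return samples, trajectories


# ---------------------------------------------------------------------------
# analyte truth and RFU generation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AnalyteTruth:
    """Planted response parameters of one analyte."""

    analyte_id: str
    analyte_class: str  # NULL, SHARED or LINE_SPECIFIC
    line: str | None  # target line for LINE_SPECIFIC, else None
    baseline: float  # C [RFU]
    amplitude: float  # A [RFU], 0 iff null
    rate: float  # B [1/mm^3]
    sigma_log: float  # noise sd in log10-RFU units
    dilution_bin: str

    def __post_init__(self):
        if self.baseline <= 0 or self.sigma_log < 0:
            raise ValueError("need C > 0 and sigma_log >= 0")
        if (self.analyte_class == NULL) != (self.amplitude == 0):
            raise ValueError("A = 0 exactly for null analytes")
        if self.analyte_class != NULL and self.rate <= 0:
            raise ValueError("responders need B > 0")

    def responds_to(self, cell_line: str) -> bool:
        if cell_line == CONTROL_LINE:
            return False
        if self.analyte_class == SHARED:
            return True
        return self.analyte_class == LINE_SPECIFIC and self.line == cell_line

    def mean_rfu(self, volume: float, cell_line: str) -> float:
        if not self.responds_to(cell_line) or volume <= 0:
            return self.baseline
        return self.baseline + self.amplitude * (1 - math.exp(-self.rate * volume))


@dataclass
class TruthLedger:
    """Everything planted: analyte truth, references and artifact scales."""

    analytes: dict[str, AnalyteTruth]
    hyb_reference: pd.Series  # 12 fixed control values
    calibrator_reference: pd.Series  # per-analyte baseline C
    hyb_scale: pd.Series | None = None  # per sample, filled by generate_rfu
    plate_scale: pd.DataFrame | None = None  # plate x analyte
    seed: int | None = None

    def validate(self) -> None:
        ids = list(self.analytes)
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate analyte ids in ledger")
        if self.hyb_scale is not None and (self.hyb_scale <= 0).any():
            raise ValueError("hybridization scales must be positive")
        if self.plate_scale is not None and (self.plate_scale <= 0).any().any():
            raise ValueError("plate scales must be positive")

    def responders(self, cell_line: str) -> set[str]:
        return {a for a, t in self.analytes.items() if t.responds_to(cell_line)}

    def shared_responders(self) -> set[str]:
        return {a for a, t in self.analytes.items() if t.analyte_class == SHARED}

    def expected_mdtv(self, analyte_id: str, z: float = 1.96) -> float:
        """Closed-form detection-limit volume of a planted responder.

        Uses the small-noise RFU-scale sd at baseline,
        ``sigma = C * ln(10) * sigma_log``; returns inf when the response
        amplitude cannot clear the two confidence bands.
        """
        t = self.analytes[analyte_id]
        if t.analyte_class == NULL:
            raise ValueError(f"{analyte_id!r} is a null analyte")
        sigma = t.baseline * math.log(10) * t.sigma_log
        x = 2 * z * sigma / t.amplitude
        if x >= 1:
            return math.inf
        return -math.log1p(-x) / t.rate


def make_truth(
    cell_lines: list[str],
    n_analytes: int = 500,
    n_shared: int = 15,
    n_line_specific: int = 10,
    sigma_log: float = 0.05,
    amplitude_over_baseline: float = 2.0,
    rate_range: tuple[float, float] = (0.005, 0.05),
    baseline_range: tuple[float, float] = (100.0, 5000.0),
    seed: int = 0,
) -> TruthLedger:
    """Plant a protein menu: shared responders that track every tumor line,
    per-line specific responders, and null analytes for the remainder."""
    n_resp = n_shared + n_line_specific * len(cell_lines)
    if n_resp > n_analytes:
        raise ValueError("more responders requested than analytes")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 202]))
    classes: list[tuple[str, str | None]] = (
        [(SHARED, None)] * n_shared
        + [(LINE_SPECIFIC, line) for line in cell_lines
           for _ in range(n_line_specific)]
        + [(NULL, None)] * (n_analytes - n_resp)
    )
    baselines = np.exp(rng.uniform(math.log(baseline_range[0]),
                                   math.log(baseline_range[1]), n_analytes))
    rates = np.exp(rng.uniform(math.log(rate_range[0]),
                               math.log(rate_range[1]), n_analytes))
    bin_idx = rng.choice(len(DILUTION_BINS), size=n_analytes, p=[0.4, 0.4, 0.2])
    analytes = {}
    for i, (cls, line) in enumerate(classes):
        aid = f"seq.{i + 1:04d}"
        analytes[aid] = AnalyteTruth(
            analyte_id=aid,
            analyte_class=cls,
            line=line,
            baseline=float(baselines[i]),
            amplitude=0.0 if cls == NULL
            else float(amplitude_over_baseline * baselines[i]),
            rate=float(rates[i]),
            sigma_log=sigma_log,
            dilution_bin=DILUTION_BINS[bin_idx[i]],
        )
    hyb_ref = pd.Series(
        np.logspace(2.0, 4.5, N_HYB_CONTROLS),
        index=[f"hce.{j + 1:02d}" for j in range(N_HYB_CONTROLS)],
        name="Reference",
    )
    cal_ref = pd.Series({a: t.baseline for a, t in analytes.items()},
                        name="Reference")
    ledger = TruthLedger(analytes, hyb_ref, cal_ref, seed=seed)
    ledger.validate()
    return ledger


def generate_rfu(
    truth: TruthLedger,
    samples: pd.DataFrame,
    seed: int,
    hyb_scale_sd: float = 0.05,
    plate_scale_sd: float = 0.05,
    include_noise: bool = True,
    include_artifacts: bool = True,
) -> RFUDataset:
    """Raw RFU matrix for *samples* under the planted truth.

    ``RFU = [C + A(1 - e^{-B V})] * hybScale(sample) * plateScale(plate,
    analyte) * 10^eps`` with ``eps ~ N(0, sigma_log)``; hybridization
    controls see only the hybridization scale and noise.  All values are
    positive by construction.  Artifact draws are recorded in the ledger.
    """
    if seed is None:
        raise ValueError("a seed must be supplied")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 303]))
    required = {"CellLine", "PlateId", "SampleType", "TumorVolume_mm3"}
    missing = required - set(samples.columns)
    if missing:
        raise ValueError(f"sample table misses columns {sorted(missing)}")

    analyte_ids = list(truth.analytes)
    hyb_ids = list(truth.hyb_reference.index)
    plates = sorted(samples["PlateId"].unique())
    n_s = len(samples)

    if include_artifacts:
        hyb_scale = pd.Series(
            np.power(10.0, rng.normal(0.0, hyb_scale_sd, n_s)),
            index=samples.index, name="HybScale")
        plate_scale = pd.DataFrame(
            np.power(10.0, rng.normal(0.0, plate_scale_sd,
                                      (len(plates), len(analyte_ids)))),
            index=pd.Index(plates, name="PlateId"), columns=analyte_ids)
    else:
        hyb_scale = pd.Series(1.0, index=samples.index, name="HybScale")
        plate_scale = pd.DataFrame(1.0, index=pd.Index(plates, name="PlateId"),
                                   columns=analyte_ids)
    truth.hyb_scale = hyb_scale
    truth.plate_scale = plate_scale
    truth.validate()

    volumes = pd.to_numeric(samples["TumorVolume_mm3"]).fillna(0.0).to_numpy()
    lines = samples["CellLine"].to_numpy()
    mean = np.empty((n_s, len(analyte_ids)))
    for j, aid in enumerate(analyte_ids):
        t = truth.analytes[aid]
        if t.amplitude == 0:
            mean[:, j] = t.baseline
        else:
            responds = np.array([t.responds_to(line) for line in lines])
            mean[:, j] = t.baseline + np.where(
                responds,
                t.amplitude * (1 - np.exp(-t.rate * volumes)),
                0.0,
            )
    mean *= hyb_scale.to_numpy()[:, None]
    mean *= plate_scale.loc[samples["PlateId"]].to_numpy()
    if include_noise:
        sig = np.array([truth.analytes[a].sigma_log for a in analyte_ids])
        mean *= np.power(10.0, rng.normal(0.0, 1.0, mean.shape) * sig[None, :])

    hyb_vals = np.tile(truth.hyb_reference.to_numpy(), (n_s, 1))
    hyb_vals *= hyb_scale.to_numpy()[:, None]
    if include_noise:
        hyb_sigma = float(np.median([t.sigma_log for t in truth.analytes.values()]))
        hyb_vals *= np.power(10.0, rng.normal(0.0, hyb_sigma, hyb_vals.shape))

    values = pd.DataFrame(
        np.hstack([mean, hyb_vals]), index=samples.index,
        columns=pd.Index(analyte_ids + hyb_ids, name="SeqId"))
    analyte_meta = pd.DataFrame(
        {
            "TargetName": [f"Target {a}" for a in analyte_ids]
            + [f"HybControl {h}" for h in hyb_ids],
            "DilutionBin": [truth.analytes[a].dilution_bin for a in analyte_ids]
            + ["none"] * len(hyb_ids),
            "AnalyteType": [PROTEIN] * len(analyte_ids)
            + [HYB_CONTROL] * len(hyb_ids),
        },
        index=values.columns,
    )
    sample_meta = samples[["AnimalId", "Group", "StudyDay", "PlateId",
                           "SampleType", "TumorVolume_mm3"]].copy()
    header = {"Source": "xenoplasma.synthetic", "Seed": str(seed)}
    return RFUDataset(values, sample_meta, analyte_meta, header)


def truth_marker_sets(
    truth: TruthLedger, groups: dict[str, str]
) -> dict[str, set[str]]:
    """Planted responder set per group (group name → cell line mapping).

    Shared responders appear in every tumor group's set; control groups map
    to the empty set; null analytes appear nowhere.
    """
    return {name: truth.responders(line) for name, line in groups.items()}
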