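"""Saturating-exponential calibration and minimum detectable tumor volume.

Each responsive analyte's plasma signal is modeled against tumor volume V as

    RFU(V) = A * (1 - exp(-B * V)) + C

with baseline C, maximal increment A and approach rate B.  Assuming the
residual RFU variance is constant in V, a 95% band around the no-tumor
baseline is ``C ± z * sigma`` and around the fitted curve
``RFU(V) ∓ z * sigma``.  The minimum detectable tumor volume (MDTV) is the
volume at which the lower curve band first clears the upper baseline
bound, which has the closed form

    MDTV = -ln(1 - 2 z sigma / A) / B,

undefined ("not detectable") when ``2 z sigma >= A``.  Mouse-scale MDTVs
translate to human-equivalent spherical tumor diameters by scaling the
volume with the human:mouse blood-volume ratio.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

CONSTANT_VARIANCE = "constant-variance closed form"
DELTA_METHOD = "delta-method band"


class FitError(RuntimeError):
    pass


@dataclass
class SaturationFit:
    """Least-squares estimate of the saturating-exponential response."""

    amplitude: float  # A [RFU]
    rate: float  # B [1/mm^3]
    baseline: float  # C [RFU]
    covariance: np.ndarray  # 3x3, parameter order (A, B, C)
    sigma: float  # residual sd [RFU], n-3 df
    n_obs: int
    converged: bool
    responder: bool  # False when A ~ 0 or B <= 0 at the optimum

    def predict(self, volume) -> np.ndarray:
        v = np.asarray(volume, dtype=float)
        return self.baseline + self.amplitude * (1 - np.exp(-self.rate * v))


@dataclass
class MDTVEstimate:
    volume: float | None  # mm^3; None when not detectable
    z: float
    baseline_interval: tuple[float, float]  # (lower, upper) [RFU]
    method: str = CONSTANT_VARIANCE

    @property
    def detectable(self) -> bool:
        return self.volume is not None


@dataclass(frozen=True)
class BloodScaling:
    """Mouse-to-human blood volume scaling.

    Defaults: a 70 kg human at 70 mL/kg (4900 mL) and a 25 g mouse at
    58.5 mL/kg (1.4625 mL), a volume ratio of ~3350.
    """

    mouse_ml: float = 0.025 * 58.5
    human_ml: float = 70.0 * 70.0

    def __post_init__(self):
        if self.mouse_ml <= 0 or self.human_ml <= 0:
            raise ValueError("blood volumes must be positive")

    @property
    def ratio(self) -> float:
        return self.human_ml / self.mouse_ml


DEFAULT_SCALING = BloodScaling()


def _model(v, a, b, c):
    return c + a * (1.0 - np.exp(-b * v))


def fit_saturation(volumes, rfu, max_restarts: int = 4) -> SaturationFit:
    """Nonlinear least-squares fit of ``RFU = A(1-e^{-BV}) + C``.

    Initialization: C0 = mean RFU at the smallest volumes, A0 = signal
    span, B0 = ln 2 / (volume at half rise).  Multiplicative restarts on
    B0 guard against a bad initial rate.  A fit whose amplitude is
    indistinguishable from zero, or whose rate is non-positive, is flagged
    ``responder=False``; non-convergence after restarts flags
    ``converged=False``.
    """
    v = np.asarray(volumes, dtype=float)
    y = np.asarray(rfu, dtype=float)
    if v.shape != y.shape or v.ndim != 1:
        raise ValueError("volumes and rfu must be matching 1-D arrays")
    if len(v) < 4:
        raise ValueError("need at least 4 observations")
    if len(np.unique(v)) < 2:
        raise FitError("all volumes identical: rate B is unidentifiable")
    if v.min() > 0.05 * v.max():
        raise FitError("no observations near V=0: baseline C is unidentifiable")

    order = np.argsort(v)
    v_s, y_s = v[order], y[order]
    n_base = max(2, int(round(0.2 * len(v))))
    c0 = float(np.mean(y_s[:n_base]))
    a0 = max(float(y.max() - y.min()), 1e-12)
    half = c0 + 0.5 * a0
    above = v_s[y_s >= half]
    v_half = float(above[0]) if len(above) and above[0] > 0 else max(
        float(np.median(v_s[v_s > 0])), 1e-12)
    b0 = math.log(2.0) / v_half

    span = float(np.ptp(y))
    best = None
    for restart in range(max_restarts + 1):
        b_init = b0 * (10.0 ** (restart - max_restarts // 2))
        try:
            popt, pcov = curve_fit(
                _model, v, y, p0=(a0, b_init, c0),
                bounds=([-np.inf, 1e-12, -np.inf], [np.inf, np.inf, np.inf]),
                maxfev=20000,
            )
        except RuntimeError:
            continue
        resid = y - _model(v, *popt)
        ss = float(resid @ resid)
        if best is None or ss < best[2]:
            best = (popt, pcov, ss)
    if best is None:
        return SaturationFit(np.nan, np.nan, np.nan, np.full((3, 3), np.nan),
                             np.nan, len(v), converged=False, responder=False)
    (a, b, c), pcov, ss = best
    dof = max(len(v) - 3, 1)
    sigma = math.sqrt(ss / dof)
    # amplitude below a few residual sds (or a vanishing share of the data
    # span) cannot be distinguished from a flat response
    responder = b > 0 and a > max(2.0 * sigma, 1e-6 * max(span, 1.0))
    return SaturationFit(float(a), float(b), float(c), np.asarray(pcov),
                         sigma, len(v), converged=True, responder=responder)


def baseline_interval(
    baseline_mean: float, sigma: float, z: float = 1.96
) -> tuple[float, float]:
    """Constant-variance confidence interval around the no-tumor signal."""
    if sigma is None or not np.isfinite(sigma):
        raise ValueError("sigma undefined")
    if sigma < 0 or z < 0:
        raise ValueError("sigma and z must be non-negative")
    return baseline_mean - z * sigma, baseline_mean + z * sigma


def estimate_mdtv(fit: SaturationFit, z: float = 1.96) -> MDTVEstimate:
    """Invert the band construction for the detection-limit volume.

    The lower band of the fitted curve, ``C + A(1-e^{-BV}) - z sigma``,
    meets the upper baseline bound ``C + z sigma`` where
    ``A(1-e^{-BV}) = 2 z sigma``; when ``2 z sigma >= A`` the two bands
    never separate and the analyte is flagged not detectable.
    """
    if not fit.converged:
        raise FitError("cannot estimate MDTV from a non-converged fit")
    if not fit.responder:
        raise FitError("cannot estimate MDTV for a non-responder fit")
    interval = baseline_interval(fit.baseline, fit.sigma, z)
    x = 2.0 * z * fit.sigma / fit.amplitude
    if x >= 1.0:
        return MDTVEstimate(None, z, interval)
    volume = -math.log1p(-x) / fit.rate
    return MDTVEstimate(float(volume), z, interval)


def human_equivalent_diameter(
    v_mouse_mm3: float,
    scaling: BloodScaling = DEFAULT_SCALING,
    ndigits: int | None = 1,
) -> float:
    """Human-equivalent spherical tumor diameter, in cm.

    Scales the mouse-detectable volume by the human:mouse blood-volume
    ratio (same tumor-to-blood dilution), then converts the scaled volume
    to the diameter of a sphere, ``d = (6V/pi)^(1/3)``.  Rounded to one
    decimal by default; pass ``ndigits=None`` for the raw value.
    """
    if v_mouse_mm3 <= 0:
        raise ValueError("mouse volume must be positive")
    v_human = v_mouse_mm3 * scaling.ratio
    d_cm = (6.0 * v_human / math.pi) ** (1.0 / 3.0) / 10.0
    return d_cm if ndigits is None else round(d_cm, ndigits)


def mdtv_table(fits: dict[str, SaturationFit], z: float = 1.96,
               scaling: BloodScaling = DEFAULT_SCALING):
    """Per-analyte MDTV summary rows (dicts, ready for a DataFrame)."""
    rows = []
    for aid, fit in fits.items():
        row = {
            "analyte": aid,
            "A": fit.amplitude, "B": fit.rate, "C": fit.baseline,
            "sigma": fit.sigma, "converged": fit.converged,
            "responder": fit.responder,
            "mdtv_mm3": np.nan, "human_diameter_cm": np.nan,
            "flag": "",
        }
        if not fit.converged:
            row["flag"] = "non-converged"
        elif not fit.responder:
            row["flag"] = "non-responder"
        else:
            est = estimate_mdtv(fit, z)
            if not est.detectable:
                row["flag"] = "not-detectable"
            else:
                row["mdtv_mm3"] = est.volume
                row["human_diameter_cm"] = human_equivalent_diameter(
                    est.volume, scaling)
        rows.append(row)
    return rows
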