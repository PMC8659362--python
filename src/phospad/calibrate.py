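"""Calibration, detection limits, inverse prediction and field statistics.

Fits the concentration-ARI response by ordinary least squares (linear over
the regulatory-relevant 0-10 mg/L range, or log-linear for wide-range
demonstration sets), derives ICH-style detection limits

    LOD = 3.3 * sigma_blank / slope,    LOQ = 10 * sigma_blank / slope,

inverts readings to concentration estimates with first-order uncertainty
propagation, classifies estimates into the four map brackets
(none < 1, low 1-3, medium 4-6, high >= 7 mg/L, after half-up integer
rounding), and provides the blank-equivalence Welch t-test, the one
significant-figure method-comparison table, and the colour-development
plateau-time estimator.
"""

from __future__ import annotations

import enum
import hashlib
import json
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InsufficientDataError, OutOfRangeError


@dataclass(frozen=True)
class CalibrationModel:
    """OLS calibration ARI = beta0 + beta1 * x, x = c or log10(c).

    sigma_resid is the residual standard deviation (ARI units);
    sigma_blank the dispersion of blank-sample (c = 0) ARI replicates,
    falling back to sigma_resid when no blanks are present.
    """

    beta0: float
    beta1: float
    sigma_resid: float
    sigma_blank: float
    r_squared: float
    valid_range: tuple[float, float]
    form: str = "linear"
    n_points: int = 0

    @property
    def accepted(self) -> bool:
        return self.beta1 > 0

    def predict(self, c):
        x = np.log10(c) if self.form == "log-linear" else np.asarray(c, dtype=float)
        return self.beta0 + self.beta1 * x

    def to_dict(self) -> dict:
        return {
            "beta0": self.beta0,
            "beta1": self.beta1,
            "sigma_resid": self.sigma_resid,
            "sigma_blank": self.sigma_blank,
            "r_squared": self.r_squared,
            "valid_range": list(self.valid_range),
            "form": self.form,
            "n_points": self.n_points,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CalibrationModel":
        return cls(
            beta0=d["beta0"],
            beta1=d["beta1"],
            sigma_resid=d["sigma_resid"],
            sigma_blank=d["sigma_blank"],
            r_squared=d["r_squared"],
            valid_range=tuple(d["valid_range"]),
            form=d.get("form", "linear"),
            n_points=d.get("n_points", 0),
        )


def fit_calibration(points, form: str = "linear") -> CalibrationModel:
    """Fit the calibration line to (concentration, ARI) replicate pairs.

    ``points`` is any iterable of (c, ari) pairs, an (n, 2) array, or a
    DataFrame with columns ``concentration_mg_per_L`` and ``ari``.  At least
    three distinct concentrations are required; the log-linear form requires
    all concentrations positive.
    """
    if isinstance(points, pd.DataFrame):
        arr = points[["concentration_mg_per_L", "ari"]].to_numpy(dtype=float)
    else:
        arr = np.asarray(list(points) if not isinstance(points, np.ndarray) else points, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("points must be (concentration, ARI) pairs")
    c, y = arr[:, 0], arr[:, 1]
    if len(np.unique(c)) < 3:
        raise InsufficientDataError(
            f"need >= 3 distinct concentrations, got {len(np.unique(c))}"
        )
    if form == "log-linear":
        if np.any(c <= 0):
            raise ValueError("log-linear form requires all concentrations > 0")
        x = np.log10(c)
    elif form == "linear":
        x = c
    else:
        raise ValueError(f"unknown form {form!r}")

    res = stats.linregress(x, y)
    fitted = res.intercept + res.slope * x
    resid = y - fitted
    dof = len(y) - 2
    sigma_resid = float(np.sqrt(np.sum(resid**2) / dof)) if dof > 0 else 0.0
    blanks = y[c == 0]
    if len(blanks) >= 2:
        sigma_blank = float(np.std(blanks, ddof=1))
    else:
        sigma_blank = sigma_resid
    return CalibrationModel(
        beta0=float(res.intercept),
        beta1=float(res.slope),
        sigma_resid=sigma_resid,
        sigma_blank=sigma_blank,
        r_squared=float(res.rvalue**2),
        valid_range=(float(c.min()), float(c.max())),
        form=form,
        n_points=len(y),
    )


def lod_loq(model: CalibrationModel) -> tuple[float, float]:
    """ICH-style limits: LOD = 3.3 sigma_blank/slope, LOQ = 10 sigma_blank/slope."""
    if model.beta1 <= 0:
        raise ValueError(
            f"model slope must be positive for LOD/LOQ, got {model.beta1}"
        )
    lod = 3.3 * model.sigma_blank / model.beta1
    loq = 10.0 * model.sigma_blank / model.beta1
    return (lod, loq)


@dataclass(frozen=True)
class ConcentrationEstimate:
    """Inverse prediction with a first-order uncertainty interval."""

    value: float  # mg/L (numeric value always retained, even below LOD)
    se: float
    ci_low: float
    ci_high: float
    below_lod: bool
    lod: float

    @property
    def label(self) -> str:
        return "<LOD" if self.below_lod else f"{self.value:.2f} mg/L"


def invert(
    model: CalibrationModel, ari_mean: float, ari_sd: float = 0.0, n: int = 1
) -> ConcentrationEstimate:
    """Invert a device reading (mean ARI of n zones) to a concentration.

    The standard error combines the reading's own uncertainty ari_sd/sqrt(n)
    with the calibration residual dispersion, both divided by the slope
    (first-order propagation); the interval is the +/- 1.96 se band.
    Readings above the response at the top of the calibrated range raise
    :class:`OutOfRangeError` rather than extrapolate.
    """
    if not model.accepted:
        raise ValueError("calibration model has non-positive slope; refusing inversion")
    if model.form != "linear":
        raise ValueError("inversion implemented for the linear form only")
    c_max = model.valid_range[1]
    if ari_mean > model.predict(c_max) + 2.0 * model.sigma_resid:
        raise OutOfRangeError(
            f"ARI {ari_mean:.4f} above calibrated response at {c_max} mg/L"
        )
    value = (ari_mean - model.beta0) / model.beta1
    se_ari = math.sqrt((ari_sd / math.sqrt(max(n, 1))) ** 2 + model.sigma_resid**2)
    se = se_ari / model.beta1
    lod = lod_loq(model)[0]
    return ConcentrationEstimate(
        value=float(value),
        se=float(se),
        ci_low=float(value - 1.96 * se),
        ci_high=float(value + 1.96 * se),
        below_lod=bool(value < lod),
        lod=float(lod),
    )


def save_model(model: CalibrationModel, path, provenance: dict | None = None) -> None:
    doc = model.to_dict()
    doc["provenance"] = provenance or {}
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)


def load_model(path) -> CalibrationModel:
    with open(path) as fh:
        return CalibrationModel.from_dict(json.load(fh))


def input_hash(path) -> str:
    """SHA-256 of an input file, for model provenance."""
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        h.update(fh.read())
    return h.hexdigest()


# ---------------------------------------------------------------------------
# bracket classification


class LevelCategory(enum.IntEnum):
    """Ordered phosphate brackets used for map pins."""

    NONE = 0
    LOW = 1
    MEDIUM = 2
    HIGH = 3

    @property
    def label(self) -> str:
        return self.name.lower()


def classify_level(c: float) -> LevelCategory:
    """Map a concentration (mg/L) to its bracket.

    The concentration is rounded half-up to the nearest integer first
    (the brackets are integer-valued: 0 none, 1-3 low, 4-6 medium, >= 7
    high), which closes the printed gaps between 3 and 4 and between
    6 and 7.
    """
    if c < 0:
        raise ValueError(f"concentration must be non-negative, got {c}")
    rounded = math.floor(c + 0.5)
    if rounded == 0:
        return LevelCategory.NONE
    if rounded <= 3:
        return LevelCategory.LOW
    if rounded <= 6:
        return LevelCategory.MEDIUM
    return LevelCategory.HIGH


# ---------------------------------------------------------------------------
# field statistics


@dataclass(frozen=True)
class BlankEquivalenceResult:
    t_stat: float
    t_crit: float
    df: float
    p_value: float
    indistinguishable: bool

    @property
    def verdict(self) -> str:
        return (
            "indistinguishable from blank"
            if self.indistinguishable
            else "distinguishable from blank"
        )


def blank_equivalence_test(sample_aris, blank_aris, alpha: float = 0.05) -> BlankEquivalenceResult:
    """Welch two-sample two-tailed t-test of sample vs blank ARIs.

    The verdict is "indistinguishable from blank" iff |t| < t_crit at the
    given alpha (Welch-Satterthwaite degrees of freedom).
    """
    a = np.asarray(sample_aris, dtype=float)
    b = np.asarray(blank_aris, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise InsufficientDataError("need >= 2 values per group for the t-test")
    va, vb = np.var(a, ddof=1), np.var(b, ddof=1)
    na, nb = len(a), len(b)
    se2 = va / na + vb / nb
    if se2 == 0:
        t_stat, df = 0.0, float(na + nb - 2)
        p = 1.0
    else:
        t_stat = float((np.mean(a) - np.mean(b)) / math.sqrt(se2))
        df = float(se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1)))
        p = float(2.0 * stats.t.sf(abs(t_stat), df))
    t_crit = float(stats.t.ppf(1.0 - alpha / 2.0, df))
    return BlankEquivalenceResult(
        t_stat=t_stat,
        t_crit=t_crit,
        df=df,
        p_value=p,
        indistinguishable=bool(abs(t_stat) < t_crit),
    )


def round_1sf(x: float) -> float:
    """Round to one significant figure, half away from zero."""
    if x == 0:
        return 0.0
    sign = 1.0 if x > 0 else -1.0
    mag = abs(x)
    e = math.floor(math.log10(mag))
    f = 10.0**e
    return sign * math.floor(mag / f + 0.5) * f


@dataclass(frozen=True)
class MethodComparison:
    table: pd.DataFrame
    agreement: float  # fraction of pairs matching to 1 s.f.


def compare_methods(pad_estimates, reference_estimates) -> MethodComparison:
    """Pairwise agreement of device vs reference estimates to 1 s.f.

    Both methods are judged equivalent on a sample when their concentration
    estimates round to the same single significant figure.
    """
    pad = list(pad_estimates)
    ref = list(reference_estimates)
    if len(pad) != len(ref):
        raise ValueError(
            f"paired lists must have equal length ({len(pad)} vs {len(ref)})"
        )
    rows = []
    for p, r in zip(pad, ref):
        p1, r1 = round_1sf(float(p)), round_1sf(float(r))
        rows.append(
            {
                "pad": float(p),
                "reference": float(r),
                "pad_1sf": p1,
                "reference_1sf": r1,
                "agree": p1 == r1,
            }
        )
    table = pd.DataFrame(rows)
    agreement = float(table["agree"].mean()) if rows else float("nan")
    return MethodComparison(table=table, agreement=agreement)


def plateau_time(timecourse, tolerance: float = 0.05) -> float:
    """Earliest time at which colour development is within ``tolerance`` of
    its plateau.

    The plateau is estimated as the mean of the last two intensity points;
    returns the smallest t with intensity >= (1 - tolerance) * plateau.
    """
    arr = np.asarray(list(timecourse) if not isinstance(timecourse, np.ndarray) else timecourse, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("timecourse must be (t, intensity) pairs")
    if len(arr) < 4:
        raise InsufficientDataError("need >= 4 time points")
    t, y = arr[:, 0], arr[:, 1]
    if np.any(np.diff(t) <= 0):
        raise ValueError("time points must be strictly increasing")
    plateau = float(np.mean(y[-2:]))
    threshold = (1.0 - tolerance) * plateau
    reached = np.nonzero(y >= threshold)[0]
    if len(reached) == 0:
        return float(t[-1])
    return float(t[reached[0]])
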