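"""K_air-surrogate imaging-dose framework.

Air kerma free-in-air at isocenter (K_air) is linear in cumulative tube mAs at
a fixed potential, and linearly tracks the in-phantom cone-beam dose indices
(CBDI at the centre, CBDIw = 1/3 centre + 2/3 periphery), which licenses it as
a surrogate dose metric: fit K_air-vs-mAs once per tube potential, then
estimate the dose of any protocol from its cumulative mAs.  The combined
dual-energy dose is the sum of the per-potential estimates, reported both in
mGy and as a percentage of a reference (clinical) protocol.

The embedded calibration table carries measured (mAs, K_air) pairs for seven
protocols at 80 and 140 kVp; CBDI measured in the 32 cm body phantom converts
to the 16 cm head phantom scale with the standard factor 2.34.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import DegenerateInputError, PairingError, ValidationError
from .materials import _read_resource

#: body (32 cm) to head (16 cm) CTDI-phantom conversion factor
BODY_TO_HEAD_FACTOR = 2.34

#: reference temperature (degC) and pressure (kPa) for chamber corrections
REFERENCE_TEMPERATURE_C = 22.0
REFERENCE_PRESSURE_KPA = 101.325


@dataclass(frozen=True)
class KairRecord:
    kvp: float
    cumulative_mAs: float
    framerate: float
    kair: float  # mGy

    def __post_init__(self) -> None:
        if min(self.kvp, self.cumulative_mAs, self.framerate, self.kair) <= 0:
            raise ValidationError("K_air record fields must be positive")


@dataclass(frozen=True)
class CBDIRecord:
    cbdi_center: float
    peripheral: tuple[float, float, float, float]
    phantom_diameter_cm: float = 32.0

    def __post_init__(self) -> None:
        if len(self.peripheral) != 4:
            raise ValidationError("need exactly four peripheral CBDI values")
        if self.cbdi_center <= 0 or min(self.peripheral) <= 0:
            raise ValidationError("CBDI values must be positive")

    @property
    def cbdiw(self) -> float:
        return cbdiw(self.cbdi_center, self.peripheral)


@dataclass(frozen=True)
class LinearModel:
    slope: float
    intercept: float
    r_squared: float
    n_points: int
    x_range: tuple[float, float]

    def __post_init__(self) -> None:
        if self.n_points < 2:
            raise ValidationError("a linear model needs at least two points")
        if not (-1e-12 <= self.r_squared <= 1.0 + 1e-12):
            raise ValidationError("R^2 must lie in [0, 1]")


@dataclass(frozen=True)
class ChamberCalibration:
    nk: float  # Gy/C
    electrometer_factor: float = 1.0
    temperature_c: float = REFERENCE_TEMPERATURE_C
    pressure_kpa: float = REFERENCE_PRESSURE_KPA

    def __post_init__(self) -> None:
        if self.nk <= 0 or self.pressure_kpa <= 0:
            raise ValidationError("calibration coefficient and pressure must be positive")

    @property
    def ptp_correction(self) -> float:
        return (
            (273.15 + self.temperature_c)
            / (273.15 + REFERENCE_TEMPERATURE_C)
            * REFERENCE_PRESSURE_KPA
            / self.pressure_kpa
        )


@dataclass(frozen=True)
class DoseEstimate:
    kair_80: float
    kair_140: float
    combined: float
    relative_percent: int
    extrapolation_flag: bool = False
    meta: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# fitting and estimation
# ---------------------------------------------------------------------------


def fit_linear(points) -> LinearModel:
    """Ordinary least squares y = slope x + intercept over (x, y) pairs."""
    pts = np.asarray(points, float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 2:
        raise ValidationError("need at least two (x, y) points")
    x, y = pts[:, 0], pts[:, 1]
    if np.ptp(x) == 0:
        raise ValidationError("zero variance in x; cannot fit")
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 if ss_tot == 0 else 1.0 - float((resid**2).sum()) / ss_tot
    return LinearModel(
        slope=float(slope),
        intercept=float(intercept),
        r_squared=min(max(r2, 0.0), 1.0),
        n_points=int(x.size),
        x_range=(float(x.min()), float(x.max())),
    )


def kair_from_charge(charge_c: float, cal: ChamberCalibration) -> float:
    """Air kerma (mGy) from collected charge (C) and chamber calibration."""
    if charge_c <= 0:
        raise ValidationError("charge must be positive")
    gray = charge_c * cal.nk * cal.electrometer_factor * cal.ptp_correction
    return gray * 1000.0


def estimate_kair(model: LinearModel, mAs: float) -> tuple[float, bool]:
    """K_air (mGy) at ``mAs``; flags extrapolation beyond the fitted range."""
    if mAs < 0:
        raise ValidationError("mAs must be non-negative")
    flag = not (model.x_range[0] <= mAs <= model.x_range[1])
    return model.slope * mAs + model.intercept, flag


def combined_dose(
    est_80: float, est_140: float, reference: float, extrapolation_flag: bool = False
) -> DoseEstimate:
    """Total DE dose and its integer percentage of the reference dose."""
    if reference <= 0:
        raise DegenerateInputError("reference dose must be positive")
    if est_80 < 0 or est_140 < 0:
        raise ValidationError("dose estimates must be non-negative")
    total = est_80 + est_140
    return DoseEstimate(
        kair_80=float(est_80),
        kair_140=float(est_140),
        combined=float(total),
        relative_percent=int(round(100.0 * total / reference)),
        extrapolation_flag=extrapolation_flag,
    )


def percent_difference(estimate: float, measurement: float) -> float:
    """Signed percent difference (one decimal) of estimate vs measurement."""
    if measurement == 0:
        raise DegenerateInputError("measurement must be nonzero")
    return round(100.0 * (estimate - measurement) / measurement, 1)


def validation_summary(estimates, measurements) -> tuple[float, float]:
    """Mean +/- sd of the signed percent differences over a protocol set."""
    diffs = [percent_difference(e, m) for e, m in zip(estimates, measurements)]
    return float(np.mean(diffs)), float(np.std(diffs))


def cbdiw(center: float, peripheral) -> float:
    """Weighted dose index: 1/3 centre + 2/3 mean of four peripheral values."""
    peripheral = tuple(peripheral)
    if len(peripheral) != 4:
        raise ValidationError("need exactly four peripheral values")
    return center / 3.0 + 2.0 / 3.0 * float(np.mean(peripheral))


def convert_phantom(cbdi_body: float) -> float:
    """Convert a 32 cm body-phantom CBDI to the 16 cm head-phantom scale."""
    if cbdi_body < 0:
        raise ValidationError("dose index must be non-negative")
    return BODY_TO_HEAD_FACTOR * cbdi_body


def correlate_surrogate(cbdi_records: dict, kair_records: dict) -> LinearModel:
    """Fit CBDI (or CBDIw) against K_air over protocols paired by key."""
    if set(cbdi_records) != set(kair_records):
        raise PairingError("CBDI and K_air records are not paired by protocol")
    keys = sorted(cbdi_records)
    pts = [(kair_records[k], cbdi_records[k]) for k in keys]
    return fit_linear(pts)


# ---------------------------------------------------------------------------
# embedded calibration data
# ---------------------------------------------------------------------------


def load_kair_table() -> pd.DataFrame:
    """Embedded (mAs, K_air) calibration measurements per tube potential."""
    return _read_resource("kair_measurements.csv")


def load_protocol_table() -> pd.DataFrame:
    """Embedded pulsed CBCT protocol definitions."""
    return _read_resource("cbct_protocols.csv")


def load_de_run_table() -> pd.DataFrame:
    """Embedded dual-energy run matrix with published K_air values."""
    return _read_resource("de_runs.csv")


def dose_models(use_measured: bool = True) -> dict[int, LinearModel]:
    """K_air-vs-mAs models per tube potential, refit on the embedded table."""
    df = load_kair_table()
    col = "measured_mGy" if use_measured else "estimate_mGy"
    out = {}
    for kvp, grp in df.groupby("kvp"):
        out[int(kvp)] = fit_linear(list(zip(grp["cumulative_mAs"], grp[col])))
    return out
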