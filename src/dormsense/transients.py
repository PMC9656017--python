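"""OJIP fluorescence transients and JIP-test parameters.

A dark-adapted leaf or shoot flashed with saturating light emits a fast
chlorophyll-a fluorescence rise with characteristic inflections: O (origin,
~20 us), J (~2 ms), I (~30 ms) and P (peak).  The JIP test condenses this
curve into algebraic descriptors of photosystem II energy fluxes.  Here the
minimal fluorescence F0 and the raw initial slope are estimated as the
intercept and slope of an ordinary-least-squares line over the initial
(approximately linear) segment of the rise, by default t <= 300 us; the
maximal fluorescence Fm is the global maximum of the transient, so that
curves that decline after an early peak (e.g. frost-killed tissue) are
handled gracefully.

Derived quantities (all dimensionless except M0 in ms^-1):

- Fv/Fm = 1 - F0/Fm           maximal PSII quantum yield (phi_P0)
- VJ = (FJ - F0)/(Fm - F0)    relative variable fluorescence at the J step
- M0 = slope0/(Fm - F0)       initial slope of relative variable fluorescence
- TR0/RC = M0/VJ              trapped energy flux per reaction center
- ABS/RC = TR0/RC / (Fv/Fm)   absorbed energy flux per RC
- ET0/RC = TR0/RC * (1 - VJ)  electron transport flux per RC
- DI0/RC = ABS/RC - TR0/RC    thermally dissipated flux per RC

Frost damage destroys the J-I-P fine structure and collapses Fv/Fm, which
is the basis of the shape classifier in :func:`classify_frost_damage`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "FluorescenceTransient",
    "JipParameters",
    "FrostDamageVerdict",
    "FrostThresholds",
    "InvalidTransientError",
    "estimate_f0_m0",
    "compute_jip",
    "classify_frost_damage",
    "read_transients_csv",
    "write_jip_csv",
    "jip_frame",
]

J_STEP_MS = 2.0
I_STEP_MS = 30.0
#: nearest sample must lie within this factor of the nominal step time
STEP_TIME_TOLERANCE = 1.5
DEFAULT_SEGMENT_END_US = 300.0


class InvalidTransientError(ValueError):
    """Raised when a fluorescence transient cannot be analysed at all."""


@dataclass(frozen=True)
class FluorescenceTransient:
    """One OJIP induction curve.

    times are elapsed microseconds since pulse onset (strictly increasing,
    log-spaced in practice); fluorescence is in arbitrary detector units.
    Negative intensities are clipped to zero at construction and the curve
    is flagged, consistent with the downstream negative-value filtering.
    """

    sensor_id: str
    measured_at: pd.Timestamp
    times_us: np.ndarray
    fluorescence: np.ndarray
    clipped: bool = False

    def __post_init__(self):
        t = np.asarray(self.times_us, dtype=float)
        f = np.asarray(self.fluorescence, dtype=float)
        if t.ndim != 1 or f.ndim != 1 or len(t) != len(f):
            raise InvalidTransientError("times and fluorescence must be equal-length 1-D")
        if len(t) < 30:
            raise InvalidTransientError(f"transient has {len(t)} samples; need >= 30")
        if not np.all(np.diff(t) > 0):
            raise InvalidTransientError("times must be strictly increasing")
        if not np.all(np.isfinite(t)) or not np.all(np.isfinite(f)):
            raise InvalidTransientError("non-finite values in transient")
        clipped = bool(self.clipped)
        if np.any(f < 0):
            f = np.clip(f, 0.0, None)
            clipped = True
        object.__setattr__(self, "times_us", t)
        object.__setattr__(self, "fluorescence", f)
        object.__setattr__(self, "clipped", clipped)

    def __len__(self) -> int:
        return len(self.times_us)


@dataclass(frozen=True)
class JipParameters:
    """JIP-test descriptors of one transient; NaN-filled when invalid."""

    F0: float
    Fm: float
    FJ: float
    FI: float
    Fv_over_Fm: float
    VJ: float
    M0: float
    ABS_per_RC: float
    TR0_per_RC: float
    ET0_per_RC: float
    DI0_per_RC: float
    quality: str  # ok | degraded | invalid
    measured_at: pd.Timestamp | None = None
    sensor_id: str = ""

    FIELDS = (
        "F0", "Fm", "FJ", "FI", "Fv_over_Fm", "VJ", "M0",
        "ABS_per_RC", "TR0_per_RC", "ET0_per_RC", "DI0_per_RC",
    )

    def to_dict(self) -> dict:
        d = {"sensor_id": self.sensor_id, "measured_at": self.measured_at}
        d.update({k: getattr(self, k) for k in self.FIELDS})
        d["quality"] = self.quality
        return d


@dataclass(frozen=True)
class FrostThresholds:
    """Decision thresholds for the frost-damage shape classifier."""

    fv_over_fm: float = 0.2
    step_prominence: float = 0.05


@dataclass(frozen=True)
class FrostDamageVerdict:
    status: str  # healthy | damaged | indeterminate
    features: dict
    measured_at: pd.Timestamp | None = None


def estimate_f0_m0(
    transient: FluorescenceTransient,
    segment_end_us: float = DEFAULT_SEGMENT_END_US,
) -> tuple[float, float]:
    """OLS fit of the initial linear segment of the rise.

    Returns (F0, slope0) where F0 is the intercept (a.u.) and slope0 the
    slope in a.u. per millisecond, fitted over all samples with
    t <= segment_end_us.
    """
    sel = transient.times_us <= segment_end_us
    if sel.sum() < 3:
        raise InvalidTransientError(
            f"only {int(sel.sum())} samples at t <= {segment_end_us} us; need >= 3"
        )
    t_ms = transient.times_us[sel] / 1000.0
    f = transient.fluorescence[sel]
    slope0, f0 = np.polyfit(t_ms, f, 1)
    return float(f0), float(slope0)


def _nearest_sample(transient: FluorescenceTransient, t_ms: float) -> tuple[float, float]:
    """(fluorescence, actual time ms) of the sample nearest a nominal time."""
    i = int(np.argmin(np.abs(transient.times_us - t_ms * 1000.0)))
    return float(transient.fluorescence[i]), float(transient.times_us[i] / 1000.0)


def compute_jip(
    transient: FluorescenceTransient,
    segment_end_us: float = DEFAULT_SEGMENT_END_US,
) -> JipParameters:
    """Compute JIP-test parameters from one OJIP transient.

    Quality grading: ``invalid`` when there is no variable fluorescence
    (flat curve, or Fm <= F0); ``degraded`` when the curve is usable but
    dubious (non-positive fitted F0, Fm barely above F0, VJ outside (0,1),
    step markers far from their nominal times, clipped negatives);
    ``ok`` otherwise.
    """
    meta = {"measured_at": transient.measured_at, "sensor_id": transient.sensor_id}
    f = transient.fluorescence
    if np.ptp(f) == 0:
        nan = float("nan")
        return JipParameters(*(nan,) * 11, quality="invalid", **meta)

    f0_fit, slope0 = estimate_f0_m0(transient, segment_end_us)
    fm = float(np.max(f))
    degraded = transient.clipped
    f0 = f0_fit
    if f0 <= 0:
        degraded = True
        f0 = max(f0, float(np.min(f)))  # fall back to the observed minimum
        if f0 <= 0:
            f0 = np.finfo(float).tiny
    if fm <= f0:
        nan = float("nan")
        return JipParameters(*(nan,) * 11, quality="invalid", **meta)
    if fm <= f0 * 1.05:
        degraded = True

    fj, tj = _nearest_sample(transient, J_STEP_MS)
    fi, ti = _nearest_sample(transient, I_STEP_MS)
    for actual, nominal in ((tj, J_STEP_MS), (ti, I_STEP_MS)):
        ratio = actual / nominal
        if ratio > STEP_TIME_TOLERANCE or ratio < 1.0 / STEP_TIME_TOLERANCE:
            degraded = True

    fv = fm - f0
    fv_fm = 1.0 - f0 / fm
    vj = (fj - f0) / fv
    m0 = slope0 / fv
    if not (0.0 < vj < 1.0):
        degraded = True
    with np.errstate(divide="ignore", invalid="ignore"):
        tr0_rc = m0 / vj if vj != 0 else float("nan")
        abs_rc = tr0_rc / fv_fm if fv_fm > 0 else float("nan")
        et0_rc = tr0_rc * (1.0 - vj)
        di0_rc = abs_rc - tr0_rc
    return JipParameters(
        F0=float(f0), Fm=fm, FJ=fj, FI=fi,
        Fv_over_Fm=float(fv_fm), VJ=float(vj), M0=float(m0),
        ABS_per_RC=float(abs_rc), TR0_per_RC=float(tr0_rc),
        ET0_per_RC=float(et0_rc), DI0_per_RC=float(di0_rc),
        quality="degraded" if degraded else "ok", **meta,
    )


def _smoothed_relative_fluorescence(
    transient: FluorescenceTransient, f0: float, fm: float, n_grid: int = 200
) -> tuple[np.ndarray, np.ndarray]:
    """V(t) = (F - F0)/(Fm - F0) resampled to a uniform log10-time grid and
    smoothed with a short moving average."""
    x = np.log10(transient.times_us / 1000.0)  # log10 ms
    v = (transient.fluorescence - f0) / (fm - f0)
    grid = np.linspace(x[0], x[-1], n_grid)
    vg = np.interp(grid, x, v)
    kernel = np.ones(9) / 9.0
    vs = np.convolve(np.pad(vg, 4, mode="edge"), kernel, mode="valid")
    return grid, vs


def _step_prominences(transient: FluorescenceTransient, params: JipParameters) -> dict:
    """Rise of smoothed V(t) across the J and I step regions.

    A healthy curve rises markedly through ~1-4 ms (into J) and ~15-60 ms
    (through I towards P); a frost-killed curve is a single featureless
    creep, so both rises collapse.  Values are already normalized by Fv
    because V is.
    """
    grid, vs = _smoothed_relative_fluorescence(transient, params.F0, params.Fm)

    def v_at(t_ms: float) -> float:
        return float(np.interp(np.log10(t_ms), grid, vs))

    return {
        "J_prominence": v_at(4.0) - v_at(1.0),
        "I_prominence": v_at(60.0) - v_at(15.0),
    }


def classify_frost_damage(
    params: JipParameters,
    transient: FluorescenceTransient,
    thresholds: FrostThresholds = FrostThresholds(),
) -> FrostDamageVerdict:
    """Classify a shoot as healthy or frost-damaged from transient shape.

    Damaged when Fv/Fm falls below the viability threshold, or when both
    the J and the I step prominences vanish (loss of the O-J-I-P fine
    structure).  Invalid transients yield ``indeterminate``.
    """
    if params.quality == "invalid" or not np.isfinite(params.Fv_over_Fm):
        return FrostDamageVerdict(
            status="indeterminate", features={}, measured_at=transient.measured_at
        )
    features = _step_prominences(transient, params)
    features["Fv_over_Fm"] = params.Fv_over_Fm
    low_yield = params.Fv_over_Fm < thresholds.fv_over_fm
    no_steps = (
        features["J_prominence"] < thresholds.step_prominence
        and features["I_prominence"] < thresholds.step_prominence
    )
    status = "damaged" if (low_yield or no_steps) else "healthy"
    return FrostDamageVerdict(
        status=status, features=features, measured_at=transient.measured_at
    )


# ---------------------------------------------------------------------------
# CSV dialects

def read_transients_csv(path) -> list[FluorescenceTransient]:
    """Read a batch CSV (sensor_id, measured_at, time_us, fluorescence)."""
    df = pd.read_csv(path, comment="#")
    required = {"sensor_id", "measured_at", "time_us", "fluorescence"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    df["measured_at"] = pd.to_datetime(df["measured_at"], utc=True)
    out = []
    for (sensor, when), grp in df.groupby(["sensor_id", "measured_at"], sort=True):
        grp = grp.sort_values("time_us")
        out.append(
            FluorescenceTransient(
                sensor_id=str(sensor),
                measured_at=when,
                times_us=grp["time_us"].to_numpy(float),
                fluorescence=grp["fluorescence"].to_numpy(float),
            )
        )
    return out


def jip_frame(params: list[JipParameters]) -> pd.DataFrame:
    """Stack JipParameters into a DataFrame (one row per transient)."""
    return pd.DataFrame([p.to_dict() for p in params])


def write_jip_csv(params: list[JipParameters], path) -> None:
    with open(path, "w") as fh:
        fh.write("# dormsense jip parameters v1\n")
        jip_frame(params).to_csv(fh, index=False)
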