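"""Targeted peak extraction from EIC tables.

The workflow mirrors routine targeted post-processing of untargeted LC-MS
data: (1) locate internal-standard apexes within a 0.20-min window around
their library retention times, (2) fit a quadratic recalibration between
expected and observed standard retention times per sample, (3) extract every
target's peak height as the maximum intensity within a 0.20-min window
centered on its recalibrated retention time, and (4) compute signal-to-noise
as peak height over the median intensity of the full +/- 1 min EIC span.
No smoothing or area integration is applied; the apex location of an
internal standard is refined by three-point parabolic interpolation in log
intensity (exact for a Gaussian peak), which sharpens the recalibration fit
without altering any reported peak height.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .library import IonDatabase
from .matrix import FeatureMatrix
from .simulate import EICSet, InjectionPlan

__all__ = [
    "PeakMeasurement",
    "RTCalibration",
    "observed_standard_rt",
    "fit_rt_recalibration",
    "extract_peak",
    "signal_to_noise",
    "assemble_feature_matrix",
    "extract_run",
    "format_search_window",
]

DEFAULT_WINDOW = 0.20  # minutes, total width of the peak-search window


@dataclasses.dataclass(frozen=True)
class PeakMeasurement:
    ion_id: str
    sample_id: str
    peak_height: float
    apex_rt: float
    snr: float
    window_lo: float
    window_hi: float
    flags: frozenset[str] = frozenset()


@dataclasses.dataclass(frozen=True)
class RTCalibration:
    """Quadratic expected -> observed retention-time map for one sample."""

    sample_id: str
    a: float
    b: float
    c: float
    residuals: tuple[float, ...] = ()
    n_standards: int = 0
    flags: frozenset[str] = frozenset()

    def apply(self, expected_rt: float | np.ndarray):
        e = np.asarray(expected_rt, dtype=float)
        out = self.a * e**2 + self.b * e + self.c
        return float(out) if np.isscalar(expected_rt) else out

    @classmethod
    def identity(cls, sample_id: str, flags: Iterable[str] = ()) -> "RTCalibration":
        return cls(sample_id=sample_id, a=0.0, b=1.0, c=0.0,
                   flags=frozenset(flags))


def _window_indices(
    rt: np.ndarray, center: float, window: float
) -> tuple[int, int, set[str]]:
    lo, hi = center - window / 2.0, center + window / 2.0
    flags: set[str] = set()
    if lo < rt[0] - 1e-12 or hi > rt[-1] + 1e-12:
        flags.add("window_truncated")
    i0 = int(np.searchsorted(rt, lo, side="left"))
    i1 = int(np.searchsorted(rt, hi, side="right"))
    if i1 <= i0:
        raise ValueError(
            f"no grid points inside the window [{lo:.4f}, {hi:.4f}] min"
        )
    return i0, i1, flags


def _parabolic_refine(rt: np.ndarray, y: np.ndarray, idx: int) -> float:
    """Refine an apex position by a log-intensity parabola through the apex
    and its two neighbours; exact for Gaussian peaks once the baseline is
    removed.  Falls back to the grid apex when the geometry is degenerate."""
    if idx <= 0 or idx >= len(y) - 1:
        return float(rt[idx])
    baseline = float(np.median(y))
    y3 = y[idx - 1 : idx + 2] - baseline
    if np.any(y3 <= 0) or not (y3[1] > y3[0] and y3[1] > y3[2]):
        return float(rt[idx])
    l0, l1, l2 = np.log(y3)
    denom = l0 - 2.0 * l1 + l2
    if denom >= 0 or not np.isfinite(denom):
        return float(rt[idx])
    step = (rt[idx + 1] - rt[idx - 1]) / 2.0
    delta = 0.5 * (l0 - l2) / denom
    delta = float(np.clip(delta, -0.5, 0.5))
    return float(rt[idx] + delta * step)


def observed_standard_rt(
    rt: Sequence[float] | np.ndarray,
    intensities: Sequence[float] | np.ndarray,
    expected_rt: float,
    window: float = DEFAULT_WINDOW,
    refine: bool = True,
) -> tuple[float | None, set[str]]:
    """Apex retention time of an internal standard near its expected RT.

    Returns ``(apex_rt, flags)``.  The apex is the grid point of maximum
    intensity inside ``expected_rt +/- window/2`` (ties broken toward the
    earliest RT); an all-zero window yields ``(None, {"not_detected"})`` so
    the standard is excluded from the recalibration fit.  An apex sitting on
    a window boundary is flagged ``"apex_on_boundary"`` but still usable.
    """
    rt = np.asarray(rt, dtype=float)
    y = np.asarray(intensities, dtype=float)
    if rt.shape != y.shape or rt.ndim != 1:
        raise ValueError("rt and intensities must be 1-D arrays of equal length")
    i0, i1, flags = _window_indices(rt, expected_rt, window)
    seg = y[i0:i1]
    if np.all(seg == 0):
        flags.add("not_detected")
        return None, flags
    rel = int(np.argmax(seg))  # argmax returns the first (earliest) maximum
    idx = i0 + rel
    if rel == 0 or rel == len(seg) - 1:
        flags.add("apex_on_boundary")
    apex = _parabolic_refine(rt, y, idx) if refine else float(rt[idx])
    return apex, flags


def fit_rt_recalibration(
    expected: Sequence[float],
    observed: Sequence[float],
    sample_id: str = "",
) -> RTCalibration:
    """Least-squares quadratic fit observed = a*expected**2 + b*expected + c."""
    e = np.asarray(expected, dtype=float)
    o = np.asarray(observed, dtype=float)
    if e.shape != o.shape or e.ndim != 1:
        raise ValueError("expected and observed must be 1-D arrays of equal length")
    if len(e) < 3:
        raise ValueError(
            f"insufficient standards for the quadratic fit: {len(e)} < 3"
        )
    if np.unique(e).size < 3:
        raise ValueError("rank-deficient design: need >= 3 distinct expected RTs")
    a, b, c = np.polyfit(e, o, 2)
    residuals = o - (a * e**2 + b * e + c)
    return RTCalibration(
        sample_id=sample_id,
        a=float(a),
        b=float(b),
        c=float(c),
        residuals=tuple(float(r) for r in residuals),
        n_standards=len(e),
    )


def extract_peak(
    rt: Sequence[float] | np.ndarray,
    intensities: Sequence[float] | np.ndarray,
    calibrated_rt: float,
    window: float = DEFAULT_WINDOW,
    ion_id: str = "",
    sample_id: str = "",
) -> PeakMeasurement:
    """Peak height = maximum intensity within ``calibrated_rt +/- window/2``.

    The apex is the earliest grid point attaining the maximum.  Signal-to-
    noise is computed against the median of the full trace and may be
    infinite on a zero-median trace (flagged).
    """
    rt = np.asarray(rt, dtype=float)
    y = np.asarray(intensities, dtype=float)
    i0, i1, flags = _window_indices(rt, calibrated_rt, window)
    seg = y[i0:i1]
    rel = int(np.argmax(seg))
    height = float(seg[rel])
    apex = float(rt[i0 + rel])
    snr, snr_flags = signal_to_noise(y, height)
    return PeakMeasurement(
        ion_id=ion_id,
        sample_id=sample_id,
        peak_height=height,
        apex_rt=apex,
        snr=snr,
        window_lo=calibrated_rt - window / 2.0,
        window_hi=calibrated_rt + window / 2.0,
        flags=frozenset(flags | snr_flags),
    )


def signal_to_noise(
    intensities: Sequence[float] | np.ndarray, peak_height: float
) -> tuple[float, set[str]]:
    """Peak height divided by the median intensity of the full EIC span."""
    y = np.asarray(intensities, dtype=float)
    if y.size == 0:
        raise ValueError("empty trace")
    if np.any(y < 0):
        raise ValueError("negative intensities: corrupt input")
    med = float(np.median(y))
    if med == 0.0:
        return math.inf, {"zero_median_noise"}
    return peak_height / med, set()


def format_search_window(
    lo: float, hi: float, decimals: int = 2
) -> tuple[float, float]:
    """Truncate window bounds for display (floor to the given decimals)."""
    f = 10.0**decimals
    return math.floor(lo * f) / f, math.floor(hi * f) / f


def assemble_feature_matrix(
    measurements: Iterable[PeakMeasurement],
    plan: InjectionPlan,
    db: IonDatabase,
    provenance: str = "raw",
) -> FeatureMatrix:
    """Merge per-(sample, ion) measurements into a samples x ions matrix.

    Every measurement must belong to a planned sample; (sample, ion) cells
    without a measurement hold an explicit NaN marker, never zero.
    """
    known_samples = set(plan.sample_ids)
    rows = []
    for m in measurements:
        if m.sample_id not in known_samples:
            raise ValueError(
                f"measurement for sample {m.sample_id!r} absent from the plan"
            )
        rows.append(
            (m.sample_id, m.ion_id, m.peak_height, m.snr, m.apex_rt)
        )
    long = pd.DataFrame(
        rows, columns=["sample_id", "ion_id", "peak_height", "snr", "apex_rt"]
    )
    if long.duplicated(["sample_id", "ion_id"]).any():
        raise ValueError("more than one measurement per (sample, ion)")
    sample_order = plan.sample_ids
    ion_order = db.ion_ids

    def _pivot(col: str) -> pd.DataFrame:
        wide = long.pivot(index="sample_id", columns="ion_id", values=col)
        return wide.reindex(index=sample_order, columns=ion_order)

    values = _pivot("peak_height")
    snr = _pivot("snr")
    apex = _pivot("apex_rt")
    return FeatureMatrix(
        values=values,
        samples=plan.annotations(),
        ions=db.to_frame(),
        provenance=provenance,
        snr=snr,
        apex_rt=apex,
    )


def extract_run(
    eics: EICSet,
    plan: InjectionPlan,
    db: IonDatabase,
    window: float = DEFAULT_WINDOW,
) -> tuple[FeatureMatrix, dict[str, RTCalibration]]:
    """Full per-sample extraction: standard apexes, recalibration, peak table.

    Each non-blank sample gets its own quadratic recalibration from the
    internal standards of both polarities; blanks (which carry no spiked
    standards) and samples whose fit is infeasible fall back to the identity
    calibration, flagged in the returned calibration table.
    """
    standards = [ion for ion in db if ion.is_internal_standard]
    calibrations: dict[str, RTCalibration] = {}
    measurements: list[PeakMeasurement] = []
    sample_types = dict(
        zip(plan.records["sample_id"], plan.records["sample_type"])
    )
    sample_pos = {s: i for i, s in enumerate(eics.samples)}

    for sample_id in plan.sample_ids:
        i = sample_pos[sample_id]
        if sample_types[sample_id] == "blank":
            cal = RTCalibration.identity(sample_id, flags=("blank",))
        else:
            expected, observed = [], []
            for std in standards:
                grid = eics.grids[std.ion_id]
                apex, flags = observed_standard_rt(
                    grid, eics.traces[std.ion_id][i], std.expected_rt, window=window
                )
                if apex is None:
                    continue
                expected.append(std.expected_rt)
                observed.append(apex)
            try:
                cal = fit_rt_recalibration(expected, observed, sample_id=sample_id)
            except ValueError:
                cal = RTCalibration.identity(
                    sample_id, flags=("calibration_failed",)
                )
        calibrations[sample_id] = cal
        for ion in db:
            cal_rt = cal.apply(ion.expected_rt)
            measurements.append(
                extract_peak(
                    eics.grids[ion.ion_id],
                    eics.traces[ion.ion_id][i],
                    cal_rt,
                    window=window,
                    ion_id=ion.ion_id,
                    sample_id=sample_id,
                )
            )
    fm = assemble_feature_matrix(measurements, plan, db, provenance="raw")
    return fm, calibrations
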