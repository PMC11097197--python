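"""Inter-modality agreement statistics for velocity-field sequences.

Cardiac cycles are aligned at peak systole (maximum of the
spatial-mean speed), ensemble-averaged, resampled onto a common
reference grid and a 100-point normalized cycle, and compared through
Bland-Altman-style limits of agreement (mean +/- 1.96 SD of the paired
speed differences), per-node difference maps, and absolute peak
differences of temporal velocity profiles.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Optional, Tuple

import numpy as np
from scipy.interpolate import RegularGridInterpolator, interp1d

from .types import VelocityField2D

__all__ = [
    "CardiacEnsemble",
    "AgreementReport",
    "align_cycles",
    "ensemble_from_periodic",
    "resample_to_reference",
    "limits_of_agreement",
    "peak_difference",
]


@dataclass
class CardiacEnsemble:
    """Cycle-aligned, ensemble-averaged velocity field.

    ``mean_vx``/``mean_vy`` have shape (n_phase, ny, nx) on the
    normalized cycle ``phase`` in [0, 1); ``sd_speed`` is the
    cycle-to-cycle SD of the speed (None for a single cycle).
    ``offsets`` records the peak-systole alignment index per cycle.
    """

    x: np.ndarray
    y: np.ndarray
    phase: np.ndarray
    mean_vx: np.ndarray
    mean_vy: np.ndarray
    mask: np.ndarray
    sd_speed: Optional[np.ndarray] = None
    n_cycles: int = 1
    offsets: np.ndarray = dc_field(default_factory=lambda: np.zeros(0, dtype=int))

    def speed(self) -> np.ndarray:
        return np.hypot(self.mean_vx, self.mean_vy)

    def mean_speed_series(self) -> np.ndarray:
        sp = self.speed()[:, self.mask]
        return sp.mean(axis=1)


@dataclass
class AgreementReport:
    """Limits-of-agreement summary of paired speed differences.

    Differences are test minus reference, cm/s; limits are
    mean +/- 1.96 SD.  ``mean_map``/``sd_map`` are the per-node mean
    and SD of the difference over the cycle.
    """

    mean_difference: float
    sd_difference: float
    loa_low: float
    loa_high: float
    n: int
    mean_map: np.ndarray
    sd_map: np.ndarray

    def __post_init__(self) -> None:
        span = self.loa_high - self.loa_low
        if not np.isclose(span, 2 * 1.96 * self.sd_difference, rtol=1e-9, atol=1e-12):
            raise ValueError("limits of agreement inconsistent with mean/SD")


def align_cycles(
    field: VelocityField2D, period: float, n_cycles: int, n_phase: int = 100
) -> CardiacEnsemble:
    """Align cardiac cycles at peak systole and ensemble-average.

    Peak systole in each cycle is the maximum of the spatial-mean
    speed (earliest sample on ties).  Each cycle is cropped to one
    period starting at its peak, linearly resampled to ``n_phase``
    points, and averaged; the per-node/per-phase SD of the speed over
    cycles is stored.
    """
    dt = 1.0 / field.frame_rate
    n_per = int(round(period / dt))
    if n_per < 2:
        raise ValueError("field rate too low to resolve the cycle")
    series = field.mean_speed_series()
    nt = series.size

    peaks = []
    for c in range(nt // n_per):
        seg = series[c * n_per : (c + 1) * n_per]
        p = c * n_per + int(np.argmax(seg))
        if p + n_per <= nt:
            peaks.append(p)
    if len(peaks) < n_cycles:
        raise ValueError(
            f"found only {len(peaks)} complete cycles with a detectable peak, "
            f"need {n_cycles}"
        )
    peaks = peaks[:n_cycles]

    phase = np.linspace(0.0, 1.0, n_phase, endpoint=False)
    src_phase = np.arange(n_per) / n_per
    cyc_vx = np.empty((n_cycles, n_phase, field.y.size, field.x.size))
    cyc_vy = np.empty_like(cyc_vx)
    for i, p in enumerate(peaks):
        seg_x = field.vx[p : p + n_per]
        seg_y = field.vy[p : p + n_per]
        fx = interp1d(src_phase, seg_x, axis=0, bounds_error=False,
                      fill_value=(seg_x[0], seg_x[-1]))
        fy = interp1d(src_phase, seg_y, axis=0, bounds_error=False,
                      fill_value=(seg_y[0], seg_y[-1]))
        cyc_vx[i] = fx(phase)
        cyc_vy[i] = fy(phase)

    mean_vx = cyc_vx.mean(axis=0)
    mean_vy = cyc_vy.mean(axis=0)
    sd_speed = None
    if n_cycles >= 2:
        sd_speed = np.hypot(cyc_vx, cyc_vy).std(axis=0, ddof=1)
    return CardiacEnsemble(
        x=field.x.copy(), y=field.y.copy(), phase=phase,
        mean_vx=mean_vx, mean_vy=mean_vy, mask=field.mask.copy(),
        sd_speed=sd_speed, n_cycles=n_cycles,
        offsets=np.asarray(peaks, dtype=int),
    )


def ensemble_from_periodic(
    field: VelocityField2D, n_phase: int = 100
) -> CardiacEnsemble:
    """Ensemble view of a field that spans exactly one period.

    Used for analytic ground-truth fields: the cycle is rolled so peak
    systole sits at phase 0 (matching :func:`align_cycles` output) and
    resampled to ``n_phase`` points.  SD is zero by construction and
    reported as None.
    """
    peak = int(np.argmax(field.mean_speed_series()))
    vx = np.roll(field.vx, -peak, axis=0)
    vy = np.roll(field.vy, -peak, axis=0)
    src = np.arange(field.t.size) / field.t.size
    phase = np.linspace(0.0, 1.0, n_phase, endpoint=False)
    # periodic linear interpolation via a wrapped endpoint
    src_w = np.concatenate([src, [1.0]])
    vx_w = np.concatenate([vx, vx[:1]], axis=0)
    vy_w = np.concatenate([vy, vy[:1]], axis=0)
    fx = interp1d(src_w, vx_w, axis=0)
    fy = interp1d(src_w, vy_w, axis=0)
    return CardiacEnsemble(
        x=field.x.copy(), y=field.y.copy(), phase=phase,
        mean_vx=fx(phase), mean_vy=fy(phase), mask=field.mask.copy(),
        sd_speed=None, n_cycles=1, offsets=np.array([peak]),
    )


def resample_to_reference(
    test: CardiacEnsemble,
    reference: CardiacEnsemble | VelocityField2D,
    n_time: int = 100,
) -> CardiacEnsemble:
    """Resample an ensemble onto a reference grid and cycle axis.

    Bilinear interpolation in space at the reference node positions,
    linear interpolation in time to ``n_time`` phase points.
    Reference nodes outside the test grid or test mask are flagged
    missing (masked out) and excluded from downstream statistics.
    """
    ref_x, ref_y, ref_mask = reference.x, reference.y, reference.mask

    overlap_x = (ref_x >= test.x[0]) & (ref_x <= test.x[-1])
    overlap_y = (ref_y >= test.y[0]) & (ref_y <= test.y[-1])
    if not (overlap_x.any() and overlap_y.any()):
        raise ValueError("no spatial overlap between test and reference grids")

    phase = np.linspace(0.0, 1.0, n_time, endpoint=False)
    vx_nan = np.where(test.mask[None], test.mean_vx, np.nan)
    vy_nan = np.where(test.mask[None], test.mean_vy, np.nan)
    if test.phase.size != n_time or not np.allclose(test.phase, phase):
        fx = interp1d(test.phase, vx_nan, axis=0, bounds_error=False,
                      fill_value=(vx_nan[0], vx_nan[-1]))
        fy = interp1d(test.phase, vy_nan, axis=0, bounds_error=False,
                      fill_value=(vy_nan[0], vy_nan[-1]))
        vx_nan = fx(phase)
        vy_nan = fy(phase)

    xx, yy = np.meshgrid(ref_x, ref_y)
    query = np.stack([yy.ravel(), xx.ravel()], axis=-1)
    out_vx = np.empty((n_time, ref_y.size, ref_x.size))
    out_vy = np.empty_like(out_vx)
    for i in range(n_time):
        ix = RegularGridInterpolator((test.y, test.x), vx_nan[i],
                                     bounds_error=False, fill_value=np.nan)
        iy = RegularGridInterpolator((test.y, test.x), vy_nan[i],
                                     bounds_error=False, fill_value=np.nan)
        out_vx[i] = ix(query).reshape(ref_y.size, ref_x.size)
        out_vy[i] = iy(query).reshape(ref_y.size, ref_x.size)

    new_mask = ref_mask & np.all(np.isfinite(out_vx) & np.isfinite(out_vy), axis=0)
    if not new_mask.any():
        raise ValueError("no valid nodes after resampling onto the reference grid")
    out_vx[:, ~new_mask] = 0.0
    out_vy[:, ~new_mask] = 0.0
    return CardiacEnsemble(
        x=ref_x.copy(), y=ref_y.copy(), phase=phase,
        mean_vx=out_vx, mean_vy=out_vy, mask=new_mask,
        sd_speed=None, n_cycles=test.n_cycles, offsets=test.offsets.copy(),
    )


def limits_of_agreement(
    test: CardiacEnsemble,
    reference: CardiacEnsemble,
    scope: str = "all_timepoints",
) -> AgreementReport:
    """Bland-Altman limits of agreement of speed differences.

    Differences (test speed minus reference speed) are pooled over all
    common valid nodes — over every phase sample for
    ``scope='all_timepoints'`` or at the reference's peak-systole phase
    only for ``scope='peak_systole'``.  Nodes missing in either
    ensemble are excluded pairwise.
    """
    if scope not in ("all_timepoints", "peak_systole"):
        raise ValueError("scope must be 'all_timepoints' or 'peak_systole'")
    if test.mean_vx.shape != reference.mean_vx.shape:
        raise ValueError("ensembles must share grid and time base; resample first")
    common = test.mask & reference.mask
    if not common.any():
        raise ValueError("no common valid nodes")

    diff_t = test.speed() - reference.speed()  # (n_phase, ny, nx)
    if scope == "peak_systole":
        peak = int(np.argmax(reference.mean_speed_series()))
        pooled = diff_t[peak][common]
    else:
        pooled = diff_t[:, common].ravel()

    mean = float(np.mean(pooled))
    sd = float(np.std(pooled, ddof=1)) if pooled.size > 1 else 0.0
    mean_map = np.where(common, diff_t.mean(axis=0), np.nan)
    sd_map = np.where(common, diff_t.std(axis=0, ddof=0), np.nan)
    return AgreementReport(
        mean_difference=mean,
        sd_difference=sd,
        loa_low=mean - 1.96 * sd,
        loa_high=mean + 1.96 * sd,
        n=int(pooled.size),
        mean_map=mean_map,
        sd_map=sd_map,
    )


def peak_difference(
    test_profile: np.ndarray, reference_profile: np.ndarray
) -> float:
    """Absolute difference of the temporal-profile peaks, |max - max|.

    Compares only the peak magnitudes of the two cycle-averaged
    series, so it is invariant to a time shift of the peak.
    """
    test_profile = np.asarray(test_profile, dtype=float)
    reference_profile = np.asarray(reference_profile, dtype=float)
    return float(abs(test_profile.max() - reference_profile.max()))
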