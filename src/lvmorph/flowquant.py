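"""Phase-contrast flow quantification.

A gated PC-MRI series encodes the through-plane velocity of each pixel in the
image phase: a phase of +/- pi corresponds to a velocity of +/- venc (cm/s).
Summing velocities over a lumen ROI gives a per-cardiac-phase flow rate curve
Q_i (mL/s); the stroke volume over the cycle is the mean of the integrals of
the positive and negative parts of that curve, reported in microliters per
cardiac cycle.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError

__all__ = [
    "FlowSeries",
    "FlowCurve",
    "StrokeVolume",
    "phase_to_velocity",
    "roi_flow",
    "stroke_volume",
]


@dataclass
class FlowSeries:
    """A velocity-encoded phase stack over one cardiac cycle.

    ``phases`` has shape ``(nx, ny, n_phases)`` with values in [-pi, pi]
    (radians); ``venc`` is the velocity-encoding sensitivity in cm/s;
    ``period`` the cardiac cycle length in seconds.
    """

    phases: np.ndarray
    venc: float
    pixel_size: tuple[float, float]  # mm
    period: float  # s
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.phases = np.asarray(self.phases, dtype=float)
        if self.phases.ndim != 3 or self.phases.shape[2] < 2:
            raise ValidationError("phase stack must be (nx, ny, n_phases) with >= 2 phases")
        if self.venc <= 0:
            raise ValidationError(f"venc must be positive, got {self.venc}")
        if self.period <= 0:
            raise ValidationError(f"cardiac period must be positive, got {self.period}")
        dx, dy = self.pixel_size
        if dx <= 0 or dy <= 0:
            raise ValidationError(f"pixel size must be positive, got {(dx, dy)}")
        _check_phase_range(self.phases)

    @property
    def n_phases(self) -> int:
        return self.phases.shape[2]

    @property
    def dt(self) -> float:
        """Uniform inter-phase interval, s (retrospective gating assumed uniform)."""
        return self.period / self.n_phases


@dataclass
class FlowCurve:
    """Per-cardiac-phase flow rates (mL/s) with their uniform time step (s)."""

    q_ml_s: np.ndarray
    dt: float
    level: str = "aqueduct"  # or "cervical"

    def __post_init__(self) -> None:
        self.q_ml_s = np.asarray(self.q_ml_s, dtype=float)
        if self.q_ml_s.ndim != 1 or self.q_ml_s.size < 2:
            raise ValidationError("flow curve must be 1D with >= 2 phases")
        if not np.all(np.isfinite(self.q_ml_s)):
            raise ValidationError("flow curve contains non-finite values")
        if self.dt <= 0:
            raise ValidationError(f"dt must be positive, got {self.dt}")

    @property
    def n_phases(self) -> int:
        return self.q_ml_s.size

    @property
    def times(self) -> np.ndarray:
        """Midpoint times of each cardiac phase bin, s."""
        return (np.arange(self.n_phases) + 0.5) * self.dt


@dataclass(frozen=True)
class StrokeVolume:
    """Displaced CSF volume per cardiac cycle, in microliters.

    ``value`` is the mean of the positive-lobe and (magnitude of the)
    negative-lobe volumes; ``net`` their signed difference, near zero for a
    balanced oscillatory flow.
    """

    value_ul: float
    v_pos_ul: float
    v_neg_ul: float

    @property
    def net_ul(self) -> float:
        return self.v_pos_ul - self.v_neg_ul


def _check_phase_range(phase: np.ndarray) -> None:
    # Tiny headroom for float round-off when a generator writes exactly +/-pi.
    if np.any(np.abs(phase) > np.pi * (1 + 1e-12)):
        raise ValidationError(
            "phase values outside [-pi, pi]; aliased data is rejected (no unwrapping)"
        )


def phase_to_velocity(phase: np.ndarray, venc: float) -> np.ndarray:
    """Decode image phase (rad) to velocity (cm/s): v = venc * phi / pi."""
    phase = np.asarray(phase, dtype=float)
    if venc <= 0:
        raise ValidationError(f"venc must be positive, got {venc}")
    _check_phase_range(phase)
    return venc * phase / np.pi


def roi_flow(
    series: FlowSeries,
    roi: np.ndarray,
    *,
    level: str = "aqueduct",
    background_roi: np.ndarray | None = None,
) -> FlowCurve:
    """Integrate ROI velocities into a per-phase flow-rate curve (mL/s).

    ``Q_i = sum_{p in roi} v_{p,i} * dx * dy / 100`` (cm/s times cm^2 gives
    cm^3/s = mL/s).  ``background_roi``, if given, enables static-tissue
    baseline subtraction: the mean background velocity of each phase is
    removed from every ROI pixel before integration (off by default).
    """
    roi = np.asarray(roi).astype(bool)
    if roi.shape != series.phases.shape[:2]:
        raise ValidationError(
            f"ROI shape {roi.shape} does not match phase images {series.phases.shape[:2]}"
        )
    if not roi.any():
        raise ValidationError("empty ROI")
    v = phase_to_velocity(series.phases, series.venc)
    if background_roi is not None:
        background_roi = np.asarray(background_roi).astype(bool)
        if background_roi.shape != roi.shape:
            raise ValidationError("background ROI shape mismatch")
        if not background_roi.any():
            raise ValidationError("empty background ROI")
        v = v - v[background_roi, :].mean(axis=0)[None, None, :]
    dx, dy = series.pixel_size
    pixel_area_cm2 = dx * dy / 100.0
    q = v[roi, :].sum(axis=0) * pixel_area_cm2
    return FlowCurve(q_ml_s=q, dt=series.dt, level=level)


def stroke_volume(curve: FlowCurve) -> StrokeVolume:
    """Stroke volume of a flow curve, in microliters per cardiac cycle.

    Midpoint-rule integration with uniform dt: the positive lobe is
    ``sum max(Q_i, 0) dt``, the negative lobe ``sum max(-Q_i, 0) dt``, and
    the stroke volume their mean (1 mL = 1000 ul).
    """
    q = curve.q_ml_s
    v_pos = float(np.sum(np.maximum(q, 0.0)) * curve.dt) * 1000.0
    v_neg = float(np.sum(np.maximum(-q, 0.0)) * curve.dt) * 1000.0
    return StrokeVolume(value_ul=(v_pos + v_neg) / 2.0, v_pos_ul=v_pos, v_neg_ul=v_neg)
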