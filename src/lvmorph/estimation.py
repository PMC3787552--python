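"""Area-to-volume estimation and method agreement.

The headline clinical result this package packages: lateral-ventricle volume
(LvV, mL) is proportional to the ventricle area (LvA, cm^2) on a single
well-positioned axial reference slice,

    LvV = 7 * LvA - 61        (published coefficients)

so a 1-minute single-slice measurement can replace 15-minute 3D volumetry in
follow-up.  ``AreaVolumeModel`` fits that line to paired data by ordinary
least squares (statsmodels under the hood) and returns an
``AreaVolumeResults`` carrying coefficients, confidence intervals, R^2,
Spearman's rho and a ``summary()`` table; ``PUBLISHED_MODEL`` holds the
printed coefficients verbatim.  ``bland_altman`` quantifies agreement between
two volume measurements with the standard bias +/- 1.96 SD limits.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ValidationError

__all__ = [
    "AreaVolumeModel",
    "AreaVolumeResults",
    "PUBLISHED_MODEL",
    "estimate_volume",
    "bland_altman",
    "AgreementResult",
]


@dataclass(frozen=True)
class AreaVolumeResults:
    """A (possibly fitted) linear area-to-volume model.

    ``provenance`` is ``"published"`` for the printed coefficients and
    ``"fitted"`` for OLS results; fit diagnostics are ``None`` on the
    published model.
    """

    slope: float  # mL per cm^2
    intercept: float  # mL
    provenance: str = "fitted"
    rsquared: float | None = None
    resid_sd: float | None = None
    spearman_rho: float | None = None
    spearman_p: float | None = None
    slope_ci: tuple[float, float] | None = None
    intercept_ci: tuple[float, float] | None = None
    nobs: int | None = None

    def __post_init__(self) -> None:
        if not np.isfinite(self.slope) or not np.isfinite(self.intercept):
            raise ValidationError("slope and intercept must be finite")

    def predict(self, lva_cm2):
        """Estimated volume (mL) for area(s) in cm^2; may extrapolate below 0."""
        return estimate_volume(self, lva_cm2)

    def conf_int(self) -> pd.DataFrame:
        """95% confidence intervals for intercept and slope (fitted models only)."""
        if self.slope_ci is None or self.intercept_ci is None:
            raise ValidationError("confidence intervals are only available on fitted models")
        return pd.DataFrame(
            [self.intercept_ci, self.slope_ci],
            index=["intercept", "slope"],
            columns=["lower", "upper"],
        )

    def summary(self) -> str:
        lines = [
            "Area-to-volume linear model",
            "===========================",
            f"provenance : {self.provenance}",
            f"LvV (mL)   = {self.slope:g} * LvA (cm^2) + {self.intercept:g}",
        ]
        if self.nobs is not None:
            lines.append(f"n          : {self.nobs}")
        if self.rsquared is not None:
            lines.append(f"R^2 (OLS)  : {self.rsquared:.4f}")
        if self.spearman_rho is not None:
            lines.append(f"Spearman r : {self.spearman_rho:.4f} (p = {self.spearman_p:.3g})")
        if self.resid_sd is not None:
            lines.append(f"resid SD   : {self.resid_sd:.3f} mL")
        if self.slope_ci is not None:
            lines.append(f"slope 95% CI     : [{self.slope_ci[0]:.3f}, {self.slope_ci[1]:.3f}]")
            lines.append(
                f"intercept 95% CI : [{self.intercept_ci[0]:.3f}, {self.intercept_ci[1]:.3f}]"
            )
        return "\n".join(lines)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps(
            {"slope": self.slope, "intercept": self.intercept, "provenance": self.provenance},
            indent=2,
        )
        if path is not None:
            Path(path).write_text(payload + "\n")
        return payload

    @classmethod
    def from_json(cls, path: str | Path) -> "AreaVolumeResults":
        d = json.loads(Path(path).read_text())
        return cls(slope=d["slope"], intercept=d["intercept"], provenance=d.get("provenance", "fitted"))


#: The coefficients as printed: 7 mL/cm^2 slope, -61 mL intercept.  Never
#: overwritten by fitted models.
PUBLISHED_MODEL = AreaVolumeResults(slope=7.0, intercept=-61.0, provenance="published")


class AreaVolumeModel:
    """OLS regression of volume (mL) on single-slice area (cm^2).

    Parameters
    ----------
    lva_cm2, lvv_ml : array-like
        Paired area and volume measurements, one row per subject.

    Examples
    --------
    >>> res = AreaVolumeModel([10, 20, 30], [9, 79, 149]).fit()
    >>> round(res.slope, 6), round(res.intercept, 6)
    (7.0, -61.0)
    """

    def __init__(self, lva_cm2, lvv_ml):
        lva = np.asarray(lva_cm2, dtype=float)
        lvv = np.asarray(lvv_ml, dtype=float)
        if lva.ndim != 1 or lva.shape != lvv.shape:
            raise ValidationError("lva and lvv must be 1D arrays of equal length")
        if lva.size < 3:
            raise ValidationError(f"need >= 3 pairs to fit, got {lva.size}")
        if not (np.all(np.isfinite(lva)) and np.all(np.isfinite(lvv))):
            raise ValidationError("non-finite values in the fit data")
        if np.ptp(lva) == 0:
            raise ValidationError("constant LvA: the fit is singular")
        self.lva = lva
        self.lvv = lvv

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, area_col: str = "lva_cm2", volume_col: str = "lvv_ml"
    ) -> "AreaVolumeModel":
        return cls(df[area_col].to_numpy(), df[volume_col].to_numpy())

    def fit(self) -> AreaVolumeResults:
        import statsmodels.api as sm
        from scipy import stats

        exog = sm.add_constant(self.lva)
        res = sm.OLS(self.lvv, exog).fit()
        ci = res.conf_int(alpha=0.05)
        rho, p = stats.spearmanr(self.lva, self.lvv)
        resid_sd = float(np.sqrt(res.ssr / res.df_resid)) if res.df_resid > 0 else 0.0
        return AreaVolumeResults(
            slope=float(res.params[1]),
            intercept=float(res.params[0]),
            provenance="fitted",
            rsquared=float(res.rsquared),
            resid_sd=resid_sd,
            spearman_rho=float(rho),
            spearman_p=float(p),
            slope_ci=(float(ci[1, 0]), float(ci[1, 1])),
            intercept_ci=(float(ci[0, 0]), float(ci[0, 1])),
            nobs=int(res.nobs),
        )


def estimate_volume(model: AreaVolumeResults, lva_cm2):
    """Evaluate ``slope * LvA + intercept`` (mL).

    Areas below the line's root give negative volumes; these are returned
    as-is with a warning since they flag model extrapolation, not data.
    """
    lva = np.asarray(lva_cm2, dtype=float)
    if np.any(lva < 0):
        raise ValidationError("areas must be nonnegative")
    est = model.slope * lva + model.intercept
    if np.any(est < -1e-9):  # float dust at the root is not extrapolation
        warnings.warn(
            "estimated volume is negative: area below the model's root "
            f"({-model.intercept / model.slope:.2f} cm^2); extrapolation",
            stacklevel=2,
        )
    return float(est) if est.ndim == 0 else est


@dataclass(frozen=True)
class AgreementResult:
    """Bland–Altman agreement between two paired measurements (a - b)."""

    bias: float
    sd: float
    loa_lower: float
    loa_upper: float
    fraction_within: float
    n: int

    def summary(self) -> str:
        return "\n".join(
            [
                "Bland-Altman agreement",
                "======================",
                f"n               : {self.n}",
                f"bias (a - b)    : {self.bias:.3f} mL",
                f"SD of diffs     : {self.sd:.3f} mL",
                f"limits          : [{self.loa_lower:.3f}, {self.loa_upper:.3f}] mL",
                f"within limits   : {100 * self.fraction_within:.1f}%",
            ]
        )

    def plot(self, a=None, b=None, ax=None):
        """Bland–Altman plot: per-pair differences against means, with the
        bias and limit-of-agreement lines.  Requires the original pairs."""
        import matplotlib.pyplot as plt

        if a is None or b is None:
            raise ValidationError("plot() needs the original paired values")
        a = np.asarray(a, dtype=float)
        b = np.asarray(b, dtype=float)
        if ax is None:
            _, ax = plt.subplots()
        ax.scatter((a + b) / 2, a - b, s=14, alpha=0.7)
        for y, style in ((self.bias, "-"), (self.loa_lower, "--"), (self.loa_upper, "--")):
            ax.axhline(y, color="k", linestyle=style, linewidth=1)
        ax.set_xlabel("mean of methods (mL)")
        ax.set_ylabel("difference a - b (mL)")
        ax.set_title("Bland-Altman agreement")
        return ax


def bland_altman(a, b) -> AgreementResult:
    """Bland–Altman analysis of two paired measurement vectors.

    Differences are ``a - b``; the bias is their mean and the limits of
    agreement ``bias +/- 1.96 * SD`` with the sample (n-1) SD — the standard
    normal-quantile convention, under which about 95% of differences fall
    inside the limits.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.ndim != 1 or a.shape != b.shape:
        raise ValidationError("paired vectors must be 1D and of equal length")
    if a.size < 2:
        raise ValidationError(f"need >= 2 pairs, got {a.size}")
    d = a - b
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    lower, upper = bias - 1.96 * sd, bias + 1.96 * sd
    within = float(np.mean((d >= lower) & (d <= upper)))
    return AgreementResult(
        bias=bias, sd=sd, loa_lower=lower, loa_upper=upper, fraction_within=within, n=a.size
    )
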