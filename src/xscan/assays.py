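"""Assay arithmetic: HTRF specificity ratios, dose-response fits, lysis.

Three small, exactly specified computations used throughout binder triage:

* HTRF specificity — the ratio of the binding signal on the target
  HLA/peptide complex to the worst (largest) negative-control signal; a
  clone is a hit when the ratio reaches a fold threshold (25-fold in the
  primary screen; a stringent 50-fold preset is also provided).
* A three-parameter log(agonist) vs. response model (bottom, top, EC50;
  Hill slope fixed at 1) with the closed-form EC_F derivation
  ``EC_F = EC50 * F / (100 - F)``, so EC90 = 9 x EC50.
* Chromium-release cytotoxicity, ``% specific lysis =
  (experimental - spontaneous) / (maximum - spontaneous) * 100``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

#: Fold threshold of the primary HTRF screen ("at least 25-fold").
HTRF_FOLD_SCREEN: float = 25.0
#: Stringent fold threshold used for final binder selection (">50-fold").
HTRF_FOLD_STRINGENT: float = 50.0


@dataclass(frozen=True)
class HtrfRecord:
    """HTRF signals for one clone: target complex vs negative controls."""

    clone_id: str
    signal_target: float
    signals_negative: tuple[float, ...]

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "signals_negative", tuple(float(s) for s in self.signals_negative)
        )
        if not self.signals_negative:
            raise ValueError(f"{self.clone_id}: at least one negative control required")
        if self.signal_target < 0 or any(s < 0 for s in self.signals_negative):
            raise ValueError(f"{self.clone_id}: signals must be >= 0")


@dataclass(frozen=True)
class HtrfResult:
    clone_id: str
    ratio: float
    hit: bool
    fold_threshold: float


def htrf_specificity(
    record: HtrfRecord,
    fold_threshold: float = HTRF_FOLD_SCREEN,
    floor_epsilon: float | None = None,
) -> HtrfResult:
    """Specificity ratio against the worst negative control; inclusive hit call.

    The ratio divides the target signal by the *maximum* negative-control
    signal — the conservative reading of specificity against several
    controls.  Zero negative signals are floored at ``floor_epsilon``
    (default: smallest positive observed signal x 1e-3) so the ratio stays
    defined; a clone is a hit when ``ratio >= fold_threshold``.
    """
    negatives = np.asarray(record.signals_negative, dtype=float)
    if floor_epsilon is None:
        positive = [s for s in (record.signal_target, *negatives) if s > 0]
        floor_epsilon = (min(positive) * 1e-3) if positive else 1e-12
    negatives = np.maximum(negatives, floor_epsilon)
    ratio = float(record.signal_target / negatives.max())
    return HtrfResult(
        clone_id=record.clone_id,
        ratio=ratio,
        hit=ratio >= fold_threshold,
        fold_threshold=fold_threshold,
    )


def three_parameter_logistic(
    dose: np.ndarray | float, bottom: float, top: float, ec50: float
) -> np.ndarray | float:
    """Response at ``dose`` under the unit-slope 3-parameter logistic model.

    ``response = bottom + (top - bottom) / (1 + 10**(log10(EC50) - log10(dose)))``,
    which simplifies to ``bottom + (top - bottom) / (1 + ec50/dose)``.
    """
    dose = np.asarray(dose, dtype=float)
    return bottom + (top - bottom) / (1.0 + ec50 / dose)


def effective_concentration(ec50: float, f: float) -> float:
    """Concentration producing F% of the span between bottom and top.

    Closed form for the unit-slope model: ``EC_F = EC50 * F / (100 - F)``;
    F = 50 returns EC50 itself, F = 90 returns 9 x EC50.
    """
    if not 0 < f < 100:
        raise ValueError("F must lie strictly between 0 and 100")
    if ec50 <= 0:
        raise ValueError("EC50 must be positive")
    return ec50 * f / (100.0 - f)


class DoseResponseModel:
    """Three-parameter log(agonist) vs. response model.

    Parameters are bottom and top plateaus (response units) and EC50
    (concentration, same units as ``doses``); the Hill slope is fixed at 1 —
    that is what makes the model three-parameter rather than four.

    Fitting is deterministic: starting values are bottom = min(response),
    top = max(response), EC50 = the dose whose response is nearest the
    half-maximum, and the optimizer works in log10(EC50) space with EC50
    bounded three decades beyond the measured dose range.
    """

    def __init__(self, doses: Sequence[float], responses: Sequence[float]):
        doses = np.asarray(doses, dtype=float)
        responses = np.asarray(responses, dtype=float)
        if doses.shape != responses.shape or doses.ndim != 1:
            raise ValueError("doses and responses must be equal-length 1-D arrays")
        if np.any(doses <= 0):
            raise ValueError("doses must be strictly positive (log-agonist model)")
        if not (np.all(np.isfinite(doses)) and np.all(np.isfinite(responses))):
            raise ValueError("doses and responses must be finite")
        if len(np.unique(doses)) < 4:
            raise ValueError("at least 4 distinct dose levels are required")
        if np.ptp(responses) == 0:
            raise ValueError("responses are constant; dose-response fit is degenerate")
        self.doses = doses
        self.responses = responses

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, dose_col: str = "dose_molar", response_col: str = "response"
    ) -> "DoseResponseModel":
        return cls(df[dose_col].to_numpy(), df[response_col].to_numpy())

    def _initial_params(self) -> tuple[float, float, float]:
        bottom = float(self.responses.min())
        top = float(self.responses.max())
        half = 0.5 * (bottom + top)
        ec50 = float(self.doses[np.argmin(np.abs(self.responses - half))])
        return bottom, top, ec50

    def fit(self) -> "DoseResponseResults":
        b0, t0, e0 = self._initial_params()
        span = max(t0 - b0, 1.0)
        log_lo = np.log10(self.doses.min()) - 3.0
        log_hi = np.log10(self.doses.max()) + 3.0

        def model(dose, bottom, top, log_ec50):
            return three_parameter_logistic(dose, bottom, top, 10.0 ** log_ec50)

        p0 = (b0, t0, float(np.clip(np.log10(e0), log_lo, log_hi)))
        bounds = (
            [b0 - 10 * span, b0 - 10 * span, log_lo],
            [t0 + 10 * span, t0 + 10 * span, log_hi],
        )
        popt, pcov = curve_fit(
            model, self.doses, self.responses, p0=p0, bounds=bounds, maxfev=20000
        )
        bottom, top, log_ec50 = popt
        if top < bottom:  # canonicalize: report top >= bottom
            bottom, top = top, bottom
        fitted = model(self.doses, bottom, top, log_ec50)
        residuals = self.responses - fitted
        return DoseResponseResults(
            model=self,
            bottom=float(bottom),
            top=float(top),
            ec50=float(10.0 ** log_ec50),
            cov=pcov,
            residuals=residuals,
        )


@dataclass
class DoseResponseResults:
    """Fitted 3PL parameters with residual diagnostics."""

    model: DoseResponseModel
    bottom: float
    top: float
    ec50: float
    cov: np.ndarray
    residuals: np.ndarray

    @property
    def ec90(self) -> float:
        return self.effective_concentration(90.0)

    @property
    def rss(self) -> float:
        return float(np.sum(self.residuals**2))

    @property
    def bse(self) -> dict[str, float]:
        """Approximate standard errors (bottom, top, log10_ec50)."""
        se = np.sqrt(np.clip(np.diag(self.cov), 0, np.inf))
        return {"bottom": se[0], "top": se[1], "log10_ec50": se[2]}

    def predict(self, doses: Sequence[float]) -> np.ndarray:
        return three_parameter_logistic(
            np.asarray(doses, dtype=float), self.bottom, self.top, self.ec50
        )

    def effective_concentration(self, f: float) -> float:
        """EC_F for this fit; EC90 = 9 x EC50 under the unit-slope model."""
        return effective_concentration(self.ec50, f)

    def summary(self) -> str:
        se = self.bse
        lines = [
            "Three-parameter log(agonist) vs. response fit (Hill slope = 1)",
            f"  n observations : {len(self.model.doses)}",
            f"  bottom         : {self.bottom:.4g}  (se {se['bottom']:.2g})",
            f"  top            : {self.top:.4g}  (se {se['top']:.2g})",
            f"  EC50           : {self.ec50:.4g}  (se(log10) {se['log10_ec50']:.2g})",
            f"  EC90 (9xEC50)  : {self.ec90:.4g}",
            f"  residual SS    : {self.rss:.4g}",
        ]
        return "\n".join(lines)


def fit_dose_response(
    doses: Sequence[float], responses: Sequence[float]
) -> DoseResponseResults:
    """Convenience wrapper: build a :class:`DoseResponseModel` and fit it."""
    return DoseResponseModel(doses, responses).fit()


@dataclass(frozen=True)
class LysisMeasurement:
    """Chromium-release counts for one well (counts per minute)."""

    experimental: float
    spontaneous: float
    maximum: float

    def __post_init__(self) -> None:
        if self.spontaneous < 0:
            raise ValueError("spontaneous release must be >= 0")
        if self.maximum <= self.spontaneous:
            raise ValueError("maximum release must exceed spontaneous release")


def specific_lysis(m: LysisMeasurement) -> float:
    """Percent specific lysis from chromium-release counts.

    ``(experimental - spontaneous) / (maximum - spontaneous) * 100``.
    The result may fall below 0 or exceed 100 (counter noise); it is
    reported as-is rather than clipped.
    """
    return (m.experimental - m.spontaneous) / (m.maximum - m.spontaneous) * 100.0
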