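"""Worked-example arithmetic of the initiation and exchange assays.

Three small calculation families:

* the labeled-pool / subunit-exchange mixture model — given the coincidence
  measured for a fully double-labeled positive control, the coincidence
  measured in an exchange experiment, and the fold excess of labeled large
  subunits over unlabeled monosomes, infer what fraction of initiation
  events exchanged the large subunit and what fraction occurred on intact
  monosomes;
* fluorescence-intensity calibration (OLS line) and its inversion for mRNA
  concentration, plus the fraction-bound quantification of binding assays;
* filter-binding background subtraction and the dipeptide
  elongation-competence ratio of P-site vs A-site tRNA occupancies.

All internal values are unrounded; display helpers reproduce the rounding
conventions used when reporting (nearest integer percent for coincidence,
nearest ten percent for competence).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import InvalidConfigError, InvalidInputError, UndefinedResultError

__all__ = [
    "ExchangeInputs",
    "ExchangeResult",
    "CalibrationCurve",
    "BindingQuant",
    "labeled_pool_fraction",
    "predicted_full_exchange",
    "exchange_split",
    "exchange_model",
    "fit_calibration",
    "intensity_to_concentration",
    "fraction_bound",
    "subtract_background",
    "elongation_competence",
    "normalize_gradient_profile",
    "round_percent",
    "round_to_nearest_ten",
]


@dataclass(frozen=True)
class ExchangeInputs:
    """Inputs of the exchange mixture model, all as printed percentages."""

    f_positive: float   # positive-control coincidence, percent
    f_observed: float   # exchange-experiment coincidence, percent
    excess_fold: float  # labeled-LSU excess over unlabeled monosomes

    def __post_init__(self) -> None:
        for name in ("f_positive", "f_observed"):
            v = getattr(self, name)
            if not 0.0 <= v <= 100.0:
                raise InvalidConfigError(f"{name} must be in [0, 100], got {v}")
        if not self.excess_fold > 0:
            raise InvalidConfigError(
                f"excess_fold must be > 0, got {self.excess_fold}")
        if self.f_observed > self.f_positive:
            warnings.warn(
                "observed coincidence exceeds the positive control; "
                "check inputs", stacklevel=3)


@dataclass(frozen=True)
class ExchangeResult:
    """Outputs of the exchange mixture model.

    ``exchanged_fraction + monosome_fraction == 1`` exactly;
    ``f_predicted_full == f_positive * labeled_pool_fraction``.
    """

    labeled_pool_fraction: float
    f_predicted_full: float   # percent
    exchanged_fraction: float
    monosome_fraction: float
    clamped: bool = False

    def to_dict(self) -> dict:
        return {
            "labeled_pool_fraction": self.labeled_pool_fraction,
            "f_predicted_full": self.f_predicted_full,
            "f_predicted_full_display": round_percent(self.f_predicted_full),
            "exchanged_fraction": self.exchanged_fraction,
            "monosome_fraction": self.monosome_fraction,
            "clamped": self.clamped,
        }


def labeled_pool_fraction(excess_fold: float) -> float:
    """Fraction of the large-subunit pool that is labeled, given an
    ``excess_fold``-fold excess of labeled subunits over the (unlabeled)
    monosome-derived pool: excess / (excess + 1). A 5-fold excess gives
    5/6."""
    if not excess_fold > 0:
        raise InvalidConfigError(f"excess_fold must be > 0, got {excess_fold}")
    return excess_fold / (excess_fold + 1.0)


def predicted_full_exchange(f_positive: float, pool: float) -> float:
    """Coincidence (percent) predicted if every initiation event exchanged
    its large subunit with the labeled pool: f_positive * pool."""
    if not 0.0 <= f_positive <= 100.0:
        raise InvalidConfigError("f_positive must be in [0, 100]")
    if not 0.0 <= pool <= 1.0:
        raise InvalidConfigError("pool must be in [0, 1]")
    return f_positive * pool


def exchange_split(f_observed: float, f_predicted_full: float
                   ) -> tuple[float, float, bool]:
    """Split observed coincidence into exchanged vs intact-monosome events.

    Returns ``(exchanged_fraction, monosome_fraction, clamped)`` where
    ``exchanged = f_observed / f_predicted_full`` (clamped to [0, 1] with
    a warning, since printed +/- uncertainties can push it outside) and
    ``monosome = 1 - exchanged``.
    """
    if f_predicted_full == 0:
        raise UndefinedResultError(
            "exchange split undefined for zero predicted coincidence")
    exchanged = f_observed / f_predicted_full
    clamped = False
    if not 0.0 <= exchanged <= 1.0:
        warnings.warn(
            f"exchanged fraction {exchanged:.3f} outside [0, 1]; clamped",
            stacklevel=2)
        exchanged = min(max(exchanged, 0.0), 1.0)
        clamped = True
    return exchanged, 1.0 - exchanged, clamped


def exchange_model(inputs: ExchangeInputs) -> ExchangeResult:
    """Full mixture model: pool fraction, predicted full-exchange
    coincidence, and the exchanged/monosome split."""
    pool = labeled_pool_fraction(inputs.excess_fold)
    predicted = predicted_full_exchange(inputs.f_positive, pool)
    exchanged, monosome, clamped = exchange_split(inputs.f_observed, predicted)
    return ExchangeResult(pool, predicted, exchanged, monosome, clamped)


@dataclass(frozen=True)
class CalibrationCurve:
    """Linear fluorescence-intensity-to-concentration mapping,
    intensity = slope * concentration + intercept."""

    slope: float       # intensity units per nM
    intercept: float   # intensity units
    r_squared: float
    n_points: int

    def to_dict(self) -> dict:
        return {"slope": self.slope, "intercept": self.intercept,
                "r_squared": self.r_squared, "n_points": self.n_points}


def fit_calibration(known_concentrations, intensities) -> CalibrationCurve:
    """OLS line through (concentration, intensity) standards.

    Fitted with an intercept: buffer background contributes a
    concentration-independent offset.
    """
    conc = np.asarray(known_concentrations, dtype=float)
    inten = np.asarray(intensities, dtype=float)
    if conc.shape != inten.shape or conc.ndim != 1:
        raise InvalidInputError("concentrations and intensities must be "
                                "1-D sequences of equal length")
    if len(conc) < 3:
        raise InvalidInputError(f"need >= 3 calibration points, got {len(conc)}")
    if np.ptp(conc) == 0:
        raise InvalidInputError("calibration concentrations have zero variance")
    fit = stats.linregress(conc, inten)
    return CalibrationCurve(slope=float(fit.slope),
                            intercept=float(fit.intercept),
                            r_squared=float(fit.rvalue) ** 2,
                            n_points=len(conc))


def intensity_to_concentration(curve: CalibrationCurve,
                               intensity: float) -> float:
    """Invert the calibration line; negative concentrations are clamped to
    zero with a warning."""
    if curve.slope <= 0:
        raise InvalidConfigError(
            f"calibration slope must be > 0, got {curve.slope}")
    conc = (intensity - curve.intercept) / curve.slope
    if conc < 0:
        warnings.warn(
            f"intensity {intensity} below the calibration intercept; "
            "concentration clamped to 0", stacklevel=2)
        conc = 0.0
    return conc


@dataclass(frozen=True)
class BindingQuant:
    """Fraction of ribosomes carrying an mRNA, from molar concentrations."""

    mrna_concentration: float      # nM
    ribosome_concentration: float  # nM
    fraction_bound: float

    @classmethod
    def from_concentrations(cls, mrna_nm: float, ribosome_nm: float
                            ) -> "BindingQuant":
        return cls(mrna_nm, ribosome_nm, fraction_bound(mrna_nm, ribosome_nm))


def fraction_bound(mrna_nm: float, ribosome_nm: float) -> float:
    """min(1, [mRNA] / [ribosome]); one mRNA per initiation complex."""
    if ribosome_nm <= 0:
        raise UndefinedResultError("ribosome concentration must be > 0")
    if mrna_nm < 0:
        raise InvalidInputError("mRNA concentration must be >= 0")
    return min(1.0, mrna_nm / ribosome_nm)


def subtract_background(signal: float, background: float
                        ) -> tuple[float, bool]:
    """max(0, signal - background); the flag reports whether the floor at
    zero was applied."""
    corrected = signal - background
    if corrected < 0:
        return 0.0, True
    return corrected, False


def elongation_competence(p_site_occupancy: float,
                          a_site_occupancy: float) -> float:
    """Fraction of initiation complexes competent for dipeptide-bond
    formation: A-site (Phe-tRNA) occupancy over P-site (fMet-tRNA)
    occupancy, both in percent of ribosomes."""
    if p_site_occupancy <= 0:
        raise UndefinedResultError("P-site occupancy must be > 0")
    if a_site_occupancy < 0:
        raise InvalidInputError("A-site occupancy must be >= 0")
    return a_site_occupancy / p_site_occupancy


def normalize_gradient_profile(values_per_fraction) -> np.ndarray:
    """Normalize a sucrose-gradient profile to its first collected
    fraction; the first output element is exactly 1."""
    values = np.asarray(values_per_fraction, dtype=float)
    if values.ndim != 1 or len(values) == 0:
        raise InvalidInputError("profile must be a non-empty 1-D sequence")
    if values[0] == 0:
        raise UndefinedResultError(
            "cannot normalize: first fraction value is zero")
    return values / values[0]


def round_percent(value: float) -> int:
    """Nearest integer percent, as printed for coincidence values."""
    return int(math.floor(value + 0.5))


def round_to_nearest_ten(value: float) -> int:
    """Nearest ten percent, as printed for the competence estimate."""
    return int(10 * math.floor(value / 10.0 + 0.5))
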