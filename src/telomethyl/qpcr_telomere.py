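"""Relative telomere length (T/S ratio) from multiplex qPCR Cq data.

The assay amplifies the telomeric repeat (target ``TEL``) and a single-copy
gene, beta-globin (target ``SCG``), on one plate.  Serial dilutions of a
reference DNA give one standard curve per target (Cq regressed on log10
input mass); unknowns are quantified off the curves, the per-replicate T/S
ratio is the TEL quantity over the SCG quantity, sample values are the mean
of duplicates, and everything is normalised so a designated reference sample
has T/S = 1.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

TARGETS = ("TEL", "SCG")

#: Plate CSV schema shared with the synthetic generator.
PLATE_COLUMNS = ["well", "sample_id", "target", "role", "input_ng", "replicate", "Cq"]


class CurveFitError(ValueError):
    """Standard curve cannot be fit (too few dilutions or non-negative slope)."""


@dataclass(frozen=True)
class StandardCurve:
    """OLS fit of Cq on log10(input ng) for one target.

    ``efficiency`` is the per-cycle amplification gain, ``10**(-1/slope) - 1``;
    perfect doubling per cycle gives slope = -1/log10(2) = -3.3219 and
    efficiency exactly 1.0.
    """

    slope: float  # cycles per log10(ng); always < 0
    intercept: float  # cycles at 1 ng
    r_squared: float
    efficiency: float
    n_points: int  # distinct dilution points

    def quantity(self, cq) -> np.ndarray | float:
        return 10.0 ** ((np.asarray(cq, dtype=float) - self.intercept) / self.slope)


@dataclass(frozen=True)
class TelomereMeasurement:
    sample_id: str
    ts_ratio: float  # reference-normalised mean of replicate ratios
    replicate_ts: tuple
    cv: float  # SD(n-1)/mean over replicate ratios; NaN for single replicate


def fit_standard_curve(wells: pd.DataFrame, r2_warn: float = 0.99) -> StandardCurve:
    """Fit a standard curve from the standard wells of one target.

    ``wells`` needs columns ``input_ng`` and ``Cq``; replicate wells enter
    the regression individually (five dilutions in triplicate = 15 points).
    """
    mass = wells["input_ng"].to_numpy(dtype=float)
    cq = wells["Cq"].to_numpy(dtype=float)
    if not np.all(np.isfinite(cq)):
        raise CurveFitError("standard wells contain non-finite Cq")
    if (mass <= 0).any():
        raise CurveFitError("standard input masses must be positive")
    n_points = len(np.unique(mass))
    if n_points < 2:
        raise CurveFitError(f"need >=2 distinct dilution points, got {n_points}")
    x = np.log10(mass)
    fit = stats.linregress(x, cq)
    if fit.slope >= 0:
        raise CurveFitError(
            f"fitted slope {fit.slope:.4g} is non-negative; curve failed"
        )
    r2 = float(fit.rvalue**2)
    if r2 < r2_warn:
        warnings.warn(f"standard curve r^2 = {r2:.4f} < {r2_warn}", stacklevel=2)
    return StandardCurve(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=r2,
        efficiency=float(10.0 ** (-1.0 / fit.slope) - 1.0),
        n_points=n_points,
    )


def quantify_well(cq: float, curve: StandardCurve) -> float:
    """Invert the standard curve: quantity = 10**((cq - intercept)/slope)."""
    return float(curve.quantity(cq))


def _validate_ntc(plate: pd.DataFrame) -> None:
    ntc = plate[plate["role"] == "ntc"]
    amplifying = ntc["Cq"].notna() & np.isfinite(ntc["Cq"].astype(float))
    if amplifying.any():
        warnings.warn(
            f"{int(amplifying.sum())} NTC wells show amplification", stacklevel=3
        )


def fit_plate_curves(plate: pd.DataFrame) -> dict[str, StandardCurve]:
    standards = plate[plate["role"] == "standard"]
    curves = {}
    for target in TARGETS:
        sub = standards[standards["target"] == target]
        if sub.empty:
            raise CurveFitError(f"no standard wells for target {target}")
        curves[target] = fit_standard_curve(sub)
    return curves


def compute_ts_ratios(
    plate: pd.DataFrame, reference_sample_id: str
) -> list[TelomereMeasurement]:
    """Per-sample T/S ratios from a plate, normalised to the reference sample.

    For each unknown sample, every replicate with a Cq on both targets yields
    one raw ratio (TEL quantity / SCG quantity); the sample value is the mean
    over replicates divided by the reference sample's mean, so the reference
    reports exactly 1.  Samples missing a target entirely are flagged and
    excluded.  The reference sample must be present as unknown wells on both
    targets.
    """
    _validate_ntc(plate)
    curves = fit_plate_curves(plate)

    unknowns = plate[plate["role"] == "unknown"].copy()
    unknowns["quantity"] = np.where(
        unknowns["target"] == "TEL",
        curves["TEL"].quantity(unknowns["Cq"]),
        curves["SCG"].quantity(unknowns["Cq"]),
    )
    wide = unknowns.pivot_table(
        index=["sample_id", "replicate"], columns="target", values="quantity"
    )

    raw: dict[str, np.ndarray] = {}
    for sample_id, sub in wide.groupby(level="sample_id"):
        sub = sub.dropna(subset=[t for t in TARGETS if t in sub.columns], how="any")
        if not {"TEL", "SCG"} <= set(wide.columns) or sub.empty:
            logger.warning("sample %s missing a target; excluded", sample_id)
            continue
        raw[str(sample_id)] = (sub["TEL"] / sub["SCG"]).to_numpy()

    if reference_sample_id not in raw:
        raise ValueError(
            f"reference sample {reference_sample_id!r} absent from unknown wells"
        )
    ref_mean = float(np.mean(raw[reference_sample_id]))

    measurements = []
    for sample_id, ratios in raw.items():
        norm = ratios / ref_mean
        mean = float(np.mean(norm))
        cv = float(np.std(norm, ddof=1) / mean) if len(norm) >= 2 else float("nan")
        measurements.append(
            TelomereMeasurement(
                sample_id=sample_id,
                ts_ratio=mean,
                replicate_ts=tuple(float(v) for v in norm),
                cv=cv,
            )
        )
    return measurements


def plate_cv_summary(measurements: list[TelomereMeasurement]) -> float:
    """Mean coefficient of variation over samples with >=2 replicates."""
    cvs = [m.cv for m in measurements if len(m.replicate_ts) >= 2]
    n_single = len(measurements) - len(cvs)
    if n_single:
        warnings.warn(
            f"{n_single} single-replicate samples excluded from CV summary",
            stacklevel=2,
        )
    if not cvs:
        raise ValueError("no samples with >=2 replicates")
    return float(np.mean(cvs))


def measurements_to_frame(measurements: list[TelomereMeasurement]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sample_id": [m.sample_id for m in measurements],
            "ts_ratio": [m.ts_ratio for m in measurements],
            "cv": [m.cv for m in measurements],
        }
    ).set_index("sample_id")
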