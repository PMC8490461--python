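"""Resting-fluorescence budget and dF/F background correction.

In whole-heart voltage imaging the resting fluorescence F that enters
dF/F = (F_peak - F_rest)/F_rest is not produced by the voltage reporter
alone: tissue autofluorescence and the excitation-contraction uncoupler
blebbistatin contribute voltage-insensitive background.  Measured dF/F
therefore underestimates the reporter's true fractional response by the
factor (reporter + tissue + blebbistatin) / reporter.  All components are
expressed on one common absolute intensity scale.
"""
from __future__ import annotations

from dataclasses import dataclass

from .errors import FluorometryError


@dataclass(frozen=True)
class FluorescenceBudget:
    """Additive decomposition of resting fluorescence (common absolute scale)."""

    reporter: float
    tissue_autofluorescence: float
    blebbistatin: float

    def __post_init__(self) -> None:
        if min(self.reporter, self.tissue_autofluorescence, self.blebbistatin) < 0:
            raise FluorometryError("budget components must be non-negative")

    @property
    def total(self) -> float:
        return self.reporter + self.tissue_autofluorescence + self.blebbistatin

    @property
    def reporter_fraction(self) -> float:
        if self.total == 0:
            raise FluorometryError("empty budget")
        return self.reporter / self.total

    def normalized(self) -> "FluorescenceBudget":
        """Budget rescaled so the components are percentages of the total."""
        t = self.total
        if t == 0:
            raise FluorometryError("empty budget")
        return FluorescenceBudget(
            reporter=100.0 * self.reporter / t,
            tissue_autofluorescence=100.0 * self.tissue_autofluorescence / t,
            blebbistatin=100.0 * self.blebbistatin / t,
        )


def decompose_resting_fluorescence(
    total_resting: float,
    tissue_autofluorescence: float,
    blebbistatin: float,
) -> FluorescenceBudget:
    """Infer the reporter component by subtracting the wild-type background.

    The background (tissue + blebbistatin) is measured in reporter-free
    hearts and subtracted from the total resting fluorescence of a
    reporter-expressing heart on the same intensity scale.
    """
    reporter = total_resting - tissue_autofluorescence - blebbistatin
    if reporter < 0:
        raise FluorometryError(
            f"background ({tissue_autofluorescence + blebbistatin}) exceeds total resting "
            f"fluorescence ({total_resting}); negative inferred reporter component"
        )
    return FluorescenceBudget(
        reporter=reporter,
        tissue_autofluorescence=tissue_autofluorescence,
        blebbistatin=blebbistatin,
    )


def correction_factor(budget: FluorescenceBudget) -> float:
    """Underestimation factor (total / reporter) for measured dF/F."""
    if budget.reporter <= 0:
        raise FluorometryError("reporter component must be positive")
    return budget.total / budget.reporter


def correct_dff(measured_dff_percent: float, factor: float) -> float:
    """Background-corrected dF/F (%): measured value times the factor."""
    if factor < 1:
        raise FluorometryError("correction factor must be >= 1")
    return measured_dff_percent * factor
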