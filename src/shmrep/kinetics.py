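"""Plasma-cell decay kinetics and virus-neutralization titres.

Half-lives of transferred antibody-secreting cells are estimated by ordinary
least squares on ln(count / initial count) against time; the decay constant
lambda (the slope) gives t_half = ln 2 / |lambda|.  Two populations' decay
rates are compared with a t-test on the slope difference using each
regression's standard error.  Neutralization titres are read off serial-
dilution OD450 tables with the 50%-specific-signal rule: threshold =
(OD_virus_control - OD_cell_control)/2 + OD_cell_control, and the titre is
the highest dilution in the initial run of dilutions whose OD stays below
that threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass
class DecaySeries:
    """An ASC count time course (days, positive counts)."""

    timepoints: np.ndarray
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.timepoints = np.asarray(self.timepoints, dtype=float)
        self.counts = np.asarray(self.counts, dtype=float)
        if self.timepoints.shape != self.counts.shape:
            raise ValueError("timepoints and counts must have the same length")
        if self.timepoints.size and np.any(np.diff(self.timepoints) <= 0):
            raise ValueError("timepoints must be strictly increasing")
        if np.any(self.counts <= 0):
            raise ValueError("counts must be positive for log-linear regression")

    @property
    def ratio(self) -> np.ndarray:
        """Counts normalized to the first timepoint (ratio[0] = 1)."""
        return self.counts / self.counts[0]


@dataclass
class HalfLifeEstimate:
    slope: float  # per day, on ln(ratio)
    slope_se: float
    intercept: float
    r_squared: float
    n: int
    half_life_days: float  # ln2/|slope|; nan when slope >= 0
    defined: bool


def estimate_half_life(series: DecaySeries, through_origin: bool = False) -> HalfLifeEstimate:
    """OLS of ln(count/count_initial) on time; t_half = ln2 / |slope|.

    With ``through_origin`` the intercept is forced to 0 (exact ratio 1 at
    the first timepoint); by default the intercept is free, which tolerates
    measurement noise at t = 0.  A non-negative slope (no decay) yields an
    undefined half-life (``defined`` False, ``half_life_days`` NaN).
    """
    if series.timepoints.size < 3:
        raise ValueError("need at least 3 timepoints for a half-life estimate")
    t = series.timepoints
    y = np.log(series.ratio)
    if through_origin:
        tt = t - t[0]
        slope = float(np.sum(tt * y) / np.sum(tt * tt))
        resid = y - slope * tt
        dof = t.size - 1
        slope_se = float(np.sqrt(np.sum(resid**2) / dof / np.sum(tt * tt)))
        intercept = 0.0
        ss_tot = float(np.sum(y**2))
        r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 1.0
    else:
        fit = stats.linregress(t, y)
        slope, intercept, slope_se = float(fit.slope), float(fit.intercept), float(fit.stderr)
        r2 = float(fit.rvalue**2)
    defined = slope < 0
    half_life = np.log(2) / abs(slope) if defined else float("nan")
    return HalfLifeEstimate(
        slope=slope,
        slope_se=slope_se,
        intercept=intercept,
        r_squared=r2,
        n=int(t.size),
        half_life_days=float(half_life),
        defined=defined,
    )


def compare_decay_slopes(a: DecaySeries, b: DecaySeries) -> tuple[float, float]:
    """Two-sided t-test for equal decay slopes of two log-linear regressions.

    t = (slope_a - slope_b) / sqrt(se_a^2 + se_b^2) with n_a + n_b - 4
    degrees of freedom.  Returns (t statistic, p-value).
    """
    ea = estimate_half_life(a)
    eb = estimate_half_life(b)
    se = np.sqrt(ea.slope_se**2 + eb.slope_se**2)
    if not np.isfinite(se) or se == 0:
        if ea.slope == eb.slope:
            return 0.0, 1.0
        raise ValueError("degenerate slope variance; cannot compare")
    t_stat = (ea.slope - eb.slope) / se
    dof = ea.n + eb.n - 4
    p = 2.0 * stats.t.sf(abs(t_stat), dof)
    return float(t_stat), float(min(p, 1.0))


@dataclass
class NeutralizationInput:
    """Serial-dilution OD450 readings plus assay controls.

    ``dilutions`` are reciprocal dilution factors, strictly increasing
    (e.g. 10, 20, 40, ...); ``od450`` parallel readings; virus control is
    infection without serum, cell control is uninfected cells.
    """

    dilutions: np.ndarray
    od450: np.ndarray
    virus_control: float
    cell_control: float

    def __post_init__(self) -> None:
        self.dilutions = np.asarray(self.dilutions, dtype=float)
        self.od450 = np.asarray(self.od450, dtype=float)
        if self.dilutions.shape != self.od450.shape or self.dilutions.size == 0:
            raise ValueError("dilutions and od450 must be equal-length and non-empty")
        if np.any(np.diff(self.dilutions) <= 0):
            raise ValueError("dilution series must be strictly increasing")
        if np.any(self.od450 < 0) or self.virus_control < 0 or self.cell_control < 0:
            raise ValueError("OD readings must be non-negative")


def neutralization_titre(input: NeutralizationInput) -> tuple[float, bool]:
    """Reciprocal neutralization titre by the 50%-specific-signal rule.

    Threshold = (OD_virus - OD_cell)/2 + OD_cell.  Scanning from the lowest
    dilution, the titre is the last dilution of the initial run of ODs below
    the threshold (a neutralized well has low OD).  Returns
    ``(titre, below_first)``: when even the lowest dilution fails to
    neutralize, ``below_first`` is True and the titre is reported as the
    first dilution (interpret as "< first dilution").
    """
    if input.virus_control <= input.cell_control:
        raise ValueError("no assay window: virus control OD <= cell control OD")
    threshold = (input.virus_control - input.cell_control) / 2.0 + input.cell_control
    below = input.od450 < threshold
    if not below[0]:
        return float(input.dilutions[0]), True
    run_end = 0
    for i, ok in enumerate(below):
        if not ok:
            break
        run_end = i
    return float(input.dilutions[run_end]), False
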