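"""Companion quantifications: calibration linearity and the CAPS assay.

The calibration series mixes two plasmids (edited / unedited at a known
position) at defined ratios, sequences the mix, and compares measured
peak-ratio fractions to the expected mixing fractions — an ordinary
least-squares fit summarises sensitivity (slope) and reproducibility
(r²).

CAPS (cleaved amplified polymorphic sequence) converts editing at one
position into a restriction site; after digestion the cleaved fraction
of the amplicon, quantified from Bioanalyzer band molarities, reports
the editing extent.  Group comparisons use an unpaired two-tailed
t-test (Welch by default, pooled-variance optionally).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .trace_io import BandTable

__all__ = [
    "CalibrationSeries",
    "CapsResult",
    "AssayFailure",
    "fit_calibration",
    "caps_cleaved_fraction",
    "compare_caps_groups",
]


class AssayFailure(ValueError):
    """The assay's internal control did not behave as expected."""


@dataclass
class CalibrationSeries:
    """Known mixing fractions vs fractions measured by peak quantification."""

    expected: np.ndarray
    measured: np.ndarray
    site: int | None = None

    def __post_init__(self):
        self.expected = np.asarray(self.expected, dtype=float)
        self.measured = np.asarray(self.measured, dtype=float)
        if self.expected.shape != self.measured.shape:
            raise ValueError("expected and measured lengths differ")
        for name, arr in (("expected", self.expected), ("measured", self.measured)):
            if np.any((arr < 0) | (arr > 1)):
                raise ValueError(f"{name} fractions outside [0, 1]")

    def __len__(self) -> int:
        return len(self.expected)


@dataclass
class CapsResult:
    """Two-group cleaved-fraction comparison."""

    mean_a: float
    sd_a: float
    n_a: int
    mean_b: float
    sd_b: float
    n_b: int
    t_statistic: float
    p_value: float
    df: float
    test: str = "welch"


def fit_calibration(series: CalibrationSeries):
    """OLS of measured on expected fraction: ``(slope, intercept, r_squared)``.

    Requires >= 3 points over >= 2 distinct expected values.  A perfectly
    linear assay has slope 1, intercept 0; r² near 1 certifies
    reproducibility across the dilution series.
    """
    if len(series) < 3:
        raise ValueError("calibration needs at least 3 points")
    if len(np.unique(series.expected)) < 2:
        raise AssayFailure("degenerate design: all expected fractions identical")
    fit = stats.linregress(series.expected, series.measured)
    r_squared = float(fit.rvalue ** 2)
    if math.isnan(r_squared):  # zero variance in measured: perfectly flat
        r_squared = 0.0
    return float(fit.slope), float(fit.intercept), r_squared


def _match_band(bands, length: float, tolerance: float):
    """Quantity of the band closest to ``length`` within +/- tolerance (relative)."""
    best = None
    for band_len, qty in bands:
        if abs(band_len - length) <= tolerance * length:
            if best is None or abs(band_len - length) < abs(best[0] - length):
                best = (band_len, qty)
    return best


def caps_cleaved_fraction(lane: BandTable, uncleaved_length: float,
                          cleaved_lengths, tolerance: float = 0.10,
                          undigested_control: BandTable | None = None) -> float:
    """Cleaved fraction of one digested lane.

    Band lengths are matched to the expected uncleaved length and to the
    *larger* expected cleavage fragment (counting one fragment per cut
    molecule avoids double counting); matching tolerance is relative
    (default 10%).  Quantities are compared on a molar scale.  When an
    undigested control lane is supplied, it must contain the uncleaved
    band, else the assay itself failed.  Returns NaN when neither band
    is present in the digested lane.
    """
    if lane.treatment != "digested":
        raise ValueError("cleaved fraction is defined on a digested lane")
    if undigested_control is not None:
        if _match_band(undigested_control.molar_bands(),
                       uncleaved_length, tolerance) is None:
            raise AssayFailure(
                f"undigested control lane {undigested_control.lane_id!r} lacks "
                f"the expected {uncleaved_length:g} nt band")

    bands = lane.molar_bands()
    uncut = _match_band(bands, uncleaved_length, tolerance)
    marker_len = max(cleaved_lengths)
    cut = _match_band(bands, marker_len, tolerance)
    uncut_qty = uncut[1] if uncut else 0.0
    cut_qty = cut[1] if cut else 0.0
    total = uncut_qty + cut_qty
    if total <= 0:
        return math.nan
    return cut_qty / total


def compare_caps_groups(group_a, group_b, equal_var: bool = False) -> CapsResult:
    """Unpaired two-tailed t-test between two groups of cleaved fractions.

    Welch's unequal-variance form by default; ``equal_var=True`` switches
    to the pooled-variance Student form.  Zero pooled variance with a
    mean difference yields an infinite statistic with p = 0 (and t = 0,
    p = 1 when the means also coincide).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs n >= 2")

    if np.all(a == a[0]) and np.all(b == b[0]):
        if a.mean() == b.mean():
            t_stat, p_val, dof = 0.0, 1.0, float(len(a) + len(b) - 2)
        else:
            t_stat = math.inf if a.mean() > b.mean() else -math.inf
            p_val, dof = 0.0, float(len(a) + len(b) - 2)
    else:
        res = stats.ttest_ind(a, b, equal_var=equal_var)
        t_stat, p_val = float(res.statistic), float(res.pvalue)
        dof = float(res.df)

    return CapsResult(
        mean_a=float(a.mean()), sd_a=float(a.std(ddof=1)), n_a=len(a),
        mean_b=float(b.mean()), sd_b=float(b.std(ddof=1)), n_b=len(b),
        t_statistic=t_stat, p_value=p_val, df=dof,
        test="student" if equal_var else "welch",
    )
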