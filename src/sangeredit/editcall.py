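"""Per-site relative editing, background correction and significance calling.

At each candidate position the relative editing is the product-channel
peak area over the substrate-plus-product area: e = G/(A+G) for
adenosine deamination, e = T/(C+T) for cytidine deamination.  Control
replicates (e.g. a Luciferase infiltration) define a per-position
background mean that is subtracted from each sample replicate.  A site
is called significant when BOTH hold:

1. the background-corrected mean exceeds three times the sample standard
   deviation (n-1 denominator) of the corrected replicate values
   (strict inequality), and
2. the uncorrected mean is at least twice the control mean at that
   position (>=); when the control mean is numerically zero, any
   positive uncorrected mean satisfies this criterion.

No multiple-testing correction is applied; the 3-sigma rule is the
stated guard, and the per-run site count is reported so users can apply
an FDR externally.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .refmap import CandidateSites, PRODUCT_BASE, SUBSTRATE_BASE

__all__ = [
    "EditingTable",
    "SignificanceResult",
    "editing_ratio",
    "build_editing_table",
    "call_significant_sites",
    "summarize_run",
    "ZERO_CONTROL_EPS",
]

ZERO_CONTROL_EPS = 1e-9


@dataclass
class EditingTable:
    """Sites x replicates matrix of relative editing values.

    ``values`` has shape (n_sites, n_replicates); missing (not
    evaluable) cells are NaN, all others lie in [0, 1].
    """

    edit_mode: str
    positions: np.ndarray          # 1-based reference positions, sorted unique
    ref_bases: list
    values: np.ndarray
    replicate_ids: list
    group: str = "sample"          # "sample" | "control"

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=int)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.positions), len(self.replicate_ids)):
            raise ValueError("values shape does not match sites x replicates")
        if len(np.unique(self.positions)) != len(self.positions):
            raise ValueError("duplicate site positions")
        if np.any(np.diff(self.positions) <= 0):
            raise ValueError("site positions must be sorted")
        finite = self.values[np.isfinite(self.values)]
        if finite.size and (finite.min() < 0 or finite.max() > 1):
            raise ValueError("editing values must lie in [0, 1]")
        if self.group not in ("sample", "control"):
            raise ValueError(f"unknown group {self.group!r}")

    @property
    def n_sites(self) -> int:
        return len(self.positions)

    @property
    def n_replicates(self) -> int:
        return len(self.replicate_ids)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.replicate_ids)
        df.insert(0, "position", self.positions)
        df.insert(1, "ref_base", self.ref_bases)
        return df


@dataclass
class SignificanceResult:
    """Per-site corrected statistics and the two criterion flags."""

    position: int
    ref_base: str
    raw_values: np.ndarray
    raw_mean: float
    control_mean: float
    corrected_values: np.ndarray
    corrected_mean: float
    corrected_sd: float
    criterion1: bool
    criterion2: bool
    significant: bool
    n_sample: int
    n_control: int
    evaluable: bool = True


def editing_ratio(areas: dict, edit_mode: str, min_total_area: float = 0.0) -> float:
    """Relative editing from one site's four channel areas.

    Returns NaN (missing) when substrate + product area does not exceed
    ``min_total_area`` (default 0: only an exactly-zero sum is missing).
    """
    sub = SUBSTRATE_BASE[edit_mode]
    prod = PRODUCT_BASE[edit_mode]
    a_sub = float(areas[sub])
    a_prod = float(areas[prod])
    if a_sub < 0 or a_prod < 0:
        raise ValueError("areas must be non-negative")
    total = a_sub + a_prod
    if total <= min_total_area:
        return math.nan
    return a_prod / total


def build_editing_table(peak_tables, site_maps, candidates: CandidateSites,
                        group: str = "sample",
                        replicate_ids=None,
                        min_total_area: float = 0.0) -> EditingTable:
    """Assemble the sites x replicates editing matrix for one condition.

    Parameters
    ----------
    peak_tables, site_maps
        One :class:`PeakQuantTable` and matching :class:`SiteMap` per
        replicate, all against the same reference.
    candidates
        Substrate positions to evaluate.

    A site not covered by an aligned call in some replicate is missing
    (NaN) for that replicate only.
    """
    peak_tables = list(peak_tables)
    site_maps = list(site_maps)
    if not peak_tables:
        raise ValueError("at least one replicate is required")
    if len(peak_tables) != len(site_maps):
        raise ValueError("one site map is required per peak table")
    if replicate_ids is None:
        replicate_ids = [
            pt.sample_id or f"rep{i + 1}" for i, pt in enumerate(peak_tables)
        ]

    n_sites = len(candidates.positions)
    values = np.full((n_sites, len(peak_tables)), np.nan)
    for r, (pt, sm) in enumerate(zip(peak_tables, site_maps)):
        ref_to_call = sm.ref_to_call
        for s, pos in enumerate(candidates.positions):
            call_idx = ref_to_call.get(pos)
            if call_idx is None or call_idx >= len(pt):
                continue
            values[s, r] = editing_ratio(
                pt.areas_at(call_idx), candidates.edit_mode, min_total_area)

    return EditingTable(
        edit_mode=candidates.edit_mode,
        positions=np.asarray(candidates.positions, dtype=int),
        ref_bases=list(candidates.ref_bases),
        values=values,
        replicate_ids=list(replicate_ids),
        group=group,
    )


def call_significant_sites(sample: EditingTable, control: EditingTable,
                           min_replicates: int = 3,
                           strict_criterion2: bool = False) -> list:
    """Apply background correction and the two significance criteria.

    Sites with fewer than ``min_replicates`` non-missing sample values
    or no non-missing control value are returned with
    ``evaluable=False`` and no call.  With ``strict_criterion2`` every
    individual sample replicate (not just the mean) must reach twice the
    control mean.
    """
    if sample.edit_mode != control.edit_mode:
        raise ValueError("sample and control edit modes differ")
    if not np.array_equal(sample.positions, control.positions):
        raise ValueError("sample and control site lists differ")

    results = []
    for s, pos in enumerate(sample.positions):
        raw = sample.values[s]
        ctrl = control.values[s]
        raw_ok = raw[np.isfinite(raw)]
        ctrl_ok = ctrl[np.isfinite(ctrl)]
        base = sample.ref_bases[s]
        if len(raw_ok) < min_replicates or len(ctrl_ok) < 1:
            results.append(SignificanceResult(
                position=int(pos), ref_base=base, raw_values=raw,
                raw_mean=math.nan, control_mean=math.nan,
                corrected_values=np.full_like(raw, np.nan),
                corrected_mean=math.nan, corrected_sd=math.nan,
                criterion1=False, criterion2=False, significant=False,
                n_sample=len(raw_ok), n_control=len(ctrl_ok),
                evaluable=False,
            ))
            continue

        control_mean = float(np.mean(ctrl_ok))
        corrected = raw_ok - control_mean
        corrected_mean = float(np.mean(corrected))
        corrected_sd = float(np.std(corrected, ddof=1)) if len(corrected) > 1 else 0.0
        raw_mean = float(np.mean(raw_ok))

        criterion1 = corrected_mean - 3.0 * corrected_sd > 0.0
        if control_mean < ZERO_CONTROL_EPS:
            criterion2 = (np.all(raw_ok > 0.0) if strict_criterion2
                          else raw_mean > 0.0)
        elif strict_criterion2:
            criterion2 = bool(np.all(raw_ok >= 2.0 * control_mean))
        else:
            criterion2 = raw_mean >= 2.0 * control_mean

        results.append(SignificanceResult(
            position=int(pos), ref_base=base, raw_values=raw,
            raw_mean=raw_mean, control_mean=control_mean,
            corrected_values=corrected, corrected_mean=corrected_mean,
            corrected_sd=corrected_sd,
            criterion1=bool(criterion1), criterion2=bool(criterion2),
            significant=bool(criterion1 and criterion2),
            n_sample=len(raw_ok), n_control=len(ctrl_ok),
            evaluable=True,
        ))
    return results


def summarize_run(results) -> dict:
    """Counts and the strongest site of one significance run.

    Ties on the maximum corrected mean break toward the smallest
    position; an empty or fully non-evaluable run reports zeros.
    """
    results = list(results)
    evaluable = [r for r in results if r.evaluable]
    significant = [r for r in evaluable if r.significant]
    summary = {
        "n_sites": len(results),
        "n_evaluable": len(evaluable),
        "n_significant": len(significant),
        "max_corrected_mean": 0.0,
        "max_position": None,
    }
    if evaluable:
        best = max(evaluable, key=lambda r: (r.corrected_mean, -r.position))
        summary["max_corrected_mean"] = float(best.corrected_mean)
        summary["max_position"] = int(best.position)
    return summary
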