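"""End-to-end pipeline steps shared by the CLI and programmatic use.

``quantify_inputs`` turns trace files or pre-quantified peak tables into
per-replicate peak tables plus reference site maps; ``call_run`` builds
the editing matrices and applies the significance criteria.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import trace_io
from .editcall import build_editing_table, call_significant_sites, summarize_run
from .peakquant import PeakQuantTable, integrate_called_peaks
from .refmap import align_basecalls, enumerate_candidates

__all__ = ["RunConfig", "quantify_inputs", "call_run", "peak_table_to_quant"]


@dataclass
class RunConfig:
    """Validated configuration of one calling run."""

    reference: str
    sample_paths: list
    control_paths: list
    edit_mode: str = "A_to_G"
    min_replicates: int = 3
    identity_floor: float = 0.70
    min_total_area: float = 0.0
    strict_criterion2: bool = False
    baseline: str = "chord"
    output_dir: Path = Path(".")
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.identity_floor <= 1.0:
            raise ValueError("identity_floor must lie in [0, 1]")
        if self.min_replicates < 1:
            raise ValueError("min_replicates must be >= 1")
        if self.min_total_area < 0:
            raise ValueError("min_total_area must be non-negative")
        if self.baseline not in ("none", "window_min", "chord"):
            raise ValueError(f"unknown baseline {self.baseline!r}")


def peak_table_to_quant(df: pd.DataFrame, sample_id: str = "") -> PeakQuantTable:
    """Wrap an external peak-area table as a :class:`PeakQuantTable`.

    External tables are 1-based on the reference; call ordinals become
    0-based internally.
    """
    entries = pd.DataFrame({
        "call_index": np.arange(len(df)),
        "called_base": df["base"].to_numpy(),
        "window_start": np.nan,
        "window_end": np.nan,
    })
    for b in trace_io.BASES:
        entries[f"area_{b}"] = df[f"area_{b}"].to_numpy(dtype=float)
    return PeakQuantTable(entries=entries, sample_id=sample_id)


def _load_one(path, reference: str, baseline: str, identity_floor: float):
    """One replicate -> (PeakQuantTable, SiteMap), from AB1 or a peak table."""
    path = Path(path)
    if path.suffix.lower() in (".ab1", ".abi", ".fsa"):
        chrom = trace_io.read_ab1(path)
        pt = integrate_called_peaks(chrom, baseline=baseline)
        sm = align_basecalls(chrom.basecalls, reference,
                             identity_floor=identity_floor)
    else:
        df = trace_io.read_peak_table(path)
        pt = peak_table_to_quant(df, sample_id=path.stem)
        basecalls = "".join(df["base"])
        sm = align_basecalls(basecalls, reference,
                             identity_floor=identity_floor)
    return pt, sm


def quantify_inputs(paths, reference: str, baseline: str = "chord",
                    identity_floor: float = 0.70):
    """Load and quantify every replicate input.

    Returns ``(peak_tables, site_maps)``; errors are re-raised with the
    offending file name attached.
    """
    tables, maps = [], []
    for path in paths:
        try:
            pt, sm = _load_one(path, reference, baseline, identity_floor)
        except Exception as exc:
            raise type(exc)(f"{path}: {exc}") from exc
        tables.append(pt)
        maps.append(sm)
    return tables, maps


def call_run(config: RunConfig):
    """Full run: quantify, map, build tables, call significance.

    Returns ``(results, summary)`` where ``summary`` also records every
    decision threshold used.
    """
    if len(config.sample_paths) < config.min_replicates:
        raise ValueError(
            f"{len(config.sample_paths)} sample replicates provided but "
            f"min_replicates={config.min_replicates}")
    if not config.control_paths:
        raise ValueError("at least one control replicate is required")

    candidates = enumerate_candidates(config.reference, config.edit_mode)
    s_tabs, s_maps = quantify_inputs(config.sample_paths, config.reference,
                                     config.baseline, config.identity_floor)
    c_tabs, c_maps = quantify_inputs(config.control_paths, config.reference,
                                     config.baseline, config.identity_floor)
    sample = build_editing_table(s_tabs, s_maps, candidates, group="sample",
                                 min_total_area=config.min_total_area)
    control = build_editing_table(c_tabs, c_maps, candidates, group="control",
                                  min_total_area=config.min_total_area)
    results = call_significant_sites(sample, control,
                                     min_replicates=config.min_replicates,
                                     strict_criterion2=config.strict_criterion2)
    summary = summarize_run(results)
    summary["thresholds"] = {
        "edit_mode": config.edit_mode,
        "min_replicates": config.min_replicates,
        "identity_floor": config.identity_floor,
        "min_total_area": config.min_total_area,
        "strict_criterion2": config.strict_criterion2,
        "baseline": config.baseline,
    }
    return results, summary


def write_run_outputs(results, summary, output_dir) -> dict:
    """Write the results TSV and JSON summary; returns the paths."""
    output_dir = Path(output_dir)
    output_dir.mkdir(parents=True, exist_ok=True)
    results_path = output_dir / "results.tsv"
    summary_path = output_dir / "summary.json"
    trace_io.write_results(results, results_path)
    with open(summary_path, "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return {"results": results_path, "summary": summary_path}
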