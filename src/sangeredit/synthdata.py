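"""Synthetic four-channel chromatograms with known ground-truth editing.

The generator emits one Gaussian peak per reference base at uniform
spacing.  At an edited position with true fraction f the substrate
channel carries (1-f) of the peak amplitude and the product channel f —
exactly the mixed-template signal a Sanger trace shows when a fraction
f of the molecules is edited.  Symmetric inter-channel crosstalk
produces the small nonzero background that control subtraction must
remove, additive Gaussian noise models detector noise, and a global
per-replicate amplitude factor models replicate-to-replicate signal
variation.  Everything is reproducible from a single seed.

The generator models the trace, not the biochemistry: PCR amplification
bias, RT errors and mobility shifts are outside its scope.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .editcall import build_editing_table, call_significant_sites
from .peakquant import integrate_called_peaks
from .refmap import (SUBSTRATE_BASE, PRODUCT_BASE, align_basecalls,
                     enumerate_candidates)
from .trace_io import BASES, Chromatogram

__all__ = [
    "TraceModel",
    "EditSpec",
    "SyntheticExperiment",
    "simulate_chromatogram",
    "simulate_experiment",
    "simulate_calibration_series",
    "estimate_operating_characteristics",
    "periodic_reference",
]

_TWO_BASE_CODE = {
    frozenset("AG"): "R", frozenset("CT"): "Y", frozenset("CG"): "S",
    frozenset("AT"): "W", frozenset("GT"): "K", frozenset("AC"): "M",
}


@dataclass
class TraceModel:
    """Tunable parameters of the synthetic sequencer.

    peak_spacing : trace samples between adjacent called peaks (12).
    peak_sd : Gaussian peak width in samples (3.0).
    amplitude : nominal peak amplitude in fluorescence units (1000).
    amplitude_cv : relative replicate-to-replicate amplitude variation (0.1).
    crosstalk : fraction of each peak leaking symmetrically into each
        other channel (0.01) — the dominant source of nonzero background.
    noise_sd : additive per-sample channel noise, fluorescence units (10).
    jitter : peak-centre jitter in samples (0; nonzero breaks the
        uniform-spacing assumption deliberately).
    ambiguity_threshold : minor/major amplitude ratio above which the
        basecall becomes a two-base IUPAC code (0.25), mirroring how
        trace viewers flag secondary peaks.
    """

    peak_spacing: int = 12
    peak_sd: float = 3.0
    amplitude: float = 1000.0
    amplitude_cv: float = 0.1
    crosstalk: float = 0.01
    noise_sd: float = 10.0
    jitter: float = 0.0
    ambiguity_threshold: float = 0.25

    def __post_init__(self):
        for name in ("peak_spacing", "peak_sd", "amplitude", "amplitude_cv",
                     "crosstalk", "noise_sd", "jitter"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.peak_spacing < 2 * self.peak_sd:
            import warnings
            warnings.warn("peaks overlap by >= 50%: areas will mix heavily",
                          stacklevel=2)


@dataclass
class EditSpec:
    """Ground-truth editing: (1-based position, true fraction) pairs."""

    edits: list = field(default_factory=list)
    edit_mode: str = "A_to_G"

    def fractions_for(self, reference: str) -> dict:
        sub = SUBSTRATE_BASE[self.edit_mode]
        out = {}
        for pos, frac in self.edits:
            if not 1 <= pos <= len(reference):
                raise ValueError(f"edit position {pos} outside reference")
            if reference[pos - 1].upper() != sub:
                raise ValueError(
                    f"edit position {pos} is {reference[pos - 1]!r}, not the "
                    f"substrate base {sub!r} of mode {self.edit_mode}")
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"true fraction {frac} outside [0, 1]")
            out[pos] = frac
        return out


@dataclass
class SyntheticExperiment:
    """Sample and control replicate traces with their generating truth."""

    reference: str
    edit_mode: str
    sample: list
    control: list
    truth: dict     # position -> true fraction (samples; controls are 0)

    def truth_frame(self) -> pd.DataFrame:
        items = sorted(self.truth.items())
        return pd.DataFrame(items, columns=["position", "true_fraction"])


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def simulate_chromatogram(reference: str, edits: EditSpec | None = None,
                          model: TraceModel | None = None,
                          seed=0, sample_id: str = "synthetic") -> Chromatogram:
    """Generate one chromatogram for ``reference`` under ``model``.

    Basecalls are derived from the noiseless per-peak channel amplitudes
    (maximum channel's base, or a two-base IUPAC code when the minor
    channel exceeds the ambiguity threshold); peak locations are the
    true peak centres.  Identical inputs and seed give bit-identical
    output.
    """
    if not reference:
        raise ValueError("reference must be non-empty")
    reference = reference.upper()
    model = model or TraceModel()
    edits = edits or EditSpec()
    rng = _as_rng(seed)
    fractions = edits.fractions_for(reference)
    sub = SUBSTRATE_BASE[edits.edit_mode]
    prod = PRODUCT_BASE[edits.edit_mode]

    n = len(reference)
    spacing = model.peak_spacing
    centers = spacing * (1.0 + np.arange(n))
    if model.jitter > 0:
        centers = centers + rng.normal(0.0, model.jitter, size=n)
        centers = np.maximum.accumulate(centers)  # keep ordering
        centers += np.arange(n) * 1e-6
    length = spacing * (n + 2)

    rep_factor = max(float(rng.normal(1.0, model.amplitude_cv)), 0.2)
    amp = model.amplitude * rep_factor

    # per-peak channel amplitudes before crosstalk
    channel_amp = np.zeros((n, 4))
    base_index = {b: k for k, b in enumerate(BASES)}
    for i, base in enumerate(reference):
        f = fractions.get(i + 1)
        if f is None or base != sub:
            channel_amp[i, base_index[base]] = amp
        else:
            channel_amp[i, base_index[sub]] = (1.0 - f) * amp
            channel_amp[i, base_index[prod]] = f * amp

    # symmetric crosstalk: every channel receives a fixed fraction of
    # every other channel's peak at the same position
    c = model.crosstalk
    totals = channel_amp.sum(axis=1, keepdims=True)
    mixed = channel_amp + c * (totals - channel_amp)

    # basecalls from noiseless mixed amplitudes
    calls = []
    for i in range(n):
        order = np.argsort(mixed[i])[::-1]
        major, minor = order[0], order[1]
        if mixed[i, major] <= 0:
            calls.append("N")
        elif mixed[i, minor] > model.ambiguity_threshold * mixed[i, major]:
            calls.append(_TWO_BASE_CODE[frozenset((BASES[major], BASES[minor]))])
        else:
            calls.append(BASES[major])

    x = np.arange(length, dtype=float)
    traces = {b: np.zeros(length) for b in BASES}
    half_width = int(np.ceil(6 * model.peak_sd))
    for i in range(n):
        lo = max(int(centers[i]) - half_width, 0)
        hi = min(int(centers[i]) + half_width + 1, length)
        shape = np.exp(-0.5 * ((x[lo:hi] - centers[i]) / model.peak_sd) ** 2)
        for k, b in enumerate(BASES):
            if mixed[i, k] > 0:
                traces[b][lo:hi] += mixed[i, k] * shape

    if model.noise_sd > 0:
        for b in BASES:
            traces[b] = traces[b] + rng.normal(0.0, model.noise_sd, size=length)
    for b in BASES:
        traces[b] = np.clip(traces[b], 0.0, None)

    peak_locations = np.round(centers).astype(int)

    return Chromatogram(
        sample_id=sample_id,
        traces=traces,
        basecalls="".join(calls),
        peak_locations=peak_locations,
        quality=np.full(n, 50, dtype=int),
        channel_order="ACGT",
    )


def simulate_experiment(reference: str, edits: EditSpec,
                        model: TraceModel | None = None,
                        n_sample: int = 4, n_control: int = 4,
                        seed=0) -> SyntheticExperiment:
    """Generate paired sample/control replicate sets.

    Controls are generated from the same model with every true fraction
    zero — they carry the same crosstalk background the correction must
    remove.  Per-replicate seeds derive deterministically from the
    master seed.
    """
    if n_sample < 1 or n_control < 1:
        raise ValueError("need at least one sample and one control replicate")
    model = model or TraceModel()
    master = seed if isinstance(seed, np.random.SeedSequence) \
        else np.random.SeedSequence(seed)
    children = master.spawn(n_sample + n_control)
    sample = [
        simulate_chromatogram(reference, edits, model,
                              seed=np.random.default_rng(children[i]),
                              sample_id=f"sample_rep{i + 1}")
        for i in range(n_sample)
    ]
    null = EditSpec(edits=[], edit_mode=edits.edit_mode)
    control = [
        simulate_chromatogram(reference, null, model,
                              seed=np.random.default_rng(children[n_sample + i]),
                              sample_id=f"control_rep{i + 1}")
        for i in range(n_control)
    ]
    return SyntheticExperiment(
        reference=reference,
        edit_mode=edits.edit_mode,
        sample=sample,
        control=control,
        truth=edits.fractions_for(reference),
    )


def periodic_reference(n_sites: int, edit_mode: str = "A_to_G",
                       pad: str | None = None) -> str:
    """Deterministic reference with ``n_sites`` substrate positions in
    cycling sequence contexts (used by tests and the characterisation
    harness).

    Spacers avoid placing the substrate or product base directly next to
    a candidate site, so neighbouring-peak tails cannot leak into the
    channels that form the editing ratio.
    """
    sub = SUBSTRATE_BASE[edit_mode]
    prod = PRODUCT_BASE[edit_mode]
    neutral = [b for b in BASES if b not in (sub, prod)]
    a, b = neutral
    spacers = [a + b, b + a, a + a, b + b]
    if pad is None:
        pad = a + b
    parts = [pad]
    for i in range(n_sites):
        parts.append(sub)
        parts.append(spacers[i % len(spacers)])
    parts.append(pad)
    return "".join(parts)


def _pipeline_tables(chroms, reference, candidates, group, baseline="chord"):
    tables, maps = [], []
    for ch in chroms:
        tables.append(integrate_called_peaks(ch, baseline=baseline))
        maps.append(align_basecalls(ch.basecalls, reference))
    return build_editing_table(tables, maps, candidates, group=group)


def run_experiment(experiment: SyntheticExperiment, min_replicates: int = 3,
                   baseline: str = "chord"):
    """Quantify, map and call one synthetic experiment end to end."""
    candidates = enumerate_candidates(experiment.reference, experiment.edit_mode)
    sample_tab = _pipeline_tables(experiment.sample, experiment.reference,
                                  candidates, "sample", baseline)
    control_tab = _pipeline_tables(experiment.control, experiment.reference,
                                   candidates, "control", baseline)
    return call_significant_sites(sample_tab, control_tab,
                                  min_replicates=min_replicates)


def simulate_calibration_series(expected_fractions, model: TraceModel | None = None,
                                seed=0, site_context: str = "GCTACTG",
                                site_position: int = 4):
    """Emulate the plasmid-mix calibration: sequence defined mixes of an
    edited and an unedited template and measure the peak-ratio fraction
    at the mutated position.

    Returns ``(expected, measured)`` arrays ready for
    :func:`sangeredit.assays.fit_calibration`.
    """
    model = model or TraceModel()
    rng = _as_rng(seed)
    reference = site_context
    if reference[site_position - 1] != "A":
        raise ValueError("site_position must index an A in site_context")
    measured = []
    for f in expected_fractions:
        edits = EditSpec(edits=[(site_position, float(f))], edit_mode="A_to_G")
        chrom = simulate_chromatogram(reference, edits, model, seed=rng)
        pt = integrate_called_peaks(chrom)
        sm = align_basecalls(chrom.basecalls, reference)
        call_idx = sm.ref_to_call[site_position]
        areas = pt.areas_at(call_idx)
        measured.append(areas["G"] / (areas["A"] + areas["G"]))
    return np.asarray(expected_fractions, dtype=float), np.asarray(measured)


def estimate_operating_characteristics(reference: str,
                                       model: TraceModel | None = None,
                                       fractions=(0.0, 0.25, 0.5, 1.0),
                                       n_sites: int | None = None,
                                       n_sample: int = 4, n_control: int = 4,
                                       n_runs: int = 5, seed=0,
                                       edit_mode: str = "A_to_G") -> pd.DataFrame:
    """Monte-Carlo call rate of the significance criteria per true fraction.

    For each fraction f, ``n_runs`` experiments are generated with the
    first ``n_sites`` candidate positions all edited at f, the full
    pipeline is run, and the fraction of significant calls recorded.
    The f = 0 row is the type-I error rate; rows with f > 0 are power.
    Binomial standard errors and the mean estimation bias
    (corrected mean minus f) accompany each rate.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    model = model or TraceModel()
    candidates = enumerate_candidates(reference, edit_mode)
    positions = candidates.positions[:n_sites] if n_sites else candidates.positions
    if not positions:
        raise ValueError("reference contains no substrate positions")
    master = np.random.SeedSequence(seed)
    run_seeds = master.spawn(len(fractions) * n_runs)

    rows = []
    for fi, f in enumerate(fractions):
        n_called = 0
        n_total = 0
        biases = []
        for r in range(n_runs):
            edits = EditSpec(edits=[(p, float(f)) for p in positions],
                             edit_mode=edit_mode)
            exp = simulate_experiment(reference, edits, model,
                                      n_sample=n_sample, n_control=n_control,
                                      seed=run_seeds[fi * n_runs + r])
            results = run_experiment(exp)
            for res in results:
                if res.position in set(positions) and res.evaluable:
                    n_total += 1
                    n_called += int(res.significant)
                    biases.append(res.corrected_mean - f)
        rate = n_called / n_total if n_total else float("nan")
        se = (np.sqrt(rate * (1 - rate) / n_total) if n_total else float("nan"))
        rows.append({
            "true_fraction": float(f),
            "call_rate": rate,
            "binomial_se": se,
            "n_evaluated": n_total,
            "mean_bias": float(np.mean(biases)) if biases else float("nan"),
        })
    return pd.DataFrame(rows)
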