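"""Editing-profile plots: percent editing per candidate position along
the reference, significant sites highlighted."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt

__all__ = ["plot_editing_profile"]

_BACKGROUND = dict(color="0.6", marker="o", s=18, zorder=2)
_SIGNIFICANT = dict(color="crimson", marker="o", s=42, zorder=3)


def plot_editing_profile(results, path, condition: str = "",
                         show_corrected: bool = True) -> None:
    """Scatter of editing (%) against reference position.

    Evaluable sites are grey; significant ones are drawn larger and in
    colour.  ``show_corrected`` plots the background-corrected mean
    (clipped at zero for display); otherwise the raw mean.  Output
    format follows the file extension; PNG metadata is pinned so reruns
    on identical inputs are byte-identical.
    """
    results = [r for r in results if r.evaluable]
    if not results:
        raise ValueError("no evaluable results to plot")

    def value(r):
        v = r.corrected_mean if show_corrected else r.raw_mean
        return max(v, 0.0) * 100.0

    fig, ax = plt.subplots(figsize=(8, 3))
    plain = [r for r in results if not r.significant]
    hits = [r for r in results if r.significant]
    ax.scatter([r.position for r in plain], [value(r) for r in plain],
               label="not significant", **_BACKGROUND)
    if hits:
        ax.scatter([r.position for r in hits], [value(r) for r in hits],
                   label="significant", **_SIGNIFICANT)
        ax.errorbar([r.position for r in hits],
                    [value(r) for r in hits],
                    yerr=[r.corrected_sd * 100.0 for r in hits],
                    fmt="none", ecolor="crimson", elinewidth=1, capsize=2,
                    zorder=3)
    ax.set_xlabel("reference position (nt)")
    ax.set_ylabel("editing (%)")
    ax.set_ylim(bottom=0)
    if condition:
        ax.set_title(condition)
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    metadata = None
    if str(path).lower().endswith(".png"):
        metadata = {"Software": "sangeredit"}
    fig.savefig(path, dpi=150, metadata=metadata)
    plt.close(fig)
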