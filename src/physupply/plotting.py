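"""Minimal plotting of sufficiency trajectories under scenarios."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt  # noqa: E402


def plot_sufficiency(results, group: str, path, threshold: float = 1.0) -> None:
    """One line per scenario for a group's sufficiency level, threshold dashed."""
    fig, ax = plt.subplots(figsize=(7, 4))
    for result in results:
        levels = result.sufficiency[group].levels
        ax.plot(levels.index, levels.values, label=result.name)
    ax.axhline(threshold, color="grey", linestyle="--", linewidth=1)
    ax.set_xlabel("year")
    ax.set_ylabel("sufficiency level")
    ax.set_title(f"Sufficiency level, {group}")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
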