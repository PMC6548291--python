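"""Discrete-state assignment for the Rab:GDI complex and histogram reports.

Two categorical descriptors are assigned per frame:

* binding mode — ``tight`` vs ``loose`` from the inter-protein COM distance.
  The reported tight complexes sit at 3.2–3.5 nm and the loose ones average
  3.7 nm, so the default boundary is the midpoint 3.55 nm (config-exposed).
* pocket state — ``open`` / ``semi-open`` / ``close``, primarily from the
  pocket-volume bands.  The three reported state means are 692.1, 396.4 and
  169.8 Å³; the default band edges 250 and 550 Å³ are the midpoints between
  them.  The opening-angle/insertion-depth criterion for the open state
  (θ > 40° and depth ≤ 2.3 nm) is reported as a per-frame concordance flag
  rather than a competing classifier, since only the open state has a stated
  angle criterion.

Whole-window labels are majority votes over frames; binding ties break to
``loose`` (the conservative call).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .descriptors import DescriptorSeries

__all__ = [
    "StateThresholds",
    "StateAssignment",
    "classify_binding_mode",
    "classify_pocket_state",
    "histogram_report",
]


@dataclass
class StateThresholds:
    """Decision thresholds for binding-mode and pocket-state assignment."""

    tight_max_dinter: float = 3.55          # nm
    open_min_theta: float = 40.0            # degrees
    open_max_depth: float = 2.3             # nm
    volume_bands: tuple[float, float] = (250.0, 550.0)  # Å³: close|semi-open|open

    def __post_init__(self) -> None:
        lo, hi = self.volume_bands
        if not 0 < lo < hi:
            raise ValueError("volume bands must be strictly increasing and positive")
        if min(self.tight_max_dinter, self.open_min_theta, self.open_max_depth) <= 0:
            raise ValueError("thresholds must be positive")


@dataclass
class StateAssignment:
    """Per-frame labels plus the window-majority label and label fractions."""

    category: str                       # "binding" or "pocket"
    labels: np.ndarray                  # per-frame str labels
    majority: str
    fractions: dict[str, float]
    concordant: np.ndarray | None = None  # pocket only: θ/depth agreement flags

    def __post_init__(self) -> None:
        total = sum(self.fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"label fractions sum to {total}, expected 1")


def _fractions(labels: np.ndarray, categories: list[str]) -> dict[str, float]:
    n = len(labels)
    return {c: float(np.sum(labels == c)) / n for c in categories}


def classify_binding_mode(d_inter: DescriptorSeries,
                          thresholds: StateThresholds | None = None) -> StateAssignment:
    """Tight/loose binding from the d_inter series (nm).

    Per-frame tight iff d_inter ≤ tight_max_dinter; window majority label,
    ties resolved to loose.
    """
    thresholds = thresholds or StateThresholds()
    if len(d_inter) == 0:
        raise ValueError("classify_binding_mode: empty series")
    if d_inter.unit != "nm":
        raise ValueError(f"d_inter series must be in nm, got {d_inter.unit!r}")
    labels = np.where(d_inter.values <= thresholds.tight_max_dinter,
                      "tight", "loose").astype(object)
    frac = _fractions(labels, ["tight", "loose"])
    majority = "tight" if frac["tight"] > 0.5 else "loose"
    return StateAssignment("binding", labels, majority, frac)


def classify_pocket_state(volume: DescriptorSeries,
                          theta: DescriptorSeries | None = None,
                          depth_mean: DescriptorSeries | None = None,
                          thresholds: StateThresholds | None = None) -> StateAssignment:
    """Open/semi-open/close pocket state from the volume series (Å³).

    Band rule is left-closed: volume < 250 → close, 250 ≤ volume < 550 →
    semi-open, volume ≥ 550 → open.  When θ (degrees) and mean insertion
    depth (nm) series are supplied, a per-frame concordance flag records
    whether the open-state geometric criterion (θ > open_min_theta and
    depth ≤ open_max_depth) agrees with the volume-based label.
    """
    thresholds = thresholds or StateThresholds()
    if len(volume) == 0:
        raise ValueError("classify_pocket_state: empty series")
    for series in (theta, depth_mean):
        if series is not None and len(series) != len(volume):
            raise ValueError("classify_pocket_state: misaligned series lengths")
    lo, hi = thresholds.volume_bands
    labels = np.empty(len(volume), dtype=object)
    labels[volume.values < lo] = "close"
    labels[(volume.values >= lo) & (volume.values < hi)] = "semi-open"
    labels[volume.values >= hi] = "open"
    frac = _fractions(labels, ["open", "semi-open", "close"])
    majority = max(frac, key=lambda k: frac[k])
    concordant = None
    if theta is not None and depth_mean is not None:
        geometric_open = ((theta.values > thresholds.open_min_theta)
                          & (depth_mean.values <= thresholds.open_max_depth))
        concordant = geometric_open == (labels == "open")
    return StateAssignment("pocket", labels, majority, frac, concordant=concordant)


def histogram_report(series: DescriptorSeries, bin_width: float,
                     reference_lines: list[float] | None = None,
                     plot_path=None) -> pd.DataFrame:
    """Normalized frequency histogram of a descriptor series.

    Bin frequencies sum to 1; ``reference_lines`` (e.g. the crystal-structure
    value of the quantity) are echoed into the table attributes and drawn as
    vertical lines when a plot is written.
    """
    if bin_width <= 0:
        raise ValueError("bin width must be positive")
    vals = series.values
    lo = np.floor(vals.min() / bin_width) * bin_width
    if lo > vals.min():  # guard against floating-point rounding of the floor
        lo -= bin_width
    n_bins = max(1, int(np.floor((vals.max() - lo) / bin_width)) + 1)
    edges = lo + bin_width * np.arange(n_bins + 1)
    while edges[-1] <= vals.max():
        edges = np.append(edges, edges[-1] + bin_width)
    counts, edges = np.histogram(vals, bins=edges)
    freq = counts / counts.sum()
    table = pd.DataFrame({
        "bin_left": edges[:-1],
        "bin_right": edges[1:],
        "frequency": freq,
    })
    table.attrs["name"] = series.name
    table.attrs["unit"] = series.unit
    table.attrs["reference_lines"] = list(reference_lines or [])
    if plot_path is not None:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(5, 3.2))
        ax.bar(edges[:-1], freq, width=bin_width, align="edge",
               edgecolor="black", linewidth=0.4)
        for ref in reference_lines or []:
            ax.axvline(ref, color="black", linestyle="--", linewidth=1.0)
        ax.set_xlabel(f"{series.name} ({series.unit})")
        ax.set_ylabel("frequency")
        fig.tight_layout()
        fig.savefig(plot_path)
        plt.close(fig)
    return table
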