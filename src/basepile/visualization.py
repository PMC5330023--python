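"""Bar-plot rendering of per-position base composition.

One plot per sample (panels = target positions) or one plot per position
(panels = samples).  Observed event counts rise from the positive y axis;
the reference base — and any known-variant alternates, stacked below it —
hangs from the negative y axis at a fixed unit height.  Bars are colored by
base (A green, C blue, G yellow, T red, deletion black; insertions take the
inserted base's color with a purple edge) and darkened toward high mean
base quality.  Dashed segments mark genotype-expected heights; horizontal
lines mark user-chosen ratio thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
from matplotlib.colors import to_rgb

from .aggregation import BASES
from .pileup_engine import QUALITY_OFFSET

#: Fixed category coloring.
CATEGORY_COLORS = {
    "A": "green",
    "C": "blue",
    "G": "yellow",
    "T": "red",
    "N": "grey",
    "deletion": "black",
}
INSERTION_EDGE_COLOR = "purple"

#: Drawing order of positive-axis bars within one panel.
_BAR_ORDER = ("A", "C", "G", "T", "N", "deletion")


@dataclass(frozen=True)
class Panel:
    """One bar group: a (sample, position) or (position, sample) slot."""

    label: str
    heights: dict                  # category -> bar height (count or fraction)
    mean_quality: dict             # category -> mean Phred, retained bases only
    ref_base: str
    known_alts: tuple = ()
    expected: Optional[dict] = None  # category -> expected height
    insertion_breakdown: dict = field(default_factory=dict)  # base -> height
    depth: int = 0


@dataclass(frozen=True)
class PlotSpec:
    mode: str                      # per_sample | per_position
    count_mode: str                # absolute | relative
    panels: tuple
    marks: tuple = ()
    quality_lower_bound: int = 53  # ASCII codes
    quality_upper_bound: int = 73


def quality_shade(mean_q: float, lower: int, upper: int) -> float:
    """Map a mean Phred quality to a darkness fraction in [0, 1].

    ``lower`` and ``upper`` are ASCII codes; the map is linear over the
    corresponding Phred interval and clamped outside it.
    """
    if lower >= upper:
        raise ValueError(f"quality lower bound {lower} must be below upper bound {upper}")
    lo = lower - QUALITY_OFFSET
    hi = upper - QUALITY_OFFSET
    return min(1.0, max(0.0, (mean_q - lo) / (hi - lo)))


def _shade_color(category_color: str, shade: float):
    """Blend toward white for low shade; full color at shade 1."""
    r, g, b = to_rgb(category_color)
    fade = 0.65 * (1.0 - shade)
    return (r + (1 - r) * fade, g + (1 - g) * fade, b + (1 - b) * fade)


def build_plot_specs(records_by_sample: dict, config) -> list:
    """Assemble plot specs from per-sample record lists.

    ``per_sample`` mode yields one spec per sample with one panel per target;
    ``per_position`` mode yields one spec per target with one panel per
    sample.  Names derive from the sample or from ``chrom_pos``.
    """
    relative = config.count_mode == "relative"
    specs = []

    def make_panel(rec, label):
        depth = rec.counts.depth
        scale = (1.0 / depth) if (relative and depth) else (0.0 if relative else 1.0)
        heights = {
            c: rec.counts.get(c) * scale if relative else float(rec.counts.get(c))
            for c in _BAR_ORDER + ("insertion",)
        }
        breakdown = {
            b: (n * scale if relative else float(n))
            for b, n in sorted(rec.insertion_display.items())
        }
        heights["insertion"] = sum(breakdown.values())
        expected = None
        if rec.expected is not None:
            expected = {
                c: (v * scale if relative else float(v))
                for c, v in rec.expected.items()
                if v > 0
            }
        return Panel(
            label=label,
            heights=heights,
            mean_quality=dict(rec.counts.mean_quality),
            ref_base=rec.ref_base,
            known_alts=tuple(rec.known_alts),
            expected=expected,
            insertion_breakdown=breakdown,
            depth=depth,
        )

    common = dict(
        count_mode=config.count_mode,
        marks=tuple(config.marks),
        quality_lower_bound=config.quality_lower_bound,
        quality_upper_bound=config.quality_upper_bound,
    )
    if config.plot_mode == "per_sample":
        for sample, records in records_by_sample.items():
            panels = tuple(
                make_panel(r, f"{r.target.chrom}:{r.target.pos}") for r in records
            )
            specs.append((sample, PlotSpec(mode="per_sample", panels=panels, **common)))
    else:
        sample_names = list(records_by_sample)
        if not sample_names:
            return []
        n_targets = len(records_by_sample[sample_names[0]])
        for i in range(n_targets):
            recs = [records_by_sample[s][i] for s in sample_names]
            t = recs[0].target
            name = f"{t.chrom}_{t.pos}"
            if t.occurrence_index > 1:
                name += f"_{t.occurrence_index}"
            panels = tuple(make_panel(r, r.sample) for r in recs)
            specs.append((name, PlotSpec(mode="per_position", panels=panels, **common)))
    return specs


def render_plot(spec: PlotSpec, path, title: Optional[str] = None) -> Path:
    """Render one spec to a PNG (150 dpi)."""
    if not spec.panels:
        raise ValueError("plot spec has no panels")

    n = len(spec.panels)
    relative = spec.count_mode == "relative"
    max_pos = max(
        [h for p in spec.panels for h in p.heights.values()] + [1e-9]
    )
    # Reference bars are unit height, never depth-scaled; in absolute mode a
    # fixed fraction of the tallest bar keeps them visible at any coverage.
    unit = 1.0 if relative else 0.15 * max(max_pos, 1.0)

    fig, ax = plt.subplots(figsize=(max(3.0, 1.6 * n), 4.5))
    bar_w = 0.1

    for i, panel in enumerate(spec.panels):
        cats = [c for c in _BAR_ORDER if panel.heights.get(c, 0) > 0]
        slots = len(cats) + (1 if panel.heights.get("insertion", 0) > 0 else 0)
        x0 = i - bar_w * (slots - 1) / 2 if slots else i
        xj = x0
        for c in cats:
            shade = quality_shade(
                panel.mean_quality.get(c, 0.0),
                spec.quality_lower_bound,
                spec.quality_upper_bound,
            ) if c != "deletion" else 1.0
            ax.bar(
                xj, panel.heights[c], width=bar_w,
                color=_shade_color(CATEGORY_COLORS[c], shade),
                edgecolor="none",
            )
            xj += bar_w
        if panel.heights.get("insertion", 0) > 0:
            shade = quality_shade(
                panel.mean_quality.get("insertion", 0.0),
                spec.quality_lower_bound,
                spec.quality_upper_bound,
            )
            bottom = 0.0
            segments = panel.insertion_breakdown or {"N": panel.heights["insertion"]}
            for base in sorted(segments):
                h = segments[base]
                ax.bar(
                    xj, h, width=bar_w, bottom=bottom,
                    color=_shade_color(CATEGORY_COLORS.get(base, "grey"), shade),
                    edgecolor=INSERTION_EDGE_COLOR, linewidth=1.2,
                )
                bottom += h
        # negative axis: reference base, then known alternates stacked below
        ref_stack = (panel.ref_base,) + tuple(panel.known_alts)
        for j, b in enumerate(ref_stack):
            ax.bar(
                i, -unit, width=0.6, bottom=-unit * j,
                color=CATEGORY_COLORS.get(b.upper(), "grey"),
                edgecolor="white", linewidth=0.5,
            )
        # genotype-expected heights as dashed segments across the panel
        if panel.expected:
            for c, h in sorted(panel.expected.items()):
                ax.hlines(
                    h, i - 0.4, i + 0.4,
                    colors=CATEGORY_COLORS.get(c if c != "insertion" else "N", "grey")
                    if c != "insertion" else INSERTION_EDGE_COLOR,
                    linestyles="dashed", linewidth=1.0,
                )
        if not relative:
            for m in spec.marks:
                ax.hlines(m * panel.depth, i - 0.45, i + 0.45,
                          colors="dimgrey", linewidth=0.8)

    if relative:
        for m in spec.marks:
            ax.axhline(m, color="dimgrey", linewidth=0.8)

    ax.axhline(0, color="black", linewidth=0.8)
    ax.set_xticks(range(n))
    ax.set_xticklabels([p.label for p in spec.panels], rotation=45, ha="right")
    ax.set_ylabel(
        "relative number of reads" if relative else "absolute number of reads"
    )
    if title:
        ax.set_title(title)
    max_stack = max(1 + len(p.known_alts) for p in spec.panels)
    ax.set_ylim(-unit * (max_stack + 0.3), max(max_pos, unit) * 1.1)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)
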