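"""Candidate triage: intersect the screen ranking with protein lists.

The screen's enriched-gene set is crossed with an interactome protein list
(e.g. an IP-MS bait interactome) and optionally a third set, yielding the
ordered overlap and exclusive Venn-region counts. The enrichment criterion
(top-N or a fold-change floor) is an explicit parameter and is echoed in the
result metadata, since "significantly enriched" has no universal definition
for a rank-only screen.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .io import ValidationError


@dataclass(frozen=True)
class TriageResult:
    overlap_genes: list[str]  # screen-rank order
    venn_counts: dict[str, int]  # exclusive region sizes
    parameters: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "overlap_genes": self.overlap_genes,
            "n_overlap": len(self.overlap_genes),
            "venn_counts": self.venn_counts,
            "parameters": self.parameters,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")


def select_enriched(
    ranking: pd.DataFrame,
    top_n: int | None = None,
    min_avg_fold_change: float | None = None,
) -> list[str]:
    """Genes meeting the enrichment cutoff, in rank order.

    Exactly one of ``top_n`` or ``min_avg_fold_change`` (inclusive ``>=``)
    must be given.
    """
    if (top_n is None) == (min_avg_fold_change is None):
        raise ValidationError(
            "exactly one of top_n or min_avg_fold_change must be supplied"
        )
    ordered = ranking.sort_values("rank")
    if top_n is not None:
        if top_n > len(ordered):
            warnings.warn(
                f"top_n={top_n} exceeds ranking size {len(ordered)}; returning all",
                stacklevel=2,
            )
        return list(ordered["gene"].head(top_n))
    keep = ordered["avg_fold_change"] >= min_avg_fold_change
    return list(ordered.loc[keep, "gene"])


def intersect_sets(
    set_a: Sequence[str],
    set_b: Iterable[str],
    set_c: Iterable[str] | None = None,
    parameters: dict | None = None,
) -> TriageResult:
    """Overlap and exclusive Venn-region counts for 2 or 3 gene sets.

    ``set_a`` is ordered (screen-rank order); the overlap preserves that
    order. Symbols are uppercased before comparison.
    """
    a_order = list(dict.fromkeys(s.upper() for s in set_a))
    a, b = set(a_order), {s.upper() for s in set_b}
    if set_c is None:
        overlap = [g for g in a_order if g in b]
        venn = {
            "a_only": len(a - b),
            "b_only": len(b - a),
            "ab": len(a & b),
        }
    else:
        c = {s.upper() for s in set_c}
        overlap = [g for g in a_order if g in b and g in c]
        venn = {
            "a_only": len(a - b - c),
            "b_only": len(b - a - c),
            "c_only": len(c - a - b),
            "ab": len((a & b) - c),
            "ac": len((a & c) - b),
            "bc": len((b & c) - a),
            "abc": len(a & b & c),
        }
    return TriageResult(overlap, venn, parameters or {})


def plot_venn(
    result: TriageResult,
    labels: Sequence[str] = ("screen", "interactome", "third set"),
    path: str | Path | None = None,
):
    """Proportion-free 2- or 3-circle Venn sketch annotated with counts."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.patches import Circle

    venn = result.venn_counts
    fig, ax = plt.subplots(figsize=(5, 4))
    three = "abc" in venn
    centers = [(-0.5, 0.25), (0.5, 0.25), (0.0, -0.55)] if three else [(-0.45, 0), (0.45, 0)]
    colors = ["#1f77b4", "#ff7f0e", "#2ca02c"]
    for (x, y), color, label in zip(centers, colors, labels):
        ax.add_patch(Circle((x, y), 1.0, alpha=0.3, color=color))
        ax.annotate(label, (x, y + 1.05), ha="center", fontsize=9)
    if three:
        spots = {
            "a_only": (-1.0, 0.5), "b_only": (1.0, 0.5), "c_only": (0.0, -1.1),
            "ab": (0.0, 0.6), "ac": (-0.6, -0.35), "bc": (0.6, -0.35),
            "abc": (0.0, 0.0),
        }
    else:
        spots = {"a_only": (-0.95, 0), "b_only": (0.95, 0), "ab": (0.0, 0)}
    for region, (x, y) in spots.items():
        ax.annotate(str(venn[region]), (x, y), ha="center", va="center")
    ax.set_xlim(-2.1, 2.1)
    ax.set_ylim(-2.1, 1.8)
    ax.set_aspect("equal")
    ax.axis("off")
    if path is not None:
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
    return fig
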