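"""In vivo enrichment ranking for a bottlenecked metastasis screen.

The analysis compares each metastatic lung's guide distribution with the
pre-injection input baseline:

1. exclude guides with fewer than ``min_lung_reads`` raw reads in a lung
   (applied per lung sample, i.e. per mouse);
2. normalize every sample to reads-per-million (total-count normalization);
3. per mouse, fold change = (lung RPM + pc) / (input RPM + pc);
4. average fold change across mice;
5. per gene, take the most enriched guide and rank genes by its average
   fold change (rank 1 = most enriched).

Step 4 has two modes. ``mouse_denominator="metastatic"`` (default) divides
the summed fold changes by the number of metastatic mice, so a guide that
was filtered out of a lung contributes zero enrichment evidence for that
mouse; this suppresses single-mouse jackpot clones, which otherwise dominate
the top of the ranking in a severely bottlenecked screen.
``"retained"`` averages over only the mice in which the guide passed the
read filter.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import LibraryManifest, SampleSheet, ValidationError


@dataclass(frozen=True)
class InVivoConfig:
    """Parameters of the in vivo ranking.

    min_lung_reads
        Raw-read floor below which a guide is excluded from a lung sample
        (default 50; a guide with exactly 50 reads is retained).
    normalization_scale
        Per-sample total after normalization (default 1e6, reads-per-million).
    pseudocount
        Added to numerator and denominator of every fold change, in
        normalized units (default 0.5 RPM); guards against division by zero
        for guides absent from the input.
    averaging
        "arithmetic" (default) or "geometric" mean of per-mouse fold changes.
        Geometric averaging always uses retained mice only.
    mouse_denominator
        "metastatic" (default) or "retained"; see module docstring.
    """

    min_lung_reads: int = 50
    normalization_scale: float = 1e6
    pseudocount: float = 0.5
    averaging: str = "arithmetic"
    mouse_denominator: str = "metastatic"

    def __post_init__(self) -> None:
        if self.min_lung_reads < 0:
            raise ValidationError("min_lung_reads must be >= 0")
        if self.normalization_scale <= 0:
            raise ValidationError("normalization_scale must be positive")
        if self.pseudocount < 0:
            raise ValidationError("pseudocount must be >= 0")
        if self.averaging not in {"arithmetic", "geometric"}:
            raise ValidationError("averaging must be 'arithmetic' or 'geometric'")
        if self.mouse_denominator not in {"metastatic", "retained"}:
            raise ValidationError("mouse_denominator must be 'metastatic' or 'retained'")


def filter_low_coverage(
    counts: pd.DataFrame, sheet: SampleSheet, config: InVivoConfig = InVivoConfig()
) -> pd.DataFrame:
    """Boolean retention mask per (guide, lung sample) on *raw* counts.

    True iff the guide has at least ``min_lung_reads`` reads in that lung.
    """
    lungs = [s for s in sheet.samples_with_role("lung") if s in counts.columns]
    if not lungs:
        raise ValidationError("no lung samples found in count matrix")
    return counts[lungs] >= config.min_lung_reads


def normalize_total(counts: pd.DataFrame, scale: float = 1e6) -> pd.DataFrame:
    """Total-count normalization: value = raw * scale / column sum."""
    sums = counts.sum(axis=0)
    zero = sums[sums <= 0]
    if len(zero):
        raise ValidationError(f"sample {zero.index[0]!r} has zero total counts")
    return counts * (scale / sums)


def per_mouse_fold_change(
    normalized: pd.DataFrame,
    sheet: SampleSheet,
    mask: pd.DataFrame,
    config: InVivoConfig = InVivoConfig(),
) -> pd.DataFrame:
    """Fold change of every retained (guide, mouse) pair vs the input baseline.

    Returns a long-format DataFrame with columns guide_id, mouse_id,
    fold_change containing only retained pairs.
    """
    inputs = [s for s in sheet.samples_with_role("input") if s in normalized.columns]
    if len(inputs) != 1:
        raise ValidationError(
            f"exactly one input sample required, found {len(inputs)}"
        )
    pc = config.pseudocount
    input_norm = normalized[inputs[0]]
    blocks = []
    for lung in mask.columns:
        retained = mask[lung]
        fc = (normalized.loc[retained, lung] + pc) / (input_norm[retained] + pc)
        blocks.append(
            pd.DataFrame(
                {
                    "guide_id": fc.index,
                    "mouse_id": sheet.mouse_of(lung),
                    "fold_change": fc.to_numpy(),
                }
            )
        )
    if not blocks:
        return pd.DataFrame(columns=["guide_id", "mouse_id", "fold_change"])
    return pd.concat(blocks, ignore_index=True)


def aggregate_across_mice(
    fcs: pd.DataFrame,
    config: InVivoConfig = InVivoConfig(),
    n_mice: int | None = None,
    all_guides: pd.Index | None = None,
) -> tuple[pd.DataFrame, list[str]]:
    """Average per-mouse fold changes into one value per guide.

    Parameters
    ----------
    fcs
        Long-format output of :func:`per_mouse_fold_change`.
    n_mice
        Number of metastatic mice; required when
        ``config.mouse_denominator == "metastatic"``.
    all_guides
        Full guide universe; guides retained in zero mice are reported in
        the dropped list (they never appear in ``fcs``).

    Returns
    -------
    per_guide, dropped
        ``per_guide`` has columns guide_id, avg_fold_change, n_mice_retained;
        ``dropped`` lists guides retained in no mouse.
    """
    grouped = fcs.groupby("guide_id")["fold_change"]
    n_retained = grouped.size()
    if config.averaging == "geometric":
        avg = np.exp(grouped.apply(lambda v: np.log(v).mean()))
    elif config.mouse_denominator == "metastatic":
        if n_mice is None:
            raise ValidationError(
                "n_mice is required with mouse_denominator='metastatic'"
            )
        avg = grouped.sum() / n_mice
    else:
        avg = grouped.mean()
    per_guide = pd.DataFrame(
        {
            "guide_id": avg.index,
            "avg_fold_change": avg.to_numpy(),
            "n_mice_retained": n_retained.reindex(avg.index).to_numpy(),
        }
    ).reset_index(drop=True)
    dropped: list[str] = []
    if all_guides is not None:
        dropped = list(pd.Index(all_guides).difference(per_guide["guide_id"]))
    return per_guide, dropped


def gene_rank(
    per_guide: pd.DataFrame, manifest: LibraryManifest
) -> pd.DataFrame:
    """Best-guide-per-gene ranking, rank 1 = most enriched.

    Ties in average fold change are broken by gene symbol (ascending) so the
    ranking is reproducible; within a gene, tied guides resolve to the
    lexicographically smallest guide_id.
    """
    genes = manifest.genes
    unknown = pd.Index(per_guide["guide_id"]).difference(genes.index)
    if len(unknown):
        raise ValidationError(f"guide {unknown[0]!r} not present in manifest")
    table = per_guide.assign(gene=genes.loc[per_guide["guide_id"]].to_numpy())
    best = (
        table.sort_values(
            ["gene", "avg_fold_change", "guide_id"],
            ascending=[True, False, True],
        )
        .groupby("gene", sort=False)
        .head(1)
    )
    ranking = best.sort_values(
        ["avg_fold_change", "gene"], ascending=[False, True]
    ).reset_index(drop=True)
    ranking["rank"] = np.arange(1, len(ranking) + 1)
    return ranking.rename(columns={"guide_id": "best_guide_id"})[
        ["gene", "best_guide_id", "avg_fold_change", "n_mice_retained", "rank"]
    ]


def rank_genes_invivo(
    counts: pd.DataFrame,
    manifest: LibraryManifest,
    sheet: SampleSheet,
    config: InVivoConfig = InVivoConfig(),
) -> tuple[pd.DataFrame, list[str]]:
    """Full in vivo pipeline: filter, normalize, fold change, average, rank.

    Returns the gene ranking and the list of guides retained in no mouse.
    """
    mask = filter_low_coverage(counts, sheet, config)
    normalized = normalize_total(counts, config.normalization_scale)
    fcs = per_mouse_fold_change(normalized, sheet, mask, config)
    per_guide, dropped = aggregate_across_mice(
        fcs, config, n_mice=mask.shape[1], all_guides=counts.index
    )
    return gene_rank(per_guide, manifest), dropped
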