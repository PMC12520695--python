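"""Sorted-reporter stability screen scoring by alpha robust rank aggregation.

In a fluorescence-ratio stability screen, cells carrying a reporter whose
EGFP/DsRed ratio tracks the stability of a substrate protein are sorted into
ratio-high and ratio-low gates, and each gate's guide library is sequenced.
Guides enriched in the low gate destabilized the reporter substrate,
implicating the targeted gene (e.g. a kinase whose loss destabilizes the
substrate) as a stability regulator.

Scoring has two layers:

* per guide, a signed log2 ratio of the two gates' normalized counts
  (low over high by default, so hits score positive);
* per gene, alpha robust rank aggregation (alpha-RRA): guides are ranked by
  score and their normalized ranks r = rank/n compared against the uniform
  order-statistic distribution. For a gene with g guides whose sorted
  normalized ranks are r_(1) <= ... <= r_(g), the score is

      rho = min over selected k of  P(U_(k) <= r_(k))
          = min_k  I_{r_(k)}(k, g - k + 1)

  where I is the regularized incomplete beta function and "selected" keeps
  only guides with r <= alpha. Genes with no guide in the top alpha fraction
  get rho = 1. Significance comes from a permutation null that redraws each
  gene's guide ranks (without replacement, preserving guide counts) from the
  observed rank pool; p = (1 + #{null rho <= observed}) / (n_permutations + 1),
  followed by Benjamini-Hochberg FDR.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import betainc
from scipy.stats import rankdata

from .invivo import normalize_total
from .io import LibraryManifest, SampleSheet, ValidationError

# cap on floats drawn per chunk while sampling null rank subsets
_CHUNK_BUDGET = 20_000_000


@dataclass(frozen=True)
class SortScreenConfig:
    """Parameters of the sorted-screen scoring.

    pseudocount
        Added to both gates' normalized counts before the log ratio
        (default 0.5, normalized units).
    direction
        "low" (default): enrichment in the ratio-low gate scores positive —
        the hit sense for a screen seeking regulators whose loss destabilizes
        the reporter substrate. "high" flips the sign.
    alpha
        Fraction of top-ranked guides considered by alpha-RRA (default 0.25).
    n_permutations
        Monte-Carlo permutations for the null (default 10,000).
    seed
        Seed for the permutation RNG.
    """

    pseudocount: float = 0.5
    direction: str = "low"
    alpha: float = 0.25
    n_permutations: int = 10_000
    seed: int = 0
    normalization_scale: float = 1e6

    def __post_init__(self) -> None:
        if not (0 < self.alpha <= 1):
            raise ValidationError("alpha must be in (0, 1]")
        if self.n_permutations < 1:
            raise ValidationError("n_permutations must be >= 1")
        if self.direction not in {"low", "high"}:
            raise ValidationError("direction must be 'low' or 'high'")
        if self.pseudocount < 0:
            raise ValidationError("pseudocount must be >= 0")


def score_guides_sorted(
    counts: pd.DataFrame,
    sheet: SampleSheet,
    config: SortScreenConfig = SortScreenConfig(),
) -> pd.Series:
    """Per-guide signed log2 gate ratio on total-count-normalized counts.

    score = log2((low_norm + pc) / (high_norm + pc)), negated when
    ``config.direction == "high"``. Requires exactly one sorted_high and one
    sorted_low sample in the count matrix.
    """
    gates = {}
    for role in ("sorted_high", "sorted_low"):
        ids = [s for s in sheet.samples_with_role(role) if s in counts.columns]
        if len(ids) != 1:
            raise ValidationError(
                f"exactly one {role} sample required, found {len(ids)}"
            )
        gates[role] = ids[0]
    norm = normalize_total(
        counts[[gates["sorted_high"], gates["sorted_low"]]],
        config.normalization_scale,
    )
    pc = config.pseudocount
    score = np.log2(
        (norm[gates["sorted_low"]] + pc) / (norm[gates["sorted_high"]] + pc)
    )
    if config.direction == "high":
        score = -score
    return score.rename("score")


def benjamini_hochberg(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up FDR adjustment.

    q_(i) = min_{j >= i} p_(j) * m / j, clipped at 1, returned in the input
    order. All p-values must lie in (0, 1].
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValidationError("p_values must be a non-empty 1-d sequence")
    if np.any((p <= 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValidationError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    scaled = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum(1.0, np.minimum.accumulate(scaled[::-1])[::-1])
    q = np.empty(m)
    q[order] = q_sorted
    return q


def _rho_from_sorted_ranks(sorted_r: np.ndarray, alpha: float) -> np.ndarray:
    """alpha-RRA rho per row of an (m, g) matrix of ascending normalized ranks."""
    m, g = sorted_r.shape
    k = np.arange(1, g + 1, dtype=float)
    cdf = betainc(k, g - k + 1.0, sorted_r)
    cdf = np.where(sorted_r <= alpha, cdf, np.inf)
    rho = cdf.min(axis=1)
    return np.where(np.isfinite(rho), rho, 1.0)


def _sample_null_rho(
    r: np.ndarray, g: int, alpha: float, n_perm: int, rng: np.random.Generator
) -> np.ndarray:
    """Null rho for genes with g guides: subsets of size g drawn without
    replacement from the observed normalized-rank pool."""
    n = r.size
    if g >= n:
        return np.full(n_perm, _rho_from_sorted_ranks(np.sort(r)[None, :], alpha)[0])
    out = np.empty(n_perm)
    chunk = max(1, _CHUNK_BUDGET // n)
    done = 0
    while done < n_perm:
        m = min(chunk, n_perm - done)
        keys = rng.random((m, n))
        idx = np.argpartition(keys, g - 1, axis=1)[:, :g]
        sampled = np.sort(r[idx], axis=1)
        out[done : done + m] = _rho_from_sorted_ranks(sampled, alpha)
        done += m
    return out


def alpha_rra(
    scores: pd.Series,
    manifest: LibraryManifest,
    config: SortScreenConfig = SortScreenConfig(),
) -> pd.DataFrame:
    """Gene-level alpha-RRA with a permutation null and BH FDR.

    Parameters
    ----------
    scores
        Per-guide scores indexed by guide_id (larger = stronger hit).
    manifest
        Maps guides to genes; every scored guide must be present.
    config
        alpha, permutation count and seed.

    Returns
    -------
    DataFrame with columns gene, rho, p_value, fdr, n_guides,
    n_guides_selected, rank — sorted ascending by rho (rank 1 = strongest),
    ties broken by p then gene symbol. Deterministic given the seed.
    """
    if len(scores) < 2:
        raise ValidationError("alpha_rra needs at least 2 scored guides")
    genes = manifest.genes
    unknown = scores.index.difference(genes.index)
    if len(unknown):
        raise ValidationError(f"guide {unknown[0]!r} not present in manifest")

    # keep manifest order for determinism regardless of input ordering
    ordered = genes.index.intersection(scores.index)
    values = scores.loc[ordered].to_numpy(dtype=float)
    gene_of = genes.loc[ordered].to_numpy()

    n = values.size
    r = rankdata(-values, method="average") / n  # ties get average ranks

    gene_frame = pd.DataFrame({"gene": gene_of, "r": r})
    grouped = gene_frame.groupby("gene", sort=False)["r"]
    gene_names = list(grouped.groups)
    rho_obs = np.empty(len(gene_names))
    n_guides = np.empty(len(gene_names), dtype=int)
    n_selected = np.empty(len(gene_names), dtype=int)
    by_size: dict[int, list[int]] = {}
    for i, (_, rs) in enumerate(grouped):
        sorted_r = np.sort(rs.to_numpy())
        rho_obs[i] = _rho_from_sorted_ranks(sorted_r[None, :], config.alpha)[0]
        n_guides[i] = sorted_r.size
        n_selected[i] = int((sorted_r <= config.alpha).sum())
        by_size.setdefault(sorted_r.size, []).append(i)

    rng = np.random.default_rng(config.seed)
    p = np.empty(len(gene_names))
    n_perm = config.n_permutations
    for g in sorted(by_size):
        null = np.sort(_sample_null_rho(r, g, config.alpha, n_perm, rng))
        idx = by_size[g]
        hits = np.searchsorted(null, rho_obs[idx], side="right")
        p[idx] = (1.0 + hits) / (n_perm + 1.0)

    result = pd.DataFrame(
        {
            "gene": gene_names,
            "rho": rho_obs,
            "p_value": p,
            "fdr": benjamini_hochberg(p),
            "n_guides": n_guides,
            "n_guides_selected": n_selected,
        }
    )
    result = result.sort_values(
        ["rho", "p_value", "gene"], ascending=[True, True, True]
    ).reset_index(drop=True)
    result["rank"] = np.arange(1, len(result) + 1)
    return result[
        ["gene", "rho", "p_value", "fdr", "n_guides", "n_guides_selected", "rank"]
    ]


def run_sort_screen(
    counts: pd.DataFrame,
    manifest: LibraryManifest,
    sheet: SampleSheet,
    config: SortScreenConfig = SortScreenConfig(),
) -> pd.DataFrame:
    """Score guides from gate counts and aggregate to gene level."""
    scores = score_guides_sorted(counts, sheet, config)
    return alpha_rra(scores, manifest, config)
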