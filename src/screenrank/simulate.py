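"""Seeded synthetic data emulating the statistical structure of the screens.

Three generators stand in for real sequencing data:

* a synthetic guide library (3 guides/gene, distinct random 20-mers);
* an in vivo metastasis screen — an overdispersed input baseline sampled at
  a fixed cells-per-guide coverage, then per-mouse lungs founded by a small
  number of clones drawn with gene-specific seeding weights (the clonal
  bottleneck) and expanded with log-normal growth noise;
* a fluorescence-ratio sorting screen — one guide per cell, a Gaussian
  reporter log-ratio shifted by gene-specific stability effects, top/bottom
  quantile gates, and multinomial read sampling per gate.

Every generator is a pure function of its config (including the seed):
re-runs are identical, and each simulated sample's read total equals its
configured depth exactly.
"""

from __future__ import annotations

import gzip
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .io import LibraryManifest, SampleSheet, ValidationError

_BASES = np.array(list("ACGT"))

# standard human U6 vector tail immediately upstream of the protospacer
DEFAULT_CONSTANT_PREFIX = "TTGTGGAAAGGACGAAACACCG"


@dataclass(frozen=True)
class SimLibraryConfig:
    """Genome-wide CRISPRa library geometry: 23,430 genes x 3 guides."""

    n_genes: int = 23_430
    guides_per_gene: int = 3
    seed: int = 0


@dataclass(frozen=True)
class InVivoSimConfig:
    """In vivo screen generator.

    input_coverage_cells_per_guide
        Cells per guide in the transduced pool (default 500, i.e. 3.6e7
        cells for the full 70,290-guide library).
    abundance_dispersion
        Log-normal sigma of per-guide library skew (default 0.5).
    n_mice / metastasis_penetrance
        18 transplanted mice, each metastatic with probability 0.5
        (emulating lung metastasis in 9 of 18 mice).
    clones_per_mouse
        Founding clones seeding each metastatic lung (default 200);
        ``None`` disables the bottleneck and resamples lungs directly from
        the input cell distribution.
    driver_genes
        gene symbol -> seeding weight (> 1 enriches that gene's guides at
        lung seeding).
    expansion_noise_sigma
        Log-normal sigma of per-clone growth noise (default 0.5).
    input_depth_reads / lung_depth_reads
        Sequencing depths; ``None`` means 500 reads per guide.
    """

    input_coverage_cells_per_guide: int = 500
    input_depth_reads: int | None = None
    abundance_dispersion: float = 0.5
    n_mice: int = 18
    metastasis_penetrance: float = 0.5
    clones_per_mouse: int | None = 200
    driver_genes: Mapping[str, float] = field(default_factory=dict)
    expansion_noise_sigma: float = 0.5
    lung_depth_reads: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.metastasis_penetrance <= 1):
            raise ValidationError("metastasis_penetrance must be in [0, 1]")
        if self.clones_per_mouse is not None and self.clones_per_mouse < 1:
            raise ValidationError("clones_per_mouse must be >= 1 (or None)")
        if any(w <= 0 for w in self.driver_genes.values()):
            raise ValidationError("driver weights must be > 0")


@dataclass(frozen=True)
class SortSimConfig:
    """Sorting-screen generator.

    n_cells
        Reporter-expressing cells run through the sorter (default 2e7;
        desk-scale scenarios use 1e5).
    gate_fraction_high / gate_fraction_low
        Top and bottom quantile fractions sorted (default 5% each).
    baseline_log_ratio_sigma
        Cell-to-cell sd of the reporter log-ratio (default 1.0).
    effect_genes
        gene symbol -> shift of the log-ratio for cells carrying that
        gene's guides; negative = destabilized reporter (low gate).
    reads_per_gate
        Sequencing depth per gate; ``None`` means 500 reads per guide.
    """

    n_cells: int = 20_000_000
    gate_fraction_high: float = 0.05
    gate_fraction_low: float = 0.05
    baseline_log_ratio_sigma: float = 1.0
    effect_genes: Mapping[str, float] = field(default_factory=dict)
    reads_per_gate: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        for f in (self.gate_fraction_high, self.gate_fraction_low):
            if not (0 < f <= 0.5):
                raise ValidationError("gate fractions must lie in (0, 0.5]")
        if self.n_cells < 1:
            raise ValidationError("n_cells must be >= 1")


def generate_library(config: SimLibraryConfig = SimLibraryConfig()) -> LibraryManifest:
    """Synthetic library: GENE000001... symbols, distinct random 20-mers."""
    n = config.n_genes * config.guides_per_gene
    space = 4**20
    if n > space // 4:
        raise ValidationError("protospacer space exhausted for requested library size")
    rng = np.random.default_rng(config.seed)
    codes = np.unique(rng.integers(0, space, size=n, dtype=np.int64))
    attempts = 0
    while codes.size < n:
        attempts += 1
        if attempts > 100:
            raise ValidationError("failed to draw distinct protospacers")
        extra = rng.integers(0, space, size=n - codes.size, dtype=np.int64)
        codes = np.unique(np.concatenate([codes, extra]))
    codes = rng.permutation(codes)[:n]

    digits = np.empty((n, 20), dtype=np.int64)
    rem = codes.copy()
    for pos in range(19, -1, -1):
        digits[:, pos] = rem % 4
        rem //= 4
    protospacers = ["".join(row) for row in _BASES[digits]]

    genes = [f"GENE{i + 1:06d}" for i in range(config.n_genes)]
    frame = pd.DataFrame(
        {
            "guide_id": [
                f"{genes[i // config.guides_per_gene]}_sg{i % config.guides_per_gene + 1}"
                for i in range(n)
            ],
            "gene": np.repeat(genes, config.guides_per_gene),
            "protospacer": protospacers,
        }
    )
    return LibraryManifest.from_frame(frame)


def _default_depth(depth: int | None, n_guides: int) -> int:
    return int(depth) if depth is not None else 500 * n_guides


def _guide_weights(manifest: LibraryManifest, gene_weights: Mapping[str, float]) -> np.ndarray:
    w = np.ones(len(manifest))
    if gene_weights:
        weights = {g.upper(): float(v) for g, v in gene_weights.items()}
        unknown = set(weights) - set(manifest.gene_names)
        if unknown:
            raise ValidationError(f"effect gene(s) not in manifest: {sorted(unknown)}")
        w = (
            manifest.frame["gene"].map(lambda g: weights.get(g, 1.0)).to_numpy()
        )
    return w


def simulate_input_counts(
    manifest: LibraryManifest,
    config: InVivoSimConfig = InVivoSimConfig(),
    rng: np.random.Generator | None = None,
) -> tuple[pd.Series, pd.Series]:
    """Input baseline: cell pool at fixed coverage, then sequencing reads.

    Per-guide abundance weights are log-normal(0, abundance_dispersion);
    integer cell counts are a multinomial draw of
    ``coverage x n_guides`` cells over those weights, and reads a multinomial
    draw of the input depth over the cell counts.

    Returns (read counts, cell counts), both indexed by guide_id.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    n = len(manifest)
    if config.abundance_dispersion > 0:
        weights = rng.lognormal(0.0, config.abundance_dispersion, n)
    else:
        weights = np.ones(n)
    n_cells = config.input_coverage_cells_per_guide * n
    cells = rng.multinomial(n_cells, weights / weights.sum())
    depth = _default_depth(config.input_depth_reads, n)
    reads = rng.multinomial(depth, cells / cells.sum())
    idx = manifest.guide_ids
    return (
        pd.Series(reads, index=idx, name="input"),
        pd.Series(cells, index=idx, name="input_cells"),
    )


def simulate_lung_metastasis(
    input_cells: pd.Series,
    manifest: LibraryManifest,
    config: InVivoSimConfig = InVivoSimConfig(),
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, SampleSheet]:
    """Per-mouse bottlenecked lung counts.

    Each of ``n_mice`` mice is metastatic with probability
    ``metastasis_penetrance``. A metastatic lung is founded by
    ``clones_per_mouse`` cells drawn with probability proportional to
    input cell abundance times the guide's gene seeding weight; each clone's
    final size is multiplied by log-normal growth noise, and reads are a
    multinomial draw at the lung depth over the clone-size mixture.

    Returns lung count columns (one per metastatic mouse) and a sample
    sheet of the lung samples.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    cells = input_cells.to_numpy(dtype=float)
    if cells.sum() <= 0:
        raise ValidationError("input cell abundances must have positive sum")
    n = len(manifest)
    w = cells * _guide_weights(manifest, config.driver_genes)
    p = w / w.sum()
    depth = _default_depth(config.lung_depth_reads, n)
    sigma = config.expansion_noise_sigma

    metastatic = rng.random(config.n_mice) < config.metastasis_penetrance
    columns: dict[str, np.ndarray] = {}
    rows = []
    for i in range(config.n_mice):
        if not metastatic[i]:
            continue
        mouse = f"mouse{i + 1:02d}"
        if config.clones_per_mouse is None:
            mass = w * (rng.lognormal(0.0, sigma, n) if sigma > 0 else 1.0)
        else:
            founders = rng.choice(n, size=config.clones_per_mouse, p=p)
            sizes = (
                rng.lognormal(0.0, sigma, config.clones_per_mouse)
                if sigma > 0
                else np.ones(config.clones_per_mouse)
            )
            mass = np.bincount(founders, weights=sizes, minlength=n)
        columns[f"lung_{mouse}"] = rng.multinomial(depth, mass / mass.sum())
        rows.append({"sample_id": f"lung_{mouse}", "role": "lung", "mouse_id": mouse})

    if not columns:
        warnings.warn(
            "no metastatic mice drawn; returning empty lung set", stacklevel=2
        )
        empty = pd.DataFrame(index=manifest.guide_ids)
        empty.index.name = "guide_id"
        return empty, SampleSheet.from_frame(
            pd.DataFrame(columns=["sample_id", "role", "mouse_id"])
        )
    frame = pd.DataFrame(columns, index=manifest.guide_ids)
    frame.index.name = "guide_id"
    return frame, SampleSheet.from_frame(pd.DataFrame(rows))


def simulate_invivo_screen(
    manifest: LibraryManifest, config: InVivoSimConfig = InVivoSimConfig()
) -> tuple[pd.DataFrame, SampleSheet]:
    """Input baseline plus per-mouse lungs, with a complete sample sheet."""
    ss = np.random.SeedSequence(config.seed)
    rng_input, rng_lung = (np.random.default_rng(c) for c in ss.spawn(2))
    reads, cells = simulate_input_counts(manifest, config, rng_input)
    lungs, lung_sheet = simulate_lung_metastasis(cells, manifest, config, rng_lung)
    counts = pd.concat([reads.to_frame(), lungs], axis=1)
    counts.index.name = "guide_id"
    sheet_frame = pd.concat(
        [
            pd.DataFrame([{"sample_id": "input", "role": "input", "mouse_id": pd.NA}]),
            lung_sheet.frame,
        ],
        ignore_index=True,
    )
    return counts, SampleSheet.from_frame(sheet_frame)


def simulate_sorted_gates(
    manifest: LibraryManifest,
    config: SortSimConfig = SortSimConfig(),
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, SampleSheet]:
    """Two-gate fluorescence-ratio sort.

    Each cell carries one guide (uniform over the library); its reporter
    log-ratio is Normal(effect(gene), baseline sigma). The top
    ``gate_fraction_high`` and bottom ``gate_fraction_low`` quantiles are
    sorted and sequenced at ``reads_per_gate`` each.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    n_guides = len(manifest)
    n_cells = int(config.n_cells)
    k_high = int(np.floor(config.gate_fraction_high * n_cells))
    k_low = int(np.floor(config.gate_fraction_low * n_cells))
    if k_high < 1 or k_low < 1:
        raise ValidationError("gate fraction x n_cells yields an empty gate")

    shift = np.zeros(n_guides)
    if config.effect_genes:
        effects = {g.upper(): float(v) for g, v in config.effect_genes.items()}
        unknown = set(effects) - set(manifest.gene_names)
        if unknown:
            raise ValidationError(f"effect gene(s) not in manifest: {sorted(unknown)}")
        shift = manifest.frame["gene"].map(lambda g: effects.get(g, 0.0)).to_numpy()

    guide_of_cell = rng.integers(0, n_guides, n_cells)
    log_ratio = shift[guide_of_cell] + rng.normal(
        0.0, config.baseline_log_ratio_sigma, n_cells
    )
    order = np.argsort(log_ratio)
    low_cells = guide_of_cell[order[:k_low]]
    high_cells = guide_of_cell[order[-k_high:]]

    depth = _default_depth(config.reads_per_gate, n_guides)
    columns = {}
    for name, members in (("sorted_high", high_cells), ("sorted_low", low_cells)):
        gate_counts = np.bincount(members, minlength=n_guides)
        columns[name] = rng.multinomial(depth, gate_counts / gate_counts.sum())
    frame = pd.DataFrame(columns, index=manifest.guide_ids)
    frame.index.name = "guide_id"
    frame.attrs["gate_cells"] = {"sorted_high": k_high, "sorted_low": k_low}
    sheet = SampleSheet.from_frame(
        pd.DataFrame(
            {
                "sample_id": ["sorted_high", "sorted_low"],
                "role": ["sorted_high", "sorted_low"],
            }
        )
    )
    return frame, sheet


def emit_fastq(
    counts: pd.DataFrame,
    manifest: LibraryManifest,
    out_dir: str | Path,
    constant_prefix: str = DEFAULT_CONSTANT_PREFIX,
    seed: int = 0,
    gzip_output: bool = False,
) -> dict[str, Path]:
    """Write per-sample FASTQ with exactly ``count`` copies of each guide read.

    Reads are ``constant_prefix + protospacer`` in seeded shuffled order with
    constant quality; quantifying the output with a matching prefix length
    recovers the count matrix exactly. Returns sample -> path.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    protos = manifest.frame["protospacer"].to_numpy()
    if (counts.index != manifest.guide_ids).any():
        counts = counts.reindex(manifest.guide_ids, fill_value=0)
    rng = np.random.default_rng(seed)
    paths: dict[str, Path] = {}
    suffix = ".fastq.gz" if gzip_output else ".fastq"
    for sample in counts.columns:
        col = counts[sample].to_numpy(dtype=np.int64)
        if (col < 0).any():
            raise ValidationError("counts must be non-negative")
        reads = rng.permutation(np.repeat(np.arange(len(protos)), col))
        path = out_dir / f"{sample}{suffix}"
        opener = gzip.open if gzip_output else open
        with opener(path, "wt") as handle:
            for i, row in enumerate(reads):
                seq = constant_prefix + protos[row]
                handle.write(
                    f"@{sample}_read{i + 1}\n{seq}\n+\n{'I' * len(seq)}\n"
                )
        paths[sample] = path
    return paths


# ---------------------------------------------------------------------------
# Desk-scale scenario factories


def scaled_invivo_scenario(
    seed: int = 0,
) -> tuple[SimLibraryConfig, InVivoSimConfig]:
    """Desk-scale in vivo screen: 500 genes x 3 guides, 8 metastatic mice,
    200 founding clones per lung, 5 driver genes at seeding weight 20,
    1e6 reads per sample."""
    lib = SimLibraryConfig(n_genes=500, guides_per_gene=3, seed=seed)
    drivers = {f"GENE{i:06d}": 20.0 for i in (50, 150, 250, 350, 450)}
    cfg = InVivoSimConfig(
        n_mice=8,
        metastasis_penetrance=1.0,
        clones_per_mouse=200,
        driver_genes=drivers,
        input_depth_reads=1_000_000,
        lung_depth_reads=1_000_000,
        seed=seed,
    )
    return lib, cfg


def null_invivo_scenario(
    seed: int = 0,
) -> tuple[SimLibraryConfig, InVivoSimConfig]:
    """No-enrichment control: lungs resampled from the input distribution
    (no bottleneck, no drivers, no growth noise) at 200 reads/guide."""
    lib = SimLibraryConfig(n_genes=500, guides_per_gene=3, seed=seed)
    depth = 200 * lib.n_genes * lib.guides_per_gene
    cfg = InVivoSimConfig(
        n_mice=8,
        metastasis_penetrance=1.0,
        clones_per_mouse=None,
        expansion_noise_sigma=0.0,
        input_depth_reads=depth,
        lung_depth_reads=depth,
        seed=seed,
    )
    return lib, cfg


def scaled_sort_scenario(
    seed: int = 0,
) -> tuple[SimLibraryConfig, SortSimConfig]:
    """Desk-scale sorting screen: 500 genes x 3 guides, 1e5 cells, 5%/5%
    gates, 5 destabilizer-effect genes at -2 sigma."""
    lib = SimLibraryConfig(n_genes=500, guides_per_gene=3, seed=seed)
    effects = {f"GENE{i:06d}": -2.0 for i in (60, 160, 260, 360, 460)}
    cfg = SortSimConfig(
        n_cells=100_000,
        effect_genes=effects,
        reads_per_gate=500_000,
        seed=seed,
    )
    return lib, cfg


def scale_config(config, **overrides):
    """Return a copy of a frozen sim config with fields replaced."""
    return replace(config, **overrides)
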