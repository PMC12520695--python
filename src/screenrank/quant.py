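"""Guide quantification from amplicon reads.

Each sequencing read carries a constant vector portion followed by the
20-nt protospacer. The constant portion is removed — either a fixed-length
prefix or everything up to and including an anchor sequence — and the
candidate 20-mer is matched exactly against the library. No mismatches,
no reverse-complement search, no quality filtering: counting is meant to be
conservative and fully deterministic.
"""

from __future__ import annotations

import gzip
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from .io import LibraryManifest, ValidationError


@dataclass(frozen=True)
class QuantConfig:
    """How to locate the protospacer within a read.

    Exactly one of ``constant_prefix_length`` (fixed-offset mode) or
    ``anchor_sequence`` (scan for the anchor, take the following 20 bases)
    must be set.
    """

    constant_prefix_length: int | None = None
    anchor_sequence: str | None = None
    protospacer_length: int = 20

    def __post_init__(self) -> None:
        if (self.constant_prefix_length is None) == (self.anchor_sequence is None):
            raise ValidationError(
                "exactly one of constant_prefix_length or anchor_sequence must be set"
            )
        if self.constant_prefix_length is not None and self.constant_prefix_length < 0:
            raise ValidationError("constant_prefix_length must be >= 0")
        if self.anchor_sequence is not None and not self.anchor_sequence:
            raise ValidationError("anchor_sequence must be non-empty")
        if self.protospacer_length < 1:
            raise ValidationError("protospacer_length must be positive")


@dataclass
class SampleQuant:
    total_reads: int = 0
    matched_reads: int = 0

    @property
    def unmatched_reads(self) -> int:
        return self.total_reads - self.matched_reads

    @property
    def mapping_rate(self) -> float:
        return self.matched_reads / self.total_reads if self.total_reads else 0.0


@dataclass
class QuantReport:
    """Per-sample read accounting: matched + unmatched = total."""

    per_sample: dict[str, SampleQuant] = field(default_factory=dict)

    @property
    def total_reads(self) -> int:
        return sum(s.total_reads for s in self.per_sample.values())

    @property
    def matched_reads(self) -> int:
        return sum(s.matched_reads for s in self.per_sample.values())

    @property
    def unmatched_reads(self) -> int:
        return self.total_reads - self.matched_reads

    def to_dict(self) -> dict:
        return {
            "total_reads": self.total_reads,
            "matched_reads": self.matched_reads,
            "unmatched_reads": self.unmatched_reads,
            "per_sample": {
                name: {
                    "total_reads": s.total_reads,
                    "matched_reads": s.matched_reads,
                    "unmatched_reads": s.unmatched_reads,
                    "mapping_rate": s.mapping_rate,
                }
                for name, s in self.per_sample.items()
            },
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")


def extract_protospacer(read_sequence: str, config: QuantConfig) -> str | None:
    """Return the 20-base protospacer candidate, or None if unextractable."""
    seq = read_sequence.upper()
    k = config.protospacer_length
    if config.constant_prefix_length is not None:
        start = config.constant_prefix_length
    else:
        hit = seq.find(config.anchor_sequence.upper())
        if hit < 0:
            return None
        start = hit + len(config.anchor_sequence)
    if len(seq) < start + k:
        return None
    return seq[start : start + k]


def _iter_fastq(path: str | Path):
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as handle:
        parser = SeqIO.parse(handle, "fastq")
        index = 0
        while True:
            try:
                record = next(parser)
            except StopIteration:
                return
            except ValueError as err:
                raise ValidationError(
                    f"{path}: malformed FASTQ at record {index + 1}: {err}"
                ) from err
            index += 1
            yield str(record.seq)


def count_guides(
    fastq_by_sample: Mapping[str, str | Path | Sequence[str | Path]],
    manifest: LibraryManifest,
    config: QuantConfig,
) -> tuple[pd.DataFrame, QuantReport]:
    """Count exact protospacer matches per sample.

    Parameters
    ----------
    fastq_by_sample
        Mapping sample_id -> FASTQ path (or sequence of paths to pool).
    manifest
        Library whose protospacers define the match targets; protospacers
        must be unique.
    config
        Protospacer extraction settings.

    Returns
    -------
    counts, report
        ``counts`` is an int64 guide-by-sample DataFrame in manifest order;
        ``report`` carries total/matched/unmatched read tallies per sample.
    """
    proto_to_row = {
        proto: row for row, proto in enumerate(manifest.frame["protospacer"])
    }
    if len(proto_to_row) != len(manifest):
        manifest.protospacer_index()  # raises naming the duplicate

    counts = np.zeros((len(manifest), len(fastq_by_sample)), dtype=np.int64)
    report = QuantReport()
    for col, (sample, paths) in enumerate(fastq_by_sample.items()):
        if isinstance(paths, (str, Path)):
            paths = [paths]
        tally = SampleQuant()
        for path in paths:
            for seq in _iter_fastq(path):
                tally.total_reads += 1
                proto = extract_protospacer(seq, config)
                row = proto_to_row.get(proto) if proto is not None else None
                if row is not None:
                    counts[row, col] += 1
                    tally.matched_reads += 1
        report.per_sample[sample] = tally

    frame = pd.DataFrame(
        counts, index=manifest.guide_ids, columns=list(fastq_by_sample)
    )
    frame.index.name = "guide_id"
    return frame, report
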