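"""Quantify guides from amplicon FASTQ by exact protospacer matching.

Emits FASTQ from a known count matrix (constant vector prefix + 20-nt
protospacer per read), then counts it back: the recovered matrix must equal
the original exactly, read for read.
"""

import tempfile
from pathlib import Path

import numpy as np
import pandas as pd

import screenrank as sr
from screenrank.simulate import DEFAULT_CONSTANT_PREFIX

manifest = sr.generate_library(sr.SimLibraryConfig(n_genes=10, guides_per_gene=3, seed=4))
rng = np.random.default_rng(4)
counts = pd.DataFrame(
    {"gate_low": rng.integers(0, 100, len(manifest))}, index=manifest.guide_ids
)
counts.index.name = "guide_id"

with tempfile.TemporaryDirectory() as tmp:
    paths = sr.emit_fastq(counts, manifest, Path(tmp), seed=4)
    config = sr.QuantConfig(constant_prefix_length=len(DEFAULT_CONSTANT_PREFIX))
    recovered, report = sr.count_guides(paths, manifest, config)

print(f"reads emitted: {counts['gate_low'].sum()}")
tally = report.per_sample["gate_low"]
print(f"matched {tally.matched_reads}/{tally.total_reads} "
      f"(mapping rate {tally.mapping_rate:.3f})")
print(f"matrix recovered exactly: {recovered.equals(counts)}")
# Matching is exact and orientation-sensitive: any single-base change in a
# read's protospacer sends it to the unmatched tally instead.
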