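"""Readers, writers and validation for screen tables.

All stages of the pipeline key on three tables: a library manifest
(guide -> gene -> 20-nt protospacer), a sample sheet assigning sequencing
samples to roles, and a guide-by-sample integer count matrix. Tables are
tab-separated UTF-8 text with ``#`` comment lines; pass ``sep=","`` for CSV.
Gene and protein symbols are upper-cased at the I/O boundary so that screen
genes and interactome proteins intersect reliably.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
import pandas as pd

SAMPLE_ROLES = frozenset({"input", "lung", "sorted_high", "sorted_low"})
PROTOSPACER_LENGTH = 20
_DNA = frozenset("ACGT")


class ValidationError(ValueError):
    """An input table violates a screen-data invariant."""


@dataclass(frozen=True)
class GuideRecord:
    guide_id: str
    gene: str
    protospacer: str


@dataclass(frozen=True)
class LibraryManifest:
    """Ordered catalog of sgRNAs: guide id, target gene, 20-nt protospacer.

    Row order is the library design order and is preserved through every
    read/write; all count matrices are aligned to it.
    """

    frame: pd.DataFrame  # columns: guide_id, gene, protospacer

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "LibraryManifest":
        frame = frame.loc[:, ["guide_id", "gene", "protospacer"]].copy()
        for col in frame.columns:
            frame[col] = frame[col].astype(str).str.strip()
        frame["gene"] = frame["gene"].str.upper()
        frame["protospacer"] = frame["protospacer"].str.upper()

        dup = frame["guide_id"][frame["guide_id"].duplicated()]
        if len(dup):
            raise ValidationError(f"duplicate guide_id: {dup.iloc[0]!r}")
        for row, (length_ok, alpha_ok) in enumerate(
            zip(
                frame["protospacer"].str.len() == PROTOSPACER_LENGTH,
                frame["protospacer"].map(lambda s: set(s) <= _DNA),
            ),
            start=1,
        ):
            if not length_ok:
                raise ValidationError(
                    f"row {row}: protospacer is not {PROTOSPACER_LENGTH} nt"
                )
            if not alpha_ok:
                raise ValidationError(
                    f"row {row}: protospacer contains characters outside A/C/G/T"
                )
        if frame.empty:
            raise ValidationError("library manifest is empty")
        frame = frame.reset_index(drop=True)
        return cls(frame)

    def __len__(self) -> int:
        return len(self.frame)

    def __iter__(self) -> Iterator[GuideRecord]:
        for row in self.frame.itertuples(index=False):
            yield GuideRecord(row.guide_id, row.gene, row.protospacer)

    @property
    def guide_ids(self) -> pd.Index:
        return pd.Index(self.frame["guide_id"])

    @property
    def genes(self) -> pd.Series:
        """Gene symbol per guide, indexed by guide_id, in design order."""
        return pd.Series(
            self.frame["gene"].to_numpy(), index=self.guide_ids, name="gene"
        )

    @property
    def gene_names(self) -> list[str]:
        return list(dict.fromkeys(self.frame["gene"]))

    @property
    def n_genes(self) -> int:
        return self.frame["gene"].nunique()

    def protospacer_index(self) -> dict[str, str]:
        """protospacer -> guide_id; raises if protospacers are not unique."""
        if self.frame["protospacer"].duplicated().any():
            dup = self.frame["protospacer"][self.frame["protospacer"].duplicated()]
            raise ValidationError(f"duplicate protospacer: {dup.iloc[0]!r}")
        return dict(zip(self.frame["protospacer"], self.frame["guide_id"]))


@dataclass(frozen=True)
class SampleSheet:
    """Sample-to-role assignment (input baseline, per-mouse lung, sort gates)."""

    frame: pd.DataFrame  # columns: sample_id, role, mouse_id (NA outside lung)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "SampleSheet":
        frame = frame.copy()
        if "mouse_id" not in frame.columns:
            frame["mouse_id"] = pd.NA
        frame = frame.loc[:, ["sample_id", "role", "mouse_id"]]
        frame["sample_id"] = frame["sample_id"].astype(str).str.strip()
        frame["role"] = frame["role"].astype(str).str.strip()
        frame["mouse_id"] = frame["mouse_id"].map(
            lambda v: pd.NA if pd.isna(v) or str(v).strip() == "" else str(v).strip()
        )

        dup = frame["sample_id"][frame["sample_id"].duplicated()]
        if len(dup):
            raise ValidationError(f"duplicate sample_id: {dup.iloc[0]!r}")
        bad = set(frame["role"]) - SAMPLE_ROLES
        if bad:
            raise ValidationError(
                f"unknown sample role(s) {sorted(bad)}; expected one of {sorted(SAMPLE_ROLES)}"
            )
        lung = frame[frame["role"] == "lung"]
        if lung["mouse_id"].isna().any():
            missing = lung.loc[lung["mouse_id"].isna(), "sample_id"].iloc[0]
            raise ValidationError(f"lung sample {missing!r} has no mouse_id")
        if lung["mouse_id"].duplicated().any():
            dup = lung["mouse_id"][lung["mouse_id"].duplicated()].iloc[0]
            raise ValidationError(f"mouse_id {dup!r} assigned to more than one lung sample")
        nonlung = frame[frame["role"] != "lung"]
        if nonlung["mouse_id"].notna().any():
            bad_id = nonlung.loc[nonlung["mouse_id"].notna(), "sample_id"].iloc[0]
            raise ValidationError(
                f"sample {bad_id!r} has a mouse_id but is not a lung sample"
            )
        return cls(frame.reset_index(drop=True))

    @property
    def sample_ids(self) -> pd.Index:
        return pd.Index(self.frame["sample_id"])

    def samples_with_role(self, role: str) -> list[str]:
        return list(self.frame.loc[self.frame["role"] == role, "sample_id"])

    def mouse_of(self, sample_id: str) -> str:
        row = self.frame[self.frame["sample_id"] == sample_id]
        if row.empty or row["role"].iloc[0] != "lung":
            raise ValidationError(f"{sample_id!r} is not a lung sample")
        return row["mouse_id"].iloc[0]


def _read_table(path: str | Path, sep: str) -> pd.DataFrame:
    return pd.read_csv(path, sep=sep, comment="#", dtype=str)


def read_library_manifest(path: str | Path, sep: str = "\t") -> LibraryManifest:
    """Read a library manifest TSV (columns guide_id, gene, protospacer)."""
    frame = _read_table(path, sep)
    required = {"guide_id", "gene", "protospacer"}
    missing = required - set(frame.columns)
    if missing:
        raise ValidationError(f"{path}: missing manifest column(s) {sorted(missing)}")
    return LibraryManifest.from_frame(frame)


def write_library_manifest(
    manifest: LibraryManifest, path: str | Path, sep: str = "\t"
) -> None:
    manifest.frame.to_csv(path, sep=sep, index=False)


def read_sample_sheet(path: str | Path, sep: str = "\t") -> SampleSheet:
    frame = _read_table(path, sep)
    missing = {"sample_id", "role"} - set(frame.columns)
    if missing:
        raise ValidationError(f"{path}: missing sample-sheet column(s) {sorted(missing)}")
    return SampleSheet.from_frame(frame)


def write_sample_sheet(sheet: SampleSheet, path: str | Path, sep: str = "\t") -> None:
    sheet.frame.to_csv(path, sep=sep, index=False)


def read_count_table(
    path: str | Path,
    manifest: LibraryManifest,
    sheet: SampleSheet | None = None,
    sep: str = "\t",
) -> pd.DataFrame:
    """Read a guide-by-sample count table aligned to the manifest.

    The first column must be ``guide_id``. Guides present in the manifest but
    absent from the file are filled with zero (with a warning); guides absent
    from the manifest are a hard error, surfacing library/count mismatches.
    Returns an int64 DataFrame indexed by guide_id in manifest order.
    """
    frame = _read_table(path, sep)
    if frame.columns[0] != "guide_id":
        raise ValidationError(f"{path}: first column must be guide_id")
    frame = frame.set_index("guide_id")
    if frame.index.duplicated().any():
        dup = frame.index[frame.index.duplicated()][0]
        raise ValidationError(f"{path}: duplicate guide_id {dup!r}")

    unknown = frame.index.difference(manifest.guide_ids)
    if len(unknown):
        raise ValidationError(
            f"{path}: {len(unknown)} guide(s) not in manifest, e.g. {list(unknown[:3])}"
        )
    if sheet is not None:
        extra = frame.columns.difference(sheet.sample_ids)
        if len(extra):
            raise ValidationError(
                f"{path}: sample column(s) not in sample sheet: {list(extra)}"
            )

    numeric = pd.DataFrame(index=frame.index)
    for col in frame.columns:
        vals = pd.to_numeric(frame[col], errors="coerce")
        if vals.isna().any():
            guide = frame.index[vals.isna()][0]
            raise ValidationError(
                f"{path}: non-numeric count at guide {guide!r}, sample {col!r}"
            )
        if (vals < 0).any():
            guide = frame.index[vals < 0][0]
            raise ValidationError(
                f"{path}: negative count at guide {guide!r}, sample {col!r}"
            )
        if (vals % 1 != 0).any():
            guide = frame.index[vals % 1 != 0][0]
            raise ValidationError(
                f"{path}: non-integer count at guide {guide!r}, sample {col!r}"
            )
        numeric[col] = vals.astype(np.int64)

    n_missing = len(manifest.guide_ids.difference(numeric.index))
    if n_missing:
        warnings.warn(
            f"{path}: {n_missing} manifest guide(s) absent from count table; "
            "filled with zero counts",
            stacklevel=2,
        )
    out = numeric.reindex(manifest.guide_ids, fill_value=0)
    out.index.name = "guide_id"
    return out


def write_count_table(counts: pd.DataFrame, path: str | Path, sep: str = "\t") -> None:
    out = counts.copy()
    out.index.name = "guide_id"
    out.to_csv(path, sep=sep)


def read_protein_list(path: str | Path) -> set[str]:
    """Read a plain-text symbol list (one per line) into an uppercase set.

    Blank lines and ``#`` comments are ignored; an empty result is an error.
    """
    names: set[str] = set()
    with open(path, encoding="utf-8") as handle:
        for line in handle:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            names.add(line.upper())
    if not names:
        raise ValidationError(f"{path}: protein list is empty after filtering")
    return names


def write_protein_list(names: Iterable[str], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as handle:
        for name in sorted({str(n).upper() for n in names}):
            handle.write(name + "\n")
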