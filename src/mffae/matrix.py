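"""Sample x protein abundance matrices and their tab-separated on-disk form.

The wide TSV dialect is the one produced by MaxQuant-style exports: a header
row, a leading ID column, tab separation, numeric cells with empty/NA tokens
for missing values. In label-free quantification a stored 0 conventionally
means "not detected", so zeros are treated as missing by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = ["AbundanceMatrix", "read_abundance_tsv", "write_abundance_tsv"]

_NA_TOKENS = {"", "na", "nan", "n/a", "null"}


@dataclass
class AbundanceMatrix:
    """A samples x proteins abundance matrix with an explicit missingness mask.

    Parameters
    ----------
    sample_ids : sequence of str
        Unique sample identifiers, one per row.
    protein_ids : sequence of str
        Unique protein identifiers, one per column.
    values : ndarray of shape (n_samples, n_proteins)
        Abundances (arbitrary intensity units). Cells flagged missing hold NaN.
    missing_mask : ndarray of bool, same shape
        True where the measurement is absent.
    """

    sample_ids: list[str]
    protein_ids: list[str]
    values: np.ndarray
    missing_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.protein_ids = [str(p) for p in self.protein_ids]
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D samples x proteins array")
        if self.missing_mask is None:
            self.missing_mask = np.isnan(self.values)
        self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
        if self.values.shape != (len(self.sample_ids), len(self.protein_ids)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.protein_ids)} proteins"
            )
        if self.missing_mask.shape != self.values.shape:
            raise ValueError("missing_mask shape must match values shape")
        for name, ids in (("sample", self.sample_ids), ("protein", self.protein_ids)):
            dupes = _duplicates(ids)
            if dupes:
                raise ValueError(f"duplicate {name} IDs: {sorted(dupes)}")
        # Missing slots carry the NaN sentinel so no statistic can use them.
        self.values = self.values.copy()
        self.values[self.missing_mask] = np.nan

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_proteins(self) -> int:
        return len(self.protein_ids)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def observed_values(self) -> np.ndarray:
        """All non-missing cells as a flat array."""
        return self.values[~self.missing_mask]

    def copy(self) -> "AbundanceMatrix":
        return AbundanceMatrix(
            list(self.sample_ids),
            list(self.protein_ids),
            self.values.copy(),
            self.missing_mask.copy(),
        )

    def to_frame(self) -> pd.DataFrame:
        """Samples-as-rows DataFrame with NaN in missing cells."""
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.protein_ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "AbundanceMatrix":
        return cls(list(df.index.astype(str)), list(df.columns.astype(str)), df.to_numpy(dtype=float))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AbundanceMatrix):
            return NotImplemented
        return (
            self.sample_ids == other.sample_ids
            and self.protein_ids == other.protein_ids
            and np.array_equal(self.missing_mask, other.missing_mask)
            and np.array_equal(
                np.where(self.missing_mask, 0.0, self.values),
                np.where(other.missing_mask, 0.0, other.values),
            )
        )


def _duplicates(ids: Sequence[str]) -> set[str]:
    seen: set[str] = set()
    dupes: set[str] = set()
    for i in ids:
        (dupes if i in seen else seen).add(i)
    return dupes


def read_abundance_tsv(
    path,
    orientation: str = "samples_as_rows",
    zero_as_missing: bool = True,
    column_prefix: str | None = None,
) -> AbundanceMatrix:
    """Read a wide abundance TSV into samples x proteins orientation.

    Parameters
    ----------
    path : path-like
        Tab-separated file with a header row and a leading ID column.
    orientation : {"samples_as_rows", "proteins_as_rows"}
        Layout of the file; the returned matrix is always samples x proteins.
    zero_as_missing : bool
        Treat literal 0 as "not detected" (the MaxQuant LFQ convention).
    column_prefix : str, optional
        Keep only columns whose header starts with this prefix (and strip it),
        e.g. ``"LFQ intensity "`` to ingest raw proteinGroups.txt tables.
    """
    if orientation not in ("samples_as_rows", "proteins_as_rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    df = pd.read_csv(path, sep="\t", header=0, index_col=0, dtype=str, keep_default_na=False)
    if column_prefix is not None:
        keep = [c for c in df.columns if c.startswith(column_prefix)]
        if not keep:
            raise ValueError(f"no columns start with prefix {column_prefix!r}")
        df = df[keep]
        df.columns = [c[len(column_prefix):] for c in keep]

    values = np.empty(df.shape, dtype=float)
    mask = np.zeros(df.shape, dtype=bool)
    cols = list(df.columns)
    rows = list(df.index.astype(str))
    raw = df.to_numpy()
    for i in range(df.shape[0]):
        for j in range(df.shape[1]):
            cell = str(raw[i, j]).strip()
            if cell.lower() in _NA_TOKENS:
                mask[i, j] = True
                values[i, j] = np.nan
                continue
            try:
                v = float(cell)
            except ValueError:
                raise ValueError(
                    f"non-numeric cell {cell!r} at row {rows[i]!r}, column {cols[j]!r}"
                ) from None
            if zero_as_missing and v == 0.0:
                mask[i, j] = True
                values[i, j] = np.nan
            else:
                values[i, j] = v

    if orientation == "proteins_as_rows":
        values, mask = values.T, mask.T
        sample_ids, protein_ids = cols, rows
    else:
        sample_ids, protein_ids = rows, cols
    if len(sample_ids) < 2 or len(protein_ids) < 2:
        raise ValueError(
            f"need at least 2 samples and 2 proteins, got "
            f"{len(sample_ids)} x {len(protein_ids)}"
        )
    return AbundanceMatrix(sample_ids, protein_ids, values, mask)


def write_abundance_tsv(m: AbundanceMatrix, path, orientation: str = "samples_as_rows") -> None:
    """Write an :class:`AbundanceMatrix` as wide TSV; missing cells become empty fields."""
    if orientation not in ("samples_as_rows", "proteins_as_rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    if m.n_samples == 0 or m.n_proteins == 0:
        raise ValueError("refusing to write a zero-width matrix")
    df = m.to_frame()
    if orientation == "proteins_as_rows":
        df = df.T
        df.index.name = "protein_id"
    else:
        df.index.name = "sample_id"
    # repr() round-trips doubles exactly; missing cells are empty fields
    df.to_csv(path, sep="\t", na_rep="", float_format="%.17g")
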