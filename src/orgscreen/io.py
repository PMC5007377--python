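"""Sample sheets, expression matrices and their TSV readers/writers.

The pipeline's substrate is a genes x samples matrix of normalized
expression values on the log2 scale, paired with a sample sheet that maps
each array to a tissue group.  The default study design mirrors a
9-tissue x 3-replicate microarray experiment (27 arrays): early and late
Hensen's node and posterior primitive streak, ventral vs dorsal neural
tube, and posterior vs anterior wing bud at two stages.

TSV dialect: tab-separated, UTF-8, "." decimal, no quoting; the first
header cell of an expression matrix is literally ``gene_id``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DesignError, ParseError

#: Tissue-group labels of the default 9-group design.
DEFAULT_GROUPS: tuple[str, ...] = (
    "HH4 HN",
    "HH6 HN",
    "HH4 PS",
    "VNT",
    "DNT",
    "HH20 PL",
    "HH20 AL",
    "HH24 PL",
    "HH24 AL",
)

DEFAULT_REPLICATES = 3


@dataclass(frozen=True)
class SampleSheet:
    """Maps sample (array) identifiers to tissue groups.

    Parameters
    ----------
    samples
        DataFrame with columns ``sample_id``, ``group``, ``replicate``.
        Sample ids must be unique, replicates positive integers, and every
        group must carry at least two samples so that a within-group
        variance is estimable.
    """

    samples: pd.DataFrame = field(repr=False)

    def __post_init__(self):
        required = {"sample_id", "group", "replicate"}
        missing = required - set(self.samples.columns)
        if missing:
            raise DesignError(f"sample sheet missing columns: {sorted(missing)}")
        ids = self.samples["sample_id"]
        if ids.duplicated().any():
            dups = sorted(ids[ids.duplicated()].unique())
            raise DesignError(f"duplicate sample_ids: {dups}")
        reps = self.samples["replicate"]
        if (reps.astype(int) != reps).any() or (reps <= 0).any():
            raise DesignError("replicate numbers must be positive integers")
        counts = self.samples.groupby("group").size()
        small = counts[counts < 2]
        if not small.empty:
            raise DesignError(
                f"groups with <2 samples (variance not estimable): {sorted(small.index)}"
            )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.samples["sample_id"])

    @property
    def groups(self) -> list[str]:
        """Group labels in first-appearance order."""
        return list(dict.fromkeys(self.samples["group"]))

    def group_samples(self, group: str) -> list[str]:
        """Sample ids belonging to ``group``."""
        sel = self.samples.loc[self.samples["group"] == group, "sample_id"]
        if sel.empty:
            raise DesignError(f"unknown group: {group!r}")
        return list(sel)

    def __len__(self) -> int:
        return len(self.samples)

    @classmethod
    def default_design(
        cls,
        groups: tuple[str, ...] = DEFAULT_GROUPS,
        n_replicates: int = DEFAULT_REPLICATES,
    ) -> "SampleSheet":
        """The study design: every group in triplicate (9 x 3 = 27 arrays)."""
        rows = [
            {
                "sample_id": f"{g.replace(' ', '_')}_r{r}",
                "group": g,
                "replicate": r,
            }
            for g in groups
            for r in range(1, n_replicates + 1)
        ]
        return cls(pd.DataFrame(rows))


@dataclass(frozen=True)
class ExpressionMatrix:
    """A genes x samples matrix (log2 units) with its sample sheet.

    ``values`` is indexed by gene_id and has one column per sample, ordered
    as in the sheet.  Values must be finite; gene ids unique.
    """

    values: pd.DataFrame = field(repr=False)
    sheet: SampleSheet

    def __post_init__(self):
        if list(self.values.columns) != self.sheet.sample_ids:
            raise DesignError(
                "expression matrix columns do not match the sample sheet "
                f"({len(self.values.columns)} columns vs {len(self.sheet)} samples)"
            )
        idx = self.values.index
        if idx.duplicated().any():
            dups = sorted(idx[idx.duplicated()].unique())
            raise DesignError(f"duplicate gene_ids: {dups[:10]}")
        if idx.isna().any() or (idx.astype(str) == "").any():
            raise DesignError("missing gene_ids in expression matrix")
        arr = self.values.to_numpy()
        if not np.isfinite(arr).all():
            bad = np.argwhere(~np.isfinite(arr))[0]
            raise DesignError(
                f"non-finite expression value at gene {idx[bad[0]]!r}, "
                f"sample {self.values.columns[bad[1]]!r}"
            )

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    def group_values(self, group: str) -> pd.DataFrame:
        """Sub-matrix of the samples in ``group``."""
        return self.values[self.sheet.group_samples(group)]


def read_sample_sheet(path: str | Path) -> SampleSheet:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "group": str})
    return SampleSheet(df)


def write_sample_sheet(sheet: SampleSheet, path: str | Path) -> None:
    sheet.samples.to_csv(path, sep="\t", index=False)


def read_expression(matrix_path: str | Path, sheet_path: str | Path) -> ExpressionMatrix:
    """Read an expression matrix TSV together with its sample sheet.

    The matrix header row is ``gene_id`` followed by sample ids; column
    order in the returned matrix follows the sheet.  A sheet sample missing
    from the matrix header is a design error; a non-numeric cell is a parse
    error naming its row and column.
    """
    sheet = read_sample_sheet(sheet_path)
    raw = pd.read_csv(matrix_path, sep="\t", dtype=str)
    if raw.columns[0] != "gene_id":
        raise ParseError(
            f"first header cell must be 'gene_id', got {raw.columns[0]!r}"
        )
    raw = raw.set_index("gene_id")
    header = set(raw.columns)
    for sid in sheet.sample_ids:
        if sid not in header:
            raise DesignError(f"sample {sid!r} listed in sheet but absent from matrix header")
    extra = header - set(sheet.sample_ids)
    if extra:
        raise DesignError(f"matrix columns absent from sheet: {sorted(extra)}")
    try:
        values = raw.astype(float)
    except ValueError:
        for col in raw.columns:
            numeric = pd.to_numeric(raw[col], errors="coerce")
            bad = numeric.isna() & raw[col].notna()
            if bad.any():
                gene = raw.index[bad.to_numpy().nonzero()[0][0]]
                raise ParseError(
                    f"non-numeric expression value at gene {gene!r}, sample {col!r}"
                ) from None
        raise
    return ExpressionMatrix(values[sheet.sample_ids], sheet)


def write_expression(
    matrix: ExpressionMatrix,
    matrix_path: str | Path,
    sheet_path: str | Path | None = None,
) -> None:
    """Write the matrix (and optionally its sheet) as TSV.

    Floats use :func:`repr` precision so that write-then-read round-trips
    values exactly.
    """
    out = matrix.values.copy()
    out.index.name = "gene_id"
    out.to_csv(matrix_path, sep="\t", float_format=None)
    if sheet_path is not None:
        write_sample_sheet(matrix.sheet, sheet_path)
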