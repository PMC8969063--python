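"""Gene-level FPKM expression matrices and sample designs.

The unit of expression throughout the package is FPKM (fragments per
kilobase of transcript per million mapped fragments), as produced by
transcript-abundance estimators such as Cufflinks.  Matrices are genes x
samples; a sample design maps each sample to its (species, treatment,
time, replicate) factors; replicate aggregation collapses samples to one
column per experimental condition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

TREATMENTS = ("intact", "interfamily", "self", "wound")
TIME_POINTS = (0, 3, 7)


class ExpressionError(ValueError):
    """Raised for malformed expression inputs (named cell in the message)."""


@dataclass
class ExpressionMatrix:
    """Genes x samples FPKM table.

    Invariants enforced at construction: unique gene and sample IDs, all
    values finite and non-negative.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        if df.index.duplicated().any():
            dup = df.index[df.index.duplicated()][0]
            raise ExpressionError(f"duplicate gene ID {dup!r}")
        if df.columns.duplicated().any():
            dup = df.columns[df.columns.duplicated()][0]
            raise ExpressionError(f"duplicate sample ID {dup!r}")
        values = df.to_numpy(dtype=float, copy=False)
        bad = ~np.isfinite(values) | (values < 0)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ExpressionError(
                f"invalid FPKM value {df.iat[i, j]!r} for gene "
                f"{df.index[i]!r}, sample {df.columns[j]!r} "
                "(must be finite and >= 0)"
            )
        df = df.astype(float)
        df.index = df.index.rename("gene_id")
        df.columns = df.columns.rename(None)
        self.data = df

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape


@dataclass
class SampleDesign:
    """Maps sample IDs to (species, treatment, time_dag, replicate).

    ``intact`` samples are the ungrafted controls and carry time 0 by
    convention, so every treatment series is indexed over {0, 3, 7} days
    after grafting (DAG).
    """

    table: pd.DataFrame  # index sample_id; columns species, treatment, time_dag, replicate

    REQUIRED = ("species", "treatment", "time_dag", "replicate")

    def __post_init__(self) -> None:
        t = self.table
        missing = [c for c in self.REQUIRED if c not in t.columns]
        if missing:
            raise ExpressionError(f"design table missing columns {missing}")
        if t.index.duplicated().any():
            raise ExpressionError(
                f"duplicate sample ID {t.index[t.index.duplicated()][0]!r} in design"
            )
        bad_tr = set(t["treatment"]) - set(TREATMENTS)
        if bad_tr:
            raise ExpressionError(f"unknown treatment(s) {sorted(bad_tr)}; expected {TREATMENTS}")
        t = t.assign(time_dag=t["time_dag"].astype(int), replicate=t["replicate"].astype(int))
        bad_t = set(t["time_dag"]) - set(TIME_POINTS)
        if bad_t:
            raise ExpressionError(f"time_dag values {sorted(bad_t)} outside {TIME_POINTS}")
        intact = t[t["treatment"] == "intact"]
        if (intact["time_dag"] != 0).any():
            raise ExpressionError("intact samples must have time_dag == 0")
        if (t["replicate"] < 1).any():
            raise ExpressionError("replicate index must be >= 1")
        for sp, grp in t.groupby("species"):
            if not (grp["treatment"] == "intact").any():
                raise ExpressionError(f"species {sp!r} has no intact sample")
        self.table = t

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    @property
    def species(self) -> list[str]:
        return sorted(self.table["species"].unique())


@dataclass
class ConditionMatrix:
    """Genes x conditions table, one column per (species, treatment, time_dag)."""

    data: pd.DataFrame  # columns: MultiIndex (species, treatment, time_dag)

    def __post_init__(self) -> None:
        if not isinstance(self.data.columns, pd.MultiIndex) or self.data.columns.nlevels != 3:
            raise ExpressionError("condition columns must be (species, treatment, time_dag)")
        if self.data.columns.duplicated().any():
            raise ExpressionError("duplicate condition column")
        if (self.data.to_numpy() < 0).any():
            raise ExpressionError("negative aggregated FPKM")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    def value(self, gene: str, species: str, treatment: str, time_dag: int) -> float:
        return float(self.data.at[gene, (species, treatment, time_dag)])

    def species(self) -> list[str]:
        return sorted({c[0] for c in self.data.columns})


def _parse_numeric(df: pd.DataFrame) -> pd.DataFrame:
    """Strict numeric conversion; names the offending cell, forbids NA/'.'."""
    out = {}
    for col in df.columns:
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna()
        if bad.any():
            gene = df.index[bad.to_numpy().argmax()]
            raise ExpressionError(
                f"non-numeric or missing value {df[col][bad].iloc[0]!r} "
                f"for gene {gene!r}, sample {col!r}"
            )
        out[col] = converted
    return pd.DataFrame(out, index=df.index)


def read_fpkm_table(path, dialect: str = "generic_tsv") -> ExpressionMatrix:
    """Read an FPKM table.

    ``generic_tsv``: tab-separated, header row, first column gene ID.
    ``cufflinks_tracking``: a ``genes.fpkm_tracking``-style file with a
    ``tracking_id`` column and one ``<sample>_FPKM`` column per sample.

    Duplicate gene rows, negative or non-numeric values are errors, never
    silently repaired.
    """
    if dialect == "generic_tsv":
        raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str, keep_default_na=False)
    elif dialect == "cufflinks_tracking":
        full = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
        if "tracking_id" not in full.columns:
            raise ExpressionError(f"{path}: cufflinks dialect requires a 'tracking_id' column")
        fpkm_cols = [c for c in full.columns if c.endswith("_FPKM")]
        if not fpkm_cols:
            raise ExpressionError(f"{path}: no '*_FPKM' columns found")
        raw = full.set_index("tracking_id")[fpkm_cols]
        raw.columns = [c[: -len("_FPKM")] for c in fpkm_cols]
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    raw.index = raw.index.astype(str)
    return ExpressionMatrix(_parse_numeric(raw))


def read_design(path) -> SampleDesign:
    """Read a sample-design TSV with columns sample_id, species, treatment, time_dag, replicate."""
    t = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "species": str, "treatment": str})
    if "sample_id" not in t.columns:
        raise ExpressionError(f"{path}: design table must have a 'sample_id' column")
    return SampleDesign(t.set_index("sample_id"))


def write_matrix(matrix: ExpressionMatrix, path) -> None:
    """Write a matrix as TSV preserving row/column order; round-trips exactly."""
    matrix.data.to_csv(path, sep="\t")


def write_design(design: SampleDesign, path) -> None:
    design.table.to_csv(path, sep="\t", index_label="sample_id")


def aggregate_replicates(
    matrix: ExpressionMatrix, design: SampleDesign, statistic: str = "mean"
) -> ConditionMatrix:
    """Collapse replicate samples to one column per (species, treatment, time_dag).

    The default statistic is the arithmetic mean of replicate FPKMs;
    ``median`` is available as a robust alternative.  Order of replicates
    never matters.
    """
    if statistic not in ("mean", "median"):
        raise ValueError(f"unknown statistic {statistic!r}")
    missing = [s for s in matrix.sample_ids if s not in design.table.index]
    if missing:
        raise ExpressionError(f"sample(s) {missing} absent from design")
    des = design.table.loc[matrix.sample_ids]
    keys = pd.MultiIndex.from_frame(des[["species", "treatment", "time_dag"]])
    grouped = matrix.data.T.groupby(keys)
    agg = grouped.mean() if statistic == "mean" else grouped.median()
    agg.index = pd.MultiIndex.from_tuples(agg.index, names=("species", "treatment", "time_dag"))
    return ConditionMatrix(agg.T)
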