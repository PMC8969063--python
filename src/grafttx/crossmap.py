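"""Cross-species best-hit mapping and gene-set intersection accounting.

Each species' genes are projected onto a common annotation space
(Arabidopsis gene IDs) via the single most similar subject in a tabular
alignment-hit file (the 12-column outfmt-6 dialect of BLAST/TBLASTX);
projected upregulated sets are then intersected and summarised as Venn
region counts and shared fractions.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import pandas as pd

BLAST_COLUMNS = (
    "query_id",
    "subject_id",
    "percent_identity",
    "alignment_length",
    "mismatches",
    "gap_opens",
    "q_start",
    "q_end",
    "s_start",
    "s_end",
    "e_value",
    "bit_score",
)
_NUMERIC = {
    "percent_identity": float,
    "alignment_length": int,
    "mismatches": int,
    "gap_opens": int,
    "q_start": int,
    "q_end": int,
    "s_start": int,
    "s_end": int,
    "e_value": float,
    "bit_score": float,
}


def read_blast_tab(path) -> pd.DataFrame:
    """Read a 12-column tabular hit file; '#' comment lines are skipped.

    Rows are returned in file order with typed columns; a row with the
    wrong column count or an unparsable numeric field raises with the
    1-based line number.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 12:
                raise ValueError(
                    f"{path}:{lineno}: expected 12 tab-separated columns, got {len(parts)}"
                )
            row = dict(zip(BLAST_COLUMNS, parts))
            for col, typ in _NUMERIC.items():
                try:
                    row[col] = typ(row[col])
                except ValueError as exc:
                    raise ValueError(
                        f"{path}:{lineno}: cannot parse {col}={row[col]!r}"
                    ) from exc
            if row["e_value"] < 0:
                raise ValueError(f"{path}:{lineno}: negative e-value")
            rows.append(row)
    return pd.DataFrame(rows, columns=list(BLAST_COLUMNS))


@dataclass
class HomologMap:
    """gene_id -> best annotation_id, with the winning hit's scores."""

    table: pd.DataFrame  # columns gene_id, annotation_id, bit_score, e_value

    def __post_init__(self) -> None:
        if self.table["gene_id"].duplicated().any():
            raise ValueError("HomologMap must assign at most one annotation per gene")
        self._lookup = dict(zip(self.table["gene_id"], self.table["annotation_id"]))

    def get(self, gene_id: str) -> str | None:
        return self._lookup.get(gene_id)

    def __len__(self) -> int:
        return len(self.table)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._lookup


def best_hit_map(hits: pd.DataFrame, max_evalue: float | None = None) -> HomologMap:
    """Pick the single most similar subject per query.

    Ranking: maximal bit score, ties broken by minimal e-value, then by
    lexicographically smallest subject ID — independent of row order.
    An optional e-value ceiling filters hits before selection.
    """
    h = hits
    if max_evalue is not None:
        h = h[h["e_value"] <= max_evalue]
    if len(h) == 0:
        return HomologMap(pd.DataFrame(columns=["gene_id", "annotation_id", "bit_score", "e_value"]))
    ranked = h.sort_values(
        ["query_id", "bit_score", "e_value", "subject_id"],
        ascending=[True, False, True, True],
        kind="mergesort",
    ).drop_duplicates("query_id")
    table = ranked.rename(columns={"query_id": "gene_id", "subject_id": "annotation_id"})[
        ["gene_id", "annotation_id", "bit_score", "e_value"]
    ].reset_index(drop=True)
    return HomologMap(table)


def project_gene_set(genes, homolog_map: HomologMap) -> tuple[set[str], int]:
    """Map a gene set into annotation space.

    Returns the set of distinct annotation IDs (many-to-one collapses
    count once) and the number of genes with no mapping.
    """
    annotations: set[str] = set()
    unmapped = 0
    for g in genes:
        a = homolog_map.get(g)
        if a is None:
            unmapped += 1
        else:
            annotations.add(a)
    return annotations, unmapped


@dataclass
class VennCounts:
    """Region counts for 2 or 3 labeled sets.

    ``regions`` maps each non-empty label subset (a sorted tuple) to the
    number of elements belonging to exactly those sets.
    """

    labels: tuple[str, ...]
    regions: dict[tuple[str, ...], int]

    def set_size(self, label: str) -> int:
        return sum(n for key, n in self.regions.items() if label in key)

    def shared_count(self, label: str) -> int:
        """Members of the labeled set found in at least one other set."""
        return sum(n for key, n in self.regions.items() if label in key and len(key) > 1)

    def center(self) -> int:
        return self.regions.get(tuple(sorted(self.labels)), 0)


def venn_counts(sets: dict[str, set]) -> VennCounts:
    """Exact region counts for 2 or 3 labeled sets by membership enumeration."""
    if not 2 <= len(sets) <= 3:
        raise ValueError(f"venn_counts supports 2 or 3 sets, got {len(sets)}")
    labels = tuple(sets)
    regions = {}
    for r in range(1, len(labels) + 1):
        for combo in combinations(sorted(labels), r):
            inside = set.intersection(*(sets[l] for l in combo))
            outside = set.union(set(), *(sets[l] for l in labels if l not in combo))
            regions[combo] = len(inside - outside)
    return VennCounts(labels, regions)


def shared_fraction(counts: VennCounts, label: str) -> float:
    """Fraction of the labeled set present in >= 1 other set, in [0, 1]."""
    if label not in counts.labels:
        raise KeyError(f"unknown set label {label!r}")
    size = counts.set_size(label)
    if size == 0:
        raise ValueError(f"set {label!r} is empty; shared fraction undefined")
    return counts.shared_count(label) / size


def venn_table(counts: VennCounts) -> pd.DataFrame:
    rows = [
        {"region": "&".join(key), "n_sets": len(key), "count": n}
        for key, n in sorted(counts.regions.items(), key=lambda kv: (len(kv[0]), kv[0]))
    ]
    return pd.DataFrame(rows)
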