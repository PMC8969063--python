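"""Extraction of graft-upregulated genes and treatment-pattern classes.

A gene counts as upregulated under a treatment when its expression at
3 DAG is more than twice the intact (time-0) level and its expression at
7 DAG exceeds the 3-DAG level — i.e. a sustained, monotone rise.  An
optional FPKM floor on the peak of the interfamily series screens out
barely-expressed genes; a pseudocount stabilises the fold ratio when the
intact level is near zero.

Extracted genes are then partitioned into four classes by whether the
same rise (floor-free) is also seen after self-grafting and/or wounding:

=====  ==========  ===========  ==================================================
class  self-graft  wounding     reading
=====  ==========  ===========  ==================================================
1      rising      not rising   graft-associated; wound response fades by 7 DAG
2      not rising  not rising   specific to the interfamily graft
3      rising      rising       generic wound/regeneration response
4      not rising  rising       all other patterns
=====  ==========  ===========  ==================================================
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .expression import ConditionMatrix

#: Published lower FPKM limits used to equalise extracted-set sizes between
#: species; the focal species carries no floor.
DEFAULT_FPKM_FLOORS = {"N_benthamiana": 10.0, "I_nil": 12.0}

CLASS_LABELS = (1, 2, 3, 4)


@dataclass(frozen=True)
class Trajectory:
    """FPKM at 0 (intact), 3 and 7 days after grafting for one gene/treatment."""

    x0: float
    x3: float
    x7: float

    def __post_init__(self) -> None:
        for name in ("x0", "x3", "x7"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"trajectory {name}={v!r} must be finite and >= 0")


@dataclass(frozen=True)
class ExtractionParams:
    """Thresholds of the upregulation rule.

    fold_threshold
        Required (strict) fold increase at 3 DAG over intact; default 2.
    fpkm_floor
        Lower FPKM limit applied to max(x3, x7); default 0 (no floor).
    pseudocount
        FPKM added to both sides of the fold ratio; 0 gives the literal
        rule, the default 1.0 tames genes silent in intact tissue.
    """

    fold_threshold: float = 2.0
    fpkm_floor: float = 0.0
    pseudocount: float = 1.0

    def __post_init__(self) -> None:
        if self.fold_threshold <= 0:
            raise ValueError("fold_threshold must be > 0")
        if self.fpkm_floor < 0 or self.pseudocount < 0:
            raise ValueError("fpkm_floor and pseudocount must be >= 0")


@dataclass
class UpregulationRecord:
    """Per-gene extraction evidence: trajectories, pass flag, class label."""

    gene_id: str
    trajectories: dict[str, Trajectory]
    passed: bool
    class_label: int | None = None

    def __post_init__(self) -> None:
        if (self.class_label is not None) and not self.passed:
            raise ValueError("class_label present on a gene that did not pass")


def trajectory_upregulated(t: Trajectory, p: ExtractionParams) -> bool:
    """True iff the trajectory shows the sustained rise (strict inequalities)."""
    c = p.pseudocount
    return (
        (t.x3 + c) > p.fold_threshold * (t.x0 + c)
        and t.x7 > t.x3
        and max(t.x3, t.x7) > p.fpkm_floor
    )


def _series(cond: ConditionMatrix, species: str, treatment: str) -> pd.DataFrame:
    cols = {}
    for t in (0, 3, 7):
        key = (species, "intact", 0) if t == 0 else (species, treatment, t)
        if key not in cond.data.columns:
            raise KeyError(
                f"missing condition {key} — the ({species}, {treatment}) series "
                "needs times 0 (intact), 3 and 7"
            )
        cols[t] = cond.data[key]
    return pd.DataFrame(cols)


def gene_trajectory(cond: ConditionMatrix, gene: str, species: str, treatment: str) -> Trajectory:
    s = _series(cond, species, treatment).loc[gene]
    return Trajectory(float(s[0]), float(s[3]), float(s[7]))


def extract_upregulated(
    cond: ConditionMatrix,
    species: str,
    treatment: str = "interfamily",
    params: ExtractionParams = ExtractionParams(),
) -> list[UpregulationRecord]:
    """Apply the upregulation rule along one treatment series.

    Returns one record per passing gene, in the matrix's gene order, with
    trajectories attached for every treatment present for the species.
    """
    s = _series(cond, species, treatment)
    x0, x3, x7 = (s[t].to_numpy() for t in (0, 3, 7))
    c = params.pseudocount
    mask = (
        ((x3 + c) > params.fold_threshold * (x0 + c))
        & (x7 > x3)
        & (np.maximum(x3, x7) > params.fpkm_floor)
    )
    treatments = sorted(
        {col[1] for col in cond.data.columns if col[0] == species and col[1] != "intact"}
    )
    records = []
    for gene in np.asarray(cond.gene_ids)[mask]:
        trajs = {tr: gene_trajectory(cond, gene, species, tr) for tr in treatments}
        records.append(UpregulationRecord(str(gene), trajs, passed=True))
    return records


def classify_gene(rec: UpregulationRecord, params: ExtractionParams = ExtractionParams()) -> int:
    """Assign the four-way treatment-pattern class to an extracted gene.

    The class is the boolean signature of the same rise predicate — with
    the FPKM floor removed — evaluated on the self-graft and wounding
    trajectories, so a single definition of "rising" is used throughout.
    """
    if not rec.passed:
        raise ValueError(f"gene {rec.gene_id!r} was not extracted; nothing to classify")
    for tr in ("self", "wound"):
        if tr not in rec.trajectories:
            raise KeyError(f"gene {rec.gene_id!r} lacks a {tr!r} trajectory")
    u = replace(params, fpkm_floor=0.0)
    up_self = trajectory_upregulated(rec.trajectories["self"], u)
    up_wound = trajectory_upregulated(rec.trajectories["wound"], u)
    if up_self and up_wound:
        return 3
    if up_self:
        return 1
    if up_wound:
        return 4
    return 2


def classify_set(
    records: list[UpregulationRecord], params: ExtractionParams = ExtractionParams()
) -> dict[int, int]:
    """Label every record in place and return counts per class (1..4).

    Counts always sum to the number of extracted genes: the classes
    partition the extracted set.
    """
    counts = Counter()
    for rec in records:
        rec.class_label = classify_gene(rec, params)
        counts[rec.class_label] += 1
    return {c: counts.get(c, 0) for c in CLASS_LABELS}


def records_table(records: list[UpregulationRecord]) -> pd.DataFrame:
    """Flatten records to a TSV-ready table (x0/x3/x7 per treatment, class)."""
    rows = []
    for rec in records:
        row: dict = {"gene_id": rec.gene_id}
        for tr, t in sorted(rec.trajectories.items()):
            row.update({f"{tr}_x0": t.x0, f"{tr}_x3": t.x3, f"{tr}_x7": t.x7})
        row["passed"] = rec.passed
        row["class_label"] = rec.class_label if rec.class_label is not None else ""
        rows.append(row)
    return pd.DataFrame(rows)
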