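"""GO-term over-representation with hypergeometric tails and BH FDR.

The statistic is the one-sided hypergeometric upper tail (equivalent to a
one-sided Fisher exact test): given a universe of N annotated genes of
which K carry a term, the p-value of observing k carriers in a query of
size n is P[X >= k], X ~ Hypergeometric(N, K, n).  The three GO
namespaces are tested as independent families, each with its own
Benjamini–Hochberg adjustment.  Annotations are used exactly as given —
no ancestor propagation over the GO graph.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

NAMESPACES = ("biological_process", "cellular_component", "molecular_function")
_GAF_ASPECT = {"P": "biological_process", "C": "cellular_component", "F": "molecular_function"}


@dataclass
class AnnotationMap:
    """gene_id -> set of (term_id, namespace) annotations."""

    annotations: dict[str, set[tuple[str, str]]]

    def __post_init__(self) -> None:
        for gene, terms in self.annotations.items():
            for term, ns in terms:
                if not term:
                    raise ValueError(f"empty term ID for gene {gene!r}")
                if ns not in NAMESPACES:
                    raise ValueError(f"unknown namespace {ns!r} for gene {gene!r}")

    @property
    def genes(self) -> set[str]:
        return set(self.annotations)

    def terms_of(self, gene: str) -> set[tuple[str, str]]:
        return self.annotations.get(gene, set())


def read_annotation_tsv(path) -> AnnotationMap:
    """Read a 3-column TSV: gene_id, term_id, namespace."""
    t = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"gene_id", "term_id", "namespace"}
    if not required <= set(t.columns):
        raise ValueError(f"{path}: annotation table needs columns {sorted(required)}")
    ann: dict[str, set[tuple[str, str]]] = {}
    for gene, term, ns in zip(t["gene_id"], t["term_id"], t["namespace"]):
        ann.setdefault(gene, set()).add((term, ns))
    return AnnotationMap(ann)


def read_gaf(path) -> AnnotationMap:
    """Read a GAF 2.x file (columns 2, 5, 9: gene, term, aspect letter)."""
    ann: dict[str, set[tuple[str, str]]] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("!"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 9:
                raise ValueError(f"{path}: GAF line with fewer than 9 columns")
            gene, term, aspect = parts[1], parts[4], parts[8]
            ann.setdefault(gene, set()).add((term, _GAF_ASPECT[aspect]))
    return AnnotationMap(ann)


def hypergeom_tail(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail P[X >= k] for X ~ Hypergeometric(N, K, n)."""
    if not (0 <= k <= min(K, n) and K <= N and n <= N and k >= 0):
        raise ValueError(f"inconsistent counts k={k}, K={K}, n={n}, N={N}")
    if k == 0:
        return 1.0
    return float(hypergeom.sf(k - 1, N, K, n))


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted values, clipped to [0, 1]."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def enrich(
    query: set[str],
    annotations: AnnotationMap,
    universe: set[str] | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Over-representation of every term hit by the query, per namespace.

    The universe (background) defaults to all annotated genes and is
    shared by the three namespaces; the namespaces form independent BH
    families.  Rows are sorted by (namespace, p_value, term_id); the
    ``significant`` column flags q < alpha.
    """
    universe = annotations.genes if universe is None else set(universe)
    query = set(query)
    stray = query - universe
    if stray:
        raise ValueError(
            f"{len(stray)} query gene(s) absent from the universe, e.g. {sorted(stray)[:3]}"
        )
    N, n = len(universe), len(query)
    frames = []
    for ns in NAMESPACES:
        term_genes: dict[str, set[str]] = {}
        for gene in universe:
            for term, term_ns in annotations.terms_of(gene):
                if term_ns == ns:
                    term_genes.setdefault(term, set()).add(gene)
        rows = []
        for term, genes in term_genes.items():
            k = len(genes & query)
            if k == 0:
                continue
            K = len(genes)
            rows.append(
                {
                    "term_id": term,
                    "namespace": ns,
                    "k": k,
                    "K": K,
                    "n": n,
                    "N": N,
                    "p_value": hypergeom_tail(k, K, n, N),
                }
            )
        if not rows:
            continue
        df = pd.DataFrame(rows).sort_values(["p_value", "term_id"], kind="mergesort")
        # the BH family is every testable term of the namespace: terms the
        # query missed entirely enter as p = 1, otherwise the selection
        # "has >= 1 hit" would shrink the family and break FDR control
        padded = np.concatenate([df["p_value"].to_numpy(),
                                 np.ones(len(term_genes) - len(df))])
        df["q_value"] = bh_adjust(padded)[: len(df)]
        df["significant"] = df["q_value"] < alpha
        frames.append(df)
    if not frames:
        return pd.DataFrame(
            columns=["term_id", "namespace", "k", "K", "n", "N", "p_value", "q_value", "significant"]
        )
    return pd.concat(frames, ignore_index=True)
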