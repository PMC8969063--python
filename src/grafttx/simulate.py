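"""Synthetic pipeline inputs with known ground truth.

Emulates the processed form of a three-species grafting time-series
RNA-seq study: per-species FPKM matrices over treatments {interfamily,
self, wound} x times {0 (intact), 3, 7} DAG with replicates, in which a
planted subset of genes follows the trajectory signature of one of the
four treatment-pattern classes; tabular homology hits tying each
species' genes to a common annotation space; GO annotations with
optionally planted enriched terms; and binomial graft-trial tables.

Everything is a pure function of (config, seed): the same configuration
reproduces every artifact bit for bit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .crossmap import BLAST_COLUMNS
from .enrichment import NAMESPACES, AnnotationMap
from .expression import ExpressionMatrix, SampleDesign, write_design, write_matrix
from .stats import GraftTrialRow

#: Planted class mix: proportions of the extracted set falling in classes
#: 1..4, shaped like the observed 128/173/166/201 partition; total planted
#: fraction 0.1 of the transcriptome.
DEFAULT_CLASS_FRACTIONS = {1: 0.0192, 2: 0.0259, 3: 0.0248, 4: 0.0301}

#: Trial-arm structure of the glucanase-inhibitor experiment: success
#: probability and graft count per treatment arm.
DEFAULT_TRIAL_ARMS = {
    "water": (0.77, 35),
    "glucose": (0.96, 28),
    "gluconolactone": (0.0, 31),
}

_TREATMENT_TIMES = [("intact", 0), ("interfamily", 3), ("interfamily", 7),
                    ("self", 3), ("self", 7), ("wound", 3), ("wound", 7)]

#: Planted genes are drawn as expressed genes: baselines below this FPKM
#: are lifted to it so a genuine >2-fold rise is detectable above noise.
MIN_PLANTED_BASELINE = 3.0


@dataclass
class SimConfig:
    """Study-condition knobs of the generator.

    Baselines are log-normal (natural-log mean 2, sd 1: median ~7.4 FPKM,
    so a realistic share of genes sits below the 10/12 FPKM floors);
    each planted "increase" step multiplies expression by a factor drawn
    uniformly from ``fold_range``; replicate noise is multiplicative
    log-normal with sd ``noise_sd`` on the log2 scale.
    """

    n_genes: int = 1000
    species: tuple[str, ...] = ("P_hybrida", "N_benthamiana", "I_nil")
    class_fractions: dict[int, float] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_FRACTIONS)
    )
    baseline_meanlog: float = 2.0
    baseline_sdlog: float = 1.0
    fold_range: tuple[float, float] = (2.5, 6.0)
    decay_range: tuple[float, float] = (0.3, 0.8)  # 7-DAG fall-off of fading wound response
    noise_sd: float = 0.05
    replicates: int = 3
    homolog_coverage: float = 0.9
    n_decoys: int = 2
    decoy_margin: tuple[float, float] = (5.0, 50.0)
    shared_upregulation: float = 0.12
    go_n_terms: int = 50
    go_genes_per_term: int = 20
    go_planted_terms: int = 1
    go_enrichment_odds: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 1 <= len(self.species) <= 3:
            raise ValueError("1 to 3 species supported")
        if sum(self.class_fractions.values()) > 1:
            raise ValueError("class fractions must sum to <= 1")
        if any(f < 0 for f in self.class_fractions.values()):
            raise ValueError("class fractions must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        for name in ("homolog_coverage", "shared_upregulation"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.replicates < 1:
            raise ValueError("need >= 1 replicate")

    def gene_id(self, species: str, i: int) -> str:
        return f"{species}_g{i + 1:05d}"

    def annotation_id(self, i: int) -> str:
        return f"AT{i + 1:05d}"


@dataclass
class SimTruth:
    """Ground truth the generator plants, for recovery scoring.

    planted
        species -> gene_id -> class label (1..4).
    annotation_of
        species -> gene_id -> core annotation ID (the bijective homolog
        core, before any coverage dropout).
    homolog_emitted
        species -> gene_ids that actually received hit rows.
    shared_annotations
        Annotation IDs whose gene is planted in every species.
    enriched_terms
        Term IDs planted as enriched in the GO annotations.
    """

    planted: dict[str, dict[str, int]]
    annotation_of: dict[str, dict[str, str]]
    homolog_emitted: dict[str, list[str]] = field(default_factory=dict)
    shared_annotations: set[str] = field(default_factory=set)
    enriched_terms: list[str] = field(default_factory=list)

    def planted_set(self, species: str, classes=None) -> set[str]:
        items = self.planted[species].items()
        if classes is None:
            return {g for g, _ in items}
        classes = set(classes)
        return {g for g, c in items if c in classes}

    def class_counts(self, species: str) -> dict[int, int]:
        counts = {1: 0, 2: 0, 3: 0, 4: 0}
        for c in self.planted[species].values():
            counts[c] += 1
        return counts


def _planted_trajectories(rng, cfg: SimConfig, x0: float, label: int) -> dict[tuple[str, int], float]:
    """Noiseless condition values for one planted gene (floor-free signatures)."""

    def rising(base):
        f1 = rng.uniform(*cfg.fold_range)
        f2 = rng.uniform(*cfg.fold_range)
        return base * f1, base * f1 * f2

    def fading(base):  # rises at 3 DAG, falls back below it by 7 DAG
        f1 = rng.uniform(*cfg.fold_range)
        u = rng.uniform(*cfg.decay_range)
        return base * f1, base * f1 * u

    def flat(base):
        return base, base

    shapes = {
        1: (rising, fading),   # self rises, wound fades
        2: (flat, flat),       # interfamily-only
        3: (rising, rising),   # generic wound response
        4: (flat, rising),     # residual patterns
    }
    self_shape, wound_shape = shapes[label]
    vals = {("intact", 0): x0}
    vals[("interfamily", 3)], vals[("interfamily", 7)] = rising(x0)
    vals[("self", 3)], vals[("self", 7)] = self_shape(x0)
    vals[("wound", 3)], vals[("wound", 7)] = wound_shape(x0)
    return vals


def generate_expression(
    cfg: SimConfig,
) -> tuple[dict[str, tuple[ExpressionMatrix, SampleDesign]], SimTruth]:
    """Per-species FPKM matrices plus designs, with planted class truth.

    With ``noise_sd == 0`` every planted gene's replicate-mean trajectory
    satisfies its class signature exactly and every unplanted gene is
    flat, so downstream extraction recovers the truth identically.
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_genes
    class_counts = {c: int(round(f * n)) for c, f in cfg.class_fractions.items() if f > 0}
    total_planted = sum(class_counts.values())

    focal = cfg.species[0]
    focal_idx = rng.choice(n, size=total_planted, replace=False)
    planted_idx: dict[str, dict[int, int]] = {sp: {} for sp in cfg.species}  # idx -> class
    pos = 0
    for c in sorted(class_counts):
        for i in focal_idx[pos : pos + class_counts[c]]:
            planted_idx[focal][int(i)] = c
        pos += class_counts[c]

    # a focal planted gene is shared (same class, same core index) into
    # every other species with the configured probability
    shared = {i for i in planted_idx[focal] if rng.random() < cfg.shared_upregulation}
    taken = set(planted_idx[focal])
    for sp in cfg.species[1:]:
        for i in shared:
            planted_idx[sp][i] = planted_idx[focal][i]
        # fresh planted genes from indices unplanted anywhere, matching the
        # focal per-class counts so extracted-set sizes stay comparable;
        # if the unplanted pool runs dry (fractions summing to ~1) fall
        # back on focal-planted genes, accepting the extra overlap
        free = sorted(set(range(n)) - taken)
        need = {c: class_counts[c] - sum(1 for i in shared if planted_idx[focal][i] == c)
                for c in class_counts}
        n_fresh = sum(need.values())
        if len(free) < n_fresh:
            free = free + sorted(set(planted_idx[focal]) - shared)
        fresh = (
            rng.choice(np.array(free, dtype=int), size=n_fresh, replace=False)
            if n_fresh
            else np.array([], dtype=int)
        )
        taken.update(int(i) for i in fresh)
        pos = 0
        for c in sorted(need):
            for i in fresh[pos : pos + need[c]]:
                planted_idx[sp][int(i)] = c
            pos += need[c]

    bundles = {}
    planted_names: dict[str, dict[str, int]] = {}
    annotation_of = {
        sp: {cfg.gene_id(sp, i): cfg.annotation_id(i) for i in range(n)} for sp in cfg.species
    }
    for sp in cfg.species:
        genes = [cfg.gene_id(sp, i) for i in range(n)]
        x0 = rng.lognormal(cfg.baseline_meanlog, cfg.baseline_sdlog, size=n)
        noiseless = np.empty((n, len(_TREATMENT_TIMES)))
        for i in range(n):
            label = planted_idx[sp].get(i)
            if label is None:
                noiseless[i] = x0[i]
            else:
                base = max(x0[i], MIN_PLANTED_BASELINE)
                vals = _planted_trajectories(rng, cfg, base, label)
                noiseless[i] = [vals[ct] for ct in _TREATMENT_TIMES]
        sample_ids, design_rows, columns = [], [], []
        for treatment, t in _TREATMENT_TIMES:
            for r in range(1, cfg.replicates + 1):
                sid = f"{sp}_{treatment}_{t}_r{r}"
                sample_ids.append(sid)
                design_rows.append(
                    {"sample_id": sid, "species": sp, "treatment": treatment,
                     "time_dag": t, "replicate": r}
                )
                col = noiseless[:, _TREATMENT_TIMES.index((treatment, t))]
                if cfg.noise_sd > 0:
                    col = col * np.exp2(rng.normal(0.0, cfg.noise_sd, size=n))
                columns.append(col)
        matrix = ExpressionMatrix(
            pd.DataFrame(np.column_stack(columns), index=genes, columns=sample_ids)
        )
        design = SampleDesign(pd.DataFrame(design_rows).set_index("sample_id"))
        bundles[sp] = (matrix, design)
        planted_names[sp] = {cfg.gene_id(sp, i): c for i, c in sorted(planted_idx[sp].items())}

    shared_all = set.intersection(*(set(planted_idx[sp]) for sp in cfg.species)) if len(
        cfg.species
    ) > 1 else set(planted_idx[focal])
    truth = SimTruth(
        planted=planted_names,
        annotation_of=annotation_of,
        shared_annotations={cfg.annotation_id(i) for i in shared_all},
    )
    return bundles, truth


def generate_homology(cfg: SimConfig, truth: SimTruth, seed: int | None = None) -> dict[str, pd.DataFrame]:
    """Tabular 12-column hit files per species.

    Each covered gene receives its true core annotation as the top-scoring
    subject plus lower-scoring decoy subjects; genes failing the coverage
    draw emit no rows at all, so best-hit mapping on the output recovers
    exactly the covered part of the core.
    """
    rng = np.random.default_rng(cfg.seed + 1 if seed is None else seed)
    tables = {}
    n = cfg.n_genes
    for sp in cfg.species:
        rows = []
        emitted = []
        for i in range(n):
            gene = cfg.gene_id(sp, i)
            if rng.random() > cfg.homolog_coverage:
                continue
            emitted.append(gene)
            true_bit = rng.uniform(200.0, 500.0)
            subjects = [(cfg.annotation_id(i), true_bit)]
            for _ in range(cfg.n_decoys):
                j = int(rng.integers(0, n - 1))
                j = j if j < i else j + 1  # decoy subject differs from the true one
                subjects.append((cfg.annotation_id(j), true_bit - rng.uniform(*cfg.decoy_margin)))
            for subject, bit in subjects:
                length = int(rng.integers(80, 400))
                rows.append(
                    (gene, subject, round(rng.uniform(40.0, 95.0), 2), length,
                     int(rng.integers(0, 40)), int(rng.integers(0, 5)),
                     1, length, 1, length, 10.0 ** (-bit / 10.0), round(bit, 1))
                )
        tables[sp] = pd.DataFrame(rows, columns=list(BLAST_COLUMNS))
        truth.homolog_emitted[sp] = emitted
    return tables


def generate_go(
    cfg: SimConfig, truth: SimTruth, seed: int | None = None, odds: float | None = None
) -> AnnotationMap:
    """GO annotations over the common annotation space.

    Planted enriched terms draw their member genes with sampling weight
    ``odds`` on the cross-species shared-upregulated set and 1 elsewhere;
    the remaining terms draw uniformly.  ``odds == 1`` is an exchangeable
    null with nothing enriched.
    """
    rng = np.random.default_rng(cfg.seed + 2 if seed is None else seed)
    odds = cfg.go_enrichment_odds if odds is None else odds
    universe = np.array([cfg.annotation_id(i) for i in range(cfg.n_genes)])
    shared = truth.shared_annotations
    ann: dict[str, set[tuple[str, str]]] = {}
    enriched = []
    size = min(cfg.go_genes_per_term, cfg.n_genes)
    for t in range(cfg.go_n_terms):
        term = f"GO:{t + 1:07d}"
        planted = t < cfg.go_planted_terms
        ns = "molecular_function" if planted else NAMESPACES[t % len(NAMESPACES)]
        if planted and odds != 1.0 and shared:
            w = np.where(np.isin(universe, sorted(shared)), float(odds), 1.0)
            members = rng.choice(universe, size=size, replace=False, p=w / w.sum())
            enriched.append(term)
        else:
            members = rng.choice(universe, size=size, replace=False)
        for g in members:
            ann.setdefault(str(g), set()).add((term, ns))
    truth.enriched_terms = enriched
    return AnnotationMap(ann)


def generate_grafting_trials(
    arms: dict[str, tuple[float, int]] | None = None, seed: int = 0
) -> list[GraftTrialRow]:
    """Binomial graft-trial counts per arm: label -> (p_success, n_trials)."""
    arms = DEFAULT_TRIAL_ARMS if arms is None else arms
    rng = np.random.default_rng(seed)
    rows = []
    for label, (p, ntr) in arms.items():
        if not 0 <= p <= 1:
            raise ValueError(f"{label!r}: success probability {p} outside [0, 1]")
        rows.append(GraftTrialRow(label, ntr, int(rng.binomial(ntr, p))))
    return rows


def simulate(cfg: SimConfig, outdir) -> tuple[dict[str, Path], SimTruth]:
    """Emit the full input bundle plus a truth JSON into a directory.

    Files: per species ``expression_<sp>.tsv``, ``design_<sp>.tsv``,
    ``hits_<sp>.tsv``; ``go_annotations.tsv``; ``trials.tsv``;
    ``truth.json``.  Returns the path map and the in-memory truth.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    bundles, truth = generate_expression(cfg)
    hits = generate_homology(cfg, truth)
    go = generate_go(cfg, truth)
    trials = generate_grafting_trials(seed=cfg.seed + 3)
    paths: dict[str, Path] = {}
    for sp, (matrix, design) in bundles.items():
        paths[f"expression_{sp}"] = outdir / f"expression_{sp}.tsv"
        write_matrix(matrix, paths[f"expression_{sp}"])
        paths[f"design_{sp}"] = outdir / f"design_{sp}.tsv"
        write_design(design, paths[f"design_{sp}"])
        paths[f"hits_{sp}"] = outdir / f"hits_{sp}.tsv"
        hits[sp].to_csv(paths[f"hits_{sp}"], sep="\t", index=False, header=False)
    paths["go"] = outdir / "go_annotations.tsv"
    go_rows = [
        {"gene_id": g, "term_id": term, "namespace": ns}
        for g in sorted(go.annotations)
        for term, ns in sorted(go.annotations[g])
    ]
    pd.DataFrame(go_rows).to_csv(paths["go"], sep="\t", index=False)
    paths["trials"] = outdir / "trials.tsv"
    pd.DataFrame(
        [{"label": r.label, "trials": r.trials, "successes": r.successes} for r in trials]
    ).to_csv(paths["trials"], sep="\t", index=False)
    paths["truth"] = outdir / "truth.json"
    with open(paths["truth"], "w") as fh:
        json.dump(
            {
                "planted": truth.planted,
                "annotation_of": truth.annotation_of,
                "homolog_emitted": truth.homolog_emitted,
                "shared_annotations": sorted(truth.shared_annotations),
                "enriched_terms": truth.enriched_terms,
            },
            fh,
            indent=1,
            sort_keys=True,
        )
    return paths, truth
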