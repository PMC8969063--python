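"""End-to-end orchestration of the comparative grafting analysis.

Stage order mirrors the study workflow: extract upregulated genes per
species -> classify the focal species' set by treatment pattern ->
sample-level clustering and PCA of log-ratio profiles -> best-hit
projection onto the common annotation space -> Venn/shared-fraction
accounting -> SOM profiling of the focal set's homologs in every
species -> GO enrichment of the cross-species intersection -> graft
success statistics.  Every stage writes its table into the output
directory and contributes to a JSON run report; any stage failure aborts
with the stage name attached.
"""

from __future__ import annotations

import hashlib
import json
import logging
import tomllib
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from . import __version__
from .crossmap import best_hit_map, project_gene_set, read_blast_tab, shared_fraction, venn_counts, venn_table
from .enrichment import enrich, read_annotation_tsv
from .expression import aggregate_replicates, read_design, read_fpkm_table
from .profiles import dendrogram_to_newick, pca, ratio_profiles, train_som, ward_cluster
from .stats import pairwise_fisher, read_trials_tsv, trials_report
from .upregulation import (
    DEFAULT_FPKM_FLOORS,
    ExtractionParams,
    classify_set,
    extract_upregulated,
    records_table,
)

log = logging.getLogger("grafttx")


class PipelineStageError(RuntimeError):
    """A stage failed; carries the stage name and the original cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class SpeciesInputs:
    expression: str
    design: str
    hits: str | None = None
    fold_threshold: float = 2.0
    fpkm_floor: float = 0.0
    pseudocount: float = 1.0

    def extraction_params(self) -> ExtractionParams:
        return ExtractionParams(self.fold_threshold, self.fpkm_floor, self.pseudocount)


@dataclass
class PipelineConfig:
    species: dict[str, SpeciesInputs]
    focal_species: str
    outdir: str = "grafttx_out"
    annotations: str | None = None
    trials: str | None = None
    alpha: float = 0.05
    ratio_pseudocount: float = 1.0
    som_grid: tuple[int, int] = (4, 4)
    som_epochs: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if self.focal_species not in self.species:
            raise ValueError(f"focal species {self.focal_species!r} not configured")

    @classmethod
    def from_toml(cls, path) -> "PipelineConfig":
        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        species = {}
        for name, sect in raw.get("species", {}).items():
            sect = dict(sect)
            sect.setdefault("fpkm_floor", DEFAULT_FPKM_FLOORS.get(name, 0.0))
            species[name] = SpeciesInputs(**sect)
        som = raw.get("som", {})
        return cls(
            species=species,
            focal_species=raw["focal_species"],
            outdir=raw.get("outdir", "grafttx_out"),
            annotations=raw.get("annotations"),
            trials=raw.get("trials"),
            alpha=raw.get("alpha", 0.05),
            ratio_pseudocount=raw.get("ratio_pseudocount", 1.0),
            som_grid=tuple(som.get("grid", (4, 4))),
            som_epochs=som.get("epochs", 50),
            seed=raw.get("seed", 0),
        )

    def hash(self) -> str:
        blob = json.dumps(
            {
                "species": {k: vars(v) for k, v in sorted(self.species.items())},
                "focal_species": self.focal_species,
                "annotations": self.annotations,
                "trials": self.trials,
                "alpha": self.alpha,
                "ratio_pseudocount": self.ratio_pseudocount,
                "som_grid": list(self.som_grid),
                "som_epochs": self.som_epochs,
                "seed": self.seed,
            },
            sort_keys=True,
        )
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute every stage and return the run report (also written as JSON)."""
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "provenance": {"version": __version__, "seed": cfg.seed, "config_hash": cfg.hash()},
        "species": {},
    }

    def stage(name):
        log.info("stage %s", name)

        class _Ctx:
            def __enter__(self):
                return None

            def __exit__(self, exc_type, exc, tb):
                if exc is not None:
                    report["failed_stage"] = name
                    raise PipelineStageError(name, exc) from exc

        return _Ctx()

    conds, records = {}, {}
    with stage("expression_io"):
        for sp, inp in cfg.species.items():
            matrix = read_fpkm_table(inp.expression)
            design = read_design(inp.design)
            conds[sp] = aggregate_replicates(matrix, design)

    with stage("extract"):
        for sp, inp in cfg.species.items():
            records[sp] = extract_upregulated(conds[sp], sp, "interfamily", inp.extraction_params())
            report["species"][sp] = {"extracted": len(records[sp])}

    with stage("classify"):
        focal = cfg.focal_species
        counts = classify_set(records[focal], cfg.species[focal].extraction_params())
        records_table(records[focal]).to_csv(out / f"extracted_{focal}.tsv", sep="\t", index=False)
        report["class_counts"] = {str(c): n for c, n in counts.items()}
        assert sum(counts.values()) == len(records[focal])

    with stage("cluster_pca"):
        ratios = ratio_profiles(conds[focal], focal, cfg.ratio_pseudocount)
        nonzero = ratios.data.loc[(ratios.data != 0).any(axis=1)]
        labels = [f"{tr}_{t}DAG" for tr, t in nonzero.columns]
        dendro = ward_cluster(nonzero.T.to_numpy(), labels)
        (out / "sample_dendrogram.nwk").write_text(dendrogram_to_newick(dendro))
        pres = pca(nonzero.T.to_numpy())
        pres.scores.assign(condition=labels).to_csv(out / "pca_scores.tsv", sep="\t", index=False)
        report["pca_variance_fractions"] = [round(float(f), 6) for f in pres.variance_fractions]

    maps, projected = {}, {}
    with stage("crossmap"):
        for sp, inp in cfg.species.items():
            if inp.hits is None:
                raise FileNotFoundError(f"no hit table configured for species {sp!r}")
            maps[sp] = best_hit_map(read_blast_tab(inp.hits))
            genes = [r.gene_id for r in records[sp]]
            projected[sp], unmapped = project_gene_set(genes, maps[sp])
            report["species"][sp].update(
                {"projected_annotations": len(projected[sp]), "unmapped": unmapped}
            )
            maps[sp].table.to_csv(out / f"best_hits_{sp}.tsv", sep="\t", index=False)

    with stage("venn"):
        counts3 = venn_counts(projected)
        venn_table(counts3).to_csv(out / "venn_regions.tsv", sep="\t", index=False)
        report["venn"] = {"&".join(k): v for k, v in counts3.regions.items()}
        report["shared_fractions"] = {
            sp: round(shared_fraction(counts3, sp), 4) for sp in projected if counts3.set_size(sp)
        }
        intersection = counts3.center()
        report["intersection_annotations"] = intersection

    with stage("som"):
        focal_annotations = projected[cfg.focal_species]
        som_report = {}
        for sp in cfg.species:
            # homologs (in this species) of the focal upregulated set
            homolog_genes = [
                g for g in conds[sp].gene_ids if maps[sp].get(g) in focal_annotations
            ]
            report["species"][sp]["focal_set_homologs"] = len(homolog_genes)
            ratios_sp = ratio_profiles(conds[sp], sp, cfg.ratio_pseudocount)
            profiles = ratios_sp.data.loc[homolog_genes]
            profiles = profiles.loc[(profiles != 0).any(axis=1)]
            if len(profiles) == 0:
                continue
            som = train_som(profiles, cfg.som_grid, cfg.som_epochs, cfg.seed)
            pd.DataFrame(
                {"gene_id": profiles.index, "node": som.assignments}
            ).to_csv(out / f"som_assignments_{sp}.tsv", sep="\t", index=False)
            som_report[sp] = {
                "final_quantization_error": round(float(som.qe_trace[-1]), 6),
                "profiles": int(len(profiles)),
            }
        report["som"] = som_report

    if cfg.annotations is not None:
        with stage("enrichment"):
            ann = read_annotation_tsv(cfg.annotations)
            universe = ann.genes
            center = set.intersection(*projected.values()) if projected else set()
            query = center & universe
            dropped = len(center) - len(query)
            if dropped:
                log.info("enrichment: %d intersection IDs lack annotations; dropped", dropped)
            table = enrich(query, ann, alpha=cfg.alpha) if query else pd.DataFrame()
            table.to_csv(out / "enrichment.tsv", sep="\t", index=False)
            sig = (
                table[table["significant"]].groupby("namespace").size().to_dict()
                if len(table)
                else {}
            )
            report["enrichment"] = {
                "query_size": len(query),
                "unannotated_dropped": dropped,
                "significant_terms": sig,
            }

    if cfg.trials is not None:
        with stage("graft_stats"):
            rows = read_trials_tsv(cfg.trials)
            trials_report(rows).to_csv(out / "graft_rates.tsv", sep="\t", index=False)
            fisher = pairwise_fisher(rows)
            fisher.raw.to_csv(out / "fisher_raw.tsv", sep="\t")
            fisher.adjusted.to_csv(out / "fisher_bh.tsv", sep="\t")
            report["graft_stats"] = {
                "rates_pct": {
                    r.label: round(100.0 * r.successes / r.trials, 4) for r in rows
                },
                "min_raw_p": float(
                    min(
                        fisher.raw.iloc[i, j]
                        for i in range(len(rows))
                        for j in range(i + 1, len(rows))
                    )
                ),
            }

    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
    return report
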