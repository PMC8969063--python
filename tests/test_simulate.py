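import numpy as np
import pandas as pd
import pytest

from grafttx.crossmap import best_hit_map
from grafttx.enrichment import enrich
from grafttx.expression import aggregate_replicates
from grafttx.simulate import (
    SimConfig,
    generate_expression,
    generate_go,
    generate_grafting_trials,
    generate_homology,
    simulate,
)
from grafttx.upregulation import ExtractionParams, extract_upregulated


class TestConfigValidation:
    def test_fractions_must_sum_below_one(self):
        with pytest.raises(ValueError):
            SimConfig(class_fractions={1: 0.6, 2: 0.6})

    def test_probabilities_in_unit_interval(self):
        with pytest.raises(ValueError):
            SimConfig(homolog_coverage=1.5)


class TestGenerateExpression:
    def test_deterministic_given_seed(self):
        cfg = SimConfig(n_genes=100, seed=4)
        (b1, _), (b2, _) = generate_expression(cfg), generate_expression(cfg)
        for sp in cfg.species:
            pd.testing.assert_frame_equal(b1[sp][0].data, b2[sp][0].data)

    def test_noiseless_extraction_is_exact(self, noiseless_bundle):
        cfg, _, conds, truth = noiseless_bundle
        for sp in cfg.species:
            got = {r.gene_id for r in extract_upregulated(conds[sp], sp)}
            assert got == truth.planted_set(sp)

    def test_noiseless_trajectories_satisfy_class_signatures(self, noiseless_bundle):
        cfg, _, conds, truth = noiseless_bundle
        from grafttx.upregulation import Trajectory, gene_trajectory, trajectory_upregulated

        p0 = ExtractionParams(pseudocount=0.0)
        sp = cfg.species[0]
        signature = {1: (True, False), 2: (False, False), 3: (True, True), 4: (False, True)}
        for gene, label in truth.planted[sp].items():
            up = tuple(
                trajectory_upregulated(gene_trajectory(conds[sp], gene, sp, tr), p0)
                for tr in ("self", "wound")
            )
            assert up == signature[label], (gene, label)

    def test_recovery_degrades_with_noise_on_average(self):
        """Monitored trend: extraction F1 at high noise <= F1 at low noise."""

        def mean_f1(sigma):
            scores = []
            for seed in range(3):
                cfg = SimConfig(n_genes=300, noise_sd=sigma, seed=seed)
                bundles, truth = generate_expression(cfg)
                sp = cfg.species[0]
                got = {r.gene_id for r in extract_upregulated(aggregate_replicates(*bundles[sp]), sp)}
                want = truth.planted_set(sp)
                tp = len(got & want)
                scores.append(2 * tp / (len(got) + len(want)))
            return np.mean(scores)

        assert mean_f1(0.8) <= mean_f1(0.05) + 1e-9


class TestGenerateHomology:
    def test_full_coverage_recovers_true_map(self):
        cfg = SimConfig(n_genes=50, homolog_coverage=1.0, n_decoys=2, seed=8)
        _, truth = generate_expression(cfg)
        hits = generate_homology(cfg, truth)
        for sp in cfg.species:
            m = best_hit_map(hits[sp])
            for gene, anno in truth.annotation_of[sp].items():
                assert m.get(gene) == anno

    def test_zero_coverage_empty_map(self):
        cfg = SimConfig(n_genes=20, homolog_coverage=0.0, seed=8)
        _, truth = generate_expression(cfg)
        hits = generate_homology(cfg, truth)
        assert all(len(t) == 0 for t in hits.values())

    def test_decoys_one_bit_below_never_win(self):
        cfg = SimConfig(n_genes=30, homolog_coverage=1.0, n_decoys=3,
                        decoy_margin=(1.0, 1.0), seed=8)
        _, truth = generate_expression(cfg)
        hits = generate_homology(cfg, truth)
        sp = cfg.species[0]
        m = best_hit_map(hits[sp])
        assert all(m.get(g) == a for g, a in truth.annotation_of[sp].items())


class TestGenerateGo:
    def test_null_odds_rarely_significant(self):
        """odds=1 is an exchangeable null: >= 95% of seeds find nothing."""
        clean = 0
        for seed in range(100):
            cfg = SimConfig(n_genes=300, go_n_terms=20, go_genes_per_term=15, seed=seed)
            _, truth = generate_expression(cfg)
            ann = generate_go(cfg, truth, odds=1.0)
            rng = np.random.default_rng(seed)
            query = set(rng.choice(sorted(ann.genes), size=20, replace=False))
            table = enrich(query, ann)
            if len(table) == 0 or not table["significant"].any():
                clean += 1
        assert clean >= 95

    def test_planted_term_attains_minimal_q(self):
        cfg = SimConfig(n_genes=1000, seed=11)
        _, truth = generate_expression(cfg)
        ann = generate_go(cfg, truth, odds=20.0)
        query = truth.shared_annotations & ann.genes
        table = enrich(query, ann)
        best = table.loc[table["q_value"].idxmin(), "term_id"]
        assert best in truth.enriched_terms

    def test_annotated_ids_come_from_the_homolog_core(self):
        cfg = SimConfig(n_genes=40, seed=2)
        _, truth = generate_expression(cfg)
        ann = generate_go(cfg, truth)
        core = set(truth.annotation_of[cfg.species[0]].values())
        assert ann.genes <= core


class TestGraftingTrials:
    def test_degenerate_probabilities(self):
        rows = generate_grafting_trials({"all": (1.0, 20), "none": (0.0, 15)}, seed=0)
        assert rows[0].successes == 20
        assert rows[1].successes == 0

    def test_binomial_mean_matches_moments(self):
        draws = [
            generate_grafting_trials({"w": (0.77, 35)}, seed=s)[0].successes
            for s in range(10_000)
        ]
        mean, expected = np.mean(draws), 0.77 * 35
        sd = np.sqrt(35 * 0.77 * 0.23)
        assert abs(mean - expected) <= 3 * sd / np.sqrt(len(draws))


class TestSimulateBundle:
    def test_bundle_reproducible_bit_for_bit(self, tmp_path):
        cfg = SimConfig(n_genes=60, seed=3)
        paths1, _ = simulate(cfg, tmp_path / "a")
        paths2, _ = simulate(cfg, tmp_path / "b")
        for key in paths1:
            assert paths1[key].read_bytes() == paths2[key].read_bytes(), key
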