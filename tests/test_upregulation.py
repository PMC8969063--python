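import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from grafttx.expression import aggregate_replicates
from grafttx.simulate import SimConfig, generate_expression
from grafttx.upregulation import (
    ExtractionParams,
    Trajectory,
    UpregulationRecord,
    classify_gene,
    classify_set,
    extract_upregulated,
    trajectory_upregulated,
)


class TestTrajectoryRule:
    @pytest.mark.parametrize(
        "traj,params,expected",
        [
            # sustained rise: 12 > 2*5 and 20 > 12
            ((5, 12, 20), dict(pseudocount=0.0), True),
            # "more than twice" is strict: 10 == 2*5 fails
            ((5, 10, 20), dict(pseudocount=0.0), False),
            # 7-DAG tie fails "exceeded"
            ((5, 12, 12), dict(pseudocount=0.0), False),
            # floor gates on max(x3, x7)
            ((0, 8, 9), dict(pseudocount=1.0, fpkm_floor=10.0), False),
            ((0, 8, 9), dict(pseudocount=1.0, fpkm_floor=0.0), True),
        ],
    )
    def test_rule_examples(self, traj, params, expected):
        t = Trajectory(*map(float, traj))
        assert trajectory_upregulated(t, ExtractionParams(**params)) is expected

    def test_scaling_invariance_without_pseudocount(self):
        p = ExtractionParams(pseudocount=0.0)
        rng = np.random.default_rng(3)
        for _ in range(50):
            x = rng.uniform(0.1, 50, size=3)
            scale = rng.uniform(0.01, 100)
            t1 = Trajectory(*x)
            t2 = Trajectory(*(x * scale))
            assert trajectory_upregulated(t1, p) == trajectory_upregulated(t2, p)

    @given(
        x=st.tuples(*[st.floats(0, 1e4) for _ in range(3)]),
        thresholds=st.tuples(st.floats(0.5, 10), st.floats(0.5, 10)),
    )
    @settings(max_examples=200, deadline=None)
    def test_monotone_in_fold_threshold(self, x, thresholds):
        """Raising the fold threshold can only remove genes, never add."""
        lo, hi = sorted(thresholds)
        t = Trajectory(*x)
        passed_hi = trajectory_upregulated(t, ExtractionParams(fold_threshold=hi))
        if passed_hi:
            assert trajectory_upregulated(t, ExtractionParams(fold_threshold=lo))


class TestExtraction:
    def test_planted_genes_in_input_order(self, make_condition_matrix):
        series = {f"g{i}": (5.0, 5.0, 5.0) for i in range(10)}
        for g in ("g2", "g5", "g9"):
            series[g] = (5.0, 12.0, 20.0)
        cond = make_condition_matrix(series)
        recs = extract_upregulated(cond, "P_hybrida", params=ExtractionParams(pseudocount=0.0))
        assert [r.gene_id for r in recs] == ["g2", "g5", "g9"]

    def test_all_zero_matrix_empty(self, make_condition_matrix):
        cond = make_condition_matrix({f"g{i}": (0.0, 0.0, 0.0) for i in range(5)})
        assert extract_upregulated(cond, "P_hybrida") == []

    def test_missing_time_point_errors(self, make_condition_matrix):
        cond = make_condition_matrix({"g": (1.0, 5.0, 9.0)})
        trimmed = cond.data.drop(columns=[("P_hybrida", "interfamily", 7)])
        from grafttx.expression import ConditionMatrix

        with pytest.raises(KeyError, match="interfamily"):
            extract_upregulated(ConditionMatrix(trimmed), "P_hybrida")

    def test_noisy_recovery_jaccard(self):
        """At sigma=0.05 the rule recovers the planted set almost exactly."""
        cfg = SimConfig(n_genes=1000, noise_sd=0.05, seed=1)
        bundles, truth = generate_expression(cfg)
        sp = cfg.species[0]
        cond = aggregate_replicates(*bundles[sp])
        got = {r.gene_id for r in extract_upregulated(cond, sp)}
        want = truth.planted_set(sp)
        assert len(got & want) / len(got | want) >= 0.95


class TestClassification:
    def _rec(self, self_traj, wound_traj):
        return UpregulationRecord(
            "g",
            {
                "interfamily": Trajectory(5, 12, 25),
                "self": Trajectory(*map(float, self_traj)),
                "wound": Trajectory(*map(float, wound_traj)),
            },
            passed=True,
        )

    @pytest.mark.parametrize(
        "self_traj,wound_traj,expected",
        [
            ((5, 12, 20), (5, 12, 8), 1),  # wound response fades by 7 DAG
            ((5, 6, 6), (5, 6, 5), 2),  # interfamily-specific
            ((5, 12, 20), (5, 12, 20), 3),  # generic wound response
            ((5, 6, 6), (5, 12, 20), 4),  # wound-only rise
        ],
    )
    def test_class_signatures(self, self_traj, wound_traj, expected):
        p = ExtractionParams(pseudocount=0.0)
        assert classify_gene(self._rec(self_traj, wound_traj), p) == expected

    def test_classification_ignores_floor(self):
        """The FPKM floor applies to extraction, not to the class predicate."""
        rec = self._rec((5, 12, 20), (5, 6, 6))
        assert classify_gene(rec, ExtractionParams(pseudocount=0.0, fpkm_floor=1e6)) == 1

    def test_unpassed_gene_rejected(self):
        rec = UpregulationRecord("g", {}, passed=False)
        with pytest.raises(ValueError, match="not extracted"):
            classify_gene(rec)

    def test_counts_partition_extracted_set(self):
        p = ExtractionParams(pseudocount=0.0)
        recs = [
            self._rec((5, 12, 20), (5, 12, 8)),
            self._rec((5, 6, 6), (5, 6, 5)),
            self._rec((5, 12, 20), (5, 12, 20)),
            self._rec((5, 6, 6), (5, 12, 20)),
        ]
        counts = classify_set(recs, p)
        assert counts == {1: 1, 2: 1, 3: 1, 4: 1}
        assert sum(counts.values()) == len(recs)
        assert classify_set([], p) == {1: 0, 2: 0, 3: 0, 4: 0}

    def test_class_recovery_on_planted_proportions(self):
        """Planted class mix (0.2, 0.3, 0.25, 0.25) is recovered at >= 90%."""
        cfg = SimConfig(
            n_genes=400,
            class_fractions={1: 0.2, 2: 0.3, 3: 0.25, 4: 0.25},
            noise_sd=0.05,
            seed=7,
        )
        bundles, truth = generate_expression(cfg)
        sp = cfg.species[0]
        recs = extract_upregulated(aggregate_replicates(*bundles[sp]), sp)
        classify_set(recs)
        assigned = {r.gene_id: r.class_label for r in recs}
        for c in (1, 2, 3, 4):
            planted = truth.planted_set(sp, classes={c})
            correct = sum(1 for g in planted if assigned.get(g) == c)
            assert correct / len(planted) >= 0.9
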