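"""Cell-state catalog, expression transforms, assignment and clustering."""

import warnings

import numpy as np
import pandas as pd
import pytest

import endonet as en
from endonet.state_matching import (PANCREAS_STABLE_TYPES, assign_cells,
                                    binarize_expression, catalog_from_atlas,
                                    correlation_cluster, transform_expression)
from endonet.synthetic import GeneratorSpec, generate_cells


class TestCatalog:
    def test_eleven_distinct_stable_patterns(self, catalog):
        assert len(catalog) == 11
        assert len({tuple(p) for p in catalog.patterns}) == 11

    def test_all_zero_attractor_gives_all_zero_pattern(self, catalog):
        i = catalog.labels.index("S1")
        assert not catalog.patterns[i].any()

    def test_threshold_binarization(self, atlas):
        s = atlas.get("S2")  # ductal-like: SOX9/HES1 high, rest low
        pat = s.binarize(0.5)
        assert set(pat) <= {0, 1}
        assert pat[3] == 1 and pat[4] == 1 and pat[0] == 0

    def test_annotations_attached(self, atlas):
        cat = catalog_from_atlas(atlas, annotations={"S1": "expresses no major marker"})
        assert "no major marker" in cat.to_frame().set_index("label").loc["S1", "annotation"]

    def test_colliding_patterns_warn_but_are_kept(self, atlas):
        with pytest.warns(UserWarning, match="same binary pattern"):
            cat = catalog_from_atlas(atlas, include_transition=True)
        assert len(cat) == 27


class TestCellTypeAnnotation:
    def test_marker_patterns_identify_all_lineage_states(self, cell_types):
        expected = set(PANCREAS_STABLE_TYPES) | {"MP", "EEP", "LEP"}
        assert expected <= set(cell_types)

    def test_saddle_cell_types_are_transition_states(self, atlas, cell_types):
        for name in ("MP", "EEP", "LEP"):
            assert atlas.get(cell_types[name]).classification == "transition"

    def test_progenitor_hierarchy_wiring(self, graph, cell_types):
        # MP bifurcates to TiP and TrP; LEP bifurcates to the islet fates
        assert set(graph.successors(cell_types["MP"])) == \
            {cell_types["TiP"], cell_types["TrP"]}
        assert set(graph.successors(cell_types["LEP"])) == \
            {cell_types["Ialpha"], cell_types["Ibeta"]}


class TestTransform:
    def test_pseudocount(self):
        m = pd.DataFrame([[0.0, 9.0]], index=["g"], columns=["c1", "c2"])
        out = transform_expression(m, "count")
        assert out.iloc[0, 0] == 1.0 and out.iloc[0, 1] == 10.0

    def test_log2_of_unit_value_is_zero(self):
        m = pd.DataFrame([[0.0]], index=["g"], columns=["c"])
        assert transform_expression(m, "tpm", log2=True).iloc[0, 0] == 0.0

    def test_negative_values_rejected(self):
        m = pd.DataFrame([[-1.0]], index=["g"], columns=["c"])
        with pytest.raises(ValueError):
            transform_expression(m, "count")

    def test_invalid_mode_rejected(self):
        with pytest.raises(ValueError):
            transform_expression(pd.DataFrame([[1.0]]), "fpkm")

    def test_binarization_consistent_across_transforms(self):
        raw = pd.DataFrame([[0, 3, 5, 80]], index=["g"],
                           columns=list("abcd"), dtype=float)
        b_raw = binarize_expression(raw)
        b_shift = binarize_expression(transform_expression(raw, "count"))
        b_log = binarize_expression(transform_expression(raw, "count", log2=True))
        for b in (b_shift, b_log):
            np.testing.assert_array_equal(b_raw.values, b.values)
        np.testing.assert_array_equal(b_raw.values, [[0, 0, 1, 1]])


class TestAssignment:
    def test_zero_noise_cells_fully_recovered(self, catalog):
        spec = GeneratorSpec(catalog=catalog, cells_per_state=20,
                             on_mean=100.0, off_mean=1e-6, dispersion=1e6,
                             dropout_prob=0.0, seed=0)
        M, truth = generate_cells(spec)
        asn = assign_cells(transform_expression(M, "count"), catalog)
        assert asn.labels == list(truth)

    def test_all_zero_cell_gets_all_off_state(self, catalog):
        genes = catalog.genes
        m = pd.DataFrame(np.zeros((len(genes), 1)), index=genes, columns=["c"])
        asn = assign_cells(m, catalog)
        assert asn.labels == ["S1"]

    def test_missing_core_gene_rejected_and_gene_map_fixes_it(self, catalog):
        genes = ["Pdx1_mouse"] + catalog.genes[1:]
        m = pd.DataFrame(np.zeros((len(genes), 1)), index=genes, columns=["c"])
        with pytest.raises(KeyError, match="PDX1"):
            assign_cells(m, catalog)
        asn = assign_cells(m, catalog, gene_map={"PDX1": "Pdx1_mouse"})
        assert asn.labels == ["S1"]

    def test_counts_sum_to_total_cells(self, catalog):
        M, _ = generate_cells(GeneratorSpec(catalog=catalog, cells_per_state=30, seed=3))
        asn = assign_cells(transform_expression(M, "count"), catalog)
        assert asn.summary.n_cells.sum() == M.shape[1]

    def test_assignment_independent_of_cell_order(self, catalog):
        M, _ = generate_cells(GeneratorSpec(catalog=catalog, cells_per_state=25, seed=4))
        asn = assign_cells(M, catalog)
        rng = np.random.default_rng(0)
        perm = rng.permutation(M.shape[1])
        asn_p = assign_cells(M.iloc[:, perm], catalog)
        assert [asn.labels[i] for i in perm] == asn_p.labels
        pd.testing.assert_frame_equal(asn.summary, asn_p.summary)

    def test_noisy_recovery_matches_independent_resimulation(self, catalog):
        """Exact-pattern recovery under the default noise model agrees with
        an independently coded per-gene Bernoulli oracle within Monte-Carlo
        error."""
        spec = GeneratorSpec(catalog=catalog, cells_per_state=200, seed=1)
        M, truth = generate_cells(spec)
        asn = assign_cells(transform_expression(M, "count"), catalog)
        observed = np.mean([a == t for a, t in zip(asn.labels, truth)])
        # oracle: simulate the per-gene detection outcome directly
        rng = np.random.default_rng(12345)
        n_mc = 20000
        from endonet.state_matching import DETECTION_MIN
        hits = 0
        n_states = len(catalog)
        for _ in range(n_mc):
            pat = catalog.patterns[rng.integers(n_states)]
            ok = True
            for bit in pat:
                mean = spec.on_mean if bit else spec.off_mean
                c = rng.negative_binomial(spec.dispersion,
                                          spec.dispersion / (spec.dispersion + mean))
                if bit and rng.random() < spec.dropout_prob:
                    c = 0
                if (c >= DETECTION_MIN) != bool(bit):
                    ok = False
                    break
            hits += ok
        expected = hits / n_mc
        se = np.sqrt(expected * (1 - expected) * (1 / n_mc + 1 / len(truth)))
        assert abs(observed - expected) < 4 * se + 0.01


class TestClustering:
    def test_duplicated_blocks_recovered_exactly(self):
        rng = np.random.default_rng(0)
        a = rng.uniform(0, 1, 10)
        b = rng.uniform(0, 1, 10)
        m = pd.DataFrame(np.column_stack([a, a, a, b, b, b]),
                         index=[f"g{i}" for i in range(10)],
                         columns=[f"c{i}" for i in range(6)])
        labels = correlation_cluster(m, 2)
        assert len(set(labels[:3])) == 1 and len(set(labels[3:])) == 1
        assert labels[0] != labels[3]

    def test_k1_is_single_group(self):
        m = pd.DataFrame(np.random.default_rng(0).uniform(size=(5, 4)))
        assert set(correlation_cluster(m, 1)) == {1}

    def test_too_few_cells_rejected(self):
        m = pd.DataFrame(np.ones((5, 2)))
        with pytest.raises(ValueError):
            correlation_cluster(m, 3)

    def test_four_state_mixture_recovers_groups(self, catalog):
        """Correlation-distance clustering of a noisy 4-state mixture aligns
        with the generating states (median adjusted Rand index > 0.9)."""
        from sklearn.metrics import adjusted_rand_score

        scores = []
        for seed in range(1, 11):
            M, truth = generate_cells(GeneratorSpec(
                catalog=catalog, seed=seed,
                cells_per_state={"S2": 60, "S6": 60, "S7": 60, "S11": 60}))
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", UserWarning)
                labels = correlation_cluster(
                    transform_expression(M.loc[catalog.genes], "count", log2=True), 4)
            scores.append(adjusted_rand_score(truth, labels))
        assert np.median(scores) > 0.9

    def test_endocrine_lineage_states_all_detected(self, catalog, cell_types, atlas):
        """Cells generated at the endocrine-lineage attractor patterns are all
        recovered by exact matching (the scRNA-seq validation logic)."""
        lineage = {cell_types[n] for n in ("TrP", "Ialpha", "Ibeta")}
        M, truth = generate_cells(GeneratorSpec(
            catalog=catalog, cells_per_state={l: 100 for l in lineage}, seed=6))
        asn = assign_cells(transform_expression(M, "count"), catalog)
        assert lineage <= set(asn.labels)
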