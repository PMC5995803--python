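import numpy as np
import pandas as pd
import pytest

from brainsig.io import LabeledCountMatrix
from brainsig.signatures import (
    NormalizationParams,
    ReferenceCellSet,
    absolute_expression,
    bh_adjust,
    enrichment,
    filter_expressed,
    make_reference_set,
    quantile_normalize,
    shrunken_group_logfc,
    specificity,
    volcano_flags,
)
from brainsig.simulate import SimulationConfig, simulate_cells


def _matrix(counts: dict, labels: list, index) -> LabeledCountMatrix:
    df = pd.DataFrame(counts, index=index)
    return LabeledCountMatrix(df, pd.Series(labels, index=df.columns))


class TestReferenceSets:
    def test_mol_opc_mutually_excluded(self):
        ref = make_reference_set("MOL", ["AST", "END", "MIC", "NEU", "MOL", "OPC"])
        assert "OPC" not in ref.reference
        ref = make_reference_set("OPC", ["AST", "MOL", "OPC"])
        assert ref.reference == ("AST",)
        with pytest.raises(ValueError):
            ReferenceCellSet(target="OPC", reference=("MOL",))
        with pytest.raises(ValueError):
            ReferenceCellSet(target="AST", reference=("AST", "NEU"))


class TestFilterExpressed:
    def test_group_mean_threshold_boundary_inclusive(self):
        # best-group means: 6.0 (kept), 5.0 (kept, >= is inclusive), 4.5 (dropped)
        m = _matrix(
            {
                "a1": [6, 5, 5],
                "a2": [6, 5, 4],
                "n1": [0, 0, 0],
                "n2": [0, 0, 1],
            },
            ["AST", "AST", "NEU", "NEU"],
            ["g_keep_hi", "g_keep_eq", "g_drop"],
        )
        kept = filter_expressed(m, NormalizationParams(min_mean_count=5))
        assert list(kept.gene_ids) == ["g_keep_hi", "g_keep_eq"]

    def test_empty_result_is_an_error(self, tiny_matrix):
        with pytest.raises(ValueError, match="no genes pass"):
            filter_expressed(tiny_matrix, NormalizationParams(min_mean_count=1e6))


class TestShrunkenLogFC:
    def test_hand_computed_value(self):
        # equal libraries 1e6, prior 10, group means 80 vs 5 -> log2(90/15)
        counts = pd.DataFrame(
            {
                "a1": [80, 10**6 - 80],
                "a2": [80, 10**6 - 80],
                "b1": [5, 10**6 - 5],
                "b2": [5, 10**6 - 5],
            },
            index=["g", "fill"],
        )
        m = LabeledCountMatrix(counts, pd.Series(["A", "A", "B", "B"], index=counts.columns))
        fc = shrunken_group_logfc(m, ["a1", "a2"], ["b1", "b2"], NormalizationParams())
        assert fc["g"] == pytest.approx(np.log2(6), abs=1e-12)

    def test_identical_groups_and_all_zero_gene_give_zero(self):
        counts = pd.DataFrame(
            {"a1": [7, 0, 100], "a2": [7, 0, 100], "b1": [7, 0, 100], "b2": [7, 0, 100]},
            index=["same", "zero", "fill"],
        )
        m = LabeledCountMatrix(counts, pd.Series(["A", "A", "B", "B"], index=counts.columns))
        fc = shrunken_group_logfc(m, ["a1", "a2"], ["b1", "b2"])
        assert fc["same"] == pytest.approx(0.0, abs=1e-12)
        assert fc["zero"] == pytest.approx(0.0, abs=1e-12)

    def test_empty_group_rejected(self, tiny_matrix):
        with pytest.raises(ValueError):
            shrunken_group_logfc(tiny_matrix, [], ["b1"])

    def test_shrinkage_monotone_in_prior(self):
        cfg = SimulationConfig(
            n_genes=500, cell_types=("A", "B"), n_markers_per_type=50, seed=3
        )
        m, _ = simulate_cells(cfg)
        a, b = m.samples_of("A"), m.samples_of("B")
        prev = None
        for prior in (0, 1, 10, 100):
            fc = shrunken_group_logfc(m, a, b, NormalizationParams(prior_count=prior)).abs()
            if prev is not None:
                assert (fc <= prev + 1e-9).all()
            prev = fc


class TestQuantileNormalize:
    def test_permuted_samples_share_sorted_values(self, rng):
        base = rng.integers(0, 500, size=60)
        df = pd.DataFrame({"s1": base, "s2": rng.permutation(base), "s3": rng.permutation(base)})
        qn = quantile_normalize(df)
        for col in qn.columns[1:]:
            assert np.allclose(np.sort(qn["s1"]), np.sort(qn[col]))

    def test_ties_get_mean_of_target_values(self):
        df = pd.DataFrame({"s1": [0.0, 0.0, 10.0], "s2": [1.0, 2.0, 3.0]})
        qn = quantile_normalize(df)
        ref = np.sort(df.to_numpy(), axis=0).mean(axis=1)  # [0.5, 1.0, 6.5]
        assert qn["s1"].iloc[0] == qn["s1"].iloc[1] == pytest.approx(ref[:2].mean())
        assert qn["s1"].iloc[2] == pytest.approx(ref[2])


class TestEnrichmentAndSpecificity:
    def test_fourfold_difference_approaches_two_at_high_counts(self):
        # 4x counts at high expression, equal libraries: shrinkage vanishes
        n = 4
        counts = pd.DataFrame(
            {
                **{f"a{i}": [400000, 600000] for i in range(n)},
                **{f"b{i}": [100000, 900000] for i in range(n)},
            },
            index=["g", "fill"],
        )
        m = LabeledCountMatrix(
            counts, pd.Series(["T"] * n + ["R"] * n, index=counts.columns)
        )
        tab = enrichment(m, "T", compute_pvalues=False).set_index("gene_id")
        assert tab.loc["g", "stat"] == pytest.approx(2.0, abs=1e-3)

    def test_two_cell_types_make_specificity_equal_enrichment(self, rng):
        cfg = SimulationConfig(
            n_genes=120, cell_types=("AST", "NEU"), n_markers_per_type=10,
            cells_per_type=10, seed=7,
        )
        m, _ = simulate_cells(cfg)
        e = enrichment(m, "AST", compute_pvalues=False).set_index("gene_id")["stat"]
        s = specificity(m, "AST", compute_pvalues=False).set_index("gene_id")["stat"]
        assert np.allclose(e.sort_index(), s.sort_index())

    def test_shared_high_gene_specific_nowhere_but_enriched(self):
        # high in AST and END, low elsewhere: AST specificity ~0, enrichment > 0
        rng = np.random.default_rng(0)
        genes = ["shared", "fill"]
        cols, labels, data = [], [], []
        for ct, level in [("AST", 800), ("END", 800), ("MIC", 20), ("NEU", 20)]:
            for i in range(6):
                cols.append(f"{ct}{i}")
                labels.append(ct)
                data.append([level, 5000])
        counts = pd.DataFrame(np.array(data).T, index=genes, columns=cols)
        m = LabeledCountMatrix(counts, pd.Series(labels, index=cols))
        spec = specificity(m, "AST", compute_pvalues=False).set_index("gene_id")
        enr = enrichment(m, "AST", compute_pvalues=False).set_index("gene_id")
        assert abs(spec.loc["shared", "stat"]) < 0.1
        assert enr.loc["shared", "stat"] > 1.0

    def test_planted_marker_effect_recovered(self, sim_default):
        cfg, m, truth = sim_default
        m = filter_expressed(m)
        planted = [g for g, ct in truth.marker_assignments.items() if ct == "AST"]
        enr = enrichment(m, "AST", compute_pvalues=False).set_index("gene_id")
        spec = specificity(m, "AST", compute_pvalues=False).set_index("gene_id")
        # shrinkage pulls the estimate slightly below the planted effect; the
        # typical estimate stays within +/-0.3 and no marker strays past 0.5
        assert abs(enr.loc[planted, "stat"].median() - cfg.marker_log2_effect) < 0.3
        assert (enr.loc[planted, "stat"] - cfg.marker_log2_effect).abs().max() < 0.5
        assert abs(spec.loc[planted, "stat"].median() - cfg.marker_log2_effect) < 0.3
        assert (spec.loc[planted, "stat"] - cfg.marker_log2_effect).abs().max() < 0.5

    def test_planted_marker_significant(self):
        cfg = SimulationConfig(n_genes=300, n_markers_per_type=5, seed=9)
        m, truth = simulate_cells(cfg)
        m = filter_expressed(m)
        tab = enrichment(m, "AST").set_index("gene_id")
        planted = [g for g, ct in truth.marker_assignments.items() if ct == "AST"]
        assert (tab.loc[planted, "adj_p"] < 0.05).all()

    def test_specificity_not_above_any_pairwise_logfc(self, sim_default):
        cfg, m, truth = sim_default
        m = filter_expressed(m)
        refset = make_reference_set("MIC", m.cell_types())
        spec = specificity(m, "MIC", refset, compute_pvalues=False).set_index("gene_id")["stat"]
        tgt = m.samples_of("MIC")
        for r in refset.reference:
            pair = shrunken_group_logfc(m, tgt, m.samples_of(r))
            assert (spec.sort_index() <= pair.sort_index() + 1e-9).all()

    def test_enrichment_between_pairwise_extremes_with_balanced_groups(self):
        # equal group sizes and library sizes: pooled-mean CPM is the mean of
        # group means, so enrichment must lie within the pairwise FC envelope
        rng = np.random.default_rng(42)
        types = ["AST", "NEU", "MIC"]
        mat = rng.integers(10, 200, size=(30, 12))
        cols = [f"{t}{i}" for t in types for i in range(4)]
        labels = [t for t in types for _ in range(4)]
        counts = pd.DataFrame(mat, index=[f"g{i}" for i in range(30)], columns=cols)
        # force equal library sizes by padding a filler gene
        lib = counts.sum(axis=0)
        counts.loc["fill"] = int(lib.max()) - lib + 1000
        m = LabeledCountMatrix(counts, pd.Series(labels, index=cols))
        enr = enrichment(m, "AST", compute_pvalues=False).set_index("gene_id")["stat"]
        pair = pd.DataFrame(
            {
                r: shrunken_group_logfc(m, m.samples_of("AST"), m.samples_of(r))
                for r in ("NEU", "MIC")
            }
        )
        assert (enr.sort_index() >= pair.min(axis=1).sort_index() - 1e-9).all()
        assert (enr.sort_index() <= pair.max(axis=1).sort_index() + 1e-9).all()

    def test_confounded_covariate_raises_naming_it(self):
        cfg = SimulationConfig(
            n_genes=60, cell_types=("AST", "NEU"), n_markers_per_type=5,
            cells_per_type=5, seed=1,
        )
        m, _ = simulate_cells(cfg)
        m.covariates["batch"] = (m.cell_type == "AST").astype(float)
        with pytest.raises(ValueError, match="batch"):
            enrichment(m, "AST", covariates=["batch"])


class TestNullBehaviour:
    def test_null_type_one_error_and_no_volcano_hits(self):
        cfg = SimulationConfig(n_genes=2000, marker_log2_effect=0.0, seed=11)
        m, _ = simulate_cells(cfg)
        m = filter_expressed(m)
        tab = enrichment(m, "AST")
        frac = float(np.nanmean(tab["p_value"] < 0.05))
        assert 0.02 <= frac <= 0.10
        assert volcano_flags(tab).sum() == 0
        assert float(np.nanmean(tab["adj_p"] < 0.05)) <= 0.1


class TestAbsoluteExpression:
    def test_single_sample_rpkm(self):
        counts = pd.DataFrame({"s1": [200, 10**6 - 200]}, index=["g", "fill"])
        m = LabeledCountMatrix(counts, pd.Series(["AST"], index=["s1"]))
        lengths = pd.Series({"g": 2000, "fill": 1000})
        tab = absolute_expression(m, lengths, "AST").set_index("gene_id")
        assert tab.loc["g", "stat"] == pytest.approx(100.0)

    def test_ranking_and_missing_lengths(self, tiny_matrix):
        lengths = pd.Series({"g1": 1000, "g2": 1000})  # g3 missing -> dropped
        tab = absolute_expression(tiny_matrix, lengths, "AST")
        assert set(tab["gene_id"]) == {"g1", "g2"}
        by_rank = tab.sort_values("rank")
        assert list(by_rank["gene_id"]) == ["g1", "g2"]  # g1 higher in AST
        assert list(by_rank["rank"]) == [1, 2]


class TestVolcanoAndBH:
    @pytest.mark.parametrize(
        "stat,adj_p,expected",
        [(2.0, 0.049, True), (1.99, 1e-10, False), (2.0, 0.05, False)],
    )
    def test_volcano_thresholds(self, stat, adj_p, expected):
        rows = pd.DataFrame({"stat": [stat], "adj_p": [adj_p]})
        assert bool(volcano_flags(rows).item()) == expected

    def test_bh_matches_brute_force_oracle(self, rng):
        def bh_oracle(p):
            n = len(p)
            order = np.argsort(p)
            adj = np.empty(n)
            running = 1.0
            for i in range(n - 1, -1, -1):
                running = min(running, p[order[i]] * n / (i + 1))
                adj[order[i]] = running
            return adj

        for _ in range(20):
            p = rng.random(rng.integers(3, 60))
            assert np.allclose(bh_adjust(p), bh_oracle(p))

    def test_bh_monotone_in_p_rank(self, rng):
        p = rng.random(200)
        adj = bh_adjust(p)
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-12).all()
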