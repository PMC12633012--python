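import numpy as np
import pandas as pd
import pytest

from alveoniche import qc, signatures, synthetic
from alveoniche.datatypes import GeneSignature
from alveoniche.signatures import (
    assign_at2_state,
    assign_labels_nearest_centroid,
    build_maturation_sets,
    build_signature,
    rank_markers,
    score_maturation,
    score_modules,
)
from conftest import make_count_matrix


@pytest.fixture(scope="module")
def state_cohort():
    cfg = synthetic.CohortConfig(
        n_specimens_per_class=2, cells_per_specimen=300, seed=21
    )
    cm, gt = synthetic.generate_expression_cohort(cfg)
    norm = qc.normalize_counts(cm)
    return norm, gt


class TestRankMarkers:
    def test_planted_marker_recovered(self, state_cohort):
        norm, gt = state_cohort
        types = gt.cell_truth["cell_type"].to_numpy()
        mr = rank_markers(norm, types, "AT2", "AT1")
        planted = set(gt.markers_of("AT2"))
        found = planted & set(mr.index[mr["log2fc"] > 0])
        assert len(found) >= 0.9 * len(planted)
        sig = mr.loc[sorted(found)]
        assert (sig["p_adjusted"] < 0.05).all()

    def test_pct_filter_excludes(self):
        # gene 0 expressed in 20% of g1, 10% of g2 -> excluded at min_pct=0.25
        x = np.zeros((2, 20))
        x[0, :2] = 1.0  # 2/10 of group1
        x[0, 10] = 1.0  # 1/10 of group2
        x[1] = np.linspace(1, 2, 20)  # keeps the matrix non-degenerate
        m = make_count_matrix(np.ones((2, 20), dtype=int))
        norm = qc.normalize_counts(m)
        norm.values = __import__("scipy.sparse", fromlist=["csr_matrix"]).csr_matrix(x)
        labels = ["g1"] * 10 + ["g2"] * 10
        mr = rank_markers(norm, labels, "g1", "g2", min_pct=0.25, min_logfc=0.0)
        assert "g0" not in mr.index

    def test_exclude_patterns(self, state_cohort):
        norm, gt = state_cohort
        types = gt.cell_truth["cell_type"].to_numpy()
        mr = rank_markers(norm, types, "AT2", "AT1", min_pct=0.0, min_logfc=0.0)
        assert not any(g.startswith(("MT-", "RPS", "RPL")) for g in mr.index)

    def test_overlap_error(self, state_cohort):
        norm, gt = state_cohort
        types = gt.cell_truth["cell_type"].to_numpy()
        with pytest.raises(ValueError, match="overlap"):
            rank_markers(norm, types, "AT2", ["AT2", "AT1"])

    def test_adjusted_ge_raw(self, state_cohort):
        norm, gt = state_cohort
        types = gt.cell_truth["cell_type"].to_numpy()
        mr = rank_markers(norm, types, "AT2", "AT1")
        assert (mr["p_adjusted"] >= mr["p"] - 1e-15).all()

    def test_type_one_error_calibration(self, state_cohort):
        norm, gt = state_cohort
        rng = np.random.default_rng(99)
        sub = norm.subset_cells(np.arange(400))
        sub = signatures.NormalizedMatrix(
            genes=sub.genes[:200], cells=sub.cells, values=sub.values[:200],
            scale_factor=sub.scale_factor, cell_meta=sub.cell_meta,
        )
        hits = total = 0
        for _ in range(20):
            labels = rng.permutation(["a"] * 200 + ["b"] * 200)
            p = signatures.rank_sum_pvalues_all_genes(sub, labels, "a", "b")
            hits += (p < 0.05).sum()
            total += len(p)
        assert 0.03 <= hits / total <= 0.07


class TestBuildSignature:
    def _mr(self, rows):
        return pd.DataFrame(rows).set_index("gene")

    def test_top_two_up(self):
        mr = self._mr([
            {"gene": "a", "log2fc": 2.0, "p": 0.01},
            {"gene": "b", "log2fc": 1.0, "p": 0.01},
            {"gene": "c", "log2fc": 0.5, "p": 0.01},
        ])
        sig = build_signature(mr, 2, "up")
        assert sig.genes == ["a", "b"]

    def test_tie_broken_by_p_then_gene(self):
        mr = self._mr([
            {"gene": "z", "log2fc": 1.0, "p": 0.001},
            {"gene": "a", "log2fc": 1.0, "p": 0.01},
            {"gene": "b", "log2fc": 1.0, "p": 0.01},
        ])
        sig = build_signature(mr, 3, "up")
        assert sig.genes == ["z", "a", "b"]

    def test_down_direction(self):
        mr = self._mr([
            {"gene": "a", "log2fc": -2.0, "p": 0.01},
            {"gene": "b", "log2fc": 1.0, "p": 0.01},
        ])
        sig = build_signature(mr, 1, "down")
        assert sig.genes == ["a"]

    def test_short_list_warns(self):
        mr = self._mr([{"gene": "a", "log2fc": 1.0, "p": 0.01}])
        with pytest.warns(UserWarning, match="only 1"):
            sig = build_signature(mr, 5, "up")
        assert sig.genes == ["a"]

    def test_empty_errors(self):
        empty = pd.DataFrame(columns=["log2fc", "p"], index=pd.Index([], name="gene"))
        with pytest.raises(ValueError, match="empty"):
            build_signature(empty, 5, "up")

    def test_gene_order_permutation_invariant(self, rng):
        rows = [
            {"gene": f"g{i}", "log2fc": float(f), "p": float(p)}
            for i, (f, p) in enumerate(zip(rng.random(20), rng.random(20)))
        ]
        mr = self._mr(rows)
        shuffled = mr.sample(frac=1.0, random_state=1)
        assert build_signature(mr, 10, "up").genes == build_signature(shuffled, 10, "up").genes


class TestScoreModules:
    def test_degenerate_binning_equals_direct_contrast(self, rng):
        counts = rng.poisson(5.0, size=(4, 6)) + 1
        m = make_count_matrix(counts)
        norm = qc.normalize_counts(m)
        sig = GeneSignature("mod", ["g1"])
        ms = score_modules(norm, [sig], n_bins=1, n_controls=3, seed=0)
        dense = norm.dense()
        expected = dense[1] - dense[[0, 2, 3]].mean(axis=0)
        np.testing.assert_allclose(ms.scores["mod"].to_numpy(), expected, atol=1e-12)

    def test_seed_determinism(self, state_cohort):
        norm, gt = state_cohort
        sig = GeneSignature("s", gt.markers_of("AT2")[:20])
        a = score_modules(norm, [sig], seed=5).scores
        b = score_modules(norm, [sig], seed=5).scores
        pd.testing.assert_frame_equal(a, b)
        c = score_modules(norm, [sig], seed=6).scores
        assert not np.allclose(a["s"], c["s"])

    def test_planted_module_separates(self, state_cohort):
        norm, gt = state_cohort
        sig = GeneSignature("at2", gt.markers_of("AT2"))
        ms = score_modules(norm, [sig], seed=0)
        at2 = (gt.cell_truth["cell_type"] == "AT2").to_numpy()
        s = ms.scores["at2"].to_numpy()
        from scipy.stats import mannwhitneyu

        p = mannwhitneyu(s[at2], s[~at2], alternative="greater").pvalue
        assert p < 1e-6

    def test_missing_genes_dropped_with_warning(self, state_cohort):
        norm, gt = state_cohort
        sig = GeneSignature("s", gt.markers_of("AT2")[:5] + ["NOT_A_GENE"])
        with pytest.warns(UserWarning, match="dropping 1"):
            score_modules(norm, [sig], seed=0)

    def test_all_missing_errors(self, state_cohort):
        norm, _ = state_cohort
        with pytest.warns(UserWarning):
            with pytest.raises(ValueError, match="no genes"):
                score_modules(norm, [GeneSignature("s", ["NOPE"])], seed=0)


class TestAssignState:
    def _panel(self, f, c):
        return pd.DataFrame({"fmo5": f, "cftr": c}, index=[f"c{i}" for i in range(len(f))])

    def test_panel_rules(self):
        counts = self._panel([5, 1, 0, 3, 2], [0, 1, 5, 3, 4])
        out = assign_at2_state(None, mode="panel_counts", panel_counts=counts)
        assert list(out) == ["FMO5+", "Unassigned", "CFTR+", "Unassigned", "CFTR+"]

    def test_score_mode(self):
        scores = pd.DataFrame(
            {"f": [1.0, -0.5, 0.2], "c": [0.2, -0.2, 0.2]}, index=["a", "b", "c"]
        )
        out = assign_at2_state(None, scores=scores, tau=0.0)
        assert list(out) == ["FMO5+", "Unassigned", "Unassigned"]  # tie -> Unassigned

    def test_spatial_state_recovery(self):
        cfg = synthetic.SpatialConfig(n_sections=1, cells_per_section=2000, seed=31)
        ccfg = synthetic.CohortConfig(seed=31)
        secs, gt = synthetic.generate_spatial_sections(cfg, ccfg)
        s = secs[0]
        model = synthetic.ExpressionModel(ccfg)
        panels = synthetic.state_panel_genes(model)
        gidx = {g: i for i, g in enumerate(s.panel_genes)}
        dense = np.asarray(s.panel_counts.todense())
        f_idx = [gidx[g] for g in panels["FMO5+"] if g in gidx]
        c_idx = [gidx[g] for g in panels["CFTR+"] if g in gidx]
        counts = pd.DataFrame(
            {
                "fmo5": dense[f_idx].sum(axis=0),
                "cftr": dense[c_idx].sum(axis=0),
            },
            index=s.cells["cell_id"],
        )
        at2 = s.cells["label"].isin(["AT2_FMO5", "AT2_CFTR"]).to_numpy()
        out = assign_at2_state(None, mode="panel_counts", panel_counts=counts[at2])
        truth = s.cells.loc[at2, "label"].map(
            {"AT2_FMO5": "FMO5+", "AT2_CFTR": "CFTR+"}
        ).to_numpy()
        assigned = out.to_numpy() != "Unassigned"
        acc = (out.to_numpy()[assigned] == truth[assigned]).mean()
        assert assigned.mean() > 0.5
        assert acc >= 0.90


class TestMaturation:
    @pytest.fixture(scope="class")
    def series(self):
        cfg = synthetic.CohortConfig(
            n_specimens_per_class=1, cells_per_specimen=250, seed=51,
            cell_type_catalog={"AT2": 0.5, "AT1": 0.3, "AF_c1": 0.2},
        )
        cm, gt = synthetic.generate_maturation_series(
            cfg, stages=("fetal", "s1", "s2", "s3"), program_size=50,
            n_arrest_specimens=1, specimens_per_stage=1,
        )
        norm = qc.normalize_counts(cm)
        return norm, gt

    def test_on_off_disjoint_and_recovered(self, series):
        norm, gt = series
        truth = gt.cell_truth
        normal = ~truth["arrested"].to_numpy()
        ref = norm.subset_cells(normal)
        sets = build_maturation_sets(
            ref, truth.loc[normal, "stage"].to_numpy(),
            truth.loc[normal, "cell_type"].to_numpy(), "fetal", top_n=50,
        )
        for t, d in sets.sets.items():
            assert not (set(d["on"].genes) & set(d["off"].genes))
        on_true = set(gt.program_genes("maturation_on:AT2"))
        assert len(on_true & set(sets.sets["AT2"]["on"].genes)) >= 45

    def test_scores_move_oppositely(self, series):
        norm, gt = series
        truth = gt.cell_truth
        normal = ~truth["arrested"].to_numpy()
        ref = norm.subset_cells(normal)
        sets = build_maturation_sets(
            ref, truth.loc[normal, "stage"].to_numpy(),
            truth.loc[normal, "cell_type"].to_numpy(), "fetal", top_n=50,
        )
        sc = score_maturation(norm, truth["cell_type"].to_numpy(), sets, seed=0)
        sc["stage"] = truth["stage"].to_numpy()
        sc["arrested"] = truth["arrested"].to_numpy()
        per = sc[~sc["arrested"]].groupby("stage")[["on_score", "off_score"]].mean()
        per = per.loc[["fetal", "s1", "s2", "s3"]]
        on = per["on_score"].to_numpy()
        off = per["off_score"].to_numpy()
        assert (np.diff(on) > 0).all()
        assert (np.diff(off) < 0).all()
        # arrest specimen sits between fetal and s2 on-score means
        arr = sc.loc[sc["arrested"], "on_score"].mean()
        assert per.loc["fetal", "on_score"] < arr < per.loc["s2", "on_score"]

    def test_fetal_below_postnatal(self, series):
        norm, gt = series
        truth = gt.cell_truth
        normal = ~truth["arrested"].to_numpy()
        ref = norm.subset_cells(normal)
        sets = build_maturation_sets(
            ref, truth.loc[normal, "stage"].to_numpy(),
            truth.loc[normal, "cell_type"].to_numpy(), "fetal", top_n=50,
        )
        sc = score_maturation(norm, truth["cell_type"].to_numpy(), sets, seed=0)
        fet = sc["on_score"][(truth["stage"] == "fetal").to_numpy()]
        post = sc["on_score"][(truth["stage"] == "s3").to_numpy() & ~truth["arrested"].to_numpy()]
        from scipy.stats import mannwhitneyu

        assert mannwhitneyu(post, fet, alternative="greater").pvalue < 1e-6

    def test_missing_fetal_stage_errors(self, series):
        norm, gt = series
        with pytest.raises(ValueError, match="fetal"):
            build_maturation_sets(
                norm, gt.cell_truth["stage"].to_numpy(),
                gt.cell_truth["cell_type"].to_numpy(), "not_a_stage",
            )


class TestNearestCentroid:
    def test_exact_centroid_match(self):
        centroids = pd.DataFrame(
            {"A": [1.0, 0.0, 2.0], "B": [0.0, 2.0, 1.0]},
            index=["g0", "g1", "g2"],
        )
        m = make_count_matrix(np.array([[10, 0], [0, 20], [20, 10]]))
        norm = qc.normalize_counts(m)
        # cell 0 proportional to centroid A's pattern, cell 1 to B's
        out = assign_labels_nearest_centroid(norm, centroids)
        assert list(out["label"]) == ["A", "B"]
        assert (out["confidence"] > 0).all()

    def test_identical_centroids_tie(self):
        centroids = pd.DataFrame(
            {"b_type": [1.0, 2.0], "a_type": [1.0, 2.0]}, index=["g0", "g1"]
        )
        m = make_count_matrix(np.array([[5], [10]]))
        norm = qc.normalize_counts(m)
        out = assign_labels_nearest_centroid(norm, centroids)
        assert out["label"].iloc[0] == "a_type"  # lexicographic tie-break
        assert out["confidence"].iloc[0] == pytest.approx(0.0)

    def test_constant_cell_unassigned(self):
        centroids = pd.DataFrame({"A": [1.0, 2.0], "B": [2.0, 1.0]}, index=["g0", "g1"])
        m = make_count_matrix(np.array([[5], [5]]))
        norm = qc.normalize_counts(m)
        out = assign_labels_nearest_centroid(norm, centroids)
        assert out["label"].iloc[0] == "Unassigned"

    def test_holdout_accuracy(self, state_cohort):
        norm, gt = state_cohort
        types = gt.cell_truth["cell_type"].to_numpy()
        n = norm.n_cells
        train = np.zeros(n, dtype=bool)
        train[::2] = True
        dense = norm.dense()
        cents = {}
        for t in np.unique(types):
            cents[t] = dense[:, train & (types == t)].mean(axis=1)
        centroids = pd.DataFrame(cents, index=norm.genes)
        query = norm.subset_cells(~train)
        out = assign_labels_nearest_centroid(query, centroids)
        acc = (out["label"].to_numpy() == types[~train]).mean()
        assert acc >= 0.90
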