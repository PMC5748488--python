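import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pairprog import (ExpressionMatrix, PipelineConfig, SWVgModel,
                      apply_frozen, combine_pt_at, fit_swvg, gene_vote,
                      load_ribosomal_panel, scan_cutoff, swvg_score)
from pairprog.swvg import DegenerateScores, PanelGene, StratificationResult

from .conftest import random_survival


class TestGeneVote:
    def test_design2_above_cutoff_votes_hr(self):
        assert gene_vote(5.0, 4.0, 2) == 1

    def test_design1_above_cutoff_votes_lr(self):
        assert gene_vote(5.0, 4.0, 1) == 0

    def test_boundary_on_le_side(self):
        assert gene_vote(4.0, 4.0, 2) == 0
        assert gene_vote(4.0, 4.0, 1) == 1

    @given(st.floats(-50, 50), st.floats(-50, 50))
    @settings(max_examples=100, deadline=None)
    def test_designs_complementary(self, value, cutoff):
        assert gene_vote(value, cutoff, 1) + gene_vote(value, cutoff, 2) == 1


class TestSwvgScore:
    def test_all_zero_votes(self):
        assert swvg_score(np.zeros(5), np.ones(5)) == 0.0

    def test_all_one_votes(self):
        assert swvg_score(np.ones(5), np.ones(5)) == 1.0

    def test_half_votes_equal_weights(self):
        assert swvg_score(np.array([1, 1, 0, 0]), np.ones(4)) == 0.5

    def test_zero_weights_error(self):
        with pytest.raises(ValueError):
            swvg_score(np.ones(3), np.zeros(3))

    @given(st.integers(0, 7))
    @settings(max_examples=50, deadline=None)
    def test_flipping_vote_monotone(self, flip):
        rng = np.random.default_rng(flip)
        weights = rng.random(8) + 0.1
        votes = rng.integers(0, 2, 8).astype(float)
        votes[flip] = 0
        low = swvg_score(votes, weights)
        votes[flip] = 1
        assert swvg_score(votes, weights) >= low


@pytest.fixture
def training_setup():
    """Five informative genes + survival, for classifier fits."""
    rng = np.random.default_rng(5150)
    n = 120
    z = rng.random(n) < 0.4
    genes = [f"G{i}" for i in range(5)]
    vals = np.vstack([8 + 1.8 * z + rng.standard_normal(n) for _ in genes])
    samples = [f"S{j}" for j in range(n)]
    times = rng.exponential(1 / (0.2 * np.exp(1.1 * z)))
    events = (times < 5).astype(float)
    times = np.minimum(times, 5.0)
    surv = pd.DataFrame({"os_years": times, "event": events}, index=samples)
    matrix = ExpressionMatrix(genes, samples, vals)
    cfg = PipelineConfig()
    candidates = {
        g: scan_cutoff(vals[i], times, events, cfg, gene_id=g,
                       sample_ids=samples)
        for i, g in enumerate(genes)
    }
    return matrix, surv, candidates, cfg


class TestFitSwvg:
    def test_single_candidate_reduces_to_gene_split(self, training_setup):
        matrix, surv, candidates, cfg = training_setup
        one = {"G0": candidates["G0"]}
        model = fit_swvg(one, matrix, surv, cfg)
        assert [g.gene_id for g in model.genes] == ["G0"]
        assert model.score_cutoff == 0.5
        strat = apply_frozen(model, matrix)
        expected = candidates["G0"].labels
        got = dict(zip(strat.assignments.index, strat.assignments["label"]))
        assert got == expected

    def test_identical_votes_collapse_to_one_gene(self, training_setup):
        matrix, surv, candidates, cfg = training_setup
        # clone G0's expression row under new names -> identical votes
        base = candidates["G0"]
        vals = np.vstack([matrix.values[0]] * 3)
        clones = ExpressionMatrix(["G0", "C1", "C2"], matrix.sample_ids, vals)
        cand = {}
        for g in clones.gene_ids:
            r = scan_cutoff(vals[0], surv["os_years"].to_numpy(),
                            surv["event"].to_numpy(), cfg, gene_id=g,
                            sample_ids=matrix.sample_ids)
            cand[g] = r
        model = fit_swvg(cand, clones, surv, cfg)
        assert len(model.genes) == 1
        assert model.genes[0].train_wald_p == base.wald_p

    def test_no_candidate_passes_alpha(self, training_setup):
        matrix, surv, candidates, cfg = training_setup
        strict = cfg.with_(alpha_pre=1e-12, alpha_sel=1e-12)
        with pytest.raises(ValueError, match="alpha_sel"):
            fit_swvg(candidates, matrix, surv, strict)

    def test_insample_selection_path(self, training_setup):
        matrix, surv, candidates, cfg = training_setup
        model = fit_swvg(candidates, matrix, surv, cfg, selection="insample")
        assert 1 <= len(model.genes) <= 5
        assert 0 < model.score_cutoff < 1

    def test_weights_are_neg_log10_p(self, training_setup):
        matrix, surv, candidates, cfg = training_setup
        model = fit_swvg(candidates, matrix, surv, cfg)
        for g in model.genes:
            assert g.weight == pytest.approx(-np.log10(g.train_wald_p))


class TestModelSerialization:
    def test_json_round_trip_bit_exact(self, training_setup, tmp_path):
        matrix, surv, candidates, cfg = training_setup
        model = fit_swvg(candidates, matrix, surv, cfg)
        path = tmp_path / "model.json"
        model.to_json(path)
        back = SWVgModel.from_json(path)
        assert back.score_cutoff == model.score_cutoff
        for a, b in zip(back.genes, model.genes):
            assert (a.gene_id, a.cutoff, a.design, a.weight) == \
                   (b.gene_id, b.cutoff, b.design, b.weight)
        # second serialization is byte-identical
        path2 = tmp_path / "model2.json"
        back.to_json(path2)
        assert path.read_text() == path2.read_text()

    def test_invariants_enforced(self):
        good = PanelGene("G1", 1.0, 2, 1.0)
        with pytest.raises(ValueError):
            SWVgModel(genes=[], score_cutoff=0.5)
        with pytest.raises(ValueError):
            SWVgModel(genes=[good], score_cutoff=1.5)
        with pytest.raises(ValueError):
            SWVgModel(genes=[PanelGene("G1", 1.0, 2, 0.0)], score_cutoff=0.5)


class TestApplyFrozen:
    def test_training_labels_reproduced(self, training_setup):
        matrix, surv, candidates, cfg = training_setup
        model = fit_swvg(candidates, matrix, surv, cfg)
        with_surv = apply_frozen(model, matrix, surv)
        without = apply_frozen(model, matrix)
        pd.testing.assert_series_equal(with_surv.assignments["label"],
                                       without.assignments["label"])
        assert without.summary is None
        assert with_surv.summary["n_lr"] + with_surv.summary["n_hr"] == 120

    def test_sample_order_invariance(self, training_setup):
        matrix, surv, candidates, cfg = training_setup
        model = fit_swvg(candidates, matrix, surv, cfg)
        base = apply_frozen(model, matrix)
        rng = np.random.default_rng(3)
        perm = list(rng.permutation(matrix.sample_ids))
        shuffled = apply_frozen(model, matrix.subset_samples(perm))
        for s in matrix.sample_ids:
            assert (shuffled.assignments.loc[s, "label"]
                    == base.assignments.loc[s, "label"])
            assert (shuffled.assignments.loc[s, "score"]
                    == base.assignments.loc[s, "score"])

    def test_missing_panel_gene_errors(self, training_setup):
        matrix, surv, candidates, cfg = training_setup
        model = fit_swvg(candidates, matrix, surv, cfg)
        reduced = matrix.subset_genes([g for g in matrix.gene_ids
                                      if g != model.genes[0].gene_id])
        with pytest.raises(KeyError, match=model.genes[0].gene_id):
            apply_frozen(model, reduced)

    def test_pure_function_of_expression(self, training_setup):
        matrix, surv, candidates, cfg = training_setup
        model = fit_swvg(candidates, matrix, surv, cfg)
        shuffled_surv = surv.sample(frac=1, random_state=1)
        a = apply_frozen(model, matrix, surv)
        b = apply_frozen(model, matrix, shuffled_surv)
        pd.testing.assert_frame_equal(a.assignments, b.assignments)


def strat_from_labels(labels: dict[str, str]) -> StratificationResult:
    frame = pd.DataFrame({
        "score": 0.5, "label": pd.Series(labels),
        "patient_id": list(labels),
    })
    frame.index.name = "sample_id"
    return StratificationResult(assignments=frame, summary=None, flagged=[])


class TestCombinePtAt:
    def test_rule_table(self):
        t = strat_from_labels({"p1": "LR", "p2": "LR", "p3": "HR"})
        a = strat_from_labels({"p1": "LR", "p2": "HR", "p3": "HR"})
        combined = combine_pt_at(t, a)
        assert combined["p1"] == "LR"      # (LR, LR) -> LR
        assert combined["p2"] == "HR"      # (LR, HR) -> HR
        assert combined["p3"] == "HR"      # (HR, HR) -> HR

    def test_set_identity(self, rng):
        patients = [f"p{i}" for i in range(40)]
        lab_t = {p: ("LR" if rng.random() < 0.6 else "HR") for p in patients}
        lab_a = {p: ("LR" if rng.random() < 0.6 else "HR") for p in patients}
        combined = combine_pt_at(strat_from_labels(lab_t),
                                 strat_from_labels(lab_a))
        lr_combined = {p for p, v in combined.items() if v == "LR"}
        lr_t = {p for p, v in lab_t.items() if v == "LR"}
        lr_a = {p for p, v in lab_a.items() if v == "LR"}
        assert lr_combined == lr_t & lr_a

    def test_intersection_only(self):
        t = strat_from_labels({"p1": "LR", "p2": "LR"})
        a = strat_from_labels({"p2": "LR", "p3": "LR"})
        combined = combine_pt_at(t, a)
        assert list(combined.index) == ["p2"]

    def test_empty_intersection_errors(self):
        t = strat_from_labels({"p1": "LR"})
        a = strat_from_labels({"p2": "LR"})
        with pytest.raises(ValueError):
            combine_pt_at(t, a)


class TestPackagedPanel:
    def test_24_genes_with_probe_ids(self):
        panel = load_ribosomal_panel()
        assert len(panel) == 24
        assert set(panel.columns) == {"gene_symbol", "probe_id"}
        assert panel["gene_symbol"].is_unique
        assert panel["probe_id"].str.startswith("ILMN_").all()
        assert "RPL3" in set(panel["gene_symbol"])
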