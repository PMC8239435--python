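import numpy as np
import pandas as pd
import pytest

from togglefate.classify import classify_cells, scale_scores, summarize_fates
from togglefate.io import ExpressionMatrix, GeneSignature, normalize_counts
from togglefate.model import ToggleParams, classify_starting_points
from togglefate.synth import SynthConfig, extreme_separation_config, generate_population


def _normalized(values, gene_ids):
    values = np.asarray(values, dtype=float)
    return ExpressionMatrix(
        values,
        gene_ids=gene_ids,
        cell_ids=[f"c{i}" for i in range(values.shape[0])],
        layer_tag="normalized",
    )


class TestScaleScores:
    def test_min_max_definition(self):
        xs, ys = scale_scores(np.array([-2.0, 0.0, 2.0]), np.array([0.0, 1.0, 2.0]), 2.2)
        np.testing.assert_allclose(xs, [0.0, 1.1, 2.2])
        np.testing.assert_allclose(ys, [0.0, 1.1, 2.2])

    def test_constant_axis_maps_to_midpoint(self, caplog):
        with caplog.at_level("WARNING"):
            xs, ys = scale_scores(np.array([1.0, 1.0]), np.array([0.0, 1.0]), 2.2)
        np.testing.assert_allclose(xs, [1.1, 1.1])
        assert "no spread" in caplog.text

    def test_joint_scaling_equals_concatenation(self):
        rng = np.random.default_rng(2)
        a = rng.normal(size=10)
        b = rng.normal(size=15)
        xs_joint, _ = scale_scores(np.concatenate([a, b]), np.zeros(25) + rng.normal(size=25), 2.2)
        np.testing.assert_allclose(xs_joint[:10], xs_joint[: len(a)])

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError, match="finite"):
            scale_scores(np.array([np.nan, 1.0]), np.array([0.0, 1.0]), 2.2)


class TestClassifyCells:
    def _meta(self, n, condition="u"):
        return pd.DataFrame({"cell_id": [f"c{i}" for i in range(n)], "condition": condition})

    def test_equal_axes_are_all_ambivalent(self):
        """Cells with x_raw == y_raw start on the diagonal and stay on it."""
        rng = np.random.default_rng(4)
        g = rng.gamma(2.0, 1.0, size=20)
        m = _normalized(np.column_stack([g, g]), ["GX", "GY"])
        result = classify_cells(
            m, self._meta(20), GeneSignature("x", ("GX",)), GeneSignature("y", ("GY",))
        )
        assert (result.cells["fate"] == "ambivalent").all()
        assert result.proportions.loc["u", "ambivalent"] == 1.0

    def test_mirrored_axes_swap_fates_exactly(self):
        rng = np.random.default_rng(9)
        values = rng.gamma(2.0, 1.0, size=(40, 2))
        m = _normalized(values, ["GX", "GY"])
        sx, sy = GeneSignature("x", ("GX",)), GeneSignature("y", ("GY",))
        forward = classify_cells(m, self._meta(40), sx, sy)
        mirrored = classify_cells(m, self._meta(40), sy, sx)
        swap = {"immunogenic": "tolerogenic", "tolerogenic": "immunogenic"}
        expected = forward.cells["fate"].map(lambda f: swap.get(f, f))
        assert (mirrored.cells["fate"] == expected).all()

    def test_deterministic(self):
        rng = np.random.default_rng(1)
        values = rng.gamma(2.0, 1.0, size=(30, 2))
        m = _normalized(values, ["GX", "GY"])
        args = (m, self._meta(30), GeneSignature("x", ("GX",)), GeneSignature("y", ("GY",)))
        r1, r2 = classify_cells(*args), classify_cells(*args)
        pd.testing.assert_frame_equal(r1.cells, r2.cells)
        pd.testing.assert_frame_equal(r1.proportions, r2.proportions)

    def test_proportions_sum_to_one_per_condition(self):
        cfg = SynthConfig(n_cells_per_condition=120, seed=3)
        matrix, meta, _ = generate_population(cfg)
        result = classify_cells(
            normalize_counts(matrix),
            meta,
            GeneSignature("x", cfg.programme_x_genes),
            GeneSignature("y", cfg.programme_y_genes),
        )
        np.testing.assert_allclose(result.proportions.sum(axis=1), 1.0)
        converged_counts = result.counts[["immunogenic", "tolerogenic", "ambivalent"]].sum(axis=1)
        assert (converged_counts + result.counts["unconverged"]).sum() == matrix.n_cells

    def test_extreme_separation_recovers_planted_proportions(self):
        """Large-effect, well-separated populations recover the planted
        three-way split (averaged over seeds to damp sampling noise)."""
        planted = np.array([0.35, 0.34, 0.31])
        recovered = []
        for seed in range(3):
            cfg = extreme_separation_config(
                n_cells_per_condition=300,
                fate_proportions={"u": tuple(planted)},
                effect_size=8.0,
                seed=seed,
            )
            matrix, meta, _ = generate_population(cfg)
            result = classify_cells(
                normalize_counts(matrix),
                meta,
                GeneSignature("x", cfg.programme_x_genes),
                GeneSignature("y", cfg.programme_y_genes),
            )
            recovered.append(result.proportions.loc["u"].to_numpy())
        assert np.abs(np.mean(recovered, axis=0) - planted).max() < 0.05

    def test_monotone_response_to_x_shift(self, default_params, default_attractors):
        """With a fixed scaling window, raising every x score never lowers
        the immunogenic fraction."""
        rng = np.random.default_rng(6)
        x = rng.normal(0.0, 1.0, size=150)
        y = rng.normal(0.0, 1.0, size=150)
        window = (-4.0, 4.0)
        fractions = []
        for shift in (0.0, 0.5, 1.0):
            xs, ys = scale_scores(
                x + shift, y, default_params.x_max, x_range=window, y_range=window
            )
            labels, _ = classify_starting_points(
                np.column_stack([xs, ys]), default_params, default_attractors
            )
            fractions.append(np.mean(labels == "immunogenic"))
        assert fractions[0] <= fractions[1] <= fractions[2]

    def test_missing_metadata_row_raises(self):
        m = _normalized(np.array([[0.0, 1.0], [1.0, 0.0]]), ["GX", "GY"])
        meta = pd.DataFrame({"cell_id": ["c0"], "condition": ["u"]})
        with pytest.raises(ValueError, match="metadata"):
            classify_cells(m, meta, GeneSignature("x", ("GX",)), GeneSignature("y", ("GY",)))


class TestSummarizeFates:
    def _result_from_counts(self, counts):
        from togglefate.classify import FateResult

        conditions = list(counts)
        frame = pd.DataFrame(counts).T
        frame.columns = ["immunogenic", "tolerogenic", "ambivalent", "unconverged"]
        proportions = frame[["immunogenic", "tolerogenic", "ambivalent"]].div(
            frame[["immunogenic", "tolerogenic", "ambivalent"]].sum(axis=1), axis=0
        )
        cells = pd.DataFrame({"cell_id": ["x"], "condition": [conditions[0]]})
        return FateResult(cells=cells, proportions=proportions, counts=frame)

    def test_percentages_match_counts(self):
        result = self._result_from_counts({"u": (35, 34, 31, 0)})
        table = summarize_fates(result)
        assert list(table["percentage"]) == [35.0, 34.0, 31.0]
        assert table["percentage"].sum() == pytest.approx(100.0, abs=0.01)

    def test_single_fate_condition(self):
        table = summarize_fates(self._result_from_counts({"u": (0, 0, 50, 2)}))
        assert list(table["percentage"]) == [0.0, 0.0, 100.0]
        assert (table["unconverged"] == 2).all()

    def test_rounding_keeps_total_near_hundred(self):
        table = summarize_fates(self._result_from_counts({"u": (1, 1, 1, 0)}))
        assert table["percentage"].sum() == pytest.approx(100.0, abs=0.02)
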