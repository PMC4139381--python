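import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from devptn import (
    AnalysisThresholds,
    ExpressionMatrix,
    ValidationError,
    build_pattern_catalog,
    call_transitions,
    assign_pattern_codes,
    classify_genes,
    fdr_adjust,
    template_profile,
)
from devptn.pattern_classification import ptn_counts


class TestTemplates:
    @pytest.mark.parametrize("code,expected", [
        ("uuu", (0, -1, -2, -3)),
        ("ddd", (0, 1, 2, 3)),
        ("nnn", (0, 0, 0, 0)),
        ("udn", (0, -1, 0, 0)),
    ])
    def test_cumulative_walk(self, code, expected):
        assert template_profile(code).tolist() == list(expected)

    def test_invalid_character_errors(self):
        with pytest.raises(ValidationError):
            template_profile("uxd")

    @given(st.text(alphabet="udn", min_size=1, max_size=6))
    @settings(deadline=None, max_examples=50)
    def test_walk_steps_bounded_by_one(self, code):
        prof = template_profile(code)
        assert len(prof) == len(code) + 1
        assert np.all(np.abs(np.diff(prof)) <= 1)


class TestCatalog:
    def test_27_codes_with_anchors(self):
        cat = build_pattern_catalog()
        assert len(cat) == 27
        assert cat.index_of("uuu") == 1
        assert cat.index_of("nnn") == 14
        assert cat.index_of("ddd") == 27
        # 26 variable patterns remain after excluding the flat code
        assert len([c for c in cat.code_to_index if c != "nnn"]) == 26

    def test_extreme_codes_anticorrelated(self):
        r = np.corrcoef(template_profile("uuu"), template_profile("ddd"))[0, 1]
        assert r == pytest.approx(-1.0)

    def test_correlation_sequence_non_increasing(self):
        cat = build_pattern_catalog()
        corr = [cat.correlations[cat.code_of(i)] for i in range(1, 28) if i != 14]
        assert all(a >= b - 1e-12 for a, b in zip(corr, corr[1:]))

    def test_order_matches_independent_correlation_sort_oracle(self):
        """All 25 non-anchor slots agree with a separately computed
        correlation sort (np.corrcoef + python sort)."""
        cat = build_pattern_catalog()
        from itertools import product
        codes = ["".join(c) for c in product("udn", repeat=3)]
        ref = template_profile("uuu")
        rank = {"u": 0, "n": 1, "d": 2}

        def corr(c):
            return float(np.corrcoef(template_profile(c), ref)[0, 1])

        rest = [c for c in codes if c not in ("uuu", "nnn")]
        rest.sort(key=lambda c: (-corr(c), [rank[ch] for ch in c]))
        slots = [i for i in range(2, 28) if i != 14]
        oracle = dict(zip(rest, slots))
        for code, slot in oracle.items():
            assert cat.index_of(code) == slot


class TestFdrAdjust:
    def test_step_up_closed_form(self):
        q = fdr_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert fdr_adjust([0.37])[0] == pytest.approx(0.37)

    def test_matches_bruteforce_step_up_oracle(self):
        rng = np.random.default_rng(5)
        p = rng.random(1000)

        def bh_oracle(pv):
            m = len(pv)
            order = np.argsort(pv)
            q = np.empty(m)
            running = 1.0
            for rank_i in range(m, 0, -1):
                idx = order[rank_i - 1]
                running = min(running, pv[idx] * m / rank_i)
                q[idx] = running
            return q

        assert np.allclose(fdr_adjust(p), bh_oracle(p))

    def test_out_of_range_errors(self):
        with pytest.raises(ValidationError):
            fdr_adjust([0.5, 1.2])


def _matrix_from_stage_blocks(design, blocks):
    """blocks: gene -> list of per-stage value lists."""
    cols, data = [], []
    genes = list(blocks)
    for stage in design.ordered_stages:
        cols += design.samples_for(stage)
    for g in genes:
        row = []
        for si, stage in enumerate(design.ordered_stages):
            row += list(blocks[g][si])
        data.append(row)
    return ExpressionMatrix(pd.DataFrame(data, index=genes, columns=cols))


class TestCallTransitions:
    def test_identical_stages_called_n_with_p_one(self, four_stage_design):
        design = four_stage_design((3, 3, 3, 3))
        m = _matrix_from_stage_blocks(design, {"g": [[5, 5, 5]] * 4})
        calls = call_transitions(m, design)
        assert (calls["direction"] == "n").all()
        assert (calls["p"] == 1.0).all()

    def test_large_drop_called_u_against_null_background(self, four_stage_design):
        """Higher expression in the earlier stage is 'u' (the steadily
        decreasing pattern), even amid a 1000-gene null background."""
        design = four_stage_design((3, 3, 3, 3))
        rng = np.random.default_rng(0)
        blocks = {f"null{i}": [rng.normal(0, 1, 3) for _ in range(4)] for i in range(1000)}
        blocks["hit"] = [[10, 10.05, 9.95], [2, 2.1, 1.9], [2, 2.1, 1.9], [2, 2.1, 1.9]]
        m = _matrix_from_stage_blocks(design, blocks)
        calls = call_transitions(m, design)
        hit = calls[calls["gene"] == "hit"].set_index("transition")
        assert hit.loc[1, "direction"] == "u"
        assert hit.loc[2, "direction"] == "n"

    def test_null_pvalues_approximately_uniform(self, four_stage_design):
        design = four_stage_design((10, 10, 10, 10))
        rng = np.random.default_rng(8)
        n_genes = 2000
        blocks = {f"g{i}": [rng.normal(0, 1, 10) for _ in range(4)] for i in range(n_genes)}
        m = _matrix_from_stage_blocks(design, blocks)
        calls = call_transitions(m, design)
        for t in (1, 2, 3):
            p = calls.loc[calls["transition"] == t, "p"].to_numpy()
            frac = (p < 0.05).mean()
            se = np.sqrt(0.05 * 0.95 / n_genes)
            assert abs(frac - 0.05) < 4 * se

    def test_stage_with_one_sample_errors(self, four_stage_design):
        design = four_stage_design((3, 3, 3, 1))
        m = _matrix_from_stage_blocks(
            design, {"g": [[1, 2, 3], [1, 2, 3], [1, 2, 3], [1]]})
        with pytest.raises(ValidationError, match="MatureL"):
            call_transitions(m, design)

    def test_within_stage_label_swap_leaves_calls_unchanged(self, four_stage_design):
        design = four_stage_design((4, 4, 4, 4))
        rng = np.random.default_rng(2)
        blocks = {f"g{i}": [rng.normal(0, 1, 4) for _ in range(4)] for i in range(50)}
        m = _matrix_from_stage_blocks(design, blocks)
        swapped = m.data.rename(columns={"EarlyL_0": "EarlyL_1", "EarlyL_1": "EarlyL_0"})
        m2 = ExpressionMatrix(swapped[m.sample_ids])
        c1 = call_transitions(m, design)
        c2 = call_transitions(m2, design)
        pd.testing.assert_frame_equal(c1, c2)


class TestAssignAndClassify:
    @pytest.mark.parametrize("dirs,code", [
        (("u", "u", "u"), "uuu"),
        (("n", "n", "n"), "nnn"),
        (("u", "d", "n"), "udn"),
    ])
    def test_code_concatenation(self, dirs, code):
        calls = pd.DataFrame({
            "gene": ["g"] * 3, "transition": [1, 2, 3], "direction": list(dirs),
        })
        assert assign_pattern_codes(calls).loc["g"] == code

    def test_missing_transition_errors(self):
        calls = pd.DataFrame({"gene": ["g", "g"], "transition": [1, 3],
                              "direction": ["u", "u"]})
        with pytest.raises(ValidationError):
            assign_pattern_codes(calls)

    def test_planted_recovery_and_partition(self, staged_data):
        cfg, matrix, design, truth = staged_data
        assignment = classify_genes(matrix, design)
        codes = pd.Series(truth.planted_codes)
        uuu = codes.index[codes == "uuu"]
        assert (assignment.loc[uuu, "ptn_index"] == 1).mean() >= 0.95
        # a partition: every gene appears once, counts sum to the total
        assert len(assignment) == matrix.shape[0]
        assert ptn_counts(assignment).sum() == matrix.shape[0]

    def test_all_null_matrix_stays_flat(self, four_stage_design):
        design = four_stage_design((10, 10, 9, 15))
        rng = np.random.default_rng(21)
        blocks = {f"g{i}": [rng.normal(8, 0.5, n) for n in (10, 10, 9, 15)]
                  for i in range(500)}
        m = _matrix_from_stage_blocks(design, blocks)
        assignment = classify_genes(m, design)
        assert (assignment["ptn_index"] == 14).mean() >= 0.99
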