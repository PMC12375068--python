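"""Cost calculators, parameter counting, and hyperparameter recovery."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ievit.accounting import (PUBLISHED_LAYER_TABLE, PUBLISHED_TOTAL,
                              ConvSpec, CostParams, DenseSpec, SearchSpace,
                              count_params, dsconv_cost_eq1, solve_config,
                              standard_conv_cost_eq2, summarize_model,
                              summary_total)
from ievit.blocks import DSConvSpec, InceptionSpec, MV2Spec, ViTBlockSpec
from ievit.model import build_ievit


# ---------------------------------------------------------------------------
# cost formulas
# ---------------------------------------------------------------------------

def test_separable_cost_printed_form():
    p = CostParams(d_f=16, d_k=3, m=8, n=16)
    assert dsconv_cost_eq1(p) == 9 * 8 * 256 + 8 * 16 * 9 == 19584


def test_separable_cost_degenerate_n0():
    p = CostParams(d_f=16, d_k=3, m=8, n=0)
    assert dsconv_cost_eq1(p) == 9 * 8 * 256


def test_separable_cost_standard_form():
    p = CostParams(d_f=16, d_k=3, m=8, n=16)
    assert dsconv_cost_eq1(p, form="standard") == 18432 + 32768 == 51200


def test_standard_conv_cost():
    assert standard_conv_cost_eq2(CostParams(16, 3, 8, 16)) == 294912
    assert standard_conv_cost_eq2(CostParams(1, 1, 1, 1)) == 1


@settings(max_examples=200, deadline=None)
@given(st.integers(1, 64), st.sampled_from([1, 3, 5, 7]),
       st.integers(1, 64), st.integers(1, 128))
def test_cost_ratio_identity(d_f, d_k, m, n):
    """standard-form separable / standard cost == 1/N + 1/D_K^2 exactly."""
    p = CostParams(d_f, d_k, m, n)
    ratio = dsconv_cost_eq1(p, form="standard") / standard_conv_cost_eq2(p)
    assert ratio == pytest.approx(1 / n + 1 / d_k ** 2, rel=1e-12)


@settings(max_examples=100, deadline=None)
@given(st.integers(1, 32), st.sampled_from([3, 5, 7]),
       st.integers(1, 32), st.integers(2, 64))
def test_separable_never_costlier_in_standard_form(d_f, d_k, m, n):
    """Holds whenever 1/N + 1/D_K^2 <= 1, i.e. for every kernel/filter
    combination the architecture uses (K >= 3, N >= 2)."""
    p = CostParams(d_f, d_k, m, n)
    assert dsconv_cost_eq1(p, form="standard") <= standard_conv_cost_eq2(p)


# ---------------------------------------------------------------------------
# parameter counting
# ---------------------------------------------------------------------------

def test_forced_row_counts():
    assert count_params(ConvSpec(3, 3, 16, bias=True)) == 448
    assert count_params(ConvSpec(1, 96, 320, bias=True)) == 31040
    assert count_params(DenseSpec(320, 5)) == 1605


def test_dsconv_spec_count():
    # K^2*M*alpha + M*alpha*N + N
    assert count_params(DSConvSpec(3, 4, 6, depth_multiplier=2)) == \
        9 * 4 * 2 + 4 * 2 * 6 + 6


def test_count_rejects_unknown_spec():
    with pytest.raises(TypeError):
        count_params("not a spec")


@pytest.mark.parametrize("spec", [
    InceptionSpec(5, 3, 4, 5, 6, 7, 8, 9, kernel=3, pool="max"),
    MV2Spec(10, 12, expansion=4, stride=2),
    MV2Spec(8, 8, expansion=2, pre_reduce_from=24),
    ViTBlockSpec(6, 10, embed_dim=8, depth=2, heads=2, attn_dim=12,
                 mlp_hidden=20, qkv_bias=False, patch_size=2),
])
def test_analytic_count_equals_weight_enumeration(spec):
    """Closed-form counts agree with enumerating the real weight arrays."""
    from ievit.blocks import InceptionA, MV2Block, ViTBlock
    rng = np.random.default_rng(0)
    builders = {InceptionSpec: InceptionA, MV2Spec: MV2Block,
                ViTBlockSpec: ViTBlock}
    block = builders[type(spec)](spec, rng)
    assert count_params(spec) == block.param_count()


# ---------------------------------------------------------------------------
# model summary
# ---------------------------------------------------------------------------

def test_summary_reproduces_published_table():
    model = build_ievit()
    rows = summarize_model(model)
    assert len(rows) == 13
    ref = {name: (h, w, c, p) for name, h, w, c, p in PUBLISHED_LAYER_TABLE}
    for r in rows:
        h, w, c, p = ref[r.name]
        assert (r.output.height, r.output.width, r.output.channels) == (h, w, c)
        assert r.params == p
    assert summary_total(rows) == PUBLISHED_TOTAL


def test_summary_total_is_sum_and_empty_is_zero():
    rows = summarize_model(build_ievit())
    assert summary_total(rows) == sum(r.params for r in rows)
    assert summary_total([]) == 0


# ---------------------------------------------------------------------------
# configuration search
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def solved():
    return solve_config()


def test_solve_config_matches_every_row(solved):
    assert solved.all_matched
    assert {r.name for r in solved.report} >= {
        "conv_stem", "inception_a", "inception_b", "vit_1", "vit_2",
        "conv_head", "dense"}


def test_solve_config_recovers_shipped_defaults(solved):
    from ievit.model import (_DEF_INC_A, _DEF_INC_B, _DEF_MV2, _DEF_MV2_5,
                             _DEF_VIT_1, _DEF_VIT_2)
    assert solved.inception_a == _DEF_INC_A
    assert solved.inception_b == _DEF_INC_B
    assert tuple(solved.mv2[:4]) == _DEF_MV2
    assert solved.mv2[4] == _DEF_MV2_5
    assert solved.vit[0] == _DEF_VIT_1
    assert solved.vit[1] == _DEF_VIT_2


def test_solve_config_stem_and_head_unique(solved):
    assert solved.stem == ConvSpec(3, 3, 16, bias=True, bn=False)
    assert solved.head == ConvSpec(1, 96, 320, bias=True, bn=False)
    assert solved.dense == DenseSpec(320, 5)


def test_solve_config_deterministic():
    a, b = solve_config(), solve_config()
    assert a.inception_a == b.inception_a
    assert a.vit == b.vit
    assert a.report_lines() == b.report_lines()


def test_solve_config_reports_near_miss_for_unmatchable_row():
    # perturb one printed count so no configuration can match it exactly
    table = [list(row) for row in PUBLISHED_LAYER_TABLE]
    for row in table:
        if row[0] == "vit_1":
            row[4] += 1
    sc = solve_config(targets=[tuple(r) for r in table])
    row = {r.name: r for r in sc.report}["vit_1"]
    assert not row.matched
    assert abs(row.residual) >= 1
    assert "false" in sc.report_lines()


def test_solve_config_rejects_empty_targets():
    with pytest.raises(ValueError, match="empty"):
        solve_config(targets=[])


def test_search_space_is_finite_default():
    s = SearchSpace()
    assert s.width_step == 8 and max(s.vit_depths) <= 8
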