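"""Architecture construction: layer shapes, parameter counts, loss."""

import math

import numpy as np
import pytest

from splicecode import (ArchitectureError, DSCConfig, binary_cross_entropy,
                        build_baseline, build_dsc, model_summary,
                        summary_to_tsv)

# the published layer table of the eight-hidden-layer variant:
# (conv temporal length, filters, conv params) per block, then the head
EXPECTED_BLOCKS = [(134, 8, 232), (64, 16, 528), (30, 32, 1568), (14, 64, 4160)]
EXPECTED_POOLED = [67, 32, 15, 7]


def conv_params(kernel, in_ch, filters):
    return kernel * in_ch * filters + filters


def summary_by_name(net):
    return {row.layer_name: row for row in model_summary(net)}


class TestDSCArchitecture:
    def test_layer_table_matches_published_shapes_and_counts(self):
        rows = summary_by_name(build_dsc())
        for branch in ("branch_a", "branch_b"):
            for i, (length, filters, params) in enumerate(EXPECTED_BLOCKS, 1):
                conv = rows[f"{branch}/conv{i}"]
                assert conv.output_shape == (length, filters)
                assert conv.param_count == params
                assert rows[f"{branch}/maxpool{i}"].output_shape == \
                    (EXPECTED_POOLED[i - 1], filters)
        assert rows["concatenate_branches"].output_shape == (7, 128)
        assert rows["flatten"].output_shape == (896,)
        assert rows["concatenate_features"].output_shape == (899,)
        assert rows["dense_hidden"].param_count == 921600
        assert rows["dense_output"].param_count == 1025

    def test_weightless_layers_report_zero_params(self):
        for row in model_summary(build_dsc()):
            if "conv" not in row.layer_name and "dense" not in row.layer_name:
                assert row.param_count == 0
            if "dropout" in row.layer_name:
                assert row.param_count == 0

    def test_summary_total_equals_model_param_count(self):
        net = build_dsc()
        assert sum(r.param_count for r in model_summary(net)) == net.n_params

    def test_branch_symmetry(self):
        rows = model_summary(build_dsc())
        a = [(r.output_shape, r.param_count) for r in rows
             if r.layer_name.startswith("branch_a")]
        b = [(r.output_shape, r.param_count) for r in rows
             if r.layer_name.startswith("branch_b")]
        assert a == b

    def test_single_filter_closed_form(self):
        net = build_dsc(DSCConfig(branch_filters=(1,), branch_kernels=(1,)))
        first = next(r for r in model_summary(net) if r.layer_name == "branch_a/conv1")
        assert first.param_count == 1 * 4 * 1 + 1 == 5

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_shape_and_count_oracle_random_configs(self, seed):
        """Valid-padding/pooling cascade and the closed-form parameter
        count hold for arbitrary configurations."""
        rng = np.random.default_rng(seed)
        depth = int(rng.integers(1, 5))
        filters = tuple(int(f) for f in rng.integers(1, 32, size=depth))
        kernels = tuple(int(k) for k in rng.integers(1, 8, size=depth))
        cfg = DSCConfig(branch_filters=filters, branch_kernels=kernels,
                        dense_units=int(rng.integers(2, 64)))
        try:
            net = build_dsc(cfg)
        except ArchitectureError:
            return
        rows = summary_by_name(net)
        length, in_ch = cfg.seq_len, cfg.n_channels
        for i, (f, k) in enumerate(zip(filters, kernels), 1):
            length = length - k + 1
            assert rows[f"branch_a/conv{i}"].output_shape == (length, f)
            assert rows[f"branch_a/conv{i}"].param_count == conv_params(k, in_ch, f)
            length //= 2
            assert rows[f"branch_a/maxpool{i}"].output_shape == (length, f)
            in_ch = f
        flat = 2 * length * filters[-1]
        assert rows["flatten"].output_shape == (flat,)
        assert rows["dense_hidden"].param_count == \
            (flat + 3) * cfg.dense_units + cfg.dense_units

    def test_collapsing_cascade_raises_naming_layer(self):
        cfg = DSCConfig(branch_filters=(4, 4, 4, 4, 4, 4),
                        branch_kernels=(7, 7, 7, 7, 7, 7))
        with pytest.raises(ArchitectureError, match=r"conv|pool"):
            build_dsc(cfg)

    def test_output_strictly_inside_unit_interval(self):
        net = build_dsc(seed=3)
        rng = np.random.default_rng(0)
        p = net.predict_proba(rng.random((8, 140, 4)), rng.random((8, 140, 4)),
                              rng.random((8, 3)) * 10 - 5)
        assert np.all(p > 0) and np.all(p < 1)

    def test_config_validation(self):
        with pytest.raises(ValueError, match="equal length"):
            DSCConfig(branch_filters=(8, 16), branch_kernels=(7,))
        with pytest.raises(ValueError, match="dropout"):
            DSCConfig(conv_dropout=1.0)

    def test_summary_tsv_mirrors_table(self):
        text = summary_to_tsv(build_dsc())
        assert "dense_hidden\t(1024)\t921600" in text
        assert text.splitlines()[0] == "layer\toutput_shape\tparams"


class TestBaseline:
    def test_three_conv_blocks_per_branch(self):
        rows = model_summary(build_baseline())
        convs = [r for r in rows if "conv" in r.layer_name]
        assert len(convs) == 6  # six hidden conv layers in total

    def test_first_conv_closed_form_count_and_length(self):
        rows = summary_by_name(build_baseline())
        first = rows["branch_a/conv1"]
        assert first.param_count == 7 * 4 * 32 + 32 == 928
        assert first.output_shape == (134, 32)

    def test_baseline_dropout_rate(self):
        assert build_baseline().config.conv_dropout == 0.2


class TestBinaryCrossEntropy:
    @pytest.mark.parametrize("y,p,expected", [
        ([1.0], [1.0], 0.0),
        ([1.0], [0.5], math.log(2)),
        ([0.0, 1.0], [0.25, 0.75], -math.log(0.75)),
    ])
    def test_hand_evaluated_examples(self, y, p, expected):
        assert binary_cross_entropy(y, p) == pytest.approx(expected, abs=1e-6)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="equal length"):
            binary_cross_entropy([1, 0], [0.5])

    def test_permutation_invariant_and_minimised_at_labels(self):
        rng = np.random.default_rng(5)
        y = rng.integers(0, 2, 50).astype(float)
        p = rng.random(50)
        perm = rng.permutation(50)
        assert binary_cross_entropy(y, p) == pytest.approx(
            binary_cross_entropy(y[perm], p[perm]), abs=1e-12)
        assert binary_cross_entropy(y, y) < binary_cross_entropy(y, p)

    def test_hard_wrong_prediction_is_finite(self):
        assert np.isfinite(binary_cross_entropy([1.0], [0.0]))


def test_weight_checkpoint_round_trip(tmp_path):
    net = build_dsc(seed=7)
    rng = np.random.default_rng(1)
    x = (rng.random((4, 140, 4)), rng.random((4, 140, 4)), rng.random((4, 3)))
    before = net.predict_proba(*x)
    net.save_weights(tmp_path / "w.npz")
    other = build_dsc(seed=99)
    assert not np.allclose(other.predict_proba(*x), before)
    other.load_weights(tmp_path / "w.npz")
    np.testing.assert_array_equal(other.predict_proba(*x), before)
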