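"""Gain thresholding, sign-pure cluster labeling, and correction dispatch."""

import numpy as np
import pytest

import strfkit
from strfkit.exceptions import InvalidParameterError
from strfkit.sta import StrfEstimate


def toy_sta(values):
    values = np.asarray(values, dtype=np.float64)
    return StrfEstimate(
        values=values,
        freq_axis=np.arange(values.shape[0]) * 0.1,
        lag_axis=np.arange(values.shape[1]) * 0.001,
        n_spikes_used=10,
    )


def flood_fill_oracle(values, connectivity):
    """Independent recursive flood fill with sign purity."""
    h, w = values.shape
    seen = np.zeros((h, w), dtype=bool)
    if connectivity == 8:
        neigh = [(a, b) for a in (-1, 0, 1) for b in (-1, 0, 1) if (a, b) != (0, 0)]
    else:
        neigh = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    out = []
    for i in range(h):
        for j in range(w):
            if values[i, j] != 0 and not seen[i, j]:
                sign = np.sign(values[i, j])
                stack, pix = [(i, j)], []
                seen[i, j] = True
                while stack:
                    a, b = stack.pop()
                    pix.append((a, b))
                    for da, db in neigh:
                        x, y = a + da, b + db
                        if (
                            0 <= x < h and 0 <= y < w and not seen[x, y]
                            and values[x, y] != 0 and np.sign(values[x, y]) == sign
                        ):
                            seen[x, y] = True
                            stack.append((x, y))
                mass = sum(abs(values[a, b]) for a, b in pix)
                out.append((frozenset(pix), "exc" if sign > 0 else "inh", mass))
    return out


class TestGainThreshold:
    def test_hand_computed_mask(self):
        v = np.array(
            [
                [3.0, -1.0, 0.5, -4.0],
                [2.0, 1.9, -2.0, 0.0],
                [-2.1, 0.1, 2.5, -0.5],
                [1.0, -3.5, 0.2, 2.0],
            ]
        )
        out = strfkit.apply_gain_threshold(toy_sta(v), -2.0, 2.0)
        expected = np.where((v <= -2.0) | (v >= 2.0), v, 0.0)
        np.testing.assert_array_equal(out.values, expected)
        # surviving pixels keep their exact values (sparsity-only contract)
        surv = out.values != 0
        np.testing.assert_array_equal(out.values[surv], v[surv])

    def test_cutoffs_beyond_extremes_zero_everything(self):
        v = np.array([[1.0, -2.0], [0.5, 3.0]])
        out = strfkit.apply_gain_threshold(toy_sta(v), -10.0, 10.0)
        assert np.all(out.values == 0.0)

    def test_ties_survive(self):
        v = np.array([[2.0, 1.999], [-2.0, -1.999]])
        out = strfkit.apply_gain_threshold(toy_sta(v), -2.0, 2.0)
        np.testing.assert_array_equal(out.values, [[2.0, 0.0], [-2.0, 0.0]])

    def test_cutoff_order_violation(self):
        with pytest.raises(InvalidParameterError):
            strfkit.apply_gain_threshold(toy_sta(np.ones((2, 2))), 1.0, -1.0)

    def test_monotone_in_stringency(self, driven_unit):
        sta, grids = driven_unit["sta"], driven_unit["grids"]
        prev = None
        for p in strfkit.make_p_grid().p_values[1:]:
            lo, hi = grids.gain_cutoffs(p)
            mask = strfkit.apply_gain_threshold(sta, lo, hi).values != 0
            if prev is not None:
                assert np.all(mask <= prev)  # survivors only shrink
            prev = mask


class TestLabelClusters:
    def test_diagonal_connectivity(self):
        v = np.zeros((3, 3))
        v[0, 0] = v[1, 1] = 1.0
        assert len(strfkit.label_clusters(toy_sta(v), connectivity=8)) == 1
        assert len(strfkit.label_clusters(toy_sta(v), connectivity=4)) == 2

    def test_sign_purity_splits_adjacent_opposite_pixels(self):
        v = np.zeros((2, 3))
        v[0, 0], v[0, 1] = 2.0, -2.0
        cs = strfkit.label_clusters(toy_sta(v), connectivity=8)
        assert len(cs) == 2
        assert sorted(c.sign for c in cs.clusters) == ["exc", "inh"]
        np.testing.assert_allclose(sorted(c.mass for c in cs.clusters), [2.0, 2.0])

    @pytest.mark.parametrize("connectivity", [4, 8])
    def test_matches_flood_fill_oracle(self, connectivity):
        rng = np.random.default_rng(0)
        for _ in range(100):
            v = rng.normal(0, 1, (30, 30))
            v[np.abs(v) < 1.0] = 0.0
            got = strfkit.label_clusters(toy_sta(v), connectivity=connectivity)
            got_set = {
                (frozenset(zip(c.rows.tolist(), c.cols.tolist())), c.sign)
                for c in got.clusters
            }
            oracle = flood_fill_oracle(v, connectivity)
            assert got_set == {(p, s) for p, s, _ in oracle}
            np.testing.assert_allclose(
                sorted(c.mass for c in got.clusters),
                sorted(m for _, _, m in oracle),
                rtol=1e-12,
            )

    def test_empty_input_gives_empty_set(self):
        assert len(strfkit.label_clusters(toy_sta(np.zeros((4, 4))))) == 0


class TestClusterThreshold:
    def _clustered(self):
        v = np.zeros((6, 8))
        v[0, 0:3] = [2.0, 2.0, 1.5]  # mass 5.5
        v[3, 2] = -1.2  # mass 1.2
        v[5, 5:7] = [1.5, 1.5]  # mass 3.0
        sta = toy_sta(v)
        return sta, strfkit.label_clusters(sta)

    def test_zero_cutoff_is_identity(self):
        sta, cs = self._clustered()
        out = strfkit.apply_cluster_threshold(sta, cs, cutoff=0.0)
        np.testing.assert_array_equal(out.values, sta.values)

    def test_cutoff_above_max_mass_zeroes_all(self):
        sta, cs = self._clustered()
        out = strfkit.apply_cluster_threshold(sta, cs, cutoff=100.0)
        assert np.all(out.values == 0.0)

    def test_tie_at_cutoff_survives(self):
        sta, cs = self._clustered()
        out = strfkit.apply_cluster_threshold(sta, cs, cutoff=3.0)
        surviving = strfkit.label_clusters(out)
        np.testing.assert_allclose(sorted(surviving.masses()), [3.0, 5.5])

    def test_per_sign_cutoffs(self):
        sta, cs = self._clustered()
        out = strfkit.apply_cluster_threshold(sta, cs, cutoff_exc=4.0, cutoff_inh=1.0)
        surviving = strfkit.label_clusters(out)
        masses = {c.sign: c.mass for c in surviving.clusters}
        assert masses == {"exc": pytest.approx(5.5), "inh": pytest.approx(1.2)}


class TestCorrect:
    def test_p_one_is_raw_passthrough(self, driven_unit):
        sta, grids = driven_unit["sta"], driven_unit["grids"]
        out = strfkit.correct(
            sta, strfkit.CorrectionSetting(variant="gain", p_gain=1.0), grids
        )
        np.testing.assert_array_equal(out.values, sta.values)
        assert out.correction_tag == "raw"

    def test_cluster_variant_composes_the_two_steps(self, driven_unit):
        sta, grids = driven_unit["sta"], driven_unit["grids"]
        setting = strfkit.CorrectionSetting(variant="cluster", p_gain=0.05, p_clst=0.01)
        via_dispatch = strfkit.correct(sta, setting, grids)
        lo, hi = grids.gain_cutoffs(0.05)
        thr = strfkit.apply_gain_threshold(sta, lo, hi)
        cs = strfkit.label_clusters(thr)
        manual = strfkit.apply_cluster_threshold(
            thr, cs, cutoff=grids.cluster_mass_cutoff(0.05, 0.01)
        )
        np.testing.assert_array_equal(via_dispatch.values, manual.values)

    def test_cluster_ei_with_identical_fits_equals_joint(self, driven_unit):
        # when the per-sign null fits coincide with the joint fit, the
        # independent variant at equal p must reproduce the joint variant
        sta, grids = driven_unit["sta"], driven_unit["grids"]
        joint_fit = grids.get_cluster_fit(0.05, "both")
        sym = strfkit.SignificanceGrid(
            p_grid=grids.p_grid, gain_fit=grids.gain_fit
        )
        for scope in ("both", "exc", "inh"):
            sym.set_cluster_fit(0.05, scope, joint_fit)
        joint = strfkit.correct(
            sta,
            strfkit.CorrectionSetting(variant="cluster", p_gain=0.05, p_clst=1e-3),
            sym,
        )
        ei = strfkit.correct(
            sta,
            strfkit.CorrectionSetting(
                variant="cluster_ei", p_gain=0.05, p_clst_exc=1e-3, p_clst_inh=1e-3
            ),
            sym,
        )
        np.testing.assert_array_equal(joint.values, ei.values)

    def test_gain_ei_with_equal_p_matches_joint(self, driven_unit):
        sta, grids = driven_unit["sta"], driven_unit["grids"]
        joint = strfkit.correct(
            sta, strfkit.CorrectionSetting(variant="gain", p_gain=0.01), grids
        )
        ei = strfkit.correct(
            sta,
            strfkit.CorrectionSetting(
                variant="gain_ei", p_gain_exc=0.01, p_gain_inh=0.01
            ),
            grids,
        )
        np.testing.assert_array_equal(joint.values, ei.values)

    def test_correction_never_alters_surviving_values(self, driven_unit):
        sta, grids = driven_unit["sta"], driven_unit["grids"]
        level = float(grids.p_grid.retained_gain_levels[2])
        out = strfkit.correct(
            sta,
            strfkit.CorrectionSetting(variant="cluster", p_gain=level, p_clst=1e-4),
            grids,
        )
        surv = out.values != 0
        np.testing.assert_array_equal(out.values[surv], sta.values[surv])

    def test_false_positive_suppression_on_noise(self, noise_unit):
        # pure-noise unit: cluster correction at p_clst <= 1e-3 leaves fewer
        # pixels than the same gain level alone
        sta, ens = noise_unit["sta"], noise_unit["ens"]
        grids = strfkit.build_significance_grid(
            ens, gain_levels=[0.05], stride_i=2
        )
        lo, hi = grids.gain_cutoffs(0.05)
        gain_only = strfkit.apply_gain_threshold(sta, lo, hi)
        clustered = strfkit.correct(
            sta,
            strfkit.CorrectionSetting(variant="cluster", p_gain=0.05, p_clst=1e-3),
            grids,
        )
        n_gain = np.count_nonzero(gain_only.values)
        n_clst = np.count_nonzero(clustered.values)
        assert n_clst < n_gain
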