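"""QC filters, colour correction, background subtraction and BMIQ."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from methewas import simulate_cohort
from methewas.preprocess import (
    DetectionPMatrix, apply_qc_filters, background_subtract, beta_to_m,
    betas_from_intensities, bmiq_normalize, color_bias_correct, compute_beta,
    detection_pvalues, fit_beta_mixture, m_to_beta, remove_crossreactive,
)

from conftest import beta_matrix, small_config, toy_raw


class TestBetaTransforms:
    @pytest.mark.parametrize("meth,unmeth,expected", [
        (300.0, 600.0, 0.3),        # 300 / 1000 with the +100 offset
        (0.0, 0.0, 0.0),            # offset forces 0/100
        (100.0, 100.0, 1.0 / 3.0),
    ])
    def test_compute_beta_formula(self, meth, unmeth, expected):
        assert compute_beta(meth, unmeth) == pytest.approx(expected)

    def test_compute_beta_rejects_negative(self):
        with pytest.raises(ValueError):
            compute_beta(-1.0, 10.0)

    @pytest.mark.parametrize("beta,m", [(0.5, 0.0), (0.8, 2.0), (0.2, -2.0)])
    def test_beta_to_m_values(self, beta, m):
        assert beta_to_m(beta) == pytest.approx(m)

    @given(st.floats(min_value=1e-5, max_value=1 - 1e-5))
    @settings(max_examples=100, deadline=None)
    def test_round_trip_identity(self, b):
        assert m_to_beta(beta_to_m(b)) == pytest.approx(b, abs=1e-12)

    def test_monotone(self):
        x = np.linspace(1e-4, 1 - 1e-4, 500)
        assert (np.diff(beta_to_m(x)) > 0).all()


class TestDetectionP:
    def test_centred_probe_has_p_half(self):
        raw = toy_raw(n_probes=5, n_samples=4, seed=1)
        neg_sum = (raw.controls_red.values + raw.controls_green.values)
        mu = neg_sum.mean(axis=0)
        raw.meth.iloc[0] = mu / 2
        raw.unmeth.iloc[0] = mu / 2
        detp = detection_pvalues(raw)
        np.testing.assert_allclose(detp.values.iloc[0], 0.5, atol=1e-12)

    def test_strong_signal_far_tail(self):
        raw = toy_raw(n_probes=5, n_samples=4, seed=1)
        detp = detection_pvalues(raw)  # toy signals are ~25 sigma above bg
        assert (detp.values.iloc[1:].values < 1e-15).all()

    def test_degenerate_controls_rejected(self):
        raw = toy_raw(n_probes=5, n_samples=3, seed=1)
        raw.controls_red.iloc[:, :] = 100.0
        raw.controls_green.iloc[:, :] = 100.0
        with pytest.raises(ValueError, match="degenerate"):
            detection_pvalues(raw)

    def test_failed_probes_look_like_background(self):
        """Generated background-only cells get median detection p > 0.1."""
        cfg = small_config(failed_probe_fraction=0.05, low_bead_fraction=0.0,
                           n_probes=300)
        cohort = simulate_cohort(cfg, keep_truth=False)
        detp = detection_pvalues(cohort.raw)
        # recover which cells failed: signal ~ 2 backgrounds, far below T
        total = cohort.raw.meth.values + cohort.raw.unmeth.values
        failed = total < 2000
        assert failed.sum() > 100
        assert np.median(detp.values.values[failed]) > 0.1
        assert np.median(detp.values.values[~failed]) < 1e-10


class TestQcFilters:
    def test_clean_simulation_nothing_masked(self, tiny_clean_cohort):
        raw = tiny_clean_cohort.raw
        qc = apply_qc_filters(raw, detection_pvalues(raw))
        assert qc.mask.values.all()
        assert qc.log["n_samples_dropped"] == 0
        assert qc.log["n_probes_dropped"] == 0

    def test_background_only_sample_dropped(self):
        raw = toy_raw(n_probes=30, n_samples=5, seed=2)
        raw.meth.iloc[:, 2] = 100.0
        raw.unmeth.iloc[:, 2] = 100.0
        qc = apply_qc_filters(raw, detection_pvalues(raw))
        assert "S2" in qc.log["samples_dropped"]
        assert qc.log["n_samples_retained"] == 4

    def test_five_percent_probe_rule(self):
        """A probe failing in half the samples is dropped; 19 of 20 remain."""
        raw = toy_raw(n_probes=20, n_samples=6, seed=3)
        raw.beads.iloc[7, :3] = 1  # probe 7 fails (low beads) in 3/6 samples
        qc = apply_qc_filters(raw, detection_pvalues(raw))
        assert qc.log["n_probes_retained"] == 19
        assert raw.probe_ids[7] not in qc.retained_probes

    def test_all_samples_dropped_is_error(self):
        raw = toy_raw(n_probes=10, n_samples=3, seed=4)
        raw.beads.iloc[:, :] = 0
        with pytest.raises(ValueError, match="all samples"):
            apply_qc_filters(raw, detection_pvalues(raw))


def _half_red_half_green_manifest(n):
    from methewas import ProbeManifest
    probes = pd.Index([f"cg{i:06d}" for i in range(n)], name="probe_id")
    table = pd.DataFrame({
        "chromosome": "1", "position": np.arange(1, n + 1), "gene": "",
        "design_type": "I",
        "channel": ["red"] * (n // 2) + ["green"] * (n - n // 2),
        "cgi_relation": "open_sea",
    }, index=probes)
    return ProbeManifest(table)


class TestColorBias:
    def test_identical_distributions_is_identity(self):
        """When red and green pools coincide the map is the identity."""
        n = 400
        manifest = _half_red_half_green_manifest(n)
        rng = np.random.default_rng(5)
        vals_m = rng.uniform(300, 5000, size=(n // 2, 3))
        vals_u = rng.uniform(300, 5000, size=(n // 2, 3))
        raw = toy_raw(manifest=manifest, n_samples=3, seed=5)
        raw.meth.iloc[:n // 2] = vals_m       # red half
        raw.meth.iloc[n // 2:] = vals_m       # green half: same values
        raw.unmeth.iloc[:n // 2] = vals_u
        raw.unmeth.iloc[n // 2:] = vals_u
        out = color_bias_correct(raw, manifest)
        np.testing.assert_allclose(out.meth.values, raw.meth.values,
                                   rtol=0.02)
        np.testing.assert_allclose(out.unmeth.values, raw.unmeth.values,
                                   rtol=0.02)

    def test_doubled_red_channel_corrected(self):
        """red = 2 x green at matched quantiles -> ratio pulled to ~1."""
        n = 400
        manifest = _half_red_half_green_manifest(n)
        rng = np.random.default_rng(6)
        base_m = rng.uniform(500, 4000, size=(n, 3))
        base_u = rng.uniform(500, 4000, size=(n, 3))
        raw = toy_raw(manifest=manifest, n_samples=3, seed=6)
        raw.meth.iloc[:, :] = base_m
        raw.unmeth.iloc[:, :] = base_u
        raw.meth.iloc[:n // 2] *= 2.0   # red channel doubled
        raw.unmeth.iloc[:n // 2] *= 2.0
        out = color_bias_correct(raw, manifest)
        for j in range(3):
            red = np.sort(np.concatenate([out.meth.values[:n // 2, j],
                                          out.unmeth.values[:n // 2, j]]))
            green = np.sort(np.concatenate([out.meth.values[n // 2:, j],
                                            out.unmeth.values[n // 2:, j]]))
            q = np.linspace(0.1, 0.9, 9)
            ratio = np.quantile(red, q) / np.quantile(green, q)
            assert (ratio > 0.95).all() and (ratio < 1.05).all()

    def test_monotone_order_preserved_within_channel(self):
        n = 400
        manifest = _half_red_half_green_manifest(n)
        raw = toy_raw(manifest=manifest, n_samples=4, seed=7)
        out = color_bias_correct(raw, manifest)
        for sel in (slice(None, n // 2), slice(n // 2, None)):
            for j in range(4):
                before = raw.meth.values[sel, j]
                after = out.meth.values[sel, j]
                assert (np.argsort(before, kind="stable")
                        == np.argsort(after, kind="stable")).all()


class TestBackgroundSubtract:
    def test_median_subtraction(self, toy_manifest):
        raw = toy_raw(manifest=toy_manifest, n_samples=3, seed=8)
        raw.controls_red.iloc[:, :] = 200.0
        raw.controls_red.iloc[0, :] = 190.0  # keep a spread, median 200
        raw.controls_red.iloc[1, :] = 210.0
        raw.controls_green.iloc[:, :] = 200.0
        raw.meth.iloc[:, :] = 500.0
        out = background_subtract(raw, toy_manifest)
        np.testing.assert_allclose(out.meth.values, 300.0)

    def test_floor_at_one(self, toy_manifest):
        raw = toy_raw(manifest=toy_manifest, n_samples=3, seed=9)
        raw.controls_red.iloc[:, :] = 200.0
        raw.controls_green.iloc[:, :] = 200.0
        raw.meth.iloc[:, :] = 150.0
        out = background_subtract(raw, toy_manifest)
        np.testing.assert_allclose(out.meth.values, 1.0)

    def test_recovers_signal_on_simulation(self):
        """Subtracting the negative-control median undoes the added bg."""
        cfg = small_config(n_probes=200, seed=30).noise_free_variant()
        cohort = simulate_cohort(cfg, keep_truth=True)
        out = background_subtract(cohort.raw, cohort.manifest)
        T = np.exp(cfg.intensity_log_mean)
        resid = (out.meth.values + out.unmeth.values) - T
        # residual is twice the (median - mean) background estimate error
        assert np.abs(resid).mean() < 0.02 * T


class TestBmiq:
    def _mixed_matrix(self, rng, n=3000, compress=None):
        """Realistic methylome mixture (sharp unmethylated/methylated
        modes, ~15% hemimethylated); optionally compress the type II half."""
        from methewas import ProbeManifest
        half = n // 2
        comp = rng.choice(3, size=n, p=[0.425, 0.15, 0.425])
        b = np.empty(n)
        b[comp == 0] = rng.beta(2, 18, size=(comp == 0).sum())
        b[comp == 1] = rng.beta(5, 5, size=(comp == 1).sum())
        b[comp == 2] = rng.beta(18, 2, size=(comp == 2).sum())
        b2 = b[half:].copy()
        if compress is not None:
            lo, slope = compress
            b2 = lo + slope * b2
        vals = np.concatenate([b[:half], b2])[:, None]
        probes = pd.Index([f"cg{i:06d}" for i in range(n)], name="probe_id")
        table = pd.DataFrame({
            "chromosome": "1", "position": np.arange(1, n + 1), "gene": "",
            "design_type": ["I"] * half + ["II"] * (n - half),
            "channel": ["red"] * half + ["both"] * (n - half),
            "cgi_relation": "open_sea"}, index=probes)
        return beta_matrix(vals), ProbeManifest(table)

    def test_identity_when_distributions_agree(self):
        rng = np.random.default_rng(10)
        betas, manifest = self._mixed_matrix(rng)
        out, fits = bmiq_normalize(betas, manifest)
        is_two = (manifest.table["design_type"] == "II").values
        diff = np.abs(out.values.values[is_two, 0]
                      - betas.values.values[is_two, 0])
        assert diff.mean() < 0.01

    def test_compressed_type2_ks_halved(self):
        rng = np.random.default_rng(11)
        betas, manifest = self._mixed_matrix(rng, compress=(0.1, 0.8))
        is_two = (manifest.table["design_type"] == "II").values
        one = betas.values.values[~is_two, 0]
        two_before = betas.values.values[is_two, 0]
        ks_before = stats.ks_2samp(one, two_before).statistic
        out, _fits = bmiq_normalize(betas, manifest)
        ks_after = stats.ks_2samp(one, out.values.values[is_two, 0]).statistic
        assert ks_after <= 0.5 * ks_before

    def test_outputs_in_unit_interval(self):
        rng = np.random.default_rng(12)
        vals = rng.uniform(0.0, 1.0, size=(1000, 1))
        betas, manifest = self._mixed_matrix(rng, n=1000)
        out, _ = bmiq_normalize(betas, manifest)
        v = out.values.values
        assert np.isfinite(v[betas.mask.values]).all()
        assert (v[betas.mask.values] >= 0).all()
        assert (v[betas.mask.values] <= 1).all()

    def test_mixture_fit_invariants(self):
        rng = np.random.default_rng(13)
        x = np.concatenate([rng.beta(2, 10, 400), rng.beta(5, 5, 150),
                            rng.beta(10, 2, 450)])
        mix = fit_beta_mixture(x)
        w = np.array([mix.weights[k] for k in mix.STATES])
        assert w.min() >= 0
        assert w.sum() == pytest.approx(1.0)
        for a, b in mix.params.values():
            assert a > 0 and b > 0
        ll = np.array(mix.loglik_trace)
        assert (np.diff(ll) >= -1e-8).all()

    def test_state_rank_order_preserved(self):
        rng = np.random.default_rng(14)
        betas, manifest = self._mixed_matrix(rng, compress=(0.1, 0.8))
        out, fits = bmiq_normalize(betas, manifest)
        fit = list(fits.values())[0]
        is_two = (manifest.table["design_type"] == "II").values
        before = betas.values.values[is_two, 0]
        after = out.values.values[is_two, 0]
        for state in (0, 1, 2):
            sel = fit.states_type2 == state
            if sel.sum() > 1:
                order = np.argsort(before[sel])
                assert (np.diff(after[sel][order]) >= -1e-9).all()


class TestCrossReactive:
    def test_removal(self):
        m = beta_matrix(np.random.default_rng(1).uniform(size=(10, 2)))
        out = remove_crossreactive(m, ["cg000001", "cg000005"])
        assert len(out.probe_ids) == 8
        assert "cg000001" not in out.probe_ids

    def test_empty_blacklist_is_identity(self):
        m = beta_matrix(np.random.default_rng(1).uniform(size=(10, 2)))
        out = remove_crossreactive(m, [])
        pd.testing.assert_frame_equal(out.values, m.values)

    def test_absent_entries_ignored(self):
        m = beta_matrix(np.random.default_rng(1).uniform(size=(10, 2)))
        out = remove_crossreactive(m, ["cg999999"])
        assert len(out.probe_ids) == 10


class TestFullChain:
    def test_noise_free_chain_recovers_truth(self):
        """QC -> colour -> background -> beta -> BMIQ reproduces the
        generator's true beta to < 0.01 MAE at unplanted probes, and
        keeps X/Y probes in the matrix."""
        cfg = small_config(n_probes=2000, seed=21).noise_free_variant()
        cohort = simulate_cohort(cfg, keep_truth=True)
        raw, manifest = cohort.raw, cohort.manifest
        qc = apply_qc_filters(raw, detection_pvalues(raw))
        betas = betas_from_intensities(
            background_subtract(color_bias_correct(raw, manifest), manifest),
            qc.mask)
        betas, _ = bmiq_normalize(betas, manifest)
        betas = remove_crossreactive(betas, [])
        planted = {idx for idx, _ in cfg.planted_effects}
        keep = np.array([i for i in range(cfg.n_probes) if i not in planted])
        mae = np.abs(betas.values.values[keep]
                     - cohort.true_beta.T[keep]).mean()
        assert mae < 0.01
        chroms = manifest.table.loc[betas.probe_ids, "chromosome"]
        assert chroms.isin(["X", "Y"]).any()

    def test_mask_never_resurrected(self):
        cfg = small_config(n_probes=400, failed_probe_fraction=0.02, seed=22)
        cohort = simulate_cohort(cfg, keep_truth=False)
        raw, manifest = cohort.raw, cohort.manifest
        qc = apply_qc_filters(raw, detection_pvalues(raw))
        betas = betas_from_intensities(
            background_subtract(color_bias_correct(raw, manifest), manifest),
            qc.mask)
        masked_before = ~betas.mask.values
        betas, _ = bmiq_normalize(betas, manifest)
        assert (~betas.mask.values == masked_before).all()
        assert np.isnan(betas.values.values[masked_before]).all()
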