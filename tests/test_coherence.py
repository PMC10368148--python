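import numpy as np
import pandas as pd
import pytest

from meagamma.coherence import (BETWEEN, WITHIN_CA1, WITHIN_CA3, band_coherence, build_graph,
                                multitaper_coherence, pairwise_table, power_correlation_map)
from meagamma.errors import ParameterError
from meagamma.preprocess import LfpRecording, to_lfp
from meagamma.spectral import BandDefinition, BandPowerSeries
from meagamma.synth import ArrayLayout, Epoch, make_layout


class TestMultitaperCoherence:
    def test_identity_is_one(self, rng):
        x = rng.standard_normal(60000)
        cs = multitaper_coherence(x, x, 1000.0)
        assert np.abs(cs.coherence - 1.0).max() < 1e-9

    def test_symmetry_exact(self, rng):
        x, y = rng.standard_normal((2, 20000))
        a = multitaper_coherence(x, y, 1000.0).coherence
        b = multitaper_coherence(y, x, 1000.0).coherence
        assert np.array_equal(a, b)

    def test_independent_noise_bias_floor(self, rng):
        x, y = rng.standard_normal((2, 300000))
        cs = multitaper_coherence(x, y, 1000.0)
        assert band_coherence(cs) <= 0.10

    @pytest.mark.parametrize("rho", [0.25, 0.5, 0.75])
    def test_shared_source_fraction(self, rho, rng):
        s, n1, n2 = rng.standard_normal((3, 300000))
        a, b = np.sqrt(rho), np.sqrt(1.0 - rho)
        cs = multitaper_coherence(a * s + b * n1, a * s + b * n2, 1000.0)
        assert band_coherence(cs) == pytest.approx(rho, abs=0.05)

    def test_length_mismatch_rejected(self, rng):
        with pytest.raises(ParameterError):
            multitaper_coherence(rng.standard_normal(1000), rng.standard_normal(999), 1000.0)

    def test_bounds_on_simulated_pairs(self, quick_recording):
        lfp = to_lfp(quick_recording)
        ids = lfp.layout.recording_ids[:6]
        seg = lfp.segment(10.0, 70.0)
        for i in range(len(ids)):
            for j in range(i + 1, len(ids)):
                cs = multitaper_coherence(seg[lfp.layout.channel_index(ids[i])],
                                          seg[lfp.layout.channel_index(ids[j])], lfp.fs_hz)
                assert np.all(cs.coherence >= 0.0) and np.all(cs.coherence <= 1.0)


class TestBandCoherence:
    def test_all_ones(self):
        from meagamma.coherence import CoherenceSpectrum
        f = np.linspace(0.0, 500.0, 1001)
        cs = CoherenceSpectrum(f, np.ones_like(f))
        assert band_coherence(cs) == 1.0

    def test_half_band_half_value(self):
        from meagamma.coherence import CoherenceSpectrum
        f = np.arange(0.0, 100.5, 0.5)
        c = np.zeros_like(f)
        band = BandDefinition(25.0, 59.0)
        m = (f >= band.f_lo) & (f <= band.f_hi)
        idx = np.flatnonzero(m)
        c[idx[: idx.size // 2]] = 1.0
        cs = CoherenceSpectrum(f, c)
        assert band_coherence(cs, band) == pytest.approx(0.5, abs=0.02)

    def test_band_outside_range_rejected(self):
        from meagamma.coherence import CoherenceSpectrum
        f = np.linspace(0.0, 30.0, 61)
        with pytest.raises(ParameterError):
            band_coherence(CoherenceSpectrum(f, np.ones_like(f)), BandDefinition(25.0, 59.0))


class TestMonotonicity:
    def test_coherence_monotone_in_shared_fraction(self, rng):
        """Increasing shared power never decreases expected band coherence."""
        rhos = np.linspace(0.1, 0.9, 5)
        means = []
        for rho in rhos:
            vals = []
            for _ in range(20):
                s, n1, n2 = rng.standard_normal((3, 20000))
                a, b = np.sqrt(rho), np.sqrt(1 - rho)
                cs = multitaper_coherence(a * s + b * n1, a * s + b * n2, 1000.0)
                vals.append(band_coherence(cs))
            means.append(np.mean(vals))
        assert np.all(np.diff(means) > 0)


class TestPairwiseTable:
    def test_pair_combinatorics(self, quick_recording):
        lfp = to_lfp(quick_recording)
        windows = {"vehicle": (0.0, 10.0), "kainate": (60.0, 70.0)}
        df = pairwise_table(lfp, windows, window_s=1.0)
        n_ca1 = len(lfp.layout.region_ids("CA1"))   # 30
        n_ca3 = len(lfp.layout.region_ids("CA3"))   # 29
        counts = df[df.condition == "kainate"]["region_pair"].value_counts()
        assert counts[WITHIN_CA1] == n_ca1 * (n_ca1 - 1) // 2
        assert counts[WITHIN_CA3] == n_ca3 * (n_ca3 - 1) // 2
        assert counts[BETWEEN] == n_ca1 * n_ca3
        assert len(df) == 2 * (59 * 58 // 2)

    def test_all_ca1_layout_only_within(self, quick_cfg):
        from meagamma.synth import simulate_recording
        lay = make_layout(region_split=0)
        lfp = to_lfp(simulate_recording(quick_cfg, lay))
        df = pairwise_table(lfp, {"kainate": (60.0, 70.0)}, window_s=1.0)
        assert set(df["region_pair"]) == {WITHIN_CA1}

    def test_within_fold_exceeds_between_when_unmixed(self, quick_cfg, layout):
        """w_between = 0: drug adds shared power within regions only."""
        from meagamma.synth import SimConfig, simulate_recording
        cfg = SimConfig(**{**quick_cfg.to_dict(), "w_between": 0.0, "seed": 21})
        lfp = to_lfp(simulate_recording(cfg, layout))
        # windows of equal length so the estimator bias floor cancels in the ratio
        windows = {"vehicle": (0.0, 10.0), "kainate": (60.0, 70.0)}
        df = pairwise_table(lfp, windows, window_s=1.0)
        drug = df[df.condition == "kainate"]
        fold = drug.groupby("region_pair")["fold_change"].mean()
        assert fold[BETWEEN] == pytest.approx(1.0, abs=0.25)
        assert fold[WITHIN_CA1] > 1.5
        assert fold[WITHIN_CA3] > 1.5


class TestPowerCorrelationMap:
    def _bps(self, power):
        return BandPowerSeries(times_s=np.arange(power.shape[1], dtype=float),
                               power=power, electrode_ids=np.arange(power.shape[0]))

    def test_duplicated_channel_r_one(self, rng):
        base = rng.standard_normal(100)
        p = np.vstack([base, base, rng.standard_normal(100)])
        _, r = power_correlation_map(self._bps(p))
        assert r[0, 1] == pytest.approx(1.0)

    def test_sign_flip_r_minus_one(self, rng):
        base = rng.standard_normal(100)
        _, r = power_correlation_map(self._bps(np.vstack([base, -base])))
        assert r[0, 1] == pytest.approx(-1.0)

    def test_independent_envelopes_mostly_small(self, rng):
        p = rng.standard_normal((30, 100))
        _, r = power_correlation_map(self._bps(p))
        off = r[np.triu_indices(30, 1)]
        assert np.mean(np.abs(off) <= 0.3) >= 0.99

    def test_zero_variance_channel_flagged(self, rng):
        p = np.vstack([np.ones(100), rng.standard_normal(100)])
        with pytest.warns(UserWarning, match="zero-variance"):
            _, r = power_correlation_map(self._bps(p))
        assert np.isnan(r[0, 1])


class TestBuildGraph:
    def _records(self, coh_values, layout):
        ids = layout.recording_ids
        rows = []
        k = 0
        for i in range(len(coh_values)):
            rows.append({"slice_id": "s", "elec1": int(ids[2 * i]), "elec2": int(ids[2 * i + 1]),
                         "region_pair": WITHIN_CA3, "condition": "kainate",
                         "band_coherence": coh_values[i], "fold_change": 1.0})
        return pd.DataFrame(rows)

    def test_threshold_inclusive(self, layout):
        df = self._records([0.45, 0.449], layout)
        g = build_graph(df, {}, layout)
        assert g.number_of_edges() == 1
        u, v, d = list(g.edges(data=True))[0]
        assert d["band_coherence"] == pytest.approx(0.45)

    def test_zero_coherence_edgeless_but_nodes_present(self, layout):
        df = self._records([0.0, 0.0, 0.0], layout)
        g = build_graph(df, {}, layout)
        assert g.number_of_edges() == 0
        assert g.number_of_nodes() == 6

    def test_edge_count_nonincreasing_in_threshold(self, layout, rng):
        df = self._records(list(rng.uniform(0, 1, 20)), layout)
        counts = [build_graph(df, {}, layout, threshold=th).number_of_edges()
                  for th in np.linspace(0.0, 1.0, 11)]
        assert np.all(np.diff(counts) <= 0)

    def test_node_attributes(self, layout):
        df = self._records([0.9], layout)
        g = build_graph(df, {int(layout.recording_ids[0]): 2.5}, layout)
        n0 = g.nodes[int(layout.recording_ids[0])]
        assert n0["band_power"] == 2.5
        assert n0["region"] in ("CA1", "CA3")
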