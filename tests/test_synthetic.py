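"""Synthetic generators: process statistics, coupling modes, blinking.

The generator is the ground-truth source for every downstream stage, so
its own distributional properties are pinned here: Poisson means, seeded
determinism, coupling-mode anchors, and the blinking round trip through
the over-counting correction.
"""

import numpy as np
import pytest

from smlmpatterns import (
    ROI,
    BlinkingParams,
    SyntheticConfig,
    ThomasParams,
    dbscan_clusters,
    emulate_blinking,
    merge_localizations,
    simulate_csr,
    simulate_thomas,
    simulate_two_color,
)


class TestCsr:
    def test_poisson_mean_count(self, roi4um):
        cfg = SyntheticConfig(window=roi4um, process="csr", intensity=100.0)
        counts = [len(simulate_csr(cfg, np.random.default_rng(s))) for s in range(50)]
        # 100 pts/um^2 over 16 um^2 -> mean 1600, sd 40; 50-rep mean sd ~5.7
        assert abs(np.mean(counts) - 1600) < 3 * 40 / np.sqrt(50)

    def test_seeded_determinism(self, roi4um):
        cfg = SyntheticConfig(window=roi4um, process="csr", intensity=50.0, seed=42)
        np.testing.assert_array_equal(simulate_csr(cfg), simulate_csr(cfg))

    def test_points_inside_window(self, roi4um):
        cfg = SyntheticConfig(window=roi4um, process="csr", intensity=20.0)
        pts = simulate_csr(cfg, np.random.default_rng(0))
        assert roi4um.contains(pts[:, 0], pts[:, 1]).all()


class TestThomas:
    def test_mean_total_count_is_product_of_means(self, roi4um):
        # 5 parents/um^2 x 10 offspring x 16 um^2 -> mean 800
        cfg = SyntheticConfig(window=roi4um, process="thomas")
        counts = [
            len(simulate_thomas(cfg, np.random.default_rng(s))[0]) for s in range(50)
        ]
        # var of a Thomas count = lam_p*A*mu*(1+mu); sd ~ sqrt(80*10*11) ~ 94
        assert abs(np.mean(counts) - 800) < 3 * 94 / np.sqrt(50)

    def test_huge_sigma_limit_approaches_csr(self, roi4um):
        from smlmpatterns import default_bins, pcf

        cfg = SyntheticConfig(
            window=roi4um,
            process="thomas",
            thomas=ThomasParams(cluster_sigma=5000.0),
        )
        vals = []
        for s in range(20):
            pts, _, _ = simulate_thomas(cfg, np.random.default_rng(s))
            vals.append(pcf(pts, roi4um, default_bins()).mean_g(20, 200))
        sem = np.std(vals, ddof=1) / np.sqrt(len(vals))
        assert abs(np.mean(vals) - 1.0) < 3 * sem + 1e-9

    def test_parents_recoverable_by_clustering_when_tight(self):
        # tight clusters (sigma 15 nm) on well-separated parents: DBSCAN at
        # 45 nm recovers the parent partition
        w = ROI(0, 4000, 0, 4000)
        rng = np.random.default_rng(5)
        grid = np.array(
            [[400.0 + 800 * i, 400.0 + 800 * j] for i in range(5) for j in range(5)]
        )
        cfg = SyntheticConfig(
            window=w,
            process="thomas",
            thomas=ThomasParams(mean_offspring=8.0, cluster_sigma=15.0),
        )
        pts, parent_idx, _ = simulate_thomas(cfg, rng, parents=grid)
        res = dbscan_clusters(pts, 45.0, 2)
        # every non-monomer cluster maps to exactly one true parent
        for cid in range(res.n_clusters):
            members = parent_idx[res.labels == cid]
            assert len(set(members.tolist())) == 1

    def test_truncate_boundary_drops_outside_children(self):
        w = ROI(0, 1000, 0, 1000)
        parents = np.array([[5.0, 5.0]])  # hugs the corner
        cfg_wrap = SyntheticConfig(window=w, process="thomas", boundary="wrap",
                                   thomas=ThomasParams(mean_offspring=200.0, cluster_sigma=50.0))
        cfg_trunc = SyntheticConfig(window=w, process="thomas", boundary="truncate",
                                    thomas=ThomasParams(mean_offspring=200.0, cluster_sigma=50.0))
        wrap_pts, _, _ = simulate_thomas(cfg_wrap, np.random.default_rng(1), parents=parents)
        trunc_pts, _, _ = simulate_thomas(cfg_trunc, np.random.default_rng(1), parents=parents)
        assert len(trunc_pts) < len(wrap_pts)
        assert w.contains(wrap_pts[:, 0], wrap_pts[:, 1]).all()
        assert w.contains(trunc_pts[:, 0], trunc_pts[:, 1]).all()


class TestTwoColor:
    def test_random_label_splits_binomially(self, roi4um):
        cfg = SyntheticConfig(
            window=roi4um, process="csr", intensity=62.5, coupling="random_label"
        )
        n1, ntot = [], []
        for s in range(30):
            sample = simulate_two_color(cfg, np.random.default_rng(s))
            n1.append(sample.n1)
            ntot.append(sample.n1 + sample.n2)
        frac = np.sum(n1) / np.sum(ntot)
        assert abs(frac - 0.5) < 3 * 0.5 / np.sqrt(np.sum(ntot))

    def test_segregated_zero_displacement_shares_parents(self, roi4um):
        cfg = SyntheticConfig(
            window=roi4um, coupling="segregated", displacement=0.0
        )
        s = simulate_two_color(cfg, np.random.default_rng(0))
        np.testing.assert_array_equal(s.parents1, s.parents2)

    def test_independent_channels_have_separate_parents(self, roi4um):
        cfg = SyntheticConfig(window=roi4um, coupling="independent")
        s = simulate_two_color(cfg, np.random.default_rng(0))
        assert len(s.parents1) != len(s.parents2) or not np.array_equal(
            s.parents1, s.parents2
        )

    def test_ground_truth_sidecar_covers_all_molecules(self, roi4um):
        cfg = SyntheticConfig(window=roi4um, coupling="co_clustered")
        s = simulate_two_color(cfg, np.random.default_rng(0))
        gt = s.ground_truth_frame()
        assert len(gt) == s.n1 + s.n2
        assert set(gt["channel"]) == {1, 2}
        assert (gt["parent"] >= 0).all()

    def test_co_clustered_requires_thomas(self, roi4um):
        cfg = SyntheticConfig(window=roi4um, process="csr", coupling="co_clustered")
        with pytest.raises(ValueError, match="Thomas"):
            simulate_two_color(cfg, np.random.default_rng(0))


class TestBlinking:
    def test_identity_limit(self, roi4um):
        # one emission, no jitter: output reproduces the input exactly
        pts = np.random.default_rng(0).uniform(0, 4000, (50, 2))
        blink = BlinkingParams(mean_emissions=1.0, localization_sigma=0.0)
        table = emulate_blinking(pts, blinking=blink, rng=np.random.default_rng(1))
        assert len(table) == 50
        got = table.data.sort_values("molecule_id")[["x", "y"]].to_numpy()
        np.testing.assert_array_equal(got, pts)

    def test_mean_emission_count(self):
        pts = np.zeros((400, 2))
        blink = BlinkingParams(mean_emissions=4.0)
        table = emulate_blinking(pts, blinking=blink, rng=np.random.default_rng(2))
        # geometric mean 4 -> sd sqrt(12); 400-molecule total sd ~ 69
        assert abs(len(table) - 1600) < 3 * np.sqrt(400 * 12)

    def test_records_sorted_by_frame(self, rng):
        pts = rng.uniform(0, 1000, (100, 2))
        table = emulate_blinking(pts, blinking=BlinkingParams(), rng=rng)
        frames = table.data["frame"].to_numpy()
        assert (np.diff(frames) >= 0).all()

    def test_seeded_determinism(self, roi4um):
        cfg = SyntheticConfig(window=roi4um, process="thomas", seed=7)
        pts, _, _ = simulate_thomas(cfg, np.random.default_rng(7))
        a = emulate_blinking(pts, cfg, rng=np.random.default_rng(8))
        b = emulate_blinking(pts, cfg, rng=np.random.default_rng(8))
        import pandas.testing as pdt

        pdt.assert_frame_equal(a.data, b.data)

    def test_round_trip_recovers_molecule_count_default_sigma(self):
        # 100 well-separated molecules, default 15 nm precision; merge
        # radius 60 nm (~4 sigma) matched to the jitter
        grid = np.array(
            [[200.0 + 360 * i, 200.0 + 360 * j] for i in range(10) for j in range(10)]
        )
        blink = BlinkingParams(mean_emissions=4.0, localization_sigma=15.0)
        table = emulate_blinking(grid, blinking=blink, rng=np.random.default_rng(3))
        merged = merge_localizations(table, 60.0, 50.0, frame_rate=13.4)
        assert abs(len(merged) - 100) <= 10

    def test_round_trip_at_paper_thresholds_with_matched_precision(self):
        # the standard (20 nm, 50 ms) merge settings presume ~5 nm
        # per-axis localization precision
        grid = np.array(
            [[200.0 + 360 * i, 200.0 + 360 * j] for i in range(10) for j in range(10)]
        )
        blink = BlinkingParams(mean_emissions=4.0, localization_sigma=5.0)
        table = emulate_blinking(grid, blinking=blink, rng=np.random.default_rng(4))
        merged = merge_localizations(table, 20.0, 50.0, frame_rate=13.4)
        assert abs(len(merged) - 100) <= 10

    def test_round_trip_position_error_scale(self):
        # merged positions average the jitter down toward sigma/sqrt(k)
        grid = np.array(
            [[300.0 + 500 * i, 300.0 + 500 * j] for i in range(8) for j in range(8)]
        )
        blink = BlinkingParams(mean_emissions=4.0, localization_sigma=15.0)
        table = emulate_blinking(grid, blinking=blink, rng=np.random.default_rng(5))
        merged = merge_localizations(table, 60.0, 50.0, frame_rate=13.4)
        got = merged.data[["x", "y"]].to_numpy()
        # match each molecule to its nearest recovered position
        from scipy.spatial import cKDTree

        d, _ = cKDTree(got).query(grid)
        rms = float(np.sqrt(np.mean(d**2)))
        # per-axis RMS of a k-averaged position is sigma/sqrt(k); the 2D
        # radial error is sqrt(2) larger, k ~ mean_emissions
        assert rms < 3 * 15.0 / np.sqrt(4.0) * np.sqrt(2)

    def test_gap_frames_distribution_spreads_bursts(self):
        pts = np.zeros((200, 2))
        tight = emulate_blinking(
            pts,
            blinking=BlinkingParams(mean_emissions=4.0, gap_frames_mean=0.0),
            rng=np.random.default_rng(6),
        )
        spread = emulate_blinking(
            pts,
            blinking=BlinkingParams(mean_emissions=4.0, gap_frames_mean=5.0),
            rng=np.random.default_rng(6),
        )

        def mean_span(table):
            g = table.data.groupby("molecule_id")["frame"]
            return float((g.max() - g.min()).mean())

        assert mean_span(spread) > mean_span(tight)
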