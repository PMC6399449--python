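"""TF network loading/filtering, spline peak detection, phase classification."""

import math

import numpy as np
import pandas as pd
import pytest

from perioscope import preprocess, synthetic, tf_phase
from perioscope.matrix import ExpressionMatrix
from perioscope.tf_phase import (
    TFNetwork,
    classify_phases,
    detect_target_peaks,
    filter_oscillating_tfs,
    load_tf_network,
    mean_target_signal,
    phase_resolution,
)


def log2fc(rows: dict, times):
    df = pd.DataFrame(rows, index=times).T
    return ExpressionMatrix(df, stage="log2fc")


def network(edges):
    return TFNetwork(pd.DataFrame(edges, columns=["tf", "target", "evidence"]))


class TestLoadNetwork:
    def test_three_row_file(self, tmp_path):
        p = tmp_path / "edges.tsv"
        p.write_text("tf\ttarget\tevidence\nA\tx\tboth\nA\ty\tboth\nB\tz\tdna\n")
        net = load_tf_network(p)
        assert len(net.edges) == 3

    def test_duplicate_rows_collapse_with_warning(self, tmp_path):
        p = tmp_path / "edges.tsv"
        p.write_text("A\tx\tboth\nA\tx\tboth\n")
        with pytest.warns(UserWarning, match="duplicate"):
            net = load_tf_network(p)
        assert len(net.edges) == 1

    def test_evidence_filter(self, tmp_path):
        p = tmp_path / "edges.tsv"
        p.write_text("A\tx\tboth\nA\ty\tdna\nB\tz\tboth\n")
        net = load_tf_network(p, evidence="both")
        assert len(net.edges) == 2

    def test_malformed_row_reports_line_number(self, tmp_path):
        p = tmp_path / "edges.tsv"
        p.write_text("A\tx\tboth\nbroken-line\n")
        with pytest.raises(ValueError, match=":2"):
            load_tf_network(p)


class TestMeanTargetSignal:
    def test_single_target_returns_its_trajectory(self, time_grid):
        y = np.sin(time_grid / 10)
        m = log2fc({"x": y - y.mean()}, time_grid)
        net = network([("A", "x", "both")])
        np.testing.assert_allclose(mean_target_signal(net, "A", m), y - y.mean())

    def test_opposite_trajectories_cancel(self, time_grid):
        y = np.cos(2 * np.pi * time_grid / 64)
        m = log2fc({"x": y, "y": -y}, time_grid)
        net = network([("A", "x", "both"), ("A", "y", "both")])
        np.testing.assert_allclose(mean_target_signal(net, "A", m), 0.0, atol=1e-12)

    def test_no_measured_target_is_an_error(self, time_grid):
        m = log2fc({"x": np.zeros(22)}, time_grid)
        with pytest.raises(ValueError, match="no measured target"):
            mean_target_signal(network([("A", "zzz", "both")]), "A", m)


class TestFilterOscillatingTFs:
    def test_two_target_tf_discarded_despite_perfect_periodicity(self, time_grid):
        y = np.cos(2 * np.pi * (time_grid - 20) / 64)
        m = log2fc({"x": y, "y": y}, time_grid)
        net = network([("A", "x", "both"), ("A", "y", "both")])
        out = filter_oscillating_tfs(net, m, score_cutoff=0.0, min_targets=3)
        assert out.tf_scores == {}

    def test_flat_targets_discarded_on_score(self, time_grid):
        rng = np.random.default_rng(0)
        rows = {f"x{i}": rng.normal(0, 0.05, 22) for i in range(10)}
        m = log2fc(rows, time_grid)
        net = network([("A", f"x{i}", "both") for i in range(10)])
        with pytest.warns(UserWarning, match="no TF passes"):
            out = filter_oscillating_tfs(net, m, score_cutoff=15.0)
        assert out.tf_scores == {}

    def test_synthetic_classification_groups_retained_distractors_dropped(
        self, wt_preset, calibration
    ):
        net, m = synthetic.simulate_tf_network(wt_preset, seed=3)
        fc = preprocess.preprocess_counts(m)
        out = filter_oscillating_tfs(net, fc, score_cutoff=calibration.score_cutoff)
        expected = {tf for _, tfs in synthetic.CLASSIFICATION_GROUPS for tf in tfs}
        assert set(out.tf_scores) == expected
        assert "DIST_SMALL" not in out.tf_scores
        assert "DIST_FLAT" not in out.tf_scores

    def test_raising_cutoff_never_adds_a_tf(self, wt_preset, calibration):
        net, m = synthetic.simulate_tf_network(wt_preset, seed=3)
        fc = preprocess.preprocess_counts(m)
        lo = set(filter_oscillating_tfs(net, fc, score_cutoff=5.0).tf_scores)
        hi = set(filter_oscillating_tfs(net, fc, score_cutoff=30.0).tf_scores)
        assert hi <= lo

    def test_edges_between_retained_tfs_oriented_by_peak_time(self, time_grid):
        early = np.cos(2 * np.pi * (time_grid - 10) / 64)
        late = np.cos(2 * np.pi * (time_grid - 40) / 64)
        rows = {f"e{i}": early for i in range(3)} | {f"l{i}": late for i in range(3)}
        rows["B"] = late  # TF B is itself a target of A
        m = log2fc(rows, time_grid)
        edges = [("A", f"e{i}", "both") for i in range(3)]
        edges += [("B", f"l{i}", "both") for i in range(3)]
        edges += [("A", "B", "both")]
        out = filter_oscillating_tfs(network(edges), m, score_cutoff=1.0)
        assert out.edge_orientation is not None
        row = out.edge_orientation.iloc[0]
        assert (row["tf"], row["target"], row["orientation"]) == ("A", "B", "forward")


class TestPeakDetection:
    def test_monotone_signal_has_no_peaks(self, time_grid):
        assert detect_target_peaks(time_grid, time_grid / 150.0) == []

    def test_cosine_peaks_found_terminal_peak_ineligible(self, time_grid):
        y = np.cos(2 * np.pi * (time_grid - 20) / 64)
        peaks = detect_target_peaks(time_grid, y)
        assert len(peaks) == 2
        assert peaks[0] == pytest.approx(20, abs=1)
        assert peaks[1] == pytest.approx(84, abs=1)  # 148 falls in the truncated window

    def test_plateau_ties_are_not_peaks(self):
        t = np.arange(0.0, 41.0, 1.0)
        y = np.minimum(t, 40 - t)
        y[19] = y[21] = y[20]  # flat top: no strict exceedance
        assert detect_target_peaks(t, y, window=10) == []

    def test_matches_literal_grid_scan(self, time_grid):
        rng = np.random.default_rng(5)
        from scipy.interpolate import CubicSpline

        for _ in range(10):
            y = rng.normal(0, 1, len(time_grid))
            peaks = detect_target_peaks(time_grid, y)
            spline = CubicSpline(time_grid, y, bc_type="natural")
            grid = np.arange(0.0, 151.0)
            g = spline(grid)
            literal = [
                float(grid[i])
                for i in range(10, len(grid) - 10)
                if all(g[i] > g[j] for j in range(i - 10, i + 11) if j != i)
            ]
            assert peaks == literal

    def test_too_short_signal_rejected(self):
        with pytest.raises(ValueError):
            detect_target_peaks(np.array([0.0]), np.array([1.0]))


def group_matrix(time_grid, peak_times, n_targets=4, noise=0.0, seed=0, period=64.0):
    """Synthetic log2fc matrix + network with one TF per requested peak time."""
    rng = np.random.default_rng(seed)
    rows, edges = {}, []
    for k, phi in enumerate(peak_times):
        tf = f"TF{k}"
        for j in range(n_targets):
            y = 1.2 * np.cos(2 * np.pi * (time_grid - phi) / period)
            rows[f"{tf}_t{j}"] = y + rng.normal(0, noise, len(time_grid))
            edges.append((tf, f"{tf}_t{j}", "both"))
    return log2fc(rows, time_grid), network(edges)


class TestClassifyPhases:
    def test_transition_is_mean_of_tf_peaks(self, time_grid):
        m, net = group_matrix(time_grid, [18.0, 22.0])
        groups = [("G1/S", ["TF0", "TF1"])]
        ann = classify_phases(groups, net, m)
        assert ann.transitions["G1/S"] == pytest.approx(20.0, abs=1.0)

    def test_out_of_order_peak_invalidates_annotation(self, time_grid):
        # second group's only peak is earlier than the first group's
        m, net = group_matrix(time_grid, [40.0, 15.0])
        groups = [("G1/S", ["TF0"]), ("S/G2", ["TF1"])]
        ann = classify_phases(groups, net, m)
        assert not ann.complete
        # the 15-min peak is invalid; the second-cycle peak (~79) would be
        # next, so G1/S is assigned but S/G2 jumps a cycle or stays empty
        assert "G1/S" in ann.transitions

    def test_noise_free_boundary_recovery_within_interpolation_resolution(
        self, wt_preset, time_grid
    ):
        bounds = wt_preset.phase_boundaries()
        m, net = group_matrix(
            time_grid,
            [bounds[k] for k in ("G1/S", "S/G2", "G2/M", "M/G1")],
            noise=0.0,
        )
        groups = [(k, [f"TF{i}"]) for i, k in enumerate(("G1/S", "S/G2", "G2/M", "M/G1"))]
        ann = classify_phases(groups, net, m)
        assert ann.complete
        for i, k in enumerate(("G1/S", "S/G2", "G2/M", "M/G1")):
            assert ann.transitions[k] == pytest.approx(bounds[k], abs=1.0)
        assert ann.transitions["G1/S"] < ann.transitions["S/G2"] < ann.transitions["G2/M"]

    def test_durations_merge_g2_and_m(self, time_grid):
        m, net = group_matrix(time_grid, [14.0, 34.0, 49.0, 64.0], period=64.0)
        groups = [(k, [f"TF{i}"]) for i, k in enumerate(("G1/S", "S/G2", "G2/M", "M/G1"))]
        ann = classify_phases(groups, net, m)
        assert ann.durations["G1"] == pytest.approx(14.0, abs=1.0)
        assert ann.durations["S"] == pytest.approx(20.0, abs=1.5)
        assert ann.durations["G2M"] == pytest.approx(30.0, abs=1.5)


class TestPhaseResolution:
    def _setup(self, seeds, noise):
        grid = synthetic.default_time_grid()
        mats, net = [], None
        preset = synthetic.make_strain_preset("WT")
        bounds = preset.phase_boundaries()
        for s in seeds:
            m, net = group_matrix(
                grid, [bounds[k] for k in ("G1/S", "S/G2", "G2/M", "M/G1")],
                n_targets=8, noise=noise, seed=s,
            )
            mats.append(m)
        groups = [(k, [f"TF{i}"]) for i, k in enumerate(("G1/S", "S/G2", "G2/M", "M/G1"))]
        return mats, net, groups

    def test_identical_replicates_have_zero_spread(self):
        mats, net, groups = self._setup([3, 3], noise=0.0)
        assert phase_resolution(mats, groups, net) == 0.0

    def test_single_replicate_rejected(self):
        mats, net, groups = self._setup([3], noise=0.0)
        with pytest.raises(ValueError):
            phase_resolution(mats[:1], groups, net)
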