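"""Pearson correlation, index-level and edge-level screening."""

import numpy as np
import pandas as pd
import pytest
import scipy.stats
from oracles import permutation_pearson

from p3net.io import Adjacency, DEFAULT_CHANNELS
from p3net.stats import edgewise_correlations, metric_correlations, pearson


class TestPearson:
    def test_perfect_linear_relationships(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        r, p = pearson(x, 2 * x + 1)
        assert r == pytest.approx(1.0)
        assert p == pytest.approx(0.0, abs=1e-12)
        r, p = pearson(x, -x)
        assert r == pytest.approx(-1.0)

    def test_hand_computed_example(self):
        """r = 0.6 for (1,2,3,4) vs (2,1,4,3); p from t = 1.0607 on 2 df."""
        x = np.array([1.0, 2.0, 3.0, 4.0])
        y = np.array([2.0, 1.0, 4.0, 3.0])
        r, p = pearson(x, y)
        assert r == pytest.approx(0.6, abs=1e-12)
        t = 0.6 * np.sqrt(2 / (1 - 0.36))
        assert t == pytest.approx(1.06066, abs=1e-4)
        assert p == pytest.approx(2 * scipy.stats.t.sf(t, df=2), abs=1e-12)

    def test_agrees_with_permutation_oracle(self, rng):
        """Sign matches exactly; p matches the exact permutation null
        to within the usual t-vs-permutation discrepancy at tiny n."""
        for _ in range(5):
            x = rng.normal(size=6)
            y = 0.8 * x + rng.normal(size=6)
            r, p = pearson(x, y)
            r_perm, p_perm = permutation_pearson(x, y)
            assert np.sign(r) == np.sign(r_perm)
            assert r == pytest.approx(r_perm, abs=1e-10)
            assert abs(p - p_perm) < 0.12

    def test_affine_invariance(self, rng):
        x = rng.normal(size=20)
        y = rng.normal(size=20)
        r0, p0 = pearson(x, y)
        r1, p1 = pearson(3.0 * x - 7.0, 0.5 * y + 2.0)
        assert r1 == pytest.approx(r0, abs=1e-12)
        assert p1 == pytest.approx(p0, abs=1e-12)

    def test_error_paths(self):
        with pytest.raises(ValueError, match="constant input"):
            pearson([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        with pytest.raises(ValueError, match="equal-length"):
            pearson([1.0, 2.0, 3.0], [1.0, 2.0])
        with pytest.raises(ValueError, match="at least 3"):
            pearson([1.0, 2.0], [1.0, 2.0])


def _tables(n=20, rho_noise=0.1, seed=0):
    """Truth-level metric/P3 tables with known positive coupling and the
    characteristic sign flip for path length."""
    rng = np.random.default_rng(seed)
    le = rng.uniform(0.2, 0.8, size=n)
    noise = lambda: rho_noise * rng.normal(size=n)
    metrics = pd.DataFrame({
        "subject_id": [f"s{i}" for i in range(n)],
        "MFC": 0.2 + 0.5 * le + noise(),
        "C": 0.15 + 0.5 * le + noise(),
        "Ge": 0.25 + 0.5 * le + noise(),
        "Le": 0.2 + 0.5 * le + noise(),
        "L": 1.0 / (0.25 + 0.5 * le + noise()),
    })
    p3 = pd.DataFrame({
        "subject_id": [f"s{i}" for i in range(n)],
        "amplitude": 4.27 + 2.0 * (le - 0.5) + noise(),
        "latency": 400.0 + 30.0 * rng.normal(size=n),
    })
    return metrics, p3


class TestMetricCorrelations:
    def test_sign_pattern_on_coupled_tables(self):
        metrics, p3 = _tables()
        out = metric_correlations(metrics, p3)
        amp = out[out["y"] == "amplitude"].set_index("x")["r"]
        assert (amp[["MFC", "C", "Ge", "Le"]] > 0).all()
        assert amp["L"] < 0
        assert len(out) == 11  # 5 indexes x 2 measures + amp-lat

    def test_row_order_is_irrelevant(self):
        metrics, p3 = _tables()
        shuffled = p3.sample(frac=1.0, random_state=3).reset_index(drop=True)
        a = metric_correlations(metrics, p3)
        b = metric_correlations(metrics, shuffled)
        pd.testing.assert_frame_equal(a, b)

    def test_mismatched_ids_error(self):
        metrics, p3 = _tables()
        p3 = p3.drop(index=0)
        with pytest.raises(ValueError, match="s0"):
            metric_correlations(metrics, p3)


def _null_adjacencies(rng, n_subjects, labels=DEFAULT_CHANNELS):
    out = {}
    n = len(labels)
    for s in range(n_subjects):
        w = rng.uniform(0.1, 0.9, size=(n, n))
        w = (w + w.T) / 2
        np.fill_diagonal(w, 0.0)
        out[f"s{s:02d}"] = Adjacency(w=w, labels=list(labels))
    return out


class TestEdgewise:
    def test_planted_edge_detected_false_flags_bounded(self, rng):
        n_sub = 24
        adjs = _null_adjacencies(rng, n_sub)
        ids = sorted(adjs)
        amp = rng.normal(4.3, 1.1, size=n_sub)
        # make edge (CPz, Pz) an affine function of amplitude
        i = list(DEFAULT_CHANNELS).index("CPz")
        j = list(DEFAULT_CHANNELS).index("Pz")
        for k, sid in enumerate(ids):
            w = adjs[sid].w
            w[i, j] = w[j, i] = 0.1 + 0.08 * (amp[k] - 2.0)
        p3 = pd.DataFrame({"subject_id": ids, "amplitude": amp,
                           "latency": rng.normal(400, 30, size=n_sub)})
        out = edgewise_correlations(adjs, p3, alpha=0.01)
        planted = out[(out["node_i"].isin(["CPz", "Pz"]))
                      & (out["node_j"].isin(["CPz", "Pz"]))]
        assert bool(planted["sig_amp"].iloc[0])
        # 209 null edges at alpha=0.01: expect ~2 false flags; bound at 9
        assert int(out["sig_amp"].sum()) - 1 <= 9
        # the planted edge dominates the |r| ordering
        assert sorted(out.iloc[0][["node_i", "node_j"]]) == ["CPz", "Pz"]
        assert len(out) == 210

    def test_alpha_one_flags_everything(self, rng):
        adjs = _null_adjacencies(rng, 10)
        ids = sorted(adjs)
        p3 = pd.DataFrame({"subject_id": ids,
                           "amplitude": rng.normal(size=10),
                           "latency": rng.normal(size=10)})
        out = edgewise_correlations(adjs, p3, alpha=1.0)
        assert out["sig_amp"].all() and out["sig_lat"].all()

    def test_bh_controls_null_flags(self, rng):
        flags = 0
        for seed in range(10):
            r = np.random.default_rng(seed)
            adjs = _null_adjacencies(r, 15)
            ids = sorted(adjs)
            p3 = pd.DataFrame({"subject_id": ids,
                               "amplitude": r.normal(size=15),
                               "latency": r.normal(size=15)})
            out = edgewise_correlations(adjs, p3, alpha=0.05,
                                        correction="bh")
            flags += int(out["sig_amp"].sum())
        assert flags <= 2  # FDR on a global null: flags are rare

    def test_inconsistent_node_order_error(self, rng):
        adjs = _null_adjacencies(rng, 5)
        ids = sorted(adjs)
        other = list(DEFAULT_CHANNELS)[::-1]
        adjs[ids[2]] = Adjacency(w=adjs[ids[2]].w, labels=other)
        p3 = pd.DataFrame({"subject_id": ids,
                           "amplitude": rng.normal(size=5),
                           "latency": rng.normal(size=5)})
        with pytest.raises(ValueError, match="node order"):
            edgewise_correlations(adjs, p3)

    def test_output_sorted_by_amplitude_correlation(self, rng):
        adjs = _null_adjacencies(rng, 12)
        ids = sorted(adjs)
        p3 = pd.DataFrame({"subject_id": ids,
                           "amplitude": rng.normal(size=12),
                           "latency": rng.normal(size=12)})
        out = edgewise_correlations(adjs, p3)
        mags = out["r_amp"].abs().to_numpy()
        assert np.all(np.diff(mags) <= 1e-12)
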