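"""Single-molecule co-accessibility machinery: anchoring, windowing,
pairing (against an exhaustive reference), clustering, binarization and
the Fisher dependence test."""

import numpy as np
import pandas as pd
import pytest

from tridram import simgen, singlemol
from tridram.singlemol import (FilterIntervalSet, binarize,
                               cluster_observations, dependence_test,
                               filter_calls_by_window, pair_observations)
from conftest import make_calls


def _iv(midpoints, strands=None, chrom="chr1"):
    strands = strands or ["+"] * len(midpoints)
    return pd.DataFrame({
        "chrom": chrom, "start": [m - 10 for m in midpoints],
        "end": [m + 10 for m in midpoints],
        "name": [f"iv{i}" for i in range(len(midpoints))],
        "score": 0.0, "strand": strands})


# ---------------------------------------------------------------------------
# exhaustive O(n*m) reference for the anchoring/filter/pair path


def reference_observations(calls, anchorsA, anchorsB, window, min_sep,
                           max_sep, context="GCH"):
    feats = {}
    for key, df in (("A", anchorsA), ("B", anchorsB)):
        feats[key] = [((int(r.start) + int(r.end)) // 2, r.chrom, i)
                      for i, r in enumerate(df.itertuples(index=False))]

    def retained(side):
        rows = []
        for c in calls.itertuples(index=False):
            if c.context != context or c.source != "genomic":
                continue
            best, bestd = None, None
            for mid, chrom, i in feats[side]:
                if chrom != c.chrom:
                    continue
                d = abs(c.pos - mid)
                if bestd is None or d < bestd or (d == bestd and mid < best[0]):
                    best, bestd = (mid, i), d
            if best is not None and bestd <= window / 2:
                rows.append((c.read_id, c.mate, c.pos, bestd, best[1],
                             best[0], c.state == "methylated"))
        return rows

    def summarize(rows):
        out = {}
        for rid, mate, pos, d, aid, amid, meth in sorted(
                rows, key=lambda r: (r[0], r[1], r[3], r[2])):
            key = (rid, mate)
            if key not in out:
                out[key] = {"n": 0, "s": 0.0, "aid": aid, "amid": amid}
            out[key]["n"] += 1
            out[key]["s"] += meth
        return out

    sa, sb = summarize(retained("A")), summarize(retained("B"))
    obs = {}
    for mate_a, mate_b in ((1, 2), (2, 1)):
        for (rid, mate), a in sa.items():
            if mate != mate_a:
                continue
            b = sb.get((rid, mate_b))
            if b is None:
                continue
            sep = abs(a["amid"] - b["amid"])
            if sep < min_sep or (max_sep is not None and sep > max_sep):
                continue
            if rid not in obs:
                obs[rid] = (a["aid"], b["aid"], a["n"], b["n"],
                            a["s"] / a["n"], b["s"] / b["n"], sep)
    return obs


class TestNearestInterval:
    def test_basic_and_tie_rule(self):
        iv = FilterIntervalSet(_iv([100, 500]))
        row, d = iv.nearest("chr1", 120)
        assert iv.features.loc[row, "midpoint"] == 100 and d == 20
        row, d = iv.nearest("chr1", 300)          # equidistant
        assert iv.features.loc[row, "midpoint"] == 100 and d == 200

    def test_empty_chromosome_signals_not_found(self):
        iv = FilterIntervalSet(_iv([100]))
        with pytest.raises(singlemol.NotFoundError):
            iv.nearest("chr2", 10)

    def test_matches_linear_scan_oracle(self):
        rng = np.random.default_rng(53)
        mids = sorted(int(m) for m in
                      np.unique(rng.integers(100, 100_000, 80)))
        iv = FilterIntervalSet(_iv(mids))
        queries = rng.integers(0, 110_000, 1000)
        vec_rows, vec_d = iv.nearest_many("chr1", np.sort(queries))
        for pos, vrow, vd in zip(np.sort(queries), vec_rows, vec_d):
            best = min(mids, key=lambda m: (abs(int(pos) - m), m))
            row, d = iv.nearest("chr1", int(pos))
            assert iv.features.loc[row, "midpoint"] == best
            assert d == abs(int(pos) - best)
            assert (row, d) == (vrow, vd)


class TestWindowFilter:
    def test_window_boundary(self):
        iv = FilterIntervalSet(_iv([1000]))
        calls = make_calls([("r1", 1, "chr1", 1049, "GCH", "methylated"),
                            ("r2", 1, "chr1", 1051, "GCH", "methylated")])
        out = filter_calls_by_window(calls, iv, window=100)
        assert list(out["read_id"]) == ["r1"]

    def test_positive_window_required(self):
        with pytest.raises(singlemol.InputError):
            filter_calls_by_window(make_calls([]), FilterIntervalSet(_iv([5])),
                                   window=0)


class TestPathOracle:
    def test_full_path_equals_exhaustive_reference(self):
        """Anchoring + window filter + pairing on ~1,000 calls x 100
        intervals must equal the O(n*m) reference exactly."""
        rng = np.random.default_rng(59)
        mids = sorted(int(m) for m in np.unique(rng.integers(500, 200_000, 100)))
        anchorsA = _iv(mids[:50])
        anchorsB = _iv(mids[50:])
        rows = []
        for i in range(250):
            for mate in (1, 2):
                base = int(rng.choice(mids)) + int(rng.integers(-120, 120))
                for k in range(rng.integers(1, 4)):
                    rows.append((f"rp{i}", mate, "chr1",
                                 base + int(rng.integers(-60, 60)), "GCH",
                                 "methylated" if rng.random() < 0.5
                                 else "unmethylated"))
        calls = make_calls(rows)
        assert len(calls) <= 1000

        ivA, ivB = FilterIntervalSet(anchorsA), FilterIntervalSet(anchorsB)
        fA = filter_calls_by_window(calls, ivA, 100)
        fB = filter_calls_by_window(calls, ivB, 100)
        obs = pair_observations(fA, fB, min_sep=1000, max_sep=None)
        ref = reference_observations(calls, anchorsA, anchorsB, 100, 1000, None)

        assert set(obs["pair_id"]) == set(ref)
        for row in obs.itertuples(index=False):
            aid, bid, na, nb, ma, mb, sep = ref[row.pair_id]
            assert (row.anchorA_id, row.anchorB_id) == (aid, bid)
            assert (row.n_callsA, row.n_callsB) == (na, nb)
            assert row.meanA == pytest.approx(ma, abs=1e-12)
            assert row.meanB == pytest.approx(mb, abs=1e-12)
            assert row.separation == sep


class TestPairing:
    def _calls_at(self, rid, mate, pos, state="methylated"):
        return (rid, mate, "chr1", pos, "GCH", state)

    def test_separation_limits(self):
        ivA = FilterIntervalSet(_iv([1000]))
        ivB = FilterIntervalSet(_iv([1200, 10_000]))
        calls = make_calls([
            self._calls_at("near", 1, 1000), self._calls_at("near", 2, 1210),
            self._calls_at("far", 1, 990), self._calls_at("far", 2, 10_020)])
        fA = filter_calls_by_window(calls, ivA, 100)
        fB = filter_calls_by_window(calls, ivB, 100)
        assert list(pair_observations(fA, fB, min_sep=1000)["pair_id"]) == ["far"]
        assert list(pair_observations(fA, fB, min_sep=0, max_sep=500)
                    ["pair_id"]) == ["near"]

    def test_convergent_orientation_rule(self):
        ivA = FilterIntervalSet(_iv([1000], ["+"]))
        conv = FilterIntervalSet(_iv([5000], ["-"]))
        div = FilterIntervalSet(_iv([5000], ["+"]))
        calls = make_calls([self._calls_at("r", 1, 1010),
                            self._calls_at("r", 2, 4990)])
        fA = filter_calls_by_window(calls, ivA, 100)
        assert len(pair_observations(
            fA, filter_calls_by_window(calls, conv, 100),
            min_sep=1000, orientation="convergent")) == 1
        assert len(pair_observations(
            fA, filter_calls_by_window(calls, div, 100),
            min_sep=1000, orientation="convergent")) == 0

    def test_presets_match_stated_parameters(self):
        p = singlemol.PRESETS
        assert p["ctcf_convergent"]["min_sep"] == 1000
        assert p["ctcf_convergent"]["orientation"] == "convergent"
        assert p["cre_tss"]["min_sep"] == 5000
        assert p["tf_pair"]["window"] == 50
        assert (p["tf_pair"]["min_sep"], p["tf_pair"]["max_sep"]) == (100, 300)


class TestClustering:
    def _blobs(self, n_per=25, jitter=0.02, seed=61):
        rng = np.random.default_rng(seed)
        centers = [(1, 1), (1, 0), (0, 1), (0, 0)]
        rows = []
        for cx, cy in centers:
            for _ in range(n_per):
                rows.append((cx + jitter * rng.standard_normal(),
                             cy + jitter * rng.standard_normal()))
        return pd.DataFrame(rows, columns=["meanA", "meanB"])

    def test_separated_blobs_recovered_in_order(self):
        obs = self._blobs()
        labels, means = cluster_observations(obs, k=4, seed=1)
        # cluster 1 is (1,1), cluster 4 is (0,0)
        assert means.iloc[0][["meanA", "meanB"]].to_numpy() == pytest.approx(
            [1, 1], abs=0.1)
        assert means.iloc[3][["meanA", "meanB"]].to_numpy() == pytest.approx(
            [0, 0], abs=0.1)
        first_blob = labels[:25]
        assert (first_blob == 1).all()

    def test_deterministic_under_seed(self):
        obs = self._blobs(jitter=0.2)
        l1, _ = cluster_observations(obs, k=4, seed=5)
        l2, _ = cluster_observations(obs, k=4, seed=5)
        assert (l1 == l2).all()

    def test_beats_random_assignments(self):
        obs = self._blobs(n_per=10, jitter=0.15)
        X = obs[["meanA", "meanB"]].to_numpy()
        labels, _ = cluster_observations(obs, k=4, seed=2)

        def wcss(assign):
            return sum(((X[assign == c] - X[assign == c].mean(0)) ** 2).sum()
                       for c in np.unique(assign))

        ours = wcss(labels)
        rng = np.random.default_rng(3)
        rand = [wcss(rng.integers(1, 5, len(X))) for _ in range(1000)]
        assert ours <= min(rand)

    def test_too_few_rows_rejected(self):
        with pytest.raises(singlemol.InputError):
            cluster_observations(self._blobs(n_per=25).head(3), k=4)


class TestBinarizeAndDependence:
    def _obs(self, means, n_calls=3):
        return pd.DataFrame({
            "n_callsA": n_calls, "n_callsB": n_calls,
            "meanA": [m[0] for m in means], "meanB": [m[1] for m in means]})

    def test_threshold_boundary_is_open(self):
        a, b, _ = binarize(self._obs([(0.5, 0.0)]), threshold=0.5)
        assert a[0] and not b[0]

    def test_insufficient_calls_excluded_and_counted(self):
        obs = self._obs([(1, 1), (0, 0)])
        obs.loc[0, "n_callsA"] = 0
        a, b, n_excl = binarize(obs, min_calls=1)
        assert n_excl == 1 and len(a) == 1

    def test_cofraction_monotone_in_threshold(self):
        rng = np.random.default_rng(67)
        obs = self._obs(list(zip(rng.random(200), rng.random(200))))
        fracs = []
        for thr in (0.1, 0.3, 0.5, 0.7, 0.9):
            a, b, _ = binarize(obs, threshold=thr)
            fracs.append(dependence_test(a, b)["co_accessible_fraction"])
        assert all(x >= y for x, y in zip(fracs, fracs[1:]))

    def test_closed_form_odds_ratio(self):
        a = np.repeat([True, True, False, False], [30, 10, 10, 20])
        b = np.repeat([True, False, True, False], [30, 10, 10, 20])
        # reorder into matched vectors: 20/10/10/20 table
        a = np.array([True] * 20 + [True] * 10 + [False] * 10 + [False] * 20)
        b = np.array([True] * 20 + [False] * 10 + [True] * 10 + [False] * 20)
        res = dependence_test(a, b)
        assert res["table"] == [[20, 10], [10, 20]]
        assert res["odds_ratio"] == pytest.approx(4.0)

    def test_independent_table(self):
        a = np.array([True] * 50 + [False] * 50)
        b = np.array(([True] * 25 + [False] * 25) * 2)
        res = dependence_test(a, b)
        assert res["odds_ratio"] == pytest.approx(1.0)
        assert res["p_value"] == pytest.approx(1.0)

    def test_degenerate_margin(self):
        res = dependence_test(np.array([True, True]), np.array([True, False]))
        assert res["odds_ratio"] is None and res["p_value"] == 1.0

    def test_haldane_correction_on_zero_cell(self):
        a = np.array([True] * 10 + [False] * 10)
        b = np.array([True] * 10 + [False] * 10)
        res = dependence_test(a, b)      # n10 = n01 = 0
        assert res["odds_ratio"] == pytest.approx((10.5 * 10.5) / 0.25)

    def test_type_one_error_near_alpha(self):
        rng = np.random.default_rng(71)
        rej = 0
        reps = 200
        for _ in range(reps):
            o1, o2 = simgen.sample_joint_states(500, 0.3, 0.3, 1.0, rng)
            if dependence_test(o1, o2)["p_value"] < 0.05:
                rej += 1
        assert 0.01 <= rej / reps <= 0.09


class TestFullPath:
    def test_symmetry_under_anchor_swap(self, anchored_sim, anchors_bed):
        _, _, _, _, calls = anchored_sim
        a_feats = anchors_bed[anchors_bed["strand"] == "+"]
        b_feats = anchors_bed[anchors_bed["strand"] == "-"]
        r1 = singlemol.co_accessibility(calls, a_feats, b_feats,
                                        min_sep=1000, seed=1)
        r2 = singlemol.co_accessibility(calls, b_feats, a_feats,
                                        min_sep=1000, seed=1)
        t1, t2 = np.array(r1.table), np.array(r2.table)
        assert (t1 == t2.T).all()
        assert r1.odds_ratio == pytest.approx(r2.odds_ratio)
        assert r1.p_value == pytest.approx(r2.p_value)

    def test_odds_ratio_recovery(self, anchored_sim, anchors_bed):
        cfg, _, _, _, calls = anchored_sim
        res = singlemol.co_accessibility(calls, anchors_bed, min_sep=1000,
                                         seed=1)
        assert len(res.observations) == cfg.n_anchored_pairs
        assert res.odds_ratio == pytest.approx(3.0, rel=0.25)

    def test_control_determinism_and_depletion(self):
        rng = np.random.default_rng(73)
        mids = np.sort(rng.choice(np.arange(20_000, 480_000, 4000), 30, False))
        feats = tuple(("chr1", int(m), "+" if i % 2 == 0 else "-", f"f{i}")
                      for i, m in enumerate(mids))
        cfg = simgen.SimConfig(
            genome_length=500_000, n_pairs=40_000, anchor_features=feats,
            n_anchored_pairs=3000, odds_ratio=3.0, seed=79)
        pairs, truth = simgen.simulate_contact_pairs(cfg)
        calls = simgen.simulate_read_meth_calls(cfg, pairs, truth)
        anchors = pd.DataFrame({
            "chrom": "chr1", "start": mids - 25, "end": mids + 25,
            "name": [f[3] for f in feats], "score": 0.0,
            "strand": [f[2] for f in feats]})
        res = singlemol.co_accessibility(calls, anchors, min_sep=1000,
                                         seed=7, with_control=True)
        ctrl = res.control
        assert len(ctrl.observations) >= 30
        # anchored pairs carry the planted joint signal; the one-sided
        # control sees background accessibility at the free mate
        assert ctrl.co_accessible_fraction < res.co_accessible_fraction
        res2 = singlemol.co_accessibility(calls, anchors, min_sep=1000,
                                          seed=7, with_control=True)
        pd.testing.assert_frame_equal(ctrl.observations,
                                      res2.control.observations)

    def test_comethylation_fully_methylated_single_cluster(self, anchored_sim,
                                                           anchors_bed):
        cfg, _, pairs, truth = anchored_sim[0], None, anchored_sim[2], anchored_sim[3]
        cfg2 = simgen.SimConfig(**{**cfg.to_dict(), "cpg_meth_baseline": 1.0,
                                   "conversion_failure": 0.0})
        calls = simgen.simulate_read_meth_calls(
            cfg2, *simgen.simulate_contact_pairs(cfg2)[:2])
        res = singlemol.co_methylation(calls, anchors_bed, min_sep=1000,
                                       k=2, seed=1)
        assert res.co_accessible_fraction == pytest.approx(100.0)
        assert res.cluster_means.iloc[0]["meanA"] == pytest.approx(1.0)

    def test_comethylation_independent_or_near_one(self, anchored_sim,
                                                   anchors_bed):
        _, _, _, _, calls = anchored_sim
        # HCG methylation is drawn independently per call at the baseline
        res = singlemol.co_methylation(calls, anchors_bed, min_sep=1000,
                                       threshold=0.75, seed=1)
        assert res.odds_ratio == pytest.approx(1.0, abs=0.45)
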