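"""Single-molecule co-accessibility / co-methylation analysis.

Each proximity-ligated read pair reports the chromatin state of two loci
on the same molecule. Both mates are anchored to filter intervals
(e.g. CTCF motifs under ChIP peaks); methylation calls within a fixed
window of the nearest interval midpoint are retained; the per-mate mean
GpC accessibility (or CpG methylation) forms a two-column observation
matrix. Observations are k-means clustered for display, binarized into
open/closed states, and the dependence between the two mates is tested
with a two-sided Fisher exact test on the 2x2 contingency table; the
sample odds ratio and the co-accessible fraction (both-open percentage)
are reported, alongside a randomized control in which only one mate is
required to overlap a filter interval.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as _stats
from sklearn.cluster import KMeans

DEFAULT_WINDOW = 100          # total width, i.e. midpoint +/- 50 bp
DEFAULT_THRESHOLD = 0.5
DEFAULT_MIN_CALLS = 1

#: Analysis presets. Separations are between anchor midpoints.
PRESETS = {
    "ctcf_convergent": dict(window=100, min_sep=1000, max_sep=None,
                            orientation="convergent"),
    "cre_tss": dict(window=100, min_sep=5000, max_sep=None, orientation=None),
    "tf_pair": dict(window=50, min_sep=100, max_sep=300, orientation=None),
}


class NotFoundError(KeyError):
    pass


class InputError(ValueError):
    pass


# ---------------------------------------------------------------------------
# anchoring


class FilterIntervalSet:
    """Sorted, stranded genomic intervals queried by nearest midpoint."""

    def __init__(self, features: pd.DataFrame):
        feats = features.reset_index(drop=True).copy()
        if "strand" not in feats.columns:
            feats["strand"] = "."
        if "name" not in feats.columns:
            feats["name"] = [f"iv{i}" for i in range(len(feats))]
        feats["midpoint"] = (feats["start"].astype(np.int64)
                             + feats["end"].astype(np.int64)) // 2
        self.features = feats
        self._by_chrom = {}
        for chrom, grp in feats.groupby("chrom", sort=False):
            grp = grp.sort_values(["midpoint"], kind="mergesort")
            self._by_chrom[chrom] = (grp["midpoint"].to_numpy(np.int64),
                                     grp.index.to_numpy())

    def __len__(self):
        return len(self.features)

    def nearest(self, chrom: str, pos: int):
        """Interval (global row id) with midpoint nearest to ``pos``.

        Ties are broken toward the lower coordinate. Raises
        NotFoundError on a chromosome with no intervals.
        """
        entry = self._by_chrom.get(chrom)
        if entry is None:
            raise NotFoundError(f"no filter intervals on {chrom}")
        mids, rows = entry
        j = int(np.searchsorted(mids, pos))
        best, bestd = None, None
        for cand in (j - 1, j):
            if 0 <= cand < len(mids):
                d = abs(int(mids[cand]) - int(pos))
                if best is None or d < bestd:   # strict: lower wins ties
                    best, bestd = cand, d
        return int(rows[best]), int(bestd)

    def nearest_many(self, chrom: str, pos: np.ndarray):
        """Vectorized ``nearest``; returns (row ids, distances)."""
        entry = self._by_chrom.get(chrom)
        if entry is None:
            raise NotFoundError(f"no filter intervals on {chrom}")
        mids, rows = entry
        j = np.searchsorted(mids, pos)
        left = np.clip(j - 1, 0, len(mids) - 1)
        right = np.clip(j, 0, len(mids) - 1)
        dl = np.abs(mids[left] - pos)
        dr = np.abs(mids[right] - pos)
        use_left = (dl <= dr)                    # tie -> lower coordinate
        idx = np.where(use_left, left, right)
        return rows[idx], np.where(use_left, dl, dr).astype(np.int64)


def nearest_interval(pos: int, intervals: FilterIntervalSet, chrom: str):
    """Nearest filter interval to ``pos``; see FilterIntervalSet.nearest."""
    row, dist = intervals.nearest(chrom, pos)
    return intervals.features.loc[row], dist


def filter_calls_by_window(calls: pd.DataFrame, intervals: FilterIntervalSet,
                           window: int = DEFAULT_WINDOW,
                           context: str = "GCH") -> pd.DataFrame:
    """Retain calls within ``window/2`` of their nearest interval midpoint.

    Annotates retained rows with ``anchor_id`` (interval row id),
    ``anchor_mid`` and ``anchor_strand``. Reads whose calls all fall
    outside every window are dropped entirely.
    """
    if window <= 0:
        raise InputError("window must be > 0")
    sub = calls[(calls["context"] == context) & (calls["source"] == "genomic")]
    out = []
    for chrom, grp in sub.groupby("chrom", sort=False):
        try:
            rows, dist = intervals.nearest_many(
                chrom, grp["pos"].to_numpy(np.int64))
        except NotFoundError:
            continue
        keep = dist <= window / 2
        g = grp.loc[keep].copy()
        g["anchor_id"] = rows[keep]
        g["distance"] = dist[keep]
        out.append(g)
    if not out:
        cols = list(calls.columns) + ["anchor_id", "distance",
                                      "anchor_mid", "anchor_strand"]
        return pd.DataFrame(columns=cols)
    res = pd.concat(out, ignore_index=True)
    feats = intervals.features
    res["anchor_mid"] = feats.loc[res["anchor_id"], "midpoint"].to_numpy()
    res["anchor_strand"] = feats.loc[res["anchor_id"], "strand"].to_numpy()
    return res


# ---------------------------------------------------------------------------
# pairing


def _per_mate_summary(filtered: pd.DataFrame) -> pd.DataFrame:
    """One row per (read_id, mate): call count, mean state, nearest anchor."""
    if len(filtered) == 0:
        return pd.DataFrame(columns=["read_id", "mate", "n_calls", "mean",
                                     "anchor_id", "anchor_mid", "anchor_strand"])
    f = filtered.copy()
    f["meth"] = (f["state"] == "methylated").astype(float)
    f = f.sort_values(["read_id", "mate", "distance", "pos"],
                      kind="mergesort")
    grp = f.groupby(["read_id", "mate"], sort=False)
    out = grp.agg(n_calls=("meth", "size"), mean=("meth", "mean"),
                  anchor_id=("anchor_id", "first"),
                  anchor_mid=("anchor_mid", "first"),
                  anchor_strand=("anchor_strand", "first")).reset_index()
    return out


def _apply_orientation(obs: pd.DataFrame, orientation: str | None):
    if orientation is None or len(obs) == 0:
        return obs
    if orientation != "convergent":
        raise InputError(f"unknown orientation rule {orientation!r}")
    up_strand = np.where(obs["midA"] <= obs["midB"],
                         obs["strandA"], obs["strandB"])
    dn_strand = np.where(obs["midA"] <= obs["midB"],
                         obs["strandB"], obs["strandA"])
    return obs[(up_strand == "+") & (dn_strand == "-")]


def pair_observations(filteredA: pd.DataFrame, filteredB: pd.DataFrame,
                      min_sep: int = 0, max_sep: int | None = None,
                      orientation: str | None = None) -> pd.DataFrame:
    """Merge anchored mates into per-molecule paired observations.

    ``filteredA`` / ``filteredB`` are outputs of filter_calls_by_window
    against the two anchor sets. Both mate assignments (mate 1 to A with
    mate 2 to B, and the reverse) are formed and pooled; a read pair
    qualifying in both directions is kept once (first direction).
    Separation is measured between anchor midpoints and restricted to
    ``[min_sep, max_sep]``.
    """
    sumA = _per_mate_summary(filteredA)
    sumB = _per_mate_summary(filteredB)
    pieces = []
    for mate_a, mate_b in ((1, 2), (2, 1)):
        a = sumA[sumA["mate"] == mate_a]
        b = sumB[sumB["mate"] == mate_b]
        m = a.merge(b, on="read_id", suffixes=("A", "B"))
        pieces.append(m)
    obs = pd.concat(pieces, ignore_index=True)
    if len(obs) == 0:
        return pd.DataFrame(columns=[
            "pair_id", "anchorA_id", "anchorB_id", "n_callsA", "n_callsB",
            "meanA", "meanB", "separation"])
    obs = obs.rename(columns={
        "anchor_idA": "anchorA_id", "anchor_idB": "anchorB_id",
        "anchor_midA": "midA", "anchor_midB": "midB",
        "anchor_strandA": "strandA", "anchor_strandB": "strandB"})
    obs["separation"] = (obs["midA"] - obs["midB"]).abs().astype(np.int64)
    obs = obs[obs["separation"] >= min_sep]
    if max_sep is not None:
        obs = obs[obs["separation"] <= max_sep]
    obs = _apply_orientation(obs, orientation)
    obs = obs.drop_duplicates(subset="read_id", keep="first")
    obs = obs.rename(columns={"read_id": "pair_id"})
    return obs[["pair_id", "anchorA_id", "anchorB_id", "n_callsA",
                "n_callsB", "meanA", "meanB", "separation"]].reset_index(drop=True)


# ---------------------------------------------------------------------------
# clustering, binarization, dependence


def cluster_observations(obs: pd.DataFrame, k: int = 4, seed: int = 0):
    """Seeded k-means on the (meanA, meanB) matrix.

    Cluster labels are relabeled 1..k by descending cluster grand mean,
    so cluster 1 is the most accessible (or most methylated) group.
    Returns ``(assignments, cluster_means)``.
    """
    if len(obs) < k:
        raise InputError(f"need at least k={k} observations, have {len(obs)}")
    X = obs[["meanA", "meanB"]].to_numpy(float)
    km = KMeans(n_clusters=k, n_init=10, random_state=int(seed)).fit(X)

    def _mean(mask, col=None):
        if not mask.any():
            return np.nan        # degenerate input can leave a cluster empty
        sel = X[mask] if col is None else X[mask, col]
        return sel.mean()

    grand = np.array([_mean(km.labels_ == c) for c in range(k)])
    order = np.argsort(-grand, kind="stable")       # descending, NaN last
    relabel = np.empty(k, dtype=int)
    relabel[order] = np.arange(1, k + 1)
    assignments = relabel[km.labels_]
    means = pd.DataFrame({
        "cluster": np.arange(1, k + 1),
        "meanA": [_mean(assignments == c, 0) for c in range(1, k + 1)],
        "meanB": [_mean(assignments == c, 1) for c in range(1, k + 1)],
        "n": [int((assignments == c).sum()) for c in range(1, k + 1)],
    })
    return assignments, means


def binarize(obs: pd.DataFrame, min_calls: int = DEFAULT_MIN_CALLS,
             threshold: float = DEFAULT_THRESHOLD):
    """Open/closed state per mate: open iff mean >= threshold.

    Observations with fewer than ``min_calls`` calls on either mate are
    excluded and counted. Returns ``(stateA, stateB, n_excluded)``.
    """
    ok = (obs["n_callsA"] >= min_calls) & (obs["n_callsB"] >= min_calls)
    sub = obs[ok]
    stateA = sub["meanA"].to_numpy(float) >= threshold
    stateB = sub["meanB"].to_numpy(float) >= threshold
    return stateA, stateB, int((~ok).sum())


def dependence_test(stateA: np.ndarray, stateB: np.ndarray) -> dict:
    """Two-sided Fisher exact test of mate-state independence.

    The 2x2 table is ``[[n11, n10], [n01, n00]]`` (first index = mate A
    open). The reported odds ratio is the sample cross-product
    ``n11*n00 / (n10*n01)``, with a Haldane-Anscombe 0.5 added to every
    cell when any cell is zero; a zero margin leaves the odds ratio
    undefined (None) with p = 1.
    """
    a = np.asarray(stateA, dtype=bool)
    b = np.asarray(stateB, dtype=bool)
    n11 = int(np.sum(a & b))
    n10 = int(np.sum(a & ~b))
    n01 = int(np.sum(~a & b))
    n00 = int(np.sum(~a & ~b))
    n = n11 + n10 + n01 + n00
    table = [[n11, n10], [n01, n00]]
    margins = (n11 + n10, n01 + n00, n11 + n01, n10 + n00)
    if n == 0 or 0 in margins:
        odds_ratio, p = None, 1.0
    else:
        if 0 in (n11, n10, n01, n00):
            odds_ratio = ((n11 + 0.5) * (n00 + 0.5)) / ((n10 + 0.5) * (n01 + 0.5))
        else:
            odds_ratio = (n11 * n00) / (n10 * n01)
        _, p = _stats.fisher_exact(table, alternative="two-sided")
    return {
        "n": n,
        "table": table,
        "odds_ratio": odds_ratio,
        "p_value": float(p),
        "co_accessible_fraction": (100.0 * n11 / n) if n else float("nan"),
    }


# ---------------------------------------------------------------------------
# results container and the full path


@dataclass
class CoAccessibilityResult:
    observations: pd.DataFrame
    cluster_assignments: np.ndarray | None
    cluster_means: pd.DataFrame | None
    table: list
    odds_ratio: float | None
    p_value: float
    co_accessible_fraction: float
    top_cluster_fraction: float | None
    n_excluded: int
    control: "CoAccessibilityResult | None" = None

    def stats_dict(self) -> dict:
        d = {
            "n_pairs": int(len(self.observations)),
            "table": self.table,
            "odds_ratio": self.odds_ratio,
            "p_value": self.p_value,
            "co_accessible_fraction": self.co_accessible_fraction,
            "top_cluster_fraction": self.top_cluster_fraction,
            "n_excluded": self.n_excluded,
        }
        if self.control is not None:
            d["control"] = self.control.stats_dict()
        return d


def _result_from_observations(obs, k, seed, min_calls, threshold,
                              cluster=True):
    stateA, stateB, n_excl = binarize(obs, min_calls, threshold)
    dep = dependence_test(stateA, stateB)
    assignments = means = None
    top_frac = None
    if cluster and len(obs) >= k:
        assignments, means = cluster_observations(obs, k=k, seed=seed)
        top_frac = 100.0 * float(np.mean(assignments == 1))
    return CoAccessibilityResult(
        observations=obs, cluster_assignments=assignments,
        cluster_means=means, table=dep["table"],
        odds_ratio=dep["odds_ratio"], p_value=dep["p_value"],
        co_accessible_fraction=dep["co_accessible_fraction"],
        top_cluster_fraction=top_frac, n_excluded=n_excl)


def co_accessibility(calls: pd.DataFrame, anchorsA: pd.DataFrame,
                     anchorsB: pd.DataFrame | None = None,
                     window: int = DEFAULT_WINDOW, min_sep: int = 1000,
                     max_sep: int | None = None,
                     orientation: str | None = None, k: int = 4,
                     min_calls: int = DEFAULT_MIN_CALLS,
                     threshold: float = DEFAULT_THRESHOLD, seed: int = 0,
                     context: str = "GCH",
                     with_control: bool = False) -> CoAccessibilityResult:
    """Full single-molecule co-accessibility path.

    Anchors both mates of every read pair to the nearest filter
    interval, window-filters the calls, pairs mates across the two
    anchor sets, clusters, binarizes and tests dependence. With
    ``context="HCG"`` the identical machinery measures co-methylation.
    """
    ivA = FilterIntervalSet(anchorsA)
    ivB = ivA if anchorsB is None else FilterIntervalSet(anchorsB)
    fA = filter_calls_by_window(calls, ivA, window, context)
    fB = filter_calls_by_window(calls, ivB, window, context)
    obs = pair_observations(fA, fB, min_sep=min_sep, max_sep=max_sep,
                            orientation=orientation)
    res = _result_from_observations(obs, k, seed, min_calls, threshold)
    if with_control:
        res.control = randomized_control(
            calls, ivA, window=window, min_sep=min_sep, max_sep=max_sep,
            seed=seed, context=context, n_target=len(obs),
            min_calls=min_calls, threshold=threshold, k=k)
    return res


def co_methylation(calls, anchorsA, anchorsB=None, **kwargs):
    """Co-methylation: the co-accessibility machinery on HCG calls.

    Cluster ordering is still by descending mean, i.e. cluster 1 is the
    most methylated group.
    """
    kwargs.setdefault("context", "HCG")
    return co_accessibility(calls, anchorsA, anchorsB, **kwargs)


def randomized_control(calls: pd.DataFrame, intervals, window: int,
                       min_sep: int = 0, max_sep: int | None = None,
                       seed: int = 0, context: str = "GCH",
                       n_target: int | None = None,
                       min_calls: int = DEFAULT_MIN_CALLS,
                       threshold: float = DEFAULT_THRESHOLD,
                       k: int = 4) -> CoAccessibilityResult:
    """Control in which only one mate overlaps a filter interval.

    The anchored mate is processed as in the main analysis; the other
    mate's window is centered on the midpoint of its own call span, so
    it measures background accessibility at an arbitrary locus at a
    comparable separation. The control set is subsampled (seeded) to
    ``n_target`` observations when larger.
    """
    if not isinstance(intervals, FilterIntervalSet):
        intervals = FilterIntervalSet(intervals)
    anchored = filter_calls_by_window(calls, intervals, window, context)
    anch = _per_mate_summary(anchored)

    sub = calls[(calls["context"] == context) & (calls["source"] == "genomic")]
    grp = sub.groupby(["read_id", "mate"], sort=False)
    span = grp["pos"].agg(["min", "max"]).reset_index()
    span["center"] = (span["min"] + span["max"]) // 2
    sub = sub.merge(span[["read_id", "mate", "center"]], on=["read_id", "mate"])
    sub = sub[(sub["pos"] - sub["center"]).abs() <= window / 2].copy()
    sub["meth"] = (sub["state"] == "methylated").astype(float)
    free = sub.groupby(["read_id", "mate"], sort=False).agg(
        n_calls=("meth", "size"), mean=("meth", "mean"),
        center=("center", "first")).reset_index()

    anchored_idx = pd.MultiIndex.from_frame(anch[["read_id", "mate"]])
    pieces = []
    for mate_a, mate_f in ((1, 2), (2, 1)):
        a = anch[anch["mate"] == mate_a]
        f = free[free["mate"] == mate_f]
        if len(f):
            f_idx = pd.MultiIndex.from_frame(f[["read_id", "mate"]])
            f = f[~f_idx.isin(anchored_idx)]
        m = a.merge(f, on="read_id", suffixes=("A", "B"))
        pieces.append(m)
    obs = pd.concat(pieces, ignore_index=True)
    if len(obs):
        obs["separation"] = (obs["anchor_mid"] - obs["center"]).abs().astype(np.int64)
        obs = obs[obs["separation"] >= min_sep]
        if max_sep is not None:
            obs = obs[obs["separation"] <= max_sep]
        obs = obs.drop_duplicates(subset="read_id", keep="first")
    obs = obs.rename(columns={
        "read_id": "pair_id", "anchor_id": "anchorA_id",
        "n_callsA": "n_callsA", "meanA": "meanA",
        "n_callsB": "n_callsB", "meanB": "meanB"})
    if len(obs) == 0:
        obs = pd.DataFrame(columns=["pair_id", "anchorA_id", "anchorB_id",
                                    "n_callsA", "n_callsB", "meanA", "meanB",
                                    "separation"])
    else:
        obs["anchorB_id"] = -1
        obs = obs[["pair_id", "anchorA_id", "anchorB_id", "n_callsA",
                   "n_callsB", "meanA", "meanB", "separation"]]
    if n_target is not None and len(obs) > n_target:
        rng = np.random.default_rng([int(seed), 99])
        take = np.sort(rng.choice(len(obs), size=n_target, replace=False))
        obs = obs.iloc[take].reset_index(drop=True)
    else:
        obs = obs.reset_index(drop=True)
    return _result_from_observations(obs, k, seed, min_calls, threshold,
                                     cluster=len(obs) >= k)
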