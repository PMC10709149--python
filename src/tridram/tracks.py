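"""Bulk-level aggregation of per-read methylation calls.

Per-cytosine pileups with coverage floors (5x per replicate, 10x for
merged replicates), spike-in conversion QC, and strand-aware
feature-centered metaprofiles.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

DEFAULT_MIN_COV_REPLICATE = 5
DEFAULT_MIN_COV_MERGED = 10


class QCError(ValueError):
    """A required spike-in source is absent."""


class InputError(ValueError):
    pass


def pileup(calls: pd.DataFrame, context: str = "GCH",
           min_cov: int = DEFAULT_MIN_COV_REPLICATE) -> pd.DataFrame:
    """Per-position methylated fraction for one context.

    Only genomic calls of the requested context contribute;
    GCG-ambiguous calls never enter either channel. Positions covered
    by fewer than ``min_cov`` calls are absent from the output.
    """
    if context not in ("HCG", "GCH"):
        raise InputError(f"unknown pileup context {context!r}")
    if min_cov < 1:
        raise InputError("min_cov must be >= 1")
    sub = calls[(calls["context"] == context) & (calls["source"] == "genomic")]
    if len(sub) == 0:
        return pd.DataFrame(columns=["chrom", "pos", "context",
                                     "n_meth", "n_total", "fraction"])
    grp = sub.groupby(["chrom", "pos"], sort=True)
    n_total = grp.size()
    n_meth = grp["state"].apply(lambda s: int((s == "methylated").sum()))
    out = pd.DataFrame({"n_meth": n_meth, "n_total": n_total}).reset_index()
    out = out[out["n_total"] >= min_cov].reset_index(drop=True)
    out["context"] = context
    out["fraction"] = out["n_meth"] / out["n_total"]
    return out[["chrom", "pos", "context", "n_meth", "n_total", "fraction"]]


def conversion_qc(spikein_calls: pd.DataFrame) -> dict:
    """Bisulfite conversion QC from spike-in controls.

    conversion_efficiency (%): unmethylated fraction of HCG calls on the
    unmethylated lambda template — failures to convert read as
    methylation. detection_rate (%): methylated fraction on the
    methylated controls (pUC19 calls plus GCH calls on in-situ
    GpC-methylated lambda), measuring the false-negative rate.
    """
    lam = spikein_calls[spikein_calls["source"] == "lambda_spikein"]
    lam_cpg = lam[lam["context"] == "HCG"]
    if len(lam_cpg) == 0:
        raise QCError("no lambda_spikein HCG calls: cannot estimate conversion")
    conv = 100.0 * (lam_cpg["state"] == "unmethylated").mean()

    puc = spikein_calls[spikein_calls["source"] == "puc19_spikein"]
    lam_gpc = lam[lam["context"] == "GCH"]
    ctrl = pd.concat([puc, lam_gpc], ignore_index=True)
    detection = (100.0 * (ctrl["state"] == "methylated").mean()
                 if len(ctrl) else None)
    return {
        "conversion_efficiency": float(conv),
        "detection_rate": None if detection is None else float(detection),
        "n_lambda_cpg": int(len(lam_cpg)),
        "n_methylated_control": int(len(ctrl)),
    }


def metaprofile(track: pd.DataFrame, features: pd.DataFrame, window: int,
                bin_size: int, flip_by_strand: bool = True):
    """Feature-centered matrix of mean fractions in fixed-width bins.

    ``track`` is a pileup (``chrom``, ``pos``, ``fraction``);
    ``features`` a BED-like frame. Each row of the result is one
    feature, columns are ``2*window/bin_size`` bins spanning the
    feature midpoint +/- window. Minus-strand features are
    column-reversed when ``flip_by_strand``, so bin 0 is always the
    most upstream in feature orientation. Empty bins are NaN and are
    excluded from the mean profile (absence of coverage is not a zero).

    Returns ``(matrix, mean_profile)``.
    """
    if window % bin_size != 0:
        raise InputError("window must be a multiple of bin_size")
    n_bins = 2 * window // bin_size
    if len(features) == 0:
        return np.empty((0, n_bins)), np.full(n_bins, np.nan)
    mat = np.full((len(features), n_bins), np.nan)
    by_chrom = {c: g.sort_values("pos") for c, g in track.groupby("chrom")}
    for i, feat in enumerate(features.itertuples(index=False)):
        grp = by_chrom.get(feat.chrom)
        if grp is None:
            continue
        mid = (int(feat.start) + int(feat.end)) // 2
        pos = grp["pos"].to_numpy(np.int64)
        frac = grp["fraction"].to_numpy(float)
        lo = np.searchsorted(pos, mid - window)
        hi = np.searchsorted(pos, mid + window)
        if hi == lo:
            continue
        b = (pos[lo:hi] - (mid - window)) // bin_size
        sums = np.bincount(b, weights=frac[lo:hi], minlength=n_bins)
        cnts = np.bincount(b, minlength=n_bins)
        with np.errstate(invalid="ignore"):
            row = sums / cnts
        if flip_by_strand and getattr(feat, "strand", "+") == "-":
            row = row[::-1]
        mat[i] = row
    import warnings
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean_profile = np.nanmean(mat, axis=0)
    return mat, mean_profile
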