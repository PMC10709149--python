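"""Pre-alignment read processing for proximity-ligated bisulfite reads.

Chimeric molecules carry a ligation junction formed by two filled-in
DpnII half-sites; after bisulfite conversion the junction reads as one
of four 8-mers (GATTGATT / GATTGATC on the forward strand, AATCAATC /
GATCAATC on the reverse, covering conversion of the unmethylated
internal cytosine). Reads are split at these junctions before
alignment. Downstream, mapped pair coordinates are projected onto
restriction fragment ends (fends) for deduplication, and per-cytosine
methylation calls are classified into NOMe contexts (HCG / GCH /
GCG-ambiguous).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

DEFAULT_JUNCTION_MOTIFS = ("GATTGATT", "GATTGATC", "AATCAATC", "GATCAATC")
DEFAULT_MIN_PRODUCT_LEN = 20

_VALID = set("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class InputError(ValueError):
    pass


@dataclass
class SeqRead:
    read_id: str
    mate: int
    sequence: str
    qualities: str | None = None

    def __post_init__(self):
        if not self.sequence:
            raise InputError(f"{self.read_id}: empty sequence")
        if self.qualities is not None and len(self.qualities) != len(self.sequence):
            raise InputError(f"{self.read_id}: quality/sequence length mismatch")


# ---------------------------------------------------------------------------
# junction splitting


def find_junction_sites(seq: str, motifs=DEFAULT_JUNCTION_MOTIFS):
    """All (possibly overlapping) exact motif occurrences, left to right.

    Returns a list of ``(offset, motif)`` sorted by offset (motif-list
    order breaks offset ties).
    """
    if set(seq) - _VALID:
        raise InputError(f"non-ACGTN characters in sequence: "
                         f"{sorted(set(seq) - _VALID)}")
    hits = []
    for motif in motifs:
        start = seq.find(motif)
        while start != -1:
            hits.append((start, motif))
            start = seq.find(motif, start + 1)
    hits.sort(key=lambda h: (h[0], motifs.index(h[1])))
    return hits


def split_chimeric_read(read: SeqRead, motifs=DEFAULT_JUNCTION_MOTIFS,
                        min_len: int = DEFAULT_MIN_PRODUCT_LEN):
    """Cut a read at the midpoint of each junction 8-mer.

    Each product keeps one 4-bp half-site, mirroring the symmetry of the
    fill-in ligation junction. Products shorter than ``min_len`` are
    dropped. A junction-free read is returned unchanged (same object
    identity not guaranteed, same content).
    """
    hits = find_junction_sites(read.sequence, motifs)
    if not hits:
        return [read]
    cuts = sorted({off + 4 for off, _ in hits})
    bounds = [0] + cuts + [len(read.sequence)]
    products = []
    k = 0
    for lo, hi in zip(bounds[:-1], bounds[1:]):
        if hi - lo < min_len:
            continue
        k += 1
        products.append(SeqRead(
            read_id=f"{read.read_id}/s{k}",
            mate=read.mate,
            sequence=read.sequence[lo:hi],
            qualities=read.qualities[lo:hi] if read.qualities else None,
        ))
    return products


# ---------------------------------------------------------------------------
# fragment ends


@dataclass
class FragmentIndex:
    """Per-chromosome sorted restriction cut-site coordinates.

    A cut site is the 0-based position of the first base of the
    recognition motif. Each site carries two fends: ``2*i`` for its
    upstream (left) side and ``2*i + 1`` for its downstream (right)
    side. Positions beyond the terminal sites map to chromosome-terminal
    pseudo-fends ``2*n`` (right end) and ``2*n + 1`` (left end).
    """

    sites: dict  # chrom -> sorted np.ndarray of cut positions

    @classmethod
    def from_genome(cls, genome: dict, motif: str = "GATC"):
        sites = {}
        for chrom, seq in genome.items():
            pos, found = [], seq.find(motif)
            while found != -1:
                pos.append(found)
                found = seq.find(motif, found + 1)
            sites[chrom] = np.asarray(pos, dtype=np.int64)
        return cls(sites=sites)

    def to_bed(self) -> pd.DataFrame:
        rows = [pd.DataFrame({"chrom": chrom, "start": p, "end": p + 1})
                for chrom, p in sorted(self.sites.items())]
        return pd.concat(rows, ignore_index=True) if rows else pd.DataFrame(
            columns=["chrom", "start", "end"])


def assign_fend(chrom: str, pos: int, strand: str, index: FragmentIndex) -> int:
    """Project a mapped read position onto a restriction fragment end.

    A + strand read extends rightward and is assigned the upstream side
    of the nearest cut site at or downstream of ``pos``; a - strand read
    the downstream side of the nearest site at or upstream.
    """
    sites = index.sites.get(chrom)
    if sites is None or len(sites) == 0:
        raise InputError(f"no cut sites on {chrom}")
    n = len(sites)
    if strand == "+":
        i = int(np.searchsorted(sites, pos, side="left"))
        return 2 * n if i == n else 2 * i
    i = int(np.searchsorted(sites, pos, side="right")) - 1
    return 2 * n + 1 if i < 0 else 2 * i + 1


def assign_fends(pairs: pd.DataFrame, index: FragmentIndex) -> pd.DataFrame:
    """Vectorized fend assignment for both sides of a pair table."""
    out = pairs.copy()
    for side in ("1", "2"):
        fends = np.empty(len(out), dtype=np.int64)
        for chrom, grp in out.groupby(f"chrom{side}", sort=False):
            sites = index.sites.get(chrom)
            if sites is None or len(sites) == 0:
                raise InputError(f"no cut sites on {chrom}")
            n = len(sites)
            pos = grp[f"pos{side}"].to_numpy(np.int64)
            plus = grp[f"strand{side}"].to_numpy() == "+"
            i_plus = np.searchsorted(sites, pos, side="left")
            i_minus = np.searchsorted(sites, pos, side="right") - 1
            f = np.where(plus,
                         np.where(i_plus == n, 2 * n, 2 * i_plus),
                         np.where(i_minus < 0, 2 * n + 1, 2 * i_minus + 1))
            fends[grp.index.to_numpy()] = f
        out[f"fend{side}"] = fends
    return out


def dedup_contact_pairs(pairs: pd.DataFrame):
    """Keep the first pair per unordered (chrom, fend) x (chrom, fend) key.

    Returns ``(deduplicated table, n_removed)``.
    """
    if len(pairs) == 0:
        return pairs.copy(), 0
    if pairs["fend1"].isna().any() or pairs["fend2"].isna().any():
        raise InputError("fends must be assigned before deduplication")
    a = list(zip(pairs["chrom1"], pairs["fend1"].astype(np.int64)))
    b = list(zip(pairs["chrom2"], pairs["fend2"].astype(np.int64)))
    keys = [tuple(sorted((x, y))) for x, y in zip(a, b)]
    keep = ~pd.Series(keys).duplicated().to_numpy()
    out = pairs.loc[keep].reset_index(drop=True)
    return out, int((~keep).sum())


# ---------------------------------------------------------------------------
# NOMe context classification


def classify_context(seq: str, pos: int, strand: str = "+") -> str:
    """NOMe context of the cytosine at ``pos`` on ``strand``.

    HCG: CpG-informative (endogenous methylation channel);
    GCH: GpC-informative (accessibility channel);
    GCG_ambiguous: both flanks G-side, excluded from both channels;
    other: neither. The - strand is evaluated on the reverse complement,
    so the base at ``pos`` must be G on the forward sequence.
    """
    if strand == "+":
        if pos < 0 or pos >= len(seq) or seq[pos] != "C":
            raise InputError(f"position {pos} is not a + strand cytosine")
        prev = seq[pos - 1] if pos > 0 else "N"
        nxt = seq[pos + 1] if pos + 1 < len(seq) else "N"
    elif strand == "-":
        if pos < 0 or pos >= len(seq) or seq[pos] != "G":
            raise InputError(f"position {pos} is not a - strand cytosine")
        prev = seq[pos + 1].translate(_COMPLEMENT) if pos + 1 < len(seq) else "N"
        nxt = seq[pos - 1].translate(_COMPLEMENT) if pos > 0 else "N"
    else:
        raise InputError(f"invalid strand {strand!r}")
    prev_g = prev == "G"
    next_g = nxt == "G"
    if prev_g and next_g:
        return "GCG_ambiguous"
    if prev_g:
        return "GCH"
    if next_g:
        return "HCG"
    return "other"
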