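"""Seeded synthetic-data generator with known ground truth.

Emulates the substrate of a joint 3D-genome / NOMe-style experiment:

* a random genome with restriction sites and informative GpC (GCH) and
  CpG (HCG) cytosines planted at configurable mean spacings;
* cis contact pairs whose genomic separation follows a truncated power
  law P(s) ∝ s^(-alpha), optionally up-weighted within TAD blocks and
  within same-compartment checkerboard bins;
* read pairs anchored at configured feature pairs whose per-molecule
  open/closed accessibility states follow a joint Bernoulli law with
  configurable marginals and odds ratio;
* per-read GCH/HCG methylation calls conditioned on the latent state,
  with a bisulfite conversion-failure rate epsilon;
* unmethylated-lambda / methylated-pUC19 spike-in calls.

Every draw is funnelled through numpy Generators keyed on
``(seed, stage offset)``, so adding a stage never perturbs earlier draws
and identical configs give byte-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .io import PAIRS_COLUMNS, METHCALL_COLUMNS

# fixed sub-stream offsets (see module docstring)
_STREAM_GENOME = 1
_STREAM_PAIRS = 2
_STREAM_LATENT = 3
_STREAM_METH = 4
_STREAM_SPIKE = 5
_STREAM_READS = 6
_STREAM_MATRIX = 7


class InvalidParameterError(ValueError):
    """A simulation parameter is outside its admissible range."""


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng([int(seed), int(stream)])


# ---------------------------------------------------------------------------
# configuration


@dataclass(frozen=True)
class SimConfig:
    """Full parameterization of one synthetic experiment.

    Distances and positions are base pairs; probabilities are in [0, 1].
    ``odds_ratio`` couples the two mates' latent open states at anchored
    read pairs; ``decay_exponent`` is the power-law exponent alpha of the
    cis contact distance distribution.
    """

    genome_length: int = 2_000_000
    n_chroms: int = 1
    restriction_motif: str = "GATC"
    restriction_spacing: int = 400
    gpc_spacing: int = 15
    cpg_spacing: int = 60
    tad_boundaries: tuple = ()
    tad_boost: float = 1.0
    compartment_bin: int = 0          # 0 disables the checkerboard
    compartment_boost: float = 1.0
    decay_exponent: float = 1.0
    min_dist: int = 1000              # decay sampling floor
    anchor_features: tuple = ()       # (chrom, pos, strand, label)
    anchor_pairs: tuple = ()          # index pairs into anchor_features
    n_anchored_pairs: int = 0
    marginal_open_prob: tuple = (0.3, 0.3)
    odds_ratio: float = 1.0
    background_open_prob: float = 0.15
    p_meth_given_open: float = 0.8
    p_meth_given_closed: float = 0.05
    cpg_meth_baseline: float = 0.75
    conversion_failure: float = 0.01
    n_pairs: int = 10_000
    read_len: int = 100
    anchor_jitter: int = 10
    seed: int = 0

    def __post_init__(self):
        probs = {
            "marginal_open_prob[0]": self.marginal_open_prob[0],
            "marginal_open_prob[1]": self.marginal_open_prob[1],
            "background_open_prob": self.background_open_prob,
            "p_meth_given_open": self.p_meth_given_open,
            "p_meth_given_closed": self.p_meth_given_closed,
            "cpg_meth_baseline": self.cpg_meth_baseline,
            "conversion_failure": self.conversion_failure,
        }
        for name, p in probs.items():
            if not 0.0 <= p <= 1.0:
                raise InvalidParameterError(f"{name}={p} outside [0, 1]")
        if self.odds_ratio <= 0:
            raise InvalidParameterError("odds_ratio must be > 0")
        if self.decay_exponent <= 0:
            raise InvalidParameterError("decay_exponent must be > 0")
        if list(self.tad_boundaries) != sorted(self.tad_boundaries):
            raise InvalidParameterError("tad_boundaries must be sorted")
        if any(not 0 < b < self.genome_length for b in self.tad_boundaries):
            raise InvalidParameterError("tad_boundaries must lie inside the genome")
        if self.min_dist < 1 or self.min_dist >= self.genome_length:
            raise InvalidParameterError("min_dist outside genome span")

    @property
    def chrom_names(self):
        return [f"chr{i + 1}" for i in range(self.n_chroms)]

    def effective_anchor_pairs(self):
        if self.anchor_pairs:
            return list(self.anchor_pairs)
        n = len(self.anchor_features)
        return [(i, i + 1) for i in range(0, n - 1, 2)]

    def to_dict(self):
        return asdict(self)


@dataclass
class TruthRecord:
    """Planted ground truth for one simulated experiment.

    ``latent`` has one row per simulated read pair: mate coordinates
    before canonical ordering, the latent open state of each mate, and
    the anchor labels ("" for background pairs).
    """

    latent: pd.DataFrame
    tad_boundaries: tuple
    compartment_bin: int
    joint_probs: tuple            # (p11, p10, p01, p00) of anchored pairs
    config: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# joint Bernoulli law


def solve_joint_bernoulli(p1: float, p2: float, theta: float):
    """Cell probabilities of the 2x2 Bernoulli law with given marginals
    and odds ratio (the Plackett construction).

    Returns ``(p11, p10, p01, p00)`` with ``p11 + p10 = p1``,
    ``p11 + p01 = p2`` and ``p11*p00 / (p10*p01) = theta``. ``p11`` is
    the unique root of the implied quadratic inside the Frechet bounds
    ``(max(0, p1 + p2 - 1), min(p1, p2))``.
    """
    if not (0.0 < p1 < 1.0 and 0.0 < p2 < 1.0):
        raise InvalidParameterError("marginals must lie strictly inside (0, 1)")
    if theta <= 0:
        raise InvalidParameterError("odds ratio must be > 0")
    if theta == 1.0:
        p11 = p1 * p2
    else:
        b = 1.0 + (theta - 1.0) * (p1 + p2)
        disc = b * b - 4.0 * theta * (theta - 1.0) * p1 * p2
        p11 = (b - math.sqrt(disc)) / (2.0 * (theta - 1.0))
    p10 = p1 - p11
    p01 = p2 - p11
    p00 = 1.0 - p1 - p2 + p11
    return p11, p10, p01, p00


def sample_joint_states(n: int, p1: float, p2: float, theta: float,
                        rng: np.random.Generator):
    """Draw n latent (open1, open2) state pairs from the joint law."""
    p11, p10, p01, p00 = solve_joint_bernoulli(p1, p2, theta)
    u = rng.random(n)
    cell = np.searchsorted(np.cumsum([p11, p10, p01]), u, side="right")
    open1 = cell <= 1          # cells 0 (11) and 1 (10)
    open2 = (cell == 0) | (cell == 2)
    return open1, open2


# ---------------------------------------------------------------------------
# genome


def simulate_genome(config: SimConfig) -> dict:
    """Random uniform ACGT chromosomes with planted restriction motifs and
    informative GCH / HCG cytosines.

    Planting guarantees a floor density of informative sites; random
    background sequence contributes additional sites, which is fine
    because downstream call simulation scans the realized sequence.
    """
    rng = _rng(config.seed, _STREAM_GENOME)
    bases = np.array([b"A", b"C", b"G", b"T"], dtype="S1")
    genome = {}
    L = config.genome_length
    motif = np.frombuffer(config.restriction_motif.encode(), dtype="S1")
    for chrom in config.chrom_names:
        arr = bases[rng.integers(0, 4, size=L)]
        # restriction sites
        for start in range(config.restriction_spacing, L - len(motif),
                           config.restriction_spacing):
            arr[start:start + len(motif)] = motif
        # HCG sites: non-G, C, G  (plant before GCH so GCH wins collisions)
        h = np.arange(config.cpg_spacing + 7, L - 2, config.cpg_spacing)
        arr[h - 1] = np.where(arr[h - 1] == b"G", b"A", arr[h - 1])
        arr[h] = b"C"
        arr[h + 1] = b"G"
        # GCH sites: G, C, non-G
        g = np.arange(config.gpc_spacing, L - 2, config.gpc_spacing)
        arr[g - 1] = b"G"
        arr[g] = b"C"
        arr[g + 1] = np.where(arr[g + 1] == b"G", b"A", arr[g + 1])
        genome[chrom] = arr.tobytes().decode()
    return genome


def informative_sites(seq: str):
    """Positions of forward-strand GCH and HCG cytosines in ``seq``."""
    arr = np.frombuffer(seq.encode(), dtype="S1")
    is_c = arr == b"C"
    prev_g = np.empty(len(arr), dtype=bool)
    prev_g[0] = False
    prev_g[1:] = arr[:-1] == b"G"
    next_g = np.empty(len(arr), dtype=bool)
    next_g[-1] = False
    next_g[:-1] = arr[1:] == b"G"
    gch = np.flatnonzero(is_c & prev_g & ~next_g)
    hcg = np.flatnonzero(is_c & ~prev_g & next_g)
    return gch, hcg


# ---------------------------------------------------------------------------
# contact pairs


def _sample_powerlaw(rng, n, alpha, smin, smax):
    u = rng.random(n)
    if alpha == 1.0:
        return smin * (smax / smin) ** u
    a1 = 1.0 - alpha
    return (smin ** a1 + u * (smax ** a1 - smin ** a1)) ** (1.0 / a1)


def _block_id(pos, boundaries):
    if len(boundaries) == 0:
        return np.zeros(len(pos), dtype=np.int64)
    return np.searchsorted(np.asarray(boundaries), pos, side="right")


def simulate_contact_pairs(config: SimConfig):
    """Generate a deduplication-ready contact-pair table plus ground truth.

    Background cis pairs follow the truncated power-law distance decay,
    reweighted by ``tad_boost`` for within-TAD pairs and
    ``compartment_boost`` for same-compartment pairs (rejection
    sampling, exact). Anchored pairs connect the configured feature
    pairs; their latent open states are drawn from the joint Bernoulli
    law. Background mates draw independent latent states at
    ``background_open_prob``.
    """
    rng = _rng(config.seed, _STREAM_PAIRS)
    rng_lat = _rng(config.seed, _STREAM_LATENT)
    L = config.genome_length
    rl = config.read_len
    smax = max(config.min_dist + 1, L - rl - 1)

    rows_chrom = []
    rows_p1 = []
    rows_p2 = []
    n_bg = config.n_pairs
    chrom_idx = rng.integers(0, config.n_chroms, size=n_bg) if n_bg else np.array([], dtype=int)
    wmax = max(config.tad_boost, 1.0) * max(config.compartment_boost, 1.0)
    collected = 0
    p1_all = np.empty(n_bg, dtype=np.int64)
    p2_all = np.empty(n_bg, dtype=np.int64)
    while collected < n_bg:
        m = max(1024, 2 * (n_bg - collected))
        s = _sample_powerlaw(rng, m, config.decay_exponent, config.min_dist, smax)
        s = np.minimum(s.astype(np.int64), smax)
        a = rng.integers(0, np.maximum(L - rl - s, 1))
        b = a + s
        w = np.ones(m)
        if config.tad_boost != 1.0 and len(config.tad_boundaries):
            same = _block_id(a, config.tad_boundaries) == _block_id(b, config.tad_boundaries)
            w *= np.where(same, config.tad_boost, 1.0)
        if config.compartment_boost != 1.0 and config.compartment_bin > 0:
            same = (a // config.compartment_bin) % 2 == (b // config.compartment_bin) % 2
            w *= np.where(same, config.compartment_boost, 1.0)
        keep = rng.random(m) < w / wmax
        a, b = a[keep], b[keep]
        take = min(len(a), n_bg - collected)
        p1_all[collected:collected + take] = a[:take]
        p2_all[collected:collected + take] = b[:take]
        collected += take

    chroms = np.array(config.chrom_names)
    bg_chrom = chroms[chrom_idx]
    bg_open1 = rng_lat.random(n_bg) < config.background_open_prob
    bg_open2 = rng_lat.random(n_bg) < config.background_open_prob

    # anchored pairs
    n_anc = config.n_anchored_pairs
    ap = config.effective_anchor_pairs()
    if n_anc and not ap:
        raise InvalidParameterError("n_anchored_pairs > 0 but no anchor pairs configured")
    p1m, p2m = config.marginal_open_prob
    if n_anc:
        which = rng.integers(0, len(ap), size=n_anc)
        feats = list(config.anchor_features)
        ia = np.array([ap[w][0] for w in which])
        ib = np.array([ap[w][1] for w in which])
        anc_chrom = np.array([feats[i][0] for i in ia])
        mid_a = np.array([feats[i][1] for i in ia], dtype=np.int64)
        mid_b = np.array([feats[i][1] for i in ib], dtype=np.int64)
        j = config.anchor_jitter
        jit_a = rng.integers(-j, j + 1, size=n_anc) if j else 0
        jit_b = rng.integers(-j, j + 1, size=n_anc) if j else 0
        anc_p1 = np.clip(mid_a - rl // 2 + jit_a, 0, L - rl - 1)
        anc_p2 = np.clip(mid_b - rl // 2 + jit_b, 0, L - rl - 1)
        anc_open1, anc_open2 = sample_joint_states(n_anc, p1m, p2m,
                                                   config.odds_ratio, rng_lat)
        lab_a = np.array([feats[i][3] for i in ia])
        lab_b = np.array([feats[i][3] for i in ib])
    else:
        anc_chrom = np.array([], dtype=str)
        anc_p1 = anc_p2 = np.array([], dtype=np.int64)
        anc_open1 = anc_open2 = np.array([], dtype=bool)
        lab_a = lab_b = np.array([], dtype=str)

    read_ids = np.concatenate([
        np.char.add("sim:bg:", np.arange(n_bg).astype(str)),
        np.char.add("sim:anch:", np.arange(n_anc).astype(str)),
    ])
    chrom_all = np.concatenate([bg_chrom, anc_chrom])
    m1 = np.concatenate([p1_all, anc_p1])
    m2 = np.concatenate([p2_all, anc_p2])
    open1 = np.concatenate([bg_open1, anc_open1])
    open2 = np.concatenate([bg_open2, anc_open2])
    anchor1 = np.concatenate([np.repeat("", n_bg), lab_a])
    anchor2 = np.concatenate([np.repeat("", n_bg), lab_b])

    strand1 = np.where(rng.random(len(read_ids)) < 0.5, "+", "-")
    strand2 = np.where(rng.random(len(read_ids)) < 0.5, "+", "-")

    # canonical pair order (lower coordinate first)
    swap = m1 > m2
    c1 = np.where(swap, m2, m1)
    c2 = np.where(swap, m1, m2)
    pairs = pd.DataFrame({
        "read_id": read_ids,
        "chrom1": chrom_all, "pos1": c1,
        "chrom2": chrom_all, "pos2": c2,
        "strand1": np.where(swap, strand2, strand1),
        "strand2": np.where(swap, strand1, strand2),
        "fend1": np.nan, "fend2": np.nan,
    })[PAIRS_COLUMNS]

    latent = pd.DataFrame({
        "read_id": read_ids,
        "chrom": chrom_all,
        "pos_mate1": m1, "pos_mate2": m2,
        "open1": open1, "open2": open2,
        "anchor1": anchor1, "anchor2": anchor2,
    })
    joint = (solve_joint_bernoulli(p1m, p2m, config.odds_ratio)
             if n_anc else (np.nan,) * 4)
    truth = TruthRecord(latent=latent,
                        tad_boundaries=tuple(config.tad_boundaries),
                        compartment_bin=config.compartment_bin,
                        joint_probs=tuple(joint),
                        config=config.to_dict())
    return pairs, truth


# ---------------------------------------------------------------------------
# methylation calls


def _expand_sites(sites: np.ndarray, starts: np.ndarray, read_len: int):
    """Row index and site position for every site covered by each read."""
    i0 = np.searchsorted(sites, starts)
    i1 = np.searchsorted(sites, starts + read_len)
    counts = i1 - i0
    total = int(counts.sum())
    row = np.repeat(np.arange(len(starts)), counts)
    offs = np.arange(total) - np.repeat(np.cumsum(counts) - counts, counts)
    pos = sites[i0[row] + offs]
    return row, pos


def simulate_read_meth_calls(config: SimConfig, pairs: pd.DataFrame,
                             truth: TruthRecord, genome: dict | None = None
                             ) -> pd.DataFrame:
    """Per-read GCH and HCG calls conditioned on the planted latent states.

    Each mate covers ``read_len`` bp from its mapped position; every
    informative forward-strand cytosine under the read yields one call.
    GCH calls are methylated with ``p_meth_given_open`` or
    ``p_meth_given_closed`` according to the mate's latent state; HCG
    calls with ``cpg_meth_baseline``. Conversion failure flips
    unmethylated calls to methylated with probability epsilon.
    """
    if genome is None:
        genome = simulate_genome(config)
    rng = _rng(config.seed, _STREAM_METH)
    lat = truth.latent
    out = []
    for chrom in config.chrom_names:
        seq = genome[chrom]
        gch, hcg = informative_sites(seq)
        sub = lat[lat["chrom"] == chrom]
        for mate, pos_col, open_col in ((1, "pos_mate1", "open1"),
                                        (2, "pos_mate2", "open2")):
            starts = sub[pos_col].to_numpy(np.int64)
            is_open = sub[open_col].to_numpy(bool)
            rid = sub["read_id"].to_numpy()
            for ctx, sites in (("GCH", gch), ("HCG", hcg)):
                row, pos = _expand_sites(sites, starts, config.read_len)
                if ctx == "GCH":
                    p = np.where(is_open[row], config.p_meth_given_open,
                                 config.p_meth_given_closed)
                else:
                    p = np.full(len(row), config.cpg_meth_baseline)
                meth = rng.random(len(row)) < p
                if config.conversion_failure > 0:
                    flip = (~meth) & (rng.random(len(row)) < config.conversion_failure)
                    meth = meth | flip
                out.append(pd.DataFrame({
                    "read_id": rid[row], "mate": mate, "chrom": chrom,
                    "pos": pos, "context": ctx,
                    "state": np.where(meth, "methylated", "unmethylated"),
                    "source": "genomic",
                }))
    if not out:
        return pd.DataFrame(columns=METHCALL_COLUMNS)
    calls = pd.concat(out, ignore_index=True)
    return calls[METHCALL_COLUMNS]


def simulate_spikein(n_calls: int, epsilon: float, truly_methylated: bool,
                     seed: int, source: str | None = None,
                     context: str = "HCG") -> pd.DataFrame:
    """Spike-in control calls.

    Unmethylated template (lambda): a call reads methylated only on
    conversion failure, probability epsilon. Methylated template
    (pUC19 / in-situ GpC-methylated lambda): a call reads unmethylated
    on detection failure, probability epsilon.
    """
    if n_calls <= 0:
        raise InvalidParameterError("n_calls must be > 0")
    if source is None:
        source = "puc19_spikein" if truly_methylated else "lambda_spikein"
    rng = _rng(seed, _STREAM_SPIKE)
    fail = rng.random(n_calls) < epsilon
    meth = fail if not truly_methylated else ~fail
    chrom = "pUC19" if source == "puc19_spikein" else "lambda"
    return pd.DataFrame({
        "read_id": np.char.add("spike:", np.arange(n_calls).astype(str)),
        "mate": 1, "chrom": chrom,
        "pos": np.arange(n_calls, dtype=np.int64),
        "context": context,
        "state": np.where(meth, "methylated", "unmethylated"),
        "source": source,
    })[METHCALL_COLUMNS]


# ---------------------------------------------------------------------------
# junction-bearing test reads


_JUNCTION_MOTIFS = ("GATTGATT", "GATTGATC", "AATCAATC", "GATCAATC")


def simulate_junction_reads(n_reads: int, read_len: int, seed: int,
                            max_junctions: int = 3):
    """Random reads with 0..max_junctions planted converted-junction 8-mers.

    Returns ``(reads, n_planted)``. Additional motif occurrences can
    arise by chance in the random background; callers comparing against
    a scan oracle are unaffected.
    """
    from .readproc import SeqRead

    rng = _rng(seed, _STREAM_READS)
    bases = np.array(list("ACGT"))
    reads, planted = [], []
    for i in range(n_reads):
        seq = bases[rng.integers(0, 4, size=read_len)]
        k = int(rng.integers(0, max_junctions + 1))
        placed = []
        for _ in range(k):
            for _try in range(20):
                off = int(rng.integers(0, read_len - 8 + 1))
                if all(abs(off - o) >= 8 for o in placed):
                    placed.append(off)
                    motif = _JUNCTION_MOTIFS[int(rng.integers(0, 4))]
                    seq[off:off + 8] = list(motif)
                    break
        reads.append(SeqRead(read_id=f"jr:{i}", mate=1,
                             sequence="".join(seq)))
        planted.append(len(placed))
    return reads, planted


# ---------------------------------------------------------------------------
# constructed contact matrices (for contact-statistics ground-truth tests)


def block_matrix(n_bins: int, boundaries, boost: float, bin_size: int = 1000,
                 depth: float = 20.0, alpha: float = 0.75,
                 seed: int | None = 0, chrom: str = "chr1"):
    """Poisson contact map with planted TAD blocks.

    Expected count decays as ``(1 + d)^-alpha`` with distance d in bins,
    multiplied by ``boost`` for bin pairs inside the same block.
    ``seed=None`` returns the noiseless expectation.
    """
    from .hicstats import BinnedContactMatrix

    idx = np.arange(n_bins)
    d = np.abs(idx[:, None] - idx[None, :])
    lam = depth * (1.0 + d) ** (-alpha)
    block = np.searchsorted(np.asarray(boundaries), idx, side="right")
    same = block[:, None] == block[None, :]
    lam = lam * np.where(same, boost, 1.0)
    if seed is None:
        mat = lam
    else:
        rng = _rng(seed, _STREAM_MATRIX)
        upper = rng.poisson(lam)
        mat = np.triu(upper) + np.triu(upper, 1).T
    return BinnedContactMatrix(chrom=chrom, bin_size=bin_size,
                               matrix=mat.astype(float))


def checkerboard_matrix(n_bins: int, contrast: float, bin_size: int = 250_000,
                        depth: float = 50.0, alpha: float = 0.4,
                        seed: int | None = 0, block: int = 1,
                        chrom: str = "chr1"):
    """Poisson contact map with a planted A/B compartment checkerboard.

    Same-compartment bin pairs carry ``contrast`` times the contact
    intensity of cross-compartment pairs at every distance. Returns
    ``(matrix, labels)`` with labels +1 (A) / -1 (B) alternating every
    ``block`` bins. ``seed=None`` returns the noiseless expectation.
    """
    from .hicstats import BinnedContactMatrix

    idx = np.arange(n_bins)
    labels = np.where((idx // block) % 2 == 0, 1, -1)
    d = np.abs(idx[:, None] - idx[None, :])
    lam = depth * (1.0 + d) ** (-alpha)
    same = labels[:, None] == labels[None, :]
    lam = lam * np.where(same, contrast, 1.0)
    if seed is None:
        mat = lam
    else:
        rng = _rng(seed, _STREAM_MATRIX)
        upper = rng.poisson(lam)
        mat = np.triu(upper) + np.triu(upper, 1).T
    bcm = BinnedContactMatrix(chrom=chrom, bin_size=bin_size,
                              matrix=mat.astype(float))
    return bcm, labels
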