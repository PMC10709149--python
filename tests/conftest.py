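import numpy as np
import pandas as pd
import pytest

from tridram import simgen


@pytest.fixture(scope="session")
def anchored_sim():
    """A small simulated experiment with anchored read pairs (theta=3)."""
    cfg = simgen.SimConfig(
        genome_length=400_000, n_pairs=2000,
        anchor_features=(("chr1", 80_000, "+", "a1"),
                         ("chr1", 120_000, "-", "b1"),
                         ("chr1", 250_000, "+", "a2"),
                         ("chr1", 300_000, "-", "b2")),
        n_anchored_pairs=4000, odds_ratio=3.0,
        marginal_open_prob=(0.3, 0.3), seed=11)
    genome = simgen.simulate_genome(cfg)
    pairs, truth = simgen.simulate_contact_pairs(cfg)
    calls = simgen.simulate_read_meth_calls(cfg, pairs, truth, genome=genome)
    return cfg, genome, pairs, truth, calls


@pytest.fixture
def anchors_bed(anchored_sim):
    cfg = anchored_sim[0]
    feats = cfg.anchor_features
    return pd.DataFrame({
        "chrom": [f[0] for f in feats],
        "start": [f[1] - 25 for f in feats],
        "end": [f[1] + 25 for f in feats],
        "name": [f[3] for f in feats],
        "score": 0.0,
        "strand": [f[2] for f in feats],
    })


def make_calls(rows):
    """Build a methylation-call table from (read_id, mate, chrom, pos,
    context, state) tuples; source defaults to genomic."""
    df = pd.DataFrame(rows, columns=["read_id", "mate", "chrom", "pos",
                                     "context", "state"])
    df["source"] = "genomic"
    return df
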