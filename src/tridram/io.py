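"""Readers and writers for the plain-text formats used across the pipeline.

All tables travel as pandas DataFrames. Coordinates are 0-based half-open
in memory; writers convert where a format demands otherwise (the
methylation-call TSV exposes a 1-based position column, mirroring common
bisulfite extractor output; BED/bedGraph stay 0-based).

Every TSV carries a ``#schema_version`` header line; readers reject unknown
major versions.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

SCHEMA_VERSION = 1

METHCALL_COLUMNS = ["read_id", "mate", "chrom", "pos", "context", "state", "source"]
PAIRS_COLUMNS = [
    "read_id", "chrom1", "pos1", "chrom2", "pos2",
    "strand1", "strand2", "fend1", "fend2",
]
BED_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]

CONTEXTS = ("HCG", "GCH", "GCG_ambiguous", "other")
STATES = ("methylated", "unmethylated")
SOURCES = ("genomic", "lambda_spikein", "puc19_spikein")


class SchemaError(ValueError):
    """Raised when a table violates its declared schema."""


def _check_schema_line(line: str, path) -> None:
    if not line.startswith("#schema_version="):
        raise SchemaError(f"{path}: missing #schema_version header")
    major = int(line.strip().split("=", 1)[1].split(".")[0])
    if major != SCHEMA_VERSION:
        raise SchemaError(f"{path}: unsupported schema version {major}")


# ---------------------------------------------------------------------------
# methylation-call TSV


def write_methcalls(calls: pd.DataFrame, path) -> None:
    """Write a methylation-call table (1-based position column on disk)."""
    out = calls.loc[:, METHCALL_COLUMNS].copy()
    out["pos_1based"] = out.pop("pos").astype(np.int64) + 1
    out = out[["read_id", "mate", "chrom", "pos_1based", "context", "state", "source"]]
    with open(path, "w") as fh:
        fh.write(f"#schema_version={SCHEMA_VERSION}\n")
        out.to_csv(fh, sep="\t", index=False)


def read_methcalls(path) -> pd.DataFrame:
    with open(path) as fh:
        _check_schema_line(fh.readline(), path)
        df = pd.read_csv(fh, sep="\t", dtype={"read_id": str, "chrom": str})
    validate_methcalls_disk(df, path)
    df["pos"] = df.pop("pos_1based").astype(np.int64) - 1
    return df[METHCALL_COLUMNS]


def validate_methcalls_disk(df: pd.DataFrame, path="<methcalls>") -> None:
    expect = ["read_id", "mate", "chrom", "pos_1based", "context", "state", "source"]
    if list(df.columns) != expect:
        raise SchemaError(f"{path}: columns {list(df.columns)} != {expect}")
    bad_ctx = set(df["context"].unique()) - set(CONTEXTS)
    if bad_ctx:
        raise SchemaError(f"{path}: unknown contexts {sorted(bad_ctx)}")
    bad_state = set(df["state"].unique()) - set(STATES)
    if bad_state:
        raise SchemaError(f"{path}: unknown states {sorted(bad_state)}")


# ---------------------------------------------------------------------------
# 4DN .pairs text


def write_pairs(pairs: pd.DataFrame, path) -> None:
    """Write contact pairs in 4DN ``.pairs`` text form.

    The two optional fend columns are appended after the standard seven
    when present and non-null.
    """
    cols = ["read_id", "chrom1", "pos1", "chrom2", "pos2", "strand1", "strand2"]
    have_fends = (
        "fend1" in pairs.columns
        and len(pairs) > 0
        and not pairs["fend1"].isna().any()
    )
    out = pairs.copy()
    if have_fends:
        cols = cols + ["fend1", "fend2"]
        out["fend1"] = out["fend1"].astype(np.int64)
        out["fend2"] = out["fend2"].astype(np.int64)
    colnames = ["readID", "chr1", "pos1", "chr2", "pos2", "strand1", "strand2"]
    if have_fends:
        colnames += ["fend1", "fend2"]
    with open(path, "w") as fh:
        fh.write("## pairs format v1.0\n")
        fh.write(f"#schema_version={SCHEMA_VERSION}\n")
        fh.write("#columns: " + " ".join(colnames) + "\n")
        out.loc[:, cols].to_csv(fh, sep="\t", index=False, header=False)


def read_pairs(path) -> pd.DataFrame:
    header_cols = None
    n_header = 0
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                n_header += 1
                if line.startswith("#columns:"):
                    header_cols = line[len("#columns:"):].split()
                elif line.startswith("#schema_version="):
                    _check_schema_line(line, path)
            else:
                break
    if header_cols is None:
        raise SchemaError(f"{path}: missing #columns: header")
    rename = {"readID": "read_id", "chr1": "chrom1", "chr2": "chrom2"}
    cols = [rename.get(c, c) for c in header_cols]
    df = pd.read_csv(
        path, sep="\t", comment="#", names=cols, dtype={"read_id": str}
    )
    for c in ("fend1", "fend2"):
        if c not in df.columns:
            df[c] = np.nan
    return df[PAIRS_COLUMNS]


# ---------------------------------------------------------------------------
# BED / bedGraph


def write_bed(features: pd.DataFrame, path) -> None:
    cols = [c for c in BED_COLUMNS if c in features.columns]
    features.loc[:, cols].to_csv(path, sep="\t", index=False, header=False)


def read_bed(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     dtype={0: str})
    df.columns = BED_COLUMNS[: df.shape[1]]
    for col, default in (("name", "."), ("score", 0.0), ("strand", ".")):
        if col not in df.columns:
            df[col] = default
    df = df.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)
    return df[BED_COLUMNS]


def write_bedgraph(track: pd.DataFrame, path, value_col: str = "fraction",
                   percent: bool = False) -> None:
    """Write a per-position track as bedGraph (one bp per row)."""
    out = pd.DataFrame({
        "chrom": track["chrom"],
        "start": track["pos"].astype(np.int64),
        "end": track["pos"].astype(np.int64) + 1,
        "value": track[value_col] * (100.0 if percent else 1.0),
    })
    out.to_csv(path, sep="\t", index=False, header=False)


# ---------------------------------------------------------------------------
# FASTA / FASTQ (4-line records)


def write_fasta(seqs: dict, path) -> None:
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    records = [SeqRecord(Seq(s), id=name, description="")
               for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> dict:
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fastq(reads, path) -> None:
    """Write SeqRead-like records (``read_id``, ``sequence``, ``qualities``)."""
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    records = []
    for r in reads:
        qual = r.qualities if r.qualities is not None else "I" * len(r.sequence)
        rec = SeqRecord(Seq(r.sequence), id=r.read_id, description="")
        rec.letter_annotations["phred_quality"] = [ord(c) - 33 for c in qual]
        records.append(rec)
    SeqIO.write(records, str(path), "fastq")


def read_fastq(path):
    from Bio import SeqIO

    from .readproc import SeqRead

    reads = []
    for rec in SeqIO.parse(str(path), "fastq"):
        qual = "".join(chr(q + 33)
                       for q in rec.letter_annotations["phred_quality"])
        reads.append(SeqRead(read_id=rec.id, mate=1, sequence=str(rec.seq),
                             qualities=qual or None))
    return reads


# ---------------------------------------------------------------------------
# JSON helpers


def write_json(obj, path) -> None:
    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serializable: {type(o)}")

    Path(path).write_text(
        json.dumps(obj, indent=2, sort_keys=True, default=_default) + "\n"
    )


def read_json(path):
    return json.loads(Path(path).read_text())


def write_matrix_tsv(matrix: np.ndarray, path, index=None, columns=None) -> None:
    df = pd.DataFrame(matrix, index=index, columns=columns)
    df.to_csv(path, sep="\t", float_format="%.6g")
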