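"""Readers and writers for alignments, pattern-count tables and reports.

Alignments travel as sequential PHYLIP or FASTA (via Biopython);
pattern-count matrices as TSV with columns ``locus, x0..x4``; dataset
provenance as a JSON sidecar.
"""

from __future__ import annotations

import json
import math
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import AlignIO, SeqIO
from Bio.Align import MultipleSeqAlignment
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .core import ParameterError
from .simulate import LocusCounts, MultilocusDataset, counts_from_sequences

COUNT_COLUMNS = ["locus", "x0", "x1", "x2", "x3", "x4"]


def write_counts_tsv(data: MultilocusDataset, path: str | Path) -> None:
    if data.exact:
        raise ParameterError("cannot write counts for an infinite-sites dataset")
    df = pd.DataFrame(data.counts, columns=COUNT_COLUMNS[1:])
    df.insert(0, "locus", np.arange(1, data.m + 1))
    df.to_csv(path, sep="\t", index=False)


def read_counts_tsv(path: str | Path) -> MultilocusDataset:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in COUNT_COLUMNS[1:] if c not in df.columns]
    if missing:
        raise ParameterError(f"counts TSV missing columns {missing}")
    counts = df[COUNT_COLUMNS[1:]].to_numpy(dtype=np.int64)
    n = counts.sum(axis=1)
    if len(set(n.tolist())) != 1:
        raise ParameterError("all loci must share the same number of sites")
    return MultilocusDataset(n=int(n[0]), counts=counts)


def write_provenance(data: MultilocusDataset, path: str | Path) -> None:
    prov = dict(data.provenance or {})
    if "seed" in prov and prov["seed"] is not None:
        prov["seed"] = int(prov["seed"])
    Path(path).write_text(json.dumps(prov, indent=2) + "\n")


def _records(seqs: dict[str, str]):
    return [SeqRecord(Seq(s), id=label, description="") for label, s in seqs.items()]


def write_alignment(seqs: dict[str, str], path: str | Path, fmt: str = "phylip") -> None:
    """Write one three-sequence alignment as sequential PHYLIP or FASTA."""
    aln = MultipleSeqAlignment(_records(seqs))
    fmt = {"phylip": "phylip-sequential", "fasta": "fasta"}.get(fmt, fmt)
    AlignIO.write(aln, str(path), fmt)


def read_alignment(path: str | Path, fmt: str | None = None) -> LocusCounts:
    """Read a three-sequence alignment and reduce it to pattern counts."""
    path = Path(path)
    if fmt is None:
        fmt = "fasta" if path.suffix.lower() in (".fa", ".fasta", ".fna") else "phylip-sequential"
    elif fmt == "phylip":
        fmt = "phylip-sequential"
    records = list(SeqIO.parse(str(path), fmt))
    if len(records) != 3:
        raise ParameterError(f"expected 3 sequences in {path}, found {len(records)}")
    seqs = {r.id: str(r.seq) for r in records}
    return counts_from_sequences(seqs)


def read_alignments(paths, fmt: str | None = None) -> MultilocusDataset:
    """Read several per-locus alignments into one dataset."""
    loci = [read_alignment(p, fmt=fmt) for p in paths]
    ns = {int(lc.n) for lc in loci}
    if len(ns) != 1:
        raise ParameterError("all loci must share the same number of sites")
    return MultilocusDataset(n=ns.pop(), counts=np.stack([lc.x for lc in loci]))


def parse_n(text: str) -> float:
    """Parse a sequence length that may be 'inf'."""
    if str(text).lower() in ("inf", "infinity", "oo"):
        return math.inf
    n = int(text)
    if n < 1:
        raise ParameterError("n must be >= 1 or inf")
    return n
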