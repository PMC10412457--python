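"""Count tables, library fractions and enrichment for proteolysis selections.

The raw observable of the experiment is a table of sequencing read counts per
library member per selection condition (two proteases x twelve conditions x
replicates, plus a pre-selection column per protease).  Reads are assigned by
exact match to the ordered library sequences; everything downstream works on
library fractions (counts / column total) and enrichment relative to the
pre-selection library.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

ROUND_PRE = "pre"
ROUND_POST = "post"


@dataclass(frozen=True)
class Condition:
    """One selection condition (or the pre-selection reference)."""

    protease: str
    replicate: int = 1
    conc_uM: float = 0.0
    round: str = ROUND_POST

    def __post_init__(self) -> None:
        if self.conc_uM < 0:
            raise ValueError("conc_uM must be >= 0")
        if self.round not in (ROUND_PRE, ROUND_POST):
            raise ValueError("round must be 'pre' or 'post'")
        if self.round == ROUND_PRE and self.conc_uM != 0:
            raise ValueError("pre-selection condition must have conc_uM = 0")

    @property
    def key(self) -> str:
        if self.round == ROUND_PRE:
            return f"{self.protease}.r{self.replicate}.pre"
        return f"{self.protease}.r{self.replicate}.{self.conc_uM:g}"


class CountTable:
    """Integer (or expected-value) read counts per sequence per condition."""

    def __init__(self, counts: pd.DataFrame, conditions: Sequence[Condition]):
        conditions = list(conditions)
        keys = [c.key for c in conditions]
        if list(counts.columns) != keys:
            raise ValueError("count columns must match condition keys in order")
        if (counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        self.counts = counts
        self.conditions = conditions

    @property
    def seq_ids(self) -> pd.Index:
        return self.counts.index

    def column_totals(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def select(self, protease: str | None = None, round: str | None = None,
               replicate: int | None = None) -> "CountTable":
        keep = [
            c for c in self.conditions
            if (protease is None or c.protease == protease)
            and (round is None or c.round == round)
            and (replicate is None or c.replicate == replicate)
        ]
        return CountTable(self.counts[[c.key for c in keep]], keep)

    def to_tsv(self, path: str | Path) -> None:
        out = self.counts.copy()
        out.insert(0, "seq_id", out.index)
        out.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "CountTable":
        df = pd.read_csv(path, sep="\t").set_index("seq_id")
        return cls(df, [parse_condition_key(k) for k in df.columns])


def parse_condition_key(key: str) -> Condition:
    """Parse a 'protease.rN.conc' / 'protease.rN.pre' column name."""
    protease, rep, conc = key.split(".", 2)
    replicate = int(rep.lstrip("r"))
    if conc == "pre":
        return Condition(protease, replicate, 0.0, ROUND_PRE)
    return Condition(protease, replicate, float(conc), ROUND_POST)


def count_exact_matches(reads: Iterable[str], library: Mapping[str, str]):
    """Assign reads to library members by exact sequence match.

    Returns ``(counts, discarded)`` where counts is a Series over library ids
    and discarded the number of unassigned reads; assigned + discarded equals
    the total reads.  Duplicate library sequences are an error (assignment
    would be ambiguous).
    """
    if len(library) == 0:
        raise ValueError("library must be non-empty")
    seq_to_id: dict[str, str] = {}
    for seq_id, seq in library.items():
        seq = str(seq).upper()
        if seq in seq_to_id:
            raise ValueError(f"duplicate library sequence for {seq_id!r} and {seq_to_id[seq]!r}")
        seq_to_id[seq] = seq_id
    counts = pd.Series(0, index=pd.Index(library.keys(), name="seq_id"), dtype=int)
    discarded = 0
    for read in reads:
        seq_id = seq_to_id.get(str(read).upper())
        if seq_id is None:
            discarded += 1
        else:
            counts[seq_id] += 1
    return counts, discarded


def load_library(fasta_path: str | Path) -> dict[str, str]:
    """Read the ordered library: FASTA, header = sequence id (variant annotation)."""
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(fasta_path), "fasta")}


def load_reads(fastq_path: str | Path) -> list[str]:
    return [str(rec.seq) for rec in SeqIO.parse(str(fastq_path), "fastq")]


def library_fractions(table: CountTable, pseudocount: float = 0.0) -> pd.DataFrame:
    """Counts to per-condition library fractions; sums to 1 when pseudocount=0."""
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    c = table.counts.astype(float) + pseudocount
    totals = c.sum(axis=0)
    if (totals <= 0).any():
        bad = list(totals.index[totals <= 0])
        raise ValueError(f"all-zero count column(s): {bad}")
    return c / totals


def enrichment(fractions: pd.DataFrame, reference: str) -> pd.DataFrame:
    """Fraction ratios relative to the pre-selection reference column.

    Sequences with zero reference fraction get NaN ratios (flagged missing;
    excluded from inference).
    """
    if reference not in fractions.columns:
        raise ValueError(f"reference column {reference!r} not in fractions")
    ref = fractions[reference].to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        out = fractions.div(fractions[reference], axis=0)
    out[np.asarray(ref) == 0] = np.nan
    return out
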