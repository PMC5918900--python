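"""Exact-identity read overlap between mother and daughter root samples.

The statistic is the percentage of daughter reads whose sequence occurs,
character for character, at least once among the mother reads. Matching is
case-insensitive exact string equality — no trimming, no alignment, and no
reverse-complement matching (amplicons are orientation-normalised upstream).
Dereplicated FASTA with ``;size=N`` abundance annotations is honoured.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO

_SIZE_RE = re.compile(r";size=(\d+)", re.I)
_ALPHABET = set("ACGTN")


@dataclass
class ReadSet:
    """A multiset of reads, stored dereplicated as sequence -> abundance."""
    role: str
    marker: str
    sequences: Counter = field(default_factory=Counter)

    @property
    def total_reads(self) -> int:
        return sum(self.sequences.values())

    def add(self, seq: str, abundance: int = 1) -> None:
        if abundance < 1:
            raise ValueError("abundance must be >= 1")
        seq = seq.upper()
        bad = set(seq) - _ALPHABET
        if bad:
            raise ValueError(f"non-ACGTN characters {sorted(bad)} in read")
        self.sequences[seq] += abundance


def read_fasta(path: str | Path, role: str, marker: str = "bacteria_16S") -> ReadSet:
    """Load a (possibly dereplicated) FASTA into a ReadSet."""
    rs = ReadSet(role, marker)
    for rec in SeqIO.parse(str(path), "fasta"):
        m = _SIZE_RE.search(rec.description)
        rs.add(str(rec.seq), int(m.group(1)) if m else 1)
    if not rs.sequences:
        raise ValueError(f"no sequences in {path}")
    return rs


def shared_read_fraction(mothers: ReadSet, daughters: ReadSet) -> float:
    """Percentage of daughter reads with an exact sequence match in mothers."""
    if daughters.total_reads == 0:
        raise ValueError("empty daughter read set")
    if mothers.total_reads == 0:
        raise ValueError("empty mother read set")
    mother_seqs = set(mothers.sequences)
    shared = sum(n for seq, n in daughters.sequences.items() if seq in mother_seqs)
    return 100.0 * shared / daughters.total_reads
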