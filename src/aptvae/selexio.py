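"""Reading, filtering and selecting HT-SELEX sequencing rounds.

Reads come in as FASTA or FASTQ (optionally gzipped); adapters are matched
exactly as prefix/suffix, the extracted variable region must have exactly
the design length, and only variable regions seen more than once survive.
The working round is the one with the smallest unique ratio

    U(T) = |{distinct reads in round T}| / |reads in round T|

subject to U(T) > 0.5 — a pool that has begun to enrich (duplicated reads)
but has not collapsed.  DNA input is mapped T -> U since the aptamers are
RNA.
"""

from __future__ import annotations

import gzip
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO


class ParseError(ValueError):
    """Malformed sequence file."""


class RoundSelectionError(ValueError):
    """No round satisfies the unique-ratio restriction."""


@dataclass
class SelexRound:
    """One SELEX round: variable-region sequences with read counts."""

    round_index: int
    counts: dict[str, int] = field(default_factory=dict)
    adapter5: str = ""
    adapter3: str = ""
    design_length: int | None = None

    @property
    def total_reads(self) -> int:
        return sum(self.counts.values())

    @property
    def n_unique(self) -> int:
        return len(self.counts)


def _open_maybe_gzip(path: Path):
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return path.open()


def _sniff_format(path: Path) -> str:
    name = path.name[: -len(".gz")] if path.suffix == ".gz" else path.name
    ext = Path(name).suffix.lower()
    if ext in {".fq", ".fastq"}:
        return "fastq"
    if ext in {".fa", ".fasta", ".txt"}:
        return "fasta"
    with _open_maybe_gzip(path) as fh:
        first = fh.readline()
    return "fastq" if first.startswith("@") else "fasta"


def read_reads(path: str | Path, fmt: str | None = None) -> Counter:
    """Read a FASTA/FASTQ file into a sequence -> count table.

    Counts of identical reads are aggregated; quality scores are ignored;
    T is mapped to U.  An empty file yields an empty table.
    """
    path = Path(path)
    fmt = fmt or _sniff_format(path)
    counts: Counter = Counter()
    n_parsed = 0
    with _open_maybe_gzip(path) as fh:
        try:
            for rec in SeqIO.parse(fh, fmt):
                n_parsed += 1
                counts[str(rec.seq).upper().replace("T", "U")] += 1
        except ValueError as exc:
            raise ParseError(
                f"{path}: malformed {fmt} near record {n_parsed + 1}: {exc}"
            ) from exc
    return counts


def filter_reads(reads: Counter | dict[str, int], adapter5: str, adapter3: str,
                 design_length: int) -> dict[str, int]:
    """Apply the three filtering rules; returns variable region -> count.

    A read survives iff (i) both adapters match exactly, (ii) the variable
    region between them has exactly the design length, and (iii) after
    aggregating identical variable regions, the total count is >= 2.
    """
    adapter5 = adapter5.upper().replace("T", "U")
    adapter3 = adapter3.upper().replace("T", "U")
    regions: Counter = Counter()
    for seq, count in reads.items():
        seq = seq.upper().replace("T", "U")
        if not seq.startswith(adapter5):
            continue
        if adapter3 and not seq.endswith(adapter3):
            continue
        region = seq[len(adapter5) : len(seq) - len(adapter3) or None]
        if len(region) != design_length:
            continue
        regions[region] += count
    return {seq: c for seq, c in regions.items() if c >= 2}


def load_round(path: str | Path, round_index: int, adapter5: str, adapter3: str,
               design_length: int, fmt: str | None = None) -> SelexRound:
    """Read one round's file and filter it into a :class:`SelexRound`."""
    counts = filter_reads(read_reads(path, fmt), adapter5, adapter3, design_length)
    return SelexRound(round_index, counts, adapter5, adapter3, design_length)


def unique_ratio(rnd: SelexRound) -> float:
    """Distinct reads over total reads (with multiplicity), in (0, 1]."""
    if rnd.total_reads == 0:
        raise ValueError(f"round {rnd.round_index} is empty")
    return rnd.n_unique / rnd.total_reads


def select_round(rounds: list[SelexRound]) -> SelexRound:
    """The round minimizing U(T) subject to U(T) > 0.5; ties -> larger T."""
    eligible = [(unique_ratio(r), r) for r in rounds if unique_ratio(r) > 0.5]
    if not eligible:
        raise RoundSelectionError("no round has unique ratio > 0.5")
    return min(eligible, key=lambda ur: (ur[0], -ur[1].round_index))[1]


def write_unique_fasta(rnd: SelexRound, fasta_path: str | Path,
                       counts_path: str | Path | None = None) -> None:
    """Write the unique variable regions as FASTA plus a count TSV."""
    fasta_path = Path(fasta_path)
    with fasta_path.open("w") as fh:
        for i, (seq, count) in enumerate(sorted(rnd.counts.items())):
            fh.write(f">round{rnd.round_index}_{i} count={count}\n{seq}\n")
    if counts_path is not None:
        with Path(counts_path).open("w") as fh:
            fh.write("sequence\tcount\n")
            for seq, count in sorted(rnd.counts.items()):
                fh.write(f"{seq}\t{count}\n")
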