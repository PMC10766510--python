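"""Seeded generators for the two synthetic motif datasets.

Both generators emulate idealized selection pools in which every read
carries a planted motif signal and everything else is uniform random
padding — the ground-truth labels make downstream clustering and
reconstitution checks possible without re-deriving the motifs.

* Single-motif mode: ten distinct random 10-nt motifs; each read picks one
  motif uniformly, mutates it (each position independently carries an edit
  with 10% probability, the edit type uniform over deletion / insertion /
  substitution, i.e. 3.33% each), and is padded with uniform random
  letters on both sides to exactly 20 nt.  10,000 unique reads by default.
* Paired-motif mode: two fixed 5-nt motifs; each is dropped independently
  with probability 25% (draws losing both are redrawn), surviving pairs
  are separated by a uniform random 2-6 nt gap, and reads are padded to
  20 nt.  Labels are "both", "left_only" or "right_only"; 5,000 reads by
  default.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .phmm import ALPHABET


@dataclass(frozen=True)
class LabeledSequence:
    sequence: str
    label: int | str
    edits: tuple = field(default_factory=tuple)  # (kind, motif_position) pairs


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(ALPHABET[i] for i in rng.integers(0, 4, size=n))


def _mutate_motif(motif: str, error_rate: float,
                  rng: np.random.Generator) -> tuple[str, tuple]:
    """Apply at most one edit per motif position, each with ``error_rate``
    probability, type uniform over deletion/insertion/substitution."""
    out: list[str] = []
    edits: list[tuple[str, int]] = []
    for pos, c in enumerate(motif):
        if rng.random() < error_rate:
            kind = ("deletion", "insertion", "substitution")[rng.integers(0, 3)]
            edits.append((kind, pos))
            if kind == "deletion":
                continue
            if kind == "substitution":
                others = [a for a in ALPHABET if a != c]
                out.append(others[rng.integers(0, 3)])
            else:  # insert one uniform letter after this position
                out.append(c)
                out.append(ALPHABET[rng.integers(0, 4)])
        else:
            out.append(c)
    return "".join(out), tuple(edits)


def _pad_to(core: str, target_len: int, rng: np.random.Generator) -> str:
    pad = target_len - len(core)
    if pad < 0:
        raise ValueError(
            f"core of length {len(core)} exceeds target length {target_len}")
    left = int(rng.integers(0, pad + 1))
    return _random_seq(rng, left) + core + _random_seq(rng, pad - left)


def generate_single_motif_dataset(n: int = 10000, n_motifs: int = 10,
                                  motif_len: int = 10, target_len: int = 20,
                                  error_rate: float = 0.10, seed: int = 0,
                                  return_motifs: bool = False):
    """Unique length-``target_len`` reads, each carrying one mutated motif.

    Returns exactly ``n`` distinct sequences labeled by motif index;
    duplicates are rejected and redrawn.  With ``return_motifs=True`` the
    list of planted motifs is returned alongside the data.
    """
    rng = np.random.default_rng(seed)
    motifs: list[str] = []
    while len(motifs) < n_motifs:
        cand = _random_seq(rng, motif_len)
        if cand not in motifs:
            motifs.append(cand)
    out: list[LabeledSequence] = []
    seen: set[str] = set()
    while len(out) < n:
        label = int(rng.integers(0, n_motifs))
        core, edits = _mutate_motif(motifs[label], error_rate, rng)
        seq = _pad_to(core, target_len, rng)
        if seq not in seen:
            seen.add(seq)
            out.append(LabeledSequence(seq, label, edits))
    return (out, motifs) if return_motifs else out


def generate_paired_motif_dataset(n: int = 5000, motif_len: int = 5,
                                  gap_range: tuple[int, int] = (2, 6),
                                  drop_prob: float = 0.25, target_len: int = 20,
                                  seed: int = 0, return_motifs: bool = False):
    """Length-``target_len`` reads carrying a split motif pair.

    Each of the two fixed motifs is dropped independently with probability
    ``drop_prob``; draws losing both are redrawn, so labels are "both",
    "left_only" or "right_only".  Surviving pairs get a uniform random gap
    of ``gap_range`` nt.
    """
    rng = np.random.default_rng(seed)
    left = _random_seq(rng, motif_len)
    right = left
    while right == left:
        right = _random_seq(rng, motif_len)
    lo, hi = gap_range
    out: list[LabeledSequence] = []
    while len(out) < n:
        drop_left = rng.random() < drop_prob
        drop_right = rng.random() < drop_prob
        if drop_left and drop_right:
            continue  # redraw: every read keeps at least one motif
        if drop_left:
            core, label = right, "right_only"
        elif drop_right:
            core, label = left, "left_only"
        else:
            gap = int(rng.integers(lo, hi + 1))
            core, label = left + _random_seq(rng, gap) + right, "both"
        out.append(LabeledSequence(_pad_to(core, target_len, rng), label))
    return (out, (left, right)) if return_motifs else out


def write_dataset(data: list[LabeledSequence], out_dir: str | Path,
                  name: str, params: dict | None = None) -> dict[str, Path]:
    """Write FASTA (label in header), a TSV label table and a JSON manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    fasta = out_dir / f"{name}.fasta"
    with fasta.open("w") as fh:
        for i, rec in enumerate(data):
            fh.write(f">{name}_{i} label={rec.label}\n{rec.sequence}\n")
    table = out_dir / f"{name}_labels.tsv"
    with table.open("w") as fh:
        fh.write("id\tsequence\tlabel\n")
        for i, rec in enumerate(data):
            fh.write(f"{name}_{i}\t{rec.sequence}\t{rec.label}\n")
    manifest = out_dir / f"{name}_manifest.json"
    manifest.write_text(json.dumps({"n": len(data), **(params or {})}, indent=1))
    return {"fasta": fasta, "labels": table, "manifest": manifest}
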