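"""Sliding-window stacking profiles and base-composition summaries.

A length-L sequence has L-2 interior positions whose trinucleotide window
is fully defined, so a profile is a vector of L-2 stacking free energies
(for the 36-bp probes used in binding-affinity models this is 34). Window i
covers 0-based positions [i, i+3) and its value is attributed to the
central base i+1.
"""

from __future__ import annotations

import gzip
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
from Bio.SeqIO.FastaIO import SimpleFastaParser

from ._util import DNA_BASES, check_acgt
from .energy import DinucleotideTable, trimer_energy

__all__ = [
    "StackingProfile",
    "CompositionSummary",
    "stacking_profile",
    "composition",
    "read_fasta",
    "write_profile_tsv",
]


@dataclass(frozen=True)
class StackingProfile:
    """Per-position trinucleotide stacking energies of one sequence."""

    sequence_id: str
    values: np.ndarray  # kcal/mol, length L-2
    offset: int = 1  # 0-based index of the first scored (central) position

    def __len__(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class CompositionSummary:
    at_count: int
    gc_count: int
    skipped: int = 0

    @property
    def at_fraction(self) -> float:
        """A/T percentage of the counted bases."""
        total = self.at_count + self.gc_count
        if total == 0:
            raise ValueError("no countable bases")
        return 100.0 * self.at_count / total


def stacking_profile(
    seq: str, table: DinucleotideTable, sequence_id: str = ""
) -> StackingProfile:
    """Score every full trinucleotide window of ``seq``.

    Sequences shorter than 3 give an empty profile with a warning;
    ambiguous bases are a hard error (their stacking energy is undefined).
    """
    if len(seq) < 3:
        warnings.warn(
            f"sequence {sequence_id or seq!r} shorter than 3 bp: empty profile"
        )
        return StackingProfile(sequence_id, np.empty(0))
    s = check_acgt(seq, what=f"sequence {sequence_id or seq!r}")
    # dG(window i) = dG(step i) + dG(step i+1): compute the L-1 step
    # energies once and sum adjacent pairs.
    steps = np.array([table[s[i : i + 2]] for i in range(len(s) - 1)])
    return StackingProfile(sequence_id, steps[:-1] + steps[1:])


def composition(seqs: Iterable[str] | str) -> CompositionSummary:
    """Pooled A/T vs G/C counts across sequences.

    Ambiguous bases are excluded from both counts and reported in the
    ``skipped`` tally.
    """
    if isinstance(seqs, str):
        seqs = [seqs]
    at = gc = skipped = 0
    for seq in seqs:
        for b in seq.upper():
            if b in "AT":
                at += 1
            elif b in "GC":
                gc += 1
            else:
                skipped += 1
    return CompositionSummary(at, gc, skipped)


def read_fasta(path: str | Path) -> Iterator[tuple[str, str]]:
    """Yield (id, uppercased sequence) from a FASTA file, plain or gzipped.

    Ids are the first whitespace token of the header; duplicate ids and
    empty files are errors.
    """
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    seen: set[str] = set()
    n = 0
    with opener(path, "rt") as handle:
        for header, seq in SimpleFastaParser(handle):
            name = header.split()[0]
            if name in seen:
                raise ValueError(f"duplicate FASTA id {name!r} in {path}")
            seen.add(name)
            n += 1
            yield name, seq.upper()
    if n == 0:
        raise ValueError(f"no FASTA records in {path}")


def write_profile_tsv(
    profiles: Iterable[StackingProfile],
    seqs: dict[str, str],
    path: str | Path,
) -> Path:
    """Write profiles as ``seq_id<TAB>position<TAB>trimer<TAB>dG`` rows."""
    path = Path(path)
    with open(path, "w") as out:
        out.write("seq_id\tposition\ttrimer\tdG\n")
        for prof in profiles:
            seq = seqs[prof.sequence_id]
            for i, v in enumerate(prof.values):
                center = prof.offset + i
                out.write(
                    f"{prof.sequence_id}\t{center}\t"
                    f"{seq[center - 1 : center + 2]}\t{v:.6g}\n"
                )
    return path
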