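"""Dinucleotide stacking constants and the trinucleotide free-energy matrices.

The physical model: the stacking free energy of a trinucleotide ABC is the
sum of its two constituent dinucleotide-step energies,

    dG(ABC) = dG(AB) + dG(BC)        [kcal/mol]

and the effect of a single-base substitution at the central position is the
difference

    ddGs(ABC -> AB'C) = dG(AB'C) - dG(ABC)   (mutated minus wild type),

so substitutions that strengthen stacking are negative. Step energies are
assigned to an ordered dinucleotide read 5'->3' on one strand; because a
step and its reverse complement describe the same stacked base-pair dimer,
the table carries 10 unique values on 16 keys and every derived quantity is
strand-invariant.

The bundled default is the nicked-duplex experimental set of Protozanova,
Yakovchuk & Frank-Kamenetskii (J Mol Biol 2004), ranging from -2.17 (GC)
to -0.19 (TA) kcal/mol.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from ._util import DNA_BASES, check_acgt, revcomp

__all__ = [
    "DinucleotideTable",
    "TrimerMatrix",
    "DifferenceMatrix",
    "ALL_DINUCLEOTIDES",
    "ALL_TRIMERS",
    "load_dinucleotide_table",
    "trimer_energy",
    "build_trimer_matrix",
    "build_difference_matrix",
    "matrix_extremes",
    "export_matrix",
    "import_trimer_matrix",
    "import_difference_matrix",
]

ALL_DINUCLEOTIDES = tuple(a + b for a in DNA_BASES for b in DNA_BASES)
ALL_TRIMERS = tuple("".join(t) for t in itertools.product(DNA_BASES, repeat=3))

#: Nicked-duplex dinucleotide stacking free energies (kcal/mol), the 10
#: unique values; the other 6 keys follow by reverse-complement symmetry.
PROTOZANOVA = {
    "AA": -1.11,
    "AC": -1.81,
    "AG": -1.06,
    "AT": -1.34,
    "CA": -0.55,
    "CC": -1.44,
    "CG": -0.91,
    "GA": -1.43,
    "GC": -2.17,
    "TA": -0.19,
}

BUNDLED_TABLES = {"protozanova": PROTOZANOVA}

_SYMMETRY_TOL = 1e-9


@dataclass(frozen=True)
class DinucleotideTable:
    """The 16-entry dinucleotide stacking free-energy table (kcal/mol)."""

    entries: dict[str, float]
    source_label: str = "custom"

    def __post_init__(self) -> None:
        missing = [d for d in ALL_DINUCLEOTIDES if d not in self.entries]
        if missing:
            raise ValueError(f"dinucleotide table incomplete, missing {missing}")
        extra = [k for k in self.entries if k not in ALL_DINUCLEOTIDES]
        if extra:
            raise ValueError(f"unexpected dinucleotide keys {extra}")
        for d in ALL_DINUCLEOTIDES:
            v, w = self.entries[d], self.entries[revcomp(d)]
            if not (math.isfinite(v) and math.isfinite(w)):
                raise ValueError(f"non-finite stacking energy for {d}")
            if abs(v - w) > _SYMMETRY_TOL:
                raise ValueError(
                    "reverse-complement symmetry violated: "
                    f"dG({d})={v} vs dG({revcomp(d)})={w}"
                )

    def __getitem__(self, dinucleotide: str) -> float:
        return self.entries[dinucleotide]

    @property
    def min(self) -> float:
        return min(self.entries.values())

    @property
    def max(self) -> float:
        return max(self.entries.values())


@dataclass(frozen=True)
class TrimerMatrix:
    """All 64 trinucleotide stacking free energies (kcal/mol)."""

    entries: dict[str, float]
    table_source: str = "custom"

    def __post_init__(self) -> None:
        if sorted(self.entries) != sorted(ALL_TRIMERS):
            raise ValueError("trimer matrix must have exactly the 64 ACGT trimers")

    def __getitem__(self, trimer: str) -> float:
        return self.entries[trimer]


@dataclass(frozen=True)
class DifferenceMatrix:
    """The 64x4 central-substitution ddGs matrix (kcal/mol).

    Keyed by (wild-type trimer, substituted central base); the 64 identity
    entries are stored with value 0 so the grid is complete, but enrichment
    statistics exclude them.
    """

    entries: dict[tuple[str, str], float]
    table_source: str = "custom"

    def __post_init__(self) -> None:
        expected = {(t, b) for t in ALL_TRIMERS for b in DNA_BASES}
        if set(self.entries) != expected:
            raise ValueError("difference matrix must cover 64 trimers x 4 bases")

    def __getitem__(self, key: tuple[str, str]) -> float:
        return self.entries[key]

    def substitutions(self) -> dict[tuple[str, str], float]:
        """The 192 non-identity entries."""
        return {k: v for k, v in self.entries.items() if k[0][1] != k[1]}


def _complete_by_symmetry(values: dict[str, float]) -> dict[str, float]:
    out = dict(values)
    for d, v in values.items():
        rc = revcomp(d)
        if rc not in out:
            out[rc] = v
    return out


def load_dinucleotide_table(
    source_name: str = "protozanova",
    override_path: str | Path | None = None,
) -> DinucleotideTable:
    """Load a named bundled constant set, or a custom 2-column TSV.

    The TSV format is ``dinucleotide<TAB>dG_kcal_per_mol`` with ``#``
    comments; if only the 10 unique values are given, reverse-complement
    partners are filled in automatically.
    """
    if override_path is not None:
        values: dict[str, float] = {}
        for lineno, line in enumerate(
            Path(override_path).read_text().splitlines(), start=1
        ):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(
                    f"{override_path}:{lineno}: expected 2 tab-separated columns"
                )
            dinuc = check_acgt(parts[0], what=f"{override_path}:{lineno}")
            if len(dinuc) != 2:
                raise ValueError(f"{override_path}:{lineno}: {dinuc!r} is not a 2-mer")
            try:
                values[dinuc] = float(parts[1])
            except ValueError as exc:
                raise ValueError(
                    f"{override_path}:{lineno}: non-numeric value {parts[1]!r}"
                ) from exc
        return DinucleotideTable(
            _complete_by_symmetry(values), source_label=str(override_path)
        )
    try:
        unique = BUNDLED_TABLES[source_name]
    except KeyError:
        raise ValueError(
            f"unknown constant set {source_name!r}; "
            f"bundled sets: {sorted(BUNDLED_TABLES)} (or pass override_path)"
        ) from None
    return DinucleotideTable(_complete_by_symmetry(unique), source_label=source_name)


def trimer_energy(table: DinucleotideTable, trimer: str) -> float:
    """dG(ABC) = dG(AB) + dG(BC), kcal/mol."""
    t = check_acgt(trimer, what="trimer")
    if len(t) != 3:
        raise ValueError(f"expected a trinucleotide, got {trimer!r}")
    return table[t[:2]] + table[t[1:]]


def build_trimer_matrix(table: DinucleotideTable) -> TrimerMatrix:
    """Compute all 64 trinucleotide stacking free energies."""
    return TrimerMatrix(
        {t: trimer_energy(table, t) for t in ALL_TRIMERS},
        table_source=table.source_label,
    )


def build_difference_matrix(tm: TrimerMatrix) -> DifferenceMatrix:
    """Central-substitution ddGs for every trimer (mutated minus wild type)."""
    entries = {
        (t, b): tm[t[0] + b + t[2]] - tm[t]
        for t in ALL_TRIMERS
        for b in DNA_BASES
    }
    return DifferenceMatrix(entries, table_source=tm.table_source)


def matrix_extremes(
    m: TrimerMatrix | DifferenceMatrix, tol: float = 1e-9
) -> tuple[list, float, list, float]:
    """All keys attaining the minimum and maximum (ties reported together).

    Returns ``(argmin_keys, min_value, argmax_keys, max_value)``.
    """
    entries = m.entries
    lo = min(entries.values())
    hi = max(entries.values())
    arg_lo = sorted(k for k, v in entries.items() if v <= lo + tol)
    arg_hi = sorted(k for k, v in entries.items() if v >= hi - tol)
    return arg_lo, lo, arg_hi, hi


def _fmt(value: float, decimals: int | None) -> str:
    return repr(value) if decimals is None else f"{value:.{decimals}f}"


def export_matrix(
    m: TrimerMatrix | DifferenceMatrix,
    path: str | Path,
    layout: str = "long",
    decimals: int | None = None,
) -> Path:
    """Serialize a matrix as TSV.

    Layouts: ``fig1a`` (rows = first two nucleotides, columns = last
    nucleotide; trimer matrix only), ``fig1b`` (rows = 64 trimers, columns =
    central substitution; difference matrix only), ``long`` (key/value
    pairs). With ``decimals=None`` values are written at full precision and
    round-trip exactly through the matching importer; ``decimals=2`` matches
    the precision the energies are usually reported at.
    """
    path = Path(path)
    lines: list[str] = []
    if layout == "fig1a":
        if not isinstance(m, TrimerMatrix):
            raise ValueError("fig1a layout applies to a TrimerMatrix")
        lines.append("first_two\t" + "\t".join(DNA_BASES))
        for pre in ALL_DINUCLEOTIDES:
            row = [_fmt(m[pre + b], decimals) for b in DNA_BASES]
            lines.append(pre + "\t" + "\t".join(row))
    elif layout == "fig1b":
        if not isinstance(m, DifferenceMatrix):
            raise ValueError("fig1b layout applies to a DifferenceMatrix")
        lines.append("trimer\t" + "\t".join(DNA_BASES))
        for t in ALL_TRIMERS:
            row = [_fmt(m[(t, b)], decimals) for b in DNA_BASES]
            lines.append(t + "\t" + "\t".join(row))
    elif layout == "long":
        if isinstance(m, TrimerMatrix):
            lines.append("trimer\tdG")
            for t in ALL_TRIMERS:
                lines.append(f"{t}\t{_fmt(m[t], decimals)}")
        else:
            lines.append("trimer\talt\tddG")
            for t in ALL_TRIMERS:
                for b in DNA_BASES:
                    lines.append(f"{t}\t{b}\t{_fmt(m[(t, b)], decimals)}")
    else:
        raise ValueError(f"unknown layout {layout!r}")
    path.write_text("\n".join(lines) + "\n")
    return path


def _read_rows(path: str | Path) -> Iterable[list[str]]:
    for line in Path(path).read_text().splitlines():
        if line.strip():
            yield line.split("\t")


def import_trimer_matrix(path: str | Path, layout: str = "long") -> TrimerMatrix:
    rows = list(_read_rows(path))
    header, body = rows[0], rows[1:]
    entries: dict[str, float] = {}
    if layout == "fig1a":
        cols = header[1:]
        for row in body:
            for b, v in zip(cols, row[1:]):
                entries[row[0] + b] = float(v)
    elif layout == "long":
        for row in body:
            entries[row[0]] = float(row[1])
    else:
        raise ValueError(f"unknown trimer layout {layout!r}")
    return TrimerMatrix(entries)


def import_difference_matrix(
    path: str | Path, layout: str = "long"
) -> DifferenceMatrix:
    rows = list(_read_rows(path))
    header, body = rows[0], rows[1:]
    entries: dict[tuple[str, str], float] = {}
    if layout == "fig1b":
        cols = header[1:]
        for row in body:
            for b, v in zip(cols, row[1:]):
                entries[(row[0], b)] = float(v)
    elif layout == "long":
        for row in body:
            entries[(row[0], row[1])] = float(row[2])
    else:
        raise ValueError(f"unknown difference layout {layout!r}")
    return DifferenceMatrix(entries)
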