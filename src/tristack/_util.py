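"""Small shared helpers for DNA alphabet handling."""

from __future__ import annotations

DNA_BASES = "ACGT"

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def revcomp(seq: str) -> str:
    """Reverse complement of an ACGT string (uppercase in, uppercase out)."""
    return seq.translate(_COMPLEMENT)[::-1]


class AmbiguousBaseError(ValueError):
    """A base outside {A, C, G, T} (N or another IUPAC code) was encountered."""


def check_acgt(seq: str, *, what: str = "sequence") -> str:
    """Uppercase ``seq`` and reject any non-ACGT character.

    Returns the uppercased sequence. Raises :class:`AmbiguousBaseError`
    naming the first offending position.
    """
    up = seq.upper()
    for i, b in enumerate(up):
        if b not in DNA_BASES:
            raise AmbiguousBaseError(
                f"ambiguous base {b!r} at position {i} in {what}; "
                "only A/C/G/T are scorable"
            )
    return up
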