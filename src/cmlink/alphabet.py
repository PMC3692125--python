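"""RNA alphabet helpers.

The toolkit works strictly over {A, C, G, U}. DNA input is accepted anywhere a
sequence enters the library: ``T`` is mapped to ``U`` on read. IUPAC ambiguity
codes are rejected with a clear error, because model emission vectors are
defined over concrete nucleotides only.
"""

from __future__ import annotations

RNA = "ACGU"
NT_INDEX = {c: i for i, c in enumerate(RNA)}

#: row-major pair order AA, AC, ..., UU used by MP emission vectors
PAIRS = tuple(a + b for a in RNA for b in RNA)


class AlphabetError(ValueError):
    """Raised when a sequence contains characters outside {A,C,G,U,T}."""


def normalize_rna(sequence: str) -> str:
    """Uppercase, map T->U, and validate a nucleotide sequence.

    Raises :class:`AlphabetError` for IUPAC ambiguity codes or anything else
    outside the concrete RNA/DNA alphabet.
    """
    seq = sequence.upper().replace("T", "U")
    for pos, ch in enumerate(seq):
        if ch not in NT_INDEX:
            raise AlphabetError(
                f"invalid nucleotide {ch!r} at position {pos}: "
                "only A, C, G, U (or T, mapped to U) are accepted; "
                "IUPAC ambiguity codes are not supported"
            )
    return seq


def pair_index(left: str, right: str) -> int:
    """Index of an ordered nucleotide pair in a 16-long MP emission vector."""
    return NT_INDEX[left] * 4 + NT_INDEX[right]
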