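"""Compact integer encoding of k-mers for nucleotide and peptide alphabets.

Nucleotides are packed at 2 bits per base (A=00, C=01, G=10, T=11) and
amino acids at 5 bits per residue (A..Z mapped to 0..25).  Packing is
big-endian: the first character of the k-mer occupies the most significant
symbol slot.  Because the per-symbol codes follow alphabetical order, the
integer order of two equal-length codes coincides with the lexicographic
order of the decoded strings — which makes canonical (strand-symmetric)
selection a plain integer ``min``.

Supported k ranges mirror the fixed-width storage tiers of the counting
engine: a k-mer must fit a 128-bit word, giving k ≤ 63 for nucleotides and
3 ≤ k ≤ 25 for peptides.  :func:`width_class` exposes the tier (16, 32, 64
or 128 bits) a given k falls into.
"""

from __future__ import annotations

import string
from dataclasses import dataclass

from .errors import EncodingError, UnsupportedOperationError

__all__ = [
    "Alphabet",
    "KmerCode",
    "NUCLEOTIDE",
    "PEPTIDE",
    "encode",
    "decode",
    "reverse_complement",
    "canonical",
    "width_class",
]


@dataclass(frozen=True)
class Alphabet:
    """A fixed symbol set with a per-symbol bit width and supported k range.

    Attributes
    ----------
    kind:
        ``"nucleotide"`` or ``"peptide"``.
    symbols:
        Permitted characters in code order; the i-th symbol encodes as i.
    bits_per_symbol:
        2 for nucleotide, 5 for peptide.
    min_k, max_k:
        Inclusive bounds of the supported k-mer lengths.
    """

    kind: str
    symbols: str
    bits_per_symbol: int
    min_k: int
    max_k: int


#: DNA alphabet; lowercase (soft-masked) input is uppercased before encoding.
NUCLEOTIDE = Alphabet("nucleotide", "ACGT", 2, 1, 63)

#: Protein alphabet.  All 26 letters are admitted (5 bits hold 32 symbols),
#: so ambiguity codes such as B, J, X or Z are counted rather than dropped.
#: ``*`` (stop) is deliberately absent: windows containing it are skipped.
PEPTIDE = Alphabet("peptide", string.ascii_uppercase, 5, 3, 25)

# Storage tiers as (max_k, bit width), checked in order.
_WIDTH_TIERS: dict[str, tuple[tuple[int, int], ...]] = {
    "nucleotide": ((15, 32), (31, 64), (63, 128)),
    "peptide": ((3, 16), (6, 32), (12, 64), (25, 128)),
}

_INDEX: dict[str, dict[str, int]] = {
    a.kind: {ch: i for i, ch in enumerate(a.symbols)} for a in (NUCLEOTIDE, PEPTIDE)
}


def symbol_index(alphabet: Alphabet) -> dict[str, int]:
    """Character → symbol code lookup table for *alphabet*."""
    return _INDEX[alphabet.kind]


@dataclass(frozen=True)
class KmerCode:
    """A k-mer packed into a non-negative integer.

    ``value`` occupies at most ``bits_per_symbol * k`` bits; the first
    character of the k-mer sits in the most significant symbol slot.
    """

    value: int
    k: int
    alphabet: Alphabet

    def __post_init__(self):
        if self.value < 0 or self.value >> (self.alphabet.bits_per_symbol * self.k):
            raise EncodingError(
                f"code value {self.value} does not fit {self.k} symbols of "
                f"{self.alphabet.bits_per_symbol} bits"
            )


def width_class(k: int, alphabet: Alphabet) -> int:
    """Return the storage tier (16, 32, 64 or 128 bits) for length *k*.

    Nucleotide tiers: 32-bit for k ≤ 15, 64-bit for 16 ≤ k ≤ 31, 128-bit for
    32 ≤ k ≤ 63.  Peptide tiers: 16-bit for k = 3, 32-bit for 4 ≤ k ≤ 6,
    64-bit for 7 ≤ k ≤ 12, 128-bit for 13 ≤ k ≤ 25.

    Raises
    ------
    ValueError
        If *k* is outside the alphabet's supported range.
    """
    if not alphabet.min_k <= k <= alphabet.max_k:
        raise ValueError(
            f"k={k} out of range for {alphabet.kind} alphabet "
            f"(supported: {alphabet.min_k}..{alphabet.max_k})"
        )
    for max_k, width in _WIDTH_TIERS[alphabet.kind]:
        if k <= max_k:
            return width
    raise AssertionError("unreachable")  # pragma: no cover


def encode(kmer: str, alphabet: Alphabet = NUCLEOTIDE) -> KmerCode:
    """Encode *kmer* as a :class:`KmerCode`.

    Input is uppercased first, so soft-masked sequence encodes identically
    to its unmasked form.  Raises :class:`EncodingError` when a character is
    not in the alphabet and ``ValueError`` when ``len(kmer)`` is outside the
    supported range.
    """
    k = len(kmer)
    width_class(k, alphabet)  # validates the k range
    index = _INDEX[alphabet.kind]
    bits = alphabet.bits_per_symbol
    value = 0
    for ch in kmer.upper():
        sym = index.get(ch)
        if sym is None:
            raise EncodingError(
                f"character {ch!r} is not in the {alphabet.kind} alphabet"
            )
        value = (value << bits) | sym
    return KmerCode(value, k, alphabet)


def decode(code: KmerCode) -> str:
    """Decode a :class:`KmerCode` back to its (uppercase) string form."""
    bits = code.alphabet.bits_per_symbol
    mask = (1 << bits) - 1
    symbols = code.alphabet.symbols
    value = code.value
    chars = [""] * code.k
    for i in range(code.k - 1, -1, -1):
        chars[i] = symbols[value & mask]
        value >>= bits
    return "".join(chars)


def reverse_complement(code: KmerCode) -> KmerCode:
    """Reverse complement of a nucleotide code (A↔T, C↔G, order reversed).

    With the 2-bit mapping the complement of a symbol is ``3 - symbol``
    (equivalently XOR 3), so the whole operation is a reversed pass over the
    2-bit groups.  Applying it twice returns the input.
    """
    if code.alphabet.kind != "nucleotide":
        raise UnsupportedOperationError(
            "reverse complement is defined only for the nucleotide alphabet"
        )
    value = code.value
    rc = 0
    for _ in range(code.k):
        rc = (rc << 2) | (3 - (value & 3))
        value >>= 2
    return KmerCode(rc, code.k, code.alphabet)


def canonical(code: KmerCode) -> KmerCode:
    """The lexicographically smaller of a k-mer and its reverse complement.

    Because numeric order of codes equals lexicographic order of the decoded
    strings, this is ``min`` on the integer values.  Idempotent, and
    invariant under reverse complement of the input.
    """
    rc = reverse_complement(code)
    return code if code.value <= rc.value else rc
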