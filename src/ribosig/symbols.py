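"""IUPAC degenerate-code set algebra over the five-symbol alphabet {A,C,G,T,-}.

The gap is a first-class symbol so that indel signatures (columns whose
diagnostic state is the presence/absence of a base) fall out of the same set
operations as substitutions.

Two distinct roles for ambiguity codes:

* in *input sequences* an ambiguity character (``N``, ``Y``, ``R``, ...) is
  treated as :data:`MISSING` — a sequencing ambiguity is not evidence for
  every base it could denote, and counting it as such would veto true
  signatures;
* in *reports* ambiguity codes are used to summarise the set of residues a
  taxonomic group actually exhibits at a column.

``T`` and ``U`` are identified; all output uses the DNA alphabet.
"""

from __future__ import annotations

GAP = "-"
BASES: tuple[str, ...] = ("A", "C", "G", "T")
ALPHABET: tuple[str, ...] = BASES + (GAP,)

#: Type alias: a non-empty subset of ALPHABET.
SymbolSet = frozenset


class _Missing:
    """Sentinel for residues that carry no information (N, ?, X, ...)."""

    __slots__ = ()

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return "MISSING"


MISSING = _Missing()

# Degenerate nucleotide codes (DNA alphabet; U accepted on decode only).
IUPAC_TO_SET: dict[str, SymbolSet] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

SET_TO_IUPAC: dict[SymbolSet, str] = {s: c for c, s in IUPAC_TO_SET.items()}

_NORMALIZE: dict[str, str] = {}
for _b in "ACGT":
    _NORMALIZE[_b] = _b
    _NORMALIZE[_b.lower()] = _b
_NORMALIZE.update({"u": "T", "U": "T", "-": GAP, ".": GAP})


def normalize_residue(raw: str):
    """Map a raw sequence character to a symbol of the alphabet or MISSING.

    ``a/A → A`` etc., ``t/T/u/U → T``, ``-/. → gap``; every other character
    (IUPAC ambiguity codes included) maps to :data:`MISSING`.  Total
    function: never raises.
    """
    return _NORMALIZE.get(raw, MISSING)


def decode_iupac(code: str) -> SymbolSet:
    """Expand an IUPAC code, ``-`` or a gap-or-base code like ``-Y``.

    A leading ``-`` adds the gap symbol to the expansion of the remainder.

    Raises
    ------
    ValueError
        If ``code`` is not a recognised code (the message names it).
    """
    code = code.strip()
    if code == GAP:
        return frozenset((GAP,))
    if code.startswith(GAP) and len(code) == 2:
        return frozenset((GAP,)) | decode_iupac(code[1:])
    c = code.upper()
    if c == "U":
        return frozenset("T")
    if len(c) == 1 and c in IUPAC_TO_SET:
        return IUPAC_TO_SET[c]
    raise ValueError(f"unknown IUPAC code: {code!r}")


def encode_iupac(s: SymbolSet) -> str:
    """Inverse of :func:`decode_iupac`: render a symbol set as a code.

    Pure gap prints as ``-``; a gap-containing mixed set prints as ``-`` plus
    the code of its base part (the Table-style ``-Y`` dialect).
    """
    s = frozenset(s)
    if not s:
        raise ValueError("cannot encode an empty symbol set")
    if not s <= frozenset(ALPHABET):
        bad = sorted(s - frozenset(ALPHABET))
        raise ValueError(f"symbols outside alphabet: {bad}")
    if GAP in s:
        rest = s - {GAP}
        return GAP if not rest else GAP + SET_TO_IUPAC[rest]
    return SET_TO_IUPAC[s]
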