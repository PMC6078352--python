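"""Variant identifiers and the ubiquitin reference sequences.

A deep mutational scan of a 76-residue protein enumerates, at every
position except the initiator methionine, the 19 non-wild-type amino
acids plus a stop codon.  Variants are named with the conventional
``K63R`` / ``K63*`` tokens (wild-type residue, 1-based position,
substituted residue); the unmutated allele is the special token ``WT``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

#: Canonical ordering of the 20 amino acids plus the stop marker.
AMINO_ACIDS: tuple[str, ...] = tuple("ACDEFGHIKLMNPQRSTVWY")
STOP: str = "*"
RESIDUES: tuple[str, ...] = AMINO_ACIDS + (STOP,)

#: Saccharomyces cerevisiae ubiquitin (76 aa).
YEAST_UBIQUITIN = "MQIFVKTLTGKTITLEVESSDTIDNVKSKIQDKEGIPPDQQRLIFAGKQLEDGRTLSDYNIQKESTLHLVLRLRGG"
#: Human ubiquitin (76 aa); differs from yeast at positions 19, 24 and 28.
HUMAN_UBIQUITIN = "MQIFVKTLTGKTITLEVEPSDTIENVKAKIQDKEGIPPDQQRLIFAGKQLEDGRTLSDYNIQKESTLHLVLRLRGG"

_TOKEN_RE = re.compile(r"^([A-Y])(\d+)([A-Y*])$")


@dataclass(frozen=True)
class VariantID:
    """One amino-acid substitution, or the wild-type allele.

    ``position`` is 1-based in protein coordinates.  Substitution
    libraries start at position 2: the initiator methionine carries no
    data.  ``is_wt`` entries carry no (position, residue) pair.
    """

    position: int | None
    residue: str | None
    is_wt: bool = False

    def __post_init__(self) -> None:
        if self.is_wt:
            if self.position is not None or self.residue is not None:
                raise ValueError("WT entries carry no substitution")
        else:
            if self.position is None or self.residue is None:
                raise ValueError("substitutions need a position and residue")
            if self.residue not in RESIDUES:
                raise ValueError(f"unknown residue {self.residue!r}")
            if self.position < 2:
                raise ValueError("substitutions start at position 2 (Met1 carries no data)")

    def token(self, wt_sequence: str) -> str:
        """Render as ``WT`` or the ``K63R``-style token."""
        if self.is_wt:
            return "WT"
        wt_res = wt_sequence[self.position - 1]
        if self.residue == wt_res:
            raise ValueError(f"residue equals wild type at position {self.position}")
        return f"{wt_res}{self.position}{self.residue}"

    @property
    def is_stop(self) -> bool:
        return not self.is_wt and self.residue == STOP


WT_VARIANT = VariantID(None, None, is_wt=True)


def parse_token(token: str, wt_sequence: str | None = None) -> VariantID:
    """Parse a ``K63R`` / ``K63*`` / ``WT`` token.

    When ``wt_sequence`` is given, the leading residue letter is checked
    against it.
    """
    if token == "WT":
        return WT_VARIANT
    m = _TOKEN_RE.match(token)
    if m is None:
        raise ValueError(f"malformed variant token {token!r}")
    wt_res, pos, res = m.group(1), int(m.group(2)), m.group(3)
    if wt_sequence is not None:
        if pos > len(wt_sequence):
            raise ValueError(f"position {pos} beyond sequence of length {len(wt_sequence)}")
        if wt_sequence[pos - 1] != wt_res:
            raise ValueError(
                f"token {token!r} names wild-type {wt_res} but sequence has "
                f"{wt_sequence[pos - 1]} at position {pos}"
            )
    if wt_res == res:
        raise ValueError(f"token {token!r} is not a substitution")
    return VariantID(pos, res)


def token_position(token: str) -> int:
    """Position of a substitution token (``K63R`` -> 63)."""
    m = _TOKEN_RE.match(token)
    if m is None:
        raise ValueError(f"malformed variant token {token!r}")
    return int(m.group(2))


def token_residue(token: str) -> str:
    """Substituted residue of a token (``K63R`` -> ``R``)."""
    m = _TOKEN_RE.match(token)
    if m is None:
        raise ValueError(f"malformed variant token {token!r}")
    return m.group(3)


def enumerate_substitutions(wt_sequence: str, first_position: int = 2):
    """Yield every single substitution (19 AAs + stop per position).

    Positions run from ``first_position`` to the sequence length; at
    each, every residue other than the wild-type one is emitted, stop
    last within the canonical residue order.
    """
    for pos in range(first_position, len(wt_sequence) + 1):
        wt_res = wt_sequence[pos - 1]
        for res in RESIDUES:
            if res != wt_res:
                yield VariantID(pos, res)
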