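"""Restriction enzyme definitions with IUPAC-degenerate recognition sites.

An :class:`Enzyme` carries a recognition pattern written in IUPAC nucleotide
codes and the cut offset on the top strand, measured in bases from the start
of the site.  ``EcoRI`` (``G^AATTC``) therefore has ``cut_offset=1`` and
``NlaIII`` (``CATG^``) has ``cut_offset=4``.

The five built-in enzymes commonly used for two-enzyme GBS library design
are all palindromic under IUPAC-aware reverse complement, which is why cut
positions only need to be computed on the top strand.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

#: IUPAC nucleotide code -> set of matching sequence characters.
#: A pattern ``N`` matches any base including ``N``; every other code matches
#: only unambiguous bases, so an ``N`` in the sequence never satisfies a
#: non-``N`` pattern position.
IUPAC_CODES: dict[str, str] = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGTN",
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def reverse_complement(pattern: str) -> str:
    """IUPAC-aware reverse complement of a nucleotide pattern."""
    return pattern.upper().translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Enzyme:
    """A restriction enzyme: name, IUPAC recognition site, top-strand cut offset."""

    name: str
    site: str
    cut_offset: int

    def __post_init__(self) -> None:
        site = self.site.upper()
        object.__setattr__(self, "site", site)
        for code in site:
            if code not in IUPAC_CODES:
                raise ValueError(f"invalid IUPAC code {code!r} in site {site!r}")
        if not 0 <= self.cut_offset <= len(site):
            raise ValueError(
                f"cut_offset {self.cut_offset} outside [0, {len(site)}] for {site!r}"
            )

    @property
    def is_palindromic(self) -> bool:
        return self.site == reverse_complement(self.site)

    def site_regex(self) -> re.Pattern[str]:
        """Compiled lookahead regex reporting every (overlapping) site match."""
        classes = "".join(f"[{IUPAC_CODES[c]}]" for c in self.site)
        return re.compile(f"(?=({classes}))")


ECORI = Enzyme("EcoRI", "GAATTC", 1)
NLAIII = Enzyme("NlaIII", "CATG", 4)
PSTI = Enzyme("PstI", "CTGCAG", 5)
APEKI = Enzyme("ApeKI", "GCWGC", 1)
BSTNI = Enzyme("BstNI", "CCWGG", 2)

BUILTIN_ENZYMES: dict[str, Enzyme] = {
    e.name: e for e in (ECORI, NLAIII, PSTI, APEKI, BSTNI)
}


def get_enzyme(name: str) -> Enzyme:
    """Look up a built-in enzyme by (case-insensitive) name."""
    for key, enz in BUILTIN_ENZYMES.items():
        if key.lower() == name.lower():
            return enz
    raise KeyError(f"unknown enzyme {name!r}; built-ins: {sorted(BUILTIN_ENZYMES)}")
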