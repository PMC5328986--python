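"""Degenerate-primer matching and in-silico PCR.

Primer coordinates follow the convention used in nitrogenase amplicon
studies: the number in a forward primer's name is the 1-based template
position of its first (5') base, and the number in a reverse primer's
name is the 3'-most template position of its binding site.  With that
convention the nested nifD amplicon spans 820-1331 (512 bp) and the
anf/vnfD amplicon spans 548-1291 (744 bp).
"""

from __future__ import annotations

import re
from dataclasses import dataclass

IUPAC_DNA = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


class PrimerError(ValueError):
    """Raised for invalid primer definitions or ambiguous matches."""


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA string, IUPAC codes included."""
    return seq.upper().translate(_COMPLEMENT)[::-1]


def iupac_to_regex(primer: str) -> str:
    """Compile an IUPAC degenerate primer into a character-class regex."""
    parts = []
    for base in primer.upper():
        if base not in IUPAC_DNA:
            raise PrimerError(f"invalid IUPAC code {base!r} in primer {primer!r}")
        expanded = IUPAC_DNA[base]
        parts.append(expanded if len(expanded) == 1 else f"[{expanded}]")
    return "".join(parts)


def find_primer_matches(template: str, primer: str) -> list[int]:
    """0-based start positions of exact (zero-mismatch) degenerate matches."""
    pattern = re.compile(iupac_to_regex(primer))
    return [m.start() for m in pattern.finditer(template.upper())]


@dataclass(frozen=True)
class PrimerPair:
    """A forward/reverse primer pair with its reference coordinates.

    ``forward_ref_start`` is the 1-based reference position of the first
    forward-primer base; ``reverse_ref_end`` the 1-based 3'-most template
    position covered by the reverse-primer binding site.  The amplicon on
    an unmutated reference therefore has length
    ``reverse_ref_end - forward_ref_start + 1``.
    """

    name: str
    forward: str
    reverse: str
    forward_ref_start: int
    reverse_ref_end: int

    def __post_init__(self) -> None:
        for p in (self.forward, self.reverse):
            iupac_to_regex(p)  # validates characters
        if self.forward_ref_start >= self.reverse_ref_end:
            raise PrimerError("forward_ref_start must be < reverse_ref_end")

    @property
    def expected_amplicon_length(self) -> int:
        return self.reverse_ref_end - self.forward_ref_start + 1


# Published nested-PCR primer sets for nitrogenase alpha-subunit genes.
NIFD_OUTER = PrimerPair(
    "nifD820F/nifD1389R", "CACTGCTAYCGBTCGATGAACTAC", "GATGTCRCGSGCGAAGAT", 820, 1389
)
NIFD_INNER = PrimerPair(
    "nifD820F/nifD1331R", "CACTGCTAYCGBTCGATGAACTAC", "CAGGAGTGCATYTGVCGG", 820, 1331
)
ANFVNFD_OUTER = PrimerPair(
    "vnfD_anfD548F/1337R", "TSAAYATCGSCTGGRTSA", "GCGTTRTAVATRTCKCGSGC", 548, 1337
)
ANFVNFD_INNER = PrimerPair(
    "vnfD_anfD548F/1291R", "TSAAYATCGSCTGGRTSA", "TGTANGGRCCRTTGTGRTA", 548, 1291
)

PRIMER_SETS = {
    "nifD": (NIFD_OUTER, NIFD_INNER),
    "anfD": (ANFVNFD_OUTER, ANFVNFD_INNER),
    "vnfD": (ANFVNFD_OUTER, ANFVNFD_INNER),
}


def insilico_pcr(
    template: str, primers: PrimerPair, nested_inner: PrimerPair | None = None
) -> str | None:
    """Amplify ``template`` with a degenerate primer pair, zero mismatches.

    Returns the inclusive span from the first base of the forward-primer
    match through the last base of the reverse-primer binding site (the
    reverse primer is matched as its reverse complement), or ``None`` when
    either primer fails to find a site.  ``nested_inner``, when given, is
    applied to the first-round product.

    Raises
    ------
    PrimerError
        If the forward primer matches at more than one position.
    """
    if not template:
        raise ValueError("template must be non-empty")
    template = template.upper()

    fwd_hits = find_primer_matches(template, primers.forward)
    if len(fwd_hits) > 1:
        raise PrimerError(
            f"forward primer {primers.name} matches at multiple positions: "
            f"{[p + 1 for p in fwd_hits]}"
        )
    if not fwd_hits:
        return None
    start = fwd_hits[0]

    rev_site = reverse_complement(primers.reverse)
    rev_hits = [
        p for p in find_primer_matches(template, rev_site)
        if p + len(rev_site) > start + len(primers.forward)
    ]
    if not rev_hits:
        return None
    end = rev_hits[-1] + len(rev_site)  # 3'-most site

    product = template[start:end]
    if nested_inner is not None:
        return insilico_pcr(product, nested_inner)
    return product
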