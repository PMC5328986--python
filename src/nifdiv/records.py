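"""Core record types shared across the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field

ISOZYMES = ("nifD", "anfD", "vnfD")
INTERNAL_STANDARD = "internal_standard"


@dataclass(frozen=True)
class ReferenceSequence:
    """A curated nitrogenase reference gene (or the spiked internal standard).

    ``frame`` is the 0-based offset of the first complete codon of the
    coding frame; nitrogenase entries translate stop-free in that frame.
    The internal standard is non-coding (``protein`` empty).
    """

    id: str
    isozyme: str  # nifD | anfD | vnfD | internal_standard
    dna: str
    protein: str
    taxon_label: str = ""
    frame: int = 0


@dataclass(frozen=True)
class ReadTruth:
    """Ground-truth provenance for a simulated read."""

    source_ref_id: str
    is_chimera: bool = False
    chimera_parents: tuple[str, str] | None = None
    is_internal_standard: bool = False
    n_errors: int = 0


@dataclass
class ReadRecord:
    """One DNA amplicon read; ``truth`` is present iff the read is simulated."""

    id: str
    dna: str
    site: str = "synthetic"
    truth: ReadTruth | None = None
    protein: str = ""  # filled by the translation QC stage

    def __post_init__(self) -> None:
        if not self.dna:
            raise ValueError(f"read {self.id}: empty sequence")
        bad = set(self.dna.upper()) - set("ACGTN")
        if bad:
            raise ValueError(f"read {self.id}: invalid characters {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.dna)
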