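"""Read-filtering cascade for nitrogenase amplicon libraries.

Stages, in order: size selection (> 450 bp), translated homology screen
(six-frame, BLOSUM62, E <= 1e-5; reads failing it are rescued to the
control stream when they match the internal-standard DNA), homopolymer
(> 10) and ambiguous-base (> 0) filters, reference-based bimera removal,
single-frame translation with stop-codon rejection, and alignment-trim
to a uniform 458 bp window.  Reads are translated in frame 1 relative to
the forward-primer start (the primers are designed in-frame), and the
trim window starts at the reference position immediately following the
forward primer.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import align
from .primers import PRIMER_SETS
from .records import INTERNAL_STANDARD, ReadRecord, ReferenceSequence
from .simulate import reference_amplicon


class QCError(ValueError):
    pass


@dataclass(frozen=True)
class QCConfig:
    min_len_exclusive: int = 450
    homology_evalue_max: float = 1e-5
    max_homopolymer: int = 10
    max_ambiguous: int = 0
    trim_window_len: int = 458
    bimera_min_divergence: float = 0.05
    bimera_min_segment: int = 100

    def __post_init__(self) -> None:
        if self.max_ambiguous < 0 or min(
            self.min_len_exclusive,
            self.max_homopolymer,
            self.trim_window_len,
            self.bimera_min_segment,
        ) <= 0 or self.homology_evalue_max <= 0 or self.bimera_min_divergence <= 0:
            raise QCError("invalid QC thresholds")


@dataclass
class FilterReport:
    """Per-stage accounting; every stage partitions its input."""

    stages: list[dict] = field(default_factory=list)

    def add(self, name: str, n_in: int, n_kept: int, n_discarded: int,
            n_routed_to_control: int = 0) -> None:
        if n_in != n_kept + n_discarded + n_routed_to_control:
            raise QCError(f"stage {name}: counts do not partition the input")
        if self.stages and self.stages[-1]["n_kept"] != n_in:
            raise QCError(f"stage {name}: input does not match previous stage")
        self.stages.append(
            dict(stage_name=name, n_in=n_in, n_kept=n_kept,
                 n_discarded=n_discarded, n_routed_to_control=n_routed_to_control)
        )


@dataclass
class ReferencePanel:
    """References with their precomputed amplicons and trim windows."""

    references: list[ReferenceSequence]
    amplicons: dict[str, str]
    windows: dict[str, str]  # ref_id -> 458 bp interior window
    internal_standard: ReferenceSequence | None

    @classmethod
    def build(cls, references: list[ReferenceSequence],
              window_len: int = 458) -> "ReferencePanel":
        amplicons, windows = {}, {}
        internal = None
        for ref in references:
            if ref.isozyme == INTERNAL_STANDARD:
                internal = ref
                continue
            amp = reference_amplicon(ref)
            fwd_len = len(PRIMER_SETS[ref.isozyme][1].forward)
            if fwd_len + window_len > len(amp):
                raise QCError(
                    f"trim window ({window_len} bp) exceeds amplicon of {ref.id}"
                )
            amplicons[ref.id] = amp
            windows[ref.id] = amp[fwd_len : fwd_len + window_len]
        return cls(references, amplicons, windows, internal)

    @property
    def nitrogenase(self) -> list[ReferenceSequence]:
        return [r for r in self.references if r.isozyme != INTERNAL_STANDARD]


def filter_by_length(
    reads: list[ReadRecord], min_len_exclusive: int = 450
) -> tuple[list[ReadRecord], list[ReadRecord]]:
    """Keep reads strictly longer than the threshold; order preserved."""
    kept = [r for r in reads if len(r) > min_len_exclusive]
    discarded = [r for r in reads if len(r) <= min_len_exclusive]
    return kept, discarded


def translated_homology_screen(
    reads: list[ReadRecord],
    panel: ReferencePanel,
    evalue_max: float = 1e-5,
) -> tuple[list[ReadRecord], list[ReadRecord], list[ReadRecord]]:
    """Six-frame translate each read and align to the reference proteins;
    route non-matching reads that align to the internal-standard DNA to
    the control stream, discard the rest."""
    proteins = [r.protein for r in panel.nitrogenase]
    if not proteins or any(not p for p in proteins):
        raise QCError("all nitrogenase references need protein sequences")
    nitro, control, discarded = [], [], []
    for read in reads:
        if align.best_protein_evalue(read.dna, proteins) <= evalue_max:
            nitro.append(read)
        elif (
            panel.internal_standard is not None
            and align.nucleotide_evalue(read.dna, panel.internal_standard.dna)
            <= evalue_max
        ):
            control.append(read)
        else:
            discarded.append(read)
    return nitro, control, discarded


def longest_homopolymer(seq: str) -> int:
    best = run = 1
    for a, b in zip(seq, seq[1:]):
        run = run + 1 if a == b else 1
        best = max(best, run)
    return best if seq else 0


def filter_homopolymers_and_ambiguities(
    reads: list[ReadRecord], max_homopolymer: int = 10, max_ambiguous: int = 0
) -> tuple[list[ReadRecord], list[ReadRecord]]:
    kept, discarded = [], []
    for r in reads:
        seq = r.dna.upper()
        n_ambig = sum(c not in "ACGT" for c in seq)
        if longest_homopolymer(seq) > max_homopolymer or n_ambig > max_ambiguous:
            discarded.append(r)
        else:
            kept.append(r)
    return kept, discarded


def detect_reference_bimeras(
    reads: list[ReadRecord],
    panel: ReferencePanel,
    min_divergence: float = 0.05,
    min_segment: int = 100,
) -> tuple[list[ReadRecord], list[dict]]:
    """Reference-based two-parent chimera detection.

    A read is flagged when some breakpoint splits it into a left segment
    matching reference A and a right segment matching reference B != A,
    both segments >= ``min_segment``, the parents >= ``min_divergence``
    divergent, and the two-parent model strictly beats the best
    single-parent identity.  Returns (kept, flagged) where each flagged
    entry records the read and its inferred parents.
    """
    ref_ids = list(panel.amplicons)
    if len(ref_ids) < 2:
        return list(reads), []
    # pairwise parent divergence
    div = {}
    for i, a in enumerate(ref_ids):
        for b in ref_ids[i + 1 :]:
            d = align.edit_distance(panel.amplicons[a], panel.amplicons[b])
            d /= max(len(panel.amplicons[a]), len(panel.amplicons[b]))
            div[(a, b)] = div[(b, a)] = d

    kept, flagged = [], []
    for read in reads:
        profiles = {
            rid: align.match_profile(read.dna, panel.amplicons[rid])
            for rid in ref_ids
        }
        totals = {rid: int(p.sum()) for rid, p in profiles.items()}
        best_single = max(totals.values())
        L = len(read.dna)
        best = None
        if L >= 2 * min_segment:
            prefixes = {rid: np.concatenate([[0], np.cumsum(p)])
                        for rid, p in profiles.items()}
            ks = np.arange(min_segment, L - min_segment + 1)
            for a in ref_ids:
                for b in ref_ids:
                    if a == b or div[(a, b)] < min_divergence:
                        continue
                    two = prefixes[a][ks] + (totals[b] - prefixes[b][ks])
                    k_best = int(np.argmax(two))
                    if two[k_best] > best_single and (
                        best is None or two[k_best] > best[0]
                    ):
                        best = (int(two[k_best]), a, b, int(ks[k_best]))
        if best is None:
            kept.append(read)
        else:
            flagged.append(
                dict(read=read, parent_a=best[1], parent_b=best[2],
                     breakpoint=best[3], score=best[0])
            )
    return kept, flagged


def translate_and_drop_stop_reads(
    reads: list[ReadRecord],
) -> tuple[list[ReadRecord], list[ReadRecord]]:
    """Translate in frame 1 relative to the forward-primer start (= read
    start for amplicon reads), truncating the 3' remainder; discard reads
    whose translation contains a stop."""
    kept, discarded = [], []
    for r in reads:
        prot = align.translate(r.dna.upper().replace("N", "A"))
        if "*" in prot:
            discarded.append(r)
        else:
            kept.append(replace_protein(r, prot))
    return kept, discarded


def replace_protein(read: ReadRecord, protein: str) -> ReadRecord:
    out = ReadRecord(id=read.id, dna=read.dna, site=read.site, truth=read.truth)
    out.protein = protein
    return out


def align_trim_fixed_window(
    reads: list[ReadRecord],
    panel: ReferencePanel,
    window_len: int = 458,
) -> tuple[list[ReadRecord], list[ReadRecord]]:
    """Crop each read to the fixed 458 bp interior window of its nearest
    reference; discard reads not covering the full window ungapped."""
    kept, discarded = [], []
    for r in reads:
        nearest = min(
            panel.amplicons,
            key=lambda rid: (
                align.edit_distance(r.dna, panel.amplicons[rid], mode="HW"),
                rid,
            ),
        )
        window = panel.windows[nearest]
        if len(window) != window_len:
            raise QCError("reference window shorter than requested length")
        projected = align.project_onto_reference(r.dna, window)
        if sum(c != "-" for c in projected) < window_len:
            discarded.append(r)
        else:
            out = ReadRecord(id=r.id, dna=projected, site=r.site, truth=r.truth)
            # the window starts on a codon boundary, so re-derive the
            # protein from the trimmed sequence (keeps run_qc idempotent)
            out.protein = align.translate(projected) if r.protein else ""
            kept.append(out)
    return kept, discarded


def run_qc(
    reads: list[ReadRecord],
    references: list[ReferenceSequence],
    config: QCConfig | None = None,
) -> tuple[list[ReadRecord], list[ReadRecord], FilterReport]:
    """Run the full cascade; returns (clean_reads, control_reads, report)."""
    config = config or QCConfig()
    panel = ReferencePanel.build(references, config.trim_window_len)
    report = FilterReport()

    kept, disc = filter_by_length(reads, config.min_len_exclusive)
    report.add("length", len(reads), len(kept), len(disc))

    n_in = len(kept)
    kept, control, disc = translated_homology_screen(
        kept, panel, config.homology_evalue_max
    )
    report.add("homology_screen", n_in, len(kept), len(disc), len(control))

    n_in = len(kept)
    kept, disc = filter_homopolymers_and_ambiguities(
        kept, config.max_homopolymer, config.max_ambiguous
    )
    report.add("homopolymer_ambiguity", n_in, len(kept), len(disc))

    n_in = len(kept)
    kept, flagged = detect_reference_bimeras(
        kept, panel, config.bimera_min_divergence, config.bimera_min_segment
    )
    report.add("bimera", n_in, len(kept), len(flagged))

    n_in = len(kept)
    kept, disc = translate_and_drop_stop_reads(kept)
    report.add("translation", n_in, len(kept), len(disc))

    n_in = len(kept)
    kept, disc = align_trim_fixed_window(kept, panel, config.trim_window_len)
    report.add("trim", n_in, len(kept), len(disc))

    return kept, control, report
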