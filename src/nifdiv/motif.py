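"""Conserved cofactor-ligand motif analysis for AnfD/VnfD proteins.

The alpha-subunit cysteine that ligates the FeMo/FeV/FeFe cofactor
(position 275 in the Azotobacter vinelandii numbering) sits in a
conserved 'CAR' tripeptide.  Sequences are scanned for 'CAR', trimmed to
the 13-residue '--V--CAR---Y' window (cysteine at window position 6,
valine at 3, tyrosine at 13), and windows lacking the full motif or
occurring only once in the collection are removed.  The surviving
windows are summarized as a position-frequency matrix with per-position
information content for sequence-logo rendering.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import align

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
WINDOW_LEN = 13
ALPHA_CYS_POSITION = 6  # 1-based within the window


class MotifError(ValueError):
    pass


@dataclass(frozen=True)
class MotifWindow:
    source_id: str
    residues: str

    def __post_init__(self) -> None:
        r = self.residues
        if len(r) != WINDOW_LEN:
            raise MotifError("motif window must be 13 residues")
        if r[2] != "V" or r[5:8] != "CAR" or r[12] != "Y":
            raise MotifError(f"window {r!r} violates the '--V--CAR---Y' pattern")


@dataclass
class PositionFrequencyMatrix:
    counts: pd.DataFrame  # 13 x 20 integers
    frequencies: pd.DataFrame  # row-stochastic
    n_sequences: int
    information_bits: np.ndarray  # per position, in [0, log2 20]


def _candidate_windows(seq: str) -> list[str]:
    """All 13-mers around 'CAR' occurrences satisfying the window
    constraints ('X' never matches and disqualifies a window)."""
    out = []
    start = 0
    while True:
        idx = seq.find("CAR", start)
        if idx == -1:
            break
        start = idx + 1
        if idx < 5 or idx + 8 > len(seq):
            continue
        window = seq[idx - 5 : idx + 8]
        if window[2] == "V" and window[12] == "Y" and set(window) <= set(AMINO_ACIDS):
            out.append(window)
    return out


def extract_motif_windows(
    proteins: list[tuple[str, str]],
) -> tuple[list[MotifWindow], list[str], list[str]]:
    """Trim proteins to their '--V--CAR---Y' window.

    Returns (windows, removed_incomplete, removed_singletons) — ids of
    sequences with no valid window, and of windows whose exact 13-mer
    occurs only once in the collection.  When a sequence has several
    valid windows the 5'-most is kept.
    """
    candidates: list[MotifWindow] = []
    removed_incomplete: list[str] = []
    for pid, seq in proteins:
        wins = _candidate_windows(seq.upper())
        if not wins:
            removed_incomplete.append(pid)
        else:
            candidates.append(MotifWindow(source_id=pid, residues=wins[0]))
    tallies = Counter(w.residues for w in candidates)
    windows = [w for w in candidates if tallies[w.residues] > 1]
    removed_singletons = [w.source_id for w in candidates if tallies[w.residues] == 1]
    return windows, removed_incomplete, removed_singletons


def windows_from_reads(reads) -> tuple[list[MotifWindow], list[str], list[str]]:
    """Extract motif windows from DNA reads via six-frame translation.

    Matches the looser screening stream: a full stop-free translation is
    not required — the first frame yielding a valid window is used.
    """
    proteins = []
    for r in reads:
        seq = ""
        for frame_prot in align.six_frame_translations(r.dna.upper().replace("N", "X")):
            if _candidate_windows(frame_prot):
                seq = frame_prot
                break
        proteins.append((r.id, seq))
    return extract_motif_windows(proteins)


def build_pfm(windows: list[MotifWindow]) -> PositionFrequencyMatrix:
    """Counts, frequencies, and information content per window position."""
    if not windows:
        raise MotifError("no windows to summarize")
    counts = np.zeros((WINDOW_LEN, len(AMINO_ACIDS)), dtype=int)
    aa_index = {aa: k for k, aa in enumerate(AMINO_ACIDS)}
    for w in windows:
        for pos, aa in enumerate(w.residues):
            counts[pos, aa_index[aa]] += 1
    freqs = counts / counts.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(freqs > 0, freqs * np.log2(freqs), 0.0)
    entropy = -plogp.sum(axis=1)
    info = np.log2(len(AMINO_ACIDS)) - entropy
    idx = pd.RangeIndex(1, WINDOW_LEN + 1, name="position")
    cols = list(AMINO_ACIDS)
    return PositionFrequencyMatrix(
        counts=pd.DataFrame(counts, index=idx, columns=cols),
        frequencies=pd.DataFrame(freqs, index=idx, columns=cols),
        n_sequences=len(windows),
        information_bits=info,
    )
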