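"""Local/global alignment helpers and Karlin-Altschul E-values.

The homology screens use conventional BLAST-like parameterizations:
BLOSUM62 with affine gaps 11/1 for protein searches and +2/-3 with gaps
5/2 for nucleotide searches.  E-values follow the Karlin-Altschul formula
E = K * m * n * exp(-lambda * S) with the standard gapped constants for
those scoring systems, and a search space of (query length x total
subject length).
"""

from __future__ import annotations

from functools import lru_cache

import edlib
import numpy as np
from Bio.Align import PairwiseAligner, substitution_matrices
from Bio.Seq import Seq

# Gapped Karlin-Altschul constants (BLAST defaults for these systems).
PROTEIN_LAMBDA, PROTEIN_K = 0.267, 0.041  # BLOSUM62, gap open 11 extend 1
NUC_LAMBDA, NUC_K = 0.625, 0.41  # match +2 mismatch -3, gap open 5 extend 2

BACTERIAL_TABLE = 11


@lru_cache(maxsize=1)
def protein_aligner() -> PairwiseAligner:
    aln = PairwiseAligner()
    aln.mode = "local"
    aln.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aln.open_gap_score = -11.0
    aln.extend_gap_score = -1.0
    return aln


@lru_cache(maxsize=1)
def nucleotide_aligner() -> PairwiseAligner:
    aln = PairwiseAligner()
    aln.mode = "local"
    aln.match_score = 2.0
    aln.mismatch_score = -3.0
    aln.open_gap_score = -5.0
    aln.extend_gap_score = -2.0
    return aln


def evalue(score: float, m: int, n: int, *, protein: bool) -> float:
    lam, k = (PROTEIN_LAMBDA, PROTEIN_K) if protein else (NUC_LAMBDA, NUC_K)
    return float(k * m * n * np.exp(-lam * score))


def translate(dna: str, frame: int = 0, table: int = BACTERIAL_TABLE) -> str:
    """Translate from ``frame`` (0-based), truncating the 3' remainder."""
    sub = dna[frame:]
    sub = sub[: len(sub) - len(sub) % 3]
    if not sub:
        return ""
    return str(Seq(sub).translate(table=table))


def six_frame_translations(dna: str, table: int = BACTERIAL_TABLE) -> list[str]:
    rc = str(Seq(dna).reverse_complement())
    return [translate(s, f, table) for s in (dna, rc) for f in (0, 1, 2)]


def _sanitize_protein(seq: str) -> str:
    # PairwiseAligner rejects letters outside the matrix alphabet.
    keep = set("ARNDCQEGHILKMFPSTWYVBZX*")
    return "".join(c if c in keep else "X" for c in seq.upper())


def best_protein_evalue(read_dna: str, ref_proteins: list[str]) -> float:
    """Best (smallest) E-value of any six-frame translation vs any reference."""
    aln = protein_aligner()
    total_n = sum(len(p) for p in ref_proteins)
    best = np.inf
    for prot in six_frame_translations(read_dna):
        if not prot:
            continue
        q = _sanitize_protein(prot)
        for ref in ref_proteins:
            score = aln.score(q, _sanitize_protein(ref))
            e = evalue(score, len(q), total_n, protein=True)
            best = min(best, e)
    return best


def nucleotide_evalue(read_dna: str, ref_dna: str) -> float:
    aln = nucleotide_aligner()
    score = aln.score(read_dna.upper().replace("N", "A"), ref_dna.upper())
    return evalue(score, len(read_dna), len(ref_dna), protein=False)


def edit_distance(a: str, b: str, mode: str = "NW") -> int:
    """Edit distance; mode "NW" is global, "HW" treats ``a`` as an infix
    of ``b`` (end gaps in ``b`` are free)."""
    return edlib.align(a, b, mode=mode)["editDistance"]


def _parse_cigar(cigar: str):
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            yield int(num), ch
            num = ""


def project_onto_reference(read: str, ref: str) -> str:
    """Infix-align ``read`` to ``ref`` and return the read projected onto
    reference coordinates: one character per reference position ('-' where
    the read has a deletion or does not cover; read insertions dropped)."""
    res = edlib.align(read, ref, mode="HW", task="path")
    start, _end = res["locations"][0]
    out = ["-"] * len(ref)
    ri = 0  # read index
    ti = start  # target (ref) index
    for length, op in _parse_cigar(res["cigar"]):
        if op in "=XM":
            for k in range(length):
                out[ti + k] = read[ri + k]
            ri += length
            ti += length
        elif op == "I":  # insertion in read relative to ref
            ri += length
        elif op == "D":  # deletion in read
            ti += length
    return "".join(out)


def match_profile(read: str, ref: str) -> np.ndarray:
    """Boolean per-read-position array: True where the read base matches
    ``ref`` under an infix alignment."""
    res = edlib.align(read, ref, mode="HW", task="path")
    prof = np.zeros(len(read), dtype=bool)
    ri = 0
    ti = res["locations"][0][0]
    for length, op in _parse_cigar(res["cigar"]):
        if op == "=":
            prof[ri : ri + length] = True
            ri += length
            ti += length
        elif op in "XM":
            if op == "M":
                for k in range(length):
                    prof[ri + k] = read[ri + k] == ref[ti + k]
            ri += length
            ti += length
        elif op == "I":
            ri += length
        elif op == "D":
            ti += length
    return prof
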