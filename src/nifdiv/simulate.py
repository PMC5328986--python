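"""Synthetic-data generator for the whole pipeline.

Emulates the study conditions the downstream stages expect: curated
nifD/anfD/vnfD reference genes carrying the published nested-primer sites
(so in-silico PCR yields the 512 bp nifD and 744 bp anf/vnfD amplicons),
CCS-like reads with substitution/homopolymer/ambiguity errors, two-parent
chimeras, a 600 bp 60%-GC internal-standard spike-in at a 1% target,
isotope (delta-13C) samples from the two-endmember mixing model, acetylene
reduction time courses, and genome gene-suite tables.

All simulators take an explicit integer seed and are byte-identical on
rerun; there is no hidden global random state.
"""

from __future__ import annotations

import itertools

import numpy as np

from .align import BACTERIAL_TABLE, translate
from .isara import Endmembers, IsotopeSample, TimeCourse
from .primers import PRIMER_SETS, find_primer_matches, insilico_pcr
from .records import INTERNAL_STANDARD, ISOZYMES, ReadRecord, ReadTruth, ReferenceSequence
from .screen import GENE_VOCABULARY, GeneSuite

REF_LEN = 1401
IS_LEN = 600
IS_GC_BAND = (0.58, 0.62)

_STOPS = {"TAA", "TAG", "TGA"}  # genetic code table 11
_BASES = "ACGT"
NONSTOP_CODONS = [
    "".join(c) for c in itertools.product(_BASES, repeat=3) if "".join(c) not in _STOPS
]

# Concrete realizations of the degenerate primer binding sites embedded in
# every generated reference, keyed by isozyme: (0-based start, template
# sequence).  Reverse sites are stored as they appear on the template
# (reverse complement of the primer).
_FIXED_SITES = {
    "nifD": [
        (819, "CACTGCTACCGCTCGATGAACTAC"),  # nifD820F
        (1313, "CCGGCAGATGCACTCCTG"),  # nifD1331R site
        (1371, "ATCTTCGCGCGCGACATC"),  # nifD1389R site
    ],
    "anfvnf": [
        (547, "TCAATATCGCCTGGATCA"),  # vnfD_anfD548F
        (1272, "TATCACAATGGTCCGTACA"),  # vnfD_anfD1291R site
        (1317, "GCGCGAGATATGTATAACGC"),  # vnfD_anfD1337R site
    ],
}

# Coding-frame offset (0-based) putting the forward-primer start on a codon
# boundary: position 820 = 3*273+1 is frame 0; position 548 = 3*182+2 needs
# offset 1.
FRAME_OFFSET = {"nifD": 0, "anfD": 1, "vnfD": 1}

# The 13-residue cofactor-ligand window ('--V--CAR---Y') embedded in every
# anfD/vnfD reference.  Codon start 766 (0-based) is on the anf/vnf frame
# and inside the 458 bp trim window of the 744 bp amplicon.
MOTIF_CODON_START = 766
_MOTIF_FIXED_CODONS = {2: "GTG", 5: "TGC", 6: "GCT", 7: "CGT", 12: "TAC"}  # V,C,A,R,Y


class SimulationError(ValueError):
    pass


def _codon_starts(frame: int) -> range:
    return range(frame, REF_LEN - 2, 3)


def _protected_positions(isozyme: str) -> set[int]:
    key = "anfvnf" if isozyme in ("anfD", "vnfD") else "nifD"
    prot: set[int] = set()
    for start, seq in _FIXED_SITES[key]:
        prot.update(range(start, start + len(seq)))
    if key == "anfvnf":
        for ci, _codon in _MOTIF_FIXED_CODONS.items():
            start = MOTIF_CODON_START + 3 * ci
            prot.update(range(start, start + 3))
    return prot


def _build_ancestor(isozyme: str, rng: np.random.Generator) -> list[str]:
    """Random stop-free gene with the fixed primer/motif sites embedded."""
    frame = FRAME_OFFSET[isozyme]
    seq = list(rng.choice(list(_BASES), size=REF_LEN))
    # stop-free coding frame
    for cs in _codon_starts(frame):
        seq[cs : cs + 3] = list(NONSTOP_CODONS[rng.integers(len(NONSTOP_CODONS))])
    key = "anfvnf" if isozyme in ("anfD", "vnfD") else "nifD"
    for start, site in _FIXED_SITES[key]:
        seq[start : start + len(site)] = list(site)
    if key == "anfvnf":
        for ci, codon in _MOTIF_FIXED_CODONS.items():
            start = MOTIF_CODON_START + 3 * ci
            seq[start : start + 3] = list(codon)
    # repair any stop codon created at a fixed-site boundary: set a free
    # base to C (no stop codon contains C)
    protected = _protected_positions(isozyme)
    for cs in _codon_starts(frame):
        if "".join(seq[cs : cs + 3]) in _STOPS:
            free = [p for p in range(cs, cs + 3) if p not in protected]
            if not free:
                raise SimulationError("stop codon locked by fixed sites")
            seq[free[0]] = "C"
    return seq


def _mutate(
    ancestor: list[str], isozyme: str, rng: np.random.Generator, n_codons: int = 30
) -> str:
    """Replace ``n_codons`` unprotected codons with random non-stop codons."""
    frame = FRAME_OFFSET[isozyme]
    protected = _protected_positions(isozyme)
    mutable = [
        cs
        for cs in _codon_starts(frame)
        if not any(p in protected for p in range(cs, cs + 3))
    ]
    seq = list(ancestor)
    for cs in rng.choice(len(mutable), size=min(n_codons, len(mutable)), replace=False):
        start = mutable[cs]
        old = "".join(seq[start : start + 3])
        new = old
        while new == old:
            new = NONSTOP_CODONS[rng.integers(len(NONSTOP_CODONS))]
        seq[start : start + 3] = list(new)
    return "".join(seq)


def _generate_internal_standard(rng: np.random.Generator) -> str:
    """600 bp random sequence with GC fraction in the 0.58-0.62 band."""
    while True:
        seq = list(rng.choice(list(_BASES), size=IS_LEN, p=[0.2, 0.3, 0.3, 0.2]))
        gc = sum(b in "GC" for b in seq) / IS_LEN
        lo, hi = IS_GC_BAND
        guard = 0
        while not (lo <= gc <= hi):
            i = int(rng.integers(IS_LEN))
            if gc < lo and seq[i] in "AT":
                seq[i] = "G" if rng.integers(2) else "C"
                gc += 1 / IS_LEN
            elif gc > hi and seq[i] in "GC":
                seq[i] = "A" if rng.integers(2) else "T"
                gc -= 1 / IS_LEN
            guard += 1
            if guard > 10 * IS_LEN:  # pragma: no cover
                break
        dna = "".join(seq)
        hits = sum(
            len(find_primer_matches(dna, pair.forward))
            for pairs in PRIMER_SETS.values()
            for pair in pairs
        )
        if hits == 0:
            return dna


def generate_reference_set(n_per_isozyme: int, seed: int) -> list[ReferenceSequence]:
    """Generate ``3 * n_per_isozyme`` nitrogenase references plus one
    internal standard.

    Same-isozyme references are <=15% pairwise divergent (bounded by
    construction: each carries at most 30 mutated codons); different
    isozymes are >=30% divergent.  Every reference carries exact binding
    sites for its gene's nested primer pairs, and every anfD/vnfD protein
    contains the 13-residue '--V--CAR---Y' cofactor window.
    """
    if n_per_isozyme < 0:
        raise SimulationError("n_per_isozyme must be >= 0")
    rng = np.random.default_rng(seed)
    refs: list[ReferenceSequence] = []
    ancestors = {iso: _build_ancestor(iso, rng) for iso in ISOZYMES}
    for iso in ISOZYMES:
        for i in range(n_per_isozyme):
            dna = _mutate(ancestors[iso], iso, rng)
            frame = FRAME_OFFSET[iso]
            outer, inner = PRIMER_SETS[iso]
            if len(find_primer_matches(dna, outer.forward)) != 1:
                raise SimulationError("forward primer site not unique")
            refs.append(
                ReferenceSequence(
                    id=f"{iso}_ref_{i:02d}",
                    isozyme=iso,
                    dna=dna,
                    protein=translate(dna, frame, BACTERIAL_TABLE),
                    taxon_label=f"synthetic diazotroph {iso}-{i}",
                    frame=frame,
                )
            )
    refs.append(
        ReferenceSequence(
            id="internal_standard",
            isozyme=INTERNAL_STANDARD,
            dna=_generate_internal_standard(rng),
            protein="",
            taxon_label="synthetic spike-in control",
        )
    )
    return refs


def reference_amplicon(ref: ReferenceSequence) -> str:
    """Nested-PCR product of a reference (the full 600 bp for the internal
    standard, which is sequenced as-is)."""
    if ref.isozyme == INTERNAL_STANDARD:
        return ref.dna
    outer, inner = PRIMER_SETS[ref.isozyme]
    product = insilico_pcr(ref.dna, outer, nested_inner=inner)
    if product is None:
        raise SimulationError(f"primers fail on reference {ref.id}")
    return product


def _find_runs(seq: list[str], min_len: int = 3) -> list[tuple[int, int]]:
    runs = []
    i = 0
    while i < len(seq):
        j = i
        while j < len(seq) and seq[j] == seq[i]:
            j += 1
        if j - i >= min_len:
            runs.append((i, j))
        i = j
    return runs


def _apply_errors(
    dna: str, error_rates: dict, rng: np.random.Generator
) -> tuple[str, int]:
    sub = error_rates.get("substitution", 0.0)
    homo = error_rates.get("homopolymer_extension", 0.0)
    amb = error_rates.get("ambiguity", 0.0)
    seq = list(dna)
    n_err = 0
    n_sub = rng.binomial(len(seq), sub)
    if n_sub:
        for pos in rng.choice(len(seq), size=n_sub, replace=False):
            choices = [b for b in _BASES if b != seq[pos]]
            seq[pos] = choices[rng.integers(3)]
        n_err += int(n_sub)
    if homo > 0:
        # extend or contract existing homopolymer runs by one base
        for start, end in reversed(_find_runs(seq)):
            if rng.random() < homo:
                if rng.integers(2):
                    seq.insert(start, seq[start])
                else:
                    del seq[start]
                n_err += 1
    n_amb = rng.binomial(len(seq), amb)
    if n_amb:
        for pos in rng.choice(len(seq), size=n_amb, replace=False):
            seq[pos] = "N"
        n_err += int(n_amb)
    return "".join(seq), n_err


def simulate_ccs_reads(
    references: list[ReferenceSequence],
    composition: dict[str, int],
    error_rates: dict | None = None,
    chimera_rate: float = 0.0,
    internal_standard_fraction: float = 0.0,
    seed: int = 0,
    site: str = "synthetic",
) -> list[ReadRecord]:
    """Simulate consensus (CCS-like) amplicon reads.

    ``composition`` maps nitrogenase reference ids to read counts.  A
    binomial draw at ``internal_standard_fraction`` of the reads is
    replaced by internal-standard reads and a binomial draw at
    ``chimera_rate`` by single-breakpoint two-parent splices (breakpoint
    uniform in the middle 50% of the amplicon, both parents recorded).
    """
    error_rates = error_rates or {}
    for key, val in {
        "chimera_rate": chimera_rate,
        "internal_standard_fraction": internal_standard_fraction,
        **error_rates,
    }.items():
        if not 0.0 <= val <= 1.0:
            raise SimulationError(f"{key} must be in [0, 1]")
    if any(c < 0 for c in composition.values()):
        raise SimulationError("composition counts must be >= 0")
    total = sum(composition.values())
    if total == 0 and (chimera_rate > 0 or internal_standard_fraction > 0):
        raise SimulationError("empty composition with nonzero fractions")

    by_id = {r.id: r for r in references}
    amplicons = {}
    pools = {}  # ref_id -> chimera-compatible pool key
    for rid in composition:
        ref = by_id[rid]
        amplicons[rid] = reference_amplicon(ref)
        pools[rid] = "nifD" if ref.isozyme == "nifD" else "anfvnf"
    is_ref = next((r for r in references if r.isozyme == INTERNAL_STANDARD), None)

    rng = np.random.default_rng(seed)
    sources = [rid for rid in composition for _ in range(composition[rid])]

    n_is = rng.binomial(total, internal_standard_fraction) if total else 0
    idx = rng.permutation(total)
    is_idx = set(idx[:n_is].tolist())
    rest = idx[n_is:]
    n_chim = min(rng.binomial(total, chimera_rate), len(rest)) if total else 0
    chim_idx = set(rest[:n_chim].tolist())

    reads: list[ReadRecord] = []
    for i in range(total):
        rid = sources[i]
        if i in is_idx:
            if is_ref is None:
                raise SimulationError("internal standard requested but no "
                                      "internal_standard reference supplied")
            base, truth_src = is_ref.dna, is_ref.id
            truth = dict(is_internal_standard=True)
        elif i in chim_idx:
            partners = [r for r in composition if r != rid and pools[r] == pools[rid]]
            if partners:
                partner = partners[int(rng.integers(len(partners)))]
                a, b = amplicons[rid], amplicons[partner]
                lo, hi = len(a) // 4, 3 * min(len(a), len(b)) // 4
                bp = int(rng.integers(lo, hi + 1))
                base, truth_src = a[:bp] + b[bp:], rid
                truth = dict(is_chimera=True, chimera_parents=(rid, partner))
            else:  # no compatible partner: leave the read non-chimeric
                base, truth_src, truth = amplicons[rid], rid, {}
        else:
            base, truth_src, truth = amplicons[rid], rid, {}
        dna, n_err = _apply_errors(base, error_rates, rng)
        reads.append(
            ReadRecord(
                id=f"read_{i:05d}",
                dna=dna,
                site=site,
                truth=ReadTruth(source_ref_id=truth_src, n_errors=n_err, **truth),
            )
        )
    return reads


def simulate_isotope_samples(
    f_alt_true: float,
    alt_isozyme: str,
    endmembers: Endmembers | None = None,
    delta_acetylene: float = -24.0,
    noise_sd: float = 0.2,
    n: int = 3,
    seed: int = 0,
    sample_id: str = "sim",
) -> list[IsotopeSample]:
    """Draw replicate delta-13C pairs for a true alternative-isozyme
    fraction: the expressed fractionation is f*eps_alt + (1-f)*eps_Mo."""
    em = endmembers or Endmembers()
    if not 0.0 <= f_alt_true <= 1.0:
        raise SimulationError("f_alt_true must be in [0, 1]")
    if n < 1:
        raise SimulationError("n must be >= 1")
    if alt_isozyme == "Fe":
        eps_alt = em.eps_Fe
    elif alt_isozyme == "V":
        eps_alt = em.eps_V
    else:
        raise SimulationError(f"unknown isozyme {alt_isozyme!r} (use 'Fe' or 'V')")
    rng = np.random.default_rng(seed)
    eps_mix = f_alt_true * eps_alt + (1.0 - f_alt_true) * em.eps_Mo
    out = []
    for i in range(n):
        noise = rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0
        out.append(
            IsotopeSample(
                sample_id=sample_id,
                delta13C_acetylene=delta_acetylene,
                delta13C_ethylene=delta_acetylene - eps_mix + noise,
                replicate=i + 1,
            )
        )
    return out


def simulate_ara_timecourse(
    rate: float,
    times: list[float],
    noise_sd: float = 0.0,
    seed: int = 0,
    sample_id: str = "sim",
) -> TimeCourse:
    """Linear ethylene accumulation (ppmv) with Gaussian noise, floored at 0."""
    if len(times) < 3:
        raise SimulationError("need at least 3 time points")
    rng = np.random.default_rng(seed)
    t = np.asarray(times, dtype=float)
    eth = rate * t
    if noise_sd > 0:
        eth = eth + rng.normal(0.0, noise_sd, size=len(t))
    eth = np.maximum(eth, 0.0)
    return TimeCourse(sample_id=sample_id, times=t.tolist(), ethylene=eth.tolist())


def simulate_gene_suites(profiles: list[dict], seed: int = 0) -> list[GeneSuite]:
    """Build GeneSuite rows from presence profiles.

    Each profile is ``{"genome_id": str, "genes_present": set,
    "evalues": optional map}``; present genes default to E = 1e-50.
    """
    suites = []
    for prof in profiles:
        present = set(prof.get("genes_present", set()))
        unknown = present - set(GENE_VOCABULARY)
        if unknown:
            raise SimulationError(f"unknown gene names: {sorted(unknown)}")
        evalues = {g: 1e-50 for g in present}
        evalues.update(prof.get("evalues", {}))
        suites.append(GeneSuite(genome_id=prof["genome_id"], evalues=evalues))
    return suites
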