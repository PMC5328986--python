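"""Genome screening for nitrogenase isozyme gene suites.

A genome is credited with an isozyme when it carries the minimum gene
set: NifHDKENB for Mo-nitrogenase, Anf/VnfDKG plus at least one H
protein (NifH, AnfH, or VnfH — the H genes are not diagnostic for the
isozyme) for the alternative enzymes.  Protochlorophyllide/chlorophyllide
reductase subunits (BchL/N/X/Y) are homologous to nitrogenase components
and are used as competing queries: a proteome protein whose best hit is a
Bch query is not credited to a nitrogenase gene.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from . import align

NIF_GENES = ("NifH", "NifD", "NifK", "NifE", "NifN", "NifB")
ANF_GENES = ("AnfH", "AnfD", "AnfK", "AnfG")
VNF_GENES = ("VnfH", "VnfD", "VnfK", "VnfG")
BCH_GENES = ("BchL", "BchN", "BchX", "BchY")
NITROGENASE_GENES = NIF_GENES + ANF_GENES + VNF_GENES
GENE_VOCABULARY = NITROGENASE_GENES + BCH_GENES

H_GENES = ("NifH", "AnfH", "VnfH")
DEFAULT_EVALUE_MAX = 1e-20


class ScreenError(ValueError):
    pass


@dataclass
class GeneSuite:
    """Best-hit E-value per query gene for one genome (absent genes omitted)."""

    genome_id: str
    evalues: dict[str, float] = field(default_factory=dict)
    bch_confounded: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        unknown = set(self.evalues) - set(GENE_VOCABULARY)
        if unknown:
            raise ScreenError(f"unknown gene names: {sorted(unknown)}")
        if any(e <= 0 for e in self.evalues.values()):
            raise ScreenError("e-values must be > 0")

    def present(self, gene: str, evalue_max: float = DEFAULT_EVALUE_MAX) -> bool:
        return self.evalues.get(gene, float("inf")) <= evalue_max


@dataclass(frozen=True)
class SuiteClassification:
    genome_id: str
    has_Mo: bool
    has_Fe_only: bool
    has_V: bool
    incomplete_nif_flag: bool
    bch_confounded: frozenset[str] = frozenset()


def classify_suites(
    suite: GeneSuite, evalue_max: float = DEFAULT_EVALUE_MAX
) -> SuiteClassification:
    """Apply the minimum-gene-set rules to one genome.

    Mo-nitrogenase requires NifHDKENB; genomes with NifHDKB but missing
    only NifE and/or NifN keep has_Mo with the incomplete-Nif flag set.
    Fe-only requires AnfDKG, V requires VnfDKG, each plus at least one H
    protein of any system.  Each flag is evaluated independently.
    """
    p = {g: suite.present(g, evalue_max) for g in NITROGENASE_GENES}
    has_h = any(p[g] for g in H_GENES)
    core_mo = p["NifH"] and p["NifD"] and p["NifK"] and p["NifB"]
    full_mo = core_mo and p["NifE"] and p["NifN"]
    incomplete = core_mo and not full_mo
    has_fe = p["AnfD"] and p["AnfK"] and p["AnfG"] and has_h
    has_v = p["VnfD"] and p["VnfK"] and p["VnfG"] and has_h
    return SuiteClassification(
        genome_id=suite.genome_id,
        has_Mo=full_mo or incomplete,
        has_Fe_only=has_fe,
        has_V=has_v,
        incomplete_nif_flag=incomplete,
        bch_confounded=frozenset(suite.bch_confounded),
    )


def screen_proteome(
    proteome: list[tuple[str, str]],
    queries: dict[str, str],
    evalue_max: float = DEFAULT_EVALUE_MAX,
    genome_id: str = "genome",
) -> GeneSuite:
    """Best-hit screen of a proteome against nitrogenase and Bch queries.

    ``proteome`` is a list of (protein_id, sequence); ``queries`` maps
    gene names from the fixed vocabulary to query protein sequences.  A
    proteome protein is credited to the query gene with its best (lowest)
    E-value; hits to nitrogenase queries from proteins whose best hit is
    a Bch query are rejected and recorded in ``bch_confounded``.
    """
    if not queries:
        raise ScreenError("empty query set")
    unknown = set(queries) - set(GENE_VOCABULARY)
    if unknown:
        raise ScreenError(f"unknown query genes: {sorted(unknown)}")
    if not proteome:
        raise ScreenError("empty proteome")

    aligner = align.protein_aligner()
    total_n = sum(len(s) for _, s in proteome)
    best_per_gene: dict[str, float] = {}
    confounded: set[str] = set()
    for _pid, seq in proteome:
        hits = {}
        for gene, qseq in queries.items():
            score = aligner.score(align._sanitize_protein(qseq),
                                  align._sanitize_protein(seq))
            hits[gene] = align.evalue(score, len(qseq), total_n, protein=True)
        best_gene = min(hits, key=lambda g: (hits[g], g))
        if best_gene in BCH_GENES:
            confounded.update(
                g for g in NITROGENASE_GENES if g in hits and hits[g] <= evalue_max
            )
            continue
        if hits[best_gene] < best_per_gene.get(best_gene, float("inf")):
            best_per_gene[best_gene] = hits[best_gene]
    evalues = {g: e for g, e in best_per_gene.items() if e <= evalue_max}
    return GeneSuite(genome_id=genome_id, evalues=evalues, bch_confounded=confounded)


def nearest_reference_isozyme(
    query_protein: str, refs: list[tuple[str, str, str]]
) -> tuple[str, float]:
    """Assign an alpha-subunit protein to the isozyme of its nearest
    labeled reference.

    ``refs`` is a list of (ref_id, label, protein).  Distance is the
    normalized global edit distance; returns (label, margin) where margin
    is the gap to the nearest reference of any other label.  An exact tie
    returns label "ambiguous".
    """
    if not refs:
        raise ScreenError("empty reference set")
    dists: dict[str, float] = {}
    for _rid, label, prot in refs:
        d = align.edit_distance(query_protein, prot) / max(
            len(query_protein), len(prot), 1
        )
        dists[label] = min(dists.get(label, float("inf")), d)
    ordered = sorted(dists.items(), key=lambda kv: (kv[1], kv[0]))
    if len(ordered) == 1:
        return ordered[0][0], float("inf")
    (lab1, d1), (_lab2, d2) = ordered[0], ordered[1]
    if d1 == d2:
        return "ambiguous", 0.0
    return lab1, float(d2 - d1)
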