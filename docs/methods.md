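# Methods

This note documents the models, parameter choices, and numerical
conventions behind `nifdiv`, and what the synthetic-data generator does
and does not emulate.

## Synthetic references and reads

The generator produces, per isozyme (*nifD*, *anfD*, *vnfD*), a random
1401 bp "ancestor" gene that is stop-free in its coding frame under the
bacterial/archaeal genetic code (table 11) and carries exact binding
sites for the published nested primer pairs at their literal
coordinates: the forward site starting at position 820 (*nifD*) or 548
(*anf/vnfD*) and reverse sites ending at 1331/1389 and 1291/1337. With
the convention that a reverse primer's coordinate is the 3'-most
template position of its binding site, nested in-silico PCR yields the
512 bp and 744 bp products those coordinates imply. Each *anfD/vnfD*
ancestor additionally carries the 13-codon cofactor-ligand window
('--V--CAR---Y') inside the 458 bp trim window of its amplicon.

Because 548 is not congruent to 1 modulo 3, a single reading frame
cannot start at reference position 1 and keep the forward primer
in-frame; each reference therefore records an explicit coding-frame
offset (0 for *nifD*, 1 for *anf/vnfD*), and amplicons remain
codon-aligned at the forward primer. Downstream translation of amplicon
reads always uses frame 1 relative to the read start, matching
in-frame primer design.

References within an isozyme are derived from the ancestor by replacing
exactly 30 unprotected codons with random non-stop codons. This bounds
same-isozyme pairwise divergence at 12.9% (≤ 15% by construction,
typically ~9%) while keeping distinct references > 3% apart, so they
fall into separate OTUs at the 97% level. Independent random ancestors
put different isozymes ≥ 30% apart (typically ~70%). Primer sites and
the five anchored motif codons are protected from mutation; the eight
free motif codons may vary, which is what gives the position-frequency
matrix non-trivial columns.

The internal standard is a 600 bp random sequence with GC fraction held
in 0.58–0.62 and verified to contain no primer sites; it emulates the
synthetic spike-in used to measure error-driven OTU inflation, at a
default target of 1% of reads.

Read simulation draws, per read: substitution errors (binomial per
base), homopolymer events (each run of ≥ 3 identical bases extends or
contracts by one base with the stated probability — the dominant
long-read consensus error mode), and ambiguity calls (base → N).
Chimeras are single-breakpoint two-parent splices with the breakpoint
uniform in the middle 50% of the amplicon, parents drawn from the same
primer pool (the *anfD/vnfD* amplicons share primers and can recombine;
*nifD* recombines with *nifD*). Default fixture rates — 1% chimeras,
0.5% errors — are choices for realistic consensus-read data, not
measured values. All simulators consume an explicit integer seed and
are byte-identical on rerun.

What the generator does **not** emulate: polymerase-pass/quality-score
structure of raw subreads (consensus reads are generated directly),
phylogenetically realistic sequence evolution (mutations are uniform
over codons), abundance-skewed communities (compositions are supplied
by the caller), and PCR amplification bias. Passing tests therefore
demonstrate correctness of the algorithms under controlled error
models, not performance on any particular real library.

## QC cascade

Stage order and thresholds: length > 450 bp (strict), translated
homology screen at E ≤ 1e-5, homopolymer runs > 10 and ambiguous bases
> 0 discarded, reference-based bimera removal, stop-codon screen,
alignment-trim to 458 bp. Conservation holds at every stage (input =
kept + discarded + routed-to-control), and the cascade is idempotent on
its own clean output.

E-values use the Karlin–Altschul formula E = K·m·n·exp(−λS) with the
standard gapped constants for the scoring systems employed: BLOSUM62
with gap open/extend 11/1 (λ = 0.267, K = 0.041) for six-frame protein
searches, and +2/−3 with gaps 5/2 (λ = 0.625, K = 0.41) for the
nucleotide rescue of internal-standard reads into the control stream.
The search space is query length × total subject length. Reads failing
the protein screen but matching the internal-standard DNA at the same
E-value cutoff are routed to the control stream rather than discarded.

Bimera detection follows the two-parent model: per read, per-position
match profiles against every reference amplicon (infix alignment) are
combined over all ordered parent pairs and breakpoints; a read is
flagged only when the best two-parent identity *strictly* exceeds the
best single-parent identity, both segments are ≥ 100 bp, and the
parents are ≥ 5% divergent. The strict inequality makes noise-free
single-parent reads unflaggable, which is why the false-flag rate on
clean fixtures is 0; recall on constructed chimeras with ≥ 10%
divergent parents is 1.0 in the test fixtures. Defaults (0.05, 100 bp)
are configuration, chosen to mimic reference-based chimera detectors.

Trimming projects each read, via an infix edit-distance alignment, onto
the 458 bp window of its nearest reference that starts immediately
after the forward primer (a codon boundary). Reads not covering the
window, or carrying a deletion inside it, are discarded; survivors are
ungapped 458-mers, so 458 refers to ungapped length. Insertions
relative to the reference are dropped in projection.

## Diversity statistics

Average-neighbor clustering is agglomerative average linkage
(Lance–Williams update) stopped when the minimum average inter-cluster
distance exceeds the cutoff; tied merges take the pair whose smallest
member ids sort lexicographically least, and an OTU is labeled by its
smallest member id, making results order-independent. Distances are
mismatch fractions over positions where neither sequence is gapped.
The implementation is checked against a brute-force enumeration of all
tie-breaking merge orders on inputs of up to six sequences.

Shannon is −Σ p ln p in nats (magnitudes printed for hundreds of OTUs,
≤ ~4.5, are consistent with natural logs). Chao1 is the bias-corrected
form S_obs + n1(n1−1)/(2(n2+1)); its SE uses the classical variance
n2(r²/2 + r³ + r⁴/4), r = n1/n2, with the standard n2 = 0 limit form.
Rarefaction is the exact hypergeometric expectation (log-gamma
evaluation), validated against Monte-Carlo subsampling; even resampling
is a multivariate hypergeometric draw, dropping pools shallower than
the target depth (100 by default).

Percent shares per isozyme use half-away-from-zero rounding, except
that shares strictly below 1% are reported as "<1" — the convention
that reproduces every printed percentage column of the reference
diversity table, including a 0.62% entry shown as "<1" (plain rounding
would print 1).

The spurious-OTU rate clusters internal-standard control reads with the
same distance/clustering machinery but skips reference-based chimera
removal and the translation requirement (the standard is non-coding);
spurious OTUs = max(0, OTUs − 1), reported per clustered read.

## ISARA mixing model

ε_AR is computed per replicate and averaged; its SE is the sample
SD/√n. The mixing fraction f = (ε_Mo − ε_AR)/(ε_Mo − ε_alt) is clamped
to [0, 1], with a warning when the unclamped value falls outside
[−0.05, 1.05] (small overshoots are measurement noise; large ones
indicate inconsistent endmembers). Because ε_Fe < ε_V, the Fe-only
assumption yields the smaller f for any ε_AR between the endmembers —
the conservative lower bound. Three-endmember unmixing is
underdetermined with a single tracer and is not attempted.

Uncertainty propagation draws ε_AR and both endmembers from independent
Gaussians at their stated SEs (default 10,000 draws, seeded) and
reports the mean and central 95% interval of the clamped fractions.
SE = 0 degenerates to the point value, so the all-SEs-zero limit
collapses the interval. A 500-replicate simulation in the test suite —
true endmembers perturbed at their SEs, replicate noise at 0.3‰, the
known measurement SD supplied as the ε_AR SE — shows 95.4% empirical
coverage of the true fraction.

ARA rates are OLS slopes over the first three time points of the
ethylene time course (later points can leave the linear range as
acetylene or activity declines); the point count is configurable.

## Genome screening

Gene presence uses best-hit logic at E ≤ 1e-20: each proteome protein
is credited to the single query gene with its lowest E-value, and
proteins whose best hit is a BchL/N/X/Y query are excluded from
nitrogenase credit (recorded as confounded). The same 1e-20 threshold
applies to the per-gene confirmation searches and is exposed as
configuration. Classification is a pure boolean function of the suite:
Mo requires NifHDKB plus NifE and NifN, with genomes missing only
NifE/NifN keeping Mo status under an incomplete-Nif flag; missing NifB
revokes Mo outright. Fe-only/V require Anf/VnfDKG plus at least one H
protein of any system, since H genes are not isozyme-diagnostic. The
classifier is validated exhaustively over all 2^14 presence patterns of
the nitrogenase vocabulary.

Phylogenetic placement of α-subunit sequences is replaced by
nearest-reference assignment: normalized global edit distance to
labeled NifD/AnfD/VnfD references, returning the nearest label with the
margin to the nearest other-label reference (ties → "ambiguous"). Tree
building and placement are delegated to external tools and out of
scope, as are live database searches.

## Problem sizes in the test suite

The suite exercises the pipeline at desk scale: reference panels of 2–3
sequences per isozyme, read sets of tens to a few thousand reads
(largest: 10,000 reads for the spike-in fraction check), 10,000-rep
Monte-Carlo comparisons for rarefaction and the ARA slope, 500
replicate experiments for interval coverage, and the full 16,384-case
classifier enumeration. These sizes were chosen so each statistical
check has enough power (3-SD binomial/SE bands) while the whole suite
runs in well under a minute.
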