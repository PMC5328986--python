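"""OTU clustering and alpha-diversity statistics.

Sequences are clustered by average-neighbor (UPGMA-style agglomerative)
clustering at a distance cutoff (0.03 for the 97% level), and each pool
is summarized with the observed richness S_obs, the bias-corrected Chao1
estimator with its classical standard error, and the Shannon index in
natural-log units.  Rarefaction uses the exact hypergeometric
expectation rather than resampling; even resampling across pools is a
without-replacement multivariate hypergeometric draw.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.special import gammaln


class DiversityError(ValueError):
    pass


@dataclass
class DistanceMatrix:
    ids: list[str]
    d: np.ndarray  # symmetric, zero diagonal, entries in [0, 1]

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.ids)
        if self.d.shape != (n, n):
            raise DiversityError("matrix shape does not match ids")
        if not np.allclose(self.d, self.d.T) or np.any(np.diag(self.d) != 0):
            raise DiversityError("matrix must be symmetric with zero diagonal")
        if n and (self.d.min() < 0 or self.d.max() > 1):
            raise DiversityError("distances must lie in [0, 1]")


@dataclass(frozen=True)
class DiversityResult:
    S_obs: int
    chao1: float
    chao1_se: float
    shannon: float  # nats
    n: int  # sampling depth
    n1: int  # singletons
    n2: int  # doubletons


def pairwise_distances(ids: list[str], seqs: list[str]) -> DistanceMatrix:
    """Mismatch fraction over positions where neither sequence has a gap;
    pairs sharing no ungapped position get distance 1."""
    if len(set(map(len, seqs))) > 1:
        raise DiversityError("sequences must have equal (aligned) length")
    arr = np.array([list(s.upper()) for s in seqs])
    gap = (arr == "-") | (arr == ".")
    n = len(seqs)
    d = np.zeros((n, n))
    for i in range(n):
        ok = ~gap[i] & ~gap[i + 1 :]
        comp = (arr[i] != arr[i + 1 :]) & ok
        denom = ok.sum(axis=1)
        with np.errstate(invalid="ignore"):
            row = np.where(denom > 0, comp.sum(axis=1) / np.maximum(denom, 1), 1.0)
        d[i, i + 1 :] = row
        d[i + 1 :, i] = row
    return DistanceMatrix(list(ids), d)


def cluster_average_neighbor(dm: DistanceMatrix, cutoff: float) -> dict[str, str]:
    """Average-linkage agglomerative clustering stopped when the minimum
    average inter-cluster distance exceeds ``cutoff``.

    Tied merges pick the pair whose smallest member ids are
    lexicographically least.  Each sequence maps to an OTU labeled by the
    lexicographically smallest member id of its cluster.
    """
    if not 0.0 <= cutoff <= 1.0:
        raise DiversityError("cutoff must be in [0, 1]")
    n = len(dm.ids)
    if n == 0:
        return {}
    d = dm.d.astype(float).copy()
    np.fill_diagonal(d, np.inf)
    members: dict[int, list[str]] = {i: [dm.ids[i]] for i in range(n)}
    minid = {i: dm.ids[i] for i in range(n)}
    sizes = np.ones(n)
    active = set(range(n))
    while len(active) > 1:
        dmin = d.min()
        if not np.isfinite(dmin) or dmin > cutoff:
            break
        # among ties, merge the pair whose smallest member ids sort least
        ti, tj = np.nonzero(d <= dmin + 1e-12)
        best = min(
            (tuple(sorted((minid[i], minid[j]))), i, j)
            for i, j in zip(ti.tolist(), tj.tolist())
            if i < j
        )
        _, i, j = best
        # Lance-Williams average-linkage update into slot i
        new = (sizes[i] * d[i] + sizes[j] * d[j]) / (sizes[i] + sizes[j])
        d[i, :] = d[:, i] = new
        d[i, i] = np.inf
        d[j, :] = d[:, j] = np.inf
        members[i] += members[j]
        minid[i] = min(minid[i], minid[j])
        sizes[i] += sizes[j]
        active.discard(j)
    out = {}
    for i in active:
        label = minid[i]
        for sid in members[i]:
            out[sid] = label
    return out


def shannon_index(counts) -> float:
    """H = -sum p_i ln p_i over nonzero abundances (nats)."""
    c = np.asarray([x for x in counts if x > 0], dtype=float)
    if c.size == 0:
        raise DiversityError("all-zero abundance vector")
    p = c / c.sum()
    return float(-(p * np.log(p)).sum())


def chao1_index(counts) -> tuple[float, float]:
    """Bias-corrected Chao1 with its classical variance-based SE.

    chao1 = S_obs + n1(n1-1)/(2(n2+1)).  For n2 > 0 the variance is
    n2 * (r^2/2 + r^3 + r^4/4) with r = n1/n2; for n2 = 0 the limit form
    n1(n1-1)/2 + n1(2n1-1)^2/4 - n1^4/(4*chao1) is used.
    """
    c = np.asarray([x for x in counts if x > 0])
    s_obs = len(c)
    if s_obs == 0:
        raise DiversityError("all-zero abundance vector")
    n1 = int((c == 1).sum())
    n2 = int((c == 2).sum())
    chao1 = s_obs + n1 * (n1 - 1) / (2.0 * (n2 + 1))
    if n1 == 0:
        var = 0.0
    elif n2 > 0:
        r = n1 / n2
        var = n2 * (r**2 / 2 + r**3 + r**4 / 4)
    else:
        var = n1 * (n1 - 1) / 2 + n1 * (2 * n1 - 1) ** 2 / 4 - n1**4 / (4 * chao1)
    return float(chao1), float(math.sqrt(max(var, 0.0)))


def diversity_result(counts) -> DiversityResult:
    c = np.asarray([x for x in counts if x > 0])
    chao1, se = chao1_index(c)
    return DiversityResult(
        S_obs=len(c),
        chao1=chao1,
        chao1_se=se,
        shannon=shannon_index(c),
        n=int(c.sum()),
        n1=int((c == 1).sum()),
        n2=int((c == 2).sum()),
    )


def rarefaction_expected(counts, depths) -> list[float]:
    """Exact expected richness E[S_d] = sum_i 1 - C(N-N_i, d)/C(N, d)."""
    c = np.asarray([x for x in counts if x > 0], dtype=int)
    N = int(c.sum())
    out = []
    for d in depths:
        if d > N:
            raise DiversityError(f"depth {d} exceeds total count {N}")
        if d < 0:
            raise DiversityError("depth must be >= 0")
        # log C(N-Ni, d) - log C(N, d), with C(N-Ni, d) = 0 when d > N-Ni
        terms = np.zeros(len(c))
        for i, ni in enumerate(c):
            if d > N - ni:
                terms[i] = 1.0
            else:
                logp = (
                    gammaln(N - ni + 1) - gammaln(d + 1) - gammaln(N - ni - d + 1)
                    - (gammaln(N + 1) - gammaln(d + 1) - gammaln(N - d + 1))
                )
                terms[i] = 1.0 - math.exp(logp)
        out.append(float(terms.sum()))
    return out


def otu_table(assignments: dict[str, dict[str, str]], cutoff: float) -> pd.DataFrame:
    """Build a pools x OTUs count table from per-pool assignment maps
    (pool label -> {sequence id -> OTU label})."""
    rows = {}
    for pool, assign in assignments.items():
        counts: dict[str, int] = {}
        for otu in assign.values():
            counts[otu] = counts.get(otu, 0) + 1
        rows[pool] = counts
    table = pd.DataFrame(rows).T.fillna(0).astype(int)
    table = table.loc[:, (table.sum(axis=0) > 0)]
    table.attrs["cutoff"] = cutoff
    return table.sort_index(axis=1)


def resample_table(
    table: pd.DataFrame, depth: int, seed: int
) -> tuple[pd.DataFrame, list[str]]:
    """Subsample each pool to exactly ``depth`` sequences without
    replacement; pools with fewer sequences are dropped and reported."""
    if depth <= 0:
        raise DiversityError("depth must be > 0")
    rng = np.random.default_rng(seed)
    kept_rows, dropped = {}, []
    for pool, row in table.iterrows():
        total = int(row.sum())
        if total < depth:
            dropped.append(str(pool))
            continue
        counts = row.to_numpy(dtype=int)
        kept_rows[pool] = rng.multivariate_hypergeometric(counts, depth)
    out = pd.DataFrame(kept_rows, index=table.columns).T
    if not out.empty:
        out = out.loc[:, out.sum(axis=0) > 0]
    out.attrs["cutoff"] = table.attrs.get("cutoff")
    return out, dropped


def site_overlap(site_otus: dict[str, set[str]]) -> dict[str, int]:
    """Venn-region OTU counts for two or three sites clustered jointly."""
    sites = sorted(site_otus)
    if not 2 <= len(sites) <= 3:
        raise DiversityError("site_overlap supports exactly 2 or 3 sites")
    regions = {}
    for k in range(1, len(sites) + 1):
        for combo in combinations(sites, k):
            inside = set.intersection(*(site_otus[s] for s in combo))
            outside = set.union(
                set(), *(site_otus[s] for s in sites if s not in combo)
            )
            regions["&".join(combo)] = len(inside - outside)
    return regions


def isozyme_share_percent(values: dict[str, float]) -> dict[str, int | str]:
    """Integer percent share per gene; genes whose share is below 1% are
    reported as "<1" and the rest use half-away-from-zero rounding."""
    if any(v < 0 for v in values.values()):
        raise DiversityError("values must be >= 0")
    total = sum(values.values())
    if total <= 0:
        raise DiversityError("at least one value must be > 0")
    out: dict[str, int | str] = {}
    for gene, v in values.items():
        pct = 100.0 * v / total
        if 0 < pct < 1:
            out[gene] = "<1"
        else:
            out[gene] = int(math.floor(pct + 0.5))  # half away from zero (pct >= 0)
    return out


def spurious_otu_rate(
    control_reads,
    internal_standard_dna: str,
    cutoff: float = 0.03,
    max_homopolymer: int = 10,
    max_ambiguous: int = 0,
) -> dict:
    """Cluster internal-standard control reads and report the error-driven
    OTU excess.

    Reference-based chimera removal and the translation requirement are
    skipped (the standard is non-coding and has no external reference
    alignment); reads are homopolymer/ambiguity-filtered, projected onto
    the standard, and clustered at ``cutoff``.  Spurious OTUs =
    max(0, OTUs - 1); the rate is per clustered read.
    """
    from . import align
    from .qc import filter_homopolymers_and_ambiguities

    if not control_reads:
        raise DiversityError("empty control read set: spurious rate undefined")
    kept, _ = filter_homopolymers_and_ambiguities(
        control_reads, max_homopolymer, max_ambiguous
    )
    ids, seqs = [], []
    for r in kept:
        proj = align.project_onto_reference(r.dna, internal_standard_dna)
        if "-" not in proj:
            ids.append(r.id)
            seqs.append(proj)
    if not ids:
        raise DiversityError("no control reads survived projection")
    assign = cluster_average_neighbor(pairwise_distances(ids, seqs), cutoff)
    n_otus = len(set(assign.values()))
    return {
        "otus_observed": n_otus,
        "n_reads": len(ids),
        "spurious_per_read": max(0, n_otus - 1) / len(ids),
    }
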