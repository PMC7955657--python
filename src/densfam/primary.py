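"""First round of density-peak clustering: alignments on one query.

Alignments of a query sequence are compared through the interval-overlap
(Jaccard) distance between their query regions,

    d(Q_i, Q_j) = 1 - |Q_i ∩ Q_j| / |Q_i ∪ Q_j|,

where |.| counts residues.  The local density rho_i of an alignment is the
number of alignments of the same query within mu1 of it (self included);
delta_i is the distance to the nearest denser alignment (density ties
broken by input order; 1 for the density maximum), and peaks are chosen by
scanning the sorted product
gamma_i = rho_i * delta_i for a multiplicative gap of 10**delta_exp.
Every other alignment is assigned to its nearest peak when closer than mu1,
or discarded.  The resulting clusters approximate the domain-like regions
of the query.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from densfam.alignments import Alignment, QueryAlignmentSet, Region


@dataclass(frozen=True, slots=True)
class PrimaryClusteringParams:
    """Tunable parameters of the per-query clustering round.

    mu1
        Neighbourhood radius for the density estimate and the assignment
        cutoff, in units of the [0,1] overlap distance.  0.2 keeps, on
        typical alignment sets, the average neighbourhood at roughly 1-2%
        of the points.
    delta_exp
        The gap exponent: two consecutive sorted gamma values separated by
        a factor >= 10**delta_exp mark a candidate peak/non-peak boundary.
    g_max
        Maximum number of peaks allowed per query; the gamma-gap scan is
        restricted to gap indices <= g_max.
    """

    mu1: float = 0.2
    delta_exp: float = 0.5
    g_max: int = 20

    def __post_init__(self) -> None:
        if not 0 < self.mu1 < 1:
            raise ValueError(f"mu1 must be in (0,1), got {self.mu1}")
        if self.delta_exp <= 0:
            raise ValueError(f"delta_exp must be > 0, got {self.delta_exp}")
        if self.g_max < 1:
            raise ValueError(f"g_max must be >= 1, got {self.g_max}")


@dataclass(frozen=True, slots=True)
class ScoredAlignment:
    """An alignment annotated with its DPC scores rho, delta and gamma."""

    alignment: Alignment
    rho: int
    delta: float = float("nan")
    index: int = -1  # position in the input set, used for deterministic ties

    @property
    def gamma(self) -> float:
        return self.rho * self.delta


@dataclass(slots=True)
class PrimaryCluster:
    """A density peak and the alignments assigned to it on one query."""

    cluster_id: str
    query_id: str
    peak: Alignment
    members: list[Alignment] = field(default_factory=list)

    @property
    def n_c(self) -> int:
        return len(self.members)


def region_distance(a: Region, b: Region) -> float:
    """Interval-overlap distance between two regions of the same sequence.

    Returns ``1 - |a ∩ b| / |a ∪ b|`` with residue counts: 0 iff the two
    intervals are identical, 1 iff they are disjoint.  The union counts
    only residues inside either interval, never the gap between them,
    which makes the distance a metric.
    """
    if a.seq_id != b.seq_id:
        raise ValueError(
            f"regions on different sequences: {a.seq_id!r} vs {b.seq_id!r}"
        )
    inter = a.intersection_length(b)
    return 1.0 - inter / (a.length + b.length - inter)


def _distance_matrix(regions: list[Region]) -> np.ndarray:
    """Pairwise interval-overlap distances for co-sequential regions."""
    starts = np.array([r.start for r in regions], dtype=np.int64)
    ends = np.array([r.end for r in regions], dtype=np.int64)
    inter = np.minimum(ends[:, None], ends[None, :]) - np.maximum(
        starts[:, None], starts[None, :]
    ) + 1
    np.clip(inter, 0, None, out=inter)
    lengths = ends - starts + 1
    union = lengths[:, None] + lengths[None, :] - inter
    return 1.0 - inter / union


def local_densities(
    qset: QueryAlignmentSet, params: PrimaryClusteringParams
) -> list[ScoredAlignment]:
    """Count, for each alignment, the alignments within mu1 of it.

    The count includes the alignment itself, so rho >= 1 and isolated
    alignments still have a well-defined gamma.
    """
    if len(qset) == 0:
        raise ValueError("empty query alignment set")
    dist = _distance_matrix([a.query_region for a in qset.alignments])
    rho = (dist < params.mu1).sum(axis=1)
    return [
        ScoredAlignment(alignment=a, rho=int(rho[i]), index=i)
        for i, a in enumerate(qset.alignments)
    ]


def _deltas(dist: np.ndarray, rho: np.ndarray) -> np.ndarray:
    """delta_i = min distance to a denser point; 1 at the density maximum.

    Densities are integer counts, so ties are pervasive; they are broken
    by input order: point i measures its delta against points of strictly
    higher density *and* against earlier points of equal density.  Exactly
    one point — the lowest-index global density maximum — ends up with no
    reference point and takes delta = 1, the distance maximum.  Without
    the equal-density term, every member of a co-located plateau would
    inherit delta = 1 and masquerade as a peak.
    """
    n = len(rho)
    idx = np.arange(n)
    delta = np.empty(n, dtype=float)
    for i in range(n):
        cand = (rho > rho[i]) | ((rho == rho[i]) & (idx < i))
        delta[i] = dist[i, cand].min() if cand.any() else 1.0
    return delta


def gamma_ranking(
    scored: list[ScoredAlignment], params: PrimaryClusteringParams | None = None
) -> list[ScoredAlignment]:
    """Fill delta and gamma, and sort by decreasing gamma.

    Ties in gamma are broken by input order so the ranking is deterministic.
    """
    if not scored:
        return []
    regions = [s.alignment.query_region for s in scored]
    dist = _distance_matrix(regions)
    rho = np.array([s.rho for s in scored], dtype=np.int64)
    delta = _deltas(dist, rho)
    filled = [
        ScoredAlignment(alignment=s.alignment, rho=s.rho, delta=float(delta[i]),
                        index=s.index)
        for i, s in enumerate(scored)
    ]
    return sorted(filled, key=lambda s: (-s.gamma, s.index))


def select_gap_peaks(
    ranked: list[ScoredAlignment], params: PrimaryClusteringParams
) -> list[Alignment]:
    """Pick peaks by the largest trailing multiplicative gap in gamma.

    With Gamma = (gamma_1 >= gamma_2 >= ...), zero entries removed, the scan
    looks for the largest 1-based index g <= g_max such that
    gamma_{g-1}/gamma_g >= 10**delta_exp while every later consecutive ratio
    stays below the threshold.  The g-1 alignments above the gap become
    peaks.  If no index qualifies, no peaks are returned and the caller
    skips the query.
    """
    gammas = [s for s in ranked if s.gamma > 0]
    if not gammas:
        return []
    if len(gammas) == 1:
        # the gap between the lone positive gamma and the dropped zero
        # entries is effectively infinite: the entry is the single peak
        # (degenerate but common when many alignments are co-located)
        return [gammas[0].alignment]
    thresh = 10.0 ** params.delta_exp
    ratios = [gammas[i - 1].gamma / gammas[i].gamma for i in range(1, len(gammas))]
    # ratios[k] corresponds to gap index g = k + 2 (1-based positions)
    g = None
    for k in range(len(ratios) - 1, -1, -1):
        if ratios[k] >= thresh:
            g = k + 2
            break
    if g is None or g > params.g_max:
        return []
    n_peaks = min(g - 1, params.g_max)
    return [s.alignment for s in gammas[:n_peaks]]


def assign_primary(
    qset: QueryAlignmentSet,
    peaks: list[Alignment],
    params: PrimaryClusteringParams,
) -> list[PrimaryCluster]:
    """Assign each alignment to its nearest peak when closer than mu1.

    Alignments at distance >= mu1 from every peak are discarded.  When an
    alignment is equidistant from several peaks the higher-ranked peak
    (earlier in *peaks*, i.e. higher gamma) wins.  Cluster ids are
    ``<query_id>/p<rank>``.
    """
    clusters = [
        PrimaryCluster(
            cluster_id=f"{qset.query_id}/p{rank}",
            query_id=qset.query_id,
            peak=peak,
        )
        for rank, peak in enumerate(peaks)
    ]
    if not clusters:
        return []
    peak_rank = {id(p): rank for rank, p in enumerate(peaks)}
    for aln in qset.alignments:
        rank = peak_rank.get(id(aln))
        if rank is not None:
            # a peak always belongs to its own cluster, even when another
            # peak happens to sit at distance 0
            clusters[rank].members.append(aln)
            continue
        best_rank, best_d = -1, np.inf
        for rank, peak in enumerate(peaks):
            d = region_distance(aln.query_region, peak.query_region)
            if d < best_d:  # strict: earlier (higher-gamma) peak wins ties
                best_rank, best_d = rank, d
        if best_d < params.mu1:
            clusters[best_rank].members.append(aln)
    return clusters


def cluster_query(
    qset: QueryAlignmentSet, params: PrimaryClusteringParams | None = None
) -> list[PrimaryCluster]:
    """Run the full per-query round: densities, ranking, gap scan, assignment.

    Returns an empty list for queries whose gamma sequence shows no
    qualifying gap (such queries contribute no primary clusters).
    """
    params = params or PrimaryClusteringParams()
    if len(qset) == 0:
        return []
    ranked = gamma_ranking(local_densities(qset, params), params)
    peaks = select_gap_peaks(ranked, params)
    return assign_primary(qset, peaks, params)
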