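"""Second round of density-peak clustering: primary clusters into families.

Two primary clusters — possibly from different query sequences — are close
when many of their alignments land on the same search sequences, on
overlapping regions.  The distance is

    D(c, c0) = 1 - M / min(N_c, N_c0)

where M counts one-to-one matched alignment pairs (m in c, n in c0) with
the same search sequence and search-region overlap distance < mu_d.  The
matching is a maximum bipartite matching over qualifying pairs, which keeps
D within [0,1] even when several regions of one cluster overlap a single
region of the other.  Density peaks must be mutually non-overlapping
(delta_c = 1) and supported by more than one neighbouring cluster
(rho_c > 1); assigned clusters form metaclusters, which are then merged
when their average cross-cluster distance falls below a threshold, and
finally pruned of member regions with no same-sequence partner.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import maximum_bipartite_matching

from densfam.alignments import Alignment, Region
from densfam.primary import PrimaryCluster, _deltas, _distance_matrix, region_distance

logger = logging.getLogger("densfam")


@dataclass(frozen=True, slots=True)
class MetaclusteringParams:
    """Parameters of the cross-query clustering round.

    mu_d
        Overlap cutoff on *search*-sequence regions: two alignments on the
        same search sequence are "shared" when their regions are closer
        than mu_d.  Chosen coherently with the primary-round mu1.
    mu2
        Assignment/density cutoff in the primary-cluster distance space.
    merge_threshold
        Metacluster pairs whose average cross distance is below this are
        merged (transitively).
    min_size
        Metaclusters with fewer member regions after filtering are dropped:
        a family hypothesis needs enough support to stand out from noise.
    member_cap, seed_cap
        Random subsample sizes for reporting members and for seed-set
        export, respectively.
    member_identity, seed_identity
        Pairwise-identity levels of the greedy redundancy reduction applied
        (when sequences are available) before capping members and before
        exporting seeds.
    printed_merge_factor
        The merge distance is implemented as the plain mean of cross-pair
        distances; this flag doubles it (an alternative reading of the
        normalisation, see docs/methods.md).
    """

    mu_d: float = 0.2
    mu2: float = 0.9
    merge_threshold: float = 0.9
    min_size: int = 100
    member_cap: int = 5000
    seed_identity: float = 0.60
    member_identity: float = 0.95
    seed_cap: int = 1000
    rng_seed: int = 0
    printed_merge_factor: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.mu_d < 1:
            raise ValueError(f"mu_d must be in (0,1), got {self.mu_d}")
        if not 0 < self.mu2 <= 1:
            raise ValueError(f"mu2 must be in (0,1], got {self.mu2}")
        if not 0 < self.merge_threshold <= 1:
            raise ValueError(
                f"merge_threshold must be in (0,1], got {self.merge_threshold}"
            )
        if self.min_size < 1 or self.member_cap < 1 or self.seed_cap < 1:
            raise ValueError("min_size and caps must be positive")


@dataclass(frozen=True, slots=True)
class MCMember:
    """A search-sequence region belonging to a metacluster, with provenance."""

    region: Region
    alignment: Alignment
    source_cluster_id: str

    @property
    def seq_id(self) -> str:
        return self.region.seq_id


@dataclass(slots=True)
class Metacluster:
    """A set of primary clusters grouped across queries: a putative family."""

    mc_id: str
    primary_clusters: list[PrimaryCluster]
    members: list[MCMember] = field(default_factory=list)
    rho_c: int = 0
    delta_c: float = 0.0

    @property
    def n_mc(self) -> int:
        """Number of primary clusters."""
        return len(self.primary_clusters)

    @property
    def size(self) -> int:
        """Number of member regions."""
        return len(self.members)


def _members_of(clusters: Iterable[PrimaryCluster]) -> list[MCMember]:
    return [
        MCMember(region=aln.search_region, alignment=aln,
                 source_cluster_id=pc.cluster_id)
        for pc in clusters
        for aln in pc.members
    ]


def _matching_size(qualify: np.ndarray) -> int:
    """Maximum bipartite matching size over a boolean incidence matrix."""
    if not qualify.any():
        return 0
    if 1 in qualify.shape:
        return 1
    match = maximum_bipartite_matching(csr_matrix(qualify), perm_type="column")
    return int((match != -1).sum())


def primary_cluster_distance(
    c: PrimaryCluster, c0: PrimaryCluster, mu_d: float = 0.2
) -> float:
    """Shared-search-region distance between two primary clusters.

    Qualifying pairs (same search sequence, region distance < mu_d) are
    matched one-to-one; each alignment contributes to at most one counted
    pair, so the count never exceeds min(N_c, N_c0).  The matching problem
    decomposes over search sequences because pairs never cross sequences.
    """
    if c.n_c == 0 or c0.n_c == 0:
        raise ValueError("primary clusters must be nonempty")
    by_seq: dict[str, list[Region]] = {}
    for aln in c.members:
        by_seq.setdefault(aln.search_id, []).append(aln.search_region)
    matched = 0
    seen: dict[str, list[Region]] = {}
    for aln in c0.members:
        seen.setdefault(aln.search_id, []).append(aln.search_region)
    for seq_id, regions0 in seen.items():
        regions = by_seq.get(seq_id)
        if not regions:
            continue
        qualify = np.array(
            [[region_distance(r, r0) < mu_d for r0 in regions0] for r in regions]
        )
        matched += _matching_size(qualify)
    d = 1.0 - matched / min(c.n_c, c0.n_c)
    return min(max(d, 0.0), 1.0)


def primary_cluster_distance_matrix(
    clusters: Sequence[PrimaryCluster], mu_d: float = 0.2
) -> np.ndarray:
    """All pairwise primary-cluster distances, via a search-sequence index.

    Equivalent to calling :func:`primary_cluster_distance` on every pair
    but orders of magnitude faster: qualifying pairs are enumerated per
    search sequence, and matched counts are scattered into a shared-pair
    matrix.  Search sequences on which every involved cluster has a single
    region (the overwhelmingly common case) need no explicit matching.
    """
    n = len(clusters)
    shared = np.zeros((n, n), dtype=np.int64)
    index: dict[str, list[tuple[int, Region]]] = {}
    for ci, pc in enumerate(clusters):
        if pc.n_c == 0:
            raise ValueError(f"empty primary cluster {pc.cluster_id}")
        for aln in pc.members:
            index.setdefault(aln.search_id, []).append((ci, aln.search_region))
    for entries in index.values():
        if len(entries) < 2:
            continue
        ci = np.array([e[0] for e in entries], dtype=np.int64)
        regions = [e[1] for e in entries]
        qualify = _distance_matrix(regions) < mu_d
        counts = np.bincount(ci, minlength=n)
        if counts.max() == 1:
            np.add.at(shared, (ci[:, None], ci[None, :]), qualify)
        else:
            by_cluster: dict[int, list[int]] = {}
            for row, c in enumerate(ci):
                by_cluster.setdefault(int(c), []).append(row)
            keys = sorted(by_cluster)
            for i, a in enumerate(keys):
                rows_a = by_cluster[a]
                for b in keys[i + 1:]:
                    rows_b = by_cluster[b]
                    sub = qualify[np.ix_(rows_a, rows_b)]
                    m = _matching_size(sub)
                    shared[a, b] += m
                    shared[b, a] += m
    sizes = np.array([pc.n_c for pc in clusters], dtype=np.int64)
    dist = 1.0 - shared / np.minimum.outer(sizes, sizes)
    np.clip(dist, 0.0, 1.0, out=dist)
    np.fill_diagonal(dist, 0.0)
    return dist


def metacluster_peaks(
    clusters: Sequence[PrimaryCluster],
    params: MetaclusteringParams,
    dist: np.ndarray | None = None,
) -> tuple[list[PrimaryCluster], np.ndarray, np.ndarray]:
    """Densities, deltas and peaks in primary-cluster space.

    rho_c counts the *other* clusters within mu2 (self excluded, so an
    isolated cluster has rho_c = 0); delta_c is the distance to the nearest
    strictly denser cluster (1 for the global maximum).  Peaks must satisfy
    both delta_c = 1 — peaks may not overlap each other at all — and
    rho_c > 1.  Returns (peaks, rho, delta).
    """
    if len(clusters) == 0:
        raise ValueError("no primary clusters")
    if dist is None:
        dist = primary_cluster_distance_matrix(clusters, params.mu_d)
    within = dist < params.mu2
    rho = within.sum(axis=1) - within.diagonal()  # exclude self
    delta = _deltas(dist, rho)
    peak_mask = (delta >= 1.0 - 1e-12) & (rho > 1)
    peaks = [clusters[i] for i in np.flatnonzero(peak_mask)]
    return peaks, rho, delta


def assign_to_metaclusters(
    clusters: Sequence[PrimaryCluster],
    peaks: Sequence[PrimaryCluster],
    params: MetaclusteringParams,
    dist: np.ndarray | None = None,
) -> list[Metacluster]:
    """Assign each primary cluster to its nearest peak when D < mu2.

    Clusters at distance >= mu2 from every peak are discarded.  Ties go to
    the earlier peak.  Each returned metacluster carries its pooled member
    regions (the search regions of all alignments of its primary clusters).
    """
    if not peaks:
        return []
    if dist is not None:
        by_identity = {id(c): i for i, c in enumerate(clusters)}
        peak_rows = [by_identity[id(p)] for p in peaks]
    assigned: dict[int, list[PrimaryCluster]] = {i: [] for i in range(len(peaks))}
    n_discarded = 0
    for ci, pc in enumerate(clusters):
        best_rank, best_d = -1, np.inf
        for rank, peak in enumerate(peaks):
            if dist is not None:
                d = dist[ci, peak_rows[rank]]
            else:
                d = primary_cluster_distance(pc, peak, params.mu_d)
            if d < best_d:
                best_rank, best_d = rank, d
        if best_d < params.mu2:
            assigned[best_rank].append(pc)
        else:
            n_discarded += 1
    if n_discarded:
        logger.info("discarded %d primary clusters (no peak within mu2)", n_discarded)
    out = []
    for rank in range(len(peaks)):
        pcs = assigned[rank]
        if pcs:
            out.append(
                Metacluster(mc_id=f"MC{rank + 1}", primary_clusters=pcs,
                            members=_members_of(pcs))
            )
    return out


def metacluster_distance(
    a: Metacluster,
    b: Metacluster,
    params: MetaclusteringParams,
    dist_fn: Callable[[PrimaryCluster, PrimaryCluster], float] | None = None,
) -> float:
    """Average primary-cluster distance across two metaclusters.

    With ``printed_merge_factor`` the mean is doubled (and clipped to 1).
    """
    if dist_fn is None:
        dist_fn = lambda c, c0: primary_cluster_distance(c, c0, params.mu_d)
    total = 0.0
    for c in a.primary_clusters:
        for c0 in b.primary_clusters:
            total += dist_fn(c, c0)
    mean = total / (a.n_mc * b.n_mc)
    if params.printed_merge_factor:
        mean = min(2.0 * mean, 1.0)
    return mean


def merge_metaclusters(
    mcs: Sequence[Metacluster],
    params: MetaclusteringParams,
    dist_fn: Callable[[PrimaryCluster, PrimaryCluster], float] | None = None,
) -> list[Metacluster]:
    """Merge metacluster pairs with average cross distance < merge_threshold.

    Merging is transitive: connected components of the below-threshold
    graph are pooled, so the output is a well-defined partition.  Merged
    metaclusters are renumbered MC1, MC2, ... by decreasing member count.
    """
    n = len(mcs)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if metacluster_distance(mcs[i], mcs[j], params, dist_fn) < params.merge_threshold:
                parent[find(i)] = find(j)
    groups: dict[int, list[Metacluster]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(mcs[i])
    pooled = []
    for group in groups.values():
        pcs = [pc for mc in group for pc in mc.primary_clusters]
        pooled.append(Metacluster(mc_id="", primary_clusters=pcs,
                                  members=_members_of(pcs)))
    pooled.sort(key=lambda mc: (-mc.size, mc.primary_clusters[0].cluster_id))
    for k, mc in enumerate(pooled):
        mc.mc_id = f"MC{k + 1}"
    return pooled


def filter_member_regions(mc: Metacluster, params: MetaclusteringParams) -> Metacluster:
    """Drop member regions with no same-sequence partner within mu_d.

    A region survives iff another member region of the same metacluster
    lies on the same search sequence at overlap distance < mu_d.  The
    partner relation is symmetric, so a single pass suffices and every
    retained region keeps a retained partner.
    """
    by_seq: dict[str, list[int]] = {}
    for i, m in enumerate(mc.members):
        by_seq.setdefault(m.seq_id, []).append(i)
    keep = np.zeros(len(mc.members), dtype=bool)
    for idxs in by_seq.values():
        if len(idxs) < 2:
            continue
        d = _distance_matrix([mc.members[i].region for i in idxs])
        np.fill_diagonal(d, 1.0)  # a region is not its own partner
        has_partner = (d < params.mu_d).any(axis=1)
        for local, i in enumerate(idxs):
            keep[i] = has_partner[local]
    return Metacluster(
        mc_id=mc.mc_id,
        primary_clusters=mc.primary_clusters,
        members=[m for i, m in enumerate(mc.members) if keep[i]],
        rho_c=mc.rho_c,
        delta_c=mc.delta_c,
    )


def _mc_rng(params: MetaclusteringParams, mc_id: str) -> np.random.Generator:
    # per-metacluster stream so subsampling one MC is independent of the others
    return np.random.default_rng([params.rng_seed, zlib.crc32(mc_id.encode())])


def _identity(seq_a: str, seq_b: str) -> float:
    """Fraction of the shorter sequence matched in its best alignment to the longer."""
    import edlib

    if not seq_a or not seq_b:
        return 0.0
    short, long_ = (seq_a, seq_b) if len(seq_a) <= len(seq_b) else (seq_b, seq_a)
    ed = edlib.align(short, long_, mode="HW", task="distance")["editDistance"]
    return max(0.0, 1.0 - ed / len(short))


def _region_sequence(region: Region, sequences: Mapping[str, str]) -> str:
    try:
        seq = sequences[region.seq_id]
    except KeyError:
        raise KeyError(
            f"no sequence for member region {region.seq_id}:{region.start}-{region.end}"
        ) from None
    if region.end > len(seq):
        raise ValueError(
            f"region {region.seq_id}:{region.start}-{region.end} exceeds "
            f"sequence length {len(seq)}"
        )
    return seq[region.start - 1: region.end]


def _greedy_identity_reduce(
    members: list[MCMember], sequences: Mapping[str, str], identity: float
) -> list[MCMember]:
    """Longest-first greedy reduction: drop members >= identity to a kept one."""
    order = sorted(
        range(len(members)),
        key=lambda i: (-members[i].region.length, i),
    )
    kept: list[int] = []
    kept_seqs: list[str] = []
    for i in order:
        s = _region_sequence(members[i].region, sequences)
        if any(_identity(s, ks) >= identity for ks in kept_seqs):
            continue
        kept.append(i)
        kept_seqs.append(s)
    kept.sort()
    return [members[i] for i in kept]


def reduce_and_cap_members(
    mc: Metacluster,
    sequences: Mapping[str, str] | None = None,
    params: MetaclusteringParams = MetaclusteringParams(),
) -> Metacluster | None:
    """Redundancy-reduce, size-filter and subsample a metacluster's members.

    Steps, in order: (a) if *sequences* are supplied, greedy redundancy
    reduction at ``member_identity`` (an external CD-HIT run may replace
    this step by pre-filtering the members); when absent the identity step
    is skipped with a warning; (b) metaclusters left with fewer than
    ``min_size`` members are removed (``None`` is returned); (c) larger
    metaclusters are subsampled uniformly at random to ``member_cap`` using
    the configured seed, deterministically per metacluster id.
    """
    members = mc.members
    if sequences is not None:
        members = _greedy_identity_reduce(members, sequences, params.member_identity)
    else:
        logger.warning(
            "%s: no sequences supplied; identity-based redundancy reduction skipped",
            mc.mc_id,
        )
    if len(members) < params.min_size:
        logger.info("%s dropped: %d members < min_size=%d",
                    mc.mc_id, len(members), params.min_size)
        return None
    if len(members) > params.member_cap:
        rng = _mc_rng(params, mc.mc_id)
        pick = np.sort(rng.choice(len(members), size=params.member_cap, replace=False))
        members = [members[i] for i in pick]
    return Metacluster(
        mc_id=mc.mc_id,
        primary_clusters=mc.primary_clusters,
        members=list(members),
        rho_c=mc.rho_c,
        delta_c=mc.delta_c,
    )


def export_seed_set(
    mc: Metacluster,
    sequences: Mapping[str, str],
    params: MetaclusteringParams = MetaclusteringParams(),
):
    """Member subsequences suitable as seeds for an MSA and a profile HMM.

    Members are redundancy-reduced at ``seed_identity`` and capped at
    ``seed_cap`` (seeded random choice).  Returns Biopython ``SeqRecord``
    objects with ids ``<seq_id>/<start>-<end>``; write them with
    ``Bio.SeqIO`` and feed them to external MSA (e.g. MUSCLE) and
    profile-HMM (e.g. HMMER) builders.
    """
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    members = _greedy_identity_reduce(mc.members, sequences, params.seed_identity)
    if len(members) > params.seed_cap:
        rng = _mc_rng(params, mc.mc_id + "/seed")
        pick = np.sort(rng.choice(len(members), size=params.seed_cap, replace=False))
        members = [members[i] for i in pick]
    records = []
    for m in members:
        sub = _region_sequence(m.region, sequences)
        rid = f"{m.region.seq_id}/{m.region.start}-{m.region.end}"
        records.append(SeqRecord(Seq(sub), id=rid, description=""))
    return records
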