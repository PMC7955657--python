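"""End-to-end clustering pipeline and the robustness protocol.

``run_cluster`` chains the stages in order: read -> group by query -> same-
search-sequence dedup -> per-query density-peak clustering -> cross-query
metaclustering -> merging -> member filtering -> redundancy reduction,
size filter and capping.  Every run emits a manifest recording resolved
parameters, the seed, input digests and per-stage counts, so that a run
can be reproduced exactly.

``run_robustness`` reruns the pipeline under perturbed parameters (the
reference protocol perturbs mu1, mu2 and the gap exponent by +/-10%) and
compares each run to the reference through the number of metaclustered
alignments, the percentage of the reference's metaclustered alignments
recovered, and the NMI over commonly clustered alignments.  Assignments
are compared *before* the member-filtering step.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import asdict, dataclass, replace
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from densfam.alignments import (
    Alignment,
    dedup_same_search,
    group_by_query,
    read_alignment_table,
)
from densfam.evaluation import clustering_nmi
from densfam.metaclusters import (
    Metacluster,
    MetaclusteringParams,
    assign_to_metaclusters,
    filter_member_regions,
    merge_metaclusters,
    metacluster_peaks,
    primary_cluster_distance_matrix,
    reduce_and_cap_members,
)
from densfam.primary import PrimaryCluster, PrimaryClusteringParams, cluster_query

logger = logging.getLogger("densfam")

_version = "0.1.0"  # kept in sync with the package version


@dataclass
class ClusterResult:
    """Everything a clustering run produces.

    ``metaclusters`` holds the final (filtered, size-checked, capped)
    metaclusters; ``assignment`` maps alignment keys to metacluster ids as
    of the merge step, before member filtering — the granularity at which
    robustness runs are compared.
    """

    metaclusters: list[Metacluster]
    assignment: dict[tuple, str]
    primary_clusters: list[PrimaryCluster]
    manifest: dict

    def member_table(self) -> pd.DataFrame:
        """One row per final member region, with provenance."""
        rows = [
            {
                "mc_id": mc.mc_id,
                "search_id": m.region.seq_id,
                "sstart": m.region.start,
                "send": m.region.end,
                "query_id": m.alignment.query_id,
                "cluster_id": m.source_cluster_id,
                "evalue": m.alignment.evalue,
            }
            for mc in self.metaclusters
            for m in mc.members
        ]
        return pd.DataFrame(
            rows,
            columns=["mc_id", "search_id", "sstart", "send",
                     "query_id", "cluster_id", "evalue"],
        )


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_cluster(
    alignments: Sequence[Alignment] | str | Path,
    primary: PrimaryClusteringParams | None = None,
    meta: MetaclusteringParams | None = None,
    sequences: Mapping[str, str] | None = None,
    evalue_max: float = 0.1,
) -> ClusterResult:
    """Run the full two-round clustering on an alignment table.

    *alignments* may be a path to an outfmt-6 TSV (read with the strict
    ``evalue < evalue_max`` filter) or an in-memory alignment list.  When
    *sequences* (a mapping id -> residue string) are provided, member
    redundancy reduction at ``meta.member_identity`` is applied before the
    size filter; otherwise that step is skipped.
    """
    primary = primary or PrimaryClusteringParams()
    meta = meta or MetaclusteringParams()
    manifest: dict = {
        "tool": "densfam",
        "version": _version,
        "parameters": {"primary": asdict(primary), "metaclustering": asdict(meta),
                       "evalue_max": evalue_max},
        "rng_seed": meta.rng_seed,
        "inputs": {},
        "counts": {},
    }
    if isinstance(alignments, (str, Path)):
        manifest["inputs"]["alignment_table"] = {
            "path": str(alignments), "sha256": _sha256(alignments)
        }
        alignments = read_alignment_table(alignments, evalue_max=evalue_max)
    counts = manifest["counts"]
    counts["alignments_read"] = len(alignments)

    qsets = group_by_query(alignments)
    counts["queries"] = len(qsets)
    deduped = [dedup_same_search(qs, primary.mu1) for qs in qsets]
    counts["alignments_after_dedup"] = sum(len(qs) for qs in deduped)

    clusters: list[PrimaryCluster] = []
    skipped = 0
    for qs in deduped:
        pcs = cluster_query(qs, primary)
        if pcs:
            clusters.extend(pcs)
        else:
            skipped += 1
    counts["queries_skipped"] = skipped
    counts["queries_clustered"] = len(deduped) - skipped
    counts["primary_clusters"] = len(clusters)

    if not clusters:
        logger.info("no primary clusters; empty result")
        counts.update(
            metaclusters_before_merge=0, metaclusters_after_merge=0,
            members_before_filter=0, members_after_filter=0, metaclusters_final=0,
        )
        return ClusterResult([], {}, [], manifest)

    dist = primary_cluster_distance_matrix(clusters, meta.mu_d)
    peaks, rho, delta = metacluster_peaks(clusters, meta, dist=dist)
    mcs = assign_to_metaclusters(clusters, peaks, meta, dist=dist)
    counts["metaclusters_before_merge"] = len(mcs)

    row_of = {id(c): i for i, c in enumerate(clusters)}
    for mc in mcs:
        # pre-merge mc ids are "MC<rank+1>" in peak order
        r = row_of[id(peaks[int(mc.mc_id[2:]) - 1])]
        mc.rho_c, mc.delta_c = int(rho[r]), float(delta[r])
    mcs = merge_metaclusters(
        mcs, meta, dist_fn=lambda a, b: float(dist[row_of[id(a)], row_of[id(b)]])
    )
    counts["metaclusters_after_merge"] = len(mcs)
    counts["members_before_filter"] = sum(mc.size for mc in mcs)

    assignment = {
        m.alignment.key: mc.mc_id for mc in mcs for m in mc.members
    }

    filtered = [filter_member_regions(mc, meta) for mc in mcs]
    counts["members_after_filter"] = sum(mc.size for mc in filtered)
    final = []
    for mc in filtered:
        reduced = reduce_and_cap_members(mc, sequences, meta)
        if reduced is not None:
            final.append(reduced)
    counts["metaclusters_final"] = len(final)
    counts["members_final"] = sum(mc.size for mc in final)
    logger.info("pipeline counts: %s", counts)
    return ClusterResult(final, assignment, clusters, manifest)


def standard_perturbations(
    primary: PrimaryClusteringParams, meta: MetaclusteringParams
) -> dict[str, tuple[PrimaryClusteringParams, MetaclusteringParams]]:
    """The +/-10% perturbations of mu1, mu2 and the gap exponent."""
    out: dict[str, tuple[PrimaryClusteringParams, MetaclusteringParams]] = {}
    for sign, tag in ((1.1, "+10%"), (0.9, "-10%")):
        out[f"mu1{tag}"] = (replace(primary, mu1=primary.mu1 * sign), meta)
        out[f"mu2{tag}"] = (primary, replace(meta, mu2=min(meta.mu2 * sign, 1.0)))
        out[f"delta{tag}"] = (replace(primary, delta_exp=primary.delta_exp * sign), meta)
    return out


def run_robustness(
    alignments: Sequence[Alignment],
    primary: PrimaryClusteringParams | None = None,
    meta: MetaclusteringParams | None = None,
    perturbations: Mapping[str, tuple[PrimaryClusteringParams, MetaclusteringParams]]
    | None = None,
) -> pd.DataFrame:
    """Compare perturbed clustering runs against the reference run.

    Returns one row per run (the reference first) with: the number of
    metaclustered alignments, the percentage of the reference run's
    metaclustered alignments that are also metaclustered, and the NMI of
    the two partitions over the commonly clustered alignments.
    """
    primary = primary or PrimaryClusteringParams()
    meta = meta or MetaclusteringParams()
    if perturbations is None:
        perturbations = standard_perturbations(primary, meta)
    if not perturbations:
        raise ValueError("perturbation list is empty")
    reference = run_cluster(alignments, primary, meta)
    ref_keys = set(reference.assignment)
    rows = [
        {
            "run": "reference",
            "n_metaclustered": len(ref_keys),
            "pct_of_reference": 100.0,
            "nmi": 1.0,
        }
    ]
    for name, (pp, mp) in perturbations.items():
        res = run_cluster(alignments, pp, mp)
        keys = set(res.assignment)
        common = ref_keys & keys
        pct = 100.0 * len(common) / len(ref_keys) if ref_keys else float("nan")
        nmi = (
            clustering_nmi(reference.assignment, res.assignment)
            if common
            else float("nan")
        )
        rows.append(
            {
                "run": name,
                "n_metaclustered": len(keys),
                "pct_of_reference": pct,
                "nmi": nmi,
            }
        )
    return pd.DataFrame(rows, columns=["run", "n_metaclustered",
                                       "pct_of_reference", "nmi"])
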