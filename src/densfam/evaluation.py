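"""Comparison of metaclusters against a reference domain classification.

Given per-sequence domain annotations (family, clan, interval, E-value) a
*ground-truth architecture* (GTA) of a region is the ordered list of
annotated families (or clans) overlapping it by at least one residue; the
*dominant architecture* (DA) of a metacluster is its modal GTA.  Member
consistency is summarised by a cumulative ladder of percentages

    %DAF <= %DAC <= %DACF <= %DACFA

(exact family match, exact clan match, plus fewer-clans members, plus
additional-clan members), boundary agreement by the mean fractions F_red
(reference covered interval missed by the member region) and F_ext (member
region extending beyond it), coverage by greedy cumulative curves over
profile-HMM hits, and robustness by normalized mutual information between
two clusterings of the same alignments.
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Hashable, Mapping, Sequence

import numpy as np
from sklearn.metrics import normalized_mutual_info_score

from densfam.alignments import Region

logger = logging.getLogger("densfam")

BOUNDARY_THRESHOLD = 0.2  # on mean F_ext / F_red, defines the four categories


@dataclass(frozen=True, slots=True)
class DomainAnnotation:
    """One reference domain annotation on a sequence.

    ``clan_id`` falls back to the family id when the family belongs to no
    clan, so clan-level architectures are always defined.
    """

    seq_id: str
    family_id: str
    clan_id: str
    region: Region
    evalue: float

    def __post_init__(self) -> None:
        if self.region.seq_id != self.seq_id:
            raise ValueError("annotation region must lie on seq_id")
        if not (self.evalue >= 0):
            raise ValueError(f"negative or NaN E-value: {self.evalue}")


@dataclass(frozen=True, slots=True)
class GroundTruthArchitecture:
    """Ordered family/clan labels overlapping a region, and their span.

    ``covered`` runs from the start of the first overlapping annotation to
    the end of the last one, including every residue between them; it is
    ``None`` iff no annotation overlaps the region.
    """

    labels: tuple[str, ...]
    covered: Region | None

    @property
    def key(self) -> str:
        """The architecture as an underscore-joined string ('' if empty)."""
        return "_".join(self.labels)


@dataclass(slots=True)
class MCReport:
    """Per-metacluster comparison statistics against the reference."""

    mc_id: str
    size: int
    avg_length: float
    sdl: float
    da_family: tuple[str, ...]
    da_clan: tuple[str, ...]
    pct_daf: float
    pct_dac: float
    pct_dacf: float
    pct_dacfa: float
    f_red: float
    f_ext: float
    category: str | None
    extra_clans: int
    lc_fraction: float | None = None
    order_violations: int = 0


def read_annotation_table(path: str | Path) -> list[DomainAnnotation]:
    """Read a TSV of ``seq_id family_id clan_id start end evalue`` rows.

    An empty or '-' clan field falls back to the family id.
    """
    out = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            raw = raw.rstrip("\n")
            if not raw or raw.startswith("#"):
                continue
            f = raw.split("\t")
            if len(f) < 6:
                raise ValueError(f"{path}:{lineno}: expected 6 columns, got {len(f)}")
            clan = f[2] if f[2] not in ("", "-") else f[1]
            out.append(
                DomainAnnotation(
                    seq_id=f[0], family_id=f[1], clan_id=clan,
                    region=Region(f[0], int(f[3]), int(f[4])),
                    evalue=float(f[5]),
                )
            )
    return out


def read_clan_map(path: str | Path) -> dict[str, str]:
    """Read a family-to-clan TSV map (two columns)."""
    out: dict[str, str] = {}
    with open(path) as fh:
        for raw in fh:
            raw = raw.rstrip("\n")
            if not raw or raw.startswith("#"):
                continue
            fam, clan = raw.split("\t")[:2]
            out[fam] = clan if clan not in ("", "-") else fam
    return out


def read_mask_table(path: str | Path) -> dict[str, list[Region]]:
    """Read low-complexity mask intervals: ``seq_id start end`` TSV rows."""
    out: dict[str, list[Region]] = {}
    with open(path) as fh:
        for raw in fh:
            raw = raw.rstrip("\n")
            if not raw or raw.startswith("#"):
                continue
            f = raw.split("\t")
            out.setdefault(f[0], []).append(Region(f[0], int(f[1]), int(f[2])))
    return out


def resolve_annotation_overlaps(
    annotations: Sequence[DomainAnnotation],
) -> list[DomainAnnotation]:
    """Resolve overlapping annotations of one sequence by lowest E-value.

    Greedy in ascending E-value (ties by input order): an annotation is
    kept iff its interval shares no residue with an already-kept one;
    losers are removed entirely.  Nested annotations are treated as plain
    overlaps — domain nesting is not modelled — so a nested domain always
    loses to an enclosing one of lower E-value.  The result is returned in
    sequence order.
    """
    if not annotations:
        return []
    seq_ids = {a.seq_id for a in annotations}
    if len(seq_ids) > 1:
        raise ValueError(f"annotations span several sequences: {sorted(seq_ids)}")
    order = sorted(range(len(annotations)), key=lambda i: (annotations[i].evalue, i))
    kept: list[DomainAnnotation] = []
    for i in order:
        a = annotations[i]
        if any(a.region.intersection_length(k.region) > 0 for k in kept):
            continue
        kept.append(a)
    kept.sort(key=lambda a: a.region.start)
    return kept


def gta_of_region(
    region: Region,
    resolved: Sequence[DomainAnnotation],
    level: str = "family",
) -> GroundTruthArchitecture:
    """Ground-truth architecture of a region: overlapping labels, in order.

    A single shared residue is enough for an annotation to enter the GTA.
    ``covered`` spans from the first overlapping annotation's start to the
    last one's end.  ``level`` selects family or clan labels.
    """
    if level not in ("family", "clan"):
        raise ValueError(f"level must be 'family' or 'clan', got {level!r}")
    hits = [
        a for a in resolved
        if a.seq_id == region.seq_id and a.region.intersection_length(region) > 0
    ]
    hits.sort(key=lambda a: a.region.start)
    if not hits:
        return GroundTruthArchitecture(labels=(), covered=None)
    labels = tuple(a.family_id if level == "family" else a.clan_id for a in hits)
    covered = Region(region.seq_id, hits[0].region.start, hits[-1].region.end)
    return GroundTruthArchitecture(labels=labels, covered=covered)


def dominant_architecture(
    gtas: Sequence[GroundTruthArchitecture],
) -> tuple[str, ...]:
    """Modal architecture among members.

    Empty GTAs take part in the counting, but an empty architecture never
    beats a nonempty one on a tie; ties among nonempty architectures break
    lexicographically.  Returns an empty tuple only when every member is
    unannotated (flagged with a warning).
    """
    if not gtas:
        raise ValueError("no member architectures")
    counts = Counter(g.labels for g in gtas)
    top_nonempty = max((c for labels, c in counts.items() if labels != ()), default=0)
    if top_nonempty == 0 or counts.get((), 0) > top_nonempty:
        logger.warning("dominant architecture is empty (unannotated majority)")
        return ()
    candidates = [
        labels for labels, c in counts.items() if labels != () and c == top_nonempty
    ]
    return min(candidates, key=lambda labels: "_".join(labels))


def is_order_preserving_subsequence(
    sub: Sequence[str], full: Sequence[str]
) -> bool:
    """Greedy left-to-right subsequence test (repeats matched greedily)."""
    it = iter(full)
    return all(any(x == y for y in it) for x in sub)


def consistency_scores(
    family_gtas: Sequence[GroundTruthArchitecture],
    clan_gtas: Sequence[GroundTruthArchitecture],
    da_family: tuple[str, ...],
    da_clan: tuple[str, ...],
) -> tuple[float, float, float, float]:
    """The cumulative consistency ladder %DAF, %DAC, %DACF, %DACFA.

    %DAF: members whose family-level GTA equals the family-level DA.
    %DAC: members whose clan-level GTA equals the clan-level DA ("DA
    members").  %DACF adds members whose clan GTA is a proper
    order-preserving subsequence of the DA clans — including members with
    no annotation at all, since absence of reference annotation does not
    place a region outside the family.  %DACFA further adds members whose
    clan GTA carries at least one DA clan alongside at least one clan not
    in the DA.  All values are percentages of the member count.
    """
    if not da_clan:
        raise ValueError("dominant architecture is empty")
    n = len(clan_gtas)
    if n == 0 or len(family_gtas) != n:
        raise ValueError("need matching nonempty family- and clan-level GTA lists")
    da_clan_set = set(da_clan)
    n_daf = sum(1 for g in family_gtas if g.labels == da_family)
    n_dac = n_f = n_a = 0
    for g in clan_gtas:
        if g.labels == da_clan:
            n_dac += 1
        elif is_order_preserving_subsequence(g.labels, da_clan):
            # proper subsequence (includes the empty GTA)
            n_f += 1
        else:
            has_da = any(c in da_clan_set for c in g.labels)
            has_extra = any(c not in da_clan_set for c in g.labels)
            if has_da and has_extra:
                n_a += 1
    pct = 100.0 / n
    return (n_daf * pct, n_dac * pct, (n_dac + n_f) * pct, (n_dac + n_f + n_a) * pct)


def boundary_category(f_ext: float, f_red: float) -> str:
    """Four-way boundary-agreement category at the 0.2 thresholds."""
    if f_ext < BOUNDARY_THRESHOLD:
        return "equivalent" if f_red < BOUNDARY_THRESHOLD else "reduced"
    return "extended" if f_red < BOUNDARY_THRESHOLD else "shifted"


def member_boundary_fractions(member: Region, covered: Region) -> tuple[float, float]:
    """(F_red, F_ext) of one member region against its reference span.

    F_red is the fraction of the reference interval P not covered by the
    member region S; F_ext the fraction of S outside P (residue counts).
    """
    inter = member.intersection_length(covered)
    f_red = (covered.length - inter) / covered.length
    f_ext = (member.length - inter) / member.length
    return f_red, f_ext


def boundary_scores(
    members: Sequence[tuple[Region, Region | None]],
) -> tuple[float, float, str]:
    """Mean F_red, mean F_ext and the boundary category over DA members.

    *members* holds (member region S, reference covered interval P) pairs;
    members with an empty P are skipped with a warning.
    """
    reds, exts = [], []
    for s, p in members:
        if p is None:
            logger.warning("member %s:%d-%d has no reference span; skipped",
                           s.seq_id, s.start, s.end)
            continue
        f_red, f_ext = member_boundary_fractions(s, p)
        reds.append(f_red)
        exts.append(f_ext)
    if not reds:
        raise ValueError("no members with a nonempty reference span")
    f_red = float(np.mean(reds))
    f_ext = float(np.mean(exts))
    return f_red, f_ext, boundary_category(f_ext, f_red)


def coverage_curve(
    reference_regions: Sequence[Region],
    hits_by_mc: Mapping[str, Sequence[Region]],
    fraction: float = 0.75,
) -> list[tuple[str, float]]:
    """Greedy cumulative coverage of reference regions by metacluster hits.

    A reference region is covered by a metacluster iff one of that MC's
    hits overlaps at least ``fraction`` of the region's residues (use 1.0
    for exact full coverage).  Metaclusters are ranked by decreasing
    marginal contribution; each region counts once even when covered by
    several MCs.  Returns (mc_id, cumulative covered fraction) per rank.
    """
    if not 0 < fraction <= 1:
        raise ValueError(f"fraction must be in (0,1], got {fraction}")
    n_ref = len(reference_regions)
    if n_ref == 0:
        return []
    covered_sets: dict[str, set[int]] = {}
    for mc_id, hits in hits_by_mc.items():
        by_seq: dict[str, list[Region]] = {}
        for h in hits:
            by_seq.setdefault(h.seq_id, []).append(h)
        cov = set()
        for i, ref in enumerate(reference_regions):
            need = ref.length * fraction
            for h in by_seq.get(ref.seq_id, ()):
                if h.intersection_length(ref) >= need:
                    cov.add(i)
                    break
        covered_sets[mc_id] = cov
    curve: list[tuple[str, float]] = []
    done: set[int] = set()
    remaining = dict(covered_sets)
    while remaining:
        mc_id = max(
            remaining,
            key=lambda m: (len(remaining[m] - done), m),
        )
        done |= remaining.pop(mc_id)
        curve.append((mc_id, len(done) / n_ref))
    return curve


def read_domtblout(
    path: str | Path,
    seq_evalue_max: float | None = 0.01,
    dom_evalue_max: float | None = 0.03,
) -> dict[str, list[Region]]:
    """Read per-domain hit envelopes from a HMMER ``--domtblout`` file.

    Returns hit envelope regions on the target sequences, grouped by query
    (profile) name.  Hits failing the full-sequence or per-domain
    (independent) E-value thresholds are dropped; pass ``None`` to disable
    either threshold.
    """
    from Bio import SearchIO

    out: dict[str, list[Region]] = {}
    for qresult in SearchIO.parse(str(path), "hmmsearch3-domtab"):
        regions = out.setdefault(qresult.id, [])
        for hit in qresult.hits:
            if seq_evalue_max is not None and hit.evalue >= seq_evalue_max:
                continue
            for hsp in hit.hsps:
                if dom_evalue_max is not None and hsp.evalue >= dom_evalue_max:
                    continue
                # SearchIO envelope coordinates are 0-based half-open
                regions.append(Region(hit.id, hsp.env_start + 1, hsp.env_end))
    return out


def clustering_nmi(
    labels_a: Mapping[Hashable, Hashable],
    labels_b: Mapping[Hashable, Hashable],
) -> float:
    """Normalized mutual information 2 I/(H1+H2) over commonly labelled items.

    Only items present in both labelings are compared.  When both
    partitions are single-class (zero entropy) and thus identical over the
    common items, the NMI is 1 by convention.
    """
    common = sorted(set(labels_a) & set(labels_b), key=repr)
    if not common:
        raise ValueError("no items labelled in both classifications")
    a = [labels_a[k] for k in common]
    b = [labels_b[k] for k in common]
    if len(set(a)) == 1 and len(set(b)) == 1:
        return 1.0
    return float(
        normalized_mutual_info_score(
            _as_int_labels(a), _as_int_labels(b), average_method="arithmetic"
        )
    )


def _as_int_labels(labels: Sequence[Hashable]) -> list[int]:
    codes: dict[Hashable, int] = {}
    return [codes.setdefault(x, len(codes)) for x in labels]


def lc_fraction_of(
    member_regions: Sequence[Region], mask: Mapping[str, Sequence[Region]]
) -> float:
    """Fraction of all member residues lying inside masked intervals."""
    total = masked = 0
    merged_cache: dict[str, list[tuple[int, int]]] = {}
    for r in member_regions:
        total += r.length
        if r.seq_id not in merged_cache:
            ivals = sorted((m.start, m.end) for m in mask.get(r.seq_id, ()))
            merged: list[tuple[int, int]] = []
            for s, e in ivals:
                if merged and s <= merged[-1][1] + 1:
                    merged[-1] = (merged[-1][0], max(merged[-1][1], e))
                else:
                    merged.append((s, e))
            merged_cache[r.seq_id] = merged
        for s, e in merged_cache[r.seq_id]:
            masked += max(0, min(e, r.end) - max(s, r.start) + 1)
    if total == 0:
        raise ValueError("no member residues")
    return masked / total


def report_metacluster(
    mc_id: str,
    member_regions: Sequence[Region],
    resolved_by_seq: Mapping[str, Sequence[DomainAnnotation]],
    mask: Mapping[str, Sequence[Region]] | None = None,
) -> MCReport:
    """Aggregate the full per-metacluster comparison report.

    *resolved_by_seq* maps sequence ids to their overlap-resolved
    annotations.  Member length statistics use the population standard
    deviation.  ``extra_clans`` counts clans outside the DA that appear in
    the clan GTA of at least 5% of members; ``order_violations`` counts
    additional-clan members whose DA clans appear out of order.  When every
    member is unannotated the DA is empty and the consistency/boundary
    fields are None-like (NaN / None).
    """
    if not member_regions:
        raise ValueError(f"metacluster {mc_id} has no members")
    fam_gtas, clan_gtas = [], []
    for r in member_regions:
        resolved = resolved_by_seq.get(r.seq_id, ())
        fam_gtas.append(gta_of_region(r, resolved, "family"))
        clan_gtas.append(gta_of_region(r, resolved, "clan"))
    lengths = np.array([r.length for r in member_regions], dtype=float)
    da_family = dominant_architecture(fam_gtas)
    da_clan = dominant_architecture(clan_gtas)
    lc = lc_fraction_of(member_regions, mask) if mask is not None else None
    if not da_clan:
        return MCReport(
            mc_id=mc_id, size=len(member_regions),
            avg_length=float(lengths.mean()), sdl=float(lengths.std()),
            da_family=(), da_clan=(),
            pct_daf=math.nan, pct_dac=math.nan, pct_dacf=math.nan,
            pct_dacfa=math.nan, f_red=math.nan, f_ext=math.nan,
            category=None, extra_clans=0, lc_fraction=lc,
        )
    pct_daf, pct_dac, pct_dacf, pct_dacfa = consistency_scores(
        fam_gtas, clan_gtas, da_family, da_clan
    )
    da_clan_set = set(da_clan)
    da_pairs = [
        (r, g.covered)
        for r, g in zip(member_regions, clan_gtas)
        if g.labels == da_clan
    ]
    f_red, f_ext, category = boundary_scores(da_pairs)
    clan_presence: Counter[str] = Counter()
    order_violations = 0
    for g in clan_gtas:
        for clan in set(g.labels):
            clan_presence[clan] += 1
        has_da = any(c in da_clan_set for c in g.labels)
        has_extra = any(c not in da_clan_set for c in g.labels)
        if has_da and has_extra:
            da_part = [c for c in g.labels if c in da_clan_set]
            if not is_order_preserving_subsequence(da_part, da_clan):
                order_violations += 1
    threshold = 0.05 * len(member_regions)
    extra = sum(
        1 for clan, c in clan_presence.items()
        if clan not in da_clan_set and c >= threshold
    )
    return MCReport(
        mc_id=mc_id, size=len(member_regions),
        avg_length=float(lengths.mean()), sdl=float(lengths.std()),
        da_family=da_family, da_clan=da_clan,
        pct_daf=pct_daf, pct_dac=pct_dac, pct_dacf=pct_dacf, pct_dacfa=pct_dacfa,
        f_red=f_red, f_ext=f_ext, category=category,
        extra_clans=extra, lc_fraction=lc,
        order_violations=order_violations,
    )
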