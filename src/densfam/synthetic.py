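"""Planted-truth proteome and alignment-table simulator.

The generator builds multi-domain proteins by concatenating per-family
domain instances and random linkers, then emits a BLAST-like alignment
table directly from the planted domain coordinates: every ordered pair of
instances of the same family yields an alignment with a configurable
detection probability, endpoint jitter and a sampled E-value, plus
Poisson-distributed spurious alignments between unrelated regions.  Because
alignment regions derive from the planted truth rather than from actually
aligning the sequences, the planted family of every region is an exact
oracle for clustering results, while the sequences themselves (per-family
consensus with point mutations) still exercise identity-based redundancy
reduction.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from densfam.alignments import Alignment, Region, write_alignment_table
from densfam.evaluation import DomainAnnotation

AMINO_ACIDS = np.array(list("ACDEFGHIKLMNPQRSTVWY"))

#: Planted truth: per-protein ordered, non-overlapping annotations.
PlantedTruth = dict[str, list[DomainAnnotation]]


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for the planted benchmark.

    Defaults describe a small three-family proteome with two multi-domain
    architectures (-A-, -A-B-) plus a third independent single-domain
    family, imperfect detection (90% of homologous pairs aligned), mild
    boundary jitter (SD 3 residues) and a low spurious-alignment rate (0.1
    per protein) — conditions under which the two-round clustering should
    recover the planted families while still being exposed to noise.
    """

    n_families: int = 3
    family_length_range: tuple[int, int] = (80, 120)
    architectures: tuple[tuple[tuple[str, ...], float], ...] = (
        (("F1",), 0.4),
        (("F1", "F2"), 0.3),
        (("F3",), 0.3),
    )
    n_proteins: int = 300
    linker_length_range: tuple[int, int] = (10, 30)
    fragment_fraction: float = 0.1
    detection_prob: float = 0.9
    boundary_jitter_sd: float = 3.0
    join_prob: float = 0.0
    noise_alignment_rate: float = 0.1
    evalue_log10_range: tuple[float, float] = (-40.0, -2.0)
    noise_evalue_log10_range: tuple[float, float] = (-3.0, -1.05)
    super_threshold_rate: float = 0.0
    mutation_rate: float = 0.10
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for p in (self.fragment_fraction, self.detection_prob, self.join_prob):
            if not 0 <= p <= 1:
                raise ValueError(f"probability out of [0,1]: {p}")
        if self.noise_alignment_rate < 0 or self.super_threshold_rate < 0:
            raise ValueError("rates must be >= 0")
        lo, hi = self.family_length_range
        if lo < 1 or hi < lo:
            raise ValueError(f"bad family_length_range {self.family_length_range}")
        known = self.family_ids
        total = 0.0
        for arch, freq in self.architectures:
            for fam in arch:
                if fam not in known:
                    raise ValueError(f"architecture references unknown family {fam!r}")
            if freq < 0:
                raise ValueError("architecture frequencies must be >= 0")
            total += freq
        if total <= 0:
            raise ValueError("architecture frequencies sum to zero")

    @property
    def family_ids(self) -> tuple[str, ...]:
        return tuple(f"F{i + 1}" for i in range(self.n_families))


def _random_protein_id(i: int) -> str:
    return f"P{i:04d}"


def _mutate(consensus: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    out = consensus.copy()
    hit = rng.random(len(out)) < rate
    out[hit] = AMINO_ACIDS[rng.integers(0, len(AMINO_ACIDS), hit.sum())]
    return out


def simulate_proteome(config: SyntheticConfig):
    """Generate proteins and their planted annotations.

    Returns ``(records, truth)`` where *records* are Biopython SeqRecords
    and *truth* maps protein ids to ordered non-overlapping annotations
    (clan id = family id; the planted families have no clan structure).
    A ``fragment_fraction`` of proteins is C-terminally truncated at a
    uniform position, with annotations clipped to the remaining length
    (dropped when entirely cut away).  Identical config and seed give
    byte-identical output.
    """
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    rng = np.random.default_rng(config.rng_seed)
    lo, hi = config.family_length_range
    consensus = {
        fam: AMINO_ACIDS[rng.integers(0, len(AMINO_ACIDS), int(rng.integers(lo, hi + 1)))]
        for fam in config.family_ids
    }
    archs = [a for a, _ in config.architectures]
    freqs = np.array([f for _, f in config.architectures], dtype=float)
    freqs /= freqs.sum()
    llo, lhi = config.linker_length_range
    records: list[SeqRecord] = []
    truth: PlantedTruth = {}
    for i in range(config.n_proteins):
        pid = _random_protein_id(i)
        arch = archs[int(rng.choice(len(archs), p=freqs))]
        parts: list[np.ndarray] = []
        anns: list[tuple[str, int, int]] = []
        pos = 0
        for fam in arch:
            linker = AMINO_ACIDS[rng.integers(0, len(AMINO_ACIDS), int(rng.integers(llo, lhi + 1)))]
            parts.append(linker)
            pos += len(linker)
            dom = _mutate(consensus[fam], config.mutation_rate, rng)
            anns.append((fam, pos + 1, pos + len(dom)))
            parts.append(dom)
            pos += len(dom)
        tail = AMINO_ACIDS[rng.integers(0, len(AMINO_ACIDS), int(rng.integers(llo, lhi + 1)))]
        parts.append(tail)
        seq = np.concatenate(parts)
        if rng.random() < config.fragment_fraction and len(seq) > 1:
            cut = int(rng.integers(1, len(seq)))
            seq = seq[:cut]
            anns = [
                (fam, s, min(e, cut)) for fam, s, e in anns if s <= cut
            ]
        truth[pid] = [
            DomainAnnotation(
                seq_id=pid, family_id=fam, clan_id=fam,
                region=Region(pid, s, e), evalue=1e-30,
            )
            for fam, s, e in anns
        ]
        records.append(SeqRecord(Seq("".join(seq)), id=pid, description=""))
    return records, truth


def _jitter_region(
    region: Region, sd: float, seq_len: int, rng: np.random.Generator
) -> Region:
    if sd <= 0:
        return region
    start = region.start + int(round(rng.normal(0, sd)))
    end = region.end + int(round(rng.normal(0, sd)))
    start, end = min(start, end), max(start, end)
    start = min(max(start, 1), seq_len)
    end = min(max(end, 1), seq_len)
    if end < start:
        start = end
    return Region(region.seq_id, start, end)


def _sample_evalue(log10_range: tuple[float, float], rng: np.random.Generator) -> float:
    return float(10.0 ** rng.uniform(*log10_range))


def simulate_alignments(
    proteome, truth: PlantedTruth, config: SyntheticConfig
) -> list[Alignment]:
    """Emit a BLAST-like alignment table from the planted truth.

    For every ordered pair of distinct instances of the same family an
    alignment is emitted with probability ``detection_prob``; its query and
    search regions equal the planted regions perturbed by rounded Gaussian
    endpoint jitter, clipped to the protein.  With probability
    ``join_prob`` per pair, neighbouring domain instances of matching
    adjacent architectures are additionally emitted as a single spanning
    alignment (a known failure mode of architecture-aware clustering).
    Spurious alignments between unrelated random regions are added at
    ``noise_alignment_rate`` per protein (Poisson); ``super_threshold_rate``
    adds rows with E-value >= 0.1 to exercise the reader's filter.
    """
    rng = np.random.default_rng([config.rng_seed, 1])
    seq_len = {r.id: len(r.seq) for r in proteome}
    instances: dict[str, list[DomainAnnotation]] = {}
    for anns in truth.values():
        for a in anns:
            instances.setdefault(a.family_id, []).append(a)
    out: list[Alignment] = []
    for fam in sorted(instances):
        fam_insts = instances[fam]
        for qa in fam_insts:
            for sa in fam_insts:
                if qa is sa:
                    continue
                if rng.random() >= config.detection_prob:
                    continue
                q = _jitter_region(qa.region, config.boundary_jitter_sd,
                                   seq_len[qa.seq_id], rng)
                s = _jitter_region(sa.region, config.boundary_jitter_sd,
                                   seq_len[sa.seq_id], rng)
                out.append(
                    Alignment(
                        query_id=qa.seq_id, search_id=sa.seq_id,
                        query_region=q, search_region=s,
                        evalue=_sample_evalue(config.evalue_log10_range, rng),
                    )
                )
    if config.join_prob > 0:
        pairs: dict[tuple[str, str], list[tuple[DomainAnnotation, DomainAnnotation]]] = {}
        for anns in truth.values():
            for a, b in zip(anns, anns[1:]):
                pairs.setdefault((a.family_id, b.family_id), []).append((a, b))
        for key in sorted(pairs):
            spans = pairs[key]
            for qa, qb in spans:
                for sa, sb in spans:
                    if qa is sa:
                        continue
                    if rng.random() >= config.join_prob:
                        continue
                    q = _jitter_region(
                        Region(qa.seq_id, qa.region.start, qb.region.end),
                        config.boundary_jitter_sd, seq_len[qa.seq_id], rng)
                    s = _jitter_region(
                        Region(sa.seq_id, sa.region.start, sb.region.end),
                        config.boundary_jitter_sd, seq_len[sa.seq_id], rng)
                    out.append(
                        Alignment(
                            query_id=qa.seq_id, search_id=sa.seq_id,
                            query_region=q, search_region=s,
                            evalue=_sample_evalue(config.evalue_log10_range, rng),
                        )
                    )
    pids = sorted(seq_len)
    n_noise = int(rng.poisson(config.noise_alignment_rate * config.n_proteins))
    for _ in range(n_noise):
        qid, sid = (pids[int(k)] for k in rng.choice(len(pids), 2, replace=False))
        out.append(
            Alignment(
                query_id=qid, search_id=sid,
                query_region=_random_region(qid, seq_len[qid], rng),
                search_region=_random_region(sid, seq_len[sid], rng),
                evalue=_sample_evalue(config.noise_evalue_log10_range, rng),
            )
        )
    n_super = int(rng.poisson(config.super_threshold_rate * config.n_proteins))
    for _ in range(n_super):
        qid, sid = (pids[int(k)] for k in rng.choice(len(pids), 2, replace=False))
        out.append(
            Alignment(
                query_id=qid, search_id=sid,
                query_region=_random_region(qid, seq_len[qid], rng),
                search_region=_random_region(sid, seq_len[sid], rng),
                evalue=float(10.0 ** rng.uniform(-1, 1)),
            )
        )
    return out


def _random_region(seq_id: str, seq_len: int, rng: np.random.Generator) -> Region:
    length = min(int(rng.integers(30, 101)), seq_len)
    start = int(rng.integers(1, seq_len - length + 2))
    return Region(seq_id, start, start + length - 1)


def planted_label_of_region(region: Region, truth: PlantedTruth) -> str | None:
    """Planted family of a region: the maximum-overlap annotation, if any."""
    best, best_overlap = None, 0
    for a in truth.get(region.seq_id, ()):
        ov = a.region.intersection_length(region)
        if ov > best_overlap:
            best, best_overlap = a.family_id, ov
    return best


def write_fixture(proteome, truth: PlantedTruth, alignments, out_dir, config) -> dict:
    """Write FASTA, annotation TSV, alignment TSV and a manifest to *out_dir*.

    The annotation TSV uses the evaluation dialect (seq_id, family, clan,
    start, end, evalue) with clan = family.  Returns the paths written.
    """
    from Bio import SeqIO

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "fasta": out_dir / "proteome.fasta",
        "annotations": out_dir / "planted_annotations.tsv",
        "alignments": out_dir / "alignments.tsv",
        "manifest": out_dir / "manifest.json",
    }
    SeqIO.write(proteome, paths["fasta"], "fasta")
    with open(paths["annotations"], "w") as fh:
        for pid in sorted(truth):
            for a in truth[pid]:
                fh.write(
                    f"{a.seq_id}\t{a.family_id}\t{a.clan_id}\t"
                    f"{a.region.start}\t{a.region.end}\t{a.evalue:g}\n"
                )
    write_alignment_table(alignments, paths["alignments"])
    manifest = {
        "config": dataclasses.asdict(config),
        "rng_seed": config.rng_seed,
        "n_proteins": len(proteome),
        "n_alignments": len(alignments),
    }
    with open(paths["manifest"], "w") as fh:
        json.dump(manifest, fh, indent=2, default=list)
        fh.write("\n")
    return {k: str(v) for k, v in paths.items()}


def simulate(config: SyntheticConfig):
    """Convenience wrapper: proteome, truth and alignments in one call."""
    proteome, truth = simulate_proteome(config)
    alignments = simulate_alignments(proteome, truth, config)
    return proteome, truth, alignments
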