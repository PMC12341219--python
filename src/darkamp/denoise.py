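"""Per-library denoising into ZOTUs, OTU clustering, and taxonomy.

Each library is dereplicated (singletons discarded), denoised with a
greedy abundance-skew pass in the style of the UNOISE algorithm, screened
for exact two-parent chimeras, and the resulting zero-radius OTUs
(ZOTUs/ASVs) are pooled across samples and clustered into 97%-identity
OTUs.  Taxonomy is assigned by a k-mer bootstrap classifier with an 80%
confidence cutoff, in the style of SINTAX.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import edlib
import numpy as np

__all__ = [
    "UniqueSeq",
    "Zotu",
    "OtuMap",
    "TaxonomyReference",
    "dereplicate",
    "unoise_denoise",
    "beta_skew",
    "flag_chimeras",
    "pairwise_identity",
    "cluster_otus",
    "classify_taxonomy",
    "build_zotu_table",
    "RANKS",
]

RANKS = ("domain", "phylum", "class", "order", "family", "genus", "species")
_RANK_CODES = dict(zip("dpcofgs", RANKS))


@dataclass
class UniqueSeq:
    """A dereplicated sequence with its per-sample occurrence count."""

    seq: str
    count: int
    sample_id: str = ""


@dataclass
class Zotu:
    """A denoised sequence variant with accumulated member counts."""

    zotu_id: str
    centroid_seq: str
    counts: dict[str, int] = field(default_factory=dict)  # sample -> reads
    chimera_flag: bool = False
    taxonomy: dict[str, str] = field(default_factory=dict)
    confidences: dict[str, float] = field(default_factory=dict)

    @property
    def total(self) -> int:
        return sum(self.counts.values())


@dataclass
class OtuMap:
    """Greedy 97%-identity clusters over ZOTUs.

    ``members`` maps otu_id -> ordered zotu_ids (centroid first).
    """

    members: dict[str, list[str]]

    @property
    def zotu_to_otu(self) -> dict[str, str]:
        return {z: o for o, zsz in self.members.items() for z in zsz}


def dereplicate(seqs: Iterable[str], sample_id: str = "",
                min_count: int = 2) -> list[UniqueSeq]:
    """Exact-sequence grouping; sequences below ``min_count`` are dropped.

    Singleton removal (the default) happens here, before denoising.
    """
    counts = Counter(seqs)
    uniques = [UniqueSeq(s, c, sample_id) for s, c in counts.items() if c >= min_count]
    uniques.sort(key=lambda u: (-u.count, u.seq))
    return uniques


def beta_skew(d: int, alpha: float = 2.0) -> float:
    """Maximum abundance skew for merging a variant at edit distance d."""
    return 1.0 / 2 ** (alpha * d + 1)


def _edit_distance(a: str, b: str) -> int:
    return edlib.align(a, b, mode="NW", task="distance")["editDistance"]


def unoise_denoise(uniques: Sequence[UniqueSeq], alpha: float = 2.0,
                   minsize: int = 2) -> tuple[list[Zotu], dict[str, str]]:
    """Greedy abundance-skew denoising of one library.

    Candidates are visited in descending count order.  A candidate joins
    the first accepted centroid C (in acceptance order) at edit distance
    d >= 1 with count(candidate)/count(C) <= 1/2^(alpha*d+1); otherwise it
    founds a new ZOTU provided count >= minsize.  Returns the ZOTUs and a
    map from member sequence to its centroid sequence.
    """
    ordered = sorted(uniques, key=lambda u: (-u.count, u.seq))
    sample = ordered[0].sample_id if ordered else ""
    centroids: list[tuple[str, int]] = []  # (seq, founding count)
    merged: dict[str, int] = {}  # centroid seq -> accumulated count
    member_map: dict[str, str] = {}
    for u in ordered:
        joined = False
        for cseq, ccount in centroids:
            d = _edit_distance(u.seq, cseq)
            if d >= 1 and u.count / ccount <= beta_skew(d, alpha):
                merged[cseq] += u.count
                member_map[u.seq] = cseq
                joined = True
                break
        if not joined and u.count >= minsize:
            centroids.append((u.seq, u.count))
            merged[u.seq] = u.count
            member_map[u.seq] = u.seq
    zotus = [Zotu(f"Zotu{i + 1}", seq, {sample: merged[seq]} if sample else {"": merged[seq]})
             for i, (seq, _) in enumerate(centroids)]
    return zotus, member_map


def flag_chimeras(zotus: Sequence[Zotu], min_parent_ratio: float = 2.0) -> None:
    """Flag exact two-parent bipartition chimeras in place.

    A ZOTU is flagged when some breakpoint splits it into a left segment
    matching one parent's prefix and a right segment matching a distinct
    parent's suffix exactly, with both parents at least
    ``min_parent_ratio`` times as abundant.
    """
    by_total = sorted(zotus, key=lambda z: -z.total)
    for z in by_total:
        parents = [p for p in by_total
                   if p is not z and p.total >= min_parent_ratio * z.total
                   and p.centroid_seq != z.centroid_seq]
        if len(parents) < 2:
            continue
        seq = z.centroid_seq
        n = len(seq)
        for k in range(1, n):
            left, right = seq[:k], seq[k:]
            left_parents = [p for p in parents if p.centroid_seq[:k] == left]
            right_parents = [p for p in parents
                             if p.centroid_seq[-(n - k):] == right]
            if any(a is not b for a in left_parents for b in right_parents):
                z.chimera_flag = True
                break


def pairwise_identity(a: str, b: str) -> float:
    """Global-alignment identity: matches / alignment columns.

    Unit edit costs with end gaps penalised; computed from the alignment
    path, so insertions count as columns.
    """
    if a == b:
        return 1.0
    res = edlib.align(a, b, mode="NW", task="path")
    cols = 0
    matches = 0
    for length, op in re.findall(r"(\d+)([=XIDM])", res["cigar"]):
        length = int(length)
        cols += length
        if op == "=":
            matches += length
    return matches / cols if cols else 0.0


def cluster_otus(zotus: Sequence[Zotu], identity: float = 0.97) -> OtuMap:
    """Greedy centroid clustering of pooled ZOTUs at an identity cutoff.

    ZOTUs are visited in descending total count (ties by id); each joins
    the first existing centroid — centroids kept in descending abundance
    order — whose identity meets the cutoff, else founds a new OTU.
    """
    ordered = sorted(zotus, key=lambda z: (-z.total, z.zotu_id))
    members: dict[str, list[str]] = {}
    centroid_seqs: list[tuple[str, str]] = []  # (otu_id, seq)
    for z in ordered:
        placed = False
        for otu_id, cseq in centroid_seqs:
            if pairwise_identity(z.centroid_seq, cseq) >= identity:
                members[otu_id].append(z.zotu_id)
                placed = True
                break
        if not placed:
            otu_id = f"Otu{len(centroid_seqs) + 1}"
            centroid_seqs.append((otu_id, z.centroid_seq))
            members[otu_id] = [z.zotu_id]
    return OtuMap(members)


class TaxonomyReference:
    """Reference sequences with rank-annotated headers.

    Headers carry ``tax=d:...,p:...,c:...,o:...,f:...,g:...,s:...`` with any
    suffix of ranks optional.
    """

    def __init__(self, records: dict[str, str], lineages: dict[str, dict[str, str]]):
        self.records = records
        self.lineages = lineages

    @classmethod
    def from_fasta(cls, path) -> "TaxonomyReference":
        from Bio import SeqIO

        records: dict[str, str] = {}
        lineages: dict[str, dict[str, str]] = {}
        for rec in SeqIO.parse(str(path), "fasta"):
            header = rec.description
            m = re.search(r"tax=([^;]+)", header)
            lineage: dict[str, str] = {}
            if m:
                for part in m.group(1).split(","):
                    code, _, name = part.partition(":")
                    code = code.strip()
                    if code in _RANK_CODES and name:
                        lineage[_RANK_CODES[code]] = name.strip()
            records[rec.id] = str(rec.seq).upper()
            lineages[rec.id] = lineage
        return cls(records, lineages)

    @classmethod
    def from_dict(cls, entries: dict[str, tuple[str, dict[str, str]]]) -> "TaxonomyReference":
        return cls({k: s.upper() for k, (s, _) in entries.items()},
                   {k: lin for k, (_, lin) in entries.items()})


def _kmer_set(seq: str, k: int) -> list[str]:
    return sorted({seq[i:i + k] for i in range(len(seq) - k + 1)})


def classify_taxonomy(seq: str, reference: TaxonomyReference,
                      n_boot: int = 100, kmer: int = 8, subsample: int = 32,
                      cutoff: float = 0.80,
                      rng: np.random.Generator | None = None
                      ) -> tuple[dict[str, str], dict[str, float]]:
    """k-mer bootstrap taxonomy with per-rank confidence.

    Each bootstrap draws ``subsample`` k-mers with replacement from the
    query's k-mer set and votes for the reference sharing the most of
    them (ties broken at random, seeded via ``rng``).  Confidence at a
    rank is the vote fraction of the winning lineage path down to that
    rank, so confidences are non-increasing with depth.  The lineage is
    reported down to the deepest rank with confidence >= ``cutoff``.
    """
    if not reference.records:
        raise ValueError("empty taxonomy reference")
    rng = rng or np.random.default_rng()
    kmers = _kmer_set(seq.upper(), kmer)
    if not kmers:
        return {}, {}
    ref_ids = sorted(reference.records)
    ref_sets = {r: set(_kmer_set(reference.records[r], kmer)) for r in ref_ids}
    if not any(ref_sets[r] & set(kmers) for r in ref_ids):
        return {}, {}
    votes: list[dict[str, str]] = []
    for _ in range(n_boot):
        draw = rng.choice(len(kmers), size=subsample, replace=True)
        picked = [kmers[i] for i in draw]
        scores = [sum(km in ref_sets[r] for km in picked) for r in ref_ids]
        best = max(scores)
        ties = [r for r, s in zip(ref_ids, scores) if s == best]
        winner = ties[rng.integers(len(ties))] if len(ties) > 1 else ties[0]
        votes.append(reference.lineages[winner])
    # nested winning path: at each rank, the most voted label among votes
    # consistent with the already-chosen shallower path
    lineage: dict[str, str] = {}
    confidences: dict[str, float] = {}
    consistent = votes
    for rank in RANKS:
        labels = Counter(v.get(rank) for v in consistent if v.get(rank))
        if not labels:
            break
        label, _ = labels.most_common(1)[0]
        support = sum(1 for v in votes
                      if all(v.get(r) == lineage.get(r) for r in lineage)
                      and v.get(rank) == label) / n_boot
        lineage[rank] = label
        confidences[rank] = support
        consistent = [v for v in consistent if v.get(rank) == label]
    reported = {r: lineage[r] for r in lineage if confidences[r] >= cutoff}
    reported_conf = {r: confidences[r] for r in reported}
    return reported, reported_conf


def build_zotu_table(per_sample_zotus: dict[str, list[Zotu]]) -> list[Zotu]:
    """Merge per-library ZOTUs into one table keyed by exact sequence.

    Denoising is strictly per library; identity across samples is
    established by exact sequence match.  Returns pooled ZOTUs renumbered
    by descending total count.
    """
    pooled: dict[str, Zotu] = {}
    for sample, zotus in per_sample_zotus.items():
        for z in zotus:
            entry = pooled.setdefault(z.centroid_seq,
                                      Zotu("", z.centroid_seq, {}))
            for s, c in z.counts.items():
                key = s or sample
                entry.counts[key] = entry.counts.get(key, 0) + c
    ranked = sorted(pooled.values(), key=lambda z: (-z.total, z.centroid_seq))
    for i, z in enumerate(ranked):
        z.zotu_id = f"Zotu{i + 1}"
    return ranked
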