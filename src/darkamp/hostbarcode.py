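"""Host COI barcode designation, species clustering, and naming.

Each insect's barcode is the most abundant sequence within its dominant
arthropod OTU, subject to sample QC (>= 300 reads in the dominant OTU and
>= 95% of all arthropod reads).  Dereplicated barcodes (genotypes) are
clustered into species-level groups by average-linkage on p-distance with
a 3% cut; clusters that mix references of more than one named species are
flagged ambiguous rather than resolved.  Names are assigned at >= 97%
identity to a named reference, with genus/family fallback from the
k-mer classifier.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.cluster.hierarchy import average, fcluster
from scipy.spatial.distance import squareform
from scipy.stats import chi2

from .denoise import OtuMap, Zotu, pairwise_identity

__all__ = [
    "BarcodeRecord",
    "SpeciesAssignment",
    "select_barcode",
    "dereplicate_genotypes",
    "propose_species_clusters",
    "assign_name",
    "sex_ratio_test",
]

BARCODE_LENGTH = 418
MIN_DOMINANT_READS = 300
MIN_ARTHROPOD_RATIO = 0.95


@dataclass
class BarcodeRecord:
    sample_id: str
    barcode_seq: Optional[str]
    dominant_otu_reads: int
    arthropod_ratio: float
    passed: bool
    reject_reason: str = ""


@dataclass
class SpeciesAssignment:
    genotype_id: str
    species_cluster_id: int
    name: str
    name_level: str  # "species" | "genus" | "family" | "unassigned"
    name_identity: float
    ambiguous_flag: bool = False


def select_barcode(sample_id: str, zotus: Sequence[Zotu], otu_map: OtuMap,
                   is_arthropod: dict[str, bool],
                   min_dominant_reads: int = MIN_DOMINANT_READS,
                   min_ratio: float = MIN_ARTHROPOD_RATIO,
                   barcode_length: int = BARCODE_LENGTH) -> BarcodeRecord:
    """Designate one sample's barcode from its COI ZOTU counts.

    ``is_arthropod`` flags ZOTUs classified as Arthropoda; the table is
    assumed already stripped of chimeric and off-length sequences.
    """
    z_by_id = {z.zotu_id: z for z in zotus}
    otu_reads: dict[str, int] = {}
    for otu_id, members in otu_map.members.items():
        arth = [m for m in members if is_arthropod.get(m, False)]
        if not arth:
            continue
        reads = sum(z_by_id[m].counts.get(sample_id, 0) for m in arth)
        if reads > 0:
            otu_reads[otu_id] = reads
    total_arthropod = sum(otu_reads.values())
    if total_arthropod == 0:
        return BarcodeRecord(sample_id, None, 0, 0.0, False, "no_barcode")
    dominant = max(otu_reads, key=lambda o: (otu_reads[o], o))
    dom_reads = otu_reads[dominant]
    ratio = dom_reads / total_arthropod
    members = [m for m in otu_map.members[dominant] if is_arthropod.get(m, False)]
    barcode_zotu = max(members,
                       key=lambda m: (z_by_id[m].counts.get(sample_id, 0), m))
    seq = z_by_id[barcode_zotu].centroid_seq
    if dom_reads < min_dominant_reads:
        return BarcodeRecord(sample_id, seq, dom_reads, ratio, False, "low_reads")
    if ratio < min_ratio:
        return BarcodeRecord(sample_id, seq, dom_reads, ratio, False, "low_ratio")
    if len(seq) != barcode_length:
        return BarcodeRecord(sample_id, seq, dom_reads, ratio, False, "off_length")
    return BarcodeRecord(sample_id, seq, dom_reads, ratio, True)


def dereplicate_genotypes(records: Sequence[BarcodeRecord]) -> dict[str, list[str]]:
    """Group passing samples by exact barcode; genotype ids by abundance.

    Returns genotype_id -> sample ids; genotype numbering follows
    descending individual counts, ties by first occurrence.
    """
    groups: dict[str, list[str]] = {}
    order: list[str] = []
    for rec in records:
        if not rec.passed or rec.barcode_seq is None:
            continue
        if rec.barcode_seq not in groups:
            groups[rec.barcode_seq] = []
            order.append(rec.barcode_seq)
        groups[rec.barcode_seq].append(rec.sample_id)
    ranked = sorted(order, key=lambda s: (-len(groups[s]), order.index(s)))
    return {f"G{i + 1:04d}": groups[s] for i, s in enumerate(ranked)}


def p_distance(a: str, b: str, max_n_frac: float = 0.10) -> float:
    """Proportion of differing sites over positions where neither base is N.

    Returns NaN when more than ``max_n_frac`` of the compared length is
    masked by N in either sequence.
    """
    n = min(len(a), len(b))
    valid = [(x, y) for x, y in zip(a[:n], b[:n]) if x != "N" and y != "N"]
    if n == 0 or len(valid) < (1 - max_n_frac) * n:
        return float("nan")
    diffs = sum(1 for x, y in valid if x != y)
    return diffs / len(valid)


def propose_species_clusters(genotype_seqs: dict[str, str],
                             reference_seqs: dict[str, str] | None = None,
                             reference_species: dict[str, str] | None = None,
                             cut: float = 0.03) -> dict[str, tuple[int, bool]]:
    """Average-linkage clustering of genotypes (plus references) on p-distance.

    Clusters are cut at ``cut`` (3% by default).  A cluster joining
    references of more than one named species is flagged ambiguous — an
    automated stand-in for expert dendrogram review.  Returns
    genotype_id -> (cluster id, ambiguous flag).
    """
    reference_seqs = reference_seqs or {}
    reference_species = reference_species or {}
    ids = list(genotype_seqs) + list(reference_seqs)
    seqs = {**genotype_seqs, **reference_seqs}
    if len(ids) == 1:
        return {ids[0]: (1, False)} if ids[0] in genotype_seqs else {}
    m = len(ids)
    dist = np.zeros((m, m))
    for i in range(m):
        for j in range(i + 1, m):
            d = p_distance(seqs[ids[i]], seqs[ids[j]])
            # pairs with excessive N overlap: treated as maximally distant
            dist[i, j] = dist[j, i] = d if np.isfinite(d) else 1.0
    labels = fcluster(average(squareform(dist)), t=cut, criterion="distance")
    cluster_refs: dict[int, set[str]] = {}
    for idx, gid in enumerate(ids):
        if gid in reference_species:
            cluster_refs.setdefault(labels[idx], set()).add(reference_species[gid])
    out: dict[str, tuple[int, bool]] = {}
    for idx, gid in enumerate(ids):
        if gid in genotype_seqs:
            amb = len(cluster_refs.get(labels[idx], set())) > 1
            out[gid] = (int(labels[idx]), amb)
    return out


def assign_name(genotype_seq: str, named_refs: dict[str, str],
                ref_species: dict[str, str],
                classifier_lineage: dict[str, str] | None = None,
                min_identity: float = 0.97) -> tuple[str, str, float]:
    """Name a genotype from its best named reference.

    A species name requires >= ``min_identity`` global identity to a named
    reference; below that, the genus then family label from the k-mer
    classifier is used as a fallback.  Returns (name, level, identity).
    """
    best_id, best_ident = "", -1.0
    for rid in sorted(named_refs):
        ident = pairwise_identity(genotype_seq, named_refs[rid])
        if ident > best_ident:
            best_id, best_ident = rid, ident
    if best_ident >= min_identity and best_id:
        return ref_species[best_id], "species", best_ident
    lineage = classifier_lineage or {}
    if "genus" in lineage:
        return lineage["genus"], "genus", max(best_ident, 0.0)
    if "family" in lineage:
        return lineage["family"], "family", max(best_ident, 0.0)
    return "", "unassigned", max(best_ident, 0.0)


def sex_ratio_test(n_female: int, n_male: int) -> tuple[float, float]:
    """Chi-squared test (1 df) of departure from a 1:1 sex ratio."""
    n = n_female + n_male
    if n == 0:
        raise ValueError("no individuals")
    expected = n / 2
    stat = (n_female - expected) ** 2 / expected + (n_male - expected) ** 2 / expected
    p = float(chi2.sf(stat, df=1))
    return float(stat), p
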