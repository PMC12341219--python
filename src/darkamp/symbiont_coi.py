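"""Wolbachia strain tables from COI bycatch and 16S cross-checks.

Insect COI primers co-amplify the COI gene of alphaproteobacterial
endosymbionts; that bycatch is kept and turned into strain-level
(ZOTU/OTU) tables.  Presence is called from summed Wolbachia reads per
sample, and concordance with 16S-based detection is reported under
cutoffs chosen to exclude likely cross-contamination.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .denoise import OtuMap, Zotu, cluster_otus

__all__ = [
    "WolbachiaTable",
    "extract_wolbachia",
    "call_presence",
    "cross_marker_agreement",
]

WOLBACHIA_LENGTH = 418


@dataclass
class WolbachiaTable:
    """Read counts of Wolbachia COI ZOTUs across samples, with OTU map."""

    zotus: list[Zotu]
    otu_map: OtuMap
    table: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        if self.table.empty and self.zotus:
            samples = sorted({s for z in self.zotus for s in z.counts})
            self.table = pd.DataFrame(
                {s: [z.counts.get(s, 0) for z in self.zotus] for s in samples},
                index=[z.zotu_id for z in self.zotus],
            )


def extract_wolbachia(zotus: list[Zotu],
                      taxonomy: dict[str, dict[str, str]],
                      length: int = WOLBACHIA_LENGTH,
                      otu_identity: float = 0.97) -> WolbachiaTable:
    """Subset COI ZOTUs to Wolbachia and rebuild strain-level tables.

    Rickettsiales bycatch is narrowed to genus Wolbachia; chimeric
    sequences and those off the expected 418-bp length are discarded.
    """
    kept = []
    for z in zotus:
        lineage = taxonomy.get(z.zotu_id, {})
        if lineage.get("genus") != "Wolbachia":
            continue
        if z.chimera_flag or len(z.centroid_seq) != length:
            continue
        kept.append(z)
    otu_map = cluster_otus(kept, identity=otu_identity) if kept else OtuMap({})
    return WolbachiaTable(kept, otu_map)


def call_presence(table: pd.DataFrame, min_reads: int = 2) -> pd.Series:
    """Per-sample presence: summed Wolbachia reads >= ``min_reads``."""
    if table.empty:
        return pd.Series(dtype=bool)
    return table.sum(axis=0) >= min_reads


def cross_marker_agreement(coi_presence: pd.Series, s16_presence: pd.Series
                           ) -> tuple[float, pd.DataFrame, float]:
    """Concordance of COI- and 16S-based Wolbachia detection.

    Both series must cover the same samples.  Returns (simple agreement,
    2x2 contingency table, Cohen's kappa).
    """
    samples = coi_presence.index.intersection(s16_presence.index)
    if len(samples) == 0:
        raise ValueError("no shared samples between the two presence calls")
    a = coi_presence[samples].astype(bool)
    b = s16_presence[samples].astype(bool)
    n = len(samples)
    both = int((a & b).sum())
    neither = int((~a & ~b).sum())
    only_coi = int((a & ~b).sum())
    only_16s = int((~a & b).sum())
    ct = pd.DataFrame(
        [[both, only_coi], [only_16s, neither]],
        index=pd.Index([True, False], name="COI"),
        columns=pd.Index([True, False], name="16S"),
    )
    agreement = (both + neither) / n
    p_yes = ((both + only_coi) / n) * ((both + only_16s) / n)
    p_no = ((neither + only_16s) / n) * ((neither + only_coi) / n)
    pe = p_yes + p_no
    kappa = (agreement - pe) / (1 - pe) if pe < 1 else 1.0
    return agreement, ct, kappa
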