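"""Contamination filtering against blank libraries and spike-in handling.

The ratio rule (the QUACK rule) keeps a ZOTU only if its relative
abundance in at least one experimental sample is at least ``factor``
(default 5) times the maximum relative abundance seen in any blank.
Non-target taxa (Archaea, Eukaryota, chloroplast, mitochondria) and
flagged chimeras are stripped, and extraction spike-in reads are
tabulated per sample then removed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd

from .denoise import pairwise_identity

__all__ = [
    "ContaminantDecision",
    "to_percentages",
    "quack_filter",
    "remove_nontarget",
    "split_spikein",
]


@dataclass
class ContaminantDecision:
    zotu_id: str
    max_sample_pct: float
    max_blank_pct: float
    keep: bool
    reason: str  # ratio | archaea | eukaryota | chloroplast | mitochondria | chimera | spikein | kept


def to_percentages(table: pd.DataFrame) -> pd.DataFrame:
    """Column-wise relative abundances in percent (each column sums to 100).

    ``table`` has ZOTU rows and sample columns.  Empty columns are
    excluded with a warning.
    """
    sums = table.sum(axis=0)
    empty = sums[sums == 0].index.tolist()
    if empty:
        warnings.warn(f"excluding {len(empty)} empty sample column(s): {empty[:5]}")
    kept = table.drop(columns=empty)
    return 100.0 * kept / kept.sum(axis=0)


def quack_filter(pct: pd.DataFrame, experimental_ids: list[str],
                 blank_ids: list[str], factor: float = 5.0
                 ) -> list[ContaminantDecision]:
    """Keep a ZOTU iff some experimental percentage >= factor x max blank percentage.

    ZOTUs absent from every blank are kept whenever present in any
    experimental sample.  With no blanks supplied everything is kept and
    a loud warning issued.
    """
    overlap = set(experimental_ids) & set(blank_ids)
    if overlap:
        raise ValueError(f"samples in both experimental and blank sets: {sorted(overlap)[:5]}")
    exp = [s for s in experimental_ids if s in pct.columns]
    blk = [s for s in blank_ids if s in pct.columns]
    if not blk:
        warnings.warn("no blank libraries supplied: contamination rule skipped, "
                      "all ZOTUs kept")
    decisions = []
    for zotu_id, row in pct.iterrows():
        max_exp = float(row[exp].max()) if exp else 0.0
        max_blank = float(row[blk].max()) if blk else 0.0
        if max_blank == 0.0:
            keep = max_exp > 0.0
        else:
            keep = max_exp >= factor * max_blank
        decisions.append(ContaminantDecision(str(zotu_id), max_exp, max_blank,
                                             keep, "kept" if keep else "ratio"))
    return decisions


NONTARGET_DOMAINS = {"Archaea", "Eukaryota"}
NONTARGET_ORGANELLES = {"Chloroplast", "Mitochondria"}


def remove_nontarget(table: pd.DataFrame, taxonomy: dict[str, dict[str, str]],
                     chimera_flags: dict[str, bool] | None = None
                     ) -> tuple[pd.DataFrame, list[ContaminantDecision]]:
    """Strip Archaea, Eukaryota, chloroplast, mitochondria, and chimeras.

    Organelle 16S shows up under Chloroplast/Mitochondria labels at the
    order/family rank in standard references; any rank match triggers
    removal.
    """
    chimera_flags = chimera_flags or {}
    decisions = []
    drop = []
    for zotu_id in table.index:
        lineage = taxonomy.get(str(zotu_id), {})
        reason = None
        if chimera_flags.get(str(zotu_id), False):
            reason = "chimera"
        elif lineage.get("domain") in NONTARGET_DOMAINS:
            reason = lineage["domain"].lower()
        else:
            organelle = NONTARGET_ORGANELLES & set(lineage.values())
            if organelle:
                reason = sorted(organelle)[0].lower()
        if reason:
            drop.append(zotu_id)
            decisions.append(ContaminantDecision(str(zotu_id), 0.0, 0.0, False, reason))
    return table.drop(index=drop), decisions


def split_spikein(table: pd.DataFrame, zotu_seqs: dict[str, str],
                  spikein_seqs: dict[str, str], min_identity: float = 0.99
                  ) -> tuple[pd.DataFrame, pd.Series, list[str]]:
    """Identify spike-in ZOTUs, tabulate their reads, and drop them.

    ZOTUs matching a spike-in reference at >= ``min_identity`` are
    treated as spike-in.  Returns (table without spike-ins, per-sample
    spike-in read counts, spike-in zotu ids).  Samples with zero spike-in
    reads are flagged for discard downstream, not here.
    """
    spike_ids = []
    for zotu_id in table.index:
        seq = zotu_seqs.get(str(zotu_id), "")
        if seq and any(pairwise_identity(seq, ref) >= min_identity
                       for ref in spikein_seqs.values()):
            spike_ids.append(zotu_id)
    spike_counts = table.loc[spike_ids].sum(axis=0) if spike_ids else \
        pd.Series(0, index=table.columns)
    return table.drop(index=spike_ids), spike_counts, [str(z) for z in spike_ids]
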