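"""Spike-in-calibrated absolute 16S rRNA copy-number estimation.

Known numbers of synthetic template copies (10,000 or 20,000 per batch)
are added to one-fifth of each insect homogenate before purification, so
the estimated copy number of a ZOTU is

    copies = (zotu_reads / spike_reads) * C * f

with C the spike-in input copies and f the inverse homogenate fraction
(default 5).  Totals are sums over ZOTUs; richness summaries count taxa
at or above a copy threshold (default 100).
"""

from __future__ import annotations

import pandas as pd

__all__ = [
    "zotu_copies",
    "abundance_table",
    "sample_total",
    "richness_at_threshold",
]


def zotu_copies(zotu_reads: float, spike_reads: float, spikein_copies: float,
                homogenate_factor: float = 5.0) -> float:
    """Estimated 16S rRNA copies for one ZOTU in one sample."""
    if spike_reads <= 0:
        raise ValueError("sample without extraction spike-in reads must be discarded")
    return (zotu_reads / spike_reads) * spikein_copies * homogenate_factor


def abundance_table(reads: pd.DataFrame, spike_reads: pd.Series,
                    spikein_copies: pd.Series,
                    homogenate_factor: float = 5.0) -> pd.DataFrame:
    """Per-sample, per-ZOTU copy numbers from a read-count table.

    Samples with zero spike-in reads are dropped (they cannot be
    calibrated), mirroring the discard rule for such libraries.
    """
    common = [s for s in reads.columns if spike_reads.get(s, 0) > 0]
    scale = spikein_copies[common] * homogenate_factor / spike_reads[common]
    return reads[common] * scale


def sample_total(abundances: pd.DataFrame) -> pd.Series:
    """Total bacterial copies per sample (sum over ZOTUs)."""
    return abundances.sum(axis=0)


def aggregate_otus(abundances: pd.DataFrame,
                   zotu_to_otu: dict[str, str]) -> pd.DataFrame:
    """OTU-level copy numbers as sums over member ZOTUs."""
    groups = pd.Series({z: zotu_to_otu.get(str(z), str(z)) for z in abundances.index})
    return abundances.groupby(groups).sum()


def richness_at_threshold(abundances: pd.DataFrame,
                          min_copies: float = 100.0) -> pd.Series:
    """Per-sample count of taxa with >= ``min_copies`` estimated copies."""
    return (abundances >= min_copies).sum(axis=0)
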