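"""Primer-based splitting of mixed-target reads, pair merging, and QC filters.

Libraries contain a mixture of COI (BF3/BR2) and 16S-V4 (515F/806R)
amplicons, with variable-length heterogeneity spacers between the adapter
and the primer.  Reads are assigned to a target when both mates carry the
target's primers, primers and spacers are trimmed, mates are merged on
their best ungapped overlap, and merged contigs are filtered on the
expected length window and on low-quality runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np

__all__ = [
    "ReadPair",
    "PrimerScheme",
    "MergedContig",
    "PrimerMatch",
    "match_primer",
    "split_reads",
    "merge_pair",
    "qc_filter",
    "revcomp",
    "DEFAULT_SCHEMES",
    "LENGTH_WINDOWS",
]

# IUPAC nucleotide codes -> the set of bases each matches.
IUPAC = {
    "A": {"A"}, "C": {"C"}, "G": {"G"}, "T": {"T"},
    "R": {"A", "G"}, "Y": {"C", "T"}, "S": {"C", "G"}, "W": {"A", "T"},
    "K": {"G", "T"}, "M": {"A", "C"},
    "B": {"C", "G", "T"}, "D": {"A", "G", "T"},
    "H": {"A", "C", "T"}, "V": {"A", "C", "G"},
    "N": {"A", "C", "G", "T"},
}

_COMP = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def revcomp(seq: str) -> str:
    """Reverse complement of an IUPAC nucleotide string."""
    return seq.translate(_COMP)[::-1]


@dataclass
class ReadPair:
    """One paired-end read with per-base Phred qualities."""

    read_id: str
    fwd_seq: str
    rev_seq: str
    fwd_qual: list[int]
    rev_qual: list[int]

    def __post_init__(self) -> None:
        if len(self.fwd_seq) != len(self.fwd_qual) or len(self.rev_seq) != len(self.rev_qual):
            raise ValueError(f"{self.read_id}: sequence/quality length mismatch")


@dataclass(frozen=True)
class PrimerScheme:
    """Primer pair for one amplicon target.

    ``max_spacer_len`` allows variable-length heterogeneity inserts before
    the primer; ``max_mismatches`` is the per-primer tolerance under
    IUPAC-compatible comparison.
    """

    target_id: str
    fwd_primer: str
    rev_primer: str
    max_spacer_len: int = 7
    max_mismatches: int = 1

    def __post_init__(self) -> None:
        for p in (self.fwd_primer, self.rev_primer):
            if not p:
                raise ValueError("empty primer")
            bad = set(p) - set(IUPAC)
            if bad:
                raise ValueError(f"invalid IUPAC code(s) {sorted(bad)} in primer {p!r}")
        if self.max_spacer_len < 0:
            raise ValueError("max_spacer_len must be >= 0")


# Primer sequences of the two study targets: 16S-V4 (515F/806R) and a
# 418-bp COI fragment (BF3/BR2).
DEFAULT_SCHEMES = [
    PrimerScheme("16S-V4", "GTGYCAGCMGCCGCGGTAA", "GGACTACNVGGGTWTCTAAT"),
    PrimerScheme("COI", "CCHGAYATRGCHTTYCCHCG", "TCDGGRTGNCCRAARAAYCA"),
]

# Expected merged-contig length windows per target (inclusive).
LENGTH_WINDOWS = {"COI": (400, 430), "16S-V4": (250, 260)}


@dataclass(frozen=True)
class PrimerMatch:
    offset: int
    mismatches: int


def _mismatches(window: str, primer: str) -> int:
    n = 0
    for base, code in zip(window, primer):
        if base not in IUPAC[code]:
            n += 1
    return n


import functools
import re as _re


@functools.lru_cache(maxsize=64)
def _primer_regex(primer: str):
    return _re.compile("".join("[%s]" % "".join(sorted(IUPAC[c])) for c in primer))


def match_primer(seq: str, primer: str, max_spacer: int = 7,
                 max_mm: int = 1) -> Optional[PrimerMatch]:
    """Locate ``primer`` near the 5' end of ``seq``.

    Offsets 0..max_spacer are scanned; among offsets with at most
    ``max_mm`` IUPAC-compatible mismatches the one with the fewest
    mismatches wins, ties going to the smaller offset.  Returns ``None``
    when no offset qualifies.
    """
    bad = set(primer) - set(IUPAC)
    if bad:
        raise ValueError(f"invalid IUPAC code(s) {sorted(bad)} in primer {primer!r}")
    k = len(primer)
    # exact-offset fast path: a 0-mismatch hit always wins
    m = _primer_regex(primer).search(seq, 0, min(len(seq), max_spacer + k))
    if m is not None and m.start() <= max_spacer:
        return PrimerMatch(m.start(), 0)
    if max_mm == 0:
        return None
    best: Optional[PrimerMatch] = None
    for off in range(min(max_spacer, max(len(seq) - k, 0)) + 1):
        window = seq[off:off + k]
        if len(window) < k:
            break
        mm = _mismatches(window, primer)
        if mm <= max_mm and (best is None or mm < best.mismatches):
            best = PrimerMatch(off, mm)
    return best


@dataclass
class SplitResult:
    """Per-target primer-trimmed read pairs plus the unassigned bin."""

    bins: dict[str, list[ReadPair]]
    unassigned: list[ReadPair]
    counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.counts = {t: len(v) for t, v in self.bins.items()}
        self.counts["unassigned"] = len(self.unassigned)


def _try_assign(pair: ReadPair, scheme: PrimerScheme) -> Optional[ReadPair]:
    """Trimmed pair if both mates carry the scheme's primers, else None.

    Reads are assumed forward-primer-on-R1; a rescue pass with swapped
    mate roles is attempted before giving up.
    """
    for fwd_seq, rev_seq, fwd_q, rev_q in (
        (pair.fwd_seq, pair.rev_seq, pair.fwd_qual, pair.rev_qual),
        (pair.rev_seq, pair.fwd_seq, pair.rev_qual, pair.fwd_qual),
    ):
        mf = match_primer(fwd_seq, scheme.fwd_primer,
                          scheme.max_spacer_len, scheme.max_mismatches)
        mr = match_primer(rev_seq, scheme.rev_primer,
                          scheme.max_spacer_len, scheme.max_mismatches)
        if mf is not None and mr is not None:
            fa = mf.offset + len(scheme.fwd_primer)
            ra = mr.offset + len(scheme.rev_primer)
            return ReadPair(pair.read_id, fwd_seq[fa:], rev_seq[ra:],
                            fwd_q[fa:], rev_q[ra:])
    return None


def split_reads(pairs: Iterable[ReadPair],
                schemes: list[PrimerScheme] | None = None) -> SplitResult:
    """Assign each pair to at most one target by primer recognition.

    A pair whose mates match primers of different targets, or no target at
    all, lands in the unassigned bin.  Primers and spacers are removed
    from assigned reads.
    """
    if schemes is None:
        schemes = DEFAULT_SCHEMES
    bins: dict[str, list[ReadPair]] = {s.target_id: [] for s in schemes}
    unassigned: list[ReadPair] = []
    for pair in pairs:
        hits = [(s.target_id, trimmed)
                for s in schemes
                if (trimmed := _try_assign(pair, s)) is not None]
        if len(hits) == 1:
            target, trimmed = hits[0]
            bins[target].append(trimmed)
        else:
            unassigned.append(pair)
    return SplitResult(bins, unassigned)


@dataclass
class MergedContig:
    sample_id: str
    target_id: str
    seq: str
    qual: list[int]
    overlap_len: int


def merge_pair(pair: ReadPair, min_overlap: int = 20,
               max_mismatch_frac: float = 0.25,
               sample_id: str = "", target_id: str = "") -> Optional[MergedContig]:
    """Merge a primer-trimmed pair on the best ungapped overlap.

    The reverse mate is reverse-complemented and slid against the 3' end
    of the forward mate; the overlap maximising (matches - mismatches) is
    taken.  At mismatching positions the higher-quality base wins; at
    matching positions the consensus quality is the max of the two.
    Returns ``None`` when no overlap of at least ``min_overlap`` bases
    stays within ``max_mismatch_frac``.
    """
    fwd, rc_rev = pair.fwd_seq, revcomp(pair.rev_seq)
    rc_qual = pair.rev_qual[::-1]
    best = None  # (score, overlap)
    max_ov = min(len(fwd), len(rc_rev))
    fa = np.frombuffer(fwd.encode(), dtype=np.uint8)
    ba = np.frombuffer(rc_rev.encode(), dtype=np.uint8)
    for ov in range(min_overlap, max_ov + 1):
        n_mism = int((fa[len(fwd) - ov:] != ba[:ov]).sum())
        if n_mism / ov > max_mismatch_frac:
            continue
        score = ov - 2 * n_mism
        if best is None or score > best[0]:
            best = (score, ov)
    if best is None:
        return None
    _, ov = best
    start = len(fwd) - ov
    seq = list(fwd)
    qual = list(pair.fwd_qual)
    for i in range(ov):
        qa, qb = pair.fwd_qual[start + i], rc_qual[i]
        if fwd[start + i] != rc_rev[i]:
            if qb > qa:
                seq[start + i] = rc_rev[i]
                qual[start + i] = qb
        else:
            qual[start + i] = max(qa, qb)
    seq_str = "".join(seq) + rc_rev[ov:]
    qual_full = qual + rc_qual[ov:]
    return MergedContig(sample_id, target_id or "unknown", seq_str, qual_full, ov)


def qc_filter(contig: MergedContig, target_id: str | None = None,
              length_windows: dict[str, tuple[int, int]] | None = None,
              q_threshold: int = 30, run_length: int = 3) -> tuple[bool, str]:
    """Length-window and low-quality-run filter for merged contigs.

    A contig is rejected when its length falls outside the target's
    expected window, or when it contains a run of at least ``run_length``
    consecutive bases with Phred quality <= ``q_threshold``.
    Returns (keep, reason) with reason one of {"ok", "length", "quality"}.
    """
    target = target_id or contig.target_id
    windows = length_windows or LENGTH_WINDOWS
    if target not in windows:
        raise ValueError(f"unknown target {target!r}")
    lo, hi = windows[target]
    if not lo <= len(contig.seq) <= hi:
        return False, "length"
    run = 0
    for q in contig.qual:
        run = run + 1 if q <= q_threshold else 0
        if run >= run_length:
            return False, "quality"
    return True, "ok"
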