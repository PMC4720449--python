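"""Evaluation computations for synthetic long reads.

Covers the custom N50 statistic, truth-fragment alignment with positional
mismatch/indel profiles, end trimming, GC distribution, coverage evenness,
dual-parent mixture classification (chimera detection), and probe-count
haplotype-phasing regression.

The N50 used throughout is defined over synthetic reads of at least
``min_len`` bases: the first length at which the cumulative sum of
descending-sorted lengths reaches half the total. "Longer than 1 kb" is
implemented inclusively as ``>= min_len`` with min_len = 1000.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, Optional, Sequence

import edlib
import numpy as np
import pandas as pd

from .align import AlignmentStats, align_ends_free, local_align, shared_kmer_count
from .assembly import SyntheticRead
from .barcodes import BarcodeGroup
from .io import SequenceRecord, reverse_complement

__all__ = [
    "n50",
    "AlignmentResult",
    "align_to_truth",
    "mismatch_profile",
    "end_trim",
    "gc_distribution",
    "coverage_evenness",
    "local_align",
    "MixtureCall",
    "classify_mixture",
    "probe_counts",
    "phasing_regression",
]


def n50(lengths: Iterable[int], min_len: int = 1000) -> int:
    """Length L such that reads of length >= L hold half the total bases.

    Only lengths >= ``min_len`` participate. Returns 0 for empty input.
    """
    kept = sorted((int(x) for x in lengths if x >= min_len), reverse=True)
    if not kept:
        return 0
    half = sum(kept) / 2.0
    running = 0
    for length in kept:
        running += length
        if running >= half:
            return length
    return kept[-1]


@dataclass(slots=True)
class AlignmentResult:
    """A query aligned to its truth target, with binned positional errors."""

    query_id: str
    target_id: str
    query_length: int
    stats: AlignmentStats

    @property
    def mismatch_rate(self) -> float:
        return self.stats.mismatch_rate


def align_to_truth(
    read: SyntheticRead | SequenceRecord,
    truth_fragment: str,
    truth_id: str = "truth",
    band: float = 0.05,
) -> Optional[AlignmentResult]:
    """Banded ends-free alignment of a synthetic read to its truth fragment.

    Both strands are tried; returns None when no 31-mer is shared with either
    strand (unalignable).
    """
    stats = align_ends_free(read.sequence, truth_fragment, band=band)
    if stats is None:
        return None
    return AlignmentResult(read.id, truth_id, len(read.sequence), stats)


def mismatch_profile(
    results: Sequence[AlignmentResult], bins: int = 100
) -> pd.DataFrame:
    """Per-relative-position mismatch and indel rates across alignments.

    Each aligned query position p of a read of length L maps to bin
    floor(bins * p / L); the mismatch rate per bin is mismatches over aligned
    positions in that bin. Total mismatches are conserved across bins.
    """
    mm = np.zeros(bins, dtype=np.int64)
    pos = np.zeros(bins, dtype=np.int64)
    ins = np.zeros(bins, dtype=np.int64)
    dels = np.zeros(bins, dtype=np.int64)
    for res in results:
        L = res.query_length
        s = res.stats
        if len(s.query_positions):
            b = np.minimum((bins * s.query_positions) // L, bins - 1)
            np.add.at(pos, b, 1)
            np.add.at(mm, b[s.mismatch_flags], 1)
        if len(s.insertion_positions):
            b = np.minimum((bins * s.insertion_positions) // L, bins - 1)
            np.add.at(ins, b, 1)
        if len(s.deletion_positions):
            b = np.minimum(
                (bins * np.minimum(s.deletion_positions, L - 1)) // L, bins - 1
            )
            np.add.at(dels, b, 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        rate = np.where(pos > 0, mm / np.maximum(pos, 1), 0.0)
        ins_rate = np.where(pos > 0, ins / np.maximum(pos, 1), 0.0)
        del_rate = np.where(pos > 0, dels / np.maximum(pos, 1), 0.0)
    return pd.DataFrame(
        {
            "bin": np.arange(bins),
            "aligned_positions": pos,
            "mismatches": mm,
            "mismatch_rate": rate,
            "insertions": ins,
            "insertion_rate": ins_rate,
            "deletions": dels,
            "deletion_rate": del_rate,
        }
    )


def end_trim(reads: Sequence[SyntheticRead], n: int = 100) -> list[SyntheticRead]:
    """Remove n bases from each end; drop reads that would fall to <= 0."""
    out = []
    for r in reads:
        if len(r.sequence) <= 2 * n:
            continue
        out.append(
            SyntheticRead(
                id=r.id,
                sequence=r.sequence[n : len(r.sequence) - n] if n else r.sequence,
                group_key=r.group_key,
                read_pair_count=r.read_pair_count,
                contig_count=r.contig_count,
                mean_coverage=r.mean_coverage,
                primary=r.primary,
            )
        )
    return out


def gc_distribution(reads: Iterable[SequenceRecord | SyntheticRead]) -> pd.DataFrame:
    """GC fraction per read binned at 1% resolution."""
    fracs = []
    for r in reads:
        seq = r.sequence
        if seq:
            fracs.append((seq.count("G") + seq.count("C")) / len(seq))
    counts, edges = np.histogram(fracs, bins=np.linspace(0.0, 1.0, 101))
    return pd.DataFrame({"gc_low": edges[:-1], "gc_high": edges[1:], "count": counts})


def _locate_read(seq: str, fragment: str, max_frac: float = 0.2) -> Optional[tuple[int, int]]:
    """Best infix placement of a read in a fragment (either strand), via edlib."""
    best = None
    k = int(max_frac * len(seq))
    for s in (seq, reverse_complement(seq)):
        res = edlib.align(s, fragment, mode="HW", task="locations", k=k)
        if res["editDistance"] >= 0 and res["locations"]:
            if best is None or res["editDistance"] < best[0]:
                a, b = res["locations"][0]
                best = (res["editDistance"], a, b + 1)
    if best is None:
        return None
    return best[1], best[2]


def coverage_evenness(
    group: BarcodeGroup, truth_fragment: str, flank: int = 20
) -> tuple[np.ndarray, float]:
    """Per-position coverage of the truth fragment plus its CV.

    Reads are placed by infix edit-distance alignment on either strand.
    The coefficient of variation (sd/mean) is computed over the fragment
    interior, excluding ``flank`` bases at each end (the adapter-proximal
    positions the protocol covers trivially).
    """
    cov = np.zeros(len(truth_fragment), dtype=np.int64)
    for read in group.reads:
        loc = _locate_read(read.sequence, truth_fragment)
        if loc is not None:
            cov[loc[0] : loc[1]] += 1
    interior = cov[flank : len(cov) - flank] if len(cov) > 2 * flank else cov
    mean = interior.mean() if len(interior) else 0.0
    cv = float(interior.std() / mean) if mean > 0 else float("nan")
    return cov, cv


@dataclass(slots=True)
class MixtureCall:
    """Dual-alignment classification of one synthetic read."""

    read_id: str
    rate_parent1: float
    rate_parent2: float
    call: str  # "parent1" | "parent2" | "ambiguous"


def classify_mixture(
    read: SyntheticRead | SequenceRecord,
    parent1: str,
    parent2: str,
    assign_max: float = 0.01,
    margin_min: float = 0.01,
) -> MixtureCall:
    """Assign a read to one of two parent variants by dual local alignment.

    The mismatch rate against each parent is 1 - identity over the aligned
    span of a Smith–Waterman alignment. The lower-rate parent is called iff
    its rate is at most ``assign_max`` and the other parent's rate exceeds it
    by at least ``margin_min``; otherwise the read is ambiguous (the
    signature of a chimera or a badly assembled read).
    """
    seq = read.sequence
    # orient the read once, using shared-k-mer support against both parents
    fwd = shared_kmer_count(seq, parent1) + shared_kmer_count(seq, parent2)
    rc = reverse_complement(seq)
    rev = shared_kmer_count(rc, parent1) + shared_kmer_count(rc, parent2)
    if rev > fwd:
        seq = rc
    rates = []
    for parent in (parent1, parent2):
        stats = local_align(seq, parent)
        rates.append(1.0 - stats.identity if stats.aligned_length else 1.0)
    r1, r2 = rates
    call = "ambiguous"
    if r1 < r2 and r1 <= assign_max and (r2 - r1) >= margin_min:
        call = "parent1"
    elif r2 < r1 and r2 <= assign_max and (r1 - r2) >= margin_min:
        call = "parent2"
    return MixtureCall(read.id, r1, r2, call)


def probe_counts(
    groups: Dict[str, BarcodeGroup], probes: Sequence[SequenceRecord]
) -> pd.DataFrame:
    """Exact occurrence counts of each probe (and its reverse complement)
    across the payload reads of each group; rows = groups, columns = probes."""
    data = {}
    texts = {key: "\n".join(r.sequence for r in g.reads) for key, g in groups.items()}
    for probe in probes:
        fwd, rev = probe.sequence, reverse_complement(probe.sequence)
        col = []
        for key in texts:
            text = texts[key]
            c = text.count(fwd)
            if rev != fwd:
                c += text.count(rev)
            col.append(c)
        data[probe.id] = col
    return pd.DataFrame(data, index=list(texts))


@dataclass(slots=True)
class PhasingRegression:
    slope: float
    intercept: float
    r_squared: Optional[float]  # None when the response is constant

    @property
    def defined(self) -> bool:
        return self.r_squared is not None


def phasing_regression(
    counts: pd.DataFrame, x_probe: str, y_probe: str
) -> PhasingRegression:
    """Ordinary least squares of probe-count y on x across barcode groups."""
    x = counts[x_probe].to_numpy(dtype=float)
    y = counts[y_probe].to_numpy(dtype=float)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    if len(x) < 2 or float(((x - x.mean()) ** 2).sum()) == 0.0:
        return PhasingRegression(float("nan"), float("nan"), None)
    slope, intercept = np.polyfit(x, y, 1)
    if ss_tot == 0.0:
        return PhasingRegression(float(slope), float(intercept), None)
    resid = y - (slope * x + intercept)
    r2 = 1.0 - float((resid**2).sum()) / ss_tot
    return PhasingRegression(float(slope), float(intercept), r2)
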