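"""From raw read pairs to barcode-defined read groups.

The stages mirror the read-preparation half of the protocol: 3'-end quality
trimming (the 5' end holds the barcode and is never trimmed), merging of
overlapping pairs, barcode/index extraction with demultiplexing, exact-text
grouping, and greedy Hamming-distance collapse of spurious barcodes created
by sequencing errors in the barcode region.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, Optional, Sequence, Union

import numpy as np

from .io import SequenceRecord, reverse_complement

REJECT_SHORT = "short"
REJECT_N_IN_BARCODE = "n_in_barcode"
REJECT_ANCHOR = "anchor_mismatch"
REJECT_INDEX = "index_unassigned"


@dataclass(slots=True)
class AdapterSpec:
    """Layout of the forward-read prefix: [barcode][index?][anchor][payload]."""

    barcode_length: int = 18
    index_length: int = 0
    anchor: str = "CC"
    anchor_max_mismatch: int = 1
    index_table: dict[str, str] = field(default_factory=dict)  # index seq -> sample

    def __post_init__(self) -> None:
        if not self.anchor:
            raise ValueError("anchor must be non-empty")
        if self.barcode_length < 8:
            raise ValueError("barcode_length must be >= 8")
        for idx in self.index_table:
            if len(idx) != self.index_length:
                raise ValueError(f"index {idx!r} does not match index_length")

    def prefix_length(self) -> int:
        return self.barcode_length + self.index_length + len(self.anchor)


@dataclass(slots=True)
class Extraction:
    """Outcome of barcode extraction; rejection is a value, not an exception."""

    barcode: Optional[str]
    sample: str
    payload: Optional[SequenceRecord]
    reject_reason: Optional[str] = None

    @property
    def ok(self) -> bool:
        return self.reject_reason is None


@dataclass
class BarcodeGroup:
    """All payload reads extracted with one exact barcode."""

    barcode: str
    sample: str = ""
    reads: list[SequenceRecord] = field(default_factory=list)
    read_pair_count: int = 0


def quality_trim(
    record: SequenceRecord,
    q_threshold: int = 20,
    window: int = 4,
    min_len: int = 30,
) -> Optional[SequenceRecord]:
    """Sliding-window 3' quality trim; returns None when the read is rejected.

    Scans non-overlapping windows of ``window`` bases from the 3' end inward
    and cuts after the first (i.e. most 3') window whose mean quality reaches
    the threshold. The 5' end is never touched because the barcode lives
    there.
    """
    if record.quality is None:
        raise ValueError(f"record {record.id!r} has no qualities to trim on")
    q = record.quality
    n = len(q)
    if n < window:
        return record if n >= min_len else None
    target = q_threshold * window
    end = 0
    for e in range(n, window - 1, -window):
        if sum(q[e - window : e]) >= target:
            end = e
            break
    if end < min_len:
        return None
    if end == n:
        return record
    qual = q[:end] if not isinstance(q, list) else q[:end]
    return SequenceRecord(record.id, record.sequence[:end], qual)


def _overlap_matches(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """matches[o] = matching bases when the last o of ``a`` overlap the first o of ``b``."""
    n1, n2 = len(a), len(b)
    total = np.zeros(n1 + n2 - 1, dtype=np.int32)
    for base in b"ACGT":
        ia = (a == base).astype(np.int32)
        ib = (b == base).astype(np.int32)
        total += np.correlate(ia, ib, "full")
    max_o = min(n1, n2)
    out = np.zeros(max_o + 1, dtype=np.int32)
    # full correlation index n1 + n2 - 1 - o corresponds to overlap o
    out[1:] = total[n1 + n2 - 1 - max_o : n1 + n2 - 1][::-1]
    return out


def merge_read_pair(
    r1: SequenceRecord,
    r2: SequenceRecord,
    min_overlap: int = 10,
    max_mismatch_frac: float = 0.25,
) -> Union[SequenceRecord, tuple[SequenceRecord, SequenceRecord]]:
    """Merge an overlapping pair into one record, or return the pair unchanged.

    The reverse read is reverse-complemented and the overlap minimizing the
    mismatch fraction (ties broken toward the longer overlap) is accepted if
    it reaches ``min_overlap`` bases at a mismatch fraction at most
    ``max_mismatch_frac``. Overlap bases are resolved toward the higher
    quality, ties toward the forward read.
    """
    if not r1.sequence or not r2.sequence:
        return r1, r2
    rc2 = r2.reverse_complement()
    a = np.frombuffer(r1.sequence.encode("ascii"), dtype=np.uint8)
    b = np.frombuffer(rc2.sequence.encode("ascii"), dtype=np.uint8)
    matches = _overlap_matches(a, b)
    max_o = min(len(a), len(b))
    if max_o < min_overlap:
        return r1, r2
    o_arr = np.arange(min_overlap, max_o + 1)
    fracs = (o_arr - matches[min_overlap:]) / o_arr
    # minimize mismatch fraction; ties broken toward the longer overlap
    best_idx = len(fracs) - 1 - int(np.argmin(fracs[::-1]))
    best_o, best_frac = int(o_arr[best_idx]), float(fracs[best_idx])
    if best_frac > max_mismatch_frac:
        return r1, r2
    o = best_o
    n1 = len(r1.sequence)
    left = r1.sequence[: n1 - o]
    right = rc2.sequence[o:]
    q1 = r1.quality
    q2 = rc2.quality
    overlap_chars = []
    overlap_quals = bytearray()
    for i in range(o):
        c1, c2 = r1.sequence[n1 - o + i], rc2.sequence[i]
        qa = q1[n1 - o + i] if q1 is not None else 0
        qb = q2[i] if q2 is not None else 0
        overlap_chars.append(c2 if qb > qa else c1)
        overlap_quals.append(max(qa, qb))
    seq = left + "".join(overlap_chars) + right
    quality: Optional[bytes] = None
    if q1 is not None and q2 is not None:
        quality = bytes(q1[: n1 - o]) + bytes(overlap_quals) + bytes(q2[o:])
    return SequenceRecord(r1.id, seq, quality)


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def extract_barcode(record: SequenceRecord, spec: AdapterSpec) -> Extraction:
    """Split a forward read into barcode, sample (via index), and payload."""
    B = spec.barcode_length
    if len(record.sequence) <= spec.prefix_length():
        return Extraction(None, "", None, REJECT_SHORT)
    barcode = record.sequence[:B]
    if "N" in barcode:
        return Extraction(None, "", None, REJECT_N_IN_BARCODE)
    pos = B
    sample = ""
    if spec.index_length:
        index = record.sequence[pos : pos + spec.index_length]
        best: list[str] = []
        best_d = spec.index_length + 1
        for key, name in spec.index_table.items():
            d = _hamming(index, key)
            if d < best_d:
                best, best_d = [name], d
            elif d == best_d:
                best.append(name)
        if best_d > 1 or len(best) != 1:
            return Extraction(barcode, "", None, REJECT_INDEX)
        sample = best[0]
        pos += spec.index_length
    anchor_obs = record.sequence[pos : pos + len(spec.anchor)]
    if _hamming(anchor_obs, spec.anchor) > spec.anchor_max_mismatch:
        return Extraction(barcode, sample, None, REJECT_ANCHOR)
    pos += len(spec.anchor)
    payload = SequenceRecord(
        record.id,
        record.sequence[pos:],
        None if record.quality is None else record.quality[pos:],
    )
    return Extraction(barcode, sample, payload, None)


def group_by_barcode(
    items: Iterable[tuple[str, str, Sequence[SequenceRecord]]]
) -> Dict[str, BarcodeGroup]:
    """Partition extracted read units into groups keyed by exact barcode text.

    Each item is one read unit (a merged single or a surviving pair):
    (barcode, sample, payload records). Every item lands in exactly one group.
    """
    groups: Dict[str, BarcodeGroup] = {}
    for barcode, sample, reads in items:
        group = groups.get(barcode)
        if group is None:
            group = groups[barcode] = BarcodeGroup(barcode=barcode, sample=sample)
        group.reads.extend(reads)
        group.read_pair_count += 1
    return groups


def filter_groups(
    groups: Dict[str, BarcodeGroup], min_read_pairs: int = 50
) -> Dict[str, BarcodeGroup]:
    """Keep groups with at least ``min_read_pairs`` read pairs."""
    return {bc: g for bc, g in groups.items() if g.read_pair_count >= min_read_pairs}


def collapse_hamming(items: Dict[str, int], max_dist: int = 2) -> list[str]:
    """Greedy longest-first collapse of near-duplicate barcodes.

    Barcodes are processed in decreasing order of their associated length
    (ties broken lexicographically); a barcode survives iff no already-kept
    barcode lies within Hamming distance ``max_dist``. Spurious barcodes —
    sequencing-error copies of a real barcode — thereby collapse onto the
    barcode with the longer associated synthetic read. Idempotent.
    """
    if not items:
        return []
    lengths = {len(bc) for bc in items}
    if len(lengths) != 1:
        raise ValueError(f"barcodes of unequal lengths: {sorted(lengths)}")
    (bc_len,) = lengths
    order = sorted(items, key=lambda bc: (-items[bc], bc))
    mat = np.frombuffer("".join(order).encode("ascii"), dtype=np.uint8).reshape(
        len(order), bc_len
    )
    kept_rows = np.empty((len(order), bc_len), dtype=np.uint8)
    n_kept = 0
    kept: list[str] = []
    for i, bc in enumerate(order):
        if n_kept:
            dists = (kept_rows[:n_kept] != mat[i]).sum(axis=1)
            if int(dists.min()) <= max_dist:
                continue
        kept_rows[n_kept] = mat[i]
        n_kept += 1
        kept.append(bc)
    return kept


@dataclass
class GroupingStats:
    """Counts accumulated while turning read pairs into groups."""

    pairs_in: int = 0
    pairs_trimmed_away: int = 0
    merged: int = 0
    rejections: dict[str, int] = field(default_factory=dict)
    accepted: int = 0


def build_groups(
    read_pairs: Iterable[tuple[SequenceRecord, SequenceRecord]],
    spec: AdapterSpec,
    q_threshold: int = 20,
    trim_window: int = 4,
    min_len: int = 30,
    min_overlap: int = 10,
    max_mismatch_frac: float = 0.25,
) -> tuple[Dict[str, BarcodeGroup], GroupingStats]:
    """Run trim -> merge -> extract -> group over a stream of read pairs.

    The forward read carries the adapter prefix, so its minimum retained
    length is the prefix plus ``min_len`` payload bases.
    """
    stats = GroupingStats()
    items = []
    r1_min = spec.prefix_length() + min_len
    for r1, r2 in read_pairs:
        stats.pairs_in += 1
        r1t = quality_trim(r1, q_threshold, trim_window, r1_min)
        if r1t is None:
            stats.pairs_trimmed_away += 1
            continue
        r2t = quality_trim(r2, q_threshold, trim_window, min_len)
        if r2t is None:
            merged: Union[SequenceRecord, tuple] = r1t
        else:
            merged = merge_read_pair(r1t, r2t, min_overlap, max_mismatch_frac)
        if isinstance(merged, SequenceRecord):
            if r2t is not None:
                stats.merged += 1
            extraction = extract_barcode(merged, spec)
            payload = [extraction.payload] if extraction.ok else []
        else:
            extraction = extract_barcode(r1t, spec)
            payload = [extraction.payload, r2t] if extraction.ok else []
        if not extraction.ok:
            stats.rejections[extraction.reject_reason] = (
                stats.rejections.get(extraction.reject_reason, 0) + 1
            )
            continue
        stats.accepted += 1
        items.append((extraction.barcode, extraction.sample, payload))
    return group_by_barcode(items), stats
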