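"""Per-group de novo micro-assembly of barcode read groups.

Each barcode group holds a few hundred short reads drawn from one molecule of
at most ~20 kb, so a single-k bidirected de Bruijn graph with abundance
filtering, tip clipping and simple bubble popping is sufficient to recover
the molecule as one contig. K-mers are counted in canonical form (the
lexicographically smaller of a k-mer and its reverse complement) because the
two read groups of a molecule observe the fragment from opposite ends and
strands.

An external-assembler seam accepts any command that maps a group FASTQ to a
contig FASTA, for parity experiments against full assemblers.
"""

from __future__ import annotations

import shlex
import subprocess
import tempfile
from concurrent.futures import ProcessPoolExecutor
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Iterable, Optional, Sequence

import numpy as np

from .barcodes import BarcodeGroup
from .errors import ConfigurationError
from .io import SequenceRecord, read_fasta, reverse_complement, write_fastq

_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i
_DECODE = "ACGT"


@dataclass(slots=True)
class AssemblyParams:
    k: int = 31
    min_kmer_count: int = 2
    min_contig_len: int = 1000
    tip_max_len: Optional[int] = None  # default 2k
    bubble_max_len: Optional[int] = None  # default 2k + 10
    external_assembler: Optional[str] = None

    def __post_init__(self) -> None:
        if self.k % 2 == 0 or not 15 <= self.k <= 63:
            raise ConfigurationError("k must be odd and in [15, 63]")
        if min(self.min_kmer_count, self.min_contig_len) < 0:
            raise ConfigurationError("thresholds must be >= 0")

    @property
    def tip_len(self) -> int:
        return self.tip_max_len if self.tip_max_len is not None else 2 * self.k

    @property
    def bubble_len(self) -> int:
        return self.bubble_max_len if self.bubble_max_len is not None else 2 * self.k + 10


@dataclass(slots=True)
class Contig:
    sequence: str
    mean_coverage: float

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(slots=True)
class SyntheticRead:
    """An assembled consensus with provenance."""

    id: str
    sequence: str
    group_key: str
    read_pair_count: int
    contig_count: int
    mean_coverage: float
    primary: bool

    def __len__(self) -> int:
        return len(self.sequence)


# ---------------------------------------------------------------------------
# k-mer machinery (2-bit packed, canonical orientation)


def encode_sequence(seq: str) -> np.ndarray:
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def _revcomp_py(x: int, k: int) -> int:
    y = 0
    for _ in range(k):
        y = (y << 2) | (3 - (x & 3))
        x >>= 2
    return y


def _revcomp_kmers(kmers: np.ndarray, k: int) -> np.ndarray:
    """Reverse-complement 2-bit packed k-mers (vectorized bit shuffle).

    k > 31 exceeds a 64-bit word; those use arbitrary-precision integers.
    """
    if k > 31 or kmers.dtype != np.uint64:
        return np.array([_revcomp_py(int(x), k) for x in kmers], dtype=object)
    x = (~kmers).astype(np.uint64)
    m2 = np.uint64(0x3333333333333333)
    m4 = np.uint64(0x0F0F0F0F0F0F0F0F)
    m8 = np.uint64(0x00FF00FF00FF00FF)
    m16 = np.uint64(0x0000FFFF0000FFFF)
    x = ((x >> np.uint64(2)) & m2) | ((x & m2) << np.uint64(2))
    x = ((x >> np.uint64(4)) & m4) | ((x & m4) << np.uint64(4))
    x = ((x >> np.uint64(8)) & m8) | ((x & m8) << np.uint64(8))
    x = ((x >> np.uint64(16)) & m16) | ((x & m16) << np.uint64(16))
    x = (x >> np.uint64(32)) | (x << np.uint64(32))
    return x >> np.uint64(64 - 2 * k)


def count_kmers(reads: Iterable[str], k: int) -> tuple[np.ndarray, np.ndarray]:
    """Canonical k-mer counts over all reads; windows containing N are skipped."""
    if k > 31:
        return _count_kmers_wide(reads, k)
    pieces = []
    sep = np.array([4], dtype=np.uint8)
    for seq in reads:
        if len(seq) >= k:
            pieces.append(encode_sequence(seq))
            pieces.append(sep)
    if not pieces:
        return np.empty(0, dtype=np.uint64), np.empty(0, dtype=np.int64)
    codes = np.concatenate(pieces)
    n = len(codes)
    windows = np.lib.stride_tricks.sliding_window_view(codes, k)
    valid = (windows != 4).all(axis=1)
    w = windows[valid].astype(np.uint64)
    if len(w) == 0:
        return np.empty(0, dtype=np.uint64), np.empty(0, dtype=np.int64)
    shifts = (np.uint64(2) * np.arange(k - 1, -1, -1, dtype=np.uint64)).astype(np.uint64)
    kmers = (w << shifts).sum(axis=1, dtype=np.uint64)
    rc = _revcomp_kmers(kmers, k)
    canon = np.minimum(kmers, rc)
    uniq, counts = np.unique(canon, return_counts=True)
    return uniq, counts


def _count_kmers_wide(reads: Iterable[str], k: int) -> tuple[np.ndarray, np.ndarray]:
    """Arbitrary-precision counting path for k > 31 (2k bits > one word)."""
    from collections import Counter

    counter: Counter = Counter()
    mask = (1 << (2 * k)) - 1
    for seq in reads:
        codes = encode_sequence(seq)
        x = 0
        run = 0  # clean bases accumulated since the last N
        for c in codes:
            if c == 4:
                run = 0
                x = 0
                continue
            x = ((x << 2) | int(c)) & mask
            run += 1
            if run >= k:
                counter[min(x, _revcomp_py(x, k))] += 1
    if not counter:
        return np.empty(0, dtype=object), np.empty(0, dtype=np.int64)
    keys = sorted(counter)
    return (
        np.array(keys, dtype=object),
        np.array([counter[key] for key in keys], dtype=np.int64),
    )


def decode_kmer(x: int, k: int) -> str:
    return "".join(_DECODE[(x >> (2 * (k - 1 - i))) & 3] for i in range(k))


def _revcomp_int(x: int, k: int) -> int:
    return int(_revcomp_kmers(np.array([x], dtype=np.uint64), k)[0])


class _Graph:
    """Bidirected de Bruijn graph over a canonical k-mer set.

    Orientation handling is precomputed: ``canon_of`` maps both orientations
    of every surviving k-mer to its canonical form, so the hot neighbor
    queries are plain dict lookups.
    """

    def __init__(self, canon_kmers: np.ndarray, counts: np.ndarray, k: int) -> None:
        self.k = k
        self.mask = (1 << (2 * k)) - 1
        self.high = 2 * (k - 1)
        rc = _revcomp_kmers(canon_kmers, k)
        self.counts: Dict[int, int] = {
            int(c): int(n) for c, n in zip(canon_kmers, counts)
        }
        self.canon_of: Dict[int, int] = {}
        self.rc_of: Dict[int, int] = {}
        for c, r in zip(canon_kmers.tolist(), rc.tolist()):
            self.canon_of[c] = c
            self.canon_of[r] = c
            self.rc_of[c] = r
            self.rc_of[r] = c

    def canon(self, x: int) -> int:
        return self.canon_of[x]

    def present(self, x: int) -> bool:
        return x in self.canon_of

    def successors(self, x: int) -> list[int]:
        base = (x << 2) & self.mask
        return [base | b for b in range(4) if (base | b) in self.canon_of]

    def predecessors(self, x: int) -> list[int]:
        base = x >> 2
        return [
            base | (b << self.high)
            for b in range(4)
            if (base | (b << self.high)) in self.canon_of
        ]

    def remove(self, canon_kmers: Iterable[int]) -> None:
        for c in canon_kmers:
            if c in self.counts:
                r = self.rc_of[c]
                del self.counts[c]
                self.canon_of.pop(c, None)
                self.canon_of.pop(r, None)
                self.rc_of.pop(c, None)
                self.rc_of.pop(r, None)


@dataclass(slots=True)
class _Unitig:
    path: list[int]  # oriented k-mers
    sequence: str
    coverage: float

    def __len__(self) -> int:
        return len(self.sequence)


def _build_unitigs(graph: _Graph) -> list[_Unitig]:
    k = graph.k
    visited: set[int] = set()
    unitigs: list[_Unitig] = []
    for start in sorted(graph.counts):
        if start in visited:
            continue
        path = [start]
        in_path = {start}
        # forward extension
        x = start
        while True:
            succ = graph.successors(x)
            if len(succ) != 1:
                break
            y = succ[0]
            if len(graph.predecessors(y)) != 1:
                break
            cy = graph.canon(y)
            if cy in in_path or cy in visited:
                break
            path.append(y)
            in_path.add(cy)
            x = y
        # backward extension
        x = start
        while True:
            pred = graph.predecessors(x)
            if len(pred) != 1:
                break
            y = pred[0]
            if len(graph.successors(y)) != 1:
                break
            cy = graph.canon(y)
            if cy in in_path or cy in visited:
                break
            path.insert(0, y)
            in_path.add(cy)
            x = y
        visited |= in_path
        seq = decode_kmer(path[0], k) + "".join(
            _DECODE[p & 3] for p in path[1:]
        )
        cov = float(np.mean([graph.counts[graph.canon(p)] for p in path]))
        unitigs.append(_Unitig(path, seq, cov))
    return unitigs


def _clip_tips(graph: _Graph, unitigs: list[_Unitig], tip_max: int) -> int:
    """Remove short dead-end unitigs that hang off a junction. Returns count."""
    clipped = 0
    for u in unitigs:
        if len(u.sequence) > tip_max:
            continue
        first, last = u.path[0], u.path[-1]
        fwd_succ = graph.successors(last)
        back_pred = graph.predecessors(first)
        # exclude self (single-kmer unitigs may see themselves via palindromic wrap)
        dead_fwd = len(fwd_succ) == 0
        dead_back = len(back_pred) == 0
        if dead_fwd == dead_back:
            continue  # either isolated or internal: not a tip
        junction = back_pred[0] if dead_fwd else fwd_succ[0]
        # an alternative continuation must exist at the junction
        if dead_fwd:
            alt = len(graph.successors(junction)) >= 2
        else:
            alt = len(graph.predecessors(junction)) >= 2
        if alt:
            graph.remove(graph.canon(p) for p in u.path)
            clipped += 1
    return clipped


def _pop_bubbles(graph: _Graph, unitigs: list[_Unitig], bubble_max: int) -> int:
    """Pop simple bubbles: parallel short unitigs between the same junctions."""
    candidates: Dict[tuple[int, int], list[_Unitig]] = {}
    for u in unitigs:
        if len(u.sequence) > bubble_max:
            continue
        preds = graph.predecessors(u.path[0])
        succs = graph.successors(u.path[-1])
        if len(preds) != 1 or len(succs) != 1:
            continue
        a, b = preds[0], succs[0]
        key = (a, b)
        alt_key = (graph.rc_of[b], graph.rc_of[a])
        key = min(key, alt_key)
        candidates.setdefault(key, []).append(u)
    popped = 0
    for key in sorted(candidates):
        group = candidates[key]
        if len(group) < 2:
            continue
        group.sort(key=lambda u: (-u.coverage, u.sequence))
        for u in group[1:]:
            graph.remove(graph.canon(p) for p in u.path)
            popped += 1
    return popped


def assemble_group(group: BarcodeGroup, params: AssemblyParams) -> list[Contig]:
    """Assemble one read group into contigs with mean k-mer coverage.

    Deterministic: contigs are reported in canonical orientation (the
    lexicographically smaller of the contig and its reverse complement),
    sorted by decreasing length then sequence.
    """
    if params.external_assembler:
        return _assemble_external(group, params)
    reads = [r.sequence for r in group.reads]
    uniq, counts = count_kmers(reads, params.k)
    keep = counts >= params.min_kmer_count
    if not keep.any():
        return []
    graph = _Graph(uniq[keep], counts[keep], params.k)
    for _ in range(8):
        unitigs = _build_unitigs(graph)
        if _clip_tips(graph, unitigs, params.tip_len) == 0:
            break
    for _ in range(8):
        unitigs = _build_unitigs(graph)
        if _pop_bubbles(graph, unitigs, params.bubble_len) == 0:
            break
    unitigs = _build_unitigs(graph)
    contigs = []
    for u in unitigs:
        rc = reverse_complement(u.sequence)
        seq = u.sequence if u.sequence <= rc else rc
        contigs.append(Contig(seq, u.coverage))
    contigs.sort(key=lambda c: (-len(c.sequence), c.sequence))
    return contigs


def _assemble_external(group: BarcodeGroup, params: AssemblyParams) -> list[Contig]:
    """Run an external assembler command mapping group FASTQ -> contig FASTA.

    The command is formatted with {reads} and {contigs} placeholders.
    """
    with tempfile.TemporaryDirectory() as tmp:
        reads_path = Path(tmp) / "reads.fastq"
        contigs_path = Path(tmp) / "contigs.fasta"
        records = [
            SequenceRecord(f"r{i}", r.sequence, r.quality or bytes([30]) * len(r.sequence))
            for i, r in enumerate(group.reads)
        ]
        write_fastq(records, reads_path)
        cmd = params.external_assembler.format(reads=reads_path, contigs=contigs_path)
        subprocess.run(shlex.split(cmd), check=True, capture_output=True)
        contigs = []
        if contigs_path.exists():
            for rec in read_fasta(contigs_path):
                rc = reverse_complement(rec.sequence)
                seq = rec.sequence if rec.sequence <= rc else rc
                contigs.append(Contig(seq, float("nan")))
        contigs.sort(key=lambda c: (-len(c.sequence), c.sequence))
        return contigs


def select_synthetic_reads(
    contigs: Sequence[Contig],
    params: AssemblyParams,
    group_key: str = "group",
    read_pair_count: int = 0,
) -> list[SyntheticRead]:
    """Keep contigs of at least ``min_contig_len``; the longest is primary."""
    kept = [c for c in contigs if len(c.sequence) >= params.min_contig_len]
    out = []
    for i, c in enumerate(kept):
        out.append(
            SyntheticRead(
                id=f"{group_key}.{i}",
                sequence=c.sequence,
                group_key=group_key,
                read_pair_count=read_pair_count,
                contig_count=len(kept),
                mean_coverage=c.mean_coverage,
                primary=(i == 0),
            )
        )
    return out


def _assemble_one(item: tuple[str, BarcodeGroup, AssemblyParams]):
    key, group, params = item
    contigs = assemble_group(group, params)
    return key, select_synthetic_reads(contigs, params, key, group.read_pair_count)


def assemble_all(
    groups: Dict[str, BarcodeGroup],
    params: AssemblyParams,
    workers: int = 1,
) -> tuple[list[SyntheticRead], list[tuple[str, str]]]:
    """Assemble every group independently; failures are logged, never fatal.

    Output is order-normalized (sorted by group key) and identical for any
    worker count.
    """
    items = [(key, groups[key], params) for key in sorted(groups)]
    results: list[SyntheticRead] = []
    log: list[tuple[str, str]] = []
    if workers > 1:
        with ProcessPoolExecutor(max_workers=workers) as pool:
            for (key, _, _), outcome in zip(
                items, pool.map(_assemble_one_safe, items, chunksize=8)
            ):
                if isinstance(outcome, str):
                    log.append((key, outcome))
                else:
                    results.extend(outcome[1])
                    log.append((key, f"ok:{len(outcome[1])}"))
    else:
        for item in items:
            outcome = _assemble_one_safe(item)
            if isinstance(outcome, str):
                log.append((item[0], outcome))
            else:
                results.extend(outcome[1])
                log.append((item[0], f"ok:{len(outcome[1])}"))
    return results, log


def _assemble_one_safe(item):
    try:
        return _assemble_one(item)
    except Exception as exc:  # per-group isolation
        return f"error:{type(exc).__name__}:{exc}"
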