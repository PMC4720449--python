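"""Recovering the two-barcodes-per-molecule structure from pairing reads.

A pairing read carries the two barcodes of one circularized molecule joined
by a constant spacer. Parsed barcode pairs are accumulated into a weighted
co-occurrence graph; disjoint pairs are resolved with a strict mutual-best
rule so that one erroneous pairing read can never fuse two molecules, and
the corresponding read groups are merged under a canonical key.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Dict, Iterable, Optional

from .barcodes import AdapterSpec, BarcodeGroup, _hamming
from .io import SequenceRecord, reverse_complement


@dataclass
class PairingGraph:
    """Symmetric co-occurrence counts between barcodes (no self-pairs)."""

    counts: Counter = field(default_factory=Counter)
    dropped_self_pairs: int = 0

    @staticmethod
    def _key(a: str, b: str) -> tuple[str, str]:
        return (a, b) if a <= b else (b, a)

    def add(self, a: str, b: str, n: int = 1) -> None:
        if a == b:
            self.dropped_self_pairs += n
            return
        self.counts[self._key(a, b)] += n

    def count(self, a: str, b: str) -> int:
        return self.counts.get(self._key(a, b), 0)

    def __len__(self) -> int:
        return len(self.counts)


def parse_pairing_read(
    record: SequenceRecord,
    spec: AdapterSpec,
    spacer: str,
    spacer_max_mismatch: int = 2,
    reverse_layout: bool = False,
) -> Optional[tuple[str, str]]:
    """Extract (barcodeA, barcodeB) from a pairing read, or None on rejection.

    Layout: barcodeA + spacer + revcomp(barcodeB). ``reverse_layout`` accepts
    the single-tube chemistry variant in which the whole product is read from
    the opposite strand; the information content is identical.
    """
    seq = record.sequence
    if reverse_layout:
        seq = reverse_complement(seq)
    B = spec.barcode_length
    if len(seq) < 2 * B + len(spacer):
        return None
    bc_a = seq[:B]
    spacer_obs = seq[B : B + len(spacer)]
    bc_b = reverse_complement(seq[B + len(spacer) : 2 * B + len(spacer)])
    if "N" in bc_a or "N" in bc_b:
        return None
    if _hamming(spacer_obs, spacer) > spacer_max_mismatch:
        return None
    return bc_a, bc_b


def build_cooccurrence(pairs: Iterable[tuple[str, str]]) -> PairingGraph:
    """Aggregate parsed barcode pairs into a symmetric count graph."""
    graph = PairingGraph()
    for a, b in pairs:
        graph.add(a, b)
    return graph


@dataclass
class ResolvedPairs:
    """Disjoint barcode pairs plus diagnostics on conflicted barcodes."""

    pairs: list[tuple[str, str]] = field(default_factory=list)
    conflicts: list[tuple[str, str, int, str, int]] = field(default_factory=list)

    def partner_map(self) -> Dict[str, str]:
        out: Dict[str, str] = {}
        for a, b in self.pairs:
            out[a] = b
            out[b] = a
        return out


def resolve_pairs(
    graph: PairingGraph, min_count: int = 2, require_mutual_best: bool = True
) -> ResolvedPairs:
    """Resolve disjoint barcode pairs from the co-occurrence graph.

    An edge (A, B) with count >= ``min_count`` is accepted iff B is A's
    strict-maximum-count neighbor and vice versa; ties leave both barcodes
    unpaired. Strict mutual best makes accepted edges disjoint by
    construction. Barcodes whose top two edge counts are within a factor of
    two are reported as conflicts (possible barcode collisions).
    """
    neighbors: Dict[str, list[tuple[str, int]]] = defaultdict(list)
    for (a, b), n in graph.counts.items():
        if n >= min_count:
            neighbors[a].append((b, n))
            neighbors[b].append((a, n))

    def strict_best(bc: str) -> Optional[tuple[str, int]]:
        edges = neighbors.get(bc, [])
        if not edges:
            return None
        edges_sorted = sorted(edges, key=lambda e: (-e[1], e[0]))
        if len(edges_sorted) > 1 and edges_sorted[0][1] == edges_sorted[1][1]:
            return None  # tie: leave unpaired
        return edges_sorted[0]

    resolved = ResolvedPairs()
    for bc in sorted(neighbors):
        edges_sorted = sorted(neighbors[bc], key=lambda e: (-e[1], e[0]))
        if len(edges_sorted) > 1 and edges_sorted[0][1] < 2 * edges_sorted[1][1]:
            resolved.conflicts.append(
                (bc, edges_sorted[0][0], edges_sorted[0][1], edges_sorted[1][0], edges_sorted[1][1])
            )
    seen: set[str] = set()
    for a in sorted(neighbors):
        if a in seen:
            continue
        best_a = strict_best(a)
        if best_a is None:
            continue
        b = best_a[0]
        if not require_mutual_best:
            if b not in seen:
                resolved.pairs.append((a, b) if a <= b else (b, a))
                seen.update((a, b))
            continue
        best_b = strict_best(b)
        if best_b is not None and best_b[0] == a:
            resolved.pairs.append((a, b) if a <= b else (b, a))
            seen.update((a, b))
    return resolved


def canonical_pair_key(a: str, b: str) -> str:
    return f"{a}|{b}" if a <= b else f"{b}|{a}"


def merge_groups(
    groups: Dict[str, BarcodeGroup], resolved: ResolvedPairs
) -> Dict[str, BarcodeGroup]:
    """Concatenate the two groups of each resolved pair under a canonical key.

    Unpaired groups pass through unchanged; the total read count is conserved.
    A pair whose barcodes both lack groups contributes nothing.
    """
    partner = resolved.partner_map()
    merged: Dict[str, BarcodeGroup] = {}
    done: set[str] = set()
    for bc, group in groups.items():
        if bc in done:
            continue
        other = partner.get(bc)
        if other is None or other not in groups:
            merged[bc] = group
            done.add(bc)
            continue
        other_group = groups[other]
        key = canonical_pair_key(bc, other)
        first, second = (group, other_group) if bc <= other else (other_group, group)
        merged[key] = BarcodeGroup(
            barcode=key,
            sample=first.sample or second.sample,
            reads=first.reads + second.reads,
            read_pair_count=first.read_pair_count + second.read_pair_count,
        )
        done.update((bc, other))
    return merged
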