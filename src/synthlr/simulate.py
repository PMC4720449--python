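"""Generative model of the barcoded circularization library protocol.

The simulator reproduces the statistical structure that the wet-lab protocol
imposes on short reads, so that every downstream stage (grouping, pairing,
assembly, QC) can be exercised against known ground truth:

* each target fragment receives two distinct degenerate barcodes, one per end;
* PCR produces many copies of the fragment, each carrying independent
  substitution errors with a transition bias;
* each copy suffers a Poisson number of enzymatic breaks; circularization
  joins the newly exposed internal end to the barcode at the *opposite* end
  of the piece, so sequencing reads start at the barcode and run from the
  break inward — coverage therefore decays with distance from the barcoded
  end, and the two barcodes of one molecule cover complementary ends;
* copies with zero breaks re-circularize into barcode-pairing products that
  carry both barcodes around a constant spacer, emitted as a small fraction
  of the library;
* sequencing adds uniform substitution errors over the full read, including
  the barcode region.

All randomness flows from one top-level seed through named per-molecule
substreams, so per-molecule output is stable under reordering.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, Optional, Sequence

import numpy as np

from .errors import ConfigurationError
from .io import (
    MoleculeTruth,
    SequenceRecord,
    reverse_complement,
    write_fastq,
    write_truth_table,
)

BASES = "ACGT"
_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
_TRANSVERSIONS = {"A": "CT", "G": "CT", "C": "AG", "T": "AG"}

#: Constant spacer joining the two barcodes in a pairing read.
DEFAULT_SPACER = "CTGAGTCGGAGACACGCAGG"


@dataclass(slots=True)
class SimulationConfig:
    """Parameters of the simulated library.

    Fragment lengths follow a lognormal with the given mean and sd in bases,
    truncated to [fragment_min, fragment_max]. ``copies_per_molecule`` is the
    mean of a Poisson; ``break_lambda`` the mean number of enzymatic breaks
    per copy. Substitution rates are per base; ``transition_fraction`` is the
    share of PCR substitutions that are transitions.
    """

    reference_path: Optional[str] = None
    random_reference_length: int = 1_000_000
    gc_fraction: float = 0.5
    n_molecules: int = 200
    fragment_mean: float = 8000.0
    fragment_sd: float = 1000.0
    fragment_min: int = 6000
    fragment_max: int = 10000
    barcode_length: int = 18
    index_length: int = 0
    sample_indexes: dict[str, str] = field(default_factory=dict)
    anchor: str = "CC"
    copies_per_molecule: float = 300.0
    break_lambda: float = 1.0
    pcr_sub_rate: float = 2e-4
    transition_fraction: float = 0.756
    seq_sub_rate: float = 1e-3
    read_length: int = 150
    insert_mean: float = 500.0
    insert_sd: float = 50.0
    insert_min: Optional[int] = None
    pairing_read_fraction: float = 0.03
    spacer: str = DEFAULT_SPACER
    high_quality: int = 37
    low_quality: int = 2
    low_tail_prob: float = 0.05
    seed: int = 0

    def prefix_length(self) -> int:
        return self.barcode_length + self.index_length + len(self.anchor)

    def effective_insert_min(self) -> int:
        if self.insert_min is not None:
            return self.insert_min
        return max(1, 2 * self.read_length - 50)

    def validate(self) -> None:
        for name in ("pcr_sub_rate", "seq_sub_rate", "transition_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name}={v} outside [0, 1]")
        if self.barcode_length < 8:
            raise ConfigurationError("barcode_length must be >= 8")
        if not 0.0 <= self.pairing_read_fraction <= 0.2:
            raise ConfigurationError("pairing_read_fraction outside [0, 0.2]")
        if self.index_length not in (0, 6):
            raise ConfigurationError("index_length must be 0 or 6")
        if self.index_length and not self.sample_indexes:
            raise ConfigurationError("index_length set but no sample_indexes given")
        for sample, idx in self.sample_indexes.items():
            if len(idx) != self.index_length:
                raise ConfigurationError(
                    f"index for sample {sample!r} has length {len(idx)}, "
                    f"expected {self.index_length}"
                )
        if not self.anchor:
            raise ConfigurationError("anchor must be non-empty")
        if self.read_length <= self.prefix_length():
            raise ConfigurationError("read_length leaves no payload after the adapter prefix")
        if not 0 < self.fragment_min <= self.fragment_max:
            raise ConfigurationError("invalid fragment length bounds")
        if self.fragment_min < 2 * self.read_length:
            raise ConfigurationError("fragment_min must be at least twice the read length")


@dataclass(slots=True)
class JunctionConstruct:
    """One circularization junction: a barcode joined to a break position.

    ``side`` names which end barcode the junction carries; ``junction_pos``
    is a 0-based offset into the fragment. ``copy_errors`` are the PCR
    substitutions of the originating copy as (offset, original, new).
    """

    molecule_id: str
    side: str  # "left" | "right"
    barcode: str
    junction_pos: int
    copy_errors: list[tuple[int, str, str]]


def make_random_reference(length: int, gc_fraction: float, seed: int) -> SequenceRecord:
    """i.i.d. random reference with P(G) + P(C) = gc_fraction, split evenly."""
    if length < 1:
        raise ConfigurationError("reference length must be >= 1")
    if not 0.0 <= gc_fraction <= 1.0:
        raise ConfigurationError("gc_fraction outside [0, 1]")
    rng = np.random.default_rng(seed)
    at = (1.0 - gc_fraction) / 2.0
    gc = gc_fraction / 2.0
    codes = rng.choice(4, size=length, p=[at, gc, gc, at])
    seq = codes.astype(np.uint8)
    lut = np.frombuffer(b"ACGT", dtype=np.uint8)
    return SequenceRecord("random_ref", lut[seq].tobytes().decode("ascii"))


def make_variant(sequence: str, divergence: float, seed: int) -> str:
    """Substitute a ``divergence`` fraction of positions (uniform alternatives).

    Used to build pairs of known parent variants for mixture experiments.
    """
    if not 0.0 <= divergence <= 1.0:
        raise ConfigurationError("divergence outside [0, 1]")
    rng = np.random.default_rng(seed)
    n_sub = int(round(divergence * len(sequence)))
    positions = rng.choice(len(sequence), size=n_sub, replace=False)
    chars = list(sequence)
    for pos in positions:
        alt = BASES.replace(chars[pos], "") if chars[pos] in BASES else BASES
        chars[pos] = alt[int(rng.integers(0, len(alt)))]
    return "".join(chars)


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    if sd <= 0:
        return math.log(mean), 0.0
    sigma2 = math.log(1.0 + (sd / mean) ** 2)
    mu = math.log(mean) - sigma2 / 2.0
    return mu, math.sqrt(sigma2)


def _random_barcode(rng: np.random.Generator, length: int) -> str:
    return "".join(BASES[b] for b in rng.integers(0, 4, size=length))


def draw_fragments(
    reference: SequenceRecord, config: SimulationConfig, rng: np.random.Generator
) -> list[tuple[MoleculeTruth, str]]:
    """Draw fragments with uniform placement and truncated-lognormal lengths.

    All 2 * n_molecules barcodes are pairwise distinct (collisions resampled).
    """
    ref_len = len(reference.sequence)
    if ref_len < config.fragment_min:
        raise ConfigurationError(
            f"reference ({ref_len} bp) shorter than minimum fragment ({config.fragment_min} bp)"
        )
    mu, sigma = _lognormal_params(config.fragment_mean, config.fragment_sd)
    seen_barcodes: set[str] = set()
    samples = list(config.sample_indexes.items())
    out: list[tuple[MoleculeTruth, str]] = []
    for i in range(config.n_molecules):
        frag_max = min(config.fragment_max, ref_len)
        if config.fragment_min == frag_max:
            length = frag_max
        else:
            while True:
                length = int(round(rng.lognormal(mu, sigma))) if sigma > 0 else int(
                    round(config.fragment_mean)
                )
                if config.fragment_min <= length <= frag_max:
                    break
        start = int(rng.integers(0, ref_len - length + 1))
        barcodes = []
        while len(barcodes) < 2:
            bc = _random_barcode(rng, config.barcode_length)
            if bc not in seen_barcodes:
                seen_barcodes.add(bc)
                barcodes.append(bc)
        sample_index = samples[i % len(samples)][1] if samples else ""
        truth = MoleculeTruth(
            molecule_id=f"mol{i:05d}",
            sample_index=sample_index,
            ref_id=reference.id,
            start=start,
            end=start + length,
            barcode_left=barcodes[0],
            barcode_right=barcodes[1],
        )
        out.append((truth, reference.sequence[start : start + length]))
    return out


def _draw_copy_errors(
    rng: np.random.Generator, fragment: str, config: SimulationConfig
) -> list[tuple[int, str, str]]:
    n = rng.binomial(len(fragment), config.pcr_sub_rate)
    if n == 0:
        return []
    errors = []
    for off in rng.integers(0, len(fragment), size=n):
        off = int(off)
        orig = fragment[off]
        if rng.random() < config.transition_fraction:
            new = _TRANSITION[orig]
        else:
            new = _TRANSVERSIONS[orig][int(rng.integers(0, 2))]
        errors.append((off, orig, new))
    return errors


def simulate_copies_and_breaks(
    molecule: MoleculeTruth,
    fragment: str,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> list[JunctionConstruct]:
    """PCR-copy and break one molecule into junction constructs.

    Each copy carries independent PCR substitutions and a Poisson number of
    breaks. Copies with no break yield no junction construct (they become
    pairing-read sources); broken copies yield exactly two constructs, the
    left barcode joined to the leftmost break and the right barcode joined to
    the rightmost (interior pieces carry no barcode and are discarded).
    """
    L = len(fragment)
    if L < 2 * config.read_length:
        raise ConfigurationError(
            f"fragment {molecule.molecule_id} shorter than twice the read length"
        )
    n_copies = int(rng.poisson(config.copies_per_molecule))
    constructs: list[JunctionConstruct] = []
    ks = rng.poisson(config.break_lambda, size=n_copies)
    for k in ks:
        if k == 0:
            continue
        errors = _draw_copy_errors(rng, fragment, config)
        breaks = rng.integers(1, L, size=int(k))
        p_min, p_max = int(breaks.min()), int(breaks.max())
        constructs.append(
            JunctionConstruct(molecule.molecule_id, "left", molecule.barcode_left, p_min, errors)
        )
        constructs.append(
            JunctionConstruct(molecule.molecule_id, "right", molecule.barcode_right, p_max, errors)
        )
    return constructs


def _mutated_window(
    fragment: str, a: int, b: int, copy_errors: Sequence[tuple[int, str, str]]
) -> str:
    window = fragment[a:b]
    hits = [(off - a, new) for off, _, new in copy_errors if a <= off < b]
    if not hits:
        return window
    chars = list(window)
    for pos, new in hits:
        chars[pos] = new
    return "".join(chars)


def _apply_seq_errors(seq: str, rng: np.random.Generator, rate: float) -> str:
    if rate <= 0.0 or not seq:
        return seq
    n = rng.binomial(len(seq), rate)
    if n == 0:
        return seq
    chars = list(seq)
    for pos in rng.integers(0, len(seq), size=n):
        pos = int(pos)
        alt = BASES.replace(chars[pos], "") if chars[pos] in BASES else BASES
        chars[pos] = alt[int(rng.integers(0, len(alt)))]
    return "".join(chars)


def _qualities(
    n: int, rng: np.random.Generator, config: SimulationConfig
) -> bytes:
    qual = bytearray([config.high_quality]) * n
    if config.low_tail_prob > 0 and rng.random() < config.low_tail_prob:
        t = min(n, int(rng.integers(5, 26)))
        qual[n - t :] = bytes([config.low_quality]) * t
    return bytes(qual)


def emit_read_pair(
    construct: JunctionConstruct,
    fragment: str,
    config: SimulationConfig,
    rng: np.random.Generator,
    sample_index: str = "",
    pair_id: str = "",
) -> Optional[tuple[SequenceRecord, SequenceRecord]]:
    """Emit one paired-end read from a junction construct.

    The sequenced insert runs from the junction into the barcode-bearing
    piece and is clipped at the piece boundary (the barcoded end) rather
    than wrapping. The forward read is [barcode][index?][anchor][payload];
    the reverse read is the opposite end of the insert, reverse-complemented,
    and never extends into the adapter prefix (adapter read-through is not
    modeled). PCR copy errors, then sequencing errors, are applied.
    """
    L = len(fragment)
    p = construct.junction_pos
    available = p if construct.side == "left" else L - p
    if available < 1:
        return None
    insert_len = int(round(rng.normal(config.insert_mean, config.insert_sd)))
    insert_len = max(config.effective_insert_min(), insert_len)
    pl = min(insert_len, available)
    if construct.side == "left":
        payload = reverse_complement(_mutated_window(fragment, p - pl, p, construct.copy_errors))
    else:
        payload = _mutated_window(fragment, p, p + pl, construct.copy_errors)
    prefix = construct.barcode + sample_index + config.anchor
    insert = prefix + payload
    R = config.read_length
    r1_seq = insert[:R]
    if len(insert) - R < len(prefix):
        r2_seq = reverse_complement(insert[len(prefix) :])[:R]
    else:
        r2_seq = reverse_complement(insert)[:R]
    if not r2_seq:
        return None
    r1_seq = _apply_seq_errors(r1_seq, rng, config.seq_sub_rate)
    r2_seq = _apply_seq_errors(r2_seq, rng, config.seq_sub_rate)
    rid = pair_id or f"{construct.molecule_id}|{construct.side}|{p}"
    r1 = SequenceRecord(rid, r1_seq, _qualities(len(r1_seq), rng, config))
    r2 = SequenceRecord(rid, r2_seq, _qualities(len(r2_seq), rng, config))
    return r1, r2


def emit_pairing_reads(
    truths: Sequence[MoleculeTruth],
    config: SimulationConfig,
    rng: np.random.Generator,
    main_record_count: int,
) -> list[SequenceRecord]:
    """Emit barcode-pairing reads: barcode_left + spacer + revcomp(barcode_right).

    The count is chosen so pairing reads make up ``pairing_read_fraction`` of
    all emitted read records; reads are allocated to molecules uniformly at
    random, which at default settings gives every molecule a pairing read
    with overwhelming probability.
    """
    f = config.pairing_read_fraction
    if f <= 0.0 or not truths:
        return []
    n_pairing = int(round(main_record_count * f / (1.0 - f)))
    n_pairing = max(n_pairing, len(truths) * 8 if main_record_count else 0)
    counts = rng.multinomial(n_pairing, [1.0 / len(truths)] * len(truths))
    out: list[SequenceRecord] = []
    for truth, count in zip(truths, counts):
        core = truth.barcode_left + config.spacer + reverse_complement(truth.barcode_right)
        for j in range(int(count)):
            seq = _apply_seq_errors(core, rng, config.seq_sub_rate)
            out.append(
                SequenceRecord(
                    f"{truth.molecule_id}|pairing|{j}",
                    seq,
                    bytes([config.high_quality]) * len(seq),
                )
            )
    return out


class SimulatedLibrary:
    """A fully specified simulated library: truth plus lazily emitted reads.

    Reads are regenerated deterministically from per-molecule substreams on
    every iteration, so the library can be streamed several times without
    holding all reads in memory.
    """

    def __init__(
        self,
        config: SimulationConfig,
        reference: SequenceRecord,
        truths: list[MoleculeTruth],
        fragments: list[str],
        constructs: list[list[JunctionConstruct]],
    ) -> None:
        self.config = config
        self.reference = reference
        self.truths = truths
        self.fragments = fragments
        self.constructs = constructs

    @property
    def n_read_pairs(self) -> int:
        return sum(len(c) for c in self.constructs)

    def iter_read_pairs(self) -> Iterator[tuple[SequenceRecord, SequenceRecord]]:
        cfg = self.config
        for i, (truth, fragment, constructs) in enumerate(
            zip(self.truths, self.fragments, self.constructs)
        ):
            rng = np.random.default_rng([cfg.seed, 2, i])
            for j, construct in enumerate(constructs):
                pair = emit_read_pair(
                    construct,
                    fragment,
                    cfg,
                    rng,
                    sample_index=truth.sample_index,
                    pair_id=f"{truth.molecule_id}|{construct.side}|{j}",
                )
                if pair is not None:
                    yield pair

    def pairing_reads(self) -> list[SequenceRecord]:
        rng = np.random.default_rng([self.config.seed, 3])
        return emit_pairing_reads(self.truths, self.config, rng, 2 * self.n_read_pairs)

    def write(self, out_dir) -> dict[str, Path]:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        paths = {
            "r1": out_dir / "reads_R1.fastq",
            "r2": out_dir / "reads_R2.fastq",
            "pairing": out_dir / "pairing.fastq",
            "truth": out_dir / "truth.tsv",
            "reference": out_dir / "reference.fasta",
        }
        pairs = self.iter_read_pairs()
        from .io import write_fasta  # local import to avoid cycle at module load

        with open(paths["r1"], "w") as h1, open(paths["r2"], "w") as h2:
            for r1, r2 in pairs:
                q1 = "".join(chr(q + 33) for q in r1.quality)
                q2 = "".join(chr(q + 33) for q in r2.quality)
                h1.write(f"@{r1.id}/1\n{r1.sequence}\n+\n{q1}\n")
                h2.write(f"@{r2.id}/2\n{r2.sequence}\n+\n{q2}\n")
        write_fastq(self.pairing_reads(), paths["pairing"])
        write_truth_table(self.truths, paths["truth"])
        write_fasta([self.reference], paths["reference"])
        return paths


def concatenate_libraries(
    libraries: Sequence[SimulatedLibrary], prefixes: Optional[Sequence[str]] = None
) -> SimulatedLibrary:
    """Pool several simulated libraries into one (e.g. a two-variant mixture).

    Molecule ids are prefixed to stay unique; emission parameters are taken
    from the first library's config. The constituent libraries should be
    simulated with distinct seeds so their barcode spaces are independent.
    """
    if not libraries:
        raise ConfigurationError("no libraries to concatenate")
    if prefixes is None:
        prefixes = [f"lib{i}_" for i in range(len(libraries))]
    truths: list[MoleculeTruth] = []
    fragments: list[str] = []
    constructs: list[list[JunctionConstruct]] = []
    for lib, prefix in zip(libraries, prefixes):
        for t in lib.truths:
            truths.append(replace(t, molecule_id=prefix + t.molecule_id))
        fragments.extend(lib.fragments)
        constructs.extend(lib.constructs)
    return SimulatedLibrary(
        libraries[0].config, libraries[0].reference, truths, fragments, constructs
    )


def simulate_library(config: SimulationConfig) -> SimulatedLibrary:
    """Build the full simulated library (deterministic given config.seed)."""
    config.validate()
    if config.reference_path is not None:
        from .io import read_fasta

        reference = next(iter(read_fasta(config.reference_path)))
    else:
        rng_ref = np.random.default_rng([config.seed, 0])
        reference = make_random_reference(
            config.random_reference_length, config.gc_fraction, int(rng_ref.integers(2**31))
        )
    rng_frag = np.random.default_rng([config.seed, 1])
    drawn = draw_fragments(reference, config, rng_frag)
    truths = [t for t, _ in drawn]
    fragments = [f for _, f in drawn]
    constructs = []
    for i, (truth, fragment) in enumerate(drawn):
        rng = np.random.default_rng([config.seed, 10, i])
        constructs.append(simulate_copies_and_breaks(truth, fragment, config, rng))
    return SimulatedLibrary(config, reference, truths, fragments, constructs)
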