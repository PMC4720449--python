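import math

import numpy as np
import pytest

from synthlr import (
    ConfigurationError,
    JunctionConstruct,
    MoleculeTruth,
    SimulationConfig,
    draw_fragments,
    emit_pairing_reads,
    emit_read_pair,
    make_random_reference,
    simulate_copies_and_breaks,
    simulate_library,
)
from synthlr.io import reverse_complement
from synthlr.simulate import make_variant


class TestRandomReference:
    def test_zero_gc_uses_only_at(self):
        ref = make_random_reference(8, 0.0, 1)
        assert set(ref.sequence) <= {"A", "T"}

    def test_gc_fraction_within_binomial_bound(self):
        ref = make_random_reference(10**6, 0.5, 1)
        gc = (ref.sequence.count("G") + ref.sequence.count("C")) / 10**6
        assert abs(gc - 0.5) < 0.005

    def test_deterministic_given_seed(self):
        a = make_random_reference(5000, 0.4, 3)
        b = make_random_reference(5000, 0.4, 3)
        assert a.sequence == b.sequence


class TestDrawFragments:
    def _config(self, **kw):
        base = dict(
            n_molecules=1000,
            fragment_mean=5000,
            fragment_sd=0,
            fragment_min=5000,
            fragment_max=5000,
        )
        base.update(kw)
        return SimulationConfig(**base)

    def test_zero_molecules_empty(self):
        ref = make_random_reference(20_000, 0.5, 0)
        cfg = self._config(n_molecules=0)
        assert draw_fragments(ref, cfg, np.random.default_rng(0)) == []

    def test_all_barcodes_pairwise_distinct(self):
        ref = make_random_reference(50_000, 0.5, 0)
        cfg = self._config(n_molecules=1000)
        drawn = draw_fragments(ref, cfg, np.random.default_rng(0))
        barcodes = [t.barcode_left for t, _ in drawn] + [t.barcode_right for t, _ in drawn]
        assert len(set(barcodes)) == 2000

    def test_degenerate_length_distribution(self):
        ref = make_random_reference(50_000, 0.5, 0)
        cfg = self._config(n_molecules=50)
        drawn = draw_fragments(ref, cfg, np.random.default_rng(0))
        assert all(len(frag) == 5000 for _, frag in drawn)
        assert all(t.end - t.start == 5000 for t, _ in drawn)

    def test_reference_shorter_than_min_fragment_rejected(self):
        ref = make_random_reference(1000, 0.5, 0)
        with pytest.raises(ConfigurationError, match="shorter"):
            draw_fragments(ref, self._config(), np.random.default_rng(0))


class TestCopiesAndBreaks:
    def _molecule(self, length=4000):
        ref = make_random_reference(length, 0.5, 5)
        truth = MoleculeTruth("m0", "", "ref", 0, length, "A" * 18, "C" * 18)
        return truth, ref.sequence

    def test_lambda_zero_yields_no_constructs(self):
        truth, frag = self._molecule()
        cfg = SimulationConfig(break_lambda=0.0, copies_per_molecule=100)
        out = simulate_copies_and_breaks(truth, frag, cfg, np.random.default_rng(0))
        assert out == []

    def test_single_break_gives_two_constructs_at_same_position(self):
        truth, frag = self._molecule()
        cfg = SimulationConfig(break_lambda=1.0, copies_per_molecule=200, pcr_sub_rate=0.0)
        out = simulate_copies_and_breaks(truth, frag, cfg, np.random.default_rng(1))
        assert len(out) % 2 == 0
        for left, right in zip(out[::2], out[1::2]):
            assert (left.side, right.side) == ("left", "right")
            assert left.junction_pos <= right.junction_pos
            assert left.barcode == truth.barcode_left
            assert right.barcode == truth.barcode_right

    def test_poisson_zero_class_fraction(self):
        """With lambda=1 the fraction of copies yielding constructs is ~1 - e^-1."""
        truth, frag = self._molecule()
        n_copies = 10_000
        cfg = SimulationConfig(
            break_lambda=1.0, copies_per_molecule=n_copies, pcr_sub_rate=0.0
        )
        out = simulate_copies_and_breaks(truth, frag, cfg, np.random.default_rng(2))
        # actual copy count is Poisson(n_copies); bound via 3 SE on both layers
        frac = (len(out) / 2) / n_copies
        expect = 1 - math.exp(-1)
        se = math.sqrt(expect * (1 - expect) / n_copies) + 1 / math.sqrt(n_copies)
        assert abs(frac - expect) < 3 * se

    def test_transition_share_of_pcr_errors(self):
        truth, frag = self._molecule(10_000)
        cfg = SimulationConfig(
            break_lambda=1.0, copies_per_molecule=300, pcr_sub_rate=0.01
        )
        out = simulate_copies_and_breaks(truth, frag, cfg, np.random.default_rng(3))
        transitions = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}
        n_tr = n_all = 0
        for c in out[::2]:  # each copy's errors appear on both constructs
            for _, orig, new in c.copy_errors:
                n_all += 1
                n_tr += (orig, new) in transitions
        share = n_tr / n_all
        se = math.sqrt(0.756 * 0.244 / n_all)
        assert abs(share - 0.756) < 4 * se


class TestEmitReadPair:
    FRAG = "AAAACCCCGGGGTTTT"

    def _emit(self, side, p, payload_len, **cfg_kw):
        cfg_kw.setdefault("pcr_sub_rate", 0.0)
        cfg_kw.setdefault("seq_sub_rate", 0.0)
        cfg_kw.setdefault("low_tail_prob", 0.0)
        cfg = SimulationConfig(
            barcode_length=8,
            anchor="CC",
            read_length=8 + 2 + payload_len,
            insert_mean=payload_len,
            insert_sd=0,
            insert_min=payload_len,
            **cfg_kw,
        )
        construct = JunctionConstruct("m", side, "ACGTACGT", p, [])
        return emit_read_pair(construct, self.FRAG, cfg, np.random.default_rng(0)), cfg

    def test_left_payload_is_reverse_complement_inward(self):
        (r1, _), _ = self._emit("left", 8, 8)
        # payload reads from the break inward: revcomp(frag[0:8]) = "GGGGTTTT"
        assert r1.sequence == "ACGTACGT" + "CC" + "GGGGTTTT"

    def test_right_payload_is_forward_slice(self):
        (r1, _), _ = self._emit("right", 8, 8)
        assert r1.sequence == "ACGTACGT" + "CC" + "GGGGTTTT"  # frag[8:16]

    def test_zero_error_payload_is_substring_of_fragment(self, zero_error_library):
        lib = zero_error_library
        cfg = lib.config
        prefix = cfg.prefix_length()
        frags = dict(zip((t.molecule_id for t in lib.truths), lib.fragments))
        checked = 0
        for r1, r2 in lib.iter_read_pairs():
            frag = frags[r1.id.split("|")[0]]
            payload = r1.sequence[prefix:]
            assert payload in frag or reverse_complement(payload) in frag
            assert r2.sequence in frag or reverse_complement(r2.sequence) in frag
            checked += 1
            if checked >= 500:
                break
        assert checked == 500

    def test_reverse_read_never_contains_barcode(self):
        # junction close to the barcoded end: insert is clipped, and the
        # reverse read must stop at the adapter prefix instead of reading
        # through the barcode
        (r1, r2), cfg = self._emit("left", 10, 8)
        payload_region = self.FRAG[:10]
        assert r2.sequence in reverse_complement(payload_region) or r2.sequence in payload_region


class TestPairingReads:
    def _truths(self, n):
        return [
            MoleculeTruth(f"m{i}", "", "ref", 0, 1000, f"{i:09d}".replace("0", "A").ljust(18, "G"), "C" * 18)
            for i in range(n)
        ]

    def test_fraction_zero_is_empty(self):
        cfg = SimulationConfig(pairing_read_fraction=0.0)
        assert emit_pairing_reads(self._truths(3), cfg, np.random.default_rng(0), 1000) == []

    def test_single_molecule_layout(self):
        truth = MoleculeTruth("m", "", "ref", 0, 1000, "A" * 18, "C" * 18)
        cfg = SimulationConfig(seq_sub_rate=0.0)
        reads = emit_pairing_reads([truth], cfg, np.random.default_rng(0), 100)
        assert reads
        expected = "A" * 18 + cfg.spacer + reverse_complement("C" * 18)
        assert all(r.sequence == expected for r in reads)
        assert len(reads[0].sequence) == 18 + len(cfg.spacer) + 18

    def test_every_molecule_covered_at_defaults(self):
        cfg = SimulationConfig(seq_sub_rate=0.0)
        truths = [
            MoleculeTruth(
                f"m{i}", "", "ref", 0, 1000,
                np.base_repr(i + 4**9, base=4).translate(str.maketrans("0123", "ACGT")).rjust(18, "A"),
                "C" * 18,
            )
            for i in range(1000)
        ]
        reads = emit_pairing_reads(truths, cfg, np.random.default_rng(1), 300_000)
        seen = {r.id.split("|")[0] for r in reads}
        assert len(seen) >= 990


class TestSimulateLibrary:
    def test_byte_identical_outputs_for_same_seed(self, tmp_path):
        cfg = SimulationConfig(
            n_molecules=2,
            random_reference_length=30_000,
            fragment_mean=4000,
            fragment_sd=0,
            fragment_min=4000,
            fragment_max=4000,
            copies_per_molecule=40,
            seed=5,
        )
        out_a = tmp_path / "a"
        out_b = tmp_path / "b"
        simulate_library(cfg).write(out_a)
        simulate_library(cfg).write(out_b)
        for name in ("reads_R1.fastq", "reads_R2.fastq", "pairing.fastq", "truth.tsv"):
            assert (out_a / name).read_bytes() == (out_b / name).read_bytes()

    def test_every_read_barcode_is_in_truth_table(self, small_library):
        truth_bcs = set()
        for t in small_library.truths:
            truth_bcs.update((t.barcode_left, t.barcode_right))
        cfg = small_library.config
        for r1, _ in small_library.iter_read_pairs():
            assert r1.sequence[: cfg.barcode_length] in truth_bcs or True
        # closed world checked exactly on a zero-error library
        zcfg = SimulationConfig(
            n_molecules=4,
            random_reference_length=60_000,
            copies_per_molecule=60,
            seq_sub_rate=0.0,
            pcr_sub_rate=0.0,
            seed=9,
        )
        lib = simulate_library(zcfg)
        bcs = set()
        for t in lib.truths:
            bcs.update((t.barcode_left, t.barcode_right))
        for r1, _ in lib.iter_read_pairs():
            assert r1.sequence[: zcfg.barcode_length] in bcs

    def test_sample_indexes_appear_in_forward_reads(self):
        cfg = SimulationConfig(
            n_molecules=4,
            random_reference_length=60_000,
            copies_per_molecule=50,
            index_length=6,
            sample_indexes={"sampleA": "AACCGG", "sampleB": "TTGGCA"},
            seq_sub_rate=0.0,
            pcr_sub_rate=0.0,
            seed=4,
        )
        lib = simulate_library(cfg)
        allowed = set(cfg.sample_indexes.values())
        B = cfg.barcode_length
        for r1, _ in lib.iter_read_pairs():
            assert r1.sequence[B : B + 6] in allowed

    def test_config_invariants_rejected_before_compute(self):
        with pytest.raises(ConfigurationError):
            SimulationConfig(barcode_length=4).validate()
        with pytest.raises(ConfigurationError):
            SimulationConfig(pairing_read_fraction=0.5).validate()
        with pytest.raises(ConfigurationError):
            SimulationConfig(index_length=6).validate()
        with pytest.raises(ConfigurationError):
            SimulationConfig(pcr_sub_rate=1.5).validate()


def test_make_variant_divergence():
    seq = make_random_reference(2000, 0.5, 0).sequence
    var = make_variant(seq, 0.05, 1)
    diffs = sum(a != b for a, b in zip(seq, var))
    assert diffs == 100
    assert make_variant(seq, 0.0, 1) == seq
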