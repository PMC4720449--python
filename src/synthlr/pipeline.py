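"""End-to-end pipeline: simulate/ingest -> group -> pair -> assemble -> QC.

Configuration is a structured document with one section per stage; unknown
keys are rejected before any compute. Reruns with the same config and seed
produce identical artifacts.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Optional

import numpy as np
import pandas as pd

from .assembly import AssemblyParams, SyntheticRead, assemble_all
from .barcodes import (
    AdapterSpec,
    BarcodeGroup,
    GroupingStats,
    build_groups,
    collapse_hamming,
    filter_groups,
)
from .errors import ConfigurationError, StageError
from .io import ReportTable, SequenceRecord, write_fasta
from .pairing import (
    ResolvedPairs,
    build_cooccurrence,
    merge_groups,
    parse_pairing_read,
    resolve_pairs,
)
from .qc import n50
from .simulate import SimulatedLibrary, SimulationConfig, simulate_library


@dataclass(slots=True)
class GroupParams:
    min_read_pairs: int = 50
    q_threshold: int = 20
    trim_window: int = 4
    min_len: int = 30
    min_overlap: int = 10
    max_mismatch_frac: float = 0.25


@dataclass(slots=True)
class PairParams:
    min_count: int = 2
    require_mutual_best: bool = True
    spacer_max_mismatch: int = 2
    reverse_layout: bool = False


@dataclass(slots=True)
class QcParams:
    min_len: int = 1000
    accuracy_min_len: int = 1500
    end_trim_n: int = 100
    hamming_clean: bool = True
    hamming_max_dist: int = 2


@dataclass
class PipelineConfig:
    simulate: SimulationConfig = field(default_factory=SimulationConfig)
    group: GroupParams = field(default_factory=GroupParams)
    pair: PairParams = field(default_factory=PairParams)
    assemble: AssemblyParams = field(default_factory=AssemblyParams)
    qc: QcParams = field(default_factory=QcParams)
    seed: Optional[int] = None  # overrides simulate.seed when set
    log_level: str = "INFO"

    def adapter_spec(self) -> AdapterSpec:
        sim = self.simulate
        return AdapterSpec(
            barcode_length=sim.barcode_length,
            index_length=sim.index_length,
            anchor=sim.anchor,
            index_table={idx: name for name, idx in sim.sample_indexes.items()},
        )


_SECTIONS = {
    "simulate": SimulationConfig,
    "group": GroupParams,
    "pair": PairParams,
    "assemble": AssemblyParams,
    "qc": QcParams,
}


def config_from_dict(doc: dict) -> PipelineConfig:
    """Build a PipelineConfig from a nested mapping; unknown keys rejected."""
    cfg = PipelineConfig()
    for key, value in doc.items():
        if key == "seed":
            cfg.seed = int(value)
            continue
        if key == "log_level":
            cfg.log_level = str(value)
            continue
        cls = _SECTIONS.get(key)
        if cls is None:
            raise ConfigurationError(f"unknown config section {key!r}")
        known = {f.name for f in dataclasses.fields(cls)}
        for sub in value:
            if sub not in known:
                raise ConfigurationError(f"unknown config key {key}.{sub}")
        setattr(cfg, key, cls(**value))
    if cfg.seed is not None:
        cfg.simulate.seed = cfg.seed
    return cfg


def load_config(path) -> PipelineConfig:
    import yaml

    with open(path) as handle:
        doc = yaml.safe_load(handle) or {}
    if not isinstance(doc, dict):
        raise ConfigurationError(f"{path}: config root must be a mapping")
    return config_from_dict(doc)


def config_hash(cfg: PipelineConfig) -> str:
    doc = dataclasses.asdict(cfg)
    return hashlib.sha256(json.dumps(doc, sort_keys=True, default=str).encode()).hexdigest()[:16]


@dataclass
class PipelineResult:
    """In-memory artifacts of one pipeline run."""

    config: PipelineConfig
    library: Optional[SimulatedLibrary]
    groups: Dict[str, BarcodeGroup]
    merged_groups: Dict[str, BarcodeGroup]
    resolved: Optional[ResolvedPairs]
    synthetic_reads: list[SyntheticRead]
    grouping_stats: GroupingStats
    report: ReportTable
    assembly_log: list[tuple[str, str]] = field(default_factory=list)


def hamming_clean_synthetic(
    synthetic_reads: list[SyntheticRead],
    max_dist: int = 2,
) -> list[SyntheticRead]:
    """Drop synthetic reads whose group barcode collapses onto a barcode with
    a longer synthetic read (Hamming distance <= max_dist).

    A merged group contributes both constituent barcodes, keyed by its
    longest synthetic read; the group survives iff all its barcodes survive.
    """
    best_len: Dict[str, int] = {}
    group_barcodes: Dict[str, list[str]] = {}
    for read in synthetic_reads:
        bcs = read.group_key.split("|")
        group_barcodes[read.group_key] = bcs
        for bc in bcs:
            best_len[bc] = max(best_len.get(bc, 0), len(read.sequence))
    if not best_len:
        return []
    survivors = set(collapse_hamming(best_len, max_dist=max_dist))
    return [
        r
        for r in synthetic_reads
        if all(bc in survivors for bc in group_barcodes[r.group_key])
    ]


def run_pipeline(
    config: PipelineConfig,
    out_dir=None,
    skip_pairing: bool = False,
    workers: int = 1,
    library: Optional[SimulatedLibrary] = None,
) -> PipelineResult:
    """Execute simulate -> group -> pair -> assemble -> qc summary.

    ``library`` may be passed to reuse an already simulated library (e.g. to
    compare paired and unpaired runs on identical input). With ``out_dir``
    set, stage artifacts and a machine-readable run manifest are written.
    """
    config.simulate.validate()
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "config_hash": config_hash(config),
        "seed": config.simulate.seed,
        "stages": {},
    }

    def fail(stage: str, exc: Exception):
        manifest["stages"][stage] = f"failed: {exc}"
        if out is not None:
            (out / "run_manifest.json").write_text(json.dumps(manifest, indent=2))
        raise StageError(f"stage {stage!r} failed: {exc}") from exc

    try:
        if library is None:
            library = simulate_library(config.simulate)
        manifest["stages"]["simulate"] = f"ok: {library.n_read_pairs} read pairs"
    except (StageError, ConfigurationError):
        raise
    except Exception as exc:
        fail("simulate", exc)

    spec = config.adapter_spec()
    gp = config.group
    try:
        groups, gstats = build_groups(
            library.iter_read_pairs(),
            spec,
            q_threshold=gp.q_threshold,
            trim_window=gp.trim_window,
            min_len=gp.min_len,
            min_overlap=gp.min_overlap,
            max_mismatch_frac=gp.max_mismatch_frac,
        )
        groups = filter_groups(groups, gp.min_read_pairs)
        manifest["stages"]["group"] = f"ok: {len(groups)} groups"
    except Exception as exc:
        fail("group", exc)

    resolved: Optional[ResolvedPairs] = None
    if skip_pairing:
        merged = groups
        manifest["stages"]["pair"] = "skipped"
    else:
        try:
            parsed = []
            for rec in library.pairing_reads():
                hit = parse_pairing_read(
                    rec,
                    spec,
                    config.simulate.spacer,
                    spacer_max_mismatch=config.pair.spacer_max_mismatch,
                    reverse_layout=config.pair.reverse_layout,
                )
                if hit is not None:
                    parsed.append(hit)
            graph = build_cooccurrence(parsed)
            resolved = resolve_pairs(
                graph,
                min_count=config.pair.min_count,
                require_mutual_best=config.pair.require_mutual_best,
            )
            merged = merge_groups(groups, resolved)
            manifest["stages"]["pair"] = f"ok: {len(resolved.pairs)} pairs"
        except Exception as exc:
            fail("pair", exc)

    try:
        synthetic, alog = assemble_all(merged, config.assemble, workers=workers)
        if config.qc.hamming_clean:
            synthetic = hamming_clean_synthetic(synthetic, config.qc.hamming_max_dist)
        manifest["stages"]["assemble"] = f"ok: {len(synthetic)} synthetic reads"
    except Exception as exc:
        fail("assemble", exc)

    report = ReportTable()
    lengths = [len(s.sequence) for s in synthetic]
    report.add("read_pairs_in", gstats.pairs_in)
    report.add("read_pairs_accepted", gstats.accepted)
    report.add("groups_min_pairs", len(groups))
    report.add("barcode_pairs_resolved", 0 if resolved is None else len(resolved.pairs))
    report.add("merged_groups", len(merged))
    report.add("synthetic_reads", sum(1 for L in lengths if L >= config.qc.min_len))
    report.add("synthetic_bases", sum(L for L in lengths if L >= config.qc.min_len))
    report.add("n50", n50(lengths, config.qc.min_len))
    report.add("longest", max(lengths, default=0))

    if out is not None:
        write_fasta(
            [
                SequenceRecord(
                    f"{s.id} group={s.group_key} pairs={s.read_pair_count} "
                    f"contigs={s.contig_count} cov={s.mean_coverage:.1f} primary={int(s.primary)}",
                    s.sequence,
                )
                for s in synthetic
            ],
            out / "synthetic_reads.fasta",
        )
        manifest_rows = [
            (g.barcode, g.sample, g.read_pair_count, len(g.reads)) for g in merged.values()
        ]
        pd.DataFrame(
            manifest_rows, columns=["barcode", "sample", "pairs", "reads"]
        ).to_csv(out / "group_manifest.tsv", sep="\t", index=False)
        if resolved is not None:
            pd.DataFrame(resolved.pairs, columns=["barcode_a", "barcode_b"]).to_csv(
                out / "barcode_pairs.tsv", sep="\t", index=False
            )
        report.write(out / "report.tsv")
        (out / "run_manifest.json").write_text(json.dumps(manifest, indent=2))

    return PipelineResult(
        config=config,
        library=library,
        groups=groups,
        merged_groups=merged,
        resolved=resolved,
        synthetic_reads=synthetic,
        grouping_stats=gstats,
        report=report,
        assembly_log=alog,
    )


def demux_report(
    groups: Dict[str, BarcodeGroup],
    synthetic_reads: list[SyntheticRead],
    index_table: Dict[str, str],
    genome_size: Optional[int] = None,
    min_len: int = 1000,
) -> pd.DataFrame:
    """Per-sample demultiplexing summary: reads, groups, N50, coverage.

    Coverage is summed synthetic-read bases over the supplied genome size;
    the column is left empty (NaN) when no genome size is given.
    """
    samples = sorted(set(index_table.values()))
    by_group_sample = {key: g.sample for key, g in groups.items()}
    rows = []
    for sample in samples:
        sample_groups = [g for g in groups.values() if g.sample == sample]
        reads = sum(len(g.reads) for g in sample_groups)
        synth = [
            s
            for s in synthetic_reads
            if by_group_sample.get(s.group_key, "") == sample
        ]
        lengths = [len(s.sequence) for s in synth if len(s.sequence) >= min_len]
        bases = sum(lengths)
        coverage = bases / genome_size if genome_size else np.nan
        rows.append(
            {
                "sample": sample,
                "reads": reads,
                "groups": len(sample_groups),
                "synthetic_reads": len(lengths),
                "synthetic_bases": bases,
                "n50": n50(lengths, min_len),
                "coverage": coverage,
            }
        )
    return pd.DataFrame(rows)
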