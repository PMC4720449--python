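"""Optional plotting helpers for QC reports."""

from __future__ import annotations

from typing import Iterable, Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd


def plot_length_histogram(lengths: Sequence[int], path, min_len: int = 1000) -> None:
    """Length histogram of synthetic reads above the reporting cutoff."""
    kept = [x for x in lengths if x >= min_len]
    fig, ax = plt.subplots(figsize=(5, 3.2))
    ax.hist(kept, bins=40, color="#3b6ea5")
    ax.set_xlabel("synthetic read length (bp)")
    ax.set_ylabel("count")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_mismatch_profile(profile: pd.DataFrame, path) -> None:
    """Mismatch rate as a function of relative position (see qc.mismatch_profile)."""
    fig, ax = plt.subplots(figsize=(5, 3.2))
    ax.plot(profile["bin"], profile["mismatch_rate"], color="#a53b3b")
    ax.set_xlabel("relative position (bin of 100)")
    ax.set_ylabel("mismatch rate")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_coverage(coverage: Iterable[int], path) -> None:
    """Per-position coverage across one truth fragment."""
    cov = list(coverage)
    fig, ax = plt.subplots(figsize=(5, 3.2))
    ax.fill_between(range(len(cov)), cov, color="#4a9a6f", alpha=0.8)
    ax.set_xlabel("position in fragment (bp)")
    ax.set_ylabel("coverage")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
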