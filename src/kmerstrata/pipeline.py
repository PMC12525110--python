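"""End-to-end orchestration: one config in, a bundle of tables out.

``run_all`` composes the library stages — count, full and stratified
spectra, m-mer RF tables, divergence scores, peak distances with
permutation p-values, island calling — and writes deterministic TSV/BED
outputs plus a log and an echo of the config.  Rerunning with the same
config and seed reproduces every output byte for byte.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .genome_io import GenomeSet, read_fasta, write_bed
from .kmer_spectrum import KmerCountTable, count_kmers, fa_spectrum
from .stratification import DINUCLEOTIDES, build_strata, stratum_spectrum
from .mmer_usage import mmer_rf
from .divergence_metrics import divergence_scores
from .peak_inference import find_peak, permutation_test
from .kmer_spectrum import smooth
from .cpg_islands import call_islands, window_stats

_FLOAT_FMT = "%.6g"


@dataclass
class RunConfig:
    fasta: str | None = None
    k: int = 8
    m_values: list[int] = field(default_factory=lambda: [3, 4])
    dinucleotides: list[str] = field(default_factory=lambda: list(DINUCLEOTIDES))
    peak_dinucleotides: list[str] = field(default_factory=lambda: ["CG"])
    smooth_window: int = 10
    smooth_passes: int = 1
    permutation_B: int = 10_000
    seed: int = 0
    island_window: int = 1000
    island_step: int = 500
    island_gc_min: float = 0.5
    island_oe_min: float = 0.6
    outdir: str = "kmerstrata_out"

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


def _write(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def _spectrum_frame(spec) -> pd.DataFrame:
    x = np.arange(len(spec.n_x))
    return pd.DataFrame({"x": x, "N_x": spec.n_x, "FA": spec.fa})


def run_all(config: RunConfig, genome: GenomeSet | None = None) -> dict:
    """Run every stage; returns a dict of the in-memory results.

    ``genome`` overrides ``config.fasta`` (used by tests and the
    simulator path); one of the two must be provided.
    """
    t0 = time.time()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_lines: list[str] = [f"kmerstrata {__version__}"]

    def log(stage: str, msg: str) -> None:
        log_lines.append(f"[{time.time() - t0:8.2f}s] {stage}: {msg}")

    if genome is None:
        if config.fasta is None:
            raise ValueError("config.fasta or an in-memory genome is required")
        genome = read_fasta(config.fasta)
    log("input", f"{len(genome)} sequence(s), {genome.total_length} bp")

    try:
        table = count_kmers(genome, config.k)
    except Exception as exc:
        raise RuntimeError(f"stage 'count' failed on input: {exc}") from exc
    log("count", f"{table.windows_counted} windows at k={config.k}")

    full_spec = fa_spectrum(table)
    _write(_spectrum_frame(full_spec), outdir / "spectrum_full.tsv")

    # stratified spectra + sizes
    sizes_rows, spectra_rows = [], []
    strata_by_label = {}
    for xy in config.dinucleotides:
        for stratum in build_strata(xy):
            strata_by_label[stratum.label] = stratum
            sizes_rows.append({"dinucleotide": xy,
                               "occupancy_class": stratum.occupancy_class,
                               "size": stratum.size})
            spec = stratum_spectrum(table, stratum)
            frame = _spectrum_frame(spec)
            frame.insert(0, "occupancy_class", stratum.occupancy_class)
            frame.insert(0, "dinucleotide", xy)
            spectra_rows.append(frame)
    _write(pd.DataFrame(sizes_rows), outdir / "strata_sizes.tsv")
    _write(pd.concat(spectra_rows, ignore_index=True), outdir / "strata_spectra.tsv")
    log("stratify", f"{len(sizes_rows)} strata over {len(config.dinucleotides)} dinucleotides")

    # m-mer RF tables + divergence scores
    divergence_rows = []
    rf_frames = {}
    for m in config.m_values:
        overall = mmer_rf(table, None, m)
        cols = {"mmer": overall.as_series().index, "rf_overall": overall.rf}
        for xy in config.dinucleotides:
            for stratum in build_strata(xy):
                try:
                    prof = mmer_rf(table, stratum, m)
                except ValueError:
                    log("rf", f"stratum {stratum.label} has zero weight; skipped")
                    continue
                cols[f"rf_{stratum.label}"] = prof.rf
                sc = divergence_scores(overall.rf, prof.rf, stratum.label, m)
                divergence_rows.append({
                    "dinucleotide": xy,
                    "occupancy_class": stratum.occupancy_class,
                    "m": m, "nsre": sc.nsre, "s1": sc.s1, "s2": sc.s2,
                })
        rf_frames[m] = pd.DataFrame(cols)
        _write(rf_frames[m], outdir / f"rf_m{m}.tsv")
    _write(pd.DataFrame(divergence_rows), outdir / "divergence.tsv")
    log("divergence", f"{len(divergence_rows)} stratum/m score rows")

    # peak distances + permutation tests
    peak_rows = []
    for xy in config.peak_dinucleotides:
        s0, s1_, s2_ = build_strata(xy)
        peaks = {}
        for stratum in (s0, s1_, s2_):
            spec = stratum_spectrum(table, stratum)
            curve = smooth(spec, config.smooth_window, config.smooth_passes)
            peaks[stratum.label] = find_peak(curve)
        row = {"dinucleotide": xy}
        for a, b in ((s0, s1_), (s0, s2_), (s1_, s2_)):
            res = permutation_test(table, a, b, B=config.permutation_B,
                                   seed=config.seed,
                                   window=config.smooth_window,
                                   passes=config.smooth_passes)
            row[f"D_{a.label}_{b.label}"] = res.d_obs
            row[f"p_{a.label}_{b.label}"] = res.p_display()
        for label, pk in peaks.items():
            row[f"peak_{label}"] = pk.x_hat
        peak_rows.append(row)
    _write(pd.DataFrame(peak_rows), outdir / "peak_distances.tsv")
    log("peaks", f"{len(peak_rows)} dinucleotide(s) tested, B={config.permutation_B}")

    # CpG islands
    islands = []
    for seq in genome:
        stats = window_stats(seq, config.island_window, config.island_step)
        ann = call_islands(stats, config.island_gc_min, config.island_oe_min)
        islands.extend((seq.id, s, e) for s, e in ann.intervals)
    write_bed(islands, outdir / "islands.bed")
    log("islands", f"{len(islands)} interval(s)")

    config.to_yaml(outdir / "config.yaml")
    log("done", "all stages complete")
    (outdir / "log.txt").write_text("\n".join(log_lines) + "\n")

    return {
        "table": table,
        "full_spectrum": full_spec,
        "strata": strata_by_label,
        "rf": rf_frames,
        "divergence": pd.DataFrame(divergence_rows),
        "peaks": pd.DataFrame(peak_rows),
        "islands": islands,
    }
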