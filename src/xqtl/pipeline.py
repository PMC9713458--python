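"""Convenience driver chaining inference, scan and peak calling."""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from . import genome_scan, haplotype_inference, peak_calling
from .io_formats import FounderPanel, GeneticMap, PooledSample


@dataclass
class PipelineResult:
    freqs: haplotype_inference.WindowFreqs
    track: pd.DataFrame
    qtls: list[peak_calling.QTLCall]


def run_pipeline(
    panel: FounderPanel,
    gmap: GeneticMap,
    samples: list[PooledSample],
    window_cm: float = haplotype_inference.DEFAULT_WINDOW_CM,
    step_cm: float = haplotype_inference.DEFAULT_STEP_CM,
    min_snps: int = haplotype_inference.DEFAULT_MIN_SNPS,
    weights: str = "depth",
    error_stratum: str = "three-way",
    span: float = peak_calling.DEFAULT_SPAN,
    threshold: float = peak_calling.DEFAULT_THRESHOLD,
    drop: float = peak_calling.DEFAULT_DROP,
    annotate_shifts: bool = True,
) -> PipelineResult:
    """Window haplotype inference -> ANOVA scan -> smoothing -> QTL calls."""
    grid = haplotype_inference.build_window_grid(gmap, window_cm, step_cm)
    freqs = haplotype_inference.infer_all_windows(
        panel, samples, grid, min_snps=min_snps, weights=weights
    )
    track = genome_scan.scan_genome(freqs, error_stratum=error_stratum)
    track = peak_calling.smooth_track(track, span=span)
    qtls = peak_calling.call_peaks(track, gmap, threshold=threshold, drop=drop)
    if annotate_shifts:
        for q in qtls:
            q.founder_shift = peak_calling.peak_founder_shift(freqs, q)
    return PipelineResult(freqs, track, qtls)
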