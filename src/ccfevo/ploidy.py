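"""Genome ploidy classes and acquired whole-genome doubling.

A sample is high-ploidy when its mean copy number is 2.8 or above.  High
ploidy can arise from accumulated independent gains or from one
whole-genome doubling (WGD); the two are distinguished by the fraction of
the autosomal genome under LOH: a doubled genome carries its pre-existing
LOH forward at elevated total copy number, so genuine WGD genomes sit
above the line ``ploidy = wgd_intercept - wgd_slope * LOH_fraction``
(defaults 2.9 and 2.0).  Comparing time-ordered samples of one patient
yields the acquired-WGD call at relapse.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .config import PipelineConfig
from .genome import AUTOSOMES


@dataclass
class PloidyCall:
    sample: str
    ploidy: float
    loh_fraction: float
    high_ploidy: bool
    wgd: bool


def mean_ploidy(segments: pd.DataFrame) -> float:
    """Length-weighted mean total copy number over autosomal segments."""
    s = segments[segments["chrom"].isin(AUTOSOMES)]
    if s.empty:
        raise ValueError("no autosomal segments")
    lengths = (s["end"] - s["start"] + 1).to_numpy(dtype=float)
    total = (s["major_cn"] + s["minor_cn"]).to_numpy(dtype=float)
    return float((lengths * total).sum() / lengths.sum())


def call_ploidy(
    segments: pd.DataFrame,
    sample: str,
    ploidy: float | None = None,
    config: PipelineConfig | None = None,
) -> PloidyCall:
    """Ploidy class, genome LOH fraction and WGD call for one sample.

    ``loh_fraction`` is the length-weighted fraction of autosomal
    segments with minor copy number 0 (sex chromosomes are excluded: male
    hemizygosity would confound it).  ``ploidy`` defaults to the
    length-weighted mean copy number of the segmentation.
    """
    config = config or PipelineConfig()
    s = segments[(segments["sample"] == sample) & segments["chrom"].isin(AUTOSOMES)]
    if s.empty:
        raise ValueError(f"empty segmentation for sample {sample!r}")
    if ploidy is None:
        ploidy = mean_ploidy(s)
    lengths = (s["end"] - s["start"] + 1).to_numpy(dtype=float)
    loh = (s["minor_cn"] == 0).to_numpy()
    loh_fraction = float((lengths * loh).sum() / lengths.sum())
    high = ploidy >= config.ploidy_gate
    wgd = high and (ploidy > config.wgd_intercept - config.wgd_slope * loh_fraction)
    return PloidyCall(sample, float(ploidy), loh_fraction, bool(high), bool(wgd))


def acquired_wgd(pre: PloidyCall, post: PloidyCall) -> bool:
    """Whole-genome doubling acquired between two time-ordered samples."""
    return post.wgd and not pre.wgd
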