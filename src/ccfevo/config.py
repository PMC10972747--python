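"""Pipeline configuration: every threshold in one namespace.

Defaults are the thresholds the analysis is defined with:

==================  =======  ====================================================
key                 default  meaning
==================  =======  ====================================================
rc                  10       read-count product threshold of the low-AF power
                             gate, ``min(C_tumour, C_normal) * VAF < rc`` fails
fr_threshold        0.2      minimum forward-reverse strand-balance score for
                             low-AF calls
af_gate             0.2      VAF below which the strand and power gates apply
indel_window        10       bp; SNMs strictly closer than this to an indel fail
tail_fraction       0.015    fraction of chromosome length treated as telomeric
                             tail
mapq_fraction       0.10     maximum tolerated fraction of low-MAPQ reads
trim_z              1.96     z-score cutting 2.5% per tail off the log-normal
                             per-read power score distribution
alpha               0.05     BH false-discovery level of the private-mutation
                             binomial test
detection_k         1        "not detected" means fewer than k variant reads
min_cluster         4        minimum mutations per CCF cluster
epsilon             0.1      CCF tolerance for clonality, ancestry and sum rule
bin_width           0.05     2D CCF histogram bin width
ccf_max             1.5      upper edge of the CCF histogram (CCFs > 1 kept)
peak_floor          0.05     surface peaks below this fraction of the maximum
                             are ignored (ripple suppression)
smoothing           None     spline smoothing parameter; None = selected by
                             robust generalised cross-validation
gcv_gamma           2.0      GCV inflation factor guarding against the
                             undersmoothing GCV shows on sparse count grids
split_alpha         1e-4     chi-square level of the cluster overdispersion
                             test that triggers a variance-aware split
min_sig_cases       5        cohort prevalence threshold for signature subset
min_subclonal_mut   20       subclonal signature fits need > this many mutations
min_clonal_mut      300      clonal signature fits need > this many mutations
sig_cost_threshold  0.02     tolerated relative cost increase of backward
                             signature selection, relative to the full fit
ploidy_gate         2.8      mean copy number at or above which a genome is
                             called high-ploidy
wgd_intercept/slope 2.9/2.0  WGD rule: high-ploidy and ploidy > intercept -
                             slope * LOH fraction
normal_cn           2        copy number of the matched normal (autosomes)
==================  =======  ====================================================
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml


@dataclass
class PipelineConfig:
    # artifact filters
    rc: float = 10.0
    rc_per_sample: dict[str, float] = field(default_factory=dict)
    fr_threshold: float = 0.2
    af_gate: float = 0.2
    indel_window: int = 10
    tail_fraction: float = 0.015
    mapq_fraction: float = 0.10
    # statistical filters
    trim_z: float = 1.96
    alpha: float = 0.05
    detection_k: int = 1
    # clustering
    min_cluster: int = 4
    bin_width: float = 0.05
    ccf_max: float = 1.5
    peak_floor: float = 0.05
    smoothing: float | None = None
    gcv_gamma: float = 2.0
    split_alpha: float = 1e-4
    # phylogeny
    epsilon: float = 0.1
    # signatures
    min_sig_cases: int = 5
    min_subclonal_mut: int = 20
    min_clonal_mut: int = 300
    sig_cost_threshold: float = 0.02
    # ploidy / WGD
    ploidy_gate: float = 2.8
    wgd_intercept: float = 2.9
    wgd_slope: float = 2.0
    # genome model
    normal_cn: int = 2
    male: bool = False

    def rc_for(self, sample: str) -> float:
        """Per-sample stringency override of the read-count threshold."""
        return float(self.rc_per_sample.get(sample, self.rc))

    def normal_cn_for(self, chrom: str) -> int:
        """Normal copy number: 2 on autosomes, 1 on sex chromosomes of males."""
        if self.male and chrom in ("chrX", "chrY", "X", "Y"):
            return 1
        return self.normal_cn

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)
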