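"""Compute cancer cell fractions for a handful of hand-written variant
calls, showing how purity, copy number and multiplicity enter."""

import pandas as pd

from ccfevo import compute_ccf_table, expected_vaf

# a clonal heterozygous mutation in a pure diploid tumour has E[VAF] 0.5
print("E[VAF] (p=1.0, CN=2, m=1):", expected_vaf(1.0, 2, 1))
# at purity 0.85 with a single-copy gain (CN=3) and two mutated copies:
print("E[VAF] (p=0.85, CN=3, m=2):", round(expected_vaf(0.85, 3, 2), 4))

segments = pd.DataFrame(
    [
        {"sample": "S1", "chrom": "chr1", "start": 1, "end": 100_000_000,
         "major_cn": 1, "minor_cn": 1, "subclonal_cn": False},
        {"sample": "S1", "chrom": "chr2", "start": 1, "end": 100_000_000,
         "major_cn": 2, "minor_cn": 1, "subclonal_cn": False},
    ]
)
mutations = pd.DataFrame(
    [
        # clonal on the diploid segment: VAF 0.42 ~ E[VAF] 0.425 -> CCF ~1
        {"mutation_id": "clonal_dip", "chrom": "chr1", "pos": 5_000_000,
         "sample": "S1", "depth": 120, "alt_reads": 50},
        # subclonal at half the cells: VAF ~0.21 -> CCF ~0.5
        {"mutation_id": "subclonal", "chrom": "chr1", "pos": 6_000_000,
         "sample": "S1", "depth": 120, "alt_reads": 25},
        # on the gained segment with both copies mutated: VAF ~0.6; the
        # multiplicity that brings the CCF closest to 1 is m=2
        {"mutation_id": "clonal_m2", "chrom": "chr2", "pos": 7_000_000,
         "sample": "S1", "depth": 120, "alt_reads": 72},
    ]
)

table = compute_ccf_table(mutations, segments, purity={"S1": 0.85})
print("\n", table[["mutation_id", "vaf", "total_cn", "multiplicity",
                   "expected_vaf", "ccf"]].round(3).to_string(index=False))
# ccf is the fraction of tumour cells carrying each mutation; the third
# row shows the multiplicity search resolving the copy-number ambiguity.
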