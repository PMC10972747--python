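"""Call genome ploidy classes and acquired whole-genome doubling from
allele-specific segment profiles of a pre/post-treatment pair."""

import pandas as pd

from ccfevo import acquired_wgd, call_ploidy
from ccfevo.genome import AUTOSOMES, HG19_CHROM_LENGTHS


def genome(states, sample):
    rows = []
    for i, chrom in enumerate(AUTOSOMES):
        major, minor = states[i % len(states)]
        rows.append({"sample": sample, "chrom": chrom, "start": 1,
                     "end": HG19_CHROM_LENGTHS[chrom], "major_cn": major,
                     "minor_cn": minor, "subclonal_cn": False})
    return pd.DataFrame(rows)


# pre-treatment: diploid genome with ~10% LOH
pre_states = [(1, 1)] * 9 + [(1, 0)]
# at relapse: the same genome after one whole-genome doubling
post_states = [(2 * M, 2 * m) for M, m in pre_states]

segments = pd.concat([genome(pre_states, "pre"), genome(post_states, "post")])
pre = call_ploidy(segments, "pre")
post = call_ploidy(segments, "post")

for call in (pre, post):
    print(f"{call.sample}: ploidy={call.ploidy:.2f}  LOH fraction={call.loh_fraction:.2f}  "
          f"high_ploidy={call.high_ploidy}  WGD={call.wgd}")
print("acquired whole-genome doubling:", acquired_wgd(pre, post))
# A doubled genome carries its pre-existing LOH forward at elevated total
# copy number, so high ploidy with a modest LOH fraction indicates one
# doubling event rather than piecemeal gains.
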