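import numpy as np
import pandas as pd
import pytest

from ccfevo import PipelineConfig, SimConfig, bundle_from_truth, emit_reads, simulate_patient


@pytest.fixture
def config():
    return PipelineConfig()


@pytest.fixture(scope="session")
def sim_conditions():
    """Study conditions used by the recovery experiments."""
    return SimConfig(mean_depth=120.0, subclonal_bounds=(50, 200))


@pytest.fixture(scope="session")
def class_e_bundle(sim_conditions):
    gt = simulate_patient(3, 2, "E", seed=3, sim=sim_conditions)
    reads = emit_reads(gt, mean_depth=120, sim=sim_conditions)
    return gt, bundle_from_truth(gt, reads)


@pytest.fixture
def diploid_segments():
    """One diploid segment per sample on a toy chromosome."""
    return pd.DataFrame(
        [
            {"sample": s, "chrom": "chr1", "start": 1, "end": 249_250_621,
             "major_cn": 1, "minor_cn": 1, "subclonal_cn": False}
            for s in ("S1", "S2")
        ]
    )


def make_mutations(rows):
    """Long-format mutation table from terse tuples.

    rows: (mutation_id, sample, chrom, pos, depth, alt, fwd) — remaining
    schema columns get neutral defaults.
    """
    out = []
    for mid, sample, chrom, pos, depth, alt, fwd in rows:
        out.append(
            {"mutation_id": mid, "chrom": chrom, "pos": pos, "ref": "C", "alt": "T",
             "kind": "SNM", "trinucleotide": "ACA", "sample": sample, "depth": depth,
             "alt_reads": alt, "forward_alt": fwd, "reverse_alt": alt - fwd,
             "normal_depth": depth, "fraction_lowmapq": 0.0}
        )
    return pd.DataFrame(out)
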