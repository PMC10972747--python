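"""Patient bundles: file formats, schema validation, round-tripping.

A patient is a directory of plain-text tables:

``mutations.tsv``
    long format, one row per (mutation, sample):
    mutation_id, chrom, pos (1-based), ref, alt, kind (SNM/insertion/
    deletion), trinucleotide (optional), sample, depth, alt_reads,
    forward_alt, reverse_alt, normal_depth, fraction_lowmapq
``segments.tsv``
    sample, chrom, start, end (1-based inclusive), major_cn, minor_cn,
    subclonal_cn
``samples.tsv``
    sample, purity, ploidy, timepoint, site, sample_type
``truth.json`` (optional)
    simulator ground truth
``config.yaml`` (optional)

VCF 4.x mutation input is supported when cyvcf2 is installed; positions
are converted to the package's 1-based inclusive convention on ingest
(VCF is already 1-based for SNVs).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

MUTATION_COLUMNS = [
    "mutation_id", "chrom", "pos", "ref", "alt", "kind", "trinucleotide",
    "sample", "depth", "alt_reads", "forward_alt", "reverse_alt",
    "normal_depth", "fraction_lowmapq",
]
SEGMENT_COLUMNS = ["sample", "chrom", "start", "end", "major_cn", "minor_cn", "subclonal_cn"]
SAMPLE_COLUMNS = ["sample", "purity", "ploidy", "timepoint", "site", "sample_type"]


class SchemaError(ValueError):
    """Input violates the documented schema; offending lines are named."""


@dataclass
class PatientBundle:
    """All inputs of one patient, validated and internally consistent."""

    patient_id: str
    samples: pd.DataFrame
    mutations: pd.DataFrame
    segments: pd.DataFrame
    truth: dict | None = None
    meta: dict = field(default_factory=dict)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.samples["sample"])

    def purity(self) -> dict[str, float]:
        return dict(zip(self.samples["sample"], self.samples["purity"].astype(float)))

    def ploidy(self) -> dict[str, float]:
        return dict(zip(self.samples["sample"], self.samples["ploidy"].astype(float)))

    def validate(self) -> None:
        ids = self.samples["sample"].tolist()
        if len(ids) != len(set(ids)):
            raise SchemaError("sample ids must be unique")
        for col, df, name in (("sample", self.mutations, "mutations"),
                              ("sample", self.segments, "segments")):
            extra = set(df[col]) - set(ids)
            if extra:
                raise SchemaError(f"{name} reference unknown samples: {sorted(extra)}")
        for s in ids:
            if self.mutations[self.mutations["sample"] == s].empty:
                raise SchemaError(f"sample {s} has no mutation rows")
            if self.segments[self.segments["sample"] == s].empty:
                raise SchemaError(f"sample {s} has no segments")
        bad = self.mutations[self.mutations["alt_reads"] > self.mutations["depth"]]
        if not bad.empty:
            raise SchemaError(f"alt_reads > depth at rows {list(bad.index[:5])}")
        bad = self.mutations[
            self.mutations["forward_alt"] + self.mutations["reverse_alt"]
            != self.mutations["alt_reads"]
        ]
        if not bad.empty:
            raise SchemaError(f"forward_alt + reverse_alt != alt_reads at rows {list(bad.index[:5])}")
        for (s, c), seg in self.segments.groupby(["sample", "chrom"]):
            seg = seg.sort_values("start")
            starts, ends = seg["start"].to_numpy(), seg["end"].to_numpy()
            overlap = np.nonzero(starts[1:] <= ends[:-1])[0]
            if overlap.size:
                lines = [int(seg.index[i + 1]) + 2 for i in overlap[:5]]  # +2: header + 0-base
                raise SchemaError(f"overlapping segments for {s}/{c} at file lines {lines}")
        p = self.samples["purity"].astype(float)
        if ((p <= 0) | (p > 1)).any():
            raise SchemaError("purity must lie in (0, 1]")


def _check_columns(df: pd.DataFrame, required: list[str], path: Path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")


def read_bundle(directory: str | Path, patient_id: str | None = None) -> PatientBundle:
    d = Path(directory)
    mut_path, seg_path, smp_path = d / "mutations.tsv", d / "segments.tsv", d / "samples.tsv"
    for p in (mut_path, seg_path, smp_path):
        if not p.exists():
            raise FileNotFoundError(p)
    mutations = pd.read_csv(mut_path, sep="\t", dtype={"chrom": str, "trinucleotide": str})
    segments = pd.read_csv(seg_path, sep="\t", dtype={"chrom": str})
    samples = pd.read_csv(smp_path, sep="\t")
    _check_columns(mutations, [c for c in MUTATION_COLUMNS if c != "trinucleotide"], mut_path)
    _check_columns(segments, SEGMENT_COLUMNS, seg_path)
    _check_columns(samples, ["sample", "purity", "ploidy"], smp_path)
    if "trinucleotide" not in mutations.columns:
        mutations["trinucleotide"] = ""
    mutations["trinucleotide"] = mutations["trinucleotide"].fillna("")
    truth = None
    if (d / "truth.json").exists():
        import json

        truth = json.loads((d / "truth.json").read_text())
    bundle = PatientBundle(
        patient_id=patient_id or d.name,
        samples=samples,
        mutations=mutations,
        segments=segments,
        truth=truth,
    )
    bundle.validate()
    return bundle


def write_bundle(bundle: PatientBundle, directory: str | Path) -> Path:
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    cols = [c for c in MUTATION_COLUMNS if c in bundle.mutations.columns]
    bundle.mutations[cols].to_csv(d / "mutations.tsv", sep="\t", index=False)
    bundle.segments[SEGMENT_COLUMNS].to_csv(d / "segments.tsv", sep="\t", index=False)
    smp_cols = [c for c in SAMPLE_COLUMNS if c in bundle.samples.columns]
    bundle.samples[smp_cols].to_csv(d / "samples.tsv", sep="\t", index=False)
    if bundle.truth is not None:
        import json

        (d / "truth.json").write_text(json.dumps(bundle.truth, indent=2))
    return d


def bundle_from_truth(gt, reads: pd.DataFrame, patient_id: str = "SIM") -> PatientBundle:
    """Assemble a validated bundle from simulator output."""
    import json

    samples = pd.DataFrame(
        {
            "sample": gt.samples,
            "purity": [gt.purity[s] for s in gt.samples],
            "ploidy": [gt.ploidy[s] for s in gt.samples],
            "timepoint": list(range(len(gt.samples))),
            "site": ["primary"] + ["metastasis"] * (len(gt.samples) - 1),
            "sample_type": ["tumour"] * len(gt.samples),
        }
    )
    bundle = PatientBundle(
        patient_id=patient_id,
        samples=samples,
        mutations=reads.reset_index(drop=True),
        segments=gt.segments.copy(),
        truth=json.loads(gt.to_json()),
    )
    bundle.validate()
    return bundle


def read_vcf(path: str | Path, sample: str) -> pd.DataFrame:
    """Read somatic SNM/indel calls from a VCF into the mutation schema.

    Requires cyvcf2; uses FORMAT/DP for depth and FORMAT/AD (ref, alt) for
    variant reads.  Strand counts default to an even split when the VCF
    carries no SB annotation; normal depth defaults to DP.
    """
    try:
        from cyvcf2 import VCF
    except ImportError as err:  # pragma: no cover
        raise ImportError("VCF input needs the optional cyvcf2 dependency") from err

    rows = []
    vcf = VCF(str(path))
    si = vcf.samples.index(sample) if sample in vcf.samples else 0
    for i, var in enumerate(vcf):
        ref, alt = var.REF, var.ALT[0]
        if len(ref) == 1 and len(alt) == 1:
            kind = "SNM"
        elif len(alt) > len(ref):
            kind = "insertion"
        else:
            kind = "deletion"
        depth = int(var.format("DP")[si][0]) if var.format("DP") is not None else 0
        ad = var.format("AD")
        alt_reads = int(ad[si][1]) if ad is not None and len(ad[si]) > 1 else 0
        fwd = alt_reads // 2
        rows.append(
            {
                "mutation_id": f"{var.CHROM}:{var.POS}:{ref}>{alt}",
                "chrom": var.CHROM, "pos": int(var.POS), "ref": ref, "alt": alt,
                "kind": kind, "trinucleotide": "", "sample": sample, "depth": depth,
                "alt_reads": alt_reads, "forward_alt": fwd, "reverse_alt": alt_reads - fwd,
                "normal_depth": depth, "fraction_lowmapq": 0.0,
            }
        )
    return pd.DataFrame(rows, columns=MUTATION_COLUMNS)
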