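"""Mutational-signature refitting for clonal and subclonal catalogues.

Single-base substitutions are tallied into the standard 96 trinucleotide
channels (pyrimidine-strand convention) and decomposed over a catalogue
of reference SBS spectra by non-negative least squares.  A backward
selection procedure then prunes signatures whose removal barely changes
the reconstruction cost, keeping the minimal subset that still explains
the catalogue; cohort-level prevalence subsetting and mutation-count
eligibility thresholds decide which subsets are fitted at all.  The
platinum-chemotherapy signatures SBS31 and SBS35 are force-included when
fitting subclonal mutations of post-treatment samples.

Indel-based summary ratios (indel/substitution burden, deletion/insertion)
complement the SBS analysis, since ionizing radiation marks genomes by
deletions rather than single-base substitutions.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import nnls

BASES = "ACGT"
SUBSTITUTIONS = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
COMPLEMENT = str.maketrans("ACGT", "TGCA")

#: canonical channel order: A[C>A]A, A[C>A]C, ... T[T>G]T
SBS96_CHANNELS: tuple[str, ...] = tuple(
    f"{five}[{sub}]{three}" for sub in SUBSTITUTIONS for five in BASES for three in BASES
)

#: the prevalent signature subset used throughout, plus the platinum pair
PREVALENT_SIGNATURES = (
    "SBS1", "SBS2", "SBS3", "SBS4", "SBS5", "SBS13", "SBS15", "SBS16",
    "SBS24", "SBS29", "SBS39", "SBS40", "SBS92",
)
PLATINUM_SIGNATURES = ("SBS31", "SBS35")


@dataclass
class ExposureVector:
    """Fitted signature activities for one mutation subset."""

    exposures: pd.Series  # counts per signature, >= 0
    cost: float
    subset: str = ""  # e.g. clonal_C0 / subclonal_pre / subclonal_post

    @property
    def relative(self) -> pd.Series:
        total = self.exposures.sum()
        return self.exposures / total if total > 0 else self.exposures


def reverse_complement(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


def channel_of(context: str, ref: str, alt: str) -> str:
    """96-channel label of an SNM given its trinucleotide context.

    Purine references are folded onto the pyrimidine strand by reverse
    complementing context, ref and alt.
    """
    context, ref, alt = context.upper(), ref.upper(), alt.upper()
    if len(context) != 3 or context[1] != ref:
        raise ValueError(f"context {context!r} does not match ref {ref!r}")
    if ref in "AG":
        context, ref, alt = reverse_complement(context), ref.translate(COMPLEMENT), alt.translate(COMPLEMENT)
    return f"{context[0]}[{ref}>{alt}]{context[2]}"


def build_catalogue(mutations: pd.DataFrame, subset: str = "") -> tuple[pd.Series, int]:
    """96-channel count vector from SNMs with a ``trinucleotide`` column.

    Non-SNM rows (indels) are skipped and counted; the vector sums to the
    number of tallied SNMs.
    """
    counts = pd.Series(0, index=list(SBS96_CHANNELS), name=subset or "catalogue")
    skipped = 0
    for _, row in mutations.iterrows():
        if row.get("kind", "SNM") != "SNM":
            skipped += 1
            continue
        counts[channel_of(row["trinucleotide"], row["ref"], row["alt"])] += 1
    return counts, skipped


def read_catalog(path: str | Path) -> pd.DataFrame:
    """Read a COSMIC-layout signature TSV (channels x signatures).

    First column holds the channel labels ('Type'); remaining columns are
    signature probability vectors, each summing to 1.
    """
    df = pd.read_csv(path, sep="\t")
    df = df.set_index(df.columns[0])
    df = df.loc[list(SBS96_CHANNELS)]
    sums = df.sum(axis=0)
    if not np.allclose(sums, 1.0, atol=1e-4):
        raise ValueError("signature columns must each sum to 1")
    if (df.to_numpy() < 0).any():
        raise ValueError("signature catalogue must be non-negative")
    return df


def write_catalog(catalog: pd.DataFrame, path: str | Path) -> None:
    out = catalog.copy()
    out.index.name = "Type"
    out.to_csv(path, sep="\t")


def synthetic_catalog(
    names: tuple[str, ...] = PREVALENT_SIGNATURES + PLATINUM_SIGNATURES,
) -> pd.DataFrame:
    """Deterministic synthetic stand-in for a COSMIC SBS catalogue.

    Each named signature is a sparse random 96-channel spectrum drawn
    from a symmetric Dirichlet (concentration 0.08) seeded by the CRC of
    the signature name, so profiles are stable across runs, mutually
    near-orthogonal and realistic in sparsity.  This is synthetic data
    for tests and simulations, not the COSMIC reference profiles; real
    analyses should load a COSMIC file via :func:`read_catalog`.
    """
    cols = {}
    for name in names:
        rng = np.random.default_rng(zlib.crc32(name.encode()) % (2**31))
        v = rng.dirichlet(np.full(96, 0.08))
        cols[name] = v / v.sum()
    return pd.DataFrame(cols, index=list(SBS96_CHANNELS))


def sample_catalogue(catalog: pd.DataFrame, exposures: dict[str, float], n: int,
                     rng: np.random.Generator) -> pd.Series:
    """Draw ``n`` mutations from a signature mixture (testing/simulation)."""
    w = np.zeros(96)
    for name, e in exposures.items():
        w += e * catalog[name].to_numpy()
    w /= w.sum()
    counts = rng.multinomial(n, w)
    return pd.Series(counts, index=list(SBS96_CHANNELS))


def fit_exposures(catalogue: pd.Series, catalog: pd.DataFrame, subset: str = "") -> ExposureVector:
    """Non-negative least-squares decomposition of a 96-channel catalogue.

    Exposures are in mutation-count space (they need not sum exactly to
    the catalogue total because the fit is unconstrained in scale); the
    reported cost is the L2 reconstruction residual.
    """
    if catalog.shape[1] == 0:
        raise ValueError("empty signature subset")
    y = catalogue.loc[list(SBS96_CHANNELS)].to_numpy(dtype=float)
    if y.sum() <= 0:
        raise ValueError("empty mutation catalogue")
    A = catalog.loc[list(SBS96_CHANNELS)].to_numpy(dtype=float)
    x, cost = nnls(A, y)
    return ExposureVector(pd.Series(x, index=catalog.columns), float(cost), subset)


def backward_select(
    catalogue: pd.Series,
    catalog: pd.DataFrame,
    cost_threshold: float = 0.02,
    subset: str = "",
) -> ExposureVector:
    """Minimal signature subset whose fit cost stays near the full fit.

    Iteratively removes the signature whose removal increases the cost
    least, as long as the refitted cost stays within ``cost_threshold``
    (relative) of the full-catalogue fit; signatures that are exactly
    redundant are always removable.  Returns the refit on the surviving
    subset (absent signatures carry exposure 0).
    """
    full = fit_exposures(catalogue, catalog, subset)
    budget = full.cost * (1.0 + cost_threshold) + 1e-9
    keep = list(catalog.columns)
    current = full
    while len(keep) > 1:
        best = None
        for name in keep:
            trial = [s for s in keep if s != name]
            fit = fit_exposures(catalogue, catalog[trial], subset)
            if fit.cost <= budget and (best is None or fit.cost < best[0].cost):
                best = (fit, name)
        if best is None:
            break
        current, removed = best
        keep.remove(removed)
    exposures = pd.Series(0.0, index=catalog.columns)
    exposures[keep] = current.exposures
    return ExposureVector(exposures, current.cost, subset)


def cohort_subset(
    per_case_exposures: list[pd.Series],
    min_cases: int = 5,
    force_platinum: bool = False,
) -> list[str]:
    """Signatures active (exposure > 0) in at least ``min_cases`` cases.

    ``force_platinum`` adds SBS31/SBS35 regardless of prevalence — the
    subset used when fitting subclonal mutations of post-treatment
    samples, where platinum scars are expected a priori.
    """
    if not per_case_exposures:
        raise ValueError("empty cohort")
    active = pd.DataFrame([e > 0 for e in per_case_exposures]).sum(axis=0)
    selected = [s for s in active.index if active[s] >= min_cases]
    if force_platinum:
        for s in PLATINUM_SIGNATURES:
            if s not in selected:
                selected.append(s)
    return selected


def eligibility(n_mutations: int, kind: str, config=None) -> bool:
    """Whether a mutation subset is large enough to fit signatures to.

    Clonal fits need > 300 mutations, subclonal fits > 20 (both strict).
    """
    from .config import PipelineConfig

    config = config or PipelineConfig()
    if kind == "clonal":
        return n_mutations > config.min_clonal_mut
    if kind == "subclonal":
        return n_mutations > config.min_subclonal_mut
    raise ValueError(f"unknown subset kind {kind!r}")


def radiation_ratios(mutations: pd.DataFrame) -> tuple[float | None, float | None]:
    """(indel/substitution burden, deletion/insertion) ratios.

    Radiation damage shows as deletions rather than base substitutions;
    undefined denominators yield None, never 0.
    """
    n_snm = int((mutations["kind"] == "SNM").sum())
    n_ins = int((mutations["kind"] == "insertion").sum())
    n_del = int((mutations["kind"] == "deletion").sum())
    indel_sub = (n_ins + n_del) / n_snm if n_snm > 0 else None
    del_ins = n_del / n_ins if n_ins > 0 else None
    return indel_sub, del_ins
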