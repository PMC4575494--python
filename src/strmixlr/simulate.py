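"""Deterministic synthetic data: frequency tables, genotypes and evidence.

The generator provides everything a self-contained analysis needs — a
frequency database, reference profiles drawn from it, and evidence profiles
produced under a known drop-out/drop-in regime — so the engine can be
exercised and calibrated without any external population data.

The generative drop-out mechanism is independence per allele copy (each of
the c copies of an allele survives with probability 1 - p_do), which matches
the likelihood model's per-allele factors exactly when alpha = 1.  The
likelihood's alpha < 1 is a correction applied on the inference side with no
generative counterpart, so simulator-versus-engine agreement checks pin
alpha = 1.  Drop-in adds exactly one frequency-weighted allele with
probability p_di.  Peak heights, stutter and degradation are not simulated.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np

from .datamodel import FrequencyTable, Genotype, LocusEvidence, ReferenceProfile


def make_frequency_table(
    seed: int,
    markers: int = 5,
    alleles_per_marker: int = 6,
    n_individuals: int = 1000,
) -> FrequencyTable:
    """Random frequency table; per-locus frequencies sum exactly to 1.

    Markers are named "M1".."Mk"; alleles at every marker are labelled "8",
    "9", ... following STR repeat-count convention.  Frequencies are
    normalized Dirichlet-like draws, reproducible from ``seed``.
    """
    if markers < 1 or alleles_per_marker < 1:
        raise ValueError("markers and alleles_per_marker must be >= 1")
    rng = np.random.default_rng(seed)
    freqs: dict[str, dict[str, float]] = {}
    labels = [str(8 + k) for k in range(alleles_per_marker)]
    for m in range(1, markers + 1):
        raw = rng.gamma(shape=2.0, scale=1.0, size=alleles_per_marker)
        norm = raw / raw.sum()
        # largest allele absorbs rounding residue so the sum is exactly 1
        vals = [float(v) for v in norm]
        residue = 1.0 - sum(vals)
        vals[int(np.argmax(norm))] += residue
        freqs[f"M{m}"] = dict(zip(labels, vals))
    return FrequencyTable(
        population=f"synthetic-{seed}", n_individuals=n_individuals, freqs=freqs
    )


def sample_genotype(
    table: FrequencyTable, marker: str, rng: np.random.Generator
) -> Genotype:
    """Two independent draws from the locus frequencies (theta = 0)."""
    fmap = table.freqs[marker]
    alleles = list(fmap)
    probs = np.asarray([fmap[a] for a in alleles], dtype=float)
    probs = probs / probs.sum()
    a1, a2 = rng.choice(len(alleles), size=2, replace=True, p=probs)
    return Genotype(alleles[int(a1)], alleles[int(a2)])


def sample_profile(
    table: FrequencyTable, sample_name: str, rng: np.random.Generator
) -> ReferenceProfile:
    """A full reference profile with one genotype per marker in the table."""
    return ReferenceProfile(
        sample_name=sample_name,
        genotypes={m: sample_genotype(table, m, rng) for m in table.freqs},
    )


def simulate_evidence(
    contributors: Sequence[ReferenceProfile],
    p_do: float,
    p_di: float,
    table: FrequencyTable,
    rng: np.random.Generator,
    markers: Optional[Sequence[str]] = None,
) -> dict[str, LocusEvidence]:
    """Simulate an evidence profile from typed contributors.

    Every allele copy drops independently with probability ``p_do``; with
    probability ``p_di`` exactly one drop-in allele (frequency-weighted) is
    added.  Loci where everything drops out stay in the output with an empty
    detected set.
    """
    if markers is None:
        markers = list(table.freqs)
    out: dict[str, LocusEvidence] = {}
    for marker in markers:
        detected: set[str] = set()
        for person in contributors:
            g = person.genotypes[marker]
            for allele in g.alleles():
                if rng.random() >= p_do:
                    detected.add(allele)
        if rng.random() < p_di:
            fmap = table.freqs[marker]
            alleles = list(fmap)
            probs = np.asarray([fmap[a] for a in alleles], dtype=float)
            probs = probs / probs.sum()
            detected.add(alleles[int(rng.choice(len(alleles), p=probs))])
        out[marker] = LocusEvidence(marker=marker, detected=frozenset(detected))
    return out
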