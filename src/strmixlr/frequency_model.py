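"""Allele-frequency adjustment and theta-corrected sampling probabilities.

Two population-genetic corrections are applied before likelihoods are
computed:

* a minimum-frequency floor of 5/(2n) for any allele appearing in the
  suspected contributor's profile or the evidence, where n is the number of
  individuals in the frequency database — rare and previously unobserved
  alleles are never given an unrealistically small (or zero) frequency;

* the Balding–Nichols coancestry adjustment, applied at the allelic level:
  the probability of sampling one more copy of allele a, given that m_a
  copies have already been sampled out of m total, is

      P(a | counts) = (m_a * theta + (1 - theta) * p_a) / (1 + (m - 1) * theta)

  which reduces to p_a when theta = 0 or when nothing has been sampled yet.

Genotype probabilities are built from two sequential allelic draws (the draw
order does not matter), and relative genotype probabilities mix over the
number of alleles shared identical-by-descent with the suspected contributor.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

from .datamodel import Allele, FrequencyTable, Genotype, IBDTriple


@dataclass
class ConditioningCounts:
    """Counts of allele copies already sampled (suspect + assumed donors +
    previously drawn unknown alleles) for the sequential sampling formula."""

    counts: dict[Allele, int] = field(default_factory=dict)

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def copy(self) -> "ConditioningCounts":
        return ConditioningCounts(dict(self.counts))

    def add(self, allele: Allele, copies: int = 1) -> None:
        self.counts[allele] = self.counts.get(allele, 0) + copies

    def add_genotype(self, g: Genotype) -> None:
        self.add(g.a1)
        self.add(g.a2)

    @classmethod
    def from_genotypes(cls, genotypes: Iterable[Genotype]) -> "ConditioningCounts":
        cc = cls()
        for g in genotypes:
            cc.add_genotype(g)
        return cc


def apply_min_frequency(
    table: FrequencyTable, flagged: Mapping[str, Iterable[Allele]]
) -> FrequencyTable:
    """Return a copy of ``table`` with the 5/(2n) floor applied.

    ``flagged`` maps each marker to the alleles seen in the suspect profile or
    the evidence there.  Flagged alleles below the floor are raised to it;
    flagged alleles absent from the table are inserted at it; everything else
    is untouched and no renormalization is performed (per-locus sums may
    slightly exceed 1).  Idempotent.
    """
    floor = table.min_frequency
    new_freqs = {m: dict(fmap) for m, fmap in table.freqs.items()}
    for marker, alleles in flagged.items():
        locus = new_freqs.setdefault(marker, {})
        for a in alleles:
            if locus.get(a, 0.0) < floor:
                locus[a] = floor
    return FrequencyTable(
        population=table.population, n_individuals=table.n_individuals, freqs=new_freqs
    )


def conditional_allele_prob(
    a: Allele,
    cond: ConditioningCounts,
    theta: float,
    locus_freqs: Mapping[Allele, float],
) -> float:
    """Balding–Nichols probability of sampling one more copy of ``a``."""
    try:
        p_a = locus_freqs[a]
    except KeyError:
        raise KeyError(
            f"allele {a!r} has no frequency at this locus; the minimum-frequency "
            "floor must be applied to suspect and evidence alleles first"
        ) from None
    m = cond.total
    if m == 0:
        return p_a
    m_a = cond.counts.get(a, 0)
    return (m_a * theta + (1.0 - theta) * p_a) / (1.0 + (m - 1) * theta)


def genotype_prob(
    g: Genotype,
    cond: ConditioningCounts,
    theta: float,
    locus_freqs: Mapping[Allele, float],
) -> float:
    """Probability of an unknown individual's genotype under the coancestry
    model: two sequential allelic draws, times 2 for a heterozygote."""
    p1 = conditional_allele_prob(g.a1, cond, theta, locus_freqs)
    inner = cond.copy()
    inner.add(g.a1)
    p2 = conditional_allele_prob(g.a2, inner, theta, locus_freqs)
    p = p1 * p2
    if not g.is_homozygous:
        p *= 2.0
    return p


def _one_ibd_prob(
    g: Genotype,
    suspect_g: Genotype,
    cond: ConditioningCounts,
    theta: float,
    locus_freqs: Mapping[Allele, float],
) -> float:
    """P(relative has genotype g | exactly one allele shared IBD).

    For a heterozygous suspect each allele is the shared one with probability
    1/2; the non-shared allele is a fresh conditional draw.  The IBD copy is
    inherited, not sampled from the population, so it does not update the
    conditioning counts for the non-shared draw.  Summed over the ways g can
    arise (shared-allele choice x position of the free allele in g).
    """
    total = 0.0
    shared_options = (
        [(suspect_g.a1, 0.5), (suspect_g.a2, 0.5)]
        if not suspect_g.is_homozygous
        else [(suspect_g.a1, 1.0)]
    )
    for shared, w in shared_options:
        # ways the unordered pair g can contain the shared allele
        if g.is_homozygous:
            if g.a1 == shared:
                total += w * conditional_allele_prob(g.a1, cond, theta, locus_freqs)
        else:
            if g.a1 == shared:
                total += w * conditional_allele_prob(g.a2, cond, theta, locus_freqs)
            elif g.a2 == shared:
                total += w * conditional_allele_prob(g.a1, cond, theta, locus_freqs)
    return total


def relative_genotype_prob(
    g: Genotype,
    suspect_g: Genotype,
    ibd: IBDTriple,
    cond: ConditioningCounts,
    theta: float,
    locus_freqs: Mapping[Allele, float],
) -> float:
    """Genotype probability for a relative of the suspected contributor.

    Mixes the identical-by-descent sharing states: with probability k2 the
    relative carries the suspect's genotype; with k1 one allele is shared and
    the other is a conditional population draw; with k0 the relative is an
    ordinary unknown.
    """
    p = 0.0
    if ibd.k2 > 0.0 and g == suspect_g:
        p += ibd.k2
    if ibd.k1 > 0.0:
        p += ibd.k1 * _one_ibd_prob(g, suspect_g, cond, theta, locus_freqs)
    if ibd.k0 > 0.0:
        p += ibd.k0 * genotype_prob(g, cond, theta, locus_freqs)
    return p


def all_genotypes(alleles: Iterable[Allele]) -> list[Genotype]:
    """All A(A+1)/2 unordered genotypes constructible from an allele set."""
    uniq = sorted(set(alleles))
    return [
        Genotype(uniq[i], uniq[j])
        for i in range(len(uniq))
        for j in range(i, len(uniq))
    ]
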