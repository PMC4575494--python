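"""Per-locus evidence probabilities and likelihood ratios.

The semi-continuous model scores an evidence profile E at a locus given a
hypothesized set of contributors by the drop-out and drop-in events needed to
turn the contributors' alleles into E:

* a contributor allele carried in c copies drops out entirely with
  probability alpha^(c-1) * P(D_O)^c (alpha < 1 makes complete drop-out of a
  homozygote rarer than independence would predict), and is detected with one
  minus that;
* an evidence allele attributable to an assumed (undisputed) donor is masked:
  its detection is certain, factor 1, regardless of how many hypothesized
  contributors also carry it;
* evidence alleles carried by no hypothesized contributor must have dropped
  in: at most one drop-in per locus, with probability P(D_I) weighted by the
  allele's (floored) population frequency; two or more unexplained alleles
  make the hypothesis impossible at that locus.

Unknown contributors are marginalized by the law of total probability over
their genotypes, sampled sequentially with the Balding–Nichols coancestry
adjustment.  Two routes compute this sum: ``brute_force_sum`` enumerates
ordered genotype tuples directly, and ``sum_over_unknowns`` runs a dynamic
program over allele-count vectors that exploits the exchangeability of
sequential draws; the brute force is the reference the DP must reproduce.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

from .datamodel import (
    Allele,
    FrequencyTable,
    Genotype,
    Hypothesis,
    HypothesisPair,
    IBDTriple,
    LocusEvidence,
    LRResult,
    Params,
    ReferenceProfile,
)
from .frequency_model import (
    ConditioningCounts,
    all_genotypes,
    apply_min_frequency,
    genotype_prob,
    relative_genotype_prob,
)

_BRUTE_FORCE_GUARD = 10_000_000


def dropout_prob(copies: int, p_do: float, alpha: float) -> float:
    """Probability that all ``copies`` copies of an allele drop out:
    alpha^(copies-1) * p_do^copies."""
    if copies < 1:
        raise ValueError("dropout_prob requires at least one allele copy")
    return alpha ** (copies - 1) * p_do**copies


def _evidence_factor(
    allele: Allele,
    copies: int,
    detected: frozenset[Allele],
    mask: frozenset[Allele],
    params: Params,
) -> float:
    """Drop-out/detection factor for one contributor allele (copies >= 1)."""
    if allele in mask:
        return 1.0
    d = dropout_prob(copies, params.p_dropout, params.alpha)
    return (1.0 - d) if allele in detected else d


def locus_evidence_prob(
    evidence: LocusEvidence,
    contributor_counts: Mapping[Allele, int],
    mask: frozenset[Allele],
    params: Params,
    locus_freqs: Mapping[Allele, float],
) -> float:
    """P(E | fully specified contributor allele counts) at one locus."""
    detected = evidence.detected
    if not mask <= detected:
        raise ValueError("masking set must be a subset of detected alleles")
    prob = 1.0
    for allele, copies in contributor_counts.items():
        if copies <= 0:
            continue
        prob *= _evidence_factor(allele, copies, detected, mask, params)
    carried = {a for a, c in contributor_counts.items() if c > 0}
    unexplained = detected - carried - mask
    if len(unexplained) == 0:
        prob *= 1.0 - params.p_dropin
    elif len(unexplained) == 1:
        (d,) = unexplained
        try:
            p_d = locus_freqs[d]
        except KeyError:
            raise KeyError(
                f"drop-in allele {d!r} has no frequency; apply the minimum-"
                "frequency floor to evidence alleles first"
            ) from None
        prob *= params.p_dropin * p_d
    else:
        return 0.0
    return prob


def brute_force_sum(
    evidence: LocusEvidence,
    fixed: Mapping[Allele, int],
    mask: frozenset[Allele],
    n_unknown: int,
    relative: Optional[tuple[IBDTriple, Genotype]],
    base_cond: ConditioningCounts,
    params: Params,
    locus_freqs: Mapping[Allele, float],
) -> float:
    """Naive law-of-total-probability sum over unknown-contributor genotypes.

    Enumerates ordered genotype tuples with sequential conditional genotype
    probabilities (each drawn genotype joins the conditioning counts for the
    next).  Reference implementation for ``sum_over_unknowns``; guarded
    against combinatorial blow-up.
    """
    if not locus_freqs:
        raise ValueError("empty allele universe at this locus")
    genos = all_genotypes(locus_freqs)
    if len(genos) ** max(n_unknown, 0) > _BRUTE_FORCE_GUARD:
        raise ValueError("genotype combination count exceeds brute-force guard")

    def leaf(counts: dict[Allele, int]) -> float:
        total = {a: c for a, c in fixed.items()}
        for a, c in counts.items():
            total[a] = total.get(a, 0) + c
        return locus_evidence_prob(evidence, total, mask, params, locus_freqs)

    def recurse(
        remaining: int, cond: ConditioningCounts, counts: dict[Allele, int]
    ) -> float:
        if remaining == 0:
            return leaf(counts)
        acc = 0.0
        for g in genos:
            pg = genotype_prob(g, cond, params.theta, locus_freqs)
            if pg == 0.0:
                continue
            cond2 = cond.copy()
            cond2.add_genotype(g)
            counts2 = dict(counts)
            for a in g.alleles():
                counts2[a] = counts2.get(a, 0) + 1
            acc += pg * recurse(remaining - 1, cond2, counts2)
        return acc

    if relative is not None:
        ibd, suspect_g = relative
        if n_unknown < 1:
            raise ValueError("a relative hypothesis consumes one unknown slot")
        acc = 0.0
        for g in all_genotypes(locus_freqs):
            pr = relative_genotype_prob(
                g, suspect_g, ibd, base_cond, params.theta, locus_freqs
            )
            if pr == 0.0:
                continue
            cond2 = base_cond.copy()
            cond2.add_genotype(g)
            counts = {}
            for a in g.alleles():
                counts[a] = counts.get(a, 0) + 1
            acc += pr * recurse(n_unknown - 1, cond2, counts)
        return acc

    return recurse(n_unknown, base_cond, {})


def _dp_sum_unrelated(
    evidence: LocusEvidence,
    fixed: Mapping[Allele, int],
    mask: frozenset[Allele],
    n_unknown: int,
    base_cond: ConditioningCounts,
    params: Params,
    locus_freqs: Mapping[Allele, float],
) -> float:
    """DP over allele-count vectors for ``n_unknown`` unrelated unknowns.

    Sequential Balding–Nichols draws are exchangeable: every ordered sequence
    of 2U alleles with count vector c has the same probability, with a
    numerator that factorizes per allele and a denominator common to all
    sequences.  Reading a sequence as U consecutive pairs puts ordered
    sequences in bijection with (ordered genotype tuple, within-pair order)
    combinations, so summing multinomial(2U; c) x sequence probability x
    evidence factor over count vectors equals the brute-force genotype sum.
    The drop-in state is carried as the number of evidence alleles left
    unexplained, capped at 2 (at which point the term is impossible).
    """
    detected = evidence.detected
    theta = params.theta
    n_draws = 2 * n_unknown
    table_alleles = sorted(locus_freqs)

    for a in detected - mask:
        if a not in locus_freqs:
            raise KeyError(
                f"evidence allele {a!r} has no frequency; apply the minimum-"
                "frequency floor first"
            )

    # contributor alleles outside the drawable universe keep their fixed factor
    prefactor = 1.0
    for a, c in fixed.items():
        if c > 0 and a not in locus_freqs:
            prefactor *= _evidence_factor(a, c, detected, mask, params)
    if prefactor == 0.0:
        return 0.0

    # state: (draws used, unexplained evidence alleles so far) -> partial sum
    states: dict[tuple[int, int], float] = {(0, 0): prefactor}
    for a in table_alleles:
        p_a = locus_freqs[a]
        m_a = base_cond.counts.get(a, 0)
        f_a = fixed.get(a, 0)
        new_states: dict[tuple[int, int], float] = {}
        for (used, unexp), val in states.items():
            seq_num = 1.0  # prod_{j<c} ((m_a+j)theta + (1-theta)p_a) / c!
            for c in range(0, n_draws - used + 1):
                if c > 0:
                    seq_num *= ((m_a + c - 1) * theta + (1.0 - theta) * p_a) / c
                total_copies = f_a + c
                n_unexp = unexp
                if a in mask:
                    ev = 1.0
                elif total_copies > 0:
                    ev = _evidence_factor(a, total_copies, detected, mask, params)
                elif a in detected:
                    # unexplained: weight by drop-in frequency, count it
                    ev = p_a
                    n_unexp += 1
                else:
                    ev = 1.0
                if n_unexp >= 2:
                    continue
                contrib = val * seq_num * ev
                if contrib == 0.0 and c == 0:
                    continue
                key = (used + c, n_unexp)
                new_states[key] = new_states.get(key, 0.0) + contrib
        states = new_states

    t0 = base_cond.total
    seq_denom = 1.0
    for i in range(n_draws):
        seq_denom *= 1.0 + (t0 + i - 1) * theta
    total = 0.0
    for (used, unexp), val in states.items():
        if used != n_draws:
            continue
        dropin = (1.0 - params.p_dropin) if unexp == 0 else params.p_dropin
        total += val * dropin
    return total * math.factorial(n_draws) / seq_denom


def sum_over_unknowns(
    evidence: LocusEvidence,
    fixed: Mapping[Allele, int],
    mask: frozenset[Allele],
    n_unknown: int,
    relative: Optional[tuple[IBDTriple, Genotype]],
    base_cond: ConditioningCounts,
    params: Params,
    locus_freqs: Mapping[Allele, float],
) -> float:
    """P(E | typed contributors + ``n_unknown`` unknowns), marginalizing the
    unknowns' genotypes by dynamic programming.

    A relative contributor (at most one) is enumerated explicitly around the
    DP; its realized genotype joins both the contributor counts and the
    conditioning counts for the remaining unknowns.
    """
    if not locus_freqs:
        raise ValueError("empty allele universe at this locus")
    if n_unknown < 0 or n_unknown > 4:
        raise ValueError("n_unknown must be between 0 and 4")

    if relative is None:
        return _dp_sum_unrelated(
            evidence, fixed, mask, n_unknown, base_cond, params, locus_freqs
        )

    ibd, suspect_g = relative
    if n_unknown < 1:
        raise ValueError("a relative hypothesis consumes one unknown slot")
    acc = 0.0
    for g in all_genotypes(locus_freqs):
        pr = relative_genotype_prob(
            g, suspect_g, ibd, base_cond, params.theta, locus_freqs
        )
        if pr == 0.0:
            continue
        cond2 = base_cond.copy()
        cond2.add_genotype(g)
        fixed2 = dict(fixed)
        for a in g.alleles():
            fixed2[a] = fixed2.get(a, 0) + 1
        acc += pr * _dp_sum_unrelated(
            evidence, fixed2, mask, n_unknown - 1, cond2, params, locus_freqs
        )
    return acc


@dataclass
class LocusLR:
    """Numerator and denominator probabilities and their ratio at one locus."""

    numerator: float
    denominator: float
    lr: float
    warning: Optional[str] = None


def _genotype_counts(g: Genotype) -> dict[Allele, int]:
    counts: dict[Allele, int] = {}
    for a in g.alleles():
        counts[a] = counts.get(a, 0) + 1
    return counts


def locus_lr(
    evidence: LocusEvidence,
    suspect_g: Optional[Genotype],
    assumed_gs: Sequence[Genotype],
    hyp: HypothesisPair,
    params: Params,
    locus_freqs: Mapping[Allele, float],
) -> LocusLR:
    """Likelihood ratio at one locus.

    Assumed donors contribute only masking (their detected alleles) and
    conditioning counts; the suspect's genotype conditions the unknown-
    genotype sampling on both sides, which is what lets theta > 0 raise the
    denominator toward the suspect's profile.
    """
    mask_alleles: set[Allele] = set()
    for g in assumed_gs:
        mask_alleles.update(g.alleles())
    mask = frozenset(mask_alleles & set(evidence.detected))

    base_cond = ConditioningCounts()
    if suspect_g is not None:
        base_cond.add_genotype(suspect_g)
    for g in assumed_gs:
        base_cond.add_genotype(g)

    def side_prob(h: Hypothesis) -> float:
        if h.includes_suspect:
            if suspect_g is None:
                raise ValueError(
                    "hypothesis includes the suspect but no suspect genotype is "
                    "available at this locus"
                )
            fixed = _genotype_counts(suspect_g)
        else:
            fixed = {}
        rel = None
        if h.relative is not None:
            if suspect_g is None:
                raise ValueError(
                    "relative hypothesis requires a suspect genotype at this locus"
                )
            rel = (h.relative, suspect_g)
        return sum_over_unknowns(
            evidence, fixed, mask, h.n_unknowns, rel, base_cond, params, locus_freqs
        )

    num = side_prob(hyp.numerator)
    den = side_prob(hyp.denominator)
    if den > 0.0:
        return LocusLR(num, den, num / den)
    if num == 0.0:
        return LocusLR(
            num, den, 1.0,
            warning="both hypotheses assign probability 0 to this locus; "
            "LR reported as 1",
        )
    return LocusLR(
        num, den, math.inf,
        warning="denominator probability is 0 while numerator is positive; "
        "LR is infinite",
    )


def compute_case(
    evidence: Mapping[str, LocusEvidence],
    suspect: Optional[ReferenceProfile],
    hyp: HypothesisPair,
    params: Params,
    tables: Sequence[FrequencyTable],
) -> list[LRResult]:
    """Compute per-locus and overall LRs for every population table.

    For each population the 5/(2n) floor is applied to suspect and evidence
    alleles, then every evidence marker is scored and the overall LR is the
    product across markers.
    """
    flagged: dict[str, set[Allele]] = {}
    for marker, ev in evidence.items():
        alleles = set(ev.detected)
        if suspect is not None and marker in suspect.genotypes:
            alleles.update(suspect.genotypes[marker].alleles())
        flagged[marker] = alleles

    results = []
    for table in tables:
        floored = apply_min_frequency(table, flagged)
        per_locus: dict[str, float] = {}
        warnings: dict[str, str] = {}
        overall = 1.0
        for marker, ev in evidence.items():
            sg = suspect.genotypes.get(marker) if suspect is not None else None
            assumed_gs = [
                p.genotypes[marker] for p in hyp.assumed if marker in p.genotypes
            ]
            res = locus_lr(ev, sg, assumed_gs, hyp, params, floored.freqs[marker])
            per_locus[marker] = res.lr
            overall *= res.lr
            if res.warning:
                warnings[marker] = res.warning
        results.append(
            LRResult(
                population=table.population,
                per_locus=per_locus,
                overall=overall,
                params=params,
                hypothesis=hyp.describe(),
                warnings=warnings,
            )
        )
    return results
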