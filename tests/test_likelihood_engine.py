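import itertools
import math

import numpy as np
import pytest

from strmixlr.datamodel import (
    FrequencyTable,
    Genotype,
    Hypothesis,
    HypothesisPair,
    IBDTriple,
    LocusEvidence,
    Params,
    ReferenceProfile,
)
from strmixlr.frequency_model import ConditioningCounts, genotype_prob
from strmixlr.likelihood_engine import (
    brute_force_sum,
    compute_case,
    dropout_prob,
    locus_evidence_prob,
    locus_lr,
    sum_over_unknowns,
)


def ev(*alleles: str) -> LocusEvidence:
    return LocusEvidence("M", frozenset(alleles))


NO_MASK = frozenset()


class TestDropoutProb:
    @pytest.mark.parametrize(
        "copies, p_do, alpha, expected",
        [
            (1, 0.2, 0.5, 0.2),          # single copy: just P(D_O)
            (2, 0.2, 0.5, 0.02),         # homozygote: alpha * P(D_O)^2
            (3, 0.1, 0.5, 0.00025),      # alpha^2 * P(D_O)^3
            (2, 0.3, 1.0, 0.09),         # alpha=1 recovers independence
        ],
    )
    def test_copy_number_formula(self, copies, p_do, alpha, expected):
        assert dropout_prob(copies, p_do, alpha) == pytest.approx(expected, rel=1e-12)

    def test_zero_copies_rejected(self):
        with pytest.raises(ValueError):
            dropout_prob(0, 0.1, 0.5)


class TestLocusEvidenceProb:
    def test_full_detection_of_heterozygote(self, four_allele_locus):
        p = locus_evidence_prob(
            ev("8", "9"), {"8": 1, "9": 1}, NO_MASK,
            Params(p_dropout=0.1, p_dropin=0.01, theta=0.0), four_allele_locus,
        )
        assert p == pytest.approx(0.9 * 0.9 * 0.99, rel=1e-12)

    def test_one_allele_dropped(self, four_allele_locus):
        p = locus_evidence_prob(
            ev("8"), {"8": 1, "9": 1}, NO_MASK,
            Params(p_dropout=0.1, p_dropin=0.01, theta=0.0), four_allele_locus,
        )
        assert p == pytest.approx(0.9 * 0.1 * 0.99, rel=1e-12)

    def test_homozygote_detected_plus_dropin(self):
        freqs = {"a": 0.9, "b": 0.05}
        p = locus_evidence_prob(
            ev("a", "b"), {"a": 2}, NO_MASK,
            Params(p_dropout=0.1, p_dropin=0.01, theta=0.0, alpha=0.5), freqs,
        )
        assert p == pytest.approx((1 - 0.5 * 0.01) * 0.01 * 0.05, rel=1e-12)

    def test_unexplained_allele_impossible_without_dropin(self, four_allele_locus):
        p = locus_evidence_prob(
            ev("8", "9"), {"8": 1}, NO_MASK,
            Params(p_dropout=0.1, p_dropin=0.0, theta=0.0), four_allele_locus,
        )
        assert p == 0.0

    def test_two_unexplained_alleles_impossible(self, four_allele_locus):
        p = locus_evidence_prob(
            ev("8", "9", "10"), {"8": 1}, NO_MASK,
            Params(p_dropout=0.1, p_dropin=0.05, theta=0.0), four_allele_locus,
        )
        assert p == 0.0

    def test_masked_allele_factor_is_one_even_with_copies(self, four_allele_locus):
        params = Params(p_dropout=0.4, p_dropin=0.0, theta=0.0)
        masked = locus_evidence_prob(
            ev("8"), {"8": 2}, frozenset({"8"}), params, four_allele_locus
        )
        assert masked == pytest.approx(1.0)

    def test_empty_locus_complete_dropout(self, four_allele_locus):
        params = Params(p_dropout=0.3, p_dropin=0.01, theta=0.0, alpha=0.5)
        p = locus_evidence_prob(ev(), {"8": 2}, NO_MASK, params, four_allele_locus)
        assert p == pytest.approx(0.5 * 0.09 * 0.99, rel=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_normalization_over_evidence_subsets(self, seed, four_allele_locus):
        """With p_di = 0, detect/drop-out factors are complementary, so the
        evidence probability sums to 1 over all subsets of contributor alleles."""
        rng = np.random.default_rng(seed)
        alleles = list(four_allele_locus)
        cc = {a: int(rng.integers(1, 4)) for a in rng.choice(alleles, 3, replace=False)}
        params = Params(
            p_dropout=float(rng.uniform(0, 0.9)),
            p_dropin=0.0,
            theta=0.0,
            alpha=float(rng.uniform(0.1, 1.0)),
        )
        total = 0.0
        support = sorted(cc)
        for r in range(len(support) + 1):
            for subset in itertools.combinations(support, r):
                total += locus_evidence_prob(
                    LocusEvidence("M", frozenset(subset)), cc, NO_MASK, params,
                    four_allele_locus,
                )
        assert total == pytest.approx(1.0, abs=1e-12)


class TestSumOverUnknowns:
    def test_zero_unknowns_reduces_to_evidence_prob(self, four_allele_locus):
        params = Params(p_dropout=0.2, p_dropin=0.01, theta=0.01)
        fixed = {"8": 1, "9": 1}
        cond = ConditioningCounts({"8": 1, "9": 1})
        got = sum_over_unknowns(
            ev("8", "9"), fixed, NO_MASK, 0, None, cond, params, four_allele_locus
        )
        want = locus_evidence_prob(ev("8", "9"), fixed, NO_MASK, params, four_allele_locus)
        assert got == pytest.approx(want, rel=1e-12)

    def test_one_unknown_only_matching_genotype_survives(self, four_allele_locus):
        """Without drop-out or drop-in, the only genotype compatible with a
        two-allele evidence profile is the matching heterozygote."""
        params = Params(p_dropout=0.0, p_dropin=0.0, theta=0.0)
        got = sum_over_unknowns(
            ev("8", "9"), {}, NO_MASK, 1, None, ConditioningCounts(), params,
            four_allele_locus,
        )
        assert got == pytest.approx(2 * 0.1 * 0.2, rel=1e-12)

    def test_two_unknowns_two_allele_locus_hand_expansion(self):
        """theta = 0: hand-expanded sum over the 9 ordered genotype pairs of a
        2-allele locus, each with its exact drop-out/drop-in factors."""
        pa, pb = 0.3, 0.7
        freqs = {"a": pa, "b": pb}
        d, di, alpha = 0.2, 0.01, 0.5
        params = Params(p_dropout=d, p_dropin=di, theta=0.0, alpha=alpha)

        def drop(c):
            return alpha ** (c - 1) * d**c

        expected = 0.0
        genos = [("a", "a"), ("a", "b"), ("b", "b")]
        gp = {("a", "a"): pa * pa, ("a", "b"): 2 * pa * pb, ("b", "b"): pb * pb}
        for g1 in genos:
            for g2 in genos:
                counts: dict[str, int] = {}
                for al in g1 + g2:
                    counts[al] = counts.get(al, 0) + 1
                # evidence {a, b}: both alleles must be detected (or dropped in)
                f = 1.0
                unexplained = []
                for al in ("a", "b"):
                    c = counts.get(al, 0)
                    if c:
                        f *= 1 - drop(c)
                    else:
                        unexplained.append(al)
                if len(unexplained) == 0:
                    f *= 1 - di
                elif len(unexplained) == 1:
                    f *= di * freqs[unexplained[0]]
                else:
                    f = 0.0
                expected += gp[g1] * gp[g2] * f

        got = sum_over_unknowns(
            ev("a", "b"), {}, NO_MASK, 2, None, ConditioningCounts(), params, freqs
        )
        assert got == pytest.approx(expected, rel=1e-12)

    def test_empty_allele_universe_rejected(self):
        with pytest.raises(ValueError):
            sum_over_unknowns(
                ev(), {}, NO_MASK, 1, None, ConditioningCounts(),
                Params(p_dropout=0.1), {},
            )


def _random_locus(rng, n_alleles):
    raw = rng.gamma(2.0, 1.0, n_alleles)
    raw = raw / raw.sum()
    return {str(8 + i): float(v) for i, v in enumerate(raw)}


def _random_case(rng):
    freqs = _random_locus(rng, int(rng.integers(2, 9)))
    labels = sorted(freqs)
    params = Params(
        p_dropout=float(rng.choice([0.0, 0.05, 0.3, 0.7])),
        p_dropin=float(rng.choice([0.0, 0.01, 0.05])),
        theta=float(rng.choice([0.0, 0.01, 0.03])),
        alpha=float(rng.choice([0.5, 1.0])),
    )
    detected = frozenset(a for a in labels if rng.random() < 0.5)
    evidence = LocusEvidence("M", detected)
    n_unknown = int(rng.integers(0, 4))
    fixed: dict[str, int] = {}
    cond = ConditioningCounts()
    suspect_g = None
    if rng.random() < 0.7:
        a1, a2 = rng.choice(labels, 2)
        suspect_g = Genotype(str(a1), str(a2))
        cond.add_genotype(suspect_g)
        if rng.random() < 0.5:
            for a in suspect_g.alleles():
                fixed[a] = fixed.get(a, 0) + 1
    mask = NO_MASK
    if detected and rng.random() < 0.4:
        mask = frozenset({str(rng.choice(sorted(detected)))})
    relative = None
    if suspect_g is not None and n_unknown >= 1 and not fixed and rng.random() < 0.4:
        relative = (IBDTriple(0.25, 0.5, 0.25), suspect_g)
    return evidence, fixed, mask, n_unknown, relative, cond, params, freqs


class TestOracleEquivalence:
    def test_dp_matches_brute_force_on_randomized_cases(self):
        """The count-vector DP must reproduce the naive genotype enumeration
        across allele counts, unknown counts, theta/drop-out/drop-in grids,
        masking and relative hypotheses."""
        rng = np.random.default_rng(424242)
        checked = 0
        for _ in range(250):
            case = _random_case(rng)
            dp = sum_over_unknowns(*case)
            bf = brute_force_sum(*case)
            assert dp == pytest.approx(bf, rel=1e-9, abs=1e-300)
            checked += 1
        assert checked == 250

    def test_brute_force_guard(self, four_allele_locus):
        freqs = {str(i): 1 / 60 for i in range(60)}
        with pytest.raises(ValueError):
            brute_force_sum(
                ev("1"), {}, NO_MASK, 4, None, ConditioningCounts(),
                Params(p_dropout=0.1), freqs,
            )


class TestLocusLR:
    def susp_vs_unknown(self):
        return HypothesisPair(Hypothesis(True, 0), Hypothesis(False, 1))

    def test_single_source_het_closed_form(self, four_allele_locus):
        params = Params(p_dropout=0.0, p_dropin=0.0, theta=0.0)
        sg = Genotype("8", "9")
        res = locus_lr(ev("8", "9"), sg, [], self.susp_vs_unknown(), params,
                       four_allele_locus)
        assert res.lr == pytest.approx(1.0 / (2 * 0.1 * 0.2), rel=1e-12)

    def test_single_source_hom_closed_form(self, four_allele_locus):
        params = Params(p_dropout=0.0, p_dropin=0.0, theta=0.0)
        sg = Genotype("8", "8")
        res = locus_lr(ev("8"), sg, [], self.susp_vs_unknown(), params,
                       four_allele_locus)
        assert res.lr == pytest.approx(100.0, rel=1e-12)

    def test_identical_hypotheses_give_lr_one(self, four_allele_locus):
        params = Params(p_dropout=0.2, p_dropin=0.01, theta=0.02)
        hyp = HypothesisPair(Hypothesis(False, 2), Hypothesis(False, 2))
        res = locus_lr(ev("8", "9"), Genotype("8", "9"), [], hyp, params,
                       four_allele_locus)
        assert res.lr == pytest.approx(1.0, rel=1e-12)

    def test_rmp_upper_bound(self):
        """LR for (suspect) vs (one unknown) never exceeds the inverse of the
        theta-corrected random match probability."""
        rng = np.random.default_rng(99)
        for _ in range(150):
            freqs = _random_locus(rng, int(rng.integers(2, 7)))
            labels = sorted(freqs)
            a1, a2 = rng.choice(labels, 2)
            sg = Genotype(str(a1), str(a2))
            params = Params(
                p_dropout=float(rng.uniform(0.0, 0.8)),
                p_dropin=float(rng.choice([0.0, 0.01, 0.05])),
                theta=float(rng.choice([0.0, 0.01, 0.03])),
            )
            detected = set(a for a in labels if rng.random() < 0.5)
            res = locus_lr(
                LocusEvidence("M", frozenset(detected)), sg, [],
                self.susp_vs_unknown(), params, freqs,
            )
            cond = ConditioningCounts()
            cond.add_genotype(sg)
            rmp = genotype_prob(sg, cond, params.theta, freqs)
            if math.isfinite(res.lr):
                assert res.lr <= 1.0 / rmp + 1e-9

    def test_relative_unrelated_limit(self, four_allele_locus):
        params = Params(p_dropout=0.1, p_dropin=0.01, theta=0.02)
        sg = Genotype("8", "9")
        plain = locus_lr(ev("8", "9"), sg, [], self.susp_vs_unknown(), params,
                         four_allele_locus)
        rel = locus_lr(
            ev("8", "9"), sg, [],
            HypothesisPair(
                Hypothesis(True, 0),
                Hypothesis(False, 1, relative=IBDTriple(1, 0, 0)),
            ),
            params, four_allele_locus,
        )
        assert rel.lr == pytest.approx(plain.lr, rel=1e-9)

    def test_identical_twin_denominator_gives_lr_one(self, four_allele_locus):
        params = Params(p_dropout=0.1, p_dropin=0.01, theta=0.02)
        sg = Genotype("8", "9")
        res = locus_lr(
            ev("8", "9"), sg, [],
            HypothesisPair(
                Hypothesis(True, 0),
                Hypothesis(False, 1, relative=IBDTriple(0, 0, 1)),
            ),
            params, four_allele_locus,
        )
        assert res.lr == pytest.approx(1.0, rel=1e-9)

    def test_sibling_denominator_lowers_lr(self, four_allele_locus):
        params = Params(p_dropout=0.0, p_dropin=0.0, theta=0.0)
        sg = Genotype("8", "9")
        plain = locus_lr(ev("8", "9"), sg, [], self.susp_vs_unknown(), params,
                         four_allele_locus)
        sib = locus_lr(
            ev("8", "9"), sg, [],
            HypothesisPair(
                Hypothesis(True, 0),
                Hypothesis(False, 1, relative=IBDTriple(0.25, 0.5, 0.25)),
            ),
            params, four_allele_locus,
        )
        assert sib.lr < plain.lr

    def test_theta_monotonicity_single_source(self, four_allele_locus):
        """For a full single-source match without drop-out/in, increasing
        theta brings the denominator closer to the suspect and lowers the LR."""
        sg = Genotype("8", "9")
        last = math.inf
        for theta in (0.0, 0.01, 0.02, 0.05, 0.1):
            params = Params(p_dropout=0.0, p_dropin=0.0, theta=theta)
            res = locus_lr(ev("8", "9"), sg, [], self.susp_vs_unknown(), params,
                           four_allele_locus)
            assert res.lr <= last + 1e-9
            last = res.lr

    def test_extra_unknown_on_both_sides_keeps_lr_finite(self, four_allele_locus):
        params = Params(p_dropout=0.3, p_dropin=0.01, theta=0.01)
        sg = Genotype("8", "9")
        res = locus_lr(
            ev("8", "9", "10"), sg, [],
            HypothesisPair(Hypothesis(True, 1), Hypothesis(False, 2)),
            params, four_allele_locus,
        )
        assert math.isfinite(res.lr) and res.lr > 0

    def test_masking_by_assumed_donor(self, four_allele_locus):
        """An assumed major donor's detected alleles stop penalizing the
        hypothesis: with masking the suspect's dropped allele is explained."""
        params = Params(p_dropout=0.0, p_dropin=0.0, theta=0.0)
        sg = Genotype("8", "9")
        donor_g = Genotype("8", "10")
        res = locus_lr(
            ev("8", "9", "10"), sg, [donor_g],
            HypothesisPair(Hypothesis(True, 0), Hypothesis(False, 1)),
            params, four_allele_locus,
        )
        assert math.isfinite(res.lr) and res.lr > 0

    def test_zero_zero_reports_lr_one_with_warning(self, four_allele_locus):
        # unexplained allele on both sides with p_di = 0: both probabilities 0
        params = Params(p_dropout=0.0, p_dropin=0.0, theta=0.0)
        sg = Genotype("8", "8")
        res = locus_lr(
            ev("8", "9", "10"), sg, [],
            HypothesisPair(Hypothesis(True, 0), Hypothesis(False, 1)),
            params, four_allele_locus,
        )
        assert res.numerator == 0.0 and res.denominator == 0.0
        assert res.lr == 1.0
        assert res.warning is not None

    def test_infinite_lr_with_warning(self):
        # evidence allele only the suspect can explain; denominator must drop
        # in two alleles at once -> impossible
        freqs = {"8": 0.5, "9": 0.5}
        params = Params(p_dropout=0.0, p_dropin=0.5, theta=0.0)
        sg = Genotype("8", "9")
        res = locus_lr(
            LocusEvidence("M", frozenset({"8", "9"})), sg, [],
            HypothesisPair(Hypothesis(True, 0), Hypothesis(False, 0)),
            params, freqs,
        )
        assert math.isinf(res.lr)
        assert res.warning is not None


class TestComputeCase:
    def test_structure_and_overall_product(self, small_table):
        suspect = ReferenceProfile(
            "S", {"D3S1358": Genotype("8", "9"), "VWA": Genotype("14", "15")}
        )
        evidence = {
            "D3S1358": LocusEvidence("D3S1358", frozenset({"8", "9"})),
            "VWA": LocusEvidence("VWA", frozenset({"14", "15"})),
        }
        hyp = HypothesisPair(Hypothesis(True, 0), Hypothesis(False, 1))
        params = Params(p_dropout=0.1)
        other = FrequencyTable("POP-B", 800, small_table.freqs)
        results = compute_case(evidence, suspect, hyp, params, [small_table, other])
        assert [r.population for r in results] == ["POP-A", "POP-B"]
        for r in results:
            assert set(r.per_locus) == {"D3S1358", "VWA"}
            prod = math.prod(r.per_locus.values())
            assert r.overall == pytest.approx(prod, rel=1e-9)

    def test_one_locus_case_equals_locus_lr(self, small_table):
        suspect = ReferenceProfile("S", {"VWA": Genotype("14", "15")})
        evidence = {"VWA": LocusEvidence("VWA", frozenset({"14", "15"}))}
        hyp = HypothesisPair(Hypothesis(True, 0), Hypothesis(False, 1))
        params = Params(p_dropout=0.1, p_dropin=0.0, theta=0.0)
        results = compute_case(evidence, suspect, hyp, params, [small_table])
        direct = locus_lr(
            evidence["VWA"], suspect.genotypes["VWA"], [], hyp, params,
            small_table.freqs["VWA"],
        )
        assert results[0].overall == pytest.approx(direct.lr, rel=1e-12)

    def test_floor_applied_to_unseen_suspect_allele(self):
        """A suspect allele missing from the table enters at 5/(2n) rather
        than crashing or getting probability zero."""
        table = FrequencyTable("P", 500, {"M": {"14": 0.9, "15": 0.1}})
        suspect = ReferenceProfile("S", {"M": Genotype("22", "22")})
        evidence = {"M": LocusEvidence("M", frozenset({"22"}))}
        hyp = HypothesisPair(Hypothesis(True, 0), Hypothesis(False, 1))
        params = Params(p_dropout=0.0, p_dropin=0.0, theta=0.0)
        results = compute_case(evidence, suspect, hyp, params, [table])
        floor = 5.0 / 1000.0
        assert results[0].overall == pytest.approx(1.0 / floor**2, rel=1e-9)
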