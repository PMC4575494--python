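"""Domain types for semi-continuous STR mixture interpretation.

Alleles are opaque string labels ("12", "13.3", "OL"): microvariants and
off-ladder calls pass through without numeric interpretation.  A genotype is
an unordered pair of alleles; reference profiles map markers to genotypes;
evidence is the per-marker set of detected alleles, optionally with peak
heights in RFU.

Hypotheses describe one side of a likelihood ratio: whether the suspected
contributor is a donor, how many unknown (untyped) donors there are, and
whether one unknown is replaced by a specified relative of the suspect
(summarised by IBD sharing probabilities k0/k1/k2).  Assumed donors — typed
individuals whose contribution is not in dispute — are common to both sides.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

MAX_UNKNOWNS = 4
MAX_UNKNOWNS_WITH_SUSPECT = 3

Allele = str


def clean_allele(label: str) -> Allele:
    """Normalize an allele label: strip whitespace, require non-empty."""
    s = str(label).strip()
    if not s:
        raise ValueError("allele label must be a non-empty string")
    return s


@dataclass(frozen=True)
class Genotype:
    """Unordered pair of alleles; ``a1 == a2`` for a homozygote.

    The pair is canonically ordered at construction so (x, y) and (y, x)
    compare and hash equal.
    """

    a1: Allele
    a2: Allele

    def __post_init__(self) -> None:
        a1 = clean_allele(self.a1)
        a2 = clean_allele(self.a2)
        if a2 < a1:
            a1, a2 = a2, a1
        object.__setattr__(self, "a1", a1)
        object.__setattr__(self, "a2", a2)

    @property
    def is_homozygous(self) -> bool:
        return self.a1 == self.a2

    def alleles(self) -> tuple[Allele, Allele]:
        return (self.a1, self.a2)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.a1}/{self.a2}"


@dataclass
class LocusEvidence:
    """Detected alleles at one marker; empty set = complete locus drop-out."""

    marker: str
    detected: frozenset[Allele]
    heights: Optional[dict[Allele, float]] = None

    def __post_init__(self) -> None:
        self.detected = frozenset(clean_allele(a) for a in self.detected)
        if self.heights is not None:
            self.heights = {clean_allele(a): float(h) for a, h in self.heights.items()}
            extra = set(self.heights) - set(self.detected)
            if extra:
                raise ValueError(
                    f"heights for undetected alleles at {self.marker}: {sorted(extra)}"
                )
            for a, h in self.heights.items():
                if not (h > 0):
                    raise ValueError(f"non-positive peak height {h} for {a} at {self.marker}")


@dataclass
class ReferenceProfile:
    """Per-locus genotypes of a typed individual (suspect or assumed donor)."""

    sample_name: str
    genotypes: dict[str, Genotype]


@dataclass
class FrequencyTable:
    """Per-population allele frequencies with database size.

    ``n_individuals`` is the number of individuals in the frequency database,
    which sets the 5/(2n) minimum-frequency floor.  Per-locus frequency sums
    may exceed 1 after the floor is applied; no renormalization is done.
    """

    population: str
    n_individuals: int
    freqs: dict[str, dict[Allele, float]]

    def __post_init__(self) -> None:
        if self.n_individuals <= 0:
            raise ValueError("n_individuals must be a positive integer")
        for marker, fmap in self.freqs.items():
            for allele, f in fmap.items():
                if not (0.0 < f <= 1.0):
                    raise ValueError(
                        f"frequency {f} for {marker} allele {allele} outside (0, 1]"
                    )

    @property
    def min_frequency(self) -> float:
        """The 5/(2n) floor value for this database."""
        return 5.0 / (2.0 * self.n_individuals)


@dataclass(frozen=True)
class Params:
    """Scalar model parameters.

    p_dropout : probability a single allele copy from a true contributor is
        not detected, P(D_O).
    p_dropin : probability that exactly one spurious allele appears at a
        locus, P(D_I); default 0.01.
    theta : coancestry coefficient (F_ST) for the Balding–Nichols allelic
        adjustment; default 0.01.
    alpha : correction so that complete drop-out of c copies of an allele has
        probability alpha^(c-1) * p_dropout^c; default 0.5.
    """

    p_dropout: float
    p_dropin: float = 0.01
    theta: float = 0.01
    alpha: float = 0.5

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_dropout < 1.0):
            raise ValueError(f"p_dropout must be in [0, 1), got {self.p_dropout}")
        if not (0.0 <= self.p_dropin < 1.0):
            raise ValueError(f"p_dropin must be in [0, 1), got {self.p_dropin}")
        if not (0.0 <= self.theta < 1.0):
            raise ValueError(f"theta must be in [0, 1), got {self.theta}")
        if not (0.0 < self.alpha <= 1.0):
            raise ValueError(f"alpha must be in (0, 1], got {self.alpha}")


@dataclass(frozen=True)
class IBDTriple:
    """Probabilities that a relative shares 0, 1 or 2 alleles IBD with the
    suspected contributor (e.g. full siblings: 0.25, 0.5, 0.25)."""

    k0: float
    k1: float
    k2: float

    def __post_init__(self) -> None:
        for k in (self.k0, self.k1, self.k2):
            if not (0.0 <= k <= 1.0):
                raise ValueError(f"IBD probabilities must be in [0, 1], got {k}")
        if abs(self.k0 + self.k1 + self.k2 - 1.0) > 1e-9:
            raise ValueError("IBD probabilities k0 + k1 + k2 must sum to 1")


UNRELATED = IBDTriple(1.0, 0.0, 0.0)
SIBLINGS = IBDTriple(0.25, 0.5, 0.25)
PARENT_CHILD = IBDTriple(0.0, 1.0, 0.0)


@dataclass
class Hypothesis:
    """One side of the LR: which contributors explain the evidence.

    ``relative``, when set, replaces one of the ``n_unknowns`` unknown
    contributors with a random relative of the suspected contributor; it is
    only meaningful on a side that does not itself include the suspect.
    """

    includes_suspect: bool
    n_unknowns: int
    relative: Optional[IBDTriple] = None
    assumed: Sequence[ReferenceProfile] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.n_unknowns < 0:
            raise ValueError("n_unknowns must be >= 0")
        if self.n_unknowns > MAX_UNKNOWNS:
            raise ValueError(
                f"at most {MAX_UNKNOWNS} unknown contributors are supported, "
                f"got {self.n_unknowns}"
            )
        if self.includes_suspect and self.n_unknowns > MAX_UNKNOWNS_WITH_SUSPECT:
            raise ValueError(
                f"with a named suspect at most {MAX_UNKNOWNS_WITH_SUSPECT} unknowns "
                f"are supported, got {self.n_unknowns}"
            )
        if self.relative is not None:
            if self.includes_suspect:
                raise ValueError(
                    "a relative hypothesis replaces the suspect; it cannot be "
                    "combined with includes_suspect on the same side"
                )
            if self.n_unknowns < 1:
                raise ValueError("a relative hypothesis consumes one unknown slot")
        self.assumed = tuple(self.assumed)


@dataclass
class HypothesisPair:
    """Numerator and denominator hypotheses; assumed donors are shared."""

    numerator: Hypothesis
    denominator: Hypothesis

    def __post_init__(self) -> None:
        num_names = [p.sample_name for p in self.numerator.assumed]
        den_names = [p.sample_name for p in self.denominator.assumed]
        if num_names != den_names:
            raise ValueError(
                "assumed contributors must be identical in numerator and denominator"
            )

    @property
    def assumed(self) -> tuple[ReferenceProfile, ...]:
        return tuple(self.numerator.assumed)

    def describe(self) -> str:
        def side(h: Hypothesis) -> str:
            parts = []
            if h.includes_suspect:
                parts.append("suspect")
            if h.relative is not None:
                r = h.relative
                parts.append(f"relative(k0={r.k0:g},k1={r.k1:g},k2={r.k2:g})")
                rest = h.n_unknowns - 1
            else:
                rest = h.n_unknowns
            if rest:
                parts.append(f"{rest} unknown" + ("s" if rest != 1 else ""))
            if h.assumed:
                parts.append(f"{len(h.assumed)} assumed")
            return " + ".join(parts) if parts else "nobody"

        return f"H1: {side(self.numerator)} | H2: {side(self.denominator)}"


@dataclass
class LRResult:
    """Likelihood ratios for one population frequency database."""

    population: str
    per_locus: dict[str, float]
    overall: float
    params: Params
    hypothesis: str
    warnings: dict[str, str] = field(default_factory=dict)


@dataclass
class ValidationIssue:
    level: str  # "fatal" or "warning"
    marker: Optional[str]
    message: str


@dataclass
class ValidationReport:
    issues: list[ValidationIssue] = field(default_factory=list)
    analyzed_markers: list[str] = field(default_factory=list)

    @property
    def fatal(self) -> bool:
        return any(i.level == "fatal" for i in self.issues)

    def warnings(self) -> list[ValidationIssue]:
        return [i for i in self.issues if i.level == "warning"]


def validate_case(
    evidence: Mapping[str, LocusEvidence],
    suspect: Optional[ReferenceProfile],
    hyp: HypothesisPair,
    tables: Sequence[FrequencyTable],
) -> ValidationReport:
    """Check a case for analyzability before computing likelihood ratios.

    Only markers present in the evidence are analyzed.  A marker missing from
    every frequency table is fatal (its likelihood cannot be evaluated).  An
    assumed-donor allele absent from the evidence at its locus is a warning
    only: an undetected peak cannot mask anything, so the allele is simply
    excluded from the masking set.
    """
    report = ValidationReport()
    if not tables:
        report.issues.append(ValidationIssue("fatal", None, "no frequency tables supplied"))
        return report

    needs_suspect = (
        hyp.numerator.includes_suspect
        or hyp.denominator.includes_suspect
        or hyp.numerator.relative is not None
        or hyp.denominator.relative is not None
    )
    if needs_suspect and suspect is None:
        report.issues.append(
            ValidationIssue(
                "fatal", None, "hypotheses reference a suspected contributor but no "
                "suspect profile was supplied"
            )
        )

    for marker in evidence:
        in_any = any(marker in t.freqs for t in tables)
        if not in_any:
            report.issues.append(
                ValidationIssue(
                    "fatal", marker, f"marker {marker} has no allele frequency data "
                    "in any supplied population table"
                )
            )
            continue
        missing = [t.population for t in tables if marker not in t.freqs]
        for pop in missing:
            report.issues.append(
                ValidationIssue(
                    "fatal", marker, f"marker {marker} missing from population {pop}"
                )
            )
        if needs_suspect and suspect is not None and marker not in suspect.genotypes:
            report.issues.append(
                ValidationIssue(
                    "fatal", marker,
                    f"suspect profile has no genotype at analyzed marker {marker}",
                )
            )
        for prof in hyp.assumed:
            g = prof.genotypes.get(marker)
            if g is None:
                continue
            undetected = set(g.alleles()) - set(evidence[marker].detected)
            for a in sorted(undetected):
                report.issues.append(
                    ValidationIssue(
                        "warning", marker,
                        f"assumed donor {prof.sample_name} allele {a} not detected "
                        f"at {marker}; it cannot mask and is ignored for masking",
                    )
                )
        report.analyzed_markers.append(marker)

    if report.fatal:
        report.analyzed_markers = []
    return report
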