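# strmixlr

Semi-continuous likelihood ratios for complex forensic STR profiles.

Low-template, mixed or partial DNA profiles cannot be interpreted by simple
inclusion/exclusion: true contributors' alleles drop out, contaminant alleles
drop in, and several donors' peaks overlap.  `strmixlr` weighs such evidence
probabilistically, for forensic scientists and researchers who need a
transparent, scriptable calculation: it computes

    LR = P(E | H1) / P(E | H2)

where E is the set of detected alleles per locus and H1/H2 are competing
contributor hypotheses (e.g. "the suspect plus one unknown" versus "two
unknowns", or "the suspect" versus "a sibling of the suspect").  The model
is semi-continuous: peaks are present or absent, heights are not modelled.

The per-locus likelihood marginalizes the genotypes of up to four unknown
contributors:

    P(E | H) = Σ_j P(j | θ, conditioning) · P(E | alleles of H's contributors and j)

with

* **drop-out**: an allele carried in c copies drops out with probability
  α^(c−1)·P(D_O)^c (α = 0.5 by default, making homozygote drop-out rarer
  than independence would predict);
* **drop-in**: at most one unexplained allele per locus, with probability
  P(D_I) weighted by the allele's population frequency (default P(D_I) = 0.01);
* **coancestry**: genotype probabilities use the Balding–Nichols conditional
  sampling formula at the allelic level,
  P(a | counts) = (m_a·θ + (1−θ)·p_a)/(1 + (m−1)·θ), with θ = 0.01 by
  default, conditioning on the suspect's and assumed donors' genotypes;
* **minimum frequency**: suspect/evidence alleles rarer than 5/(2n) are
  floored at 5/(2n), n the frequency-database size;
* **assumed contributors**: undisputed donors whose detected alleles mask
  identical alleles of disputed contributors (factor 1, no drop-out model);
* **relatives**: a denominator unknown may be a relative of the suspect with
  IBD sharing probabilities (k0, k1, k2), e.g. siblings (¼, ½, ¼).

The sum over unknown genotypes runs as a dynamic program over allele-count
vectors (exploiting exchangeability of sequential Balding–Nichols draws) and
is verified against brute-force enumeration to 1e-9 relative on randomized
cases.  See `docs/methods.md` for the full model description.

## Worked example

```python
import numpy as np, strmixlr as s

# a synthetic 3-marker frequency database and a suspect drawn from it
table = s.make_frequency_table(seed=11, markers=3, alleles_per_marker=5,
                               n_individuals=1000)
rng = np.random.default_rng(4)
suspect = s.sample_profile(table, "SUSPECT", rng)

# evidence simulated from the suspect with 20% drop-out, 1% drop-in
evidence = s.simulate_evidence([suspect], p_do=0.2, p_di=0.01,
                               table=table, rng=rng)

# H1: the suspect is the source; H2: one unknown person is
hyp = s.HypothesisPair(
    s.Hypothesis(includes_suspect=True, n_unknowns=0),
    s.Hypothesis(includes_suspect=False, n_unknowns=1),
)
params = s.Params(p_dropout=0.2)   # P(D_I)=0.01, theta=0.01, alpha=0.5 defaults

result = s.compute_case(evidence, suspect, hyp, params, [table])[0]
for marker, lr in result.per_locus.items():
    g = suspect.genotypes[marker]
    det = ",".join(sorted(evidence[marker].detected))
    print(f"{marker}: suspect {g}, detected {{{det}}}, LR = {lr:.3f}")
print(f"overall LR = {result.overall:.2f}")
```

prints

```
M1: suspect 10/12, detected {10}, LR = 3.444
M2: suspect 12/8, detected {12,8}, LR = 11.557
M3: suspect 9/9, detected {9}, LR = 3.179
overall LR = 126.55
```

At M1 one suspect allele dropped out, so the locus only weakly favors H1; at
M2 the full heterozygote is present and the locus is worth more; the overall
LR is the product across loci — the evidence is about 127 times more
probable if the suspect, rather than an unknown person, is the source.

## Command line

The same computation runs from a shell on genetic-analyzer CSV exports
(`Sample Name`/`Sample File`, `Marker`, `Allele 1..k`, optional
`Height 1..k` columns) and long-format `Marker,Allele,Frequency` tables:

```sh
strmixlr --evidence case.csv --evidence-sample EVID \
         --suspect case.csv --suspect-sample SUSPECT \
         --freqs popA.csv:POP-A:1036 --freqs popB.csv:POP-B:800 \
         --pdo 0.2 --num-unknowns-denominator 1 \
         --out results.csv
```

`results.csv` echoes all parameters, then one row per marker with an LR
column per population and a final overall row.  `--pdo 0.1,0.3,0.5` sweeps
several drop-out values; `--dropout-model model.json` instead predicts
P(D_O) from the average detected peak height with a laboratory-calibrated
logistic regression; `--relative-ibd 0.25,0.5,0.25` makes the denominator's
unknown a sibling of the suspect; `--assumed victim.csv:VICTIM` conditions
both hypotheses on an undisputed donor.

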