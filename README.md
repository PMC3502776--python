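# marrowmatch

Unrelated hematopoietic stem cell (HSC) donor searching, as a library:
HLA match grading, haplotype-frequency-based match-probability
estimation, the heuristic criteria that flag difficult searches, a
synthetic donor-registry generator, and a simulator of the staged
search workflow — with reporting that reproduces published cohort
summary tables from their margins.

It is written for transplant immunogenetics laboratories, registry
scientists, and anyone studying search strategy: when a patient needs an
unrelated donor, the first question is whether a fully matched donor
(10/10 over HLA-A, B, C, DRB1, DQB1, or 12/12 adding DPB1) is likely to
exist among the millions of registered volunteers, and the answer drives
how many donors to request, whether to type DPB1 prospectively, and when
to accept a mismatch or switch to an alternative stem-cell source.

## The model

Under Hardy–Weinberg equilibrium an individual is an independent draw of
two five-locus haplotypes, so the probability that a random donor is
genotype-identical to a patient with haplotype pair frequencies
*f<sub>i</sub>*, *f<sub>j</sub>* is

```
p_single = Σ over unordered pairs (i, j) reproducing the genotype of
           2 f_i f_j   (i ≠ j)   or   f_i²   (i = j)
```

Matching is allele-based, not phase-based: a donor carrying the same ten
alleles on different haplotypes counts as matched. With *N* registry
donors of which a fraction *a* is actually available, the search-level
probability is

```
p_registry = 1 − (1 − p_single · a)^N
```

which is classified **high** (> 95%), **intermediate**, or **low**
(< 5%). A rule layer demotes this estimate when warning criteria fire
(very few registry donors, non-European ancestry, rare alleles, unusual
B–C or DRB1–DQB1 associations, mismatch-risk B haplotypes), except when
a rare allele travels on a known conserved haplotype. The search
simulator then plays out the workflow per category: request rounds of
2–4 (high) or 4–6 (other) donors, availability attrition, confirmatory
typing, DPB1 evaluation with a TCE3-permissiveness fallback for
non-urgent high-probability searches, ranked mismatch acceptance for low
ones.

## Worked example

```python
import numpy as np
from marrowmatch import (Genotype, SearchCase, SearchPolicy, categorize,
                         donor_match_probability, registry_match_probability,
                         generate_registry, RegistryConfig, run_search)
from marrowmatch import datasets

table = datasets.load_demo_frequency_table()
serotype_map = datasets.load_serotype_map()

patient = Genotype.from_strings("pt", {
    "A": ["A*01:01", "A*02:01"], "B": ["B*08:01", "B*07:02"],
    "C": ["C*07:01", "C*07:02"], "DRB1": ["DRB1*03:01", "DRB1*15:01"],
    "DQB1": ["DQB1*02:01", "DQB1*06:02"],
})
p_single = donor_match_probability(patient, table)
p_reg = registry_match_probability(p_single, n_donors=10_000, availability=0.75)
print(f"p_single={p_single:.4f}  p_registry={p_reg:.3f}  {categorize(p_reg)}")

registry = generate_registry(
    RegistryConfig(n_donors=10_000, population_mix=[(table, 1.0)], seed=42),
    serotype_map)
case = SearchCase(patient=patient, category=categorize(p_reg))
out = run_search(case, registry, SearchPolicy(urgent=True),
                 np.random.default_rng(0), serotype_map=serotype_map)
print(out.best_grade, out.terminated_reason, out.donors_tested,
      out.days_to_identification)
```

prints

```
p_single=0.0056  p_registry=1.000  high
m10 matched_found 2 24
```

i.e. a patient composed of two common European haplotypes has a 0.56%
chance per donor of an allele-identical match — near certainty somewhere
in a 10,000-donor registry — and the simulated search confirms a 10/10
donor after typing two candidates, 24 stub-clock days in.

The same flows are available from the shell:

```
marrowmatch report --dpb1-margins
marrowmatch estimate --patients patients.tsv --n-donors 10000
marrowmatch simulate --patients patients.tsv --registry-size 10000 \
    --seed 1 --out report.json
marrowmatch fixtures --dest fixtures/
```

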