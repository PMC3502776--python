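# Methods

## Match grading

HLA identity is evaluated at two-field (protein-level) resolution over
HLA-A, B, C, DRB1 and DQB1 — ten alleles, the 10/10 grade — optionally
extended by DPB1 to 12/12. Clinically relevant matching rests on the
peptide-binding-domain exons, so two alleles are identical when their
first two nomenclature fields agree; third and fourth fields
(synonymous and non-coding variation) are ignored, their clinical
relevance being unestablished. Within a locus the two patient alleles
are paired with the two donor alleles so as to minimise mismatches
(0, 1 or 2 per locus), the standard convention.

Secondary DRB loci (DRB3/4/5) are scored as a single disparity flag: if
both sides carry any DRB3/4/5 typing and the allele supports differ, one
point is deducted — never more, however many secondary alleles differ,
because registry accounting treats "a DRB3 disparity" as converting a
10/10 into a 9/10. A DRB3/4/5 disparity combined with an ordinary allele
mismatch deducts cumulatively (8/10); published accounting is silent on
this combination, and cumulative deduction keeps the score additive.

A single recorded allele at a locus is treated as homozygous for grading
but stays flagged, because registries often omit a second identical or
unresolved allele. Cross-resolution comparisons (serotype or allele
group versus two-field) yield an explicit `ambiguous` status; grading
never silently matches an ambiguous comparison, it reports the locus as
not evaluable. An unmapped serotype also stays ambiguous: containment
can be neither proven nor excluded, so such donors remain candidates for
confirmatory typing rather than being silently discarded.

DPB1 disparities carry a direction: graft-versus-host when the patient
has an allele the donor lacks, rejection (host-versus-graft) when the
donor has one the patient lacks. Permissiveness of DPB1 mismatches uses
the three-group T-cell-epitope (TCE3) classification: each individual is
assigned the minimum (most immunogenic) group of its two alleles and the
group indices are compared. The authoritative TCE3 rule is published
elsewhere; the minimum-group comparison implemented here is an
interpretation, deliberately isolated behind one function
(`matching.tce3_classify`) and driven by a user-replaceable table.

## Match probability

Donor–patient identity probability follows from five-locus haplotype
frequencies under Hardy–Weinberg equilibrium (HWE): genotype probability
is the sum of `2·f_i·f_j` (or `f_i²`) over all haplotype pairs whose
allele union reproduces the patient's per-locus allele pairs — including
phase-swapped recombinant pairs, since grading is allele-based.
Frequency tables rarely sum to one; the residual mass is an implicit
"other" pseudo-haplotype assumed never to match, a deliberately
conservative bias. Mixed-population registries are handled as a
weighted mixture: `p_single = Σ w_k p_k` over per-population tables.

Registry-level probability assumes donors independent:
`p_registry = 1 − (1 − p_single·a)^N` with availability `a` defaulting
to 0.75 (donor attrition above 20% is the norm once donors are actually
requested). Categories: high above 0.95, low below 0.05, intermediate
between, thresholds configurable. The numeric machinery behind
registry practice (HapLogic, OptiMatch, EasyMatch) is proprietary or
unpublished; this HWE engine is a standard reconstruction and is
labelled as such, validated internally against brute-force enumeration
and Monte-Carlo sampling rather than against those systems.

## Warning-rule layer

Seven closed criteria capture what frequency tables alone miss: fewer
than a configurable minimum of donors in the worldwide registry (≤ 3
forces a low estimate outright), non-European ancestry (an input flag,
never inferred), a rare allele (< 5% of the alleles carrying the
patient's serotype, computed from the supplied table so the classifier
is self-contained), rare B–C and rare DRB1–DQB1 associations
(conditional partner frequency below 5%, phase-agnostic: the
best-supported partner among the patient's alleles is used), and B
alleles whose haplotypes carry elevated risk of C or B*35 mismatches.
A rare allele residing on a whitelisted conserved haplotype — the
package ships a catalogue of conserved extended haplotypes known to
carry otherwise-rare class I alleles — is exempted, because such alleles
travel with a fixed haplotype and the search may well succeed.

How criteria combine with the numeric estimate is genuinely open; the
design here is a demotion ladder — each distinct firing rule family
demotes the category one step, floored at low — chosen because the
criteria are defined as contributors to a low estimate, not as a score.
Both pre- and post-demotion categories and every hit are reported so the
ladder is auditable. Whether two simultaneous hits should demote two
steps is undecidable from available evidence; the ladder says yes and
records it.

## Synthetic registry

Donors are HWE draws from the haplotype table(s). Residual-mass draws
become sentinel haplotypes with private `*NNN:NNNN` alleles (first field
≥ 100, far above real allele groups, unique per draw from the generator
RNG), so residual donors can never grade as matched while same-seed runs
stay bit-identical. DRB3/4/5 are assigned from the DRB1 group via the
standard linkage map (DR3/11/12/13/14 → DRB3, DR4/7/9 → DRB4,
DR15/16 → DRB5), with DRB1*13 haplotypes split 80/20 between
DRB3*01:01 and DRB3*02:02 to create the DRB3-mismatch risk that the
search workflow's DRB3-typing branch addresses. DPB1 is sampled
independently from a separate allele-frequency list, reflecting its
weak linkage to the class II block.

Typing heterogeneity: each donor's reported genotype is a degradation of
the true one under a profile — full high resolution, class-I low
resolution (class I mapped to serotypes, class II truncated to allele
groups), or serologic-only (additionally drops DPB1). The default
profile mix (50/30/20) is a configuration placeholder; real registry
composition is not published. Class I alleles missing from the serotype
map degrade to allele-group resolution and are reported in an
`unmappable` list, never silently dropped.

The packaged demo frequency table is synthetic but European-like: 46
five-locus haplotypes in three tiers (common ancestral haplotypes such
as A*01:01-B*08:01-C*07:01-DRB1*03:01-DQB1*02:01 near 5–7%, a
middle tier around 1–2%, and a rare tier at 0.1–0.6% that includes the
conserved rare-allele haplotypes and the rare-association examples used
by the rule layer), totalling ≈ 0.67 explicit mass with ≈ 0.33 residual.
Patients sampled from it spread over all three probability categories in
roughly the 30/10–20/50 proportions seen in practice for a
10,000-donor registry at 75% availability. What the generator does NOT
emulate: linkage between DPB1 and the main haplotype, registry growth
over time, within-population substructure, and NMDP-style ambiguity
codes — so passing simulations demonstrate internal consistency of the
method, not calibration against any real registry.

## Search simulation

Candidate preselection scans *reported* typings: donors whose reported
genotype could still be a full match come first (reported-exact before
ambiguous), followed by donors with exactly one definitely mismatched
locus (potential 9/10, which low-probability searches consider early);
two or more definite mismatches exclude a donor. Requests go out in
rounds — 2–4 donors for high-probability searches (the second-best
graded donor is retained as the recorded back-up), 4–6 otherwise —
with availability resampled per request. Tested donors are graded on
their true genotypes (confirmatory typing). Non-urgent high-probability
searches evaluate DPB1 aiming at 12/12 and keep searching while rounds
remain; if no DPB1-matched donor emerges they fall back to a
TCE3-permissive mismatch, then to a plain 10/10. Searches that end with
only 9/10 donors accept the top-ranked mismatch when the search is low
probability or urgent (ranking: DQB1 first, then the locus carrying the
patient's rare allele, then B preserving C, then DRB1 preserving DQB1,
then the rest; ties on donor id). A low-probability search with nothing
acceptable terminates toward another HSC source.

The clock is a stub: fixed per-action durations (request 7 d, typing
14 d, report 3 d) give reproducible, ordered day stamps suitable for
relative comparisons only; it is explicitly not a model of real search
durations, which depend on registry logistics outside scope. "Urgent"
is a caller-supplied policy flag; clinical urgency criteria are out of
scope.

## Numerical choices and problem sizes

Probabilities are exact floating-point sums (no sampling) except where a
check is explicitly Monte-Carlo; frequency-table validation tolerates
1e-9 excess mass. Rounding in reports is decimal half-up at the stated
precision (percentages one decimal by default, means two); day means
round to whole days. Determinism everywhere: numpy `Generator` seeded
per run, per-case seeds spawned from a root `SeedSequence`, ties broken
on ids.

Validation sizes, chosen to give three-standard-error resolution on the
quantities checked: probability-engine oracle equivalence over 1000
random tables of ≤ 6 haplotypes; single-donor identity rate over 10⁵
sampled donors; registry-level probability over 2000 simulated
100-donor registries; category monotonicity on 200 synthetic patients
against a 10,000-donor registry.

## Known limitations

Haplotype-frequency *estimation* (EM from genotype data) is out of
scope: tables are inputs. The residual-mass convention biases
`p_single` downward for patients whose genotype partially overlaps
unlisted haplotypes. The demotion ladder and the TCE3 minimum-group
rule are documented interpretations, not reproductions of any specific
registry system. Cohort fixtures ship as published margins, not
per-patient rows; three printed cells of the source cohort table are
mutually inconsistent with its own margins at one printed ulp under any
single rounding convention, and the reporting layer reproduces the
margins' arithmetic, not those three cells.
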