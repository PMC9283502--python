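# Methods

This note records the models, conventions and design choices behind
`kdrmon`, in the order the pipeline uses them.

## Loci and genotype classes

Two *vgsc-h1* codons are monitored, in Musca-orthologous numbering:
L1014F (wild-type codon CTT, mutant TTT; the variant base is the first
codon position, transcript coordinate 3070) and M918I (ATG → ATA; third
codon position, coordinate 2784).  Both codons sit in one reading frame
(CDS offset 31), which the synthetic reference preserves.  Coordinates are
1-based inclusive throughout.

A diploid call is an unordered pair of amino acids, rendered wild-type
first ("L/F", never "F/L").  The nine concrete two-locus genotypes map onto
resistance classes as follows: no 1014F allele → *wild type* (or *918-only*
when a 918I allele is present without 1014F — these are tabulated as their
own column and deliberately kept out of the kdr/super-kdr classes); 1014F
without 918I → *kdr* heterozygote/homozygote; 1014F together with 918I →
*super-kdr* heterozygote, unless both loci are homozygous mutant
(*super-kdr* homozygote).  The partition is total and disjoint over the
nine classes (asserted by enumeration in the tests).

Heterozygous positions in Sanger consensus sequences are represented by
IUPAC ambiguity codes (Y = C/T at 3070, R = G/A at 2784).  Codon
translation expands ambiguity codes and translates every concrete codon
with the standard genetic code; one amino acid means a homozygous call, two
a heterozygous call, more (or a stop) an error.

## Assay simulation

**PCR-RFLP (L1014F).**  Primer matching is exact (0 mismatches) and must be
unique in the template; template IUPAC codes match a concrete primer base
when the base is in the code's expansion.  The 439 bp amplicon is digested
with BstEII (recognition GGTNACC, a degenerate palindrome; cut G^GTNACC,
offset 1).  The susceptible C allele retains the site and yields 154 +
285 bp; the resistant T allele (GGTNACT) runs undigested at 439 bp.  A
consensus amplicon is first expanded into concrete alleles (at most two
ambiguous sites; more signals an unusable trace), each allele is digested,
and the band pattern is the union over alleles.  Fragment accounting uses
the standard single-strand convention (cut position = site start + offset
on the scanned strand), under which fragments always sum to the allele
length and the diagnostic sizes are reproduced exactly.  Because BstEII cuts
off-centre and leaves 5-nt overhangs, the two *end* fragments measured this
way shift by 5 nt between orientations; site positions themselves and all
interior fragments are strand-symmetric, and that is the form in which the
palindromy property is asserted.

**LCR (M918I).**  The upstream allele-specific probes share a 25-nt
annealing core ending on the variant base (3'-G for wild type, 3'-A for
mutant); the mutant probe carries a 24-base non-annealing 5' extension.  A
probe ligates on an allele only when its core matches exactly and the
common 5'-phosphorylated downstream probe anneals immediately 3' of the
variant.  Tailed amplification sizes are fixed by construction: 17 (tail) +
25 (P1 core) + 81 (P2) + 18 (tail) = 141 bp for wild type and 165 bp for
mutant.  The wet-lab probe sequences are not distributed with this package, so
the 141/165 bp sizes are treated as the binding contract and the synthetic
probe set is built to honour it.

**Direct codon calling** anchors the codon by exact match of a 20 bp
reference flank (5' first, 3' fallback), then expands and translates.
`genotype_sample` runs all three routes and raises a discordance error
listing the conflicting calls when any two disagree — e.g. a lesion inside
the restriction site flips the RFLP call but not the codon call.

## Association and allele-trend statistics

**Exact test.**  Genotype × phenotype association uses a two-sided exact
test for 2×k tables: condition on both margins, enumerate the full
conditional (multivariate hypergeometric) distribution, and sum the
probabilities of all tables no more probable than the observed one (ties
included).  Probabilities are compared as exact integers
(∏ⱼ C(cⱼ, xⱼ)), so tie handling has no floating-point ambiguity.
Zero-margin columns are dropped; an all-zero row (e.g. a stratum with no
survivors) is degenerate and reported as a missing p-value.  When the
enumeration bound exceeds a configurable budget (default 10⁷ fillings) the
test falls back to Monte Carlo with 10⁶ multivariate-hypergeometric draws
under a fixed, logged seed.

**RAF and odds ratios.**  RAF = 100·(2·hom_mut + het)/(2n); heterozygotes
contribute one allele of each kind, and each individual's two alleles are
treated as independent Bernoulli observations (no Hardy–Weinberg
adjustment) — the same convention the GLM uses.  The post/pre allele-count
odds ratio carries a Wald CI, exp(ln OR ± 1.96·√Σ 1/count); any zero cell
triggers a separation warning and the Haldane–Anscombe 0.5 correction,
always flagged in the result.

**Pooling contract.**  The logit model P(resistant) ~ time + location +
time×location is fit by IRLS (statsmodels, binomial family) on aggregated
allele counts.  The design is saturated in the 2×L cells, so each
location's fitted post-minus-pre logit contrast equals the raw-count log
odds ratio exactly (asserted to 1e-8 in the tests).  The pooled odds ratio
is the equal-weight average of those per-location contrasts, exponentiated
— i.e. the geometric mean of per-location odds ratios — with its CI from
the averaged contrast's variance.  An additive (no-interaction) model would
not reproduce the per-location values, which is why the interaction term is
mandatory.  The model-based marginal RAF is the inverse-logit of the
equal-weight averaged linear predictor at each time point; its exact
weighting is an interpretive choice and it is reported alongside, never in
place of, the raw RAF.

Report rounding: one decimal for percentages and RAF, two decimals for
odds ratios, applied only at the report layer.

## Dose-response model

Mortality follows the three-parameter log-logistic law
p(x) = d / (1 + exp(−b·(ln x − ln e))) with lower limit 0: slope b > 0
(mortality increases with dose), upper limit d ∈ (0, 1], and LC50 e in
µg ml⁻¹ (p(e) = d/2 exactly).  Counts of dead at each positive
concentration are binomial; replicates are pooled per concentration, since
replicate-level structure is not recoverable from count tables.  Dose-0
control rows are excluded from the likelihood and only validated (a warning
above 10% control mortality); no Abbott correction is applied.

Estimation maximises the binomial log-likelihood with L-BFGS-B over
(b, ln e, d) from a fixed multi-start schedule — b ∈ {0.5, 1, 2, 4}, d ∈
{0.9, 1.0}, ln e at the dose-grid quartiles — with a 1e-8 likelihood
tolerance.  If the optimum pins d at 1, the model is refit with d fixed and
flagged, and the lack-of-fit df drops from groups − 3 to groups − 2.
Standard errors come from the inverse finite-difference Hessian at the
optimum; the LC50 interval is the delta-method Wald interval
ê ± 1.96·ê·SE(ln ê), truncated at 0.  Lack of fit is the Pearson χ² over
positive-dose groups.  Resistance and synergist ratios are ratios of LC50
point estimates, flagged significant when the two 95% CIs do not overlap.

All-dead, all-alive or dose-constant mortality raises a
non-identifiability error rather than returning a degenerate fit.

## Synthetic-data generator

The generator emulates the monitoring study's data-generating conditions
with known ground truth.

*Reference.*  A deterministic 3525 bp transcript with wild-type codons CTT
at 3070–3072 and ATG at 2782–2784 in one frame.  The diagnostic digest sizes
(154 + 285 of a 439 bp amplicon) are incompatible with placing the
restriction site at the transcript coordinates of the real amplicon —
the wet-lab assay runs on genomic DNA, where introns decouple gel sizes
from transcript coordinates — so the synthetic kdr amplicon spans 2911–3349,
putting the site's final C at 3070 and the cut 154 bp from the amplicon
start.  This keeps both the variant-in-site chemistry and the diagnostic
sizes exact.  The 151 bp M918I amplicon spans 2726–2876.  Accidental
BstEII matches inside the amplicon (on either the wild-type or mutant
backbone) are repaired deterministically; primers and probes are extracted
afterwards and checked unique.

*Cohorts.*  Individuals are random unions of two gametes drawn
independently from the four haplotype frequencies (L·M, L·I, F·M, F·I);
linkage disequilibrium is controlled entirely by those frequencies (no
inbreeding parameter — clonal structure is not identifiable from count
tables).  The default frequencies (0.58, 0.02, 0.32, 0.08) give per-locus
resistant allele frequencies of 0.40 (1014F) and 0.10 (918I), matching the
magnitude of the pooled pre-application field samples.

*Sequences.*  Consensus transcripts carry IUPAC codes at heterozygous
sites; optional uniform substitution noise is applied only away from
assay-critical positions (primers, probes, site, codons), modelling trace
error without destroying the assay's anchor points.

*Selection.*  Survival is Bernoulli per individual with class-specific
probabilities; the default model (wild type 0.05 → super-kdr homozygote
0.90) orders survival with resistance.  Post-selection class frequencies
converge to f_g·s_g / Σ f_h·s_h (asserted at n = 10⁵ within 3 SE).

*Bioassays.*  Deaths are binomial under the LL.3 law at 8 concentrations ×
60 insects (three pooled replicates of 20).  The assay envelope is 0.0008–60 µg ml⁻¹, but a grid spanning that whole envelope leaves most
groups at 0% or 100% expected mortality for any single population and
makes the Pearson χ² uncalibratable; per bioassay practice the default
grid is geometric from e/8 to e·8 (clipped to the envelope), bracketing
each population's LC50 — the only design under which the lack-of-fit
χ² can calibrate to its degrees of freedom.

*Seeding.*  One top-level seed feeds named substreams (population, noise,
selection, bioassay), so each stage is independently reproducible.

What the generator does **not** emulate: real linkage to other *vgsc*
variants, PCR/ligation failure modes, chromatogram quality, clonal
population structure, migration, or multi-generation selection.  Passing
tests therefore demonstrate correctness of the assay logic and statistics
under idealised consensus sequences, not robustness to degraded field
traces.

## Known limitations

* The 2×k exact test is exponential in k at large margins; the Monte Carlo
  fallback bounds the cost but yields a simulated p (flagged by the fixed
  seed in the call signature).
* LC50 CIs are Wald-type; profile-likelihood intervals would behave better
  at very small n or boundary d.
* Marker loci other than 1014/918 can be configured, but no resistance-class
  semantics are defined for them.
* The boundary refit for d = 1 changes the lack-of-fit df between otherwise
  similar datasets; both branches are flagged in the output.
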