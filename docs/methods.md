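# Methods

This note documents the models behind `mosabench`: what the synthetic
reference standard emulates, what the caller emulation does and does not
capture, the exact definitions of the evaluation statistics, and the design
choices made where the design was genuinely open.

## 1. The synthetic reference standard (`truthsim`)

### Founder panel

Six founder genotype sets stand in for pregenotyped normal cell lines. Each
founder carries germline variants at positions drawn uniformly without
replacement over a single region (default `chr1:0-2,000,000`), so every
site belongs to exactly one founder — *mutual exclusivity*, the property
that makes mixing proportions translate directly into expected VAFs.
Alleles are parsimony-normalized on construction (shared suffix then prefix
trimmed, position advanced); SNV and INDEL counts are apportioned at the
panel level by largest remainder at a 40:1 ratio, reflecting the roughly
40:1 SNV:INDEL balance of high-confidence germline call sets. Zygosity is
heterozygous with probability 0.55, homozygous otherwise.

### Mixing design

The design mimics mosaic variant acquisition during early development:
within each category a fixed, ordered set of carrier founders joins the
lineage one cumulative step at a time, and a mixture assigns geometrically
decaying fractions along that order. Defaults:

| parameter | default | meaning |
|---|---|---|
| category sizes | M1=9, M2=12, M3=18 | 39 mixtures total |
| carriers | M1={0,1,2,4}, M2={0,1,3,5}, M3=all six | category site sets |
| decay ratio | per-mixture, linspace over [0.45, 0.55] | fraction schedule |
| fraction cap | 0.56 | dominant founder never exceeds 56% |
| founder variant counts | (140, 140, 280, 280, 560, 560) | doubling with tree depth |

Every mixture in a category therefore shares the same mutation sites but
represents them at different VAFs (`expected_vaf = fraction × dosage / 2`,
dosage 1 for het and 2 for hom — exactly linear in composition). Founders
deeper in the tree receive smaller fractions and carry more variants,
which enriches the pooled spectrum in low VAFs. With the defaults the
pooled truth VAFs span ~0.5–56% with ~73% of positives under 10% VAF;
the package's own tests assert the 0.65–0.75 band and the 56% cap. The
real standard's mixing fractions are not public, so these defaults were
set once, by closed-form spectrum arithmetic against those published
range constraints, and are not data-fitted. Any schedule can be supplied
via configuration.

### Negative controls

Set A (nonvariant, reference-homozygous) and Set B (germline) sites are
sampled once, disjoint from all panel sites, and shared by all mixtures —
as they would be for physical mixtures of the same cell lines. Set B sites
are germline in *all six* founders (het → VAF 0.5 or hom → VAF 1.0; hom
fraction 0.2 by default), so mixing cannot dilute them: they stay germline
in every mixture, which is what makes them a distinct error class from
Set A. Defaults: 200,000 Set A and 1,000 Set B sites on 2 Mb — the same
~100:1 negative:positive imbalance direction as a real exome standard,
scaled to desk size.

### Read-count evidence

Per-site depth at the deepest tier follows a negative binomial with mean
1,100 and dispersion r = 10, emulating capture unevenness (the coefficient
of variation ≈ 0.32 is in the range seen for exome capture); the paper
describes unevenness only qualitatively, so the NB form and r are this
package's choice. Alt read counts are `Binomial(depth, p)` with p = truth
VAF at positives, the per-base error rate (default 1e-3) at Set A, and 0.5
or 1.0 at Set B. Lower tiers (500/250/125×) are *nested subsamples*:
depth is binomially thinned tier-to-tier and alt reads follow by
hypergeometric draws, so depth and alt count are non-increasing from
1,100× down at every site — matching multistep down-sampling of one
sequencing run rather than independent runs.

Evidence covers *all* panel sites, not just a mixture's positives: a site
carried only by another mixture's founders is still sequenced, and shows
alt bases at the error rate. Paired-sample rescue depends on this.

What the generator deliberately does **not** emulate: read-level artifacts
(mapping, clipping, strand bias), position-correlated error processes,
multi-allelic sites, and real genotype backgrounds. Consequently, passing
tests demonstrate that the *evaluation machinery* is correct and that the
*strategies* behave as designed under known conditions — they say nothing
about how any real caller performs on real data.

## 2. Caller emulation (`callers`)

A caller is an operating profile, not an algorithm:

- **Sensitivity** per VAF bin and depth tier. A positive must be
  *detectable* (≥ 1 alt read at the tier) before the sensitivity draw
  applies — the detection-limit physics is never bypassed.
- **FP rates** per Mbp for the nonvariant and germline classes, drawn
  Poisson and placed uniformly without replacement over covered negative
  sites (defaults of order 0.1–1/Mbp mirror reported magnitudes for real
  callers; tests often use larger rates for statistical power on 2 Mb).
- **Score**: `logistic(a·log1p(alt_count) + b·vaf + noise − 2)`. The log
  on alt count keeps the score from saturating at 1,100× depth; only its
  monotone relation to evidence matters, since AUPRC is rank-based.
- **Features**: binormal models — TP values `N(μ, 1)`, FP values
  `N(0, 1)` with `μ = √2·Φ⁻¹(AUC)`, so a feature's empirical ROC AUC
  against its targeted FP class equals the configured value in
  expectation. This gives the feature-analysis layer a known ground truth.

**Joint vs single genotyping.** For a truth-shared site, single genotyping
draws detection independently per sample (shared detection ≈ product of
sensitivities). Joint genotyping is one Bernoulli event for the pair with
success probability the *mean* of the two per-sample sensitivities: a
joint model pools evidence, so strong support in one sample compensates
weak support in the other. Under this model, at equal marginal
sensitivity, joint mode is robust to VAF imbalance while single mode loses
shared sensitivity (AM–GM: s̄² > s_lo·s_hi) — the directional contrast the
paired evaluation is designed to expose.

## 3. Evaluation definitions (`metrics`, `concordance`, `paired`)

- **VAF bins** (percent): SNV {<1, 1–2, 2–3, 3–4, 4–7.5, 7.5–9.6, 9.6–25,
  ≥25}; INDEL {<1, 1–2, 2–4, 4–5, 5–9.6, 9.6–16, ≥16}. Intervals are
  half-open `[lo, hi)` (left-closed; the published bin labels do not state
  closure, so one deterministic convention was fixed). Positives are
  binned by truth VAF; false positives, having none, by observed VAF.
- **Classification** is exhaustive and exclusive: exact normalized
  (chrom, pos, ref, alt) match → TP; call at a Set B locus → germline FP;
  any other in-region call → nonvariant FP (including a wrong-alt call at
  a positive site — counting those as TPs would overstate accuracy);
  unmatched positives → FN. Out-of-region calls are dropped and counted;
  malformed records are rejected per-record and logged.
- **Recalibrated precision**: `w = expected density × region Mbp /
  n positives`, computed once per variant type over the whole region and
  applied uniformly to every bin; `precision = TP·w / (TP·w + FP)`.
  Expected densities default to 1/Mb (SNV) and 0.1/Mb (INDEL). Empty bins
  yield missing values, never zeros.
- **AUPRC**: precision–recall swept over score thresholds with ties
  grouped, precision recalibrated at each threshold, area accumulated
  step-wise (average precision) — no trapezoidal interpolation, which is
  optimistic for PR curves. Recall is measured against all positives, so
  AUPRC is bounded by overall sensitivity.
- **Detection upper limit**: `P(X ≥ k_min)`, `X ~ Binomial(depth, VAF)`,
  default `k_min = 3` (a typical minimum alt-read requirement; the value
  is configurable since the exact published criterion is not in the main
  text).
- **Concordance**: Jaccard on normalized site keys per error class; NA
  (empty union) propagates as missing, excluded from aggregates rather
  than treated as 0. Depth consistency partitions the union of per-tier
  call sets by exact tier membership.
- **Paired analysis**: shared = called in both samples, specific = called
  in one. A truth-shared variant called in exactly one sample is
  *misclassified*: it counts against shared sensitivity and as a false
  positive of the specific class. Balance: a shared variant is balanced
  when its two VAFs differ by less than twofold; exactly twofold is
  assigned unbalanced by default (the published wording is ambiguous at
  the boundary, so it is configurable). The 16 areas are the product of
  per-sample ranges {≤5, (5,10], (10,25], >25}%; truth VAFs index
  positives, observed VAFs index FPs; areas without assignable positives
  are NA. Overall normalized F1 rescales every bin to unit positive
  weight (FPs by the same factor); FPs in bins without positives cannot
  be rescaled and are excluded with their count reported.

## 4. Strategies (`strategies`)

- **Area ensemble**: each shared call is routed to the area of its
  observed VAF pair and kept iff it belongs to the caller mapped to that
  area. Because areas partition the VAF plane, the ensemble's per-area
  performance equals the mapped caller's by construction; with the true
  per-area best map it attains the per-area maximum F1.
- **Rescue** (defaults min_alt = 2 reads, min_vaf = 0.005): one-sample-only
  calls are promoted to shared when the other sample's pileup supports
  them. Promotion-only — no call is ever removed, so shared sensitivity
  can only improve. The original read-level criteria of the published
  ensemble pipeline are not printed; these thresholds are configurable and
  logged.
- **Lineage filtering**: variants shared by a developmentally distal pair
  (M1, M2) must predate the lineage split and should therefore appear in
  a proximal third sample (M3); shared calls absent from the third
  sample's call set are removed. With a perfect third-sample caller no
  triple-shared truth variant is removed; with independent FP placement a
  shared FP survives with probability equal to the third sample's
  per-site hit rate.
- **Foreign-feature filtering**: a feature computed by one caller
  thresholds another caller's call set (e.g. remove when alt_softclip
  > 0.05). Calls lacking the feature are retained and reported as
  unadjustable. Directions are explicit configuration (`remove_above` /
  `remove_below`) because feature polarity differs across callers.

## 5. Feature analysis (`features`)

Feature AUC is the normalized Mann–Whitney U (ties count half), orientation
auto-flipped so AUC ≥ 0.5 with the flip recorded. The shipped registry has
48 features in three origin categories — sequencing (20), alignment (15),
genotype (13); the features named in the field's tooling are included by
name and the remaining slots carry synthetic placeholder names, since the
full catalog is caller documentation rather than package scope. Category
comparison uses the two-sided Wilcoxon rank-sum test, exact for combined
n ≤ 20 (ties force the normal approximation), asymptotic otherwise.
Filter efficiency requires default ⊆ disabled (a filter only removes) and
reports ΔF1 = F1(default) − F1(disabled), which may be negative.
Order-dependent (serial) filters are out of scope for per-filter
efficiency, as disabling one member of a chain is not interpretable.

## 6. Problem sizes, determinism, degenerate inputs

The shipped default is desk scale: 2 Mb, ~1,960 panel variants (~2,000
positives in an M3 mixture), 200,000 + 1,000 negative controls, four depth
tiers. Full-scale runs are a configuration change, not a code change. All
randomness flows through a single `numpy` Generator per operation, seeded
explicitly; identical seeds reproduce identical outputs byte-for-byte,
including VCF/TSV artifacts (writers stamp the seed and a configuration
hash). Degenerate inputs have defined behavior: precision with no calls is
missing (not 0); empty bins are missing; an empty call set has F1 = 0;
Jaccard of empty sets is NA; zero-VAF inputs to balance or area assignment
are errors, since a shared variant must have support in both samples.

## 7. Known limitations

- Caller emulation is an operating profile; it cannot reveal anything
  about real callers' error mechanisms, only validate the bench.
- The mixing-design defaults reproduce the published spectrum
  *constraints*, not the actual (unpublished) 39 compositions; shared-site
  counts between categories are symmetric here where the real standard's
  are not.
- Set B models pure germline sites; the real standard's germline-site
  recovery procedure is more involved.
- Evidence is a per-site count model: no read identities, so strand,
  position-in-read and mapping-quality features exist only as parametric
  stand-ins.
- Single-region (one contig) truth sets; multi-contig regions are
  supported by the region machinery but the simulator places all sites on
  one contig.
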