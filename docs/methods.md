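# Methods

## Problem setting

Single-strand annealing between two tandem repeats deletes the intervening
sequence and one repeat copy. When the repeats differ at a few positions
(divergent sites), the annealed intermediate is a heteroduplex that is
mismatched at every divergent site, with a nick (or 3′ non-homologous tail)
at each former DSB end. The deletion product read out by amplicon sequencing
shows, per site, whether the base of the Cdkn1A-side repeat ("top strand",
the sequencing reference) or of the GFP-side repeat ("bottom strand") was
retained. `rmdkit` implements (i) the product-analysis pipeline that turns
amplicon reads into per-site percent top-strand retention, (ii) a
quantitative generative model of how that retention pattern arises, and
(iii) the reporter-assay normalization and screen statistics that surround
such experiments.

## Repeat geometry

Repeats are 287 bp by default. Divergent variants are constructed by
centered equal partitioning: `n` substitutions are placed at offsets
`floor((i − 0.5)·L/n)`, `i = 1..n`, which for `n = 8, L = 287` gives offsets
17, 53, …, 269 with spacings equal to within 1 bp. The exact spacing of the
real reporter's mismatches is not modelled; spacing is configurable and any
user-supplied FASTA pair overrides the synthetic default. Substitutions are
transitions by default (transversion mode available) — the substituted base
identities do not enter any downstream statistic, only TOP/BOTTOM identity
does. Offsets are 0-based internally; ranks 1..K (rank 1 = Cdkn1A-proximal)
are the external site labels. `divergence_percent` rounds half away from
zero, so 8/287 → 3% and 3/287 → 1%.

## Resolution model

Per molecule, two excision events are drawn independently:

- with probability `pi_b`, a bottom-strand excision tract starts at the
  Cdkn1A-proximal nick; its length is Geometric with continuation
  probability `theta_b` (`P(len ≥ d) = theta_b^(d−1)`), and every divergent
  site within reach (offset + 1 ≤ length) resolves TOP;
- with probability `pi_t`, a top-strand tract from the GFP-proximal nick
  resolves sites within reach (`L − offset ≤ length`) to BOTTOM.

Sites reached by neither tract remain heteroduplex and segregate at
replication: all of a molecule's unresolved sites jointly inherit TOP or
BOTTOM with probability ½ (one daughter strand is sampled, reflecting
semiconservative replication — this correlates sites within a molecule and
affects variance, not means).

**Exclusivity.** Under the default `exclusive` policy, exclusivity holds at
the *site* level: a site covered by both tracts (possible only when both
excision events occur) resolves TOP or BOTTOM by an independent fair coin.
This choice admits any `(pi_b, pi_t)` in the unit square and makes the
closed form

    p_top(x) = 1/2 + [pi_b·theta_b^x − pi_t·theta_t^(L−x−1)]/2

*exact*: writing `B = pi_b·theta_b^x` and `T = pi_t·theta_t^(L−x−1)`,
`p_top = B(1−T) + BT/2 + (1−B)(1−T)/2 = 1/2 + (B−T)/2`. A molecule-level
exclusive draw (mechanism ∼ Categorical(pi_b, pi_t, 1−pi_b−pi_t)) yields the
identical closed form on its domain `pi_b + pi_t ≤ 1`; the site-level
formulation was chosen so that strong-excision regimes such as
`pi_b = pi_t = 0.6` are representable. A `first-wins` sensitivity policy
(the Cdkn1A-side incision acts first and its conversions are final) is
Monte-Carlo only; `expected_retention` refuses it.

Geometric tract lengths are the minimal one-parameter choice and no
tract-length data constrain them; the default `theta = 0.99` (mean tract
100 nt) is an arbitrary but documented scale. Excision probabilities
`pi_b = pi_t = 0.6` serve as the wild-type-like default; scaling both down
(e.g. 4×) emulates mismatch-repair loss and provably shrinks the
rank-1-minus-rank-K polarity linearly. 3′ non-homologous tails are not
modelled; the nick position stands in for the tail-proximal end.

## Read simulation

Reads span the full repeat window plus optional flanks. Errors are i.i.d.
substitutions (default rates 0–1%, hard-capped at 10%); an optional per-base
deletion mode exercises the gap-call path. A configurable fraction of reads
is emitted reverse-complemented. Phred+33 qualities are constant at
`round(−10·log10(error_rate))` (Q40 for error-free reads); the pipeline
deliberately ignores qualities, since the procedure it mirrors filters by
abundance only. What the generator does *not* emulate: PCR jackpotting and
chimeras, indel-rich sequencing profiles, coverage variation along the
amplicon, and any dependence of deletion *frequency* on DSB/repeat distance
(screen frequencies are drawn directly, not mechanistically). Passing tests
therefore validate the pipeline's arithmetic and the model's internal
consistency, not platform-specific artefact handling.

## Retention pipeline

1. **Collapse & filter** — unique-sequence counts over all reads; retain
   sequences whose count/total ≥ `min_fraction` (default 0.001, inclusive ≥,
   denominator = pre-filter total). With realistic error rates, individual
   error-bearing variants each fall well below 0.1% and are removed, so the
   retained set is dominated by true product haplotypes.
2. **Align & call** — each retained unique read is aligned globally to the
   top-strand reference with match/mismatch/gap = +1/−2/−3 and free end
   gaps, in both orientations; the better score is kept (ties → forward).
   At each divergent site the aligned base is TOP, BOTTOM, OTHER (third
   base, i.e. error or novel mutation) or GAP (deleted/uncovered). Reads
   under 80% identity to the reference over the repeat window are called
   GAP at all sites.
3. **Profile** — counts are abundance-weighted; OTHER and GAP are excluded
   from numerator *and* denominator (so top% + bottom% = 100 per site) and
   tallied as `n_excluded`; a site with no informative read is reported
   missing (NaN), never 0.
4. **Aggregate & compare** — replicate mean and sample SD (ddof = 1);
   all-pairs two-sided Student t-tests (Welch by flag) with Holm–Šidák
   step-down adjustment (`adj_k = max_{j≤k} 1−(1−p_j)^(m−j+1)`, clipped to
   [0,1]); two constant equal groups compare at p = 1 by convention.
5. **Fit** — box-constrained trust-region least squares of the closed form
   against mean percentages, multi-started from a fixed grid plus seeded
   random points; the best residual sum of squares wins. With noise-free
   closed-form input the four parameters are recovered to ≲1e−3; a flat 50%
   profile drives both `pi` estimates to ~0.

The 0.1% abundance filter can drop rare tract/segregation haplotypes and
thus bias site percentages by a fraction of a percent; the suite's exact
closed-form comparisons therefore run with the filter disabled, while
parameter-recovery checks (tolerance ±0.05 on `pi`) run with the default
filter, matching how the procedure is used in practice.

## Reporter statistics

`value = raw GFP+ / parallel transfection GFP+` (transfection efficiency
cancels exactly under common rescaling); `control_scaled_value = value /
mean(control values)`, making the control mean exactly 1 per batch (a batch
is the list passed in; callers group per transfection day). Triage flags a
gene when any assay's mean fold is ≥ 1.5 or ≤ 1/1.5 — decreases count
symmetrically, since suppressors and promoters are both of interest. Assay
labels follow `"<divergence>:<distance>"` so the divergent/identical ratio
can pair assays at matched DSB/repeat distance. ΔΔCt uses condition-mean
ΔCt (target − ACTIN) referenced to the control condition; the control's
2^−ΔΔCt is exactly 1. Group comparisons: one-way ANOVA with Tukey HSD on
the studentized-range distribution (via scipy), or pairwise equal-variance
t-tests with the same Holm–Šidák machinery as the site comparisons;
all-identical constant groups return p = 1 by convention.

## Problem sizes and determinism

Default verification sizes: closed-form vs Monte-Carlo agreement at 10⁵
molecules per parameter draw (3 binomial SE per site); end-to-end parameter
recovery from 3 replicates × 5·10⁴ molecules at 0.5% base error; polarity
checks at 2·10⁴ molecules. All generators take explicit integer seeds and
are byte-reproducible; the simulator draws its random variates in a fixed
order (bottom event, bottom tract, top event, top tract, segregation coin,
collision coins).

## Known limitations

- Indel-aware re-genotyping is limited to GAP exclusion; junction/tail
  sequences and paired-end merging are out of scope (reads are assumed to
  span the repeat).
- The tract-length scale `theta` is weakly identified when tracts are much
  longer than the repeat (curves saturate); `pi` remains well identified.
- Whether observed percentages should be weighted by read abundance across
  unique sequences is not externally fixed; count-weighted is the default
  and unweighted analysis can be had by setting all counts to 1.
- Screen frequencies are phenomenological (planted folds + lognormal
  noise), suitable for validating arithmetic and triage, not for power
  analysis of real screens.
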