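# Methods

## The assay being modelled

Each sample × SNP is measured in two duplex reactions: a wild-type-specific
and a variant-specific primer set, each co-amplifying a GAPDH internal
positive control (IPC) on a second fluorescence channel. A 45-cycle run
produces one amplification curve per well and channel. Because germline
variants occur at template fractions of 0, 50 or 100%, the two
allele-specific reactions of a SNP either start from the same amount of
matched template (heterozygote, ΔCt ≈ 0) or differ by the full mismatch
discrimination of the primer (homozygote, ΔCt large), and a threshold on
ΔCt separates the two cleanly.

## Ct estimation

* **Baseline**: least-squares line over cycles 3–15, subtracted per well.
  Cycles 1–2 are excluded for settling artifacts. The fit absorbs constant
  offsets and linear drift exactly, which gives the shift-invariance
  property of the estimator.
* **Threshold**: the classic 10-sigma rule, 10× the baseline noise SD
  (residual SD of the baseline fit, ddof = 2). A single 13-cycle window
  estimates that SD with ~21% relative error, which would translate into
  ~0.1–0.15 cycles of threshold-placement error per well; since baseline
  noise is an instrument/channel property, the plate pipeline pools the
  per-well SDs (median across wells, robust to wells whose amplification
  encroaches on the window) into one threshold per channel, as real
  instruments do. Isolated single curves fall back to the per-well rule.
  The threshold is floored at 10⁻⁶ of the plate's maximum corrected
  fluorescence so noise-free curves still get a finite threshold.
* **Crossing**: the first cycle at or above threshold that stays above it
  for ≥ 2 cycles (rejecting single-cycle spikes), interpolated between the
  flanking cycles linearly in log-fluorescence. Log-linear interpolation is
  exact for exponential-phase growth; plain linear interpolation there has
  a systematic bias of up to ~0.2 cycles at the curve shapes involved,
  larger than the estimator's entire random error. A non-positive flanking
  value falls back to linear interpolation. No qualifying crossing within
  the run ⇒ UNDETERMINED.

On plates of default-noise simulated curves the estimator's median absolute
error is ≈ 0.07 cycles (asserted < 0.1 in the suite, 1,000 curves).

## Interpretation rules and their constants

| constant | default | meaning |
|---|---|---|
| `ipc_max_ct` | 30.0 | IPC must amplify with Ct strictly < 30 for a reaction to count |
| `delta_ct_threshold` | 2.0 cycles | het/hom decision boundary; at efficiency 2 it equals a 4-fold template imbalance |
| `max_cycle` | 45 | run length; also the reference for one-sided ΔCt |
| `min_input_ng_per_ul` | 5.0 | below this the `LOW_INPUT` flag is set (reproducibility warning, not a no-call) |

Decisions at the edges, each deliberate:

* **ΔCt exactly 2.0 is homozygous** — a 4-fold imbalance is already
  evidence of a single amplifying allele.
* **One-sided amplification is a homozygote**, not a no-call: a true
  homozygote's mismatched reaction may simply never cross within 45
  cycles; ΔCt is recorded as `max_cycle − Ct`, floored at the threshold.
* **IPC failure voids only its SNP**, because the IPC certifies each
  individual reaction.
* **No inconclusive zone** between the heterozygote (<1) and homozygote
  (>8) clusters: the rule is a single threshold at 2. A richer rule with
  an explicit gray zone would be a straightforward extension but is not
  implemented.
* Genotype vectors that no declared star-allele pair can explain (they
  would imply a haplotype such as c.238G>C + c.719A>G in cis that the
  panel does not declare) surface as an error from the enumeration API and
  as an *indeterminate* sample in the plate pipeline. Of the 27 possible
  three-SNP genotype vectors, 14 are explainable over the default panel
  (15 allele pairs, two of which produce the same vector).

## Diplotype ambiguity

Het c.460 + het c.719 is the only ambiguous vector for the default panel:
\*1/\*3A (cis) vs \*3B/\*3C (trans), which differ clinically (intermediate
vs poor metabolizer). Default policy ranks candidates by Hardy–Weinberg
prior products 2·p·q using configurable allele priors (shipped defaults:
\*1 0.95, \*3C 0.03, \*3A 0.015, \*3B 0.0049, \*2 0.0001 — an East-Asian-
shaped prior where \*3C predominates; these are ranking weights, not
measurements). The alternative pair, its normalized score and its phenotype
are always reported, and `ambiguity_policy: worst_case` instead reports the
candidate with the poorer phenotype for conservative dosing.

## Validation statistics

Allele frequencies are reported per SNP (variant count = 2·hom_var + het;
no-call samples leave that SNP's denominator) and per star allele (from
per-sample diplotype resolution over fully-called samples), with exact
Clopper–Pearson 95% CIs and round-half-even percent formatting (10/488 →
2.05). Concordance is per-sample exact matching over all SNPs, with
no-call samples excluded from the comparable set and listed. The
Hardy–Weinberg test is the exact conditional test (full enumeration of
heterozygote counts given allele counts via log-gamma), because expected
variant-homozygote counts at these frequencies are far below chi-square
validity.

## The simulator

Deterministic core: Ct = A − log_E(copies) + mismatch_penalty·(1 −
matched), with A = 38 (Ct of one matched copy), E = 2, penalty = 12
cycles. Stochastic layers:

* **Template sampling** — a well's matched template fraction is 1 / 0.5 / 0
  for matching homozygote / heterozygote / opposite homozygote; each route
  (matched, mismatched remainder) detects Poisson(p·copies) effective
  copies with per-copy detection efficiency *p*; zero on all routes means
  no amplification. This Poisson layer is what creates a finite limit of
  detection.
* **Cycle noise** — Normal(0, 0.15) cycles per well; IPC Ct ~
  Normal(24, 0.3).
* **Curves** — baseline 0.05 + 0.002/cycle drift + a logistic
  fmax/(1+e^(−k(c−m))) with fmax = 3, k = 1.8/cycle, midpoint m placed so
  the noise-free curve crosses fluorescence 0.1 exactly at the well's Ct
  (the analytic oracle for estimator tests), + Normal(0, 0.01)
  per-point noise, clipped at zero. The shape constants were chosen from
  an error budget so that the 10-sigma threshold sits in the exponential
  phase and the estimator meets its 0.1-cycle accuracy target; they are not
  fitted to any instrument.

Unit conversions follow the assay's characterization: 1 ng/µL genomic DNA ≡
10³ copies/µL (the assay's own reported equivalence — higher than the
~300 copies/ng expected from a 3.3 pg haploid genome; it is exposed as
`copies_per_ng_ul` rather than silently corrected), and 5 µL template per
50 µL reaction, so copies/reaction = 5 × copies/µL.

Detection efficiency defaults are **calibrated, not measured**: p = 0.05
puts the per-replicate detection probability at 100 copies at
1 − e^(−5) ≈ 0.993, so the ≥ 95%-of-replicates rule lands the LOD at 10²
copies/reaction robustly across seeds; the c.719A>G preset p = 0.01 fails
at 10² (detection ≈ 0.63) and lands at 10³. A boundary value (p = 0.03,
detection exactly 0.950 at 100 copies) would make the LOD a coin flip over
20 replicates, which is why it was not used. The LOD routine walks the
dilution grid from high to low and reports the smallest amount still in an
unbroken chain of ≥ 95%-correct concentrations.

The validation-cohort preset (`paper_panel`) is 234 \*1/\*1 + 10 \*1/\*3C
patients at 10 ng/µL plus the NA09301 (\*1/\*3B) and NA03579 (\*1/\*3C)
Coriell controls — 246 samples, 1,476 wells, 2,952 curves; a full
simulate → estimate → call → validate cycle takes ~2 s, so no scaling-down
was needed anywhere in the suite. All randomness flows from one seeded
`numpy` generator; identical seeds give bit-identical output files.

## What the simulator does and does not show

It reproduces the *mechanisms* that make the assay work — ΔCt separation
driven by a mismatch penalty, IPC-based QC, Poisson-limited detection,
baseline/drift/noise on curves — so passing tests demonstrate that the
interpretation chain is correct *given* those mechanisms. It does not
model primer-specific breakthrough kinetics (the mismatch penalty is one
fixed number), fluorophore crosstalk, plate-position effects, inhibitors,
or non-logistic curve shapes; agreement with the simulator is therefore not
evidence about any particular instrument's chemistry. The homozygote/
heterozygote ΔCt margins (> 8 / < 1) emerge from the penalty and noise
settings and match the validated assay's reported separation by
construction.

## Degenerate inputs and tie-breaks

* A curve crossing threshold exactly at an integer cycle returns that
  integer; a crossing at the final cycle cannot satisfy the 2-cycle
  sustain guard and is UNDETERMINED.
* Unordered allele pairs are canonicalized by name sort for stable output.
* Missing DNA concentration is a warning flag (`LOW_INPUT_UNKNOWN`), never
  an error.
* Ct values are reported to 2 decimals in TSV reports; full precision is
  retained internally and in JSON.
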