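# tpmtyper

Allele-specific real-time PCR genotyping of **TPMT** star alleles, as a
tested software pipeline.

Thiopurine drugs (azathioprine, 6-mercaptopurine, 6-thioguanine) are
inactivated by thiopurine S-methyltransferase (TPMT). Patients carrying two
nonfunctional *TPMT* alleles risk severe myelosuppression at standard doses,
so clinical laboratories genotype the three SNPs that define the common
nonfunctional star alleles — c.238G>C (\*2), c.460G>A (\*3A/\*3B) and
c.719A>G (\*3A/\*3C) — before therapy. A fast way to do this is duplex
allele-specific qPCR: each SNP is assayed in two wells, one with a
wild-type-specific primer and one with a variant-specific primer, each
co-amplifying a GAPDH internal positive control (IPC). `tpmtyper` implements
the entire interpretation chain for such an assay, plus a calibrated
simulator so the chain can be exercised and validated without an
instrument.

## The method

For a well with amplification efficiency *E* and *N* starting template
copies, the threshold cycle follows

&nbsp;&nbsp;&nbsp;&nbsp;Ct = A − log<sub>E</sub>(N) (+ penalty if the primer's 3′ end mismatches the template),

so with *E* = 2 a ΔCt of 2 between the two allele-specific reactions of one
SNP corresponds to a ≥ 4-fold template imbalance. Interpretation is:

1. **Ct estimation** — least-squares baseline subtraction (cycles 3–15),
   threshold = 10× baseline noise SD pooled per channel across the plate,
   log-linear interpolation at the first sustained crossing.
2. **QC gate** — a reaction counts only if its IPC Ct < 30; an IPC failure
   voids that SNP (no-call), not the sample. DNA input below 5 ng/µL is
   flagged (`LOW_INPUT`) but still interpreted.
3. **ΔCt call** — |Ct_wt − Ct_var| < 2 ⇒ heterozygote; ≥ 2 ⇒ homozygote for
   the earlier-amplifying allele; one-sided amplification ⇒ homozygote with
   ΔCt = 45 − Ct; no amplification ⇒ no-call.
4. **Diplotyping** — exhaustive enumeration of star-allele pairs consistent
   with the unphased genotype vector; phase ambiguity (het c.460 + het
   c.719: \*1/\*3A in cis vs \*3B/\*3C in trans) resolved by
   Hardy–Weinberg prior products (or a conservative `worst_case` policy),
   with alternatives always reported. Phenotype = normal / intermediate /
   poor metabolizer for 0 / 1 / 2 nonfunctional alleles.
5. **Validation statistics** — per-sample concordance against a reference
   method, allele frequencies with exact Clopper–Pearson 95% CIs, and an
   exact conditional Hardy–Weinberg test.

## A worked example

```python
from tpmtyper import (SimParams, Stratum, default_panel, process_plate,
                      simulate_panel, write_report)

panel = default_panel()
plate = simulate_panel([Stratum("*1/*1", 1, 10.0), Stratum("*1/*3C", 1, 10.0)],
                       panel, SimParams(seed=17))
results = process_plate(plate.wells, plate.metas, panel)
print(write_report(results, panel)[0])
```

prints (abridged):

```
sample_id  genotype:c.238G>C  delta_ct:c.238G>C  ...  genotype:c.719A>G  delta_ct:c.719A>G  diplotype  phenotype
S0001      hom_wt             11.74              ...  hom_wt             11.98              *1/*1      normal
S0002      hom_wt             12.17              ...  het                0.10               *1/*3C     intermediate
```

Each row is one sample. Homozygous SNPs show ΔCt near the 12-cycle
mismatch penalty (only one allele amplifies on time); the heterozygote at
c.719A>G shows ΔCt ≈ 0.1 (both alleles amplify together), which makes the
sample \*1/\*3C — one nonfunctional allele, an intermediate metabolizer.
The scripts in `examples/` extend this to cohort statistics and
limit-of-detection estimation, and the same pipeline is available from the
shell:

```bash
tpmtyper simulate --preset paper_panel --seed 17 --out-dir run/
tpmtyper call --layout run/layout.csv --curves run/curves.csv \
              --samples run/samples.csv --out-prefix run/report
tpmtyper validate --calls run/report.genotypes.tsv --reference run/truth.tsv \
                  --out-prefix run/validation
```

## Scope

Primer/probe design, wet-lab chemistry and direct-sequencing itself are out
of scope (reference genotypes are consumed as a table); RDML parsing and
instrument binary formats are non-goals. The panel definition is data
(`src/tpmtyper/data/tpmt_panel.yaml`), so adding, e.g., \*6 (c.539A>T) is a
config edit, not a code change. See `docs/methods.md` for the model,
parameter choices and known limitations.
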