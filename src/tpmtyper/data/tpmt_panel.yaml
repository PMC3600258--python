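# Default TPMT genotyping panel: the three SNPs that define the clinically
# relevant star alleles *2, *3A, *3B and *3C.
#
# prior_freq values are configurable population priors used ONLY to rank
# phase-ambiguous diplotypes (e.g. het c.460 + het c.719: *1/*3A vs *3B/*3C).
# They reflect the qualitative East Asian picture (*3C predominant, *2 rare);
# they are defaults, not measured frequencies.
schema_version: 1
name: TPMT
snps:
  - snp_id: "c.238G>C"
    rsid: rs1800462
    wt_base: G
    var_base: C
    protein_change: p.Ala80Pro
  - snp_id: "c.460G>A"
    rsid: rs1800460
    wt_base: G
    var_base: A
    protein_change: p.Ala154Thr
  - snp_id: "c.719A>G"
    rsid: rs1142345
    wt_base: A
    var_base: G
    protein_change: p.Tyr240Cys
  # TPMT*6 is not in current dosing guidelines; uncomment to genotype it.
  # - snp_id: "c.539A>T"
  #   rsid: rs75543815
  #   wt_base: A
  #   var_base: T
  #   protein_change: p.Tyr180Phe
alleles:
  - name: "*1"
    variant_snps: []
    prior_freq: 0.95
    functional: normal
  - name: "*2"
    variant_snps: ["c.238G>C"]
    prior_freq: 0.0001
    functional: nonfunctional
  - name: "*3A"
    variant_snps: ["c.460G>A", "c.719A>G"]
    prior_freq: 0.015
    functional: nonfunctional
  - name: "*3B"
    variant_snps: ["c.460G>A"]
    prior_freq: 0.0049
    functional: nonfunctional
  - name: "*3C"
    variant_snps: ["c.719A>G"]
    prior_freq: 0.03
    functional: nonfunctional
  # - name: "*6"
  #   variant_snps: ["c.539A>T"]
  #   prior_freq: 0.005
  #   functional: nonfunctional
phenotype_map:
  0: normal
  1: intermediate
  2: poor
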