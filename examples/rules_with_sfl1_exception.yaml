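# Default three-interaction rule set plus an optional low-penetrance rule
# for the one exceptional rough sfl1-deletion segregant whose genotype was
# END3-BY FLO8-3S MSS11-BY TRR1-BY (TRR1 carries the BY allele instead of
# 3S).  Several explanations are possible for that single individual, so
# it is not part of the default rules; the 0.05 penetrance here is an
# illustrative choice, not a measured value.
default_phenotype: SMOOTH
rules:
- name: five_way
  background: IRA2_D2933
  required_alleles: {END3: BY, FLO8: 3S, MSS11: BY, TRR1: 3S}
  phenotype: ROUGH
  penetrance: 1.0
- name: six_way
  background: IRA2_D2933
  required_alleles: {END3: 3S, FLO8: 3S, MGA1: BY, MSS11: BY, SFL1: BY}
  phenotype: ROUGH
  penetrance: 1.0
- name: sfl1_delta
  background: SFL1_DELETED
  required_alleles: {END3: BY, FLO8: 3S, MSS11: BY, TRR1: 3S}
  phenotype: ROUGH
  penetrance: 1.0
- name: sfl1_delta_trr1_by_exception
  background: SFL1_DELETED
  required_alleles: {END3: BY, FLO8: 3S, MSS11: BY, TRR1: BY}
  phenotype: ROUGH
  penetrance: 0.05
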