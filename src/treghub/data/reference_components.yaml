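# Component inputs for the six candidate indications of the CCR8 + ICI
# integrated scoring analysis.  BRCA checkpoint correlations are given as the
# raw TCGA p-values (binned at scoring time); all other components are the
# pre-binned 0-3 (or summed 0-9) scores.
BRCA:
  checkpoint_pvalues: {PDCD1: 9.67e-102, CD274: 4.12e-63, CTLA4: 2.64e-206}
  treg_score: 3
  tmb_score: 9
  msi_score: 6
  soc: true
HNSC:
  checkpoint_scores: {PDCD1: 2, CD274: 2, CTLA4: 2}
  treg_score: 3
  tmb_score: 6
  msi_score: 6
  soc: true
COAD:
  checkpoint_scores: {PDCD1: 2, CD274: 2, CTLA4: 2}
  treg_score: 2
  tmb_score: 6
  msi_score: 6
  soc: true
STAD:
  checkpoint_scores: {PDCD1: 2, CD274: 2, CTLA4: 2}
  treg_score: 3
  tmb_score: 6
  msi_score: 5
  soc: true
THCA:
  checkpoint_scores: {PDCD1: 2, CD274: 0, CTLA4: 2}
  treg_score: 3
  tmb_score: 4
  msi_score: 3
  soc: false
READ:
  checkpoint_scores: {PDCD1: 0, CD274: 0, CTLA4: 1}
  treg_score: 1
  tmb_score: 6
  msi_score: 5
  soc: false
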