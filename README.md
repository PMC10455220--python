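# synergyseek

Drug-resistant acute myeloid leukemia (AML) is usually treated with
cytarabine plus an anthracycline such as daunorubicin, and resistance to
the anthracycline is a major cause of treatment failure. `synergyseek`
turns treatment-evoked gene-expression changes in drug-sensitive vs.
drug-resistant AML cell lines into ranked, experimentally checkable
drug-combination candidates. It is a library plus a `synergyseek` CLI for
computational biologists working on transcriptional drug-response
signatures and combination screening.

The pipeline:

1. **Differential expression** from gene-level counts: TMM normalization,
   an exact negative-binomial test at fixed dispersion φ (conditional on
   the two-group total the count split is Beta-Binomial(t, n₁/φ, n₂/φ)),
   BH correction, and the call rule |log2FC| > 1, FDR < 0.05.
2. **Signatures**: a *resistance* profile — changes seen in the resistant
   line under the drug alone and absent (same direction) from every
   sensitive line under drug and combination — and a *response* profile —
   changes common to all sensitive lines under drug and combination and
   absent from the resistant line.
3. **Connectivity**: each profile is scored against a perturbagen
   reference-signature library with Connectivity Map-style statistics
   (weighted-KS enrichment score ES, two-sided WTCS = (ES_up − ES_down)/2
   for sign-discordant pairs, NCS normalized within (cell line,
   perturbagen type)). Partners must reverse the resistance profile
   (NCS ≤ −1) and mimic the response profile (NCS ≥ +1); ambiguous
   knockdown/overexpression targets and double-profile mimics are
   filtered, compounds must be concordant with a knockdown of their
   annotated target, and surviving classes are ranked by cell-line
   support.
4. **Bliss validation**: on a viability dose matrix the expected combined
   inhibition is y_a + y_b − y_a·y_b; the average excess over it (×100) is
   the Bliss score (> 0 synergistic, < 0 antagonistic), with ALMANAC-style
   per-class aggregation across cell-line panels.
5. **Genomic association**: each binary alteration is tested against
   synergy scores by one-way ANOVA (≡ pooled t-test, F = t²) with Cohen's
   d effect sizes and Storey–Tibshirani q-values; defaults p < 0.001,
   FDR < 25%, ≥ 3 cell lines per group.

A seeded synthetic-data module generates counts, libraries, dose matrices
and mutation panels with planted ground truth, so the whole pipeline is
testable end to end without downloads. See `docs/methods.md` for the
model details and design choices.

## Worked example

One command simulates a full study and runs every stage:

```sh
synergyseek demo --seed 1 --out demo
```

`demo/inputs/` holds the generated counts/metadata, signature library,
dose matrix, mutation panel and `truth.json`; `demo/results/` holds one DE
table per (cell line, treatment), overlap and enrichment reports,
`profiles.json`, `candidates.tsv`, `synergy.tsv`, `associations.tsv` and a
run manifest. With seed 1:

* `profiles.json` — resistance profile of 196 inductions / 92 repressions,
  response profile of 40 / 9. The planted programs (60/30 and 40/10) are
  inside these; the resistance profile also legitimately contains changes
  unique to the resistant line beyond the planted module.
* `candidates.tsv` — a single candidate class survives the filters:

  ```
  class  n_support_cell_lines  mean_ncs_resist  mean_ncs_response  members
  TGTR   3                     -2.67            2.97               CPD_REV1;CPD_REV2;KD_TGTR
  ```

  i.e. the two planted reverser compounds and the knockdown of their
  annotated target, supported in all 3 library cell lines: they reverse
  the resistance signature (NCS −2.67) while mimicking the response
  signature (NCS +2.97). Decoys and the planted ambiguous
  knockdown/overexpression pair are filtered out.
* `synergy.tsv` — the generated dose matrix scores 15.49 (synergistic);
  the generator planted a Bliss excess of 15 plus noise.
* `associations.tsv` — the planted synergy-shifting mutation `M001` is the
  top hit (Cohen's d 2.97, p 1.6e-08, q 7.6e-07, significant); the best
  decoy gene reaches only p ≈ 0.01 and is not significant at the p < 0.001
  threshold.

The same stages are available individually (`synergyseek simulate`, `de`,
`profiles`, `connect`, `bliss`, `bliss-batch`, `assoc`, `run`) and as
library functions (`de_analysis`, `build_resist_profile`,
`predict_partners`, `bliss_matrix_score`, `run_association_scan`, ...).

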