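# qtalert

Structural-alert screening and structure–activity modelling for
**drug-induced QT-interval prolongation (DIQT)**, with reporting-odds-ratio
disproportionality ranking of adverse-event data and fully synthetic,
ground-truth-bearing test data.

Many non-cardiac drugs prolong the ventricular repolarization (QT) interval,
which can degenerate into torsades de pointes. `qtalert` is aimed at
cheminformaticians and drug-safety scientists who want to ask: *which chemical
substructures distinguish QT-prolonging drugs from drugs with no DIQT concern,
and how well do those substructures predict risk?* It implements the complete
analysis chain:

1. **Alert screen** — match a dictionary of named SMARTS structural alerts
   (SAs) against a positive (QT-prolonging) and a negative (no-DIQT-concern)
   cohort. For alert *j*, with nⱼ⁺ of N⁺ positives and nⱼ⁻ of N⁻ negatives
   carrying ≥1 embedding, the screen reports pⱼ⁺ = nⱼ⁺/N⁺, pⱼ⁻ = nⱼ⁻/N⁻ and
   Δⱼ = pⱼ⁺ − pⱼ⁻, retaining alerts with Δⱼ > 0.20 (strict). Counting is per
   molecule, never per occurrence.
2. **SA-linked descriptors** — ten substructure-count descriptors tied to the
   retained alerts (tertiary aliphatic amines, halogen atoms, aryl/alkyl
   ethers, amides, …; Mold2 codes D718…D598), plus CSV import of externally
   computed matrices and a population-variance filter (columns with
   var ≤ 0.001 dropped).
3. **SAR models** — RBF-kernel SVM (with logistic regression, random forest
   and gradient-boosted trees as comparison families) under repeated
   stratified 5-fold cross-validation, a permutation-label negative control
   (`Permutation_Y`), a nine-metric panel (accuracy, recall/SE, precision,
   MCC, F1, BACC, AUC, AP, SP), sampled-Shapley/permutation feature
   attribution, and a reduced model on the ten SA-linked features.
4. **Disproportionality** — case-level 2×2 aggregation of drug–event reports
   and the reporting odds ratio ROR = ad/(bc) with Wald 95% CI
   (Haldane–Anscombe correction on zero cells), descending ROR ranking,
   top-N subsets and recall-at-top-N evaluation, plus ATC-matched
   independent-test construction.
5. **Synthetic data** — generators that *plant* known truth: molecules
   assembled from carrier fragments at chosen alert prevalences, case tables
   whose per-drug 2×2 cells are reproduced exactly on aggregation, and
   Gaussian descriptor matrices with known Bayes error.

## Worked example

Screen arithmetic over the reference per-alert counts (cohort sizes 144/95)
shipped with the package:

```python
from qtalert.alerts import load_reference_counts, screen_from_counts
report = screen_from_counts(load_reference_counts(), 144, 95)
print(report.to_frame().head(5).to_string(index=False))
```

```
 alert_id class_group                            name  n_pos  p_pos  n_neg  p_neg  difference  retained
        1      amines                 tertiary amines     88 0.6111     12 0.1263      0.4848      True
        2      amines sp3-hybridized carbon atoms (2)    117 0.8125     36 0.3789      0.4336      True
        3      amines       tertiary aliphatic amines     76 0.5278      9 0.0947      0.4330      True
        4      amines               16-tertiary amine     91 0.6319     19 0.2000      0.4319      True
        5      amines                          amines    119 0.8264     38 0.4000      0.4264      True
```

61% of QT-prolonging drugs carry a tertiary amine versus 13% of no-concern
drugs (Δ = 0.4848); all 24 shipped alerts pass the 20% retention rule.

A reporting odds ratio from a 2×2 table — 20 of 30 reports for the drug
mention the event, versus 5 of 45 without the drug:

```python
from qtalert import ContingencyTable, compute_ror
r = compute_ror(ContingencyTable(20, 10, 5, 40), drug_id="drugA")
print(f"ROR={r.ror:.1f}  95% CI ({r.ci95[0]:.2f}, {r.ci95[1]:.2f})")
# ROR=16.0  95% CI (4.82, 53.13)
```

The permutation negative control at the reference class sizes (144/95, noise
features, 100 iterations of 5-fold CV with the RBF-SVM) sits at chance —
balanced accuracy ½, MCC 0, precision at the positive prevalence
144/239 ≈ 0.602:

```python
from qtalert.acceptance_runs import permutation_reference_run
s = permutation_reference_run(seed=1, n_iterations=100)
print(s.formatted()[["bacc", "mcc", "precision"]].to_string())
# bacc          0.501 ± 0.018
# mcc          -0.003 ± 0.067
# precision     0.604 ± 0.010
```

## Command line

```bash
qtalert simulate --n-pos 144 --n-neg 95 --seed 1 --outdir sim/
qtalert screen --pos sim/cohort_positive.csv --neg sim/cohort_negative.csv --out screen.tsv
qtalert run-all --outdir run/ --seed 1          # whole workflow on synthetic data
```

Subcommands `descriptors`, `cv`, `permute`, `select-features`, `ror` and
`topn-recall` expose the intermediate stages; every stage reads and writes
plain CSV/TSV, and `run-all` writes a `manifest.json` with SHA-256 checksums
so a rerun with the same seed is byte-identical.

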