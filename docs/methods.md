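# Methods

This note documents the models, conventions and parameter choices behind
`qtalert`, and what its synthetic-data tests do and do not establish about
real drug-safety data.

## Structure standardization

All structures pass one fixed normalization before any matching or counting:
the largest covalent fragment is kept (salt/counter-ion stripping, with
carbon-containing fragments preferred over bare inorganic ions), charges are
neutralized where chemically possible, stereochemistry is discarded, and
aromaticity is perceived under RDKit's default model. The operation is
idempotent and is verified as such on every fixture. Rationale: every
downstream feature is a 2D substructure count, so stereochemistry carries no
information here, and alert matching depends on the aromaticity model, which
must therefore be uniform. Records whose structures fail to parse are
excluded with a logged warning rather than aborting a load — curated drug
sets routinely contain a few broken entries — but duplicate identifiers are
a hard error, since cohorts are expected to be curated and unique.

## The alert screen

An alert is a named SMARTS pattern; a molecule "carries" an alert if at
least one embedding exists. The screen statistic for alert *j* is the
difference of per-cohort carrier proportions Δⱼ = nⱼ⁺/N⁺ − nⱼ⁻/N⁻, and the
retention rule keeps alerts with Δⱼ strictly greater than the threshold
(default 0.20). Strictness is immaterial for the shipped reference rows
(minimum difference 0.2109) but is fixed for reproducibility. No
significance test is attached: the screen is deliberately the plain
proportion difference.

The 24 shipped alert definitions (`src/qtalert/data/alert_dictionary.tsv`)
are this package's own SMARTS readings of the named fragment classes from
the ToxAlert vocabulary (e.g. *tertiary aliphatic amines* =
`[NX3;H0;!$(NC=O...)]([CX4])([CX4])[CX4]`); the service's internal
definitions are not public. The dictionary is data, not code: replace the
file to use other definitions. Overlapping classes (e.g. *tertiary amines* ⊃
*tertiary aliphatic amines*) are screened independently, with no hierarchy
de-duplication, because the reference screen reports both. The per-alert
reference counts (144/95 cohorts) ship alongside so the screen arithmetic is
reproducible without the underlying proprietary structures.

## SA-linked descriptors

The ten substructure-count descriptors (D718, D756, D661, D759, D627, D130,
D647, D626, D757, D598) are re-implemented from their one-line printed
descriptions, counting symmetry-unique occurrences anchored on the
group-defining atom (one NR₃ nitrogen is one tertiary amine however its
substituents are enumerated). Interpretation choices worth noting:

* D756's "R-O-C=X" is read with X ∈ {O, S, N}; the three sub-patterns
  (Al-O-Ar, Ar-O-Ar, R-O-C=X) are merged by counting distinct oxygen atoms.
* D647 and D757 both reduce to "NH₂ on an sp3 carbon" under their printed
  descriptions (the D647 footnote makes the hybridization explicit); both
  codes are kept, with identical counting rules.
* D626 ("secondary amides, aromatic") is read as the N-aryl secondary amide
  (anilide) nitrogen.
* The original 777-descriptor generator is a closed binary; only these ten
  are computed locally, and full externally computed matrices can be
  imported by CSV. Counting conventions are validated against a
  hand-enumerated 20-molecule fixture set, which is the strongest available
  oracle given that the original conventions are unpublished.

The variance filter uses the population variance (ddof = 0) of the raw,
unstandardized values and removes columns with variance ≤ 0.001; it is
idempotent and erroring when nothing survives.

## SAR modelling

The core protocol is repeated stratified 5-fold cross-validation: each
iteration reshuffles fold assignment with a seed derived from the global
seed (via `numpy` seed sequences, so reruns are bit-identical), trains on
four folds and pools out-of-fold predicted probabilities, thresholded at
0.5 (strictly greater = positive). Per-iteration metric panels are
summarized as mean ± sample sd across iterations. The iteration count
defaults to 1000 and is configurable; validation runs in this repository
use 100 iterations (chance-level means at the reference class sizes are
then resolved to ± ~0.002–0.007 Monte-Carlo standard error, ample for the
checks performed), and unit tests use smaller counts still.

Model families: RBF-kernel SVC, logistic regression, random forest and
gradient-boosted trees (scikit-learn implementations throughout). Margin
and linear models are standardized with a scaler fit on training folds
only; tree models see raw values. The SVM's probabilities come from a Platt
sigmoid calibrator fit on inner training splits
(`CalibratedClassifierCV(..., ensemble=False)`), which is what makes the
0.5 probability threshold meaningful for a margin classifier. A nested
3-fold grid search (default coarse log₂ grids C ∈ 2⁻⁵…2¹⁵, γ ∈ 2⁻¹⁵…2³,
selected by balanced accuracy) is available via `Hyperparams.grid`; the
default configuration uses fixed C = 1, γ = 'scale', which is the
package's choice for routine and chance-level runs where the grid cannot
change the answer, only the runtime.

### Metric panel

Threshold metrics are computed from explicit confusion counts by their
closed forms, with defined degenerate fallbacks: MCC = 0 when any marginal
is zero; precision (hence F1) = 0 with no positive predictions. AUC is the
rank-based ROC area and AP the precision–recall area, both over pooled
out-of-fold probabilities. `auc_point` — the one-operating-point trapezoid
AUC, which algebraically equals balanced accuracy — is reported alongside
the proper AUC, because some published panels report that quantity under
the AUC heading (visible when printed AUC and BACC columns coincide
exactly).

### Permutation control

The negative control permutes the label vector independently before every
iteration and runs the identical protocol. For *any* feature matrix its
expectations are: balanced accuracy ½, MCC 0, and precision equal to the
positive-class prevalence (with 144/95 cohorts, 144/239 ≈ 0.602). These are
the package's desk-reproducible reference quantities; they are recomputed
from scratch by `scripts/acceptance.py`.

### Attribution and the reduced model

Feature scores are mean absolute attributions, computed per
cross-validation fold on held-out samples and averaged. The default method
is a native Monte-Carlo **sampled Shapley** estimate on the predicted
positive-class probability: for each evaluation sample, random feature
orderings are drawn and each feature's marginal change in the
background-marginalized model output is accumulated (the background is a
subsample of the training fold, default 25 rows, 10 orderings). The
model-agnostic fallback is permutation importance (held-out balanced
accuracy drop, 5 repeats), which is the practical choice for wide matrices
— the sampled-Shapley cost grows linearly in the number of features *and*
orderings. The top-50 features are intersected with the ten SA-linked codes
to drive the reduced ten-feature model, which is evaluated under the
unchanged CV protocol.

Whether attribution should be computed on training or held-out samples was
an open design choice; held-out samples were chosen to keep the ranking an
out-of-sample statement.

## Disproportionality

Aggregation is case-level: a case mentioning a drug (or event) five times
contributes once to the corresponding margin, and a + b + c + d equals the
number of distinct cases. The reporting odds ratio is ROR = ad/(bc), the
standard pharmacovigilance 2×2 odds ratio; the 95% CI is
exp(ln ROR ± 1.96·√(1/a + 1/b + 1/c + 1/d)). With any zero cell the
Haldane–Anscombe correction (0.5 added to all cells) is applied by default
and flagged per drug — spontaneous-report tables at scale routinely contain
zero cells. Ranking uses the point ROR, descending, with lexicographic
drug-id tie-breaks; the CI is an extension and does not influence rank.
The matched independent-test constructor pairs top-k positives with k pool
negatives by greedy ATC level-1 histogram matching, reallocating deficits
to the most frequent remaining pool letters (logged) and reporting the
residual L1 histogram distance.

## Synthetic data: what it emulates, and what it does not

* **Cohorts.** Molecules are assembled by attaching carrier fragments
  (e.g. `-N(CH3)2`, `-C6H4Cl`, `-OC6H5`) to inert alkane scaffolds, with
  independent Bernoulli draws per alert. Defaults plant the three alerts
  with registered carriers — tertiary aliphatic amines, aryl halide,
  alkylarylethers — at the reference screen proportions, with cohort sizes
  144/95. Independent planting of *overlapping* alert classes (tertiary
  amines vs amines vs base) is chemically unsatisfiable, which is why the
  default vocabulary is the mutually exclusive subset; the `implies`
  mapping supports correlated planting where one alert subsumes another.
  Every product is verified against the dictionary and re-drawn on
  violation, so realized counts are exact truth. These molecules are
  deliberately *not* drug-like: they validate counting and screening
  machinery, not chemistry-space realism, so passing tests say nothing
  about how informative the alerts are on real pharmacopoeia.
* **Report tables.** All drugs share one case universe with one drug per
  case and a common background event rate (default 5%); per-drug cells are
  solved from target RORs by a short fixed-point pass over the shared event
  margin, and record aggregation reproduces the cells exactly. The
  sampling mode draws the exposed-with-event and background-event cells
  binomially, which is the model under which the Wald CI's ~95% coverage
  is verified. Real spontaneous-report data — duplicated reports,
  polypharmacy, MedDRA coding — is out of scope.
* **Signal matrices.** Two-class Gaussians: informative columns get class
  means ±δ/2 at unit variance, noise columns are class-independent. The
  truth record carries a 200 000-draw Monte-Carlo estimate of the Bayes
  error (the optimal rule reduces to a 1-D projection), giving an absolute
  yardstick for classifier accuracy. Real descriptor matrices are integer,
  sparse, and correlated; the Gaussian harness checks the pipeline, not
  descriptor ecology.

## Numerical and reproducibility choices

* One global seed expands into fixed per-stage substreams (stage keys are
  constants), so toggling a pipeline stage does not shift another's
  randomness; all derived seeds stay below 2³¹.
* Retention and decision thresholds are strict inequalities; screen
  proportions are carried at full precision and rendered to 4 decimals.
* Ties in feature scores and ROR ranks break deterministically (stable
  sort / lexicographic id).
* Pipeline outputs contain no timestamps; `manifest.json` records SHA-256
  checksums, and a rerun with the same config is byte-identical.

## Known limitations

* The shipped SMARTS are documented approximations of named fragment
  classes whose authoritative definitions are not public; screening real
  cohorts with them will not reproduce counts derived from the original
  service's dictionary.
* Only the ten SA-linked descriptors are computed natively; analyses that
  need the full 777-descriptor set must import an externally computed
  matrix.
* The ROR machinery implements no other disproportionality statistic
  (PRR, IC, EBGM) and no report de-duplication.
* Grid-searched hyperparameters can shift real-data CV means relative to
  fixed-parameter runs; the chance-level control is insensitive to this,
  but substantive real-data modelling should enable the grid.
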