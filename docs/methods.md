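# Methods

## Model

The package ranks pharmacovigilance DDI signals by *maximum similarity to a
known interaction*. The underlying assumption is pharmacological clustering:
drugs of the same class share structure, targets, side effects and
classification codes, and tend to share interaction partners. A candidate
pair {i, j} therefore inherits evidence from the most similar known pair:

    M3(i, j) = max( max_{k ∈ N(i)} M2(k, j),  max_{k ∈ N(j)} M2(k, i) )

with N(x) the reference partners of x and M2 a drug×drug similarity matrix
with zero diagonal. The score is a similarity, not a probability; it is used
only for ranking and for explanation (the arg-max reference pair).

**Leave-one-out falls out of the zero diagonal.** For a pair {i, j} that is
itself a reference DDI, j ∈ N(i), and its own contribution to the max is
M2(j, j) = 0. So a known pair is scored exclusively through *other* known
pairs, with no case analysis. Sketch: every term in the max is M2(k, j) with
k ∈ N(i); the only term referencing the pair's own entry is k = j, which the
zero diagonal annihilates; symmetrically for M2(k, i), k = j′ = i. Hence
max-aggregation over a zero-diagonal M2 equals max-aggregation over the
reference set with the pair's own entry deleted.

**Ties.** The arg-max provenance breaks ties by the lexicographically
smallest (reference pair, matched drug), making explanations deterministic
under permutation of the input order.

**Aggregation.** `max` is the model. A `mean_top` option (mean of the t
highest reference links, default t = 3) exists as an alternative aggregation
for sensitivity analyses; it is intentionally not used by the pipeline
defaults.

**Scope.** Scores exist only for pairs with at least one drug in the
reference universe. Pairs with both drugs outside it are *unscorable* and
are reported as such (`MaxSimilarityScorer.unscorable`), never silently 0.

## Similarity measures

| domain | features | notes |
|--------|----------|-------|
| 2D     | 166 MACCS structural keys | computed from SMILES via RDKit's public 166-key dictionary; key-definition variants across toolkits can shift Tc by roughly ±0.02 |
| 3D     | external shape-screening scores | consumed as a labeled TSV matrix; asymmetric inputs are symmetrized by the elementwise max, nonzero diagonals forced to 0 with a warning |
| ADEPF  | adverse-effect terms | case-folded, trimmed |
| TPF    | protein targets | organism suffixes (`_HUMAN`-style, trailing parentheticals) stripped so the same protein from different organisms is one feature; numeric suffixes are part of the identifier |
| DDIPF  | known interaction partners | case-folded ids |
| ATC    | 4 upper ATC levels per code | level-tagged prefixes (1, 3, 4, 5 characters); multi-code drugs take the union |

Tc of two all-zero fingerprints is defined as 0: absence of evidence must
not read as maximal similarity. Drugs missing a domain entirely get an
all-zero fingerprint and a run-report warning rather than being dropped.

## Signal screening and labeling

Signals are kept when PRR > 1 **and** p < .05, both strict, matching the
conventional screen. A kept pair becomes a labeled candidate only if both
drugs map into the reference universe (case-fold + trim + optional alias
map); it is positive exactly when it is a reference DDI. Duplicate unordered
pairs (possible per event term in TWOSIDES-style extracts) keep the max-PRR
record. External relabeling against tiered interaction compendia is
cumulative: requesting level "theoretical" admits well-established, probable
and theoretical tiers as positives; "well-established" admits only that tier.

## Score fusion

**PCA.** One-component PCA on the correlation matrix of the score columns
(scores live on different scales, so covariance PCA would be dominated by
the widest column). Factor loadings are reported as variable–component
correlations. An eigenvector's sign is arbitrary; the component is oriented
to correlate positively with the row mean of standardized scores so that
larger = more DDI-like. Ranking is unaffected by the orientation.

**LDA.** Two-class linear discriminant w = S_w⁻¹(μ₁ − μ₀) with equal
priors (ranking by discriminant score is prior-invariant). Stepwise mode
enters, at each step, the variable minimizing Wilks' Λ = det(W)/det(T),
admitted when its Rao partial-F

    F = (Λ_p/Λ_{p+1} − 1)(n − 2 − p),  df (1, n − 2 − p)

has p < 0.05 (the `p_enter` default; the literature names the forward-stepwise
procedure but no universal threshold exists). Forced mode fits a given
variable list directly, which is the mode to use when reproducing a published
model whose selection path is unknown. Model quality is summarized by Λ (U),
the exact two-class transform F = ((n−p−1)/p)(1−U)/U with df (p, n−p−1), and
its significance. The pipeline falls back from stepwise to forced when no
variable clears entry (small or weakly separated candidate sets).

## Evaluation

* **Enrichment factor** EF = (k/n)/(K/N) with a one-sided hypergeometric
  tail P(X ≥ k) — the exact test for a 2×2 enrichment design.
* **AUROC** by the Mann–Whitney midrank formulation (identical to the
  trapezoidal area over the tie-grouped ROC). When computed on the signal
  subset rather than the full pair universe, outputs name it
  `subset_auroc`. p-value rankings use `direction="lower_is_positive"`.
* **95% CI** by DeLong's placement-value method; a seeded stratified
  bootstrap (2,000 resamples by default) is available as a cross-check.
  The CI method behind published DDI-ranking intervals is typically
  unnamed; DeLong is this package's choice.
* **Precision@k** with deterministic tie order (score descending, then pair
  id ascending); k > n clamps to n with a warning.
* **Correlations** between measure columns are computed over a caller-chosen
  pair set, since correlations over all pairs and over the screened subset
  answer different questions.

## Synthetic universe

The generator (`ddisim.synthetic`) emulates the one regularity the method
needs: *pharmacological analogs of interacting drugs also interact*.

* A fraction `analog_rate` (default 0.5) of the n_drugs (default 300) are
  analogs: per-domain copies of a parent with feature-flip noise
  (default 0.05 per feature). The rest are independent "parents" with
  random feature sets (ADEPF 20/250, TPF 10/150, DDIPF 12/200 features per
  drug/pool; one synthetic ATC code each).
* `n_reference_ddis` (default 60) known DDIs are planted among parents. A
  fraction `class_sibling_rate` (default 0.5) additionally get a same-class
  twin pair (analog, partner) inside the reference standard — real reference
  standards cluster by class, and this is what lets a known DDI rank well
  under leave-one-out.
* The signal table (default 400 records) mixes planted novel true pairs
  (analog–partner pairs, default 25%), a small share of known reference
  pairs (default 3.5%, matching the order of known-DDI prevalence in real
  screened subsets), and random spurious pairs. True interactions draw
  PRR ~ LogNormal(log 6, 0.6) and p ~ 0.05·Beta(0.5, 8); spurious pairs
  PRR ~ LogNormal(log 1.6, 0.5) and p ~ 0.05·Beta(1.2, 2), so the
  disproportionality statistics carry a weak signal and the similarity
  scores a strong one. The returned truth flag marks planted *novel*
  interactions; known pairs are labeled downstream via the reference
  standard.

With the defaults, max-similarity scoring recovers planted novel pairs at
AUROC ≈ 0.99; with `analog_rate=0` there is no similarity structure and
recovery sits at chance. These benchmarks validate the machinery, not the
biology: synthetic features are abstract bit patterns with independent
noise, there is no correlation between domains beyond shared parentage, no
reporting biases or confounding in the signal table, and no real chemistry
(the MACCS path is exercised separately with embedded real structures).
Passing them shows the pipeline ranks what it was built to rank, not that
real pharmacovigilance data satisfies the analog assumption.

## Numerical and design notes

* Similarity matrices are validated centrally: symmetric, entries in [0, 1],
  diagonal exactly 0, unique ids. External matrices are reordered to the
  requested universe; a missing drug is an error, not an imputation.
* Matrix files are labeled TSV with 6-decimal floats; round-trips are exact
  to written precision.
* Degenerate inputs fail loudly and early: constant columns (PCA), singular
  scatter (Wilks), single-class labels (LDA, AUROC), empty stepwise
  selection (with advice to use forced mode).
* The DeLong interval is asymptotic; its empirical coverage is checked by
  simulation at n = 200 per replicate (50 positives / 150 negatives), a size
  where the normal approximation is expected to hold. At much smaller n the
  interval can undercover by a point or two, which is a known property of
  the method, not an implementation defect.
* Problem sizes in the test-bench and acceptance runs (300-drug universes,
  400-signal tables, 500-replicate coverage simulations) are chosen to make
  the statistical assertions stable at desk scale.

## Known limitations

* 3D conformer generation and shape screening are out of scope; 3D scores
  are consumed, not computed.
* No mining of raw adverse-event reports: PRR and p-values are inputs.
* Only two-class discriminants; no regularization, no cross-validated model
  selection.
* The method cannot score a pair when both drugs are outside the reference
  universe — a structural limit of similarity-to-reference ranking.
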