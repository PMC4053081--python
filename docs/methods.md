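# Methods

## The model

survnet searches a protein–protein interaction (PPI) network for *survival-
related subnetworks*: small connected gene sets whose joint expression is
associated with patient survival. The statistical engine is the Cox
proportional-hazards model. For a candidate set of p genes with (per-sample)
expression x ∈ R^p, the hazard of patient j at time t is

    λ(t | x_j) = λ0(t) · exp(βᵀ x_j),

and β is estimated by maximizing the log partial likelihood. Each candidate
subnetwork is scored by the **global Wald χ² test** of all its coefficients
jointly,

    W = β̂ᵀ Î(β̂) β̂  ~  χ²(p)  under H0: β = 0,

where Î is the observed information at the optimum; the subnetwork's P value
is the upper tail of χ²(p) at W. A global (rather than per-coefficient) test
is used because the search needs a single subnetwork-level P value for
ranking and FDR control; per-coefficient Wald P values are exposed alongside
for reporting.

### Fitting

The fitter is a damped Newton–Raphson on the ties-adjusted log partial
likelihood (Breslow by default, Efron available), with:

* convergence when the gradient max-norm falls below 1e-8, up to 50
  iterations, halving any step that would decrease the likelihood;
* covariance = inverse observed information at the optimum;
* a non-convergence *flag* (never an exception) for constant covariates,
  ill-conditioned information (1-norm condition estimate > 1e10), or
  monotone likelihood (|β̂| > 30 — with z-scored covariates a log hazard
  ratio of 30 per SD only arises under separation). Flagged fits carry
  P = 1 and are skipped by the search.

Risk-set bookkeeping (the descending-time sort and tie groups) is
precomputed once per cohort and shared across the many thousands of small
fits the search performs; inside the greedy growth each fit warm-starts
from its parent model's coefficients. The implementation was verified
against lifelines (coefficients and standard errors to ~1e-9) and against a
bounded 1-D numeric maximization of the partial likelihood; lifelines is
never on the computation path.

Breslow is the default tie handling because event times in the intended
inputs (survival months) are effectively continuous and Breslow admits the
fully vectorized prefix-sum evaluation; Efron matters only under heavy
ties and is evaluated group-by-group.

## The search

Every network protein with a matching expression row is a **seed**. Its
candidate pool is all expressed genes within shortest-path distance k of
the seed (default k = 3), where distances are measured on the *full*
network: a protein without expression data can still act as a bridge, it
just cannot become a member.

Growth is adjacency-constrained greedy forward selection:

1. start from the seed alone;
2. at each step, fit the multivariate Cox model for every pool gene
   adjacent to the current member set;
3. adopt the candidate with the smallest global Wald P — provided it
   strictly lowers the current P *and* its own coefficient is significant
   at the entry level `alpha_enter` (default 0.05);
4. stop when no candidate qualifies, the pool is exhausted, or the size cap
   (default 10 genes) is hit;
5. report the member set attaining the minimum P anywhere along the growth
   path — by construction never worse than the seed-only model.

Ties between candidates (P equal after rounding to 12 *significant*
digits) are broken by gene symbol, making the whole search deterministic.
Significant digits, not decimal places, are the right rounding here:
subnetwork P values routinely reach 1e-20 and below, where any fixed
decimal precision would collapse all candidates into a single "tie".

The per-coefficient **entry gate** in step 3 is the classical stepwise-
selection entry test (the conventional 0.05 entry significance). It is what
keeps the procedure honest under the null: without it, the "adopt anything
that lowers the global P" rule accumulates noise covariates without bound —
each step adds the best of ~10–40 chance χ²(1) contributions, so pure-noise
subnetworks routinely reach P ≈ 1e-5 and the FDR gate becomes meaningless.
With the gate, growth on noise stalls after at most a gene or two. Setting
`alpha_enter = 1` restores the ungated rule for comparison.

Per-seed minimum P values are then adjusted across seeds by
Benjamini–Hochberg, and subnetworks with adjusted P ≤ 0.001 are reported,
ranked by adjusted then raw P.

**Selection bias, stated plainly:** the reported P value of a subnetwork is
the minimum over a data-driven model search, which makes it
anti-conservative even with the entry gate; the same data choose the model
and score it. The adjusted P values order subnetworks and gate obvious
noise, but they are not calibrated error rates for the selected models —
confirmation on independent data is the appropriate follow-up. The null
simulations quantify the residual optimism: typically zero discoveries per
null cohort at FDR ≤ 0.001, with occasional runs reporting a handful when a
few genes are chance-prognostic for the shared survival vector (every
seed's P value depends on the same n patients, so per-seed P values are
strongly dependent and discovery counts are bursty rather than Poisson).

An exhaustive enumeration mode (all connected subsets containing the seed,
capped at 5 genes) exists purely as a test oracle for the greedy search.

A degrees-of-freedom guard skips candidate models with p ≥ n_events/3
covariates, preventing near-saturated fits on small cohorts; with the
default size cap of 10 it only binds when there are fewer than ~30 events.

## Preprocessing

The pipeline accepts an already-normalized expression matrix (platform
normalization such as RMA is upstream of this tool's contract) and offers
log2 transform and per-gene z-scoring (sample SD, ddof = 1). Z-scoring is
on by default: it puts every hazard ratio on a per-SD scale and
stabilizes Newton–Raphson. Probe-level matrices are collapsed to genes by
the arithmetic mean over a probe→gene map. Rows with missing values are
dropped (or mean-imputed on request); zero-variance rows are dropped with a
warning. Expression and survival tables are aligned on their shared sample
ids before any fit.

## The comparator: univariate screen + enrichment

As the conventional baseline, every gene is screened with a univariate Cox
model; genes with P < 0.05 form the survival-gene list, which is tested for
over-representation in user-supplied gene sets (GMT format) with the
one-sided hypergeometric test, BH-corrected across sets. The universe
defaults to the union of set members and selected genes, but supplying the
full assayed gene list is recommended and is what the pipeline does. No
gene-ontology service is called: collections are plain input files, so
results do not depend on an annotation-database version.

## The synthetic-data generator

The generator produces cohorts with exactly the structure the search
assumes, so recovery is a well-posed oracle for the whole stack:

* **network** — Barabási–Albert preferential attachment (default n = 300,
  mean degree 4), matching the heavy-tailed degree distributions of curated
  PPI networks; Erdős–Rényi available for contrast;
* **planted module** — a uniformly seeded random connected subgraph
  (default 5 genes) grown by random frontier expansion;
* **expression** — standard normal per gene; module genes share a latent
  factor giving pairwise correlation ρ (default 0.3, a realistic
  co-expression level for interacting proteins) while keeping standard
  normal marginals;
* **survival** — exponential event times with rate
  λ0 · exp(Σ β_g x_g) (default λ0 = 0.05/month, i.e. ~14 months median
  null survival, in the range of advanced-HCC cohorts; default β = 0.8 per
  SD for each planted gene), independent exponential censoring (default
  0.008/month) truncated at a 120-month administrative follow-up. At the
  defaults this censors ~30% of patients.

The four stages draw from independent child streams of one seed, so a
dataset is fully reproducible from its parameter record. What the generator
deliberately does **not** model: probe-level noise, batch effects,
non-proportional hazards, hub-correlated expression outside the module, or
network false edges/false negatives. Passing recovery benchmarks therefore
demonstrate correctness of the machinery under the model's own assumptions,
not performance on real microarray cohorts.

## Benchmarks the package computes about itself

Problem sizes here were chosen to make each property measurable in seconds
to a few minutes on a laptop:

* **Cox oracle equivalence** — single-covariate MLEs match a bounded 1-D
  golden-section maximization of the Breslow partial likelihood to 1e-4 on
  50 random 12-patient cohorts.
* **Wald calibration** — under a null with n = 80 and one standard-normal
  covariate (2000 replicates), rejection at nominal 0.05 stays within
  [0.03, 0.07].
* **Planted-module recovery** — on the default benchmark (300-gene
  network, 5-gene module, β = 0.8/SD, ρ = 0.3, 200 patients, ~30%
  censoring), the best-overlapping reported subnetwork attains mean F1
  well above 0.9 across repeated cohorts.
* **Null specificity** — the same benchmark with all coefficients zero
  typically yields zero discoveries at FDR ≤ 0.001 (see the selection-bias
  caveat above for the bursty exceptions).
* **Coefficient recovery** — fitting the generative model on the planted
  covariates at n = 1000, β = 0.5 recovers coefficients with mean absolute
  bias ≤ 0.1 (observed ≈ 0.04).

## Module merging and reporting

Top subnetworks often overlap; following the usual presentation of such
results, subnetworks sharing at least one gene are merged into larger
functional modules (connected components of the shared-gene relation, with
an optional Jaccard threshold for stricter merging). The bundled example —
five published top-ranked HCC prognostic subnetworks — merges into exactly
two modules: a chemokine/ECM branch joined through FBLN2 and a CAV1
cell-death branch. Results export as TSV tables plus SIF/GraphML with
per-node subnetwork-membership labels for network viewers.

## Degenerate inputs and numerical choices

* No events in the survival table → explicit error (the partial likelihood
  is undefined).
* Seeds whose own model does not converge are reported as flagged
  single-gene subnetworks with P = 1.
* η = Xβ is centered by its maximum before exponentiation, so risk-set
  sums cannot overflow.
* The stable sort on follow-up time makes every computation invariant to
  sample relabeling/reordering.
* BH adjustment is the exact step-up formula (sorted cumulative minimum),
  clipped at 1, returned in input order.

## Known limitations

* Reported P values are post-selection (see above); the FDR gate is a
  ranking device, not an error guarantee.
* Greedy growth can miss the global minimum-P subnetwork; the exhaustive
  oracle exists only at toy sizes (the problem is exponential).
* The Wald test's finite-sample behavior degrades with many covariates and
  few events; the df guard mitigates but does not remove this.
* Overlapping subnetworks from different seeds are reported as-is; merging
  is a presentation step, not a deduplication of the statistics.
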