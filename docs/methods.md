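# Methods

This note documents the models, estimators, numerical choices and known
limitations of `gcnet`, in the order the pipeline runs them.

## Synthetic cohort generator (`gcnet.synthcohort`)

**Model.** Each subject is a stable VAR(p) process over R regions,
x[n] = Σ_k A_k x[n−k] + e[n], with diagonal innovation covariance shared by
both groups (so group differences are in connectivity, never in innovation
power).  A directed band-limited influence is a *band target*: the source
region carries a damped-oscillator pole pair at radius r = exp(−π·bw/fs)
and angle 2πf₀/fs (so its −3 dB bandwidth is approximately bw), and the
target receives a lag-1 cross-coefficient equal to the coupling gain.
Regions without an oscillator follow a mildly heterogeneous AR(1) baseline
(diagonal coefficient ≈ 0.3) drawn deterministically from the seed.  Every
constructed model must pass the companion-matrix stationarity gate
(spectral radius < 1); simulation discards a 1000-sample burn-in, and all
randomness flows through explicit integer seeds.

**Cohort wiring.** Each band owns disjoint slices of the frontal,
posterior and temporo-central clusters and builds triangle motifs
src → recv, recv → sink (at half gain), src → sink.  Slow bands (theta
6 ± 3 Hz, alpha 10 ± 2 Hz) send frontal → posterior (top-down); fast bands
(beta 22 ± 4 Hz, gamma 35 ± 4 Hz) send posterior → frontal (bottom-up).
Design constraints, all fixed from population-level computations with the
analytic oracle:

- *Acyclic coupling graph.* Sources precede receivers precede sinks, so the
  companion matrix is block triangular and stationarity holds for any gain.
  Cyclic wiring through high-Q resonators is easily non-stationary.
- *Band-pure receivers.* A receiver fed by two bands couples their causal
  shares: attenuating one band then *raises* the other band's pairwise GC
  into that receiver (the causal share of the remaining input grows).
  Receivers therefore carry inflow of a single band; sinks are shared only
  between band pairs whose default attenuation matches (theta/gamma,
  alpha/beta).
- *Triangle motifs.* A lone edge gives zero local efficiency; the triangle
  makes every motif node's neighbour subgraph connected, so LE is non-zero
  and responds to the band's gain.
- *Sink noise ×4 and half-gain relay.* With unit sink noise the sink's
  spectrum is causally swamped and the relay edge's GC responds
  *non-monotonically* to gain near resonance; with 4× intrinsic sink noise
  the analytic oracle shows every motif edge responding monotonically
  (direction-correct) to attenuation.

**Defaults as study conditions.** Cohorts default to 54/55 subjects,
68 ROIs (the packaged atlas), 120 s at 500 Hz; the desk-scale demo
(`demo_cohort_config`) uses 25/25 subjects, 10 ROIs, 30 s at 250 Hz.  The
group effect is a 30% multiplicative reduction of the high group's theta
top-down and gamma bottom-up gains — a calibration choice, since no
effect sizes for real connectivity differences are available.  The coupling
gain (0.05) was chosen so spectral-GC peaks sit where the p = 30 estimator
tracks the analytic oracle within 10% of peak at T = 60 000; band-mean GC
values are consequently larger (∼0.01–0.7 nats) than typical source-space
EEG magnitudes (∼0.01), which only rescales, and does not reorder, the
group contrasts.

**What the generator does not emulate.** Volume conduction / source
leakage, non-stationarity, artifacts, 1/f broadband background, and
inter-subject topology variability (subjects differ only in innovation
realizations).  Passing recovery tests therefore demonstrates correctness
of the pipeline's inference machinery under the model's assumptions, not
robustness to real-EEG confounds.

## Analytic spectral-GC oracle

From true coefficients, S(f) = H(f) Σ H(f)ᴴ is exact.  Pairwise GC for a
pair whose ancestral closure is the pair itself comes from the exact 2×2
sub-VAR.  Otherwise the pair's 2×2 cross-spectrum is factorized with
Wilson's algorithm (spectral matrix factorization on a 1024-point uniform
grid, plus-operator iteration, convergence on the reconstruction error)
into minimum-phase H and innovation covariance, and Geweke's formula is
applied; values are interpolated onto the requested grid.  The
factorization reproduces the closed-form route to ∼1e−13 on closed pairs.

## Estimator (`gcnet.specgc`)

Bivariate AR(p) fits use ordinary least squares on lagged regressors
(Cholesky-solved normal equations; a rank-deficient Gram matrix raises a
degenerate-input error), residual covariance with denominator T − p, and
univariate AR(p) fits of each channel for the time-domain GC
ln(σ²_reduced/σ²_full).  Per subject, one lagged Gram matrix over all
channels is computed once and pair models solved from its sub-blocks —
algebraically identical to fitting pairs separately.  Defaults p = 30,
Δf = 0.1 Hz, grid inclusive of 0 and Nyquist.  Numerical conventions:

- GC values are clamped at 0 when round-off drives the log argument below
  1; the causal-power denominator is floored at 1e−12·S_jj; clamp events
  are counted in the run report.
- Band edges are inclusive at both ends (8 Hz belongs to theta *and*
  alpha, 30 Hz to beta *and* gamma); the 12–14 Hz gap is excluded.
- Pair-fit failures mark the edge missing (NaN), never zero.
- Pairwise (not conditional) GC is used throughout; common drivers
  therefore induce spurious pairwise links in both the estimator and the
  oracle, which is faithful to the method being reproduced and is why the
  oracle-agreement test compares like with like.

The Geweke integral identity — (1/π)∫₀^π GC(λ)dλ equals the time-domain GC
— is used as a consistency check whenever estimated instantaneous causality
ln(Σ₁₁Σ₂₂/det Σ) < 0.01; it holds to ≪1% on fitted models at T = 20 000.

## Sparsification (`gcnet.sparsify`)

Pooled-variance Student t per edge (Welch deliberately not used: groups are
near-balanced); one shared sequence of free label permutations across all
edges (each edge's null uses only its own statistic, so sharing shuffles is
valid and fully vectorizable); exact-test p = (1 + #{|t*| ≥ |t|})/(B + 1),
so p > 0 always.  Zero-pooled-variance edges get t = 0, p = 1.  The same
cohort defines the mask and the downstream statistics — the circularity is
inherent to the reproduced procedure and inflates downstream contrasts on
null edges; the `--no-sparsify` control pipeline is the check.

## Graph metrics (`gcnet.graphmetrics`)

Edge length is the reciprocal weight 1/A_ij (the Brain Connectivity
Toolbox convention for "stronger = closer"); directed shortest paths via
Dijkstra; disconnected pairs contribute 0 (1/∞).  LE uses the verbal
definition — mean over nodes of the GE of the neighbour subgraph (union of
in- and out-neighbours, node removed), nodes with < 2 neighbours
contributing 0 — not the cube-root weighted variant some toolboxes
implement; this is a documented divergence risk against other software.
Both metrics are validated against exhaustive simple-path enumeration on
≤ 8-node graphs.  Node significance Bonferroni-corrects within band ×
metric (factor = number of nodes); the family definition is not pooled
across bands.

## Directional indices (`gcnet.dirindex`)

The packaged 68-ROI Desikan–Killiany table assigns 22 labels to the frontal
and 18 to the posterior (parieto-occipital) cluster and excludes the 28
temporo-central labels.  The posterior membership is a reconstruction — the
nine bilateral parietal + occipital labels excluding insula, isthmus
cingulate and postcentral — shipped as an editable TSV so users can
override it.  The index denominators use subnetwork sizes N_p·N_fo,
N_f·N_po, N_pi·N_f, N_fi·N_p (the InPF size uses the number of *posterior*
regions, correcting an apparent typo in the source description).  An index
with an empty significant-node set is undefined and propagates as missing;
a combined index with exactly one defined component equals that component
(averaging over available components preserves scale).

## Group statistics (`gcnet.stats`)

Planned contrasts: classical pooled-variance two-sample t, two-tailed,
Bonferroni families of 4 (bands, for GE/LE) and 8 (band × direction, for
the combined indices).  The omnibus model delegates to statsmodels MixedLM
(subject random intercept, ML fit) and reports sequential (type-I)
likelihood-ratio chi-squares per term — main effects first, then
interactions of increasing order; a non-converging fit falls back to
per-band contrasts with a warning rather than failing the run.

## Problem sizes used in the validation suite

Consistency checks run at T = 60 000 samples (oracle agreement, order-30
vs order-40 stability) or T = 20 000 (integral identity); calibration uses
20 null cohorts with 1000 permutations; end-to-end recovery uses ten
25 + 25-subject demo cohorts with 5000 permutations.  These sizes keep the
suite to a few minutes while leaving each check's sampling error well
inside its tolerance.

## Known limitations

Pairwise GC cannot distinguish direct from indirect or common-driver
influence; the AR order is fixed rather than selected per subject; the
permutation test permutes freely rather than within matched pairs; LMM
omnibus chi-squares are sequential, so term order matters for non-balanced
data; and the synthetic generator's simplifications listed above mean real
EEG performance claims require real data.
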