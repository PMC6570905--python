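# Methods

## The circuit and the question

`autorep` models a single-copy negatively auto-regulated gene: TetR, fused to
the fluorescent protein Venus, represses its own promoter by binding as a dimer
to either of two operator sites. The inducer anhydrotetracycline (aTc) enters
the cell, binds TetR 1:1 and the complex can no longer occupy the operator.
Because the inducer removes free repressor, it tunes the *effective speed* of
operator binding and unbinding without touching the gene itself. When that
switching is slow compared with protein turnover (the non-adiabatic regime),
the on and off gene states each leave their own mark on the expression
distribution and the population splits into two coexisting phenotypes that
interconvert on the hour scale.

## Reaction scheme

States: gene occupancy A^ij (i, j ∈ {0, 1}; 1 = operator site free), free TetR
monomers n, TetR·aTc complexes (Ta) m, internal aTc i. All propensities per
minute:

| reaction | propensity | notes |
|---|---|---|
| A11→A10, A11→A01, A10→A00, A01→A00 | ½·h·n(n−1) each | dimer binding, consumes 2 TetR |
| A10→A11, A01→A11, A00→A10, A00→A01 | f·n each | competitor-assisted release, +2 TetR |
| ∅→TetR | g_ij (gene-state dependent) | transcription+translation lumped |
| TetR→∅ | k1·n | degradation + dilution |
| TetR+I→Ta | b·n·i ; reverse a·m ; Ta→∅ k2·m | sequestration |
| ∅→I (c·E_aTc), I→∅ (c·i) | membrane transport | E_aTc held constant |

The unbinding propensity f·n expresses competitor-induced dissociation: the
bound dimer is released through exchange with a free monomer, so unbinding
slows down linearly as free TetR is titrated away, while binding slows down
quadratically. The `constant` variant replaces f·n by the fixed value
f·n_ref; n_ref defaults to the mean free TetR of the repressed gene state at
300 ng/mL (≈0.5 molecules), which keeps the variant in the non-adiabatic
regime where it can display its own bimodality.

Two derived quantities: ω = f/k1 (adiabaticity) and Xeq = f/h (inverse
operator affinity). Cell division is not an explicit event; k1 is
degradation-plus-dilution (default ln2/46 min ≈ 0.015/min, a 46-minute cell
cycle).

## Solvers

* **SSA** — Gillespie's direct method (numba-compiled), bit-reproducible for a
  given seed. A second kernel accumulates the time-weighted occupancy of an
  observable (free TetR, or total fluorescent monomers = free + complexed +
  DNA-bound) after a burn-in, for stationary estimation without storing events.
* **CME** — the truncated master equation over (gene state × n × m × i) solved
  for its null vector by a sparse direct solve with a normalisation row
  (shift-inverted eigenvector as fallback). Reactions leaving the truncation
  box are disabled; if the stationary mass on the box boundary is ≥ 1e-6 the
  solver raises with the measured mass rather than returning a biased answer.
  The CME is the brute-force oracle for small systems (the Poisson limit
  h=b=c=0 is matched to total variation < 1e-8); the SSA covers the real
  parameter regime and agrees with the CME within TV 0.05 on shared cases.

## Kinetic defaults are calibration values

The source for this circuit does not print its rate-constant table, so the
shipped defaults are the package's own calibration (all overridable in
config): h = 3e-4, f = 0.01 (ω = 0.67), g11 = 6, g10 = g01 = g00 = 0.03,
k1 = k2 = 0.015, b = 1.2e-4, a = 0.01, c = 0.1, reaction volume 1 fL
(1 ng/mL aTc ≙ 1.30 molecules at 462.9 g/mol). They were chosen so that
(i) operator unbinding is comparable to protein turnover at zero inducer,
(ii) the high expression state carries ~1.4×10² fluorescent molecules, and
(iii) an inducer sweep over 300–1500 ng/mL ends in a bimodal region (1100,
1300, 1500 ng/mL) whose low-state weight grows with inducer
(≈0.14→0.25→0.33), while the Fano factor rises monotonically across the grid
(≈3→60) — the dose-response signature of emerging bimodality.

Two caveats are part of the record. First, at the bottom of the grid the model
sits in a partially repressed unimodal state of intermediate brightness rather
than a deeply repressed dim state: with this reaction scheme the per-step
repression bias h(n−1)/2f is linear in free TetR, free TetR can change by at
most the factor (k1+bE_top)/(k1+bE_bottom) < 5.2 across the grid, and deep
repression at 300 ng/mL together with a persistent bright state at
1500 ng/mL needs an order of magnitude more dynamic range. Second, the
constant-unbinding variant is not bimodal inside 300–1500 ng/mL at the shared
defaults; its bimodal window sits at 5000–8000 ng/mL, where its high-state
weight grows with inducer (≈0.59→0.70) — the mirror image of the
concentration-dependent trend, which is the property of interest. Mode
statistics of model distributions are computed on log10-rebinned mass
(`detect_modes_log`), the scale on which fluorescence distributions are
inspected; mode weights use a minimum-valley split with the valley bin
assigned to the left mode, and plateau maxima resolve to their leftmost bin.

## Trajectory analysis (two-state HMM)

Single-cell log10-fluorescence series (5-minute sampling) are modelled by a
two-state hidden Markov chain with Gaussian emissions. Fitting is Baum–Welch
over all trajectories jointly (hmmlearn backend): initialisation by 2-means
clustering of pooled emissions plus a sticky transition matrix
[[0.9, 0.1], [0.1, 0.9]]; 10 restarts with jittered means; convergence at
relative log-likelihood change < 1e-8 or 500 iterations; the log-likelihood
history is asserted non-decreasing; restarts in which a state captures fewer
than 2 frames are discarded and an error is raised if all restarts degenerate.
States are relabelled so μ_low < μ_high. Division frames are carried through
as annotations only; lineages are tracked across divisions, so divisions are
not segmentation breakpoints.

Viterbi decoding yields dwell segments; the first and last segment of every
trajectory are censoring-flagged. The mean residence time of a state is total
observed time in the state divided by the number of observed exits; the
exclude-censored and include-censored conventions bracket the estimate (the
bracket stands in for an exact finite-length correction, and is labelled as
such in output). A never-exiting state is reported as a lower bound. State
weights are reported both as the stationary distribution of the fitted
transition matrix and as decoded frame occupancy — these differ in finite
samples and the decoded occupancy also carries misclassification bias when
emissions overlap. Fit quality is a quantile–quantile Pearson correlation
between pooled data intensities and model-simulated surrogates matched in
trajectory number and length.

With the reference parameters (peak centres 2.690/2.933, variances
0.085/0.080, self-transitions 0.977/0.963) the emissions overlap strongly
(mean gap 0.24 at sd ≈ 0.29): a forward–backward oracle puts per-frame
decoding accuracy at ≈0.90 (Viterbi ≈0.88), and the pooled emission histogram
is unimodal even though two states are present — temporal persistence, not
histogram shape, is what identifies the states. A consequence verified
numerically: a fully free two-Gaussian mixture fit on pooled draws cannot
recover the state weights (its likelihood is nearly flat along the
weight/mean trade-off and the weight estimate collapses toward 0.5), so the
mixture-weight recovery experiment holds the component densities at their
known values and re-estimates only the mixing weight by EM.

## Synthetic data

The trajectory generator draws hidden state paths from the reference
transition matrix, Gaussian log10 emissions, lengths uniform on 40–60 frames
(163 trajectories ≈ 8150 pooled points), and division marks at uniform
40–60 min intervals; ground-truth paths are retained so every estimator can be
scored. The snapshot generator draws per-cell intensities from a two-component
log-normal mixture with an explicit per-concentration schedule (weight and
component positions); the default schedule shifts a single peak upward with
inducer and makes the top two levels bimodal with the low weight rising, and
its linear-scale Fano factor increases monotonically across the grid.
Generation configs enforce the 1900 ng/mL cytotoxicity bound; the reaction
network itself may be simulated at any inducer level. What the generator does
not emulate: lineage structure and partitioning noise at division,
photobleaching, segmentation errors, and any inducer dependence of emission
variance — so passing recovery tests demonstrate estimator correctness under
the stated model, not robustness to those artefacts. The microscope noise CV
for SSA-derived fluorescence defaults to 0.05 (a placeholder swept in tests).

## Numerical choices and problem sizes

Recovery experiments use 20 seeded replicates of the full study-size data set;
sweep estimates use 4 replicate SSA runs of 60 000 simulated minutes (3000 min
burn-in) per inducer level, and the dichotomy/trend checks use 2–4 replicates
of 40 000–60 000 min — sizes at which the asserted differences (mode-weight
steps of ~0.1) exceed the replicate-to-replicate spread (~0.02). Per-replicate
seeds derive from one root seed via `numpy.random.SeedSequence`. Fluorescence
totals are floored at one molecule before taking logs. Degenerate inputs
(empty distributions, negative counts, non-uniform frame spacing, toxic
inducer levels in generation configs) raise errors rather than propagating.

## Known limitations

* The dim→bright→bimodal dose-response of the real circuit is reproduced only
  from its middle upward (see calibration caveat above).
* Residence-time brackets are a censoring-convention heuristic, not an exact
  finite-length likelihood correction.
* The CME solver is exponential in the number of bounded species; it is an
  oracle for small systems, not a production solver for the full model.
* mRNA dynamics, spatial effects and explicit division events are out of
  scope; k1 lumps dilution.
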