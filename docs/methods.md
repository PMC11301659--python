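# Methods

## Model

A track is an ordered sequence of 2-D positions $X_0,\dots,X_T$ at
regular, implicit time steps (irregular sampling is out of scope). Two
angular views of the increments define two model classes:

* **r-HMM** (relative): emissions are step lengths $S_t$ and turning
  angles $\vartheta_t$ between successive increments, $t=2,\dots,T$ — a
  piecewise-stationary correlated random walk. The first step has no
  turning angle.
* **a-HMM** (absolute): emissions are $S_t$ and absolute angles
  $\alpha_t$ of each increment measured counterclockwise from the x-axis,
  $t=1,\dots,T$ — a piecewise-stationary biased random walk. After
  per-track PCA the x-axis is the first principal component, the
  direction of greatest movement variability, which is why it is the
  natural reference.

Conditional on an $N$-state hidden Markov chain, $S_t$ is Gamma
distributed with state-specific mean $\mu_\Gamma$ and standard deviation
$\sigma_\Gamma$ (converted internally to shape $(\mu/\sigma)^2$ and scale
$\sigma^2/\mu$), and the angle is von Mises with state-specific mean
direction $\mu \in (-\pi,\pi]$ and concentration $\kappa \ge 0$; a
wrapped Cauchy family (concentration $\rho \in [0,1)$) is available as a
robustness alternative. Angles are kept in $(-\pi,\pi]$ with $+\pi$ at
the branch cut. Zero-length increments have undefined direction; the
affected angles are marked missing and their likelihood terms contribute
a factor of one rather than raising an error, matching the convention of
established movement-HMM software.

The initial state distribution is tied to the stationary distribution of
the transition matrix $\Gamma$ rather than estimated freely, giving
$p = 4N + N(N-1)$ free parameters. The BIC sample size is the number of
steps $T$ in both modes (the undefined first turning angle does not
reduce it); a single consistent definition keeps BIC comparable between
the r-HMM and a-HMM fitted to the same track.

## The absolutize transformation

Rebuilding a track with headings $\psi_t = \psi_{t-1} + \alpha_t$
($\psi_0 = 0$) and the original step lengths makes the original absolute
angles reappear as the turning angles of the new track, so a
turning-angle engine can fit the a-HMM unchanged. A dummy first
increment along the reference axis is prepended so that $\alpha_1$ also
becomes a defined turning angle; its length defaults to the mean observed
step and is excluded from the step-length likelihood, so it contributes
no information. With the initial distribution stationary, the
relative-mode likelihood of the transformed track (dummy step excluded)
equals the native absolute-mode likelihood exactly; the test suite
verifies this to 1e-8 on random parameter/track pairs, and the native
absolute mode is the default fitting path.

## Estimation

The likelihood is computed by the forward recursion with per-step
scaling (each time slice rescaled by its maximum log emission before
exponentiation). Maximization is quasi-Newton (L-BFGS-B) over
unconstrained working parameters: angle means unconstrained and wrapped,
$\log\kappa$ (or logit $\rho$), $\log\mu_\Gamma$, $\log\sigma_\Gamma$,
and multinomial logits for each transition-matrix row with the diagonal
as reference category. Gradients are analytic via the Fisher identity —
the score of the marginal likelihood equals the posterior expectation of
the complete-data score — using one forward–backward pass per
evaluation, including the exact correction term for the dependence of
the stationary initial distribution on $\Gamma$ (a linear solve against
the fundamental matrix $I - \Gamma + \mathbf{1}\delta$). Gradient
correctness is checked against finite differences in the test suite.
Convergence tolerance is 1e-8 on the relative change of the log
likelihood; iteration cap 1000.

Each state count is fitted from a deterministic grid of starting values
(16 combinations for one state, 256 for two and three; the published
one-state $\sigma_\Gamma$ grid value 5 is used as printed even though
multi-state grids use 0.5). Transition matrices start at diagonal 0.8
with uniform off-diagonal mass — a mild persistence prior, configurable.
Four-state fits, needed only as the overfitting candidate in the
simulation study, use an analogous extension of the three-state grid. A
start is discarded as warning-equivalent when the optimizer reports
failure, the likelihood is non-finite, or the estimate sits on a
boundary ($\kappa > 10^3$, $\mu_\Gamma$ or $\sigma_\Gamma < 10^{-6}$);
the best surviving start wins. Fitted states are relabelled by
increasing step mean (then angle mean) for reporting stability, and
Viterbi ties are broken toward the lower state index.

## State-count selection

Candidate state counts 1..max (default 3, hard cap 4) are fitted
independently; fits containing a degenerate state — a state decoded for
exactly one time step (optionally also zero) — are discarded, and the
smallest-BIC survivor is chosen, ties within 1e-6 going to fewer states.
`compare_modes` runs this in both angular modes on the same track and
reports the BIC difference (absolute minus relative; negative favours
the a-HMM), and `paired_sign_test` summarizes a cohort of such
differences with a two-sided Wilcoxon signed-rank test.

## Simulator and the recovery study

`simulate_track` draws the hidden chain from its stationary
distribution, then state-conditional Gamma steps and circular angles,
applied as turning angles (heading accumulates; the first heading is
uniform) or absolute angles (heading equals the drawn angle). The
recovery study simulates 10 tracks per true state count (1–3) of T=500
steps, fits 1–4 states per track, and tabulates the AIC- and BIC-chosen
counts over the same degenerate-filtered candidates.

The generating defaults are three well-separated movement modes chosen
to emulate slow near-diffusive motion versus fast filament-directed
transport, in arbitrary length units per time step:

| state  | step mean | step sd | $\kappa$ |
|--------|-----------|---------|----------|
| slow   | 0.05      | 0.05    | 0.3      |
| medium | 0.30      | 0.12    | 2        |
| fast   | 1.00      | 0.30    | 8        |

with all angle means 0, transition diagonal 0.9 (mean dwell 10 steps).
Separation is deliberately strong in both channels — step means at least
2.5 standard deviations apart and concentrations an order of magnitude
apart — because the study's purpose is to compare *selection criteria*
under a correctly specified, identifiable model, not to probe weak
separation. The one-state setting uses the medium state, the two-state
setting slow+fast. The study default thins each starting grid to a
deterministic 16-point subset (evenly strided through the grid's product
order); on stuck instances the full 256-point grid was verified to find
the same optimum, so the thinning changes cost, not conclusions.

## What the simulator does and does not emulate

Simulated tracks are exactly model-generated: stationary within states,
exact Gamma/von Mises emissions, geometric dwell times, no localization
noise, no zero-length steps, no irregular sampling, and 2-D from the
start (no PCA step). Passing recovery and selection tests therefore
demonstrates the estimator and selection machinery, not robustness to
measurement error, model misspecification, or short-track small-sample
behaviour in real recordings.

## Numerical choices and degenerate inputs

* Scaled forward recursion in linear space after row-max shifting;
  log-sum-exp only in the brute-force test oracles.
* Working-parameter magnitudes capped at 300 to keep exponentials
  finite; evaluations outside return $+\infty$.
* Stationary distributions solved from $\delta(I-\Gamma)=0$ with the
  normalization row substituted; a least-squares fallback covers
  near-reducible chains.
* Tracks must have at least 2 positions (absolute mode) or 3 (relative
  mode); all-identical positions make PCA fail loudly.
* All simulation randomness flows through one seeded generator per
  batch; fitting itself is deterministic given track and configuration.

## Known limitations

* No covariate-dependent transition probabilities, random effects, or
  continuous-time variants; no 3-D angular emissions (3-D tracks are
  reduced by per-track PCA, which the package reports via the explained
  variance fraction).
* Dwell times are reported both as Viterbi-run means (default) and as
  the geometric $1/(1-\Gamma_{ii})$; the two agree only when decoding is
  reliable.
* The degenerate-state rule keeps never-visited states by default
  (`include_zero=False`); BIC's parameter penalty handles those.
* Step lengths of exactly zero are treated as missing observations, not
  modelled (no zero-inflation).
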