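# Methods

## Generative model

One cell's S phase over an origin triplet `x1 < x2 < x3` is generated as
follows. Each origin is licenced independently with probability `q_i`;
licenced origins receive potential firing times `t_i ~ N(mu_i, sigma_i^2)`.
Forks move bidirectionally at a common constant speed, so time is measured
in replicated base pairs (rbp): 1 rbp is the time a fork needs to copy 1 bp.
The replication front from a set of licenced origins reaches position `y` at
`min_j (t_j + |y - x_j|)`; an origin is *obscured* if that front reaches its
position strictly before (ties count as obscured, a probability-zero event)
its own firing time, and *realized* (fork-producing) otherwise. Because an
obscured intermediate origin never delays the front, this single formula
also accounts for fork blocking by intermediate origins. Obscuring is
attributed to the realized origin whose fork arrives first. Adjacent
realized origins `i < j` terminate by passive collision at
`x_ij = (x_i + x_j + t_j - t_i) / 2`; in the no-obscuring regime `x_ij` is
Gaussian with mean `(x_i + x_j + mu_j - mu_i)/2` and s.d.
`sqrt(sigma_i^2 + sigma_j^2)/2`.

The single-cell profile is 1 where a rightward-moving fork passed (0
otherwise); under the default strand convention rightward forks produce
forward-strand Okazaki fragments, and a flag flips the convention. The
population profile `F_ave` is the mean of `M` single-cell profiles; its
values are multiples of `1/M`, it is non-increasing strictly between
origins, and its discontinuity at an origin equals that origin's
realized-firing fraction.

**Prohibited states.** Cells with no realized origin, or in which a single
end origin replicates the whole region (double overrun), have constant
profiles indistinguishable from background and are excluded by per-cell
rejection — the generative model is conditioned on admissible states. A
guard (`max_resample`, default 1000 rounds) raises an error in degenerate
regimes such as `q = (1, 0, 0)` where admissible states are essentially
unreachable.

**Discretisation.** Boxes are half-open `[start, start + s_box)` windows of
`s_box = 50` bp tiling `[x1, x3)`; a single-cell profile is evaluated at box
midpoints, so breakpoint localisation error is at most `s_box / 2`. This was
chosen over exact fractional-overlap boxing for speed; at 50 bp the
difference is far below the measurement noise.

## Observation model

Boxed strand counts are modelled as
`X^f = ((1-b) F + 0.5 b) * eps`, `X^r = ((1-b)(1-F) + 0.5 b) * eps'` with
independent `eps = exp(N(-1/(2 tau), 1/tau))` per box and strand. The
shifted log-mean makes `E[eps] = 1`, matching the data normalization
(forward plus reverse counts average to 1 over the region). Expected
intensities satisfy `m_f + m_r = 1` exactly per box. One `(b, tau)` pair is
shared by both strands. Independence across boxes is assumed; residual
autocorrelation is a diagnostic, not part of the model.

Zero counts (possible in real data) are floored at half the smallest
positive normalized count in the region before logs are taken; the
log-normal density is undefined at zero and the flooring rule is our
declared choice.

## Preprocessing

Per-strand coverage is corrected by the chromosome-wide strand bias
`b_chr = sum(forward) / sum(reverse)`, boxed at 50 bp from `x1`, and
normalized by the mean per-bp bias-corrected count `n` over the half-open
window `[O1, O3)` (or `[O1, O4)` when overlapping triplets are compared).
With the half-open window, `mean(c_f' + c_r') = 1` holds exactly whenever
the region length is a whole number of boxes; the trailing partial box is
dropped. OF fragments are length-filtered to 120–200 bp. All coordinates
are 0-based, intervals half-open; alignment and MAPQ > 10 filtering are
upstream contracts.

## Inference

The posterior is over `(mu, sigma, q, b, tau)` and the latent population of
`M` cells (licenced sets and firing times). The likelihood uses the
empirical `F_ave` of the latent cells, cached as per-box integer tallies and
updated incrementally. One sweep comprises:

1. **Firing-time random walks** for a fraction (default 10%) of cells, with
   the likelihood change evaluated only on boxes whose profile bit flipped.
2. **Reversible-jump licencing toggles**: death removes a cell's licencing
   and firing time for one origin; birth re-adds them with the time drawn
   from its conditional prior `N(mu_i, sigma_i^2)`, so the acceptance ratio
   is the likelihood ratio times `q/(1-q)` (unit Jacobian). Proposals that
   create prohibited cells are rejected.
3. **Conjugate updates**: `mu_i` (Gaussian posterior), `sigma_i^2` (inverse
   gamma), and `q_i` — see below.
4. **Group moves** that translate `(mu_i, all licenced t_i)` jointly and
   scale `(sigma_i, centred t_i)` jointly. These are essential: without
   them the `sigma` draw is pinned to the current latent-time dispersion,
   which itself moves only diffusively, and chains show R-hat ≈ 3 on
   `sigma`. For the scale move with factor `c` the latent-prior and Jacobian
   terms collapse to `c^(-2 a0) * exp(-(b0/sigma^2)(c^-2 - 1))`.
5. **Noise parameters**: Metropolis walks on `log tau` (Gamma(0.01, 0.01)
   prior) and `logit b` (uniform prior).

Proposal scales adapt toward 30% acceptance during burn-in only
(Robbins–Monro, gain `1/sqrt(block)`), then freeze, so retained samples come
from the exact invariant distribution.

**Priors.** `sigma^2 ~ InvGamma(0.01, 0.01)` (draws clamped to
`[1e-8, 1e10]` to avoid overflow when an origin has no licenced cells),
`q ~ Beta(1, 1)`, `b ~ Uniform(0, 1)`, `tau ~ Gamma(0.01, 0.01)`. For `mu`
we use a proper `N(0, (N1+N2)^2)` prior rather than an improper flat one:
the likelihood constrains only firing-time differences, and when the middle
origin is never realized the direction "`mu_2` later, `mu_1 + mu_3`
earlier" leaves the likelihood constant (licenced-but-always-obscured cells
have no data consequence), so a flat prior yields an improper posterior. A
fork traverses the whole region in `N1 + N2` rbp, so offsets beyond that
scale are unidentifiable and the prior is effectively uninformative wherever
the data speak. Reported `mu` samples are recentred to `sum(mu) = 0`, the
conventional normalization.

**Admissibility correction for `q`.** Because the latent cells are
conditioned on admissibility, the exact conditional for `q_i` is the
conjugate Beta form times `Z(q)^(-M)` with `Z = P(admissible)`. Ignoring
this factor biases `q` upward by several posterior s.d. at `M = 512`
(prohibited states are licencing-poor, so conditioning inflates latent
licenced fractions). We use the licencing-only closed form
`Z = 1 - (1 - q2)(1 - q1 q3)`, linear in each `q_i`, and draw the 1-D tilted
conditional exactly by inverse-CDF on a 4096-point grid.
Obscuring-induced prohibitions (double overruns) are neglected in `Z`; they
are rare and their omission is shared with the `mu`/`sigma` updates.

**Scale.** The desk-scale default is `M = 512` latent cells with 3 chains of
20 000 sweeps (5 000 burn-in); production analyses should use `M = 4992`
(smaller `M` leaves visible `1/M` discretization in the reconstructed
profile) and longer chains — a warning is logged. Convergence is declared at
R-hat < 1.1 on all scalar parameters; non-convergence is a warning, never a
silent failure.

## Posterior summaries

Licencing and obscuring fractions are summarized by medians and
lower/upper quartiles (midpoint quantile convention), since these posteriors
are often strongly skewed; significance of obscuring against zero uses a
Gaussian approximation fitted to the posterior mean and variance. Collision
and firing-difference densities pool a per-sample subsample of latent cells
(default 32 per retained draw); firing differences `t_j - t_i` are
conditioned on both origins being licenced and annotated with the obscuring
thresholds `±N_ij`. Firing-order probabilities `pi(t_{i+1} < t_i) =
Phi(-(mu_{i+1} - mu_i)/sqrt(sigma_i^2 + sigma_{i+1}^2))` are reported both
as a plug-in at posterior means and averaged over posterior samples; the two
differ for skewed posteriors and both are printed. Replication-time
profiles simulate `K` cells at the posterior-median parameters, take
`T(x) = min_i (t_i + |x - x_i|)` over realized origins per cell, and report
per-box median and 5th/95th percentiles in minutes,
`(T - min_i mu_i)/(1000 nu) + anchor` for fork velocity `nu` in kb/min.

## Synthetic scenarios and what they do (not) show

`okfire.synthetic` fixes the canonical study conditions: a triplet at
200/1500/2800 bp and three firing regimes (staggered strong origins; a 30%
licenced middle origin; a middle origin obscured from the left in ~68% of
cells), with noise `b = 0.1`, `tau = 50` (log-noise s.d. ≈ 0.14, i.e. ~14%
multiplicative noise per 50-bp box, representative of deep OF-seq
coverage). The generator emulates Bernoulli licencing, Gaussian firing,
equal-speed forks, passive collision, obscuring, log-normal noise and the
uniform background — it does not emulate mappability gaps, copy-number
variation, fork stalling, variable fork speed, incoming forks from outside
the triplet, or autocorrelated noise, so green tests certify the method's
statistical correctness under the stated model, not robustness to every
artefact of real libraries.

Two known limitations follow from the model itself. First, the
licencing/obscuring decomposition is only weakly identified when an origin
is strongly obscured: configurations along the ridge
`q * (1 - P_obscured) = const` differ only through the tail shape of the
truncated collision density, so at desk-scale noise the posterior spreads
along that ridge (this mirrors the behaviour of real triplets where one
region cannot distinguish the two mechanisms, and is why quartiles rather
than point estimates are reported). Second, at noise precision much below
`tau ≈ 50` the broad-`sigma`/high-`q` explanation becomes posterior-dominant
over the true tight-`sigma`/partial-`q` one; informative data (deep
coverage, several boxes per transition) are a prerequisite for a sharp
decomposition.

## Numerical choices

Rejection resampling implements the admissibility conditioning exactly.
Box values are midpoint evaluations (above). The `tau` initial value comes
from a method of moments on adjacent-box log-count differences
(`Var(diff log c) ≈ 2/tau`); `sigma` initialises at `0.15 max(N1, N2)`, `q`
at 0.9, `b` at 0.05, `mu` at 0. Chain seeds derive from one user seed via
`numpy.random.SeedSequence`, and every stochastic entry point takes an
explicit seed or generator, so runs are bit-reproducible. Sample containers
are compressed `.npz`; all tabular I/O is TSV/bedGraph/BED via pandas.
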