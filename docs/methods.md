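# Methods

## Model overview

`coldsim` couples a discrete stochastic agent layer to a continuous
reaction–diffusion field on a common 2-D toroidal lattice.

**Agents.** Tumour cells carry a heritable basal PD-L1 expression
`E_basal` (TPM) assigned at t = 0 by sampling with replacement from the
expression cohort; daughters inherit `E_basal` exactly (clonal
transmission). CTLs carry only a position. Each lattice site holds at most
one tumour cell and at most one CTL; co-occupation of a site by one of each
is what defines an engagement.

**Engagement.** When a CTL occupies a tumour cell's site, the outcome is
resolved immediately: the tumour cell evades with logistic probability
`1/(1+exp(−k(E_total−x0)))` and is otherwise removed. Every engagement
deposits one secretion quantum (S = 10 normalised units) of IFN-γ at that
site, applied at the next field update — the agent phase of step *t* forces
the field of step *t + 1*, the standard operator-splitting convention for
hybrid models. Secretion is unconditional on outcome, since it represents
cytokine release during the synapse rather than a consequence of the kill.
On an evaded engagement the CTL dies with probability `p_exhaust`
(see *Calibration* below). Each CTL resolves at most one engagement per
step; no CTL recruitment is modelled, so the CTL count is non-increasing.

**Movement.** CTLs move on the Moore neighbourhood: uniformly over the 8
neighbours plus stay-still, except that when a tumour cell lies within
Chebyshev distance 3 *and* a cytokine field exists, the step is
chemotactically biased with probability 0.5 toward the neighbour with
maximal local IFN-γ (ties uniform). A move blocked by another CTL becomes a
stay. Moving onto a tumour-occupied site is allowed and triggers the
engagement. Static (field-free) arms therefore reduce to a pure random
walk.

**Proliferation and seeding.** Each tumour cell attempts division with
probability 0.02 per step; the daughter goes to a uniformly chosen
tumour-free Moore neighbour. A fully crowded neighbourhood fails the
division (contact inhibition — the carrying-capacity feedback), except that
with probability 0.001 the daughter is instead placed at a uniformly chosen
tumour-free site anywhere on the grid ("distant seeding", the model's
metastasis proxy; the event, the founding clone's effective expression at
shedding, and the lineage are logged).

**Cytokine field.** C(x, y, t) evolves by
`∂C/∂t = D∇²C + S − δC` with D = 0.05 grid²/step and δ = 0.1/step,
discretised forward-time centred-space with a 5-point Laplacian and
periodic wrap. Three analytic bounds gate a run: the diffusion CFL ratio
`DΔt/Δx² ≤ 1/4`, the decay non-overshoot bound `δΔt < 1`, and the joint
amplitude bound `Δt(4D/Δx² + δ/2) ≤ 1` (0.25 at baseline). Amplitude
stability does not by itself guarantee positivity: the explicit update is
sign-preserving when `4DΔt + δΔt ≤ 1`, which the baseline satisfies with
margin; the solver additionally hard-fails on any negative concentration.
On the torus the scheme obeys the exact mass balance
`total(t+1) = (1−δΔt)·total(t) + Δt·Σ(sources)`, used as a regression
oracle. At 10 µm grid spacing the per-step RMS diffusion length is
`sqrt(2DΔt)` ≈ 3.2 µm, which fixes the time step at roughly 5–6 minutes of
biological time (500 steps ≈ 50 h at 6 min/step).

**Induction coupling.** Each step, every tumour cell's induced expression
is recomputed from its own site's concentration via the Hill function
`P_max·Cⁿ/(Kⁿ+Cⁿ)` (P_max = 15 TPM, K = 5, n = 2), and
`E_total = E_basal + E_induced`. Induction is memoryless — no hysteresis —
so adaptive resistance is fully reversible when the field decays.

**Step order.** (1) field advance with last step's sources (adaptive arms);
(2) induction update; (3) tumour phase over a shuffled agent list;
(4) immune phase over a shuffled agent list; (5) recording every 10 steps.
A replicate ends at tumour extinction, carrying capacity (L·W cells), or
the step horizon (500 for static-phase arms; knockout comparisons are also
reported at step 500).

## The expression cohort

The synthetic generator emulates a primary prostate-tumour *CD274* TPM
distribution through its published quantile anchors (min 0.07, Q1 0.91,
median 1.48, Q3 2.14, p90 3.21, p95 4.10, p99 7.06, max 18.50) plus two
tail anchors pinning 9/554 of the mass above 6 TPM and 2/554 above 9 TPM.
The quantile function interpolates the anchors piecewise-linearly in
log(TPM) — preserving positivity and the heavy right tail — and samples by
inverse transform; linear-space interpolation is an exposed option.
Descriptive statistics use the type-7 (linear between order statistics)
quantile convention, recorded in the output, and Fisher-adjusted sample
skewness.

What the generator does *not* emulate: the anchors describe inter-patient
variation, used here as a proxy for intra-tumoural heterogeneity, so the
absolute frequency of rare high expressors inside one simulated tumour
follows the cohort frequency (~0.4% above 9 TPM) rather than any measured
single-cell distribution. A finite 554-sample draw also jitters the
realised median/max below or above the anchors (the worked example's
median 1.44, max 15.2). Passing tests therefore demonstrate internal
consistency of the sampling machinery, not single-cell realism.

## Parameters

| Parameter | Default | Units | Role |
|---|---|---|---|
| grid L×W | 50×50 | sites | tissue patch (~0.25 mm² at 10 µm/site) |
| n_tumour0 / n_immune0 | 500 / 250 | cells | initial densities 0.20 / 0.10 |
| p_prolif | 0.02 | /step | division attempt rate |
| p_seed | 0.001 | /step | distant seeding on contact inhibition |
| x0, k | 3.0 TPM, 1.0 /TPM | — | evasion logistic midpoint/steepness |
| P_max, K, n | 15 TPM, 5, 2 | — | Hill induction ceiling/half-sat/cooperativity |
| D, δ, S | 0.05, 0.1, 10 | grid²/step, /step, units | field dynamics |
| p_bias | 0.5 | — | chemotactic bias when tumour within radius 3 |
| p_exhaust | 0.3 | — | CTL death per evaded engagement (calibrated) |
| max_steps | 500 | steps | horizon (≈50 h at 6 min/step) |

## Design choices where the design was open

**Initial placement.** Tumour cells are seeded uniformly without collision
inside a central compact region of exactly ⌈L·W/4⌉ sites (25×25 at
baseline), CTLs uniformly over the remaining sites. This produces a
coherent tumour mass with an invasive periphery where engagements, IFN-γ
hotspots and sanctuaries localise. The layout is configurable; a scattered
initialisation grows faster (more frontier) and changes saturation times.

**Within-step ordering.** Agents shuffle within type each step; the whole
tumour phase precedes the whole immune phase. Movement conflicts resolve
sequentially in shuffled order; there is no simultaneous-move arbitration.

**Seed scheme.** The replicate seed is SHA-256 of
`"{base_seed}:{arm_id}:{replicate_index}"` reduced mod 2³¹, feeding numpy's
default generator. The *contract* is documented so independent
implementations can agree on identity, though not on the resulting stream.

**Sanctuary windows.** The three detection criteria all use the same 3×3
Moore window: local mean effective PD-L1 over tumour-occupied sites, local
CTL count/9 versus the snapshot-mean CTL density, and trailing 50-step
survival fraction (survived/faced engagements). Sites with zero engagements
in the window get survival 0 and are excluded from the survival-percentile
pool, which would otherwise degenerate to a percentile of zeros. Components
are 8-connected with toroidal wrap; the minimum area is 4 sites. Because
both expression thresholds are snapshot percentiles, detection is invariant
under positive affine rescaling of the expression field.

**Seeding colonies.** A colony is "established" when a distant-seeded
lineage has ≥ 5 living descendants at simulation end and was founded in a
different grid quadrant (axes split at L/2, W/2) than the centroid of the
non-seeded population at seeding time. The founder's phenotype is the
effective expression of the shedding clone at the seeding step. The
5-descendant rule is this package's operationalisation of "established".

**Clock.** `minutes_per_step` defaults to 5.5 (the diffusion-calibration
midpoint); hour conversions that quote 50 h / 500 steps use 6.0. Both are
exposed.

## Calibration of CTL attrition (`p_exhaust`)

The model needs some CTL attrition: PD-1 ligation on an evaded engagement
plausibly drives CTL exhaustion and death, and without any attrition an
immortal CTL population suppresses even highly evasive tumours to far below
carrying capacity, which is inconsistent with the validation panel the
model is built around (static-engine tumours persisting near capacity while
the null-evasion control is eradicated). `p_exhaust` is the only free
behavioural parameter; all others are fixed a priori.

We calibrated it against the validation/knockout panel as a whole.
Sweeping p_exhaust over [0, 1] shows: null-evasion clearance is independent
of it (no evasions, hence no attrition); the static arm's final burden
rises monotonically with it (≈1350 cells at 0 up to ≈2300 at 1); and the
knockout ordering — induction knockout below static below adaptive, with
the induction knockout's characteristically large between-replicate
variance — is sharpest near 0.3. The default 0.3 reproduces the knockout
panel (induction-KO mean ≈1750 ± 200, diffusion-KO within a few percent of
the adaptive arm) while keeping the adaptive arm near capacity.

One consequence is documented as a limitation: with meaningful attrition
the CTL population decays by roughly step 300 at baseline densities, so
IFN-γ-driven phenomena that require *ongoing* engagement at late times —
large late-time immunoediting ratios of effective expression, and
sanctuaries persisting to step 400+ — appear transiently (sanctuaries
emerge between steps ~60 and ~250 with ≈2× PD-L1 enrichment, then fade as
engagements cease). Conversely, setting p_exhaust ≲ 0.003 preserves
late-time sanctuaries and effective-expression enrichment but collapses the
static arm's burden and inflates its basal editing ratio. No single
attrition value produces both regimes; this is an intrinsic trade-off of
the engagement-driven secretion design, not a numerical artefact.

## Problem sizes in tests and the acceptance script

The test suite runs its quantitative panels at 20 replicates per arm and
the grid-scale protocol at 10 replicates per size; the null-evasion
clearance check uses the full 50 replicates (those runs are cheap because
the population shrinks). The acceptance script uses the same sizes and
finishes in about a minute on one CPU. Per-replicate results are
deterministic given the seed scheme, so all reported aggregates are exactly
reproducible.

## Known limitations

* Two cell types only: no Tregs/MDSCs/M2 macrophages, TGF-β, recruitment,
  or CTL exhaustion-state dynamics beyond the single attrition probability;
  2-D lattice, toroidal boundaries only.
* The TPM→evasion logistic is phenomenological; (x0, k) are calibration
  targets, not measurements, and are first-class sweep axes.
* Field units are normalised (one unit ≈ 0.5–1.0 ng/mL is a documentation
  note only, never used quantitatively).
* The clock is calibrated to cytokine/migration timescales; proliferation
  is correspondingly ~an order of magnitude faster than real prostate cell
  cycles, so simulated seeding rates are not clinical metastasis rates.
* Inter-patient expression variance proxies intra-tumoural heterogeneity
  (see *The expression cohort*).
* Endgame clearance in the null-evasion control is random-walk limited:
  median extinction near step 275, and roughly one replicate in a few
  hundred carries a <10-cell remnant past the 500-step horizon before
  dying.
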