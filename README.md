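# coldsim

Hybrid discrete–continuum simulation of PD-L1 / IFN-γ mediated immune
evasion in immunologically "cold" tumours.

Prostate cancer evades cytotoxic T lymphocytes (CTLs) even though bulk
*CD274* (PD-L1) expression is low and non-prognostic. `coldsim` implements
a mechanistic model of how that can happen through two coupled layers:

* a **static engine** — rare tumour clones with intrinsically high basal
  PD-L1, drawn from a heavy-tailed expression distribution, survive initial
  immune attack (Darwinian immunoediting); and
* an **adaptive engine** — CTL-secreted IFN-γ diffuses locally and induces
  PD-L1 on nearby tumour cells, a reversible phenotypic feedback that
  organises resistance into spatial *protective sanctuaries*.

The package is aimed at computational-oncology researchers who want a
reproducible, scriptable testbed for checkpoint-evasion dynamics: every
replicate is bit-reproducible from `(base_seed, arm_id, replicate_index)`.

## Model

Tumour cells and CTLs live on an L×W toroidal lattice (baseline 50×50, one
tumour plus one CTL allowed per site). A tumour cell with total PD-L1
expression *E* (TPM) evades an engaging CTL with logistic probability

    p_evasion(E) = 1 / (1 + exp[−k (E − x₀)]),    x₀ = 3.0 TPM, k = 1.0,

and is killed with probability `1 − p_evasion`. On an evaded engagement the
CTL itself dies with probability `p_exhaust` (PD-1 ligation driving
exhaustion/apoptosis; calibrated default 0.3). Each engagement deposits
S = 10 units of IFN-γ into a concentration field C(x, y, t) obeying

    ∂C/∂t = D ∇²C + S(x, t) − δC,    D = 0.05 grid²/step, δ = 0.1/step,

solved by an explicit FTCS scheme on the torus (combined stability factor
Δt·(4D/Δx² + δ/2) = 0.25 at baseline). Local concentration feeds back into
expression through a Hill function,

    E_induced(C) = P_max Cⁿ / (Kⁿ + Cⁿ),    P_max = 15 TPM, K = 5, n = 2,

with `E_total = E_basal + E_induced` recomputed every step (memoryless,
reversible induction). Basal expression is sampled from a synthetic cohort
reproducing published quantile anchors of primary prostate-tumour *CD274*
TPM (median 1.48, IQR 0.91–2.14, max 18.5, 2/554 samples above 9 TPM).

Experiment arms cover the validation and knockout panel: `no_immunity`,
`null_evasion`, `uniform_high`, `tcga_static` (static engine only),
`adaptive` (full feedback), `induction_ko` (P_max = 0), `diffusion_ko`
(D = 0), and `immune_disabled`, plus grid-scale, logistic-parameter and
effector-ratio sweeps, three-criterion sanctuary detection, immunoediting
ratios, distant-seeding (metastasis proxy) classification, and a
Wilson-interval / test-selection statistics harness.

## Worked example

```python
import numpy as np
from coldsim import build_synthetic_cohort, cohort_stats
from coldsim.experiments import ArmSpec, run_arm

cohort = build_synthetic_cohort(n=554, rng_seed=1)
st = cohort_stats(cohort)
print(f"cohort: n={st.n} median={st.median:.2f} TPM  IQR={st.q1:.2f}-{st.q3:.2f}  "
      f"max={st.max:.2f}  skew={st.skewness:.2f}  >9 TPM: {st.count_gt[9.0]}")

for arm in ("null_evasion", "tcga_static", "adaptive"):
    s = run_arm(ArmSpec(name=arm, n_replicates=5, max_steps=500), cohort, base_seed=1)
    ratio = "n/a" if np.isnan(s.mean_editing_ratio) else f"{s.mean_editing_ratio:.2f}"
    print(f"{arm:12s}  final count {s.mean_final:6.1f} +/- {s.sd_final:5.1f}   "
          f"editing ratio {ratio}   terminations {s.termination_tally}")
```

prints

```
cohort: n=554 median=1.44 TPM  IQR=0.93-2.14  max=15.23  skew=2.82  >9 TPM: 1
null_evasion  final count    0.0 +/-   0.0   editing ratio n/a   terminations {'extinction': 5}
tcga_static   final count 1958.2 +/- 123.9   editing ratio 2.50   terminations {'max_steps_reached': 5}
adaptive      final count 2354.6 +/-  63.3   editing ratio 1.25   terminations {'max_steps_reached': 5}
```

Reading this: with evasion disabled the CTLs eradicate all five replicate
tumours (the cytotoxicity control). With heterogeneous basal PD-L1 the
tumour persists near carrying capacity (2500 sites), and the surviving
population's median PD-L1 is enriched ~2.5-fold over the initial median —
the immunoediting signature. The adaptive arm ends *larger* (IFN-γ-induced
PD-L1 shields cells during the CTL attack) with weaker basal enrichment,
because induced — not inherited — expression does the evading.

A thin CLI wraps the same functions (`coldsim run-arm`, `grid-sweep`,
`heatmap`, `effector-sweep`, `detect-sanctuaries`, `make-fixtures`); see
`coldsim --help`.

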