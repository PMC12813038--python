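# circoord

Vector coding and Bayesian circular mixed-effects analysis of lower-limb
inter-joint coordination, built for jump-shot kinematics recorded with
markerless motion capture (OpenSim-style angular-velocity exports).

## The problem

How do athletes reorganise hip–knee–ankle coordination as task demands
change — for example, basketball jump shots taken from increasing
distances?  Single-joint kinematics miss this: coordination lives in the
*relationship* between joints.  `circoord` implements the full analysis
chain for angular-velocity-based vector coding with circular-statistics
inference:

1. **Kinematics** — read tab-delimited motion/storage tables (time, COM
   height, six sagittal-plane joint angular velocities), low-pass filter
   them with a 4th-order zero-phase Butterworth (8 Hz default), split each
   trial into a **Loading** phase (quiet stance → COM minimum) and a
   **Jump** phase (COM minimum → COM maximum), and time-normalize each
   phase to 0–100%.
2. **Vector coding** — the coupling angle
   γ = atan2(ω_proximal, ω_distal) ∈ [0°, 360°) captures the instantaneous
   coordination of a joint pair (Hip–Knee, Hip–Ankle, Knee–Ankle, both
   sides); γ is classified into in-/anti-phase × distal/proximal dominancy
   bins, and per-trial **circular means**
   γ̄ = atan2(ȳ, x̄), x̄ = (1/n)Σcos γᵢ, ȳ = (1/n)Σsin γᵢ
   become the response variable.
3. **Circular mixed-effects model** — γ̄ is modelled as the direction of a
   latent bivariate normal vector (a *projected normal* distribution):

       y = r(cos θ, sin θ),  y ~ N₂(μ, I₂),
       μ = (xᵀβ_I + u_I[subj], xᵀβ_II + u_II[subj]),

   with a full Condition(4) × Phase(2) factorial design (reference cell
   P1/Loading) on both latent components and subject random intercepts.
   A data-augmentation Gibbs sampler draws the posterior; effects are
   shortest circular differences of population-level marginal predicted
   cell angles, summarised by 95% highest-posterior-density (HPD)
   intervals, with the interaction → simple-main-effects / main-effects
   decision tree applied per coupling.
4. **Synthetic data** — generators for full trial kinematics with
   analytically known coupling targets and for mean-angle tables drawn
   from the model itself, so every stage is testable without any
   recordings.

## Worked example

Recover known interaction effects at the study's design size (14 subjects
× 4 distances × 2 phases × 4 trials):

```bash
python examples/03_fit_circular_model.py
```

```
448 mean-angle observations, 14 subjects
sampler: 8000 retained draws, max R-hat 1.198, min ESS 17

interaction   estimate            95% HPD  truth
P1 vs. P2       -4.85° [ -6.83,  -2.91]*  -6.0°
P1 vs. P3      -10.08° [-12.15,  -8.08]*  -9.0°
P1 vs. P4      -12.06° [-13.96, -10.19]* -12.0°
```

Each row is an interaction contrast: how much the Jump-vs-Loading phase
difference at a given shooting distance deviates from that difference at
the nearest distance (P1).  The posterior means sit within about a degree
of the generating effects and every 95% HPD interval excludes zero (`*`),
the evidence criterion.  (The inflated coefficient R-hat reflects the
weakly identified latent scale of the projected normal; the angular
contrasts themselves mix well — see `docs/methods.md`.)

The other examples walk through coupling-angle basics
(`01_vector_coding_basics.py`), a single synthetic trial through the
kinematics pipeline (`02_synthetic_trial_pipeline.py`), and a full
end-to-end run with artifact outputs (`04_full_pipeline.py`).

A thin CLI wraps the same library calls:

```bash
circoord generate --seed 3 --out data/        # synthetic motion tables
circoord code --manifest data/manifest.csv --out obs.csv
circoord fit --observations obs.csv --coupling R_Hip-Knee --out results/
circoord run --config run.yaml                # full pipeline
```

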