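# graspkin

Unsupervised, video-based analysis of rodent single-pellet grasping.

In the single-pellet task a rodent reaches through a slit to retrieve a
sugar pellet; how the paw moves and which posture sequence it passes
through distinguishes true restoration of skilled reaching from mere
compensation after a motor-cortex lesion.  `graspkin` turns raw frame
sequences of such sessions into quantitative kinematics without any
manual labelling:

1. **Foreground extraction** — frames are split into a low-rank
   background model and a sparse foreground by principal component
   pursuit; candidate paw regions are sampled from the foreground and
   described by noise-robust HOG over a 10×10 cell grid; rare outliers
   are pruned by kNN density.
2. **Posture codebook** — for each candidate an ensemble of *K*
   randomized exemplar SVMs (soft margin C = 0.01) is trained against
   random negative sets, aggregated by a coordinatewise max-projection
   `w_i := max_k w_i^k`, and calibrated to probabilities by logistic
   regression.  The pairwise similarity
   `s(x_i,x_j) = ½(⟨w_i,x_j⟩ + ⟨w_j,x_i⟩)` is merged by normalized cuts
   into a dictionary 𝒟 of prototypical posture classifiers (medoids).
3. **Detection & tracking** — all codebook classifiers are applied
   densely; each window is scored by the mean of its top-k calibrated
   responses; detections are linked into tracks, grasp bouts are cut at
   slit crossings, and each bout yields its furthest extension toward
   the pellet.
4. **Sequence matching** — a grasp is the sequence `S_j = [e_1 … e_M]`
   of posture embeddings `e = [⟨w_1,x⟩, …, ⟨w_|𝒟|,x⟩]`.  Two grasps are
   aligned by

       min_π  Σᵢ ‖e_i − e'_{π(i)}‖ + λ Σᵢ 1(π(i) > π(i+1)),
       s.t.  |π(i) − i| ≤ B  for matched frames,  π(i)=0 ⇒ outlier (cost τ),

   solved exactly (integer program / chain dynamic program /
   enumeration, all agreeing to machine precision).  A dictionary of
   canonical grasp sequences gives every grasp a sequence-level
   embedding `F' = [d(S', S_1), …, d(S', S_Q)]`.
5. **Cohort statistics** — sessions are triangulated from their mean
   distances to pre-lesion baseline and 2-days-post anchors; recovery is
   declared by a two-sample Kolmogorov–Smirnov test on per-grasp
   distances to the baseline prototypes; furthest-extension
   distributions under perturbation conditions are compared via their
   x-marginals; phase-resolved posture deviations are reported in units
   of baseline SD.

A built-in synthetic scene generator (articulated paw over a static cage
background, programmable lesion phenotypes and recovery schedules)
provides ground truth for every stage, so the whole pipeline is testable
on a laptop.  See `docs/methods.md` for the model details and all
numerical choices.

## Worked example

Run the desk-scale five-cohort synthetic study (5 cohorts × 2 animals ×
6 time points, 200-frame sessions) end to end:

```bash
graspkin run --seed 1 --out study/
```

This prints a summary like

```json
{
 "config_hash": "0dbcaff20d81",
 "seed": 1,
 "stages": {"simulate": 16.7, "codebook": 20.9, "detect": 49.9, "report": 6.6},
 "tables": {"triangulation": 20, "recovery_ks": 20, "activity": 60, "phase_bars": 25}
}
```

and writes `study/report/` with one CSV per figure panel plus plots.
The triangulation table locates every (cohort, time point) between the
baseline anchor (x/c = 0) and the acute 2-day anchor (x/c = 1); in the
run above the cohort with a full recovery schedule moves steadily toward
baseline,

```
cohort              time_point   x_norm
recovered_training  7d           0.520
recovered_training  14d          0.472
recovered_training  21d          0.409
recovered_training  35d          0.369
```

while the untreated cohort with a persistent supination deficit stays
near the acute state (x/c ≈ 0.82–0.84 at all time points).  Matching a
pair of grasps directly:

```bash
graspkin match --a grasp_a.npy --b grasp_b.npy --lam 1.0 --band 10 --tau 1.0
# {"pi": [1, 2, 3, 4, 5], "objective": 0.0, "distance": 0.0, "status": "optimal"}
```

Other subcommands (`simulate`, `candidates`, `codebook`, `detect`) expose
the individual stages; `--config cfg.yaml` overrides any default, and
every output table carries the config hash and seed.

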