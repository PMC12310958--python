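# rehabdst

Decision-support tools for robotic upper-limb rehabilitation after stroke.

Planar rehabilitation robots that mediate therapy through virtual "serious
games" log a round-by-round stream of kinematic summaries (speeds, work
terms, movement smoothness, durations) alongside the difficulty levels the
therapist sets (stiffness, weight, viscosity). `rehabdst` turns those raw
per-round logs into harmonized per-patient time series and builds two
models on top of them, for therapists and rehabilitation-informatics
researchers who want session-by-session decision support without waiting
for the discharge assessment:

1. **Clinical-outcome prediction** — at every therapy time-step, predict the
   patient's discharge scores on three standard scales: the Action Research
   Arm Test (ARAT, 0–57), the upper-extremity Fugl-Meyer Assessment
   (FMA, 0–66) and the Motricity Index (MI, 0–100).
2. **Difficulty recommendation** — predict the stiffness / weight /
   viscosity levels an expert therapist would set for the *next* session,
   from a short look-back window of recent sessions.

Because clinical datasets of this kind are not freely redistributable, the
package ships a seeded synthetic-cohort generator with the same statistical
structure (seven games with partially overlapping feature sets, multiple
rounds per game per day, passive "automode" rounds, a persistence-biased
therapist policy, and discharge scores driven by a latent recovery
trajectory), so the entire pipeline and both models are exercisable and
testable end to end.

## The data-management method

Raw rounds pass through a fixed sequence of steps:

* **Timeline creation** — automode (passive) rounds are removed but
  counted; remaining rounds of the same game on the same date are averaged
  into one *session*, the time-step of the patient's series.
* **Mutuality filter** — only kinematic features reported by more than 70%
  of the seven games are kept (16 canonical features survive).
* **Missing-value filling** — same-date mean, then front-fill.
* **Exclusions** — patients need at least 10 distinct attendance dates and
  complete discharge assessments.
* **Feature assembly** — each session becomes a 36-column vector:
  3 demographics + 16 kinematic + 3 robot parameters + 7 one-hot game
  choice + 7 time-related features (day offsets, session counters, automode
  counts).
* **Normalization** — everything to [0, 1] with invertible fitted state:
  kinematics by per-(game, feature) training maxima, time features by each
  patient's own maxima, latency log-scaled, clinical scores by their scale
  maxima.
* **Padding or shrinking** — every series is brought to exactly 64
  time-points: short series are zero-padded and masked; long series are
  shrunk by iteratively deleting the most popular game from the most
  game-diverse date group, recomputing after every deletion.

The outcome model is a stack of six 32-unit LSTM layers with a per-time-step
dense head (masked MSE, batch size 1); the recommenders are one LSTM
classifier per robot parameter (look-back 3, 3 and 5 time-points). Both are
compared against random-forest baselines trained on identical patient-level
folds and evaluated with RMSE/MAE (outcome) and overall accuracy / F1
(recommendation), prediction-error stratification against the minimal
clinically important difference (MCID, 10% of each scale), and permutation
feature importance. The recurrent networks are implemented in NumPy inside
the package (`rehabdst.nn`), with the sequential step loops JIT-compiled by
numba when available.

## Worked example

```python
from rehabdst import SimConfig, generate_cohort, prepare_cohort, run_cross_validation
from rehabdst.models import OutcomeModelConfig

rounds, patients, _ = generate_cohort(SimConfig(n_patients=20, seed=1))
prep = prepare_cohort(rounds, patients)
print(prep.schema.width, prep.exclusion_report.n_retained)

report = run_cross_validation(
    prep, k=2, seed=1,
    outcome_config=OutcomeModelConfig(max_epochs=60, patience=15, seed=1),
)
summary = report.outcome_summary("lstm")
print({s: round(summary[s]["rmse"]["mean"], 3) for s in ("arat", "fma", "mi")})
```

prints

```
36 20
{'arat': 0.138, 'fma': 0.133, 'mi': 0.135}
```

i.e. the 36-column schema, all 20 synthetic patients retained, and a pooled
per-session test RMSE of about 0.13–0.14 on the normalized 0–1 scale
(about 7.9 ARAT points, 8.8 FMA points, 13.5 MI points), averaged over two
patient-level folds.

The same pipeline is scriptable from the shell:

```bash
rehabdst run-all -d myrun -c config.yaml   # or stage by stage:
rehabdst simulate -d myrun && rehabdst ingest -d myrun && ...
```

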