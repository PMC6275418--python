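# simondelta

Chronometric analysis of response inhibition in Simon tasks: trial
exclusion with category accounting, Simon-effect summaries, Vincentized
delta-plots with segment slopes, conditional accuracy functions, and
fully within-subject factorial inference — plus an activation–suppression
trial generator so the whole pipeline can be exercised, validated and
stress-tested without human data.

## The problem

In a Simon task, participants respond with the left or right hand to a
non-spatial stimulus feature (color, shape) while the stimulus appears on
a task-irrelevant side.  Responses are slower when stimulus side and
responding side conflict (*incongruent* trials); the **Simon effect** is

```
ΔRT = mean RT(incongruent) − mean RT(congruent).
```

Under the activation–suppression account, the irrelevant location
automatically activates the spatially corresponding response, which is
then selectively suppressed.  Because suppression takes time to build up,
the account makes *distributional* predictions beyond the mean effect:

* **Delta-plots.**  Per subject, correct-trial RTs of each congruence
  level are rank ordered and divided into quartile bins; the effect in
  bin *b* is the difference of the incongruent and congruent bin means,
  plotted against the midpoint of those means.  The slope of the final
  segment (Q3–Q4) indexes late selective suppression — the more negative,
  the more effective.
* **Conditional accuracy functions (CAF).**  All incongruent trials —
  including *kinematic errors* (KE; responses initiated with the wrong
  hand) — are binned by RT; bin accuracy is `correct / (correct + KE)`.
  Impulsive, location-driven responses produce a characteristic accuracy
  dip in the fastest bins.

The package is aimed at researchers analyzing conflict-task RT data with
designs crossing congruence with motor factors such as movement type
(simple lifting vs. complex reaching) and movement-type selection
(movements blocked separately vs. interleaved so the action itself must
be selected).  Inference uses repeated-measures ANOVA on subject × cell
means with partial eta squared (`η²ₚ = F·df₁ / (F·df₁ + df₂)`), planned
paired contrasts, Bonferroni adjustment for the fast-bin CAF comparison,
and a square-root transform for skewed KE rates.

## Worked example

Simulate a mixed-block ("active movement-type selection") regime in which
one movement is strongly activated and then suppressed, and run the full
analysis:

```sh
simondelta all --preset exp2_like --seed 11 --out demo/
```

or equivalently from Python:

```python
from simondelta.pipeline import RunConfig, run_pipeline
results = run_pipeline(RunConfig(out_dir="demo", preset_name="exp2_like", seed=11))
print(results["simon_summary.csv"].round(1))
print(results["slopes_group.csv"].round(3))
```

Output (16 simulated subjects, 288 trials each):

```
movement  mean_rt_congruent  mean_rt_incongruent  effect_ms  n_subjects
 lifting              635.0                658.9       24.0          16
reaching              557.0                628.6       71.6          16

selection_mode movement  slope_mean  slope_se  slope_of_group_means  n_subjects
        active  lifting      -0.066     0.051                -0.079          16
        active reaching       0.090     0.062                 0.092          16
```

The lifting action shows the smaller Simon effect and a *negative-going*
final delta-plot slope (effective late suppression), while reaching shows
the larger effect and a *positive-going* slope — the qualitative
dissociation this regime encodes.  The CAF for lifting dips in the
fastest bin (accuracy 0.788 in Q1 vs. 0.969 in Q2, group means),
the fast-error signature of strong initial response activation.  The
output directory also contains the exclusion accounting (here 3.65% of
trials excluded: 3.12% KE, 0.52% ME), per-subject delta-plot and CAF
tables, ANOVA tables for RT, KE rate, slopes and fast CAF bins,
delta-plot/CAF figures with standard-error bars, and a manifest that
makes the run bit-reproducible.

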