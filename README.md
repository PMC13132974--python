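# numcomp

Tools for dissecting **numerical comparison performance** into its
value-based (psychophysical) and statistics-based (association/frequency)
components. The package is aimed at researchers in numerical cognition and
psychophysics who want to simulate, analyze, or power comparison
experiments in which the *statistics of the stimulus stream* — how often
each numerosity appears, and how often it is the smaller or larger member
of a pair — are manipulated independently of the numerosities themselves.

## The scientific problem

In a two-alternative comparison task ("which side has more dots?"), two
classic effects characterize performance:

* the **distance effect** — accuracy rises and RT falls as |x₁ − x₂| grows;
* the **size effect** — performance degrades as both values grow.

A psychophysical (Weber-type) account derives both from a single **ratio
effect**: difficulty ∝ *a* · ln(large/distance) + *b*. A statistics-based
account instead composes two independent pieces — a distance term driven by
each value's association with the "smaller"/"larger" response categories,
and a size term driven by stimulus frequency — with difficulty
*a₁*·distance + *a₂*·(x₁⁻¹ + x₂⁻¹) + *b*. The two surfaces look deceptively
similar, but they dissociate under two designs implemented here:

1. an **omitted-range design** over {5, 10, 15, 35, 40, 45} (ties
   excluded, 30 ordered pairs × 20 repeats = 600 trials), where value-based
   and rank-based predictors ln(large − small) vs ln(rank_large −
   rank_small) decorrelate;
2. a **frequency-manipulated design** over multiples of 5 in [5, 45],
   where base token frequencies follow an everyday (≈ 1/value), uniform, or
   reversed-everyday distribution (ordered pair (i, j) appears
   f(i)·f(j)·repeats times — 1,588, 1,584 and 1,588 trials respectively),
   moving the size effect without touching the distance effect.

Trial-level data are generated by a Wiener diffusion process whose drift
carries the ratio effect, v = k·ln(large/small), and whose threshold,
nondecision time, or drift can be coupled to pair frequency (optionally
decaying over blocks). EZ-style closed-form diffusion recovery and a
qualitative signature classifier then attribute frequency effects to the
responsible parameter: faster *and* more precise responses implicate the
drift rate, while faster but no-more-precise responses implicate a lowered
threshold and/or nondecision time.

## Worked example

Simulate the three frequency conditions with the threshold coupled to pair
frequency, fit per-participant size-effect slopes on median RT, contrast
the conditions, and ask the diffusion diagnostics which parameter carried
the effect:

```python
import pandas as pd
import numcomp as nc

values = nc.ValueSet(nc.STUDY2_VALUES)
coupling = nc.FrequencyCoupling(threshold_gain=0.3)   # frequent pairs -> lower threshold
cohorts = []
for i, (condition, n) in enumerate([("everyday", 16), ("uniform", 24),
                                    ("reversed_everyday", 21)]):
    table = nc.build_frequency_table(condition, values)
    design = nc.build_trial_templates(table, repeats=22 if condition == "uniform" else 2)
    trials = nc.simulate_ans_cohort(design, nc.CohortSpec(n_participants=n, seed=100 + i),
                                    coupling=coupling)
    trials["participant_id"] = condition + "_" + trials["participant_id"]
    cohorts.append(trials)
trials = pd.concat(cohorts, ignore_index=True)

stats = nc.pair_stats(trials)                          # per participant x unordered pair
size = nc.make_regressor("size_sum", values)
fits = nc.fit_effect(stats, size, outcome="median_rt")
condition = trials.groupby("participant_id")["condition"].first()
slopes = fits.assign(condition=fits["participant_id"].map(condition))
print(slopes.groupby("condition")["slope"].mean().round(2))

contrast = nc.study2_slope_contrast(slopes, outcome_label="median_rt")
print(f"{contrast.name}: stat={contrast.statistic:.2f}, p={contrast.p_value:.4f}")

everyday = trials[trials["condition"] == "everyday"]
report = nc.frequency_diffusion_report(everyday,
                                       nc.build_frequency_table("everyday", values))
v = report["verdict"]
print(f"delta RT = {report['delta_rt_s']*1000:+.0f} ms, "
      f"delta ER = {report['delta_error_rate']:+.3f}")
print(f"attribution: {sorted(v.attribution)} ({v.direction})")
```

Output:

```
condition
everyday             12.92
reversed_everyday     3.71
uniform               6.26
Name: slope, dtype: float64
kruskal_wallis[median_rt]: stat=35.82, p=0.0000
delta RT = -24 ms, delta ER = +0.010
attribution: ['nondecision', 'threshold'] (decrease)
```

The RT size-effect slope (ms per unit of the sum-of-values regressor) is
steepest when small numbers are frequent (everyday), intermediate under
uniform frequencies, and shallowest when large numbers are frequent —
the Kruskal–Wallis omnibus confirms the conditions differ. Within the
everyday cohort, frequent pairs are ~24 ms faster than rare pairs after
removing the ratio-difficulty gradient, with slightly *more* errors — the
signature of a lowered decision threshold and/or nondecision time, not of
a drift-rate change; the classifier reports exactly that.

A thin CLI mirrors the library
(`numcomp design|simulate|analyze|power ...`), e.g.
`numcomp power anova --f 0.64` prints `42`.

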