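# rtbold

**Reaction-time-controlled analysis of neural congruency effects in
event-related fMRI.**

In distracter-interference tasks (Stroop, flanker, MSIT) incongruent trials
evoke more activity than congruent trials in the posterior medial frontal
cortex (pMFC). But incongruent trials are also *slower*, and BOLD amplitude
grows with time on task — so an apparent "congruency effect" may be nothing
but a reaction-time (RT) confound. `rtbold` implements, end to end, the
statistical machinery needed to separate the two accounts:

1. **A first-level GLM with polynomial RT modulators.** Each condition of
   interest gets a main regressor (unit impulses at stimulus onsets
   convolved with the canonical double-gamma HRF) plus parametric regressors
   of orders 1–4 built from mean-centred RTs, so that for condition *c*

   $$y(t) = \sum_c \beta_c x_c(t) + \sum_{p=1}^{4} \beta_{c,p}\, x_{c,p}(t) + \text{nuisance} + \varepsilon,$$

   with cosine high-pass columns (1/128 Hz), an optional 24-parameter motion
   expansion, and AR(1) serial-correlation correction by Cochrane–Orcutt
   prewhitening. The order-1 coefficient $\hat\beta_{c,1}$ is the RT–BOLD
   slope in signal units per ms.
2. **RT-equating.** Congruent activity is extrapolated to the incongruent
   mean RT: $\mathrm{Congruent_{EQ}} = \hat\beta_{C} + \hat\beta_{C,1}\,
   (\overline{RT}_I - \overline{RT}_C)$; the controlled contrast is
   $\hat\beta_I - \mathrm{Congruent_{EQ}}$.
3. **RT-matching.** A maximum-cardinality pairing of congruent with
   incongruent trials whose RTs differ by ≤ 10 ms (deterministic two-pointer
   greedy, provably optimal for this interval structure), followed by a
   categorical first-level model over matched / unmatched / error trials.
4. **RT-subsampling.** A power control: the same *number* of trials as the
   matched set, drawn at uniform strides through each condition's RT-sorted
   list so the native RT distributions (and hence the behavioural congruency
   effect) are preserved.

Because no public dataset accompanies this design, the package ships a
first-class synthetic generator (`rtbold.simulate`) that emulates the
multi-source interference task: 5 runs × (24 congruent + 24 incongruent +
12 fixation) trials of 3 s at TR = 2 s, ex-Gaussian RTs calibrated to
condition means 686.9 / 969.8 ms and error rates 0.1% / 8.2%, and BOLD
series whose trial amplitudes are linear in RT with an optional genuine
congruency increment, AR(1) noise and low-frequency drift. Every analysis is
therefore testable against known ground truth: with an RT-only generative
truth the full and subsampled contrasts must detect an "effect" while the
equated and matched contrasts must not.

Sphere-ROI extraction (default: 8 mm at MNI (2, 16, 46)) and
summary-statistics group inference (one-sample t, congruency × sampling
within-participant ANOVA, age ANCOVA) complete the pipeline.

## Worked example

```python
import rtbold as rb

cfg = rb.PipelineConfig(seed=1)      # 28 participants, default calibration
res = rb.run_experiment(cfg)
print(res.summary())
```

prints

```
RT-controlled congruency analysis
========================================================
participants: 28
behavioural congruency effect (full): 282.1 ms
behavioural congruency effect (matched): -0.6 ms
behavioural congruency effect (subsampled): 280.5 ms
--------------------------------------------------------
full        one_sample_t: t(27) = 20.095, p = 9.034e-18, effect = 0.5351 (se 0.02663)
equated     one_sample_t: t(27) = -0.837, p = 0.4098, effect = -0.03247 (se 0.03879)
matched     one_sample_t: t(27) = 1.316, p = 0.1992, effect = 0.06369 (se 0.04839)
subsampled  one_sample_t: t(27) = 14.110, p = 5.606e-14, effect = 0.5423 (se 0.03844)
anova_congruency anova_F: F(1, 27) = 56.181, p = 4.609e-08, effect = 0.303 (se 0.04043)
anova_interaction anova_F: F(1, 27) = 207.936, p = 3.33e-14, effect = 0.4786 (se 0.03319)
ancova_congruency_at_mean_age ancova: t(26) = 19.865, p = 3.072e-17, effect = 0.5351 (se 0.02694)
ancova_age_slope ancova: t(26) = -0.620, p = 0.5404, effect = -0.005478 (se 0.00883)
========================================================
```

Read it as follows. The default generator has **no** genuine congruency
increment — trial amplitudes depend on RT only (slope 0.002 units/ms).
Matching trims the 282 ms behavioural effect to −0.6 ms; subsampling keeps
it at 280 ms. Accordingly the full congruency contrast is hugely
"significant" (t(27) = 20.1, ≈ 0.002 × 282 ≈ 0.57 signal units), but it
vanishes once RT is controlled — the equated (t = −0.84) and matched
(t = 1.32) contrasts are null — while the trial-count-matched subsampled
contrast stays significant, and the congruency × sampling interaction
confirms the confound is carried by the RT difference. Generate a cohort
with `BoldTruth(congruency_increment=0.3)` instead and all four contrasts
detect the effect.

The same stages are scriptable from a shell (`rtbold simulate | filter |
fit-glm | rt-equate | rt-match | rt-subsample | roi-stats | run-all`); see
`rtbold --help`.

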