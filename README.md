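# smiletrace

Quantifying infant smile dynamics from automated facial action-unit (AU)
coding, for research on early markers of atypical social development.

Caregiver–infant interaction videos, run through an AU estimator such as
OpenFace, yield per-frame intensity traces for AU12 (lip-corner puller, the
common substrate of all smiles) and AU06 (cheek raiser, the Duchenne marker
that distinguishes a *Social Smile* from a *Simple Smile*). `smiletrace`
turns those traces into per-subject smile features and a two-group
statistical comparison:

1. **Ingest & quality gating** — read the OpenFace CSV dialect; keep only
   frames whose tracking confidence C > 0.75 (strict); split recordings at
   low-confidence runs longer than 0.5 s, bridging shorter gaps by linear
   interpolation.
2. **Event detection** — smooth AU traces with a width-4 boxcar; a smile
   event is a maximal run with smoothed AU12 ≥ τ (default 0.5 on the 0–5
   scale) lasting ≥ 1 s; events with AU06 co-active on ≥ 50% of frames are
   Social (SO), the rest Simple (SI).
3. **Featureization** — per subject and smile type: mean event duration,
   mean event intensity, and frequency as events per 120 s of usable time.
4. **Group statistics** — one-way MANOVA (Pillai's trace
   V = tr[**B**(**B**+**W**)⁻¹] with its exact two-group F transform),
   follow-up one-way ANOVAs with partial η² = SSB/(SSB+SSW) and a
   Bonferroni per-test threshold α/m (0.05/7 ≈ 0.00714), assumption
   screening (Shapiro–Wilk, Levene, Mahalanobis outliers, pairwise-r
   collinearity), partial Spearman correlations against IQ and sex, and
   demographic t/χ² comparisons.

Because clinical home-video datasets cannot be shared, the package includes
a marked-point-process simulator (`smiletrace.simulate`) that generates
fully ground-truthed synthetic cohorts with the same signal structure —
Poisson smile events with log-normal durations, amplitude-marked plateaus
with half-cosine ramps, AU06 co-activation for Social events only, baseline
noise and confidence dropouts — so the entire pipeline is testable end to
end.

## Worked example

Simulate a 33-subject cohort (18 ASD / 15 TD, the default presets plant a
lower Social-smile rate and lower AU amplitudes in the ASD group) and run
the full pipeline:

```bash
smiletrace simulate --out data --seed 7 --n-asd 18 --n-td 15
smiletrace run-all --in data --out results
```

`results/report.txt` then contains (abridged):

```
Omnibus MANOVA (Pillai's trace): V = 0.9698, F(6, 26) = 139.190, p = 1.719e-18
Complete cases analyzed: 33  (excluded listwise: 0)
------------------------------------------------------------------------------
Follow-up ANOVAs (Bonferroni: p < 0.00714 for alpha = 0.05, m = 7)
DV                     F        df           p  part.eta2  sig
dur_SI             0.112    (1,31)      0.7402      0.004
dur_SO             0.647    (1,31)      0.4273      0.020
freq_SI            0.756    (1,31)      0.3913      0.024
freq_SO            6.614    (1,31)     0.01513      0.176
int_SI_au12      269.469    (1,31)   7.676e-17      0.897    *
int_SO_au12      198.558    (1,31)   5.064e-15      0.865    *
int_SO_au06      224.521    (1,31)   9.551e-16      0.879    *
```

Reading: the groups differ on the combined smile features (the omnibus F);
the intensity DVs are flagged by the corrected rule (planted amplitude
difference recovered), the duration DVs are not (durations were generated
identically), and the Social-smile frequency shows the planted but smaller
rate difference. `results/stats.json` holds the same content
machine-readably; `events.csv` and `features.csv` hold the per-event and
per-subject tables.

The same analysis is available as a library through statsmodels-style
objects:

```python
from smiletrace import SmileGroupModel, generate_cohort
from smiletrace.experiments import features_frame

df = features_frame(generate_cohort(seed=7))
results = SmileGroupModel.from_features_frame(df).fit()
print(results.summary())
results.anova("int_SO_au12").partial_eta2
```

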