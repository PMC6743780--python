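# ragamood

Cross-cultural analysis of musical emotion in Hindustani *ragas*.

Listeners from different cultures often report strikingly similar emotions
when hearing the same melody — but they may reach those emotions through
different acoustic cues. `ragamood` implements an end-to-end pipeline for
studying this question with raga-like stimuli and two listener groups,
*enculturated* (E, familiar with the Hindustani tonal system) and
*non-enculturated* (NE):

1. **Stimulus characterization.** Melodic pitch per 30 ms frame is
   expressed in cents against the tonic drone, `1200·log₂(f₁/f₀)`, collated
   into 100-cent bins over three octaves (−1200…2400 cents) and folded into
   one octave. The **tonality ratio** m/M is the occupancy of the minor
   (komal + tritone) bins {100, 300, 600, 800, 1000} over the major
   (shuddh) bins {0, 200, 400, 500, 700, 900, 1100}. Rhythm is summarized
   by **pulse clarity** (1 − normalized Shannon entropy of the
   onset-envelope fluctuation spectrum, 0.25–10 Hz) and **event density**
   (note onsets per second). The two presentation modes — free-rhythm
   *alaap* and pulsed *gat* — differ in rhythm but share tonality.
2. **Group comparison.** Per-group 24 × 8 (excerpt × emotion) mean-rating
   matrices; modal emotion labels; two-sample KS tests on rating
   distributions; Welch-t and Wilcoxon comparisons of rating intensity for
   all 192 excerpt × emotion cells, Hochberg step-up corrected.
   *Universality* is declared when strictly more than half of the adjusted
   p-values exceed 0.05.
3. **Cue reliance.** Per emotion and group, mean ratings of the 24 excerpts
   are regressed on tonality, rhythm (0 = alaap, 1 = gat) and rater
   familiarity by iteratively reweighted least squares with Tukey's
   bisquare ψ (c = 4.685, MAD scale). Each predictor's unique share of
   variance is the drop in robust R² when it is removed.
4. **Odds ratio.** Group reliance on tonality vs rhythm is contrasted by

   OR = [%Var(Ton, E) / %Var(Rhy, E)] ÷ [%Var(Ton, NE) / %Var(Rhy, NE)]

   with percentile-bootstrap CIs over excerpts and a Cochran-Q
   heterogeneity check before any pooling.

Because no survey data are deposited for this paradigm, the package ships a
first-class synthetic generator: raga-like audio (tonic drone at 261.5 Hz,
melody drawn from prescribed swara weights with just-intonation offsets,
alaap/gat rendering, ground-truth pitch tracks) and simulated 0–4 integer
ratings with group-specific linear cue dependence. Every stage is therefore
testable offline.

## Worked example

```python
from ragamood import (default_raga_specs, render_stimulus_set,
                      feature_table, compute_odds_ratio)

stim = render_stimulus_set(default_raga_specs(), duration_s=180, seed=1)
print(feature_table(stim).head(4).round(3))
#       raga   mode  tonality_ratio  pulse_clarity  event_density
# 0  Bilawal  alaap           0.000          0.128          0.550
# 1  Bilawal    gat           0.000          0.190          1.494
# 2   Khamaj  alaap           0.086          0.129          0.428
# 3   Khamaj    gat           0.086          0.212          1.494
```

Bilawal (all-shuddh scale) has tonality 0 in both modes, while gat shows
the higher pulse clarity and the ~1.5 onsets/s of its isochronous grid
against alaap's ~0.5. An all-in-one run:

```bash
ragamood all --seed 1 --out ragamood_out
# universality=True (70/192 significant); outputs in ragamood_out
```

writes `features.csv`, per-group mean matrices, `comparisons.csv` (Welch +
Wilcoxon, Hochberg-adjusted), `variance_partition.csv`,
`odds_ratios.csv`, `verdict.json` and a markdown report. With the default
group profiles (tonality-dominant E, rhythm-dominant NE) the odds ratios
come out far above 1 for the tonality-driven emotions, e.g.

```
 emotion  odds_ratio  ci_lower  ci_upper
    calm       57.80     36.17    154.67
     sad       29.24     15.37     56.57
   angry        1.09      0.58      1.89
```

(angry sits near 1 because both groups' profiles keep it tonality-led),
and the heterogeneity check (Q = 114.4, p ≈ 0) correctly forbids pooling a
common odds ratio. The odds-ratio point estimate from published variance
shares, e.g. `compute_odds_ratio(33.41, 9.69, 10.22, 59.15)`, gives 19.96.

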