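# intakevar

Estimating the distribution of *usual* (long-run average) nutrient intake
from short-term dietary data — 24-h recalls or food records — requires
separating two sources of variation: day-to-day variation within a person
(within-individual variance, WIV) and true variation between people
(between-individual variance, BIV). With repeat days per person a mixed
model can split them; with only a single day per person the split must be
borrowed from an external study as a variance ratio. `intakevar` implements
both workflows for nutrition epidemiologists and survey analysts, and —
because the borrowed ratio is the weakest link — makes it easy to quantify
how much the headline result, the prevalence of inadequate intake, moves as
that assumption varies.

## The model

On a Box-Cox transformed scale *g*(·), the intake of subject *i* on day *j*
is

    g(y_ij) = mu + seq_j + w·weekend_ij + b_i + e_ij,
    b_i ~ N(0, s_b²),  e_ij ~ N(0, s_w²),

with recall sequence and weekend indicator as fixed effects, a subject
random intercept, and independent day residuals. The power λ is chosen on a
grid by maximizing the Shapiro–Wilk normality of the model residuals.
Variance ratios interconvert as

    R_CV = CV_w / CV_b,    α = s_w²/s_b² = R_CV²,
    β = s_w²/(s_b² + s_w²) = α/(1+α),    α = β/(1−β),

and ratios with α > 10 (β > 0.91) are flagged implausible. The usual-intake
distribution is the bias-corrected back-transformation of N(mu, s_b²) on a
percentile grid; prevalence of inadequacy is the mass below the Estimated
Average Requirement (EAR cut-point method, trustworthy when true prevalence
is neither <8–10% nor >90–92%). In the single-day (1-d) workflow the total
variance s² is estimated from the data and split by an external β:
s_w² = β·s², s_b² = (1−β)·s². Survey standard errors use balanced repeated
replication with a Fay coefficient (default 48 replicates, Fay 0.7).

## Worked example

The numbered scripts under `analysis/` run the whole study on synthetic
populations with known truth:

```sh
python analysis/01_simulate_recalls.py
python analysis/02_decompose_variance.py
python analysis/03_sensitivity_curves.py
python analysis/04_brr_uncertainty.py
```

Step 02 decomposes a 500-woman × 2-recall dataset generated with true
WIV:total = 2/3 on the log scale:

```
Box-Cox power selected by residual normality: lambda = -0.01 (Shapiro-Wilk W = 0.9991; generative truth +0.00)
   reml: s_w2 = 0.5150, s_b2 = 0.1824 -> WIV:total = 0.7385 (truth 0.6667)
```

The fitted power lands at the generative log scale and the REML ratio is
within sampling error of the truth. Step 03 then runs the 1-d pipeline on
the first recall only, sweeping the assumed ratio across 0.05…0.95, 0.99
for a zinc-like EAR of 6 mg/d:

```
  prevalence falls from 35.2% to 0.0% (monotone: True)
  over the recommended sensitivity range 0.5-0.9: 1.8% to 22.2%
  2-d reference: 11.5% at WIV:total = 0.739 (truth 0.667)
  1-d curve at the nearest grid point (0.75): 10.5%
```

Reading: the same single-day data supports *any* prevalence between ~0 and
35% depending on the assumed ratio — a 20-point spread even within the
recommended 0.5–0.9 sensitivity band — while the 1-d curve evaluated at the
repeat-day estimate reproduces the 2-d answer within a point. Step 04 shows
the companion uncertainty effect on a stratified-cluster survey: BRR
standard errors grow from 1.9 to 4.2 percentage points as the assumed ratio
rises from 0.3 to 0.9.

The same workflows are scriptable via the `intakevar` command
(`simulate`, `decompose`, `sensitivity`, `convert-ratio`), e.g.

```sh
intakevar convert-ratio 10 --from wiv_to_biv --to wiv_to_total
# wiv_to_biv=10 -> wiv_to_total=0.909091
```

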