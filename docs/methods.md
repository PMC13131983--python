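# Methods

## Problem setting

After catheter ablation for atrial fibrillation (AF), the electroanatomic
bipolar voltage map of the left atrium (LA) carries information about how
complete the treatment is: residual conduction gaps in the encircling
lesions around the pulmonary veins (PVs) predispose to a redo pulmonary-vein
isolation (PVI), and untreated low-voltage substrate elsewhere in the
atrium predisposes to a redo of ablation beyond PVI (be-PVI). This package
models that link end to end: it renders synthetic voltage maps with known
substrate, trains an image model that predicts a censored three-category
ablation-completeness status per task, and evaluates the predictions with
time-to-event statistics.

Because no real mapped cohort is distributed with the package, the
synthetic generator is a first-class component: every quantitative claim
the test suite makes is a claim about recovery of *planted* signal under
*known* censoring, not about clinical performance.

## Synthetic voltage maps

**Geometry.** The LA is an ellipsoid shell (default semi-axes 35 x 30 x
28 mm, roughly a mildly enlarged atrium) discretized as a subdivided
icosphere with 20,480 faces, giving ~1.1 mm vertex spacing — finer than a
pixel at the 256x256 clinical rendering and at the 64x64 desk-scale
rendering used in tests. Four PV ostia (LSPV, LIPV, RSPV, RIPV) sit at
fixed canonical directions on the posterior wall; positions were chosen
once for anatomical plausibility and are not tuned. The LA appendage is
simply never modeled, mirroring displays from which it has been removed.

**Voltage field.** Healthy bipolar voltage is log-normal (median 1.5 mV,
log-dispersion 0.7) with spatial correlation imposed by neighbor-averaging
smooth noise on the mesh, so the sub-0.5 mV tail forms contiguous regions
rather than speckle. Diseased substrate is added as 0–3 circular
low-voltage patches (radius 5–15 mm) whose cores are reduced by a severity
factor of 0.6–1.0, with a linear border zone over an extra 30% of the
radius. Ablated tissue is set to 0.05 mV and flagged in an explicit lesion
mask.

**Summary features.** Two scalars connect images to outcomes:

* mean PV gap fraction `g` — the average over the four veins of the
  fraction of each encircling ring left unablated (1 before any PVI);
* low-voltage burden `b` — the area fraction of the non-PV surface that is
  below 0.5 mV and *not* lesioned. Ablated scar is excluded because it is
  treated substrate; this is what lets be-PVI ablation reduce `b` even
  though it lowers voltage.

**Rendering.** Orthographic projections from four fixed cameras (AP, PA,
INF, SUP) are ray-cast analytically against the ellipsoid; each anatomy
pixel takes the color of its nearest mesh vertex. Color follows the common
clinical convention: red at or below 0.1 mV, purple at or above 0.5 mV,
rainbow hue ramp in between (both thresholds configurable — vendors and
labs differ, and no single standard exists). Background is black and
anatomy colors are never black, so the foreground mask is trivial.
A fidelity check inverts the hue ramp on the rendered AP+PA pixels,
weights each pixel by inverse foreshortening (1/|n·d|) to approximate a
surface integral, and confirms Spearman ρ ≥ 0.9 against the phantom's `b`
over 100 phantoms.

**Outcomes.** Each task has a discrete-time hazard, constant across K = 12
monthly bins of the 365-day horizon: h = logistic(β0 + β1·feature), with
`g` driving redo-PVI and `b` driving redo-be-PVI. Event bins are geometric
draws (events beyond the horizon are allowed and become event-free
labels); the event day is uniform within its bin. Follow-up ends at an
administrative censoring day uniform on (180, 730), matching a collection
window of up to two years; an event is recorded only if it precedes the
censoring day. Defaults β0 = −5 with β1 = 6 (PVI) and β1 = 12 (be-PVI)
give a strong planted effect: roughly 8% 1-year risk for a fully treated
atrium rising steeply with residual gaps or burden, and a cohort-level
1-year recurrence in the realistic 20–40% range.

**Operator model.** Each simulated session is: pre-ablation map → initial
PVI (each PV keeps a residual gap with probability 0.4, gap fraction
uniform on 0.1–0.6) and, when indicated by burden, be-PVI (treating 50–90%
of the low-voltage area) → post map → with probability 0.5, additional
ablation *if* the post map is incomplete (mean gap > 0.02 or burden >
0.10), which fully closes gaps and treats 80% of residual burden, followed
by a final map. Outcomes are simulated from the end-of-session phantom, so
additional ablation genuinely improves prognosis — the ground truth behind
the additional-ablation impact analysis. With 5% probability a recurrence
loses its redo-target identity, exercising the unknown-target censoring
branch. A no-effect variant (gap closure and burden effect set to zero)
provides the matching null for the impact analysis.

## Labels

Each map is labeled independently per task:

* Category 1 (pre-intervention) if that task's ablation occurred after the
  map in the same session;
* Category 2 (event) if a same-target redo occurred within 365 days, with
  the event's monthly bin;
* Category 3 (event-free) if followed ≥ 365 days without a same-target
  redo;
* censored otherwise, carrying the last fully survived bin. A bin whose
  right edge equals the end of follow-up counts as survived; a recurrence
  of unknown redo target censors *before* the recurrence day (the event
  could lie in that bin). Censoring at bin 0 is retained — such maps still
  teach "not pre-intervention".

Sessions that never perform a task at all are treated as post-intervention
for that task. K = 12 monthly bins is a package choice balancing temporal
resolution against per-bin event counts; every metric accepts an arbitrary
bin scheme.

## Model

A minimal ConvMixer: patch embedding (stride-4 4x4 convolution to 16
channels), four mixer blocks (9x9 depthwise convolution with residual
connection, then pointwise convolution; GELU and batch normalization after
each), global average pooling, and two parallel softmax heads of width
K + 2 = 14 — one distribution (p_pre, p_1..p_K, p_free) per task. The four
views enter as a single 12-channel stack; channel concatenation through
one shared trunk is the minimal-parameter fusion and preserves cross-view
alignment. The network is fully convolutional, so the ~10k trainable
parameters are independent of image side; tests run at side 64 (and 32),
the default rendering is 256.

The implementation is self-contained numpy: each layer carries an explicit
backward pass (verified against central differences to <1e-4 relative),
and the depthwise convolution is evaluated in the frequency domain — the
forward pass, kernel gradient, and input gradient are each one batched FFT
product with transform size ≥ H + k − 1 to avoid circular wrap. GELU uses
the standard tanh approximation. Batch normalization uses batch statistics
during training and frozen running statistics at inference, so batched and
single-item inference agree.

## Losses

The likelihood term is the DeepHit-style censored negative log-likelihood
of the category/bin distribution: −log p_pre, −log p_k, −log p_free for
Categories 1/2/3, and −log(Σ_{k>c} p_k + p_free) for a map censored after
c survived bins, with a 1e-8 floor inside the log. The ranking term
penalizes discordant pairs: for each event i in bin k_i and each j known
event-free through k_i, it adds exp(−(F_i(k_i) − F_j(k_i))/σ), where F is
the task's cumulative incidence; pre-intervention maps join neither side,
and the CIF is compared at the earlier event's time (the DeepHit
convention). Defaults σ = 0.1, ranking weight α = 1, equal task weights.
Gradients with respect to the head logits are closed-form.

## Training and evaluation

Patient-grouped 5-fold cross-validation: folds partition patients, never
maps, so no patient's maps straddle train and test. Each fold trains with
Adam (lr 1e-3 by default; the bundled studies use 2e-3), batch 32, joint
left-right flips as the only augmentation (applied to training batches
only — flipping all 12 channels together preserves the cross-view
positional relationship), early stopping on a 10% held-in validation split
with best-weights restore, and global-norm gradient clipping at 5. One
root seed fans out to per-fold seeds by fixed offsets.

Discrimination uses the cumulative/dynamic time-dependent AUC on the bin
grid: at horizon m, positives are Category 1 plus events in bins ≤ m;
negatives are maps known event-free through m; maps censored before m drop
out. The implementation is the exact midrank (tie-aware) pair count and is
tested against an O(n²) enumeration. The prognosis-mode risk score is
p_pre + F(m) (separating Categories 1∪2 from 3), the practice-mode score
is p_pre (separating 1 from 2∪3); the summary c-statistic is the AUC at
the 1-year bin, reported both pooled across folds and as per-fold
mean ± SD. Kaplan–Meier curves and log-rank tests are delegated to
lifelines.

For the binary Complete/Incomplete call, each fold's threshold maximizes
the Youden index on that fold's *training* predictions and is applied to
its held-out maps. Stratified analyses then compare: (a) Incomplete vs
Complete end-of-session maps on any-recurrence survival, and (b) within
each stratum of intra-procedural (post) maps, additional vs no-additional
ablation, per task and for the union. Empty or eventless strata are
reported as undefined rather than raised.

## Saliency

SmoothGrad: the mean over n = 32 noisy copies (Gaussian noise, σ = 0.1 of
the input dynamic range) of the absolute input gradient of a chosen risk
functional, channel-summed per view. The risk functionals are linear in
the output probabilities, so their gradient seeds are indicator vectors
pushed back through the softmax. Gradient magnitude (not sign) is
reported, matching how such maps are usually displayed.

## Bundled studies and what they show

`vmap.experiments.run_study` is the standard desk-scale experiment:
400 patients at side 64, 5-fold CV, 30 epochs per fold — sizes chosen so
the whole study runs in minutes on one CPU while leaving the planted
signal comfortably recoverable. Its null counterpart re-simulates outcomes
from intercept-only hazards (β0 = −4, ~20% 1-year risk) independent of the
substrate.

One structural caveat documented deliberately: Category 1 is a
*timing-based* label. Pre-ablation maps have no lesion rings and remain
perfectly recognizable even when outcomes are randomized, so the pooled
prognosis AUC (whose positives include Category 1) stays high under the
null. The outcome-linked discrimination that a null control actually
randomizes lives in the post-intervention maps, so the package reports
both the pooled AUC and the post-intervention-only AUC, and the null
control is judged on the latter. Under the planted effect both are
informative; under the null the post-only AUC hovers at chance.

What passing tests do and do not show: the generator plants a clean,
strongly identified signal — co-registered views, a single lesion
geometry, no catheter-contact artifacts, no inter-institution color-scale
or projection variability, no class imbalance beyond what the operator
model induces. Recovery here demonstrates that the pipeline (labels,
losses, training, metrics, stratification) is correct and unbiased, not
that any particular clinical performance level is attainable.

## Numerical choices and degenerate inputs

* log floor 1e-8 in the likelihood; softmax is max-shifted.
* AUC ties count 1/2 exactly (midranks); batches ≤ 500 are also checked
  against brute-force enumeration in the tests.
* Youden threshold candidates are midpoints of consecutive distinct
  scores; all-identical scores raise a threshold error, and a degenerate
  training fold falls back to calling nothing Incomplete.
* Dataset CSVs are written with %.17g and read with round-trip float
  parsing, so write∘read is the identity on all fields.
* Event days drawn inside bin k lie in (edge_{k-1}, edge_k], matching the
  bin convention used by the labeler.
* The geometric event-bin draw is unbounded; draws beyond the censoring
  day are recorded as censoring, beyond the horizon as event-free.

## Known limitations

* The ellipsoid shell has no appendage stump, no vein sleeves, and no
  trabeculation; PV positions are fixed rather than sampled.
* Discrete hazards are piecewise constant per bin; no frailty and no
  competing-risk coupling between the two tasks beyond their shared
  censoring day.
* The operator model reacts to the true substrate, not to a noisy reading
  of it, so "practice-based" behavior is cleaner than reality.
* Training determinism is guaranteed for a fixed BLAS/FFT configuration;
  different linear-algebra backends may differ in the last bits.
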