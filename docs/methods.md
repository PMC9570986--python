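# Methods

## Problem

People with Parkinson's disease exhibit three clinically distinct hand
tremor types — resting (relaxed muscles), postural (holding a position
against gravity) and action (during voluntary movement) — and a wearable
tremor-suppression device must distinguish the wearer's voluntary motion
from the tremor riding on it. `emgtremor` implements a pipeline that
classifies both the voluntary task being performed and the tremor type
from 8-channel forearm surface EMG (sEMG) sampled at 200 Hz, using a
bidirectional LSTM trained per subject, with hyperparameters selected by
regularized (aging) evolutionary search.

## Synthetic session generator

Clinical sEMG from this population is generally not shareable, so the
package includes a first-class generator that emulates a six-task
assessment protocol: rest palm-down (`1a`) and palm-up (`1b`), a postural
hold (`2`), two repeated reach-pinch-return movements (`3`, `4`), and
spiral drawing (`5`). Tasks 1a/1b/2 run one minute; tasks 3/4 are five
repetitions; task 5 is a single trial.

The generative model is a tremor-modulated synergy mixture. Channel *c*
at time *t* is

    x_c(t) = noise + sum_p  A[c,p] * m_p * g(t) * (1 + a * sin(2*pi*f*t + phi))

where `A` is an (8 x 4) non-negative, column-stochastic synergy matrix
(each muscle primitive concentrates on a different ring sector of the
armband), `m` is the task's primitive mix, `g(t)` the task activation
profile, `f` the subject's tremor frequency (uniform 4–7 Hz, the classic
parkinsonian band), `a` the tremor modulation depth for the tremor type
the task elicits, and `phi` a trial-specific phase. The multiplicative
form reflects that tremor bursts appear in the EMG as rhythmic modulation
of muscle activation.

Design choices, fixed once:

- **Why everything sits below 20 Hz.** The pipeline's 20 Hz low-pass
  filter would destroy any discriminative content above the cutoff, so
  the generator places all task envelopes (constant, trapezoidal bursts,
  a 0.6 Hz drawing oscillation) and the tremor oscillation below it.
- **Durations not fixed by the protocol**: 4 s per repetition for tasks
  3/4 (20 s total each) and 15 s for the spiral — plausible paces for
  the movements described, chosen once and kept.
- **Amplitudes**: tremor modulation depths 0.8 / 0.5 / 0.3 for
  resting / postural / action; sensor noise SD 0.05 against envelope
  levels 0.3–0.9, i.e. moderate SNR. No population statistics exist to
  calibrate against; these are engineering defaults, all overridable per
  subject.
- **Task 3 vs 4 confusability**: the two movements use the same muscles,
  so their primitive mixes deliberately share a 0.7 overlap fraction
  (`TASK34_MIX_OVERLAP`), making the 6-class problem genuinely harder
  than the merged 5-class problem.
- **Reproducibility**: noise and phase come from a counter-based Philox
  stream keyed on `(profile.seed, trial_seed)`, so any subject or trial
  regenerates bit-identically in isolation.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: motor-unit action-potential shapes and
recruitment, electrode lift-off and powerline artefacts, inter-session
electrode shift, fatigue-induced spectral compression, and the large
inter-subject variability of real tremor dynamics. Synthetic task classes
are cleanly separable by construction (near-ceiling accuracies here say
the pipeline works, not that real-data accuracy would match published
cross-participant figures); the tests are recovery properties, not
clinical benchmarks.

## Preprocessing

4th-order Butterworth low-pass at 20 Hz (scipy), zero-phase
(forward-backward, squared magnitude response) by default since analysis
is offline; a causal forward-only mode is kept for streaming use. Windows
are 250 ms (50 samples) with 50 % overlap; window count is
`floor((N - l)/hop) + 1` with the trailing partial window discarded — the
only convention under which a 50-sample recording yields exactly one
window and 49 samples is an error. The split is chronological per
recording: first 80 % of windows to train, final 20 % to test, because the
data are a time series and the model must be evaluated on its future. The
50 % overlap means one window at the boundary shares samples with the
training side; the faithful no-gap behaviour is the default. No
rectification or envelope extraction is applied — the classifier consumes
raw filtered windows.

Label schemes: `task6` (six tasks), `task5` (tasks 3 and 4 merged into
`3or4`, motivated by their intrinsic confusability), and `tremor3`
(1a,1b -> resting; 2 -> postural; 3,4,5 -> action). Schemes are identity
on their own output classes, so relabelling is idempotent.

## Classifier

A single bidirectional LSTM layer over the 50-sample window, one label
per window. Two cell modes:

- `paper_literal`: the minimal cell
  `i,f,o = sigma(W* x_t + h_{t-1})`, `c_t = f.c_{t-1} + i.tanh(Wc x_t)`,
  `h_t = tanh(c_t).o` — no recurrent weight matrices, no biases, the
  previous hidden state added unweighted to the gate pre-activations.
  Exercised in unit tests and available for study.
- `standard`: the conventional cell with recurrent matrices `U*` and
  biases; the training default, because the literal cell's lack of
  learned recurrence limits trainability.

The final forward and backward hidden states are concatenated (forward
first) into a dense softmax head. Loss is categorical cross-entropy (the
conventional choice for k-class problems). Optimizers: plain SGD or Adam
with beta1=0.9, beta2=0.999, eps=1e-8. Weights are scaled-uniform
(+-1/sqrt(fan-in)) keyed on a seed; biases start at zero. The
tanh-vs-ReLU hyperparameter selects the cell-candidate nonlinearity;
gates remain logistic and the cell output transform remains tanh (the
conventional placement when a ReLU variant is offered). Gradients are
exact BPTT, verified against central finite differences to 1e-4 relative
in both modes in the test-suite. Everything is numpy; training of a
20-unit model on ~1500 windows for 50 epochs takes tens of seconds on one
CPU core.

Warm starting copies tensors from a trained source model into a fresh
target: `strict` requires identical architectures; `compatible_only`
copies shape-matching tensors and reports the copied fraction.

## Hyperparameter search

Discrete space of 2400 configurations: hidden width {20, 50, 100, 200,
500}, learning rate {1e-3 … 1e-8}, epochs {10, 20, 50, 100, 250}, batch
{32, 64, 128, 256}, optimizer {Adam, SGD}, activation {tanh, ReLU}.
Aging evolution: after a warm-up that fills the population with `p`
random evaluated candidates (no removals), each cycle tournament-selects
a parent (fittest of `k` sampled without replacement, ties to the
earliest birth), mutates exactly one field to a different option, inserts
the evaluated child and removes the *oldest* member. Termination is
best-worst: stop when the population's fitness spread drops below
epsilon, else at `max_cycles`. Because aging can evict the incumbent
best, the returned optimum is tracked over the full evaluation log.
Defaults `p=16, k=4, epsilon=0.01, max_cycles=100` are engineering
choices sized for desk-scale fitness evaluations, all configurable.

Fitness for real training is validation accuracy on the chronologically
last 20 % of the *training* partition, so the held-out test windows are
never touched during the search. The pipeline can cap epoch counts during
search (`nas_max_epochs`) to keep desk-scale searches affordable; the
winning configuration is then retrained at full budget.

## Evaluation

Confusion matrices with rows = true class, columns = predicted class
(the orientation under which the packaged worked example's row/column
sums reproduce its published per-task recalls/precisions). Per class,
TP is the diagonal entry, FN the rest of the row, FP the rest of the
column, TN the remainder; accuracy = trace/total, precision = TP/(TP+FP),
recall = TP/(TP+FN). Zero-denominator ratios are reported as absent,
never as 0. Chance level is 1/K (20 % for five classes, 33 % for three).
Comparisons against printed two-decimal values round half-up with
tolerance +-0.005. Two printed entries of the 6-class worked example are
internally inconsistent with their matrix (task 1a recall: derived
190/286 = 0.66 vs 0.71 printed; task 5 precision: derived 233/277 = 0.84
vs 0.90 printed); they are documented and excluded from fixtures — no
guess is made about which side is the typo.

The warm-vs-cold comparison trains both initializations under identical
hyperparameters and seeds on a target subject, warm-started from another
subject's trained model, and reports paired per-class precision/recall
and accuracy deltas across seeds.

## Problem sizes used in tests and the acceptance script

Synthetic studies use 3 subjects (classification recovery) and 2 subjects
(warm-start comparison) at the default protocol (~1870 windows per
subject, ~1500 train), with a fixed small architecture (20 neurons,
Adam 1e-3, batch 128; 50 epochs for recovery, 20 for the warm-start
comparison) — sizes chosen so the full pipeline exercises every stage on
one CPU core in a few minutes. The search-oracle check uses a
deterministic toy fitness (negative normalized index distance to a known
target configuration) over the full 2400-point grid, 20 seeded runs at
p=16, k=4, 300 cycles, compared against exhaustive enumeration.

## Known limitations

- The generator is a statistical stand-in, not a physiological simulator;
  absolute accuracies on it exceed what heterogeneous clinical data would
  give.
- Single bidirectional layer only; no stacked layers, attention, GPU
  kernels or variable-length batching.
- `paper_literal` cells train poorly by construction (no learned
  recurrence); they exist for fidelity and study, not performance.
- The 50 % window overlap leaks a few shared samples across the 80/20
  boundary; an optional guard gap is not implemented beyond the split
  convention documented above.
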