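# Methods

This note documents the models implemented in `kaarma`, the choices made
where the design was genuinely open, and what the synthetic benchmarks do
and do not demonstrate.

## The KAARMA model

A kernel adaptive ARMA (KAARMA) network is a recurrent state-space model
whose transition function lives in a reproducing kernel Hilbert space
(RKHS).  The augmented state `s = [x; y]` (hidden block `x`, output block
`y`) evolves as

    s_i = A^T k_i,        k_i[j] = K_s(c_j^s, s_{i-1}) · K_u(c_j^u, u_i),
    y_i = I_sel s_i,

where the dictionary `{(c_j^s, c_j^u)}` holds `m` (state, input) centers
with coefficient rows `A ∈ R^{m×n_s}`, `K_s` is a Gaussian kernel of size
`a_s`, and `K_u` is either a Gaussian of size `a_u` (continuous feature
vectors) or the Schoenberg spike-train kernel of size `a_λ` (multichannel
spike frames).  The tensor-product structure means a dictionary entry fires
only when both the previous state **and** the current input resemble its
centers — a soft transition rule, which is what lets the model behave like
a learned automaton.

Supervision is sequence-level only: a single target `d ∈ {−1, +1}^{n_y}` at
the final step.  Training backpropagates `e_f = d − y_f` through the state
recursion with the kernel trick: with state Jacobians
`Γ_i = ∂s_i/∂s_{i-1} = 2 a_s A^T diag(k_i)(C_s − 1 s_{i-1}^T)` and
sensitivities `Ψ_i = Γ_f ⋯ Γ_{i+1}`, every step proposes a center
`(s_{i-1}, u_i)` with coefficient row `η (I_sel Ψ_i)^T e_f`; the weight
update is applied once per sequence.  The analytic Jacobians and the full
output/coefficient sensitivity are verified against central finite
differences to better than `1e-4` relative error (the test suite's gradient
oracle); machine-precision agreement is typical.

### Stabilization choices

Two choices were required to make the recursion work in practice;
both are parameters with documented defaults.

* **Non-zero fixed initial state** (`s0_scale = 0.5`).  With `s0 = 0` and an
  empty initial dictionary the hidden block of the state is invariantly
  zero: proposed rows are `η Ψ^T I_sel^T e`, whose hidden components vanish
  whenever every visited state has zero hidden block, and the Jacobians can
  never mix output into hidden components whose centers are all zero there.
  The recursion then degenerates to a memoryless readout (chance-level on
  grammar tasks).  Any fixed, asymmetric initial vector breaks the symmetry;
  the default is a seeded Gaussian vector of scale 0.5, identical for every
  sequence and every run.
* **Sensitivity clipping** (`sensitivity_clip = 1.0`).  The Jacobian norm
  grows with the coefficient mass, so the products `Ψ_i` explode once
  training has accumulated moderate coefficients — the recurrent-network
  gradient-explosion problem in RKHS form; unclipped training reliably
  diverges within a few hundred sequences.  The backward pass therefore caps
  the Frobenius norm of `I_sel Ψ_i` at 1.  This also bounds the effective
  per-sequence update gain `η Σ_i ‖I_sel Ψ_i‖²` (stability requires it below
  2 for a contraction argument on the per-sequence error).

### Quantized dictionary growth

Each proposal is merged into its nearest dictionary neighbor when the joint
squared distance `‖Δs‖² + d_u(Δu)` falls within the threshold `ε`; otherwise
it is appended (lowest index wins ties).  `d_u` is the same metric the input
kernel exponentiates: squared Euclidean for vectors, the channel-averaged
`1/T²`-normalized ordered-set spike distance for frames.  **The threshold
bounds the squared distance directly** (merge iff `d² ≤ ε`).  This
comparison space matters: nearest-neighbor squared joint distances on
realistic spike-word data concentrate around 0.15–0.4, so a threshold of
`ε² = 0.0625` (the "distance ≤ ε" reading at the reference `ε = 0.25`)
merges essentially nothing and the dictionary grows by every training frame.
Bounding `d² ≤ ε` instead yields the strong compaction the quantized
learner exists for — at `ε = 0.25`, chain networks keep roughly 37–49 % of
their training frames (≈1.9 k centers from ≈4.3 k frames) with no accuracy
loss, while `ε = 0` grows one center per non-duplicate proposal.

## Spike-train kernels

Spike trains are segmented into overlapping frames (25 ms windows, 10 ms
stride — 100 frames/s, the standard speech geometry).  Within a frame the
conditional intensity function (CIF) of the underlying point process is
estimated by smoothing the spike times with a rectangular function of width
equal to the frame; the CIF estimate is then a unit-step staircase, and the
Schoenberg kernel is `exp(−a_λ D)` with `D` a squared distance between the
two staircases, averaged (default) or summed over channels.

Two readings of `D` are implemented:

* `ordered_set` (default): squared Euclidean distance between the ordered
  spike-time sets, the shorter padded with the frame duration `T`, scaled by
  `1/T²`.  Because the pad value is `T`, padding both sets to any common
  width leaves the distance unchanged, which is what allows the learner to
  keep its dictionary as one rectangular array.
* `staircase_integral`: the exact integral `∫ (λ̂_a − λ̂_b)² dt`, computed
  in closed form over the merged breakpoints.

The two agree when prefix counts never differ by more than one and diverge
otherwise (the worked pair {5, 15} ms vs {10} ms gives 0.2 and 24.0); the
ordered-set form is the default because it is the operational reading of the
squared-Euclidean-on-ordered-sets description of the distance, and it makes
the kernel a Gaussian on padded vectors (hence trivially positive
definite).  The staircase integral is validated against 1 µs numerical
quadrature in the test suite.

## Front-ends

* **Gammatone filterbank** — FIR filtering with the truncated impulse
  response `a_g t^{n−1} e^{−2πbt} cos(2πf_c t + φ)`; order `n = 4`,
  bandwidth `b = 1.019·ERB(f_c)` (standard auditory convention), `φ = 0`,
  `a_g` normalized to unit peak magnitude response per channel.  Twelve
  channels equally spaced on the ERB-rate scale
  `E(f) = 21.4 log10(0.00437 f + 1)` between 50 Hz and 8 kHz.
* **LIF neurons with SRA** — one neuron per channel; forward-Euler
  integration of `τ_m dV/dt = (E_rest − V) + R_m I − (V − E_k) R_m (g_sra +
  g_ref)` at `dt = 1/fs`, threshold crossing strictly above `V_th`, reset to
  `V_reset`, conductances incremented by `Δ_sra`, `Δ_ref` per spike and
  decaying exponentially between spikes.  Constants (mV/ms/MΩ/nS):
  `R_m = 10`, `τ_m = 10`, `V_th = −55`, `V_reset = −80`, `E_rest = −70`
  (absent from the reference parameter set; configurable), `E_k = −200`,
  `τ_sra = 200`, `τ_ref = 2`, `Δ_sra = 5`, `Δ_ref = 200`.
  **Unit convention:** the reference pairing of a 4 µA current normalization
  with `R_m = 10 MΩ` is not self-consistent — read literally it is a 40 V
  drive (the neuron fires on every oscillation ripple, ~160 spikes per
  frame); read as millivolts it is a 40 mV drive that the 10 ms membrane
  low-passes below threshold for any audio-band carrier (zero spikes,
  a dead front-end).  `lif_encode` therefore applies an explicit drive gain,
  default 100 mV/(MΩ·µA), chosen so that encoded speech-like signals land
  inside the reference range of 0.42–25.49 mean spikes per 25 ms frame
  observed for this kind of encoder on speech.
* **Endpoint detection** — amplitude normalization to max |x| = 1 and
  cropping to the smallest window of 10 ms frames whose energy reaches 1 %
  of the maximum frame energy (threshold configurable).
* **MFCC** — 25 ms Hamming frames at 100 fps, pre-emphasis α = 0.95,
  magnitude spectrum (512-point FFT), 26 triangular Mel filters over
  [0, fs/2], log compression, orthonormal DCT-II; c0 dropped, c1–c12
  returned.  Verified against an independent straight-line recomputation.
* **Rate coding** — per-channel spike count divided by the frame duration.

## Chain classifier

An utterance's frame sequence is split into `L` contiguous, near-equal
"grammar state" segments (remainder-first sizing: `(3,2,2,2,2)` for 11
frames and `L = 5`; sequences shorter than `L` repeat their final frame).
Each grammar state holds one one-vs-all KAARMA network per class (targets
±1, positives replicated three times at seeded random positions to offset
the 1-in-K imbalance); within a state the K final outputs pass through a
max-subtracted softmax, and a class's chain score is the product of its
per-state posteriors, accumulated in the log domain.  Chain transitions are
fixed (state i feeds state i+1 with probability 1); the argmax of the
product implements the MAP decision, ties to the lowest index.  A second
chain trained on frame-reversed sequences supplies a complementary grammar;
bi-directional fusion multiplies the two scores element-wise.

## Synthetic data

The generators replace a licensed speech corpus; their defaults are the
study conditions of the built-in benchmarks.

* **Tomita grammar strings** — uniform random binary strings labeled by
  membership in grammars 1–7 (e.g. #4 = no `000` substring), balanced by
  rejection sampling and shuffled so the class sequence is exchangeable
  (rejection fills one class quota first; an in-order single pass over an
  unshuffled list ends on a single-class run and biases the final model).
* **Spike words** — each of K classes owns a (12 channels × 4 segments)
  matrix of firing rates drawn once, uniformly from 10–200 Hz (0.25–5
  expected spikes per 25 ms channel-frame, inside the span observed for
  LIF-encoded speech); a word realizes the class profile as an inhomogeneous
  Poisson process over 0.415 s (40 analysis frames) with ±10 ms segment
  boundary jitter.  Words are therefore separable in principle but noisy in
  both spike timing and count.
* **Tone words** — class-specific three-tone "formant" stacks with gliding
  frequencies, for exercising the audio front-end.
* **Noise** — for continuous signals: white Gaussian, pink (power ∝ 1/f,
  spectrally shaped), and a babble surrogate (six amplitude-modulated
  multi-tone streams at syllabic rates), each scaled so the realized SNR
  matches the request exactly (full-signal power ratio).  The babble
  surrogate is *not* equivalent to recorded multi-speaker babble.  For spike
  trains the white-noise analog is a superimposed homogeneous Poisson train
  per channel with rate `λ_mean · 10^(−SNR/20)` — the flat-intensity point
  process playing the role of a flat-spectrum signal.

## Built-in studies and their problem sizes

* **Grammar inference** (Tomita #4): 1,000 training strings of length 3–15,
  one single-epoch pass, 200 held-out strings, five seeds.  Strings are
  presented as overlapping 3-symbol sliding windows with ±1 coding —
  the same frame-based presentation the speech pipeline uses (a speech
  "frame" is likewise an overlapping window of the signal, not a single
  sample).  This presentation matters: with one raw symbol per step,
  single-pass training plateaus near 70 % because the reject-evidence (a
  local trigram) must be both detected and latched from terminal-only
  supervision; with windowed frames the same network reaches 100 % held-out
  accuracy on all five seeds.  Network: `n_s = 4`, `a_s = a_u = 1`,
  `η = 0.05`, `ε = 0.005`.
* **Spike-word benchmark**: 5 classes × 100 words, stratified 67/33
  train/test split, `L = 5` bidirectional chain with the speech-setting
  parameters (`n_s = 3`, `a_s = 4`, `a_λ = 1`, `η = 0.1`, `ε = 0.25`), one
  epoch, five seeds.  The same runs supply the noise sweep (SNR 25, 15, 5,
  −5 dB point-process noise, clean-trained models) and the dictionary
  compaction statistics.
* **Compaction check**: one one-vs-all network of the chain retrained at
  `ε = 0.25` and `ε = 0` on its ≈4.3 k training frames.

These sizes keep the full suite and the acceptance script comfortably
reproducible on a single CPU.

## What the synthetic benchmarks do and do not show

The spike-word generator produces class-conditional inhomogeneous Poisson
processes with stationary per-segment rates.  Real speech spike trains have
speaker- and session-dependent rate ranges, strong cross-channel envelope
correlations, coarticulation between segments, and duration variation —
none of which the generator emulates.  Passing the built-in benchmarks
therefore demonstrates that the machinery (kernels, gradients, quantization,
chain scoring, fusion, noise protocol) is correct and that the system
separates spectrotemporally structured point processes under its reference
parameterization; it does not certify word-recognition accuracy on any real
corpus.  Likewise the noise sweep shows the qualitative robustness shape
(accuracy non-increasing as SNR falls), not corpus-level SNR curves.

## Numerical notes

* Kernel evaluations against the dictionary run as BLAS mat-vecs over a
  flattened, pre-padded center array with cached squared norms; squared
  distances are clipped at zero to absorb cancellation error.
* Frames are half-open `[k·stride, k·stride + T)`; a spike on a boundary
  belongs to the later frame.  Empty frames are valid everywhere (the
  all-`T` padded representation).
* Forward trajectories abort with a diagnostic if any state component
  exceeds 1e6 (divergence guard).
* Model containers are versioned JSON; reloading reproduces
  `decision_function` bit-for-bit (squared norms are recomputed with the
  same contraction order).
* The empty model is defined as the zero map, so training bootstraps from
  an empty dictionary (the first sequence seeds it).
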