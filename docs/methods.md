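# Methods

## Model

`dmnet` simulates networks of non-spiking point neurons with threshold-linear
(rectified-linear) dynamics,

    tau_t dV_i/dt = -V_i + sum_j w_ij f(V_j) + V_rest_t + e_i,      f(V) = max(V, 0),

integrated by first-order Euler with the time constant clamped at the step,
`tau = max(tau, dt)`.  The rectification models graded, voltage-gated
transmitter release; its threshold is fixed at 0 (the contrast and direction
indices downstream are defined for rectification at 0, and no protocol here
requires a free threshold).  External input `e_i` is nonzero only for
photoreceptor neurons, which receive the raw luminance of their column in
[0, 1]; whether the input should instead be mean-subtracted is not
observable in the statistics we compute, which are baseline-subtracted (receptive
fields) or contrast ratios (FRI, DSI).

Connectivity is compiled from cell-type filter tables on a hexagonal
retinotopic lattice in axial coordinates `(u, v)` (implicit third coordinate
`-(u+v)`; pointy-top Cartesian embedding; angle zero along +u).  A filter
entry `(pre_type, post_type, du, dv, N)` produces one connection for every
column pair at that offset with both endpoints instantiated, with weight

    w = alpha[pre_type, post_type] * sigma[pre_type, post_type] * N,

so within a type pair, weights are proportional to measured synapse counts
and a single non-negative unitary synapse strength `alpha` is the free
parameter.  Signs come from the sign table; counts are accepted as positive
reals (per-column averages).  Connections whose presynaptic column falls
outside the lattice are truncated, not wrapped: the lattice models a central
patch of the visual field and padding would fabricate synapses.

Free parameters of the fully constrained model: one `alpha` per connected
type pair, one time constant and one resting potential per type (Q + 2T
scalars; 734 for the fly tables with Q = 604, T = 65).  Initialization:
`tau = 50 ms`, `V_rest ~ N(0.5, 0.05)`, `alpha = 0.01 / <N>` with `<N>` the
mean synapse count over the pair's offsets.  Relaxed sharing schemes used
for constraint-ablation studies learn, instead: per-offset non-negative
magnitudes (counts unknown); magnitudes over a three-column window
(single-cell connectivity unknown; 19 offsets with |du|, |dv|, |du+dv| < 3);
per-presynaptic-type signs together with the alphas (signs unknown; the
sign enters the weight product as a trainable scalar initialized at +-1);
or fully signed per-offset weights.  Learned magnitudes and weights start
from N(0, 2/n_in) (magnitudes by absolute value), n_in the mean presynaptic
count per neuron.

## Simulation protocols

Every protocol starts from the steady state reached on a grey screen (the
state before the warmup is `V = V_rest`, the fixed point of the unconnected
system).  Stated integration steps: 5 ms for flashes and edges, 20 ms during
training.  Protocols: disc flashes of hex radius 6 and intensity 0 or 1 on
grey 0.5 (1 s warmup, 1 s flash); moving luminance step edges along 12
directions at 6 speeds (13.92-145 deg/s), sweeping -13.5 to +13.5 deg;
single-ommatidium flashes of 5-300 ms between 2 s and 5 s of grey.  One
column subtends 5.8 deg (the single-column receptive-field radius), which
converts angular speeds to lattice units.  Edges are hard binary steps
sampled at column centres; since the indices compare relative responses
across directions, edge softness is immaterial at this scale.  Augmentation
applies hex flips/rotations, Gaussian pixel noise (sigma 0.08, clamped at
0), and the contrast/brightness map `X' = c(X - 0.5) + 0.5 + cb` with
`log c ~ N(0, 0.04)`, `b ~ N(0, 0.01)`.

Numerical divergence (non-finite state) aborts with the offending step
rather than clipping: silently clipped voltages would corrupt every
statistic downstream.

## Tuning statistics

FRI = (r_on - r_off)/(r_on + r_off) from peak responses made non-negative by
adding the absolute global minimum over both contrasts; undefined (flagged
missing) if both peaks are zero.  DSI: rectified peak responses over
directions enter a complex vector sum, normalized per speed by the
max-over-intensity total response and averaged over speeds; zero-denominator
speeds are skipped so the average keeps its meaning.  The preferred
direction is the argument of the vector sum at the speed with the largest
sum.  The selectivity threshold is the 99% quantile of permutation-null
samples d* computed per condition from symmetric-input cell types (100
permutations), and a cell type counts as direction selective if the count
of ensemble members with DSI above threshold beats a one-sided binomial
null with p0 = 0.1 at alpha 0.05.  STRFs are baseline-subtracted at
stimulus onset; the SRF slices the STRF at the central-impulse extremum.
Cross-model averaging divides responses by the RMS of the cell's
naturalistic responses (models with zero RMS are excluded, not zeroed);
tuning-curve agreement is the maximum Pearson correlation over speeds, with
constant curves treated as missing rather than zero.

## Optic-flow task

The decoder maps the rectified voltages of the designated output types,
rastered to a Cartesian grid, through 5x5 conv (8 channels), batch norm,
softplus and dropout, then a second 5x5 conv to 3 channels; the third
channel, through a softplus, divides the other two (a learned shared
normalization -- the division form is our choice, and pluggable).  The
raster uses collision-free axial-to-offset rows, a shear of the true
embedding that preserves locality.  Filter weights start at 0.001.  The
loss is the L2 norm of the flow residual plus an activity regularizer
`R(V)`: a piecewise quadratic around a target `a` on time-averaged
central-column responses, weighted gamma = 1 below and delta = 0.01 above,
scaled by lambda_V = 0.1.  Training is backpropagation through time with
adaptive-moment SGD (beta1 0.9, beta2 0.999; full-scale schedule 5e-5 to
5e-6 in ten steps, batch 4, 19-frame clips at 24 Hz resampled to a 20 ms
step, flow targets linearly interpolated); non-negative buffers and time
constants are re-clamped after every step, and the grey steady state is
recomputed each epoch.  An optional phase updates the resting potentials by
plain SGD against `R(V)` alone.  Task error is the end-point error (EPE):
the mean Euclidean norm of the per-column flow residual.

Because all training here is gradient-based and `torch` is not a
dependency, the package carries a small reverse-mode autodiff engine over
numpy (`dmnet.autodiff`); every primitive's gradient is tested against
central finite differences, and the BPTT forward pass is tested to
reproduce the plain numpy simulator exactly.

## Synthetic data and desk-scale study conditions

The generators in `dmnet.fixtures` stand in for data that cannot be bundled:

* **Motion motif**: photoreceptor -> fast excitatory relay (same column) +
  slow inhibitory relay (one column over, tau ratio 4) -> detector.  The
  detector's preferred direction (centre toward flank) is ground-truth
  metadata; a mirrored motif flips it 180 deg and removing the inhibitory
  arm destroys selectivity.  Inhibition is weighted 10% over excitation and
  the detector rests at -0.05 a.u. so the sustained full-field response
  rectifies away and the rectified peak is dominated by the directional
  transient.  The four-flank **detector bank** (opponent directions 0, 60,
  180, 240 deg) is the minimal connectome on which 2-D flow decoding is
  well posed.
* **Drifting dataset**: rigidly drifting binary band patterns (wavelength 4
  columns, values 0.1/0.9) whose flow target is exactly the generating
  velocity.  Directions are evenly spaced with +-0.1 rad jitter and speeds
  (4 and 8 columns/s) cycled, so neither split carries a mean-flow bias a
  constant predictor could exploit; the speeds sit in the detectors'
  temporal passband (arm delay 60 ms, one-column flank), as the edge
  protocol's printed speeds (2.4-25 columns/s) do for the fly circuit.
  Train and validation draw from one seeded stream with distinct
  direction/phase combinations (no leakage).
* **Digit task**: ten smooth random templates (28x28) plus Gaussian noise
  (sigma 0.5), clipped to [0, 1], exactly class-balanced.  At sigma 0.5 a
  dense baseline classifier exceeds 90% held-out accuracy while the task is
  hard enough to constrain network function, which the identifiability
  study requires.

What these fixtures do not emulate: naturalistic image statistics (sparse
edges, 1/f spectra), optical blur across ommatidia, neuronal superposition,
and the real tables' per-type column coverage.  Tests passing on them show
the machinery is correct and the qualitative mechanisms operate; they do
not certify quantitative agreement with recordings.

Desk-scale training study (acceptance suite): radius-3 lattice, detector
bank, 24 training and 12 validation sequences, 300 iterations at lr 3e-3
to 3e-4, dropout 0, lambda_V = 0.  The joint run starts from the designed
operating point of the bank and trains biophysics plus decoder; the control
freezes the naive random-initialization parameters and trains the decoder
only (the random-parameter baseline analogue).  Starting the joint run from
the naive initialization is not informative at this scale: the initial
`alpha = 0.01/<N>` network is nearly silent and the task gradient cannot
shape it within a desk-scale budget (the full-scale recipe spends 250,000
iterations there), while the regularizer target `a = 5 a.u.` belongs to the
full-scale operating point and, imposed on the toy, simply bleaches the
inhibitory pairs.  The reported comparison -- trained-network decoding
beats decoder-on-uninformative-dynamics, and joint training strictly
reduces held-out EPE -- is the scaled-down form of the full-scale ordering.

## Identifiability experiment

Ground-truth networks: six hidden rectified layers, width 128, Dale's law
(one sign per presynaptic unit, including input pixels; non-negative
magnitudes clamped after every step), trained with adaptive-moment SGD
(max-variant), lr 1e-3 decaying 0.5 per epoch, then iteratively
magnitude-pruned (layer-local, 20% of survivors per round, readout never
pruned, fine-tuning between rounds and a consolidation retrain at the
target) to the requested connectivity.  Two initialization choices keep
deep Dale networks trainable and are applied throughout: per-unit balancing
of excitatory and inhibitory input sums at initialization, and centring of
the [0, 1] images (both remove a large common-mode drive that otherwise
silences whole layers at the rectifier -- an absorbing state under the
non-negativity clamp).

Measurement copies adjacency and signs; the with-strength regime adds
multiplicative uniform noise `eps ~ U(0.5, 1.5)` to the magnitudes.
Refitting freezes adjacency and signs and task-optimizes magnitudes and
biases; with strength measurements the magnitudes start at the noisy values
and a squared-distance penalty to them is weighted 10x the cross-entropy
(implemented as 10x the mean over existing connections, keeping the two
terms on comparable scales).  Refits restart the decayed learning-rate
schedule three times, which sparse masks need to reach convergence from a
random initialization.  Similarity is the median Pearson correlation of
rectified voltages of up to 100 sampled neurons per hidden layer over the
held-out stimulus set, pooled over layers and pairs; constant responders
are excluded and counted.

Desk scale: 10,000 training / 1,000 test images, batch 250, 6 epochs, three
ground-truth/refit pairs per density at 10/40/80% connectivity (about six
minutes on one CPU).  The full-scale quantitative values require the real
handwritten-digit corpus and longer training; the desk-scale run reproduces
the orderings (connectivity-only similarity decreasing in density;
with-strength above it everywhere, exceeding 0.9).

## Ensemble analysis

Per-model response vectors (central-column responses, RMS-normalized per
model) are embedded to 2-D -- the embedding is a pluggable deterministic
contract, UMAP by default, PCA provided -- and clustered with full-covariance
Gaussian mixtures, k in 2..5 chosen by BIC; the embedding is z-scored and
the mixtures use a 1e-3 covariance floor so duplicate or degenerate points
cannot buy likelihood spikes.  Maximally excitatory stimulus search takes
the dataset argmax of the central cell's peak response; the regularized
variant minimizes `sum_n ||V(X*) - V(X')||^2 + (1/C) sum ||X' - 0.5||^2` by
gradient descent on the stimulus with backtracking (accepted steps never
increase the objective) and clipping to [0, 1].

## Known limitations

Scaled-down studies demonstrate orderings and mechanisms, not the printed
full-scale values.  Euler at 20 ms is first-order; halving `dt` is tested to
shrink the error but protocol statistics are computed at the stated steps.
The real fly filter/sign/coverage tables are external supplementary data:
the loaders accept them (CSV schema in `dmnet.connectome`), but the bundled
fixtures are synthetic and labelled as such.  Electrical synapses,
adaptation, and multi-compartment structure beyond a two-entry compartment
split are out of scope.
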