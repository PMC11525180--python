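"""Tuning statistics: contrast and direction selectivity, permutation nulls,
receptive fields, cross-model normalization and tuning-curve correlation.

All statistics are computed from central-column voltage traces of one cell
type under the standard protocols (circular flashes, moving edges,
single-ommatidium flashes):

* **FRI** (flash response index): normalized difference of non-negative peak
  responses to ON vs OFF disc flashes; sign gives the preferred contrast.
* **DSI** (direction selectivity index): magnitude of the complex vector sum
  of rectified peak responses over 12 motion directions, normalized by the
  maximum-over-intensity total response at each speed and averaged over
  speeds.
* A permutation null for the DSI of cell types with spatially symmetric
  inputs yields the selectivity threshold (99% quantile), and a one-sided
  binomial test across an ensemble decides whether a type counts as
  direction selective.
* **STRF/SRF/TRF** from single-ommatidium impulse responses, baseline
  subtracted at stimulus onset.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "measure_fri",
    "measure_edge_peaks",
    "PeakResponse",
    "ReceptiveField",
    "fri",
    "peak_responses",
    "dsi",
    "preferred_direction",
    "permutation_null",
    "classify_direction_selective",
    "receptive_fields",
    "normalize_for_averaging",
    "tuning_correlation",
    "select_models",
]


def measure_fri(network, params, cell_type: str, dt: float = 5.0,
                flash_radius: int = 6, **flash_kwargs):
    """Run the circular-flash protocol on one cell type and return its FRI."""
    from .dynamics import SimConfig, simulate
    from .stimuli import circular_flash

    nid = network.central_neuron(cell_type)
    cfg = SimConfig(dt=dt, record=np.array([nid]))
    radius = min(flash_radius, network.lattice.radius)
    traces = {
        I: simulate(network, params,
                    circular_flash(network.lattice, I, radius=radius, dt=dt,
                                   **flash_kwargs), cfg).data[:, 0]
        for I in (1.0, 0.0)
    }
    return fri(traces[1.0], traces[0.0])


def measure_edge_peaks(network, params, cell_type: str, intensities=(0.0, 1.0),
                       speeds=None, directions_deg=None, dt: float = 5.0) -> "PeakResponse":
    """Run the moving-edge battery and collect rectified peak responses."""
    from .dynamics import SimConfig, simulate
    from .stimuli import EDGE_ANGLES, EDGE_SPEEDS, moving_edge

    speeds = EDGE_SPEEDS if speeds is None else tuple(speeds)
    directions_deg = EDGE_ANGLES if directions_deg is None else tuple(directions_deg)
    nid = network.central_neuron(cell_type)
    cfg = SimConfig(dt=dt, record=np.array([nid]))
    r = np.empty((len(intensities), len(speeds), len(directions_deg)))
    for i, I in enumerate(intensities):
        for s, S in enumerate(speeds):
            for a, th in enumerate(directions_deg):
                trace = simulate(network, params,
                                 moving_edge(network.lattice, th, S, I, dt=dt), cfg)
                r[i, s, a] = max(np.max(trace.data[:, 0]), 0.0)
    return PeakResponse(r=r, intensities=tuple(intensities), speeds=speeds,
                        directions_deg=directions_deg)


@dataclass
class PeakResponse:
    """Rectified peak responses r[intensity, speed, direction] >= 0."""

    r: np.ndarray                  # (n_intensities, n_speeds, n_directions)
    intensities: tuple
    speeds: tuple
    directions_deg: tuple

    def __post_init__(self):
        if (self.r < 0).any():
            raise ValueError("peak responses must be non-negative")


def peak_responses(traces: np.ndarray, intensities, speeds, directions_deg) -> PeakResponse:
    """Rectify voltages and take the max over time.

    `traces` has shape (n_intensities, n_speeds, n_directions, n_time).
    """
    r = np.maximum(np.asarray(traces), 0.0).max(axis=-1)
    return PeakResponse(r=r, intensities=tuple(intensities), speeds=tuple(speeds),
                        directions_deg=tuple(directions_deg))


def fri(trace_on: np.ndarray, trace_off: np.ndarray) -> float | None:
    """Flash response index in [-1, 1]; None if both peaks are zero.

    Peaks are made non-negative by adding the absolute global minimum over
    both contrasts: r_peak(I) = max_n V[n](I) + |min_{n,I} V[n](I)|.
    """
    trace_on = np.asarray(trace_on, dtype=float)
    trace_off = np.asarray(trace_off, dtype=float)
    offset = abs(min(trace_on.min(), trace_off.min()))
    r_on = trace_on.max() + offset
    r_off = trace_off.max() + offset
    denom = r_on + r_off
    if denom == 0:
        return None
    return float((r_on - r_off) / denom)


def _vector_sum(r_theta: np.ndarray, theta_rad: np.ndarray) -> complex:
    return complex(np.sum(r_theta * np.exp(1j * theta_rad)))


def dsi(peaks: PeakResponse, intensity) -> float:
    """Direction selectivity index for one intensity, averaged over speeds.

    Speeds whose normalizer (max-over-intensity total response) is zero are
    skipped and the average taken over the remaining speeds.
    """
    i = peaks.intensities.index(intensity)
    theta = np.deg2rad(peaks.directions_deg)
    vals = []
    for s in range(len(peaks.speeds)):
        denom = max(abs(peaks.r[j, s, :].sum()) for j in range(len(peaks.intensities)))
        if denom == 0:
            continue
        vals.append(abs(_vector_sum(peaks.r[i, s, :], theta)) / denom)
    return float(np.mean(vals)) if vals else 0.0


def preferred_direction(peaks: PeakResponse, intensity) -> float:
    """Argument (deg, in [0, 360)) of the vector sum at the best speed."""
    i = peaks.intensities.index(intensity)
    theta = np.deg2rad(peaks.directions_deg)
    sums = [_vector_sum(peaks.r[i, s, :], theta) for s in range(len(peaks.speeds))]
    best = int(np.argmax([abs(z) for z in sums]))
    ang = float(np.rad2deg(np.angle(sums[best])) % 360.0)
    return 0.0 if ang >= 360.0 - 1e-9 else ang


def permutation_null(sym_peaks: list[PeakResponse], n_perm: int = 100,
                     quantile: float = 0.99, seed: int = 0):
    """Null DSI samples d* from angle permutations of symmetric-input types.

    For each (intensity, speed) condition of each supplied peak table and
    each of `n_perm` independent permutations theta* of the direction axis,
    d* = |sum_theta* r exp(i theta)| / |sum_theta r|.  Returns (samples,
    threshold) with the threshold the pooled `quantile` quantile.
    """
    if not sym_peaks:
        raise ValueError("need at least one symmetric cell type")
    rng = np.random.default_rng(seed)
    samples = []
    for peaks in sym_peaks:
        theta = np.deg2rad(peaks.directions_deg)
        n_dir = len(theta)
        for _ in range(n_perm):
            perm = rng.permutation(n_dir)
            for i in range(len(peaks.intensities)):
                for s in range(len(peaks.speeds)):
                    r = peaks.r[i, s, :]
                    denom = abs(r.sum())
                    if denom == 0:
                        continue
                    samples.append(abs(np.sum(r[perm] * np.exp(1j * theta))) / denom)
    samples = np.array(samples)
    threshold = float(np.quantile(samples, quantile)) if len(samples) else np.nan
    return samples, threshold


def classify_direction_selective(dsis: np.ndarray, threshold: float,
                                 p0: float = 0.1, alpha: float = 0.05):
    """One-sided binomial test: is P(DSI > threshold) greater than p0?

    Returns (selective, p_value) over the per-model DSI samples of one type.
    """
    dsis = np.asarray(dsis, dtype=float)
    k = int((dsis > threshold).sum())
    res = stats.binomtest(k, len(dsis), p=p0, alternative="greater")
    return bool(res.pvalue < alpha), float(res.pvalue)


@dataclass
class ReceptiveField:
    """Spatio-temporal receptive field and its spatial/temporal slices."""

    strf: np.ndarray       # (n_time, n_offsets), baseline-subtracted voltage
    offsets: np.ndarray    # (n_offsets, 2) flashed-column coordinates (u, v)
    dt: float
    extremum_step: int = field(init=False)

    def __post_init__(self):
        centre = self._centre_index()
        self.extremum_step = int(np.argmax(np.abs(self.strf[:, centre])))

    def _centre_index(self) -> int:
        hits = np.flatnonzero((self.offsets[:, 0] == 0) & (self.offsets[:, 1] == 0))
        if len(hits) != 1:
            raise ValueError("offsets must include the central column exactly once")
        return int(hits[0])

    @property
    def srf(self) -> np.ndarray:
        """Spatial receptive field: STRF sliced at the central-flash extremum."""
        return self.strf[self.extremum_step]

    @property
    def trf(self) -> np.ndarray:
        """Temporal receptive field: central-column impulse time course."""
        return self.strf[:, self._centre_index()]


def receptive_fields(traces: np.ndarray, offsets, dt: float) -> ReceptiveField:
    """Build STRF/SRF/TRF from per-offset single-ommatidium flash traces.

    `traces` has shape (n_offsets, n_time): the central cell's voltage when
    the flash is delivered at each offset column.  Baseline subtraction uses
    the first recorded step, so STRF[0] == 0.
    """
    traces = np.asarray(traces, dtype=float)
    strf = (traces - traces[:, :1]).T  # (time, offsets)
    return ReceptiveField(strf=strf, offsets=np.asarray(offsets, dtype=int), dt=dt)


def normalize_for_averaging(trace: np.ndarray, naturalistic: np.ndarray):
    """Divide a response by the RMS of the cell's naturalistic responses.

    Returns (normalized trace, excluded flag); excluded (and unscaled) when
    the RMS is zero, mirroring the model-exclusion rule used before
    cross-model averaging.
    """
    nat = np.asarray(naturalistic, dtype=float)
    rms = float(np.sqrt(np.mean(nat**2)))
    if rms == 0:
        return np.asarray(trace, dtype=float), True
    return np.asarray(trace, dtype=float) / rms, False


def tuning_correlation(model_curves: np.ndarray, reference: np.ndarray) -> float:
    """Max over speeds of the Pearson correlation with a reference curve.

    `model_curves` is (n_speeds, n_directions); speeds with constant curves
    (undefined correlation) are skipped; nan if all are.
    """
    model_curves = np.atleast_2d(np.asarray(model_curves, dtype=float))
    reference = np.asarray(reference, dtype=float)
    best = np.nan
    for s in range(model_curves.shape[0]):
        x = model_curves[s]
        if len(x) < 3 or np.std(x) == 0 or np.std(reference) == 0:
            continue
        r = float(stats.pearsonr(x, reference).statistic)
        best = r if np.isnan(best) else max(best, r)
    return best


def _angdiff(a: float, b: float) -> float:
    return abs((a - b + 180.0) % 360.0 - 180.0)


def select_models(results: list[dict], targets: dict) -> list:
    """Filter ensemble members against reference tuning.

    `results` holds one dict per model with per-type entries
    ``{"fri": x, "dsi": y, "pd": deg}``; `targets` maps type name to
    ``{"fri_sign": +-1, "dsi_threshold": d, "pd": deg, "pd_tol": 45.0}``
    (any key may be omitted to skip that criterion).  Returns the indices of
    models passing every criterion for every listed type.
    """
    keep = []
    for idx, model in enumerate(results):
        ok = True
        for tname, crit in targets.items():
            got = model.get(tname)
            if got is None:
                ok = False
                break
            if "fri_sign" in crit and np.sign(got.get("fri", 0.0)) != crit["fri_sign"]:
                ok = False
                break
            if "dsi_threshold" in crit and not got.get("dsi", 0.0) > crit["dsi_threshold"]:
                ok = False
                break
            if "pd" in crit and _angdiff(got.get("pd", np.nan), crit["pd"]) > crit.get("pd_tol", 45.0):
                ok = False
                break
        if ok:
            keep.append(idx)
    return keep
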