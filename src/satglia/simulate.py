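"""Synthetic generators for every input the analysis pipeline consumes.

Each generator emits data with the statistical structure the corresponding
analysis assumes, with known ground-truth parameters, so every estimator in
the package can be exercised closed-loop without external recordings:

* 3D soma fields at striatal densities (Poisson, hard-core or lattice
  placement) and their slab-sampled 2D section tables;
* pacemaker / bursting spike-train rasters with a programmed light response
  (rate multiplier after a programmed latency);
* current-step voltage traces with programmed passive and active membrane
  parameters (input resistance, sag, AP threshold / amplitude / half-width,
  AHP, interspike intervals);
* Nernstian electrode calibration tables;
* step-response fluorescence series with a programmed peak dF/F.

All generators are deterministic under a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd

from .ephys import CurrentStep, TrialRaster, VoltageTrace
from .field import CellField
from .sensors import FluorescenceSeries
from .spatial import DensitySpec, PackingInfeasibleError, SomaGeometry

__all__ = [
    "SpikeTrainConfig",
    "TraceConfig",
    "generate_cell_field",
    "sample_section",
    "generate_spike_trains",
    "generate_current_step_traces",
    "generate_calibration_points",
    "generate_fluorescence_series",
    "CALIBRATION_CONCS_MM",
]

CALIBRATION_CONCS_MM = (0.0, 0.1, 0.2, 0.4, 0.8, 1.2, 1.6, 2.0)

_TYPE_RADII = {"pSPN": "r_spn", "astrocyte": "r_astro", "ChI": "r_chi"}


# ---------------------------------------------------------------------------
# cell fields and sections
# ---------------------------------------------------------------------------

def _type_densities(spec: DensitySpec) -> dict[str, float]:
    return {"pSPN": spec.spn_density, "astrocyte": spec.astro_density,
            "ChI": spec.chi_density}


def generate_cell_field(spec: DensitySpec = DensitySpec(),
                        geometry: SomaGeometry = SomaGeometry(),
                        box: tuple[float, float, float] = (400.0, 400.0, 60.0),
                        process: str = "poisson",
                        seed: int = 0,
                        max_attempts: int = 1_000_000) -> CellField:
    """Place pSPN, astrocyte and ChI somata in a box at the given densities.

    ``process`` selects the placement model: ``poisson`` (independent
    uniform), ``hardcore`` (dart throwing; no two somata closer than their
    summed radii) or ``lattice`` (each type on its own jittered cubic
    lattice with spacing density**(-1/3)).
    """
    rng = np.random.default_rng(seed)
    vol = box[0] * box[1] * box[2]
    densities = _type_densities(spec)
    radii = {t: getattr(geometry, attr) for t, attr in _TYPE_RADII.items()}

    rows: list[tuple[str, float, float, float, float]] = []
    if process == "poisson":
        for ctype, lam in densities.items():
            n = rng.poisson(lam * vol)
            pos = rng.uniform(0.0, 1.0, (n, 3)) * np.asarray(box)
            rows.extend((ctype, *p, radii[ctype]) for p in pos)
    elif process == "hardcore":
        # place large somata first; greedy rejection against all placed
        order = sorted(densities, key=lambda t: -radii[t])
        placed_pos = np.empty((0, 3))
        placed_rad = np.empty(0)
        attempts = 0
        for ctype in order:
            n = rng.poisson(densities[ctype] * vol)
            r = radii[ctype]
            for _ in range(n):
                while True:
                    if attempts >= max_attempts:
                        raise PackingInfeasibleError(
                            f"hard-core packing failed after {attempts} "
                            "attempts")
                    cand = rng.uniform(0.0, 1.0, 3) * np.asarray(box)
                    attempts += 1
                    if placed_pos.size:
                        d = np.linalg.norm(placed_pos - cand, axis=1)
                        if np.any(d < placed_rad + r):
                            continue
                    break
                placed_pos = np.vstack([placed_pos, cand])
                placed_rad = np.append(placed_rad, r)
                rows.append((ctype, *cand, r))
    elif process == "lattice":
        for ctype, lam in densities.items():
            spacing = lam ** (-1.0 / 3.0)
            origin = rng.uniform(0.0, spacing, 3)
            axes = [np.arange(origin[i], box[i], spacing) for i in range(3)]
            X, Y, Z = np.meshgrid(*axes, indexing="ij")
            for p in zip(X.ravel(), Y.ravel(), Z.ravel()):
                rows.append((ctype, *p, radii[ctype]))
    else:
        raise ValueError(f"unknown process {process!r}")

    cells = pd.DataFrame(rows,
                         columns=["cell_type", "x", "y", "z", "radius"])
    return CellField(box=box, cells=cells, process=process, seed=seed,
                     meta={"densities": densities})


def sample_section(field: CellField, slab_thickness: float = 30.0,
                   margin: float = 0.0,
                   z_center: float | None = None) -> pd.DataFrame:
    """Slab-sample a 3D field into a 2D section table.

    Cells whose z-centre falls within the effective thickness
    ``slab_thickness - 2 * margin`` (centred on ``z_center``) are kept and
    projected to x/y; soma area is the equatorial circle pi * r**2.  The
    margin models the requirement that a nucleus be identifiable inside the
    imaged stack.
    """
    t_eff = slab_thickness - 2.0 * margin
    if t_eff <= 0:
        raise ValueError("effective slab thickness must be positive")
    if z_center is None:
        z_center = field.box[2] / 2.0
    lo, hi = z_center - t_eff / 2.0, z_center + t_eff / 2.0
    if lo < 0 or hi > field.box[2]:
        raise ValueError("slab does not fit inside the field box")

    cells = field.cells
    keep = cells[(cells["z"] >= lo) & (cells["z"] < hi)]
    if keep.empty:
        raise ValueError("no cells fall inside the slab")
    return pd.DataFrame({
        "cell_id": [f"{t}_{i:05d}" for i, t in
                    zip(keep.index, keep["cell_type"])],
        "cell_type": keep["cell_type"].to_numpy(),
        "x_um": keep["x"].to_numpy(float),
        "y_um": keep["y"].to_numpy(float),
        "soma_area_um2": math.pi * keep["radius"].to_numpy(float) ** 2,
    })


# ---------------------------------------------------------------------------
# spike trains
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SpikeTrainConfig:
    """Ground-truth parameters for simulated ChI spike trains.

    The regular (pacemaker) pattern is a gamma-renewal process with the
    stated rate and coefficient of variation; bursting alternates
    exponentially-distributed burst and silence epochs with Poisson firing
    inside bursts.  During the light epoch, after the programmed latency,
    the instantaneous rate is multiplied by ``light_multiplier``.
    """

    baseline_rate_hz: float = 6.0
    cv: float = 0.2
    light_multiplier: float = 1.0
    latency_ms: float = 0.0
    pattern: str = "regular"  # regular | bursting
    burst_rate_hz: float = 20.0
    burst_duration_s: float = 0.5
    silence_duration_s: float = 1.0
    trial_duration_s: float = 4.0
    light_onset_s: float = 2.0
    light_duration_s: float = 0.5

    def __post_init__(self) -> None:
        if self.baseline_rate_hz < 0 or self.cv < 0:
            raise ValueError("rate and CV must be non-negative")
        if self.pattern not in ("regular", "bursting"):
            raise ValueError(f"unknown pattern {self.pattern!r}")


def _warped_renewal(rng: np.random.Generator, breaks: np.ndarray,
                    rates: np.ndarray, shape_k: float) -> np.ndarray:
    """Renewal process with piecewise-constant intensity via time rescaling.

    Unit-rate gamma-renewal arrivals (shape ``shape_k``, mean interval 1)
    are generated in operational time and mapped back through the inverse
    of the cumulative intensity, which is piecewise linear.
    """
    seg = np.diff(breaks) * rates
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    total = cum[-1]
    if total <= 0:
        return np.empty(0)
    # draw enough intervals to exceed the operational horizon
    arrivals: list[float] = []
    t_op = 0.0
    while t_op < total:
        t_op += rng.gamma(shape_k, 1.0 / shape_k)
        if t_op < total:
            arrivals.append(t_op)
    if not arrivals:
        return np.empty(0)
    return np.interp(np.asarray(arrivals), cum, breaks)


def _rate_profile(cfg: SpikeTrainConfig,
                  rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Breakpoints and per-segment rates for one trial."""
    T = cfg.trial_duration_s
    t_on = min(T, cfg.light_onset_s + cfg.latency_ms / 1000.0)
    t_off = min(T, t_on + cfg.light_duration_s)

    if cfg.pattern == "regular":
        base_breaks = [0.0, T]
        base_rates = [cfg.baseline_rate_hz]
    else:
        # alternating burst/silence epochs, exponential durations
        base_breaks = [0.0]
        base_rates = []
        bursting = rng.random() < (cfg.burst_duration_s /
                                   (cfg.burst_duration_s +
                                    cfg.silence_duration_s))
        t = 0.0
        while t < T:
            mean = (cfg.burst_duration_s if bursting
                    else cfg.silence_duration_s)
            t = min(T, t + rng.exponential(mean))
            base_breaks.append(t)
            base_rates.append(cfg.burst_rate_hz if bursting else 0.0)
            bursting = not bursting

    # overlay the light-epoch multiplier
    breaks = sorted(set(base_breaks) | {t_on, t_off})
    rates = []
    for a, b in zip(breaks[:-1], breaks[1:]):
        mid = (a + b) / 2.0
        j = np.searchsorted(base_breaks, mid) - 1
        r = base_rates[min(j, len(base_rates) - 1)]
        if t_on <= mid < t_off:
            r *= cfg.light_multiplier
        rates.append(r)
    return np.asarray(breaks), np.asarray(rates)


def generate_spike_trains(cfg: SpikeTrainConfig = SpikeTrainConfig(),
                          n_trials: int = 20, seed: int = 0,
                          neuron_id: str = "sim") -> TrialRaster:
    """Simulate a raster of light-stimulation trials for one neuron."""
    rng = np.random.default_rng(seed)
    shape_k = 1.0 if cfg.cv == 0 else 1.0 / (cfg.cv * cfg.cv)
    trials = []
    for _ in range(n_trials):
        breaks, rates = _rate_profile(cfg, rng)
        trials.append(_warped_renewal(rng, breaks, rates, shape_k))
    return TrialRaster(
        neuron_id=neuron_id, trials=tuple(trials),
        light_onset=cfg.light_onset_s, light_duration=cfg.light_duration_s,
        trial_duration=cfg.trial_duration_s)


# ---------------------------------------------------------------------------
# current-step voltage traces
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TraceConfig:
    """Ground-truth membrane parameters for simulated step traces.

    The AP waveform is a stereotyped piecewise-linear template scaled to
    the programmed threshold, amplitude, half-width and AHP, inserted at
    programmed interspike intervals on the suprathreshold step; this gives
    the property-extraction code exact ground truth rather than biophysics.
    """

    rin_mohm: float = 150.0
    base_mv: float = -60.0
    sag_fraction: float = 0.75  # steady / trough deflection on -200 pA
    tau_sag_s: float = 0.03
    tau_membrane_s: float = 0.01
    ap_threshold_mv: float = -40.0
    ap_amplitude_mv: float = 65.0
    ap_halfwidth_ms: float = 1.5
    ahp_mv: float = 15.0
    supra_isis_s: tuple[float, ...] = (0.1, 0.15)
    first_spike_delay_s: float = 0.05
    spont_rate_hz: float = 6.0
    ramp_slope_mv_per_ms: float = 5.0
    noise_sd_mv: float = 0.0


def _ap_template(cfg: TraceConfig, fs: float,
                 resting_mv: float) -> np.ndarray:
    """Stereotyped AP waveform starting at threshold, ending at
    ``resting_mv`` after the AHP.

    Linear rise/fall around the peak (so the half-width is exactly
    (rise + fall) / 2), then a linear drop into a parabolic AHP trough
    whose vertex sits on the sample grid at exactly
    ``threshold - ahp_mv``, then a slow linear recovery.  The parabola
    joins the drop with matched slope and keeps all upward slopes well
    below the 10 mV/ms spike-detection criterion.
    """
    dt = 1.0 / fs
    snap = lambda x: round(x * fs) / fs  # noqa: E731
    thr = cfg.ap_threshold_mv
    peak = thr + cfg.ap_amplitude_mv
    trough = thr - cfg.ahp_mv
    # triangle rise tr / fall tf around the peak: half-width = (tr + tf) / 2
    tr = snap(0.6 * cfg.ap_halfwidth_ms / 1000.0)
    tf = snap(1.4 * cfg.ap_halfwidth_ms / 1000.0)
    delta = min(2.0, cfg.ahp_mv / 2.0)  # parabola depth below its edges, mV
    drop_slope = 5.0  # mV/ms, below the detection criterion
    t_drop = snap((cfg.ahp_mv - delta) / drop_slope / 1000.0)
    half_w = snap(2.0 * delta / drop_slope / 1000.0)  # slope-matched join
    t_rec = 0.020

    t1 = tr
    t2 = t1 + tf
    t3 = t2 + t_drop  # enters the parabola at trough + delta
    tv = t3 + half_w  # vertex (grid-aligned)
    t4 = tv + half_w
    t5 = t4 + t_rec
    t = np.arange(0.0, t5 + 0.5 * dt, dt)

    v = np.empty_like(t)
    seg = t <= t1
    v[seg] = thr + (peak - thr) * t[seg] / max(t1, dt)
    seg = (t > t1) & (t <= t2)
    v[seg] = peak + (thr - peak) * (t[seg] - t1) / max(tf, dt)
    seg = (t > t2) & (t <= t3)
    v[seg] = thr + (trough + delta - thr) * (t[seg] - t2) / max(t_drop, dt)
    seg = (t > t3) & (t <= t4)
    v[seg] = trough + delta * ((t[seg] - tv) / max(half_w, dt)) ** 2
    seg = t > t4
    v[seg] = (trough + delta
              + (resting_mv - trough - delta) * (t[seg] - t4) / t_rec)
    return v


def _insert_spikes(v: np.ndarray, fs: float, cfg: TraceConfig,
                   spike_times_s: np.ndarray, resting_mv: float) -> None:
    """Insert ramp + AP template at each spike time (template start)."""
    template = _ap_template(cfg, fs, resting_mv)
    ramp_s = max(0.0, (cfg.ap_threshold_mv - resting_mv)
                 / cfg.ramp_slope_mv_per_ms / 1000.0)
    n_ramp = int(round(ramp_s * fs))
    for t_sp in spike_times_s:
        i0 = int(round(t_sp * fs))
        if n_ramp:
            ramp = np.linspace(resting_mv, cfg.ap_threshold_mv,
                               n_ramp + 1)[:-1]
            a = i0 - n_ramp
            if a >= 0:
                v[a:i0] = ramp
        j = min(v.size, i0 + template.size)
        v[i0:j] = template[:j - i0]


def generate_current_step_traces(
        cfg: TraceConfig = TraceConfig(),
        amplitudes_pa: tuple[float, ...] = (-200.0, -100.0, -50.0, -25.0,
                                            0.0, 25.0, 50.0, 100.0),
        sampling_rate: float = 20_000.0,
        pre_s: float = 0.2, step_s: float = 0.75, post_s: float = 0.2,
        seed: int = 0) -> list[VoltageTrace]:
    """Simulate a square current-step protocol for one cell.

    Hyperpolarizing steps jump to a trough ``steady / sag_fraction`` and
    relax exponentially to the steady level (the sag).  Depolarizing
    subthreshold steps charge exponentially to ``Rin * I``.  The
    suprathreshold step (+100 pA by default) carries AP templates at the
    programmed interspike intervals; the 0 pA trace carries spontaneous
    spikes at the programmed rate.
    """
    fs = sampling_rate
    rng = np.random.default_rng(seed)
    n_pre = int(round(pre_s * fs))
    n_step = int(round(step_s * fs))
    n_post = int(round(post_s * fs))
    n_tot = n_pre + n_step + n_post
    t_step = np.arange(n_step) / fs
    supra_amp = max(amplitudes_pa)

    traces = []
    for amp in amplitudes_pa:
        v = np.full(n_tot, cfg.base_mv)
        steady = cfg.rin_mohm * amp / 1000.0  # mV
        sl = slice(n_pre, n_pre + n_step)
        if amp < 0:
            trough = steady / cfg.sag_fraction
            v[sl] = (cfg.base_mv + steady
                     + (trough - steady) * np.exp(-t_step / cfg.tau_sag_s))
        elif amp > 0:
            v[sl] = (cfg.base_mv
                     + steady * (1.0 - np.exp(-t_step / cfg.tau_membrane_s)))
        if amp != 0 and n_post:
            # smooth relaxation at step offset keeps the derivative well
            # below the spike-detection slope criterion
            t_post = np.arange(n_post) / fs
            v_end = v[n_pre + n_step - 1]
            v[n_pre + n_step:] = (cfg.base_mv + (v_end - cfg.base_mv)
                                  * np.exp(-t_post / cfg.tau_membrane_s))
        if amp == 0 and cfg.spont_rate_hz > 0:
            period = 1.0 / cfg.spont_rate_hz
            times = np.arange(period / 2.0, n_tot / fs - 0.05, period)
            _insert_spikes(v, fs, cfg, times, cfg.base_mv)
        elif amp == supra_amp and amp > 0:
            resting = cfg.base_mv + steady
            t0 = pre_s + cfg.first_spike_delay_s
            times = t0 + np.concatenate([[0.0],
                                         np.cumsum(cfg.supra_isis_s)])
            _insert_spikes(v, fs, cfg, times, resting)
        if cfg.noise_sd_mv > 0:
            v = v + rng.normal(0.0, cfg.noise_sd_mv, n_tot)
        traces.append(VoltageTrace(
            sampling_rate=fs, voltage=v,
            step=CurrentStep(amplitude_pa=amp, onset_s=pre_s,
                             duration_s=step_s)))
    return traces


# ---------------------------------------------------------------------------
# sensor inputs
# ---------------------------------------------------------------------------

def generate_calibration_points(slope: float = 30.4, intercept: float = 0.0,
                                noise_sd: float = 0.0,
                                concs_mm: tuple[float, ...] =
                                CALIBRATION_CONCS_MM,
                                seed: int = 0,
                                zero_floor_mv: float | None = None
                                ) -> pd.DataFrame:
    """Nernstian calibration readings V = slope * log10(c) + intercept.

    The 0 mM solution gets a floor reading (default: the model potential at
    0.02 mM) since the log response saturates at the electrode's detection
    limit.
    """
    rng = np.random.default_rng(seed)
    if zero_floor_mv is None:
        zero_floor_mv = slope * math.log10(0.02) + intercept
    rows = []
    for c in concs_mm:
        if c > 0:
            v = slope * math.log10(c) + intercept
            if noise_sd > 0:
                v += rng.normal(0.0, noise_sd)
        else:
            v = zero_floor_mv
        rows.append((c, v))
    return pd.DataFrame(rows, columns=["conc_mM", "potential_mV"])


def generate_fluorescence_series(f0: float = 100.0, peak_dff: float = 0.3,
                                 onset_s: float = 2.0,
                                 decay_tau_s: float = 1.0,
                                 duration_s: float = 10.0,
                                 frame_rate: float = 10.0,
                                 background_level: float = 50.0,
                                 noise_sd: float = 0.0,
                                 seed: int = 0) -> FluorescenceSeries:
    """Step-and-decay sensor response with a programmed peak dF/F.

    The background-subtracted intensity is ``f0`` at baseline and jumps to
    ``f0 * (1 + peak_dff)`` at ``onset_s``, decaying exponentially back
    with ``decay_tau_s``.
    """
    if f0 <= 0:
        raise ValueError("f0 must be positive")
    rng = np.random.default_rng(seed)
    t = np.arange(int(round(duration_s * frame_rate))) / frame_rate
    resp = np.where(t >= onset_s,
                    peak_dff * np.exp(-(t - onset_s) / decay_tau_s), 0.0)
    signal = f0 * (1.0 + resp) + background_level
    background = np.full(t.size, background_level)
    if noise_sd > 0:
        signal = signal + rng.normal(0.0, noise_sd, t.size)
        background = background + rng.normal(0.0, noise_sd, t.size)
    return FluorescenceSeries(frame_rate=frame_rate, signal=signal,
                              background=background, f0_window_s=1.0)
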