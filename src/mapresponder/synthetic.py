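"""Synthetic cohorts for corticomotor mapping studies.

The generator emulates the data a two-session (baseline / Day-2) TMS mapping
experiment produces: per-participant corticomotor excitability surfaces over a
5 x 7 cm scalp grid, pseudorandom stimulation sessions with multiplicative
lognormal trial-to-trial MEP variability, peri-stimulus EMG sweeps, and
behavioural outcome tables (PPT, NRS pain ratings, soreness, pain area, LEFS,
MVIC, single-leg hop) whose pressure-pain-threshold change is negatively
coupled to the programmed map-volume change.

Experimental participants fall into facilitation (map gain > 1), depression
(gain < 1) or no-change regimes; controls draw their Day-2 gain from a narrow
band around 1.  All randomness flows through an explicitly passed
``numpy.random.Generator`` — there is no global state, and a fixed seed yields
a byte-identical cohort.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal

from .emg import EMGFrame
from .mapping import GridSpec, StimulationEvent, build_map, percent_change

__all__ = [
    "ExcitabilitySurface",
    "ParticipantScenario",
    "FrameSpec",
    "simulate_surface",
    "simulate_session",
    "simulate_emg_frame",
    "simulate_outcomes",
    "slope_for_target_r",
    "make_scenarios",
    "generate_cohort",
    "true_map_metrics",
]

OUTCOME_NAMES = (
    "ppt_kpa",
    "nrs_rest",
    "nrs_reach",
    "nrs_drag",
    "soreness",
    "pain_area",
    "lefs",
    "mvic_nm",
    "hop_cm",
)

#: Day-2 outcome levels the generator targets, per group: (mean, sd, low, high).
#: Control pain outcomes concentrate at zero with an occasional 1 (mild DOMS
#: from the non-painful protocol); soreness is an integer 0-6 Likert scale.
_DAY2_PAIN_LEVELS = {
    "experimental": {
        "nrs_rest": (1.3, 1.2, 0.0, 10.0),
        "nrs_reach": (5.4, 2.5, 0.0, 10.0),
        "nrs_drag": (3.4, 2.1, 0.0, 10.0),
        "soreness": (4.5, 1.8, 0.0, 6.0),
        "pain_area": (25.9, 16.6, 0.0, np.inf),
    },
    "control": {
        "nrs_rest": None,  # exactly zero
        "nrs_reach": 0.2,  # Bernoulli(p): mean .2, SD .4
        "nrs_drag": None,
        "soreness": 0.2,
        "pain_area": 0.2,
    },
}


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def _trunc_normal(rng, mean, sd, low, high, size=None):
    """Normal draw redrawn into [low, high] (rejection; falls back to clip)."""
    x = rng.normal(mean, sd, size=size)
    bad = (x < low) | (x > high)
    for _ in range(100):
        if not np.any(bad):
            break
        x = np.where(bad, rng.normal(mean, sd, size=np.shape(x)), x)
        bad = (x < low) | (x > high)
    return np.clip(x, low, high)


@dataclass(frozen=True)
class ExcitabilitySurface:
    """Gaussian-bump model of a corticomotor representation.

    ``S(x, y) = floor + peak_amplitude * exp(-((x-cx)^2 + (y-cy)^2) / (2 spread^2))``

    in mV as a function of scalp position (cm).  ``floor`` keeps the surface
    strictly positive so every grid site yields a measurable response.
    """

    peak_amplitude: float
    center: tuple[float, float]
    spread: float
    floor: float = 0.05

    def __post_init__(self) -> None:
        if self.peak_amplitude <= 0 or self.spread <= 0 or self.floor < 0:
            raise ValueError("peak_amplitude and spread must be > 0, floor >= 0")

    def value(self, x, y):
        cx, cy = self.center
        return self.floor + self.peak_amplitude * np.exp(
            -((np.asarray(x) - cx) ** 2 + (np.asarray(y) - cy) ** 2) / (2 * self.spread**2)
        )


@dataclass(frozen=True)
class ParticipantScenario:
    """Ground-truth parameters for one simulated participant.

    ``day2_gain`` multiplies the peak amplitude at Day 2 (facilitation > 1,
    depression < 1), ``day2_shift`` translates the representation (cm), and
    ``ppt_slope`` couples the pressure pain threshold change (kPa) to the true
    percent map-volume change.
    """

    participant_id: str
    group: str  # "experimental" | "control"
    baseline_surface: ExcitabilitySurface
    day2_gain: float = 1.0
    day2_spread_factor: float = 1.0
    day2_shift: tuple[float, float] = (0.0, 0.0)
    trial_noise_sigma: float = 0.15
    ppt_slope: float = -0.6  # kPa per % map-volume change
    ppt_noise_sd: float = 80.0
    regime: str = "none"  # bookkeeping: facilitation | depression | none

    def __post_init__(self) -> None:
        if self.group not in ("experimental", "control"):
            raise ValueError(f"unknown group {self.group!r}")
        if self.day2_gain <= 0 or self.day2_spread_factor <= 0:
            raise ValueError("day2_gain and day2_spread_factor must be > 0")
        if self.trial_noise_sigma < 0:
            raise ValueError("trial_noise_sigma must be >= 0")


@dataclass(frozen=True)
class FrameSpec:
    """Geometry of one simulated EMG sweep (2 kHz sampling by default)."""

    sampling_rate: float = 2000.0
    pre_ms: float = 100.0
    post_ms: float = 100.0
    # 10%-MVC background level; its peak-to-peak (~4.6x RMS over the MEP
    # window) must stay below 25% of typical map peaks or the noise floor
    # masquerades as active cortex in low-amplitude (depressed) sessions
    background_rms_mv: float = 0.02
    mep_onset_ms: float = 20.0
    mep_duration_ms: float = 15.0

    @property
    def n_pre(self) -> int:
        return int(round(self.pre_ms * self.sampling_rate / 1000.0))

    @property
    def n_post(self) -> int:
        return int(round(self.post_ms * self.sampling_rate / 1000.0))


def simulate_surface(
    scenario: ParticipantScenario, timepoint: str
) -> ExcitabilitySurface:
    """Noise-free excitability surface of a scenario at a timepoint.

    Baseline returns the base surface; Day 2 applies the programmed gain,
    spread factor and center shift.
    """
    if timepoint == "baseline":
        return scenario.baseline_surface
    if timepoint == "day2":
        base = scenario.baseline_surface
        dx, dy = scenario.day2_shift
        cx, cy = base.center
        return replace(
            base,
            peak_amplitude=base.peak_amplitude * scenario.day2_gain,
            spread=base.spread * scenario.day2_spread_factor,
            center=(cx + dx, cy + dy),
        )
    raise ValueError(f"unknown timepoint {timepoint!r}")


def simulate_session(
    surface: ExcitabilitySurface,
    grid: GridSpec | None = None,
    n_stimuli: int = 90,
    seed=None,
    trial_noise_sigma: float = 0.15,
    jitter_cm: float = 0.2,
    amplitude_floor_mv: float = 0.02,
) -> list[StimulationEvent]:
    """Simulate one pseudorandom mapping session over the stimulation grid.

    Every grid site receives at least one stimulus; the remaining pulses are
    spread uniformly over sites.  Coordinates are jittered up to ``jitter_cm``
    around site centers (clipped to the grid), and each MEP amplitude is
    ``S(x, y) * eps`` with ``eps ~ LogNormal(0, sigma^2)``, floored at the
    discernibility floor.
    """
    grid = grid or GridSpec()
    rng = _as_rng(seed)
    sites = grid.site_coordinates()
    n_sites = len(sites)
    if n_stimuli < n_sites:
        raise ValueError(
            f"n_stimuli={n_stimuli} cannot cover all {n_sites} grid sites"
        )

    extra = rng.integers(0, n_sites, size=n_stimuli - n_sites)
    site_idx = np.concatenate([np.arange(n_sites), extra])
    rng.shuffle(site_idx)

    coords = sites[site_idx] + rng.uniform(-jitter_cm, jitter_cm, size=(n_stimuli, 2))
    ox, oy = grid.origin
    coords[:, 0] = np.clip(coords[:, 0], ox, ox + grid.width_cm)
    coords[:, 1] = np.clip(coords[:, 1], oy, oy + grid.height_cm)

    s = surface.value(coords[:, 0], coords[:, 1])
    if trial_noise_sigma > 0:
        eps = rng.lognormal(mean=0.0, sigma=trial_noise_sigma, size=n_stimuli)
    else:
        eps = np.ones(n_stimuli)
    amps = np.maximum(s * eps, amplitude_floor_mv)

    return [
        StimulationEvent(x=float(coords[i, 0]), y=float(coords[i, 1]),
                         amplitude=float(amps[i]), trial=i)
        for i in range(n_stimuli)
    ]


def _mep_waveform(n_samples: int, spec: FrameSpec) -> np.ndarray:
    """Unit peak-to-peak biphasic waveform (derivative of a Gaussian)."""
    fs = spec.sampling_rate
    t = np.arange(n_samples) / fs * 1000.0  # ms after stimulus
    t_c = spec.mep_onset_ms + spec.mep_duration_ms / 2.0
    s = spec.mep_duration_ms / 6.0
    w = -(t - t_c) * np.exp(-((t - t_c) ** 2) / (2 * s**2))
    ptp = w.max() - w.min()
    return w / ptp


def simulate_emg_frame(
    amplitude: float,
    frame_spec: FrameSpec | None = None,
    seed=None,
    participant_id: str = "",
    timepoint: str = "",
    trial: int = 0,
) -> EMGFrame:
    """Synthesize one peri-stimulus EMG sweep.

    Band-limited (20-950 Hz) background contraction noise at the frame spec's
    RMS level is summed with a biphasic MEP whose peak-to-peak amplitude
    equals ``amplitude`` (mV), onset at ``mep_onset_ms`` after the stimulus.
    """
    if amplitude < 0:
        raise ValueError("MEP amplitude must be >= 0")
    spec = frame_spec or FrameSpec()
    rng = _as_rng(seed)
    n_pre, n_post = spec.n_pre, spec.n_post
    n = n_pre + n_post

    samples = np.zeros(n)
    if spec.background_rms_mv > 0:
        white = rng.standard_normal(n)
        sos = signal.butter(
            4, [20.0, 0.95 * spec.sampling_rate / 2], btype="bandpass",
            fs=spec.sampling_rate, output="sos",
        )
        bg = signal.sosfiltfilt(sos, white)
        rms = np.sqrt(np.mean(bg**2))
        samples += bg / rms * spec.background_rms_mv
    if amplitude > 0:
        samples[n_pre:] += amplitude * _mep_waveform(n_post, spec)

    return EMGFrame(
        samples=samples, sampling_rate=spec.sampling_rate, stim_onset_index=n_pre,
        participant_id=participant_id, timepoint=timepoint, trial=trial,
    )


def slope_for_target_r(
    target_r: float, sd_delta_volume: float, sd_ppt_noise: float
) -> float:
    """PPT slope (kPa per %) yielding population correlation ``target_r``.

    Under ``dPPT = slope * dV + eps`` with ``dV ~ (.., sd_delta_volume^2)`` and
    ``eps ~ (0, sd_ppt_noise^2)``, the population Pearson correlation is
    ``slope * sd_dV / sqrt(slope^2 sd_dV^2 + sd_eps^2)``; inverting gives
    ``slope = r / sqrt(1 - r^2) * sd_eps / sd_dV``.
    """
    if not -1 < target_r < 1:
        raise ValueError("target_r must lie strictly inside (-1, 1)")
    if sd_delta_volume <= 0 or sd_ppt_noise < 0:
        raise ValueError("scale parameters must be positive")
    return target_r / math.sqrt(1 - target_r**2) * sd_ppt_noise / sd_delta_volume


def simulate_outcomes(
    scenario: ParticipantScenario, true_delta_volume: float, seed=None
) -> dict[str, dict[str, float]]:
    """Draw the behavioural outcome panel for one participant.

    Returns ``{"baseline": {...}, "day2": {...}}`` over the outcome names in
    :data:`OUTCOME_NAMES`.  The Day-2 PPT change is
    ``ppt_slope * true_delta_volume + Normal(0, ppt_noise_sd)``; Day-2 pain and
    function outcomes are drawn from group-level truncated distributions
    (instrument ranges: NRS 0-10, soreness 0-6, LEFS 0-80), with control pain
    outcomes at or near zero.
    """
    rng = _as_rng(seed)
    exp = scenario.group == "experimental"

    base = {
        "ppt_kpa": float(_trunc_normal(rng, 600.0, 150.0, 100.0, np.inf)),
        "nrs_rest": 0.0,
        "nrs_reach": 0.0,
        "nrs_drag": 0.0,
        "soreness": 0.0,
        "pain_area": 0.0,
        "lefs": float(np.round(_trunc_normal(rng, 77.5, 5.9, 0.0, 80.0))),
        "mvic_nm": float(_trunc_normal(rng, 103.0, 41.0, 10.0, np.inf)),
        "hop_cm": float(_trunc_normal(rng, 150.0, 25.0, 50.0, np.inf)),
    }

    d_ppt = scenario.ppt_slope * true_delta_volume + rng.normal(0.0, scenario.ppt_noise_sd)
    day2 = {"ppt_kpa": max(base["ppt_kpa"] + d_ppt, 10.0)}

    levels = _DAY2_PAIN_LEVELS["experimental" if exp else "control"]
    if exp:
        for name, (m, sd, lo, hi) in levels.items():
            day2[name] = float(_trunc_normal(rng, m, sd, lo, hi))
        day2["soreness"] = float(np.round(day2["soreness"]))
        day2["lefs"] = float(np.round(_trunc_normal(rng, 51.4, 17.5, 0.0, 80.0)))
        day2["mvic_nm"] = float(_trunc_normal(rng, 60.8, 41.2, 10.0, np.inf))
    else:
        for name, p in levels.items():
            day2[name] = float(rng.random() < p) if p is not None else 0.0
        day2["lefs"] = float(np.round(_trunc_normal(rng, 77.5, 5.9, 0.0, 80.0)))
        day2["mvic_nm"] = float(_trunc_normal(rng, 103.2, 41.2, 10.0, np.inf))
    day2["hop_cm"] = float(max(base["hop_cm"] + rng.normal(0.0, 8.0), 50.0))

    return {"baseline": base, "day2": day2}


def true_map_metrics(
    scenario: ParticipantScenario, grid: GridSpec | None = None, n_stimuli: int = 90
) -> dict[str, float]:
    """Programmed (noise-free) map metrics and their baseline→Day-2 changes.

    Builds noise-free maps from both timepoints' surfaces with a fixed session
    layout, giving the ground truth against which recovered metrics and
    responder labels are judged.
    """
    grid = grid or GridSpec()
    out: dict[str, float] = {}
    maps = {}
    for tp in ("baseline", "day2"):
        surf = simulate_surface(scenario, tp)
        events = simulate_session(
            surf, grid, n_stimuli=n_stimuli, seed=0, trial_noise_sigma=0.0, jitter_cm=0.0
        )
        maps[tp] = build_map(events, grid)
    out["true_delta_volume_pct"] = percent_change(maps["baseline"].volume, maps["day2"].volume)
    out["true_delta_area_pct"] = percent_change(maps["baseline"].area, maps["day2"].area)
    dx, dy = scenario.day2_shift
    out["true_ed_cm"] = float(np.hypot(dx, dy))
    return out


def make_scenarios(
    n_experimental: int = 26,
    n_control: int = 10,
    seed=None,
    regime_weights: tuple[float, float, float] = (12 / 26, 12 / 26, 2 / 26),
    grid: GridSpec | None = None,
    trial_noise_sigma: float = 0.15,
    ppt_slope: float | None = None,
) -> list[ParticipantScenario]:
    """Draw a cohort of participant scenarios.

    Experimental participants are assigned facilitation / depression /
    no-change regimes in the proportions ``regime_weights`` (largest-remainder
    apportionment, order shuffled).  Facilitation centers the Day-2 gain on
    x2 and depression on x0.5, each with multiplicative lognormal spread;
    no-change and control gains sit in a narrow band around 1
    (Normal(1, 0.05) truncated positive).  Day-2 center shifts average 1.2 cm
    for the experimental group and 0.4 cm for controls.
    """
    rng = _as_rng(seed)
    grid = grid or GridSpec()
    ox, oy = grid.origin
    gcx, gcy = ox + grid.width_cm / 2, oy + grid.height_cm / 2

    counts = _apportion(n_experimental, regime_weights)
    regimes = (
        ["facilitation"] * counts[0] + ["depression"] * counts[1] + ["none"] * counts[2]
    )
    rng.shuffle(regimes)
    if ppt_slope is None:
        # default coupling targets a strong (~ -0.56) volume-PPT correlation
        # for the heavy-tailed experimental delta-volume mix (SD ~ 120 %)
        ppt_slope = slope_for_target_r(-0.56, 120.0, 80.0)

    scenarios: list[ParticipantScenario] = []
    specs = [("experimental", i, regimes[i]) for i in range(n_experimental)]
    specs += [("control", i, "none") for i in range(n_control)]
    for group, i, regime in specs:
        spread = float(_trunc_normal(rng, 0.9, 0.1, 0.4, 2.0))
        bx0, bx1, by0, by1 = _interior_box(spread, grid)
        base = ExcitabilitySurface(
            peak_amplitude=float(_trunc_normal(rng, 1.2, 0.3, 0.4, np.inf)),
            center=(
                float(np.clip(gcx + rng.normal(0.0, 0.3), bx0, bx1)),
                float(np.clip(gcy + rng.normal(0.0, 0.3), by0, by1)),
            ),
            spread=spread,
        )
        # regimes scale both peak (gain) and spatial extent (spread factor):
        # map volume tracks the product, map area tracks the spread squared
        if group == "experimental":
            if regime == "facilitation":
                gain = 2.0 * float(rng.lognormal(0.0, 0.35))
                spread_factor = 1.25 * float(rng.lognormal(0.0, 0.15))
            elif regime == "depression":
                gain = 0.5 * float(rng.lognormal(0.0, 0.35))
                spread_factor = 0.8 * float(rng.lognormal(0.0, 0.15))
            else:
                gain = float(_trunc_normal(rng, 1.0, 0.05, 0.01, np.inf))
                spread_factor = float(_trunc_normal(rng, 1.0, 0.05, 0.5, 2.0))
            shift_mag = float(_trunc_normal(rng, 1.2, 0.8, 0.0, 3.0))
        else:
            gain = float(_trunc_normal(rng, 1.0, 0.05, 0.01, np.inf))
            spread_factor = float(_trunc_normal(rng, 1.0, 0.05, 0.5, 2.0))
            shift_mag = float(_trunc_normal(rng, 0.4, 0.1, 0.0, 3.0))
        shift = _shift_within_grid(rng, base, shift_mag, grid)
        scenarios.append(
            ParticipantScenario(
                participant_id=f"{'E' if group == 'experimental' else 'C'}{i + 1:02d}",
                group=group,
                baseline_surface=base,
                day2_gain=gain,
                day2_spread_factor=spread_factor,
                day2_shift=shift,
                trial_noise_sigma=trial_noise_sigma,
                ppt_slope=ppt_slope,
                regime=regime,
            )
        )
    return scenarios


def _interior_box(spread: float, grid: GridSpec) -> tuple[float, float, float, float]:
    """Interior region keeping the suprathreshold bump inside the grid.

    The active region of a Gaussian bump extends about ``sqrt(2 ln 4)`` ~ 1.67
    spreads from its center (where the surface crosses 25% of peak); centers
    are kept at least that margin from every edge, capped so the box never
    collapses.
    """
    ox, oy = grid.origin
    margin = 1.67 * spread
    mx = min(margin, grid.width_cm / 2 - 0.7)
    my = min(margin, grid.height_cm / 2 - 0.5)
    return ox + mx, ox + grid.width_cm - mx, oy + my, oy + grid.height_cm - my


def _shift_within_grid(
    rng: np.random.Generator,
    base: ExcitabilitySurface,
    magnitude: float,
    grid: GridSpec,
    max_tries: int = 32,
) -> tuple[float, float]:
    """Displacement of ``magnitude`` cm keeping the shifted bump on the grid.

    A uniform direction is resampled until the shifted center stays inside the
    interior box; failing that, the final direction is truncated at the box
    boundary (large programmed shifts near an edge realize slightly shorter).
    """
    cx, cy = base.center
    x0, x1, y0, y1 = _interior_box(base.spread, grid)
    angle = 0.0
    for _ in range(max_tries):
        angle = rng.uniform(0, 2 * np.pi)
        dx, dy = magnitude * math.cos(angle), magnitude * math.sin(angle)
        if x0 <= cx + dx <= x1 and y0 <= cy + dy <= y1:
            return (dx, dy)
    ux, uy = math.cos(angle), math.sin(angle)
    t = magnitude
    if ux > 0:
        t = min(t, (x1 - cx) / ux)
    elif ux < 0:
        t = min(t, (x0 - cx) / ux)
    if uy > 0:
        t = min(t, (y1 - cy) / uy)
    elif uy < 0:
        t = min(t, (y0 - cy) / uy)
    t = max(t, 0.0)
    return (t * ux, t * uy)


def _apportion(n: int, weights) -> list[int]:
    """Integer counts summing to n, proportional to weights (largest remainder)."""
    w = np.asarray(weights, dtype=float)
    w = w / w.sum()
    raw = w * n
    counts = np.floor(raw).astype(int)
    rem = n - counts.sum()
    order = np.argsort(-(raw - counts))
    counts[order[:rem]] += 1
    return counts.tolist()


def generate_cohort(
    scenarios: list[ParticipantScenario],
    grid: GridSpec | None = None,
    n_stimuli: int = 90,
    seed=None,
    with_emg: bool = False,
    frame_spec: FrameSpec | None = None,
):
    """Simulate the full two-session dataset for a cohort.

    Returns a dict with:

    ``events``
        ``{(participant_id, timepoint): [StimulationEvent, ...]}``
    ``frames``
        same keys → list of :class:`~mapresponder.emg.EMGFrame` (only when
        ``with_emg`` is true; each frame realizes its event's amplitude)
    ``outcomes``
        ``{participant_id: {"baseline": {...}, "day2": {...}}}``
    ``truth``
        ``{participant_id: {"group", "regime", true metric dict...}}``

    Child seeds are spawned deterministically per participant/stage from the
    single ``seed``, so a fixed seed reproduces the cohort exactly.
    """
    grid = grid or GridSpec()
    ss = np.random.SeedSequence(seed if isinstance(seed, int) else None) \
        if not isinstance(seed, np.random.SeedSequence) else seed
    frame_spec = frame_spec or FrameSpec()

    events: dict[tuple[str, str], list[StimulationEvent]] = {}
    frames: dict[tuple[str, str], list[EMGFrame]] = {}
    outcomes: dict[str, dict] = {}
    truth: dict[str, dict] = {}

    children = ss.spawn(len(scenarios))
    for scenario, child in zip(scenarios, children):
        rng = np.random.default_rng(child)
        tm = true_map_metrics(scenario, grid, n_stimuli)
        for tp in ("baseline", "day2"):
            surf = simulate_surface(scenario, tp)
            evts = simulate_session(
                surf, grid, n_stimuli=n_stimuli, seed=rng,
                trial_noise_sigma=scenario.trial_noise_sigma,
            )
            events[(scenario.participant_id, tp)] = evts
            if with_emg:
                frames[(scenario.participant_id, tp)] = [
                    simulate_emg_frame(
                        ev.amplitude, frame_spec, seed=rng,
                        participant_id=scenario.participant_id, timepoint=tp,
                        trial=ev.trial,
                    )
                    for ev in evts
                ]
        outcomes[scenario.participant_id] = simulate_outcomes(
            scenario, tm["true_delta_volume_pct"], seed=rng
        )
        truth[scenario.participant_id] = {
            "group": scenario.group, "regime": scenario.regime, **tm,
        }

    return {"events": events, "frames": frames, "outcomes": outcomes, "truth": truth}
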