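"""Synthetic multiple-fission movie generator with full ground truth.

Emulates two/three-channel time-lapse movies of a *Chlamydomonas*-like cell
going through 0-3 rounds of multiple fission, providing known answers for
every analysis stage:

* chloroplast autofluorescence in a red reference channel, bleeding into the
  reporter channel at a fixed per-frame green-per-red ratio ``true_F``;
* a nuclear reporter (cyclin B-like) that accumulates linearly for ~20 min
  and is degraded exponentially with a ~3 min half-life, reaching baseline
  ~1.2 min before each division; divisions ~30 min apart;
* EB1-like microtubule structures: an anterior polar dot that splits into
  two foci (PS), a bipolar spindle crossing the cell midline ~4 min later
  (SP) with a ~4 min lifetime (SPB), and a cleavage-furrow line
  perpendicular to the former spindle axis (CF); cortical comets that are
  suppressed while a spindle is present;
* Poisson photon noise plus additive Gaussian read noise.

Cells are rendered as circles; divisions are synchronous among siblings and
the analysed footprint remains the mother outline throughout, matching how
real movies are quantified.  All randomness derives from a single master
seed through named child streams, so identical seeds give byte-identical
movies.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np

from .movie_io import Movie

PRESETS = ("wildtype", "apc_mutant", "cycb1_mutant", "cdkb1_mutant")


# ---------------------------------------------------------------------------
# parameter bundles
# ---------------------------------------------------------------------------
@dataclass
class KineticParams:
    """Reporter accumulation/degradation kinetics, all times in minutes.

    The trace is piecewise per division cycle: baseline until onset, a
    linear rise of ``accumulation_duration`` at ``accumulation_rate``, then
    exponential decay with half-life ``degradation_halflife`` until the
    amplitude has fallen to ``decay_end_fraction`` of the peak, at which
    point it snaps to baseline (the trough).  Division follows the trough by
    ``trough_to_division``.  With ``degradation_disabled`` the trace rises
    and then plateaus indefinitely (APC-inactivated behaviour); with
    ``accumulation_disabled`` it stays at baseline.
    """

    baseline: float = 2000.0
    onset_time: float = 5.0
    accumulation_duration: float = 20.0
    accumulation_rate: float = 5000.0
    degradation_halflife: float = 3.0
    trough_to_division: float = 1.2
    inter_division_interval: float = 30.0
    n_divisions: int = 1
    decay_end_fraction: float = 0.15
    degradation_disabled: bool = False
    accumulation_disabled: bool = False

    def __post_init__(self) -> None:
        if self.n_divisions < 0:
            raise ValueError("n_divisions must be >= 0")
        if self.trough_to_division < 0:
            raise ValueError("trough_to_division must be >= 0")
        for name in ("accumulation_duration", "degradation_halflife",
                     "inter_division_interval"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not 0 < self.decay_end_fraction < 1:
            raise ValueError("decay_end_fraction must be in (0, 1)")

    @property
    def peak_amplitude(self) -> float:
        return self.accumulation_rate * self.accumulation_duration

    @property
    def decay_duration(self) -> float:
        """Minutes from peak until the trace snaps to baseline."""
        return self.degradation_halflife * math.log2(1.0 / self.decay_end_fraction)

    def cycle_span(self) -> float:
        return self.accumulation_duration + self.decay_duration + self.trough_to_division


@dataclass
class EB1Params:
    """Geometry and schedule of EB1-like structures (px, px/min, min, a.u.)."""

    dot_radius: float = 2.0
    dot_intensity: float = 12000.0
    initial_pole_separation: float = 10.0
    pole_separation_speed: float = 2.0
    pole_split_to_spindle: float = 4.0
    spindle_lifetime: float = 4.0
    spindle_length_frac: float = 1.2   # x cell radius
    spindle_width: float = 3.0
    spindle_intensity: float = 15000.0
    spb_to_cf: float = 1.5
    furrow_persistence: float = 2.0
    furrow_intensity: float = 12000.0
    comet_rate: float = 6.0            # expected comets per frame
    comet_radius: float = 1.5
    comet_intensity: float = 5000.0    # well below spindle/dot brightness
    diffuse_level: float = 30.0        # cytosolic EB1 pool, counts per px
    diffuse_suppression: float = 0.3   # fraction remaining while a spindle exists

    def __post_init__(self) -> None:
        if self.spindle_lifetime <= 0:
            raise ValueError("spindle_lifetime must be > 0")


@dataclass
class NoiseParams:
    """Poisson-Gaussian camera model: shot noise on expected counts plus
    additive Gaussian read noise of ``read_sigma`` counts."""

    read_sigma: float = 5.0
    poisson: bool = True

    @classmethod
    def noiseless(cls) -> "NoiseParams":
        return cls(read_sigma=0.0, poisson=False)


@dataclass
class SceneParams:
    """Rendering geometry and per-scene configuration.

    The cell is a circle of ``cell_radius`` px centred in the image, with a
    cup-shaped chloroplast occupying the posterior (brightest at the
    posterior rim) and the nucleus in the anterior clear zone.  ``true_F``
    is the green-per-red bleed-through ratio applied uniformly.
    """

    image_size: int = 128
    cell_radius: float = 40.0
    nucleus_radius: float = 8.0
    af_cell_level: float = 800.0       # autofluorescence across the whole body
    af_cup_level: float = 1200.0       # extra in the chloroplast cup
    true_F: float = 1.5
    reporter: str = "cyclin"           # "cyclin" or "eb1"
    brightfield: bool = False
    bf_level: float = 1000.0
    eb1: EB1Params = field(default_factory=EB1Params)
    noise: NoiseParams = field(default_factory=NoiseParams)
    preset: str = "wildtype"

    def __post_init__(self) -> None:
        if self.true_F <= 0:
            raise ValueError("true_F must be > 0")
        if self.nucleus_radius >= self.cell_radius:
            raise ValueError("nucleus_radius must be < cell_radius")
        if self.preset not in PRESETS:
            raise ValueError(f"unknown preset {self.preset!r}")
        if self.reporter not in ("cyclin", "eb1"):
            raise ValueError("reporter must be 'cyclin' or 'eb1'")


@dataclass
class CycleEvents:
    """True mitotic event times (minutes) for one division cycle.

    Any entry may be ``None`` when the preset forbids the event.
    """

    cycle: int
    PS: float | None = None
    SP: float | None = None
    SPB: float | None = None
    CF: float | None = None


@dataclass
class GroundTruth:
    """Simulator-side truth for every analysis stage."""

    times: np.ndarray                  # frame times, minutes
    true_trace: np.ndarray             # noiseless total reporter per frame
    cycles: list                       # list of CycleEvents
    division_times: list               # minutes, one per completed division
    trace_landmarks: list              # dicts: onset/peak/trough/division per cycle
    true_F: float
    frame_interval: float
    comet_counts: np.ndarray

    def event_frame(self, cycle: int, event: str) -> int | None:
        """First frame index at or after the true event time."""
        t = getattr(self.cycles[cycle], event)
        if t is None:
            return None
        return int(np.searchsorted(self.times, t - 1e-9))

    def to_json(self) -> str:
        d = {
            "times": self.times.tolist(),
            "true_trace": self.true_trace.tolist(),
            "cycles": [asdict(c) for c in self.cycles],
            "division_times": list(self.division_times),
            "trace_landmarks": self.trace_landmarks,
            "true_F": self.true_F,
            "frame_interval": self.frame_interval,
            "comet_counts": self.comet_counts.tolist(),
        }
        return json.dumps(d, indent=2)


# ---------------------------------------------------------------------------
# kinetic trace
# ---------------------------------------------------------------------------
def trace_schedule(k: KineticParams) -> list[dict]:
    """Onset/peak/trough/division times (min) for each cycle.

    With degradation disabled there is a single open-ended cycle (no trough,
    no division); with accumulation disabled the schedule is empty.
    """
    if k.accumulation_disabled:
        return []
    if k.degradation_disabled:
        return [{
            "onset": k.onset_time,
            "peak": k.onset_time + k.accumulation_duration,
            "trough": None,
            "division": None,
        }]
    if k.n_divisions == 0:
        return []
    if k.n_divisions >= 2 and k.cycle_span() > k.inter_division_interval:
        raise ValueError(
            "inconsistent durations: accumulation + decay + trough_to_division "
            f"({k.cycle_span():.1f} min) exceed inter_division_interval "
            f"({k.inter_division_interval:.1f} min)"
        )
    first_division = k.onset_time + k.cycle_span()
    out = []
    for c in range(k.n_divisions):
        division = first_division + c * k.inter_division_interval
        trough = division - k.trough_to_division
        peak = trough - k.decay_duration
        onset = peak - k.accumulation_duration
        out.append({"onset": onset, "peak": peak, "trough": trough, "division": division})
    return out


def simulate_trace(k: KineticParams, times: Sequence[float]) -> np.ndarray:
    """Evaluate the deterministic (noise-free) reporter trace at ``times``.

    ``times`` must be strictly increasing.  Returns total reporter signal in
    arbitrary units; constant ``baseline`` when there are no divisions.
    """
    t = np.asarray(times, dtype=float)
    if t.ndim != 1 or t.size == 0:
        raise ValueError("times must be a non-empty 1-D sequence")
    if np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing")
    y = np.full(t.shape, float(k.baseline))
    for cyc in trace_schedule(k):
        onset, peak = cyc["onset"], cyc["peak"]
        rise = (t >= onset) & (t < peak)
        y[rise] = k.baseline + k.accumulation_rate * (t[rise] - onset)
        if cyc["trough"] is None:
            y[t >= peak] = k.baseline + k.peak_amplitude
        else:
            decay = (t >= peak) & (t < cyc["trough"])
            y[decay] = k.baseline + k.peak_amplitude * np.exp2(
                -(t[decay] - peak) / k.degradation_halflife
            )
    return y


# ---------------------------------------------------------------------------
# event schedule
# ---------------------------------------------------------------------------
def event_schedule(scene: SceneParams, k: KineticParams) -> list[CycleEvents]:
    """True PS/SP/SPB/CF times per cycle for the given preset.

    Wild type anchors mitosis to the division: CF coincides with division,
    SPB precedes CF by ``spb_to_cf``, the spindle lives ``spindle_lifetime``
    and pole splitting precedes the spindle by ``pole_split_to_spindle``.
    The APC-inactivated preset reaches PS and SP (anchored to the reporter
    peak) but the spindle never breaks down; cyclin/CDK loss-of-function
    presets produce no events at all.
    """
    e = scene.eb1
    if scene.preset in ("cycb1_mutant", "cdkb1_mutant"):
        return []
    if scene.preset == "apc_mutant":
        peak = k.onset_time + k.accumulation_duration
        ps = peak
        return [CycleEvents(cycle=0, PS=ps, SP=ps + e.pole_split_to_spindle)]
    cycles = []
    for c, cyc in enumerate(trace_schedule(k)):
        if cyc["division"] is None:
            continue
        cf = cyc["division"]
        spb = cf - e.spb_to_cf
        sp = spb - e.spindle_lifetime
        ps = sp - e.pole_split_to_spindle
        if not ps < sp < spb <= cf:
            raise ValueError("event schedule violates PS < SP < SPB <= CF")
        cycles.append(CycleEvents(cycle=c, PS=ps, SP=sp, SPB=spb, CF=cf))
    return cycles


# ---------------------------------------------------------------------------
# rendering primitives
# ---------------------------------------------------------------------------
def _grid(n: int):
    yy, xx = np.mgrid[0:n, 0:n].astype(float)
    return yy, xx


def _soft_disk(yy, xx, center, radius, power: float = 4.0) -> np.ndarray:
    """Radially decreasing profile, exactly zero outside ``radius``."""
    d2 = (yy - center[0]) ** 2 + (xx - center[1]) ** 2
    r = np.sqrt(d2) / radius
    prof = np.clip(1.0 - r ** power, 0.0, None)
    return prof


def _gauss_dot(yy, xx, center, sigma, amp) -> np.ndarray:
    """Compact dot: Gaussian core truncated to zero beyond 3 sigma.

    Compact support keeps rendered structures entirely inside the
    thresholded peak mask, so cytoplasm-region totals carry no skirt
    leakage from bright structures.
    """
    d2 = (yy - center[0]) ** 2 + (xx - center[1]) ** 2
    prof = np.exp(-d2 / (2.0 * sigma ** 2))
    prof[d2 > (3.0 * sigma) ** 2] = 0.0
    return amp * prof


def _bar(yy, xx, center, angle, length, width, amp) -> np.ndarray:
    """Compact bar through ``center`` at ``angle`` (radians, from +x axis)."""
    dy = yy - center[0]
    dx = xx - center[1]
    # coordinates along / across the bar axis (image y points down)
    u = dx * math.cos(angle) + dy * math.sin(angle)
    v = -dx * math.sin(angle) + dy * math.cos(angle)
    along = np.clip(np.abs(u) - length / 2.0, 0.0, None)
    across = np.abs(v)
    sig_across = width / 2.0
    prof = np.exp(-(along ** 2) / 2.0) * np.exp(-(across ** 2) / (2.0 * sig_across ** 2))
    prof[(along > 3.0) | (across > 3.0 * sig_across)] = 0.0
    return amp * prof


class _SceneGeometry:
    """Static geometry shared by all frames of one movie."""

    def __init__(self, scene: SceneParams):
        n = scene.image_size
        self.yy, self.xx = _grid(n)
        self.center = ((n - 1) / 2.0, (n - 1) / 2.0)
        cy, cx = self.center
        R = scene.cell_radius
        d = np.sqrt((self.yy - cy) ** 2 + (self.xx - cx) ** 2)
        self.cell_mask = d <= R
        # anterior is -y (top of image); cup = cell minus an anterior clear zone
        hole = np.sqrt((self.yy - (cy - 0.5 * R)) ** 2 + (self.xx - cx) ** 2) <= 0.75 * R
        self.cup_mask = self.cell_mask & ~hole
        posteriorness = np.clip((self.yy - cy) / R, 0.0, 1.0)
        self.red_clean = (
            scene.af_cell_level * self.cell_mask
            + scene.af_cup_level * (1.0 + posteriorness) * self.cup_mask
        )
        self.R = R


def _compartment_centers(geom: _SceneGeometry, n_done: int) -> list[tuple[float, float]]:
    """Centres of the 2**n_done sibling compartments inside the mother."""
    cy, cx = geom.center
    R = geom.R
    if n_done == 0:
        return [(cy, cx)]
    if n_done == 1:
        return [(cy, cx - 0.45 * R), (cy, cx + 0.45 * R)]
    # 4 or 8 compartments: pack on a grid inside the mother outline
    offs = [(-0.4, -0.4), (-0.4, 0.4), (0.4, -0.4), (0.4, 0.4)]
    pts = [(cy + a * R, cx + b * R) for a, b in offs]
    if n_done == 2:
        return pts
    return pts + [(cy + a * 0.75 * R, cx) for a in (-0.75, 0.75)] + [
        (cy, cx + a * 0.75 * R) for a in (-0.75, 0.75)
    ]


def _nucleus_image(geom, scene, centers, total_signal) -> np.ndarray:
    """Nuclear reporter distributed over current nuclei; sums to total exactly."""
    if total_signal <= 0:
        return np.zeros_like(geom.red_clean)
    cy, cx = geom.center
    R = geom.R
    prof = np.zeros_like(geom.red_clean)
    rn = scene.nucleus_radius
    for (ccy, ccx) in centers:
        # nuclei sit in the anterior clear zone of their compartment
        nc = (cy - 0.55 * R, ccx) if len(centers) == 1 else (ccy - 0.25 * R, ccx)
        prof += _soft_disk(geom.yy, geom.xx, nc, rn)
    s = prof.sum()
    if s <= 0:
        return np.zeros_like(prof)
    return prof * (total_signal / s)


def _spindle_length(geom: _SceneGeometry, scene: SceneParams, cycle: int) -> float:
    return scene.eb1.spindle_length_frac * geom.R * (0.5 ** (cycle / 2.0))


def _render_eb1(geom, scene, t, events, rng) -> tuple[np.ndarray, np.ndarray, int]:
    """EB1 structures + furrow mask for one frame.

    Returns (eb1 image, furrow line profile in [0,1], comet count).
    """
    e = scene.eb1
    yy, xx = geom.yy, geom.xx
    img = np.zeros_like(geom.red_clean)
    furrow = np.zeros_like(img)
    # which cycle are we in? count completed CFs
    n_done = sum(1 for c in events if c.CF is not None and t >= c.CF)
    centers = _compartment_centers(geom, min(n_done, 3))
    radius = geom.R * (0.5 ** (min(n_done, 3) / 2.0))

    current = None
    for c in events:
        end = c.CF if c.CF is not None else math.inf
        start = c.PS if c.PS is not None else c.SP
        if start is not None and start <= t and (t < end + e.furrow_persistence):
            current = c
    spindle_present = False
    if current is not None:
        sp, spb, cf = current.SP, current.SPB, current.CF
        spindle_present = sp is not None and t >= sp and (spb is None or t < spb)

    for (mcy, mcx) in centers:
        anterior = (mcy - 0.8 * radius, mcx)
        state = "interphase"
        if current is not None:
            ps, sp, spb, cf = current.PS, current.SP, current.SPB, current.CF
            if ps is not None and t >= ps and (sp is None or t < sp):
                state = "poles"
            elif sp is not None and t >= sp and (spb is None or t < spb):
                state = "spindle"
            elif spb is not None and t >= spb and (cf is None or t < cf):
                state = "midzone"
            elif cf is not None and cf <= t < cf + e.furrow_persistence:
                state = "furrow"
        if state == "interphase":
            img += _gauss_dot(yy, xx, anterior, e.dot_radius, e.dot_intensity)
        elif state == "poles":
            sep = e.initial_pole_separation + e.pole_separation_speed * (t - current.PS)
            p0 = (mcy - 0.7 * radius, mcx - sep / 2.0)
            p1 = (mcy - 0.7 * radius, mcx + sep / 2.0)
            img += _gauss_dot(yy, xx, p0, e.dot_radius, e.dot_intensity)
            img += _gauss_dot(yy, xx, p1, e.dot_radius, e.dot_intensity)
        elif state == "spindle":
            length = _spindle_length(geom, scene, current.cycle)
            img += _bar(yy, xx, (mcy, mcx), 0.0, length, e.spindle_width,
                        e.spindle_intensity)
        elif state == "midzone":
            img += _gauss_dot(yy, xx, (mcy, mcx), e.dot_radius, 0.5 * e.dot_intensity)
        elif state == "furrow":
            length = 1.4 * radius
            img += _bar(yy, xx, (mcy, mcx), math.pi / 2.0, length, 2.0,
                        e.furrow_intensity)
            furrow += _bar(yy, xx, (mcy, mcx), math.pi / 2.0, length, 2.0, 1.0)

    # cortical comets and most of the diffuse cytosolic pool are suppressed
    # while a spindle is present (permanently for the APC preset once the
    # stable spindle has formed): EB1 redistributes onto the spindle
    suppressed = spindle_present
    if scene.preset == "apc_mutant" and current is not None and current.SP is not None:
        suppressed = suppressed or t >= current.SP
    if e.diffuse_level > 0:
        factor = e.diffuse_suppression if suppressed else 1.0
        img += factor * e.diffuse_level * geom.cell_mask
    n_comets = 0
    if not suppressed and e.comet_rate > 0:
        n_comets = int(rng.poisson(e.comet_rate))
        cy, cx = geom.center
        for _ in range(n_comets):
            # lateral cortex only (60-150 deg either side of the anterior
            # axis): keeps both the anterior polar dot and the brightest
            # posterior chloroplast pixels unobstructed
            side = 1.0 if rng.random() < 0.5 else -1.0
            ang = side * rng.uniform(math.pi / 3.0, 5.0 * math.pi / 6.0)
            p = (cy - 0.9 * geom.R * math.cos(ang), cx + 0.9 * geom.R * math.sin(ang))
            img += _gauss_dot(yy, xx, p, e.comet_radius, e.comet_intensity)
    return img, np.clip(furrow, 0.0, 1.0), n_comets


def _apply_noise(clean: np.ndarray, noise: NoiseParams, rng) -> np.ndarray:
    out = np.asarray(clean, dtype=float)
    if noise.poisson:
        out = rng.poisson(np.clip(out, 0.0, None)).astype(float)
    if noise.read_sigma > 0:
        out = out + rng.normal(0.0, noise.read_sigma, size=out.shape)
    return out


# ---------------------------------------------------------------------------
# movie assembly
# ---------------------------------------------------------------------------
def simulate_movie(
    scene: SceneParams,
    kinetics: KineticParams,
    seed: int,
    frame_interval: float = 3.0,
    n_frames: int | None = None,
) -> tuple[Movie, GroundTruth]:
    """Render a synthetic movie and its ground truth.

    Channels are ``reporter`` and ``reference`` (plus ``brightfield`` when
    ``scene.brightfield``).  The reporter channel is
    ``true_F x (noiseless red) + structures + noise``; with zero noise and no
    reporter it therefore equals ``true_F x red`` exactly.
    """
    if 2 * scene.cell_radius + 4 > scene.image_size:
        raise ValueError("cell does not fit in the image")
    geom = _SceneGeometry(scene)
    sched = trace_schedule(kinetics)
    events = event_schedule(scene, kinetics)
    if n_frames is None:
        last = 0.0
        for cyc in sched:
            last = max(last, (cyc["division"] or cyc["peak"]) + 5.0)
        for ev in events:
            for v in (ev.PS, ev.SP, ev.SPB, ev.CF):
                if v is not None:
                    last = max(last, v + 5.0)
        if not sched and not events:
            last = 15.0
        if scene.preset == "apc_mutant":
            last += 10.0  # observe the persistent spindle for a while
        n_frames = int(math.ceil(last / frame_interval)) + 1
    times = np.arange(n_frames) * float(frame_interval)
    true_trace = simulate_trace(kinetics, times)

    ss = np.random.SeedSequence(int(seed))
    rng_structs, rng_noise = [np.random.default_rng(s) for s in ss.spawn(2)]

    division_times = [c["division"] for c in sched if c["division"] is not None]
    n_channels = 3 if scene.brightfield else 2
    data = np.zeros((n_frames, n_channels, scene.image_size, scene.image_size),
                    dtype=float)
    comet_counts = np.zeros(n_frames, dtype=int)

    for i, t in enumerate(times):
        red_clean = geom.red_clean
        n_done = sum(1 for d in division_times if t >= d)
        green_clean = scene.true_F * red_clean
        furrow_prof = np.zeros_like(red_clean)
        if scene.reporter == "cyclin":
            centers = _compartment_centers(geom, min(n_done, 3))
            green_clean = green_clean + _nucleus_image(
                geom, scene, centers, true_trace[i]
            )
            for c in events:
                if c.CF is not None and c.CF <= t < c.CF + scene.eb1.furrow_persistence:
                    length = 1.4 * geom.R * (0.5 ** (min(n_done, 3) / 2.0))
                    furrow_prof += _bar(geom.yy, geom.xx, geom.center,
                                        math.pi / 2.0, length, 2.0, 1.0)
        else:
            eb1_img, furrow_prof, n_com = _render_eb1(geom, scene, t, events,
                                                      rng_structs)
            green_clean = green_clean + eb1_img
            comet_counts[i] = n_com

        data[i, 0] = _apply_noise(green_clean, scene.noise, rng_noise)
        data[i, 1] = _apply_noise(red_clean, scene.noise, rng_noise)
        if scene.brightfield:
            bf = scene.bf_level * (1.0 - 0.7 * np.clip(furrow_prof, 0.0, 1.0))
            data[i, 2] = _apply_noise(bf, scene.noise, rng_noise)

    names = ["reporter", "reference"] + (["brightfield"] if scene.brightfield else [])
    movie = Movie(data=data, channel_names=names, frame_interval=frame_interval,
                  pixel_size=0.2)
    truth = GroundTruth(
        times=times,
        true_trace=true_trace,
        cycles=events,
        division_times=division_times,
        trace_landmarks=sched,
        true_F=scene.true_F,
        frame_interval=frame_interval,
        comet_counts=comet_counts,
    )
    return movie, truth


def make_preset_config(
    name: str, reporter: str = "cyclin", n_divisions: int = 1
) -> tuple[SceneParams, KineticParams]:
    """Parameter bundles for the four phenotypic presets.

    ``wildtype``: full accumulation/degradation cycle and all four EB1
    events.  ``apc_mutant`` (cdc27/cdc20-like): degradation disabled, PS and
    SP occur but the spindle is stable indefinitely (no SPB/CF, permanent
    comet suppression).  ``cycb1_mutant``: no accumulation, only the
    persistent anterior EB1 dot, no events.  ``cdkb1_mutant``: reporter
    accumulates but is never precipitously degraded; spindle morphogenesis
    fails, so no events.
    """
    if name not in PRESETS:
        raise ValueError(f"unknown preset {name!r}; expected one of {PRESETS}")
    scene = SceneParams(preset=name, reporter=reporter)
    k = KineticParams(n_divisions=n_divisions)
    if name == "apc_mutant":
        k.degradation_disabled = True
        k.n_divisions = 0
    elif name == "cycb1_mutant":
        k.accumulation_disabled = True
        k.n_divisions = 0
    elif name == "cdkb1_mutant":
        k.degradation_disabled = True
        k.n_divisions = 0
    return scene, k
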