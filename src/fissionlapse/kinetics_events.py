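"""Degradation kinetics and mitotic event scoring.

Kinetics: reporter traces are segmented into cycles by robust landmark
detection (baseline = median of the pre-onset segment, onset at
baseline + 3*MAD, peak, and trough back at baseline); the degradation
half-life is a log-linear least-squares fit of ``ln(signal - baseline)``
against time over the decay window, ``t_1/2 = ln 2 / |slope|``.  The
trough-to-division interval may be negative when the trough is reached
after the furrow appears.

Events: per frame, connected components of the peak mask are classified.

* **PS** (pole separation): first frame with >= 2 compact anterior foci
  whose centroids are at least ``d_min`` apart.
* **SP** (spindle): first frame with a component whose major axis is at
  least the cell radius — a signal continuous across the cell midline.
* **SPB** (spindle breakdown): first later frame with no component aligned
  (within an angle tolerance) with the recorded spindle axis.
* **CF** (cleavage furrow): first frame with a dark brightfield line, or an
  elongated EB1 component perpendicular (within the tolerance) to the
  former spindle axis.

Censoring follows the published rules: a never-seen spindle counts as a
zero-frame duration only when the preceding PS was clearly visible; when
neither PS nor SP is seen, the values are not recorded.  Interval
statistics over cells report mean +/- sample s.d. with n, or "ND" when no
cell qualifies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from skimage import measure

from .movie_io import Movie
from .quantification import CellTrace
from .segmentation import MaskSet

EVENT_TYPES = ("PS", "SP", "SPB", "CF")
OBSERVED = "observed"
ASSUMED_ZERO = "assumed_zero_duration"
NOT_RECORDED = "not_recorded"


@dataclass
class DecayFit:
    halflife: float
    fit_window: tuple[int, int]
    baseline: float
    r_squared: float
    n_points: int

    def __post_init__(self) -> None:
        if self.halflife <= 0:
            raise ValueError("halflife must be > 0")
        if self.n_points < 2:
            raise ValueError("need at least two fitted points")


@dataclass
class Event:
    type: str
    cycle_index: int
    frame: int | None
    censoring_flag: str = OBSERVED


@dataclass
class EventLog:
    cell_id: int
    events: list = field(default_factory=list)
    frame_interval: float = 3.0

    def get(self, type_: str, cycle: int) -> Event | None:
        for ev in self.events:
            if ev.type == type_ and ev.cycle_index == cycle:
                return ev
        return None

    @property
    def n_cycles(self) -> int:
        return 1 + max((ev.cycle_index for ev in self.events), default=-1)


@dataclass
class IntervalStats:
    pair: str
    mean: float | None
    sd: float | None
    n: int

    @property
    def is_nd(self) -> bool:
        return self.n == 0

    def __str__(self) -> str:
        if self.is_nd:
            return f"{self.pair}: ND"
        return f"{self.pair}: {self.mean:.1f} +/- {self.sd:.1f} ({self.n})"


# ---------------------------------------------------------------------------
# trace landmarks and decay fitting
# ---------------------------------------------------------------------------
def _mad(x: np.ndarray) -> float:
    med = np.median(x)
    return float(np.median(np.abs(x - med)))


def detect_trace_landmarks(
    trace: CellTrace, min_baseline_frames: int = 3
) -> list[dict]:
    """Per-cycle (onset, peak, trough) frame indices of a reporter trace.

    The baseline segment grows greedily from the first frames while values
    stay below ``median + 3*MAD`` of the segment so far; the onset is the
    first exceeding frame.  The peak is the maximum before the trace first
    returns to the baseline band (the trough).  Repeats for later cycles.
    A flat trace yields an empty list (not an error).
    """
    y = np.asarray(trace.total_signal, dtype=float)
    n = y.size
    if n == 0:
        raise ValueError("empty trace")
    k = min(min_baseline_frames, n)
    seg_end = k
    while seg_end < n:
        base = np.median(y[:seg_end])
        thr = base + max(3.0 * _mad(y[:seg_end]), 1e-9 * max(abs(base), 1.0))
        if y[seg_end] > thr:
            break
        seg_end += 1
    if seg_end >= n:
        return []  # flat: no onset found
    baseline = float(np.median(y[:seg_end]))
    noise = max(3.0 * _mad(y[:seg_end]), 1e-9 * max(abs(baseline), 1.0))
    thr = baseline + noise

    landmarks = []
    i = 0  # the onset may fall inside the minimum baseline window
    while i < n:
        # onset: first frame above the baseline band
        while i < n and y[i] <= thr:
            i += 1
        if i >= n:
            break
        onset = i
        # trough: first frame at/below the band after the rise
        j = onset
        while j < n and y[j] > thr:
            j += 1
        seg = y[onset:j] if j > onset else y[onset:onset + 1]
        peak = onset + int(np.argmax(seg))
        trough = j if j < n else None
        landmarks.append({
            "onset": onset, "peak": peak, "trough": trough,
            "baseline": baseline, "noise_band": noise,
        })
        if trough is None:
            break
        i = trough
    return landmarks


def fit_degradation_halflife(
    trace: CellTrace,
    peak: int,
    trough: int,
    baseline: float | None = None,
) -> DecayFit:
    """Log-linear half-life fit over the decay window ``[peak, trough]``.

    Fits ``ln(y - baseline)`` vs time by least squares over the frames from
    the peak to the trough whose values lie strictly above baseline, and
    returns ``ln 2 / |slope|``.  Exact on noiseless exponentials.

    Raises
    ------
    ValueError
        If fewer than two frames qualify or the fitted slope is not
        negative.
    """
    if trough <= peak:
        raise ValueError("trough must come after peak")
    y = np.asarray(trace.total_signal, dtype=float)
    t = np.asarray(trace.times, dtype=float)
    if baseline is None:
        lms = detect_trace_landmarks(trace)
        baseline = lms[0]["baseline"] if lms else float(np.min(y))
    idx = np.arange(peak, min(trough, y.size - 1) + 1)
    above = y[idx] > baseline
    idx = idx[above]
    if idx.size < 2:
        raise ValueError("fewer than two decay points above baseline")
    ln_y = np.log(y[idx] - baseline)
    slope, intercept = np.polyfit(t[idx], ln_y, 1)
    if slope >= 0:
        raise ValueError("decay fit has non-negative slope")
    pred = slope * t[idx] + intercept
    ss_res = float(np.sum((ln_y - pred) ** 2))
    ss_tot = float(np.sum((ln_y - ln_y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return DecayFit(
        halflife=float(math.log(2.0) / abs(slope)),
        fit_window=(int(idx[0]), int(idx[-1])),
        baseline=float(baseline),
        r_squared=r2,
        n_points=int(idx.size),
    )


def trough_to_division_interval(
    trough_frame: int, division_frame: int, frame_interval: float
) -> float:
    """(division - trough) x frame interval, in minutes; may be negative."""
    if trough_frame is None or division_frame is None:
        raise ValueError("both trough and division frames are required")
    return (division_frame - trough_frame) * float(frame_interval)


# ---------------------------------------------------------------------------
# event scoring
# ---------------------------------------------------------------------------
def _components(mask: np.ndarray, cell_region: np.ndarray | None,
                intensity: np.ndarray | None = None):
    m = mask if cell_region is None else (mask & cell_region)
    labels = measure.label(m, connectivity=1)
    return measure.regionprops(labels, intensity_image=intensity)


def _angle_of(region) -> float:
    """Component orientation as an angle in [0, pi) from the +x image axis."""
    # skimage orientation: angle between the 0th (row) axis and the major
    # axis, in (-pi/2, pi/2]; convert to angle from the x (col) axis.
    return (math.pi / 2.0 - region.orientation) % math.pi


def _angular_diff(a: float, b: float) -> float:
    d = abs(a - b) % math.pi
    return min(d, math.pi - d)


def _dark_line_frame(bf: np.ndarray, level: float) -> bool:
    """Detect a furrow: a contiguous run of clearly dark brightfield pixels."""
    dark = bf < 0.7 * level
    if not dark.any():
        return False
    labels = measure.label(dark, connectivity=1)
    return any(r.area >= 10 and r.axis_major_length >= 8
               for r in measure.regionprops(labels))


def score_mitotic_events(
    eb1_movie: Movie,
    masks: list[MaskSet],
    cell_region: np.ndarray | None = None,
    d_min: float = 3.0,
    angle_tol_deg: float = 20.0,
    spindle_length_factor: float = 1.0,
    d_max_factor: float = 0.6,
    max_cycles: int = 3,
) -> EventLog:
    """Score PS/SP/SPB/CF events from an EB1 movie with per-frame masks.

    The cell radius is estimated from the cell mask area; for cycle ``c``
    the spindle-length criterion scales by ``2**(-c/2)`` because daughters
    halve in area each round.  A pole split requires a focus pair between
    ``d_min`` px and ``d_max_factor`` x current radius apart: the lower
    bound resolves genuinely split poles, the upper bound rejects the
    anterior dots of separate sibling cells.  Unobserved events are
    recorded with censoring flags rather than errors.
    """
    if len(masks) != eb1_movie.n_frames:
        raise ValueError("need one MaskSet per frame")
    angle_tol = math.radians(angle_tol_deg)
    has_bf = eb1_movie.has_channel("brightfield")
    bf = eb1_movie.channel("brightfield") if has_bf else None
    log = EventLog(cell_id=1, frame_interval=eb1_movie.frame_interval)

    cell_area = max(ms.cell_mask.sum() for ms in masks)
    radius0 = math.sqrt(cell_area / math.pi)
    eb1 = eb1_movie.channel("reporter")

    # anterior reference: the interphase polar dot is the one compact focus
    # that stays put, while comets appear at fresh positions every frame --
    # take the recurring centroid over the first frames
    anterior_ref = None
    n_ref = min(8, eb1_movie.n_frames)
    cand: list[np.ndarray] = []
    per_frame: list[list[np.ndarray]] = []
    for j in range(n_ref):
        comps = _components(masks[j].peak_mask,
                            cell_region if cell_region is not None
                            else masks[j].cell_mask,
                            np.asarray(eb1[j], dtype=float))
        cents = [np.asarray(c.centroid) for c in comps
                 if c.axis_major_length < spindle_length_factor * radius0]
        per_frame.append(cents)
        cand.extend(cents)
    best_count = 0
    for c in cand:
        count = sum(1 for frame in per_frame
                    if any(np.hypot(*(c - o)) <= 3.0 for o in frame))
        if count > best_count:
            best_count = count
            anterior_ref = c

    cycle = 0
    state = "interphase"
    ps_frame = sp_frame = spb_frame = cf_frame = None
    spindle_axis = None
    for i in range(eb1_movie.n_frames):
        region = cell_region if cell_region is not None else masks[i].cell_mask
        comps = _components(masks[i].peak_mask, region)
        radius = radius0 * (0.5 ** (cycle / 2.0))
        min_len = spindle_length_factor * radius

        elongated = [c for c in comps if c.axis_major_length >= min_len]
        compact = [c for c in comps if c.axis_major_length < min_len]

        if state == "furrow_wait":
            # let the previous cycle's furrow line fade before rescanning
            if not elongated:
                state = "interphase"
            else:
                continue

        if state in ("interphase", "poles"):
            if elongated:
                sp_frame = i
                spindle_axis = _angle_of(elongated[0])
                state = "spindle"
            elif state == "interphase" and len(compact) >= 2:
                # pole separation: >=2 resolved anterior foci far enough apart
                cents = np.array([c.centroid for c in compact])
                if anterior_ref is not None:
                    near = np.hypot(*(cents - anterior_ref).T) <= 0.6 * radius0
                    cents = cents[near]
                if len(cents) >= 2:
                    d_max = d_max_factor * radius
                    split = False
                    for a in range(len(cents)):
                        for b in range(a + 1, len(cents)):
                            d = float(np.hypot(*(cents[a] - cents[b])))
                            if d_min <= d <= d_max:
                                split = True
                    if split:
                        ps_frame = i
                        state = "poles"
            continue

        if state == "spindle":
            still = [c for c in elongated
                     if _angular_diff(_angle_of(c), spindle_axis) <= angle_tol]
            if not still:
                spb_frame = i
                state = "post_spindle"
            # fall through to the furrow check in the same frame
        if state == "post_spindle":
            furrow_seen = False
            if has_bf and _dark_line_frame(np.asarray(bf[i], dtype=float),
                                           float(np.median(bf[i]))):
                furrow_seen = True
            else:
                perp = [c for c in elongated
                        if _angular_diff(_angle_of(c),
                                         spindle_axis + math.pi / 2.0) <= angle_tol]
                if perp:
                    furrow_seen = True
            if furrow_seen:
                cf_frame = i
                _append_cycle(log, cycle, ps_frame, sp_frame, spb_frame, cf_frame)
                cycle += 1
                ps_frame = sp_frame = spb_frame = cf_frame = None
                spindle_axis = None
                state = "furrow_wait"
                if cycle >= max_cycles:
                    break

    if state not in ("interphase", "furrow_wait") or (cycle == 0 and not log.events):
        # movie ended mid-cycle (or nothing happened): flush with censoring
        _append_cycle(log, cycle, ps_frame, sp_frame, spb_frame, cf_frame)
    return log


def _append_cycle(log: EventLog, cycle: int, ps, sp, spb, cf) -> None:
    """Append one cycle's events, applying the censoring rules."""
    if ps is None and sp is None:
        # neither PS nor SP seen: values not recorded
        for t in EVENT_TYPES:
            log.events.append(Event(t, cycle, None, NOT_RECORDED))
        return
    log.events.append(Event("PS", cycle, ps,
                            OBSERVED if ps is not None else NOT_RECORDED))
    if sp is not None:
        log.events.append(Event("SP", cycle, sp, OBSERVED))
    else:
        # spindle never seen but PS clearly visible: zero-frame duration
        log.events.append(Event("SP", cycle, None, ASSUMED_ZERO))
    log.events.append(Event("SPB", cycle, spb,
                            OBSERVED if spb is not None else NOT_RECORDED))
    log.events.append(Event("CF", cycle, cf,
                            OBSERVED if cf is not None else NOT_RECORDED))


def scored_duration(
    frame_a: int, frame_b: int, frame_interval: float
) -> float:
    """(frame_b - frame_a) x frame interval, minutes; requires b >= a."""
    if frame_b < frame_a:
        raise ValueError("second event precedes the first")
    return (frame_b - frame_a) * float(frame_interval)


def event_pair_duration(log: EventLog, pair: str) -> float | None:
    """Duration of one labelled interval (e.g. ``"SP1->SP1B"``) for a cell.

    Returns minutes, 0.0 for a censored zero-duration spindle, or ``None``
    when the cell does not qualify (not-recorded events).
    """
    a_label, b_label = [p.strip() for p in pair.split("->")]

    def parse(label: str) -> tuple[str, int]:
        if label.startswith("SP") and label.endswith("B") and len(label) > 2:
            return "SPB", int(label[2:-1]) - 1
        if label.startswith("SP") and len(label) > 2:
            return "SP", int(label[2:]) - 1
        if label.startswith("CF"):
            return "CF", int(label[2:]) - 1
        if label in ("PS", "Polesep", "Pole sep"):
            return "PS", 0
        raise ValueError(f"cannot parse event label {label!r}")

    ta, ca = parse(a_label)
    tb, cb = parse(b_label)
    ev_a, ev_b = log.get(ta, ca), log.get(tb, cb)
    if ev_a is None or ev_b is None:
        return None
    # a spindle assumed missed between frames scores a zero-frame duration,
    # even when the breakdown itself went unrecorded
    if ASSUMED_ZERO in (ev_a.censoring_flag, ev_b.censoring_flag):
        if (ta, tb) in (("SP", "SPB"), ("PS", "SP")):
            return 0.0
        return None
    if ev_a.censoring_flag == NOT_RECORDED or ev_b.censoring_flag == NOT_RECORDED:
        return None
    return scored_duration(ev_a.frame, ev_b.frame, log.frame_interval)


def interval_statistics(
    logs: list[EventLog], pair: str, frame_interval: float | None = None
) -> IntervalStats:
    """Mean +/- s.d. (n) of one interval over cells, honouring censoring.

    Cells with not-recorded events are excluded; assumed-zero-duration
    spindles contribute 0.  ``n == 0`` is reported as ND.
    """
    durations = []
    for log in logs:
        if frame_interval is not None:
            log = EventLog(log.cell_id, log.events, frame_interval)
        d = event_pair_duration(log, pair)
        if d is not None:
            durations.append(d)
    if not durations:
        return IntervalStats(pair=pair, mean=None, sd=None, n=0)
    arr = np.asarray(durations, dtype=float)
    sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
    return IntervalStats(pair=pair, mean=float(arr.mean()), sd=sd, n=arr.size)
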