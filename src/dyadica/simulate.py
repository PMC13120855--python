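"""Synthetic-data generators with known ground truth.

The bout generator is a semi-Markov (alternating renewal) process per
fly: from the idle state, each action competes with an exponential
waiting time at its initiation rate; the winning action occupies the fly
for a gamma-distributed dwell, optionally chains into a successor drawn
from a row-stochastic transition kernel, and then returns the fly to
idle. Renewal structure gives closed-form oracles for bout counts
(expected cycles x dwell occupancy), trio preference indices and
photostimulation rate ratios.

Dominance between the two flies of a pair is a single scalar delta in
[0, 1] scaling both courtship and aggression initiation as (1 + delta)
for fly A versus (1 - delta) for fly B, so the same fly both courts and
attacks more by construction. Copulation arises with a constant hazard
during copulation-attempt bouts and ends the trial.

Per-fly random streams are split from the trial seed with NumPy
``SeedSequence`` spawn keys, so adding a fly never perturbs another
fly's draws, and identical (specification, seed) pairs are bit-identical.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Optional, Sequence, Union

import numpy as np

from .catalog import ActionCatalog, DEFAULT_CATALOG
from .core import Bout, BoutTable, FlyInfo, Trial, seconds_to_frames
from .optostim import PSProtocol
from .song import SongEvent, SongEvents, Train


# ---------------------------------------------------------------------------
# behavior profiles


@dataclass(frozen=True)
class ActionParams:
    """Initiation rate (events/s of idle time) and gamma dwell for one action."""

    rate: float
    dwell_mean: float = 1.0
    dwell_shape: float = 2.0

    def __post_init__(self) -> None:
        if not math.isfinite(self.rate) or self.rate < 0:
            raise ValueError(f"initiation rate must be finite and >= 0, got {self.rate}")
        if self.dwell_mean <= 0 or self.dwell_shape <= 0:
            raise ValueError("dwell parameters must be positive")


@dataclass(frozen=True)
class BehaviorProfile:
    """Generative specification of one fly's social behavior.

    ``ps_on_gain`` multiplies courtship initiation during a
    photostimulation block (a scalar, a ``{frequency: gain}`` mapping, or
    a callable of frequency); after each block offset, aggression
    initiation is multiplied by ``1 + ps_off_amp * exp(-dt / ps_off_tau)``.
    """

    actions: dict[str, ActionParams]
    catalog: ActionCatalog = DEFAULT_CATALOG
    kernel: Optional[dict[str, dict[str, float]]] = None
    chain_prob: float = 0.0
    chain_gap_range: tuple[float, float] = (0.1, 0.5)
    dominance: float = 0.0
    copulation_hazard: float = 0.0
    ps_on_gain: Union[float, dict[float, float], Callable[[float], float]] = 1.0
    ps_off_amp: float = 0.0
    ps_off_tau: float = 30.0

    def __post_init__(self) -> None:
        if not 0 <= self.dominance <= 1:
            raise ValueError("dominance must lie in [0, 1]")
        if self.ps_off_tau <= 0:
            raise ValueError("ps_off_tau must be positive")
        if self.copulation_hazard < 0:
            raise ValueError("copulation_hazard must be >= 0")
        if self.kernel is not None:
            for a, row in self.kernel.items():
                s = sum(row.values())
                if abs(s - 1.0) > 1e-9:
                    raise ValueError(f"kernel row for {a!r} sums to {s}, not 1")
        for a in self.actions:
            if a not in self.catalog:
                raise ValueError(f"profile action {a!r} not in catalog")

    def on_gain(self, freq_hz: float) -> float:
        g = self.ps_on_gain
        if callable(g):
            return float(g(freq_hz))
        if isinstance(g, dict):
            return float(g.get(freq_hz, 1.0))
        return float(g)

    def max_on_gain(self, freqs: Sequence[float]) -> float:
        return max([1.0] + [self.on_gain(f) for f in freqs])


def santomea_like_profile(**overrides) -> BehaviorProfile:
    """High-courtship, low-aggression male profile (20 min dyad scale)."""
    params = dict(
        actions={
            "UWE": ActionParams(rate=0.05, dwell_mean=2.0, dwell_shape=2.0),
            "circle": ActionParams(rate=0.01, dwell_mean=1.5, dwell_shape=2.0),
            "copulation attempt": ActionParams(rate=0.005, dwell_mean=1.0),
            "lunge": ActionParams(rate=0.002, dwell_mean=0.3, dwell_shape=1.5),
        }
    )
    params.update(overrides)
    return BehaviorProfile(**params)


def melanogaster_like_profile(**overrides) -> BehaviorProfile:
    """High-aggression, low male-male-courtship profile."""
    params = dict(
        actions={
            "lunge": ActionParams(rate=0.1, dwell_mean=0.3, dwell_shape=1.5),
            "threat": ActionParams(rate=0.02, dwell_mean=1.0),
            "UWE": ActionParams(rate=0.002, dwell_mean=2.0),
        }
    )
    params.update(overrides)
    return BehaviorProfile(**params)


# ---------------------------------------------------------------------------
# semi-Markov bout generation


def _fly_rng(seed: int, index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(index,)))


def _dom_factor(profile: BehaviorProfile, side: int) -> float:
    # side +1 -> favored fly (1 + delta), side -1 -> (1 - delta), 0 -> 1
    return 1.0 + side * profile.dominance


def _simulate_fly(
    profile: BehaviorProfile,
    fly_id: str,
    duration_s: float,
    rng: np.random.Generator,
    dom_side: int = 0,
    court_mod: Optional[Callable[[float], float]] = None,
    agg_mod: Optional[Callable[[float], float]] = None,
    court_bound: float = 1.0,
    agg_bound: float = 1.0,
) -> tuple[list[tuple[str, float, float]], Optional[float]]:
    """One fly's bout sequence in seconds via thinned renewal generation.

    Returns ``(bouts, copulation_time)`` where bouts are
    ``(action, start_s, end_s)``. The acceptance draw of the thinning
    step is only consumed when the acceptance probability is below 1, so
    a null modulation reproduces the unmodulated stream exactly.
    """
    cat = profile.catalog
    names = [a for a, p in profile.actions.items() if p.rate > 0]
    if not names:
        return [], None
    dom = _dom_factor(profile, dom_side)
    base = {}
    bound = {}
    for a in names:
        r = profile.actions[a].rate
        if cat.is_courtship(a) or cat.is_aggression(a):
            r *= dom
        base[a] = r
        if cat.is_courtship(a):
            bound[a] = r * court_bound
        elif cat.is_aggression(a):
            bound[a] = r * agg_bound
        else:
            bound[a] = r
    tot = sum(bound.values())
    if tot <= 0:
        return [], None
    probs = np.array([bound[a] / tot for a in names])

    def mod_at(a: str, t: float) -> float:
        if cat.is_courtship(a) and court_mod is not None:
            return court_mod(t)
        if cat.is_aggression(a) and agg_mod is not None:
            return agg_mod(t)
        return 1.0

    def draw_dwell(a: str) -> float:
        p = profile.actions[a]
        return rng.gamma(p.dwell_shape, p.dwell_mean / p.dwell_shape)

    bouts: list[tuple[str, float, float]] = []
    cop_time: Optional[float] = None
    t = 0.0
    while True:
        if tot <= 0:
            break
        t += rng.exponential(1.0 / tot)
        if t >= duration_s:
            break
        a = names[rng.choice(len(names), p=probs)]
        accept = base[a] * mod_at(a, t) / bound[a]
        if accept < 1.0 and rng.random() >= accept:
            continue
        # run the bout, possibly chaining through the kernel
        while True:
            dwell = draw_dwell(a)
            end = min(t + dwell, duration_s)
            bouts.append((a, t, end))
            if a == "copulation attempt" and profile.copulation_hazard > 0:
                lat = rng.exponential(1.0 / profile.copulation_hazard)
                if t + lat < end:
                    cop_time = t + lat
                    return bouts, cop_time
            t = end
            if t >= duration_s:
                return bouts, cop_time
            if (
                profile.kernel is not None
                and a in profile.kernel
                and profile.chain_prob > 0
                and rng.random() < profile.chain_prob
            ):
                gap = rng.uniform(*profile.chain_gap_range)
                t += gap
                if t >= duration_s:
                    return bouts, cop_time
                row = profile.kernel[a]
                dests = list(row)
                a = dests[rng.choice(len(dests), p=np.array([row[d] for d in dests]))]
                continue
            break
    return bouts, cop_time


def _to_frames(
    raw: list[tuple[str, float, float]],
    fly_id: str,
    frame_rate: float,
    n_frames: int,
    target_of: Optional[dict[int, str]] = None,
) -> list[Bout]:
    out = []
    for i, (a, s, e) in enumerate(raw):
        sf = seconds_to_frames(s, frame_rate)
        ef = min(seconds_to_frames(e, frame_rate), n_frames)
        if ef > sf:
            out.append(
                Bout(
                    fly_id=fly_id,
                    action=a,
                    start=sf,
                    end=ef,
                    target=None if target_of is None else target_of.get(i),
                )
            )
    return out


def _male(fly_id: str, **kw) -> FlyInfo:
    return FlyInfo(fly_id=fly_id, sex="male", **kw)


def simulate_dyad(
    profileA: BehaviorProfile,
    profileB: BehaviorProfile,
    duration_s: float,
    frame_rate: float = 30.0,
    seed: int = 0,
    trial_id: str = "sim-dyad",
    assay: str = "dyad",
) -> tuple[Trial, BoutTable]:
    """Simulate a pair of interacting flies.

    Dominance scaling uses ``profileA.dominance``: fly A initiates social
    actions at ``(1 + delta)`` times its base rates and fly B at
    ``(1 - delta)`` times its own. If either fly's copulation hazard
    fires, generation ends there and the trial records the onset.
    """
    n_frames = seconds_to_frames(duration_s, frame_rate)
    delta_pair = profileA.dominance
    pb = replace(profileB, dominance=delta_pair)
    rawA, copA = _simulate_fly(
        profileA, "A", duration_s, _fly_rng(seed, 0), dom_side=+1
    )
    rawB, copB = _simulate_fly(pb, "B", duration_s, _fly_rng(seed, 1), dom_side=-1)
    cops = [c for c in (copA, copB) if c is not None]
    cop_frame = None
    if cops:
        cop_frame = seconds_to_frames(min(cops), frame_rate)
        cop_frame = min(max(cop_frame, 1), n_frames - 1) if n_frames > 1 else None
    bouts = _to_frames(rawA, "A", frame_rate, n_frames) + _to_frames(
        rawB, "B", frame_rate, n_frames
    )
    if cop_frame is not None:
        clipped = []
        for b in bouts:
            if b.start >= cop_frame:
                continue
            if b.end > cop_frame:
                b = replace(b, end=cop_frame)
            clipped.append(b)
        bouts = clipped
    trial = Trial(
        trial_id=trial_id,
        assay=assay,
        frame_rate=frame_rate,
        duration=n_frames,
        roster=(_male("A"), _male("B", wing_clipped=True)),
        copulation_onset=cop_frame,
    )
    return trial, BoutTable(trial_id, tuple(bouts))


def simulate_trio(
    profile: BehaviorProfile,
    target_rates: dict[str, float],
    duration_s: float,
    frame_rate: float = 30.0,
    seed: int = 0,
    courtship_action: str = "UWE",
    target_dwell: Optional[dict[str, float]] = None,
    trial_id: str = "sim-trio",
) -> tuple[Trial, BoutTable]:
    """Simulate a tester fly courting two targets (e.g. female and male).

    Courtship toward each target competes as an independent renewal
    stream; each bout carries the target's label. With rates ``lF, lM``
    and dwell means ``mF, mM`` the expected preference index is
    ``(lF*mF - lM*mM) / (lF*mF + lM*mM)``.
    """
    for k, v in target_rates.items():
        if not math.isfinite(v) or v < 0:
            raise ValueError(f"target rate for {k!r} must be finite and >= 0")
    base = profile.actions.get(courtship_action, ActionParams(rate=1.0, dwell_mean=2.0))
    n_frames = seconds_to_frames(duration_s, frame_rate)
    rng = _fly_rng(seed, 0)
    targets = list(target_rates)
    rates = np.array([target_rates[k] for k in targets], dtype=float)
    tot = rates.sum()
    raw: list[tuple[str, float, float]] = []
    target_of: dict[int, str] = {}
    t = 0.0
    while tot > 0:
        t += rng.exponential(1.0 / tot)
        if t >= duration_s:
            break
        tgt = targets[rng.choice(len(targets), p=rates / tot)]
        mean = (target_dwell or {}).get(tgt, base.dwell_mean)
        dwell = rng.gamma(base.dwell_shape, mean / base.dwell_shape)
        end = min(t + dwell, duration_s)
        target_of[len(raw)] = tgt
        raw.append((courtship_action, t, end))
        t = end
    bouts = _to_frames(raw, "tester", frame_rate, n_frames, target_of)
    trial = Trial(
        trial_id=trial_id,
        assay="trio",
        frame_rate=frame_rate,
        duration=n_frames,
        roster=(
            _male("tester"),
            FlyInfo(fly_id="target_female", sex="female"),
            _male("target_male"),
        ),
    )
    return trial, BoutTable(trial_id, tuple(bouts))


def simulate_ps_trial(
    profile: BehaviorProfile,
    protocol: PSProtocol,
    pair: bool = True,
    seed: int = 0,
    duration_s: Optional[float] = None,
    frame_rate: float = 30.0,
    trial_id: str = "sim-ps",
) -> tuple[Trial, BoutTable]:
    """Simulate a photostimulation trial.

    During ON blocks, courtship initiation is multiplied by the
    profile's frequency-dependent gain; after each block offset,
    aggression initiation is multiplied by
    ``1 + A * exp(-dt / tau)`` measured from the most recent offset.
    Sham protocols apply no modulation. Generation uses thinning against
    the worst-case gain, so a null modulation reproduces the
    protocol-free stream draw for draw.
    """
    if duration_s is None:
        duration_s = protocol.end_s + 120.0
    if protocol.blocks and protocol.end_s > duration_s:
        raise ValueError("protocol exceeds trial duration")
    blocks = () if protocol.sham else protocol.blocks
    onsets = np.array([b.onset_s for b in blocks])
    offsets = np.array([b.offset_s for b in blocks])
    gains = np.array([profile.on_gain(b.freq_hz) for b in blocks])

    def court_mod(t: float) -> float:
        i = np.searchsorted(onsets, t, side="right") - 1
        if i >= 0 and t < offsets[i]:
            return float(gains[i])
        return 1.0

    def agg_mod(t: float) -> float:
        i = np.searchsorted(offsets, t, side="right") - 1
        if i < 0:
            return 1.0
        dt = t - offsets[i]
        return 1.0 + profile.ps_off_amp * math.exp(-dt / profile.ps_off_tau)

    court_bound = profile.max_on_gain([b.freq_hz for b in blocks]) if len(blocks) else 1.0
    agg_bound = (1.0 + profile.ps_off_amp) if len(blocks) else 1.0
    n_frames = seconds_to_frames(duration_s, frame_rate)
    fly_ids = ["A", "B"] if pair else ["A"]
    bouts: list[Bout] = []
    for i, fid in enumerate(fly_ids):
        raw, _ = _simulate_fly(
            profile,
            fid,
            duration_s,
            _fly_rng(seed, i),
            dom_side=0,
            court_mod=court_mod,
            agg_mod=agg_mod,
            court_bound=court_bound,
            agg_bound=agg_bound,
        )
        bouts.extend(_to_frames(raw, fid, frame_rate, n_frames))
    trial = Trial(
        trial_id=trial_id,
        assay="dyad" if pair else "solitary",
        frame_rate=frame_rate,
        duration=n_frames,
        roster=tuple(_male(f) for f in fly_ids),
        protocol_ref=protocol.protocol_id,
    )
    return trial, BoutTable(trial_id, tuple(bouts))


# ---------------------------------------------------------------------------
# courtship song synthesis


@dataclass(frozen=True)
class SongSynthSpec:
    """Parameters of the peaks-and-gaps song synthesizer.

    Within-train gap ranges default to values strictly inside the
    segmentation thresholds (pulse < 200 ms, clack < 400 ms) so ground
    truth trains are recoverable; between-train gaps exceed both.
    """

    sample_rate: float = 10_000.0
    pulse_carrier_hz: float = 250.0
    clack_carrier_hz: float = 800.0
    pulse_sigma_ms: float = 3.0
    clack_sigma_ms: float = 1.5
    amplitude_range: tuple[float, float] = (0.5, 1.0)
    pulse_gap_range: tuple[float, float] = (0.08, 0.15)
    clack_gap_range: tuple[float, float] = (0.15, 0.35)
    between_gap_range: tuple[float, float] = (0.8, 1.5)
    train_size_range: tuple[int, int] = (3, 8)
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.sample_rate < 2 * max(self.pulse_carrier_hz, self.clack_carrier_hz):
            raise ValueError("sample rate must be at least twice the carrier")
        for name in (
            "pulse_sigma_ms",
            "clack_sigma_ms",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def synthesize_song(
    spec: SongSynthSpec,
    n_trains: dict[str, int],
    seed: int = 0,
) -> tuple[np.ndarray, SongEvents]:
    """Synthesize a song waveform with exact ground-truth events.

    Each event is a Gabor-like wavelet (cosine carrier under a Gaussian
    envelope) whose noise-free absolute maximum falls exactly on the
    event's sample-aligned time. Trains of the two types are interleaved
    in shuffled order along the recording.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(0,)))
    fs = spec.sample_rate
    kinds = ["pulse"] * n_trains.get("pulse", 0) + ["clack"] * n_trains.get("clack", 0)
    rng.shuffle(kinds)
    gap_range = {"pulse": spec.pulse_gap_range, "clack": spec.clack_gap_range}
    carrier = {"pulse": spec.pulse_carrier_hz, "clack": spec.clack_carrier_hz}
    sigma = {
        "pulse": spec.pulse_sigma_ms / 1000.0,
        "clack": spec.clack_sigma_ms / 1000.0,
    }
    events: list[SongEvent] = []
    trains: list[Train] = []
    cursor = 0.5
    for kind in kinds:
        size = int(rng.integers(spec.train_size_range[0], spec.train_size_range[1] + 1))
        members = []
        for j in range(size):
            t_snap = round(cursor * fs) / fs
            amp = rng.uniform(*spec.amplitude_range)
            members.append(len(events))
            events.append(SongEvent(kind, t_snap, amp))
            if j + 1 < size:
                cursor = t_snap + rng.uniform(*gap_range[kind])
        trains.append(Train(kind, tuple(members)))
        cursor = events[-1].time_s + rng.uniform(*spec.between_gap_range)
    total_s = cursor + 0.5
    n = int(round(total_s * fs))
    wave = np.zeros(n)
    for e in events:
        s = sigma[e.type]
        f = carrier[e.type]
        half = int(round(4 * s * fs))
        c = int(round(e.time_s * fs))
        lo, hi = max(0, c - half), min(n, c + half + 1)
        tt = (np.arange(lo, hi) / fs) - e.time_s
        wave[lo:hi] += e.amplitude * np.cos(2 * np.pi * f * tt) * np.exp(
            -(tt**2) / (2 * s**2)
        )
    if spec.noise_sd > 0:
        wave = wave + rng.normal(0.0, spec.noise_sd, n)
    order = np.argsort([e.time_s for e in events], kind="stable")
    remap = {int(old): new for new, old in enumerate(order)}
    events_sorted = tuple(events[int(i)] for i in order)
    for i, e in enumerate(events_sorted[1:], 1):
        if round(e.time_s * fs) - round(events_sorted[i - 1].time_s * fs) < 2:
            raise ValueError("song events overlap beyond sample resolution")
    trains_sorted = tuple(
        Train(t.type, tuple(sorted(remap[m] for m in t.member_indices)))
        for t in trains
    )
    return wave, SongEvents(events_sorted, trains_sorted)


# ---------------------------------------------------------------------------
# y-maze walks and rendering


@dataclass(frozen=True)
class ArenaSpec:
    """Geometry of the synthetic y-maze image.

    Scoring masks (left arm, right arm, bottom arm, central bowl) are
    pairwise disjoint; the walkable region additionally includes the
    connecting strips between each arm and the bowl.
    """

    width: int = 200
    height: int = 140
    bowl_center: tuple[float, float] = (100.0, 100.0)
    bowl_radius: float = 17.5
    arm_halfwidth: int = 11
    blob_radius: int = 3
    step_scale: float = 2.0
    odor_arm: str = "left"

    def __post_init__(self) -> None:
        if self.blob_radius < 1:
            raise ValueError("blob radius must be at least 1 px")

    def masks(self) -> dict[str, np.ndarray]:
        """Disjoint scoring masks: left, right, bottom arms and bowl."""
        H, W = self.height, self.width
        cx, cy = self.bowl_center
        yy, xx = np.mgrid[0:H, 0:W]
        bowl = (xx - cx) ** 2 + (yy - cy) ** 2 < self.bowl_radius**2
        hw = self.arm_halfwidth
        band = (yy >= cy - hw) & (yy <= cy + hw)
        vband = (xx >= cx - hw) & (xx <= cx + hw)
        left = band & (xx >= 10) & (xx < cx - self.bowl_radius) & ~bowl
        right = band & (xx > cx + self.bowl_radius) & (xx <= W - 10) & ~bowl
        bottom = vband & (yy >= 20) & (yy < cy - self.bowl_radius) & ~bowl
        return {"left": left, "right": right, "bottom": bottom, "bowl": bowl}

    def allowed(self) -> np.ndarray:
        m = self.masks()
        H, W = self.height, self.width
        cx, cy = self.bowl_center
        yy, xx = np.mgrid[0:H, 0:W]
        hw = self.arm_halfwidth
        band = (yy >= cy - hw) & (yy <= cy + hw)
        strip = band & (xx >= 10) & (xx <= W - 10)
        vstrip = (xx >= cx - hw) & (xx <= cx + hw) & (yy >= 20) & (yy <= cy)
        return m["bowl"] | strip | vstrip

    def odor_target(self) -> tuple[float, float]:
        cy = self.bowl_center[1]
        if self.odor_arm == "left":
            return (15.0, float(cy))
        if self.odor_arm == "right":
            return (float(self.width - 15), float(cy))
        return (self.bowl_center[0], 25.0)


def simulate_walk(
    arena: ArenaSpec,
    beta: float,
    duration_frames: int,
    seed: int = 0,
    n_flies: int = 1,
) -> np.ndarray:
    """Biased random walk(s) confined to the maze; shape (frames, flies, 2).

    Each proposal step is isotropic Gaussian (``step_scale`` px) plus a
    drift of ``beta`` px/frame toward the odor arm's far end; proposals
    leaving the walkable region are rejected (the fly stays put). With
    ``beta = 0`` and the default left/right-symmetric arena the expected
    occupancy index is zero.
    """
    if beta < 0:
        raise ValueError("beta must be >= 0")
    allowed = arena.allowed()
    H, W = arena.height, arena.width
    tx, ty = arena.odor_target()
    out = np.empty((duration_frames, n_flies, 2))
    for k in range(n_flies):
        rng = _fly_rng(seed, k)
        x, y = arena.bowl_center
        steps = rng.normal(0.0, arena.step_scale, size=(duration_frames, 2))
        for i in range(duration_frames):
            dx, dy = steps[i]
            if beta > 0:
                vx, vy = tx - x, ty - y
                norm = math.hypot(vx, vy)
                if norm > 1e-9:
                    dx += beta * vx / norm
                    dy += beta * vy / norm
            nx, ny = x + dx, y + dy
            xi, yi = int(nx + 0.5), int(ny + 0.5)
            if 0 <= xi < W and 0 <= yi < H and allowed[yi, xi]:
                x, y = nx, ny
            out[i, k, 0] = x
            out[i, k, 1] = y
    return out


def render_frames(
    arena: ArenaSpec,
    trace: np.ndarray,
    background_level: float = 0.9,
    fly_level: float = 0.1,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> np.ndarray:
    """Render a trace as an image stack: dark disks on a bright field."""
    if trace.ndim == 2:
        trace = trace[:, None, :]
    n, n_flies, _ = trace.shape
    H, W = arena.height, arena.width
    r = arena.blob_radius
    yy, xx = np.mgrid[-r : r + 1, -r : r + 1]
    disk = (xx**2 + yy**2) <= r**2
    frames = np.full((n, H, W), background_level, dtype=float)
    for i in range(n):
        for k in range(n_flies):
            x, y = trace[i, k]
            cx, cy = int(round(x)), int(round(y))
            if not (0 <= cx < W and 0 <= cy < H):
                raise ValueError(f"trace exits image bounds at frame {i}")
            x0, x1 = max(0, cx - r), min(W, cx + r + 1)
            y0, y1 = max(0, cy - r), min(H, cy + r + 1)
            sub = disk[(y0 - cy + r) : (y1 - cy + r), (x0 - cx + r) : (x1 - cx + r)]
            block = frames[i, y0:y1, x0:x1]
            block[sub] = fly_level
    if noise_sd > 0:
        rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(99,)))
        frames = frames + rng.normal(0.0, noise_sd, frames.shape)
    return frames
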