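"""Synthetic ground-truth generator for wheel-running video and activity.

The study's videos were never deposited, so this module supplies the data
the rest of the pipeline is validated against: 1-s clips whose true
foot-strike frequency is known by construction, and 2-h bouts whose
per-second frequency series is coupled to per-minute wheel-turn counts.

The scene model is deliberately minimal — a static cage background, a
bright body blob whose hindquarters bob with the gait cycle, and a limb
marker that touches a fixed "wheel surface" row once per foot strike.
That gives the classifier the same kind of learnable periodic signature a
camera above an angled running wheel records (the published network was
observed to key on hindquarter shape changes), without attempting
photorealism.

Class distributions default to the published label fractions of the
human-scored datasets: the aged cohort (n = 4800 clips, 8 classes, 68.6 %
of seconds at 0 Hz) and the young cohort (n = 1000 clips, 11 classes,
faster gait).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .io import FPS, FrameStack, LabeledClip

__all__ = [
    "AGED_FRACTIONS",
    "YOUNG_FRACTIONS",
    "ClassDistribution",
    "ClipRenderSpec",
    "BoutSpec",
    "DistributionError",
    "RenderError",
    "aged_distribution",
    "young_distribution",
    "uniform_distribution",
    "sample_labels",
    "render_clip",
    "render_dataset",
    "simulate_bout",
]

# Published label fractions (percent) of the human-scored datasets,
# classes 0..8 Hz.  The aged row is zero at 8 Hz, so the aged cohort uses
# N_freq = 8 (classes 0..7); the young cohort uses N_freq = 11 with the
# unobserved 9- and 10-Hz classes at zero.
AGED_FRACTIONS = (68.6, 1.7, 3.7, 5.6, 8.3, 8.6, 3.4, 0.1)
YOUNG_FRACTIONS = (49.2, 2.0, 3.1, 2.2, 3.8, 5.7, 15.4, 16.8, 1.8, 0.0, 0.0)


class DistributionError(ValueError):
    """Invalid class distribution (negative mass or not normalized)."""


class RenderError(ValueError):
    """Un-renderable clip request (bad geometry or frequency)."""


@dataclass(frozen=True)
class ClassDistribution:
    """Probabilities over foot-strike-frequency classes 0..N_freq-1."""

    fractions: tuple[float, ...]

    def __post_init__(self) -> None:
        fr = tuple(float(f) for f in self.fractions)
        object.__setattr__(self, "fractions", fr)
        if len(fr) < 1:
            raise DistributionError("empty distribution")
        if any(f < 0 for f in fr):
            raise DistributionError(f"negative class fraction in {fr}")
        total = sum(fr)
        if abs(total - 1.0) > 1e-9:
            raise DistributionError(f"fractions sum to {total!r}, not 1")

    @property
    def n_classes(self) -> int:
        return len(self.fractions)

    @classmethod
    def from_percent(cls, percents: Sequence[float]) -> "ClassDistribution":
        """Build from percentages (e.g. a published table row); renormalizes
        the printed, rounded values so they sum exactly to 1."""
        arr = np.asarray(percents, dtype=np.float64)
        if arr.sum() <= 0:
            raise DistributionError("percentages sum to zero")
        return cls(tuple(arr / arr.sum()))

    def restrict_running(self) -> "ClassDistribution":
        """The distribution conditioned on the animal actually running
        (class 0 removed and the rest renormalized)."""
        if self.n_classes < 2:
            raise DistributionError("cannot restrict a single-class distribution")
        rest = np.asarray(self.fractions[1:])
        if rest.sum() <= 0:
            raise DistributionError("no mass on running classes")
        return ClassDistribution(tuple(np.concatenate([[0.0], rest / rest.sum()])))


def aged_distribution() -> ClassDistribution:
    return ClassDistribution.from_percent(AGED_FRACTIONS)


def young_distribution() -> ClassDistribution:
    return ClassDistribution.from_percent(YOUNG_FRACTIONS)


def uniform_distribution(n_classes: int) -> ClassDistribution:
    return ClassDistribution(tuple([1.0 / n_classes] * n_classes))


def sample_labels(dist: ClassDistribution, n: int, seed: int) -> np.ndarray:
    """Draw ``n`` i.i.d. frequency labels from ``dist`` (reproducible)."""
    if n < 0:
        raise ValueError(f"n must be nonnegative, got {n}")
    rng = np.random.default_rng(seed)
    return rng.choice(dist.n_classes, size=n, p=np.asarray(dist.fractions))


@dataclass(frozen=True)
class ClipRenderSpec:
    """Geometry and noise parameters of the synthetic clip renderer.

    All lengths are in pixels.  ``strike_jitter`` perturbs each strike
    time by a uniform fraction of the inter-strike interval, approximating
    steady gait with realistic irregularity.  Defaults render 64x64
    frames — full-fidelity 240x320 rendering is just a spec change.
    """

    height: int = 64
    width: int = 64
    fps: int = FPS
    body_radius: float = 0.18  # vertical semi-axis, as a fraction of height
    limb_amplitude: float = 0.12  # limb lift between strikes, fraction of height
    strike_jitter: float = 0.2
    noise_sigma: float = 0.0
    background_seedable: bool = True

    def __post_init__(self) -> None:
        if self.height <= 0 or self.width <= 0:
            raise RenderError("frame dimensions must be positive")
        if self.fps <= 0:
            raise RenderError("fps must be positive")
        if self.noise_sigma < 0:
            raise RenderError("noise_sigma must be >= 0")
        if not 0 <= self.strike_jitter < 0.5:
            raise RenderError("strike_jitter must lie in [0, 0.5)")
        if self.limb_amplitude * self.height >= self.height / 2:
            raise RenderError("limb_amplitude must be below height/2")


def _strike_times(freq_hz: int, jitter: float, rng: np.random.Generator) -> np.ndarray:
    """Strike instants (i + u_i)/f seconds, u_i ~ U(-jitter, jitter), in [0, 1)."""
    u = rng.uniform(-jitter, jitter, size=freq_hz)
    t = (np.arange(freq_hz) + u) / freq_hz
    return np.clip(t, 0.0, np.nextafter(1.0, 0.0))


def _contact_frames(times: np.ndarray, fps: int) -> np.ndarray:
    """Map strike instants to distinct frame indices at least 2 frames apart,
    so each contact is a single frame flanked by lifted-limb frames and
    event counting is unambiguous."""
    k = np.clip(np.round(times * fps).astype(int), 0, fps - 1)
    k.sort()
    for i in range(1, len(k)):
        if k[i] <= k[i - 1] + 1:
            k[i] = k[i - 1] + 2
    if len(k) and k[-1] >= fps:
        # ran off the end; repack leftwards keeping the 2-frame spacing
        k[-1] = fps - 1
        for i in range(len(k) - 2, -1, -1):
            if k[i] >= k[i + 1] - 1:
                k[i] = k[i + 1] - 2
    return k


def _lift_profile(contacts: np.ndarray, fps: int, freq_hz: int) -> np.ndarray:
    """Per-frame limb lift in [0, 1]: zero at contact frames, a sine arc
    between consecutive contacts, cyclically extended at the clip edges.

    Non-contact frames are floored at 0.4 so the limb marker is several
    pixels clear of the wheel surface except at the strike instant — the
    contact event is unambiguous at any rendering resolution.
    """
    lift = np.ones(fps)
    if len(contacts) == 0:
        return lift
    gap = max(2, round(fps / max(freq_hz, 1)))
    ext = np.concatenate([[contacts[0] - gap], contacts, [contacts[-1] + gap]])
    arc = np.ones(fps)
    for a, b in zip(ext[:-1], ext[1:]):
        span = b - a
        for m in range(max(a, 0), min(b + 1, fps)):
            arc[m] = min(arc[m], abs(math.sin(math.pi * (m - a) / span)))
    lift = 0.4 + 0.6 * arc
    lift[contacts] = 0.0
    return lift


def _disc(h: int, w: int, cy: float, cx: float, ry: float, rx: float) -> np.ndarray:
    yy, xx = np.ogrid[:h, :w]
    return ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2 <= 1.0


def render_clip(freq_hz: int, spec: ClipRenderSpec, seed: int) -> FrameStack:
    """Render one 1-s clip containing exactly ``freq_hz`` limb-strike events.

    The scene: a static textured background with a bright "wheel surface"
    row near the bottom; an elliptical body whose hindquarters bob with
    the gait cycle; and a limb marker that descends to the surface row
    once per strike.  A 0-Hz clip renders (seeded coin flip) either an
    empty cage or a present-but-motionless mouse.  Deterministic given
    ``(freq_hz, spec, seed)``; intensities lie in [0, 1].
    """
    if freq_hz < 0 or freq_hz > spec.fps / 2:
        raise RenderError(
            f"freq_hz={freq_hz} outside [0, fps/2] (Nyquist limit at {spec.fps} fps)"
        )
    rng = np.random.default_rng(seed)
    h, w, fps = spec.height, spec.width, spec.fps

    # static background: coarse texture upsampled, plus the surface row
    if spec.background_seedable:
        coarse = rng.uniform(0.05, 0.22, size=(-(-h // 8), -(-w // 8)))
        bg = np.kron(coarse, np.ones((8, 8)))[:h, :w]
    else:
        bg = np.full((h, w), 0.12)
    surface_row = int(round(0.88 * h))
    bg[surface_row, :] = 0.4

    body_cy, body_cx = 0.42 * h, 0.5 * w
    body_ry, body_rx = spec.body_radius * h, 1.5 * spec.body_radius * w / 2
    limb_cx = 0.62 * w
    limb_r = max(1.0, 0.035 * h)
    amp = spec.limb_amplitude * h

    present = True
    if freq_hz == 0:
        present = rng.random() < 0.5  # absent vs. on-wheel-but-motionless
        lift = np.ones(fps)
    else:
        times = _strike_times(freq_hz, spec.strike_jitter, rng)
        contacts = _contact_frames(times, fps)
        lift = _lift_profile(contacts, fps, freq_hz)

    frames = np.empty((fps, h, w), dtype=np.float32)
    for t in range(fps):
        frame = bg.copy()
        if present:
            bob = 0.05 * h * (1.0 - lift[t]) if freq_hz > 0 else 0.0
            frame[_disc(h, w, body_cy + bob, body_cx, body_ry, body_rx)] = 0.7
            limb_y = surface_row - amp * lift[t]
            frame[_disc(h, w, limb_y, limb_cx, limb_r, limb_r)] = 1.0
        frames[t] = frame
    if spec.noise_sigma > 0:
        frames = frames + rng.normal(0.0, spec.noise_sigma, size=frames.shape)
    frames = np.clip(frames, 0.0, 1.0).astype(np.float32)
    return FrameStack(frames, fps=fps, origin=(f"synthetic-{freq_hz}hz-{seed}", 0))


def render_dataset(
    dist: ClassDistribution, n: int, spec: ClipRenderSpec, seed: int
) -> list[LabeledClip]:
    """``n`` labeled clips with frequencies drawn from ``dist``.

    Per-clip render seeds are spawned deterministically from the master
    seed, so the dataset is reproducible as a whole while every clip gets
    an independent stream.
    """
    labels = sample_labels(dist, n, seed)
    child_seeds = np.random.SeedSequence(seed).spawn(n)
    clips = []
    for i, (label, child) in enumerate(zip(labels, child_seeds)):
        clip_seed = int(child.generate_state(1)[0] % (2**31))
        stack = render_clip(int(label), spec, clip_seed)
        stack.origin = (stack.origin[0], i)
        clips.append(
            LabeledClip(stack=stack, label=int(label), mouse_id="sim", bout_id="sim")
        )
    return clips


@dataclass(frozen=True)
class BoutSpec:
    """Parameters of a simulated 2-h wheel-access bout.

    Running is episodic: episode onsets follow a Poisson process with
    ``episode_rate`` starts per hour and exponential lengths of mean
    ``episode_length_s`` seconds.  Within an episode the per-second
    frequency is drawn from ``freq_distribution`` conditioned on running
    (class 0 removed); outside episodes the frequency is 0 Hz.  Wheel
    turns per minute are ``turns_per_strike`` x strikes that minute plus
    Gaussian noise (wheel free-spin and telemetry slop), floored at zero
    and rounded to integers.
    """

    duration_s: int = 7200
    episode_rate: float = 6.0  # episode starts per hour
    episode_length_s: float = 120.0
    freq_distribution: ClassDistribution = field(default_factory=aged_distribution)
    turns_per_strike: float = 0.25  # one stride advances ~1/4 wheel turn
    turn_noise_sd: float = 5.0  # turns/min
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        if self.turns_per_strike <= 0:
            raise ValueError("turns_per_strike must be positive")
        if self.episode_rate < 0 or self.episode_length_s <= 0:
            raise ValueError("invalid episode parameters")
        if self.turn_noise_sd < 0:
            raise ValueError("turn_noise_sd must be >= 0")


def simulate_bout(spec: BoutSpec) -> tuple[np.ndarray, np.ndarray]:
    """One bout: (per-second frequency series, per-minute wheel-turn counts).

    Reproducible given ``spec.seed``; off-episode seconds are 0 Hz.
    """
    rng = np.random.default_rng(spec.seed)
    freq = np.zeros(spec.duration_s, dtype=np.int64)
    n_episodes = rng.poisson(spec.episode_rate * spec.duration_s / 3600.0)
    starts = np.sort(rng.uniform(0, spec.duration_s, size=n_episodes))
    lengths = rng.exponential(spec.episode_length_s, size=n_episodes)
    running = spec.freq_distribution.restrict_running()
    p = np.asarray(running.fractions)
    for s, ln in zip(starts, lengths):
        a, b = int(s), min(int(s + ln) + 1, spec.duration_s)
        freq[a:b] = rng.choice(running.n_classes, size=b - a, p=p)
    n_minutes = -(-spec.duration_s // 60)
    strikes_per_min = np.add.reduceat(freq, np.arange(0, spec.duration_s, 60))
    turns = spec.turns_per_strike * strikes_per_min
    if spec.turn_noise_sd > 0:
        turns = turns + rng.normal(0.0, spec.turn_noise_sd, size=n_minutes)
    turns = np.round(np.maximum(turns, 0.0)).astype(np.int64)
    return freq, turns
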