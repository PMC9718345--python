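"""Stimulus schedules: ordered music / white-noise blocks plus reward times.

The behavioural protocol alternates 3-minute auditory blocks (three musical
pieces at 212, 113 and 85 beats/min, and three white-noise controls) with
1-minute silent gaps; small liquid rewards (0.2 ml) are delivered roughly
once per 30 s during each block.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "StimulusBlock",
    "SessionSchedule",
    "build_default_schedule",
    "MUSIC_TEMPOS_BPM",
    "BLOCK_DURATION_S",
    "BLOCK_GAP_S",
    "REWARDS_PER_BLOCK",
]

#: Tempos of the three musical stimuli, beats per minute (fast, medium, slow).
MUSIC_TEMPOS_BPM = (212, 113, 85)
BLOCK_DURATION_S = 180.0
BLOCK_GAP_S = 60.0
REWARDS_PER_BLOCK = 6
MIN_REWARD_SPACING_S = 10.0
MUSIC_LEVEL_DB_SPL = 67.5   # midpoint of the 65.0-70.0 dB SPL presentation range
NOISE_LEVEL_DB_SPL = 40.0


@dataclass(frozen=True)
class StimulusBlock:
    """One auditory stimulation block."""

    kind: str                 # "music" or "noise"
    tempo_bpm: float          # 0 for noise
    level_db_spl: float
    start: float              # seconds from session start
    duration: float           # seconds

    def __post_init__(self) -> None:
        if self.kind not in ("music", "noise"):
            raise ValueError(f"unknown block kind {self.kind!r}")
        if not self.duration > 0:
            raise ValueError("block duration must be positive")
        if self.kind == "music" and not self.tempo_bpm > 0:
            raise ValueError("music blocks require tempo_bpm > 0")

    @property
    def end(self) -> float:
        return self.start + self.duration

    def contains(self, t: float) -> bool:
        return self.start <= t < self.end


@dataclass
class SessionSchedule:
    """Time-ordered, non-overlapping stimulus blocks plus reward times."""

    blocks: list[StimulusBlock] = field(default_factory=list)
    reward_times: np.ndarray = field(default_factory=lambda: np.empty(0))
    reward_volume_ml: float = 0.2

    def __post_init__(self) -> None:
        self.reward_times = np.sort(np.asarray(self.reward_times, dtype=float))
        for a, b in zip(self.blocks, self.blocks[1:]):
            if b.start < a.end:
                raise ValueError("blocks must be time-ordered and non-overlapping")
        for t in self.reward_times:
            if self.block_at(t) is None:
                raise ValueError(f"reward at t={t:g}s falls outside every block")

    @property
    def end(self) -> float:
        return self.blocks[-1].end if self.blocks else 0.0

    def block_at(self, t: float) -> int | None:
        """Index of the block containing time ``t``, or None."""
        for i, b in enumerate(self.blocks):
            if b.contains(t):
                return i
        return None

    def to_dict(self) -> dict:
        return {
            "blocks": [
                {"kind": b.kind, "tempo_bpm": b.tempo_bpm,
                 "level_db_spl": b.level_db_spl, "start": b.start,
                 "duration": b.duration}
                for b in self.blocks
            ],
            "reward_times": self.reward_times.tolist(),
            "reward_volume_ml": self.reward_volume_ml,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SessionSchedule":
        blocks = [StimulusBlock(**b) for b in d["blocks"]]
        return cls(blocks=blocks, reward_times=np.asarray(d["reward_times"]),
                   reward_volume_ml=d.get("reward_volume_ml", 0.2))


def _draw_reward_times(rng: np.random.Generator, block: StimulusBlock,
                       n: int = REWARDS_PER_BLOCK,
                       min_spacing: float = MIN_REWARD_SPACING_S) -> np.ndarray:
    """n reward times uniform in the block with a minimum spacing (rejection)."""
    while True:
        t = np.sort(rng.uniform(block.start, block.end, size=n))
        if n < 2 or np.min(np.diff(t)) >= min_spacing:
            return t


def build_default_schedule(seed: int) -> SessionSchedule:
    """The standard one-day session: six 180 s blocks in seeded shuffled order.

    Three music blocks (212 / 113 / 85 bpm) and three white-noise blocks are
    shuffled and separated by 60 s gaps, giving a total span of
    6*180 + 5*60 = 1380 s.  Each block carries six reward times drawn
    uniformly with at least 10 s spacing.
    """
    rng = np.random.default_rng(seed)
    specs = [("music", float(bpm), MUSIC_LEVEL_DB_SPL) for bpm in MUSIC_TEMPOS_BPM]
    specs += [("noise", 0.0, NOISE_LEVEL_DB_SPL)] * 3
    order = rng.permutation(len(specs))
    blocks = []
    for slot, j in enumerate(order):
        kind, bpm, level = specs[j]
        start = slot * (BLOCK_DURATION_S + BLOCK_GAP_S)
        blocks.append(StimulusBlock(kind=kind, tempo_bpm=bpm, level_db_spl=level,
                                    start=start, duration=BLOCK_DURATION_S))
    rewards = np.concatenate([_draw_reward_times(rng, b) for b in blocks])
    return SessionSchedule(blocks=blocks, reward_times=rewards)
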