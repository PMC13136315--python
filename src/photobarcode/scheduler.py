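"""Illumination scheduling for patterned-light barcoding.

Given a codebook assignment (region → codeword), every ligation round is
split into at most ``m`` illumination steps: in round ``r`` under letter
``ℓ``, all regions whose codeword has digit ``ℓ`` at position ``r`` are lit
simultaneously and receive that letter.  A complete ``m**n`` codebook
therefore needs exactly ``m * n`` steps.  The module also verifies that a
schedule is decodable (round-tripping back to the assignment) and renders
per-step binary masks for a digital micromirror device.

Mask conventions: origin at top-left, x rightward, y downward, pixel centers
at integer coordinates.  A pixel is lit iff its center lies inside any
illuminated region's geometry.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .codebook import Codebook, Codeword

__all__ = [
    "ScheduleError",
    "Rect",
    "Circle",
    "Region",
    "LigationStep",
    "IlluminationSchedule",
    "build_schedule",
    "reconstruct_assignment",
    "render_masks",
    "write_masks",
]


class ScheduleError(ValueError):
    """Inconsistent schedule, assignment, or geometry."""


@dataclass(frozen=True)
class Rect:
    """Axis-aligned rectangle; covers integer pixel centers in
    ``[x, x + width) × [y, y + height)``."""

    x: float
    y: float
    width: float
    height: float

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise ScheduleError("rectangle must have positive area")

    def contains(self, xs: np.ndarray, ys: np.ndarray) -> np.ndarray:
        return (
            (xs >= self.x)
            & (xs < self.x + self.width)
            & (ys >= self.y)
            & (ys < self.y + self.height)
        )

    def bounds(self) -> tuple[float, float, float, float]:
        return (self.x, self.y, self.x + self.width, self.y + self.height)


@dataclass(frozen=True)
class Circle:
    """Disc of given radius; covers pixel centers within ``radius`` of
    ``(cx, cy)`` inclusive."""

    cx: float
    cy: float
    radius: float

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ScheduleError("circle must have positive radius")

    def contains(self, xs: np.ndarray, ys: np.ndarray) -> np.ndarray:
        return (xs - self.cx) ** 2 + (ys - self.cy) ** 2 <= self.radius ** 2

    def bounds(self) -> tuple[float, float, float, float]:
        return (
            self.cx - self.radius,
            self.cy - self.radius,
            self.cx + self.radius,
            self.cy + self.radius,
        )


Geometry = Union[Rect, Circle]


@dataclass(frozen=True)
class Region:
    """A spatial region to barcode; geometry is only needed for masks."""

    id: str
    geometry: Optional[Geometry] = None


@dataclass(frozen=True)
class LigationStep:
    """One illumination + ligation event: one letter, a set of regions."""

    round: int
    letter_id: int
    regions: frozenset[str]

    def __post_init__(self) -> None:
        if not self.regions:
            raise ScheduleError("a ligation step must illuminate >= 1 region")


@dataclass
class IlluminationSchedule:
    """Ordered ligation steps sorted by (round, letter id)."""

    steps: list[LigationStep]
    n: int
    m: int

    def __post_init__(self) -> None:
        keys = [(s.round, s.letter_id) for s in self.steps]
        if keys != sorted(keys):
            raise ScheduleError("steps must be sorted by (round, letter_id)")
        if len(set(keys)) != len(keys):
            raise ScheduleError("duplicate (round, letter) step")

    def __len__(self) -> int:
        return len(self.steps)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "step_index": range(1, len(self.steps) + 1),
                "round": [s.round for s in self.steps],
                "letter_id": [s.letter_id for s in self.steps],
                "region_ids": [";".join(sorted(s.regions)) for s in self.steps],
            }
        )

    def save_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def load_csv(cls, path: str | Path, n: int, m: int) -> "IlluminationSchedule":
        df = pd.read_csv(path)
        steps = [
            LigationStep(
                int(row["round"]),
                int(row["letter_id"]),
                frozenset(str(row["region_ids"]).split(";")),
            )
            for _, row in df.iterrows()
        ]
        return cls(steps, n=n, m=m)


def build_schedule(
    codebook: Codebook, regions: Sequence[Region | str]
) -> IlluminationSchedule:
    """Group regions into simultaneous illumination steps, round by round.

    For each round ``r`` and each letter ``ℓ`` (ascending id), emit one step
    containing exactly the regions whose assigned codeword carries ``ℓ`` at
    digit ``r``.  Letters unused in a round produce no step, so the total is
    at most ``m * n`` with equality for a fully used assignment.
    """
    region_ids = [r.id if isinstance(r, Region) else str(r) for r in regions]
    if len(set(region_ids)) != len(region_ids):
        raise ScheduleError("region ids must be unique")
    missing = [rid for rid in region_ids if rid not in codebook.assignment]
    if missing:
        raise ScheduleError(f"regions without assigned codeword: {missing}")
    steps = []
    for rnd in range(1, codebook.n + 1):
        groups: dict[int, list[str]] = {}
        for rid in region_ids:
            digit = codebook.assignment[rid].digits[rnd - 1]
            groups.setdefault(digit, []).append(rid)
        for letter_id in sorted(groups):
            steps.append(LigationStep(rnd, letter_id, frozenset(groups[letter_id])))
    return IlluminationSchedule(steps, n=codebook.n, m=codebook.m)


def reconstruct_assignment(
    schedule: IlluminationSchedule,
) -> dict[str, Codeword]:
    """Reassemble each region's codeword from the steps it appears in.

    Raises :class:`ScheduleError` if any (region, round) pair is missing or
    duplicated — i.e. if the schedule is not uniquely decodable.
    """
    digits: dict[str, dict[int, int]] = {}
    for step in schedule.steps:
        for rid in step.regions:
            per_region = digits.setdefault(rid, {})
            if step.round in per_region:
                raise ScheduleError(
                    f"region {rid!r} appears twice in round {step.round}"
                )
            per_region[step.round] = step.letter_id
    assignment: dict[str, Codeword] = {}
    for rid, per_region in digits.items():
        if set(per_region) != set(range(1, schedule.n + 1)):
            missing = sorted(set(range(1, schedule.n + 1)) - set(per_region))
            raise ScheduleError(f"region {rid!r} missing rounds {missing}")
        assignment[rid] = Codeword(
            tuple(per_region[rnd] for rnd in range(1, schedule.n + 1))
        )
    return assignment


def render_masks(
    schedule: IlluminationSchedule,
    regions: Sequence[Region],
    width: int,
    height: int,
) -> list[np.ndarray]:
    """Render one binary (0/1 uint8) mask per step on a width×height canvas."""
    geom = {}
    for region in regions:
        if region.geometry is None:
            continue
        x0, y0, x1, y1 = region.geometry.bounds()
        if x0 < 0 or y0 < 0 or x1 > width or y1 > height:
            raise ScheduleError(
                f"region {region.id!r} geometry outside {width}x{height} canvas"
            )
        geom[region.id] = region.geometry
    xs, ys = np.meshgrid(np.arange(width), np.arange(height))
    masks = []
    for step in schedule.steps:
        missing = [rid for rid in step.regions if rid not in geom]
        if missing:
            raise ScheduleError(f"regions without geometry: {sorted(missing)}")
        mask = np.zeros((height, width), dtype=np.uint8)
        for rid in step.regions:
            mask |= geom[rid].contains(xs, ys).astype(np.uint8)
        masks.append(mask)
    return masks


def write_masks(
    masks: Sequence[np.ndarray],
    schedule: IlluminationSchedule,
    out_dir: str | Path,
) -> list[Path]:
    """Write each mask as a plain-text PGM (P2), 0 = dark, 1 = lit."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for idx, (mask, step) in enumerate(zip(masks, schedule.steps), start=1):
        path = out_dir / f"step{idx}_round{step.round}_L{step.letter_id}.pgm"
        h, w = mask.shape
        lines = [f"P2", f"{w} {h}", "1"]
        lines += [" ".join(str(int(v)) for v in row) for row in mask]
        path.write_text("\n".join(lines) + "\n")
        paths.append(path)
    return paths
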