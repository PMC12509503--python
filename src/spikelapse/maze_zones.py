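"""Maze-zone segmentation and trial parsing for the delayed alternation task.

The task maze is a figure-8: a central stem holding the delay zone, a
choice box at the top of the stem, outer arms running along the top and
down the east/west sides, reward boxes at the bottom corners, and return
corridors back to the stem.  Statistics downstream consume four zone
classes -- delay, choice, outer arm, reward -- with the reward and outer
zones carrying an east/west side.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Trajectory",
    "ZoneMap",
    "default_zone_map",
    "assign_zones",
    "parse_trials",
    "count_by_zone",
    "ZONE_CLASSES",
]

ZONE_CLASSES = ("delay", "choice", "outer_arm", "reward")


@dataclass
class Trajectory:
    """Timestamped 2-D position samples (cm)."""

    t_s: np.ndarray
    x_cm: np.ndarray
    y_cm: np.ndarray

    def __post_init__(self) -> None:
        self.t_s = np.asarray(self.t_s, dtype=float)
        self.x_cm = np.asarray(self.x_cm, dtype=float)
        self.y_cm = np.asarray(self.y_cm, dtype=float)
        if not (len(self.t_s) == len(self.x_cm) == len(self.y_cm)):
            raise ValueError("t, x, y must have equal length")

    @property
    def sample_period_s(self) -> float:
        return float(np.median(np.diff(self.t_s))) if len(self.t_s) > 1 else np.nan

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"t_s": self.t_s, "x_cm": self.x_cm, "y_cm": self.y_cm})


@dataclass
class ZoneMap:
    """Named axis-aligned rectangles; first match wins, off-maze is 'none'.

    ``rects`` maps a zone instance name (e.g. ``reward_east``) to
    ``(x0, x1, y0, y1)``.  ``zone_class`` and ``side`` give the statistical
    zone and east/west side of each instance.
    """

    rects: dict[str, tuple[float, float, float, float]]
    zone_class: dict[str, str]
    side: dict[str, str | None]
    bounds: tuple[float, float, float, float] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.bounds is None:
            xs = [r[0] for r in self.rects.values()] + [r[1] for r in self.rects.values()]
            ys = [r[2] for r in self.rects.values()] + [r[3] for r in self.rects.values()]
            self.bounds = (min(xs), max(xs), min(ys), max(ys))

    def lookup(self, x: float, y: float) -> str:
        for name, (x0, x1, y0, y1) in self.rects.items():
            if x0 <= x <= x1 and y0 <= y <= y1:
                return name
        return "none"


def default_zone_map(width_cm: float = 80.0, height_cm: float = 90.0) -> ZoneMap:
    """Figure-8 maze with the standard zone sizes.

    Delay occupies 40 cm of the central arm, the stem/choice box is
    15 x 15 cm, reward boxes are 15 x 25 cm, and the outer arms are the
    top corridor plus the descending side corridors.
    """
    hw = width_cm / 2.0
    h = height_cm
    rects = {
        "reward_east": (hw - 15.0, hw, 0.0, 25.0),
        "reward_west": (-hw, -hw + 15.0, 0.0, 25.0),
        "choice": (-7.5, 7.5, h - 15.0, h),
        "delay": (-5.0, 5.0, 10.0, 50.0),
        "outer_top_east": (7.5, hw, h - 10.0, h),
        "outer_top_west": (-hw, -7.5, h - 10.0, h),
        "outer_side_east": (hw - 10.0, hw, 25.0, h - 10.0),
        "outer_side_west": (-hw, -hw + 10.0, 25.0, h - 10.0),
    }
    zone_class = {
        "reward_east": "reward",
        "reward_west": "reward",
        "choice": "choice",
        "delay": "delay",
        "outer_top_east": "outer_arm",
        "outer_top_west": "outer_arm",
        "outer_side_east": "outer_arm",
        "outer_side_west": "outer_arm",
    }
    side = {
        "reward_east": "east",
        "reward_west": "west",
        "choice": None,
        "delay": None,
        "outer_top_east": "east",
        "outer_top_west": "west",
        "outer_side_east": "east",
        "outer_side_west": "west",
    }
    return ZoneMap(rects=rects, zone_class=zone_class, side=side,
                   bounds=(-hw, hw, 0.0, h))


def assign_zones(traj: Trajectory, zm: ZoneMap, merge_classes: bool = False) -> np.ndarray:
    """Label every trajectory sample with its zone instance (or 'none').

    With ``merge_classes`` the east/west instances collapse to the four
    statistical zone classes.
    """
    if not (np.all(np.isfinite(traj.x_cm)) and np.all(np.isfinite(traj.y_cm))):
        raise ValueError("positions must be finite")
    labels = np.array([zm.lookup(x, y) for x, y in zip(traj.x_cm, traj.y_cm)], dtype=object)
    if merge_classes:
        labels = np.array(
            [zm.zone_class.get(name, "none") for name in labels], dtype=object
        )
    return labels


def occupancy_seconds(labels: np.ndarray, sample_period_s: float) -> dict[str, float]:
    """Occupancy per label = sample count x sample period."""
    out: dict[str, float] = {}
    for name, count in zip(*np.unique(labels, return_counts=True)):
        out[str(name)] = float(count) * sample_period_s
    return out


def parse_trials(
    zones: np.ndarray,
    times: np.ndarray,
    zm: ZoneMap,
    delay_interval_s: float = 30.0,
    session: int = 0,
) -> pd.DataFrame:
    """Parse a session into trials from the sequence of zone entries.

    A trial runs from a delay-zone entry to the next reward-zone entry.
    Correctness follows the alternation rule (side differs from the
    previous trial's side); the first trial counts as correct.  Delay exit
    latency is measured from the end of the imposed delay interval to the
    delay-zone exit.
    """
    zones = np.asarray(zones, dtype=object)
    times = np.asarray(times, dtype=float)
    # collapse to entry events
    change = np.concatenate([[True], zones[1:] != zones[:-1]])
    seq = zones[change]
    seq_t = times[change]
    rows = []
    prev_side = None
    trial = 0
    i = 0
    while i < len(seq):
        if seq[i] != "delay":
            i += 1
            continue
        delay_entry = seq_t[i]
        delay_exit = seq_t[i + 1] if i + 1 < len(seq) else times[-1]
        j = i + 1
        reward_name = None
        while j < len(seq):
            if zm.zone_class.get(seq[j], "none") == "reward":
                reward_name = seq[j]
                break
            if seq[j] == "delay":
                break
            j += 1
        if reward_name is None:
            i = j if j > i else i + 1
            continue
        side = zm.side[reward_name]
        correct = prev_side is None or side != prev_side
        rows.append(
            {
                "session": session,
                "trial": trial,
                "choice": side,
                "correct": bool(correct),
                "delay_entry_s": float(delay_entry),
                "delay_exit_s": float(delay_exit),
                "reward_entry_s": float(seq_t[j]),
                "delay_exit_latency_s": float(delay_exit - delay_entry - delay_interval_s),
            }
        )
        prev_side = side
        trial += 1
        i = j + 1
    return pd.DataFrame(
        rows,
        columns=[
            "session", "trial", "choice", "correct", "delay_entry_s",
            "delay_exit_s", "reward_entry_s", "delay_exit_latency_s",
        ],
    )


def count_by_zone(
    event_times_s: np.ndarray,
    zones: np.ndarray,
    times: np.ndarray,
    sample_period_s: float,
) -> pd.DataFrame:
    """One ZoneCountTable row set: spike counts and occupancy per zone class.

    Each event takes the zone of the trajectory sample nearest its
    timestamp; events landing off-maze ('none') are excluded from counts
    but reported in the ``n_excluded`` attribute.
    """
    event_times_s = np.asarray(event_times_s, dtype=float)
    times = np.asarray(times, dtype=float)
    idx = np.clip(np.searchsorted(times, event_times_s), 0, len(times) - 1)
    # nearest sample, not insertion point
    left = np.clip(idx - 1, 0, len(times) - 1)
    use_left = np.abs(times[left] - event_times_s) < np.abs(times[idx] - event_times_s)
    idx = np.where(use_left, left, idx)
    ev_zone = np.asarray(zones, dtype=object)[idx]
    occ = occupancy_seconds(np.asarray(zones, dtype=object), sample_period_s)
    rows = []
    for z in ZONE_CLASSES:
        rows.append(
            {
                "zone": z,
                "spikes": int(np.sum(ev_zone == z)),
                "occupancy_s": occ.get(z, 0.0),
            }
        )
    df = pd.DataFrame(rows)
    df.attrs["n_excluded"] = int(np.sum(ev_zone == "none"))
    return df


def expected_counts(table: pd.DataFrame) -> np.ndarray:
    """Chi-square expected counts: percent time in zone x total spike count."""
    p_time = table["occupancy_s"].to_numpy() / table["occupancy_s"].sum()
    return p_time * table["spikes"].sum()
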