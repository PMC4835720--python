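"""Trajectory tables and directed interaction-event extraction.

Tracked fly trajectories (one row per frame per individual: position in mm
and body length) are turned into directed interaction events using three
rules commonly applied to arena-tracking data:

* **proximity** — centre-to-centre distance below a multiple of the
  replicate's mean body length (default 1.1, a 10% margin for contacts
  between antennae or front legs that the tracker cannot resolve);
* **persistence** — the proximity run must last strictly more than five
  frames (0.5 s at 10 fps); shorter episodes are flies crossing paths;
* **initiator rule** — the faster of the two flies over the four frames
  preceding the contact (path length travelled) is credited as initiator.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = ("frame", "individual", "x", "y", "body_length")


@dataclass(frozen=True)
class ExtractionConfig:
    """Parameters of the interaction-calling rules.

    Attributes
    ----------
    distance_factor : float
        Proximity threshold in units of the replicate mean body length.
    min_frames : int
        Minimum run length in frames for a proximity run to count as an
        interaction. The default 6 encodes "strictly more than five frames".
    speed_window : int
        Number of frames preceding a contact over which travelled distance
        decides the initiator.
    fps : float
        Recording rate, frames per second.
    """

    distance_factor: float = 1.1
    min_frames: int = 6
    speed_window: int = 4
    fps: float = 10.0

    def __post_init__(self) -> None:
        if self.distance_factor <= 0:
            raise ValueError("distance_factor must be positive")
        if self.min_frames < 1:
            raise ValueError("min_frames must be >= 1")
        if self.speed_window < 1:
            raise ValueError("speed_window must be >= 1")


@dataclass(frozen=True, order=True)
class InteractionEvent:
    """One directed contact: ``initiator`` approached ``receiver`` during
    the inclusive frame span [start_frame, end_frame]."""

    start_frame: int
    end_frame: int
    initiator: int
    receiver: int

    def __post_init__(self) -> None:
        if self.initiator == self.receiver:
            raise ValueError("initiator and receiver must differ")
        if self.end_frame < self.start_frame:
            raise ValueError("end_frame must be >= start_frame")

    @property
    def n_frames(self) -> int:
        return self.end_frame - self.start_frame + 1


@dataclass
class TrajectoryTable:
    """Per-frame positions of identified individuals in one replicate.

    ``data`` holds one row per (frame, individual) with columns
    ``frame, individual, x, y, body_length`` (positions and lengths in mm).
    Missing (frame, individual) rows are tracking gaps. ``classes`` maps an
    individual id to its binary covariate (informed = 1, uninformed = 0).
    """

    data: pd.DataFrame
    fps: float = 10.0
    classes: dict[int, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in REQUIRED_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"missing required columns: {missing}")
        dup = self.data.duplicated(subset=["frame", "individual"])
        if dup.any():
            row = self.data.loc[dup.idxmax()]
            raise ValueError(
                "duplicate (frame, individual) pair: "
                f"frame={int(row['frame'])}, individual={row['individual']}"
            )
        if (self.data["body_length"] <= 0).any():
            raise ValueError("body_length must be positive everywhere")
        self.data = self.data.sort_values(["individual", "frame"]).reset_index(drop=True)

    @property
    def individuals(self) -> list[int]:
        return sorted(self.data["individual"].unique().tolist())

    @property
    def frame_range(self) -> tuple[int, int]:
        return int(self.data["frame"].min()), int(self.data["frame"].max())

    def gaps(self) -> dict[int, list[int]]:
        """Missing frames per individual, within that individual's span."""
        out: dict[int, list[int]] = {}
        for ind, grp in self.data.groupby("individual"):
            frames = grp["frame"].to_numpy()
            full = np.arange(frames.min(), frames.max() + 1)
            miss = np.setdiff1d(full, frames)
            if miss.size:
                out[ind] = miss.tolist()
        return out

    def positions_of(self, individual: int) -> pd.DataFrame:
        sub = self.data[self.data["individual"] == individual]
        return sub.set_index("frame")[["x", "y"]]


def read_trajectories(
    path, format: str = "csv", classes_path=None, fps: float = 10.0
) -> TrajectoryTable:
    """Read a trajectory CSV (``frame,individual,x,y,body_length``).

    An optional two-column CSV ``individual,class`` attaches the binary
    informed/uninformed covariate. Malformed rows raise a parse error that
    names the offending line; duplicate (frame, individual) pairs raise a
    validation error.
    """
    if format != "csv":
        raise ValueError(f"unsupported format: {format!r}")
    try:
        df = pd.read_csv(
            path,
            dtype={
                "frame": np.int64,
                "individual": np.int64,
                "x": np.float64,
                "y": np.float64,
                "body_length": np.float64,
            },
        )
    except (ValueError, pd.errors.ParserError) as exc:
        raise ValueError(f"malformed trajectory file {path}: {exc}") from exc
    bad = (
        df[list(REQUIRED_COLUMNS[2:])].isna().any(axis=1)
        if set(REQUIRED_COLUMNS) <= set(df.columns)
        else None
    )
    if bad is not None and bad.any():
        # +2: one for the header line, one for 0- vs 1-based numbering
        line = int(bad.idxmax()) + 2
        raise ValueError(f"malformed row at line {line} of {path}")
    classes: dict[int, int] = {}
    if classes_path is not None:
        cdf = pd.read_csv(classes_path, dtype={"individual": np.int64, "class": np.int64})
        classes = dict(zip(cdf["individual"], cdf["class"]))
    table = TrajectoryTable(df, fps=fps, classes=classes)
    gaps = table.gaps()
    if gaps:
        n = sum(len(v) for v in gaps.values())
        logger.info("trajectory has %d missing frames across %d individuals", n, len(gaps))
    return table


def mean_body_length(traj: TrajectoryTable) -> float:
    """Replicate-level mean body length: the arithmetic mean over every
    (frame, individual) observation, a single scalar per video."""
    if len(traj.data) == 0:
        raise ValueError("empty trajectory table")
    return float(traj.data["body_length"].mean())


def _path_length(pos: pd.DataFrame, frames: np.ndarray) -> float:
    """Distance travelled within the window: summed step lengths between
    consecutive frames where the fly is tracked on both ends (tracking
    gaps contribute no displacement)."""
    sub = pos.reindex(frames)
    xy = sub.to_numpy(dtype=float)
    steps = np.linalg.norm(np.diff(xy, axis=0), axis=1)
    return float(np.nansum(steps))


def initiator_of(
    traj: TrajectoryTable,
    pair: tuple[int, int],
    start_frame: int,
    cfg: ExtractionConfig | None = None,
) -> int:
    """Identify the initiator of a contact beginning at ``start_frame``.

    The initiator is the fly with the greater travelled distance over the
    ``speed_window`` frames strictly preceding the contact. Ties (for
    instance two stationary flies) go deterministically to the lower actor
    id, and are logged. Returns -1 (with a warning) when neither fly has
    any position in the window — the caller drops the event.
    """
    cfg = cfg or ExtractionConfig()
    a, b = pair
    window = np.arange(max(0, start_frame - cfg.speed_window), start_frame)
    if window.size == 0:
        logger.warning(
            "contact at frame %d has no preceding frames; event dropped", start_frame
        )
        return -1
    pos_a = traj.positions_of(a)
    pos_b = traj.positions_of(b)
    tracked_a = pos_a.index.intersection(window).size > 0
    tracked_b = pos_b.index.intersection(window).size > 0
    if not tracked_a and not tracked_b:
        logger.warning(
            "neither fly of pair (%s, %s) tracked before frame %d; event dropped",
            a, b, start_frame,
        )
        return -1
    dist_a = _path_length(pos_a, window)
    dist_b = _path_length(pos_b, window)
    if dist_a > dist_b:
        return a
    if dist_b > dist_a:
        return b
    winner = min(a, b)
    logger.debug(
        "speed tie (%g mm) for pair (%s, %s) at frame %d; initiator = %s",
        dist_a, a, b, start_frame, winner,
    )
    return winner


def _proximity_runs(mask: np.ndarray, frames: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of consecutive frames where ``mask`` is True.

    ``frames`` carries the actual frame numbers; a jump in frame number
    (tracking gap) breaks a run even if the mask is True on both sides.
    """
    runs: list[tuple[int, int]] = []
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return runs
    f = frames[idx]
    # split where consecutive proximate frames are not adjacent in time
    breaks = np.flatnonzero(np.diff(f) != 1)
    starts = np.concatenate(([0], breaks + 1))
    ends = np.concatenate((breaks, [f.size - 1]))
    for s, e in zip(starts, ends):
        runs.append((int(f[s]), int(f[e])))
    return runs


def extract_interactions(
    traj: TrajectoryTable, cfg: ExtractionConfig | None = None
) -> list[InteractionEvent]:
    """Call directed interaction events from a trajectory table.

    For every unordered pair of flies, every maximal run of consecutive
    frames with centre distance strictly below
    ``distance_factor × mean_body_length`` and length ``>= min_frames``
    yields one directed event, oriented by the initiator rule (the fly
    with the longer travelled path over the ``speed_window`` frames
    preceding the run; ties to the lower id). Runs are broken by tracking
    gaps. Events are returned sorted by start frame.

    Vectorised over the full frame grid; agrees with the per-event
    :func:`initiator_of` on every run.
    """
    cfg = cfg or ExtractionConfig()
    threshold = cfg.distance_factor * mean_body_length(traj)
    inds = traj.individuals
    fmin, fmax = traj.frame_range
    grid = np.arange(fmin, fmax + 1)
    xp = traj.data.pivot(index="frame", columns="individual", values="x").reindex(grid)
    yp = traj.data.pivot(index="frame", columns="individual", values="y").reindex(grid)
    col = {a: k for k, a in enumerate(xp.columns)}
    X = xp.to_numpy(dtype=float)
    Y = yp.to_numpy(dtype=float)
    # per-frame step lengths (NaN across gaps -> no displacement) and
    # their prefix sums, for O(1) initiator path sums per run
    steps = np.nan_to_num(np.hypot(np.diff(X, axis=0), np.diff(Y, axis=0)), nan=0.0)
    csum = np.vstack([np.zeros(X.shape[1]), np.cumsum(steps, axis=0)])
    tracked = ~np.isnan(X)
    tcum = np.vstack([np.zeros(X.shape[1]), np.cumsum(tracked, axis=0)])

    def window_path(k: int, s_idx: int) -> tuple[float, bool]:
        lo = max(s_idx - cfg.speed_window, 0)
        # steps between consecutive window frames lo .. s_idx-1
        path = float(csum[s_idx - 1, k] - csum[lo, k])
        any_tracked = (tcum[s_idx, k] - tcum[lo, k]) > 0
        return path, bool(any_tracked)

    events: list[InteractionEvent] = []
    n_dropped = 0
    for ai in range(len(inds)):
        for bi in range(ai + 1, len(inds)):
            a, b = inds[ai], inds[bi]
            ka, kb = col[a], col[b]
            d = np.hypot(X[:, ka] - X[:, kb], Y[:, ka] - Y[:, kb])
            mask = d < threshold  # NaN compares False: gaps break runs
            for s, e in _proximity_runs(mask, grid):
                if e - s + 1 < cfg.min_frames:
                    continue
                s_idx = s - fmin
                if s_idx == 0:
                    n_dropped += 1
                    continue
                path_a, ok_a = window_path(ka, s_idx)
                path_b, ok_b = window_path(kb, s_idx)
                if not ok_a and not ok_b:
                    n_dropped += 1
                    continue
                init = a if path_a > path_b else b if path_b > path_a else min(a, b)
                recv = b if init == a else a
                events.append(InteractionEvent(s, e, init, recv))
    if n_dropped:
        logger.warning("%d events dropped for lack of pre-contact positions", n_dropped)
    events.sort()
    return events


def write_events(events: list[InteractionEvent], path) -> None:
    """Write events as TSV: ``initiator  receiver  start_frame  end_frame``."""
    df = pd.DataFrame(
        [(ev.initiator, ev.receiver, ev.start_frame, ev.end_frame) for ev in events],
        columns=["initiator", "receiver", "start_frame", "end_frame"],
    )
    df.to_csv(path, sep="\t", index=False)


def read_events(path) -> list[InteractionEvent]:
    df = pd.read_csv(path, sep="\t")
    return [
        InteractionEvent(int(r.start_frame), int(r.end_frame), int(r.initiator), int(r.receiver))
        for r in df.itertuples()
    ]
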