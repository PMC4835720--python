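"""Network-panel construction, Jaccard screening, and condition labels.

Interaction events are binned into fixed-length time slices (5, 10 or
15 min) and binarized: actor i has a directed tie to actor j in a slice
iff i initiated at least one contact with j whose start frame falls in
that slice. The first slice is usually discarded (flies are hyperactive
right after introduction into the arena). Consecutive slices are screened
with the Jaccard index — panels changing too abruptly (index <= 0.2) are
not successive states of one evolving network and are unsuitable for
actor-oriented modelling.

Replicates are labelled by where the uninformed flies later laid their
eggs: ``Followed`` if more than 80% of their eggs are on the medium the
informed flies were trained to prefer, ``Avoided`` if less than 20%,
``Excluded`` otherwise.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .trajectories import InteractionEvent

logger = logging.getLogger(__name__)


class ConditionLabel(enum.Enum):
    FOLLOWED = "Followed"
    AVOIDED = "Avoided"
    EXCLUDED = "Excluded"


@dataclass
class NetworkPanel:
    """An ordered sequence of binary directed networks on a fixed actor set.

    Attributes
    ----------
    group_id : str
        Replicate label (one panel per video / arena run).
    observations : np.ndarray
        Array of shape (M, n, n), entries in {0, 1}, zero diagonal.
    covariate : np.ndarray
        Per-actor binary class, informed = 1 / uninformed = 0.
    interval_minutes : float
        Length of each slice.
    actor_ids : list
        Actor labels in matrix order.
    meta : dict
        Free-form provenance (e.g. generating parameters of synthetic
        panels, used for recovery scoring).
    """

    group_id: str
    observations: np.ndarray
    covariate: np.ndarray
    interval_minutes: float = 10.0
    actor_ids: list = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.observations = np.asarray(self.observations, dtype=np.int8)
        self.covariate = np.asarray(self.covariate, dtype=np.int8)
        if self.observations.ndim != 3 or self.observations.shape[1] != self.observations.shape[2]:
            raise ValueError("observations must have shape (M, n, n)")
        n = self.observations.shape[1]
        if self.covariate.shape != (n,):
            raise ValueError("covariate must have one value per actor")
        if not np.isin(self.observations, (0, 1)).all():
            raise ValueError("observations must be binary")
        if not np.isin(self.covariate, (0, 1)).all():
            raise ValueError("covariate must be binary (informed=1, uninformed=0)")
        diag = self.observations[:, np.arange(n), np.arange(n)]
        if diag.any():
            raise ValueError("diagonal must be zero in every observation")
        if not self.actor_ids:
            self.actor_ids = list(range(n))

    @property
    def n_actors(self) -> int:
        return self.observations.shape[1]

    @property
    def n_observations(self) -> int:
        return self.observations.shape[0]


def build_panel(
    events: list[InteractionEvent],
    n_actors: int,
    interval_minutes: float,
    fps: float,
    total_minutes: float,
    drop_first: bool = True,
    covariate: np.ndarray | None = None,
    group_id: str = "group",
    actor_ids: list | None = None,
) -> NetworkPanel:
    """Bin events into binary directed adjacency matrices.

    Each event is assigned to the slice containing its start frame
    (half-open frame ranges ``[m*L, (m+1)*L)``); a trailing partial slice
    is dropped. ``x_ij = 1`` in a slice iff at least one i→j event starts
    there. With ``drop_first`` the first slice is removed before return.
    """
    actor_ids = actor_ids if actor_ids is not None else list(range(n_actors))
    index = {a: k for k, a in enumerate(actor_ids)}
    frames_per_slice = int(round(interval_minutes * 60 * fps))
    total_frames = int(round(total_minutes * 60 * fps))
    n_slices = total_frames // frames_per_slice
    if n_slices < 1:
        raise ValueError("total_minutes shorter than one interval")
    obs = np.zeros((n_slices, n_actors, n_actors), dtype=np.int8)
    for ev in events:
        if not (0 <= ev.start_frame < total_frames):
            raise ValueError(
                f"event {ev.initiator}->{ev.receiver} at frame {ev.start_frame} "
                f"outside the recording range [0, {total_frames})"
            )
        m = ev.start_frame // frames_per_slice
        if m >= n_slices:  # inside the dropped trailing partial slice
            continue
        obs[m, index[ev.initiator], index[ev.receiver]] = 1
    if drop_first:
        obs = obs[1:]
    if covariate is None:
        covariate = np.zeros(n_actors, dtype=np.int8)
    return NetworkPanel(
        group_id=group_id,
        observations=obs,
        covariate=covariate,
        interval_minutes=interval_minutes,
        actor_ids=actor_ids,
    )


def jaccard_index(a: np.ndarray, b: np.ndarray) -> float:
    """Jaccard similarity of the off-diagonal tie sets of two binary
    directed networks: shared ties / union ties. Two empty networks are
    identical by convention (returns 1)."""
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    off = ~np.eye(a.shape[0], dtype=bool)
    a_t = a[off].astype(bool)
    b_t = b[off].astype(bool)
    n11 = int((a_t & b_t).sum())
    union = int((a_t | b_t).sum())
    if union == 0:
        return 1.0
    return n11 / union


def screen_panel(
    panel: NetworkPanel, threshold: float = 0.2
) -> list[tuple[int, float, bool]]:
    """Jaccard screen of consecutive observations.

    Returns one ``(slice index, jaccard, passed)`` record per consecutive
    pair; a pair passes when its index is strictly above ``threshold``.
    """
    if panel.n_observations < 2:
        raise ValueError("panel needs at least two observations to screen")
    records = []
    for m in range(panel.n_observations - 1):
        j = jaccard_index(panel.observations[m], panel.observations[m + 1])
        records.append((m, j, j > threshold))
    n_pass = sum(1 for _, _, p in records if p)
    logger.info(
        "panel %s: %d/%d consecutive pairs pass the Jaccard screen (> %.2f)",
        panel.group_id, n_pass, len(records), threshold,
    )
    return records


def classify_condition(
    eggs_informed_medium: int, eggs_other_medium: int
) -> tuple[float, ConditionLabel]:
    """Label a replicate from the uninformed flies' egg counts.

    ``Followed`` if the proportion on the informed medium exceeds 0.8,
    ``Avoided`` below 0.2, ``Excluded`` in between (boundary values are
    Excluded; the thresholds are strict).
    """
    total = eggs_informed_medium + eggs_other_medium
    if total <= 0:
        raise ValueError("total egg count must be positive")
    p = eggs_informed_medium / total
    if p > 0.8:
        label = ConditionLabel.FOLLOWED
    elif p < 0.2:
        label = ConditionLabel.AVOIDED
    else:
        label = ConditionLabel.EXCLUDED
    return p, label


# ---------------------------------------------------------------------------
# panel serialization: one whitespace-delimited 0/1 matrix per slice plus a
# YAML manifest (group id, actor ids, covariate, interval, provenance)

def save_panel(panel: NetworkPanel, directory) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for m in range(panel.n_observations):
        np.savetxt(directory / f"obs_{m:03d}.txt", panel.observations[m], fmt="%d")
    manifest = {
        "group_id": panel.group_id,
        "actor_ids": [int(a) if isinstance(a, (int, np.integer)) else a for a in panel.actor_ids],
        "covariate": panel.covariate.astype(int).tolist(),
        "interval_minutes": float(panel.interval_minutes),
        "n_observations": int(panel.n_observations),
        "meta": panel.meta,
    }
    with open(directory / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)


def load_panel(directory) -> NetworkPanel:
    directory = Path(directory)
    with open(directory / "manifest.yaml") as fh:
        manifest = yaml.safe_load(fh)
    obs = np.stack(
        [
            np.loadtxt(directory / f"obs_{m:03d}.txt", dtype=np.int8, ndmin=2)
            for m in range(manifest["n_observations"])
        ]
    )
    return NetworkPanel(
        group_id=manifest["group_id"],
        observations=obs,
        covariate=np.asarray(manifest["covariate"], dtype=np.int8),
        interval_minutes=manifest["interval_minutes"],
        actor_ids=manifest["actor_ids"],
        meta=manifest.get("meta") or {},
    )
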