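"""Synthetic inputs with the statistical structure the pipeline assumes.

Three generators stand in for the unavailable raw recordings:

* :func:`generate_trajectories` — 8 informed and 4 uninformed flies in a
  100 mm circular arena, recorded at 10 fps for 4 h. Flies diffuse with a
  class-dependent step scale and, at ordered class-pair specific rates,
  start *approach bouts*: a fly walks to a chosen conspecific, dwells in
  contact for a moment, then loses interest for a refractory period.
  Approach rates control the directed contact structure — with the
  default cross-class-dominated rates and the 8/4 class split, uninformed
  flies both start and receive more contacts per capita, the
  class-asymmetric regime the analysis is designed to detect. The model
  is phenomenological: it emulates contact-rate structure, not
  *Drosophila* locomotion.
* :func:`generate_panel` — network panels simulated from a SAOM with
  known effect parameters (the ground truth for estimator recovery).
* :func:`generate_egg_counts` — egg counts on the two oviposition media
  whose proportion classifies a replicate as Followed/Avoided/Excluded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numba import njit

from .netbuild import ConditionLabel, NetworkPanel, classify_condition
from .saom import ModelSpec, _simulate_from_seedseq
from .trajectories import TrajectoryTable

#: default per-class step scale while walking, mm per frame
DEFAULT_STEP_SCALE = {1: 0.8, 0: 0.8}

#: default per-class probability of walking (vs resting) each frame;
#: uninformed flies are the more active class during transmission
DEFAULT_MOVE_PROB = {1: 0.15, 0: 0.25}

#: default approach-bout rates, per minute per (self fly, target fly)
#: ordered class pair. Cross-class approaches dominate, so with 8 informed
#: and 4 uninformed flies the uninformed are per capita both the busier
#: senders (8 cross-class targets each) and the busier receivers (8
#: cross-class approachers aiming at 4 flies); the uninformed-uninformed
#: rate additionally exceeds the informed-informed one, so uninformed
#: flies are over-received within classes as well (alter preference, not
#: just heterophily)
DEFAULT_APPROACH_BIAS = {
    (0, 1): 0.06,
    (1, 0): 0.06,
    (0, 0): 0.035,
    (1, 1): 0.008,
}

# approach-bout state codes
_IDLE, _APPROACH, _DWELL, _REFRACTORY = 0, 1, 2, 3


@dataclass
class ArenaConfig:
    """Synthetic-arena parameters (lengths in mm, time in frames at ``fps``)."""

    arena_radius: float = 50.0
    n_informed: int = 8
    n_uninformed: int = 4
    duration_minutes: float = 240.0
    fps: float = 10.0
    body_length_mean: float = 2.5
    body_length_sd: float = 0.25
    step_scale: dict = field(default_factory=lambda: dict(DEFAULT_STEP_SCALE))
    move_prob: dict = field(default_factory=lambda: dict(DEFAULT_MOVE_PROB))
    approach_bias: dict = field(default_factory=lambda: dict(DEFAULT_APPROACH_BIAS))
    approach_speed: float = 1.2  # mm per frame while walking to a target
    contact_distance: float = 2.0  # mm; bout switches to dwelling below this
    dwell_frames: int = 10
    refractory_frames: int = 50
    approach_timeout: int = 100  # frames before an unsuccessful bout is abandoned
    pair_affinity_sd: float = 0.8  # lognormal sigma of static pair rate multipliers
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_informed < 0 or self.n_uninformed < 0 or self.n_informed + self.n_uninformed == 0:
            raise ValueError("need a positive number of flies")
        if self.arena_radius <= self.body_length_mean:
            raise ValueError("arena radius must exceed the mean body length")
        if any(s < 0 for s in self.step_scale.values()):
            raise ValueError("step scales must be non-negative")
        if any(r < 0 for r in self.approach_bias.values()):
            raise ValueError("approach rates must be non-negative")
        if self.duration_minutes <= 0 or self.fps <= 0:
            raise ValueError("duration and fps must be positive")

    @property
    def n_flies(self) -> int:
        return self.n_informed + self.n_uninformed

    @property
    def n_frames(self) -> int:
        return int(round(self.duration_minutes * 60 * self.fps))

    def classes(self) -> np.ndarray:
        return np.array([1] * self.n_informed + [0] * self.n_uninformed, dtype=np.int64)


@njit(cache=True)
def _arena_kernel(pos0, cls, step_scale, move_prob, rate_per_frame, affinity, radius, speed,
                  contact_d, dwell_n, refr_n, timeout_n, noise, u_start, u_target,
                  u_move):  # pragma: no cover
    T = noise.shape[0]
    n = pos0.shape[0]
    out = np.empty((T + 1, n, 2))
    pos = pos0.copy()
    out[0] = pos
    state = np.zeros(n, dtype=np.int64)
    target = np.full(n, -1, dtype=np.int64)
    ttl = np.zeros(n, dtype=np.int64)
    step = np.empty((n, 2))
    for t in range(T):
        for i in range(n):
            # intermittent walk/rest diffusion
            if u_move[t, i] < move_prob[cls[i]]:
                sx = step_scale[cls[i]] * noise[t, i, 0]
                sy = step_scale[cls[i]] * noise[t, i, 1]
            else:
                # resting micro-jitter, proportional to the walk scale so a
                # zero-step configuration is fully static
                sx = 0.03 * step_scale[cls[i]] * noise[t, i, 0]
                sy = 0.03 * step_scale[cls[i]] * noise[t, i, 1]
            if state[i] == _IDLE:
                # total bout-start hazard toward every possible target
                tot = 0.0
                for j in range(n):
                    if j != i:
                        tot += rate_per_frame[cls[i], cls[j]] * affinity[i, j]
                if u_start[t, i] < tot:
                    # pick the target in proportion to its hazard share
                    u = u_target[t, i] * tot
                    acc = 0.0
                    for j in range(n):
                        if j == i:
                            continue
                        acc += rate_per_frame[cls[i], cls[j]] * affinity[i, j]
                        if u < acc:
                            target[i] = j
                            break
                    state[i] = _APPROACH
                    ttl[i] = timeout_n
            elif state[i] == _REFRACTORY:
                ttl[i] -= 1
                if ttl[i] <= 0:
                    state[i] = _IDLE
            if state[i] == _APPROACH or state[i] == _DWELL:
                j = target[i]
                dx = pos[j, 0] - pos[i, 0]
                dy = pos[j, 1] - pos[i, 1]
                d = np.sqrt(dx * dx + dy * dy)
                if state[i] == _APPROACH:
                    if d < contact_d:
                        state[i] = _DWELL
                        ttl[i] = dwell_n
                    else:
                        ttl[i] -= 1
                        if ttl[i] <= 0:
                            state[i] = _REFRACTORY
                            ttl[i] = refr_n
                            target[i] = -1
                if state[i] == _APPROACH and target[i] >= 0:
                    adv = speed if speed < d else d
                    if d > 1e-9:
                        sx = adv * dx / d + 0.1 * noise[t, i, 0]
                        sy = adv * dy / d + 0.1 * noise[t, i, 1]
                elif state[i] == _DWELL:
                    # stay glued to the target while dwelling
                    adv = d - 0.8 * contact_d
                    if adv < 0.0:
                        adv = 0.0
                    if adv > speed:
                        adv = speed
                    if d > 1e-9:
                        sx = adv * dx / d + 0.05 * noise[t, i, 0]
                        sy = adv * dy / d + 0.05 * noise[t, i, 1]
                    ttl[i] -= 1
                    if ttl[i] <= 0:
                        state[i] = _REFRACTORY
                        ttl[i] = refr_n
                        target[i] = -1
            step[i, 0] = sx
            step[i, 1] = sy
        for i in range(n):
            px = pos[i, 0] + step[i, 0]
            py = pos[i, 1] + step[i, 1]
            r = np.sqrt(px * px + py * py)
            if r > radius:
                # radial reflection at the wall
                rr = 2.0 * radius - r
                if rr < 0.0:
                    rr = radius
                px *= rr / r
                py *= rr / r
            pos[i, 0] = px
            pos[i, 1] = py
        out[t + 1] = pos
    return out


def generate_trajectories(cfg: ArenaConfig) -> TrajectoryTable:
    """Simulate arena trajectories with diffusive motion and approach bouts.

    Each fly alternates walking (isotropic Gaussian steps of
    class-dependent scale, at a class-dependent per-frame probability)
    with resting. At a per-frame hazard given by the ordered class-pair
    ``approach_bias`` rates (per minute, per potential target), an idle
    fly starts an approach bout: it walks toward the chosen fly at
    ``approach_speed``, dwells in contact for ``dwell_frames`` once
    within ``contact_distance``, then ignores everyone for
    ``refractory_frames``. The arena boundary is reflective. Body lengths
    are drawn once per fly from a positive-truncated normal.
    Deterministic given ``cfg.seed``.
    """
    n = cfg.n_flies
    T = cfg.n_frames
    rng = np.random.default_rng(np.random.SeedSequence((cfg.seed, 4242)))
    cls = cfg.classes()
    # start positions uniform on the disc (by rejection)
    pos0 = np.empty((n, 2))
    got = 0
    while got < n:
        cand = rng.uniform(-cfg.arena_radius, cfg.arena_radius, size=2)
        if np.hypot(*cand) <= cfg.arena_radius:
            pos0[got] = cand
            got += 1
    body = rng.normal(cfg.body_length_mean, cfg.body_length_sd, size=n)
    while (body <= 0).any():
        bad = body <= 0
        body[bad] = rng.normal(cfg.body_length_mean, cfg.body_length_sd, size=int(bad.sum()))
    step_scale = np.zeros(2)
    for c, s in cfg.step_scale.items():
        step_scale[c] = s
    move_prob = np.zeros(2)
    for c, p in cfg.move_prob.items():
        move_prob[c] = p
    rate_per_frame = np.zeros((2, 2))
    for (a, b), per_min in cfg.approach_bias.items():
        rate_per_frame[a, b] = per_min / (60.0 * cfg.fps)
    steps = max(T - 1, 0)
    noise = rng.standard_normal((steps, n, 2))
    u_start = rng.random((steps, n))
    u_target = rng.random((steps, n))
    u_move = rng.random((steps, n))
    # static pair affinities: persistent pair preferences that carry tie
    # structure across time slices (symmetric per unordered pair)
    sd = cfg.pair_affinity_sd
    aff = np.exp(rng.normal(-0.5 * sd * sd, sd, size=(n, n))) if sd > 0 else np.ones((n, n))
    aff = np.triu(aff, 1)
    aff = aff + aff.T
    np.fill_diagonal(aff, 0.0)
    track = _arena_kernel(
        pos0, cls, step_scale, move_prob, rate_per_frame, aff, float(cfg.arena_radius),
        float(cfg.approach_speed), float(cfg.contact_distance),
        int(cfg.dwell_frames), int(cfg.refractory_frames), int(cfg.approach_timeout),
        noise, u_start, u_target, u_move,
    )[:T]
    frames = np.repeat(np.arange(T), n)
    individuals = np.tile(np.arange(n), T)
    df = pd.DataFrame(
        {
            "frame": frames,
            "individual": individuals,
            "x": track[:, :, 0].ravel(),
            "y": track[:, :, 1].ravel(),
            "body_length": np.tile(body, T),
        }
    )
    classes = {int(i): int(c) for i, c in enumerate(cls)}
    return TrajectoryTable(df, fps=cfg.fps, classes=classes)


def generate_panel(
    n_actors: int,
    covariate_split: tuple[int, int],
    n_periods: int,
    model: ModelSpec,
    lam: float,
    seed: int = 0,
    x0_density: float = 0.1,
    group_id: str = "sim",
) -> NetworkPanel:
    """Simulate a network panel from a SAOM with known parameters.

    The first observation is an Erdős–Rényi digraph at ``x0_density``
    (first-observation conditioning makes its distribution irrelevant to
    estimation, and a non-empty start makes period-1 statistics
    informative); each later observation evolves from the previous one by
    :func:`flynet.saom.simulate_period` dynamics at rate ``lam``. The
    generating parameters are recorded in ``panel.meta`` for recovery
    scoring.
    """
    n_inf, n_uninf = covariate_split
    if n_inf + n_uninf != n_actors:
        raise ValueError("covariate split must sum to n_actors")
    if lam <= 0:
        raise ValueError("rate must be positive")
    v = np.array([1] * n_inf + [0] * n_uninf, dtype=np.int8)
    rng = np.random.default_rng(np.random.SeedSequence((seed, 777)))
    x0 = (rng.random((n_actors, n_actors)) < x0_density).astype(np.int8)
    np.fill_diagonal(x0, 0)
    obs = [x0]
    beta7 = model.dense_beta()
    for m in range(n_periods - 1):
        ss = np.random.SeedSequence((seed, 778, m))
        obs.append(_simulate_from_seedseq(obs[-1], v, beta7, lam, ss))
    return NetworkPanel(
        group_id=group_id,
        observations=np.stack(obs),
        covariate=v,
        meta={
            "true_effects": {e.name: e.weight for e in model.effects},
            "true_rate": float(lam),
            "x0_density": float(x0_density),
            "seed": int(seed),
        },
    )


def generate_egg_counts(
    condition: ConditionLabel | str, total_eggs: int, seed: int = 0
) -> tuple[int, int]:
    """Draw (informed-medium, other-medium) egg counts for a condition.

    The underlying proportion is uniform on (0.8, 1], [0, 0.2) or
    [0.2, 0.8] for Followed / Avoided / Excluded; the count is binomial,
    resampled until :func:`flynet.netbuild.classify_condition` returns the
    requested label (binomial discreteness can otherwise cross a
    threshold).
    """
    if total_eggs <= 0:
        raise ValueError("total_eggs must be positive")
    label = condition if isinstance(condition, ConditionLabel) else ConditionLabel(condition)
    lo, hi = {
        ConditionLabel.FOLLOWED: (0.8, 1.0),
        ConditionLabel.AVOIDED: (0.0, 0.2),
        ConditionLabel.EXCLUDED: (0.2, 0.8),
    }[label]
    rng = np.random.default_rng(np.random.SeedSequence((seed, 99)))
    while True:
        p = rng.uniform(lo, hi)
        informed = int(rng.binomial(total_eggs, p))
        _, got = classify_condition(informed, total_eggs - informed)
        if got == label:
            return informed, total_eggs - informed
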