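"""Stochastic actor-oriented models (SAOMs) for binary directed network panels.

A SAOM treats the observed sequence of networks as snapshots of a
continuous-time Markov process: actors get change opportunities at rate
``λ`` per observation period; at each opportunity the chosen actor may
toggle one of its outgoing ties (or leave the network unchanged), picking
among the ``n`` candidate next states by a multinomial logit on its
evaluation function

    f_i(x) = Σ_k β_k s_ik(x),

where the ``s_ik`` are actor-level effect statistics. Seven effects are
implemented: ``density`` (outdegree), ``recip`` (reciprocated ties),
``inPop`` (sum of contacts received by the actor's out-neighbours),
``outAct`` (squared outdegree), and three binary-covariate effects —
``altX`` (covariate-weighted indegree popularity), ``egoX``
(covariate-weighted activity) and ``sameX`` (same-covariate homophily).

Estimation is by the Method of Moments with first-observation
conditioning: each period is simulated forward from its observed starting
network, expected statistics are matched to the observed ones, and the
moment equations are solved by three-phase Robbins–Monro stochastic
approximation (finite-difference derivative with common random numbers;
iterative gain-decreasing updates; a final large simulation phase for
standard errors and convergence t-ratios). Several independent groups can
be fitted jointly with shared evaluation parameters and group-specific
period rates (multi-group analysis).

Covariates are used uncentred (0/1). RSiena centres covariates by
default, so estimated magnitudes of ``egoX``/``altX``/``sameX`` differ
from RSiena output by reparametrisation (signs and tests are unaffected;
the intercept shift is absorbed by ``density``).
"""

from __future__ import annotations

import json
import logging
import zlib
from dataclasses import dataclass, field, asdict

import numpy as np
from numba import njit
from scipy import stats as sps

from .netbuild import NetworkPanel

logger = logging.getLogger(__name__)

EFFECT_NAMES = ("density", "recip", "inPop", "outAct", "altX", "egoX", "sameX")


# ---------------------------------------------------------------------------
# model specification

@dataclass(frozen=True)
class EffectSpec:
    name: str
    weight: float = 0.0

    def __post_init__(self) -> None:
        if self.name not in EFFECT_NAMES:
            raise ValueError(f"unknown effect {self.name!r}; choose from {EFFECT_NAMES}")


@dataclass
class ModelSpec:
    """A set of evaluation effects with weights, plus optional period rates.

    The ``density`` effect must always be present: the other statistics
    are correlated with it and it serves as the density control.
    """

    effects: list[EffectSpec]
    rates: np.ndarray | None = None  # per-period rates (simulation use)

    def __post_init__(self) -> None:
        names = [e.name for e in self.effects]
        if len(set(names)) != len(names):
            raise ValueError("effect names must be unique within a model")
        if "density" not in names:
            raise ValueError("the density effect must be included as a control")
        if self.rates is not None:
            self.rates = np.asarray(self.rates, dtype=float)
            if (self.rates <= 0).any():
                raise ValueError("rate parameters must be strictly positive")

    @property
    def effect_names(self) -> list[str]:
        return [e.name for e in self.effects]

    @property
    def weights(self) -> np.ndarray:
        return np.array([e.weight for e in self.effects], dtype=float)

    def dense_beta(self) -> np.ndarray:
        """Weights as a dense vector in canonical effect order."""
        beta = np.zeros(len(EFFECT_NAMES))
        for e in self.effects:
            beta[EFFECT_NAMES.index(e.name)] = e.weight
        return beta

    def with_weights(self, weights: np.ndarray) -> "ModelSpec":
        return ModelSpec(
            effects=[EffectSpec(e.name, float(w)) for e, w in zip(self.effects, weights)],
            rates=self.rates,
        )


# ---------------------------------------------------------------------------
# effect statistics and the evaluation function

def effect_statistic(name: str, x: np.ndarray, v: np.ndarray, i: int) -> float:
    """Actor ``i``'s statistic ``s_ik(x)`` for one effect.

    ``x`` is a binary adjacency matrix with zero diagonal, ``v`` the
    binary actor covariate (informed = 1, uninformed = 0).
    """
    x = np.asarray(x)
    v = np.asarray(v)
    row = x[i]
    if name == "density":
        return float(row.sum())
    if name == "recip":
        return float((row * x[:, i]).sum())
    if name == "inPop":
        return float((row * x.sum(axis=0)).sum())
    if name == "outAct":
        return float(row.sum()) ** 2
    if name == "altX":
        return float((row * v).sum())
    if name == "egoX":
        return float(v[i] * row.sum())
    if name == "sameX":
        return float((row * (v == v[i])).sum())
    raise ValueError(f"unknown effect {name!r}")


def statistics_matrix(x: np.ndarray, v: np.ndarray, names) -> np.ndarray:
    """All actors' statistics, shape (n, len(names))."""
    n = x.shape[0]
    return np.array(
        [[effect_statistic(nm, x, v, i) for nm in names] for i in range(n)], dtype=float
    )


def evaluation_function(x: np.ndarray, v: np.ndarray, i: int, model: ModelSpec) -> float:
    """f_i(x) = Σ_k β_k s_ik(x)."""
    return float(
        sum(e.weight * effect_statistic(e.name, x, v, i) for e in model.effects)
    )


def _change_contributions(x: np.ndarray, v: np.ndarray, i: int) -> np.ndarray:
    """Change in each canonical statistic of actor ``i`` when x_ij is
    toggled, for every j (row j; row i is zeros = the no-change option).

    Closed forms (z = +1 for tie creation, -1 for deletion):
    density z; recip z·x_ji; inPop z·indeg_j + 1{z=+1} (the created tie
    itself raises j's indegree); outAct 2·z·outdeg_i + 1; altX z·v_j;
    egoX z·v_i; sameX z·1{v_i = v_j}.
    """
    n = x.shape[0]
    z = 1.0 - 2.0 * x[i].astype(float)
    indeg = x.sum(axis=0).astype(float)
    outdeg_i = float(x[i].sum())
    d = np.zeros((n, len(EFFECT_NAMES)))
    d[:, 0] = z
    d[:, 1] = z * x[:, i]
    d[:, 2] = z * indeg + (z > 0)
    d[:, 3] = 2.0 * outdeg_i * z + 1.0
    d[:, 4] = z * v
    d[:, 5] = z * v[i]
    d[:, 6] = z * (v == v[i])
    d[i] = 0.0
    return d


def micro_step_probabilities(
    x: np.ndarray, v: np.ndarray, i: int, model: ModelSpec
) -> np.ndarray:
    """Multinomial-logit choice probabilities for one change opportunity.

    Returns a length-``n`` vector: entry ``j != i`` is the probability of
    toggling the tie ``i→j``; entry ``i`` is the probability of leaving
    the network unchanged. Each alternative ``a`` has probability
    proportional to ``exp(f_i(x^(a)))``.
    """
    x = np.asarray(x)
    v = np.asarray(v)
    beta = model.dense_beta()
    df = _change_contributions(x, v, i) @ beta  # df[i] == 0 (no change)
    w = np.exp(df - df.max())
    return w / w.sum()


# ---------------------------------------------------------------------------
# micro-step simulation kernel

@njit(cache=True)
def _simulate_kernel(x, v, beta, outdeg, indeg, actors, unifs):  # pragma: no cover
    n = x.shape[0]
    df = np.empty(n)
    for t in range(actors.shape[0]):
        i = actors[t]
        dmax = 0.0
        for j in range(n):
            if j == i:
                df[j] = 0.0
                continue
            z = 1.0 - 2.0 * x[i, j]
            val = beta[0] * z
            val += beta[1] * z * x[j, i]
            val += beta[2] * (z * indeg[j] + (1.0 if z > 0 else 0.0))
            val += beta[3] * (2.0 * outdeg[i] * z + 1.0)
            val += beta[4] * z * v[j]
            val += beta[5] * z * v[i]
            val += beta[6] * (z if v[i] == v[j] else 0.0)
            df[j] = val
            if val > dmax:
                dmax = val
        total = 0.0
        for j in range(n):
            df[j] = np.exp(df[j] - dmax)
            total += df[j]
        u = unifs[t] * total
        acc = 0.0
        choice = i
        for j in range(n):
            acc += df[j]
            if u < acc:
                choice = j
                break
        if choice != i:
            z8 = 1 - 2 * x[i, choice]
            x[i, choice] += z8
            outdeg[i] += z8
            indeg[choice] += z8


def _simulate_from_seedseq(
    x0: np.ndarray, v: np.ndarray, beta7: np.ndarray, lam: float, ss: np.random.SeedSequence
) -> np.ndarray:
    """One period of micro-step dynamics from ``x0``; K ~ Poisson(n·λ).

    Opportunity count, actor choices and logit draws come from three
    sub-streams so that runs at perturbed parameters share randomness
    (common random numbers for finite-difference derivatives).
    """
    n = x0.shape[0]
    ss_k, ss_a, ss_u = ss.spawn(3)
    k = int(np.random.default_rng(ss_k).poisson(n * lam))
    x = x0.astype(np.int8).copy()
    if k == 0:
        return x
    actors = np.random.default_rng(ss_a).integers(0, n, size=k)
    unifs = np.random.default_rng(ss_u).random(k)
    outdeg = x.sum(axis=1).astype(np.float64)
    indeg = x.sum(axis=0).astype(np.float64)
    _simulate_kernel(
        x, np.asarray(v, dtype=np.float64), np.asarray(beta7, dtype=np.float64),
        outdeg, indeg, actors, unifs,
    )
    return x


def simulate_period(
    x0: np.ndarray, v: np.ndarray, model: ModelSpec, lam: float, rng_seed
) -> np.ndarray:
    """Simulate one observation period of the SAOM.

    Draws ``K ~ Poisson(n·λ)`` change opportunities; each opportunity picks
    an actor uniformly and applies one multinomial-logit micro-step. Fully
    reproducible given ``rng_seed`` (an int or a ``SeedSequence``).
    """
    if lam < 0:
        raise ValueError("rate must be non-negative")
    ss = rng_seed if isinstance(rng_seed, np.random.SeedSequence) else np.random.SeedSequence(rng_seed)
    return _simulate_from_seedseq(np.asarray(x0), np.asarray(v), model.dense_beta(), lam, ss)


# ---------------------------------------------------------------------------
# Method-of-Moments targets

def hamming(a: np.ndarray, b: np.ndarray) -> int:
    """Number of differing off-diagonal cells of two adjacency matrices."""
    a = np.asarray(a)
    b = np.asarray(b)
    off = ~np.eye(a.shape[0], dtype=bool)
    return int((a[off] != b[off]).sum())


def observed_targets(panel: NetworkPanel, model: ModelSpec) -> tuple[np.ndarray, np.ndarray]:
    """Moment targets of one panel under first-observation conditioning.

    Evaluation targets: for each effect ``k``, ``Σ_{m≥2} Σ_i s_ik(x(t_m))``
    over the non-first observations. Rate targets: the Hamming distance
    between consecutive observations, one per period.
    """
    if panel.n_observations < 2:
        raise ValueError("panel needs at least two observations")
    names = model.effect_names
    ev = np.zeros(len(names))
    for m in range(1, panel.n_observations):
        ev += statistics_matrix(panel.observations[m], panel.covariate, names).sum(axis=0)
    rates = np.array(
        [
            hamming(panel.observations[m], panel.observations[m + 1])
            for m in range(panel.n_observations - 1)
        ],
        dtype=float,
    )
    return ev, rates


# ---------------------------------------------------------------------------
# fit machinery

@dataclass
class MoMSettings:
    """Robbins–Monro estimation settings.

    ``n1`` phase-1 simulations estimate the derivative matrix by
    common-random-number finite differences (step ``fd_step``); phase 2
    runs ``n2_subphases`` subphases of ``n2_iterations`` updates with the
    gain halved per subphase (iterate-averaged at subphase end); phase 3
    runs ``n3`` simulations at the solution for covariances, standard
    errors and convergence t-ratios (all below ``conv_threshold`` in
    absolute value counts as converged).
    """

    n1: int = 50
    n2_subphases: int = 4
    n2_iterations: int = 40
    n2_growth: float = 1.5
    n3: int = 1000
    gain: float = 0.3
    fd_step: float = 0.1
    conv_threshold: float = 0.1
    max_restarts: int = 2
    rate_min: float = 0.05
    rate_max: float = 20.0
    beta_max: float = 10.0
    seed: int = 0


@dataclass
class FitResult:
    """Method-of-Moments fit of a SAOM to one or more network panels."""

    effects: list[str]
    estimates: np.ndarray
    standard_errors: np.ndarray
    wald_t: np.ndarray
    p_values: np.ndarray
    rate_estimates: list[tuple[str, np.ndarray]]
    rate_standard_errors: list[tuple[str, np.ndarray]]
    conv_t_ratios: np.ndarray  # one per evaluation effect
    rate_conv_t_ratios: np.ndarray  # one per group-period rate statistic
    converged: bool
    n_restarts: int = 0
    message: str = ""
    seed: int = 0

    @property
    def max_conv_t_ratio(self) -> float:
        return float(np.nanmax(np.abs(self.conv_t_ratios)))

    def effect_index(self, name: str) -> int:
        return self.effects.index(name)

    def summary(self) -> str:
        lines = [
            f"SAOM Method-of-Moments fit (converged={self.converged}, "
            f"max |conv t| = {self.max_conv_t_ratio:.3f})"
        ]
        lines.append(f"{'effect':>10s} {'est':>9s} {'se':>8s} {'t':>8s} {'p':>8s}")
        for k, name in enumerate(self.effects):
            lines.append(
                f"{name:>10s} {self.estimates[k]:9.4f} {self.standard_errors[k]:8.4f} "
                f"{self.wald_t[k]:8.3f} {self.p_values[k]:8.4f}"
            )
        for gid, rates in self.rate_estimates:
            lines.append(f"rates[{gid}]: " + " ".join(f"{r:.3f}" for r in rates))
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "effects": list(self.effects),
            "estimates": np.asarray(self.estimates).tolist(),
            "standard_errors": np.asarray(self.standard_errors).tolist(),
            "wald_t": np.asarray(self.wald_t).tolist(),
            "p_values": np.asarray(self.p_values).tolist(),
            "rate_estimates": [
                {"group": g, "rates": np.asarray(r).tolist()} for g, r in self.rate_estimates
            ],
            "rate_standard_errors": [
                {"group": g, "rates": np.asarray(r).tolist()}
                for g, r in self.rate_standard_errors
            ],
            "conv_t_ratios": np.asarray(self.conv_t_ratios).tolist(),
            "rate_conv_t_ratios": np.asarray(self.rate_conv_t_ratios).tolist(),
            "converged": bool(self.converged),
            "n_restarts": int(self.n_restarts),
            "message": self.message,
            "seed": int(self.seed),
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def _group_hash(group_id) -> int:
    return zlib.crc32(str(group_id).encode())


class _MoMProblem:
    """Internal: panels + model flattened into one parameter/statistic space.

    Parameter vector: [β_1..β_K, λ_{g1,1}..λ_{g1,M1-1}, λ_{g2,1}, ...].
    Statistic vector aligned the same way: evaluation statistics summed
    over groups, then one Hamming-distance statistic per group-period.
    Per-period seeds depend on the group id (not its list position), so
    multi-group fits are reproducible regardless of group order.
    """

    def __init__(self, panels: list[NetworkPanel], model: ModelSpec, settings: MoMSettings):
        self.panels = panels
        self.model = model
        self.settings = settings
        self.names = model.effect_names
        self.K = len(self.names)
        self.periods = [(g, m) for g, p in enumerate(panels) for m in range(p.n_observations - 1)]
        self.R = len(self.periods)
        self.P = self.K + self.R
        ev = np.zeros(self.K)
        rates = []
        for p in panels:
            e, r = observed_targets(p, model)
            ev += e
            rates.append(r)
        self.s_obs = np.concatenate([ev, np.concatenate(rates)])
        self.dense_idx = np.array([EFFECT_NAMES.index(n) for n in self.names])

    def theta0(self) -> np.ndarray:
        theta = np.zeros(self.P)
        lam0 = []
        for g, m in self.periods:
            n = self.panels[g].n_actors
            h = self.s_obs[self.K + len(lam0)]
            lam0.append(max(h / max(n - 1, 1), 0.5))
        theta[self.K:] = lam0
        return theta

    def clip(self, theta: np.ndarray) -> np.ndarray:
        s = self.settings
        out = theta.copy()
        out[: self.K] = np.clip(out[: self.K], -s.beta_max, s.beta_max)
        out[self.K:] = np.clip(out[self.K:], s.rate_min, s.rate_max)
        return out

    def _beta7(self, theta: np.ndarray) -> np.ndarray:
        beta = np.zeros(len(EFFECT_NAMES))
        beta[self.dense_idx] = theta[: self.K]
        return beta

    def _period_seed(self, tag: int, rep: int, g: int, m: int) -> np.random.SeedSequence:
        return np.random.SeedSequence(
            entropy=(self.settings.seed, tag, rep, _group_hash(self.panels[g].group_id), m)
        )

    def _sim_period(self, theta, ridx: int, tag: int, rep: int) -> tuple[np.ndarray, float]:
        """Simulate one period; returns (eval-statistic vector, hamming)."""
        g, m = self.periods[ridx]
        panel = self.panels[g]
        lam = theta[self.K + ridx]
        x_end = _simulate_from_seedseq(
            panel.observations[m], panel.covariate, self._beta7(theta), lam,
            self._period_seed(tag, rep, g, m),
        )
        ev = statistics_matrix(x_end, panel.covariate, self.names).sum(axis=0)
        return ev, float(hamming(panel.observations[m], x_end))

    def simulate_stats(self, theta, tag: int, rep: int) -> np.ndarray:
        """Full simulated statistic vector for one replicate."""
        ev = np.zeros(self.K)
        ham = np.zeros(self.R)
        for ridx in range(self.R):
            e, h = self._sim_period(theta, ridx, tag, rep)
            ev += e
            ham[ridx] = h
        return np.concatenate([ev, ham])

    def derivative(
        self,
        theta,
        tag: int,
        n1: int | None = None,
        fd: float | None = None,
        central: bool = False,
    ) -> np.ndarray:
        """Finite-difference derivative matrix D[s, p] = ∂E[S_s]/∂θ_p.

        Common random numbers across the base run and each perturbation.
        A rate parameter only enters its own period's simulation, so its
        column re-simulates that single period; an evaluation parameter
        re-simulates all periods. ``central`` switches to central
        differences: twice the cost, but the curvature bias of the
        forward secant is removed — used for the final derivative that
        enters the standard errors, where an upward-biased derivative
        would understate them.
        """
        s = self.settings
        eps = s.fd_step if fd is None else fd
        n1 = s.n1 if n1 is None else n1
        if central:
            return self._central_derivative(theta, tag, n1, eps)
        D = np.zeros((self.P, self.P))
        for rep in range(n1):
            base = [self._sim_period(theta, r, tag, rep) for r in range(self.R)]
            base_ev = np.sum([b[0] for b in base], axis=0)
            base_ham = np.array([b[1] for b in base])
            for k in range(self.K):
                th = theta.copy()
                th[k] += eps
                ev = np.zeros(self.K)
                ham = np.zeros(self.R)
                for ridx in range(self.R):
                    e, h = self._sim_period(th, ridx, tag, rep)
                    ev += e
                    ham[ridx] = h
                D[: self.K, k] += (ev - base_ev) / eps
                D[self.K:, k] += (ham - base_ham) / eps
            for ridx in range(self.R):
                th = theta.copy()
                th[self.K + ridx] += eps
                e, h = self._sim_period(th, ridx, tag, rep)
                D[: self.K, self.K + ridx] += (e - base[ridx][0]) / eps
                D[self.K + ridx, self.K + ridx] += (h - base[ridx][1]) / eps
        return D / n1

    def _central_derivative(self, theta, tag: int, n1: int, eps: float) -> np.ndarray:
        D = np.zeros((self.P, self.P))
        for rep in range(n1):
            for p in range(self.P):
                thp = theta.copy()
                thm = theta.copy()
                thp[p] += eps / 2.0
                thm[p] -= eps / 2.0
                if p < self.K:
                    sp = self.simulate_stats(thp, tag, rep)
                    sm = self.simulate_stats(thm, tag, rep)
                    D[:, p] += (sp - sm) / eps
                else:
                    ridx = p - self.K
                    ep, hp = self._sim_period(thp, ridx, tag, rep)
                    em, hm = self._sim_period(thm, ridx, tag, rep)
                    D[: self.K, p] += (ep - em) / eps
                    D[self.K + ridx, p] += (hp - hm) / eps
        return D / n1


def _invert_derivative(
    D: np.ndarray, n_eval: int | None = None, diag_mix: float = 0.2, strict: bool = True
) -> np.ndarray:
    """Invert the moment-derivative matrix for the update direction.

    The finite-difference estimate of ``D`` is noisy; a raw inverse
    amplifies the noise along nearly-flat directions (e.g. a rate close
    to its saturation value on small sparse networks). The matrix is
    therefore partially diagonalised — ``(1-diag_mix)·D + diag_mix·diag(D)``
    with the diagonal floored at a small positive value — before
    inversion, and a pseudo-inverse is used when it is still badly
    conditioned. A truly singular matrix (collinear effects) is a
    modelling error and raises.
    """
    # collinear evaluation effects make the eval-statistic block singular;
    # that is a modelling error (a saturated rate merely flattens its own
    # column and is handled numerically below)
    n_eval = D.shape[0] if n_eval is None else n_eval
    eval_block = D[:n_eval, :n_eval]
    cond_eval = np.linalg.cond(eval_block) if n_eval > 0 else 1.0
    if not np.isfinite(cond_eval) or cond_eval > 1e10:
        if strict:
            raise ValueError(
                "derivative matrix is singular; the model is likely "
                "over-parameterised for these data — try removing effects"
            )
        logger.warning("near-singular derivative at an intermediate point; regularised")
    d = np.diag(D).copy()
    floor = max(1e-3, 1e-3 * float(np.abs(d).max()))
    d = np.where(d < floor, floor, d)
    mixed = (1.0 - diag_mix) * D + diag_mix * np.diag(d)
    mixed[np.diag_indices_from(mixed)] = np.maximum(np.diag(mixed), floor)
    if np.linalg.cond(mixed) > 1e6:
        return np.linalg.pinv(mixed, rcond=1e-8)
    return np.linalg.inv(mixed)


def _block_update_direction(D: np.ndarray, n_eval: int, strict: bool) -> np.ndarray:
    """Block-structured update map for the phase-2 iterations.

    The evaluation-parameter block is the inverted K×K eval-statistic
    derivative; each rate parameter is driven by its own statistic alone
    (inverse diagonal, floored). Decoupling the blocks keeps a rate stuck
    at its saturation bound — whose deviation can never vanish on small
    sparse networks — from biasing the evaluation parameters through the
    full inverse; the Robbins–Monro fixed point (all matchable deviations
    zero) is unchanged.
    """
    P = D.shape[0]
    M = np.zeros((P, P))
    M[:n_eval, :n_eval] = _invert_derivative(D[:n_eval, :n_eval], strict=strict)
    diag = np.diag(D)[n_eval:]
    floor = max(1e-2, 1e-3 * float(np.abs(diag).max() if diag.size else 1.0))
    safe = np.where(diag < floor, floor, diag)
    M[np.arange(n_eval, P), np.arange(n_eval, P)] = 1.0 / safe
    return M


def fit_mom(panels, model: ModelSpec, settings: MoMSettings | None = None) -> FitResult:
    """Fit a SAOM to one or more panels by the Method of Moments.

    Three-phase Robbins–Monro stochastic approximation (see
    :class:`MoMSettings`); refit restarts from the current point up to
    ``max_restarts`` times when the convergence criterion (all
    |t-ratios| < ``conv_threshold``) is not met. Evaluation parameters are
    shared across panels; rates are estimated per period per group.
    """
    if isinstance(panels, NetworkPanel):
        panels = [panels]
    panels = list(panels)
    settings = settings or MoMSettings()
    prob = _MoMProblem(panels, model, settings)

    if prob.s_obs[prob.K:].sum() == 0:
        logger.warning(
            "no tie changes between any consecutive observations; "
            "evaluation parameters are unidentifiable"
        )
        nan = np.full(prob.K, np.nan)
        return FitResult(
            effects=prob.names, estimates=nan, standard_errors=nan.copy(),
            wald_t=nan.copy(), p_values=nan.copy(),
            rate_estimates=[(p.group_id, np.zeros(p.n_observations - 1)) for p in panels],
            rate_standard_errors=[
                (p.group_id, np.full(p.n_observations - 1, np.nan)) for p in panels
            ],
            conv_t_ratios=np.full(prob.K, np.nan),
            rate_conv_t_ratios=np.full(prob.R, np.nan), converged=False,
            message="zero observed change: evaluation parameters unidentifiable",
            seed=settings.seed,
        )

    theta = prob.theta0()
    best: tuple[float, np.ndarray, np.ndarray, np.ndarray] | None = None
    for attempt in range(settings.max_restarts + 1):
        D = prob.derivative(theta, tag=100 + attempt)
        Dinv = _block_update_direction(D, prob.K, strict=attempt == 0)
        # phase 2: gain-decreasing Robbins–Monro updates, iterate-averaged,
        # subphase length growing as the gain shrinks; a subphase whose
        # deviations blow up is rolled back with a halved gain
        a = settings.gain
        rep = 0
        d0 = None
        for sub in range(settings.n2_subphases):
            n_iter = int(round(settings.n2_iterations * settings.n2_growth**sub))
            theta_sub = theta.copy()
            acc = np.zeros_like(theta)
            recent = []
            for _ in range(n_iter):
                s_sim = prob.simulate_stats(theta, tag=200 + attempt, rep=rep)
                rep += 1
                dev = s_sim - prob.s_obs
                recent.append(float(np.linalg.norm(dev)))
                if d0 is None:
                    d0 = recent[-1]
                step = a * (Dinv @ dev)
                theta = prob.clip(theta - np.clip(step, -0.5, 0.5))
                acc += theta
            tail = float(np.mean(recent[-max(5, n_iter // 4):]))
            if d0 is not None and tail > 3.0 * d0 + 1.0:
                logger.debug("subphase %d diverged (|dev| %.1f vs %.1f); rolled back", sub, tail, d0)
                theta = theta_sub
            else:
                theta = prob.clip(acc / n_iter)
            a /= 2.0
        # phase 3 at the candidate solution, with Newton polish rounds:
        # the averaged Robbins–Monro iterate retains a small finite-gain
        # offset, which the high-precision phase-3 deviation estimate can
        # remove directly before the final assessment
        for rnd in range(3):
            devs = np.array(
                [
                    prob.simulate_stats(theta, tag=300 + 10 * attempt + rnd, rep=r)
                    - prob.s_obs
                    for r in range(settings.n3)
                ]
            )
            mean_dev = devs.mean(axis=0)
            sd_dev = devs.std(axis=0, ddof=1)
            with np.errstate(divide="ignore", invalid="ignore"):
                tratios = np.where(
                    sd_dev > 0, mean_dev / sd_dev, np.where(mean_dev == 0, 0.0, np.inf)
                )
            # dual convergence bar: the published per-effect criterion
            # plus an overall cap on every statistic (rates included) so
            # a badly unsolved rate cannot silently distort the effects
            eval_maxt = float(np.max(np.abs(tratios[: prob.K])))
            all_maxt = float(np.max(np.abs(tratios)))
            score = max(eval_maxt, all_maxt / 2.5)
            if best is None or score < best[0]:
                best = (score, theta.copy(), devs, tratios)
            if score < settings.conv_threshold or rnd == 2:
                break
            theta = prob.clip(theta - np.clip(Dinv @ mean_dev, -0.3, 0.3))
        converged = best[0] < settings.conv_threshold
        if converged:
            break
        logger.info(
            "fit attempt %d not converged (criterion score %.3f)%s",
            attempt + 1, best[0],
            "; restarting from best point" if attempt < settings.max_restarts else "",
        )
        theta = best[1].copy()
    _, theta, devs, tratios = best
    converged = best[0] < settings.conv_threshold

    # derivative re-estimated at the solution for the covariance
    D_hat = prob.derivative(
        theta, tag=500, n1=max(150, 3 * settings.n1), fd=0.2, central=True
    )
    Dinv = _invert_derivative(D_hat, n_eval=prob.K, strict=False)
    sigma = np.cov(devs, rowvar=False)
    cov_theta = Dinv @ sigma @ Dinv.T
    se = np.sqrt(np.clip(np.diag(cov_theta), 0.0, None))
    beta = theta[: prob.K]
    beta_se = se[: prob.K]
    with np.errstate(divide="ignore", invalid="ignore"):
        wald = np.where(beta_se > 0, beta / beta_se, np.nan)
    pvals = 2.0 * sps.norm.sf(np.abs(wald))

    rate_estimates, rate_ses = [], []
    pos = prob.K
    for p in panels:
        m = p.n_observations - 1
        rate_estimates.append((p.group_id, theta[pos : pos + m].copy()))
        rate_ses.append((p.group_id, se[pos : pos + m].copy()))
        pos += m

    return FitResult(
        effects=prob.names, estimates=beta, standard_errors=beta_se,
        wald_t=wald, p_values=pvals,
        rate_estimates=rate_estimates, rate_standard_errors=rate_ses,
        conv_t_ratios=tratios[: prob.K], rate_conv_t_ratios=tratios[prob.K :],
        converged=converged, n_restarts=attempt,
        message="" if converged else "not converged after restarts",
        seed=settings.seed,
    )


def multi_group_fit(
    panels: list[NetworkPanel], model: ModelSpec, settings: MoMSettings | None = None
) -> FitResult:
    """Joint fit of independent groups: shared evaluation parameters,
    one rate per period per group, targets summed over groups."""
    panels = list(panels)
    codings = {tuple(sorted(np.unique(p.covariate))) for p in panels}
    for c in codings:
        if not set(c) <= {0, 1}:
            raise ValueError(f"inconsistent covariate coding across groups: {codings}")
    return fit_mom(panels, model, settings)


def stepwise_select(
    panels,
    candidate_effects,
    settings: MoMSettings | None = None,
    alpha: float = 0.05,
    return_details: bool = False,
):
    """Forward stepwise effect selection.

    Each candidate effect is fitted alongside ``density`` in its own
    model; the per-effect Wald tests are tabulated and effects with
    ``p < alpha`` are retained; the joint model (density + retained) is
    then refitted. ``density`` is always kept as the control.
    """
    if isinstance(panels, NetworkPanel):
        panels = [panels]
    settings = settings or MoMSettings()
    candidates = list(candidate_effects)
    if "density" not in candidates:
        raise ValueError("candidates must include the density control")
    optional = [c for c in candidates if c != "density"]
    details = {}
    retained = []
    for j, name in enumerate(optional):
        sub = MoMSettings(**{**asdict(settings), "seed": settings.seed + 1000 * (j + 1)})
        fit = fit_mom(panels, ModelSpec([EffectSpec("density"), EffectSpec(name)]), sub)
        k = fit.effect_index(name)
        details[name] = {
            "estimate": float(fit.estimates[k]),
            "wald_t": float(fit.wald_t[k]),
            "p_value": float(fit.p_values[k]),
            "converged": fit.converged,
        }
        # retention requires a converged screening fit: with unmatched
        # moment conditions the estimates drift and their Wald tests are
        # meaningless. Panels that pass the Jaccard screen change slowly
        # enough for the rate conditions to be solvable.
        if fit.converged and fit.p_values[k] < alpha:
            retained.append(name)
    joint_names = ["density"] + retained
    joint = fit_mom(
        panels, ModelSpec([EffectSpec(n) for n in joint_names]),
        MoMSettings(**{**asdict(settings), "seed": settings.seed + 7}),
    )
    selected = ModelSpec(
        [EffectSpec(n, float(joint.estimates[joint.effect_index(n)])) for n in joint_names]
    )
    if return_details:
        return selected, {"per_effect": details, "joint": joint}
    return selected


# ---------------------------------------------------------------------------
# goodness of fit

@dataclass
class GofResult:
    auxiliary: str
    p_value: float
    observed_distance: float
    simulated_distances: np.ndarray
    used_mahalanobis: bool


def _aux_vector(obs_list: list[np.ndarray], auxiliary: str, nmax: int) -> np.ndarray:
    """Cumulative degree counts (actors with degree <= k) summed over the
    given observations."""
    out = np.zeros(nmax)
    for x in obs_list:
        deg = x.sum(axis=1) if auxiliary == "outdegree_distribution" else x.sum(axis=0)
        for k in range(nmax):
            out[k] += (deg <= k).sum()
    return out


def gof(
    fit: FitResult,
    panels,
    auxiliary: str = "indegree_distribution",
    n_sim: int = 200,
    seed: int = 0,
) -> GofResult:
    """Simulation-based goodness of fit on a degree-distribution auxiliary.

    Panels are re-simulated ``n_sim`` times from the fitted model (each
    period conditional on its observed starting network); the auxiliary
    statistic (cumulative in- or out-degree counts over non-first
    observations, summed over groups) is compared between observation and
    simulations via a variance-regularised Mahalanobis distance, giving a
    Monte-Carlo tail p-value.
    """
    if auxiliary not in ("indegree_distribution", "outdegree_distribution"):
        raise ValueError(f"unknown auxiliary {auxiliary!r}")
    if not fit.converged:
        raise ValueError("goodness of fit requires a converged fit")
    if isinstance(panels, NetworkPanel):
        panels = [panels]
    panels = list(panels)
    model = ModelSpec([EffectSpec(n, w) for n, w in zip(fit.effects, fit.estimates)])
    beta7 = model.dense_beta()
    rates = {g: r for g, r in fit.rate_estimates}
    nmax = max(p.n_actors for p in panels)

    obs_vec = _aux_vector(
        [p.observations[m] for p in panels for m in range(1, p.n_observations)],
        auxiliary, nmax,
    )
    sims = np.zeros((n_sim, nmax))
    for r in range(n_sim):
        sim_obs = []
        for p in panels:
            lam = rates[p.group_id]
            for m in range(p.n_observations - 1):
                ss = np.random.SeedSequence(
                    entropy=(seed, 990, r, _group_hash(p.group_id), m)
                )
                sim_obs.append(
                    _simulate_from_seedseq(p.observations[m], p.covariate, beta7, lam[m], ss)
                )
        sims[r] = _aux_vector(sim_obs, auxiliary, nmax)

    center = sims.mean(axis=0)
    spread = sims.std(axis=0)
    keep = spread > 1e-12
    used_mahalanobis = True
    if keep.sum() == 0:
        used_mahalanobis = False
        d_obs = float(np.linalg.norm(obs_vec - center))
        d_sim = np.linalg.norm(sims - center, axis=1)
        logger.warning("degenerate auxiliary covariance; falling back to Euclidean distance")
    else:
        cov = np.cov(sims[:, keep], rowvar=False).reshape(keep.sum(), keep.sum())
        cov += 1e-8 * np.eye(keep.sum()) * max(np.trace(cov) / keep.sum(), 1.0)
        try:
            cinv = np.linalg.inv(cov)
            dif_obs = obs_vec[keep] - center[keep]
            d_obs = float(dif_obs @ cinv @ dif_obs)
            dif = sims[:, keep] - center[keep]
            d_sim = np.einsum("ij,jk,ik->i", dif, cinv, dif)
        except np.linalg.LinAlgError:
            used_mahalanobis = False
            d_obs = float(np.linalg.norm(obs_vec - center))
            d_sim = np.linalg.norm(sims - center, axis=1)
            logger.warning("singular auxiliary covariance; falling back to Euclidean distance")
    p = (1.0 + float((d_sim >= d_obs).sum())) / (n_sim + 1.0)
    return GofResult(
        auxiliary=auxiliary, p_value=p, observed_distance=d_obs,
        simulated_distances=np.asarray(d_sim), used_mahalanobis=used_mahalanobis,
    )
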