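"""Incremental-window analysis of covariate effects over time.

To see how class differences in contact behaviour evolve during the
transmission phase, the monadic model (density + egoX + altX + sameX) is
refitted on nested windows of the panel: observations 1..2, then 1..3,
and so on up to the full panel, and the Wald t-statistics for the ego and
alter covariate effects are recorded per window. The resulting series is
then regressed on time (window end) and experimental condition
(Followed/Avoided), and a linear model is compared against a quadratic
one with an F-test: a significant quadratic term indicates that class
differences first grow and then level off as the network stabilises.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

from .netbuild import NetworkPanel, ConditionLabel
from .saom import EffectSpec, ModelSpec, MoMSettings, fit_mom

logger = logging.getLogger(__name__)

MONADIC_MODEL = ["density", "egoX", "altX", "sameX"]


@dataclass
class WindowRecord:
    group_id: str
    condition: str
    window_end_interval: int
    ego_t: float
    alter_t: float
    converged: bool


class WindowSeries:
    """Ego/alter Wald t-statistics across incremental windows."""

    def __init__(self, records: list[WindowRecord]):
        self.records = list(records)
        by_group: dict[str, int] = {}
        for r in self.records:
            prev = by_group.get(r.group_id)
            if prev is not None and r.window_end_interval <= prev:
                raise ValueError(
                    f"window_end_interval not strictly increasing in group {r.group_id}"
                )
            by_group[r.group_id] = r.window_end_interval

    def __len__(self) -> int:
        return len(self.records)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame([asdict(r) for r in self.records])
        return df.rename(
            columns={"group_id": "group", "window_end_interval": "window_end"}
        )[["group", "condition", "window_end", "ego_t", "alter_t", "converged"]]

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "WindowSeries":
        df = pd.read_csv(path, comment="#")
        return cls(
            [
                WindowRecord(
                    str(r.group), str(r.condition), int(r.window_end),
                    float(r.ego_t), float(r.alter_t), bool(r.converged),
                )
                for r in df.itertuples()
            ]
        )

    def usable(self) -> pd.DataFrame:
        """Only converged window fits enter the trend tests."""
        df = self.to_frame()
        return df[df["converged"]].reset_index(drop=True)


def incremental_fits(
    labeled_panels: list[tuple[NetworkPanel, ConditionLabel]],
    settings: MoMSettings | None = None,
) -> WindowSeries:
    """Fit the monadic model on windows of increasing length.

    For each condition-labelled panel with observations 1..M, fits the
    model on observations 1..L for L = 2, ..., M and records the egoX and
    altX Wald t-statistics. Non-converged window fits are kept in the
    series but flagged and excluded from downstream trend tests.
    """
    settings = settings or MoMSettings()
    model = ModelSpec([EffectSpec(n) for n in MONADIC_MODEL])
    records: list[WindowRecord] = []
    for panel, label in labeled_panels:
        if panel.n_observations < 2:
            raise ValueError(f"panel {panel.group_id} has fewer than two observations")
        for L in range(2, panel.n_observations + 1):
            window = NetworkPanel(
                group_id=panel.group_id,
                observations=panel.observations[:L],
                covariate=panel.covariate,
                interval_minutes=panel.interval_minutes,
                actor_ids=panel.actor_ids,
            )
            sub = MoMSettings(**{**asdict(settings), "seed": settings.seed + 131 * L})
            fit = fit_mom(window, model, sub)
            records.append(
                WindowRecord(
                    group_id=panel.group_id,
                    condition=label.value if isinstance(label, ConditionLabel) else str(label),
                    window_end_interval=L,
                    ego_t=float(fit.wald_t[fit.effect_index("egoX")]),
                    alter_t=float(fit.wald_t[fit.effect_index("altX")]),
                    converged=fit.converged,
                )
            )
            if not fit.converged:
                logger.info(
                    "window fit %s L=%d not converged; excluded from trends",
                    panel.group_id, L,
                )
    return WindowSeries(records)


@dataclass
class TrendTest:
    """Linear vs quadratic time trend of a window t-statistic series."""

    response: str
    n: int
    linear_params: dict
    quadratic_params: dict
    condition_t_linear: float
    condition_p_linear: float
    condition_t_quadratic: float
    condition_p_quadratic: float
    rss_linear: float
    rss_quadratic: float
    f_statistic: float
    p_value: float

    def to_dict(self) -> dict:
        return asdict(self)


def trend_test(series: WindowSeries | pd.DataFrame, response: str = "ego_t") -> TrendTest:
    """F-test of a quadratic vs linear time trend.

    Ordinary least squares of the response on (time, condition) and on
    (time, time², condition); both models share the same records (paired
    nesting), and F = ((RSS_lin − RSS_quad)/1) / (RSS_quad/(N − p_quad)).
    The condition contrast's t-test is reported for each model.
    """
    if response not in ("ego_t", "alter_t"):
        raise ValueError("response must be 'ego_t' or 'alter_t'")
    df = series.usable() if isinstance(series, WindowSeries) else series
    if len(df) < 4:
        raise ValueError("need at least four usable records for the trend test")
    conds = sorted(df["condition"].unique())
    if len(conds) < 2:
        raise ValueError("both experimental conditions must be present")
    t = df["window_end"].to_numpy(dtype=float)
    cond = (df["condition"] == conds[1]).to_numpy(dtype=float)
    if np.ptp(t) == 0:
        raise ValueError("time predictor is constant")
    y = df[response].to_numpy(dtype=float)

    X_lin = sm.add_constant(np.column_stack([t, cond]))
    X_quad = sm.add_constant(np.column_stack([t, t**2, cond]))
    for X, label in ((X_lin, "linear"), (X_quad, "quadratic")):
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise ValueError(f"collinear predictors in the {label} model")
    lin = sm.OLS(y, X_lin).fit()
    quad = sm.OLS(y, X_quad).fit()

    rss_lin = float(lin.ssr)
    rss_quad = float(quad.ssr)
    dof = len(y) - X_quad.shape[1]
    if dof <= 0:
        raise ValueError("too few records for the quadratic model")
    tol = np.finfo(float).eps * max(1.0, float(y @ y))
    if rss_lin <= tol:
        # the linear model is already exact; no quadratic improvement
        f_stat, p = 0.0, 1.0
    elif rss_quad <= tol:
        f_stat, p = np.inf, 0.0
    else:
        f_stat = (rss_lin - rss_quad) / (rss_quad / dof)
        p = float(sps.f.sf(f_stat, 1, dof))

    return TrendTest(
        response=response,
        n=len(y),
        linear_params={"const": lin.params[0], "time": lin.params[1], "condition": lin.params[2]},
        quadratic_params={
            "const": quad.params[0], "time": quad.params[1],
            "time2": quad.params[2], "condition": quad.params[3],
        },
        condition_t_linear=float(lin.tvalues[2]),
        condition_p_linear=float(lin.pvalues[2]),
        condition_t_quadratic=float(quad.tvalues[3]),
        condition_p_quadratic=float(quad.pvalues[3]),
        rss_linear=rss_lin,
        rss_quadratic=rss_quad,
        f_statistic=float(f_stat),
        p_value=float(p),
    )
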