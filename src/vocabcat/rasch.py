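"""Dichotomous Rasch model: calibration, ability estimation, fit, reliability.

The model is the one-parameter logistic: the probability that person *n*
answers item *i* correctly is ``P = exp(theta_n - b_i) / (1 + exp(theta_n - b_i))``
with ability ``theta_n`` and difficulty ``b_i`` on a shared logit scale.

Item calibration uses marginal maximum likelihood via EM with a Normal(0,
sigma^2) ability prior; the prior mean is fixed at 0 for identification and
sigma is estimated from the data.  The posterior over abilities is carried
on a fixed quadrature grid (91 equally spaced nodes on [-12, 12] logits):
the grid must extend well past the difficulty span of the bank and the
tails of the ability distribution, since truncating the posterior of
extreme respondents compresses the recovered difficulty scale.
This formulation handles the structural missingness of adaptive designs —
cells that were never administered simply contribute to no sums — as well
as extreme response patterns.

Fit statistics follow standard Rasch practice: with ``W = P(1-P)`` and
standardized residual ``z = (x - P)/sqrt(W)``, outfit is the unweighted mean
of ``z^2`` over scored cells and infit the information-weighted mean
``sum(W z^2)/sum(W)``.  Standardized forms use the Wilson–Hilferty cube-root
transform with the model variance of each mean-square computed from the
kurtosis of the cell residuals.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

__all__ = [
    "ResponseMatrix",
    "FitStatistics",
    "ReliabilitySummary",
    "CalibrationResult",
    "CalibrationConfig",
    "ExtremeResponsePatternError",
    "response_probability",
    "estimate_ability",
    "calibrate_items",
    "fit_statistics",
    "separation_reliability",
    "item_response_curve",
]

QUAD_POINTS = 91
QUAD_RANGE = (-12.0, 12.0)


class ExtremeResponsePatternError(ValueError):
    """ML ability is not finite for an all-correct/all-incorrect pattern."""


# ---------------------------------------------------------------------------
# containers


@dataclass
class ResponseMatrix:
    """Person x item dichotomous scores with structural missingness.

    ``scores`` is a float array with entries in {0.0, 1.0, NaN}; NaN marks a
    cell that was never administered (missing by design).
    """

    person_ids: tuple[str, ...]
    item_ids: tuple[str, ...]
    scores: np.ndarray

    def __post_init__(self) -> None:
        self.person_ids = tuple(self.person_ids)
        self.item_ids = tuple(self.item_ids)
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.shape != (len(self.person_ids), len(self.item_ids)):
            raise ValueError("scores shape does not match id axes")
        if len(set(self.person_ids)) != len(self.person_ids):
            raise ValueError("duplicate person ids")
        if len(set(self.item_ids)) != len(self.item_ids):
            raise ValueError("duplicate item ids")
        observed = self.scores[~np.isnan(self.scores)]
        if observed.size and not np.isin(observed, (0.0, 1.0)).all():
            raise ValueError("scored entries must be 0 or 1")

    @property
    def n_persons(self) -> int:
        return len(self.person_ids)

    @property
    def n_items(self) -> int:
        return len(self.item_ids)

    def subset_items(self, item_ids: Sequence[str]) -> "ResponseMatrix":
        index = {iid: j for j, iid in enumerate(self.item_ids)}
        cols = [index[i] for i in item_ids]
        return ResponseMatrix(self.person_ids, tuple(item_ids), self.scores[:, cols])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.scores, index=list(self.person_ids), columns=list(self.item_ids)
        )

    def to_csv(self, path: str | Path) -> None:
        frame = self.to_frame()
        frame.index.name = "person_id"
        frame.to_csv(path, na_rep="NA")

    @classmethod
    def from_csv(cls, path: str | Path) -> "ResponseMatrix":
        frame = pd.read_csv(path, index_col=0, na_values=["NA"])
        return cls(
            tuple(str(p) for p in frame.index),
            tuple(str(c) for c in frame.columns),
            frame.to_numpy(dtype=float),
        )


@dataclass(frozen=True)
class FitStatistics:
    """Raw and standardized mean-square fit for one item or person."""

    entity_id: str
    outfit_mse: float
    infit_mse: float
    std_outfit: float
    std_infit: float
    n_responses: int = 0


@dataclass(frozen=True)
class ReliabilitySummary:
    item_location_mean_sd: tuple[float, float]
    person_location_mean_sd: tuple[float, float]
    item_separation_reliability: float
    person_separation_reliability: float
    item_separation_G: float
    person_separation_G: float
    item_strata: float
    person_strata: float


@dataclass
class CalibrationResult:
    """Output of :func:`calibrate_items`."""

    item_difficulties: dict[str, tuple[float, float]]
    person_abilities: dict[str, tuple[float, float]]
    item_fit: list[FitStatistics]
    person_fit: list[FitStatistics]
    summary: ReliabilitySummary
    converged: bool
    iterations: int
    non_estimable: tuple[str, ...] = ()
    prior_sd: float = float("nan")

    # -- exports --------------------------------------------------------

    def item_table(self) -> pd.DataFrame:
        fit = {f.entity_id: f for f in self.item_fit}
        rows = []
        for iid, (b, se) in self.item_difficulties.items():
            f = fit.get(iid)
            rows.append(
                {
                    "item_id": iid,
                    "difficulty": b,
                    "se": se,
                    "outfit_mse": f.outfit_mse if f else np.nan,
                    "infit_mse": f.infit_mse if f else np.nan,
                    "std_outfit": f.std_outfit if f else np.nan,
                    "std_infit": f.std_infit if f else np.nan,
                }
            )
        return pd.DataFrame(rows)

    def person_table(self) -> pd.DataFrame:
        fit = {f.entity_id: f for f in self.person_fit}
        rows = []
        for pid, (theta, se) in self.person_abilities.items():
            f = fit.get(pid)
            rows.append(
                {
                    "person_id": pid,
                    "ability": theta,
                    "se": se,
                    "outfit_mse": f.outfit_mse if f else np.nan,
                    "infit_mse": f.infit_mse if f else np.nan,
                    "std_outfit": f.std_outfit if f else np.nan,
                    "std_infit": f.std_infit if f else np.nan,
                }
            )
        return pd.DataFrame(rows)

    def wright_map_frame(self) -> pd.DataFrame:
        """Two-column (axis, location) table for item-person map plotting."""
        rows = [
            {"axis": "person", "location": theta}
            for theta, _ in self.person_abilities.values()
        ] + [
            {"axis": "item", "location": b}
            for b, _ in self.item_difficulties.values()
        ]
        return pd.DataFrame(rows)

    def write_outputs(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.item_table().to_csv(out / "items.csv", index=False)
        self.person_table().to_csv(out / "persons.csv", index=False)
        self.wright_map_frame().to_csv(out / "wright_map.csv", index=False)
        doc = {
            "converged": self.converged,
            "iterations": self.iterations,
            "prior_sd": self.prior_sd,
            "non_estimable": list(self.non_estimable),
            "summary": {
                "item_location_mean_sd": list(self.summary.item_location_mean_sd),
                "person_location_mean_sd": list(self.summary.person_location_mean_sd),
                "item_separation_reliability": self.summary.item_separation_reliability,
                "person_separation_reliability": self.summary.person_separation_reliability,
                "item_separation_G": self.summary.item_separation_G,
                "person_separation_G": self.summary.person_separation_G,
                "item_strata": self.summary.item_strata,
                "person_strata": self.summary.person_strata,
            },
        }
        (out / "calibration.json").write_text(json.dumps(doc, indent=1))


@dataclass
class CalibrationConfig:
    """EM settings for marginal maximum likelihood calibration."""

    quadrature_points: int = QUAD_POINTS
    quadrature_range: tuple[float, float] = QUAD_RANGE
    max_iter: int = 500
    tol: float = 1e-6
    prior_sd_init: float = 2.0
    estimate_prior_sd: bool = True
    min_prior_sd: float = 0.1


# ---------------------------------------------------------------------------
# response probability


def response_probability(theta, b):
    """Rasch probability of a correct response, ``expit(theta - b)``.

    Strictly increasing in ``theta``, decreasing in ``b``; accepts scalars
    or broadcastable arrays.
    """
    theta = np.asarray(theta, dtype=float)
    b = np.asarray(b, dtype=float)
    if not (np.isfinite(theta).all() and np.isfinite(b).all()):
        raise ValueError("response_probability requires finite inputs")
    p = expit(theta - b)
    if p.ndim == 0:
        return float(p)
    return p


# ---------------------------------------------------------------------------
# ability estimation


def _quad_grid(config: CalibrationConfig | None = None) -> np.ndarray:
    cfg = config or CalibrationConfig()
    lo, hi = cfg.quadrature_range
    return np.linspace(lo, hi, cfg.quadrature_points)


def estimate_ability(
    responses: Sequence[tuple[float, int]],
    method: str = "eap",
    prior: tuple[float, float] = (0.0, 3.0),
) -> tuple[float, float]:
    """Estimate a person's ability from scored (difficulty, score) pairs.

    ``method="ml"`` solves the score equation ``sum(x - P) = 0`` and reports
    ``SE = 1/sqrt(I(theta))``; it raises :class:`ExtremeResponsePatternError`
    for all-correct or all-incorrect patterns, for which the root diverges.
    ``method="eap"`` returns the posterior mean and SD under a normal prior
    evaluated on the fixed quadrature grid, and is finite for any pattern.
    """
    if len(responses) == 0:
        raise ValueError("at least one scored response is required")
    b = np.array([r[0] for r in responses], dtype=float)
    x = np.array([r[1] for r in responses], dtype=float)
    if not np.isin(x, (0.0, 1.0)).all():
        raise ValueError("scores must be 0 or 1")

    if method == "ml":
        if x.min() == x.max():
            raise ExtremeResponsePatternError(
                "ML ability is not finite for an extreme response pattern"
            )
        from scipy.optimize import brentq

        def score_eq(t: float) -> float:
            return float(np.sum(x - expit(t - b)))

        theta = brentq(score_eq, -30.0, 30.0, xtol=1e-12)
        p = expit(theta - b)
        info = float(np.sum(p * (1.0 - p)))
        return float(theta), 1.0 / np.sqrt(info)

    if method != "eap":
        raise ValueError(f"unknown ability estimator {method!r}")
    mean, sd = prior
    if sd <= 0:
        raise ValueError("EAP prior sd must be positive")
    grid = _quad_grid()
    # log-likelihood of the response pattern at each node
    p = expit(grid[:, None] - b[None, :])
    ll = x[None, :] * np.log(p) + (1.0 - x[None, :]) * np.log1p(-p)
    logpost = ll.sum(axis=1) - 0.5 * ((grid - mean) / sd) ** 2
    logpost -= logpost.max()
    w = np.exp(logpost)
    w /= w.sum()
    theta = float(np.dot(w, grid))
    var = float(np.dot(w, grid**2) - theta**2)
    return theta, float(np.sqrt(max(var, 0.0)))


# ---------------------------------------------------------------------------
# calibration


def calibrate_items(
    matrix: ResponseMatrix, config: CalibrationConfig | None = None
) -> CalibrationResult:
    """Marginal maximum likelihood Rasch calibration of *matrix*.

    Items whose scored responses are all 0 or all 1 (or absent) carry no
    finite difficulty estimate; they are reported in ``non_estimable`` and
    excluded from estimation rather than silently dropped.
    """
    cfg = config or CalibrationConfig()
    if matrix.n_persons == 0 or matrix.n_items == 0:
        raise ValueError("cannot calibrate an empty response matrix")

    X = matrix.scores
    obs = ~np.isnan(X)
    col_n = obs.sum(axis=0)
    col_s = np.nansum(X, axis=0)
    estimable = (col_n > 0) & (col_s > 0) & (col_s < col_n)
    non_estimable = tuple(
        iid for iid, ok in zip(matrix.item_ids, estimable) if not ok
    )
    if not estimable.any():
        raise ValueError("no estimable items in the response matrix")

    item_ids = [iid for iid, ok in zip(matrix.item_ids, estimable) if ok]
    Xe = X[:, estimable]
    obs_e = obs[:, estimable]
    x1 = np.where(obs_e, np.nan_to_num(Xe), 0.0)
    x0 = np.where(obs_e, 1.0 - np.nan_to_num(Xe), 0.0)
    S = x1.sum(axis=0)
    n_i = obs_e.sum(axis=0)

    grid = np.linspace(*cfg.quadrature_range, cfg.quadrature_points)
    p_obs = S / n_i
    b = np.log((1.0 - p_obs) / p_obs)  # PROX-style start
    sigma = cfg.prior_sd_init

    n_persons = matrix.n_persons
    converged = False
    iterations = 0
    W = np.full((n_persons, grid.size), 1.0 / grid.size)
    for iterations in range(1, cfg.max_iter + 1):
        # E-step: posterior weights over the quadrature grid per person
        P = expit(grid[:, None] - b[None, :])  # nodes x items
        ll = x1 @ np.log(P).T + x0 @ np.log1p(-P).T  # persons x nodes
        ll += -0.5 * (grid / sigma) ** 2 - np.log(sigma)
        ll -= ll.max(axis=1, keepdims=True)
        W = np.exp(ll)
        W /= W.sum(axis=1, keepdims=True)

        if cfg.estimate_prior_sd:
            sigma = max(
                float(np.sqrt((W @ grid**2).sum() / n_persons)), cfg.min_prior_sd
            )

        # M-step: expected node counts per item, then Newton per item
        M = obs_e.T @ W  # items x nodes
        b_old = b.copy()
        for _ in range(50):
            Pq = expit(grid[None, :] - b[:, None])  # items x nodes
            E = (M * Pq).sum(axis=1)
            V = (M * Pq * (1.0 - Pq)).sum(axis=1)
            step = np.clip((E - S) / np.maximum(V, 1e-12), -1.0, 1.0)
            b = np.clip(b + step, -9.5, 9.5)
            if np.max(np.abs(step)) < 1e-10:
                break
        if np.max(np.abs(b - b_old)) < cfg.tol:
            converged = True
            break

    # item SEs from the expected Fisher information at the solution
    Pq = expit(grid[None, :] - b[:, None])
    M = obs_e.T @ W
    info = (M * Pq * (1.0 - Pq)).sum(axis=1)
    b_se = 1.0 / np.sqrt(np.maximum(info, 1e-12))

    item_difficulties = {
        iid: (float(bi), float(se)) for iid, bi, se in zip(item_ids, b, b_se)
    }

    # person EAP estimates under the fitted prior and difficulties
    theta = W @ grid
    theta_var = W @ grid**2 - theta**2
    theta_se = np.sqrt(np.maximum(theta_var, 0.0))
    person_abilities = {
        pid: (float(t), float(se))
        for pid, t, se in zip(matrix.person_ids, theta, theta_se)
    }

    sub = matrix.subset_items(item_ids)
    diff_map = {iid: bi for iid, (bi, _) in item_difficulties.items()}
    abil_map = {pid: t for pid, (t, _) in person_abilities.items()}
    item_fit = fit_statistics(sub, diff_map, abil_map, axis="item")
    person_fit = fit_statistics(sub, diff_map, abil_map, axis="person")

    item_rel, item_G, item_strata = separation_reliability(
        list(item_difficulties.values())
    )
    person_rel, person_G, person_strata = separation_reliability(
        list(person_abilities.values())
    )
    b_vals = np.array([v for v, _ in item_difficulties.values()])
    t_vals = np.array([v for v, _ in person_abilities.values()])
    summary = ReliabilitySummary(
        item_location_mean_sd=(float(b_vals.mean()), float(b_vals.std(ddof=1))),
        person_location_mean_sd=(float(t_vals.mean()), float(t_vals.std(ddof=1))),
        item_separation_reliability=item_rel,
        person_separation_reliability=person_rel,
        item_separation_G=item_G,
        person_separation_G=person_G,
        item_strata=item_strata,
        person_strata=person_strata,
    )
    return CalibrationResult(
        item_difficulties=item_difficulties,
        person_abilities=person_abilities,
        item_fit=item_fit,
        person_fit=person_fit,
        summary=summary,
        converged=converged,
        iterations=iterations,
        non_estimable=non_estimable,
        prior_sd=float(sigma),
    )


# ---------------------------------------------------------------------------
# fit statistics


def _as_value(v) -> float:
    if isinstance(v, tuple):
        return float(v[0])
    return float(v)


def fit_statistics(
    matrix: ResponseMatrix,
    difficulties: Mapping[str, float | tuple[float, float]],
    abilities: Mapping[str, float | tuple[float, float]],
    axis: str = "item",
) -> list[FitStatistics]:
    """Outfit/infit mean squares and their standardized forms per entity.

    Every scored cell must have both a difficulty and an ability; entities
    with zero scored cells are omitted with a warning.
    """
    if axis not in {"item", "person"}:
        raise ValueError("axis must be 'item' or 'person'")
    for iid in matrix.item_ids:
        if iid not in difficulties:
            raise ValueError(f"no difficulty for item {iid!r}")
    for pid in matrix.person_ids:
        if pid not in abilities:
            raise ValueError(f"no ability for person {pid!r}")

    b = np.array([_as_value(difficulties[i]) for i in matrix.item_ids])
    t = np.array([_as_value(abilities[p]) for p in matrix.person_ids])
    X = matrix.scores
    obs = ~np.isnan(X)
    P = expit(t[:, None] - b[None, :])
    Wv = P * (1.0 - P)
    resid2 = np.where(obs, (np.nan_to_num(X) - P) ** 2, 0.0)
    z2 = np.where(obs, resid2 / Wv, 0.0)
    # residual kurtosis: E[(x - P)^4] for a Bernoulli cell
    C = np.where(obs, Wv * ((1.0 - P) ** 3 + P**3), 0.0)
    Wm = np.where(obs, Wv, 0.0)

    if axis == "item":
        ids = matrix.item_ids
        ax = 0
    else:
        ids = matrix.person_ids
        ax = 1

    N = obs.sum(axis=ax)
    out: list[FitStatistics] = []
    sum_z2 = z2.sum(axis=ax)
    sum_r2 = resid2.sum(axis=ax)
    sum_W = Wm.sum(axis=ax)
    sum_C = C.sum(axis=ax)
    sum_CW2 = np.where(obs, C / Wv**2, 0.0).sum(axis=ax)
    for k, eid in enumerate(ids):
        n = int(N[k])
        if n == 0:
            warnings.warn(f"{axis} {eid!r} has no scored responses; omitted")
            continue
        outfit = sum_z2[k] / n
        infit = sum_r2[k] / sum_W[k]
        q2_out = max(sum_CW2[k] / n**2 - 1.0 / n, 0.0)
        q2_in = max(sum_C[k] - (Wm[:, k] ** 2 if ax == 0 else Wm[k, :] ** 2).sum(), 0.0)
        q2_in /= sum_W[k] ** 2
        out.append(
            FitStatistics(
                entity_id=eid,
                outfit_mse=float(outfit),
                infit_mse=float(infit),
                std_outfit=_wilson_hilferty(outfit, q2_out),
                std_infit=_wilson_hilferty(infit, q2_in),
                n_responses=n,
            )
        )
    return out


def _wilson_hilferty(mse: float, q2: float) -> float:
    """Cube-root standardization of a mean-square fit statistic."""
    if q2 <= 0.0:
        return 0.0
    q = np.sqrt(q2)
    return float((mse ** (1.0 / 3.0) - 1.0) * (3.0 / q) + q / 3.0)


# ---------------------------------------------------------------------------
# reliability of separation


def separation_reliability(
    estimates: Sequence[tuple[float, float]],
) -> tuple[float, float, float]:
    """Reliability of separation, separation index G, and STRATA.

    With observed variance ``SD_obs^2`` of the estimates and mean error
    variance ``MSE_err = mean(se^2)``, the adjusted (true) variance is
    ``max(SD_obs^2 - MSE_err, 0)``; reliability R is the adjusted share of
    the observed variance, ``G = sqrt(adjusted/MSE_err)``, and
    ``STRATA = (4G + 1)/3`` — the number of statistically distinguishable
    performance levels.  R and G satisfy ``R = G^2/(1 + G^2)``.
    """
    if len(estimates) < 2:
        raise ValueError("separation needs at least 2 estimates")
    values = np.array([e[0] for e in estimates], dtype=float)
    ses = np.array([e[1] for e in estimates], dtype=float)
    sd_obs2 = float(values.var(ddof=1))
    mse_err = float(np.mean(ses**2))
    if sd_obs2 <= 0.0:
        warnings.warn("zero observed variance; reliability set to 0 by convention")
        return 0.0, 0.0, 1.0 / 3.0
    adjusted = max(sd_obs2 - mse_err, 0.0)
    reliability = adjusted / sd_obs2
    if mse_err == 0.0:
        return 1.0, float("inf"), float("inf")
    G = float(np.sqrt(adjusted / mse_err))
    strata = (4.0 * G + 1.0) / 3.0
    return float(reliability), G, float(strata)


# ---------------------------------------------------------------------------
# item response curves


def item_response_curve(
    matrix: ResponseMatrix,
    item_id: str,
    difficulty: float,
    abilities: Mapping[str, float | tuple[float, float]],
    n_bins: int = 10,
) -> pd.DataFrame:
    """Empirical vs. expected proportion correct across ability bins.

    Respondents who answered *item_id* are split into ``n_bins``
    equal-count ability bins; each row reports the bin's mean ability, the
    observed proportion correct, the model-expected probability at that
    mean ability, and the respondent count.  Bins are reduced (with a
    warning) when there are fewer scored responses, or fewer distinct
    ability values, than requested bins.
    """
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    j = matrix.item_ids.index(item_id)
    col = matrix.scores[:, j]
    mask = ~np.isnan(col)
    if not mask.any():
        raise ValueError(f"item {item_id!r} has no scored responses")
    scores = col[mask]
    theta = np.array(
        [_as_value(abilities[p]) for p, m in zip(matrix.person_ids, mask) if m]
    )
    if scores.size < n_bins or np.unique(theta).size < n_bins:
        n_bins = max(min(scores.size, np.unique(theta).size), 1)
        warnings.warn(f"reduced to {n_bins} ability bins for item {item_id!r}")
    order = np.argsort(theta, kind="stable")
    rows = []
    for chunk in np.array_split(order, n_bins):
        t_mean = float(theta[chunk].mean())
        rows.append(
            {
                "ability": t_mean,
                "observed": float(scores[chunk].mean()),
                "expected": float(expit(t_mean - difficulty)),
                "count": int(chunk.size),
            }
        )
    return pd.DataFrame(rows)
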