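"""Mixed-effects estimation and paired cluster-bootstrap model comparison.

Two model families are supported, both REML-fitted with a random intercept
per subject and random slopes for every repeated-measure predictor:

* ``time_on_distance`` — linguistic distance regressed on time in
  treatment (random intercept + time slope by client);
* ``symptoms_on_distance`` — internalizing symptoms regressed on the
  within- and between-person components of distance (random intercept +
  within-component slope by client).

Coefficients are reported in pseudo-standardized units: each predictor is
scaled by its standard deviation *at its own level* (pooled within-person SD
for repeated measures, SD of person means for person-level predictors) and
the outcome by its SD at the matching level.  Effect size per predictor is
the semipartial R^2_beta = F / (F + df2), where F is the coefficient's Wald
statistic (numerator df 1) and df2 its Satterthwaite denominator df.

Two scoring methods are compared with a paired cluster bootstrap: clusters
(clients or therapists) are resampled with replacement, duplicates relabeled
as distinct clusters, both models refitted on the identical resample, and
the difference in the focal predictor's R^2_beta recorded; the central 95%
of the B differences forms the confidence interval, and the difference is
significant when that interval excludes zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .lmm import LMM, LMMResult

logger = logging.getLogger(__name__)

__all__ = ["ModelSpec", "EffectEstimate", "ModelFit", "BootstrapComparison",
           "fit_model", "paired_bootstrap_compare"]

# predictor name -> (table column, is repeated-measure)
_PREDICTORS = {
    "time": ("time", True),
    "within": ("score_within", True),
    "between": ("score_between", False),
}


@dataclass(frozen=True)
class ModelSpec:
    """One of the two regression families (or a custom predictor set)."""

    outcome: str
    predictors: tuple[str, ...]
    name: str = "custom"

    @classmethod
    def time_on_distance(cls) -> "ModelSpec":
        return cls(outcome="score", predictors=("time",),
                   name="time_on_distance")

    @classmethod
    def symptoms_on_distance(cls) -> "ModelSpec":
        return cls(outcome="internalizing", predictors=("within", "between"),
                   name="symptoms_on_distance")

    @property
    def repeated(self) -> tuple[str, ...]:
        return tuple(p for p in self.predictors if _PREDICTORS[p][1])


@dataclass
class EffectEstimate:
    predictor: str
    beta: float
    beta_std: float
    se: float
    p_value: float
    r2_beta: float
    denominator_df: float
    degenerate: bool = False


@dataclass
class ModelFit:
    spec: ModelSpec
    effects: dict[str, EffectEstimate]
    lmm: LMMResult | None
    converged: bool
    singular: bool
    n_obs: int
    n_groups: int


def _level_sds(values: np.ndarray, groups: np.ndarray) -> tuple[float, float]:
    """(pooled within-person SD, SD of person means) for one variable."""
    codes, inv = np.unique(groups, return_inverse=True)
    counts = np.bincount(inv)
    means = np.bincount(inv, weights=values) / counts
    within = values - means[inv]
    sd_w = float(np.std(within, ddof=1)) if len(values) > 1 else 0.0
    sd_b = float(np.std(means, ddof=1)) if len(codes) > 1 else 0.0
    return sd_w, sd_b


def _prepare(table: pd.DataFrame, spec: ModelSpec):
    """Design matrices + standardization SDs from a windowed table."""
    df = table
    need_decomp = any(p in ("within", "between") for p in spec.predictors)
    if need_decomp and "score_within" not in df.columns:
        from .longitudinal import decompose

        df = decompose(df, "score")
    y = df[spec.outcome].to_numpy(dtype=float)
    groups = df["client_id"].to_numpy()
    cols = [np.ones(len(df))]
    zcols = [np.ones(len(df))]
    for p in spec.predictors:
        col = df[_PREDICTORS[p][0]].to_numpy(dtype=float)
        cols.append(col)
        if _PREDICTORS[p][1]:
            zcols.append(col)
    X = np.column_stack(cols)
    Z = np.column_stack(zcols)

    sd_y_w, sd_y_b = _level_sds(y, groups)
    scale = {}
    for j, p in enumerate(spec.predictors, start=1):
        x = X[:, j]
        sd_x_w, sd_x_b = _level_sds(x, groups)
        if _PREDICTORS[p][1]:  # repeated measure: within level
            scale[p] = (sd_x_w, sd_y_w if sd_y_w > 0 else 1.0)
        else:
            scale[p] = (sd_x_b, sd_y_b if sd_y_b > 0 else 1.0)
    return y, X, Z, groups, scale


def fit_model(table: pd.DataFrame, spec: ModelSpec,
              start=None) -> ModelFit:
    """REML fit of one model family on a windowed regression table.

    Returns per-predictor pseudo-standardized coefficients, Satterthwaite
    p-values and semipartial R^2_beta.  A predictor with zero variance is
    flagged degenerate (NaN estimates) rather than silently dropped;
    non-convergence or a singular random-effects fit is flagged on the
    result, never hidden.
    """
    y, X, Z, groups, scale = _prepare(table, spec)
    for j, p in enumerate(spec.predictors, start=1):
        if float(np.std(X[:, j])) == 0.0:
            effects = {
                q: EffectEstimate(q, np.nan, np.nan, np.nan, np.nan, np.nan,
                                  np.nan, degenerate=True)
                for q in spec.predictors
            }
            logger.warning("predictor %r has zero variance; fit flagged "
                           "degenerate", p)
            return ModelFit(spec, effects, None, converged=False,
                            singular=True, n_obs=len(y),
                            n_groups=len(np.unique(groups)))
    res = LMM(y, X, Z, groups).fit(reml=True, start=start)
    effects: dict[str, EffectEstimate] = {}
    for j, p in enumerate(spec.predictors, start=1):
        tt = res.t_test(j)
        sd_x, sd_y = scale[p]
        r2 = tt["F"] / (tt["F"] + tt["df"]) if np.isfinite(tt["df"]) else np.nan
        effects[p] = EffectEstimate(
            predictor=p,
            beta=tt["beta"],
            beta_std=tt["beta"] * sd_x / sd_y,
            se=tt["se"],
            p_value=tt["p"],
            r2_beta=r2,
            denominator_df=tt["df"],
        )
    return ModelFit(spec, effects, res, converged=res.converged,
                    singular=res.singular, n_obs=len(y),
                    n_groups=len(np.unique(groups)))


@dataclass
class BootstrapComparison:
    B: int
    unit: str
    focal: str
    deltas: np.ndarray
    ci_low: float
    ci_high: float
    significant: bool
    n_failed_fits: int
    n_fallback: int
    r2_full_a: float
    r2_full_b: float
    unreliable: bool = False

    @property
    def delta_full(self) -> float:
        return self.r2_full_a - self.r2_full_b


def _r2_for_focal(y, X, Z, groups, focal_idx, start, n_fallback_box):
    """One bootstrap-resample fit; drops the random slope on failure."""
    try:
        res = LMM(y, X, Z, groups).fit(reml=True, start=start)
        if res.converged:
            tt = res.t_test(focal_idx)
            if np.isfinite(tt["df"]) and tt["df"] > 0:
                return tt["F"] / (tt["F"] + tt["df"])
    except (np.linalg.LinAlgError, ValueError):
        pass
    # simplified random structure (intercept only) as bootstrap fallback
    n_fallback_box[0] += 1
    res = LMM(y, X, Z[:, :1], groups).fit(reml=True)
    if not res.converged:
        raise RuntimeError("fallback fit failed")
    tt = res.t_test(focal_idx)
    return tt["F"] / (tt["F"] + tt["df"])


def paired_bootstrap_compare(
    table_a: pd.DataFrame,
    table_b: pd.DataFrame,
    spec: ModelSpec,
    focal: str,
    B: int = 2000,
    unit: str = "client",
    seed: int = 0,
) -> BootstrapComparison:
    """Paired cluster bootstrap of the focal predictor's R^2_beta difference.

    ``table_a`` and ``table_b`` are windowed tables for the two scoring
    methods over the same clients.  Each of the B resamples draws N clusters
    with replacement (N = number held in the full data), relabels duplicate
    clusters as distinct (required for valid random-effects refits), rebuilds
    both tables from the identical resample, refits both models, and records
    the difference in semipartial R^2_beta.  Failed fits are skipped and
    counted; more than 10% failures flags the comparison unreliable.
    """
    if focal not in spec.predictors:
        raise ValueError(f"focal predictor {focal!r} not in spec")
    if unit not in ("client", "therapist"):
        raise ValueError(f"unknown bootstrap unit: {unit!r}")
    rng = np.random.default_rng(seed)
    focal_idx = 1 + spec.predictors.index(focal)

    full_a = fit_model(table_a, spec)
    full_b = fit_model(table_b, spec)
    start_a = full_a.lmm.theta if full_a.lmm is not None else None
    start_b = full_b.lmm.theta if full_b.lmm is not None else None

    # pre-extract arrays per cluster for fast resample assembly
    def _cluster_rows(table):
        y, X, Z, groups, _ = _prepare(table, spec)
        order = {}
        for i, gid in enumerate(groups):
            order.setdefault(gid, []).append(i)
        return y, X, Z, {g: np.array(ix) for g, ix in order.items()}

    y_a, X_a, Z_a, rows_a = _cluster_rows(table_a)
    y_b, X_b, Z_b, rows_b = _cluster_rows(table_b)
    if set(rows_a) != set(rows_b):
        raise ValueError("the two tables must cover the same clients")

    if unit == "client":
        clusters = sorted(rows_a)
        members = {c: [c] for c in clusters}
    else:
        tmap = table_a.groupby("therapist_id")["client_id"].unique()
        clusters = sorted(tmap.index)
        members = {t: sorted(tmap[t]) for t in clusters}
    N = len(clusters)

    need_decomp = any(p in ("within", "between") for p in spec.predictors)
    within_j = (1 + spec.predictors.index("within")) if "within" in \
        spec.predictors else None
    between_j = (1 + spec.predictors.index("between")) if "between" in \
        spec.predictors else None

    def _assemble(y, X, Z, rows, chosen):
        # relabel sequentially: one fresh group code per (cluster copy,
        # client), so duplicate clusters enter the refit as distinct
        idx_list, gparts = [], []
        code = 0
        for cl in chosen:
            for cid in members[cl]:
                ix = rows[cid]
                idx_list.append(ix)
                gparts.append(np.full(len(ix), code, dtype=int))
                code += 1
        idx = np.concatenate(idx_list)
        groups = np.concatenate(gparts)
        return y[idx], X[idx].copy(), Z[idx].copy(), groups, idx

    # store raw score for decomposition re-computation
    raw_score_a = table_a["score"].to_numpy(dtype=float) if need_decomp else None
    raw_score_b = table_b["score"].to_numpy(dtype=float) if need_decomp else None

    def _redecompose(Xr, raw, idx, groups, Zr):
        vals = raw[idx]
        counts = np.bincount(groups)
        means = np.bincount(groups, weights=vals) / counts
        grand = means.mean()
        Xr[:, within_j] = vals - means[groups]
        Xr[:, between_j] = means[groups] - grand
        Zr[:, 1] = Xr[:, within_j]
        return Xr, Zr

    deltas = []
    n_failed = 0
    n_fallback_box = [0]
    for _ in range(B):
        chosen = [clusters[i] for i in rng.integers(0, N, size=N)]
        try:
            ya, Xa, Za, ga, idxa = _assemble(y_a, X_a, Z_a, rows_a, chosen)
            yb, Xb, Zb, gb, idxb = _assemble(y_b, X_b, Z_b, rows_b, chosen)
            if need_decomp:
                Xa, Za = _redecompose(Xa, raw_score_a, idxa, ga, Za)
                Xb, Zb = _redecompose(Xb, raw_score_b, idxb, gb, Zb)
            r2a = _r2_for_focal(ya, Xa, Za, ga, focal_idx, start_a,
                                n_fallback_box)
            r2b = _r2_for_focal(yb, Xb, Zb, gb, focal_idx, start_b,
                                n_fallback_box)
        except Exception:  # noqa: BLE001 - resample-level isolation
            n_failed += 1
            continue
        deltas.append(r2a - r2b)
    deltas = np.asarray(deltas)
    if len(deltas) == 0:
        raise RuntimeError("every bootstrap fit failed")
    ci_low, ci_high = np.percentile(deltas, [2.5, 97.5])
    unreliable = n_failed > 0.1 * B
    if unreliable:
        logger.warning("bootstrap comparison unreliable: %d/%d failed fits",
                       n_failed, B)
    if n_fallback_box[0]:
        logger.info("%d bootstrap fit(s) fell back to intercept-only random "
                    "structure", n_fallback_box[0])
    return BootstrapComparison(
        B=B, unit=unit, focal=focal, deltas=deltas,
        ci_low=float(ci_low), ci_high=float(ci_high),
        significant=bool(ci_low > 0 or ci_high < 0),
        n_failed_fits=n_failed, n_fallback=n_fallback_box[0],
        r2_full_a=full_a.effects[focal].r2_beta,
        r2_full_b=full_b.effects[focal].r2_beta,
        unreliable=unreliable,
    )
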