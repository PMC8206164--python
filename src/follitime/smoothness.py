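"""Trajectory-quality statistics and the combined smoothness/divergence gene filter.

Three per-gene statistics over the 7-point coded time grid x = (−3…3):

* **PVE** — fraction of a trajectory's variance captured by a least-squares
  cubic polynomial ``y = a·x³ + b·x² + c·x + d``; computed for the 5X and
  10X series separately and averaged.  Cubic (not higher) order is fixed:
  adding terms would let rugged trajectories score well.
* **Cohesion C** — from the 7×7 matrix of absolute pairwise differences,
  ``C = SSD_A / SSD_{N−A}`` with SSD_A the sum of squares of the 6 adjacent
  Δ values and SSD_{N−A} the sum over the 15 non-adjacent pairs.  Smooth
  trajectories have small C; spiky ones approach or exceed 1.
* **F statistics** — a two-factor (condition × time) ANOVA on the 2×7
  table.  The unreplicated layout leaves no within-cell error df, so the
  error mean square is built from the pooled cubic-fit residuals of the two
  series (3 df each, 6 total); at the table level those per-gene error mean
  squares are additionally shrunk across genes by the empirical-Bayes
  squeeze (mode ``"moderated"``, the default for :func:`compute_scores`),
  which stops a gene's F denominator from collapsing just because its own
  noise happened to look smooth.

The default filter retains genes with PVE > 0.6, C < 0.35 and F_int > 2;
genes with undefined statistics (constant trajectories) always fail.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .matrix import CODED_X
from .trajectory import TrajectoryMatrix

__all__ = [
    "CubicFit",
    "FilterThresholds",
    "cubic_pve",
    "mean_pve",
    "cohesion",
    "anova_ss",
    "twofactor_anova",
    "compute_scores",
    "apply_filter",
]

_EPS = 1e-12

# fixed design: columns x^3, x^2, x, 1 on the coded grid
_DESIGN = np.vander(CODED_X, 4)
_PINV = np.linalg.pinv(_DESIGN)
_HAT = _DESIGN @ _PINV

# adjacent vs non-adjacent index pairs among the 7 time points
_PAIRS = [(i, j) for i in range(7) for j in range(i + 1, 7)]
_ADJACENT = [(i, j) for (i, j) in _PAIRS if j - i == 1]
_NONADJACENT = [(i, j) for (i, j) in _PAIRS if j - i > 1]
assert len(_ADJACENT) == 6 and len(_NONADJACENT) == 15


@dataclass
class CubicFit:
    """Least-squares cubic fit of a 7-point trajectory on coded time."""

    a: float
    b: float
    c: float
    d: float
    rss: float
    v_c: float
    v_t: float

    def predict(self, x: np.ndarray) -> np.ndarray:
        return np.polyval([self.a, self.b, self.c, self.d], np.asarray(x, dtype=float))


@dataclass(frozen=True)
class FilterThresholds:
    """Retention thresholds: PVE strictly above, C strictly below, F strictly above."""

    thr_pve: float = 0.6
    thr_c: float = 0.35
    thr_f: float = 2.0


def _cubic_many(Y: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized cubic fit of each row of ``Y`` (n_genes x 7).

    Returns (coef, rss, v_c, v_t) with sums of squares about the mean;
    PVE = v_c / v_t is invariant to the n vs n−1 normalization, which
    cancels in the ratio.
    """
    Y = np.asarray(Y, dtype=float)
    coef = (_PINV @ Y.T).T                      # n_genes x 4
    fitted = (_HAT @ Y.T).T
    rss = ((Y - fitted) ** 2).sum(axis=1)
    centered = Y - Y.mean(axis=1, keepdims=True)
    v_t = (centered**2).sum(axis=1)
    v_c = v_t - rss
    return coef, rss, v_c, v_t


def cubic_pve(y: np.ndarray) -> tuple[CubicFit, float]:
    """Fit a cubic to one 7-point trajectory and return (fit, PVE).

    PVE = V_C / V_T, clipped to [0, 1] against roundoff.  A constant
    trajectory (V_T = 0) has undefined PVE: NaN is returned and the gene
    fails the filter downstream.
    """
    y = np.asarray(y, dtype=float)
    if y.shape != (7,):
        raise ValueError("trajectory must have exactly 7 points")
    if not np.isfinite(y).all():
        raise ValueError("trajectory must be finite")
    coef, rss, v_c, v_t = _cubic_many(y[None, :])
    fit = CubicFit(*coef[0], rss=float(rss[0]), v_c=float(v_c[0]), v_t=float(v_t[0]))
    if v_t[0] <= _EPS:
        return fit, float("nan")
    return fit, float(np.clip(v_c[0] / v_t[0], 0.0, 1.0))


def mean_pve(y5x: np.ndarray, y10x: np.ndarray) -> float:
    """Average of the per-condition PVEs; NaN if either is undefined."""
    _, p5 = cubic_pve(y5x)
    _, p10 = cubic_pve(y10x)
    return (p5 + p10) / 2.0


def cohesion(y: np.ndarray) -> tuple[float, float, float]:
    """Cohesion C = SSD_A / SSD_{N−A} for one 7-point trajectory.

    Returns ``(C, SSD_A, SSD_{N−A})``; C is NaN when the non-adjacent sum
    is zero (constant trajectory).
    """
    y = np.asarray(y, dtype=float)
    if y.shape != (7,):
        raise ValueError("trajectory must have exactly 7 points")
    delta = np.abs(y[:, None] - y[None, :])
    ssd_a = float(sum(delta[i, j] ** 2 for i, j in _ADJACENT))
    ssd_na = float(sum(delta[i, j] ** 2 for i, j in _NONADJACENT))
    c = ssd_a / ssd_na if ssd_na > _EPS else float("nan")
    return c, ssd_a, ssd_na


def _cohesion_many(Y: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    Y = np.asarray(Y, dtype=float)
    d2 = (Y[:, :, None] - Y[:, None, :]) ** 2
    ai, aj = zip(*_ADJACENT)
    ni, nj = zip(*_NONADJACENT)
    ssd_a = d2[:, ai, aj].sum(axis=1)
    ssd_na = d2[:, ni, nj].sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        c = np.where(ssd_na > _EPS, ssd_a / ssd_na, np.nan)
    return c, ssd_a, ssd_na


def anova_ss(y5x: np.ndarray, y10x: np.ndarray) -> dict[str, float]:
    """Sum-of-squares decomposition of the 2x7 table.

    Returns ss_group, ss_time, ss_int and ss_total; the first three add up
    to the last exactly (balanced two-way layout).
    """
    Y = np.stack([np.asarray(y5x, float), np.asarray(y10x, float)])
    if Y.shape != (2, 7):
        raise ValueError("need two 7-point series")
    grand = Y.mean()
    row = Y.mean(axis=1, keepdims=True)
    col = Y.mean(axis=0, keepdims=True)
    return {
        "ss_group": float(7.0 * ((row - grand) ** 2).sum()),
        "ss_time": float(2.0 * ((col - grand) ** 2).sum()),
        "ss_int": float(((Y - row - col + grand) ** 2).sum()),
        "ss_total": float(((Y - grand) ** 2).sum()),
    }


def twofactor_anova(
    y5x: np.ndarray, y10x: np.ndarray, error: str = "cubic_residual"
) -> tuple[float, float, float]:
    """F statistics for the unreplicated 2 (condition) × 7 (time) layout.

    Sums of squares decompose exactly: SS_total = SS_group + SS_time +
    SS_int.  ``error="cubic_residual"`` (default) uses the pooled cubic-fit
    residuals of the two series as the error mean square (6 df);
    ``error="interaction"`` tests group and time against the interaction
    mean square and the group × cubic-polynomial terms against the residual
    of the polynomial interaction model.  Returns (F_group, F_time, F_int);
    NaN when the error mean square is zero.
    """
    f = _anova_many(np.asarray(y5x, float)[None, :], np.asarray(y10x, float)[None, :], error=error)
    return tuple(float(v[0]) for v in f)


def _anova_many(
    Y5: np.ndarray, Y10: np.ndarray, error: str = "cubic_residual"
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-gene F statistics for the 2x7 layout.

    Error modes: ``"cubic_residual"`` divides by the gene's own pooled
    cubic-fit residual mean square (6 df); ``"moderated"`` additionally
    shrinks those error mean squares across genes by the empirical-Bayes
    squeeze, so a gene's F denominator is not tied to how smooth its own
    noise happened to look; ``"interaction"`` uses the interaction mean
    square itself (then F_int is identically 1 and only the main-effect F
    values are meaningful).
    """
    if Y5.shape != Y10.shape or Y5.shape[1] != 7:
        raise ValueError("need matching n_genes x 7 arrays for both conditions")
    Y = np.stack([Y5, Y10], axis=1)                 # n x 2 x 7
    grand = Y.mean(axis=(1, 2), keepdims=True)
    row = Y.mean(axis=2, keepdims=True)             # condition means
    col = Y.mean(axis=1, keepdims=True)             # time means
    ss_group = 7.0 * ((row - grand) ** 2).sum(axis=(1, 2))
    ss_time = 2.0 * ((col - grand) ** 2).sum(axis=(1, 2))
    resid = Y - row - col + grand
    ss_int = (resid**2).sum(axis=(1, 2))
    ms_group = ss_group / 1.0
    ms_time = ss_time / 6.0
    ms_int = ss_int / 6.0

    if error in ("cubic_residual", "moderated"):
        _, rss5, _, _ = _cubic_many(Y5)
        _, rss10, _, _ = _cubic_many(Y10)
        ms_err = (rss5 + rss10) / 6.0
        if error == "moderated":
            from .diffexpr import ebayes_moderate

            pos = ms_err > _EPS
            if pos.sum() >= 2:
                ms_err = ms_err.copy()
                ms_err[pos] = ebayes_moderate(ms_err[pos], df=6.0).posterior_var
    elif error == "interaction":
        ms_err = ms_int
    else:
        raise ValueError(f"unknown error mode {error!r}")

    def _ratio(ms_num: np.ndarray) -> np.ndarray:
        # effect MS at roundoff level counts as exactly zero (additive tables
        # give F_int = 0, not 1e-32); zero error MS makes any real effect
        # infinitely significant, while 0/0 stays undefined (sentinel)
        ms_num = np.where(ms_num > _EPS, ms_num, 0.0)
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(
                ms_err > _EPS,
                ms_num / np.where(ms_err > _EPS, ms_err, 1.0),
                np.where(ms_num > 0.0, np.inf, np.nan),
            )

    return _ratio(ms_group), _ratio(ms_time), _ratio(ms_int)


def compute_scores(t: TrajectoryMatrix, anova_error: str = "moderated") -> pd.DataFrame:
    """Per-gene smoothness/divergence score table for a whole trajectory set.

    Columns: pve_5x, pve_10x, pve_mean, c_5x, c_10x, c_mean (per-condition
    cohesion averaged, mirroring the PVE averaging), ssd_a/ssd_na per
    condition, F_group, F_time, F_int.  NaN marks undefined statistics.
    """
    Y5 = t.condition("5X").to_numpy(dtype=float)
    Y10 = t.condition("10X").to_numpy(dtype=float)
    _, _, vc5, vt5 = _cubic_many(Y5)
    _, _, vc10, vt10 = _cubic_many(Y10)
    with np.errstate(divide="ignore", invalid="ignore"):
        pve5 = np.where(vt5 > _EPS, np.clip(vc5 / vt5, 0.0, 1.0), np.nan)
        pve10 = np.where(vt10 > _EPS, np.clip(vc10 / vt10, 0.0, 1.0), np.nan)
    c5, ssa5, ssna5 = _cohesion_many(Y5)
    c10, ssa10, ssna10 = _cohesion_many(Y10)
    f_group, f_time, f_int = _anova_many(Y5, Y10, error=anova_error)
    return pd.DataFrame(
        {
            "pve_5x": pve5,
            "pve_10x": pve10,
            "pve_mean": (pve5 + pve10) / 2.0,
            "c_5x": c5,
            "c_10x": c10,
            "c_mean": (c5 + c10) / 2.0,
            "ssd_a_5x": ssa5,
            "ssd_na_5x": ssna5,
            "ssd_a_10x": ssa10,
            "ssd_na_10x": ssna10,
            "F_group": f_group,
            "F_time": f_time,
            "F_int": f_int,
        },
        index=t.gene_ids,
    )


def apply_filter(
    scores: pd.DataFrame,
    thr: FilterThresholds = FilterThresholds(),
    f_mode: str = "interaction",
) -> tuple[pd.Index, dict[str, int]]:
    """Apply the combined PVE/C/F filter; genes with NaN statistics fail.

    ``f_mode="interaction"`` (default) requires F_int > thr_f, reflecting
    selection focused on condition × time divergence; ``"any"`` accepts
    max(F_group, F_time, F_int) > thr_f instead.  Returns the retained gene
    index and per-criterion pass counts.
    """
    pass_pve = scores["pve_mean"] > thr.thr_pve
    pass_c = scores["c_mean"] < thr.thr_c
    if f_mode == "interaction":
        fstat = scores["F_int"]
    elif f_mode == "any":
        fstat = scores[["F_group", "F_time", "F_int"]].max(axis=1)
    else:
        raise ValueError(f"unknown f_mode {f_mode!r}")
    pass_f = fstat > thr.thr_f
    keep = pass_pve.fillna(False) & pass_c.fillna(False) & pass_f.fillna(False)
    counts = {
        "n_input": int(len(scores)),
        "n_pass_pve": int(pass_pve.fillna(False).sum()),
        "n_pass_c": int(pass_c.fillna(False).sum()),
        "n_pass_f": int(pass_f.fillna(False).sum()),
        "n_retained": int(keep.sum()),
    }
    return scores.index[keep], counts
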