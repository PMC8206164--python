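"""Two-group differential expression with empirical-Bayes moderated t-statistics.

Per gene, a two-group linear model gives a log-fold change and a pooled
residual variance; variances are then shrunk toward a common prior fitted by
method of moments on the log variances (the scaled-F model of Smyth-style
empirical Bayes), and moderated t-statistics are referred to a t
distribution with augmented degrees of freedom.  A logFC ranking and a
generic GMT hypergeometric enrichment round out the module.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import digamma, polygamma
from statsmodels.stats.multitest import multipletests

from .matrix import ExpressionMatrix

__all__ = [
    "TwoGroupFit",
    "ModeratedModel",
    "fit_two_group",
    "ebayes_moderate",
    "moderated_t",
    "run_de",
    "rank_by_logfc",
    "read_gmt",
    "write_gmt",
    "hypergeometric_enrichment",
]


@dataclass
class TwoGroupFit:
    """Per-gene logFC (mean B − mean A), pooled residual variance and df."""

    gene_ids: pd.Index
    logfc: np.ndarray
    s2: np.ndarray
    df: float
    n_a: int
    n_b: int


@dataclass
class ModeratedModel:
    """Fitted variance prior: d0 prior df, s0_sq prior variance, posterior variances."""

    d0: float
    s0_sq: float
    posterior_var: np.ndarray


def fit_two_group(m: ExpressionMatrix, group_a: list[str], group_b: list[str]) -> TwoGroupFit:
    """Fit the per-gene two-group model on the log scale.

    ``logfc = mean(B) − mean(A)``; ``s2`` is the pooled within-group
    variance with ``df = (nA−1) + (nB−1)``.  A group with a single sample
    contributes a valid mean but no variance information.
    """
    a, b = list(group_a), list(group_b)
    if set(a) & set(b):
        raise ValueError("groups overlap")
    unknown = (set(a) | set(b)) - set(m.sample_ids)
    if unknown:
        raise ValueError(f"unknown sample IDs: {sorted(unknown)}")
    n_a, n_b = len(a), len(b)
    if n_a < 1 or n_b < 1 or n_a + n_b < 3:
        raise ValueError("need nA >= 1, nB >= 1 and nA + nB >= 3")
    A = m.values[a].to_numpy(dtype=float)
    B = m.values[b].to_numpy(dtype=float)
    logfc = B.mean(axis=1) - A.mean(axis=1)
    ss = ((A - A.mean(axis=1, keepdims=True)) ** 2).sum(axis=1) + (
        (B - B.mean(axis=1, keepdims=True)) ** 2
    ).sum(axis=1)
    df = (n_a - 1) + (n_b - 1)
    s2 = ss / df
    return TwoGroupFit(m.gene_ids, logfc, s2, float(df), n_a, n_b)


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x by Newton's method (monotone, well-conditioned)."""
    if x <= 0:
        return np.inf
    y = 0.5 + 1.0 / x
    for _ in range(100):
        tri = float(polygamma(1, y))
        dif = tri * (1.0 - tri / x) / float(polygamma(2, y))
        y += dif
        if abs(dif) < 1e-10 * y:
            break
    return y


def ebayes_moderate(s2: np.ndarray, df: float, d0_override: float | None = None) -> ModeratedModel:
    """Fit the scaled-F prior to sample variances and shrink them.

    Hyperparameters (d0, s0²) are estimated by method of moments on
    log variances: the excess spread of ``log s2`` beyond what the
    chi-square sampling distribution alone implies determines d0; when no
    excess remains, d0 is infinite and every posterior variance equals s0².
    Posterior variance per gene is ``(d0·s0² + df·s2) / (d0 + df)``.
    """
    s2 = np.asarray(s2, dtype=float)
    if s2.size < 2:
        raise ValueError("need at least 2 genes")
    if np.any(s2 < 0):
        raise ValueError("variances must be nonnegative")
    if np.all(s2 == 0):
        raise ValueError("all variances are zero: degenerate input")
    if df < 1:
        raise ValueError("df must be >= 1")
    # zero variances cannot enter the log-moment fit; floor them well below
    # the smallest positive variance (they stay shrunken toward s0_sq anyway)
    positive_min = s2[s2 > 0].min()
    s2_safe = np.where(s2 == 0, positive_min * 1e-8, s2)

    if d0_override is not None:
        d0 = float(d0_override)
        if d0 < 0:
            raise ValueError("d0 must be >= 0")
        if np.isinf(d0):
            s0_sq = float(np.exp(np.mean(np.log(s2_safe) - digamma(df / 2) + np.log(df / 2))))
        elif d0 == 0.0:
            # no shrinkage: posterior variances are the raw sample variances
            s0_sq = float(np.exp(np.mean(np.log(s2_safe))))
        else:
            z = np.log(s2_safe)
            e = z - digamma(df / 2) + np.log(df / 2)
            s0_sq = float(np.exp(np.mean(e) + digamma(d0 / 2) - np.log(d0 / 2)))
    else:
        z = np.log(s2_safe)
        e = z - digamma(df / 2) + np.log(df / 2)
        emean = float(np.mean(e))
        evar = float(np.var(e, ddof=1)) - float(polygamma(1, df / 2))
        if float(np.ptp(z)) == 0.0:
            # literally no spread: the sampling model is degenerate and the
            # only consistent prior is the common variance itself
            d0 = np.inf
            s0_sq = float(np.exp(z[0]))
        elif evar > 0:
            d0 = 2.0 * _trigamma_inverse(evar)
            s0_sq = float(np.exp(emean + digamma(d0 / 2) - np.log(d0 / 2)))
        else:
            d0 = np.inf
            s0_sq = float(np.exp(emean))
    if np.isinf(d0):
        post = np.full_like(s2, s0_sq)
    else:
        post = (d0 * s0_sq + df * s2) / (d0 + df)
    return ModeratedModel(d0=d0, s0_sq=s0_sq, posterior_var=post)


def moderated_t(fit: TwoGroupFit, model: ModeratedModel) -> pd.DataFrame:
    """Moderated t and two-sided p per gene.

    ``t = logFC / sqrt(post_var · (1/nA + 1/nB))`` referred to a t
    distribution with ``df + d0`` degrees of freedom (standard normal when
    d0 is infinite).  Ordinary t (from the raw pooled variance) is reported
    alongside for diagnostics.
    """
    if fit.gene_ids.size != model.posterior_var.size:
        raise ValueError("fit and model cover different gene sets")
    if np.any(model.posterior_var <= 0):
        raise ValueError("nonpositive posterior variance")
    scale = 1.0 / fit.n_a + 1.0 / fit.n_b
    se = np.sqrt(model.posterior_var * scale)
    t_mod = fit.logfc / se
    with np.errstate(divide="ignore", invalid="ignore"):
        t_ord = np.where(fit.s2 > 0, fit.logfc / np.sqrt(fit.s2 * scale), np.nan)
    df_total = fit.df + model.d0
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t_mod))
    else:
        p = 2.0 * stats.t.sf(np.abs(t_mod), df_total)
    out = pd.DataFrame(
        {
            "logFC": fit.logfc,
            "s2": fit.s2,
            "df": fit.df,
            "t_ordinary": t_ord,
            "t_moderated": t_mod,
            "p_value": p,
        },
        index=fit.gene_ids,
    )
    out["adj_p"] = multipletests(out["p_value"].to_numpy(), method="fdr_bh")[1]
    return out


def run_de(
    m: ExpressionMatrix,
    group_a: list[str],
    group_b: list[str],
    d0_override: float | None = None,
) -> pd.DataFrame:
    """Convenience: fit, moderate, test, and rank in one call."""
    fit = fit_two_group(m, group_a, group_b)
    model = ebayes_moderate(fit.s2, fit.df, d0_override=d0_override)
    table = moderated_t(fit, model)
    table.attrs["d0"] = model.d0
    table.attrs["s0_sq"] = model.s0_sq
    order = rank_by_logfc(table)
    table["rank_by_logFC"] = pd.Series(
        np.arange(1, len(order) + 1), index=order
    )
    return table


def rank_by_logfc(results: pd.DataFrame) -> pd.Index:
    """Genes ordered by descending logFC; ties by |moderated t| desc, then ID."""
    if results.empty:
        raise ValueError("empty DE table")
    df = results.assign(_abs_t=results["t_moderated"].abs(), _gid=results.index)
    df = df.sort_values(
        by=["logFC", "_abs_t", "_gid"], ascending=[False, False, True], kind="stable"
    )
    return df.index


# ----------------------------------------------------------------------
# GMT gene sets and hypergeometric enrichment


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Read a GMT file: one set per line (name, description, members...)."""
    sets: dict[str, set[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"malformed GMT line: {line[:60]!r}")
        sets[parts[0]] = set(parts[2:])
    return sets


def write_gmt(sets: dict[str, set[str]], path: str | Path, description: str = "na") -> None:
    lines = [
        "\t".join([name, description, *sorted(members)]) for name, members in sets.items()
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def hypergeometric_enrichment(
    hits: set[str],
    universe: set[str],
    collection: dict[str, set[str]],
    max_set_size: int = 500,
) -> pd.DataFrame:
    """Upper-tail hypergeometric over-representation test per gene set.

    Sets are intersected with the universe first; sets larger than
    ``max_set_size`` (after intersection) are excluded.  Benjamini–Hochberg
    adjusted p-values are reported.
    """
    if not universe:
        raise ValueError("empty universe")
    if not hits <= universe:
        raise ValueError("hits must be a subset of the universe")
    M, N = len(universe), len(hits)
    rows = []
    for name, members in collection.items():
        in_universe = members & universe
        n = len(in_universe)
        if n == 0 or n > max_set_size:
            continue
        overlap = len(in_universe & hits)
        p = float(stats.hypergeom.sf(overlap - 1, M, n, N))
        rows.append({"set": name, "set_size": n, "overlap": overlap, "p_value": min(p, 1.0)})
    out = pd.DataFrame(rows, columns=["set", "set_size", "overlap", "p_value"])
    if len(out):
        out["adj_p"] = multipletests(out["p_value"].to_numpy(), method="fdr_bh")[1]
        out = out.sort_values("p_value", kind="stable").reset_index(drop=True)
    else:
        out["adj_p"] = []
    return out
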