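"""Cross-dataset developmental-transition concordance via t-score agreement.

The in vitro time course (conditions averaged, days grouped into Early /
Middle / Late culture) and a stage-labelled comparator dataset (Primary /
Multilayer Secondary / Antral follicles) are first harmonized — gene sets
intersected and all samples quantile-normalized together — then each
dataset is separately subjected to moderated-t differential expression for
each developmental transition (Early→Middle, Middle→Late, Early→Late).
Per-transition agreement is summarized by the Pearson correlation of the
paired per-gene t-scores, tested against r = 0 through Fisher's z
transformation, plus sign-agreement and -disagreement gene lists.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import diffexpr, preprocess
from .matrix import CONDITIONS, DAYS, ExpressionMatrix

__all__ = [
    "StageMapping",
    "TransitionConcordance",
    "ConcordanceResult",
    "harmonize",
    "collapse_conditions",
    "transition_tscores",
    "tscore_concordance",
    "run_concordance",
]

TRANSITIONS: tuple[tuple[str, str], ...] = (
    ("Early", "Middle"),
    ("Middle", "Late"),
    ("Early", "Late"),
)


@dataclass(frozen=True)
class StageMapping:
    """Which days / comparator stages make up each developmental stage.

    The in vitro Early group is day 2 alone (day 0 was never profiled), so
    its variance information comes entirely from pooling and shrinkage.
    """

    invitro: dict[str, tuple[int, ...]] = field(
        default_factory=lambda: {"Early": (2,), "Middle": (4, 6, 7, 8), "Late": (10, 12)}
    )
    comparator: dict[str, str] = field(
        default_factory=lambda: {
            "Early": "Primary",
            "Middle": "MultilayerSecondary",
            "Late": "Antral",
        }
    )

    def __post_init__(self) -> None:
        days = [d for grp in self.invitro.values() for d in grp]
        if len(days) != len(set(days)) or any(len(g) == 0 for g in self.invitro.values()):
            raise ValueError("in vitro stage day groups must be nonempty and disjoint")
        stages = list(self.comparator.values())
        if len(stages) != len(set(stages)):
            raise ValueError("comparator stages must be distinct")


@dataclass
class TransitionConcordance:
    transition: str
    t_invitro: pd.Series
    t_comparator: pd.Series
    pearson_r: float
    fisher_z: float
    p_value: float
    n_genes: int
    agreement: list[str]
    disagreement: list[str]
    zero_score: list[str]


@dataclass
class ConcordanceResult:
    transitions: dict[str, TransitionConcordance]
    n_shared_genes: int

    def summary(self) -> dict:
        return {
            "n_shared_genes": self.n_shared_genes,
            "transitions": {
                name: {
                    "pearson_r": tc.pearson_r,
                    "fisher_z": tc.fisher_z,
                    "p_value": tc.p_value,
                    "n_genes": tc.n_genes,
                    "n_agreement": len(tc.agreement),
                    "n_disagreement": len(tc.disagreement),
                    "n_zero_score": len(tc.zero_score),
                }
                for name, tc in self.transitions.items()
            },
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.summary(), indent=1))


def harmonize(
    invitro: ExpressionMatrix, comparator: ExpressionMatrix
) -> tuple[ExpressionMatrix, ExpressionMatrix]:
    """Intersect gene sets and jointly quantile-normalize both datasets."""
    shared = invitro.gene_ids.intersection(comparator.gene_ids)
    if len(shared) == 0:
        raise ValueError("no genes shared between the datasets")
    a = invitro.subset_genes(shared)
    b = comparator.subset_genes(shared)
    a, b = preprocess.quantile_normalize([a, b])
    return a, b


def collapse_conditions(invitro: ExpressionMatrix) -> ExpressionMatrix:
    """Average the 5X and 10X columns into one column per day."""
    meta = invitro.sample_meta
    cols = {}
    for d in DAYS:
        day_cols = []
        for c in CONDITIONS:
            match = meta.index[(meta["condition"] == c) & (meta["day"] == d)]
            if len(match) == 0:
                raise ValueError(f"missing sample for condition {c}, day {d}")
            day_cols.extend(match.tolist())
        cols[f"d{d:02d}"] = invitro.values[day_cols].mean(axis=1)
    values = pd.DataFrame(cols, index=invitro.gene_ids)
    meta_out = pd.DataFrame(
        {"day": list(DAYS)}, index=pd.Index(values.columns, name="sample_id")
    )
    return ExpressionMatrix(values, meta_out)


def transition_tscores(
    dataset: ExpressionMatrix, from_group: list[str], to_group: list[str]
) -> pd.Series:
    """Per-gene moderated t for to_group vs from_group (positive = up over time)."""
    de = diffexpr.run_de(dataset, group_a=list(from_group), group_b=list(to_group))
    return de["t_moderated"]


def tscore_concordance(t1: pd.Series, t2: pd.Series, name: str = "") -> TransitionConcordance:
    """Pearson r of two paired t-score vectors, with a Fisher-transform test.

    z = atanh(r); two-sided p from z·sqrt(n−3) against the standard normal.
    Genes with the same t sign in both datasets form the agreement list,
    opposite signs the disagreement list; zero scores are reported apart.
    """
    if not t1.index.equals(t2.index):
        raise ValueError("t-score vectors must cover the same genes in the same order")
    n = len(t1)
    if n < 4:
        raise ValueError("need at least 4 genes")
    v1, v2 = t1.to_numpy(dtype=float), t2.to_numpy(dtype=float)
    if np.std(v1) == 0 or np.std(v2) == 0:
        raise ValueError("zero variance in a t-score vector")
    r = float(np.corrcoef(v1, v2)[0, 1])
    if abs(r) >= 1.0:
        z = float(np.sign(r) * np.inf)
        p = 0.0
    else:
        z = float(np.arctanh(r))
        p = float(2.0 * stats.norm.sf(abs(z) * np.sqrt(n - 3)))
    s1, s2 = np.sign(v1), np.sign(v2)
    agreement = t1.index[(s1 == s2) & (s1 != 0)].tolist()
    disagreement = t1.index[(s1 == -s2) & (s1 != 0) & (s2 != 0)].tolist()
    zero = t1.index[(s1 == 0) | (s2 == 0)].tolist()
    return TransitionConcordance(
        transition=name,
        t_invitro=t1,
        t_comparator=t2,
        pearson_r=r,
        fisher_z=z,
        p_value=p,
        n_genes=n,
        agreement=agreement,
        disagreement=disagreement,
        zero_score=zero,
    )


def run_concordance(
    invitro: ExpressionMatrix,
    comparator: ExpressionMatrix,
    mapping: StageMapping | None = None,
) -> ConcordanceResult:
    """Full concordance analysis: harmonize, collapse, per-transition t, compare."""
    mapping = mapping or StageMapping()
    a, b = harmonize(invitro, comparator)
    a_days = collapse_conditions(a)

    invitro_groups = {
        stage: a_days.sample_meta.index[a_days.sample_meta["day"].isin(days)].tolist()
        for stage, days in mapping.invitro.items()
    }
    comp_meta = b.sample_meta
    comp_groups = {
        stage: comp_meta.index[comp_meta["stage"] == comp_stage].tolist()
        for stage, comp_stage in mapping.comparator.items()
    }
    for stage, grp in {**invitro_groups}.items():
        if not grp:
            raise ValueError(f"in vitro stage {stage!r} has no samples")
    for stage, grp in comp_groups.items():
        if not grp:
            raise ValueError(f"comparator stage {stage!r} has no samples")

    transitions: dict[str, TransitionConcordance] = {}
    for frm, to in TRANSITIONS:
        name = f"{frm}->{to}"
        t_a = transition_tscores(a_days, invitro_groups[frm], invitro_groups[to])
        t_b = transition_tscores(b, comp_groups[frm], comp_groups[to])
        transitions[name] = tscore_concordance(t_a, t_b, name=name)
    return ConcordanceResult(transitions=transitions, n_shared_genes=a.n_genes)
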