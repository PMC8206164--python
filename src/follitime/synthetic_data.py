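"""Synthetic time-course and stage-comparator data with planted structure.

Every downstream stage of the pipeline is exercised on data generated here,
so each gene carries a ground-truth label: which trajectory archetype it was
drawn from, whether the archetype diverges between the 5X and 10X culture
conditions, and its noiseless per-condition base trajectory.

Archetypes mirror the temporal patterns the analysis is designed to find:
early activators that decay through culture, transient mid-culture peaks,
delayed activation around day 4 with a late decline, activation only in the
final days, flat background, a smooth oscillation, and three
condition-divergent patterns (U-shape vs monotone rise, inverted U vs fall,
fall vs rise).  Base curves are fixed closed forms (logistic, Gaussian bump,
quadratic or linear in coded time); shapes are documented in
``docs/methods.md``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .matrix import CODED_X, CONDITIONS, DAYS, ExpressionMatrix, stage_meta, timecourse_meta

__all__ = [
    "ARCHETYPE_NAMES",
    "DIVERGENT_ARCHETYPES",
    "ArchetypeSpec",
    "SyntheticTruth",
    "archetype_curve",
    "generate_timecourse",
    "generate_invivo_counterpart",
]

#: Stage labels of the freshly-isolated comparator dataset, in developmental order.
COMPARATOR_STAGES: tuple[str, str, str] = ("Primary", "MultilayerSecondary", "Antral")

DIVERGENT_ARCHETYPES = frozenset(
    {"u_shape_5x_vs_rise_10x", "inverse_u_5x_vs_fall_10x", "fall_5x_vs_rise_10x"}
)


def _sig(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-z))


def _unit_curves(x: np.ndarray) -> dict[str, dict[str, np.ndarray]]:
    """Unit-amplitude base curves per archetype and condition on grid ``x``."""
    rise = (x + 3.0) / 6.0          # monotone 0 -> 1
    fall = (3.0 - x) / 6.0          # monotone 1 -> 0
    shared = {
        "early_activator": 1.0 - _sig(1.4 * (x + 1.0)),
        "transient_mid": np.exp(-((x / 1.5) ** 2)),
        "delayed_activator": _sig(1.8 * (x + 2.0)) - 0.5 * _sig(3.0 * (x - 2.2)),
        "late_activator": _sig(1.8 * (x - 1.8)),
        "flat": np.zeros_like(x),
        "oscillatory": 0.6 * np.cos(np.pi * x / 2.0),
    }
    curves = {name: {"5X": c, "10X": c} for name, c in shared.items()}
    curves["u_shape_5x_vs_rise_10x"] = {"5X": (x / 3.0) ** 2, "10X": rise}
    curves["inverse_u_5x_vs_fall_10x"] = {"5X": 1.0 - (x / 3.0) ** 2, "10X": fall}
    curves["fall_5x_vs_rise_10x"] = {"5X": fall, "10X": rise}
    return curves


ARCHETYPE_NAMES: tuple[str, ...] = tuple(_unit_curves(CODED_X).keys())


def archetype_curve(name: str, condition: str, x: np.ndarray | None = None, amplitude: float = 1.0) -> np.ndarray:
    """Deterministic noiseless base trajectory for one archetype and condition.

    Parameters
    ----------
    name
        One of :data:`ARCHETYPE_NAMES`.
    condition
        ``"5X"`` or ``"10X"``.  Non-divergent archetypes return the same
        curve for both conditions.
    x
        Coded time grid; defaults to the canonical 7-point grid (−3…3).
    amplitude
        Multiplies the unit-amplitude shape (log-expression units).
    """
    if x is None:
        x = CODED_X
    x = np.asarray(x, dtype=float)
    curves = _unit_curves(x)
    if name not in curves:
        raise ValueError(f"unknown archetype {name!r}; expected one of {sorted(curves)}")
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}; expected one of {CONDITIONS}")
    return amplitude * curves[name][condition]


@dataclass(frozen=True)
class ArchetypeSpec:
    """How many genes to draw from one archetype, and at what signal/noise."""

    name: str
    n_genes: int
    amplitude: float = 2.0
    noise_sd: float = 0.3

    def __post_init__(self) -> None:
        if self.name not in ARCHETYPE_NAMES:
            raise ValueError(f"unknown archetype {self.name!r}")
        if self.n_genes < 0:
            raise ValueError("n_genes must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not np.isfinite(self.amplitude):
            raise ValueError("amplitude must be finite")

    @property
    def divergent(self) -> bool:
        return self.name in DIVERGENT_ARCHETYPES


@dataclass
class TruthRecord:
    archetype: str
    divergent: bool
    base_5x: np.ndarray
    base_10x: np.ndarray

    @property
    def base_consensus(self) -> np.ndarray:
        return 0.5 * (self.base_5x + self.base_10x)


@dataclass
class SyntheticTruth:
    """Ground-truth ledger: gene ID -> archetype and noiseless trajectories."""

    records: dict[str, TruthRecord] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.records)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.records)

    def genes_of(self, archetype: str) -> list[str]:
        return [g for g, r in self.records.items() if r.archetype == archetype]

    def archetype_labels(self) -> pd.Series:
        return pd.Series({g: r.archetype for g, r in self.records.items()}, name="archetype")

    def to_json(self, path: str | Path) -> None:
        payload = {
            g: {
                "archetype": r.archetype,
                "divergent": r.divergent,
                "base_5x": r.base_5x.tolist(),
                "base_10x": r.base_10x.tolist(),
            }
            for g, r in self.records.items()
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        payload = json.loads(Path(path).read_text())
        return cls(
            {
                g: TruthRecord(
                    d["archetype"], d["divergent"], np.array(d["base_5x"]), np.array(d["base_10x"])
                )
                for g, d in payload.items()
            }
        )


def generate_timecourse(
    specs: list[ArchetypeSpec],
    seed: int,
    baseline: float = 6.0,
    noise_prior_df: float | None = None,
) -> tuple[ExpressionMatrix, SyntheticTruth]:
    """Simulate the 14-sample (2 conditions x 7 days) time course.

    Each gene's value is ``baseline + archetype curve + N(0, noise_sd)``.
    With ``noise_prior_df`` set, per-gene noise variances are drawn from a
    scaled inverse-chi-square prior with that many degrees of freedom and
    scale ``noise_sd**2`` — the variance model empirical-Bayes moderation
    assumes — instead of being homoscedastic.

    Returns the expression matrix (bit-identical for a fixed seed) and the
    ground-truth ledger.
    """
    if not specs:
        raise ValueError("at least one ArchetypeSpec is required")
    if sum(s.n_genes for s in specs) < 1:
        raise ValueError("total gene count must be >= 1")
    rng = np.random.default_rng(seed)
    meta = timecourse_meta()
    counters: dict[str, int] = {}
    gene_ids: list[str] = []
    rows: list[np.ndarray] = []
    truth = SyntheticTruth()
    for spec in specs:
        base = {c: baseline + archetype_curve(spec.name, c, amplitude=spec.amplitude) for c in CONDITIONS}
        signal = np.concatenate([base[c] for c in CONDITIONS])  # matches meta ordering
        for _ in range(spec.n_genes):
            i = counters.get(spec.name, 0)
            counters[spec.name] = i + 1
            gid = f"{spec.name}_{i:04d}"
            if noise_prior_df is not None:
                sd = spec.noise_sd * np.sqrt(noise_prior_df / rng.chisquare(noise_prior_df))
            else:
                sd = spec.noise_sd
            rows.append(signal + rng.normal(0.0, sd, size=signal.size))
            gene_ids.append(gid)
            truth.records[gid] = TruthRecord(
                spec.name, spec.divergent, base["5X"].copy(), base["10X"].copy()
            )
    values = pd.DataFrame(np.vstack(rows), index=pd.Index(gene_ids, name="gene_id"), columns=meta.index)
    return ExpressionMatrix(values, meta), truth


# stage composition of the in vitro course, used to derive transition signs
_STAGE_SLICES = {"Early": slice(0, 1), "Middle": slice(1, 5), "Late": slice(5, 7)}


def invitro_stage_means(truth: SyntheticTruth) -> pd.DataFrame:
    """Noiseless Early/Middle/Late consensus stage means per gene."""
    out = {
        stage: [truth.records[g].base_consensus[sl].mean() for g in truth.records]
        for stage, sl in _STAGE_SLICES.items()
    }
    return pd.DataFrame(out, index=pd.Index(truth.gene_ids, name="gene_id"))


def generate_invivo_counterpart(
    truth: SyntheticTruth,
    shared_sign_fraction: float,
    reps_per_stage: int = 3,
    noise_sd: float = 0.3,
    seed: int = 0,
    baseline: float = 6.0,
) -> ExpressionMatrix:
    """Simulate a 3-stage replicate dataset sharing transition signs with the course.

    For a randomly chosen ``shared_sign_fraction`` of genes, the
    Primary->MultilayerSecondary and MultilayerSecondary->Antral stage-mean
    changes keep the sign (and magnitude) of the corresponding in vitro
    Early->Middle and Middle->Late consensus transitions; for the remaining
    genes each transition's sign is flipped or kept independently at random.
    """
    if not 0.0 <= shared_sign_fraction <= 1.0:
        raise ValueError("shared_sign_fraction must be in [0, 1]")
    if reps_per_stage < 2:
        raise ValueError("reps_per_stage must be >= 2")
    if len(truth) == 0:
        raise ValueError("truth ledger is empty")
    rng = np.random.default_rng(seed)
    genes = truth.gene_ids
    stage_means = invitro_stage_means(truth)
    d1 = (stage_means["Middle"] - stage_means["Early"]).to_numpy()
    d2 = (stage_means["Late"] - stage_means["Middle"]).to_numpy()

    n = len(genes)
    n_shared = int(round(shared_sign_fraction * n))
    shared = np.zeros(n, dtype=bool)
    shared[rng.permutation(n)[:n_shared]] = True
    flip1 = rng.choice([-1.0, 1.0], size=n)
    flip2 = rng.choice([-1.0, 1.0], size=n)
    d1_out = np.where(shared, d1, flip1 * np.abs(d1))
    d2_out = np.where(shared, d2, flip2 * np.abs(d2))

    mu = np.column_stack([np.full(n, baseline), baseline + d1_out, baseline + d1_out + d2_out])
    meta = stage_meta(COMPARATOR_STAGES, reps_per_stage)
    cols = []
    for s_idx in range(3):
        for _ in range(reps_per_stage):
            cols.append(mu[:, s_idx] + rng.normal(0.0, noise_sd, size=n))
    values = pd.DataFrame(
        np.column_stack(cols), index=pd.Index(genes, name="gene_id"), columns=meta.index
    )
    return ExpressionMatrix(values, meta)
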