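"""Expression-matrix container and plain-text I/O.

The pipeline's universal currency is a genes x samples matrix of log-scale
expression values together with a per-sample metadata table.  Two metadata
layouts occur: the in vitro time course carries (condition, day) and the
stage-labelled comparator carries (stage, replicate).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

#: Calendar days of the in vitro time course, in order.
DAYS: tuple[int, ...] = (2, 4, 6, 7, 8, 10, 12)

#: Coded time grid used for all polynomial fits; day 7 sits at x = 0.
CODED_X: np.ndarray = np.arange(-3, 4, dtype=float)

#: The two co-culture conditions (follicles per alginate bead).
CONDITIONS: tuple[str, str] = ("5X", "10X")


@dataclass
class ExpressionMatrix:
    """Genes x samples log-scale expression values plus sample metadata.

    Parameters
    ----------
    values
        DataFrame indexed by gene ID with one column per sample ID.
    sample_meta
        DataFrame indexed by sample ID.  Time-course matrices carry columns
        ``condition`` and ``day``; stage matrices carry ``stage`` and
        ``replicate``.  Every column of ``values`` must appear in the index.
    """

    values: pd.DataFrame
    sample_meta: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene IDs: {dups[:5]}")
        if self.values.columns.has_duplicates:
            raise ValueError("duplicate sample IDs in values")
        if not np.isfinite(self.values.to_numpy()).all():
            raise ValueError("expression values must be finite")
        missing = self.values.columns.difference(self.sample_meta.index)
        if len(missing):
            raise ValueError(f"samples without metadata: {missing.tolist()}")
        # keep metadata aligned to the value columns
        self.sample_meta = self.sample_meta.loc[self.values.columns]

    # ------------------------------------------------------------------
    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def subset_genes(self, genes) -> "ExpressionMatrix":
        """Return a new matrix restricted to ``genes`` (order preserved)."""
        return ExpressionMatrix(self.values.loc[genes], self.sample_meta.copy())

    def subset_samples(self, samples) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values[list(samples)], self.sample_meta.loc[list(samples)])

    # ------------------------------------------------------------------
    def write_tsv(self, values_path: str | Path, meta_path: str | Path) -> None:
        """Write values (genes as rows) and metadata as TSV with full precision."""
        self.values.to_csv(values_path, sep="\t", index_label="gene_id", float_format="%.17g")
        self.sample_meta.to_csv(meta_path, sep="\t", index_label="sample_id")

    @classmethod
    def read_tsv(cls, values_path: str | Path, meta_path: str | Path) -> "ExpressionMatrix":
        values = pd.read_csv(
            values_path, sep="\t", index_col="gene_id", float_precision="round_trip"
        )
        meta = pd.read_csv(meta_path, sep="\t", index_col="sample_id")
        return cls(values, meta)


def timecourse_meta(conditions=CONDITIONS, days=DAYS) -> pd.DataFrame:
    """Canonical 14-sample metadata: one sample per condition x day."""
    rows = [
        {"sample_id": f"{cond}_d{day:02d}", "condition": cond, "day": day}
        for cond in conditions
        for day in days
    ]
    return pd.DataFrame(rows).set_index("sample_id")


def stage_meta(stages, reps_per_stage: int) -> pd.DataFrame:
    rows = [
        {"sample_id": f"{stage}_r{r + 1}", "stage": stage, "replicate": r + 1}
        for stage in stages
        for r in range(reps_per_stage)
    ]
    return pd.DataFrame(rows).set_index("sample_id")
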