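"""Shared data containers for the genotoxicity pipeline.

These are thin, validated wrappers around pandas objects.  They exist so
that every stage of the pipeline receives data whose invariants (integer
counts, matched gene panels, positive variances, two-class labels) have
already been checked, and so the on-disk TSV formats have a single
canonical in-memory form.
"""

from __future__ import annotations

import dataclasses
from collections.abc import Sequence

import numpy as np
import pandas as pd

DDI = "DDI"
NON_DDI = "non-DDI"
INDETERMINATE = "indeterminate"


@dataclasses.dataclass
class ProbeCountMatrix:
    """Probe-level read counts: probes x samples plus a probe->gene map.

    ``counts`` is indexed by probe id with one column per sample;
    ``gene_symbols`` maps every probe id to exactly one gene symbol.
    Library size is the column sum.
    """

    counts: pd.DataFrame
    gene_symbols: pd.Series

    def __post_init__(self) -> None:
        if self.counts.index.has_duplicates:
            raise ValueError("duplicate probe ids in count matrix")
        if self.counts.columns.has_duplicates:
            raise ValueError("duplicate sample ids in count matrix")
        values = self.counts.to_numpy()
        if not np.issubdtype(values.dtype, np.integer):
            if not np.allclose(values, np.round(values)):
                raise ValueError("counts must be integers")
            self.counts = self.counts.astype(np.int64)
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        missing = self.counts.index.difference(self.gene_symbols.index)
        if len(missing):
            raise ValueError(f"probes without a gene symbol: {list(missing)[:5]}")
        self.gene_symbols = self.gene_symbols.loc[self.counts.index]

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def library_sizes(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def genes(self) -> list[str]:
        seen: dict[str, None] = {}
        for g in self.gene_symbols:
            seen.setdefault(g, None)
        return list(seen)


@dataclasses.dataclass
class TrainingSet:
    """Labeled biomarker profiles for the reference chemicals.

    ``X`` holds one log2 fold-change vector per reference chemical (rows)
    over the ordered biomarker panel (columns); ``y`` holds the DDI /
    non-DDI class label per chemical.
    """

    X: pd.DataFrame
    y: pd.Series

    def __post_init__(self) -> None:
        if self.X.index.has_duplicates:
            dups = self.X.index[self.X.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate chemical ids in training set: {dups}")
        if not self.X.index.equals(self.y.index):
            self.y = self.y.loc[self.X.index]
        if self.X.isna().any().any():
            raise ValueError("training profiles contain missing values")
        counts = self.y.value_counts()
        if len(counts) < 2:
            raise ValueError("training set needs at least two classes")
        small = counts[counts < 2]
        if len(small):
            raise ValueError(
                "each class needs >= 2 members (within-class sd undefined): "
                f"{small.to_dict()}"
            )

    @property
    def genes(self) -> list[str]:
        return list(self.X.columns)

    @property
    def classes(self) -> list[str]:
        return sorted(self.y.unique())

    def class_sizes(self) -> dict[str, int]:
        return self.y.value_counts().to_dict()


@dataclasses.dataclass
class GeneExpressionProfile:
    """Per-condition biomarker profile: log2 fold change and variance per gene.

    The profile is measured against the condition's matched vehicle control.
    Variances come from count-based (Poisson) error propagation because the
    pooled-RNA design has one sequencing library per condition, so there are
    no biological replicates to estimate variance from.
    """

    condition: str
    log2fc: pd.Series
    variance: pd.Series

    def __post_init__(self) -> None:
        if not self.log2fc.index.equals(self.variance.index):
            self.variance = self.variance.loc[self.log2fc.index]
        arr = self.log2fc.to_numpy(float)
        if not np.all(np.isfinite(arr)):
            raise ValueError(f"non-finite log2 fold changes in {self.condition}")
        var = self.variance.to_numpy(float)
        if not np.all(np.isfinite(var)) or (var <= 0).any():
            raise ValueError(f"variances must be finite and > 0 in {self.condition}")

    @property
    def genes(self) -> list[str]:
        return list(self.log2fc.index)

    def require_panel(self, panel: Sequence[str]) -> None:
        if set(self.genes) != set(panel):
            missing = sorted(set(panel) - set(self.genes))
            extra = sorted(set(self.genes) - set(panel))
            raise ValueError(
                f"profile {self.condition} does not match the biomarker panel; "
                f"missing={missing[:5]} extra={extra[:5]}"
            )


@dataclasses.dataclass
class QCReport:
    """Pairwise sample-correlation screen on log2 reads-per-million."""

    pairs: pd.DataFrame  # sample_a, sample_b, correlation
    threshold: float
    excluded_pairs: list[tuple[str, str]] = dataclasses.field(default_factory=list)

    def __post_init__(self) -> None:
        corr = self.pairs["correlation"].to_numpy(float)
        if len(corr) and (np.abs(corr) > 1 + 1e-12).any():
            raise ValueError("correlations must lie in [-1, 1]")

    @property
    def min_correlation(self) -> float:
        return float(self.pairs["correlation"].min())

    @property
    def passed(self) -> bool:
        """True iff no evaluable sample pair falls below the threshold."""
        return bool(self.min_correlation >= self.threshold)
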