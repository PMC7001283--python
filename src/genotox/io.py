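"""Tab-separated readers and writers for every pipeline table.

All formats are UTF-8 TSV with a header row.  Writers and readers are
paired so that every table round-trips losslessly (integer columns stay
integers, floats survive via shortest-repr formatting).
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .containers import GeneExpressionProfile, ProbeCountMatrix, TrainingSet

_SAMPLE_COLUMNS = ["sample_id", "chemical", "tier", "vehicle", "role"]
_FLOW_COLUMNS = ["chemical", "concentration_index", "replicate", "scored_cells",
                 "mn_events", "nuclei_count", "bead_count", "is_vehicle"]


def _write(df: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=index)


def write_counts(matrix: ProbeCountMatrix, path: str | Path) -> None:
    out = matrix.counts.copy()
    out.insert(0, "gene_symbol", matrix.gene_symbols)
    out.index.name = "probe_id"
    _write(out, path, index=True)


def read_counts(path: str | Path) -> ProbeCountMatrix:
    df = pd.read_csv(path, sep="\t", index_col="probe_id")
    genes = df.pop("gene_symbol")
    return ProbeCountMatrix(counts=df, gene_symbols=genes)


def write_samples(samples: pd.DataFrame, path: str | Path) -> None:
    _write(samples[_SAMPLE_COLUMNS], path)


def read_samples(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    missing = set(_SAMPLE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"samples table missing columns: {sorted(missing)}")
    return df[_SAMPLE_COLUMNS]


def write_training(training: TrainingSet, path: str | Path) -> None:
    out = training.X.copy()
    out.insert(0, "label", training.y)
    out.index.name = "chemical"
    _write(out, path, index=True)


def read_training(path: str | Path) -> TrainingSet:
    df = pd.read_csv(path, sep="\t", index_col="chemical", float_precision="round_trip")
    y = df.pop("label")
    return TrainingSet(X=df, y=y)


def write_flow(flow: pd.DataFrame, path: str | Path) -> None:
    _write(flow[_FLOW_COLUMNS], path)


def read_flow(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    missing = set(_FLOW_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"flow table missing columns: {sorted(missing)}")
    df["is_vehicle"] = df["is_vehicle"].astype(bool)
    return df[_FLOW_COLUMNS]


def profiles_to_frame(profiles: list[GeneExpressionProfile]) -> pd.DataFrame:
    rows = []
    for p in profiles:
        for gene in p.genes:
            rows.append(dict(condition=p.condition, gene=gene,
                             log2fc=float(p.log2fc[gene]),
                             variance=float(p.variance[gene])))
    return pd.DataFrame(rows, columns=["condition", "gene", "log2fc", "variance"])


def profiles_from_frame(df: pd.DataFrame) -> list[GeneExpressionProfile]:
    profiles = []
    for condition, grp in df.groupby("condition", sort=False):
        profiles.append(GeneExpressionProfile(
            condition=str(condition),
            log2fc=pd.Series(grp["log2fc"].to_numpy(), index=grp["gene"].tolist()),
            variance=pd.Series(grp["variance"].to_numpy(), index=grp["gene"].tolist()),
        ))
    return profiles


def write_profiles(profiles: list[GeneExpressionProfile], path: str | Path) -> None:
    _write(profiles_to_frame(profiles), path)


def read_profiles(path: str | Path) -> list[GeneExpressionProfile]:
    return profiles_from_frame(pd.read_csv(path, sep="\t", float_precision="round_trip"))


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    """Generic TSV writer for result tables (calls, MN results, QC)."""
    _write(df, path)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", float_precision="round_trip")
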