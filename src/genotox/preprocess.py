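"""Probe-level counts -> per-condition biomarker profiles.

Stages: reads-per-million (RPM) normalization, a pairwise log2-RPM
correlation QC screen (the run-level quality gate: every sample pair is
expected to correlate at >= 0.97), per-probe log2 treated/control ratios
with count-based delta-method variances, and inverse-variance ("error
weighted") aggregation of probes to gene symbols.

No normalization beyond RPM is applied, and no differential-expression
testing happens here: the design pools RNA into a single library per
condition, so per-gene uncertainty comes from Poisson counting error, not
replicate variance.
"""

from __future__ import annotations

import warnings
from collections.abc import Sequence

import numpy as np
import pandas as pd

from .containers import GeneExpressionProfile, ProbeCountMatrix, QCReport

RPM_SCALE = 1_000_000.0


def rpm_normalize(matrix: ProbeCountMatrix) -> pd.DataFrame:
    """Scale each sample to reads-per-million (columns sum to 1e6)."""
    sizes = matrix.library_sizes
    zero = sizes[sizes == 0]
    if len(zero):
        raise ValueError(f"zero library size for sample(s): {list(zero.index)}")
    return matrix.counts / sizes.to_numpy() * RPM_SCALE


def qc_pairwise_correlation(
    rpm: pd.DataFrame, threshold: float = 0.97, pseudo: float = 0.5
) -> QCReport:
    """Pearson correlation of log2(RPM + pseudo) for every sample pair.

    The screen fails closed: any evaluable pair below ``threshold`` fails
    the run.  A constant sample (zero variance after the log transform)
    makes its pairs undefined; those pairs are excluded with a warning
    rather than silently passing or failing.
    """
    if rpm.shape[1] < 2:
        raise ValueError("QC screen needs at least two samples")
    log_rpm = np.log2(rpm.to_numpy(float) + pseudo)
    sd = log_rpm.std(axis=0)
    samples = list(rpm.columns)

    rows, excluded = [], []
    for i in range(len(samples)):
        for j in range(i + 1, len(samples)):
            if sd[i] == 0.0 or sd[j] == 0.0:
                excluded.append((samples[i], samples[j]))
                continue
            r = float(np.corrcoef(log_rpm[:, i], log_rpm[:, j])[0, 1])
            rows.append(dict(sample_a=samples[i], sample_b=samples[j],
                             correlation=r))
    if excluded:
        warnings.warn(
            f"{len(excluded)} sample pair(s) excluded from QC "
            "(constant log2-RPM, correlation undefined)", stacklevel=2)
    pairs = pd.DataFrame(rows, columns=["sample_a", "sample_b", "correlation"])
    return QCReport(pairs=pairs, threshold=threshold, excluded_pairs=excluded)


def probe_log_ratios(
    matrix: ProbeCountMatrix,
    treated: str,
    control: str,
    pseudo: float = 0.5,
) -> pd.DataFrame:
    """Per-probe log2 ratio treated vs control, with Poisson variance.

    ratio = log2(rpm_t + pseudo) - log2(rpm_c + pseudo); the variance comes
    from first-order (delta-method) propagation of Poisson counting error
    on the raw counts n: var = (1/(n_t + pseudo) + 1/(n_c + pseudo)) / ln(2)^2.
    The pseudo-count keeps zeros finite in the single-library design.
    """
    for sample in (treated, control):
        if sample not in matrix.counts.columns:
            raise KeyError(f"sample {sample!r} not in count matrix")
    rpm = rpm_normalize(matrix)
    n_t = matrix.counts[treated].to_numpy(float)
    n_c = matrix.counts[control].to_numpy(float)
    ratio = np.log2(rpm[treated].to_numpy() + pseudo) - np.log2(
        rpm[control].to_numpy() + pseudo)
    variance = (1.0 / (n_t + pseudo) + 1.0 / (n_c + pseudo)) / np.log(2.0) ** 2
    return pd.DataFrame(
        {
            "gene_symbol": matrix.gene_symbols.to_numpy(),
            "log2_ratio": ratio,
            "variance": variance,
        },
        index=matrix.counts.index,
    )


def aggregate_probes_to_genes(
    probe_ratios: pd.DataFrame,
    panel: Sequence[str],
    condition: str = "condition",
) -> GeneExpressionProfile:
    """Error-weighted average of probe ratios per biomarker gene.

    Inverse-variance weights: gene value = sum(w_i r_i) / sum(w_i) with
    w_i = 1 / var_i, and gene variance = 1 / sum(w_i).  Single-probe genes
    pass through unchanged.  Every panel gene must have at least one probe.
    """
    sub = probe_ratios[probe_ratios["gene_symbol"].isin(set(panel))]
    missing = sorted(set(panel) - set(sub["gene_symbol"]))
    if missing:
        raise ValueError(f"biomarker genes with no probes: {missing}")

    w = 1.0 / sub["variance"]
    grouped = pd.DataFrame({
        "wsum": w.groupby(sub["gene_symbol"]).sum(),
        "wxsum": (w * sub["log2_ratio"]).groupby(sub["gene_symbol"]).sum(),
    })
    value = grouped["wxsum"] / grouped["wsum"]
    variance = 1.0 / grouped["wsum"]
    return GeneExpressionProfile(
        condition=condition,
        log2fc=value.loc[list(panel)],
        variance=variance.loc[list(panel)],
    )


def build_profiles(
    matrix: ProbeCountMatrix,
    samples: pd.DataFrame,
    panel: Sequence[str],
    pseudo: float = 0.5,
) -> list[GeneExpressionProfile]:
    """One biomarker profile per test condition, against its matched vehicle.

    ``samples`` follows the samples.tsv layout (sample_id, chemical, tier,
    vehicle, role); each chemical must have exactly one vehicle_control
    sample, shared by its tiers.
    """
    profiles = []
    for chemical, grp in samples.groupby("chemical", sort=False):
        controls = grp.loc[grp["role"] == "vehicle_control", "sample_id"]
        if len(controls) != 1:
            raise ValueError(
                f"chemical {chemical!r} needs exactly one vehicle control, "
                f"found {len(controls)}")
        control = controls.iloc[0]
        for _, row in grp[grp["role"] == "test"].iterrows():
            ratios = probe_log_ratios(matrix, row["sample_id"], control, pseudo)
            profiles.append(aggregate_probes_to_genes(
                ratios, panel, condition=str(row["sample_id"])))
    return profiles
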