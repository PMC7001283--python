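"""End-to-end orchestration: simulate -> flow stats -> profiles -> calls.

`run_pipeline` chains the stages and writes every intermediate table to
the output directory, so each stage can also be re-run in isolation from
its TSV inputs (the CLI exposes them individually).  Given the same
configuration and seed the run is byte-identical.
"""

from __future__ import annotations

import dataclasses
import logging
import time
from pathlib import Path

import pandas as pd
import yaml

from . import io
from .containers import DDI, ProbeCountMatrix, TrainingSet
from .integrate import integrate_study
from .clustering import BranchClassifier
from .mn import analyze_chemical, select_concentrations
from .nsc import NSCClassifier, select_delta_loocv
from .panel import biomarker_panel, load_panel
from .preprocess import build_profiles, qc_pairwise_correlation, rpm_normalize
from .projection import PCAAxisClassifier
from .reference import STUDY_DESIGN
from .simulate import SimulationParams, default_test_panel, generate_flow_study, \
    generate_test_study, generate_training_set

log = logging.getLogger("genotox")

TIER_ORDER = ("low", "mid", "high")


@dataclasses.dataclass
class RunConfig:
    """Pipeline configuration: paths, thresholds and simulation parameters."""

    out_dir: str = "genotox_out"
    seed: int = 42
    panel_path: str | None = None
    delta: float | None = None          # None -> choose by LOOCV
    delta_grid: tuple[float, ...] | None = None
    probability_threshold: float = 0.90
    mn_alpha: float = 0.01
    rs_alpha: float = 0.05
    fold_threshold: float = 2.0
    rs_cutoff: float = 40.0
    concentration_cap: float | None = None
    plots: bool = False
    log_level: str = "INFO"
    simulation: SimulationParams | None = None

    def __post_init__(self) -> None:
        for name, value, lo, hi in (
            ("probability_threshold", self.probability_threshold, 0.5, 1.0),
            ("mn_alpha", self.mn_alpha, 0.0, 1.0),
            ("rs_alpha", self.rs_alpha, 0.0, 1.0),
        ):
            if not lo <= value <= hi:
                raise ValueError(f"{name}={value} outside [{lo}, {hi}]")
        if self.fold_threshold < 1.0:
            raise ValueError("fold_threshold must be >= 1")
        if not 0.0 < self.rs_cutoff < 100.0:
            raise ValueError("rs_cutoff must be a percentage in (0, 100)")
        if self.simulation is None:
            self.simulation = SimulationParams(seed=self.seed)

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim = raw.pop("simulation", None)
        raw.update({k: v for k, v in overrides.items() if v is not None})
        if sim is not None:
            sim.setdefault("seed", raw.get("seed", 42))
            raw["simulation"] = SimulationParams(**sim)
        return cls(**raw)

    def panel(self) -> list[str]:
        if self.panel_path:
            return load_panel(self.panel_path)
        return biomarker_panel(self.simulation.n_biomarker_genes)


@dataclasses.dataclass
class StudyReport:
    """Integrated per-chemical verdicts in the published-table layout."""

    table: pd.DataFrame      # one row per chemical
    calls: pd.DataFrame      # per tier x analysis calls with scores
    mn_results: pd.DataFrame
    warnings: list[str] = dataclasses.field(default_factory=list)

    def concordance(self) -> pd.DataFrame:
        """Chemical-level MN vs TGx-DDI agreement summary."""
        t = self.table
        return pd.DataFrame({
            "chemical": t["chemical"],
            "mn_positive": t["mn_positive"],
            "tgx_ddi": t["chemical_call"] == DDI,
            "concordant": t["mn_positive"] == (t["chemical_call"] == DDI),
        })


# ---------------------------------------------------------------------------
# stages


def simulate_stage(config: RunConfig, out: Path):
    params = config.simulation
    chemicals = default_test_panel()
    training = generate_training_set(params)
    counts, samples = generate_test_study(chemicals, params)
    flow = generate_flow_study(chemicals, params)
    io.write_training(training, out / "training.tsv")
    io.write_counts(counts, out / "counts.tsv")
    io.write_samples(samples, out / "samples.tsv")
    io.write_flow(flow, out / "flow.tsv")
    log.info("simulated %d training chemicals, %d samples, %d wells",
             len(training.X), samples.shape[0], flow.shape[0])
    return training, counts, samples, flow


def mn_stage(flow: pd.DataFrame, config: RunConfig, out: Path
             ) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, dict[str, int]]]:
    """Flow statistics per chemical: RS, GEE fits, MN calls, tier selection."""
    rows, chem_rows = [], []
    selections: dict[str, dict[str, int]] = {}
    for chemical, wells in flow.groupby("chemical", sort=False):
        rs, mn_fit, rs_fit, result, retained = analyze_chemical(
            wells, fold_threshold=config.fold_threshold,
            mn_alpha=config.mn_alpha, rs_cutoff=config.rs_cutoff)
        design = STUDY_DESIGN.get(chemical)
        doses = pd.Series(
            {i: design["concentrations"][i - 1] for i in retained}
            if design else {i: float(i) for i in retained})
        cap = None if (design and design["cytotoxic"]) else config.concentration_cap
        sel = select_concentrations(doses, cap=cap)
        selections[str(chemical)] = sel
        table = result.table.merge(rs.rename("rs_pct"), left_on="concentration_index",
                                   right_index=True)
        table.insert(0, "chemical", chemical)
        rows.append(table)
        tier_flags = {f"mn_{tier}": "+" if bool(
            result.table.set_index("concentration_index")
            .loc[idx, "positive"]) else "-" for tier, idx in sel.items()}
        chem_rows.append(dict(chemical=chemical, mn_positive=result.positive,
                              excluded=",".join(map(str, result.excluded)),
                              low_index=sel["low"], mid_index=sel["mid"],
                              high_index=sel["high"],
                              continuity_adjusted=",".join(
                                  map(str, mn_fit.continuity_adjusted)),
                              **tier_flags))
    mn_results = pd.concat(rows, ignore_index=True)
    chemical_mn = pd.DataFrame(chem_rows)
    io.write_table(mn_results, out / "mn_results.tsv")
    io.write_table(chemical_mn, out / "chemical_mn_calls.tsv")
    log.info("MN analysis: %d/%d chemicals MN-positive",
             int(chemical_mn["mn_positive"].sum()), len(chemical_mn))
    return mn_results, chemical_mn, selections


def preprocess_stage(counts: ProbeCountMatrix, samples: pd.DataFrame,
                     config: RunConfig, out: Path):
    rpm = rpm_normalize(counts)
    qc = qc_pairwise_correlation(rpm)
    profiles = build_profiles(counts, samples, config.panel())
    io.write_table(qc.pairs, out / "qc.tsv")
    io.write_profiles(profiles, out / "profiles.tsv")
    warn = [] if qc.passed else [
        f"QC screen failed: min pairwise correlation {qc.min_correlation:.4f}"
        f" < {qc.threshold}"]
    log.info("QC min pairwise correlation %.4f (threshold %.2f)",
             qc.min_correlation, qc.threshold)
    return profiles, qc, warn


def classify_stage(training: TrainingSet, profiles, config: RunConfig, out: Path
                   ) -> tuple[pd.DataFrame, pd.DataFrame, float]:
    delta = config.delta
    if delta is None:
        delta = select_delta_loocv(training, grid=config.delta_grid)
        log.info("LOOCV selected delta = %.3f", delta)
    nsc = NSCClassifier(delta=delta,
                        threshold=config.probability_threshold
                        ).fit(training.X, training.y)
    pca = PCAAxisClassifier().fit(training.X, training.y)
    dc = BranchClassifier().fit(training.X, training.y)

    rows = []
    for profile in profiles:
        x = profile.log2fc.to_frame().T
        chemical, _, tier = profile.condition.rpartition("|")
        pa_call = str(nsc.call(x)[0])
        pa_prob = float(nsc.predict_proba(x)[0][list(nsc.classes_).index(DDI)])
        pca_call = str(pca.call(x)[0])
        pca_score = float(pca.decision_function(x)[0])
        dc_call, dc_purity = dc.classify_one(x)
        rows.append(dict(chemical=chemical or profile.condition, tier=tier,
                         PA_call=pa_call, PA_prob=pa_prob,
                         PCA_call=pca_call, PCA_score=pca_score,
                         DC_call=dc_call, DC_purity=dc_purity))
    calls = pd.DataFrame(rows)
    calls, chemical_calls = integrate_study(calls)
    io.write_table(calls, out / "calls.tsv")
    io.write_table(chemical_calls, out / "chemical_calls.tsv")
    log.info("TGx-DDI: %d/%d chemicals classified DDI",
             int((chemical_calls["chemical_call"] == DDI).sum()),
             len(chemical_calls))
    return calls, chemical_calls, delta


def report_stage(calls: pd.DataFrame, chemical_calls: pd.DataFrame,
                 mn_results: pd.DataFrame, chemical_mn: pd.DataFrame,
                 out: Path, warnings: list[str] | None = None) -> StudyReport:
    wide = calls.pivot(index="chemical", columns="tier", values="overall_call")
    rows = []
    for _, mn_row in chemical_mn.iterrows():
        chemical = mn_row["chemical"]
        row = dict(chemical=chemical)
        for tier in TIER_ORDER:
            row[f"mn_{tier}"] = mn_row[f"mn_{tier}"]
        for tier in TIER_ORDER:
            row[f"tgx_{tier}"] = wide.loc[chemical, tier]
        row["chemical_call"] = chemical_calls.set_index("chemical").loc[
            chemical, "chemical_call"]
        row["mn_positive"] = bool(mn_row["mn_positive"])
        rows.append(row)
    table = pd.DataFrame(rows)
    report = StudyReport(table=table, calls=calls, mn_results=mn_results,
                         warnings=list(warnings or []))
    io.write_table(table, out / "report.tsv")
    (out / "report.txt").write_text(render_calls_table(report))
    return report


def render_calls_table(report: StudyReport) -> str:
    """Plain-text integrated calls table with the decision-rule footnotes."""
    t = report.table
    required = [f"mn_{x}" for x in TIER_ORDER] + [f"tgx_{x}" for x in TIER_ORDER]
    if t[required].isna().any().any():
        raise ValueError("incomplete tiers in report table")
    header = (f"{'Chemical':32s} {'MN(L/M/H)':>10s} "
              f"{'TGx(L/M/H)':>24s} {'Chemical call':>14s}")
    lines = [header, "-" * len(header)]
    for _, r in t.iterrows():
        mn = "/".join(r[f"mn_{x}"] for x in TIER_ORDER)
        tgx = "/".join(r[f"tgx_{x}"] for x in TIER_ORDER)
        lines.append(f"{r['chemical']:32s} {mn:>10s} {tgx:>24s} "
                     f"{r['chemical_call']:>14s}")
    lines += [
        "",
        "MN '+': statistically significant induction and >= twofold over the",
        "matched vehicle control; '-': not induced. A tier is DDI overall when",
        "any of the three analyses (PA, PCA, 2DC) calls it DDI; a chemical is",
        "DDI when any tested tier is DDI overall.",
    ]
    if report.warnings:
        lines += [""] + [f"warning: {w}" for w in report.warnings]
    return "\n".join(lines) + "\n"


def run_pipeline(config: RunConfig) -> StudyReport:
    """Run every stage on a synthetic study and write all artifacts."""
    logging.basicConfig(level=config.log_level)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()

    training, counts, samples, flow = simulate_stage(config, out)
    mn_results, chemical_mn, _ = mn_stage(flow, config, out)
    profiles, qc, warns = preprocess_stage(counts, samples, config, out)
    calls, chemical_calls, _ = classify_stage(training, profiles, config, out)
    report = report_stage(calls, chemical_calls, mn_results, chemical_mn, out,
                          warnings=warns)
    if config.plots:
        from . import plots
        plots.render_all(training, profiles, out)
    log.info("pipeline finished in %.1fs", time.time() - t0)
    return report
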