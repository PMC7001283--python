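"""Synthetic study generator.

Emulates the data structure of the integrated genotoxicity study design:

* a labeled training set of per-chemical biomarker log2-ratio profiles
  (28 reference chemicals by default, 64-gene panel);
* probe-level AmpliSeq-style count matrices for a test panel of chemicals
  at three concentration tiers, one pooled RNA sample per condition;
* flow-cytometry micronucleus well tables (duplicate wells of ~20,000
  scored cells, counting beads spiked in for relative survival).

Everything is driven by a single RNG seed; identical parameters and seed
give byte-identical outputs.  The generator's defaults are the study
conditions the downstream statistics assume, not tuning knobs.
"""

from __future__ import annotations

import dataclasses
from collections.abc import Sequence

import numpy as np
import pandas as pd

from .containers import DDI, NON_DDI, ProbeCountMatrix, TrainingSet
from .panel import biomarker_panel
from .reference import STUDY_DESIGN

TIERS = ("low", "mid", "high")


@dataclasses.dataclass(frozen=True)
class SimulationParams:
    """Parameters of the synthetic study.

    Expression side: the biomarker panel has ``n_biomarker_genes`` genes of
    which ``responsive_fraction`` respond to DDI exposure, half shifted up
    and half down by ``ddi_effect`` log2 units at the high tier; lower tiers
    scale the effect by ``concentration_multipliers``.  Training profiles
    add gaussian noise of ``profile_noise_sd`` log2 units per gene.

    Flow side: each chemical x concentration gets ``n_replicate_wells``
    wells of roughly normal(``cells_per_well_mean``, ``cells_per_well_sd``)
    scored cells (sd 667 makes the +/-2000 envelope a ~3-sd band);
    micronucleated cells are binomial at ``baseline_mn_rate`` times the
    chemical's per-concentration fold.  Relative survival follows a Hill
    curve in dose/top-dose with midpoint ``cytotox_ec50`` (cytotoxic
    chemicals) or ``benign_ec50`` (all others).
    """

    n_biomarker_genes: int = 64
    n_background_genes: int = 936
    n_train_ddi: int = 14
    n_train_nonddi: int = 14
    ddi_effect: float = 1.0
    responsive_fraction: float = 0.6
    profile_noise_sd: float = 0.30
    concentration_multipliers: tuple[float, float, float] = (0.25, 0.6, 1.0)
    library_size: int = 1_000_000
    probes_per_gene: tuple[int, int] = (1, 3)
    n_replicate_wells: int = 2
    cells_per_well_mean: float = 20_000.0
    cells_per_well_sd: float = 667.0
    baseline_mn_rate: float = 0.006
    mn_fold_curve_ddi: tuple[float, ...] = (1.0, 1.5, 2.5, 4.0, 6.0, 8.0)
    mn_fold_curve_aneugen: tuple[float, ...] = (1.0, 1.0, 1.0, 2.2, 2.5, 2.9)
    cytotox_ec50: float = 0.7
    cytotox_hill: float = 2.5
    benign_ec50: float = 3.0
    beads_per_well: float = 5_000.0
    nuclei_per_bead: float = 2.0
    seed: int = 42

    def __post_init__(self) -> None:
        counts = dict(
            n_biomarker_genes=self.n_biomarker_genes,
            n_background_genes=self.n_background_genes,
            n_train_ddi=self.n_train_ddi,
            n_train_nonddi=self.n_train_nonddi,
            library_size=self.library_size,
            n_replicate_wells=self.n_replicate_wells,
        )
        for name, value in counts.items():
            if value < (0 if name == "n_background_genes" else 1):
                raise ValueError(f"{name} must be positive, got {value}")
        if not 0.0 <= self.responsive_fraction <= 1.0:
            raise ValueError("responsive_fraction must lie in [0, 1]")
        if not 0.0 <= self.baseline_mn_rate <= 1.0:
            raise ValueError("baseline_mn_rate must lie in [0, 1]")
        m = self.concentration_multipliers
        if len(m) != 3 or any(b < a for a, b in zip(m, m[1:])):
            raise ValueError("concentration multipliers must be 3 non-decreasing values")
        lo, hi = self.probes_per_gene
        if lo < 1 or hi < lo:
            raise ValueError("probes_per_gene must be a range with 1 <= lo <= hi")
        if self.profile_noise_sd < 0 or self.cells_per_well_sd < 0:
            raise ValueError("standard deviations must be non-negative")

    def rng(self, stream: int) -> np.random.Generator:
        """Independent generator for one of the simulation streams."""
        return np.random.default_rng(np.random.SeedSequence([int(self.seed), stream]))


@dataclasses.dataclass(frozen=True)
class ChemicalSpec:
    """One test chemical: truth class, dose series and cytotoxicity shape."""

    name: str
    truth_class: str
    aneugen: bool = False
    concentrations: tuple[float, ...] = (0.3125, 0.625, 1.25, 2.5, 5.0, 10.0)
    cytotoxic: bool = False
    vehicle: str = "media"
    mn_fold_curve: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if self.truth_class not in (DDI, NON_DDI):
            raise ValueError(f"truth_class must be {DDI!r} or {NON_DDI!r}")
        if self.aneugen and self.truth_class != NON_DDI:
            raise ValueError("an aneugen is transcriptionally non-DDI by definition")
        if len(self.concentrations) != 6:
            raise ValueError("exactly six concentrations are required")
        if any(b <= a for a, b in zip(self.concentrations, self.concentrations[1:])):
            raise ValueError("concentrations must be strictly increasing")
        if self.mn_fold_curve is not None and len(self.mn_fold_curve) != 6:
            raise ValueError("mn_fold_curve needs one fold per concentration")


def default_test_panel() -> list[ChemicalSpec]:
    """The ten-chemical reference panel: 5 DDI, 4 inert non-DDI, 1 aneugen."""
    return [
        ChemicalSpec(
            name=name,
            truth_class=d["truth"],
            aneugen=d["aneugen"],
            concentrations=d["concentrations"],
            cytotoxic=d["cytotoxic"],
            vehicle=d["vehicle"],
        )
        for name, d in STUDY_DESIGN.items()
    ]


# ---------------------------------------------------------------------------
# expression side


def responsive_genes(params: SimulationParams) -> tuple[list[str], list[str]]:
    """(up-regulated, down-regulated) biomarker genes under DDI exposure.

    Deterministic in the params: the first responsive half shifts up, the
    second half down, mirroring the red/green block structure of the
    biomarker heatmap.
    """
    panel = biomarker_panel(params.n_biomarker_genes)
    n_resp = int(round(params.responsive_fraction * params.n_biomarker_genes))
    n_up = n_resp // 2 + n_resp % 2
    return panel[:n_up], panel[n_up:n_resp]


def ddi_effect_vector(params: SimulationParams) -> pd.Series:
    """Per-gene log2 effect of a DDI exposure at the high tier."""
    panel = biomarker_panel(params.n_biomarker_genes)
    up, down = responsive_genes(params)
    effect = pd.Series(0.0, index=panel)
    effect[up] = params.ddi_effect
    effect[down] = -params.ddi_effect
    return effect


def generate_training_set(params: SimulationParams) -> TrainingSet:
    """Simulate the labeled reference-chemical training set.

    DDI chemicals have the responsive genes shifted by +/- ``ddi_effect``
    plus per-gene gaussian noise; non-DDI chemicals are pure noise around
    zero.  Stands in for the microarray-derived reference profiles the
    published classifier was trained on.
    """
    if params.n_train_ddi < 2 or params.n_train_nonddi < 2:
        raise ValueError("need >= 2 training chemicals per class "
                         "(within-class sd is undefined otherwise)")
    rng = params.rng(1)
    panel = biomarker_panel(params.n_biomarker_genes)
    effect = ddi_effect_vector(params).to_numpy()

    rows, labels, names = [], [], []
    for i in range(params.n_train_ddi):
        noise = rng.normal(0.0, params.profile_noise_sd, len(panel))
        rows.append(effect + noise)
        labels.append(DDI)
        names.append(f"TRAIN-DDI-{i + 1:02d}")
    for i in range(params.n_train_nonddi):
        rows.append(rng.normal(0.0, params.profile_noise_sd, len(panel)))
        labels.append(NON_DDI)
        names.append(f"TRAIN-NON-{i + 1:02d}")

    X = pd.DataFrame(rows, index=pd.Index(names, name="chemical"),
                     columns=panel)
    return TrainingSet(X=X, y=pd.Series(labels, index=X.index, name="label"))


def _probe_layout(params: SimulationParams, rng: np.random.Generator
                  ) -> tuple[pd.Series, pd.Series]:
    """Assign probes to genes and baseline per-probe rates (sum to 1).

    Gene abundances are log-normal (a heavy-tailed library composition);
    each gene gets 1-3 probes with Dirichlet-split shares.
    """
    panel = biomarker_panel(params.n_biomarker_genes)
    background = [f"BG{i:04d}" for i in range(1, params.n_background_genes + 1)]
    genes = panel + background

    abundance = rng.lognormal(mean=0.0, sigma=1.0, size=len(genes))
    abundance /= abundance.sum()

    lo, hi = params.probes_per_gene
    n_probes = rng.integers(lo, hi + 1, size=len(genes))

    probe_ids, probe_genes, probe_rates = [], [], []
    for gene, abund, k in zip(genes, abundance, n_probes):
        shares = rng.dirichlet(np.full(k, 5.0))
        for j, share in enumerate(shares, start=1):
            probe_ids.append(f"{gene}_p{j}")
            probe_genes.append(gene)
            probe_rates.append(abund * share)
    index = pd.Index(probe_ids, name="probe_id")
    gene_map = pd.Series(probe_genes, index=index, name="gene_symbol")
    rates = pd.Series(probe_rates, index=index, name="rate")
    return gene_map, rates


def generate_test_study(
    chemicals: Sequence[ChemicalSpec], params: SimulationParams
) -> tuple[ProbeCountMatrix, pd.DataFrame]:
    """Simulate probe-level counts for the test chemicals at three tiers.

    One pooled sample per chemical x tier plus one matched vehicle-control
    sample per chemical.  Treated expected counts are the control rate times
    ``2 ** (tier multiplier * per-gene effect)``; observed counts are
    Poisson.  Returns the count matrix and a sample metadata table.
    """
    if not chemicals:
        raise ValueError("chemical list is empty")
    names = [c.name for c in chemicals]
    if len(set(names)) != len(names):
        raise ValueError("duplicate chemical names")

    rng = params.rng(2)
    gene_map, base_rates = _probe_layout(params, rng)
    effect_full = pd.Series(0.0, index=pd.unique(gene_map))
    effect_full.update(ddi_effect_vector(params))

    probe_effect = gene_map.map(effect_full).to_numpy()
    rates = base_rates.to_numpy()

    columns: dict[str, np.ndarray] = {}
    meta_rows = []
    for chem in chemicals:
        control_id = f"{chem.name}|control"
        lam = rates * params.library_size
        columns[control_id] = rng.poisson(lam)
        meta_rows.append(dict(sample_id=control_id, chemical=chem.name,
                              tier="control", vehicle=chem.vehicle,
                              role="vehicle_control"))
        chem_scale = 1.0 if chem.truth_class == DDI else 0.0
        for tier, mult in zip(TIERS, params.concentration_multipliers):
            sample_id = f"{chem.name}|{tier}"
            lam_t = lam * np.exp2(mult * chem_scale * probe_effect)
            columns[sample_id] = rng.poisson(lam_t)
            meta_rows.append(dict(sample_id=sample_id, chemical=chem.name,
                                  tier=tier, vehicle=chem.vehicle, role="test"))

    counts = pd.DataFrame(columns, index=gene_map.index)
    samples = pd.DataFrame(meta_rows)
    return ProbeCountMatrix(counts=counts, gene_symbols=gene_map), samples


# ---------------------------------------------------------------------------
# flow-cytometry side


def relative_survival_curve(chem: ChemicalSpec, params: SimulationParams
                            ) -> np.ndarray:
    """True relative-survival fraction at each of the six concentrations.

    Hill curve in normalized dose d = conc / top conc:
    RS = 1 / (1 + (d / ec50) ** hill), with a far-right midpoint for
    non-cytotoxic chemicals so their RS stays near 100%.
    """
    doses = np.asarray(chem.concentrations, float)
    d = doses / doses[-1]
    ec50 = params.cytotox_ec50 if chem.cytotoxic else params.benign_ec50
    return 1.0 / (1.0 + (d / ec50) ** params.cytotox_hill)


def mn_fold_curve(chem: ChemicalSpec, params: SimulationParams) -> np.ndarray:
    """True micronucleus fold over vehicle at each concentration."""
    if chem.mn_fold_curve is not None:
        return np.asarray(chem.mn_fold_curve, float)
    if chem.aneugen:
        return np.asarray(params.mn_fold_curve_aneugen, float)
    if chem.truth_class == DDI:
        return np.asarray(params.mn_fold_curve_ddi, float)
    return np.ones(6)


def generate_flow_study(
    chemicals: Sequence[ChemicalSpec], params: SimulationParams
) -> pd.DataFrame:
    """Simulate the micronucleus / relative-survival well table.

    Per chemical x concentration x replicate well: scored cells are a
    rounded normal draw, MN events binomial at the baseline rate times the
    chemical's fold curve, and nuclei / bead counts Poisson draws whose
    ratio tracks the relative-survival curve.  Vehicle wells are included
    per chemical.  Never emits negative counts; MN events never exceed
    scored cells.
    """
    if not chemicals:
        raise ValueError("chemical list is empty")
    rng = params.rng(3)
    rows = []
    for chem in chemicals:
        rs_curve = relative_survival_curve(chem, params)
        folds = mn_fold_curve(chem, params)
        mn_rates = np.clip(params.baseline_mn_rate * folds, 0.0, 1.0)
        # concentration_index 0 denotes the matched vehicle-control wells
        for conc_idx in range(0, 7):
            rs = 1.0 if conc_idx == 0 else rs_curve[conc_idx - 1]
            rate = params.baseline_mn_rate if conc_idx == 0 else mn_rates[conc_idx - 1]
            for rep in range(1, params.n_replicate_wells + 1):
                cells = max(1, int(round(rng.normal(
                    params.cells_per_well_mean, params.cells_per_well_sd))))
                mn = int(rng.binomial(cells, rate))
                beads = max(1, int(rng.poisson(params.beads_per_well)))
                nuclei = int(rng.poisson(params.nuclei_per_bead * beads * rs))
                rows.append(dict(
                    chemical=chem.name, concentration_index=conc_idx,
                    replicate=rep, scored_cells=cells, mn_events=mn,
                    nuclei_count=nuclei, bead_count=beads,
                    is_vehicle=conc_idx == 0))
    return pd.DataFrame(rows)
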