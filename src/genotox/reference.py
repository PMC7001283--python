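"""Reference ten-chemical validation study: design and published calls.

The HepaRG validation study exposed cells to ten chemicals — five DNA
damage-inducing (aflatoxin B1, cisplatin, etoposide, methyl
methanesulfonate, 2-nitrofluorene) and five non-DDI (ampicillin,
colchicine, 2-deoxy-D-glucose, sodium ascorbate, sodium chloride; the
aneugen colchicine is MN-positive but transcriptionally non-DDI) — at six
concentrations each.  This module transcribes that study's design
(concentration series, vehicles, cytotoxic top doses) and its published
per-analysis classification calls and micronucleus flags at the low / mid /
high concentrations used for sequencing.  The call table is an *input*: it
drives the integration-rule validation and supplies the default simulated
chemical panel.
"""

from __future__ import annotations

import io

import pandas as pd

from .containers import DDI, NON_DDI

TIERS = ("low", "mid", "high")

#: chemical -> (abbreviation, truth class, aneugen flag, vehicle,
#:              concentrations, cytotoxic top dose)
STUDY_DESIGN: dict[str, dict] = {
    "Aflatoxin B1": dict(
        abbr="AFB1", truth=DDI, aneugen=False, vehicle="DMSO",
        concentrations=(0.1, 0.25, 0.5, 1.0, 2.5, 5.0), cytotoxic=True),
    "Cisplatin": dict(
        abbr="CISP", truth=DDI, aneugen=False, vehicle="DMSO",
        concentrations=(1.0, 2.0, 3.0, 5.0, 10.0, 20.0), cytotoxic=True),
    "Etoposide": dict(
        abbr="ETP", truth=DDI, aneugen=False, vehicle="DMSO",
        concentrations=(0.25, 0.5, 1.0, 2.5, 5.0, 10.0), cytotoxic=False),
    "Methyl methanesulfonate": dict(
        abbr="MMS", truth=DDI, aneugen=False, vehicle="water",
        concentrations=(5.0, 10.0, 20.0, 50.0, 100.0, 200.0), cytotoxic=False),
    "2-Nitrofluorene": dict(
        abbr="2NF", truth=DDI, aneugen=False, vehicle="DMSO",
        concentrations=(2.0, 10.0, 50.0, 100.0, 250.0, 500.0), cytotoxic=True),
    "Ampicillin Trihydrate": dict(
        abbr="AMP", truth=NON_DDI, aneugen=False, vehicle="media",
        concentrations=(0.4, 1.0, 2.0, 3.0, 5.0, 10.0), cytotoxic=False),
    "Colchicine": dict(
        abbr="COL", truth=NON_DDI, aneugen=True, vehicle="DMSO",
        concentrations=(0.0125, 0.025, 0.05, 0.1, 0.2, 0.3), cytotoxic=False),
    "2-Deoxy-D-Glucose": dict(
        abbr="2DG", truth=NON_DDI, aneugen=False, vehicle="media",
        concentrations=(0.3125, 0.625, 1.25, 2.5, 5.0, 10.0), cytotoxic=False),
    "Sodium Ascorbate": dict(
        abbr="ASC", truth=NON_DDI, aneugen=False, vehicle="media",
        concentrations=(0.1, 0.4, 1.0, 2.0, 4.0, 10.0), cytotoxic=False),
    "Sodium Chloride": dict(
        abbr="NaCl", truth=NON_DDI, aneugen=False, vehicle="media",
        concentrations=(0.5, 1.0, 2.5, 5.0, 7.5, 10.0), cytotoxic=False),
}

# Published per-tier calls: MN induction flag (+/-), overall TGx-DDI call,
# and the three per-analysis calls (PA = NSC probability analysis,
# PCA = principal-component projection, DC = clustering branch).
_CALLS_TSV = """\
chemical\ttier\tmn\toverall\tpa\tpca\tdc
Aflatoxin B1\tlow\t+\tnon-DDI\tnon-DDI\tnon-DDI\tnon-DDI
Aflatoxin B1\tmid\t+\tDDI\tDDI\tDDI\tnon-DDI
Aflatoxin B1\thigh\t+\tDDI\tDDI\tDDI\tDDI
Cisplatin\tlow\t-\tnon-DDI\tnon-DDI\tnon-DDI\tnon-DDI
Cisplatin\tmid\t+\tnon-DDI\tnon-DDI\tnon-DDI\tnon-DDI
Cisplatin\thigh\t+\tDDI\tDDI\tDDI\tnon-DDI
Etoposide\tlow\t+\tDDI\tDDI\tnon-DDI\tnon-DDI
Etoposide\tmid\t+\tDDI\tDDI\tDDI\tnon-DDI
Etoposide\thigh\t+\tDDI\tDDI\tDDI\tnon-DDI
Methyl methanesulfonate\tlow\t-\tnon-DDI\tnon-DDI\tnon-DDI\tnon-DDI
Methyl methanesulfonate\tmid\t+\tDDI\tDDI\tDDI\tDDI
Methyl methanesulfonate\thigh\t+\tDDI\tDDI\tDDI\tDDI
2-Nitrofluorene\tlow\t-\tnon-DDI\tnon-DDI\tnon-DDI\tnon-DDI
2-Nitrofluorene\tmid\t+\tDDI\tDDI\tDDI\tDDI
2-Nitrofluorene\thigh\t+\tDDI\tDDI\tDDI\tDDI
Ampicillin Trihydrate\tlow\t-\tnon-DDI\tnon-DDI\tnon-DDI\tnon-DDI
Ampicillin Trihydrate\tmid\t-\tnon-DDI\tnon-DDI\tnon-DDI\tnon-DDI
Ampicillin Trihydrate\thigh\t-\tnon-DDI\tnon-DDI\tnon-DDI\tnon-DDI
Colchicine\tlow\t-\tnon-DDI\tnon-DDI\tnon-DDI\tnon-DDI
Colchicine\tmid\t+\tnon-DDI\tnon-DDI\tnon-DDI\tnon-DDI
Colchicine\thigh\t+\tnon-DDI\tnon-DDI\tnon-DDI\tnon-DDI
2-Deoxy-D-Glucose\tlow\t-\tnon-DDI\tnon-DDI\tnon-DDI\tnon-DDI
2-Deoxy-D-Glucose\tmid\t-\tnon-DDI\tnon-DDI\tnon-DDI\tnon-DDI
2-Deoxy-D-Glucose\thigh\t-\tnon-DDI\tnon-DDI\tnon-DDI\tnon-DDI
Sodium Ascorbate\tlow\t-\tnon-DDI\tnon-DDI\tnon-DDI\tnon-DDI
Sodium Ascorbate\tmid\t-\tnon-DDI\tnon-DDI\tnon-DDI\tnon-DDI
Sodium Ascorbate\thigh\t-\tnon-DDI\tnon-DDI\tnon-DDI\tnon-DDI
Sodium Chloride\tlow\t-\tnon-DDI\tnon-DDI\tnon-DDI\tnon-DDI
Sodium Chloride\tmid\t-\tnon-DDI\tnon-DDI\tnon-DDI\tnon-DDI
Sodium Chloride\thigh\t-\tnon-DDI\tnon-DDI\tnon-DDI\tnon-DDI
"""


def reference_calls() -> pd.DataFrame:
    """Published per-tier MN flags, per-analysis calls and overall calls."""
    return pd.read_csv(io.StringIO(_CALLS_TSV), sep="\t")


def chemical_truth() -> pd.Series:
    """DDI / non-DDI truth class per reference test chemical."""
    return pd.Series({name: d["truth"] for name, d in STUDY_DESIGN.items()},
                     name="truth_class")
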