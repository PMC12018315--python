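"""Reference descriptor panels from the original competition analysis.

The anti-breast-cancer candidate-drug competition dataset ships with a
published selection of molecular descriptors: a 20-descriptor panel driving
the ER-alpha activity (pIC50) model and five 25-descriptor panels, one per
binary ADMET endpoint (Caco-2 permeability, CYP3A4 metabolism, hERG
cardiotoxicity, HOB oral bioavailability, MN mutagenicity).  Their union —
106 distinct descriptors, 39 duplicate occurrences — forms the decision
space of the swarm optimizer.  The names are reproduced verbatim as
printed, including inconsistent separators and one known misprint; they are
canonicalized through :func:`qsaropt.names.normalize_name` on access.
"""

from __future__ import annotations

from .names import normalize_names

ADMET_PROPERTIES = ("Caco-2", "CYP3A4", "hERG", "HOB", "MN")

# 20 descriptors of the ER-alpha activity panel, in published rank order.
_ACTIVITY_RAW = [
    "LipoaffinityIndex", "BCUTc-1l", "minsssN", "minHsOH", "maxsOH",
    "ATSc3", "nHBAcc", "BCUTp-1h", "minsOH", "minHBint10",
    "MEDC-23", "MLogP", "minHBint5", "XLogP", "ATSc2",
    "mindssC", "MDEO-12", "MAXDP2", "ETA_BetaP_s", "C3SP2",
]

_ADMET_RAW = {
    "Caco-2": [
        "BCUTc-1h", "SP-1", "SP-2", "ECCEN", "SHBd",
        "SHother", "SsCH3", "SaaO", "minHBa", "minwHBa",
        "minaaO", "maxaaO", "ETA_Alpha", "ETA_Beta_s", "ETA_Eta_R_L",
        "FMF", "MDEC-23", "MLFER_S", "MLFER_L", "TopoPSA",
        "MW", "WTPT-1", "WTPT-3", "WTPT-4", "WPATH",
    ],
    "CYP3A4": [
        "ATSc1", "bpol", "VCH-6", "SP-4", "SP-7",
        "VP-2", "VP-4", "VP-7", "SHaaCH", "ETA_dEpsilon_D",
        "ETA_Eta", "WTPT-1", "Zagreb", "ATSc2", "SCH-7",
        "SP-3", "SP-5", "VP-1", "VP-3", "VP-5",
        "SHBd", "minHBa", "ETA_Beta_s", "ETA_Eta_L", "WTPT-3",
    ],
    "hERG": [
        "ATSc2", "bpol", "VP-0", "CrippenMR", "SHBint8",
        "SsOH", "maxHBd", "maxaaCH", "LipoaffinityIndex", "ETA_EtaP_F",
        "Kier2", "McGowan_Volume", "WPATH", "BCUTc-1l", "SP-1",
        "VP-1", "ECCEN", "SHother", "minaasC", "maxHsOH",
        "hmin", "ETA_EtaP", "Kier1", "Kier3", "MDEO-11",
    ],
    "HOB": [
        "ATSc2", "BCUTp-1l", "VP-3", "VP-6", "SHsOH",
        "SdO", "minsOH", "maxsOH", "hmin", "ETA_BetaP_s",
        "ETA_EtaP_F_L", "MLFER_A", "WTPT-4", "BCUTc-1l", "SC-5",
        "VP-5", "VP-7", "SsOH", "minHBa", "maxHsOH",
        "maxdO", "ETA_Shape_P", "ETA_EtaP_L", "Kier3", "MLFER_BO",
    ],
    "MN": [
        "nN", "VPC-5", "SssCH2", "minHBa", "maxsCH3",
        "ETA Epsilon 1", "ETA dEpsilon A", "ETA BetaP", "ETA EtaP B RC",
        "nHBAcc Lipinski", "MLFER E", "WTPT-3", "WTPT-5", "SCH-7",
        "nssCH2", "SssO", "mindssC", "maxsssCH", "ETA Epsilon 4",
        "ETA dEpsilon C", "ETA BetaP s", "FMF", "MLFER S", "TopoPSA",
        "WTPT-4",
    ],
}


def activity_panel() -> list[str]:
    """The 20-descriptor activity panel, normalized, in rank order."""
    return normalize_names(_ACTIVITY_RAW)


def admet_panel(prop: str) -> list[str]:
    """The 25-descriptor panel for one ADMET endpoint, normalized."""
    if prop not in _ADMET_RAW:
        raise KeyError(f"unknown ADMET property {prop!r}; expected one of {ADMET_PROPERTIES}")
    return normalize_names(_ADMET_RAW[prop])


def admet_panels() -> dict[str, list[str]]:
    """All five ADMET panels, normalized, keyed by property."""
    return {p: admet_panel(p) for p in ADMET_PROPERTIES}
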