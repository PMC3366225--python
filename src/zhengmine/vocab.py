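"""Controlled vocabularies for the CHD four-diagnostic dataset.

The 69 symptom indicators collected by the four diagnostic methods
(inspection, listening/smelling, inquiry, palpation), the 90-item clinical
biomarker panel (blood/urine routine, biochemistry, coagulation, thyroid
function, cardiac markers, ECG, echocardiography), the seven TCM syndromes
suggested by the 3-core network, and the default symptom-to-syndrome
assignments.
"""

from __future__ import annotations

SYMPTOMS: tuple[str, ...] = (
    "chest pain",
    "chest distress",
    "short breath",
    "cardiopalmus",
    "cough",
    "hypodynamia",
    "spontaneous perspiration",
    "night sweat",
    "burning sensation of five centres",
    "eyestrain",
    "dry mouth",
    "dizziness",
    "amnesia",
    "fainting feeling",
    "tinnitus",
    "insomnia",
    "irritable tantrum",
    "hypochondrium distending pain",
    "sighing",
    "depression",
    "anorexia",
    "abdominal distension",
    "epigastric fullness",
    "belching",
    "nausea and vomiting",
    "sore waist and knee",
    "frequency of micturition at night",
    "limb numbness",
    "heel pain",
    "pachylosis",
    "obesity",
    "white phlegm",
    "yellow phlegm",
    "frothy phlegm",
    "tastelessness in the mouth",
    "bitter taste in the mouth",
    "sweet taste in the mouth",
    "salty taste in the mouth",
    "viscous and greasy taste in the mouth",
    "yellow urine and oliguria",
    "clear urine in large amounts",
    "residual urine",
    "cold abdomen and waist",
    "heavy limbs",
    "darkish complexion",
    "red complexion",
    "conjunctival congestion",
    "dark color around eyes",
    "dark red lip gingiva",
    "pale lips and finger nails",
    "dark color in palatal mucosa",
    "lower abdominal tenderness",
    "faint low voice",
    "emaciation",
    "swollen tongue body",
    "tooth-marked tongue",
    "thick tongue coating",
    "greasy tongue coating",
    "thick and greasy tongue coating",
    "yellow tongue coating",
    "glossal petechia",
    "lavender subglossal collateral vessels",
    "blue purple subglossal collateral vessels",
    "mauve subglossal collateral vessels",
    "subglossal collateral vessels engorgement",
    "deep pulse",
    "thready pulse",
    "uneven pulse",
    "weak pulse",
)

# 90 clinical testing indicators, grouped by panel.
_BLOOD_ROUTINE = (
    "WBC", "NEUT#", "NEUT%", "LYMPH#", "LYMPH%", "MONO", "EO#", "BASO#",
    "RBC", "HGB", "HCT", "MCV", "MCH", "MCHC", "RDW-CV", "RDW-SD",
    "PLT", "MPV", "PDW", "PCT",
)
_URINE_ROUTINE = (
    "urine pH", "urine SG", "X TAL", "urine WBC", "urine RBC",
    "urine protein", "urine glucose", "urine ketone",
)
_BIOCHEMISTRY = (
    "ALT", "AST", "ALP", "GGT", "TBIL", "DBIL", "IBIL", "TP", "ALB", "GLB",
    "BUN", "CREA", "UA", "FBG", "TC", "TG", "LDL", "HDL", "ApoA1", "ApoB",
    "Lp(a)", "K", "Na", "Cl", "Ca", "P", "Mg", "CK", "CK-MB", "LDH",
    "HBDH", "hs-CRP",
)
_COAGULATION = ("PT", "INR", "APTT", "TT", "FIB", "D-dimer")
_THYROID = ("TSH", "FT3", "FT4", "T3", "T4")
_CARDIAC = ("TNI", "BNP")
_ECG = ("heart rate", "P-R interval", "QRS duration", "QT interval", "QTc")
_ECHO = (
    "LVEF", "E peak", "A peak", "E/A ratio", "LVEDD", "LVESD",
    "IVST", "LVPWT", "LA diameter", "AO diameter", "RV diameter", "FS",
)

BIOMARKERS: tuple[str, ...] = (
    _BLOOD_ROUTINE + _URINE_ROUTINE + _BIOCHEMISTRY + _COAGULATION
    + _THYROID + _CARDIAC + _ECG + _ECHO
)

BIOMARKER_PANELS: dict[str, tuple[str, ...]] = {
    "blood routine": _BLOOD_ROUTINE,
    "urine routine": _URINE_ROUTINE,
    "biochemistry": _BIOCHEMISTRY,
    "coagulation": _COAGULATION,
    "thyroid function": _THYROID,
    "cardiac markers": _CARDIAC,
    "ECG": _ECG,
    "echocardiography": _ECHO,
}

# The seven syndromes suggested by the 31 central (core-value-3) nodes.
SYNDROMES: tuple[str, ...] = (
    "qi deficiency",
    "qi stagnation",
    "yin deficiency",
    "yang deficiency",
    "blood stasis",
    "phlegm turbid",
    "heat",
)
UNASSIGNED = "unassigned"
# Composite excessive core syndrome used as a classification target.
PHLEGM_BLOOD_STASIS = "phlegm-blood stasis"

QI_DEFICIENCY_SYMPTOMS: tuple[str, ...] = (
    "dizziness", "hypodynamia", "spontaneous perspiration", "short breath",
    "faint low voice", "cardiopalmus", "chest distress", "weak pulse",
    "tooth-marked tongue", "tastelessness in the mouth", "anorexia",
)
PHLEGM_TURBID_SYMPTOMS: tuple[str, ...] = (
    "swollen tongue body", "fainting feeling", "white phlegm",
    "thick and greasy tongue coating",
)
BLOOD_STASIS_SYMPTOMS: tuple[str, ...] = (
    "blue purple subglossal collateral vessels",
    "subglossal collateral vessels engorgement",
    "glossal petechia", "dark color around eyes",
    "dark red lip gingiva", "limb numbness",
)

#: Published partial assignment of core symptoms to syndromes; every other
#: symptom is left "unassigned" rather than guessed.
DEFAULT_SYNDROME_MAP: dict[str, str] = {
    **{s: "qi deficiency" for s in QI_DEFICIENCY_SYMPTOMS},
    **{s: "phlegm turbid" for s in PHLEGM_TURBID_SYMPTOMS},
    **{s: "blood stasis" for s in BLOOD_STASIS_SYMPTOMS},
}

#: Symptom lifting map for the cohort generator: the two latent classification
#: targets are qi deficiency and the composite phlegm-blood stasis syndrome,
#: the phlegm-turbid and blood-stasis symptom groups both lifting the latter.
GENERATOR_SYNDROME_MAP: dict[str, str] = {
    **{s: "qi deficiency" for s in QI_DEFICIENCY_SYMPTOMS},
    **{s: PHLEGM_BLOOD_STASIS
       for s in PHLEGM_TURBID_SYMPTOMS + BLOOD_STASIS_SYMPTOMS},
}

#: The 8 biomarkers of the qi-deficiency identification mode.
QI_MODE_BIOMARKERS: tuple[str, ...] = (
    "X TAL", "RDW-CV", "K", "TSH", "MONO", "hs-CRP", "LDL", "A peak",
)
#: The 6 biomarkers of the phlegm-blood-stasis identification mode.
PHLEGM_MODE_BIOMARKERS: tuple[str, ...] = (
    "hs-CRP", "TBIL", "GGT", "PLT", "FBG", "P-R interval",
)

assert len(SYMPTOMS) == 69
assert len(BIOMARKERS) == len(set(BIOMARKERS)) == 90
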