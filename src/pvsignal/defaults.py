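"""Shipped default inputs: drug synonym list, PT exclusion lists, and a demo
PT-to-SOC vocabulary.

The PT->SOC map shipped here is a small synthetic demonstration vocabulary in
MedDRA style (preferred terms mapped to one system organ class each); it is not
a licensed MedDRA dictionary. Users analysing real FAERS extracts should supply
their own mapping table.
"""

from __future__ import annotations

# Brand/generic name variants under which the target drug appears in the
# DRUGNAME field of real spontaneous reports (verbatim strings, matched
# case-insensitively after whitespace normalisation).
TILDRAKIZUMAB_SYNONYMS: tuple[str, ...] = (
    "TILDRAKIZUMAB",
    "IIUMYA",
    "ILUMYA",
    "SCH900222",
    "SCH-900222",
    "MK-3222",
    "BLINDED TILDRAKIZUMAB 100 MG ML INJECTION",
    "BLINDED TILDRAKIZUMAB INJECTION",
    "BLINDED TILDRAKIZUMAB",
    "TILDRAKIZUMAB ASMN",
    "ILUMYA TILDRAKIZUMAB",
    "ILUMYA TILDRAKIZUMAB ASMN",
)

# Non-drug-related preferred terms removed from reaction lists before signal
# detection (administration/handling issues, not adverse reactions).
PT_EXCLUSIONS: tuple[str, ...] = (
    "Product administration interrupted",
    "Product administration error",
    "Product distribution issue",
    "Product storage error",
    "Product dose omission issue",
    "Circumstance or information capable of leading to medication error",
    "Treatment noncompliance",
    "Needle issue",
    "Inappropriate schedule of product administration",
)

# Removed from the indications table (carries no clinical information).
INDICATION_EXCLUSIONS: tuple[str, ...] = ("Product used for unknown indication",)

# Demo PT -> SOC vocabulary with baseline per-report occurrence probabilities
# used by the synthetic generator. Baselines are order-of-magnitude realistic
# for a spontaneous-report database (common tolerability terms frequent, specific
# infections rare).
PT_VOCABULARY: tuple[tuple[str, str, float], ...] = (
    ("Drug ineffective", "General disorders and administration site conditions", 0.060),
    ("Condition aggravated", "General disorders and administration site conditions", 0.020),
    ("Fatigue", "General disorders and administration site conditions", 0.030),
    ("Therapeutic response decreased", "General disorders and administration site conditions", 0.004),
    ("Headache", "Nervous system disorders", 0.020),
    ("Dizziness", "Nervous system disorders", 0.015),
    ("Nausea", "Gastrointestinal disorders", 0.025),
    ("Diarrhoea", "Gastrointestinal disorders", 0.020),
    ("Abdominal pain", "Gastrointestinal disorders", 0.010),
    ("Rash", "Skin and subcutaneous tissue disorders", 0.018),
    ("Pruritus", "Skin and subcutaneous tissue disorders", 0.015),
    ("Psoriasis", "Skin and subcutaneous tissue disorders", 0.003),
    ("Urticaria", "Skin and subcutaneous tissue disorders", 0.006),
    ("Pneumonia", "Infections and infestations", 0.008),
    ("Urinary tract infection", "Infections and infestations", 0.006),
    ("Bronchitis", "Infections and infestations", 0.003),
    ("Upper respiratory tract infection", "Infections and infestations", 0.004),
    ("Nasopharyngitis", "Infections and infestations", 0.006),
    ("Vulvovaginal candidiasis", "Infections and infestations", 0.002),
    ("Herpes zoster", "Infections and infestations", 0.002),
    ("Atrial fibrillation", "Cardiac disorders", 0.004),
    ("Myocardial infarction", "Cardiac disorders", 0.004),
    ("Arthralgia", "Musculoskeletal and connective tissue disorders", 0.015),
    ("Back pain", "Musculoskeletal and connective tissue disorders", 0.010),
    ("Therapy cessation", "Surgical and medical procedures", 0.003),
    ("Therapy interrupted", "Surgical and medical procedures", 0.002),
    ("Injection site pain", "General disorders and administration site conditions", 0.008),
    ("Insomnia", "Psychiatric disorders", 0.008),
    ("Anxiety", "Psychiatric disorders", 0.006),
    ("Dyspnoea", "Respiratory, thoracic and mediastinal disorders", 0.010),
)

#: PT -> SOC mapping derived from the vocabulary (plus the excluded terms,
#: which belong to procedural SOCs).
PT_SOC_MAP: dict[str, str] = {pt: soc for pt, soc, _ in PT_VOCABULARY}
PT_SOC_MAP.update(
    {pt: "Injury, poisoning and procedural complications" for pt in PT_EXCLUSIONS}
)

# Indication vocabulary for the generator ("" means no indication reported).
INDICATION_TABLE: dict[str, float] = {
    "Psoriasis": 0.545,
    "Hypertension": 0.060,
    "Diabetes mellitus": 0.017,
    "Psoriatic arthropathy": 0.016,
    "Depression": 0.008,
    "Product used for unknown indication": 0.150,
    "": 0.204,
}

# Demographic sampling tables. Unknowns for sex/age/weight arise from the
# missingness block of the generator config, so these tables are conditional
# on the value being reported. Reporter, country, and outcome tables carry an
# explicit unknown/none category directly.
DEMOGRAPHIC_DISTRIBUTIONS: dict[str, dict[str, float]] = {
    # P(F)=0.399/0.84, P(M)=0.441/0.84 given 16% missing
    "sex": {"F": 0.475, "M": 0.525},
    # conditional on the 42% of reports with age
    "age": {"18-64": 0.597, "65-85": 0.383, ">=86": 0.020},
    # conditional on the 21.1% of reports with weight
    "weight": {"<50": 0.028, "50-100": 0.666, ">100": 0.306},
    "reporter": {"CN": 0.522, "HP": 0.254, "MD": 0.164, "PH": 0.031, "OT": 0.008, "": 0.021},
    "country": {"US": 0.681, "DE": 0.083, "ES": 0.051, "GB": 0.041, "AU": 0.032, "FR": 0.050, "CA": 0.062},
    # single worst outcome per report; "" = no outcome record filed
    "outcome": {"OT": 0.240, "HO": 0.140, "DE": 0.028, "LT": 0.012, "DS": 0.006, "CA": 0.002, "": 0.572},
}

BACKGROUND_DRUGS: tuple[tuple[str, float], ...] = (
    ("ADALIMUMAB", 0.14),
    ("USTEKINUMAB", 0.08),
    ("SECUKINUMAB", 0.08),
    ("ETANERCEPT", 0.07),
    ("METHOTREXATE", 0.10),
    ("IBUPROFEN", 0.09),
    ("METFORMIN", 0.09),
    ("LISINOPRIL", 0.08),
    ("ATORVASTATIN", 0.09),
    ("OMEPRAZOLE", 0.08),
    ("PREDNISONE", 0.06),
    ("ASPIRIN", 0.04),
)
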