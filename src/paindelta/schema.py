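"""Column dictionary for the admission-assessment cohort table.

One row per admission assessment. Categorical items are stored as small
integer codes (pandas nullable ``Int64`` round-trips through CSV); an empty
field / NA means the item was not completed. The labels below document the
codes; they mirror the MDS 3.0 admission-assessment items the analysis uses.
"""

from __future__ import annotations

# ---------------------------------------------------------------------------
# Identifiers / structure
ID = "resident_id"
ADMISSION_SEQ = "admission_seq"  # 1 = first admission of the year
BLOCK = "block_id"               # imputation block (stand-in for state)

# Demographics
AGE_GROUP = "age_group"          # 0: 50-64, 1: 65-74, 2: 75-84, 3: 85+
AGE_LABELS = ["50-64", "65-74", "75-84", "85+"]
GENDER = "gender"                # 0: male, 1: female
RACE = "race_ethnicity"          # 0: white NH, 1: black NH, 2: hispanic, 3: other
RACE_LABELS = ["white_nh", "black_nh", "hispanic", "other"]
MARITAL = "marital_status"       # 0 never, 1 married, 2 widowed, 3 separated, 4 divorced
MARITAL_LABELS = ["never_married", "married", "widowed", "separated", "divorced"]
AGE_YEARS = "age_years"          # integer age, used only by the inclusion filter

# Clinical status
COMATOSE = "comatose"            # 0/1
BIMS = "bims"                    # 0-15, NA if interview not completed
CPS = "cps"                      # 0-6, NA unless BIMS missing
ADL_SCORE = "adl_score"          # ADL hierarchy 0-6

# Comorbidity flags (0/1), the Table-1 set
COMORBIDITIES = [
    "cancer", "heart_failure", "cad", "vte", "pvd",
    "cirrhosis", "gerd_ulcer", "ibd", "uti", "pneumonia",
    "diabetes", "thyroid", "arthritis", "osteoporosis", "fracture",
    "dementia", "anxiety", "depression", "asthma_copd", "resp_failure",
]

# PHQ mood items, frequency over the last 2 weeks
# 0: never/1 day, 1: 2-6 days, 2: 7-11 days, 3: 12-14 days
PHQ_ITEMS = ["phq_little_interest", "phq_down", "phq_tired"]

# Resident-reported pain channel (past 5 days)
RES_PRESENCE = "res_pain_presence"    # 0 no, 1 yes
RES_FREQ = "res_pain_freq"            # 0 no pain, 1 rarely, 2 occasionally,
FREQ_LABELS = ["no_pain", "rarely", "occasionally", "frequently", "almost_constantly"]
RES_EFFECT = "res_pain_effect"        # pain made it hard to sleep / limited activity; 0/1
RES_NUMERIC = "res_pain_numeric"      # 0-10 numeric rating
RES_VERBAL = "res_pain_verbal"        # 0 no pain, 1 mild, 2 moderate, 3 severe, 4 very severe
VERBAL_LABELS = ["no_pain", "mild", "moderate", "severe", "very_severe"]

# Staff-assessed pain channel (completed when the resident cannot self-report)
STAFF_BEHAVIORS = [
    "staff_nonverbal_sounds", "staff_vocal_complaints",
    "staff_facial_expressions", "staff_protective_movements",
]                                      # each 0/1
STAFF_FREQ = "staff_pain_freq"         # 1: 1-2 days, 2: 3-4 days, 3: daily
STAFF_FREQ_LABELS = {1: "1-2_days", 2: "3-4_days", 3: "daily"}

# Pharmacologic pain management
PAIN_MGMT = "pain_mgmt"                # 0 none, 1 PRN only, 2 scheduled only, 3 scheduled+PRN
PAIN_MGMT_LABELS = ["none", "prn_only", "scheduled_only", "scheduled_prn"]

# Derived by cohort_prep
COG_CAT = "cognitive_category"         # "no_mild" / "moderate" / "severe"
ADL_CAT = "adl_category"               # "no_minimal" / "moderate" / "severe"
STAFF_PRESENCE = "staff_pain_presence"  # any of the four behaviors observed

STRATA = ["no_mild", "moderate", "severe"]
IMPAIRED_STRATA = ["moderate", "severe"]
ADL_CATS = ["no_minimal", "moderate", "severe"]

RES_PAIN_ITEMS = [RES_PRESENCE, RES_FREQ, RES_EFFECT, RES_NUMERIC, RES_VERBAL]

ALL_COLUMNS = (
    [ID, ADMISSION_SEQ, BLOCK, AGE_GROUP, AGE_YEARS, GENDER, RACE, MARITAL,
     COMATOSE, BIMS, CPS, ADL_SCORE]
    + COMORBIDITIES
    + PHQ_ITEMS
    + RES_PAIN_ITEMS
    + STAFF_BEHAVIORS
    + [STAFF_FREQ, PAIN_MGMT]
)
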