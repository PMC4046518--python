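"""Default word pools for the synthetic terminology generator.

Anatomy entries are (noun, adjectival form or None, synonym or None); the
adjectival forms are exactly those recoverable by the default derivation
table of :mod:`smqforge.structuring`.  Pathology entries are
(base word, synonym tuple); synonyms are globally unique strings so that
substitution never collides across concepts.  Decoy words appear in the
synonym lexicon but in no term label, and noise words build labels that no
structuring rule should relate to anything.
"""

from __future__ import annotations

ANATOMY_POOL: tuple[tuple[str, str | None, str | None], ...] = (
    ("artery", "arterial", None),
    ("abdomen", "abdominal", "belly"),
    ("muscle", "muscular", "musculus"),
    ("ventricle", "ventricular", None),
    ("clavicle", "clavicular", None),
    ("follicle", "follicular", None),
    ("cortex", "cortical", None),
    ("sternum", "sternal", None),
    ("rectum", "rectal", None),
    ("duodenum", "duodenal", None),
    ("cranium", "cranial", None),
    ("pericardium", "pericardial", None),
    ("ileum", "ileal", None),
    ("jejunum", "jejunal", None),
    ("atrium", "atrial", None),
    ("thymus", "thymic", None),
    ("orbit", "orbital", None),
    ("duct", "ductal", None),
    ("tendon", None, "sinew"),
    ("ligament", None, None),
    ("shoulder", None, None),
    ("elbow", None, None),
    ("wrist", None, "carpus"),
    ("hip", None, None),
    ("knee", None, None),
    ("ankle", None, None),
    ("spine", None, "backbone"),
    ("liver", None, None),
    ("kidney", None, None),
    ("stomach", None, None),
    ("colon", None, None),
    ("pancreas", None, None),
    ("spleen", None, None),
    ("gallbladder", None, None),
    ("oesophagus", None, "gullet"),
    ("heart", None, None),
    ("aorta", None, None),
    ("vein", None, None),
    ("capillary", None, None),
    ("valve", None, None),
    ("lung", None, None),
    ("bronchus", None, None),
    ("trachea", None, "windpipe"),
    ("larynx", None, None),
    ("pharynx", None, None),
    ("tonsil", None, None),
    ("sinus", None, None),
    ("nostril", None, None),
    ("eye", None, None),
    ("retina", None, None),
    ("cornea", None, None),
    ("iris", None, None),
    ("sclera", None, None),
    ("conjunctiva", None, None),
    ("eyelid", None, None),
    ("ear", None, None),
    ("cochlea", None, None),
    ("skin", None, "cutis"),
    ("dermis", None, None),
    ("scalp", None, None),
    ("nail", None, None),
    ("brain", None, None),
    ("cerebellum", None, None),
    ("thalamus", None, None),
    ("nerve", None, None),
    ("ganglion", None, None),
    ("meninges", None, None),
    ("bladder", None, None),
    ("urethra", None, None),
    ("ureter", None, None),
    ("prostate", None, None),
    ("uterus", None, "womb"),
    ("ovary", None, None),
    ("cervix", None, None),
    ("testis", None, None),
    ("breast", None, None),
    ("thyroid", None, None),
    ("pituitary", None, None),
    ("marrow", None, None),
    ("tongue", None, None),
    ("gum", None, "gingiva"),
    ("tooth", None, None),
    ("jaw", None, None),
    ("lip", None, None),
    ("palate", None, None),
    ("throat", None, None),
    ("neck", None, None),
    ("chest", None, "thorax"),
    ("pelvis", None, None),
    ("groin", None, None),
    ("thigh", None, None),
    ("calf", None, None),
    ("foot", None, None),
    ("toe", None, None),
    ("hand", None, None),
    ("finger", None, "digit"),
    ("forearm", None, None),
    ("scapula", None, None),
    ("rib", None, None),
    ("skull", None, None),
    ("femur", None, None),
    ("tibia", None, None),
)

PATHOLOGY_POOL: tuple[tuple[str, tuple[str, ...]], ...] = (
    ("pain", ("ache", "soreness")),
    ("oedema", ("swelling",)),
    ("haemorrhage", ("bleeding",)),
    ("ulcer", ("sore",)),
    ("spasm", ("cramp",)),
    ("rupture", ("laceration",)),
    ("stenosis", ("narrowing",)),
    ("abscess", ("boil",)),
    ("necrosis", ("gangrene",)),
    ("fibrosis", ("scarring",)),
    ("pruritus", ("itching",)),
    ("paraesthesia", ("tingling",)),
    ("asthenia", ("weakness",)),
    ("fracture", ("crack",)),
    ("dislocation", ("luxation",)),
    ("infection", ("sepsis",)),
    ("tumour", ("neoplasm", "growth")),
    ("cyst", ("vesicle",)),
    ("palsy", ("paralysis",)),
    ("tremor", ("shaking",)),
    ("atrophy", ("wasting",)),
    ("hypertrophy", ("enlargement",)),
    ("obstruction", ("blockage",)),
    ("perforation", ("puncture",)),
    ("thrombosis", ("clotting",)),
    ("embolism", ("occlusion",)),
    ("aneurysm", ("dilatation",)),
    ("ischaemia", ("hypoxia",)),
    ("infarction", ("infarct",)),
    ("degeneration", ("deterioration",)),
    ("calcification", ("mineralisation",)),
    ("contusion", ("bruise",)),
    ("xerosis", ("dryness",)),
    ("discharge", ("secretion",)),
    ("discolouration", ("staining",)),
    ("hyperplasia", ("overgrowth",)),
    ("prolapse", ("descent",)),
    ("herniation", ("protrusion",)),
    ("erosion", ("abrasion",)),
    ("congestion", ("engorgement",)),
    ("inflammation", ("irritation",)),
    ("dysplasia", ("malformation",)),
    ("stiffness", ("rigidity",)),
    ("nodule", ("lump",)),
    ("erythema", ("redness",)),
    ("neuralgia", ("hyperaesthesia",)),
    ("effusion", ("exudate",)),
    ("torsion", ("twisting",)),
    ("adhesion", ("tethering",)),
    ("haematoma", ("ecchymosis",)),
)

#: single-word noise terms; each gets its own abnormality-axis concept
NOISE_SINGLE_WORDS: tuple[str, ...] = (
    "malaise", "vertigo", "syncope", "fatigue", "insomnia",
    "anorexia", "dyspepsia", "polyuria", "dysuria", "photophobia",
    "tinnitus", "diplopia", "epistaxis", "hiccups", "sneezing",
    "yawning", "shivering", "flushing", "sweating", "drooling",
)

#: heads and modifiers for two-word noise terms; heads are never terms
NOISE_HEADS: tuple[str, ...] = ("dizziness", "restlessness", "irritability", "drowsiness", "stupor")
NOISE_MODIFIERS: tuple[str, ...] = ("transient", "intermittent", "recurrent", "nocturnal")

#: lexicon pairs whose words occur in no label (exercise precision)
DECOY_SYNONYM_PAIRS: tuple[tuple[str, str], ...] = (
    ("accord", "concordance"),
    ("aceperone", "acetabutone"),
    ("quiescence", "dormancy"),
    ("lassitude", "languor"),
    ("turbidity", "cloudiness"),
    ("friability", "crumbliness"),
    ("pliability", "suppleness"),
    ("viscosity", "thickness"),
    ("opacity", "haziness"),
    ("granularity", "coarseness"),
)

SOC_REGIONS: tuple[str, ...] = (
    "musculoskeletal", "cardiovascular", "gastrointestinal",
    "respiratory", "neurological", "dermatological",
    "urological", "ophthalmic", "endocrine", "haematological",
)
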