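"""Fixed vocabularies shared by every stage of the pipeline.

The class vocabulary is the 33 TCGA study abbreviations plus ``NORM`` for
non-cancerous tissue.  Its order is the canonical ordering used for one-hot
encoding, confusion matrices and report rows, so it lives in exactly one
place.
"""

CANCER_CODES: tuple[str, ...] = (
    "ACC", "BLCA", "BRCA", "CESC", "CHOL", "COAD", "DLBC", "ESCA", "GBM",
    "HNSC", "KICH", "KIRC", "KIRP", "LAML", "LGG", "LIHC", "LUAD", "LUSC",
    "MESO", "OV", "PAAD", "PCPG", "PRAD", "READ", "SARC", "SKCM", "STAD",
    "TGCT", "THCA", "THYM", "UCEC", "UCS", "UVM",
)

NORMAL_LABEL = "NORM"

#: the full 34-label vocabulary, cancers first then NORM
CLASS_LABELS: tuple[str, ...] = CANCER_CODES + (NORMAL_LABEL,)

#: sample types; metastatic/recurrent samples are held out of training
SAMPLE_TYPES: tuple[str, ...] = ("primary", "metastatic", "recurrent", "normal_tissue")

#: tokens treated as missing in beta matrices (matched case-insensitively)
NA_TOKENS: frozenset[str] = frozenset({"na", "nan", ""})
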