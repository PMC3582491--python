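"""Literal reference data for the APP promoter proximal regulatory element (PRE).

The PRE is the 30-nt segment at -76..-47 of the human APP promoter
(TSS = +1, no position 0).  This module carries the published inputs the
analyses operate on: the literal transcription-factor site catalog with
molecular weights, the wildtype and mutant 30-mers used in the gel-shift
(EMSA) study, the natural SNP variants of the genomic PRE, and the
adjusted group means / anchor effect sizes from the mutant EMSA + reporter
ELISA experiments that serve as the worked example for the effect-size
statistics.

Mutant labelling: the published oligomer list prints the "M4" label twice;
the two rows are resolved here by their site-level consequences (the first
deletes the GATA/SP1(II) sites and creates GR/PR sites -> M4; the second
alters the 5' end and deletes the R/TCERG1(I) sites -> M5), which makes the
literal-string site diffs agree with the published deleted-site table for
the single-string factors.
"""

from __future__ import annotations

# ---------------------------------------------------------------------------
# Coordinates (promoter convention: ..., -2, -1, +1, +2, ...; no zero)
# ---------------------------------------------------------------------------

PRE_START = -76
PRE_END = -47
ALIGNMENT_START = -326
ALIGNMENT_END = +202

# ---------------------------------------------------------------------------
# TF site catalog: factor -> (literal site strings, molecular weights in kDa)
# Lowercase letters are flanking context bases matched case-insensitively.
# ---------------------------------------------------------------------------

TF_SITE_CATALOG: dict[str, dict] = {
    "AP2": {"sites": ["GGGGTGGGCCG"], "kda": [32, 40, 47, 48, 49, 50, 51, 52]},
    "BTEB1": {"sites": ["GAGCGG", "GGCCGG"], "kda": []},
    "BTEB2": {"sites": ["GAGCGG", "GGCCGG"], "kda": [25]},
    "GATA1": {"sites": ["GGGTGGGC", "CCGGATCAGc"], "kda": [43, 51]},
    "GATA2": {"sites": ["CCGGATCAGc"], "kda": [50]},
    "Msx1": {"sites": ["GAGCGG", "GGCCGG"], "kda": [31]},
    "Pax4a": {"sites": ["GGGGTGGGCCGG"], "kda": [38]},
    "PuF": {"sites": ["GGGTGGG"], "kda": [17]},
    "R": {"sites": ["GTGCCGAGCGGGGTGGGC"], "kda": [67]},
    "SP1": {
        "sites": ["GGGTGG", "TGGGCCGGATCAGctg", "GAGCGG", "GGCCGG"],
        "kda": [81, 95, 105],
    },
    "TCERG1": {"sites": ["CGAGTG", "CGAGCG"], "kda": [122, 124]},
    "USF1": {"sites": ["GGATCAGctgactc"], "kda": [34, 43, 55]},
    "USF2": {"sites": ["GGATCAGctgactc"], "kda": [37, 44]},
}

# ---------------------------------------------------------------------------
# EMSA oligomers (forward strands, 30 nt).  The wildtype oligomer starts
# TCGA... (a filled cloning overhang); the genomic wildtype starts TCGG...
# ---------------------------------------------------------------------------

EMSA_OLIGOMERS: dict[str, str] = {
    "PRE": "TCGAGTGCCGAGCGGGGTGGGCCGGATCAG",
    "M1": "TCGAGTGCCGAGCGGGGTGGTACCGATCAG",
    "M2": "TCGAGTGCCGAGCGCTGTGGGCCGGATCAG",
    "M3": "TCGAGTCGCGAGCGGGGTGGGCCGGATCAG",
    "M4": "TCGAGTGCCGAGCGGGGTGGGCCTGTACAG",
    "M5": "TCCATGGCCGAGCGGGGTGGGCCGGATCAG",
    "M6": "TCGAGTGCCGATCGGGGTGGGCCGGATCAG",
    "M7": "TCGAGTCCGGAGCGGGGTGGGCCGGATCAG",
}

# 3' plasmid context downstream of the PRE in the reporter clone, used when
# scanning catalog entries whose lowercase context extends past the 30-mer.
PLASMID_CONTEXT_3P = "CTGACTTGCC"

# Genomic PRE and its two reported natural SNP variants (plus the combined
# double-SNP haplotype).
GENOMIC_PRE: dict[str, str] = {
    "wildtype": "TCGGGTGCCGAGCGGGGTGGGCCGGATCAG",
    "rs201592736": "TCGGGTGCCGAGCGAGGTGGGCCGGATCAG",
    "rs200621906": "TCGGGTGCCGAGCGGGGTGGGCCAGATCAG",
    "both": "TCGGGTGCCGAGCGAGGTGGGCCAGATCAG",
}

# ---------------------------------------------------------------------------
# Worked example: published adjusted group means (control-anchored) and the
# published M1 effect size used to recover sqrt(MSerror) for each assay
# column.  Design: k = 8 groups (wildtype PRE + M1..M7), n = 3 replicates.
# EMSA columns are film-standardized (control mean 0); ELISA columns are
# ratio-normalized (control mean 1).
# ---------------------------------------------------------------------------

VARIANT_ORDER = ["PRE", "M1", "M2", "M3", "M4", "M5", "M6", "M7"]

WORKED_EXAMPLE = {
    "NB": {
        "emsa_band_I": {
            "means": [0.00, 1.81, -1.33, 0.60, 0.40, -0.28, 0.27, 1.00],
            "control_mean": 0.0,
            "anchor": ("M1", 3.24),
            "published_psi": 1.65,
        },
        "emsa_band_II": {
            "means": [0.00, -1.76, -0.43, 0.79, -1.62, 0.07, -0.61, 0.87],
            "control_mean": 0.0,
            "anchor": ("M1", -4.86),
            "published_psi": 2.72,
        },
        "elisa": {
            "means": [1.00, 0.37, 0.81, 1.69, 0.89, 0.34, 0.16, 1.04],
            "control_mean": 1.0,
            "anchor": ("M1", -3.12),
            "published_psi": 2.43,
        },
    },
    "PC12": {
        "emsa_band_I": {
            "means": [0.00, 1.25, -0.91, 0.56, 0.61, 0.16, 0.27, 1.46],
            "control_mean": 0.0,
            "anchor": ("M1", 1.77),
            "published_psi": 1.09,
        },
        "emsa_band_II": {
            "means": [0.00, -1.38, -0.14, 1.20, -1.04, 0.30, -0.25, 1.58],
            "control_mean": 0.0,
            "anchor": ("M1", -5.56),
            "published_psi": 4.05,
        },
        "elisa": {
            "means": [1.00, 0.39, 0.67, 0.83, 0.45, 0.43, 0.43, 1.03],
            "control_mean": 1.0,
            "anchor": ("M1", -6.84),
            "published_psi": 2.89,
        },
    },
}

# Published pairwise effect sizes (g) per assay column, for the EMSA-vs-ELISA
# correlation meta-analysis.  Order follows VARIANT_ORDER; the wildtype
# control contributes the (0, 0) pair.
EFFECT_SIZE_TABLE = {
    "NB": {
        "emsa_band_I": [0.00, 3.24, -2.39, 1.07, 0.72, -0.51, 0.48, 1.78],
        "emsa_band_II": [0.00, -4.86, -1.18, 2.19, -4.48, 0.19, -1.68, 2.41],
        "elisa": [0.00, -3.12, -0.91, 3.40, -0.52, -3.24, -4.14, 0.18],
    },
    "PC12": {
        "emsa_band_I": [0.00, 1.77, -1.43, 0.84, 0.91, 0.25, 0.41, 2.04],
        "emsa_band_II": [0.00, -5.56, -0.56, 4.82, -4.20, 1.23, -1.01, 6.36],
        "elisa": [0.00, -6.84, -2.05, -0.80, -5.33, -5.69, -5.68, 0.12],
    },
}

# Published deleted-site assignments for each mutant oligomer (factor level).
DELETED_SITES_TABLE = {
    "M1": {"AP2", "GATA1", "GC Box (II)", "PuF", "R", "SP1 (I)"},
    "M2": {"AP2", "GC Box (I)", "GATA1", "Pax4a", "PuF", "SP1 (I)"},
    "M3": {"R", "TCERG1 (I)"},
    "M4": {"GATA1/GATA2", "SP1 (II)"},
    "M5": {"R", "TCERG1 (I)"},
    "M6": {"TCERG1 (II)"},
    "M7": {"TCERG1 (I, II)", "R"},
}
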