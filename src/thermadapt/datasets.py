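"""Published reference tables bundled for worked examples and checks.

Two small tables from a comparative study of Arctic (Kongsfjord) and
Subarctic (Porsangerfjord) *Strongylocentrotus* sea-urchin populations:

* the COG functional-category tally of convergent amino acid
  substitutions (CAAS) detected between the populations, and
* per-group summary statistics (mean, SD, n = 5) of digestive-enzyme
  activities at 5 °C and 10 °C and of activation energies fitted over
  2–20 °C, for stomach and intestine tissue.

These are *inputs* (printed counts and summaries), not expected
outputs: percentages, p-values and the like are always recomputed by
the package.
"""

from __future__ import annotations

import pandas as pd

_COG_ROWS = [
    # category, subcategory (COG letter), count
    ("Cellular processes and signaling", "Signal transduction mechanisms (T)", 78),
    ("Cellular processes and signaling",
     "Posttranslational modification, protein turnover, chaperones (O)", 64),
    ("Cellular processes and signaling", "RNA processing and modification (A)", 19),
    ("Cellular processes and signaling",
     "Intracellular trafficking, secretion, and vesicular transport (U)", 14),
    ("Cellular processes and signaling", "Cytoskeleton (Z)", 11),
    ("Cellular processes and signaling", "Chromatin structure and dynamics (B)", 9),
    ("Cellular processes and signaling", "Defense mechanisms (V)", 9),
    ("Cellular processes and signaling",
     "Cell cycle control, cell division, chromosome partitioning (D)", 6),
    ("Cellular processes and signaling",
     "Cell wall/membrane/envelope biogenesis (M)", 3),
    ("Cellular processes and signaling", "Extracellular structures (W)", 3),
    ("Cellular processes and signaling", "Nuclear structure (Y)", 1),
    ("Metabolism", "Carbohydrate transport metabolism (G)", 34),
    ("Metabolism", "Lipid transport metabolism (I)", 29),
    ("Metabolism", "Amino acid transport metabolism (E)", 26),
    ("Metabolism", "Energy production conversion (C)", 15),
    ("Metabolism",
     "Secondary metabolites biosynthesis transport catabolism (Q)", 13),
    ("Metabolism", "Inorganic ion transport metabolism (P)", 9),
    ("Metabolism", "Nucleotide transport metabolism (F)", 6),
    ("Information storage and processing",
     "Translation, ribosomal structure and biogenesis (J)", 23),
    ("Information storage and processing", "Transcription (K)", 18),
    ("Information storage and processing",
     "Replication, recombination, and repair (L)", 16),
    ("Information storage and processing",
     "RNA processing and modification (A)", 2),
    ("Poorly characterized", "Function unknown (S)", 169),
]


def cog_category_counts() -> pd.DataFrame:
    """CAAS counts per COG category/subcategory (columns: category,
    subcategory, count)."""
    return pd.DataFrame(_COG_ROWS, columns=["category", "subcategory", "count"])


# (tissue, enzyme, measure) -> arctic mean, arctic sd, subarctic mean,
# subarctic sd; n = 5 per group throughout.  "activity_5C"/"activity_10C"
# are assay rates at that temperature; "ea" is the activation energy in
# kJ/mol fitted between 2 and 20 C.
_ENZYME_ROWS = [
    ("stomach", "Esterase (C4)", "activity_5C", 2.404, 0.189, 2.038, 0.688),
    ("stomach", "Esterase (C4)", "activity_10C", 3.565, 0.519, 4.901, 1.520),
    ("stomach", "Esterase (C4)", "ea", 50.102, 7.144, 60.406, 7.658),
    ("stomach", "Esterase (C7)", "activity_5C", 3.895, 0.654, 4.322, 1.416),
    ("stomach", "Esterase (C7)", "activity_10C", 4.642, 0.644, 7.113, 2.121),
    ("stomach", "Esterase (C7)", "ea", 51.017, 5.672, 53.396, 2.941),
    ("stomach", "Ala-AP", "activity_5C", 0.045, 0.009, 0.031, 0.009),
    ("stomach", "Ala-AP", "activity_10C", 0.067, 0.013, 0.042, 0.011),
    ("stomach", "Ala-AP", "ea", 49.579, 2.460, 47.642, 7.757),
    ("stomach", "Leu-AP", "activity_5C", 0.032, 0.010, 0.013, 0.003),
    ("stomach", "Leu-AP", "activity_10C", 0.043, 0.018, 0.022, 0.005),
    ("stomach", "Leu-AP", "ea", 43.621, 5.838, 45.490, 7.923),
    ("stomach", "alpha-glucosidase", "activity_5C", 0.033, 0.003, 0.033, 0.014),
    ("stomach", "alpha-glucosidase", "activity_10C", 0.053, 0.006, 0.049, 0.024),
    ("stomach", "alpha-glucosidase", "ea", 55.964, 3.617, 43.840, 5.693),
    ("stomach", "beta-galactosidase", "activity_5C", 0.007, 0.001, 0.004, 0.001),
    ("stomach", "beta-galactosidase", "activity_10C", 0.011, 0.003, 0.008, 0.002),
    ("stomach", "beta-galactosidase", "ea", 52.109, 4.843, 61.766, 9.190),
    ("stomach", "beta-glucosidase", "activity_5C", 0.044, 0.014, 0.018, 0.004),
    ("stomach", "beta-glucosidase", "activity_10C", 0.062, 0.022, 0.027, 0.007),
    ("stomach", "beta-glucosidase", "ea", 48.319, 5.036, 41.935, 4.911),
    ("intestine", "Esterase (C4)", "activity_5C", 1.773, 0.558, 1.294, 0.338),
    ("intestine", "Esterase (C4)", "activity_10C", 2.588, 1.178, 3.171, 0.843),
    ("intestine", "Esterase (C4)", "ea", 47.058, 7.724, 58.907, 4.888),
    ("intestine", "Esterase (C7)", "activity_5C", 2.568, 1.075, 1.918, 0.513),
    ("intestine", "Esterase (C7)", "activity_10C", 4.568, 2.131, 2.862, 0.654),
    ("intestine", "Esterase (C7)", "ea", 51.852, 6.706, 55.063, 3.029),
    ("intestine", "Ala-AP", "activity_5C", 0.058, 0.015, 0.045, 0.018),
    ("intestine", "Ala-AP", "activity_10C", 0.085, 0.022, 0.073, 0.027),
    ("intestine", "Ala-AP", "ea", 45.881, 4.725, 60.190, 5.255),
    ("intestine", "Leu-AP", "activity_5C", 0.033, 0.012, 0.031, 0.008),
    ("intestine", "Leu-AP", "activity_10C", 0.047, 0.018, 0.052, 0.009),
    ("intestine", "Leu-AP", "ea", 39.255, 3.903, 55.345, 9.528),
    ("intestine", "alpha-glucosidase", "activity_5C", 0.032, 0.004, 0.031, 0.014),
    ("intestine", "alpha-glucosidase", "activity_10C", 0.051, 0.006, 0.048, 0.023),
    ("intestine", "alpha-glucosidase", "ea", 51.171, 3.468, 54.148, 3.722),
    ("intestine", "beta-galactosidase", "activity_5C", 0.006, 0.001, 0.006, 0.002),
    ("intestine", "beta-galactosidase", "activity_10C", 0.013, 0.004, 0.009, 0.003),
    ("intestine", "beta-galactosidase", "ea", 52.046, 5.866, 47.357, 5.032),
    ("intestine", "beta-glucosidase", "activity_5C", 0.090, 0.058, 0.040, 0.011),
    ("intestine", "beta-glucosidase", "activity_10C", 0.134, 0.076, 0.059, 0.016),
    ("intestine", "beta-glucosidase", "ea", 41.962, 4.502, 40.540, 4.496),
]


def enzyme_summary() -> pd.DataFrame:
    """Published digestive-enzyme summary statistics (n = 5 per group).

    Columns: tissue, enzyme, measure, arctic_mean, arctic_sd,
    subarctic_mean, subarctic_sd, n.
    """
    df = pd.DataFrame(
        _ENZYME_ROWS,
        columns=[
            "tissue", "enzyme", "measure",
            "arctic_mean", "arctic_sd", "subarctic_mean", "subarctic_sd",
        ],
    )
    df["n"] = 5
    return df
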