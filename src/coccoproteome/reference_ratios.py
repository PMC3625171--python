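"""Published per-replicate protein expression ratios used for validation.

These are the replicate iTRAQ ratio triples (114:113, 116:115, 118:117;
high-CO2 : ambient) reported for every quantified homologous protein group
in the E. huxleyi NZEH ocean-acidification experiment that this pipeline
re-implements, together with the published geometric-mean 95% CI range
(rounded to 2 decimal places as printed).  They serve as reference inputs:
feeding the triples through :func:`coccoproteome.itraq.replicate_geomean_ci`
and :func:`coccoproteome.itraq.classify_regulation` should recover the
published ranges and the published census of four down-regulated groups
(histones H2A, H3, H4 and a chloroplastic 30S ribosomal protein S7) with no
up-regulated group.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["reference_ratio_table", "REFERENCE_RATIOS"]

# (identification, accession/cluster, r1, r2, r3, published_low, published_high)
REFERENCE_RATIOS = [
    ("30S ribosomal protein S7", "Q4G343", 0.28, 0.45, 0.61, 0.27, 0.66),
    ("Histone H2A", "D0MWJ7", 0.49, 0.41, 0.39, 0.37, 0.49),
    ("Histone H2A", "87a", 0.62, 0.55, 0.45, 0.45, 0.64),
    ("Histone H2A", "EHUXJGI72235", 0.49, 0.45, 0.39, 0.38, 0.50),
    ("Histone H3", "EHUXJGI255477", 0.36, 0.20, 0.32, 0.20, 0.40),
    ("Histone H4", "C1MUM2", 0.37, 0.25, 0.56, 0.24, 0.59),
    ("Histone H4", "92a", 0.37, 0.25, 0.56, 0.24, 0.59),
    ("Histone H4", "EHUXJGI201707", 0.37, 0.22, 0.39, 0.21, 0.46),
    ("40S ribosomal protein S12", "81a", 2.09, 2.01, 0.27, 0.28, 3.90),
    ("40S ribosomal protein S12", "EHUXJGI240824", 2.01, 1.87, 0.28, 0.29, 3.60),
    ("50S ribosomal protein L12 (chloroplastic)", "86a", 1.95, 1.88, 0.24, 0.25, 3.70),
    ("50S ribosomal protein L12 (chloroplastic)", "EHUXJGI86748", 1.86, 1.83, 0.23, 0.24, 3.60),
    ("Acyl carrier protein", "97a", 1.81, 2.47, 1.01, 0.99, 2.76),
    ("Adenosylhomocysteinase", "26a", 0.27, 1.05, 1.27, 0.27, 1.86),
    ("Adenylate kinase (putative)", "33a", 1.45, 1.82, 0.68, 0.67, 2.18),
    ("Ankyrin repeat protein (putative)", "51a", 1.69, 1.86, 0.47, 0.47, 2.72),
    ("Apocytochrome f (precursor)", "Q4G3D7", 0.88, 0.81, 0.61, 0.61, 0.94),
    ("Apocytochrome f (precursor)", "35a", 0.88, 0.81, 0.61, 0.61, 0.94),
    ("ATP ase/synthase (vacuolar)", "91a", 2.57, 1.97, 0.44, 0.45, 3.83),
    ("ATP ase/synthase (vacuolar)", "EHUXJGI210241", 2.48, 1.88, 0.45, 0.45, 3.62),
    ("ATP synthase subunit alpha", "07a", 0.71, 0.96, 1.24, 0.69, 1.30),
    ("ATP synthase subunit alpha", "EHUXJGI199000", 0.65, 1.36, 1.06, 0.64, 1.50),
    ("ATP synthase F(1) sector subunit alpha (chloroplastic)", "Q4G397", 0.32, 0.78, 1.12, 0.32, 1.35),
    ("ATP synthase F(1) sector subunit alpha (chloroplastic)", "C7BEK1", 0.40, 0.70, 1.11, 0.38, 1.20),
    ("ATP synthase F(0) sector subunit b' (chloroplastic)", "Q4G3A0", 0.95, 0.57, 0.77, 0.56, 1.00),
    ("ATP synthase F(1) sector subunit beta (chloroplastic)", "Q4G3C8", 0.62, 1.02, 1.09, 0.63, 1.24),
    ("Chloroplast light harvesting protein isoform", "12a", 0.33, 0.57, 0.78, 0.32, 0.87),
    ("Chloroplast light harvesting protein isoform", "12b", 0.24, 0.44, 0.90, 0.22, 0.96),
    ("Clathrin small chain (putative)", "18a", 1.21, 1.36, 0.84, 0.83, 1.48),
    ("Clp protease ATP binding subunit", "Q4G3D0", 0.43, 0.59, 0.74, 0.42, 0.78),
    ("Cold shock DNA-binding protein (putative)", "96a", 2.22, 6.00, 0.47, 0.43, 7.87),
    ("Cold shock DNA-binding protein (putative)", "EHUXJGI111020", 1.23, 1.32, 0.70, 0.71, 1.55),
    ("Demethylmenaquinone methyltransferase (putative)", "09a", 1.98, 1.91, 0.40, 0.41, 3.23),
    ("ETC complex I protein (putative)", "44a", 1.29, 1.25, 0.73, 0.73, 1.51),
    ("Ferredoxin-NADP reductase", "29a", 0.59, 0.90, 0.79, 0.58, 0.96),
    ("FKBP-type peptidyl-prolyl cis-trans isomerase", "50a", 1.68, 4.68, 0.71, 0.61, 5.15),
    ("FKBP-type peptidyl-prolyl cis-trans isomerase", "50b", 0.75, 1.34, 0.67, 0.58, 1.34),
    ("FKBP-type peptidyl-prolyl cis-trans isomerase", "EHUXJGI239227", 1.58, 3.20, 0.76, 0.70, 3.53),
    ("Glycerol-3-phosphate dehydrogenase EC 1.1.1.8", "45a", 0.77, 0.91, 0.67, 0.66, 0.92),
    ("Glycerol-3-phosphate dehydrogenase EC 1.1.1.8", "EHUXJGI87542", 0.85, 0.75, 0.82, 0.75, 0.86),
    ("Histone H2B", "89a", 0.43, 0.40, 1.04, 0.31, 1.03),
    ("Histone H2B", "EHUXJGI96192", 0.43, 0.52, 0.89, 0.38, 0.90),
    ("Nascent polypetide-associated complex protein/transcription factor (putative)", "52a", 1.84, 1.82, 0.34, 0.34, 3.15),
    ("No BLAST hit", "08a", 0.76, 0.69, 0.32, 0.32, 0.94),
    ("No BLAST hit", "EHUXJGI349877", 0.82, 0.67, 0.32, 0.32, 0.99),
    ("No BLAST hit", "13a", 3.28, 1.01, 0.43, 0.36, 3.57),
    ("No BLAST hit", "EHUXJGI205571", 2.51, 1.01, 0.53, 0.45, 2.67),
    ("No BLAST hit", "57a", 1.80, 1.42, 0.39, 0.40, 2.53),
    ("No BLAST hit", "76a", 1.16, 1.27, 0.76, 0.76, 1.42),
    ("No BLAST hit", "EHUXJGI237243", 1.17, 1.36, 0.78, 0.78, 1.48),
    ("No BLAST hit", "83a", 1.90, 1.70, 0.42, 0.42, 2.87),
    ("No BLAST hit", "EHUX110219", 1.32, 1.35, 0.87, 0.88, 1.53),
    ("No BLAST hit", "EHUXJGI218259", 3.12, 2.52, 0.31, 0.31, 5.73),
    ("Periplasmic binding/iron transport lipoprotein (putative)", "EHUXJGI269712", 1.16, 0.95, 1.23, 0.95, 1.29),
    ("Phosphoglycerate kinase", "Q5ENR8", 0.91, 1.44, 1.48, 0.91, 1.70),
    ("Phosphoglycerate kinase", "11a", 0.95, 1.06, 1.06, 0.95, 1.10),
    ("Phosphoglycerate kinase", "EHUXJGI270670", 1.05, 0.99, 1.05, 0.99, 1.07),
    ("Phosphoribulokinase (chloroplastic)", "14a", 0.70, 1.35, 0.86, 0.63, 1.36),
    ("Photosystem II 12 kDa extrinsic protein (chloroplastic)", "12f", 0.70, 0.99, 0.56, 0.53, 1.01),
    ("Photosystem II oxygen evolving enhancer (chloroplastic)", "34a", 1.29, 1.09, 0.73, 0.73, 1.40),
    ("Photosystem II oxygen evolving enhancer (chloroplastic)", "27a", 1.46, 0.89, 0.82, 0.72, 1.45),
    ("Photosystem II oxygen evolving enhancer (chloroplastic)", "27b", 1.38, 0.84, 0.83, 0.71, 1.37),
    ("Photosystem II oxygen evolving enhancer (chloroplastic)", "EHUXJGI265795", 1.12, 1.10, 0.72, 0.72, 1.27),
    ("Predicted protein", "65a", 1.85, 1.55, 0.54, 0.54, 2.46),
    ("Predicted protein", "82a", 1.51, 1.67, 0.29, 0.30, 2.73),
    ("Predicted protein", "21a", 0.98, 0.91, 0.72, 0.72, 1.04),
    ("Predicted protein", "21b", 0.98, 0.91, 0.72, 0.72, 1.04),
    ("Predicted protein", "21c", 1.46, 1.47, 0.67, 0.68, 1.88),
    ("Predicted protein", "72a", 1.72, 1.45, 0.56, 0.56, 2.22),
    ("Predicted protein", "84a", 2.31, 7.08, 0.48, 0.43, 9.20),
    ("Predicted protein", "EHUXJGI96453", 2.22, 7.28, 0.47, 0.41, 9.32),
    ("Predicted protein", "EHUXJGI243179", 2.26, 7.38, 0.46, 0.41, 9.54),
    ("Ribulose bisphosphate carboxylase large chain", "Q4G3F4", 0.17, 0.81, 0.76, 0.17, 1.29),
    ("S-adenosylmethionine synthetase", "06a", 0.92, 0.63, 0.64, 0.57, 0.91),
    ("S-adenosylmethionine synthetase", "06b", 0.96, 0.54, 0.49, 0.42, 0.96),
    ("S-adenosylmethionine synthetase", "06c", 0.96, 0.53, 0.47, 0.40, 0.96),
    ("S-adenosylmethionine synthetase", "EHUXJGI62235", 0.91, 0.85, 0.51, 0.51, 1.05),
    ("S-adenosylmethionine synthetase", "EHUXJGI267646", 0.96, 0.83, 0.49, 0.49, 1.09),
    ("Ubiquitin family protein (putative)", "01f", 1.77, 2.18, 0.74, 0.74, 2.71),
]


def reference_ratio_table() -> pd.DataFrame:
    """The reference triples as a DataFrame (one row per accession)."""
    return pd.DataFrame(
        REFERENCE_RATIOS,
        columns=[
            "identification",
            "accession",
            "r1",
            "r2",
            "r3",
            "published_low",
            "published_high",
        ],
    )
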