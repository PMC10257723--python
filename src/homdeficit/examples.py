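"""Published worked-example data.

Summary counts from a large six-population meta-analysis of 1.52 million
North-Western Europeans (Denmark, Finland, Iceland, Norway, Sweden, UK) in
which 25 genes carried protein-altering variants with a strong deficit of
homozygosity. Only printed summary numbers are bundled — combined observed
and expected homozygote counts per reported gene, the gene-set 2x2 tables of
the over-representation analysis, and the test counts behind the multiple-
testing thresholds. They serve as ground truth for worked examples; no
individual-level data is included or needed.
"""

from __future__ import annotations

import pandas as pd

#: individuals in the combined meta-analysis
META_ANALYSIS_N = 1_520_000

#: pLOF single variants with expected homozygote count >= 5
N_PLOF_TESTS_E5 = 1736
#: geneLOF units with expected homozygote count >= 5
N_GENELOF_TESTS_E5 = 1258

_DEFICIT_ROWS = [
    # gene, impact class, combined observed O, combined expected E
    ("DHCR7", "plof", 0, 100.0),
    ("TSFM", "plof", 1, 29.2),
    ("CCDC59", "plof", 0, 21.6),
    ("ATP5PB", "plof", 0, 15.8),
    ("MTG2", "plof", 0, 13.4),
    ("BRF2", "plof", 0, 11.1),
    ("GTF2H3", "plof", 0, 10.7),
    ("CENPF", "plof", 0, 10.5),
    ("PUM3", "plof", 0, 10.2),
    ("ELOF1", "plof", 0, 10.2),
    ("PKHD1", "plof", 0, 9.62),
    ("RPAP2", "plof", 0, 9.26),
    ("WARS2", "plof", 0, 9.10),
    ("PNKP", "plof", 0, 8.53),
    ("BRIP1", "plof", 0, 7.74),
    ("GBE1", "plof", 0, 7.29),
    ("AGK", "plof", 0, 5.79),
    ("CDC7", "plof", 0, 5.34),
    ("DIAPH3", "plof", 0, 5.29),
    ("MRPS30", "moderate", 1, 48.2),
    ("PMM2", "moderate", 4, 54.1),
    ("HYLS1", "moderate", 1, 14.9),
    ("MVD", "moderate", 0, 11.1),
    ("GLE1", "moderate", 0, 11.0),
    ("CASP9", "moderate", 1, 11.9),
]


def deficit_gene_table() -> pd.DataFrame:
    """Combined observed/expected homozygote counts for the 25 reported genes."""
    return pd.DataFrame(_DEFICIT_ROWS,
                        columns=["gene", "impact_class", "observed", "expected"])


#: gene-set over-representation 2x2 tables, [[deficit&in-set, deficit&not],
#: [no-deficit&in-set, no-deficit&not]], per expected-count stratum
GENE_SET_TABLES = {
    ("ar_omim", "[1,5)"): [[39, 60], [103, 623]],
    ("ar_omim", "[5,inf)"): [[9, 10], [147, 1074]],
    ("cell_essential", "[1,5)"): [[31, 61], [30, 603]],
    ("cell_essential", "[5,inf)"): [[11, 8], [85, 942]],
    ("mouse_lethal", "[1,5)"): [[40, 30], [104, 341]],
    ("mouse_lethal", "[5,inf)"): [[13, 2], [179, 539]],
}
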