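"""Small bundled reference tables used as fixtures and regression anchors."""

from __future__ import annotations

import pandas as pd

# Published 17-linkage-group summary (marker counts, map lengths in cM and
# largest adjacent gaps) from a 98-progeny outcrossed fruit-tree family;
# used to pin down the aggregation conventions of map statistics.
_LG_ROWS = [
    ("LG1", 89, 61.9, 4.4),
    ("LG2", 58, 96.0, 15.4),
    ("LG3", 229, 68.4, 7.9),
    ("LG4", 138, 72.4, 4.0),
    ("LG5", 194, 50.4, 1.8),
    ("LG6", 208, 53.1, 5.6),
    ("LG7", 177, 88.8, 5.2),
    ("LG8", 117, 64.0, 5.2),
    ("LG9", 90, 58.8, 3.0),
    ("LG10", 151, 54.1, 2.3),
    ("LG11", 83, 58.4, 3.2),
    ("LG12", 179, 59.4, 2.2),
    ("LG13", 115, 58.7, 6.1),
    ("LG14", 124, 66.1, 5.2),
    ("LG15", 221, 63.7, 3.7),
    ("LG16", 39, 38.7, 6.9),
    ("LG17", 176, 95.1, 14.2),
]

# Published broad-sense heritabilities (plot / family-mean basis) for 14
# fruit-quality traits; kept as a magnitude reference for simulations.
_H2_ROWS = [
    ("FW", 0.85, 0.94), ("LDF", 0.88, 0.96), ("TDF", 0.83, 0.94),
    ("LDC", 0.71, 0.88), ("TDC", 0.73, 0.89), ("LFS", 0.61, 0.82),
    ("RFS", 0.61, 0.82), ("SS", 0.79, 0.92), ("HN", 0.69, 0.86),
    ("SUS", 0.52, 0.76), ("SC", 0.93, 0.97), ("TS", 0.95, 0.98),
    ("SSU", 0.98, 0.99), ("CS", 0.80, 0.92),
]


def reference_lg_table() -> pd.DataFrame:
    """17-row linkage-group summary fixture (lg, n_snps, length_cm, max_gap_cm)."""
    return pd.DataFrame(_LG_ROWS, columns=["lg", "n_snps", "length_cm", "max_gap_cm"])


def reference_h2_table() -> pd.DataFrame:
    """Published plot- and family-mean-basis heritabilities for 14 traits."""
    return pd.DataFrame(_H2_ROWS, columns=["trait", "h2_plot", "h2_family"])
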