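"""Published reference figures from the Chilean bird COI barcode survey.

These are the survey's printed sampling numbers, shipped so the package's
comparison-count accounting and reporting arithmetic can be exercised
without access to the underlying GenBank/BOLD records: per-species sample
sizes (and mean intraspecific K2P) for the 43 species represented by two
or more sequences, plus dataset-level totals.
"""

from __future__ import annotations

from importlib import resources
from math import comb

import pandas as pd

#: Dataset-level totals of the survey.
N_SPECIES = 76
N_INDIVIDUALS = 197
N_DISTINGUISHABLE = 72
ALIGNMENT_LENGTH = 443
#: Resident/regular bird species known from Chile (denominator of coverage).
N_CHILEAN_SPECIES = 443
#: Interspecific comparisons below the maximum intraspecific distance.
N_OVERLAP = 22


def intraspecific_counts() -> pd.DataFrame:
    """Per-species sample sizes for species with >=2 sequences."""
    path = resources.files("coibarcode") / "data" / "chilean_birds_intraspecific.tsv"
    with resources.as_file(path) as p:
        return pd.read_csv(p, sep="\t")


def interspecific_n_comparisons(n_species: int = N_SPECIES) -> int:
    """Species-pair accounting: one comparison per unordered species pair."""
    return comb(n_species, 2)


def intraspecific_n_comparisons(counts) -> int:
    """Individual-pair accounting: sum of C(n_i, 2) over species."""
    return int(sum(comb(int(n), 2) for n in counts))
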