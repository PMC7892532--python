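"""Species distinguishability by DNA barcode.

A species is distinguishable when (a) its individuals form a monophyletic
cluster on the rooted tree and (b) none of its individuals shares a barcode
with an individual of another species. Barcode sharing defaults to identity
over compared sites (distance 0); a positive distance threshold may be
supplied instead.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd

from .dist import DistanceMatrix
from .phylo import is_monophyletic, leaf_labels
from .seqio import Alignment


@dataclass
class SpeciesVerdict:
    species: str
    n_individuals: int
    monophyletic: bool
    shares_barcode: bool

    @property
    def distinguishable(self) -> bool:
        return self.monophyletic and not self.shares_barcode


@dataclass
class IdentificationReport:
    verdicts: list[SpeciesVerdict]

    @property
    def n_species(self) -> int:
        return len(self.verdicts)

    @property
    def n_distinguishable(self) -> int:
        return sum(v.distinguishable for v in self.verdicts)

    @property
    def rate_percent(self) -> float:
        return identification_rate(self.n_distinguishable, self.n_species)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "species": v.species,
                    "n_individuals": v.n_individuals,
                    "monophyletic": v.monophyletic,
                    "shares_barcode": v.shares_barcode,
                    "distinguishable": v.distinguishable,
                }
                for v in self.verdicts
            ]
        )

    def summary(self) -> str:
        return (
            f"{self.n_distinguishable} of {self.n_species} species distinguishable "
            f"({self.rate_percent:.1f}%)"
        )


def identification_rate(n_distinguishable: int, n_species: int) -> float:
    """Dataset-level identification rate, percent to 1 decimal."""
    return round(100.0 * n_distinguishable / n_species, 1)


def _species_indices(alignment: Alignment) -> dict[str, list[int]]:
    out: dict[str, list[int]] = {}
    for i, rec in enumerate(alignment):
        if not rec.outgroup:
            out.setdefault(rec.species, []).append(i)
    return out


def shares_barcode(
    species: str,
    dm: DistanceMatrix,
    alignment: Alignment,
    threshold: float = 0.0,
) -> bool:
    """True iff some individual of ``species`` is within ``threshold`` distance
    of an individual of a different species (outgroup excluded)."""
    groups = _species_indices(alignment)
    if species not in groups or not groups[species]:
        raise ValueError(f"species {species!r} has no individuals")
    own = groups[species]
    others = [i for sp, idx in groups.items() if sp != species for i in idx]
    pos = {rec.id: dm.labels.index(rec.id) for rec in alignment}
    ids = alignment.ids
    for i in own:
        for j in others:
            d = dm.values[pos[ids[i]], pos[ids[j]]]
            if not np.isnan(d) and d <= threshold:
                return True
    return False


def identification_report(
    tree: dendropy.Tree,
    dm: DistanceMatrix,
    alignment: Alignment,
    threshold: float = 0.0,
) -> IdentificationReport:
    """Per-species monophyly and barcode-sharing verdicts plus the overall rate.

    ``tree`` must be rooted and its leaves must be exactly the ingroup
    individuals (plus, optionally, the outgroup). Singleton species are
    monophyletic by convention and count toward the total.
    """
    groups = _species_indices(alignment)
    ids = alignment.ids
    leaves = leaf_labels(tree)
    ingroup_ids = {ids[i] for idx in groups.values() for i in idx}
    missing = ingroup_ids - leaves
    if missing:
        raise ValueError(f"tree is missing ingroup leaves: {sorted(missing)[:5]}")
    verdicts = []
    for sp in sorted(groups):
        members = {ids[i] for i in groups[sp]}
        verdicts.append(
            SpeciesVerdict(
                species=sp,
                n_individuals=len(members),
                monophyletic=is_monophyletic(tree, members),
                shares_barcode=shares_barcode(sp, dm, alignment, threshold=threshold),
            )
        )
    return IdentificationReport(verdicts=verdicts)
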