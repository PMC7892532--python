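"""Pairwise p and Kimura 2-parameter distances and their taxonomic-level summaries.

The K2P distance corrects observed transition (P) and transversion (Q)
proportions for multiple hits:

    d = -1/2 * ln((1 - 2P - Q) * sqrt(1 - 2Q))

Sites with a gap or ambiguity code in either member of a pair are excluded
(pairwise deletion). A pair for which the logarithm's argument is
non-positive is saturated: its distance is undefined and reported as NaN,
never as an error.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .seqio import Alignment

logger = logging.getLogger(__name__)

_PURINE = np.array([True, False, True, False, False])  # A,C,G,T,other


@dataclass
class PairCounts:
    """Comparable-site and mismatch counts for one sequence pair."""

    n_sites: int
    n_transitions: int
    n_transversions: int

    def __post_init__(self) -> None:
        if self.n_transitions + self.n_transversions > self.n_sites:
            raise ValueError("mismatches exceed compared sites")

    @property
    def P(self) -> float:
        return self.n_transitions / self.n_sites

    @property
    def Q(self) -> float:
        return self.n_transversions / self.n_sites


def pair_counts(seq_a: str, seq_b: str) -> PairCounts:
    """Count comparable sites, transitions (A<->G, C<->T) and transversions.

    Pairwise deletion: a site counts only when both sequences carry an
    unambiguous base there.
    """
    if len(seq_a) != len(seq_b):
        raise ValueError("sequences have unequal lengths")
    enc = {b: i for i, b in enumerate("ACGT")}
    a = np.array([enc.get(c, 4) for c in seq_a.upper()], dtype=np.int8)
    b = np.array([enc.get(c, 4) for c in seq_b.upper()], dtype=np.int8)
    valid = (a < 4) & (b < 4)
    n = int(valid.sum())
    if n == 0:
        raise ValueError("zero comparable sites between the pair")
    diff = valid & (a != b)
    ts = int((diff & (_PURINE[a] == _PURINE[b])).sum())
    tv = int(diff.sum()) - ts
    return PairCounts(n_sites=n, n_transitions=ts, n_transversions=tv)


def p_distance(counts: PairCounts) -> float:
    return (counts.n_transitions + counts.n_transversions) / counts.n_sites


def k2p(counts: PairCounts) -> float:
    """Kimura 2-parameter distance; NaN when the pair is saturated."""
    P, Q = counts.P, counts.Q
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    if w1 <= 0.0 or w2 <= 0.0:
        logger.info("saturated pair (P=%.4f, Q=%.4f): K2P undefined", P, Q)
        return math.nan
    return -0.5 * math.log(w1 * math.sqrt(w2)) + 0.0  # +0.0 folds -0.0


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distance matrix with a method tag ('p' or 'k2p').

    NaN entries mark saturated pairs (undefined K2P); the diagonal is zero.
    """

    labels: list[str]
    values: np.ndarray
    method: str = "k2p"
    n_sites: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(np.diag(self.values), 0.0):
            raise ValueError("diagonal must be zero")

    def __getitem__(self, pair: tuple[str, str]) -> float:
        i = self.labels.index(pair[0])
        j = self.labels.index(pair[1])
        return float(self.values[i, j])

    @property
    def n_undefined(self) -> int:
        iu = np.triu_indices(len(self.labels), k=1)
        return int(np.isnan(self.values[iu]).sum())

    def to_long_frame(self) -> pd.DataFrame:
        rows = []
        for i, j in itertools.combinations(range(len(self.labels)), 2):
            rows.append(
                {
                    "id_a": self.labels[i],
                    "id_b": self.labels[j],
                    "method": self.method,
                    "distance": self.values[i, j],
                    "n_sites": int(self.n_sites[i, j]) if self.n_sites is not None else -1,
                }
            )
        return pd.DataFrame(rows)

    def to_phylip(self) -> str:
        lines = [f"{len(self.labels)}"]
        for lab, row in zip(self.labels, self.values):
            lines.append(lab + "  " + "  ".join(f"{v:.8f}" for v in row))
        return "\n".join(lines) + "\n"


def _pairwise_arrays(enc: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized all-pairs (n_sites, transitions, transversions) counts."""
    n = enc.shape[0]
    valid = enc < 4
    purine = _PURINE[enc]
    ns = np.zeros((n, n), dtype=int)
    ts = np.zeros((n, n), dtype=int)
    tv = np.zeros((n, n), dtype=int)
    for i in range(n):
        both = valid[i] & valid[i + 1 :]
        diff = both & (enc[i] != enc[i + 1 :])
        t = diff & (purine[i] == purine[i + 1 :])
        ns[i, i + 1 :] = both.sum(axis=1)
        ts[i, i + 1 :] = t.sum(axis=1)
        tv[i, i + 1 :] = diff.sum(axis=1) - t.sum(axis=1)
    for m in (ns, ts, tv):
        m += m.T
    np.fill_diagonal(ns, 1)  # avoid 0/0 on the diagonal; distances there are 0
    return ns, ts, tv


def distance_matrix(alignment: Alignment, method: str = "k2p") -> DistanceMatrix:
    """All-pairs distance matrix under pairwise deletion.

    A pair with zero comparable sites is an error naming the pair;
    saturated K2P pairs yield NaN entries.
    """
    if method not in ("p", "k2p"):
        raise ValueError(f"unknown distance method {method!r}")
    if len(alignment) < 2:
        raise ValueError("distance matrix requires at least 2 records")
    enc = alignment.encoded()
    ns, ts, tv = _pairwise_arrays(enc)
    labels = alignment.ids
    iu = np.triu_indices(len(labels), k=1)
    zero_pairs = np.argwhere(ns == 0)
    if len(zero_pairs):
        i, j = zero_pairs[0]
        raise ValueError(
            f"zero comparable sites between {labels[i]!r} and {labels[j]!r}"
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        P = ts / ns
        Q = tv / ns
        if method == "p":
            d = P + Q
        else:
            w1 = 1.0 - 2.0 * P - Q
            w2 = 1.0 - 2.0 * Q
            arg = w1 * np.sqrt(np.where(w2 > 0, w2, np.nan))
            d = np.where(
                (w1 > 0) & (w2 > 0), -0.5 * np.log(np.where(arg > 0, arg, np.nan)), np.nan
            ) + 0.0
    np.fill_diagonal(d, 0.0)
    dm = DistanceMatrix(labels=labels, values=d, method=method, n_sites=ns)
    if dm.n_undefined:
        logger.warning("%d saturated pair(s) with undefined K2P", dm.n_undefined)
    return dm


@dataclass
class LevelSummary:
    """One row of a taxonomic-level distance table (percent scale)."""

    level: str  # 'intraspecific' | 'interspecific' | 'intrageneric'
    group: str  # species/genus name or 'ALL'
    n_individuals: int
    n_taxa: int
    n_comparisons: int
    mean: float
    se: float
    min: float
    max: float


def _summary_row(level: str, group: str, n_ind: int, n_taxa: int, dists) -> LevelSummary:
    d = np.asarray(dists, dtype=float) * 100.0 + 0.0  # +0.0 folds -0.0 into 0.0
    se = float(np.std(d, ddof=1) / math.sqrt(len(d))) if len(d) > 1 else 0.0
    return LevelSummary(
        level=level,
        group=group,
        n_individuals=n_ind,
        n_taxa=n_taxa,
        n_comparisons=len(d),
        mean=float(np.mean(d)),
        se=se,
        min=float(np.min(d)),
        max=float(np.max(d)),
    )


def _species_map(alignment: Alignment) -> dict[str, list[int]]:
    groups: dict[str, list[int]] = {}
    for i, rec in enumerate(alignment):
        groups.setdefault(rec.species, []).append(i)
    return groups


def intraspecific_distances(dm: DistanceMatrix, alignment: Alignment) -> dict[str, list[float]]:
    """Within-species pairwise distances, per species with >=2 individuals."""
    out: dict[str, list[float]] = {}
    for sp, idx in _species_map(alignment).items():
        if len(idx) < 2:
            continue
        vals = [
            dm.values[i, j]
            for i, j in itertools.combinations(idx, 2)
            if not np.isnan(dm.values[i, j])
        ]
        if vals:
            out[sp] = vals
    return out


def species_pair_distances(
    dm: DistanceMatrix, alignment: Alignment, within_genus: str | None = None
) -> dict[tuple[str, str], float]:
    """Distance between species pairs: the mean of all cross-individual distances.

    This species-pair accounting is what makes the pooled interspecific
    comparison count equal C(n_species, 2).
    """
    groups = _species_map(alignment)
    if within_genus is not None:
        groups = {
            sp: idx for sp, idx in groups.items() if sp.split()[0] == within_genus
        }
    out: dict[tuple[str, str], float] = {}
    for sp_a, sp_b in itertools.combinations(sorted(groups), 2):
        vals = [
            dm.values[i, j]
            for i in groups[sp_a]
            for j in groups[sp_b]
            if not np.isnan(dm.values[i, j])
        ]
        if vals:
            out[(sp_a, sp_b)] = float(np.mean(vals))
    return out


def individual_pair_distances(
    dm: DistanceMatrix, alignment: Alignment, within_genus: str | None = None
) -> list[float]:
    """All cross-species individual-pair distances (pooled accounting)."""
    groups = _species_map(alignment)
    if within_genus is not None:
        groups = {
            sp: idx for sp, idx in groups.items() if sp.split()[0] == within_genus
        }
    vals = []
    for sp_a, sp_b in itertools.combinations(sorted(groups), 2):
        for i in groups[sp_a]:
            for j in groups[sp_b]:
                v = dm.values[i, j]
                if not np.isnan(v):
                    vals.append(float(v))
    return vals


def summarize_level(
    dm: DistanceMatrix,
    alignment: Alignment,
    level: str,
    species_pair_accounting: bool = True,
) -> list[LevelSummary]:
    """Distance summaries at one taxonomic level (percent, outgroup excluded).

    intraspecific: one row per species with >=2 individuals plus a pooled
    ALL row over all within-species individual pairs. interspecific: a
    pooled ALL row over species-pair distances (or individual pairs when
    ``species_pair_accounting`` is off). intrageneric: one row per genus
    with >=2 species, within-species distances excluded.
    """
    keep = [i for i, r in enumerate(alignment) if not r.outgroup]
    if len(keep) < len(alignment):
        sub = Alignment([alignment.records[i] for i in keep])
        dm = DistanceMatrix(
            labels=[dm.labels[i] for i in keep],
            values=dm.values[np.ix_(keep, keep)],
            method=dm.method,
        )
        alignment = sub
    for rec in alignment:
        if rec.id not in dm.labels:
            raise ValueError(f"label {rec.id!r} missing from distance matrix")
    groups = _species_map(alignment)

    if level == "intraspecific":
        per_species = intraspecific_distances(dm, alignment)
        rows = [
            _summary_row("intraspecific", sp, len(groups[sp]), 1, vals)
            for sp, vals in sorted(per_species.items())
        ]
        pooled = [v for vals in per_species.values() for v in vals]
        if pooled:
            n_ind = sum(len(groups[sp]) for sp in per_species)
            rows.append(
                _summary_row("intraspecific", "ALL", n_ind, len(per_species), pooled)
            )
        return rows

    if level == "interspecific":
        if species_pair_accounting:
            vals = list(species_pair_distances(dm, alignment).values())
        else:
            vals = individual_pair_distances(dm, alignment)
        if not vals:
            return []
        return [
            _summary_row("interspecific", "ALL", len(alignment), len(groups), vals)
        ]

    if level == "intrageneric":
        genera: dict[str, set[str]] = {}
        for sp in groups:
            genera.setdefault(sp.split()[0], set()).add(sp)
        rows = []
        for genus in sorted(genera):
            if len(genera[genus]) < 2:
                continue
            if species_pair_accounting:
                vals = list(
                    species_pair_distances(dm, alignment, within_genus=genus).values()
                )
            else:
                vals = individual_pair_distances(dm, alignment, within_genus=genus)
            if not vals:
                continue
            n_ind = sum(len(groups[sp]) for sp in genera[genus])
            rows.append(
                _summary_row("intrageneric", genus, n_ind, len(genera[genus]), vals)
            )
        return rows

    raise ValueError(f"unknown level {level!r}")


def summaries_to_frame(rows: list[LevelSummary]) -> pd.DataFrame:
    """Table-style export: percent values rounded to 1 decimal."""
    return pd.DataFrame(
        [
            {
                "level": r.level,
                "group": r.group,
                "n_individuals": r.n_individuals,
                "n_taxa": r.n_taxa,
                "n_comparisons": r.n_comparisons,
                "mean": round(r.mean, 1),
                "SE": round(r.se, 1),
                "min": round(r.min, 1),
                "max": round(r.max, 1),
            }
            for r in rows
        ]
    )


@dataclass
class BarcodeGapReport:
    """Separation between intra- and interspecific distance distributions."""

    max_intraspecific: float | None  # percent
    min_interspecific: float | None  # percent
    n_interspecific: int
    n_overlap: int  # interspecific comparisons below max intraspecific
    overlap_fraction: float  # in [0,1]
    bins: np.ndarray  # bin edges, percent
    intra_hist: np.ndarray
    inter_hist: np.ndarray

    @property
    def has_gap(self) -> bool:
        if self.max_intraspecific is None or self.min_interspecific is None:
            return False
        return self.min_interspecific > self.max_intraspecific

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_left": self.bins[:-1],
                "bin_right": self.bins[1:],
                "intraspecific": self.intra_hist,
                "interspecific": self.inter_hist,
            }
        )


def barcode_gap(
    dm: DistanceMatrix,
    alignment: Alignment,
    bin_width: float = 1.0,
    species_pair_accounting: bool = True,
) -> BarcodeGapReport:
    """Barcode-gap analysis: distribution overlap of intra- vs interspecific distances.

    ``bin_width`` is in percentage points. The overlap count is the number
    of interspecific comparisons strictly below the maximum intraspecific
    distance.
    """
    keep = [r for r in alignment if not r.outgroup]
    sub = Alignment(keep)
    idx = [dm.labels.index(r.id) for r in keep]
    sdm = DistanceMatrix(
        labels=[r.id for r in keep], values=dm.values[np.ix_(idx, idx)], method=dm.method
    )
    intra = [
        v * 100.0
        for vals in intraspecific_distances(sdm, sub).values()
        for v in vals
    ]
    if species_pair_accounting:
        inter = [v * 100.0 for v in species_pair_distances(sdm, sub).values()]
    else:
        inter = [v * 100.0 for v in individual_pair_distances(sdm, sub)]
    if not inter:
        raise ValueError("no interspecific comparisons available")
    max_intra = max(intra) if intra else None
    min_inter = min(inter)
    n_overlap = sum(v < max_intra for v in inter) if intra else 0
    top = max(inter + (intra or [0.0]))
    edges = np.arange(0.0, top + 2 * bin_width, bin_width)
    intra_hist, _ = np.histogram(intra, bins=edges)
    inter_hist, _ = np.histogram(inter, bins=edges)
    return BarcodeGapReport(
        max_intraspecific=max_intra,
        min_interspecific=min_inter,
        n_interspecific=len(inter),
        n_overlap=n_overlap,
        overlap_fraction=n_overlap / len(inter),
        bins=edges,
        intra_hist=intra_hist,
        inter_hist=inter_hist,
    )
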