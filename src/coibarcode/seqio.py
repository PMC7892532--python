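"""Sequence input/output, alignment validation, NUMT screening, alignment statistics.

Sequences are COI barcode nucleotide sequences over IUPAC codes plus ``-``.
FASTA headers may carry taxonomy inline (``id|species|genus|family`` by
default) or taxonomy can be joined from a delimited metadata table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

IUPAC_CODES = set("ACGTURYSWKMBDHVN-")
UNAMBIGUOUS = "ACGT"

#: Stop codons of the vertebrate mitochondrial genetic code.
MITO_STOPS = frozenset({"TAA", "TAG", "AGA", "AGG"})


class BarcodeError(ValueError):
    """Raised on malformed input data (bad FASTA, metadata mismatch, bad window)."""


@dataclass
class SequenceRecord:
    """One barcode sequence plus its taxonomic and voucher metadata.

    ``genus`` defaults to the first whitespace token of ``species``.
    ``outgroup`` marks the rooting taxon, which is exempt from the
    species-required rule.
    """

    id: str
    seq: str
    species: str = ""
    genus: str = ""
    family: str = ""
    voucher: str = ""
    site: str = ""
    outgroup: bool = False

    def __post_init__(self) -> None:
        if not self.id:
            raise BarcodeError("sequence record requires a nonempty id")
        if not self.seq:
            raise BarcodeError(f"record {self.id!r}: empty sequence")
        if self.species and not self.genus:
            self.genus = self.species.split()[0]

    def degapped(self) -> str:
        return self.seq.replace("-", "")


class Alignment:
    """Fixed-length matrix of sequences; the unit all statistics are computed on."""

    def __init__(self, records: Sequence[SequenceRecord]):
        records = list(records)
        if not records:
            raise BarcodeError("alignment requires at least one record")
        lengths = {len(r.seq) for r in records}
        if len(lengths) != 1:
            raise BarcodeError(f"sequences have unequal lengths: {sorted(lengths)}")
        ids = [r.id for r in records]
        dups = {i for i in ids if ids.count(i) > 1}
        if dups:
            raise BarcodeError(f"duplicate sequence ids: {sorted(dups)}")
        self.records = records
        self.length = lengths.pop()

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def __getitem__(self, i: int) -> SequenceRecord:
        return self.records[i]

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    def record(self, rec_id: str) -> SequenceRecord:
        for r in self.records:
            if r.id == rec_id:
                return r
        raise KeyError(rec_id)

    def ingroup(self) -> "Alignment":
        """Alignment restricted to non-outgroup records."""
        recs = [r for r in self.records if not r.outgroup]
        return Alignment(recs)

    def to_matrix(self) -> np.ndarray:
        """Character matrix of shape (n, L), dtype '<U1'."""
        return np.array([list(r.seq) for r in self.records])

    def encoded(self) -> np.ndarray:
        """Integer matrix: A=0, C=1, G=2, T=3, anything else (gap/ambiguity)=4."""
        mat = self.to_matrix()
        out = np.full(mat.shape, 4, dtype=np.int8)
        for code, base in enumerate(UNAMBIGUOUS):
            out[mat == base] = code
        return out

    def resample_columns(self, rng: np.random.Generator) -> "Alignment":
        """Bootstrap replicate: sample L columns with replacement."""
        cols = rng.integers(0, self.length, size=self.length)
        mat = self.to_matrix()[:, cols]
        recs = [replace(r, seq="".join(row)) for r, row in zip(self.records, mat)]
        return Alignment(recs)


@dataclass
class AlignmentStats:
    n_variable: int
    n_parsimony_informative: int
    base_freq: dict[str, float]


@dataclass
class NumtVerdict:
    """Pseudogene screen result: ``flagged`` iff the best forward reading frame
    still contains a stop codon under the vertebrate mitochondrial code."""

    record_id: str
    best_frame: int
    n_stops_best_frame: int
    flagged: bool


def _parse_header(header: str, delimiter: str) -> dict[str, str]:
    parts = [p.strip() for p in header.split(delimiter)]
    keys = ("id", "species", "genus", "family")
    return {k: v for k, v in zip(keys, parts) if v}


def read_fasta(
    path: str | Path,
    delimiter: str = "|",
    outgroup_ids: Iterable[str] = (),
) -> list[SequenceRecord]:
    """Read FASTA records, parsing ``id|species|genus|family`` headers.

    Sequences are uppercased and U is mapped to T. Non-IUPAC characters
    raise an error naming the record and 1-based position.
    """
    path = Path(path)
    outgroup_ids = set(outgroup_ids)
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for entry in SeqIO.parse(str(path), "fasta"):
        header = entry.description
        fields = _parse_header(header, delimiter)
        rec_id = fields.get("id", entry.id)
        if rec_id in seen:
            raise BarcodeError(f"duplicate sequence id {rec_id!r} in {path}")
        seen.add(rec_id)
        seq = str(entry.seq).upper().replace("U", "T")
        for pos, ch in enumerate(seq, start=1):
            if ch not in IUPAC_CODES:
                raise BarcodeError(
                    f"record {rec_id!r}: non-IUPAC character {ch!r} at position {pos}"
                )
        records.append(
            SequenceRecord(
                id=rec_id,
                seq=seq,
                species=fields.get("species", ""),
                genus=fields.get("genus", ""),
                family=fields.get("family", ""),
                outgroup=rec_id in outgroup_ids,
            )
        )
    if not records:
        raise BarcodeError(f"no FASTA records in {path}")
    return records


def write_fasta(
    records: Iterable[SequenceRecord], path: str | Path, delimiter: str = "|"
) -> None:
    """Write records with ``id|species|genus|family`` headers (trailing empties dropped)."""
    out = []
    for r in records:
        parts = [r.id, r.species, r.genus, r.family]
        while len(parts) > 1 and not parts[-1]:
            parts.pop()
        header = delimiter.join(parts)
        out.append(_BioSeqRecord(Seq(r.seq), id=header, description=""))
    SeqIO.write(out, str(path), "fasta-2line")


def read_metadata(path: str | Path, sep: str | None = None) -> pd.DataFrame:
    """Read a metadata table (TSV/CSV with header: id, species[, genus, family, voucher, site])."""
    if sep is None:
        sep = "," if str(path).endswith(".csv") else "\t"
    table = pd.read_csv(path, sep=sep, dtype=str).fillna("")
    if "id" not in table.columns or "species" not in table.columns:
        raise BarcodeError("metadata table requires 'id' and 'species' columns")
    return table


def attach_metadata(
    records: Sequence[SequenceRecord], table: pd.DataFrame
) -> list[SequenceRecord]:
    """Join taxonomy onto records by sequence id.

    Table ids absent from the records produce a warning; a non-outgroup
    record left without a species is an error.
    """
    rows = {row["id"]: row for _, row in table.iterrows()}
    record_ids = {r.id for r in records}
    for tid in rows:
        if tid not in record_ids:
            warnings.warn(f"metadata id {tid!r} matches no sequence record")
    out = []
    for r in records:
        row = rows.get(r.id)
        if row is not None:
            r = replace(
                r,
                species=row.get("species", r.species) or r.species,
                genus=row.get("genus", "") or "",
                family=row.get("family", r.family) or r.family,
                voucher=row.get("voucher", r.voucher) or r.voucher,
                site=row.get("site", r.site) or r.site,
            )
            if not r.genus and r.species:
                r = replace(r, genus=r.species.split()[0])
        if not r.species and not r.outgroup:
            raise BarcodeError(f"record {r.id!r} has no species and is not an outgroup")
        out.append(r)
    return out


def trim_to_window(
    records: Sequence[SequenceRecord], start: int, end: int
) -> Alignment:
    """Restrict aligned records to the half-open column window [start, end).

    The window that yields the conserved 443-column COI barcode block is a
    user parameter; coordinates are 0-based internally.
    """
    if end <= start:
        raise BarcodeError(f"empty trim window [{start}, {end})")
    if start < 0:
        raise BarcodeError(f"window start {start} < 0")
    trimmed = []
    for r in records:
        if end > len(r.seq):
            raise BarcodeError(
                f"record {r.id!r}: window [{start}, {end}) exceeds length {len(r.seq)}"
            )
        trimmed.append(replace(r, seq=r.seq[start:end]))
    return Alignment(trimmed)


def numt_screen(
    record: SequenceRecord, scan_reverse_frames: bool = False
) -> NumtVerdict:
    """Screen one sequence for nuclear-pseudogene (NUMT) contamination.

    The degapped sequence is translated in all three forward frames under
    the vertebrate mitochondrial code; the best frame is the one with the
    fewest stop codons (ties broken toward the lowest frame index). A true
    COI barcode lies inside the reading frame, so any in-frame stop flags
    the sequence. COI amplicons are read in coding orientation; reverse
    frames are only scanned on request.
    """
    seq = record.degapped()
    if len(seq) < 3:
        raise BarcodeError(f"record {record.id!r}: fewer than 3 ungapped bases")

    def count_stops(s: str) -> list[int]:
        counts = []
        for frame in range(3):
            codons = [s[i : i + 3] for i in range(frame, len(s) - 2, 3)]
            counts.append(sum(c in MITO_STOPS for c in codons))
        return counts

    counts = count_stops(seq)
    if scan_reverse_frames:
        comp = seq.translate(str.maketrans("ACGT", "TGCA"))[::-1]
        counts = counts + count_stops(comp)
    best = int(np.argmin(counts))
    n_stops = counts[best]
    return NumtVerdict(
        record_id=record.id,
        best_frame=best % 3,
        n_stops_best_frame=n_stops,
        flagged=n_stops > 0,
    )


def screen_alignment(
    records: Sequence[SequenceRecord], **kwargs
) -> list[NumtVerdict]:
    return [numt_screen(r, **kwargs) for r in records]


def verdicts_to_frame(verdicts: Sequence[NumtVerdict]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "record_id": v.record_id,
                "best_frame": v.best_frame,
                "n_stops_best_frame": v.n_stops_best_frame,
                "flagged": v.flagged,
            }
            for v in verdicts
        ]
    )


def alignment_stats(alignment: Alignment) -> AlignmentStats:
    """Variable / parsimony-informative site counts and base composition.

    A site is variable when at least two distinct unambiguous bases occur
    among its non-gap characters, and parsimony-informative when at least
    two distinct bases each occur in at least two sequences. Base
    frequencies are taken over all unambiguous characters.
    """
    enc = alignment.encoded()
    n_variable = 0
    n_pi = 0
    for col in enc.T:
        counts = np.bincount(col[col < 4], minlength=4)
        present = counts[counts > 0]
        if len(present) >= 2:
            n_variable += 1
            if np.sum(present >= 2) >= 2:
                n_pi += 1
    totals = np.bincount(enc[enc < 4].ravel(), minlength=4).astype(float)
    denom = totals.sum()
    freqs = totals / denom if denom > 0 else totals
    return AlignmentStats(
        n_variable=n_variable,
        n_parsimony_informative=n_pi,
        base_freq=dict(zip(UNAMBIGUOUS, freqs.tolist())),
    )
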