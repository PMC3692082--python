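"""Readers and writers for ComiR's external representations.

Handles the four external formats the pipeline touches:

* FASTA target sequences (3'UTRs and/or user-supplied custom sequences),
  with the longest-isoform-per-gene rule;
* the miRNA expression table (CSV, samples in columns), including the
  degenerate "bare list of miRNA IDs" form;
* per-site binding-score tables for the four scoring channels, as a
  5-column TSV (gene_id, mirna_id, start, end, score; 0-based half-open
  coordinates on the target's sense strand);
* result tables (CSV/TSV).

All sequences are canonicalized to an uppercase DNA alphabet on ingestion
(U -> T), so complementarity tests elsewhere work on a single alphabet.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import TYPE_CHECKING, Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

if TYPE_CHECKING:  # pragma: no cover
    from .svm import ComirResult

__all__ = [
    "Channel",
    "ENERGY_CHANNELS",
    "WEIGHTED_SUM_CHANNELS",
    "FormatError",
    "TargetSequence",
    "ExpressionTable",
    "SiteScore",
    "SiteScoreTable",
    "canonicalize_sequence",
    "read_fasta",
    "write_fasta",
    "read_expression_table",
    "read_site_scores",
    "write_site_scores",
    "write_results",
    "read_results",
]


class Channel(str, Enum):
    """The four per-site scoring channels combined by the method."""

    MIRANDA_ENERGY = "miranda_energy"  # duplex binding energy, kcal/mol
    PITA_DDG = "pita_ddg"  # binding energy minus site-opening cost, kcal/mol
    TARGETSCAN_SEED = "targetscan_seed"  # seed-match site counts
    MIRSVR = "mirsvr"  # regression-based per-site scores


#: Channels aggregated through the Fermi-Dirac occupancy model (energies).
ENERGY_CHANNELS = frozenset({Channel.MIRANDA_ENERGY, Channel.PITA_DDG})
#: Channels aggregated by a concentration-weighted sum.
WEIGHTED_SUM_CHANNELS = frozenset({Channel.TARGETSCAN_SEED, Channel.MIRSVR})


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


_VALID_BASES = frozenset("ACGTN")
_U_TO_T = str.maketrans("Uu", "Tt")


def canonicalize_sequence(seq: str, *, context: str = "sequence") -> str:
    """Uppercase a nucleotide string and map U -> T.

    Raises :class:`FormatError` if the result contains characters outside
    {A, C, G, T, N} or is empty.
    """
    s = seq.translate(_U_TO_T).upper()
    if not s:
        raise FormatError(f"{context}: empty sequence")
    bad = set(s) - _VALID_BASES
    if bad:
        raise FormatError(
            f"{context}: invalid characters {sorted(bad)} (expected A/C/G/T/U/N)"
        )
    return s


@dataclass(frozen=True)
class TargetSequence:
    """A candidate target sequence (a 3'UTR or a custom sequence)."""

    gene_id: str
    sequence: str
    source: str = "reference_utr"  # or "custom"

    def __post_init__(self) -> None:
        object.__setattr__(
            self,
            "sequence",
            canonicalize_sequence(self.sequence, context=f"record {self.gene_id!r}"),
        )
        if self.source not in ("reference_utr", "custom"):
            raise ValueError(f"unknown source {self.source!r}")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class ExpressionTable:
    """miRNA x sample matrix of expression levels.

    ``levels`` is linear-scale and nonnegative unless ``is_log_input`` is
    set, in which case values are as declared by the user and converted by
    :func:`comir.expression.log_to_linear` before any downstream use.
    """

    mirna_ids: list[str]
    sample_ids: list[str]
    levels: np.ndarray  # shape (n_mirnas, n_samples)
    is_log_input: bool = False
    dropped_ids: list[tuple[str, str]] = field(default_factory=list)  # (id, reason)

    def __post_init__(self) -> None:
        self.levels = np.asarray(self.levels, dtype=float)
        if self.levels.shape != (len(self.mirna_ids), len(self.sample_ids)):
            raise ValueError(
                f"levels shape {self.levels.shape} inconsistent with "
                f"{len(self.mirna_ids)} miRNAs x {len(self.sample_ids)} samples"
            )
        dup = _duplicates(self.mirna_ids)
        if dup:
            raise FormatError(f"duplicate miRNA IDs: {sorted(dup)}")
        if not self.is_log_input and np.any(self.levels < 0):
            raise ValueError("linear-scale expression levels must be nonnegative")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.levels, index=self.mirna_ids, columns=self.sample_ids)


@dataclass(frozen=True)
class SiteScore:
    """One predicted binding site on a target sequence.

    ``start``/``end`` are 0-based half-open on the target sense strand.
    ``score`` is kcal/mol for the energy channels (more negative = stronger
    binding), exactly 1.0 per detected site for the seed channel, and native
    units for the mirSVR-type channel.
    """

    gene_id: str
    mirna_id: str
    start: int
    end: int
    channel: Channel
    score: float
    site_class: str = "imported"

    def __post_init__(self) -> None:
        if self.start < 0 or self.end <= self.start:
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) for "
                f"{self.gene_id}:{self.mirna_id}"
            )


@dataclass
class SiteScoreTable:
    """All sites of one scoring channel; ``n_rejected`` counts dropped rows."""

    channel: Channel
    records: list[SiteScore] = field(default_factory=list)
    n_rejected: int = 0

    def __post_init__(self) -> None:
        self.channel = Channel(self.channel)
        for rec in self.records:
            if rec.channel != self.channel:
                raise ValueError(
                    f"record channel {rec.channel} does not match table "
                    f"channel {self.channel}"
                )

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def validate_against(self, targets: Iterable[TargetSequence]) -> None:
        """Check that every site interval lies within its gene's sequence."""
        lengths = {t.gene_id: len(t) for t in targets}
        for rec in self.records:
            n = lengths.get(rec.gene_id)
            if n is not None and rec.end > n:
                raise FormatError(
                    f"site [{rec.start}, {rec.end}) exceeds length {n} of "
                    f"gene {rec.gene_id}"
                )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                (r.gene_id, r.mirna_id, r.start, r.end, r.score, r.site_class)
                for r in self.records
            ],
            columns=["gene_id", "mirna_id", "start", "end", "score", "site_class"],
        )


def _duplicates(items: Sequence[str]) -> set[str]:
    seen: set[str] = set()
    dup: set[str] = set()
    for x in items:
        if x in seen:
            dup.add(x)
        seen.add(x)
    return dup


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(
    path: str | Path,
    *,
    keep_longest_per_gene: bool = True,
    source: str = "reference_utr",
) -> list[TargetSequence]:
    """Read target sequences from FASTA.

    When ``keep_longest_per_gene`` is set, only the longest sequence is
    retained for each gene ID (the standard rule when several 3'UTR isoforms
    map to one gene); ties keep the first record encountered.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    records: list[TargetSequence] = []
    with open(path) as fh:
        # SeqIO silently skips leading junk; enforce a FASTA header up front.
        pos = fh.tell()
        first = fh.readline()
        while first and not first.strip():
            first = fh.readline()
        if not first:
            raise FormatError(f"{path}: empty FASTA file")
        if not first.startswith(">"):
            raise FormatError(f"{path}: not FASTA (first line {first.strip()!r})")
        fh.seek(pos)
        for rec in SeqIO.parse(fh, "fasta"):
            try:
                records.append(
                    TargetSequence(gene_id=rec.id, sequence=str(rec.seq), source=source)
                )
            except FormatError as exc:
                raise FormatError(f"{path}: malformed record {rec.id!r}: {exc}") from exc
    if not records:
        raise FormatError(f"{path}: no FASTA records")
    if not keep_longest_per_gene:
        return records
    best: dict[str, TargetSequence] = {}
    for t in records:
        cur = best.get(t.gene_id)
        if cur is None or len(t) > len(cur):  # tie -> first encountered wins
            best[t.gene_id] = t
    return list(best.values())


def write_fasta(sequences: Iterable[TargetSequence], path: str | Path) -> None:
    with open(path, "w") as fh:
        for t in sequences:
            fh.write(f">{t.gene_id}\n{t.sequence}\n")


# ---------------------------------------------------------------------------
# Expression table
# ---------------------------------------------------------------------------

def read_expression_table(
    path: str | Path, *, is_log_input: bool = False
) -> ExpressionTable:
    """Read the miRNA expression CSV.

    The first row holds sample IDs (with or without a corner label) and the
    first column miRNA IDs.  A file in which every row is a single bare
    miRNA ID is accepted as an ID-only list and yields one implicit sample
    in which every miRNA has level 1 (all miRNAs equally expressed).
    """
    path = Path(path)
    with open(path, newline="") as fh:
        rows = [row for row in csv.reader(fh) if any(cell.strip() for cell in row)]
    if not rows:
        raise FormatError(f"{path}: empty expression table")
    rows = [[cell.strip() for cell in row] for row in rows]

    if all(len(row) == 1 for row in rows):
        ids = [row[0] for row in rows]
        return ExpressionTable(
            mirna_ids=ids,
            sample_ids=["sample_1"],
            levels=np.ones((len(ids), 1)),
            is_log_input=False,  # ones are already linear
        )

    header, data = rows[0], rows[1:]
    if not data:
        raise FormatError(f"{path}: header only, no miRNA rows")
    widths = {len(row) for row in data}
    if len(widths) != 1:
        raise FormatError(f"{path}: ragged rows (widths {sorted(widths)})")
    (width,) = widths
    n_samples = width - 1
    if n_samples < 1:
        raise FormatError(f"{path}: no expression columns")
    if len(header) == width:
        sample_ids = header[1:]  # corner label present
    elif len(header) == n_samples:
        sample_ids = header
    else:
        raise FormatError(
            f"{path}: header has {len(header)} fields but data rows have {width}"
        )

    mirna_ids = [row[0] for row in data]
    levels = np.empty((len(data), n_samples))
    for i, row in enumerate(data):
        for j, cell in enumerate(row[1:]):
            try:
                levels[i, j] = float(cell)
            except ValueError:
                raise FormatError(
                    f"{path}: non-numeric value {cell!r} at row {i + 2} "
                    f"(miRNA {row[0]!r}), column {j + 2} (sample {sample_ids[j]!r})"
                ) from None
    return ExpressionTable(
        mirna_ids=mirna_ids,
        sample_ids=sample_ids,
        levels=levels,
        is_log_input=is_log_input,
    )


# ---------------------------------------------------------------------------
# Site-score tables
# ---------------------------------------------------------------------------

def read_site_scores(
    path: str | Path, channel: Channel | str, *, strict: bool = False
) -> SiteScoreTable:
    """Read a per-site score TSV (gene_id, mirna_id, start, end, score).

    Coordinates are 0-based half-open.  Rows that cannot be parsed or that
    carry an invalid interval (negative coordinates, end <= start) are
    rejected and counted in ``n_rejected`` (raised immediately under
    ``strict``); rows_in = rows_kept + rows_rejected always holds.
    """
    channel = Channel(channel)
    records: list[SiteScore] = []
    n_rejected = 0
    with open(path, newline="") as fh:
        for lineno, row in enumerate(csv.reader(fh, delimiter="\t"), start=1):
            if not row or row[0].startswith("#"):
                continue
            try:
                if len(row) != 5:
                    raise ValueError(f"expected 5 fields, got {len(row)}")
                gene_id, mirna_id = row[0].strip(), row[1].strip()
                start, end = int(row[2]), int(row[3])
                score = float(row[4])
                records.append(
                    SiteScore(gene_id, mirna_id, start, end, channel, score)
                )
            except ValueError as exc:
                if strict:
                    raise FormatError(f"{path}: line {lineno}: {exc}") from exc
                n_rejected += 1
    return SiteScoreTable(channel=channel, records=records, n_rejected=n_rejected)


def write_site_scores(table: SiteScoreTable, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        for r in table.records:
            writer.writerow([r.gene_id, r.mirna_id, r.start, r.end, repr(r.score)])


# ---------------------------------------------------------------------------
# Result tables
# ---------------------------------------------------------------------------

def write_results(result: "ComirResult", path: str | Path, fmt: str = "csv") -> None:
    """Write a result table: one row per gene, one score column per label,
    plus any appended difference / p-value columns."""
    if fmt not in ("csv", "tsv"):
        raise ValueError(f"unknown format {fmt!r}")
    frame = result.to_frame()
    frame.to_csv(path, sep="," if fmt == "csv" else "\t", index=False)


def read_results(path: str | Path, fmt: str = "csv") -> pd.DataFrame:
    return pd.read_csv(path, sep="," if fmt == "csv" else "\t")
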