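"""Screen-result tables: parsing, validation, and pattern queries.

The genome-wide RNAi screen for heat shock response (HSR) regulators in
*C. elegans* yields three tables that this module reads from packaged TSV
fixtures (or user-supplied files in the same format):

* the positive regulators, whose knockdown blocks heat-shock induction of the
  ``phsp70::gfp`` reporter;
* the negative regulators, whose knockdown constitutively activates the
  reporter, each annotated with the tissues in which induction is observed
  (spermatheca / intestine / muscle, encoded 1/0);
* a ten-gene comparison of induction across three HSF1-dependent reporters
  (``hsp70``, ``ckb-2``, ``hsp-16.2``) broken down by tissue.

Files are UTF-8 TSV with a header row; lines starting with ``#`` are comments.
Cosmid names are the canonical gene identifiers (some screen hits have no
common gene name) and are the join key against interaction networks.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

SIGN_POSITIVE = "positive"
SIGN_NEGATIVE = "negative"

#: Recognised functional classes, derived from the free-text description.
FUNCTIONAL_CLASSES = (
    "chaperone",
    "cochaperone",
    "proteasome",
    "trafficking",
    "mitochondrial",
    "ubiquitin",
    "synthesis",
    "gene_expression",
    "other",
)

# Keyword -> class map applied to the lower-cased description; first match
# wins, so order encodes precedence: organelle tags ("(mito)", "(ER)") beat
# the generic machine name they decorate.
_CLASS_KEYWORDS: tuple[tuple[str, str], ...] = (
    ("(mito)", "mitochondrial"),
    ("tim44", "mitochondrial"),
    ("cochaperone", "cochaperone"),
    ("(er)", "trafficking"),
    ("srp", "trafficking"),
    ("copi", "trafficking"),
    ("proteasome", "proteasome"),
    ("chaperon", "chaperone"),
    ("ubiquitin", "ubiquitin"),
    ("synthetase", "synthesis"),
    ("ef-2", "synthesis"),
    ("transcription", "gene_expression"),
    ("splicing", "gene_expression"),
    ("snrpd", "gene_expression"),
    ("usp39", "gene_expression"),
    ("nurd", "gene_expression"),
    ("nurf", "gene_expression"),
    ("mediator", "gene_expression"),
    ("integrator", "gene_expression"),
    ("heat shock factor", "gene_expression"),
)


def classify_description(description: str) -> str:
    """Map a free-text description to a functional class keyword."""
    text = description.lower()
    for needle, cls in _CLASS_KEYWORDS:
        if needle in text:
            return cls
    return "other"


@dataclass(frozen=True)
class TissuePattern:
    """Reporter induction flags for the three scored tissues."""

    spermatheca: bool
    intestine: bool
    muscle: bool

    def as_tuple(self) -> tuple[bool, bool, bool]:
        return (self.spermatheca, self.intestine, self.muscle)

    @property
    def category(self) -> str:
        """Compact label, e.g. ``'SI-'`` for spermatheca+intestine induction."""
        return ("S" if self.spermatheca else "-") + (
            "I" if self.intestine else "-"
        ) + ("M" if self.muscle else "-")

    @classmethod
    def from_flags(cls, s: int, i: int, m: int) -> "TissuePattern":
        return cls(bool(s), bool(i), bool(m))


#: All eight possible spermatheca/intestine/muscle categories.
ALL_PATTERN_CATEGORIES = tuple(
    ("S" if s else "-") + ("I" if i else "-") + ("M" if m else "-")
    for s in (1, 0)
    for i in (1, 0)
    for m in (1, 0)
)


@dataclass(frozen=True)
class GeneRecord:
    """One screen hit.

    ``gene`` may be empty (several hits are known only by cosmid); ``cosmid``
    is therefore the unique key. ``pattern`` is present only for negative
    regulators scored per tissue.
    """

    cosmid: str
    gene: str
    description: str
    sign: str
    functional_class: str = "other"
    pattern: TissuePattern | None = None

    def __post_init__(self) -> None:
        if not self.cosmid:
            raise ValueError("GeneRecord requires a non-empty cosmid")
        if self.sign not in (SIGN_POSITIVE, SIGN_NEGATIVE):
            raise ValueError(f"invalid sign {self.sign!r}")


@dataclass(frozen=True)
class ReporterRow:
    """Induction flags of one gene across the three-reporter comparison."""

    gene: str
    hsp70_I: bool
    hsp70_M: bool
    ckb2_I: bool
    hsp16_I: bool
    hsp16_M: bool


REPORTER_FLAG_COLUMNS = ("hsp70_I", "hsp70_M", "ckb2_I", "hsp16_I", "hsp16_M")


@dataclass(frozen=True)
class ConcordanceCounts:
    """Pairwise agreement tally between two boolean reporter columns."""

    both: int
    neither: int
    discordant: int

    @property
    def total(self) -> int:
        return self.both + self.neither + self.discordant


def _read_tsv(path: str | Path) -> pd.DataFrame:
    try:
        frame = pd.read_csv(
            path, sep="\t", comment="#", dtype=str, keep_default_na=False
        )
    except pd.errors.EmptyDataError as exc:
        raise ValueError(f"{path}: missing header row") from exc
    frame.columns = [c.strip() for c in frame.columns]
    return frame


def _parse_flag(value: str, column: str, row_number: int) -> bool:
    if value not in ("0", "1"):
        raise ValueError(
            f"row {row_number}: flag column {column!r} must be 0 or 1, "
            f"got {value!r}"
        )
    return value == "1"


def read_gene_table(path: str | Path, sign: str | None = None) -> list[GeneRecord]:
    """Read a screen-hit table into :class:`GeneRecord` rows, order preserved.

    Required columns: ``cosmid``, ``gene``, ``description``. If the per-tissue
    flag columns ``S``/``I``/``M`` are present each record also carries a
    :class:`TissuePattern`. Unless ``sign`` is given explicitly, tables with
    tissue flags are taken to list negative regulators and tables without
    them positive regulators (matching the screen's two read-outs).
    """
    frame = _read_tsv(path)
    for column in ("cosmid", "gene", "description"):
        if column not in frame.columns:
            raise ValueError(f"{path}: missing required column {column!r}")
    has_pattern = all(c in frame.columns for c in ("S", "I", "M"))
    if sign is None:
        sign = SIGN_NEGATIVE if has_pattern else SIGN_POSITIVE

    records: list[GeneRecord] = []
    seen: set[str] = set()
    for row_number, row in enumerate(frame.itertuples(index=False), start=1):
        cosmid = row.cosmid.strip()
        if not cosmid:
            raise ValueError(f"{path}: row {row_number}: empty cosmid")
        if cosmid in seen:
            raise ValueError(f"{path}: duplicate cosmid {cosmid!r}")
        seen.add(cosmid)
        pattern = None
        if has_pattern:
            pattern = TissuePattern(
                _parse_flag(row.S, "S", row_number),
                _parse_flag(row.I, "I", row_number),
                _parse_flag(row.M, "M", row_number),
            )
        description = row.description.strip()
        records.append(
            GeneRecord(
                cosmid=cosmid,
                gene=row.gene.strip(),
                description=description,
                sign=sign,
                functional_class=classify_description(description),
                pattern=pattern,
            )
        )
    return records


def write_gene_table(records: Sequence[GeneRecord], path: str | Path) -> None:
    """Serialize records back to the TSV layout accepted by read_gene_table."""
    has_pattern = any(r.pattern is not None for r in records)
    columns = ["cosmid", "gene", "description"] + (
        ["S", "I", "M"] if has_pattern else []
    )
    rows = []
    for r in records:
        row = [r.cosmid, r.gene, r.description]
        if has_pattern:
            if r.pattern is None:
                raise ValueError(f"record {r.cosmid} lacks a tissue pattern")
            row += [str(int(f)) for f in r.pattern.as_tuple()]
        rows.append(row)
    frame = pd.DataFrame(rows, columns=columns)
    frame.to_csv(path, sep="\t", index=False)


def read_reporter_table(path: str | Path) -> list[ReporterRow]:
    """Read the three-reporter comparison table, order preserved."""
    frame = _read_tsv(path)
    if "gene" not in frame.columns:
        raise ValueError(f"{path}: missing required column 'gene'")
    for column in REPORTER_FLAG_COLUMNS:
        if column not in frame.columns:
            raise ValueError(f"{path}: missing required column {column!r}")
    rows: list[ReporterRow] = []
    for row_number, row in enumerate(frame.itertuples(index=False), start=1):
        flags = {
            column: _parse_flag(getattr(row, column), column, row_number)
            for column in REPORTER_FLAG_COLUMNS
        }
        rows.append(ReporterRow(gene=row.gene.strip(), **flags))
    return rows


def concordance_counts(
    rows: Sequence[ReporterRow], col_a: str, col_b: str
) -> ConcordanceCounts:
    """Tally joint induction of two reporter columns over the table rows.

    ``both`` counts genes inducing under both columns, ``neither`` genes
    inducing under neither, and ``discordant`` genes inducing under exactly
    one — the comparison used to ask how consistently different heat-shock
    reporters respond in the same tissue.
    """
    if not rows:
        raise ValueError("concordance_counts requires at least one row")
    for column in (col_a, col_b):
        if column not in REPORTER_FLAG_COLUMNS:
            raise ValueError(f"unknown reporter column {column!r}")
    both = neither = discordant = 0
    for row in rows:
        a = getattr(row, col_a)
        b = getattr(row, col_b)
        if a and b:
            both += 1
        elif not a and not b:
            neither += 1
        else:
            discordant += 1
    return ConcordanceCounts(both=both, neither=neither, discordant=discordant)


def filter_by_pattern(
    records: Iterable[GeneRecord], pattern: TissuePattern
) -> list[GeneRecord]:
    """Records whose tissue flags equal ``pattern`` exactly."""
    out = []
    for record in records:
        if record.pattern is None:
            raise ValueError(f"record {record.cosmid} carries no tissue pattern")
        if record.pattern == pattern:
            out.append(record)
    return out


def pattern_class_sizes(records: Iterable[GeneRecord]) -> dict[str, int]:
    """Number of records in each of the eight S/I/M categories."""
    sizes = {category: 0 for category in ALL_PATTERN_CATEGORIES}
    for record in records:
        if record.pattern is None:
            raise ValueError(f"record {record.cosmid} carries no tissue pattern")
        sizes[record.pattern.category] += 1
    return sizes


def _fixture_path(name: str):
    return resources.files("hsnet.data").joinpath(name)


def load_positive_regulators() -> list[GeneRecord]:
    """Packaged table of the seven conserved positive HSR regulators."""
    with resources.as_file(_fixture_path("table1_positive.tsv")) as path:
        return read_gene_table(path, sign=SIGN_POSITIVE)


def load_negative_regulators() -> list[GeneRecord]:
    """Packaged table of the 52 negative HSR regulators with tissue flags."""
    with resources.as_file(_fixture_path("table2_negative.tsv")) as path:
        return read_gene_table(path, sign=SIGN_NEGATIVE)


def load_reporter_table() -> list[ReporterRow]:
    """Packaged ten-gene, three-reporter tissue-induction comparison."""
    with resources.as_file(_fixture_path("table3_reporters.tsv")) as path:
        return read_reporter_table(path)
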