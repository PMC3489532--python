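"""PSM record/table domain types and delimited-text I/O.

The package's native interchange format is a delimited text table (tab by
default) with one row per peptide-spectrum match. Mandatory columns are
``spectrum_id``, ``charge`` and at least one score column; everything else
is optional. Unknown numeric columns are preserved in each record's
``features`` map so any search engine's quantities survive a round trip.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd

__all__ = [
    "PSMRecord",
    "PSMTable",
    "PSMFormatError",
    "read_psm_table",
    "write_psm_table",
]

#: Columns with dedicated fields on PSMRecord (everything else numeric
#: lands in ``features``).
_RESERVED = {
    "spectrum_id",
    "charge",
    "discriminant_score",
    "ntt",
    "nmc",
    "delta_mass",
    "is_decoy",
    "peptide",
    "protein",
    "rank",
    "true_label",
}

_TRUE_STRINGS = {"true", "t", "1", "yes", "y"}
_FALSE_STRINGS = {"false", "f", "0", "no", "n"}


class PSMFormatError(ValueError):
    """Raised when a PSM table file violates the format contract."""


@dataclass
class PSMRecord:
    """One identified spectrum with its match scores and auxiliary features.

    Parameters
    ----------
    spectrum_id : str
        Identifier of the MS/MS spectrum.
    charge : int
        Precursor ion charge (>= 1). Mixture models are fit per charge.
    features : dict
        Search-engine quantities (e.g. XCorr, deltaCn, SpRank, logDot).
    discriminant_score : float or None
        Summarized score S; None until a discriminant has been applied
        or when the input carries raw features only.
    ntt : int or None
        Number of tryptic termini (0, 1 or 2).
    nmc : int or None
        Number of missed cleavages (>= 0).
    delta_mass : float or None
        Precursor mass minus theoretical peptide mass, in Daltons.
    is_decoy : bool
        True when the match is against a decoy (e.g. reversed) sequence.
        Decoys are known-incorrect and anchor the negative component.
    peptide : str or None
        Matched peptide sequence.
    protein : str or None
        Accession of the matched protein (used for decoy-prefix detection).
    rank : int
        Candidate rank for its spectrum; the best match has rank 1.
    true_label : str or None
        Ground truth ("correct"/"incorrect"); synthetic data only.
    """

    spectrum_id: str
    charge: int
    features: dict[str, float] = field(default_factory=dict)
    discriminant_score: float | None = None
    ntt: int | None = None
    nmc: int | None = None
    delta_mass: float | None = None
    is_decoy: bool = False
    peptide: str | None = None
    protein: str | None = None
    rank: int = 1
    true_label: str | None = None

    def __post_init__(self) -> None:
        if self.charge < 1:
            raise ValueError(f"charge must be >= 1, got {self.charge}")
        if self.rank < 1:
            raise ValueError(f"rank must be >= 1, got {self.rank}")
        if self.ntt is not None and self.ntt not in (0, 1, 2):
            raise ValueError(f"ntt must be in {{0,1,2}}, got {self.ntt}")
        if self.nmc is not None and self.nmc < 0:
            raise ValueError(f"nmc must be >= 0, got {self.nmc}")
        if self.true_label is not None and self.true_label not in ("correct", "incorrect"):
            raise ValueError(f"true_label must be 'correct' or 'incorrect', got {self.true_label!r}")
        if self.is_decoy and self.true_label == "correct":
            raise ValueError("a decoy record cannot carry true_label='correct'")


@dataclass
class PSMTable:
    """Ordered collection of PSM records plus provenance metadata."""

    records: list[PSMRecord] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: set[tuple[str, int]] = set()
        for rec in self.records:
            key = (rec.spectrum_id, rec.rank)
            if key in seen:
                raise ValueError(f"duplicate (spectrum_id, rank) pair: {key}")
            seen.add(key)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def charges(self) -> list[int]:
        """Distinct charges present, ascending."""
        return sorted({r.charge for r in self.records})

    def targets(self) -> list[PSMRecord]:
        return [r for r in self.records if not r.is_decoy]

    def decoys(self) -> list[PSMRecord]:
        return [r for r in self.records if r.is_decoy]


def _parse_bool(value, line_no: int, column: str) -> bool:
    if isinstance(value, bool):
        return value
    text = str(value).strip().lower()
    if text in _TRUE_STRINGS:
        return True
    if text in _FALSE_STRINGS:
        return False
    raise PSMFormatError(f"line {line_no}: cannot parse boolean {value!r} in column {column!r}")


def _parse_float(value, line_no: int, column: str) -> float:
    try:
        return float(value)
    except (TypeError, ValueError):
        raise PSMFormatError(
            f"line {line_no}: cannot parse numeric value {value!r} in column {column!r}"
        ) from None


def _is_missing(value) -> bool:
    if value is None:
        return True
    if isinstance(value, float) and math.isnan(value):
        return True
    return isinstance(value, str) and value.strip() == ""


def read_psm_table(
    path,
    delimiter: str = "\t",
    decoy_prefix: str = "rev_",
) -> PSMTable:
    """Read a delimited PSM table.

    The header must name at least ``spectrum_id``, ``charge`` and one score
    column. The decoy flag is taken from an ``is_decoy`` column when
    present; otherwise a record is marked decoy when its ``protein``
    accession starts with ``decoy_prefix`` (reversed-sequence convention).

    Raises
    ------
    PSMFormatError
        On a missing mandatory column or an unparseable cell (the message
        names the column and, for cells, the 1-based data line number).
    """
    df = pd.read_csv(path, sep=delimiter, dtype=str, keep_default_na=False)
    for col in ("spectrum_id", "charge"):
        if col not in df.columns:
            raise PSMFormatError(f"mandatory column {col!r} missing from {path}")
    score_cols = [c for c in df.columns if c not in ("spectrum_id", "charge")]
    if not score_cols:
        raise PSMFormatError(f"no score column found in {path}")

    feature_cols = [c for c in df.columns if c not in _RESERVED]
    records: list[PSMRecord] = []
    for idx, row in enumerate(df.itertuples(index=False), start=1):
        row = dict(zip(df.columns, row))
        protein = None if _is_missing(row.get("protein")) else str(row["protein"])
        if "is_decoy" in row and not _is_missing(row["is_decoy"]):
            is_decoy = _parse_bool(row["is_decoy"], idx, "is_decoy")
        else:
            is_decoy = protein is not None and protein.startswith(decoy_prefix)
        features = {
            c: _parse_float(row[c], idx, c) for c in feature_cols if not _is_missing(row[c])
        }
        try:
            rec = PSMRecord(
                spectrum_id=str(row["spectrum_id"]),
                charge=int(_parse_float(row["charge"], idx, "charge")),
                features=features,
                discriminant_score=None
                if _is_missing(row.get("discriminant_score"))
                else _parse_float(row["discriminant_score"], idx, "discriminant_score"),
                ntt=None if _is_missing(row.get("ntt")) else int(_parse_float(row["ntt"], idx, "ntt")),
                nmc=None if _is_missing(row.get("nmc")) else int(_parse_float(row["nmc"], idx, "nmc")),
                delta_mass=None
                if _is_missing(row.get("delta_mass"))
                else _parse_float(row["delta_mass"], idx, "delta_mass"),
                is_decoy=is_decoy,
                peptide=None if _is_missing(row.get("peptide")) else str(row["peptide"]),
                protein=protein,
                rank=1 if _is_missing(row.get("rank")) else int(_parse_float(row["rank"], idx, "rank")),
                true_label=None if _is_missing(row.get("true_label")) else str(row["true_label"]),
            )
        except ValueError as exc:
            if isinstance(exc, PSMFormatError):
                raise
            raise PSMFormatError(f"line {idx}: {exc}") from exc
        records.append(rec)
    return PSMTable(records=records, metadata={"source": str(path)})


def write_psm_table(table: PSMTable, path, delimiter: str = "\t") -> None:
    """Write a PSM table as delimited text readable by :func:`read_psm_table`.

    Floats are serialized with ``repr`` (17 significant digits), so a
    write/read round trip preserves values exactly.
    """
    feature_names = sorted({name for rec in table.records for name in rec.features})
    columns = [
        "spectrum_id",
        "charge",
        "rank",
        "discriminant_score",
        "ntt",
        "nmc",
        "delta_mass",
        "is_decoy",
        "peptide",
        "protein",
        "true_label",
        *feature_names,
    ]

    def fmt(value) -> str:
        if value is None:
            return ""
        if isinstance(value, bool):
            return "true" if value else "false"
        if isinstance(value, float):
            return repr(value)
        return str(value)

    with open(path, "w", encoding="utf-8") as fh:
        fh.write(delimiter.join(columns) + "\n")
        for rec in table.records:
            row = [
                rec.spectrum_id,
                str(rec.charge),
                str(rec.rank),
                fmt(rec.discriminant_score),
                fmt(rec.ntt),
                fmt(rec.nmc),
                fmt(rec.delta_mass),
                fmt(rec.is_decoy),
                fmt(rec.peptide),
                fmt(rec.protein),
                fmt(rec.true_label),
            ]
            row.extend(fmt(rec.features.get(name)) for name in feature_names)
            fh.write(delimiter.join(row) + "\n")
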