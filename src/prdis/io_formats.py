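"""Variant tables and multiple sequence alignments.

Variant tables follow the supplementary-file dialect used for curated
missense-variant panels: one row per amino-acid substitution carrying the
replacement token (e.g. ``A42V``), the UniProt accession, three biological
feature values, the raw output of each reference pathogenicity predictor
(``?`` marking a predictor that produced no output), and a dataset tag.

Alignments are plain aligned FASTA; one record is the human reference.
"""

from __future__ import annotations

import csv
import math
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO

__all__ = [
    "MISSING",
    "Missing",
    "VariantRecord",
    "Msa",
    "DEFAULT_PREDICTORS",
    "DEFAULT_DIALECT",
    "read_variant_table",
    "write_variant_table",
    "read_msa",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: Reference predictors whose outputs the pipeline consumes.
DEFAULT_PREDICTORS = ("SIFT", "PolyPhen2", "PON-P2", "CADD", "MutationTaster2")


class Missing:
    """Sentinel for a predictor that produced no output for a variant.

    Distinct from every numeric score (``MISSING == x`` is False for any
    number) and rendered as ``?`` in variant tables.
    """

    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:
        return "MISSING"

    def __bool__(self) -> bool:
        return False


MISSING = Missing()

_REPLACEMENT_RE = re.compile(r"^([A-Za-z])(\d+)([A-Za-z])$")


class VariantTableError(ValueError):
    """Malformed variant table (bad replacement token, unknown column...)."""


class MsaFormatError(ValueError):
    """Malformed alignment (ragged rows, duplicate identifiers...)."""


@dataclass
class VariantRecord:
    """One amino-acid substitution with its annotations.

    ``position`` is 1-based in the ungapped human reference sequence
    (UniProt convention).  ``predictor_outputs`` maps predictor name to a
    raw output: a float score, a verbatim categorical call, or MISSING.
    ``features`` is the (blosum62, pssm_nat, entropy) triple or None.
    """

    protein_id: str
    native_aa: str
    position: int
    variant_aa: str
    label: str = "unlabeled"  # pathogenic | neutral | unlabeled
    predictor_outputs: dict = field(default_factory=dict)
    features: tuple | None = None
    dataset_tag: str = "other"

    def __post_init__(self):
        if self.native_aa == self.variant_aa:
            raise ValueError(
                f"native and variant residue identical: {self.replacement}"
            )
        if self.position < 1:
            raise ValueError(f"position must be >= 1, got {self.position}")

    @property
    def replacement(self) -> str:
        return f"{self.native_aa}{self.position}{self.variant_aa}"

    @property
    def key(self) -> tuple:
        """(protein, native, position, variant) identity of the substitution."""
        return (self.protein_id, self.native_aa, self.position, self.variant_aa)

    def copy(self, **changes) -> "VariantRecord":
        rec = replace(self, **changes)
        rec.predictor_outputs = dict(rec.predictor_outputs)
        return rec


@dataclass
class Msa:
    """An aligned protein family with a designated human reference row."""

    sequences: list  # list of (identifier, aligned residue string)
    human_index: int = 0

    def __post_init__(self):
        lengths = {len(s) for _, s in self.sequences}
        if len(lengths) > 1:
            raise MsaFormatError(f"ragged alignment: lengths {sorted(lengths)}")
        if not 0 <= self.human_index < len(self.sequences):
            raise MsaFormatError("human reference index out of range")

    def __len__(self) -> int:
        return len(self.sequences)

    @property
    def n_columns(self) -> int:
        return len(self.sequences[0][1]) if self.sequences else 0

    @property
    def human_id(self) -> str:
        return self.sequences[self.human_index][0]

    @property
    def human_seq(self) -> str:
        return self.sequences[self.human_index][1]

    def human_column_of_position(self, position: int) -> int:
        """Alignment column (0-based) holding ungapped human position (1-based)."""
        seen = 0
        for col, aa in enumerate(self.human_seq):
            if aa != "-":
                seen += 1
                if seen == position:
                    return col
        raise IndexError(
            f"position {position} beyond human sequence "
            f"({seen} residues) in {self.human_id}"
        )

    def position_of_human_column(self, col: int) -> int:
        """Ungapped human position (1-based) of alignment column ``col``."""
        if self.human_seq[col] == "-":
            raise ValueError(f"human reference has a gap at column {col}")
        return sum(1 for aa in self.human_seq[: col + 1] if aa != "-")


def _parse_replacement(token: str, row_number: int) -> tuple[str, int, str]:
    m = _REPLACEMENT_RE.match(token.strip())
    if not m:
        raise VariantTableError(
            f"row {row_number}: malformed replacement token {token!r}"
        )
    return m.group(1).upper(), int(m.group(2)), m.group(3).upper()


def _parse_cell(raw: str):
    """'?' -> MISSING; numeric text -> float; anything else kept verbatim."""
    raw = raw.strip()
    if raw in ("?", ""):
        return MISSING
    try:
        value = float(raw)
    except ValueError:
        return raw
    if math.isnan(value):
        return MISSING
    return value


#: Column mapping matching the supplementary-table narrative order:
#: replacement, protein accession, three features, predictor outputs
#: (both PolyPhen-2 versions are listed; only HDIV feeds the analyses),
#: dataset tag.
DEFAULT_DIALECT = {
    "replacement": "replacement",
    "protein": "protein",
    "label": "label",
    "features": {
        "blosum62": "blosum62",
        "pssm_nat": "pssm_nat",
        "entropy": "entropy",
    },
    "predictors": {
        "SIFT": "SIFT",
        "PolyPhen2": "PolyPhen2_HDIV",
        "PolyPhen2_HVAR": "PolyPhen2_HVAR",
        "PON-P2": "PON-P2",
        "CADD": "CADD",
        "MutationTaster2": "MutationTaster2",
    },
    "dataset_tag": "dataset",
    "delimiter": None,  # auto-detect among , ; \t
}


def _sniff_delimiter(sample: str) -> str:
    try:
        return csv.Sniffer().sniff(sample, delimiters=",;\t").delimiter
    except csv.Error:
        return ","


def read_variant_table(
    path, dialect_config: Mapping | None = None
) -> list[VariantRecord]:
    """Read a variant table into :class:`VariantRecord` objects.

    ``dialect_config`` follows :data:`DEFAULT_DIALECT`; absent keys fall
    back to the default.  A ``?`` (or empty) cell in a predictor or feature
    column becomes MISSING.  Rows with malformed replacement tokens raise
    :class:`VariantTableError` naming the row.
    """
    cfg = dict(DEFAULT_DIALECT)
    if dialect_config:
        cfg.update(dialect_config)
    path = Path(path)
    text = path.read_text()
    if not text.strip():
        return []
    delimiter = cfg.get("delimiter") or _sniff_delimiter(text.splitlines()[0])
    reader = csv.DictReader(text.splitlines(), delimiter=delimiter)
    header = reader.fieldnames or []

    pred_cols = cfg["predictors"]
    known_pred_cols = {name: col for name, col in pred_cols.items() if col in header}
    feat_cols = cfg["features"]
    have_features = all(col in header for col in feat_cols.values())

    records: list[VariantRecord] = []
    for i, row in enumerate(reader, start=2):  # 1 is the header line
        if cfg["replacement"] in row and row[cfg["replacement"]] not in (None, ""):
            native, pos, variant = _parse_replacement(row[cfg["replacement"]], i)
        else:
            try:
                native = row[cfg.get("native", "native")].strip().upper()
                pos = int(row[cfg.get("position", "position")])
                variant = row[cfg.get("variant", "variant")].strip().upper()
            except (KeyError, TypeError, ValueError):
                raise VariantTableError(
                    f"row {i}: no replacement token and no "
                    "native/position/variant columns"
                ) from None
        outputs = {
            name: _parse_cell(row[col]) for name, col in known_pred_cols.items()
        }
        features = None
        if have_features:
            vals = [_parse_cell(row[feat_cols[k]]) for k in ("blosum62", "pssm_nat", "entropy")]
            if all(isinstance(v, float) for v in vals):
                features = tuple(vals)
        records.append(
            VariantRecord(
                protein_id=row.get(cfg["protein"], "").strip(),
                native_aa=native,
                position=pos,
                variant_aa=variant,
                label=row.get(cfg["label"], "unlabeled").strip() or "unlabeled",
                predictor_outputs=outputs,
                features=features,
                dataset_tag=row.get(cfg["dataset_tag"], "other").strip() or "other",
            )
        )
    return records


def _format_cell(value) -> str:
    if value is MISSING:
        return "?"
    if isinstance(value, float):
        return repr(value)
    return str(value)


def write_variant_table(
    records: Sequence[VariantRecord],
    path,
    dialect_config: Mapping | None = None,
) -> Path:
    """Write records as CSV in the supplementary dialect (MISSING -> '?')."""
    cfg = dict(DEFAULT_DIALECT)
    if dialect_config:
        cfg.update(dialect_config)
    path = Path(path)
    pred_names = list(cfg["predictors"])
    present = [
        n for n in pred_names if any(n in r.predictor_outputs for r in records)
    ] or [n for n in pred_names if cfg["predictors"][n] != "PolyPhen2_HVAR"]
    feat_cols = cfg["features"]
    header = (
        [cfg["replacement"], cfg["protein"], cfg["label"]]
        + [feat_cols[k] for k in ("blosum62", "pssm_nat", "entropy")]
        + [cfg["predictors"][n] for n in present]
        + [cfg["dataset_tag"]]
    )
    delimiter = cfg.get("delimiter") or ","
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter=delimiter)
        writer.writerow(header)
        for rec in records:
            feats = rec.features if rec.features is not None else (MISSING,) * 3
            writer.writerow(
                [rec.replacement, rec.protein_id, rec.label]
                + [_format_cell(v) for v in feats]
                + [_format_cell(rec.predictor_outputs.get(n, MISSING)) for n in present]
                + [rec.dataset_tag]
            )
    return path


def read_msa(path, human_id: str | None = None) -> Msa:
    """Read an aligned FASTA file.

    Residues are upper-cased and gap characters ('.', '-') normalised to
    '-'.  The human reference is the record whose id matches ``human_id``,
    or the first record when ``human_id`` is None.
    """
    seqs: list[tuple[str, str]] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise MsaFormatError(f"duplicate identifier {rec.id!r} in {path}")
        seen.add(rec.id)
        seqs.append((rec.id, str(rec.seq).upper().replace(".", "-")))
    if not seqs:
        raise MsaFormatError(f"no sequences in {path}")
    human_index = 0
    if human_id is not None:
        matches = [i for i, (sid, _) in enumerate(seqs) if sid == human_id]
        if len(matches) != 1:
            raise MsaFormatError(
                f"human reference {human_id!r} found {len(matches)} times in {path}"
            )
        human_index = matches[0]
    return Msa(sequences=seqs, human_index=human_index)
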