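"""Biological features of an amino-acid substitution.

Three properties enrich the raw predictor scores: the BLOSUM62 element of
the replacement, the Shannon entropy of the alignment column holding the
variant, and pssm_nat = log(f_nat,i / f_nat,MSA) — the log-ratio of the
native residue's frequency at the variant column versus over the whole
alignment.  Entropy and pssm_nat use natural logarithms by default; the
base only rescales both monotonically.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from Bio.Align import substitution_matrices

from .io_formats import AMINO_ACIDS, Msa, VariantRecord

__all__ = [
    "MsaColumnProfile",
    "blosum62_element",
    "shannon_entropy",
    "pssm_nat",
    "column_profile",
    "annotate_features",
]

_BLOSUM62 = substitution_matrices.load("BLOSUM62")


def blosum62_element(native_aa: str, variant_aa: str) -> int:
    """Canonical BLOSUM62 entry for the replacement (symmetric)."""
    for aa in (native_aa, variant_aa):
        if aa not in AMINO_ACIDS:
            raise ValueError(f"non-standard amino acid {aa!r}")
    return int(_BLOSUM62[native_aa, variant_aa])


@dataclass
class MsaColumnProfile:
    """Residue composition of one alignment column plus alignment-wide
    context for the native residue.  Gaps are excluded from all counts."""

    counts: dict  # amino acid -> count in the column
    native_aa: str
    native_msa_count: int  # native residue count over the whole alignment
    msa_total: int  # residue (non-gap) count over the whole alignment

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    @property
    def p(self) -> dict:
        n = self.total
        return {aa: c / n for aa, c in self.counts.items() if c > 0}

    @property
    def f_nat_i(self) -> float:
        return self.counts.get(self.native_aa, 0) / self.total

    @property
    def f_nat_msa(self) -> float:
        return self.native_msa_count / self.msa_total


def column_profile(msa: Msa, position: int, native_aa: str | None = None) -> MsaColumnProfile:
    """Profile of the column holding ungapped human ``position`` (1-based)."""
    col = msa.human_column_of_position(position)
    native = native_aa if native_aa is not None else msa.human_seq[col]
    counts: dict[str, int] = {}
    for _, seq in msa.sequences:
        aa = seq[col]
        if aa != "-":
            counts[aa] = counts.get(aa, 0) + 1
    native_msa = 0
    total = 0
    for _, seq in msa.sequences:
        for aa in seq:
            if aa == "-":
                continue
            total += 1
            if aa == native:
                native_msa += 1
    return MsaColumnProfile(
        counts=counts, native_aa=native, native_msa_count=native_msa, msa_total=total
    )


def shannon_entropy(profile: MsaColumnProfile | Mapping[str, int], base: float | None = None) -> float:
    """-sum_i p_i log(p_i) over the residues observed in the column."""
    counts = profile.counts if isinstance(profile, MsaColumnProfile) else dict(profile)
    total = sum(counts.values())
    if total == 0:
        raise ValueError("empty column: entropy undefined")
    h = 0.0
    for c in counts.values():
        if c > 0:
            p = c / total
            h -= p * math.log(p)
    if base is not None:
        h /= math.log(base)
    return h


def pssm_nat(
    profile: MsaColumnProfile,
    pseudocount: float = 0.5,
    base: float | None = None,
) -> float:
    """log(f_nat,i / f_nat,MSA) with optional additive smoothing.

    With ``pseudocount`` q, frequencies become (count + q)/(total + 20 q)
    so the ratio stays finite even when the native residue is absent from
    the column of a sparse alignment.  q = 0 is the raw formula and raises
    when either frequency vanishes.
    """
    q = pseudocount
    if q < 0:
        raise ValueError("pseudocount must be >= 0")
    n_aa = len(AMINO_ACIDS)
    f_i = (profile.counts.get(profile.native_aa, 0) + q) / (profile.total + n_aa * q)
    f_msa = (profile.native_msa_count + q) / (profile.msa_total + n_aa * q)
    if f_i == 0 or f_msa == 0:
        raise ValueError(
            "native residue absent and pseudocount 0: pssm_nat non-finite"
        )
    value = math.log(f_i / f_msa)
    if base is not None:
        value /= math.log(base)
    return value


def compute_feature_triple(
    record: VariantRecord,
    msa: Msa,
    pseudocount: float = 0.5,
    base: float | None = None,
) -> tuple[float, float, float]:
    """(blosum62, pssm_nat, entropy) for one variant from its family MSA."""
    col = msa.human_column_of_position(record.position)
    human_aa = msa.human_seq[col]
    if human_aa != record.native_aa:
        raise ValueError(
            f"{record.replacement}: human reference has {human_aa} at "
            f"position {record.position}"
        )
    profile = column_profile(msa, record.position, record.native_aa)
    return (
        float(blosum62_element(record.native_aa, record.variant_aa)),
        pssm_nat(profile, pseudocount=pseudocount, base=base),
        shannon_entropy(profile, base=base),
    )


def annotate_features(
    records: Sequence[VariantRecord],
    msas: Mapping[str, Msa],
    recompute: bool = False,
    pseudocount: float = 0.5,
    base: float | None = None,
) -> tuple[list[VariantRecord], list[tuple[VariantRecord, str]]]:
    """Fill each record's feature triple from its protein's alignment.

    Records already carrying features are left unchanged unless
    ``recompute``.  Returns (annotated records, failures) where failures
    pairs a record with the reason it could not be annotated; failed
    records keep their original features.
    """
    out: list[VariantRecord] = []
    failures: list[tuple[VariantRecord, str]] = []
    for rec in records:
        if rec.features is not None and not recompute:
            out.append(rec)
            continue
        msa = msas.get(rec.protein_id)
        if msa is None:
            failures.append((rec, "no alignment for protein"))
            out.append(rec)
            continue
        try:
            triple = compute_feature_triple(
                rec, msa, pseudocount=pseudocount, base=base
            )
        except (IndexError, ValueError) as exc:
            failures.append((rec, str(exc)))
            out.append(rec)
            continue
        out.append(rec.copy(features=triple))
    return out, failures
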