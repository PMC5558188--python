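"""Assembly of pathogenic/neutral variant datasets.

Pathogenic variants come from a curated table (Humsavar-style "Disease"
annotations); proteins contributing fewer than ``thres`` pathogenic
variants are dropped to limit the neutral/pathogenic imbalance.  Neutral
variants come from a homology-based model: every deviation from the human
reference observed in a close homolog (>= 95% pairwise identity) within
the family alignment is taken as tolerated, hence neutral.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from Bio.Data import CodonTable

from .io_formats import Msa, VariantRecord

__all__ = [
    "DatasetBuildConfig",
    "filter_by_protein_count",
    "pairwise_identity",
    "harvest_neutral_variants",
    "filter_snv_reachable",
    "assemble_dataset",
]

logger = logging.getLogger(__name__)


@dataclass
class DatasetBuildConfig:
    """Knobs of the dataset build.

    thres: minimum pathogenic variants a protein must contribute (30 keeps
        the neutral:pathogenic ratio near 2.8 in the original curation).
    identity_min_neutral: homologs at or above this pairwise identity to
        the human sequence donate neutral variants (0.95).
    identity_min_keep: homologs below this identity are discarded from the
        alignment before harvesting (0.40).
    snv_only: restrict to substitutions reachable by a single nucleotide
        change in some codon of the native residue.
    count_all_labels: count every variant, not just pathogenic ones,
        toward ``thres``.
    """

    thres: int = 30
    identity_min_neutral: float = 0.95
    identity_min_keep: float = 0.40
    snv_only: bool = False
    count_all_labels: bool = False

    def __post_init__(self):
        if self.thres < 0:
            raise ValueError("thres must be non-negative")
        if not 0 <= self.identity_min_keep <= self.identity_min_neutral <= 1:
            raise ValueError(
                "need 0 <= identity_min_keep <= identity_min_neutral <= 1"
            )


def filter_by_protein_count(
    records: Sequence[VariantRecord],
    thres: int,
    count_all_labels: bool = False,
) -> list[VariantRecord]:
    """Drop pathogenic records of proteins with fewer than ``thres`` of them.

    A protein contributing >= thres pathogenic variants keeps all its
    records; below the threshold its pathogenic records are removed
    (non-pathogenic records are untouched either way).
    """
    if thres < 0:
        raise ValueError("thres must be non-negative")
    counts = Counter(
        r.protein_id
        for r in records
        if count_all_labels or r.label == "pathogenic"
    )
    kept = [
        r
        for r in records
        if r.label != "pathogenic" or counts[r.protein_id] >= thres
    ]
    return kept


def pairwise_identity(seq_a: str, seq_b: str) -> float:
    """Fraction of identical residues over mutually gap-free columns."""
    if len(seq_a) != len(seq_b):
        raise ValueError("aligned sequences must have equal length")
    same = 0
    comparable = 0
    for a, b in zip(seq_a, seq_b):
        if a == "-" or b == "-":
            continue
        comparable += 1
        if a == b:
            same += 1
    if comparable == 0:
        raise ValueError("no mutually gap-free columns; identity undefined")
    return same / comparable


def harvest_neutral_variants(
    msa: Msa, config: DatasetBuildConfig | None = None
) -> list[VariantRecord]:
    """Collect neutral variants from close homologs in a family alignment.

    Every mutually gap-free column where a homolog of identity >=
    ``identity_min_neutral`` differs from the human reference yields one
    neutral record (native = human residue, variant = homolog residue,
    position = ungapped human position).  The same substitution seen in
    several homologs is emitted once.  Homologs below
    ``identity_min_keep`` are ignored entirely.
    """
    config = config or DatasetBuildConfig()
    human = msa.human_seq
    protein = msa.human_id
    seen: set[tuple] = set()
    out: list[VariantRecord] = []
    for i, (sid, seq) in enumerate(msa.sequences):
        if i == msa.human_index:
            continue
        identity = pairwise_identity(human, seq)
        if identity < config.identity_min_keep:
            continue
        if identity < config.identity_min_neutral:
            continue
        pos = 0
        for col, h_aa in enumerate(human):
            if h_aa == "-":
                continue
            pos += 1
            v_aa = seq[col]
            if v_aa == "-" or v_aa == h_aa:
                continue
            rec = VariantRecord(
                protein_id=protein,
                native_aa=h_aa,
                position=pos,
                variant_aa=v_aa,
                label="neutral",
            )
            if rec.key in seen:
                continue
            seen.add(rec.key)
            out.append(rec)
    return out


def _snv_reachable_pairs() -> frozenset[tuple[str, str]]:
    """All (native, variant) amino-acid pairs one nucleotide change apart.

    Enumerates every codon pair of the standard genetic code differing at
    exactly one position.
    """
    table = CodonTable.unambiguous_dna_by_id[1]
    codons_of: dict[str, list[str]] = {}
    for codon, aa in table.forward_table.items():
        codons_of.setdefault(aa, []).append(codon)
    pairs = set()
    for aa_a, codons_a in codons_of.items():
        for aa_b, codons_b in codons_of.items():
            if aa_a == aa_b:
                continue
            if any(
                sum(x != y for x, y in zip(ca, cb)) == 1
                for ca in codons_a
                for cb in codons_b
            ):
                pairs.add((aa_a, aa_b))
    return frozenset(pairs)


_SNV_PAIRS = None


def snv_reachable(native_aa: str, variant_aa: str) -> bool:
    """True when the substitution is achievable by one nucleotide change."""
    global _SNV_PAIRS
    if _SNV_PAIRS is None:
        _SNV_PAIRS = _snv_reachable_pairs()
    for aa in (native_aa, variant_aa):
        if aa not in "ACDEFGHIKLMNPQRSTVWY":
            raise ValueError(f"non-standard amino acid {aa!r}")
    return (native_aa, variant_aa) in _SNV_PAIRS


def filter_snv_reachable(records: Sequence[VariantRecord]) -> list[VariantRecord]:
    """Keep substitutions reachable by a single nucleotide replacement."""
    return [r for r in records if snv_reachable(r.native_aa, r.variant_aa)]


def assemble_dataset(
    pathogenic: Sequence[VariantRecord],
    msas: Mapping[str, Msa],
    config: DatasetBuildConfig | None = None,
    dataset_tag: str = "other",
) -> tuple[list[VariantRecord], dict]:
    """Build the pathogenic + harvested-neutral dataset.

    Returns (records, build_log).  Proteins passing the ``thres`` filter
    but lacking an alignment are listed in ``build_log['skipped']`` and
    contribute only their pathogenic records.
    """
    config = config or DatasetBuildConfig()
    kept = filter_by_protein_count(
        pathogenic, config.thres, config.count_all_labels
    )
    proteins = sorted({r.protein_id for r in kept})
    records = [r.copy(dataset_tag=dataset_tag) for r in kept]
    skipped = []
    per_protein: dict[str, dict] = {}
    for protein in proteins:
        n_path = sum(1 for r in kept if r.protein_id == protein)
        if protein not in msas:
            skipped.append(protein)
            per_protein[protein] = {"pathogenic": n_path, "neutral": 0}
            continue
        neutral = harvest_neutral_variants(msas[protein], config)
        records.extend(r.copy(dataset_tag=dataset_tag) for r in neutral)
        per_protein[protein] = {"pathogenic": n_path, "neutral": len(neutral)}
    if config.snv_only:
        records = filter_snv_reachable(records)
    n_path = sum(1 for r in records if r.label == "pathogenic")
    n_neut = sum(1 for r in records if r.label == "neutral")
    build_log = {
        "proteins": len(proteins),
        "pathogenic": n_path,
        "neutral": n_neut,
        "total": len(records),
        "skipped": skipped,
        "per_protein": per_protein,
    }
    if skipped:
        logger.warning("no alignment for %d protein(s): %s", len(skipped), skipped)
    logger.info(
        "assembled dataset: %d proteins, %d pathogenic, %d neutral",
        len(proteins), n_path, n_neut,
    )
    return records, build_log
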