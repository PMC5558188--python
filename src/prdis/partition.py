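"""Coincidence-rule partitioning of a variant set.

Clinical guidelines (ACMG/AMP) accept computational evidence only when
every applied in-silico tool agrees on the call; on disagreement the
evidence is discarded.  For a chosen combination of reference predictors
this tri-partitions a variant set into AGREE (unanimous calls), PRDIS
(contradictory calls — the subset the specific predictors target) and
NO-OUTPUT (at least one predictor gave no output).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .io_formats import MISSING, VariantRecord

__all__ = [
    "PredictorSpec",
    "PartitionResult",
    "binarize",
    "apply_coincidence_rule",
    "enumerate_combinations",
    "partition_report",
    "default_registry",
]

PATHOGENIC = "pathogenic"
NEUTRAL = "neutral"


class BinarizationError(ValueError):
    """A raw predictor output could not be mapped to a binary call."""


@dataclass
class PredictorSpec:
    """How one predictor's raw output maps to a binary call.

    Exactly one mode is active: ``score_threshold`` compares a numeric
    score against ``threshold`` (ties are called pathogenic), with
    ``direction`` saying which side is pathogenic; ``categorical_map``
    translates verbatim calls.  When a record carries a categorical call
    for a score-mode predictor the category map (if given) takes
    precedence.
    """

    name: str
    mode: str = "score_threshold"  # or "categorical_map"
    threshold: float | None = None
    direction: str = "higher_is_pathogenic"  # or lower_is_pathogenic
    category_map: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.mode not in ("score_threshold", "categorical_map"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "score_threshold":
            if self.threshold is None or not (
                float("-inf") < self.threshold < float("inf")
            ):
                raise ValueError(f"{self.name}: finite threshold required")
        if self.direction not in ("higher_is_pathogenic", "lower_is_pathogenic"):
            raise ValueError(f"unknown direction {self.direction!r}")


def default_registry() -> dict[str, PredictorSpec]:
    """Binarization specs for the five reference predictors.

    Cutoffs follow each tool's published convention: SIFT scores below
    0.05 are deleterious; PolyPhen-2 (HDIV) probabilities at or above 0.5
    are damaging; CADD phred scores at or above 15 are deleterious;
    PON-P2 and MutationTaster2 emit categorical calls (PON-P2's
    "unknown" class is treated as no output).  All overridable in config.
    """
    return {
        "SIFT": PredictorSpec(
            "SIFT", threshold=0.05, direction="lower_is_pathogenic"
        ),
        "PolyPhen2": PredictorSpec(
            "PolyPhen2",
            threshold=0.5,
            category_map={
                "probably_damaging": PATHOGENIC,
                "possibly_damaging": PATHOGENIC,
                "benign": NEUTRAL,
            },
        ),
        "CADD": PredictorSpec("CADD", threshold=15.0),
        "PON-P2": PredictorSpec(
            "PON-P2",
            mode="categorical_map",
            category_map={
                "pathogenic": PATHOGENIC,
                "neutral": NEUTRAL,
                "unknown": MISSING,
            },
        ),
        "MutationTaster2": PredictorSpec(
            "MutationTaster2",
            mode="categorical_map",
            category_map={
                "disease_causing": PATHOGENIC,
                "disease_causing_automatic": PATHOGENIC,
                "polymorphism": NEUTRAL,
                "polymorphism_automatic": NEUTRAL,
            },
        ),
    }


def binarize(record: VariantRecord, spec: PredictorSpec):
    """Binary call {pathogenic, neutral, MISSING} for one predictor output."""
    raw = record.predictor_outputs.get(spec.name, MISSING)
    if raw is MISSING:
        return MISSING
    if isinstance(raw, str):
        key = raw.strip().lower().replace(" ", "_")
        if key not in spec.category_map:
            raise BinarizationError(
                f"{spec.name}: call {raw!r} absent from category map"
            )
        return spec.category_map[key]
    if spec.mode == "categorical_map":
        raise BinarizationError(
            f"{spec.name}: numeric output {raw!r} for a categorical predictor"
        )
    # Ties at the threshold are called pathogenic.
    if spec.direction == "higher_is_pathogenic":
        return PATHOGENIC if raw >= spec.threshold else NEUTRAL
    return PATHOGENIC if raw <= spec.threshold else NEUTRAL


@dataclass
class PartitionResult:
    """Tri-partition of a variant set under one predictor combination.

    Variants are addressed by their index in the input sequence.  The
    three sets are pairwise disjoint and cover the input: ``agree`` maps
    index -> unanimous call, ``prdis`` holds the contradictory cases,
    ``no_output`` those with at least one missing output.
    """

    combination: tuple
    agree: dict  # index -> agreed call
    prdis: set
    no_output: set
    n_input: int

    def __post_init__(self):
        a, p, n = set(self.agree), self.prdis, self.no_output
        if a & p or a & n or p & n:
            raise ValueError("partition sets overlap")
        if len(a) + len(p) + len(n) != self.n_input:
            raise ValueError("partition does not cover the input set")


def apply_coincidence_rule(
    records: Sequence[VariantRecord],
    combination: Sequence[str],
    specs: Mapping[str, PredictorSpec] | None = None,
) -> PartitionResult:
    """Partition ``records`` into AGREE / PRDIS / NO-OUTPUT.

    The rule is unanimous: a variant is AGREE only when every predictor
    in the combination produced an output and all binary calls coincide;
    any missing output sends it to NO-OUTPUT; otherwise it is PRDIS.
    """
    if len(combination) < 2:
        raise ValueError("coincidence rule needs at least two predictors")
    specs = specs if specs is not None else default_registry()
    for name in combination:
        if name not in specs:
            raise ValueError(f"no binarization spec registered for {name!r}")
    agree: dict[int, str] = {}
    prdis: set[int] = set()
    no_output: set[int] = set()
    for i, rec in enumerate(records):
        calls = [binarize(rec, specs[name]) for name in combination]
        if any(c is MISSING for c in calls):
            no_output.add(i)
        elif all(c == calls[0] for c in calls):
            agree[i] = calls[0]
        else:
            prdis.add(i)
    return PartitionResult(
        combination=tuple(combination),
        agree=agree,
        prdis=prdis,
        no_output=no_output,
        n_input=len(records),
    )


def enumerate_combinations(
    predictors: Sequence[str], min_size: int = 2
) -> list[tuple]:
    """All predictor subsets of size >= min_size, by size then lexicographic."""
    if min_size < 2:
        raise ValueError("the coincidence rule is undefined below two predictors")
    combos: list[tuple] = []
    for size in range(min_size, len(predictors) + 1):
        combos.extend(
            sorted(itertools.combinations(sorted(predictors), size))
        )
    return combos


def partition_report(result: PartitionResult, total: int | None = None) -> dict:
    """Counts and percentages of each partition relative to the input set.

    ``entered`` counts the variants receiving output from every predictor
    (AGREE + PRDIS).  Percentages are relative to ``total`` (defaults to
    the partition's input size).
    """
    total = result.n_input if total is None else total
    if total < len(result.agree) + len(result.prdis) + len(result.no_output):
        raise ValueError("total smaller than the partition union")
    n_agree = len(result.agree)
    n_prdis = len(result.prdis)
    n_no = len(result.no_output)
    entered = n_agree + n_prdis

    def pct(n):
        return 100.0 * n / total if total else 0.0

    return {
        "combination": list(result.combination),
        "total": total,
        "agree": n_agree,
        "prdis": n_prdis,
        "no_output": n_no,
        "entered": entered,
        "agree_pct": pct(n_agree),
        "prdis_pct": pct(n_prdis),
        "no_output_pct": pct(n_no),
        "entered_pct": pct(entered),
    }
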