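"""Synthetic variant panels with the statistical structure the pipeline
assumes.

Each variant carries a latent binary label; every reference predictor
observes the label through a Gaussian channel — latent score
s = signal_strength·(±1) + N(0, noise_sd) — squashed onto the tool's
native scale and masked as missing at the tool's no-output rate.  Family
alignments are generated with a mixture of conserved and variable
columns, and pathogenic variants land preferentially on conserved
columns (the flip side of the homology-based neutral model, where
tolerated substitutions cluster at variable positions).  The Gaussian
channel is chosen for its analytic agreement/disagreement rates, which
serve as closed-form oracles; no claim is made that it matches real
score distributions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import norm

from .features import annotate_features, blosum62_element
from .io_formats import AMINO_ACIDS, MISSING, Msa, VariantRecord
from .partition import PredictorSpec

__all__ = [
    "PredictorModel",
    "ConservationMix",
    "SyntheticPanelSpec",
    "generate_panel",
    "synthetic_registry",
    "expected_partition_fractions",
]


@dataclass
class PredictorModel:
    """Gaussian observation channel for one reference tool.

    ``signal_strength`` / ``noise_sd`` set the per-tool error rate
    Phi(-signal/noise); 0.85/1.0 gives the ~80% single-tool accuracy
    typical of the field.  ``scale`` maps the latent score onto the
    tool's native range: "unit" (logistic squash to [0,1]),
    "unit_inverted" (lower = pathogenic, SIFT-style) or "phred"
    (15 + 5 s, CADD-style).
    """

    signal_strength: float = 0.85
    noise_sd: float = 1.0
    missing_rate: float = 0.0
    scale: str = "unit"

    def __post_init__(self):
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")
        if self.scale not in ("unit", "unit_inverted", "phred"):
            raise ValueError(f"unknown scale {self.scale!r}")

    @property
    def error_rate(self) -> float:
        """Probability the binarized call contradicts the label."""
        if self.noise_sd == 0:
            return 0.0 if self.signal_strength > 0 else 0.5
        return float(norm.sf(self.signal_strength / self.noise_sd))

    def squash(self, s: float) -> float:
        if self.scale == "unit":
            return 1.0 / (1.0 + math.exp(-s))
        if self.scale == "unit_inverted":
            return 1.0 / (1.0 + math.exp(s))
        return 15.0 + 5.0 * s


def default_predictor_models() -> dict[str, PredictorModel]:
    """Five tools with no-output rates mirroring the coverages observed
    on curated panels (SIFT ~97%, PolyPhen-2 ~99%, MutationTaster2 and
    CADD ~55% — they skip substitutions needing more than one nucleotide
    change — and PON-P2 in between)."""
    return {
        "SIFT": PredictorModel(missing_rate=0.03, scale="unit_inverted"),
        "PolyPhen2": PredictorModel(missing_rate=0.01),
        "PON-P2": PredictorModel(missing_rate=0.30),
        "CADD": PredictorModel(missing_rate=0.45, scale="phred"),
        "MutationTaster2": PredictorModel(missing_rate=0.45),
    }


@dataclass
class ConservationMix:
    """Two-component column model for generated alignments.

    A column is conserved with probability ``p_conserved`` and then
    substituted in homologs at rate ``conserved_sub``; otherwise it is
    variable with substitution rate ``variable_sub``.  Pathogenic
    variants are placed on conserved columns (and neutral ones on
    variable columns) with probability ``placement_fidelity``.
    """

    p_conserved: float = 0.5
    conserved_sub: float = 0.03
    variable_sub: float = 0.40
    placement_fidelity: float = 0.9


@dataclass
class SyntheticPanelSpec:
    """Generative parameters of a synthetic variant panel.

    Defaults emulate the curated-panel conditions: ~26% pathogenic
    prevalence (15,723 of 59,442 variants), tens of variants per
    protein, alignments of 30 sequences.
    """

    n_proteins: int = 10
    variants_per_protein: int = 60
    prevalence: float = 0.265
    predictor_models: dict = field(default_factory=default_predictor_models)
    msa_depth: int = 30
    conservation: ConservationMix = field(default_factory=ConservationMix)
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.prevalence < 1:
            raise ValueError("prevalence must be in (0, 1)")


def synthetic_registry(spec: SyntheticPanelSpec) -> dict[str, PredictorSpec]:
    """Binarization specs matching the generator's squashing functions.

    Every tool's decision boundary sits at latent score 0: 0.5 on the
    unit scales, 15 on the phred scale.
    """
    registry = {}
    for name, model in spec.predictor_models.items():
        if model.scale == "unit":
            registry[name] = PredictorSpec(name, threshold=0.5)
        elif model.scale == "unit_inverted":
            registry[name] = PredictorSpec(
                name, threshold=0.5, direction="lower_is_pathogenic"
            )
        else:
            registry[name] = PredictorSpec(name, threshold=15.0)
    return registry


def _weighted_variant_aa(native: str, pathogenic: bool, rng) -> str:
    """Pick a replacement residue; pathogenic substitutions lean radical
    (lower BLOSUM62), neutral ones conservative, echoing real panels."""
    candidates = rng.choice(
        [aa for aa in AMINO_ACIDS if aa != native], size=2, replace=False
    )
    scores = [blosum62_element(native, aa) for aa in candidates]
    pick = int(np.argmin(scores)) if pathogenic else int(np.argmax(scores))
    return str(candidates[pick])


def generate_panel(
    spec: SyntheticPanelSpec,
) -> tuple[list[VariantRecord], dict[str, Msa]]:
    """Generate a labelled variant panel plus per-protein alignments.

    Fully reproducible under ``spec.seed``.  Records carry predictor
    outputs on each tool's native scale ('?'-style MISSING at the
    tool's no-output rate) and the annotated biological feature triple.
    """
    rng = np.random.default_rng(spec.seed)
    mix = spec.conservation
    records: list[VariantRecord] = []
    msas: dict[str, Msa] = {}
    aa_arr = np.array(list(AMINO_ACIDS))
    for p in range(spec.n_proteins):
        protein = f"SYN{p:04d}"
        n_var = spec.variants_per_protein
        length = max(2 * n_var, 50)
        human = rng.choice(aa_arr, size=length)
        conserved = rng.random(length) < mix.p_conserved
        sub_rate = np.where(conserved, mix.conserved_sub, mix.variable_sub)
        seqs = [(f"{protein}_HUMAN", "".join(human))]
        for h in range(spec.msa_depth - 1):
            mask = rng.random(length) < sub_rate
            hom = human.copy()
            for j in np.where(mask)[0]:
                choices = aa_arr[aa_arr != human[j]]
                hom[j] = rng.choice(choices)
            seqs.append((f"{protein}_hom{h}", "".join(hom)))
        msa = Msa(sequences=seqs, human_index=0)
        msas[protein] = msa

        cons_pos = list(np.where(conserved)[0] + 1)
        var_pos = list(np.where(~conserved)[0] + 1)
        rng.shuffle(cons_pos)
        rng.shuffle(var_pos)
        labels = rng.random(n_var) < spec.prevalence
        for is_path in labels:
            want_conserved = (
                is_path
                if rng.random() < mix.placement_fidelity
                else not is_path
            )
            pool = cons_pos if want_conserved else var_pos
            if not pool:
                pool = var_pos if want_conserved else cons_pos
            position = pool.pop()
            native = str(human[position - 1])
            variant = _weighted_variant_aa(native, bool(is_path), rng)
            outputs = {}
            for name, model in spec.predictor_models.items():
                if rng.random() < model.missing_rate:
                    outputs[name] = MISSING
                    continue
                s = model.signal_strength * (1.0 if is_path else -1.0)
                s += rng.normal(0.0, model.noise_sd)
                outputs[name] = model.squash(s)
            records.append(
                VariantRecord(
                    protein_id=protein,
                    native_aa=native,
                    position=position,
                    variant_aa=variant,
                    label="pathogenic" if is_path else "neutral",
                    predictor_outputs=outputs,
                    dataset_tag="synthetic",
                )
            )
    records, failures = annotate_features(records, msas)
    assert not failures, f"feature annotation failed: {failures[:3]}"
    return records, msas


def expected_partition_fractions(
    spec: SyntheticPanelSpec, combination: Sequence[str]
) -> tuple[float, float, float]:
    """Closed-form (agree, prdis, no_output) fractions under independence.

    With per-tool output probability o_j = 1 - missing_rate_j and error
    rate e_j, a variant has full output with probability prod(o_j), and
    conditional on that the calls are unanimous with probability
    prod(1 - e_j) + prod(e_j) (all correct or all wrong; the Gaussian
    channel is label-symmetric).
    """
    models = [spec.predictor_models[name] for name in combination]
    p_out = float(np.prod([1.0 - m.missing_rate for m in models]))
    errs = [m.error_rate for m in models]
    unanimous = float(np.prod([1.0 - e for e in errs]) + np.prod(errs))
    agree = p_out * unanimous
    prdis = p_out * (1.0 - unanimous)
    no_output = 1.0 - p_out
    return agree, prdis, no_output
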