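import pytest

from prdis import (
    MISSING,
    Msa,
    PredictorSpec,
    SyntheticPanelSpec,
    VariantRecord,
    generate_panel,
    synthetic_registry,
)


@pytest.fixture
def two_predictor_registry():
    """Score-mode specs for a toy pair of tools (both 0.5 cutoffs)."""
    return {
        "A": PredictorSpec("A", threshold=0.5),
        "B": PredictorSpec("B", threshold=0.5),
    }


@pytest.fixture
def eight_variant_fixture():
    """Hand-built labelled set exercising agree / disagree / missing.

    Predictors A and B give probabilities (higher = pathogenic, cutoff
    0.5). Per variant: (label, A, B) ->
      v0 path  (0.9, 0.9) agree-correct      v4 neut (0.1, 0.9) prdis
      v1 path  (0.1, 0.1) agree-wrong        v5 neut (0.2, 0.1) agree-correct
      v2 path  (0.8, 0.2) prdis              v6 neut (0.9, 0.8) agree-wrong
      v3 path  (0.7, ?)   no-output          v7 neut (?,   0.3) no-output
    """
    rows = [
        ("pathogenic", 0.9, 0.9),
        ("pathogenic", 0.1, 0.1),
        ("pathogenic", 0.8, 0.2),
        ("pathogenic", 0.7, MISSING),
        ("neutral", 0.1, 0.9),
        ("neutral", 0.2, 0.1),
        ("neutral", 0.9, 0.8),
        ("neutral", MISSING, 0.3),
    ]
    natives = "ACDEFGHI"
    return [
        VariantRecord(
            protein_id="P00001",
            native_aa=natives[i],
            position=i + 1,
            variant_aa="V" if natives[i] != "V" else "L",
            label=label,
            predictor_outputs={"A": a, "B": b},
        )
        for i, (label, a, b) in enumerate(rows)
    ]


@pytest.fixture
def toy_msa():
    """Five-row alignment; human reference first, one gap column."""
    return Msa(
        sequences=[
            ("P00001_HUMAN", "ACDEFGHIKL"),
            ("hom1", "ACDEFGHIKL"),
            ("hom2", "ACDEFGHVKL"),
            ("hom3", "AC-EFGHIKL"),
            ("hom4", "MCDEFGHIKL"),
        ],
        human_index=0,
    )


@pytest.fixture(scope="session")
def default_panel():
    """A medium synthetic panel under the default study conditions."""
    spec = SyntheticPanelSpec(n_proteins=12, variants_per_protein=80, seed=11)
    records, msas = generate_panel(spec)
    return spec, records, msas, synthetic_registry(spec)
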