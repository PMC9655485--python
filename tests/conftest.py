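import pytest

from lactoteq import (
    Basis,
    CensorState,
    CongenerMeasurement,
    GeneratorConfig,
    MilkComposition,
    MilkSample,
    Units,
    congener,
    generate,
)


@pytest.fixture(scope="session")
def small_dataset():
    """A small deterministic synthetic dataset shared across tests."""
    return generate(GeneratorConfig(n_mothers=6, seed=42))


@pytest.fixture
def composition():
    return MilkComposition(
        lipid_pct=4.0, dry_matter_pct=12.0, protein_pct=1.2, lactose_pct=6.5
    )


@pytest.fixture
def make_sample(composition):
    """Factory building a MilkSample from {iupac: spec} measurement specs.

    Each spec is (value, basis, units) or (value, basis, units, censor, lod, loq).
    """

    def _make(measurements, sample_id="S1", stage_days=7, comp=None):
        ms = []
        for iupac, spec in measurements.items():
            if len(spec) == 3:
                value, basis, units = spec
                censor, lod, loq = CensorState.DETECTED, None, None
            else:
                value, basis, units, censor, lod, loq = spec
            ms.append(
                CongenerMeasurement(
                    congener=congener(iupac),
                    value=value,
                    basis=Basis(basis),
                    units=Units(units),
                    censor=CensorState(censor),
                    lod=lod,
                    loq=loq,
                )
            )
        return MilkSample(
            sample_id=sample_id,
            mother_id="M1",
            stage_days=stage_days,
            composition=comp or composition,
            measurements=tuple(ms),
        )

    return _make
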