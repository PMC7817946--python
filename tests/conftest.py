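import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from hcascreen import FeatureSchema, ProfileTable, attribute_channels

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def small_schema() -> FeatureSchema:
    """Six features: one per channel plus one unattributed."""
    names = (
        "Cells_Intensity_MeanIntensity_ER",
        "Cells_Intensity_MeanIntensity_Golgi",
        "Nuclei_Intensity_IntegratedIntensity_Hoechst",
        "Nuclei_Texture_Contrast_Syto",
        "Cytoplasm_Granularity_1_Mito",
        "Cells_AreaShape_Compactness",
    )
    return attribute_channels(FeatureSchema(feature_names=names))


@pytest.fixture
def make_table(small_schema):
    """Factory for small profile tables with seeded gaussian cells."""

    def build(treatment_id="t", n_cells=20, shift=None, seed=0, schema=None):
        schema = schema or small_schema
        rng = np.random.default_rng(seed)
        values = rng.normal(size=(n_cells, schema.n_features))
        if shift is not None:
            values = values + np.asarray(shift, dtype=float)
        return ProfileTable(treatment_id=treatment_id, schema=schema, values=values)

    return build
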