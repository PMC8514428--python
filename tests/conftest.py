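import pytest
from hypothesis import HealthCheck, settings

from oncofreq import CategoryMap, StudyAssignment

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def toy_map() -> CategoryMap:
    """Two registry entries (one exact-site, one wildcard), one three-way study."""
    cmap = CategoryMap()
    cmap.add_entry("8140/3", "C18", "colorectal_ac")
    cmap.add_entry("8720/3", "*", "melanoma")
    cmap.categories["colorectal_ac"] = "adenocarcinoma"
    cmap.categories["melanoma"] = "malignant_melanoma"
    cmap.categories.setdefault("lung_ac", "adenocarcinoma")
    cmap.categories.setdefault("lung_scc", "squamous_cell_carcinoma")
    cmap.studies["lung_study_1"] = StudyAssignment(
        study_id="lung_study_1",
        default_category="lung_ac",
        predicates=[("histology", "squamous", "lung_scc")],
        sample_overrides={"SAMPLE-X": "melanoma"},
    )
    cmap.validate()
    return cmap
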