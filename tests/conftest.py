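import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import screenrank as sr

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow, HealthCheck.function_scoped_fixture],
)
settings.load_profile("default")


@pytest.fixture
def tiny_manifest() -> sr.LibraryManifest:
    """4 genes x 3 guides with distinct random protospacers."""
    return sr.generate_library(sr.SimLibraryConfig(n_genes=4, guides_per_gene=3, seed=11))


@pytest.fixture
def invivo_sheet() -> sr.SampleSheet:
    return sr.SampleSheet.from_frame(
        pd.DataFrame(
            {
                "sample_id": ["input", "lung_a", "lung_b"],
                "role": ["input", "lung", "lung"],
                "mouse_id": [None, "m1", "m2"],
            }
        )
    )


def make_counts(manifest: sr.LibraryManifest, columns: dict) -> pd.DataFrame:
    frame = pd.DataFrame(columns, index=manifest.guide_ids, dtype="int64")
    frame.index.name = "guide_id"
    return frame
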