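import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from pollenscan import GenotypeMatrix, MarkerDef, MarkerMap
from pollenscan import datasets

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def tangor_map() -> MarkerMap:
    return datasets.load_tangor_map()


@pytest.fixture(scope="session")
def lemon_map() -> MarkerMap:
    return datasets.load_lemon_map()


@pytest.fixture(scope="session")
def sd_counts() -> pd.DataFrame:
    return datasets.load_sd_counts()


@pytest.fixture()
def toy_map() -> MarkerMap:
    """Two chromosomes: four markers on LG1 around a centromere at 25 cM,
    two on LG2."""
    markers = [
        MarkerDef("m1", 1, 0.0, "SSR", ("101", "103"), ("105", "105")),
        MarkerDef("m2", 1, 10.0, "SSR", ("201", "203"), ("205", "205")),
        MarkerDef("m3", 1, 30.0, "SNP", ("A", "G"), ("G", "G")),
        MarkerDef("m4", 1, 50.0, "SNP", ("C", "T"), ("T", "T")),
        MarkerDef("m5", 2, 0.0, "SSR", ("301", "303"), ("305", "305")),
        MarkerDef("m6", 2, 20.0, "SSR", ("401", "403"), ("405", "405")),
    ]
    return MarkerMap(markers=markers, centromere_cm={1: 25.0, 2: 10.0})


def haploid_matrix(calls: dict[str, list], loci: list[str]) -> GenotypeMatrix:
    frame = pd.DataFrame.from_dict(calls, orient="index", columns=loci)
    frame = frame.where(pd.notna(frame))
    return GenotypeMatrix(calls=frame, ploidy=1)


@pytest.fixture()
def unlinked_map() -> MarkerMap:
    """Nine mutually unlinked markers (one per linkage group), used for
    calibration experiments where marker tests must be independent."""
    markers = [
        MarkerDef(f"u{lg}", lg, 0.0, "SNP", ("A", "G"), ("C", "C"))
        for lg in range(1, 10)
    ]
    return MarkerMap(markers=markers, centromere_cm={lg: 0.0 for lg in range(1, 10)})
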