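from __future__ import annotations

import pytest

from genometric import (
    FixtureSpec,
    GDMDataset,
    MetadataSet,
    Region,
    Sample,
    Schema,
    make_dataset,
)


@pytest.fixture
def tiny_schema() -> Schema:
    return Schema((("score", "integer"), ("name", "string")))


@pytest.fixture
def tiny_dataset(tiny_schema) -> GDMDataset:
    """Two small samples with stranded regions and multi-valued metadata."""
    s1 = Sample(
        "S_00001",
        [
            Region("chr1", 100, 200, "+", (5, "a")),
            Region("chr1", 150, 250, "-", (7, "b")),
            Region("chr2", 0, 50, "*", (None, "c")),
        ],
        MetadataSet([("cell", "H1-hESC"), ("age", "42"), ("tag", "x"), ("tag", "y")]),
    )
    s2 = Sample(
        "S_00002",
        [Region("chr1", 300, 400, "+", (1, "d"))],
        MetadataSet([("cell", "K562"), ("age", "70")]),
    )
    return GDMDataset(tiny_schema, [s1, s2], name="tiny")


def random_dataset(seed: int, *, small_coords: bool = True, n_samples: int = None):
    """Random dataset in the regime of the operator-oracle tests.

    Coordinates stay below 10**4 so per-base oracles remain cheap.
    """
    import numpy as np

    rng = np.random.default_rng(seed)
    chroms = {"chrA": 10_000, "chrB": 10_000} if small_coords else dict()
    spec = FixtureSpec(
        seed=seed,
        n_samples=int(rng.integers(1, 5)) if n_samples is None else n_samples,
        regions_per_sample=(0, 100),
        max_region_length=500,
        **({"chroms": chroms} if chroms else {}),
    )
    return make_dataset(spec)
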