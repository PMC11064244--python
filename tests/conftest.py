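from __future__ import annotations

from pathlib import Path

import pytest
from hypothesis import settings

from tomspace import SyntheticConfig, generate_dataset, write_dataset

settings.register_profile("deterministic", derandomize=True, database=None)
settings.load_profile("deterministic")


def write_tsv(path: Path, header: list[str], rows: list[tuple]) -> Path:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(str(x) for x in row) + "\n")
    return path


@pytest.fixture
def tsv_writer(tmp_path):
    def _write(name: str, header: list[str], rows: list[tuple]) -> Path:
        return write_tsv(tmp_path / name, header, rows)

    return _write


@pytest.fixture(scope="session")
def clean_bundle():
    """Synthetic bundle without toxic compounds or CYP genes: pipeline
    supports must equal the planted ratios exactly."""
    return generate_dataset(SyntheticConfig(seed=11))


@pytest.fixture(scope="session")
def noisy_bundle():
    """Synthetic bundle with toxic compounds and CYP-named genes planted."""
    return generate_dataset(SyntheticConfig(seed=12, toxic_fraction=0.25, cyp_fraction=0.05))


@pytest.fixture
def bundle_dir(tmp_path, noisy_bundle):
    return write_dataset(noisy_bundle, tmp_path / "data")
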