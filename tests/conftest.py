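from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from crossdeg.ingest import StudyCall

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def random_calls(rng: np.random.Generator, n_studies: int, n_genes: int,
                 report_prob: float = 0.4) -> list[StudyCall]:
    """Random collapsed study calls: each (gene, study) pair appears at most
    once, with a random direction and adjusted p."""
    calls = []
    for s in range(n_studies):
        for g in range(n_genes):
            if rng.random() < report_prob:
                calls.append(
                    StudyCall(
                        study_id=f"S{s}",
                        canonical_symbol=f"G{g:03d}",
                        direction=int(rng.choice([1, -1])),
                        best_adj_p=float(rng.uniform(1e-6, 0.049)),
                    )
                )
    return calls


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240901)


@pytest.fixture
def deg_tsv(tmp_path):
    """Write a DEG table to a temp file and return its path."""

    def _write(rows, header="gene_symbol\tlog2fc\tadj_p", name="study.tsv"):
        path = tmp_path / name
        path.write_text("\n".join([header, *rows]) + "\n", encoding="utf-8")
        return path

    return _write


@pytest.fixture
def gmt_file(tmp_path):
    def _write(lines, name="sets.gmt"):
        path = tmp_path / name
        path.write_text("".join(f"{line}\n" for line in lines), encoding="utf-8")
        return path

    return _write
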