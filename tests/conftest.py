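import numpy as np
import pytest
from hypothesis import settings

import promstr as ps

settings.register_profile("suite", deadline=None, derandomize=True)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def panel():
    return ps.default_panel()


@pytest.fixture(scope="session")
def tri_fixture():
    return ps.load_paper_fixture("tri")


@pytest.fixture(scope="session")
def tetra_fixture():
    return ps.load_paper_fixture("tetra")


@pytest.fixture(scope="session")
def small_dataset():
    """A 40-gene planted-truth dataset shared across tests (seed 11)."""
    cfg = ps.SimConfig(n_genes=40, frac_hs_str=0.3, seed=11)
    return ps.generate_dataset(cfg)


def random_window(rng: np.random.Generator, length: int = 150,
                  gc: float = 0.5, species: str = "human",
                  gene: str = "RND") -> ps.PromoterRecord:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    seq = "".join(rng.choice(list("ACGT"), size=length, p=p))
    return ps.PromoterRecord(gene=gene, transcript_id=f"{gene}.1",
                             variant_no="", species=species,
                             sequence=seq, tss_index=length - 1)
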