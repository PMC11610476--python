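from __future__ import annotations

import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from zfx import synthetic
from zfx.io_core import GeneModel


@pytest.fixture(scope="session")
def study_proteome():
    """The synthetic study proteome (77 proteins, fixed seed) + truth."""
    records, truth = synthetic.make_proteome(seed=20240301)
    return records, truth


@pytest.fixture()
def random_sequences():
    """Random protein-like sequences enriched in C/H so fingers occur."""
    rng = np.random.default_rng(1234)
    alphabet = list("ACDEFGHIKLMNPQRSTVWY" + "CH" * 4)  # C/H enriched

    def make(n, max_len=200):
        return [
            "".join(rng.choice(alphabet, size=rng.integers(1, max_len + 1)))
            for _ in range(n)
        ]

    return make


@pytest.fixture()
def toy_gff3(tmp_path):
    """Three-gene toy annotation over two chromosomes."""
    genes = [
        GeneModel("geneB", "Zj01", 100, 400, "+",
                  [(100, 150), (200, 260), (300, 400)], protein_id="pB"),
        GeneModel("geneA", "Zj01", 50, 80, "-", [(50, 80)], protein_id="pA"),
        GeneModel("geneC", "Zj02", 10, 90, "+", [(10, 40), (60, 90)], protein_id="pC"),
    ]
    path = tmp_path / "toy.gff3"
    synthetic.genes_to_gff3(genes, path)
    return path, genes
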