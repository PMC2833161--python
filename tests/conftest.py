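"""Shared fixtures: small planted vector sets, a reference topic corpus,
and a tiny PDB file written on the fly."""

from __future__ import annotations

import numpy as np
import pytest

from envclust.coherence import build_index
from envclust.synthdata import CorpusGenSpec, VectorGenSpec, gen_corpus, gen_vectors


@pytest.fixture(scope="session")
def planted_vectors():
    """150 vectors in 3 tight planted clusters (60° separation, noise 0.1)."""
    ms, labels = gen_vectors(VectorGenSpec(sizes=[50, 50, 50], dim=264, seed=11))
    return ms, labels


@pytest.fixture(scope="session")
def reference_corpus():
    """The reference synthetic corpus: 200 proteins, 20 planted 10-protein
    topic clusters, 5 docs/protein, word overlap 0.8 within / 0.05 across."""
    clusters = {t: [f"s{i:03d}" for i in range(t * 10, (t + 1) * 10)] for t in range(20)}
    corpus, truth = gen_corpus(CorpusGenSpec(n_proteins=200, clusters=clusters, seed=7))
    return corpus, truth, clusters


@pytest.fixture(scope="session")
def reference_index(reference_corpus):
    corpus, _, _ = reference_corpus
    return build_index(corpus, m=20)


PDB_TEMPLATE = "{kind:<6}{serial:>5} {name:<4}{res:>4} {chain}{resnum:>4}    {x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00          {elem:>2}\n"


def pdb_line(kind, serial, name, res, chain, resnum, x, y, z, elem):
    # PDB fixed columns: atom name starts at col 13 (14 for 1-char elements)
    padded = f" {name:<3}" if len(name) < 4 else name
    return PDB_TEMPLATE.format(kind=kind, serial=serial, name=padded, res=res,
                               chain=chain, resnum=resnum, x=x, y=y, z=z, elem=elem)


@pytest.fixture()
def four_cys_pdb(tmp_path):
    """Structure with 2 free CYS and 2 disulfide-bonded CYS (SG–SG 2.05 Å)."""
    lines = ["HEADER    TEST STRUCTURE\n"]
    serial = 1

    def cys(resnum, sg_xyz, ca_xyz):
        nonlocal serial
        out = []
        out.append(pdb_line("ATOM", serial, "CA", "CYS", "A", resnum, *ca_xyz, "C"))
        serial += 1
        out.append(pdb_line("ATOM", serial, "SG", "CYS", "A", resnum, *sg_xyz, "S"))
        serial += 1
        return out

    lines += cys(1, (0.0, 0.0, 0.0), (1.5, 0.0, 0.0))     # disulfide pair
    lines += cys(2, (2.05, 0.0, 0.0), (3.5, 0.0, 0.0))
    lines += cys(10, (20.0, 0.0, 0.0), (21.5, 0.0, 0.0))  # free
    lines += cys(20, (40.0, 0.0, 0.0), (41.5, 0.0, 0.0))  # free
    lines.append("END\n")
    path = tmp_path / "four_cys.pdb"
    path.write_text("".join(lines))
    return path
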