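"""Cysteine site extraction and surrogate property vectors from a PDB file.

Writes a minimal PDB-format structure containing a disulfide-bonded CYS
pair and two free cysteines, lists the free CYS sites (disulfide
exclusion uses an SG–SG distance heuristic), and computes the surrogate
per-shell property vector for one site.  The property set here (residue
presences, C/N/O/S counts, aromatic-ring atoms, signed charges over six
1.25 Å shells) is a simple configurable stand-in, not a full
physicochemical description — pipeline correctness never depends on it.
"""

import tempfile
from pathlib import Path

from envclust.microenv import extract_cys_sites, shell_feature_names, simple_properties

PDB = """\
HEADER    EXAMPLE
ATOM      1  CA  CYS A   1       1.500   0.000   0.000  1.00  0.00           C
ATOM      2  SG  CYS A   1       0.000   0.000   0.000  1.00  0.00           S
ATOM      3  CA  CYS A   2       3.500   0.000   0.000  1.00  0.00           C
ATOM      4  SG  CYS A   2       2.050   0.000   0.000  1.00  0.00           S
ATOM      5  CA  CYS A  10      21.500   0.000   0.000  1.00  0.00           C
ATOM      6  SG  CYS A  10      20.000   0.000   0.000  1.00  0.00           S
ATOM      7  CA  HIS A  11      22.000   2.000   0.000  1.00  0.00           C
ATOM      8  CA  CYS A  20      41.500   0.000   0.000  1.00  0.00           C
ATOM      9  SG  CYS A  20      40.000   0.000   0.000  1.00  0.00           S
END
"""

with tempfile.TemporaryDirectory() as tmp:
    path = Path(tmp) / "example.pdb"
    path.write_text(PDB)

    free = extract_cys_sites(path, exclude_disulfides=True)
    every = extract_cys_sites(path, exclude_disulfides=False)
    print(f"{len(every)} CYS sites total, {len(free)} after disulfide exclusion:")
    for s in free:
        print(f"  {s}")

    vec = simple_properties(path, free[0], n_shells=6, radius=7.5)
    names = shell_feature_names(6)
    nonzero = [(n, v) for n, v in zip(names, vec) if v != 0]
    print(f"non-zero surrogate features around {free[0]}:")
    for n, v in nonzero:
        print(f"  {n} = {v:g}")
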