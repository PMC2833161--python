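"""Protein microenvironment vectors.

A microenvironment summarizes the spherical region (default 7.5 Å radius)
around a site of interest — here cysteine SG atoms — as physicochemical
property counts accumulated over concentric radial shells.  The module
models sets of such vectors, reads and writes them as TSV, standardizes
them feature-wise, and provides a simplified property extractor from
PDB-format structure files.  The extractor's property set is a documented
surrogate, not the original 44-property FEATURE set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

ID_COLUMNS = ["structure_id", "chain", "residue_number", "residue_name"]

#: default shell geometry
N_SHELLS = 6
RADIUS_ANGSTROM = 7.5

#: default SG-SG distance below which two cysteines are considered
#: disulfide-bonded (the covalent bond length is ~2.05 Å)
DISULFIDE_THRESHOLD = 2.5


class VectorParseError(ValueError):
    """Raised when a vector table cannot be parsed."""


class ValidationError(ValueError):
    """Raised when data violates a structural invariant."""


@dataclass(frozen=True, order=True)
class SiteId:
    """Identity of one site: structure code, chain, author residue number, residue name."""

    structure_id: str
    chain: str
    residue_number: int
    residue_name: str

    def __post_init__(self):
        object.__setattr__(self, "residue_name", self.residue_name.upper())

    def __str__(self) -> str:
        return f"{self.residue_name}{self.residue_number} in {self.structure_id}:{self.chain}"


@dataclass
class MicroenvironmentSet:
    """An ordered collection of sites with a sites × D feature matrix.

    ``space_tag`` records which space the matrix lives in: ``raw`` counts,
    ``standardized`` (each feature divided by its population standard
    deviation over the whole set), or ``reduced`` (principal-component
    scores).
    """

    sites: list[SiteId]
    features: np.ndarray
    feature_names: list[str]
    space_tag: str = "raw"
    n_shells: int = N_SHELLS
    radius_angstrom: float = RADIUS_ANGSTROM

    def __post_init__(self):
        self.features = np.asarray(self.features, dtype=float)
        if self.features.ndim != 2:
            raise ValidationError("feature matrix must be 2-D")
        if self.features.shape[0] != len(self.sites):
            raise ValidationError(
                f"{len(self.sites)} sites but {self.features.shape[0]} feature rows"
            )
        if self.features.shape[1] != len(self.feature_names):
            raise ValidationError("feature_names length does not match matrix width")
        if not np.all(np.isfinite(self.features)):
            raise ValidationError("feature matrix contains non-finite values")
        keys = [(s.structure_id, s.chain, s.residue_number) for s in self.sites]
        if len(set(keys)) != len(keys):
            dup = [k for k in keys if keys.count(k) > 1][0]
            raise ValidationError(f"duplicate site {dup}")

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_features(self) -> int:
        return self.features.shape[1]

    def subset(self, indices) -> "MicroenvironmentSet":
        """Row subset, preserving order of ``indices``."""
        indices = list(indices)
        return replace(
            self,
            sites=[self.sites[i] for i in indices],
            features=self.features[indices],
            feature_names=list(self.feature_names),
        )


def read_vectors(path) -> MicroenvironmentSet:
    """Read a microenvironment vector table (TSV) into a raw-space set.

    The table must carry the four id columns (structure_id, chain,
    residue_number, residue_name) followed by numeric feature columns.
    Row order is preserved.
    """
    try:
        df = pd.read_csv(path, sep="\t", dtype={"structure_id": str, "chain": str},
                         float_precision="round_trip")
    except Exception as exc:  # noqa: BLE001 - rewrap as our parse error
        raise VectorParseError(f"cannot read vector table {path}: {exc}") from exc
    missing = [c for c in ID_COLUMNS if c not in df.columns]
    if missing:
        raise VectorParseError(f"vector table {path} lacks id columns {missing}")
    feature_cols = [c for c in df.columns if c not in ID_COLUMNS]
    if not feature_cols:
        raise VectorParseError(f"vector table {path} has no feature columns")
    for col in feature_cols:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise VectorParseError(
                f"non-numeric or missing value at row {row}, column {col!r}"
            )
        df[col] = coerced
    sites = [
        SiteId(str(r.structure_id), str(r.chain), int(r.residue_number), str(r.residue_name))
        for r in df.itertuples(index=False)
    ]
    return MicroenvironmentSet(
        sites=sites,
        features=df[feature_cols].to_numpy(dtype=float),
        feature_names=feature_cols,
    )


def write_vectors(ms: MicroenvironmentSet, path) -> None:
    """Write a set as TSV with full float precision (round-trip exact)."""
    ids = pd.DataFrame(
        {
            "structure_id": [s.structure_id for s in ms.sites],
            "chain": [s.chain for s in ms.sites],
            "residue_number": [s.residue_number for s in ms.sites],
            "residue_name": [s.residue_name for s in ms.sites],
        }
    )
    feats = pd.DataFrame(ms.features, columns=ms.feature_names)
    pd.concat([ids, feats], axis=1).to_csv(path, sep="\t", index=False, float_format="%.17g")


def standardize(ms: MicroenvironmentSet) -> MicroenvironmentSet:
    """Divide each feature by its population standard deviation over the set.

    Constant features (std 0) are left unchanged so no NaNs propagate.
    Features are scaled, not centered; centering happens inside PCA.
    """
    if ms.space_tag != "raw":
        raise ValidationError(f"standardize expects raw space, got {ms.space_tag!r}")
    if ms.n_sites < 2:
        raise ValidationError("standard deviation undefined for a single site")
    std = ms.features.std(axis=0)  # population (divisor n)
    divisor = np.where(std > 0, std, 1.0)
    return replace(ms, features=ms.features / divisor, space_tag="standardized")


# ---------------------------------------------------------------------------
# structure-file plumbing (gemmi-backed)
# ---------------------------------------------------------------------------

_STANDARD_RESIDUES = [
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
]

_AROMATIC_RING_ATOMS = {
    "PHE": {"CG", "CD1", "CD2", "CE1", "CE2", "CZ"},
    "TYR": {"CG", "CD1", "CD2", "CE1", "CE2", "CZ"},
    "TRP": {"CG", "CD1", "CD2", "NE1", "CE2", "CE3", "CZ2", "CZ3", "CH2"},
    "HIS": {"CG", "ND1", "CD2", "CE1", "NE2"},
}

# side-chain terminal heavy atoms carrying the formal charge
_CHARGE_ATOMS = {("LYS", "NZ"): 1.0, ("ARG", "CZ"): 1.0, ("ASP", "CG"): -1.0, ("GLU", "CD"): -1.0}

SIMPLE_PROPERTY_NAMES = (
    [f"res_{r}" for r in _STANDARD_RESIDUES]
    + ["atom_C", "atom_N", "atom_O", "atom_S", "aromatic_ring_atoms", "charge_sum"]
)


def _load_structure(structure_file):
    import gemmi

    try:
        st = gemmi.read_structure(str(structure_file))
    except Exception as exc:  # noqa: BLE001
        raise VectorParseError(f"cannot parse structure file {structure_file}: {exc}") from exc
    if len(st) == 0:
        raise VectorParseError(f"structure file {structure_file} has no models")
    return st


def extract_cys_sites(structure_file, exclude_disulfides: bool = True,
                      disulfide_threshold: float = DISULFIDE_THRESHOLD) -> list[SiteId]:
    """List CYS sites (those with an SG atom) in a PDB-format file.

    With ``exclude_disulfides``, any CYS whose SG lies within
    ``disulfide_threshold`` Å of another CYS SG is dropped — a geometric
    heuristic for disulfide participation.
    """
    st = _load_structure(structure_file)
    model = st[0]
    code = (st.name or "xxxx")[:4].lower()
    cys = []
    for chain in model:
        for res in chain:
            if res.name == "CYS":
                sg = res.find_atom("SG", "*")
                if sg is not None:
                    cys.append((chain.name, res.seqid.num, np.array(sg.pos.tolist())))
    if exclude_disulfides and len(cys) > 1:
        pos = np.array([c[2] for c in cys])
        d = np.linalg.norm(pos[:, None, :] - pos[None, :, :], axis=-1)
        np.fill_diagonal(d, np.inf)
        keep = d.min(axis=1) > disulfide_threshold
        cys = [c for c, k in zip(cys, keep) if k]
    return [SiteId(code, chain, num, "CYS") for chain, num, _ in cys]


def _site_center(model, site: SiteId) -> np.ndarray:
    """Center atom position for a site: SG, falling back to CB then CA."""
    for chain in model:
        if chain.name != site.chain:
            continue
        for res in chain:
            if res.seqid.num == site.residue_number and res.name == site.residue_name:
                for name in ("SG", "CB", "CA"):
                    atom = res.find_atom(name, "*")
                    if atom is not None:
                        if name != "SG":
                            logger.warning("site %s lacks SG; using %s as center", site, name)
                        return np.array(atom.pos.tolist())
    raise LookupError(f"site {site} not found in structure")


def simple_properties(structure_file, site: SiteId, n_shells: int = N_SHELLS,
                      radius: float = RADIUS_ANGSTROM) -> np.ndarray:
    """Surrogate per-shell property vector around a site's center atom.

    For each of ``n_shells`` equal-width concentric shells (half-open
    [inner, outer) bins, outermost closed) this collects: presence counts
    of the 20 standard residue types (a residue counts once per shell in
    which it has at least one atom), C/N/O/S atom counts, aromatic-ring
    atom count, and the signed sum of side-chain formal charges.
    Concatenated shell-major.  This is an explicitly configurable stand-in
    for a full physicochemical property system; do not interpret it as one.
    """
    if radius <= 0 or n_shells < 1:
        raise ValueError("radius must be positive and n_shells >= 1")
    st = _load_structure(structure_file)
    model = st[0]
    center = _site_center(model, site)
    width = radius / n_shells
    n_props = len(SIMPLE_PROPERTY_NAMES)
    out = np.zeros((n_shells, n_props))
    res_index = {r: i for i, r in enumerate(_STANDARD_RESIDUES)}
    elem_index = {"C": 20, "N": 21, "O": 22, "S": 23}

    for chain in model:
        for res in chain:
            shells_with_res = set()
            for atom in res:
                d = np.linalg.norm(np.array(atom.pos.tolist()) - center)
                if d > radius:
                    continue
                shell = min(int(d // width), n_shells - 1)
                elem = atom.element.name.upper()
                if elem in elem_index:
                    out[shell, elem_index[elem]] += 1
                if atom.name in _AROMATIC_RING_ATOMS.get(res.name, ()):
                    out[shell, 24] += 1
                charge = _CHARGE_ATOMS.get((res.name, atom.name))
                if charge is not None:
                    out[shell, 25] += charge
                if res.name in res_index:
                    shells_with_res.add(shell)
            for shell in shells_with_res:
                out[shell, res_index[res.name]] += 1
    return out.reshape(-1)


def shell_feature_names(n_shells: int = N_SHELLS,
                        property_names=None) -> list[str]:
    """Labels of form property@shell, shell-major to match simple_properties."""
    props = list(property_names or SIMPLE_PROPERTY_NAMES)
    return [f"{p}@{s}" for s in range(n_shells) for p in props]
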