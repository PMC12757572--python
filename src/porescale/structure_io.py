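"""Reading, cleaning, orienting, and hydropathically annotating all-atom structures.

The analysis downstream treats a channel structure as a bare point cloud with
per-atom hydropathic weights, oriented so that the membrane normal is +z and
+z points extracellularly.  Parsing and writing of PDB files is delegated to
biotite; this module owns the cleaning policy (protein ATOM records, first
altloc, no waters/hetero groups unless requested) and the binarized
hydropathy annotation.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field, replace
from importlib import resources

import numpy as np
import pandas as pd
import biotite.structure as bst
from biotite.structure.io.pdb import PDBFile

__all__ = [
    "MolecularStructure",
    "StructureParseError",
    "HydropathyError",
    "read_structure",
    "write_structure",
    "load_hydropathy_scale",
    "assign_hydropathy",
    "orient_structure",
]

WATER_NAMES = {"HOH", "WAT", "H2O", "DOD", "TIP", "TIP3"}


class StructureParseError(ValueError):
    """Raised when a PDB text contains no usable ATOM records."""


class HydropathyError(KeyError):
    """Raised when atoms cannot be matched against the hydropathy scale."""


@dataclass
class MolecularStructure:
    """Cleaned all-atom coordinate set with per-atom hydropathic weights.

    Coordinates are in Å.  ``weight`` holds the binarized hydropathic weight
    w_a in kcal (±0.5 after annotation, NaN before).  ``perpendicular_axis``
    is the membrane normal e⊥ (points extracellularly after orientation) and
    ``parallel_frame`` spans the membrane plane.
    """

    serial: np.ndarray
    name: np.ndarray
    res_name: np.ndarray
    chain: np.ndarray
    res_seq: np.ndarray
    coords: np.ndarray
    weight: np.ndarray
    perpendicular_axis: np.ndarray = field(
        default_factory=lambda: np.array([0.0, 0.0, 1.0]))
    parallel_frame: np.ndarray = field(
        default_factory=lambda: np.eye(3)[:2])

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coords must be an (n, 3) array")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coords must be finite")

    @property
    def n_total(self) -> int:
        """card(A): total number of atoms in the cleaned structure."""
        return len(self.coords)

    def residue_center(self, chain: str, res_seq: int) -> np.ndarray:
        """Geometric center of all atoms of one residue (backbone included)."""
        mask = (self.chain == chain) & (self.res_seq == int(res_seq))
        if not mask.any():
            raise KeyError(f"residue {chain}/{res_seq} not in structure")
        return self.coords[mask].mean(axis=0)

    def copy(self) -> "MolecularStructure":
        return MolecularStructure(
            serial=self.serial.copy(), name=self.name.copy(),
            res_name=self.res_name.copy(), chain=self.chain.copy(),
            res_seq=self.res_seq.copy(), coords=self.coords.copy(),
            weight=self.weight.copy(),
            perpendicular_axis=self.perpendicular_axis.copy(),
            parallel_frame=self.parallel_frame.copy())


def _from_atom_array(atoms: bst.AtomArray) -> MolecularStructure:
    try:
        serial = np.asarray(atoms.atom_id, dtype=int)
    except AttributeError:
        serial = np.arange(1, atoms.array_length() + 1)
    return MolecularStructure(
        serial=serial,
        name=np.asarray(atoms.atom_name, dtype="U6"),
        res_name=np.asarray(atoms.res_name, dtype="U5"),
        chain=np.asarray(atoms.chain_id, dtype="U4"),
        res_seq=np.asarray(atoms.res_id, dtype=int),
        coords=np.asarray(atoms.coord, dtype=float),
        weight=np.full(atoms.array_length(), np.nan),
    )


def read_structure(pdb_text: str, keep_het: bool = False,
                   chain_whitelist=None) -> MolecularStructure:
    """Parse PDB text into a cleaned :class:`MolecularStructure`.

    Keeps protein ATOM records (hydrogens retained if present) of the first
    model and the first alternate location; drops waters always and other
    hetero groups unless ``keep_het``.  ``chain_whitelist`` restricts the
    atom set to the listed chains (used to exclude auxiliary β subunits).
    Weights are left unset (NaN sentinel).
    """
    lines = pdb_text.splitlines()
    if not any(line.startswith(("ATOM", "HETATM")) for line in lines):
        first = next((ln for ln in lines if ln.strip()), "<empty input>")
        raise StructureParseError(
            f"no ATOM records found; first line was: {first!r}")
    pdb = PDBFile.read(io.StringIO(pdb_text))
    atoms = pdb.get_structure(model=1, altloc="first",
                              extra_fields=["atom_id"])
    mask = ~np.isin(atoms.res_name, list(WATER_NAMES))
    if not keep_het:
        mask &= ~atoms.hetero
    if chain_whitelist is not None:
        mask &= np.isin(atoms.chain_id, list(chain_whitelist))
    atoms = atoms[mask]
    if atoms.array_length() == 0:
        raise StructureParseError(
            "no protein ATOM records survived cleaning")
    # duplicate (chain, res_seq, atom name) records: keep the first
    keys = [f"{c}|{r}|{n}" for c, r, n in
            zip(atoms.chain_id, atoms.res_id, atoms.atom_name)]
    _, first_idx, counts = np.unique(keys, return_index=True,
                                     return_counts=True)
    if (counts > 1).any():
        ndup = int((counts - 1).sum())
        warnings.warn(f"{ndup} duplicate (chain, residue, atom) records "
                      "dropped; first occurrence kept")
        atoms = atoms[np.sort(first_idx)]
    return _from_atom_array(atoms)


def write_structure(structure: MolecularStructure, path) -> None:
    """Write the structure as a standard PDB file (coordinates to 1e-3 Å)."""
    n = structure.n_total
    atoms = bst.AtomArray(n)
    atoms.coord = structure.coords.astype(np.float32)
    atoms.atom_name = structure.name
    atoms.res_name = structure.res_name
    atoms.chain_id = structure.chain
    atoms.res_id = structure.res_seq
    atoms.hetero = np.zeros(n, dtype=bool)
    # element guessed from the first alphabetic character of the atom name
    atoms.element = np.array([next((c for c in nm if c.isalpha()), "C")
                              for nm in structure.name])
    pdb = PDBFile()
    pdb.set_structure(atoms)
    pdb.write(str(path))


def load_hydropathy_scale(path=None) -> pd.DataFrame:
    """Load the packaged (or a user-supplied) binarized atomic hydropathy table.

    The table is keyed by (residue_name, atom_name) and maps to ±0.5 kcal.
    """
    if path is None:
        ref = resources.files("porescale.data") / "atomic_hydropathy.tsv"
        with ref.open() as fh:
            table = pd.read_csv(fh, sep="\t", comment="#")
    else:
        table = pd.read_csv(path, sep="\t", comment="#")
    required = {"residue_name", "atom_name", "weight"}
    if not required.issubset(table.columns):
        raise ValueError(f"scale table must have columns {sorted(required)}")
    return table


@dataclass
class HydropathyCoverage:
    """Report of how many atoms matched the scale and how mismatches were fixed."""
    n_atoms: int
    n_matched: int
    n_hydrogen_default: int
    n_fallback: int
    unmatched: list

    @property
    def coverage(self) -> float:
        return self.n_matched / max(self.n_atoms, 1)


def assign_hydropathy(structure: MolecularStructure, scale=None,
                      on_missing: str = "fail"):
    """Annotate every atom with a binarized hydropathic weight (±0.5 kcal).

    Hydrogens absent from the table default to −0.5 (carbon-attached; all
    heteroatom-bound hydrogens are tabulated explicitly).  Remaining
    unmatched atoms follow ``on_missing``: ``"fail"`` raises,
    ``"residue-majority"`` assigns the majority sign of the residue's matched
    atoms with a warning.

    Returns ``(annotated_structure, coverage_report)``.  Annotation is
    idempotent: re-running on an annotated structure gives identical weights.
    """
    if on_missing not in ("fail", "residue-majority"):
        raise ValueError("on_missing must be 'fail' or 'residue-majority'")
    if scale is None:
        scale = load_hydropathy_scale()
    lut = {(r, a): w for r, a, w in
           zip(scale["residue_name"], scale["atom_name"], scale["weight"])}
    out = structure.copy()
    weights = np.full(out.n_total, np.nan)
    matched = np.zeros(out.n_total, dtype=bool)
    hydrogen_default = 0
    unmatched = []
    for i, (res, atom) in enumerate(zip(out.res_name, out.name)):
        w = lut.get((res, atom))
        if w is not None:
            weights[i] = w
            matched[i] = True
        elif atom.startswith("H") or (len(atom) > 1 and atom[0].isdigit()
                                      and atom[1] == "H"):
            weights[i] = -0.5
            hydrogen_default += 1
        else:
            unmatched.append((res, atom))
    n_fallback = 0
    if unmatched:
        if on_missing == "fail":
            raise HydropathyError(
                f"{len(unmatched)} atoms unmatched by the hydropathy scale, "
                f"e.g. {unmatched[:5]}")
        warnings.warn(f"{len(unmatched)} unmatched atoms assigned the "
                      "residue-majority hydropathy sign")
        for i in np.flatnonzero(np.isnan(weights)):
            res_mask = ((out.chain == out.chain[i]) &
                        (out.res_seq == out.res_seq[i]) & matched)
            majority = weights[res_mask].sum() if res_mask.any() else -1.0
            weights[i] = 0.5 if majority > 0 else -0.5
            n_fallback += 1
    out.weight = weights
    report = HydropathyCoverage(
        n_atoms=out.n_total, n_matched=int(matched.sum()),
        n_hydrogen_default=hydrogen_default, n_fallback=n_fallback,
        unmatched=unmatched)
    return out, report


def _rotation_to_z(axis: np.ndarray) -> np.ndarray:
    """Rotation matrix mapping the unit vector ``axis`` onto +z."""
    axis = axis / np.linalg.norm(axis)
    z = np.array([0.0, 0.0, 1.0])
    v = np.cross(axis, z)
    c = float(axis @ z)
    if np.linalg.norm(v) < 1e-12:
        return np.eye(3) if c > 0 else np.diag([1.0, -1.0, -1.0])
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx / (1.0 + c)


def orient_structure(structure: MolecularStructure, mode: str = "as-is",
                     flip: bool = False) -> MolecularStructure:
    """Orient the structure so the membrane normal (pseudo-symmetry axis) is +z.

    ``mode="as-is"`` trusts the input orientation (OPM-style, z = membrane
    normal).  ``mode="principal-axis"`` rotates the smallest-moment principal
    axis of the coordinate cloud (the axis minimizing the moment of inertia,
    i.e. the largest-variance eigenvector) onto +z about the centroid.  The
    extracellular direction is ambiguous under a mirror flip; the default
    deterministic choice is +z, override with ``flip=True``.
    """
    if structure.n_total < 4:
        raise ValueError("orientation requires at least 4 atoms")
    out = structure.copy()
    if mode == "as-is":
        return out
    if mode != "principal-axis":
        raise ValueError("mode must be 'as-is' or 'principal-axis'")
    center = out.coords.mean(axis=0)
    x = out.coords - center
    cov = x.T @ x / len(x)
    evals, evecs = np.linalg.eigh(cov)  # ascending
    if evals[2] - evals[1] <= 1e-9 * max(evals[2], 1e-30):
        raise ValueError("degenerate coordinate cloud: principal axis "
                         "is not unique")
    axis = evecs[:, 2]
    # deterministic sign: largest-magnitude component made positive, then +z
    axis = axis * np.sign(axis[np.argmax(np.abs(axis))] or 1.0)
    if flip:
        axis = -axis
    rot = _rotation_to_z(axis)
    out.coords = x @ rot.T + center
    return out
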