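"""Molecular geometry containers, atomic weighting schemes and SDF input.

Descriptor computation needs only three things from a molecule: element
symbols, 3-D coordinates (Å) and the heavy-connectivity graph.
:class:`MoleculeGeometry` holds exactly that, so toy fixtures and real
molecules read from SDF flow through the same code path.

Weighting schemes follow the convention of topological/3-D descriptor
suites: each atomic property is divided by the carbon value so that carbon
always has weight 1 and the unweighted scheme maps every element to 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import ConfigurationError

# ----------------------------------------------------------------------
# atomic property tables (raw, per element)
# ----------------------------------------------------------------------

#: standard atomic masses (u)
ATOMIC_MASS = {
    "H": 1.008, "B": 10.811, "C": 12.011, "N": 14.007, "O": 15.999,
    "F": 18.998, "Si": 28.086, "P": 30.974, "S": 32.06, "Cl": 35.453,
    "Se": 78.971, "Br": 79.904, "I": 126.904,
}

#: Bondi van der Waals radii (Å); volumes are 4/3 π r³
_VDW_RADIUS = {
    "H": 1.20, "B": 1.92, "C": 1.70, "N": 1.55, "O": 1.52,
    "F": 1.47, "Si": 2.10, "P": 1.80, "S": 1.80, "Cl": 1.75,
    "Se": 1.90, "Br": 1.85, "I": 1.98,
}
VDW_VOLUME = {el: 4.0 / 3.0 * np.pi * r**3 for el, r in _VDW_RADIUS.items()}

#: Sanderson electronegativities (dimensionless)
SANDERSON_EN = {
    "H": 2.592, "B": 2.275, "C": 2.746, "N": 3.194, "O": 3.654,
    "F": 4.000, "Si": 2.138, "P": 2.515, "S": 2.957, "Cl": 3.475,
    "Se": 2.424, "Br": 3.219, "I": 2.778,
}

#: atomic polarizabilities (1e-24 cm³)
POLARIZABILITY = {
    "H": 0.667, "B": 3.030, "C": 1.760, "N": 1.100, "O": 0.802,
    "F": 0.557, "Si": 5.380, "P": 3.630, "S": 2.900, "Cl": 2.180,
    "Se": 3.770, "Br": 3.050, "I": 5.350,
}

#: electronegative heavy atoms for the C-005 (CH3-X) fragment count
ELECTRONEGATIVE = frozenset({"O", "N", "S", "P", "Se", "F", "Cl", "Br", "I"})

#: nominal valences used to infer implicit hydrogens when SDF omits them
STANDARD_VALENCE = {
    "H": 1, "B": 3, "C": 4, "N": 3, "O": 2, "F": 1, "Si": 4,
    "P": 3, "S": 2, "Cl": 1, "Se": 2, "Br": 1, "I": 1,
}

_PROPERTY_TABLES = {
    "mass": ATOMIC_MASS,
    "vdw_volume": VDW_VOLUME,
    "electronegativity": SANDERSON_EN,
    "polarizability": POLARIZABILITY,
}

WEIGHT_LETTER = {
    "u": "unweighted",
    "m": "mass",
    "v": "vdw_volume",
    "e": "electronegativity",
    "p": "polarizability",
}


@dataclass(frozen=True)
class WeightScheme:
    """Mapping element symbol -> carbon-scaled atomic weight.

    ``unweighted`` maps every element to 1.  Custom schemes (arbitrary
    ``atom_values``) are accepted for testing with synthetic elements.
    """

    name: str
    atom_values: dict[str, float]

    @classmethod
    def from_name(cls, name: str) -> "WeightScheme":
        if name == "unweighted":
            return cls("unweighted", {})
        if name not in _PROPERTY_TABLES:
            raise ConfigurationError(
                f"unknown weight scheme {name!r}; expected one of "
                f"unweighted, {', '.join(_PROPERTY_TABLES)}"
            )
        table = _PROPERTY_TABLES[name]
        carbon = table["C"]
        return cls(name, {el: v / carbon for el, v in table.items()})

    @classmethod
    def from_letter(cls, letter: str) -> "WeightScheme":
        if letter not in WEIGHT_LETTER:
            raise ConfigurationError(f"unknown weight letter {letter!r}")
        return cls.from_name(WEIGHT_LETTER[letter])

    def weight(self, element: str) -> float:
        if self.name == "unweighted":
            return 1.0
        try:
            return self.atom_values[element]
        except KeyError:
            raise ConfigurationError(
                f"no {self.name} weight for element {element!r}"
            ) from None

    def weights_for(self, elements: list[str]) -> np.ndarray:
        return np.array([self.weight(el) for el in elements], dtype=float)


@dataclass
class MoleculeGeometry:
    """Atoms with element symbols, 3-D coordinates and bond adjacency.

    ``bonds`` is a list of ``(i, j)`` atom-index pairs describing an
    undirected simple graph; bond orders are not tracked (the descriptors
    computed here do not need them).
    """

    elements: list[str]
    coordinates: np.ndarray
    bonds: list[tuple[int, int]]
    id: str = "mol"

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        n = len(self.elements)
        if self.coordinates.shape != (n, 3):
            raise ConfigurationError(
                f"coordinates shape {self.coordinates.shape} for {n} atoms"
            )
        if not np.all(np.isfinite(self.coordinates)):
            raise ConfigurationError("coordinates must be finite")
        seen = set()
        norm_bonds = []
        for i, j in self.bonds:
            if not (0 <= i < n and 0 <= j < n) or i == j:
                raise ConfigurationError(f"bond ({i}, {j}) references invalid atoms")
            key = (min(i, j), max(i, j))
            if key not in seen:
                seen.add(key)
                norm_bonds.append(key)
        self.bonds = norm_bonds

    @property
    def n_atoms(self) -> int:
        return len(self.elements)

    def adjacency(self) -> np.ndarray:
        """Symmetric 0/1 adjacency matrix."""
        n = self.n_atoms
        adj = np.zeros((n, n), dtype=int)
        for i, j in self.bonds:
            adj[i, j] = adj[j, i] = 1
        return adj

    def neighbors(self, i: int) -> list[int]:
        return [b if a == i else a for a, b in self.bonds if i in (a, b)]

    def distance_matrix(self) -> np.ndarray:
        """Euclidean interatomic distances (Å)."""
        diff = self.coordinates[:, None, :] - self.coordinates[None, :, :]
        return np.sqrt((diff**2).sum(axis=-1))

    def topological_distances(self) -> np.ndarray:
        """Shortest bond-path lengths; ``inf`` for disconnected pairs."""
        from scipy.sparse.csgraph import shortest_path

        if self.n_atoms == 0:
            return np.zeros((0, 0))
        return shortest_path(self.adjacency(), method="D", unweighted=True)

    def implicit_hydrogens(self, i: int) -> int:
        """Hydrogens inferred from the standard valence of atom ``i``.

        Returns 0 when explicit hydrogens are present anywhere in the
        molecule (the file is then assumed to be fully explicit), or when
        the element has no standard valence on record.
        """
        if "H" in self.elements:
            return 0
        valence = STANDARD_VALENCE.get(self.elements[i])
        if valence is None:
            return 0
        return max(0, valence - len(self.neighbors(i)))


@dataclass(frozen=True)
class RDFConfig:
    """Radial-distribution-function evaluation grid.

    ``radii`` follow the common descriptor-suite convention: a label such
    as RDF105 means r = 10.5 Å.  ``B`` (Å⁻²) is the Gaussian smoothing
    parameter; ``f`` a global scaling factor.
    """

    f: float = 1.0
    B: float = 100.0
    radii: tuple[float, ...] = tuple(np.arange(0.5, 15.6, 0.5))

    def __post_init__(self) -> None:
        if self.B <= 0:
            raise ConfigurationError("RDF smoothing parameter B must be > 0")
        r = np.asarray(self.radii, dtype=float)
        if r.size == 0 or np.any(r <= 0) or np.any(np.diff(r) <= 0):
            raise ConfigurationError("radii must be positive and strictly increasing")


# ----------------------------------------------------------------------
# SDF input (V2000 via RDKit; 3-D coordinates used as-is)
# ----------------------------------------------------------------------

def read_sdf(path: str | Path) -> list[MoleculeGeometry]:
    """Read molecules from an SDF file.

    Coordinates are taken verbatim from the file (no conformer
    generation); hydrogens are kept if present.  Molecules RDKit cannot
    sanitize are still accepted as raw graphs.
    """
    from rdkit import Chem

    supplier = Chem.SDMolSupplier(str(path), removeHs=False, sanitize=False)
    mols = []
    for idx, mol in enumerate(supplier):
        if mol is None:
            continue
        name = mol.GetProp("_Name") if mol.HasProp("_Name") else ""
        mols.append(from_rdkit(mol, mol_id=name.strip() or f"mol{idx + 1}"))
    return mols


def from_rdkit(mol, mol_id: str = "mol") -> MoleculeGeometry:
    """Convert an RDKit Mol (with a conformer) to :class:`MoleculeGeometry`."""
    conf = mol.GetConformer()
    elements = [atom.GetSymbol() for atom in mol.GetAtoms()]
    coords = np.array(
        [[conf.GetAtomPosition(i).x, conf.GetAtomPosition(i).y, conf.GetAtomPosition(i).z]
         for i in range(mol.GetNumAtoms())]
    )
    bonds = [(b.GetBeginAtomIdx(), b.GetEndAtomIdx()) for b in mol.GetBonds()]
    return MoleculeGeometry(elements=elements, coordinates=coords, bonds=bonds, id=mol_id)
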