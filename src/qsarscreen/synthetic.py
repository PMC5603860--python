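"""Synthetic descriptor matrices and toy molecules with known ground truth.

The generator emulates the situation the modelling pipeline is built for:
a few dozen compounds described by hundreds of numeric descriptors, of
which a handful carry a linear signal for the activity, some are
near-duplicates of each other (collinear pairs) and some are constant.
Defaults mirror that regime: 46 compounds, 300 descriptors, 8 active ones,
Gaussian noise of 0.3 pIC50 units on the activity.

Everything is driven by one integer seed through a single NumPy
``default_rng`` stream, so a fixed spec reproduces byte-identical tables.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import ConfigurationError
from .molecules import MoleculeGeometry, WeightScheme
from .table import DescriptorTable

__all__ = [
    "SyntheticSpec",
    "SyntheticDataset",
    "generate_dataset",
    "generate_toy_molecules",
    "path_weight_scheme",
]


@dataclass(frozen=True)
class SyntheticSpec:
    """Configuration of one synthetic descriptor matrix.

    ``true_coefficients`` (activity units per descriptor unit) may be
    ``None``, in which case one coefficient per active descriptor is drawn
    uniformly from ±[0.5, 1.5] using the same seeded stream.
    """

    n_compounds: int = 46
    n_descriptors: int = 300
    n_active: int = 8
    true_coefficients: tuple[float, ...] | None = None
    intercept: float = 5.0
    noise_sd: float = 0.3
    n_collinear_pairs: int = 5
    collinear_r: float = 0.95
    n_constant: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_compounds < 2:
            raise ConfigurationError("n_compounds must be >= 2")
        if self.n_active + 2 * self.n_collinear_pairs + self.n_constant > self.n_descriptors:
            raise ConfigurationError(
                "n_active + 2*n_collinear_pairs + n_constant "
                f"({self.n_active} + 2*{self.n_collinear_pairs} + {self.n_constant}) "
                f"exceeds n_descriptors ({self.n_descriptors})"
            )
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")
        if self.n_collinear_pairs > 0 and not 0.9 < self.collinear_r < 1:
            raise ConfigurationError("collinear_r must lie in (0.9, 1)")
        if self.true_coefficients is not None and len(self.true_coefficients) != self.n_active:
            raise ConfigurationError(
                f"{len(self.true_coefficients)} coefficients for {self.n_active} active descriptors"
            )


@dataclass
class SyntheticDataset:
    """A generated table plus the ground truth that produced it."""

    table: DescriptorTable
    active_names: list[str]
    true_coefficients: np.ndarray
    intercept: float
    noise: np.ndarray
    collinear_pairs: list[tuple[str, str]] = field(default_factory=list)
    constant_names: list[str] = field(default_factory=list)

    def write(self, csv_path: str | Path, truth_path: str | Path | None = None) -> None:
        """Write the table as CSV and the ground truth as a JSON sidecar."""
        self.table.to_csv(csv_path)
        if truth_path is None:
            truth_path = Path(csv_path).with_suffix(".truth.json")
        truth = {
            "active_names": self.active_names,
            "true_coefficients": self.true_coefficients.tolist(),
            "intercept": self.intercept,
            "collinear_pairs": [list(p) for p in self.collinear_pairs],
            "constant_names": self.constant_names,
        }
        Path(truth_path).write_text(json.dumps(truth, indent=2))


def generate_dataset(spec: SyntheticSpec) -> SyntheticDataset:
    """Generate a descriptor matrix with a planted linear activity signal.

    Layout of the descriptor columns:

    * ``X001..`` — active columns (standard normal), then independent
      inactive columns (standard normal),
    * ``COLa#/COLb#`` — collinear pairs, the partner built as
      x' = r·x + sqrt(1−r²)·z so the expected correlation is exactly r
      (redrawn until the sample correlation is within ±0.05 of r),
    * ``CONST#`` — constant columns.

    Activity = intercept + X_active·β + Normal(0, noise_sd); the realized
    noise vector is recorded for tests.
    """
    rng = np.random.default_rng(spec.seed)
    n, p = spec.n_compounds, spec.n_descriptors
    n_plain = p - 2 * spec.n_collinear_pairs - spec.n_constant

    if spec.true_coefficients is None:
        coeffs = rng.uniform(0.5, 1.5, size=spec.n_active) * rng.choice(
            [-1.0, 1.0], size=spec.n_active
        )
    else:
        coeffs = np.asarray(spec.true_coefficients, dtype=float)

    columns: list[np.ndarray] = []
    names: list[str] = []
    # active + independent inactive columns
    plain = rng.standard_normal((n, n_plain))
    width = len(str(max(p, 1)))
    for j in range(n_plain):
        columns.append(plain[:, j])
        names.append(f"X{j + 1:0{width}d}")
    active_names = names[: spec.n_active]

    # collinear pairs (nuisance columns, independent of the signal)
    collinear_pairs: list[tuple[str, str]] = []
    r = spec.collinear_r
    for q in range(spec.n_collinear_pairs):
        x = rng.standard_normal(n)
        for _ in range(100):
            partner = r * x + np.sqrt(1 - r**2) * rng.standard_normal(n)
            if abs(np.corrcoef(x, partner)[0, 1] - r) <= 0.05:
                break
        a, b = f"COLa{q + 1}", f"COLb{q + 1}"
        columns += [x, partner]
        names += [a, b]
        collinear_pairs.append((a, b))

    # constant columns
    constant_names = []
    for q in range(spec.n_constant):
        level = float(rng.uniform(-2, 2))
        columns.append(np.full(n, level))
        name = f"CONST{q + 1}"
        names.append(name)
        constant_names.append(name)

    values = np.column_stack(columns) if columns else np.zeros((n, 0))
    design = values[:, : spec.n_active]
    noise = rng.normal(0.0, spec.noise_sd, size=n) if spec.noise_sd > 0 else np.zeros(n)
    activity = spec.intercept + design @ coeffs + noise

    ids = [f"cmpd{i + 1:03d}" for i in range(n)]
    table = DescriptorTable(
        compound_ids=ids, descriptor_names=names, values=values, activity=activity
    )
    return SyntheticDataset(
        table=table,
        active_names=active_names,
        true_coefficients=coeffs,
        intercept=spec.intercept,
        noise=noise,
        collinear_pairs=collinear_pairs,
        constant_names=constant_names,
    )


# ----------------------------------------------------------------------
# toy molecules for descriptor oracles
# ----------------------------------------------------------------------

def path_weight_scheme(weights: tuple[float, ...]) -> WeightScheme:
    """Custom weight scheme for the synthetic elements Z1, Z2, ... used by
    the ``path3`` fixture (Z_k gets the k-th weight)."""
    return WeightScheme(
        name="custom",
        atom_values={f"Z{k + 1}": float(w) for k, w in enumerate(weights)},
    )


def _methane() -> MoleculeGeometry:
    d = 1.09 / np.sqrt(3)
    coords = [[0, 0, 0], [d, d, d], [d, -d, -d], [-d, d, -d], [-d, -d, d]]
    return MoleculeGeometry(
        elements=["C", "H", "H", "H", "H"],
        coordinates=np.array(coords),
        bonds=[(0, 1), (0, 2), (0, 3), (0, 4)],
        id="methane",
    )


def _with_methyl_h(elements, coords, bonds, carbon_indices, mol_id):
    """Attach three explicit hydrogens to each listed methyl carbon."""
    elements = list(elements)
    coords = [np.asarray(c, dtype=float) for c in coords]
    bonds = list(bonds)
    offsets = np.array([[0.63, 0.63, 0.63], [0.63, -0.63, -0.63], [-0.63, 0.63, -0.63]])
    for ci in carbon_indices:
        base = coords[ci]
        for off in offsets:
            elements.append("H")
            coords.append(base + off)
            bonds.append((ci, len(elements) - 1))
    return MoleculeGeometry(
        elements=elements, coordinates=np.array(coords), bonds=bonds, id=mol_id
    )


def _dimethyl_ether() -> MoleculeGeometry:
    # CH3-O-CH3, explicit hydrogens
    return _with_methyl_h(
        ["C", "O", "C"],
        [[-1.41, 0, 0], [0, 0.59, 0], [1.41, 0, 0]],
        [(0, 1), (1, 2)],
        carbon_indices=[0, 2],
        mol_id="dimethyl_ether",
    )


def _anisole() -> MoleculeGeometry:
    # 4-methoxyphenyl fragment: benzene ring + O-CH3, ring H explicit
    ring = [
        [np.cos(np.pi / 3 * k) * 1.4, np.sin(np.pi / 3 * k) * 1.4, 0.0]
        for k in range(6)
    ]
    elements = ["C"] * 6 + ["O", "C"]
    coords = ring + [[2.75, 0.0, 0.0], [3.5, 1.2, 0.0]]
    bonds = [(k, (k + 1) % 6) for k in range(6)] + [(0, 6), (6, 7)]
    # explicit H on ring carbons 1..5
    for k in range(1, 6):
        elements.append("H")
        coords.append([ring[k][0] * 1.77, ring[k][1] * 1.77, 0.0])
        bonds.append((k, len(elements) - 1))
    return _with_methyl_h(elements, coords, bonds, carbon_indices=[7], mol_id="anisole")


_METHYL_PROBES = {
    "methane": _methane,
    "dimethyl_ether": _dimethyl_ether,
    "anisole": _anisole,
}


def generate_toy_molecules(kind: str, **parameters) -> MoleculeGeometry:
    """Small hand-constructed geometries for descriptor oracles.

    * ``pair`` — two unweighted-equivalent atoms at ``distance`` Å
      (elements default to carbon).
    * ``path3`` — three atoms bonded in a chain, with synthetic elements
      Z1, Z2, Z3 so that :func:`path_weight_scheme` can assign the
      ``weights`` tuple as atomic properties.
    * ``methyl_probe`` — one of ``methane``, ``dimethyl_ether``,
      ``anisole`` (known C-005 counts 0, 2, 1), selected by ``name``.
    """
    if kind == "pair":
        distance = float(parameters.get("distance", 2.0))
        element = parameters.get("element", "C")
        return MoleculeGeometry(
            elements=[element, element],
            coordinates=np.array([[0.0, 0.0, 0.0], [distance, 0.0, 0.0]]),
            bonds=[(0, 1)],
            id=f"pair_{distance:g}",
        )
    if kind == "path3":
        n_atoms = len(parameters["weights"]) if "weights" in parameters else 3
        spacing = float(parameters.get("spacing", 1.0))
        return MoleculeGeometry(
            elements=[f"Z{k + 1}" for k in range(n_atoms)],
            coordinates=np.array([[k * spacing, 0.0, 0.0] for k in range(n_atoms)]),
            bonds=[(0, 1), (1, 2)],
            id="path3",
        )
    if kind == "methyl_probe":
        name = parameters.get("name", "dimethyl_ether")
        if name not in _METHYL_PROBES:
            raise ConfigurationError(
                f"unknown methyl probe {name!r}; expected one of {sorted(_METHYL_PROBES)}"
            )
        return _METHYL_PROBES[name]()
    raise ConfigurationError(
        f"unknown toy molecule kind {kind!r}; expected pair, path3 or methyl_probe"
    )
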