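"""Molecular descriptors: RDF codes, Moran/Geary autocorrelations, C-005.

The three families implemented here are the ones a typical
descriptor-based MLR model of small-molecule activity draws on:

* **RDF codes** (3-D): a Gaussian-smoothed, property-weighted histogram of
  interatomic distances,

      g(r) = f · Σ_{i<j} A_i A_j · exp(−B (r − r_ij)²),

  evaluated on a fixed radius grid.  By construction g(r) is invariant to
  rigid motion of the molecule and to atom relabelling.
* **MATS / GATS** (2-D): Moran and Geary spatial autocorrelations of an
  atomic property over the molecular graph, at a fixed topological lag
  (shortest bond-path length).
* **C-005**: the Ghose–Crippen atom-centred fragment counting methyl
  groups bonded to an electronegative atom (CH3–X, X ∈ O, N, S, P, Se,
  halogens).

Descriptor names use the conventional grammar ``RDF###w``, ``MATS#w``,
``GATS#w`` and ``C-005``, where the trailing letter selects the weighting
(u=unweighted, m=mass, v=van der Waals volume, e=Sanderson
electronegativity, p=polarizability) and the RDF number divided by 10 is
the radius in Å (RDF105 → 10.5 Å).
"""

from __future__ import annotations

import re
from typing import Sequence

import numpy as np

from .errors import ConfigurationError
from .molecules import (
    ELECTRONEGATIVE,
    MoleculeGeometry,
    RDFConfig,
    WeightScheme,
)
from .table import DescriptorTable

__all__ = [
    "rdf_code",
    "moran_autocorrelation",
    "geary_autocorrelation",
    "c005_count",
    "compute_descriptor_table",
    "parse_descriptor_name",
]


def rdf_code(
    mol: MoleculeGeometry,
    weights: WeightScheme,
    config: RDFConfig = RDFConfig(),
) -> np.ndarray:
    """RDF code of a molecule: one g(r) value per configured radius.

    A single-atom molecule has no atom pairs and yields the zero vector.
    """
    radii = np.asarray(config.radii, dtype=float)
    n = mol.n_atoms
    if n < 2:
        return np.zeros(len(radii))
    w = weights.weights_for(mol.elements)
    dist = mol.distance_matrix()
    iu, ju = np.triu_indices(n, k=1)
    pair_w = w[iu] * w[ju]
    pair_d = dist[iu, ju]
    # radii × pairs Gaussian kernel, summed over pairs
    g = config.f * (pair_w * np.exp(-config.B * (radii[:, None] - pair_d[None, :]) ** 2)).sum(axis=1)
    return g


def _lag_pairs(mol: MoleculeGeometry, lag: int) -> np.ndarray:
    """Boolean mask of ordered atom pairs at topological distance ``lag``."""
    topo = mol.topological_distances()
    with np.errstate(invalid="ignore"):
        return topo == lag


def moran_autocorrelation(
    mol: MoleculeGeometry, weights: WeightScheme, lag: int
) -> float:
    """Moran autocorrelation (MATS) of an atomic property at a given lag.

    MATS = [ (1/Δ) Σ_{d_ij=lag} (w_i−w̄)(w_j−w̄) ] / [ (1/N) Σ_i (w_i−w̄)² ]

    where the sum runs over ordered pairs at topological distance ``lag``
    and Δ counts them.  Returns 0 when no pair realizes the lag or the
    property has zero variance over the molecule.
    """
    if lag < 1:
        raise ConfigurationError("lag must be >= 1")
    if mol.n_atoms < 2:
        return 0.0
    w = weights.weights_for(mol.elements)
    dev = w - w.mean()
    denom = (dev**2).sum() / mol.n_atoms
    if denom == 0.0:
        return 0.0
    mask = _lag_pairs(mol, lag)
    delta = int(mask.sum())
    if delta == 0:
        return 0.0
    num = (dev[:, None] * dev[None, :])[mask].sum() / delta
    return float(num / denom)


def geary_autocorrelation(
    mol: MoleculeGeometry, weights: WeightScheme, lag: int
) -> float:
    """Geary autocorrelation (GATS) of an atomic property at a given lag.

    GATS = [ (1/(2Δ)) Σ_{d_ij=lag} (w_i−w_j)² ] / [ (1/(N−1)) Σ_i (w_i−w̄)² ]

    with Δ counting ordered pairs; same zero conventions as MATS.
    """
    if lag < 1:
        raise ConfigurationError("lag must be >= 1")
    if mol.n_atoms < 2:
        return 0.0
    w = weights.weights_for(mol.elements)
    dev = w - w.mean()
    denom = (dev**2).sum() / (mol.n_atoms - 1)
    if denom == 0.0:
        return 0.0
    mask = _lag_pairs(mol, lag)
    delta = int(mask.sum())
    if delta == 0:
        return 0.0
    num = ((w[:, None] - w[None, :]) ** 2)[mask].sum() / (2 * delta)
    return float(num / denom)


def c005_count(mol: MoleculeGeometry) -> int:
    """Count CH3 groups bonded to an electronegative atom (CH3–X).

    A carbon qualifies when its single heavy-atom neighbour is in
    {O, N, S, P, Se, F, Cl, Br, I} and it carries three hydrogens —
    explicit ones if the molecule has any H atoms, otherwise inferred
    from the standard carbon valence.
    """
    count = 0
    for i, el in enumerate(mol.elements):
        if el != "C":
            continue
        nbrs = mol.neighbors(i)
        heavy = [j for j in nbrs if mol.elements[j] != "H"]
        n_h = len(nbrs) - len(heavy) + mol.implicit_hydrogens(i)
        if n_h == 3 and len(heavy) == 1 and mol.elements[heavy[0]] in ELECTRONEGATIVE:
            count += 1
    return count


# ----------------------------------------------------------------------
# name grammar and batch computation
# ----------------------------------------------------------------------

_NAME_RE = re.compile(r"^(RDF|MATS|GATS)(\d+)([umvep])$")


def parse_descriptor_name(name: str):
    """Parse ``RDF###w`` / ``MATS#w`` / ``GATS#w`` / ``C-005``.

    Returns ``(family, parameter, weight_scheme)`` where ``parameter`` is
    the radius in Å for RDF, the lag for MATS/GATS, and ``None`` for
    C-005.
    """
    if name == "C-005":
        return "C-005", None, None
    m = _NAME_RE.match(name)
    if m is None:
        raise ConfigurationError(
            f"cannot parse descriptor name {name!r}; expected RDF###w, "
            "MATS#w, GATS#w (w in u/m/v/e/p) or C-005"
        )
    family, number, letter = m.groups()
    scheme = WeightScheme.from_letter(letter)
    if family == "RDF":
        return "RDF", int(number) / 10.0, scheme
    return family, int(number), scheme


def compute_descriptor_table(
    mols: Sequence[MoleculeGeometry],
    requested: Sequence[str],
    rdf_f: float = 1.0,
    rdf_B: float = 100.0,
) -> DescriptorTable:
    """Compute the requested descriptors for every molecule.

    One row per molecule, columns in the requested order.  RDF columns for
    the same weighting are evaluated in one pass over the pair list.
    """
    parsed = [parse_descriptor_name(name) for name in requested]
    rows = np.zeros((len(mols), len(requested)))
    for i, mol in enumerate(mols):
        # group RDF requests by weight letter to share the pair loop
        rdf_groups: dict[str, list[int]] = {}
        for j, (family, param, scheme) in enumerate(parsed):
            if family == "RDF":
                rdf_groups.setdefault(scheme.name, []).append(j)
            elif family == "MATS":
                rows[i, j] = moran_autocorrelation(mol, scheme, param)
            elif family == "GATS":
                rows[i, j] = geary_autocorrelation(mol, scheme, param)
            else:  # C-005
                rows[i, j] = c005_count(mol)
        for scheme_name, cols in rdf_groups.items():
            radii = tuple(parsed[j][1] for j in cols)
            order = np.argsort(radii)
            config = RDFConfig(f=rdf_f, B=rdf_B, radii=tuple(np.asarray(radii)[order]))
            g = rdf_code(mol, WeightScheme.from_name(scheme_name), config)
            for pos, j_idx in enumerate(order):
                rows[i, cols[j_idx]] = g[pos]
    return DescriptorTable(
        compound_ids=[mol.id for mol in mols],
        descriptor_names=list(requested),
        values=rows,
    )
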