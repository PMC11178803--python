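"""Reaction featurization: Morgan fingerprints, a differential reaction
fingerprint, descriptor concatenation, and molecular graphs.

A reaction is a map from roles (aryl halide, ligand, base, additive by
default) to SMILES strings plus an observed percent yield.  Four input
representations are built from it:

* ``morgan_reaction_fp`` — per-component hashed circular (ECFP-like)
  fingerprints, concatenated in fixed role order or summed;
* ``drfp_reaction_fp`` — a differential reaction fingerprint: the hashed
  symmetric difference of the circular-substructure sets of the reactant and
  product sides of a reaction SMILES;
* ``descriptor_concat`` — lookup and concatenation of externally supplied
  per-component numeric descriptors (e.g. DFT-derived);
* ``mol_to_graph`` — node/edge feature arrays for message-passing networks.

All featurizers are deterministic for fixed input and configuration.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem, RDLogger
from rdkit.Chem import rdFingerprintGenerator

RDLogger.DisableLog("rdApp.*")

__all__ = [
    "DEFAULT_ROLES",
    "Reaction",
    "FeatureMatrix",
    "MolecularGraph",
    "FeaturizationError",
    "morgan_reaction_fp",
    "drfp_reaction_fp",
    "descriptor_concat",
    "mol_to_graph",
    "reactions_to_graphs",
    "GraphFeatureConfig",
]

#: fixed role order used for all concatenations
DEFAULT_ROLES = ("aryl_halide", "ligand", "base", "additive")


class FeaturizationError(ValueError):
    """Raised when a reaction or molecule cannot be featurized."""


@dataclass(frozen=True)
class Reaction:
    """One reaction: role → SMILES plus an optional percent yield."""

    components: dict
    yield_: float | None = None
    id: str = ""

    def __post_init__(self):
        if self.yield_ is not None:
            y = float(self.yield_)
            if not np.isfinite(y) or not (0.0 <= y <= 100.0):
                raise ValueError(f"reaction {self.id!r}: yield {y} outside [0, 100]")


@dataclass
class FeatureMatrix:
    """n × d numeric matrix with provenance of the featurizer that built it."""

    values: np.ndarray
    featurizer_tag: str

    def __post_init__(self):
        self.values = np.atleast_2d(np.asarray(self.values, dtype=np.float64))
        if not np.isfinite(self.values).all():
            raise ValueError("feature matrix contains NaN/Inf")

    @property
    def d(self) -> int:
        return self.values.shape[1]

    @property
    def n(self) -> int:
        return self.values.shape[0]


def _parse(smiles: str, rxn_id: str = "", role: str = "") -> Chem.Mol:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        where = f" (reaction {rxn_id!r}, role {role!r})" if rxn_id or role else ""
        raise FeaturizationError(f"unparseable SMILES {smiles!r}{where}")
    return mol


def morgan_reaction_fp(
    reactions,
    radius: int = 2,
    bits_per_component: int = 512,
    mode: str = "concat",
    roles=DEFAULT_ROLES,
) -> FeatureMatrix:
    """Per-component Morgan fingerprints combined into a reaction vector.

    ``concat`` joins the per-role bit vectors in the fixed role order, giving
    width ``bits_per_component * len(roles)`` (512 bits × 4 roles = 2048 by
    default); ``sum`` adds them element-wise, giving width
    ``bits_per_component`` with non-negative integer counts.
    """
    if mode not in ("concat", "sum"):
        raise ValueError(f"mode must be 'concat' or 'sum', got {mode!r}")
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=bits_per_component)
    rows = []
    for rxn in reactions:
        blocks = []
        for role in roles:
            if role not in rxn.components:
                raise FeaturizationError(f"reaction {rxn.id!r}: missing role {role!r}")
            mol = _parse(rxn.components[role], rxn.id, role)
            blocks.append(gen.GetFingerprintAsNumPy(mol).astype(np.float64))
        rows.append(np.concatenate(blocks) if mode == "concat" else np.sum(blocks, axis=0))
    return FeatureMatrix(np.array(rows), f"morgan_{mode}")


def _circular_shingling(mol: Chem.Mol, radius: int) -> set:
    """Canonical SMILES of every circular atom environment up to `radius`."""
    shingles = set()
    for atom in mol.GetAtoms():
        idx = atom.GetIdx()
        shingles.add(Chem.MolFragmentToSmiles(mol, atomsToUse=[idx], canonical=True))
        for r in range(1, radius + 1):
            bond_ids = Chem.FindAtomEnvironmentOfRadiusN(mol, r, idx)
            if not bond_ids:
                continue
            atoms = set()
            for b in bond_ids:
                bond = mol.GetBondWithIdx(b)
                atoms.update((bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()))
            shingles.add(
                Chem.MolFragmentToSmiles(
                    mol, atomsToUse=sorted(atoms), bondsToUse=list(bond_ids), canonical=True
                )
            )
    return shingles


def _stable_hash(s: str, n_bits: int) -> int:
    """Platform-independent substructure → bit index map (first 8 sha1 bytes)."""
    return int.from_bytes(hashlib.sha1(s.encode("utf8")).digest()[:8], "big") % n_bits


def drfp_reaction_fp(reaction_smiles: str, radius: int = 2, n_bits: int = 2048) -> np.ndarray:
    """Differential reaction fingerprint of a ``reactants>>products`` SMILES.

    Circular substructures (canonical fragment SMILES up to ``radius``) are
    enumerated as a set for each side; surviving members of the symmetric
    difference are hashed into ``[0, n_bits)`` with a stable seeded hash and
    the corresponding bits set.  An empty symmetric difference (for example
    ``"X>>X"``) gives the all-zero vector.
    """
    parts = reaction_smiles.split(">")
    if len(parts) == 3:
        left, _agents, right = parts
    elif len(parts) == 2:
        left, right = parts
    else:
        raise FeaturizationError(f"malformed reaction SMILES {reaction_smiles!r}")
    sides = []
    for side_smiles, side_name in ((left, "reactant"), (right, "product")):
        mols = [s for s in side_smiles.split(".") if s]
        if not mols:
            raise FeaturizationError(f"reaction SMILES has empty {side_name} side")
        shingles = set()
        for s in mols:
            mol = Chem.MolFromSmiles(s)
            if mol is None:
                raise FeaturizationError(f"unparseable {side_name} SMILES {s!r}")
            shingles |= _circular_shingling(mol, radius)
        sides.append(shingles)
    diff = sides[0] ^ sides[1]
    vec = np.zeros(n_bits, dtype=np.float64)
    for sub in diff:
        vec[_stable_hash(sub, n_bits)] = 1.0
    return vec


def descriptor_concat(reactions, tables: dict, roles=DEFAULT_ROLES) -> FeatureMatrix:
    """Concatenate per-component descriptor vectors looked up from role tables.

    ``tables`` maps role → {component SMILES or id → 1-D descriptor vector};
    each role table must have a single fixed width.  Output width is the sum
    of per-role widths (120 for the reference descriptor set).
    """
    widths = {}
    for role in roles:
        if role not in tables:
            raise FeaturizationError(f"no descriptor table for role {role!r}")
        table_widths = {len(np.ravel(v)) for v in tables[role].values()}
        if len(table_widths) != 1:
            raise FeaturizationError(f"ragged descriptor table for role {role!r}: widths {sorted(table_widths)}")
        widths[role] = table_widths.pop()
    rows = []
    for rxn in reactions:
        parts = []
        for role in roles:
            key = rxn.components.get(role)
            if key not in tables[role]:
                raise FeaturizationError(
                    f"reaction {rxn.id!r}: component {key!r} missing from {role!r} descriptor table"
                )
            parts.append(np.ravel(np.asarray(tables[role][key], dtype=np.float64)))
        rows.append(np.concatenate(parts))
    return FeatureMatrix(np.array(rows), "descriptor")


# ---------------------------------------------------------------- graphs
_HYBRIDIZATIONS = (
    Chem.HybridizationType.SP,
    Chem.HybridizationType.SP2,
    Chem.HybridizationType.SP3,
    Chem.HybridizationType.SP3D,
    Chem.HybridizationType.SP3D2,
)
_CHIRAL_TAGS = (
    Chem.ChiralType.CHI_UNSPECIFIED,
    Chem.ChiralType.CHI_TETRAHEDRAL_CW,
    Chem.ChiralType.CHI_TETRAHEDRAL_CCW,
)
_BOND_TYPES = (
    Chem.BondType.SINGLE,
    Chem.BondType.DOUBLE,
    Chem.BondType.TRIPLE,
    Chem.BondType.AROMATIC,
)
_BOND_STEREO = (Chem.BondStereo.STEREONONE, Chem.BondStereo.STEREOZ, Chem.BondStereo.STEREOE)


@dataclass(frozen=True)
class GraphFeatureConfig:
    """Atom/bond feature plan for graph construction.

    ``elements`` is the one-hot vocabulary; atoms outside it fall into a
    trailing "other" slot.  The default covers the elements common in
    cross-coupling chemistry.
    """

    elements: tuple = ("C", "N", "O", "F", "P", "S", "Cl", "Br", "I")
    max_degree: int = 5
    max_h: int = 4

    @property
    def node_width(self) -> int:
        return (
            len(self.elements) + 1  # element one-hot + other
            + self.max_degree + 2   # degree one-hot (+ overflow slot)
            + 1                     # formal charge (scalar)
            + len(_HYBRIDIZATIONS) + 1
            + 1                     # aromatic flag
            + self.max_h + 2        # attached-H one-hot (+ overflow slot)
            + len(_CHIRAL_TAGS) + 1
        )

    @property
    def aromatic_index(self) -> int:
        """Column of the aromatic flag in the node feature vector."""
        return len(self.elements) + 1 + self.max_degree + 2 + 1 + len(_HYBRIDIZATIONS) + 1

    @property
    def edge_width(self) -> int:
        return len(_BOND_TYPES) + 1 + 1 + 1 + len(_BOND_STEREO) + 1


@dataclass
class MolecularGraph:
    """Undirected molecular graph with per-atom and per-bond feature vectors.

    Edges are stored once as unordered index pairs; message-passing code
    expands each to two directed arcs.
    """

    node_features: np.ndarray
    edges: np.ndarray          # (n_edges, 2) int
    edge_features: np.ndarray  # (n_edges, edge_width)
    smiles: str = ""

    def __post_init__(self):
        self.node_features = np.atleast_2d(np.asarray(self.node_features, dtype=np.float64))
        self.edges = np.asarray(self.edges, dtype=np.intp).reshape(-1, 2)
        ef = np.asarray(self.edge_features, dtype=np.float64)
        self.edge_features = ef.reshape(self.edges.shape[0], -1) if ef.size else ef.reshape(0, ef.shape[-1] if ef.ndim > 1 else 0)
        n = self.node_features.shape[0]
        if n < 1:
            raise ValueError("graph must have at least one node")
        if self.edges.size and (self.edges.min() < 0 or self.edges.max() >= n):
            raise ValueError("edge index out of range")

    @property
    def n_atoms(self) -> int:
        return self.node_features.shape[0]


def _one_hot(value, choices) -> list:
    vec = [0.0] * (len(choices) + 1)
    try:
        vec[list(choices).index(value)] = 1.0
    except ValueError:
        vec[-1] = 1.0  # "other" bucket
    return vec


def mol_to_graph(smiles: str, config: GraphFeatureConfig = GraphFeatureConfig()) -> MolecularGraph:
    """Build a molecular graph with atom and bond features from a SMILES.

    Atoms are renumbered by rdkit's canonical ranking so equivalent SMILES
    writings (kekulized vs aromatic benzene) produce identical graphs.
    """
    mol = _parse(smiles)
    if mol.GetNumHeavyAtoms() < 1:
        raise FeaturizationError(f"no heavy atoms in {smiles!r}")
    order = tuple(np.argsort(list(Chem.CanonicalRankAtoms(mol, breakTies=True))))
    mol = Chem.RenumberAtoms(mol, [int(i) for i in order])
    nodes = []
    for atom in mol.GetAtoms():
        feats = (
            _one_hot(atom.GetSymbol(), config.elements)
            + _one_hot(min(atom.GetDegree(), config.max_degree), range(config.max_degree + 1))
            + [float(atom.GetFormalCharge())]
            + _one_hot(atom.GetHybridization(), _HYBRIDIZATIONS)
            + [1.0 if atom.GetIsAromatic() else 0.0]
            + _one_hot(min(atom.GetTotalNumHs(), config.max_h), range(config.max_h + 1))
            + _one_hot(atom.GetChiralTag(), _CHIRAL_TAGS)
        )
        nodes.append(feats)
    edges, efeats = [], []
    for bond in mol.GetBonds():
        edges.append((bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()))
        efeats.append(
            _one_hot(bond.GetBondType(), _BOND_TYPES)
            + [1.0 if bond.GetIsConjugated() else 0.0]
            + [1.0 if bond.IsInRing() else 0.0]
            + _one_hot(bond.GetStereo(), _BOND_STEREO)
        )
    edge_arr = np.array(edges, dtype=np.intp).reshape(-1, 2)
    efeat_arr = (
        np.array(efeats, dtype=np.float64)
        if efeats
        else np.zeros((0, config.edge_width), dtype=np.float64)
    )
    return MolecularGraph(
        node_features=np.array(nodes, dtype=np.float64),
        edges=edge_arr,
        edge_features=efeat_arr,
        smiles=smiles,
    )


def reactions_to_graphs(reactions, roles=DEFAULT_ROLES, config: GraphFeatureConfig = GraphFeatureConfig()):
    """Per-reaction role → graph maps, one graph per component."""
    out = []
    for rxn in reactions:
        graphs = {}
        for role in roles:
            if role not in rxn.components:
                raise FeaturizationError(f"reaction {rxn.id!r}: missing role {role!r}")
            try:
                graphs[role] = mol_to_graph(rxn.components[role], config)
            except FeaturizationError as e:
                raise FeaturizationError(f"reaction {rxn.id!r}, role {role!r}: {e}") from e
        out.append(graphs)
    return out
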