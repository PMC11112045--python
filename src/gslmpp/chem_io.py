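"""Dataset I/O, SMILES featurization, fingerprints and scaffold splits.

Datasets follow the MoleculeNet CSV dialect: a header row, one SMILES
column, one or more numeric target columns; blank target cells mean the
label is missing and are carried as a boolean mask so no loss or metric
ever reads them.

Atom-level graphs use a fixed featurization scheme (element one-hot over a
small organic vocabulary, degree, formal charge, aromaticity, hydrogen
count, hybridization). Bond features are deliberately not used: the
molecular encoder is a plain GIN over the atom graph.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from rdkit import Chem, RDLogger
from rdkit.Chem import rdFingerprintGenerator
from rdkit.Chem.Scaffolds import MurckoScaffold

from .exceptions import ConfigurationError, InputError, SmilesParseError

logger = logging.getLogger(__name__)

RDLogger.DisableLog("rdApp.*")  # rdkit parse warnings are surfaced via our own log

SPLITS = ("train", "valid", "test", "unassigned")


# ---------------------------------------------------------------------------
# domain types

@dataclass
class MoleculeRecord:
    """One compound: identifier, SMILES, target vector with missing-label mask."""

    id: str
    smiles: str
    targets: np.ndarray
    target_mask: np.ndarray
    split: str = "unassigned"

    def __post_init__(self):
        self.targets = np.atleast_1d(np.asarray(self.targets, dtype=np.float64))
        self.target_mask = np.atleast_1d(np.asarray(self.target_mask, dtype=bool))
        if self.targets.shape != self.target_mask.shape or self.targets.size < 1:
            raise ConfigurationError("targets and target_mask must share length >= 1")
        if self.split not in SPLITS:
            raise ConfigurationError(f"unknown split {self.split!r}")


@dataclass
class MolecularGraph:
    """Atom-level attributed graph: one node per heavy atom, one edge per bond."""

    node_features: np.ndarray  # (n_v, feature_dim)
    edges: np.ndarray          # (n_e, 2) undirected, each bond listed once
    n_v: int
    n_e: int

    def __post_init__(self):
        self.edges = np.asarray(self.edges, dtype=np.intp).reshape(-1, 2)
        if self.n_v < 1:
            raise InputError("molecular graph needs at least one heavy atom")
        if self.n_e and (self.edges.min() < 0 or self.edges.max() >= self.n_v):
            raise InputError("edge endpoint out of range")


@dataclass
class Fingerprint:
    """Fixed-length binary substructure fingerprint."""

    bits: np.ndarray
    radius: int
    n_bits: int

    def __post_init__(self):
        self.bits = np.asarray(self.bits, dtype=bool)
        if self.bits.size != self.n_bits:
            raise ConfigurationError("bit vector length != n_bits")

    def comparable_with(self, other: "Fingerprint") -> bool:
        return self.radius == other.radius and self.n_bits == other.n_bits


# ---------------------------------------------------------------------------
# featurization

ATOM_VOCAB = ("C", "N", "O", "F", "P", "S", "Cl", "Br", "I")
HYBRIDIZATIONS = (
    Chem.HybridizationType.SP,
    Chem.HybridizationType.SP2,
    Chem.HybridizationType.SP3,
    Chem.HybridizationType.SP3D,
    Chem.HybridizationType.SP3D2,
)


@dataclass
class FeaturizationConfig:
    """Atom feature scheme; the defaults define the package-wide scheme."""

    atom_vocab: tuple = ATOM_VOCAB
    max_degree: int = 5
    max_h: int = 4

    def feature_names(self) -> list[str]:
        names = [f"element_{s}" for s in self.atom_vocab] + ["element_other"]
        names += [f"degree_{d}" for d in range(self.max_degree + 1)]
        names += ["formal_charge", "is_aromatic"]
        names += [f"num_h_{h}" for h in range(self.max_h + 1)]
        names += [f"hybrid_{h}" for h in ("sp", "sp2", "sp3", "sp3d", "sp3d2")]
        names += ["hybrid_other"]
        return names

    @property
    def dim(self) -> int:
        return len(self.feature_names())


def _mol_from_smiles(smiles: str) -> Chem.Mol:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesParseError(smiles)
    return mol


def canonical_smiles(smiles: str) -> str:
    return Chem.MolToSmiles(_mol_from_smiles(smiles))


def _atom_features(atom: Chem.Atom, scheme: FeaturizationConfig) -> np.ndarray:
    x = np.zeros(scheme.dim, dtype=np.float64)
    off = 0
    sym = atom.GetSymbol()
    vocab = scheme.atom_vocab
    x[off + (vocab.index(sym) if sym in vocab else len(vocab))] = 1.0
    off += len(vocab) + 1
    x[off + min(atom.GetDegree(), scheme.max_degree)] = 1.0
    off += scheme.max_degree + 1
    x[off] = float(atom.GetFormalCharge())
    x[off + 1] = float(atom.GetIsAromatic())
    off += 2
    x[off + min(atom.GetTotalNumHs(), scheme.max_h)] = 1.0
    off += scheme.max_h + 1
    hyb = atom.GetHybridization()
    idx = HYBRIDIZATIONS.index(hyb) if hyb in HYBRIDIZATIONS else len(HYBRIDIZATIONS)
    x[off + idx] = 1.0
    return x


def featurize_molecule(smiles: str, scheme: FeaturizationConfig | None = None) -> MolecularGraph:
    """Turn a SMILES into its heavy-atom graph with per-atom feature vectors."""
    scheme = scheme or FeaturizationConfig()
    mol = _mol_from_smiles(smiles)
    feats = np.stack([_atom_features(a, scheme) for a in mol.GetAtoms()])
    edges = np.array(
        [(b.GetBeginAtomIdx(), b.GetEndAtomIdx()) for b in mol.GetBonds()],
        dtype=np.intp,
    ).reshape(-1, 2)
    return MolecularGraph(feats, edges, mol.GetNumAtoms(), mol.GetNumBonds())


# ---------------------------------------------------------------------------
# fingerprints and Tanimoto similarity

def compute_fingerprint(smiles: str, radius: int = 2, n_bits: int = 2048) -> Fingerprint:
    """Morgan/ECFP circular fingerprint hashed into `n_bits` bits."""
    if radius < 0 or n_bits < 1:
        raise ConfigurationError("radius must be >= 0 and n_bits >= 1")
    mol = _mol_from_smiles(smiles)
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits)
    return Fingerprint(gen.GetFingerprintAsNumPy(mol).astype(bool), radius, n_bits)


def tanimoto(a: Fingerprint, b: Fingerprint) -> float:
    """|A∩B| / |A∪B| over the set bits; 0.0 for two empty fingerprints."""
    if not a.comparable_with(b):
        raise ConfigurationError(
            "fingerprints are not comparable (radius/n_bits differ)")
    inter = int(np.count_nonzero(a.bits & b.bits))
    union = int(np.count_nonzero(a.bits | b.bits))
    if union == 0:
        logger.warning("Tanimoto of two empty fingerprints defined as 0.0")
        return 0.0
    return inter / union


# ---------------------------------------------------------------------------
# dataset parsing

def parse_dataset(path, smiles_column: str = "smiles",
                  target_columns: list[str] | None = None,
                  id_column: str | None = None) -> list[MoleculeRecord]:
    """Read a MoleculeNet-dialect delimited table into molecule records.

    Rows whose SMILES fails to parse are dropped with a counted warning;
    blank target cells become masked entries.
    """
    df = pd.read_csv(path, sep=None, engine="python")
    if smiles_column not in df.columns:
        raise ConfigurationError(f"missing SMILES column {smiles_column!r}")
    if target_columns is None:
        target_columns = [c for c in df.columns
                          if c not in (smiles_column, id_column, "id")]
    missing = [c for c in target_columns if c not in df.columns]
    if missing:
        raise ConfigurationError(f"missing target columns: {missing}")
    if not target_columns:
        raise ConfigurationError("at least one target column is required")

    records: list[MoleculeRecord] = []
    dropped = 0
    for i, row in df.iterrows():
        smi = str(row[smiles_column])
        if Chem.MolFromSmiles(smi) is None:
            dropped += 1
            continue
        vals = pd.to_numeric(row[target_columns], errors="coerce").to_numpy(dtype=np.float64)
        mask = np.isfinite(vals)
        vals = np.where(mask, vals, 0.0)
        if id_column and id_column in df.columns:
            rid = str(row[id_column])
        elif "id" in df.columns:
            rid = str(row["id"])
        else:
            rid = f"mol{i}"
        records.append(MoleculeRecord(rid, smi, vals, mask))
    if dropped:
        logger.warning("dropped %d rows with unparseable SMILES", dropped)
    if not records:
        raise InputError("no parseable rows in dataset")
    return records


# ---------------------------------------------------------------------------
# scaffold splitting

def murcko_scaffold(smiles: str) -> str:
    return MurckoScaffold.MurckoScaffoldSmiles(smiles=smiles, includeChirality=False)


def scaffold_split(records: list[MoleculeRecord],
                   fractions: tuple[float, float, float] = (0.8, 0.1, 0.1),
                   seed: int = 0) -> list[MoleculeRecord]:
    """Balanced Bemis–Murcko scaffold split.

    Molecules sharing a scaffold never straddle splits. Scaffold groups
    larger than half the valid/test capacity are forced into train; the
    remaining groups are seed-shuffled and assigned greedily train-first.
    """
    f_train, f_valid, f_test = fractions
    if min(fractions) <= 0 or abs(sum(fractions) - 1.0) > 1e-8:
        raise ConfigurationError("fractions must be positive and sum to 1")
    n = len(records)
    n_valid = int(round(f_valid * n))
    n_test = int(round(f_test * n))
    n_train = n - n_valid - n_test

    groups: dict[str, list[int]] = {}
    for i, rec in enumerate(records):
        groups.setdefault(murcko_scaffold(rec.smiles), []).append(i)

    if len(groups) < 3:
        logger.warning("fewer than 3 distinct scaffolds; assigning all to train")
        for rec in records:
            rec.split = "train"
        return records

    big, small = [], []
    # groups too large for either held-out bucket are pinned to train;
    # floor of 1 keeps singleton scaffolds assignable on tiny datasets
    cap = max(1.0, min(n_valid, n_test) / 2.0)
    for idxs in groups.values():
        (big if len(idxs) > cap else small).append(idxs)
    rng = np.random.default_rng(seed)
    rng.shuffle(small)

    train: list[int] = [i for g in big for i in g]
    valid: list[int] = []
    test: list[int] = []
    for g in small:
        if len(train) + len(g) <= n_train or (len(valid) >= n_valid and len(test) >= n_test):
            train.extend(g)
        elif len(valid) + len(g) <= n_valid or len(test) >= n_test:
            valid.extend(g)
        else:
            test.extend(g)
    for i in train:
        records[i].split = "train"
    for i in valid:
        records[i].split = "valid"
    for i in test:
        records[i].split = "test"
    return records


def write_split_manifest(records: list[MoleculeRecord], path) -> None:
    pd.DataFrame({"id": [r.id for r in records],
                  "split": [r.split for r in records]}).to_csv(path, index=False)


def read_split_manifest(records: list[MoleculeRecord], path) -> list[MoleculeRecord]:
    mapping = pd.read_csv(path).set_index("id")["split"].to_dict()
    for rec in records:
        if rec.id in mapping:
            rec.split = str(mapping[rec.id])
    return records
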