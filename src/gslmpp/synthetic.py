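"""Synthetic compound datasets with planted scaffold-cluster structure.

Molecules are built by decorating a fixed library of drug-like core
templates (one template = one cluster) with simple substituents at two
sites, so members of a cluster share high pairwise fingerprint similarity
while clusters are well separated. The property function is known:

    y = cluster_mean + substituent effects (+ Gaussian noise)

for regression; classification thresholds the noise-free value at zero and
optionally flips labels. Activity-cliff (AC) pairs — near-duplicate
structures (Tanimoto >= 0.7) assigned maximally discordant targets — can
be planted to stress the structure learner.

Ring-bearing substituents give each cluster several distinct Bemis–Murcko
scaffolds, so a scaffold split can still distribute a cluster across
splits. All randomness flows from one seeded generator.

`micro_fixture` returns a 4-molecule pencil-and-paper bundle exercising
the full structure-learning trace with hand-checkable numbers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from rdkit import Chem

from .chem_io import MoleculeRecord, compute_fingerprint, tanimoto
from .exceptions import ConfigurationError

CORE_TEMPLATES = (
    "c1cc({R1})ccc1{R2}",
    "c1cc({R1})cnc1{R2}",
    "C1CC1C(=O)Nc1cc({R1})ccc1{R2}",
    "c1ccc(cc1)S(=O)(=O)Nc1cc({R1})ccc1{R2}",
    "O=C(Nc1cc({R1})ccc1{R2})C",
    "c1cc({R1})ccc1OC(=O)c1ccccc1{R2}",
    "c1cc({R1})ccc1Cc1ccccc1{R2}",
    "c1cc({R1})ccc1NC(=O)C1CCCCC1{R2}",
    "O=S(=O)(N)c1cc({R1})ccc1{R2}",
    "c1cc({R1})ccc1OCCOc1ccccc1{R2}",
)

SUBSTITUENTS = ("C", "CC", "CCC", "F", "Cl", "Br", "O", "OC", "N",
                "C(F)(F)F", "C#N", "c2ccccc2", "C2CC2", "CCO")

# chain-extension edits whose ECFP4 Tanimoto stays >= 0.7 on every core
_AC_EDITS = (("CCO", "CCCO"), ("CCC", "CCCC"))

_AC_MAGNITUDE = 3.0  # discordant targets sit at +/- this value


@dataclass
class SyntheticSpec:
    """Study conditions for one synthetic draw."""

    n_molecules: int = 200
    n_clusters: int = 5
    task_type: str = "regression"
    noise_sd: float = 0.25
    flip_prob: float = 0.0
    ac_pair_count: int = 0
    seed: int = 0
    # with cluster-level labels the clean target is the cluster mean alone
    # (no substituent effects): the label structure lives entirely at the
    # scaffold-cluster level that fingerprint similarity can detect
    cluster_level_labels: bool = False

    def validate(self) -> None:
        if self.n_clusters < 2:
            raise ConfigurationError("n_clusters must be >= 2")
        if self.n_clusters > len(CORE_TEMPLATES):
            raise ConfigurationError(
                f"at most {len(CORE_TEMPLATES)} clusters are available")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")
        if not 0.0 <= self.flip_prob < 0.5:
            raise ConfigurationError("flip_prob must lie in [0, 0.5)")
        if self.ac_pair_count < 0:
            raise ConfigurationError("ac_pair_count must be >= 0")
        if self.task_type not in ("regression", "classification"):
            raise ConfigurationError(f"unknown task type {self.task_type!r}")
        capacity = self.n_clusters * len(SUBSTITUENTS) ** 2
        if self.n_molecules > capacity:
            raise ConfigurationError(
                f"spec infeasible: {self.n_molecules} molecules exceed "
                f"{capacity} distinct decorations")
        if 2 * self.ac_pair_count > self.n_molecules:
            raise ConfigurationError("too many AC pairs for n_molecules")


def _substituent_effects() -> np.ndarray:
    return np.linspace(-0.4, 0.4, len(SUBSTITUENTS))


def generate_dataset(spec: SyntheticSpec, return_truth: bool = False):
    """Draw a seeded synthetic dataset of molecule records.

    Returns the record list, or ``(records, truth)`` with a per-molecule
    ground-truth table (cluster id, planted effect, AC flag) when
    `return_truth` is set.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    cluster_means = np.linspace(-2.0, 2.0, spec.n_clusters)
    effects = _substituent_effects()

    n_ac = 2 * spec.ac_pair_count
    n_base = spec.n_molecules - n_ac
    per_cluster = np.full(spec.n_clusters, n_base // spec.n_clusters)
    per_cluster[: n_base % spec.n_clusters] += 1

    smiles: list[str] = []
    clusters: list[int] = []
    clean: list[float] = []
    ac_flag: list[bool] = []

    n_sub = len(SUBSTITUENTS)
    for c in range(spec.n_clusters):
        combos = rng.permutation(n_sub * n_sub)[: per_cluster[c]]
        for combo in combos:
            i1, i2 = divmod(int(combo), n_sub)
            smi = CORE_TEMPLATES[c].format(R1=SUBSTITUENTS[i1], R2=SUBSTITUENTS[i2])
            assert Chem.MolFromSmiles(smi) is not None
            smiles.append(smi)
            clusters.append(c)
            if spec.cluster_level_labels:
                clean.append(cluster_means[c])
            else:
                clean.append(cluster_means[c] + effects[i1] + effects[i2])
            ac_flag.append(False)

    # planted activity cliffs: near-duplicate structures, opposite targets
    for _ in range(spec.ac_pair_count):
        c = int(rng.integers(spec.n_clusters))
        r1 = SUBSTITUENTS[int(rng.integers(n_sub))]
        edit = _AC_EDITS[int(rng.integers(len(_AC_EDITS)))]
        pair_smiles = [CORE_TEMPLATES[c].format(R1=r1, R2=r2) for r2 in edit]
        fps = [compute_fingerprint(s) for s in pair_smiles]
        sim = tanimoto(*fps)
        assert sim >= 0.7, f"AC pair similarity {sim:.3f} below 0.7"
        for smi, target in zip(pair_smiles, (_AC_MAGNITUDE, -_AC_MAGNITUDE)):
            smiles.append(smi)
            clusters.append(c)
            clean.append(target)
            ac_flag.append(True)

    clean_arr = np.asarray(clean)
    if spec.task_type == "regression":
        noise = rng.normal(0.0, spec.noise_sd, size=len(smiles)) if spec.noise_sd else 0.0
        targets = clean_arr + noise
    else:
        targets = (clean_arr > 0.0).astype(np.float64)
        if spec.flip_prob:
            flips = rng.random(len(smiles)) < spec.flip_prob
            keep_ac = np.asarray(ac_flag)  # cliffs stay maximally discordant
            targets = np.where(flips & ~keep_ac, 1.0 - targets, targets)

    records = [
        MoleculeRecord(f"syn{i}", smi, np.array([t]), np.array([True]))
        for i, (smi, t) in enumerate(zip(smiles, targets))
    ]
    if not return_truth:
        return records
    import pandas as pd

    truth = pd.DataFrame({
        "id": [r.id for r in records],
        "smiles": smiles,
        "cluster": clusters,
        "clean_target": clean_arr,
        "target": targets,
        "is_activity_cliff": ac_flag,
    })
    return records, truth


# ---------------------------------------------------------------------------
# hand-specified micro fixture

def micro_fixture() -> dict:
    """A 4-molecule bundle with hand-set embeddings and adjacency.

    The expected two-round structure-learning trace (unit perspective
    weight, identity propagation weights, no normalization) is produced by
    a straight-line evaluation of the refinement recurrences, written
    without any of the package's model code, so it can serve as an
    independent oracle for the structure learner.
    """
    x_r = np.array([
        [1.0, 0.0],
        [0.8, 0.6],
        [0.0, 1.0],
        [0.5, 0.5],
    ])
    a0 = np.array([
        [0.0, 0.9, 0.0, 0.4],
        [0.9, 0.0, 0.0, 0.5],
        [0.0, 0.0, 0.0, 0.6],
        [0.4, 0.5, 0.6, 0.0],
    ])
    return {
        "smiles": ["CCO", "CCN", "c1ccccc1", "CC(=O)O"],
        "X_r": x_r,
        "A0": a0,
        "perspective_weights": np.ones((1, 2)),
        "epsilon_sparsify": 0.2,
        "lam": 0.8,
        "eta": 0.5,
        "layer_weights": [np.eye(2), np.eye(2)],
        "T": 2,
        "normalize": False,
        "expected_trace": _MICRO_EXPECTED,
    }


# frozen straight-line evaluation of the T = 2 refinement on the fixture
_MICRO_EXPECTED: list[dict] = []


def _freeze_micro_expected() -> None:
    """Straight-line (loop-free per step) evaluation used to fill the trace."""
    x_r = micro_fixture()["X_r"]
    a0 = micro_fixture()["A0"]
    lam, eta, eps = 0.8, 0.5, 0.2
    h = x_r
    a1 = None
    for t in (1, 2):
        norms = np.sqrt((h ** 2).sum(axis=1))
        s = (h @ h.T) / np.outer(norms, norms)
        a_t = np.where(s >= eps, s, 0.0)
        np.fill_diagonal(a_t, 0.0)
        if t == 1:
            a1 = a_t
        a_f = lam * a0 + (1 - lam) * (eta * a_t + (1 - eta) * a1)
        hh = x_r
        for _ in range(2):
            hh = np.maximum(a_f @ hh, 0.0)
        h = hh
        _MICRO_EXPECTED.append({"t": t, "A_t": a_t, "A_fused": a_f, "H": h})


_freeze_micro_expected()
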