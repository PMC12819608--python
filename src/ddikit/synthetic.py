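"""Synthetic multimodal drug cohorts with planted, controllable structure.

Real DDI benchmarks pair each drug with several heterogeneous feature
sources (substructure fingerprints, adverse-effect profiles, expression
signatures, ...) and binary interaction labels on drug pairs.  The
generator here emulates that shape with fully known ground truth:

* drugs fall into latent clusters; exactly one modality (index 0) carries
  cluster-separable signal (cluster centroids + Gaussian noise), the rest
  are pure noise;
* context annotations (therapeutic-class stand-ins) equal the cluster id
  plus one random extra context per drug;
* co-prescription counts are Poisson, with the within-cluster rate 5x the
  between-cluster rate;
* pair labels are 1 for within-cluster pairs and 0 otherwise, flipped
  independently with a small probability, with negatives subsampled to a
  roughly 1:1 class balance.

Everything is a pure function of (parameters, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SyntheticCohort",
    "MolecularGraphToy",
    "generate_cohort",
    "generate_molecular_toys",
    "molecular_graph_from_smiles",
    "DEFAULT_COHORT_PARAMS",
    "N_ATOM_TYPES", "N_DEGREE_LABELS", "N_CHARGE_LABELS", "N_BOND_TYPES",
]

#: Study-condition defaults for the end-to-end experiments: 200 drugs,
#: 4 modalities with one informative, 5% label noise.
DEFAULT_COHORT_PARAMS = dict(
    n_drugs=200, n_modalities=4, n_clusters=4, noise_sd=1.0, flip_prob=0.05,
)

WITHIN_CLUSTER_RATE = 5.0   #: Poisson co-prescription rate inside a cluster
BETWEEN_CLUSTER_RATE = 1.0  #: ... and across clusters
N_EXTRA_CONTEXTS = 3        #: pool of non-cluster context labels

N_ATOM_TYPES = 6
N_DEGREE_LABELS = 4
N_CHARGE_LABELS = 3
N_BOND_TYPES = 3


@dataclass(frozen=True)
class SyntheticCohort:
    """A generated drug cohort with known latent structure."""

    n_drugs: int
    cluster_assignment: np.ndarray          # (n_drugs,) int
    modality_features: list                 # list of (n_drugs, dim_m) arrays
    informative_modality_index: int
    context_labels: list                    # per drug: list of context ids
    coprescription_counts: np.ndarray       # (n_drugs, n_drugs) int, symmetric
    pair_labels: np.ndarray                 # (n_pairs, 3) int: i, j, label
    seed: int
    drug_ids: list = field(default_factory=list)

    def __post_init__(self):
        if not self.drug_ids:
            object.__setattr__(
                self, "drug_ids",
                [f"D{i:04d}" for i in range(self.n_drugs)])

    @property
    def n_modalities(self) -> int:
        return len(self.modality_features)

    @property
    def feature_matrix(self) -> np.ndarray:
        """All modality blocks concatenated column-wise (the matrix X)."""
        return np.concatenate(self.modality_features, axis=1)

    @property
    def modality_slices(self) -> list:
        slices, start = [], 0
        for m in self.modality_features:
            slices.append(slice(start, start + m.shape[1]))
            start += m.shape[1]
        return slices


@dataclass(frozen=True)
class MolecularGraphToy:
    """A small random connected molecular graph (atoms = nodes, bonds = edges).

    Atom labels are categorical (type, degree label, aromatic flag, formal
    charge label); each undirected bond is stored once as (u, v, bond_type)
    with u < v.
    """

    drug_id: str
    atom_labels: list    # list of (type, degree, aromatic, charge) int tuples
    bond_list: list      # list of (u, v, bond_type) with u < v

    @property
    def n_atoms(self) -> int:
        return len(self.atom_labels)

    def adjacency(self) -> np.ndarray:
        a = np.zeros((self.n_atoms, self.n_atoms))
        for u, v, _ in self.bond_list:
            a[u, v] = a[v, u] = 1.0
        return a


def generate_cohort(n_drugs: int, n_modalities: int = 4, dims=None,
                    n_clusters: int = 4, noise_sd: float = 1.0,
                    flip_prob: float = 0.05, seed: int = 0,
                    binary_noise: bool = False) -> SyntheticCohort:
    """Generate a cohort with one informative modality (index 0).

    Parameters
    ----------
    dims : sequence of int, optional
        Per-modality feature dimensions (default 32 each).
    binary_noise : bool
        If True, non-informative modalities are Bernoulli(0.3) 0/1
        "fingerprint-like" blocks (so the Jaccard kernel path is testable).
    """
    if n_modalities < 2:
        raise ValueError("n_modalities must be >= 2")
    if n_clusters < 1 or n_drugs < 2 * n_clusters:
        raise ValueError("need n_drugs >= 2 * n_clusters")
    if not 0.0 <= flip_prob < 0.5:
        raise ValueError("flip_prob must lie in [0, 0.5): labels would be "
                         "uninformative otherwise")
    if noise_sd <= 0:
        raise ValueError("noise_sd must be positive")
    if dims is None:
        dims = [32] * n_modalities
    dims = list(dims)
    if len(dims) != n_modalities or any(d <= 0 for d in dims):
        raise ValueError("dims must give a positive size per modality")

    rng = np.random.default_rng(seed)

    # balanced cluster assignment, shuffled
    clusters = rng.permutation(np.arange(n_drugs) % n_clusters)

    # modality 0: centroids + Gaussian noise; others: pure noise
    centroids = rng.normal(0.0, 1.0, size=(n_clusters, dims[0]))
    feats = [centroids[clusters] + rng.normal(0.0, noise_sd,
                                              size=(n_drugs, dims[0]))]
    for m in range(1, n_modalities):
        if binary_noise:
            feats.append((rng.random((n_drugs, dims[m])) < 0.3)
                         .astype(np.float64))
        else:
            feats.append(rng.normal(0.0, 1.0, size=(n_drugs, dims[m])))

    # contexts: own cluster id plus one random extra context
    contexts = [[int(c), int(n_clusters + rng.integers(N_EXTRA_CONTEXTS))]
                for c in clusters]

    # co-prescription counts: Poisson, elevated within clusters
    same = clusters[:, None] == clusters[None, :]
    rates = np.where(same, WITHIN_CLUSTER_RATE, BETWEEN_CLUSTER_RATE)
    upper = rng.poisson(rates)
    counts = np.triu(upper, k=1)
    counts = counts + counts.T

    # pair labels: all within-cluster positives, balanced negatives, flips
    iu, ju = np.triu_indices(n_drugs, k=1)
    within = same[iu, ju]
    pos_pairs = np.stack([iu[within], ju[within]], axis=1)
    neg_all = np.stack([iu[~within], ju[~within]], axis=1)
    n_neg = min(len(pos_pairs), len(neg_all))
    sel = rng.choice(len(neg_all), size=n_neg, replace=False)
    neg_pairs = neg_all[sel]
    pairs = np.concatenate([pos_pairs, neg_pairs], axis=0)
    labels = np.concatenate([np.ones(len(pos_pairs), dtype=int),
                             np.zeros(n_neg, dtype=int)])
    if flip_prob > 0:
        flips = rng.random(len(labels)) < flip_prob
        labels = np.where(flips, 1 - labels, labels)
    order = rng.permutation(len(labels))
    pair_labels = np.column_stack([pairs[order], labels[order]])

    return SyntheticCohort(
        n_drugs=n_drugs,
        cluster_assignment=clusters,
        modality_features=feats,
        informative_modality_index=0,
        context_labels=contexts,
        coprescription_counts=counts,
        pair_labels=pair_labels,
        seed=seed,
    )


def generate_molecular_toys(n_drugs: int, size_range=(5, 30),
                            seed: int = 0) -> list:
    """Random connected molecular graphs (spanning tree + extra edges)."""
    lo, hi = size_range
    if lo < 2:
        raise ValueError("minimum atom count must be >= 2")
    if hi < lo:
        raise ValueError("size_range must satisfy min <= max")
    rng = np.random.default_rng(seed)
    toys = []
    for d in range(n_drugs):
        n = int(rng.integers(lo, hi + 1))
        atoms = [(int(rng.integers(N_ATOM_TYPES)),
                  int(rng.integers(N_DEGREE_LABELS)),
                  int(rng.integers(2)),
                  int(rng.integers(N_CHARGE_LABELS)))
                 for _ in range(n)]
        edges = set()
        for v in range(1, n):               # random spanning tree
            u = int(rng.integers(v))
            edges.add((u, v))
        n_extra = int(rng.integers(0, max(1, n // 3) + 1))
        for _ in range(n_extra):
            u, v = rng.choice(n, size=2, replace=False)
            u, v = int(min(u, v)), int(max(u, v))
            edges.add((u, v))
        bonds = [(u, v, int(rng.integers(N_BOND_TYPES)))
                 for u, v in sorted(edges)]
        toys.append(MolecularGraphToy(drug_id=f"D{d:04d}",
                                      atom_labels=atoms, bond_list=bonds))
    return toys


_ELEMENT_INDEX = {"C": 0, "N": 1, "O": 2, "S": 3, "F": 4}  # others -> 5


def molecular_graph_from_smiles(drug_id: str, smiles: str) -> MolecularGraphToy:
    """Parse a SMILES string into the categorical atom/bond graph format.

    Requires RDKit (optional dependency).  Atom descriptors are coarsened
    to the same categorical ranges the synthetic toys use: element index
    (C/N/O/S/F/other), capped degree, aromatic flag, and formal charge
    mapped to {-1, 0, +1}.
    """
    from rdkit import Chem

    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparseable SMILES for {drug_id!r}: {smiles!r}")
    atoms = []
    for atom in mol.GetAtoms():
        atoms.append((
            _ELEMENT_INDEX.get(atom.GetSymbol(), N_ATOM_TYPES - 1),
            min(atom.GetDegree(), N_DEGREE_LABELS - 1),
            int(atom.GetIsAromatic()),
            int(np.clip(atom.GetFormalCharge(), -1, 1)) + 1,
        ))
    bonds = []
    for bond in mol.GetBonds():
        u, v = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        kind = str(bond.GetBondType())
        btype = {"SINGLE": 0, "DOUBLE": 1}.get(kind, 2)
        bonds.append((min(u, v), max(u, v), btype))
    return MolecularGraphToy(drug_id=drug_id, atom_labels=atoms,
                             bond_list=sorted(bonds))
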