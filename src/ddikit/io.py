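"""Readers and writers for the package's plain-text formats.

All tabular formats are tab-delimited UTF-8 with a header row and "." as
the decimal separator.  Drug ids are opaque strings; pair files store
unordered pairs with id_a < id_b lexicographically; internal indexing is
0-based.  Floats round-trip losslessly (written with repr precision).
"""

from __future__ import annotations

import datetime
import hashlib
import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .synthetic import MolecularGraphToy, SyntheticCohort

__all__ = [
    "RunManifest", "write_manifest",
    "write_matrix", "read_matrix", "write_edge_list",
    "write_cohort", "read_cohort",
    "write_pairs", "read_pairs", "write_predictions", "read_predictions",
    "write_molecular_toys", "read_molecular_toys", "write_smiles",
    "write_history", "write_metrics",
    "save_model_state", "load_model_state",
    "load_config", "dump_config",
]

FORMAT_VERSION = "ddikit-1"


@dataclass
class RunManifest:
    """Provenance record written next to every command's outputs."""

    command: str
    config: dict
    input_digests: dict
    seed: int | None
    version: str
    timestamp: str


def _digest(path: Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def write_manifest(out_dir, command: str, config: dict, inputs=(),
                   seed: int | None = None) -> Path:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        command=command, config=config,
        input_digests={str(p): _digest(p) for p in inputs},
        seed=seed, version=FORMAT_VERSION,
        timestamp=datetime.datetime.now(datetime.timezone.utc).isoformat())
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(asdict(manifest), indent=2, sort_keys=True))
    return path


# ---------------------------------------------------------------------
# matrices and edge lists
# ---------------------------------------------------------------------

def _check_finite(a: np.ndarray, what: str):
    if not np.isfinite(a).all():
        raise ValueError(f"refusing to write non-finite values in {what}")


def write_matrix(path, matrix: np.ndarray, drug_ids) -> Path:
    """Whole-matrix delimited text: first column = drug id."""
    m = np.asarray(matrix, dtype=np.float64)
    _check_finite(m, str(path))
    df = pd.DataFrame(m, columns=[f"c{i}" for i in range(m.shape[1])])
    df.insert(0, "drug_id", list(drug_ids))
    df.to_csv(path, sep="\t", index=False)
    return Path(path)


def read_matrix(path):
    """Returns (matrix, drug_ids)."""
    try:
        df = pd.read_csv(path, sep="\t", float_precision="round_trip")
        ids = df["drug_id"].astype(str).tolist()
        mat = df.drop(columns=["drug_id"]).to_numpy(dtype=np.float64)
    except (ValueError, KeyError) as exc:
        raise ValueError(f"{path}: malformed matrix table ({exc})") from exc
    return mat, ids


def write_edge_list(path, matrix: np.ndarray, drug_ids,
                    include_zeros: bool = False) -> Path:
    """Upper-triangle (id_a, id_b, weight) rows; id_a < id_b."""
    m = np.asarray(matrix, dtype=np.float64)
    _check_finite(m, str(path))
    ids = list(drug_ids)
    rows = []
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            if include_zeros or m[i, j] != 0:
                a, b = sorted((ids[i], ids[j]))
                rows.append((a, b, m[i, j]))
    pd.DataFrame(rows, columns=["id_a", "id_b", "weight"]).to_csv(
        path, sep="\t", index=False)
    return Path(path)


# ---------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------

def write_cohort(cohort: SyntheticCohort, out_dir) -> Path:
    """One numeric table per modality, a context table, a co-prescription
    table, a pair-label table, cluster ground truth and metadata."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ids = cohort.drug_ids
    for m, feats in enumerate(cohort.modality_features):
        write_matrix(out / f"modality_{m}.tsv", feats, ids)
    ctx_rows = [(ids[i], c) for i in range(cohort.n_drugs)
                for c in cohort.context_labels[i]]
    pd.DataFrame(ctx_rows, columns=["drug_id", "context_id"]).to_csv(
        out / "contexts.tsv", sep="\t", index=False)
    co_rows = []
    for i in range(cohort.n_drugs):
        for j in range(i + 1, cohort.n_drugs):
            c = int(cohort.coprescription_counts[i, j])
            if c:
                co_rows.append((ids[i], ids[j], c))
    pd.DataFrame(co_rows, columns=["id_a", "id_b", "count"]).to_csv(
        out / "coprescription.tsv", sep="\t", index=False)
    write_pairs(out / "pairs.tsv", cohort.pair_labels, ids)
    pd.DataFrame({"drug_id": ids,
                  "cluster": cohort.cluster_assignment}).to_csv(
        out / "clusters.tsv", sep="\t", index=False)
    meta = {"n_drugs": cohort.n_drugs,
            "n_modalities": cohort.n_modalities,
            "informative_modality_index": cohort.informative_modality_index,
            "seed": cohort.seed, "version": FORMAT_VERSION}
    (out / "cohort.json").write_text(json.dumps(meta, indent=2))
    return out


def read_cohort(in_dir) -> SyntheticCohort:
    src = Path(in_dir)
    meta = json.loads((src / "cohort.json").read_text())
    feats, ids = [], None
    for m in range(meta["n_modalities"]):
        mat, mids = read_matrix(src / f"modality_{m}.tsv")
        feats.append(mat)
        ids = mids if ids is None else ids
        if mids != ids:
            raise ValueError("modality tables disagree on drug ids")
    index = {d: i for i, d in enumerate(ids)}
    n = len(ids)
    contexts: list[list[int]] = [[] for _ in range(n)]
    for lineno, row in enumerate(
            pd.read_csv(src / "contexts.tsv", sep="\t").itertuples(), start=2):
        did = str(row.drug_id)
        if did not in index:
            raise ValueError(f"contexts.tsv line {lineno}: unknown drug id "
                             f"{did!r}")
        contexts[index[did]].append(int(row.context_id))
    counts = np.zeros((n, n), dtype=int)
    co = pd.read_csv(src / "coprescription.tsv", sep="\t")
    for lineno, row in enumerate(co.itertuples(), start=2):
        try:
            i, j = index[str(row.id_a)], index[str(row.id_b)]
            counts[i, j] = counts[j, i] = int(row.count)
        except (KeyError, ValueError) as exc:
            raise ValueError(
                f"coprescription.tsv line {lineno}: bad row ({exc})") from exc
    pair_labels = read_pairs(src / "pairs.tsv", ids)
    clusters = np.full(n, -1, dtype=int)
    cl_path = src / "clusters.tsv"
    if cl_path.exists():
        cl = pd.read_csv(cl_path, sep="\t")
        for _, row in cl.iterrows():
            clusters[index[str(row["drug_id"])]] = int(row["cluster"])
    return SyntheticCohort(
        n_drugs=n, cluster_assignment=clusters, modality_features=feats,
        informative_modality_index=meta["informative_modality_index"],
        context_labels=contexts, coprescription_counts=counts,
        pair_labels=pair_labels, seed=meta["seed"], drug_ids=ids)


def write_pairs(path, pair_labels: np.ndarray, drug_ids) -> Path:
    ids = list(drug_ids)
    rows = []
    for i, j, y in np.asarray(pair_labels, dtype=int):
        a, b = sorted((ids[i], ids[j]))
        rows.append((a, b, int(y)))
    pd.DataFrame(rows, columns=["id_a", "id_b", "label"]).to_csv(
        path, sep="\t", index=False)
    return Path(path)


def read_pairs(path, drug_ids) -> np.ndarray:
    index = {d: i for i, d in enumerate(drug_ids)}
    out = []
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:3] != ["id_a", "id_b", "label"]:
            raise ValueError(f"{path} line 1: expected header id_a/id_b/label")
        for lineno, line in enumerate(fh, start=2):
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 3:
                raise ValueError(f"{path} line {lineno}: expected 3 columns")
            a, b, lab = parts
            if a not in index or b not in index:
                raise ValueError(f"{path} line {lineno}: unknown drug id")
            if lab not in ("0", "1"):
                raise ValueError(f"{path} line {lineno}: label must be 0/1")
            out.append((index[a], index[b], int(lab)))
    return np.asarray(out, dtype=int)


def write_predictions(path, pairs: np.ndarray, scores: np.ndarray,
                      drug_ids) -> Path:
    ids = list(drug_ids)
    _check_finite(np.asarray(scores, float), str(path))
    rows = []
    for (i, j, y), s in zip(np.asarray(pairs, int), scores):
        a, b = sorted((ids[i], ids[j]))
        rows.append((a, b, int(y), float(s)))
    pd.DataFrame(rows, columns=["id_a", "id_b", "label", "score"]).to_csv(
        path, sep="\t", index=False)
    return Path(path)


def read_predictions(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = {"id_a", "id_b", "label", "score"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return df


# ---------------------------------------------------------------------
# molecular toys / SMILES
# ---------------------------------------------------------------------

def write_molecular_toys(path, toys) -> Path:
    """Edge-list text with atom-attribute header lines per molecule."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# {FORMAT_VERSION} molecular toys\n")
        for toy in toys:
            fh.write(f"M\t{toy.drug_id}\t{toy.n_atoms}\t{len(toy.bond_list)}\n")
            for t, d, ar, ch in toy.atom_labels:
                fh.write(f"A\t{t}\t{d}\t{ar}\t{ch}\n")
            for u, v, b in toy.bond_list:
                fh.write(f"B\t{u}\t{v}\t{b}\n")
    return Path(path)


def read_molecular_toys(path):
    toys = []
    with open(path, encoding="utf-8") as fh:
        atoms, bonds, drug_id, want_a, want_b = [], [], None, 0, 0
        for lineno, line in enumerate(fh, start=1):
            if line.startswith("#") or not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            tag = parts[0]
            try:
                if tag == "M":
                    if drug_id is not None:
                        toys.append(MolecularGraphToy(drug_id, atoms, bonds))
                    drug_id, want_a, want_b = parts[1], int(parts[2]), int(parts[3])
                    atoms, bonds = [], []
                elif tag == "A":
                    atoms.append(tuple(int(x) for x in parts[1:5]))
                elif tag == "B":
                    bonds.append(tuple(int(x) for x in parts[1:4]))
                else:
                    raise ValueError(f"unknown record tag {tag!r}")
            except (IndexError, ValueError) as exc:
                raise ValueError(f"{path} line {lineno}: {exc}") from exc
        if drug_id is not None:
            toys.append(MolecularGraphToy(drug_id, atoms, bonds))
    return toys


def write_smiles(path, entries) -> Path:
    """One "ID<TAB>SMILES" per line; '#' comments allowed."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# id\tsmiles\n")
        for drug_id, smi in entries:
            fh.write(f"{drug_id}\t{smi}\n")
    return Path(path)


def read_smiles(path) -> list:
    """Read (id, smiles) tuples; '#'-prefixed lines are comments."""
    entries = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path} line {lineno}: expected "
                                 "ID<TAB>SMILES")
            entries.append((parts[0], parts[1]))
    return entries


# ---------------------------------------------------------------------
# training artefacts
# ---------------------------------------------------------------------

def write_history(path, history: list) -> Path:
    pd.DataFrame(history).to_csv(path, sep="\t", index=False)
    return Path(path)


def write_metrics(path, metrics: dict) -> Path:
    Path(path).write_text(json.dumps(metrics, indent=2, sort_keys=True))
    return Path(path)


def save_model_state(path, state: dict, config: dict) -> Path:
    """Single binary container (npz) with a version tag."""
    np.savez(path, __version__=np.array(FORMAT_VERSION),
             __config__=np.array(json.dumps(config)), **state)
    return Path(path)


def load_model_state(path):
    with np.load(path, allow_pickle=False) as data:
        version = str(data["__version__"])
        if version != FORMAT_VERSION:
            raise ValueError(f"unsupported model container version {version}")
        config = json.loads(str(data["__config__"]))
        state = {k: data[k] for k in data.files
                 if k not in ("__version__", "__config__")}
    return state, config


def load_config(path) -> dict:
    with open(path, encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return cfg


def dump_config(path, config: dict) -> Path:
    Path(path).write_text(yaml.safe_dump(config, sort_keys=True))
    return Path(path)
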