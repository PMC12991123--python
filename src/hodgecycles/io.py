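"""File formats: delimited matrices, array stacks, phenotype tables, ROI
label tables, sparse cycle-basis triplets, results tables and run manifests.

All formats round-trip losslessly (to float64 text precision where text is
used) and validate their headers; errors name the offending column, subject
or file.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .profiling import NetworkLabels
from .topology import CycleBasis

__all__ = [
    "read_matrix",
    "write_matrix",
    "read_array_stack",
    "write_array_stack",
    "read_phenotype",
    "write_phenotype",
    "read_labels",
    "write_labels",
    "read_basis",
    "write_basis",
    "write_manifest",
    "write_cohort",
]

PHENOTYPE_REQUIRED = ("subject", "group", "age", "sex", "fd", "site")


def read_matrix(path: str | Path) -> np.ndarray:
    """Read a delimited numeric matrix (comma/tab/whitespace autodetected,
    optional header row of node ids)."""
    path = Path(path)
    df = pd.read_csv(path, sep=None, engine="python", header=None)
    first = df.iloc[0]
    if first.map(lambda v: isinstance(v, str)).any():
        df = df.iloc[1:].reset_index(drop=True)
    try:
        return df.to_numpy(dtype=float)
    except ValueError as exc:
        raise ValueError(f"non-numeric data in matrix file {path}: {exc}") from exc


def write_matrix(M: np.ndarray, path: str | Path, delimiter: str = "\t") -> None:
    np.savetxt(path, np.asarray(M), delimiter=delimiter, fmt="%.17g")


def read_array_stack(path: str | Path) -> tuple[np.ndarray, list[str]]:
    """Read a binary array stack (.npz with ``data`` and ``subjects``)."""
    with np.load(path, allow_pickle=False) as z:
        if "data" not in z or "subjects" not in z:
            raise ValueError(f"array stack {path} must contain 'data' and 'subjects'")
        return z["data"], [str(s) for s in z["subjects"]]


def write_array_stack(
    data: np.ndarray, subjects: list[str], path: str | Path
) -> None:
    np.savez_compressed(path, data=np.asarray(data), subjects=np.asarray(subjects))


def read_phenotype(path: str | Path) -> pd.DataFrame:
    """Read and validate the phenotype CSV (subject, group, age, sex, fd,
    site)."""
    df = pd.read_csv(path)
    missing = [c for c in PHENOTYPE_REQUIRED if c not in df.columns]
    if missing:
        raise ValueError(f"phenotype file {path} missing column(s): {missing}")
    if df["subject"].duplicated().any():
        dupes = df.loc[df["subject"].duplicated(), "subject"].tolist()
        raise ValueError(f"duplicate subject id(s) in {path}: {dupes[:5]}")
    return df


def write_phenotype(df: pd.DataFrame, path: str | Path) -> None:
    missing = [c for c in PHENOTYPE_REQUIRED if c not in df.columns]
    if missing:
        raise ValueError(f"phenotype table missing column(s): {missing}")
    df.to_csv(path, index=False)


def read_labels(path: str | Path) -> NetworkLabels:
    """Read the ROI label table (TSV with columns ``node`` and ``network``),
    returning labels in node order."""
    df = pd.read_csv(path, sep="\t")
    for col in ("node", "network"):
        if col not in df.columns:
            raise ValueError(f"label table {path} missing column {col!r}")
    df = df.sort_values("node")
    expected = np.arange(len(df))
    if not np.array_equal(df["node"].to_numpy(), expected):
        raise ValueError(f"label table {path} must label nodes 0..{len(df) - 1}")
    return NetworkLabels(labels=tuple(df["network"].astype(str)))


def write_labels(labels: NetworkLabels, path: str | Path) -> None:
    pd.DataFrame(
        {"node": np.arange(len(labels.labels)), "network": labels.labels}
    ).to_csv(path, sep="\t", index=False)


def write_basis(basis: CycleBasis, triplet_path: str | Path, header_path: str | Path) -> None:
    """Serialize a cycle basis as sparse triplets (cycle, edge, coeff) plus
    a JSON header recording shape, convention and closing edges."""
    coo = basis.phi.tocoo()
    df = pd.DataFrame({"cycle": coo.row, "edge": coo.col, "coeff": coo.data})
    df.to_csv(triplet_path, sep="\t", index=False, float_format="%.17g")
    header = {
        "n": basis.n,
        "m": basis.m,
        "q": basis.q,
        "edge_order": "lexicographic-upper-triangular-0-based",
        "closing_edges": basis.closing_edges.tolist(),
    }
    Path(header_path).write_text(json.dumps(header))


def read_basis(triplet_path: str | Path, header_path: str | Path) -> CycleBasis:
    header = json.loads(Path(header_path).read_text())
    df = pd.read_csv(triplet_path, sep="\t")
    phi = sp.csr_matrix(
        (df["coeff"], (df["cycle"], df["edge"])), shape=(header["q"], header["m"])
    )
    return CycleBasis(
        phi=phi,
        closing_edges=np.asarray(header["closing_edges"], dtype=np.int64),
        n=header["n"],
        m=header["m"],
    )


def write_manifest(manifest: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(manifest, indent=2, default=str))


def write_cohort(cohort, out_dir: str | Path, fmt: str = "tsv") -> None:
    """Write a synthetic cohort: one FC matrix file per subject (or one
    array stack), the phenotype CSV and the ground-truth JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    subjects = cohort.phenotype["subject"].tolist()
    if fmt == "npz":
        write_array_stack(cohort.fc_matrices, subjects, out / "fc_stack.npz")
    elif fmt == "tsv":
        fc_dir = out / "fc"
        fc_dir.mkdir(exist_ok=True)
        for sub, M in zip(subjects, cohort.fc_matrices):
            write_matrix(M, fc_dir / f"{sub}.tsv")
    else:
        raise ValueError(f"unknown cohort format {fmt!r}")
    write_phenotype(cohort.phenotype, out / "phenotype.csv")
    write_labels(NetworkLabels(labels=cohort.labels), out / "labels.tsv")
    Path(out / "truth.json").write_text(json.dumps(cohort.truth))
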