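"""Delimited-text I/O for datasets, truth records and chains.

Matrices are header-bearing CSV; response times are stored in seconds at
rest for readability and log-transformed on ingest. All validation errors
name the offending row/column.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .mcmc import PosteriorResult
from .model import Dataset, QMatrix, UMatrix
from .simulate import TruthRecord

__all__ = [
    "read_dataset",
    "write_dataset",
    "read_truth",
    "write_truth",
    "draws_table",
    "write_manifest",
]


def _read_matrix(path: Path, name: str) -> np.ndarray:
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ValueError(f"could not parse {name} file {path}: {exc}") from exc
    return df.to_numpy()


def read_dataset(
    y_path, t_path, q_path, u_path, allow_multi_testlet: bool = False
) -> Dataset:
    """Load and validate a paired dataset from four CSV files.

    ``t_path`` holds response times in seconds; they are log-transformed on
    ingest. Y, Q and U must be strictly binary; times strictly positive.
    """
    y = _read_matrix(Path(y_path), "Y")
    t = _read_matrix(Path(t_path), "T")
    q = _read_matrix(Path(q_path), "Q")
    u = _read_matrix(Path(u_path), "U")
    bad = ~np.isin(y, (0, 1))
    if bad.any():
        r, c = np.argwhere(bad)[0]
        raise ValueError(f"non-binary response at Y row {r}, column {c}")
    if y.shape != t.shape:
        raise ValueError(f"Y shape {y.shape} does not match T shape {t.shape}")
    nonpos = ~(np.asarray(t, dtype=float) > 0)
    if nonpos.any():
        r, c = np.argwhere(nonpos)[0]
        raise ValueError(f"non-positive response time at T row {r}, column {c}")
    if q.shape[0] != y.shape[1]:
        raise ValueError(
            f"Q has {q.shape[0]} item rows but Y has {y.shape[1]} item columns")
    if u.shape[0] != y.shape[1]:
        raise ValueError(
            f"U has {u.shape[0]} item rows but Y has {y.shape[1]} item columns")
    return Dataset(
        Y=y.astype(np.int8),
        logT=np.log(t.astype(float)),
        Q=QMatrix(q),
        U=UMatrix(u, allow_multi_testlet=allow_multi_testlet),
    )


def write_dataset(data: Dataset, out_dir) -> dict[str, Path]:
    """Write Y/T/Q/U as CSV under ``out_dir``; times stored in seconds."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    I = data.n_items
    paths = {}
    item_cols = [f"item_{i+1}" for i in range(I)]
    paths["Y"] = out / "Y.csv"
    pd.DataFrame(data.Y, columns=item_cols).to_csv(paths["Y"], index=False)
    paths["T"] = out / "T.csv"
    pd.DataFrame(np.exp(data.logT), columns=item_cols).to_csv(paths["T"], index=False)
    paths["Q"] = out / "Q.csv"
    pd.DataFrame(data.Q.entries,
                 columns=[f"attr_{k+1}" for k in range(data.Q.n_attributes)]
                 ).to_csv(paths["Q"], index=False)
    paths["U"] = out / "U.csv"
    pd.DataFrame(data.U.entries,
                 columns=[f"testlet_{m+1}" for m in range(data.U.n_testlets)]
                 ).to_csv(paths["U"], index=False)
    return paths


def write_truth(truth: TruthRecord, path) -> Path:
    path = Path(path)
    path.write_text(truth.to_json())
    return path


def read_truth(path) -> TruthRecord:
    return TruthRecord.from_json(Path(path).read_text())


def draws_table(result: PosteriorResult,
                names: tuple[str, ...] | None = None) -> pd.DataFrame:
    """Rectangular draws table: one row per retained draw, labelled columns.

    Suitable for standard MCMC-diagnostic tooling. Person-level blocks are
    excluded by default (they dominate the column count).
    """
    if names is None:
        names = tuple(n for n in result.draws
                      if n not in ("alpha", "theta", "tau", "gamma", "lam"))
    cols = {}
    n_chains = result.deviance.shape[0]
    n_draws = result.deviance.shape[1]
    cols["chain"] = np.repeat(np.arange(n_chains), n_draws)
    cols["draw"] = np.tile(np.arange(n_draws), n_chains)
    for name in names:
        d = result.draws[name]
        flat = d.reshape(n_chains * n_draws, -1)
        if flat.shape[1] == 1:
            cols[name] = flat[:, 0]
        else:
            for j in range(flat.shape[1]):
                cols[f"{name}[{j}]"] = flat[:, j]
    cols["deviance"] = result.deviance.reshape(-1)
    return pd.DataFrame(cols)


def write_manifest(path, seed: int, command: str, options: dict) -> Path:
    """Reproducibility manifest: seed, command, options, package version."""
    from . import __version__

    path = Path(path)
    payload = {
        "package": "jtdina",
        "version": __version__,
        "command": command,
        "seed": seed,
        "options": options,
    }
    path.write_text(json.dumps(payload, indent=1, sort_keys=True))
    return path
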