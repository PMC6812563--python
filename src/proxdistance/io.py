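"""File formats and result serialization for the command-line interface.

Dense matrices and vectors travel as delimited text (TSV/CSV, 17 significant
digits so round-trips are bit-faithful); sparse matrices as MatrixMarket.
Results are written as JSON with the run configuration echoed verbatim, plus
an optional per-iteration TSV trace.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import scipy.io
import scipy.sparse as sp

__all__ = ["RunConfig", "read_matrix", "read_vector", "write_matrix", "write_result"]


@dataclass
class RunConfig:
    """Fully serializable description of one solver run."""

    solver: str
    instance: dict = field(default_factory=dict)
    rho_init: float = 1.0
    rho_factor: float = 2.0
    rho_period: int = 100
    rho_cap: float = float(2**22)
    eps_loss: float = 1e-6
    eps_dist: float = 1e-4
    max_iter: int = 5000
    accelerate: bool = True
    seed: int | None = None
    backend: str | None = None
    output: str | None = None
    trace: str | None = None
    verbosity: int = 0
    options: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _parse_delimited(path: Path) -> np.ndarray:
    rows: list[list[float]] = []
    width = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith("#"):
                continue
            delim = "," if "," in stripped else None
            fields = [f for f in stripped.split(delim) if f != ""]
            try:
                row = [float(f) for f in fields]
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-numeric cell ({exc})") from None
            if width is None:
                width = len(row)
            elif len(row) != width:
                raise ValueError(
                    f"{path}:{lineno}: ragged row has {len(row)} cells, expected {width}"
                )
            rows.append(row)
    if not rows:
        raise ValueError(f"{path}: no numeric data found")
    return np.asarray(rows, dtype=float)


def read_matrix(path: str | Path, format: str | None = None, symmetric: bool = False):
    """Read a matrix: dense from delimited text, sparse from MatrixMarket.

    ``format`` is inferred from the extension when omitted (``.mtx`` →
    MatrixMarket).  With ``symmetric=True`` the matrix is validated square and
    symmetrized to within 1e−10.
    """
    path = Path(path)
    if format is None:
        format = "mtx" if path.suffix.lower() == ".mtx" else "delimited"
    if format == "mtx":
        M = scipy.io.mmread(path)
        M = sp.csr_matrix(M)
    elif format == "delimited":
        M = _parse_delimited(path)
    else:
        raise ValueError(f"unknown matrix format {format!r}")
    if symmetric:
        if M.shape[0] != M.shape[1]:
            raise ValueError(f"{path}: expected a square matrix, got {M.shape}")
        D = M.toarray() if sp.issparse(M) else M
        if np.max(np.abs(D - D.T)) > 1e-10:
            raise ValueError(f"{path}: matrix is not symmetric to 1e-10")
        M = 0.5 * (D + D.T)
    return M


def read_labeled_matrix(path: str | Path) -> tuple[np.ndarray, list[str] | None]:
    """Read a square matrix whose first row may be a header of sample IDs.

    Returns ``(matrix, ids)`` with ``ids=None`` when no header is present.
    Used for kinship candidates, where the IDs are mirrored into the result.
    """
    path = Path(path)
    with open(path) as fh:
        first = ""
        for line in fh:
            if line.strip() and not line.lstrip().startswith("#"):
                first = line.strip()
                break
    delim = "," if "," in first else None
    fields = [f for f in first.split(delim) if f != ""]
    try:
        [float(f) for f in fields]
        ids = None
        data = _parse_delimited(path)
    except ValueError:
        ids = fields
        rows = path.read_text().splitlines()
        body = "\n".join(
            r for r in rows if r.strip() and not r.lstrip().startswith("#")
        ).split("\n")[1:]
        tmp = path.with_suffix(path.suffix + ".body")
        try:
            tmp.write_text("\n".join(body) + "\n")
            data = _parse_delimited(tmp)
        finally:
            tmp.unlink(missing_ok=True)
        if len(ids) != data.shape[1]:
            raise ValueError(
                f"{path}: header has {len(ids)} ids but matrix has {data.shape[1]} columns"
            )
    return data, ids


def read_vector(path: str | Path) -> np.ndarray:
    """Read a vector from single-column (or single-row) delimited text."""
    arr = _parse_delimited(Path(path))
    if 1 not in arr.shape and arr.ndim == 2:
        raise ValueError(f"{path}: expected a vector, got shape {arr.shape}")
    return arr.ravel()


def write_matrix(M, path: str | Path) -> None:
    """Write a matrix: MatrixMarket when sparse or .mtx, else delimited TSV
    with 17 significant digits."""
    path = Path(path)
    if sp.issparse(M) or path.suffix.lower() == ".mtx":
        # mmwrite appends .mtx itself when the suffix is missing
        scipy.io.mmwrite(str(path), sp.coo_matrix(M))
        return
    np.savetxt(path, np.atleast_2d(M), fmt="%.17g", delimiter="\t")


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def write_result(result, path: str | Path, config: RunConfig | None = None) -> None:
    """Serialize a SolveResult or SPCAResult to JSON (config echoed)."""
    payload: dict = {}
    if hasattr(result, "solution"):
        payload.update(
            {
                "solution": _jsonable(result.solution),
                "loss": result.loss_value,
                "penalized_loss": result.penalized_value,
                "constraint_distance": result.constraint_distance,
                "iterations": result.iterations,
                "converged": result.converged,
                "message": result.message,
                "extras": _jsonable({k: v for k, v in result.extras.items()}),
            }
        )
    elif hasattr(result, "U"):  # SPCA
        payload.update(
            {
                "loadings": _jsonable(result.U),
                "pve": result.pve,
                "objective": result.objective,
                "iterations": result.iterations,
                "converged": result.converged,
                "nnz_per_column": result.extras.get("nnz_per_column"),
            }
        )
    elif hasattr(result, "index"):  # copositivity
        payload.update(
            {
                "index": result.index,
                "argmin": _jsonable(result.argmin),
                "per_start": _jsonable(result.per_start),
            }
        )
    else:
        raise TypeError(f"cannot serialize result of type {type(result)!r}")
    if config is not None:
        payload["config"] = _jsonable(config.to_dict())
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
        fh.write("\n")
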