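"""Delimited-matrix round-tripping and model (de)serialization.

Matrices are stored as delimited numeric text with rows = features / labels
/ clusters and columns = time points (a ``--transpose`` flag on the CLI
accommodates samples-as-rows files).  Models are stored as a single
human-readable JSON document that round-trips to full float precision.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
from numpy.typing import ArrayLike, NDArray

from .learning import FittedModel
from .model_core import GaussianCentroids, HyperParams, LossBreakdown, feasibility_errors

__all__ = ["read_matrix", "write_matrix", "save_model", "load_model"]


class MatrixParseError(ValueError):
    """A delimited matrix file could not be parsed."""


def _detect_delimiter(line: str) -> str:
    return "\t" if line.count("\t") >= line.count(",") and "\t" in line else ","


def read_matrix(
    path: str | Path,
    expect_stochastic_columns: bool = False,
    header: bool = False,
) -> NDArray[np.float64]:
    """Parse a comma- or tab-delimited numeric matrix (delimiter autodetected).

    With ``header`` the first line is skipped.  Ragged or non-numeric input
    raises :class:`MatrixParseError` naming the offending row and column;
    with ``expect_stochastic_columns`` the columns must each sum to one.
    """
    path = Path(path)
    lines = [ln for ln in path.read_text().splitlines() if ln.strip()]
    if header:
        lines = lines[1:]
    if not lines:
        raise MatrixParseError(f"{path}: no data rows")
    delim = _detect_delimiter(lines[0])
    rows: list[list[float]] = []
    width = None
    for i, ln in enumerate(lines, start=1):
        fields = [f.strip() for f in ln.split(delim)]
        if width is None:
            width = len(fields)
        elif len(fields) != width:
            raise MatrixParseError(
                f"{path}: row {i} has {len(fields)} fields, expected {width}"
            )
        row = []
        for j, f in enumerate(fields, start=1):
            try:
                row.append(float(f))
            except ValueError:
                raise MatrixParseError(
                    f"{path}: non-numeric value {f!r} at row {i}, column {j}"
                ) from None
        rows.append(row)
    M = np.asarray(rows, dtype=float)
    if expect_stochastic_columns:
        errs = feasibility_errors(M, tol=1e-6)
        if errs:
            raise MatrixParseError(f"{path}: not column-stochastic: " + "; ".join(errs))
    return M


def write_matrix(path: str | Path, M: ArrayLike, delimiter: str = "\t") -> None:
    """Write a matrix as delimited text at full float precision."""
    M = np.atleast_2d(np.asarray(M, dtype=float))
    with open(path, "w") as fh:
        for row in M:
            fh.write(delimiter.join(repr(float(v)) for v in row) + "\n")


def save_model(path: str | Path, model: FittedModel) -> None:
    """Serialize a fitted model to human-readable JSON (full precision)."""
    doc = {
        "format": "espamarkov-model",
        "version": 1,
        "hyperparameters": {
            "eps_L": model.hp.eps_L,
            "eps_E": model.hp.eps_E,
            "eps_CL": model.hp.eps_CL,
            "K": int(model.hp.K),
        },
        "mu": model.theta.mu.tolist(),
        "sigma": model.theta.sigma.tolist(),
        "lambda": model.lam.tolist(),
        "W": model.W.tolist(),
        "P": model.P.tolist(),
        "loss": {
            "likelihood_term": model.loss.likelihood_term,
            "entropy_term": model.loss.entropy_term,
            "classification_term": model.loss.classification_term,
            "markov_term": model.loss.markov_term,
            "total": model.loss.total,
        },
        "loss_trace": model.loss_trace,
        "iterations": model.iterations,
        "n_starts": model.n_starts,
        "seed": model.seed,
        "feature_stats": None
        if model.feature_stats is None
        else {
            "mean": model.feature_stats[0].ravel().tolist(),
            "sd": model.feature_stats[1].ravel().tolist(),
        },
    }
    Path(path).write_text(json.dumps(doc, indent=1) + "\n")


def load_model(path: str | Path) -> FittedModel:
    """Load a model written by :func:`save_model` (loss-identical round trip)."""
    doc = json.loads(Path(path).read_text())
    if doc.get("format") != "espamarkov-model":
        raise ValueError(f"{path}: not an espamarkov model file")
    hp = HyperParams(**doc["hyperparameters"])
    loss = LossBreakdown(**doc["loss"])
    stats = doc.get("feature_stats")
    return FittedModel(
        theta=GaussianCentroids(np.asarray(doc["mu"]), np.asarray(doc["sigma"])),
        lam=np.asarray(doc["lambda"], dtype=float),
        W=np.asarray(doc["W"], dtype=float),
        P=np.asarray(doc["P"], dtype=float),
        hp=hp,
        loss=loss,
        gamma_train=np.zeros((hp.K, 0)),
        loss_trace=list(doc.get("loss_trace", [])),
        iterations=int(doc.get("iterations", 0)),
        n_starts=int(doc.get("n_starts", 1)),
        seed=doc.get("seed"),
        feature_stats=None
        if stats is None
        else (
            np.asarray(stats["mean"], dtype=float).reshape(-1, 1),
            np.asarray(stats["sd"], dtype=float).reshape(-1, 1),
        ),
    )
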