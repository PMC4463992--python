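"""Fitting the nine combination weights by back-propagation.

The overall similarity is an intercept-free linear form in the nine
parameter similarities, so the default trainer is a single linear output
unit without bias, trained full-batch by gradient descent on mean squared
error — the simplest network whose converged weights are exactly the
published combination rule's coefficients.  A one-hidden-layer variant
(linear activations, trained by back-propagation through both layers) is
available; its two weight matrices collapse to an equivalent nine-weight
linear map, which is what gets returned.

Training tables are plain TSV with a header row ``S1..S9  S``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from shellsim.similarity import WeightVector

__all__ = [
    "TrainingPair",
    "TrainingConfig",
    "TrainingDivergedError",
    "train_weights",
    "evaluate_weights",
    "read_training_table",
    "write_training_table",
    "read_weights_file",
    "write_weights_file",
]

TRAINING_COLUMNS = ["S1", "S2", "S3", "S4", "S5", "S6", "S7", "S8", "S9", "S"]


class TrainingDivergedError(RuntimeError):
    """Raised when the loss becomes non-finite (learning rate too large)."""


@dataclass(frozen=True)
class TrainingPair:
    """One labelled pair: nine feature similarities and an overall label."""

    features: tuple[float, ...]
    label: float

    def __post_init__(self) -> None:
        if len(self.features) != 9:
            raise ValueError(f"expected 9 features, got {len(self.features)}")
        if not (np.all(np.isfinite(self.features)) and np.isfinite(self.label)):
            raise ValueError("features and label must be finite")


@dataclass(frozen=True)
class TrainingConfig:
    learning_rate: float = 0.2
    epochs: int = 50_000
    seed: int = 0
    architecture: str = "linear"  # "linear" | "one-hidden-layer"
    hidden_units: int = 6
    tolerance: float = 1e-13  # stop when the epoch loss decrease falls below this

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning rate must be positive")
        if self.epochs < 1:
            raise ValueError("epoch count must be at least 1")
        if self.architecture not in ("linear", "one-hidden-layer"):
            raise ValueError(f"unknown architecture {self.architecture!r}")


def _as_matrices(pairs: Sequence[TrainingPair]) -> tuple[np.ndarray, np.ndarray]:
    X = np.array([p.features for p in pairs], dtype=float)
    y = np.array([p.label for p in pairs], dtype=float)
    return X, y


def train_weights(
    pairs: Sequence[TrainingPair], cfg: TrainingConfig = TrainingConfig()
) -> tuple[WeightVector, dict]:
    """Fit the nine weights by full-batch gradient descent on squared error.

    Deterministic given ``cfg.seed`` (the seed only matters for the
    hidden-layer initialisation; the linear model starts at zero).  Returns
    the fitted :class:`WeightVector` and a diagnostics dict with the final
    loss, the number of epochs run, and the loss trajectory endpoints.

    Raises
    ------
    ValueError
        On an empty training set.
    TrainingDivergedError
        If the loss becomes non-finite, naming the epoch.
    """
    if len(pairs) == 0:
        raise ValueError("training set is empty")
    X, y = _as_matrices(pairs)
    n = len(pairs)
    rng = np.random.default_rng(cfg.seed)

    if cfg.architecture == "linear":
        w = np.zeros(9)
        W1 = W2 = None
    else:
        # small random init; linear activations, so the composition is linear
        W1 = rng.normal(scale=0.3, size=(cfg.hidden_units, 9))
        W2 = rng.normal(scale=0.3, size=(1, cfg.hidden_units))
        w = (W2 @ W1).ravel()

    prev_loss = np.inf
    epochs_run = 0
    for epoch in range(cfg.epochs):
        with np.errstate(over="ignore", invalid="ignore"):
            pred = X @ w
            resid = pred - y
            loss = float(np.mean(resid**2))
        if not np.isfinite(loss):
            raise TrainingDivergedError(
                f"training loss became non-finite at epoch {epoch}; lower the learning rate"
            )
        if 0 <= prev_loss - loss < cfg.tolerance and epoch > 0:
            epochs_run = epoch
            break
        prev_loss = loss
        grad_out = (2.0 / n) * (X.T @ resid)  # dL/dw for the composite linear map
        if cfg.architecture == "linear":
            w = w - cfg.learning_rate * grad_out
        else:
            # back-propagate through both linear layers
            H = X @ W1.T  # (n, hidden)
            dW2 = (2.0 / n) * (resid[None, :] @ H)  # (1, hidden)
            dW1 = (2.0 / n) * (W2.T @ resid[None, :]) @ X  # (hidden, 9)
            W2 = W2 - cfg.learning_rate * dW2
            W1 = W1 - cfg.learning_rate * dW1
            w = (W2 @ W1).ravel()
        epochs_run = epoch + 1

    final_loss = float(np.mean((X @ w - y) ** 2))
    diagnostics = {
        "final_loss": final_loss,
        "final_rmse": float(np.sqrt(final_loss)),
        "epochs_run": epochs_run,
        "architecture": cfg.architecture,
        "n_pairs": n,
    }
    return WeightVector.from_array(w), diagnostics


def evaluate_weights(w: WeightVector, pairs: Sequence[TrainingPair]) -> float:
    """Root-mean-squared prediction error of the dot-product model."""
    if len(pairs) == 0:
        raise ValueError("no pairs to evaluate")
    X, y = _as_matrices(pairs)
    return float(np.sqrt(np.mean((X @ w.as_array() - y) ** 2)))


# --- table and weight-file I/O -------------------------------------------

def write_training_table(pairs: Iterable[TrainingPair], path: str | Path) -> Path:
    path = Path(path)
    df = pd.DataFrame(
        [list(p.features) + [p.label] for p in pairs], columns=TRAINING_COLUMNS
    )
    df.to_csv(path, sep="\t", index=False)
    return path

def read_training_table(path: str | Path) -> list[TrainingPair]:
    """Read a 10-column TSV (S1..S9, S) into training pairs."""
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t")
    except Exception as exc:  # pandas raises several parse error types
        raise ValueError(f"cannot parse training table {path}: {exc}") from exc
    missing = [c for c in TRAINING_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    pairs = []
    for i, row in df.iterrows():
        try:
            pairs.append(
                TrainingPair(
                    features=tuple(float(row[c]) for c in TRAINING_COLUMNS[:9]),
                    label=float(row["S"]),
                )
            )
        except (TypeError, ValueError) as exc:
            raise ValueError(f"{path}: bad row at line {i + 2}: {exc}") from exc
    return pairs

def write_weights_file(w: WeightVector, path: str | Path) -> Path:
    path = Path(path)
    lines = [f"Q{i + 1}\t{v:.10g}" for i, v in enumerate(w.as_array())]
    path.write_text("\n".join(lines) + "\n")
    return path

def read_weights_file(path: str | Path) -> WeightVector:
    """Read a two-column key/value weights file (Q1..Q9)."""
    path = Path(path)
    values: dict[str, float] = {}
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.replace(":", "\t").split()
        if len(parts) != 2:
            raise ValueError(f"{path}:{lineno}: expected 'Qi value', got {line!r}")
        values[parts[0].upper()] = float(parts[1])
    try:
        return WeightVector.from_array([values[f"Q{i}"] for i in range(1, 10)])
    except KeyError as exc:
        raise ValueError(f"{path}: missing weight {exc}") from exc
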