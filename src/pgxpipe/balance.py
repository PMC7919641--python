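"""Synthetic minority oversampling with majority undersampling (SMOTE).

For each minority-class point, ``perc_over/100`` synthetic points are placed
uniformly at random on the segment towards one of its k nearest minority
neighbours; binary columns copy either the parent or the neighbour. The
majority class is then downsampled to ``perc_under/100`` times the number of
synthetic points. Counts obey the closed forms

    n_synthetic = round(n_minority * perc_over / 100)
    n_majority_kept = round(perc_under / 100 * n_synthetic)

exactly (the latter capped at the available majority, with a warning).
Provenance (parent and neighbour row of every synthetic point) is retained
so that resampling harnesses can prove no leakage across fold boundaries.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd


@dataclass
class SmoteConfig:
    k_neighbors: int = 5
    perc_over: float = 200.0
    perc_under: float = 200.0
    standardize: bool = False

    def validate(self) -> None:
        if self.k_neighbors < 1:
            raise ValueError("k_neighbors must be >= 1")
        if self.perc_over < 100:
            raise ValueError("perc_over uses >= 100 step semantics")
        if self.perc_under < 0:
            raise ValueError("perc_under must be non-negative")


@dataclass
class SmoteResult:
    """Balanced design matrix plus full provenance of every output row."""

    X: np.ndarray
    y: np.ndarray
    #: original row index of each retained minority point
    minority_rows: np.ndarray
    #: original row index of each retained (downsampled) majority point
    majority_rows: np.ndarray
    #: per synthetic point: original row index of its parent
    synthetic_parent: np.ndarray
    #: per synthetic point: original row index of the interpolation neighbour
    synthetic_neighbor: np.ndarray
    #: per synthetic point: interpolation coefficient u in [0, 1)
    synthetic_u: np.ndarray
    columns: list[str] | None = None
    binary_mask: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=bool))

    @property
    def source_rows(self) -> np.ndarray:
        """Every original row that influenced the balanced sample."""
        return np.unique(
            np.concatenate(
                [
                    self.minority_rows,
                    self.majority_rows,
                    self.synthetic_parent,
                    self.synthetic_neighbor,
                ]
            )
        )

    def frame(self) -> pd.DataFrame:
        cols = self.columns or [f"x{i}" for i in range(self.X.shape[1])]
        out = pd.DataFrame(self.X, columns=cols)
        out["label"] = self.y
        return out


def detect_binary_columns(X: np.ndarray) -> np.ndarray:
    """Mask of columns whose observed values are a subset of {0, 1}."""
    mask = np.zeros(X.shape[1], dtype=bool)
    for j in range(X.shape[1]):
        vals = np.unique(X[:, j])
        mask[j] = np.isin(vals, (0.0, 1.0)).all()
    return mask


def nearest_minority_neighbors(
    X_min: np.ndarray, k: int, scale: np.ndarray | None = None
) -> np.ndarray:
    """Indices (into X_min) of each minority point's k nearest minority
    neighbours, self excluded; Euclidean distance, ties broken by lowest row
    index."""
    n = len(X_min)
    if n < 2:
        return np.zeros((n, 0), dtype=np.int64)
    Z = X_min if scale is None else X_min / scale
    d2 = ((Z[:, None, :] - Z[None, :, :]) ** 2).sum(axis=2)
    np.fill_diagonal(d2, np.inf)
    k_eff = min(k, n - 1)
    order = np.lexsort((np.broadcast_to(np.arange(n), (n, n)), d2), axis=1)
    return order[:, :k_eff].astype(np.int64)


def smote_sample(
    X: np.ndarray | pd.DataFrame,
    y: Sequence,
    config: SmoteConfig | None = None,
    seed: int | np.random.Generator = 0,
    binary_columns: Sequence[str] | np.ndarray | None = None,
) -> SmoteResult:
    """Balance a two-class dataset by SMOTE oversampling + undersampling.

    Rows of the result are ordered: original minority, synthetic minority,
    downsampled majority. Deterministic given ``seed``.
    """
    config = config or SmoteConfig()
    config.validate()

    columns = list(X.columns) if isinstance(X, pd.DataFrame) else None
    Xa = np.asarray(X, dtype=float)
    ya = np.asarray(y)
    if Xa.ndim != 2 or len(Xa) != len(ya):
        raise ValueError("X must be 2-D with one label per row")
    classes, counts = np.unique(ya, return_counts=True)
    if len(classes) != 2:
        raise ValueError(f"exactly two classes required, got {len(classes)}")

    minority_class = classes[np.argmin(counts)]
    min_rows = np.flatnonzero(ya == minority_class)
    maj_rows = np.flatnonzero(ya != minority_class)
    n_min = len(min_rows)

    if binary_columns is None:
        bin_mask = detect_binary_columns(Xa)
    elif columns is not None and len(binary_columns) and isinstance(
        next(iter(binary_columns)), str
    ):
        bin_mask = np.asarray([c in set(binary_columns) for c in columns])
    else:
        bin_mask = np.asarray(binary_columns, dtype=bool)

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    X_min = Xa[min_rows]
    scale = None
    if config.standardize:
        sd = X_min.std(axis=0)
        sd[sd == 0] = 1.0
        scale = sd
    nn = nearest_minority_neighbors(X_min, config.k_neighbors, scale)

    n_syn = round(n_min * config.perc_over / 100.0)
    per_point = np.full(n_min, n_syn // n_min, dtype=np.int64) if n_min else np.zeros(0, np.int64)
    remainder = n_syn - int(per_point.sum())
    if remainder > 0:
        extra = rng.permutation(n_min)[:remainder]
        per_point[extra] += 1

    parents = np.repeat(np.arange(n_min), per_point)
    if n_min == 1 or nn.shape[1] == 0:
        if n_syn > 0:
            warnings.warn(
                "minority class has a single member; synthetic points are copies",
                stacklevel=2,
            )
        neighbors = parents.copy()
    else:
        choice = rng.integers(0, nn.shape[1], size=len(parents))
        neighbors = nn[parents, choice]

    u = rng.random(len(parents))
    Xp, Xn = X_min[parents], X_min[neighbors]
    X_syn = Xp + u[:, None] * (Xn - Xp)
    if bin_mask.any() and len(parents):
        # binary columns: copy parent's or neighbour's value, uniform per cell
        take_neighbor = rng.random((len(parents), int(bin_mask.sum()))) < 0.5
        X_syn[:, bin_mask] = np.where(take_neighbor, Xn[:, bin_mask], Xp[:, bin_mask])

    n_keep = round(config.perc_under / 100.0 * n_syn)
    if n_keep > len(maj_rows):
        warnings.warn(
            f"requested {n_keep} majority rows but only {len(maj_rows)} exist; "
            "keeping all",
            stacklevel=2,
        )
        n_keep = len(maj_rows)
    kept_maj = maj_rows[np.sort(rng.permutation(len(maj_rows))[:n_keep])]

    X_out = np.vstack([X_min, X_syn, Xa[kept_maj]])
    y_out = np.concatenate(
        [
            np.full(n_min + n_syn, minority_class),
            np.full(n_keep, classes[classes != minority_class][0]),
        ]
    )
    return SmoteResult(
        X=X_out,
        y=y_out,
        minority_rows=min_rows,
        majority_rows=kept_maj,
        synthetic_parent=min_rows[parents],
        synthetic_neighbor=min_rows[neighbors],
        synthetic_u=u,
        columns=columns,
        binary_mask=bin_mask,
    )
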