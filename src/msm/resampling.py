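"""SMOTE: synthetic minority oversampling for imbalanced cohorts.

Per-condition sick/not-sick labels are typically imbalanced (e.g. 29 of 156
students with inferiority). SMOTE rebalances the *training* data by
synthesising minority-class points: pick a minority sample ``x``, pick one
of its ``k`` nearest minority neighbours ``x_n`` (Euclidean distance), and
emit ``x_new = x + r * (x_n - x)`` with ``r ~ Uniform(0, 1)`` — a random
point on the segment between the two. That interpolation is the
``canonical`` formula mode. The ``as_printed`` mode instead computes
``x_new = x + r * (x - x_n)``, which extrapolates *away* from the
neighbour; it is provided for comparison with descriptions that write the
update in that orientation, and is not the default.

Resampling belongs inside a cross-validation training fold only; applying
it before splitting leaks synthetic copies of held-out points into
training.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.neighbors import NearestNeighbors

__all__ = ["SMOTE", "SmoteConfig", "smote"]


@dataclass
class SmoteConfig:
    k_neighbors: int = 5
    target_ratio: float = 1.0  # desired minority/majority size ratio
    seed: int = 0
    formula_mode: str = "canonical"  # or "as_printed"

    def __post_init__(self) -> None:
        if self.k_neighbors < 1:
            raise ValueError("k_neighbors must be >= 1")
        if not 0.0 < self.target_ratio <= 1.0:
            raise ValueError("target_ratio must be in (0, 1]")
        if self.formula_mode not in ("canonical", "as_printed"):
            raise ValueError(
                "formula_mode must be 'canonical' or 'as_printed'"
            )


class SMOTE:
    """Minority oversampler with a ``fit_resample`` interface.

    Parameters mirror :class:`SmoteConfig`; identical seed and inputs give
    an identical output matrix. Original rows are returned untouched, with
    synthetic minority rows appended until the minority/majority ratio
    reaches ``target_ratio``.
    """

    def __init__(
        self,
        k_neighbors: int = 5,
        target_ratio: float = 1.0,
        seed: int = 0,
        formula_mode: str = "canonical",
    ):
        self.k_neighbors = k_neighbors
        self.target_ratio = target_ratio
        self.seed = seed
        self.formula_mode = formula_mode

    def get_params(self, deep: bool = True) -> dict:
        return {
            "k_neighbors": self.k_neighbors,
            "target_ratio": self.target_ratio,
            "seed": self.seed,
            "formula_mode": self.formula_mode,
        }

    def set_params(self, **params) -> "SMOTE":
        for k, v in params.items():
            if not hasattr(self, k):
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def _config(self) -> SmoteConfig:
        return SmoteConfig(
            k_neighbors=self.k_neighbors,
            target_ratio=self.target_ratio,
            seed=self.seed,
            formula_mode=self.formula_mode,
        )

    def fit_resample(
        self, X: np.ndarray, y: np.ndarray
    ) -> tuple[np.ndarray, np.ndarray]:
        cfg = self._config()
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y)
        if X.ndim != 2 or len(X) != len(y):
            raise ValueError("X must be 2-D and row-aligned with y")
        classes, counts = np.unique(y, return_counts=True)
        if len(classes) != 2:
            raise ValueError("SMOTE requires exactly two classes")
        minority = classes[np.argmin(counts)]
        n_min, n_maj = counts.min(), counts.max()
        if n_min <= cfg.k_neighbors:
            raise ValueError(
                f"minority class has {n_min} samples; SMOTE with "
                f"k_neighbors={cfg.k_neighbors} needs at least "
                f"{cfg.k_neighbors + 1}"
            )
        n_target = int(np.ceil(cfg.target_ratio * n_maj))
        n_new = max(0, n_target - n_min)
        if n_new == 0:
            return X.copy(), y.copy()

        X_min = X[y == minority]
        nn = NearestNeighbors(n_neighbors=cfg.k_neighbors + 1).fit(X_min)
        # drop column 0: each point is its own nearest neighbour
        neighbor_idx = nn.kneighbors(X_min, return_distance=False)[:, 1:]

        rng = np.random.default_rng(cfg.seed)
        base = rng.integers(0, len(X_min), size=n_new)
        pick = rng.integers(0, cfg.k_neighbors, size=n_new)
        r = rng.uniform(0.0, 1.0, size=n_new)

        x = X_min[base]
        x_n = X_min[neighbor_idx[base, pick]]
        if cfg.formula_mode == "canonical":
            X_new = x + r[:, None] * (x_n - x)
        else:  # as_printed: extrapolation away from the neighbour
            X_new = x + r[:, None] * (x - x_n)

        X_out = np.vstack([X, X_new])
        y_out = np.concatenate([y, np.full(n_new, minority, dtype=y.dtype)])
        return X_out, y_out


def smote(
    X: np.ndarray, y: np.ndarray, cfg: SmoteConfig | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Function-style wrapper over :class:`SMOTE`."""
    cfg = cfg or SmoteConfig()
    return SMOTE(**cfg.__dict__).fit_resample(X, y)
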