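"""Core data containers for landmark-based morphometrics.

A *landmark configuration* is one specimen's ``p x k`` matrix of point
coordinates (``k`` = 2 or 3); a *sample* is an ordered collection of
configurations sharing the same landmarks. Covariates (sex, size, BMI-like
measurements) ride along in a pandas DataFrame keyed by specimen id.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd


class LandmarkError(ValueError):
    """Raised for malformed or degenerate landmark data."""


@dataclass(frozen=True)
class LandmarkConfiguration:
    """One specimen: ``p`` landmarks in ``k`` dimensions.

    Parameters
    ----------
    id : str
        Specimen label.
    coords : (p, k) ndarray
        Landmark coordinates; units arbitrary but consistent.
    landmark_names : sequence of str, optional
        Unique landmark labels; defaults to ``L1..Lp``.
    """

    id: str
    coords: np.ndarray
    landmark_names: tuple = None

    def __post_init__(self):
        coords = np.asarray(self.coords, dtype=float)
        if coords.ndim != 2:
            raise LandmarkError(f"coords must be 2-D, got shape {coords.shape}")
        p, k = coords.shape
        if k not in (2, 3):
            raise LandmarkError(f"dimension k must be 2 or 3, got {k}")
        if p < 3:
            raise LandmarkError(f"need at least 3 landmarks, got {p}")
        if not np.isfinite(coords).all():
            bad = np.argwhere(~np.isfinite(coords))
            raise LandmarkError(f"non-finite coordinates at (landmark, axis) {bad.tolist()}")
        names = self.landmark_names
        if names is None:
            names = tuple(f"L{i + 1}" for i in range(p))
        else:
            names = tuple(str(x) for x in names)
            if len(names) != p:
                raise LandmarkError(f"{len(names)} landmark names for {p} landmarks")
            if len(set(names)) != p:
                raise LandmarkError("landmark names must be unique")
        object.__setattr__(self, "coords", coords)
        object.__setattr__(self, "landmark_names", names)

    @property
    def p(self) -> int:
        return self.coords.shape[0]

    @property
    def k(self) -> int:
        return self.coords.shape[1]

    def with_coords(self, coords: np.ndarray) -> "LandmarkConfiguration":
        return replace(self, coords=np.asarray(coords, dtype=float))


@dataclass
class LandmarkSample:
    """Ordered collection of congruent configurations, optionally with covariates."""

    configurations: list
    covariates: pd.DataFrame = None

    def __post_init__(self):
        configs = list(self.configurations)
        if not configs:
            raise LandmarkError("empty sample")
        ref = configs[0]
        for c in configs[1:]:
            if c.p != ref.p or c.k != ref.k:
                raise LandmarkError(
                    f"configuration {c.id!r} has shape ({c.p},{c.k}), "
                    f"expected ({ref.p},{ref.k})"
                )
            if c.landmark_names != ref.landmark_names:
                raise LandmarkError(f"configuration {c.id!r} has different landmark names")
        self.configurations = configs

    @property
    def n(self) -> int:
        return len(self.configurations)

    @property
    def p(self) -> int:
        return self.configurations[0].p

    @property
    def k(self) -> int:
        return self.configurations[0].k

    @property
    def ids(self) -> list:
        return [c.id for c in self.configurations]

    @property
    def landmark_names(self) -> tuple:
        return self.configurations[0].landmark_names

    def as_array(self) -> np.ndarray:
        """Stack coordinates into an (n, p, k) array."""
        return np.stack([c.coords for c in self.configurations])

    def as_flat(self) -> np.ndarray:
        """Row-per-specimen (n, p*k) matrix, landmark-major flattening."""
        return self.as_array().reshape(self.n, -1)

    def __iter__(self):
        return iter(self.configurations)

    def __getitem__(self, i):
        return self.configurations[i]

    def with_coords(self, arr: np.ndarray) -> "LandmarkSample":
        """New sample with coordinates replaced by ``arr`` of shape (n, p, k)."""
        arr = np.asarray(arr, float)
        if arr.shape != (self.n, self.p, self.k):
            raise LandmarkError(f"array shape {arr.shape} != ({self.n},{self.p},{self.k})")
        return LandmarkSample(
            [c.with_coords(a) for c, a in zip(self.configurations, arr)],
            covariates=self.covariates,
        )


def flat_to_configs(flat: np.ndarray, k: int) -> np.ndarray:
    """Reshape an (n, p*k) matrix back to (n, p, k)."""
    flat = np.atleast_2d(np.asarray(flat, float))
    return flat.reshape(flat.shape[0], -1, k)


def make_sample(coords: np.ndarray, ids: Sequence[str] = None,
                landmark_names: Sequence[str] = None,
                covariates: pd.DataFrame = None) -> LandmarkSample:
    """Convenience constructor from an (n, p, k) array."""
    coords = np.asarray(coords, float)
    if coords.ndim != 3:
        raise LandmarkError("expected an (n, p, k) array")
    n = coords.shape[0]
    if ids is None:
        ids = [f"case_{i + 1}" for i in range(n)]
    configs = [
        LandmarkConfiguration(str(ids[i]), coords[i], landmark_names) for i in range(n)
    ]
    return LandmarkSample(configs, covariates=covariates)
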