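"""Small shared helpers: RNG handling, geographic distance, matrix checks."""

from __future__ import annotations

import numpy as np

EARTH_RADIUS_KM = 6371.0088


def as_rng(seed) -> np.random.Generator:
    """Return a Generator from a seed, an existing Generator, or None."""
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def spawn_seed(rng: np.random.Generator) -> int:
    """Draw a child seed below 2**31 so it is safe for any downstream RNG."""
    return int(rng.integers(0, 2**31 - 1))


def haversine_km(lat: np.ndarray, lon: np.ndarray) -> np.ndarray:
    """Pairwise great-circle distance matrix (km) from degree coordinates."""
    lat = np.radians(np.asarray(lat, dtype=float))
    lon = np.radians(np.asarray(lon, dtype=float))
    dlat = lat[:, None] - lat[None, :]
    dlon = lon[:, None] - lon[None, :]
    a = np.sin(dlat / 2.0) ** 2 + np.cos(lat)[:, None] * np.cos(lat)[None, :] * np.sin(dlon / 2.0) ** 2
    a = np.clip(a, 0.0, 1.0)
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(a))


def check_square_symmetric(mat: np.ndarray, name: str = "matrix", tol: float = 1e-8) -> np.ndarray:
    mat = np.asarray(mat, dtype=float)
    if mat.ndim != 2 or mat.shape[0] != mat.shape[1]:
        raise ValueError(f"{name} must be square, got shape {mat.shape}")
    if not np.allclose(mat, mat.T, atol=tol, equal_nan=True):
        raise ValueError(f"{name} must be symmetric")
    return mat


def offdiag(mat: np.ndarray) -> np.ndarray:
    """Upper-triangle (off-diagonal) entries of a square matrix as a vector."""
    mat = np.asarray(mat)
    iu = np.triu_indices(mat.shape[0], k=1)
    return mat[iu]
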