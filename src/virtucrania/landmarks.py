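"""Named 3D landmark configurations and basic morphometric scalars.

A :class:`LandmarkConfiguration` is the fundamental container of the
package: an ordered set of named anatomical points in millimetres, with a
missing-value mask and an optional bilateral pairing table (left/right
pairs plus midline names) used for symmetrisation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "LandmarkConfiguration",
    "PairingTable",
    "centroid_size",
    "procrustes_distance",
    "cumulative_euclidean_distance",
]


class InvalidLandmarksError(ValueError):
    """Raised when a configuration violates its structural invariants."""


@dataclass(frozen=True)
class PairingTable:
    """Bilateral pairing of landmark names.

    ``pairs`` lists (left_name, right_name) tuples; ``midline`` lists the
    unpaired midsagittal names. Every landmark of the host configuration
    must appear exactly once across the two.
    """

    pairs: tuple[tuple[str, str], ...]
    midline: tuple[str, ...]

    def validate(self, names: list[str]) -> None:
        seen: list[str] = []
        for left, right in self.pairs:
            seen.extend((left, right))
        seen.extend(self.midline)
        if sorted(seen) != sorted(names):
            extra = set(seen) - set(names)
            missing = set(names) - set(seen)
            raise InvalidLandmarksError(
                f"pairing table does not cover landmark names exactly once "
                f"(unknown: {sorted(extra)}, uncovered: {sorted(missing)})"
            )


@dataclass
class LandmarkConfiguration:
    """Ordered, named 3D landmarks (mm) for one specimen."""

    specimen_id: str
    landmark_names: list[str]
    coords: np.ndarray  # (N, 3) float
    missing_mask: np.ndarray | None = None  # (N,) bool, True = missing
    pairing: PairingTable | None = None
    estimated_mask: np.ndarray | None = None  # provenance: True = TPS-estimated
    group: str | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise InvalidLandmarksError("coords must be an (N, 3) array")
        n = self.coords.shape[0]
        if len(self.landmark_names) != n:
            raise InvalidLandmarksError(
                f"{len(self.landmark_names)} names for {n} coordinate rows"
            )
        if len(set(self.landmark_names)) != n:
            dupes = sorted(
                {x for x in self.landmark_names if self.landmark_names.count(x) > 1}
            )
            raise InvalidLandmarksError(f"duplicate landmark names: {dupes}")
        if self.missing_mask is None:
            self.missing_mask = ~np.isfinite(self.coords).all(axis=1)
        else:
            self.missing_mask = np.asarray(self.missing_mask, dtype=bool).copy()
            if self.missing_mask.shape != (n,):
                raise InvalidLandmarksError("missing_mask length mismatch")
        if self.estimated_mask is None:
            self.estimated_mask = np.zeros(n, dtype=bool)
        else:
            self.estimated_mask = np.asarray(self.estimated_mask, dtype=bool).copy()
        present = ~self.missing_mask
        if not np.isfinite(self.coords[present]).all():
            raise InvalidLandmarksError("non-missing coordinates must be finite")
        if self.pairing is not None:
            self.pairing.validate(self.landmark_names)

    # -- convenience ---------------------------------------------------

    def __len__(self) -> int:
        return self.coords.shape[0]

    @property
    def n_present(self) -> int:
        return int((~self.missing_mask).sum())

    def index_of(self, name: str) -> int:
        try:
            return self.landmark_names.index(name)
        except ValueError:
            raise KeyError(f"landmark {name!r} not in configuration") from None

    def get(self, name: str) -> np.ndarray:
        return self.coords[self.index_of(name)]

    def subset(self, names: list[str], specimen_id: str | None = None) -> "LandmarkConfiguration":
        """New configuration restricted to ``names``, in the given order."""
        idx = [self.index_of(n) for n in names]
        return LandmarkConfiguration(
            specimen_id=specimen_id or self.specimen_id,
            landmark_names=list(names),
            coords=self.coords[idx].copy(),
            missing_mask=self.missing_mask[idx].copy(),
            estimated_mask=self.estimated_mask[idx].copy(),
            group=self.group,
        )

    def with_coords(self, coords: np.ndarray, specimen_id: str | None = None) -> "LandmarkConfiguration":
        """Copy of this configuration with replaced coordinates."""
        return LandmarkConfiguration(
            specimen_id=specimen_id or self.specimen_id,
            landmark_names=list(self.landmark_names),
            coords=np.asarray(coords, dtype=float).copy(),
            missing_mask=self.missing_mask.copy(),
            pairing=self.pairing,
            estimated_mask=self.estimated_mask.copy(),
            group=self.group,
        )

    def copy(self) -> "LandmarkConfiguration":
        return self.with_coords(self.coords)


def _present_coords(config: LandmarkConfiguration) -> np.ndarray:
    return config.coords[~config.missing_mask]


def centroid_size(config: LandmarkConfiguration) -> float:
    """Centroid size: sqrt of summed squared deviations from the centroid.

    The standard geometric-morphometric size measure, computed over the
    non-missing landmarks only. Requires at least 3 usable landmarks.
    """
    pts = _present_coords(config)
    if pts.shape[0] < 3:
        raise InvalidLandmarksError(
            f"centroid size needs >=3 non-missing landmarks, got {pts.shape[0]}"
        )
    centred = pts - pts.mean(axis=0)
    return float(np.sqrt((centred**2).sum()))


def _check_same_names(a: LandmarkConfiguration, b: LandmarkConfiguration) -> None:
    if a.landmark_names != b.landmark_names:
        raise InvalidLandmarksError(
            "configurations must share landmark names in the same order"
        )


def procrustes_distance(a: LandmarkConfiguration, b: LandmarkConfiguration) -> float:
    """Shape distance between two already-superimposed configurations.

    Both configurations are centred and scaled to unit centroid size, then
    the root of the summed squared coordinate differences is returned. The
    caller is responsible for rotational superimposition.
    """
    _check_same_names(a, b)
    common = ~(a.missing_mask | b.missing_mask)
    pa = a.coords[common]
    pb = b.coords[common]
    pa = pa - pa.mean(axis=0)
    pb = pb - pb.mean(axis=0)
    sa = np.sqrt((pa**2).sum())
    sb = np.sqrt((pb**2).sum())
    return float(np.sqrt(((pa / sa - pb / sb) ** 2).sum()))


def cumulative_euclidean_distance(
    a: LandmarkConfiguration,
    b: LandmarkConfiguration,
    reduce: str = "sum",
    size_warning_tol: float = 0.25,
) -> float:
    """Cumulative Euclidean distance in mm between aligned configurations.

    Sum (default) or mean over landmarks of the pointwise 3D distances,
    with no rescaling: this is the raw morphological distance used to
    rank reference specimens. A large centroid-size mismatch suggests the
    inputs were never superimposed; that triggers a warning, not an error.
    """
    _check_same_names(a, b)
    common = ~(a.missing_mask | b.missing_mask)
    pa = a.coords[common]
    pb = b.coords[common]
    sa = np.sqrt(((pa - pa.mean(axis=0)) ** 2).sum())
    sb = np.sqrt(((pb - pb.mean(axis=0)) ** 2).sum())
    if sa > 0 and sb > 0 and abs(sa - sb) / max(sa, sb) > size_warning_tol:
        warnings.warn(
            f"centroid sizes differ by more than {size_warning_tol:.0%} "
            f"({sa:.2f} vs {sb:.2f} mm); configurations may not be superimposed",
            stacklevel=2,
        )
    dists = np.linalg.norm(pa - pb, axis=1)
    if reduce == "sum":
        return float(dists.sum())
    if reduce == "mean":
        return float(dists.mean())
    raise ValueError(f"unknown reduce mode {reduce!r}")
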