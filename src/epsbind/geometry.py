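"""Helix-geometry and superposition metrics.

Covers the three geometric observables used to compare ε-subunit variants:
the centre-of-mass distance between the two C-terminal α-helices, per-frame
interaction-distance series against crystal reference distances, and rigid
least-squares superposition RMSD.

The helix residue ranges are deliberately NOT defaulted: the C-terminal
domain spans residues 112–133, but where to split it into "the two α-helices"
is a modelling choice the caller must make explicitly (via config).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.spatial.transform import Rotation

from .core import Ensemble, Frame, SelectionError, SelectionSpec, resolve_selection

__all__ = [
    "ReferenceDistances",
    "HelixPair",
    "DistanceSeries",
    "ELEMENT_MASSES",
    "com_distance",
    "interaction_distance_series",
    "superpose_rmsd",
]

# Average atomic masses (u) for the elements appearing in these systems.
ELEMENT_MASSES: Mapping[str, float] = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999,
    "P": 30.974, "S": 32.06, "MG": 24.305, "NA": 22.990, "CL": 35.45,
}


@dataclass(frozen=True)
class ReferenceDistances:
    """Named crystal-structure reference distances in Å (e.g. from 2E5Y)."""

    values: Mapping[str, float]
    source: str = ""

    def __post_init__(self) -> None:
        for name, v in self.values.items():
            if v <= 0:
                raise ValueError(f"reference distance {name!r} must be > 0")


@dataclass(frozen=True)
class HelixPair:
    """Two disjoint selections whose centre-of-mass distance is tracked."""

    helix_a: SelectionSpec
    helix_b: SelectionSpec
    mass_convention: str = "unit"  # "unit" | "element"

    def __post_init__(self) -> None:
        if self.mass_convention not in ("unit", "element"):
            raise ValueError("mass_convention must be 'unit' or 'element'")


def _masses(frame: Frame, indices: Sequence[int], convention: str) -> np.ndarray:
    if convention == "unit":
        return np.ones(len(indices))
    return np.array([ELEMENT_MASSES.get(frame.atoms[i].element.upper(), 12.011)
                     for i in indices])


def com_distance(frame: Frame, pair: HelixPair) -> float:
    """Euclidean distance in Å between the mass-weighted centroids of the two
    helix selections (unit masses by default)."""
    idx_a = resolve_selection(pair.helix_a, frame, strict=True)
    idx_b = resolve_selection(pair.helix_b, frame, strict=True)
    if set(idx_a) & set(idx_b):
        raise ValueError("helix selections must be disjoint")
    com = []
    for idx in (idx_a, idx_b):
        m = _masses(frame, idx, pair.mass_convention)
        com.append(np.average(frame.coords[idx], axis=0, weights=m))
    return float(np.linalg.norm(com[0] - com[1]))


@dataclass(frozen=True)
class DistanceSeries:
    """Per-frame interaction distances with histogram and reference deviation."""

    name: str
    distances: tuple[float, ...]  # post-equilibration frames, run order
    bin_edges: tuple[float, ...]
    bin_counts: tuple[int, ...]
    reference: float | None
    mean_deviation: float | None  # mean(distance - reference)


def interaction_distance_series(ensemble: Ensemble,
                                sel_a: SelectionSpec,
                                sel_b: SelectionSpec,
                                reference: ReferenceDistances | None = None,
                                reference_key: str | None = None,
                                bin_width: float = 0.1,
                                min_distance_mode: bool = False,
                                ) -> DistanceSeries:
    """Distance between two atom selections over all analysis frames.

    By default each selection must resolve to exactly one atom per frame; in
    ``min_distance_mode`` multi-atom groups (e.g. an arginine NHx pair) are
    allowed and the per-frame minimum over all atom pairs is recorded —
    matching how NHx-type interactions are plotted against crystal references.
    """
    distances: list[float] = []
    for frame in ensemble.iter_analysis_frames():
        idx_a = resolve_selection(sel_a, frame, strict=True)
        idx_b = resolve_selection(sel_b, frame, strict=True)
        if not min_distance_mode and (len(idx_a) != 1 or len(idx_b) != 1):
            raise SelectionError(
                f"selections {sel_a.name!r}/{sel_b.name!r} must resolve to one "
                f"atom each (got {len(idx_a)}/{len(idx_b)}); use min-distance "
                f"mode for multi-atom groups"
            )
        d = np.linalg.norm(frame.coords[idx_a][:, None, :]
                           - frame.coords[idx_b][None, :, :], axis=-1)
        distances.append(float(d.min()))

    arr = np.asarray(distances)
    lo = np.floor(arr.min() / bin_width) * bin_width
    hi = np.ceil(arr.max() / bin_width) * bin_width
    n_bins = max(1, int(round((hi - lo) / bin_width)))
    counts, edges = np.histogram(arr, bins=n_bins, range=(lo, lo + n_bins * bin_width))

    ref_value = None
    mean_dev = None
    if reference is not None and reference_key is not None:
        ref_value = float(reference.values[reference_key])
        mean_dev = float(np.mean(arr - ref_value))
    name = f"{sel_a.name}-{sel_b.name}"
    return DistanceSeries(name=name, distances=tuple(distances),
                          bin_edges=tuple(float(e) for e in edges),
                          bin_counts=tuple(int(c) for c in counts),
                          reference=ref_value, mean_deviation=mean_dev)


def superpose_rmsd(frame_a: Frame, frame_b: Frame,
                   selection: SelectionSpec | None = None) -> float:
    """RMSD in Å after optimal rigid-body superposition (Kabsch).

    Both frames are reduced to ``selection`` (all atoms when ``None``); the
    two selections must have equal atom counts in corresponding order.  The
    rotation is the proper (det = +1) least-squares rotation; degenerate
    (collinear) configurations follow the SVD convention of
    ``scipy.spatial.transform.Rotation.align_vectors``.
    """
    if selection is not None:
        idx_a = resolve_selection(selection, frame_a, strict=True)
        idx_b = resolve_selection(selection, frame_b, strict=True)
    else:
        idx_a = list(range(len(frame_a)))
        idx_b = list(range(len(frame_b)))
    if len(idx_a) != len(idx_b):
        raise ValueError(f"atom count mismatch: {len(idx_a)} vs {len(idx_b)}")
    a = frame_a.coords[idx_a]
    b = frame_b.coords[idx_b]
    a_c = a - a.mean(axis=0)
    b_c = b - b.mean(axis=0)
    # align_vectors returns the proper rotation minimizing sum ||a - R b||^2;
    # degenerate (collinear) inputs trigger a scipy uniqueness warning but the
    # RMSD itself is still well defined
    import warnings
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="Optimal rotation is not",
                                category=UserWarning)
        _, rssd = Rotation.align_vectors(a_c, b_c)
    return float(rssd / np.sqrt(len(idx_a)))
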