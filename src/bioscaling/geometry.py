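"""Coordinate-level chain geometry: Rg, end-to-end, RMSD, RMSF, B-factors.

All beads carry equal mass; the radius of gyration is the unweighted
root-mean-square distance of beads from their centroid, matching the
segment-based definition used by the scaling model.  Superposition is the
least-squares rigid (proper) rotation via scipy's align_vectors.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np
from scipy.spatial.transform import Rotation

__all__ = [
    "Conformation",
    "StructureEnsemble",
    "center_of_mass",
    "radius_of_gyration",
    "end_to_end_distance",
    "kabsch_superpose",
    "rmsd",
    "rmsf",
    "bfactor_classify",
]

ENSEMBLE_KINDS = ("trajectory", "nmr_ensemble", "sample_set")

B_CONFIDENT_BELOW = 30.0
B_DISORDERED_ABOVE = 60.0


@dataclass(frozen=True)
class Conformation:
    """One chain snapshot: ordered 3-D bead coordinates in Å.

    ``labels`` optionally names each bead (residue name/number);
    ``frame_time`` is the snapshot time in ps when part of a trajectory.
    """

    coordinates: np.ndarray
    labels: tuple[str, ...] | None = None
    frame_time: float | None = None

    def __post_init__(self) -> None:
        coords = np.asarray(self.coordinates, dtype=float)
        if coords.ndim != 2 or coords.shape[1] != 3 or coords.shape[0] < 1:
            raise ValueError("coordinates must be a non-empty (n, 3) array")
        if not np.all(np.isfinite(coords)):
            raise ValueError("coordinates must be finite")
        coords.setflags(write=False)
        object.__setattr__(self, "coordinates", coords)
        if self.labels is not None:
            labels = tuple(str(x) for x in self.labels)
            if len(labels) != coords.shape[0]:
                raise ValueError("labels length must match bead count")
            object.__setattr__(self, "labels", labels)

    @property
    def n_beads(self) -> int:
        return self.coordinates.shape[0]

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "Conformation":
        """Apply a rigid transform r -> R r + t."""
        coords = self.coordinates @ np.asarray(rotation).T + np.asarray(translation)
        return Conformation(coords, self.labels, self.frame_time)


@dataclass(frozen=True)
class StructureEnsemble:
    """Ordered set of equal-length conformations.

    ``kind`` distinguishes time-ordered trajectories (non-decreasing
    frame times), NMR model sets and independent sample sets.
    """

    members: tuple[Conformation, ...]
    kind: str = "sample_set"

    def __post_init__(self) -> None:
        members = tuple(self.members)
        if not members:
            raise ValueError("ensemble must have >= 1 member")
        counts = {m.n_beads for m in members}
        if len(counts) != 1:
            raise ValueError(f"members have unequal bead counts: {sorted(counts)}")
        if self.kind not in ENSEMBLE_KINDS:
            raise ValueError(f"kind must be one of {ENSEMBLE_KINDS}")
        if self.kind == "trajectory":
            times = [m.frame_time for m in members if m.frame_time is not None]
            if any(b < a for a, b in zip(times, times[1:])):
                raise ValueError("trajectory frame times must be non-decreasing")
        object.__setattr__(self, "members", members)

    def __len__(self) -> int:
        return len(self.members)

    def __iter__(self) -> Iterator[Conformation]:
        return iter(self.members)

    def __getitem__(self, i: int) -> Conformation:
        return self.members[i]

    @property
    def n_beads(self) -> int:
        return self.members[0].n_beads

    def coordinate_array(self) -> np.ndarray:
        """Stack coordinates into an (n_frames, n_beads, 3) array."""
        return np.stack([m.coordinates for m in self.members])


def center_of_mass(conformation: Conformation) -> np.ndarray:
    """Equal-mass centroid of the beads."""
    return conformation.coordinates.mean(axis=0)


def radius_of_gyration(conformation: Conformation) -> float:
    """RMS distance of beads from their centroid (Å)."""
    dev = conformation.coordinates - center_of_mass(conformation)
    return float(np.sqrt((dev * dev).sum(axis=1).mean()))


def end_to_end_distance(conformation: Conformation) -> float:
    """Euclidean distance between the first and last bead (Å)."""
    if conformation.n_beads < 2:
        raise ValueError("need >= 2 beads for an end-to-end distance")
    return float(np.linalg.norm(conformation.coordinates[-1] - conformation.coordinates[0]))


def kabsch_superpose(
    mobile: Conformation, target: Conformation
) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid superposition of ``mobile`` onto ``target``.

    Returns ``(rotation, translation, rmsd)`` such that
    ``rotation @ r + translation`` best fits the target in the
    least-squares sense.  The rotation is always proper (det +1);
    reflections are corrected.
    """
    if mobile.n_beads != target.n_beads:
        raise ValueError("bead counts must match")
    if mobile.n_beads < 3:
        raise ValueError("need >= 3 beads for a unique superposition")
    mob_c = center_of_mass(mobile)
    tar_c = center_of_mass(target)
    rot, _ = Rotation.align_vectors(
        target.coordinates - tar_c, mobile.coordinates - mob_c
    )
    matrix = rot.as_matrix()
    translation = tar_c - matrix @ mob_c
    # residual computed from the transformed coordinates: cancellation-free
    # for (near-)congruent pairs, unlike the singular-value form
    diff = mobile.coordinates @ matrix.T + translation - target.coordinates
    value = float(np.sqrt((diff * diff).sum(axis=1).mean()))
    return matrix, translation, value


def rmsd(a: Conformation, b: Conformation, superpose: bool = True) -> float:
    """Root-mean-square deviation between two conformations (Å).

    With ``superpose`` (default), the Kabsch-minimal RMSD; otherwise the
    raw coordinate RMSD, useful as a trajectory-drift diagnostic.
    """
    if a.n_beads != b.n_beads:
        raise ValueError("bead counts must match")
    if superpose:
        return kabsch_superpose(a, b)[2]
    diff = a.coordinates - b.coordinates
    return float(np.sqrt((diff * diff).sum(axis=1).mean()))


def rmsf(
    ensemble: StructureEnsemble, reference: Conformation | None = None
) -> np.ndarray:
    """Per-bead root-mean-square fluctuation across an aligned ensemble.

    Each member is rigidly superposed onto ``reference`` (default: the
    first member); the RMSF of bead k is the RMS deviation of its aligned
    positions from their mean.
    """
    if reference is None:
        reference = ensemble[0]
    if reference.n_beads != ensemble.n_beads:
        raise ValueError("reference bead count must match ensemble")
    aligned = np.empty((len(ensemble), ensemble.n_beads, 3))
    for i, member in enumerate(ensemble):
        rot, trans, _ = kabsch_superpose(member, reference)
        aligned[i] = member.coordinates @ rot.T + trans
    dev = aligned - aligned.mean(axis=0)
    return np.sqrt((dev * dev).sum(axis=2).mean(axis=0))


def bfactor_classify(values: Sequence[float]) -> list[str]:
    """Classify per-atom B-factors (Å²) by confidence.

    Below 30 is "confident", above 60 "disordered", the boundary values
    and everything between "intermediate".
    """
    arr = np.asarray(values, dtype=float)
    if np.any(arr < 0):
        raise ValueError("B-factors must be non-negative")
    out = []
    for b in arr.ravel():
        if b < B_CONFIDENT_BELOW:
            out.append("confident")
        elif b > B_DISORDERED_ABOVE:
            out.append("disordered")
        else:
            out.append("intermediate")
    return out
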