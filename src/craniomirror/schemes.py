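"""Landmark schemes: named anatomical points, bilateral pairing, and derived symbols.

A scheme declares which landmarks lie on the midline and which come in
left/right pairs. The pairing determines which raw inter-landmark distances
are mirror images of each other and therefore get averaged into a single
symmetric feature. Schemes also carry the landmark triples that define
angular features (e.g. the nasomental and labiomental angles) and, for
rodent mandibles, named landmark groups whose centroids define mandibular
length and width.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

__all__ = [
    "LandmarkScheme",
    "human_face_scheme",
    "rodent_dorsal_scheme",
]

_ROLES = ("midline", "left", "right")


@dataclass(frozen=True)
class LandmarkScheme:
    """An ordered set of named landmarks with bilateral pairing.

    Parameters
    ----------
    name : str
        Identifier for the scheme.
    landmarks : tuple of (label, role)
        Ordered landmark labels with role ``midline``, ``left`` or ``right``.
    pairing : mapping
        Maps each left label to its right partner (one direction suffices;
        the reverse map is derived).
    species : str
        One of ``human``, ``rat``, ``mouse``, ``zebrafish``.
    angles : mapping, optional
        Angle-feature name -> (a, vertex, c) landmark labels.
    mandible_groups : mapping, optional
        Group name (``incisor``, ``left_ramus``, ``right_ramus``) -> labels.
    """

    name: str
    landmarks: tuple[tuple[str, str], ...]
    pairing: Mapping[str, str]
    species: str = "human"
    angles: Mapping[str, tuple[str, str, str]] = field(default_factory=dict)
    mandible_groups: Mapping[str, tuple[str, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        labels = [lab for lab, _ in self.landmarks]
        if len(set(labels)) != len(labels):
            raise ValueError(f"duplicate landmark labels in scheme {self.name!r}")
        roles = {lab: role for lab, role in self.landmarks}
        for lab, role in roles.items():
            if role not in _ROLES:
                raise ValueError(f"landmark {lab!r} has invalid role {role!r}")
        lefts = {lab for lab, role in self.landmarks if role == "left"}
        rights = {lab for lab, role in self.landmarks if role == "right"}
        if set(self.pairing) != lefts:
            raise ValueError("pairing keys must be exactly the left-role labels")
        if set(self.pairing.values()) != rights or len(set(self.pairing.values())) != len(self.pairing):
            raise ValueError("pairing values must biject onto the right-role labels")
        for grp, labs in self.mandible_groups.items():
            unknown = set(labs) - set(labels)
            if unknown:
                raise ValueError(f"mandible group {grp!r} references unknown labels {sorted(unknown)}")
        for ang, (a, v, c) in self.angles.items():
            for lab in (a, v, c):
                if lab not in roles:
                    raise ValueError(f"angle {ang!r} references unknown label {lab!r}")

    # -- derived views -------------------------------------------------

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(lab for lab, _ in self.landmarks)

    @property
    def roles(self) -> dict[str, str]:
        return {lab: role for lab, role in self.landmarks}

    def index(self, label: str) -> int:
        return self.labels.index(label)

    @property
    def n_midline(self) -> int:
        return sum(1 for _, role in self.landmarks if role == "midline")

    @property
    def n_pairs(self) -> int:
        return len(self.pairing)

    def mirror_label(self, label: str) -> str:
        """The bilateral partner of ``label`` (midline labels map to themselves)."""
        role = self.roles[label]
        if role == "midline":
            return label
        if role == "left":
            return self.pairing[label]
        reverse = {r: l for l, r in self.pairing.items()}
        return reverse[label]

    def validate_labels(self, labels: Iterable[str]) -> None:
        unknown = set(labels) - set(self.labels)
        if unknown:
            raise ValueError(
                f"labels not in scheme {self.name!r}: {sorted(unknown)}"
            )


def human_face_scheme() -> LandmarkScheme:
    """Default 24-landmark facial scheme: 8 bilateral pairs + 8 midline points.

    Labels are the numerals "1".."24". Labels 1-8 are left-side landmarks
    paired with 9-16 (1/9 frontotemporale, 2/10 lateral brow, 4/12 medial
    brow, 5/13 exocanthion, ...); 17-24 lie on the midline (glabella,
    nasion, pronasale, subnasale, labiale superius, labiale inferius,
    sublabiale, pogonion). The nasomental angle (NMA) is triangulated at
    the pronasale between nasion and pogonion; the labiomental angle (LMA)
    at the sublabiale between labiale inferius and pogonion. Angle triples
    are conventional defaults and can be overridden in a custom scheme.
    """
    landmarks = tuple(
        [(str(i), "left") for i in range(1, 9)]
        + [(str(i), "right") for i in range(9, 17)]
        + [(str(i), "midline") for i in range(17, 25)]
    )
    pairing = {str(i): str(i + 8) for i in range(1, 9)}
    angles = {"NMA": ("18", "19", "24"), "LMA": ("22", "23", "24")}
    return LandmarkScheme(
        name="human24", landmarks=landmarks, pairing=pairing,
        species="human", angles=angles,
    )


def rodent_dorsal_scheme(species: str = "rat") -> LandmarkScheme:
    """Default 19-landmark dorsal skull scheme: 8 bilateral pairs + 3 midline.

    Covers the frontal, nasal and maxillary regions of the dorsal skull.
    Labels 1-8 (left) pair with 9-16 (right); 17-19 are midline. The
    mandible is handled separately through centroid-based metrics
    (:func:`craniomirror.geometry.mandible_metrics`).
    """
    landmarks = tuple(
        [(str(i), "left") for i in range(1, 9)]
        + [(str(i), "right") for i in range(9, 17)]
        + [(str(i), "midline") for i in range(17, 20)]
    )
    pairing = {str(i): str(i + 8) for i in range(1, 9)}
    return LandmarkScheme(
        name=f"{species}_dorsal19", landmarks=landmarks, pairing=pairing,
        species=species,
    )
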