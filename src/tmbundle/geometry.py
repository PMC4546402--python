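"""Rigid-body helix geometry for four-helix transmembrane bundles.

The bundle is modelled at C-alpha resolution in a fixed membrane frame:
the z axis is the membrane normal, +z points to the extracellular side,
and the membrane is centred on z = 0.  Each transmembrane (TM) helix is
an ideal alpha-helical C-alpha trace treated as a rigid body; a
:class:`RigidTransform` (axial rotation, tilt, constrained translation)
carries all of its degrees of freedom.

The default helix definitions describe the four predicted TM segments of
bilitranslocase (BTL, UniProt O88750).  Only TM2 and TM3 have published
sequences; TM1 and TM4 ship as synthetic placeholder sequences of the
correct length with the experimentally referenced boundary and contact
residues pinned (see :func:`btl_helices`).
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.spatial.transform import Rotation

#: Ideal alpha-helix geometry (config-overridable via build_ideal_helix args).
RISE_PER_RESIDUE = 1.5  # Angstrom per residue along the axis
TWIST_PER_RESIDUE = 100.0  # degrees per residue
HELIX_RADIUS = 2.3  # Angstrom, C-alpha distance from the axis

STANDARD_AA = frozenset("ACDEFGHIKLMNPQRSTVWY")

AA_1TO3 = {
    "A": "ALA", "C": "CYS", "D": "ASP", "E": "GLU", "F": "PHE",
    "G": "GLY", "H": "HIS", "I": "ILE", "K": "LYS", "L": "LEU",
    "M": "MET", "N": "ASN", "P": "PRO", "Q": "GLN", "R": "ARG",
    "S": "SER", "T": "THR", "V": "VAL", "W": "TRP", "Y": "TYR",
}
AA_3TO1 = {v: k for k, v in AA_1TO3.items()}


class GeometryError(ValueError):
    """Invalid helix definition or rigid-body transform."""


@dataclass(frozen=True)
class HelixSpec:
    """Definition of one transmembrane helix.

    Parameters
    ----------
    name : str
        Helix label, e.g. ``"TM1"``.
    sequence : str
        One-letter amino-acid sequence (standard 20 letters).
    start_resnum, end_resnum : int
        1-based UniProt residue numbers of the first/last residue.
    allowed_axes : frozenset of {"x", "y", "z"}
        Translation axes this helix may move along during sampling.
    n_term_side : {"extracellular", "cytoplasmic"}
        Which membrane side the N-terminus faces (fixes the helix
        direction in the bundle; the default BTL topology alternates).
    """

    name: str
    sequence: str
    start_resnum: int
    end_resnum: int
    allowed_axes: frozenset = frozenset({"x", "y", "z"})
    n_term_side: str = "extracellular"

    def __post_init__(self):
        if not self.sequence:
            raise GeometryError(f"{self.name}: empty sequence")
        bad = set(self.sequence) - STANDARD_AA
        if bad:
            raise GeometryError(
                f"{self.name}: non-standard amino-acid letters {sorted(bad)}"
            )
        if self.end_resnum - self.start_resnum + 1 != len(self.sequence):
            raise GeometryError(
                f"{self.name}: residue range {self.start_resnum}-{self.end_resnum} "
                f"does not match sequence length {len(self.sequence)}"
            )
        if not set(self.allowed_axes) <= {"x", "y", "z"}:
            raise GeometryError(f"{self.name}: allowed_axes must be a subset of x,y,z")
        if self.n_term_side not in ("extracellular", "cytoplasmic"):
            raise GeometryError(f"{self.name}: bad n_term_side {self.n_term_side!r}")
        object.__setattr__(self, "allowed_axes", frozenset(self.allowed_axes))

    @property
    def n_residues(self) -> int:
        return len(self.sequence)

    @property
    def helix_length_A(self) -> float:
        """Axial length of the ideal helix in Angstrom."""
        return (self.n_residues - 1) * RISE_PER_RESIDUE

    @property
    def resnums(self) -> np.ndarray:
        return np.arange(self.start_resnum, self.end_resnum + 1)

    def index_of(self, resnum: int) -> int:
        if not self.start_resnum <= resnum <= self.end_resnum:
            raise KeyError(f"residue {resnum} not in {self.name}")
        return resnum - self.start_resnum


@dataclass(frozen=True)
class RigidTransform:
    """Constrained rigid-body transform of one helix.

    Applied as: rotation about the helix's own axis (``axial_rotation``),
    then a tilt away from the membrane normal (polar angle toward the
    in-plane direction given by ``tilt_azimuth``), then a translation.
    Components of ``translation`` on axes outside the helix's allowed
    set must be zero.
    """

    axial_rotation: float = 0.0  # degrees
    tilt_polar: float = 0.0  # degrees, >= 0
    tilt_azimuth: float = 0.0  # degrees
    translation: tuple = (0.0, 0.0, 0.0)  # Angstrom

    def __post_init__(self):
        if self.tilt_polar < 0:
            raise GeometryError("tilt_polar must be >= 0")
        object.__setattr__(self, "translation", tuple(float(v) for v in self.translation))

    def validate_axes(self, spec: HelixSpec) -> None:
        for axis, value in zip("xyz", self.translation):
            if value != 0.0 and axis not in spec.allowed_axes:
                raise GeometryError(
                    f"{spec.name}: translation along forbidden axis {axis!r}"
                )

    @property
    def tilt_vector(self) -> tuple:
        """Tilt as in-plane components (polar * (cos az, sin az)), degrees."""
        az = np.deg2rad(self.tilt_azimuth)
        return (self.tilt_polar * np.cos(az), self.tilt_polar * np.sin(az))

    @staticmethod
    def from_tilt_vector(axial_rotation, tx, ty, translation=(0.0, 0.0, 0.0)):
        polar = float(np.hypot(tx, ty))
        azimuth = float(np.rad2deg(np.arctan2(ty, tx))) if polar > 0 else 0.0
        return RigidTransform(axial_rotation, polar, azimuth, translation)


IDENTITY = RigidTransform()


def build_ideal_helix(
    spec: HelixSpec,
    rise: float = RISE_PER_RESIDUE,
    twist: float = TWIST_PER_RESIDUE,
    radius: float = HELIX_RADIUS,
) -> np.ndarray:
    """Ideal alpha-helical C-alpha trace for one helix.

    The axis lies along +z through the origin; the trace is centred at
    z = 0 with the N-terminus at the highest z (the orientation of a
    helix whose N-terminus faces the extracellular side).  Residue i
    carries residue number ``start_resnum + i``.

    Returns an (n_residues, 3) float array in Angstrom.
    """
    n = spec.n_residues
    i = np.arange(n)
    theta = np.deg2rad(-i * twist)
    z = ((n - 1) / 2.0 - i) * rise
    return np.column_stack([radius * np.cos(theta), radius * np.sin(theta), z])


def principal_axis(coords: np.ndarray, twist: float | None = TWIST_PER_RESIDUE) -> np.ndarray:
    """Unit helix axis of a C-alpha trace, oriented toward +z.

    For a trace with a known per-residue twist Omega the points
    ``(c[i+1] + c[i-1] - 2 cos(Omega) c[i]) / (2 (1 - cos(Omega)))`` lie
    exactly on the helix axis, so a line fit through them recovers the
    axis without the bias a plain principal-component fit suffers on
    short traces with incomplete turns (several degrees for a 10-20
    residue helix).  Pass ``twist=None`` to force the plain
    principal-component fit; single points default to +z.
    """
    coords = np.asarray(coords, float)
    if len(coords) < 2:
        return np.array([0.0, 0.0, 1.0])
    axis = None
    if twist is not None and len(coords) >= 4:
        cw = np.cos(np.deg2rad(twist))
        on_axis = (coords[2:] + coords[:-2] - 2.0 * cw * coords[1:-1]) / (2.0 * (1.0 - cw))
        centered = on_axis - on_axis.mean(axis=0)
        u, s, vt = np.linalg.svd(centered, full_matrices=False)
        if s[0] > 1e-9:
            axis = vt[0]
    if axis is None:
        centered = coords - coords.mean(axis=0)
        _, _, vt = np.linalg.svd(centered, full_matrices=False)
        axis = vt[0]
    if axis[2] < 0:
        axis = -axis
    elif axis[2] == 0 and (axis[0] < 0 or (axis[0] == 0 and axis[1] < 0)):
        axis = -axis  # deterministic orientation for in-plane axes
    return axis / np.linalg.norm(axis)


def affine_from_transform(coords: np.ndarray, t: RigidTransform):
    """Rotation matrix and offset such that ``out = coords @ R.T + offset``.

    Encodes the transform convention: axial rotation about the trace's
    own principal axis through its centroid, then tilt about an in-plane
    axis through the centroid, then translation.
    """
    coords = np.asarray(coords, float)
    c = coords.mean(axis=0)
    u = principal_axis(coords)
    r_axial = Rotation.from_rotvec(np.deg2rad(t.axial_rotation) * u)
    az = np.deg2rad(t.tilt_azimuth)
    tilt_axis = np.array([-np.sin(az), np.cos(az), 0.0])
    r_tilt = Rotation.from_rotvec(np.deg2rad(t.tilt_polar) * tilt_axis)
    rot = (r_tilt * r_axial).as_matrix()
    offset = c - rot @ c + np.asarray(t.translation, float)
    return rot, offset


def apply_transform(coords: np.ndarray, t: RigidTransform, spec: HelixSpec) -> np.ndarray:
    """Apply a constrained rigid-body transform to a helix trace.

    Raises :class:`GeometryError` if the translation has a component on
    an axis the helix is not allowed to move along.  Rigid: all pairwise
    intra-helix distances are preserved.
    """
    t.validate_axes(spec)
    rot, offset = affine_from_transform(coords, t)
    return np.asarray(coords, float) @ rot.T + offset


def scan_motif(sequence: str, pattern: str, start_resnum: int = 1):
    """Scan a sequence for a small-residue dimerization motif.

    ``pattern`` uses fixed letters from {A, G, S} (the small residues of
    GxxxG-type transmembrane dimerization motifs) plus the wildcard
    ``x``.  Returns all (possibly overlapping) matches as
    ``(start_resnum_of_match, matched_substring)`` tuples.
    """
    if not pattern:
        raise GeometryError("empty motif pattern")
    bad = set(pattern) - set("AGSx")
    if bad:
        raise GeometryError(f"motif pattern letters must be in {{A,G,S,x}}: {sorted(bad)}")
    regex = re.compile("(?=(" + pattern.replace("x", ".") + "))")
    return [
        (start_resnum + m.start(), m.group(1)) for m in regex.finditer(sequence)
    ]


# ---------------------------------------------------------------------------
# Default BTL helix definitions
# ---------------------------------------------------------------------------

# TM2 helix Phe75-Cys94, a 20-residue window of the synthetic TM2B peptide
# (Ser73-Leu99).  TM3 is shipped in two variants because the published
# 18-letter sequence does not fill the stated Gly220-Tyr238 range:
#   "printed"  -> the 18-mer exactly as printed, numbered 220-237
#   "range"    -> the 18-mer with Tyr appended, numbered 220-238
TM2_SEQ = "FCLFVATLQSPFSAGVSGLC"
TM3_SEQ_PRINTED = "GSVQCAGLISLPIAIEFT"
TM3_SEQ_RANGE = TM3_SEQ_PRINTED + "Y"

# Synthetic placeholder sequences: BTL TM1/TM4 sequences are unpublished;
# only length and the boundary/contact residues (Phe24, His43, Asp48;
# Pro254, Pro258, Ser276) are constrained by the experimental record.
TM1_SEQ_SYNTHETIC = "F" + "LAIVLGSAILVAGLIVAL" + "H" + "LIVA" + "D"  # 24-48
TM4_SEQ_SYNTHETIC = "P" + "LIV" + "P" + "ALIVGSAILVAGLIVAL" + "S"  # 254-276


def btl_helices(tm3_variant: str = "printed") -> tuple:
    """Default helix definitions for the four BTL transmembrane segments.

    Translation freedom follows the sampling protocol: TM1 may translate
    only along z (its centre of mass is otherwise fixed), TM2 along y and
    z, TM3 and TM4 along all three axes.  Topology alternates
    (TM1/TM3 N-termini extracellular, TM2/TM4 cytoplasmic).
    """
    if tm3_variant == "printed":
        tm3_seq, tm3_end = TM3_SEQ_PRINTED, 237
    elif tm3_variant == "range":
        tm3_seq, tm3_end = TM3_SEQ_RANGE, 238
    else:
        raise GeometryError(f"unknown tm3_variant {tm3_variant!r}")
    return (
        HelixSpec("TM1", TM1_SEQ_SYNTHETIC, 24, 48, frozenset("z"), "extracellular"),
        HelixSpec("TM2", TM2_SEQ, 75, 94, frozenset("yz"), "cytoplasmic"),
        HelixSpec("TM3", tm3_seq, 220, tm3_end, frozenset("xyz"), "extracellular"),
        HelixSpec("TM4", TM4_SEQ_SYNTHETIC, 254, 276, frozenset("xyz"), "cytoplasmic"),
    )


def enumerate_helix_pairs(specs: Sequence[HelixSpec]):
    """All unordered helix pairs (C(n,2) of them)."""
    return list(itertools.combinations([s.name for s in specs], 2))


# ---------------------------------------------------------------------------
# Bundle conformations and ensembles
# ---------------------------------------------------------------------------

_FLIP = np.diag([1.0, -1.0, -1.0])  # 180 deg about x: points N-terminus down


def place_helix(spec: HelixSpec, xy, axial_rotation: float = 0.0,
                **helix_kwargs) -> np.ndarray:
    """Ideal helix trace placed at in-plane position ``xy``, oriented by topology.

    Helices whose N-terminus faces the cytoplasm are flipped (180 deg
    about x) so the N-terminus sits at the lowest z.  ``axial_rotation``
    spins the helix about its own (z) axis before placement, in degrees.
    """
    coords = build_ideal_helix(spec, **helix_kwargs)
    if spec.n_term_side == "cytoplasmic":
        coords = coords @ _FLIP.T
    if axial_rotation:
        a = np.deg2rad(axial_rotation)
        rz = np.array([
            [np.cos(a), -np.sin(a), 0.0],
            [np.sin(a), np.cos(a), 0.0],
            [0.0, 0.0, 1.0],
        ])
        coords = coords @ rz.T
    coords = coords + np.array([xy[0], xy[1], 0.0])
    return coords


def square_positions(side: float) -> np.ndarray:
    """Corner positions of a square, clockwise from top-left viewed from +z."""
    h = side / 2.0
    return np.array([[-h, h], [h, h], [h, -h], [-h, -h]])


@dataclass
class BundleConformation:
    """C-alpha coordinates of all helices plus the transforms that made them.

    ``base_coords`` holds the untransformed placement of each helix (ideal
    trace at its site); current coordinates are always recomputed from the
    base so repeated moves never accumulate numerical drift.
    """

    specs: tuple
    base_coords: dict
    transforms: dict
    score: float | None = None

    def __post_init__(self):
        for spec in self.specs:
            c = self.base_coords[spec.name]
            if c.shape != (spec.n_residues, 3):
                raise GeometryError(
                    f"{spec.name}: coordinate shape {c.shape} does not match spec"
                )
            if not np.all(np.isfinite(c)):
                raise GeometryError(f"{spec.name}: non-finite coordinates")

    @property
    def coords(self) -> dict:
        """Current per-helix coordinates (transform applied to base)."""
        return {
            spec.name: apply_transform(
                self.base_coords[spec.name], self.transforms[spec.name], spec
            )
            for spec in self.specs
        }

    def stacked_coords(self) -> np.ndarray:
        coords = self.coords
        return np.concatenate([coords[s.name] for s in self.specs])

    def with_transform(self, name: str, t: RigidTransform) -> "BundleConformation":
        transforms = dict(self.transforms)
        transforms[name] = t
        return BundleConformation(self.specs, self.base_coords, transforms)

    def spec(self, name: str) -> HelixSpec:
        for s in self.specs:
            if s.name == name:
                return s
        raise KeyError(name)


def square_bundle(
    specs: Sequence[HelixSpec],
    side: float = 10.0,
    transforms: Mapping[str, RigidTransform] | None = None,
) -> BundleConformation:
    """Four helices on a square (spec order clockwise from top-left)."""
    specs = tuple(specs)
    pos = square_positions(side)
    base = {s.name: place_helix(s, pos[i]) for i, s in enumerate(specs)}
    tr = {s.name: IDENTITY for s in specs}
    if transforms:
        tr.update(transforms)
    return BundleConformation(specs, base, tr)


def helix_slices(specs: Sequence[HelixSpec]) -> dict:
    """Row slices of each helix inside a stacked coordinate array."""
    out, offset = {}, 0
    for s in specs:
        out[s.name] = slice(offset, offset + s.n_residues)
        offset += s.n_residues
    return out


@dataclass
class Ensemble:
    """A set of bundle conformations with shared helix definitions.

    ``coords`` has shape (n_conformations, n_atoms, 3) with helices
    stacked in spec order (see :func:`helix_slices`).
    """

    specs: tuple
    coords: np.ndarray
    scores: np.ndarray | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.coords = np.asarray(self.coords, float)
        n_atoms = sum(s.n_residues for s in self.specs)
        if self.coords.ndim != 3 or self.coords.shape[1:] != (n_atoms, 3):
            raise GeometryError(
                f"ensemble coords shape {self.coords.shape} does not match specs "
                f"({n_atoms} atoms expected)"
            )
        if self.scores is not None:
            self.scores = np.asarray(self.scores, float)
            if self.scores.shape != (len(self.coords),):
                raise GeometryError("scores length does not match ensemble size")

    def __len__(self) -> int:
        return len(self.coords)

    @property
    def slices(self) -> dict:
        return helix_slices(self.specs)

    def helix_coords(self, i: int) -> dict:
        sl = self.slices
        return {s.name: self.coords[i, sl[s.name]] for s in self.specs}

    def midpoints(self) -> np.ndarray:
        """Per-helix centroid of every conformation, (n, n_helices, 3)."""
        sl = self.slices
        return np.stack(
            [self.coords[:, sl[s.name]].mean(axis=1) for s in self.specs], axis=1
        )

    def subset(self, index) -> "Ensemble":
        index = np.asarray(index)
        scores = None if self.scores is None else self.scores[index]
        return Ensemble(self.specs, self.coords[index], scores, dict(self.metadata))
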