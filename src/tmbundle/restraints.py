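"""Scoring terms guiding bundle sampling and ranking.

All terms operate on C-alpha coordinates in the membrane frame and are
invariant under global rotation about z and global in-plane translation
(membrane symmetry).  Penalty terms are flat-bottom quadratics (zero
inside the allowed region); the packing term is a negative contact
reward; the residue-pair potential is a transparent knowledge-based
stand-in for a statistical helix-packing potential, with a fully
user-replaceable contact-energy table (the default favours hydrophobic
contacts via a Kyte-Doolittle sum).

No published weights exist for combining these terms; the defaults are
all 1.0 and every run records the weights it used in its metadata.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .geometry import (
    HELIX_RADIUS,
    BundleConformation,
    HelixSpec,
    principal_axis,
)

#: Kyte-Doolittle hydropathy scale (kcal-free units, positive = hydrophobic).
KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}

AA_ORDER = "ACDEFGHIKLMNPQRSTVWY"


def hydrophobicity_table(scale: Mapping[str, float] | None = None,
                         prefactor: float = -0.1) -> pd.DataFrame:
    """Default residue-pair contact-energy table.

    ``table[a, b] = prefactor * (scale[a] + scale[b])``; with the default
    negative prefactor, contacts between hydrophobic residues are
    rewarded (lower energy).  Any 20x20 table indexed by one-letter
    codes can be substituted.
    """
    scale = dict(scale or KYTE_DOOLITTLE)
    values = np.array([scale[a] for a in AA_ORDER])
    table = prefactor * (values[:, None] + values[None, :])
    return pd.DataFrame(table, index=list(AA_ORDER), columns=list(AA_ORDER))


@dataclass(frozen=True)
class InteractionPair:
    """Flat-bottom restraint on the axis-axis distance of a helix pair."""

    helix_i: str
    helix_j: str
    axis_distance_upper: float = 10.4  # Angstrom
    weight: float = 1.0


@dataclass(frozen=True)
class ContactRestraint:
    """Certainty-weighted flat-bottom restraint on one C-alpha contact."""

    resnum_i: int
    resnum_j: int
    distance_upper: float = 8.0  # Angstrom
    certainty: float = 1.0

    def __post_init__(self):
        if not 0.0 < self.certainty <= 1.0:
            raise ValueError("certainty must be in (0, 1]")


def btl_interaction_pairs() -> tuple:
    """Predicted interacting helix pairs of BTL (TM2-TM3 and TM1-TM4)."""
    return (InteractionPair("TM2", "TM3"), InteractionPair("TM1", "TM4"))


def btl_contact_restraints() -> tuple:
    """Predicted BTL residue contacts with their prediction certainties."""
    return (
        ContactRestraint(81, 223, certainty=1.00),   # Thr81-Gln223
        ContactRestraint(81, 224, certainty=0.96),   # Thr81-Cys224
        ContactRestraint(85, 222, certainty=0.82),   # Pro85-Val222
        ContactRestraint(76, 225, certainty=0.81),   # Cys76-Ala225
        ContactRestraint(43, 258, certainty=0.79),   # His43-Pro258
    )


@dataclass
class RestraintSet:
    """Weighted scoring terms for a helix bundle."""

    diameter_target: float = 26.0  # Angstrom
    diameter_weight: float = 1.0
    membrane_thickness: float = 30.0  # Angstrom
    clash_distance: float = 4.0  # Angstrom
    clash_weight: float = 1.0
    contact_window: tuple = (4.0, 6.5)  # Angstrom
    packing_weight: float = 1.0
    tilt_weight: float = 1.0
    depth_weight: float = 1.0
    interaction_weight: float = 1.0
    contact_weight: float = 1.0
    pair_potential_weight: float = 1.0
    interaction_pairs: tuple = dc_field(default_factory=btl_interaction_pairs)
    contact_restraints: tuple = dc_field(default_factory=btl_contact_restraints)
    pair_potential_table: pd.DataFrame | None = None
    axial_radius: float = HELIX_RADIUS

    def __post_init__(self):
        for name in ("diameter_weight", "clash_weight", "packing_weight",
                     "tilt_weight", "depth_weight", "interaction_weight",
                     "contact_weight", "pair_potential_weight"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.pair_potential_table is None:
            self.pair_potential_table = hydrophobicity_table()
        self.interaction_pairs = tuple(self.interaction_pairs)
        self.contact_restraints = tuple(self.contact_restraints)

    # -- term evaluations ---------------------------------------------------

    def diameter_score(self, coords: Mapping[str, np.ndarray]) -> float:
        """Quadratic penalty on bundle diameter above the target.

        Diameter = largest in-plane distance between helix midpoints plus
        twice the helical radius.
        """
        names = list(coords)
        if len(names) < 2:
            raise ValueError("diameter restraint needs at least 2 helices")
        mids = np.array([coords[n].mean(axis=0)[:2] for n in names])
        dmax = max(
            float(np.linalg.norm(mids[i] - mids[j]))
            for i in range(len(mids)) for j in range(i + 1, len(mids))
        )
        diameter = dmax + 2.0 * self.axial_radius
        return self.diameter_weight * max(0.0, diameter - self.diameter_target) ** 2

    def excluded_volume_score(self, coords: Mapping[str, np.ndarray]) -> float:
        """Quadratic clash penalty for inter-helix C-alpha pairs closer than
        ``clash_distance``."""
        total = 0.0
        names = list(coords)
        for i in range(len(names)):
            for j in range(i + 1, len(names)):
                d = cdist(coords[names[i]], coords[names[j]])
                close = d[d < self.clash_distance]
                if close.size:
                    total += float(np.sum((self.clash_distance - close) ** 2))
        return self.clash_weight * total

    def packing_score(self, coords: Mapping[str, np.ndarray]) -> float:
        """Contact reward: minus the number of inter-helix C-alpha pairs
        inside the contact window."""
        lo, hi = self.contact_window
        count = 0
        names = list(coords)
        for i in range(len(names)):
            for j in range(i + 1, len(names)):
                d = cdist(coords[names[i]], coords[names[j]])
                count += int(np.count_nonzero((d >= lo) & (d <= hi)))
        return -self.packing_weight * count

    def tilt_depth_score(self, coords: Mapping[str, np.ndarray],
                         specs: Sequence[HelixSpec]) -> float:
        """Tilt and membrane-span (depth) penalties per helix.

        The maximum tilt a helix can afford is set by its length:
        ``tilt_max = arccos(min(1, thickness / length))`` (a helix shorter
        than the membrane cannot tilt without losing span).  Tilts beyond
        the limit incur a harmonic penalty (in squared radians).  The
        depth term penalises the squared deficit by which the helix axis
        z-extent (length * cos(tilt), centred on the helix midpoint)
        fails to reach +/- thickness/2; helices longer than the membrane
        can shift by their slack before being penalised.
        """
        half = self.membrane_thickness / 2.0
        total = 0.0
        for spec in specs:
            c = coords[spec.name]
            length = spec.helix_length_A
            axis = principal_axis(c)
            cos_tilt = float(np.clip(abs(axis[2]), -1.0, 1.0))
            tilt = float(np.degrees(np.arccos(cos_tilt)))
            tilt_max = float(np.degrees(np.arccos(min(1.0, self.membrane_thickness / length)))) \
                if length > 0 else 0.0
            if tilt > tilt_max:
                total += self.tilt_weight * (np.deg2rad(tilt - tilt_max)) ** 2
            z_center = float(c[:, 2].mean())
            z_top = z_center + 0.5 * length * cos_tilt
            z_bot = z_center - 0.5 * length * cos_tilt
            total += self.depth_weight * (
                max(0.0, half - z_top) ** 2 + max(0.0, z_bot + half) ** 2
            )
        return total

    def interaction_score(self, coords: Mapping[str, np.ndarray],
                          specs: Sequence[HelixSpec]) -> float:
        """Flat-bottom restraints on predicted helix-helix interactions.

        Per interaction pair: penalty on the minimal axis-axis distance
        above the pair's upper bound.  Per residue contact: certainty-
        weighted penalty on the C-alpha distance above its upper bound.
        """
        total = 0.0
        for pair in self.interaction_pairs:
            d = _axis_segment_distance(coords[pair.helix_i], coords[pair.helix_j])
            total += (self.interaction_weight * pair.weight
                      * max(0.0, d - pair.axis_distance_upper) ** 2)
        if self.contact_restraints:
            lookup = _residue_lookup(specs)
            for c in self.contact_restraints:
                (hi, ii), (hj, ij) = lookup[c.resnum_i], lookup[c.resnum_j]
                d = float(np.linalg.norm(coords[hi][ii] - coords[hj][ij]))
                total += (self.contact_weight * c.certainty
                          * max(0.0, d - c.distance_upper) ** 2)
        return total

    def pair_potential_score(self, coords: Mapping[str, np.ndarray],
                             specs: Sequence[HelixSpec]) -> float:
        """Residue-type contact potential summed over inter-helix pairs
        within the contact window."""
        lo, hi = self.contact_window
        table = self.pair_potential_table.reindex(
            index=list(AA_ORDER), columns=list(AA_ORDER)
        ).to_numpy()
        aa_index = {a: k for k, a in enumerate(AA_ORDER)}
        codes = {
            s.name: np.array([aa_index[a] for a in s.sequence]) for s in specs
        }
        total = 0.0
        names = [s.name for s in specs]
        for a in range(len(names)):
            for b in range(a + 1, len(names)):
                d = cdist(coords[names[a]], coords[names[b]])
                ii, jj = np.nonzero((d >= lo) & (d <= hi))
                if ii.size:
                    total += float(table[codes[names[a]][ii], codes[names[b]][jj]].sum())
        return self.pair_potential_weight * total

    # -- aggregation --------------------------------------------------------

    def breakdown(self, conf_or_coords, specs: Sequence[HelixSpec] | None = None) -> dict:
        """Per-term score values plus their sum (key ``"total"``)."""
        if isinstance(conf_or_coords, BundleConformation):
            coords = conf_or_coords.coords
            specs = conf_or_coords.specs
        else:
            coords = conf_or_coords
            if specs is None:
                raise ValueError("specs required when passing raw coordinates")
        terms = {
            "diameter": self.diameter_score(coords),
            "excluded_volume": self.excluded_volume_score(coords),
            "packing": self.packing_score(coords),
            "tilt_depth": self.tilt_depth_score(coords, specs),
            "interaction": self.interaction_score(coords, specs),
            "pair_potential": self.pair_potential_score(coords, specs),
        }
        terms["total"] = float(sum(terms.values()))
        return terms

    def total_score(self, conf_or_coords, specs: Sequence[HelixSpec] | None = None) -> float:
        return self.breakdown(conf_or_coords, specs)["total"]

    def scorer(self, specs: Sequence[HelixSpec]):
        """Closure ``f(coords, transforms) -> float`` for the MC sampler."""
        def score(coords, transforms=None):
            return self.total_score(coords, specs)
        return score

    def to_metadata(self) -> dict:
        """JSON-serialisable record of every parameter (for run outputs)."""
        d = asdict(self)
        d["pair_potential_table"] = "custom" \
            if not self.pair_potential_table.equals(hydrophobicity_table()) \
            else "hydrophobicity_sum(kyte_doolittle, prefactor=-0.1)"
        return d


def _residue_lookup(specs: Sequence[HelixSpec]) -> dict:
    """Map UniProt residue number -> (helix name, index within helix)."""
    lookup = {}
    for s in specs:
        for idx, resnum in enumerate(s.resnums):
            lookup[int(resnum)] = (s.name, idx)
    return lookup


def _axis_segment_distance(coords_a: np.ndarray, coords_b: np.ndarray) -> float:
    """Minimal distance between the axis segments of two helices.

    Each axis segment spans the projections of the trace onto its
    principal axis through the centroid.
    """
    p1, d1 = _axis_segment(coords_a)
    p2, d2 = _axis_segment(coords_b)
    return _segment_segment_distance(p1, p1 + d1, p2, p2 + d2)


def _axis_segment(coords: np.ndarray):
    c = coords.mean(axis=0)
    u = principal_axis(coords)
    proj = (coords - c) @ u
    start = c + proj.min() * u
    return start, (proj.max() - proj.min()) * u


def _segment_segment_distance(p1, q1, p2, q2) -> float:
    """Minimum distance between 3D segments [p1,q1] and [p2,q2]."""
    d1, d2 = q1 - p1, q2 - p2
    r = p1 - p2
    a, e, f = d1 @ d1, d2 @ d2, d2 @ r
    eps = 1e-12
    if a <= eps and e <= eps:
        return float(np.linalg.norm(r))
    if a <= eps:
        s, t = 0.0, np.clip(f / e, 0.0, 1.0)
    else:
        c = d1 @ r
        if e <= eps:
            t, s = 0.0, np.clip(-c / a, 0.0, 1.0)
        else:
            b = d1 @ d2
            denom = a * e - b * b
            s = np.clip((b * f - c * e) / denom, 0.0, 1.0) if denom > eps else 0.0
            t = (b * s + f) / e
            if t < 0.0:
                t, s = 0.0, np.clip(-c / a, 0.0, 1.0)
            elif t > 1.0:
                t, s = 1.0, np.clip((b - c) / a, 0.0, 1.0)
    closest1 = p1 + s * d1
    closest2 = p2 + t * d2
    return float(np.linalg.norm(closest1 - closest2))
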