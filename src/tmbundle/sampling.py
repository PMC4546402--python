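"""Metropolis Monte Carlo sampling of bundle configurations.

A move perturbs one randomly chosen helix by one randomly chosen move
type — axial rotation, tilt, or translation along one of the helix's
allowed axes — with uniform step draws.  Acceptance follows the
Metropolis rule exp(-dE/T) under a varying-temperature schedule
(default: a geometric annealing ladder from 5.0 down to 0.2 in ten
rungs, repeated for every restart).  Every run requires a seed and is
bit-reproducible from (seed, config).

Energies are the restraint scores; temperatures are in the same
arbitrary energy units.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np

from .geometry import (
    BundleConformation,
    Ensemble,
    HelixSpec,
    RigidTransform,
    apply_transform,
    square_bundle,
)


class MonteCarloError(RuntimeError):
    """Sampling failure (e.g. non-finite score encountered)."""


def annealing_schedule(t_high: float = 5.0, t_low: float = 0.2,
                       n_rungs: int = 10, steps_per_rung: int = 1000):
    """Geometric temperature ladder from ``t_high`` down to ``t_low``."""
    temps = np.geomspace(t_high, t_low, n_rungs)
    return [(float(t), int(steps_per_rung)) for t in temps]


@dataclass
class MCConfig:
    """Monte Carlo run configuration.

    ``temperature_schedule`` is a list of (temperature, n_steps) pairs
    executed in order within each restart.  The seed is mandatory:
    unseeded runs are not reproducible and are refused.
    """

    seed: int
    temperature_schedule: list = field(
        default_factory=lambda: annealing_schedule()
    )
    record_stride: int = 10
    axial_rotation_max: float = 30.0  # degrees
    tilt_step_max: float = 5.0  # degrees
    translation_step_max: float = 1.0  # Angstrom
    n_restarts: int = 1

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("MCConfig requires an explicit seed")
        for t, n in self.temperature_schedule:
            if t <= 0:
                raise ValueError("temperatures must be > 0")
            if n < 0:
                raise ValueError("step counts must be >= 0")
        if min(self.axial_rotation_max, self.tilt_step_max,
               self.translation_step_max) < 0:
            raise ValueError("move amplitudes must be >= 0")
        if self.record_stride < 1:
            raise ValueError("record_stride must be >= 1")

    @property
    def n_steps(self) -> int:
        return sum(n for _, n in self.temperature_schedule)


def propose_move(conf: BundleConformation, rng: np.random.Generator,
                 config: MCConfig) -> BundleConformation:
    """One elementary move: perturb one helix by one move type.

    The helix and the move type (axial rotation / tilt / translation)
    are drawn uniformly; translations only ever touch the helix's
    allowed axes.  Tilt moves perturb the tilt vector components (polar
    angle times the in-plane direction), which keeps the proposal
    symmetric around zero tilt.
    """
    spec = conf.specs[rng.integers(len(conf.specs))]
    proposal = _propose_single(conf.transforms, spec, rng, config)
    if proposal is None:
        return conf
    return conf.with_transform(*proposal)


def randomize_transforms(specs: Sequence[HelixSpec], rng: np.random.Generator,
                         tilt_max: float = 10.0, translation_max: float = 2.0) -> dict:
    """Random initial transforms drawn from the seeded stream.

    Axial rotations are uniform over the full circle; tilts are drawn as
    a uniform tilt vector inside ``tilt_max`` degrees; translations are
    uniform within ``translation_max`` Angstrom on each allowed axis.
    """
    out = {}
    for spec in specs:
        axial = rng.uniform(-180.0, 180.0)
        tx, ty = rng.uniform(-tilt_max, tilt_max, size=2)
        tr = [0.0, 0.0, 0.0]
        for k, axis in enumerate("xyz"):
            if axis in spec.allowed_axes:
                tr[k] = rng.uniform(-translation_max, translation_max)
        out[spec.name] = RigidTransform.from_tilt_vector(axial, tx, ty, tuple(tr))
    return out


def initial_bundle(specs: Sequence[HelixSpec], rng: np.random.Generator,
                   side: float = 10.0) -> BundleConformation:
    """Ideal helices on a square with randomized starting transforms."""
    return square_bundle(specs, side=side,
                         transforms=randomize_transforms(specs, rng))


ScoreFn = Callable[[dict, dict], float]


def run_mc(initial: BundleConformation, scorer: ScoreFn, config: MCConfig) -> Ensemble:
    """Metropolis Monte Carlo run under the given score function.

    ``scorer(coords, transforms)`` maps the current per-helix coordinate
    dict (and transform dict, for toy/diagnostic scorers) to an energy.
    Every ``record_stride``-th visited conformation is recorded, so the
    ensemble holds ``floor(n_steps / record_stride) * n_restarts``
    members.  Restarts beyond the first re-randomize the starting
    transforms from the same seeded stream.
    """
    rng = np.random.default_rng(config.seed)
    specs = initial.specs
    recorded, scores = [], []
    order = [s.name for s in specs]

    for restart in range(config.n_restarts):
        if restart == 0:
            transforms = dict(initial.transforms)
        else:
            transforms = randomize_transforms(specs, rng)
        coords = {
            s.name: apply_transform(initial.base_coords[s.name], transforms[s.name], s)
            for s in specs
        }
        energy = float(scorer(coords, transforms))
        if not math.isfinite(energy):
            raise MonteCarloError(
                f"non-finite initial score {energy!r} (restart {restart})"
            )
        step_counter = 0
        for temperature, n_steps in config.temperature_schedule:
            spec_map = {s.name: s for s in specs}
            for _ in range(n_steps):
                spec = specs[rng.integers(len(specs))]
                proposal = _propose_single(transforms, spec, rng, config)
                if proposal is not None:
                    name, new_t = proposal
                    new_coords = dict(coords)
                    new_coords[name] = apply_transform(
                        initial.base_coords[name], new_t, spec_map[name]
                    )
                    new_energy = float(scorer(new_coords, {**transforms, name: new_t}))
                    if not math.isfinite(new_energy):
                        raise MonteCarloError(
                            f"non-finite score {new_energy!r} at step {step_counter}"
                        )
                    d_e = new_energy - energy
                    if d_e <= 0 or rng.random() < math.exp(
                        -min(d_e / temperature, 700.0)
                    ):
                        transforms = {**transforms, name: new_t}
                        coords = new_coords
                        energy = new_energy
                step_counter += 1
                if step_counter % config.record_stride == 0:
                    recorded.append(
                        np.concatenate([coords[n] for n in order])
                    )
                    scores.append(energy)

    coords_arr = (np.array(recorded) if recorded
                  else np.empty((0, sum(s.n_residues for s in specs), 3)))
    metadata = {
        "seed": config.seed,
        "n_steps": config.n_steps,
        "record_stride": config.record_stride,
        "n_restarts": config.n_restarts,
        "temperature_schedule": [list(x) for x in config.temperature_schedule],
    }
    return Ensemble(specs, coords_arr, np.array(scores, float), metadata)


def _propose_single(transforms: dict, spec: HelixSpec,
                    rng: np.random.Generator, config: MCConfig):
    """Draw one move for a pre-selected helix; returns (name, transform)."""
    t = transforms[spec.name]
    move = rng.integers(3)
    if move == 0:
        delta = rng.uniform(-config.axial_rotation_max, config.axial_rotation_max)
        return spec.name, replace(t, axial_rotation=t.axial_rotation + delta)
    if move == 1:
        tx, ty = t.tilt_vector
        tx += rng.uniform(-config.tilt_step_max, config.tilt_step_max)
        ty += rng.uniform(-config.tilt_step_max, config.tilt_step_max)
        return spec.name, RigidTransform.from_tilt_vector(
            t.axial_rotation, tx, ty, t.translation
        )
    axes = sorted(spec.allowed_axes)
    if not axes:
        return None
    axis = axes[rng.integers(len(axes))]
    k = "xyz".index(axis)
    tr = list(t.translation)
    tr[k] += rng.uniform(-config.translation_step_max, config.translation_step_max)
    return spec.name, replace(t, translation=tuple(tr))
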