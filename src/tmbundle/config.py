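"""Pipeline configuration: YAML/JSON loading with strict validation.

Unknown keys are rejected so that typos never silently fall back to
defaults; every run writes the fully resolved configuration (plus seed
and package version) into its output metadata.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .geometry import HelixSpec, btl_helices
from .restraints import ContactRestraint, InteractionPair, RestraintSet
from .sampling import MCConfig, annealing_schedule


class ConfigError(ValueError):
    """Invalid pipeline configuration."""


_HELIX_KEYS = {"name", "sequence", "start", "end", "allowed_axes", "n_term_side"}
_MC_KEYS = {"t_high", "t_low", "n_rungs", "steps_per_rung", "record_stride",
            "axial_rotation_max", "tilt_step_max", "translation_step_max",
            "n_restarts"}
_RESTRAINT_KEYS = {
    "diameter_target", "diameter_weight", "membrane_thickness",
    "clash_distance", "clash_weight", "contact_window", "packing_weight",
    "tilt_weight", "depth_weight", "interaction_weight", "contact_weight",
    "pair_potential_weight", "interaction_pairs", "contact_restraints",
}
_TOP_KEYS = {"helices", "restraints", "mc", "clustering_cutoff", "top_k",
             "initial_side", "crossing_angle_max", "seed", "tm3_variant"}


@dataclass
class PipelineConfig:
    """Resolved configuration for the end-to-end bundle pipeline."""

    specs: tuple
    restraints: RestraintSet
    mc: MCConfig
    clustering_cutoff: float = 2.0
    top_k: int = 100
    initial_side: float = 10.0
    crossing_angle_max: float = 40.0
    seed: int = 0

    def to_metadata(self) -> dict:
        return {
            "helices": [
                {
                    "name": s.name, "sequence": s.sequence,
                    "start": int(s.start_resnum), "end": int(s.end_resnum),
                    "allowed_axes": sorted(s.allowed_axes),
                    "n_term_side": s.n_term_side,
                }
                for s in self.specs
            ],
            "restraints": self.restraints.to_metadata(),
            "mc": {
                "seed": self.mc.seed,
                "temperature_schedule": [list(x) for x in self.mc.temperature_schedule],
                "record_stride": self.mc.record_stride,
                "axial_rotation_max": self.mc.axial_rotation_max,
                "tilt_step_max": self.mc.tilt_step_max,
                "translation_step_max": self.mc.translation_step_max,
                "n_restarts": self.mc.n_restarts,
            },
            "clustering_cutoff": self.clustering_cutoff,
            "top_k": self.top_k,
            "initial_side": self.initial_side,
            "crossing_angle_max": self.crossing_angle_max,
            "seed": self.seed,
        }


def _check_keys(mapping: dict, allowed: set, context: str) -> None:
    unknown = set(mapping) - allowed
    if unknown:
        raise ConfigError(f"{context}: unknown keys {sorted(unknown)}")


def _parse_helix(entry: dict) -> HelixSpec:
    _check_keys(entry, _HELIX_KEYS, f"helix {entry.get('name', '?')}")
    for key in ("name", "sequence", "start", "end"):
        if key not in entry:
            raise ConfigError(f"helix entry missing {key!r}")
    return HelixSpec(
        entry["name"], entry["sequence"], int(entry["start"]), int(entry["end"]),
        frozenset(entry.get("allowed_axes", "xyz")),
        entry.get("n_term_side", "extracellular"),
    )


def load_config(path_or_mapping, seed: int | None = None) -> PipelineConfig:
    """Load and validate a pipeline configuration.

    Accepts a YAML/JSON file path or an already-parsed mapping.  A
    ``seed`` argument overrides the config's seed; one of the two must
    be present (stages that draw randomness refuse to run unseeded).
    """
    if isinstance(path_or_mapping, (str, Path)):
        text = Path(path_or_mapping).read_text()
        raw = yaml.safe_load(text)
    else:
        raw = dict(path_or_mapping)
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError("top-level config must be a mapping")
    _check_keys(raw, _TOP_KEYS, "config")

    if seed is None:
        seed = raw.get("seed")
    if seed is None:
        raise ConfigError("a seed is required (config key 'seed' or --seed)")
    seed = int(seed)

    if "helices" in raw:
        specs = tuple(_parse_helix(e) for e in raw["helices"])
    else:
        specs = btl_helices(raw.get("tm3_variant", "printed"))

    r_raw = dict(raw.get("restraints", {}))
    _check_keys(r_raw, _RESTRAINT_KEYS, "restraints")
    if "interaction_pairs" in r_raw:
        r_raw["interaction_pairs"] = tuple(
            InteractionPair(p["helix_i"], p["helix_j"],
                            p.get("axis_distance_upper", 10.4),
                            p.get("weight", 1.0))
            for p in r_raw["interaction_pairs"]
        )
    if "contact_restraints" in r_raw:
        r_raw["contact_restraints"] = tuple(
            ContactRestraint(c["resnum_i"], c["resnum_j"],
                             c.get("distance_upper", 8.0),
                             c.get("certainty", 1.0))
            for c in r_raw["contact_restraints"]
        )
    if "contact_window" in r_raw:
        r_raw["contact_window"] = tuple(r_raw["contact_window"])
    restraints = RestraintSet(**r_raw)

    m_raw = dict(raw.get("mc", {}))
    _check_keys(m_raw, _MC_KEYS, "mc")
    schedule = annealing_schedule(
        m_raw.pop("t_high", 5.0), m_raw.pop("t_low", 0.2),
        int(m_raw.pop("n_rungs", 10)), int(m_raw.pop("steps_per_rung", 1000)),
    )
    mc = MCConfig(seed=seed, temperature_schedule=schedule, **m_raw)

    return PipelineConfig(
        specs=specs, restraints=restraints, mc=mc,
        clustering_cutoff=float(raw.get("clustering_cutoff", 2.0)),
        top_k=int(raw.get("top_k", 100)),
        initial_side=float(raw.get("initial_side", 10.0)),
        crossing_angle_max=float(raw.get("crossing_angle_max", 40.0)),
        seed=seed,
    )


def dump_metadata(config: PipelineConfig, path) -> None:
    Path(path).write_text(json.dumps(config.to_metadata(), indent=2))
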