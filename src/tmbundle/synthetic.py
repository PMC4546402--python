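"""Seeded synthetic-data generators with recorded ground truth.

Every generator takes an explicit seed, is bit-reproducible from
(seed, parameters), and returns a :class:`SyntheticTruth` record
alongside its data; file-writing helpers place the truth in a JSON
sidecar next to the data file.

The generators emulate the study conditions of the analysis stages:
helix-bundle ensembles with planted arrangement labels or planted
cluster structure, 15N relaxation tables drawn from the isotropic
model-free spectral density, and FRET titrations from the 1:1 quadratic
binding isotherm.  Noise on rates and emission ratios is multiplicative
Gaussian, reflecting how NMR and fluorescence uncertainties are
typically reported (switch to additive via ``noise_mode``).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import modelfree
from .geometry import (
    Ensemble,
    HelixSpec,
    btl_helices,
    helix_slices,
    place_helix,
    square_positions,
)
from .titration import binding_model


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth record emitted by every generator."""

    generator: str
    seed: int
    params: dict

    @property
    def provenance(self) -> str:
        return f"tmbundle.synthetic.{self.generator}(seed={self.seed})"

    def to_json(self, path) -> None:
        payload = {
            "generator": self.generator,
            "seed": self.seed,
            "params": _jsonable(self.params),
            "provenance": self.provenance,
        }
        Path(path).write_text(json.dumps(payload, indent=2))


def _jsonable(obj):
    if isinstance(obj, Mapping):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def _apply_noise(values: np.ndarray, noise_frac: float,
                 rng: np.random.Generator, noise_mode: str) -> np.ndarray:
    if noise_frac < 0:
        raise ValueError("noise_frac must be >= 0")
    if noise_frac == 0:
        return np.asarray(values, float).copy()
    z = rng.standard_normal(np.shape(values))
    if noise_mode == "multiplicative":
        return values * (1.0 + noise_frac * z)
    if noise_mode == "additive":
        return values + noise_frac * z
    raise ValueError(f"unknown noise_mode {noise_mode!r}")


# ---------------------------------------------------------------------------
# Bundle ensembles
# ---------------------------------------------------------------------------

def _bundle_coords_for_label(specs: Sequence[HelixSpec], label: str,
                             side: float, rotations=None) -> np.ndarray:
    """Four helices on a square in the clockwise order given by ``label``.

    ``label`` is a cyclic order of the letters A.. (A = first helix in
    ``specs``); letter k of the label occupies the k-th clockwise corner
    (from top-left, viewed from the extracellular side).  ``rotations``
    optionally gives one axial-rotation angle (degrees) per helix.
    """
    corners = square_positions(side)
    if rotations is None:
        rotations = np.zeros(len(specs))
    coords = [None] * len(specs)
    for corner_idx, letter in enumerate(label):
        helix_idx = ord(letter) - ord("A")
        coords[helix_idx] = place_helix(
            specs[helix_idx], corners[corner_idx],
            axial_rotation=float(rotations[helix_idx]),
        )
    return np.concatenate(coords)


def gen_bundle_ensemble(n: int, label_probs: Mapping[str, float] | None = None,
                        jitter_A: float = 0.3, seed: int = 0,
                        specs: Sequence[HelixSpec] | None = None,
                        side_range=(9.0, 11.0)):
    """Ensemble of square-packed bundles with planted arrangement labels.

    For each conformation an arrangement label is drawn from
    ``label_probs`` (uniform over the six types by default), the helices
    are placed on a square with side drawn uniformly from
    ``side_range`` with uniformly random axial rotations (as the
    sampling stage would produce), and Gaussian coordinate jitter of
    scale ``jitter_A`` is added.  Returns (ensemble, labels, truth).
    """
    from .analysis import enumerate_arrangements  # local import, no cycle at module load

    specs = tuple(specs) if specs is not None else btl_helices()
    if label_probs is None:
        labels_all = enumerate_arrangements(len(specs))
        probs = np.full(len(labels_all), 1.0 / len(labels_all))
    else:
        labels_all = list(label_probs)
        probs = np.array([label_probs[l] for l in labels_all], float)
        if not np.isclose(probs.sum(), 1.0):
            raise ValueError("label probabilities must sum to 1")
    rng = np.random.default_rng(seed)
    n_atoms = sum(s.n_residues for s in specs)
    coords = np.empty((n, n_atoms, 3))
    drawn = rng.choice(labels_all, size=n, p=probs)
    for i, label in enumerate(drawn):
        side = rng.uniform(*side_range)
        rotations = rng.uniform(0.0, 360.0, size=len(specs))
        base = _bundle_coords_for_label(specs, label, side, rotations)
        coords[i] = base + jitter_A * rng.standard_normal(base.shape)
    truth = SyntheticTruth("gen_bundle_ensemble", seed, {
        "n": n, "labels": drawn, "jitter_A": jitter_A,
        "side_range": list(side_range),
        "label_probs": {l: float(p) for l, p in zip(labels_all, probs)},
    })
    ens = Ensemble(specs, coords, metadata={"provenance": truth.provenance})
    return ens, np.asarray(drawn), truth


def gen_clustered_confs(k: int, separation_A: float = 20.0, spread_A: float = 0.5,
                        n_per_cluster: int = 10, seed: int = 0,
                        specs: Sequence[HelixSpec] | None = None):
    """Ensemble with planted cluster structure.

    ``k`` reference conformations are spaced ``separation_A`` apart in
    RMSD (rigid x-shifts of a square bundle); each gets
    ``n_per_cluster`` copies with per-coordinate Gaussian jitter of
    scale ``spread_A / sqrt(3)``, so the typical member-to-reference
    RMSD is about ``spread_A``.  Returns (ensemble, cluster_ids, truth).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    specs = tuple(specs) if specs is not None else btl_helices()
    rng = np.random.default_rng(seed)
    base = _bundle_coords_for_label(specs, "ABCD", 10.0)
    coords, ids = [], []
    for j in range(k):
        ref = base + np.array([j * separation_A, 0.0, 0.0])
        for _ in range(n_per_cluster):
            noise = (spread_A / np.sqrt(3.0)) * rng.standard_normal(ref.shape) \
                if spread_A > 0 else 0.0
            coords.append(ref + noise)
            ids.append(j)
    truth = SyntheticTruth("gen_clustered_confs", seed, {
        "k": k, "separation_A": separation_A, "spread_A": spread_A,
        "n_per_cluster": n_per_cluster,
    })
    ens = Ensemble(specs, np.array(coords), metadata={"provenance": truth.provenance})
    return ens, np.array(ids), truth


# ---------------------------------------------------------------------------
# Relaxation and titration datasets
# ---------------------------------------------------------------------------

def gen_relaxation(residue_params: Sequence[tuple], tau_m: float,
                   field: float = 18.8, noise_frac: float = 0.02,
                   seed: int = 0, noise_mode: str = "multiplicative"):
    """Synthetic per-residue 15N relaxation table from model-free truth.

    ``residue_params`` is a sequence of (residue_label, S2, tau_e_seconds);
    all residues share the overall correlation time ``tau_m`` (seconds).
    Rates come from :func:`tmbundle.modelfree.predict_rates` with
    multiplicative Gaussian noise of fractional size ``noise_frac``;
    the nominal noise level is recorded in the ``*_err`` columns.
    Returns (DataFrame, truth).
    """
    rng = np.random.default_rng(seed)
    rows = []
    for label, s2, tau_e in residue_params:
        r1, r2, noe = modelfree.predict_rates(s2, tau_e, tau_m, field)
        rows.append((label, r1, r2, noe))
    df = pd.DataFrame(rows, columns=["residue", "R1", "R2", "NOE"])
    clean = df[["R1", "R2", "NOE"]].to_numpy()
    noisy = _apply_noise(clean, noise_frac, rng, noise_mode)
    df[["R1", "R2", "NOE"]] = noisy
    for col in ("R1", "R2", "NOE"):
        df[f"{col}_err"] = noise_frac * np.abs(clean[:, ["R1", "R2", "NOE"].index(col)]) \
            if noise_frac > 0 else 0.0
    truth = SyntheticTruth("gen_relaxation", seed, {
        "residue_params": [
            {"residue": label, "S2": s2, "tau_e": tau_e}
            for label, s2, tau_e in residue_params
        ],
        "tau_m": tau_m, "field": field,
        "noise_frac": noise_frac, "noise_mode": noise_mode,
    })
    return df, truth


def gen_titration(kd: float, d_total: float = 50.0,
                  conc_grid: Sequence[float] | None = None,
                  r_free: float = 1.0, r_bound: float = 0.3,
                  noise_frac: float = 0.03, seed: int = 0,
                  noise_mode: str = "multiplicative"):
    """Synthetic FRET titration from the 1:1 quadratic isotherm.

    ``conc_grid`` defaults to 12 points spanning 0-1000 uM.  Returns
    (DataFrame with conc_uM / ratio / err, truth); concentrations are
    strictly increasing.
    """
    if conc_grid is None:
        conc_grid = np.linspace(0.0, 1000.0, 12)
    conc = np.asarray(conc_grid, float)
    if np.any(np.diff(conc) <= 0):
        raise ValueError("concentration grid must be strictly increasing")
    rng = np.random.default_rng(seed)
    clean = binding_model(kd, d_total, conc, r_free, r_bound)
    ratio = _apply_noise(clean, noise_frac, rng, noise_mode)
    df = pd.DataFrame({
        "conc_uM": conc,
        "ratio": ratio,
        "err": noise_frac * np.abs(clean) if noise_frac > 0 else 0.0,
    })
    truth = SyntheticTruth("gen_titration", seed, {
        "kd": kd, "d_total": d_total, "r_free": r_free, "r_bound": r_bound,
        "conc_grid": conc, "noise_frac": noise_frac, "noise_mode": noise_mode,
    })
    return df, truth


# ---------------------------------------------------------------------------
# File output with truth sidecars
# ---------------------------------------------------------------------------

def write_with_truth(df: pd.DataFrame, truth: SyntheticTruth, path) -> Path:
    """Write a generated table as CSV with its truth JSON sidecar."""
    path = Path(path)
    df.to_csv(path, index=False)
    truth.to_json(path.with_suffix(path.suffix + ".truth.json"))
    return path
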