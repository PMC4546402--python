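"""Multi-model PDB reading/writing for C-alpha bundle models.

Models are written with one chain per helix (A-D for the first four
helices), CA-only ATOM records, occupancy 1.00 and element C, wrapped in
MODEL/ENDMDL records.  The reader accepts exactly this subset and
reports parse failures with the offending line number.  Coordinates
round-trip to the PDB precision of 1e-3 Angstrom.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np

from .geometry import AA_1TO3, AA_3TO1, Ensemble, HelixSpec

CHAIN_IDS = "ABCDEFGH"


class PdbParseError(ValueError):
    """Malformed PDB input; carries the 1-based line number."""

    def __init__(self, line_number: int, message: str):
        self.line_number = line_number
        super().__init__(f"line {line_number}: {message}")


def write_pdb(path, ensemble_or_coords, specs: Sequence[HelixSpec] | None = None,
              scores=None) -> Path:
    """Write conformations as a CA-only multi-model PDB file.

    Accepts an :class:`~tmbundle.geometry.Ensemble`, a single (n_atoms, 3)
    array, or an (n_models, n_atoms, 3) stack (the latter two require
    ``specs``).  Scores, when present, are recorded as per-model REMARK
    records.
    """
    if isinstance(ensemble_or_coords, Ensemble):
        coords = ensemble_or_coords.coords
        specs = ensemble_or_coords.specs
        if scores is None:
            scores = ensemble_or_coords.scores
    else:
        coords = np.asarray(ensemble_or_coords, float)
        if coords.ndim == 2:
            coords = coords[None]
        if specs is None:
            raise ValueError("specs required when writing raw coordinates")
    path = Path(path)
    with path.open("w") as fh:
        for m, model in enumerate(coords, start=1):
            fh.write(f"MODEL     {m:4d}\n")
            if scores is not None:
                fh.write(f"REMARK 250 SCORE {float(scores[m - 1]):.6f}\n")
            serial = 1
            offset = 0
            for h, spec in enumerate(specs):
                chain = CHAIN_IDS[h]
                for i in range(spec.n_residues):
                    x, y, z = model[offset + i]
                    resname = AA_1TO3[spec.sequence[i]]
                    resnum = spec.start_resnum + i
                    fh.write(
                        f"ATOM  {serial:5d}  CA  {resname} {chain}{resnum:4d}    "
                        f"{x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{0.00:6.2f}"
                        f"          {'C':>2s}\n"
                    )
                    serial += 1
                offset += spec.n_residues
                fh.write("TER\n")
            fh.write("ENDMDL\n")
        fh.write("END\n")
    return path


def read_pdb(path):
    """Read a CA-only multi-model PDB file.

    Returns ``(coords, chains)`` where ``coords`` is an
    (n_models, n_atoms, 3) array and ``chains`` is a list of
    ``(chain_id, resnums, one_letter_sequence)`` tuples describing the
    shared chain layout.  Raises :class:`PdbParseError` with the line
    number on malformed input.
    """
    models = []
    current: list | None = None
    layout: list | None = None
    current_layout: list = []
    with Path(path).open() as fh:
        for lineno, line in enumerate(fh, start=1):
            record = line[:6].strip()
            if record == "MODEL":
                if current is not None:
                    raise PdbParseError(lineno, "nested MODEL record")
                current, current_layout = [], []
            elif record == "ENDMDL":
                if current is None:
                    raise PdbParseError(lineno, "ENDMDL without MODEL")
                if layout is None:
                    layout = current_layout
                elif current_layout != layout:
                    raise PdbParseError(lineno, "models differ in chain layout")
                models.append(current)
                current = None
            elif record == "ATOM":
                if current is None:
                    raise PdbParseError(lineno, "ATOM record outside MODEL")
                if line[12:16].strip() != "CA":
                    raise PdbParseError(
                        lineno, f"expected CA atom, got {line[12:16].strip()!r}"
                    )
                resname = line[17:20].strip()
                if resname not in AA_3TO1:
                    raise PdbParseError(lineno, f"unknown residue name {resname!r}")
                try:
                    chain = line[21]
                    resnum = int(line[22:26])
                    xyz = [float(line[30:38]), float(line[38:46]), float(line[46:54])]
                except (ValueError, IndexError) as exc:
                    raise PdbParseError(lineno, f"malformed ATOM record ({exc})") from None
                current.append(xyz)
                current_layout.append((chain, resnum, AA_3TO1[resname]))
            elif record in ("TER", "REMARK", "END", ""):
                continue
            else:
                raise PdbParseError(lineno, f"unsupported record {record!r}")
    if current is not None:
        raise PdbParseError(lineno, "file ends inside a MODEL block")
    if not models:
        raise PdbParseError(lineno if "lineno" in locals() else 0, "no models found")
    coords = np.array(models, float)
    chains = []
    for chain_id in dict.fromkeys(c for c, _, _ in layout):
        entries = [(r, aa) for c, r, aa in layout if c == chain_id]
        resnums = np.array([r for r, _ in entries])
        seq = "".join(aa for _, aa in entries)
        chains.append((chain_id, resnums, seq))
    return coords, chains


def read_ensemble(path, specs: Sequence[HelixSpec]) -> Ensemble:
    """Read a multi-model PDB written by :func:`write_pdb` back into an
    Ensemble, validating the chain layout against ``specs``."""
    coords, chains = read_pdb(path)
    if len(chains) != len(specs):
        raise ValueError(
            f"PDB has {len(chains)} chains but {len(specs)} helices expected"
        )
    for (chain_id, resnums, seq), spec in zip(chains, specs):
        if seq != spec.sequence or resnums[0] != spec.start_resnum:
            raise ValueError(f"chain {chain_id} does not match helix {spec.name}")
    return Ensemble(tuple(specs), coords)
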