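"""Readers and writers for the package's on-disk formats.

Formats
-------
* topology — JSON: ``atoms`` (id, element, resname, resnum, segment, charge,
  sigma, epsilon, radius, optional role), ``bonds`` (i, j, k, r0), ``angles``
  (i, j, k, k_theta, theta0), ``dihedrals`` (i, j, k, l, barrier,
  periodicity, phase). Units: Å, e, kcal/mol, radians.
* coordinates — a tolerant PDB subset: ATOM/HETATM records, with
  MODEL/ENDMDL blocks mapping to trajectory frames. Occupancy and B-factor
  columns are ignored.
* energy tables — CSV with columns role, ligand_id, replica, frame and the
  five component energies.
* experimental tables — CSV with columns ligand_id, dataset, dG_expt,
  dG_err, pIC50, bound_flag.
"""

from __future__ import annotations

import json
import math
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .model import (
    ENERGY_COLUMNS,
    WATER_RESNAMES,
    ComponentEnergyRecord,
    ExperimentalRecord,
    MolecularSystem,
    TrajectoryFrame,
    ValidationError,
    validate_energy_table,
)

# ---------------------------------------------------------------------------
# Topology (JSON)


def loads_topology(text: str) -> MolecularSystem:
    """Parse a topology JSON document (coordinates are all-zero placeholders)."""
    doc = json.loads(text)
    atoms = doc.get("atoms", [])
    if not atoms:
        raise ValidationError("topology contains no atoms")
    fields: dict[str, list] = {k: [] for k in
                               ("id", "element", "resname", "resnum", "segment",
                                "charge", "sigma", "epsilon", "radius", "role")}
    for rec in atoms:
        try:
            fields["id"].append(int(rec["id"]))
            fields["element"].append(str(rec["element"]))
            fields["resname"].append(str(rec["resname"]))
            fields["resnum"].append(int(rec["resnum"]))
            fields["segment"].append(str(rec.get("segment", "A")))
            fields["charge"].append(float(rec["charge"]))
            fields["sigma"].append(float(rec["sigma"]))
            fields["epsilon"].append(float(rec["epsilon"]))
            fields["radius"].append(float(rec["radius"]))
        except (KeyError, TypeError, ValueError) as exc:
            raise ValidationError(f"malformed atom record {rec!r}: {exc}") from exc
        role = rec.get("role")
        if role is None:
            role = "water" if rec["resname"].upper() in WATER_RESNAMES else None
        if role is None:
            raise ValidationError(f"atom {rec['id']}: missing role and residue "
                                  f"{rec['resname']!r} is not a water residue")
        fields["role"].append(str(role))

    def term(name: str, keys: Sequence[str], idx: int) -> tuple[np.ndarray, np.ndarray]:
        rows = doc.get(name, [])
        if not rows:
            return np.empty((0, idx), int), np.empty((0, len(keys) - idx))
        arr = np.array([[float(r[k]) for k in keys] for r in rows])
        return arr[:, :idx].astype(int), arr[:, idx:]

    bonds, bond_params = term("bonds", ("i", "j", "k", "r0"), 2)
    angles, angle_params = term("angles", ("i", "j", "k", "k_theta", "theta0"), 3)
    dihedrals, dihedral_params = term(
        "dihedrals", ("i", "j", "k", "l", "barrier", "periodicity", "phase"), 4)

    return MolecularSystem(
        ids=np.array(fields["id"]),
        elements=np.array(fields["element"]),
        resnames=np.array(fields["resname"]),
        resnums=np.array(fields["resnum"]),
        segments=np.array(fields["segment"]),
        charges=np.array(fields["charge"], float),
        sigma=np.array(fields["sigma"], float),
        epsilon=np.array(fields["epsilon"], float),
        radius=np.array(fields["radius"], float),
        roles=np.array(fields["role"]),
        bonds=bonds, bond_params=bond_params,
        angles=angles, angle_params=angle_params,
        dihedrals=dihedrals, dihedral_params=dihedral_params,
    )


def dumps_topology(system: MolecularSystem) -> str:
    atoms = []
    for i in range(system.n_atoms):
        atoms.append({
            "id": int(system.ids[i]),
            "element": str(system.elements[i]),
            "resname": str(system.resnames[i]),
            "resnum": int(system.resnums[i]),
            "segment": str(system.segments[i]),
            "charge": float(system.charges[i]),
            "sigma": float(system.sigma[i]),
            "epsilon": float(system.epsilon[i]),
            "radius": float(system.radius[i]),
            "role": str(system.roles[i]),
        })
    doc = {"atoms": atoms}
    if len(system.bonds):
        doc["bonds"] = [{"i": int(b[0]), "j": int(b[1]),
                         "k": float(p[0]), "r0": float(p[1])}
                        for b, p in zip(system.bonds, system.bond_params)]
    if len(system.angles):
        doc["angles"] = [{"i": int(a[0]), "j": int(a[1]), "k": int(a[2]),
                          "k_theta": float(p[0]), "theta0": float(p[1])}
                         for a, p in zip(system.angles, system.angle_params)]
    if len(system.dihedrals):
        doc["dihedrals"] = [{"i": int(d[0]), "j": int(d[1]), "k": int(d[2]),
                             "l": int(d[3]), "barrier": float(p[0]),
                             "periodicity": int(p[1]), "phase": float(p[2])}
                            for d, p in zip(system.dihedrals, system.dihedral_params)]
    return json.dumps(doc, indent=1)


# ---------------------------------------------------------------------------
# PDB (tolerant subset)


def loads_pdb_frames(text: str) -> list[np.ndarray]:
    """Coordinates of each MODEL block (or the whole file) as (n, 3) arrays."""
    frames: list[list[list[float]]] = []
    current: list[list[float]] = []
    in_model = False
    for lineno, line in enumerate(text.splitlines(), start=1):
        rec = line[:6].strip()
        if rec == "MODEL":
            if current:
                frames.append(current)
            current, in_model = [], True
        elif rec == "ENDMDL":
            frames.append(current)
            current, in_model = [], False
        elif rec in ("ATOM", "HETATM"):
            try:
                xyz = [float(line[30:38]), float(line[38:46]), float(line[46:54])]
            except ValueError as exc:
                raise ValidationError(f"PDB line {lineno}: bad coordinate field") from exc
            if not all(math.isfinite(v) for v in xyz):
                raise ValidationError(f"PDB line {lineno}: non-finite coordinate")
            current.append(xyz)
    if current:
        frames.append(current)
    if not frames:
        raise ValidationError("PDB text contains no ATOM/HETATM records")
    counts = {len(f) for f in frames}
    if len(counts) != 1:
        raise ValidationError(f"PDB MODEL blocks have differing atom counts: {sorted(counts)}")
    return [np.asarray(f, dtype=float) for f in frames]


def dumps_pdb(system: MolecularSystem, frames: Sequence[TrajectoryFrame]) -> str:
    """Write frames as a multi-MODEL PDB (3-decimal coordinate precision)."""
    lines: list[str] = []
    multi = len(frames) > 1
    for m, fr in enumerate(frames, start=1):
        fr.check(system)
        if multi:
            lines.append(f"MODEL     {m:4d}")
        for i in range(system.n_atoms):
            x, y, z = fr.coords[i]
            name = str(system.elements[i])[:4]
            lines.append(
                f"ATOM  {int(system.ids[i]) % 100000:5d} {name:<4s}"
                f"{str(system.resnames[i])[:3]:>4s} {int(system.resnums[i]) % 10000:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00      "
                f"{str(system.segments[i])[:4]:<4s}{str(system.elements[i])[:2]:>2s}")
        if multi:
            lines.append("ENDMDL")
    lines.append("END")
    return "\n".join(lines) + "\n"


def read_system(topology_text: str, coordinates_text: str,
                ) -> tuple[MolecularSystem, list[TrajectoryFrame]]:
    """Build a validated system plus its frames from topology + PDB text.

    Each PDB MODEL becomes one :class:`TrajectoryFrame` (replica 1, frame
    index counted from 1); callers assemble replica ensembles from several
    files or re-tag the frames.
    """
    system = loads_topology(topology_text)
    coords = loads_pdb_frames(coordinates_text)
    if coords[0].shape[0] != system.n_atoms:
        raise ValidationError(
            f"atom count mismatch: topology has {system.n_atoms}, "
            f"PDB has {coords[0].shape[0]}")
    frames = [TrajectoryFrame(replica=1, frame=i + 1, coords=c)
              for i, c in enumerate(coords)]
    return system, frames


def write_system(system: MolecularSystem, frames: Sequence[TrajectoryFrame],
                 ) -> tuple[str, str]:
    """Inverse of :func:`read_system`; topology round-trips bit-exactly."""
    return dumps_topology(system), dumps_pdb(system, frames)


# ---------------------------------------------------------------------------
# Energy-component tables (CSV)


def read_energy_table(source: str | Path) -> pd.DataFrame:
    """Read and validate an energy-component CSV (path or CSV text)."""
    if isinstance(source, Path) or "\n" not in str(source):
        df = pd.read_csv(source)
    else:
        from io import StringIO
        df = pd.read_csv(StringIO(source))
    return validate_energy_table(df)


def write_energy_table(df: pd.DataFrame, path: str | Path) -> None:
    validate_energy_table(df).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Experimental affinity tables (CSV)

EXPERIMENTAL_COLUMNS = ("ligand_id", "dataset", "dG_expt", "dG_err", "pIC50", "bound_flag")


def read_experimental_table(source: str | Path) -> list[ExperimentalRecord]:
    if isinstance(source, Path) or "\n" not in str(source):
        df = pd.read_csv(source)
    else:
        from io import StringIO
        df = pd.read_csv(StringIO(source))
    missing = [c for c in ("ligand_id",) if c not in df.columns]
    if missing:
        raise ValidationError(f"experimental table missing column(s): {missing}")
    records = []
    for _, row in df.iterrows():
        def opt(col):
            v = row.get(col)
            return None if v is None or (isinstance(v, float) and math.isnan(v)) else float(v)
        records.append(ExperimentalRecord(
            ligand_id=str(row["ligand_id"]),
            dataset=str(row.get("dataset", "DIV")),
            dG_expt=opt("dG_expt"),
            dG_err=opt("dG_err"),
            pIC50=opt("pIC50"),
            bound=bool(row.get("bound_flag", False)),
        ))
    ids = [r.ligand_id for r in records]
    if len(set(ids)) != len(ids):
        raise ValidationError("duplicate ligand_id in experimental table")
    return records


def write_experimental_table(records: Iterable[ExperimentalRecord], path: str | Path) -> None:
    rows = [{"ligand_id": r.ligand_id, "dataset": r.dataset, "dG_expt": r.dG_expt,
             "dG_err": r.dG_err, "pIC50": r.pIC50, "bound_flag": r.bound}
            for r in records]
    pd.DataFrame(rows, columns=list(EXPERIMENTAL_COLUMNS)).to_csv(path, index=False)
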