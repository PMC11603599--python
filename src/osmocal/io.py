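"""File formats: .xvg RDFs, GRO / CSV particle configurations, and
dissociation-record tables.

RDFs travel as the two-column GROMACS .xvg dialect (``#``/``@`` comment
lines, then ``r g`` pairs).  Frame sets round-trip exactly through a
plain CSV table (frame, molecule, species, x, y, z, mass[, residue]);
GRO files are supported for interoperability, read through MDAnalysis
(one frame per file, species taken from residue names, positions
converted back to nm).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .binding import DimerRecord
from .frames import FrameSet
from .rdf import RadialDistribution
from .synthetic import BEAD_MASS

__all__ = [
    "read_xvg",
    "write_xvg",
    "read_frames_csv",
    "write_frames_csv",
    "read_frames_gro",
    "write_frames_gro",
    "read_dimer_tsv",
    "write_dimer_tsv",
]


def write_xvg(rdf: RadialDistribution, path) -> None:
    """Two-column r/g table with the usual comment header."""
    lines = [
        "# radial distribution function",
        f"# species_pair = {rdf.species_pair[0]} {rdf.species_pair[1]}",
        f"# n_frames = {rdf.n_frames}",
        f"# box_length = {rdf.box_length if rdf.box_length is not None else 'nan'}",
        f"# run_id = {rdf.run_id}",
        '@    title "g(r)"',
        '@    xaxis  label "r (nm)"',
        '@    yaxis  label "g(r)"',
    ]
    for r, g in zip(rdf.bin_centers, rdf.g):
        lines.append(f"{r:12.6f} {g:14.8f}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_xvg(path, run_id: str | None = None) -> RadialDistribution:
    """Read an .xvg-dialect RDF; bin edges are reconstructed from the
    (uniform) centre spacing."""
    meta = {}
    rows = []
    for line in Path(path).read_text().splitlines():
        stripped = line.strip()
        if not stripped:
            continue
        if stripped.startswith(("#", "@")):
            if stripped.startswith("#") and "=" in stripped:
                key, _, val = stripped.lstrip("#").partition("=")
                meta[key.strip()] = val.strip()
            continue
        parts = stripped.split()
        rows.append((float(parts[0]), float(parts[1])))
    if len(rows) < 2:
        raise ValueError(f"{path}: fewer than two data rows")
    centers = np.array([r for r, _ in rows])
    g = np.array([v for _, v in rows])
    widths = np.diff(centers)
    if not np.allclose(widths, widths[0], rtol=1e-6):
        raise ValueError(f"{path}: non-uniform r grid")
    w = widths[0]
    edges = np.concatenate((centers - w / 2, [centers[-1] + w / 2]))
    # Distance grids that start at w/2 correspond to edges starting at 0.
    if abs(edges[0]) < 1e-9:
        edges[0] = 0.0
    box = meta.get("box_length")
    box_length = None if box in (None, "nan", "None") else float(box)
    pair = tuple(meta.get("species_pair", "i j").split()[:2])
    return RadialDistribution(
        bin_edges=edges,
        g=np.clip(g, 0.0, None),
        n_frames=int(meta.get("n_frames", 1)),
        box_length=box_length,
        species_pair=pair,  # type: ignore[arg-type]
        run_id=run_id if run_id is not None else meta.get("run_id", Path(path).stem),
    )


# ---------------------------------------------------------------- frames


def write_frames_csv(frames: FrameSet, path) -> None:
    recs = []
    has_res = frames.residue_index is not None
    for f_idx, coords in enumerate(frames.frames):
        for b in range(frames.n_beads):
            mol = int(frames.molecule_index[b])
            rec = {
                "frame": f_idx,
                "molecule": mol,
                "species": frames.species_index[mol],
                "x": coords[b, 0],
                "y": coords[b, 1],
                "z": coords[b, 2],
                "mass": frames.masses[b],
            }
            if has_res:
                rec["residue"] = int(frames.residue_index[b])
            recs.append(rec)
    df = pd.DataFrame.from_records(recs)
    df.attrs["box_length"] = frames.box_length
    with open(path, "w") as fh:
        fh.write(f"# box_length = {frames.box_length!r}\n")
        df.to_csv(fh, index=False)


def read_frames_csv(path) -> FrameSet:
    with open(path) as fh:
        first = fh.readline()
        if not first.startswith("#"):
            raise ValueError(f"{path}: missing '# box_length = ...' header")
        box_length = float(first.partition("=")[2])
        df = pd.read_csv(fh)
    frame_ids = sorted(df["frame"].unique())
    f0 = df[df["frame"] == frame_ids[0]].reset_index(drop=True)
    molecule_index = f0["molecule"].to_numpy(dtype=int)
    species_index = {
        int(m): s for m, s in zip(f0["molecule"], f0["species"])
    }
    masses = f0["mass"].to_numpy(dtype=float)
    residue_index = (
        f0["residue"].to_numpy(dtype=int) if "residue" in f0.columns else None
    )
    coords = []
    for fid in frame_ids:
        sub = df[df["frame"] == fid]
        coords.append(sub[["x", "y", "z"]].to_numpy(dtype=float))
    return FrameSet(
        frames=coords,
        box_length=box_length,
        molecule_index=molecule_index,
        species_index=species_index,
        masses=masses,
        residue_index=residue_index,
    )


def write_frames_gro(frames: FrameSet, path, frame: int = 0) -> None:
    """Write one frame as a GRO file (positions in nm, one residue per
    molecule, residue name = species truncated to 5 characters)."""
    coords = frames.frames[frame]
    lines = [f"osmocal frame {frame}", f"{frames.n_beads:5d}"]
    for b in range(frames.n_beads):
        mol = int(frames.molecule_index[b])
        resname = frames.species_index[mol][:5]
        x, y, z = coords[b]
        lines.append(
            f"{(mol % 99999) + 1:5d}{resname:<5s}{'B':>5s}{(b % 99999) + 1:5d}"
            f"{x:8.3f}{y:8.3f}{z:8.3f}"
        )
    L = frames.box_length
    lines.append(f"{L:10.5f}{L:10.5f}{L:10.5f}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_frames_gro(path, mass: float = BEAD_MASS) -> FrameSet:
    """Read a single-frame GRO file through MDAnalysis.

    Species labels come from residue names and each residue becomes one
    molecule; GRO carries no masses, so a uniform coarse-bead mass is
    assigned.
    """
    import MDAnalysis as mda

    u = mda.Universe(str(path))
    coords = u.atoms.positions / 10.0  # Angstrom -> nm
    box_length = float(u.dimensions[0]) / 10.0
    resids = u.atoms.resids
    resnames = u.atoms.resnames
    mol_ids = np.unique(resids, return_inverse=True)[1]
    species_index = {}
    for m, rn in zip(mol_ids, resnames):
        species_index[int(m)] = str(rn)
    coords = np.mod(coords, box_length)
    return FrameSet(
        frames=[coords],
        box_length=box_length,
        molecule_index=mol_ids,
        species_index=species_index,
        masses=np.full(len(mol_ids), float(mass)),
    )


# ------------------------------------------------------------- survival


def write_dimer_tsv(record: DimerRecord, path) -> None:
    df = pd.DataFrame(
        {
            "duration": record.durations,
            "event_time": [
                "NA" if np.isnan(t) else repr(float(t)) for t in record.event_times
            ],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_dimer_tsv(path) -> DimerRecord:
    df = pd.read_csv(path, sep="\t", na_values=["NA"], float_precision="round_trip")
    return DimerRecord(
        durations=df["duration"].to_numpy(dtype=float),
        event_times=df["event_time"].to_numpy(dtype=float),
    )
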