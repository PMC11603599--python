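"""Centre-of-mass radial distribution functions under cubic periodic
boundaries.

The RDF protocol mirrors the standard ``gmx rdf`` setup for solute pairs:
distances are measured between molecular centres of mass, histogrammed on
a uniform grid (default bin 0.1 nm out to 10 nm), and normalised by the
spherical-shell volume and the ideal-gas pair density, which averages over
orientations by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .frames import FrameSet

__all__ = [
    "RadialDistribution",
    "MissingSpeciesError",
    "GeometryError",
    "molecule_centers",
    "compute_rdf",
]


class MissingSpeciesError(KeyError):
    """A requested species label is absent from the frame set."""


class GeometryError(ValueError):
    """The requested RDF range is incompatible with the box geometry."""


@dataclass
class RadialDistribution:
    """Binned radial distribution function g(r).

    ``bin_edges`` is a strictly increasing uniform grid of length
    ``len(g) + 1``; ``box_length`` may be ``None`` for RDFs read from
    files that carry no box metadata.
    """

    bin_edges: np.ndarray
    g: np.ndarray
    pair_counts: np.ndarray | None = None
    n_frames: int = 1
    box_length: float | None = None
    species_pair: tuple[str, str] = ("i", "j")
    run_id: str = ""

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.g = np.asarray(self.g, dtype=float)
        if self.pair_counts is not None:
            self.pair_counts = np.asarray(self.pair_counts, dtype=float)
        widths = np.diff(self.bin_edges)
        if len(self.g) != len(self.bin_edges) - 1:
            raise ValueError("len(g) must equal len(bin_edges) - 1")
        if np.any(widths <= 0):
            raise ValueError("bin_edges must be strictly increasing")
        if not np.allclose(widths, widths[0], rtol=1e-6, atol=1e-12):
            raise ValueError("bin_edges must be uniform")
        if np.any(self.g < 0):
            raise ValueError("g must be non-negative")

    @property
    def bin_width(self) -> float:
        return float(self.bin_edges[1] - self.bin_edges[0])

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def r_max(self) -> float:
        return float(self.bin_edges[-1])


def _minimum_image(delta: np.ndarray, box_length: float) -> np.ndarray:
    return delta - box_length * np.round(delta / box_length)


def molecule_centers(frames: FrameSet, species: str) -> list[np.ndarray]:
    """Mass-weighted molecular centres of mass, one ``(n_mol, 3)`` array
    per frame.

    Molecules split across the periodic boundary are made whole first:
    every bead is shifted by the minimum-image displacement relative to
    the molecule's first bead before mass weighting, and the resulting
    centre is wrapped back into ``[0, box_length)``.
    """
    mols = frames.molecules_of(species)
    if len(mols) == 0:
        raise MissingSpeciesError(
            f"species {species!r} not present (have {sorted(frames.species)})"
        )
    L = frames.box_length
    # Precompute bead slices per molecule (constant topology across frames).
    bead_lists = [np.flatnonzero(frames.molecule_index == m) for m in mols]
    masses = [frames.masses[b] for b in bead_lists]
    out = []
    for coords in frames.frames:
        centers = np.empty((len(mols), 3))
        for k, (beads, m) in enumerate(zip(bead_lists, masses)):
            x = coords[beads]
            ref = x[0]
            delta = _minimum_image(x - ref, L)
            com = ref + (m[:, None] * delta).sum(axis=0) / m.sum()
            centers[k] = np.mod(com, L)
        out.append(centers)
    return out


def _pair_distances(
    xi: np.ndarray, xj: np.ndarray, box_length: float, same: bool
) -> np.ndarray:
    delta = xi[:, None, :] - xj[None, :, :]
    delta = _minimum_image(delta, box_length)
    r = np.sqrt((delta**2).sum(axis=-1))
    if same:
        iu = np.triu_indices(len(xi), k=1)
        return r[iu]
    return r.ravel()


def compute_rdf(
    frames: FrameSet,
    species_i: str,
    species_j: str,
    bin_width: float = 0.1,
    r_max: float = 10.0,
    stride: int = 1,
    run_id: str = "",
) -> RadialDistribution:
    """Centre-of-mass RDF between two species.

    Distances are reduced by the minimum-image convention, histogrammed on
    half-open bins ``[edge_k, edge_{k+1})`` (a distance exactly equal to
    ``r_max`` is discarded), and normalised per frame by the
    spherical-shell volume times the ideal-gas pair density: ``N_i N_j / V``
    for distinct species and ``N (N - 1) / 2 / V`` unordered pairs for
    ``species_i == species_j``.

    ``stride`` subsamples frames, standing in for a sampling cadence in
    time when frames carry no clock.
    """
    if r_max > frames.box_length / 2 + 1e-12:
        raise GeometryError(
            f"r_max={r_max} exceeds half the box length "
            f"({frames.box_length / 2})"
        )
    if bin_width <= 0 or stride < 1:
        raise ValueError("bin_width must be > 0 and stride >= 1")
    same = species_i == species_j
    centers_i = molecule_centers(frames, species_i)
    centers_j = centers_i if same else molecule_centers(frames, species_j)

    n_bins = int(round(r_max / bin_width))
    edges = np.linspace(0.0, n_bins * bin_width, n_bins + 1)
    counts = np.zeros(n_bins)
    used = 0
    for xi, xj in list(zip(centers_i, centers_j))[::stride]:
        r = _pair_distances(xi, xj, frames.box_length, same)
        idx = np.floor(r / bin_width).astype(int)
        ok = idx < n_bins
        counts += np.bincount(idx[ok], minlength=n_bins)
        used += 1

    n_i, n_j = len(centers_i[0]), len(centers_j[0])
    if n_i == 0 or n_j == 0:
        raise MissingSpeciesError("empty species selection")
    volume = frames.box_length**3
    shell = (4.0 / 3.0) * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
    if same:
        pairs_per_frame = n_i * (n_i - 1) / 2.0
    else:
        pairs_per_frame = n_i * n_j
    expected = used * pairs_per_frame * shell / volume
    g = counts / expected
    return RadialDistribution(
        bin_edges=edges,
        g=g,
        pair_counts=counts,
        n_frames=used,
        box_length=frames.box_length,
        species_pair=(species_i, species_j),
        run_id=run_id,
    )
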