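"""In-memory container for coarse-grained particle configurations.

A :class:`FrameSet` is the minimal stand-in for a simulation trajectory:
per-frame bead coordinates in a cubic periodic box, plus the bookkeeping
needed to group beads into molecules and molecules into species.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["FrameSet"]


@dataclass
class FrameSet:
    """Bead coordinates for one or more frames in a cubic periodic box.

    Parameters
    ----------
    frames:
        List of ``(n_beads, 3)`` coordinate arrays in nm, all in
        ``[0, box_length)``.
    box_length:
        Cubic box edge in nm.
    molecule_index:
        Integer array mapping each bead to a molecule id.
    species_index:
        Mapping molecule id -> species label (e.g. ``"protein"``,
        ``"sugar"``).
    masses:
        Per-bead masses in amu.
    residue_index:
        Optional integer array mapping each bead to a residue id (used by
        residue-contact analysis; may be ``None``).
    """

    frames: list[np.ndarray]
    box_length: float
    molecule_index: np.ndarray
    species_index: dict[int, str]
    masses: np.ndarray
    residue_index: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        if self.box_length <= 0:
            raise ValueError("box_length must be positive")
        self.frames = [np.asarray(f, dtype=float) for f in self.frames]
        self.molecule_index = np.asarray(self.molecule_index, dtype=int)
        self.masses = np.asarray(self.masses, dtype=float)
        if self.residue_index is not None:
            self.residue_index = np.asarray(self.residue_index, dtype=int)
        n = self.n_beads
        for k, f in enumerate(self.frames):
            if f.shape != (n, 3):
                raise ValueError(
                    f"frame {k} has shape {f.shape}, expected ({n}, 3)"
                )
            if np.any(f < 0) or np.any(f >= self.box_length):
                raise ValueError(
                    f"frame {k} has coordinates outside [0, box_length)"
                )
        if self.masses.shape != (n,):
            raise ValueError("masses must have one entry per bead")
        if np.any(self.masses <= 0):
            raise ValueError("masses must be positive")
        missing = set(np.unique(self.molecule_index)) - set(self.species_index)
        if missing:
            raise ValueError(f"molecules without species label: {sorted(missing)}")

    @property
    def n_beads(self) -> int:
        return len(self.molecule_index)

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def species(self) -> set[str]:
        return set(self.species_index.values())

    def molecules_of(self, species: str) -> np.ndarray:
        """Sorted molecule ids belonging to a species."""
        return np.array(
            sorted(m for m, s in self.species_index.items() if s == species),
            dtype=int,
        )
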