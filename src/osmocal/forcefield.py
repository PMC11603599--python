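"""Rescaling of Lennard-Jones cross interactions in Martini-style
topology tables.

The calibration adjusts protein-sugar interaction strengths through a
single scan parameter lambda:

    eps_lambda = eps_0 + lambda * (eps_original - eps_0)

with ``eps_0 = 2 kJ/mol``, a well depth weak enough to act as purely
repulsive.  lambda = 1 recovers the original table; lambda = 0 turns the
cross interaction off except for excluded volume.  Only well depths are
touched — never sigma, and never pairs outside the selected group pair.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field, replace

__all__ = [
    "NonbondedEntry",
    "NonbondedTable",
    "ScalingSpec",
    "ItpParseError",
    "MissingPairError",
    "parse_nonbond",
    "write_nonbond",
    "scale_cross",
    "mixing_lambda",
]


class ItpParseError(ValueError):
    """A nonbond_params section is absent or contains a malformed row."""


class MissingPairError(KeyError):
    """A requested cross pair is not tabulated."""

    def __init__(self, pairs):
        self.pairs = sorted(pairs)
        super().__init__(
            "cross pairs absent from the table (mixing rules are not "
            f"applied): {self.pairs}"
        )


@dataclass(frozen=True)
class NonbondedEntry:
    """One tabulated pair: bead types, LJ function, sigma (nm),
    epsilon (kJ/mol)."""

    type_i: str
    type_j: str
    func: int
    sigma: float
    epsilon: float
    comment: str = ""  # trailing ';...' text, preserved verbatim

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError(f"sigma must be positive ({self.type_i}-{self.type_j})")
        if self.epsilon < 0:
            raise ValueError(f"epsilon must be >= 0 ({self.type_i}-{self.type_j})")

    @property
    def key(self) -> frozenset:
        return frozenset((self.type_i, self.type_j))


@dataclass
class NonbondedTable:
    """Parsed ``[ nonbond_params ]`` section with verbatim surroundings.

    ``preamble`` holds everything before the section's first data row and
    ``trailer`` everything after the last, so writing reproduces the file
    around the (possibly rescaled) numeric rows.
    """

    entries: list[NonbondedEntry]
    preamble: list[str] = field(default_factory=list)
    trailer: list[str] = field(default_factory=list)
    interleaved: dict[int, list[str]] = field(default_factory=dict)
    source: str = ""

    def __post_init__(self) -> None:
        seen = {}
        for e in self.entries:
            if e.key in seen:
                raise ValueError(
                    f"duplicate pair {e.type_i}-{e.type_j} in nonbond_params"
                )
            seen[e.key] = e

    def lookup(self, a: str, b: str) -> NonbondedEntry | None:
        key = frozenset((a, b))
        for e in self.entries:
            if e.key == key:
                return e
        return None


@dataclass(frozen=True)
class ScalingSpec:
    """Cross-interaction scaling: lambda in [0, 1], repulsive floor
    eps_0 (kJ/mol, default 2), and the two bead-label groups whose cross
    pairs are rescaled."""

    lam: float
    group_a: frozenset
    group_b: frozenset
    epsilon_floor: float = 2.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.lam <= 1.0:
            raise ValueError(f"lambda must be in [0, 1], got {self.lam}")
        if self.epsilon_floor <= 0:
            raise ValueError("epsilon_floor must be positive")
        object.__setattr__(self, "group_a", frozenset(self.group_a))
        object.__setattr__(self, "group_b", frozenset(self.group_b))
        if not self.group_a or not self.group_b:
            raise ValueError("bead groups must be non-empty")


_SECTION_RE = re.compile(r"^\s*\[\s*(?P<name>[\w-]+)\s*\]\s*(;.*)?$")


def parse_nonbond(text: str, source: str = "") -> NonbondedTable:
    """Parse the ``[ nonbond_params ]`` section of a GROMACS .itp text.

    Data rows are ``type_i  type_j  func  sigma  epsilon`` with optional
    ``;`` comments; comment/blank lines inside the section, and all text
    before and after it, are preserved for round-tripping.
    """
    lines = text.splitlines()
    start = None
    for i, line in enumerate(lines):
        m = _SECTION_RE.match(line)
        if m and m.group("name") == "nonbond_params":
            start = i
            break
    if start is None:
        raise ItpParseError("no [ nonbond_params ] section found")

    entries: list[NonbondedEntry] = []
    interleaved: dict[int, list[str]] = {}
    end = len(lines)
    for i in range(start + 1, len(lines)):
        line = lines[i]
        if _SECTION_RE.match(line):
            end = i
            break
        stripped = line.strip()
        if not stripped or stripped.startswith((";", "#")):
            interleaved.setdefault(len(entries), []).append(line)
            continue
        body, _, comment = line.partition(";")
        fields = body.split()
        if len(fields) != 5:
            raise ItpParseError(
                f"line {i + 1}: expected 5 fields "
                f"(type_i type_j func sigma epsilon), got {len(fields)}: "
                f"{line!r}"
            )
        try:
            entry = NonbondedEntry(
                type_i=fields[0],
                type_j=fields[1],
                func=int(fields[2]),
                sigma=float(fields[3]),
                epsilon=float(fields[4]),
                comment=comment,
            )
        except ValueError as exc:
            raise ItpParseError(f"line {i + 1}: {exc}") from exc
        entries.append(entry)
    return NonbondedTable(
        entries=entries,
        preamble=lines[: start + 1],
        trailer=lines[end:],
        interleaved=interleaved,
        source=source,
    )


def write_nonbond(table: NonbondedTable) -> str:
    """Serialise a table back to .itp text; numeric values carry at
    least 6 significant digits so parse-write-parse is lossless."""
    out = list(table.preamble)
    for k, entry in enumerate(table.entries):
        out.extend(table.interleaved.get(k, []))
        line = (
            f"  {entry.type_i:<6s} {entry.type_j:<6s} {entry.func:d} "
            f"{entry.sigma:.6e} {entry.epsilon:.6e}"
        )
        if entry.comment:
            line += f" ;{entry.comment}"
        out.append(line)
    out.extend(table.interleaved.get(len(table.entries), []))
    out.extend(table.trailer)
    return "\n".join(out) + "\n"


def scale_cross(table: NonbondedTable, spec: ScalingSpec) -> NonbondedTable:
    """Rescale every group_a x group_b well depth by
    ``eps <- eps_0 + lambda (eps - eps_0)``.

    Sigma and all pairs outside the selection are untouched.  Every cross
    pair must already be tabulated; absent pairs raise
    :class:`MissingPairError` rather than being synthesised from mixing
    rules.
    """
    wanted = {frozenset((a, b)) for a in spec.group_a for b in spec.group_b}
    present = {e.key for e in table.entries}
    missing = wanted - present
    if missing:
        raise MissingPairError("-".join(sorted(p)) for p in missing)
    new_entries = []
    for e in table.entries:
        if e.key in wanted:
            eps = spec.epsilon_floor + spec.lam * (e.epsilon - spec.epsilon_floor)
            e = replace(e, epsilon=eps)
        new_entries.append(e)
    provenance = (
        f"; cross eps rescaled: eps -> {spec.epsilon_floor:g} + "
        f"{spec.lam:g}*(eps - {spec.epsilon_floor:g}) for "
        f"{sorted(spec.group_a)} x {sorted(spec.group_b)}"
    )
    return NonbondedTable(
        entries=new_entries,
        preamble=list(table.preamble) + [provenance],
        trailer=list(table.trailer),
        interleaved={k: list(v) for k, v in table.interleaved.items()},
        source=table.source,
    )


def mixing_lambda(alpha: float, gamma: float) -> float:
    """Geometric-mean prediction of the cross scale factor from the
    like-pair factors: sqrt(alpha * gamma).

    E.g. protein-protein 0.3 with sugar-sugar 0.5 predicts ~0.39 — a
    useful reference point precisely because calibrated cross factors
    tend to come out lower.
    """
    if alpha < 0 or gamma < 0:
        raise ValueError("scale factors must be non-negative")
    return math.sqrt(alpha * gamma)
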