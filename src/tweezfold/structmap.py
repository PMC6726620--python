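"""Structure utilities: residue contact maps and structure-based ΔLc.

Contacts are defined on heavy atoms (hydrogens ignored): residues i, j with
|i−j| >= 2 are in contact when their minimum inter-residue heavy-atom
distance is at or below a cutoff (8 Å by convention here). Contacts are
partitioned by named regions, e.g. for the PKA regulatory subunit:
within the N3A motif, N3A–B/C helix, N3A–CNB-B, and everything else.

The expected contour-length change of an unfolding unit follows from its
size and folded geometry: ΔLc = n_residues × l_aa − d_NC, with
l_aa = 0.365 nm per residue and d_NC the folded N-to-C distance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio.PDB import PDBParser

from .constants import L_AA_NM
from .errors import InvalidGeometryError, InvalidInputError

__all__ = ["RegionDef", "ContactMap", "contact_map", "expected_delta_lc"]

_HYDROGEN = ("H", "D")


@dataclass(frozen=True)
class RegionDef:
    """Named residue ranges (inclusive) in the structure's own numbering."""

    regions: dict  # name -> (first_residue, last_residue)

    def __post_init__(self) -> None:
        for name, (lo, hi) in self.regions.items():
            if lo > hi:
                raise InvalidInputError(f"region {name!r}: first > last residue")

    def label_of(self, resnum: int):
        for name, (lo, hi) in self.regions.items():
            if lo <= resnum <= hi:
                return name
        return None


@dataclass(frozen=True)
class ContactMap:
    """Residue pairs within the cutoff, with a partition label per pair."""

    pairs: list  # [(i, j), ...] with i < j, |i−j| >= 2
    labels: list  # partition label per pair
    cutoff: float  # Å
    partition_counts: dict = field(default_factory=dict)

    def count(self, label: str) -> int:
        return sum(1 for l in self.labels if l == label)


def _load_coords(source):
    """(residue numbers, list of heavy-atom coordinate arrays)."""
    if isinstance(source, (str, Path)):
        parser = PDBParser(QUIET=True)
        structure = parser.get_structure("s", str(source))
        resnums, coords = [], []
        for res in structure.get_residues():
            if res.id[0].strip():  # skip heteroatoms/waters
                continue
            xyz = np.array(
                [a.coord for a in res.get_atoms() if a.element not in _HYDROGEN]
            )
            if len(xyz):
                resnums.append(res.id[1])
                coords.append(xyz)
        return resnums, coords
    # mapping residue_number -> (n_atoms, 3) array
    resnums = sorted(source)
    return resnums, [np.asarray(source[r], dtype=float) for r in resnums]


def _pair_label(ri: int, rj: int, regions: RegionDef | None) -> str:
    if regions is None:
        return "all"
    li, lj = regions.label_of(ri), regions.label_of(rj)
    names = list(regions.regions)
    hub = names[0]  # first region is the partition hub (e.g. the N3A motif)
    if li == hub and lj == hub:
        return f"intra-{hub}"
    if hub in (li, lj):
        other = lj if li == hub else li
        return f"{hub}-{other}" if other else "other"
    return "other"


def contact_map(
    coords,
    cutoff: float = 8.0,
    regions: RegionDef | None = None,
) -> ContactMap:
    """Residue contact map from atomic coordinates.

    ``coords`` is either a PDB file path or a mapping
    residue_number -> (n_heavy_atoms, 3) coordinate array in Å. A contact
    is a pair (i, j), |i−j| >= 2, whose minimum heavy-atom distance is
    <= ``cutoff``. With ``regions`` given, each pair is labeled
    intra-<hub>, <hub>-<region>, or "other", where the hub is the first
    declared region; pairs are labeled exactly once.

    Raises InvalidInputError on an empty structure and a range error when a
    region lies outside the structure's numbering.
    """
    if cutoff <= 0:
        raise InvalidInputError("cutoff must be positive")
    resnums, atom_sets = _load_coords(coords)
    if not resnums:
        raise InvalidInputError("empty structure: no residues with heavy atoms")
    if regions is not None:
        lo, hi = min(resnums), max(resnums)
        for name, (a, b) in regions.regions.items():
            if b < lo or a > hi:
                raise InvalidInputError(
                    f"region {name!r} ({a}-{b}) outside structure numbering "
                    f"({lo}-{hi})"
                )
    pairs, labels = [], []
    n = len(resnums)
    centers = np.array([c.mean(axis=0) for c in atom_sets])
    radii = np.array(
        [np.max(np.linalg.norm(c - m, axis=1)) for c, m in zip(atom_sets, centers)]
    )
    for i in range(n):
        for j in range(i + 1, n):
            if abs(resnums[j] - resnums[i]) < 2:
                continue
            # cheap sphere rejection before the all-pairs distance
            if np.linalg.norm(centers[j] - centers[i]) > cutoff + radii[i] + radii[j]:
                continue
            diff = atom_sets[i][:, None, :] - atom_sets[j][None, :, :]
            dmin = float(np.sqrt((diff**2).sum(axis=2).min()))
            if dmin <= cutoff:
                pairs.append((resnums[i], resnums[j]))
                labels.append(_pair_label(resnums[i], resnums[j], regions))
    counts: dict = {}
    for l in labels:
        counts[l] = counts.get(l, 0) + 1
    return ContactMap(pairs=pairs, labels=labels, cutoff=cutoff, partition_counts=counts)


def expected_delta_lc(n_residues: int, l_aa: float = L_AA_NM, d_nc: float = 0.0) -> float:
    """Structure-based expected ΔLc = n_residues × l_aa − d_NC (nm)."""
    if n_residues <= 0:
        raise InvalidInputError("n_residues must be positive")
    if d_nc < 0:
        raise InvalidInputError("d_nc must be non-negative")
    dlc = n_residues * l_aa - d_nc
    if dlc <= 0:
        raise InvalidGeometryError(
            f"expected ΔLc = {dlc:.3g} nm <= 0: d_NC exceeds the chain contour"
        )
    return dlc
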