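"""Sub-pocket definition, hydrogen-bond occupancy and pocket averaging.

Sub-pockets follow the Schechter–Berger scheme: pocket Sn of the protease is
the set of residues with at least one atom within a distance cutoff (default
3.5 Å, hydrogens included) of the substrate residue bound at position Pn.
Definitions from several complexes can be merged (per-pocket set union) into
a common binding-site definition.

Hydrogen bonds between protease and peptide are counted per frame with the
conventional geometric criterion: donor–acceptor heavy-atom distance at most
3.0 Å and the D–H···A arrangement within 45° of linearity.  Pocket occupancy
is the ensemble-average *number* of such bonds per frame attributed to the
pocket's residues, so values above 1 indicate multiple simultaneous bonds.

Residue-wise metrics (B-factors, dihedral entropies, …) are aggregated to
pocket level as unweighted arithmetic means.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
from scipy.spatial import cKDTree

from .trajectory_io import FrameEnsemble, ResidueID

logger = logging.getLogger(__name__)

__all__ = [
    "POCKET_LABELS",
    "SubPocketDefinition",
    "HBondCriteria",
    "PocketMetricTable",
    "define_subpockets",
    "merge_definitions",
    "hbond_occupancy",
    "pocket_average",
]

#: Non-prime sub-pockets, outer to inner (S1 abuts the scissile bond).
POCKET_LABELS: tuple[str, ...] = ("S6", "S5", "S4", "S3", "S2", "S1")

#: Default any-atom contact cutoff for pocket membership, Å.
CONTACT_CUTOFF = 3.5

#: Maximum distance (Å) at which a hydrogen counts as bonded to a heavy atom.
COVALENT_H_CUTOFF = 1.2


def pocket_for_position(p_label: str) -> str:
    """Map a substrate position label (``P3``) to its pocket (``S3``)."""
    if not p_label.startswith("P"):
        raise ValueError(f"not a substrate position label: {p_label!r}")
    return "S" + p_label[1:]


@dataclass
class SubPocketDefinition:
    """Ordered map pocket label → set of protease residues, with provenance.

    Pockets may legitimately be empty (flagged, never silently dropped) and
    residue sets may overlap between pockets.
    """

    pockets: dict[str, set[ResidueID]]
    source_complexes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(set(self.pockets)) != len(self.pockets):
            raise ValueError("duplicate pocket labels")

    @property
    def empty_pockets(self) -> list[str]:
        return [lab for lab, resis in self.pockets.items() if not resis]

    def all_residues(self) -> set[ResidueID]:
        out: set[ResidueID] = set()
        for resis in self.pockets.values():
            out |= resis
        return out

    def to_json(self, path: str | Path) -> None:
        obj = {
            "source_complexes": self.source_complexes,
            "pockets": {lab: sorted(r.label() for r in resis)
                        for lab, resis in self.pockets.items()},
        }
        Path(path).write_text(json.dumps(obj, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "SubPocketDefinition":
        obj = json.loads(Path(path).read_text())
        return cls(
            pockets={lab: {ResidueID.from_label(s) for s in labels}
                     for lab, labels in obj["pockets"].items()},
            source_complexes=list(obj.get("source_complexes", [])),
        )


@dataclass(frozen=True)
class HBondCriteria:
    """Geometric hydrogen-bond definition.

    ``max_heavy_distance``: donor–acceptor heavy-atom distance ceiling, Å.
    ``max_dha_deviation``: maximum deviation of the D–H···A angle from
    linearity, degrees (45° means the D–H···A angle must be ≥ 135°).
    """

    max_heavy_distance: float = 3.0
    max_dha_deviation: float = 45.0

    def __post_init__(self) -> None:
        if self.max_heavy_distance <= 0 or self.max_dha_deviation <= 0:
            raise ValueError("hydrogen-bond criteria must be strictly positive")


@dataclass
class PocketMetricTable:
    """Pocket-wise arithmetic means of a residue-wise metric.

    ``value_by_pocket`` holds NaN for pockets with no covered residue; those
    pockets are listed in ``missing_pockets`` rather than silently zeroed.
    """

    metric_name: str
    value_by_pocket: dict[str, float]
    n_by_pocket: dict[str, int] = field(default_factory=dict)
    missing_pockets: list[str] = field(default_factory=list)

    def values(self, labels: Iterable[str] | None = None) -> np.ndarray:
        labels = list(labels) if labels is not None else list(self.value_by_pocket)
        return np.array([self.value_by_pocket[lab] for lab in labels], dtype=float)


def define_subpockets(
    complex_ensemble: FrameEnsemble,
    peptide_chain: str,
    position_map: Mapping[ResidueID, str],
    cutoff: float = CONTACT_CUTOFF,
    frame: int = 0,
) -> SubPocketDefinition:
    """Sub-pockets of a protease–peptide complex by any-atom distance.

    Pocket Sn collects every protease residue (any chain other than
    ``peptide_chain``) with at least one atom — hydrogens included — within
    ``cutoff`` of at least one atom of the peptide residue mapped to Pn.
    A single structure is used (``frame``, default the first).  Peptide
    residues named in ``position_map`` but absent from the complex are a
    hard error; empty pockets are retained and flagged with a warning.
    """
    topo = complex_ensemble.topology
    coords = complex_ensemble.coordinates[frame]

    res_chain = np.array([topo.residues[j].chain for j in topo.atom_residue_index])
    protease_mask = res_chain != peptide_chain
    if not protease_mask.any() or protease_mask.all():
        raise ValueError("complex must contain both protease and peptide atoms")
    protease_idx = np.flatnonzero(protease_mask)
    tree = cKDTree(coords[protease_idx])

    pockets: dict[str, set[ResidueID]] = {lab: set() for lab in POCKET_LABELS}
    present = set(topo.residues)
    for pep_res, p_label in position_map.items():
        pocket_label = pocket_for_position(p_label)
        if pocket_label not in pockets:
            pockets[pocket_label] = set()
        if pep_res not in present:
            raise ValueError(f"peptide residue {pep_res.label()} absent from complex")
        pep_atoms = topo.atoms_of_residue(pep_res)
        hits = tree.query_ball_point(coords[pep_atoms], r=cutoff)
        for hit in hits:
            for k in hit:
                pockets[pocket_label].add(topo.residue_of_atom(protease_idx[k]))

    definition = SubPocketDefinition(
        pockets=pockets,
        source_complexes=[f"cutoff={cutoff}A frame={frame}"],
    )
    for lab in definition.empty_pockets:
        logger.warning("pocket %s is empty at cutoff %.2f Å", lab, cutoff)
    return definition


def merge_definitions(a: SubPocketDefinition, b: SubPocketDefinition) -> SubPocketDefinition:
    """Per-pocket set union of two definitions with the same pocket labels."""
    if set(a.pockets) != set(b.pockets):
        raise ValueError(
            f"pocket label mismatch: {sorted(a.pockets)} vs {sorted(b.pockets)}"
        )
    return SubPocketDefinition(
        pockets={lab: a.pockets[lab] | b.pockets[lab] for lab in a.pockets},
        source_complexes=a.source_complexes + b.source_complexes,
    )


def _polar_topology(topo, coords0: np.ndarray):
    """Donor (heavy, H) pairs and acceptor heavy atoms, by element.

    Donors are N/O heavy atoms with a covalently bonded hydrogen (H within
    1.2 Å in the first frame); acceptors are all N/O atoms.
    """
    elements = np.array([str(e).upper() for e in topo.elements])
    heavy_idx = np.flatnonzero((elements == "N") | (elements == "O"))
    h_idx = np.flatnonzero(elements == "H")
    donors: list[tuple[int, int]] = []
    if len(h_idx):
        tree = cKDTree(coords0[heavy_idx])
        for h in h_idx:
            hits = tree.query_ball_point(coords0[h], r=COVALENT_H_CUTOFF)
            for k in hits:
                donors.append((int(heavy_idx[k]), int(h)))
    return donors, heavy_idx


def hbond_occupancy(
    ensemble: FrameEnsemble,
    pockets: SubPocketDefinition,
    peptide_chain: str,
    criteria: HBondCriteria = HBondCriteria(),
) -> PocketMetricTable:
    """Pocket-wise mean hydrogen-bond count per frame (occupancy).

    Every protease↔peptide donor/acceptor combination is tested in every
    frame against the distance and linearity criteria; each bond found is
    attributed to the pocket(s) containing its protease residue.  The pocket
    value is the mean number of bonds per frame and may exceed 1.
    """
    topo = ensemble.topology
    coords = ensemble.coordinates
    res_chain = np.array([topo.residues[j].chain for j in topo.atom_residue_index])
    is_pep = res_chain == peptide_chain
    if not is_pep.any() or is_pep.all():
        raise ValueError("complex must contain both protease and peptide atoms")

    donors, acceptor_idx = _polar_topology(topo, coords[0])
    if not donors:
        raise ValueError(
            "no polar hydrogens found; hydrogen-bond analysis needs a protonated input"
        )

    # protease-residue pocket membership (a residue may sit in several pockets)
    pocket_of: dict[ResidueID, list[str]] = {}
    for lab, resis in pockets.pockets.items():
        for res in resis:
            pocket_of.setdefault(res, []).append(lab)

    # candidate (D, H, A) triples crossing the interface
    triples: list[tuple[int, int, int, ResidueID]] = []
    for d, h in donors:
        for a in acceptor_idx:
            if a == d:
                continue
            if is_pep[d] == is_pep[a]:
                continue  # same side of the interface
            protease_atom = a if is_pep[d] else d
            prot_res = topo.residue_of_atom(int(protease_atom))
            triples.append((d, h, int(a), prot_res))

    counts = {lab: np.zeros(ensemble.n_frames) for lab in pockets.pockets}
    cos_limit = np.cos(np.radians(180.0 - criteria.max_dha_deviation))
    for d, h, a, prot_res in triples:
        labs = pocket_of.get(prot_res)
        if not labs:
            continue
        rd, rh, ra = coords[:, d], coords[:, h], coords[:, a]
        dist = np.linalg.norm(rd - ra, axis=1)
        v1 = rd - rh
        v2 = ra - rh
        cosang = (v1 * v2).sum(axis=1) / (
            np.linalg.norm(v1, axis=1) * np.linalg.norm(v2, axis=1)
        )
        # D–H···A angle >= 180 - max_dha_deviation  <=>  cos(angle) <= cos_limit
        bonded = (dist <= criteria.max_heavy_distance) & (cosang <= cos_limit)
        for lab in labs:
            counts[lab] += bonded

    values = {lab: float(c.mean()) for lab, c in counts.items()}
    return PocketMetricTable(
        metric_name="hbond_occupancy",
        value_by_pocket=values,
        n_by_pocket={lab: len(resis) for lab, resis in pockets.pockets.items()},
        missing_pockets=pockets.empty_pockets,
    )


def pocket_average(
    metric: Mapping[ResidueID, float],
    pockets: SubPocketDefinition,
    metric_name: str = "metric",
) -> PocketMetricTable:
    """Unweighted arithmetic mean of a residue-wise metric per pocket.

    Residues belonging to several pockets contribute to each.  Pockets with
    no covered residue get NaN and are listed as missing.
    """
    values: dict[str, float] = {}
    n_by: dict[str, int] = {}
    missing: list[str] = []
    for lab, resis in pockets.pockets.items():
        covered = [metric[r] for r in sorted(resis) if r in metric]
        n_by[lab] = len(covered)
        if covered:
            values[lab] = float(np.mean(covered))
        else:
            values[lab] = float("nan")
            missing.append(lab)
            logger.warning("pocket %s has no residue covered by metric %r", lab, metric_name)
    return PocketMetricTable(
        metric_name=metric_name, value_by_pocket=values,
        n_by_pocket=n_by, missing_pockets=missing,
    )
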