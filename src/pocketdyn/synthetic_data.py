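"""Synthetic inputs with known ground truth for the whole pipeline.

Real inputs for this kind of analysis are microsecond MD ensembles and a
curated substrate database; neither is needed to validate the estimators.
This module generates every input the pipeline consumes, with closed-form
(or high-resolution quadrature) ground truth stored alongside:

* substrate tables with planted positional residue distributions
  (truth: the normalised Shannon entropy of each planted distribution);
* backbone torsion ensembles sampled from von Mises mixtures, optionally
  realised as Cartesian multi-model ensembles by internal-coordinate chain
  building, so that torsions recomputed from coordinates round-trip
  (truth: analytic von Mises differential entropy, degree measure);
* Cα coordinate ensembles with per-residue isotropic Gaussian fluctuation
  plus optional global rigid-body jitter (truth: ``B = (8π²/3)·3σ²``);
* protease–peptide complex ensembles with planted contacts and hydrogen
  bonds present in a known fraction ``q`` of frames (truth: pocket
  definition and occupancy).

Samples are i.i.d. across frames by default (an optional AR(1) mode adds
autocorrelation to stress convergence diagnostics); all randomness flows
from an explicit seed and identical (spec, seed) pairs give bit-identical
outputs.  The packaged "thrombin-like" scenario plants the study design the
estimators are meant to resolve: a specificity gradient S1 (specific,
rigid) → S6 (promiscuous, flexible) with concordant flexibility, plus a
paper-style hydrogen-bond pattern that is deliberately *not* rank-ordered
with specificity.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy.special import ive

from .flexibility_metrics import GAS_CONSTANT, B_FROM_MSF
from .interface_analysis import POCKET_LABELS, SubPocketDefinition
from .substrate_specificity import (
    AMINO_ACIDS,
    NONPRIME_POSITIONS,
    SubstrateRecord,
    SubstrateTable,
)
from .trajectory_io import FrameEnsemble, ResidueID, Topology
from .flexibility_metrics import DihedralSeries

__all__ = [
    "VonMisesSpec",
    "vonmises_entropy",
    "mixture_entropy",
    "sample_vonmises_mixture",
    "gen_substrate_table",
    "gen_dihedral_ensemble",
    "gen_torsion_ensemble",
    "gen_coordinate_ensemble",
    "gen_interface_ensemble",
    "PocketPlan",
    "ThrombinLikeScenario",
    "ScenarioData",
]


# ---------------------------------------------------------------------------
# Von Mises machinery
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VonMisesSpec:
    """One von Mises mixture component: mean (degrees), concentration, weight.

    ``kappa = 0`` is the circular uniform distribution.
    """

    mean_angle: float
    kappa: float
    weight: float = 1.0

    def __post_init__(self) -> None:
        if self.kappa < 0:
            raise ValueError("kappa must be >= 0")
        if not 0.0 <= self.weight <= 1.0:
            raise ValueError("weight must lie in [0, 1]")


def _check_mixture(specs: Sequence[VonMisesSpec]) -> None:
    w = sum(s.weight for s in specs)
    if not np.isclose(w, 1.0, atol=1e-9):
        raise ValueError(f"mixture weights sum to {w}, expected 1")


def vonmises_entropy(kappa: float) -> float:
    """Closed-form torsion entropy of a single von Mises component.

    ``S = R·[ln(2π·I0(κ)) − κ·I1(κ)/I0(κ)] + R·ln(180/π)`` in J/(mol·K),
    degree measure.  Exponentially scaled Bessel functions keep the
    expression stable for large κ; κ = 0 gives ``R·ln 360``.
    """
    if kappa < 0:
        raise ValueError("kappa must be >= 0")
    i0e = ive(0, kappa)
    i1e = ive(1, kappa)
    s_rad = np.log(2.0 * np.pi) + kappa + np.log(i0e) - kappa * i1e / i0e
    return float(GAS_CONSTANT * (s_rad + np.log(180.0 / np.pi)))


def mixture_density(grid_deg: np.ndarray, specs: Sequence[VonMisesSpec]) -> np.ndarray:
    """Analytic mixture density per degree on a grid of degrees."""
    _check_mixture(specs)
    theta = np.radians(np.asarray(grid_deg, dtype=float))
    dens = np.zeros_like(theta)
    for s in specs:
        mu = np.radians(s.mean_angle)
        i0 = ive(0, s.kappa)
        dens += s.weight * np.exp(s.kappa * (np.cos(theta - mu) - 1.0)) / (2.0 * np.pi * i0)
    return dens * np.pi / 180.0


def mixture_entropy(specs: Sequence[VonMisesSpec], n_grid: int = 1_000_000) -> float:
    """Torsion entropy of a von Mises mixture by high-resolution quadrature.

    Single components use the closed form; mixtures integrate the analytic
    density on an ``n_grid``-point periodic grid (rectangle rule).
    """
    _check_mixture(specs)
    if len(specs) == 1:
        return vonmises_entropy(specs[0].kappa)
    grid = -180.0 + 360.0 * np.arange(n_grid) / n_grid
    p = mixture_density(grid, specs)
    dx = 360.0 / n_grid
    mask = p > 1e-300
    return float(-GAS_CONSTANT * (p[mask] * np.log(p[mask])).sum() * dx)


def sample_vonmises_mixture(
    specs: Sequence[VonMisesSpec], n: int, rng: np.random.Generator
) -> np.ndarray:
    """``n`` i.i.d. draws from a von Mises mixture, degrees in [−180, 180)."""
    _check_mixture(specs)
    weights = np.array([s.weight for s in specs])
    comp = rng.choice(len(specs), size=n, p=weights)
    out = np.empty(n)
    for i, s in enumerate(specs):
        mask = comp == i
        m = int(mask.sum())
        if m == 0:
            continue
        mu = np.radians(s.mean_angle)
        if s.kappa == 0.0:
            theta = rng.uniform(-np.pi, np.pi, size=m)
        elif s.kappa > 1e4:
            # wrapped-normal limit, numerically safer than vonmises at huge kappa
            theta = mu + rng.normal(0.0, 1.0 / np.sqrt(s.kappa), size=m)
        else:
            theta = rng.vonmises(mu, s.kappa, size=m)
        out[mask] = np.degrees(theta)
    return (out + 180.0) % 360.0 - 180.0


def _ar1_circular(values: np.ndarray, rho: float, rng: np.random.Generator) -> np.ndarray:
    """Impose AR(1) autocorrelation on i.i.d. angular draws (degrees).

    Reorders nothing; mixes each draw with the previous output through the
    shortest angular path.  The marginal distribution is only approximately
    preserved — intended solely to stress block-convergence diagnostics.
    """
    out = values.copy()
    for t in range(1, len(out)):
        d = ((out[t] - out[t - 1] + 180.0) % 360.0) - 180.0
        out[t] = ((out[t - 1] + (1.0 - rho) * d + 180.0) % 360.0) - 180.0
    return out


# ---------------------------------------------------------------------------
# Substrate tables
# ---------------------------------------------------------------------------

@dataclass
class GeneratedSubstrates:
    table: SubstrateTable
    truth_entropy: dict[str, float]
    probabilities: dict[str, np.ndarray]


def planted_entropy(probs: np.ndarray) -> float:
    """Normalised Shannon entropy (base 20) of a planted distribution."""
    p = np.asarray(probs, dtype=float)
    nz = p[p > 0]
    return float(-(nz * np.log(nz)).sum() / np.log(len(AMINO_ACIDS)))


def gen_substrate_table(
    position_probs: Mapping[str, np.ndarray | Mapping[str, float]],
    n: int,
    seed: int,
    source: str = "synthetic",
) -> GeneratedSubstrates:
    """Sample ``n`` substrates i.i.d. from planted positional distributions.

    ``position_probs`` maps a position label to either a length-20
    probability vector (alphabet order) or a residue→probability mapping.
    Truth is the normalised Shannon entropy of each planted distribution.
    """
    rng = np.random.default_rng(seed)
    probs: dict[str, np.ndarray] = {}
    for pos, p in position_probs.items():
        if isinstance(p, Mapping):
            vec = np.zeros(len(AMINO_ACIDS))
            for aa, w in p.items():
                vec[AMINO_ACIDS.index(aa)] = w
        else:
            vec = np.asarray(p, dtype=float)
        if vec.min() < 0:
            raise ValueError(f"negative probabilities at {pos}")
        if not np.isclose(vec.sum(), 1.0, atol=1e-9):
            raise ValueError(f"probabilities at {pos} sum to {vec.sum()}, expected 1")
        probs[pos] = vec

    positions = tuple(position_probs)
    draws = {pos: rng.choice(len(AMINO_ACIDS), size=n, p=vec) for pos, vec in probs.items()}
    records = [
        SubstrateRecord(
            substrate_id=f"syn{i + 1:05d}",
            residues={pos: AMINO_ACIDS[draws[pos][i]] for pos in positions},
        )
        for i in range(n)
    ]
    table = SubstrateTable(records=records, source=source, positions=positions)
    truth = {pos: planted_entropy(vec) for pos, vec in probs.items()}
    return GeneratedSubstrates(table=table, truth_entropy=truth, probabilities=probs)


# ---------------------------------------------------------------------------
# Torsion ensembles
# ---------------------------------------------------------------------------

@dataclass
class GeneratedDihedrals:
    series: list[DihedralSeries]
    truth_entropy: dict[tuple[str, str], float]  # (residue label, kind) -> S


def gen_dihedral_ensemble(
    specs: Mapping[ResidueID, Mapping[str, Sequence[VonMisesSpec]]],
    n_frames: int,
    seed: int,
    ar1_rho: float = 0.0,
) -> GeneratedDihedrals:
    """Sample per-residue φ/ψ torsion series from von Mises mixtures.

    ``specs[residue]["phi"/"psi"]`` is a mixture; truth entropies come from
    the closed form (single component) or analytic-density quadrature
    (mixtures), never from the estimator under test.
    """
    if n_frames < 2:
        raise ValueError("need at least 2 frames")
    rng = np.random.default_rng(seed)
    series: list[DihedralSeries] = []
    truth: dict[tuple[str, str], float] = {}
    for res, kinds in specs.items():
        for kind, mixture in kinds.items():
            values = sample_vonmises_mixture(list(mixture), n_frames, rng)
            if ar1_rho:
                values = _ar1_circular(values, ar1_rho, rng)
            series.append(DihedralSeries(kind, res, values))
            truth[(res.label(), kind)] = mixture_entropy(list(mixture))
    return GeneratedDihedrals(series=series, truth_entropy=truth)


# Ideal backbone internal coordinates (Å / degrees, Engh–Huber-like values).
_B_N_CA, _B_CA_C, _B_C_N = 1.458, 1.525, 1.329
_A_N_CA_C, _A_CA_C_N, _A_C_N_CA = 111.2, 116.2, 121.7
_OMEGA = 180.0


def _place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
                bond: float, angle_deg: float, torsion_deg) -> np.ndarray:
    """Next-atom placement from internal coordinates (batched over frames).

    Positions atom D so that |C−D| = bond, angle(B,C,D) = angle and torsion
    (A,B,C,D) = torsion in the IUPAC sign convention.
    """
    theta = np.radians(angle_deg)
    chi = np.radians(np.asarray(torsion_deg, dtype=float))
    bc = c - b
    bc_u = bc / np.linalg.norm(bc, axis=-1, keepdims=True)
    ab = b - a
    n = np.cross(ab, bc_u)
    n_u = n / np.linalg.norm(n, axis=-1, keepdims=True)
    m_u = np.cross(n_u, bc_u)
    d_local = (
        -bond * np.cos(theta) * bc_u
        + (bond * np.sin(theta) * np.cos(chi))[..., None] * m_u
        - (bond * np.sin(theta) * np.sin(chi))[..., None] * n_u
    )
    return c + d_local


def build_backbone(phi: np.ndarray, psi: np.ndarray, omega: float = _OMEGA) -> np.ndarray:
    """Cartesian N/CA/C backbone frames from torsion series.

    ``phi`` and ``psi`` are ``(M, n_res)`` arrays in degrees; ``phi[:, 0]``
    and ``psi[:, -1]`` are ignored (undefined at chain termini).  Returns
    coordinates of shape ``(M, 3·n_res, 3)`` in atom order N, CA, C per
    residue, built with ideal bond lengths/angles and trans peptide bonds.
    """
    phi = np.atleast_2d(np.asarray(phi, dtype=float))
    psi = np.atleast_2d(np.asarray(psi, dtype=float))
    m, n_res = phi.shape
    if psi.shape != (m, n_res):
        raise ValueError("phi and psi must have the same shape")
    coords = np.empty((m, 3 * n_res, 3))
    theta0 = np.radians(_A_N_CA_C)
    coords[:, 0] = (0.0, 0.0, 0.0)  # N1
    coords[:, 1] = (_B_N_CA, 0.0, 0.0)  # CA1
    coords[:, 2] = coords[:, 1] + _B_CA_C * np.array(
        [-np.cos(theta0), np.sin(theta0), 0.0]
    )  # C1 in the xy-plane
    for i in range(1, n_res):
        n_prev, ca_prev, c_prev = coords[:, 3 * i - 3], coords[:, 3 * i - 2], coords[:, 3 * i - 1]
        n_i = _place_atom(n_prev, ca_prev, c_prev, _B_C_N, _A_CA_C_N, psi[:, i - 1])
        ca_i = _place_atom(ca_prev, c_prev, n_i, _B_N_CA, _A_C_N_CA, omega)
        c_i = _place_atom(c_prev, n_i, ca_i, _B_CA_C, _A_N_CA_C, phi[:, i])
        coords[:, 3 * i] = n_i
        coords[:, 3 * i + 1] = ca_i
        coords[:, 3 * i + 2] = c_i
    return coords


def _backbone_topology(n_res: int, chain: str, res_name: str = "ALA",
                       start_number: int = 1) -> Topology:
    residues = [ResidueID(chain, start_number + i, "", res_name) for i in range(n_res)]
    atom_names = []
    elements = []
    res_index = []
    for i in range(n_res):
        atom_names += ["N", "CA", "C"]
        elements += ["N", "C", "C"]
        res_index += [i, i, i]
    return Topology(np.array(atom_names, dtype=object), np.array(elements, dtype=object),
                    np.array(res_index), residues)


@dataclass
class GeneratedTorsionEnsemble:
    ensemble: FrameEnsemble
    truth_entropy: dict[tuple[str, str], float]  # (residue label, kind) -> S
    planted: dict[tuple[str, str], Sequence[VonMisesSpec]]


def gen_torsion_ensemble(
    phi_specs: Sequence[Sequence[VonMisesSpec] | None],
    psi_specs: Sequence[Sequence[VonMisesSpec] | None],
    n_frames: int,
    seed: int,
    chain: str = "T",
) -> GeneratedTorsionEnsemble:
    """Cartesian backbone ensemble realising planted torsion distributions.

    One spec per residue (None = rigid at an ideal helix angle); frames are
    built by internal-coordinate chain extension, so torsions recomputed
    from the coordinates reproduce the planted samples exactly and their
    distributions have the planted analytic entropies.
    """
    n_res = len(phi_specs)
    if len(psi_specs) != n_res:
        raise ValueError("phi_specs and psi_specs must have one entry per residue")
    rng = np.random.default_rng(seed)
    phi = np.full((n_frames, n_res), -57.0)
    psi = np.full((n_frames, n_res), -47.0)
    truth: dict[tuple[str, str], float] = {}
    planted: dict[tuple[str, str], Sequence[VonMisesSpec]] = {}
    topo = _backbone_topology(n_res, chain)
    for i in range(n_res):
        label = topo.residues[i].label()
        if phi_specs[i] is not None and i > 0:
            phi[:, i] = sample_vonmises_mixture(list(phi_specs[i]), n_frames, rng)
            truth[(label, "phi")] = mixture_entropy(list(phi_specs[i]))
            planted[(label, "phi")] = tuple(phi_specs[i])
        if psi_specs[i] is not None and i < n_res - 1:
            psi[:, i] = sample_vonmises_mixture(list(psi_specs[i]), n_frames, rng)
            truth[(label, "psi")] = mixture_entropy(list(psi_specs[i]))
            planted[(label, "psi")] = tuple(psi_specs[i])
    coords = build_backbone(phi, psi)
    return GeneratedTorsionEnsemble(FrameEnsemble(topo, coords), truth, planted)


# ---------------------------------------------------------------------------
# Coordinate (B-factor) ensembles
# ---------------------------------------------------------------------------

@dataclass
class GeneratedCoordinates:
    ensemble: FrameEnsemble
    truth_bfactor: dict[ResidueID, float]
    anchor_query: str  # selection of noise-free scaffold Cα atoms
    probe_residues: list[ResidueID]


def gen_coordinate_ensemble(
    sigmas: Sequence[float],
    n_frames: int,
    seed: int,
    rigid_jitter: bool = False,
    n_anchor: int = 20,
    jitter_rotation_deg: float = 5.0,
    jitter_translation: float = 1.0,
    chain: str = "A",
) -> GeneratedCoordinates:
    """Backbone scaffold with per-residue isotropic Gaussian fluctuation.

    ``sigmas`` gives the per-axis displacement σ (Å) of each *probe*
    residue; probes are appended to a rigid anchor scaffold of ``n_anchor``
    zero-σ residues arranged on a helix.  The anchors serve as the global
    alignment frame: fitting on noisy atoms alone would absorb part of the
    planted fluctuation into the rigid-body fit.  With ``rigid_jitter`` a
    random global rotation/translation is added to every frame; a correct
    superposition step must remove it exactly.  Truth:
    ``B = (8π²/3)·3σ²`` per probe residue.
    """
    sigmas = np.asarray(sigmas, dtype=float)
    if np.any(sigmas < 0):
        raise ValueError("sigma must be >= 0")
    rng = np.random.default_rng(seed)
    n_probe = len(sigmas)
    n_res = n_anchor + n_probe

    # anchors on a helix (never collinear), probes continuing the curve
    t = np.arange(n_res)
    ca = np.stack([5.0 * np.cos(0.6 * t), 5.0 * np.sin(0.6 * t), 1.8 * t], axis=1)
    base = np.empty((3 * n_res, 3))
    base[0::3] = ca + np.array([-1.2, 0.4, -0.4])  # N
    base[1::3] = ca
    base[2::3] = ca + np.array([1.2, 0.4, 0.4])  # C

    residues = [ResidueID(chain, i + 1, "", "GLY" if i < n_anchor else "ALA")
                for i in range(n_res)]
    atom_names = np.array(["N", "CA", "C"] * n_res, dtype=object)
    elements = np.array(["N", "C", "C"] * n_res, dtype=object)
    res_index = np.repeat(np.arange(n_res), 3)
    topo = Topology(atom_names, elements, res_index, residues)

    atom_sigma = np.zeros(3 * n_res)
    for j, s in enumerate(sigmas):
        atom_sigma[3 * (n_anchor + j) : 3 * (n_anchor + j) + 3] = s

    coords = np.broadcast_to(base, (n_frames, 3 * n_res, 3)).copy()
    if atom_sigma.any():
        noise = rng.normal(0.0, 1.0, size=(n_frames, 3 * n_res, 3)) * atom_sigma[None, :, None]
        coords += noise

    if rigid_jitter:
        axes = rng.normal(size=(n_frames, 3))
        axes /= np.linalg.norm(axes, axis=1, keepdims=True)
        angles = np.radians(rng.normal(0.0, jitter_rotation_deg, size=n_frames))
        k = axes
        cos_a = np.cos(angles)[:, None, None]
        sin_a = np.sin(angles)[:, None, None]
        kx = np.zeros((n_frames, 3, 3))
        kx[:, 0, 1], kx[:, 0, 2] = -k[:, 2], k[:, 1]
        kx[:, 1, 0], kx[:, 1, 2] = k[:, 2], -k[:, 0]
        kx[:, 2, 0], kx[:, 2, 1] = -k[:, 1], k[:, 0]
        eye = np.eye(3)[None]
        rot = eye + sin_a * kx + (1.0 - cos_a) * (kx @ kx)
        trans = rng.normal(0.0, jitter_translation, size=(n_frames, 1, 3))
        centroid = coords.mean(axis=1, keepdims=True)
        coords = (coords - centroid) @ np.swapaxes(rot, 1, 2) + centroid + trans

    truth = {residues[n_anchor + j]: float(B_FROM_MSF * 3.0 * s**2)
             for j, s in enumerate(sigmas)}
    return GeneratedCoordinates(
        ensemble=FrameEnsemble(topo, coords),
        truth_bfactor=truth,
        anchor_query="resname GLY and name CA",
        probe_residues=residues[n_anchor:],
    )


# ---------------------------------------------------------------------------
# Interface (complex) ensembles
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PocketPlan:
    """Planted composition of one sub-pocket in the toy complex.

    ``n_contact`` residues sit within the 3.5 Å contact shell (no hydrogen
    bond), ``n_distant`` outside it, and ``n_hbonds`` donor residues form a
    planted hydrogen bond to the peptide in a fraction ``hbond_q`` of
    frames (N···O 2.9 Å, collinear, when present; displaced to 3.9 Å when
    absent — which keeps the residue inside the contact shell).
    """

    n_contact: int = 1
    n_distant: int = 0
    n_hbonds: int = 0
    hbond_q: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.hbond_q <= 1.0:
            raise ValueError("hbond_q must lie in [0, 1]")


_HBOND_DIRECTIONS = np.array([
    [0.0, -1.0, 0.0],
    [0.0, -0.6, 0.8],
    [0.0, -0.6, -0.8],
    [0.55, -0.6, 0.58],
    [-0.55, -0.6, 0.58],
    [0.55, -0.6, -0.58],
])
_HBOND_DIRECTIONS /= np.linalg.norm(_HBOND_DIRECTIONS, axis=1, keepdims=True)

_HBOND_ON = 2.9  # N···O distance when the planted bond is formed, Å
_HBOND_OFF = 3.9  # displaced distance: fails 3.0 Å but stays in contact


@dataclass
class GeneratedInterface:
    ensemble: FrameEnsemble
    pockets_truth: SubPocketDefinition
    occupancy_truth: dict[str, float]  # planted expected bonds per frame
    position_map: dict[ResidueID, str]  # peptide residue -> P-label
    peptide_chain: str = "P"


def gen_interface_ensemble(
    plans: Mapping[str, PocketPlan],
    n_frames: int,
    seed: int,
    peptide_chain: str = "P",
    protease_chain: str = "E",
) -> GeneratedInterface:
    """Toy protease–hexapeptide complex with planted contacts and H-bonds.

    The peptide (chain P, residues P6…P1 spaced 10 Å apart) carries an
    amide N–H and a carbonyl O per residue; each pocket's planted donor
    residues point an N–H at the corresponding peptide carbonyl in perfect
    bonding geometry with per-frame probability ``hbond_q``.  Ground truth
    (pocket membership, expected occupancy) is returned alongside.
    """
    if set(plans) - set(POCKET_LABELS):
        raise ValueError(f"unknown pocket labels {sorted(set(plans) - set(POCKET_LABELS))}")
    rng = np.random.default_rng(seed)

    atom_names: list[str] = []
    elements: list[str] = []
    res_index: list[int] = []
    residues: list[ResidueID] = []
    base: list[np.ndarray] = []

    def add_residue(rid: ResidueID, atoms: list[tuple[str, str, np.ndarray]]) -> None:
        residues.append(rid)
        for name, el, pos in atoms:
            atom_names.append(name)
            elements.append(el)
            res_index.append(len(residues) - 1)
            base.append(np.asarray(pos, dtype=float))

    # peptide: residue j (1..6) carries position P(7-j); N-terminal is P6
    position_map: dict[ResidueID, str] = {}
    pep_O: dict[str, np.ndarray] = {}
    pep_CA: dict[str, np.ndarray] = {}
    for j in range(1, 7):
        p_label = f"P{7 - j}"
        x = 10.0 * j
        rid = ResidueID(peptide_chain, j, "", "GLY")
        n = np.array([x, 0.0, 0.0])
        add_residue(rid, [
            ("N", "N", n),
            ("H", "H", n + [0.0, 0.0, -1.01]),
            ("CA", "C", [x + 1.5, 1.0, 0.0]),
            ("C", "C", [x + 3.0, 0.0, 0.0]),
            ("O", "O", [x + 3.0, -1.23, 0.0]),
        ])
        position_map[rid] = p_label
        pep_O[p_label] = np.array([x + 3.0, -1.23, 0.0])
        pep_CA[p_label] = np.array([x + 1.5, 1.0, 0.0])

    pockets_truth: dict[str, set[ResidueID]] = {lab: set() for lab in POCKET_LABELS}
    occupancy_truth: dict[str, float] = {lab: 0.0 for lab in POCKET_LABELS}
    donor_atoms: list[tuple[int, int, np.ndarray, np.ndarray]] = []  # (iN, iH, dir, bern)
    next_num = 1

    for lab in POCKET_LABELS:
        plan = plans.get(lab)
        if plan is None:
            continue
        p_label = "P" + lab[1:]
        ca = pep_CA[p_label]
        o = pep_O[p_label]
        # plain contact residues: nearest atom 3.4 Å above the peptide CA
        for c in range(plan.n_contact):
            rid = ResidueID(protease_chain, next_num, "", "ALA")
            next_num += 1
            top = ca + np.array([0.8 * c, 3.4, 0.0])
            add_residue(rid, [
                ("N", "N", top),
                ("CA", "C", top + [1.5, 1.0, 0.0]),
                ("C", "C", top + [3.0, 0.4, 0.0]),
            ])
            pockets_truth[lab].add(rid)
        # distant residues: well outside the shell
        for c in range(plan.n_distant):
            rid = ResidueID(protease_chain, next_num, "", "LEU")
            next_num += 1
            top = ca + np.array([0.8 * c, 12.0, 0.0])
            add_residue(rid, [
                ("N", "N", top),
                ("CA", "C", top + [1.5, 1.0, 0.0]),
                ("C", "C", top + [3.0, 0.4, 0.0]),
            ])
        # donor residues with planted hydrogen bonds to the carbonyl O
        for k in range(plan.n_hbonds):
            if k >= len(_HBOND_DIRECTIONS):
                raise ValueError("at most 6 planted bonds per pocket supported")
            u = _HBOND_DIRECTIONS[k]
            rid = ResidueID(protease_chain, next_num, "", "SER")
            next_num += 1
            n_pos = o + _HBOND_ON * u
            h_pos = n_pos - 1.01 * u  # on the N→O axis: perfectly linear
            add_residue(rid, [
                ("N", "N", n_pos),
                ("H", "H", h_pos),
                ("CA", "C", n_pos + 1.5 * u + [0.0, 0.0, 0.0]),
                ("C", "C", n_pos + 3.0 * u),
            ])
            i_n = len(atom_names) - 4
            i_h = len(atom_names) - 3
            bern = (rng.random(n_frames) < plan.hbond_q)
            donor_atoms.append((i_n, i_h, u, bern))
            pockets_truth[lab].add(rid)
            occupancy_truth[lab] += plan.hbond_q

    topo = Topology(np.array(atom_names, dtype=object), np.array(elements, dtype=object),
                    np.array(res_index, dtype=int), residues)
    base_arr = np.stack(base)
    coords = np.broadcast_to(base_arr, (n_frames, len(base), 3)).copy()
    for i_n, i_h, u, bern in donor_atoms:
        shift = np.where(bern, 0.0, _HBOND_OFF - _HBOND_ON)[:, None] * u[None, :]
        coords[:, i_n] += shift
        coords[:, i_h] += shift

    return GeneratedInterface(
        ensemble=FrameEnsemble(topo, coords),
        pockets_truth=SubPocketDefinition(pockets=pockets_truth,
                                          source_complexes=[f"synthetic seed={seed}"]),
        occupancy_truth=occupancy_truth,
        position_map=position_map,
        peptide_chain=peptide_chain,
    )


# ---------------------------------------------------------------------------
# The packaged thrombin-like scenario
# ---------------------------------------------------------------------------

#: Planted pocket order (inner, specific, rigid → outer, promiscuous, flexible).
#: Specificity mixes a preferred residue with a uniform background; the mixing
#: weights are tuned to the published cleavage-entropy pattern for thrombin
#: (S1 < 0.2, S2 < 0.7, S3–S6 within 0.89–0.97).
SCENARIO_UNIFORM_WEIGHT = {"S1": 0.05, "S2": 0.45, "S3": 0.74,
                           "S4": 0.79, "S5": 0.83, "S6": 0.86}
SCENARIO_PREFERRED = {"S1": "R", "S2": "P", "S3": "V", "S4": "G", "S5": "A", "S6": "S"}
#: Torsion concentration per pocket (dimensionless; larger = more rigid).
SCENARIO_KAPPA = {"S1": 64.0, "S2": 16.0, "S3": 6.0, "S4": 3.5, "S5": 1.8, "S6": 0.8}
#: Cα fluctuation σ per pocket, Å per axis.
SCENARIO_SIGMA = {"S1": 0.15, "S2": 0.25, "S3": 0.40, "S4": 0.55, "S5": 0.70, "S6": 0.90}
#: Hydrogen-bond plan mirroring the published occupancy pattern (strong S1,
#: moderate S6/S3, none in S2/S4) — deliberately not rank-concordant with
#: specificity.
SCENARIO_HBONDS = {
    "S1": (4, 0.85), "S2": (0, 0.0), "S3": (1, 0.6),
    "S4": (0, 0.0), "S5": (1, 0.01), "S6": (1, 1.0),
}
SCENARIO_RESIDUES_PER_POCKET = 3


@dataclass
class ScenarioData:
    """All generated inputs of the thrombin-like scenario plus ground truth."""

    substrates: GeneratedSubstrates
    torsions: GeneratedTorsionEnsemble
    torsion_pockets: SubPocketDefinition
    coordinates: GeneratedCoordinates
    coordinate_pockets: SubPocketDefinition
    interface: GeneratedInterface
    seed: int

    def truth_json(self) -> dict:
        return {
            "seed": self.seed,
            "cleavage_entropy": self.substrates.truth_entropy,
            "dihedral_entropy": {f"{lab}:{kind}": s
                                 for (lab, kind), s in self.torsions.truth_entropy.items()},
            "bfactor": {r.label(): b for r, b in self.coordinates.truth_bfactor.items()},
            "hbond_occupancy": self.interface.occupancy_truth,
        }


@dataclass
class ThrombinLikeScenario:
    """Study design: 6 pockets, specificity and flexibility rank-concordant.

    Defaults are the scenario's study conditions: 20,000 frames for the
    flexibility ensembles, 5,000 for the complex, 1,000 substrates, three
    binding-site residues per pocket.
    """

    seed: int = 0
    n_frames: int = 20_000
    n_frames_interface: int = 5_000
    n_substrates: int = 1_000
    residues_per_pocket: int = SCENARIO_RESIDUES_PER_POCKET

    def position_probs(self) -> dict[str, np.ndarray]:
        probs = {}
        for lab in POCKET_LABELS:
            lam = SCENARIO_UNIFORM_WEIGHT[lab]
            vec = np.full(len(AMINO_ACIDS), lam / len(AMINO_ACIDS))
            vec[AMINO_ACIDS.index(SCENARIO_PREFERRED[lab])] += 1.0 - lam
            probs["P" + lab[1:]] = vec
        return probs

    def generate(self) -> ScenarioData:
        rng = np.random.default_rng(self.seed)
        seeds = rng.integers(0, 2**31 - 1, size=4)

        substrates = gen_substrate_table(self.position_probs(), self.n_substrates,
                                         seed=int(seeds[0]), source="thrombin-like scenario")

        # torsion ensemble: flank + 3 residues per pocket (S1 innermost) + flank
        rpp = self.residues_per_pocket
        n_res = 2 + rpp * len(POCKET_LABELS)
        pocket_of_res: dict[int, str] = {}
        phi_specs: list = [None] * n_res
        psi_specs: list = [None] * n_res
        for pi, lab in enumerate(POCKET_LABELS):
            kappa = SCENARIO_KAPPA[lab]
            for k in range(rpp):
                i = 1 + pi * rpp + k
                pocket_of_res[i] = lab
                phi_specs[i] = [VonMisesSpec(-65.0, kappa)]
                psi_specs[i] = [VonMisesSpec(-40.0, kappa)]
        torsions = gen_torsion_ensemble(phi_specs, psi_specs, self.n_frames,
                                        seed=int(seeds[1]))
        t_res = torsions.ensemble.topology.residues
        torsion_pockets = SubPocketDefinition(
            pockets={lab: {t_res[i] for i, l in pocket_of_res.items() if l == lab}
                     for lab in POCKET_LABELS},
            source_complexes=["scenario torsion ensemble"],
        )

        # coordinate ensemble: 3 probe residues per pocket behind rigid anchors
        sigmas = [SCENARIO_SIGMA[lab] for lab in POCKET_LABELS for _ in range(rpp)]
        coordinates = gen_coordinate_ensemble(sigmas, self.n_frames, seed=int(seeds[2]),
                                              rigid_jitter=True)
        probe = coordinates.probe_residues
        coordinate_pockets = SubPocketDefinition(
            pockets={lab: set(probe[pi * rpp : (pi + 1) * rpp])
                     for pi, lab in enumerate(POCKET_LABELS)},
            source_complexes=["scenario coordinate ensemble"],
        )

        plans = {lab: PocketPlan(n_contact=1, n_distant=1,
                                 n_hbonds=SCENARIO_HBONDS[lab][0],
                                 hbond_q=SCENARIO_HBONDS[lab][1])
                 for lab in POCKET_LABELS}
        interface = gen_interface_ensemble(plans, self.n_frames_interface, seed=int(seeds[3]))

        return ScenarioData(
            substrates=substrates,
            torsions=torsions,
            torsion_pockets=torsion_pockets,
            coordinates=coordinates,
            coordinate_pockets=coordinate_pockets,
            interface=interface,
            seed=self.seed,
        )


def analyze_scenario(data: ScenarioData, with_exact_p: bool = False):
    """Run the full specificity-vs-flexibility pipeline on scenario data.

    Computes cleavage entropy per pocket, Cα B-factors (after alignment on
    the rigid anchors), Sφ/Sψ (torsions recomputed from coordinates),
    hydrogen-bond occupancy (pockets re-derived from the complex geometry,
    not from generator bookkeeping), pocket averages and Spearman ρ of each
    metric against cleavage entropy.
    Returns a :class:`~pocketdyn.correlation_report.SpecificityFlexibilityReport`.
    """
    from .correlation_report import correlate_specificity
    from .flexibility_metrics import (
        calpha_bfactors,
        dihedral_entropy_profile,
        kabsch_superpose,
    )
    from .interface_analysis import define_subpockets, hbond_occupancy, pocket_average
    from .substrate_specificity import cleavage_entropy_profile
    from .trajectory_io import select

    profile = cleavage_entropy_profile(data.substrates.table)
    spec_by_pocket = {"S" + pos[1:]: s for pos, s in profile.entropy_by_position.items()}

    anchors = select(data.coordinates.ensemble, data.coordinates.anchor_query)
    aligned = kabsch_superpose(data.coordinates.ensemble, anchors, reference=0)
    bfac = calpha_bfactors(aligned)
    bfac_table = pocket_average(bfac.value_by_residue, data.coordinate_pockets,
                                metric_name="bfactor_global_ca")

    dihedrals = dihedral_entropy_profile(data.torsions.ensemble)
    sphi_table = pocket_average(dihedrals.s_phi, data.torsion_pockets, metric_name="s_phi")
    spsi_table = pocket_average(dihedrals.s_psi, data.torsion_pockets, metric_name="s_psi")

    pockets = define_subpockets(data.interface.ensemble, data.interface.peptide_chain,
                                data.interface.position_map)
    hbonds = hbond_occupancy(data.interface.ensemble, pockets, data.interface.peptide_chain)

    return correlate_specificity(
        spec_by_pocket,
        [bfac_table, sphi_table, spsi_table, hbonds],
        with_exact_p=with_exact_p,
    )


def write_scenario(data: ScenarioData, out_dir: str | Path) -> dict[str, Path]:
    """Write scenario inputs as portable text files plus a ground-truth JSON."""
    from .trajectory_io import write_multimodel_pdb, write_residue_set

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "substrates": out / "substrates.csv",
        "torsion_ensemble": out / "torsion_ensemble.pdb",
        "coordinate_ensemble": out / "coordinate_ensemble.pdb",
        "interface_ensemble": out / "interface_ensemble.pdb",
        "truth": out / "ground_truth.json",
    }
    data.substrates.table.to_frame().to_csv(paths["substrates"], index=False)
    write_multimodel_pdb(paths["torsion_ensemble"], data.torsions.ensemble)
    write_multimodel_pdb(paths["coordinate_ensemble"], data.coordinates.ensemble)
    write_multimodel_pdb(paths["interface_ensemble"], data.interface.ensemble)
    for lab, resis in data.torsion_pockets.pockets.items():
        p = out / f"pocket_{lab}_torsion.txt"
        write_residue_set(p, sorted(resis))
        paths[f"pocket_{lab}_torsion"] = p
    paths["truth"].write_text(json.dumps(data.truth_json(), indent=2))
    return paths
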