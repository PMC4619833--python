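"""Flexibility metrics over conformational ensembles.

Two complementary views of binding-site dynamics:

* **Global** — residue-wise Cα B-factors after a *single* global rigid-body
  alignment of all frames onto one reference: ``B = (8π²/3)·MSF`` with the
  mean-square fluctuation about the ensemble-mean position, in Å².
* **Local** — backbone dihedral entropies.  The φ/ψ torsion distribution of
  each residue is estimated by Gaussian kernel density estimation treated
  periodically on the circle, and integrated as

      S_α = −R ∫ p(α) ln p(α) dα      (degree measure)

  with R = 8.314 J/(mol·K).  On this convention an idealised torsion locked
  into a 1°-wide peak has entropy ≈ 0, while a fully disordered (uniform)
  torsion reaches R·ln 360 ≈ 48.94 J/(mol·K).

A pairwise minimal-RMSD matrix over frames (2D-RMSD) is provided as a
sampling/convergence diagnostic.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .trajectory_io import AtomSelection, FrameEnsemble, ResidueID, Topology

logger = logging.getLogger(__name__)

__all__ = [
    "GAS_CONSTANT",
    "SuperpositionResult",
    "BFactorProfile",
    "DihedralSeries",
    "DihedralEntropyProfile",
    "RmsdMatrix",
    "kabsch_rotation",
    "kabsch_superpose",
    "calpha_bfactors",
    "backbone_dihedrals",
    "circular_silverman_bandwidth",
    "periodic_kde",
    "dihedral_entropy",
    "dihedral_entropy_profile",
    "rmsd_matrix",
]

#: Molar gas constant, J/(mol·K).
GAS_CONSTANT = 8.314

B_FROM_MSF = 8.0 * np.pi**2 / 3.0

#: Peptide-bond C(i−1)–N(i) distance above which a chain break is assumed.
CHAIN_BREAK_CUTOFF = 2.5


# ---------------------------------------------------------------------------
# Superposition and B-factors
# ---------------------------------------------------------------------------

@dataclass
class SuperpositionResult:
    aligned_ensemble: FrameEnsemble
    per_frame_rmsd: np.ndarray  # (M,) Å over the fit selection
    reference_frame: int | None  # None if an external reference was used
    selection: AtomSelection | None = None


@dataclass
class BFactorProfile:
    """Per-residue Cα B-factor (Å²) and underlying mean-square fluctuation."""

    value_by_residue: dict[ResidueID, float]
    msf_by_residue: dict[ResidueID, float]

    def __post_init__(self) -> None:
        for res, b in self.value_by_residue.items():
            msf = self.msf_by_residue[res]
            if not np.isclose(b, B_FROM_MSF * msf, rtol=1e-10, atol=1e-12):
                raise ValueError(f"B/MSF identity violated for {res.label()}")


def _check_fit_atoms(ref: np.ndarray) -> None:
    if ref.shape[0] < 3:
        raise ValueError("superposition needs at least 3 fit atoms")
    c = ref - ref.mean(axis=0)
    s = np.linalg.svd(c, compute_uv=False)
    if s[1] < 1e-8 * max(s[0], 1.0):
        raise ValueError("degenerate (collinear) fit selection")


def kabsch_rotation(mobile: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Optimal rotation matrices mapping centred ``mobile`` onto ``target``.

    ``mobile`` is ``(..., N, 3)`` (batched), ``target`` ``(N, 3)``; both must
    already be centred.  Returns matrices ``A`` with ``det A = +1`` (the
    determinant correction forbids improper reflections) to be applied as
    ``x_row @ A``.
    """
    h = np.swapaxes(mobile, -1, -2) @ target  # (..., 3, 3)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(u @ vt))
    u = u.copy()
    u[..., :, 2] *= d[..., None]
    return u @ vt


def kabsch_superpose(
    ensemble: FrameEnsemble,
    selection: AtomSelection,
    reference: int | np.ndarray = 0,
) -> SuperpositionResult:
    """Rigid-body align every frame onto a reference over the fit selection.

    The rotation/translation minimising the RMSD of the selected atoms is
    computed per frame (Kabsch algorithm with determinant correction) and
    applied to *all* atoms of the frame.  ``reference`` is a frame index or
    an external ``(n_sel, 3)`` coordinate array for the selected atoms.
    """
    coords = ensemble.coordinates
    sel = selection.indices
    if isinstance(reference, (int, np.integer)):
        if not (0 <= reference < ensemble.n_frames):
            raise ValueError(f"reference frame {reference} out of range")
        ref_sel = coords[reference, sel]
        ref_index: int | None = int(reference)
    else:
        ref_sel = np.asarray(reference, dtype=float)
        if ref_sel.shape != (len(sel), 3):
            raise ValueError("external reference must match the selection shape (n_sel, 3)")
        ref_index = None
    _check_fit_atoms(ref_sel)

    ref_centroid = ref_sel.mean(axis=0)
    ref_c = ref_sel - ref_centroid

    mob_sel = coords[:, sel, :]
    mob_centroid = mob_sel.mean(axis=1, keepdims=True)  # (M, 1, 3)
    rot = kabsch_rotation(mob_sel - mob_centroid, ref_c)  # (M, 3, 3)

    aligned = (coords - mob_centroid) @ rot + ref_centroid
    diff = aligned[:, sel, :] - ref_sel
    rmsd = np.sqrt((diff**2).sum(axis=(1, 2)) / len(sel))

    out = FrameEnsemble(ensemble.topology, aligned, ensemble.frame_labels)
    return SuperpositionResult(out, rmsd, ref_index, selection)


def calpha_bfactors(aligned: SuperpositionResult | FrameEnsemble) -> BFactorProfile:
    """Residue-wise Cα B-factors of an aligned ensemble.

    ``MSF_i = ⟨‖r_i − ⟨r_i⟩‖²⟩`` over frames, ``B_i = (8π²/3)·MSF_i``.
    Residues without a Cα atom are skipped with a warning.
    """
    ens = aligned.aligned_ensemble if isinstance(aligned, SuperpositionResult) else aligned
    topo = ens.topology
    coords = ens.coordinates
    values: dict[ResidueID, float] = {}
    msfs: dict[ResidueID, float] = {}
    ca_mask = np.array([n == "CA" for n in topo.atom_names])
    for ri, res in enumerate(topo.residues):
        idx = np.flatnonzero(ca_mask & (topo.atom_residue_index == ri))
        if len(idx) == 0:
            logger.warning("residue %s has no CA atom; skipped in B-factor profile", res.label())
            continue
        r = coords[:, idx[0], :]
        if (r == r[0]).all():  # strictly static: exactly zero, no rounding
            msf = 0.0
        else:
            msf = float(((r - r.mean(axis=0)) ** 2).sum(axis=1).mean())
        msfs[res] = msf
        values[res] = B_FROM_MSF * msf
    return BFactorProfile(value_by_residue=values, msf_by_residue=msfs)


# ---------------------------------------------------------------------------
# Backbone dihedrals
# ---------------------------------------------------------------------------

@dataclass
class DihedralSeries:
    """Per-frame values of one backbone torsion of one residue, degrees."""

    angle_kind: str  # "phi" or "psi"
    residue: ResidueID
    values: np.ndarray  # (M,) in [-180, 180)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.angle_kind not in ("phi", "psi"):
            raise ValueError("angle_kind must be 'phi' or 'psi'")
        if np.any(self.values < -180.0) or np.any(self.values >= 180.0):
            raise ValueError("dihedral values must lie in [-180, 180)")


def dihedral_angles(p1: np.ndarray, p2: np.ndarray, p3: np.ndarray, p4: np.ndarray) -> np.ndarray:
    """Torsion angle(s) of four points, IUPAC sign convention, in [-180, 180).

    Accepts ``(..., 3)`` arrays; syn-periplanar (cis) is 0°, anti-periplanar
    (trans) maps to −180°.
    """
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    b2n = b2 / np.linalg.norm(b2, axis=-1, keepdims=True)
    m1 = np.cross(n1, b2n)
    x = (n1 * n2).sum(axis=-1)
    y = (m1 * n2).sum(axis=-1)
    ang = np.degrees(np.arctan2(y, x))
    return ((ang + 180.0) % 360.0) - 180.0


def _backbone_index(topo: Topology, names=("N", "CA", "C")) -> dict[int, dict[str, int]]:
    table: dict[int, dict[str, int]] = {ri: {} for ri in range(topo.n_residues)}
    for i, (name, ri) in enumerate(zip(topo.atom_names, topo.atom_residue_index)):
        if name in names and name not in table[ri]:
            table[ri][name] = i
    return table


def backbone_dihedrals(ensemble: FrameEnsemble) -> list[DihedralSeries]:
    """φ and ψ series for every residue where they are defined.

    φ(i) = C(i−1)–N(i)–Cα(i)–C(i); ψ(i) = N(i)–Cα(i)–C(i)–N(i+1).  The first
    residue of a chain has no φ, the last no ψ — those series are absent, not
    padded.  A C(i−1)–N(i) distance above 2.5 Å (first frame) is treated as a
    chain break.  Residues missing backbone atoms lose their affected series
    with a logged note.
    """
    topo = ensemble.topology
    coords = ensemble.coordinates
    bb = _backbone_index(topo)

    # residues grouped by chain, topology order
    chains: dict[str, list[int]] = {}
    for ri, res in enumerate(topo.residues):
        chains.setdefault(res.chain, []).append(ri)

    series: list[DihedralSeries] = []
    for chain_resis in chains.values():
        for pos, ri in enumerate(chain_resis):
            res = topo.residues[ri]
            here = bb[ri]
            prev = bb[chain_resis[pos - 1]] if pos > 0 else {}
            nxt = bb[chain_resis[pos + 1]] if pos + 1 < len(chain_resis) else {}

            def linked(other: dict[str, int], other_atom: str, this_atom: str) -> bool:
                if other_atom not in other or this_atom not in here:
                    return False
                d = np.linalg.norm(coords[0, other[other_atom]] - coords[0, here[this_atom]])
                return d <= CHAIN_BREAK_CUTOFF

            if all(a in here for a in ("N", "CA", "C")):
                if prev and linked(prev, "C", "N"):
                    phi = dihedral_angles(
                        coords[:, prev["C"]], coords[:, here["N"]],
                        coords[:, here["CA"]], coords[:, here["C"]],
                    )
                    series.append(DihedralSeries("phi", res, phi))
                if nxt and "N" in nxt:
                    d = np.linalg.norm(coords[0, here["C"]] - coords[0, nxt["N"]])
                    if d <= CHAIN_BREAK_CUTOFF:
                        psi = dihedral_angles(
                            coords[:, here["N"]], coords[:, here["CA"]],
                            coords[:, here["C"]], coords[:, nxt["N"]],
                        )
                        series.append(DihedralSeries("psi", res, psi))
            else:
                missing = [a for a in ("N", "CA", "C") if a not in here]
                logger.info("residue %s missing backbone atom(s) %s; torsions skipped",
                            res.label(), missing)
    return series


# ---------------------------------------------------------------------------
# Periodic KDE and dihedral entropy
# ---------------------------------------------------------------------------

#: Fallback bandwidth (degrees) for degenerate zero-spread samples.
DEGENERATE_BANDWIDTH = 1.0
#: Numerical bandwidth floor (degrees) set by the finest internal grid.
MIN_BANDWIDTH = 0.01


def circular_silverman_bandwidth(values_deg: np.ndarray) -> float:
    """Silverman rule-of-thumb bandwidth from the circular standard deviation.

    ``h = (4/3)^{1/5} · σ_circ · n^{-1/5}`` in degrees, where
    ``σ_circ = sqrt(−2 ln R̄)`` and ``R̄`` is the mean resultant length.
    Zero-spread samples fall back to a 1° bandwidth with a warning.
    """
    theta = np.radians(np.asarray(values_deg, dtype=float))
    n = len(theta)
    if n < 2:
        raise ValueError("bandwidth selection needs at least 2 samples")
    rbar = np.abs(np.exp(1j * theta).mean())
    if rbar >= 1.0 - 1e-12:
        warnings.warn("zero circular spread; falling back to 1 degree bandwidth")
        return DEGENERATE_BANDWIDTH
    sigma = np.degrees(np.sqrt(-2.0 * np.log(rbar)))
    h = (4.0 / 3.0) ** 0.2 * sigma * n ** (-0.2)
    return float(max(h, MIN_BANDWIDTH))


def _resolve_bandwidth(values: np.ndarray, bandwidth) -> float:
    if bandwidth == "auto" or bandwidth is None:
        return circular_silverman_bandwidth(values)
    h = float(bandwidth)
    if h <= 0:
        raise ValueError("bandwidth must be positive")
    return h


def _fine_kde(values: np.ndarray, h: float, grid_points: int) -> tuple[np.ndarray, np.ndarray]:
    """Gaussian KDE on the circle on an internal grid refined to the bandwidth.

    Samples are binned at grid resolution and convolved with a wrapped
    Gaussian kernel by circular FFT convolution — the limit of periodically
    duplicating the data at ±360° with an exact one-period normalisation.
    The internal grid is ``grid_points`` times a power of two, at least 8
    bins per bandwidth, so narrow peaks stay resolved.
    """
    values = np.asarray(values, dtype=float)
    n = len(values)
    if n < 2:
        raise ValueError("periodic KDE needs at least 2 samples")
    needed = 8.0 * 360.0 / h
    factor = 1
    while grid_points * factor < needed and factor < 1024:
        factor *= 2
    nb = grid_points * factor
    dx = 360.0 / nb

    idx = np.round((values + 180.0) / dx).astype(int) % nb
    hist = np.bincount(idx, minlength=nb).astype(float)

    offs = (np.arange(nb) * dx + 180.0) % 360.0 - 180.0
    n_images = int(np.ceil(6.0 * h / 360.0)) + 1
    kernel = np.zeros(nb)
    for k in range(-n_images, n_images + 1):
        kernel += np.exp(-0.5 * ((offs + 360.0 * k) / h) ** 2)
    kernel /= np.sqrt(2.0 * np.pi) * h

    dens = np.fft.irfft(np.fft.rfft(hist) * np.fft.rfft(kernel), nb) / n
    dens = np.maximum(dens, 0.0)
    dens /= dens.sum() * dx  # integral over one period == 1 exactly
    grid = -180.0 + np.arange(nb) * dx
    return grid, dens


def periodic_kde(
    values: np.ndarray,
    bandwidth: float | str = "auto",
    grid_points: int = 720,
) -> tuple[np.ndarray, np.ndarray]:
    """Periodic Gaussian KDE of angular samples (degrees) over [−180, 180).

    Returns ``(grid, density)`` with ``grid_points`` equally spaced points;
    the density integrates to 1 over one period (per-degree units).  The
    estimate is computed on a finer internal grid when the bandwidth demands
    it and subsampled to the requested grid.
    """
    h = _resolve_bandwidth(np.asarray(values, dtype=float), bandwidth)
    grid, dens = _fine_kde(np.asarray(values, dtype=float), h, grid_points)
    step = len(grid) // grid_points
    return grid[::step], dens[::step]


def dihedral_entropy(
    values: np.ndarray,
    bandwidth: float | str = "auto",
    grid_points: int = 720,
) -> float:
    """Torsion entropy ``S = −R ∫ p ln p dα`` in J/(mol·K), degree measure.

    The KDE density is integrated by the rectangle rule on the uniform
    circular grid (equivalent to the trapezoid rule on a periodic grid);
    grid points where the density underflows contribute 0 (``0·ln 0 = 0``).
    """
    values = np.asarray(values, dtype=float)
    h = _resolve_bandwidth(values, bandwidth)
    grid, dens = _fine_kde(values, h, grid_points)
    dx = grid[1] - grid[0]
    mask = dens > 1e-300
    p = dens[mask]
    return float(-GAS_CONSTANT * (p * np.log(p)).sum() * dx)


@dataclass
class DihedralEntropyProfile:
    """Per-residue Sφ and Sψ in J/(mol·K) plus the KDE settings used."""

    s_phi: dict[ResidueID, float]
    s_psi: dict[ResidueID, float]
    kde_settings: dict = field(default_factory=dict)

    UNIFORM_CEILING = GAS_CONSTANT * np.log(360.0)

    def __post_init__(self) -> None:
        for d in (self.s_phi, self.s_psi):
            for res, s in d.items():
                if not np.isfinite(s):
                    raise ValueError(f"non-finite entropy for {res.label()}")
                if s > self.UNIFORM_CEILING + 0.1:
                    raise ValueError(
                        f"entropy {s:.3f} for {res.label()} exceeds the uniform ceiling"
                    )


def dihedral_entropy_profile(
    source: FrameEnsemble | list[DihedralSeries],
    bandwidth: float | str = "auto",
    grid_points: int = 720,
) -> DihedralEntropyProfile:
    """Sφ/Sψ for every residue of an ensemble (or precomputed series)."""
    series = backbone_dihedrals(source) if isinstance(source, FrameEnsemble) else source
    s_phi: dict[ResidueID, float] = {}
    s_psi: dict[ResidueID, float] = {}
    for s in series:
        target = s_phi if s.angle_kind == "phi" else s_psi
        target[s.residue] = dihedral_entropy(s.values, bandwidth=bandwidth, grid_points=grid_points)
    return DihedralEntropyProfile(
        s_phi=s_phi, s_psi=s_psi,
        kde_settings={"bandwidth": bandwidth, "grid_points": grid_points},
    )


# ---------------------------------------------------------------------------
# 2D-RMSD
# ---------------------------------------------------------------------------

@dataclass
class RmsdMatrix:
    values: np.ndarray  # (m, m) Å
    selection: AtomSelection
    stride: int = 1

    def __post_init__(self) -> None:
        v = self.values
        if not np.allclose(v, v.T, atol=1e-9):
            raise ValueError("RMSD matrix must be symmetric")
        if not np.allclose(np.diag(v), 0.0, atol=1e-9):
            raise ValueError("RMSD matrix must have a zero diagonal")


def rmsd_matrix(ensemble: FrameEnsemble, selection: AtomSelection, stride: int = 1) -> RmsdMatrix:
    """Pairwise minimal RMSD between frames over a selection (2D-RMSD).

    Entry (i, j) is the RMSD of the selected atoms after pairwise Kabsch
    superposition of frame j onto frame i.
    """
    if stride < 1:
        raise ValueError("stride must be >= 1")
    sel = selection.indices
    coords = ensemble.coordinates[::stride, sel, :]
    m, n, _ = coords.shape
    _check_fit_atoms(coords[0])
    centred = coords - coords.mean(axis=1, keepdims=True)
    sq = (centred**2).sum(axis=(1, 2))  # (m,)

    out = np.zeros((m, m))
    for i in range(m - 1):
        mob = centred[i + 1 :]  # (m-i-1, n, 3)
        h = np.swapaxes(mob, -1, -2) @ centred[i]
        u, s, vt = np.linalg.svd(h)
        d = np.sign(np.linalg.det(u @ vt))
        trace = s[:, 0] + s[:, 1] + d * s[:, 2]
        val = (sq[i + 1 :] + sq[i] - 2.0 * trace) / n
        out[i, i + 1 :] = np.sqrt(np.maximum(val, 0.0))
    out = out + out.T
    return RmsdMatrix(values=out, selection=selection, stride=stride)
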