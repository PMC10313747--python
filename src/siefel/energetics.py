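"""Intermolecular energies, SIE binding free energy, per-residue decomposition.

The solvated interaction energy (SIE) estimate of a binding free energy is

    dG_bind = alpha * (E_vdw + gamma*dSA + E_ele + G_RF) + C

with calibrated coefficients alpha = 0.105, gamma = 0.013 kcal/mol/A^2 and
C = -2.89 kcal/mol. E_vdw and E_ele are the intermolecular Lennard-Jones and
Coulomb energies of the bound complex (no cutoff, vacuum dielectric);
gamma*dSA is the cavity (nonpolar solvation) term over the surface area
buried on binding; G_RF is the change in electrostatic solvation (reaction
field) on binding, computed here with a Still-type pairwise generalized Born
model (interior dielectric 2.25, solvent 78.5) over fixed per-atom Born
radii. The combiner accepts externally computed components, so published
component tables can be pushed through the same equation unchanged.

The per-residue decomposition splits the receptor-ligand interaction into
residue-wise van der Waals + nonpolar-solvation and Coulomb +
polar-solvation terms; residues stabilising the complex by more than
1 kcal/mol (total < -1.00) are flagged as key residues.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .structure_io import AnalysisError, ParameterError, Topology, Trajectory
from .surface import SASAParams, shrake_rupley_sasa

__all__ = [
    "COULOMB_CONSTANT",
    "BORN_CONSTANT",
    "SIECoefficients",
    "SIEComponents",
    "SIEResult",
    "lj_energy",
    "coulomb_energy",
    "intermolecular_terms",
    "born_reaction_field",
    "reaction_field_binding",
    "cavity_term",
    "delta_sasa",
    "sie_combine",
    "sie_from_trajectory",
    "per_residue_decomposition",
    "key_residues",
    "KEY_RESIDUE_THRESHOLD",
]

#: Coulomb constant, kcal Å mol^-1 e^-2.
COULOMB_CONSTANT = 332.0636
#: Born self-energy constant (half the Coulomb constant).
BORN_CONSTANT = 166.0318
#: Residues with a decomposed contribution below this are "key" (kcal/mol).
KEY_RESIDUE_THRESHOLD = -1.00

#: Generalized-Born dielectrics paired with the SIE coefficients.
DEFAULT_EPS_IN = 2.25
DEFAULT_EPS_OUT = 78.5


@dataclass(frozen=True)
class SIECoefficients:
    alpha: float = 0.105
    gamma: float = 0.013
    constant: float = -2.89

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")


@dataclass(frozen=True)
class SIEComponents:
    """The four SIE energy terms (kcal/mol); cavity is the gamma*dSA value."""

    e_vdw: float
    e_ele: float
    g_rf: float
    cavity: float

    def __post_init__(self) -> None:
        vals = (self.e_vdw, self.e_ele, self.g_rf, self.cavity)
        if not all(math.isfinite(v) for v in vals):
            raise ValueError(f"non-finite SIE components: {vals}")


@dataclass
class SIEResult:
    per_snapshot: pd.DataFrame
    mean: float
    sd: float
    coefficients: SIECoefficients = field(default_factory=SIECoefficients)

    @property
    def dg_bind(self) -> float:
        return self.mean


def lj_energy(rmin_i_half: float, eps_i: float, rmin_j_half: float,
              eps_j: float, r: float) -> float:
    """12-6 Lennard-Jones pair energy with Lorentz-Berthelot combination.

    ``rmin = rmin_i_half + rmin_j_half`` is the pair minimum-energy distance
    and ``eps = sqrt(eps_i * eps_j)`` the well depth, so the energy is
    ``eps * ((rmin/r)^12 - 2 (rmin/r)^6)``: exactly ``-eps`` at ``r = rmin``
    and zero at ``r = rmin / 2^(1/6)``.
    """
    if r <= 0:
        raise AnalysisError("LJ energy undefined at r <= 0")
    rmin = rmin_i_half + rmin_j_half
    eps = math.sqrt(eps_i * eps_j)
    q = (rmin / r) ** 6
    return eps * (q * q - 2.0 * q)


def coulomb_energy(qi: float, qj: float, r: float, dielectric: float = 1.0) -> float:
    """Coulomb pair energy, kcal/mol: ``332.0636 qi qj / (eps r)``."""
    if r <= 0:
        raise AnalysisError("Coulomb energy undefined at r <= 0")
    if dielectric <= 0:
        raise AnalysisError("dielectric must be positive")
    return COULOMB_CONSTANT * qi * qj / (dielectric * r)


def _require_parameterised(top: Topology, idx: np.ndarray) -> None:
    q = top.charges[idx]
    rm = top.lj_rmin_half[idx]
    ep = top.lj_epsilon[idx]
    bad = np.nonzero(~(np.isfinite(q) & np.isfinite(rm) & np.isfinite(ep)))[0]
    if bad.size:
        serials = [top.atoms[int(idx[k])].serial for k in bad[:20]]
        raise ParameterError(f"unparameterised atoms (serials {serials})")


def intermolecular_terms(frame: np.ndarray, topology: Topology,
                         receptor_group: str = "receptor",
                         ligand_group: str = "ligand") -> tuple[float, float]:
    """Receptor-ligand (E_vdw, E_ele) in kcal/mol, summed over all pairs.

    No distance cutoff; the Coulomb term uses dielectric 1.
    """
    rec = topology.group_indices(receptor_group)
    lig = topology.group_indices(ligand_group)
    if np.intersect1d(rec, lig).size:
        raise AnalysisError("receptor and ligand groups overlap")
    _require_parameterised(topology, rec)
    _require_parameterised(topology, lig)
    X = np.asarray(frame, dtype=float)
    d = np.linalg.norm(X[rec][:, None, :] - X[lig][None, :, :], axis=2)
    if np.any(d <= 0):
        raise AnalysisError("coincident receptor/ligand atoms (r = 0)")
    rmin = topology.lj_rmin_half[rec][:, None] + topology.lj_rmin_half[lig][None, :]
    eps = np.sqrt(topology.lj_epsilon[rec][:, None] * topology.lj_epsilon[lig][None, :])
    q6 = (rmin / d) ** 6
    e_vdw = float((eps * (q6 * q6 - 2.0 * q6)).sum())
    qq = topology.charges[rec][:, None] * topology.charges[lig][None, :]
    e_ele = float((COULOMB_CONSTANT * qq / d).sum())
    return e_vdw, e_ele


def _gb_f(r2: np.ndarray, aij: np.ndarray) -> np.ndarray:
    """Still's generalized-Born effective distance f_GB."""
    return np.sqrt(r2 + aij * np.exp(-r2 / (4.0 * aij)))


def born_reaction_field(charges: np.ndarray, born_radii: np.ndarray,
                        positions: np.ndarray,
                        eps_in: float = DEFAULT_EPS_IN,
                        eps_out: float = DEFAULT_EPS_OUT) -> float:
    """Still-type pairwise generalized-Born solvation energy (kcal/mol).

    ``-166.0318 (1/eps_in - 1/eps_out) * sum_ij qi qj / f_GB(r_ij)`` over all
    ordered pairs including i = j, where ``f_GB = sqrt(r^2 + ai aj
    exp(-r^2 / 4 ai aj))``. A single charge reduces to the Born ion formula
    ``-166.0318 q^2 (1/eps_in - 1/eps_out) / a``.
    """
    if not eps_out > eps_in >= 1:
        raise AnalysisError("require eps_out > eps_in >= 1")
    q = np.asarray(charges, dtype=float)
    a = np.asarray(born_radii, dtype=float)
    X = np.asarray(positions, dtype=float)
    if np.any(a <= 0) or np.any(~np.isfinite(a)):
        raise ParameterError("Born radii must be positive and finite")
    tau = 1.0 / eps_in - 1.0 / eps_out
    r2 = ((X[:, None, :] - X[None, :, :]) ** 2).sum(axis=2)
    f = _gb_f(r2, a[:, None] * a[None, :])
    return float(-BORN_CONSTANT * tau * (q[:, None] * q[None, :] / f).sum())


def reaction_field_binding(frame: np.ndarray, topology: Topology,
                           receptor_group: str = "receptor",
                           ligand_group: str = "ligand",
                           eps_in: float = DEFAULT_EPS_IN,
                           eps_out: float = DEFAULT_EPS_OUT) -> float:
    """G_RF of binding: GB(complex) - GB(receptor) - GB(ligand).

    With fixed Born radii the self and intra-group terms cancel, leaving the
    cross receptor-ligand screening term; that is what is evaluated.
    """
    rec = topology.group_indices(receptor_group)
    lig = topology.group_indices(ligand_group)
    q = topology.charges
    a = topology.born_radii
    if np.any(~np.isfinite(a[np.concatenate([rec, lig])])):
        raise ParameterError("Born radii missing for some atoms")
    X = np.asarray(frame, dtype=float)
    tau = 1.0 / eps_in - 1.0 / eps_out
    r2 = ((X[rec][:, None, :] - X[lig][None, :, :]) ** 2).sum(axis=2)
    f = _gb_f(r2, a[rec][:, None] * a[lig][None, :])
    return float(-BORN_CONSTANT * tau * 2.0 * (q[rec][:, None] * q[lig][None, :] / f).sum())


def delta_sasa(frame: np.ndarray, topology: Topology,
               receptor_group: str = "receptor", ligand_group: str = "ligand",
               sasa_params: SASAParams = SASAParams()) -> float:
    """Buried area on binding: SASA(complex) - SASA(receptor) - SASA(ligand)."""
    rec = topology.group_indices(receptor_group)
    lig = topology.group_indices(ligand_group)
    both = np.concatenate([rec, lig])
    s_complex = shrake_rupley_sasa(frame, topology, sasa_params, indices=both).sum()
    s_rec = shrake_rupley_sasa(frame, topology, sasa_params, indices=rec).sum()
    s_lig = shrake_rupley_sasa(frame, topology, sasa_params, indices=lig).sum()
    return float(s_complex - s_rec - s_lig)


def cavity_term(delta_sa: float, gamma: float = 0.013) -> float:
    """Nonpolar (cavity) term: gamma * dSASA, kcal/mol."""
    return gamma * delta_sa


def sie_combine(components: SIEComponents,
                coeffs: SIECoefficients = SIECoefficients()) -> float:
    """Combine the four SIE terms into the binding free energy (kcal/mol)."""
    return coeffs.alpha * (components.e_vdw + components.cavity
                           + components.e_ele + components.g_rf) + coeffs.constant


def _snapshot_indices(window: range, n_snapshots: int) -> np.ndarray:
    frames = np.asarray(list(window), dtype=int)
    if len(frames) < n_snapshots:
        raise AnalysisError(
            f"window has {len(frames)} frames, fewer than the "
            f"{n_snapshots} requested snapshots")
    pick = np.unique(np.round(np.linspace(0, len(frames) - 1, n_snapshots)).astype(int))
    return frames[pick]


def sie_from_trajectory(traj: Trajectory,
                        coeffs: SIECoefficients = SIECoefficients(),
                        window: range | None = None,
                        n_snapshots: int = 100,
                        sasa_params: SASAParams = SASAParams(),
                        eps_in: float = DEFAULT_EPS_IN,
                        eps_out: float = DEFAULT_EPS_OUT,
                        receptor_group: str = "receptor",
                        ligand_group: str = "ligand") -> SIEResult:
    """SIE binding free energy over evenly spaced snapshots of a window.

    The window defaults to the final 10% of the trajectory (the equilibrium
    phase convention); ``n_snapshots`` evenly spaced frames, first and last
    included, are evaluated and the mean and sample SD reported.
    """
    if window is None:
        window = traj.window(last_fraction=0.1)
    snaps = _snapshot_indices(window, n_snapshots)
    rows = []
    for f in snaps:
        frame = traj.frames[f]
        e_vdw, e_ele = intermolecular_terms(frame, traj.topology,
                                            receptor_group, ligand_group)
        g_rf = reaction_field_binding(frame, traj.topology, receptor_group,
                                      ligand_group, eps_in, eps_out)
        dsa = delta_sasa(frame, traj.topology, receptor_group, ligand_group,
                         sasa_params)
        cav = cavity_term(dsa, coeffs.gamma)
        dg = sie_combine(SIEComponents(e_vdw, e_ele, g_rf, cav), coeffs)
        rows.append((int(f), traj.times[f], e_vdw, e_ele, g_rf, dsa, cav, dg))
    df = pd.DataFrame(rows, columns=["frame_index", "time_ps", "e_vdw", "e_ele",
                                     "g_rf", "delta_sasa", "cavity", "dg_bind"])
    sd = float(df["dg_bind"].std(ddof=1)) if len(df) > 1 else 0.0
    return SIEResult(per_snapshot=df, mean=float(df["dg_bind"].mean()),
                     sd=sd, coefficients=coeffs)


def per_residue_decomposition(traj: Trajectory,
                              window: range | None = None,
                              n_snapshots: int = 25,
                              gamma: float = 0.013,
                              sasa_params: SASAParams = SASAParams(),
                              eps_in: float = DEFAULT_EPS_IN,
                              eps_out: float = DEFAULT_EPS_OUT,
                              receptor_group: str = "receptor",
                              ligand_group: str = "ligand",
                              threshold: float = KEY_RESIDUE_THRESHOLD,
                              include_solvation: bool = True) -> pd.DataFrame:
    """Residue-wise binding-energy decomposition, averaged over snapshots.

    Per receptor residue: ``vdw_term`` = pairwise Lennard-Jones with the
    ligand plus the residue's nonpolar-solvation share (gamma times the
    residue's buried SASA); ``ele_term`` = pairwise Coulomb plus the
    residue's share of the generalized-Born cross term; ``total`` is their
    sum and drives the key-residue flag (total < threshold). The pairwise
    parts sum over residues exactly to the intermolecular totals.

    ``include_solvation=False`` restricts the decomposition to the pairwise
    vacuum terms (useful for conservation checks).
    """
    top = traj.topology
    rec = top.group_indices(receptor_group)
    lig = top.group_indices(ligand_group)
    _require_parameterised(top, rec)
    _require_parameterised(top, lig)
    if window is None:
        window = traj.window(last_fraction=0.1)
    snaps = _snapshot_indices(window, min(n_snapshots, len(window)))
    res_of = top.residue_seqs[rec]
    residues = np.unique(res_of)
    res_pos = {r: k for k, r in enumerate(residues)}
    row_res = np.array([res_pos[r] for r in res_of])
    acc = {name: np.zeros(len(residues))
           for name in ("vdw_pair", "ele_pair", "polar", "nonpolar")}
    qr, ql = top.charges[rec], top.charges[lig]
    ar, al = top.born_radii[rec], top.born_radii[lig]
    rmin = top.lj_rmin_half[rec][:, None] + top.lj_rmin_half[lig][None, :]
    eps = np.sqrt(top.lj_epsilon[rec][:, None] * top.lj_epsilon[lig][None, :])
    tau = 1.0 / eps_in - 1.0 / eps_out
    for f in snaps:
        X = traj.frames[f]
        d2 = ((X[rec][:, None, :] - X[lig][None, :, :]) ** 2).sum(axis=2)
        d = np.sqrt(d2)
        q6 = (rmin / d) ** 6
        vdw = (eps * (q6 * q6 - 2.0 * q6)).sum(axis=1)
        ele = (COULOMB_CONSTANT * qr[:, None] * ql[None, :] / d).sum(axis=1)
        np.add.at(acc["vdw_pair"], row_res, vdw)
        np.add.at(acc["ele_pair"], row_res, ele)
        if include_solvation:
            fgb = _gb_f(d2, ar[:, None] * al[None, :])
            pol = (-BORN_CONSTANT * tau * 2.0 * qr[:, None] * ql[None, :] / fgb
                   ).sum(axis=1)
            np.add.at(acc["polar"], row_res, pol)
            both = np.concatenate([rec, lig])
            s_cplx = shrake_rupley_sasa(X, top, sasa_params, indices=both)
            s_rec = shrake_rupley_sasa(X, top, sasa_params, indices=rec)
            datom = s_cplx[: len(rec)] - s_rec  # receptor-atom buried SASA
            np.add.at(acc["nonpolar"], row_res, gamma * datom)
    for name in acc:
        acc[name] /= len(snaps)
    names = [top.residue_name_of(int(r)) for r in residues]
    df = pd.DataFrame({
        "residue_seq": residues,
        "residue_name": names,
        "vdw_pair": acc["vdw_pair"],
        "ele_pair": acc["ele_pair"],
        "polar_solv": acc["polar"],
        "nonpolar_solv": acc["nonpolar"],
    })
    df["vdw_term"] = df["vdw_pair"] + df["nonpolar_solv"]
    df["ele_term"] = df["ele_pair"] + df["polar_solv"]
    df["total"] = df["vdw_term"] + df["ele_term"]
    df["is_key"] = df["total"] < threshold
    return df


def key_residues(decomposition: pd.DataFrame,
                 threshold: float = KEY_RESIDUE_THRESHOLD) -> pd.DataFrame:
    """Residues with total contribution strictly below the threshold.

    A residue at exactly the threshold is excluded ("lower than" is strict).
    Sorted by total ascending (most stabilising first).
    """
    out = decomposition[decomposition["total"] < threshold]
    return out.sort_values("total", ascending=True, ignore_index=True)
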