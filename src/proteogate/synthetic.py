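"""Synthetic-data generators with known ground truth.

Every input the pipeline consumes can be generated here: noisy
Michaelis–Menten grids under a stated inhibition mechanism, dose–response
curves, multi-exponential stopped-flow traces, cooperative k_obs series from
the two-state gating model, and toy two-chain structures with planted ionic
contacts or a pseudo alpha-ring with a planted square of carboxylate
centroids.  All randomness flows through an explicit integer seed (never
global state) and identical arguments + seed give identical output, bitwise
for text files.

Noise models: reaction rates and k_obs carry multiplicative relative noise
(rate data are heteroscedastic with roughly constant CV); absorbance traces
carry additive Gaussian noise (detector noise is amplitude-independent).

The module-level default grids are the simulated study conditions: inhibitor
6–100 µM on a 6x6 substrate grid, porphyrin 0.2–100 µM log-spaced for k_obs
series, 5 s / 1 kHz stopped-flow records.
"""

from __future__ import annotations

from dataclasses import asdict, is_dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .gating import KobsSeries, kobs_model
from .params import (
    DoseResponseParams,
    InhibitionParams,
    ProgressPhases,
    ReferenceFixture,
    ToyComplexSpec,
    TwoStateParams,
    get_fixture,
)
from .steady_state import DoseResponse, MichaelisDataset, rate_law
from .stopped_flow import ProgressCurve

__all__ = [
    "gen_michaelis",
    "gen_dose_response",
    "gen_progress_curve",
    "gen_kobs_series",
    "gen_toy_complex",
    "gen_pseudo_ring",
    "generate_fixture",
    "write_provenance",
    "MM_S_GRID",
    "MM_I_GRID",
    "DOSE_I_GRID",
    "SF_T_GRID",
    "KOBS_X_GRID",
]

# default study-condition grids
MM_S_GRID = np.geomspace(10.0, 200.0, 6)                       # µM
MM_I_GRID = np.concatenate([[0.0], np.geomspace(6.0, 100.0, 5)])  # µM
DOSE_I_GRID = np.geomspace(0.05, 50.0, 10)                     # µM
SF_T_GRID = np.linspace(0.0, 5.0, 1000)                        # s
KOBS_X_GRID = np.geomspace(0.2e-6, 100e-6, 15)                 # M

DEFAULT_NOISE = {
    "michaelis_cv": 0.03,
    "dose_cv": 0.03,
    "progress_sd": 0.002,
    "kobs_cv": 0.05,
}


# ---------------------------------------------------------------------------
# Kinetic data
# ---------------------------------------------------------------------------


def gen_michaelis(mechanism: str, params: InhibitionParams,
                  s_grid=MM_S_GRID, i_grid=MM_I_GRID,
                  noise_cv: float = 0.0, seed: int = 0) -> MichaelisDataset:
    """Simulate one rate per (S, I) pair: rate-law value x (1 + N(0, cv)).

    Negative draws (possible only at large ``noise_cv``) are clipped at zero.
    The true mechanism and parameters are recorded in ``provenance``.
    """
    s_grid = np.asarray(s_grid, dtype=float)
    i_grid = np.asarray(i_grid, dtype=float)
    if np.any(s_grid <= 0) or np.any(i_grid < 0):
        raise ValueError("concentrations must be positive (I may include 0)")
    if noise_cv < 0:
        raise ValueError("noise_cv must be >= 0")
    S, I = map(np.ravel, np.meshgrid(s_grid, i_grid, indexing="ij"))
    truth = rate_law(mechanism, S, I, params)
    rng = np.random.default_rng(seed)
    v = truth * (1.0 + noise_cv * rng.standard_normal(truth.shape))
    return MichaelisDataset(
        S, I, np.clip(v, 0.0, None),
        provenance={"mechanism": mechanism, "seed": seed, "noise_cv": noise_cv,
                    **{k: v_ for k, v_ in asdict(params).items() if v_ is not None}},
    )


def gen_dose_response(ic50: float, hill: float = 1.0, i_grid=DOSE_I_GRID,
                      noise_cv: float = 0.0, seed: int = 0) -> DoseResponse:
    """Fractional activity a(I) = 1/(1 + (I/IC50)^h) x (1 + N(0, cv))."""
    if not ic50 > 0 or not hill > 0:
        raise ValueError("ic50 and hill must be > 0")
    i_grid = np.asarray(i_grid, dtype=float)
    if i_grid.size == 0:
        raise ValueError("empty concentration grid")
    truth = 1.0 / (1.0 + (i_grid / ic50) ** hill)
    rng = np.random.default_rng(seed)
    a = truth * (1.0 + noise_cv * rng.standard_normal(truth.shape))
    return DoseResponse(i_grid, a,
                        provenance={"ic50": ic50, "hill": hill, "seed": seed,
                                    "noise_cv": noise_cv})


def gen_progress_curve(phases: Sequence[tuple[float, float]], offset: float,
                       t_grid=SF_T_GRID, noise_sd: float = 0.0,
                       seed: int = 0, **meta) -> ProgressCurve:
    """Simulate A(t) = offset + sum a_i·exp(-k_i·t) + N(0, sd).

    Raises on duplicate rates (within 1e-9), which would make any fit of the
    same model class ill-conditioned.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    rates = np.array([k for _, k in phases], dtype=float)
    if np.any(rates <= 0):
        raise ValueError("phase rates must be > 0")
    if rates.size > 1:
        r = np.sort(rates)
        if np.any(np.diff(r) < 1e-9):
            raise ValueError("duplicate phase rates (within 1e-9): ill-conditioned")
    A = np.full_like(t_grid, float(offset))
    for a, k in phases:
        A = A + a * np.exp(-k * t_grid)
    rng = np.random.default_rng(seed)
    if noise_sd > 0:
        A = A + noise_sd * rng.standard_normal(t_grid.shape)
    return ProgressCurve(t_grid, A,
                         provenance={"phases": list(map(tuple, phases)),
                                     "offset": offset, "noise_sd": noise_sd,
                                     "seed": seed}, **meta)


def gen_kobs_series(params: TwoStateParams, x_grid=KOBS_X_GRID,
                    noise_cv: float = 0.0, seed: int = 0) -> KobsSeries:
    """k_obs(x) from the gating model with lognormal relative noise.

    The bimolecular law is used automatically when ``params`` has no
    closed-state branch.  The noise factor is mean-one lognormal with
    coefficient of variation ``noise_cv``.
    """
    x_grid = np.asarray(x_grid, dtype=float)
    if np.any(x_grid <= 0):
        raise ValueError("x grid must be > 0")
    if noise_cv < 0:
        raise ValueError("noise_cv must be >= 0")
    truth = kobs_model(x_grid, params)
    k = np.asarray(truth, dtype=float).copy()
    if noise_cv > 0:
        rng = np.random.default_rng(seed)
        sigma = np.sqrt(np.log1p(noise_cv**2))
        k = k * rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=k.shape)
    return KobsSeries(x_grid, k, system=params.label)


# ---------------------------------------------------------------------------
# Toy structures
# ---------------------------------------------------------------------------

_NEG_ATOMS = {"GLU": ("CA", "CB", "CG", "CD", "OE1", "OE2"),
              "ASP": ("CA", "CB", "CG", "OD1", "OD2")}
_POS_ATOMS = {"LYS": ("CA", "CE", "NZ"), "ARG": ("CA", "CZ", "NE", "NH1", "NH2")}


def _pdb_atom(serial: int, name: str, resname: str, chain: str, resseq: int,
              xyz, element: str) -> str:
    name_f = f" {name:<3s}" if len(name) < 4 else name
    x, y, z = xyz
    return (f"ATOM  {serial:5d} {name_f}{'':1s}{resname:>3s} {chain}"
            f"{resseq:4d}    {x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{0.00:6.2f}"
            f"          {element:>2s}")


def _neg_residue_atoms(resname: str, anchor: np.ndarray) -> list[tuple[str, np.ndarray, str]]:
    """Side-chain atoms of an acidic residue with its primary carboxylate
    oxygen exactly at ``anchor``; all other atoms sit at x < anchor_x."""
    ax, ay, az = anchor
    if resname == "GLU":
        return [("CA", np.array([ax - 3.4, ay, az + 0.5]), "C"),
                ("CB", np.array([ax - 2.6, ay + 0.4, az]), "C"),
                ("CG", np.array([ax - 1.8, ay - 0.4, az]), "C"),
                ("CD", np.array([ax - 0.9, ay + 0.2, az]), "C"),
                ("OE1", anchor.copy(), "O"),
                ("OE2", np.array([ax - 0.9, ay + 1.4, az]), "O")]
    if resname == "ASP":
        return [("CA", np.array([ax - 3.0, ay, az + 0.5]), "C"),
                ("CB", np.array([ax - 2.2, ay + 0.4, az]), "C"),
                ("CG", np.array([ax - 1.0, ay, az]), "C"),
                ("OD1", anchor.copy(), "O"),
                ("OD2", np.array([ax - 1.0, ay + 1.3, az]), "O")]
    raise ValueError(f"negative residue must be GLU or ASP, got {resname!r}")


def _pos_residue_atoms(resname: str, anchor: np.ndarray) -> list[tuple[str, np.ndarray, str]]:
    """Basic residue with its primary charged nitrogen exactly at ``anchor``;
    all other atoms sit at x > anchor_x (farther from the partner)."""
    ax, ay, az = anchor
    if resname == "LYS":
        return [("CA", np.array([ax + 3.0, ay, az + 0.3]), "C"),
                ("CE", np.array([ax + 1.3, ay + 0.4, az]), "C"),
                ("NZ", anchor.copy(), "N")]
    if resname == "ARG":
        return [("CA", np.array([ax + 3.5, ay, az + 0.3]), "C"),
                ("CZ", np.array([ax + 0.9, ay, az]), "C"),
                ("NE", np.array([ax + 1.4, ay + 1.0, az]), "N"),
                ("NH1", anchor.copy(), "N"),
                ("NH2", np.array([ax + 1.3, ay - 1.1, az]), "N")]
    raise ValueError(f"positive residue must be LYS or ARG, got {resname!r}")


def gen_toy_complex(pairs: Sequence[tuple[str, str, float]], decoys: int = 0,
                    seed: int = 0) -> str:
    """PDB text of a two-chain complex with planted ionic contacts.

    Each requested pair places an acidic side-chain oxygen in chain A at
    exactly the stated distance from a basic side-chain nitrogen in chain B;
    every other atom of the pair is farther away, so the minimum-distance
    atom pair is the planted one.  Decoys are charged residues (alternating
    acidic in chain A / basic in chain B) placed > 8 Å from any opposite
    charge.
    """
    rng = np.random.default_rng(seed)
    lines = ["HEADER    SYNTHETIC TOY COMPLEX",
             "TITLE     PLANTED IONIC CONTACT FIXTURE"]
    serial = 1
    resseq_a = resseq_b = 0
    for i, (neg, pos, dist) in enumerate(pairs):
        if not dist > 0:
            raise ValueError("planted distances must be > 0")
        y = 30.0 * i
        anchor_neg = np.array([0.0, y, 0.0])
        anchor_pos = np.array([float(dist), y, 0.0])
        resseq_a += 1
        for name, xyz, el in _neg_residue_atoms(neg.upper(), anchor_neg):
            lines.append(_pdb_atom(serial, name, neg.upper(), "A", resseq_a, xyz, el))
            serial += 1
        resseq_b += 1
        for name, xyz, el in _pos_residue_atoms(pos.upper(), anchor_pos):
            lines.append(_pdb_atom(serial, name, pos.upper(), "B", resseq_b, xyz, el))
            serial += 1
    for j in range(decoys):
        y = 30.0 * (len(pairs) + j) + rng.uniform(-2.0, 2.0)
        if j % 2 == 0:  # acidic decoy, chain A, far +z
            resseq_a += 1
            anchor = np.array([rng.uniform(-3, 3), y, 60.0])
            for name, xyz, el in _neg_residue_atoms("GLU", anchor):
                lines.append(_pdb_atom(serial, name, "GLU", "A", resseq_a, xyz, el))
                serial += 1
        else:  # basic decoy, chain B, far -z
            resseq_b += 1
            anchor = np.array([rng.uniform(-3, 3), y, -60.0])
            for name, xyz, el in _pos_residue_atoms("LYS", anchor):
                lines.append(_pdb_atom(serial, name, "LYS", "B", resseq_b, xyz, el))
                serial += 1
    lines.append("END")
    return "\n".join(lines) + "\n"


def gen_pseudo_ring(n_subunits: int = 7, square_side: float = 17.0,
                    seed: int = 0, ring_radius: float = 40.0,
                    scatter_per_subunit: int = 2) -> str:
    """PDB text of a pseudo alpha-ring with a planted carboxylate square.

    ``n_subunits`` pseudo-subunits (one chain each) sit on a circle of radius
    ``ring_radius``; each carries ``scatter_per_subunit`` glutamates with
    randomly scattered carboxylate centroids.  One exact square of side
    ``square_side`` is planted in the groove between the first two subunits
    (residues 900+; two corners per groove chain), so a geometry match at
    that side length has a known best hit.
    """
    if n_subunits < 4:
        raise ValueError("n_subunits must be >= 4")
    if not square_side > 0:
        raise ValueError("square_side must be > 0")
    rng = np.random.default_rng(seed)
    chains = [chr(ord("A") + i) for i in range(n_subunits)]
    lines = ["HEADER    SYNTHETIC PSEUDO ALPHA-RING",
             "TITLE     PLANTED CARBOXYLATE SQUARE FIXTURE"]
    serial = 1

    def add_glu(chain: str, resseq: int, centroid: np.ndarray, nonlocal_serial):
        """Glutamate whose OE1/OE2 midpoint is exactly ``centroid``."""
        s = nonlocal_serial[0]
        half = np.array([1.1, 0.0, 0.0])
        atoms = [("CA", centroid + np.array([-3.0, 1.5, 0.8]), "C"),
                 ("CD", centroid + np.array([-0.8, 0.9, 0.0]), "C"),
                 ("OE1", centroid + half, "O"),
                 ("OE2", centroid - half, "O")]
        for name, xyz, el in atoms:
            lines.append(_pdb_atom(s, name, "GLU", chain, resseq, xyz, el))
            s += 1
        nonlocal_serial[0] = s

    ser = [serial]
    for i, chain in enumerate(chains):
        theta = 2.0 * np.pi * i / n_subunits
        center = ring_radius * np.array([np.cos(theta), np.sin(theta), 0.0])
        for r in range(scatter_per_subunit):
            offset = rng.uniform(-5.0, 5.0, size=3)
            offset[2] = rng.uniform(-3.0, 3.0)
            add_glu(chain, 10 + r, center + offset, ser)

    # planted square in the groove between subunits 0 and 1, tangent plane
    theta_g = np.pi / n_subunits
    c = ring_radius * np.array([np.cos(theta_g), np.sin(theta_g), 0.0])
    u = np.array([-np.sin(theta_g), np.cos(theta_g), 0.0])  # tangential
    w = np.array([0.0, 0.0, 1.0])
    h = square_side / 2.0
    corners = [c + du * h * u + dw * h * w
               for du, dw in ((-1, -1), (-1, 1), (1, -1), (1, 1))]
    for j, corner in enumerate(corners):
        add_glu(chains[j % 2], 900 + j, corner, ser)

    lines.append("END")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Fixture dispatch and provenance
# ---------------------------------------------------------------------------


def write_provenance(path, info: dict) -> None:
    """Plain-text key-value sidecar recording truth parameters and seed."""
    with open(path, "w") as fh:
        for k, v in info.items():
            fh.write(f"{k}: {v}\n")


def generate_fixture(name: str, seed: Optional[int] = None,
                     out_dir: Optional[str] = None, noiseless: bool = False):
    """Generate a registered reference fixture under its default conditions.

    Returns the generated object; with ``out_dir`` also writes the dataset
    (CSV, or PDB for structures) plus a provenance sidecar.
    """
    fx = get_fixture(name)
    seed = fx.seed if seed is None else int(seed)
    p = fx.params
    if fx.kind == "kobs":
        cv = 0.0 if noiseless else DEFAULT_NOISE["kobs_cv"]
        obj = gen_kobs_series(p, KOBS_X_GRID, noise_cv=cv, seed=seed)
        payload, ext = obj.to_frame(), "csv"
    elif fx.kind == "inhibition":
        cv = 0.0 if noiseless else DEFAULT_NOISE["michaelis_cv"]
        obj = gen_michaelis(p.mechanism, p, MM_S_GRID, MM_I_GRID,
                            noise_cv=cv, seed=seed)
        payload, ext = obj.to_frame(), "csv"
    elif fx.kind == "dose_response":
        cv = 0.0 if noiseless else DEFAULT_NOISE["dose_cv"]
        obj = gen_dose_response(p.ic50, p.hill, DOSE_I_GRID, noise_cv=cv, seed=seed)
        payload, ext = obj.to_frame(), "csv"
    elif fx.kind == "progress":
        sd = 0.0 if noiseless else DEFAULT_NOISE["progress_sd"]
        obj = gen_progress_curve(p.phases, p.offset, SF_T_GRID,
                                 noise_sd=sd, seed=seed, ligand_M=5e-6,
                                 enzyme_M=1e-9)
        payload, ext = obj.to_frame(), "csv"
    elif fx.kind == "toy_complex":
        obj = gen_toy_complex(p.pairs, p.decoys, seed=seed)
        payload, ext = obj, "pdb"
    elif fx.kind == "pseudo_ring":
        obj = gen_pseudo_ring(p["n_subunits"], p["square_side"], seed=seed)
        payload, ext = obj, "pdb"
    else:  # pragma: no cover
        raise ValueError(f"unhandled fixture kind {fx.kind!r}")

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        target = out / f"{name}.{ext}"
        if ext == "pdb":
            target.write_text(payload)
        else:
            payload.to_csv(target, index=False)
        prov = {"fixture": name, "seed": seed, "kind": fx.kind}
        if is_dataclass(p):
            prov.update({k: v for k, v in asdict(p).items() if v is not None})
        elif isinstance(p, dict):
            prov.update(p)
        write_provenance(out / f"{name}.provenance.txt", prov)
    return obj
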