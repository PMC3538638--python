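"""Seeded synthetic data: toy-dimer trajectories with programmable
hydrogen-bond behaviour, Michaelis–Menten rate tables and two-state melting
curves.

These generators stand in for MD production runs and wet-lab assays so that
every downstream stage (bond tracing and classification, clustering, kinetic
and melt fitting, mechanism reporting) can be exercised and validated
end-to-end.  They emulate the *observed phenomenology* — distance traces that
sit at ~3 Å, step to 5 or 7 Å, or flicker between states; saturating rate
curves; sigmoidal 222 nm melts — not the underlying physics: there is no
force field, no solvent and no thermodynamics here.

All randomness flows from a single integer seed through independent
``numpy.random.Generator`` substreams, so outputs are bitwise reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .structure import Frame, Topology, Trajectory, DEFAULT_FRAME_SPACING_PS

__all__ = [
    "BondProgram",
    "AssayTruth",
    "make_toy_dimer",
    "simulate_trajectory",
    "simulate_kinetics",
    "simulate_melting_curve",
]


@dataclass(frozen=True)
class BondProgram:
    """Prescribed behaviour of one monitored donor–acceptor distance.

    kind
        ``"stable"``: stays at ``baseline_distance``.
        ``"breaking"``: steps from baseline to ``broken_distance`` at
        ``break_fraction`` of the trajectory (the 3 Å → 5 Å and 3 Å → 7 Å
        step patterns seen for broken bonds in variant simulations).
        ``"intermittent"``: two-state flicker with per-frame switching
        probability ``switch_prob`` (a "clear fluctuation" trace).
    jitter_sd
        Gaussian noise (Å) added to the programmed distance each frame.
    """

    kind: str = "stable"
    baseline_distance: float = 3.0
    broken_distance: float = 5.0
    break_fraction: float = 0.5
    switch_prob: float = 0.05
    jitter_sd: float = 0.15

    def __post_init__(self) -> None:
        if self.kind not in ("stable", "breaking", "intermittent"):
            raise ValueError(f"unknown bond program kind {self.kind!r}")
        if not 0 < self.baseline_distance < self.broken_distance:
            raise ValueError("require 0 < baseline_distance < broken_distance")
        if not 0 <= self.break_fraction <= 1:
            raise ValueError("break_fraction must lie in [0, 1]")
        if not 0 <= self.switch_prob <= 1:
            raise ValueError("switch_prob must lie in [0, 1]")
        if self.jitter_sd < 0:
            raise ValueError("jitter_sd must be >= 0")

    def target_distances(self, n_frames: int, rng: np.random.Generator) -> np.ndarray:
        """Noise-free per-frame target distance trace (Å)."""
        if self.kind == "stable":
            return np.full(n_frames, self.baseline_distance)
        if self.kind == "breaking":
            d = np.full(n_frames, self.baseline_distance)
            d[int(np.floor(self.break_fraction * n_frames)):] = self.broken_distance
            return d
        # intermittent: start bound, flip state with switch_prob each frame
        flips = rng.random(n_frames - 1) < self.switch_prob
        state = np.concatenate([[0], np.cumsum(flips) % 2])  # 0 = bound
        return np.where(state == 0, self.baseline_distance, self.broken_distance)


@dataclass(frozen=True)
class AssayTruth:
    """Ground-truth assay parameters for one protein variant.

    Units match the reporting convention of the kinetics/stability stages:
    ``v_max`` µmol·min⁻¹·mg⁻¹, ``k_m`` µM, ``k_cat`` s⁻¹, ``t_m`` °C.
    ``noise_sd`` is relative (fractional) on rates and absolute (mdeg) on
    ellipticity.  ``None`` marks a quantity not determined for that variant.
    """

    v_max: float | None = None
    k_m: float | None = None
    k_cat: float | None = None
    t_m: float | None = None
    noise_sd: float = 0.05

    def __post_init__(self) -> None:
        for name in ("v_max", "k_m", "k_cat", "t_m"):
            val = getattr(self, name)
            if val is not None and val <= 0:
                raise ValueError(f"{name} must be positive when given")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


# one polar side-chain heavy atom per residue type (toy reduction)
_SIDE_ATOM: dict[str, str | None] = {
    "SER": "OG", "THR": "OG1", "TYR": "OH", "ASN": "ND2", "GLN": "NE2",
    "ASP": "OD1", "GLU": "OE1", "LYS": "NZ", "ARG": "NH1", "HIS": "NE2",
    "TRP": "NE1", "ALA": "CB", "VAL": "CB", "LEU": "CB", "ILE": "CB",
    "PHE": "CB", "MET": "CB", "CYS": "SG", "PRO": "CB", "GLY": None,
}


def make_toy_dimer(
    n_residues_per_chain: int,
    seed: int,
    residue_types: Mapping[int, str] | None = None,
    default_residue: str = "SER",
    chain_separation: float = 8.0,
) -> Frame:
    """A deterministic two-chain reference structure.

    Each chain (labels A and B) is an extended backbone with residues spaced
    3.8 Å apart carrying N, CA, C, O plus one polar side-chain atom whose
    name follows the residue type (``residue_types`` overrides the default
    type per residue number; glycine gets no side-chain atom).  A small
    seeded perturbation (< 0.3 Å) breaks exact collinearity.
    """
    if n_residues_per_chain < 4:
        raise ValueError("toy dimer needs at least 4 residues per chain")
    rng = np.random.default_rng(seed)
    residue_types = dict(residue_types or {})

    chains, resnums, resnames, atoms, coords = [], [], [], [], []
    for ci, (chain, y0) in enumerate([("A", 0.0), ("B", chain_separation)]):
        for r in range(1, n_residues_per_chain + 1):
            resname = residue_types.get(r, default_residue).upper()
            x = 3.8 * (r - 1)
            template = [
                ("N", (x, y0, 0.0)),
                ("CA", (x + 1.2, y0 + 0.5, 0.0)),
                ("C", (x + 2.4, y0, 0.0)),
                ("O", (x + 2.4, y0 - 1.2, 0.4)),
            ]
            side = _SIDE_ATOM.get(resname, "CB")
            if side is not None:
                template.append((side, (x + 1.2, y0 + 1.9, 0.5)))
            for name, xyz in template:
                chains.append(chain)
                resnums.append(r)
                resnames.append(resname)
                atoms.append(name)
                coords.append(xyz)
    coords = np.asarray(coords, dtype=float)
    coords += rng.normal(0.0, 0.1, size=coords.shape)  # deterministic wobble
    top = Topology(chains, resnums, resnames, atoms)
    return Frame(top, coords, time=0.0)


def _resolve_single(topology: Topology, address: tuple[str, int, str]) -> int:
    chain, resnum, atom = address
    return topology.index_of(chain, resnum, atom)


def simulate_trajectory(
    reference: Frame,
    programs: Mapping,
    n_frames: int = 500,
    seed: int = 0,
    frame_spacing_ps: float = DEFAULT_FRAME_SPACING_PS,
    global_jitter_sd: float = 0.15,
    label: str = "",
) -> Trajectory:
    """Jitter a reference structure into an ensemble, forcing programmed
    donor–acceptor distances to follow their :class:`BondProgram`.

    ``programs`` maps bond watches (anything with single-atom ``donor`` and
    ``acceptor`` address tuples, e.g. :class:`mfe2dh.hbonds.BondWatch`) to
    programs.  Every atom receives isotropic Gaussian jitter around the
    reference; each programmed *acceptor* atom is then re-placed along the
    reference donor→acceptor axis so the realized distance equals the
    programmed target plus the program's own jitter.  Donor atoms stay near
    the reference, so the distance trace is exact by construction (a
    piecewise-constant trace when ``jitter_sd=0``).
    """
    if n_frames < 2:
        raise ValueError("a trajectory needs at least 2 frames")
    top = reference.topology
    root = np.random.SeedSequence(seed)
    streams = root.spawn(1 + len(programs))
    rng_global = np.random.default_rng(streams[0])

    coords = reference.coords[None, :, :] + rng_global.normal(
        0.0, global_jitter_sd, size=(n_frames, top.n_atoms, 3)
    )

    for (watch, program), stream in zip(programs.items(), streams[1:]):
        rng = np.random.default_rng(stream)
        donor = getattr(watch, "donor", None) or watch[0]
        acceptor = getattr(watch, "acceptor", None) or watch[1]
        i_d = _resolve_single(top, tuple(donor))
        i_a = _resolve_single(top, tuple(acceptor))
        axis = reference.coords[i_a] - reference.coords[i_d]
        norm = np.linalg.norm(axis)
        if norm == 0:
            raise ValueError(f"degenerate watch: donor and acceptor coincide at {donor}")
        axis = axis / norm
        d = program.target_distances(n_frames, rng)
        if program.jitter_sd > 0:
            d = d + rng.normal(0.0, program.jitter_sd, size=n_frames)
        coords[:, i_a, :] = coords[:, i_d, :] + d[:, None] * axis[None, :]

    times = np.arange(n_frames, dtype=float) * frame_spacing_ps
    return Trajectory(top, coords, times, label=label)


def simulate_kinetics(
    truth: AssayTruth,
    substrate_grid,
    seed: int = 0,
    noise_sd: float | None = None,
) -> pd.DataFrame:
    """Michaelis–Menten rate table ``(substrate_uM, rate)`` with relative
    Gaussian noise: ``rate = Vmax·S/(Km+S) · (1 + ε)``, ``ε ~ N(0, noise_sd)``.
    """
    S = np.asarray(list(substrate_grid), dtype=float)
    if S.size == 0:
        raise ValueError("substrate grid is empty")
    if np.any(S <= 0):
        raise ValueError("substrate concentrations must be positive")
    if truth.v_max is None or truth.k_m is None:
        raise ValueError("assay truth lacks v_max/k_m (kinetics not determined)")
    sd = truth.noise_sd if noise_sd is None else noise_sd
    rng = np.random.default_rng(seed)
    v = truth.v_max * S / (truth.k_m + S)
    rate = v * (1.0 + rng.normal(0.0, sd, size=S.shape)) if sd > 0 else v
    return pd.DataFrame({"substrate_uM": S, "rate": rate})


def simulate_melting_curve(
    truth: AssayTruth,
    t_grid,
    seed: int = 0,
    noise_sd: float | None = None,
    folded_baseline: tuple[float, float] = (-20.0, 0.02),
    unfolded_baseline: tuple[float, float] = (-4.0, 0.01),
    transition_slope: float = 0.4,
) -> pd.DataFrame:
    """Two-state 222 nm melt ``(temperature_C, ellipticity)``.

    Signal is a logistic transition between linear folded and unfolded
    baselines with midpoint ``truth.t_m`` and slope ``transition_slope``
    (1/°C); noise is additive Gaussian in mdeg.  At T = t_m the noiseless
    signal is exactly the midpoint of the two local baselines.
    """
    T = np.asarray(list(t_grid), dtype=float)
    if T.size < 2 or not np.all(np.diff(T) > 0):
        raise ValueError("temperature grid must be ascending with >= 2 points")
    if truth.t_m is None:
        raise ValueError("assay truth lacks t_m")
    sd = truth.noise_sd if noise_sd is None else noise_sd
    bf = folded_baseline[0] + folded_baseline[1] * T
    bu = unfolded_baseline[0] + unfolded_baseline[1] * T
    frac = 1.0 / (1.0 + np.exp(-transition_slope * (T - truth.t_m)))
    signal = bf + (bu - bf) * frac
    if sd > 0:
        signal = signal + np.random.default_rng(seed).normal(0.0, sd, size=T.shape)
    return pd.DataFrame({"temperature_C": T, "ellipticity": signal})
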