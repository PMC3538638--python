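"""Hydrogen-bond persistence analysis over coordinate ensembles.

The central quantities: for each watched donor–acceptor pair, the per-frame
shortest heavy-atom distance (minimum over atom groups such as the
arginine NH1/NH2 pair), the *occupancy* — the fraction of analysis-window
frames with distance at or below a 3.5 Å threshold — and a stable (+) /
fluctuating (−) call per monomer, with the consensus requiring stability in
both monomers of the dimer.

No angular criterion is applied by default: the classification follows the
shortest-distance convention, using heavy atoms only.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .chemistry import GROUP_SHORTHAND, enumerate_donors_acceptors
from .structure import MissingAtomError, Trajectory

__all__ = [
    "BondWatch",
    "BondTrace",
    "StabilityCall",
    "HBondParams",
    "trace_bond",
    "occupancy",
    "classify_bond",
    "find_replacement_partners",
    "bond_report",
    "load_watchlist",
]

AtomAddress = tuple[str, int, str]

STABLE = "+"
FLUCTUATING = "-"


@dataclass(frozen=True)
class BondWatch:
    """A donor–acceptor pair to monitor.

    Addresses are ``(chain, residue_number, atom_name)``; the atom name may
    be group shorthand (``NH`` → NH1/NH2, ``OE`` → OE1/OE2, ``OD`` →
    OD1/OD2), in which case the monitored distance is the per-frame minimum
    over the group.  ``scope`` is ``intra_monomer`` when donor and acceptor
    share a chain, ``inter_monomer`` otherwise; it is inferred when omitted.
    """

    donor: AtomAddress
    acceptor: AtomAddress
    scope: str | None = None
    label: str = ""

    def __post_init__(self) -> None:
        donor = (str(self.donor[0]), int(self.donor[1]), str(self.donor[2]))
        acceptor = (str(self.acceptor[0]), int(self.acceptor[1]), str(self.acceptor[2]))
        object.__setattr__(self, "donor", donor)
        object.__setattr__(self, "acceptor", acceptor)
        inferred = "intra_monomer" if donor[0] == acceptor[0] else "inter_monomer"
        if self.scope is None:
            object.__setattr__(self, "scope", inferred)
        elif self.scope != inferred:
            raise ValueError(
                f"scope {self.scope!r} inconsistent with chains "
                f"{donor[0]!r}/{acceptor[0]!r}"
            )

    @property
    def name(self) -> str:
        d, a = self.donor, self.acceptor
        return f"{d[0]}:{d[1]}:{d[2]}-{a[0]}:{a[1]}:{a[2]}"

    def in_chains(self, donor_chain: str, acceptor_chain: str) -> "BondWatch":
        """The same residue/atom pair re-addressed to other chains."""
        return BondWatch(
            (donor_chain, self.donor[1], self.donor[2]),
            (acceptor_chain, self.acceptor[1], self.acceptor[2]),
            label=self.label,
        )


@dataclass
class BondTrace:
    """Per-frame donor–acceptor distance for one watch."""

    watch: BondWatch
    times: np.ndarray
    distances: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.distances = np.asarray(self.distances, dtype=float)
        if self.times.shape != self.distances.shape:
            raise ValueError("times and distances length mismatch")
        if np.any(self.distances <= 0):
            raise ValueError("distances must be positive")

    @property
    def n_frames(self) -> int:
        return len(self.distances)


@dataclass(frozen=True)
class HBondParams:
    """Classification parameters.

    threshold
        Donor–acceptor heavy-atom distance defining a formed bond (Å).
    window
        Analysis window as a fraction interval of the trajectory; the
        default ``(0.4, 1.0)`` discards the first 40% as equilibration
        (20 ns of a 50 ns run).
    occupancy_cutoff
        Minimum within-window occupancy for a stable (+) call.
    """

    threshold: float = 3.5
    window: tuple[float, float] = (0.4, 1.0)
    occupancy_cutoff: float = 0.70

    def __post_init__(self) -> None:
        if self.threshold <= 0:
            raise ValueError("threshold must be positive")
        lo, hi = self.window
        if not 0 <= lo < hi <= 1:
            raise ValueError("window must satisfy 0 <= start < end <= 1")


@dataclass
class StabilityCall:
    """Per-monomer occupancies/calls and the AND-consensus for one watch."""

    watch: BondWatch
    per_monomer: dict[str, tuple[float, str]]
    params: HBondParams

    @property
    def consensus(self) -> str:
        return STABLE if all(c == STABLE for _, c in self.per_monomer.values()) else FLUCTUATING

    @property
    def occupancy(self) -> float:
        """Worst-case (minimum) per-monomer occupancy."""
        return min(occ for occ, _ in self.per_monomer.values())


def _resolve_group(topology, address: AtomAddress) -> list[int]:
    """Atom indices for an address, expanding group shorthand to the atoms
    actually present (at least one must exist)."""
    chain, resnum, atom = address
    if atom in GROUP_SHORTHAND:
        present = set(topology.residue_atom_names(chain, resnum))
        indices = [
            topology.index_of(chain, resnum, member)
            for member in GROUP_SHORTHAND[atom]
            if member in present
        ]
        if not indices:
            raise MissingAtomError(
                f"no atom of group {atom!r} ({'/'.join(GROUP_SHORTHAND[atom])}) "
                f"in chain {chain!r} residue {resnum}"
            )
        return indices
    return [topology.index_of(chain, resnum, atom)]


def trace_bond(traj: Trajectory, watch: BondWatch) -> BondTrace:
    """Per-frame shortest heavy-atom distance for a watch.

    For group shorthand on either side the distance is the per-frame minimum
    over all donor-atom × acceptor-atom combinations.
    """
    di = _resolve_group(traj.topology, watch.donor)
    ai = _resolve_group(traj.topology, watch.acceptor)
    # (frames, donors, acceptors) pairwise distances, reduced by min
    diff = traj.coords[:, di, None, :] - traj.coords[:, None, ai, :]
    dist = np.sqrt((diff**2).sum(axis=-1)).min(axis=(1, 2))
    return BondTrace(watch, traj.times.copy(), dist)


def _window_slice(n_frames: int, window: tuple[float, float]) -> slice:
    lo, hi = window
    if not 0 <= lo < hi <= 1:
        raise ValueError("window must satisfy 0 <= start < end <= 1")
    start = int(np.floor(lo * n_frames))
    stop = int(np.floor(hi * n_frames)) if hi < 1 else n_frames
    if stop <= start:
        raise ValueError("analysis window contains no frames")
    return slice(start, stop)


def occupancy(
    trace: BondTrace,
    threshold: float = 3.5,
    window: tuple[float, float] = (0.4, 1.0),
) -> float:
    """Fraction of frames inside the window with distance <= threshold."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    sl = _window_slice(trace.n_frames, window)
    d = trace.distances[sl]
    return float(np.count_nonzero(d <= threshold) / d.size)


def _monomer_variants(traj: Trajectory, watch: BondWatch) -> dict[str, BondWatch]:
    """The directed per-monomer readings of a watch.

    Intra-monomer bonds are evaluated once per chain; inter-monomer bonds in
    both directed chain pairings (A→B and B→A for a dimer).
    """
    chains = traj.topology.chains
    if watch.scope == "intra_monomer":
        return {c: watch.in_chains(c, c) for c in chains}
    pairs: dict[str, BondWatch] = {}
    for cd in chains:
        for ca in chains:
            if cd != ca:
                pairs[f"{cd}->{ca}"] = watch.in_chains(cd, ca)
    return pairs


def classify_bond(
    traj: Trajectory,
    watch: BondWatch,
    params: HBondParams = HBondParams(),
) -> StabilityCall:
    """Stable/fluctuating call per monomer plus the AND consensus.

    A bond is stable in a monomer iff its within-window occupancy at the
    distance threshold reaches ``params.occupancy_cutoff``; the consensus is
    stable only if every per-monomer reading is stable (effects must be
    similar in both monomers of the dimer to count).
    """
    per: dict[str, tuple[float, str]] = {}
    for key, w in _monomer_variants(traj, watch).items():
        occ = occupancy(trace_bond(traj, w), params.threshold, params.window)
        per[key] = (occ, STABLE if occ >= params.occupancy_cutoff else FLUCTUATING)
    return StabilityCall(watch, per, params)


def find_replacement_partners(
    traj: Trajectory,
    watch: BondWatch,
    radius: float = 5.0,
    orphan: str = "donor",
    params: HBondParams = HBondParams(),
) -> list[tuple[AtomAddress, float]]:
    """Candidate replacement partners near the orphaned side of a lost bond.

    When a variant removes one partner of a native bond, the retained atom
    (``orphan='donor'`` keeps the donor and searches for new acceptors, and
    vice versa) may bond elsewhere.  Candidates are all complementary
    donor/acceptor atoms within ``radius`` Å of the orphaned atom in the
    first frame, excluding the original partner and the orphan's own
    residue; they are ranked by occupancy at the distance threshold
    (descending, ties by address).
    """
    if orphan not in ("donor", "acceptor"):
        raise ValueError("orphan must be 'donor' or 'acceptor'")
    ref = traj[0]
    donors, acceptors = enumerate_donors_acceptors(ref)
    kept_addr = watch.donor if orphan == "donor" else watch.acceptor
    lost_addr = watch.acceptor if orphan == "donor" else watch.donor
    candidates = acceptors if orphan == "donor" else donors

    kept_idx = _resolve_group(traj.topology, kept_addr)
    kept_pos = ref.coords[kept_idx].mean(axis=0)

    scored: list[tuple[AtomAddress, float]] = []
    for addr in candidates:
        if addr == lost_addr or addr[:2] == kept_addr[:2]:
            continue
        pos = ref.coords[traj.topology.index_of(*addr)]
        if np.linalg.norm(pos - kept_pos) > radius:
            continue
        pair = (
            BondWatch(kept_addr, addr) if orphan == "donor" else BondWatch(addr, kept_addr)
        )
        occ = occupancy(trace_bond(traj, pair), params.threshold, params.window)
        scored.append((addr, occ))
    scored.sort(key=lambda item: (-item[1], item[0]))
    return scored


def bond_report(
    trajectories: Mapping[str, Trajectory],
    watches: Sequence[BondWatch],
    params: HBondParams = HBondParams(),
    bond_ids: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Bond × variant matrix of +/− consensus calls with occupancies.

    Rows follow ``watches`` order (indexed by ``bond_ids`` or the watch
    name); for each variant there is a call column and a
    ``<variant>_occupancy`` column carrying the worst per-monomer occupancy.
    """
    if bond_ids is None:
        bond_ids = [w.name for w in watches]
    if len(bond_ids) != len(watches):
        raise ValueError("bond_ids length must match watches")
    data: dict[str, list] = {"scope": [w.scope for w in watches], "label": [w.label for w in watches]}
    for variant, traj in trajectories.items():
        calls, occs = [], []
        for w in watches:
            sc = classify_bond(traj, w, params)
            calls.append(sc.consensus)
            occs.append(round(sc.occupancy, 4))
        data[variant] = calls
        data[f"{variant}_occupancy"] = occs
    return pd.DataFrame(data, index=pd.Index(bond_ids, name="bond"))


def load_watchlist(path: str | Path) -> tuple[list[BondWatch], pd.DataFrame]:
    """Read a bond-watch TSV.

    Required columns: ``donor_chain donor_res donor_atom acceptor_chain
    acceptor_res acceptor_atom scope label``; extra columns (e.g. ``bond_id``,
    ``site`` or published per-variant calls) are returned untouched in the
    accompanying frame.
    """
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    required = [
        "donor_chain", "donor_res", "donor_atom",
        "acceptor_chain", "acceptor_res", "acceptor_atom", "scope", "label",
    ]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: watchlist missing columns {missing}")
    watches = [
        BondWatch(
            (row.donor_chain, int(row.donor_res), row.donor_atom),
            (row.acceptor_chain, int(row.acceptor_res), row.acceptor_atom),
            scope=row.scope or None,
            label=row.label,
        )
        for row in df.itertuples()
    ]
    return watches, df
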